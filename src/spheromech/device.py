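"""Extracorporeal-circuit coagulation metrics.

An in vitro hemodialysis run is monitored through the dialyzer inlet
pressure: as thrombus occludes hollow fibers the resistance rises and the
run is terminated at the *clotting time*, the first sample at which the
pressure rise strictly exceeds a threshold (a 50 % rise, equivalently
+25 mmHg from a 50 mmHg baseline). The module also computes clotting-time
prolongation between conditions, fiber occlusion ratios, activated
clotting time (ACT) deltas, thrombus-mass totals, and the ng/mL → nM dose
conversion used to relate an in vitro drug level to plasma exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Default inlet-pressure baseline, mmHg.
DEFAULT_BASELINE_MMHG = 50.0

#: Colchicine molar mass, g/mol (standard chemical constant).
COLCHICINE_MOLAR_MASS = 399.4


@dataclass
class PressureSeries:
    """Dialyzer inlet-pressure time series."""

    t: np.ndarray  # min
    pressure: np.ndarray  # mmHg
    baseline: float = DEFAULT_BASELINE_MMHG

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.t.size == 0:
            raise ValidationError("pressure series is empty")
        if self.pressure.shape != self.t.shape:
            raise ValidationError("time and pressure lengths differ")
        if not np.all(np.diff(self.t) > 0):
            raise ValidationError("time must be strictly increasing")
        if np.any(self.pressure <= 0):
            raise ValidationError("pressures must be positive")
        if self.baseline <= 0:
            raise ValidationError("baseline must be positive")


@dataclass(frozen=True)
class ClottingRule:
    """Termination rule: percent rise or absolute rise over baseline.

    The two forms coincide at the standard 50 mmHg baseline
    (+50 % ≡ +25 mmHg).
    """

    percent: float | None = 50.0
    absolute_mmHg: float | None = None

    def threshold_mmHg(self, baseline: float) -> float:
        if (self.percent is None) == (self.absolute_mmHg is None):
            raise ValidationError("specify exactly one of percent/absolute_mmHg")
        if self.percent is not None:
            return baseline * self.percent / 100.0
        return float(self.absolute_mmHg)


@dataclass
class RunOutcome:
    """Bundled metrics of one circuit run."""

    label: str
    clotting_time: float | None  # min; None when censored
    censored: bool
    act_delta: float | None  # s, last − first
    occlusion_ratio: float | None
    thrombus_mass: float | None  # mg, dialyzer + canister
    act_series: list = field(default_factory=list)


def percent_rise(baseline: float, current: float) -> float:
    """100 × (current − baseline) / baseline."""
    if baseline <= 0:
        raise ValidationError("baseline must be positive")
    return 100.0 * (current - baseline) / baseline


def clotting_time(series: PressureSeries,
                  rule: ClottingRule | None = None) -> float | None:
    """First timestamp whose rise strictly exceeds the rule threshold.

    No interpolation between samples; a series that never crosses returns
    None (censored). A series starting above threshold clots at its first
    timestamp.
    """
    rule = rule or ClottingRule()
    thr = rule.threshold_mmHg(series.baseline)
    above = series.pressure - series.baseline > thr
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return None
    return float(series.t[idx[0]])


def prolongation_percent(t_control: float, t_treated: float) -> float:
    """100 × (t_treated − t_control) / t_control."""
    if t_control <= 0:
        raise ValidationError("control clotting time must be positive")
    return 100.0 * (t_treated - t_control) / t_control


def occlusion_ratio(occluded_fibers: int, total_fibers: int) -> float:
    """Fraction of dialyzer fibers blocked by thrombus."""
    if total_fibers <= 0:
        raise ValidationError("total fiber count must be positive")
    if not 0 <= occluded_fibers <= total_fibers:
        raise ValidationError("occluded count must lie in [0, total]")
    return occluded_fibers / total_fibers


def dose_to_molar(conc_ng_per_ml: float, molar_mass: float) -> float:
    """ng/mL → nM: conc × 1000 / molar mass (g/mol)."""
    if molar_mass <= 0:
        raise ValidationError("molar mass must be positive")
    if conc_ng_per_ml < 0:
        raise ValidationError("concentration must be >= 0")
    return conc_ng_per_ml * 1000.0 / molar_mass


def molar_to_dose(conc_nM: float, molar_mass: float) -> float:
    """Inverse of :func:`dose_to_molar`: nM → ng/mL."""
    if molar_mass <= 0:
        raise ValidationError("molar mass must be positive")
    return conc_nM * molar_mass / 1000.0


def summarize_run(series: PressureSeries, act_pairs: list[tuple[float, float]],
                  occluded_fibers: int | None = None,
                  total_fibers: int | None = None,
                  dialyzer_mass_mg: float | None = None,
                  canister_mass_mg: float | None = None,
                  rule: ClottingRule | None = None,
                  label: str = "") -> RunOutcome:
    """Bundle clotting time, ACT delta, occlusion ratio and thrombus mass."""
    ct = clotting_time(series, rule)
    act_delta = None
    if act_pairs:
        act_delta = float(act_pairs[-1][1] - act_pairs[0][1])
    ratio = None
    if occluded_fibers is not None and total_fibers is not None:
        ratio = occlusion_ratio(occluded_fibers, total_fibers)
    mass = None
    if dialyzer_mass_mg is not None:
        mass = float(dialyzer_mass_mg) + float(canister_mass_mg or 0.0)
    return RunOutcome(
        label=label,
        clotting_time=ct,
        censored=ct is None,
        act_delta=act_delta,
        occlusion_ratio=ratio,
        thrombus_mass=mass,
        act_series=list(act_pairs),
    )
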