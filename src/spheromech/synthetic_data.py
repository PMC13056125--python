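"""Seeded generators for every input the analysis modules consume.

Each generator emulates the statistical structure of one experimental data
stream — AFM force–displacement curves with a terminal rupture jump and
optional pre-rupture peaks, donor-emission/acceptor-excitation spectral
bands, platelet rolling/sliding tracks, dialyzer inlet-pressure and ACT
series with logistic clot growth, discoid-fraction shape kinetics, and
two-region FLIM efficiency maps — so the downstream estimators can be
exercised, and validated against recorded ground truth, without any
external data. Noise is additive i.i.d. Gaussian throughout; every
generator takes one explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import fret
from .errors import CalibrationError, ValidationError
from .force_spectroscopy import ForceCurve, default_peak_sigma
from .kinematics import TrackedPlatelet
from .device import PressureSeries

__all__ = [
    "CurveSpec", "SpectraSpec", "TrackSpec", "DeviceSpec", "KineticsSpec",
    "DeviceRun", "gen_force_curve", "gen_spectra", "calibrate_spectra_to_r0",
    "gen_track", "gen_cohort", "gen_pressure_series",
    "occlusion_growth_for_clot_time", "gen_shape_kinetics", "gen_flim_map",
]


# --------------------------------------------------------------------------
# specifications

@dataclass(frozen=True)
class CurveSpec:
    """Parameters of one synthetic force–displacement curve.

    The rupture force is drawn from Normal(rupture_mean, rupture_sd); each
    entry of ``peak_amplitudes_sd_units`` injects one pre-rupture bump of
    that amplitude in units of the noise SD (or of ``peak_force_scale`` pN
    when ``noise_sd`` is zero).
    """

    mode: str = "tangential"
    rupture_mean: float = 39.9  # pN
    rupture_sd: float = 6.5  # pN
    peak_amplitudes_sd_units: tuple = ()
    peak_force_scale: float = 1.0  # pN per SD unit at zero noise
    noise_sd: float = 2.0  # pN
    n_points: int = 4096
    displacement_span: float = 200.0  # nm
    condition: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("tangential", "normal"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.n_points < 64:
            raise ValidationError("n_points must be >= 64")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.rupture_mean <= 0:
            raise ValidationError("rupture_mean must be positive")
        if self.rupture_sd < 0:
            raise ValidationError("rupture_sd must be >= 0")
        if self.displacement_span <= 0:
            raise ValidationError("displacement_span must be positive")
        if self.peak_force_scale <= 0:
            raise ValidationError("peak_force_scale must be positive")
        object.__setattr__(self, "peak_amplitudes_sd_units",
                           tuple(float(a) for a in self.peak_amplitudes_sd_units))


@dataclass(frozen=True)
class SpectraSpec:
    """Gaussian donor-emission and acceptor-excitation bands.

    Defaults emulate a DiO-like emission band and a Rhodamine-B-like
    excitation band on a 400–700 nm grid.
    """

    donor_peak: float = 505.0  # nm
    donor_width: float = 20.0  # nm (Gaussian sigma)
    acceptor_peak: float = 555.0  # nm
    acceptor_width: float = 28.0  # nm
    acceptor_eps_max: float = 106_000.0  # M^-1 cm^-1
    grid_start: float = 400.0
    grid_stop: float = 700.0
    grid_step: float = 1.0

    def __post_init__(self) -> None:
        if self.donor_width <= 0 or self.acceptor_width <= 0:
            raise ValidationError("band widths must be positive")
        if self.acceptor_eps_max <= 0:
            raise ValidationError("acceptor_eps_max must be positive")
        if self.grid_step <= 0 or self.grid_stop <= self.grid_start:
            raise ValidationError("grid must be increasing with positive step")
        for peak, width, name in ((self.donor_peak, self.donor_width, "donor"),
                                  (self.acceptor_peak, self.acceptor_width,
                                   "acceptor")):
            if peak - 2 * width < self.grid_start or peak + 2 * width > self.grid_stop:
                raise ValidationError(f"grid does not cover the {name} band")


@dataclass(frozen=True)
class TrackSpec:
    """Parameters of one synthetic platelet wall track.

    ``slip`` couples rotation to translation for the rolling kind:
    1 = perfect no-slip rolling, 0 = the rolling contribution removed.
    """

    kind: str = "rolling"  # rolling | sliding
    radius: float = 1.25  # µm (typical platelet)
    speed: float = 1.0  # µm/s
    speed_profile: str = "constant"  # constant | accelerating | decelerating
    slip: float = 1.0
    noise_sd_pos: float = 0.0  # µm
    noise_sd_angle: float = 0.0  # deg per frame
    n_frames: int = 60
    dt: float = 1.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("rolling", "sliding"):
            raise ValidationError(f"unknown track kind {self.kind!r}")
        if self.speed_profile not in ("constant", "accelerating", "decelerating"):
            raise ValidationError(f"unknown speed profile {self.speed_profile!r}")
        if self.radius <= 0 or self.dt <= 0 or self.speed <= 0:
            raise ValidationError("radius, dt and speed must be positive")
        if not 0 <= self.slip <= 1:
            raise ValidationError("slip must lie in [0, 1]")
        if self.n_frames < 3:
            raise ValidationError("n_frames must be >= 3")
        if self.noise_sd_pos < 0 or self.noise_sd_angle < 0:
            raise ValidationError("noise SDs must be >= 0")


@dataclass(frozen=True)
class DeviceSpec:
    """Parameters of a dialyzer inlet-pressure / ACT run.

    Occlusion grows logistically from 1 % of ``occlusion_max`` with rate
    ``occlusion_growth``; pressure follows the parallel-conduit resistance
    model P = baseline / (1 − occlusion). ACT decays linearly.
    """

    baseline_pressure: float = 50.0  # mmHg
    occlusion_growth: float = 0.3  # per min (logistic rate)
    occlusion_max: float = 0.6  # fraction
    duration: float = 60.0  # min
    sample_interval: float = 1.0  # min
    act_baseline: float = 140.0  # s
    act_decay: float = 8.0 / 3.0  # s per min (140 -> 100 s over 15 min)
    noise_sd: float = 0.0  # mmHg
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_pressure <= 0:
            raise ValidationError("baseline_pressure must be positive")
        if not 0 <= self.occlusion_max < 1:
            raise ValidationError("occlusion_max must lie in [0, 1)")
        if self.duration <= 0 or self.sample_interval <= 0:
            raise ValidationError("duration and sample_interval must be positive")
        if self.occlusion_growth < 0 or self.noise_sd < 0:
            raise ValidationError("rates and noise must be >= 0")


@dataclass(frozen=True)
class KineticsSpec:
    """Discoid-fraction kinetics: drug-induced spherification and recovery.

    Piecewise single-exponential: decay from ``initial_discoid_fraction``
    toward ``plateau_fraction`` from t = 0, then relaxation toward
    ``recovery_plateau`` after the last of ``switch_times`` (drug removal).
    """

    initial_discoid_fraction: float = 0.90
    plateau_fraction: float = 0.10
    rate: float = 0.15  # per min
    recovery_plateau: float = 0.65
    recovery_rate: float = 0.08  # per min
    switch_times: tuple = (30.0, 60.0)  # min
    t_end_min: float = 120.0
    dt_min: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.initial_discoid_fraction, self.plateau_fraction,
                  self.recovery_plateau):
            if not 0 <= f <= 1:
                raise ValidationError("fractions must lie in [0, 1]")
        if self.rate < 0 or self.recovery_rate < 0:
            raise ValidationError("rates must be >= 0")
        st = tuple(float(s) for s in self.switch_times)
        if any(b <= a for a, b in zip(st, st[1:])):
            raise ValidationError("switch_times must be strictly increasing")
        if st and (st[0] < 0 or st[-1] > self.t_end_min):
            raise ValidationError("switch_times must lie within [0, t_end]")
        object.__setattr__(self, "switch_times", st)


# --------------------------------------------------------------------------
# force curves

def _curve_layout(n: int) -> tuple[int, int, int]:
    """(baseline length, ramp length, tail length) for an n-sample curve."""
    nb = max(24, round(0.2 * n))
    nt = max(2, n // 64)
    return nb, n - nb - nt, nt


def gen_force_curve(spec: CurveSpec, seed: int | None = None) -> ForceCurve:
    """One synthetic force–displacement record.

    Flat noisy baseline, a linear loading ramp descending to −F with
    F ~ Normal(rupture_mean, rupture_sd), injected Gaussian pre-rupture
    bumps (width shared with the detector's matched-filter template), a
    single-step jump back to ~0, and a short zero tail. Ground truth is
    recorded in ``metadata``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_points
    nb, nl, nt = _curve_layout(n)
    f_rupture = float(max(spec.rupture_mean + spec.rupture_sd * rng.standard_normal(),
                          1e-3))

    force = np.zeros(n)
    j = np.arange(1, nl + 1, dtype=float)
    force[nb:nb + nl] = -f_rupture * j / nl

    amps = spec.peak_amplitudes_sd_units
    scale = spec.noise_sd if spec.noise_sd > 0 else spec.peak_force_scale
    sig = default_peak_sigma(nl)
    if len(amps) == 1:
        fracs = [0.575]
    else:
        fracs = np.linspace(0.35, 0.8, len(amps))
    centers = [round(f * nl) for f in fracs]
    idx = np.arange(nl, dtype=float)
    for a, c in zip(amps, centers):
        force[nb:nb + nl] += a * scale * np.exp(-((idx - c) ** 2) / (2.0 * sig**2))

    if spec.noise_sd > 0:
        force += rng.normal(0.0, spec.noise_sd, n)

    return ForceCurve(
        displacement=np.linspace(0.0, spec.displacement_span, n),
        force=force,
        mode=spec.mode,
        condition=spec.condition,
        baseline_window=(0, nb),
        metadata={
            "generator": "gen_force_curve",
            "true_rupture_pN": f_rupture,
            "true_peak_amplitudes_sd_units": list(amps),
            "peak_sigma_samples": sig,
            "peak_centers": [nb + c for c in centers],
            "noise_sd": spec.noise_sd,
            "peak_force_scale": spec.peak_force_scale,
        },
    )


# --------------------------------------------------------------------------
# spectra

def gen_spectra(spec: SpectraSpec) -> tuple[fret.Spectrum, fret.Spectrum]:
    """(donor emission, acceptor excitation) Gaussian bands on one grid.

    The donor band is area-normalized on the grid (unit trapezoid area);
    the acceptor band peaks at ``acceptor_eps_max``.
    """
    lam = np.arange(spec.grid_start, spec.grid_stop + spec.grid_step / 2,
                    spec.grid_step)
    donor = np.exp(-((lam - spec.donor_peak) ** 2) / (2 * spec.donor_width**2))
    donor /= np.trapezoid(donor, lam)
    acceptor = spec.acceptor_eps_max * np.exp(
        -((lam - spec.acceptor_peak) ** 2) / (2 * spec.acceptor_width**2)
    )
    return fret.Spectrum(lam, donor), fret.Spectrum(lam.copy(), acceptor)


def calibrate_spectra_to_r0(spec: SpectraSpec, target_r0: float,
                            params: fret.FretParams | None = None) -> SpectraSpec:
    """Rescale ``acceptor_eps_max`` so the pair realizes a target R0.

    R0 ∝ ε_max^(1/6), so the rescaling is closed-form:
    ε'_max = ε_max (target/current)⁶.
    """
    if target_r0 <= 0:
        raise ValidationError("target R0 must be positive")
    donor, acceptor = gen_spectra(spec)
    j = fret.overlap_integral(donor, acceptor)
    if j <= 0:
        raise CalibrationError("spectra do not overlap; R0 cannot be calibrated")
    current = fret.forster_radius(j, params)
    return replace(spec,
                   acceptor_eps_max=spec.acceptor_eps_max * (target_r0 / current) ** 6)


# --------------------------------------------------------------------------
# tracks

def _speed_series(spec: TrackSpec) -> np.ndarray:
    n = spec.n_frames - 1  # frame-to-frame steps
    if spec.speed_profile == "constant":
        return np.full(n, spec.speed)
    if spec.speed_profile == "accelerating":
        return np.linspace(0.5 * spec.speed, 1.5 * spec.speed, n)
    return np.linspace(1.5 * spec.speed, 0.5 * spec.speed, n)


def wrap_angle_deg(theta: np.ndarray) -> np.ndarray:
    """Wrap angles into [−180, 180) deg."""
    return (np.asarray(theta) + 180.0) % 360.0 - 180.0


def gen_track(spec: TrackSpec, seed: int | None = None) -> TrackedPlatelet:
    """One platelet wall track (centroid + wrapped orientation series).

    Rolling kind: the per-frame unwrapped orientation increment is
    slip × (arc displacement / radius) plus angular noise; sliding kind:
    angular noise only. The motion runs along +x with the configured
    speed profile; positional noise is added to both coordinates.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    t = np.arange(spec.n_frames) * spec.dt
    ds = _speed_series(spec) * spec.dt
    x = np.concatenate([[0.0], np.cumsum(ds)])
    y = np.zeros(spec.n_frames)
    if spec.noise_sd_pos > 0:
        x = x + rng.normal(0.0, spec.noise_sd_pos, spec.n_frames)
        y = y + rng.normal(0.0, spec.noise_sd_pos, spec.n_frames)

    dtheta = np.zeros(spec.n_frames - 1)
    if spec.kind == "rolling":
        dtheta += spec.slip * (ds / spec.radius) * (180.0 / math.pi)
    if spec.noise_sd_angle > 0:
        dtheta += rng.normal(0.0, spec.noise_sd_angle, spec.n_frames - 1)
    theta_unwrapped = np.concatenate([[0.0], np.cumsum(dtheta)])

    group = "spherical" if spec.kind == "rolling" else "discoid"
    return TrackedPlatelet(
        t=t, x=x, y=y,
        orientation=wrap_angle_deg(theta_unwrapped),
        radius=spec.radius,
        group=group,
        metadata={"generator": "gen_track", "true_kind": spec.kind,
                  "true_slip": spec.slip},
    )


def gen_cohort(p_roll_a: float, p_roll_b: float, n_per_group: int,
               spec: TrackSpec, seed: int = 0) -> dict[str, list[TrackedPlatelet]]:
    """Two labeled track cohorts with group-specific rolling probabilities.

    Group "a" (spherical) rolls with probability ``p_roll_a``, group "b"
    (discoid) with ``p_roll_b``; non-rolling tracks are sliding. Per-track
    child seeds are drawn from the cohort seed, so the cohort is fully
    reproducible.
    """
    for p in (p_roll_a, p_roll_b):
        if not 0 <= p <= 1:
            raise ValidationError("rolling probabilities must lie in [0, 1]")
    if n_per_group < 1:
        raise ValidationError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    out: dict[str, list[TrackedPlatelet]] = {}
    for name, p, grp in (("a", p_roll_a, "spherical"), ("b", p_roll_b, "discoid")):
        tracks = []
        for i in range(n_per_group):
            rolls = bool(rng.random() < p)
            child = int(rng.integers(0, 2**31 - 1))
            tr = gen_track(
                replace(spec, kind="rolling" if rolls else "sliding"),
                seed=child,
            )
            tr.group = grp
            tr.id = f"{name}{i:04d}"
            tracks.append(tr)
        out[name] = tracks
    return out


# --------------------------------------------------------------------------
# device series

#: Initial occlusion as a fraction of occlusion_max in the logistic model.
LOGISTIC_SEED_FRACTION = 0.01


@dataclass
class DeviceRun:
    """Synthetic dialyzer run: pressure series, ACT pairs, true occlusion."""

    pressure: PressureSeries
    act_t: np.ndarray  # min
    act_s: np.ndarray  # s
    occlusion: np.ndarray  # true occluded fraction at each sample
    metadata: dict = field(default_factory=dict)


def _logistic_occlusion(t: np.ndarray, spec: DeviceSpec) -> np.ndarray:
    omax = spec.occlusion_max
    if omax == 0 or spec.occlusion_growth == 0:
        o0 = LOGISTIC_SEED_FRACTION * omax
        return np.full_like(t, o0, dtype=float)
    o0 = LOGISTIC_SEED_FRACTION * omax
    return omax / (1.0 + ((omax - o0) / o0) * np.exp(-spec.occlusion_growth * t))


def gen_pressure_series(spec: DeviceSpec, seed: int | None = None) -> DeviceRun:
    """Inlet-pressure and ACT time series under logistic clot growth.

    With ``occlusion_growth = 0`` the occluded fraction stays at its 1 %
    seed value and pressure is (nearly) constant at baseline.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    t = np.arange(0.0, spec.duration + spec.sample_interval / 2,
                  spec.sample_interval)
    if spec.occlusion_growth == 0:
        occlusion = np.zeros_like(t)
    else:
        occlusion = _logistic_occlusion(t, spec)
    pressure = spec.baseline_pressure / (1.0 - occlusion)
    if spec.noise_sd > 0:
        pressure = pressure + rng.normal(0.0, spec.noise_sd, t.size)
    act = np.maximum(spec.act_baseline - spec.act_decay * t, 1.0)
    return DeviceRun(
        pressure=PressureSeries(t=t, pressure=pressure,
                                baseline=spec.baseline_pressure),
        act_t=t.copy(), act_s=act,
        occlusion=occlusion,
        metadata={"generator": "gen_pressure_series", "spec": spec},
    )


def occlusion_growth_for_clot_time(spec: DeviceSpec, rise_mmHg: float,
                                   t_cross: float) -> float:
    """Logistic rate putting the pressure-rise crossing at ``t_cross`` min.

    Inverts P(t) = baseline/(1−o(t)) = baseline + rise for the logistic
    occlusion model, i.e. o(t_cross) = rise/(baseline + rise).
    """
    oc = rise_mmHg / (spec.baseline_pressure + rise_mmHg)
    omax = spec.occlusion_max
    if not 0 < oc < omax:
        raise ValidationError(
            f"crossing occlusion {oc:.3f} is not reachable below "
            f"occlusion_max {omax}"
        )
    o0 = LOGISTIC_SEED_FRACTION * omax
    return math.log(((omax - o0) / o0) * oc / (omax - oc)) / t_cross


# --------------------------------------------------------------------------
# shape kinetics

def gen_shape_kinetics(spec: KineticsSpec) -> pd.DataFrame:
    """Discoid-fraction time course (columns t_min, discoid_fraction, phase).

    Exponential decay toward ``plateau_fraction`` from t = 0; after the
    last switch time (drug removal) the fraction relaxes toward
    ``recovery_plateau`` with ``recovery_rate``. Phases: ``treatment``
    before the first switch, ``circulation`` between switches,
    ``recovery`` after the last.
    """
    t = np.arange(0.0, spec.t_end_min + spec.dt_min / 2, spec.dt_min)
    f0, fp = spec.initial_discoid_fraction, spec.plateau_fraction
    frac = fp + (f0 - fp) * np.exp(-spec.rate * t)
    if spec.switch_times:
        s_rec = spec.switch_times[-1]
        f_at_switch = fp + (f0 - fp) * math.exp(-spec.rate * s_rec)
        rec = spec.recovery_plateau - (
            (spec.recovery_plateau - f_at_switch)
            * np.exp(-spec.recovery_rate * np.maximum(t - s_rec, 0.0))
        )
        frac = np.where(t >= s_rec, rec, frac)
    phase = np.full(t.shape, "recovery", dtype=object)
    if spec.switch_times:
        phase[t < spec.switch_times[-1]] = "circulation"
        phase[t < spec.switch_times[0]] = "treatment"
    else:
        phase[:] = "treatment"
    return pd.DataFrame({"t_min": t, "discoid_fraction": np.clip(frac, 0, 1),
                         "phase": phase})


# --------------------------------------------------------------------------
# FLIM efficiency maps

def gen_flim_map(region_efficiencies: list[tuple[np.ndarray, float]],
                 noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """Per-pixel apparent-efficiency map from (mask, efficiency) regions.

    Pixels outside every mask are NaN; overlapping masks are rejected.
    """
    if not region_efficiencies:
        raise ValidationError("at least one region is required")
    masks = [np.asarray(m, dtype=bool) for m, _ in region_efficiencies]
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValidationError("all region masks must share one shape")
    if np.any(np.sum(masks, axis=0) > 1):
        raise ValidationError("region masks overlap")
    rng = np.random.default_rng(seed)
    out = np.full(shape, np.nan)
    for m, (_, e) in zip(masks, region_efficiencies):
        vals = np.full(int(m.sum()), float(e))
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, vals.size)
        out[m] = vals
    return out
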