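"""Constrained least-squares estimation of MAD parameters and ADC.

Per voxel, the normalized decay curve is fit twice: a log-linear ordinary
least squares fit over all b-values for the mono-exponential ADC, and a
bound-constrained nonlinear least squares fit of the four-compartment MAD
model. The MAD fit optimizes seven free parameters (D_r, D_h, D_f, alpha_h
and the fractions f_r, f_h, f_f); f_ui is the remainder 1 - f_r - f_h - f_f,
kept non-negative by a penalty residual, and D_ui is fixed at 3 um^2/ms.

Multi-exponential least squares has local minima, so the fit is multistarted
from a segmented log-linear initialization plus seeded jitter; the lowest
residual wins, ties broken by earliest start index, which makes the result
deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .model import (
    D_UI,
    ADCFit,
    BValueScheme,
    DegenerateInputError,
    MADParameters,
    SignalCurve,
    ValidationError,
    mad_signal,
)

__all__ = [
    "FitConfig",
    "MADFitResult",
    "ParameterMaps",
    "MAP_NAMES",
    "fit_adc",
    "initialize_mad",
    "fit_mad",
    "fit_volume",
]

# Free-parameter vector layout for the optimizer.
_FREE_NAMES = ("D_r", "D_h", "D_f", "alpha_h", "f_r", "f_h", "f_f")
_EPS = 1e-9
_LOWER = np.array([0.0, 0.2, 3.0 + _EPS, 1e-6, 0.0, 0.0, 0.0])
_UPPER = np.array([0.2 - _EPS, 3.0, 100.0, 2.0, 1.0, 1.0, 1.0])

#: Quantities written by fit_volume, one 3D grid each.
MAP_NAMES = (
    "D_r", "D_h", "D_f", "f_r", "f_h", "f_ui", "f_f", "alpha_h",
    "ADC", "r_squared", "converged",
)


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings shared by the ADC and MAD fits.

    ``n_multistart`` starts are tried per voxel: the segmented-heuristic
    initialization first, then seeded jittered copies. ``min_signal_floor``
    is the fraction of S(0) below which samples are dropped from log fits.
    """

    n_multistart: int = 8
    max_iterations: int = 400
    residual_tolerance: float = 1e-14
    relative_step_tolerance: float = 1e-14
    seed: int = 0
    min_signal_floor: float = 1e-6
    penalty_weight: float = 100.0
    lower: tuple[float, ...] = tuple(_LOWER)
    upper: tuple[float, ...] = tuple(_UPPER)

    def __post_init__(self) -> None:
        if self.n_multistart < 1:
            raise ValidationError("n_multistart must be >= 1")
        if self.residual_tolerance <= 0 or self.relative_step_tolerance <= 0:
            raise ValidationError("tolerances must be > 0")
        object.__setattr__(self, "lower", tuple(float(v) for v in self.lower))
        object.__setattr__(self, "upper", tuple(float(v) for v in self.upper))


@dataclass(frozen=True)
class MADFitResult:
    """One voxel's MAD fit: parameters plus diagnostics."""

    params: MADParameters
    residual_norm: float
    r_squared: float
    converged: bool
    n_starts_tried: int
    at_bound_flags: dict[str, bool] = field(default_factory=dict)


@dataclass
class ParameterMaps:
    """Voxel-wise grids of fitted quantities sharing one spatial geometry.

    Unfitted voxels (outside the mask, S(0) below floor, failed fits) hold
    NaN. ``converged`` is 1.0/0.0 on fitted voxels and NaN elsewhere.
    """

    maps: dict[str, np.ndarray]
    affine: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.maps.values()}
        if len(shapes) > 1:
            raise ValidationError(f"map grids disagree on shape: {shapes}")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.maps.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]


def fit_adc(curve: SignalCurve, config: FitConfig = FitConfig()) -> ADCFit:
    """Mono-exponential ADC by OLS of ln(signal) on b over all usable points.

    Points with signal <= ``min_signal_floor`` are dropped, not clamped.
    Deterministic; a negative slope estimate is reported with adc < 0.
    """
    curve = curve.normalize()
    y = curve.array
    b = curve.scheme.b_array
    usable = y > config.min_signal_floor
    if int(usable.sum()) < 2:
        raise DegenerateInputError(
            f"need >= 2 points above the signal floor, got {int(usable.sum())}"
        )
    bu, logy = b[usable], np.log(y[usable])
    slope, intercept = np.polyfit(bu, logy, 1)
    pred = slope * bu + intercept
    ss_res = float(np.sum((logy - pred) ** 2))
    ss_tot = float(np.sum((logy - logy.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return ADCFit(
        adc=float(-slope),
        intercept=float(intercept),
        r_squared=r2,
        n_points_used=int(usable.sum()),
    )


def _log_slope(b: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS slope/intercept of ln(y) on b; assumes y > 0."""
    slope, intercept = np.polyfit(b, np.log(y), 1)
    return float(slope), float(intercept)


def initialize_mad(curve: SignalCurve) -> MADParameters:
    """Segmented log-linear start point for the MAD fit.

    The curve is split into a low-b segment (b <= 0.1 ms/um^2, dominated by
    flow), a mid segment (0.2 <= b <= 1.0, hindered/unimpeded) and a high-b
    plateau (b >= 2.0, restricted). Log-linear slopes over the segments seed
    the diffusivities and fractions; alpha_h starts at 1.
    """
    curve = curve.normalize()
    b = curve.scheme.b_array
    y = np.maximum(curve.array, 1e-12)

    low = b <= 0.1
    mid = (b >= 0.2) & (b <= 1.0)
    high = b >= 2.0
    if int(low.sum()) < 2 or int(high.sum()) < 1:
        raise DegenerateInputError(
            "scheme must include at least two b <= 0.1 and one b >= 2.0 ms/um^2"
        )
    if int(mid.sum()) < 2:
        raise DegenerateInputError("scheme must include two points in 0.2 <= b <= 1.0")

    slope_low, _ = _log_slope(b[low], y[low])
    slope_mid, icept_mid = _log_slope(b[mid], y[mid])

    # Fast-decaying share: signal missing at b=0 from the mid-range
    # extrapolation. Slow plateau share: mean high-b signal.
    f_f0 = float(np.clip(1.0 - np.exp(icept_mid), 0.02, 0.6))
    f_r0 = float(np.clip(np.mean(y[high]), 0.005, 0.6))
    rate_low = max(-slope_low, 0.0)
    D_f0 = float(np.clip(rate_low / max(f_f0, 0.05), 5.0, 60.0))
    D_h0 = float(np.clip(-slope_mid, 0.25, 2.9))

    f_h0 = max(1.0 - f_f0 - f_r0, 0.02) * 0.6
    f_ui0 = max(1.0 - f_f0 - f_r0, 0.02) * 0.4
    fr = np.clip(np.array([f_r0, f_h0, f_ui0, f_f0]), 0.01, 0.97)
    fr = fr / fr.sum()

    return MADParameters(
        D_r=0.05, D_h=D_h0, D_f=D_f0, alpha_h=1.0,
        f_r=float(fr[0]), f_h=float(fr[1]), f_ui=float(fr[2]), f_f=float(fr[3]),
    )


def _params_to_x(p: MADParameters) -> np.ndarray:
    return np.array([p.D_r, p.D_h, p.D_f, p.alpha_h, p.f_r, p.f_h, p.f_f])


def _x_to_params(x: np.ndarray) -> MADParameters:
    f_r, f_h, f_f = x[4], x[5], x[6]
    f_ui = 1.0 - f_r - f_h - f_f
    fr = np.maximum(np.array([f_r, f_h, f_ui, f_f]), 0.0)
    fr = fr / fr.sum()
    return MADParameters(
        D_r=float(np.clip(x[0], 0.0, 0.2 - _EPS)),
        D_h=float(np.clip(x[1], 0.2, 3.0)),
        D_f=float(np.clip(x[2], 3.0 + _EPS, 100.0)),
        alpha_h=float(np.clip(x[3], 1e-6, 2.0)),
        f_r=float(fr[0]), f_h=float(fr[1]), f_ui=float(fr[2]), f_f=float(fr[3]),
    )


def _residuals(x: np.ndarray, b: np.ndarray, y: np.ndarray, penalty: float) -> np.ndarray:
    D_r, D_h, D_f, alpha, f_r, f_h, f_f = x
    f_ui = 1.0 - f_r - f_h - f_f
    model = (
        f_r * np.exp(-D_r * b)
        + f_h * np.exp(-D_h * b ** alpha)
        + f_ui * np.exp(-D_UI * b)
        + f_f * np.exp(-D_f * b)
    )
    res = model - y
    # keep the remainder fraction non-negative
    return np.append(res, penalty * max(0.0, -f_ui))


def _jitter_start(x0: np.ndarray, rng: np.random.Generator, lo: np.ndarray, up: np.ndarray) -> np.ndarray:
    x = x0.copy()
    x[0] = x0[0] * rng.lognormal(0.0, 0.6)                      # D_r
    x[1] = x0[1] * rng.lognormal(0.0, 0.3)                      # D_h
    x[2] = x0[2] * rng.lognormal(0.0, 0.5)                      # D_f
    x[3] = np.clip(x0[3] + rng.normal(0.0, 0.25), 0.3, 1.8)     # alpha_h
    fr = np.array([x0[4], x0[5], 1.0 - x0[4] - x0[5] - x0[6], x0[6]])
    fr = np.maximum(fr * rng.lognormal(0.0, 0.4, size=4), 1e-3)
    fr = fr / fr.sum()
    x[4], x[5], x[6] = fr[0], fr[1], fr[3]
    return np.clip(x, lo + 1e-12, up - 1e-12)


def _global_start(rng: np.random.Generator, lo: np.ndarray, up: np.ndarray) -> np.ndarray:
    """A start point dispersed over the whole feasible box, independent of
    the heuristic init — guards against basins the init cannot reach (e.g.
    D_h near the fixed unimpeded rate)."""
    fr = rng.dirichlet([1.0, 2.0, 1.5, 1.0])
    x = np.array([
        rng.uniform(0.005, 0.18),       # D_r
        rng.uniform(0.3, 2.9),          # D_h
        np.exp(rng.uniform(np.log(4.0), np.log(80.0))),  # D_f
        rng.uniform(0.5, 1.5),          # alpha_h
        fr[0], fr[1], fr[3],
    ])
    return np.clip(x, lo + 1e-12, up - 1e-12)


def fit_mad(curve: SignalCurve, config: FitConfig = FitConfig()) -> MADFitResult:
    """Fit the MAD model to one normalized curve by multistart trust-region
    least squares within the physiological bounds.

    Never raises on optimizer failure: if no start converges, the best
    attempt is returned with ``converged=False`` so downstream stages can
    drop the voxel.
    """
    if not curve.normalized:
        raise ValidationError("fit_mad requires a normalized curve")
    if not curve.scheme.supports_mad_fit:
        raise ValidationError(
            f"MAD fit needs >= 6 distinct b-values, scheme has {len(curve.scheme)}"
        )
    b = curve.scheme.b_array
    y = curve.array
    lo, up = np.asarray(config.lower), np.asarray(config.upper)

    try:
        x_init = _params_to_x(initialize_mad(curve))
    except DegenerateInputError:
        x_init = np.array([0.05, 1.0, 15.0, 1.0, 0.1, 0.4, 0.2])
    x_init = np.clip(x_init, lo + 1e-12, up - 1e-12)

    rng = np.random.default_rng(config.seed)
    starts = [x_init]
    for s in range(config.n_multistart - 1):
        if s % 2 == 0:
            starts.append(_jitter_start(x_init, rng, lo, up))
        else:
            starts.append(_global_start(rng, lo, up))

    best = None
    best_cost = np.inf
    any_converged = False
    for idx, x0 in enumerate(starts):
        sol = least_squares(
            _residuals, x0, bounds=(lo, up),
            args=(b, y, config.penalty_weight),
            method="trf", x_scale="jac",
            ftol=config.residual_tolerance,
            xtol=config.relative_step_tolerance,
            gtol=1e-15,
            max_nfev=config.max_iterations * len(x0),
        )
        any_converged = any_converged or sol.status > 0
        # strict < keeps the earliest start on exact ties
        if sol.cost < best_cost:
            best_cost = sol.cost
            best = sol

    params = _x_to_params(best.x)
    resid = _residuals(best.x, b, y, config.penalty_weight)[:-1]
    residual_norm = float(np.linalg.norm(resid))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    tol = 1e-7
    at_bound = {
        name: bool(best.x[i] - lo[i] < tol * (up[i] - lo[i])
                   or up[i] - best.x[i] < tol * (up[i] - lo[i]))
        for i, name in enumerate(_FREE_NAMES)
    }
    return MADFitResult(
        params=params,
        residual_norm=residual_norm,
        r_squared=max(min(r2, 1.0), -np.inf),
        converged=bool(any_converged),
        n_starts_tried=len(starts),
        at_bound_flags=at_bound,
    )


def fit_volume(
    dwi: np.ndarray,
    scheme: BValueScheme,
    mask: np.ndarray,
    config: FitConfig = FitConfig(),
    affine: np.ndarray | None = None,
) -> ParameterMaps:
    """Voxel-by-voxel MAD + ADC fitting of a 4D volume.

    Each masked voxel is normalized by its own measured S(0) and fit
    independently with the same seed, so the result does not depend on the
    voxel visit order. Voxels whose b=0 signal is at or below the floor, or
    whose MAD fit fails to converge, become NaN in every map.
    """
    dwi = np.asarray(dwi, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if dwi.ndim != 4:
        raise ValidationError(f"dwi must be 4D, got shape {dwi.shape}")
    if dwi.shape[3] != len(scheme):
        raise ValidationError(
            f"dwi has {dwi.shape[3]} volumes but scheme has {len(scheme)} b-values"
        )
    if mask.shape != dwi.shape[:3]:
        raise ValidationError(
            f"mask shape {mask.shape} does not match spatial dims {dwi.shape[:3]}"
        )
    if not mask.any():
        raise DegenerateInputError("mask selects no voxels")

    if affine is None:
        affine = np.eye(4)
    maps = {name: np.full(dwi.shape[:3], np.nan) for name in MAP_NAMES}

    for ijk in np.argwhere(mask):
        i, j, k = (int(v) for v in ijk)
        sig = dwi[i, j, k, :]
        s0 = sig[0]
        if s0 <= config.min_signal_floor:
            continue
        curve = SignalCurve(scheme, np.maximum(sig, 0.0) / s0, normalized=False)
        curve = SignalCurve(scheme, np.append(1.0, curve.array[1:]), normalized=True)
        res = fit_mad(curve, config)
        if not res.converged:
            continue
        try:
            adc = fit_adc(curve, config)
        except DegenerateInputError:
            continue
        p = res.params
        for name, val in (
            ("D_r", p.D_r), ("D_h", p.D_h), ("D_f", p.D_f),
            ("f_r", p.f_r), ("f_h", p.f_h), ("f_ui", p.f_ui), ("f_f", p.f_f),
            ("alpha_h", p.alpha_h), ("ADC", adc.adc),
            ("r_squared", res.r_squared), ("converged", 1.0),
        ):
            maps[name][i, j, k] = val

    return ParameterMaps(maps=maps, affine=np.asarray(affine, dtype=float))
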