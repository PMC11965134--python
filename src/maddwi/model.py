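"""Forward models and shared domain types for multimodal apparent diffusion (MAD) DWI.

The MAD model decomposes the normalized diffusion-weighted signal of a voxel
into four water populations distinguished by their apparent diffusivity:

    S(b)/S(0) = f_r exp(-D_r b) + f_h exp(-D_h b^alpha_h)
              + f_ui exp(-D_ui b) + f_f exp(-D_f b)

with restricted (D_r < 0.2 um^2/ms), hindered (0.2 <= D_h <= 3 um^2/ms,
stretched-exponential with heterogeneity exponent alpha_h), unimpeded
(D_ui = 3 um^2/ms, fixed) and flow (D_f > 3 um^2/ms) compartments, and
volume fractions summing to one.

Units: b-values are stored in ms/um^2 (1 ms/um^2 = 1000 s/mm^2) so that
D*b products are dimensionless. The stretched term raises the numeric value
of b in ms/um^2 to alpha_h; this convention is fixed and documented in
docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "D_UI",
    "FRACTION_SUM_TOL",
    "BValueScheme",
    "MADParameters",
    "SignalCurve",
    "ADCFit",
    "b_smm2_to_msum2",
    "b_msum2_to_smm2",
    "mad_signal",
    "mad_signal_curve",
    "mono_signal",
]

#: Diffusivity of the unimpeded (free-water-like) compartment, um^2/ms.
#: Held constant: free water at body temperature diffuses at ~3 um^2/ms, and
#: letting it float would be collinear with the upper range of D_h.
D_UI: float = 3.0

#: Tolerance for the fraction sum-to-one invariant.
FRACTION_SUM_TOL: float = 1e-9

#: Minimum number of distinct b-values needed to fit the 8-parameter model.
MIN_B_VALUES_FOR_MAD: int = 6


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


class DegenerateInputError(ValueError):
    """Raised when an input is structurally valid but carries no information
    for the requested operation (e.g. too few usable points)."""


def b_smm2_to_msum2(b: "np.ndarray | float") -> "np.ndarray | float":
    """Convert b-values from s/mm^2 to the internal ms/um^2 convention."""
    return np.asarray(b, dtype=float) / 1000.0 if np.ndim(b) else float(b) / 1000.0


def b_msum2_to_smm2(b: "np.ndarray | float") -> "np.ndarray | float":
    """Convert b-values from ms/um^2 back to s/mm^2."""
    return np.asarray(b, dtype=float) * 1000.0 if np.ndim(b) else float(b) * 1000.0


@dataclass(frozen=True)
class BValueScheme:
    """Diffusion-weighting axis: b-values (ms/um^2) with per-b averaging counts.

    ``n_averages`` is the number of excitations (NEX) averaged per b-value;
    noise standard deviation scales as 1/sqrt(NEX).
    """

    b_values: tuple[float, ...]
    n_averages: tuple[int, ...]

    def __init__(
        self,
        b_values: Sequence[float],
        n_averages: Sequence[int] | None = None,
    ) -> None:
        b = tuple(float(x) for x in b_values)
        if n_averages is None:
            n_averages = [1] * len(b)
        nex = tuple(int(n) for n in n_averages)
        if len(b) != len(nex):
            raise ValidationError(
                f"b_values ({len(b)}) and n_averages ({len(nex)}) lengths differ"
            )
        if len(b) == 0 or b[0] != 0.0:
            raise ValidationError("first b-value must be exactly 0")
        if any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise ValidationError("b_values must be strictly increasing")
        if any(n < 1 for n in nex):
            raise ValidationError("every n_averages must be >= 1")
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "n_averages", nex)

    def __len__(self) -> int:
        return len(self.b_values)

    @property
    def b_array(self) -> np.ndarray:
        return np.asarray(self.b_values, dtype=float)

    @property
    def nex_array(self) -> np.ndarray:
        return np.asarray(self.n_averages, dtype=int)

    @property
    def supports_mad_fit(self) -> bool:
        return len(self.b_values) >= MIN_B_VALUES_FOR_MAD

    @classmethod
    def from_smm2(
        cls, b_values_smm2: Sequence[float], n_averages: Sequence[int] | None = None
    ) -> "BValueScheme":
        """Build a scheme from b-values given in s/mm^2."""
        return cls([b / 1000.0 for b in b_values_smm2], n_averages)

    def to_smm2(self) -> np.ndarray:
        return self.b_array * 1000.0


# (lower, upper) bounds per parameter; D_r upper is an open bound in theory
# but fits clamp to it, so it is stored closed here.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "D_r": (0.0, 0.2),
    "D_h": (0.2, 3.0),
    "D_f": (3.0, 100.0),
    "f_r": (0.0, 1.0),
    "f_h": (0.0, 1.0),
    "f_ui": (0.0, 1.0),
    "f_f": (0.0, 1.0),
    "alpha_h": (0.0, 2.0),
}

PARAM_NAMES: tuple[str, ...] = (
    "D_r", "D_h", "D_ui", "D_f", "f_r", "f_h", "f_ui", "f_f", "alpha_h",
)


@dataclass(frozen=True)
class MADParameters:
    """The nine MAD quantities for one voxel or one tissue class.

    Diffusivities in um^2/ms; fractions unitless and summing to one;
    ``alpha_h`` is the stretching exponent of the hindered compartment
    (1 = mono-exponential, <1 = broader intra-voxel rate distribution).
    """

    D_r: float
    D_h: float
    D_f: float
    f_r: float
    f_h: float
    f_ui: float
    f_f: float
    alpha_h: float
    D_ui: float = D_UI

    def __post_init__(self) -> None:
        if not (0.0 <= self.D_r < 0.2):
            raise ValidationError(f"D_r={self.D_r} outside [0, 0.2)")
        if not (0.2 <= self.D_h <= 3.0):
            raise ValidationError(f"D_h={self.D_h} outside [0.2, 3.0]")
        if self.D_ui != D_UI:
            raise ValidationError(f"D_ui is fixed at {D_UI} um^2/ms")
        if not (3.0 < self.D_f <= 100.0):
            raise ValidationError(f"D_f={self.D_f} outside (3.0, 100]")
        if not (0.0 < self.alpha_h <= 2.0):
            raise ValidationError(f"alpha_h={self.alpha_h} outside (0, 2]")
        fracs = (self.f_r, self.f_h, self.f_ui, self.f_f)
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValidationError(f"fractions {fracs} outside [0, 1]")
        if abs(sum(fracs) - 1.0) > FRACTION_SUM_TOL:
            raise ValidationError(
                f"fractions sum to {sum(fracs):.12f}, not 1 within {FRACTION_SUM_TOL}"
            )

    @property
    def fractions(self) -> np.ndarray:
        return np.array([self.f_r, self.f_h, self.f_ui, self.f_f])

    def as_dict(self) -> dict[str, float]:
        return {
            "D_r": self.D_r, "D_h": self.D_h, "D_ui": self.D_ui, "D_f": self.D_f,
            "f_r": self.f_r, "f_h": self.f_h, "f_ui": self.f_ui, "f_f": self.f_f,
            "alpha_h": self.alpha_h,
        }

    def replace(self, **changes) -> "MADParameters":
        return replace(self, **changes)

    @classmethod
    def from_fractions_renormalized(
        cls,
        D_r: float,
        D_h: float,
        D_f: float,
        f_r: float,
        f_h: float,
        f_ui: float,
        f_f: float,
        alpha_h: float,
        hold: str | None = None,
    ) -> "MADParameters":
        """Build parameters from fractions that need not sum to one.

        With ``hold=None`` all four fractions are scaled by 1/sum. With
        ``hold`` naming one fraction, that fraction is kept at its given
        value and the other three are rescaled to complete the unit sum.
        Useful for published ROI-mean fractions, which are averages of
        independently fitted maps and typically miss the unit sum slightly.
        """
        vals = {"f_r": f_r, "f_h": f_h, "f_ui": f_ui, "f_f": f_f}
        if hold is None:
            total = sum(vals.values())
            if total <= 0:
                raise ValidationError("fraction sum must be positive")
            scaled = {k: v / total for k, v in vals.items()}
        else:
            if hold not in vals:
                raise ValidationError(f"unknown fraction name {hold!r}")
            rest = 1.0 - vals[hold]
            rest_sum = sum(v for k, v in vals.items() if k != hold)
            if rest < 0 or rest_sum <= 0:
                raise ValidationError("cannot rescale remaining fractions")
            scaled = {
                k: (vals[hold] if k == hold else v * rest / rest_sum)
                for k, v in vals.items()
            }
        return cls(D_r=D_r, D_h=D_h, D_f=D_f, alpha_h=alpha_h, **scaled)


@dataclass(frozen=True)
class SignalCurve:
    """A measured or synthesized signal decay along a b-value scheme."""

    scheme: BValueScheme
    values: tuple[float, ...]
    normalized: bool = True

    def __init__(
        self, scheme: BValueScheme, values: Sequence[float], normalized: bool = True
    ) -> None:
        vals = tuple(float(v) for v in values)
        if len(vals) != len(scheme):
            raise ValidationError(
                f"curve has {len(vals)} values for {len(scheme)} b-values"
            )
        if any(v < 0 for v in vals):
            raise ValidationError("signal values must be non-negative")
        if normalized and abs(vals[0] - 1.0) > 1e-12:
            raise ValidationError(f"normalized curve must start at 1, got {vals[0]}")
        object.__setattr__(self, "scheme", scheme)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "normalized", normalized)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def normalize(self) -> "SignalCurve":
        """Divide by the b=0 entry; error if it is zero."""
        if self.normalized:
            return self
        s0 = self.values[0]
        if s0 <= 0:
            raise DegenerateInputError("cannot normalize: S(0) <= 0")
        return SignalCurve(self.scheme, [v / s0 for v in self.values], normalized=True)


@dataclass(frozen=True)
class ADCFit:
    """Result of the mono-exponential (log-linear) ADC fit.

    A negative slope estimate (adc < 0) can arise on noisy or pathological
    curves; it is reported as-is with ``physical=False`` rather than clamped.
    """

    adc: float
    intercept: float
    r_squared: float
    n_points_used: int

    @property
    def physical(self) -> bool:
        return self.adc >= 0.0


def _validate_b(b) -> np.ndarray:
    barr = np.asarray(b, dtype=float)
    if np.any(barr < 0):
        raise ValidationError("b must be >= 0")
    return barr


def mad_signal(params: MADParameters, b) -> "float | np.ndarray":
    """Normalized MAD signal S(b)/S(0) at weighting ``b`` (ms/um^2).

    Accepts a scalar or array b; returns the four-compartment sum
    f_r e^(-D_r b) + f_h e^(-D_h b^alpha_h) + f_ui e^(-D_ui b) + f_f e^(-D_f b).
    """
    barr = _validate_b(b)
    s = (
        params.f_r * np.exp(-params.D_r * barr)
        + params.f_h * np.exp(-params.D_h * barr ** params.alpha_h)
        + params.f_ui * np.exp(-params.D_ui * barr)
        + params.f_f * np.exp(-params.D_f * barr)
    )
    return float(s) if np.ndim(b) == 0 else s


def mad_signal_curve(params: MADParameters, scheme: BValueScheme) -> SignalCurve:
    """Evaluate the MAD forward model along a b-value scheme."""
    vals = mad_signal(params, scheme.b_array)
    return SignalCurve(scheme, vals, normalized=True)


def mono_signal(adc: float, b) -> "float | np.ndarray":
    """Mono-exponential signal e^(-ADC*b); adc in um^2/ms, b in ms/um^2."""
    if adc < 0:
        raise ValidationError(f"adc={adc} must be >= 0")
    barr = _validate_b(b)
    s = np.exp(-adc * barr)
    return float(s) if np.ndim(b) == 0 else s
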