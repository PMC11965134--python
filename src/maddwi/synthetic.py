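"""Synthetic signal curves, phantoms and cohorts with known ground truth.

The generator reproduces the acquisition and population structure the
analysis assumes: the 12-b-value trace-DWI scheme from 0 to 3000 s/mm^2
with per-b averaging counts, Rician magnitude noise with NEX averaging,
and two subject groups (low- vs high-grade clear cell renal cell
carcinoma) whose ROI-mean MAD parameters follow published group means and
standard deviations. Every output is reproducible bit-exactly from
(seed, config).

Parameters are drawn independently per quantity (the published summaries
carry no covariance information) and truncated to the physical bounds;
fractions are renormalized to sum to one after drawing. For the two
quantities summarized as median (IQR) rather than mean +/- SD, the median
stands in for the mean and IQR/1.349 (the normal-equivalent) for the SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .fitting import ParameterMaps
from .model import (
    PARAM_BOUNDS,
    BValueScheme,
    MADParameters,
    SignalCurve,
    ValidationError,
    mad_signal_curve,
)
from .roi import STAT_PARAMS, CohortTable, SubjectRecord

__all__ = [
    "GradeParameterDistribution",
    "NoiseConfig",
    "PhantomTruth",
    "default_scheme",
    "low_grade_distribution",
    "high_grade_distribution",
    "add_rician_noise",
    "sample_subject_params",
    "make_phantom",
    "make_cohort",
]

# Published 12-b acquisition: b in s/mm^2 with per-b NEX counts.
_DEFAULT_B_SMM2 = (0, 20, 50, 100, 200, 500, 800, 1000, 1500, 2000, 2500, 3000)
_DEFAULT_NEX = (1, 1, 1, 1, 1, 2, 3, 3, 4, 6, 8, 9)

# IQR -> SD for a normal distribution.
_IQR_TO_SD = 1.0 / 1.349

# Group summaries: ROI-mean MAD parameters and mono-exponential ADC for
# low-grade (WHO-ISUP 1-2) and high-grade (3-4) ccRCC. D_r and f_ui were
# summarized as median (IQR); their SDs below are IQR/1.349.
_LOW_MEANS = {
    "D_r": 0.039, "D_h": 1.360, "D_f": 15.012,
    "f_r": 0.060, "f_h": 0.413, "f_ui": 0.275, "f_f": 0.219,
    "alpha_h": 0.872, "ADC": 0.924,
}
_LOW_SDS = {
    "D_r": (0.072 - 0.014) * _IQR_TO_SD, "D_h": 0.112, "D_f": 1.8,
    "f_r": 0.005, "f_h": 0.029, "f_ui": (0.373 - 0.224) * _IQR_TO_SD, "f_f": 0.023,
    "alpha_h": 0.224, "ADC": 0.081,
}
_HIGH_MEANS = {
    "D_r": 0.045, "D_h": 1.254, "D_f": 14.335,
    "f_r": 0.080, "f_h": 0.442, "f_ui": 0.274, "f_f": 0.196,
    "alpha_h": 0.896, "ADC": 0.854,
}
_HIGH_SDS = {
    "D_r": (0.069 - 0.033) * _IQR_TO_SD, "D_h": 0.134, "D_f": 1.2,
    "f_r": 0.009, "f_h": 0.031, "f_ui": (0.320 - 0.230) * _IQR_TO_SD, "f_f": 0.022,
    "alpha_h": 0.393, "ADC": 0.045,
}

_FRACTIONS = ("f_r", "f_h", "f_ui", "f_f")
# truncation bounds per sampled quantity
_TRUNC = dict(PARAM_BOUNDS)
_TRUNC["alpha_h"] = (1e-6, 2.0)
_TRUNC["D_f"] = (3.0 + 1e-9, 100.0)
_TRUNC["D_r"] = (0.0, 0.2 - 1e-9)
_TRUNC["ADC"] = (0.0, 4.0)


def default_scheme() -> BValueScheme:
    """The 12-b-value scheme 0-3000 s/mm^2 with its NEX averaging counts."""
    return BValueScheme.from_smm2(_DEFAULT_B_SMM2, _DEFAULT_NEX)


@dataclass(frozen=True)
class GradeParameterDistribution:
    """Per-grade generating distribution: independent truncated normals."""

    grade: str
    means: dict[str, float]
    sds: dict[str, float]

    def __post_init__(self) -> None:
        if self.grade not in ("low", "high"):
            raise ValidationError(f"grade must be 'low' or 'high', got {self.grade!r}")
        for name in STAT_PARAMS:
            if name not in self.means or name not in self.sds:
                raise ValidationError(f"distribution missing parameter {name}")
            if self.sds[name] < 0:
                raise ValidationError(f"SD for {name} must be >= 0")
            lo, up = _TRUNC[name]
            if not (lo <= self.means[name] <= up):
                raise ValidationError(f"mean for {name} outside bounds ({lo}, {up})")

    def renormalized_fraction_means(self, hold: str | None = None) -> dict[str, float]:
        """Fraction means scaled to sum to one.

        Published ROI means of independently fitted fraction maps need not
        sum exactly to one; signal synthesis requires a unit sum. With
        ``hold``, that fraction keeps its published value and the other
        three are rescaled proportionally.
        """
        vals = {k: self.means[k] for k in _FRACTIONS}
        if hold is None:
            total = sum(vals.values())
            return {k: v / total for k, v in vals.items()}
        rest = 1.0 - vals[hold]
        rest_sum = sum(v for k, v in vals.items() if k != hold)
        return {k: (vals[k] if k == hold else vals[k] * rest / rest_sum)
                for k in _FRACTIONS}

    def mean_params(self, hold: str | None = None) -> MADParameters:
        """Group-mean MADParameters with fractions renormalized to sum 1."""
        fr = self.renormalized_fraction_means(hold)
        return MADParameters(
            D_r=self.means["D_r"], D_h=self.means["D_h"], D_f=self.means["D_f"],
            alpha_h=self.means["alpha_h"], **fr,
        )


def low_grade_distribution() -> GradeParameterDistribution:
    return GradeParameterDistribution("low", dict(_LOW_MEANS), dict(_LOW_SDS))


def high_grade_distribution() -> GradeParameterDistribution:
    return GradeParameterDistribution("high", dict(_HIGH_MEANS), dict(_HIGH_SDS))


@dataclass(frozen=True)
class NoiseConfig:
    """Rician noise scale (relative to S(0)) and NEX-averaging behavior."""

    sigma: float = 0.02
    apply_averaging: bool = True
    seed: int = 0
    gaussian: bool = False  # debugging mode: additive real Gaussian noise

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")


@dataclass
class PhantomTruth:
    """Ground truth for a synthetic phantom: parameter maps + tissue labels.

    ``labels``: 0 = background, 1 = low-grade tissue, 2 = high-grade tissue.
    Truth maps are NaN on background.
    """

    maps: ParameterMaps
    labels: np.ndarray

    LABEL_BACKGROUND = 0
    LABEL_LOW = 1
    LABEL_HIGH = 2


def _truncnorm_draw(
    rng: np.random.Generator, mean: float, sd: float, lo: float, up: float, size=None
):
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, up))) if size else float(np.clip(mean, lo, up))
    a, b = (lo - mean) / sd, (up - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def add_rician_noise(clean: SignalCurve, noise: NoiseConfig) -> SignalCurve:
    """Corrupt a curve with magnitude (Rician) noise, averaged over NEX.

    Each b-value's output is the mean of ``n_averages`` independent draws of
    |s + eta_1 + i*eta_2| with eta ~ N(0, sigma) per channel (Rician with
    location s). With ``apply_averaging=False`` a single draw is used per b.
    In the Gaussian debug mode only a real-channel eta_1 is added.
    """
    if noise.sigma == 0:
        return clean
    rng = np.random.default_rng(noise.seed)
    out = []
    for s, nex in zip(clean.values, clean.scheme.n_averages):
        n = nex if noise.apply_averaging else 1
        if noise.gaussian:
            draws = s + rng.normal(0.0, noise.sigma, size=n)
        else:
            draws = np.abs(
                s + rng.normal(0.0, noise.sigma, size=n)
                + 1j * rng.normal(0.0, noise.sigma, size=n)
            )
        out.append(float(np.mean(draws)))
    return SignalCurve(clean.scheme, out, normalized=False)


def sample_subject_params(
    dist: GradeParameterDistribution, seed: "int | np.random.Generator"
) -> MADParameters:
    """Draw one subject's (or voxel's) MAD parameters from a grade distribution.

    Independent truncated-normal draws per quantity; fractions renormalized
    to sum to one after drawing. Always satisfies the parameter invariants.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = {}
    for name in ("D_r", "D_h", "D_f", "alpha_h", *_FRACTIONS):
        lo, up = _TRUNC[name]
        draws[name] = float(_truncnorm_draw(rng, dist.means[name], dist.sds[name], lo, up))
    total = sum(draws[f] for f in _FRACTIONS)
    for f in _FRACTIONS:
        draws[f] /= total
    return MADParameters(**draws)


def make_phantom(
    shape: tuple[int, int, int],
    lesions: list[tuple[str, np.ndarray]],
    low_dist: GradeParameterDistribution | None = None,
    high_dist: GradeParameterDistribution | None = None,
    scheme: BValueScheme | None = None,
    noise: NoiseConfig = NoiseConfig(sigma=0.0),
    s0: float = 1000.0,
) -> tuple[np.ndarray, PhantomTruth]:
    """Build a 4D DWI phantom with lesions of known MAD parameters.

    ``lesions`` is a list of ('low'|'high', boolean mask) pairs; masks must
    be disjoint and lie inside ``shape``. Each lesion voxel draws its own
    parameters from the grade's distribution, generates the clean MAD decay
    scaled by ``s0``, and is corrupted with Rician noise per ``noise``.
    Background voxels contain pure noise. Returns the signal grid and the
    stored truth (per-voxel generating parameters + labels).
    """
    scheme = scheme or default_scheme()
    low_dist = low_dist or low_grade_distribution()
    high_dist = high_dist or high_grade_distribution()
    dists = {"low": low_dist, "high": high_dist}
    labels_of = {"low": PhantomTruth.LABEL_LOW, "high": PhantomTruth.LABEL_HIGH}

    occupancy = np.zeros(shape, dtype=int)
    for grade, m in lesions:
        if grade not in dists:
            raise ValidationError(f"lesion grade must be 'low' or 'high', got {grade!r}")
        m = np.asarray(m, dtype=bool)
        if m.shape != tuple(shape):
            raise ValidationError(f"lesion mask shape {m.shape} != phantom shape {shape}")
        occupancy += m.astype(int)
    if np.any(occupancy > 1):
        raise ValidationError("lesion regions overlap")

    rng = np.random.default_rng(noise.seed)
    nb = len(scheme)
    signal = np.zeros((*shape, nb))
    labels = np.zeros(shape, dtype=int)
    truth_names = ("D_r", "D_h", "D_f", "f_r", "f_h", "f_ui", "f_f", "alpha_h")
    truth_maps = {n: np.full(shape, np.nan) for n in truth_names}

    for grade, m in lesions:
        m = np.asarray(m, dtype=bool)
        labels[m] = labels_of[grade]
        for ijk in np.argwhere(m):
            i, j, k = (int(v) for v in ijk)
            p = sample_subject_params(dists[grade], rng)
            for n in truth_names:
                truth_maps[n][i, j, k] = getattr(p, n)
            clean = mad_signal_curve(p, scheme)
            if noise.sigma > 0:
                sub = NoiseConfig(
                    sigma=noise.sigma, apply_averaging=noise.apply_averaging,
                    seed=int(rng.integers(0, 2**31)), gaussian=noise.gaussian,
                )
                noisy = add_rician_noise(clean, sub).array
            else:
                noisy = clean.array
            signal[i, j, k, :] = s0 * noisy

    if noise.sigma > 0:
        bg = labels == PhantomTruth.LABEL_BACKGROUND
        nex = scheme.nex_array
        for b_idx in range(nb):
            n = nex[b_idx] if noise.apply_averaging else 1
            draws = np.abs(
                rng.normal(0.0, noise.sigma, size=(int(bg.sum()), n))
                + 1j * rng.normal(0.0, noise.sigma, size=(int(bg.sum()), n))
            ).mean(axis=1)
            signal[..., b_idx][bg] = s0 * draws

    truth = PhantomTruth(
        maps=ParameterMaps(maps=truth_maps, affine=np.eye(4)), labels=labels
    )
    return signal, truth


def make_cohort(
    n_low: int = 30,
    n_high: int = 24,
    low_dist: GradeParameterDistribution | None = None,
    high_dist: GradeParameterDistribution | None = None,
    seed: int = 0,
) -> CohortTable:
    """Simulate a two-group cohort of per-subject ROI-mean parameters.

    Each subject is one draw from its grade's distribution (the subject-level
    draw stands in for ROI averaging of voxel-level variation). ADC is drawn
    from its own published group summary rather than derived from the MAD
    draw, so its group statistics match the published ones. Default group
    sizes mirror the study cohort (30 low-grade, 24 high-grade).
    """
    if n_low < 2 or n_high < 2:
        raise ValidationError("need at least 2 subjects per group")
    low_dist = low_dist or low_grade_distribution()
    high_dist = high_dist or high_grade_distribution()
    rng = np.random.default_rng(seed)
    records = []
    for grade, dist, n in (("low", low_dist, n_low), ("high", high_dist, n_high)):
        for i in range(n):
            p = sample_subject_params(dist, rng)
            lo, up = _TRUNC["ADC"]
            adc = float(_truncnorm_draw(rng, dist.means["ADC"], dist.sds["ADC"], lo, up))
            values = {**{k: getattr(p, k) for k in STAT_PARAMS if k != "ADC"}, "ADC": adc}
            records.append(
                SubjectRecord(
                    subject_id=f"{grade}_{i:03d}", grade=grade, values=values,
                    n_voxels=1,
                )
            )
    return CohortTable(records=records, provenance="synthetic", seed=seed)
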