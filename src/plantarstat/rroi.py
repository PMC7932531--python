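"""Statistically determined risk regions (R-ROIs) and pressure redistribution.

The clinical question: which 5 mm cells of a foot's mean peak pressure map
(MPPM) carry peak pressures at or above the 200 kPa ulceration-risk
threshold, once step-to-step gait variability is accounted for?  A cell
enters the risk-region of interest (R-ROI) based on a one-sample t
comparison of its per-stance peak pressures against the threshold, rather
than a naive comparison of the mean alone.  Four inclusion rules are
provided (``RROIConfig.rule``):

``not_significantly_below`` (default)
    Retain a cell unless its mean is *significantly below* the threshold
    (t < −t_crit).  Cells whose mean sits under 200 kPa but whose gait
    variability is high enough that they are statistically compatible with
    the threshold are kept — the conservative reading of statistical risk.
``significantly_above``
    The strict converse: require t > +t_crit.
``direct_threshold``
    mean ≥ threshold; the naive rule the statistical rules improve on.
``dispersion_band``
    mean ≥ threshold, or within t_crit · SD of it (a dispersion band using
    the SD rather than the SEM).

For every rule, a cell with zero variance is decided by direct comparison
of its mean to the threshold (the limit behaviour of the t rules).
R-ROI cells are grouped into connected clusters (8-connectivity by
default) and quantified by total area in cm²; no anatomical mask is
applied — risk regions fall wherever the statistics place them.

Between two insole conditions, :func:`redistribution_map` runs a per-cell
paired t-test on step-paired peak pressures, classifying each cell as
significantly decreased/increased, an unchanged R-ROI cell, or unchanged.
:func:`residual_reduction` summarizes how much pressure a custom insole
removed from the residual risk region relative to the reference (flat
insole) condition.

The model-style interface (`RiskRegionModel`, `RedistributionModel`) wraps
these operations statsmodels-fashion: construct from data, ``fit()``,
inspect the Results object or its ``summary()``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

from .gait import MeanPeakPressureMap, PeakPressureMap, mean_peak_map
from .io import RegularGrid

__all__ = [
    "RROIConfig",
    "RROIMask",
    "RedistributionMap",
    "ReductionReport",
    "CATEGORY_UNCHANGED",
    "CATEGORY_SIG_DECREASE",
    "CATEGORY_SIG_INCREASE",
    "CATEGORY_RROI_UNCHANGED",
    "classify_cell",
    "classify_map",
    "build_rroi",
    "redistribution_map",
    "residual_reduction",
    "RiskRegionModel",
    "RiskRegionResults",
    "RedistributionModel",
    "RedistributionResults",
]

_RULES = (
    "not_significantly_below",
    "significantly_above",
    "direct_threshold",
    "dispersion_band",
)

# redistribution categories (exhaustive and exclusive per cell)
CATEGORY_UNCHANGED = 0
CATEGORY_SIG_DECREASE = 1
CATEGORY_SIG_INCREASE = 2
CATEGORY_RROI_UNCHANGED = 3

CATEGORY_NAMES = {
    CATEGORY_UNCHANGED: "unchanged",
    CATEGORY_SIG_DECREASE: "sig_decrease",
    CATEGORY_SIG_INCREASE: "sig_increase",
    CATEGORY_RROI_UNCHANGED: "rroi_unchanged",
}


@dataclass(frozen=True)
class RROIConfig:
    """Risk-region determination parameters.

    threshold : kPa, the at-risk peak-pressure cut-off (200 kPa standard).
    alpha : type-I level of the per-cell tests.
    rule : cell inclusion rule, see module docstring.
    connectivity : 4 or 8, neighbourhood for clustering.
    bonferroni_cells : apply a Bonferroni correction across cells (off by
        default; exposed for sensitivity analysis only).
    pairing : "paired" (by step order) or "unpaired" (Welch) for the
        between-condition per-cell test.
    """

    threshold: float = 200.0
    alpha: float = 0.05
    rule: str = "not_significantly_below"
    connectivity: int = 8
    bonferroni_cells: bool = False
    pairing: str = "paired"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.rule not in _RULES:
            raise ValueError(f"rule must be one of {_RULES}, got {self.rule!r}")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.pairing not in ("paired", "unpaired"):
            raise ValueError("pairing must be 'paired' or 'unpaired'")


@dataclass(frozen=True)
class RROIMask:
    """Boolean risk map with connected clusters and total area."""

    grid: RegularGrid
    in_rroi: np.ndarray  # bool (n_rows, n_cols)
    cluster_labels: np.ndarray  # int, 0 = background
    n_clusters: int
    total_area_cm2: float

    @property
    def n_cells(self) -> int:
        return int(np.count_nonzero(self.in_rroi))

    @property
    def is_empty(self) -> bool:
        return self.n_cells == 0

    def cluster_areas_cm2(self) -> np.ndarray:
        """Area of each cluster, cm², ordered by label."""
        counts = np.bincount(self.cluster_labels.ravel(), minlength=self.n_clusters + 1)
        return counts[1:] * self.grid.cell_area_cm2


@dataclass(frozen=True)
class RedistributionMap:
    """Per-cell classification of pressure change between two conditions."""

    grid: RegularGrid
    category: np.ndarray  # int codes, see CATEGORY_*
    alpha: float
    pairing: str

    def count(self, code: int) -> int:
        return int(np.count_nonzero(self.category == code))


@dataclass(frozen=True)
class ReductionReport:
    """Pressure reduction achieved in the residual risk region.

    ``optimal`` means the alternative condition removed the risk region
    entirely; then the achieved reduction is not directly measurable (cells
    below threshold are not quantified) but is bounded from below by
    ``lower_bound_kPa`` = (reference R-ROI mean) − threshold.
    """

    optimal: bool
    lower_bound_kPa: float
    mean_reduction_kPa: float | None = None
    mean_reduction_pct: float | None = None


# ---------------------------------------------------------------------------
# cell classification
# ---------------------------------------------------------------------------


def _t_crit(alpha: float, df: int) -> float:
    return float(stats.t.ppf(1.0 - alpha, df))


def classify_map(
    mean: np.ndarray,
    sd: np.ndarray,
    n: int,
    cfg: RROIConfig = RROIConfig(),
) -> np.ndarray:
    """Vectorized R-ROI membership for arrays of per-cell mean and SD."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    thr = cfg.threshold
    alpha = cfg.alpha
    if cfg.bonferroni_cells:
        alpha = alpha / mean.size

    if cfg.rule == "direct_threshold":
        if n < 1:
            raise ValueError("direct_threshold needs n >= 1")
        return mean >= thr
    if n < 2:
        raise ValueError(f"rule {cfg.rule!r} needs n >= 2")

    tcrit = _t_crit(alpha, n - 1)
    zero_var = sd == 0
    direct = mean >= thr

    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean - thr) / (sd / math.sqrt(n))

    if cfg.rule == "not_significantly_below":
        result = ~(t < -tcrit)
    elif cfg.rule == "significantly_above":
        result = t > tcrit
    else:  # dispersion_band: within t_crit SDs (not SEMs) of the threshold
        result = direct | ((thr - mean) <= tcrit * sd)
    # zero-variance cells: t undefined; decide by direct comparison
    return np.where(zero_var, direct, result)


def classify_cell(mean: float, sd: float, n: int, cfg: RROIConfig = RROIConfig()) -> bool:
    """R-ROI membership of a single cell (scalar convenience wrapper)."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    return bool(classify_map(np.array([mean]), np.array([sd]), n, cfg)[0])


def _label_clusters(mask: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    labels, n = ndimage.label(mask, structure=structure)
    return labels, int(n)


def build_rroi(mppm: MeanPeakPressureMap, cfg: RROIConfig = RROIConfig()) -> RROIMask:
    """Cell-wise R-ROI classification, clustering and total area.

    No anatomical masking is applied: every grid cell is tested, and the
    statistics alone determine where risk regions fall.
    """
    in_rroi = classify_map(mppm.mean, mppm.sd, mppm.n, cfg)
    labels, n_clusters = _label_clusters(in_rroi, cfg.connectivity)
    area = float(np.count_nonzero(in_rroi)) * mppm.grid.cell_area_cm2
    return RROIMask(mppm.grid, in_rroi, labels, n_clusters, area)


# ---------------------------------------------------------------------------
# between-condition comparison
# ---------------------------------------------------------------------------


def _stack(maps: Sequence[PeakPressureMap]) -> np.ndarray:
    return np.stack([m.values for m in maps])


def redistribution_map(
    peaks_ref: Sequence[PeakPressureMap],
    peaks_alt: Sequence[PeakPressureMap],
    rroi_ref: RROIMask,
    cfg: RROIConfig = RROIConfig(),
) -> RedistributionMap:
    """Per-cell two-sided t comparison of peak pressures between conditions.

    In paired mode (default) step i of the reference condition is paired
    with step i of the alternative, which requires equal step counts; the
    unpaired Welch fallback (``cfg.pairing = "unpaired"``) drops that
    requirement.  Significant cells are classified by the sign of the
    (alt − ref) mean difference; non-significant cells inside the reference
    R-ROI are flagged ``rroi_unchanged``, all others ``unchanged``.
    Cells with identically zero differences are not significant.
    """
    if len(peaks_ref) < 2 or len(peaks_alt) < 2:
        raise ValueError("need at least 2 peak maps per condition")
    grid = peaks_ref[0].grid
    for m in (*peaks_ref, *peaks_alt):
        if m.grid != grid:
            raise ValueError("peak maps are on different grids")
    if rroi_ref.grid != grid:
        raise ValueError("reference R-ROI is on a different grid")

    a = _stack(peaks_ref)
    b = _stack(peaks_alt)
    with warnings.catch_warnings():
        # constant differences give degenerate t (inf or nan); the limit
        # behaviour (p=0 for nonzero shift, not significant for zero) is
        # exactly what we want, so silence scipy's precision warning
        warnings.simplefilter("ignore", RuntimeWarning)
        if cfg.pairing == "paired":
            if a.shape[0] != b.shape[0]:
                raise ValueError(
                    f"paired mode needs equal step counts, got {a.shape[0]} vs "
                    f"{b.shape[0]}; use pairing='unpaired' for the Welch fallback"
                )
            res = stats.ttest_rel(b, a, axis=0)
        else:
            res = stats.ttest_ind(b, a, axis=0, equal_var=False)

    alpha = cfg.alpha / grid.n_rows / grid.n_cols if cfg.bonferroni_cells else cfg.alpha
    pvals = np.asarray(res.pvalue)
    diff = b.mean(axis=0) - a.mean(axis=0)
    significant = np.nan_to_num(pvals, nan=1.0) < alpha

    category = np.full(grid.shape, CATEGORY_UNCHANGED, dtype=int)
    category[significant & (diff < 0)] = CATEGORY_SIG_DECREASE
    category[significant & (diff > 0)] = CATEGORY_SIG_INCREASE
    category[~significant & rroi_ref.in_rroi] = CATEGORY_RROI_UNCHANGED
    return RedistributionMap(grid, category, alpha, cfg.pairing)


def residual_reduction(
    mppm_ref: MeanPeakPressureMap,
    rroi_ref: RROIMask,
    mppm_alt: MeanPeakPressureMap,
    rroi_alt: RROIMask,
    cfg: RROIConfig = RROIConfig(),
) -> ReductionReport:
    """Mean pressure reduction in the residual risk region.

    For a non-optimal outcome (the alternative condition retains a risk
    region), the reduction is the difference between the reference MPPM
    averaged over the reference R-ROI and the alternative MPPM averaged
    over the residual R-ROI, with the percentage relative to the reference
    mean.  When the alternative removes the risk region entirely
    (``optimal``), only the lower bound
    (reference R-ROI mean − threshold) is reported: cells below threshold
    carry no quantified pressure, so the achieved reduction is at least the
    margin by which the reference region exceeded the threshold.
    """
    if mppm_ref.grid != mppm_alt.grid:
        raise ValueError("conditions are on different grids")
    if rroi_ref.is_empty:
        raise ValueError("no reference risk region")
    ref_mean = float(mppm_ref.mean[rroi_ref.in_rroi].mean())
    lower_bound = ref_mean - cfg.threshold
    if rroi_alt.is_empty:
        return ReductionReport(optimal=True, lower_bound_kPa=lower_bound)
    alt_mean = float(mppm_alt.mean[rroi_alt.in_rroi].mean())
    reduction = ref_mean - alt_mean
    return ReductionReport(
        optimal=False,
        lower_bound_kPa=lower_bound,
        mean_reduction_kPa=reduction,
        mean_reduction_pct=100.0 * reduction / ref_mean,
    )


# ---------------------------------------------------------------------------
# model-style interface
# ---------------------------------------------------------------------------


class RiskRegionModel:
    """Risk-region determination for one foot/condition.

    Construct from an MPPM (or from raw per-stance peak maps via
    :meth:`from_peak_maps`) and ``fit()`` to obtain a
    :class:`RiskRegionResults`.

    Examples
    --------
    >>> model = RiskRegionModel.from_peak_maps(maps)          # doctest: +SKIP
    >>> res = model.fit()                                     # doctest: +SKIP
    >>> res.total_area_cm2                                    # doctest: +SKIP
    """

    def __init__(self, mppm: MeanPeakPressureMap, config: RROIConfig = RROIConfig()):
        self.mppm = mppm
        self.config = config

    @classmethod
    def from_peak_maps(
        cls,
        maps: Sequence[PeakPressureMap],
        config: RROIConfig = RROIConfig(),
        min_n: int = 24,
    ) -> "RiskRegionModel":
        return cls(mean_peak_map(maps, min_n=min_n), config)

    def fit(self, **config_overrides) -> "RiskRegionResults":
        cfg = replace(self.config, **config_overrides) if config_overrides else self.config
        return RiskRegionResults(self, build_rroi(self.mppm, cfg), cfg)


@dataclass(frozen=True)
class RiskRegionResults:
    model: RiskRegionModel
    mask: RROIMask
    config: RROIConfig = field(default_factory=RROIConfig)

    @property
    def total_area_cm2(self) -> float:
        return self.mask.total_area_cm2

    @property
    def n_clusters(self) -> int:
        return self.mask.n_clusters

    def summary(self) -> str:
        m = self.mask
        mppm = self.model.mppm
        lines = [
            "Risk-Region (R-ROI) Results",
            "=" * 42,
            f"rule:                {self.config.rule}",
            f"threshold:           {self.config.threshold:g} kPa",
            f"alpha:               {self.config.alpha:g}",
            f"stances (n):         {mppm.n}",
            f"grid:                {mppm.grid.n_rows} x {mppm.grid.n_cols} "
            f"@ {mppm.grid.cell_size:g} mm",
            f"R-ROI cells:         {m.n_cells}",
            f"clusters:            {m.n_clusters} (connectivity {self.config.connectivity})",
            f"total area:          {m.total_area_cm2:.2f} cm^2",
        ]
        if m.n_clusters:
            areas = ", ".join(f"{a:.2f}" for a in m.cluster_areas_cm2())
            lines.append(f"cluster areas:       {areas} cm^2")
        if m.n_cells:
            lines.append(
                f"mean peak in R-ROI:  {mppm.mean[m.in_rroi].mean():.1f} kPa"
            )
        return "\n".join(lines)


class RedistributionModel:
    """Between-condition redistribution analysis for one foot.

    Built from the per-stance peak maps of a reference condition (flat
    insole) and an alternative condition (custom insole); ``fit()`` returns
    a :class:`RedistributionResults` carrying the per-cell change map and
    the residual-reduction report.
    """

    def __init__(
        self,
        peaks_ref: Sequence[PeakPressureMap],
        peaks_alt: Sequence[PeakPressureMap],
        config: RROIConfig = RROIConfig(),
        min_n: int = 24,
    ):
        self.peaks_ref = list(peaks_ref)
        self.peaks_alt = list(peaks_alt)
        self.config = config
        self.min_n = min_n

    def fit(self, **config_overrides) -> "RedistributionResults":
        cfg = replace(self.config, **config_overrides) if config_overrides else self.config
        mppm_ref = mean_peak_map(self.peaks_ref, min_n=self.min_n)
        mppm_alt = mean_peak_map(self.peaks_alt, min_n=self.min_n)
        rroi_ref = build_rroi(mppm_ref, cfg)
        rroi_alt = build_rroi(mppm_alt, cfg)
        change = redistribution_map(self.peaks_ref, self.peaks_alt, rroi_ref, cfg)
        report = (
            residual_reduction(mppm_ref, rroi_ref, mppm_alt, rroi_alt, cfg)
            if not rroi_ref.is_empty
            else None
        )
        return RedistributionResults(
            self, cfg, mppm_ref, mppm_alt, rroi_ref, rroi_alt, change, report
        )


@dataclass(frozen=True)
class RedistributionResults:
    model: RedistributionModel
    config: RROIConfig
    mppm_ref: MeanPeakPressureMap
    mppm_alt: MeanPeakPressureMap
    rroi_ref: RROIMask
    rroi_alt: RROIMask
    change_map: RedistributionMap
    reduction: ReductionReport | None  # None when reference R-ROI is empty

    def summary(self) -> str:
        c = self.change_map
        lines = [
            "Pressure Redistribution Results",
            "=" * 42,
            f"pairing:             {c.pairing} (alpha {c.alpha:g})",
            f"reference area:      {self.rroi_ref.total_area_cm2:.2f} cm^2",
            f"alternative area:    {self.rroi_alt.total_area_cm2:.2f} cm^2",
            f"sig. decreased:      {c.count(CATEGORY_SIG_DECREASE)} cells",
            f"sig. increased:      {c.count(CATEGORY_SIG_INCREASE)} cells",
            f"R-ROI unchanged:     {c.count(CATEGORY_RROI_UNCHANGED)} cells",
        ]
        r = self.reduction
        if r is None:
            lines.append("reduction:           n/a (no reference risk region)")
        elif r.optimal:
            lines.append(
                f"outcome:             optimal (R-ROI removed); reduction >= "
                f"{r.lower_bound_kPa:.1f} kPa"
            )
        else:
            lines.append(
                f"mean reduction:      {r.mean_reduction_kPa:.1f} kPa "
                f"({r.mean_reduction_pct:.1f}%)"
            )
        return "\n".join(lines)
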