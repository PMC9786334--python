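"""Nucleus classification, viability computation, and replicate statistics.

A segmented nucleus is classified by how much of its area lies under the
green (calcein, viable) and red (propidium iodide, dead) binary masks.  The
dead class takes precedence on double-positive nuclei: a compromised membrane
admits propidium iodide regardless of residual calcein.  Nuclei under neither
mask are counted as unclassified and excluded from the viability ratio

    viability % = 100 * N_viable / (N_viable + N_dead)

which is undefined (reported as missing, never 0 or 100) when no nucleus is
classified.  Replicate-level statistics follow the standard small-sample
workflow: Jarque–Bera normality screening and one-way ANOVA at alpha = 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy import stats

from .segmentation import BinaryMask, LabelMap

__all__ = [
    "NucleusRecord",
    "ViabilityResult",
    "JarqueBeraResult",
    "AnovaResult",
    "GroupStats",
    "classify_nuclei",
    "compute_viability",
    "jarque_bera",
    "one_way_anova",
    "aggregate_condition",
]

CLASSES = ("viable", "dead", "unclassified")


@dataclass(frozen=True)
class NucleusRecord:
    """One segmented nucleus with its mask overlaps and viability class."""

    label: int
    centroid: tuple[float, float]
    area: int
    overlap_green: float
    overlap_red: float
    klass: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_green <= 1.0 and 0.0 <= self.overlap_red <= 1.0):
            raise ValueError("overlap fractions must lie in [0, 1]")
        if self.klass not in CLASSES:
            raise ValueError(f"klass must be one of {CLASSES}")


@dataclass(frozen=True)
class ViabilityResult:
    """Viable/dead/unclassified counts and the viability percentage.

    ``viability_percent`` is ``None`` when no nucleus was classified
    (``defined`` is then False); unclassified nuclei never enter the ratio.
    """

    n_viable: int
    n_dead: int
    n_unclassified: int = 0

    @property
    def n_total(self) -> int:
        return self.n_viable + self.n_dead + self.n_unclassified

    @property
    def defined(self) -> bool:
        return (self.n_viable + self.n_dead) > 0

    @property
    def viability_percent(self) -> float | None:
        denom = self.n_viable + self.n_dead
        return 100.0 * self.n_viable / denom if denom else None


@dataclass(frozen=True)
class JarqueBeraResult:
    statistic: float
    p_value: float
    normal: bool  # fail to reject normality at the given alpha
    alpha: float = 0.05


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p_value: float
    significant: bool
    alpha: float = 0.05


@dataclass
class GroupStats:
    """Condition-level replicate summary with normality screen and ANOVA."""

    labels: list[str]
    values: dict[str, list[float]]
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    jarque_bera: dict[str, JarqueBeraResult | None] = field(default_factory=dict)
    anova: AnovaResult | None = None
    alpha: float = 0.05


def classify_nuclei(
    labels: LabelMap,
    green: BinaryMask | np.ndarray,
    red: BinaryMask | np.ndarray,
    overlap_threshold: float = 0.5,
    mode: str = "overlap",
) -> list[NucleusRecord]:
    """Assign each labeled nucleus a viable/dead/unclassified class.

    In ``mode='overlap'`` (default) the overlap fraction of the nucleus area
    with each stain mask is compared against ``overlap_threshold``; in
    ``mode='centroid'`` the mask value at the (rounded) nucleus centroid
    decides.  Dead takes precedence over viable on double positives.
    """
    if not 0.0 < overlap_threshold <= 1.0:
        raise ValueError("overlap_threshold must lie in (0, 1]")
    if mode not in ("overlap", "centroid"):
        raise ValueError("mode must be 'overlap' or 'centroid'")
    lab = labels.labels if isinstance(labels, LabelMap) else np.asarray(labels)
    g = green.pixels if isinstance(green, BinaryMask) else np.asarray(green, bool)
    r = red.pixels if isinstance(red, BinaryMask) else np.asarray(red, bool)
    if not (lab.shape == g.shape == r.shape):
        raise ValueError(
            f"shape mismatch: labels {lab.shape}, green {g.shape}, red {r.shape}"
        )
    n = int(lab.max())
    if n == 0:
        return []

    flat = lab.ravel()
    areas = np.bincount(flat, minlength=n + 1)
    green_px = np.bincount(flat, weights=g.ravel().astype(float), minlength=n + 1)
    red_px = np.bincount(flat, weights=r.ravel().astype(float), minlength=n + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        overlap_green = np.where(areas > 0, green_px / np.maximum(areas, 1), 0.0)
        overlap_red = np.where(areas > 0, red_px / np.maximum(areas, 1), 0.0)
    centroids = ndi.center_of_mass(np.ones_like(lab), lab, index=np.arange(1, n + 1))

    records = []
    for i in range(1, n + 1):
        if areas[i] == 0:
            continue
        og, orr = float(overlap_green[i]), float(overlap_red[i])
        if mode == "overlap":
            in_red = orr >= overlap_threshold
            in_green = og >= overlap_threshold
        else:
            rr = int(round(centroids[i - 1][0]))
            cc = int(round(centroids[i - 1][1]))
            rr = min(max(rr, 0), lab.shape[0] - 1)
            cc = min(max(cc, 0), lab.shape[1] - 1)
            in_red, in_green = bool(r[rr, cc]), bool(g[rr, cc])
        klass = "dead" if in_red else ("viable" if in_green else "unclassified")
        records.append(
            NucleusRecord(
                label=i,
                centroid=(float(centroids[i - 1][0]), float(centroids[i - 1][1])),
                area=int(areas[i]),
                overlap_green=og,
                overlap_red=orr,
                klass=klass,
            )
        )
    return records


def compute_viability(records: list[NucleusRecord]) -> ViabilityResult:
    """Count classes and form the viability percentage (missing when undefined)."""
    n_viable = sum(1 for rec in records if rec.klass == "viable")
    n_dead = sum(1 for rec in records if rec.klass == "dead")
    n_uncl = sum(1 for rec in records if rec.klass == "unclassified")
    return ViabilityResult(n_viable, n_dead, n_uncl)


def jarque_bera(values, alpha: float = 0.05) -> JarqueBeraResult:
    """Jarque–Bera normality test: JB = n/6 * (S^2 + (K - 3)^2 / 4).

    S is the sample skewness and K the (non-excess) sample kurtosis, both from
    biased central moments; the p-value comes from the chi-squared(2) reference
    distribution.  Requires n >= 3 and nonzero variance; a small-sample caveat
    is warned for n < 30 (the chi-squared approximation is asymptotic).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3 or not np.all(np.isfinite(x)):
        raise ValueError("need at least 3 finite values in a 1-D array")
    n = x.size
    if n < 30:
        warnings.warn(
            f"Jarque-Bera with n={n} < 30: the chi-squared reference is asymptotic "
            "and the test has little power",
            stacklevel=2,
        )
    d = x - x.mean()
    m2 = float((d**2).mean())
    if m2 == 0:
        raise ValueError("zero variance: Jarque-Bera statistic is undefined")
    skew = float((d**3).mean()) / m2**1.5
    kurt = float((d**4).mean()) / m2**2
    jb = n / 6.0 * (skew**2 + (kurt - 3.0) ** 2 / 4.0)
    p = float(stats.chi2.sf(jb, df=2))
    return JarqueBeraResult(float(jb), p, normal=p >= alpha, alpha=alpha)


def one_way_anova(groups, alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA from the sum-of-squares decomposition.

    F = (SSB / (k-1)) / (SSW / (N-k)) with p from the F(k-1, N-k) distribution.
    Degenerate data with zero within-group variance yields F = +inf and p = 0
    (with a warning), except when the between-group variance is also zero, in
    which case F = 0 and p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 values")
    k = len(arrays)
    sizes = np.array([a.size for a in arrays])
    n_total = int(sizes.sum())
    grand = float(np.concatenate(arrays).mean())
    means = np.array([a.mean() for a in arrays])
    ssb = float((sizes * (means - grand) ** 2).sum())
    ssw = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_b, df_w = k - 1, n_total - k
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(0.0, df_b, df_w, 1.0, False, alpha)
        warnings.warn(
            "zero within-group variance: F is infinite (degenerate data)",
            stacklevel=2,
        )
        return AnovaResult(math.inf, df_b, df_w, 0.0, True, alpha)
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), df_b, df_w, p, p < alpha, alpha)


def aggregate_condition(
    per_image_results,
    grouping,
    alpha: float = 0.05,
    pooling: str = "pooled",
) -> GroupStats:
    """Aggregate per-image counts into condition statistics.

    Parameters
    ----------
    per_image_results
        Iterable of ``(sample_id, ViabilityResult)`` pairs, one per image
        (frame).  A sample is one biological replicate.
    grouping
        Mapping ``sample_id -> condition``; every imaged sample must appear.
    pooling
        ``'pooled'`` (default) sums viable/dead counts over all frames of a
        replicate before forming its viability, which weights frames by cell
        count; ``'frame'`` averages the per-frame viabilities instead.

    Per condition the replicate viabilities are summarized as mean and sd,
    screened with Jarque–Bera where possible (n >= 3, nonzero variance), and
    compared across conditions by one-way ANOVA.  Conditions with a single
    replicate are excluded from the ANOVA with a warning.
    """
    if pooling not in ("pooled", "frame"):
        raise ValueError("pooling must be 'pooled' or 'frame'")
    per_sample: dict[str, list[ViabilityResult]] = {}
    for sample_id, result in per_image_results:
        if sample_id not in grouping:
            raise ValueError(f"sample {sample_id!r} has no condition in the grouping map")
        per_sample.setdefault(sample_id, []).append(result)

    replicate_viability: dict[str, float] = {}
    for sample_id, results in per_sample.items():
        if pooling == "pooled":
            nv = sum(r.n_viable for r in results)
            nd = sum(r.n_dead for r in results)
            value = 100.0 * nv / (nv + nd) if (nv + nd) else None
        else:
            defined = [r.viability_percent for r in results if r.defined]
            value = float(np.mean(defined)) if defined else None
        if value is None:
            warnings.warn(
                f"sample {sample_id!r} has no classified cells; viability undefined, "
                "replicate dropped",
                stacklevel=2,
            )
            continue
        replicate_viability[sample_id] = value

    values: dict[str, list[float]] = {}
    for sample_id, value in replicate_viability.items():
        values.setdefault(grouping[sample_id], []).append(value)
    labels = sorted(values)
    stats_out = GroupStats(labels=labels, values=values, alpha=alpha)
    for cond in labels:
        v = np.asarray(values[cond], dtype=float)
        stats_out.means[cond] = float(v.mean())
        stats_out.sds[cond] = float(v.std(ddof=1)) if v.size > 1 else 0.0
        jb = None
        if v.size >= 3 and np.ptp(v) > 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # small-sample caveat is implied here
                jb = jarque_bera(v, alpha=alpha)
        stats_out.jarque_bera[cond] = jb

    eligible = [cond for cond in labels if len(values[cond]) >= 2]
    skipped = set(labels) - set(eligible)
    if skipped:
        warnings.warn(
            f"conditions excluded from ANOVA (single replicate): {sorted(skipped)}",
            stacklevel=2,
        )
    if len(eligible) >= 2:
        stats_out.anova = one_way_anova([values[c] for c in eligible], alpha=alpha)
    return stats_out
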