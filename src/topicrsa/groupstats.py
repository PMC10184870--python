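"""Group-level inference for ROI and searchlight RSA outputs.

One-tailed one-sample and paired t-tests (the paired test is the two-level
GLM with subject constants in its two-condition form), Bonferroni-adjusted
alpha levels, paired Cohen's d, voxelwise paired contrasts, and a sign-flip
permutation substitute for random-field FWE cluster correction: clusters are
face-connected components above a cluster-forming one-tailed threshold, and
the null distribution of the maximal cluster extent is built by randomly
negating each subject's difference map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

logger = logging.getLogger("topicrsa")

#: finite stand-in for an infinite t in voxel maps (zero-variance, nonzero
#: mean differences — "degenerate certain")
DEGENERATE_T = 1e10

__all__ = [
    "TestResult",
    "ClusterRow",
    "ClusterTable",
    "one_sample_ttest_onetailed",
    "paired_ttest_onetailed",
    "bonferroni_alpha",
    "cohens_d_paired",
    "voxelwise_paired_contrast",
    "cluster_correct_permutation",
]


@dataclass
class TestResult:
    """One-tailed t-test outcome."""

    t: float
    df: int
    p: float
    direction: str
    n: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.df != self.n - 1:
            raise ValueError("df must equal n - 1")
        if not 0 <= self.p <= 1:
            raise ValueError("p must be in [0, 1]")


@dataclass
class ClusterRow:
    extent: int
    peak_t: float
    peak_voxel: tuple[int, int, int]
    p_corrected: float


@dataclass
class ClusterTable:
    rows: list[ClusterRow] = field(default_factory=list)
    n_permutations: int = 0

    def __iter__(self):
        return iter(self.rows)

    def __len__(self):
        return len(self.rows)

    def significant(self, alpha: float = 0.05) -> list[ClusterRow]:
        return [r for r in self.rows if r.p_corrected < alpha]

    def to_tsv(self, path) -> None:
        lines = ["extent\tpeak_t\tpeak_x\tpeak_y\tpeak_z\tp_corrected"]
        for r in self.rows:
            x, y, z = r.peak_voxel
            lines.append(f"{r.extent}\t{r.peak_t:.6g}\t{x}\t{y}\t{z}\t{r.p_corrected:.6g}")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")


def _onetailed_p(t: float, df: int, direction: str) -> float:
    if direction == "greater":
        return float(stats.t.sf(t, df))
    if direction == "less":
        return float(stats.t.cdf(t, df))
    raise ValueError("direction must be 'greater' or 'less'")


def one_sample_ttest_onetailed(values, direction: str = "greater") -> TestResult:
    """t = mean / (sd / sqrt(n)) with sample sd; p from the stated tail.

    Zero variance with zero mean is undefined (error); zero variance with a
    nonzero mean is a degenerate-certain outcome (t = ±inf, flagged).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need n >= 2")
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        if mean == 0:
            raise ValueError("zero variance with zero mean: t undefined")
        t = np.inf if mean > 0 else -np.inf
        p = 0.0 if (mean > 0) == (direction == "greater") else 1.0
        return TestResult(float(t), n - 1, p, direction, n, degenerate=True)
    t = mean / (sd / np.sqrt(n))
    return TestResult(float(t), n - 1, _onetailed_p(t, n - 1, direction), direction, n)


def paired_ttest_onetailed(a, b, direction: str = "greater") -> TestResult:
    """One-sample one-tailed test on the paired differences a - b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("a and b must have equal length")
    return one_sample_ttest_onetailed(a - b, direction)


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-test alpha = alpha / m (display at 4 dp)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def cohens_d_paired(a, b) -> float:
    """mean(a - b) / sd(a - b) with sample sd."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if d.size < 2:
        raise ValueError("need n >= 2")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: d undefined")
    return float(d.mean() / sd)


def _tmap_from_diffs(diffs: np.ndarray) -> np.ndarray:
    """Voxelwise one-sample t over subjects (axis 0); NaN where fewer than 2
    finite subjects, DEGENERATE_T where variance is 0 with nonzero mean."""
    valid = np.isfinite(diffs)
    n = valid.sum(axis=0)
    d0 = np.where(valid, diffs, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = d0.sum(axis=0) / n
        var = (np.where(valid, (diffs - mean) ** 2, 0.0)).sum(axis=0) / np.maximum(n - 1, 1)
        t = mean / np.sqrt(var / n)
    t = np.asarray(t)
    zero_var = (var == 0) & (n >= 2)
    t[zero_var & (mean > 0)] = DEGENERATE_T
    t[zero_var & (mean < 0)] = -DEGENERATE_T
    t[zero_var & (mean == 0)] = np.nan
    t[n < 2] = np.nan
    return t


def voxelwise_paired_contrast(
    maps_a: list, maps_b: list, direction: str = "greater"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel paired one-tailed t over subjects; returns (t-map, p-map).

    ``maps_a`` / ``maps_b`` are per-subject SearchlightMaps (or bare arrays)
    with aligned geometry; sentinel (NaN) voxels are excluded per voxel, and
    voxels with fewer than 2 valid subjects stay NaN.
    """
    if len(maps_a) != len(maps_b) or len(maps_a) < 2:
        raise ValueError("need equal-length subject lists, n >= 2")
    A = np.stack([np.asarray(getattr(m, "data", m), dtype=float) for m in maps_a])
    B = np.stack([np.asarray(getattr(m, "data", m), dtype=float) for m in maps_b])
    if A.shape != B.shape:
        raise ValueError("map geometries are not aligned")
    diffs = A - B
    t = _tmap_from_diffs(diffs)
    n = np.isfinite(diffs).sum(axis=0)
    p = np.full(t.shape, np.nan)
    ok = np.isfinite(t)
    with np.errstate(invalid="ignore"):
        if direction == "greater":
            p[ok] = stats.t.sf(t[ok], np.maximum(n[ok] - 1, 1))
        elif direction == "less":
            p[ok] = stats.t.cdf(t[ok], np.maximum(n[ok] - 1, 1))
        else:
            raise ValueError("direction must be 'greater' or 'less'")
    return t, p


_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def _max_cluster_extent(supra: np.ndarray) -> int:
    labels, n = ndimage.label(supra, structure=_FACE_STRUCTURE)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def cluster_correct_permutation(
    diff_maps: np.ndarray | list,
    cluster_forming_p: float = 0.001,
    n_permutations: int = 1000,
    seed: int = 0,
    direction: str = "greater",
) -> ClusterTable:
    """Sign-flip permutation FWE correction by maximal cluster extent.

    Observed clusters are face-connected components of voxels whose one-tailed
    one-sample t (over subjects' difference maps) exceeds the cluster-forming
    threshold.  The null distribution of the maximal cluster extent is built
    by randomly negating each subject's difference map; corrected
    p = (1 + #{perm max extent >= observed}) / (1 + n_permutations).
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    D = np.stack([np.asarray(getattr(m, "data", m), dtype=float) for m in diff_maps])
    n_sub = D.shape[0]
    df = n_sub - 1
    sign = 1.0 if direction == "greater" else -1.0
    t_crit = float(stats.t.isf(cluster_forming_p, df))

    t_obs = _tmap_from_diffs(D)
    supra = np.nan_to_num(sign * t_obs, nan=-np.inf) > t_crit
    labels, n_clust = ndimage.label(supra, structure=_FACE_STRUCTURE)
    if n_clust == 0:
        return ClusterTable([], n_permutations)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_permutations, dtype=int)
    for i in range(n_permutations):
        flips = rng.choice([-1.0, 1.0], size=n_sub)
        t_perm = _tmap_from_diffs(D * flips[:, None, None, None])
        null_max[i] = _max_cluster_extent(
            np.nan_to_num(sign * t_perm, nan=-np.inf) > t_crit
        )

    rows = []
    for c in range(1, n_clust + 1):
        members = labels == c
        extent = int(members.sum())
        tvals = np.where(members, sign * t_obs, -np.inf)
        peak = np.unravel_index(int(np.argmax(tvals)), t_obs.shape)
        p_corr = (1 + int((null_max >= extent).sum())) / (1 + n_permutations)
        rows.append(
            ClusterRow(extent, float(sign * tvals[peak]), tuple(int(x) for x in peak), p_corr)
        )
    rows.sort(key=lambda r: -r.extent)
    return ClusterTable(rows, n_permutations)
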