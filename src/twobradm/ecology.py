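"""Community ecology statistics for case-control abundance studies.

Alpha diversity (Chao1, Shannon, Simpson), beta diversity (Bray-Curtis,
binary Jaccard, Euclidean) with PERMANOVA, rank-sum group comparisons,
shared/unique species partitions, and inter-kingdom Spearman
correlation networks.

Conventions:

* Chao1 operates on integer read counts (it needs singleton/doubleton
  frequencies); Shannon and Simpson renormalize the same counts to
  proportions.  Shannon uses the natural logarithm.
* Beta diversity is computed on relative abundances (binary Jaccard on
  presence/absence) so samples of different sequencing depth are
  comparable.
* Permutation p-values use the add-one convention
  ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu, spearmanr, wilcoxon
from skbio.stats.distance import DistanceMatrix

logger = logging.getLogger(__name__)

BETA_METRICS = ("bray_curtis", "jaccard_binary", "euclidean")


@dataclass
class AbundanceStudy:
    """Species x sample abundance study with group labels.

    ``matrix`` holds relative abundances (columns sum to 1 over detected
    species, or are all zero for an empty sample); ``counts`` holds the
    integer assigned-read counts S with the same shape and labels.
    ``groups`` maps sample id -> group label; ``kingdom`` (optional)
    maps species -> kingdom; ``lineage`` (optional) is a species x rank
    table used for taxonomic aggregation.
    """

    matrix: pd.DataFrame
    counts: pd.DataFrame
    groups: pd.Series
    kingdom: pd.Series | None = None
    lineage: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.matrix.shape != self.counts.shape:
            raise ValueError("matrix and counts shapes differ")
        if not (self.matrix.index.equals(self.counts.index)
                and self.matrix.columns.equals(self.counts.columns)):
            raise ValueError("matrix and counts labels differ")
        missing = set(self.matrix.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        self.groups = self.groups.loc[self.matrix.columns]
        colsum = self.matrix.sum(axis=0)
        ok = np.isclose(colsum, 1.0, atol=1e-6) | np.isclose(colsum, 0.0)
        if not ok.all():
            bad = list(self.matrix.columns[~ok])
            raise ValueError(f"abundance columns must sum to 1 (or 0): {bad}")

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def species(self) -> list[str]:
        return list(self.matrix.index)

    def group_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


# ---------------------------------------------------------------- alpha

def _check_counts(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.size and arr.min() < 0:
        raise ValueError("negative counts")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("Chao1 requires integer read counts, not proportions")
    return np.round(arr).astype(np.int64)


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1))."""
    arr = _check_counts(counts)
    s_obs = int((arr > 0).sum())
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def _proportions(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size and arr.min() < 0:
        raise ValueError("negative abundances")
    total = arr.sum()
    return arr / total if total > 0 else arr


def shannon(values) -> float:
    """Shannon entropy H = -sum p ln p (natural log), from counts or proportions."""
    p = _proportions(values)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum()) if p.size else 0.0


def simpson(values) -> float:
    """Gini-Simpson index 1 - sum p^2, from counts or proportions."""
    p = _proportions(values)
    return float(1.0 - (p ** 2).sum()) if p.size else 0.0


def alpha_diversity_table(study: AbundanceStudy) -> pd.DataFrame:
    """Per-sample Chao1 / Shannon / Simpson from the count matrix."""
    rows = []
    for s in study.samples:
        c = study.counts[s].to_numpy()
        rows.append((s, chao1(c), shannon(c), simpson(c)))
    return pd.DataFrame(rows, columns=["sample", "chao1", "shannon", "simpson"]
                        ).set_index("sample")


# ----------------------------------------------------------------- beta

def beta_distance(study_or_matrix, metric: str) -> DistanceMatrix:
    """Pairwise sample distances under one of the supported metrics.

    ``bray_curtis`` and ``euclidean`` act on relative abundances;
    ``jaccard_binary`` on presence/absence.
    """
    if isinstance(study_or_matrix, AbundanceStudy):
        mat = study_or_matrix.matrix
    else:
        mat = study_or_matrix
    if mat.shape[1] < 2:
        raise ValueError("beta diversity needs at least 2 samples")
    X = mat.to_numpy(dtype=float).T  # samples x species
    if metric == "bray_curtis":
        d = pdist(X, metric="braycurtis")
    elif metric == "jaccard_binary":
        d = pdist(X > 0, metric="jaccard")
    elif metric == "euclidean":
        d = pdist(X, metric="euclidean")
    else:
        raise ValueError(f"unknown beta-diversity metric {metric!r}; "
                         f"choose from {BETA_METRICS}")
    return DistanceMatrix(squareform(np.nan_to_num(d)), ids=list(mat.columns))


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    n_samples: int
    n_groups: int


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = len(codes)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        # identical samples within every group: complete separation if any
        # among-group spread remains, otherwise no structure at all
        return np.inf if ss_among > 0 else 0.0
    return (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(dm: DistanceMatrix, groups, n_perm: int = 999,
              seed: int | None = None) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    The pseudo-F statistic compares among-group to within-group sums of
    squared distances; significance comes from ``n_perm`` random label
    permutations with the add-one p-value convention, so the smallest
    attainable p is ``1 / (1 + n_perm)``.
    """
    if isinstance(groups, pd.Series):
        groups = groups.loc[list(dm.ids)]
    labels = np.asarray(groups)
    if len(labels) != len(dm.ids):
        raise ValueError("group labels do not match distance matrix size")
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        raise ValueError("every group needs at least 2 samples")
    d2 = dm.data.astype(float) ** 2
    f_obs = _pseudo_f(d2, codes, len(uniq))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _pseudo_f(d2, rng.permutation(codes), len(uniq)) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(pseudo_f=float(f_obs), p_value=float(p),
                           n_permutations=n_perm, n_samples=len(labels),
                           n_groups=len(uniq))


# ------------------------------------------------------- group testing

def rank_sum_test(x, y, paired: bool = False) -> tuple[float, float]:
    """Two-sided rank test between two samples.

    Unpaired: Wilcoxon rank-sum (Mann-Whitney U), exact enumeration for
    small tie-free samples (n <= 10 per group), tie-corrected normal
    approximation otherwise.  Paired: Wilcoxon signed-rank; identical
    vectors return (0, 1) by contract (no nonzero differences to rank).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    if paired:
        if x.size != y.size:
            raise ValueError("paired test requires equal-length samples")
        if np.all(x == y):
            return 0.0, 1.0
        res = wilcoxon(x, y, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < combined.size
    method = "exact" if (max(x.size, y.size) <= 10 and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------- venn

@dataclass
class VennCounts:
    """Shared/unique species partition between two groups."""

    group_a: str
    group_b: str
    shared: int
    unique_a: int
    unique_b: int

    @property
    def total(self) -> int:
        return self.shared + self.unique_a + self.unique_b

    def percentages(self) -> dict[str, float]:
        t = self.total or 1
        return {"shared": 100.0 * self.shared / t,
                f"unique_{self.group_a}": 100.0 * self.unique_a / t,
                f"unique_{self.group_b}": 100.0 * self.unique_b / t}


def venn_counts(study: AbundanceStudy) -> VennCounts:
    """Partition species by detection in each group.

    A species counts as detected in a group when it has screened-in
    abundance > 0 in at least one sample of that group.
    """
    labels = study.group_labels()
    if len(labels) != 2:
        raise ValueError(f"venn_counts needs exactly 2 groups, got {labels}")
    a, b = labels
    present = study.matrix > 0
    in_a = present[study.samples_in(a)].any(axis=1)
    in_b = present[study.samples_in(b)].any(axis=1)
    return VennCounts(group_a=a, group_b=b,
                      shared=int((in_a & in_b).sum()),
                      unique_a=int((in_a & ~in_b).sum()),
                      unique_b=int((in_b & ~in_a).sum()))


# ---------------------------------------------------- correlation nets

def _aggregate(matrix: pd.DataFrame, lineage: pd.DataFrame | None,
               level: str) -> pd.DataFrame:
    if lineage is None:
        raise ValueError("study has no lineage table for taxonomic aggregation")
    if level not in lineage.columns:
        raise ValueError(f"rank {level!r} not in lineage table "
                         f"(has {list(lineage.columns)})")
    ranks = lineage[level].reindex(matrix.index)
    if ranks.isna().any():
        missing = list(matrix.index[ranks.isna()])
        raise ValueError(f"species missing from lineage table: {missing}")
    return matrix.groupby(ranks).sum()


def aggregate_to_rank(study: AbundanceStudy, level: str) -> pd.DataFrame:
    """Sum species abundances up to a taxonomic rank (needs ``lineage``)."""
    return _aggregate(study.matrix, study.lineage, level)


def correlation_network(study: AbundanceStudy, level: str = "phylum",
                        scope: tuple[str, str] = ("bacteria", "fungi"),
                        rho_threshold: float = 0.0) -> pd.DataFrame:
    """Spearman co-abundance edges between two kingdoms, per group.

    Species are aggregated to ``level`` within each kingdom of ``scope``;
    for every cross-kingdom taxon pair and every group, Spearman rho and
    p are computed across that group's samples.  Edges with
    ``|rho| < rho_threshold`` (or undefined rho) are dropped.
    """
    if study.kingdom is None:
        raise ValueError("study has no kingdom annotation")
    king_a, king_b = scope
    rows = []
    agg = {}
    for king in scope:
        sp = study.kingdom.index[study.kingdom == king]
        sp = [s for s in sp if s in study.matrix.index]
        if not sp:
            raise ValueError(f"no species of kingdom {king!r} in study")
        lineage = None if study.lineage is None else study.lineage.loc[sp]
        agg[king] = _aggregate(study.matrix.loc[sp], lineage, level)
    for group in study.group_labels():
        cols = study.samples_in(group)
        for ta in agg[king_a].index:
            va = agg[king_a].loc[ta, cols].to_numpy(dtype=float)
            for tb in agg[king_b].index:
                vb = agg[king_b].loc[tb, cols].to_numpy(dtype=float)
                rho, p = spearmanr(va, vb)
                if np.isnan(rho) or abs(rho) < rho_threshold:
                    continue
                rows.append((ta, tb, float(rho), float(p), group))
    return pd.DataFrame(rows, columns=["taxon1", "taxon2", "rho", "p", "group"])
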