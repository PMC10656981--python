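"""Differential-taxon discovery and single-feature diagnostics.

Four stages mirror a standard microbiome biomarker workflow:

* :func:`indval` — Dufrene-Legendre indicator value per species:
  specificity A (share of the species' mean abundance found in a group)
  times fidelity B (fraction of the group's samples where the species
  is detected), significance by group-label permutation.
* :func:`lefse_lite` — a deterministic effect-size ranking: a
  Kruskal-Wallis screen at ``alpha`` followed by a signed
  log10 scaled-mean-difference score.  This replaces the bootstrap-LDA
  internals of the original LEfSe procedure with a simpler score that
  serves the same ranking/display role.
* :func:`ensemble_importance` — a bagged decision-tree ensemble
  (mtry = floor(sqrt(p)) features per split) reporting the two
  randomForest-style importances: mean decrease in Gini impurity and
  mean decrease in out-of-bag accuracy under per-feature permutation.
* :func:`roc_auc` — single-feature ROC/AUC via the rank (Mann-Whitney)
  formulation with half-credit for ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kruskal, rankdata
from sklearn.tree import DecisionTreeClassifier

from .ecology import AbundanceStudy

logger = logging.getLogger(__name__)


# --------------------------------------------------------------- IndVal

@dataclass
class IndicatorResult:
    """Indicator value of one species: indval = A (specificity) x B (fidelity)."""

    species: str
    group: str
    A: float
    B: float
    indval: float
    p: float


def _indval_components(X: np.ndarray, masks: list[np.ndarray]):
    """Per-species max-over-groups indicator value and argmax group."""
    means = np.stack([X[:, m].mean(axis=1) for m in masks])        # G x S
    denom = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(denom > 0, means / denom, 0.0)
    B = np.stack([(X[:, m] > 0).mean(axis=1) for m in masks])
    iv = A * B
    return iv.max(axis=0), iv.argmax(axis=0), A, B


def indval(study: AbundanceStudy, n_perm: int = 999,
           seed: int | None = None) -> list[IndicatorResult]:
    """Indicator-species analysis with permutation p-values.

    For each species the statistic is the maximum over groups of
    A_{i,g} * B_{i,g}; p is the add-one permutation probability of an
    equal or larger statistic under random group labels.  Species absent
    from every sample are skipped (logged).
    """
    labels = study.group_labels()
    if len(labels) < 2:
        raise ValueError("indval needs at least 2 groups")
    for g in labels:
        if len(study.samples_in(g)) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    X = study.matrix.to_numpy(dtype=float)
    species = np.array(study.species)
    nonzero = X.sum(axis=1) > 0
    if not nonzero.all():
        logger.info("indval: skipping %d species absent from every sample",
                    int((~nonzero).sum()))
    X = X[nonzero]
    species = species[nonzero]
    grp = study.groups.to_numpy()
    masks = [grp == g for g in labels]

    iv_obs, argmax, A, B = _indval_components(X, masks)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(species), dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(X.shape[1])
        iv_perm, _, _, _ = _indval_components(X, [m[perm] for m in masks])
        exceed += iv_perm >= iv_obs
    pvals = (1 + exceed) / (1 + n_perm)

    results = [
        IndicatorResult(species=sp, group=labels[g],
                        A=float(A[g, i]), B=float(B[g, i]),
                        indval=float(iv_obs[i]), p=float(pvals[i]))
        for i, (sp, g) in enumerate(zip(species, argmax))
    ]
    results.sort(key=lambda r: (-r.indval, r.species))
    return results


# ----------------------------------------------------------- LEfSe-lite

@dataclass
class EffectSizeResult:
    """Signed log10 effect size for one differentially abundant species."""

    species: str
    kw_p: float
    enriched_group: str
    lda_like_score: float


def lefse_lite(study: AbundanceStudy, alpha: float = 0.05,
               scale: float = 1e6) -> list[EffectSizeResult]:
    """Kruskal-Wallis screen + signed log10 scaled-mean-difference score.

    Abundances are scaled by ``scale`` (per-million by default), and for
    species passing the KW test at ``alpha`` the effect is
    ``log10(|mean_a - mean_b| + 1)`` with the sign pointing at the
    enriched group (positive for the first group label).  Constant
    species are excluded.  Results are sorted by |effect| descending.
    """
    labels = study.group_labels()
    if len(labels) != 2:
        raise ValueError("lefse_lite needs exactly 2 groups")
    a, b = labels
    cols_a, cols_b = study.samples_in(a), study.samples_in(b)
    out: list[EffectSizeResult] = []
    for sp in study.species:
        va = study.matrix.loc[sp, cols_a].to_numpy(dtype=float)
        vb = study.matrix.loc[sp, cols_b].to_numpy(dtype=float)
        pooled = np.concatenate([va, vb])
        if np.all(pooled == pooled[0]):
            continue  # constant taxon: kw undefined, excluded
        kw_p = float(kruskal(va, vb).pvalue)
        if kw_p >= alpha:
            continue
        ma, mb = va.mean() * scale, vb.mean() * scale
        effect = float(np.log10(abs(ma - mb) + 1.0))
        enriched = a if ma >= mb else b
        out.append(EffectSizeResult(species=sp, kw_p=kw_p, enriched_group=enriched,
                                    lda_like_score=effect if enriched == a else -effect))
    out.sort(key=lambda r: (-abs(r.lda_like_score), r.species))
    return out


# ----------------------------------------------- random-forest importances

@dataclass
class ImportanceResult:
    """randomForest-style importances for one feature (species)."""

    species: str
    mean_decrease_gini: float
    mean_decrease_accuracy: float


def ensemble_importance(study: AbundanceStudy, n_trees: int = 500,
                        seed: int | None = None) -> list[ImportanceResult]:
    """Bagged-tree feature importances: mean decrease Gini and accuracy.

    Each of ``n_trees`` CART trees is grown on a bootstrap sample with
    mtry = floor(sqrt(p)) candidate features per split.  Gini importance
    accumulates each feature's total split-impurity decrease, averaged
    over trees; accuracy importance is the average drop in out-of-bag
    accuracy when the feature's values are permuted among the OOB
    samples.  Fully deterministic for a given seed; output sorted by
    Gini importance with ties broken by species name.
    """
    X = study.matrix.to_numpy(dtype=float).T  # samples x species
    features = list(study.species)
    classes, y = np.unique(study.groups.to_numpy(), return_inverse=True)
    if len(classes) < 2:
        raise ValueError("ensemble_importance needs at least 2 classes")
    n, p = X.shape
    rng = np.random.default_rng(seed)
    gini_total = np.zeros(p)
    acc_drop_sum = np.zeros(p)
    acc_drop_trees = 0
    for _ in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot)
        if len(np.unique(y[boot])) < 2:
            continue
        tree = DecisionTreeClassifier(
            max_features="sqrt",
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(X[boot], y[boot])
        gini_total += tree.tree_.compute_feature_importances(normalize=False)
        if len(oob) == 0:
            continue
        X_oob = X[oob]
        y_oob = y[oob]
        m = len(oob)
        # one batched prediction per tree: intact OOB block + one block
        # per feature with that feature's values permuted among OOB rows
        stacked = np.tile(X_oob, (p + 1, 1))
        for j in range(p):
            block = slice((j + 1) * m, (j + 2) * m)
            stacked[block, j] = X_oob[rng.permutation(m), j]
        raw = tree.tree_.predict(np.ascontiguousarray(stacked, dtype=np.float32))
        pred = raw.reshape(p + 1, m, -1).argmax(axis=2)
        acc = (pred == y_oob[None, :]).mean(axis=1)
        acc_drop_sum += acc[0] - acc[1:]
        acc_drop_trees += 1
    mdg = gini_total / n_trees
    mda = acc_drop_sum / max(acc_drop_trees, 1)
    results = [ImportanceResult(species=sp, mean_decrease_gini=float(mdg[j]),
                                mean_decrease_accuracy=float(mda[j]))
               for j, sp in enumerate(features)]
    results.sort(key=lambda r: (-r.mean_decrease_gini, r.species))
    return results


# ------------------------------------------------------------------ ROC

def roc_auc(scores, labels, positive=None) -> tuple[float, pd.DataFrame]:
    """AUC via the rank (Mann-Whitney) formulation, plus the ROC curve.

    ``labels`` may be boolean or two-valued; ``positive`` names the
    positive class (defaults to True/1, or must be given explicitly for
    string labels).  Ties receive half credit.  The curve sweeps the
    observed score values as thresholds (score >= threshold => predicted
    positive) and includes the (0, 0) endpoint.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    if positive is None:
        uniq = set(np.unique(labels).tolist())
        if uniq <= {0, 1} or uniq <= {False, True}:
            positive = 1
        else:
            raise ValueError(f"ambiguous labels {sorted(map(str, uniq))}; "
                             "pass positive= explicitly")
    pos = labels == positive
    n1 = int(pos.sum())
    n0 = int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)  # average ranks: half credit for ties
    auc = (ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    thresholds = np.unique(scores)[::-1]
    rows = [(np.inf, 0.0, 0.0)]
    for thr in thresholds:
        pred = scores >= thr
        tpr = float((pred & pos).sum()) / n1
        fpr = float((pred & ~pos).sum()) / n0
        rows.append((float(thr), fpr, tpr))
    curve = pd.DataFrame(rows, columns=["threshold", "fpr", "tpr"])
    return float(auc), curve
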