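"""Cohort-level statistics on a samples x drugs DSS matrix: subtype group
comparisons, pairwise subtype correlations, Ward/Euclidean clustering, PCA and
empirical-Bayes differential drug sensitivity with BH adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from statsmodels.stats.multitest import multipletests

from .dss import ScreenMatrix, effectiveness_calls

logger = logging.getLogger(__name__)


def sem(values) -> float:
    """Standard error of the mean, sd/sqrt(n) with ddof=1."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        return float("nan")
    return float(values.std(ddof=1) / np.sqrt(len(values)))


def welch_t(a, b) -> tuple[float, float]:
    """Two-tailed Welch's t test; (t, p).

    Returns (0, 1) for two identical groups even when both are constant
    (scipy yields NaN there); groups smaller than 2 give (nan, nan).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return float("nan"), float("nan")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (float("inf"), 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def one_way_anova(*groups) -> tuple[float, float]:
    """One-way ANOVA F test across >=2 groups; (F, p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in groups):
        return float("nan"), float("nan")
    if all(g.std(ddof=1) == 0 for g in groups):
        means = {g.mean() for g in groups}
        return (0.0, 1.0) if len(means) == 1 else (float("inf"), 0.0)
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def subtype_group_stats(matrix: ScreenMatrix, level: str = "class",
                        threshold: float = 10.0) -> pd.DataFrame:
    """Per-subtype summary with Welch pairwise and ANOVA p-values.

    level="class": per-sample effective-drug fractions for all/chemotherapy/
    targeted, aggregated per subtype (mean +/- SEM).  level="drug": raw DSS
    per drug.
    """
    subtypes = matrix.subtypes
    groups = sorted(subtypes.unique())

    if level == "class":
        fractions = effectiveness_calls(matrix, threshold=threshold).fractions
        units = fractions  # samples x {all, chemotherapy, targeted}
    elif level == "drug":
        units = matrix.dss
    else:
        raise ValueError(f"unknown level {level!r}")

    rows = []
    for col in units.columns:
        values = {g: units.loc[subtypes[subtypes == g].index, col].to_numpy()
                  for g in groups}
        row = {"unit": col}
        for g in groups:
            row[f"mean_{g}"] = float(np.mean(values[g])) if len(values[g]) else np.nan
            row[f"sem_{g}"] = sem(values[g])
        f, p = one_way_anova(*(values[g] for g in groups))
        row["anova_F"], row["anova_p"] = f, p
        for i, g1 in enumerate(groups):
            for g2 in groups[i + 1:]:
                t, p2 = welch_t(values[g1], values[g2])
                row[f"welch_t_{g1}_vs_{g2}"] = t
                row[f"welch_p_{g1}_vs_{g2}"] = p2
        rows.append(row)
    return pd.DataFrame(rows)


def pairwise_subtype_correlation(matrix: ScreenMatrix) -> pd.DataFrame:
    """Spearman rho between per-drug average DSS of each subtype pair."""
    subtypes = matrix.subtypes
    groups = sorted(subtypes.unique())
    means = {g: matrix.dss.loc[subtypes[subtypes == g].index].mean(axis=0)
             for g in groups}
    rows = []
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            v1, v2 = means[g1].to_numpy(), means[g2].to_numpy()
            if len(v1) < 3:
                raise ValueError("need >=3 shared drugs for correlation")
            if np.ptp(v1) == 0 or np.ptp(v2) == 0:
                rows.append({"group_a": g1, "group_b": g2, "rho": np.nan,
                             "p": np.nan, "flag": "constant_vector"})
                continue
            rho, p = stats.spearmanr(v1, v2)
            rows.append({"group_a": g1, "group_b": g2, "rho": float(rho),
                         "p": float(p), "flag": ""})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ClusteringResult:
    linkage_matrix: np.ndarray
    leaf_order: list[str]
    labels: pd.Series | None  # cluster id per sample when k requested


def hierarchical_clustering(matrix: ScreenMatrix,
                            k: int | None = None) -> ClusteringResult:
    """Ward linkage on Euclidean distances over DSS rows.

    Leaf order follows scipy's deterministic tie rule (earlier-formed cluster
    first).  ``k`` cuts the tree into that many flat clusters.
    """
    X = matrix.dss.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; impute or filter first")
    if X.shape[0] < 2:
        return ClusteringResult(np.empty((0, 4)), list(matrix.dss.index), None)
    Z = linkage(X, method="ward", metric="euclidean")
    order = [matrix.dss.index[i] for i in leaves_list(Z)]
    labels = None
    if k is not None:
        labels = pd.Series(fcluster(Z, t=k, criterion="maxclust"),
                           index=matrix.dss.index, name="cluster")
    return ClusteringResult(Z, order, labels)


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame  # samples x PCs
    loadings: pd.DataFrame  # drugs x PCs
    explained_fraction: np.ndarray
    dropped_columns: list[str]


def pca_projection(matrix: ScreenMatrix, n_components: int = 2,
                   scale: bool = True) -> PCAResult:
    """Column-centred (optionally unit-variance) SVD projection of samples.

    Zero-variance drugs are dropped with a log message.  Component signs are
    fixed so the largest-magnitude loading of each PC is positive.
    """
    if matrix.dss.shape[0] < 3:
        raise ValueError("need >=3 samples for PCA")
    X = matrix.dss.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [str(c) for c in matrix.dss.columns[~keep]]
    if dropped:
        logger.info("dropping %d zero-variance drugs before PCA", len(dropped))
    X = X[:, keep]
    X = X - X.mean(axis=0)
    if scale:
        X = X / X.std(axis=0, ddof=1)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    n_components = min(n_components, len(S))
    # Sign convention: largest-magnitude loading positive.
    for i in range(n_components):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    scores = pd.DataFrame(
        U[:, :n_components] * S[:n_components],
        index=matrix.dss.index,
        columns=[f"PC{i + 1}" for i in range(n_components)])
    loadings = pd.DataFrame(
        Vt[:n_components].T, index=matrix.dss.columns[keep],
        columns=scores.columns)
    explained = (S ** 2) / float(np.sum(S ** 2))
    return PCAResult(scores=scores, loadings=loadings,
                     explained_fraction=explained[:n_components],
                     dropped_columns=dropped)


def _moment_match_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Estimate prior df d0 and prior variance s0^2 for variance shrinkage.

    Under the scaled inverse-chi-square prior, sample variances follow
    s0^2 * F(d, d0); matching the first two moments of the observed variance
    distribution gives closed-form d0 and s0^2.  Degenerate cases fall back
    to complete pooling (very large d0).
    """
    s2 = s2[np.isfinite(s2)]
    m1 = float(np.mean(s2))
    v = float(np.var(s2, ddof=1)) if len(s2) > 1 else 0.0
    if m1 <= 0 or v <= 0:
        return 1e6, max(m1, 1e-12)
    r = v / m1 ** 2
    denom = r * d - 2.0
    if denom <= 0:
        return 1e6, m1
    d0 = (2.0 * (d - 2.0) + 4.0 * r * d) / denom
    if not np.isfinite(d0) or d0 <= 4.0:
        d0 = 4.0 + 1e-6
    d0 = min(d0, 1e6)
    s02 = m1 * (d0 - 2.0) / d0
    return float(d0), float(s02)


def moderated_ttest(A: np.ndarray, B: np.ndarray) -> pd.DataFrame:
    """Per-feature empirical-Bayes moderated t between two sample groups.

    ``A`` (nA x features) and ``B`` (nB x features).  Pooled per-feature
    variances are shrunk toward a common prior before the t statistic, which
    gains d0 prior degrees of freedom.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    nA, nB = A.shape[0], B.shape[0]
    if nA < 2 or nB < 2:
        raise ValueError("need >=2 samples per group")
    d = nA + nB - 2
    meanA, meanB = A.mean(axis=0), B.mean(axis=0)
    ssA = ((A - meanA) ** 2).sum(axis=0)
    ssB = ((B - meanB) ** 2).sum(axis=0)
    s2 = (ssA + ssB) / d
    d0, s02 = _moment_match_prior(s2, d)
    s2_post = (d0 * s02 + d * s2) / (d0 + d)
    se = np.sqrt(s2_post * (1.0 / nA + 1.0 / nB))
    effect = meanA - meanB
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / se
    t = np.where((se == 0) & (effect == 0), 0.0, t)
    df_total = min(d + d0, 1e7)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isnan(t), np.nan, p)
    return pd.DataFrame({"effect": effect, "t_mod": t, "p": p,
                         "s2": s2, "s2_post": s2_post})


def differential_sensitivity(matrix: ScreenMatrix, group_a, group_b,
                             threshold: float = 10.0) -> pd.DataFrame:
    """Volcano table of per-drug differential DSS between two sample groups.

    Drugs enter only if DSS >= threshold in at least one sample of either
    group.  Effects are mean(group_a) - mean(group_b); p-values come from the
    moderated t and q-values from Benjamini-Hochberg across included drugs.
    """
    group_a, group_b = list(group_a), list(group_b)
    sub = matrix.dss.loc[group_a + group_b]
    include = (sub >= threshold).any(axis=0)
    if not include.any():
        logger.warning("inclusion filter (DSS >= %g) removed every drug",
                       threshold)
        return pd.DataFrame(columns=["drug_id", "effect", "t_mod", "p", "q"])
    sub = sub.loc[:, include]
    res = moderated_ttest(sub.loc[group_a].to_numpy(),
                          sub.loc[group_b].to_numpy())
    res.insert(0, "drug_id", sub.columns.to_numpy())
    valid = res["p"].notna()
    q = np.full(len(res), np.nan)
    if valid.any():
        q[valid.to_numpy()] = multipletests(res.loc[valid, "p"],
                                            method="fdr_bh")[1]
    res["q"] = q
    return res.sort_values("p", kind="mergesort").reset_index(drop=True)
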