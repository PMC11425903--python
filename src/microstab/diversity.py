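"""Alpha/beta diversity, ordination, and the group tests behind them.

Shannon entropy is reported in nats (natural log), matching the R
``vegan`` default. Chao1 is the bias-corrected estimator and therefore
requires integer (rarefied) counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
from scipy.spatial.distance import pdist, squareform

from .tables import CountTable

logger = logging.getLogger(__name__)


@dataclass
class AlphaRecord:
    sample_id: str
    shannon: float
    chao1: float
    observed_otus: int


@dataclass
class OrdinationResult:
    """Classical-scaling (PCoA) embedding of a dissimilarity matrix."""

    sample_ids: list[str]
    coordinates: np.ndarray  # samples x axes, eigenvalue-ordered
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # per retained axis, sums <= 1


def shannon(counts) -> float:
    """Shannon entropy H = -sum p_i ln p_i over positive entries (nats)."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative abundances")
    total = counts.sum()
    if total <= 0:
        raise ValueError("Shannon is undefined for an all-zero profile")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1)).

    F1/F2 are singleton/doubleton counts, which only make sense on integer
    (e.g. rarefied) counts; relative abundances are rejected.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative abundances")
    if not np.allclose(counts, np.rint(counts)):
        raise ValueError("Chao1 requires integer counts")
    counts = np.rint(counts).astype(np.int64)
    if counts.sum() == 0:
        raise ValueError("Chao1 is undefined for an all-zero profile")
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def alpha_diversity(table: CountTable) -> list[AlphaRecord]:
    records = []
    for sid, col in zip(table.sample_ids, table.counts.T):
        records.append(
            AlphaRecord(
                sample_id=sid,
                shannon=shannon(col),
                chao1=chao1(col),
                observed_otus=int((col > 0).sum()),
            )
        )
    return records


def bray_curtis_matrix(table: CountTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples.

    d(a, b) = sum|a_i - b_i| / sum(a_i + b_i); symmetric, zero diagonal,
    values in [0, 1].
    """
    if table.n_samples < 2:
        raise ValueError("need at least two samples")
    sums = table.counts.sum(axis=0)
    if np.any(sums == 0):
        bad = [s for s, t in zip(table.sample_ids, sums) if t == 0]
        raise ValueError(f"Bray-Curtis undefined for all-zero samples: {bad}")
    d = squareform(pdist(table.counts.T, metric="braycurtis"))
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)


def pcoa(d: pd.DataFrame, n_axes: int = 2) -> OrdinationResult:
    """Principal coordinates (classical scaling) of a dissimilarity matrix.

    Negative eigenvalues (non-Euclidean input) are reported but only
    positive-eigenvalue axes are retained for coordinates.
    """
    dm = np.asarray(d, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(dm, dm.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    ids = list(d.index) if isinstance(d, pd.DataFrame) else [str(i) for i in range(len(dm))]
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm ** 2) @ j
    evals, evecs = scipy.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # numerically-zero eigenvalues are treated as zero
    tol = max(abs(evals[0]), 1.0) * 1e-10 if len(evals) else 0.0
    pos = evals > tol
    n_keep = min(n_axes, int(pos.sum()))
    coords = evecs[:, :n_keep] * np.sqrt(evals[:n_keep]) if n_keep else np.zeros((n, 0))
    pos_total = evals[pos].sum()
    prop = evals[:n_keep] / pos_total if pos_total > 0 else np.zeros(n_keep)
    return OrdinationResult(
        sample_ids=ids,
        coordinates=coords,
        eigenvalues=evals,
        proportion_explained=prop,
    )


def _permanova_f(d2: np.ndarray, groups: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F from the among/within partition of squared dissimilarities."""
    n = d2.shape[0]
    a = len(labels)
    ss_t = d2[np.triu_indices(n, k=1)].sum() / n
    ss_w = 0.0
    for g in labels:
        idx = np.where(groups == g)[0]
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_w += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_a = ss_t - ss_w
    if ss_w <= 0:
        return np.inf
    return (ss_a / (a - 1)) / (ss_w / (n - a))


def permanova(d, groups, n_perm: int = 999, seed: int = 0):
    """PERMANOVA (Adonis): pseudo-F plus a label-permutation p-value.

    p = (1 + #{permuted F >= observed}) / (n_perm + 1); reproducible for a
    fixed ``seed``. Groups with a single member are kept but warned about.
    """
    dm = np.asarray(d, dtype=float)
    groups = np.asarray(list(groups))
    if len(groups) != dm.shape[0]:
        raise ValueError("one group label per sample is required")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if np.any(counts < 2):
        singletons = labels[counts < 2].tolist()
        warnings.warn(f"groups with a single member: {singletons}")
    d2 = dm ** 2
    f_obs = _permanova_f(d2, groups, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        if _permanova_f(d2, perm, labels) >= f_obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return float(f_obs), float(p)


def group_trend(values, timepoints):
    """OLS of a per-sample scalar on integer-coded ordered timepoints.

    Returns ``(slope, p, adj_r2)`` with a two-sided slope test.
    """
    import statsmodels.api as sm

    values = np.asarray(values, dtype=float)
    codes = pd.Categorical(
        list(timepoints), categories=list(dict.fromkeys(timepoints)),
        ordered=True,
    ).codes.astype(float)
    if len(np.unique(codes)) < 3:
        raise ValueError("trend fit needs at least three distinct timepoints")
    x = sm.add_constant(codes)
    fit = sm.OLS(values, x).fit()
    return float(fit.params[1]), float(fit.pvalues[1]), float(fit.rsquared_adj)


def group_compare(values_a, values_b):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) for two independent groups.

    Exact enumeration when the combined sample is small (n <= 20) and
    untied; the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least three values")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) + len(b) <= 20 and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))
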