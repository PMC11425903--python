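"""Association layers: taxa-SCFA Spearman screens, Mantel tests,
abundance rankings and phase-to-phase abundance changes."""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .tables import CountTable, StudyMetadata

logger = logging.getLogger(__name__)


def spearman_screen(
    features_x: pd.DataFrame,
    features_y: pd.DataFrame,
    alpha: float = 0.05,
    min_pairs: int = 4,
) -> pd.DataFrame:
    """All-pairs Spearman correlations with Benjamini-Hochberg correction.

    Both inputs are samples x features and are inner-joined on their index,
    so features measured on only a subset of samples (e.g. SCFAs) are
    handled pairwise-complete. Pairs with fewer than ``min_pairs`` complete
    observations are excluded with a warning.

    Returns a long-format frame: feature_x, feature_y, rho, p, q,
    significant (q < alpha), n.
    """
    shared = features_x.index.intersection(features_y.index)
    if len(shared) == 0:
        raise ValueError("no shared sample IDs between the two feature tables")
    fx = features_x.loc[shared]
    fy = features_y.loc[shared]
    if (
        len(shared) >= min_pairs
        and not fx.isna().any().any()
        and not fy.isna().any().any()
    ):
        report = _spearman_screen_complete(fx, fy)
    else:
        report = _spearman_screen_pairwise(fx, fy, min_pairs)
    if len(report):
        reject, q, _, _ = multipletests(report["p"], method="fdr_bh")
        report["q"] = q
        report["significant"] = reject & (report["q"] < alpha)
    else:
        report["q"] = []
        report["significant"] = []
    return report


def _spearman_screen_complete(fx: pd.DataFrame, fy: pd.DataFrame) -> pd.DataFrame:
    """Vectorized all-pairs Spearman for complete data (t-approximation p)."""
    n = len(fx)
    rx = scipy.stats.rankdata(fx.to_numpy(dtype=float), axis=0)
    ry = scipy.stats.rankdata(fy.to_numpy(dtype=float), axis=0)

    def _std(z):
        z = z - z.mean(axis=0)
        sd = z.std(axis=0)
        sd[sd == 0] = np.inf  # constant feature -> rho 0
        return z / sd

    rho = (_std(rx).T @ _std(ry)) / n
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.isnan(t), np.where(np.abs(rho) == 1.0, 0.0, 1.0), p)
    rows = [
        {"feature_x": cx, "feature_y": cy, "rho": float(rho[i, j]),
         "p": float(min(p[i, j], 1.0)), "n": n}
        for i, cx in enumerate(fx.columns)
        for j, cy in enumerate(fy.columns)
    ]
    return pd.DataFrame(rows, columns=["feature_x", "feature_y", "rho", "p", "n"])


def _spearman_screen_pairwise(
    fx: pd.DataFrame, fy: pd.DataFrame, min_pairs: int
) -> pd.DataFrame:
    rows = []
    skipped = 0
    for cx in fx.columns:
        for cy in fy.columns:
            pair = pd.concat([fx[cx], fy[cy]], axis=1).dropna()
            if len(pair) < min_pairs:
                skipped += 1
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", scipy.stats.ConstantInputWarning)
                rho, p = scipy.stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
            if np.isnan(rho):
                skipped += 1
                continue
            rows.append({"feature_x": cx, "feature_y": cy, "rho": float(rho),
                         "p": float(p), "n": len(pair)})
    if skipped:
        warnings.warn(f"spearman_screen: excluded {skipped} pair(s) with "
                      f"fewer than {min_pairs} complete observations")
    return pd.DataFrame(rows, columns=["feature_x", "feature_y", "rho", "p", "n"])


def mantel(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel test: Pearson correlation of two distance matrices.

    The p-value permutes the rows/columns of the second matrix jointly;
    two-sided, reproducible for a fixed seed. Requires identical sample
    sets (order is aligned automatically).
    """
    ids1 = list(d1.index)
    if set(ids1) != set(d2.index):
        raise ValueError("Mantel requires the same sample set in both matrices")
    m1 = np.asarray(d1, dtype=float)
    m2 = np.asarray(d2.loc[ids1, ids1], dtype=float)
    for m in (m1, m2):
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("distance matrices must be symmetric")
    n = m1.shape[0]
    iu = np.triu_indices(n, k=1)
    v1 = m1[iu]

    def corr_with(mat: np.ndarray) -> float:
        v2 = mat[iu]
        if v1.std() == 0 or v2.std() == 0:
            return 0.0
        return float(np.corrcoef(v1, v2)[0, 1])

    r_obs = corr_with(m2)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if abs(corr_with(m2[np.ix_(perm, perm)])) >= abs(r_obs) - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return r_obs, float(p)


def top_taxa(table: CountTable, k: int = 30) -> list[str]:
    """Taxa ranked by mean relative abundance across all samples.

    Ties break lexicographically by taxon ID, so the ranking is stable.
    """
    if k > table.n_taxa:
        raise ValueError(f"k={k} exceeds the {table.n_taxa} taxa present")
    mean_rel = table.relative_abundance().mean(axis=1)
    order = sorted(
        range(table.n_taxa), key=lambda i: (-mean_rel[i], table.taxon_ids[i])
    )
    return [table.taxon_ids[i] for i in order[:k]]


def phase_change(
    table: CountTable,
    metadata: StudyMetadata,
    taxon: str,
    phase_a: str,
    phase_b: str,
    mode: str = "points",
) -> float:
    """Change in a taxon's mean relative abundance from phase_a to phase_b.

    ``mode='points'`` (default) reports percentage points (mean% in b minus
    mean% in a); ``mode='fold'`` reports the relative change in percent,
    100 * (mean_b - mean_a) / mean_a. The two readings of "up by X%" differ,
    so the mode is always explicit.
    """
    if taxon not in table.taxon_ids:
        raise KeyError(f"taxon {taxon!r} not in table")
    if mode not in ("points", "fold"):
        raise ValueError("mode must be 'points' or 'fold'")
    meta = metadata.align_to(table)
    rel = table.relative_abundance()[table.taxon_ids.index(taxon)]
    means = {}
    for phase in (phase_a, phase_b):
        idx = meta.frame.index[meta.frame["phase"] == phase].to_numpy()
        if len(idx) < 2:
            raise ValueError(f"phase {phase!r} has fewer than two samples")
        means[phase] = rel[idx].mean()
    if mode == "points":
        return float(100.0 * (means[phase_b] - means[phase_a]))
    if means[phase_a] == 0:
        raise ValueError("fold change undefined: zero mean abundance in phase_a")
    return float(100.0 * (means[phase_b] - means[phase_a]) / means[phase_a])
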