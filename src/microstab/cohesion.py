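"""Per-sample community cohesion from null-model-corrected correlations.

Cohesion summarises, per sample, how much of the community belongs to taxa
that co-vary positively (cooperation, C_pos >= 0) or negatively
(competition, C_neg <= 0) with the rest of the community. Observed pairwise
correlations are corrected by a taxa-shuffle null model so that
compositional and prevalence artefacts do not masquerade as interaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class CohesionResult:
    taxon_ids: list[str]
    connectedness_pos: np.ndarray  # per-taxon mean positive corrected r, >= 0
    connectedness_neg: np.ndarray  # per-taxon mean negative corrected r, <= 0
    sample_ids: list[str]
    c_pos: np.ndarray  # per-sample positive cohesion, >= 0
    c_neg: np.ndarray  # per-sample negative cohesion, <= 0
    n_null: int
    seed: int
    frame: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.frame is None:
            self.frame = pd.DataFrame(
                {"sample_id": self.sample_ids, "c_pos": self.c_pos,
                 "c_neg": self.c_neg}
            )


def _standardize(x: np.ndarray) -> np.ndarray:
    """Column-standardize; zero-variance columns become all-zero."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    out = np.zeros_like(x)
    ok = sd > 0
    out[:, ok] = (x[:, ok] - mu[ok]) / sd[ok]
    return out


def corrected_correlations(
    rel_abund: np.ndarray,
    n_null: int = 200,
    seed: int = 0,
    min_copresent: int = 3,
) -> np.ndarray:
    """Observed pairwise Pearson r minus its taxa-shuffle null mean.

    ``rel_abund`` is samples x taxa with rows summing to 1. Each null
    iteration independently permutes every taxon's abundances across
    samples and correlates the shuffled matrix against the observed one;
    the per-pair null mean (symmetrised) is subtracted from the observed
    correlation. Pairs with fewer than ``min_copresent`` co-nonzero
    samples, and zero-variance taxa, get corrected r = 0.
    """
    x = np.asarray(rel_abund, dtype=float)
    if x.ndim != 2:
        raise ValueError("rel_abund must be samples x taxa")
    row_sums = x.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=1e-6):
        raise ValueError("rows of rel_abund must sum to 1 (relative abundances)")
    if n_null < 50:
        raise ValueError("n_null must be at least 50 for a stable null mean")
    n, t = x.shape
    rng = np.random.default_rng(seed)
    z = _standardize(x)
    denom = max(n - 1, 1)
    obs = (z.T @ z) / denom
    null_sum = np.zeros((t, t))
    for _ in range(n_null):
        perm = np.empty_like(z)
        for j in range(t):
            perm[:, j] = z[rng.permutation(n), j]
        cross = (z.T @ perm) / denom
        null_sum += (cross + cross.T) / 2.0
    corrected = obs - null_sum / n_null
    present = (x > 0).astype(float)
    copresent = present.T @ present
    corrected[copresent < min_copresent] = 0.0
    variance_ok = x.std(axis=0) > 0
    corrected[~variance_ok, :] = 0.0
    corrected[:, ~variance_ok] = 0.0
    np.fill_diagonal(corrected, 0.0)
    return (corrected + corrected.T) / 2.0


def connectedness(corrected: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-taxon mean positive and mean negative corrected correlation.

    For taxon j: pos_j = mean of corrected r_jk > 0 over k != j (0 if
    none); neg_j likewise over negative entries.
    """
    c = np.asarray(corrected, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("corrected matrix must be square")
    if not np.allclose(c, c.T, atol=1e-10):
        raise ValueError("corrected matrix must be symmetric")
    t = c.shape[0]
    pos = np.zeros(t)
    neg = np.zeros(t)
    for j in range(t):
        row = np.delete(c[j], j)
        p = row[row > 0]
        m = row[row < 0]
        pos[j] = p.mean() if p.size else 0.0
        neg[j] = m.mean() if m.size else 0.0
    return pos, neg


def sample_cohesion(
    rel_abund: np.ndarray, pos: np.ndarray, neg: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Abundance-weighted cohesion per sample.

    c_pos(s) = sum_j a_sj * pos_j and c_neg(s) = sum_j a_sj * neg_j with
    a the samples x taxa relative abundances. Bounded by the extreme
    connectedness values since each is a convex combination.
    """
    x = np.asarray(rel_abund, dtype=float)
    if x.shape[1] != len(pos) or x.shape[1] != len(neg):
        raise ValueError("connectedness vectors must match taxa dimension")
    return x @ pos, x @ neg


def cohesion(
    rel_abund: np.ndarray,
    sample_ids: list[str],
    taxon_ids: list[str],
    n_null: int = 200,
    seed: int = 0,
) -> CohesionResult:
    """Full cohesion pipeline: corrected correlations -> connectedness ->
    per-sample C_pos / C_neg."""
    corrected = corrected_correlations(rel_abund, n_null=n_null, seed=seed)
    pos, neg = connectedness(corrected)
    c_pos, c_neg = sample_cohesion(rel_abund, pos, neg)
    return CohesionResult(
        taxon_ids=list(taxon_ids),
        connectedness_pos=pos,
        connectedness_neg=neg,
        sample_ids=list(sample_ids),
        c_pos=c_pos,
        c_neg=c_neg,
        n_null=n_null,
        seed=seed,
    )
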