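"""Random-matrix-theory threshold selection for co-occurrence networks.

The idea: the eigenvalue nearest-neighbour spacing distribution (NNSD) of a
correlation matrix follows Gaussian-orthogonal-ensemble (GOE, Wigner
surmise) statistics when the matrix is dominated by random noise, and
Poisson statistics when only system-specific (modular, non-random)
structure remains. Scanning the hard threshold applied to |r| upward, the
spacing statistics cross from GOE to Poisson; the transition point is the
correlation cutoff used to define network adjacency, which removes noise
while keeping the maximal set of real interactions.

Pipeline per candidate threshold s:

1. zero every |r| < s (diagonal kept), drop taxa left without any
   off-diagonal entry;
2. eigendecompose; collapse numerically degenerate eigenvalues;
3. unfold the spectrum — map eigenvalues through a smooth monotone fit
   (PCHIP through quantile knots) of the cumulative spectral density so
   the mean spacing is 1;
4. chi-square goodness of fit of the spacings against Poisson
   P(d) = e^-d and against the Wigner surmise P(d) = (pi d / 2) e^(-pi d^2/4),
   using equal-probability bins under each reference law;
5. the threshold is the smallest s that is Poisson-consistent
   (p > 0.05) with Poisson fitting better than GOE, for two consecutive
   scan steps (guards against single noisy steps).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
from scipy.interpolate import PchipInterpolator

from .tables import CountTable

logger = logging.getLogger(__name__)


class ThresholdNotFound(RuntimeError):
    """No GOE-to-Poisson transition inside the scanned threshold range."""


@dataclass
class CorrelationMatrix:
    """Symmetric taxa x taxa correlation matrix with unit diagonal."""

    taxon_ids: list[str]
    values: np.ndarray
    method: str = "pearson"
    n_pairs: np.ndarray | None = None  # complete observations per pair

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.shape != (len(self.taxon_ids), len(self.taxon_ids)):
            raise ValueError("correlation matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("correlation matrix diagonal must be 1")


def prepare_abundances(
    table: CountTable,
    sample_ids: list[str] | None = None,
    min_prevalence: float = 0.5,
    min_samples: int = 5,
    zero_mode: str = "auto",
) -> tuple[list[str], np.ndarray]:
    """Prevalence-filter and log10-transform a group of samples.

    Keeps taxa present in at least ``min_prevalence`` of the group's
    samples. Zeros are handled per ``zero_mode``:

    * ``"auto"`` (default): ``"missing"`` when the group has at least 30
      samples (enough pairwise-complete observations), ``"pseudocount"``
      otherwise;
    * ``"pseudocount"``: zeros replaced by half the smallest
      positive count before the log — every pair is then estimated on the
      full sample set, and shared absence contributes to co-occurrence
      (how the standard network pipelines treat zeros);
    * ``"missing"``: zeros flagged NaN so correlations use
      pairwise-complete observations only — stricter about zero-inflation,
      but it pre-sparsifies the correlation matrix when samples are few,
      which confuses the spectral transition scan.

    Returns ``(kept_taxon_ids, taxa x samples matrix)``.
    """
    if zero_mode not in ("auto", "pseudocount", "missing"):
        raise ValueError(f"unknown zero_mode {zero_mode!r}")
    sub = table.select_samples(sample_ids) if sample_ids is not None else table
    if zero_mode == "auto":
        zero_mode = "missing" if sub.n_samples >= 30 else "pseudocount"
        logger.info("prepare_abundances: zero_mode auto -> %s (%d samples)",
                    zero_mode, sub.n_samples)
    if sub.n_samples < min_samples:
        raise ValueError(
            f"group has {sub.n_samples} samples, below the floor of "
            f"{min_samples} needed for a stable correlation network"
        )
    prevalence = (sub.counts > 0).mean(axis=1)
    keep = prevalence >= min_prevalence
    kept_ids = [t for t, k in zip(sub.taxon_ids, keep) if k]
    mat = sub.counts[keep].astype(float).copy()
    if zero_mode == "pseudocount":
        positive = mat[mat > 0]
        pc = 0.5 * positive.min() if positive.size else 0.5
        mat = np.log10(np.where(mat > 0, mat, pc))
    else:
        with np.errstate(divide="ignore"):
            mat = np.where(mat > 0, np.log10(np.where(mat > 0, mat, 1.0)), np.nan)
    return kept_ids, mat


def correlation_matrix(
    taxon_ids: list[str],
    prepared: np.ndarray,
    method: str = "pearson",
    min_pairs: int | None = None,
) -> CorrelationMatrix:
    """Pairwise-complete Pearson (default) or Spearman correlations.

    Pairs with fewer than ``min_pairs`` complete observations (default:
    half of the group's samples, at least 4 — correlations estimated on a
    handful of co-present samples are noise), and taxa with zero variance,
    get r = 0.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if min_pairs is None:
        min_pairs = max(4, int(np.ceil(0.5 * prepared.shape[1])))
    frame = pd.DataFrame(prepared.T, columns=taxon_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = frame.corr(method=method, min_periods=min_pairs)
    values = corr.to_numpy()
    n_con = np.isnan(values).sum()
    if n_con:
        logger.warning(
            "correlation_matrix: %d pair(s) undefined (constant taxon or "
            "too few complete pairs); set to 0", int(n_con)
        )
    values = np.nan_to_num(values, nan=0.0)
    np.fill_diagonal(values, 1.0)
    values = (values + values.T) / 2.0
    notna = (~np.isnan(prepared)).astype(float)
    n_pairs = notna @ notna.T
    return CorrelationMatrix(
        taxon_ids=list(taxon_ids), values=values, method=method, n_pairs=n_pairs
    )


def unfold_spectrum(eigenvalues: np.ndarray, n_knots: int | None = None,
                    dedup_tol: float = 1e-8) -> np.ndarray:
    """Unfolded nearest-neighbour spacings of a spectrum (mean spacing 1).

    Degenerate eigenvalues are collapsed first (the standard treatment —
    exact multiplicities come from disconnected identical blocks and carry
    no spacing information). The cumulative spectral density is fitted with
    a monotone PCHIP interpolant through quantile knots; eigenvalues mapped
    through it have locally-uniform density, and their consecutive gaps are
    the spacings.
    """
    eigs = np.sort(np.asarray(eigenvalues, dtype=float))
    scale = max(1.0, np.abs(eigs).max())
    uniq = [eigs[0]]
    for e in eigs[1:]:
        if e - uniq[-1] > dedup_tol * scale:
            uniq.append(e)
    eigs = np.asarray(uniq)
    m = len(eigs)
    if m < 10:
        raise ValueError(f"only {m} distinct eigenvalues; too few to unfold")
    if n_knots is None:
        n_knots = int(np.clip(m // 8, 4, 20))
    knot_idx = np.unique(np.linspace(0, m - 1, n_knots).astype(int))
    x = eigs[knot_idx]
    y = knot_idx.astype(float)
    # knots must be strictly increasing in x
    keep = np.concatenate([[True], np.diff(x) > 0])
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("spectrum too degenerate to unfold")
    smooth_cdf = PchipInterpolator(x, y)
    unfolded = smooth_cdf(eigs)
    spacings = np.diff(unfolded)
    spacings = spacings[spacings > 0]
    if len(spacings) < 8:
        raise ValueError("too few positive spacings after unfolding")
    return spacings / spacings.mean()


def _chi2_pvalue(spacings: np.ndarray, inverse_cdf) -> float:
    """Equal-probability-bin chi-square p-value against a reference NNSD."""
    n = len(spacings)
    n_bins = int(np.ceil(np.sqrt(n)))
    qs = np.arange(1, n_bins) / n_bins
    edges = inverse_cdf(qs)
    observed = np.histogram(spacings, bins=np.concatenate([[0.0], edges, [np.inf]]))[0]
    expected = n / n_bins
    stat = ((observed - expected) ** 2 / expected).sum()
    return float(scipy.stats.chi2.sf(stat, n_bins - 1))


def nnsd_pvalues(spacings: np.ndarray) -> tuple[float, float]:
    """(p_poisson, p_goe) goodness-of-fit p-values for a spacing sample.

    Poisson NNSD: P(d) = e^-d, CDF 1 - e^-d.
    GOE Wigner surmise: P(d) = (pi d / 2) e^(-pi d^2 / 4), CDF 1 - e^(-pi d^2/4).
    """
    p_poisson = _chi2_pvalue(spacings, lambda q: -np.log1p(-q))
    p_goe = _chi2_pvalue(spacings, lambda q: np.sqrt(-4.0 * np.log1p(-q) / np.pi))
    return p_poisson, p_goe


@dataclass
class ThresholdScan:
    threshold: float
    diagnostics: pd.DataFrame = field(repr=False)


def rmt_threshold(
    corr: CorrelationMatrix,
    scan_start: float = 0.30,
    scan_end: float = 0.99,
    step: float = 0.01,
    alpha: float = 0.05,
    consecutive: int = 2,
    min_taxa: int = 30,
    n_knots: int | None = None,
) -> ThresholdScan:
    """Scan hard thresholds for the GOE-to-Poisson NNSD transition.

    Returns the detected threshold plus a per-step diagnostics table
    (threshold, matrix size, #spacings, p_poisson, p_goe) for audit.
    Raises :class:`ThresholdNotFound` if no transition lies in the range —
    widen the scan rather than silently defaulting.
    """
    values = corr.values
    if values.shape[0] < min_taxa:
        raise ValueError(
            f"need at least {min_taxa} taxa for spacing statistics, "
            f"got {values.shape[0]}"
        )
    if corr.n_pairs is not None:
        # correlations below ~2 null standard errors are indistinguishable
        # from sampling noise; scanning there invites spurious transitions
        off = corr.n_pairs[np.triu_indices_from(corr.n_pairs, k=1)]
        n_eff = float(np.median(off))
        if n_eff > 4:
            noise_floor = round(2.0 / np.sqrt(n_eff - 1.0), 2)
            if noise_floor > scan_start:
                logger.info(
                    "rmt_threshold: raising scan start from %.2f to the "
                    "noise floor %.2f (median %d obs/pair)",
                    scan_start, noise_floor, int(n_eff),
                )
                scan_start = noise_floor
    rows = []
    qualifying = []  # thresholds passing the Poisson-not-GOE rule, in order
    for s in np.arange(scan_start, scan_end + step / 2, step):
        m = np.where(np.abs(values) >= s, values, 0.0)
        np.fill_diagonal(m, 1.0)
        off_deg = (m != 0).sum(axis=1) - 1
        keep = off_deg > 0
        size = int(keep.sum())
        row = {"threshold": round(float(s), 10), "n_taxa": size,
               "n_spacings": 0, "p_poisson": np.nan, "p_goe": np.nan}
        if size >= min_taxa:
            sub = m[np.ix_(keep, keep)]
            eigs = scipy.linalg.eigvalsh(sub)
            try:
                spacings = unfold_spectrum(eigs, n_knots=n_knots)
                p_poisson, p_goe = nnsd_pvalues(spacings)
                row.update(
                    n_spacings=len(spacings),
                    p_poisson=p_poisson,
                    p_goe=p_goe,
                )
            except ValueError:
                pass
        rows.append(row)
    diagnostics = pd.DataFrame(rows)
    # qualify where the spacings are Poisson-consistent and Poisson fits
    # better than the Wigner surmise: at the spacing counts typical of
    # these matrices a formal GOE rejection is often underpowered, so the
    # completed transition shows up as the Poisson side winning
    ok = (diagnostics["p_poisson"] > alpha) & (
        diagnostics["p_goe"] < diagnostics["p_poisson"]
    )
    ok = ok.fillna(False).to_numpy()
    for i in range(len(ok) - consecutive + 1):
        if ok[i:i + consecutive].all():
            threshold = float(diagnostics["threshold"].iloc[i])
            return ThresholdScan(threshold=threshold, diagnostics=diagnostics)
    raise ThresholdNotFound(
        f"no GOE-to-Poisson transition found in [{scan_start}, {scan_end}]; "
        "widen the scan range or lower the consecutive-step requirement"
    )
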