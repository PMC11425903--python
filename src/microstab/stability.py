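"""Average Variation Degree (AVD): a per-group community stability index.

For a group of k samples, each OTU i with within-group mean x̄_i and
standard deviation δ_i contributes |x_ij − x̄_i| / δ_i for every sample j.
AVD is the grand sum divided by k × n, where n counts the OTUs actually
used. A lower AVD means samples sit closer to the group mean profile in
per-OTU standard-deviation units — a more stable community.

Conventions (the index's published description leaves these open):

* the numerator sums over samples as well as OTUs, and the denominator is
  k × n — this keeps the index a per-sample, per-OTU average and makes it
  comparable across groups of different sizes;
* δ_i is the sample standard deviation (ddof = 1), configurable;
* OTUs with δ_i = 0 inside a group carry no dispersion information and are
  excluded from both the sum and n.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .tables import CountTable

logger = logging.getLogger(__name__)


@dataclass
class AvdResult:
    group: str
    avd: float
    k: int  # samples in the group
    n_used: int  # OTUs with nonzero within-group dispersion


def avd_single(matrix: np.ndarray, ddof: int = 1) -> tuple[float, int]:
    """AVD of one group given its taxa x samples abundance matrix.

    Returns ``(avd, n_used)``.
    """
    matrix = np.asarray(matrix, dtype=float)
    k = matrix.shape[1]
    if k < 2:
        raise ValueError("AVD needs at least two samples in a group")
    mean = matrix.mean(axis=1, keepdims=True)
    sd = matrix.std(axis=1, ddof=ddof)
    used = sd > 0
    n_used = int(used.sum())
    if n_used == 0:
        return 0.0, 0
    dev = np.abs(matrix[used] - mean[used]) / sd[used, None]
    return float(dev.sum() / (k * n_used)), n_used


def avd(table: CountTable, groups, ddof: int = 1) -> list[AvdResult]:
    """AVD per sample group.

    ``groups`` maps position-wise to ``table.sample_ids`` (one label per
    sample). Groups of a single sample are skipped with a warning. The
    table is expected to be rarefied (the index is defined on rarefied
    abundances); a non-rarefied table is accepted with a warning since the
    index is invariant to global rescaling anyway.
    """
    groups = np.asarray(list(groups))
    if len(groups) != table.n_samples:
        raise ValueError("one group label per sample is required")
    if not table.is_rarefied:
        warnings.warn("AVD computed on a non-rarefied table")
    results = []
    for g in dict.fromkeys(groups):  # unique labels in first-seen order
        idx = np.where(groups == g)[0]
        if len(idx) < 2:
            warnings.warn(f"AVD: skipping group {g!r} with a single sample")
            continue
        value, n_used = avd_single(table.counts[:, idx], ddof=ddof)
        if n_used == 0:
            warnings.warn(f"AVD: group {g!r} has no OTU with nonzero dispersion")
        results.append(AvdResult(group=str(g), avd=value, k=len(idx), n_used=n_used))
    return results
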