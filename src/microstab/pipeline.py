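"""High-level analyses composing the library modules.

These are the entry points the command line uses; each takes the in-memory
tables and returns tidy frames/records, leaving file I/O to the caller.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import association, diversity, network, rmt, stability
from .cohesion import cohesion as _cohesion
from .tables import CountTable, ScfaTable, StudyMetadata, default_rarefaction_depth, rarefy

logger = logging.getLogger(__name__)

#: group used as the pre-collapse reference network: baseline patients plus
#: their family members (pooled for sample size, as small groups cannot
#: support a stable correlation estimate)
BASELINE_TIMEPOINTS = ("S1", "F")
#: sterile-endpoint network group; widened when no spectral transition is
#: found on the smaller pool
STERILE_TIMEPOINTS = ("S4", "S5")
STERILE_WIDENED = ("S3", "S4", "S5")


def alpha_table(table: CountTable, meta: StudyMetadata) -> pd.DataFrame:
    """Per-sample alpha diversity joined with the study design."""
    records = diversity.alpha_diversity(table)
    frame = pd.DataFrame([r.__dict__ for r in records])
    return frame.merge(meta.frame, on="sample_id")


def stability_table(
    table: CountTable,
    meta: StudyMetadata,
    group_by: str = "timepoint",
    depth: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """AVD per group on a rarefied copy of the table."""
    if depth is None:
        depth = default_rarefaction_depth(table)
    rare = rarefy(table, depth, seed=seed)
    aligned = meta.align_to(rare)
    groups = aligned.frame[group_by].to_numpy()
    results = stability.avd(rare, groups)
    frame = pd.DataFrame([r.__dict__ for r in results])
    frame.insert(0, "group_by", group_by)
    frame["rarefaction_depth"] = depth
    return frame


def beta_tests(
    table: CountTable,
    meta: StudyMetadata,
    group_by: str = "phase",
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Bray-Curtis + PCoA + PERMANOVA across the given design factor."""
    d = diversity.bray_curtis_matrix(table)
    aligned = meta.align_to(table)
    groups = aligned.frame[group_by].to_numpy()
    f_stat, p = diversity.permanova(d, groups, n_perm=n_perm, seed=seed)
    ordination = diversity.pcoa(d, n_axes=2)
    return {
        "distance": d,
        "pcoa": ordination,
        "pseudo_F": f_stat,
        "p_value": p,
        "group_by": group_by,
    }


def group_network(
    table: CountTable,
    meta: StudyMetadata,
    timepoints,
    min_prevalence: float = 0.5,
    seed: int = 0,
    **scan_kwargs,
):
    """RMT-thresholded network for the samples at the given timepoints.

    Returns ``(SignedNetwork, ThresholdScan, TopologyRecord)``.
    """
    ids = meta.samples_for(timepoint=list(timepoints))
    taxa, prepared = rmt.prepare_abundances(
        table, ids, min_prevalence=min_prevalence
    )
    corr = rmt.correlation_matrix(taxa, prepared)
    scan = rmt.rmt_threshold(corr, **scan_kwargs)
    net = network.build_network(corr, scan.threshold)
    record = network.full_topology(net, seed=seed)
    return net, scan, record


def collapse_network_pair(table: CountTable, meta: StudyMetadata, seed: int = 0):
    """Baseline vs sterile-endpoint networks (the collapse signature).

    The sterile pool widens from S4+S5 to S3-S5 when the spectral scan
    finds no transition on the smaller group.
    """
    base_net, base_scan, base_topo = group_network(
        table, meta, BASELINE_TIMEPOINTS, seed=seed
    )
    try:
        sterile_net, sterile_scan, sterile_topo = group_network(
            table, meta, STERILE_TIMEPOINTS, seed=seed
        )
        sterile_group = STERILE_TIMEPOINTS
    except rmt.ThresholdNotFound:
        logger.warning(
            "no transition on %s; widening the sterile pool to %s",
            STERILE_TIMEPOINTS, STERILE_WIDENED,
        )
        sterile_net, sterile_scan, sterile_topo = group_network(
            table, meta, STERILE_WIDENED, seed=seed
        )
        sterile_group = STERILE_WIDENED
    return {
        "baseline": {"net": base_net, "scan": base_scan, "topology": base_topo,
                     "timepoints": BASELINE_TIMEPOINTS},
        "sterile": {"net": sterile_net, "scan": sterile_scan,
                    "topology": sterile_topo, "timepoints": sterile_group},
    }


def cohesion_table(
    table: CountTable,
    meta: StudyMetadata,
    n_null: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample positive/negative cohesion joined with the design."""
    rel = table.relative_abundance().T  # samples x taxa
    result = _cohesion(
        rel, table.sample_ids, table.taxon_ids, n_null=n_null, seed=seed
    )
    return result.frame.merge(meta.frame, on="sample_id")


def scfa_association(
    table: CountTable,
    meta: StudyMetadata,
    scfa: ScfaTable,
    top_k: int = 30,
) -> pd.DataFrame:
    """Spearman screen of the top-k most abundant taxa against SCFAs."""
    top = association.top_taxa(table, min(top_k, table.n_taxa))
    rel = pd.DataFrame(
        table.relative_abundance().T, index=table.sample_ids,
        columns=table.taxon_ids,
    )
    acids = scfa.frame.set_index("sample_id")
    return association.spearman_screen(rel[top], acids)


def scfa_mantel(
    table: CountTable,
    scfa: ScfaTable,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float, int]:
    """Mantel test between community Bray-Curtis and SCFA-profile distance.

    Restricted to samples with SCFA measurements; returns (r, p, n).
    """
    from scipy.spatial.distance import pdist, squareform

    shared = [s for s in table.sample_ids if s in set(scfa.sample_ids)]
    if len(shared) < 5:
        raise ValueError("too few samples with SCFA measurements")
    sub = table.select_samples(shared)
    d1 = diversity.bray_curtis_matrix(sub)
    acid_mat = scfa.frame.set_index("sample_id").loc[shared]
    d2 = pd.DataFrame(
        squareform(pdist(np.asarray(acid_mat, dtype=float))),
        index=shared, columns=shared,
    )
    r, p = association.mantel(d1, d2, n_perm=n_perm, seed=seed)
    return r, p, len(shared)
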