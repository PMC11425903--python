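"""Synthetic longitudinal cohorts with planted structure.

The generator emulates the processed data of a "sterile then normal diet"
transplant cohort: nine subjects sampled at nine weekly-to-monthly
timepoints (S1 baseline, S2-S5 sterile diet, S6-S9 normal diet) plus one
healthy family member per subject, with a few samples missing, a planted
diversity collapse and recovery, pathogen-bloom and beneficial taxa,
block-correlated taxon modules, and SCFA concentrations coupled to
nominated taxa.

Counts are drawn compositionally (logistic-normal relative abundances,
multinomial sequencing depth) rather than as independent Poissons, because
downstream correlation analysis assumes compositional coupling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .diversity import shannon
from .tables import (
    PHASE_OF_TIMEPOINT,
    SCFA_ACIDS,
    TIMEPOINTS,
    CountTable,
    ScfaTable,
    StudyMetadata,
)

logger = logging.getLogger(__name__)

#: collapse intensity schedule: 0 at baseline, ramping to 1 at the sterile
#: endpoint S5, decaying through the normal-diet phase, 0 for family samples.
COLLAPSE_SCHEDULE = {
    "S1": 0.0,
    "S2": 0.25,
    "S3": 0.5,
    "S4": 0.75,
    "S5": 1.0,
    "S6": 0.6,
    "S7": 0.4,
    "S8": 0.2,
    "S9": 0.1,
    "F": 0.0,
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Defaults reproduce the study design: 9 subjects x 9 timepoints plus 9
    family samples, with random dropout bringing the ~90 generated samples
    down to roughly 83 retained.
    """

    n_subjects: int = 9
    timepoints: tuple = tuple(t for t in TIMEPOINTS if t != "F")
    include_family: bool = True
    n_taxa: int = 300
    depth_mean: int = 20000
    depth_sigma: float = 0.25  # lognormal sd of per-sample depth (log units)
    n_modules: int = 5
    module_size: int | None = None  # default: n_taxa // (2 * n_modules)
    module_rho: float = 0.8
    collapse_severity: float = 0.6  # fraction of baseline Shannon lost at S5;
    # the master dial: every collapse channel below scales with
    # collapse_severity * c(t), so severity 0 is a true null cohort
    extinction_frac: float = 1.0  # per-subject taxon-loss probability per unit
    # of collapse severity; losses are subject-specific and persistent, so
    # subjects diverge (the within-group heterogeneity AVD measures)
    extinction_taxon_weight: float = 0.7  # how much of the extinction order
    # is shared taxon vulnerability (diet-susceptible taxa crash in every
    # subject) versus subject-specific chance
    bloom_taxa: tuple = ()
    beneficial_taxa: tuple = ()
    bloom_fraction: float = 0.67  # community share bloom taxa capture per unit
    # of collapse severity (0.4 of the community at default severity and c = 1)
    bloom_subject_sd: float = 0.3  # lognormal subject noise on that share
    beneficial_effect: float = 4.0  # log-abundance drop per unit severity
    beneficial_quantile: float = 0.9  # beneficial taxa sit high in the
    # baseline abundance ranking (common commensals), so their loss is visible
    collapse_stagger_sd: float = 0.7  # lognormal sd of per-subject collapse
    # rate; subjects hit intensity c(t)**rate, so mid-sterile groups mix
    # mildly and severely collapsed states (divergent trajectories) before
    # converging at the sterile endpoint
    base_mu_sd: float = 1.5  # spread of baseline log mean abundances
    person_sd: float = 1.8  # between-person log-abundance spread: gut taxa
    # vary by orders of magnitude between free-living individuals, so each
    # person's abundance profile carries a persistent heavy-tailed offset
    patient_person_scale: float = 0.25  # hospitalized patients share one
    # standardized diet and environment from S1 on, which damps the
    # between-person spread relative to free-living family members
    convergence: float = 0.3  # mild extra homogenization of patients while
    # the collapse deepens: person offsets and biological noise shrink by
    # (1 - convergence * intensity)
    occupancy_a: float = 8.0  # Beta(a, b) per-taxon occupancy: each person
    occupancy_b: float = 2.0  # (subject or family member) carries a taxon
    # with taxon-specific probability ~0.8 — person-specific gut membership
    sigma_log: float = 0.6  # per-taxon biological log-noise sd
    family_dispersion: float = 0.6  # family sigma_log multiplier (< 1: tighter)
    dropout_rate: float = 0.085  # patient samples only; 81 * rate ~ 7 missing
    scfa_coupling: dict = field(default_factory=dict)
    scfa_coverage: float = 0.7  # fraction of retained samples with SCFA data
    scfa_noise: float = 0.10  # relative sd of SCFA measurement noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_size is None:
            self.module_size = self.n_taxa // (2 * self.n_modules)
        if self.n_modules * self.module_size > self.n_taxa:
            raise ValueError("modules do not fit into n_taxa")
        background_start = self.n_modules * self.module_size
        if not self.bloom_taxa:
            self.bloom_taxa = tuple(range(background_start, background_start + 3))
        if not self.beneficial_taxa:
            self.beneficial_taxa = tuple(
                range(background_start + 3, background_start + 8)
            )
        self.bloom_taxa = tuple(int(i) for i in self.bloom_taxa)
        self.beneficial_taxa = tuple(int(i) for i in self.beneficial_taxa)
        for idx in (*self.bloom_taxa, *self.beneficial_taxa):
            if not 0 <= idx < self.n_taxa:
                raise ValueError(f"taxon index {idx} out of range")
        if set(self.bloom_taxa) & set(self.beneficial_taxa):
            raise ValueError("bloom and beneficial taxon sets must be disjoint")
        for name in ("module_rho", "collapse_severity", "dropout_rate",
                     "scfa_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.scfa_coupling:
            # beneficial taxa are the SCFA producers: acids track their
            # relative abundance, so concentrations dip with the collapse.
            ben = list(self.beneficial_taxa)
            base = {"acetic": 3000.0, "propionic": 1200.0, "butyric": 900.0,
                    "isobutyric": 150.0, "valeric": 120.0, "isovaleric": 130.0}
            self.scfa_coupling = {
                acid: (tuple(ben), 8.0 * base[acid]) for acid in SCFA_ACIDS
            }
        self.scfa_base = {"acetic": 3000.0, "propionic": 1200.0, "butyric": 900.0,
                          "isobutyric": 150.0, "valeric": 120.0, "isovaleric": 130.0}


@dataclass
class GroundTruth:
    """What was planted: module structure, trajectories, couplings."""

    module_membership: np.ndarray  # per-taxon module id, -1 for background
    expected_shannon: dict  # timepoint -> Shannon (nats) of expected profile
    bloom_taxa: tuple
    beneficial_taxa: tuple
    scfa_coupling: dict
    latent_correlation: np.ndarray  # n_taxa x n_taxa planted latent corr
    factor_loadings: np.ndarray  # per-taxon loading on its module factor


def _gamma_for_target(weights: np.ndarray, target_h: float) -> float:
    """Power exponent concentrating ``weights`` until Shannon == target."""

    def h_of(gamma: float) -> float:
        w = weights ** gamma
        return shannon(w)

    h0 = h_of(1.0)
    if target_h >= h0:
        return 1.0
    lo, hi = 1.0, 2.0
    while h_of(hi) > target_h:
        hi *= 2.0
        if hi > 512:
            return hi
    return brentq(lambda g: h_of(g) - target_h, lo, hi, xtol=1e-6)


def simulate_cohort(config: SimulationConfig):
    """Draw one cohort.

    Returns ``(CountTable, StudyMetadata, ScfaTable, GroundTruth)``.

    Generation: (i) one latent Gaussian factor per planted module; taxon i
    in module m has loading a_i, so within-module latent correlation is
    a_i * a_j (centred on ``module_rho``); (ii) per-taxon log-normal weights
    whose means follow the phase trajectory — at collapse intensity c the
    baseline weight profile is raised to a power gamma(c) chosen so the
    expected Shannon drops by ``collapse_severity * c`` of baseline, each
    subject persistently loses a random ``extinction_frac * c`` subset of
    taxa (losses are nested in c, so they accumulate through the sterile
    phase and reverse during recovery), beneficial taxa lose log-abundance
    proportionally to c, and bloom taxa capture a lognormally-noised
    ``bloom_fraction * c`` share of the community; (iii) multinomial
    sampling at a lognormal per-sample depth. Family samples use baseline
    means with tighter dispersion. A fixed seed gives byte-identical
    output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # --- planted module structure -------------------------------------
    membership = np.full(cfg.n_taxa, -1, dtype=int)
    for m in range(cfg.n_modules):
        membership[m * cfg.module_size:(m + 1) * cfg.module_size] = m
    # loadings vary around sqrt(module_rho) so within-module latent
    # correlations a_i*a_j are heterogeneous and rankable.
    loadings = np.zeros(cfg.n_taxa)
    in_module = membership >= 0
    half_band = min(0.15, 0.98 - cfg.module_rho, cfg.module_rho)
    rho_i = rng.uniform(
        cfg.module_rho - half_band, cfg.module_rho + half_band, in_module.sum()
    )
    loadings[in_module] = np.sqrt(rho_i)
    latent = np.eye(cfg.n_taxa)
    for m in range(cfg.n_modules):
        idx = np.where(membership == m)[0]
        block = np.outer(loadings[idx], loadings[idx])
        latent[np.ix_(idx, idx)] = block
    np.fill_diagonal(latent, 1.0)

    # --- baseline community profile ------------------------------------
    base_mu = rng.normal(0.0, cfg.base_mu_sd, cfg.n_taxa)
    bloom = np.array(cfg.bloom_taxa, dtype=int)
    beneficial = np.array(cfg.beneficial_taxa, dtype=int)
    # beneficial taxa are common commensals: pin them high in the baseline
    # ranking so their sterile-phase loss shows up in relative abundance
    base_mu[beneficial] = np.quantile(base_mu, cfg.beneficial_quantile) + rng.normal(
        0.0, 0.2, len(beneficial)
    )
    base_weights = np.exp(base_mu - base_mu.max())
    h_base = shannon(base_weights)

    # gamma(c) on a grid, interpolated per subject-specific intensity
    c_grid = np.linspace(0.0, 1.0, 21)
    gamma_grid = np.array(
        [
            _gamma_for_target(
                base_weights, h_base * (1.0 - cfg.collapse_severity * c)
            )
            for c in c_grid
        ]
    )

    expected_shannon = {}
    tp_all = list(cfg.timepoints) + (["F"] if cfg.include_family else [])
    for tp in tp_all:
        c = COLLAPSE_SCHEDULE[tp]
        # expected profile: concentrated baseline plus the bloom share
        w = base_weights ** np.interp(c, c_grid, gamma_grid)
        p = w / w.sum()
        b = cfg.bloom_fraction * cfg.collapse_severity * c if len(bloom) else 0.0
        p = (1.0 - b) * p
        p[bloom] += b / max(len(bloom), 1)
        expected_shannon[tp] = shannon(p)

    # per-subject collapse rate: intensity follows c(t) ** rate
    collapse_rate = np.exp(rng.normal(0.0, cfg.collapse_stagger_sd, cfg.n_subjects))

    # subject-persistent extinction scores: taxon i is lost by subject s at
    # collapse intensity c when its score falls below
    # extinction_frac * severity * c (nested in c, so losses accumulate and
    # then reverse). Scores blend a shared per-taxon vulnerability with
    # subject-specific chance.
    w_tax = cfg.extinction_taxon_weight
    u_ext = (
        w_tax * rng.random(cfg.n_taxa)[None, :]
        + (1.0 - w_tax) * rng.random((cfg.n_subjects, cfg.n_taxa))
    )

    # person-specific membership: subject s carries taxon i iff
    # occupancy_u[s, i] < o_i; family members get independent draws
    occupancy = rng.beta(cfg.occupancy_a, cfg.occupancy_b, cfg.n_taxa)
    occupancy[beneficial] = 0.97  # core commensals: carried by everyone
    carried_subj = rng.random((cfg.n_subjects, cfg.n_taxa)) < occupancy
    carried_fam = rng.random((cfg.n_subjects, cfg.n_taxa)) < occupancy

    def person_offsets(n_people: int) -> np.ndarray:
        """Persistent per-person log-abundance offsets, module-structured so
        within-module latent correlation is preserved at the person level."""
        pme = rng.normal(size=(n_people, cfg.n_modules))
        pbe = rng.normal(size=(n_people, cfg.n_taxa))
        z = np.where(
            in_module[None, :],
            loadings[None, :] * pme[:, np.clip(membership, 0, None)]
            + np.sqrt(np.clip(1.0 - loadings**2, 0.0, 1.0))[None, :] * pbe,
            pbe,
        )
        return cfg.person_sd * z

    offset_subj = cfg.patient_person_scale * person_offsets(cfg.n_subjects)
    offset_fam = person_offsets(cfg.n_subjects)

    # --- draw samples ---------------------------------------------------
    sample_ids, subjects, tps = [], [], []
    count_cols = []
    for subj in range(1, cfg.n_subjects + 1):
        for tp in tp_all:
            c = COLLAPSE_SCHEDULE[tp]
            if tp != "F" and c > 0:
                c = c ** collapse_rate[subj - 1]
            gamma = float(np.interp(c, c_grid, gamma_grid))
            sigma = cfg.sigma_log * (cfg.family_dispersion if tp == "F" else 1.0)
            # latent noise: shared module factor + idiosyncratic part
            factors = rng.normal(size=cfg.n_modules)
            eps = rng.normal(size=cfg.n_taxa)
            z = np.where(
                in_module,
                loadings * factors[np.clip(membership, 0, None)]
                + np.sqrt(np.clip(1.0 - loadings ** 2, 0.0, 1.0)) * eps,
                eps,
            )
            intensity = cfg.collapse_severity * c
            shrink = 1.0 - (cfg.convergence * intensity if tp != "F" else 0.0)
            offset = (offset_fam if tp == "F" else offset_subj)[subj - 1]
            log_w = gamma * (base_mu - base_mu.max()) + shrink * (
                offset + sigma * z
            )
            log_w[beneficial] -= cfg.beneficial_effect * intensity
            # structural zeros: taxa this person does not carry, plus taxa
            # lost to the collapse (losses are nested in intensity)
            absent = ~(carried_fam[subj - 1] if tp == "F" else carried_subj[subj - 1])
            if tp != "F" and intensity > 0:
                lost = u_ext[subj - 1] < cfg.extinction_frac * intensity
                lost[bloom] = False
                absent = absent | lost
            p = np.exp(log_w - log_w.max())
            p[absent] = 0.0
            p /= p.sum()
            # pathogen bloom: bloom taxa capture a share of the community
            b_share = 0.0
            if len(bloom) and intensity > 0 and tp != "F":
                b_share = min(
                    0.9,
                    cfg.bloom_fraction
                    * intensity
                    * np.exp(rng.normal(0.0, cfg.bloom_subject_sd)),
                )
            p = (1.0 - b_share) * p
            if len(bloom):
                bloom_split = rng.dirichlet(np.ones(len(bloom)))
                p[bloom] += b_share * bloom_split
            depth = int(
                np.rint(cfg.depth_mean * np.exp(rng.normal(0.0, cfg.depth_sigma)))
            )
            counts = rng.multinomial(depth, p)
            sid = f"P{subj:02d}_{tp}" if tp != "F" else f"F{subj:02d}"
            sample_ids.append(sid)
            subjects.append(f"S{subj:02d}")
            tps.append(tp)
            count_cols.append(counts)

    counts = np.array(count_cols, dtype=float).T  # taxa x samples

    # --- dropout (patient samples only, baseline kept) ------------------
    keep = np.ones(len(sample_ids), dtype=bool)
    for j, tp in enumerate(tps):
        if tp not in ("F", "S1") and rng.random() < cfg.dropout_rate:
            keep[j] = False
    dropped = [sid for sid, k in zip(sample_ids, keep) if not k]
    if dropped:
        logger.info("simulate_cohort: dropped %d samples: %s", len(dropped), dropped)
    sample_ids = [s for s, k in zip(sample_ids, keep) if k]
    subjects = [s for s, k in zip(subjects, keep) if k]
    tps = [t for t, k in zip(tps, keep) if k]
    counts = counts[:, keep]

    table = CountTable(
        taxon_ids=[f"OTU_{i:04d}" for i in range(cfg.n_taxa)],
        sample_ids=sample_ids,
        counts=counts,
    )
    meta = StudyMetadata.for_timepoints(sample_ids, subjects, tps)

    # --- SCFA table ------------------------------------------------------
    rel = counts / counts.sum(axis=0)
    measured = rng.random(len(sample_ids)) < cfg.scfa_coverage
    rows = []
    for j, sid in enumerate(sample_ids):
        if not measured[j]:
            continue
        row = {"sample_id": sid}
        for acid in SCFA_ACIDS:
            taxa, effect = cfg.scfa_coupling[acid]
            base = cfg.scfa_base[acid]
            signal = 0.2 * base + effect * rel[list(taxa), j].sum()
            noise = rng.normal(0.0, cfg.scfa_noise * base)
            row[acid] = max(0.0, signal + noise)
        rows.append(row)
    scfa = ScfaTable(pd.DataFrame(rows, columns=["sample_id", *SCFA_ACIDS]))

    truth = GroundTruth(
        module_membership=membership,
        expected_shannon=expected_shannon,
        bloom_taxa=cfg.bloom_taxa,
        beneficial_taxa=cfg.beneficial_taxa,
        scfa_coupling=cfg.scfa_coupling,
        latent_correlation=latent,
        factor_loadings=loadings,
    )
    return table, meta, scfa, truth


def planted_edge_set(truth: GroundTruth, top_q: float) -> set:
    """Within-module taxon pairs in the top ``top_q`` fraction by latent
    correlation — the ground truth for network-recovery tests.

    ``top_q = 1`` returns every within-module pair.
    """
    if not 0 < top_q <= 1:
        raise ValueError("top_q must be in (0, 1]")
    membership = truth.module_membership
    latent = np.asarray(truth.latent_correlation)
    pairs, vals = [], []
    n = len(membership)
    for i in range(n):
        if membership[i] < 0:
            continue
        for j in range(i + 1, n):
            if membership[j] == membership[i]:
                pairs.append((i, j))
                vals.append(latent[i, j])
    if not pairs:
        return set()
    vals = np.asarray(vals)
    cut = np.quantile(vals, 1.0 - top_q)
    return {p for p, v in zip(pairs, vals) if v >= cut}
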