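"""Core data containers: OTU count tables, sample metadata, SCFA tables.

All tables are taxa-as-rows. Orientation is never auto-detected: a silent
transpose is the classic microbiome bug, so the constructor takes the matrix
exactly as given and validates shapes against the ID lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical study timepoints: S1 pre-transplant baseline, S2-S5 sterile diet,
#: S6-S9 normal diet, F = healthy family member sampled alongside S9.
TIMEPOINTS = ("S1", "S2", "S3", "S4", "S5", "S6", "S7", "S8", "S9", "F")

PHASE_OF_TIMEPOINT = {
    "S1": "pre",
    "S2": "sterile",
    "S3": "sterile",
    "S4": "sterile",
    "S5": "sterile",
    "S6": "normal",
    "S7": "normal",
    "S8": "normal",
    "S9": "normal",
    "F": "family",
}

SCFA_ACIDS = ("acetic", "propionic", "butyric", "isobutyric", "valeric", "isovaleric")


class ValidationError(ValueError):
    """A table violates one of its structural invariants."""


@dataclass
class CountTable:
    """Taxa x samples matrix of non-negative counts.

    Parameters
    ----------
    taxon_ids :
        Row labels (opaque strings, e.g. ``OTU_17``). Must be unique.
    sample_ids :
        Column labels. Must be unique.
    counts :
        ``(n_taxa, n_samples)`` array of non-negative numbers.
    is_rarefied :
        Whether every column has been subsampled to a common depth.
    rarefaction_depth :
        The common column sum when ``is_rarefied``.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    is_rarefied: bool = False
    rarefaction_depth: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D taxa x samples matrix")
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValidationError("duplicate taxon IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample IDs")
        if not np.all(np.isfinite(self.counts)):
            raise ValidationError("counts contain non-finite values")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if self.is_rarefied:
            if self.rarefaction_depth is None:
                raise ValidationError("is_rarefied tables need rarefaction_depth")
            sums = self.counts.sum(axis=0)
            if not np.allclose(sums, self.rarefaction_depth):
                raise ValidationError(
                    "rarefied table has column sums not equal to rarefaction_depth"
                )

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def relative_abundance(self) -> np.ndarray:
        """Column-normalised abundances (each sample sums to 1)."""
        sums = self.counts.sum(axis=0)
        if np.any(sums == 0):
            raise ValidationError("cannot normalise a sample with zero total count")
        return self.counts / sums

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, **kwargs) -> "CountTable":
        return cls(
            taxon_ids=list(frame.index.astype(str)),
            sample_ids=list(frame.columns.astype(str)),
            counts=frame.to_numpy(dtype=float),
            **kwargs,
        )

    def select_samples(self, sample_ids: list[str]) -> "CountTable":
        """Subset (and reorder) columns; drops the rarefied flag consistency check."""
        missing = [s for s in sample_ids if s not in self.sample_ids]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return replace(
            self,
            sample_ids=list(sample_ids),
            counts=self.counts[:, idx],
        )

    def select_taxa(self, taxon_ids: list[str]) -> "CountTable":
        missing = [t for t in taxon_ids if t not in self.taxon_ids]
        if missing:
            raise KeyError(f"taxa not in table: {missing}")
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        return CountTable(
            taxon_ids=list(taxon_ids),
            sample_ids=list(self.sample_ids),
            counts=self.counts[idx, :],
            is_rarefied=False,
        )


@dataclass
class StudyMetadata:
    """Per-sample design information: subject, timepoint, diet phase.

    ``phase`` is a function of ``timepoint`` (S1 pre, S2-S5 sterile,
    S6-S9 normal, F family) and is validated on construction.
    """

    frame: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "subject_id", "timepoint", "phase")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise ValidationError(f"metadata missing column {col!r}")
        if self.frame["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in metadata")
        bad_tp = set(self.frame["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValidationError(f"unknown timepoints: {sorted(bad_tp)}")
        expected = self.frame["timepoint"].map(PHASE_OF_TIMEPOINT)
        mismatch = self.frame.loc[expected != self.frame["phase"]]
        if len(mismatch):
            raise ValidationError(
                "phase inconsistent with timepoint for samples "
                f"{mismatch['sample_id'].tolist()}"
            )
        self.frame = self.frame.reset_index(drop=True)

    @classmethod
    def from_records(cls, records) -> "StudyMetadata":
        return cls(pd.DataFrame.from_records(records))

    @classmethod
    def for_timepoints(cls, sample_ids, subject_ids, timepoints) -> "StudyMetadata":
        timepoints = list(timepoints)
        return cls(
            pd.DataFrame(
                {
                    "sample_id": list(sample_ids),
                    "subject_id": list(subject_ids),
                    "timepoint": timepoints,
                    "phase": [PHASE_OF_TIMEPOINT[t] for t in timepoints],
                }
            )
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def samples_for(self, *, timepoint=None, phase=None, subject=None) -> list[str]:
        """Sample IDs matching the given design cells (str or collection)."""
        mask = np.ones(len(self.frame), dtype=bool)

        def _match(col, value):
            if isinstance(value, str):
                value = [value]
            return self.frame[col].isin(list(value)).to_numpy()

        if timepoint is not None:
            mask &= _match("timepoint", timepoint)
        if phase is not None:
            mask &= _match("phase", phase)
        if subject is not None:
            mask &= _match("subject_id", subject)
        return list(self.frame.loc[mask, "sample_id"])

    def align_to(self, table: CountTable) -> "StudyMetadata":
        """Validate every table sample has exactly one row; reorder to match."""
        idx = self.frame.set_index("sample_id")
        missing = [s for s in table.sample_ids if s not in idx.index]
        if missing:
            raise ValidationError(f"samples without metadata: {missing}")
        sub = idx.loc[table.sample_ids].reset_index()
        return StudyMetadata(sub)


@dataclass
class ScfaTable:
    """Sample x acid concentrations (ug per g feces), non-negative."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if "sample_id" not in self.frame.columns:
            raise ValidationError("SCFA table missing sample_id column")
        acids = [c for c in self.frame.columns if c != "sample_id"]
        unknown = set(acids) - set(SCFA_ACIDS)
        if unknown:
            raise ValidationError(f"unknown acids: {sorted(unknown)}")
        vals = self.frame[acids].to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] < 0):
            raise ValidationError("SCFA concentrations must be non-negative")
        if self.frame["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in SCFA table")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def acids(self) -> list[str]:
        return [c for c in self.frame.columns if c != "sample_id"]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample each sample column to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total counts are dropped with a logged
    warning (padding would fabricate reads). Zero counts can never become
    positive. Reproducible for a fixed ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    counts = np.rint(table.counts).astype(np.int64)
    if not np.allclose(counts, table.counts):
        raise ValueError("rarefaction requires integer counts")
    sums = counts.sum(axis=0)
    keep = sums >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.warning(
            "rarefy: dropping %d sample(s) below depth %d: %s",
            len(dropped), depth, dropped,
        )
    out = np.zeros((table.n_taxa, int(keep.sum())), dtype=float)
    kept_ids = []
    j = 0
    for col, sid, ok in zip(counts.T, table.sample_ids, keep):
        if not ok:
            continue
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
        kept_ids.append(sid)
        j += 1
    return CountTable(
        taxon_ids=list(table.taxon_ids),
        sample_ids=kept_ids,
        counts=out,
        is_rarefied=True,
        rarefaction_depth=depth,
    )


def default_rarefaction_depth(table: CountTable, floor: int = 1000) -> int:
    """Minimum column sum among samples at or above ``floor`` total reads."""
    sums = table.counts.sum(axis=0)
    eligible = sums[sums >= floor]
    if eligible.size == 0:
        raise ValueError(f"no sample reaches the rarefaction floor of {floor}")
    return int(eligible.min())
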