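"""Curation of knock-in experiment tables into modelling samples.

An *experiment* is one microinjection series aiming at a particular point
mutation: a guide, a donor ssODN, and outcome counts over the animals
genotyped (how many carried the designed point mutation = HDR, how many
carried indels = NHEJ).  The same mutation is often attempted more than
once, so experiments sharing a target are merged into a single *sample* by
summing counts.  Samples with no observed mutation at all are discarded
(they measure cutting failure, not repair-pathway choice), efficiencies are
computed per sample as count / animals, and samples are labelled high or
low efficiency against the dataset median.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio.SeqUtils import gc_fraction

from .sequences import _validate_dna

logger = logging.getLogger(__name__)

#: required columns of the experiment table, in canonical order
SCHEMA = ("target_id", "guide", "ssodn", "distance", "n_mice", "n_hdr", "n_indel")
#: optional column: 5' arm length (bases before the edited centre base).
#: When absent the donor is assumed centre-symmetric.
OPTIONAL_COLUMNS = ("arm5",)


class SchemaError(ValueError):
    """Raised when an experiment table violates the documented schema."""


@dataclass(frozen=True)
class ExperimentRecord:
    """One experiment row: a target, its reagents and outcome counts."""

    target_id: str
    guide: str
    ssodn: str
    distance: int
    n_mice: int
    n_hdr: int
    n_indel: int
    arm5: Optional[int] = None

    def __post_init__(self) -> None:
        _validate_dna(self.guide, what="guide")
        _validate_dna(self.ssodn, what="ssODN")
        if min(self.n_mice, self.n_hdr, self.n_indel) < 0:
            raise SchemaError(f"{self.target_id}: counts must be non-negative")
        if self.n_hdr + self.n_indel > self.n_mice:
            raise SchemaError(
                f"{self.target_id}: n_hdr + n_indel = {self.n_hdr + self.n_indel} "
                f"exceeds n_mice = {self.n_mice}"
            )

    @property
    def center_index(self) -> int:
        """0-based donor index of the edited base (arm5, or the midpoint)."""
        return self.arm5 if self.arm5 is not None else len(self.ssodn) // 2

    @property
    def arm3(self) -> int:
        return len(self.ssodn) - self.center_index - 1


@dataclass(frozen=True)
class Sample:
    """A merged target with efficiencies and an optional high/low label."""

    target_id: str
    guide: str
    ssodn: str
    distance: int
    n_mice: int
    n_hdr: int
    n_indel: int
    arm5: Optional[int] = None
    label: Optional[str] = None  # "high" | "low"

    @property
    def hdr_eff(self) -> float:
        return self.n_hdr / self.n_mice

    @property
    def nhej_eff(self) -> float:
        return self.n_indel / self.n_mice

    @property
    def center_index(self) -> int:
        return self.arm5 if self.arm5 is not None else len(self.ssodn) // 2

    @property
    def arm3(self) -> int:
        return len(self.ssodn) - self.center_index - 1

    @property
    def arm5_len(self) -> int:
        return self.center_index


def merge_duplicates(records: Sequence[ExperimentRecord]) -> list[Sample]:
    """Merge repeated attempts at the same target into one sample each.

    Counts are summed within a target_id; guide, ssODN, distance and arm
    layout must agree within a group.  Output order follows first
    appearance of each target, so merging is order-independent up to the
    grouping itself.
    """
    groups: dict[str, list[ExperimentRecord]] = {}
    for rec in records:
        groups.setdefault(rec.target_id, []).append(rec)
    samples = []
    for tid, grp in groups.items():
        first = grp[0]
        for other in grp[1:]:
            for attr in ("guide", "ssodn", "distance", "arm5"):
                if getattr(other, attr) != getattr(first, attr):
                    raise SchemaError(
                        f"target {tid!r}: conflicting {attr} across duplicate "
                        f"experiments ({getattr(first, attr)!r} vs {getattr(other, attr)!r})"
                    )
        samples.append(
            Sample(
                target_id=tid,
                guide=first.guide,
                ssodn=first.ssodn,
                distance=first.distance,
                n_mice=sum(r.n_mice for r in grp),
                n_hdr=sum(r.n_hdr for r in grp),
                n_indel=sum(r.n_indel for r in grp),
                arm5=first.arm5,
            )
        )
    return samples


def filter_no_mutation(samples: Sequence[Sample]) -> list[Sample]:
    """Drop samples where no mutation (neither HDR nor NHEJ) was observed."""
    kept, dropped = [], []
    for s in samples:
        (kept if s.n_hdr + s.n_indel >= 1 else dropped).append(s)
    if dropped:
        logger.info(
            "discarded %d sample(s) with no observed mutation: %s",
            len(dropped),
            ", ".join(s.target_id for s in dropped),
        )
    return kept


def binarize_labels(samples: Sequence[Sample]) -> tuple[list[Sample], float]:
    """Label samples high/low efficiency around the median HDR efficiency.

    The threshold is the dataset median; "high" means strictly greater than
    it, so exact-median ties fall into the low class (and are logged).
    Returns the labelled samples and the threshold used.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to binarize labels")
    effs = np.array([s.hdr_eff for s in samples])
    if np.allclose(effs, effs[0]):
        raise ValueError("all HDR efficiencies identical; labels would be degenerate")
    threshold = float(np.median(effs))
    ties = int(np.sum(effs == threshold))
    if ties:
        logger.info("%d sample(s) tie the median %.4g and are labelled low", ties, threshold)
    labelled = [replace(s, label="high" if s.hdr_eff > threshold else "low") for s in samples]
    return labelled, threshold


def labels_array(samples: Sequence[Sample]) -> np.ndarray:
    """Binary label vector (1 = high efficiency) for modelling."""
    if any(s.label is None for s in samples):
        raise ValueError("samples are unlabelled; run binarize_labels first")
    return np.array([1 if s.label == "high" else 0 for s in samples])


def summarize(samples: Sequence[Sample]) -> dict:
    """Dataset-level summary: counts, medians/IQRs, donor geometry, GC."""
    if not samples:
        raise ValueError("cannot summarize an empty dataset")
    hdr = np.array([s.hdr_eff for s in samples])
    nhej = np.array([s.nhej_eff for s in samples])
    arm5 = np.array([s.arm5_len for s in samples], dtype=float)
    arm3 = np.array([s.arm3 for s in samples], dtype=float)
    lengths = np.array([len(s.ssodn) for s in samples], dtype=float)
    gc = np.array([gc_fraction(s.ssodn) for s in samples])

    def iqr(x: np.ndarray) -> float:
        q1, q3 = np.percentile(x, [25, 75])
        return float(q3 - q1)

    return {
        "n_samples": len(samples),
        "n_mice": int(sum(s.n_mice for s in samples)),
        "mice_per_sample_mean": float(np.mean([s.n_mice for s in samples])),
        "hdr_median": float(np.median(hdr)),
        "hdr_iqr": iqr(hdr),
        "nhej_median": float(np.median(nhej)),
        "nhej_iqr": iqr(nhej),
        "ssodn_length_mean": float(lengths.mean()),
        "arm5_mean": float(arm5.mean()),
        "arm3_mean": float(arm3.mean()),
        "gc_content_mean_pct": float(100.0 * gc.mean()),
    }


def _records_from_frame(df: pd.DataFrame) -> list[ExperimentRecord]:
    missing = [c for c in SCHEMA if c not in df.columns]
    if missing:
        raise SchemaError(f"experiment table is missing required columns: {missing}")
    records = []
    errors = []
    has_arm5 = "arm5" in df.columns
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        try:
            arm5 = getattr(row, "arm5", None) if has_arm5 else None
            if arm5 is not None and pd.isna(arm5):
                arm5 = None
            records.append(
                ExperimentRecord(
                    target_id=str(row.target_id),
                    guide=str(row.guide),
                    ssodn=str(row.ssodn),
                    distance=int(row.distance),
                    n_mice=int(row.n_mice),
                    n_hdr=int(row.n_hdr),
                    n_indel=int(row.n_indel),
                    arm5=int(arm5) if arm5 is not None else None,
                )
            )
        except (ValueError, SchemaError) as exc:
            errors.append(f"line {i}: {exc}")
    if errors:
        raise SchemaError("invalid rows in experiment table:\n" + "\n".join(errors))
    return records


def read_experiment_table(path_or_buf) -> list[ExperimentRecord]:
    """Read a TSV/CSV experiment table (columns: target_id, guide, ssodn,
    distance, n_mice, n_hdr, n_indel[, arm5]); delimiter is sniffed."""
    df = pd.read_csv(path_or_buf, sep=None, engine="python")
    return _records_from_frame(df)


def write_experiment_table(records: Sequence[ExperimentRecord], path_or_buf) -> None:
    """Write experiment records as TSV in canonical column order."""
    cols = list(SCHEMA) + (["arm5"] if any(r.arm5 is not None for r in records) else [])
    df = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])
    df.to_csv(path_or_buf, sep="\t", index=False)


def curate(records: Sequence[ExperimentRecord]) -> tuple[list[Sample], float]:
    """Full curation pipeline: merge, filter, label.  Returns (samples, threshold)."""
    return binarize_labels(filter_no_mutation(merge_duplicates(records)))


def samples_to_frame(samples: Sequence[Sample]) -> pd.DataFrame:
    """Tabular view of curated samples (one row per sample)."""
    return pd.DataFrame(
        {
            "target_id": [s.target_id for s in samples],
            "guide": [s.guide for s in samples],
            "ssodn": [s.ssodn for s in samples],
            "distance": [s.distance for s in samples],
            "n_mice": [s.n_mice for s in samples],
            "n_hdr": [s.n_hdr for s in samples],
            "n_indel": [s.n_indel for s in samples],
            "hdr_eff": [s.hdr_eff for s in samples],
            "nhej_eff": [s.nhej_eff for s in samples],
            "label": [s.label for s in samples],
        }
    )
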