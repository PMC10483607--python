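"""Longitudinal ctDNA metrics: max-VAF, alteration counts, clearance, rates.

Per sample, the monitored quantities are the maximum variant allele frequency
(max-VAF) over PASS alterations and the number of genomic alterations (GAs).
Between two plasma timepoints, dynamics are the elementwise differences
(later minus earlier; undetectable samples contribute 0) and the four-way
clearance class of the status pair. Cohort-level machinery covers detection
rates, tissue/plasma concordance over the union of GAs, and the gene-level
alteration frequency table (genes altered in more than 10% of patients).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .calls import VariantCall

TIMEPOINT_ORDER = {"P0": 0, "P1": 1, "P2": 2}


@dataclass(frozen=True)
class TimepointSummary:
    patient_id: str
    timepoint: str
    max_vaf: float
    n_gas: int
    status: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        if (self.status == "negative") != (self.n_gas == 0):
            raise ValueError("negative status iff zero alterations")
        if self.status == "negative" and self.max_vaf != 0.0:
            raise ValueError("negative samples carry max_vaf 0")


class ClearanceClass(str, Enum):
    NEG_NEG = "neg_neg"
    POS_TO_NEG = "pos_to_neg"
    NEG_TO_POS = "neg_to_pos"
    POS_POS = "pos_pos"


@dataclass(frozen=True)
class ConcordanceSummary:
    shared_fraction: float
    tissue_only_fraction: float
    plasma_only_fraction: float
    n_union: int

    @property
    def empty_union(self) -> bool:
        return self.n_union == 0


@dataclass(frozen=True)
class DetectionRate:
    n_positive: int
    n_total: int
    rate_pct: float  # percentage, 1 decimal


def summarize_timepoint(
    passing_variants: Sequence[VariantCall],
    patient_id: str,
    timepoint: str,
) -> TimepointSummary:
    """Collapse one sample's PASS calls to (max-VAF, GA count, status)."""
    for c in passing_variants:
        if c.status != "PASS":
            raise ValueError("summarize_timepoint expects PASS calls only")
        if c.patient_id is not None and c.patient_id != patient_id:
            raise ValueError(
                f"call from patient {c.patient_id!r} mixed into {patient_id!r}"
            )
    n = len(passing_variants)
    max_vaf = max((c.vaf for c in passing_variants), default=0.0)
    return TimepointSummary(
        patient_id=patient_id,
        timepoint=timepoint,
        max_vaf=max_vaf if n else 0.0,
        n_gas=n,
        status="positive" if n else "negative",
    )


def delta_metrics(
    s0: TimepointSummary, s1: TimepointSummary
) -> tuple[float, int]:
    """(delta max-VAF, delta GA count), later minus earlier.

    Undetectable samples enter as 0 on both axes, so every paired patient has
    a defined delta.
    """
    if s0.patient_id != s1.patient_id:
        raise ValueError(
            f"patient mismatch: {s0.patient_id!r} vs {s1.patient_id!r}"
        )
    if TIMEPOINT_ORDER.get(s0.timepoint, -1) >= TIMEPOINT_ORDER.get(s1.timepoint, 99):
        raise ValueError(f"{s0.timepoint} is not earlier than {s1.timepoint}")
    return (s1.max_vaf - s0.max_vaf, s1.n_gas - s0.n_gas)


def clearance_class(s0: TimepointSummary, s1: TimepointSummary) -> ClearanceClass:
    """Four-way transition class of the (earlier, later) status pair."""
    mapping = {
        ("negative", "negative"): ClearanceClass.NEG_NEG,
        ("positive", "negative"): ClearanceClass.POS_TO_NEG,
        ("negative", "positive"): ClearanceClass.NEG_TO_POS,
        ("positive", "positive"): ClearanceClass.POS_POS,
    }
    return mapping[(s0.status, s1.status)]


def cohort_detection(
    summaries: Iterable[TimepointSummary], timepoint: str
) -> DetectionRate:
    """ctDNA detection rate at one timepoint, as a 1-decimal percentage."""
    subset = [s for s in summaries if s.timepoint == timepoint]
    if not subset:
        raise ValueError(f"no summaries at timepoint {timepoint!r}")
    seen = [s.patient_id for s in subset]
    if len(seen) != len(set(seen)):
        raise ValueError("duplicate patients at one timepoint")
    n_pos = sum(s.status == "positive" for s in subset)
    n = len(subset)
    return DetectionRate(n_pos, n, round(100.0 * n_pos / n, 1))


def concordance_fractions(
    tissue_gas: set, plasma_gas: set
) -> ConcordanceSummary:
    """Shared / tissue-only / plasma-only fractions over the union of GAs."""
    union = tissue_gas | plasma_gas
    n = len(union)
    if n == 0:
        return ConcordanceSummary(0.0, 0.0, 0.0, 0)
    shared = len(tissue_gas & plasma_gas)
    t_only = len(tissue_gas - plasma_gas)
    p_only = len(plasma_gas - tissue_gas)
    return ConcordanceSummary(shared / n, t_only / n, p_only / n, n)


def gene_frequency_table(
    cohort_calls: Mapping[str, Sequence[VariantCall]],
    gene_map: Mapping[int, str],
    min_freq: float = 0.10,
) -> pd.DataFrame:
    """Genes altered in strictly more than ``min_freq`` of patients.

    A patient counts once per gene regardless of how many PASS alterations
    they carry in it; positions without a gene assignment are pooled under
    'unassigned' and excluded from the reported table. Rows sorted by
    descending frequency, gene name as tiebreak.
    """
    n_patients = len(cohort_calls)
    gene_patients: dict[str, set[str]] = {}
    for patient, calls in cohort_calls.items():
        for c in calls:
            if c.status != "PASS":
                continue
            gene = gene_map.get(c.position, "unassigned")
            gene_patients.setdefault(gene, set()).add(patient)
    rows = [
        {
            "gene": g,
            "n_patients": len(pats),
            "frequency": len(pats) / n_patients,
        }
        for g, pats in gene_patients.items()
        if g != "unassigned" and n_patients and len(pats) / n_patients > min_freq
    ]
    df = pd.DataFrame(rows, columns=["gene", "n_patients", "frequency"])
    return df.sort_values(
        ["frequency", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def summaries_to_frame(summaries: Iterable[TimepointSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient": s.patient_id,
                "timepoint": s.timepoint,
                "max_vaf": s.max_vaf,
                "n_gas": s.n_gas,
                "status": s.status,
            }
            for s in summaries
        ],
        columns=["patient", "timepoint", "max_vaf", "n_gas", "status"],
    )


def frame_to_summaries(df: pd.DataFrame) -> list[TimepointSummary]:
    return [
        TimepointSummary(
            patient_id=str(r.patient),
            timepoint=str(r.timepoint),
            max_vaf=float(r.max_vaf),
            n_gas=int(r.n_gas),
            status=str(r.status),
        )
        for r in df.itertuples()
    ]
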