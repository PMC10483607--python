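"""Variant calling and ctDNA positivity classification.

Candidates are every non-reference allele at VAF >= 0.1% (inclusive) in a
consensus pileup. They then pass through three filters: the background-noise
test against the panel of normals, a germline / clonal-hematopoiesis (CHIP)
filter against the patient's white-blood-cell (buffy coat) control, and the
positivity thresholds — tissue-informed (variant known mutant in the
patient's tumor tissue: support >= 3 and total >= 100) or naive (variant not
seen in tissue: support >= 6 and total >= 100). A sample is ctDNA-positive
iff it has at least one PASS somatic variant.

Copy-number calls are pure ratio thresholding per unit: loss at tumor/normal
depth ratio <= 0.65, gain at >= 1.50, boundaries inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errordb import BackgroundErrorDB, noise_test, substitution_key
from .groom import ConsensusPileup

MIN_VAF = 0.001
TISSUE_MIN_SUPPORT = 3
NAIVE_MIN_SUPPORT = 6
MIN_TOTAL = 100
CNV_LOSS_CUTOFF = 0.65
CNV_GAIN_CUTOFF = 1.50
WBC_MAX_AF = 0.0025
WBC_MAX_SUPPORT = 1


@dataclass
class VariantCall:
    position: int
    ref: str
    alt: str
    kind: str  # "SNV" | "indel"
    support: int
    total: int
    vaf: float
    tissue_informed: bool = False
    filters: set[str] = field(default_factory=set)
    status: str = "FAIL"  # "PASS" | "FAIL"
    patient_id: str | None = None
    timepoint: str | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref, self.alt)

    @property
    def substitution(self) -> str:
        return substitution_key(self.ref, self.alt)


def normalize_indel(ref: str, alt: str) -> tuple[str, str]:
    """Left-align and minimize an indel allele pair.

    Trims the shared suffix then the shared prefix (keeping one anchor base),
    the usual VCF minimal representation, so set membership against tissue
    variant sets is well defined.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
    return ref, alt


def call_candidates(
    pileup: ConsensusPileup,
    min_vaf: float = MIN_VAF,
    patient_id: str | None = None,
    timepoint: str | None = None,
) -> list[VariantCall]:
    """Emit one candidate per non-reference allele with VAF >= min_vaf."""
    out: list[VariantCall] = []
    for r in pileup.non_reference().itertuples():
        total = int(r.total)
        if total <= 0:
            continue
        vaf = int(r.support) / total
        if vaf < min_vaf:
            continue
        ref, alt = str(r.ref), str(r.allele)
        kind = "SNV" if len(ref) == 1 and len(alt) == 1 else "indel"
        if kind == "indel":
            ref, alt = normalize_indel(ref, alt)
        out.append(
            VariantCall(
                position=int(r.position),
                ref=ref,
                alt=alt,
                kind=kind,
                support=int(r.support),
                total=total,
                vaf=vaf,
                patient_id=patient_id,
                timepoint=timepoint,
            )
        )
    return out


def filter_noise(
    candidates: Iterable[VariantCall],
    db: BackgroundErrorDB,
    alpha: float = 0.01,
) -> list[VariantCall]:
    """Flag candidates not significantly above the background error model."""
    out = []
    for c in candidates:
        decision = noise_test(c.support, c.total, (c.position, c.substitution), db, alpha)
        c.metadata["noise_p"] = decision.p_value
        if not decision.is_signal:
            c.filters.add("noise")
        out.append(c)
    return out


def filter_germline_chip(
    candidates: Iterable[VariantCall],
    wbc_pileup: ConsensusPileup,
    wbc_max_af: float = WBC_MAX_AF,
    wbc_max_support: int = WBC_MAX_SUPPORT,
) -> list[VariantCall]:
    """Flag candidates also present in the white-blood-cell control.

    High WBC allele fraction marks germline; low-but-real WBC support marks
    clonal hematopoiesis. Candidates at positions the WBC control does not
    cover are kept and annotated ``wbc_uncovered``.
    """
    out = []
    for c in candidates:
        support, total = wbc_pileup.lookup(c.position, c.alt)
        if total == 0:
            c.metadata["wbc_uncovered"] = True
            out.append(c)
            continue
        af = support / total
        c.metadata["wbc_af"] = af
        c.metadata["wbc_support"] = support
        if af > 0.35:
            c.filters.add("germline")
        elif af > wbc_max_af or support > wbc_max_support:
            c.filters.add("chip")
        out.append(c)
    return out


def classify_positivity(
    candidate: VariantCall,
    tissue_variants: set[tuple[int, str, str]],
) -> VariantCall:
    """Apply the tissue-informed / naive positivity thresholds.

    Requires the candidate to have survived the noise and germline/CHIP
    filters; a candidate carrying filters can never PASS.
    """
    candidate.tissue_informed = candidate.key in tissue_variants
    min_support = TISSUE_MIN_SUPPORT if candidate.tissue_informed else NAIVE_MIN_SUPPORT
    if candidate.support < min_support:
        candidate.filters.add("below_support")
    if candidate.total < MIN_TOTAL:
        candidate.filters.add("below_total")
    candidate.status = "PASS" if not candidate.filters else "FAIL"
    return candidate


def call_sample(
    pileup: ConsensusPileup,
    db: BackgroundErrorDB,
    tissue_variants: set[tuple[int, str, str]],
    wbc_pileup: ConsensusPileup | None = None,
    min_vaf: float = MIN_VAF,
    alpha: float = 0.01,
    patient_id: str | None = None,
    timepoint: str | None = None,
) -> list[VariantCall]:
    """Full per-sample calling chain: candidates -> noise -> WBC -> positivity."""
    cands = call_candidates(pileup, min_vaf, patient_id, timepoint)
    cands = filter_noise(cands, db, alpha)
    if wbc_pileup is not None:
        cands = filter_germline_chip(cands, wbc_pileup)
    return [classify_positivity(c, tissue_variants) for c in cands]


def passing(calls: Iterable[VariantCall]) -> list[VariantCall]:
    return [c for c in calls if c.status == "PASS"]


def sample_status(passing_variants: Sequence[VariantCall]) -> str:
    """'positive' iff the sample has at least one PASS somatic variant."""
    return "positive" if len(passing_variants) > 0 else "negative"


@dataclass(frozen=True)
class CNVCall:
    unit: str
    ratio: float
    state: str  # "loss" | "neutral" | "gain"


def call_cnv(
    depth_ratios: Iterable[tuple[str, float]],
    loss_cutoff: float = CNV_LOSS_CUTOFF,
    gain_cutoff: float = CNV_GAIN_CUTOFF,
) -> list[CNVCall]:
    """Classify per-unit tumor/normal depth ratios (boundaries inclusive)."""
    out = []
    for unit, ratio in depth_ratios:
        if not (ratio >= 0):  # also rejects NaN
            raise ValueError(f"depth ratio for {unit!r} must be finite and >= 0")
        if ratio <= loss_cutoff:
            state = "loss"
        elif ratio >= gain_cutoff:
            state = "gain"
        else:
            state = "neutral"
        out.append(CNVCall(unit=str(unit), ratio=float(ratio), state=state))
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

VCF_HEADER = """\
##fileformat=VCFv4.2
##source=ctdnamon
##INFO=<ID=SUPP,Number=1,Type=Integer,Description="Distinct supporting consensus molecules">
##INFO=<ID=DPM,Number=1,Type=Integer,Description="Total consensus molecules at site">
##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency (SUPP/DPM)">
##INFO=<ID=TINF,Number=1,Type=Integer,Description="1 if variant known mutant in patient tissue">
##FILTER=<ID=noise,Description="Not significantly above panel-of-normals background">
##FILTER=<ID=germline,Description="High allele fraction in white-blood-cell control">
##FILTER=<ID=chip,Description="Clonal-hematopoiesis signal in white-blood-cell control">
##FILTER=<ID=below_support,Description="Supporting molecules below positivity threshold">
##FILTER=<ID=below_total,Description="Total molecules below 100">
##contig=<ID=panel>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(calls: Sequence[VariantCall], path) -> None:
    """Write calls as VCFv4.2 on the abstract 'panel' contig."""
    lines = [VCF_HEADER]
    for c in sorted(calls, key=lambda c: (c.position, c.alt)):
        filt = "PASS" if c.status == "PASS" else ";".join(sorted(c.filters)) or "FAIL"
        info = (
            f"SUPP={c.support};DPM={c.total};VAF={c.vaf:.6f};"
            f"TINF={int(c.tissue_informed)}"
        )
        lines.append(
            f"panel\t{c.position}\t.\t{c.ref}\t{c.alt}\t.\t{filt}\t{info}\n"
        )
    with open(path, "w") as fh:
        fh.writelines(lines)


def calls_to_frame(calls: Sequence[VariantCall]) -> pd.DataFrame:
    rows = [
        {
            "patient": c.patient_id,
            "timepoint": c.timepoint,
            "position": c.position,
            "ref": c.ref,
            "alt": c.alt,
            "kind": c.kind,
            "support": c.support,
            "total": c.total,
            "vaf": c.vaf,
            "tissue_informed": int(c.tissue_informed),
            "filters": ";".join(sorted(c.filters)),
            "status": c.status,
        }
        for c in calls
    ]
    cols = [
        "patient", "timepoint", "position", "ref", "alt", "kind",
        "support", "total", "vaf", "tissue_informed", "filters", "status",
    ]
    return pd.DataFrame(rows, columns=cols)


def frame_to_calls(df: pd.DataFrame) -> list[VariantCall]:
    out = []
    for r in df.itertuples():
        filters = set(str(r.filters).split(";")) - {"", "nan"}
        out.append(
            VariantCall(
                position=int(r.position),
                ref=str(r.ref),
                alt=str(r.alt),
                kind=str(r.kind),
                support=int(r.support),
                total=int(r.total),
                vaf=float(r.vaf),
                tissue_informed=bool(r.tissue_informed),
                filters=filters,
                status=str(r.status),
                patient_id=None if pd.isna(r.patient) else str(r.patient),
                timepoint=None if pd.isna(r.timepoint) else str(r.timepoint),
            )
        )
    return out
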