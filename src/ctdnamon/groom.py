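"""Molecule grooming: bi-barcode family grouping, duplex decoding, pileups.

Raw cfDNA sequencing at ~5000x produces redundant reads of each original
molecule. Reads are grouped into strand-families by (mapping position,
canonicalized barcode pair, strand); each family is collapsed to a consensus
allele, and the two strand-families of one double-stranded source molecule
(same canonical pair, opposite strands) are cross-checked: a duplex pair must
agree on the allele or the molecule is rejected as a likely single-strand
artifact. Molecules seen on one strand only (simplex) are retained but
flagged, and by default contribute to both allele support and position
totals; a duplex-only policy restricts support to duplex-confirmed molecules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["position", "strand", "barcode1", "barcode2", "allele", "n_reads"]


@dataclass
class GroomPolicy:
    """Consensus and duplex-decoding thresholds.

    Families of at most ``small_family_max`` reads must agree unanimously
    (``min_agreement_small``); larger families need a ``min_agreement``
    majority. ``duplex_only`` restricts allele support to duplex-confirmed
    molecules (simplex molecules still count toward position totals).
    """

    small_family_max: int = 3
    min_agreement_small: float = 1.0
    min_agreement: float = 0.8
    duplex_only: bool = False


@dataclass(frozen=True)
class MoleculeConsensus:
    """One decoded source molecule."""

    position: int
    barcode_key: tuple[str, str]
    allele: str
    n_reads: int
    duplex: bool


@dataclass
class GroomStats:
    n_records: int = 0
    n_rejected_records: int = 0
    n_families: int = 0
    n_low_agreement: int = 0
    n_duplex_discordant: int = 0
    n_molecules: int = 0


def canonical_pair(barcode1: str, barcode2: str) -> tuple[str, str]:
    """Strand-independent molecule key: the two tags in sorted order.

    Involution: the plus-strand pair (a, b) and the minus-strand pair (b, a)
    canonicalize identically.
    """
    return (barcode1, barcode2) if barcode1 <= barcode2 else (barcode2, barcode1)


def group_and_decode(
    reads: pd.DataFrame,
    policy: GroomPolicy | None = None,
) -> tuple[list[MoleculeConsensus], GroomStats]:
    """Partition read families into molecules and duplex-decode them.

    Malformed records (missing/empty barcode or allele, nonpositive position
    or read count) are dropped and counted, never fatal.
    """
    policy = policy or GroomPolicy()
    stats = GroomStats(n_records=len(reads))
    if len(reads) == 0:
        return [], stats

    df = reads.copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"read table lacks required columns: {missing}")

    ok = (
        df["barcode1"].astype(str).str.len().gt(0)
        & df["barcode2"].astype(str).str.len().gt(0)
        & df["allele"].astype(str).str.len().gt(0)
        & df["strand"].isin(["+", "-"])
        & pd.to_numeric(df["position"], errors="coerce").gt(0)
        & pd.to_numeric(df["n_reads"], errors="coerce").ge(1)
    )
    stats.n_rejected_records = int((~ok).sum())
    if stats.n_rejected_records:
        log.warning("dropping %d malformed read records", stats.n_rejected_records)
    df = df[ok]
    if len(df) == 0:
        return [], stats

    b1 = df["barcode1"].astype(str).to_numpy()
    b2 = df["barcode2"].astype(str).to_numpy()
    lo = np.minimum(b1, b2)
    hi = np.maximum(b1, b2)
    work = pd.DataFrame(
        {
            "position": df["position"].astype(int).to_numpy(),
            "k1": lo,
            "k2": hi,
            "strand": df["strand"].to_numpy(),
            "allele": df["allele"].astype(str).to_numpy(),
            "n_reads": df["n_reads"].astype(int).to_numpy(),
        }
    )

    # strand-family consensus: majority allele subject to agreement threshold
    fam = (
        work.groupby(["position", "k1", "k2", "strand", "allele"], sort=True)["n_reads"]
        .sum()
        .reset_index()
    )
    grp = fam.groupby(["position", "k1", "k2", "strand"], sort=True)
    totals = grp["n_reads"].transform("sum")
    best = grp["n_reads"].transform("max")
    is_best = fam["n_reads"] == best
    # deterministic tie-break: first allele in sort order among the maxima
    first_best = is_best & ~fam.assign(ib=is_best).groupby(
        ["position", "k1", "k2", "strand"], sort=True
    )["ib"].cumsum().gt(1)
    cons = fam[first_best].copy()
    cons["total_reads"] = totals[first_best].to_numpy()
    stats.n_families = len(cons)

    agreement = cons["n_reads"] / cons["total_reads"]
    small = cons["total_reads"] <= policy.small_family_max
    passed = np.where(
        small,
        agreement >= policy.min_agreement_small - 1e-12,
        agreement >= policy.min_agreement - 1e-12,
    )
    stats.n_low_agreement = int((~passed).sum())
    cons = cons[passed]

    mol = (
        cons.groupby(["position", "k1", "k2"], sort=True)
        .agg(
            n_strands=("strand", "size"),
            n_alleles=("allele", "nunique"),
            allele=("allele", "first"),
            n_reads=("total_reads", "sum"),
        )
        .reset_index()
    )
    discordant = (mol["n_strands"] == 2) & (mol["n_alleles"] > 1)
    stats.n_duplex_discordant = int(discordant.sum())
    mol = mol[~discordant]
    duplex_flags = (mol["n_strands"] == 2).to_numpy()
    molecules = [
        MoleculeConsensus(int(p), (k1, k2), str(a), int(nr), bool(dx))
        for p, k1, k2, a, nr, dx in zip(
            mol["position"].to_numpy(),
            mol["k1"].to_numpy(),
            mol["k2"].to_numpy(),
            mol["allele"].to_numpy(),
            mol["n_reads"].to_numpy(),
            duplex_flags,
        )
    ]
    stats.n_molecules = len(molecules)
    return molecules, stats


PILEUP_COLUMNS = ["position", "ref", "allele", "support", "total", "duplex_confirmed"]


@dataclass
class ConsensusPileup:
    """Per-position consensus molecule counts.

    One row per observed allele at a position, with the position's total
    decoded molecule count repeated on each row. VAF of an allele is
    support / total.
    """

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=PILEUP_COLUMNS))

    def __post_init__(self) -> None:
        f = self.frame
        if len(f) and (f["support"] > f["total"]).any():
            raise ValueError("allele support exceeds position total")
        if len(f) and ((f["support"] < 0) | (f["total"] < 0)).any():
            raise ValueError("negative counts in pileup")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ConsensusPileup":
        return cls(frame.reindex(columns=PILEUP_COLUMNS).reset_index(drop=True))

    @property
    def empty(self) -> bool:
        return len(self.frame) == 0

    def total(self, position: int) -> int:
        rows = self.frame[self.frame["position"] == position]
        return int(rows["total"].iloc[0]) if len(rows) else 0

    def non_reference(self) -> pd.DataFrame:
        f = self.frame
        return f[(f["allele"] != f["ref"]) & (f["support"] > 0)].reset_index(drop=True)

    def lookup(self, position: int, alt: str) -> tuple[int, int]:
        """(support, total) for one alternate allele; (0, total) if unseen."""
        rows = self.frame[self.frame["position"] == position]
        if not len(rows):
            return 0, 0
        hit = rows[rows["allele"] == alt]
        support = int(hit["support"].iloc[0]) if len(hit) else 0
        return support, int(rows["total"].iloc[0])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ConsensusPileup":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def build_pileup(
    molecules: Iterable[MoleculeConsensus],
    ref_map: Mapping[int, str],
    policy: GroomPolicy | None = None,
) -> ConsensusPileup:
    """Aggregate decoded molecules into a consensus pileup.

    Simplex molecules count toward totals always and toward support unless
    ``policy.duplex_only`` is set. Positions absent from ``ref_map`` are
    skipped with a warning (off-panel).
    """
    policy = policy or GroomPolicy()
    mols = list(molecules)
    if not mols:
        return ConsensusPileup()

    totals: dict[int, int] = {}
    support: dict[tuple[int, str], int] = {}
    duplex: dict[tuple[int, str], int] = {}
    skipped = 0
    for m in mols:
        ref = ref_map.get(m.position)
        if ref is None:
            skipped += 1
            continue
        totals[m.position] = totals.get(m.position, 0) + 1
        key = (m.position, m.allele)
        if m.duplex:
            duplex[key] = duplex.get(key, 0) + 1
        if m.duplex or not policy.duplex_only:
            support[key] = support.get(key, 0) + 1
    if skipped:
        log.warning("skipped %d molecules at off-panel positions", skipped)

    rows = [
        {
            "position": pos,
            "ref": ref_map[pos],
            "allele": allele,
            "support": supp,
            "total": totals[pos],
            "duplex_confirmed": duplex.get((pos, allele), 0),
        }
        for (pos, allele), supp in sorted(support.items())
    ]
    # positions whose every molecule was excluded from support still appear
    seen = {r["position"] for r in rows}
    for pos in sorted(set(totals) - seen):
        rows.append(
            {
                "position": pos,
                "ref": ref_map[pos],
                "allele": ref_map[pos],
                "support": 0,
                "total": totals[pos],
                "duplex_confirmed": 0,
            }
        )
    return ConsensusPileup.from_frame(pd.DataFrame(rows, columns=PILEUP_COLUMNS))
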