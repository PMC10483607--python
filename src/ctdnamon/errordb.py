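"""Position- and substitution-specific background error model.

Healthy-donor plasma pools estimate, per (panel position, base substitution),
the background allele fraction and the largest distinct-molecule support ever
seen in a normal sample. A candidate alteration is kept as signal only if it
is significantly higher than that background on BOTH axes: its allele
fraction (one-sided exact binomial tail against the pooled background rate)
and its distinct supporting molecules (strict exceedance of the normals'
maximum). Substitutions never observed in any donor have background 0, which
makes the allele-fraction test reduce to "any support at all" — the
supporting-reads axis and the downstream positivity thresholds carry the
burden there.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats as sps

from .groom import ConsensusPileup


def substitution_key(ref: str, alt: str) -> str:
    return f"{ref}>{alt}"


@dataclass(frozen=True)
class SiteError:
    pooled_error_af: float
    max_support_in_normals: int
    n_donors_observed: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.pooled_error_af <= 1.0):
            raise ValueError("pooled_error_af outside [0, 1]")
        if self.max_support_in_normals < 0:
            raise ValueError("max_support_in_normals negative")


_ZERO = SiteError(0.0, 0, 0)


@dataclass
class BackgroundErrorDB:
    """Map from (position, "REF>ALT") to pooled background statistics."""

    sites: dict[tuple[int, str], SiteError] = field(default_factory=dict)
    n_donors: int = 0

    def lookup(self, position: int, substitution: str) -> SiteError:
        """Background at a key; absent keys are clean (af 0, max support 0)."""
        return self.sites.get((position, substitution), _ZERO)

    def __len__(self) -> int:
        return len(self.sites)

    def to_tsv(self, path, metadata_path=None, alpha: float | None = None) -> None:
        rows = [
            {
                "position": pos,
                "substitution": sub,
                "pooled_af": se.pooled_error_af,
                "max_support": se.max_support_in_normals,
                "n_donors": se.n_donors_observed,
            }
            for (pos, sub), se in sorted(self.sites.items())
        ]
        pd.DataFrame(
            rows,
            columns=["position", "substitution", "pooled_af", "max_support", "n_donors"],
        ).to_csv(path, sep="\t", index=False)
        if metadata_path is not None:
            meta = {"n_donors": self.n_donors, "n_keys": len(self.sites)}
            if alpha is not None:
                meta["alpha"] = alpha
            with open(metadata_path, "w") as fh:
                json.dump(meta, fh, indent=2, sort_keys=True)

    @classmethod
    def from_tsv(cls, path, n_donors: int = 0) -> "BackgroundErrorDB":
        df = pd.read_csv(path, sep="\t")
        sites = {
            (int(r.position), str(r.substitution)): SiteError(
                float(r.pooled_af), int(r.max_support), int(r.n_donors)
            )
            for r in df.itertuples()
        }
        return cls(sites=sites, n_donors=n_donors)


def build_error_db(normal_pileups: Sequence[ConsensusPileup]) -> BackgroundErrorDB:
    """Pool healthy-donor pileups into the background error database.

    pooled_error_af at a key = (sum of donor supports) / (sum of donor totals
    at that position, over donors covering it); donors with zero total at a
    position are skipped for that position.
    """
    pileups = list(normal_pileups)
    if not pileups:
        raise ValueError("build_error_db requires at least one donor pileup")

    supp: dict[tuple[int, str], int] = {}
    max_supp: dict[tuple[int, str], int] = {}
    n_obs: dict[tuple[int, str], int] = {}
    pos_total: dict[int, int] = {}

    for pu in pileups:
        if pu.empty:
            continue
        per_pos = pu.frame.groupby("position")["total"].first()
        for pos, tot in per_pos.items():
            if tot > 0:
                pos_total[int(pos)] = pos_total.get(int(pos), 0) + int(tot)
        for r in pu.non_reference().itertuples():
            key = (int(r.position), substitution_key(str(r.ref), str(r.allele)))
            supp[key] = supp.get(key, 0) + int(r.support)
            max_supp[key] = max(max_supp.get(key, 0), int(r.support))
            n_obs[key] = n_obs.get(key, 0) + 1

    sites = {}
    for key, s in supp.items():
        denom = pos_total.get(key[0], 0)
        sites[key] = SiteError(
            pooled_error_af=s / denom if denom else 0.0,
            max_support_in_normals=max_supp[key],
            n_donors_observed=n_obs[key],
        )
    return BackgroundErrorDB(sites=sites, n_donors=len(pileups))


@dataclass(frozen=True)
class NoiseDecision:
    call: str  # "signal" | "noise"
    p_value: float
    background_af: float
    max_support_in_normals: int

    @property
    def is_signal(self) -> bool:
        return self.call == "signal"


def noise_test(
    support: int,
    total: int,
    key: tuple[int, str],
    db: BackgroundErrorDB,
    alpha: float = 0.01,
) -> NoiseDecision:
    """Classify a candidate as background noise or real signal.

    Signal requires both: P(X >= support | total, background af) < alpha under
    an exact one-sided binomial tail, and support strictly greater than the
    maximum distinct-molecule support seen in any normal donor. Per-candidate
    decision, no multiplicity correction.
    """
    if total <= 0:
        raise ValueError("noise_test requires total > 0")
    se = db.lookup(*key)
    if support <= 0:
        return NoiseDecision("noise", 1.0, se.pooled_error_af, se.max_support_in_normals)
    # P(X >= support) = sf(support - 1); exact, no approximation
    p = float(sps.binom.sf(support - 1, total, se.pooled_error_af))
    signal = p < alpha and support > se.max_support_in_normals
    return NoiseDecision(
        "signal" if signal else "noise",
        p,
        se.pooled_error_af,
        se.max_support_in_normals,
    )
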