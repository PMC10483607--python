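"""Synthetic cfDNA cohort generator for neoadjuvant-chemotherapy ctDNA monitoring.

Generates a fully specified truth world — a targeted panel, per-site background
error rates, per-patient tumor variant sets with tissue/plasma overlap
structure, variant-allele-fraction (VAF) trajectories by RECIST response class,
and survival times whose hazard depends on post-chemotherapy ctDNA
detectability — plus the raw material the analysis consumes: read-family
tables at duplex-barcode resolution and healthy-donor background pools.

Coordinates are abstract 1-based panel positions; alleles are single bases.
The generator is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BASES = np.array(["A", "C", "G", "T"])
RESPONSES = ("PR", "SD", "PD")
PLASMA_TIMEPOINTS = ("P0", "P1", "P2")

READ_TABLE_COLUMNS = [
    "patient",
    "timepoint",
    "position",
    "strand",
    "barcode1",
    "barcode2",
    "allele",
    "n_reads",
]


class ConfigError(ValueError):
    """A SimulationConfig field violates its constraints; names the field."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the monitored gastric-cancer cohort: 79 patients, ~5000x
    raw cfDNA depth collapsing to ~2500 consensus molecules, baseline cohort
    mean max-VAF 0.50% falling to 0.08% in partial responders, tissue/plasma
    variant overlap 33.8/56.2/9.5 (normalized), and an exponential survival
    model in which post-chemotherapy ctDNA positivity multiplies the hazard.
    """

    n_patients: int = 79
    response_mix: Mapping[str, float] = field(
        default_factory=lambda: {"PR": 0.32, "SD": 0.63, "PD": 0.05}
    )
    raw_depth: int = 5000
    consensus_depth_target: int = 2500
    panel_positions: int = 2000
    n_genes: int = 425
    n_tumor_variants_mean: float = 8.0
    baseline_maxvaf_mean: float = 0.0050
    # log-scale spread of patient baselines; 1.5 puts meaningful mass below
    # the ~0.1% detection limit so that roughly 60% of patients shed
    # detectable ctDNA at baseline while the cohort mean stays at 0.50%
    baseline_maxvaf_sigma: float = 1.5
    post_nact_factor: Mapping[str, float] = field(
        default_factory=lambda: {"PR": 0.16, "SD": 1.0, "PD": 2.5}
    )
    post_surgery_factor: Mapping[str, float] = field(
        default_factory=lambda: {"PR": 0.6, "SD": 0.9, "PD": 1.8}
    )
    trajectory_sigma: float = 0.25  # log-scale noise on per-patient factors
    shared_fraction: float = 0.338
    tissue_only_fraction: float = 0.562
    plasma_only_fraction: float = 0.095
    # survival: exponential baseline calibrated so the ctDNA-negative stratum
    # has S(36 months) ~ 0.73; positivity multiplies the hazard
    baseline_hazard: float = 0.00874  # events per month
    hazard_ratio_ctdna_pos: float = 3.4
    detectability_vaf: float = 0.001
    censoring_rate: float = 0.2
    followup_max_months: float = 60.0
    # read-family emission
    duplex_fraction: float = 0.8
    artifact_rate: float = 0.002
    family_size_mean: float = 2.0
    # background error landscape at consensus-molecule level; duplex
    # consensus suppresses raw sequencing error by orders of magnitude, so
    # residual per-substitution backgrounds center around 1e-4
    error_site_fraction: float = 0.10
    error_rate_mean: float = 1e-4
    error_rate_sigma: float = 1.0
    # non-tumor contamination exercised by the white-blood-cell filter
    chip_probability: float = 0.15
    chip_vaf_mean: float = 0.02
    germline_per_patient: int = 1
    wbc_depth: int = 1000
    n_donors: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        mix = dict(self.response_mix)
        if set(mix) != set(RESPONSES) or abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ConfigError(
                "response_mix must cover PR/SD/PD and sum to 1, got %r" % (mix,)
            )
        if any(v < 0 for v in mix.values()):
            raise ConfigError("response_mix proportions must be nonnegative")
        fracs = (
            self.shared_fraction,
            self.tissue_only_fraction,
            self.plasma_only_fraction,
        )
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ConfigError(
                "shared/tissue_only/plasma_only fractions must lie in [0, 1]"
            )
        # printed cohort fractions round to a sum of 0.995; accept near-1 sums
        # and renormalize, reject anything farther off
        if abs(sum(fracs) - 1.0) > 0.01:
            raise ConfigError(
                "shared_fraction + tissue_only_fraction + plasma_only_fraction "
                "must sum to 1 (within 0.01), got %.4f" % sum(fracs)
            )
        for name in (
            "n_patients",
            "raw_depth",
            "consensus_depth_target",
            "panel_positions",
            "n_genes",
            "wbc_depth",
            "n_donors",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive count")
        for name in (
            "baseline_maxvaf_mean",
            "censoring_rate",
            "duplex_fraction",
            "artifact_rate",
            "error_site_fraction",
            "chip_probability",
            "detectability_vaf",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be a fraction in [0, 1], got {v}")
        if self.hazard_ratio_ctdna_pos <= 0:
            raise ConfigError("hazard_ratio_ctdna_pos must be > 0")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be > 0")

    def overlap_fractions(self) -> tuple[float, float, float]:
        """Shared / tissue-only / plasma-only fractions, renormalized to 1."""
        f = np.array(
            [self.shared_fraction, self.tissue_only_fraction, self.plasma_only_fraction]
        )
        f = f / f.sum()
        return float(f[0]), float(f[1]), float(f[2])


@dataclass(frozen=True)
class Panel:
    """Abstract targeted panel: reference base and gene label per position."""

    ref: np.ndarray  # index 0 = position 1
    gene: np.ndarray

    @property
    def n_positions(self) -> int:
        return len(self.ref)

    def ref_base(self, position: int) -> str:
        return str(self.ref[position - 1])

    def ref_map(self) -> dict[int, str]:
        return {i + 1: str(b) for i, b in enumerate(self.ref)}

    def gene_map(self) -> dict[int, str]:
        return {i + 1: str(g) for i, g in enumerate(self.gene)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, self.n_positions + 1),
                "ref": self.ref,
                "gene": self.gene,
            }
        )


@dataclass
class TruePatientState:
    patient_id: str
    response: str
    tumor_fraction_by_timepoint: dict[str, float]
    tissue_variants: set[tuple[int, str, str]]
    plasma_variants: set[tuple[int, str, str]]
    # per plasma variant, its VAF relative to the sample max-VAF (max-VAF
    # variant has relative fraction 1); fixed across timepoints
    plasma_variant_fracs: dict[tuple[int, str, str], float]
    chip_variants: dict[tuple[int, str, str], float]
    germline_variants: dict[tuple[int, str, str], float]
    survival_time: float
    event: bool

    def plasma_vafs(self, timepoint: str) -> dict[tuple[int, str, str], float]:
        """True per-variant VAFs at a plasma timepoint (tumor-derived only)."""
        tf = self.tumor_fraction_by_timepoint[timepoint]
        return {v: tf * f for v, f in self.plasma_variant_fracs.items()}


def simulate_panel(config: SimulationConfig, rng: np.random.Generator) -> Panel:
    n = config.panel_positions
    ref = rng.choice(BASES, size=n)
    # contiguous gene blocks over the panel
    width = max(len(str(config.n_genes)), 3)
    gene_idx = np.minimum(
        (np.arange(n) * config.n_genes) // n, config.n_genes - 1
    )
    gene = np.array([f"G{i + 1:0{width}d}" for i in gene_idx])
    return Panel(ref=ref, gene=gene)


def simulate_error_truth(
    panel: Panel, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw the true background-error landscape.

    A configurable fraction of panel sites carries one error-prone
    substitution whose rate is log-normal around ``error_rate_mean``; all
    other (site, substitution) pairs have rate 0.
    """
    n_sites = int(round(config.error_site_fraction * panel.n_positions))
    positions = np.sort(
        rng.choice(panel.n_positions, size=n_sites, replace=False) + 1
    )
    refs = panel.ref[positions - 1]
    # pick an alt base different from the ref at each site
    offsets = rng.integers(1, 4, size=n_sites)
    ref_idx = np.searchsorted(BASES, refs)
    alts = BASES[(ref_idx + offsets) % 4]
    mu = math.log(config.error_rate_mean) - config.error_rate_sigma**2 / 2
    rates = np.exp(rng.normal(mu, config.error_rate_sigma, size=n_sites))
    rates = np.clip(rates, 0.0, 0.05)
    return pd.DataFrame(
        {"position": positions, "ref": refs, "alt": alts, "rate": rates}
    )


def _draw_variants(
    n: int,
    panel: Panel,
    rng: np.random.Generator,
    exclude: set[int] | None = None,
) -> list[tuple[int, str, str]]:
    """Draw n distinct (position, ref, alt) variants on the panel."""
    if n == 0:
        return []
    taken = set(exclude or ())
    avail = np.setdiff1d(
        np.arange(1, panel.n_positions + 1), np.fromiter(taken, int, len(taken))
    )
    if len(avail) < n:
        raise ConfigError(
            "panel_positions too small to draw %d variants without collision" % n
        )
    positions = rng.choice(avail, size=n, replace=False)
    out = []
    for pos in positions:
        ref = panel.ref_base(int(pos))
        alt = str(rng.choice(BASES[BASES != ref]))
        out.append((int(pos), ref, alt))
    return out


def simulate_variant_truth(
    n_variants: int,
    panel: Panel,
    config: SimulationConfig,
    rng: np.random.Generator,
    exclude: set[int] | None = None,
) -> tuple[set[tuple[int, str, str]], set[tuple[int, str, str]]]:
    """Draw a patient's tissue and plasma variant sets with the configured
    shared / tissue-only / plasma-only category fractions."""
    variants = _draw_variants(n_variants, panel, rng, exclude)
    p_shared, p_tissue, p_plasma = config.overlap_fractions()
    cats = rng.choice(3, size=len(variants), p=[p_shared, p_tissue, p_plasma])
    tissue = {v for v, c in zip(variants, cats) if c in (0, 1)}
    plasma = {v for v, c in zip(variants, cats) if c in (0, 2)}
    return tissue, plasma


def _class_factor(
    response: str,
    means: Mapping[str, float],
    sigma: float,
    rng: np.random.Generator,
) -> float:
    """Per-patient multiplicative VAF change, forced to the class direction."""
    f = means[response] * float(np.exp(rng.normal(0.0, sigma)))
    if response == "PR":
        f = min(f, 0.95)
    elif response == "PD":
        f = max(f, 1.05)
    return f


def simulate_cohort(
    config: SimulationConfig,
    panel: Panel | None = None,
    rng: np.random.Generator | None = None,
) -> list[TruePatientState]:
    """Generate the full patient-level truth for one cohort.

    Response labels are multinomial from ``response_mix``; baseline max-VAF is
    log-normal with the configured cohort mean; post-chemotherapy (P1) and
    post-surgery (P2) tumor fractions follow per-class multiplicative factors
    with the class direction enforced per patient. Survival is exponential
    with the hazard multiplied by ``hazard_ratio_ctdna_pos`` when the P1 tumor
    fraction reaches ``detectability_vaf``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if panel is None:
        panel = simulate_panel(config, rng)

    labels = rng.choice(
        RESPONSES,
        size=config.n_patients,
        p=[config.response_mix[r] for r in RESPONSES],
    )
    mu = (
        math.log(config.baseline_maxvaf_mean)
        - config.baseline_maxvaf_sigma**2 / 2
    )
    states: list[TruePatientState] = []
    width = len(str(config.n_patients))
    for i in range(config.n_patients):
        response = str(labels[i])
        tf0 = float(np.exp(rng.normal(mu, config.baseline_maxvaf_sigma)))
        tf0 = min(tf0, 0.3)
        f1 = _class_factor(response, config.post_nact_factor, config.trajectory_sigma, rng)
        f2 = _class_factor(response, config.post_surgery_factor, config.trajectory_sigma, rng)
        tf = {"P0": tf0, "P1": tf0 * f1, "P2": tf0 * f1 * f2}

        n_var = int(rng.poisson(config.n_tumor_variants_mean))
        tissue, plasma = simulate_variant_truth(n_var, panel, config, rng)
        fracs: dict[tuple[int, str, str], float] = {}
        if plasma:
            ordered = sorted(plasma)
            rel = rng.uniform(0.15, 1.0, size=len(ordered))
            rel[int(rng.integers(len(ordered)))] = 1.0
            fracs = {v: float(r) for v, r in zip(ordered, rel)}

        taken = {p for p, _, _ in tissue | plasma}
        chip: dict[tuple[int, str, str], float] = {}
        if rng.uniform() < config.chip_probability:
            (v,) = _draw_variants(1, panel, rng, taken)
            chip[v] = float(
                np.clip(config.chip_vaf_mean * np.exp(rng.normal(0, 0.5)), 1e-3, 0.2)
            )
            taken.add(v[0])
        germline: dict[tuple[int, str, str], float] = {}
        for v in _draw_variants(config.germline_per_patient, panel, rng, taken):
            germline[v] = float(np.clip(rng.normal(0.5, 0.05), 0.3, 0.7))
            taken.add(v[0])

        detectable = tf["P1"] >= config.detectability_vaf
        hazard = config.baseline_hazard * (
            config.hazard_ratio_ctdna_pos if detectable else 1.0
        )
        t_event = float(rng.exponential(1.0 / hazard))
        censor = config.followup_max_months
        if rng.uniform() < config.censoring_rate:
            censor = min(censor, float(rng.uniform(4.9, 36.0)))
        time = max(min(t_event, censor), 1e-3)
        event = t_event <= censor

        states.append(
            TruePatientState(
                patient_id=f"PT{i + 1:0{width}d}",
                response=response,
                tumor_fraction_by_timepoint=tf,
                tissue_variants=tissue,
                plasma_variants=plasma,
                plasma_variant_fracs=fracs,
                chip_variants=chip,
                germline_variants=germline,
                survival_time=time,
                event=event,
            )
        )
    return states


# ---------------------------------------------------------------------------
# read-family emission (duplex-barcode resolution)
# ---------------------------------------------------------------------------

def simulate_reads(
    state: TruePatientState | None,
    timepoint: str,
    error_truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    panel: Panel | None = None,
    positions: Sequence[int] | None = None,
    extra_vafs: Mapping[tuple[int, str, str], float] | None = None,
    patient: str | None = None,
) -> pd.DataFrame:
    """Emit a read-family table for one sample.

    Each consensus molecule yields one family row per sequenced strand:
    ``(patient, timepoint, position, strand, barcode1, barcode2, allele,
    n_reads)``. A ``duplex_fraction`` of molecules is sequenced on both
    strands (the minus-strand row carries the barcode pair in reversed
    order); ``artifact_rate`` injects single-strand errors, which on duplex
    molecules appear as strand-discordant allele pairs.

    ``positions`` restricts emission to a site subset (default: every site
    that carries a true variant or a nonzero background error rate, which is
    the support of the non-reference signal). ``extra_vafs`` adds spike-in
    variants, used for null samples and calibration runs.
    """
    if state is not None and timepoint not in PLASMA_TIMEPOINTS:
        raise ValueError(f"unknown timepoint {timepoint!r}; expected P0/P1/P2")

    vafs: dict[tuple[int, str, str], float] = {}
    if state is not None:
        vafs.update(state.plasma_vafs(timepoint))
        vafs.update(state.chip_variants)
        vafs.update(state.germline_variants)
    if extra_vafs:
        vafs.update(extra_vafs)

    err_by_pos = {
        int(r.position): (str(r.ref), str(r.alt), float(r.rate))
        for r in error_truth.itertuples()
    }
    if positions is None:
        pos_set = {p for p, _, _ in vafs} | set(err_by_pos)
        positions = sorted(pos_set)
    if patient is None:
        patient = state.patient_id if state is not None else "NA"

    ref_map: dict[int, str] = {}
    if panel is not None:
        ref_map = panel.ref_map()
    for (p, r, _a) in vafs:
        ref_map.setdefault(p, r)
    for p, (r, _a, _rate) in err_by_pos.items():
        ref_map.setdefault(p, r)

    var_by_pos: dict[int, list[tuple[str, float]]] = {}
    for (p, _r, a), v in vafs.items():
        var_by_pos.setdefault(p, []).append((a, v))

    rows_pos: list[np.ndarray] = []
    rows_allele: list[np.ndarray] = []
    mol_offset = 0
    all_mol_ids: list[np.ndarray] = []
    for pos in positions:
        ref = ref_map.get(pos)
        if ref is None:
            continue
        n_mol = int(rng.poisson(config.consensus_depth_target))
        if n_mol == 0:
            continue
        alleles = [ref]
        probs = [1.0]
        for a, v in var_by_pos.get(pos, ()):  # true variants
            alleles.append(a)
            probs.append(min(v, 1.0))
        if pos in err_by_pos:
            _r, ea, erate = err_by_pos[pos]
            if ea in alleles[1:]:
                probs[alleles.index(ea)] += erate
            else:
                alleles.append(ea)
                probs.append(erate)
        probs[0] = max(1.0 - sum(probs[1:]), 0.0)
        p_arr = np.asarray(probs) / np.sum(probs)
        drawn = rng.choice(np.asarray(alleles), size=n_mol, p=p_arr)
        rows_pos.append(np.full(n_mol, pos))
        rows_allele.append(drawn)
        all_mol_ids.append(np.arange(mol_offset, mol_offset + n_mol))
        mol_offset += n_mol

    if not rows_pos:
        return pd.DataFrame(columns=READ_TABLE_COLUMNS)

    pos_arr = np.concatenate(rows_pos)
    allele_arr = np.concatenate(rows_allele).astype(object)
    mol_ids = np.concatenate(all_mol_ids)
    n_total = len(pos_arr)

    is_duplex = rng.uniform(size=n_total) < config.duplex_fraction
    # per-strand artifact: replaces the strand's observed allele with a random
    # non-reference base
    plus_art = rng.uniform(size=n_total) < config.artifact_rate
    minus_art = rng.uniform(size=n_total) < config.artifact_rate

    def artifact_alleles(mask: np.ndarray) -> np.ndarray:
        out = allele_arr.copy()
        idx = np.nonzero(mask)[0]
        for i in idx:
            ref = ref_map[int(pos_arr[i])]
            out[i] = str(rng.choice(BASES[BASES != ref]))
        return out

    plus_allele = artifact_alleles(plus_art)
    minus_allele = artifact_alleles(minus_art)

    fs = lambda n: 1 + rng.poisson(max(config.family_size_mean - 1.0, 0.0), size=n)
    b1 = np.array([f"L{m:07d}" for m in mol_ids], dtype=object)
    b2 = np.array([f"R{m:07d}" for m in mol_ids], dtype=object)

    frames = []
    # plus-strand families (every molecule gets one; simplex molecules are
    # assigned a random strand below)
    simplex_minus = (~is_duplex) & (rng.uniform(size=n_total) < 0.5)
    plus_mask = is_duplex | (~is_duplex & ~simplex_minus)
    minus_mask = is_duplex | simplex_minus
    frames.append(
        pd.DataFrame(
            {
                "position": pos_arr[plus_mask],
                "strand": "+",
                "barcode1": b1[plus_mask],
                "barcode2": b2[plus_mask],
                "allele": plus_allele[plus_mask],
                "n_reads": fs(int(plus_mask.sum())),
            }
        )
    )
    frames.append(
        pd.DataFrame(
            {
                "position": pos_arr[minus_mask],
                "strand": "-",
                # reversed tag order on the opposite strand
                "barcode1": b2[minus_mask],
                "barcode2": b1[minus_mask],
                "allele": minus_allele[minus_mask],
                "n_reads": fs(int(minus_mask.sum())),
            }
        )
    )
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "timepoint", timepoint if state is not None else "NORMAL")
    out.insert(0, "patient", patient)
    return out.sort_values(["position", "barcode1", "barcode2"], kind="stable").reset_index(
        drop=True
    )


def simulate_normal_pool(
    n_donors: int,
    error_truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    panel: Panel | None = None,
    positions: Sequence[int] | None = None,
) -> list[pd.DataFrame]:
    """Read-family tables for healthy-donor plasma: background errors only."""
    if n_donors < 1:
        raise ConfigError("n_donors must be >= 1")
    return [
        simulate_reads(
            None,
            "P0",
            error_truth,
            config,
            rng,
            panel=panel,
            positions=positions,
            patient=f"HD{d + 1:03d}",
        )
        for d in range(n_donors)
    ]


# ---------------------------------------------------------------------------
# consensus-level fast path (binomial draws, no read emission)
# ---------------------------------------------------------------------------

def simulate_sample_pileup(
    state: TruePatientState | None,
    timepoint: str,
    error_truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    extra_vafs: Mapping[tuple[int, str, str], float] | None = None,
):
    """Draw a consensus pileup directly at the molecule level.

    Vectorized binomial sampling of per-site allele counts at the sites that
    can carry non-reference signal (true variants plus error-prone sites).
    This is the scaling path for cohort-sized runs; the read-family path
    (``simulate_reads`` + grooming) models the same consensus counts and is
    used for molecule-resolution checks.
    """
    from .groom import ConsensusPileup

    if state is not None and timepoint not in PLASMA_TIMEPOINTS:
        raise ValueError(f"unknown timepoint {timepoint!r}; expected P0/P1/P2")

    vafs: dict[tuple[int, str, str], float] = {}
    if state is not None:
        vafs.update(state.plasma_vafs(timepoint))
        vafs.update(state.chip_variants)
        vafs.update(state.germline_variants)
    if extra_vafs:
        vafs.update(extra_vafs)

    keys: list[tuple[int, str, str]] = list(vafs)
    rates = [min(vafs[k], 1.0) for k in keys]
    for r in error_truth.itertuples():
        k = (int(r.position), str(r.ref), str(r.alt))
        if k in vafs:
            i = keys.index(k)
            rates[i] = min(rates[i] + float(r.rate), 1.0)
        else:
            keys.append(k)
            rates.append(float(r.rate))

    pos_totals: dict[int, int] = {}
    records = []
    for (pos, ref, alt), rate in zip(keys, rates):
        if pos not in pos_totals:
            pos_totals[pos] = int(rng.poisson(config.consensus_depth_target))
        total = pos_totals[pos]
        support = int(rng.binomial(total, rate)) if total else 0
        duplex = int(rng.binomial(support, config.duplex_fraction)) if support else 0
        records.append((pos, ref, alt, support, total, duplex))

    df = pd.DataFrame(
        records,
        columns=["position", "ref", "allele", "support", "total", "duplex_confirmed"],
    )
    return ConsensusPileup.from_frame(df)


def simulate_wbc_pileup(
    state: TruePatientState,
    error_truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
):
    """Buffy-coat (white-blood-cell) control pileup for one patient.

    Carries the patient's germline variants near 50% and clonal-hematopoiesis
    variants at their blood fractions, plus panel background errors — but no
    tumor-derived signal.
    """
    from .groom import ConsensusPileup

    vafs: dict[tuple[int, str, str], float] = {}
    # tumor variant sites are covered but carry no signal in blood cells
    for v in state.plasma_variants | state.tissue_variants:
        vafs[v] = 0.0
    vafs.update(state.germline_variants)
    vafs.update(state.chip_variants)
    cfg = SimulationConfig(**{**asdict_config(config), "consensus_depth_target": config.wbc_depth})
    return simulate_sample_pileup(None, "P0", error_truth, cfg, rng, extra_vafs=vafs)


def asdict_config(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["response_mix"] = dict(d["response_mix"])
    d["post_nact_factor"] = dict(d["post_nact_factor"])
    d["post_surgery_factor"] = dict(d["post_surgery_factor"])
    return d


# ---------------------------------------------------------------------------
# truth serialization
# ---------------------------------------------------------------------------

def states_to_frames(states: Iterable[TruePatientState]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(patients table, variant truth table) as flat TSV-ready frames."""
    pat_rows, var_rows = [], []
    for s in states:
        pat_rows.append(
            {
                "patient": s.patient_id,
                "response": s.response,
                "tf_P0": s.tumor_fraction_by_timepoint["P0"],
                "tf_P1": s.tumor_fraction_by_timepoint["P1"],
                "tf_P2": s.tumor_fraction_by_timepoint["P2"],
                "survival_months": s.survival_time,
                "event": int(s.event),
            }
        )
        cats = (
            [("tissue", v) for v in sorted(s.tissue_variants - s.plasma_variants)]
            + [("shared", v) for v in sorted(s.tissue_variants & s.plasma_variants)]
            + [("plasma", v) for v in sorted(s.plasma_variants - s.tissue_variants)]
            + [("chip", v) for v in sorted(s.chip_variants)]
            + [("germline", v) for v in sorted(s.germline_variants)]
        )
        for cat, (pos, ref, alt) in cats:
            var_rows.append(
                {
                    "patient": s.patient_id,
                    "category": cat,
                    "position": pos,
                    "ref": ref,
                    "alt": alt,
                    "rel_frac": s.plasma_variant_fracs.get((pos, ref, alt), float("nan")),
                }
            )
    return pd.DataFrame(pat_rows), pd.DataFrame(var_rows)


def write_read_table(df: pd.DataFrame, path) -> None:
    """Write a read-family table as deterministic (mtime-free) gzip TSV."""
    with open(path, "wb") as fh:
        with gzip.GzipFile(fileobj=fh, mode="wb", mtime=0) as gz:
            gz.write(df.to_csv(sep="\t", index=False).encode())


def read_read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"barcode1": str, "barcode2": str})
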