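"""End-to-end orchestration: simulate -> groom -> errordb -> call -> monitor
-> stats -> report, driven by a single YAML config with a mandatory seed.

Every stage reads its inputs from and writes its outputs to a run directory;
re-running with the same config and seed reproduces byte-identical outputs
(gzip members are written without timestamps). A manifest records the config
snapshot, per-stage output checksums, and warning counts.

Config schema (all sections optional except ``seed``)::

    seed: 1
    simulate:         # any SimulationConfig field
      n_patients: 12
      panel_positions: 300
    groom:
      duplex_only: false
      min_agreement: 0.8
    errordb:
      alpha: 0.01
    calls:
      min_vaf: 0.001
      wbc_max_af: 0.0025
      wbc_max_support: 1
    monitor:
      min_gene_freq: 0.10
    stats:
      km_grid_months: [12, 24, 36]
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import calls as calls_mod
from . import monitor as monitor_mod
from . import stats as stats_mod
from .errordb import BackgroundErrorDB, build_error_db
from .groom import ConsensusPileup, GroomPolicy, build_pileup, group_and_decode
from .simcohort import (
    SimulationConfig,
    asdict_config,
    read_read_table,
    simulate_cohort,
    simulate_error_truth,
    simulate_normal_pool,
    simulate_panel,
    simulate_reads,
    simulate_wbc_pileup,
    states_to_frames,
    write_read_table,
)

log = logging.getLogger(__name__)

STAGES = ["simulate", "groom", "errordb", "call", "monitor", "stats", "report"]


class StageDependencyError(RuntimeError):
    pass


class ConfigSchemaError(ValueError):
    pass


@dataclass
class RunManifest:
    seed: int
    config: dict
    outputs: dict[str, dict[str, str]] = field(default_factory=dict)  # stage -> {path: sha256}
    warnings: dict[str, int] = field(default_factory=dict)
    stages_run: list[str] = field(default_factory=list)

    def to_json(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "config": self.config,
                    "stages_run": self.stages_run,
                    "outputs": self.outputs,
                    "warnings": self.warnings,
                },
                fh,
                indent=2,
                sort_keys=True,
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


_KNOWN_SECTIONS = {"seed", "outdir", "simulate", "groom", "errordb", "calls", "monitor", "stats"}


def load_config(config: str | Path | Mapping) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(config)
    unknown = set(cfg) - _KNOWN_SECTIONS
    if unknown:
        raise ConfigSchemaError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in cfg:
        raise ConfigSchemaError("config must set 'seed' (no implicit randomness)")
    try:
        sim = SimulationConfig(**{**cfg.get("simulate", {}), "seed": int(cfg["seed"])})
    except TypeError as e:
        raise ConfigSchemaError(f"simulate section: {e}") from None
    cfg["_sim"] = sim
    return cfg


def _rng_for(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(STAGES.index(stage),))
    )


def _require(path: Path, stage: str, upstream: str) -> Path:
    if not path.exists():
        raise StageDependencyError(
            f"stage '{stage}' requires output {path.name} from stage '{upstream}'; "
            f"run '{upstream}' first"
        )
    return path


def run_pipeline(
    config: str | Path | Mapping,
    outdir: str | Path,
    stages: Sequence[str] | None = None,
) -> RunManifest:
    """Execute the requested stages (default: all) into ``outdir``."""
    cfg = load_config(config)
    sim_cfg: SimulationConfig = cfg["_sim"]
    seed = int(cfg["seed"])
    stages = list(stages or STAGES)
    for s in stages:
        if s not in STAGES:
            raise ConfigSchemaError(f"unknown stage {s!r}")
    stages = [s for s in STAGES if s in stages]

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    snapshot = {k: v for k, v in cfg.items() if not k.startswith("_")}
    snapshot["simulate"] = asdict_config(sim_cfg)
    manifest = RunManifest(seed=seed, config=snapshot)

    policy = GroomPolicy(**cfg.get("groom", {}))
    alpha = float(cfg.get("errordb", {}).get("alpha", 0.01))
    call_opts = cfg.get("calls", {})
    min_gene_freq = float(cfg.get("monitor", {}).get("min_gene_freq", 0.10))
    km_grid = [float(t) for t in cfg.get("stats", {}).get("km_grid_months", [12, 24, 36])]

    for stage in stages:
        runner = _STAGE_RUNNERS[stage]
        log.info("[%s] starting", stage)
        files, n_warn = runner(
            out,
            sim_cfg=sim_cfg,
            seed=seed,
            policy=policy,
            alpha=alpha,
            call_opts=call_opts,
            min_gene_freq=min_gene_freq,
            km_grid=km_grid,
        )
        manifest.outputs[stage] = {str(f.relative_to(out)): _sha256(f) for f in sorted(files)}
        manifest.warnings[stage] = n_warn
        manifest.stages_run.append(stage)
        log.info("[%s] wrote %d files", stage, len(files))

    manifest.to_json(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(out: Path, *, sim_cfg, seed, **_) -> tuple[list[Path], int]:
    rng = _rng_for(seed, "simulate")
    panel = simulate_panel(sim_cfg, rng)
    error_truth = simulate_error_truth(panel, sim_cfg, rng)
    states = simulate_cohort(sim_cfg, panel, rng)

    files = []
    (out / "truth").mkdir(exist_ok=True)
    (out / "reads").mkdir(exist_ok=True)
    (out / "normals").mkdir(exist_ok=True)
    (out / "wbc").mkdir(exist_ok=True)

    p = out / "truth" / "panel.tsv"
    panel.to_frame().to_csv(p, sep="\t", index=False)
    files.append(p)
    p = out / "truth" / "error_truth.tsv"
    error_truth.to_csv(p, sep="\t", index=False)
    files.append(p)
    patients, variants = states_to_frames(states)
    p = out / "truth" / "patients.tsv"
    patients.to_csv(p, sep="\t", index=False)
    files.append(p)
    p = out / "truth" / "variants.tsv"
    variants.to_csv(p, sep="\t", index=False)
    files.append(p)
    p = out / "truth" / "config.json"
    with open(p, "w") as fh:
        json.dump(asdict_config(sim_cfg), fh, indent=2, sort_keys=True)
    files.append(p)

    for s in states:
        for tp in ("P0", "P1", "P2"):
            df = simulate_reads(s, tp, error_truth, sim_cfg, rng, panel=panel)
            p = out / "reads" / f"{s.patient_id}_{tp}.tsv.gz"
            write_read_table(df, p)
            files.append(p)
        wbc = simulate_wbc_pileup(s, error_truth, sim_cfg, rng)
        p = out / "wbc" / f"{s.patient_id}.tsv"
        wbc.to_tsv(p)
        files.append(p)

    for i, df in enumerate(
        simulate_normal_pool(sim_cfg.n_donors, error_truth, sim_cfg, rng, panel=panel)
    ):
        p = out / "normals" / f"HD{i + 1:03d}.tsv.gz"
        write_read_table(df, p)
        files.append(p)
    return files, 0


def _ref_map(out: Path, stage: str) -> dict[int, str]:
    panel = pd.read_csv(_require(out / "truth" / "panel.tsv", stage, "simulate"), sep="\t")
    return dict(zip(panel["position"].astype(int), panel["ref"].astype(str)))


def _stage_groom(out: Path, *, policy, **_) -> tuple[list[Path], int]:
    ref_map = _ref_map(out, "groom")
    (out / "pileups").mkdir(exist_ok=True)
    (out / "normal_pileups").mkdir(exist_ok=True)
    files, n_warn = [], 0
    for sub, dest in (("reads", "pileups"), ("normals", "normal_pileups")):
        src = _require(out / sub, "groom", "simulate")
        for path in sorted(src.glob("*.tsv.gz")):
            mols, st = group_and_decode(read_read_table(path), policy)
            n_warn += st.n_rejected_records
            pu = build_pileup(mols, ref_map, policy)
            p = out / dest / (path.name.removesuffix(".tsv.gz") + ".tsv")
            pu.to_tsv(p)
            files.append(p)
    return files, n_warn


def _stage_errordb(out: Path, *, alpha, **_) -> tuple[list[Path], int]:
    src = _require(out / "normal_pileups", "errordb", "groom")
    pileups = [ConsensusPileup.from_tsv(p) for p in sorted(src.glob("*.tsv"))]
    db = build_error_db(pileups)
    p1, p2 = out / "errordb.tsv", out / "errordb.json"
    db.to_tsv(p1, metadata_path=p2, alpha=alpha)
    return [p1, p2], 0


def _stage_call(out: Path, *, alpha, call_opts, **_) -> tuple[list[Path], int]:
    db = BackgroundErrorDB.from_tsv(_require(out / "errordb.tsv", "call", "errordb"))
    variants = pd.read_csv(
        _require(out / "truth" / "variants.tsv", "call", "simulate"), sep="\t"
    )
    tissue_by_patient: dict[str, set] = {}
    for r in variants.itertuples():
        if r.category in ("tissue", "shared"):
            tissue_by_patient.setdefault(str(r.patient), set()).add(
                (int(r.position), str(r.ref), str(r.alt))
            )
    (out / "calls").mkdir(exist_ok=True)
    files, n_warn = [], 0
    src = _require(out / "pileups", "call", "groom")
    for path in sorted(src.glob("*.tsv")):
        stem = path.stem  # PT01_P0
        patient, tp = stem.rsplit("_", 1)
        pu = ConsensusPileup.from_tsv(path)
        wbc_path = out / "wbc" / f"{patient}.tsv"
        wbc = ConsensusPileup.from_tsv(wbc_path) if wbc_path.exists() else None
        vcalls = calls_mod.call_sample(
            pu,
            db,
            tissue_by_patient.get(patient, set()),
            wbc,
            min_vaf=float(call_opts.get("min_vaf", calls_mod.MIN_VAF)),
            alpha=alpha,
            patient_id=patient,
            timepoint=tp,
        )
        n_warn += sum("wbc_uncovered" in c.metadata for c in vcalls)
        p = out / "calls" / f"{stem}.tsv"
        calls_mod.calls_to_frame(vcalls).to_csv(p, sep="\t", index=False)
        files.append(p)
        p = out / "calls" / f"{stem}.vcf"
        calls_mod.write_vcf(vcalls, p)
        files.append(p)
    return files, n_warn


def _load_calls_by_sample(out: Path, stage: str) -> dict[tuple[str, str], list]:
    src = _require(out / "calls", stage, "call")
    by_sample = {}
    for path in sorted(src.glob("*.tsv")):
        patient, tp = path.stem.rsplit("_", 1)
        by_sample[(patient, tp)] = calls_mod.frame_to_calls(pd.read_csv(path, sep="\t"))
    return by_sample


def _stage_monitor(out: Path, *, min_gene_freq, **_) -> tuple[list[Path], int]:
    by_sample = _load_calls_by_sample(out, "monitor")
    panel = pd.read_csv(out / "truth" / "panel.tsv", sep="\t")
    gene_map = dict(zip(panel["position"].astype(int), panel["gene"].astype(str)))
    variants = pd.read_csv(out / "truth" / "variants.tsv", sep="\t")

    summaries = [
        monitor_mod.summarize_timepoint(calls_mod.passing(v), patient, tp)
        for (patient, tp), v in sorted(by_sample.items())
    ]
    files = []
    p = out / "trajectories.tsv"
    monitor_mod.summaries_to_frame(summaries).to_csv(p, sep="\t", index=False)
    files.append(p)

    # tissue/plasma concordance pooled over the cohort's baseline truth sets
    tissue_gas, plasma_gas = set(), set()
    for r in variants.itertuples():
        key = (str(r.patient), int(r.position), str(r.ref), str(r.alt))
        if r.category in ("tissue", "shared"):
            tissue_gas.add(key)
        if r.category in ("plasma", "shared"):
            plasma_gas.add(key)
    conc = monitor_mod.concordance_fractions(tissue_gas, plasma_gas)
    p = out / "concordance.json"
    with open(p, "w") as fh:
        json.dump(
            {
                "shared_fraction": conc.shared_fraction,
                "tissue_only_fraction": conc.tissue_only_fraction,
                "plasma_only_fraction": conc.plasma_only_fraction,
                "n_union": conc.n_union,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    files.append(p)

    cohort_calls = {}
    for (patient, tp), v in by_sample.items():
        if tp == "P0":
            cohort_calls[patient] = calls_mod.passing(v)
    gf = monitor_mod.gene_frequency_table(cohort_calls, gene_map, min_gene_freq)
    p = out / "gene_frequency.tsv"
    gf.to_csv(p, sep="\t", index=False)
    files.append(p)
    return files, 0


def _stage_stats(out: Path, *, km_grid, **_) -> tuple[list[Path], int]:
    traj = pd.read_csv(_require(out / "trajectories.tsv", "stats", "monitor"), sep="\t")
    patients = pd.read_csv(
        _require(out / "truth" / "patients.tsv", "stats", "simulate"), sep="\t"
    )
    summaries = monitor_mod.frame_to_summaries(traj)
    by_pt = {(s.patient_id, s.timepoint): s for s in summaries}
    response = dict(zip(patients["patient"], patients["response"]))

    deltas_vaf: dict[str, list[float]] = {}
    deltas_gas: dict[str, list[float]] = {}
    p0_vaf, p1_vaf, p0_gas, p1_gas = [], [], [], []
    status_p1: dict[str, str] = {}
    for pid in patients["patient"]:
        s0, s1 = by_pt.get((pid, "P0")), by_pt.get((pid, "P1"))
        if s0 is None or s1 is None:
            continue
        dv, dg = monitor_mod.delta_metrics(s0, s1)
        deltas_vaf.setdefault(response[pid], []).append(dv)
        deltas_gas.setdefault(response[pid], []).append(dg)
        p0_vaf.append(s0.max_vaf)
        p1_vaf.append(s1.max_vaf)
        p0_gas.append(s0.n_gas)
        p1_gas.append(s1.n_gas)
        status_p1[pid] = s1.status

    results: dict[str, dict] = {}

    def record(name: str, tr: stats_mod.TestResult) -> None:
        results[name] = {
            "method": tr.method,
            "statistic": None if np.isnan(tr.statistic) else tr.statistic,
            "p_value": tr.p_value,
            "exact": tr.exact,
        }

    diffs_vaf = np.array(p1_vaf) - np.array(p0_vaf)
    diffs_gas = np.array(p1_gas) - np.array(p0_gas)
    if np.any(diffs_vaf != 0):
        record("max_vaf_p1_vs_p0_signed_rank", stats_mod.wilcoxon_signed_rank(diffs_vaf))
    if np.any(diffs_gas != 0):
        record("n_gas_p1_vs_p0_signed_rank", stats_mod.wilcoxon_signed_rank(diffs_gas))
    for a, b in (("PD", "SD"), ("PD", "PR"), ("SD", "PR")):
        if len(deltas_vaf.get(a, [])) and len(deltas_vaf.get(b, [])):
            record(
                f"delta_max_vaf_{a}_vs_{b}_rank_sum",
                stats_mod.wilcoxon_rank_sum(deltas_vaf[a], deltas_vaf[b]),
            )
            record(
                f"delta_n_gas_{a}_vs_{b}_rank_sum",
                stats_mod.wilcoxon_rank_sum(deltas_gas[a], deltas_gas[b]),
            )

    # survival by post-chemotherapy ctDNA status
    files = []
    km_values: dict[str, dict[str, float]] = {}
    groups: dict[str, list[stats_mod.SurvivalRecord]] = {"negative": [], "positive": []}
    for r in patients.itertuples():
        st = status_p1.get(str(r.patient))
        if st is None:
            continue
        groups[st].append(
            stats_mod.SurvivalRecord(
                str(r.patient), float(r.survival_months), bool(r.event), st
            )
        )
    (out / "km").mkdir(exist_ok=True)
    for label, recs in groups.items():
        if not recs:
            continue
        km = stats_mod.km_estimate(recs, group=label)
        km_values[label] = {str(int(t)): km.survival_at(t) for t in km_grid}
        p = out / "km" / f"p1_{label}.tsv"
        km.to_frame().to_csv(p, sep="\t", index=False)
        files.append(p)
    if all(groups.values()) and any(r.event for g in groups.values() for r in g):
        record("os_by_p1_status_gbw", stats_mod.gbw_test(groups))

    p = out / "tests.json"
    with open(p, "w") as fh:
        json.dump({"tests": results, "km_at_months": km_values}, fh, indent=2, sort_keys=True)
    files.append(p)
    return files, 0


def _stage_report(out: Path, **_) -> tuple[list[Path], int]:
    traj = pd.read_csv(_require(out / "trajectories.tsv", "report", "monitor"), sep="\t")
    patients = pd.read_csv(out / "truth" / "patients.tsv", sep="\t")
    with open(_require(out / "tests.json", "report", "stats")) as fh:
        tests = json.load(fh)
    with open(out / "concordance.json") as fh:
        concordance = json.load(fh)

    summaries = monitor_mod.frame_to_summaries(traj)
    by_pt = {(s.patient_id, s.timepoint): s for s in summaries}
    response = dict(zip(patients["patient"], patients["response"]))

    detection = {}
    for tp in ("P0", "P1", "P2"):
        subset = [s for s in summaries if s.timepoint == tp]
        if subset:
            d = monitor_mod.cohort_detection(subset, tp)
            detection[tp] = {
                "n_positive": d.n_positive,
                "n_total": d.n_total,
                "rate_pct": d.rate_pct,
            }

    clearance: dict[str, dict[str, int]] = {}
    for resp in ("PR", "SD", "PD"):
        clearance[resp] = {c.value: 0 for c in monitor_mod.ClearanceClass}
    for pid, resp in response.items():
        s0, s1 = by_pt.get((pid, "P0")), by_pt.get((pid, "P1"))
        if s0 is None or s1 is None:
            continue
        cls = monitor_mod.clearance_class(s0, s1)
        clearance[resp][cls.value] += 1

    report = {
        "detection_rates": detection,
        "clearance_by_response": clearance,
        "concordance": concordance,
        "tests": tests["tests"],
        "km_at_months": tests["km_at_months"],
    }
    p1 = out / "report.json"
    with open(p1, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)

    lines = ["ctDNA monitoring summary", "=" * 40, ""]
    for tp, d in detection.items():
        lines.append(
            f"detection {tp}: {d['n_positive']}/{d['n_total']} = {d['rate_pct']:.1f}%"
        )
    lines.append("")
    lines.append("clearance (P0 -> P1) by response class:")
    for resp, counts in clearance.items():
        lines.append(f"  {resp}: " + ", ".join(f"{k}={v}" for k, v in counts.items()))
    lines.append("")
    for label, vals in tests["km_at_months"].items():
        pretty = ", ".join(f"S({m} mo)={v:.2f}" for m, v in sorted(vals.items(), key=lambda kv: float(kv[0])))
        lines.append(f"KM P1-{label}: {pretty}")
    for name, tr in tests["tests"].items():
        lines.append(f"{name}: p={tr['p_value']:.4g} ({tr['method']})")
    p2 = out / "report.txt"
    p2.write_text("\n".join(lines) + "\n")
    return [p1, p2], 0


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "groom": _stage_groom,
    "errordb": _stage_errordb,
    "call": _stage_call,
    "monitor": _stage_monitor,
    "stats": _stage_stats,
    "report": _stage_report,
}
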