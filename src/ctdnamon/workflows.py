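"""High-level analysis workflows at consensus-molecule resolution.

These run the same calling chain as the file-based pipeline but keep
everything in memory and draw consensus pileups directly (binomial fast
path), which makes cohort-sized runs and replicate studies cheap. The
read-level path (simulate_reads -> groom) models the identical consensus
counts and is exercised separately at molecule resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import calls as calls_mod
from . import monitor as monitor_mod
from . import stats as stats_mod
from .errordb import BackgroundErrorDB, build_error_db
from .simcohort import (
    Panel,
    SimulationConfig,
    TruePatientState,
    simulate_cohort,
    simulate_error_truth,
    simulate_panel,
    simulate_sample_pileup,
    simulate_wbc_pileup,
)

PLASMA_TIMEPOINTS = ("P0", "P1", "P2")


@dataclass
class CohortResult:
    config: SimulationConfig
    states: list[TruePatientState]
    panel: Panel
    db: BackgroundErrorDB
    summaries: list[monitor_mod.TimepointSummary]
    calls_by_sample: dict[tuple[str, str], list] = field(default_factory=dict)

    def summary(self, patient_id: str, timepoint: str) -> monitor_mod.TimepointSummary:
        return next(
            s
            for s in self.summaries
            if s.patient_id == patient_id and s.timepoint == timepoint
        )

    def detection(self, timepoint: str) -> monitor_mod.DetectionRate:
        return monitor_mod.cohort_detection(self.summaries, timepoint)

    def survival_groups(
        self, timepoint: str = "P1"
    ) -> dict[str, list[stats_mod.SurvivalRecord]]:
        groups: dict[str, list[stats_mod.SurvivalRecord]] = {
            "negative": [],
            "positive": [],
        }
        for s in self.states:
            status = self.summary(s.patient_id, timepoint).status
            groups[status].append(
                stats_mod.SurvivalRecord(
                    s.patient_id, s.survival_time, s.event, status
                )
            )
        return groups


def build_normal_db(
    error_truth,
    config: SimulationConfig,
    rng: np.random.Generator,
    n_donors: int | None = None,
) -> BackgroundErrorDB:
    """Panel-of-normals database from consensus-level donor pileups."""
    n = n_donors if n_donors is not None else config.n_donors
    pileups = [
        simulate_sample_pileup(None, "P0", error_truth, config, rng)
        for _ in range(n)
    ]
    return build_error_db(pileups)


def analyze_cohort(
    config: SimulationConfig,
    seed: int | None = None,
    timepoints: tuple[str, ...] = PLASMA_TIMEPOINTS,
    alpha: float = 0.01,
) -> CohortResult:
    """Simulate a cohort and run the full calling + monitoring chain."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    panel = simulate_panel(config, rng)
    error_truth = simulate_error_truth(panel, config, rng)
    states = simulate_cohort(config, panel, rng)
    db = build_normal_db(error_truth, config, rng)

    summaries: list[monitor_mod.TimepointSummary] = []
    calls_by_sample: dict[tuple[str, str], list] = {}
    for s in states:
        wbc = simulate_wbc_pileup(s, error_truth, config, rng)
        for tp in timepoints:
            pu = simulate_sample_pileup(s, tp, error_truth, config, rng)
            vcalls = calls_mod.call_sample(
                pu,
                db,
                s.tissue_variants,
                wbc,
                alpha=alpha,
                patient_id=s.patient_id,
                timepoint=tp,
            )
            calls_by_sample[(s.patient_id, tp)] = vcalls
            summaries.append(
                monitor_mod.summarize_timepoint(
                    calls_mod.passing(vcalls), s.patient_id, tp
                )
            )
    return CohortResult(
        config=config,
        states=states,
        panel=panel,
        db=db,
        summaries=summaries,
        calls_by_sample=calls_by_sample,
    )
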