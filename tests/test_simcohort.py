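"""Generator truth: determinism, trajectory direction, overlap structure,
read-emission statistics, and the survival model's hazard contrast."""

import numpy as np
import pandas as pd
import pytest

from ctdnamon.simcohort import (
    ConfigError,
    SimulationConfig,
    simulate_cohort,
    simulate_error_truth,
    simulate_normal_pool,
    simulate_panel,
    simulate_reads,
    simulate_sample_pileup,
    simulate_variant_truth,
    states_to_frames,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, fieldname",
        [
            ({"response_mix": {"PR": 0.7, "SD": 0.2, "PD": 0.2}}, "response_mix"),
            ({"shared_fraction": 0.9}, "shared_fraction"),
            ({"n_patients": 0}, "n_patients"),
            ({"censoring_rate": 1.4}, "censoring_rate"),
            ({"hazard_ratio_ctdna_pos": -1.0}, "hazard_ratio_ctdna_pos"),
        ],
    )
    def test_invalid_config_names_field(self, kwargs, fieldname):
        with pytest.raises(ConfigError, match=fieldname):
            SimulationConfig(**kwargs)

    def test_paper_rounded_overlap_fractions_accepted(self):
        # 0.338 + 0.562 + 0.095 = 0.995; renormalized internally
        cfg = SimulationConfig()
        f = cfg.overlap_fractions()
        assert abs(sum(f) - 1.0) < 1e-12
        assert f[0] == pytest.approx(0.338 / 0.995)


class TestDeterminism:
    def test_cohort_truth_identical_across_runs(self, small_config):
        frames1 = states_to_frames(simulate_cohort(small_config))
        frames2 = states_to_frames(simulate_cohort(small_config))
        for a, b in zip(frames1, frames2):
            pd.testing.assert_frame_equal(a, b)

    def test_read_tables_identical_across_runs(self, small_config, panel, error_truth):
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(small_config.seed)
            state = simulate_cohort(small_config, panel, rng)[0]
            outs.append(
                simulate_reads(state, "P0", error_truth, small_config, rng, panel=panel)
            )
        pd.testing.assert_frame_equal(outs[0], outs[1])

    def test_normal_pool_reproducible(self, small_config, error_truth):
        pools = [
            simulate_normal_pool(
                3, error_truth, small_config, np.random.default_rng(5)
            )
            for _ in range(2)
        ]
        for a, b in zip(*pools):
            pd.testing.assert_frame_equal(a, b)


class TestTrajectories:
    def test_pr_only_cohort_declines(self):
        cfg = SimulationConfig(
            n_patients=200,
            response_mix={"PR": 1.0, "SD": 0.0, "PD": 0.0},
            panel_positions=5000,
            seed=3,
        )
        states = simulate_cohort(cfg)
        tf0 = np.array([s.tumor_fraction_by_timepoint["P0"] for s in states])
        tf1 = np.array([s.tumor_fraction_by_timepoint["P1"] for s in states])
        # forced per patient by construction, not just in expectation
        assert (tf1 < tf0).all()

    def test_pd_only_cohort_rises(self):
        cfg = SimulationConfig(
            n_patients=100,
            response_mix={"PR": 0.0, "SD": 0.0, "PD": 1.0},
            panel_positions=5000,
            seed=3,
        )
        states = simulate_cohort(cfg)
        assert all(
            s.tumor_fraction_by_timepoint["P1"] > s.tumor_fraction_by_timepoint["P0"]
            for s in states
        )


class TestVariantTruth:
    def test_shared_fraction_one_gives_equal_sets(self, panel, rng):
        cfg = SimulationConfig(
            shared_fraction=1.0, tissue_only_fraction=0.0, plasma_only_fraction=0.0
        )
        tissue, plasma = simulate_variant_truth(20, panel, cfg, rng)
        assert tissue == plasma and len(tissue) == 20

    def test_zero_variants_gives_empty_sets(self, panel, small_config, rng):
        tissue, plasma = simulate_variant_truth(0, panel, small_config, rng)
        assert tissue == set() and plasma == set()

    def test_no_duplicate_variants(self, panel, small_config, rng):
        tissue, plasma = simulate_variant_truth(50, panel, small_config, rng)
        union = tissue | plasma
        positions = [p for p, _, _ in union]
        assert len(positions) == len(set(positions))

    def test_category_fractions_converge(self, rng):
        # pooled draw of 10,000 variants recovers configured fractions +-0.02
        cfg = SimulationConfig(panel_positions=200_000)
        panel = simulate_panel(cfg, rng)
        shared = t_only = p_only = 0
        for _ in range(100):
            tissue, plasma = simulate_variant_truth(100, panel, cfg, rng)
            shared += len(tissue & plasma)
            t_only += len(tissue - plasma)
            p_only += len(plasma - tissue)
        n = shared + t_only + p_only
        assert n == 10_000
        want = cfg.overlap_fractions()
        assert shared / n == pytest.approx(want[0], abs=0.02)
        assert t_only / n == pytest.approx(want[1], abs=0.02)
        assert p_only / n == pytest.approx(want[2], abs=0.02)


class TestReadEmission:
    def test_no_signal_no_errors_gives_all_reference(self, rng):
        cfg = SimulationConfig(consensus_depth_target=400, artifact_rate=0.0)
        empty_errors = pd.DataFrame(columns=["position", "ref", "alt", "rate"])
        df = simulate_reads(
            None,
            "P0",
            empty_errors,
            cfg,
            rng,
            positions=[1, 2, 3],
            extra_vafs={(1, "A", "T"): 0.0, (2, "C", "G"): 0.0, (3, "G", "A"): 0.0},
        )
        refs = {1: "A", 2: "C", 3: "G"}
        assert all(a == refs[p] for p, a in zip(df["position"], df["allele"]))

    def test_unknown_timepoint_rejected(self, small_config, error_truth, panel, rng):
        state = simulate_cohort(small_config, panel, rng)[0]
        with pytest.raises(ValueError, match="timepoint"):
            simulate_reads(state, "P9", error_truth, small_config, rng)

    def test_spiked_vaf_recovered_binomially(self, rng):
        # 500 replicates at VAF 0.5%: mean supporting molecules ~ depth*vaf
        cfg = SimulationConfig(
            consensus_depth_target=5000, artifact_rate=0.0, seed=0
        )
        empty_errors = pd.DataFrame(columns=["position", "ref", "alt", "rate"])
        vaf, depth, reps = 0.005, 5000, 500
        supports = []
        for _ in range(reps):
            df = simulate_reads(
                None,
                "P0",
                empty_errors,
                cfg,
                rng,
                positions=[10],
                extra_vafs={(10, "A", "T"): vaf},
            )
            key = df["barcode1"].where(
                df["barcode1"] < df["barcode2"], df["barcode2"]
            )
            per_molecule = df.assign(mol=key).drop_duplicates(subset=["mol"])
            supports.append((per_molecule["allele"] == "T").sum())
        mean = np.mean(supports)
        se = np.sqrt(depth * vaf * (1 - vaf) / reps)
        assert abs(mean - depth * vaf) < 3 * se

    def test_zero_artifact_rate_gives_concordant_duplexes(self, small_config, rng):
        cfg = SimulationConfig(
            **{
                **{f: getattr(small_config, f) for f in ("n_patients", "panel_positions")},
                "artifact_rate": 0.0,
                "consensus_depth_target": 2000,
                "seed": 2,
            }
        )
        df = simulate_reads(
            None, "P0", pd.DataFrame(columns=["position", "ref", "alt", "rate"]),
            cfg, rng, positions=[1], extra_vafs={(1, "A", "T"): 0.01},
        )
        key = df["barcode1"].where(df["barcode1"] < df["barcode2"], df["barcode2"])
        n_alleles = df.groupby(key)["allele"].nunique()
        assert (n_alleles == 1).all()


class TestNormalPool:
    def test_donor_count_and_no_somatic_truth(self, small_config, error_truth, rng):
        pool = simulate_normal_pool(30, error_truth, small_config, rng)
        assert len(pool) == 30
        # only background-error alleles can appear; check rate is tiny
        for df in pool[:3]:
            refs = dict(zip(error_truth["position"], error_truth["ref"]))
            on_err = df[df["position"].isin(refs)]
            frac_nonref = (
                on_err["allele"] != on_err["position"].map(refs)
            ).mean()
            assert frac_nonref < 0.05

    def test_zero_error_truth_gives_reference_pool(self, rng):
        cfg = SimulationConfig(consensus_depth_target=400, artifact_rate=0.0)
        et = pd.DataFrame({"position": [5], "ref": ["A"], "alt": ["T"], "rate": [0.0]})
        pool = simulate_normal_pool(2, et, cfg, rng)
        for df in pool:
            assert (df["allele"] == "A").all()

    def test_invalid_donor_count(self, small_config, error_truth, rng):
        with pytest.raises(ConfigError):
            simulate_normal_pool(0, error_truth, small_config, rng)


class TestSurvivalStructure:
    def test_detectable_stratum_has_shorter_median_survival(self):
        # direct comparison of simulated medians, no model fitting
        cfg = SimulationConfig(
            n_patients=2000,
            panel_positions=50_000,
            hazard_ratio_ctdna_pos=3.0,
            censoring_rate=0.0,
            followup_max_months=10_000.0,
            seed=4,
        )
        states = simulate_cohort(cfg)
        det = np.array(
            [
                s.tumor_fraction_by_timepoint["P1"] >= cfg.detectability_vaf
                for s in states
            ]
        )
        times = np.array([s.survival_time for s in states])
        assert 100 < det.sum() < 1900  # both strata populated
        assert np.median(times[det]) < np.median(times[~det])

    def test_survival_times_positive(self, small_config):
        assert all(s.survival_time > 0 for s in simulate_cohort(small_config))


class TestFastPath:
    def test_consensus_pileup_matches_binomial_scale(self, rng):
        cfg = SimulationConfig(consensus_depth_target=5000)
        et = pd.DataFrame(columns=["position", "ref", "alt", "rate"])
        supports = []
        for _ in range(300):
            pu = simulate_sample_pileup(
                None, "P0", et, cfg, rng, extra_vafs={(1, "A", "T"): 0.005}
            )
            supports.append(int(pu.frame["support"].iloc[0]))
        mean = np.mean(supports)
        se = np.sqrt(5000 * 0.005 * 0.995 / 300)
        assert abs(mean - 25.0) < 3 * se
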