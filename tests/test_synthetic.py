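"""Generator fidelity: determinism, covariance structure, planted effects."""

import numpy as np
import pytest

from netbgc.connectivity import bgc_profile, fc_matrix
from netbgc.preprocess import framewise_displacement
from netbgc.stats import correlation_test
from netbgc.symptoms import boxcox_normalize, score_cesd
from netbgc.synthetic import (
    ItemModel,
    SimulationConfig,
    make_partition,
    quick_bgc_cohort,
    repair_positive_definite,
    simulate_cesd_items,
    simulate_cohort,
    simulate_motion,
    simulate_subject_timeseries,
)


class TestMakePartition:
    def test_two_by_two(self):
        part = make_partition([2, 2], ["A", "B"])
        assert part.n_total == 4
        assert part.network_of == ("A", "A", "B", "B")

    def test_default_geometry_is_360_regions_12_networks(self):
        cfg = SimulationConfig()
        part = make_partition(cfg.network_sizes, cfg.network_names)
        assert part.n_total == 360
        assert len(part.networks) == 12

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            make_partition([3], ["A", "B"])

    def test_duplicate_names(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_partition([2, 2], ["A", "A"])

    def test_empty_network(self):
        with pytest.raises(ValueError, match="empty"):
            make_partition([2, 0], ["A", "B"])


class TestTimeseries:
    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig.scaled_down()
        part = make_partition(cfg.network_sizes, cfg.network_names)
        a, na = simulate_subject_timeseries(part, 0.05, cfg, 123)
        b, nb = simulate_subject_timeseries(part, 0.05, cfg, 123)
        assert np.array_equal(a.data, b.data)
        assert na.equals(nb)

    def test_block_correlation_fidelity(self):
        # empirical block means converge to the targets at 5,000 frames
        cfg = SimulationConfig.scaled_down(
            network_sizes=(5, 5, 5, 5), n_frames=5000, global_amp=0.0
        )
        part = make_partition(cfg.network_sizes, cfg.network_names)
        ts, _ = simulate_subject_timeseries(part, cfg.between_corr_base, cfg, 77)
        fc = fc_matrix(ts.data, ts.region_ids)
        w = fc.values
        within_vals, between_vals = [], []
        for i in range(20):
            for j in range(i + 1, 20):
                (within_vals if i // 5 == j // 5 else between_vals).append(w[i, j])
        assert np.mean(within_vals) == pytest.approx(0.3, abs=0.02)
        assert np.mean(between_vals) == pytest.approx(0.05, abs=0.02)

    def test_zero_coupling_independence(self):
        cfg = SimulationConfig.scaled_down(
            network_sizes=(5, 5, 5, 5),
            n_frames=5000,
            global_amp=0.0,
            between_corr_base=0.0,
        )
        part = make_partition(cfg.network_sizes, cfg.network_names)
        ts, _ = simulate_subject_timeseries(part, 0.0, cfg, 78)
        fc = fc_matrix(ts.data, ts.region_ids)
        between = [
            fc.values[i, j]
            for i in range(20)
            for j in range(i + 1, 20)
            if i // 5 != j // 5
        ]
        assert abs(np.mean(between)) < 0.02

    def test_infeasible_coupling_rejected(self):
        cfg = SimulationConfig.scaled_down()
        part = make_partition(cfg.network_sizes, cfg.network_names)
        with pytest.raises(ValueError):
            simulate_subject_timeseries(part, 0.999, cfg, 1)


class TestRepairPD:
    def test_pd_input_untouched(self):
        s = np.eye(3) * 1.0
        s[0, 1] = s[1, 0] = 0.2
        assert np.array_equal(repair_positive_definite(s), s)

    def test_small_repair_bounded(self):
        # slightly indefinite matrix gets nudged back, entries barely move
        s = np.full((6, 6), 0.9)
        np.fill_diagonal(s, 1.0)
        s[0, 1] = s[1, 0] = 0.88
        fixed = repair_positive_definite(s)
        ev = np.linalg.eigvalsh(fixed)
        assert ev.min() > 0
        assert np.abs(fixed - s).max() <= 0.05

    def test_large_repair_errors(self):
        s = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValueError, match="repair"):
            repair_positive_definite(s)


class TestMotion:
    def test_no_spikes_stays_below_threshold(self):
        cfg = SimulationConfig.scaled_down(motion_spike_rate=0.0)
        motion, spikes = simulate_motion(cfg, 5)
        assert spikes == ()
        assert framewise_displacement(motion).max() < 0.3

    def test_designed_spikes_exceed_threshold(self):
        cfg = SimulationConfig.scaled_down(motion_spike_rate=0.02)
        motion, spikes = simulate_motion(cfg, 6)
        assert len(spikes) > 0
        fd = framewise_displacement(motion)
        for f in spikes:
            assert fd[f] > 0.3

    def test_same_seed_identical(self):
        cfg = SimulationConfig.scaled_down()
        a, sa = simulate_motion(cfg, 9)
        b, sb = simulate_motion(cfg, 9)
        assert np.array_equal(a, b)
        assert sa == sb


class TestCesdItems:
    def test_responses_in_range(self):
        for seed in range(20):
            items = simulate_cesd_items(0.7, ItemModel(), seed)
            assert items.shape == (20,)
            assert np.all((items >= 0) & (items <= 3))

    def test_floor_severity_scores_near_zero(self):
        totals = [
            score_cesd(simulate_cesd_items(-3.0, ItemModel(), s)).total
            for s in range(2000)
        ]
        assert np.mean(totals) < 1.0

    def test_high_severity_scores_in_upper_third(self):
        totals = [
            score_cesd(simulate_cesd_items(3.0, ItemModel(), s)).total
            for s in range(2000)
        ]
        assert np.mean(totals) > 40.0

    def test_expected_total_monotone_in_severity(self):
        means = []
        for sev in (-1.5, 0.0, 1.5):
            totals = [
                score_cesd(simulate_cesd_items(sev, ItemModel(), s)).total
                for s in range(1000)
            ]
            means.append(np.mean(totals))
        assert means[0] < means[1] < means[2]


class TestCohort:
    def test_determinism(self):
        cfg = SimulationConfig.scaled_down(n_subjects=5, seed=21)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        assert np.array_equal(a.severity, b.severity)
        assert np.array_equal(
            a.subjects[2].timeseries.data, b.subjects[2].timeseries.data
        )
        assert a.metadata.equals(b.metadata)

    def test_invariants(self):
        cfg = SimulationConfig.scaled_down(n_subjects=16, seed=22)
        cohort = simulate_cohort(cfg)
        assert cohort.severity.mean() == pytest.approx(0.0, abs=1e-12)
        assert cohort.severity.std() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.abs(cohort.couplings) < 1)
        items = cohort.metadata[[f"cesd_{i:02d}" for i in range(1, 21)]]
        assert items.isin([0, 1, 2, 3]).all().all()
        genders = cohort.metadata["gender"].value_counts()
        assert abs(genders.get("F", 0) - genders.get("M", 0)) <= 1
        assert cohort.metadata["age"].between(18, 35).all()

    def test_null_effect_association_small(self):
        # planted-null cohort: recovered effect-network correlation near 0
        cfg = SimulationConfig.scaled_down(
            n_subjects=200, effect_beta=0.0, seed=23
        )
        bgc, totals = quick_bgc_cohort(cfg)
        sym = boxcox_normalize(totals).transformed
        res = correlation_test(bgc.loc[cfg.effect_network].to_numpy(), sym)
        assert abs(res.estimate) <= 0.15

    def test_effect_monotonicity(self):
        # a stronger planted slope yields a stronger recovered correlation
        recovered = []
        for beta in (0.0, -0.004, -0.02):
            cfg = SimulationConfig.scaled_down(
                n_subjects=300, effect_beta=beta, seed=24
            )
            bgc, totals = quick_bgc_cohort(cfg)
            sym = boxcox_normalize(totals).transformed
            res = correlation_test(bgc.loc[cfg.effect_network].to_numpy(), sym)
            recovered.append(abs(res.estimate))
        assert recovered[0] < recovered[1] < recovered[2]
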