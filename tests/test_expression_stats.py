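"""MESF calibration, alignment, mixture fitting, blocks and shrinkage MI."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import repfid as rf


def make_sample(nanog, reporter=None, day=0):
    nanog = np.asarray(nanog, dtype=float)
    reporter = nanog if reporter is None else np.asarray(reporter, dtype=float)
    df = pd.DataFrame(
        {
            "cell_id": np.arange(nanog.size),
            "nanog": nanog,
            "reporter": reporter,
            "condition": "test",
            "day": day,
            "replicate": 0,
        }
    )
    return rf.ExpressionSample(data=df)


class TestMesfCalibration:
    def test_two_point_exact_fit_interpolates_beads(self):
        beads = rf.BeadSet(intensity=[100.0, 10000.0], mesf=[1000.0, 100000.0])
        sample = make_sample([100.0, 10000.0])
        calibrated, _ = rf.mesf_calibrate(beads, sample, "nanog")
        assert calibrated.units == "MESF"
        assert calibrated.data["nanog"].to_numpy() == pytest.approx([1000.0, 100000.0])

    def test_round_trip_recovers_known_gain(self):
        beads = rf.generate_beads([1e3, 1e4, 1e5, 1e6], gain=3.5, noise_sd=0.0, seed=0)
        sample = make_sample(beads.intensity)
        _, cal = rf.mesf_calibrate(beads, sample, "nanog")
        assert cal.slope == pytest.approx(1.0, abs=1e-6)
        assert cal.intercept == pytest.approx(-math.log10(3.5), abs=1e-6)

    def test_noisy_beads_recover_slope_within_three_sd(self):
        levels = np.array([1e3, 1e4, 1e5, 1e6])
        noise_sd = 0.05
        beads = rf.generate_beads(levels, gain=2.0, noise_sd=noise_sd, seed=1)
        _, cal = rf.mesf_calibrate(beads, make_sample(beads.intensity), "nanog")
        # least-squares slope SE for the 4-point log-log design
        x = np.log10(beads.intensity)
        se = (noise_sd / math.log(10)) / math.sqrt(np.sum((x - x.mean()) ** 2))
        assert abs(cal.slope - 1.0) < 3 * se

    def test_calibration_and_inverse_are_identity_on_beads(self):
        beads = rf.generate_beads([1e3, 1e4, 1e5], gain=2.0, noise_sd=0.02, seed=2)
        _, cal = rf.mesf_calibrate(beads, make_sample(beads.intensity), "nanog")
        back = cal.invert(cal.apply(beads.intensity))
        assert back == pytest.approx(beads.intensity, rel=1e-9)

    def test_decreasing_beads_rejected(self):
        with pytest.raises(rf.CalibrationError):
            rf.BeadSet(intensity=[100.0, 10.0], mesf=[10.0, 100.0])

    def test_single_level_rejected(self):
        with pytest.raises(rf.CalibrationError):
            rf.BeadSet(intensity=[100.0], mesf=[10.0])


class TestAlignment:
    def _two_day_sample(self, rng, shift=0.0):
        base = np.exp(rng.normal(5.0, 0.6, 400))
        df = pd.concat(
            [
                make_sample(base, day=0).data,
                make_sample(base * np.exp(shift), day=1).data,
            ],
            ignore_index=True,
        )
        return rf.ExpressionSample(data=df)

    def test_identical_days_need_no_shift(self, rng):
        sample = self._two_day_sample(rng, shift=0.0)
        _, shifts = rf.align_first_percentile(sample)
        assert shifts[("nanog", 1)] == pytest.approx(0.0, abs=1e-12)

    def test_known_shift_recovered_and_shape_preserved(self, rng):
        sample = self._two_day_sample(rng, shift=0.7)
        aligned, shifts = rf.align_first_percentile(sample)
        assert shifts[("nanog", 1)] == pytest.approx(-0.7, abs=1e-9)
        d0 = np.log(aligned.data.loc[aligned.data.day == 0, "nanog"])
        d1 = np.log(aligned.data.loc[aligned.data.day == 1, "nanog"])
        q = [10, 25, 50, 75, 90]
        assert np.percentile(d1, q) - np.percentile(d0, q) == pytest.approx(
            np.zeros(5), abs=1e-9
        )

    def test_idempotence(self, rng):
        sample = self._two_day_sample(rng, shift=0.4)
        once, _ = rf.align_first_percentile(sample)
        twice, shifts2 = rf.align_first_percentile(once)
        assert np.allclose(once.data["nanog"], twice.data["nanog"])
        assert all(abs(s) < 1e-12 for s in shifts2.values())


class TestGmm:
    def test_two_component_parameter_recovery(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 2500), rng.normal(4, 1, 2500)])
        fit = rf.fit_gmm(vals, k=2, seed=0)
        assert fit.weights[0] == pytest.approx(0.5, abs=0.03)
        assert fit.means[0] == pytest.approx(0.0, abs=0.1)
        assert fit.means[1] == pytest.approx(4.0, abs=0.1)

    def test_single_component_is_moment_matching(self, rng):
        vals = rng.normal(2.0, 0.5, 3000)
        fit = rf.fit_gmm(vals, k=1, seed=0)
        assert fit.means[0] == pytest.approx(np.mean(vals), abs=1e-6)
        assert fit.sds[0] == pytest.approx(np.std(vals), rel=1e-3)

    def test_same_seed_same_fit(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 500), rng.normal(3, 1, 500)])
        f1 = rf.fit_gmm(vals, k=2, seed=7)
        f2 = rf.fit_gmm(vals, k=2, seed=7)
        assert f1 == f2

    def test_degenerate_data_rejected(self):
        with pytest.raises(rf.DegenerateDataError):
            rf.fit_gmm(np.ones(100), k=1)

    def test_bic_selects_two_components_for_separated_mixture(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 2500), rng.normal(4, 1, 2500)])
        chosen = rf.select_model_bic(rf.fit_gmm(vals, 1, 0), rf.fit_gmm(vals, 2, 0))
        assert chosen.n_components == 2

    def test_bic_selects_one_component_for_plain_normal(self, rng):
        vals = rng.normal(0, 1, 5000)
        chosen = rf.select_model_bic(rf.fit_gmm(vals, 1, 0), rf.fit_gmm(vals, 2, 0))
        assert chosen.n_components == 1

    def test_bic_tie_prefers_one_component(self):
        f1 = rf.GmmFit(1, (1.0,), (0.0,), (1.0,), -10.0, 100.0, 1000)
        f2 = rf.GmmFit(2, (0.5, 0.5), (0.0, 1.0), (1.0, 1.0), -8.0, 100.0, 1000)
        assert rf.select_model_bic(f1, f2).n_components == 1

    def test_mismatched_sample_sizes_rejected(self):
        f1 = rf.GmmFit(1, (1.0,), (0.0,), (1.0,), -10.0, 100.0, 1000)
        f2 = rf.GmmFit(2, (0.5, 0.5), (0.0, 1.0), (1.0, 1.0), -8.0, 90.0, 999)
        with pytest.raises(rf.DomainError):
            rf.select_model_bic(f1, f2)


class TestBimodalityFilter:
    def test_minor_component_weight_rejected(self):
        fit = rf.GmmFit(2, (0.95, 0.05), (0.0, 4.0), (1.0, 1.0), 0.0, 0.0, 100)
        ok, reasons = rf.bimodality_filter(fit)
        assert not ok and "weight" in reasons

    def test_well_separated_equal_mixture_accepted(self):
        fit = rf.GmmFit(2, (0.5, 0.5), (0.0, 4.0), (1.0, 1.0), 0.0, 0.0, 100)
        ok, reasons = rf.bimodality_filter(fit)
        assert ok and reasons == []

    def test_buried_component_fails_peak_dominance(self):
        # the minor component's weighted peak (0.15·φ(0)=0.060) lies below the
        # major component's weighted density at that point (0.85·φ(0.4)=0.313)
        fit = rf.GmmFit(2, (0.15, 0.85), (0.0, 0.4), (1.0, 1.0), 0.0, 0.0, 100)
        ok, reasons = rf.bimodality_filter(fit)
        assert not ok and reasons == ["peak-dominance"]


class TestBayesianBlocks:
    def test_uniform_data_false_alarm_rate_near_nominal(self):
        # the p0 = 0.05 penalty should produce spurious change points on
        # structureless data at close to the nominal rate; allow twice the
        # nominal rate over 100 seeds
        false_alarms = 0
        for seed in range(100):
            v = np.random.default_rng(seed).uniform(0, 1, 1000)
            if rf.bayesian_blocks(v).size > 2:
                false_alarms += 1
        assert false_alarms <= 10

    def test_two_tight_clusters_are_separated(self, rng):
        # the bulk of each cluster lands in its own dense block, separated by
        # a near-empty block spanning the gap (the cells of the outermost
        # cluster points extend into the gap, so they may join that block)
        v = np.concatenate([rng.normal(0, 0.01, 500), rng.normal(10, 0.01, 500)])
        edges = rf.bayesian_blocks(v)
        bins = np.digitize(v, edges[1:-1])
        bulk1 = np.bincount(bins[v < 5]).argmax()
        bulk2 = np.bincount(bins[v > 5]).argmax()
        assert bulk1 != bulk2
        gap_bin = np.digitize(5.0, edges[1:-1])
        assert np.mean(bins == gap_bin) < 0.01

    def test_affine_invariance_of_block_membership(self, rng):
        v = np.concatenate([rng.uniform(0, 1, 300), rng.uniform(5, 6, 300)])
        e1 = rf.bayesian_blocks(v)
        e2 = rf.bayesian_blocks(3.0 * v + 10.0)
        assert e1.size == e2.size
        assert np.allclose(3.0 * e1 + 10.0, e2, atol=1e-9)

    def test_few_distinct_values_fall_back_to_single_bin(self):
        with pytest.warns(UserWarning):
            edges = rf.bayesian_blocks(np.array([1.0, 1.0, 2.0, 2.0, 3.0]))
        assert edges.size == 2


class TestShrinkageMi:
    def test_independent_channels_near_zero(self, rng):
        x, y = rng.uniform(0, 1, 1000), rng.uniform(0, 1, 1000)
        assert rf.mi_shrinkage(x, y).value < 0.05

    def test_deterministic_four_cluster_coupling_attains_log4(self, rng):
        cl = rng.integers(0, 4, 2000)
        x = cl * 5.0 + rng.uniform(0, 0.1, 2000)
        mi = rf.mi_shrinkage(x, x)
        assert mi.value == pytest.approx(math.log(4), abs=0.1)

    def test_symmetry(self, rng):
        x = rng.normal(0, 1, 500)
        y = 0.5 * x + rng.normal(0, 1, 500)
        assert rf.mi_shrinkage(x, y).value == pytest.approx(
            rf.mi_shrinkage(y, x).value, abs=1e-12
        )

    def test_invariance_under_monotone_reparameterization(self, rng):
        # identical block memberships ⇒ identical MI; exp preserves order so
        # the weighted-event segmentation structure carries over
        cl = rng.integers(0, 3, 900)
        x = cl * 4.0 + rng.uniform(0, 0.2, 900)
        y = (cl + rng.integers(0, 2, 900)) % 3 * 4.0 + rng.uniform(0, 0.2, 900)
        m1 = rf.mi_shrinkage(x, y)
        m2 = rf.mi_shrinkage(np.exp(x / 4.0), np.exp(y / 4.0))
        if m1.joint_counts.shape == m2.joint_counts.shape and np.array_equal(
            m1.joint_counts, m2.joint_counts
        ):
            assert m1.value == pytest.approx(m2.value, abs=1e-12)

    @given(seed=st.integers(0, 50))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_mi_bounded_by_margin_entropies(self, seed):
        g = np.random.default_rng(seed)
        cl = g.integers(0, 4, 600)
        x = cl * 3.0 + g.normal(0, 0.3, 600)
        y = cl * 2.0 + g.normal(0, 0.8, 600)
        est = rf.mi_shrinkage(x, y)
        counts = est.joint_counts
        # entropy bound evaluated on the same shrunken joint the MI used
        n = counts.sum()
        theta = counts.ravel() / n
        occ = theta > 0
        target = np.where(occ, 1.0 / occ.sum(), 0.0)
        lam = est.shrinkage
        p = (lam * target + (1 - lam) * theta).reshape(counts.shape)
        hx = -np.sum(p.sum(1)[p.sum(1) > 0] * np.log(p.sum(1)[p.sum(1) > 0]))
        hy = -np.sum(p.sum(0)[p.sum(0) > 0] * np.log(p.sum(0)[p.sum(0) > 0]))
        assert 0.0 <= est.value <= min(hx, hy) + 1e-12

    def test_mi_increases_with_regulator_dispersion_on_count_data(self):
        kin = rf.AlleleKinetics.from_means(50.0, 50.0)
        regs = [
            rf.RegulatorDistribution.constant(1.0),
            rf.RegulatorDistribution.gamma(50.0, 0.02),
            rf.RegulatorDistribution.gamma(2.0, 0.5),
        ]
        mis = []
        for i, reg in enumerate(regs):
            model = rf.JointCountModel(kin, reg)
            d = rf.sample_joint_counts(model, 1000, seed=100 + i)
            mis.append(
                rf.mi_shrinkage(
                    d["m1"].to_numpy(dtype=float), d["m2"].to_numpy(dtype=float)
                ).value
            )
        assert mis[0] < mis[1] < mis[2]
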