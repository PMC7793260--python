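import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import betainc

import fretpg as f
from fretpg.errors import (
    DomainError,
    InsufficientReplicatesError,
    UndefinedEfficiencyError,
)
from fretpg.unmixing import UnmixResult


def fake_unmix(sample_id, exc, amplitudes, scale=0.0):
    return UnmixResult(
        sample_id=sample_id,
        excitation_nm=exc,
        amplitudes=amplitudes,
        fitted=np.zeros(3),
        residuals=np.zeros(3),
        r_squared=1.0,
        residual_scale=scale,
        condition_number=1.0,
    )


def analyze_kind(kind, cfg, **overrides):
    panel = f.simulate_panel([(kind, overrides)], cfg)
    return f.analyze_spectra(panel.spectra)


class TestComputeEfa:
    def test_no_fret_when_acceptor_signal_equals_crosstalk(self, clean_basis):
        rho = clean_basis.crosstalk_rho
        u541 = fake_unmix("s", 541.0, {"background": 1.0, "donor": 5.0, "acceptor": rho * 2.0})
        u587 = fake_unmix("s", 587.0, {"background": 1.0, "acceptor": 2.0})
        res = f.compute_efa(u541, u587, clean_basis)
        assert res.efa == 0.0 and res.sensitized == 0.0

    def test_no_acceptor_is_undefined(self, clean_basis):
        u541 = fake_unmix("s", 541.0, {"background": 1.0, "donor": 5.0, "acceptor": 0.0})
        u587 = fake_unmix("s", 587.0, {"background": 1.0, "acceptor": 0.0})
        with pytest.raises(UndefinedEfficiencyError):
            f.compute_efa(u541, u587, clean_basis)

    def test_mismatched_sample_ids_rejected(self, clean_basis):
        u541 = fake_unmix("a", 541.0, {"background": 0, "donor": 1, "acceptor": 1})
        u587 = fake_unmix("b", 587.0, {"background": 0, "acceptor": 1})
        with pytest.raises(DomainError):
            f.compute_efa(u541, u587, clean_basis)

    def test_tandem_closed_loop_zero_noise(self, clean_cfg):
        res = analyze_kind("tandem", clean_cfg, true_efficiency=0.31)
        assert abs(res.summaries[0].mean_efa - 31.0) < 1e-6

    def test_negative_control_closed_loop_zero_noise(self, clean_cfg):
        res = analyze_kind("negative", clean_cfg)
        assert abs(res.summaries[0].mean_efa) < 1e-9

    def test_efa_invariant_under_joint_intensity_rescaling(self, clean_cfg):
        panel = f.simulate_panel([("pair", {})], clean_cfg)
        base = f.analyze_spectra(panel.spectra).fret_results[0].efa
        scaled = [s.with_intensities(37.5 * s.intensities) for s in panel.spectra]
        assert abs(f.analyze_spectra(scaled).fret_results[0].efa - base) < 1e-9

    def test_efa_monotone_in_true_efficiency(self, clean_cfg):
        efas = [
            analyze_kind("tandem", clean_cfg, true_efficiency=e).summaries[0].mean_efa
            for e in (0.05, 0.1, 0.2, 0.3, 0.4)
        ]
        assert all(b > a for a, b in zip(efas, efas[1:]))

    def test_parameter_recovery_under_default_noise(self):
        # 100 independent simulated experiments (fresh references each):
        # the estimator is unbiased at the group level and its per-replicate
        # scatter matches the few-percentage-point scale of biological repeats
        res, truth = f.simulate_replicate_experiments(
            "pair",
            100,
            master_seed=17,
            cfg_overrides={"true_efficiency": 0.2, "complex_fraction": 0.8},
        )
        t = truth.set_index("replicate")["efa_true_pct"]
        errs = np.array([r.efa - t.loc[r.replicate] for r in res])
        assert abs(errs.mean()) <= 1.0
        assert 0.5 <= errs.std(ddof=1) <= 4.0


class TestReplicateStatistics:
    def test_summary_hand_computed(self):
        s = f.summarize_replicates([10.0, 12.0, 14.0], "g")
        assert (s.mean_efa, s.sd, s.n) == (12.0, 2.0, 3)

    def test_single_replicate_flagged(self):
        s = f.summarize_replicates([7.9], "g")
        assert s.mean_efa == 7.9 and s.sd == 0.0 and s.n == 1
        assert "single_replicate_sd_undefined" in s.qc_flags

    def test_empty_group_rejected(self):
        with pytest.raises(InsufficientReplicatesError):
            f.summarize_replicates([], "g")

    def test_identical_groups_give_t_zero_p_one(self):
        c = f.compare_groups([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert c.t_statistic == 0.0 and c.p_value == 1.0 and c.df == 4

    def test_clear_shift_is_significant(self):
        c = f.compare_groups([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert c.p_value < 0.01 and c.stars == "**"

    def test_pooled_t_matches_incomplete_beta_oracle(self):
        a = np.array([12.7, 12.5, 12.9])
        b = np.array([4.9, 5.1, 4.7])
        c = f.compare_groups(a, b)
        # textbook pooled two-sample t and its two-sided p via I_x(df/2, 1/2)
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
            a.size + b.size - 2
        )
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
        df = a.size + b.size - 2
        p = betainc(df / 2.0, 0.5, df / (df + t**2))
        np.testing.assert_allclose(c.t_statistic, t, rtol=1e-12)
        np.testing.assert_allclose(c.p_value, p, rtol=1e-10)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(InsufficientReplicatesError):
            f.compare_groups([1.0], [1.0, 2.0])


class TestDistanceConversion:
    def test_half_efficiency_at_r0(self):
        assert f.efficiency_to_distance(0.5) == pytest.approx(6.4, abs=1e-12)
        assert f.distance_to_efficiency(6.4) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize(
        "efficiency, distance_nm",
        [(0.127, 8.8), (0.079, 9.6)],
    )
    def test_reported_apparent_distances(self, efficiency, distance_nm):
        assert round(f.efficiency_to_distance(efficiency), 1) == distance_nm

    def test_far_limit(self):
        e = f.distance_to_efficiency(5 * 6.4)
        assert e == pytest.approx(6.4e-5, rel=1e-2)

    @given(st.floats(min_value=0.01, max_value=0.99))
    def test_roundtrip_identity(self, e):
        assert f.distance_to_efficiency(f.efficiency_to_distance(e)) == pytest.approx(
            e, abs=1e-12
        )

    def test_strictly_decreasing_in_efficiency(self):
        es = np.linspace(0.01, 0.99, 50)
        rs = [f.efficiency_to_distance(e) for e in es]
        assert all(b < a for a, b in zip(rs, rs[1:]))

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_domain_errors(self, bad):
        with pytest.raises(DomainError):
            f.efficiency_to_distance(bad)
        with pytest.raises(DomainError):
            f.distance_to_efficiency(-1.0)


class TestHelixRise:
    @pytest.mark.parametrize("residues, expected", [(2, 0.3), (0, 0.0), (10, 1.5)])
    def test_rise_bound(self, residues, expected):
        assert f.helix_rise_bound(residues) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            f.helix_rise_bound(-1)
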