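"""Two-pool heterodimer model: steady states, perturbations, chase."""

import math

import numpy as np
import pytest

from stoichbuffer import kinetics as kin
from stoichbuffer.kinetics import HeterodimerModel


class TestSteadyState:
    def test_default_calibration_pools(self, model):
        """Closed-form quadratic 100 B^2 + 15 B - 1 = 0 gives B = 0.05."""
        ss = kin.steady_state(model)
        assert ss.b_free == pytest.approx(0.05, abs=1e-10)
        assert ss.a_free == pytest.approx(0.15, abs=1e-10)
        assert ss.complex == pytest.approx(0.75, abs=1e-10)

    def test_zero_synthesis_gives_empty_cell(self, model):
        m = HeterodimerModel(s_a=0.0, s_b=0.0)
        ss = kin.steady_state(m)
        assert (ss.a_free, ss.b_free, ss.complex) == (0.0, 0.0, 0.0)

    def test_no_association_decouples_birth_death(self):
        m = HeterodimerModel(k_on=0.0)
        ss = kin.steady_state(m)
        assert ss.a_free == pytest.approx(m.n_a * m.s_a / m.d_free_a)
        assert ss.b_free == pytest.approx(m.n_b * m.s_b / m.d_free_b)
        assert ss.complex == 0.0

    def test_agrees_with_long_ode_integration(self, model):
        from scipy.integrate import solve_ivp

        from stoichbuffer.kinetics import _rhs

        sol = solve_ivp(
            _rhs, (0, 200), [0, 0, 0], args=(model,), rtol=1e-11, atol=1e-13
        )
        ss = kin.steady_state(model)
        assert sol.y[:, -1] == pytest.approx([ss.a_free, ss.b_free, ss.complex], rel=1e-6)

    @pytest.mark.parametrize("k_off", [0.0, 0.5, 2.0])
    def test_flux_balance(self, k_off):
        m = HeterodimerModel(k_off=k_off, n_a=7.0)
        ss = kin.steady_state(m)
        influx = m.n_a * m.s_a
        outflux = m.d_free_a * ss.a_free + m.d_complex * ss.complex
        assert outflux == pytest.approx(influx, rel=1e-9)

    def test_tagged_share_bookkeeping(self):
        m = HeterodimerModel(n_a=20.0, tagged_copies_a=1.0)
        ss = kin.steady_state(m)
        assert ss.tagged_a_free == pytest.approx(ss.a_free / 20)
        assert ss.tagged_complex == pytest.approx(ss.complex / 20)


class TestPerturbations:
    def test_multicopy_self_keeps_tag_count(self, model):
        p = kin.perturb(model, "multicopy_self", 20)
        assert p.n_a == 20 and p.tagged_copies_a == 1.0

    def test_partner_deletion_zeroes_flux(self, model):
        p = kin.perturb(model, "partner_deletion")
        assert p.n_b * p.s_b == 0.0

    def test_full_proteasome_defect_collapses_rates(self, model):
        p = kin.perturb(model, "proteasome_defect", 0.0)
        assert p.d_free_a == p.d_free_b == p.d_complex

    def test_unknown_kind_rejected(self, model):
        with pytest.raises(ValueError, match="unknown perturbation"):
            kin.perturb(model, "heat_shock")


class TestFoldChange:
    def test_multicopy_self_compensates(self, model):
        fold = kin.fold_change(model, "multicopy_self:20")
        assert fold == pytest.approx(0.3774, abs=0.0005)

    def test_partner_deletion_destabilizes(self, model):
        assert kin.fold_change(model, "partner_deletion") == pytest.approx(1 / 3, abs=1e-6)

    def test_multicopy_partner_stabilizes(self, model):
        assert kin.fold_change(model, "multicopy_partner:20") == pytest.approx(1.649, abs=0.001)

    def test_monotone_in_self_copy_number(self, model):
        folds = [
            kin.fold_change(model, f"multicopy_self:{n}") for n in (1, 2, 5, 10, 20, 50)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(folds, folds[1:]))

    def test_no_compensation_without_stability_difference(self, model):
        """With equal degradation rates total protein is linear in dosage."""
        flat = kin.perturb(model, "proteasome_defect", 0.0)
        for n in (2, 5, 20, 50):
            assert kin.fold_change(flat, f"multicopy_self:{n}") == pytest.approx(1.0, abs=1e-9)

    def test_bidirectional_response(self, model):
        assert kin.fold_change(model, "multicopy_self:20") < 1
        assert kin.fold_change(model, "multicopy_partner:20") > 1

    def test_complex_level_concordance(self, model):
        """The native-gel observable moves with the blot observable."""
        down = kin.fold_change(model, "multicopy_self:20", "tagged_complex")
        up = kin.fold_change(model, "multicopy_partner:20", "tagged_complex")
        assert down < 1 < up


class TestFluxLimitOracle:
    def test_identity_at_single_copy(self):
        assert kin.flux_limit_fold(1, 1.5, 1.0, 5.0, 1.0) == pytest.approx(1.0)

    def test_no_stability_difference_cancels(self):
        for n in (1, 5, 20):
            assert kin.flux_limit_fold(n, 1.5, 1.0, 3.0, 3.0) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        assert kin.flux_limit_fold(20, 1, 1, 5, 1) == pytest.approx(0.24)

    def test_regime_violation_rejected(self):
        with pytest.raises(ValueError):
            kin.flux_limit_fold(2, 1.0, 3.0, 5.0, 1.0)

    def test_steady_state_matches_oracle_on_grid(self):
        """Fast-association steady states agree with the analytic limit."""
        checked = 0
        for s_a in (1.0, 1.5, 3.0):
            for d_f in (2.0, 5.0, 10.0):
                for n in (2, 10, 30):
                    m = HeterodimerModel(
                        s_a=s_a, s_b=1.0, d_free_a=d_f, d_free_b=d_f,
                        d_complex=1.0, k_on=1e6,
                    )
                    numeric = kin.fold_change(m, f"multicopy_self:{n}", "tagged_total_A")
                    analytic = kin.flux_limit_fold(n, s_a, 1.0, d_f, 1.0)
                    assert numeric == pytest.approx(analytic, rel=0.02)
                    checked += 1
        assert checked >= 27


class TestChxSimulation:
    def test_single_pool_exact_exponential(self):
        m = HeterodimerModel(k_on=0.0)
        times = [0.0, 0.5, 1.0, 2.0]
        s = kin.simulate_chx(m, times)
        for t, lv in zip(s.times, s.relative_levels):
            assert lv == pytest.approx(math.exp(-m.d_free_a * t), rel=1e-6)

    def test_multicopy_decays_faster(self, model):
        times = [0.0, 1.0, 2.0, 4.0, 6.0]
        single = kin.simulate_chx(model, times)
        multi = kin.simulate_chx(kin.perturb(model, "multicopy_self", 20), times)
        for s_lv, m_lv in zip(single.relative_levels[1:], multi.relative_levels[1:]):
            assert m_lv < s_lv

    def test_equal_rates_make_dosage_invisible(self, model):
        flat = kin.perturb(model, "proteasome_defect", 0.0)
        times = [0.0, 1.0, 2.0, 4.0]
        single = kin.simulate_chx(flat, times)
        multi = kin.simulate_chx(kin.perturb(flat, "multicopy_self", 20), times)
        assert single.relative_levels == pytest.approx(multi.relative_levels, rel=1e-8)


class TestFitParameters:
    def observations(self, m):
        return [
            ("multicopy_self:20", "tagged_total_A", kin.fold_change(m, "multicopy_self:20")),
            ("partner_deletion", "tagged_total_A", kin.fold_change(m, "partner_deletion")),
            ("multicopy_partner:20", "tagged_total_A", kin.fold_change(m, "multicopy_partner:20")),
        ]

    def test_noiseless_recovery(self, model):
        res = kin.fit_parameters(self.observations(model), model)
        assert res["converged"]
        assert res["params"]["d_ratio"] == pytest.approx(5.0, rel=0.05)

    def test_noisy_recovery(self, model):
        rng = np.random.default_rng(1)
        noisy = [
            (p, o, f * math.exp(rng.normal(0, 0.10)))
            for p, o, f in self.observations(model)
        ]
        res = kin.fit_parameters(noisy, model)
        assert res["params"]["d_ratio"] == pytest.approx(5.0, rel=0.25)

    def test_under_determined_rejected(self, model):
        with pytest.raises(ValueError, match="under-determined"):
            kin.fit_parameters(
                [("multicopy_self:20", "tagged_total_A", 0.4)],
                model,
                free=("s_ratio", "d_ratio"),
            )


class TestModelValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            HeterodimerModel(d_complex=-1.0)

    def test_tag_count_cannot_exceed_copies(self):
        with pytest.raises(ValueError):
            HeterodimerModel(n_a=1.0, tagged_copies_a=2.0)

    def test_config_round_trip(self, model, tmp_path):
        from stoichbuffer.config import dump_model, load_model

        path = tmp_path / "m.yaml"
        dump_model(model, path)
        assert load_model(path) == model

    def test_unknown_config_key_rejected(self, tmp_path):
        from stoichbuffer.config import load_model

        path = tmp_path / "m.yaml"
        path.write_text("s_a: 1.0\nburst_size: 4\n")
        with pytest.raises(ValueError, match="burst_size"):
            load_model(path)
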