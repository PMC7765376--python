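"""Excess HSA, delta Bliss, combination index, and beta scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import combiscreen as cs


from conftest import block_from_surface

hill_params = st.builds(
    cs.HillParams,
    ec50=st.floats(min_value=1e-8, max_value=5e-6),
    slope=st.floats(min_value=0.5, max_value=3.0),
    emax=st.just(0.0),
)


def normalized_from_surface(v, **kwargs):
    return cs.normalize_block(block_from_surface(v, **kwargs))


def normalized_block(pA, pB, interaction, psi=1.0, design=cs.SIX_BY_SIX):
    blk = cs.simulate_combination_block(pA, pB, interaction, design, seed=0, psi=psi)
    return cs.normalize_block(blk)


def edge_fit(nm, axis):
    fa = np.clip(1 - (nm.v[:, 0] if axis == "A" else nm.v[0, :]), 0, 1)
    doses = nm.dosesA if axis == "A" else nm.dosesB
    return cs.fit_median_effect(doses, fa)


class TestExcessHSA:
    def test_combination_matching_best_single_scores_zero(self):
        v = np.ones((4, 4))
        v[:, 0] = [1.0, 0.8, 0.6, 0.4]
        v[0, :] = [1.0, 0.9, 0.7, 0.5]
        v[1:, 1:] = np.minimum.outer(v[1:, 0], v[0, 1:])
        grid, total = cs.excess_hsa(normalized_from_surface(v))
        np.testing.assert_allclose(grid, 0.0, atol=1e-15)
        assert total == 0.0

    def test_synergistic_well_arithmetic(self):
        v = np.ones((2, 2))
        v[1, 0], v[0, 1], v[1, 1] = 0.6, 0.8, 0.4
        grid, total = cs.excess_hsa(normalized_from_surface(v))
        assert grid[0, 0] == pytest.approx(-0.2)
        assert total == pytest.approx(-0.2)

    def test_antagonistic_well_does_not_count_toward_sum(self):
        v = np.ones((2, 2))
        v[1, 0], v[0, 1], v[1, 1] = 0.6, 0.8, 0.9
        grid, total = cs.excess_hsa(normalized_from_surface(v))
        assert grid[0, 0] == pytest.approx(0.3)
        assert total == 0.0

    def test_hsa_equal_generator_gives_identically_zero(self):
        nm = normalized_block(cs.HillParams(1e-7, 1.4), cs.ANCHOR_PARAMS, "hsa_equal")
        grid, total = cs.excess_hsa(nm)
        np.testing.assert_allclose(grid, 0.0, atol=1e-15)
        assert total == 0.0


class TestDeltaBliss:
    def test_independent_combination_scores_zero(self):
        v = np.ones((2, 2))
        v[1, 0] = v[0, 1] = 0.5
        v[1, 1] = 0.25
        grid, total = cs.delta_bliss(normalized_from_surface(v))
        assert grid[0, 0] == pytest.approx(0.0, abs=1e-15)
        assert total == 0.0

    def test_excess_kill_is_negative(self):
        v = np.ones((2, 2))
        v[1, 0] = v[0, 1] = 0.5
        v[1, 1] = 0.10
        grid, total = cs.delta_bliss(normalized_from_surface(v))
        assert grid[0, 0] == pytest.approx(-0.15)
        assert total == pytest.approx(-0.15)

    @settings(max_examples=40, derandomize=True)
    @given(pA=hill_params, pB=hill_params, emaxA=st.floats(0, 0.4), emaxB=st.floats(0, 0.4))
    def test_bliss_generator_identity_for_arbitrary_hill_curves(
        self, pA, pB, emaxA, emaxB
    ):
        pA = cs.HillParams(pA.ec50, pA.slope, emaxA)
        pB = cs.HillParams(pB.ec50, pB.slope, emaxB)
        nm = normalized_block(pA, pB, "bliss_independent")
        grid, total = cs.delta_bliss(nm)
        assert np.max(np.abs(grid)) < 1e-12
        assert total == pytest.approx(0.0, abs=1e-12)

    def test_viability_and_fa_scales_agree_where_viability_below_one(self):
        nm = normalized_block(
            cs.HillParams(1e-7, 1.4, 0.1), cs.ANCHOR_PARAMS, "potency_shift", psi=3.0
        )
        assert np.all(nm.v <= 1.0)
        grid_v, _ = cs.delta_bliss(nm)
        fa = nm.fa
        fa_exp = fa[1:, :1] + fa[:1, 1:] - fa[1:, :1] * fa[:1, 1:]
        grid_fa = fa[1:, 1:] - fa_exp
        np.testing.assert_allclose(grid_v, -grid_fa, atol=1e-12)


class TestCombinationIndex:
    def test_sham_self_combination_is_additive(self):
        p = cs.HillParams(1e-7, 1.2)
        nm = normalized_block(p, p, "potency_shift", psi=1.0)
        fit = edge_fit(nm, "A")
        for policy in cs.synergy.CI_POLICIES:
            ci, fa_at, well, flags = cs.combination_index(nm, fit, fit, policy)
            assert ci == pytest.approx(1.0, abs=1e-3)
            assert 0.0 < fa_at < 1.0
            assert not flags

    @pytest.mark.parametrize("psi", [2.0, 4.0, 8.0])
    def test_potency_shift_recovers_reciprocal_psi(self, psi):
        nm = normalized_block(
            cs.HillParams(1e-7, 1.2), cs.HillParams(1e-6, 1.5), "potency_shift", psi=psi
        )
        ci, _, _, _ = cs.combination_index(nm, edge_fit(nm, "A"), edge_fit(nm, "B"))
        assert ci == pytest.approx(1.0 / psi, rel=1e-3)

    def test_ci_strictly_decreasing_in_planted_synergy(self):
        cis = []
        for psi in [1.0, 2.0, 3.0, 5.0, 8.0]:
            nm = normalized_block(
                cs.HillParams(1e-7, 1.2), cs.HillParams(1e-6, 1.5),
                "potency_shift", psi=psi,
            )
            cis.append(cs.combination_index(nm, edge_fit(nm, "A"), edge_fit(nm, "B"))[0])
        assert np.all(np.diff(cis) < 0)

    def test_unfittable_single_flags_ci_undefined(self):
        nm = normalized_block(cs.HillParams(1e-7, 1.2), cs.ANCHOR_PARAMS,
                              "bliss_independent")
        ci, _, well, flags = cs.combination_index(nm, None, edge_fit(nm, "B"))
        assert np.isnan(ci)
        assert flags == ["unfittable-single"]

    def test_inactive_pair_flagged_no_effect_band(self):
        v = np.ones((4, 4))  # nothing has any effect
        nm = normalized_from_surface(v)
        fit = cs.MedianEffectFit(Dm=1e-6, m=1.0, n_points_used=4, r_squared=1.0)
        ci, _, _, flags = cs.combination_index(nm, fit, fit)
        assert np.isnan(ci)
        assert flags == ["no-effect-band"]

    def test_over_effective_surface_falls_back_to_nearest_half(self):
        # every interior well deeper than the band: scored, not discarded
        p = cs.HillParams(2e-8, 2.5)
        nm = normalized_block(p, cs.HillParams(1e-6, 1.5), "potency_shift", psi=8.0)
        assert np.all(nm.fa[1:, 1:] > 0.75)
        ci, _, _, flags = cs.combination_index(nm, edge_fit(nm, "A"), edge_fit(nm, "B"))
        assert np.isfinite(ci)
        assert "band-fallback" in flags
        assert ci < 0.5


class TestBetaParameter:
    def make_nm(self, combo_top, singleA_top=0.4, singleB_top=0.7):
        v = np.ones((3, 3))
        v[1, 0], v[2, 0] = 0.7, singleA_top
        v[0, 1], v[0, 2] = 0.9, singleB_top
        v[1:, 1:] = combo_top
        return normalized_from_surface(v)

    def test_combo_equal_to_best_single_is_one(self):
        beta, flags = cs.beta_parameter(self.make_nm(0.4))
        assert beta == pytest.approx(1.0)
        assert not flags

    def test_deeper_combination_is_below_one(self):
        beta, _ = cs.beta_parameter(self.make_nm(0.2))
        assert beta == pytest.approx(0.5)

    def test_worse_combination_is_above_one(self):
        beta, _ = cs.beta_parameter(self.make_nm(0.5))
        assert beta == pytest.approx(1.25)

    def test_saturating_singles_leave_beta_undefined(self):
        beta, flags = cs.beta_parameter(self.make_nm(0.001, singleA_top=0.005))
        assert np.isnan(beta)
        assert flags == ["singles-saturating"]


class TestSummarizePair:
    def test_bliss_null_block_is_not_a_hit(self):
        nm = normalized_block(cs.HillParams(3e-7, 1.5), cs.ANCHOR_PARAMS,
                              "bliss_independent")
        report = cs.summarize_pair(nm, edge_fit(nm, "A"), edge_fit(nm, "B"))
        assert not report.hit
        assert report.sum_neg_bliss == pytest.approx(0.0, abs=1e-12)

    def test_planted_synergist_is_a_hit(self):
        nm = normalized_block(cs.HillParams(3e-7, 1.5, 0.2), cs.ANCHOR_PARAMS,
                              "potency_shift", psi=4.0)
        report = cs.summarize_pair(nm, edge_fit(nm, "A"), edge_fit(nm, "B"))
        assert report.hit
        assert report.ci < 0.5
        assert report.beta < 1.0

    def test_unfittable_pair_reported_with_undefined_ci(self):
        nm = normalized_block(cs.HillParams(3e-7, 1.5), cs.ANCHOR_PARAMS,
                              "bliss_independent")
        report = cs.summarize_pair(nm, None, None)
        assert not report.hit
        assert not report.ci_defined
        assert "unfittable-single" in report.flags
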