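import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ordliab import eb
from ordliab.datamodel import ModelConfig
from ordliab.design import build_design
from ordliab.eb import EBState
from ordliab.inference import (
    LOD_PER_LR,
    QtlCall,
    chisq_independence,
    declare_qtl,
    elite_alleles,
    fit_reduced_ml,
    lrt_locus,
    ml_ordinal_fit,
    predict_best_cross,
    pve,
    stage1_select,
)
from ordliab.liability import Thresholds
from ordliab.simulate import (
    QtlSpec,
    SimScenario,
    assign_qtl_effects,
    simulate_founders,
    simulate_nonfounders,
    simulate_phenotypes,
)
from tests.conftest import SYMMETRIC_CUTS


def _state(gammas, design=None):
    return EBState(
        beta=np.zeros(1),
        gamma=[np.asarray(g, dtype=float) for g in gammas],
        sigma2=np.ones(len(gammas)),
        th=Thresholds(SYMMETRIC_CUTS),
    )


class TestStage1:
    def test_zero_effects_select_nothing(self):
        assert stage1_select(_state([[0, 0], [0.0]]), 0.05) == []

    def test_threshold_picks_large_blocks_only(self):
        sel = stage1_select(_state([[0.3, -0.01], [-0.01]]), 0.05)
        assert [k for k, _ in sel] == [0]
        assert sel[0][1] == pytest.approx(0.3)

    @given(st.floats(min_value=0.0, max_value=1.0), st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=30, deadline=None)
    def test_selection_monotone_in_threshold(self, t1, t2):
        state = _state([[0.3, -0.01], [-0.2], [0.07, 0.04]])
        lo, hi = sorted((t1, t2))
        sel_hi = {k for k, _ in stage1_select(state, hi)}
        sel_lo = {k for k, _ in stage1_select(state, lo)}
        assert sel_hi <= sel_lo


@pytest.fixture(scope="module")
def mapped_dataset():
    """One strong simulated QTL, fitted end-to-end (shared, read-only)."""
    sc = SimScenario(n_nonfounders=250, qtl=[QtlSpec(1, 50.0, 0.15)], seed=31)
    rng = np.random.default_rng([31, 0])
    founders = simulate_founders(sc, rng)
    panel = simulate_nonfounders(sc, founders, rng)
    effects = assign_qtl_effects(sc, panel)
    phen = simulate_phenotypes(panel, sc, effects, rng)
    design = build_design(panel, phen)
    cfg = ModelConfig(convergence_tol=1e-4, max_iter=200, rng_seed=5)
    state = eb.fit(design, phen.categories, cfg, n_categories=5)
    return sc, panel, effects, phen, design, cfg, state


class TestLikelihoodRatio:
    def test_lod_conversion_constant(self):
        assert 9.2103 * LOD_PER_LR == pytest.approx(2.0, abs=1e-4)

    def test_ml_matches_statsmodels_ordered_probit(self):
        """Dual route: our reduced-model ML against the independently
        implemented ordered-probit likelihood in statsmodels."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        rng = np.random.default_rng(1)
        n = 250
        x = rng.standard_normal((n, 2))
        lat = x @ np.array([0.8, -0.5]) + rng.standard_normal(n)
        y = np.searchsorted([-1.2, -0.4, 0.5, 1.3], lat) + 1
        ll, coef, th, ok = ml_ordinal_fit(x, y, 5)
        sm_fit = OrderedModel(y, x, distr="probit").fit(method="bfgs", disp=0)
        assert ll == pytest.approx(sm_fit.llf, abs=1e-4)
        np.testing.assert_allclose(coef, sm_fit.params[:2], atol=1e-3)

    def test_true_qtl_yields_large_lod(self, mapped_dataset):
        sc, panel, effects, phen, design, cfg, state = mapped_dataset
        sel = [k for k, _ in stage1_select(state, cfg.stage1_threshold)]
        j = sc.qtl_locus_indices()[0]
        blk = next(i for i, b in enumerate(design.blocks) if b.locus_index == j)
        assert blk in sel
        lr, lod = lrt_locus(sel, design, phen.categories, blk, 5, state)
        assert lod >= 2.0
        assert lr == pytest.approx(lod * 2 * math.log(10), rel=1e-12)

    def test_null_block_forced_into_model_gives_small_lr(self, mapped_dataset):
        sc, panel, effects, phen, design, cfg, state = mapped_dataset
        j = sc.qtl_locus_indices()[0]
        qtl_blk = next(i for i, b in enumerate(design.blocks) if b.locus_index == j)
        null_blk = (qtl_blk + 15) % design.n_blocks  # far marker, no signal
        sel = sorted({qtl_blk, null_blk})
        lr, lod = lrt_locus(sel, design, phen.categories, null_blk, 5, state)
        # under H0 the LR is chi-square-ish with df = block dimension
        assert lr < 3 * design.z[null_blk].shape[1]

    def test_target_must_be_selected(self, mapped_dataset):
        _, _, _, phen, design, _, state = mapped_dataset
        with pytest.raises(ValueError, match="not among"):
            lrt_locus([0], design, phen.categories, 1, 5, state)


class TestPve:
    def _manual_state_design(self):
        # two blocks on 8 rows; block 0 alternates +/-0.5 (var 0.25)
        n = 8
        z0 = np.ones((n, 1))
        z0[::2] = -1.0
        z1 = np.zeros((n, 1))
        design = type("D", (), {})()
        design.z = [z0, z1]
        state = _state([[0.5], [0.0]])
        return state, design

    def test_zero_block_has_zero_pve(self):
        state, design = self._manual_state_design()
        assert pve(state, 1, design) == 0.0

    def test_single_block_arithmetic(self):
        state, design = self._manual_state_design()
        assert pve(state, 0, design) == pytest.approx(100 * 0.25 / 1.25)

    def test_recovery_on_simulated_qtl(self, fast_config):
        """Mean estimated PVE tracks the simulated 10% heritability."""
        pves = []
        for rep in range(50):
            sc = SimScenario(n_nonfounders=500, qtl=[QtlSpec(1, 50.0, 0.10)], seed=77)
            rng = np.random.default_rng([77, rep])
            founders = simulate_founders(sc, rng)
            panel = simulate_nonfounders(sc, founders, rng)
            effects = assign_qtl_effects(sc, panel)
            phen = simulate_phenotypes(panel, sc, effects, rng)
            design = build_design(panel, phen)
            state = eb.fit(
                design, phen.categories,
                fast_config.replace(rng_seed=rep, max_iter=200),
                n_categories=5,
            )
            j = sc.qtl_locus_indices()[0]
            blk = next(i for i, b in enumerate(design.blocks) if b.locus_index == j)
            pves.append(pve(state, blk, design))
        assert abs(np.mean(pves) - 10.0) <= 3.0


class TestEliteAlleles:
    def _call(self, effects, locus="m1", kind="MQ"):
        return QtlCall(
            locus_name=locus, kind=kind, block_index=0, lr=10.0,
            lod=10.0 * LOD_PER_LR, pve=5.0, allele_effects=effects,
            sigma2=0.1, var_component=0.05,
        )

    def test_smallest_effect_wins_under_minimize(self, toy_panel):
        call = self._call({"A": -0.73, "B": 0.2, "C": 0.1})
        elite_alleles([call], toy_panel)
        assert call.elite_allele == "A"
        assert call.elite_effect == pytest.approx(-0.73)
        assert call.elite_carrier == "cv1"
        assert call.elite_carriers == ["cv1", "cv2"]

    def test_maximize_flips_choice(self, toy_panel):
        call = self._call({"A": -0.73, "B": 0.2, "C": 0.1})
        elite_alleles([call], toy_panel, orientation="maximize")
        assert call.elite_allele == "B"

    def test_tie_breaks_to_more_frequent_allele(self, toy_panel):
        # A has 2 carriers, C has 1
        call = self._call({"A": -0.5, "B": 0.2, "C": -0.5})
        elite_alleles([call], toy_panel)
        assert call.elite_allele == "A"

    def test_qe_call_carrier_from_allele_part(self, toy_panel):
        call = self._call(
            {"x x 2009": 0.1, "x x 2010": -0.4, "y x 2009": 0.3}, locus="m2", kind="QE"
        )
        elite_alleles([call], toy_panel)
        assert call.elite_allele == "x x 2010"
        assert call.elite_carrier == "cv1"


class TestBestCross:
    def _calls(self):
        return [
            QtlCall("m1", "MQ", 0, 9, 2, 5, {"A": -0.7, "B": 0.2, "C": 0.0},
                    0.1, 0.05),
            QtlCall("m2", "MQ", 1, 9, 2, 5, {"x": 0.1, "y": -0.3, "z": 0.4},
                    0.1, 0.05),
        ]

    def test_matches_brute_force_enumeration(self, toy_panel):
        calls = self._calls()
        ranked = predict_best_cross(calls, toy_panel, 2, top=0)
        # independent brute force over all pairs and locus alleles
        def brute(pair):
            score = 0.0
            for call in calls:
                j = toy_panel.locus_index(call.locus_name)
                alleles = [
                    str(toy_panel.alleles[toy_panel.row_index(c), j]) for c in pair
                ]
                score += min(call.allele_effects[a] for a in alleles)
            return score
        expected = {
            pair: brute(pair)
            for pair in itertools.combinations(toy_panel.cultivar_ids, 2)
        }
        best_pair = min(expected, key=expected.get)
        assert set(ranked[0]["parents"]) == set(best_pair)
        for r in ranked:
            assert r["score"] == pytest.approx(expected[r["parents"]])

    def test_elite_pyramid_attains_lower_bound(self, toy_panel):
        calls = self._calls()
        ranked = predict_best_cross(calls, toy_panel, 2, top=0)
        bound = -0.7 + -0.3  # sum of elite effects
        assert ranked[0]["score"] >= bound
        pyramiders = [r for r in ranked if r["pyramids_all_elite"]]
        assert all(r["score"] == pytest.approx(bound) for r in pyramiders)
        # cv1 (A,x)? elite alleles A at m1 (cv1, cv2) and y at m2 (cv2, cv5)
        assert any("cv2" in r["parents"] for r in pyramiders)

    def test_larger_parent_sets_never_worse(self, toy_panel):
        calls = self._calls()
        best2 = predict_best_cross(calls, toy_panel, 2)[0]["score"]
        best3 = predict_best_cross(calls, toy_panel, 3)[0]["score"]
        best4 = predict_best_cross(calls, toy_panel, 4)[0]["score"]
        assert best4 <= best3 <= best2

    @pytest.mark.parametrize("k", [1, 5])
    def test_parent_count_bounds(self, toy_panel, k):
        with pytest.raises(ValueError):
            predict_best_cross(self._calls(), toy_panel, k)


class TestChisqIndependence:
    def test_perfect_independence(self):
        stat, df, p = chisq_independence([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        # expected counts all 12.5 -> 4 * (7.5^2 / 12.5) = 18
        stat, df, _ = chisq_independence([[20, 5], [5, 20]])
        assert stat == pytest.approx(18.0)
        assert df == 1

    def test_zero_margin_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-margin"):
            stat, df, _ = chisq_independence([[10, 0, 5], [5, 0, 10]])
        assert df == 1

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            chisq_independence([[0, 0], [0, 0]])


class TestDeclareQtl:
    def test_pipeline_declares_true_qtl_with_annotations(self, mapped_dataset):
        sc, panel, effects, phen, design, cfg, state = mapped_dataset
        result = declare_qtl(state, design, phen.categories, 5, cfg, panel=panel)
        j = sc.qtl_locus_indices()[0]
        markers = [c.locus_name for c in result.calls]
        assert panel.loci[j].name in markers
        call = result.calls[markers.index(panel.loci[j].name)]
        assert call.lod >= 2.0
        assert 0 <= call.pve <= 100
        assert call.elite_allele is not None
        # elite = argmin of the ML allele effects
        assert call.allele_effects[call.elite_allele] == pytest.approx(
            min(call.allele_effects.values())
        )
        assert call.elite_carrier in panel.cultivar_ids

    def test_lod_invariant_to_order_preserving_recoding(self, mapped_dataset):
        """Relabeling categories 1..5 -> 2..6 shifts nothing the model
        can see, so the declared LODs are unchanged."""
        sc, panel, effects, phen, design, cfg, state = mapped_dataset
        sel = [k for k, _ in stage1_select(state, cfg.stage1_threshold)]
        j = sc.qtl_locus_indices()[0]
        blk = next(i for i, b in enumerate(design.blocks) if b.locus_index == j)
        lr1, lod1 = lrt_locus(sel, design, phen.categories, blk, 5, state)
        # cold starts: the EB state's thresholds no longer match C=6
        lr2, lod2 = lrt_locus(sel, design, phen.categories + 1, blk, 6, None)
        assert lod2 == pytest.approx(lod1, abs=0.02)
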