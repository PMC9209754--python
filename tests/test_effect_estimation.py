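"""Additive/combination effects, epistasis estimation, classification."""

import itertools
from collections import OrderedDict

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qtlpyramid.effect_estimation import (
    additive_single,
    aggregate_by_donor,
    classify_effect_levels,
    combination_effect,
    epistasis_fraction,
    epistasis_from_seasons,
    estimate_epistasis,
    estimate_single_effects,
    per_qtl_epistasis,
)
from qtlpyramid.phenotype_summary import TraitSummary
from qtlpyramid.synthetic_data import (
    generate_phenotypes,
    paper_like_config,
    pairwise_epistasis,
)


def _ts(subject, mean, scale="raw_percent"):
    return TraitSummary(subject, mean, float("nan"), 1, scale)


class TestAdditiveAndCombination:
    @pytest.mark.parametrize(
        "mean, control, expected",
        [(48.1, 29.2, 18.9), (56.5, 29.2, 27.3), (29.2, 29.2, 0.0),
         (77.1, 29.2, 47.9), (70.6, 29.2, 41.4)],
    )
    def test_difference_of_means(self, mean, control, expected):
        assert additive_single(_ts("x", mean), _ts("HJX74", control)) == pytest.approx(expected)
        assert combination_effect(_ts("x", mean), _ts("HJX74", control)) == pytest.approx(expected)

    def test_scale_mismatch_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            additive_single(_ts("x", 0.7, "arcsine_sqrt"), _ts("HJX74", 29.2))


class TestEpistasisEstimator:
    def _constant(self, v, s=3):
        return np.full(s, float(v))

    def test_direct_formula_evaluation(self):
        est = epistasis_from_seasons(
            "L", self._constant(50), self._constant(30),
            OrderedDict([("A", self._constant(40)), ("B", self._constant(45))]),
        )
        # P0=30, Pn=50, a = {10, 15} -> i = 20 - 25 = -5
        assert est.i == pytest.approx(-5.0)
        assert est.additive_singles == {"A": 10.0, "B": 15.0}
        assert est.combination_effect == pytest.approx(20.0)

    def test_null_case_gives_zero_t(self):
        est = epistasis_from_seasons(
            "L", self._constant(55), self._constant(30),
            OrderedDict([("A", self._constant(40)), ("B", self._constant(45))]),
        )
        assert est.i == pytest.approx(0.0)
        assert est.t == 0.0 and est.p == 1.0

    def test_single_qtl_and_single_season_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2 QTLs"):
            epistasis_from_seasons(
                "L", self._constant(50), self._constant(30),
                OrderedDict([("A", self._constant(40))]),
            )
        with pytest.raises(ValueError, match="2 seasons"):
            epistasis_from_seasons(
                "L", self._constant(50, 1), self._constant(30, 1),
                OrderedDict([("A", self._constant(40, 1)), ("B", self._constant(45, 1))]),
            )

    def test_noise_free_generator_round_trip(self, full_panel):
        cfg = paper_like_config(
            epistasis=pairwise_epistasis({("qSER8b-gla", "qSER12-gla"): -8.0}),
            noise_sd=0.0,
        )
        records = generate_phenotypes(full_panel, cfg)
        ests = {e.line_id: e for e in estimate_epistasis(full_panel, records)}
        # 2QL-3 carries exactly that pair
        assert ests["2QL-3"].i == pytest.approx(-8.0, abs=1e-10)
        # a line without the pair has i = 0
        assert ests["A35"].i == pytest.approx(0.0, abs=1e-10)

    def test_additivity_null_everywhere(self, full_panel):
        # halved effects keep every purely-additive expectation inside
        # [0, 100], so no clipping disturbs the exact null
        cfg = paper_like_config(noise_sd=0.0)
        cfg.epistasis = pairwise_epistasis({})
        for locus in cfg.additive:
            cfg.additive[locus] *= 0.5
        records = generate_phenotypes(full_panel, cfg)
        for est in estimate_epistasis(full_panel, records):
            assert est.i == pytest.approx(0.0, abs=1e-10)

    @given(st.data())
    def test_linearity_identity(self, data):
        # (Pn-P0) - sum(ai) == Pn + (k-1)P0 - sum(SSSL means), per season
        s = 3
        draw = lambda: np.array(data.draw(st.lists(st.floats(1, 99), min_size=s, max_size=s)))
        pn, p0, c1, c2 = draw(), draw(), draw(), draw()
        est = epistasis_from_seasons(
            "L", pn, p0, OrderedDict([("A", c1), ("B", c2)]), test_scale="raw_percent"
        )
        direct = (pn.mean() - p0.mean()) - ((c1.mean() - p0.mean()) + (c2.mean() - p0.mean()))
        linear = pn.mean() + p0.mean() - c1.mean() - c2.mean()
        assert est.i == pytest.approx(direct, abs=1e-10)
        assert est.i == pytest.approx(linear, abs=1e-10)

    def test_missing_single_effect_names_locus(self, table1_panel, noise_free_records):
        records, _ = noise_free_records
        # table1 panel alone has no 1-QTL lines -> first pyramid locus named
        with pytest.raises(ValueError, match="qSER"):
            estimate_epistasis(table1_panel, records)

    def test_linked_pair_contributes_joint_term(self, full_panel, noise_free_records):
        records, cfg = noise_free_records
        # drop the separate single-QTL lines for the A35-linked pair: the
        # 2-QTL line A35 must then supply one joint term counting 2 toward n
        from qtlpyramid.genotype_data import GenotypePanel

        keep = [
            ln for ln in full_panel.lines
            if ln.line_id not in ("SSSL-qSER2a-sat", "SSSL-qSER2b-sat")
        ]
        panel = GenotypePanel(loci=full_panel.loci, lines=keep)
        recs = records[~records["line_id"].isin(["SSSL-qSER2a-sat", "SSSL-qSER2b-sat"])]
        ests = {e.line_id: e for e in estimate_epistasis(panel, recs)}
        est = ests["3QL-10"]  # carries the pair + qSER3a-sat
        assert est.n == 3
        assert list(est.additive_singles) == ["qSER2a-sat+qSER2b-sat", "qSER3a-sat"]
        # programmed diminishing epistasis: pyramid E(3) minus the joint
        # line's own E(2) (the pair's deficit is folded into its joint effect)
        e3 = cfg.epistasis.total(("a", "b", "c"))
        e2 = cfg.epistasis.total(("a", "b"))
        assert est.i == pytest.approx(e3 - e2, abs=1e-10)

    def test_variance_propagation_alternative(self, full_panel):
        cfg = paper_like_config(noise_sd=2.0, seasons=4, seed=7)
        records = generate_phenotypes(full_panel, cfg)
        blocked = estimate_epistasis(full_panel, records, method="season_blocks")
        propagated = estimate_epistasis(full_panel, records, method="propagation")
        for b, pr in zip(blocked, propagated):
            assert b.i == pytest.approx(pr.i)  # same point estimate
            assert pr.se_i > 0 and 0 <= pr.p <= 1


class TestDerivedQuantities:
    @pytest.mark.parametrize(
        "i, n, expected",
        [(-40.4, 5, -8.08), (-47.7, 6, -7.95), (0.0, 4, 0.0)],
    )
    def test_per_qtl_epistasis(self, i, n, expected):
        assert per_qtl_epistasis(i, n) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "per_qtl, mean_single, expected",
        [(-8.1, 18.9, 42.857), (0.0, 18.9, 0.0), (-6.3, 18.9, 33.333)],
    )
    def test_epistasis_fraction(self, per_qtl, mean_single, expected):
        assert epistasis_fraction(per_qtl, mean_single) == pytest.approx(expected, abs=1e-3)

    def test_fraction_needs_positive_denominator(self):
        with pytest.raises(ValueError):
            epistasis_fraction(-5.0, 0.0)


def _brute_force_partition(values, k):
    """Best contiguous k-partition of sorted values by total within-SSE."""
    vals = sorted(values)
    m = len(vals)
    best, best_cost = None, float("inf")
    for cuts in itertools.combinations(range(1, m), k - 1):
        bounds = [0, *cuts, m]
        segs = [vals[a:b] for a, b in zip(bounds, bounds[1:])]
        cost = sum(sum((x - np.mean(s)) ** 2 for x in s) for s in segs)
        if cost < best_cost - 1e-12:
            best, best_cost = segs, cost
    return best, best_cost


class TestEffectClassification:
    def test_three_levels_on_reconstructed_effects(self):
        from qtlpyramid.datasets import load_synthetic_single_effects

        res = classify_effect_levels(load_synthetic_single_effects(), 3)
        assert [len(res.members[l]) for l in res.levels] == [7, 2, 2]
        assert res.level_means["low"] == pytest.approx(16.2, abs=0.05)
        assert res.level_means["moderate"] == pytest.approx(20.8, abs=0.05)
        assert res.level_means["high"] == pytest.approx(26.4, abs=0.05)

    def test_well_separated_clusters(self):
        effects = dict(zip("abcdef", [13, 14, 20, 21, 26, 27]))
        res = classify_effect_levels(effects, 3)
        assert sorted(res.members["low"]) == ["a", "b"]
        assert sorted(res.members["moderate"]) == ["c", "d"]
        assert sorted(res.members["high"]) == ["e", "f"]

    def test_degenerate_equal_effects_rejected(self):
        with pytest.raises(ValueError, match="smaller k"):
            classify_effect_levels({"a": 5.0, "b": 5.0, "c": 5.0}, 2)

    def test_k_exceeding_locus_count_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            classify_effect_levels({"a": 1.0, "b": 2.0}, 3)

    @given(
        st.lists(
            st.floats(0, 30).map(lambda x: round(x, 2)),
            min_size=4, max_size=10, unique=True,
        ),
        st.integers(2, 3),
    )
    def test_matches_exhaustive_enumeration(self, values, k):
        effects = {f"L{j}": v for j, v in enumerate(values)}
        _, oracle_cost = _brute_force_partition(values, k)
        try:
            res = classify_effect_levels(effects, k)
        except ValueError:
            return  # non-increasing level means; oracle may still tie
        cost = sum(
            (effects[name] - res.level_means[lvl]) ** 2
            for lvl in res.levels
            for name in res.members[lvl]
        )
        assert cost == pytest.approx(oracle_cost, abs=1e-8)


class TestDonorAggregation:
    def test_reconstructed_effects_by_donor(self, table1_panel):
        from qtlpyramid.datasets import load_synthetic_single_effects

        agg = aggregate_by_donor(load_synthetic_single_effects(), table1_panel)
        assert agg["glumaepatula"][0] == pytest.approx(24.333, abs=1e-3)
        assert agg["glumaepatula"][1:] == (20.2, 27.3)
        assert agg["sativa"][0] == pytest.approx(16.6, abs=1e-9)
        assert 14.8 <= agg["sativa"][1] and agg["sativa"][2] <= 17.5

    def test_single_locus_donor(self, table1_panel):
        agg = aggregate_by_donor({"qSER5-glu": 27.3}, table1_panel)
        assert agg == {"glumaepatula": (27.3, 27.3, 27.3)}

    def test_missing_metadata_rejected(self, table1_panel):
        with pytest.raises(ValueError, match="qMYSTERY"):
            aggregate_by_donor({"qMYSTERY": 1.0}, table1_panel)


class TestSingleEffectEstimation:
    def test_noise_free_recovery(self, full_panel, noise_free_records):
        records, cfg = noise_free_records
        est = estimate_single_effects(full_panel, records)
        for locus, truth in cfg.additive.items():
            assert est[locus] == pytest.approx(truth, abs=1e-10)

    def test_missing_control_rejected(self, full_panel, noise_free_records):
        records, _ = noise_free_records
        with pytest.raises(ValueError, match="HJX74"):
            estimate_single_effects(
                full_panel, records[records["line_id"] != "HJX74"]
            )
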