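"""Synthetic panel/phenotype generator: determinism, constraints, architecture."""

import numpy as np
import pytest
from scipy import stats

from qtlpyramid.phenotype_summary import summarize
from qtlpyramid.synthetic_data import (
    ArchitectureConfig,
    diminishing_epistasis,
    generate_panel,
    generate_phenotypes,
    no_epistasis,
    paper_like_config,
    pairwise_epistasis,
)


class TestGeneratePanel:
    def test_paper_preset_is_published_matrix(self, table1_panel):
        panel = generate_panel("paper_preset")
        assert panel.presence_frame().equals(table1_panel.presence_frame())
        assert len(panel.non_control_lines) == 31

    def test_full_preset_adds_one_single_line_per_locus(self, full_panel):
        singles = full_panel.single_qtl_lines()
        assert sorted(singles) == sorted(full_panel.locus_names)
        assert all(len(v) == 1 for v in singles.values())

    def test_random_design_deterministic_given_seed(self):
        a = generate_panel("random", k_loci=4, lines_per_group=1, seed=9)
        b = generate_panel("random", k_loci=4, lines_per_group=1, seed=9)
        assert a.presence_frame().equals(b.presence_frame())

    def test_random_design_respects_count_bounds(self):
        panel = generate_panel("random", k_loci=11, lines_per_group=2, seed=0)
        counts = [
            ln.qtl_count for ln in panel.non_control_lines if ln.qtl_count > 1
        ]
        assert counts and all(2 <= c <= 6 for c in counts)

    def test_infeasible_design_rejected(self):
        with pytest.raises(ValueError, match=">= 2 loci"):
            generate_panel("random", k_loci=1, lines_per_group=1)


class TestGeneratePhenotypes:
    def test_noise_free_single_qtl_value(self, full_panel):
        cfg = paper_like_config(epistasis=no_epistasis(), noise_sd=0.0)
        cfg.additive["qSER1a-gla"] = 18.9
        records = generate_phenotypes(full_panel, cfg)
        vals = records.loc[records["line_id"] == "SSSL-qSER1a-gla", "ser"]
        assert np.allclose(vals, 29.2 + 18.9)

    def test_noise_free_pairwise_value(self, full_panel):
        cfg = paper_like_config(
            epistasis=pairwise_epistasis({("qSER8b-gla", "qSER12-gla"): -5.0}),
            noise_sd=0.0,
        )
        records = generate_phenotypes(full_panel, cfg)
        a = cfg.additive
        vals = records.loc[records["line_id"] == "2QL-3", "ser"]
        assert np.allclose(vals, 29.2 + a["qSER8b-gla"] + a["qSER12-gla"] - 5.0)

    def test_seed_reproducibility_byte_identical(self, full_panel, tmp_path):
        cfg = paper_like_config(seed=13)
        f1, f2 = tmp_path / "a.csv", tmp_path / "b.csv"
        generate_phenotypes(full_panel, cfg).to_csv(f1, index=False)
        generate_phenotypes(full_panel, cfg).to_csv(f2, index=False)
        assert f1.read_bytes() == f2.read_bytes()

    def test_missing_additive_entry_rejected(self, full_panel):
        cfg = paper_like_config()
        del cfg.additive["qSER5-glu"]
        with pytest.raises(ValueError, match="qSER5-glu"):
            generate_phenotypes(full_panel, cfg)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            ArchitectureConfig(additive={"qSYN1-sat": 10.0}, noise_sd=-1.0)

    def test_no_clipping_in_noise_free_paper_architecture(self, full_panel):
        cfg = paper_like_config(noise_sd=0.0)
        records = generate_phenotypes(full_panel, cfg)
        assert records["ser"].between(0, 100, inclusive="neither").all()

    def test_season_offsets_shift_all_lines(self, full_panel):
        cfg = paper_like_config(noise_sd=0.0, season_offsets=[0.0, 2.0, -2.0])
        for locus in cfg.additive:  # headroom so no line clips under the shift
            cfg.additive[locus] *= 0.5
        records = generate_phenotypes(full_panel, cfg)
        wide = records.pivot(index="line_id", columns="season_id", values="ser")
        assert np.allclose(wide["CS2"] - wide["CS1"], 2.0)
        assert np.allclose(wide["CS3"] - wide["CS1"], -2.0)


class TestArchitectureQualitative:
    def test_diminishing_per_qtl_deficit_grows_with_n(self):
        model = diminishing_epistasis(3.5)
        loci = [f"L{j}" for j in range(6)]
        per_qtl = [model.total(loci[:n]) / n for n in range(2, 7)]
        assert all(b < a for a, b in zip(per_qtl, per_qtl[1:]))

    def test_group_means_rise_with_qtl_count(self):
        """SER increases with the number of stacked QTLs: under paper-like
        random architectures the rank correlation between group mean and
        QTL count is positive in >= 95% of panels, and expected means are
        strictly increasing through 5 QTLs."""
        # expectation, no noise
        panel = generate_panel("random", k_loci=11, lines_per_group=6, seed=5)
        ok = 0
        n_panels = 60
        rng = np.random.default_rng(7)
        for _ in range(n_panels):
            additive = {nm: rng.uniform(13, 28) for nm in panel.locus_names}
            cfg = ArchitectureConfig(
                additive=additive,
                epistasis=diminishing_epistasis(3.5),
                noise_sd=3.0,
                seasons=3,
                seed=int(rng.integers(2**31)),
            )
            records = generate_phenotypes(panel, cfg)
            sums = summarize(records, by="group", panel=panel)
            means = {s.subject: s.mean for s in sums if s.subject.endswith("QL")}
            ns = sorted(int(g.rstrip("QL")) for g in means)
            rho = stats.spearmanr(ns, [means[f"{n}QL"] for n in ns]).statistic
            ok += rho > 0
        assert ok / n_panels >= 0.95

    def test_expected_means_increase_through_five_qtls(self):
        cfg = paper_like_config(noise_sd=0.0)
        panel = generate_panel("paper_preset_full")
        records = generate_phenotypes(panel, cfg)
        sums = summarize(records, by="group", panel=panel)
        means = {s.subject: s.mean for s in sums}
        seq = [means[f"{n}QL"] for n in range(1, 6)]
        assert all(b > a for a, b in zip(seq, seq[1:]))
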