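import itertools

import numpy as np
import pandas as pd
import pytest

from tilescreen.library import SgRNALibrary, SgRNARecord
from tilescreen.quantify import CountTable, SampleCounts, frequencies
from tilescreen.scoring import (
    GeneRanking,
    _rho,
    aggregate_replicates,
    control_behavior_report,
    log10_fold_change,
    normalize_panel,
    normalize_tiling,
    rra_gene_rank,
    score_screen,
)
from tilescreen.simulate import default_pairing, make_screen_truth, simulate_counts


def _freq_table(data, samples):
    df = pd.DataFrame(data, columns=samples)
    from tilescreen.quantify import FrequencyTable

    return FrequencyTable(values=df)


class TestLog10FoldChange:
    def test_power_of_ten(self):
        ft = _freq_table({"i": [0.001], "f": [0.0001]}, ["i", "f"])
        lfc = log10_fold_change(ft, {"r1": ("i", "f")}, pseudocount=0.0)
        assert lfc.loc[0, "r1"] == pytest.approx(-1.0)

    def test_no_change_is_zero(self):
        ft = _freq_table({"i": [0.4], "f": [0.4]}, ["i", "f"])
        assert log10_fold_change(ft, {"r1": ("i", "f")}).loc[0, "r1"] == 0.0

    def test_matches_elementwise_recomputation(self):
        rng = np.random.default_rng(1)
        f = rng.dirichlet(np.ones(30), size=4).T
        ft = _freq_table(
            {"i1": f[:, 0], "f1": f[:, 1], "i2": f[:, 2], "f2": f[:, 3]},
            ["i1", "f1", "i2", "f2"],
        )
        eps = 1e-4
        lfc = log10_fold_change(ft, {"r1": ("i1", "f1"), "r2": ("i2", "f2")}, eps)
        expected = np.log10((f[:, 1] + eps) / (f[:, 0] + eps))
        assert np.allclose(lfc["r1"], expected, atol=1e-12)

    def test_missing_pairing_sample_names_replicate(self):
        ft = _freq_table({"i": [0.5], "f": [0.5]}, ["i", "f"])
        with pytest.raises(ValueError, match="r9"):
            log10_fold_change(ft, {"r9": ("i", "missing")})


def _mini_library(n_target=3, n_neg=2, n_pos=2):
    bases = "ACGT"
    spacers = ("A" * 18 + bases[i // 4] + bases[i % 4] for i in range(16))
    recs = [SgRNARecord(f"t{i}", next(spacers), "gene_panel", "X") for i in range(n_target)]
    recs += [SgRNARecord(f"n{i}", next(spacers), "negative_control") for i in range(n_neg)]
    recs += [SgRNARecord(f"p{i}", next(spacers), "positive_control") for i in range(n_pos)]
    return SgRNALibrary(recs)


class TestNormalizations:
    def test_panel_shift(self):
        lib = _mini_library()
        raw = pd.DataFrame({"r1": [-0.7, 0.0, 0.0, 0.3, 0.3, 0.0, 0.0]},
                           index=["t0", "t1", "t2", "n0", "n1", "p0", "p1"])
        norm = normalize_panel(raw, lib)
        assert norm.loc["t0", "r1"] == pytest.approx(-1.0)
        assert norm.loc[["n0", "n1"], "r1"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_panel_identical_values_all_zero(self):
        lib = _mini_library()
        raw = pd.DataFrame({"r1": [0.42] * 7}, index=["t0", "t1", "t2", "n0", "n1", "p0", "p1"])
        assert (normalize_panel(raw, lib) == 0).all().all()

    def test_panel_negative_mean_zero_on_simulated_screen(self, panel_screen, panel_library):
        counts, _, _ = panel_screen
        st = score_screen(counts, default_pairing(3), panel_library, "panel_anchor")
        neg = [r.guide_id for r in panel_library.guides_in("negative_control")]
        anchored = st.normalized.loc[st.normalized.index.intersection(neg)].mean(axis=0)
        assert np.allclose(anchored, 0.0, atol=1e-9)

    def test_dual_anchor_values(self):
        lib = _mini_library()
        # negatives at median 0.2, positives at median -1.8
        raw = pd.DataFrame(
            {"r1": [0.2, -1.8, -0.8, 0.1, 0.3, -1.7, -1.9]},
            index=["t0", "t1", "t2", "n0", "n1", "p0", "p1"],
        )
        norm = normalize_tiling(raw, lib)
        assert norm.loc["t0", "r1"] == pytest.approx(0.0)    # at negative median
        assert norm.loc["t1", "r1"] == pytest.approx(-1.0)   # at positive median
        assert norm.loc["t2", "r1"] == pytest.approx(-0.5)   # halfway

    def test_dual_anchor_affine_invariance(self):
        lib = _mini_library()
        rng = np.random.default_rng(3)
        raw = pd.DataFrame({"r1": rng.normal(size=7), "r2": rng.normal(size=7)},
                           index=["t0", "t1", "t2", "n0", "n1", "p0", "p1"])
        norm = normalize_tiling(raw, lib)
        shifted = normalize_tiling(raw * 3.7 + 1.2, lib)
        assert np.allclose(norm, shifted, atol=1e-9)

    def test_degenerate_anchors_rejected(self):
        lib = _mini_library()
        raw = pd.DataFrame({"r1": [0.0] * 7}, index=["t0", "t1", "t2", "n0", "n1", "p0", "p1"])
        with pytest.raises(ValueError, match="degenerate"):
            normalize_tiling(raw, lib)

    def test_missing_negatives_rejected(self):
        lib = _mini_library()
        raw = pd.DataFrame({"r1": [1.0, 2.0]}, index=["t0", "t1"])
        with pytest.raises(ValueError, match="negative_control"):
            normalize_panel(raw, lib)


class TestAggregate:
    def test_constant_replicates(self):
        agg = aggregate_replicates(pd.DataFrame({"r1": [-1.0], "r2": [-1.0], "r3": [-1.0]}))
        assert agg.loc[0, "score_mean"] == -1.0 and agg.loc[0, "score_sd"] == 0.0

    def test_two_replicates(self):
        agg = aggregate_replicates(pd.DataFrame({"r1": [0.0], "r2": [-2.0]}))
        assert agg.loc[0, "score_mean"] == -1.0
        assert agg.loc[0, "score_sd"] == pytest.approx(np.sqrt(2))

    def test_matches_rowwise_reference(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(size=(20, 3)))
        agg = aggregate_replicates(m)
        assert np.allclose(agg["score_mean"], m.to_numpy().mean(axis=1))
        assert np.allclose(agg["score_sd"], m.to_numpy().std(axis=1, ddof=1))


def test_monotonicity_lower_final_count_never_raises_score(panel_screen, panel_library):
    counts, _, _ = panel_screen
    gid = panel_library.records[100].guide_id
    st = score_screen(counts, default_pairing(3), panel_library, "panel_anchor")
    perturbed = CountTable(counts.values.copy(), counts.accounting)
    perturbed.values.loc[gid, "rep1_final"] = counts.values.loc[gid, "rep1_final"] // 2
    st2 = score_screen(perturbed, default_pairing(3), panel_library, "panel_anchor")
    assert st2.normalized.loc[gid, "rep1"] <= st.normalized.loc[gid, "rep1"]


class TestRRA:
    def test_fully_depleted_gene_ranks_first_with_floor_pvalue(self, panel_library):
        rng = np.random.default_rng(0)
        gids = panel_library.guide_ids
        scores = pd.Series(rng.normal(0, 0.05, len(gids)), index=gids)
        target = [r.guide_id for r in panel_library.records if r.target_gene == "GENE07"]
        scores[target] = -10 + rng.normal(0, 0.01, len(target))  # ranks 1..25
        B = 200
        ranking = rra_gene_rank(scores, panel_library, alpha=0.25, permutations=B, seed=1)
        assert ranking.table.index[0] == "GENE07"
        assert ranking.table.loc["GENE07", "rank"] == 1
        assert ranking.table.loc["GENE07", "p_value"] == pytest.approx(1 / (B + 1))

    def test_gene_above_alpha_percentile_scores_one(self, panel_library):
        gids = panel_library.guide_ids
        scores = pd.Series(np.linspace(-1, 0, len(gids)), index=gids)
        target = [r.guide_id for r in panel_library.records if r.target_gene == "GENE07"]
        scores[target] = np.linspace(1, 2, len(target))  # worst ranks
        ranking = rra_gene_rank(scores, panel_library, alpha=0.25, permutations=100, seed=0)
        assert ranking.table.loc["GENE07", "rra_score"] == 1.0

    def test_ranks_are_permutation_and_pvalues_bounded(self, panel_library):
        rng = np.random.default_rng(2)
        scores = pd.Series(rng.normal(size=len(panel_library)), index=panel_library.guide_ids)
        ranking = rra_gene_rank(scores, panel_library, permutations=100, seed=3)
        t = ranking.table
        assert sorted(t["rank"]) == list(range(1, len(t) + 1))
        assert ((t["rra_score"] > 0) & (t["rra_score"] <= 1)).all()
        assert ((t["p_value"] >= 1 / 101) & (t["p_value"] <= 1)).all()

    def test_alpha_validation(self, panel_library):
        scores = pd.Series(0.0, index=panel_library.guide_ids)
        with pytest.raises(ValueError, match="alpha"):
            rra_gene_rank(scores, panel_library, alpha=1.5, permutations=100)

    def test_permutation_pvalues_match_exhaustive_enumeration(self):
        """5 genes x 2 guides: the permutation p-value converges to the exact
        tail probability over all C(10,2) same-size guide subsets."""
        bases = "ACGT"
        spacers = ("C" * 18 + bases[i // 4] + bases[i % 4] for i in range(16))
        recs = [
            SgRNARecord(f"G{g}_{k}", next(spacers), "gene_panel", f"G{g}")
            for g in range(5)
            for k in range(2)
        ]
        recs.append(SgRNARecord("neg", next(spacers), "negative_control"))
        lib = SgRNALibrary(recs)
        rng = np.random.default_rng(8)
        scores = pd.Series(rng.normal(size=11), index=[r.guide_id for r in recs])
        alpha, B = 0.5, 10_000
        ranking = rra_gene_rank(scores, lib, alpha=alpha, permutations=B, seed=5)

        from scipy.stats import rankdata

        u = pd.Series(rankdata(scores) / len(scores), index=scores.index)
        for gene in ranking.table.index:
            mine = _rho(u[[f"{gene}_0", f"{gene}_1"]].to_numpy(), alpha)[0]
            tail = [
                _rho(np.array(pair), alpha)[0] <= mine
                for pair in itertools.combinations(u.to_numpy(), 2)
            ]
            exact = np.mean(tail)
            est = ranking.table.loc[gene, "p_value"]
            mc_err = 4 * np.sqrt(exact * (1 - exact) / B) + 2 / B
            assert abs(est - exact) <= mc_err


class TestControlBehavior:
    def test_essential_positives_detected(self, panel_screen, panel_library):
        counts, _, _ = panel_screen
        st = score_screen(counts, default_pairing(3), panel_library, "panel_anchor")
        report = control_behavior_report(st.aggregated["score_mean"], panel_library)
        assert report["positive_control"]["median"] < report["negative_control"]["median"] - 1
        assert report["p_value_one_sided"] < 0.05

    def test_null_screen_controls_indistinguishable(self, panel_library):
        truth = make_screen_truth(panel_library, {}, positive_effect=0.0, seed=31)
        counts, _ = simulate_counts(panel_library, truth)
        st = score_screen(counts, default_pairing(3), panel_library, "panel_anchor")
        report = control_behavior_report(st.aggregated["score_mean"], panel_library)
        assert report["p_value_one_sided"] >= 0.05
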