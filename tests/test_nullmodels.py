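import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import ecoassembly as ea
from ecoassembly.containers import CommunityTable
from ecoassembly.errors import ConsistencyError, ValidationError
from ecoassembly.nullmodels import classify_pair
from ecoassembly.trees import cophenetic_matrix

from conftest import tree_from_newick


def rel_table(rows, columns, index=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    index = index or [f"s{i}" for i in range(rows.shape[0])]
    table = CommunityTable(pd.DataFrame(rows, index=index, columns=columns))
    return ea.standardize_table(table, "relative")


def brute_force_bmntd(weights, dist):
    """Independent double-loop implementation of abundance-weighted βMNTD."""
    n, s = weights.shape
    out = np.zeros((n, n))
    for k in range(n):
        for m in range(n):
            if k == m:
                continue
            acc = 0.0
            for i in range(s):
                if weights[k, i] > 0:
                    best = min(dist[i, j] for j in range(s) if weights[m, j] > 0)
                    acc += 0.5 * weights[k, i] * best
            for j in range(s):
                if weights[m, j] > 0:
                    best = min(dist[j, i] for i in range(s) if weights[k, i] > 0)
                    acc += 0.5 * weights[m, j] * best
            out[k, m] = acc
    return out


class TestBmntd:
    def test_identical_samples_zero(self, toy_tree):
        table = rel_table([[1, 2, 3], [1, 2, 3]], ["A", "B", "C"])
        bm = ea.pairwise_bmntd(table, toy_tree)
        assert bm.values.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_singleton_samples_patristic_distance(self, toy_tree):
        table = rel_table([[1, 0, 0], [0, 0, 1]], ["A", "B", "C"])
        bm = ea.pairwise_bmntd(table, toy_tree)
        assert bm.values.iloc[0, 1] == pytest.approx(4.0)

    def test_weighted_hand_example(self, toy_tree):
        table = rel_table([[1, 0, 0], [0, 0.5, 0.5]], ["A", "B", "C"])
        bm = ea.pairwise_bmntd(table, toy_tree)
        # 0.5*d(A,B) + 0.5*(0.5*d(B,A) + 0.5*d(C,A)) = 1 + 1.5
        assert bm.values.iloc[0, 1] == pytest.approx(2.5)

    def test_unweighted_mode_uses_uniform_weights(self, toy_tree):
        table = rel_table([[10, 0, 0], [0, 9, 1]], ["A", "B", "C"])
        bm = ea.pairwise_bmntd(table, toy_tree, abundance_weighted=False)
        # uniform: 0.5*d(A,B) + 0.5*mean(d(B,A), d(C,A)) = 1 + 1.5
        assert bm.values.iloc[0, 1] == pytest.approx(2.5)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n_taxa = int(rng.integers(3, 7))
            n_samp = int(rng.integers(2, 5))
            tree = ea.simulate_yule_tree(n_taxa, int(rng.integers(1000)))
            tips = [l.taxon.label for l in tree.leaf_node_iter()]
            counts = rng.integers(0, 5, size=(n_samp, n_taxa)).astype(float)
            counts[counts.sum(axis=1) == 0, 0] = 1
            table = rel_table(counts, tips)
            d = cophenetic_matrix(tree).loc[tips, tips].to_numpy()
            w = table.data.to_numpy()
            mine = ea.pairwise_bmntd(table, tree).values.to_numpy()
            oracle = brute_force_bmntd(w, d)
            assert np.abs(mine - oracle).max() < 1e-10

    def test_matches_picante_comdistnt(self, tmp_path):
        tree = ea.simulate_yule_tree(8, 3)
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 20, size=(4, 8))
        counts[counts < 5] = 0
        counts[:, 0] += 5
        table = CommunityTable(pd.DataFrame(
            counts, index=list("abcd"), columns=tips))
        mine = ea.pairwise_bmntd(ea.standardize_table(table, "relative"), tree)
        ea.write_community_table(table, tmp_path / "comm.tsv")
        ea.write_newick_tree(tree, tmp_path / "tree.nwk")
        script = textwrap.dedent(f"""
            suppressMessages(library(picante))
            comm <- as.matrix(read.table("{tmp_path}/comm.tsv", header=TRUE,
                              row.names=1, sep="\\t", check.names=FALSE))
            tree <- read.tree("{tmp_path}/tree.nwk")
            res <- as.matrix(comdistnt(decostand(comm, "total"),
                             cophenetic(tree), abundance.weighted=TRUE))
            write.table(res, "{tmp_path}/bmntd_r.tsv", sep="\\t", quote=FALSE)
        """)
        (tmp_path / "run.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "run.R")], check=True,
                       capture_output=True)
        theirs = pd.read_csv(tmp_path / "bmntd_r.tsv", sep="\t", index_col=0)
        assert np.abs(mine.values.to_numpy() -
                      theirs.loc[mine.values.index, mine.values.columns].to_numpy()
                      ).max() < 1e-8

    def test_taxa_missing_from_tree_rejected(self, toy_tree):
        table = rel_table([[1, 1, 1]], ["A", "B", "Z"])
        with pytest.raises(ConsistencyError, match="align"):
            ea.pairwise_bmntd(table, toy_tree)


class TestBnti:
    def test_deterministic_bitwise(self, random_table):
        tree = ea.simulate_yule_tree(10, seed=8)
        table = rel_table(random_table.data.to_numpy(),
                          [l.taxon.label for l in tree.leaf_node_iter()])
        b1 = ea.bnti_matrix(table, tree, n_null=99, seed=5)
        b2 = ea.bnti_matrix(table, tree, n_null=99, seed=5)
        pd.testing.assert_frame_equal(b1.values, b2.values)

    def test_star_tree_distance_constant_pairs_flagged(self):
        tree = tree_from_newick("(A:1,B:1,C:1,D:1);")
        table = rel_table([[1, 1, 0, 0], [0, 0, 1, 1]], list("ABCD"))
        bn = ea.bnti_matrix(table, tree, n_null=99, seed=1)
        assert np.isnan(bn.values.iloc[0, 1])

    def test_per_pair_shuffle_mode_close_to_joint(self):
        tree = ea.simulate_yule_tree(12, seed=9)
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 10, size=(4, 12)).astype(float)
        counts[counts.sum(axis=1) == 0, 0] = 1
        table = rel_table(counts, tips)
        joint = ea.bnti_matrix(table, tree, n_null=299, seed=5)
        indep = ea.bnti_matrix(table, tree, n_null=299, seed=5, joint_shuffle=False)
        diff = (joint.values - indep.values).to_numpy()
        assert np.nanmax(np.abs(diff)) < 1.0  # same null, different MC noise

    def test_symmetry(self, random_table):
        tree = ea.simulate_yule_tree(10, seed=8)
        table = rel_table(random_table.data.to_numpy(),
                          [l.taxon.label for l in tree.leaf_node_iter()])
        bn = ea.bnti_matrix(table, tree, n_null=99, seed=5)
        arr = bn.values.to_numpy()
        assert np.allclose(arr, arr.T, equal_nan=True, atol=1e-12)


class TestRaupCrick:
    def test_bounds(self, random_table):
        rc = ea.rc_bray_matrix(random_table, n_null=99, seed=0)
        arr = rc.values.to_numpy()
        assert ((arr >= -1) & (arr <= 1)).all()
        assert np.allclose(arr, arr.T, atol=1e-12)

    def test_identical_samples_nonpositive(self):
        table = CommunityTable(pd.DataFrame(
            [[5, 5, 2], [5, 5, 2], [9, 0, 3]],
            index=["a", "b", "c"], columns=["T1", "T2", "T3"]))
        rc = ea.rc_bray_matrix(table, n_null=199, seed=1)
        assert rc.values.loc["a", "b"] <= 0

    def test_non_integer_table_rejected(self):
        table = CommunityTable(pd.DataFrame(
            [[0.5, 0.5], [0.2, 0.8]], index=["a", "b"], columns=["T1", "T2"]))
        with pytest.raises(ValidationError, match="counts"):
            ea.rc_bray_matrix(table, n_null=99)

    def test_exact_toy_matches_hand_enumeration(self):
        # 2 taxa, richness 1, 1 read each, equal occupancy: the null pair is
        # equal w.p. 1/2 (BC 0 < obs 1) and unequal w.p. 1/2 (BC 1 = obs),
        # hence RC = 2*(0.5 + 0.25 - 0.5) = 0.5
        exact = ea.rc_exact_pair(np.array([1, 0]), np.array([0, 1]),
                                 np.array([0.5, 0.5]))
        assert exact == pytest.approx(0.5, abs=1e-12)

    def test_monte_carlo_converges_to_exact(self):
        table = CommunityTable(pd.DataFrame(
            [[1, 0], [0, 1]], index=["a", "b"], columns=["T1", "T2"]))
        occ = np.array([0.5, 0.5])
        rc = ea.rc_bray_matrix(table, n_null=999, seed=3,
                               occupancy_weights=occ,
                               abundance_weights=occ)
        assert rc.values.iloc[0, 1] == pytest.approx(0.5, abs=0.12)

    def test_null_community_preserves_richness_and_reads(self):
        rng = np.random.default_rng(4)
        occ = rng.random(20) + 0.1
        ab = rng.random(20)
        for richness, reads in [(5, 50), (20, 20), (1, 7)]:
            c = ea.rc_null_community(rng, richness, reads, occ, ab)
            assert (c > 0).sum() == richness
            assert c.sum() == reads


class TestClassification:
    @pytest.mark.parametrize("bnti,rc,expected", [
        (2.5, 0.0, "variable_selection"),
        (-2.5, 0.0, "homogeneous_selection"),
        (0.5, 0.96, "dispersal_limitation"),
        (0.5, -0.96, "homogenizing_dispersal"),
        (0.0, 0.0, "undominated"),
        # strict inequalities: boundary values fall to the stochastic side
        (2.0, 0.0, "undominated"),
        (-2.0, 0.0, "undominated"),
        (0.0, 0.95, "undominated"),
        (0.0, -0.95, "undominated"),
        (2.0, 0.96, "dispersal_limitation"),
    ])
    def test_threshold_rules(self, bnti, rc, expected):
        assert classify_pair(bnti, rc) == expected

    def test_non_finite_bnti_excluded(self):
        assert classify_pair(float("nan"), 0.99) is None

    def test_mismatched_pair_sets_rejected(self):
        ids1, ids2 = ["a", "b"], ["a", "c"]
        bn = ea.BetaNtiMatrix(
            values=pd.DataFrame(np.zeros((2, 2)), index=ids1, columns=ids1),
            bmntd_observed=pd.DataFrame(np.zeros((2, 2)), index=ids1, columns=ids1),
            n_null=99, seed=0)
        rc = ea.RcMatrix(values=pd.DataFrame(np.zeros((2, 2)), index=ids2,
                                             columns=ids2), n_null=99, seed=0)
        with pytest.raises(ConsistencyError):
            ea.classify_assembly(bn, rc)


class TestProcessFractions:
    def _result(self, labels, samples=None):
        n_pairs = len(labels)
        rows = []
        for i, lab in enumerate(labels):
            a, b = (samples[i] if samples else (f"x{i}", f"y{i}"))
            rows.append(dict(sample_a=a, sample_b=b, bmntd_obs=0.0,
                             bnti=0.0, rc=0.0, process=lab))
        return ea.AssemblyResult(pairs=pd.DataFrame(rows),
                                 n_excluded=sum(pd.isna(l) for l in labels))

    def test_single_process(self):
        res = self._result(["undominated"] * 4)
        out = ea.summarize_process_fractions(res)
        assert out.loc["entire", "undominated"] == pytest.approx(1.0)

    def test_counting_example(self):
        res = self._result(["variable_selection", "homogeneous_selection",
                            "dispersal_limitation", "dispersal_limitation"])
        out = ea.summarize_process_fractions(res)
        row = out.loc["entire"]
        assert row["variable_selection"] == pytest.approx(0.25)
        assert row["homogeneous_selection"] == pytest.approx(0.25)
        assert row["dispersal_limitation"] == pytest.approx(0.5)
        assert row["homogenizing_dispersal"] == pytest.approx(0.0)
        assert row["n_pairs"] == 4

    def test_law_of_total_probability_over_strata(self):
        labels = ["undominated"] * 3 + ["dispersal_limitation"] * 5
        res = self._result(labels)
        strata = {}
        for i in range(8):
            strata[(f"x{i}", f"y{i}")] = "euphotic" if i < 4 else "aphotic"
        out = ea.summarize_process_fractions(res, strata)
        weights = out.loc[["euphotic", "aphotic"], "n_pairs"]
        weighted = (out.loc[["euphotic", "aphotic"], "dispersal_limitation"]
                    * weights).sum() / weights.sum()
        assert weighted == pytest.approx(out.loc["entire", "dispersal_limitation"])

    def test_excluded_pairs_out_of_denominator(self):
        res = self._result(["undominated", np.nan, "undominated"])
        out = ea.summarize_process_fractions(res)
        assert out.loc["entire", "n_pairs"] == 2
        assert out.loc["entire", "n_excluded"] == 1
        assert out.loc["entire", "undominated"] == pytest.approx(1.0)

    def test_zone_strata_rule(self):
        meta = pd.DataFrame({"irradiance_zone": ["photic", "photic", "aphotic"]},
                            index=["a", "b", "c"])
        stratum = ea.zone_strata(meta)
        assert stratum("a", "b") == "euphotic"
        assert stratum("a", "c") == "mixed"
        assert stratum("c", "c") == "aphotic"
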