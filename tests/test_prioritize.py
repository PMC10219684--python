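"""Candidate selection rules, model voting, DEG overlap and sample structure."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cardiomat.prioritize import (
    ContrastBundle,
    SelectionConfig,
    deg_overlap,
    linkage_to_newick,
    model_vote,
    sample_structure,
    select_candidates,
)


def de_table(log2fcs):
    return pd.DataFrame({"log2fc": pd.Series(log2fcs), "p_value": 0.001, "base_mean": 100.0})


def act_table(passes, evaluable=None):
    tf = list(passes)
    return pd.DataFrame(
        {
            "passed": [passes[t] for t in tf],
            "evaluable": [True if evaluable is None else evaluable[t] for t in tf],
            "mean_a": 1.0,
            "mean_b": 0.0,
            "branch": "ratio",
        },
        index=pd.Index(tf, name="tf"),
    )


def make_bundles(tf_data):
    """tf_data: tf -> (fc_2d, fc_d12, act_ih, fc_c1, act_c1, fc_c2, act_c2)."""
    tfs = list(tf_data)
    ih = ContrastBundle(
        dataset="inhouse",
        role="inhouse",
        expression={
            "3D_D40_vs_2D_D40": de_table({t: tf_data[t][0] for t in tfs}),
            "3D_D40_vs_D12": de_table({t: tf_data[t][1] for t in tfs}),
        },
        activity={"3D_D40_vs_2D_D40": act_table({t: tf_data[t][2] for t in tfs})},
    )
    comps = []
    for k, ds in ((3, "comp1"), (5, "comp2")):
        comps.append(
            ContrastBundle(
                dataset=ds,
                role="comparator",
                expression={"adult_vs_fetal": de_table({t: tf_data[t][k] for t in tfs})},
                activity={"adult_vs_fetal": act_table({t: tf_data[t][k + 1] for t in tfs})},
            )
        )
    return [ih, *comps]


LOG2_15 = math.log2(1.5)


class TestSelectCandidates:
    def test_matches_brute_force_rule_evaluation(self):
        rng = np.random.default_rng(14)
        tf_data = {}
        for i in range(5):
            tf_data[f"T{i}"] = (
                float(rng.uniform(0, 1.2)),
                float(rng.uniform(0, 1.2)),
                bool(rng.random() < 0.6),
                float(rng.uniform(0, 1.2)),
                bool(rng.random() < 0.6),
                float(rng.uniform(0, 1.2)),
                bool(rng.random() < 0.6),
            )
        cfg = SelectionConfig()
        table = select_candidates(make_bundles(tf_data), cfg)
        for tf, (f1, f2, a1, f3, a2, f4, a3) in tf_data.items():
            expr_ok = all(f >= LOG2_15 for f in (f1, f2, f3, f4))
            core = expr_ok and a1 and a2 and a3
            assert (table.loc[tf, "tier"] == "core") is core

    def test_failed_comparator_blocks_core_and_is_recorded(self):
        tf_data = {"T0": (1.0, 1.0, True, 0.1, True, 1.0, True)}
        table = select_candidates(make_bundles(tf_data), SelectionConfig())
        assert table.loc["T0", "tier"] == "none"
        assert not bool(table.loc["T0", "expr_comp1_adult_vs_fetal"])
        assert bool(table.loc["T0", "expr_comp2_adult_vs_fetal"])

    def test_family_expansion_gives_extended_tier(self):
        tf_data = {"KLF2": (1.0, 1.0, False, 1.0, True, 1.0, True)}
        cfg = SelectionConfig(family_expansion={"KLF": ["KLF2", "KLF15"]})
        table = select_candidates(make_bundles(tf_data), cfg)
        assert table.loc["KLF2", "tier"] == "extended"
        assert "KLF" in table.loc["KLF2", "rationale"]

    def test_allow_list_gives_manual_tier_with_rationale(self):
        tf_data = {"T0": (0.0, 0.0, False, 0.0, False, 0.0, False)}
        cfg = SelectionConfig(allow_list={"KLF15": "strongly upregulated in adult comparators"})
        table = select_candidates(make_bundles(tf_data), cfg)
        assert table.loc["KLF15", "tier"] == "manual"
        assert table.loc["KLF15", "rationale"] != ""

    def test_no_passing_tf_yields_empty_tiers_without_error(self):
        tf_data = {"T0": (0.0, 0.0, False, 0.0, False, 0.0, False)}
        table = select_candidates(make_bundles(tf_data), SelectionConfig())
        assert (table["tier"] == "none").all()

    def test_monotone_in_expression_fold(self):
        rng = np.random.default_rng(15)
        tf_data = {
            f"T{i}": tuple(
                [float(rng.uniform(0.3, 1.2)), float(rng.uniform(0.3, 1.2)), True,
                 float(rng.uniform(0.3, 1.2)), True, float(rng.uniform(0.3, 1.2)), True]
            )
            for i in range(8)
        }
        bundles = make_bundles(tf_data)
        prev_core = None
        for fold in (1.2, 1.5, 2.0):
            t = select_candidates(bundles, SelectionConfig(expression_fold=fold))
            core = set(t.index[t["tier"] == "core"])
            if prev_core is not None:
                assert core <= prev_core
            prev_core = core

    def test_missing_required_contrast_named(self):
        bundles = make_bundles({"T0": (1.0, 1.0, True, 1.0, True, 1.0, True)})
        del bundles[0].expression["3D_D40_vs_D12"]
        with pytest.raises(ValueError, match="3D_D40_vs_D12"):
            select_candidates(bundles, SelectionConfig())


class TestModelVote:
    @staticmethod
    def model_bundle(name, fc, act, evaluable=True):
        return ContrastBundle(
            dataset=name,
            role="model",
            expression={"mat_vs_ctrl": de_table({"T0": fc})},
            activity={"mat_vs_ctrl": act_table({"T0": act}, {"T0": evaluable})},
        )

    def base_candidates(self):
        tf_data = {"T0": (1.0, 1.0, True, 1.0, True, 1.0, True)}
        return select_candidates(make_bundles(tf_data), SelectionConfig())

    def test_all_models_met_gives_full_vote(self):
        models = [self.model_bundle(f"m{i}", 1.0, True) for i in range(6)]
        out = model_vote(models, self.base_candidates(), SelectionConfig())
        assert out.loc["T0", "model_vote"] == 6

    def test_absent_tf_counts_zero_with_notes(self):
        models = [
            ContrastBundle(
                dataset=f"m{i}",
                role="model",
                expression={"mat_vs_ctrl": de_table({"OTHER": 1.0})},
                activity={"mat_vs_ctrl": act_table({"OTHER": True})},
            )
            for i in range(3)
        ]
        out = model_vote(models, self.base_candidates(), SelectionConfig())
        assert out.loc["T0", "model_vote"] == 0
        assert "not evaluable" in out.loc["T0", "vote_notes"]

    def test_disjunction_vs_conjunction_switch(self):
        models = [self.model_bundle("m1", 1.0, False), self.model_bundle("m2", 0.0, True)]
        both = model_vote(models, self.base_candidates(), SelectionConfig(vote_rule="all"))
        either = model_vote(models, self.base_candidates(), SelectionConfig(vote_rule="any"))
        assert both.loc["T0", "model_vote"] == 0
        assert either.loc["T0", "model_vote"] == 2

    def test_votes_equal_generator_truth(self, small_compendium):
        from cardiomat.pipeline import analyze_compendium, evaluate_recovery

        edges, counts, design, truth = small_compendium
        res = analyze_compendium(counts, design, edges)
        rec = evaluate_recovery(res["candidates"], truth)
        assert rec["vote_agreement"] == 1.0


class TestDegOverlap:
    @staticmethod
    def deg_set(genes_dirs):
        return pd.DataFrame(
            {"direction": list(genes_dirs.values()), "log2fc": 1.0, "p_value": 1e-4},
            index=pd.Index(list(genes_dirs), name="gene"),
        )

    def test_identical_sets(self):
        a = self.deg_set({"g1": 1, "g2": -1, "g3": 1})
        out = deg_overlap(a, a)
        assert out == {"overlap": 3, "jaccard": 1.0, "concordance": 1.0}

    def test_flipped_directions_zero_concordance(self):
        a = self.deg_set({"g1": 1, "g2": -1})
        b = self.deg_set({"g1": -1, "g2": 1})
        out = deg_overlap(a, b)
        assert out["concordance"] == 0.0
        assert out["jaccard"] == 1.0

    def test_empty_sets_give_undefined_concordance(self):
        a = self.deg_set({})
        out = deg_overlap(a, a)
        assert out["overlap"] == 0
        assert math.isnan(out["concordance"])

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(16)
        genes = [f"g{i}" for i in range(30)]
        a = self.deg_set({g: int(rng.choice([1, -1])) for g in rng.choice(genes, 20, replace=False)})
        b = self.deg_set({g: int(rng.choice([1, -1])) for g in rng.choice(genes, 20, replace=False)})
        out = deg_overlap(a, b)
        inter = [g for g in genes if g in a.index and g in b.index]
        union = {g for g in genes if g in a.index or g in b.index}
        conc = np.mean([a.loc[g, "direction"] == b.loc[g, "direction"] for g in inter])
        assert out["overlap"] == len(inter)
        assert out["jaccard"] == pytest.approx(len(inter) / len(union))
        assert out["concordance"] == pytest.approx(conc)


def brute_force_average_linkage(X):
    """Naive agglomeration over all pairs; returns merge order as frozensets."""
    clusters = {i: frozenset([i]) for i in range(len(X))}
    merges = []
    while len(clusters) > 1:
        best, pair = None, None
        for i, j in itertools.combinations(sorted(clusters), 2):
            d = np.mean(
                [np.linalg.norm(X[a] - X[b]) for a in clusters[i] for b in clusters[j]]
            )
            if best is None or d < best - 1e-12:
                best, pair = d, (i, j)
        i, j = pair
        new = clusters.pop(i) | clusters.pop(j)
        key = max(max(clusters, default=-1) + 1, len(X) + len(merges))
        merges.append((new, best))
        clusters[key] = new
    return merges


class TestSampleStructure:
    @staticmethod
    def counts_from(X):
        # X: samples x genes latent log2 profile -> integer counts
        mat = np.round(2.0 ** (X.T + 8)).astype(int)
        return pd.DataFrame(
            mat,
            index=[f"g{i}" for i in range(mat.shape[0])],
            columns=[f"s{j}" for j in range(mat.shape[1])],
        )

    def test_duplicated_samples_merge_first_at_near_zero_height(self):
        rng = np.random.default_rng(17)
        base = rng.normal(0, 1, (3, 40))
        X = np.vstack([base, base])  # 6 samples, 3 duplicated pairs
        counts = self.counts_from(X)
        f = pd.Series(1.0, index=counts.columns)
        out = sample_structure(counts, f)
        Z = out["linkage"]
        assert (Z[:3, 2] < 0.1 * Z[3:, 2].min()).all()

    def test_variance_fractions_sum_to_one(self, small_compendium):
        _, counts, design, _ = small_compendium
        ih = design.index[design["dataset"] == "inhouse"]
        from cardiomat.de import size_factors

        sub = counts[ih]
        out = sample_structure(sub, size_factors(sub))
        assert out["variance_fractions"].sum() == pytest.approx(1.0)

    def test_merge_order_matches_brute_force(self):
        rng = np.random.default_rng(18)
        X = rng.normal(0, 1, (6, 25))
        counts = self.counts_from(X)
        f = pd.Series(1.0, index=counts.columns)
        out = sample_structure(counts, f)
        Z = out["linkage"]
        # recover the actual relative-expression coordinates used
        logn = np.log2(counts / 1.0 + 1.0)
        rel = logn.sub(logn.mean(axis=1), axis=0)
        coords = rel.to_numpy().T
        coords = coords - coords.mean(axis=0)
        expected = brute_force_average_linkage(coords)
        members = {i: frozenset([i]) for i in range(6)}
        for k, (a, b, h, _) in enumerate(Z):
            members[6 + k] = members[int(a)] | members[int(b)]
            assert members[6 + k] == expected[k][0]
            assert h == pytest.approx(expected[k][1], rel=1e-9)

    def test_constant_matrix_rejected(self):
        counts = pd.DataFrame(7, index=[f"g{i}" for i in range(5)], columns=list("abc"))
        with pytest.raises(ValueError, match="constant"):
            sample_structure(counts, pd.Series(1.0, index=counts.columns))

    def test_newick_renders_all_leaves(self, small_compendium):
        _, counts, design, _ = small_compendium
        ih = design.index[design["dataset"] == "inhouse"]
        from cardiomat.de import size_factors

        sub = counts[ih]
        out = sample_structure(sub, size_factors(sub))
        for s in ih:
            assert s in out["newick"]
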