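import itertools

import numpy as np
import pandas as pd
import pytest

from devostate import reference
from devostate.io_formats import (
    CountMatrix,
    GeneSetCollection,
    OrthologMap,
    ValidationError,
)


def _toy_annotations(cells, tissue="liver", cell_type="hep", stage="adult"):
    rows = [{"cell_id": c, "tissue": tissue, "cell_type": cell_type,
             "stage": stage, "donor": "d0"} for c in cells]
    return pd.DataFrame(rows).set_index("cell_id", drop=False)


class TestFilterCells:
    def test_threshold_is_strict_less_than(self):
        df = pd.DataFrame({"c_low": [499, 0], "c_at": [250, 250]},
                          index=["g1", "g2"])
        out = reference.filter_cells(CountMatrix(df), min_umi=500)
        assert out.cell_ids == ["c_at"]

    def test_min_umi_one_is_identity_without_empty_cells(self, toy_counts):
        out = reference.filter_cells(toy_counts, min_umi=1)
        assert out.cell_ids == toy_counts.cell_ids

    def test_matches_brute_force_column_scan(self, rng):
        df = pd.DataFrame(rng.integers(0, 60, size=(30, 50)),
                          index=[f"g{i}" for i in range(30)],
                          columns=[f"c{i}" for i in range(50)])
        out = reference.filter_cells(CountMatrix(df), min_umi=800)
        expected = [c for c in df.columns if sum(df[c]) >= 800]
        assert out.cell_ids == expected

    def test_all_removed_is_error(self):
        df = pd.DataFrame({"c1": [1]}, index=["g1"])
        with pytest.raises(ValidationError, match="threshold"):
            reference.filter_cells(CountMatrix(df), min_umi=10)


class TestNormalizeCpm:
    def test_hand_computed_single_cell(self):
        df = pd.DataFrame({"c1": [1, 1, 2]}, index=["g1", "g2", "g3"])
        cpm = reference.normalize_cpm(CountMatrix(df))
        assert cpm.values["c1"].tolist() == [250000.0, 250000.0, 500000.0]

    def test_library_size_invariance(self):
        df = pd.DataFrame({"c1": [1, 3]}, index=["g1", "g2"])
        df3 = df * 3
        a = reference.normalize_cpm(CountMatrix(df)).values
        b = reference.normalize_cpm(CountMatrix(df3)).values
        pd.testing.assert_frame_equal(a, b)

    def test_elementwise_oracle_and_column_sums(self, rng):
        df = pd.DataFrame(rng.integers(1, 40, size=(20, 15)),
                          index=[f"g{i}" for i in range(20)],
                          columns=[f"c{i}" for i in range(15)])
        cpm = reference.normalize_cpm(CountMatrix(df))
        for c in df.columns:
            total = df[c].sum()
            for g in df.index:
                assert cpm.values.loc[g, c] == pytest.approx(
                    1e6 * df.loc[g, c] / total, rel=1e-12)
        np.testing.assert_allclose(cpm.values.sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_total_cell_is_error(self):
        df = pd.DataFrame({"c1": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValidationError):
            reference.normalize_cpm(CountMatrix(df))


class TestFilterCellTypes:
    def test_threshold_is_strict_less_than(self, rng):
        n1, n2 = 19, 20
        cells = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
        df = pd.DataFrame(rng.integers(1, 5, size=(5, n1 + n2)),
                          index=[f"g{i}" for i in range(5)], columns=cells)
        ann = pd.concat([
            _toy_annotations(cells[:n1], cell_type="sparse"),
            _toy_annotations(cells[n1:], cell_type="dense"),
        ])
        kept = reference.filter_cell_types(CountMatrix(df), ann, min_cells=20)
        assert kept == ["liver|dense|adult"]

    def test_matches_brute_force_tally(self, small_reference):
        counts, ann, _ = small_reference
        kept = reference.filter_cell_types(counts, ann, min_cells=30)
        states = reference.cell_states(ann.loc[counts.cell_ids])
        expected = sorted(s for s, n in states.value_counts().items() if n >= 30)
        assert kept == expected


class TestMegaReplicates:
    def _cpm_and_ann(self, small_reference):
        counts, ann, _ = small_reference
        hq = reference.filter_cells(counts, min_umi=50)
        return reference.normalize_cpm(hq), ann

    def test_replicate_count_and_membership_size(self, small_reference):
        cpm, ann = self._cpm_and_ann(small_reference)
        reps = reference.make_mega_replicates(cpm, ann, n_replicates=10, seed=1)
        for state in reps.states:
            assert reps.state_profiles(state).shape[1] == 10
        for (state, _), members in reps.members.items():
            n_state = sum(reference.cell_states(ann) == state)
            assert len(members) == n_state // 2
            assert len(set(members)) == len(members)  # without replacement

    def test_two_cell_state_replicates_equal_single_cells(self):
        cells = ["x1", "x2"]
        df = pd.DataFrame([[10, 30], [30, 10]], index=["g1", "g2"], columns=cells)
        ann = _toy_annotations(cells)
        cpm = reference.normalize_cpm(CountMatrix(df))
        reps = reference.make_mega_replicates(cpm, ann, n_replicates=6,
                                              fraction=0.5, seed=3)
        profiles = reps.state_profiles("liver|hep|adult")
        singles = {tuple(cpm.values[c]) for c in cells}
        for col in profiles.columns:
            assert tuple(profiles[col]) in singles

    def test_seed_reproducibility_and_state_independence(self, small_reference):
        cpm, ann = self._cpm_and_ann(small_reference)
        a = reference.make_mega_replicates(cpm, ann, seed=7)
        b = reference.make_mega_replicates(cpm, ann, seed=7)
        pd.testing.assert_frame_equal(a.profiles, b.profiles)
        # restricting to a subset of states leaves their draws unchanged
        sub = reference.make_mega_replicates(cpm, ann, states=a.states[:2], seed=7)
        pd.testing.assert_frame_equal(sub.profiles, a.profiles[a.states[:2]])

    def test_replicate_mean_tracks_state_mean(self, small_reference):
        # Monte-Carlo oracle: the SE of a mean of floor(n/2) cells sampled
        # without replacement bounds the replicate-average deviation.
        cpm, ann = self._cpm_and_ann(small_reference)
        reps = reference.make_mega_replicates(cpm, ann, n_replicates=10, seed=9)
        states = reference.cell_states(ann.loc[cpm.cell_ids])
        rng = np.random.default_rng(0)
        state = reps.states[0]
        cells = list(states.index[states == state])
        block = cpm.values[cells].to_numpy()
        n_take = len(cells) // 2
        # direct resampling null for the mean-of-replicate-means deviation
        sims = np.empty((2000, block.shape[0]))
        for i in range(2000):
            draws = [block[:, rng.choice(len(cells), n_take, replace=False)].mean(axis=1)
                     for _ in range(10)]
            sims[i] = np.mean(draws, axis=0)
        lo, hi = np.quantile(sims, [0.0005, 0.9995], axis=0)
        observed = reps.state_profiles(state).mean(axis=1).to_numpy()
        inside = (observed >= lo) & (observed <= hi)
        assert inside.mean() > 0.99


def _exact_mw_greater(x, y):
    """Exhaustive-enumeration Mann-Whitney U and one-sided p (no ties)."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    u_obs = sum(1 for xi in x for yj in y if xi > yj) \
        + 0.5 * sum(1 for xi in x for yj in y if xi == yj)
    count = total = 0
    for comb in itertools.combinations(range(n + m), n):
        xs = pooled[list(comb)]
        ys = np.delete(pooled, list(comb))
        u = sum(1 for xi in xs for yj in ys if xi > yj) \
            + 0.5 * sum(1 for xi in xs for yj in ys if xi == yj)
        total += 1
        if u >= u_obs:
            count += 1
    return u_obs, count / total


class TestSelectSignatureGenes:
    def _make_reps(self, data, states=("liver|a|fetal", "liver|b|adult")):
        """data: dict gene -> (state0 replicate values, state1 replicate values)."""
        cols, vals = [], []
        genes = list(data)
        for si, state in enumerate(states):
            n_rep = len(next(iter(data.values()))[si])
            for r in range(1, n_rep + 1):
                cols.append((state, r))
                vals.append([data[g][si][r - 1] for g in genes])
        profiles = pd.DataFrame(np.array(vals).T, index=genes,
                                columns=pd.MultiIndex.from_tuples(
                                    cols, names=["cell_state", "replicate"]))
        stages = pd.Series({s: s.rsplit("|", 1)[1] for s in states})
        return reference.MegaReplicateSet(profiles, {}, stages)

    def test_perfect_separation_selected(self):
        reps = self._make_reps({
            "on": ([5.0, 6, 7, 8, 9, 5, 6, 7, 8, 9], [0.0] * 10),
            "flat": ([1.0] * 10, [1.0] * 10),
        })
        table = reference.select_signature_genes(reps, top_n=5, alpha_adj=0.05)
        sel = table[(table["cell_state"] == "liver|a|fetal") & table["selected"]]
        assert sel["gene"].tolist() == ["on"]

    def test_u_and_p_match_exhaustive_enumeration(self, rng):
        # 2 states x 3 replicates, 4 genes, no ties
        data = {f"g{i}": (list(rng.normal(size=3)), list(rng.normal(size=3)))
                for i in range(4)}
        reps = self._make_reps(data)
        table = reference.select_signature_genes(reps, top_n=4, alpha_adj=1.1)
        focal = table[table["cell_state"] == "liver|a|fetal"].set_index("gene")
        for g, (x, y) in data.items():
            u, p = _exact_mw_greater(np.array(x), np.array(y))
            assert focal.loc[g, "u_stat"] == pytest.approx(u)
            assert focal.loc[g, "pvalue"] == pytest.approx(p)

    def test_top_n_truncation_keeps_largest_log2fc(self, rng):
        genes = {f"g{i:03d}": ([10.0 + i + d for d in rng.uniform(0, .1, 5)],
                               [0.0 + d for d in rng.uniform(0, .1, 5)])
                 for i in range(30)}
        reps = self._make_reps(genes)
        table = reference.select_signature_genes(reps, top_n=10, alpha_adj=0.05)
        focal = table[table["cell_state"] == "liver|a|fetal"]
        passing = focal[focal["p_adj"] < 0.05]
        if len(passing) > 10:
            selected = set(focal[focal["selected"]]["gene"])
            top_fc = set(passing.nlargest(10, "log2fc")["gene"])
            assert selected == top_fc
        assert focal["selected"].sum() <= 10

    def test_selected_genes_respect_alpha(self, small_reference):
        counts, ann, _ = small_reference
        hq = reference.filter_cells(counts, min_umi=50)
        cpm = reference.normalize_cpm(hq)
        reps = reference.make_mega_replicates(cpm, ann, seed=5)
        table = reference.select_signature_genes(reps, top_n=50, alpha_adj=0.01)
        sel = table[table["selected"]]
        assert (sel["p_adj"] < 0.01).all()
        assert sel.groupby("cell_state").size().max() <= 50

    def test_planted_markers_recovered(self, small_reference, small_signature):
        _, _, truth = small_reference
        genes = set(small_signature.gene_ids)
        for state, markers in truth.state_markers.items():
            assert set(markers) <= genes


class TestApplyExclusions:
    def _table(self, small_reference):
        counts, ann, _ = small_reference
        hq = reference.filter_cells(counts, min_umi=50)
        cpm = reference.normalize_cpm(hq)
        reps = reference.make_mega_replicates(cpm, ann, seed=5)
        return reference.select_signature_genes(reps, top_n=20, alpha_adj=0.05)

    def test_empty_catalog_is_identity(self, small_reference):
        table = self._table(small_reference)
        pd.testing.assert_frame_equal(reference.apply_exclusions(table, None), table)

    def test_excluded_gene_replaced_by_next_ranked(self, small_reference):
        table = self._table(small_reference)
        state = table["cell_state"].iloc[0]
        top_gene = table[(table["cell_state"] == state)
                         & (table["rank"] == 1)]["gene"].iloc[0]
        catalog = GeneSetCollection({"cycle": frozenset({top_gene})})
        out = reference.apply_exclusions(table, catalog)
        sel = out[(out["cell_state"] == state) & out["selected"]]
        assert top_gene not in set(sel["gene"])
        # quota refilled: same count as brute-force filter-then-truncate
        brute = table[(table["cell_state"] == state)
                      & (table["gene"] != top_gene)
                      & (table["p_adj"] < 0.05)]
        assert len(sel) == min(20, len(brute))

    def test_matches_brute_force_filter_then_truncate(self, small_reference, rng):
        table = self._table(small_reference)
        excluded = frozenset(rng.choice(table["gene"].unique(), size=40,
                                        replace=False))
        out = reference.apply_exclusions(
            table, GeneSetCollection({"x": excluded}))
        for state, sub in out.groupby("cell_state"):
            brute = (table[(table["cell_state"] == state)
                           & ~table["gene"].isin(excluded)
                           & (table["p_adj"] < 0.05)]
                     .sort_values(["log2fc", "p_adj", "gene"],
                                  ascending=[False, True, True])
                     .head(20))
            assert set(sub[sub["selected"]]["gene"]) == set(brute["gene"])


class TestBuildSignatureMatrix:
    def test_entries_equal_group_mean_oracle(self, small_reference, small_signature):
        counts, ann, _ = small_reference
        hq = reference.filter_cells(counts, min_umi=50)
        cpm = reference.normalize_cpm(hq)
        states = reference.cell_states(ann.loc[cpm.cell_ids])
        for state in small_signature.cell_states:
            cells = states.index[states == state]
            expected = cpm.values.loc[small_signature.gene_ids, cells].mean(axis=1)
            np.testing.assert_allclose(small_signature.values[state], expected)

    def test_one_state_one_cell_column_is_cell_cpm(self):
        df = pd.DataFrame({"x1": [10, 30], "x2": [1, 3]},
                          index=["g1", "g2"])
        ann = pd.concat([_toy_annotations(["x1"], cell_type="a"),
                         _toy_annotations(["x2"], cell_type="b")])
        cpm = reference.normalize_cpm(CountMatrix(df))
        table = pd.DataFrame({
            "cell_state": ["liver|a|adult", "liver|b|adult"],
            "gene": ["g1", "g2"], "u_stat": [1, 1], "pvalue": [0.001] * 2,
            "p_adj": [0.001] * 2, "log2fc": [1.0, 1.0],
            "selected": [True, True], "rank": [1, 1]})
        sig = reference.build_signature_matrix(cpm, ann, table)
        np.testing.assert_allclose(sig.values["liver|a|adult"],
                                   cpm.values["x1"].loc[sig.gene_ids])

    def test_shape_is_union_of_selected_by_states(self, small_signature,
                                                  small_reference):
        counts, ann, truth = small_reference
        assert small_signature.values.shape[1] == 4
        assert small_signature.values.shape[0] == len(set(small_signature.gene_ids))

    def test_deterministic_rebuild(self, small_reference, small_signature):
        counts, ann, _ = small_reference
        again = reference.build_signature(counts, ann, min_umi=50, min_cells=10,
                                          top_n=60, seed=202)
        pd.testing.assert_frame_equal(again.values, small_signature.values)


class TestMapOrthologs:
    def test_identity_map(self, rng):
        df = pd.DataFrame(rng.uniform(size=(3, 2)), index=list("abc"),
                          columns=["s1", "s2"])
        omap = OrthologMap({g: g for g in "abc"})
        pd.testing.assert_frame_equal(reference.map_orthologs(df, omap), df)

    def test_partial_map_keeps_map_order(self, rng):
        df = pd.DataFrame(rng.uniform(size=(5, 1)), index=list("abcde"),
                          columns=["s1"])
        omap = OrthologMap({"d": "D", "b": "B", "z": "Z"})
        out = reference.map_orthologs(df, omap)
        assert list(out.index) == ["D", "B"]

    def test_round_trip_through_inverse(self, rng):
        df = pd.DataFrame(rng.uniform(size=(4, 2)), index=list("abcd"),
                          columns=["s1", "s2"])
        omap = OrthologMap({"a": "W", "b": "X", "c": "Y"})
        there = reference.map_orthologs(df, omap)
        back = reference.map_orthologs(there, omap.inverse())
        pd.testing.assert_frame_equal(back, df.loc[["a", "b", "c"]])
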