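import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_fragments
from mnase_ssp import coverage as cov
from mnase_ssp import metaplots as mp
from mnase_ssp import rotational_shift as rs
from mnase_ssp.rotational_shift import ROTATIONAL_POSITIONS


def rot_table(values, stage="occupancy", genes=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    idx = pd.MultiIndex.from_tuples(
        [(g, 1) for g in genes], names=["gene_id", "nuc_index"]
    )
    return rs.RotationalTable(
        pd.DataFrame(values, index=idx, columns=ROTATIONAL_POSITIONS), stage=stage
    )


def anchor_set(rows):
    return mp.AnchorSet(
        pd.DataFrame(rows, columns=["chrom", "pos", "strand", "gene_id", "role"])
    )


class TestRotationalOccupancy:
    sizes = {"chr1": 3000}

    def track_from_midpoints(self, mids):
        frags = make_fragments([("chr1", m - 50, m + 51) for m in mids])
        return cov.midpoint_coverage(frags, self.sizes, norm_factor=1.0)

    def test_midpoint_at_dyad(self):
        track = self.track_from_midpoints([1000])
        tab = rs.rotational_occupancy(track, anchor_set([("chr1", 1000, "+", "g1", 1)]))
        row = tab.values.iloc[0]
        assert row[0] == 1.0
        assert row.sum() == 1.0

    def test_minus_strand_orientation(self):
        # midpoint 10 bp upstream in genomic coords = +10 for a − strand gene
        track = self.track_from_midpoints([990])
        tab = rs.rotational_occupancy(track, anchor_set([("chr1", 1000, "-", "g1", 1)]))
        row = tab.values.iloc[0]
        assert row[10] == 1.0
        assert row.sum() == 1.0

    def test_halfwidth_collects_jitter(self):
        track = self.track_from_midpoints([1008, 1012])
        tab = rs.rotational_occupancy(
            track, anchor_set([("chr1", 1000, "+", "g1", 1)]), halfwidth=2
        )
        assert tab.values.iloc[0][10] == 2.0

    def test_edge_dyads_dropped(self):
        track = self.track_from_midpoints([1000])
        anchors = anchor_set(
            [("chr1", 30, "+", "gE", 1), ("chr1", 1000, "+", "g1", 1)]
        )
        tab = rs.rotational_occupancy(track, anchors)
        assert tab.values.index.get_level_values("gene_id").tolist() == ["g1"]

    def test_periodic_occupancy_from_generator(self, small_genome, wt_medium):
        lbin = cov.STANDARD_BINS["nucleosome"]
        track = cov.midpoint_coverage(
            wt_medium.frags, small_genome.chrom_sizes, lbin, 1.0
        )
        tab = rs.rotational_occupancy(track, mp.dyad_anchors(small_genome), lbin)
        pooled = tab.values.sum(axis=0)
        # occupancy concentrated at the 10 bp grid, decaying from the dyad
        assert pooled[0] == pooled.max()
        assert pooled[10] > pooled[30]
        assert pooled[-10] > pooled[-30]
        assert pooled[40] + pooled[-40] + pooled[50] + pooled[-50] < 0.05 * pooled.sum()


class TestZscoreRows:
    def test_constant_row_maps_to_zero(self):
        z = rs.zscore_rows(rot_table(np.ones(11)))
        assert (z.values.iloc[0] == 0).all()
        assert z.stage == "zscore"

    def test_single_positive_entry_has_max_z(self):
        row = np.zeros(11)
        row[7] = 5.0
        z = rs.zscore_rows(rot_table(row)).values.iloc[0]
        assert z.idxmax() == ROTATIONAL_POSITIONS[7]
        assert z.max() > 0

    def test_matches_brute_force(self, rng):
        x = rng.exponential(1.0, size=(100, 11))
        z = rs.zscore_rows(rot_table(x)).values.to_numpy()
        for i in range(100):
            expected = (x[i] - x[i].mean()) / x[i].std()
            np.testing.assert_allclose(z[i], expected, atol=1e-12)

    def test_standardized_rows_have_zero_mean_unit_sd(self, rng):
        z = rs.zscore_rows(rot_table(rng.random((20, 11)))).values.to_numpy()
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1), 1, atol=1e-9)

    @given(
        st.lists(st.floats(0, 1e3), min_size=11, max_size=11),
        st.floats(0.1, 100),
        st.floats(0, 50),
    )
    @settings(derandomize=True, max_examples=50)
    def test_shift_scale_invariance(self, row, scale, shift):
        base = rs.zscore_rows(rot_table(row)).values.to_numpy()
        transformed = rs.zscore_rows(
            rot_table(np.asarray(row) * scale + shift)
        ).values.to_numpy()
        np.testing.assert_allclose(base, transformed, atol=1e-6)


class TestDeltaZ:
    def test_identical_inputs_zero(self, rng):
        z = rs.zscore_rows(rot_table(rng.random((5, 11))))
        d = rs.delta_z(z, z)
        assert (d.values.to_numpy() == 0).all()

    def test_row_sums_zero_and_sign_flip(self, rng):
        z1 = rs.zscore_rows(rot_table(rng.random((5, 11))))
        z2 = rs.zscore_rows(rot_table(rng.random((5, 11))))
        d12 = rs.delta_z(z1, z2).values.to_numpy()
        d21 = rs.delta_z(z2, z1).values.to_numpy()
        np.testing.assert_allclose(d12.sum(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(d12, -d21)

    def test_empty_intersection_errors(self, rng):
        z1 = rs.zscore_rows(rot_table(rng.random((2, 11)), genes=["a", "b"]))
        z2 = rs.zscore_rows(rot_table(rng.random((2, 11)), genes=["c", "d"]))
        with pytest.raises(ValueError):
            rs.delta_z(z1, z2)


def multi_index_table(rng, genes, indices, shift_at=None):
    """Random occupancy tables; optionally move mass downstream at given
    (index) positions to mimic a rotational shift."""
    rows, keys = [], []
    base = np.array([0.125, 0.25, 0.5, 1.0, 0.5, 0.25, 0.125])
    for g in genes:
        for k in indices:
            w = np.zeros(11)
            w[2:9] = base
            if shift_at and k in shift_at:
                w = 0.4 * w + 0.6 * np.roll(w, 1)
            rows.append(rng.poisson(200 * w / w.sum()))
            keys.append((g, k))
    values = pd.DataFrame(
        np.asarray(rows, dtype=float),
        index=pd.MultiIndex.from_tuples(keys, names=["gene_id", "nuc_index"]),
        columns=ROTATIONAL_POSITIONS,
    )
    return rs.RotationalTable(values, stage="occupancy")


class TestShiftTest:
    def test_null_medians_zero_for_identical_inputs(self, rng):
        genes = [f"g{i}" for i in range(30)]
        z = rs.zscore_rows(multi_index_table(rng, genes, [1, 2]))
        res = rs.shift_test(z, z)
        assert (res.table["median_dz"] == 0).all()
        assert res.table["significant"].sum() == 0

    def test_swap_symmetry(self, rng):
        genes = [f"g{i}" for i in range(25)]
        z1 = rs.zscore_rows(multi_index_table(rng, genes, [1]))
        z2 = rs.zscore_rows(multi_index_table(rng, genes, [1], shift_at=[1]))
        r12 = rs.shift_test(z1, z2)
        r21 = rs.shift_test(z2, z1)
        np.testing.assert_allclose(
            r12.table["median_dz"].to_numpy(), -r21.table["median_dz"].to_numpy()
        )
        np.testing.assert_allclose(
            r12.table["p"].to_numpy(), r21.table["p"].to_numpy()
        )

    def test_injected_shift_detected_with_correct_signs(self, rng):
        genes = [f"g{i}" for i in range(60)]
        wt = rs.zscore_rows(multi_index_table(rng, genes, [5]))
        mut = rs.zscore_rows(multi_index_table(rng, genes, [5], shift_at=[5]))
        res = rs.shift_test(mut, wt)
        t = res.table.set_index("position")
        assert t.loc[10, "median_dz"] > 0  # gained downstream
        assert t.loc[-10, "median_dz"] < 0  # lost upstream
        assert t.loc[[10, -10], "significant"].all()

    def test_min_genes_floor_skips_index(self, rng):
        z1 = rs.zscore_rows(multi_index_table(rng, ["g1", "g2"], [1]))
        z2 = rs.zscore_rows(multi_index_table(rng, ["g1", "g2"], [1]))
        with pytest.raises(ValueError):
            rs.shift_test(z1, z2, min_genes=10)
        res = rs.shift_test(z1, z2, min_genes=2)
        assert set(res.table["nuc_index"]) == {1}

    def test_gene_subset_restricts_comparison(self, rng):
        genes = [f"g{i:02d}" for i in range(40)]
        z1 = rs.zscore_rows(multi_index_table(rng, genes, [1]))
        z2 = rs.zscore_rows(multi_index_table(rng, genes, [1]))
        res = rs.shift_test(z1, z2, gene_subset=genes[:20], min_genes=5)
        assert (res.table["n_genes"] == 20).all()


class TestStratification:
    def test_eight_genes_four_groups_of_two(self):
        lengths = {f"g{i}": 100 * (i + 1) for i in range(8)}
        strat = rs.stratify_by_length(lengths)
        sizes = pd.Series(strat.assignment).value_counts()
        assert sorted(sizes.tolist()) == [2, 2, 2, 2]
        assert strat.assignment["g0"] == "Q1"
        assert strat.assignment["g7"] == "Q4"

    def test_permutation_invariance(self):
        lengths = {"a": 5, "b": 3, "c": 9, "d": 1}
        s1 = rs.stratify_by_length(lengths)
        s2 = rs.stratify_by_length(dict(reversed(list(lengths.items()))))
        assert s1.assignment == s2.assignment

    def test_ties_broken_lexicographically(self):
        lengths = {"b": 5, "a": 5, "d": 5, "c": 5}
        strat = rs.stratify_by_length(lengths)
        assert strat.assignment == {"a": "Q1", "b": "Q2", "c": "Q3", "d": "Q4"}

    def test_four_hundred_genes_exact_quartiles(self):
        lengths = {f"g{i:03d}": i for i in range(400)}
        sizes = pd.Series(rs.stratify_by_length(lengths).assignment).value_counts()
        assert sizes.tolist() == [100, 100, 100, 100]

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            rs.stratify_by_score({"a": 1}, k=4)


class TestExpressionScore:
    def test_constant_track_window_arithmetic(self):
        counts = {"chr1": np.ones(1000)}
        gene = {"chrom": "chr1", "tss": 300, "strand": "+"}
        assert rs.expression_score(counts, gene) == 101.0

    def test_zero_track(self):
        counts = {"chr1": np.zeros(1000)}
        gene = {"chrom": "chr1", "tss": 300, "strand": "+"}
        assert rs.expression_score(counts, gene) == 0.0

    def test_minus_strand_window_upstream(self):
        counts = {"chr1": np.zeros(1000)}
        counts["chr1"][100:201] = 2.0  # [tss-200, tss-100] for tss=300 on −
        gene = {"chrom": "chr1", "tss": 300, "strand": "-"}
        assert rs.expression_score(counts, gene) == 202.0

    def test_window_outside_chrom(self):
        counts = {"chr1": np.zeros(150)}
        gene = {"chrom": "chr1", "tss": 100, "strand": "+"}
        with pytest.raises(ValueError):
            rs.expression_score(counts, gene)
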