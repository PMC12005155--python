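import numpy as np
import pandas as pd
import pytest

from mnase_ssp import metaplots as mp
from mnase_ssp.synthetic_data import (
    CLASS_NAMES,
    ConditionParams,
    GenomeModel,
    estimate_cleavage_rate_ratio,
    generate_genome,
    mutant_presets,
    simulate_cut_positions,
    simulate_digestion,
    simulate_netseq,
    write_genome,
    read_genome,
    params_to_yaml,
    params_from_yaml,
)


class TestGenerateGenome:
    def test_single_gene_geometry(self):
        g = generate_genome(1, seed=7, spacing_bp=165, ndr_width_bp=140)
        g.validate()
        assert len(g.genes) == 1
        gene = g.genes.iloc[0]
        sign = 1 if gene["strand"] == "+" else -1
        dyads = g.dyads.set_index("index")
        assert dyads.loc[1, "pos"] == gene["tss"] + sign * 60
        assert dyads.loc[2, "pos"] == dyads.loc[1, "pos"] + sign * 165

    def test_quartiles_non_degenerate(self):
        g = generate_genome(400, seed=1)
        from mnase_ssp.rotational_shift import stratify_by_length

        strat = stratify_by_length(g.genes)
        sizes = pd.Series(strat.assignment).value_counts()
        assert sizes.tolist() == [100, 100, 100, 100]
        # lengths span roughly 0.5-8 kb
        assert g.genes["length"].min() >= 500
        assert g.genes["length"].max() <= 8000
        assert g.genes["length"].max() / g.genes["length"].min() > 3

    def test_seed_contract(self):
        g1 = generate_genome(50, seed=1)
        g2 = generate_genome(50, seed=2)
        assert not g1.genes["tss"].equals(g2.genes["tss"])
        g1.validate()
        g2.validate()

    def test_both_strands_present(self):
        g = generate_genome(50, seed=1)
        assert set(g.genes["strand"]) == {"+", "-"}

    def test_ndr_footprints_between_flanking_dyads(self):
        g = generate_genome(30, seed=3)
        dyads = g.dyads.set_index(["gene_id", "index"])["pos"]
        for _, f in g.ndr_footprints.iterrows():
            lo = dyads[(f["gene_id"], -1)]
            hi = dyads[(f["gene_id"], 1)]
            lo, hi = min(lo, hi), max(lo, hi)
            assert lo < f["center"] < hi

    @pytest.mark.parametrize(
        "kwargs", [{"n_genes": 0}, {"n_genes": 5, "spacing_bp": 100}]
    )
    def test_parameter_errors(self, kwargs):
        with pytest.raises(ValueError):
            generate_genome(seed=0, **{"n_genes": 5, **kwargs})


class TestConditionParams:
    def test_weights_must_sum_to_one(self):
        p = ConditionParams()
        p.class_weights["background"] += 0.1
        with pytest.raises(ValueError):
            p.validate()

    def test_scale_bounds(self):
        with pytest.raises(ValueError):
            ConditionParams(ndr_protection_scale=1.5).validate()

    def test_yaml_round_trip(self, tmp_path):
        p = mutant_presets("K192N")
        path = tmp_path / "p.yaml"
        params_to_yaml(p, path)
        back = params_from_yaml(path)
        assert back == p


class TestMutantPresets:
    def test_wt_has_no_shifts(self):
        p = mutant_presets("WT")
        assert p.shift_magnitude_bp == {}
        assert p.ndr_protection_scale == 1.0

    def test_k192n_loses_ndr_but_not_five_prime(self):
        p = mutant_presets("K192N")
        assert p.ndr_protection_scale < 0.2
        assert not p.five_prime_shift_enabled
        assert min(p.shift_magnitude_bp) == 3

    def test_141_305_keeps_ndr_and_shifts_five_prime(self):
        p = mutant_presets("141-305")
        assert p.ndr_protection_scale == 1.0
        assert p.five_prime_shift_enabled
        assert 1 in p.shift_magnitude_bp
        # larger body shifts than the other mutant
        k = mutant_presets("K192N")
        assert all(
            p.shift_magnitude_bp[i] > k.shift_magnitude_bp[i] for i in range(3, 11)
        )

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            mutant_presets("spn1-oops")


class TestSimulateDigestion:
    def test_deterministic_given_seed(self, small_genome):
        p = mutant_presets("WT")
        a = simulate_digestion(small_genome, p, 5000, seed=4)
        b = simulate_digestion(small_genome, p, 5000, seed=4)
        pd.testing.assert_frame_equal(a.frags, b.frags)

    def test_neutral_params_identical_to_wt(self, small_genome):
        neutral = ConditionParams(ndr_protection_scale=1.0, shift_magnitude_bp={})
        a = simulate_digestion(small_genome, neutral, 5000, seed=4)
        b = simulate_digestion(small_genome, mutant_presets("WT"), 5000, seed=4)
        pd.testing.assert_frame_equal(a.frags, b.frags)

    def test_mixture_conservation(self, small_genome):
        n = 60_000
        p = mutant_presets("WT")
        fs = simulate_digestion(small_genome, p, n, seed=8)
        counts = fs.frags["frag_class"].value_counts()
        for cls in CLASS_NAMES:
            w = p.class_weights[cls]
            sigma = np.sqrt(n * w * (1 - w))
            assert abs(counts[cls] - n * w) <= 3 * sigma, cls

    def test_fragments_within_bounds_and_positive_length(self, small_genome):
        fs = simulate_digestion(small_genome, mutant_presets("WT"), 20000, seed=5)
        f = fs.frags
        assert (f["end"] > f["start"]).all()
        for chrom, grp in f.groupby("chrom"):
            assert grp["start"].min() >= 0
            assert grp["end"].max() <= small_genome.chrom_sizes[chrom]

    def test_ndr_scale_zero_removes_ndr_class(self, small_genome):
        p = ConditionParams(ndr_protection_scale=0.0)
        fs = simulate_digestion(small_genome, p, 20000, seed=6)
        assert (fs.frags["frag_class"] == "ndr_short").sum() == 0

    def test_errors(self, small_genome):
        empty = GenomeModel(
            {"chr1": 1000},
            small_genome.genes.iloc[:0],
            small_genome.dyads.iloc[:0],
            small_genome.ndr_footprints.iloc[:0],
        )
        with pytest.raises(ValueError):
            simulate_digestion(empty, mutant_presets("WT"), 100, seed=0)
        bad = ConditionParams()
        bad.class_weights["nucleosome"] += 0.2
        with pytest.raises(ValueError):
            simulate_digestion(small_genome, bad, 100, seed=0)

    def test_strand_symmetry(self):
        """Mirroring the genome mirrors the fragment distribution.

        A single-gene genome and its coordinate-reflected, strand-flipped
        twin must produce the same strand-oriented midpoint distribution
        around the +1 dyad (up to sampling noise).
        """
        size = 20000

        def one_gene(strand):
            sign = 1 if strand == "+" else -1
            tss = 5000 if strand == "+" else size - 1 - 5000
            genes = pd.DataFrame(
                {
                    "gene_id": ["g1"],
                    "chrom": ["chrT"],
                    "tss": [tss],
                    "strand": [strand],
                    "length": [2000],
                    "start": [tss if strand == "+" else tss - 1999],
                    "end": [tss + 2000 if strand == "+" else tss + 1],
                }
            )
            rows = [("chrT", tss + sign * -226, "g1", -1, strand)]
            rows += [
                ("chrT", tss + sign * (60 + 165 * (k - 1)), "g1", k, strand)
                for k in range(1, 8)
            ]
            dyads = pd.DataFrame(
                rows, columns=["chrom", "pos", "gene_id", "index", "strand"]
            )
            ndr = pd.DataFrame(
                {
                    "chrom": ["chrT"],
                    "center": [tss - sign * 80],
                    "width": [30],
                    "weight": [1.0],
                    "gene_id": ["g1"],
                }
            )
            g = GenomeModel({"chrT": size}, genes, dyads, ndr)
            g.validate()
            return g

        profiles = []
        for strand, seed in (("+", 17), ("-", 17)):
            g = one_gene(strand)
            fs = simulate_digestion(g, mutant_presets("WT"), 80_000, seed=seed)
            vp = mp.build_vplot(
                fs.frags, mp.dyad_anchors(g, [1]), max_offset=50, length_range=(142, 152)
            )
            marginal = vp.counts.sum(axis=1).to_numpy(dtype=float)
            profiles.append(marginal / marginal.sum())
        np.testing.assert_allclose(profiles[0], profiles[1], atol=0.01)


class TestDigestionRateModel:
    def test_ratio_recovery_small(self, small_genome):
        cuts = simulate_cut_positions(small_genome, 200_000, seed=13)
        ratio = estimate_cleavage_rate_ratio(cuts, small_genome)
        assert ratio == pytest.approx(25.0, rel=0.10)

    def test_ratio_parameter_respected(self, small_genome):
        cuts = simulate_cut_positions(small_genome, 200_000, seed=14, linker_rate_ratio=5.0)
        ratio = estimate_cleavage_rate_ratio(cuts, small_genome)
        assert ratio == pytest.approx(5.0, rel=0.10)


class TestGenomeFiles:
    def test_write_read_round_trip(self, small_genome, tmp_path):
        write_genome(small_genome, tmp_path)
        back = read_genome(tmp_path)
        assert back.chrom_sizes == small_genome.chrom_sizes
        pd.testing.assert_frame_equal(
            back.genes.reset_index(drop=True),
            small_genome.genes[back.genes.columns].reset_index(drop=True),
            check_dtype=False,
        )
        pd.testing.assert_frame_equal(
            back.dyads.reset_index(drop=True),
            small_genome.dyads[back.dyads.columns].reset_index(drop=True),
            check_dtype=False,
        )
        back.validate()


class TestSimulateNetseq:
    def test_counts_confined_to_gene_bodies(self, small_genome):
        counts = simulate_netseq(small_genome, seed=2)
        mask = {c: np.zeros(n, dtype=bool) for c, n in small_genome.chrom_sizes.items()}
        for _, g in small_genome.genes.iterrows():
            mask[g["chrom"]][g["start"] : g["end"]] = True
        for chrom, vec in counts.items():
            assert vec[~mask[chrom]].sum() == 0
        assert sum(v.sum() for v in counts.values()) > 0
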