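import numpy as np
import pandas as pd
import pytest

from mnase_ssp import coverage as cov
from mnase_ssp import metaplots as mp
from mnase_ssp import synthetic_data as synth


@pytest.fixture(scope="session")
def small_genome():
    g = synth.generate_genome(n_genes=40, seed=101)
    g.validate()
    return g


@pytest.fixture(scope="session")
def wt_medium(small_genome):
    """A medium wild-type fragment sample shared across metaplot tests."""
    return synth.simulate_digestion(
        small_genome, synth.mutant_presets("WT"), 150_000, seed=102, sample_id="WT"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_fragments(rows):
    """Fragment frame from (chrom, start, end) tuples."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["strand"] = "."
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


@pytest.fixture
def two_gene_genome():
    """Hand-built genome: one + gene and one − gene on a 20 kb chromosome."""
    genes = pd.DataFrame(
        {
            "gene_id": ["gA", "gB"],
            "chrom": ["chrT", "chrT"],
            "tss": [2000, 12000],
            "strand": ["+", "-"],
            "length": [2000, 3000],
            "start": [2000, 9001],
            "end": [4000, 12001],
        }
    )
    dyad_rows = []
    for gid, tss, sign in (("gA", 2000, 1), ("gB", 12000, -1)):
        dyad_rows.append(("chrT", tss + sign * -226, gid, -1, "+" if sign > 0 else "-"))
        for k in range(1, 6):
            dyad_rows.append(
                ("chrT", tss + sign * (60 + (k - 1) * 165), gid, k, "+" if sign > 0 else "-")
            )
    dyads = pd.DataFrame(dyad_rows, columns=["chrom", "pos", "gene_id", "index", "strand"])
    ndr = pd.DataFrame(
        {
            "chrom": ["chrT", "chrT"],
            "center": [2000 - 80, 12000 + 80],
            "width": [30, 30],
            "weight": [1.0, 1.0],
            "gene_id": ["gA", "gB"],
        }
    )
    g = synth.GenomeModel({"chrT": 20000}, genes, dyads, ndr)
    g.validate()
    return g
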