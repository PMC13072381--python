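import numpy as np
import pandas as pd
import pytest

from specklemap import synthgen as gen
from specklemap.containers import GenotypeMatrix, PhenotypeVector


@pytest.fixture(scope="session")
def small_panel():
    """30 individuals x 200 loci, two subpopulations, some missingness."""
    spec = gen.PanelSimSpec(
        n_ind=30, K_true=2, fst=0.2, n_loci=200,
        chrom_lengths={"1": 100_000, "2": 100_000}, ld_rho=0.5,
        causal=[(5, 1.2), (120, -0.8)], h2_target=0.5,
        missing_rate=0.05, seed=2,
    )
    return gen.simulate_population(spec)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_panel):
    gm, pheno, truth = small_panel
    out = tmp_path_factory.mktemp("fixtures")
    ct = gen.simulate_ct_table(["2D", "10D"], 3, {"10D": -1.0}, seed=4)
    paths = gen.write_fixtures(
        str(out), panel=gm, panel_pheno=pheno, truth=truth, ct=ct,
        seed=2, overwrite=True,
    )
    return paths


@pytest.fixture
def toy_matrix():
    """Deterministic 6x4 genotype matrix for hand-checked computations."""
    g = np.array(
        [
            [0, 1, 2, 0],
            [1, 1, 0, 0],
            [2, 0, 1, 0],
            [0, 2, 2, 1],
            [1, 0, 0, 1],
            [2, 1, 1, 0],
        ],
        dtype=float,
    )
    loci = pd.DataFrame(
        {
            "chrom": ["1", "1", "1", "2"],
            "pos": [100, 2000, 60_000, 500],
            "ref": ["A", "C", "G", "T"],
            "alt": ["T", "G", "A", "C"],
        }
    )
    ind = pd.DataFrame({"id": [f"i{k}" for k in range(6)], "group": ["x"] * 6})
    return GenotypeMatrix(genotypes=g, loci=loci, individuals=ind)


def make_pheno(values, **kw):
    return PhenotypeVector(values=np.asarray(values), **kw)
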