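import numpy as np
import pandas as pd
import pytest

from heterochiasma.io import CODE_A, CODE_H, CODE_MISSING, GenotypeMatrix, MarkerMap
from heterochiasma import simulate as sim


def make_matrix(code_rows, positions=None, chrom="c1"):
    """Build a GenotypeMatrix from a list of per-plant code lists."""
    arr = np.asarray(code_rows, dtype=np.int8)
    n_markers = arr.shape[1]
    if positions is None:
        positions = (np.arange(n_markers) + 1) * 1_000_000
    mmap = MarkerMap(
        pd.DataFrame(
            {
                "chrom": chrom,
                "pos": positions,
                "marker": [f"{chrom}_m{j:03d}" for j in range(n_markers)],
            }
        )
    )
    calls = pd.DataFrame(
        arr, index=[f"p{i:04d}" for i in range(arr.shape[0])], columns=mmap.marker_names
    )
    return GenotypeMatrix(calls, mmap)


def make_spec(L=1.0, phys=20_000_000, n_markers=40, name="c1", cen=(9_000_000, 11_000_000), knots=None):
    return sim.ChromosomeSpec(
        name=name,
        genetic_length=L,
        physical_length=phys,
        marker_positions=tuple(np.linspace(1, phys, n_markers).astype(int)),
        centromere_span=cen,
        map_knots=knots,
    )


@pytest.fixture(scope="session")
def small_population():
    """One simulated chromosome: L = 1.0 M, nu = 3, 500 plants, 30 markers."""
    spec = make_spec(L=1.0, n_markers=30)
    return sim.simulate_population([spec], {"c1": sim.GammaModel(3.0)}, 500, seed=7), spec


@pytest.fixture(scope="session")
def clean_population():
    """Error/missing-free population at nu = 1 for exactness checks."""
    spec = make_spec(L=0.9, n_markers=25)
    return sim.simulate_population([spec], {"c1": sim.GammaModel(1.0)}, 800, seed=11), spec
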