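import numpy as np
import pandas as pd
import pytest

import aimpanel as ap


@pytest.fixture
def toy_structure_file(tmp_path):
    """2 individuals x 3 loci, one missing call, canonical dialect."""
    text = (
        "L1\tL2\tL3\n"
        "ind1\tpopA\t120\t200\t-9\n"
        "ind1\tpopA\t124\t200\t-9\n"
        "ind2\tpopB\t120\t204\t300\n"
        "ind2\tpopB\t120\t204\t304\n"
    )
    path = tmp_path / "toy.str"
    path.write_text(text)
    return path


@pytest.fixture
def small_matrix():
    """4 individuals, 2 loci, no missing data; two populations."""
    calls = np.array(
        [
            [[120, 124], [200, 204]],
            [[120, 120], [200, 200]],
            [[124, 124], [204, 204]],
            [[120, 124], [200, 204]],
        ]
    )
    g = ap.GenotypeMatrix.from_calls(["a", "b", "c", "d"], ["L1", "L2"], calls)
    meta = pd.DataFrame(
        {
            "sample_id": ["a", "b", "c", "d"],
            "population_label": ["popA", "popA", "popB", "popB"],
            "declared_group": [None] * 4,
            "role": ["reference"] * 4,
        }
    )
    return g, meta


@pytest.fixture(scope="session")
def sim_three_pops():
    """3 well-separated populations (F = 0.25) plus 30 admixed queries."""
    cfg = ap.SimulationConfig(
        k_true=3, n_loci=36, n_alleles=10, F=0.25, n_ref=50,
        cohorts=(ap.Cohort("admixed", 30, alpha=(1.0, 1.0, 1.0)),),
        seed=2,
    )
    return ap.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def random_matrix():
    """A 20 x 5 multi-allelic matrix with some missing calls."""
    rng = np.random.default_rng(42)
    calls = 100 + 2 * rng.integers(0, 6, size=(20, 5, 2))
    drop = rng.random((20, 5)) < 0.1
    calls[drop] = -9
    g = ap.GenotypeMatrix.from_calls(
        [f"s{i}" for i in range(20)], [f"L{j}" for j in range(5)], calls
    )
    pops = {"popA": [f"s{i}" for i in range(10)], "popB": [f"s{i}" for i in range(10, 20)]}
    return g, pops
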