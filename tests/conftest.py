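import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def small_run():
    """One compact telescope run on a transitive-chain benchmark,
    shared by tests that inspect different facets of the same result."""
    from metatelescope.synthetic import FamilySpec, make_benchmark
    from metatelescope.telescope import run_telescope_data

    bench = make_benchmark(
        314, spec=FamilySpec(M=90, seed=314), n_intermediates=10,
        n_decoy_contigs=15, n_decoy_proteins=120,
    )
    result = run_telescope_data(
        bench.seed_family, [bench.contigs], [("org1", bench.proteome)],
        family_name=bench.lineage.name, calib_n=400, seed=314,
    )
    return bench, result
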