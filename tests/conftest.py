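import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import presenter as ps

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def model():
    """Bundled seeded toy affinity model (8-mers)."""
    return ps.toy_model(seed=1)


@pytest.fixture(scope="session")
def small_proteome():
    return ps.simulate_proteome(n_proteins=20, length=120, seed=2)


@pytest.fixture(scope="session")
def small_design(small_proteome, model):
    """A 50-member wild-type library plus mutants on the small proteome."""
    kmers = ps.enumerate_kmers(small_proteome, 8)
    ic50 = ps.predict_ic50_many(list(kmers), model)
    cfg = ps.LibraryDesignConfig(n_select=50, seed=3)
    wt = ps.select_wildtype_library(kmers, ic50.to_dict(), cfg)
    cache = ic50.to_dict()

    def ic50_of(p, _m=model, _c=cache):
        if p not in _c:
            _c[p] = ps.predict_ic50(p, _m)
        return _c[p]

    mutants, unmutable = ps.build_mutant_library(wt, set(kmers), ic50_of, cfg)
    return {
        "kmers": kmers,
        "ic50_of": ic50_of,
        "config": cfg,
        "wildtype": wt,
        "mutants": mutants,
        "unmutable": unmutable,
    }


@pytest.fixture(scope="session")
def small_pool(small_design):
    peptides = [r.peptide for r in small_design["wildtype"][:20]]
    return ps.build_pool(peptides, seed=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
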