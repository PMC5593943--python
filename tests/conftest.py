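import numpy as np
import pytest

from rrnadip.catalog import Catalog, RrnaRecord
from rrnadip.simulate import SimulationConfig, make_reference, table2_fixture


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """One short record per category; no decoys, no errors."""
    return SimulationConfig(
        seed=11,
        n_records_per_category=(1,) * 7,
        record_length_range=(200, 400),
        n_reads={("normal", "hMeDIP"): 200, ("precocious", "hMeDIP"): 200},
        substitution_error_rate=0.0,
        decoy_fraction=0.0,
    )


@pytest.fixture(scope="session")
def tiny_catalog(tiny_config) -> Catalog:
    return make_reference(tiny_config)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def toy3_catalog() -> Catalog:
    """Three short references across two categories (for oracle comparisons)."""
    rng = np.random.default_rng(20250929)
    recs = [
        RrnaRecord.build(
            "TOYA01", "18S ribosomal RNA gene, partial sequence", _random_seq(rng, 250)
        ),
        RrnaRecord.build(
            "TOYB01", "28S ribosomal RNA gene, partial sequence", _random_seq(rng, 250)
        ),
        RrnaRecord.build(
            "TOYB02", "28S ribosomal RNA gene, partial sequence", _random_seq(rng, 250)
        ),
    ]
    return Catalog(recs)


@pytest.fixture(scope="session")
def table2():
    return table2_fixture()
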