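import numpy as np
import pytest

from nichekit import EnvStack, OccurrenceRecord


@pytest.fixture
def small_stack() -> EnvStack:
    """A deterministic 10x10 two-layer stack with one NA cell at (3, 3)."""
    rng = np.random.default_rng(42)
    a = rng.standard_normal((10, 10))
    b = rng.standard_normal((10, 10))
    b[3, 3] = np.nan
    return EnvStack({"temp": a, "wet": b}, origin=(-50.0, 10.0), cell_size=0.1)


def make_records(coords, taxon="sp", **kw):
    return [OccurrenceRecord(taxon, lon, lat, **kw) for lon, lat in coords]
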