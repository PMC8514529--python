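import numpy as np
import pytest

from crinosize.series import GenusRecord, TraitSeries
from crinosize.timescale import default_timescale


@pytest.fixture(scope="session")
def ts():
    return default_timescale()


@pytest.fixture(scope="session")
def ten_genus_table(ts):
    """Ten genera with hand-chosen ranges spanning the Ordovician-Silurian."""
    stages = ts.stages
    specs = [
        ("Alpha", "Camerata", "other", 0, 2, 1.2),
        ("Beta", "Camerata", "other", 1, 1, 0.4),
        ("Gamma", "Pentacrinoidea", "Disparida", 0, 5, -0.3),
        ("Delta", "Pentacrinoidea", "Cladida", 3, 6, 0.9),
        ("Epsilon", "Pentacrinoidea", "Cladida", 4, 4, -1.1),
        ("Zeta", "Camerata", "other", 2, 7, 2.0),
        ("Eta", "Pentacrinoidea", "Disparida", 5, 9, -0.6),
        ("Theta", "Pentacrinoidea", "other", 6, 8, 0.1),
        ("Iota", "Camerata", "other", 7, 10, 1.5),
        ("Kappa", "Pentacrinoidea", "Cladida", 9, 12, -0.2),
    ]
    return [
        GenusRecord(name, sub, parv, stages[i], stages[j], size)
        for name, sub, parv, i, j, size in specs
    ]


def make_series(mean, t=None, eps=0.01, n_per_bin=10):
    """A TraitSeries from explicit bin means with constant sampling error."""
    mean = np.asarray(mean, dtype=float)
    m = len(mean)
    t = np.arange(m, dtype=float) if t is None else np.asarray(t, dtype=float)
    return TraitSeries(
        stages=tuple(f"s{i:02d}" for i in range(m)),
        elapsed_time=t,
        mean=mean,
        variance=np.full(m, eps * n_per_bin),
        n=np.full(m, float(n_per_bin)),
    )


@pytest.fixture
def series_factory():
    return make_series
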