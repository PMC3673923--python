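import numpy as np
import pytest

from fossilprior.strat import (
    FossilRangeDataset,
    StratBin,
    StratTimescale,
    TaxonRange,
    load_timescale,
)

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass


@pytest.fixture(scope="session")
def isc():
    return load_timescale("ISC_stages")


@pytest.fixture(scope="session")
def uniform_ts():
    """A simple uniform timescale: 60 bins of 5 Ma spanning 300-0 Ma."""
    bins = tuple(
        StratBin(f"u{i:02d}", 300.0 - 5.0 * i, 300.0 - 5.0 * (i + 1))
        for i in range(60)
    )
    return StratTimescale("uniform_5Ma", bins)


def make_dataset(timescale, rows, label="test"):
    """rows: (taxon, first_bin_name, last_bin_name)."""
    ranges = tuple(
        TaxonRange(t, timescale.bin_named(f), timescale.bin_named(l))
        for t, f, l in rows
    )
    return FossilRangeDataset(timescale, ranges, clade_label=label)


@pytest.fixture(scope="session")
def toy_dataset(isc):
    from fossilprior.cli import TOY_RANGES

    return make_dataset(isc, TOY_RANGES, label="toy")
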