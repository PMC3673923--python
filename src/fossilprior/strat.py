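"""Stratigraphic timescales, fossil range data and boundary-crosser counts.

Ages are in Ma before present, so "older" means numerically larger.  A
timescale is an ordered sequence of contiguous bins from oldest to youngest;
index 0 is the oldest bin.  A numeric age ``x`` is assigned to the bin whose
interval ``(younger_bound, older_bound]`` contains it, i.e. an age falling
exactly on a shared boundary belongs to the *younger* of the two bins (the
boundary instant is the first instant of the younger interval in forward
time).  The youngest bin is closed at 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import RangeDataError, TimescaleError

logger = logging.getLogger("fossilprior")

_BUILTIN_SCHEMES = {
    "ISC_stages": "isc_stages.tsv",  # 2004 timescale calibration of ages
    "ISC_stages_2013": "isc_stages_2013.tsv",
    "PBDB_10Ma": "pbdb_10ma.tsv",
}

_BOUND_TOL = 1e-9


@dataclass(frozen=True)
class StratBin:
    """A named interval of geologic time with absolute age bounds in Ma."""

    name: str
    older_bound: float
    younger_bound: float

    def __post_init__(self):
        if not self.older_bound > self.younger_bound:
            raise TimescaleError(
                f"bin {self.name!r}: older_bound ({self.older_bound}) must exceed "
                f"younger_bound ({self.younger_bound})"
            )

    @property
    def duration(self) -> float:
        """Temporal length of the bin in Ma."""
        return self.older_bound - self.younger_bound

    def contains_age(self, age: float) -> bool:
        """Whether ``age`` falls in this bin under the (younger, older] convention."""
        if self.younger_bound == 0 and age == 0:
            return True
        return self.younger_bound < age <= self.older_bound


@dataclass(frozen=True)
class StratTimescale:
    """Ordered, contiguous stratigraphic bins from oldest to youngest."""

    scheme_name: str
    bins: tuple[StratBin, ...]

    def __post_init__(self):
        if not self.bins:
            raise TimescaleError("timescale has no bins")
        for older, younger in zip(self.bins, self.bins[1:]):
            if abs(older.younger_bound - younger.older_bound) > _BOUND_TOL:
                raise TimescaleError(
                    f"bins {older.name!r} and {younger.name!r} are not contiguous: "
                    f"{older.younger_bound} != {younger.older_bound}"
                )
        if abs(self.bins[-1].younger_bound) > _BOUND_TOL:
            raise TimescaleError(
                f"youngest bin {self.bins[-1].name!r} must reach the present (0 Ma)"
            )
        object.__setattr__(
            self, "_index", {b.name: i for i, b in enumerate(self.bins)}
        )

    def __len__(self) -> int:
        return len(self.bins)

    def __iter__(self):
        return iter(self.bins)

    @property
    def span(self) -> float:
        """Total age span covered, in Ma (older bound of the oldest bin)."""
        return self.bins[0].older_bound

    def index(self, item: StratBin | str) -> int:
        name = item.name if isinstance(item, StratBin) else item
        try:
            return self._index[name]
        except KeyError:
            raise TimescaleError(
                f"bin {name!r} is not part of timescale {self.scheme_name!r}"
            ) from None

    def bin_named(self, name: str) -> StratBin:
        return self.bins[self.index(name)]

    def bin_containing(self, age: float) -> StratBin:
        """Bin whose (younger, older] interval contains ``age``."""
        if age < 0 or age > self.span:
            raise RangeDataError(
                f"age {age} Ma lies outside timescale {self.scheme_name!r} "
                f"(span 0-{self.span} Ma)"
            )
        for b in self.bins:
            if b.contains_age(age):
                return b
        # Only reachable through floating-point edge cases at internal bounds.
        raise RangeDataError(f"age {age} Ma could not be assigned to a bin")

    def bins_overlapping(self, older_age: float, younger_age: float) -> list[StratBin]:
        """Bins intersecting the age interval [younger_age, older_age].

        A bin is included when some part of the open lifespan of a lineage
        alive over the interval falls inside it: birth strictly older than
        the bin top, death not older than the bin base.
        """
        return [
            b
            for b in self.bins
            if older_age > b.younger_bound and younger_age <= b.older_bound
        ]

    def mean_duration(self, older_limit: float | None = None) -> float:
        """Mean bin duration, optionally over bins intersecting [0, older_limit]."""
        if older_limit is None:
            bins = self.bins
        else:
            bins = [b for b in self.bins if b.younger_bound < older_limit]
        return float(np.mean([b.duration for b in bins]))


@dataclass(frozen=True)
class TaxonRange:
    """Stratigraphic range of one fossil taxon: first (oldest) to last bin."""

    taxon: str
    first_bin: StratBin
    last_bin: StratBin

    def span_bins(self, timescale: StratTimescale) -> int:
        """Number of bins the range covers (1 for a singleton)."""
        return timescale.index(self.last_bin) - timescale.index(self.first_bin) + 1


@dataclass(frozen=True)
class OccurrenceSet:
    """All individual occurrences of one taxon (one bin reference each)."""

    taxon: str
    occurrences: tuple[StratBin, ...]

    def __post_init__(self):
        if not self.occurrences:
            raise RangeDataError(f"taxon {self.taxon!r} has no occurrences")

    def to_range(self, timescale: StratTimescale) -> TaxonRange:
        idx = [timescale.index(b) for b in self.occurrences]
        return TaxonRange(
            self.taxon, timescale.bins[min(idx)], timescale.bins[max(idx)]
        )


@dataclass(frozen=True)
class FossilRangeDataset:
    """A set of taxon ranges expressed on one timescale."""

    timescale: StratTimescale
    ranges: tuple[TaxonRange, ...]
    clade_label: str = ""

    def __post_init__(self):
        if not self.ranges:
            raise RangeDataError("dataset has no taxon ranges")
        for r in self.ranges:
            i0 = self.timescale.index(r.first_bin)
            i1 = self.timescale.index(r.last_bin)
            if i0 > i1:
                raise RangeDataError(
                    f"taxon {r.taxon!r}: first bin {r.first_bin.name!r} is younger "
                    f"than last bin {r.last_bin.name!r}"
                )

    def __len__(self) -> int:
        return len(self.ranges)

    def first_last_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Vectors of (first, last) bin indices per taxon, timescale order."""
        first = np.array([self.timescale.index(r.first_bin) for r in self.ranges])
        last = np.array([self.timescale.index(r.last_bin) for r in self.ranges])
        return first, last


@dataclass(frozen=True)
class BinCrossingCounts:
    """The four fundamental range classes relative to one bin's boundaries."""

    n_bt: int  # cross both the lower (older) and upper (younger) boundary
    n_bL: int  # cross only the lower boundary
    n_Ft: int  # cross only the upper boundary
    n_FL: int  # confined to the bin
    bin: StratBin | None = None

    @property
    def n_b(self) -> int:
        """Lineages crossing the lower (older) boundary."""
        return self.n_bt + self.n_bL

    @property
    def n_t(self) -> int:
        """Lineages crossing the upper (younger) boundary."""
        return self.n_bt + self.n_Ft

    @property
    def total(self) -> int:
        """All ranges intersecting the bin."""
        return self.n_bt + self.n_bL + self.n_Ft + self.n_FL


# ---------------------------------------------------------------------------
# I/O


def _timescale_from_frame(scheme_name: str, table: pd.DataFrame) -> StratTimescale:
    required = {"name", "older_bound", "younger_bound"}
    if not required.issubset(table.columns):
        raise TimescaleError(
            f"timescale table needs columns {sorted(required)}, got "
            f"{list(table.columns)}"
        )
    table = table.sort_values("older_bound", ascending=False)
    bins = tuple(
        StratBin(str(r["name"]), float(r["older_bound"]), float(r["younger_bound"]))
        for _, r in table.iterrows()
    )
    return StratTimescale(scheme_name, bins)


def load_timescale(scheme_name: str, custom_table_path=None) -> StratTimescale:
    """Load a built-in binning scheme or a custom ``name/older/younger`` table."""
    if custom_table_path is not None:
        table = pd.read_csv(custom_table_path, sep=None, engine="python", comment="#")
        return _timescale_from_frame(scheme_name, table)
    try:
        fname = _BUILTIN_SCHEMES[scheme_name]
    except KeyError:
        raise TimescaleError(
            f"unknown scheme {scheme_name!r}; built-in schemes are "
            f"{sorted(_BUILTIN_SCHEMES)} (or pass custom_table_path)"
        ) from None
    with resources.files("fossilprior.data").joinpath(fname).open() as fh:
        table = pd.read_csv(fh, sep="\t", comment="#")
    return _timescale_from_frame(scheme_name, table)


def load_ranges(path, timescale: StratTimescale, clade_label: str = "") -> FossilRangeDataset:
    """Read a delimited taxon range file onto ``timescale``.

    Accepts either bin-name columns (``taxon, first, last``) or numeric age
    columns (``taxon, first_ma, last_ma``); numeric ages are snapped to the
    containing bin.
    """
    table = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols = set(table.columns)
    ranges = []
    if {"taxon", "first", "last"}.issubset(cols):
        for _, row in table.iterrows():
            first = timescale.bin_named(str(row["first"]))
            last = timescale.bin_named(str(row["last"]))
            ranges.append(TaxonRange(str(row["taxon"]), first, last))
    elif {"taxon", "first_ma", "last_ma"}.issubset(cols):
        for _, row in table.iterrows():
            first = timescale.bin_containing(float(row["first_ma"]))
            last = timescale.bin_containing(float(row["last_ma"]))
            ranges.append(TaxonRange(str(row["taxon"]), first, last))
    else:
        raise RangeDataError(
            "range file must have columns taxon,first,last (bin names) or "
            f"taxon,first_ma,last_ma (ages in Ma); got {sorted(cols)}"
        )
    names = [r.taxon for r in ranges]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        warnings.warn(
            f"duplicate taxon ids kept as separate lineages: {sorted(dupes)}",
            stacklevel=2,
        )
    dataset = FossilRangeDataset(timescale, tuple(ranges), clade_label)
    oldest = min(ranges, key=lambda r: timescale.index(r.first_bin)).first_bin
    logger.info(
        "loaded %d taxon ranges (%s); oldest occupied bin %s (base %.4g Ma)",
        len(ranges), clade_label or path, oldest.name, oldest.older_bound,
    )
    return dataset


def write_ranges(dataset: FossilRangeDataset, path) -> None:
    """Write a dataset back to TSV with bin-name columns (round-trips load_ranges)."""
    pd.DataFrame(
        {
            "taxon": [r.taxon for r in dataset.ranges],
            "first": [r.first_bin.name for r in dataset.ranges],
            "last": [r.last_bin.name for r in dataset.ranges],
        }
    ).to_csv(path, sep="\t", index=False)


def load_occurrences(path, timescale: StratTimescale) -> list[OccurrenceSet]:
    """Read a ``taxon,bin`` occurrence file (one row per occurrence)."""
    table = pd.read_csv(path, sep=None, engine="python", comment="#")
    if not {"taxon", "bin"}.issubset(table.columns):
        raise RangeDataError("occurrence file must have columns taxon,bin")
    out = []
    for taxon, grp in table.groupby("taxon", sort=False):
        occ = tuple(timescale.bin_named(str(b)) for b in grp["bin"])
        out.append(OccurrenceSet(str(taxon), occ))
    return out


def write_occurrences(occsets: Iterable[OccurrenceSet], path) -> None:
    rows = [(o.taxon, b.name) for o in occsets for b in o.occurrences]
    pd.DataFrame(rows, columns=["taxon", "bin"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Boundary-crosser bookkeeping


def classify_bin_crossers(dataset: FossilRangeDataset, bin: StratBin) -> BinCrossingCounts:
    """Partition ranges intersecting ``bin`` into the four crossing classes.

    A range crosses the lower (older) boundary iff its first bin is strictly
    older than ``bin``; it crosses the upper (younger) boundary iff its last
    bin is strictly younger.
    """
    k = dataset.timescale.index(bin)
    n_bt = n_bL = n_Ft = n_FL = 0
    for r in dataset.ranges:
        i0 = dataset.timescale.index(r.first_bin)
        i1 = dataset.timescale.index(r.last_bin)
        if not (i0 <= k <= i1):
            continue
        lower = i0 < k
        upper = i1 > k
        if lower and upper:
            n_bt += 1
        elif lower:
            n_bL += 1
        elif upper:
            n_Ft += 1
        else:
            n_FL += 1
    return BinCrossingCounts(n_bt, n_bL, n_Ft, n_FL, bin=bin)


def oldest_bin_diversity(dataset: FossilRangeDataset) -> tuple[StratBin, int]:
    """Oldest occupied bin and the number of ranges intersecting it.

    The bin's older bound is the minimum-age offset of the clade; the count
    is the observed first-bin diversity n of the likelihood model.  For the
    oldest occupied bin, ranges intersecting it and ranges first appearing
    in it are the same set.
    """
    first, last = dataset.first_last_indices()
    k = int(first.min())
    n = int(np.sum((first <= k) & (last >= k)))
    return dataset.timescale.bins[k], n
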