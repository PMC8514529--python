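"""Genus range tables and stage-binned trait time series.

Each genus carries a single log10 biovolume for its whole stratigraphic
range (holotype-of-type-species convention), so a genus contributes that
one value to every stage bin its range intersects ("range-through with
constant size"). Bin statistics are the unweighted mean, the unbiased
sample variance and the genus count; elapsed time runs forward in Myr
from the first included stage's midpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .geometry import SHAPES, SolidSpec, log_biovolume, solid_volume
from .timescale import GeologicTimescale

__all__ = [
    "SUBCLASSES",
    "PARVCLASSES",
    "GenusRecord",
    "TraitSeries",
    "EmptySeriesError",
    "Cohorts",
    "load_genus_table",
    "records_to_frame",
    "bin_series",
    "stage_cohorts",
]

SUBCLASSES = ("Camerata", "Pentacrinoidea", "unassigned")
PARVCLASSES = ("Disparida", "Cladida", "other", "unassigned")


class EmptySeriesError(ValueError):
    """No genus falls in the requested clade filter / stage interval."""


@dataclass(frozen=True)
class GenusRecord:
    """One genus: clade path, stratigraphic range, single log10 biovolume."""

    genus: str
    subclass: str
    parvclass: str
    first_stage: str
    last_stage: str
    log_size: float

    def validate(self, timescale: GeologicTimescale) -> None:
        if self.subclass not in SUBCLASSES:
            raise ValueError(
                f"{self.genus}: subclass {self.subclass!r} not in {SUBCLASSES}"
            )
        if self.parvclass not in PARVCLASSES:
            raise ValueError(
                f"{self.genus}: parvclass {self.parvclass!r} not in {PARVCLASSES}"
            )
        i, j = timescale.index(self.first_stage), timescale.index(self.last_stage)
        if i > j:
            raise ValueError(
                f"{self.genus}: first_stage {self.first_stage!r} is younger than "
                f"last_stage {self.last_stage!r}"
            )
        if not np.isfinite(self.log_size):
            raise ValueError(f"{self.genus}: log_size must be finite")


@dataclass(frozen=True)
class TraitSeries:
    """A stage-binned trait time series of log10 biovolume.

    ``elapsed_time`` is Myr since the first included stage's midpoint
    (zero at the first bin, strictly increasing). ``variance`` is the
    unbiased sample variance per bin; for singleton bins the pooled
    within-bin variance of the whole series is substituted and the bin
    index recorded in ``pooled_variance_bins``.
    """

    stages: tuple[str, ...]
    elapsed_time: np.ndarray
    mean: np.ndarray
    variance: np.ndarray
    n: np.ndarray
    pooled_variance_bins: tuple[int, ...] = ()
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = len(self.stages)
        for name in ("elapsed_time", "mean", "variance", "n"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (m,):
                raise ValueError(f"{name} must have length {m}, got {arr.shape}")
        if m == 0:
            raise EmptySeriesError("trait series has no bins")
        if (self.n < 1).any():
            raise ValueError("every bin must contain at least one genus")
        if (self.variance < 0).any():
            raise ValueError("bin variances must be non-negative")
        t = self.elapsed_time
        if abs(t[0]) > 1e-9 or (np.diff(t) <= 0).any():
            raise ValueError("elapsed_time must start at 0 and strictly increase")

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def eps(self) -> np.ndarray:
        """Per-bin sampling-error variance of the mean, variance_i / n_i."""
        return self.variance / self.n

    @property
    def se(self) -> np.ndarray:
        """Standard error of each bin mean, sqrt(variance_i / n_i)."""
        return np.sqrt(self.eps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": self.stages,
                "elapsed_myr": self.elapsed_time,
                "mean": self.mean,
                "variance": self.variance,
                "n": self.n.astype(int),
                "pooled_variance": [
                    i in self.pooled_variance_bins for i in range(len(self))
                ],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TraitSeries":
        pooled = ()
        if "pooled_variance" in frame.columns:
            pooled = tuple(np.flatnonzero(frame["pooled_variance"].to_numpy(bool)))
        return cls(
            stages=tuple(str(s) for s in frame["stage"]),
            elapsed_time=frame["elapsed_myr"].to_numpy(float),
            mean=frame["mean"].to_numpy(float),
            variance=frame["variance"].to_numpy(float),
            n=frame["n"].to_numpy(float),
            pooled_variance_bins=pooled,
        )


# ---------------------------------------------------------------------------
# loading


def _row_log_size(row: pd.Series, columns: Sequence[str]) -> float:
    if "log_biovolume" in columns and pd.notna(row.get("log_biovolume")):
        return float(row["log_biovolume"])
    if "biovolume_mm3" in columns and pd.notna(row.get("biovolume_mm3")):
        return log_biovolume(float(row["biovolume_mm3"]))
    if "shape" in columns and pd.notna(row.get("shape")):
        shape = str(row["shape"]).strip()
        required = SHAPES.get(shape, ((), None))[0]
        dims = {}
        for name in required:
            col = f"dim_{name}"
            if col in columns and pd.notna(row.get(col)):
                dims[name] = float(row[col])
        return log_biovolume(solid_volume(SolidSpec(shape, dims)))
    raise ValueError(
        "no size information: provide log_biovolume, biovolume_mm3, or "
        "shape plus dim_<name> columns"
    )


def load_genus_table(path, timescale: GeologicTimescale) -> list[GenusRecord]:
    """Read and validate a delimited genus table.

    Required columns: genus, subclass, parvclass, first_stage, last_stage,
    and one of log_biovolume / biovolume_mm3 / shape+dim_* (raw solid
    dimensions in mm, converted through the geometry module). Any row
    violating an invariant is rejected; the error message carries the
    1-based data row number.
    """
    frame = pd.read_csv(path, sep=None, engine="python", skipinitialspace=True)
    frame.columns = [str(c).strip() for c in frame.columns]
    required = {"genus", "subclass", "parvclass", "first_stage", "last_stage"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"genus table missing columns: {sorted(missing)}")

    records: list[GenusRecord] = []
    errors: list[str] = []
    seen: set[str] = set()
    for pos, (_, row) in enumerate(frame.iterrows(), start=1):
        try:
            genus = str(row["genus"]).strip()
            if genus in seen:
                raise ValueError(f"duplicate genus {genus!r}")
            rec = GenusRecord(
                genus=genus,
                subclass=str(row["subclass"]).strip(),
                parvclass=str(row["parvclass"]).strip(),
                first_stage=timescale.canonical(row["first_stage"]),
                last_stage=timescale.canonical(row["last_stage"]),
                log_size=_row_log_size(row, frame.columns),
            )
            rec.validate(timescale)
        except (ValueError, KeyError) as exc:
            errors.append(f"row {pos}: {exc}")
            continue
        seen.add(genus)
        records.append(rec)
    if errors:
        raise ValueError(
            "invalid genus table rows:\n  " + "\n  ".join(errors)
        )
    return records


def records_to_frame(records: Iterable[GenusRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genus": r.genus,
                "subclass": r.subclass,
                "parvclass": r.parvclass,
                "first_stage": r.first_stage,
                "last_stage": r.last_stage,
                "log_biovolume": r.log_size,
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# binning


CladeFilter = Mapping[str, str] | Callable[[GenusRecord], bool] | None


def _passes(record: GenusRecord, clade_filter: CladeFilter) -> bool:
    if clade_filter is None:
        return True
    if callable(clade_filter):
        return bool(clade_filter(record))
    return all(getattr(record, k) == v for k, v in clade_filter.items())


def bin_series(
    records: Sequence[GenusRecord],
    timescale: GeologicTimescale,
    clade_filter: CladeFilter = None,
    interval: tuple[str, str] | None = None,
) -> TraitSeries:
    """Bin genus sizes into a per-stage trait series.

    Each genus contributes its single log_size to every stage of its range
    that intersects *interval* (a contiguous (first, last) stage span;
    default the whole timescale). *clade_filter* is either a mapping of
    record fields to required values (e.g. ``{"subclass": "Camerata"}``)
    or a predicate over records. Stages with no genera are dropped with a
    warning.
    """
    if interval is None:
        span = timescale.stages
    else:
        span = timescale.span(*interval)
    values: dict[str, list[float]] = {s: [] for s in span}
    lo, hi = timescale.index(span[0]), timescale.index(span[-1])
    for rec in records:
        if not _passes(rec, clade_filter):
            continue
        i = max(timescale.index(rec.first_stage), lo)
        j = min(timescale.index(rec.last_stage), hi)
        for k in range(i, j + 1):
            values[timescale.stages[k]].append(rec.log_size)

    kept = [s for s in span if values[s]]
    if not kept:
        raise EmptySeriesError(
            f"no genus matches clade filter {clade_filter!r} within interval {interval!r}"
        )
    dropped = [s for s in span if not values[s]]
    if dropped:
        warnings.warn(f"dropping empty stage bins: {dropped}", stacklevel=2)

    mean = np.array([np.mean(values[s]) for s in kept])
    n = np.array([len(values[s]) for s in kept], dtype=float)
    variance = np.array(
        [np.var(values[s], ddof=1) if len(values[s]) > 1 else np.nan for s in kept]
    )

    # singleton bins: substitute pooled within-bin variance (the likelihood
    # machinery needs a finite sampling-error term eps_i = var_i / n_i)
    pooled_bins = tuple(int(i) for i in np.flatnonzero(np.isnan(variance)))
    if pooled_bins:
        weights = n - 1.0
        with_var = ~np.isnan(variance)
        if with_var.any():
            pooled = float(
                np.sum(variance[with_var] * weights[with_var])
                / np.sum(weights[with_var])
            )
        else:
            pooled = 0.0
        variance[~with_var] = pooled

    mid0 = timescale.midpoint_ma(kept[0])
    elapsed = np.array([mid0 - timescale.midpoint_ma(s) for s in kept])
    return TraitSeries(
        stages=tuple(kept),
        elapsed_time=elapsed,
        mean=mean,
        variance=variance,
        n=n,
        pooled_variance_bins=pooled_bins,
        metadata={
            "clade_filter": dict(clade_filter) if isinstance(clade_filter, Mapping) else repr(clade_filter),
            "interval": (span[0], span[-1]),
            "dropped_stages": tuple(dropped),
        },
    )


# ---------------------------------------------------------------------------
# cohorts


class Cohorts(NamedTuple):
    """Stage-boundary cohorts used by the extinction/origination decomposition."""

    extant: tuple[GenusRecord, ...]
    victims: tuple[GenusRecord, ...]
    survivors: tuple[GenusRecord, ...]
    originators_next: tuple[GenusRecord, ...]


def stage_cohorts(
    records: Sequence[GenusRecord], stage: str, timescale: GeologicTimescale
) -> Cohorts:
    """Partition genera at the *stage* -> successor boundary.

    extant: range includes *stage*; victims: extant with last_stage ==
    *stage*; survivors: the rest of the extant cohort; originators_next:
    genera whose first_stage is the successor stage.
    """
    k = timescale.index(stage)
    succ = timescale.successor(stage)  # raises for the youngest stage
    extant, victims, survivors, originators = [], [], [], []
    for rec in records:
        i, j = timescale.index(rec.first_stage), timescale.index(rec.last_stage)
        if i <= k <= j:
            extant.append(rec)
            (victims if j == k else survivors).append(rec)
        if rec.first_stage == succ:
            originators.append(rec)
    return Cohorts(tuple(extant), tuple(victims), tuple(survivors), tuple(originators))
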