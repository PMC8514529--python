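"""Geological timescale handling: ordered stages with base/top ages in Ma.

Ships an editable ICS-style Ordovician-Permian stage table
(Tremadocian through Changhsingian) as package data.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

__all__ = ["GeologicTimescale", "default_timescale"]


class GeologicTimescale:
    """An ordered sequence of geological stages, oldest first.

    Each stage has a base age and a top age in Ma (millions of years before
    present); ages decrease toward the present, so ``base_ma > top_ma`` and
    adjacent stages share a boundary. Stage midpoints,
    ``(base_ma + top_ma) / 2``, provide the numeric time axis for binned
    trait series.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"stage", "base_ma", "top_ma"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"timescale table missing columns: {sorted(missing)}")
        frame = frame.loc[:, ["stage", "base_ma", "top_ma"]].copy()
        frame["stage"] = frame["stage"].astype(str).str.strip()
        if frame["stage"].duplicated().any():
            dupes = frame.loc[frame["stage"].duplicated(), "stage"].tolist()
            raise ValueError(f"duplicate stage names: {dupes}")
        base = frame["base_ma"].to_numpy(float)
        top = frame["top_ma"].to_numpy(float)
        if not (base > top).all():
            bad = frame.loc[base <= top, "stage"].tolist()
            raise ValueError(f"stages with base_ma <= top_ma: {bad}")
        for i in range(len(frame) - 1):
            if abs(top[i] - base[i + 1]) > 1e-9:
                raise ValueError(
                    "stages must be contiguous old->young: "
                    f"{frame['stage'].iloc[i]!r} top {top[i]} != "
                    f"{frame['stage'].iloc[i + 1]!r} base {base[i + 1]}"
                )
        frame["midpoint_ma"] = (base + top) / 2.0
        self._frame = frame.reset_index(drop=True)
        self._index = {s.casefold(): i for i, s in enumerate(frame["stage"])}
        self._exact = {s: i for i, s in enumerate(frame["stage"])}

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "GeologicTimescale":
        return cls(pd.read_csv(path))

    # -- lookups -----------------------------------------------------------
    @property
    def stages(self) -> tuple[str, ...]:
        return tuple(self._frame["stage"])

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def __len__(self) -> int:
        return len(self._frame)

    def __contains__(self, stage: str) -> bool:
        return str(stage).strip().casefold() in self._index

    def canonical(self, stage: str) -> str:
        """Canonical stage name (whitespace-trimmed, case-insensitive match)."""
        return self._frame["stage"].iloc[self.index(stage)]

    def index(self, stage: str) -> int:
        hit = self._exact.get(stage)
        if hit is not None:
            return hit
        key = str(stage).strip().casefold()
        if key not in self._index:
            raise KeyError(
                f"unknown stage {stage!r}; valid stages: {list(self.stages)}"
            )
        return self._index[key]

    def base_ma(self, stage: str) -> float:
        return float(self._frame["base_ma"].iloc[self.index(stage)])

    def top_ma(self, stage: str) -> float:
        return float(self._frame["top_ma"].iloc[self.index(stage)])

    def midpoint_ma(self, stage: str) -> float:
        return float(self._frame["midpoint_ma"].iloc[self.index(stage)])

    def successor(self, stage: str) -> str:
        i = self.index(stage)
        if i + 1 >= len(self):
            raise ValueError(f"stage {stage!r} is the youngest; it has no successor")
        return self.stages[i + 1]

    def span(self, first: str, last: str) -> tuple[str, ...]:
        """Contiguous stage names from *first* to *last* inclusive (old->young)."""
        i, j = self.index(first), self.index(last)
        if i > j:
            raise ValueError(f"stage {first!r} is younger than {last!r}")
        return self.stages[i : j + 1]


def default_timescale() -> GeologicTimescale:
    """The packaged ICS-style Ordovician-Permian stage table."""
    with resources.files("crinosize.data").joinpath("timescale_ics.csv").open("r") as fh:
        return GeologicTimescale(pd.read_csv(fh))
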