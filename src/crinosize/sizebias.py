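"""Size-biased extinction/origination decomposition and distribution tests.

The change in mean log size between a stage and its successor is split
exactly into two parts: what extinction did (survivors' mean minus the
pre-extinction cohort mean) and what origination did (the successor
stage's overall mean minus the survivors' mean). Positive selectivity
(victims larger than survivors) drags the extinction component negative
— the signature of size-biased extinction and, in its aftermath, the
Lilliput effect.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .series import Cohorts, GenusRecord, stage_cohorts
from .timescale import GeologicTimescale

__all__ = [
    "DecompositionResult",
    "KSResult",
    "decompose",
    "decompose_all",
    "extinction_selectivity",
    "ks_two_sample",
    "interval_homogeneity",
]


def _mean(values: Sequence[float]) -> float:
    return float(np.mean(values)) if len(values) else math.nan


@dataclass(frozen=True)
class DecompositionResult:
    """Mean-size change across one stage boundary, partitioned exactly.

    extinction_component = mean_survivors - mean_extant_prev
    origination_component = mean_next - mean_survivors
    total_change = mean_next - mean_extant_prev

    The two components sum to the total by construction. When no genus
    survives the boundary the survivor mean does not exist; both
    components are NaN (flagged via ``survivors_defined``) while
    total_change remains valid.
    """

    stage_prev: str
    stage_next: str
    n_extant: int
    n_victims: int
    n_survivors: int
    n_originators: int
    mean_extant_prev: float
    mean_victims: float
    mean_survivors: float
    mean_originators: float
    mean_next: float
    extinction_component: float
    origination_component: float
    total_change: float
    survivors_defined: bool = True


def decompose(
    records: Sequence[GenusRecord],
    stage: str,
    timescale: GeologicTimescale,
) -> DecompositionResult:
    """Partition the mean-size change from *stage* to its successor.

    Every surviving genus carries its single size value into both stages
    (range-through with constant size), so the successor-stage cohort is
    exactly survivors plus originators.
    """
    cohorts = stage_cohorts(records, stage, timescale)
    extant, victims, survivors, originators = cohorts
    if not extant:
        raise ValueError(f"no genus extant in stage {stage!r}")
    succ = timescale.successor(stage)

    sizes = lambda recs: [r.log_size for r in recs]
    mean_extant = _mean(sizes(extant))
    mean_victims = _mean(sizes(victims))
    mean_survivors = _mean(sizes(survivors))
    mean_originators = _mean(sizes(originators))
    next_sizes = sizes(survivors) + sizes(originators)
    mean_next = _mean(next_sizes)

    defined = len(survivors) > 0
    if defined:
        ext = mean_survivors - mean_extant
        orig = mean_next - mean_survivors
    else:
        ext = orig = math.nan
    total = mean_next - mean_extant
    if not (victims or originators):
        # no turnover at all: the boundary changes nothing
        ext, orig, total = 0.0, 0.0, 0.0

    return DecompositionResult(
        stage_prev=timescale.canonical(stage),
        stage_next=succ,
        n_extant=len(extant),
        n_victims=len(victims),
        n_survivors=len(survivors),
        n_originators=len(originators),
        mean_extant_prev=mean_extant,
        mean_victims=mean_victims,
        mean_survivors=mean_survivors,
        mean_originators=mean_originators,
        mean_next=mean_next,
        extinction_component=ext,
        origination_component=orig,
        total_change=total,
        survivors_defined=defined,
    )


def decompose_all(
    records: Sequence[GenusRecord], timescale: GeologicTimescale
) -> list[DecompositionResult]:
    """Decompose every stage boundary with at least one extant genus."""
    out = []
    for stage in timescale.stages[:-1]:
        try:
            out.append(decompose(records, stage, timescale))
        except ValueError:  # no genus extant in this stage
            continue
    return out


def extinction_selectivity(
    victims_sizes: Sequence[float], survivors_sizes: Sequence[float]
):
    """Mean victim size minus mean survivor size, with a two-sample K-S p.

    Positive values mean larger genera were more likely to go extinct
    (size-biased extinction).
    """
    if len(victims_sizes) == 0 or len(survivors_sizes) == 0:
        raise ValueError("selectivity needs non-empty victim and survivor samples")
    diff = _mean(victims_sizes) - _mean(survivors_sizes)
    ks = ks_two_sample(victims_sizes, survivors_sizes)
    return diff, ks


@dataclass(frozen=True)
class KSResult:
    """Two-sample Kolmogorov-Smirnov comparison."""

    D: float
    p: float
    n1: int
    n2: int


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> KSResult:
    """Two-sided two-sample K-S test with the asymptotic p-value.

    D is the supremum over the pooled sample points of the difference of
    empirical CDFs; p comes from the Kolmogorov distribution at effective
    sample size n1*n2/(n1+n2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("K-S test needs non-empty samples")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return KSResult(D=float(res.statistic), p=float(min(res.pvalue, 1.0)),
                    n1=x.size, n2=y.size)


def interval_homogeneity(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> dict[str, str]:
    """Letter groups from pairwise K-S tests across named intervals.

    Pairs whose size distributions are not significantly different
    (p > alpha) are connected; connected components share a letter, in
    input order. With ``bonferroni`` the threshold is alpha divided by
    the number of pairwise comparisons (off by default).
    """
    names = list(groups)
    for name in names:
        if len(groups[name]) == 0:
            raise ValueError(f"interval group {name!r} is empty")
    n_pairs = max(len(names) * (len(names) - 1) // 2, 1)
    threshold = alpha / n_pairs if bonferroni else alpha

    adjacency = {name: {name} for name in names}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if ks_two_sample(groups[a], groups[b]).p > threshold:
                adjacency[a].add(b)
                adjacency[b].add(a)

    letters: dict[str, str] = {}
    alphabet = iter(string.ascii_lowercase)
    for name in names:
        if name in letters:
            continue
        letter = next(alphabet)
        stack = [name]
        while stack:
            node = stack.pop()
            if node in letters:
                continue
            letters[node] = letter
            stack.extend(adjacency[node] - letters.keys())
    return letters
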