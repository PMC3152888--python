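"""Seed bicluster discovery: iterative mining with a descending support threshold.

The miner is applied repeatedly to a working copy of the binary matrix.  The
first threshold equals the highest single-gene support; every maximal
frequent gene set found becomes a seed (with its phenotype vector taken from
the original, unmodified matrix) and its genes are deleted from the working
matrix.  The loop stops when the threshold would fall below the user-defined
minimum support or no genes remain.  Seed gene sets are therefore pairwise
disjoint.

Two threshold schedules are available: ``support`` (the default) descends
through the distinct single-gene support values still present in the working
matrix; ``decay`` multiplies the threshold by a fixed factor each round.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import extend as _extend
from .biclusters import BiclusterSet
from .matrix import AS_GIVEN, DOWN, UP, BinaryMatrix, ExpressionMatrix, binarize
from .mining import EPS, FrequencyThresholds, mine_maximal_frequent, phenotype

log = logging.getLogger(__name__)


@dataclass
class SeedSchedule:
    """Mining schedule: stop support, cardinality floor and descent rule."""

    min_support: float = 0.05
    c2: int = 2
    schedule: str = "support"  # "support" | "decay"
    decay: float = 0.9
    thresholds_visited: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 < self.min_support <= 1:
            raise ValueError("min_support must be in (0, 1]")
        if self.schedule not in ("support", "decay"):
            raise ValueError("schedule must be 'support' or 'decay'")
        if not 0 < self.decay < 1:
            raise ValueError("decay factor must be in (0, 1)")


def discover_seeds(
    B: BinaryMatrix, sched: SeedSchedule
) -> list[tuple[tuple[int, ...], np.ndarray]]:
    """Ordered (gene set, phenotype vector) seeds; phenotypes from the original matrix."""
    bits = B.bits
    n, m = bits.shape
    working = bits.copy()
    seeds: list[tuple[tuple[int, ...], np.ndarray]] = []
    sched.thresholds_visited = []
    prev_t = np.inf
    while True:
        sup = working.sum(axis=1) / m
        avail = np.unique(sup[sup > 0])
        if avail.size == 0:
            break
        t = float(avail[-1])
        if t >= prev_t - EPS:
            below = avail[avail < prev_t - EPS]
            if below.size == 0:
                break
            t = float(below[-1])
        if sched.schedule == "decay" and np.isfinite(prev_t):
            t = min(t, prev_t * sched.decay)
        if t < sched.min_support - EPS:
            break
        th = FrequencyThresholds(c1=t, c2=sched.c2)
        sets = mine_maximal_frequent(working, th)
        for gs in sets:
            seeds.append((gs, phenotype(gs, B)))
            working[list(gs), :] = False
        n_left = int(np.count_nonzero(working.any(axis=1)))
        log.info(
            "seed iteration: threshold=%.4g, %d maximal sets, %d genes remaining",
            t,
            len(sets),
            n_left,
        )
        sched.thresholds_visited.append(t)
        prev_t = t
    return seeds


def _as_binary(data, c: float, direction: str) -> BinaryMatrix:
    if isinstance(data, BinaryMatrix):
        if direction not in (AS_GIVEN, data.direction):
            raise ValueError(
                f"matrix is pre-binarized as {data.direction!r}; cannot run {direction!r}"
            )
        return data
    return binarize(data, c, direction)


def run_direction(
    data: ExpressionMatrix | BinaryMatrix,
    c: float,
    direction: str,
    alpha: float,
    sched: SeedSchedule | None = None,
    L: float | None = None,
) -> BiclusterSet:
    """Binarize -> mine seeds -> Fisher-extend, for one regulation direction.

    ``L`` optionally applies overlap filtering to this direction's output;
    when running both directions, filter the concatenated set instead.
    """
    sched = sched or SeedSchedule()
    B = _as_binary(data, c, direction)
    seeds = discover_seeds(B, sched)
    bics = []
    for gs, C in seeds:
        b = _extend.extend_bicluster(gs, C, B, alpha, direction=B.direction)
        if b is not None:
            bics.append(b)
    if L is not None:
        bics = _extend.filter_overlap(bics, L)
    params = {
        "direction": B.direction,
        "alpha": alpha,
        "cutoff_c": B.cutoff_c,
        "min_support": sched.min_support,
        "c2": sched.c2,
    }
    return BiclusterSet(bics, list(B.gene_ids), list(B.sample_ids), params)


def run_pipeline(
    data: ExpressionMatrix | BinaryMatrix,
    alpha: float,
    c: float = 2.0,
    direction: str = "both",
    sched: SeedSchedule | None = None,
    L: float = 0.5,
) -> BiclusterSet:
    """Full run: per-direction discovery, concatenation, overlap filtering.

    ``direction``: "up", "down", "both", or "as_given" for pre-binarized input.
    """
    sched = sched or SeedSchedule()
    if isinstance(data, BinaryMatrix) or direction == AS_GIVEN:
        directions = [AS_GIVEN]
    elif direction == "both":
        directions = [UP, DOWN]
    elif direction in (UP, DOWN):
        directions = [direction]
    else:
        raise ValueError(f"unknown direction {direction!r}")
    bics = []
    for d in directions:
        part = run_direction(data, c, d, alpha, sched=sched, L=None)
        bics.extend(part.biclusters)
    bics = _extend.filter_overlap(bics, L)
    gene_ids = list(data.gene_ids)
    sample_ids = list(data.sample_ids)
    params = {
        "direction": direction,
        "alpha": alpha,
        "cutoff_c": None if isinstance(data, BinaryMatrix) else c,
        "min_support": sched.min_support,
        "c2": sched.c2,
        "overlap_L": L,
    }
    return BiclusterSet(bics, gene_ids, sample_ids, params)
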