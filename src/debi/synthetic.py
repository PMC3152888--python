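"""Synthetic expression matrices with implanted biclusters, plus recovery scores.

The generator emulates the classic implanted-bicluster benchmark: a zero
background hosting a diagonal arrangement of elevated blocks, either with a
constant expression level or following an additive model (distinct row and
column offsets on top of the base level, so expression varies over the
conditions).  Two stress axes are available: i.i.d. Gaussian noise scaled
by the block level, and a controlled number of rows/columns shared between
consecutive blocks.

Recovered bicluster sets are scored against the implanted truth with

* the *recovery* score: mean over true biclusters of the best Jaccard
  similarity (gene dimension) to any found bicluster (the reverse
  orientation, *relevance*, is also exposed);
* the *consensus* score: Jaccard similarity on (gene, sample) cell sets,
  optimally one-to-one assigned between the two collections and divided by
  the size of the larger collection, which penalizes over- and
  under-segmentation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .matrix import AS_GIVEN, BinaryMatrix, ExpressionMatrix

log = logging.getLogger(__name__)

CONSTANT = "constant"
ADDITIVE = "additive"


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one implanted-bicluster scenario.

    ``noise`` is the Gaussian noise level relative to the block expression
    level (sigma = noise x level); in binary output mode it is instead the
    bit-flip probability.  ``overlap_degree`` d makes consecutive blocks
    share exactly d genes and d samples.
    """

    n_genes: int = 100
    n_samples: int = 50
    n_biclusters: int = 10
    bic_rows: int = 10
    bic_cols: int = 5
    model: str = CONSTANT
    noise: float = 0.0
    overlap_degree: int = 0
    level: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in (CONSTANT, ADDITIVE):
            raise ValueError("model must be 'constant' or 'additive'")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if not 0 <= self.overlap_degree < min(self.bic_rows, self.bic_cols):
            raise ValueError("overlap_degree must be < min(bic_rows, bic_cols)")

    def block_positions(self) -> list[tuple[range, range]]:
        rs = self.bic_rows - self.overlap_degree
        cs = self.bic_cols - self.overlap_degree
        out = []
        for k in range(self.n_biclusters):
            rows = range(k * rs, k * rs + self.bic_rows)
            cols = range(k * cs, k * cs + self.bic_cols)
            if rows.stop > self.n_genes or cols.stop > self.n_samples:
                raise ValueError(
                    f"bicluster {k} ({rows.stop} x {cols.stop}) exceeds the "
                    f"{self.n_genes} x {self.n_samples} matrix"
                )
            out.append((rows, cols))
        return out


TruthSet = list[tuple[frozenset, frozenset]]


def generate_scenario(
    spec: ScenarioSpec, binary: bool = False
) -> tuple[ExpressionMatrix | BinaryMatrix, TruthSet]:
    """Generate one matrix with implanted biclusters and its truth set.

    Continuous mode returns an :class:`ExpressionMatrix` (log2 scale, zero
    background); ``binary=True`` returns the thresholded matrix with bits
    flipped independently with probability ``spec.noise``.  Truth entries
    are (gene index set, sample index set) pairs.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    positions = spec.block_positions()
    values = np.zeros((spec.n_genes, spec.n_samples))
    for rows, cols in positions:
        if spec.model == CONSTANT:
            values[np.ix_(rows, cols)] = spec.level
        else:
            # additive model: base level plus distinct row/column offsets;
            # offsets are non-negative so every block cell stays at or
            # above the level, i.e. above the fold-change-2 threshold.
            roff = rng.uniform(0.0, spec.level / 2, size=len(rows))
            coff = rng.uniform(0.0, spec.level / 2, size=len(cols))
            values[np.ix_(rows, cols)] = spec.level + roff[:, None] + coff[None, :]
    truth: TruthSet = [
        (frozenset(int(i) for i in rows), frozenset(int(j) for j in cols))
        for rows, cols in positions
    ]
    gene_ids = [f"g{i:04d}" for i in range(spec.n_genes)]
    sample_ids = [f"s{j:04d}" for j in range(spec.n_samples)]
    if binary:
        bits = values >= math.log2(2.0)
        if spec.noise > 0:
            flips = rng.random(bits.shape) < spec.noise
            bits = bits ^ flips
        return BinaryMatrix(gene_ids, sample_ids, bits, AS_GIVEN), truth
    if spec.noise > 0:
        values = values + rng.normal(0.0, spec.noise * spec.level, size=values.shape)
    return ExpressionMatrix(gene_ids, sample_ids, values), truth


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    inter = len(a & b)
    return inter / (len(a) + len(b) - inter)


def _gene_sets(biclusters) -> list[frozenset]:
    return [frozenset(b[0]) for b in biclusters]


def prelic_recovery(found, truth) -> float:
    """Mean over truth of the best gene-set Jaccard match among found.

    Both arguments are sequences of (gene set, sample set) pairs.  Measures
    how completely the implanted biclusters are recovered; insensitive to
    extra found biclusters (see :func:`prelic_relevance` for the reverse).
    """
    if not truth:
        raise ValueError("truth set must be non-empty")
    if not found:
        return 0.0
    fg = _gene_sets(found)
    return float(
        np.mean([max(_jaccard(t, f) for f in fg) for t in _gene_sets(truth)])
    )


def prelic_relevance(found, truth) -> float:
    """Mean over found of the best gene-set Jaccard match among truth."""
    if not found:
        return 0.0
    return prelic_recovery(truth, found)


def _cell_similarity(a, b) -> float:
    """Jaccard index on (gene, sample) cell sets of two biclusters."""
    ga, sa = a
    gb, sb = b
    size_a = len(ga) * len(sa)
    size_b = len(gb) * len(sb)
    inter = len(frozenset(ga) & frozenset(gb)) * len(frozenset(sa) & frozenset(sb))
    union = size_a + size_b - inter
    return inter / union if union else 1.0


def hochreiter_consensus(found, truth) -> float:
    """Optimal-assignment cell-set similarity, penalized by the larger count.

    Pairwise similarities (Jaccard on gene x sample cells) are maximized by
    an exact one-to-one assignment; the summed similarity is divided by
    max(|found|, |truth|).  Symmetric in its arguments.  Two empty sets
    score 1, exactly one empty scores 0.
    """
    found, truth = list(found), list(truth)
    if not found and not truth:
        return 1.0
    if not found or not truth:
        return 0.0
    sim = np.array([[_cell_similarity(f, t) for t in truth] for f in found])
    ri, ci = linear_sum_assignment(-sim)
    return float(sim[ri, ci].sum() / max(len(found), len(truth)))


def run_benchmark(
    models=(CONSTANT, ADDITIVE),
    noise_levels=(0.0, 0.05, 0.10),
    overlap_degrees=(0,),
    n_replicates: int = 10,
    seed: int = 0,
    L: float = 0.25,
    alpha: float | str = "select",
    alpha_grid=None,
    n_random: int = 500,
    min_support: float = 0.05,
    c2: int = 2,
    binary: bool = False,
) -> pd.DataFrame:
    """Grid of scenarios x replicates, each run through the full pipeline.

    ``alpha="select"`` picks alpha per run by maximizing CS over the grid;
    a float fixes it.  Returns one row per run with the recovery, relevance
    and consensus scores of the found biclusters against the implanted
    truth, after overlap filtering at ``L``.
    """
    from . import scoring
    from .seeds import SeedSchedule, run_pipeline

    if alpha_grid is None:
        alpha_grid = scoring.DEFAULT_ALPHA_GRID
    root = np.random.SeedSequence(seed)
    rows = []
    scenario_id = 0
    for model in models:
        for overlap in overlap_degrees:
            for noise in noise_levels:
                for rep in range(n_replicates):
                    child = root.spawn(1)[0]
                    run_seed = int(child.generate_state(1)[0] % 2**31)
                    spec = ScenarioSpec(
                        model=model,
                        noise=noise,
                        overlap_degree=overlap,
                        seed=run_seed,
                    )
                    data, truth = generate_scenario(spec, binary=binary)
                    sched = SeedSchedule(min_support=min_support, c2=c2)
                    if alpha == "select":
                        scan = scoring.scan_alphas(
                            data,
                            grid=alpha_grid,
                            direction=AS_GIVEN if binary else "both",
                            sched=sched,
                            L=L,
                            n_random=n_random,
                            seed=run_seed,
                        )
                        result = scan.best_result
                        used_alpha = scan.best_alpha
                    else:
                        result = run_pipeline(
                            data,
                            alpha=float(alpha),
                            direction=AS_GIVEN if binary else "both",
                            sched=sched,
                            L=L,
                        )
                        used_alpha = float(alpha)
                    found = [
                        (frozenset(b.gene_indices), frozenset(b.sample_indices))
                        for b in result.biclusters
                    ]
                    rows.append(
                        {
                            "scenario_id": scenario_id,
                            "model": model,
                            "noise": noise,
                            "overlap": overlap,
                            "replicate": rep,
                            "seed": run_seed,
                            "alpha": used_alpha,
                            "n_found": len(found),
                            "recovery": prelic_recovery(found, truth),
                            "relevance": prelic_relevance(found, truth),
                            "consensus": hochreiter_consensus(found, truth),
                        }
                    )
                scenario_id += 1
    return pd.DataFrame(rows)
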