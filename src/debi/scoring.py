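"""Bicluster quality scores and randomization-based alpha selection.

A bicluster's raw score I is the negative sum of the natural-log Fisher
p-values of its genes.  I grows with bicluster size, so it is normalized by
the mean score of the same gene set against random phenotype vectors with
the same number of member samples: NI = I / E[I_random].  The total score
CS of a bicluster set is the sum of its NI values; the significance level
alpha is chosen by running the full pipeline over a grid of alphas and
keeping the alpha that maximizes CS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import extend as _extend
from .biclusters import Bicluster, BiclusterSet
from .matrix import AS_GIVEN, DOWN, UP, BinaryMatrix, ExpressionMatrix, binarize
from .seeds import SeedSchedule, discover_seeds

log = logging.getLogger(__name__)

#: alpha grid used by default: log-spaced subset of the dense 1e-2..1e-100 scan.
DEFAULT_ALPHA_GRID = tuple(10.0**-k for k in (2, 4, 8, 16, 32, 64, 100))
#: the dense scan: alpha = 1e-2, 1e-3, ..., 1e-100.
FULL_ALPHA_GRID = tuple(10.0**-k for k in range(2, 101))


def bicluster_score(b: Bicluster) -> float:
    """Raw enrichment score I = -sum_g ln p_g (natural log)."""
    p = np.asarray(b.pvalues, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("stored p-values must lie in (0, 1]")
    return float(-np.log(p).sum())


def expected_score(
    b: Bicluster,
    B: BinaryMatrix,
    n_random: int = 500,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Mean raw score of the bicluster's genes against random phenotypes.

    Each replicate draws, without replacement, a sample subset of the same
    cardinality as the bicluster's sample set, recomputes the per-gene
    Fisher p-values against it, and sums -ln p.  Deterministic for a fixed
    seed / generator.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = np.random.default_rng(rng)
    bits = B.bits
    m = bits.shape[1]
    n_in = b.n_samples
    genes = np.asarray(b.gene_indices)
    K = bits[genes].sum(axis=1).astype(np.int64)

    keys = rng.random((n_random, m))
    idx = np.argpartition(keys, n_in - 1, axis=1)[:, :n_in]
    R = np.zeros((n_random, m), dtype=bool)
    R[np.arange(n_random)[:, None], idx] = True

    counts = bits[genes].astype(np.int64) @ R.T.astype(np.int64)  # genes x reps
    pv = _extend._tail_p_many(counts, K[:, None], n_in, m)
    return float(-np.log(pv).sum(axis=0).mean())


def score_bicluster_set(
    result: BiclusterSet,
    B: BinaryMatrix | dict[str, BinaryMatrix],
    n_random: int = 500,
    seed: int | None = None,
) -> float:
    """Attach I and NI to every bicluster in place; return CS = sum NI.

    ``B`` is the binary matrix the p-values came from, or a mapping from
    regulation direction to matrix when the set mixes directions.
    Biclusters whose randomization mean is zero (every random p-value is 1,
    i.e. the genes carry no signal) get NI = 0 with a warning.
    """
    rng = np.random.default_rng(seed)
    cs = 0.0
    for b in result.biclusters:
        mat = B[b.direction] if isinstance(B, dict) else B
        b.score_I = bicluster_score(b)
        e = expected_score(b, mat, n_random=n_random, rng=rng)
        if e <= 0:
            log.warning("degenerate randomization mean (0): NI set to 0")
            b.score_NI = 0.0
        else:
            b.score_NI = b.score_I / e
        cs += b.score_NI
    return float(cs)


def total_score(result: BiclusterSet) -> float:
    """CS: sum of normalized bicluster scores."""
    return float(sum(b.score_NI or 0.0 for b in result.biclusters))


def make_bicluster(
    B: BinaryMatrix,
    gene_indices,
    sample_indices,
    direction: str | None = None,
) -> Bicluster:
    """Build a bicluster from explicit gene/sample index sets.

    Per-gene p-values are computed against the phenotype vector defined by
    ``sample_indices``.  Useful for scoring externally specified biclusters.
    """
    C = np.zeros(B.n_samples, dtype=bool)
    C[list(sample_indices)] = True
    genes = tuple(int(i) for i in gene_indices)
    pv = np.array([_extend.fisher_association(B.bits[i], C) for i in genes])
    return Bicluster(genes, C, direction or B.direction, pv)


@dataclass
class AlphaScan:
    """Result of an alpha grid scan."""

    best_alpha: float
    table: pd.DataFrame  # columns: alpha, n_biclusters, CS
    results: dict[float, BiclusterSet]

    @property
    def best_result(self) -> BiclusterSet:
        return self.results[self.best_alpha]


def scan_alphas(
    data: ExpressionMatrix | BinaryMatrix,
    grid=DEFAULT_ALPHA_GRID,
    c: float = 2.0,
    direction: str = "both",
    sched: SeedSchedule | None = None,
    L: float = 0.5,
    n_random: int = 500,
    seed: int | None = None,
) -> AlphaScan:
    """Run the pipeline once per alpha and score each bicluster set.

    Seed discovery does not depend on alpha, so seeds are mined once per
    regulation direction and reused across the grid.  Every alpha is scored
    with a generator freshly seeded from the shared seed, making the result
    independent of grid order.  Ties in CS go to the smaller alpha; if no
    alpha yields any bicluster the largest alpha is returned with a warning.
    """
    grid = sorted(set(float(a) for a in grid))
    if not grid:
        raise ValueError("alpha grid must be non-empty")
    if any(not 0 < a < 1 for a in grid):
        raise ValueError("every alpha must be in (0, 1)")
    sched = sched or SeedSchedule()

    if isinstance(data, BinaryMatrix) or direction == AS_GIVEN:
        mats = [data if isinstance(data, BinaryMatrix) else None]
        if mats[0] is None:
            raise ValueError("direction 'as_given' requires a BinaryMatrix")
    elif direction == "both":
        mats = [binarize(data, c, UP), binarize(data, c, DOWN)]
    elif direction in (UP, DOWN):
        mats = [binarize(data, c, direction)]
    else:
        raise ValueError(f"unknown direction {direction!r}")

    per_dir = [(B, discover_seeds(B, sched)) for B in mats]
    by_direction = {B.direction: B for B, _ in per_dir}

    results: dict[float, BiclusterSet] = {}
    rows = []
    for alpha in grid:
        bics = []
        for B, seeds in per_dir:
            for gs, C in seeds:
                b = _extend.extend_bicluster(gs, C, B, alpha, direction=B.direction)
                if b is not None:
                    bics.append(b)
        bics = _extend.filter_overlap(bics, L)
        bs = BiclusterSet(
            bics,
            list(data.gene_ids),
            list(data.sample_ids),
            {
                "direction": direction,
                "alpha": alpha,
                "cutoff_c": None if isinstance(data, BinaryMatrix) else c,
                "min_support": sched.min_support,
                "c2": sched.c2,
                "overlap_L": L,
                "n_random": n_random,
                "rng_seed": seed,
            },
        )
        cs = score_bicluster_set(bs, by_direction, n_random=n_random, seed=seed)
        results[alpha] = bs
        rows.append({"alpha": alpha, "n_biclusters": len(bs), "CS": cs})

    table = pd.DataFrame(rows)
    if (table["n_biclusters"] == 0).all():
        log.warning("no alpha in the grid produced any bicluster")
        best = max(grid)
    else:
        best_cs = table["CS"].max()
        best = float(table.loc[table["CS"] == best_cs, "alpha"].min())
    return AlphaScan(best, table, results)


def select_alpha(
    data: ExpressionMatrix | BinaryMatrix,
    grid=DEFAULT_ALPHA_GRID,
    **kwargs,
) -> tuple[float, pd.DataFrame]:
    """The CS-maximizing alpha and the full per-alpha CS table."""
    scan = scan_alphas(data, grid=grid, **kwargs)
    return scan.best_alpha, scan.table
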