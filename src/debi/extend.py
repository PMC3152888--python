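"""Seed extension by Fisher's exact test and greedy overlap filtering.

Each seed bicluster carries a fixed phenotype vector C defining its sample
set.  A gene belongs in the bicluster when its row is significantly
over-represented inside the C samples: the one-sided Fisher exact test on
the 2x2 table (gene bit) x (phenotype bit), i.e. the hypergeometric upper
tail of sigma_1,IN (the gene's 1-count inside the bicluster samples).  A
single pass over all genes removes seed genes with p > alpha and adds
outside genes with p < alpha.

The test is skipped, soundly, for genes that provably cannot reach alpha:
cut-offs on sigma_1,IN and sigma_1,OUT are precomputed from the
monotonicity of the hypergeometric tail.

Overlap filtering keeps large, little-overlapping biclusters: largest
first, any later bicluster whose overlap area with a kept one exceeds
L x its own area is dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import hypergeom

from .biclusters import Bicluster
from .matrix import BinaryMatrix

log = logging.getLogger(__name__)


@lru_cache(maxsize=1 << 20)
def _tail_p(sigma_in: int, K: int, n_in: int, M: int) -> float:
    """P(X >= sigma_in) for X ~ Hypergeom(M, K, n_in): exact one-sided p."""
    return float(hypergeom.sf(sigma_in - 1, M, K, n_in))


def _tail_p_many(sigma_in: np.ndarray, K: np.ndarray, n_in: int, M: int) -> np.ndarray:
    """Vectorized `_tail_p` over parallel arrays, deduplicated per (sigma, K)."""
    sigma_in = np.asarray(sigma_in, dtype=np.int64)
    K = np.broadcast_to(np.asarray(K, dtype=np.int64), sigma_in.shape)
    pairs = sigma_in * (M + 1) + K
    uniq, inverse = np.unique(pairs, return_inverse=True)
    us = uniq // (M + 1)
    uk = uniq % (M + 1)
    up = hypergeom.sf(us - 1, M, uk, n_in)
    return np.asarray(up)[inverse].reshape(sigma_in.shape)


def fisher_association(gene_row: np.ndarray, C: np.ndarray) -> float:
    """One-sided association p-value of a gene row with a phenotype vector.

    Degenerate phenotypes (all ones or all zeros) carry no contrast and
    return p = 1.
    """
    gene_row = np.asarray(gene_row, dtype=bool)
    C = np.asarray(C, dtype=bool)
    if gene_row.shape != C.shape or gene_row.ndim != 1:
        raise ValueError("gene row and phenotype vector must be equal-length vectors")
    m = gene_row.size
    if m < 2:
        raise ValueError("need at least two samples")
    n_in = int(C.sum())
    if n_in == 0 or n_in == m:
        log.debug("degenerate phenotype (%d of %d ones): p = 1", n_in, m)
        return 1.0
    sigma_in = int(np.count_nonzero(gene_row & C))
    K = int(np.count_nonzero(gene_row))
    return _tail_p(sigma_in, K, n_in, m)


@dataclass(frozen=True)
class ContingencyCutoffs:
    """Pre-screening bounds on the 2x2 table margins at a given alpha.

    Only genes with sigma_1,IN > ``min_sigma_in`` and sigma_1,OUT <
    ``max_sigma_out`` can reach p < alpha; all others are provably
    non-significant and need no test.  ``min_sigma_in`` may be -1 (nothing
    excluded, e.g. alpha >= 1); ``max_sigma_out`` may be n_out + 1.
    """

    min_sigma_in: int
    max_sigma_out: int
    alpha: float
    n_in: int
    n_out: int

    def tested(self, sigma_in, sigma_out):
        return (sigma_in > self.min_sigma_in) & (sigma_out < self.max_sigma_out)


def compute_cutoffs(alpha: float, n_in: int, n_out: int) -> ContingencyCutoffs:
    """Exact margin cut-offs: every gene they skip has p > alpha.

    Uses two monotonicities of the upper tail p(sigma_in, sigma_out):
    non-increasing in sigma_in at fixed sigma_out, non-decreasing in
    sigma_out at fixed sigma_in.  The best case for a gene at a given
    sigma_in is sigma_out = 0; at a given sigma_out it is sigma_in = n_in.
    """
    if n_in < 1:
        raise ValueError("n_in must be >= 1")
    M = n_in + n_out
    min_sigma_in = -1
    for s in range(n_in + 1):
        if _tail_p(s, s, n_in, M) > alpha:
            min_sigma_in = s
        else:
            break
    max_sigma_out = n_out + 1
    for t in range(n_out + 1):
        if _tail_p(n_in, n_in + t, n_in, M) > alpha:
            max_sigma_out = t
            break
    return ContingencyCutoffs(min_sigma_in, max_sigma_out, alpha, n_in, n_out)


def extend_bicluster(
    seed_genes,
    C: np.ndarray,
    B: BinaryMatrix,
    alpha: float,
    direction: str | None = None,
) -> Bicluster | None:
    """One extension/pruning pass over all genes against the fixed phenotype C.

    Seed genes with p > alpha are deleted, outside genes with p < alpha are
    added.  Returns None (bicluster dropped) when no gene survives or the
    phenotype is degenerate.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    bits = B.bits
    n, m = bits.shape
    C = np.asarray(C, dtype=bool)
    n_in = int(C.sum())
    if n_in == 0 or n_in == m:
        log.debug("degenerate phenotype (%d/%d samples): bicluster dropped", n_in, m)
        return None
    seed_mask = np.zeros(n, dtype=bool)
    seed_mask[list(seed_genes)] = True

    cut = compute_cutoffs(alpha, n_in, m - n_in)
    sigma_in = bits[:, C].sum(axis=1)
    K = bits.sum(axis=1)
    tested = np.asarray(cut.tested(sigma_in, K - sigma_in), dtype=bool)

    pv = np.ones(n)
    if tested.any():
        pv[tested] = _tail_p_many(sigma_in[tested], K[tested], n_in, m)
    # skipped genes have p > alpha: never added, and seed genes among them
    # are deleted.  p == alpha exactly is neither added nor deleted.
    keep = np.where(seed_mask, tested & (pv <= alpha), tested & (pv < alpha))
    genes = np.flatnonzero(keep)
    n_added = int(np.count_nonzero(keep & ~seed_mask))
    n_deleted = int(np.count_nonzero(seed_mask & ~keep))
    if genes.size == 0:
        log.debug("all %d genes failed at alpha=%g: bicluster dropped", n, alpha)
        return None
    log.debug(
        "extension: +%d -%d genes -> %d x %d", n_added, n_deleted, genes.size, n_in
    )
    dirn = direction if direction is not None else B.direction
    return Bicluster(tuple(genes), C, dirn, pv[genes])


def overlap_area(a: Bicluster, b: Bicluster) -> int:
    """Shared area: |common genes| x |common samples|."""
    common_genes = len(set(a.gene_indices) & set(b.gene_indices))
    common_samples = int(np.count_nonzero(a.phenotype & b.phenotype))
    return common_genes * common_samples


def filter_overlap(biclusters: list[Bicluster], L: float) -> list[Bicluster]:
    """Greedy largest-first overlap filter.

    Biclusters whose overlap area with an already-kept (larger) bicluster
    strictly exceeds L x their own area are deleted.  Ties in area are
    broken by input (discovery) order.  Survivors are returned in
    processing order (area descending).
    """
    if not 0 < L <= 1:
        raise ValueError("overlap fraction L must be in (0, 1]")
    order = sorted(range(len(biclusters)), key=lambda i: (-biclusters[i].size, i))
    kept: list[Bicluster] = []
    for i in order:
        b = biclusters[i]
        ok = True
        for k in kept:
            smaller = min(b.size, k.size)
            if overlap_area(b, k) > L * smaller + 1e-9:
                ok = False
                break
        if ok:
            kept.append(b)
    return kept
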