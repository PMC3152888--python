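"""Maximal frequent gene-set mining on binary expression matrices.

Items are genes, transactions are samples.  The *support* of a gene set is
the fraction of samples on which the elementwise AND of the member gene
rows (the *phenotype vector*) equals 1.  A gene set is (c1, c2)-frequent
when its support reaches c1 and its cardinality reaches c2; it is
*maximal* when no strict superset is frequent.

The miner performs a depth-first traversal of the gene-set lattice over a
static support-descending gene order, pruning by anti-monotonicity (every
subset of a frequent set is frequent) and by head-union-tail subsumption
against the growing maximal list.  Sample sets are Python int bitmasks.
`brute_force_maximal` is an exhaustive-enumeration oracle for small inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .matrix import BinaryMatrix

#: slack absorbing the floating-point representation of rational supports k/m,
#: so that support exactly equal to c1 counts as frequent.
EPS = 1e-12


@dataclass(frozen=True)
class FrequencyThresholds:
    """Support fraction c1 in (0, 1] and minimum cardinality c2 >= 1.

    ``strict_cardinality`` switches the cardinality condition from
    ``|G| >= c2`` (default) to the exclusive ``|G| > c2``.
    """

    c1: float
    c2: int = 2
    strict_cardinality: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.c1 <= 1:
            raise ValueError(f"c1 must be in (0, 1], got {self.c1}")
        if self.c2 < 1:
            raise ValueError(f"c2 must be >= 1, got {self.c2}")

    def min_count(self, m: int) -> int:
        """Smallest sample count k with k/m passing the support threshold."""
        return max(1, math.floor((self.c1 - EPS) * m) + 1)

    def min_card(self) -> int:
        return self.c2 + 1 if self.strict_cardinality else self.c2


def support(row: np.ndarray) -> float:
    """Fraction of samples on which a gene row is 1."""
    row = np.asarray(row)
    if row.size == 0:
        raise ValueError("empty gene row")
    return float(np.count_nonzero(row) / row.size)


def phenotype(genes, B: BinaryMatrix) -> np.ndarray:
    """Elementwise AND of the rows of ``genes``; its 1s are the set's samples."""
    genes = list(genes)
    if not genes:
        raise ValueError("phenotype of the empty gene set is undefined")
    return np.logical_and.reduce(B.bits[genes], axis=0)


def _row_masks(bits: np.ndarray) -> list[int]:
    masks = []
    for row in bits:
        mask = 0
        for j in np.flatnonzero(row):
            mask |= 1 << int(j)
        masks.append(mask)
    return masks


def mine_maximal_frequent(
    B: BinaryMatrix | np.ndarray, th: FrequencyThresholds
) -> list[tuple[int, ...]]:
    """All maximal (c1, c2)-frequent gene sets, as tuples of row indices.

    Output is canonically ordered: descending support, then lexicographic
    gene indices.
    """
    bits = B.bits if isinstance(B, BinaryMatrix) else np.asarray(B, dtype=bool)
    n, m = bits.shape
    minc = th.min_count(m)
    minl = th.min_card()
    masks = _row_masks(bits)
    counts = [mask.bit_count() for mask in masks]

    cand = [i for i in range(n) if counts[i] >= minc]
    cand.sort(key=lambda i: (-counts[i], i))

    # each maximal set as (gene bitmask, sample count, gene tuple)
    found: list[tuple[int, int, tuple[int, ...]]] = []

    def subsumed(gene_mask: int) -> bool:
        return any(gene_mask & gm == gene_mask for gm, _, _ in found)

    def dfs(head: list[int], head_gmask: int, smask: int, tail: list[int]) -> None:
        hut = head_gmask
        for g in tail:
            hut |= 1 << g
        if subsumed(hut):
            return
        for pos, g in enumerate(tail):
            new_smask = smask & masks[g]
            new_tail = [
                h for h in tail[pos + 1 :] if (new_smask & masks[h]).bit_count() >= minc
            ]
            head.append(g)
            dfs(head, head_gmask | (1 << g), new_smask, new_tail)
            head.pop()
        if not tail and len(head) >= minl and not subsumed(head_gmask):
            found.append((head_gmask, smask.bit_count(), tuple(sorted(head))))

    dfs([], 0, (1 << m) - 1, cand)
    return [genes for _, cnt, genes in sorted(found, key=lambda t: (-t[1], t[2]))]


def brute_force_maximal(
    B: BinaryMatrix | np.ndarray, th: FrequencyThresholds
) -> list[tuple[int, ...]]:
    """Exhaustive-enumeration oracle; same contract as ``mine_maximal_frequent``.

    Refuses matrices with more than 20 genes (2^n subsets).
    """
    bits = B.bits if isinstance(B, BinaryMatrix) else np.asarray(B, dtype=bool)
    n, m = bits.shape
    if n > 20:
        raise ValueError(f"brute force limited to 20 genes, got {n}")
    minc = th.min_count(m)
    minl = th.min_card()
    masks = _row_masks(bits)
    full = (1 << m) - 1

    # supp[S] = sample bitmask of the AND over genes in subset S
    supp = [full] * (1 << n)
    for S in range(1, 1 << n):
        low = S & -S
        supp[S] = supp[S ^ low] & masks[low.bit_length() - 1]

    out = []
    for S in range(1, 1 << n):
        if S.bit_count() < minl or supp[S].bit_count() < minc:
            continue
        # maximal iff no single-gene extension stays support-frequent
        if any(
            not S >> g & 1 and (supp[S] & masks[g]).bit_count() >= minc
            for g in range(n)
        ):
            continue
        genes = tuple(g for g in range(n) if S >> g & 1)
        out.append((supp[S].bit_count(), genes))
    return [genes for _, genes in sorted(out, key=lambda t: (-t[0], t[1]))]
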