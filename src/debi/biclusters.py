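"""Bicluster containers and the plain-text bicluster exchange format.

A bicluster is a pair (G', S'): a subset of genes and a subset of samples in
which every gene is coherently regulated.  The sample subset is stored as a
boolean *phenotype vector* over all samples; per-gene Fisher-test p-values and
the raw / normalized enrichment scores (I, NI) are carried alongside.

There is no community standard file format for biclusters, so results are
written as UTF-8 text blocks separated by blank lines, one ``key<TAB>values``
line per field.  The format round-trips through :func:`read_biclusters`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np


@dataclass
class Bicluster:
    """One bicluster over a fixed gene/sample universe.

    ``gene_indices`` are row indices, the phenotype vector marks member
    samples; ``pvalues`` is parallel to ``gene_indices``.
    """

    gene_indices: tuple[int, ...]
    phenotype: np.ndarray
    direction: str
    pvalues: np.ndarray
    score_I: float | None = None
    score_NI: float | None = None

    def __post_init__(self) -> None:
        self.gene_indices = tuple(int(i) for i in self.gene_indices)
        self.phenotype = np.asarray(self.phenotype, dtype=bool)
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        if len(self.pvalues) != len(self.gene_indices):
            raise ValueError("one p-value per gene required")
        if len(self.gene_indices) == 0:
            raise ValueError("bicluster needs at least one gene")
        if self.n_samples == 0:
            raise ValueError("bicluster needs at least one sample")

    @property
    def sample_indices(self) -> tuple[int, ...]:
        return tuple(int(j) for j in np.flatnonzero(self.phenotype))

    @property
    def n_genes(self) -> int:
        return len(self.gene_indices)

    @property
    def n_samples(self) -> int:
        return int(self.phenotype.sum())

    @property
    def size(self) -> int:
        """Bicluster area: number of genes times number of samples."""
        return self.n_genes * self.n_samples


@dataclass
class BiclusterSet:
    """Ordered bicluster collection plus the run provenance."""

    biclusters: list[Bicluster]
    gene_ids: list[str]
    sample_ids: list[str]
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.biclusters)

    def __iter__(self) -> Iterator[Bicluster]:
        return iter(self.biclusters)

    def __getitem__(self, i: int) -> Bicluster:
        return self.biclusters[i]

    @property
    def total_score(self) -> float:
        return float(sum(b.score_NI or 0.0 for b in self.biclusters))

    def membership_sets(self) -> list[tuple[frozenset, frozenset]]:
        """(gene-id set, sample-id set) pairs, for recovery scoring."""
        out = []
        for b in self.biclusters:
            out.append(
                (
                    frozenset(self.gene_ids[i] for i in b.gene_indices),
                    frozenset(self.sample_ids[j] for j in b.sample_indices),
                )
            )
        return out


@dataclass
class BiclusterRecord:
    """Identifier-level view of one bicluster, as stored on disk."""

    index: int
    direction: str
    alpha: float | None
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    pvalues: tuple[float, ...]
    score_I: float | None
    score_NI: float | None


def _fmt(x: float | None) -> str:
    return "" if x is None else repr(float(x))


def write_biclusters(result: BiclusterSet, path) -> None:
    """Write a bicluster set as blank-line-separated key/value text blocks."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# debi bicluster set\n")
        for key in sorted(result.params):
            fh.write(f"# {key}: {result.params[key]}\n")
        fh.write(f"# n_biclusters: {len(result)}\n")
        alpha = result.params.get("alpha")
        for idx, b in enumerate(result.biclusters):
            fh.write("\n")
            fh.write(f"bicluster\t{idx}\n")
            fh.write(f"direction\t{b.direction}\n")
            fh.write(f"alpha\t{_fmt(alpha)}\n")
            fh.write(f"n_genes\t{b.n_genes}\n")
            fh.write(f"n_samples\t{b.n_samples}\n")
            gids = [result.gene_ids[i] for i in b.gene_indices]
            sids = [result.sample_ids[j] for j in b.sample_indices]
            fh.write("genes\t" + "\t".join(gids) + "\n")
            fh.write("samples\t" + "\t".join(sids) + "\n")
            fh.write("pvalues\t" + "\t".join(repr(float(p)) for p in b.pvalues) + "\n")
            fh.write(f"score_I\t{_fmt(b.score_I)}\n")
            fh.write(f"score_NI\t{_fmt(b.score_NI)}\n")


class BiclusterParseError(ValueError):
    pass


def read_biclusters(path) -> list[BiclusterRecord]:
    """Parse the text format written by :func:`write_biclusters`."""
    blocks: list[dict] = []
    current: dict | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("#"):
                continue
            if line.strip() == "":
                current = None
                continue
            parts = line.split("\t")
            key, vals = parts[0], parts[1:]
            if key == "bicluster":
                current = {"bicluster": vals}
                blocks.append(current)
            elif current is None:
                raise BiclusterParseError(
                    f"{path}: line {lineno}: field {key!r} outside a bicluster block"
                )
            else:
                current[key] = vals
    records = []
    for blk in blocks:
        try:
            idx = int(blk["bicluster"][0])
            alpha_f = blk.get("alpha", [""])
            alpha = float(alpha_f[0]) if alpha_f and alpha_f[0] else None
            si = blk.get("score_I", [""])
            sn = blk.get("score_NI", [""])
            rec = BiclusterRecord(
                index=idx,
                direction=blk["direction"][0],
                alpha=alpha,
                gene_ids=tuple(blk["genes"]),
                sample_ids=tuple(blk["samples"]),
                pvalues=tuple(float(p) for p in blk.get("pvalues", [])),
                score_I=float(si[0]) if si and si[0] else None,
                score_NI=float(sn[0]) if sn and sn[0] else None,
            )
        except (KeyError, IndexError, ValueError) as exc:
            raise BiclusterParseError(f"{path}: malformed bicluster block: {exc}") from exc
        records.append(rec)
    return records
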