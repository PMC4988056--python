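"""Weighted Bray-Curtis gene-content dissimilarity.

The dissimilarity between strains *i* and *j* is

    BC_ij = 1 - 2 * C_ij / (S_i + S_j)

where S_i and S_j are the total numbers of genes mapped to orthologous
groups in each strain, and C_ij sums, over the orthologous groups, the
lesser of the two per-group gene counts. Counts are gene multiplicities,
not presence/absence, so gene duplications and losses move the index —
the reason Bray-Curtis is used rather than a binary index.

BC is 0 for identical profiles, 1 for profiles sharing no orthologous
group, and symmetric in its arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .profiles import OrthologProfile, ProfileTable

MatrixKind = Literal["dissimilarity", "identity"]

_SYMMETRY_TOL = 1e-12


@dataclass
class DistanceMatrix:
    """Labelled symmetric matrix of pairwise dissimilarities or identities.

    ``kind`` selects the valid range: ``"dissimilarity"`` entries lie in
    [0, 1] with a zero diagonal; ``"identity"`` entries lie in [0, 100].
    """

    labels: list[str]
    values: np.ndarray
    kind: MatrixKind = "dissimilarity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if not np.allclose(self.values, self.values.T, atol=_SYMMETRY_TOL, rtol=0):
            raise ValueError("matrix is not symmetric within 1e-12")
        lo, hi = (0.0, 1.0) if self.kind == "dissimilarity" else (0.0, 100.0)
        if self.values.min() < lo - _SYMMETRY_TOL or self.values.max() > hi + _SYMMETRY_TOL:
            raise ValueError(f"entries outside [{lo}, {hi}] for kind={self.kind!r}")
        if self.kind == "dissimilarity" and np.abs(np.diag(self.values)).max() > _SYMMETRY_TOL:
            raise ValueError("dissimilarity matrix must have a zero diagonal")

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    # -- plain-text round-tripping ------------------------------------
    # The matrix is stored fully (not triangular): square TSV with a header
    # row and column, and PHYLIP square format. Symmetry is enforced on
    # write (by construction) and re-verified on read.

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("strain_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, kind: MatrixKind = "dissimilarity") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("row and column labels differ")
        return cls([str(x) for x in df.index], df.to_numpy(dtype=float), kind)

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.values):
                fh.write(label + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def from_phylip(cls, path: str | Path, kind: MatrixKind = "dissimilarity") -> "DistanceMatrix":
        with open(path) as fh:
            tokens = fh.readline().split()
            n = int(tokens[0])
            labels, rows = [], []
            for _ in range(n):
                parts = fh.readline().split()
                labels.append(parts[0])
                rows.append([float(x) for x in parts[1 : n + 1]])
        return cls(labels, np.array(rows), kind)


def common_gene_sum(p: OrthologProfile, q: OrthologProfile) -> int:
    """C_ij: summed per-OG minima of gene counts over the union of OGs."""
    return sum(min(c, q.counts.get(og, 0)) for og, c in p.counts.items())


def bray_curtis(p: OrthologProfile, q: OrthologProfile) -> float:
    """BC_ij = 1 - 2*C_ij/(S_i + S_j), in [0, 1].

    Raises
    ------
    ValueError
        If both profiles are empty (the index is undefined, not 0 or 1;
        upstream QC makes this unreachable in normal runs).
    """
    denom = p.total_mapped + q.total_mapped
    if denom == 0:
        raise ValueError(
            f"Bray-Curtis undefined: both profiles empty "
            f"({p.strain_id!r}, {q.strain_id!r})"
        )
    return 1.0 - 2.0 * common_gene_sum(p, q) / denom


def pairwise_matrix(table: ProfileTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity over all retained strains.

    Vectorised over the count matrix; entries equal per-pair
    :func:`bray_curtis` calls exactly (integer arithmetic in the minima,
    one floating division per pair).
    """
    if len(table.strains) < 2:
        raise ValueError("need at least 2 strains for a pairwise matrix")
    x = table.counts
    totals = table.total_mapped.astype(float)
    n = x.shape[0]
    values = np.zeros((n, n))
    for i in range(n):
        # summed minima of row i against all later rows at once
        c = np.minimum(x[i], x[i + 1 :]).sum(axis=1)
        bc = 1.0 - 2.0 * c / (totals[i] + totals[i + 1 :])
        values[i, i + 1 :] = bc
        values[i + 1 :, i] = bc
    return DistanceMatrix(list(table.strains), values, kind="dissimilarity")
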