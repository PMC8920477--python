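"""Binary Sorensen-Dice dissimilarity and principal coordinates analysis.

Community membership (presence/absence of ASVs) is compared with the binary
Sorensen-Dice dissimilarity d(A, B) = 1 - 2|A∩B| / (|A| + |B|); ordination is
classical metric scaling (PCoA) with Gower double-centering and no
negative-eigenvalue correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_tables import FeatureTable, to_presence_absence

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "sorensen_dice",
    "pcoa",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_ordination",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """A labelled, symmetric, hollow dissimilarity matrix."""

    labels: tuple
    values: np.ndarray = field(repr=False)

    def __init__(self, labels, values):
        labels = tuple(str(x) for x in labels)
        values = np.asarray(values, dtype=float).copy()
        n = len(labels)
        if len(set(labels)) != n:
            raise ValueError("duplicate labels")
        if values.shape != (n, n):
            raise ValueError(f"matrix shape {values.shape} != ({n}, {n})")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        values.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)

    def __len__(self):
        return len(self.labels)

    def between(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def submatrix(self, labels) -> "DistanceMatrix":
        idx = [self.labels.index(x) for x in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)])


@dataclass(frozen=True)
class OrdinationResult:
    """PCoA output: coordinates on positive axes, all eigenvalues surfaced.

    ``eigenvalues`` holds every eigenvalue in descending order, including any
    negative ones (surfaced, never corrected, so the distortion they imply is
    visible); ``coordinates`` has one column per strictly positive eigenvalue.
    ``proportion_explained`` is each positive eigenvalue over the positive sum
    (zero for non-positive axes).
    """

    sample_ids: tuple
    coordinates: np.ndarray = field(repr=False)
    eigenvalues: np.ndarray = field(repr=False)
    proportion_explained: np.ndarray = field(repr=False)


def sorensen_dice(table: FeatureTable) -> DistanceMatrix:
    """Pairwise binary Sorensen-Dice dissimilarities between samples.

    For presence sets A and B, d = 1 - 2|A∩B| / (|A| + |B|). The table is
    binarised internally if it is not already presence/absence. A pair of
    samples that are both empty is assigned d = 0: two communities with no
    ASVs are indistinguishable.
    """
    table = to_presence_absence(table)
    b = table.counts.astype(np.float64)
    inter = b @ b.T
    sizes = b.sum(axis=1)
    denom = sizes[:, None] + sizes[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - 2.0 * inter / denom
    d[denom == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 1.0)
    return DistanceMatrix(table.sample_ids, d)


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical metric scaling of a distance matrix.

    Gower-centers the squared distances (B = -1/2 J D^2 J), eigendecomposes,
    and scales eigenvectors by the square roots of the positive eigenvalues.
    No Cailliez/Lingoes correction is applied; negative eigenvalues are
    reported with their axes omitted from the coordinates. Axis signs follow
    a fixed convention (first non-negligible loading positive) so results
    are reproducible across platforms.
    """
    d2 = dm.values ** 2
    n = len(dm)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(1e-12, 1e-10 * max(np.abs(eigvals).max(), 1.0))
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    for k in range(coords.shape[1]):
        col = coords[:, k]
        nz = np.nonzero(np.abs(col) > 1e-9)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, k] = -col
    pos_sum = eigvals[pos].sum()
    prop = np.zeros_like(eigvals)
    if pos_sum > 0:
        prop[pos] = eigvals[pos] / pos_sum
    return OrdinationResult(dm.labels, coords, eigvals, prop)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels differ")
    return DistanceMatrix(list(df.index), df.to_numpy(dtype=float))


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    df = pd.DataFrame(dm.values, index=list(dm.labels), columns=list(dm.labels))
    df.to_csv(path, sep="\t")


def write_ordination(res: OrdinationResult, path) -> None:
    """Write coordinates as TSV with a header block of eigenvalues."""
    with open(path, "w") as fh:
        fh.write("# eigenvalues\t" + "\t".join(f"{v:.10g}" for v in res.eigenvalues) + "\n")
        fh.write(
            "# proportion_explained\t"
            + "\t".join(f"{v:.10g}" for v in res.proportion_explained)
            + "\n"
        )
        k = res.coordinates.shape[1]
        fh.write("sample_id\t" + "\t".join(f"PC{i+1}" for i in range(k)) + "\n")
        for sid, row in zip(res.sample_ids, res.coordinates):
            fh.write(sid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
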