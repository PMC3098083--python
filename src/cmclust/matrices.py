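"""Labeled square similarity/distance matrices and their conversions.

The toolkit's clustering front-ends all reduce to a symmetric matrix of
pairwise similarities (Hodgkin electrostatic index, alignment identity,
ligand-shape Tanimoto, ...) or distances over a labelled item set.  This
module provides the canonical container, the similarity-to-distance
conversion D_ij = sqrt(2 (1 - SI_ij)), the global similarity summary
C_SIM (mean over the N(N-1)/2 unordered pairs), a threshold filter used
for sparse "spy plot" visualisation, and CSV / square-Phylip I/O.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LabeledSquareMatrix",
    "similarity_to_distance",
    "distance_to_similarity",
    "global_similarity",
    "spy_filter",
    "read_matrix",
    "write_matrix",
]

#: tolerance on symmetry accepted when reading matrices from disk
READ_SYMMETRY_TOL = 1e-6
#: tolerance on symmetry for in-memory construction
SYMMETRY_TOL = 1e-9


def _check_symmetry(values: np.ndarray, tol: float) -> None:
    asym = np.abs(values - values.T)
    worst = float(asym.max()) if asym.size else 0.0
    if worst > tol:
        i, j = np.unravel_index(int(np.argmax(asym)), asym.shape)
        raise ValueError(
            f"matrix is asymmetric beyond {tol:g}: entries ({i},{j}) and "
            f"({j},{i}) differ by {worst:g}"
        )


@dataclass(frozen=True)
class LabeledSquareMatrix:
    """A symmetric N x N similarity or distance matrix with item labels.

    ``kind`` is either ``"similarity"`` (unit diagonal, entries <= 1;
    negative entries are legal — the Hodgkin index ranges over [-1, 1])
    or ``"distance"`` (zero diagonal, non-negative entries).  The stored
    array is symmetrised exactly, by averaging with its transpose, after
    an input symmetry check, so downstream code may rely on
    ``values == values.T``.
    """

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    kind: str = "similarity"

    def __post_init__(self) -> None:
        labels = tuple(str(l) for l in self.labels)
        object.__setattr__(self, "labels", labels)
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate labels: {dupes}")
        values = np.asarray(self.values, dtype=float)
        n = len(labels)
        if values.shape != (n, n):
            raise ValueError(
                f"matrix shape {values.shape} does not match {n} labels"
            )
        if not np.isfinite(values).all():
            raise ValueError("matrix contains non-finite entries")
        _check_symmetry(values, SYMMETRY_TOL)
        values = (values + values.T) / 2.0
        if self.kind == "similarity":
            if not np.allclose(np.diag(values), 1.0, atol=1e-9):
                raise ValueError("similarity matrix must have unit diagonal")
            if values.max() > 1.0 + 1e-9:
                i, j = np.unravel_index(int(np.argmax(values)), values.shape)
                raise ValueError(
                    f"similarity entry ({labels[i]},{labels[j]}) = "
                    f"{values[i, j]:g} exceeds 1"
                )
            values = np.minimum(values, 1.0)
        elif self.kind == "distance":
            if not np.allclose(np.diag(values), 0.0, atol=1e-9):
                raise ValueError("distance matrix must have zero diagonal")
            if values.min() < -1e-9:
                raise ValueError("distance matrix must be non-negative")
            values = np.maximum(values, 0.0)
            np.fill_diagonal(values, 0.0)
        else:
            raise ValueError(f"kind must be 'similarity' or 'distance', got {self.kind!r}")
        values.flags.writeable = False
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def permuted(self, order: list[str]) -> "LabeledSquareMatrix":
        """Return the same matrix with rows/columns reordered to ``order``."""
        idx = [self.labels.index(l) for l in order]
        return LabeledSquareMatrix(
            tuple(order), self.values[np.ix_(idx, idx)], self.kind
        )


def similarity_to_distance(sim: LabeledSquareMatrix) -> LabeledSquareMatrix:
    """Convert a similarity matrix to distances via D = sqrt(2 (1 - SI)).

    The conversion maps SI = 1 to D = 0, SI = 0 to D = sqrt(2) and
    SI = -1 (anti-correlated potentials) to D = 2, and is strictly
    decreasing in SI.
    """
    if sim.kind != "similarity":
        raise ValueError("similarity_to_distance expects kind='similarity'")
    over = sim.values > 1.0 + 1e-9
    if over.any():
        i, j = np.unravel_index(int(np.argmax(sim.values)), sim.values.shape)
        raise ValueError(
            f"similarity ({sim.labels[i]},{sim.labels[j]}) = "
            f"{sim.values[i, j]:g} exceeds 1; cannot convert to a distance"
        )
    d = np.sqrt(2.0 * np.maximum(1.0 - sim.values, 0.0))
    np.fill_diagonal(d, 0.0)
    return LabeledSquareMatrix(sim.labels, d, "distance")


def distance_to_similarity(dist: LabeledSquareMatrix) -> LabeledSquareMatrix:
    """Inverse conversion, SI = 1 - D^2 / 2 (exact round-trip)."""
    if dist.kind != "distance":
        raise ValueError("distance_to_similarity expects kind='distance'")
    s = 1.0 - dist.values ** 2 / 2.0
    np.fill_diagonal(s, 1.0)
    return LabeledSquareMatrix(dist.labels, s, "similarity")


def global_similarity(sim: LabeledSquareMatrix) -> float:
    """C_SIM: the mean similarity over all N(N-1)/2 unordered pairs.

    The diagonal is excluded by construction (strict upper triangle), so
    each pair is counted once and self-similarities do not inflate the
    summary.
    """
    if sim.kind != "similarity":
        raise ValueError("global_similarity expects kind='similarity'")
    if sim.n < 2:
        raise ValueError("global similarity needs at least 2 items")
    iu = np.triu_indices(sim.n, k=1)
    return float(sim.values[iu].mean())


def spy_filter(m: LabeledSquareMatrix, threshold: float) -> LabeledSquareMatrix:
    """Zero every off-diagonal entry strictly greater than ``threshold``.

    Dropping the (dominant) high-similarity background leaves the sparse
    low-similarity structure, which renders well as a spy plot.  The
    diagonal is untouched.
    """
    if math.isnan(threshold):
        raise ValueError("threshold must not be NaN")
    values = m.values.copy()
    off = ~np.eye(m.n, dtype=bool)
    values[off & (values > threshold)] = 0.0
    return LabeledSquareMatrix(m.labels, values, m.kind)


# ---------------------------------------------------------------------------
# I/O
#
# CSV dialect: first row and first column carry the labels, comma-separated,
# '.' decimal.  Square Phylip: first line N, then one line per row with the
# label followed by N whitespace-separated values.  Writers always emit the
# full square matrix.

def write_matrix(m: LabeledSquareMatrix, path, format: str = "csv") -> None:
    if format == "csv":
        m.to_dataframe().to_csv(path, float_format="%.17g")
    elif format == "phylip-square":
        with open(path, "w") as fh:
            fh.write(f"{m.n}\n")
            for label, row in zip(m.labels, m.values):
                fh.write(label + "  " + "  ".join(f"{v:.17g}" for v in row) + "\n")
    else:
        raise ValueError(f"unknown matrix format {format!r}")


def read_matrix(path, format: str = "csv", kind: str = "similarity") -> LabeledSquareMatrix:
    """Read a labelled square matrix; symmetrises after a 1e-6 tolerance check."""
    if format == "csv":
        df = pd.read_csv(path, index_col=0)
        labels = [str(l) for l in df.index]
        col_labels = [str(c) for c in df.columns]
        if labels != col_labels:
            raise ValueError(
                f"{path}: row labels and column labels disagree "
                f"({labels[:3]}... vs {col_labels[:3]}...)"
            )
        values = df.to_numpy(dtype=float)
    elif format == "phylip-square":
        with open(path) as fh:
            tokens = fh.read().split("\n")
        header = tokens[0].split()
        if len(header) != 1 or not header[0].isdigit():
            raise ValueError(f"{path}: first line must be the item count")
        n = int(header[0])
        labels, rows = [], []
        for line in tokens[1:]:
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != n + 1:
                raise ValueError(
                    f"{path}: row {len(labels)} has {len(parts) - 1} values, expected {n}"
                )
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
        if len(labels) != n:
            raise ValueError(f"{path}: expected {n} rows, found {len(labels)}")
        values = np.asarray(rows, dtype=float)
    else:
        raise ValueError(f"unknown matrix format {format!r}")

    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: matrix is not square: shape {values.shape}")
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: duplicate labels")
    _check_symmetry(values, READ_SYMMETRY_TOL)
    values = (values + values.T) / 2.0
    return LabeledSquareMatrix(tuple(labels), values, kind)
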