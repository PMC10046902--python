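"""Reading, validation and conversion of Hi-C contact matrices.

Two plain-text dialects are supported, both tab/whitespace separated:

* **square** -- N rows of N numeric fields, the symmetric interaction
  frequency (IF) matrix of one chromosome at a fixed resolution;
* **sparse** -- three columns per line, ``i  j  IF``, listing only the
  observed contacts.  Bin coordinates may be raw 0-based indices or
  genomic positions (multiples of the map resolution); positions are
  reduced to indices by dividing through the greatest common divisor
  of all distinct coordinates.

Comment lines starting with ``#`` and blank lines are ignored in both
readers.  All indexing is 0-based internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ContactMatrixError",
    "SparseContacts",
    "ContactMatrix",
    "read_square_matrix",
    "read_sparse_contacts",
    "sparse_to_square",
    "square_to_sparse",
    "write_square_matrix",
    "load_contacts",
]

#: relative asymmetry tolerated in square input before it is an error
ASYMMETRY_RTOL = 1e-6


class ContactMatrixError(ValueError):
    """Raised for malformed or inconsistent contact-matrix input."""


@dataclass(frozen=True)
class SparseContacts:
    """Validated 3-column contact records ``(bin_i, bin_j, if_value)``.

    Records are canonicalized so that ``bin_i <= bin_j``; duplicate
    pairs after canonicalization are rejected as an input error.
    """

    records: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        canonical = []
        for i, j, v in self.records:
            if i < 0 or j < 0:
                raise ContactMatrixError(f"negative bin index in record ({i}, {j}, {v})")
            if v < 0:
                raise ContactMatrixError(f"negative IF value {v} for pair ({i}, {j})")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ContactMatrixError(f"duplicate contact pair {key}")
            seen.add(key)
            canonical.append((key[0], key[1], float(v)))
        object.__setattr__(self, "records", tuple(canonical))

    @property
    def n_bins(self) -> int:
        return 1 + max(max(i, j) for i, j, _ in self.records)


@dataclass(frozen=True)
class ContactMatrix:
    """Symmetric nonnegative N x N interaction-frequency matrix."""

    values: np.ndarray
    bin_labels: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ContactMatrixError(f"contact matrix must be square, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ContactMatrixError("contact matrix contains non-finite entries")
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ContactMatrixError(f"negative IF at ({i}, {j}): {values[i, j]}")
        if not np.array_equal(values, values.T):
            raise ContactMatrixError("contact matrix is not symmetric")
        object.__setattr__(self, "values", values)
        if self.bin_labels is not None and len(self.bin_labels) != values.shape[0]:
            raise ContactMatrixError("bin_labels length does not match matrix size")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


def _data_lines(path: Path) -> list[tuple[int, str]]:
    """Non-blank, non-comment lines of *path* with their 1-based numbers."""
    out = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        stripped = raw.strip()
        if not stripped or stripped.startswith("#"):
            continue
        out.append((lineno, stripped))
    return out


def read_square_matrix(path: str | Path) -> ContactMatrix:
    """Read a whitespace/tab-separated square IF matrix.

    Mild asymmetry (relative difference <= ``ASYMMETRY_RTOL``, e.g. from
    truncated text output) is repaired as ``(M + M.T) / 2``; anything
    larger is an error.
    """
    path = Path(path)
    lines = _data_lines(path)
    if not lines:
        raise ContactMatrixError(f"{path}: empty matrix file")
    rows = []
    width = None
    for lineno, line in lines:
        fields = line.split()
        if width is None:
            width = len(fields)
        elif len(fields) != width:
            raise ContactMatrixError(
                f"{path}:{lineno}: ragged row ({len(fields)} fields, expected {width})"
            )
        row = []
        for col, tok in enumerate(fields):
            try:
                row.append(float(tok))
            except ValueError:
                raise ContactMatrixError(
                    f"{path}:{lineno}: non-numeric field {tok!r} in column {col + 1}"
                ) from None
        rows.append(row)
    m = np.array(rows, dtype=float)
    if m.shape[0] != m.shape[1]:
        raise ContactMatrixError(
            f"{path}: matrix is {m.shape[0]} rows x {m.shape[1]} columns, expected square"
        )
    scale = max(np.abs(m).max(), 1.0)
    asym = np.abs(m - m.T).max()
    if asym > ASYMMETRY_RTOL * scale:
        raise ContactMatrixError(
            f"{path}: matrix asymmetric beyond tolerance (max |M - M.T| = {asym:g})"
        )
    m = (m + m.T) / 2.0
    return ContactMatrix(values=m)


def _infer_resolution(coords: Sequence[int]) -> int:
    """gcd of all distinct positive coordinates; maps genomic positions
    (e.g. multiples of 1 Mb) and raw indices to 0-based indices alike."""
    g = 0
    for c in coords:
        g = math.gcd(g, c)
    return max(g, 1)


def read_sparse_contacts(path: str | Path) -> SparseContacts:
    """Read 3-column tab-separated contact records ``i  j  IF``."""
    path = Path(path)
    lines = _data_lines(path)
    if not lines:
        raise ContactMatrixError(f"{path}: no contact records")
    raw: list[tuple[int, int, float]] = []
    for lineno, line in lines:
        fields = line.split()
        if len(fields) != 3:
            raise ContactMatrixError(
                f"{path}:{lineno}: expected 3 tab-separated fields, got {len(fields)}"
            )
        try:
            i = int(float(fields[0]))
            j = int(float(fields[1]))
            v = float(fields[2])
        except ValueError:
            raise ContactMatrixError(f"{path}:{lineno}: non-numeric field in {line!r}") from None
        if v < 0:
            raise ContactMatrixError(f"{path}:{lineno}: negative IF value {v}")
        raw.append((i, j, v))
    res = _infer_resolution([c for i, j, _ in raw for c in (i, j)])
    records = [(i // res, j // res, v) for i, j, v in raw]
    return SparseContacts(records=tuple(records))


def sparse_to_square(sparse: SparseContacts) -> ContactMatrix:
    """Expand sparse records into a full symmetric matrix.

    N is ``1 + max bin index``; cells not mentioned stay 0.
    """
    n = sparse.n_bins
    m = np.zeros((n, n), dtype=float)
    filled = np.zeros((n, n), dtype=bool)
    for i, j, v in sparse.records:
        if filled[i, j] and m[i, j] != v:
            raise ContactMatrixError(
                f"conflicting duplicate values for pair ({i}, {j}): {m[i, j]} vs {v}"
            )
        m[i, j] = m[j, i] = v
        filled[i, j] = filled[j, i] = True
    return ContactMatrix(values=m)


def square_to_sparse(matrix: ContactMatrix) -> SparseContacts:
    """Extract the nonzero upper triangle (including diagonal) as records."""
    iu, ju = np.nonzero(np.triu(matrix.values))
    if iu.size == 0:
        raise ContactMatrixError("matrix has no nonzero contacts")
    records = tuple(
        (int(i), int(j), float(matrix.values[i, j])) for i, j in zip(iu, ju)
    )
    return SparseContacts(records=records)


def write_square_matrix(matrix: ContactMatrix, path: str | Path) -> None:
    """Write a ContactMatrix as tab-separated text (full round-trip precision)."""
    path = Path(path)
    with path.open("w") as fh:
        for row in matrix.values:
            fh.write("\t".join(repr(float(v)) for v in row))
            fh.write("\n")


def load_contacts(path: str | Path, kind: str = "auto") -> ContactMatrix:
    """Load a contact matrix, auto-detecting square vs sparse layout.

    ``kind`` may be ``"square"``, ``"sparse"`` or ``"auto"``.  Auto
    detection: every data line having exactly 3 fields and the file not
    being a 3x3 square matrix heuristic is resolved as sparse when the
    first column is non-constant integer-like; a 3-line x 3-field file
    that parses as a valid symmetric square matrix is treated as square.
    """
    path = Path(path)
    if kind == "square":
        return read_square_matrix(path)
    if kind == "sparse":
        return sparse_to_square(read_sparse_contacts(path))
    if kind != "auto":
        raise ValueError(f"unknown input kind {kind!r}")
    lines = _data_lines(path)
    if not lines:
        raise ContactMatrixError(f"{path}: empty input file")
    n_fields = {len(line.split()) for _, line in lines}
    if n_fields == {3} and len(lines) != 3:
        return sparse_to_square(read_sparse_contacts(path))
    if n_fields == {3} and len(lines) == 3:
        # ambiguous 3x3: prefer the square reading, fall back to sparse
        try:
            return read_square_matrix(path)
        except ContactMatrixError:
            return sparse_to_square(read_sparse_contacts(path))
    return read_square_matrix(path)
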