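"""PDB and plain-text output of reconstructed structures.

The bead model is written as one CA pseudo-atom per chromatin bin
(residue name ``BIN``, one residue per bead), with consecutive beads
linked by CONECT records so molecular viewers draw the chromatin chain.
Optimizer coordinates live at O(1) scale, which would collapse at the
PDB format's three-decimal precision, so coordinates are multiplied by
a scale factor before writing; :func:`auto_scale` picks the factor that
gives the structure a 100-unit maximum extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .evaluation import EvaluationRecord

__all__ = [
    "Structure",
    "auto_scale",
    "write_pdb",
    "read_pdb_coordinates",
    "write_coordinate_table",
    "write_summary",
]

#: largest value renderable in a PDB %8.3f coordinate column
_PDB_COORD_MAX = 9999.999


@dataclass(frozen=True)
class Structure:
    """A reconstructed structure plus its evaluation and provenance."""

    positions: np.ndarray
    evaluation: EvaluationRecord | None = None
    bin_labels: tuple[str, ...] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] < 2:
            raise ValueError(f"positions must be N x 3 with N >= 2, got {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions contain non-finite coordinates")
        object.__setattr__(self, "positions", pos)

    @property
    def n_bins(self) -> int:
        return self.positions.shape[0]


def auto_scale(positions: np.ndarray, extent: float = 100.0) -> float:
    """Scale factor giving the structure a maximum extent of *extent*."""
    pos = np.asarray(positions, dtype=float)
    span = float(np.ptp(pos, axis=0).max())
    if span == 0:
        return 1.0
    return extent / span


def write_pdb(structure: Structure, path: str | Path, scale: float | None = None) -> None:
    """Write the bead model as fixed-column PDB ATOM/CONECT records.

    ``scale`` defaults to :func:`auto_scale`.  A scaled coordinate that
    overflows the 8.3 column width raises instead of writing a corrupt
    file.
    """
    path = Path(path)
    if scale is None:
        scale = auto_scale(structure.positions)
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    coords = structure.positions * scale
    if np.abs(coords).max() > _PDB_COORD_MAX:
        raise ValueError(
            f"scaled coordinate {np.abs(coords).max():.1f} overflows the PDB "
            f"8.3 column width; use a scale smaller than {scale:g}"
        )
    lines = []
    for k, (x, y, z) in enumerate(coords, start=1):
        lines.append(
            f"ATOM  {k:5d}  CA  BIN A{k:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           C  "
        )
    for k in range(1, structure.n_bins):
        lines.append(f"CONECT{k:5d}{k + 1:5d}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def read_pdb_coordinates(path: str | Path) -> np.ndarray:
    """Coordinates of all ATOM records, in record order (fixed columns
    31-54 per the PDB format)."""
    path = Path(path)
    coords = []
    for line in path.read_text().splitlines():
        if line.startswith("ATOM  ") or line.startswith("HETATM"):
            coords.append(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            )
    if not coords:
        raise ValueError(f"{path}: no ATOM records found")
    return np.array(coords, dtype=float)


def write_coordinate_table(structure: Structure, path: str | Path) -> None:
    """Plain-text table: one row per bin -- label, x, y, z (tab-separated)."""
    path = Path(path)
    labels = structure.bin_labels or tuple(
        str(k) for k in range(structure.n_bins)
    )
    with path.open("w") as fh:
        for label, (x, y, z) in zip(labels, structure.positions):
            fh.write(f"{label}\t{float(x)!r}\t{float(y)!r}\t{float(z)!r}\n")


def write_summary(structure: Structure, path: str | Path) -> None:
    """Plain-text run summary: input parameters plus SCC/PCC/loss."""
    path = Path(path)
    lines = [f"n_bins\t{structure.n_bins}"]
    for key, value in structure.provenance.items():
        lines.append(f"{key}\t{value}")
    ev = structure.evaluation
    if ev is not None:
        lines += [
            f"scc\t{ev.scc!r}",
            f"pcc\t{ev.pcc!r}",
            f"n_pairs\t{ev.n_pairs}",
            f"loss_name\t{ev.loss_name}",
            f"final_loss\t{ev.final_loss!r}",
        ]
    path.write_text("\n".join(lines) + "\n")
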