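"""Raster snapshots of an ecological state variable.

A snapshot is a rectangular lattice of cells, each holding either a
continuous quantity (e.g. biomass density) or a discrete occupancy state
(presence/absence of vegetation).  Sequences of snapshots ordered along a
stress gradient are the unit of trend analysis.

The grid origin is the top-left corner and storage is row-major: row 0 of a
matrix file is row 0 of the grid.  All indicators are covariant under this
convention, so it only matters for plotting and file round-trips.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np

ValueKind = Literal["continuous", "discrete_occupancy", "discrete_multistate"]
Boundary = Literal["periodic", "open"]

__all__ = [
    "SpatialGrid",
    "save_gradient",
    "load_gradient",
    "GradientSequence",
    "GridFormatError",
    "GridValidationError",
    "read_grid",
    "write_grid",
    "coarse_grain",
]


class GridValidationError(ValueError):
    """Raised when a grid violates its structural invariants."""


class GridFormatError(ValueError):
    """Raised when a matrix file cannot be parsed as a rectangular table."""


@dataclass(frozen=True)
class SpatialGrid:
    """One 2D snapshot of the state variable.

    Parameters
    ----------
    values
        2D array of cell values.  Stored as float64; occupancy grids hold
        0.0/1.0.
    value_kind
        ``continuous`` for quantitative fields (biomass, NDVI ...),
        ``discrete_occupancy`` for presence/absence, ``discrete_multistate``
        for few-state lattices.
    boundary
        Topology the data were generated on.  Simulator output is
        ``periodic``; field data is normally ``open``.
    label
        Free-text provenance tag.
    """

    values: np.ndarray
    value_kind: ValueKind = "continuous"
    boundary: Boundary = "open"
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise GridValidationError(f"grid must be 2D, got shape {arr.shape}")
        if arr.shape[0] < 2 or arr.shape[1] < 2:
            raise GridValidationError(
                f"grid must be at least 2x2, got {arr.shape[0]}x{arr.shape[1]}"
            )
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise GridValidationError(
                f"non-finite value at cell ({bad[0]}, {bad[1]})"
            )
        if self.value_kind == "discrete_occupancy":
            if not np.all((arr == 0.0) | (arr == 1.0)):
                bad = np.argwhere((arr != 0.0) & (arr != 1.0))[0]
                raise GridValidationError(
                    "occupancy grid contains a value outside {0, 1} at cell "
                    f"({bad[0]}, {bad[1]})"
                )
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def n_cells(self) -> int:
        return self.values.size

    def with_values(self, values: np.ndarray, **changes) -> "SpatialGrid":
        """Copy of this grid with new cell values (metadata preserved)."""
        return replace(self, values=np.array(values, dtype=float), **changes)


@dataclass(frozen=True)
class GradientSequence:
    """Ordered snapshots along a stress gradient.

    ``stress`` may hold driver values (rainfall, harshness ...) or integer
    ranks; it must be strictly monotone.  ``direction`` records whether
    increasing index approaches the transition.
    """

    snapshots: tuple[SpatialGrid, ...]
    stress: tuple[float, ...]
    direction: Literal["toward_transition", "away"] = "toward_transition"

    def __post_init__(self) -> None:
        snaps = tuple(self.snapshots)
        stress = tuple(float(s) for s in self.stress)
        if len(snaps) < 2:
            raise GridValidationError("a gradient needs at least 2 snapshots")
        if len(stress) != len(snaps):
            raise GridValidationError(
                f"{len(snaps)} snapshots but {len(stress)} stress values"
            )
        diffs = np.diff(stress)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise GridValidationError("stress values must be strictly monotone")
        shape = (snaps[0].nrows, snaps[0].ncols)
        kind = snaps[0].value_kind
        for i, g in enumerate(snaps):
            if (g.nrows, g.ncols) != shape:
                raise GridValidationError(
                    f"snapshot {i} has shape {(g.nrows, g.ncols)}, expected {shape}"
                )
            if g.value_kind != kind:
                raise GridValidationError(
                    f"snapshot {i} has value_kind {g.value_kind!r}, expected {kind!r}"
                )
        object.__setattr__(self, "snapshots", snaps)
        object.__setattr__(self, "stress", stress)

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self) -> Iterator[SpatialGrid]:
        return iter(self.snapshots)

    @property
    def value_kind(self) -> ValueKind:
        return self.snapshots[0].value_kind


def _sniff_delimiter(first_line: str) -> str:
    if "," in first_line:
        return ","
    if "\t" in first_line:
        return "\t"
    return " "


def read_grid(
    path: str | Path,
    delimiter: str | None = None,
    value_kind: ValueKind = "continuous",
    boundary: Boundary = "open",
) -> SpatialGrid:
    """Read a plain-text matrix file into a validated :class:`SpatialGrid`.

    The delimiter is auto-detected among comma, tab and whitespace unless
    given.  Row 0 of the file becomes row 0 of the grid.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise GridFormatError(f"{path}: empty file")
    if delimiter is None:
        delimiter = _sniff_delimiter(lines[0])
    rows: list[list[float]] = []
    width: int | None = None
    for i, ln in enumerate(lines):
        tokens = ln.split(delimiter) if delimiter != " " else re.split(r"\s+", ln.strip())
        tokens = [t for t in tokens if t != ""]
        row = []
        for j, tok in enumerate(tokens):
            try:
                row.append(float(tok))
            except ValueError:
                raise GridFormatError(
                    f"{path}: non-numeric cell {tok!r} at row {i}, column {j}"
                ) from None
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise GridFormatError(
                f"{path}: ragged row {i} has {len(row)} cells, expected {width}"
            )
        rows.append(row)
    return SpatialGrid(
        np.array(rows, dtype=float),
        value_kind=value_kind,
        boundary=boundary,
        label=path.name,
    )


def write_grid(grid: SpatialGrid, path: str | Path, delimiter: str = ",") -> None:
    """Write a grid as a plain-text matrix, one row per line.

    Continuous values are written with ``repr`` precision (17 significant
    digits) so that a read-back reproduces them bit-for-bit.
    """
    path = Path(path)
    arr = grid.values
    with path.open("w") as fh:
        for row in arr:
            fh.write(delimiter.join(_fmt(v) for v in row))
            fh.write("\n")


def _fmt(v: float) -> str:
    if v == int(v) and abs(v) < 1e15:
        return str(int(v))
    return np.format_float_scientific(v, precision=16, trim="-")


def coarse_grain(
    grid: SpatialGrid,
    sub: int,
    mode: Literal["mean", "count"] = "mean",
) -> SpatialGrid:
    """Replace each non-overlapping ``sub`` x ``sub`` block by its mean or
    occupied-cell count.

    Coarse-graining serves two purposes: converting occupancy data to a
    local-abundance field (``mode='count'``), and building the
    variance/skewness-discriminating null model (applied to reshuffled
    matrices).  Trailing rows/columns that do not fill a block are
    discarded.  ``sub=1`` returns a value-identical copy.
    """
    if sub < 1:
        raise ValueError(f"sub must be >= 1, got {sub}")
    if mode not in ("mean", "count"):
        raise ValueError(f"mode must be 'mean' or 'count', got {mode!r}")
    if mode == "count" and grid.value_kind != "discrete_occupancy":
        raise GridValidationError(
            "mode='count' requires a discrete_occupancy grid"
        )
    nr, nc = grid.nrows // sub, grid.ncols // sub
    if nr < 2 or nc < 2:
        raise GridValidationError(
            f"coarse-graining {grid.nrows}x{grid.ncols} with sub={sub} would "
            f"yield a degenerate {nr}x{nc} grid"
        )
    trimmed = grid.values[: nr * sub, : nc * sub]
    blocks = trimmed.reshape(nr, sub, nc, sub)
    if mode == "mean":
        out = blocks.mean(axis=(1, 3))
        kind: ValueKind = grid.value_kind if sub == 1 else "continuous"
    else:
        out = blocks.sum(axis=(1, 3))
        kind = "discrete_occupancy" if sub == 1 else "continuous"
    return SpatialGrid(out, value_kind=kind, boundary=grid.boundary, label=grid.label)


def save_gradient(seq: GradientSequence, directory: str | Path, delimiter: str = ",") -> Path:
    """Write a gradient sequence as one matrix file per snapshot plus a
    ``manifest.tsv`` (key=value header, then one ``file<TAB>stress`` line
    per snapshot).  Returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = [
        f"#value_kind={seq.value_kind}",
        f"#boundary={seq.snapshots[0].boundary}",
        f"#direction={seq.direction}",
    ]
    for i, (g, s) in enumerate(zip(seq.snapshots, seq.stress)):
        fname = f"snapshot_{i:03d}.csv"
        write_grid(g, directory / fname, delimiter=delimiter)
        lines.append(f"{fname}\t{_fmt(s)}")
    manifest = directory / "manifest.tsv"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest


def load_gradient(directory: str | Path) -> GradientSequence:
    """Read a gradient sequence written by :func:`save_gradient`."""
    directory = Path(directory)
    manifest = directory / "manifest.tsv"
    if not manifest.exists():
        raise GridFormatError(f"no manifest.tsv in {directory}")
    meta = {"value_kind": "continuous", "boundary": "open", "direction": "toward_transition"}
    snapshots, stress = [], []
    for ln in manifest.read_text().splitlines():
        ln = ln.strip()
        if not ln:
            continue
        if ln.startswith("#"):
            key, _, val = ln[1:].partition("=")
            meta[key.strip()] = val.strip()
            continue
        fname, _, sval = ln.partition("\t")
        snapshots.append(
            read_grid(
                directory / fname.strip(),
                value_kind=meta["value_kind"],  # type: ignore[arg-type]
                boundary=meta["boundary"],  # type: ignore[arg-type]
            )
        )
        stress.append(float(sval))
    return GradientSequence(
        snapshots=tuple(snapshots),
        stress=tuple(stress),
        direction=meta["direction"],  # type: ignore[arg-type]
    )
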