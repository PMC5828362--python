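"""Readers for GAL layouts and GPR-style raw exports; writers for the
timestamped results folder.

Both input kinds are tab-delimited Axon Text File (ATF) dialects: an
optional ``ATF 1.0`` line, a ``<n_optional_headers> <n_columns>`` count
line, ``key=value`` header records (GAL geometry lives in ``BlockN=``
lines), then a column-named table.  Parsing is lenient about the
preamble — the table carries all layout content — and strict about the
table itself.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .model import (
    ArrayData,
    ArrayLayout,
    ArrayVerdict,
    ConsolidatedMatrix,
    ControlLevel,
    ControlScheme,
    LayoutError,
    LayoutSpot,
    Settings,
    SpotRecord,
    Verdict,
)

__all__ = [
    "RawTable",
    "DEFAULT_ALIASES",
    "parse_gal",
    "parse_raw_array",
    "parse_consolidated",
    "write_outputs",
    "OUTPUT_FILENAMES",
]

log = logging.getLogger(__name__)

# The fixed inventory of a results folder.
CONSOLIDATED_FILENAME = "ProteinMicroarrayAnalyser.consolidated.txt"
REPLICATES_FILENAME = "ProteinMicroarrayAnalyser.AllAntigenReplicateValues.txt"
DISCARD_FILENAMES = {
    ControlLevel.LOW: "listOfArraysToDiscard.low.txt",
    ControlLevel.MED: "listOfArraysToDiscard.med.txt",
    ControlLevel.HIGH: "listOfArraysToDiscard.high.txt",
    ControlLevel.OVERALL: "listOfArraysToDiscard.overall.txt",
}
SETTINGS_FILENAME = "settings.txt"
OUTPUT_FILENAMES = (
    [CONSOLIDATED_FILENAME, REPLICATES_FILENAME]
    + [DISCARD_FILENAMES[l] for l in (ControlLevel.LOW, ControlLevel.MED, ControlLevel.HIGH, ControlLevel.OVERALL)]
    + [SETTINGS_FILENAME]
)

# The four per-spot quantities the pipeline needs, keyed by semantic name.
# Values are recognized column headers; GenePix exports at 635 nm are the
# de-facto dialect, generic names cover other quantification tools.
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "raw_fg": ("F635 Median", "F_median", "Foreground Median", "F Median"),
    "raw_bg": ("B635 Median", "B_median", "Background Median", "B Median"),
    "bg_sd": ("B635 SD", "B_SD", "Background SD", "B SD"),
    "pct_saturated": ("F635 % Sat.", "PctSat", "% Saturated", "F % Sat."),
}

_COORD_COLUMNS = ("Block", "Column", "Row", "ID")


@dataclass
class RawTable:
    """An ATF-dialect file split into preamble and table."""

    header_lines: list[str]
    column_names: list[str]
    records: pd.DataFrame


def _read_atf(path: Path) -> RawTable:
    lines = path.read_text().splitlines()
    # Find the table header: the first line whose tab-split fields include
    # both Block and ID (GAL and GPR tables always carry these).
    header_idx = None
    for i, line in enumerate(lines):
        fields_ = [f.strip().strip('"') for f in line.split("\t")]
        if "Block" in fields_ and "ID" in fields_:
            header_idx = i
            break
    if header_idx is None:
        raise LayoutError(f"{path}: no table header with Block and ID columns found")
    records = pd.read_csv(
        path,
        sep="\t",
        skiprows=header_idx,
        dtype=str,
        keep_default_na=False,
        quotechar='"',
    )
    records.columns = [str(c).strip().strip('"') for c in records.columns]
    return RawTable(
        header_lines=lines[:header_idx],
        column_names=list(records.columns),
        records=records,
    )


_BLOCK_RE = re.compile(r'^"?Block(\d+)"?\s*=\s*(.*)$', re.IGNORECASE)


def _geometry_from_headers(header_lines: Sequence[str]) -> dict[int, tuple[int, int]]:
    """Extract per-block (cols, rows) from ``BlockN=`` geometry lines.

    GAL geometry lines read ``BlockN= xOrigin, yOrigin, diameter,
    nColumns, colSpacing, nRows, rowSpacing``.
    """
    geom: dict[int, tuple[int, int]] = {}
    for line in header_lines:
        m = _BLOCK_RE.match(line.strip())
        if not m:
            continue
        block = int(m.group(1))
        parts = [p.strip().strip('"') for p in m.group(2).split(",")]
        if len(parts) >= 7:
            geom[block] = (int(float(parts[3])), int(float(parts[5])))
    return geom


def parse_gal(
    path: str | Path,
    control_scheme: ControlScheme,
) -> ArrayLayout:
    """Parse a GAL (GenePix Array List) file into an :class:`ArrayLayout`.

    Geometry is taken from ``BlockN=`` header lines when present,
    otherwise inferred as the per-block maximum row/column.  Every block
    must contain the same full rows x columns grid.  Control roles come
    from matching ``control_scheme``'s ID strings against the ID column.
    """
    path = Path(path)
    table = _read_atf(path)
    df = table.records
    missing = [c for c in ("Block", "Column", "Row", "ID") if c not in df.columns]
    if missing:
        raise LayoutError(f"{path}: missing required GAL columns {missing}")
    if "Name" not in df.columns:
        raise LayoutError(f"{path}: missing required GAL column ['Name']")

    spots = [
        LayoutSpot(
            block=int(r.Block),
            row=int(r.Row),
            col=int(r.Column),
            id=str(r.ID),
            name=str(r.Name),
        )
        for r in df.itertuples()
    ]
    if not spots:
        raise LayoutError(f"{path}: GAL table is empty")

    blocks = sorted({s.block for s in spots})
    n_blocks = max(blocks)
    if blocks != list(range(1, n_blocks + 1)):
        raise LayoutError(f"{path}: blocks are not numbered 1..{n_blocks}: {blocks}")

    geom = _geometry_from_headers(table.header_lines)
    if geom:
        dims = set(geom.values())
        if len(dims) != 1:
            raise LayoutError(f"{path}: BlockN geometry lines disagree: {geom}")
        cols, rows = dims.pop()
    else:
        rows = max(s.row for s in spots)
        cols = max(s.col for s in spots)

    expected = rows * cols
    per_block: dict[int, int] = {b: 0 for b in blocks}
    for s in spots:
        per_block[s.block] += 1
        if not (1 <= s.row <= rows and 1 <= s.col <= cols):
            raise LayoutError(
                f"{path}: spot ({s.block},{s.row},{s.col}) outside {rows}x{cols} block"
            )
    for b in blocks:
        if per_block[b] != expected:
            raise LayoutError(
                f"{path}: inconsistent block geometry — block {b} has "
                f"{per_block[b]} spots, expected {expected}"
            )

    return ArrayLayout(
        n_blocks=n_blocks,
        rows_per_block=rows,
        cols_per_block=cols,
        spots=spots,
        control_scheme=control_scheme,
    )


def _resolve_aliases(
    columns: Sequence[str], aliases: Mapping[str, Sequence[str]]
) -> dict[str, str]:
    resolved: dict[str, str] = {}
    for semantic, names in aliases.items():
        for name in names:
            if name in columns:
                resolved[semantic] = name
                break
        else:
            raise LayoutError(
                f"no column found for {semantic!r}; recognized names: {list(names)}"
            )
    return resolved


def parse_raw_array(
    path: str | Path,
    layout: ArrayLayout,
    aliases: Mapping[str, Sequence[str]] | None = None,
) -> ArrayData:
    """Parse one GPR-style raw file into an :class:`ArrayData`.

    Records are matched to layout positions by (block, row, column) and
    cross-checked against the ID column: a mismatch logs a warning and
    the layout's ID wins (the layout is the printing ground truth).  A
    layout position with no record is an error.
    """
    path = Path(path)
    table = _read_atf(path)
    df = table.records
    missing = [c for c in _COORD_COLUMNS if c not in df.columns]
    if missing:
        raise LayoutError(f"{path}: missing required columns {missing}")
    colmap = _resolve_aliases(df.columns, aliases or DEFAULT_ALIASES)

    # iterrows, not itertuples: raw column names carry spaces and dots.
    records: dict[tuple[int, int, int], pd.Series] = {}
    for _, row in df.iterrows():
        key = (int(row["Block"]), int(row["Row"]), int(row["Column"]))
        if key in records:
            raise LayoutError(f"{path}: duplicate record for position {key}")
        records[key] = row

    spots: list[SpotRecord] = []
    for ls in layout.spots:
        key = (ls.block, ls.row, ls.col)
        if key not in records:
            raise LayoutError(f"{path}: layout position {key} missing from file")
        row = records[key]
        file_id = str(row["ID"])
        if file_id != ls.id:
            log.warning(
                "%s: ID mismatch at %s (file %r, layout %r); layout wins",
                path.name,
                key,
                file_id,
                ls.id,
            )
        spots.append(
            SpotRecord(
                block=ls.block,
                row=ls.row,
                col=ls.col,
                id=ls.id,
                name=ls.name,
                raw_fg=float(row[colmap["raw_fg"]]),
                raw_bg=float(row[colmap["raw_bg"]]),
                bg_sd=float(row[colmap["bg_sd"]]),
                pct_saturated=float(row[colmap["pct_saturated"]]),
            )
        )
    return ArrayData(array_id=path.stem, source_path=str(path), spots=spots)


def _format_cell(value: float | str) -> str:
    if isinstance(value, str):
        return value
    return repr(float(value))


def parse_consolidated(path: str | Path) -> ConsolidatedMatrix:
    """Reparse a consolidated output file, recovering floats and the
    "NOISY"/"HIGH CV" sentinel strings cell-for-cell."""
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    array_ids = header[1:]
    antigen_ids: list[str] = []
    cells: list[list[float | str]] = []
    for line in lines[1:]:
        fields_ = line.split("\t")
        antigen_ids.append(fields_[0])
        row: list[float | str] = []
        for cell in fields_[1:]:
            if cell in ("NOISY", "HIGH CV"):
                row.append(cell)
            else:
                row.append(float(cell))
        cells.append(row)
    return ConsolidatedMatrix(antigen_ids, array_ids, cells)


def write_outputs(
    matrix_replicates: pd.DataFrame,
    matrix_means: ConsolidatedMatrix,
    discard_lists: Mapping[ControlLevel, Sequence[ArrayVerdict]],
    settings: Settings,
    out_root: str | Path,
    timestamp: Optional[datetime] = None,
) -> Path:
    """Write the results folder and return its path.

    The folder is named with the run date and time
    (``YYYY-MM-DD_HHMMSS``; a numeric suffix is appended on collision)
    and contains exactly seven tab-delimited files: the replicate-level
    and averaged consolidated tables, the four discard lists (one array
    id + offending CV per line, header always present), and a record of
    every setting used.
    """
    out_root = Path(out_root)
    out_root.mkdir(parents=True, exist_ok=True)
    stamp = (timestamp or datetime.now()).strftime("%Y-%m-%d_%H%M%S")
    folder = out_root / stamp
    suffix = 0
    while folder.exists():
        suffix += 1
        folder = out_root / f"{stamp}_{suffix}"
    folder.mkdir()

    m = matrix_means
    with open(folder / CONSOLIDATED_FILENAME, "w") as fh:
        fh.write("\t".join(["ID"] + list(m.array_ids)) + "\n")
        for antigen, row in zip(m.antigen_ids, m.cells):
            fh.write("\t".join([antigen] + [_format_cell(c) for c in row]) + "\n")

    matrix_replicates.to_csv(folder / REPLICATES_FILENAME, sep="\t", index=False)

    for level, filename in DISCARD_FILENAMES.items():
        verdicts = discard_lists.get(level, [])
        with open(folder / filename, "w") as fh:
            fh.write("Array\tCV_pct\n")
            for v in verdicts:
                if v.verdict is Verdict.DISCARD:
                    fh.write(f"{v.array_id}\t{_format_cell(v.cv_pct)}\n")

    settings.to_file(folder / SETTINGS_FILENAME)
    return folder
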