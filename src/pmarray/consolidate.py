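"""Assemble replicate-level and averaged output matrices.

Means are computed on normalized values; the NOISY/SATURATED flags
determined before normalization are carried through, since noise is a
property of raw signal versus background while comparability is a
property of normalized signal.  Row order follows first appearance in
the layout; column order is lexicographic by array id.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .model import (
    ArrayData,
    ArrayLayout,
    ConsolidatedMatrix,
    ReplicateStatus,
    Settings,
)
from .qc import replicate_summary

__all__ = ["build_matrices", "REPLICATE_COLUMNS"]

REPLICATE_COLUMNS = [
    "Antigen",
    "Array",
    "Block",
    "Row",
    "Column",
    "Value",
    "Flags",
    "Used",
    "ExclusionReason",
    "GroupStatus",
]


def build_matrices(
    arrays: Sequence[ArrayData],
    layout: ArrayLayout,
    settings: Settings,
) -> tuple[pd.DataFrame, ConsolidatedMatrix]:
    """Run replicate summarization for every antigen/control on every
    surviving array and build the two output tables.

    Returns ``(replicate_table, consolidated)``.  The replicate table
    lists every contributing spot value with its flags and whether it
    entered the mean; the consolidated matrix holds one cell per
    (antigen, array): the mean of the used replicas, or the sentinel
    "NOISY" / "HIGH CV".
    """
    antigen_ids = layout.antigen_ids
    array_ids = sorted(a.array_id for a in arrays)
    by_id = {a.array_id: a for a in arrays}

    rows: list[list] = []
    cells: list[list[float | str]] = []
    for antigen in antigen_ids:
        row_cells: list[float | str] = []
        for array_id in array_ids:
            array = by_id[array_id]
            spots = array.spots_for_id(antigen)
            values = [(s.working_value, s.flags) for s in spots]
            summary = replicate_summary(values, settings, antigen, array_id)
            row_cells.append(summary.cell)

            # Replicate table rows mirror the summary's bookkeeping.
            used = list(summary.used_values)
            outliers = [e.value for e in summary.excluded if e.reason == "OUTLIER"]
            for s in spots:
                v = s.working_value
                flags = ",".join(sorted(f.value for f in s.flags)) or "-"
                if s.flags:
                    reason = (
                        "NOISY" if any(f.value == "NOISY" for f in s.flags) else "SATURATED"
                    )
                    used_here = False
                elif v in outliers:
                    reason = "OUTLIER"
                    outliers.remove(v)
                    used_here = False
                elif summary.status is ReplicateStatus.OK and v in used:
                    reason = "-"
                    used.remove(v)
                    used_here = True
                else:
                    reason = "-"
                    used_here = False
                rows.append(
                    [
                        antigen,
                        array_id,
                        s.block,
                        s.row,
                        s.col,
                        v,
                        flags,
                        "yes" if used_here else "no",
                        reason,
                        summary.status.value,
                    ]
                )
        cells.append(row_cells)

    replicate_table = pd.DataFrame(rows, columns=REPLICATE_COLUMNS)
    consolidated = ConsolidatedMatrix(antigen_ids, array_ids, cells)
    return replicate_table, consolidated
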