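"""End-to-end orchestration: raw folder + GAL -> results folder.

Stage order: parse -> neighbourhood background -> net intensity ->
noise flags -> saturation flags -> array control CV (three levels +
overall) -> pin-to-pin -> array-to-array -> replicate summaries ->
outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import consolidate, io_formats, normalize, preprocess, qc
from .model import (
    ArrayData,
    ArrayLayout,
    ArrayVerdict,
    ConsolidatedMatrix,
    ControlLevel,
    ControlScheme,
    LayoutError,
    Settings,
    Verdict,
    validate_layout,
)

__all__ = ["PipelineResult", "run_pipeline", "process_arrays"]

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    layout: ArrayLayout
    arrays: list[ArrayData]  # surviving arrays, fully processed
    discarded: list[str]  # array ids removed by the OVERALL verdict
    verdicts: dict[str, dict[ControlLevel, ArrayVerdict]]
    replicate_table: pd.DataFrame
    consolidated: ConsolidatedMatrix
    out_folder: Optional[Path] = None


def process_arrays(
    arrays: Sequence[ArrayData],
    layout: ArrayLayout,
    settings: Settings,
) -> PipelineResult:
    """Run every computational stage on already-parsed arrays."""
    arrays = list(arrays)
    for array in arrays:
        preprocess.neighbourhood_background(array, layout, settings.neighbourhood_window)
        preprocess.net_intensity(array)
        for spot in array.spots:
            qc.flag_noisy(spot, settings.noise_sd_multiplier)
            qc.flag_saturated(
                spot, settings.saturation_threshold_pct, settings.saturation_enabled
            )
        n_sat = sum(1 for s in array.spots if any(f.value == "SATURATED" for f in s.flags))
        if n_sat:
            log.warning(
                "%s: %d saturated spot(s); consider rescanning at lower PMT gain",
                array.array_id,
                n_sat,
            )

    verdicts = qc.evaluate_arrays(arrays, layout, settings)
    survivors = [
        a
        for a in arrays
        if verdicts[a.array_id][ControlLevel.OVERALL].verdict is Verdict.KEEP
    ]
    discarded = sorted(set(a.array_id for a in arrays) - set(a.array_id for a in survivors))
    for aid in discarded:
        log.info("%s discarded by %s-control CV", aid, settings.selected_control.value)

    scheme = layout.control_scheme
    for array in survivors:
        _, factors = normalize.pin_to_pin(array, scheme)
        log.debug("%s block factors: %s", array.array_id, factors.factors)
    normalize.array_to_array(survivors, scheme)

    replicate_table, matrix = consolidate.build_matrices(survivors, layout, settings)
    return PipelineResult(
        layout=layout,
        arrays=survivors,
        discarded=discarded,
        verdicts=verdicts,
        replicate_table=replicate_table,
        consolidated=matrix,
    )


def run_pipeline(
    input_dir: str | Path,
    gal_path: str | Path,
    scheme: ControlScheme,
    settings: Settings,
    out_root: str | Path | None,
    timestamp: Optional[datetime] = None,
) -> PipelineResult:
    """Parse a dataset folder, process it, and (if ``out_root`` is
    given) write the timestamped results folder.

    Raises :class:`LayoutError` on fatal layout diagnostics and
    :class:`RuntimeError` when no array survives QC.
    """
    input_dir = Path(input_dir)
    raw_paths = sorted(p for p in input_dir.glob("*.txt"))
    if not raw_paths:
        raise LayoutError(f"no raw .txt files found in {input_dir}")

    layout = io_formats.parse_gal(gal_path, scheme)
    diags = validate_layout(layout)
    for d in diags:
        (log.error if d.fatal else log.warning)("%s", d.message)
    if any(d.fatal for d in diags):
        raise LayoutError("fatal layout diagnostics; aborting")

    arrays = [io_formats.parse_raw_array(p, layout) for p in raw_paths]
    result = process_arrays(arrays, layout, settings)
    if not result.arrays:
        raise RuntimeError("all arrays were discarded by control-CV QC")

    if out_root is not None:
        discard_lists = {
            level: [result.verdicts[aid][level] for aid in sorted(result.verdicts)]
            for level in DISCARD_LEVELS
        }
        result.out_folder = io_formats.write_outputs(
            result.replicate_table,
            result.consolidated,
            discard_lists,
            settings,
            out_root,
            timestamp=timestamp,
        )
    return result


DISCARD_LEVELS = (
    ControlLevel.LOW,
    ControlLevel.MED,
    ControlLevel.HIGH,
    ControlLevel.OVERALL,
)
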