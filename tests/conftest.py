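"""Shared fixtures: a tiny handcrafted two-block dataset whose every
value is chosen by hand, plus helpers to write its GAL/raw files."""

from __future__ import annotations

from pathlib import Path

import pytest

from pmarray.model import ArrayData, ArrayLayout, ControlScheme, LayoutSpot, SpotRecord

LOW, MED, HIGH = "PC-LOW", "PC-MED", "PC-HIGH"

# Two blocks of 2 rows x 3 cols: the control trio in row 1 of each
# block, one antigen in triplicate in row 2 (AG1 in block 1, AG2 in 2).
TINY_SPOTS = [
    (b, 1, 1, LOW)
    for b in (1, 2)
] + [(b, 1, 2, MED) for b in (1, 2)] + [(b, 1, 3, HIGH) for b in (1, 2)] + [
    (1, 2, c, "AG1") for c in (1, 2, 3)
] + [(2, 2, c, "AG2") for c in (1, 2, 3)]


@pytest.fixture
def scheme() -> ControlScheme:
    return ControlScheme(LOW, MED, HIGH)


@pytest.fixture
def tiny_layout(scheme) -> ArrayLayout:
    spots = [LayoutSpot(b, r, c, i, i) for b, r, c, i in sorted(TINY_SPOTS)]
    return ArrayLayout(
        n_blocks=2, rows_per_block=2, cols_per_block=3, spots=spots,
        control_scheme=scheme,
    )


def write_tiny_gal(path: Path, preamble: bool = True) -> Path:
    lines = []
    if preamble:
        lines += ["ATF\t1.0", "4\t5", '"Type=GenePix ArrayList V1.0"',
                  '"BlockCount=2"',
                  '"Block1= 1000, 1000, 100, 3, 200, 2, 200"',
                  '"Block2= 2000, 1000, 100, 3, 200, 2, 200"']
    lines.append("Block\tColumn\tRow\tID\tName")
    for b, r, c, i in sorted(TINY_SPOTS):
        lines.append(f"{b}\t{c}\t{r}\t{i}\t{i}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_tiny_raw(
    path: Path,
    values: dict[tuple[int, int, int], tuple[float, float, float, float]],
    columns=("F635 Median", "B635 Median", "B635 SD", "F635 % Sat."),
    id_override: dict[tuple[int, int, int], str] | None = None,
    drop: set[tuple[int, int, int]] | None = None,
) -> Path:
    """Write a GPR-style raw file for the tiny layout.

    ``values`` maps (block, row, col) -> (fg, bg, bg_sd, pct_sat).
    """
    lines = ["ATF\t1.0", "1\t9", '"Wavelengths=635"',
             "Block\tColumn\tRow\tID\tName\t" + "\t".join(columns)]
    for b, r, c, i in sorted(TINY_SPOTS):
        if drop and (b, r, c) in drop:
            continue
        fg, bg, sd, sat = values[(b, r, c)]
        spot_id = (id_override or {}).get((b, r, c), i)
        lines.append(f"{b}\t{c}\t{r}\t{spot_id}\t{i}\t{fg!r}\t{bg!r}\t{sd!r}\t{sat!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def uniform_tiny_values(
    fg: float = 1000.0, bg: float = 100.0, sd: float = 10.0, sat: float = 0.0,
    overrides: dict | None = None,
):
    vals = {(b, r, c): (fg, bg, sd, sat) for b, r, c, _ in TINY_SPOTS}
    for key, v in (overrides or {}).items():
        vals[key] = v
    return vals


def make_array(
    layout: ArrayLayout,
    nets: dict[tuple[int, int, int], float],
    array_id: str = "arr",
    bg_sd: float = 0.0,
) -> ArrayData:
    """Build an ArrayData with given net intensities directly (skipping
    parsing and background correction) for stage-level tests."""
    spots = []
    for ls in layout.spots:
        net = nets[(ls.block, ls.row, ls.col)]
        spots.append(
            SpotRecord(
                block=ls.block, row=ls.row, col=ls.col, id=ls.id, name=ls.name,
                raw_fg=net, raw_bg=0.0, bg_sd=bg_sd, pct_saturated=0.0,
                corrected_bg=0.0, net=net,
            )
        )
    return ArrayData(array_id=array_id, source_path="", spots=spots)
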