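"""Background correction and corrected net intensity.

Printing, assay and handling artefacts can inflate a spot's local
background estimate and thereby deflate its net signal.  The correction
replaces each spot's local background with the median background over a
square grid neighbourhood, which is robust to a single artefactual spike.
"""

from __future__ import annotations

import numpy as np

from .model import ArrayData, ArrayLayout

__all__ = ["neighbourhood_background", "net_intensity"]


def neighbourhood_background(
    array: ArrayData, layout: ArrayLayout, window: int = 3
) -> ArrayData:
    """Set each spot's ``corrected_bg`` to the median raw background of
    the ``window`` x ``window`` patch of grid positions centred on it.

    The patch is restricted to the spot's own block (blocks are printed
    by different pins and have independent background behaviour),
    truncated at block edges, and includes the spot itself.  The median
    of an even count is the mean of the two middle values.  A single
    pass over raw backgrounds is performed; ``raw_bg`` is never
    overwritten.  Mutates ``array`` in place and returns it.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    max_dim = max(layout.rows_per_block, layout.cols_per_block)
    if window > 2 * max_dim - 1:
        raise ValueError(
            f"window {window} exceeds 2*max(rows, cols)-1 = {2 * max_dim - 1}"
        )
    half = window // 2
    for block, spots in array.spots_by_block().items():
        bg = {(s.row, s.col): s.raw_bg for s in spots}
        for s in spots:
            patch = [
                bg[(r, c)]
                for r in range(s.row - half, s.row + half + 1)
                for c in range(s.col - half, s.col + half + 1)
                if (r, c) in bg
            ]
            s.corrected_bg = float(np.median(patch))
    return array


def net_intensity(array: ArrayData) -> ArrayData:
    """Set ``net = raw_fg - corrected_bg`` for every spot.

    Negative nets are retained rather than clipped: correction and
    filtering are separate concerns, and sub-background spots are caught
    by the noise flag downstream.  Mutates ``array`` in place.
    """
    for s in array.spots:
        if s.corrected_bg is None:
            raise ValueError(
                f"corrected_bg missing for spot ({s.block},{s.row},{s.col}); "
                "run neighbourhood_background first"
            )
        s.net = s.raw_fg - s.corrected_bg
    return array
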