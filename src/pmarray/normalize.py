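"""Composite normalization driven by the three-concentration positive control.

Two sources of systematic intensity bias are removed in sequence:

* **pin-to-pin** — blocks (sub-arrays) are deposited by different print
  pins and pick up block-wide multiplicative offsets.  Each block is
  rescaled so its control mean matches the array's grand control mean
  (total-intensity normalization: a block offers too few control spots
  for stable quantiles).
* **array-to-array** — whole arrays differ by scanner gain and assay
  run.  Each array's control distribution (three concentrations, all
  replicas) is quantile-mapped onto the rank-wise mean distribution
  across arrays; the resulting monotone piecewise-linear map is applied
  to every unflagged spot.

Only values surviving the spot-level flags, on arrays surviving the
control-CV verdict, drive the normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import ArrayData, ControlScheme, SpotRecord

__all__ = ["BlockFactors", "QuantileMap", "pin_to_pin", "array_to_array"]

log = logging.getLogger(__name__)


@dataclass
class BlockFactors:
    """Per-block scale factors for one array.

    ``factors[b]`` multiplies every net intensity in block ``b`` so the
    block's control mean equals ``reference_mean`` (the mean of the
    per-block control means)."""

    array_id: str
    factors: dict[int, float]
    reference_mean: float


@dataclass
class QuantileMap:
    """Monotone piecewise-linear map from one array's sorted control
    values onto the cross-array reference quantiles.

    Inside the control range the map interpolates linearly between
    adjacent quantiles; outside it extrapolates the outermost segment
    (antigen signals routinely exceed the highest control), and results
    are floored at 0 RFU.
    """

    array_id: str
    source_quantiles: list[float]
    reference_quantiles: list[float]
    _xs: np.ndarray = field(init=False, repr=False)
    _ys: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.source_quantiles) != len(self.reference_quantiles):
            raise ValueError("source and reference quantile lists differ in length")
        s = np.asarray(self.source_quantiles, dtype=float)
        r = np.asarray(self.reference_quantiles, dtype=float)
        if np.any(np.diff(s) < 0) or np.any(np.diff(r) < 0):
            raise ValueError("quantile lists must be sorted ascending")
        # Collapse tied source values (averaging their references) so the
        # map is a function and stays monotone.
        xs, idx = np.unique(s, return_inverse=True)
        ys = np.zeros_like(xs)
        counts = np.zeros_like(xs)
        np.add.at(ys, idx, r)
        np.add.at(counts, idx, 1)
        self._xs = xs
        self._ys = ys / counts

    def __call__(self, x: float | np.ndarray) -> float | np.ndarray:
        x = np.asarray(x, dtype=float)
        xs, ys = self._xs, self._ys
        if xs.size == 0:
            out = x.copy()
        elif xs.size == 1:
            out = x + (ys[0] - xs[0])
        else:
            out = np.interp(x, xs, ys)
            lo_slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
            hi_slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
            below = x < xs[0]
            above = x > xs[-1]
            out = np.where(below, ys[0] + (x - xs[0]) * lo_slope, out)
            out = np.where(above, ys[-1] + (x - xs[-1]) * hi_slope, out)
        out = np.maximum(out, 0.0)
        return float(out) if out.ndim == 0 else out


def _unflagged_control_values(
    spots: Sequence[SpotRecord], control_ids: frozenset[str] | set[str]
) -> list[SpotRecord]:
    return [s for s in spots if s.id in control_ids and not s.flags]


def pin_to_pin(array: ArrayData, scheme: ControlScheme) -> tuple[ArrayData, BlockFactors]:
    """Rescale each block so per-block control means equalize.

    The reference is the mean of the per-block control-net means; block
    ``b``'s factor is ``reference / block_mean``.  Every spot in the
    block (antigens and controls alike) is multiplied by the factor.  A
    block with no usable control spots, or a nonpositive control mean,
    keeps factor 1 with a logged warning.  Mutates ``array`` in place.
    """
    control_ids = set(scheme.concentration_ids)
    by_block = array.spots_by_block()
    block_means: dict[int, float | None] = {}
    for block, spots in by_block.items():
        controls = _unflagged_control_values(spots, control_ids)
        if not controls:
            log.warning(
                "%s block %d: no unflagged control spots; factor 1",
                array.array_id,
                block,
            )
            block_means[block] = None
            continue
        mean = float(np.mean([s.working_value for s in controls]))
        if mean <= 0:
            log.warning(
                "%s block %d: nonpositive control mean %.3f; factor 1",
                array.array_id,
                block,
                mean,
            )
            block_means[block] = None
        else:
            block_means[block] = mean

    usable = [m for m in block_means.values() if m is not None]
    reference = float(np.mean(usable)) if usable else 1.0
    factors = {
        block: (reference / mean if mean is not None else 1.0)
        for block, mean in block_means.items()
    }
    for block, spots in by_block.items():
        f = factors[block]
        for s in spots:
            if s.net is not None:
                s.net *= f
    return array, BlockFactors(array.array_id, factors, reference)


def array_to_array(
    arrays: Sequence[ArrayData], scheme: ControlScheme
) -> tuple[list[ArrayData], list[QuantileMap]]:
    """Quantile-normalize arrays against each other via their controls.

    Each array contributes its unflagged control nets (all three
    concentrations, all replicas), sorted ascending.  When arrays
    contribute unequal counts (some control spots flagged), longer lists
    drop their highest-rank extras, with a warning, so the rank-wise
    mean is well defined.  The reference distribution is the rank-wise
    mean; each array's map sends its own quantiles onto it and is then
    applied to every unflagged spot, writing ``normalized``.  Flagged
    spots never receive a normalized value.

    With fewer than two arrays there is nothing to normalize against and
    the identity map is used.  Mutates arrays in place.
    """
    arrays = list(arrays)
    control_ids = set(scheme.concentration_ids)

    if len(arrays) < 2:
        maps = []
        for array in arrays:
            for s in array.spots:
                if not s.flags:
                    s.normalized = s.working_value
            maps.append(QuantileMap(array.array_id, [], []))
        return arrays, maps

    vectors: dict[str, np.ndarray] = {}
    for array in arrays:
        controls = _unflagged_control_values(array.spots, control_ids)
        vectors[array.array_id] = np.sort([s.working_value for s in controls])

    n = min(v.size for v in vectors.values())
    if n == 0:
        raise ValueError("an array has no unflagged control spots to normalize with")
    for aid, v in vectors.items():
        if v.size > n:
            log.warning(
                "%s: dropping %d highest-rank control value(s) to match shortest list",
                aid,
                v.size - n,
            )
            vectors[aid] = v[:n]

    reference = np.mean(np.vstack([vectors[a.array_id] for a in arrays]), axis=0)

    maps: list[QuantileMap] = []
    for array in arrays:
        qmap = QuantileMap(
            array.array_id,
            [float(x) for x in vectors[array.array_id]],
            [float(x) for x in reference],
        )
        for s in array.spots:
            if not s.flags:
                s.normalized = float(qmap(s.working_value))
        maps.append(qmap)
    return arrays, maps
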