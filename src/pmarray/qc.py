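"""Spot-level flags, replicate summarization and array-level control QC.

All threshold comparisons are strict ("less than n SDs", "above 20%"):
a value exactly at a threshold is never flagged.

The coefficient of variation (CV) is 100 * sd / mean with the sample
(n-1) standard deviation.  A CV over values with nonpositive mean is
defined as +infinity — the ratio is meaningless there and must always
fail the threshold.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

from .model import (
    ArrayData,
    ArrayLayout,
    ArrayVerdict,
    ControlLevel,
    ExcludedValue,
    ReplicateStatus,
    ReplicateSummary,
    Settings,
    SpotFlag,
    SpotRecord,
    Verdict,
)

__all__ = [
    "cv_pct",
    "flag_noisy",
    "flag_saturated",
    "replicate_summary",
    "array_control_cv",
    "evaluate_arrays",
]


def cv_pct(values: Sequence[float]) -> float:
    """Percent coefficient of variation; +inf when the mean is <= 0."""
    arr = np.asarray(values, dtype=float)
    mean = arr.mean()
    if mean <= 0:
        return math.inf
    if arr.size < 2:
        return 0.0
    return float(100.0 * arr.std(ddof=1) / mean)


def flag_noisy(spot: SpotRecord, n: float) -> SpotRecord:
    """Add NOISY iff the spot's net intensity is strictly below ``n``
    background standard deviations.  With ``bg_sd == 0`` only negative
    nets are flagged."""
    if spot.net is None:
        raise ValueError("net intensity not computed")
    if spot.net < n * spot.bg_sd:
        spot.flags.add(SpotFlag.NOISY)
    return spot


def flag_saturated(spot: SpotRecord, threshold_pct: float, enabled: bool = True) -> SpotRecord:
    """Add SATURATED iff strictly more than ``threshold_pct`` percent of
    the spot's pixels saturated the scanner.  Disabled for AGC-scanned
    slides, where the scanner guarantees no saturation."""
    if enabled and spot.pct_saturated > threshold_pct:
        spot.flags.add(SpotFlag.SATURATED)
    return spot


def _flag_reason(flags: Iterable[SpotFlag]) -> str:
    # NOISY takes precedence when a spot carries both flags.
    flags = set(flags)
    return SpotFlag.NOISY.value if SpotFlag.NOISY in flags else SpotFlag.SATURATED.value


def replicate_summary(
    values: Sequence[tuple[float, Iterable[SpotFlag]]],
    settings: Settings,
    antigen_id: str = "",
    array_id: str = "",
) -> ReplicateSummary:
    """Summarize one antigen's replicas on one array.

    Procedure:

    1. Drop flagged replicas, recording the flag as the exclusion reason.
    2. If fewer than ``min_replicates`` unflagged values remain, the
       group is NOISY and no mean is reported.
    3. If the CV of the remaining values is within the threshold, report
       their mean (status OK).
    4. Otherwise try removing exactly one value: among the resulting
       subsets of size >= ``min_replicates`` whose CV passes, take the
       one with the smallest CV (ties broken toward the larger mean),
       record the removed value as an OUTLIER, status OK.  At most one
       replica is ever excluded as an outlier — a group that would need
       two removals is not trustworthy.
    5. If no subset passes, the group is HIGH CV and no mean is reported.

    This keeps a group usable when only one of its replicas is
    problematic, instead of discarding the whole data point.
    """
    if not values:
        raise ValueError("replicate group is empty")
    excluded: list[ExcludedValue] = []
    clean: list[float] = []
    for value, flags in values:
        flags = set(flags)
        if flags:
            excluded.append(ExcludedValue(value, _flag_reason(flags)))
        else:
            clean.append(value)

    def summary(status, used, mean=None, cv=None):
        return ReplicateSummary(
            antigen_id=antigen_id,
            array_id=array_id,
            used_values=list(used),
            excluded=excluded,
            mean=mean,
            cv_pct=cv,
            status=status,
        )

    if len(clean) < settings.min_replicates:
        return summary(ReplicateStatus.NOISY, [])

    full_cv = cv_pct(clean)
    if full_cv <= settings.replicate_cv_threshold_pct:
        return summary(
            ReplicateStatus.OK, clean, mean=float(np.mean(clean)), cv=full_cv
        )

    if len(clean) - 1 >= settings.min_replicates:
        best: tuple[float, float, int] | None = None  # (cv, mean, removed idx)
        for i in range(len(clean)):
            subset = clean[:i] + clean[i + 1 :]
            cv = cv_pct(subset)
            if cv > settings.replicate_cv_threshold_pct:
                continue
            mean = float(np.mean(subset))
            if best is None or cv < best[0] or (cv == best[0] and mean > best[1]):
                best = (cv, mean, i)
        if best is not None:
            cv, mean, idx = best
            excluded.append(ExcludedValue(clean[idx], "OUTLIER"))
            used = clean[:idx] + clean[idx + 1 :]
            return summary(ReplicateStatus.OK, used, mean=mean, cv=cv)

    return summary(ReplicateStatus.HIGH_CV, [])


def array_control_cv(array: ArrayData, control_id: str) -> float:
    """CV (percent) of one control's corrected net intensities across the
    whole array.

    All of the control's spots count, flagged or not: this QC exists to
    detect printing/coating problems, which is exactly what spot flags
    would mask.  Computed on pre-normalization nets for the same reason.
    A nonpositive mean yields +inf (the array is discarded).
    """
    nets = [s.net for s in array.spots_for_id(control_id)]
    if any(n is None for n in nets):
        raise ValueError("net intensities not computed")
    if len(nets) < 2:
        raise ValueError(
            f"control {control_id!r} occurs {len(nets)} time(s); need >= 2 for a CV"
        )
    return cv_pct([float(n) for n in nets])  # type: ignore[misc]


def evaluate_arrays(
    arrays: Sequence[ArrayData],
    layout: ArrayLayout,
    settings: Settings,
) -> dict[str, dict[ControlLevel, ArrayVerdict]]:
    """Compute per-array KEEP/DISCARD verdicts for all three control
    concentrations plus OVERALL.

    All three levels are evaluated and reported so the user learns which
    control is best suited for QC and spots printing problems early, but
    only the OVERALL verdict — that of the user-selected control —
    removes an array from downstream processing.  Verdicts are also
    stored on each ``ArrayData``.
    """
    scheme = layout.control_scheme
    out: dict[str, dict[ControlLevel, ArrayVerdict]] = {}
    for array in arrays:
        verdicts: dict[ControlLevel, ArrayVerdict] = {}
        for level in (ControlLevel.LOW, ControlLevel.MED, ControlLevel.HIGH):
            cv = array_control_cv(array, scheme.id_for_level(level))
            verdict = (
                Verdict.DISCARD
                if cv > settings.array_cv_threshold_pct
                else Verdict.KEEP
            )
            verdicts[level] = ArrayVerdict(array.array_id, level, cv, verdict)
        sel = verdicts[settings.selected_control]
        verdicts[ControlLevel.OVERALL] = ArrayVerdict(
            array.array_id, ControlLevel.OVERALL, sel.cv_pct, sel.verdict
        )
        array.discard_verdicts = verdicts
        out[array.array_id] = verdicts
    return out
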