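"""Domain types shared by every pipeline stage.

A *protein microarray* is a slide printed with a grid of antigen spots,
organized into blocks (sub-arrays), each deposited by one print pin.  A
scanned array yields, per spot, a foreground median, a local background
median and SD, and a percent-saturated-pixels figure, all in relative
fluorescence units (RFU).  The pipeline corrects backgrounds, flags
unreliable spots, rejects badly printed arrays via control CVs, normalizes
blocks within arrays and arrays against each other, and consolidates
replicate spots into one antigen-by-array matrix.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "ControlLevel",
    "SpotFlag",
    "ReplicateStatus",
    "Verdict",
    "Settings",
    "ControlScheme",
    "LayoutSpot",
    "ArrayLayout",
    "SpotRecord",
    "ArrayData",
    "ExcludedValue",
    "ReplicateSummary",
    "ConsolidatedMatrix",
    "Diagnostic",
    "validate_layout",
    "LayoutError",
]

# Sentinel strings used verbatim in the consolidated output files.
NOISY_SENTINEL = "NOISY"
HIGH_CV_SENTINEL = "HIGH CV"


class ControlLevel(str, enum.Enum):
    """The three concentrations of the normalization positive control,
    plus OVERALL (= the user-selected one) for array verdicts."""

    LOW = "LOW"
    MED = "MED"
    HIGH = "HIGH"
    OVERALL = "OVERALL"


class SpotFlag(str, enum.Enum):
    NOISY = "NOISY"
    SATURATED = "SATURATED"


class ReplicateStatus(str, enum.Enum):
    OK = "OK"
    NOISY = "NOISY"
    HIGH_CV = "HIGH_CV"


class Verdict(str, enum.Enum):
    KEEP = "KEEP"
    DISCARD = "DISCARD"


class LayoutError(ValueError):
    """Raised for fatal layout/parse problems."""


@dataclass
class Settings:
    """User-tunable pipeline parameters.

    Parameters
    ----------
    noise_sd_multiplier:
        ``n`` in the noise rule: a spot is NOISY when its corrected net
        intensity is strictly less than ``n`` background SDs.
    replicate_cv_threshold_pct:
        Replicate groups whose CV (percent) exceeds this are HIGH CV.
    array_cv_threshold_pct:
        Arrays whose positive-control CV exceeds this are discarded.
    saturation_threshold_pct:
        Spots with more saturated pixels than this are SATURATED.
    saturation_enabled:
        ``False`` models slides scanned in automatic-gain-control (AGC)
        mode, where the scanner guarantees no saturation and the flag is
        not applied.
    selected_control:
        Which control concentration drives the OVERALL array verdict.
    neighbourhood_window:
        Odd side length of the grid patch used for background correction.
    min_replicates:
        Minimum unflagged replicas needed before a mean is reported.
    """

    noise_sd_multiplier: float = 2.0
    replicate_cv_threshold_pct: float = 20.0
    array_cv_threshold_pct: float = 20.0
    saturation_threshold_pct: float = 10.0
    saturation_enabled: bool = True
    selected_control: ControlLevel = ControlLevel.MED
    neighbourhood_window: int = 3
    min_replicates: int = 2

    def __post_init__(self) -> None:
        if isinstance(self.selected_control, str):
            self.selected_control = ControlLevel(self.selected_control.upper())
        if self.selected_control is ControlLevel.OVERALL:
            raise ValueError("selected_control must be LOW, MED or HIGH")
        for name in (
            "noise_sd_multiplier",
            "replicate_cv_threshold_pct",
            "array_cv_threshold_pct",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 <= self.saturation_threshold_pct <= 100.0:
            raise ValueError("saturation_threshold_pct must be in [0, 100]")
        if self.neighbourhood_window < 3 or self.neighbourhood_window % 2 == 0:
            raise ValueError("neighbourhood_window must be an odd integer >= 3")
        if self.min_replicates < 2:
            raise ValueError("min_replicates must be >= 2")

    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            d[f.name] = v.value if isinstance(v, enum.Enum) else v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Settings":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown settings: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "Settings":
        """Read settings from YAML or flat ``key=value`` lines."""
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) if text.strip() else {}
        if isinstance(loaded, dict):
            return cls.from_dict(loaded)
        # Fall back to the flat key=value dialect (also the run-record format).
        d: dict = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, sep, value = line.partition("=")
            if not sep:
                raise ValueError(f"cannot parse settings line: {line!r}")
            d[key.strip()] = yaml.safe_load(value.strip())
        return cls.from_dict(d)

    def to_file(self, path: str | Path) -> None:
        """Write flat ``key=value`` lines (the run-record format)."""
        lines = [f"{k}={v}" for k, v in self.to_dict().items()]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class ControlScheme:
    """Spot IDs playing control roles on the array.

    The three concentration IDs are the normalization positive control
    printed at a static position in every block at low < med < high
    concentration.  Extra positives (e.g. anti-human IgG / human IgG) and
    negatives (buffer-only, tag-only) are carried through but drive no
    pipeline rule.
    """

    positive_low_id: str
    positive_med_id: str
    positive_high_id: str
    extra_positive_ids: frozenset[str] = frozenset()
    negative_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        trio = {self.positive_low_id, self.positive_med_id, self.positive_high_id}
        if len(trio) != 3:
            raise ValueError("the three concentration control IDs must be distinct")

    @property
    def concentration_ids(self) -> tuple[str, str, str]:
        return (self.positive_low_id, self.positive_med_id, self.positive_high_id)

    def id_for_level(self, level: ControlLevel) -> str:
        return {
            ControlLevel.LOW: self.positive_low_id,
            ControlLevel.MED: self.positive_med_id,
            ControlLevel.HIGH: self.positive_high_id,
        }[level]

    @property
    def all_control_ids(self) -> frozenset[str]:
        return (
            frozenset(self.concentration_ids)
            | self.extra_positive_ids
            | self.negative_ids
        )


@dataclass(frozen=True)
class LayoutSpot:
    """One printed position: 1-based (block, row, col) plus identity."""

    block: int
    row: int
    col: int
    id: str
    name: str = ""


@dataclass
class ArrayLayout:
    """Printed geometry and identity of every spot on one array design."""

    n_blocks: int
    rows_per_block: int
    cols_per_block: int
    spots: list[LayoutSpot]
    control_scheme: ControlScheme

    def __post_init__(self) -> None:
        coords = [(s.block, s.row, s.col) for s in self.spots]
        if len(set(coords)) != len(coords):
            dupes = sorted({c for c in coords if coords.count(c) > 1})
            raise LayoutError(f"duplicate layout coordinates: {dupes[:5]}")

    @property
    def antigen_ids(self) -> list[str]:
        """Distinct IDs in first-appearance order (antigens and controls)."""
        seen: dict[str, None] = {}
        for s in self.spots:
            seen.setdefault(s.id, None)
        return list(seen)

    def spots_by_block(self) -> dict[int, list[LayoutSpot]]:
        out: dict[int, list[LayoutSpot]] = {b: [] for b in range(1, self.n_blocks + 1)}
        for s in self.spots:
            out.setdefault(s.block, []).append(s)
        return out

    def multiplicity(self, spot_id: str) -> int:
        return sum(1 for s in self.spots if s.id == spot_id)


@dataclass
class SpotRecord:
    """One spot's raw, corrected, flagged and normalized values (RFU)."""

    block: int
    row: int
    col: int
    id: str
    name: str
    raw_fg: float
    raw_bg: float
    bg_sd: float
    pct_saturated: float
    corrected_bg: Optional[float] = None
    net: Optional[float] = None
    normalized: Optional[float] = None
    flags: set[SpotFlag] = field(default_factory=set)

    @property
    def working_value(self) -> float:
        """Normalized value if set, else the corrected net intensity."""
        if self.normalized is not None:
            return self.normalized
        if self.net is None:
            raise ValueError("net intensity not yet computed")
        return self.net


@dataclass
class ArrayVerdict:
    array_id: str
    control_level: ControlLevel
    cv_pct: float
    verdict: Verdict


@dataclass
class ArrayData:
    """One scanned array: layout-aligned spot records + QC verdicts."""

    array_id: str
    source_path: str
    spots: list[SpotRecord]
    discard_verdicts: dict[ControlLevel, ArrayVerdict] = field(default_factory=dict)

    def spots_for_id(self, spot_id: str) -> list[SpotRecord]:
        return [s for s in self.spots if s.id == spot_id]

    def spots_by_block(self) -> dict[int, list[SpotRecord]]:
        out: dict[int, list[SpotRecord]] = {}
        for s in self.spots:
            out.setdefault(s.block, []).append(s)
        return out


@dataclass(frozen=True)
class ExcludedValue:
    value: float
    reason: str  # NOISY | SATURATED | OUTLIER


@dataclass
class ReplicateSummary:
    """Per-antigen-per-array replicate aggregation."""

    antigen_id: str
    array_id: str
    used_values: list[float]
    excluded: list[ExcludedValue]
    mean: Optional[float]
    cv_pct: Optional[float]
    status: ReplicateStatus

    @property
    def cell(self) -> float | str:
        """The consolidated-matrix cell: the mean or a sentinel string."""
        if self.status is ReplicateStatus.OK:
            assert self.mean is not None
            return self.mean
        return NOISY_SENTINEL if self.status is ReplicateStatus.NOISY else HIGH_CV_SENTINEL


@dataclass
class ConsolidatedMatrix:
    """Antigens x arrays; cells are RFU means or "NOISY"/"HIGH CV"."""

    antigen_ids: list[str]
    array_ids: list[str]
    cells: list[list[float | str]]

    def __post_init__(self) -> None:
        if len(self.cells) != len(self.antigen_ids):
            raise ValueError("row count does not match antigen_ids")
        for row in self.cells:
            if len(row) != len(self.array_ids):
                raise ValueError("column count does not match array_ids")

    def cell(self, antigen_id: str, array_id: str) -> float | str:
        return self.cells[self.antigen_ids.index(antigen_id)][
            self.array_ids.index(array_id)
        ]


@dataclass(frozen=True)
class Diagnostic:
    severity: str  # "error" | "warning"
    message: str

    @property
    def fatal(self) -> bool:
        return self.severity == "error"


def validate_layout(layout: ArrayLayout) -> list[Diagnostic]:
    """Check a parsed layout against the pipeline's expectations.

    Errors (abort the run): a concentration-control ID missing from any
    block.  Warnings: an antigen present below triplicate — such antigens
    are processed anyway, as the replicate mean already operates on two
    values, but the reduced redundancy is worth surfacing.

    Duplicate coordinates are rejected at construction time by
    :class:`ArrayLayout` itself.
    """
    diags: list[Diagnostic] = []
    scheme = layout.control_scheme
    by_block = layout.spots_by_block()
    for block in range(1, layout.n_blocks + 1):
        ids_here = {s.id for s in by_block.get(block, [])}
        for cid in scheme.concentration_ids:
            if cid not in ids_here:
                diags.append(
                    Diagnostic(
                        "error",
                        f"control ID {cid!r} missing from block {block}",
                    )
                )
    control_ids = scheme.all_control_ids
    for aid in layout.antigen_ids:
        if aid in control_ids:
            continue
        mult = layout.multiplicity(aid)
        if mult < 3:
            diags.append(
                Diagnostic(
                    "warning",
                    f"antigen {aid!r} present below triplicate ({mult} spot(s))",
                )
            )
    return diags
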