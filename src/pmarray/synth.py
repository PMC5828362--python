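"""Deterministic synthetic-slide generator with known ground truth.

Fabricates a GAL layout plus per-array GPR-style raw files following the
multiplicative signal model the pipeline is built to invert::

    raw_fg = signal * (1 + N(0, noise_cv)) + background + N(0, background_sd)
    signal = truth * array_gain * block_factor

Fluorescence noise scales with intensity, so the dominant noise term is
a fraction (``noise_cv``) of each spot's signal; ``background_sd`` is
the scanner's local-background SD, reported per spot and governing the
noise-floor threshold.

The three-concentration positive control sits at a static location (the
first three cells of row 1) in every block; unprinted cells are filled
with buffer-only negative spots.  Planted artefacts — spots below the
noise floor, one x-K outlier replica in selected groups, saturated
spots — are recorded in a machine-readable manifest so pipeline output
can be scored against truth.  Output is byte-identical for equal seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import ArrayLayout, ControlScheme, LayoutSpot

__all__ = ["SynthParams", "GroundTruth", "generate", "build_layout", "default_scheme"]

SCANNER_MAX = 65535.0  # 16-bit scanner ceiling

LOW_ID, MED_ID, HIGH_ID = "PC-LOW", "PC-MED", "PC-HIGH"
BUFFER_ID = "BUFFER"


def default_scheme() -> ControlScheme:
    return ControlScheme(
        positive_low_id=LOW_ID,
        positive_med_id=MED_ID,
        positive_high_id=HIGH_ID,
        negative_ids=frozenset({BUFFER_ID}),
    )


@dataclass
class SynthParams:
    """Study conditions for one synthetic dataset.

    Defaults model a small antibody-profiling slide: three replica
    arrays spanning a 4x scanner-gain range, three blocks per array with
    pin biases up to 25%, twenty antigens in triplicate with signals
    well above background, and a control dilution series (low < med <
    high) bracketing most antigen signals.  Spot noise defaults to 2% of
    each spot's signal on top of background jitter.
    """

    n_arrays: int = 3
    n_blocks: int = 3
    rows_per_block: int = 6
    cols_per_block: int = 6
    n_antigens: int = 20
    replicas_per_antigen: int = 3
    control_concentrations: tuple[float, float, float] = (2000.0, 8000.0, 24000.0)
    array_gains: tuple[float, ...] = (0.5, 1.0, 2.0)
    block_factors: tuple[float, ...] = (0.8, 1.0, 1.25)
    truth_range: tuple[float, float] = (3000.0, 20000.0)
    background_level: float = 500.0
    background_sd: float = 50.0
    noise_cv: float = 0.02
    noise_fraction: float = 0.05
    outlier_fraction: float = 0.05
    outlier_factor: float = 5.0
    saturated_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        low, med, high = self.control_concentrations
        if not low < med < high:
            raise ValueError("control concentrations must satisfy low < med < high")
        if len(self.array_gains) != self.n_arrays:
            raise ValueError("need one array gain per array")
        for frac in (self.noise_fraction, self.outlier_fraction, self.saturated_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("planting fractions must be in [0, 1]")
        capacity = self.n_blocks * (self.rows_per_block * self.cols_per_block - 3)
        needed = self.n_antigens * self.replicas_per_antigen
        if needed > capacity:
            raise ValueError(
                f"layout capacity {capacity} spots < {needed} antigen spots required"
            )
        if self.cols_per_block < 3:
            raise ValueError("need at least 3 columns for the control trio")

    def factor_for_block(self, array_idx: int, block: int) -> float:
        """Block factors cycle over the configured list; every array uses
        the same per-block pin biases (one pin prints one block position
        on every replica array)."""
        return self.block_factors[(block - 1) % len(self.block_factors)]


@dataclass
class GroundTruth:
    """Machine-readable record of everything the generator planted."""

    gains: dict[str, float]
    block_factors: dict[str, dict[int, float]]
    truths: dict[str, float]
    noisy_spots: set[tuple[str, int, int, int]]  # (array, block, row, col)
    outlier_spots: set[tuple[str, int, int, int]]
    saturated_spots: set[tuple[str, int, int, int]]
    outlier_groups: set[tuple[str, str]] = field(default_factory=set)  # (antigen, array)

    def expected_flagged_noisy(self, array_id: str) -> set[tuple[int, int, int]]:
        return {(b, r, c) for a, b, r, c in self.noisy_spots if a == array_id}


def build_layout(params: SynthParams) -> ArrayLayout:
    """Construct the printed layout: control trio in the first row of
    every block, antigen replicas spread round-robin across blocks,
    buffer spots in the leftover cells."""
    spots: list[LayoutSpot] = []
    free: dict[int, list[tuple[int, int]]] = {}
    for b in range(1, params.n_blocks + 1):
        cells = [
            (r, c)
            for r in range(1, params.rows_per_block + 1)
            for c in range(1, params.cols_per_block + 1)
        ]
        for (r, c), cid in zip(cells[:3], (LOW_ID, MED_ID, HIGH_ID)):
            spots.append(LayoutSpot(b, r, c, cid, cid))
        free[b] = cells[3:]

    for i in range(params.n_antigens):
        aid = f"AG{i + 1:03d}"
        for j in range(params.replicas_per_antigen):
            b = (i + j) % params.n_blocks + 1
            if not free[b]:  # preferred block full; spill anywhere with space
                b = next(bb for bb in free if free[bb])
            r, c = free[b].pop(0)
            spots.append(LayoutSpot(b, r, c, aid, aid))

    for b, cells in free.items():
        for r, c in cells:
            spots.append(LayoutSpot(b, r, c, BUFFER_ID, "buffer-only"))

    spots.sort(key=lambda s: (s.block, s.row, s.col))
    return ArrayLayout(
        n_blocks=params.n_blocks,
        rows_per_block=params.rows_per_block,
        cols_per_block=params.cols_per_block,
        spots=spots,
        control_scheme=default_scheme(),
    )


def _write_gal(layout: ArrayLayout, path: Path) -> None:
    n_headers = 2 + layout.n_blocks
    lines = ["ATF\t1.0", f"{n_headers}\t5", '"Type=GenePix ArrayList V1.0"']
    lines.append(f'"BlockCount={layout.n_blocks}"')
    for b in range(1, layout.n_blocks + 1):
        # xOrigin, yOrigin, diameter, nCols, colSpacing, nRows, rowSpacing
        lines.append(
            f'"Block{b}= {1000 * b}, 1000, 100, {layout.cols_per_block}, 200, '
            f'{layout.rows_per_block}, 200"'
        )
    lines.append("Block\tColumn\tRow\tID\tName")
    for s in layout.spots:
        lines.append(f"{s.block}\t{s.col}\t{s.row}\t{s.id}\t{s.name}")
    path.write_text("\n".join(lines) + "\n")


_RAW_COLUMNS = [
    "Block",
    "Column",
    "Row",
    "ID",
    "Name",
    "F635 Median",
    "B635 Median",
    "B635 SD",
    "F635 % Sat.",
]


def generate(params: SynthParams, out_dir: str | Path) -> tuple[dict, GroundTruth]:
    """Write the GAL, the raw files and the ground-truth manifest.

    Returns ``(paths, truth)`` where ``paths`` maps ``"gal"``,
    ``"raw"`` (list) and ``"manifest"`` to the created files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)
    layout = build_layout(params)

    array_ids = [f"array_{i + 1:02d}" for i in range(params.n_arrays)]
    gains = dict(zip(array_ids, (float(g) for g in params.array_gains)))
    block_factors = {
        aid: {
            b: float(params.factor_for_block(i, b))
            for b in range(1, params.n_blocks + 1)
        }
        for i, aid in enumerate(array_ids)
    }

    antigen_ids = sorted({s.id for s in layout.spots if s.id.startswith("AG")})
    lo, hi = params.truth_range
    truths = {aid: float(rng.uniform(lo, hi)) for aid in antigen_ids}
    conc = dict(zip((LOW_ID, MED_ID, HIGH_ID), params.control_concentrations))

    antigen_spots = [s for s in layout.spots if s.id in truths]
    spots_by_group: dict[str, list[LayoutSpot]] = {}
    for s in antigen_spots:
        spots_by_group.setdefault(s.id, []).append(s)

    # --- choose planted artefacts -------------------------------------
    # Outlier groups first: one replica x outlier_factor, only where the
    # boosted value stays clear of the scanner ceiling.
    n_groups = params.n_antigens * params.n_arrays
    n_outlier_groups = round(params.outlier_fraction * n_groups)
    eligible: list[tuple[str, str, LayoutSpot]] = []
    for aid in array_ids:
        g = gains[aid]
        for ag, group_spots in spots_by_group.items():
            worst = max(
                truths[ag] * g * block_factors[aid][s.block] for s in group_spots
            )
            if params.outlier_factor * worst + params.background_level < SCANNER_MAX * 0.97:
                spot = group_spots[0]
                eligible.append((ag, aid, spot))
    if n_outlier_groups > len(eligible):
        raise ValueError(
            f"cannot plant {n_outlier_groups} outlier groups; only "
            f"{len(eligible)} stay below the scanner ceiling"
        )
    idx = rng.choice(len(eligible), size=n_outlier_groups, replace=False) if n_outlier_groups else []
    outlier_groups = {(eligible[i][0], eligible[i][1]) for i in idx}
    outlier_spots = {
        (eligible[i][1], eligible[i][2].block, eligible[i][2].row, eligible[i][2].col)
        for i in idx
    }

    # Noisy and saturated spots: per array, among antigen spots whose
    # group carries no outlier (mixing artefacts in one group would make
    # the expected verdict ambiguous).
    noisy_spots: set[tuple[str, int, int, int]] = set()
    saturated_spots: set[tuple[str, int, int, int]] = set()
    n_antigen_spots = len(antigen_spots)
    n_noisy = round(params.noise_fraction * n_antigen_spots)
    n_sat = round(params.saturated_fraction * n_antigen_spots)
    for aid in array_ids:
        pool = [s for s in antigen_spots if (s.id, aid) not in outlier_groups]
        picks = rng.choice(len(pool), size=min(n_noisy + n_sat, len(pool)), replace=False)
        for k, p in enumerate(picks):
            s = pool[p]
            key = (aid, s.block, s.row, s.col)
            (noisy_spots if k < n_noisy else saturated_spots).add(key)

    # Buffer spots are below the noise floor by construction; record them
    # alongside the planted noisy spots so flag scoring covers every spot.
    for aid in array_ids:
        for s in layout.spots:
            if s.id == BUFFER_ID:
                noisy_spots.add((aid, s.block, s.row, s.col))

    truth = GroundTruth(
        gains=gains,
        block_factors=block_factors,
        truths=truths,
        noisy_spots=noisy_spots,
        outlier_spots=outlier_spots,
        saturated_spots=saturated_spots,
        outlier_groups=outlier_groups,
    )

    # --- write files ---------------------------------------------------
    gal_path = out_dir / "layout.gal"
    _write_gal(layout, gal_path)

    raw_dir = out_dir / "raw"
    raw_dir.mkdir(exist_ok=True)
    raw_paths = []
    for aid in array_ids:
        g = gains[aid]
        lines = ["ATF\t1.0", "2\t9", f'"ArrayID={aid}"', '"Wavelengths=635"']
        lines.append("\t".join(_RAW_COLUMNS))
        for s in layout.spots:
            key = (aid, s.block, s.row, s.col)
            f_b = block_factors[aid][s.block]
            bg = params.background_level + float(
                rng.normal(0.0, params.background_sd / 5.0)
            )
            rel_noise = float(rng.normal(0.0, params.noise_cv))
            bg_noise = float(rng.normal(0.0, params.background_sd))
            pct_sat = 0.0
            if s.id == BUFFER_ID or key in noisy_spots:
                fg = max(0.0, params.background_level - params.background_sd)
            elif key in saturated_spots:
                fg, pct_sat = SCANNER_MAX, 50.0
            else:
                level = conc[s.id] if s.id in conc else truths[s.id]
                signal = level * g * f_b
                if key in outlier_spots:
                    signal *= params.outlier_factor
                fg = signal * (1.0 + rel_noise) + params.background_level + bg_noise
                fg = min(max(fg, 0.0), SCANNER_MAX)
            lines.append(
                f"{s.block}\t{s.col}\t{s.row}\t{s.id}\t{s.name}\t"
                f"{fg!r}\t{bg!r}\t{params.background_sd!r}\t{pct_sat!r}"
            )
        p = raw_dir / f"{aid}.txt"
        p.write_text("\n".join(lines) + "\n")
        raw_paths.append(p)

    manifest_path = out_dir / "ground_truth.tsv"
    with open(manifest_path, "w") as fh:
        fh.write("Record\tArray\tBlock\tRow\tColumn\tID\tValue\n")
        for aid, g in gains.items():
            fh.write(f"gain\t{aid}\t-\t-\t-\t-\t{g!r}\n")
        for aid, factors in block_factors.items():
            for b, f in factors.items():
                fh.write(f"block_factor\t{aid}\t{b}\t-\t-\t-\t{f!r}\n")
        for ag, t in truths.items():
            fh.write(f"truth\t-\t-\t-\t-\t{ag}\t{t!r}\n")
        id_at = {(s.block, s.row, s.col): s.id for s in layout.spots}
        for record, keys in (
            ("noisy_spot", noisy_spots),
            ("outlier_spot", outlier_spots),
            ("saturated_spot", saturated_spots),
        ):
            for aid, b, r, c in sorted(keys):
                fh.write(f"{record}\t{aid}\t{b}\t{r}\t{c}\t{id_at[(b, r, c)]}\t-\n")

    paths = {"gal": gal_path, "raw": raw_paths, "manifest": manifest_path}
    return paths, truth
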