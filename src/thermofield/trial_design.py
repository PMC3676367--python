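"""Replicated incomplete-block field layouts.

A trial places ``n_genotypes`` genotypes, each replicated ``n_reps`` times, on
a rectangular grid of plots.  Replicates occupy contiguous superblocks of rows
(a *resolvable* design) and, within each replicate, genotypes are partitioned
into incomplete blocks of a fixed small size whose order and contents are
randomised.  This reproduces the randomisation structure of an alpha design
(small incomplete blocks nested in complete replicates) without claiming
alpha-optimality of the block allocation; only the randomisation structure
matters to the downstream normalisation and resampling analyses.

Internal plot coordinates are 0-based ``(row, col)``; the CSV interface is
1-based, matching field-book convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlotKey",
    "PlotObservation",
    "TrialDesign",
    "generate_layout",
    "validate_design",
    "design_to_frame",
    "design_from_frame",
]

DESIGN_CSV_COLUMNS = ["trial_id", "row", "col", "genotype", "replicate", "block"]


@dataclass(frozen=True, order=True)
class PlotKey:
    """Identifies one plot: a (row, col) cell of a named trial, 0-based."""

    trial_id: str
    row: int
    col: int


@dataclass
class PlotObservation:
    """One plot's raw canopy temperature (IPT) in one image.

    ``ipt`` is the mean temperature (°C) of the plot's canopy pixels in a
    single image.  ``n_pixels``/``n_excluded`` record the quality-control
    bookkeeping of the pixel extraction; observations generated directly at
    plot level (without a pixel stage) carry ``n_pixels=1, n_excluded=0``.
    ``qc_flag`` marks observations whose pixel exclusion fraction exceeded the
    QC threshold; flagged observations are dropped by the normaliser.
    """

    plot: PlotKey
    image_id: str
    ipt: float
    n_pixels: int = 1
    n_excluded: int = 0
    qc_flag: bool = False


@dataclass
class TrialDesign:
    """Grid layout mapping (row, col) plot cells to genotype/replicate/block.

    Invariants (checked by :func:`validate_design`): every genotype appears
    exactly ``n_reps`` times, the grid is full with no cell assigned twice,
    and every block holds ``block_size`` distinct plots.
    """

    trial_id: str
    n_rows: int
    plots_per_row: int
    block_size: int
    assignments: dict[tuple[int, int], tuple[str, int, int]] = field(default_factory=dict)

    @property
    def n_plots(self) -> int:
        return self.n_rows * self.plots_per_row

    @property
    def genotypes(self) -> list[str]:
        """Sorted distinct genotype identifiers."""
        return sorted({g for g, _, _ in self.assignments.values()})

    @property
    def n_reps(self) -> int:
        return len({r for _, r, _ in self.assignments.values()})

    def genotype_of(self, key: PlotKey) -> str:
        return self.assignments[(key.row, key.col)][0]

    def replicate_of(self, key: PlotKey) -> int:
        return self.assignments[(key.row, key.col)][1]

    def plots(self) -> list[PlotKey]:
        """All plot keys in row-major order."""
        return [
            PlotKey(self.trial_id, r, c)
            for r in range(self.n_rows)
            for c in range(self.plots_per_row)
        ]


def generate_layout(
    n_genotypes: int,
    n_reps: int,
    plots_per_row: int,
    block_size: int,
    seed: int,
    trial_id: str = "trial1",
) -> TrialDesign:
    """Generate a resolvable randomised incomplete-block layout.

    Each replicate occupies a contiguous band of rows.  Within a replicate the
    genotypes are shuffled, partitioned into blocks of ``block_size``, the
    block order shuffled again, and the result laid out row-major.  The same
    seed always yields the bitwise-identical layout.

    Parameters
    ----------
    n_genotypes, n_reps
        Number of distinct genotypes and complete replicates.  Their product
        must be divisible by ``plots_per_row`` so replicates fill whole rows.
    plots_per_row
        Plots per field row (e.g. 16: a 192 x 2 trial then has 24 rows).
    block_size
        Incomplete-block size (the study design used 8); must be at least 2
        and divide either ``plots_per_row`` or ``n_genotypes``.
    seed
        Randomisation seed.

    Raises
    ------
    ValueError
        If the grid dimensions do not resolve or ``block_size`` is invalid.
    """
    if n_genotypes < 1 or n_reps < 1 or plots_per_row < 1:
        raise ValueError("n_genotypes, n_reps and plots_per_row must be positive")
    if block_size < 2:
        raise ValueError(f"block_size must be >= 2, got {block_size}")
    if (n_genotypes * n_reps) % plots_per_row != 0:
        raise ValueError(
            f"n_genotypes*n_reps = {n_genotypes * n_reps} not divisible by "
            f"plots_per_row = {plots_per_row}"
        )
    if n_genotypes % block_size != 0 and plots_per_row % block_size != 0:
        raise ValueError(
            f"block_size = {block_size} divides neither n_genotypes = "
            f"{n_genotypes} nor plots_per_row = {plots_per_row}"
        )
    if n_genotypes % plots_per_row != 0:
        raise ValueError(
            "each replicate must fill whole rows: n_genotypes "
            f"{n_genotypes} not divisible by plots_per_row {plots_per_row}"
        )

    rng = np.random.default_rng(seed)
    width = max(3, len(str(n_genotypes)))
    genotype_ids = [f"G{i + 1:0{width}d}" for i in range(n_genotypes)]
    rows_per_rep = n_genotypes // plots_per_row

    assignments: dict[tuple[int, int], tuple[str, int, int]] = {}
    block_counter = 0
    for rep in range(1, n_reps + 1):
        order = rng.permutation(n_genotypes)
        blocks = [order[i : i + block_size] for i in range(0, n_genotypes, block_size)]
        rng.shuffle(blocks)
        flat = [genotype_ids[g] for blk in blocks for g in blk]
        # block ids follow the shuffled block order, globally unique
        block_of = np.repeat(
            np.arange(block_counter + 1, block_counter + 1 + len(blocks)), block_size
        )[: len(flat)]
        block_counter += len(blocks)
        row0 = (rep - 1) * rows_per_rep
        for i, geno in enumerate(flat):
            r, c = row0 + i // plots_per_row, i % plots_per_row
            assignments[(r, c)] = (geno, rep, int(block_of[i]))

    return TrialDesign(
        trial_id=trial_id,
        n_rows=rows_per_rep * n_reps,
        plots_per_row=plots_per_row,
        block_size=block_size,
        assignments=assignments,
    )


def validate_design(design: TrialDesign) -> list[str]:
    """Check the design invariants; return human-readable violations.

    An empty list means the design is valid.  Violations are reported, never
    raised, so a field book with gaps can still be inspected.
    """
    report: list[str] = []
    cells = {(r, c) for r in range(design.n_rows) for c in range(design.plots_per_row)}
    for rc in sorted(cells - set(design.assignments)):
        report.append(f"missing assignment at (row, col) = {rc}")
    for rc in sorted(set(design.assignments) - cells):
        report.append(f"assignment outside grid at (row, col) = {rc}")

    counts: dict[str, int] = {}
    for g, _, _ in design.assignments.values():
        counts[g] = counts.get(g, 0) + 1
    n_reps = design.n_reps
    for g in sorted(counts):
        if counts[g] != n_reps:
            report.append(
                f"genotype {g} appears {counts[g]} times, expected {n_reps}"
            )
    if design.n_rows * design.plots_per_row != len(counts) * n_reps and not report:
        report.append(
            f"grid size {design.n_rows * design.plots_per_row} != "
            f"{len(counts)} genotypes x {n_reps} replicates"
        )

    blocks: dict[int, set[tuple[int, int]]] = {}
    for rc, (_, _, b) in design.assignments.items():
        blocks.setdefault(b, set()).add(rc)
    for b in sorted(blocks):
        if len(blocks[b]) != design.block_size:
            report.append(
                f"block {b} has {len(blocks[b])} plots, expected {design.block_size}"
            )
    return report


# ---------------------------------------------------------------------------
# CSV interface (1-based row/col externally)

def design_to_frame(design: TrialDesign) -> pd.DataFrame:
    """Design as a tidy DataFrame with 1-based row/col, row-major order."""
    records = [
        {
            "trial_id": design.trial_id,
            "row": r + 1,
            "col": c + 1,
            "genotype": g,
            "replicate": rep,
            "block": blk,
        }
        for (r, c), (g, rep, blk) in sorted(design.assignments.items())
    ]
    return pd.DataFrame.from_records(records, columns=DESIGN_CSV_COLUMNS)


def design_from_frame(frame: pd.DataFrame, block_size: int | None = None) -> TrialDesign:
    """Rebuild a :class:`TrialDesign` from the tidy CSV dialect (lossless)."""
    missing = set(DESIGN_CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    trial_ids = frame["trial_id"].unique()
    if len(trial_ids) != 1:
        raise ValueError(f"expected one trial_id, got {list(trial_ids)}")
    assignments = {
        (int(rec.row) - 1, int(rec.col) - 1): (str(rec.genotype), int(rec.replicate), int(rec.block))
        for rec in frame.itertuples()
    }
    if block_size is None:
        counts: dict[int, int] = {}
        for _, _, b in assignments.values():
            counts[b] = counts.get(b, 0) + 1
        block_size = int(max(counts.values()))
    return TrialDesign(
        trial_id=str(trial_ids[0]),
        n_rows=int(frame["row"].max()),
        plots_per_row=int(frame["col"].max()),
        block_size=block_size,
        assignments=assignments,
    )


def read_design_csv(path) -> TrialDesign:
    return design_from_frame(pd.read_csv(path))


def write_design_csv(design: TrialDesign, path) -> None:
    design_to_frame(design).to_csv(path, index=False)
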