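"""Grouping of genome-wide-significant loci into genomic blocks.

Within each (model, direction) stratum, loci sharing a chromosome are sorted
by position and split wherever two consecutive positioned loci are separated
by more than a configurable gap (default 5 Mb). Loci whose position is
unknown but whose chromosome is known are attached to that chromosome's
block when exactly one block exists there for the stratum, otherwise left
unassigned. Loci with unknown chromosome each form their own "unplaced"
singleton. A locus carrying an alternative-assembly chromosome note is
reassigned to that chromosome before grouping. Spans are computed over
positioned members only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CHROM_ORDER, TransplantCohort
from .mismatch import MATCHED, MISMATCHED, MatchMatrix

DEFAULT_GAP_BP = 5_000_000


@dataclass
class Block:
    """A run of significant loci on one chromosome for one model/direction."""

    model: str
    direction: str
    chromosome: str
    member_positions: list[int]  # positioned members, ascending
    n_unpositioned: int = 0
    unplaced: bool = False
    member_ids: list = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return len(self.member_positions) + self.n_unpositioned

    @property
    def n_positioned(self) -> int:
        return len(self.member_positions)

    @property
    def start_bp(self) -> int | None:
        return self.member_positions[0] if self.member_positions else None

    @property
    def end_bp(self) -> int | None:
        return self.member_positions[-1] if self.member_positions else None

    @property
    def span_bp(self) -> int:
        if self.n_positioned < 2:
            return 0
        return self.end_bp - self.start_bp


def block_span_mbp(block: Block) -> float | None:
    """Span in megabases, rounded to one decimal; None below two positioned members."""
    if block.n_positioned < 2:
        return None
    return round(block.span_bp / 1e6, 1)


def significant_rows(table: pd.DataFrame) -> pd.DataFrame:
    """Long-format significant rows (one per locus per model flag).

    Accepts the curated significant-SNP table (columns ``model1``/``model2``
    boolean flags) and expands it so each row names a single model, ready for
    :func:`find_blocks`.
    """
    rows = []
    for model_col, model in (("model1", "model1"), ("model2", "model2")):
        sub = table[table[model_col]].copy()
        sub["model"] = model
        rows.append(sub)
    out = pd.concat(rows, ignore_index=True)
    cols = ["chromosome", "position_bp", "model", "direction", "alt_chromosome", "unknown_location"]
    extra = [c for c in ("locus_id", "position_bp_alt") if c in out.columns]
    return out[cols + extra]


def find_blocks(
    significant: pd.DataFrame, gap_bp: int = DEFAULT_GAP_BP
) -> tuple[list[Block], pd.DataFrame]:
    """Group significant loci into blocks.

    ``significant`` needs columns ``chromosome``, ``position_bp``, ``model``,
    ``direction`` and optionally ``alt_chromosome`` / ``unknown_location``
    (derived from ``position_bp == 0`` when absent) and ``locus_id``.

    Returns ``(blocks, unassigned)`` where ``unassigned`` lists
    known-chromosome, unknown-position rows that could not be attached
    because their chromosome carries zero or several blocks in the stratum.
    """
    if gap_bp <= 0:
        raise ValueError("gap_bp must be positive")
    df = significant.copy().reset_index(drop=True)
    df["chromosome"] = df["chromosome"].astype(str)
    if "unknown_location" not in df.columns:
        df["unknown_location"] = df["position_bp"] == 0
    if "alt_chromosome" in df.columns:
        # a locus whose assembly footnote moves it to another chromosome keeps
        # no usable coordinate there: reassign and treat as position-unknown
        alt = df["alt_chromosome"].fillna("").astype(str)
        moved = alt != ""
        df.loc[moved, "chromosome"] = alt[moved]
        df.loc[moved, "unknown_location"] = True
    if "locus_id" not in df.columns:
        df["locus_id"] = [
            f"{c}:{p}" if p else f"{c}:unknown{i}"
            for i, (c, p) in enumerate(zip(df["chromosome"], df["position_bp"]))
        ]

    blocks: list[Block] = []
    leftovers = []
    for (model, direc), stratum in df.groupby(["model", "direction"], sort=True):
        # unknown chromosome: unplaced singletons
        for _, row in stratum[stratum["chromosome"] == "0"].iterrows():
            blocks.append(
                Block(model, direc, "0", [], n_unpositioned=1, unplaced=True,
                      member_ids=[row["locus_id"]])
            )
        placed = stratum[stratum["chromosome"] != "0"]
        for chrom in sorted(placed["chromosome"].unique(), key=CHROM_ORDER.get):
            sub = placed[placed["chromosome"] == chrom]
            pos = sub[~sub["unknown_location"]].sort_values("position_bp", kind="stable")
            chrom_blocks: list[Block] = []
            for _, row in pos.iterrows():
                p = int(row["position_bp"])
                if chrom_blocks and p - chrom_blocks[-1].member_positions[-1] <= gap_bp:
                    chrom_blocks[-1].member_positions.append(p)
                    chrom_blocks[-1].member_ids.append(row["locus_id"])
                else:
                    chrom_blocks.append(Block(model, direc, chrom, [p], member_ids=[row["locus_id"]]))
            unpos = sub[sub["unknown_location"]]
            if len(unpos):
                if len(chrom_blocks) == 1:
                    chrom_blocks[0].n_unpositioned += len(unpos)
                    chrom_blocks[0].member_ids.extend(unpos["locus_id"])
                else:
                    leftovers.append(unpos)
            blocks.extend(chrom_blocks)
    unassigned = (
        pd.concat(leftovers, ignore_index=True)
        if leftovers
        else df.iloc[0:0]
    )
    return blocks, unassigned


_BLOCK_COLUMNS = [
    "model", "direction", "chromosome", "n_snps", "n_positioned",
    "start_bp", "end_bp", "span_mbp", "unplaced", "member_ids",
]


def blocks_table(blocks: list[Block]) -> pd.DataFrame:
    """Tabular block summary (one row per block)."""
    if not blocks:
        return pd.DataFrame(columns=_BLOCK_COLUMNS)
    rows = []
    for b in blocks:
        rows.append(
            {
                "model": b.model,
                "direction": b.direction,
                "chromosome": b.chromosome,
                "n_snps": b.n_snps,
                "n_positioned": b.n_positioned,
                "start_bp": b.start_bp,
                "end_bp": b.end_bp,
                "span_mbp": block_span_mbp(b),
                "unplaced": b.unplaced,
                "member_ids": ";".join(str(m) for m in b.member_ids),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class OutcomeGroupCounts:
    """Distribution of pairs over the four outcome groups at one locus."""

    matched_accepted: int
    matched_rejected: int
    mismatched_accepted: int
    mismatched_rejected: int

    @property
    def total(self) -> int:
        return (
            self.matched_accepted
            + self.matched_rejected
            + self.mismatched_accepted
            + self.mismatched_rejected
        )

    @property
    def accuracy(self) -> float:
        """Predictive accuracy: concordant (matched-accepted + mismatched-rejected) fraction."""
        if self.total == 0:
            raise ValueError("no pairs with known status")
        return (self.matched_accepted + self.mismatched_rejected) / self.total


def outcome_groups(
    match: MatchMatrix, cohort: TransplantCohort | None = None, locus_id: str | None = None
) -> OutcomeGroupCounts:
    """Count the four outcome groups at one locus (known-status pairs only)."""
    cohort = cohort if cohort is not None else match.cohort
    loci = match.genotypes.loci
    idx = np.flatnonzero((loci["locus_id"] == locus_id).to_numpy())
    if idx.size == 0:
        raise KeyError(f"unknown locus_id {locus_id!r}")
    col = match.status[:, int(idx[0])]
    rej = cohort.rejected
    return OutcomeGroupCounts(
        matched_accepted=int(((col == MATCHED) & ~rej).sum()),
        matched_rejected=int(((col == MATCHED) & rej).sum()),
        mismatched_accepted=int(((col == MISMATCHED) & ~rej).sum()),
        mismatched_rejected=int(((col == MISMATCHED) & rej).sum()),
    )
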