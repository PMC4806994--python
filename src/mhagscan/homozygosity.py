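"""Within-line homozygosity profiling.

A SNP is *fixed* (invariant) within a line when every non-missing call in
that line is the same homozygote; otherwise it is *segregating*. Minor allele
frequency and heterozygosity are summarised over segregating SNPs only, per
chromosome and genome-wide. Loci with no non-missing call in a line are
excluded from that line's denominators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CHROM_ORDER, MISSING, GenotypeMatrix

#: Pseudo-chromosome label used for loci whose placement is unknown ("0").
UNKNOWN_LABEL = "Unknown position"
TOTAL_LABEL = "Total"

CATEGORIES = ("major_hom", "het", "minor_hom", "unknown")


def _genotype_counts(calls: np.ndarray):
    """Per-locus counts of (AA, AB, BB, called) over a samples x loci slice."""
    n_aa = (calls == 0).sum(axis=0)
    n_ab = (calls == 1).sum(axis=0)
    n_bb = (calls == 2).sum(axis=0)
    return n_aa, n_ab, n_bb, n_aa + n_ab + n_bb


def _per_locus_stats(calls: np.ndarray):
    """Return (has_data, fixed, maf, het) per locus for one line's calls.

    ``maf``/``het`` are NaN at fixed or all-missing loci.
    """
    n_aa, n_ab, n_bb, n_called = _genotype_counts(calls)
    a = 2 * n_aa + n_ab  # A-allele count
    b = 2 * n_bb + n_ab
    has_data = n_called > 0
    fixed = has_data & ((a == 0) | (b == 0))
    seg = has_data & ~fixed
    with np.errstate(divide="ignore", invalid="ignore"):
        maf = np.where(seg, np.minimum(a, b) / np.maximum(a + b, 1), np.nan)
        het = np.where(seg, n_ab / np.maximum(n_called, 1), np.nan)
    return has_data, fixed, maf, het


def _summarise(has_data, fixed, maf, het, sel):
    n_snps = int((has_data & sel).sum())
    n_fixed = int((fixed & sel).sum())
    n_seg = n_snps - n_fixed
    row = {
        "n_snps": n_snps,
        "prop_fixed": n_fixed / n_snps if n_snps else np.nan,
        "n_segregating": n_seg,
        "mean_maf": float(np.nanmean(np.where(sel, maf, np.nan))) if n_seg else np.nan,
        "mean_het": float(np.nanmean(np.where(sel, het, np.nan))) if n_seg else np.nan,
    }
    return row


def line_stats(
    genotypes: GenotypeMatrix,
    lines: list[str] | None = None,
    group_by: str = "chromosome",
) -> pd.DataFrame:
    """Per-line fixation/MAF/heterozygosity summaries.

    With ``group_by="chromosome"`` one row is emitted per line per chromosome
    (unknown-placement loci under their own pseudo-chromosome) plus a
    genome-total row per line; ``group_by="genome"`` emits only the totals.
    """
    if group_by not in ("chromosome", "genome"):
        raise ValueError(f"group_by must be 'chromosome' or 'genome', got {group_by!r}")
    lines = list(lines) if lines is not None else genotypes.lines
    chrom = genotypes.loci["chromosome"].astype(str).to_numpy()

    out = []
    for line in lines:
        mask = genotypes.line_mask(line)
        has_data, fixed, maf, het = _per_locus_stats(genotypes.calls[mask])
        if group_by == "chromosome":
            present = [c for c in sorted(set(chrom), key=CHROM_ORDER.get)]
            for c in present:
                sel = chrom == c
                label = UNKNOWN_LABEL if c == "0" else c
                out.append({"line": line, "chromosome": label, **_summarise(has_data, fixed, maf, het, sel)})
        out.append(
            {"line": line, "chromosome": TOTAL_LABEL, **_summarise(has_data, fixed, maf, het, np.ones_like(chrom, bool))}
        )
    return pd.DataFrame(out)


def cross_line_fixed(genotypes: GenotypeMatrix, lines: list[str] | None = None) -> float:
    """Fraction of SNPs fixed for the same homozygote across all named lines.

    The denominator is restricted to SNPs with at least one non-missing call
    in every named line, mirroring the per-line treatment of missing data.
    """
    lines = list(lines) if lines is not None else genotypes.lines
    if len(lines) < 2:
        raise ValueError("cross_line_fixed needs at least two lines")
    all_has = np.ones(genotypes.n_loci, dtype=bool)
    all_fixed = np.ones(genotypes.n_loci, dtype=bool)
    fixed_allele = None
    same = np.ones(genotypes.n_loci, dtype=bool)
    for line in lines:
        calls = genotypes.calls[genotypes.line_mask(line)]
        has_data, fixed, _, _ = _per_locus_stats(calls)
        n_aa, _, n_bb, _ = _genotype_counts(calls)
        allele = np.where(n_aa > 0, 0, 2)  # the fixed homozygote, valid where fixed
        all_has &= has_data
        all_fixed &= fixed
        if fixed_allele is None:
            fixed_allele = allele
        else:
            same &= allele == fixed_allele
    denom = int(all_has.sum())
    if denom == 0:
        raise ValueError("no locus has data in every requested line")
    return float((all_has & all_fixed & same).sum() / denom)


def homozygosity_map(genotypes: GenotypeMatrix, chromosome: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotype-category map of one chromosome, one row per pig.

    The *major* allele is the more frequent allele at a locus **within each
    pig's own line** (ties broken toward allele label A); every heterozygote
    is ``het`` and every missing call ``unknown``. Returns ``(loci, rows)``
    where ``loci`` is the position-sorted locus table for the chromosome and
    ``rows`` holds ``sample_id``, ``line`` and one category column per locus.
    """
    chromosome = str(chromosome)
    sel = genotypes.loci["chromosome"].astype(str) == chromosome
    if not sel.any():
        raise ValueError(f"chromosome {chromosome!r} not present in the locus map")
    loci = genotypes.loci.loc[sel].sort_values("position_bp", kind="stable")
    order = loci.index.to_numpy()
    loci = loci.reset_index(drop=True)

    n = genotypes.n_samples
    cats = np.empty((n, len(order)), dtype=object)
    for line in genotypes.lines:
        mask = genotypes.line_mask(line)
        calls = genotypes.calls[np.ix_(mask, order)]
        n_aa, _, n_bb, _ = _genotype_counts(calls)
        # major homozygote call code: 0 (AA) when A at least as frequent, else 2
        major_code = np.where(2 * n_aa >= 2 * n_bb, 0, 2)
        block = np.where(
            calls == MISSING,
            "unknown",
            np.where(calls == 1, "het", np.where(calls == major_code, "major_hom", "minor_hom")),
        )
        cats[mask] = block
    rows = pd.concat(
        [
            genotypes.samples[["sample_id", "line"]].reset_index(drop=True),
            pd.DataFrame(cats, columns=list(loci["locus_id"])),
        ],
        axis=1,
    )
    return loci, rows


def plot_homozygosity_map(loci: pd.DataFrame, rows: pd.DataFrame, path=None, ax=None):
    """Render a homozygosity map (pigs x SNPs raster, colour per category)."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    codes = {"major_hom": 0, "het": 1, "minor_hom": 2, "unknown": 3}
    cells = rows.drop(columns=["sample_id", "line"])
    grid = np.vectorize(codes.get)(cells.to_numpy())
    cmap = ListedColormap(["#b2182b", "#fddbc7", "#2166ac", "#ffffff"])
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 0.25 * len(rows) + 1))
    ax.imshow(grid, aspect="auto", interpolation="nearest", cmap=cmap, vmin=-0.5, vmax=3.5)
    ax.set_yticks(range(len(rows)))
    ax.set_yticklabels(rows["sample_id"])
    ax.set_xlabel("SNPs (ascending position)")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def write_line_stats(stats: pd.DataFrame, path, header_comment: str | None = None):
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        stats.to_csv(fh, sep="\t", index=False, float_format="%.4f")
    return path
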