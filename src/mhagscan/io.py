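"""Genotype, pedigree-pair and significant-SNP table input/output.

Genotype calls are biallelic and unordered; allele identity is abstracted to
the labels ``A``/``B`` per locus because every downstream computation
(homozygosity, donor-recipient matching) depends only on allele identity and
difference, never on the nucleotide. Calls are stored as the count of ``B``
alleles (0 = AA, 1 = AB, 2 = BB) with ``-1`` for a missing call.

Two on-disk dialects are supported:

* ``ped_map`` — whitespace-delimited PLINK-style PED/MAP text files. The PED
  family id column carries the line label; missing calls are ``0 0``.
* ``tsv`` — a genotype table with header ``sample_id  line  sex  <locus ids>``,
  one sample per row, each call a two-character string over the per-locus
  allele alphabet, ``NN`` = missing; the locus map travels in a companion
  ``.map.tsv`` with columns ``locus_id  chromosome  position_bp``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

#: Valid chromosome labels: 18 autosomes, X, and "0" for unknown placement.
CHROMOSOMES = tuple(str(c) for c in range(1, 19)) + ("X", "0")

#: Canonical sort order for chromosomes (unknown placement last).
CHROM_ORDER = {c: i for i, c in enumerate(CHROMOSOMES)}


class ParseError(ValueError):
    """Structured failure while reading an input file."""


@dataclass
class GenotypeMatrix:
    """Samples x loci biallelic genotype calls with line labels and a locus map.

    Attributes
    ----------
    samples : pandas.DataFrame
        Columns ``sample_id``, ``line``, ``sex`` (``1``/``2``/``0`` unknown);
        row order matches the rows of ``calls``.
    loci : pandas.DataFrame
        Columns ``locus_id``, ``chromosome``, ``position_bp``, ``assembly``,
        ``alt_chromosome`` (empty string when no alternative-assembly
        assignment exists); row order matches the columns of ``calls``.
    calls : numpy.ndarray
        ``int8`` array of shape ``(n_samples, n_loci)`` holding the count of
        B alleles, ``-1`` for missing.
    """

    samples: pd.DataFrame
    loci: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def validate(self) -> None:
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples["sample_id"][self.samples["sample_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate sample_id {dup!r}")
        if self.loci["locus_id"].duplicated().any():
            dup = self.loci["locus_id"][self.loci["locus_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate locus_id {dup!r}")
        bad = ~self.loci["chromosome"].astype(str).isin(CHROMOSOMES)
        if bad.any():
            raise ValueError(
                f"unknown chromosome label {self.loci.loc[bad, 'chromosome'].iloc[0]!r}"
            )
        if not np.isin(self.calls, (-1, 0, 1, 2)).all():
            raise ValueError("calls must be in {-1, 0, 1, 2}")

    def sample_index(self, sample_id: str) -> int:
        idx = np.flatnonzero((self.samples["sample_id"] == sample_id).to_numpy())
        if idx.size == 0:
            raise KeyError(f"unknown sample_id {sample_id!r}")
        return int(idx[0])

    def line_mask(self, line: str) -> np.ndarray:
        mask = (self.samples["line"] == line).to_numpy()
        if not mask.any():
            raise ValueError(f"no samples in line {line!r}")
        return mask

    @property
    def lines(self) -> list[str]:
        return list(dict.fromkeys(self.samples["line"]))


@dataclass
class TransplantCohort:
    """Donor -> recipient transplant pairs with binary graft outcome.

    ``pairs`` has columns ``donor_id``, ``recipient_id``, ``outcome``
    (``"accepted"``/``"rejected"``). ``donor_idx``/``recipient_idx`` are row
    indices into the genotype matrix the cohort was resolved against.
    """

    pairs: pd.DataFrame
    donor_idx: np.ndarray
    recipient_idx: np.ndarray

    def __post_init__(self) -> None:
        if self.pairs["recipient_id"].duplicated().any():
            dup = self.pairs["recipient_id"][self.pairs["recipient_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate recipient_id {dup!r}: one graft per recipient")
        bad = ~self.pairs["outcome"].isin(("accepted", "rejected"))
        if bad.any():
            raise ValueError(f"invalid outcome {self.pairs.loc[bad, 'outcome'].iloc[0]!r}")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def rejected(self) -> np.ndarray:
        """Boolean outcome vector (True = rejected), ordered as ``pairs``."""
        return (self.pairs["outcome"] == "rejected").to_numpy()


def make_cohort(pairs: pd.DataFrame, genotypes: GenotypeMatrix) -> TransplantCohort:
    """Resolve a pair table against a genotype matrix into a cohort."""
    pairs = pairs.reset_index(drop=True).copy()
    pairs["outcome"] = pairs["outcome"].str.strip().str.lower()
    didx, ridx = [], []
    for _, row in pairs.iterrows():
        for col, store in (("donor_id", didx), ("recipient_id", ridx)):
            try:
                store.append(genotypes.sample_index(str(row[col])))
            except KeyError:
                raise ParseError(f"pair table names unknown {col} {row[col]!r}") from None
    return TransplantCohort(pairs, np.array(didx, dtype=int), np.array(ridx, dtype=int))


# ---------------------------------------------------------------------------
# allele normalisation shared by both dialects


def _normalise_locus_alleles(a1, a2, locus_id: str, missing: str):
    """Map per-locus observed allele codes to {A, B}.

    Files already written in the canonical {A, B} alphabet keep their labels
    (so write/read round-trips are exact); any other allele codes (e.g.
    nucleotides) are assigned in first-observed order. Raises on >2 distinct
    alleles or half-missing calls.
    """
    n = len(a1)
    calls = np.full(n, MISSING, dtype=np.int8)
    seen: dict[str, int] = {}
    order = []
    for i in range(n):
        x, y = a1[i], a2[i]
        if x == missing or y == missing:
            if x != y:
                raise ParseError(
                    f"locus {locus_id!r}: half-missing call {x!r}/{y!r} in sample row {i + 1}"
                )
            continue
        for al in (x, y):
            if al not in seen:
                if len(seen) == 2:
                    raise ParseError(
                        f"locus {locus_id!r} has more than two alleles: "
                        f"{sorted(seen) + [al]}"
                    )
                seen[al] = len(seen)
                order.append(al)
    if set(seen) <= {"A", "B"}:
        seen = {"A": 0, "B": 1}
    for i in range(n):
        x, y = a1[i], a2[i]
        if x != missing:
            calls[i] = seen[x] + seen[y]
    return calls


def _drop_y(loci: pd.DataFrame, calls: np.ndarray):
    """Y-chromosome loci are outside the analysed genome; drop with a warning."""
    is_y = loci["chromosome"].astype(str).str.upper() == "Y"
    if is_y.any():
        logger.warning("dropping %d Y-chromosome loci", int(is_y.sum()))
        loci = loci.loc[~is_y].reset_index(drop=True)
        calls = calls[:, ~is_y.to_numpy()]
    return loci, calls


# ---------------------------------------------------------------------------
# PED/MAP dialect

_CALL_TO_ALLELES = {0: ("A", "A"), 1: ("A", "B"), 2: ("B", "B"), MISSING: ("0", "0")}


def _read_ped_map(ped_path: Path, map_path: Path, assembly: str) -> GenotypeMatrix:
    map_rows = []
    for lineno, line in enumerate(map_path.read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 4:
            raise ParseError(f"{map_path}:{lineno}: expected 4 MAP fields, got {len(fields)}")
        chrom, locus_id, _cm, bp = fields[:4]
        map_rows.append((locus_id, chrom, int(bp)))
    loci = pd.DataFrame(map_rows, columns=["locus_id", "chromosome", "position_bp"])
    loci["assembly"] = assembly
    loci["alt_chromosome"] = ""
    n_loci = len(loci)

    sample_rows, geno_rows = [], []
    for lineno, line in enumerate(ped_path.read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 6 + 2 * n_loci:
            raise ParseError(
                f"{ped_path}:{lineno}: expected {6 + 2 * n_loci} PED fields "
                f"for {n_loci} mapped loci, got {len(fields)}"
            )
        fid, iid, _pat, _mat, sex, _pheno = fields[:6]
        sample_rows.append((iid, fid, int(sex) if sex in ("0", "1", "2") else 0))
        geno_rows.append(fields[6:])
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "line", "sex"])

    calls = np.full((len(samples), n_loci), MISSING, dtype=np.int8)
    for j in range(n_loci):
        a1 = [g[2 * j] for g in geno_rows]
        a2 = [g[2 * j + 1] for g in geno_rows]
        calls[:, j] = _normalise_locus_alleles(a1, a2, loci["locus_id"].iloc[j], missing="0")

    loci, calls = _drop_y(loci, calls)
    return GenotypeMatrix(samples, loci, calls)


def _write_ped_map(gm: GenotypeMatrix, prefix: Path) -> list[Path]:
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    with map_path.open("w") as fh:
        for _, row in gm.loci.iterrows():
            fh.write(f"{row.chromosome}\t{row.locus_id}\t0\t{row.position_bp}\n")
    with ped_path.open("w") as fh:
        for i, srow in gm.samples.iterrows():
            alleles = []
            for call in gm.calls[i]:
                alleles.extend(_CALL_TO_ALLELES[int(call)])
            fh.write(
                f"{srow.line}\t{srow.sample_id}\t0\t0\t{srow.sex}\t-9\t" + "\t".join(alleles) + "\n"
            )
    return [ped_path, map_path]


# ---------------------------------------------------------------------------
# TSV dialect

_CALL_TO_TSV = {0: "AA", 1: "AB", 2: "BB", MISSING: "NN"}


def _read_tsv(geno_path: Path, map_path: Path, assembly: str) -> GenotypeMatrix:
    loci = pd.read_csv(map_path, sep="\t", comment="#", dtype={"chromosome": str})
    for col in ("locus_id", "chromosome", "position_bp"):
        if col not in loci.columns:
            raise ParseError(f"{map_path}: missing column {col!r}")
    loci = loci[["locus_id", "chromosome", "position_bp"]].copy()
    loci["assembly"] = assembly
    loci["alt_chromosome"] = ""

    table = pd.read_csv(geno_path, sep="\t", comment="#", dtype=str)
    for col in ("sample_id", "line", "sex"):
        if col not in table.columns:
            raise ParseError(f"{geno_path}: missing column {col!r}")
    locus_cols = [c for c in table.columns if c not in ("sample_id", "line", "sex")]
    if locus_cols != list(loci["locus_id"]):
        raise ParseError(
            f"{geno_path}: genotype columns do not match the locus map "
            f"({len(locus_cols)} columns vs {len(loci)} mapped loci)"
        )
    samples = table[["sample_id", "line", "sex"]].copy()
    samples["sex"] = samples["sex"].fillna("0").astype(int)

    calls = np.full((len(samples), len(loci)), MISSING, dtype=np.int8)
    for j, col in enumerate(locus_cols):
        vals = table[col].fillna("NN").astype(str)
        bad_len = vals.str.len() != 2
        if bad_len.any():
            raise ParseError(
                f"{geno_path}: locus {col!r} call {vals[bad_len].iloc[0]!r} "
                "is not a two-character string"
            )
        a1 = [v[0] for v in vals]
        a2 = [v[1] for v in vals]
        calls[:, j] = _normalise_locus_alleles(a1, a2, col, missing="N")

    loci, calls = _drop_y(loci, calls)
    return GenotypeMatrix(samples, loci, calls)


def _write_tsv(gm: GenotypeMatrix, prefix: Path) -> list[Path]:
    geno_path = prefix.with_suffix(".tsv")
    map_path = prefix.with_suffix(".map.tsv")
    gm.loci[["locus_id", "chromosome", "position_bp"]].to_csv(map_path, sep="\t", index=False)
    call_strings = np.array([_CALL_TO_TSV[c] for c in (-1, 0, 1, 2)])[gm.calls + 1]
    table = pd.concat(
        [
            gm.samples.reset_index(drop=True),
            pd.DataFrame(call_strings, columns=list(gm.loci["locus_id"])),
        ],
        axis=1,
    )
    table.to_csv(geno_path, sep="\t", index=False)
    return [geno_path, map_path]


# ---------------------------------------------------------------------------
# public entry points


def read_genotypes(
    path: str | Path,
    dialect: str = "ped_map",
    map_path: str | Path | None = None,
    assembly: str = "",
) -> GenotypeMatrix:
    """Read a genotype matrix.

    ``path`` is the PED file (or prefix) for ``ped_map``, the genotype table
    for ``tsv``. ``map_path`` defaults to the sibling ``.map`` /
    ``.map.tsv`` file.
    """
    path = Path(path)
    if dialect == "ped_map":
        ped = path if path.suffix == ".ped" else path.with_suffix(".ped")
        mp = Path(map_path) if map_path else ped.with_suffix(".map")
        _require(ped), _require(mp)
        return _read_ped_map(ped, mp, assembly)
    if dialect == "tsv":
        geno = path if path.suffix == ".tsv" else path.with_suffix(".tsv")
        mp = Path(map_path) if map_path else geno.with_suffix("").with_suffix(".map.tsv")
        _require(geno), _require(mp)
        return _read_tsv(geno, mp, assembly)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_genotypes(gm: GenotypeMatrix, prefix: str | Path, dialect: str = "ped_map") -> list[Path]:
    """Write a genotype matrix; returns the paths written."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "ped_map":
        return _write_ped_map(gm, prefix)
    if dialect == "tsv":
        return _write_tsv(gm, prefix)
    raise ValueError(f"unknown dialect {dialect!r}")


def _require(p: Path) -> None:
    if not p.exists():
        raise FileNotFoundError(p)


def read_pairs(path: str | Path, genotypes: GenotypeMatrix) -> TransplantCohort:
    """Read a donor/recipient/outcome TSV and resolve ids against a matrix.

    Outcome tokens are parsed case-insensitively from {accepted, rejected}.
    An empty table yields an empty (valid) cohort.
    """
    pairs = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("donor_id", "recipient_id", "outcome"):
        if col not in pairs.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    cohort = make_cohort(pairs[["donor_id", "recipient_id", "outcome"]], genotypes)
    return cohort


def write_pairs(cohort: TransplantCohort, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.pairs[["donor_id", "recipient_id", "outcome"]].to_csv(path, sep="\t", index=False)
    return path


def load_significant_snp_table() -> pd.DataFrame:
    """Load the packaged curated significant-SNP table.

    Returns a DataFrame with one row per reported locus and columns
    ``chromosome``, ``position_bp``, ``position_bp_alt`` (second reported
    position, 0 if none), ``model1``/``model2`` (bool significance flags),
    ``direction`` (``rejection``/``acceptance``), ``alt_chromosome``
    (original-assembly chromosome where it differed, else ``""``) and
    ``unknown_location`` (bool, printed position unknown).
    """
    with resources.files("mhagscan.data").joinpath("significant_snps.tsv").open() as fh:
        df = pd.read_csv(
            fh, sep="\t", comment="#", dtype={"chromosome": str, "alt_chromosome": str}
        )
    df["alt_chromosome"] = df["alt_chromosome"].fillna("")
    df["model1"] = df["model1"].astype(bool)
    df["model2"] = df["model2"].astype(bool)
    df["position_bp"] = df["position_bp"].astype(int)
    df["position_bp_alt"] = df["position_bp_alt"].astype(int)
    df["unknown_location"] = df["position_bp"] == 0
    if not (df["model1"] | df["model2"]).all():
        raise ValueError("fixture row without a model flag")
    return df
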