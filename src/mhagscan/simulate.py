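"""Synthetic semi-inbred multi-line genotype cohorts with planted causal loci.

The generator emulates the statistical structure the association scan
assumes: a handful of highly homozygous, MHC-homozygous lines that have each
fixed a large fraction of array SNPs (partly the same allele in every line,
partly line-private fixation), segregating sites in within-line
Hardy-Weinberg proportions with a Beta-distributed minor allele frequency,
local linkage disequilibrium created by drawing genotypes block-wise from a
small per-line haplotype pool, donor-to-recipient graft pairings in a few
line combinations, and rejection driven by donor-recipient mismatches at a
small number of planted causal minor-histocompatibility loci.

Per SNP and line the generative model is:

* with probability ``shared_fixation_prob`` (c) the SNP is fixed for the
  same allele in *every* line;
* otherwise each line is independently fixed for a line-chosen random allele
  with probability ``(f_l - c) / (1 - c)``, so that the *marginal*
  probability that line *l* is fixed equals its configured ``fixation_prob``
  ``f_l`` (this requires ``c <= min f_l``);
* a line-segregating SNP draws its minor allele frequency from
  ``0.5 * Beta(a, b)`` and its genotypes under within-line Hardy-Weinberg
  equilibrium.

With linkage disequilibrium enabled, SNPs are partitioned into blocks and
each line carries a small pool of block haplotypes; every pig draws two pool
haplotypes per block, so neighbouring SNPs co-segregate. Pool haplotypes at
a segregating SNP are conditioned to carry both alleles so that a SNP drawn
as segregating really segregates in the pool.

Graft outcome: a pair mismatched (under the causal locus's model) at one or
more causal loci is rejected with probability ``1 - prod(1 - p_k)`` over the
mismatched causal loci's penetrances ``p_k``; otherwise it is rejected with
the background rate ``epsilon``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    MISSING,
    GenotypeMatrix,
    TransplantCohort,
    make_cohort,
    write_genotypes,
    write_pairs,
)
from .mismatch import MISMATCHED, _TABLES

#: Per-chromosome share of array SNPs, mirroring the proportions of a
#: PorcineSNP60-scale map over 18 autosomes, X and unplaced SNPs.
DEFAULT_CHROM_WEIGHTS = {
    "1": 6792, "2": 3179, "3": 2694, "4": 3645, "5": 2352, "6": 2849,
    "7": 3427, "8": 2554, "9": 3088, "10": 1571, "11": 1860, "12": 1475,
    "13": 3523, "14": 3947, "15": 2774, "16": 1816, "17": 1663, "18": 1284,
    "X": 1420, "0": 7939,
}

#: Mean inter-SNP spacing used to lay positions down a chromosome (bp).
SNP_SPACING_BP = 45_000


class ConfigError(ValueError):
    """A simulation configuration violates an invariant."""


@dataclass
class LineConfig:
    label: str
    n_pigs: int
    fixation_prob: float  # marginal probability a SNP is fixed in this line


@dataclass
class PairingConfig:
    donor_line: str
    recipient_line: str
    n_grafts: int


@dataclass
class CausalLocus:
    locus_index: int  # index into the simulated locus list
    model: str  # mismatch model under which the locus acts
    penetrance: float  # P(rejection | mismatched at this locus)


@dataclass
class LDConfig:
    """Haplotype-block linkage disequilibrium."""

    block_size_mean: float = 10.0  # mean SNPs per haplotype block
    haplotypes_per_block: int = 4  # per-line pool size


@dataclass
class SimulationConfig:
    lines: list[LineConfig] = field(
        default_factory=lambda: [
            LineConfig("SLAbb", 5, 0.86),
            LineConfig("SLAcc", 27, 0.71),
            LineConfig("SLAdd", 11, 0.78),
        ]
    )
    pairings: list[PairingConfig] = field(
        default_factory=lambda: [
            PairingConfig("SLAbb", "SLAcc", 6),
            PairingConfig("SLAdd", "SLAcc", 10),
            PairingConfig("SLAcc", "SLAcc", 5),
        ]
    )
    n_snps: int = 6000
    shared_fixation_prob: float = 0.355
    maf_beta: tuple[float, float] = (3.0, 3.25)  # MAF = 0.5 * Beta(a, b); mean 0.24
    ld: LDConfig | None = field(default_factory=LDConfig)
    causal_loci: list[CausalLocus] = field(default_factory=list)
    background_rejection_rate: float = 0.05
    missing_rate: float = 0.0
    chrom_weights: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROM_WEIGHTS))
    seed: int | None = None

    def validate(self) -> None:
        if not self.lines:
            raise ConfigError("lines: at least one line required")
        labels = {ln.label for ln in self.lines}
        if len(labels) != len(self.lines):
            raise ConfigError("lines: duplicate line labels")
        for ln in self.lines:
            if ln.n_pigs < 1:
                raise ConfigError(f"lines[{ln.label}].n_pigs must be >= 1")
            if not 0.0 <= ln.fixation_prob <= 1.0:
                raise ConfigError(f"lines[{ln.label}].fixation_prob must be in [0, 1]")
        c = self.shared_fixation_prob
        if not 0.0 <= c <= 1.0:
            raise ConfigError("shared_fixation_prob must be in [0, 1]")
        if self.lines and c > min(ln.fixation_prob for ln in self.lines) + 1e-12:
            raise ConfigError(
                "shared_fixation_prob must not exceed the smallest line fixation_prob"
            )
        if self.n_snps < 1:
            raise ConfigError("n_snps must be >= 1")
        a, b = self.maf_beta
        if a <= 0 or b <= 0:
            raise ConfigError("maf_beta shape parameters must be positive")
        if not 0.0 <= self.background_rejection_rate <= 1.0:
            raise ConfigError("background_rejection_rate must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        for pr in self.pairings:
            if pr.donor_line not in labels or pr.recipient_line not in labels:
                raise ConfigError(
                    f"pairings: unknown line in {pr.donor_line}->{pr.recipient_line}"
                )
            if pr.n_grafts < 0:
                raise ConfigError("pairings.n_grafts must be >= 0")
        n_recip_needed: dict[str, int] = {}
        for pr in self.pairings:
            n_recip_needed[pr.recipient_line] = n_recip_needed.get(pr.recipient_line, 0) + pr.n_grafts
        for label, need in n_recip_needed.items():
            have = next(ln.n_pigs for ln in self.lines if ln.label == label)
            if need > have:
                raise ConfigError(
                    f"pairings need {need} distinct recipients from line {label} "
                    f"but it has only {have} pigs"
                )
        for cl in self.causal_loci:
            if not 0 <= cl.locus_index < self.n_snps:
                raise ConfigError(f"causal locus_index {cl.locus_index} out of range")
            if cl.model not in ("model1", "model2"):
                raise ConfigError(f"causal model must be model1/model2, got {cl.model!r}")
            if not 0.0 <= cl.penetrance <= 1.0:
                raise ConfigError("causal penetrance must be in [0, 1]")
        if self.ld is not None:
            if self.ld.block_size_mean < 1:
                raise ConfigError("ld.block_size_mean must be >= 1")
            if self.ld.haplotypes_per_block < 2:
                raise ConfigError("ld.haplotypes_per_block must be >= 2")


# ---------------------------------------------------------------------------
# locus map


def _build_locus_map(config: SimulationConfig, rng) -> pd.DataFrame:
    weights = pd.Series(config.chrom_weights, dtype=float)
    counts = np.floor(weights / weights.sum() * config.n_snps).astype(int)
    # distribute the rounding remainder to the largest chromosomes
    short = config.n_snps - int(counts.sum())
    for c in weights.sort_values(ascending=False).index[:short]:
        counts[c] += 1
    rows = []
    k = 0
    for chrom, n in counts.items():
        if chrom == "0":
            for _ in range(n):
                rows.append((f"snp{k:06d}", "0", 0))
                k += 1
        else:
            gaps = rng.exponential(SNP_SPACING_BP, size=n)
            pos = np.cumsum(gaps).astype(int) + 1
            for p in pos:
                rows.append((f"snp{k:06d}", str(chrom), int(p)))
                k += 1
    loci = pd.DataFrame(rows, columns=["locus_id", "chromosome", "position_bp"])
    loci["assembly"] = "synthetic"
    loci["alt_chromosome"] = ""
    return loci


def _ld_blocks(loci: pd.DataFrame, config: SimulationConfig, rng) -> np.ndarray:
    """Assign each locus to an LD block (consecutive runs within chromosomes)."""
    block_id = np.zeros(len(loci), dtype=int)
    if config.ld is None:
        return np.arange(len(loci))
    bid = 0
    for chrom in loci["chromosome"].unique():
        idx = np.flatnonzero((loci["chromosome"] == chrom).to_numpy())
        i = 0
        while i < idx.size:
            size = int(rng.geometric(1.0 / config.ld.block_size_mean))
            block_id[idx[i : i + size]] = bid
            bid += 1
            i += size
    return block_id


# ---------------------------------------------------------------------------
# genotype generation


def _draw_line_states(config: SimulationConfig, rng, causal_idx):
    """Per SNP x line: fixed allele (0/2) or segregating with a drawn MAF.

    Returns (state, maf) where state is -1 for segregating, else the fixed
    homozygote call code; causal loci are forced to segregate in every line.
    """
    n, L = config.n_snps, len(config.lines)
    a, b = config.maf_beta
    c = config.shared_fixation_prob
    state = np.full((n, L), -1, dtype=np.int8)
    shared = rng.random(n) < c
    shared_allele = rng.choice([0, 2], size=n)
    for li, line in enumerate(config.lines):
        f_resid = 0.0 if c >= 1.0 else (line.fixation_prob - c) / (1.0 - c)
        line_fixed = ~shared & (rng.random(n) < f_resid)
        allele = rng.choice([0, 2], size=n)
        state[shared, li] = shared_allele[shared]
        state[line_fixed, li] = allele[line_fixed]
    state[causal_idx, :] = -1  # causal loci segregate in every line
    maf = 0.5 * rng.beta(a, b, size=(n, L))
    return state, maf


def _genotypes_for_line(state_l, maf_l, n_pigs, block_id, config, rng):
    """Genotype calls for one line (pigs x loci)."""
    n = state_l.size
    calls = np.empty((n_pigs, n), dtype=np.int8)
    fixed = state_l >= 0
    calls[:, fixed] = np.broadcast_to(state_l[fixed], (n_pigs, int(fixed.sum())))
    seg = ~fixed
    if config.ld is None:
        m = maf_l[seg]
        calls[:, seg] = (
            (rng.random((n_pigs, int(seg.sum()))) < m).astype(np.int8)
            + (rng.random((n_pigs, int(seg.sum()))) < m).astype(np.int8)
        )
        return calls
    # haplotype-pool LD: per block, H pool haplotypes; each pig draws 2
    H = config.ld.haplotypes_per_block
    for bid in np.unique(block_id):
        in_block = block_id == bid
        seg_b = np.flatnonzero(in_block & seg)
        if seg_b.size == 0:
            continue
        m = maf_l[seg_b]
        # pool minor-allele counts ~ Binomial(H, m) truncated to 1..H-1 so the
        # pool genuinely segregates
        k = rng.binomial(H, m)
        resample = (k == 0) | (k == H)
        while resample.any():
            k[resample] = rng.binomial(H, m[resample])
            resample = (k == 0) | (k == H)
        pool = np.zeros((H, seg_b.size), dtype=np.int8)
        for j in range(seg_b.size):
            carriers = rng.choice(H, size=k[j], replace=False)
            pool[carriers, j] = 1
        draw1 = rng.integers(0, H, size=n_pigs)
        draw2 = rng.integers(0, H, size=n_pigs)
        calls[:, seg_b] = pool[draw1] + pool[draw2]
    return calls


def simulate_genotypes(config: SimulationConfig, seed=None):
    """Genotype matrix + per-locus LD block ids + per-line locus states."""
    config.validate()
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    causal_idx = np.array([cl.locus_index for cl in config.causal_loci], dtype=int)
    loci = _build_locus_map(config, rng)
    block_id = _ld_blocks(loci, config, rng)
    state, maf = _draw_line_states(config, rng, causal_idx)

    sample_rows, call_blocks = [], []
    for li, line in enumerate(config.lines):
        calls = _genotypes_for_line(state[:, li], maf[:, li], line.n_pigs, block_id, config, rng)
        for i in range(line.n_pigs):
            sample_rows.append((f"{line.label}_{i + 1:02d}", line.label, int(rng.integers(1, 3))))
        call_blocks.append(calls)
    calls = np.vstack(call_blocks)
    if config.missing_rate > 0:
        calls[rng.random(calls.shape) < config.missing_rate] = MISSING
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "line", "sex"])
    gm = GenotypeMatrix(samples, loci, calls)
    return gm, block_id, state, rng


def simulate_cohort(config: SimulationConfig, seed=None):
    """Simulate genotypes, graft pairings and outcomes.

    Returns ``(genotypes, cohort, truth)`` where ``truth`` records the causal
    loci (with their LD block ids), each locus's block id and each pair's
    causal mismatch status.
    """
    gm, block_id, state, rng = simulate_genotypes(config, seed)

    # pairings: recipients distinct across the whole design; donors reused
    # only when a pairing asks for more grafts than the line has pigs (one
    # animal can donate both corneas)
    used_recipients: set[str] = set()
    pair_rows = []
    for pr in config.pairings:
        donors_avail = list(gm.samples.loc[gm.samples["line"] == pr.donor_line, "sample_id"])
        recip_avail = [
            s
            for s in gm.samples.loc[gm.samples["line"] == pr.recipient_line, "sample_id"]
            if s not in used_recipients
        ]
        recipients = list(rng.choice(recip_avail, size=pr.n_grafts, replace=False))
        used_recipients.update(recipients)
        donors = []
        pool: list[str] = []
        for r in recipients:
            if not pool:
                pool = [d for d in donors_avail]
                rng.shuffle(pool)
            # avoid self-grafts in intra-line pairings
            choice = next((d for d in pool if d != r), pool[0])
            pool.remove(choice)
            donors.append(choice)
        pair_rows += [(d, r) for d, r in zip(donors, recipients)]

    # outcomes from causal mismatches
    donor_idx = np.array([gm.sample_index(d) for d, _ in pair_rows], dtype=int)
    recip_idx = np.array([gm.sample_index(r) for _, r in pair_rows], dtype=int)
    p_keep = np.ones(len(pair_rows))
    causal_mismatch = np.zeros(len(pair_rows), dtype=bool)
    for cl in config.causal_loci:
        dcall = gm.calls[donor_idx, cl.locus_index]
        rcall = gm.calls[recip_idx, cl.locus_index]
        mm = _TABLES[cl.model][dcall + 1, rcall + 1] == MISMATCHED
        causal_mismatch |= mm
        p_keep[mm] *= 1.0 - cl.penetrance
    p_reject = np.where(causal_mismatch, 1.0 - p_keep, config.background_rejection_rate)
    rejected = rng.random(len(pair_rows)) < p_reject

    pairs = pd.DataFrame(pair_rows, columns=["donor_id", "recipient_id"])
    pairs["outcome"] = np.where(rejected, "rejected", "accepted")
    cohort = make_cohort(pairs, gm)

    truth = {
        "causal_loci": [
            {
                "locus_id": str(gm.loci["locus_id"].iloc[cl.locus_index]),
                "locus_index": cl.locus_index,
                "chromosome": str(gm.loci["chromosome"].iloc[cl.locus_index]),
                "position_bp": int(gm.loci["position_bp"].iloc[cl.locus_index]),
                "model": cl.model,
                "penetrance": cl.penetrance,
                "ld_block": int(block_id[cl.locus_index]),
            }
            for cl in config.causal_loci
        ],
        "ld_block_id": block_id.tolist(),
        "pair_causal_mismatch": causal_mismatch.tolist(),
        "background_rejection_rate": config.background_rejection_rate,
        "n_rejected": int(rejected.sum()),
    }
    return gm, cohort, truth


def write_cohort(gm, cohort, truth, directory, dialect: str = "ped_map", prefix: str = "cohort"):
    """Write genotypes, pair table and truth record; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = write_genotypes(gm, directory / prefix, dialect=dialect)
    paths.append(write_pairs(cohort, directory / f"{prefix}.pairs.tsv"))
    truth_path = directory / f"{prefix}.truth.json"
    truth_path.write_text(json.dumps(truth, indent=2) + "\n")
    paths.append(truth_path)
    return paths


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a validated SimulationConfig from a plain mapping (YAML-friendly)."""
    kwargs = dict(d)
    if "lines" in kwargs:
        kwargs["lines"] = [LineConfig(**x) for x in kwargs["lines"]]
    if "pairings" in kwargs:
        kwargs["pairings"] = [PairingConfig(**x) for x in kwargs["pairings"]]
    if "causal_loci" in kwargs:
        kwargs["causal_loci"] = [CausalLocus(**x) for x in kwargs["causal_loci"]]
    if "ld" in kwargs:
        kwargs["ld"] = LDConfig(**kwargs["ld"]) if kwargs["ld"] is not None else None
    if "maf_beta" in kwargs:
        kwargs["maf_beta"] = tuple(kwargs["maf_beta"])
    try:
        config = SimulationConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(str(exc)) from None
    config.validate()
    return config


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
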