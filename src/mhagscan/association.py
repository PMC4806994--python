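"""Per-locus likelihood-ratio association test with a permutation threshold.

At each testable locus the donor-recipient pairs with known match status form
a 2x2 contingency table of outcome (accepted/rejected) against status
(matched/mismatched). The test statistic is the G statistic (log-likelihood
ratio test of independence),

    G = 2 * sum_ij O_ij * ln(O_ij / E_ij),    E_ij = row_i * col_j / N,

asymptotically chi-squared with one degree of freedom under the null. Terms
with ``O_ij = 0`` contribute zero, and a table with a zero row or column
marginal has ``G = 0`` by convention (independence is saturated there).

Genome-wide significance uses the maxT permutation scheme: outcome labels
are shuffled jointly across pairs with the match matrix held fixed, the
maximum statistic over testable loci is recorded per permutation, and the
family-wise threshold is the empirical (1 - alpha) quantile of those maxima
(order statistic at ``ceil((1 - alpha) * n)``). When the number of distinct
outcome assignments C(N, n_rejected) does not exceed the requested number of
permutations, all assignments are enumerated exactly instead of sampled.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy

from .io import CHROM_ORDER, GenotypeMatrix, TransplantCohort
from .mismatch import MATCHED, MISMATCHED, UNKNOWN, MatchMatrix

REJECTION, ACCEPTANCE, NONE = "rejection", "acceptance", "none"


# ---------------------------------------------------------------------------
# single-table primitives


def _as_table(table) -> np.ndarray:
    o = np.asarray(table, dtype=float)
    if o.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {o.shape}")
    if (o < 0).any():
        raise ValueError("negative counts in contingency table")
    return o


def lrt_statistic(table) -> float:
    """G statistic of a 2x2 table (rows: accepted/rejected; cols: matched/mismatched)."""
    o = _as_table(table)
    n = o.sum()
    if n == 0:
        raise ValueError("empty contingency table")
    row = o.sum(axis=1)
    col = o.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        return 0.0
    e = np.outer(row, col) / n
    return float(2.0 * xlogy(o, o / e).sum())


def direction(table) -> str:
    """Direction of association: which way the mismatched-rejected cell deviates.

    ``rejection`` when the observed mismatched-rejected count exceeds its
    expectation under independence, ``acceptance`` when it falls short,
    ``none`` when equal (includes every zero-marginal table).
    """
    o = _as_table(table)
    n = o.sum()
    row = o.sum(axis=1)
    col = o.sum(axis=0)
    if n == 0 or (row == 0).any() or (col == 0).any():
        return NONE
    e_rej_mm = row[1] * col[1] / n
    if o[1, 1] > e_rej_mm:
        return REJECTION
    if o[1, 1] < e_rej_mm:
        return ACCEPTANCE
    return NONE


# ---------------------------------------------------------------------------
# vectorised scan machinery


def _margins(match: MatchMatrix):
    """Per-locus fixed margins: mismatched counts and known counts."""
    mm = (match.status == MISMATCHED).astype(float)
    known = (match.status != UNKNOWN).astype(float)
    return mm, known


def _g_vec(r_mm, r_k, n_mm, n_k):
    """Vectorised G over loci for rejected-mismatched / rejected-known counts.

    ``n_mm``/``n_k`` are per-locus totals of mismatched and known pairs;
    ``r_*`` may be (loci,) or (perms, loci). Zero marginals yield 0.
    """
    a_k = n_k - r_k
    o = np.stack(
        [a_k - (n_mm - r_mm), n_mm - r_mm, r_k - r_mm, r_mm]
    )  # acc-matched, acc-mismatched, rej-matched, rej-mismatched
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.stack(
            [
                a_k * (n_k - n_mm) / n_k,
                a_k * n_mm / n_k,
                r_k * (n_k - n_mm) / n_k,
                r_k * n_mm / n_k,
            ]
        )
        g = 2.0 * xlogy(o, np.where(e > 0, o / np.where(e > 0, e, 1.0), 1.0)).sum(axis=0)
    # zero row/column marginal -> statistic defined as 0
    degenerate = (r_k == 0) | (a_k == 0) | (n_mm == 0) | (n_mm == n_k)
    return np.where(degenerate, 0.0, g)


def scan(match: MatchMatrix, cohort: TransplantCohort | None = None) -> pd.DataFrame:
    """Per-locus association results for one rejection model.

    Returns a DataFrame with one row per locus (untestable loci carried with
    ``lrt`` 0 and ``testable`` False) holding the statistic, its direction,
    the pointwise chi-squared(1) upper-tail probability and the counts of the
    underlying contingency table.
    """
    cohort = cohort if cohort is not None else match.cohort
    y = cohort.rejected.astype(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("cohort must contain both accepted and rejected outcomes")
    mm, known = _margins(match)
    n_mm = mm.sum(axis=0)
    n_k = known.sum(axis=0)
    r_mm = y @ mm
    r_k = y @ known
    g = _g_vec(r_mm, r_k, n_mm, n_k)
    g = np.where(match.testable, g, 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        e_rej_mm = r_k * n_mm / np.where(n_k > 0, n_k, 1.0)
    direc = np.where(
        (g > 0) & (r_mm > e_rej_mm),
        REJECTION,
        np.where((g > 0) & (r_mm < e_rej_mm), ACCEPTANCE, NONE),
    )
    loci = match.genotypes.loci
    return pd.DataFrame(
        {
            "locus_id": loci["locus_id"].to_numpy(),
            "chromosome": loci["chromosome"].astype(str).to_numpy(),
            "position_bp": loci["position_bp"].to_numpy(),
            "model": match.model,
            "lrt": g,
            "direction": direc,
            "testable": match.testable,
            "pointwise_p": stats.chi2.sf(g, df=1),
            "n_known": n_k.astype(int),
            "n_mismatched": n_mm.astype(int),
            "n_rejected_known": r_k.astype(int),
            "n_rejected_mismatched": r_mm.astype(int),
        }
    )


@dataclass
class PermutationResult:
    """Genome-wide maxT permutation null summary for one model."""

    model: str
    n_perm: int
    alpha: float
    threshold: float
    max_lrt_draws: np.ndarray
    seed: int | None
    exact: bool = False

    def quantile(self, alpha: float) -> float:
        """Empirical (1 - alpha) quantile of the recorded maxima."""
        draws = np.sort(self.max_lrt_draws)
        k = int(np.ceil((1.0 - alpha) * draws.size))
        return float(draws[max(k - 1, 0)])


def permutation_threshold(
    match: MatchMatrix,
    cohort: TransplantCohort | None = None,
    n_perm: int = 100_000,
    alpha: float = 0.05,
    seed: int | None = None,
    batch: int = 512,
) -> PermutationResult:
    """maxT permutation genome-wide threshold at level ``alpha``.

    Shuffles outcome labels across pairs (match matrix fixed), recording the
    maximum statistic over testable loci per permutation; switches to exact
    enumeration of all C(N, n_rejected) outcome assignments whenever that
    count does not exceed ``n_perm``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    cohort = cohort if cohort is not None else match.cohort
    y = cohort.rejected
    n, r = y.size, int(y.sum())

    mm, known = _margins(match)
    mm = mm[:, match.testable]
    known = known[:, match.testable]
    if mm.shape[1] == 0:
        return PermutationResult(match.model, 0, alpha, 0.0, np.zeros(1), seed, exact=True)
    n_mm = mm.sum(axis=0)
    n_k = known.sum(axis=0)

    n_distinct = comb(n, r)
    exact = n_distinct <= n_perm
    if exact:
        perms = np.zeros((n_distinct, n))
        for i, idx in enumerate(itertools.combinations(range(n), r)):
            perms[i, list(idx)] = 1.0
        maxima = _max_over_loci(perms, mm, known, n_mm, n_k, batch)
    else:
        rng = np.random.default_rng(seed)
        maxima = np.empty(n_perm)
        base = y.astype(float)
        done = 0
        while done < n_perm:
            b = min(batch, n_perm - done)
            perms = np.stack([rng.permutation(base) for _ in range(b)])
            maxima[done : done + b] = _max_over_loci(perms, mm, known, n_mm, n_k, batch)
            done += b
    draws = np.sort(maxima)
    k = int(np.ceil((1.0 - alpha) * draws.size))
    threshold = float(draws[max(k - 1, 0)])
    return PermutationResult(match.model, draws.size, alpha, threshold, draws, seed, exact)


def _max_over_loci(perms, mm, known, n_mm, n_k, batch):
    out = np.empty(perms.shape[0])
    for s in range(0, perms.shape[0], batch):
        p = perms[s : s + batch]
        g = _g_vec(p @ mm, p @ known, n_mm, n_k)
        out[s : s + batch] = g.max(axis=1)
    return out


def call_significant(results: pd.DataFrame, perm: PermutationResult) -> pd.DataFrame:
    """Flag loci whose statistic strictly exceeds the genome-wide threshold."""
    if (results["model"] != perm.model).any():
        raise ValueError("results and permutation threshold are for different models")
    out = results.copy()
    out["genomewide_significant"] = (out["lrt"] > perm.threshold) & out["testable"]
    out["threshold"] = perm.threshold
    return out


# ---------------------------------------------------------------------------
# Manhattan export


def manhattan_table(results: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready ordering: chromosomes 1..18, X, unknown last; within a
    chromosome positioned loci ascending, unknown-position loci appended."""
    df = results.copy()
    df = df[df["chromosome"].astype(str).str.upper() != "Y"]
    df["_chrom_rank"] = df["chromosome"].astype(str).map(CHROM_ORDER)
    df["_unpos"] = (df["position_bp"] == 0).astype(int)
    df = df.sort_values(["_chrom_rank", "_unpos", "position_bp"], kind="stable")
    return df.drop(columns=["_chrom_rank", "_unpos"]).reset_index(drop=True)


def manhattan_plot(results: pd.DataFrame, threshold: float | None = None, path=None, ax=None):
    """Genome-wide statistic plot with alternating chromosome colours.

    Rejection-direction loci alternate red/green by chromosome; acceptance-
    direction loci are blue; a horizontal line marks the permutation
    threshold.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = manhattan_table(results)
    table["_x"] = np.arange(len(table))
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3.5))
    for k, (chrom, grp) in enumerate(table.groupby("chromosome", sort=False)):
        rej = grp[grp["direction"] != ACCEPTANCE]
        ax.scatter(rej["_x"], rej["lrt"], s=4, color=("#b2182b" if k % 2 == 0 else "#1a9850"))
        acc = grp[grp["direction"] == ACCEPTANCE]
        ax.scatter(acc["_x"], acc["lrt"], s=6, color="#2166ac")
    if threshold is not None:
        ax.axhline(threshold, color="black", lw=0.8)
    ax.set_xlabel("loci (genome order)")
    ax.set_ylabel("LRT")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
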