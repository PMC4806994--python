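"""Donor-recipient genotype match/mismatch coding.

Two rejection models define what counts as a mismatch at a biallelic locus:

* **Model 1** (directional, host-versus-graft T-cell epitope logic): the pair
  is mismatched iff the donor (graft) carries at least one allele the
  recipient lacks. An AB graft into an AA or BB recipient is mismatched; an
  AA or BB graft into an AB recipient is matched — graft-versus-host
  reactions are irrelevant in this model.
* **Model 2** (symmetric): mismatched iff the unordered genotypes differ.

Every Model-1 mismatch is also a Model-2 mismatch. A missing call on either
side makes the pair status unknown at that locus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MISSING, GenotypeMatrix, TransplantCohort

MATCHED, MISMATCHED, UNKNOWN = 0, 1, -1

MODELS = ("model1", "model2")

_ALLELE_SETS = {0: {"A"}, 1: {"A", "B"}, 2: {"B"}}


def _build_tables():
    """4x4 status lookup tables indexed by (donor_call + 1, recipient_call + 1)."""
    m1 = np.full((4, 4), UNKNOWN, dtype=np.int8)
    m2 = np.full((4, 4), UNKNOWN, dtype=np.int8)
    for d in (0, 1, 2):
        for r in (0, 1, 2):
            m1[d + 1, r + 1] = MISMATCHED if not _ALLELE_SETS[d] <= _ALLELE_SETS[r] else MATCHED
            m2[d + 1, r + 1] = MISMATCHED if d != r else MATCHED
    return {"model1": m1, "model2": m2}


_TABLES = _build_tables()


def code_pair(donor: int, recipient: int, model: str) -> int:
    """Status of one donor/recipient call pair: MATCHED, MISMATCHED or UNKNOWN."""
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    return int(_TABLES[model][int(donor) + 1, int(recipient) + 1])


@dataclass
class MatchMatrix:
    """Per-pair per-locus match status under one rejection model.

    ``status`` is an ``int8`` grid of shape (n_pairs, n_loci) over
    {MATCHED, MISMATCHED, UNKNOWN}; ``testable`` flags loci at which both
    matched and mismatched statuses occur among known-status pairs (the
    likelihood-ratio statistic is identically zero elsewhere).
    """

    model: str
    status: np.ndarray
    testable: np.ndarray
    genotypes: GenotypeMatrix
    cohort: TransplantCohort

    @property
    def n_testable(self) -> int:
        return int(self.testable.sum())


def build_match_matrix(
    genotypes: GenotypeMatrix, cohort: TransplantCohort, model: str
) -> MatchMatrix:
    """Code every pair at every locus and flag testable loci."""
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    if cohort.n_pairs == 0:
        raise ValueError("cohort is empty")
    donor = genotypes.calls[cohort.donor_idx]
    recip = genotypes.calls[cohort.recipient_idx]
    status = _TABLES[model][donor + 1, recip + 1]
    known = status != UNKNOWN
    testable = ((status == MATCHED) & known).any(axis=0) & (status == MISMATCHED).any(axis=0)
    return MatchMatrix(model, status, testable, genotypes, cohort)


def write_match_matrix(match: MatchMatrix, path) -> None:
    """Audit export: pairs x loci status codes (M = matched, X = mismatched, ? = unknown)."""
    import pandas as pd
    from pathlib import Path

    sym = np.array(["?", "M", "X"])  # index status + 1
    grid = sym[match.status + 1]
    df = pd.DataFrame(grid, columns=match.genotypes.loci["locus_id"])
    df.insert(0, "donor_id", match.cohort.pairs["donor_id"].to_numpy())
    df.insert(1, "recipient_id", match.cohort.pairs["recipient_id"].to_numpy())
    df.insert(2, "outcome", match.cohort.pairs["outcome"].to_numpy())
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
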