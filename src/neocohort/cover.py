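"""Cohort peptide-bulk selection by greedy set cover.

The design question: what is the smallest set of candidate peptides such that
every patient carries at least one of them?  Patients x peptides incidence is
held in a :class:`CoverageMatrix`; selection is classic greedy set cover
(repeatedly pick the peptide covering the most still-uncovered patients),
which carries the H(d) approximation guarantee, d being the largest number of
patients any single peptide covers.  A self-contained branch-and-bound exact
solver serves as the optimum oracle on small instances, and per-peptide
Shannon entropy / pairwise mutual information are provided as redundancy
diagnostics for the candidate columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CoverageMatrix",
    "BulkSelection",
    "build_matrix",
    "greedy_cover",
    "exact_min_cover",
    "peptide_entropy",
    "pair_mutual_information",
    "harmonic",
]


@dataclass(frozen=True)
class CoverageMatrix:
    """Boolean incidence of patients (rows) x candidate peptides (columns).

    Construction drops all-false columns and collapses duplicate sequences to
    one column, so every column covers >=1 patient.
    """

    patients: tuple[str, ...]
    peptides: tuple[str, ...]
    incidence: np.ndarray  # bool, shape (n_patients, n_peptides)

    def __post_init__(self) -> None:
        n, m = self.incidence.shape
        if n != len(self.patients) or m != len(self.peptides):
            raise ValueError("incidence shape does not match labels")
        if m and not self.incidence.any(axis=0).all():
            raise ValueError("all-false peptide column present")

    def column(self, peptide: str) -> np.ndarray:
        return self.incidence[:, self.peptides.index(peptide)]


@dataclass(frozen=True)
class BulkSelection:
    selected: tuple[str, ...]  # greedy pick order
    covered: frozenset[str]
    uncovered: frozenset[str]
    per_step_gain: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.selected)


def build_matrix(
    per_patient: Mapping[str, Sequence[str]], identity_mode: str = "neoantigen25-sequence"
) -> CoverageMatrix:
    """Build the incidence matrix from per-patient candidate sequence lists.

    ``identity_mode`` names what the sequences are (25-AA neoantigens or
    constituent 8–11-mers); the construction is identical — sharing is exact
    sequence equality — and the mode is recorded only by the caller's choice
    of input lists.
    """
    if identity_mode not in {"neoantigen25-sequence", "constituent-peptide-sequence"}:
        raise ValueError(f"unknown identity mode {identity_mode!r}")
    patients = tuple(sorted(per_patient))
    peptide_set = sorted({s for seqs in per_patient.values() for s in seqs})
    incidence = np.zeros((len(patients), len(peptide_set)), dtype=bool)
    col = {s: j for j, s in enumerate(peptide_set)}
    for i, p in enumerate(patients):
        for s in set(per_patient[p]):
            incidence[i, col[s]] = True
    return CoverageMatrix(patients=patients, peptides=tuple(peptide_set), incidence=incidence)


def greedy_cover(matrix: CoverageMatrix) -> BulkSelection:
    """Greedy set cover over the incidence matrix.

    Ties on marginal gain are broken by higher total prevalence, then by
    lexicographically smaller peptide sequence; fully deterministic.
    Patients with no candidate at all are reported as uncovered.
    """
    inc = matrix.incidence
    n, m = inc.shape
    coverable = inc.any(axis=1)
    uncovered = coverable.copy()
    totals = inc.sum(axis=0)
    selected: list[str] = []
    gains: list[int] = []
    chosen = np.zeros(m, dtype=bool)
    while uncovered.any():
        gain = inc[uncovered].sum(axis=0)
        gain[chosen] = -1
        best_gain = gain.max()
        if best_gain <= 0:
            break
        candidates = np.flatnonzero(gain == best_gain)
        # tie-break: max prevalence, then lexicographically smallest sequence
        best = min(candidates, key=lambda j: (-totals[j], matrix.peptides[j]))
        chosen[best] = True
        selected.append(matrix.peptides[best])
        gains.append(int(best_gain))
        uncovered &= ~inc[:, best]
    return BulkSelection(
        selected=tuple(selected),
        covered=frozenset(p for p, c in zip(matrix.patients, coverable) if c),
        uncovered=frozenset(p for p, c in zip(matrix.patients, coverable) if not c),
        per_step_gain=tuple(gains),
    )


def exact_min_cover(
    matrix: CoverageMatrix, max_cols: int = 20, max_patients: int = 16
) -> tuple[int, tuple[str, ...]]:
    """Exact minimum cover size plus one witness, by branch and bound.

    Refuses instances with more than ``max_cols`` columns *and* more than
    ``max_patients`` coverable patients — beyond that the search space is not
    guaranteed tractable and silent fallback would defeat its role as an
    oracle.  Only coverable patients are covered (rows without candidates are
    ignored, matching ``greedy_cover``).
    """
    inc = matrix.incidence
    n, m = inc.shape
    coverable_rows = np.flatnonzero(inc.any(axis=1))
    if m > max_cols and len(coverable_rows) > max_patients:
        raise ValueError(
            f"instance too large for exact solver: {m} columns x {len(coverable_rows)} "
            f"coverable patients (limits: {max_cols} cols or {max_patients} patients)"
        )
    if m == 0 or len(coverable_rows) == 0:
        return 0, ()
    row_index = {r: i for i, r in enumerate(coverable_rows)}
    full = (1 << len(coverable_rows)) - 1
    col_masks = []
    for j in range(m):
        mask = 0
        for r in np.flatnonzero(inc[:, j]):
            mask |= 1 << row_index[r]
        col_masks.append(mask)

    greedy = greedy_cover(matrix)
    best_size = greedy.size
    best_witness = list(greedy.selected)
    peptide_of = list(matrix.peptides)
    cover_options = [
        [j for j in range(m) if col_masks[j] >> i & 1] for i in range(len(coverable_rows))
    ]
    max_cover = max(bin(c).count("1") for c in col_masks)

    def search(covered: int, chosen: list[int]) -> None:
        nonlocal best_size, best_witness
        if covered == full:
            if len(chosen) < best_size:
                best_size = len(chosen)
                best_witness = [peptide_of[j] for j in chosen]
            return
        remaining = bin(full & ~covered).count("1")
        if len(chosen) + math.ceil(remaining / max_cover) >= best_size:
            return  # bound: cannot beat the incumbent
        # branch on the uncovered patient with the fewest covering columns
        pivot = min(
            (i for i in range(len(coverable_rows)) if not covered >> i & 1),
            key=lambda i: len(cover_options[i]),
        )
        for j in sorted(cover_options[pivot], key=lambda j: -bin(col_masks[j] & ~covered).count("1")):
            chosen.append(j)
            search(covered | col_masks[j], chosen)
            chosen.pop()

    search(0, [])
    # verify the witness actually covers
    mask = 0
    for pep in best_witness:
        mask |= col_masks[peptide_of.index(pep)]
    assert mask == full, "exact solver produced a non-cover witness"
    return best_size, tuple(best_witness)


def _h2(q: float) -> float:
    if q <= 0.0 or q >= 1.0:
        return 0.0
    return -q * math.log2(q) - (1 - q) * math.log2(1 - q)


def peptide_entropy(matrix: CoverageMatrix) -> dict[str, float]:
    """Shannon entropy (bits) of each peptide's carrier indicator."""
    n = len(matrix.patients)
    if n == 0:
        raise ValueError("need at least one patient")
    q = matrix.incidence.mean(axis=0)
    return {pep: _h2(float(qi)) for pep, qi in zip(matrix.peptides, q)}


def pair_mutual_information(matrix: CoverageMatrix, i: str, j: str) -> float:
    """Mutual information (bits) between two peptides' carrier indicators.

    Computed from the empirical 2x2 joint table with the 0 log 0 = 0
    convention.
    """
    a = matrix.column(i).astype(int)
    b = matrix.column(j).astype(int)
    n = len(a)
    if n == 0:
        raise ValueError("need at least one patient")
    mi = 0.0
    for x in (0, 1):
        px = np.mean(a == x)
        for y in (0, 1):
            pxy = float(np.mean((a == x) & (b == y)))
            py = float(np.mean(b == y))
            if pxy > 0:
                mi += pxy * math.log2(pxy / (px * py))
    return max(0.0, mi)


def harmonic(d: int) -> float:
    """H(d) = sum_{i=1..d} 1/i, the greedy set-cover approximation factor."""
    return sum(1.0 / i for i in range(1, d + 1))
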