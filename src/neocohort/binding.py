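"""Peptide–MHC binding scorers.

The design pipeline only needs ``score(peptide, allele) -> float`` where
higher means stronger predicted binding and 0 means non-binder.  Two
implementations are provided:

* :class:`SurrogateBindingModel` — a deterministic pseudo-random scorer used
  for simulation and testing.  It hashes ``(peptide, allele, seed)`` to a
  uniform variate, classifies a configurable fraction of peptides as binders
  and maps those to a score in ``score_range``; non-binders score 0.
* :class:`NetMHCpanTableScorer` — an adapter over a precomputed NetMHCpan-style
  result table (columns peptide / allele / %rank).  The percentile rank ``r``
  is mapped to ``max(0, 1 - r/R)`` with ``R`` the binder rank cutoff
  (default 2.0), so weaker-than-cutoff peptides contribute 0.

Both are pure functions of their inputs: identical calls give identical
scores across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import pandas as pd

from ._rng import stable_unit

__all__ = ["BindingScorer", "SurrogateBindingModel", "NetMHCpanTableScorer"]


@runtime_checkable
class BindingScorer(Protocol):
    def score(self, peptide: str, allele: str) -> float:
        """Nonnegative binding score; higher = stronger, 0 = non-binder."""
        ...


@dataclass(frozen=True)
class SurrogateBindingModel:
    """Deterministic hash-based stand-in for an external binding predictor.

    Parameters
    ----------
    seed
        Included in the hash; different seeds give independent score
        landscapes.
    binder_fraction
        Expected fraction of random (peptide, allele) pairs classified as
        binders, in (0, 1).
    score_range
        ``(low, high)`` range the binder scores are mapped onto; non-binders
        always score 0.
    """

    seed: int = 0
    binder_fraction: float = 0.008
    score_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.binder_fraction < 1.0:
            raise ValueError(f"binder_fraction must be in (0,1), got {self.binder_fraction}")
        low, high = self.score_range
        if not high > low >= 0.0:
            raise ValueError(f"score_range must satisfy 0 <= low < high, got {self.score_range}")

    def _unit(self, peptide: str, allele: str) -> float:
        return stable_unit("binding", self.seed, str(allele), peptide)

    def is_binder(self, peptide: str, allele: str) -> bool:
        return self._unit(peptide, allele) < self.binder_fraction

    def score(self, peptide: str, allele: str) -> float:
        u = self._unit(peptide, allele)
        if u >= self.binder_fraction:
            return 0.0
        low, high = self.score_range
        # u/binder_fraction is Uniform(0,1) conditional on binding; invert so
        # the smallest hash values give the strongest binders.
        return low + (high - low) * (1.0 - u / self.binder_fraction)


class NetMHCpanTableScorer:
    """Score lookup over a precomputed %rank table.

    The table is tab-separated with columns ``peptide``, ``allele`` and
    ``rank`` (NetMHCpan percentile rank; lower = stronger).  A missing
    (peptide, allele) pair raises ``KeyError`` — the pipeline never treats a
    lookup failure as a silent non-binder.
    """

    def __init__(self, table: pd.DataFrame, rank_cutoff: float = 2.0):
        required = {"peptide", "allele", "rank"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"rank table missing columns: {sorted(missing)}")
        if rank_cutoff <= 0:
            raise ValueError("rank_cutoff must be positive")
        self.rank_cutoff = float(rank_cutoff)
        self._ranks: dict[tuple[str, str], float] = {
            (str(p), str(a)): float(r)
            for p, a, r in zip(table["peptide"], table["allele"], table["rank"])
        }

    @classmethod
    def from_tsv(cls, path, rank_cutoff: float = 2.0) -> "NetMHCpanTableScorer":
        return cls(pd.read_csv(path, sep="\t"), rank_cutoff=rank_cutoff)

    def score(self, peptide: str, allele: str) -> float:
        try:
            rank = self._ranks[(peptide, str(allele))]
        except KeyError:
            raise KeyError(f"no predicted rank for peptide {peptide!r} / allele {allele!r}")
        return max(0.0, 1.0 - rank / self.rank_cutoff)
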