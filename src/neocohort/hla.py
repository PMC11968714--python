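"""HLA class-I genotypes, cohort allele frequencies and expression weights.

Each patient carries six class-I allele slots (two per locus A/B/C, identical
slots when homozygous).  Allele names are normalized to two-field resolution
("A*30:01:01" -> "A*30:01").  Per-allele expression measurements (reads or
TPM — the normalization is metric-agnostic) are converted to weights summing
to 1 across the six slots; those weights enter the neoantigen score as the
relative presentation capacity of each allele.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "HLAAllele",
    "HLAGenotype",
    "parse_allele",
    "parse_genotype",
    "allele_frequencies",
    "expression_proportions",
    "genotype_weights_from_measurements",
    "genotype_key",
    "read_genotypes",
    "write_genotypes",
    "read_expression",
]

LOCI = ("A", "B", "C")

_ALLELE_RE = re.compile(r"^(?:HLA-)?([ABC])\*?(\d{1,3}):(\d{1,3})(?::\d+)*[A-Z]?$")


@dataclass(frozen=True, order=True)
class HLAAllele:
    locus: str
    name: str  # two-field, e.g. "A*30:01"

    def __str__(self) -> str:
        return self.name


def parse_allele(token: str) -> HLAAllele:
    """Normalize an allele token to two-field resolution.

    Accepts "A*30:01", "HLA-A*30:01:01", "A30:01" etc.; higher-field suffixes
    are truncated.
    """
    m = _ALLELE_RE.match(token.strip())
    if not m:
        raise ValueError(f"malformed HLA allele token: {token!r}")
    locus, f1, f2 = m.group(1), int(m.group(2)), int(m.group(3))
    return HLAAllele(locus=locus, name=f"{locus}*{f1:02d}:{f2:02d}")


@dataclass(frozen=True)
class HLAGenotype:
    """Six class-I allele slots ordered (A1, A2, B1, B2, C1, C2)."""

    patient: str
    alleles: tuple[HLAAllele, ...]
    expression_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.alleles) != 6:
            raise ValueError(f"{self.patient}: expected 6 allele slots, got {len(self.alleles)}")
        for locus, pair in zip(LOCI, (self.alleles[0:2], self.alleles[2:4], self.alleles[4:6])):
            for a in pair:
                if a.locus != locus:
                    raise ValueError(
                        f"{self.patient}: allele {a.name} in locus-{locus} slot"
                    )
        if self.expression_weights is not None:
            if len(self.expression_weights) != 6:
                raise ValueError(f"{self.patient}: expected 6 expression weights")
            if any(w < 0 for w in self.expression_weights):
                raise ValueError(f"{self.patient}: negative expression weight")
            total = sum(self.expression_weights)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{self.patient}: expression weights sum to {total}, not 1")

    def weights(self) -> tuple[float, ...]:
        """Expression weights, defaulting to uniform 1/6 when unmeasured."""
        if self.expression_weights is not None:
            return self.expression_weights
        return (1.0 / 6,) * 6

    def with_weights(self, weights: Sequence[float]) -> "HLAGenotype":
        return HLAGenotype(self.patient, self.alleles, tuple(float(w) for w in weights))


def parse_genotype(patient: str, tokens: Iterable[str]) -> HLAGenotype:
    """Build a genotype from six allele tokens (any order within the record).

    Homozygous loci are represented by repeating the same token.  Errors name
    the offending token or the missing/overfull locus.
    """
    parsed = [parse_allele(t) for t in tokens]
    by_locus: dict[str, list[HLAAllele]] = {locus: [] for locus in LOCI}
    for a in parsed:
        by_locus[a.locus].append(a)
    for locus in LOCI:
        n = len(by_locus[locus])
        if n != 2:
            raise ValueError(
                f"{patient}: locus {locus} has {n} allele(s), expected 2 "
                f"(got {[a.name for a in by_locus[locus]]})"
            )
    ordered = tuple(a for locus in LOCI for a in sorted(by_locus[locus]))
    return HLAGenotype(patient=patient, alleles=ordered)


def genotype_key(genotype: HLAGenotype) -> tuple[str, ...]:
    """Canonical key for 'same genotype': sorted multiset of the six names."""
    return tuple(sorted(a.name for a in genotype.alleles))


def allele_frequencies(genotypes: Sequence[HLAGenotype]) -> pd.DataFrame:
    """Cohort allele frequencies per locus.

    freq(allele) = number of carrying slots / (2 x n patients); sums to 1
    within each locus.  Returns columns locus / allele / count / frequency.
    """
    if not genotypes:
        raise ValueError("need at least one genotype")
    counts: dict[tuple[str, str], int] = {}
    for g in genotypes:
        for a in g.alleles:
            counts[(a.locus, a.name)] = counts.get((a.locus, a.name), 0) + 1
    denom = 2 * len(genotypes)
    rows = [
        {"locus": locus, "allele": name, "count": n, "frequency": n / denom}
        for (locus, name), n in sorted(counts.items(), key=lambda kv: (kv[0][0], -kv[1], kv[0][1]))
    ]
    return pd.DataFrame(rows)


def expression_proportions(measurements: Sequence[float]) -> tuple[float, ...]:
    """Normalize six nonnegative per-slot measurements to weights summing to 1.

    Scale-invariant: x and c*x give identical weights.  All-zero input is
    rejected (no expression information to weight by).
    """
    xs = [float(x) for x in measurements]
    if len(xs) != 6:
        raise ValueError(f"expected 6 measurements, got {len(xs)}")
    if any(x < 0 for x in xs):
        raise ValueError("negative expression measurement")
    total = sum(xs)
    if total <= 0:
        raise ValueError("all-zero expression measurements: cannot derive weights")
    return tuple(x / total for x in xs)


def genotype_weights_from_measurements(
    genotype: HLAGenotype, measurements: Mapping[str, float]
) -> HLAGenotype:
    """Attach expression weights from a map of allele name -> measurement.

    A homozygous locus reported once (jointly) has its measurement split in
    half between the two identical slots.  Alleles absent from the map get 0.
    """
    slot_values: list[float] = []
    for i, allele in enumerate(genotype.alleles):
        value = float(measurements.get(allele.name, 0.0))
        partner = genotype.alleles[i ^ 1]  # the other slot at the same locus
        if partner.name == allele.name:
            value /= 2.0
        slot_values.append(value)
    return genotype.with_weights(expression_proportions(slot_values))


# -- TSV I/O -----------------------------------------------------------------

_GENO_COLS = ["patient", "A1", "A2", "B1", "B2", "C1", "C2"]


def write_genotypes(genotypes: Sequence[HLAGenotype], path) -> None:
    rows = []
    for g in genotypes:
        rows.append({"patient": g.patient, **{c: a.name for c, a in zip(_GENO_COLS[1:], g.alleles)}})
    pd.DataFrame(rows, columns=_GENO_COLS).to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> list[HLAGenotype]:
    table = pd.read_csv(path, sep="\t")
    missing = set(_GENO_COLS) - set(table.columns)
    if missing:
        raise ValueError(f"genotype TSV missing columns: {sorted(missing)}")
    return [
        parse_genotype(str(row.patient), [getattr(row, c) for c in _GENO_COLS[1:]])
        for row in table.itertuples(index=False)
    ]


def read_expression(path) -> dict[str, dict[str, float]]:
    """Read a per-allele expression TSV (patient, allele, measurement)."""
    table = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, float]] = {}
    for row in table.itertuples(index=False):
        out.setdefault(str(row.patient), {})[parse_allele(str(row.allele)).name] = float(
            row.measurement
        )
    return out
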