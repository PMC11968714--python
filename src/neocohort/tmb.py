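"""Somatic-variant filtering and tumor mutational burden (TMB).

The workflow mirrors a standard targeted-panel TMB computation: drop variants
seen in population databases at frequency >= threshold (novel variants with
no recorded frequency are kept), restrict to the captured target region, then

    total TMB      = n variants / target size (Mb)
    functional TMB = n protein-altering variants / target size (Mb)

where "protein-altering" is a configurable consequence-class set.  BED input
is 0-based half-open; variant positions are 1-based (VCF convention).  The
conversion happens once, at the containment check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from .variants import CONSEQUENCE_CLASSES, SomaticVariant

__all__ = [
    "FUNCTIONAL_CLASSES",
    "TargetRegion",
    "TmbResult",
    "filter_population_frequency",
    "restrict_to_target",
    "is_functional",
    "compute_tmb",
    "tmb_table",
]

#: Consequence classes that change the coding protein.
FUNCTIONAL_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift", "inframe_indel", "splice_site", "start_lost", "stop_lost"}
)


@dataclass(frozen=True)
class TargetRegion:
    """Normalized (sorted, merged) target intervals, 0-based half-open."""

    intervals: tuple[tuple[str, int, int], ...]
    _trees: dict[str, IntervalTree] = field(repr=False, compare=False, default_factory=dict)

    @classmethod
    def from_intervals(cls, intervals) -> "TargetRegion":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"malformed interval {chrom}:{start}-{end} (start >= end)")
            by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
        merged: list[tuple[str, int, int]] = []
        for chrom in sorted(by_chrom):
            spans = sorted(by_chrom[chrom])
            cur_s, cur_e = spans[0]
            for s, e in spans[1:]:
                if s <= cur_e:  # overlapping or adjacent: merge
                    cur_e = max(cur_e, e)
                else:
                    merged.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            merged.append((chrom, cur_s, cur_e))
        if not merged:
            raise ValueError("target region is empty")
        region = cls(intervals=tuple(merged))
        for chrom, start, end in merged:
            region._trees.setdefault(chrom, IntervalTree()).addi(start, end)
        return region

    @classmethod
    def from_bed(cls, path) -> "TargetRegion":
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            rows.append((fields[0], int(fields[1]), int(fields[2])))
        return cls.from_intervals(rows)

    @property
    def total_size_bp(self) -> int:
        return sum(end - start for _, start, end in self.intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        """Whether 1-based position ``pos`` falls inside the region."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos - 1))


@dataclass(frozen=True)
class TmbResult:
    total_tmb: float
    functional_tmb: float
    n_total: int
    n_functional: int


def filter_population_frequency(variants, threshold: float = 0.001):
    """Keep variants with population AF strictly below ``threshold``.

    Variants with no recorded population frequency are treated as novel and
    retained.  Input order is preserved.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0,1], got {threshold}")
    return [v for v in variants if v.population_af is None or v.population_af < threshold]


def restrict_to_target(variants, region: TargetRegion):
    """Keep variants whose position lies inside the target region."""
    return [v for v in variants if region.contains(v.chrom, v.pos)]


def is_functional(
    variant: SomaticVariant, functional_classes: frozenset[str] = FUNCTIONAL_CLASSES
) -> bool:
    unknown = functional_classes - CONSEQUENCE_CLASSES
    if unknown:
        raise ValueError(f"unknown consequence classes: {sorted(unknown)}")
    return variant.consequence_class in functional_classes


def compute_tmb(
    variants,
    region: TargetRegion,
    functional_classes: frozenset[str] = FUNCTIONAL_CLASSES,
) -> TmbResult:
    """TMB in mutations per megabase over an already-filtered variant list."""
    size_mb = region.total_size_bp / 1e6
    if size_mb <= 0:
        raise ValueError("target region has zero size")
    variants = list(variants)
    n_total = len(variants)
    n_functional = sum(is_functional(v, functional_classes) for v in variants)
    return TmbResult(
        total_tmb=n_total / size_mb,
        functional_tmb=n_functional / size_mb,
        n_total=n_total,
        n_functional=n_functional,
    )


def tmb_table(
    per_patient_variants: dict[str, list[SomaticVariant]],
    region: TargetRegion,
    af_threshold: float = 0.001,
    functional_classes: frozenset[str] = FUNCTIONAL_CLASSES,
) -> pd.DataFrame:
    """Filter + restrict + TMB per patient; one row per patient."""
    rows = []
    size_mb = region.total_size_bp / 1e6
    for patient in sorted(per_patient_variants):
        kept = restrict_to_target(
            filter_population_frequency(per_patient_variants[patient], af_threshold), region
        )
        res = compute_tmb(kept, region, functional_classes)
        rows.append(
            {
                "patient": patient,
                "n_total": res.n_total,
                "n_functional": res.n_functional,
                "target_mb": size_mb,
                "total_tmb": res.total_tmb,
                "functional_tmb": res.functional_tmb,
            }
        )
    return pd.DataFrame(rows)
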