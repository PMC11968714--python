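"""Annotated somatic variants and minimal VCF I/O.

Variants carry the three annotations the downstream analyses consume: a
consequence class (from an upstream annotator), a population allele frequency
(``None`` for novel variants absent from population databases) and the RNA
mutation frequency (VAF) at the site.  On disk these live in INFO keys
``CSQCLASS``, ``AF_POP`` and ``RNAVAF`` of a minimal VCF 4.2 dialect; reading
goes through pysam and splits multi-allelic records into one variant per ALT.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pysam

__all__ = [
    "CONSEQUENCE_CLASSES",
    "SomaticVariant",
    "write_vcf",
    "read_vcf",
]

CONSEQUENCE_CLASSES = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift",
        "inframe_indel",
        "splice_site",
        "start_lost",
        "stop_lost",
        "synonymous",
        "noncoding",
        "other",
    }
)

_DNA = frozenset("ACGTN")


@dataclass(frozen=True, slots=True)
class SomaticVariant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str = "."
    consequence_class: str = "other"
    population_af: float | None = None
    rna_vaf: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if not set(self.ref) <= _DNA or not set(self.alt) <= _DNA:
            raise ValueError(f"non-DNA ref/alt at {self.chrom}:{self.pos}")
        if self.consequence_class not in CONSEQUENCE_CLASSES:
            raise ValueError(f"unknown consequence class {self.consequence_class!r}")
        for name in ("population_af", "rna_vaf"):
            value = getattr(self, name)
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {value}")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQCLASS,Number=1,Type=String,Description="Consequence class">
##INFO=<ID=AF_POP,Number=1,Type=Float,Description="Population allele frequency">
##INFO=<ID=RNAVAF,Number=1,Type=Float,Description="RNA mutation frequency (VAF)">
"""


def write_vcf(variants, path, contigs: dict[str, int] | None = None) -> None:
    """Write variants as a minimal VCF 4.2 file (no samples)."""
    lines = [_VCF_HEADER.rstrip("\n")]
    for name, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        info = [f"GENE={v.gene}", f"CSQCLASS={v.consequence_class}"]
        if v.population_af is not None:
            info.append(f"AF_POP={v.population_af:.6g}")
        if v.rna_vaf is not None:
            info.append(f"RNAVAF={v.rna_vaf:.6g}")
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t" + ";".join(info)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(
    path,
    af_key: str = "AF_POP",
    class_key: str = "CSQCLASS",
    vaf_key: str = "RNAVAF",
    gene_key: str = "GENE",
) -> list[SomaticVariant]:
    """Read a VCF; multi-allelic records are split into one variant per ALT."""
    out: list[SomaticVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            info = rec.info
            csq = info.get(class_key, "other")
            if isinstance(csq, tuple):
                csq = csq[0]
            af = info.get(af_key)
            if isinstance(af, tuple):
                af = af[0]
            vaf = info.get(vaf_key)
            if isinstance(vaf, tuple):
                vaf = vaf[0]
            gene = info.get(gene_key, ".")
            if isinstance(gene, tuple):
                gene = gene[0]
            for alt in rec.alts or ():
                out.append(
                    SomaticVariant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        gene=str(gene),
                        consequence_class=str(csq),
                        population_af=None if af is None else min(1.0, max(0.0, float(af))),
                        rna_vaf=None if vaf is None else min(1.0, max(0.0, float(vaf))),
                    )
                )
    return out
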