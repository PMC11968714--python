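"""Transcript models: cDNA with an annotated CDS and its protein product.

A transcript is a single cDNA string with 0-based half-open CDS coordinates;
the CDS includes its stop codon.  Serialisation is plain FASTA (cDNA) plus a
TSV of CDS coordinates and gene names.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["Transcript", "translate_cds", "translate_to_stop", "write_transcripts", "read_transcripts"]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def translate_cds(cds: str) -> str:
    """Translate a complete CDS (ATG..stop) to protein, stop stripped."""
    aa = str(Seq(cds).translate())
    return aa[:-1] if aa.endswith("*") else aa


def translate_to_stop(nt: str) -> tuple[str, bool]:
    """Translate in frame 0 until the first stop codon or the last complete codon.

    Returns ``(protein, hit_stop)``.  An incomplete trailing codon is dropped,
    which is the behaviour needed for frameshift neo-ORFs that run off the end
    of the cDNA.
    """
    usable = len(nt) - len(nt) % 3
    aa = str(Seq(nt[:usable]).translate())
    if "*" in aa:
        return aa[: aa.index("*")], True
    return aa, False


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    gene: str
    cdna: str
    cds_start: int  # 0-based, inclusive
    cds_end: int  # 0-based, exclusive; CDS includes the stop codon

    def __post_init__(self) -> None:
        if not 0 <= self.cds_start < self.cds_end <= len(self.cdna):
            raise ValueError(f"{self.transcript_id}: CDS coordinates out of range")
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValueError(f"{self.transcript_id}: CDS length not divisible by 3")
        if not self.cds.startswith("ATG"):
            raise ValueError(f"{self.transcript_id}: CDS does not start with ATG")
        if self.cds[-3:] not in STOP_CODONS:
            raise ValueError(f"{self.transcript_id}: CDS does not end with a stop codon")

    @property
    def cds(self) -> str:
        return self.cdna[self.cds_start : self.cds_end]

    @property
    def protein(self) -> str:
        return translate_cds(self.cds)

    @property
    def n_codons(self) -> int:
        """CDS length in codons, stop codon included."""
        return (self.cds_end - self.cds_start) // 3


def write_transcripts(transcripts, fasta_path, cds_path) -> None:
    records = [
        SeqRecord(Seq(t.cdna), id=t.transcript_id, description=t.gene) for t in transcripts
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(
        {
            "transcript_id": [t.transcript_id for t in transcripts],
            "gene": [t.gene for t in transcripts],
            "cds_start": [t.cds_start for t in transcripts],
            "cds_end": [t.cds_end for t in transcripts],
        }
    ).to_csv(cds_path, sep="\t", index=False)


def read_transcripts(fasta_path, cds_path) -> list[Transcript]:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    table = pd.read_csv(cds_path, sep="\t")
    out = []
    for row in table.itertuples(index=False):
        if row.transcript_id not in seqs:
            raise ValueError(f"transcript {row.transcript_id} in {Path(cds_path)} missing from FASTA")
        out.append(
            Transcript(
                transcript_id=row.transcript_id,
                gene=str(row.gene),
                cdna=seqs[row.transcript_id],
                cds_start=int(row.cds_start),
                cds_end=int(row.cds_end),
            )
        )
    return out
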