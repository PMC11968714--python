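"""Mutant-peptide enumeration and 25-AA neoantigen scoring.

Pipeline per somatic variant:

1. ``apply_variant`` — apply the variant to its transcript and translate,
   yielding a :class:`MutantProtein` with the set of mutant residue positions.
   Missense gives a single substituted residue; a frameshift indel yields the
   neo-ORF translated in the shifted frame from the first altered codon to the
   first stop codon, or to the end of the cDNA (last complete codon) when no
   stop occurs.  Stop-gain and synonymous variants produce no mutant residues
   and hence no protein.
2. ``enumerate_peptides`` — all 8–11-mer windows containing at least one
   mutant position.
3. ``score_peptide`` — per-allele binding scores over the patient's six HLA
   slots, combined as the expression-weighted sum.
4. ``merge_neoantigens`` — overlapping peptide windows are clustered
   transitively; each cluster becomes one <=25-AA neoantigen centered on the
   cluster's (leftmost) mutant position, with

       score = (sum of constituent peptide combined scores) x RNA VAF.

``design_patient`` chains the stages and returns the ranked candidate list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .binding import BindingScorer
from .hla import HLAGenotype
from .transcripts import Transcript, translate_to_stop
from .variants import SomaticVariant

__all__ = [
    "MutantProtein",
    "MutantPeptide",
    "Neoantigen25",
    "apply_variant",
    "enumerate_peptides",
    "score_peptide",
    "merge_neoantigens",
    "design_patient",
]

logger = logging.getLogger(__name__)

DEFAULT_K_RANGE = (8, 9, 10, 11)
NEOANTIGEN_FLANK = 12  # residues each side of the mutant site -> <=25 AA


@dataclass(frozen=True)
class MutantProtein:
    transcript_id: str
    sequence: str
    mutant_positions: tuple[int, ...]  # 0-based, sorted
    source_variant: SomaticVariant
    frameshift: bool = False

    def __post_init__(self) -> None:
        if not self.mutant_positions:
            raise ValueError("mutant_positions must be non-empty")
        if any(not 0 <= p < len(self.sequence) for p in self.mutant_positions):
            raise ValueError("mutant position outside protein")
        if self.frameshift:
            first = self.mutant_positions[0]
            expected = tuple(range(first, len(self.sequence)))
            if self.mutant_positions != expected:
                raise ValueError("frameshift mutant positions must be a contiguous suffix")


@dataclass(frozen=True)
class MutantPeptide:
    sequence: str
    protein_start: int
    covered_mutant_positions: tuple[int, ...]
    per_allele_scores: tuple[float, ...] = ()
    combined_score: float = 0.0

    def __post_init__(self) -> None:
        if not 8 <= len(self.sequence) <= 11:
            raise ValueError(f"peptide length {len(self.sequence)} outside 8..11")
        if not self.covered_mutant_positions:
            raise ValueError("peptide covers no mutant position")

    @property
    def end(self) -> int:
        return self.protein_start + len(self.sequence)


@dataclass(frozen=True)
class Neoantigen25:
    sequence: str
    constituent_peptides: tuple[MutantPeptide, ...]
    score: float
    rna_vaf: float
    transcript_id: str = ""
    gene: str = ""
    variant: str = ""
    truncated: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) > 25:
            raise ValueError(f"neoantigen sequence longer than 25 AA: {len(self.sequence)}")


def _first_difference(ref: str, alt: str) -> int:
    """Length of the common prefix of two strings."""
    n = min(len(ref), len(alt))
    for i in range(n):
        if ref[i] != alt[i]:
            return i
    return n


def apply_variant(transcript: Transcript, variant: SomaticVariant) -> MutantProtein | None:
    """Apply a somatic variant to a transcript and derive the mutant protein.

    Returns ``None`` (with a logged reason) when the variant yields no novel
    residues: synonymous changes, stop gains, variants outside the CDS.  The
    actual protein effect is derived from the sequences, not trusted from the
    annotation.  A reference mismatch raises ``ValueError``.
    """
    cdna = transcript.cdna
    i0 = variant.pos - 1
    observed = cdna[i0 : i0 + len(variant.ref)]
    if observed != variant.ref:
        raise ValueError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: "
            f"transcript has {observed!r}, variant says {variant.ref!r}"
        )
    # first base that actually differs (VCF anchors indels on a shared base)
    shift = _first_difference(variant.ref, variant.alt)
    first_altered = i0 + shift
    if not transcript.cds_start <= first_altered < transcript.cds_end - 3:
        logger.debug("variant %s:%s outside CDS of %s; skipped", variant.chrom, variant.pos, transcript.transcript_id)
        return None

    mutant_cdna = cdna[:i0] + variant.alt + cdna[i0 + len(variant.ref) :]
    delta = len(variant.alt) - len(variant.ref)
    ref_protein = transcript.protein

    if delta % 3 != 0:
        # frameshift: re-translate from the first altered codon through the
        # rest of the cDNA; stop at the first stop codon, else run to the last
        # complete codon of the cDNA.
        codon0 = (first_altered - transcript.cds_start) // 3
        tail_start = transcript.cds_start + 3 * codon0
        tail_aa, _hit_stop = translate_to_stop(mutant_cdna[tail_start:])
        sequence = ref_protein[:codon0] + tail_aa
        if len(sequence) <= codon0:
            logger.debug("frameshift at %s:%s hits an immediate stop; skipped", variant.chrom, variant.pos)
            return None
        return MutantProtein(
            transcript_id=transcript.transcript_id,
            sequence=sequence,
            mutant_positions=tuple(range(codon0, len(sequence))),
            source_variant=variant,
            frameshift=True,
        )

    # in-frame change (SNV, MNV or 3n indel): translate the shifted CDS up to
    # the original stop and diff against the reference protein.
    mutant_cds = mutant_cdna[transcript.cds_start : transcript.cds_end + delta]
    mut_protein, hit_stop = translate_to_stop(mutant_cds)
    ref_trimmed = ref_protein
    if len(mut_protein) < len(ref_trimmed) and hit_stop:
        # premature stop: any residues before it may still be novel
        pass
    left = _first_difference(ref_trimmed, mut_protein)
    if left == len(mut_protein):
        reason = "synonymous" if mut_protein == ref_trimmed else "stop gain"
        logger.debug("variant %s:%s is %s; no mutant protein", variant.chrom, variant.pos, reason)
        return None
    # align from the right to bound the altered block (handles in-frame indels)
    right = 0
    while (
        right < len(mut_protein) - left
        and right < len(ref_trimmed) - left
        and mut_protein[len(mut_protein) - 1 - right] == ref_trimmed[len(ref_trimmed) - 1 - right]
    ):
        right += 1
    positions = tuple(range(left, len(mut_protein) - right))
    if not positions:
        return None
    return MutantProtein(
        transcript_id=transcript.transcript_id,
        sequence=mut_protein,
        mutant_positions=positions,
        source_variant=variant,
        frameshift=False,
    )


def enumerate_peptides(
    mp: MutantProtein, k_range: Sequence[int] = DEFAULT_K_RANGE
) -> list[MutantPeptide]:
    """All k-mer windows (k in ``k_range``) containing >=1 mutant position.

    Windows must lie fully inside the protein.  Output is deterministic,
    ordered by start then k; a protein shorter than min(k) yields [].
    """
    seq = mp.sequence
    L = len(seq)
    mutant = set(mp.mutant_positions)
    out: list[MutantPeptide] = []
    for start in range(L):
        for k in sorted(k_range):
            if not 8 <= k <= 11:
                raise ValueError(f"k={k} outside the class-I 8..11 range")
            end = start + k
            if end > L:
                break
            covered = tuple(p for p in range(start, end) if p in mutant)
            if covered:
                out.append(
                    MutantPeptide(
                        sequence=seq[start:end],
                        protein_start=start,
                        covered_mutant_positions=covered,
                    )
                )
    return out


def score_peptide(
    peptide: MutantPeptide, genotype: HLAGenotype, scorer: BindingScorer
) -> MutantPeptide:
    """Score one peptide against the patient's six HLA slots.

    combined = sum_i weight_i x score(peptide, allele_i), weights being the
    genotype's expression weights (uniform 1/6 when unmeasured).  Scorer
    failures propagate — a lookup error is never a silent zero.
    """
    weights = genotype.weights()
    scores = tuple(scorer.score(peptide.sequence, allele.name) for allele in genotype.alleles)
    if any(s < 0 for s in scores):
        raise ValueError("binding scorer returned a negative score")
    combined = sum(w * s for w, s in zip(weights, scores))
    return replace(peptide, per_allele_scores=scores, combined_score=combined)


def _clusters(peptides: Sequence[MutantPeptide]) -> list[list[MutantPeptide]]:
    """Transitive clustering of peptides by window overlap (shared residue)."""
    ordered = sorted(peptides, key=lambda p: (p.protein_start, len(p.sequence), p.sequence))
    clusters: list[list[MutantPeptide]] = []
    cur: list[MutantPeptide] = []
    cur_end = -1
    for p in ordered:
        if cur and p.protein_start < cur_end:
            cur.append(p)
            cur_end = max(cur_end, p.end)
        else:
            if cur:
                clusters.append(cur)
            cur = [p]
            cur_end = p.end
    if cur:
        clusters.append(cur)
    return clusters


def merge_neoantigens(
    peptides: Sequence[MutantPeptide],
    protein: MutantProtein,
    rna_vaf: float | None = None,
) -> list[Neoantigen25]:
    """Merge overlapping scored peptides from one mutant protein.

    Each transitive overlap cluster yields one neoantigen: the <=25-AA window
    centered on the cluster's leftmost mutant position (12 flanking residues
    each side, truncated at the protein termini), scored as the sum of the
    cluster's combined peptide scores times the RNA VAF.  A missing VAF is
    treated as 1.0 with a warning.
    """
    if rna_vaf is None:
        rna_vaf = protein.source_variant.rna_vaf
    if rna_vaf is None:
        logger.warning(
            "no RNA VAF for variant %s:%s; scoring with VAF=1.0",
            protein.source_variant.chrom,
            protein.source_variant.pos,
        )
        rna_vaf = 1.0
    seq = protein.sequence
    v = protein.source_variant
    out: list[Neoantigen25] = []
    for cluster in _clusters(peptides):
        center = min(p for pep in cluster for p in pep.covered_mutant_positions)
        lo = max(0, center - NEOANTIGEN_FLANK)
        hi = min(len(seq), center + NEOANTIGEN_FLANK + 1)
        span_lo = min(p.protein_start for p in cluster)
        span_hi = max(p.end for p in cluster)
        truncated = span_lo < lo or span_hi > hi
        if truncated:
            logger.debug(
                "cluster at %s:%d spans %d AA; truncated to the 25-AA window",
                protein.transcript_id, center, span_hi - span_lo,
            )
        out.append(
            Neoantigen25(
                sequence=seq[lo:hi],
                constituent_peptides=tuple(cluster),
                score=sum(p.combined_score for p in cluster) * rna_vaf,
                rna_vaf=rna_vaf,
                transcript_id=protein.transcript_id,
                gene=v.gene,
                variant=f"{v.chrom}:{v.pos}:{v.ref}>{v.alt}",
                truncated=truncated,
            )
        )
    return out


def design_patient(
    variants: Iterable[SomaticVariant],
    transcripts: dict[str, Transcript],
    genotype: HLAGenotype,
    scorer: BindingScorer,
    binder_threshold: float = 0.01,
    k_range: Sequence[int] = DEFAULT_K_RANGE,
) -> list[Neoantigen25]:
    """Full per-patient design: apply -> enumerate -> score -> filter -> merge.

    Peptides with combined score below ``binder_threshold`` drop out before
    merging.  Transcripts are looked up by variant chrom (the synthetic
    cohorts put each transcript on its own contig).  Returns neoantigens
    sorted by score descending, ties broken by sequence.
    """
    results: list[Neoantigen25] = []
    for variant in variants:
        transcript = transcripts.get(variant.chrom)
        if transcript is None:
            logger.debug("no transcript for contig %s; variant skipped", variant.chrom)
            continue
        mp = apply_variant(transcript, variant)
        if mp is None:
            continue
        peptides = enumerate_peptides(mp, k_range)
        scored = [
            score_peptide(p, genotype, scorer)
            for p in peptides
            if "X" not in p.sequence  # unknown residues are unscorable
        ]
        survivors = [p for p in scored if p.combined_score >= binder_threshold]
        if survivors:
            results.extend(merge_neoantigens(survivors, mp))
    results.sort(key=lambda n: (-n.score, n.sequence))
    return results
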