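"""Self-contained synthetic cohort generator.

Generates everything the downstream analyses consume — reference transcripts,
per-patient annotated somatic variants, HLA genotypes with per-allele
expression, clonotype repertoires, and planted set-cover instances — with the
statistical structure of a small glioma vaccine cohort: ~24 patients, a few
hundred mostly patient-private mutated sites each with one extreme outlier
patient, a recurrent hotspot carried by ~21% of patients, HLA genotypes drawn
from a frequency table headed by A*30:01/A*11:01, B*13:02 and C*06:02, and
repertoires of mostly private CDR3s plus planted universal / tumor-specific
clones.

Every generator is a pure function of its seed: the same seed yields a
byte-identical cohort.  Default constants are emulation defaults chosen to
mirror published cohort summaries, not ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from ._rng import child_seed
from .hla import HLAGenotype, HLAAllele, genotype_weights_from_measurements, parse_allele
from .repertoire import AA_ALPHABET, REQUIRED_COLUMNS
from .tmb import TargetRegion
from .transcripts import STOP_CODONS, Transcript
from .variants import SomaticVariant, write_vcf

__all__ = [
    "CohortSpec",
    "RepertoireSpec",
    "Cohort",
    "generate_reference_transcripts",
    "generate_patient_variants",
    "generate_hla_genotypes",
    "generate_hla_expression",
    "plant_cover_instance",
    "generate_repertoire",
    "build_target_region",
    "simulate_cohort",
]

_BASES = "ACGT"
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in STOP_CODONS
)
_CODON_AA = {c: str(Seq(c).translate()) for c in (a + b + c for a in _BASES for b in _BASES for c in _BASES)}

DEFAULT_CLASS_PROBS = {
    "missense": 0.55,
    "synonymous": 0.14,
    "frameshift": 0.08,
    "nonsense": 0.05,
    "inframe_indel": 0.04,
    "splice_site": 0.04,
    "noncoding": 0.10,
}

# Two-field class-I allele frequencies headed by the most common genotypes in
# East-Asian cohorts; per-locus residual mass is spread over rare "other"
# alleles at sampling time.
DEFAULT_HLA_FREQUENCIES = {
    "A*30:01": 0.16, "A*11:01": 0.16, "A*02:01": 0.12, "A*24:02": 0.10,
    "A*33:03": 0.07, "A*01:01": 0.05, "A*03:01": 0.04,
    "B*13:02": 0.15, "B*46:01": 0.10, "B*40:01": 0.09, "B*58:01": 0.08,
    "B*15:01": 0.07, "B*51:01": 0.06,
    "C*06:02": 0.18, "C*01:02": 0.12, "C*07:02": 0.10, "C*03:04": 0.08,
    "C*08:01": 0.06,
}


@dataclass(frozen=True)
class RepertoireSpec:
    """Shape of the simulated TCR/BCR clonotype tables.

    Per-sample clonotype richness is Poisson around compartment x chain means
    modulated by per-patient abundance factors: a tumor lymphocyte-infiltration
    factor shared by both chains (coupling TCR and BCR richness within tumor)
    and a B-cell abundance factor shared by both compartments (coupling IGH
    richness between tumor and PBMC).  CDR3s are drawn either from a per-chain
    shared pool (producing cross-patient sharing) or privately.
    """

    mean_clonotypes: dict = field(
        default_factory=lambda: {
            ("tumor", "TRB"): 400, ("PBMC", "TRB"): 600,
            ("tumor", "IGH"): 150, ("PBMC", "IGH"): 250,
        }
    )
    length_peak: int = 15
    length_sd: dict = field(default_factory=lambda: {"TRB": 2.0, "IGH": 3.0})
    p_ca_start: float = 0.9
    shared_pool_size: int = 700
    p_shared: dict = field(
        default_factory=lambda: {
            ("tumor", "TRB"): 0.50, ("PBMC", "TRB"): 0.60,
            ("tumor", "IGH"): 0.60, ("PBMC", "IGH"): 0.30,
        }
    )
    patient_factor_sd: float = 0.4
    universal_clones: tuple = (("CASSLEETQYF", "PBMC", "TRB"),)
    tumor_specific_clones: tuple = (
        ("CASSPGQGAYEQYF", "TRB", 5),
        ("CASSLGQAYNEQFF", "TRB", 5),
        ("CASSFGRETQYF", "TRB", 5),
        ("CASSPDRGHEQYF", "TRB", 5),
    )

    def __post_init__(self) -> None:
        for mean in self.mean_clonotypes.values():
            if mean < 1:
                raise ValueError("clonotype means must be >= 1")
        for clone in [c for c, *_ in self.universal_clones] + [
            c for c, *_ in self.tumor_specific_clones
        ]:
            if not clone or any(aa not in AA_ALPHABET for aa in clone):
                raise ValueError(f"planted clone {clone!r} contains invalid amino acids")


@dataclass(frozen=True)
class CohortSpec:
    """All knobs of the synthetic cohort; defaults are the emulation targets."""

    n_patients: int = 24
    mean_sites_per_patient: float = 140.0
    outlier_patient_factor: float = 14.0
    hotspot_spec: tuple = (("IDH1_like:132", 5 / 24),)  # (gene:codon, carrier fraction)
    class_probs: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROBS))
    hla_frequency_table: dict = field(default_factory=lambda: dict(DEFAULT_HLA_FREQUENCIES))
    repertoire_spec: RepertoireSpec = field(default_factory=RepertoireSpec)
    seed: int = 0
    # synthetic genome / panel
    n_transcripts: int = 300
    transcript_length: tuple = (300.0, 100.0)  # codons (mean, sd)
    target_size_bp: int = 50_000_000  # emulated exome capture size
    germline_contam_rate: float = 0.05  # fraction with population AF >= 0.001
    recurrent_site_pool: int = 300
    p_recurrent: float = 0.10
    vaf_range: tuple = (0.05, 1.0)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.mean_sites_per_patient <= 0:
            raise ValueError("mean_sites_per_patient must be positive")
        if self.outlier_patient_factor <= 0:
            raise ValueError("outlier_patient_factor must be positive")
        total = sum(self.class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_probs sum to {total}, expected 1")
        for site, frac in self.hotspot_spec:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"hotspot {site}: carrier fraction {frac} outside [0,1]")
        by_locus: dict[str, float] = {}
        for name, freq in self.hla_frequency_table.items():
            by_locus[parse_allele(name).locus] = by_locus.get(parse_allele(name).locus, 0.0) + freq
        for locus, mass in by_locus.items():
            if mass > 1.0 + 1e-9:
                raise ValueError(f"HLA locus {locus} frequencies sum to {mass} > 1")

    def patients(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_patients)]


# -- transcripts -------------------------------------------------------------


def generate_reference_transcripts(
    n: int,
    length_dist: tuple[float, float] = (300.0, 100.0),
    seed: int = 0,
    special_genes: tuple[str, ...] = (),
) -> list[Transcript]:
    """Random transcript models: 5'UTR + (ATG .. stop) CDS + 3'UTR.

    ``length_dist`` is the (mean, sd) of CDS length in codons (stop included);
    the mean must be >= 30 codons.  ``special_genes`` names are assigned to
    the first transcripts (used for hotspot genes).
    """
    if n < 1:
        raise ValueError("need n >= 1 transcripts")
    mean, sd = float(length_dist[0]), float(length_dist[1])
    if mean < 30:
        raise ValueError(f"mean transcript length must be >= 30 codons, got {mean}")
    if sd < 0:
        raise ValueError("length sd must be nonnegative")
    rng = np.random.default_rng(child_seed(seed, "transcripts"))
    out: list[Transcript] = []
    for i in range(n):
        n_codons = max(30, int(round(rng.normal(mean, sd))))
        utr5 = "".join(rng.choice(list(_BASES), size=int(rng.integers(10, 100))))
        utr3 = "".join(rng.choice(list(_BASES), size=int(rng.integers(30, 200))))
        internal = rng.choice(len(_NONSTOP_CODONS), size=n_codons - 2)
        cds = "ATG" + "".join(_NONSTOP_CODONS[j] for j in internal) + str(
            rng.choice(sorted(STOP_CODONS))
        )
        gene = special_genes[i] if i < len(special_genes) else f"GENE{i + 1:04d}"
        out.append(
            Transcript(
                transcript_id=f"TX{i + 1:04d}",
                gene=gene,
                cdna=utr5 + cds + utr3,
                cds_start=len(utr5),
                cds_end=len(utr5) + 3 * n_codons,
            )
        )
    return out


# -- variants ----------------------------------------------------------------


def _snv_at(tx: Transcript, cdna_index: int, alt: str) -> tuple[int, str, str]:
    return cdna_index + 1, tx.cdna[cdna_index], alt


def _codon_snv(rng, tx: Transcript, codon: int, want: str):
    """A 1-bp substitution in 1-based CDS codon ``codon`` with a given effect.

    ``want`` is "missense" / "synonymous" / "nonsense".  Returns (pos, ref,
    alt) or None when the codon admits no such change.
    """
    start = tx.cds_start + 3 * (codon - 1)
    ref_codon = tx.cdna[start : start + 3]
    ref_aa = _CODON_AA[ref_codon]
    options = []
    for offset in range(3):
        for base in _BASES:
            if base == ref_codon[offset]:
                continue
            alt_codon = ref_codon[:offset] + base + ref_codon[offset + 1 :]
            alt_aa = _CODON_AA[alt_codon]
            if want == "missense" and alt_aa not in ("*", ref_aa):
                options.append((offset, base))
            elif want == "synonymous" and alt_aa == ref_aa:
                options.append((offset, base))
            elif want == "nonsense" and alt_aa == "*" and ref_aa != "*":
                options.append((offset, base))
    if not options:
        return None
    offset, base = options[int(rng.integers(len(options)))]
    return _snv_at(tx, start + offset, base)


def _indel(rng, tx: Transcript, codon: int, length: int, insertion: bool):
    """A VCF-anchored insertion/deletion of ``length`` bp inside a codon."""
    anchor = tx.cds_start + 3 * (codon - 1) + int(rng.integers(3))
    if insertion:
        ref = tx.cdna[anchor]
        alt = ref + "".join(rng.choice(list(_BASES), size=length))
    else:
        if anchor + 1 + length > len(tx.cdna):
            return None
        ref = tx.cdna[anchor : anchor + 1 + length]
        alt = ref[0]
    return anchor + 1, ref, alt


def _utr_snv(rng, tx: Transcript):
    """A substitution outside the CDS (5' or 3' UTR)."""
    utr_positions = list(range(0, tx.cds_start)) + list(range(tx.cds_end, len(tx.cdna)))
    idx = utr_positions[int(rng.integers(len(utr_positions)))]
    ref = tx.cdna[idx]
    alt = [b for b in _BASES if b != ref][int(rng.integers(3))]
    return idx + 1, ref, alt


def _random_site(rng, transcripts, weights, csq: str):
    """Draw one (transcript, pos, ref, alt) realising consequence ``csq``."""
    for _ in range(50):
        tx = transcripts[int(rng.choice(len(transcripts), p=weights))]
        if csq in ("missense", "synonymous", "nonsense"):
            codon = int(rng.integers(2, tx.n_codons - 1))  # internal coding codon
            hit = _codon_snv(rng, tx, codon, csq)
        elif csq == "frameshift":
            codon = int(rng.integers(2, tx.n_codons - 1))
            hit = _indel(rng, tx, codon, int(rng.integers(1, 3)), bool(rng.integers(2)))
        elif csq == "inframe_indel":
            codon = int(rng.integers(2, tx.n_codons - 2))
            hit = _indel(rng, tx, codon, 3, bool(rng.integers(2)))
        else:  # splice_site, noncoding, other: placed outside the CDS
            hit = _utr_snv(rng, tx)
        if hit is not None:
            return tx, hit
    raise RuntimeError(f"could not place a {csq} variant after 50 attempts")


def _resolve_hotspots(transcripts, spec: CohortSpec):
    """Resolve 'gene:codon' hotspot ids to concrete missense templates."""
    by_gene = {t.gene: t for t in transcripts}
    resolved = []
    for site_id, frac in spec.hotspot_spec:
        gene, _, codon_s = site_id.partition(":")
        if gene not in by_gene:
            raise ValueError(f"hotspot gene {gene!r} not present among transcripts")
        tx = by_gene[gene]
        codon = int(codon_s) if codon_s else tx.n_codons // 2
        if not 2 <= codon <= tx.n_codons - 1:
            raise ValueError(f"hotspot codon {codon} outside the coding region of {gene}")
        rng = np.random.default_rng(child_seed(spec.seed, f"hotspot:{site_id}"))
        hit = _codon_snv(rng, tx, codon, "missense")
        if hit is None:
            raise ValueError(f"hotspot codon {codon} of {gene} admits no missense change")
        resolved.append((tx, hit, frac))
    return resolved


def generate_patient_variants(
    transcripts: list[Transcript], spec: CohortSpec
) -> dict[str, list[SomaticVariant]]:
    """Per-patient somatic variant lists.

    Per-patient site counts are Poisson(mean_sites_per_patient) with one
    designated outlier patient scaled by ``outlier_patient_factor``; each
    hotspot is planted in round(fraction x n_patients) patients; a configurable
    minority of sites is drawn from a shared recurrent pool; every variant
    carries a consequence class drawn from ``class_probs``, an RNA VAF in
    ``vaf_range`` and (for a small contaminant fraction) a population AF
    above the filtering threshold.
    """
    if not transcripts:
        raise ValueError("empty transcript set")
    rng = np.random.default_rng(child_seed(spec.seed, "variants"))
    patients = spec.patients()
    classes = sorted(spec.class_probs)
    class_p = np.array([spec.class_probs[c] for c in classes])
    lengths = np.array([t.n_codons for t in transcripts], dtype=float)
    tx_weights = lengths / lengths.sum()

    pool = []
    for _ in range(spec.recurrent_site_pool):
        csq = classes[int(rng.choice(len(classes), p=class_p))]
        tx, (pos, ref, alt) = _random_site(rng, transcripts, tx_weights, csq)
        pool.append((tx, pos, ref, alt, csq))

    hotspots = _resolve_hotspots(transcripts, spec)
    carriers: dict[int, list] = {i: [] for i in range(len(patients))}
    for h_idx, (tx, (pos, ref, alt), frac) in enumerate(hotspots):
        n_carriers = int(round(frac * spec.n_patients))
        for i in rng.choice(spec.n_patients, size=n_carriers, replace=False):
            carriers[int(i)].append((tx, pos, ref, alt, "missense"))

    outlier = int(rng.integers(spec.n_patients))
    out: dict[str, list[SomaticVariant]] = {}
    vaf_lo, vaf_hi = spec.vaf_range
    for i, patient in enumerate(patients):
        mean = spec.mean_sites_per_patient * (
            spec.outlier_patient_factor if i == outlier else 1.0
        )
        n_sites = int(rng.poisson(mean))
        taken: dict[tuple[str, int], tuple] = {}
        for tx, pos, ref, alt, csq in carriers[i]:  # hotspots planted first
            taken[(tx.transcript_id, pos)] = (tx, pos, ref, alt, csq)
        while len(taken) < n_sites + len(carriers[i]):
            if rng.random() < spec.p_recurrent:
                tx, pos, ref, alt, csq = pool[int(rng.integers(len(pool)))]
            else:
                csq = classes[int(rng.choice(len(classes), p=class_p))]
                tx, (pos, ref, alt) = _random_site(rng, transcripts, tx_weights, csq)
            taken.setdefault((tx.transcript_id, pos), (tx, pos, ref, alt, csq))
        variants = []
        for tx, pos, ref, alt, csq in taken.values():
            af = None
            if rng.random() < spec.germline_contam_rate:
                af = float(rng.uniform(0.001, 0.05))
            elif rng.random() < 0.3:
                af = float(rng.uniform(0.0, 0.00095))
            variants.append(
                SomaticVariant(
                    chrom=tx.transcript_id,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene=tx.gene,
                    consequence_class=csq,
                    population_af=af,
                    rna_vaf=float(vaf_lo + (vaf_hi - vaf_lo) * rng.random()),
                )
            )
        variants.sort(key=lambda v: (v.chrom, v.pos, v.alt))
        out[patient] = variants
    return out


# -- HLA ---------------------------------------------------------------------


def _locus_distribution(freq_table: dict, locus: str):
    names = [n for n in sorted(freq_table) if parse_allele(n).locus == locus]
    freqs = [freq_table[n] for n in names]
    residual = 1.0 - sum(freqs)
    if residual > 1e-9:
        # spread the residual mass over ten rare synthetic alleles
        for i in range(10):
            names.append(f"{locus}*91:{i + 1:02d}")
            freqs.append(residual / 10)
    total = sum(freqs)
    return names, [f / total for f in freqs]


def generate_hla_genotypes(
    freq_table: dict, n_patients: int, seed: int = 0
) -> list[HLAGenotype]:
    """Sample two alleles per locus per patient, independently per slot."""
    if not freq_table:
        raise ValueError("empty HLA frequency table")
    rng = np.random.default_rng(child_seed(seed, "hla"))
    per_locus = {locus: _locus_distribution(freq_table, locus) for locus in "ABC"}
    for locus, (names, _) in per_locus.items():
        if not names:
            raise ValueError(f"no alleles for locus {locus} in the frequency table")
    genotypes = []
    for i in range(n_patients):
        slots = []
        for locus in "ABC":
            names, probs = per_locus[locus]
            pair = sorted(
                names[int(rng.choice(len(names), p=probs))] for _ in range(2)
            )
            slots.extend(HLAAllele(locus=locus, name=n) for n in pair)
        genotypes.append(HLAGenotype(patient=f"P{i + 1:02d}", alleles=tuple(slots)))
    return genotypes


def generate_hla_expression(
    genotypes: list[HLAGenotype], seed: int = 0
) -> dict[str, dict[str, float]]:
    """Log-normal per-slot expression, aggregated per allele name.

    Homozygous loci report one joint measurement (the sum over both slots),
    matching how allele-level quantification collapses identical alleles.
    """
    rng = np.random.default_rng(child_seed(seed, "hla-expression"))
    out: dict[str, dict[str, float]] = {}
    for g in genotypes:
        measurements: dict[str, float] = {}
        for allele in g.alleles:
            value = float(rng.lognormal(mean=5.0, sigma=0.6))
            measurements[allele.name] = measurements.get(allele.name, 0.0) + value
        out[g.patient] = measurements
    return out


# -- planted cover instances -------------------------------------------------


def _random_peptide(rng, length: int = 25) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def plant_cover_instance(
    n_patients: int, optimum_k: int, decoys: int = 0, seed: int = 0
) -> tuple[dict[str, list[str]], dict]:
    """A cohort of per-patient peptide sets with known minimum cover size.

    Patients are partitioned into ``optimum_k`` blocks, each sharing one
    planted peptide private to the block; decoy peptides are each private to
    a single patient.  Because no peptide spans two blocks, any cover needs at
    least one peptide per block and the planted peptides suffice: the exact
    minimum is ``optimum_k`` by construction.

    Returns ``(per_patient, truth)`` with the planted peptides and block
    assignment in ``truth``.
    """
    if not 1 <= optimum_k <= n_patients:
        raise ValueError(f"optimum_k must be in [1, n_patients], got {optimum_k}")
    if decoys < 0:
        raise ValueError("decoys must be >= 0")
    rng = np.random.default_rng(child_seed(seed, "cover"))
    patients = [f"P{i + 1:02d}" for i in range(n_patients)]
    order = rng.permutation(n_patients)
    blocks: list[list[str]] = [[] for _ in range(optimum_k)]
    for rank, idx in enumerate(order):
        blocks[rank % optimum_k].append(patients[int(idx)])
    planted: list[str] = []
    while len(planted) < optimum_k:
        pep = _random_peptide(rng)
        if pep not in planted:
            planted.append(pep)
    per_patient: dict[str, list[str]] = {p: [] for p in patients}
    for pep, block in zip(planted, blocks):
        for p in block:
            per_patient[p].append(pep)
    decoy_list: list[str] = []
    while len(decoy_list) < decoys:
        pep = _random_peptide(rng)
        if pep in planted or pep in decoy_list:
            continue
        decoy_list.append(pep)
        per_patient[patients[int(rng.integers(n_patients))]].append(pep)
    truth = {
        "optimum": optimum_k,
        "planted": planted,
        "blocks": [sorted(b) for b in blocks],
        "decoys": decoy_list,
    }
    return per_patient, truth


# -- repertoires -------------------------------------------------------------

_TRB_V = tuple(f"TRBV{i}" for i in (2, 4, 5, 6, 7, 9, 11, 12, 15, 19, 20, 27, 28, 30))
_TRB_J = tuple(f"TRBJ{a}-{b}" for a in (1, 2) for b in (1, 2, 3, 5, 7))
_IGH_V = tuple(f"IGHV{a}-{b}" for a in (1, 3, 4, 5) for b in (2, 7, 23, 34, 59))
_IGH_J = tuple(f"IGHJ{b}" for b in (1, 2, 3, 4, 5, 6))
_GENES = {"TRB": (_TRB_V, _TRB_J), "IGH": (_IGH_V, _IGH_J)}


def _random_cdr3(rng, length: int, p_ca: float) -> str:
    aas = list(AA_ALPHABET)
    if rng.random() < p_ca:
        prefix = "CA"
    else:
        prefix = "C" + aas[int(rng.integers(len(aas)))]
    middle = "".join(rng.choice(aas, size=max(0, length - 3)))
    return (prefix + middle + "F")[:max(4, length)]


def generate_repertoire(
    spec: RepertoireSpec, n_patients: int = 24, seed: int = 0
) -> pd.DataFrame:
    """Clonotype tables per patient x compartment (tumor, PBMC) x chain.

    Planted universal clones appear in the stated compartment of every
    patient; planted tumor-specific clones appear in the tumors of their
    carrier patients and are scrubbed from all PBMC samples.
    """
    rng = np.random.default_rng(child_seed(seed, "repertoire"))
    patients = [f"P{i + 1:02d}" for i in range(n_patients)]
    sd = spec.patient_factor_sd
    infiltration = {p: float(rng.lognormal(0.0, sd)) for p in patients}  # tumor, both chains
    b_abundance = {p: float(rng.lognormal(0.0, sd)) for p in patients}  # IGH, both compartments
    pbmc_t = {p: float(rng.lognormal(0.0, sd)) for p in patients}  # TRB in PBMC only

    pools = {
        chain: [
            _random_cdr3(rng, _draw_length(rng, spec, chain), spec.p_ca_start)
            for _ in range(spec.shared_pool_size)
        ]
        for chain in CHAINS_ORDER
    }
    gene_weights = {}
    for chain, (vs, js) in _GENES.items():
        gene_weights[chain] = (
            rng.dirichlet(np.full(len(vs), 2.0)),
            rng.dirichlet(np.full(len(js), 2.0)),
        )

    tumor_specific_seqs = {c for c, *_ in spec.tumor_specific_clones}
    rows: list[dict] = []
    for patient in patients:
        for compartment in ("tumor", "PBMC"):
            for chain in CHAINS_ORDER:
                factor = 1.0
                if compartment == "tumor":
                    factor *= infiltration[patient]
                if chain == "IGH":
                    factor *= b_abundance[patient]
                if chain == "TRB" and compartment == "PBMC":
                    factor *= pbmc_t[patient]
                mean = spec.mean_clonotypes[(compartment, chain)] * factor
                n = max(1, int(rng.poisson(mean)))
                p_shared = spec.p_shared[(compartment, chain)]
                vs, js = _GENES[chain]
                vw, jw = gene_weights[chain]
                seen: set[tuple[str, str, str]] = set()
                while len(seen) < n:
                    if rng.random() < p_shared:
                        cdr3 = pools[chain][int(rng.integers(len(pools[chain])))]
                    else:
                        cdr3 = _random_cdr3(rng, _draw_length(rng, spec, chain), spec.p_ca_start)
                    if compartment == "PBMC" and cdr3 in tumor_specific_seqs:
                        continue  # keep planted tumor-specific clones out of PBMC
                    v = vs[int(rng.choice(len(vs), p=vw))]
                    j = js[int(rng.choice(len(js), p=jw))]
                    key = (cdr3, v, j)
                    if key in seen:
                        continue
                    seen.add(key)
                    rows.append(
                        {
                            "patient": patient,
                            "compartment": compartment,
                            "chain": chain,
                            "cdr3aa": cdr3,
                            "vGene": v,
                            "jGene": j,
                            "count": int(rng.geometric(0.35)),
                        }
                    )

    # planted universal clones: one entry per patient in the stated compartment
    for cdr3, compartment, chain in spec.universal_clones:
        vs, js = _GENES[chain]
        for patient in patients:
            rows.append(
                {
                    "patient": patient, "compartment": compartment, "chain": chain,
                    "cdr3aa": cdr3, "vGene": vs[0], "jGene": js[0],
                    "count": int(rng.geometric(0.35)),
                }
            )
    # planted tumor-specific clones
    for cdr3, chain, n_carriers in spec.tumor_specific_clones:
        if n_carriers > n_patients:
            raise ValueError(f"tumor-specific clone {cdr3} wants {n_carriers} carriers > cohort")
        vs, js = _GENES[chain]
        for i in rng.choice(n_patients, size=n_carriers, replace=False):
            rows.append(
                {
                    "patient": patients[int(i)], "compartment": "tumor", "chain": chain,
                    "cdr3aa": cdr3, "vGene": vs[0], "jGene": js[0],
                    "count": int(rng.geometric(0.35)),
                }
            )
    df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    df = df.drop_duplicates(subset=["patient", "compartment", "chain", "cdr3aa", "vGene", "jGene"])
    return df.sort_values(list(REQUIRED_COLUMNS[:6])).reset_index(drop=True)


CHAINS_ORDER = ("TRB", "IGH")


def _draw_length(rng, spec: RepertoireSpec, chain: str) -> int:
    return int(np.clip(round(rng.normal(spec.length_peak, spec.length_sd[chain])), 8, 28))


# -- whole-cohort assembly ---------------------------------------------------


def build_target_region(transcripts: list[Transcript], target_size_bp: int) -> TargetRegion:
    """Target intervals covering every transcript contig, padded to size.

    The synthetic contigs total only a few hundred kb; a single zero-variant
    padding interval brings the target up to the emulated capture size so TMB
    comes out in realistic Muts/Mb units.
    """
    intervals = [(t.transcript_id, 0, len(t.cdna)) for t in transcripts]
    covered = sum(len(t.cdna) for t in transcripts)
    if target_size_bp > covered:
        intervals.append(("PADDING", 0, target_size_bp - covered))
    return TargetRegion.from_intervals(intervals)


@dataclass
class Cohort:
    spec: CohortSpec
    transcripts: list[Transcript]
    target_region: TargetRegion
    variants: dict[str, list[SomaticVariant]]
    genotypes: list[HLAGenotype]  # expression weights attached
    hla_expression: dict[str, dict[str, float]]
    clonotypes: pd.DataFrame

    def transcript_index(self) -> dict[str, Transcript]:
        return {t.transcript_id: t for t in self.transcripts}


def simulate_cohort(spec: CohortSpec, outdir: str | Path | None = None) -> Cohort:
    """Generate a full cohort; optionally write it to ``outdir``.

    Outputs (when writing): transcripts FASTA + CDS TSV, target BED,
    per-patient VCFs, HLA genotype and expression TSVs, clonotype TSV.
    """
    hotspot_genes = tuple(site.partition(":")[0] for site, _ in spec.hotspot_spec)
    transcripts = generate_reference_transcripts(
        spec.n_transcripts, spec.transcript_length, seed=spec.seed, special_genes=hotspot_genes
    )
    variants = generate_patient_variants(transcripts, spec)
    genotypes = generate_hla_genotypes(spec.hla_frequency_table, spec.n_patients, seed=spec.seed)
    expression = generate_hla_expression(genotypes, seed=spec.seed)
    genotypes = [
        genotype_weights_from_measurements(g, expression[g.patient]) for g in genotypes
    ]
    clonotypes = generate_repertoire(spec.repertoire_spec, spec.n_patients, seed=spec.seed)
    region = build_target_region(transcripts, spec.target_size_bp)
    cohort = Cohort(
        spec=spec,
        transcripts=transcripts,
        target_region=region,
        variants=variants,
        genotypes=genotypes,
        hla_expression=expression,
        clonotypes=clonotypes,
    )
    if outdir is not None:
        write_cohort(cohort, outdir)
    return cohort


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    from .hla import write_genotypes
    from .transcripts import write_transcripts

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_transcripts(cohort.transcripts, outdir / "transcripts.fa", outdir / "cds.tsv")
    with open(outdir / "target.bed", "w") as bed:
        for chrom, start, end in cohort.target_region.intervals:
            bed.write(f"{chrom}\t{start}\t{end}\n")
    vcf_dir = outdir / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    contigs = {t.transcript_id: len(t.cdna) for t in cohort.transcripts}
    for patient, variants in cohort.variants.items():
        write_vcf(variants, vcf_dir / f"{patient}.vcf", contigs=contigs)
    write_genotypes(cohort.genotypes, outdir / "hla_genotypes.tsv")
    expr_rows = [
        {"patient": patient, "allele": allele, "measurement": value}
        for patient, table in sorted(cohort.hla_expression.items())
        for allele, value in sorted(table.items())
    ]
    pd.DataFrame(expr_rows).to_csv(outdir / "hla_expression.tsv", sep="\t", index=False)
    cohort.clonotypes.to_csv(outdir / "clonotypes.tsv", sep="\t", index=False)
    manifest = asdict(cohort.spec)
    manifest["repertoire_spec"] = {
        k: (
            {" | ".join(map(str, kk)) if isinstance(kk, tuple) else kk: vv for kk, vv in v.items()}
            if isinstance(v, dict)
            else v
        )
        for k, v in manifest["repertoire_spec"].items()
    }
    (outdir / "cohort_spec.json").write_text(json.dumps(manifest, indent=2, default=str))
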