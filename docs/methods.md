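# Methods

`neocohort` implements the computational core of a cohort-level neoantigen
vaccine profiling workflow for tumors sequenced with paired WES + RNA-seq and
immune-repertoire capture. Upstream primary analysis — read QC, alignment,
variant calling, RNA quantification, HLA typing and clonotype assembly — is
out of scope: the package consumes their outputs (annotated VCFs, a target
BED, transcript models, HLA genotype tables, MiXCR-style clonotype tables)
and produces the cohort-level numbers a vaccine-design study reports.

## Somatic-variant filtering and TMB

Variants are filtered on annotated population allele frequency with a strict
`< 0.001` comparison; variants with *no* recorded population frequency are
retained, because genuinely novel somatic variants are exactly the ones
absent from population databases. Variants are then restricted to the capture
target. BED intervals are 0-based half-open and VCF positions 1-based; the
conversion happens once at the containment check, so 1-based position `end`
is the last base inside an interval `(start, end)`. Overlapping input
intervals are merged before the target size is summed. Multi-allelic VCF
records are split into one variant per ALT at parse time, so "mutated sites"
are counted per alternate allele.

TMB follows the standard panel definition:

    total TMB      = n variants / (target size / 10^6)
    functional TMB = n protein-altering variants / (target size / 10^6)

with "protein-altering" defaulting to {missense, nonsense, frameshift,
inframe indel, splice site, start lost, stop lost}. Both numerators are
counted after the population-frequency filter and the target restriction.

## Mutant proteins and peptide enumeration

`apply_variant` derives the protein effect from the sequences rather than
trusting the annotation. An in-frame substitution is re-translated and
diffed against the reference protein (aligned from both ends, so in-frame
indels mark the whole altered block); synonymous changes and stop gains
yield no mutant residues and are dropped — a stop gain introduces no novel
residue to center a peptide on, although it still counts as functional for
TMB. A frameshift indel is translated in the shifted frame from the first
altered codon onward **through the entire remaining cDNA** — the neo-ORF
ends at the first stop codon, or at the last complete codon of the cDNA when
the shifted frame never hits a stop. Mutant positions for a frameshift are
the contiguous suffix starting at the first altered codon.

Peptide enumeration emits every 8–11-mer window that lies fully inside the
mutant protein and contains at least one mutant residue. For a single
interior mutant site this gives 8+9+10+11 = 38 peptides; the general count
per k is `min(k, p+1, L−p, L−k+1)` (when positive) for a site at index `p`
in a protein of length `L`, and the test suite checks the enumeration
against brute force over the full (L, p) grid.

## Binding scores and expression weighting

Binding prediction sits behind a two-method interface: `score(peptide,
allele) -> float ≥ 0`, higher = stronger, 0 = non-binder.

* The **table adapter** reads a precomputed NetMHCpan-style %rank table and
  maps rank `r` to `max(0, 1 − r/R)` with `R = 2.0` by default (the
  conventional binder cutoff), so non-binders contribute exactly 0. A missing
  (peptide, allele) pair raises — a lookup failure is never a silent zero.
* The **surrogate model** is a pure deterministic function: SHA-256 of
  (seed, allele, peptide) mapped to a uniform variate `u`; the peptide is a
  binder when `u < binder_fraction` and its score is the rescaled conditional
  uniform on `score_range`. It exists so the entire pipeline is testable and
  reproducible without an external predictor, and its binder rate and
  determinism are themselves tested properties.

Because the six class-I alleles of a patient are expressed at very different
levels, per-allele expression measurements (reads or TPM — the normalization
is metric-agnostic) are converted to weights summing to 1 over the six
slots; a homozygous locus reported jointly has its measurement split evenly
between its two identical slots, and zero-expression alleles keep their slot
with weight 0. A peptide's combined score is the expression-weighted sum of
its per-allele scores, falling back to uniform 1/6 weights when expression
is unmeasured. The weighted *sum* (rather than max or unweighted sum) is the
default aggregation because it degrades gracefully to the uniform case and
lets a highly expressed allele dominate exactly in proportion to its
presentation capacity.

## 25-AA neoantigens

Scored peptides above the binder threshold (default 0.01 on the 0–1 score
scale) are clustered by transitive window overlap on protein coordinates.
Each cluster becomes one neoantigen whose sequence is the ≤25-AA window
centered on the cluster's leftmost mutant position (12 flanking residues per
side, truncated at the protein termini — truncation is flagged when a long
frameshift cluster spans more than 25 residues), and

    neoantigen score = (Σ constituent peptide combined scores) × RNA VAF.

A missing RNA VAF is treated as 1.0 with a warning rather than an error, so
DNA-only runs still rank candidates. Multiple variants on one transcript are
applied independently (one mutant protein each); compound haplotypes are not
modelled. Peptides containing unknown residues (X) are dropped before
scoring.

## Cohort peptide bulk (set cover)

The patient × peptide incidence matrix uses exact 25-AA sequence equality as
the sharing identity (a switch allows constituent 8–11-mer identity). HLA
compatibility needs no extra check at cover time: a sequence appears in a
patient's column only if it scored as a candidate *for that patient's
alleles*. Selection is classic greedy set cover — repeatedly take the
peptide covering the most still-uncovered patients — with deterministic tie
breaking (higher total prevalence, then lexicographically smaller sequence).
Patients with zero candidates are reported as uncoverable rather than
failing the run. Per-peptide carrier entropy and pairwise mutual information
are computed as redundancy diagnostics of the candidate columns; the
selection itself is pure greedy, which carries the classical H(d)
approximation guarantee.

A self-contained branch-and-bound exact solver (pivot on the uncovered
patient with fewest options, bound by ⌈uncovered/max-cover⌉) provides the
optimum on small instances. It refuses instances exceeding both its column
and patient limits instead of silently falling back, since its only role is
to be an oracle.

## Repertoire statistics

Clonotype identity is (CDR3aa, V, J); cross-patient *sharing* identity is
the CDR3 amino-acid sequence alone (matching how shared clones are reported
at sequence level), with a strict V/J-matching mode available. Richness is
the raw distinct-clonotype count, without rarefaction or depth
normalization. A CDR3 counts once per patient regardless of read count.
Tumor-specific clones are sequences present in strictly more than
`min_patients` tumors (default 2) and absent from every PBMC sample
cohort-wide. Terminal motifs are positional amino-acid frequencies of the
first and last four residues over distinct CDR3s, with shorter CDR3s
excluded and counted. Richness correlations default to Pearson with the
two-sided t-based p-value (n−2 df), matching R's `cor.test`; Spearman is
available by flag.

## The synthetic cohort generator

The generator produces every input the analyses consume and is a first-class,
tested component, not a fixture. It emulates the statistical shape of a
small (~24-patient) glioma vaccine cohort:

* **Transcripts** — random cDNAs (5'UTR + ATG…stop CDS + 3'UTR), CDS length
  normal around 300 codons (sd 100, floor 30), no internal stops. The 3'UTR
  matters: frameshift neo-ORFs legitimately read into it.
* **Variants** — per-patient site counts Poisson(140) with one designated
  outlier patient scaled ×14, giving a grand mean of ~200 sites/patient and
  one extreme-burden patient; ~5% of variants carry a population AF above
  the filter threshold (germline contamination the filter removes).
  Consequence classes are drawn from a fixed distribution (55% missense, 8%
  frameshift, 14% synonymous, …) and each variant is constructed on the
  actual transcript sequence so the annotated class matches the real protein
  effect. A missense hotspot at codon 132 of a designated gene is planted in
  round(5/24 × n) patients; 10% of sites are drawn from a 300-site recurrent
  pool so a *minority* of sites recur across patients while most remain
  private. RNA VAF is Uniform(0.05, 1.0].
* **Target region** — the transcript contigs plus one zero-variant padding
  interval bringing the target to 50 Mb, the scale of an exome capture, so
  TMB comes out in realistic Muts/Mb.
* **HLA** — two alleles per locus sampled independently from a frequency
  table headed by A\*30:01/A\*11:01, B\*13:02 and C\*06:02; residual
  per-locus mass is spread over rare synthetic alleles. Per-slot expression
  is log-normal (σ = 0.6), aggregated per allele name.
* **Repertoires** — per-sample clonotype richness Poisson around
  compartment × chain means (tumor < PBMC, BCR < TCR), modulated by
  per-patient log-normal abundance factors that couple tumor TCR/BCR
  richness and tumor/PBMC BCR richness (so the reported correlations have
  the right signs). CDR3s start with "CA" with probability 0.9, lengths peak
  at 15 aa, and a per-chain shared pool produces cross-patient sharing. A
  universal clone ("CASSLEETQYF") is planted in every patient's PBMC and
  four tumor-specific clones in 5 carriers each, scrubbed from all PBMC
  samples.
* **Planted cover instances** — patients partitioned into k blocks each
  sharing one block-private peptide, plus patient-private decoys; the exact
  minimum is k by construction, giving the set-cover oracle a ground truth.

Determinism: one global seed fans out to per-component child seeds through a
stable SHA-256 derivation; the same seed yields byte-identical cohorts,
reports and files, across runs and platforms.

What the generator does **not** emulate: sequencing error, alignment
artifacts, subclonal structure, linkage between variants, germline HLA–
population structure, class-II alleles, somatic hypermutation lineages in
BCR, or xCell-style cell-fraction profiles. Passing tests therefore
demonstrate correctness of the *computations* on inputs with the right
marginal shapes, not fidelity of any biological joint distribution.

## Default constants and calibration

Defaults are emulation targets mirroring published cohort summaries, chosen
once: 24 patients; Poisson mean 140 sites with ×14 outlier (grand mean ~200,
outlier >1,000 candidate neoantigens); surrogate `binder_fraction = 0.008`
with binder threshold 0.01, which puts the per-variant candidate probability
near 0.8 and the cohort mean neoantigen count in the ~110 range; recurrent
pool (300 sites at 10%) tuned so very few candidate sequences are shared by
more than two patients and the greedy bulk lands near a dozen peptides for
24 patients. These constants are the *conditions* of the simulation, not
fitted quantities, and the acceptance checks on cohort shape are soft
(logged) except for the non-outlier TMB < 5 Muts/Mb regime.

## Numerical and degenerate-input choices

* Entropy/MI use log₂ with the 0·log 0 = 0 convention; MI is clipped at 0
  against floating-point cancellation.
* All-zero expression measurements are rejected (no information), while any
  positive total is accepted and normalized; weights are validated to sum to
  1 within 1e-9.
* Proteins shorter than 8 residues yield no peptides; an immediate stop at a
  frameshift site yields no mutant protein.
* Greedy cover on an empty matrix returns an empty selection with all
  patients uncovered; `exact_min_cover` of an empty instance is 0.
* Ranked neoantigen output breaks score ties by sequence lexicographic
  order, so reports are stable across platforms.
* Problem sizes in the test and acceptance suites (cohorts of 6–24 patients,
  100-transcript frameshift sweeps, 200 random cover instances, 1,000 score
  recomputations) were chosen to exercise every code path while keeping a
  full run in the tens of seconds.

## Known limitations

* The binding surrogate shares nothing with real MHC binding except the
  interface; absolute neoantigen scores are only meaningful relative to the
  same scorer.
* The 25-AA window centered on the leftmost mutant position can truncate
  long frameshift clusters; the full cluster's peptides still contribute to
  the score, but the reported sequence is a window, not the whole neo-ORF.
* No proteasomal processing, TAP transport, class-II presentation or
  RNA-splicing-derived antigens.
* Richness is depth-sensitive; without rarefaction, comparisons across
  samples of very different sequencing depth conflate depth with diversity.
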