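# neocohort

Cohort-level neoantigen vaccine profiling for tumor sequencing studies:
somatic-variant filtering and tumor mutational burden (TMB), mutant-peptide
design with frameshift neo-ORFs, HLA allele-expression-weighted neoantigen
scoring, minimum vaccine peptide-bulk selection by greedy set cover, and
TCR/BCR repertoire statistics — plus a fully deterministic synthetic-cohort
generator so every stage runs and is testable without access to restricted
patient data.

It is written for computational immunologists assembling a peptide-vaccine
shortlist from paired WES + RNA-seq and immune-repertoire capture of a
small tumor cohort. Upstream primary analysis (alignment, variant calling,
HLA typing, clonotype assembly, NetMHCpan itself) is consumed as input, not
reimplemented.

## The computations

**TMB** — variants with population allele frequency ≥ 0.001 are removed
(novel variants are kept), the rest restricted to the capture target, and

```
total TMB      = n variants / target Mb
functional TMB = n protein-altering variants / target Mb
```

**Neoantigen design** — every somatic variant is applied to its transcript;
for frameshifts the shifted frame is translated from the first altered codon
to the first stop, or to the end of the cDNA if no stop occurs. All 8–11-mer
peptides containing a mutant residue are scored against the patient's six
HLA class-I alleles through a pluggable `score(peptide, allele)` interface
(a NetMHCpan %rank table adapter, or a deterministic surrogate), combined as
the expression-weighted sum over alleles. Intersecting peptides merge into a
≤25-AA neoantigen with

```
score = ( Σ peptide combined scores ) × RNA VAF
```

**Peptide bulk** — a patients × peptides incidence matrix feeds classic
greedy set cover (smallest peptide set giving every patient ≥ 1 candidate),
with carrier entropy / mutual-information diagnostics and a branch-and-bound
exact solver as oracle.

**Repertoire** — clonotype richness, CDR3 length distributions, N-/C-terminal
4-AA motifs, cross-patient sharing spectra, tumor-specific clones
(tumor-not-PBMC in > 2 patients), V×J pairing, and Pearson richness
correlations with `cor.test`-style p-values.

See `docs/methods.md` for the model details and design choices.

## Worked example

Run the full pipeline on the default simulated 24-patient cohort:

```
neocohort run --out run/ --seed 1
# report written to run/report.json: mean neoantigens 114.8, bulk size 10
```

Or stage by stage from Python (see `examples/` for one script per
capability):

```python
from neocohort import CohortSpec, SurrogateBindingModel, design_patient, simulate_cohort

cohort = simulate_cohort(CohortSpec(seed=1))
genotype = next(g for g in cohort.genotypes if g.patient == "P05")
candidates = design_patient(
    cohort.variants["P05"], cohort.transcript_index(), genotype,
    SurrogateBindingModel(seed=1), binder_threshold=0.01,
)
```

`examples/design_neoantigens.py` prints for that patient:

```
P05: 55 candidate neoantigens; top 5 by score

rank    score   vaf peptides  sequence
   1   0.5828  0.88        5  IIRNHIDKCALFVPPHSVAERSESG
   2   0.3261  0.58        3  ARSTTHHVLGCDNLSLIARQHKWPL
   ...
```

Each row is one 25-AA neoantigen: `peptides` counts the 8–11-mers above the
binder threshold that merged into it, `vaf` is the RNA mutation frequency at
the site, and `score` is their summed expression-weighted binding score
times the VAF — the ranking used for the vaccine shortlist.

`examples/select_bulk.py` then covers the cohort:

```
candidate peptides: 2659 across 24 patients
greedy bulk size: 10 (per-step coverage gains [5, 4, 3, 3, 2, 2, 2, 1, 1, 1])
uncovered patients: none
planted instance: exact minimum 11, greedy 11 (construction optimum 11)
```

meaning ten peptides suffice to give each of the 24 simulated patients at
least one candidate neoantigen, and on a planted instance with known optimum
the greedy and exact solvers agree.

The CLI exposes each stage on real inputs too: `neocohort tmb --vcf-dir
vcf/ --bed target.bed --out tmb.tsv`, `neocohort design ...`, `neocohort
select-bulk ...`, `neocohort repertoire ...`.

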