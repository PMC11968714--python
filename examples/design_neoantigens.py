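"""Design ranked 25-AA neoantigens for one patient.

Every somatic variant is applied to its transcript; all 8-11-mer peptides
containing a mutant residue are scored against the patient's six HLA class-I
alleles (expression-weighted sum); peptides above the binder threshold merge
into 25-AA neoantigens scored as sum(peptide scores) x RNA mutation
frequency.
"""

from neocohort import CohortSpec, SurrogateBindingModel, design_patient, simulate_cohort

cohort = simulate_cohort(CohortSpec(seed=1))
patient = "P05"
genotype = next(g for g in cohort.genotypes if g.patient == patient)
scorer = SurrogateBindingModel(seed=1)

candidates = design_patient(
    cohort.variants[patient], cohort.transcript_index(), genotype, scorer,
    binder_threshold=0.01,
)

print(f"{patient}: {len(candidates)} candidate neoantigens; top 5 by score\n")
print(f"{'rank':>4} {'score':>8} {'vaf':>5} {'peptides':>8}  sequence")
for i, neo in enumerate(candidates[:5], start=1):
    print(f"{i:>4} {neo.score:>8.4f} {neo.rna_vaf:>5.2f} "
          f"{len(neo.constituent_peptides):>8}  {neo.sequence}")
# score = (sum of the constituent peptides' expression-weighted binding
# scores) x the RNA VAF at the site; higher VAF and more/stronger binding
# peptides push a neoantigen up the vaccine shortlist.
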