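"""Variant application, peptide enumeration, scoring and 25-AA merging."""

import logging

import numpy as np
import pytest

from neocohort.binding import SurrogateBindingModel
from neocohort.design import (
    MutantPeptide,
    apply_variant,
    design_patient,
    enumerate_peptides,
    merge_neoantigens,
    score_peptide,
)
from neocohort.hla import parse_genotype
from neocohort.transcripts import Transcript
from neocohort.variants import SomaticVariant

from conftest import CODON_TABLE, oracle_translate

GENOTYPE = parse_genotype(
    "P01", ["A*30:01", "A*11:01", "B*13:02", "B*40:01", "C*06:02", "C*07:02"]
)


def make_transcript(n_codons=100, seed=0, utr5=20, utr3=60):
    """A transcript with a known random CDS of ``n_codons`` (incl. stop)."""
    rng = np.random.default_rng(seed)
    nonstop = [c for c, aa in CODON_TABLE.items() if aa != "*"]
    cds = "ATG" + "".join(rng.choice(nonstop, size=n_codons - 2)) + "TAA"
    flank5 = "".join(rng.choice(list("ACGT"), size=utr5))
    flank3 = "".join(rng.choice(list("ACGT"), size=utr3))
    return Transcript(
        transcript_id="TX1", gene="G1", cdna=flank5 + cds + flank3,
        cds_start=utr5, cds_end=utr5 + 3 * n_codons,
    )


def snv_variant(tx, cdna_index, alt, csq="missense"):
    return SomaticVariant(
        chrom=tx.transcript_id, pos=cdna_index + 1, ref=tx.cdna[cdna_index], alt=alt,
        consequence_class=csq, rna_vaf=0.5,
    )


class TestApplyVariant:
    def test_missense_single_substitution(self):
        tx = make_transcript(100, seed=1)
        # substitute the 2nd base of codon 50 to force a non-synonymous change
        idx = tx.cds_start + 3 * 49 + 1
        ref_codon = tx.cdna[tx.cds_start + 3 * 49 : tx.cds_start + 3 * 49 + 3]
        alt = next(
            b for b in "ACGT"
            if b != tx.cdna[idx]
            and CODON_TABLE[ref_codon[0] + b + ref_codon[2]] not in ("*", CODON_TABLE[ref_codon])
        )
        mp = apply_variant(tx, snv_variant(tx, idx, alt))
        assert mp is not None and not mp.frameshift
        assert len(mp.sequence) == 99  # stop codon not part of the protein
        assert mp.mutant_positions == (49,)
        assert mp.sequence[:49] == tx.protein[:49]
        assert mp.sequence[50:] == tx.protein[50:]
        assert mp.sequence[49] != tx.protein[49]

    def test_synonymous_yields_no_protein(self):
        tx = make_transcript(60, seed=2)
        # find a codon with a synonymous 3rd-base change
        for codon in range(2, 59):
            start = tx.cds_start + 3 * (codon - 1)
            c = tx.cdna[start : start + 3]
            for b in "ACGT":
                if b != c[2] and CODON_TABLE[c[:2] + b] == CODON_TABLE[c]:
                    assert apply_variant(tx, snv_variant(tx, start + 2, b, "synonymous")) is None
                    return
        pytest.skip("no synonymous site in this CDS")

    def test_stop_gain_yields_no_protein(self):
        tx = make_transcript(60, seed=3)
        for codon in range(2, 59):
            start = tx.cds_start + 3 * (codon - 1)
            c = tx.cdna[start : start + 3]
            for off in range(3):
                for b in "ACGT":
                    mutant = c[:off] + b + c[off + 1 :]
                    if b != c[off] and CODON_TABLE[mutant] == "*":
                        assert apply_variant(tx, snv_variant(tx, start + off, b, "nonsense")) is None
                        return
        pytest.skip("no nonsense site in this CDS")

    def test_frameshift_against_independent_oracle(self):
        tx = make_transcript(80, seed=4)
        # 1-bp insertion inside codon 10
        anchor = tx.cds_start + 3 * 9
        variant = SomaticVariant(
            chrom="TX1", pos=anchor + 1, ref=tx.cdna[anchor], alt=tx.cdna[anchor] + "G",
            consequence_class="frameshift", rna_vaf=0.5,
        )
        mp = apply_variant(tx, variant)
        assert mp is not None and mp.frameshift
        mutant_cdna = tx.cdna[: anchor + 1] + "G" + tx.cdna[anchor + 1 :]
        tail = oracle_translate(mutant_cdna[tx.cds_start + 3 * 9 :])
        assert mp.sequence == tx.protein[:9] + tail
        assert mp.mutant_positions == tuple(range(9, len(mp.sequence)))

    def test_frameshift_without_stop_runs_to_last_complete_codon(self):
        # construct a cDNA whose shifted frame contains no stop codon at all
        cds = "ATG" + "AAA" * 20 + "TAA"
        tx = Transcript("TX1", "G1", cdna=cds + "AAAAAAA", cds_start=0, cds_end=len(cds))
        variant = SomaticVariant(
            chrom="TX1", pos=4, ref="A", alt="AG", consequence_class="frameshift", rna_vaf=0.5
        )
        mp = apply_variant(tx, variant)
        mutant = tx.cdna[:4] + "G" + tx.cdna[4:]
        expected_tail = oracle_translate(mutant[3:])
        # oracle confirms no stop is reached and translation ends on a full codon
        assert mp.sequence == "M" + expected_tail
        assert len(mp.sequence) == 1 + (len(mutant) - 3) // 3

    def test_reference_mismatch_raises(self):
        tx = make_transcript(50, seed=5)
        idx = tx.cds_start + 10
        wrong_ref = next(b for b in "ACGT" if b != tx.cdna[idx])
        alt = next(b for b in "ACGT" if b not in (wrong_ref, tx.cdna[idx]))
        bad = SomaticVariant(chrom="TX1", pos=idx + 1, ref=wrong_ref, alt=alt,
                             consequence_class="missense")
        with pytest.raises(ValueError, match="reference mismatch"):
            apply_variant(tx, bad)

    def test_utr_variant_skipped(self):
        tx = make_transcript(50, seed=6)
        assert apply_variant(tx, snv_variant(tx, 2, "A" if tx.cdna[2] != "A" else "C",
                                             "noncoding")) is None


def brute_force_windows(L, mutant_positions, k_range=(8, 9, 10, 11)):
    wins = []
    for start in range(L):
        for k in k_range:
            if start + k <= L and any(start <= p < start + k for p in mutant_positions):
                wins.append((start, k))
    return wins


class TestEnumeratePeptides:
    def _protein(self, L, positions, frameshift=False):
        seq = "A" * L
        v = SomaticVariant(chrom="TX1", pos=1, ref="A", alt="G", consequence_class="missense")
        from neocohort.design import MutantProtein

        return MutantProtein("TX1", seq, tuple(sorted(positions)), v, frameshift=frameshift)

    def test_interior_site_yields_38(self):
        mp = self._protein(40, {20})
        assert len(enumerate_peptides(mp)) == 8 + 9 + 10 + 11

    def test_terminal_site_yields_4(self):
        mp = self._protein(30, {0})
        peps = enumerate_peptides(mp)
        assert len(peps) == 4
        assert all(p.protein_start == 0 for p in peps)

    def test_matches_bruteforce_on_random_cases(self, rng):
        for _ in range(50):
            L = int(rng.integers(8, 60))
            n_mut = int(rng.integers(1, 4))
            positions = set(int(p) for p in rng.choice(L, size=n_mut, replace=False))
            peps = enumerate_peptides(self._protein(L, positions))
            assert [(p.protein_start, len(p.sequence)) for p in peps] == sorted(
                brute_force_windows(L, positions)
            )

    def test_frameshift_suffix_matches_bruteforce(self):
        L, first = 60, 40
        mp = self._protein(L, set(range(first, L)), frameshift=True)
        peps = enumerate_peptides(mp)
        assert [(p.protein_start, len(p.sequence)) for p in peps] == sorted(
            brute_force_windows(L, range(first, L))
        )

    def test_short_protein_empty(self):
        mp = self._protein(7, {3})
        assert enumerate_peptides(mp) == []

    def test_every_peptide_contains_a_mutant_residue(self, rng):
        # mark the mutant site with a distinct residue and check sequences
        from neocohort.design import MutantProtein

        L, p = 35, 17
        seq = "A" * p + "W" + "A" * (L - p - 1)
        v = SomaticVariant(chrom="TX1", pos=1, ref="A", alt="G", consequence_class="missense")
        mp = MutantProtein("TX1", seq, (p,), v)
        for pep in enumerate_peptides(mp):
            assert "W" in pep.sequence


class TestScorePeptide:
    def _peptide(self):
        return MutantPeptide(sequence="ACDEFGHIK", protein_start=0,
                             covered_mutant_positions=(4,))

    def test_uniform_weights_average(self):
        class Const:
            def score(self, peptide, allele):
                return 1.0

        scored = score_peptide(self._peptide(), GENOTYPE, Const())
        assert scored.combined_score == pytest.approx(1.0)

    def test_single_allele_contribution(self):
        class OneHot:
            def score(self, peptide, allele):
                return 6.0 if allele == "A*11:01" else 0.0

        scored = score_peptide(self._peptide(), GENOTYPE, OneHot())
        assert scored.combined_score == pytest.approx(1.0)

    def test_matches_dot_product_oracle(self, rng):
        for _ in range(50):
            scores = {a.name: float(rng.random()) for a in GENOTYPE.alleles}
            weights = rng.dirichlet(np.ones(6))
            genotype = GENOTYPE.with_weights(weights)

            class Lookup:
                def score(self, peptide, allele):
                    return scores[allele]

            scored = score_peptide(self._peptide(), genotype, Lookup())
            expected = float(np.dot(weights, [scores[a.name] for a in GENOTYPE.alleles]))
            assert scored.combined_score == pytest.approx(expected, rel=1e-12)

    def test_negative_scorer_rejected(self):
        class Bad:
            def score(self, peptide, allele):
                return -1.0

        with pytest.raises(ValueError, match="negative"):
            score_peptide(self._peptide(), GENOTYPE, Bad())


def scored_peptide(seq, start, positions, score):
    return MutantPeptide(sequence=seq, protein_start=start,
                         covered_mutant_positions=tuple(positions),
                         combined_score=score)


class TestMergeNeoantigens:
    def _protein(self, L=100, positions=(50,), frameshift=False):
        from neocohort.design import MutantProtein

        v = SomaticVariant(chrom="TX1", pos=1, ref="A", alt="G",
                           consequence_class="missense", rna_vaf=0.4)
        return MutantProtein("TX1", "A" * L, tuple(sorted(positions)), v,
                             frameshift=frameshift)

    def test_single_cluster_score_formula(self):
        mp = self._protein(100, (50,))
        peps = [p for p in enumerate_peptides(mp)]
        peps = [scored_peptide(p.sequence, p.protein_start, p.covered_mutant_positions, 0.1)
                for p in peps]
        assert len(peps) == 38
        neos = merge_neoantigens(peps, mp)
        assert len(neos) == 1
        assert neos[0].score == pytest.approx(38 * 0.1 * 0.4)
        assert len(neos[0].sequence) == 25  # centered window, 12 each side

    def test_nonoverlapping_windows_stay_separate(self):
        mp = self._protein(200, tuple(range(20, 200)), frameshift=True)
        a = scored_peptide("A" * 8, 20, (20,), 1.0)
        b = scored_peptide("A" * 8, 100, (100,), 1.0)
        neos = merge_neoantigens([a, b], mp)
        assert len(neos) == 2

    def test_cluster_membership_matches_naive_transitive_closure(self, rng):
        mp = self._protein(300, tuple(range(0, 300)), frameshift=False)
        for _ in range(30):
            peps = []
            for _ in range(int(rng.integers(2, 15))):
                start = int(rng.integers(0, 280))
                k = int(rng.integers(8, 12))
                peps.append(scored_peptide("A" * k, start, (start,), float(rng.random())))
            neos = merge_neoantigens(peps, mp)
            # naive union-find over pairwise window overlap
            n = len(peps)
            parent = list(range(n))

            def find(i):
                while parent[i] != i:
                    i = parent[i]
                return i

            for i in range(n):
                for j in range(i + 1, n):
                    a, b = peps[i], peps[j]
                    if a.protein_start < b.end and b.protein_start < a.end:
                        parent[find(i)] = find(j)
            expected_clusters = len({find(i) for i in range(n)})
            assert len(neos) == expected_clusters
            total = sum(p.combined_score for p in peps) * 0.4
            assert sum(n_.score for n_ in neos) == pytest.approx(total, rel=1e-12)

    def test_missing_vaf_defaults_to_one_with_warning(self, caplog):
        from neocohort.design import MutantProtein

        v = SomaticVariant(chrom="TX1", pos=1, ref="A", alt="G",
                           consequence_class="missense", rna_vaf=None)
        mp = MutantProtein("TX1", "A" * 50, (25,), v)
        pep = scored_peptide("A" * 9, 21, (25,), 2.0)
        with caplog.at_level(logging.WARNING, logger="neocohort.design"):
            neos = merge_neoantigens([pep], mp)
        assert neos[0].score == pytest.approx(2.0)
        assert any("VAF" in rec.message for rec in caplog.records)


class TestDesignPatient:
    def _bundle(self):
        tx = make_transcript(120, seed=9)
        rng = np.random.default_rng(42)
        variants = []
        for codon in (20, 50, 80):
            start = tx.cds_start + 3 * (codon - 1)
            c = tx.cdna[start : start + 3]
            for off in range(3):
                for b in "ACGT":
                    mut = c[:off] + b + c[off + 1 :]
                    if b != c[off] and CODON_TABLE[mut] not in ("*", CODON_TABLE[c]):
                        variants.append(snv_variant(tx, start + off, b))
                        break
                else:
                    continue
                break
        return variants, {tx.transcript_id: tx}

    def test_infinite_threshold_empty(self):
        variants, txs = self._bundle()
        scorer = SurrogateBindingModel(seed=0, binder_fraction=0.5)
        out = design_patient(variants, txs, GENOTYPE, scorer, binder_threshold=float("inf"))
        assert out == []

    def test_deterministic_ranked_output(self):
        variants, txs = self._bundle()
        scorer = SurrogateBindingModel(seed=0, binder_fraction=0.5)
        a = design_patient(variants, txs, GENOTYPE, scorer, binder_threshold=0.0)
        b = design_patient(variants, txs, GENOTYPE, scorer, binder_threshold=0.0)
        assert a == b
        assert [n.score for n in a] == sorted((n.score for n in a), reverse=True)

    def test_raising_a_peptide_score_never_lowers_its_rank(self):
        variants, txs = self._bundle()
        base = SurrogateBindingModel(seed=0, binder_fraction=0.5)
        ranked = design_patient(variants, txs, GENOTYPE, base, binder_threshold=0.0)
        assert len(ranked) >= 2
        target = ranked[1]  # boost the runner-up's constituent peptides
        boosted_seqs = {p.sequence for p in target.constituent_peptides}

        class Boosted:
            def score(self, peptide, allele):
                s = base.score(peptide, allele)
                return s + 10.0 if peptide in boosted_seqs else s

        reranked = design_patient(variants, txs, GENOTYPE, Boosted(), binder_threshold=0.0)
        new_rank = next(i for i, n in enumerate(reranked) if n.variant == target.variant
                        and n.sequence == target.sequence)
        assert new_rank <= 1
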