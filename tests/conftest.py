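"""Shared fixtures and independent oracles.

The translation oracle here is deliberately independent of the package's
translation path: it uses the classic 64-character genetic-code string rather
than any sequence library, so frameshift and CDS checks compare two unrelated
implementations.
"""

from __future__ import annotations

import numpy as np
import pytest

from neocohort.synthetic import CohortSpec, RepertoireSpec, generate_reference_transcripts

# standard genetic code, codons ordered T/C/A/G by position
_BASES = "TCAG"
_AMINO = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def oracle_translate(nt: str, stop_at_stop: bool = True) -> str:
    """Frame-0 translation over complete codons, independent of Biopython."""
    aa = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        residue = CODON_TABLE[nt[i : i + 3]]
        if residue == "*" and stop_at_stop:
            break
        aa.append(residue)
    return "".join(aa)


@pytest.fixture(scope="session")
def transcripts5():
    return generate_reference_transcripts(5, length_dist=(100.0, 20.0), seed=7)


@pytest.fixture(scope="session")
def small_spec():
    """A reduced cohort for fast pipeline-level tests."""
    return CohortSpec(
        n_patients=6,
        mean_sites_per_patient=30.0,
        outlier_patient_factor=3.0,
        hotspot_spec=(("IDH1_like:20", 2 / 6),),
        seed=11,
        n_transcripts=40,
        transcript_length=(120.0, 30.0),
        target_size_bp=5_000_000,
        repertoire_spec=RepertoireSpec(
            mean_clonotypes={
                ("tumor", "TRB"): 60, ("PBMC", "TRB"): 90,
                ("tumor", "IGH"): 30, ("PBMC", "IGH"): 50,
            },
            shared_pool_size=80,
            tumor_specific_clones=(
                ("CASSPGQGAYEQYF", "TRB", 3),
                ("CASSFGRETQYF", "TRB", 3),
            ),
        ),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
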