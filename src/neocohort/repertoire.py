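"""TCR/BCR repertoire descriptive statistics over clonotype tables.

The in-memory container is a pandas DataFrame with one row per clonotype and
columns ``patient, compartment, chain, cdr3aa, vGene, jGene, count``
(MiXCR-style export; compartments are tumor / PBMC, chains TRB / IGH).
Clonotype identity is (cdr3aa, vGene, jGene); cross-patient sharing identity
is the CDR3 amino-acid sequence alone unless ``strict`` V/J matching is
requested.

Statistics: richness (distinct clonotypes), CDR3 length distributions,
N-/C-terminal 4-AA positional motifs, cross-patient sharing spectra,
tumor-specific clonotypes (present in more than ``min_patients`` tumors and
in no PBMC sample), V x J pairing matrices, and Pearson/Spearman richness
correlations with the classical t-based p-value.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "REQUIRED_COLUMNS",
    "validate_clonotypes",
    "richness",
    "richness_table",
    "length_distribution",
    "sharing_spectrum",
    "tumor_specific",
    "terminal_motifs",
    "vj_pairing",
    "richness_correlation",
]

REQUIRED_COLUMNS = ("patient", "compartment", "chain", "cdr3aa", "vGene", "jGene", "count")
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
COMPARTMENTS = ("tumor", "PBMC")
CHAINS = ("TRB", "IGH")


def validate_clonotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Check schema and clonotype validity; returns the (unmodified) frame."""
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"clonotype table missing columns: {sorted(missing)}")
    if (df["count"] < 1).any():
        raise ValueError("clonotype counts must be >= 1")
    bad = df.loc[~df["cdr3aa"].str.fullmatch(f"[{AA_ALPHABET}]+"), "cdr3aa"]
    if len(bad):
        raise ValueError(f"invalid CDR3 amino-acid sequence(s): {bad.head().tolist()}")
    keys = df[["patient", "compartment", "chain", "cdr3aa", "vGene", "jGene"]]
    if keys.duplicated().any():
        raise ValueError("duplicate clonotype keys within a sample")
    return df


def _subset(df: pd.DataFrame, compartment: str | None = None, chain: str | None = None) -> pd.DataFrame:
    if compartment is not None:
        df = df[df["compartment"] == compartment]
    if chain is not None:
        df = df[df["chain"] == chain]
    return df


def richness(df: pd.DataFrame) -> int:
    """Distinct clonotypes (cdr3aa, vGene, jGene) in one sample's rows."""
    return len(df[["cdr3aa", "vGene", "jGene"]].drop_duplicates())


def richness_table(df: pd.DataFrame) -> pd.DataFrame:
    """Richness per (patient, compartment, chain)."""
    return (
        df.groupby(["patient", "compartment", "chain"], as_index=False)
        .apply(lambda g: pd.Series({"richness": richness(g)}), include_groups=False)
        .reset_index(drop=True)
    )


def length_distribution(df: pd.DataFrame, normalize: bool = False) -> pd.DataFrame:
    """CDR3 AA-length histogram per (compartment, chain).

    Counts distinct CDR3 sequences; when ``normalize`` the frequencies sum to
    1 within each group.
    """
    work = df[["compartment", "chain", "cdr3aa"]].drop_duplicates()
    work = work.assign(length=work["cdr3aa"].str.len())
    table = (
        work.groupby(["compartment", "chain", "length"]).size().rename("count").reset_index()
    )
    if normalize:
        table["frequency"] = table.groupby(["compartment", "chain"])["count"].transform(
            lambda c: c / c.sum()
        )
    return table


def sharing_spectrum(
    df: pd.DataFrame, compartment: str, chain: str, strict: bool = False
) -> tuple[dict[int, float], pd.DataFrame]:
    """Cross-patient sharing of CDR3s within one compartment x chain.

    Each distinct CDR3 (or (CDR3, V, J) when ``strict``) counts once per
    patient regardless of read count.  Returns ``(spectrum, carriers)`` where
    spectrum maps number-of-carrying-patients -> fraction of distinct CDR3s,
    and carriers lists each sequence with its patient count.
    """
    sub = _subset(df, compartment, chain)
    if sub["patient"].nunique() < 2:
        raise ValueError("sharing spectrum needs >= 2 patients")
    key = ["cdr3aa", "vGene", "jGene"] if strict else ["cdr3aa"]
    carriers = (
        sub[key + ["patient"]].drop_duplicates().groupby(key)["patient"]
        .agg(n_patients="nunique", patients=lambda s: sorted(set(s)))
        .reset_index()
    )
    total = len(carriers)
    spectrum = (carriers["n_patients"].value_counts() / total).sort_index().to_dict()
    return {int(k): float(v) for k, v in spectrum.items()}, carriers


def tumor_specific(df: pd.DataFrame, chain: str, min_patients: int = 2) -> pd.DataFrame:
    """CDR3s found in more than ``min_patients`` tumors and in no PBMC sample.

    The PBMC exclusion is cohort-wide and strict: a sequence seen in even one
    patient's PBMC is removed.  Returns sequence + tumor carrier count.
    """
    tumor = _subset(df, "tumor", chain)
    pbmc_seqs = set(_subset(df, "PBMC", chain)["cdr3aa"])
    carriers = (
        tumor[["cdr3aa", "patient"]].drop_duplicates().groupby("cdr3aa")["patient"]
        .agg(n_tumor_patients="nunique", patients=lambda s: sorted(set(s)))
        .reset_index()
    )
    out = carriers[
        (carriers["n_tumor_patients"] > min_patients) & ~carriers["cdr3aa"].isin(pbmc_seqs)
    ]
    return out.sort_values(["n_tumor_patients", "cdr3aa"], ascending=[False, True]).reset_index(
        drop=True
    )


def terminal_motifs(
    df: pd.DataFrame, n_terminal: int = 4
) -> tuple[dict[str, pd.DataFrame], int]:
    """Positional AA frequencies of the first/last ``n_terminal`` residues.

    Returns ``({"N": frame, "C": frame}, n_excluded)`` where each frame is
    position (1-based from the respective end) x amino acid with rows summing
    to 1, over distinct CDR3 sequences; CDR3s shorter than ``n_terminal`` are
    excluded and counted.
    """
    seqs = df["cdr3aa"].drop_duplicates()
    usable = seqs[seqs.str.len() >= n_terminal]
    n_excluded = len(seqs) - len(usable)
    if usable.empty:
        raise ValueError(f"no CDR3 of length >= {n_terminal}")
    out = {}
    for end, extract in (("N", lambda s, i: s[i]), ("C", lambda s, i: s[len(s) - n_terminal + i])):
        rows = []
        for i in range(n_terminal):
            counts = usable.map(lambda s: extract(s, i)).value_counts()
            freqs = counts / counts.sum()
            rows.append(freqs.reindex(list(AA_ALPHABET), fill_value=0.0))
        frame = pd.DataFrame(rows, index=range(1, n_terminal + 1))
        frame.index.name = "position"
        out[end] = frame
    return out, n_excluded


def vj_pairing(
    df: pd.DataFrame,
    compartment: str | None = None,
    chain: str | None = None,
    weight: str = "clonotypes",
) -> pd.DataFrame:
    """V x J usage matrix; cells count clonotypes (default) or reads."""
    if weight not in {"clonotypes", "reads"}:
        raise ValueError(f"weight must be 'clonotypes' or 'reads', got {weight!r}")
    sub = _subset(df, compartment, chain)
    if (sub["vGene"].eq("") | sub["jGene"].eq("")).any():
        raise ValueError("empty V/J gene name")
    values = sub["count"] if weight == "reads" else pd.Series(1, index=sub.index)
    return (
        sub.assign(_w=values)
        .pivot_table(index="vGene", columns="jGene", values="_w", aggfunc="sum", fill_value=0)
        .astype(int)
    )


def richness_correlation(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> tuple[float, float]:
    """Correlation of two per-patient richness vectors with a two-sided p.

    Pearson by default (the p-value comes from the t distribution with n-2
    degrees of freedom, as R's ``cor.test``); Spearman available.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values in richness vectors")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)
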