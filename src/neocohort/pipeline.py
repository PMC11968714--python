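"""End-to-end cohort runs: simulate -> tmb -> design -> select-bulk -> repertoire.

Each stage writes plain-text outputs (TSV/JSON) under the run directory and
is skipped on resume when its outputs already exist.  The final cohort report
is a single JSON with per-patient TMB and neoantigen counts, the bulk
selection, repertoire summaries and a provenance block (config hash + seed);
identical config and seed give a byte-identical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .binding import SurrogateBindingModel
from .cover import build_matrix, greedy_cover, peptide_entropy
from .design import design_patient
from .repertoire import (
    length_distribution,
    richness_table,
    richness_correlation,
    sharing_spectrum,
    tumor_specific,
)
from .synthetic import Cohort, CohortSpec, simulate_cohort
from .tmb import tmb_table

__all__ = ["RunConfig", "run_pipeline", "neoantigen_table"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    outdir: str
    seed: int = 0
    af_threshold: float = 0.001
    binder_threshold: float = 0.01
    binder_fraction: float = 0.008
    k_range: tuple = (8, 9, 10, 11)
    sharing_threshold: int = 2
    top_n: int = 20
    cohort_overrides: dict = field(default_factory=dict)
    resume: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.af_threshold <= 1:
            raise ValueError("af_threshold must be in (0,1]")
        if self.binder_threshold < 0:
            raise ValueError("binder_threshold must be nonnegative")
        if any(not 8 <= k <= 11 for k in self.k_range):
            raise ValueError("k_range must lie within 8..11")
        if self.sharing_threshold < 0:
            raise ValueError("sharing_threshold must be nonnegative")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "k_range" in data:
            data["k_range"] = tuple(data["k_range"])
        return cls(**data)

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(seed=self.seed, **self.cohort_overrides)

    def digest(self) -> str:
        """Hash of the scientific configuration (output path and resume flag
        excluded: they do not affect any computed number)."""
        payload = asdict(self)
        payload.pop("outdir")
        payload.pop("resume")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def neoantigen_table(candidates) -> pd.DataFrame:
    rows = [
        {
            "rank": i + 1,
            "sequence": n.sequence,
            "gene": n.gene,
            "variant": n.variant,
            "n_peptides": len(n.constituent_peptides),
            "vaf": n.rna_vaf,
            "score": n.score,
        }
        for i, n in enumerate(candidates)
    ]
    return pd.DataFrame(
        rows, columns=["rank", "sequence", "gene", "variant", "n_peptides", "vaf", "score"]
    )


def _stage_fresh(path: Path, resume: bool) -> bool:
    return not (resume and path.exists())


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and return the cohort report (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = config.cohort_spec()

    # stage: simulate (always recomputed in memory — the seed pins it exactly;
    # the on-disk copy is only rewritten when absent or not resuming)
    logger.info("stage simulate: %d patients, seed %d", spec.n_patients, spec.seed)
    from .synthetic import write_cohort

    sim_dir = outdir / "simulate"
    cohort: Cohort = simulate_cohort(spec)
    if _stage_fresh(sim_dir / "cohort_spec.json", config.resume):
        write_cohort(cohort, sim_dir)

    # stage: tmb
    tmb_path = outdir / "tmb.tsv"
    if _stage_fresh(tmb_path, config.resume):
        logger.info("stage tmb")
        tmb = tmb_table(cohort.variants, cohort.target_region, config.af_threshold)
        tmb.to_csv(tmb_path, sep="\t", index=False, float_format="%.6g")
    tmb = pd.read_csv(tmb_path, sep="\t")

    # stage: design
    neo_dir = outdir / "neo"
    neo_dir.mkdir(exist_ok=True)
    scorer = SurrogateBindingModel(seed=config.seed, binder_fraction=config.binder_fraction)
    tx_index = cohort.transcript_index()
    genotype_of = {g.patient: g for g in cohort.genotypes}
    per_patient_sequences: dict[str, list[str]] = {}
    neo_counts: dict[str, int] = {}
    for patient in spec.patients():
        path = neo_dir / f"{patient}.neo.tsv"
        if _stage_fresh(path, config.resume):
            candidates = design_patient(
                cohort.variants[patient],
                tx_index,
                genotype_of[patient],
                scorer,
                binder_threshold=config.binder_threshold,
                k_range=config.k_range,
            )
            neoantigen_table(candidates).to_csv(path, sep="\t", index=False, float_format="%.8g")
        table = pd.read_csv(path, sep="\t")
        per_patient_sequences[patient] = [] if table.empty else table["sequence"].tolist()
        neo_counts[patient] = len(table)
    logger.info("stage design: mean candidates %.1f", sum(neo_counts.values()) / len(neo_counts))

    # stage: select-bulk
    bulk_path = outdir / "bulk.json"
    if _stage_fresh(bulk_path, config.resume):
        logger.info("stage select-bulk")
        matrix = build_matrix(per_patient_sequences)
        selection = greedy_cover(matrix)
        entropy = peptide_entropy(matrix)
        carriers = matrix.incidence.sum(axis=0)
        sharing = pd.DataFrame(
            {
                "sequence": matrix.peptides,
                "n_patients": carriers,
                "entropy_bits": [entropy[p] for p in matrix.peptides],
            }
        ).sort_values(["n_patients", "sequence"], ascending=[False, True])
        sharing.to_csv(outdir / "neo_sharing.tsv", sep="\t", index=False, float_format="%.6g")
        bulk = {
            "selected": list(selection.selected),
            "per_step_gain": list(selection.per_step_gain),
            "covered": sorted(selection.covered),
            "uncovered": sorted(selection.uncovered),
            "size": selection.size,
            "n_candidate_peptides": len(matrix.peptides),
            "n_shared_gt": {
                str(config.sharing_threshold): int((carriers > config.sharing_threshold).sum())
            },
        }
        bulk_path.write_text(json.dumps(bulk, indent=2))
    bulk = json.loads(bulk_path.read_text())

    # stage: repertoire
    rep_path = outdir / "repertoire_summary.json"
    if _stage_fresh(rep_path, config.resume):
        logger.info("stage repertoire")
        df = cohort.clonotypes
        rich = richness_table(df)
        rich.to_csv(outdir / "richness.tsv", sep="\t", index=False)
        length_distribution(df, normalize=True).to_csv(
            outdir / "cdr3_lengths.tsv", sep="\t", index=False, float_format="%.6g"
        )
        summary: dict = {"sharing": {}, "tumor_specific": {}, "correlations": {}}
        for chain in ("TRB", "IGH"):
            for compartment in ("tumor", "PBMC"):
                spectrum, _ = sharing_spectrum(df, compartment, chain)
                shared_frac = sum(
                    frac for n, frac in spectrum.items() if n > config.sharing_threshold
                )
                summary["sharing"][f"{chain}_{compartment}"] = {
                    "fraction_shared": shared_frac,
                    "spectrum": {str(k): v for k, v in sorted(spectrum.items())},
                }
            ts = tumor_specific(df, chain, min_patients=config.sharing_threshold)
            summary["tumor_specific"][chain] = {
                "n_sequences": int(len(ts)),
                "max_carriers": int(ts["n_tumor_patients"].max()) if len(ts) else 0,
            }
        wide = rich.pivot_table(
            index="patient", columns=["compartment", "chain"], values="richness"
        )
        pairs = {
            "IGH_tumor_vs_PBMC": (("tumor", "IGH"), ("PBMC", "IGH")),
            "TRB_tumor_vs_PBMC": (("tumor", "TRB"), ("PBMC", "TRB")),
            "tumor_TRB_vs_IGH": (("tumor", "TRB"), ("tumor", "IGH")),
        }
        for name, (a, b) in pairs.items():
            r, p = richness_correlation(wide[a], wide[b])
            summary["correlations"][name] = {"r": round(r, 6), "p_value": round(p, 6)}
        rep_path.write_text(json.dumps(summary, indent=2))
    rep_summary = json.loads(rep_path.read_text())

    report = {
        "provenance": {
            "config_digest": config.digest(),
            "seed": config.seed,
            "n_patients": spec.n_patients,
        },
        "tmb": tmb.to_dict(orient="records"),
        "neoantigen_counts": neo_counts,
        "mean_neoantigens": sum(neo_counts.values()) / len(neo_counts),
        "bulk": bulk,
        "repertoire": rep_summary,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report
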