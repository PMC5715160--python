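"""Plain-text serialization of cohorts, panels and scenario configs.

Everything is tab-delimited text: dosage matrices (subjects x variants,
header row of variant ids), phenotype tables keyed by subject id, variant
annotation tables, and a ``key: value`` scenario config capturing every
simulation parameter including the seed. VCF ingestion is limited to
extracting per-genotype dosages (``DS`` format field, falling back to hard
genotype counts) for cohort construction.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CohortData
from .synthetic_data import ScenarioSpec

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_scenario_config",
    "read_scenario_config",
    "read_vcf_dosages",
]


def write_cohort(cohort: CohortData, outdir: str | Path, prefix: str = "cohort") -> None:
    """Write dosage, phenotype and variant tables for one cohort."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dos = pd.DataFrame(cohort.dosages, columns=cohort.variant_ids)
    dos.insert(0, "subject_id", [f"S{i + 1}" for i in range(cohort.n_subjects)])
    dos.to_csv(outdir / f"{prefix}.dosages.tsv", sep="\t", index=False)

    pheno = cohort.phenotypes.copy()
    pheno.insert(0, "subject_id", [f"S{i + 1}" for i in range(cohort.n_subjects)])
    pheno.to_csv(outdir / f"{prefix}.phenotypes.tsv", sep="\t", index=False, na_rep="NA")

    cohort.variants.to_csv(outdir / f"{prefix}.variants.tsv", sep="\t", index=False)


def read_cohort(outdir: str | Path, prefix: str = "cohort") -> CohortData:
    """Read a cohort written by :func:`write_cohort`."""
    outdir = Path(outdir)
    dos = pd.read_csv(outdir / f"{prefix}.dosages.tsv", sep="\t", comment="#")
    pheno = pd.read_csv(
        outdir / f"{prefix}.phenotypes.tsv", sep="\t", comment="#", na_values=["NA"]
    )
    variants = pd.read_csv(
        outdir / f"{prefix}.variants.tsv", sep="\t", comment="#", dtype={"chr": str}
    )
    if not (dos["subject_id"] == pheno["subject_id"]).all():
        raise ValueError("dosage and phenotype subject ids disagree")
    variant_ids = [c for c in dos.columns if c != "subject_id"]
    return CohortData(
        dosages=dos[variant_ids].to_numpy(dtype=float),
        variant_ids=variant_ids,
        variants=variants,
        phenotypes=pheno.drop(columns=["subject_id"]),
    )


def write_scenario_config(scenario: ScenarioSpec, path: str | Path) -> None:
    """Write a scenario as ``key: value`` lines (one per field)."""
    lines = [f"{k}: {v}" for k, v in asdict(scenario).items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_scenario_config(path: str | Path) -> ScenarioSpec:
    """Read a ``key: value`` scenario config back into a ScenarioSpec."""
    kwargs: dict = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        key = key.strip()
        value = value.strip()
        if key == "model":
            kwargs[key] = value
        elif key in (
            "n_nd_causal",
            "n_direct_lf_causal",
            "n_subjects_per_cohort",
            "seed",
            "architecture_seed",
        ):
            kwargs[key] = int(value)
        else:
            kwargs[key] = float(value)
    return ScenarioSpec(**kwargs)


def read_vcf_dosages(path: str | Path) -> tuple[np.ndarray, pd.DataFrame]:
    """Extract per-subject dosages and variant annotation from a VCF.

    Uses the ``DS`` FORMAT field where present (imputed dosage of the ALT
    allele) and falls back to hard ALT-allele counts otherwise. Returns
    ``(dosages, variants)`` with the ALT allele as the counted allele
    ``a1``. Multi-allelic records are rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    rows = []
    dosage_cols = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"multi-allelic record at {rec.CHROM}:{rec.POS}")
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
        else:
            # gts012: 0/1/2 = ALT copies, 3 = missing
            col = np.asarray(rec.gt_types, dtype=float)
            col[col == 3] = np.nan
        rows.append(
            {
                "snp": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "chr": str(rec.CHROM).removeprefix("chr"),
                "bp": rec.POS,
                "a1": rec.ALT[0],
                "a2": rec.REF,
            }
        )
        dosage_cols.append(col)
    variants = pd.DataFrame(rows)
    dosages = np.column_stack(dosage_cols) if dosage_cols else np.empty((0, 0))
    return dosages, variants
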