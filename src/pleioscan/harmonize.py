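"""Reading, validating and allele-aligning GWAS summary statistics.

Effect sizes from different studies are only comparable once both refer to
the same effect allele on the same strand. This module reads summary-stat
TSVs, aligns each table's alleles to a reference panel (flipping beta and
effect-allele frequency where the effect/other alleles are swapped,
resolving strand flips by reverse complement, and dropping strand-ambiguous
palindromic variants), and inner-joins two aligned tables into a paired
table with a guaranteed common effect allele per variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import (
    STAT_COLUMNS,
    PairedStatTable,
    ReferencePanel,
    SummaryStatTable,
    complement,
    is_palindromic,
)

__all__ = [
    "SummaryStatTable",
    "PairedStatTable",
    "AlignmentReport",
    "ReadReport",
    "read_summary_stats",
    "align_alleles",
    "intersect_snps",
]

log = logging.getLogger(__name__)

#: default on-disk header -> internal column name
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "SNP": "snp",
    "CHR": "chr",
    "BP": "bp",
    "A1": "a1",
    "A2": "a2",
    "BETA": "beta",
    "SE": "se",
    "P": "p",
    "EAF": "eaf",
    "N": "n",
}

_MANDATORY = ["snp", "chr", "bp", "a1", "a2", "beta", "se", "p"]


@dataclass
class ReadReport:
    """Row-level accounting of one summary-stat read."""

    n_read: int = 0
    n_kept: int = 0
    n_dropped_malformed: int = 0
    n_clamped_p: int = 0

    @property
    def n_warnings(self) -> int:
        return self.n_dropped_malformed + self.n_clamped_p


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait: str | None = None,
    return_report: bool = False,
):
    """Read and validate a tab-delimited summary-statistic table.

    Rows violating the record invariants (se <= 0, p outside (0, 1],
    alleles not single A/C/G/T bases, non-finite beta) are dropped and
    counted; p = 0 is clamped to the smallest positive float with a logged
    warning; duplicate variant ids raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(column_map or DEFAULT_COLUMN_MAP)
    raw = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype={c: str for c in cmap if cmap[c] in ("snp", "chr", "a1", "a2")},
    )
    rename = {src: dst for src, dst in cmap.items() if src in raw.columns}
    df = raw.rename(columns=rename)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing mandatory column(s) {missing}")
    for opt in ("eaf", "n"):
        if opt not in df.columns:
            df[opt] = np.nan

    report = ReadReport(n_read=len(df))
    for col in ("bp", "beta", "se", "p", "eaf", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["a1"] = df["a1"].astype(str).str.upper()
    df["a2"] = df["a2"].astype(str).str.upper()

    zero_p = df["p"] == 0.0
    if zero_p.any():
        df.loc[zero_p, "p"] = np.nextafter(0.0, 1.0)
        report.n_clamped_p = int(zero_p.sum())
        log.warning(
            "%s: clamped %d zero p-values to smallest positive float",
            path.name,
            report.n_clamped_p,
        )

    ok = (
        df["a1"].isin(list("ACGT"))
        & df["a2"].isin(list("ACGT"))
        & (df["a1"] != df["a2"])
        & np.isfinite(df["beta"])
        & (df["se"] > 0)
        & (df["p"] > 0)
        & (df["p"] <= 1)
        & np.isfinite(df["bp"])
    )
    report.n_dropped_malformed = int((~ok).sum())
    if report.n_dropped_malformed:
        log.warning(
            "%s: dropped %d malformed row(s)", path.name, report.n_dropped_malformed
        )
    df = df[ok].copy()
    df["bp"] = df["bp"].astype(np.int64)
    if df["snp"].duplicated().any():
        dups = df.loc[df["snp"].duplicated(), "snp"].head(3).tolist()
        raise ValueError(f"{path.name}: duplicate variant ids, e.g. {dups}")
    report.n_kept = len(df)

    table = SummaryStatTable(df[STAT_COLUMNS], trait=trait or path.stem)
    return (table, report) if return_report else table


@dataclass
class AlignmentReport:
    """Per-variant accounting of one allele-alignment pass."""

    n_input: int = 0
    n_matched: int = 0
    n_swapped: int = 0
    n_strand_flipped: int = 0
    n_strand_swapped: int = 0
    n_palindromic_dropped: int = 0
    n_mismatch_dropped: int = 0
    n_absent_dropped: int = 0

    @property
    def n_kept(self) -> int:
        return (
            self.n_matched + self.n_swapped + self.n_strand_flipped + self.n_strand_swapped
        )

    @property
    def n_dropped(self) -> int:
        return (
            self.n_palindromic_dropped + self.n_mismatch_dropped + self.n_absent_dropped
        )


def classify_alleles(
    effect: str, other: str, panel_a1: str, panel_a2: str
) -> str:
    """Classify one record's allele pair against the panel pair.

    Returns one of ``match``, ``swap``, ``strand``, ``strand_swap``,
    ``palindromic``, ``mismatch``. Palindromic (A/T, C/G) records are
    always ambiguous and classified as such before any other rule.
    """
    if is_palindromic(effect, other):
        return "palindromic"
    if (effect, other) == (panel_a1, panel_a2):
        return "match"
    if (effect, other) == (panel_a2, panel_a1):
        return "swap"
    fe, fo = complement(effect), complement(other)
    if (fe, fo) == (panel_a1, panel_a2):
        return "strand"
    if (fe, fo) == (panel_a2, panel_a1):
        return "strand_swap"
    return "mismatch"


def align_alleles(
    stats: SummaryStatTable,
    panel: ReferencePanel,
    return_report: bool = False,
):
    """Express every record's beta on the panel's counted allele.

    Swapped records get ``beta -> -beta`` and ``eaf -> 1 - eaf``; strand
    flips relabel alleles by reverse complement first; palindromic and
    unmatched variants are dropped and tallied. Raises if no variant of
    ``stats`` is present in the panel.
    """
    report = AlignmentReport(n_input=len(stats))
    rows = []
    for rec in stats.df.itertuples(index=False):
        if rec.snp not in panel:
            report.n_absent_dropped += 1
            continue
        pa1, pa2 = panel.alleles(rec.snp)
        kind = classify_alleles(rec.a1, rec.a2, pa1, pa2)
        if kind == "palindromic":
            report.n_palindromic_dropped += 1
            continue
        if kind == "mismatch":
            report.n_mismatch_dropped += 1
            continue
        beta, eaf = rec.beta, rec.eaf
        if kind in ("swap", "strand_swap"):
            beta = -beta
            eaf = 1.0 - eaf if np.isfinite(eaf) else np.nan
        if kind == "match":
            report.n_matched += 1
        elif kind == "swap":
            report.n_swapped += 1
        elif kind == "strand":
            report.n_strand_flipped += 1
        else:
            report.n_strand_swapped += 1
        rows.append(
            (rec.snp, rec.chr, rec.bp, pa1, pa2, beta, rec.se, rec.p, eaf, rec.n)
        )
    if not rows:
        raise ValueError(
            f"no variant of trait {stats.trait!r} could be aligned to the panel"
        )
    df = pd.DataFrame(rows, columns=STAT_COLUMNS)
    aligned = SummaryStatTable(df, trait=stats.trait, build=stats.build)
    return (aligned, report) if return_report else aligned


def intersect_snps(a: SummaryStatTable, b: SummaryStatTable) -> PairedStatTable:
    """Inner-join two aligned tables on variant id.

    Both tables must already be aligned to the same panel; records whose
    effect/other alleles still disagree after alignment are treated as
    unresolvable and excluded. Raises on an empty join.
    """
    left = a.df[["snp", "a1", "a2", "beta", "se", "p"]].rename(
        columns={"beta": "beta_a", "se": "se_a", "p": "p_a"}
    )
    right = b.df[["snp", "a1", "a2", "beta", "se", "p"]].rename(
        columns={
            "a1": "b_a1",
            "a2": "b_a2",
            "beta": "beta_b",
            "se": "se_b",
            "p": "p_b",
        }
    )
    merged = left.merge(right, on="snp", how="inner", sort=True)
    same = (merged["a1"] == merged["b_a1"]) & (merged["a2"] == merged["b_a2"])
    n_discord = int((~same).sum())
    if n_discord:
        log.warning(
            "intersect_snps: excluded %d variant(s) with unresolved alleles", n_discord
        )
    merged = merged[same]
    if merged.empty:
        raise ValueError(
            f"no shared variants between traits {a.trait!r} and {b.trait!r}"
        )
    df = merged[["snp", "a1", "beta_a", "se_a", "p_a", "beta_b", "se_b", "p_b"]]
    return PairedStatTable(df.reset_index(drop=True), trait_a=a.trait, trait_b=b.trait)
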