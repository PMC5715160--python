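"""Shared in-memory containers for the pleiotropy pipeline.

GWAS summary statistics, the LD reference panel, paired (harmonized)
two-trait tables, and individual-level cohort data all flow between more
than one analysis stage, so their containers live here and are re-exported
by the stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Canonical column order of a summary-statistic table.
STAT_COLUMNS = ["snp", "chr", "bp", "a1", "a2", "beta", "se", "p", "eaf", "n"]

#: TSV dialect used on disk (PLINK-flavoured headers).
TSV_COLUMNS = {
    "snp": "SNP",
    "chr": "CHR",
    "bp": "BP",
    "a1": "A1",
    "a2": "A2",
    "beta": "BETA",
    "se": "SE",
    "p": "P",
    "eaf": "EAF",
    "n": "N",
}

VALID_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement(allele: str) -> str:
    """Complementary base of a single-nucleotide allele."""
    return _COMPLEMENT[allele]


def is_palindromic(a1: str, a2: str) -> bool:
    """True for strand-ambiguous (A/T or C/G) allele pairs."""
    return _COMPLEMENT.get(a1) == a2


class SummaryStatTable:
    """Per-variant association results for a single trait.

    Wraps a :class:`pandas.DataFrame` with columns ``snp, chr, bp, a1, a2,
    beta, se, p, eaf, n`` (``a1`` is the effect allele; ``beta`` is the
    signed effect per ``a1`` copy). ``eaf``/``n`` may be NaN. Variant ids
    are unique within a table.
    """

    def __init__(self, df: pd.DataFrame, trait: str, build: str = "hg19"):
        missing = [c for c in STAT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"summary-stat table missing columns: {missing}")
        if df["snp"].duplicated().any():
            dups = df.loc[df["snp"].duplicated(), "snp"].head(3).tolist()
            raise ValueError(f"duplicate variant ids in table: {dups}")
        self.df = df.reset_index(drop=True)
        self.trait = trait
        self.build = build

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"SummaryStatTable(trait={self.trait!r}, n={len(self)})"

    @property
    def variant_ids(self) -> pd.Series:
        return self.df["snp"]

    def subset(self, ids: Iterable[str]) -> "SummaryStatTable":
        ids = set(ids)
        return SummaryStatTable(
            self.df[self.df["snp"].isin(ids)].copy(), self.trait, self.build
        )

    def to_tsv(self, path: str | Path) -> None:
        out = self.df[STAT_COLUMNS].rename(columns=TSV_COLUMNS)
        out.to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass
class PairedStatTable:
    """Two traits' aligned records over their shared variants.

    ``df`` columns: ``snp, a1, beta_a, se_a, p_a, beta_b, se_b, p_b``.
    Both betas are expressed per copy of the common effect allele ``a1``.
    """

    df: pd.DataFrame
    trait_a: str
    trait_b: str

    def __post_init__(self) -> None:
        required = ["snp", "a1", "beta_a", "se_a", "p_a", "beta_b", "se_b", "p_b"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"paired table missing columns: {missing}")
        if self.df["snp"].duplicated().any():
            raise ValueError("duplicate variant ids in paired table")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


class ReferencePanel:
    """Haplotype reference panel used for allele alignment and LD.

    Parameters
    ----------
    variants
        DataFrame with columns ``snp, chr, bp, a1, a2, block``; ``a1`` is
        the counted (alternate) allele of the haplotype matrix.
    haplotypes
        ``(n_haplotypes, n_variants)`` 0/1 matrix, column order matching
        ``variants``.
    """

    def __init__(self, variants: pd.DataFrame, haplotypes: np.ndarray):
        required = ["snp", "chr", "bp", "a1", "a2", "block"]
        missing = [c for c in required if c not in variants.columns]
        if missing:
            raise ValueError(f"panel variant table missing columns: {missing}")
        if haplotypes.shape[1] != len(variants):
            raise ValueError("haplotype matrix width must match variant count")
        if variants["snp"].duplicated().any():
            raise ValueError("duplicate variant ids in panel")
        self.variants = variants.reset_index(drop=True)
        self.haplotypes = np.asarray(haplotypes, dtype=np.int8)
        self._index: Mapping[str, int] = {
            s: i for i, s in enumerate(self.variants["snp"])
        }

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    def __contains__(self, snp: str) -> bool:
        return snp in self._index

    def column(self, snp: str) -> int:
        return self._index[snp]

    def allele_freq(self, snp: str) -> float:
        """Frequency of the counted allele ``a1``."""
        return float(self.haplotypes[:, self._index[snp]].mean())

    def alleles(self, snp: str) -> tuple[str, str]:
        i = self._index[snp]
        row = self.variants.iloc[i]
        return row["a1"], row["a2"]

    def r2(self, snp_i: str, snp_j: str) -> float:
        """Squared haplotype correlation between two panel variants."""
        hi = self.haplotypes[:, self._index[snp_i]].astype(float)
        hj = self.haplotypes[:, self._index[snp_j]].astype(float)
        si, sj = hi.std(), hj.std()
        if si == 0.0 or sj == 0.0:
            return 0.0
        r = float(np.corrcoef(hi, hj)[0, 1])
        return r * r

    def r2_matrix(self, snps: list[str]) -> np.ndarray:
        cols = [self._index[s] for s in snps]
        h = self.haplotypes[:, cols].astype(float)
        sd = h.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(h, rowvar=False)
        r = np.atleast_2d(r)
        r[~np.isfinite(r)] = 0.0
        bad = sd == 0
        r[bad, :] = 0.0
        r[:, bad] = 0.0
        np.fill_diagonal(r, 1.0)
        return r * r

    def sample_dosages(self, n_subjects: int, rng: np.random.Generator) -> np.ndarray:
        """Draw diploid dosages by pairing haplotypes with replacement."""
        idx = rng.integers(0, self.n_haplotypes, size=(n_subjects, 2))
        return (
            self.haplotypes[idx[:, 0], :].astype(np.float64)
            + self.haplotypes[idx[:, 1], :]
        )


@dataclass
class CohortData:
    """Individual-level genotypes and phenotypes for one cohort.

    ``dosages`` is subjects x variants with values in [0, 2]; columns are
    keyed by ``variant_ids`` (counted allele = panel ``a1``).
    ``phenotypes`` holds per-subject traits and covariates. ``truth``
    carries the simulated causal architecture for recovery tests.
    """

    dosages: np.ndarray
    variant_ids: list[str]
    variants: pd.DataFrame  # snp, chr, bp, a1, a2
    phenotypes: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dosages.shape[1] != len(self.variant_ids):
            raise ValueError("dosage width must match variant id count")
        if self.dosages.shape[0] != len(self.phenotypes):
            raise ValueError("dosage rows must match phenotype rows")
        if len(self.variant_ids) and (
            self.dosages.min() < 0 or self.dosages.max() > 2
        ):
            raise ValueError("dosages must lie in [0, 2]")
        self._index = {s: i for i, s in enumerate(self.variant_ids)}

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    def __contains__(self, snp: str) -> bool:
        return snp in self._index

    def dosage(self, snp: str) -> np.ndarray:
        return self.dosages[:, self._index[snp]]
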