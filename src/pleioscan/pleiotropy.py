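"""Cross-trait SNP-overlap enrichment, direction concordance, and QQ data.

Given two harmonized GWAS (e.g. smoking-adjusted lung function and a
nicotine-dependence trait), these statistics quantify shared genetic
signal:

* **overlap enrichment** — at a p threshold, the count of variants
  significant in both studies against its chance expectation
  ``n_a * n_b / n_total`` over the shared-variant universe;
* **direction concordance** — whether the allele raising trait A also
  raises trait B (*consistent*) or lowers it (*divergent*), with an exact
  two-sided binomial test of the divergent proportion against 0.5;
* **locus lookup** — per-trait significance flags for known lead SNPs;
* **conditional QQ** — observed vs expected quantiles of one trait's
  p-values within subsets conditioned on the other trait's significance,
  whose upward lift with conditioning stringency is the visual signature
  of pleiotropic enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import binomtest

from .containers import PairedStatTable, SummaryStatTable

__all__ = [
    "OverlapResult",
    "LocusLookup",
    "QQSeries",
    "select_associated",
    "overlap_enrichment",
    "direction_concordance",
    "stratified_overlap",
    "lookup_loci",
    "conditional_qq",
]

log = logging.getLogger(__name__)


@dataclass
class OverlapResult:
    """Overlap and direction statistics for one trait pair at one threshold."""

    p_threshold: float
    n_a: int
    n_b: int
    n_total: int
    n_overlap: int
    expected_overlap: float
    enrichment_fold: float | None
    n_divergent: int | None
    n_consistent: int | None
    n_zero_excluded: int
    pct_divergent: float | None
    binomial_p: float | None

    def to_row(self) -> dict:
        return {
            "p_threshold": self.p_threshold,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_total": self.n_total,
            "n_overlap": self.n_overlap,
            "expected_overlap": self.expected_overlap,
            "enrichment_fold": self.enrichment_fold,
            "n_divergent": self.n_divergent,
            "n_consistent": self.n_consistent,
            "pct_divergent": self.pct_divergent,
            "binomial_p": self.binomial_p,
        }


@dataclass
class LocusLookup:
    """Per-trait significance flags for one known lead SNP."""

    snp: str
    locus: str
    p_values: dict[str, float | None]
    flags: dict[str, str | None]  # "Y" / "N" / None when not found


@dataclass
class QQSeries:
    """Observed and expected -log10 p quantiles for one conditioned subset."""

    conditioning_trait: str
    threshold: float
    observed: np.ndarray  # sorted ascending
    expected: np.ndarray  # sorted ascending, strictly increasing
    subset_size: int


def select_associated(stats: SummaryStatTable, threshold: float) -> set[str]:
    """Variants with p <= threshold (boundary inclusive; empty set allowed)."""
    p = stats.df["p"]
    return set(stats.df.loc[p.notna() & (p <= threshold), "snp"])


def _exact_binomial_p(k: int, n: int) -> float:
    """Exact two-sided binomial test of k/n against proportion 0.5."""
    return float(binomtest(k, n, 0.5, alternative="two-sided").pvalue)


def _direction_stats(
    beta_a: np.ndarray, beta_b: np.ndarray
) -> tuple[int, int, int]:
    """(n_divergent, n_consistent, n_zero_excluded) from aligned betas."""
    prod = beta_a * beta_b
    nonzero = prod != 0
    n_div = int((prod < 0).sum())
    n_con = int((prod > 0).sum())
    return n_div, n_con, int((~nonzero).sum())


def overlap_enrichment(
    paired: PairedStatTable, threshold_a: float, threshold_b: float
) -> OverlapResult:
    """Shared-significance enrichment over the paired-variant universe.

    ``n_total`` is the size of the paired table (variants tested in both
    studies); expected overlap under independence is ``n_a * n_b /
    n_total``. Direction is classified from the sign product of the two
    aligned betas; variants with a zero beta on either side stay in
    ``n_overlap`` but are excluded from the direction counts (tallied in
    ``n_zero_excluded``). ``pct_divergent`` is ``100 * n_divergent /
    n_overlap``.
    """
    df = paired.df
    n_total = len(df)
    in_a = (df["p_a"] <= threshold_a).to_numpy()
    in_b = (df["p_b"] <= threshold_b).to_numpy()
    n_a = int(in_a.sum())
    n_b = int(in_b.sum())
    both = in_a & in_b
    n_overlap = int(both.sum())
    expected = n_a * n_b / n_total if n_total else 0.0
    fold = n_overlap / expected if expected > 0 else None

    if n_overlap == 0:
        return OverlapResult(
            p_threshold=threshold_a,
            n_a=n_a,
            n_b=n_b,
            n_total=n_total,
            n_overlap=0,
            expected_overlap=expected,
            enrichment_fold=fold,
            n_divergent=None,
            n_consistent=None,
            n_zero_excluded=0,
            pct_divergent=None,
            binomial_p=None,
        )

    n_div, n_con, n_zero = _direction_stats(
        df.loc[both, "beta_a"].to_numpy(), df.loc[both, "beta_b"].to_numpy()
    )
    n_dir = n_div + n_con
    return OverlapResult(
        p_threshold=threshold_a,
        n_a=n_a,
        n_b=n_b,
        n_total=n_total,
        n_overlap=n_overlap,
        expected_overlap=expected,
        enrichment_fold=fold,
        n_divergent=n_div,
        n_consistent=n_con,
        n_zero_excluded=n_zero,
        pct_divergent=round(100.0 * n_div / n_overlap, 2),
        binomial_p=_exact_binomial_p(n_div, n_dir) if n_dir else None,
    )


def direction_concordance(
    paired_subset: PairedStatTable,
) -> tuple[int, int, float, float]:
    """Direction split of a set of shared variants.

    Returns ``(n_divergent, n_consistent, pct_divergent, binomial_p)``
    where the percentage (2 decimals) is over variants with both betas
    nonzero and the p-value is the exact two-sided binomial test of the
    divergent count against proportion 0.5.
    """
    n_div, n_con, _ = _direction_stats(
        paired_subset.df["beta_a"].to_numpy(), paired_subset.df["beta_b"].to_numpy()
    )
    n_dir = n_div + n_con
    if n_dir == 0:
        raise ValueError("no variant with both betas nonzero")
    pct = round(100.0 * n_div / n_dir, 2)
    return n_div, n_con, pct, _exact_binomial_p(n_div, n_dir)


def stratified_overlap(
    paired: PairedStatTable,
    thresholds: Sequence[float],
    direction_filter: str = "all",
    threshold_b: Sequence[float] | None = None,
) -> list[OverlapResult]:
    """Overlap enrichment per threshold, optionally within one direction.

    With ``direction_filter`` of ``consistent`` or ``divergent``, the
    universe (and hence both trait selections and the chance expectation)
    is restricted to variants of that sign class before counting, so the
    fold compares within-stratum overlap to within-stratum chance.
    """
    if direction_filter not in ("all", "consistent", "divergent"):
        raise ValueError("direction_filter must be all|consistent|divergent")
    sub = paired
    if direction_filter != "all":
        prod = paired.df["beta_a"] * paired.df["beta_b"]
        mask = prod > 0 if direction_filter == "consistent" else prod < 0
        sub = PairedStatTable(
            paired.df[mask].reset_index(drop=True), paired.trait_a, paired.trait_b
        )
    results = []
    tb = thresholds if threshold_b is None else threshold_b
    for t, t2 in zip(thresholds, tb):
        if len(sub) == 0:
            results.append(
                OverlapResult(
                    p_threshold=t,
                    n_a=0,
                    n_b=0,
                    n_total=0,
                    n_overlap=0,
                    expected_overlap=0.0,
                    enrichment_fold=None,
                    n_divergent=None,
                    n_consistent=None,
                    n_zero_excluded=0,
                    pct_divergent=None,
                    binomial_p=None,
                )
            )
        else:
            results.append(overlap_enrichment(sub, t, t2))
    return results


def lookup_loci(
    leads: Sequence[tuple[str, str]],
    stats_tables: Sequence[SummaryStatTable],
    alpha: float = 0.05,
) -> list[LocusLookup]:
    """Check known lead SNPs for association in each table.

    The flag is ``Y`` iff p <= alpha (boundary inclusive), ``N`` otherwise,
    and None when the lead is absent from a table.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    out = []
    lookups = [dict(zip(t.df["snp"], t.df["p"])) for t in stats_tables]
    for snp, locus in leads:
        p_values: dict[str, float | None] = {}
        flags: dict[str, str | None] = {}
        for table, lut in zip(stats_tables, lookups):
            p = lut.get(snp)
            if p is None or not np.isfinite(p):
                p_values[table.trait] = None
                flags[table.trait] = None
            else:
                p_values[table.trait] = float(p)
                flags[table.trait] = "Y" if p <= alpha else "N"
        out.append(LocusLookup(snp=snp, locus=locus, p_values=p_values, flags=flags))
    return out


def conditional_qq(
    primary: SummaryStatTable,
    conditioning: SummaryStatTable,
    thresholds: Sequence[float],
) -> list[QQSeries]:
    """QQ data of the primary trait conditioned on the secondary trait.

    For each threshold ``t``, the subset is the shared variants whose
    conditioning p-value is <= ``t``; observed values are the sorted
    ``-log10`` primary p-values and expected values the uniform midpoint
    quantiles ``-log10((i - 0.5) / m)`` over the subset size ``m``, both
    ascending. Empty subsets yield empty series (logged, not an error).
    """
    merged = primary.df[["snp", "p"]].merge(
        conditioning.df[["snp", "p"]], on="snp", suffixes=("_primary", "_cond")
    )
    out = []
    for t in thresholds:
        sel = merged.loc[merged["p_cond"] <= t, "p_primary"].dropna().to_numpy()
        m = len(sel)
        if m == 0:
            log.info(
                "conditional_qq: empty subset at conditioning threshold %g", t
            )
            out.append(
                QQSeries(
                    conditioning_trait=conditioning.trait,
                    threshold=t,
                    observed=np.empty(0),
                    expected=np.empty(0),
                    subset_size=0,
                )
            )
            continue
        observed = np.sort(-np.log10(sel))
        ranks = np.arange(m, 0, -1)  # i = m .. 1 gives ascending expected
        expected = -np.log10((ranks - 0.5) / m)
        out.append(
            QQSeries(
                conditioning_trait=conditioning.trait,
                threshold=t,
                observed=observed,
                expected=expected,
                subset_size=m,
            )
        )
    return out
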