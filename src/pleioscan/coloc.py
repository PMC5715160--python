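"""Approximate-Bayes-factor colocalization of two traits in one region.

Under a single-causal-variant-per-trait assumption, each variant's
evidence of association with a trait is the Wakefield approximate Bayes
factor computed from its estimated effect and standard error. Summing
per-variant Bayes factors over the region yields posterior probabilities
of five hypotheses:

* H0 — no association with either trait;
* H1 / H2 — association with trait 1 / trait 2 only;
* H3 — both traits associated, two distinct causal variants;
* H4 — both traits associated, one shared causal variant.

A high PP.H4 (conventionally > 0.75) supports a shared causal variant; a
high PP.H3 supports distinct variants in the same region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .containers import SummaryStatTable

__all__ = [
    "RegionSpec",
    "ColocPriors",
    "ColocResult",
    "DEFAULT_PRIORS",
    "wakefield_log_abf",
    "coloc_five_hypotheses",
    "extract_region",
]

log = logging.getLogger(__name__)

#: prior effect standard deviation by trait type (squared to a variance
#: inside the ABF): 0.15 trait-SD units for quantitative traits, 0.2
#: log-odds units for binary traits.
PRIOR_EFFECT_SD = {"quantitative": 0.15, "binary": 0.2}


@dataclass(frozen=True)
class RegionSpec:
    """One genomic region, 1-based inclusive bounds."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("region start must be < end")

    @classmethod
    def parse(cls, text: str) -> "RegionSpec":
        """Parse ``chr15:77801394-79801394`` style region strings."""
        chrom, span = text.split(":")
        start, end = span.replace(",", "").split("-")
        return cls(chromosome=chrom.removeprefix("chr"), start=int(start), end=int(end))


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant prior probabilities of association.

    ``p1``/``p2`` — associated with trait 1/2 only; ``p12`` — associated
    with both. Defaults follow the conventional colocalization software
    defaults.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p12"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.p12 > min(self.p1, self.p2):
            log.warning("p12 exceeds min(p1, p2); unusual prior configuration")


DEFAULT_PRIORS = ColocPriors()


@dataclass
class ColocResult:
    """Posterior probabilities of the five hypotheses for one region."""

    n_snps: int
    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float

    def as_array(self) -> np.ndarray:
        return np.array([self.pp_h0, self.pp_h1, self.pp_h2, self.pp_h3, self.pp_h4])


def wakefield_log_abf(beta, se, prior_effect_variance: float):
    """Log approximate Bayes factor for association at one variant.

    With ``V = se**2``, ``z = beta/se`` and shrinkage ``r = W / (V + W)``
    for prior effect variance ``W``::

        log ABF = 0.5 * (ln(1 - r) + r * z**2)

    Accepts scalars or arrays; ``W = 0`` collapses the prior and returns 0.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if prior_effect_variance < 0:
        raise ValueError("prior effect variance must be non-negative")
    v = se**2
    r = prior_effect_variance / (v + prior_effect_variance)
    z = beta / se
    out = 0.5 * (np.log1p(-r) + r * z**2)
    return float(out) if out.ndim == 0 else out


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)), clamped to -inf when b >= a (with a warning
    when the violation exceeds rounding tolerance)."""
    if b >= a:
        if b > a + 1e-9:
            log.warning("logdiffexp: negative difference clamped (b - a = %g)", b - a)
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_five_hypotheses(
    stats1: SummaryStatTable,
    stats2: SummaryStatTable,
    priors: ColocPriors = DEFAULT_PRIORS,
    trait_types: tuple[str, str] = ("quantitative", "quantitative"),
) -> ColocResult:
    """Five-hypothesis posterior decomposition over a region's shared SNPs.

    Per shared variant the two traits' log-ABFs ``l1, l2`` are accumulated
    in log space: ``S1 = logsum(l1)``, ``S2 = logsum(l2)``,
    ``S12 = logsum(l1 + l2)``. Unnormalized log posterior weights are::

        H0: 0
        H1: ln p1 + S1
        H2: ln p2 + S2
        H3: ln p1 + ln p2 + log(exp(S1 + S2) - exp(S12))
        H4: ln p12 + S12

    where the H3 term is the sum over ordered pairs of *distinct* variants.
    A single-variant region has no such pair, so PP.H3 is exactly zero.
    """
    for t in trait_types:
        if t not in PRIOR_EFFECT_SD:
            raise ValueError(f"trait type must be quantitative|binary, got {t!r}")
    merged = stats1.df[["snp", "beta", "se"]].merge(
        stats2.df[["snp", "beta", "se"]], on="snp", suffixes=("_1", "_2")
    )
    merged = merged.dropna()
    if merged.empty:
        raise ValueError("no shared variants with complete effect estimates")

    w1 = PRIOR_EFFECT_SD[trait_types[0]] ** 2
    w2 = PRIOR_EFFECT_SD[trait_types[1]] ** 2
    l1 = wakefield_log_abf(merged["beta_1"].to_numpy(), merged["se_1"].to_numpy(), w1)
    l2 = wakefield_log_abf(merged["beta_2"].to_numpy(), merged["se_2"].to_numpy(), w2)
    l1 = np.atleast_1d(l1)
    l2 = np.atleast_1d(l2)

    s1 = float(logsumexp(l1))
    s2 = float(logsumexp(l2))
    s12 = float(logsumexp(l1 + l2))
    weights = np.array(
        [
            0.0,
            np.log(priors.p1) + s1,
            np.log(priors.p2) + s2,
            np.log(priors.p1) + np.log(priors.p2) + _logdiffexp(s1 + s2, s12),
            np.log(priors.p12) + s12,
        ]
    )
    pp = np.exp(weights - logsumexp(weights))
    pp = pp / pp.sum()
    return ColocResult(
        n_snps=len(merged),
        pp_h0=float(pp[0]),
        pp_h1=float(pp[1]),
        pp_h2=float(pp[2]),
        pp_h3=float(pp[3]),
        pp_h4=float(pp[4]),
    )


def extract_region(stats: SummaryStatTable, region: RegionSpec) -> SummaryStatTable:
    """Restrict a table to one region (inclusive position bounds)."""
    df = stats.df
    chrom = str(region.chromosome).removeprefix("chr")
    mask = (
        (df["chr"].astype(str).str.removeprefix("chr") == chrom)
        & (df["bp"] >= region.start)
        & (df["bp"] <= region.end)
    )
    if not mask.any():
        raise ValueError(
            f"no variants of trait {stats.trait!r} in "
            f"{region.chromosome}:{region.start}-{region.end}"
        )
    return SummaryStatTable(df[mask].copy(), trait=stats.trait, build=stats.build)
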