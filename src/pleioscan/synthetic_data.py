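"""Synthetic cohorts, reference panels, and GWAS summary statistics.

The real inputs of this analysis (consortium smoking-behaviour GWAS,
case/control spirometry cohorts, biobank lung-function GWAS) are access
restricted, so the pipeline is exercised on generated data that reproduces
their statistical structure:

* an LD-blocked haplotype reference panel (exchangeable correlation within
  blocks via a Gaussian copula, independence across blocks);
* a nicotine-dependence (ND) liability with a sparse causal architecture,
  from which smoking phenotypes (cigarettes/day, ever/former smoking,
  onset, duration) are derived;
* lung-function traits and COPD status that receive the ND signal either
  exclusively through smoking behaviour (*causal* pleiotropy model) or
  additionally through direct per-allele effects (*independent* model);
* per-SNP summary statistics computed by single-variant regression.

The two pleiotropy models are the discrimination target of the
polygenic-score mediation contrast: under the causal model, adjusting for
smoking behaviour removes the genetic association with lung function and
COPD; under the independent model it barely moves it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .containers import CohortData, ReferencePanel, SummaryStatTable

__all__ = [
    "PanelSpec",
    "ScenarioSpec",
    "CohortData",
    "simulate_reference_panel",
    "simulate_cohort",
    "compute_gwas",
    "simulate_trait_gwas",
    "simulate_null_summary_stats",
]

# Ordered non-palindromic allele pairs; the panel never emits strand-ambiguous
# (A/T, C/G) variants so its own summary stats survive harmonization intact.
_ALLELE_PAIRS = [
    (a, b)
    for a in "ACGT"
    for b in "ACGT"
    if a != b and {a, b} not in ({"A", "T"}, {"C", "G"})
]


@dataclass(frozen=True)
class PanelSpec:
    """Parameters of the simulated haplotype reference panel."""

    n_blocks: int = 10
    block_size: int = 10
    within_block_correlation: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_haplotypes: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.block_size < 1 or self.n_haplotypes < 1:
            raise ValueError("n_blocks, block_size and n_haplotypes must be >= 1")
        if not (0.0 <= self.within_block_correlation < 1.0):
            raise ValueError("within_block_correlation must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < min <= max <= 0.5")


@dataclass(frozen=True)
class ScenarioSpec:
    """Causal architecture of one simulated study.

    ``model`` selects the pleiotropy mechanism: under ``causal`` the only
    path from ND-causal variants to lung function / COPD runs through the
    smoking phenotypes via ``smoking_effect_on_lf`` (gamma, lung-function
    units per pack-per-day); under ``independent`` a set of variants
    (overlapping the ND-causal set) additionally hits lung function and
    COPD directly.
    """

    model: str = "independent"
    n_nd_causal: int = 20
    nd_effect_sd: float = 0.3
    smoking_effect_on_lf: float = -0.5
    n_direct_lf_causal: int | None = None
    direct_lf_effect_sd: float = 0.6
    n_subjects_per_cohort: int = 5000
    copd_liability_threshold: float = 0.70
    seed: int = 0
    architecture_seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("causal", "independent"):
            raise ValueError("model must be 'causal' or 'independent'")
        if self.n_direct_lf_causal is None:
            n_direct = 0 if self.model == "causal" else self.n_nd_causal
            object.__setattr__(self, "n_direct_lf_causal", n_direct)
        if self.model == "causal" and self.n_direct_lf_causal != 0:
            raise ValueError("causal model requires n_direct_lf_causal = 0")
        if not (0.0 < self.copd_liability_threshold < 1.0):
            raise ValueError("copd_liability_threshold must lie strictly in (0, 1)")
        if self.n_subjects_per_cohort < 1:
            raise ValueError("n_subjects_per_cohort must be >= 1")
        if self.n_nd_causal < 1:
            raise ValueError("n_nd_causal must be >= 1")


def _binary_corr(latent_rho: float, maf: float) -> float:
    """Correlation of two exchangeable copula-thresholded 0/1 variables."""
    z = stats.norm.ppf(maf)
    p11 = stats.multivariate_normal(
        mean=[0.0, 0.0], cov=[[1.0, latent_rho], [latent_rho, 1.0]]
    ).cdf([z, z])
    return (p11 - maf * maf) / (maf * (1.0 - maf))


def _calibrate_latent_rho(target_r: float, maf: float) -> float:
    """Latent Gaussian correlation giving haplotype correlation ``target_r``.

    Thresholding a bivariate normal attenuates correlation, so the latent
    value is solved (at the panel's mean MAF) to hit the target on the 0/1
    haplotype scale.
    """
    if target_r <= 0.0:
        return 0.0
    f = lambda rho: _binary_corr(rho, maf) - target_r
    hi = 1.0 - 1e-9
    if f(hi) < 0:  # target unattainable; saturate
        return hi
    return float(brentq(f, 0.0, hi, xtol=1e-6))


def simulate_reference_panel(spec: PanelSpec) -> ReferencePanel:
    """Generate an LD-blocked haplotype panel.

    Within a block, haplotype alleles share an exchangeable correlation
    targeting ``spec.within_block_correlation`` (one-factor Gaussian copula,
    calibrated at the mean MAF); blocks are mutually independent. Variants
    get sequential rs-style ids, non-palindromic allele pairs, and positions
    with 10 Mb gaps between blocks so LD windows never straddle blocks.
    """
    rng = np.random.default_rng(spec.seed)
    maf_mid = 0.5 * (spec.maf_range[0] + spec.maf_range[1])
    latent_rho = _calibrate_latent_rho(spec.within_block_correlation, maf_mid)

    n_var = spec.n_blocks * spec.block_size
    mafs = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=n_var)
    haplotypes = np.empty((spec.n_haplotypes, n_var), dtype=np.int8)
    for b in range(spec.n_blocks):
        cols = slice(b * spec.block_size, (b + 1) * spec.block_size)
        common = rng.standard_normal((spec.n_haplotypes, 1))
        noise = rng.standard_normal((spec.n_haplotypes, spec.block_size))
        latent = math.sqrt(latent_rho) * common + math.sqrt(1.0 - latent_rho) * noise
        haplotypes[:, cols] = (latent < stats.norm.ppf(mafs[cols])).astype(np.int8)

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_var)
    blocks = np.repeat(np.arange(spec.n_blocks), spec.block_size)
    within = np.tile(np.arange(spec.block_size), spec.n_blocks)
    variants = pd.DataFrame(
        {
            "snp": [f"rs{i + 1}" for i in range(n_var)],
            "chr": "1",
            "bp": (blocks * 10_000_000 + within * 1_000 + 1).astype(np.int64),
            "a1": [_ALLELE_PAIRS[i][0] for i in pair_idx],
            "a2": [_ALLELE_PAIRS[i][1] for i in pair_idx],
            "block": blocks,
        }
    )
    return ReferencePanel(variants, haplotypes)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohort(panel: ReferencePanel, scenario: ScenarioSpec) -> CohortData:
    """Simulate one cohort under the requested pleiotropy model.

    ND liability is a sparse sum of +/- ``nd_effect_sd`` per-allele effects
    (Rademacher signs, so every causal variant carries signal) plus standard
    normal noise. Smoking phenotypes derive from the liability; lung
    function receives ``gamma * packs-per-day`` plus, under the independent
    model, direct per-allele effects on the overlapping causal set with sign
    opposite to the ND effect (the allele raising smoking quantity lowers
    lung function directly — the divergent-direction pattern seen at loci
    like 15q25.1). COPD status thresholds a liability built from the same
    two paths with inverted sign.
    """
    sc = scenario
    if panel.n_variants < max(sc.n_nd_causal, sc.n_direct_lf_causal):
        raise ValueError("panel has fewer variants than requested causal counts")
    rng = np.random.default_rng(sc.seed)
    n = sc.n_subjects_per_cohort

    dosages = panel.sample_dosages(n, rng)
    n_var = panel.n_variants

    # the causal architecture is a property of the scenario, not of one
    # cohort draw: cohorts differing only in `seed` (e.g. PGS training vs
    # target) share causal variants and effects
    arch_rng = np.random.default_rng(sc.architecture_seed)
    nd_idx = arch_rng.choice(n_var, size=sc.n_nd_causal, replace=False)
    nd_beta = sc.nd_effect_sd * arch_rng.choice([-1.0, 1.0], size=sc.n_nd_causal)
    g_nd = dosages[:, nd_idx] - dosages[:, nd_idx].mean(axis=0)
    liability = g_nd @ nd_beta + rng.standard_normal(n)

    # smoking phenotypes
    ever = (rng.random(n) < _sigmoid(0.5 + 0.8 * liability)).astype(float)
    cpd = np.where(ever == 1, np.maximum(0.0, np.round(10.0 + 5.0 * liability)), 0.0)
    p_former = _sigmoid(0.2 - 0.4 * liability)
    former = np.where(ever == 1, (rng.random(n) < p_former).astype(float), np.nan)
    log_onset = np.where(
        ever == 1,
        math.log(18.0) - 0.05 * liability + 0.2 * rng.standard_normal(n),
        np.nan,
    )
    age = rng.uniform(45.0, 80.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    quit_years = np.where(former == 1, rng.uniform(1.0, 15.0, size=n), 0.0)
    duration = np.where(
        ever == 1, np.clip(age - np.exp(log_onset) - quit_years, 0.0, None), 0.0
    )
    current = np.where(ever == 1, 1.0 - former, 0.0)
    packs = cpd / 10.0

    # direct (independent-model) effects: overlap the ND-causal set first,
    # with effect proportional to -beta_ND; any surplus variants get fresh
    # random-sign effects on loci disjoint from the ND set.
    direct_idx = np.empty(0, dtype=int)
    direct_beta = np.empty(0)
    if sc.n_direct_lf_causal > 0:
        k_overlap = min(sc.n_direct_lf_causal, sc.n_nd_causal)
        direct_idx = nd_idx[:k_overlap].copy()
        direct_beta = -(sc.direct_lf_effect_sd / sc.nd_effect_sd) * nd_beta[:k_overlap]
        n_extra = sc.n_direct_lf_causal - k_overlap
        if n_extra > 0:
            pool = np.setdiff1d(np.arange(n_var), nd_idx)
            extra = arch_rng.choice(pool, size=n_extra, replace=False)
            direct_idx = np.concatenate([direct_idx, extra])
            direct_beta = np.concatenate(
                [
                    direct_beta,
                    sc.direct_lf_effect_sd * arch_rng.choice([-1.0, 1.0], size=n_extra),
                ]
            )
    if len(direct_idx):
        g_d = dosages[:, direct_idx] - dosages[:, direct_idx].mean(axis=0)
        direct_contrib = g_d @ direct_beta
    else:
        direct_contrib = np.zeros(n)

    lf_signal = sc.smoking_effect_on_lf * packs + direct_contrib
    fvc = (
        3.8
        + 0.5 * sex
        - 0.03 * (age - 60.0)
        + 0.6 * lf_signal
        + 0.5 * rng.standard_normal(n)
    )
    fvc = np.clip(fvc, 0.5, None)
    fev1 = 0.75 * fvc + 0.4 * lf_signal + 0.3 * rng.standard_normal(n)
    fev1 = np.clip(fev1, 0.05, 1.45 * fvc)
    ratio = fev1 / fvc

    copd_liab = (
        -sc.smoking_effect_on_lf * packs - direct_contrib + rng.standard_normal(n)
    )
    cut = np.quantile(copd_liab, sc.copd_liability_threshold)
    copd = (copd_liab > cut).astype(float)

    phenotypes = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "ever_smoked": ever,
            "former_smoker": former,
            "cpd": cpd,
            "packs": packs,
            "log_onset": log_onset,
            "smoking_status": current,
            "smoking_duration": duration,
            "fev1": fev1,
            "fvc": fvc,
            "ratio": ratio,
            "copd_status": copd,
        }
    )
    snp = panel.variants["snp"]
    truth = {
        "model": sc.model,
        "gamma": sc.smoking_effect_on_lf,
        "nd_causal_ids": [snp.iloc[i] for i in nd_idx],
        "nd_effects": nd_beta.copy(),
        "direct_ids": [snp.iloc[i] for i in direct_idx],
        "direct_effects": direct_beta.copy(),
        "liability": liability,
    }
    return CohortData(
        dosages=dosages,
        variant_ids=list(snp),
        variants=panel.variants[["snp", "chr", "bp", "a1", "a2"]].copy(),
        phenotypes=phenotypes,
        truth=truth,
    )


# traits analysed within the ever-smoker stratum, as in smoking-behaviour
# GWAS (quantity, cessation and onset are defined only among smokers)
_SMOKER_ONLY_TRAITS = {"cpd", "packs", "log_onset", "former_smoker"}


def _linear_gwas(
    y: np.ndarray, genotypes: np.ndarray, covariates: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Exact per-column OLS of ``y`` on each genotype plus shared covariates.

    Residualizes both sides on the covariate block (Frisch–Waugh–Lovell),
    which reproduces the full-model slope, its standard error and the
    t-test p-value without fitting one model per variant. Returns
    ``(beta, se, p, usable)`` where ``usable`` is False for columns with no
    residual genotype variance (monomorphic or covariate-collinear).
    """
    n, k = covariates.shape
    coef_y, *_ = np.linalg.lstsq(covariates, y, rcond=None)
    ry = y - covariates @ coef_y
    coef_g, *_ = np.linalg.lstsq(covariates, genotypes, rcond=None)
    rg = genotypes - covariates @ coef_g

    d = np.einsum("ij,ij->j", rg, rg)
    usable = d > 1e-10
    d_safe = np.where(usable, d, 1.0)
    cross = rg.T @ ry
    beta = cross / d_safe
    df = n - k - 1
    rss = np.maximum(ry @ ry - beta * cross, 0.0)
    sigma2 = rss / df
    se = np.sqrt(sigma2 / d_safe)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    beta = np.where(usable, beta, np.nan)
    se = np.where(usable & (se > 0), se, np.nan)
    p = np.where(usable & (se > 0), p, np.nan)
    return beta, se, p, usable


def _logistic_gwas(
    y: np.ndarray, genotypes: np.ndarray, covariates: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant logistic regression (Wald tests) via statsmodels."""
    import statsmodels.api as sm

    m = genotypes.shape[1]
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    p = np.full(m, np.nan)
    usable = np.zeros(m, dtype=bool)
    for j in range(m):
        g = genotypes[:, j]
        if g.std() < 1e-8:
            continue
        X = np.column_stack([covariates, g])
        try:
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=50)
        except Exception:
            continue
        b, s = fit.params[-1], fit.bse[-1]
        if not (np.isfinite(b) and np.isfinite(s)) or s <= 0 or s > 1e3:
            continue
        beta[j], se[j] = b, s
        p[j] = 2.0 * stats.norm.sf(abs(b / s))
        usable[j] = True
    return beta, se, p, usable


def compute_gwas(
    cohort: CohortData, trait: str, covariates: Sequence[str] = ()
) -> SummaryStatTable:
    """Single-SNP association scan of one cohort trait.

    Linear regression for quantitative traits, logistic for binary (0/1)
    traits; covariates enter additively. Smoking-quantity, onset and
    cessation traits are analysed within ever-smokers. Monomorphic variants
    are emitted with NaN results and ``status='monomorphic'`` rather than
    dropped. The effect allele of every record is the panel's counted
    allele.
    """
    pheno = cohort.phenotypes
    if trait not in pheno.columns:
        raise KeyError(f"unknown trait {trait!r}")
    for c in covariates:
        if c not in pheno.columns:
            raise KeyError(f"unknown covariate {c!r}")

    mask = np.ones(cohort.n_subjects, dtype=bool)
    if trait in _SMOKER_ONLY_TRAITS:
        mask &= pheno["ever_smoked"].to_numpy() == 1
    cols = [trait, *covariates]
    mask &= ~pheno[cols].isna().any(axis=1).to_numpy()
    if mask.sum() < 10:
        raise ValueError("fewer than 10 analysable subjects")

    y = pheno.loc[mask, trait].to_numpy(dtype=float)
    if np.std(y) < 1e-12:
        raise ValueError(f"trait {trait!r} has zero variance")
    X = np.column_stack(
        [np.ones(mask.sum())] + [pheno.loc[mask, c].to_numpy(dtype=float) for c in covariates]
    )
    G = cohort.dosages[mask, :]

    binary = set(np.unique(y)) <= {0.0, 1.0}
    if binary:
        beta, se, p, usable = _logistic_gwas(y, G, X)
    else:
        beta, se, p, usable = _linear_gwas(y, G, X)

    df = cohort.variants.copy()
    df["beta"] = beta
    df["se"] = se
    df["p"] = p
    df["eaf"] = G.mean(axis=0) / 2.0
    df["n"] = int(mask.sum())
    df["status"] = np.where(usable, "ok", "monomorphic")
    return SummaryStatTable(df, trait=trait)


def simulate_trait_gwas(
    panel: ReferencePanel,
    causal_effects: Mapping[str, float],
    n_subjects: int,
    seed: int,
    noise_sd: float = 1.0,
    trait: str = "trait",
) -> SummaryStatTable:
    """Summary statistics for a quantitative trait with known architecture.

    Draws a fresh cohort from ``panel``, builds the trait as the centred
    causal-dosage combination plus Gaussian noise, and scans all panel
    variants with plain linear regression. Convenient for colocalization
    and enrichment experiments where only summary statistics are needed.
    """
    rng = np.random.default_rng(seed)
    dosages = panel.sample_dosages(n_subjects, rng)
    y = noise_sd * rng.standard_normal(n_subjects)
    for snp_id, eff in causal_effects.items():
        g = dosages[:, panel.column(snp_id)]
        y = y + eff * (g - g.mean())

    X = np.ones((n_subjects, 1))
    beta, se, p, usable = _linear_gwas(y, dosages, X)
    df = panel.variants[["snp", "chr", "bp", "a1", "a2"]].copy()
    df["beta"] = beta
    df["se"] = se
    df["p"] = p
    df["eaf"] = dosages.mean(axis=0) / 2.0
    df["n"] = n_subjects
    df["status"] = np.where(usable, "ok", "monomorphic")
    return SummaryStatTable(df, trait=trait)


def simulate_null_summary_stats(
    n_variants: int, n_samples: int, seed: int, trait: str = "null"
) -> SummaryStatTable:
    """Summary statistics for a trait with no genetic signal.

    Z-scores are standard normal, so p-values are exactly uniform —
    the chance baseline for overlap-enrichment and QQ calibration.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_variants)
    se = np.full(n_variants, 1.0 / math.sqrt(n_samples))
    df = pd.DataFrame(
        {
            "snp": [f"rs{i + 1}" for i in range(n_variants)],
            "chr": "1",
            "bp": np.arange(1, n_variants + 1, dtype=np.int64),
            "a1": "A",
            "a2": "G",
            "beta": z * se,
            "se": se,
            "p": 2.0 * stats.norm.sf(np.abs(z)),
            "eaf": 0.5,
            "n": n_samples,
        }
    )
    return SummaryStatTable(df, trait=trait)
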