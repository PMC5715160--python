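"""Polygenic scores and the crude-vs-adjusted mediation contrast.

A polygenic score (PGS) summarizes a subject's genetic predisposition for a
training trait as the weighted sum of effect-allele dosages, with weights
taken from training-GWAS betas after p-value thresholding and greedy LD
clumping. Regressing a downstream outcome (here COPD status or lung
function) on the PGS with and without smoking covariates discriminates the
two pleiotropy mechanisms: under the causal model (genotype -> smoking ->
outcome) adjustment removes the association; under the independent model it
leaves the coefficient essentially unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import CohortData, ReferencePanel, SummaryStatTable

__all__ = [
    "PGSModel",
    "AssociationResult",
    "ScoreResult",
    "ld_prune",
    "build_pgs_model",
    "score_cohort",
    "test_pgs_association",
    "mediation_contrast",
]

log = logging.getLogger(__name__)


@dataclass
class PGSModel:
    """A thresholded, LD-pruned set of scoring weights.

    ``entries`` columns: ``snp, a1, weight, p_train`` where ``weight`` is
    the training beta per copy of effect allele ``a1``.
    """

    trait: str
    p_threshold: float
    entries: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["snp", "a1", "weight", "p_train"]
        missing = [c for c in required if c not in self.entries.columns]
        if missing:
            raise ValueError(f"PGS entries missing columns: {missing}")
        if self.entries["snp"].duplicated().any():
            raise ValueError("duplicate variants in PGS model")
        if not np.isfinite(self.entries["weight"]).all():
            raise ValueError("non-finite PGS weights")
        self.entries = self.entries.reset_index(drop=True)

    @property
    def n_snps(self) -> int:
        return len(self.entries)

    def to_tsv(self, path: str | Path) -> None:
        out = self.entries.rename(
            columns={"snp": "SNP", "a1": "A1", "weight": "WEIGHT", "p_train": "P_TRAIN"}
        )
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, trait: str, p_threshold: float) -> "PGSModel":
        df = pd.read_csv(path, sep="\t", comment="#").rename(
            columns={"SNP": "snp", "A1": "a1", "WEIGHT": "weight", "P_TRAIN": "p_train"}
        )
        return cls(trait=trait, p_threshold=p_threshold, entries=df)


@dataclass
class AssociationResult:
    """One fitted score-outcome association."""

    beta: float
    se: float
    p_value: float
    n: int
    outcome: str
    covariates: tuple[str, ...]
    family: str  # "logistic" or "linear"


@dataclass
class ScoreResult:
    """Per-subject scores plus accounting of model variants not scored."""

    scores: np.ndarray
    n_used: int
    n_missing: int


def ld_prune(
    stats: SummaryStatTable,
    panel: ReferencePanel,
    r2_threshold: float = 0.2,
    window_bp: int = 250_000,
) -> set[str]:
    """Greedy p-value-ordered LD clumping.

    Variants are visited by ascending p (ties broken by ascending position
    then id, for determinism); a variant is retained iff its panel r^2 with
    every already-retained variant on the same chromosome within
    ``window_bp`` stays below ``r2_threshold``. Variants absent from the
    panel are dropped with a warning.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError("r2_threshold must lie in (0, 1]")
    df = stats.df.dropna(subset=["p"])
    absent = [s for s in df["snp"] if s not in panel]
    if absent:
        log.warning("ld_prune: dropped %d variant(s) absent from panel", len(absent))
        df = df[~df["snp"].isin(set(absent))]
    order = df.sort_values(["p", "bp", "snp"], kind="mergesort")

    retained: list[tuple[str, str, int]] = []  # (snp, chr, bp)
    for rec in order.itertuples(index=False):
        keep = True
        for snp_k, chr_k, bp_k in retained:
            if chr_k != rec.chr or abs(bp_k - rec.bp) > window_bp:
                continue
            if panel.r2(rec.snp, snp_k) >= r2_threshold:
                keep = False
                break
        if keep:
            retained.append((rec.snp, rec.chr, rec.bp))
    return {snp for snp, _, _ in retained}


def build_pgs_model(
    stats: SummaryStatTable, p_threshold: float, pruned: set[str]
) -> PGSModel:
    """Select pruned variants passing the p threshold as scoring weights."""
    if not pruned <= set(stats.df["snp"]):
        raise ValueError("pruned set contains variants absent from the table")
    df = stats.df[stats.df["snp"].isin(pruned) & (stats.df["p"] <= p_threshold)]
    if df.empty:
        raise ValueError(
            f"no variant survives p threshold {p_threshold:g} for trait {stats.trait!r}"
        )
    entries = df[["snp", "a1", "beta", "p"]].rename(
        columns={"beta": "weight", "p": "p_train"}
    )
    return PGSModel(trait=stats.trait, p_threshold=p_threshold, entries=entries)


def score_cohort(model: PGSModel, cohort: CohortData) -> ScoreResult:
    """Score subjects as the weighted dosage sum over model variants.

    Model variants missing from the cohort contribute zero and are counted
    (no mean imputation). Cohort dosage columns must count the same effect
    allele as the model weights; mismatched alleles raise.
    """
    scores = np.zeros(cohort.n_subjects)
    n_used = 0
    n_missing = 0
    cohort_a1 = dict(zip(cohort.variants["snp"], cohort.variants["a1"]))
    for rec in model.entries.itertuples(index=False):
        if rec.snp not in cohort:
            n_missing += 1
            continue
        if cohort_a1[rec.snp] != rec.a1:
            raise ValueError(
                f"effect-allele mismatch at {rec.snp}: model {rec.a1}, "
                f"cohort {cohort_a1[rec.snp]} (align both to the same panel)"
            )
        scores += rec.weight * cohort.dosage(rec.snp)
        n_used += 1
    if n_used == 0:
        raise ValueError("no overlap between PGS model and cohort variants")
    if n_missing:
        log.warning("score_cohort: %d model variant(s) missing from cohort", n_missing)
    return ScoreResult(scores=scores, n_used=n_used, n_missing=n_missing)


def _analysis_frame(
    scores: np.ndarray,
    cohort: CohortData,
    outcome: str,
    covariates: Sequence[str],
) -> pd.DataFrame:
    df = cohort.phenotypes[[outcome, *covariates]].copy()
    df.insert(0, "_score", scores)
    return df.dropna()


def _fit(
    frame: pd.DataFrame, outcome: str, covariates: Sequence[str]
) -> AssociationResult:
    y = frame[outcome].to_numpy(dtype=float)
    if np.std(y) < 1e-12:
        raise ValueError(f"outcome {outcome!r} is constant")
    score = frame["_score"].to_numpy(dtype=float)
    if np.std(score) < 1e-12:
        raise ValueError("score vector has no variance")
    X = np.column_stack(
        [score]
        + [frame[c].to_numpy(dtype=float) for c in covariates]
        + [np.ones(len(frame))]
    )
    binary = set(np.unique(y)) <= {0.0, 1.0}
    if binary:
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        if not np.isfinite(fit.bse[0]) or fit.bse[0] > 1e3:
            raise ValueError(
                "logistic fit unstable (possible perfect separation of outcome by score)"
            )
        family = "logistic"
    else:
        fit = sm.OLS(y, X).fit()
        family = "linear"
    return AssociationResult(
        beta=float(fit.params[0]),
        se=float(fit.bse[0]),
        p_value=float(fit.pvalues[0]),
        n=len(frame),
        outcome=outcome,
        covariates=tuple(covariates),
        family=family,
    )


def test_pgs_association(
    scores: np.ndarray | ScoreResult,
    cohort: CohortData,
    outcome: str,
    covariates: Sequence[str] = (),
) -> AssociationResult:
    """Regress an outcome on the PGS with additive covariates.

    Logistic regression for a binary (0/1) outcome, OLS otherwise; the
    reported coefficient is per raw score unit (log odds ratio for binary
    outcomes) with Wald standard error and p-value. Listwise deletion is
    applied; fewer than 10 remaining subjects raises.
    """
    if isinstance(scores, ScoreResult):
        scores = scores.scores
    frame = _analysis_frame(np.asarray(scores, dtype=float), cohort, outcome, covariates)
    if len(frame) < 10:
        raise ValueError("fewer than 10 subjects after listwise deletion")
    return _fit(frame, outcome, covariates)


def mediation_contrast(
    scores: np.ndarray | ScoreResult,
    cohort: CohortData,
    outcome: str,
    mediator_covariate_sets: Sequence[Sequence[str]],
) -> pd.DataFrame:
    """Crude vs mediator-adjusted PGS association contrast.

    The first covariate set is the crude model; every set is fitted on the
    identical subject set (listwise deletion over the union of covariates
    first), and each adjusted fit is reported with its attenuation ratio
    beta_adjusted / beta_crude. A ratio near 1 indicates the association is
    not mediated by the adjusted covariates (independent pleiotropy); a
    ratio near 0 indicates full mediation (causal pleiotropy).
    """
    if len(mediator_covariate_sets) < 2:
        raise ValueError("need at least two covariate sets (crude first)")
    if isinstance(scores, ScoreResult):
        scores = scores.scores
    union: list[str] = []
    for cs in mediator_covariate_sets:
        for c in cs:
            if c not in union:
                union.append(c)
    frame = _analysis_frame(np.asarray(scores, dtype=float), cohort, outcome, union)
    if len(frame) < 10:
        raise ValueError("fewer than 10 subjects after listwise deletion")

    rows = []
    beta_crude: float | None = None
    for i, cs in enumerate(mediator_covariate_sets):
        res = _fit(frame, outcome, list(cs))
        if i == 0:
            beta_crude = res.beta
            ratio = np.nan
        else:
            ratio = res.beta / beta_crude if beta_crude != 0 else np.nan
        rows.append(
            {
                "model": "crude" if i == 0 else f"adjusted_{i}",
                "covariates": ",".join(cs),
                "beta": res.beta,
                "se": res.se,
                "p_value": res.p_value,
                "n": res.n,
                "family": res.family,
                "attenuation_ratio": ratio,
            }
        )
    return pd.DataFrame(rows)
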