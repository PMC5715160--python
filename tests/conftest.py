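"""Shared fixtures: small panels, cohorts, and table constructors."""

import numpy as np
import pandas as pd
import pytest

from pleioscan import (
    PairedStatTable,
    PanelSpec,
    ReferencePanel,
    ScenarioSpec,
    SummaryStatTable,
    simulate_cohort,
    simulate_reference_panel,
)


@pytest.fixture(scope="session")
def small_panel() -> ReferencePanel:
    """4 LD blocks x 8 variants, moderate within-block correlation."""
    return simulate_reference_panel(
        PanelSpec(
            n_blocks=4,
            block_size=8,
            within_block_correlation=0.4,
            maf_range=(0.1, 0.5),
            n_haplotypes=1500,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def independent_cohort(small_panel) -> "CohortData":
    return simulate_cohort(
        small_panel,
        ScenarioSpec(
            model="independent",
            n_nd_causal=8,
            n_subjects_per_cohort=2500,
            seed=21,
            architecture_seed=5,
        ),
    )


@pytest.fixture(scope="session")
def causal_cohort(small_panel) -> "CohortData":
    return simulate_cohort(
        small_panel,
        ScenarioSpec(
            model="causal",
            n_nd_causal=8,
            n_subjects_per_cohort=2500,
            seed=22,
            architecture_seed=5,
        ),
    )


def make_stats(
    snps,
    p,
    beta=None,
    trait="trait",
    a1="A",
    a2="G",
    chrom="1",
    bp=None,
    se=0.1,
) -> SummaryStatTable:
    """Build a summary-stat table from parallel lists (scalars broadcast)."""
    n = len(snps)

    def col(x):
        return list(x) if isinstance(x, (list, tuple, np.ndarray)) else [x] * n

    df = pd.DataFrame(
        {
            "snp": list(snps),
            "chr": col(chrom),
            "bp": list(bp) if bp is not None else list(range(1, n + 1)),
            "a1": col(a1),
            "a2": col(a2),
            "beta": col(beta if beta is not None else 0.1),
            "se": col(se),
            "p": col(p),
            "eaf": 0.3,
            "n": 1000,
        }
    )
    return SummaryStatTable(df, trait=trait)


def make_paired(beta_a, beta_b, p_a, p_b, trait_a="a", trait_b="b") -> PairedStatTable:
    """Build a paired table from parallel arrays."""
    n = len(beta_a)
    df = pd.DataFrame(
        {
            "snp": [f"rs{i + 1}" for i in range(n)],
            "a1": "A",
            "beta_a": list(beta_a),
            "se_a": 0.1,
            "p_a": list(p_a),
            "beta_b": list(beta_b),
            "se_b": 0.1,
            "p_b": list(p_b),
        }
    )
    return PairedStatTable(df, trait_a=trait_a, trait_b=trait_b)


def toy_panel(allele_pairs, bp_step=100, n_haplotypes=400, seed=0) -> ReferencePanel:
    """Hand-built panel with chosen allele pairs and independent variants."""
    rng = np.random.default_rng(seed)
    n = len(allele_pairs)
    variants = pd.DataFrame(
        {
            "snp": [f"rs{i + 1}" for i in range(n)],
            "chr": "1",
            "bp": [1 + i * bp_step for i in range(n)],
            "a1": [a for a, _ in allele_pairs],
            "a2": [b for _, b in allele_pairs],
            "block": 0,
        }
    )
    haplotypes = (rng.random((n_haplotypes, n)) < 0.4).astype(np.int8)
    return ReferencePanel(variants, haplotypes)
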