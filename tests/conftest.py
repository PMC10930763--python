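"""Shared fixtures: synthetic cohorts at several scales and one fully
cross-validated gene model reused by the evaluation tests."""

import numpy as np
import pandas as pd
import pytest

import histomark as hm
from histomark import amil, pipeline


@pytest.fixture(scope="session")
def default_cohort():
    """The reference synthetic cohort: n=200, D=32, K=64, 30% informative
    patches at noise sd 0.1, one harmful planted gene."""
    return hm.generate_cohort(hm.CohortConfig(seed=0))


@pytest.fixture(scope="session")
def tiny_cohort():
    """A 60-sample cohort for fast determinism and bookkeeping checks."""
    return hm.generate_cohort(
        hm.CohortConfig(n_samples=60, n_sites=6, patches_per_bag=16, seed=7)
    )


@pytest.fixture(scope="session")
def null_cohort():
    """Survival independent of expression and covariates (all effects zero)."""
    cfg = hm.CohortConfig(
        seed=11, cox_coefficients=(0.0,) * 6
    )
    return hm.generate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_gene_cv(default_cohort):
    """Cross-validated AMIL models for the planted prognostic gene, under
    site-preserved quantile-balanced folds and the small-cohort training
    schedule; shared by predictability, attention and surrogate tests."""
    c = default_cohort
    gene = c.expression.genes[0]
    y = c.expression.gene(gene).to_numpy()
    assignment = pipeline.make_fold_assignment(c.clinical, y, seed=0)
    cv = pipeline.crossval_gene_model(
        c.bags, y, c.expression.samples, assignment,
        amil.small_cohort_config(), gene=gene,
    )
    return {"cohort": c, "gene": gene, "targets": y, "assignment": assignment, "cv": cv}


@pytest.fixture(scope="session")
def stain_tiles():
    return hm.synthetic.generate_tiles(seed=2)
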