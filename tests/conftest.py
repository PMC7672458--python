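"""Shared fixtures: synthetic annotations and fitted localization tables.

Session scope keeps the 2000-gene simulations shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from fracloc import (
    EffectModel,
    LocalizationModel,
    gene_metrics_table,
    make_toy_annotation,
    null_effect,
    simulate_fracseq_counts,
)
from fracloc.simdata import GeneClassTemplate

ANNOTATION_SEED = 1


@pytest.fixture(scope="session")
def annotation2000():
    return make_toy_annotation(seed=ANNOTATION_SEED)


@pytest.fixture(scope="session")
def metrics2000(annotation2000):
    return gene_metrics_table(annotation2000)


@pytest.fixture(scope="session")
def small_annotation():
    templates = [
        (GeneClassTemplate("histone_like", np.log(800), 0.25), 10),
        (
            GeneClassTemplate(
                "long_multiexon", np.log(20_000), 0.7, exon_count_law=("poisson1", 6.0),
                transcripts_per_gene_law=("poisson1", 0.8),
            ),
            20,
        ),
        (GeneClassTemplate("mito", np.log(1200), 0.3, chromosome_pool=("chrM",)), 3),
    ]
    return make_toy_annotation(templates, seed=7)


def _fit(annotation, metrics, effect, seed):
    exp = simulate_fracseq_counts(annotation, effect, replicates=3, seed=seed)
    model = LocalizationModel(
        exp,
        exonic_lengths=metrics["exonic_length"],
        chromosomes=metrics["chromosome"],
    )
    res = model.fit(contrast=("nuclear", "cytoplasmic"), kd_condition="KD_A")
    return exp, model, res


@pytest.fixture(scope="session")
def default_fit(annotation2000, metrics2000):
    """Default effect model: experiment, model and fitted N/C results."""
    return _fit(annotation2000, metrics2000, EffectModel(), seed=2)


@pytest.fixture(scope="session")
def null_fit(annotation2000, metrics2000):
    """Null effect model (no localization shift, no destabilization)."""
    return _fit(annotation2000, metrics2000, null_effect(), seed=2025)


@pytest.fixture(scope="session")
def pure_length_fit(annotation2000, metrics2000):
    """Length-only effect (beta_E = 0): exon count carries no true signal."""
    return _fit(annotation2000, metrics2000, EffectModel(beta_E=0.0), seed=5)
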