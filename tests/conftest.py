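"""Shared fixtures and helpers for the test suite.

All studies are generated programmatically by the simulator; nothing here
touches the network or external data.
"""

from __future__ import annotations

import numpy as np
import pytest

from mrbiome import (
    HarmonizedSet,
    HarmonizedSnp,
    MendelianRandomization,
    SimulationScenario,
    load_taxa_registry,
    simulate_study,
)


def make_hset(
    beta_exp, se_exp, beta_out, se_out, rsids=None, exposure="exp", outcome="out"
) -> HarmonizedSet:
    """Build a HarmonizedSet directly from effect arrays."""
    n = len(beta_exp)
    rsids = rsids or [f"rs{i:04d}" for i in range(n)]
    snps = [
        HarmonizedSnp(
            rsid=rsids[i],
            beta_exp=float(beta_exp[i]),
            se_exp=float(se_exp[i]),
            beta_out=float(beta_out[i]),
            se_out=float(se_out[i]),
        )
        for i in range(n)
    ]
    return HarmonizedSet(exposure_id=exposure, outcome_id=outcome, snps=snps)


def study_model(study) -> MendelianRandomization:
    """Model built straight from a simulated study's aligned records."""
    return MendelianRandomization(
        beta_exposure=[r.beta for r in study.exposure],
        se_exposure=[r.se for r in study.exposure],
        beta_outcome=[r.beta for r in study.outcome],
        se_outcome=[r.se for r in study.outcome],
        rsids=[r.rsid for r in study.exposure],
    )


@pytest.fixture(scope="session")
def registry():
    return load_taxa_registry()


@pytest.fixture()
def causal_study():
    """One seeded study with a clear causal signal (theta = 0.3, 15 SNPs)."""
    return simulate_study(SimulationScenario(theta=0.3, seed=11))


@pytest.fixture()
def null_study():
    return simulate_study(SimulationScenario(theta=0.0, seed=12))
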