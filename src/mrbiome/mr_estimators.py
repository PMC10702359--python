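"""Functional estimator surface over :class:`mrbiome.model.MendelianRandomization`.

Each function accepts a :class:`mrbiome.harmonization.HarmonizedSet` (or a
single harmonized SNP for the Wald ratio) and returns an
:class:`mrbiome.model.MRResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .harmonization import HarmonizedSet, HarmonizedSnp
from .model import EstimationError, MendelianRandomization, MRResults

__all__ = [
    "EstimatorConfig",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "weighted_mode",
    "mr_presso",
    "run_all_estimators",
]


@dataclass
class EstimatorConfig:
    """Stochastic-method defaults (bootstrap/simulation sizes and the seed)."""

    n_boot: int = 5000
    n_sim_presso: int = 1000
    presso_outlier_p: float = 0.05
    seed: int = 42
    ivw_model: str = "mre"  # "mre" | "fe"
    bandwidth_factor: float = 1.0


def _model(hset: HarmonizedSet) -> MendelianRandomization:
    return MendelianRandomization.from_harmonized(hset)


def wald_ratio(snp: HarmonizedSnp) -> MRResults:
    """Single-instrument causal estimate beta_out/beta_exp with first-order SE."""
    if snp.beta_exp == 0:
        raise EstimationError("beta_exposure of 0 yields an undefined ratio")
    m = MendelianRandomization(
        [snp.beta_exp], [snp.se_exp], [snp.beta_out], [snp.se_out], rsids=[snp.rsid]
    )
    return m.fit_wald_ratio()


def ivw(hset: HarmonizedSet, model: str = "mre") -> MRResults:
    return _model(hset).fit_ivw(model=model)


def egger(hset: HarmonizedSet) -> MRResults:
    return _model(hset).fit_egger()


def weighted_median(
    hset: HarmonizedSet, n_boot: int = 5000, seed: int = 42
) -> MRResults:
    return _model(hset).fit_weighted_median(n_boot=n_boot, seed=seed)


def weighted_mode(
    hset: HarmonizedSet,
    bandwidth_factor: float = 1.0,
    n_boot: int = 5000,
    seed: int = 42,
) -> MRResults:
    return _model(hset).fit_weighted_mode(
        bandwidth_factor=bandwidth_factor, n_boot=n_boot, seed=seed
    )


def mr_presso(
    hset: HarmonizedSet,
    n_sim: int = 1000,
    seed: int = 42,
    outlier_p: float = 0.05,
) -> MRResults:
    return _model(hset).fit_presso(n_sim=n_sim, seed=seed, outlier_p=outlier_p)


def run_all_estimators(
    source: HarmonizedSet | MendelianRandomization,
    config: EstimatorConfig | None = None,
) -> list[MRResults]:
    """Fit every method the SNP count supports.

    J=1: Wald ratio only. J=2: IVW only. J>=3 adds Egger, weighted median and
    weighted mode; J>=4 adds MR-PRESSO. The IVW (or single-SNP Wald ratio)
    result is flagged primary. An empty set yields an empty list (the caller
    emits a skip record).
    """
    cfg = config or EstimatorConfig()
    if isinstance(source, MendelianRandomization):
        m = source
    else:
        if source.n_snp == 0:
            return []
        m = _model(source)
    if m.n_snp == 1:
        return [m.fit_wald_ratio()]
    results = [m.fit_ivw(model=cfg.ivw_model)]
    if m.n_snp >= 3:
        results.append(m.fit_egger())
        results.append(m.fit_weighted_median(n_boot=cfg.n_boot, seed=cfg.seed))
        results.append(
            m.fit_weighted_mode(
                bandwidth_factor=cfg.bandwidth_factor,
                n_boot=cfg.n_boot,
                seed=cfg.seed,
            )
        )
    if m.n_snp >= 4:
        results.append(
            m.fit_presso(
                n_sim=cfg.n_sim_presso,
                seed=cfg.seed,
                outlier_p=cfg.presso_outlier_p,
                ivw_model=cfg.ivw_model,
            )
        )
    return results
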