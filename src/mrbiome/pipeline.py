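"""Orchestration of the bidirectional analysis across taxon-outcome pairs:
instrument selection -> harmonization -> estimation -> sensitivity, followed
by per-taxonomic-level multiplicity control and significance tiers.

Multiplicity convention
-----------------------
The Bonferroni divisor for a row is the number of analyzable (non-unknown)
taxa at the microbial trait's taxonomic level — the exposure's level in the
forward direction, the outcome's level in the reverse direction. With the
packaged registry that is phylum 9, class 16, order 20, family 32 and genus
119. Benjamini-Hochberg FDR is applied within the same family (direction x
method x level x non-microbial trait).

Tiers: ``significant`` iff the Bonferroni-adjusted p < 0.05; ``suggestive``
iff the raw p < 0.05 but the adjusted one is not; ``null`` otherwise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from . import __version__
from .harmonization import harmonize_effects
from .instrument_selection import (
    InstrumentSet,
    SelectionConfig,
    build_instrument_set,
)
from .mr_estimators import EstimatorConfig, run_all_estimators
from .sensitivity import SensitivityReport, sensitivity_report
from .summary_stats import (
    AssociationRow,
    GwasRecord,
    LdMatrix,
    TaxonInfo,
    analyzable_taxa,
    level_counts,
    load_taxa_registry,
    write_association_table,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# multiplicity control
# ---------------------------------------------------------------------------


def bonferroni_adjust(pval: float, n_tests: int) -> float:
    """min(1, p x n) where n is the analyzable-taxa count at the trait's
    taxonomic level."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, pval * n_tests)


def fdr_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    if len(pvals) == 0:
        raise ValueError("fdr_adjust needs at least one p-value")
    _, adjusted, _, _ = multipletests(list(pvals), method="fdr_bh")
    return [float(p) for p in adjusted]


def classify_tier(pval: float, p_bonferroni: float) -> str:
    if not (0.0 <= pval <= 1.0 and 0.0 <= p_bonferroni <= 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    if p_bonferroni < 0.05:
        return "significant"
    if pval < 0.05:
        return "suggestive"
    return "null"


# ---------------------------------------------------------------------------
# trait containers and configuration
# ---------------------------------------------------------------------------


@dataclass
class TraitData:
    """Summary statistics plus metadata for one trait.

    ``level`` is set for microbial traits (phylum..genus) and None for the
    pancreatitis phenotypes."""

    trait_id: str
    records: list[GwasRecord]
    level: str | None = None


@dataclass
class PipelineConfig:
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    estimators: EstimatorConfig = field(default_factory=EstimatorConfig)
    seed: int = 42

    def __post_init__(self) -> None:
        self.estimators.seed = self.seed


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _bonferroni_n(
    level: str | None, registry_counts: Mapping[str, int]
) -> int:
    if level is None:
        return 1
    return max(1, registry_counts.get(level, 1))


def _skip_row(exposure, outcome, direction, level) -> AssociationRow:
    return AssociationRow(
        exposure=exposure,
        outcome=outcome,
        direction=direction,
        level=level,
        method="none",
        n_snp=0,
        beta=None,
        se=None,
        or_value=None,
        ci_low=None,
        ci_high=None,
        pval=None,
        tier=None,
    )


def run_pair(
    exposure: TraitData,
    outcome: TraitData,
    ld: LdMatrix | None,
    blacklist: Mapping[str, str] | set | None,
    config: PipelineConfig,
    direction: str,
) -> tuple[list[AssociationRow], InstrumentSet, SensitivityReport | None]:
    """One exposure-outcome analysis; returns the (unadjusted) rows, the
    audited instrument set, and the sensitivity report (None if < 2 SNPs)."""
    level = exposure.level if direction == "forward" else outcome.level
    iset = build_instrument_set(
        exposure.records,
        ld=ld,
        blacklist=blacklist,
        config=config.selection,
        exposure_id=exposure.trait_id,
    )
    if iset.no_instruments:
        logger.info(
            "%s -> %s: no instruments survive selection", exposure.trait_id,
            outcome.trait_id,
        )
        return (
            [_skip_row(exposure.trait_id, outcome.trait_id, direction, level)],
            iset,
            None,
        )
    hset = harmonize_effects(
        iset.records, outcome.records, iset.exposure_id, outcome.trait_id
    )
    if hset.n_snp == 0:
        return (
            [_skip_row(exposure.trait_id, outcome.trait_id, direction, level)],
            iset,
            None,
        )
    results = run_all_estimators(hset, config.estimators)
    presso = next((r for r in results if r.method == "presso_corrected"), None)
    report = (
        sensitivity_report(hset, presso=presso, ivw_model=config.estimators.ivw_model)
        if hset.n_snp >= 2
        else None
    )
    rows = []
    for res in results:
        rows.append(
            AssociationRow(
                exposure=exposure.trait_id,
                outcome=outcome.trait_id,
                direction=direction,
                level=level,
                method=res.method,
                n_snp=res.n_snp,
                beta=res.beta,
                se=res.se,
                or_value=res.or_value,
                ci_low=res.or_ci[0],
                ci_high=res.or_ci[1],
                pval=res.pval,
            )
        )
    return rows, iset, report


def adjust_rows(
    rows: list[AssociationRow], registry_counts: Mapping[str, int]
) -> None:
    """Fill p_bonferroni / p_fdr / tier in place.

    Bonferroni multiplies each row's own p by the analyzable-taxa count at
    the row's level; BH runs within (direction, method, level, partner trait)
    families."""
    for row in rows:
        if row.pval is None:
            continue
        row.p_bonferroni = bonferroni_adjust(
            row.pval, _bonferroni_n(row.level, registry_counts)
        )
        row.tier = classify_tier(row.pval, row.p_bonferroni)
    families: dict[tuple, list[AssociationRow]] = {}
    for row in rows:
        if row.pval is None:
            continue
        partner = row.outcome if row.direction == "forward" else row.exposure
        families.setdefault(
            (row.direction, row.method, row.level, partner), []
        ).append(row)
    for members in families.values():
        adjusted = fdr_adjust([r.pval for r in members])
        for row, p in zip(members, adjusted):
            row.p_fdr = p


def run_direction(
    exposures: Sequence[TraitData],
    outcomes: Sequence[TraitData],
    ld: LdMatrix | None,
    blacklist: Mapping[str, str] | set | None,
    config: PipelineConfig,
    registry: Sequence[TaxonInfo] | None = None,
    direction: str = "forward",
) -> tuple[list[AssociationRow], dict]:
    """All exposure x outcome analyses in one direction, with multiplicity
    control applied. Returns (rows, audit summary)."""
    registry = registry if registry is not None else load_taxa_registry()
    counts = level_counts(analyzable_taxa(registry))
    rows: list[AssociationRow] = []
    audit = {"pairs": 0, "skipped": 0, "filter_exclusions": 0}
    for exp in exposures:
        for out in outcomes:
            pair_rows, iset, _ = run_pair(exp, out, ld, blacklist, config, direction)
            audit["pairs"] += 1
            audit["filter_exclusions"] += len(iset.audit)
            if pair_rows and pair_rows[0].method == "none":
                audit["skipped"] += 1
            rows.extend(pair_rows)
    adjust_rows(rows, counts)
    return rows, audit


def run_bidirectional(
    microbial_traits: Sequence[TraitData],
    pancreatitis_traits: Sequence[TraitData],
    ld: LdMatrix | None = None,
    blacklist: Mapping[str, str] | set | None = None,
    config: PipelineConfig | None = None,
    registry: Sequence[TaxonInfo] | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Forward (taxa -> pancreatitis) and reverse (pancreatitis -> taxa)
    analyses with identical machinery, plus a run manifest.

    When ``out_dir`` is given, writes forward.tsv, reverse.tsv and
    manifest.json there."""
    config = config or PipelineConfig()
    forward, audit_f = run_direction(
        microbial_traits, pancreatitis_traits, ld, blacklist, config,
        registry, "forward",
    )
    reverse, audit_r = run_direction(
        pancreatitis_traits, microbial_traits, ld, blacklist, config,
        registry, "reverse",
    )
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            **asdict(config.selection),
            "n_boot": config.estimators.n_boot,
            "n_sim_presso": config.estimators.n_sim_presso,
            "presso_outlier_p": config.estimators.presso_outlier_p,
            "ivw_model": config.estimators.ivw_model,
        },
        "forward_audit": audit_f,
        "reverse_audit": audit_r,
        "forward_rows": len(forward),
        "reverse_rows": len(reverse),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_association_table(forward, out_dir / "forward.tsv")
        write_association_table(reverse, out_dir / "reverse.tsv")
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"forward": forward, "reverse": reverse, "manifest": manifest}
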