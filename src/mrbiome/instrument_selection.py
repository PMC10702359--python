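"""Instrument selection for one exposure: p-value screen, LD clumping,
confounder blacklist, and instrument-strength (F, R²) filtering.

The filter cascade runs in a fixed, logged order:
p-screen -> clump -> blacklist -> per-SNP F computation with F < 10 exclusion.
Every removed SNP is audited as ``(rsid, filter, reason)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .summary_stats import GwasRecord, LdMatrix


@dataclass
class SelectionConfig:
    """Thresholds of the instrument-selection cascade."""

    iv_p_threshold: float = 1e-5
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    min_f: float = 10.0


@dataclass
class InstrumentSet:
    """Instruments surviving all filters, with per-SNP strength metrics."""

    exposure_id: str
    records: list[GwasRecord] = field(default_factory=list)
    per_snp_f: dict[str, float] = field(default_factory=dict)
    per_snp_r2: dict[str, float] = field(default_factory=dict)
    aggregate_f: float | None = None
    audit: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def no_instruments(self) -> bool:
        return len(self.records) == 0

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.records]


def select_by_pvalue(
    records: Iterable[GwasRecord], threshold: float = 1e-5
) -> list[GwasRecord]:
    """Keep records with p strictly below the threshold (default 1e-5, the
    inclusive genome-wide screen used for microbiome exposures)."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("p-value threshold must lie in (0, 1]")
    return [r for r in records if r.pval < threshold]


def clump(
    records: Sequence[GwasRecord],
    ld: LdMatrix | None,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000.0,
    audit: list[tuple[str, str, str]] | None = None,
) -> list[GwasRecord]:
    """Greedy LD clumping.

    Candidates are taken in ascending-p order (ties broken lexicographically
    by rsid); each index SNP removes every remaining SNP on the same
    chromosome within ``window_kb`` whose r² against it is >= the threshold.
    Pairs absent from the LD matrix count as r² = 0 (linkage equilibrium).
    Records without chrom/pos cannot be window-tested and are excluded with
    an audit entry. Output is in (p, rsid) order, so the result is invariant
    to input row order.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError("r2 threshold must lie in (0, 1]")
    usable: list[GwasRecord] = []
    for rec in records:
        if rec.chrom is None or rec.pos is None:
            if audit is not None:
                audit.append((rec.rsid, "clump", "missing chrom/pos"))
        else:
            usable.append(rec)
    pool = sorted(usable, key=lambda r: (r.pval, r.rsid))
    kept: list[GwasRecord] = []
    window_bp = window_kb * 1000.0
    while pool:
        index = pool.pop(0)
        kept.append(index)
        survivors = []
        for rec in pool:
            same_window = (
                rec.chrom == index.chrom and abs(rec.pos - index.pos) <= window_bp
            )
            r2 = ld.r2_between(index.rsid, rec.rsid) if ld is not None else 0.0
            if same_window and r2 >= r2_threshold:
                if audit is not None:
                    audit.append(
                        (rec.rsid, "clump", f"r2={r2:.4g} with index {index.rsid}")
                    )
            else:
                survivors.append(rec)
        pool = survivors
    return kept


def apply_blacklist(
    records: Iterable[GwasRecord],
    blacklist: Mapping[str, str] | set,
    audit: list[tuple[str, str, str]] | None = None,
) -> list[GwasRecord]:
    """Remove SNPs on the confounder blacklist (static stand-in for
    interactive variant-phenotype lookups)."""
    kept = []
    for rec in records:
        if rec.rsid in blacklist:
            if audit is not None:
                trait = (
                    blacklist[rec.rsid]
                    if isinstance(blacklist, Mapping)
                    else "blacklisted"
                )
                audit.append((rec.rsid, "blacklist", f"confounder: {trait}"))
        else:
            kept.append(rec)
    return kept


def snp_f_statistic(record: GwasRecord) -> float:
    """Per-SNP instrument strength F = beta² / se²."""
    return record.beta**2 / record.se**2


def snp_variance_explained(record: GwasRecord) -> float:
    """Per-SNP variance explained,
    R² = 2f(1-f)β² / (2f(1-f)β² + 2f(1-f)·n·se²),
    which simplifies to β²/(β² + n·se²). The full form is evaluated; the two
    agree to machine precision.
    """
    if record.eaf is None or record.n is None:
        raise ValueError(f"{record.rsid}: EAF and n required for R²")
    f = record.eaf
    num = 2.0 * f * (1.0 - f) * record.beta**2
    den = num + 2.0 * f * (1.0 - f) * record.n * record.se**2
    return num / den


def aggregate_f_statistic(
    r2_total: float, n: int, k: int, literal: bool = False
) -> float:
    """Multi-instrument F for total variance explained ``r2_total`` with
    exposure sample size ``n`` and ``k`` instruments:
    F = (R²/(1-R²)) · ((n-k-1)/k).

    ``literal=True`` evaluates the algebraically inconsistent expression
    (n-k-1)²/(1-R²) that sometimes circulates in print, for audit only.
    """
    if not (0.0 <= r2_total < 1.0):
        raise ValueError("total R² must lie in [0, 1)")
    if n <= k + 1 or k < 1:
        raise ValueError("need n > k+1 >= 2")
    if literal:
        return (n - k - 1) ** 2 / (1.0 - r2_total)
    return (r2_total / (1.0 - r2_total)) * ((n - k - 1) / k)


def build_instrument_set(
    records: Sequence[GwasRecord],
    ld: LdMatrix | None = None,
    blacklist: Mapping[str, str] | set | None = None,
    config: SelectionConfig | None = None,
    exposure_id: str = "exposure",
) -> InstrumentSet:
    """Run the full selection cascade and return the audited instrument set.

    Zero survivors is not an error: the set comes back empty and flagged so
    the calling pipeline can emit a skip record for the pair.
    """
    cfg = config or SelectionConfig()
    iset = InstrumentSet(exposure_id=exposure_id)
    passed_p = []
    for rec in records:
        if rec.pval < cfg.iv_p_threshold:
            passed_p.append(rec)
        else:
            iset.audit.append(
                (rec.rsid, "p_screen", f"p={rec.pval:.3g} >= {cfg.iv_p_threshold:g}")
            )
    clumped = clump(
        passed_p, ld, cfg.clump_r2, cfg.clump_window_kb, audit=iset.audit
    )
    unconfounded = apply_blacklist(clumped, blacklist or {}, audit=iset.audit)
    for rec in unconfounded:
        f_stat = snp_f_statistic(rec)
        if f_stat < cfg.min_f:
            iset.audit.append(
                (rec.rsid, "f_filter", f"weak instrument (F={f_stat:.2f})")
            )
            continue
        iset.records.append(rec)
        iset.per_snp_f[rec.rsid] = f_stat
        if rec.eaf is not None and rec.n is not None:
            iset.per_snp_r2[rec.rsid] = snp_variance_explained(rec)
    if iset.records and len(iset.per_snp_r2) == len(iset.records):
        r2_total = sum(iset.per_snp_r2.values())
        n = min(r.n for r in iset.records if r.n is not None)
        k = len(iset.records)
        if r2_total < 1.0 and n > k + 1:
            iset.aggregate_f = aggregate_f_statistic(r2_total, n, k)
    return iset
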