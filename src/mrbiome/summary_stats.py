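"""Data model and I/O for GWAS summary statistics, taxa registries, LD matrices
and association result tables.

The on-disk dialect is plain tab-separated text with a header row; missing
values are written as ``.`` (an empty field is also accepted on read).
Coordinates follow the 1-based, build-37 convention with chromosome labels as
strings ("1".."22", "X"); no liftover is performed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
TAXONOMIC_LEVELS = ("phylum", "class", "order", "family", "genus")

#: canonical column order of the association-table dialect
ASSOCIATION_COLUMNS = (
    "exposure",
    "outcome",
    "direction",
    "level",
    "method",
    "n_snp",
    "beta",
    "se",
    "or",
    "ci_low",
    "ci_high",
    "pval",
    "p_bonferroni",
    "p_fdr",
    "tier",
)

MISSING = "."


class SummaryStatsError(Exception):
    """Fatal configuration or file-format error."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GwasRecord:
    """One SNP's summary association with one trait.

    ``beta`` is the additive per-effect-allele effect; for case-control traits
    it is on the log-odds scale. ``eaf``, ``chrom``, ``pos`` and ``n`` are
    optional at read time but required by the operations that use them
    (variance explained, clumping windows).
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    chrom: str | None = None
    pos: int | None = None
    n: int | None = None

    def validation_error(self) -> str | None:
        """Return a one-line reason if any invariant fails, else None."""
        if not self.rsid:
            return "empty rsid"
        if self.effect_allele not in VALID_BASES:
            return f"invalid effect allele {self.effect_allele!r}"
        if self.other_allele not in VALID_BASES:
            return f"invalid other allele {self.other_allele!r}"
        if self.effect_allele == self.other_allele:
            return "identical alleles"
        if not math.isfinite(self.beta):
            return "non-finite beta"
        if not (math.isfinite(self.se) and self.se > 0):
            return "nonpositive SE"
        if not (0.0 < self.pval <= 1.0):
            return "p-value outside (0, 1]"
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            return "EAF outside (0, 1)"
        if self.n is not None and self.n <= 0:
            return "nonpositive sample size"
        return None


@dataclass(frozen=True)
class TaxonInfo:
    """One microbial trait in the exposure registry."""

    taxon_id: str
    level: str
    name: str
    is_unknown: bool = False

    def __post_init__(self) -> None:
        if self.level not in TAXONOMIC_LEVELS:
            raise SummaryStatsError(
                f"unknown taxonomic level {self.level!r} for {self.taxon_id}"
            )


@dataclass(frozen=True)
class TraitInfo:
    """Study-level metadata for one exposure or outcome trait."""

    trait_id: str
    trait_type: str  # "exposure" | "outcome"
    n_total: int
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("exposure", "outcome"):
            raise SummaryStatsError(f"bad trait_type {self.trait_type!r}")
        if self.n_cases is not None and self.n_controls is not None:
            if self.n_cases + self.n_controls != self.n_total:
                raise SummaryStatsError(
                    f"{self.trait_id}: n_cases + n_controls != n_total"
                )


@dataclass
class LdMatrix:
    """Squared-correlation (r²) matrix over an ordered set of SNPs."""

    rsids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.rsids)
        if self.r2.shape != (k, k):
            raise SummaryStatsError("LD matrix shape does not match rsid count")
        if k and not np.allclose(np.diag(self.r2), 1.0):
            raise SummaryStatsError("LD matrix diagonal must be 1")
        if not np.allclose(self.r2, self.r2.T):
            raise SummaryStatsError("LD matrix must be symmetric")
        if k and (self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12):
            raise SummaryStatsError("LD r² values must lie in [0, 1]")
        self._index = {rsid: i for i, rsid in enumerate(self.rsids)}

    def r2_between(self, a: str, b: str) -> float:
        """r² between two SNPs; pairs absent from the matrix are treated as
        linkage equilibrium (r² = 0)."""
        if a == b:
            return 1.0
        ia = self._index.get(a)
        ib = self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r2[ia, ib])

    @classmethod
    def identity(cls, rsids: Sequence[str]) -> "LdMatrix":
        return cls(list(rsids), np.eye(len(rsids)))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "LdMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        rsids = [str(r) for r in df.index]
        if list(df.columns) != rsids:
            raise SummaryStatsError("LD matrix header row/column disagree")
        return cls(rsids, df.to_numpy(dtype=float))

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.r2, index=self.rsids, columns=self.rsids).to_csv(
            path, sep="\t", index_label="rsid"
        )


# ---------------------------------------------------------------------------
# summary-statistic tables
# ---------------------------------------------------------------------------

_MANDATORY = ("rsid", "effect_allele", "other_allele", "beta", "se", "pval")
_OPTIONAL = ("eaf", "chrom", "pos", "n")


def _parse_float(value) -> float | None:
    if value is None:
        return None
    s = str(value).strip()
    if s in ("", MISSING, "nan", "NA"):
        return None
    return float(s)


def _parse_chrom(value) -> str | None:
    if value is None:
        return None
    s = str(value).strip()
    if s in ("", MISSING, "nan", "NA"):
        return None
    return s


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    return_rejected: bool = False,
):
    """Read a tab-separated summary-statistics table into validated records.

    ``column_map`` maps canonical names (rsid, effect_allele, ...) to the
    file's column names. Rows failing any invariant are rejected and logged
    with exactly one reason; all copies of a duplicated rsid are dropped.

    Returns the list of records, or ``(records, rejected)`` where ``rejected``
    is a list of ``(rsid, reason)`` when ``return_rejected`` is true.
    """
    path = Path(path)
    if not path.exists():
        raise SummaryStatsError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        raise SummaryStatsError(f"empty summary-statistics file: {path}")
    colmap = dict(column_map or {})
    for canon in _MANDATORY:
        source = colmap.get(canon, canon)
        if source not in df.columns:
            raise SummaryStatsError(
                f"mandatory column {canon!r} (file column {source!r}) missing"
            )

    def get(row, canon):
        source = colmap.get(canon, canon)
        return row.get(source) if source in df.columns else None

    records: list[GwasRecord] = []
    rejected: list[tuple[str, str]] = []
    for _, row in df.iterrows():
        rsid = str(get(row, "rsid")).strip()
        try:
            pos_raw = _parse_float(get(row, "pos"))
            n_raw = _parse_float(get(row, "n"))
            rec = GwasRecord(
                rsid=rsid,
                effect_allele=str(get(row, "effect_allele")).strip().upper(),
                other_allele=str(get(row, "other_allele")).strip().upper(),
                beta=_parse_float(get(row, "beta")),
                se=_parse_float(get(row, "se")),
                pval=_parse_float(get(row, "pval")),
                eaf=_parse_float(get(row, "eaf")),
                chrom=_parse_chrom(get(row, "chrom")),
                pos=int(pos_raw) if pos_raw is not None else None,
                n=int(n_raw) if n_raw is not None else None,
            )
        except (TypeError, ValueError) as exc:
            rejected.append((rsid, f"unparseable field ({exc})"))
            continue
        if rec.beta is None or rec.se is None or rec.pval is None:
            rejected.append((rsid, "missing mandatory value"))
            continue
        reason = rec.validation_error()
        if reason is not None:
            rejected.append((rsid, reason))
            continue
        records.append(rec)

    # duplicated rsids: drop every copy (no tie-break rule is defensible)
    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.rsid] = counts.get(rec.rsid, 0) + 1
    kept = [r for r in records if counts[r.rsid] == 1]
    for rsid, c in counts.items():
        if c > 1:
            rejected.append((rsid, f"duplicated rsid ({c} copies, all dropped)"))
            logger.warning("dropping %d copies of duplicated rsid %s", c, rsid)
    for rsid, reason in rejected:
        logger.info("rejected %s: %s", rsid, reason)
    if return_rejected:
        return kept, rejected
    return kept


def write_summary_stats(records: Iterable[GwasRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "rsid": r.rsid,
                "chrom": r.chrom if r.chrom is not None else MISSING,
                "pos": r.pos if r.pos is not None else MISSING,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf if r.eaf is not None else MISSING,
                "beta": repr(r.beta),
                "se": repr(r.se),
                "pval": repr(r.pval),
                "n": r.n if r.n is not None else MISSING,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "rsid",
            "chrom",
            "pos",
            "effect_allele",
            "other_allele",
            "eaf",
            "beta",
            "se",
            "pval",
            "n",
        ],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# association tables
# ---------------------------------------------------------------------------


@dataclass
class AssociationRow:
    """One taxon-outcome causal result (one estimator) with multiplicity-
    adjusted p-values and a significance tier.

    Numeric fields may be None for skip records (pairs with no surviving
    instruments) or for transcribed tables that do not print them.
    """

    exposure: str
    outcome: str
    direction: str  # "forward" | "reverse"
    level: str | None
    method: str
    n_snp: int | None
    beta: float | None
    se: float | None
    or_value: float | None
    ci_low: float | None
    ci_high: float | None
    pval: float | None
    p_bonferroni: float | None = None
    p_fdr: float | None = None
    tier: str | None = None


def _fmt(value) -> str:
    if value is None:
        return MISSING
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_association_table(
    rows: Sequence[AssociationRow], path: str | Path
) -> None:
    """Write rows in the canonical column order; round-trips losslessly."""
    out_rows = []
    for r in rows:
        out_rows.append(
            {
                "exposure": r.exposure,
                "outcome": r.outcome,
                "direction": r.direction,
                "level": r.level if r.level is not None else MISSING,
                "method": r.method,
                "n_snp": _fmt(r.n_snp),
                "beta": _fmt(r.beta),
                "se": _fmt(r.se),
                "or": _fmt(r.or_value),
                "ci_low": _fmt(r.ci_low),
                "ci_high": _fmt(r.ci_high),
                "pval": _fmt(r.pval),
                "p_bonferroni": _fmt(r.p_bonferroni),
                "p_fdr": _fmt(r.p_fdr),
                "tier": r.tier if r.tier is not None else MISSING,
            }
        )
    pd.DataFrame(out_rows, columns=ASSOCIATION_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_association_table(path: str | Path) -> list[AssociationRow]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(ASSOCIATION_COLUMNS) - set(df.columns)
    if missing:
        raise SummaryStatsError(f"association table missing columns: {missing}")
    rows = []
    for _, r in df.iterrows():
        n_snp = _parse_float(r["n_snp"])
        rows.append(
            AssociationRow(
                exposure=r["exposure"],
                outcome=r["outcome"],
                direction=r["direction"],
                level=None if r["level"] in (MISSING, "") else r["level"],
                method=r["method"],
                n_snp=int(n_snp) if n_snp is not None else None,
                beta=_parse_float(r["beta"]),
                se=_parse_float(r["se"]),
                or_value=_parse_float(r["or"]),
                ci_low=_parse_float(r["ci_low"]),
                ci_high=_parse_float(r["ci_high"]),
                pval=_parse_float(r["pval"]),
                p_bonferroni=_parse_float(r["p_bonferroni"]),
                p_fdr=_parse_float(r["p_fdr"]),
                tier=None if r["tier"] in (MISSING, "") else r["tier"],
            )
        )
    return rows


# ---------------------------------------------------------------------------
# taxa registry
# ---------------------------------------------------------------------------


def load_taxa_registry(path: str | Path | None = None) -> list[TaxonInfo]:
    """Load a taxa registry (taxon_id, level, name, is_unknown).

    With no path, the packaged registry emulating the MiBioGen composition
    (211 taxa; 196 analyzable after excluding unknown groups) is used.
    """
    if path is None:
        source = resources.files("mrbiome.data").joinpath("taxa_registry.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"taxon_id", "level", "name", "is_unknown"}
    if not required.issubset(df.columns):
        raise SummaryStatsError(f"registry must have columns {sorted(required)}")
    taxa = []
    for _, row in df.iterrows():
        taxa.append(
            TaxonInfo(
                taxon_id=row["taxon_id"],
                level=row["level"],
                name=row["name"],
                is_unknown=str(row["is_unknown"]).strip().lower()
                in ("1", "true", "yes"),
            )
        )
    return taxa


def analyzable_taxa(taxa: Iterable[TaxonInfo]) -> list[TaxonInfo]:
    """Taxa entering the analysis: unknown (unidentified) groups excluded."""
    return [t for t in taxa if not t.is_unknown]


def level_counts(taxa: Iterable[TaxonInfo]) -> dict[str, int]:
    counts = {lvl: 0 for lvl in TAXONOMIC_LEVELS}
    for t in taxa:
        counts[t.level] += 1
    return counts


def load_blacklist(path: str | Path | None = None) -> dict[str, str]:
    """Load a confounder-SNP blacklist as {rsid: confounder trait}.

    The packaged default is a static, curated stand-in for interactive
    variant-lookup services (rsid, confounder_trait, source)."""
    if path is None:
        source = resources.files("mrbiome.data").joinpath(
            "confounder_blacklist.tsv"
        )
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    if "rsid" not in df.columns:
        raise SummaryStatsError("blacklist must have an rsid column")
    trait_col = "confounder_trait" if "confounder_trait" in df.columns else None
    return {
        str(r["rsid"]): (str(r[trait_col]) if trait_col else "unspecified")
        for _, r in df.iterrows()
    }
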