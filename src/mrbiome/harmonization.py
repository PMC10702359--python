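"""Alignment of exposure and outcome summary statistics to a shared effect
allele.

Rules, applied per exposure SNP:

* absent from the outcome study          -> removed (``missing_in_outcome``)
* palindromic allele pair (A/T or C/G)   -> removed (``palindromic``),
  unconditionally — no allele-frequency rescue window
* same pair, same orientation            -> kept as-is
* same pair, swapped orientation         -> outcome beta negated,
  eaf_out -> 1 - eaf_out
* strand flip (complemented pair), with or without a swap, is reconciled for
  non-palindromic SNPs before declaring a mismatch
* anything else                          -> removed (``allele_mismatch``)
* duplicated rsid on either side         -> removed (``duplicate``)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .summary_stats import GwasRecord

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

REMOVAL_REASONS = ("palindromic", "allele_mismatch", "missing_in_outcome", "duplicate")


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    return _COMPLEMENT.get(effect_allele.upper()) == other_allele.upper()


@dataclass
class HarmonizedSnp:
    """Per-SNP aligned effect pair (shared effect allele)."""

    rsid: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None = None
    eaf_out: float | None = None


@dataclass
class HarmonizedSet:
    """Aligned exposure/outcome effects for one exposure-outcome analysis."""

    exposure_id: str
    outcome_id: str
    snps: list[HarmonizedSnp] = field(default_factory=list)
    removed: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_snp(self) -> int:
        return len(self.snps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": [s.rsid for s in self.snps],
                "beta_exp": [s.beta_exp for s in self.snps],
                "se_exp": [s.se_exp for s in self.snps],
                "beta_out": [s.beta_out for s in self.snps],
                "se_out": [s.se_out for s in self.snps],
                "eaf_exp": [s.eaf_exp for s in self.snps],
                "eaf_out": [s.eaf_out for s in self.snps],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def harmonize_effects(
    exposure: Sequence[GwasRecord],
    outcome: Iterable[GwasRecord],
    exposure_id: str = "exposure",
    outcome_id: str = "outcome",
) -> HarmonizedSet:
    """Align outcome effects to each exposure SNP's effect allele.

    All failures are audited removals (never exceptions); the retained and
    removed sets partition the exposure input.
    """
    out_index: dict[str, GwasRecord | None] = {}
    for rec in outcome:
        # duplicated outcome rsids are unusable: mark with None
        out_index[rec.rsid] = None if rec.rsid in out_index else rec

    seen_exp: dict[str, int] = {}
    for rec in exposure:
        seen_exp[rec.rsid] = seen_exp.get(rec.rsid, 0) + 1

    hset = HarmonizedSet(exposure_id=exposure_id, outcome_id=outcome_id)
    for rec in exposure:
        if seen_exp[rec.rsid] > 1:
            hset.removed.append((rec.rsid, "duplicate"))
            continue
        ea, oa = rec.effect_allele, rec.other_allele
        if is_palindromic(ea, oa):
            hset.removed.append((rec.rsid, "palindromic"))
            continue
        out = out_index.get(rec.rsid)
        if rec.rsid not in out_index:
            hset.removed.append((rec.rsid, "missing_in_outcome"))
            continue
        if out is None:
            hset.removed.append((rec.rsid, "duplicate"))
            continue
        o_ea, o_oa = out.effect_allele, out.other_allele
        flip = False
        if (o_ea, o_oa) == (ea, oa):
            pass
        elif (o_ea, o_oa) == (oa, ea):
            flip = True
        elif (_COMPLEMENT[o_ea], _COMPLEMENT[o_oa]) == (ea, oa):
            pass  # strand flip, same orientation
        elif (_COMPLEMENT[o_ea], _COMPLEMENT[o_oa]) == (oa, ea):
            flip = True  # strand flip + swap
        else:
            hset.removed.append((rec.rsid, "allele_mismatch"))
            continue
        beta_out = -out.beta if flip else out.beta
        eaf_out = (
            (1.0 - out.eaf if flip else out.eaf) if out.eaf is not None else None
        )
        hset.snps.append(
            HarmonizedSnp(
                rsid=rec.rsid,
                beta_exp=rec.beta,
                se_exp=rec.se,
                beta_out=beta_out,
                se_out=out.se,
                eaf_exp=rec.eaf,
                eaf_out=eaf_out,
            )
        )
    return hset


def harmonized_to_records(
    hset: HarmonizedSet,
) -> tuple[list[GwasRecord], list[GwasRecord]]:
    """Re-expand a harmonized set into aligned exposure/outcome record lists
    on a synthetic non-palindromic allele pair (A/G), e.g. to check that
    harmonization is idempotent."""
    exp, out = [], []
    for s in hset.snps:
        common = dict(effect_allele="A", other_allele="G")
        exp.append(
            GwasRecord(
                rsid=s.rsid, beta=s.beta_exp, se=s.se_exp, pval=1.0,
                eaf=s.eaf_exp, **common,
            )
        )
        out.append(
            GwasRecord(
                rsid=s.rsid, beta=s.beta_out, se=s.se_out, pval=1.0,
                eaf=s.eaf_out, **common,
            )
        )
    return exp, out
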