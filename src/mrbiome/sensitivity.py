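"""Heterogeneity and pleiotropy diagnostics: Cochran's Q, the Egger intercept
test, leave-one-out, and a combined report.

Q uses fixed-effect weights (its chi-square null requires them) even though
the headline IVW is multiplicative-random-effects; the per-omission
leave-one-out fits use the same IVW model as the headline estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .harmonization import HarmonizedSet
from .model import EstimationError, MendelianRandomization, MRResults


@dataclass
class LooResult:
    left_out_rsid: str
    beta: float
    se: float
    pval: float


@dataclass
class SensitivityReport:
    """Diagnostics for one exposure-outcome analysis."""

    q_stat: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    presso_global_p: float | None = None
    presso_outliers: list[str] = field(default_factory=list)
    presso_distortion_p: float | None = None
    loo: list[LooResult] = field(default_factory=list)
    loo_stable: bool | None = None
    heterogeneity_detected: bool | None = None
    pleiotropy_detected: bool | None = None

    def summary(self) -> str:
        lines = ["Sensitivity analyses"]
        if self.q_stat is not None:
            lines.append(
                f"  Cochran's Q : {self.q_stat:.3f} (df={self.q_df}, "
                f"p={self.q_pval:.3g}) heterogeneity="
                f"{'yes' if self.heterogeneity_detected else 'no'}"
            )
        if self.egger_intercept is not None:
            lines.append(
                f"  Egger intercept : {self.egger_intercept:+.4f} "
                f"(SE {self.egger_intercept_se:.4f}, p={self.egger_intercept_p:.3g}) "
                f"pleiotropy={'yes' if self.pleiotropy_detected else 'no'}"
            )
        if self.presso_global_p is not None:
            lines.append(
                f"  MR-PRESSO global p : {self.presso_global_p:.3g}; "
                f"outliers: {self.presso_outliers or 'none'}"
            )
        if self.loo:
            lines.append(
                f"  Leave-one-out : {len(self.loo)} fits, "
                f"stable={'yes' if self.loo_stable else 'no'}"
            )
        return "\n".join(lines)


def _model(hset: HarmonizedSet | MendelianRandomization) -> MendelianRandomization:
    if isinstance(hset, MendelianRandomization):
        return hset
    return MendelianRandomization.from_harmonized(hset)


def cochran_q(hset: HarmonizedSet | MendelianRandomization) -> tuple[float, int, float]:
    """Cochran's Q over the per-SNP ratio estimates: (Q, df=J-1, p)."""
    return _model(hset).q_statistic()


def egger_intercept_test(
    hset: HarmonizedSet | MendelianRandomization,
) -> tuple[float, float, float]:
    """(intercept, SE, two-sided t(J-2) p) from the Egger regression."""
    res = _model(hset).fit_egger()
    return (
        res.extras["intercept"],
        res.extras["intercept_se"],
        res.extras["intercept_pval"],
    )


def leave_one_out(
    hset: HarmonizedSet | MendelianRandomization,
    ivw_model: str = "mre",
) -> tuple[list[LooResult], bool]:
    """IVW refits each omitting one SNP, plus a stability flag.

    The flag is true when every omission preserves the sign of the full
    estimate and, if the full estimate is nominally significant (p < 0.05),
    its significance too.
    """
    m = _model(hset)
    if m.n_snp < 3:
        raise EstimationError("leave-one-out needs at least 3 SNPs")
    full = m.fit_ivw(model=ivw_model)
    results: list[LooResult] = []
    for i in range(m.n_snp):
        idx = np.array([j for j in range(m.n_snp) if j != i])
        sub = m._subset(idx)
        fit = sub.fit_ivw(model=ivw_model) if idx.size >= 2 else sub.fit_wald_ratio()
        results.append(LooResult(m.rsids[i], fit.beta, fit.se, fit.pval))
    same_sign = all(np.sign(r.beta) == np.sign(full.beta) for r in results)
    sig_kept = full.pval >= 0.05 or all(r.pval < 0.05 for r in results)
    return results, bool(same_sign and sig_kept)


def sensitivity_report(
    hset: HarmonizedSet | MendelianRandomization,
    presso: MRResults | None = None,
    ivw_model: str = "mre",
    alpha: float = 0.05,
) -> SensitivityReport:
    """Assemble the full diagnostic report (heterogeneity/pleiotropy flagged
    at p < 0.05). PRESSO results, if already computed, are folded in rather
    than recomputed."""
    m = _model(hset)
    report = SensitivityReport()
    if m.n_snp >= 2:
        report.q_stat, report.q_df, report.q_pval = m.q_statistic()
        report.heterogeneity_detected = report.q_pval < alpha
    if m.n_snp >= 3:
        (
            report.egger_intercept,
            report.egger_intercept_se,
            report.egger_intercept_p,
        ) = egger_intercept_test(m)
        report.pleiotropy_detected = report.egger_intercept_p < alpha
        report.loo, report.loo_stable = leave_one_out(m, ivw_model=ivw_model)
    if presso is not None:
        report.presso_global_p = presso.extras.get("global_pval")
        report.presso_outliers = list(presso.extras.get("outliers", []))
        report.presso_distortion_p = presso.extras.get("distortion_pval")
        if report.presso_global_p is not None:
            report.pleiotropy_detected = bool(
                (report.pleiotropy_detected or False)
                or report.presso_global_p < alpha
            )
    return report
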