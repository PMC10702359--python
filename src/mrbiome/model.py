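"""Two-sample Mendelian randomization model and results objects.

`MendelianRandomization` is built from per-SNP harmonized effect pairs
(exposure beta/SE, outcome beta/SE on a shared effect allele); `fit` returns
an `MRResults` carrying the causal estimate, its uncertainty, p-value and
method-specific diagnostics, with a `summary()` table. All estimator
mathematics lives here in closed form; the functional surface in
:mod:`mrbiome.mr_estimators` wraps this class.

Conventions
-----------
* Per-SNP ratio estimates theta_j = beta_out,j / beta_exp,j carry first-order
  weights w_j = beta_exp,j^2 / se_out,j^2 (no NOME correction).
* The headline IVW uses multiplicative random effects: the fixed-effect
  standard error is inflated by max(1, sqrt(Q/(J-1))) where Q is Cochran's Q.
* Confidence intervals use the normal 1.959964 multiplier, except the Egger
  slope and intercept which use t(J-2).
* SNPs are sorted by rsid internally before any computation (including
  bootstrap draws), so every fit is invariant to input row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

Z95 = 1.959964


class EstimationError(ValueError):
    """Raised when a method's preconditions (e.g. minimum SNP count) fail."""


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------


@dataclass
class MRResults:
    """Causal-effect estimate from one MR method.

    `beta` is on the log-odds-per-unit-exposure scale for case-control
    outcomes; `or_value` and `or_ci` are the exponentiated scale used in
    reporting.
    """

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    ci_low: float = field(default=None)
    ci_high: float = field(default=None)
    primary: bool = False
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ci_low is None:
            self.ci_low = self.beta - Z95 * self.se
        if self.ci_high is None:
            self.ci_high = self.beta + Z95 * self.se

    @property
    def or_value(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    def summary(self) -> str:
        lines = [
            f"MR estimate [{self.method}]" + ("  (primary)" if self.primary else ""),
            f"  n_snp     : {self.n_snp}",
            f"  beta (log-odds) : {self.beta:+.4f}  (SE {self.se:.4f})",
            f"  95% CI (beta)   : [{self.ci_low:+.4f}, {self.ci_high:+.4f}]",
            f"  OR [95% CI]     : {self.or_value:.3f} "
            f"[{self.or_ci[0]:.3f}, {self.or_ci[1]:.3f}]",
            f"  p-value   : {self.pval:.3g}",
        ]
        for key, val in self.extras.items():
            if isinstance(val, float):
                lines.append(f"  {key} : {val:.4g}")
            elif not isinstance(val, (list, dict, np.ndarray)):
                lines.append(f"  {key} : {val}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class MendelianRandomization:
    """Two-sample summary-data MR model for one exposure-outcome pair."""

    def __init__(
        self,
        beta_exposure: Sequence[float],
        se_exposure: Sequence[float],
        beta_outcome: Sequence[float],
        se_outcome: Sequence[float],
        rsids: Sequence[str] | None = None,
        exposure: str = "exposure",
        outcome: str = "outcome",
    ) -> None:
        bx = np.asarray(beta_exposure, dtype=float)
        sx = np.asarray(se_exposure, dtype=float)
        by = np.asarray(beta_outcome, dtype=float)
        sy = np.asarray(se_outcome, dtype=float)
        if not (bx.shape == sx.shape == by.shape == sy.shape) or bx.ndim != 1:
            raise ValueError("effect/SE arrays must be 1-D and equally long")
        if bx.size == 0:
            raise ValueError("no SNPs supplied")
        if np.any(sx <= 0) or np.any(sy <= 0):
            raise ValueError("standard errors must be positive")
        if np.any(bx == 0):
            raise EstimationError("beta_exposure of 0 yields an undefined ratio")
        if rsids is None:
            rsids = [f"snp{i}" for i in range(bx.size)]
        rsids = [str(r) for r in rsids]
        order = np.argsort(np.asarray(rsids))
        self.rsids = [rsids[i] for i in order]
        self.beta_exposure = bx[order]
        self.se_exposure = sx[order]
        self.beta_outcome = by[order]
        self.se_outcome = sy[order]
        self.exposure = exposure
        self.outcome = outcome

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_harmonized(cls, hset) -> "MendelianRandomization":
        """Build from a :class:`mrbiome.harmonization.HarmonizedSet`."""
        return cls(
            beta_exposure=[s.beta_exp for s in hset.snps],
            se_exposure=[s.se_exp for s in hset.snps],
            beta_outcome=[s.beta_out for s in hset.snps],
            se_outcome=[s.se_out for s in hset.snps],
            rsids=[s.rsid for s in hset.snps],
            exposure=hset.exposure_id,
            outcome=hset.outcome_id,
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        beta_exposure: str = "beta_exp",
        se_exposure: str = "se_exp",
        beta_outcome: str = "beta_out",
        se_outcome: str = "se_out",
        rsid: str = "rsid",
        **kwargs,
    ) -> "MendelianRandomization":
        return cls(
            beta_exposure=df[beta_exposure].to_numpy(),
            se_exposure=df[se_exposure].to_numpy(),
            beta_outcome=df[beta_outcome].to_numpy(),
            se_outcome=df[se_outcome].to_numpy(),
            rsids=df[rsid].tolist() if rsid in df.columns else None,
            **kwargs,
        )

    # -- basic quantities ---------------------------------------------------

    @property
    def n_snp(self) -> int:
        return self.beta_exposure.size

    def ratio_estimates(self) -> np.ndarray:
        """Per-SNP Wald ratios theta_j = beta_out,j / beta_exp,j."""
        return self.beta_outcome / self.beta_exposure

    def ratio_se(self) -> np.ndarray:
        """First-order delta-method SEs of the ratios."""
        return self.se_outcome / np.abs(self.beta_exposure)

    def ratio_weights(self) -> np.ndarray:
        """First-order inverse-variance weights w_j = beta_exp^2 / se_out^2."""
        return self.beta_exposure**2 / self.se_outcome**2

    def q_statistic(self) -> tuple[float, int, float]:
        """Cochran's Q over the ratio estimates with fixed-effect weights.

        Returns (Q, df, p) with df = J - 1 and a chi-square upper-tail p.
        This is the single source of the Q used both as the heterogeneity
        diagnostic and inside the IVW random-effects inflation.
        """
        if self.n_snp < 2:
            raise EstimationError("Cochran's Q needs at least 2 SNPs")
        w = self.ratio_weights()
        theta = self.ratio_estimates()
        fe = float(np.sum(w * theta) / np.sum(w))
        q = float(np.sum(w * (theta - fe) ** 2))
        df_ = self.n_snp - 1
        return q, df_, float(stats.chi2.sf(q, df_))

    # -- estimators ---------------------------------------------------------

    def fit(self, method: str = "ivw", **kwargs) -> MRResults:
        dispatch = {
            "ivw": self.fit_ivw,
            "wald_ratio": self.fit_wald_ratio,
            "egger": self.fit_egger,
            "weighted_median": self.fit_weighted_median,
            "weighted_mode": self.fit_weighted_mode,
            "presso": self.fit_presso,
            "presso_corrected": self.fit_presso,
        }
        if method not in dispatch:
            raise ValueError(f"unknown method {method!r}")
        return dispatch[method](**kwargs)

    def fit_wald_ratio(self) -> MRResults:
        """Single-instrument Wald ratio with first-order delta-method SE."""
        if self.n_snp != 1:
            raise EstimationError("Wald ratio is defined for exactly 1 SNP")
        bx = float(self.beta_exposure[0])
        beta = float(self.beta_outcome[0]) / bx
        se = float(self.se_outcome[0]) / abs(bx)
        z = beta / se
        pval = float(2 * stats.norm.sf(abs(z)))
        return MRResults(
            method="wald_ratio", beta=beta, se=se, pval=pval, n_snp=1, primary=True
        )

    def fit_ivw(self, model: str = "mre") -> MRResults:
        """Inverse-variance-weighted estimate.

        ``model='mre'`` (default) inflates the fixed-effect SE by
        max(1, sqrt(Q/(J-1))); ``model='fe'`` is the plain fixed-effect fit.
        """
        if self.n_snp < 2:
            raise EstimationError("IVW needs at least 2 SNPs (use wald_ratio)")
        if model not in ("mre", "fe"):
            raise ValueError("ivw model must be 'mre' or 'fe'")
        w = self.ratio_weights()
        theta = self.ratio_estimates()
        beta = float(np.sum(w * theta) / np.sum(w))
        se_fe = float(1.0 / np.sqrt(np.sum(w)))
        q, q_df, q_p = self.q_statistic()
        phi = max(1.0, float(np.sqrt(q / q_df))) if model == "mre" else 1.0
        se = se_fe * phi
        pval = float(2 * stats.norm.sf(abs(beta / se)))
        return MRResults(
            method="ivw",
            beta=beta,
            se=se,
            pval=pval,
            n_snp=self.n_snp,
            primary=True,
            extras={
                "model": model,
                "q_stat": q,
                "q_df": q_df,
                "q_pval": q_p,
                "phi": phi,
            },
        )

    def fit_egger(self) -> MRResults:
        """MR-Egger: weighted regression of outcome on exposure effects with a
        free intercept (weights 1/se_out^2), after orienting every exposure
        effect to be non-negative.

        Slope inference uses t(J-2) with the multiplicative residual
        inflation bounded below by 1; the intercept (the directional-
        pleiotropy diagnostic, stored in ``extras``) uses the exact
        residual-scaled t inference.
        """
        if self.n_snp < 3:
            raise EstimationError("MR-Egger needs at least 3 SNPs")
        sign = np.where(self.beta_exposure < 0, -1.0, 1.0)
        bx = self.beta_exposure * sign
        by = self.beta_outcome * sign
        w = 1.0 / self.se_outcome**2
        sw = w.sum()
        swx = np.sum(w * bx)
        swy = np.sum(w * by)
        swxx = np.sum(w * bx * bx)
        swxy = np.sum(w * bx * by)
        det = sw * swxx - swx**2
        if det <= 0:
            raise EstimationError("degenerate exposure effects in Egger fit")
        slope = (sw * swxy - swx * swy) / det
        intercept = (swy * swxx - swx * swxy) / det
        df_ = self.n_snp - 2
        resid = by - intercept - slope * bx
        sigma2 = float(np.sum(w * resid**2) / df_)  # residual inflation
        var_slope_u = sw / det  # unscaled (known-variance) sampling variances
        var_inter_u = swxx / det
        se_slope = float(np.sqrt(var_slope_u * max(1.0, sigma2)))
        se_inter = float(np.sqrt(var_inter_u * sigma2))
        t_mult = float(stats.t.ppf(0.975, df_))
        p_slope = float(2 * stats.t.sf(abs(slope / se_slope), df_))
        p_inter = float(2 * stats.t.sf(abs(intercept / se_inter), df_)) if se_inter > 0 else 1.0
        return MRResults(
            method="egger",
            beta=float(slope),
            se=se_slope,
            pval=p_slope,
            n_snp=self.n_snp,
            ci_low=float(slope - t_mult * se_slope),
            ci_high=float(slope + t_mult * se_slope),
            extras={
                "intercept": float(intercept),
                "intercept_se": se_inter,
                "intercept_pval": p_inter,
                "residual_inflation": max(1.0, sigma2),
                "sigma2": sigma2,
            },
        )

    @staticmethod
    def _weighted_median_of(theta: np.ndarray, weights: np.ndarray) -> float:
        order = np.argsort(theta, kind="stable")
        t = theta[order]
        w = weights[order] / weights.sum()
        s = np.cumsum(w) - 0.5 * w
        return float(np.interp(0.5, s, t))

    def fit_weighted_median(
        self, n_boot: int = 5000, seed: int = 42
    ) -> MRResults:
        """Weighted median of the ratio estimates (consistent when >= 50% of
        the weight comes from valid instruments).

        The estimate interpolates the order statistics at cumulative weight
        0.5; the SE comes from a parametric bootstrap resampling each ratio
        from Normal(theta_j, se_j) with the weights held fixed.
        """
        if self.n_snp < 3:
            raise EstimationError("weighted median needs at least 3 SNPs")
        theta = self.ratio_estimates()
        se_t = self.ratio_se()
        w = self.ratio_weights()
        beta = self._weighted_median_of(theta, w)
        # bootstrap on sign-canonicalized ratios so that negating every
        # outcome effect leaves the SE (hence the p-value) unchanged
        sgn = -1.0 if beta < 0 else 1.0
        rng = np.random.default_rng(seed)
        draws = rng.normal(sgn * theta, se_t, size=(n_boot, self.n_snp))
        order = np.argsort(draws, axis=1, kind="stable")
        t_sorted = np.take_along_axis(draws, order, axis=1)
        w_sorted = np.take_along_axis(
            np.broadcast_to(w, draws.shape), order, axis=1
        )
        w_norm = w_sorted / w_sorted.sum(axis=1, keepdims=True)
        s = np.cumsum(w_norm, axis=1) - 0.5 * w_norm
        boot = np.empty(n_boot)
        for i in range(n_boot):  # np.interp is 1-D
            boot[i] = np.interp(0.5, s[i], t_sorted[i])
        se = float(boot.std(ddof=1))
        pval = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else 1.0
        return MRResults(
            method="weighted_median",
            beta=beta,
            se=se,
            pval=pval,
            n_snp=self.n_snp,
            extras={"n_boot": n_boot, "seed": seed},
        )

    @staticmethod
    def _mode_of(
        theta: np.ndarray, weights: np.ndarray, bandwidth: float, grid: int = 1024
    ) -> float:
        if bandwidth <= 0 or np.ptp(theta) == 0:
            return float(theta[0])
        lo = theta.min() - 3 * bandwidth
        hi = theta.max() + 3 * bandwidth
        x = np.linspace(lo, hi, grid)
        dens = (
            weights[None, :]
            * np.exp(-0.5 * ((x[:, None] - theta[None, :]) / bandwidth) ** 2)
        ).sum(axis=1)
        i = int(np.argmax(dens))
        # golden-section refinement around the best grid point
        from scipy.optimize import minimize_scalar

        a = x[max(i - 1, 0)]
        b = x[min(i + 1, grid - 1)]

        def neg_density(v):
            return -np.sum(
                weights * np.exp(-0.5 * ((v - theta) / bandwidth) ** 2)
            )

        res = minimize_scalar(neg_density, bounds=(a, b), method="bounded")
        return float(res.x)

    def fit_weighted_mode(
        self,
        bandwidth_factor: float = 1.0,
        n_boot: int = 5000,
        seed: int = 42,
    ) -> MRResults:
        """Weighted mode: the maximiser of the inverse-variance-weighted
        Gaussian kernel density of the ratio estimates.

        The bandwidth is ``bandwidth_factor`` times the robust plug-in scale
        0.9 min(sd, 1.4826 MAD) J^(-1/5) of the ratios (MAD about their
        median); SE by parametric bootstrap as in the weighted median.
        """
        if self.n_snp < 3:
            raise EstimationError("weighted mode needs at least 3 SNPs")
        theta = self.ratio_estimates()
        se_t = self.ratio_se()
        w = self.ratio_weights()
        w = w / w.sum()
        sd = float(np.std(theta, ddof=1))
        mad = 1.4826 * float(np.median(np.abs(theta - np.median(theta))))
        scale = min(sd, mad) if mad > 0 else sd
        h = bandwidth_factor * 0.9 * scale * self.n_snp ** (-1 / 5)
        # canonical orientation (sign of the weighted median) so negating all
        # outcome effects mirrors the fit exactly
        sgn = -1.0 if self._weighted_median_of(theta, self.ratio_weights()) < 0 else 1.0
        beta = sgn * self._mode_of(sgn * theta, w, h)
        rng = np.random.default_rng(seed)
        draws = rng.normal(sgn * theta, se_t, size=(n_boot, self.n_snp))
        boot = np.empty(n_boot)
        grid = 256  # coarse grid suffices for the bootstrap spread
        for start in range(0, n_boot, 512):
            chunk = draws[start : start + 512]
            if h > 0:
                lo = chunk.min(axis=1, keepdims=True) - 3 * h
                hi = chunk.max(axis=1, keepdims=True) + 3 * h
                x = lo + (hi - lo) * np.linspace(0, 1, grid)[None, :]
                dens = (
                    w[None, None, :]
                    * np.exp(
                        -0.5
                        * ((x[:, :, None] - chunk[:, None, :]) / h) ** 2
                    )
                ).sum(axis=2)
                idx = np.argmax(dens, axis=1)
                boot[start : start + chunk.shape[0]] = np.take_along_axis(
                    x, idx[:, None], axis=1
                )[:, 0]
            else:
                boot[start : start + chunk.shape[0]] = chunk[:, 0]
        se = float(boot.std(ddof=1))
        pval = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else 1.0
        return MRResults(
            method="weighted_mode",
            beta=beta,
            se=se,
            pval=pval,
            n_snp=self.n_snp,
            extras={
                "bandwidth": h,
                "bandwidth_factor": bandwidth_factor,
                "n_boot": n_boot,
                "seed": seed,
            },
        )

    # -- MR-PRESSO ----------------------------------------------------------

    @staticmethod
    def _loo_slopes(bx: np.ndarray, by: np.ndarray, wy: np.ndarray) -> np.ndarray:
        """Leave-one-out fixed-effect IVW slopes, vectorised.

        Works on 1-D arrays or on (n_sim, J) stacks (weights broadcast)."""
        sxy = np.sum(wy * bx * by, axis=-1, keepdims=True)
        sxx = np.sum(wy * bx * bx, axis=-1, keepdims=True)
        return (sxy - wy * bx * by) / (sxx - wy * bx * bx)

    def _presso_global(
        self, idx: np.ndarray, rng: np.random.Generator, n_sim: int
    ) -> tuple[float, np.ndarray, np.ndarray]:
        """Global RSS test and per-SNP outlier p-values on the SNP subset
        ``idx``. Returns (global p, raw per-SNP upper-tail p-values, observed
        per-SNP weighted residual contributions)."""
        bx = self.beta_exposure[idx]
        sx = self.se_exposure[idx]
        by = self.beta_outcome[idx]
        sy = self.se_outcome[idx]
        wy = 1.0 / sy**2
        loo = self._loo_slopes(bx, by, wy)
        res_obs = wy * (by - loo * bx) ** 2
        rss_obs = res_obs.sum()
        bxs = rng.normal(bx, sx, size=(n_sim, idx.size))
        bys = rng.normal(loo * bx, sy, size=(n_sim, idx.size))
        loo_s = self._loo_slopes(bxs, bys, wy)
        res_s = wy * (bys - loo_s * bxs) ** 2
        global_p = float(np.mean(res_s.sum(axis=1) >= rss_obs))
        outlier_p = np.mean(res_s >= res_obs, axis=0)
        return global_p, outlier_p, res_obs

    def presso_global_test(
        self, n_sim: int = 1000, seed: int = 42
    ) -> tuple[float, np.ndarray]:
        """MR-PRESSO global pleiotropy test only (no outlier removal).

        Returns the global p and the raw per-SNP upper-tail outlier
        p-values (not yet Bonferroni-adjusted), in rsid-sorted SNP order."""
        if self.n_snp < 4:
            raise EstimationError("insufficient instruments for PRESSO (need >= 4)")
        rng = np.random.default_rng(seed)
        global_p, raw_p, _ = self._presso_global(np.arange(self.n_snp), rng, n_sim)
        return global_p, raw_p

    def fit_presso(
        self,
        n_sim: int = 1000,
        seed: int = 42,
        outlier_p: float = 0.05,
        n_perm_distortion: int = 1000,
        ivw_model: str = "mre",
    ) -> MRResults:
        """MR-PRESSO: simulation-based global pleiotropy test, per-SNP outlier
        detection with iterative removal, distortion test, and an outlier-
        corrected IVW estimate.

        The global statistic is the leave-one-out residual sum of squares
        (outcome-precision weighted), referenced against parametric
        simulations of both effect columns. While the global test rejects at
        0.05 and Bonferroni-adjusted outlier p-values fall below
        ``outlier_p``, the worst SNP is removed one at a time.
        """
        if self.n_snp < 4:
            raise EstimationError("insufficient instruments for PRESSO (need >= 4)")
        rng = np.random.default_rng(seed)
        active = np.arange(self.n_snp)
        removed: list[str] = []
        global_p_initial = None
        outlier_table: dict[str, float] = {}
        while True:
            global_p, raw_p, res_obs = self._presso_global(active, rng, n_sim)
            adj_p = np.minimum(1.0, raw_p * active.size)
            if global_p_initial is None:
                global_p_initial = global_p
                outlier_table = {
                    self.rsids[i]: float(adj_p[k]) for k, i in enumerate(active)
                }
            candidates = np.flatnonzero(adj_p < outlier_p)
            if global_p >= 0.05 or candidates.size == 0 or active.size <= 4:
                break
            # smallest outlier p; empirical-p ties broken by the larger
            # observed residual contribution, then lexicographically by rsid
            best = min(
                candidates,
                key=lambda k: (adj_p[k], -res_obs[k], self.rsids[active[k]]),
            )
            removed.append(self.rsids[active[best]])
            active = np.delete(active, best)
        sub = self._subset(active)
        corrected = (
            sub.fit_ivw(model=ivw_model) if active.size >= 2 else sub.fit_wald_ratio()
        )
        distortion_p = None
        distortion_coef = None
        if removed:
            full = self.fit_ivw(model=ivw_model)
            distortion_coef = (
                (corrected.beta - full.beta) / abs(full.beta)
                if full.beta != 0
                else np.inf
            )
            n_out = len(removed)
            d_null = np.empty(n_perm_distortion)
            for i in range(n_perm_distortion):
                keep = rng.choice(self.n_snp, self.n_snp - n_out, replace=False)
                perm = self._subset(np.sort(keep))
                pb = (
                    perm.fit_ivw(model=ivw_model).beta
                    if keep.size >= 2
                    else perm.fit_wald_ratio().beta
                )
                d_null[i] = (pb - full.beta) / abs(full.beta) if full.beta != 0 else np.inf
            distortion_p = float(np.mean(np.abs(d_null) >= abs(distortion_coef)))
        return MRResults(
            method="presso_corrected",
            beta=corrected.beta,
            se=corrected.se,
            pval=corrected.pval,
            n_snp=int(active.size),
            extras={
                "global_pval": global_p_initial,
                "global_pval_final": global_p,
                "outliers": removed,
                "outlier_pvals": outlier_table,
                "distortion_coef": distortion_coef,
                "distortion_pval": distortion_p,
                "n_sim": n_sim,
                "seed": seed,
            },
        )

    def _subset(self, idx: np.ndarray) -> "MendelianRandomization":
        return MendelianRandomization(
            self.beta_exposure[idx],
            self.se_exposure[idx],
            self.beta_outcome[idx],
            self.se_outcome[idx],
            rsids=[self.rsids[i] for i in idx],
            exposure=self.exposure,
            outcome=self.outcome,
        )

    # -- convenience --------------------------------------------------------

    def fit_all(self, config=None) -> list[MRResults]:
        """Fit every method applicable at this SNP count (see
        :func:`mrbiome.mr_estimators.run_all_estimators`)."""
        from .mr_estimators import run_all_estimators

        return run_all_estimators(self, config)

    def summary(self) -> str:
        df = pd.DataFrame(
            {
                "rsid": self.rsids,
                "beta_exp": self.beta_exposure,
                "se_exp": self.se_exposure,
                "beta_out": self.beta_outcome,
                "se_out": self.se_outcome,
            }
        )
        head = (
            f"MendelianRandomization: {self.exposure} -> {self.outcome} "
            f"({self.n_snp} SNPs)"
        )
        return head + "\n" + df.to_string(index=False)
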