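"""Summary-level simulation of exposure/outcome GWAS pairs with controlled
causal effect, pleiotropy, outliers and LD, plus the packaged reference
association tables.

The generator works directly at the summary level (no individual-level
genotypes): for SNP j with minor-allele frequency f_j,

* se_X,j = 1/sqrt(2 f_j (1-f_j) n_X)  for the quantitative exposure,
* se_Y,j = 1/sqrt(2 f_j (1-f_j) n_eff), n_eff = 4/(1/n_cases + 1/n_controls)
  for the case-control outcome (effective-sample-size approximation),
* beta_X,j ~ N(gamma_j, se_X,j²),
* beta_Y,j ~ N(theta·gamma_j + alpha_j + outlier_j, se_Y,j²),

with alpha_j the horizontal-pleiotropy shift (Normal(mu_pleio, tau²) on the
selected fraction of SNPs under the balanced/directional modes) and
outlier_j a large idiosyncratic effect on a chosen fraction of SNPs.
Defaults mirror the MiBioGen exposure cohort (n = 18,340) and the FinnGen
acute-pancreatitis outcome (3,022 cases / 195,144 controls).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

from .summary_stats import (
    AssociationRow,
    GwasRecord,
    LdMatrix,
    read_association_table,
)

_NONPALINDROMIC_PAIRS = (
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
)

#: FinnGen pancreatitis phenotypes: (n_cases, n_controls)
OUTCOME_COHORTS = {
    "AP": (3022, 195144),
    "CP": (1737, 195144),
    "AAP": (457, 218335),
    "ACP": (977, 217815),
}

#: MiBioGen-scale exposure GWAS sample size
EXPOSURE_N = 18340


@dataclass
class SimulationScenario:
    """Controlled data-generating conditions for one exposure-outcome pair.

    ``gamma_range`` bounds the magnitude of the true SNP-exposure effects
    (signs random); the default (0.08, 0.16) puts exposure z-scores around
    5-14 at n = 18,340, comfortably below the p < 1e-5 instrument screen.
    ``pleio_frac`` restricts the pleiotropic alpha to a fraction of SNPs
    (1.0 = all), which expresses invalid-instrument mixtures.
    """

    n_snps: int = 15
    n_exposure: int = EXPOSURE_N
    n_cases: int = 3022
    n_controls: int = 195144
    theta: float = 0.0
    gamma_range: tuple[float, float] = (0.08, 0.16)
    gamma_sign: str = "random"  # "random" | "positive" (exposure-oriented)
    pleiotropy_mode: str = "none"  # none | balanced | directional
    tau: float = 0.0
    mu_pleio: float = 0.0
    pleio_frac: float = 1.0
    outlier_frac: float = 0.0
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_blocks: list[tuple[int, float]] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 1 or self.n_exposure < 1:
            raise ValueError("all sizes must be positive")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("case/control counts must be positive")
        if not (0.0 <= self.outlier_frac < 1.0):
            raise ValueError("outlier_frac must lie in [0, 1)")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if not (0.0 <= self.pleio_frac <= 1.0):
            raise ValueError("pleio_frac must lie in [0, 1]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"bad pleiotropy_mode {self.pleiotropy_mode!r}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("maf_range must satisfy 0 < lo <= hi < 1")
        glo, ghi = self.gamma_range
        if not (0.0 < glo <= ghi):
            raise ValueError("gamma_range must be positive")
        if self.gamma_sign not in ("random", "positive"):
            raise ValueError(f"bad gamma_sign {self.gamma_sign!r}")

    # flat key-value round trip -------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["gamma_range"] = list(self.gamma_range)
        d["maf_range"] = list(self.maf_range)
        if self.ld_blocks is not None:
            d["ld_blocks"] = [list(b) for b in self.ld_blocks]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationScenario":
        d = yaml.safe_load(Path(path).read_text())
        if "gamma_range" in d:
            d["gamma_range"] = tuple(d["gamma_range"])
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        if d.get("ld_blocks") is not None:
            d["ld_blocks"] = [tuple(b) for b in d["ld_blocks"]]
        return cls(**d)


@dataclass
class SimulatedStudy:
    """Paired exposure/outcome summary statistics plus the generating truth."""

    exposure: list[GwasRecord]
    outcome: list[GwasRecord]
    truth: dict
    ld: LdMatrix


def _positions(scenario: SimulationScenario) -> tuple[list[str], list[int]]:
    """Chromosome/position layout. Blocks are contiguous; distinct blocks are
    separated by far more than the 10 Mb clumping window."""
    blocks: list[tuple[int, float]]
    if scenario.ld_blocks:
        blocks = list(scenario.ld_blocks)
        total = sum(b[0] for b in blocks)
        if total != scenario.n_snps:
            raise ValueError("ld_blocks sizes must sum to n_snps")
    else:
        blocks = [(1, 0.0)] * scenario.n_snps
    chroms, poss = [], []
    chrom_i, base = 1, 1_000_000
    for size, _ in blocks:
        for k in range(size):
            chroms.append(str(chrom_i))
            poss.append(base + k * 10_000)
        base += 50_000_000  # next block: far outside any clumping window
        if base > 200_000_000:
            chrom_i = chrom_i % 22 + 1
            base = 1_000_000
    return chroms, poss


def _block_ld(scenario: SimulationScenario, rsids: list[str]) -> LdMatrix:
    r2 = np.eye(scenario.n_snps)
    if scenario.ld_blocks:
        start = 0
        for size, block_r2 in scenario.ld_blocks:
            sl = slice(start, start + size)
            r2[sl, sl] = block_r2
            start += size
        np.fill_diagonal(r2, 1.0)
    return LdMatrix(list(rsids), r2)


def simulate_study(scenario: SimulationScenario) -> SimulatedStudy:
    """Draw one exposure/outcome summary-statistic pair under the scenario.

    Reproducible: the same scenario (including its seed) yields bit-identical
    output.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    j = scenario.n_snps
    rsids = [f"rs{1000000 + i}" for i in range(j)]
    chroms, poss = _positions(scenario)

    f = rng.uniform(*scenario.maf_range, size=j)
    se_x = 1.0 / np.sqrt(2.0 * f * (1.0 - f) * scenario.n_exposure)
    n_eff = 4.0 / (1.0 / scenario.n_cases + 1.0 / scenario.n_controls)
    se_y = 1.0 / np.sqrt(2.0 * f * (1.0 - f) * n_eff)

    glo, ghi = scenario.gamma_range
    signs = (
        np.ones(j)
        if scenario.gamma_sign == "positive"
        else rng.choice([-1.0, 1.0], size=j)
    )
    gamma = rng.uniform(glo, ghi, size=j) * signs

    alpha = np.zeros(j)
    if scenario.pleiotropy_mode != "none":
        n_pleio = int(round(scenario.pleio_frac * j))
        which = rng.choice(j, size=n_pleio, replace=False)
        mu = scenario.mu_pleio if scenario.pleiotropy_mode == "directional" else 0.0
        alpha[which] = rng.normal(mu, scenario.tau, size=n_pleio)

    outlier = np.zeros(j, dtype=bool)
    outlier_effect = np.zeros(j)
    n_out = int(round(scenario.outlier_frac * j))
    if n_out:
        which = rng.choice(j, size=n_out, replace=False)
        outlier[which] = True
        base = np.median(np.abs(scenario.theta * gamma))
        if base == 0.0:
            base = np.median(np.abs(gamma))
        outlier_effect[which] = 10.0 * base * rng.choice([-1.0, 1.0], size=n_out)

    bx = rng.normal(gamma, se_x)
    by = rng.normal(scenario.theta * gamma + alpha + outlier_effect, se_y)
    px = 2.0 * stats.norm.sf(np.abs(bx) / se_x)
    py = 2.0 * stats.norm.sf(np.abs(by) / se_y)
    tiny = np.finfo(float).tiny
    px = np.clip(px, tiny, 1.0)
    py = np.clip(py, tiny, 1.0)

    pairs = [_NONPALINDROMIC_PAIRS[k] for k in rng.integers(0, 8, size=j)]
    n_out_total = scenario.n_cases + scenario.n_controls
    exposure, outcome = [], []
    for i in range(j):
        ea, oa = pairs[i]
        common = dict(
            rsid=rsids[i], effect_allele=ea, other_allele=oa,
            eaf=float(f[i]), chrom=chroms[i], pos=poss[i],
        )
        exposure.append(
            GwasRecord(
                beta=float(bx[i]), se=float(se_x[i]), pval=float(px[i]),
                n=scenario.n_exposure, **common,
            )
        )
        outcome.append(
            GwasRecord(
                beta=float(by[i]), se=float(se_y[i]), pval=float(py[i]),
                n=n_out_total, **common,
            )
        )
    truth = {
        "rsids": rsids,
        "gamma": gamma,
        "alpha": alpha,
        "outlier": outlier,
        "outlier_effect": outlier_effect,
        "theta": scenario.theta,
        "flipped": np.zeros(j, dtype=bool),
        "palindromic": np.zeros(j, dtype=bool),
    }
    return SimulatedStudy(exposure, outcome, truth, _block_ld(scenario, rsids))


def scramble_for_harmonization(
    study: SimulatedStudy,
    flip_frac: float = 0.0,
    palindrome_frac: float = 0.0,
    seed: int = 0,
) -> SimulatedStudy:
    """Perturb allele bookkeeping so harmonization has work to do.

    A flipped SNP has its *outcome* record's alleles swapped, beta negated
    and EAF complemented (information-preserving). A palindrome-injected SNP
    has its alleles replaced by an A/T or C/G pair in both studies (these
    SNPs become strand-ambiguous and must be removed downstream). Counts are
    round(frac x J), drawn without replacement; truth gains ``flipped`` and
    ``palindromic`` flags.
    """
    if not (0.0 <= flip_frac <= 1.0 and 0.0 <= palindrome_frac <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    out = copy.deepcopy(study)
    j = len(out.exposure)
    rng = np.random.default_rng(seed)
    n_flip = int(round(flip_frac * j))
    n_pal = int(round(palindrome_frac * j))
    flip_idx = rng.choice(j, size=n_flip, replace=False) if n_flip else np.array([], int)
    pal_idx = rng.choice(j, size=n_pal, replace=False) if n_pal else np.array([], int)
    for i in flip_idx:
        rec = out.outcome[i]
        rec.effect_allele, rec.other_allele = rec.other_allele, rec.effect_allele
        rec.beta = -rec.beta
        if rec.eaf is not None:
            rec.eaf = 1.0 - rec.eaf
        out.truth["flipped"][i] = True
    for i in pal_idx:
        ea, oa = ("A", "T") if rng.random() < 0.5 else ("C", "G")
        out.exposure[i].effect_allele, out.exposure[i].other_allele = ea, oa
        # keep the outcome orientation consistent with any earlier flip
        if out.truth["flipped"][i]:
            out.outcome[i].effect_allele, out.outcome[i].other_allele = oa, ea
        else:
            out.outcome[i].effect_allele, out.outcome[i].other_allele = ea, oa
        out.truth["palindromic"][i] = True
    return out


# ---------------------------------------------------------------------------
# packaged reference association tables
# ---------------------------------------------------------------------------


def load_reported_associations(
    direction: str = "forward",
) -> list[AssociationRow]:
    """Load the packaged reference association tables for the
    MiBioGen x FinnGen pancreatitis bidirectional MR analysis.

    ``direction`` is ``forward`` (gut microbiota -> pancreatitis, 28 distinct
    taxon-outcome rows), ``reverse`` (pancreatitis -> gut microbiota, 30
    rows) or ``both``. Transcribed fields are the IVW odds ratio, its 95% CI
    and the raw p-value; ``beta`` (=ln OR) and ``se`` (from the CI width) are
    derived on load. Duplicated textual mentions are collapsed to one row.
    """
    if direction not in ("forward", "reverse", "both"):
        raise ValueError("direction must be forward, reverse or both")
    names = (
        ["reported_forward.tsv", "reported_reverse.tsv"]
        if direction == "both"
        else [f"reported_{direction}.tsv"]
    )
    rows: list[AssociationRow] = []
    for name in names:
        source = resources.files("mrbiome.data").joinpath(name)
        if not source.is_file():
            raise FileNotFoundError(f"packaged fixture {name} is missing")
        with resources.as_file(source) as p:
            rows.extend(read_association_table(p))
    z95 = 1.959964
    for r in rows:
        if r.or_value is not None and r.beta is None:
            r.beta = float(np.log(r.or_value))
        if r.ci_low is not None and r.ci_high is not None and r.se is None:
            r.se = float((np.log(r.ci_high) - np.log(r.ci_low)) / (2 * z95))
    return rows
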