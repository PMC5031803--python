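"""Expression-association and power analysis for the clinical stage.

The stage mirrors a tumour-cohort analysis: Pearson correlation between
miRNA and target-gene expression on a normalized-count scale, a nested
ANOVA testing whether lymph-node burden adds explanatory power for target
expression beyond tumour size, standardized residuals of the reduced model
for display, and the power of an additive single-SNP association test.

Expression values are log2(x+1)-transformed before correlation and ANOVA
by default (normalized RNA-seq counts are heavy-tailed); pass
``log_transform=False`` to analyse raw values.  Samples with distant
metastasis (M1) or missing M status are excluded before model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "AssocResult",
    "AnovaResult",
    "PowerSpec",
    "pearson_corr",
    "nested_anova_lymph",
    "reduced_model_residuals",
    "power_closed_form",
    "power_monte_carlo",
    "log2_counts",
]

CLINICAL_COLUMNS = ["sample", "pathologic_T", "pathologic_N", "henodes", "pathologic_M"]


@dataclass(frozen=True)
class AssocResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    df_num: float
    df_den: float
    n: int


@dataclass(frozen=True)
class PowerSpec:
    """Design of an additive single-SNP association test.

    ``beta_std`` is the per-allele effect in phenotype-standard-deviation
    units under additive {0,1,2} genotype coding; ``allele_freq`` the
    effect-allele frequency; ``alpha`` the two-sided test size.
    """

    n: int
    allele_freq: float
    beta_std: float
    alpha: float = 0.05
    model: str = "additive"

    def __post_init__(self):
        if not 0 < self.allele_freq < 1:
            raise ValueError("allele_freq must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.model != "additive":
            raise ValueError("only the additive model is implemented")

    @property
    def genotype_variance(self) -> float:
        p = self.allele_freq
        return 2 * p * (1 - p)


def log2_counts(x) -> np.ndarray:
    return np.log2(np.asarray(x, dtype=float) + 1.0)


def pearson_corr(x, y) -> AssocResult:
    """Product-moment correlation with a two-sided p from the t transform.

    Missing values are handled pairwise-complete; either vector having zero
    variance raises an error (the correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: zero variance in an input vector")
    res = stats.pearsonr(x, y)
    return AssocResult(float(res.statistic), float(res.pvalue), n)


def _model_frame(expr, clinical: pd.DataFrame, node_term: str) -> pd.DataFrame:
    if node_term not in ("N_stage", "henodes"):
        raise ValueError("node_term must be 'N_stage' or 'henodes'")
    missing = [c for c in CLINICAL_COLUMNS if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table lacks column(s): {', '.join(missing)}")
    df = clinical.copy()
    df["y"] = np.asarray(expr, dtype=float)
    # drop M1 and missing-M samples before association: distant metastasis
    # is a downstream state, not a covariate of the node model
    df = df[df["pathologic_M"] == "M0"]
    df = df.dropna(subset=["y", "pathologic_T", "pathologic_N", "henodes"])
    df["T"] = df["pathologic_T"].astype(int)
    df["node"] = (
        df["pathologic_N"] if node_term == "N_stage" else df["henodes"]
    ).astype(int)
    return df


def nested_anova_lymph(
    expr, clinical: pd.DataFrame, node_term: str = "N_stage"
) -> AnovaResult:
    """F-test of the node term added to a tumour-size-only linear model.

    Response: target-gene expression.  Reduced model: ``y ~ T`` with
    pathologic T coded 1-4 as an integer linear trend; full model adds the
    node term (pathologic N 0-3 ordinal, or the discrete count of
    H&E-positive nodes).  Returns the added-term F, its p-value, the df
    pair and the number of samples used (M0 only).
    """
    df = _model_frame(expr, clinical, node_term)
    n = len(df)
    if n < 4:
        raise ValueError(f"insufficient data: {n} usable samples, need >= 4")
    if df["node"].nunique() == 1:
        # constant node term adds no variance explained
        return AnovaResult(0.0, 1.0, 0.0, float(n - 2), n)
    reduced = smf.ols("y ~ T", data=df).fit()
    full = smf.ols("y ~ T + node", data=df).fit()
    table = anova_lm(reduced, full)
    return AnovaResult(
        F=float(table["F"].iloc[1]),
        p=float(table["Pr(>F)"].iloc[1]),
        df_num=float(table["df_diff"].iloc[1]),
        df_den=float(full.df_resid),
        n=n,
    )


def reduced_model_residuals(expr, clinical: pd.DataFrame) -> pd.Series:
    """Standardized residuals of the tumour-size-only model, for display.

    Residuals are divided by their sample standard deviation (ddof=1), so
    the returned vector has mean ~0 and unit sample variance; a perfect fit
    returns zeros.  Indexed by sample id of the M0 samples used.
    """
    df = _model_frame(expr, clinical, "N_stage")
    if len(df) < 3:
        raise ValueError("insufficient data to fit the reduced model")
    fit = smf.ols("y ~ T", data=df).fit()
    resid = fit.resid
    sd = float(np.std(resid, ddof=1))
    if sd < 1e-12:
        out = resid * 0.0
    else:
        out = resid / sd
    out.index = df["sample"].values
    return out


def _effect_fraction(spec: PowerSpec) -> float:
    frac = spec.beta_std**2 * spec.genotype_variance
    if frac >= 1.0:
        raise ValueError(
            "invalid effect: beta_std^2 * 2p(1-p) must be < 1 for an effect "
            "expressed in phenotype-SD units"
        )
    return frac


def power_closed_form(spec: PowerSpec) -> float:
    """Power of the two-sided 1-df additive genotype test.

    Noncentrality lambda = n * beta^2 * 2p(1-p) / (1 - beta^2 * 2p(1-p));
    power = P(noncentral-chi2(1, lambda) > chi2 critical at 1 - alpha).
    """
    frac = _effect_fraction(spec)
    lam = spec.n * frac / (1.0 - frac)
    crit = stats.chi2.ppf(1.0 - spec.alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=lam)) if lam > 0 else float(spec.alpha)


def power_monte_carlo(
    spec: PowerSpec, reps: int = 20_000, seed: int = 0, chunk: int = 4_000
) -> float:
    """Simulated power of the additive test, as an independent check.

    Each replicate draws Hardy-Weinberg genotypes at the effect-allele
    frequency, a phenotype with per-allele slope sized so the standardized
    effect equals ``beta_std`` (raw slope beta / sqrt(1 - beta^2 * 2p(1-p))
    on unit residual noise), and applies the two-sided slope test at
    ``alpha``.  Returns the rejection fraction; reproducible given seed.
    """
    if reps < 1000:
        raise ValueError("reps must be >= 1000")
    frac = _effect_fraction(spec)
    slope = spec.beta_std / np.sqrt(1.0 - frac)
    rng = np.random.default_rng(seed)
    n = spec.n
    rejections = 0
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        g = rng.binomial(2, spec.allele_freq, size=(m, n)).astype(float)
        y = slope * g + rng.standard_normal((m, n))
        gc = g - g.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        gss = np.einsum("ij,ij->i", gc, gc)
        yss = np.einsum("ij,ij->i", yc, yc)
        cross = np.einsum("ij,ij->i", gc, yc)
        valid = (gss > 0) & (yss > 0)
        r = np.zeros(m)
        r[valid] = cross[valid] / np.sqrt(gss[valid] * yss[valid])
        r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        pvals = 2 * stats.t.sf(np.abs(t), df=n - 2)
        rejections += int(np.sum(valid & (pvals < spec.alpha)))
        done += m
    return rejections / reps
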