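"""Inference battery: paired contrasts, ANCOVA, age-controlled partial
correlations with BH-FDR, and the correlation sample-size calculator.

All tests are two-sided at alpha = .05 unless stated otherwise.  Missing
cells are handled pairwise-complete and the n actually used is reported per
test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import integrate, special
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "PowerSpec",
    "PowerResult",
    "paired_t",
    "ancova",
    "partial_pearson",
    "fdr_bh",
    "power_for_correlation",
    "n_for_correlation",
    "AssociationReport",
    "association_battery",
]

SCALES = ("cesdc", "staich", "kars")


@dataclass(frozen=True)
class TestResult:
    """One test statistic with its degrees of freedom and two-sided p."""

    statistic: str            # "t" | "F" | "r"
    value: float
    df: float | tuple[float, float]
    p: float
    n: int
    covariates: tuple[str, ...] = ()

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError("p must lie in [0, 1]")


def _complete_rows(*arrays) -> list[np.ndarray]:
    cols = [np.asarray(a, float) for a in arrays]
    stacked = np.column_stack(cols)
    ok = np.isfinite(stacked).all(axis=1)
    return [c[ok] for c in cols]


def paired_t(x, y) -> TestResult:
    """Classical paired t test on pairwise-complete (x, y).

    Identical samples give t = 0, p = 1; a constant non-zero difference has
    no estimable variance and raises.
    """
    x, y = _complete_rows(x, y)
    n = len(x)
    if n < 3:
        raise ValueError("paired_t needs at least 3 complete pairs")
    d = x - y
    if np.allclose(d, 0.0):
        return TestResult("t", 0.0, float(n - 1), 1.0, n)
    if np.std(d, ddof=1) == 0.0:
        raise ValueError("paired_t: zero-variance non-zero differences")
    t, p = sps.ttest_rel(x, y)
    return TestResult("t", float(t), float(n - 1), float(p), n)


def ancova(
    y,
    factor,
    covariate,
    ss_type: int = 2,
    factor_name: str = "factor",
    covariate_name: str = "covariate",
) -> dict[str, TestResult]:
    """ANCOVA of y on a 2-level factor plus a continuous covariate.

    F statistics come from model-comparison sums of squares (Type II by
    default; Type III with sum-to-zero contrasts available), numerator df 1
    each, denominator df n - 3.
    """
    y_arr = np.asarray(y, float).ravel()
    fac_arr = np.asarray(factor, object).ravel()
    cov_arr = np.asarray(covariate, float).ravel()
    if not (len(y_arr) == len(fac_arr) == len(cov_arr)):
        raise ValueError("ancova: inputs must have equal length")
    frame = pd.DataFrame({"y": y_arr, "fac": fac_arr, "cov": cov_arr}).dropna()
    n = len(frame)
    if n < 5:
        raise ValueError("ancova needs n >= 5")
    levels = frame["fac"].unique()
    if len(levels) != 2:
        raise ValueError(f"factor must have exactly 2 levels, found {len(levels)}")
    if frame["cov"].nunique() == 1 and frame.groupby("fac")["cov"].mean().nunique() == 1:
        raise ValueError("covariate is constant: collinear with the intercept")

    if ss_type == 3:
        formula = "y ~ C(fac, Sum) + cov"
    elif ss_type == 2:
        formula = "y ~ C(fac) + cov"
    else:
        raise ValueError("ss_type must be 2 or 3")
    fit = smf.ols(formula, data=frame).fit()
    tss = float(((frame["y"] - frame["y"].mean()) ** 2).sum())
    if fit.ssr <= max(tss, 1.0) * 1e-12:
        raise ValueError("ancova: zero residual variance")
    table = sm.stats.anova_lm(fit, typ=ss_type)
    fac_row = [ix for ix in table.index if ix.startswith("C(fac")][0]
    df_den = float(n - 3)
    out = {}
    for key, row_name in ((factor_name, fac_row), (covariate_name, "cov")):
        out[key] = TestResult(
            "F",
            float(table.loc[row_name, "F"]),
            (float(table.loc[row_name, "df"]), df_den),
            float(table.loc[row_name, "PR(>F)"]),
            n,
            covariates=(covariate_name,) if key == factor_name else (),
        )
    return out


def partial_pearson(x, y, covariates=None) -> TestResult:
    """Pearson correlation of x and y after residualizing both on the
    covariates (plus an intercept); p from t with df = n - k - 2."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if covariates is None:
        Z = np.empty((len(x), 0))
    else:
        Z = np.asarray(covariates, float)
        if Z.ndim == 1:
            Z = Z[:, None]
    cols = _complete_rows(x, y, *(Z[:, j] for j in range(Z.shape[1])))
    x, y = cols[0], cols[1]
    Z = np.column_stack(cols[2:]) if Z.shape[1] else np.empty((len(x), 0))
    n, k = len(x), Z.shape[1]
    if n < k + 4:
        raise ValueError(f"partial correlation needs n >= covariates + 4 (n={n}, k={k})")
    design = np.column_stack([np.ones(n), Z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    sx, sy = np.std(rx), np.std(ry)
    if sx <= 1e-12 * max(1.0, np.std(x)) or sy <= 1e-12 * max(1.0, np.std(y)):
        raise ValueError("partial_pearson: a variable has zero residual variance")
    r = float(np.dot(rx, ry) / (np.sqrt(np.dot(rx, rx)) * np.sqrt(np.dot(ry, ry))))
    r = min(1.0, max(-1.0, r))
    df = n - k - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult("r", r, float(df), p, n,
                      covariates=tuple(f"z{j+1}" for j in range(k)))


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        raise ValueError("fdr_bh: empty p-value family")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# sample size for a correlation


@dataclass(frozen=True)
class PowerSpec:
    """Design target for detecting a Pearson correlation."""

    r: float
    alpha: float = 0.05
    power: float = 0.80
    inflation: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.r < 1.0:
            raise ValueError("r must lie in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise ValueError("power must lie in (0, 1)")
        if self.inflation < 0:
            raise ValueError("inflation must be >= 0")


@dataclass(frozen=True)
class PowerResult:
    n: int
    n_inflated: int
    spec: PowerSpec
    method: str


def _exact_r_density(x: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Sampling density of the Pearson r of a bivariate-normal sample."""
    x = np.asarray(x, float)
    ln = (
        math.log(n - 2)
        + special.gammaln(n - 1)
        - special.gammaln(n - 0.5)
        - 0.5 * math.log(2 * math.pi)
        + 0.5 * (n - 1) * math.log1p(-rho * rho)
        + 0.5 * (n - 4) * np.log1p(-x * x)
        - (n - 1.5) * np.log1p(-rho * x)
    )
    return np.exp(ln) * special.hyp2f1(0.5, 0.5, n - 0.5, (rho * x + 1) / 2)


def power_for_correlation(r: float, n: int, alpha: float = 0.05,
                          method: str = "fisher") -> float:
    """Two-sided power to detect a true correlation ``r`` at sample size n."""
    if n < 4:
        return 0.0
    if method == "fisher":
        z = math.atanh(r) * math.sqrt(n - 3)
        crit = sps.norm.ppf(1 - alpha / 2)
        return float(sps.norm.sf(crit - z) + sps.norm.cdf(-crit - z))
    if method == "exact":
        t_crit = sps.t.ppf(1 - alpha / 2, n - 2)
        r_crit = t_crit / math.sqrt(n - 2 + t_crit**2)
        upper, _ = integrate.quad(_exact_r_density, r_crit, 1.0, args=(r, n))
        lower, _ = integrate.quad(_exact_r_density, -1.0, -r_crit, args=(r, n))
        return float(upper + lower)
    raise ValueError("method must be 'fisher' or 'exact'")


def n_for_correlation(
    spec: PowerSpec | float,
    alpha: float = 0.05,
    power: float = 0.80,
    inflation: float = 0.0,
    method: str = "fisher",
) -> PowerResult:
    """Minimum n detecting the target correlation.

    ``fisher`` (default) is the z-transform closed form
    ``n = ceil(((z_{1-a/2} + z_pow) / atanh(r))^2 + 3)``; ``exact`` searches
    the smallest n whose exact bivariate-normal power reaches the target.
    """
    if not isinstance(spec, PowerSpec):
        spec = PowerSpec(r=float(spec), alpha=alpha, power=power, inflation=inflation)
    if method == "fisher":
        za = sps.norm.ppf(1 - spec.alpha / 2)
        zb = sps.norm.ppf(spec.power)
        n = math.ceil(((za + zb) / math.atanh(spec.r)) ** 2 + 3)
    elif method == "exact":
        n = 5
        while power_for_correlation(spec.r, n, spec.alpha, "exact") < spec.power:
            n += 1
            if n > 100_000:
                raise RuntimeError("sample-size search did not converge")
    else:
        raise ValueError("method must be 'fisher' or 'exact'")
    n_inflated = math.ceil(n * (1 + spec.inflation))
    return PowerResult(n=n, n_inflated=n_inflated, spec=spec, method=method)


# ---------------------------------------------------------------------------
# the headline association battery


@dataclass
class AssociationReport:
    """ANCOVA and age-controlled partial-correlation results for E-scores."""

    ancova: pd.DataFrame
    partials: pd.DataFrame
    mutual_partials: pd.DataFrame | None = None
    alpha: float = 0.05
    fdr_family: str = "partials"

    def significant(self) -> pd.DataFrame:
        return self.partials[self.partials["p_fdr"] < self.alpha]


def association_battery(
    escores: pd.DataFrame,
    participants: pd.DataFrame,
    ss_type: int = 2,
    alpha: float = 0.05,
    mutual_control: bool = False,
    min_n: int = 10,
) -> AssociationReport:
    """ANCOVA (gender + age) per E-score, then age-controlled partial
    correlations of each E-score with the three scales.

    The FDR family is the 3 x 3 partial-correlation battery; the optional
    mutual-control partials (each scale controlling for the other two and
    age) form their own family.
    """
    scores = escores.copy()
    if scores.index.name != "participant_id":
        if "participant_id" in scores.columns:
            scores = scores.set_index("participant_id")
        else:
            scores.index.name = "participant_id"
    merged = scores.join(participants.set_index("participant_id"), how="inner")
    if len(merged) < min_n:
        raise ValueError(f"only {len(merged)} joined participants (minimum {min_n})")
    escore_cols = [c for c in scores.columns]

    ancova_rows = []
    for col in escore_cols:
        res = ancova(merged[col], merged["gender"], merged["age_years"],
                     ss_type=ss_type, factor_name="gender", covariate_name="age")
        for term in ("gender", "age"):
            t = res[term]
            ancova_rows.append({
                "escore": col, "term": term, "F": t.value,
                "df_num": t.df[0], "df_den": t.df[1], "p": t.p, "n": t.n,
            })

    partial_rows = []
    for col in escore_cols:
        for scale in SCALES:
            t = partial_pearson(merged[col], merged[scale], merged[["age_years"]])
            partial_rows.append({
                "escore": col, "scale": scale, "r": t.value, "df": t.df,
                "p": t.p, "n": t.n, "covariates": "age",
            })
    partials = pd.DataFrame(partial_rows)
    partials["p_fdr"] = fdr_bh(partials["p"].to_numpy())
    partials["significant"] = partials["p_fdr"] < alpha

    mutual = None
    if mutual_control:
        rows = []
        for col in escore_cols:
            for scale in SCALES:
                others = [s for s in SCALES if s != scale]
                covs = merged[["age_years", *others]]
                t = partial_pearson(merged[col], merged[scale], covs)
                rows.append({
                    "escore": col, "scale": scale, "r": t.value, "df": t.df,
                    "p": t.p, "n": t.n, "covariates": "age+" + "+".join(others),
                })
        mutual = pd.DataFrame(rows)
        mutual["p_fdr"] = fdr_bh(mutual["p"].to_numpy())
        mutual["significant"] = mutual["p_fdr"] < alpha

    return AssociationReport(ancova=pd.DataFrame(ancova_rows), partials=partials,
                             mutual_partials=mutual, alpha=alpha)
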