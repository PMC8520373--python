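"""Synthetic CHD cohort generation and the downstream risk statistics.

The generator emulates a two-group cardiac-CT cohort: epicardial
adipose tissue (EAT) volume is Normal(124.50, 26.72^2) mL in controls
and Normal(159.41, 38.51^2) mL in CHD patients (both truncated at 0).
For CHD patients a Gaussian copula links EAT to the Gensini severity
score and to the number of stenosed coronary vessels (NSCV) with
configurable Spearman rank correlations (defaults 0.327 and 0.416);
the latent Pearson correlation is obtained from the rank correlation
via rho = 2 sin(pi * r_s / 6).  Age, sex, BMI, uric acid, smoking,
hypertension and diabetes are drawn with group-shifted means or
prevalences so that age, smoking, hypertension, diabetes and EAT are
higher in the CHD group in expectation.

Analyses: multivariable logistic regression (maximum likelihood, Wald
inference), Spearman rank correlation, empirical ROC with Youden-index
threshold selection, and per-field two-group comparison (Welch t-test
for numeric fields, continuity-corrected chi-square for binary ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score, roc_curve


class ConvergenceError(RuntimeError):
    """Logistic fit failed to converge (e.g. perfect separation)."""


@dataclass
class CohortParams:
    """Generator calibration; EAT moments and rank correlations are the
    published group parameters, the remaining covariate settings are
    fixed plausible values (see module docs)."""

    n_control: int = 42
    n_chd: int = 68
    eat_mean_control: float = 124.50
    eat_sd_control: float = 26.72
    eat_mean_chd: float = 159.41
    eat_sd_chd: float = 38.51
    rho_eat_gensini: float = 0.327
    rho_eat_nscv: float = 0.416
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_chd < 2:
            raise ValueError("need at least 2 patients per group")
        if self.eat_sd_control <= 0 or self.eat_sd_chd <= 0:
            raise ValueError("EAT standard deviations must be positive")
        for r in (self.rho_eat_gensini, self.rho_eat_nscv):
            if not (-1.0 < r < 1.0):
                raise ValueError("rank correlations must lie in (-1, 1)")


# group-level covariate settings: (control, CHD)
AGE_MEAN = (59.85, 61.67)
AGE_SD = (7.67, 6.28)
MALE_PREVALENCE = (28 / 42, 42 / 68)
BMI_MEAN = (24.6, 25.1)
BMI_SD = (3.1, 3.2)
URIC_ACID_MEAN = (338.0, 352.0)  # umol/L
URIC_ACID_SD = (72.0, 78.0)
SMOKING_PREVALENCE = (0.24, 0.46)
HYPERTENSION_PREVALENCE = (0.31, 0.54)
DIABETES_PREVALENCE = (0.14, 0.32)
# single/double/multi-vessel mix among CHD patients
NSCV_PROPORTIONS = (10 / 48, 19 / 48, 19 / 48)
GENSINI_GAMMA_SHAPE = 2.0
GENSINI_GAMMA_SCALE = 16.0


def _latent_corr(spearman_r: float) -> float:
    """Pearson correlation of the Gaussian copula achieving a target
    Spearman rank correlation: rho = 2 sin(pi r / 6)."""
    return 2.0 * np.sin(np.pi * spearman_r / 6.0)


def _truncated_normal_at_zero(mean: float, sd: float):
    return st.truncnorm((0.0 - mean) / sd, np.inf, loc=mean, scale=sd)


def generate_cohort(params: CohortParams | None = None) -> pd.DataFrame:
    """Draw a synthetic two-group cohort, one row per patient.

    Deterministic for a fixed ``params.seed``.  Controls carry Gensini 0
    and NSCV category 'none' (their stenoses are below the CHD
    threshold by construction); CHD patients receive copula-linked
    Gensini scores and NSCV categories.
    """
    if params is None:
        params = CohortParams()
    rng = np.random.default_rng(params.seed)

    r_eg = _latent_corr(params.rho_eat_gensini)
    r_en = _latent_corr(params.rho_eat_nscv)
    # conditional independence of Gensini and NSCV given the EAT latent
    corr = np.array(
        [
            [1.0, r_eg, r_en],
            [r_eg, 1.0, r_eg * r_en],
            [r_en, r_eg * r_en, 1.0],
        ]
    )
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("rank correlations give a non-PSD copula") from exc

    def covariates(n: int, g: int, chd: int) -> dict[str, np.ndarray]:
        return {
            "age": rng.normal(AGE_MEAN[g], AGE_SD[g], n),
            "sex": rng.binomial(1, MALE_PREVALENCE[g], n),
            "bmi": rng.normal(BMI_MEAN[g], BMI_SD[g], n),
            "uric_acid": rng.normal(URIC_ACID_MEAN[g], URIC_ACID_SD[g], n),
            "smoking": rng.binomial(1, SMOKING_PREVALENCE[g], n),
            "hypertension": rng.binomial(1, HYPERTENSION_PREVALENCE[g], n),
            "diabetes": rng.binomial(1, DIABETES_PREVALENCE[g], n),
            "chd": np.full(n, chd, dtype=int),
        }

    # controls
    nc = params.n_control
    eat_ctrl_dist = _truncated_normal_at_zero(
        params.eat_mean_control, params.eat_sd_control
    )
    ctrl = covariates(nc, 0, 0)
    ctrl["eat_ml"] = eat_ctrl_dist.ppf(rng.uniform(size=nc))
    ctrl["gensini"] = np.zeros(nc)
    ctrl["nscv_category"] = np.array(["none"] * nc, dtype=object)

    # CHD patients: copula-linked EAT / Gensini / NSCV
    nd = params.n_chd
    z = rng.standard_normal((nd, 3)) @ chol.T
    u = st.norm.cdf(z)
    eat_chd_dist = _truncated_normal_at_zero(params.eat_mean_chd, params.eat_sd_chd)
    chd = covariates(nd, 1, 1)
    chd["eat_ml"] = eat_chd_dist.ppf(u[:, 0])
    chd["gensini"] = st.gamma.ppf(
        u[:, 1], a=GENSINI_GAMMA_SHAPE, scale=GENSINI_GAMMA_SCALE
    )
    cuts = np.cumsum(NSCV_PROPORTIONS)[:2]
    cat_idx = np.searchsorted(cuts, u[:, 2])
    chd["nscv_category"] = np.array(["single", "double", "multi"], dtype=object)[
        cat_idx
    ]

    cols = [
        "age",
        "sex",
        "bmi",
        "uric_acid",
        "smoking",
        "hypertension",
        "diabetes",
        "eat_ml",
        "chd",
        "gensini",
        "nscv_category",
    ]
    df = pd.concat(
        [pd.DataFrame(ctrl), pd.DataFrame(chd)], ignore_index=True
    )[cols]
    df["nscv_level"] = df["nscv_category"].map(
        {"none": 0, "single": 1, "double": 2, "multi": 3}
    )
    return df


def generate_logistic_sample(
    n: int,
    beta: float = 0.023,
    intercept: float | None = None,
    x_mean: float = 140.0,
    x_sd: float = 35.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw (eat_ml, chd) pairs from a known logistic model.

    Used for slope-recovery checks: ``P(chd=1 | x) = expit(intercept +
    beta * x)``; when ``intercept`` is omitted it is set to
    ``-beta * x_mean`` so both outcome classes are well represented.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(x_mean, x_sd, n)
    b0 = -beta * x_mean if intercept is None else intercept
    p = 1.0 / (1.0 + np.exp(-(b0 + beta * x)))
    y = rng.binomial(1, p)
    return pd.DataFrame({"eat_ml": x, "chd": y})


@dataclass
class LogisticResult:
    """Wald table of a maximum-likelihood logistic regression."""

    table: pd.DataFrame  # index: const + covariates; columns B, SE, wald, OR, ...
    converged: bool
    n_iterations: int
    n_obs: int

    def coef(self, name: str) -> pd.Series:
        return self.table.loc[name]


def logistic_fit(
    cohort: pd.DataFrame, outcome: str, covariates: list[str]
) -> LogisticResult:
    """Fit outcome ~ covariates by maximum likelihood (Newton IRLS).

    Standard errors come from the inverse observed information, Wald
    statistics are (B/SE)^2 with chi-square(1) p-values, odds ratios are
    exp(B) with 95% CI exp(B +- 1.96 SE).  Perfect separation or
    non-convergence raises :class:`ConvergenceError` rather than
    returning unreliable estimates.
    """
    yv = cohort[outcome].to_numpy()
    if not np.isin(np.unique(yv), (0, 1)).all():
        raise ValueError("outcome must be binary 0/1")
    X = cohort[covariates].to_numpy(dtype=float)
    if any(np.ptp(X[:, j]) == 0 for j in range(X.shape[1])):
        raise ValueError("constant covariate in the design")
    if len(yv) <= len(covariates) + 1:
        raise ValueError("need more observations than parameters")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(yv, Xc).fit(disp=0, maxiter=100)
        except Exception as exc:  # statsmodels raises on hard separation
            raise ConvergenceError(f"logistic fit failed: {exc}") from exc
    params = np.asarray(fit.params, dtype=float)
    bse = np.asarray(fit.bse, dtype=float)
    converged = bool(fit.mle_retvals.get("converged", False))
    if not converged or not (np.isfinite(params).all() and np.isfinite(bse).all()):
        raise ConvergenceError(
            "logistic fit did not converge (possible perfect separation)"
        )

    names = ["const"] + list(covariates)
    wald = (params / bse) ** 2
    table = pd.DataFrame(
        {
            "B": params,
            "SE": bse,
            "wald": wald,
            "OR": np.exp(params),
            "ci95_low": np.exp(params - 1.959963984540054 * bse),
            "ci95_high": np.exp(params + 1.959963984540054 * bse),
            "p": st.chi2.sf(wald, df=1),
        },
        index=names,
    )
    return LogisticResult(
        table=table,
        converged=converged,
        n_iterations=int(fit.mle_retvals.get("iterations", 0)),
        n_obs=len(yv),
    )


@dataclass
class SpearmanResult:
    r: float
    p: float
    n: int


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation: Pearson correlation of midranks with a
    t-approximation p-value on n - 2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-D vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    res = st.spearmanr(x, y)
    return SpearmanResult(r=float(res.statistic), p=float(res.pvalue), n=x.size)


@dataclass
class ROCResult:
    auc: float
    points: pd.DataFrame  # columns fpr, tpr, threshold
    optimal_threshold: float
    sensitivity: float
    specificity: float
    youden_j: float


def roc_analysis(scores, labels) -> ROCResult:
    """Empirical ROC over all score thresholds, AUC by the trapezoidal rule
    (= the tie-corrected Mann-Whitney statistic).

    The operating threshold maximizes Youden's J = sensitivity +
    specificity - 1; candidate thresholds are midpoints between
    consecutive distinct scores (classification rule: score >= t is
    called positive), ties broken at the lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if not np.isin(classes, (0, 1)).all() or classes.size != 2:
        raise ValueError("labels must contain both classes 0 and 1")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thr = roc_curve(labels, scores)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})

    uniq = np.unique(scores)
    candidates = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else uniq
    pos = labels == 1
    best = None
    for t in candidates:  # ascending, so ties keep the lower threshold
        called = scores >= t
        sens = np.mean(called[pos])
        spec = np.mean(~called[~pos])
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, t, sens, spec)
    j, t, sens, spec = best
    return ROCResult(
        auc=auc,
        points=points,
        optimal_threshold=float(t),
        sensitivity=float(sens),
        specificity=float(spec),
        youden_j=float(j),
    )


@dataclass
class GroupComparison:
    field: str
    test: str  # welch_t | chi2
    mean_control: float
    sd_control: float
    mean_chd: float
    sd_chd: float
    statistic: float
    p: float


def group_compare(
    cohort: pd.DataFrame, fieldname: str, group_col: str = "chd"
) -> GroupComparison:
    """Two-group comparison: Welch t for numeric fields, continuity-
    corrected chi-square for binary fields."""
    g0 = cohort.loc[cohort[group_col] == 0, fieldname].to_numpy(dtype=float)
    g1 = cohort.loc[cohort[group_col] == 1, fieldname].to_numpy(dtype=float)
    if g0.size == 0 or g1.size == 0:
        raise ValueError("both groups must be non-empty")
    values = np.concatenate([g0, g1])
    binary = np.isin(np.unique(values), (0, 1)).all()
    if binary:
        table = np.array(
            [
                [np.sum(g0 == 1), np.sum(g0 == 0)],
                [np.sum(g1 == 1), np.sum(g1 == 0)],
            ]
        )
        chi2, p, _, _ = st.chi2_contingency(table, correction=True)
        stat, test = float(chi2), "chi2"
    else:
        tres = st.ttest_ind(g0, g1, equal_var=False)
        stat, p, test = float(tres.statistic), float(tres.pvalue), "welch_t"
    return GroupComparison(
        field=fieldname,
        test=test,
        mean_control=float(g0.mean()),
        sd_control=float(g0.std(ddof=1)),
        mean_chd=float(g1.mean()),
        sd_chd=float(g1.std(ddof=1)),
        statistic=stat,
        p=float(p),
    )
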