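"""Statistical layer: group comparisons, mixed factorial ANCOVA with an age
covariate, effect sizes, correlation comparison with FDR control,
linear-vs-quadratic AICc model comparison, and Kaplan-Meier/log-rank analysis
of achieved n-back level.

The mixed ANCOVA is computed through the general linear model using
per-subject within-contrast scores: with every within-subject factor at two
levels, each within effect is a 1-df contrast, so its test (and its
interactions with the between factor and the covariate) reduces to an OLS
regression of the subject contrast scores on a sum-coded group term and the
mean-centered covariate.  This reproduces Type III sums of squares exactly
and keeps every F on (1, n - p) degrees of freedom.  An ANCOVA is only
trusted when the homogeneity-of-regression pre-test (group x covariate) is
non-significant; otherwise the model is refit without the covariate and the
result flagged.

Partial eta squared is SS_effect / (SS_effect + SS_error), which for a 1-df
effect equals F / (F + df_error).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

ALPHA = 0.05
FDR_Q = 0.10


@dataclass
class AnovaResult:
    effect: str
    F: float
    df1: int
    df2: int
    p: float
    eta_p_sq: float

    def __post_init__(self):
        # self-consistency of the 1-df effect-size identity
        if self.df1 == 1 and np.isfinite(self.F):
            expect = partial_eta_sq(self.F, self.df1, self.df2)
            assert abs(self.eta_p_sq - expect) < 1e-9


@dataclass
class TTestResult:
    t: float
    df: int
    p: float


def partial_eta_sq(F: float, df1: int, df2: int) -> float:
    """Partial eta squared from an F ratio: F*df1 / (F*df1 + df2)."""
    if F < 0 or df1 < 1 or df2 < 1:
        raise ValueError("need F >= 0 and df >= 1")
    return F * df1 / (F * df1 + df2)


# --------------------------------------------------------------------------- #
# simple comparisons


def two_sample_t(
    a=None, b=None, *, mean1=None, sd1=None, n1=None, mean2=None, sd2=None, n2=None
) -> TTestResult:
    """Pooled-variance two-sample t test, from samples or printed summaries."""
    if a is not None:
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        if a.size < 2 or b.size < 2:
            raise ValueError("need n >= 2 per group")
        if a.std() == 0 and b.std() == 0:
            raise ValueError("zero variance in both groups")
        t, p = sps.ttest_ind(a, b, equal_var=True)
        return TTestResult(float(t), a.size + b.size - 2, float(p))
    t, p = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return TTestResult(float(t), int(n1 + n2 - 2), float(p))


def paired_t(a, b) -> TTestResult:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    t, p = sps.ttest_rel(a, b)
    return TTestResult(float(t), a.size - 1, float(p))


def chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square on a contingency table (no continuity correction)."""
    table = np.asarray(table, float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has an all-zero margin")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


# --------------------------------------------------------------------------- #
# mixed factorial ANCOVA


@dataclass
class MixedAncovaResult:
    effects: list[AnovaResult]
    homogeneity_p: float | None
    covariate_used: bool
    downgraded: bool
    n_subjects: int

    def __getitem__(self, effect: str) -> AnovaResult:
        for e in self.effects:
            if e.effect == effect:
                return e
        raise KeyError(effect)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.effects])


def _ols_term_tests(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, int]:
    """Wald t^2 (= Type III F for 1-df terms) per column of X; returns (F, df2)."""
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df2 = n - p
    sse = float(resid @ resid)
    if df2 <= 0:
        raise ValueError("not enough subjects for the model")
    mse = sse / df2
    XtX_inv = np.linalg.pinv(X.T @ X)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = beta**2 / (mse * np.diag(XtX_inv))
    return F, df2


def mixed_ancova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    between: str,
    within: list[str],
    covariate: str | None = None,
    alpha: float = ALPHA,
    force_covariate: bool = False,
) -> MixedAncovaResult:
    """Mixed factorial AN(C)OVA: one 2-level between factor, 2-level within
    factors, and at most one covariate.

    ``data`` is long-format with one row per subject x within-cell.  Every
    subject must have a complete set of within cells.  The homogeneity-of-
    regression assumption (group x covariate interaction on the subject means)
    is pre-tested at ``alpha``; on violation the covariate is dropped and the
    result flagged (``force_covariate=True`` keeps it regardless).
    """
    cols = [subject, between, dv] + within + ([covariate] if covariate else [])
    if data[cols].isna().any().any():
        raise ValueError("missing values in model columns")
    glevels = sorted(data[between].unique())
    if len(glevels) != 2:
        raise ValueError("between factor must have exactly 2 levels")
    wlevels = {}
    for w in within:
        lv = sorted(data[w].unique())
        if len(lv) != 2:
            raise ValueError(f"within factor {w!r} must have exactly 2 levels")
        wlevels[w] = lv

    wide = data.pivot_table(index=subject, columns=within, values=dv)
    if wide.isna().any().any():
        raise ValueError("unbalanced design: some subjects miss within cells")
    subj_info = data.drop_duplicates(subject).set_index(subject)
    subj_info = subj_info.loc[wide.index]
    g = np.where(subj_info[between].to_numpy() == glevels[0], 1.0, -1.0)
    n = len(wide)

    cov = None
    homo_p = None
    use_cov = covariate is not None
    downgraded = False
    if covariate is not None:
        cov_raw = subj_info[covariate].to_numpy(dtype=float)
        if np.ptp(cov_raw) == 0:
            raise ValueError("covariate is constant")
        cov = cov_raw - cov_raw.mean()
        # homogeneity of regression slopes on the subject means
        ymean = wide.to_numpy().mean(axis=1)
        Xh = np.column_stack([np.ones(n), g, cov, g * cov])
        Fh, dfh = _ols_term_tests(ymean, Xh)
        homo_p = float(sps.f.sf(Fh[3], 1, dfh))
        if homo_p < alpha and not force_covariate:
            logger.warning(
                "homogeneity of regression violated (p=%.4f); covariate dropped", homo_p
            )
            use_cov = False
            downgraded = True

    # contrast codes per within cell (columns of the wide frame)
    cells = list(wide.columns) if len(within) > 1 else [(c,) for c in wide.columns]
    codes = {}
    for w in within:
        i = within.index(w)
        codes[w] = np.array([1.0 if c[i] == wlevels[w][0] else -1.0 for c in cells])

    Y = wide.to_numpy()
    X = (
        np.column_stack([np.ones(n), g, cov])
        if use_cov
        else np.column_stack([np.ones(n), g])
    )
    cov_name = covariate if covariate else "covariate"

    effects: list[AnovaResult] = []

    def add(name: str, F: float, df2: int):
        p = float(sps.f.sf(F, 1, df2))
        effects.append(AnovaResult(name, float(F), 1, df2, p, partial_eta_sq(F, 1, df2)))

    for r in range(len(within) + 1):
        for sub in combinations(within, r):
            code = np.ones(len(cells))
            for w in sub:
                code = code * codes[w]
            score = (Y * code).mean(axis=1)
            F, df2 = _ols_term_tests(score, X)
            base = ":".join(sub)
            if not sub:
                add(between, F[1], df2)
                if use_cov:
                    add(cov_name, F[2], df2)
            else:
                add(base, F[0], df2)
                add(f"{between}:{base}", F[1], df2)
                if use_cov:
                    add(f"{cov_name}:{base}", F[2], df2)

    return MixedAncovaResult(
        effects=effects,
        homogeneity_p=homo_p,
        covariate_used=use_cov,
        downgraded=downgraded,
        n_subjects=n,
    )


# --------------------------------------------------------------------------- #
# correlations


@dataclass
class CorrelationComparison:
    by_group: dict
    z: float | None
    p: float | None
    flag: str = ""


def correlate_and_compare(x, y, groups) -> CorrelationComparison:
    """Per-group Pearson correlations and their Fisher r-to-z comparison.

    The between-group test uses z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) +
    1/(n2-3)); it is undefined (flagged) when either correlation sits on the
    +/-1 boundary.
    """
    df = pd.DataFrame({"x": np.asarray(x, float), "y": np.asarray(y, float),
                       "g": np.asarray(groups)})
    out = {}
    for gname, sub in df.groupby("g", sort=True):
        if len(sub) < 4:
            raise ValueError(f"group {gname!r} has fewer than 4 pairs")
        if sub["x"].std() == 0 or sub["y"].std() == 0:
            raise ValueError(f"zero variance in group {gname!r}")
        r, p = sps.pearsonr(sub["x"], sub["y"])
        out[gname] = dict(r=float(r), p=float(p), n=len(sub))
    if len(out) != 2:
        raise ValueError("need exactly 2 groups")
    (r1, n1), (r2, n2) = [(v["r"], v["n"]) for v in out.values()]
    if abs(r1) >= 1 - 1e-12 or abs(r2) >= 1 - 1e-12:
        return CorrelationComparison(out, None, None, flag="boundary-correlation")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    return CorrelationComparison(out, float(z), float(2 * sps.norm.sf(abs(z))))


def bh_fdr(p_values, q: float = FDR_Q) -> np.ndarray:
    """Benjamini-Hochberg step-up: flags of hypotheses surviving at level q."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


# --------------------------------------------------------------------------- #
# linear vs quadratic model comparison


@dataclass
class ModelComparisonResult:
    r2_linear: float
    r2_quadratic: float
    aicc_linear: float
    aicc_quadratic: float
    p_quadratic_better: float
    coef_linear: np.ndarray = field(repr=False, default=None)
    coef_quadratic: np.ndarray = field(repr=False, default=None)
    flag: str = ""


def aicc(n: int, rss: float, k: int) -> float:
    """Gaussian-likelihood AICc: n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1).

    ``k`` counts the intercept, slopes, and the error scale.  The additive
    constant n(ln 2 pi + 1) cancels in differences and is omitted.
    """
    if n - k - 1 <= 0:
        raise ValueError("AICc undefined: n - k - 1 <= 0")
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def evidence_p(aic_quadratic: float, aic_linear: float) -> float:
    """Evidence p-value for 'quadratic better': exp((AIC_q - AIC_l)/2)."""
    return float(np.exp((aic_quadratic - aic_linear) / 2.0))


def lin_vs_quad_aicc(x, y) -> ModelComparisonResult:
    """Fit y ~ x and y ~ x + x^2, compare by AICc.

    p >= 1 means the penalized quadratic is no better than the linear fit
    (flagged "linear preferred").  Degenerate (zero-spread) x is an error;
    near-perfect fits are floored so the comparison reduces to the penalty
    difference instead of amplifying round-off.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 6:
        raise ValueError("need n >= 6 for the quadratic AICc")
    if np.ptp(x) == 0:
        raise ValueError("x has no spread")
    tss = float(np.sum((y - y.mean()) ** 2))
    floor = max(1e-12 * max(tss, 1.0), 1e-300)

    def fit(deg: int):
        X = np.vander(x, deg + 1, increasing=True)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        return beta, max(rss, floor)

    b1, rss1 = fit(1)
    b2, rss2 = fit(2)
    rss2 = min(rss2, rss1)  # nested models: quadratic RSS cannot exceed linear
    a1 = aicc(n, rss1, 3)
    a2 = aicc(n, rss2, 4)
    p = evidence_p(a2, a1)
    return ModelComparisonResult(
        r2_linear=1.0 - rss1 / tss if tss > 0 else 0.0,
        r2_quadratic=1.0 - rss2 / tss if tss > 0 else 0.0,
        aicc_linear=a1,
        aicc_quadratic=a2,
        p_quadratic_better=p,
        coef_linear=b1,
        coef_quadratic=b2,
        flag="linear preferred" if p >= 1 else "",
    )


# --------------------------------------------------------------------------- #
# Kaplan-Meier / log-rank on achieved n-back level


@dataclass
class SurvivalResult:
    curves: dict  # group -> DataFrame(level, survival)
    chi_square: float
    df: int
    p: float


def km_logrank(values_by_group: dict) -> SurvivalResult:
    """Kaplan-Meier curves over achieved mean n-back and the two-group log-rank.

    A larger mean n-back counts as longer "survival"; every session reaches a
    terminal level, so all observations are events (no censoring).
    """
    if len(values_by_group) < 2:
        raise ValueError("need at least 2 groups")
    if len(values_by_group) != 2:
        raise ValueError("log-rank comparison implemented for exactly 2 groups")
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    curves = {}
    arrs = []
    for gname, vals in values_by_group.items():
        v = np.asarray(vals, float)
        if v.size < 2:
            raise ValueError(f"group {gname!r} has fewer than 2 observations")
        arrs.append(v)
        kmf = KaplanMeierFitter()
        kmf.fit(v, event_observed=np.ones_like(v))
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["level", "survival"]
        curves[gname] = sf
    res = logrank_test(arrs[0], arrs[1])
    return SurvivalResult(
        curves=curves,
        chi_square=float(res.test_statistic),
        df=1,
        p=float(res.p_value),
    )
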