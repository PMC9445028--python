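"""Residual age-at-onset modelling and repeat-association statistics.

Huntington's disease onset is predicted from the inherited CAG length;
the residual R (observed minus expected onset, positive = later than
expected) is the phenotype tested for repeat-length association.  The
sequenced cohort was recruited for extreme residuals, so a plain linear
regression of R on a repeat statistic overestimates the effect.  The
"regression with selection" likelihood corrects this: each individual's
normal error density is weighted by the sigmoid selection function

    S(R) = 1 / (1 + exp((R_thr - |R|) / Delta))

and renormalised by an integral that depends on that individual's
predictor value.  The selection parameters (sigma, R_thr, Delta) are fit
beforehand by minimising the Kolmogorov-Smirnov distance between the
expected and observed cumulative distributions of |R|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, roots_legendre

__all__ = [
    "LangbehnModel",
    "SelectionModel",
    "RegressionFit",
    "expected_onset",
    "residual",
    "repeat_statistics",
    "cohort_statistics",
    "selection_function",
    "selection_normalizer",
    "selected_density",
    "fit_selection_model",
    "SelectionFitResult",
    "selection_loglik",
    "fit_regression_with_selection",
    "ols_association",
    "dichotomize_and_logistic",
    "compare_statistics",
    "conditional_association",
    "bonferroni_adjust",
]

REPEAT_STATISTICS = ("sum", "diff", "max", "min", "n3rep")


# ----------------------------------------------------------------------
# expected onset and residuals
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class LangbehnModel:
    """Parametric CAG-length -> expected age-at-motor-onset relation.

    Expected onset = a + exp(b - c * CAG), the published survival-model
    conditional mean (Langbehn et al. 2004, Clin Genet 65:267-277).  Any
    onset-expectation model can be swapped in by replacing the constants
    or the object.
    """

    a: float = 21.54
    b: float = 9.556
    c: float = 0.146
    cag_min: int = 36
    cag_max: int = 60
    citation: str = "Langbehn et al. 2004, Clin Genet 65:267-277"

    def expected_onset(self, cag):
        cag_arr = np.asarray(cag)
        if np.any(cag_arr < self.cag_min) or np.any(cag_arr > self.cag_max):
            raise ValueError(
                f"CAG length outside validated range [{self.cag_min}, "
                f"{self.cag_max}]; adjust the model bounds if this is intended"
            )
        out = self.a + np.exp(self.b - self.c * cag_arr)
        return float(out) if np.isscalar(cag) else out


def expected_onset(cag, model: LangbehnModel | None = None):
    return (model or LangbehnModel()).expected_onset(cag)


def residual(onset, cag, model: LangbehnModel | None = None):
    """R = observed onset - expected onset; positive = later than expected."""
    exp_onset = expected_onset(cag, model)
    out = np.asarray(onset) - exp_onset
    return float(out) if np.isscalar(onset) else out


# ----------------------------------------------------------------------
# repeat statistics
# ----------------------------------------------------------------------

def repeat_statistics(qtr_a, qtr_b, str_a=None, str_b=None) -> dict:
    """Per-individual statistics from the two allelic unit counts.

    ``n3rep`` is the dosage (0/1/2) of the three-repeat allele, judged by
    STR unit count when available and otherwise by the QTR length that
    uniquely identifies it in the built-in inventory (35 units).
    """
    a = np.asarray(qtr_a)
    b = np.asarray(qtr_b)
    if np.any(a < 1) or np.any(b < 1):
        raise ValueError("repeat unit counts must be >= 1")
    if str_a is not None and str_b is not None:
        three = (np.asarray(str_a) == 3).astype(int) + (
            np.asarray(str_b) == 3
        ).astype(int)
    else:
        three = (a == 35).astype(int) + (b == 35).astype(int)
    out = {
        "sum": a + b,
        "diff": np.abs(a - b),
        "min": np.minimum(a, b),
        "max": np.maximum(a, b),
        "n3rep": three,
    }
    if np.isscalar(qtr_a):
        out = {k: int(v) for k, v in out.items()}
    return out


def cohort_statistics(cohort: pd.DataFrame) -> pd.DataFrame:
    """Repeat statistics for a cohort table with qtr_a/qtr_b columns."""
    stats_ = repeat_statistics(
        cohort["qtr_a"].to_numpy(),
        cohort["qtr_b"].to_numpy(),
        cohort["str_a"].to_numpy() if "str_a" in cohort else None,
        cohort["str_b"].to_numpy() if "str_b" in cohort else None,
    )
    return pd.DataFrame(stats_, index=cohort.index)


# ----------------------------------------------------------------------
# selection model
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionModel:
    """Sigmoid extreme-residual recruitment model (years)."""

    sigma: float
    r_thr: float
    delta: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


def selection_function(R, model: SelectionModel):
    """S(R) = 1/(1 + exp((R_thr - |R|)/Delta)); Delta=0 is the indicator."""
    absr = np.abs(np.asarray(R, dtype=float))
    if model.delta == 0:
        out = np.where(
            absr > model.r_thr, 1.0, np.where(absr == model.r_thr, 0.5, 0.0)
        )
    else:
        out = expit((absr - model.r_thr) / model.delta)
    return float(out) if np.isscalar(R) else out


@lru_cache(maxsize=8)
def _gl_nodes(n: int = 48):
    x, w = roots_legendre(n)
    return x, w


def selection_normalizer(mu, sigma: float, model: SelectionModel) -> np.ndarray:
    """Z(mu) = integral of N(mu, sigma^2) density times S(R) over R.

    Computed in closed form (normal CDFs) when Delta is zero or
    negligible relative to sigma, otherwise by fixed-order
    Gauss-Legendre panels split at the kinks of |R| and at +-R_thr,
    which integrates the smooth sigmoid to near machine precision.
    """
    mu_arr = np.atleast_1d(np.asarray(mu, dtype=float))
    if model.delta < 1e-4 * sigma:
        if model.r_thr <= 0:
            z = np.ones_like(mu_arr)
        else:
            z = stats.norm.cdf((-model.r_thr - mu_arr) / sigma) + stats.norm.sf(
                (model.r_thr - mu_arr) / sigma
            )
    else:
        x, w = _gl_nodes()
        pts = np.array([-model.r_thr, 0.0, model.r_thr])
        # panel edges in standardised z-space, one row per mu: the integrand
        # is analytic inside each panel (kinks only at R in {0, +-R_thr})
        inner = np.sort(
            np.clip((pts[None, :] - mu_arr[:, None]) / sigma, -10.0, 10.0), axis=1
        )
        edges = np.concatenate(
            [np.full((len(mu_arr), 1), -10.0), inner,
             np.full((len(mu_arr), 1), 10.0)], axis=1
        )  # (nmu, 5)
        a = edges[:, :-1, None]
        h = (edges[:, 1:, None] - a)                      # (nmu, 4, 1)
        t = a + 0.5 * h * (x[None, None, :] + 1.0)        # (nmu, 4, nodes)
        fx = (
            np.exp(-0.5 * t * t) / np.sqrt(2 * np.pi)
            * expit((np.abs(mu_arr[:, None, None] + sigma * t) - model.r_thr)
                    / model.delta)
        )
        z = np.einsum("mpn,n->m", fx * (0.5 * h), w)
    return float(z[0]) if np.isscalar(mu) else z


def selected_density(R, model: SelectionModel):
    """p(R) = p_N(R) S(R) / Z, the selected-population residual density."""
    z = selection_normalizer(0.0, model.sigma, model)
    num = stats.norm.pdf(np.asarray(R, dtype=float), scale=model.sigma)
    out = num * selection_function(R, model) / z
    return float(out) if np.isscalar(R) else out


# ----------------------------------------------------------------------
# selection-model fitting (KS minimum-distance)
# ----------------------------------------------------------------------

def _folded_cdf(r_sorted: np.ndarray, model: SelectionModel) -> np.ndarray:
    """Expected CDF of |R| under the selected density, on sorted points."""
    top = max(float(r_sorted[-1]), model.r_thr + 2 * model.delta) + 10 * model.sigma
    grid = np.linspace(0.0, top, 4001)
    g = stats.norm.pdf(grid, scale=model.sigma) * selection_function(grid, model)
    cum = np.concatenate(([0.0], np.cumsum((g[1:] + g[:-1]) * 0.5 * np.diff(grid))))
    total = cum[-1]
    if total <= 0:
        return np.zeros_like(r_sorted)
    return np.interp(r_sorted, grid, cum) / total


def _ks_distance(r_sorted: np.ndarray, model: SelectionModel) -> float:
    n = len(r_sorted)
    fe = _folded_cdf(r_sorted, model)
    i = np.arange(1, n + 1)
    return float(np.max(np.maximum(np.abs(fe - i / n), np.abs(fe - (i - 1) / n))))


@dataclass(frozen=True)
class SelectionFitResult:
    model: SelectionModel
    D: float
    ks_p: float
    ks_p_approximate: bool = True  # parameters were fitted from the same data


def fit_selection_model(residuals, n_starts: int = 12) -> SelectionFitResult:
    """Fit (sigma, R_thr, Delta) by minimising the KS distance D.

    Multi-start grid followed by Nelder-Mead simplex refinement on
    (log sigma, R_thr, log Delta).  The one-sample KS p-value reported is
    the asymptotic value computed from D and n; it is flagged approximate
    because the parameters are estimated from the same sample.
    """
    r = np.sort(np.abs(np.asarray(residuals, dtype=float)))
    n = len(r)
    if n < 2 or np.allclose(r, r[0]):
        raise ValueError("degenerate residuals: cannot fit a selection model")
    if n < 50:
        warnings.warn(
            f"only {n} residuals; selection-model fit is unreliable below 50",
            stacklevel=2,
        )
    sd = float(np.std(np.concatenate([r, -r])))

    def objective(theta):
        s, t, d = np.exp(theta[0]), theta[1], np.exp(theta[2])
        if not (1e-3 < s < 1e3) or not (1e-6 < d < 1e3) or abs(t) > 1e3:
            return 1.0
        return _ks_distance(r, SelectionModel(s, t, d))

    starts = []
    for s0 in (sd, 0.6 * sd, 0.35 * sd):
        for t0 in (0.0, float(np.quantile(r, 0.25)), float(np.quantile(r, 0.6))):
            for d0 in (0.5, 3.0):
                starts.append((np.log(s0), t0, np.log(d0)))
    starts.sort(key=objective)
    best = None
    for x0 in starts[:n_starts]:
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
        )
        if best is None or res.fun < best.fun:
            best = res
    s, t, d = np.exp(best.x[0]), best.x[1], np.exp(best.x[2])
    model = SelectionModel(float(s), float(t), float(d))
    D = float(best.fun)
    ks_p = float(stats.kstwo.sf(D, n))
    return SelectionFitResult(model, D, ks_p)


# ----------------------------------------------------------------------
# regression with selection
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionFit:
    method: str                      # "ols" | "logistic" | "selection"
    beta0: float
    beta1: float
    sigma: float
    loglik: float
    lrt_p: float
    ci95_beta1: tuple[float, float] | None = None
    n: int = 0
    flags: tuple[str, ...] = ()
    coefficients: dict = field(default_factory=dict)


def selection_loglik(
    R: float, x: float, beta0: float, beta1: float, sigma: float,
    model: SelectionModel | None,
) -> float:
    """Log-likelihood term of one observation under selection.

    log p_N(eps) + log S(R) - log Z(beta0 + beta1*x), with
    eps = R - (beta0 + beta1*x).  With S == 1 (no selection model) this
    reduces exactly to the ordinary linear-regression log-likelihood
    term.
    """
    mu = beta0 + beta1 * x
    eps = R - mu
    term = stats.norm.logpdf(eps, scale=sigma)
    if model is None:
        return float(term)
    s = selection_function(R, model)
    if s <= 0:
        return -np.inf
    z = selection_normalizer(mu, sigma, model)
    if not np.isfinite(z) or z <= 0:
        raise FloatingPointError("non-finite selection normaliser")
    return float(term + np.log(s) - np.log(z))


def _sel_nll_factory(R: np.ndarray, X: np.ndarray, model: SelectionModel | None):
    """Vectorised negative log-likelihood over (log sigma, b0, betas).

    The selection normaliser is evaluated once per distinct predictor
    row (it depends on x only through mu), then broadcast back.
    """
    n, k = X.shape
    uniq, inv = np.unique(X, axis=0, return_inverse=True)
    log_s = 0.0
    if model is not None:
        s = selection_function(R, model)
        if np.any(s <= 0):
            log_s = None  # impossible observations under a hard threshold
        else:
            log_s = float(np.sum(np.log(s)))

    def nll(theta):
        sigma = float(np.exp(theta[0]))
        if not (1e-3 < sigma < 1e4):
            return 1e12
        b0 = theta[1]
        betas = np.asarray(theta[2 : 2 + k])
        mu = b0 + X @ betas
        eps = R - mu
        ll = -0.5 * n * np.log(2 * np.pi * sigma**2) - float(
            np.sum(eps**2)
        ) / (2 * sigma**2)
        if model is not None:
            if log_s is None:
                return 1e12
            mu_u = b0 + uniq @ betas
            z = selection_normalizer(mu_u, sigma, model)
            if np.any(z <= 0):
                return 1e12
            ll += log_s - float(np.sum(np.log(z)[inv]))
        return -ll

    return nll


def _minimize_nll(nll, x0_list, maxiter=600):
    best = None
    for x0 in x0_list:
        res = optimize.minimize(
            nll, np.asarray(x0, dtype=float), method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best


def _resolve_xr(records, statistic):
    if isinstance(records, pd.DataFrame):
        R = records["residual"].to_numpy(dtype=float)
        if statistic in records.columns:
            x = records[statistic].to_numpy(dtype=float)
        else:
            x = cohort_statistics(records)[statistic].to_numpy(dtype=float)
    else:
        x, R = records
        x = np.asarray(x, dtype=float)
        R = np.asarray(R, dtype=float)
    return x, R


def fit_regression_with_selection(
    records,
    statistic: str = "sum",
    model: SelectionModel | None = None,
    compute_ci: bool = True,
) -> RegressionFit:
    """Maximum-likelihood linear regression corrected for selection.

    ``records`` is a cohort table (with ``residual`` and repeat columns)
    or an ``(x, R)`` pair.  The likelihood is maximised over
    (sigma, beta0, beta1); significance comes from the likelihood-ratio
    test against the beta1 = 0 model, and the 95% CI for beta1 from the
    profile likelihood.  With ``model=None`` (S == 1) the fit equals the
    ordinary least-squares maximum likelihood.
    """
    x, R = _resolve_xr(records, statistic)
    if len(x) < 3 or np.ptp(x) == 0:
        raise ValueError("need >= 3 records and a varying statistic")
    xm = float(np.mean(x))
    xc = (x - xm)[:, None]
    nll = _sel_nll_factory(R, xc, model)

    # OLS starting values (centred predictor)
    b1_ols = float(np.sum(xc[:, 0] * (R - R.mean())) / np.sum(xc[:, 0] ** 2))
    b0_ols = float(R.mean())
    resid = R - b0_ols - b1_ols * xc[:, 0]
    s_ols = float(np.std(resid)) or 1.0
    starts = [
        (np.log(s_ols), b0_ols, b1_ols),
        (np.log(s_ols / 2.5), b0_ols, b1_ols / 2.5),
        (np.log(s_ols / 2.5), b0_ols, 0.0),
    ]
    if model is not None:
        starts.append((np.log(model.sigma), b0_ols, b1_ols / 2.5))
    full = _minimize_nll(nll, starts)

    nll0 = _sel_nll_factory(R, xc[:, :0].reshape(len(R), 0), model)
    null = _minimize_nll(
        nll0, [(full.x[0], full.x[1]), (np.log(s_ols), b0_ols)]
    )
    dev = max(0.0, 2.0 * (null.fun - full.fun))
    lrt_p = float(stats.chi2.sf(dev, 1))
    sigma_hat = float(np.exp(full.x[0]))
    b0c, b1 = float(full.x[1]), float(full.x[2])
    beta0 = b0c - b1 * xm
    flags: list[str] = []
    ci = None
    if compute_ci:
        ci = _profile_ci(nll, full, flags)
    return RegressionFit(
        "selection" if model is not None else "ols-ml",
        beta0, b1, sigma_hat, -float(full.fun), lrt_p, ci, len(R), tuple(flags),
        {"beta0_centred": b0c, "x_mean": xm},
    )


def _profile_ci(nll, full, flags, level_dev: float = 3.8414588):
    """Profile-likelihood CI for the slope (last parameter)."""
    b1_hat = float(full.x[2])
    lmax = -float(full.fun)

    def profile_dev(b1):
        sub = optimize.minimize(
            lambda t: nll(np.array([t[0], t[1], b1])),
            full.x[:2], method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 300},
        )
        return 2.0 * (lmax + float(sub.fun))

    bounds = []
    for direction in (-1.0, 1.0):
        step = 0.25 * max(abs(b1_hat), 0.2)
        b = b1_hat
        hi = None
        for _ in range(40):
            b = b + direction * step
            if profile_dev(b) > level_dev:
                hi = b
                break
            step *= 1.6
        if hi is None:
            flags.append("ci-unbounded")
            bounds.append(direction * np.inf)
            continue
        lo = hi - direction * step / 1.6 if abs(hi - b1_hat) > step else b1_hat
        try:
            root = optimize.brentq(
                lambda bb: profile_dev(bb) - level_dev,
                min(b1_hat, hi), max(b1_hat, hi), xtol=1e-4,
            )
            bounds.append(root)
        except ValueError:
            flags.append("ci-bracket-failed")
            bounds.append(hi)
    return (min(bounds), max(bounds))


# ----------------------------------------------------------------------
# classical association engines
# ----------------------------------------------------------------------

def ols_association(records, statistic: str = "sum") -> RegressionFit:
    """Ordinary least-squares association of the residual with a statistic.

    On an extreme-selected cohort this deliberately overestimates the
    effect magnitude; use the selection engine for unbiased estimates.
    """
    import statsmodels.api as sm

    x, R = _resolve_xr(records, statistic)
    if len(x) < 3:
        raise ValueError("need >= 3 records")
    if np.ptp(x) == 0:
        raise ValueError(f"statistic {statistic!r} is constant")
    X = sm.add_constant(x)
    fit = sm.OLS(R, X).fit()
    ci = fit.conf_int()[1]
    return RegressionFit(
        "ols", float(fit.params[0]), float(fit.params[1]),
        float(np.sqrt(fit.scale)), float(fit.llf), float(fit.pvalues[1]),
        (float(ci[0]), float(ci[1])), int(fit.nobs),
    )


def dichotomize_and_logistic(
    records, statistic: str = "sum", threshold: float = 0.0
) -> RegressionFit:
    """Logistic regression of extreme-late vs extreme-early onset.

    Individuals with R > threshold are "late", R < -threshold "early";
    the middle band is dropped.  Perfect separation is flagged rather
    than raised.
    """
    import statsmodels.api as sm

    x, R = _resolve_xr(records, statistic)
    late = R > threshold
    early = R < -threshold
    keep = late | early
    if not late.any() or not early.any():
        raise ValueError("dichotomisation leaves an empty class")
    y = late[keep].astype(int)
    xk = x[keep]
    flags: list[str] = []
    X = sm.add_constant(xk)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        params = fit.params
        p = float(fit.llr_pvalue)
        llf = float(fit.llf)
        if not np.all(np.isfinite(fit.bse)):
            flags.append("unstable-se")
    except Exception:  # perfect separation and friends
        flags.append("perfect-separation")
        params = (np.nan, np.nan)
        p, llf = np.nan, np.nan
    return RegressionFit(
        "logistic", float(params[0]), float(params[1]), np.nan, llf, p,
        None, int(keep.sum()), tuple(flags),
    )


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(res[0]) if res.size else float(np.sum((y - X @ beta) ** 2))
    return rss, int(rank)


def compare_statistics(
    records, statistics=REPEAT_STATISTICS, alpha: float = 0.05
):
    """Pairwise nested-model comparison of repeat statistics.

    For each ordered pair (A, B) the linear model R ~ A is compared with
    R ~ A + B by an F-test; entry (A, B) is the p-value of B's
    improvement.  A statistic is "best fitting" when no other statistic
    significantly improves on it at ``alpha``.  A rank-deficient
    addition (B collinear with A) is reported as p = 1.
    """
    stats_df = (
        cohort_statistics(records)
        if isinstance(records, pd.DataFrame) and "qtr_a" in records
        else records
    )
    if isinstance(records, pd.DataFrame):
        R = records["residual"].to_numpy(dtype=float)
    else:
        raise TypeError("records must be a cohort DataFrame")
    n = len(R)
    cols = {s: stats_df[s].to_numpy(dtype=float) for s in statistics}
    pmat = pd.DataFrame(np.nan, index=list(statistics), columns=list(statistics))
    ones = np.ones(n)
    for a in statistics:
        Xa = np.column_stack([ones, cols[a]])
        rss_a, rank_a = _ols_rss(Xa, R)
        for b in statistics:
            if b == a:
                continue
            Xab = np.column_stack([ones, cols[a], cols[b]])
            rss_ab, rank_ab = _ols_rss(Xab, R)
            if rank_ab <= rank_a:
                pmat.loc[a, b] = 1.0  # collinear addition: no new information
                continue
            df2 = n - rank_ab
            f = max(0.0, (rss_a - rss_ab)) / max(rss_ab / df2, 1e-300)
            pmat.loc[a, b] = float(stats.f.sf(f, 1, df2))
    best = [
        a for a in statistics
        if all(pmat.loc[a, b] > alpha for b in statistics if b != a)
    ]
    return pmat, best


@dataclass(frozen=True)
class ConditionalResult:
    marginal_primary: RegressionFit
    marginal_covariate: RegressionFit
    partial_primary_p: float
    partial_covariate_p: float
    flags: tuple[str, ...] = ()


def conditional_association(
    records: pd.DataFrame,
    primary: str = "sum",
    covariate: str = "marker_dosage",
    engine: str = "ols",
    model: SelectionModel | None = None,
) -> ConditionalResult:
    """Joint model of R on primary + covariate with both partial tests.

    Reports each predictor's marginal association and its p-value after
    conditioning on the other, using either the OLS engine (partial
    t-tests) or the selection-likelihood engine (LRTs dropping one
    predictor at a time).
    """
    import statsmodels.api as sm

    stats_df = cohort_statistics(records) if "qtr_a" in records else records
    def col(name):
        if name in records.columns:
            return records[name].to_numpy(dtype=float)
        return stats_df[name].to_numpy(dtype=float)

    xp, xcov = col(primary), col(covariate)
    R = records["residual"].to_numpy(dtype=float)
    flags: list[str] = []
    corr = np.corrcoef(xp, xcov)[0, 1] if np.ptp(xcov) > 0 else 1.0
    if not np.isfinite(corr) or abs(corr) > 1 - 1e-10:
        flags.append("collinear")
    m_primary = ols_association((xp, R))
    m_cov = ols_association((xcov, R))
    if engine == "ols" or "collinear" in flags:
        X = sm.add_constant(np.column_stack([xp, xcov]))
        fit = sm.OLS(R, X).fit()
        pp = float(fit.pvalues[1])
        pc = float(fit.pvalues[2])
    elif engine == "selection":
        X = np.column_stack([xp, xcov])
        both = _fit_selection_design(R, X, model)
        drop_p = _fit_selection_design(R, X[:, 1:], model)
        drop_c = _fit_selection_design(R, X[:, :1], model)
        pp = float(stats.chi2.sf(max(0.0, 2 * (both - drop_p)), 1))
        pc = float(stats.chi2.sf(max(0.0, 2 * (both - drop_c)), 1))
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return ConditionalResult(m_primary, m_cov, pp, pc, tuple(flags))


def _fit_selection_design(R, X, model) -> float:
    """Maximised log-likelihood of the selection model with design X."""
    Xc = X - X.mean(axis=0, keepdims=True)
    nll = _sel_nll_factory(np.asarray(R, dtype=float), Xc, model)
    k = X.shape[1]
    beta_ols = (
        np.linalg.lstsq(
            np.column_stack([np.ones(len(R)), Xc]), R, rcond=None
        )[0]
        if k
        else np.array([np.mean(R)])
    )
    s0 = float(np.std(R)) or 1.0
    starts = [
        np.concatenate(([np.log(s0)], beta_ols)),
        np.concatenate(([np.log(s0 / 2.5)], beta_ols * (1 if k == 0 else 0.4))),
    ]
    best = _minimize_nll(nll, starts)
    return -float(best.fun)


def bonferroni_adjust(p: float, k: int = 4) -> float:
    """min(1, k*p); k defaults to the four length statistics tested."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return min(1.0, k * p)
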