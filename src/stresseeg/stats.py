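"""Mixed-model condition contrasts, model selection, Bayes factors and FDR.

Every measure (relative power, AEC, IBI difference, questionnaire score)
is modelled as ``value ~ condition + (1 | participant)``.  Two candidate
families are fitted — a linear mixed model and a gamma GLMM with identity
link — and the AIC-minimal one is kept (the gamma candidate is only
attempted when all values are positive).  The condition contrast equals
the fixed-effect coefficient for the negative condition (two balanced
levels), reported with a standardized effect size, a BIC-approximated
Bayes factor in favour of the null, and Benjamini–Hochberg adjusted
p-values over the full enumerated test family.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as spstats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConvergenceError",
    "MixedModelFit",
    "StatResult",
    "inclusion_filter",
    "apply_exclusions",
    "fit_linear_mixed",
    "fit_gamma_glmm",
    "fit_condition_model",
    "sex_covariate_check",
    "bf01_from_bic",
    "bayes_factor_bic",
    "fdr_correct",
    "enumerate_tests",
    "jeffreys_label",
    "fit_measure_table",
]

logger = logging.getLogger(__name__)

CONDITIONS = ("control", "negative")


class ConvergenceError(RuntimeError):
    """A candidate model failed to converge on the given data."""


# ---------------------------------------------------------------------------
# inclusion / exclusion bookkeeping


def inclusion_filter(
    epoch_counts: pd.DataFrame,
    min_epochs: int = 15,
    conditions=CONDITIONS,
) -> list[str]:
    """Participants with at least ``min_epochs`` epochs in *both* conditions.

    ``epoch_counts`` has columns participant, condition, n_epochs.  The
    boundary is inclusive: exactly ``min_epochs`` epochs pass.
    """
    if epoch_counts.empty:
        return []
    retained = []
    for pid, grp in epoch_counts.groupby("participant"):
        counts = dict(zip(grp["condition"], grp["n_epochs"]))
        if all(counts.get(c, 0) >= min_epochs for c in conditions):
            retained.append(pid)
        else:
            logger.info("participant %s excluded (epoch counts %s)", pid, counts)
    return sorted(retained)


def apply_exclusions(participants: pd.DataFrame) -> pd.DataFrame:
    """Drop participants with a non-empty ``exclusion_reason``.

    Mirrors sample bookkeeping: rows whose reason is NA or empty are
    retained; everything else is excluded and logged.
    """
    reason = participants["exclusion_reason"]
    excluded = reason.notna() & (reason.astype(str).str.len() > 0)
    for _, row in participants[excluded].iterrows():
        logger.info("participant %s excluded: %s", row["participant"], row["exclusion_reason"])
    return participants[~excluded].reset_index(drop=True)


# ---------------------------------------------------------------------------
# model fits


@dataclass
class MixedModelFit:
    """One fitted random-intercept model for a two-condition measure."""

    family: str                 # "linear" or "gamma-identity"
    beta: float                 # negative-vs-control contrast
    se: float
    t: float
    p: float
    llf: float
    n_params: int
    nobs: int
    resid_sd: float             # residual-scale standard deviation
    participant_sd: float       # random-intercept standard deviation
    coef_names: list[str] = field(default_factory=list)
    coefs: dict[str, float] = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.llf

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.nobs) - 2.0 * self.llf

    @property
    def total_sd(self) -> float:
        """SD pooling the participant and residual components."""
        return float(np.sqrt(self.participant_sd**2 + self.resid_sd**2))


def _design(df: pd.DataFrame, include_condition: bool, include_sex: bool):
    names = ["intercept"]
    cols = [np.ones(len(df))]
    if include_condition:
        cond = df["condition"].astype(str)
        bad = set(cond.unique()) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        cols.append((cond == "negative").to_numpy(dtype=float))
        names.append("condition[negative]")
    if include_sex:
        sexes = sorted(df["sex"].astype(str).unique())
        if len(sexes) < 2:
            raise ValueError("sex covariate requires at least two levels")
        cols.append((df["sex"].astype(str) == sexes[-1]).to_numpy(dtype=float))
        names.append(f"sex[{sexes[-1]}]")
    return np.column_stack(cols), names


def _validate_records(df: pd.DataFrame) -> None:
    if df["value"].isna().any():
        raise ValueError("records contain missing values")
    n_both = sum(
        set(g["condition"]) >= set(CONDITIONS) for _, g in df.groupby("participant")
    )
    if n_both < 2:
        raise ValueError("need at least two participants observed in both conditions")


def fit_linear_mixed(
    df: pd.DataFrame,
    include_condition: bool = True,
    include_sex: bool = False,
) -> MixedModelFit:
    """Linear mixed model with participant random intercept, ML fit."""
    X, names = _design(df, include_condition, include_sex)
    y = df["value"].to_numpy(dtype=float)
    groups = df["participant"].to_numpy()
    Xdf = pd.DataFrame(X, columns=names)
    model = MixedLM(y, Xdf, groups=groups)
    res = None
    last_exc: Exception | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in (None, "powell", "cg"):
            try:
                kwargs = {} if method is None else {"method": method}
                res = model.fit(reml=False, **kwargs)
                break
            except Exception as exc:  # noqa: BLE001 - try the next optimizer
                last_exc = exc
    if res is None:
        raise ConvergenceError(f"linear mixed model failed: {last_exc}") from last_exc
    if not np.all(np.isfinite(res.params)):
        raise ConvergenceError("linear mixed model produced non-finite estimates")
    coefs = dict(zip(names, np.asarray(res.fe_params, dtype=float)))
    if include_condition:
        i = names.index("condition[negative]")
        beta = float(np.asarray(res.fe_params)[i])
        se = float(np.asarray(res.bse_fe)[i])
        tval = beta / se if se > 0 else np.nan
        pval = float(2 * spstats.norm.sf(abs(tval))) if np.isfinite(tval) else np.nan
    else:
        beta = se = tval = pval = np.nan
    k = len(names) + 2  # fixed effects + random-intercept variance + residual variance
    return MixedModelFit(
        family="linear",
        beta=beta,
        se=se,
        t=tval,
        p=pval,
        llf=float(res.llf),
        n_params=k,
        nobs=len(y),
        resid_sd=float(np.sqrt(res.scale)),
        participant_sd=float(np.sqrt(max(res.cov_re.to_numpy()[0, 0], 0.0))),
        coef_names=names,
        coefs=coefs,
    )


def _gamma_glmm_nll(params, y, X, group_idx, n_groups, nodes, log_wts):
    """Negative marginal log-likelihood, random intercept integrated by
    Gauss–Hermite quadrature on the identity-link gamma model."""
    p = X.shape[1]
    beta = params[:p]
    shape = np.exp(params[p])
    tau = np.exp(params[p + 1])
    eta = X @ beta
    mu = eta[:, None] + np.sqrt(2.0) * tau * nodes[None, :]     # (n, K)
    valid = mu > 0
    mu_safe = np.where(valid, mu, 1.0)
    logpdf = (
        shape * np.log(shape)
        - special.gammaln(shape)
        + (shape - 1.0) * np.log(y)[:, None]
        - shape * np.log(mu_safe)
        - shape * y[:, None] / mu_safe
    )
    logpdf = np.where(valid, logpdf, -np.inf)
    per_group = np.zeros((n_groups, len(nodes)))
    np.add.at(per_group, group_idx, logpdf)
    ll = special.logsumexp(per_group + log_wts[None, :], axis=1)
    if not np.all(np.isfinite(ll)):
        return 1e10
    return -float(ll.sum())


def _numeric_hessian(f, x, eps=1e-4):
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = eps
            ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps * eps)
    return H


def fit_gamma_glmm(
    df: pd.DataFrame,
    include_condition: bool = True,
    include_sex: bool = False,
    n_quad: int = 25,
) -> MixedModelFit:
    """Gamma GLMM, identity link, participant random intercept.

    Maximum likelihood with the scalar random effect integrated out by
    Gauss–Hermite quadrature; positivity of the conditional mean is kept
    by assigning zero density to quadrature points where it fails.
    """
    y = df["value"].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise ValueError("gamma family requires strictly positive values")
    X, names = _design(df, include_condition, include_sex)
    groups, group_idx = np.unique(df["participant"].to_numpy(), return_inverse=True)
    nodes, wts = np.polynomial.hermite.hermgauss(n_quad)
    log_wts = np.log(wts) - 0.5 * np.log(np.pi)

    # moment-based starting values
    part_means = pd.Series(y).groupby(group_idx).mean()
    mu0 = float(np.mean(y))
    resid = y - part_means.to_numpy()[group_idx]
    var_w = max(float(np.var(resid)), 1e-8 * mu0**2 + 1e-12)
    shape0 = np.clip(mu0**2 / var_w, 0.05, 1e4)
    tau0 = float(np.sqrt(max(np.var(part_means.to_numpy()), 1e-12)))
    beta0 = np.zeros(X.shape[1])
    beta0[0] = mu0
    x0 = np.concatenate([beta0, [np.log(shape0), np.log(tau0)]])

    args = (y, X, group_idx, len(groups), nodes, log_wts)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        opt = optimize.minimize(
            _gamma_glmm_nll, x0, args=args, method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-7, "fatol": 1e-9},
        )
        opt = optimize.minimize(
            _gamma_glmm_nll, opt.x, args=args, method="BFGS",
            options={"maxiter": 500, "gtol": 1e-6},
        )
    if not np.all(np.isfinite(opt.x)) or opt.fun >= 1e10:
        raise ConvergenceError("gamma GLMM failed to converge")

    p = X.shape[1]
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        H = _numeric_hessian(lambda v: _gamma_glmm_nll(v, *args), opt.x)
    with np.errstate(invalid="ignore"):
        cov = np.linalg.pinv(H)
        bse = np.sqrt(np.diag(cov))
    if not np.all(np.isfinite(bse[:p])) or np.any(bse[:p] <= 0):
        raise ConvergenceError("gamma GLMM information matrix is singular")

    beta_hat = opt.x[:p]
    shape = float(np.exp(opt.x[p]))
    tau = float(np.exp(opt.x[p + 1]))
    mu_hat = np.clip(X @ beta_hat, 1e-12, None)
    resid_sd = float(np.mean(mu_hat) / np.sqrt(shape))  # dispersion-based scale
    if include_condition:
        i = names.index("condition[negative]")
        beta = float(beta_hat[i])
        se = float(bse[i])
        tval = beta / se if se > 0 else np.nan
        pval = float(2 * spstats.norm.sf(abs(tval))) if np.isfinite(tval) else np.nan
    else:
        beta = se = tval = pval = np.nan
    return MixedModelFit(
        family="gamma-identity",
        beta=beta,
        se=se,
        t=tval,
        p=pval,
        llf=-float(opt.fun),
        n_params=p + 2,
        nobs=len(y),
        resid_sd=resid_sd,
        participant_sd=tau,
        coef_names=names,
        coefs=dict(zip(names, beta_hat.astype(float))),
    )


# ---------------------------------------------------------------------------
# model comparison / reporting


@dataclass
class StatResult:
    """Per-measure model comparison output."""

    measure: str
    family: str
    beta: float
    se: float
    t: float
    p_raw: float
    ses: float
    ses_ci: tuple[float, float]
    aic_linear: float | None = None
    aic_gamma: float | None = None
    bf01: float | None = None
    sex_improves: bool | None = None
    sex_p: float | None = None
    p_fdr: float | None = None

    def __post_init__(self) -> None:
        lo, hi = self.ses_ci
        if np.isfinite(self.ses) and not (lo <= self.ses <= hi):
            raise ValueError("SES confidence interval must contain the point estimate")


def fit_condition_model(
    df: pd.DataFrame,
    measure: str = "measure",
    include_sex: bool = False,
) -> StatResult:
    """Fit both candidate families, select by AIC, standardize the contrast.

    The gamma candidate is only attempted when all values are positive.
    If a candidate fails to converge the other family is used; if both
    fail a :class:`ConvergenceError` propagates.  SES is the contrast
    divided by the model's pooled (participant + residual) SD, with a
    delta-method 95 % CI (scale treated as fixed).
    """
    _validate_records(df)
    fits: dict[str, MixedModelFit] = {}
    errors: dict[str, Exception] = {}
    try:
        fits["linear"] = fit_linear_mixed(df, include_sex=include_sex)
    except ConvergenceError as exc:
        errors["linear"] = exc
        logger.warning("%s: linear candidate failed to converge (%s)", measure, exc)
    if (df["value"] > 0).all():
        try:
            fits["gamma-identity"] = fit_gamma_glmm(df, include_sex=include_sex)
        except ConvergenceError as exc:
            errors["gamma-identity"] = exc
            logger.warning("%s: gamma candidate failed to converge (%s)", measure, exc)
    else:
        logger.info("%s: non-positive values present, linear family only", measure)
    if not fits:
        raise ConvergenceError(f"{measure}: every candidate model failed: {errors}")

    chosen = min(fits.values(), key=lambda f: f.aic)
    sd = chosen.total_sd
    if sd <= 0 or not np.isfinite(sd):
        ses, ci = np.nan, (np.nan, np.nan)
    else:
        ses = chosen.beta / sd
        half = 1.959963984540054 * chosen.se / sd
        ci = (ses - half, ses + half)
    return StatResult(
        measure=measure,
        family=chosen.family,
        beta=chosen.beta,
        se=chosen.se,
        t=chosen.t,
        p_raw=chosen.p,
        ses=ses,
        ses_ci=ci,
        aic_linear=fits["linear"].aic if "linear" in fits else None,
        aic_gamma=fits["gamma-identity"].aic if "gamma-identity" in fits else None,
    )


def sex_covariate_check(df: pd.DataFrame, family: str = "linear") -> tuple[bool, float]:
    """Likelihood-ratio check whether adding sex improves the model.

    Returns (retain sex, p value); sex is retained only when p ≤ 0.05.
    A single-sex sample skips the check with a warning.
    """
    if "sex" not in df.columns or df["sex"].nunique() < 2:
        warnings.warn("sex covariate check skipped: fewer than two sex levels", stacklevel=2)
        return False, np.nan
    fitter = fit_gamma_glmm if family == "gamma-identity" else fit_linear_mixed
    base = fitter(df, include_sex=False)
    with_sex = fitter(df, include_sex=True)
    lr = max(2.0 * (with_sex.llf - base.llf), 0.0)
    p = float(spstats.chi2.sf(lr, df=1))
    return p <= 0.05, p


def bf01_from_bic(bic_alternative: float, bic_null: float) -> float:
    """BIC-approximated Bayes factor in favour of the null model."""
    return float(np.exp((bic_alternative - bic_null) / 2.0))


def bayes_factor_bic(
    df: pd.DataFrame,
    family: str = "gamma-identity",
    include_sex: bool = False,
) -> float:
    """BF01 comparing the condition model against the no-condition null."""
    fitter = fit_gamma_glmm if family == "gamma-identity" else fit_linear_mixed
    alt = fitter(df, include_condition=True, include_sex=include_sex)
    null = fitter(df, include_condition=False, include_sex=include_sex)
    return bf01_from_bic(alt.bic, null.bic)


JEFFREYS_BANDS = (
    (1.0, "no evidence for H0"),
    (3.0, "anecdotal evidence for H0"),
    (10.0, "moderate evidence for H0"),
    (30.0, "strong evidence for H0"),
    (100.0, "very strong evidence for H0"),
    (np.inf, "extreme evidence for H0"),
)


def jeffreys_label(bf01: float) -> str:
    """Verbal interpretation of BF01 on the Jeffreys scale."""
    if not np.isfinite(bf01) or bf01 <= 0:
        return "undefined"
    if bf01 < 1.0:
        return jeffreys_label(1.0 / bf01).replace("H0", "H1")
    for upper, label in JEFFREYS_BANDS:
        if bf01 <= upper:
            return label
    return "extreme evidence for H0"


def fdr_correct(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (step-up)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj


# ---------------------------------------------------------------------------
# test-family enumeration


def enumerate_tests(
    sensor_bands=("theta", "alpha", "beta"),
    source_regions=(),
    source_bands=("theta", "alpha", "beta"),
    fc_connections=(),
) -> list[str]:
    """Stable identifiers for every test entering the FDR family.

    Sensor-level frontal power (one per band), source-level power
    (region × band) and functional connections (pair × band), in that
    order.
    """
    tests = [f"power:frontal:{b}" for b in sensor_bands]
    tests += [f"power:{r}:{b}" for r in source_regions for b in source_bands]
    tests += [f"fc:{a}--{b}:{band}" for (a, b), band in fc_connections]
    if len(set(tests)) != len(tests):
        raise ValueError("duplicate test identifiers in design")
    return tests


def fit_measure_table(
    measures: dict[str, pd.DataFrame],
    test_ids: list[str],
    q: float = 0.05,
    include_sex: bool = False,
    compute_bf01: bool = False,
) -> pd.DataFrame:
    """Fit every measure in an enumerated family and BH-adjust across it.

    ``measures`` maps test id → records table.  Measures that fail to
    converge are reported with missing estimates and excluded from the
    correction (logged).  Returns one row per test id, in family order.
    """
    rows = []
    for tid in test_ids:
        df = measures.get(tid)
        if df is None or df.empty:
            logger.warning("no data for test %s", tid)
            rows.append({"measure": tid, "p_raw": np.nan})
            continue
        try:
            res = fit_condition_model(df, measure=tid, include_sex=include_sex)
        except ConvergenceError as exc:
            logger.warning("test %s dropped: %s", tid, exc)
            rows.append({"measure": tid, "p_raw": np.nan})
            continue
        row = {
            "measure": tid,
            "family": res.family,
            "beta": res.beta,
            "se": res.se,
            "t": res.t,
            "p_raw": res.p_raw,
            "ses": res.ses,
            "ses_lo": res.ses_ci[0],
            "ses_hi": res.ses_ci[1],
            "aic_linear": res.aic_linear,
            "aic_gamma": res.aic_gamma,
        }
        if compute_bf01:
            try:
                row["bf01"] = bayes_factor_bic(df, family=res.family, include_sex=include_sex)
            except (ConvergenceError, ValueError) as exc:
                logger.warning("BF01 unavailable for %s: %s", tid, exc)
                row["bf01"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    ok = out["p_raw"].notna()
    if ok.any():
        out.loc[ok, "p_fdr"] = fdr_correct(out.loc[ok, "p_raw"].to_numpy(), q=q)
    return out
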