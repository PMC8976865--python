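"""Mixed-effects model structures, likelihood-ratio tests, and post hoc
contrasts for the dual-task training analysis.

Three model families are compared per dependent variable (DV):

    DV ~ 1 + Group + Group:Session + Group:Session:AdpTF + (1|ID)
    DV ~ 1 + Group + Group:Session + Group:Session:AdpTF + (1|ID) + (0+Short|ID)
    DV ~ 1 + Group + Group:Session + (1|ID) + (0+Short|ID)

where Group is the slope-sign individual-differences factor, Session spans
E1..H2, AdpTF is the adaptive target-find score, and Short is the mean
short-separation (extracerebral) signal entering as an uncorrelated random
slope per subject. Fixed-term significance comes from likelihood-ratio tests
between nested ML fits; post hoc contrasts use REML fits with Satterthwaite
degrees of freedom, Benjamini--Hochberg FDR correction within each DV, and
Cohen's d effect sizes.

Numerical optimization is delegated to statsmodels' MixedLM; this module owns
the model-structure construction, the estimation-mode discipline (ML for
LRTs, REML for post hocs), and the Satterthwaite machinery, which statsmodels
does not provide.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

SESSIONS = ("E1", "E2", "E3", "H1", "H2")
GROUPS = ("attention", "accuracy")

EQ_BEHAVIOR = "1 + Group + Group:Session + Group:Session:AdpTF"
EQ_NO_ADPTF = "1 + Group + Group:Session"


@dataclass(frozen=True)
class ModelSpec:
    """One mixed-model structure: fixed formula + random terms."""

    dv: str
    fixed: str                       # patsy right-hand side
    random_intercept: bool = True    # (1|ID)
    short_slope: bool = False        # (0 + Short|ID), uncorrelated with intercept
    estimation: str = "ML"           # "ML" for LRTs, "REML" for post hocs

    def __post_init__(self) -> None:
        if self.estimation not in ("ML", "REML"):
            raise ValueError("estimation must be 'ML' or 'REML'")
        if not self.random_intercept:
            raise ValueError("random terms always include (1|ID)")

    @property
    def formula(self) -> str:
        return f"{self.dv} ~ {self.fixed}"

    def label(self) -> str:
        parts = [self.fixed, "(1|ID)"]
        if self.short_slope:
            parts.append("(0+Short|ID)")
        return f"{self.dv} ~ " + " + ".join(parts)


def template_frame() -> pd.DataFrame:
    """Minimal balanced frame carrying every factor level (and non-constant
    covariates), used to size design matrices and check nesting without
    data."""
    rows = []
    for g in GROUPS:
        for s in SESSIONS:
            for adp, short in ((0.25, -1.0), (0.75, 1.0)):
                rows.append({"Group": g, "Session": s, "AdpTF": adp,
                             "Short": short, "ID": f"{g}-{s}"})
    return prepare_data(pd.DataFrame(rows))


def prepare_data(data: pd.DataFrame) -> pd.DataFrame:
    """Fix factor level order (treatment coding, reference attention / E1)."""
    out = data.copy()
    if "Group" in out:
        out["Group"] = pd.Categorical(out["Group"], categories=GROUPS)
    if "Session" in out:
        levels = [s for s in SESSIONS if s in set(out["Session"])]
        out["Session"] = pd.Categorical(out["Session"], categories=levels)
    return out


def n_fixed_columns(fixed: str, data: pd.DataFrame | None = None) -> int:
    df = data if data is not None else template_frame()
    return patsy.dmatrix(fixed, df).shape[1]


def count_parameters(spec: ModelSpec, data: pd.DataFrame | None = None) -> int:
    """Fixed-effect columns + one variance per random term + residual variance."""
    n_random = int(spec.random_intercept) + int(spec.short_slope)
    return n_fixed_columns(spec.fixed, data) + n_random + 1


@dataclass
class FitResult:
    spec: ModelSpec
    llf: float
    n_params: int
    fe_params: pd.Series
    cov_re: float          # random-intercept variance (data scale)
    vc_short: float | None  # short-slope variance, if present
    scale: float           # residual variance
    converged: bool
    singular: bool
    result: object         # statsmodels MixedLMResults
    data: pd.DataFrame     # casewise-complete analysis frame


def _model_columns(spec: ModelSpec) -> list[str]:
    cols = [spec.dv, "ID"]
    for name in ("Group", "Session", "AdpTF", "Short"):
        if name in spec.fixed or (name == "Short" and spec.short_slope):
            cols.append(name)
    return cols


def fit(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Fit one mixed model; missing rows are dropped casewise."""
    cols = [c for c in _model_columns(spec) if c in data.columns]
    missing = set(_model_columns(spec)) - set(cols)
    if missing:
        raise ValueError(f"data lacks columns required by the model: {sorted(missing)}")
    df = prepare_data(data[cols].dropna().reset_index(drop=True))
    if df.empty:
        raise ValueError("no complete cases")

    vc = {"Short": "0 + Short"} if spec.short_slope else None
    model = MixedLM.from_formula(spec.formula, df, groups=df["ID"],
                                 re_formula="1", vc_formula=vc)
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in (None, "powell", "nm", "cg"):
            kwargs = {} if method is None else {"method": method, "maxiter": 2000}
            try:
                cand = model.fit(reml=(spec.estimation == "REML"), **kwargs)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if cand.converged and np.isfinite(cand.llf):
                res = cand
                break
            if res is None or (np.isfinite(cand.llf)
                               and cand.llf > getattr(res, "llf", -np.inf)):
                res = cand
    if res is None or not np.isfinite(res.llf):
        raise RuntimeError(
            f"mixed model failed to converge for {spec.label()}; "
            f"optimizer trace: {getattr(res, 'mle_retvals', None)}")
    if not res.converged:
        logger.warning("optimizer reported non-convergence for %s; using best "
                       "finite fit", spec.label())

    cov_re = float(np.asarray(res.cov_re)[0, 0])
    vc_short = float(res.vcomp[0]) if spec.short_slope else None
    scale = float(res.scale)
    singular = cov_re < 1e-8 * scale or (vc_short is not None and vc_short < 1e-8 * scale)
    if singular:
        logger.warning("singular fit (a variance component is ~0) for %s", spec.label())
    return FitResult(
        spec=spec, llf=float(res.llf), n_params=count_parameters(spec, df),
        fe_params=res.fe_params, cov_re=cov_re, vc_short=vc_short, scale=scale,
        converged=bool(res.converged), singular=singular, result=res, data=df,
    )


@dataclass(frozen=True)
class ComparisonResult:
    reduced: str
    full: str
    chi2: float
    df: int
    p: float


def _is_nested(reduced: ModelSpec, full: ModelSpec) -> bool:
    """Fixed-effects nesting: every reduced design column lies in the column
    space of the full design (checked by rank on a balanced template, so
    e.g. a Session main effect is recognized as nested inside a
    Group:Session interaction)."""
    df = template_frame()
    Xr = np.asarray(patsy.dmatrix(reduced.fixed, df))
    Xf = np.asarray(patsy.dmatrix(full.fixed, df))
    rank_f = np.linalg.matrix_rank(Xf)
    rank_joint = np.linalg.matrix_rank(np.hstack([Xf, Xr]))
    random_ok = (reduced.random_intercept <= full.random_intercept
                 and reduced.short_slope <= full.short_slope)
    return rank_joint == rank_f and random_ok


def likelihood_ratio_test(reduced: FitResult, full: FitResult) -> ComparisonResult:
    """chi2 = 2(l_full - l_reduced) on the parameter-count difference."""
    for r in (reduced, full):
        if r.spec.estimation != "ML":
            raise ValueError("likelihood-ratio tests require ML fits")
    if reduced.spec.dv != full.spec.dv:
        raise ValueError("models must share the dependent variable")
    if not _is_nested(reduced.spec, full.spec):
        raise ValueError("reduced model is not nested in the full model")
    df = full.n_params - reduced.n_params
    chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return ComparisonResult(reduced=reduced.spec.label(), full=full.spec.label(),
                            chi2=chi2, df=df, p=p)


# ------------------------------------------------------------------
# Satterthwaite machinery (REML covariance of variance parameters)

def _random_designs(fitres: FitResult) -> tuple[list[np.ndarray],
                                                list[np.ndarray | None],
                                                list[np.ndarray]]:
    """Per-subject (y_i, z_short_i, X_i) pulled from the fitted frame."""
    df = fitres.data
    y = df[fitres.spec.dv].to_numpy(dtype=float)
    X = np.asarray(patsy.dmatrix(fitres.spec.fixed, df))
    ids = df["ID"].to_numpy()
    ys, zs, Xs = [], [], []
    for g in pd.unique(ids):
        sel = ids == g
        ys.append(y[sel])
        Xs.append(X[sel])
        if fitres.spec.short_slope:
            zs.append(df.loc[sel, "Short"].to_numpy(dtype=float))
        else:
            zs.append(None)
    return ys, zs, Xs


def _theta(fitres: FitResult) -> np.ndarray:
    th = [fitres.scale, fitres.cov_re]
    if fitres.vc_short is not None:
        th.append(fitres.vc_short)
    return np.array(th, dtype=float)


def _per_group_V(theta: np.ndarray, n_i: int, z_i: np.ndarray | None) -> np.ndarray:
    sigma2, tau_int = theta[0], theta[1]
    V = sigma2 * np.eye(n_i) + tau_int * np.ones((n_i, n_i))
    if z_i is not None:
        V += theta[2] * np.outer(z_i, z_i)
    return V


def _reml_pieces(theta, ys, zs, Xs):
    """(C, beta, restricted log-likelihood up to a constant)."""
    p = Xs[0].shape[1]
    XtVinvX = np.zeros((p, p))
    XtVinvy = np.zeros(p)
    logdetV = 0.0
    quad_parts = []
    Vinvs = []
    for y_i, z_i, X_i in zip(ys, zs, Xs):
        V = _per_group_V(theta, len(y_i), z_i)
        _, ld = np.linalg.slogdet(V)
        logdetV += ld
        Vinv_X = np.linalg.solve(V, X_i)
        Vinv_y = np.linalg.solve(V, y_i)
        XtVinvX += X_i.T @ Vinv_X
        XtVinvy += X_i.T @ Vinv_y
        Vinvs.append((y_i, X_i, Vinv_y, Vinv_X))
    C = np.linalg.inv(XtVinvX)
    beta = C @ XtVinvy
    quad = 0.0
    for y_i, X_i, Vinv_y, Vinv_X in Vinvs:
        r_i = y_i - X_i @ beta
        quad += r_i @ (Vinv_y - Vinv_X @ beta)
    _, ld_xx = np.linalg.slogdet(XtVinvX)
    llr = -0.5 * (logdetV + ld_xx + quad)
    return C, beta, llr


def satterthwaite_df(fitres: FitResult, c: np.ndarray) -> float:
    """Effective degrees of freedom for the contrast c'beta.

    df = 2 f(theta)^2 / (g' A g) with f = Var(c'beta) = c'C(theta)c,
    g its gradient in the variance parameters, and A the REML-based
    covariance of theta (inverse observed information), all evaluated
    numerically.
    """
    ys, zs, Xs = _random_designs(fitres)
    theta = np.maximum(_theta(fitres), 1e-12)
    # variance components estimated on the boundary (singular directions)
    # carry no sampling variability to propagate; treat them as fixed at
    # zero, as the reference Satterthwaite implementations do
    active = theta > 1e-6 * theta[0]
    ta = theta[active]
    k = len(ta)

    def expand(th_act: np.ndarray) -> np.ndarray:
        th = theta.copy()
        th[active] = th_act
        return th

    def fvar(th_act):
        C, _, _ = _reml_pieces(expand(th_act), ys, zs, Xs)
        return float(c @ C @ c)

    def llr(th_act):
        return _reml_pieces(expand(th_act), ys, zs, Xs)[2]

    h = 1e-4 * ta
    grad = np.zeros(k)
    for i in range(k):
        e = np.zeros(k); e[i] = h[i]
        grad[i] = (fvar(ta + e) - fvar(ta - e)) / (2 * h[i])

    H = np.zeros((k, k))
    f0 = llr(ta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                H[i, i] = (llr(ta + ei) - 2 * f0 + llr(ta - ei)) / h[i]**2
            else:
                H[i, j] = H[j, i] = (
                    llr(ta + ei + ej) - llr(ta + ei - ej)
                    - llr(ta - ei + ej) + llr(ta - ei - ej)
                ) / (4 * h[i] * h[j])
    A = np.linalg.pinv(-H)  # Var(theta_hat)
    denom = float(grad @ A @ grad)
    f = fvar(ta)
    if denom <= 0 or f <= 0:
        n_obs = sum(len(y) for y in ys)
        return float(n_obs - Xs[0].shape[1])
    return 2.0 * f * f / denom


# ------------------------------------------------------------------
# Planned contrasts

@dataclass(frozen=True)
class ContrastResult:
    label: str
    kind: str       # "between" | "within"
    estimate: float
    se: float
    df: float
    t: float
    p: float
    adj_p: float | None
    d: float
    band: str


def effect_band(d: float) -> str:
    a = abs(d)
    if a >= 0.8:
        return "large"
    if a >= 0.5:
        return "medium"
    if a >= 0.2:
        return "small"
    return "negligible"


def cohens_d(estimate: float, pooled_sd: float) -> float:
    if pooled_sd <= 0:
        raise ValueError("pooled SD must be positive")
    return estimate / pooled_sd


def _cell_row(fitres: FitResult, group: str, session: str) -> np.ndarray:
    """Fixed-design row for an estimated marginal mean at one Group x Session
    cell; covariates (AdpTF) held at their sample mean."""
    df = fitres.data
    new = {"Group": [group], "Session": [session]}
    if "AdpTF" in df.columns and "AdpTF" in fitres.spec.fixed:
        new["AdpTF"] = [float(df["AdpTF"].mean())]
    di = patsy.dmatrix(fitres.spec.fixed, prepare_data(df)).design_info
    frame = prepare_data(pd.DataFrame(new))
    frame["Group"] = pd.Categorical(frame["Group"], categories=GROUPS)
    frame["Session"] = pd.Categorical(frame["Session"],
                                      categories=list(df["Session"].cat.categories))
    (row,) = patsy.build_design_matrices([di], frame)
    return np.asarray(row)[0]


def default_contrast_scheme(sessions: tuple[str, ...] = SESSIONS) -> list[dict]:
    """5 between-group contrasts (one per session) + 3 within-group session
    pairs (E1-E3 acquisition, E3-H1 and H1-H2 transfer) per group. The
    enumerated set has 11 members."""
    scheme = []
    for s in sessions:
        scheme.append({"kind": "between", "session": s,
                       "label": f"attention vs accuracy @ {s}"})
    for g in GROUPS:
        for a, b in (("E1", "E3"), ("E3", "H1"), ("H1", "H2")):
            scheme.append({"kind": "within", "group": g, "pair": (a, b),
                           "label": f"{g}: {a} vs {b}"})
    return scheme


def planned_contrasts(
    fitres: FitResult,
    scheme: list[dict] | None = None,
    d_denominator: str = "total",
) -> list[ContrastResult]:
    """Estimated-marginal-mean differences with Satterthwaite df.

    ``d_denominator``: "total" uses sqrt(residual + intercept variance)
    (the subject-level SD); "residual" uses the residual SD alone.
    """
    if fitres.spec.estimation != "REML":
        raise ValueError("post hoc contrasts require a REML fit")
    scheme = scheme or default_contrast_scheme(
        tuple(fitres.data["Session"].cat.categories))
    sessions = set(fitres.data["Session"].cat.categories)
    beta = fitres.fe_params.to_numpy()
    ys, zs, Xs = _random_designs(fitres)
    theta = np.maximum(_theta(fitres), 1e-10)
    Cmat, _, _ = _reml_pieces(theta, ys, zs, Xs)

    sd_pool = np.sqrt(fitres.scale + (fitres.cov_re if d_denominator == "total" else 0.0))
    out = []
    for item in scheme:
        if item["kind"] == "between":
            s = item["session"]
            if s not in sessions:
                raise ValueError(f"contrast references absent session {s!r}")
            c = _cell_row(fitres, "attention", s) - _cell_row(fitres, "accuracy", s)
        else:
            g, (a, b) = item["group"], item["pair"]
            for s in (a, b):
                if s not in sessions:
                    raise ValueError(f"contrast references absent session {s!r}")
            c = _cell_row(fitres, g, a) - _cell_row(fitres, g, b)
        est = float(c @ beta)
        var = float(c @ Cmat @ c)
        se = np.sqrt(var)
        df = satterthwaite_df(fitres, c)
        tstat = est / se if se > 0 else 0.0
        p = 2.0 * float(stats.t.sf(abs(tstat), df))
        d = cohens_d(est, sd_pool)
        out.append(ContrastResult(label=item["label"], kind=item["kind"],
                                  estimate=est, se=se, df=df, t=tstat, p=p,
                                  adj_p=None, d=d, band=effect_band(d)))
    return out


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini--Hochberg step-up within one DV's comparison family."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_contrasts(contrasts: list[ContrastResult]) -> list[ContrastResult]:
    adj = fdr_adjust([c.p for c in contrasts])
    return [ContrastResult(**{**c.__dict__, "adj_p": float(a)})
            for c, a in zip(contrasts, adj)]


# ------------------------------------------------------------------
# Diagnostics and orchestration

def heteroscedasticity_check(fitres: FitResult) -> tuple[float, float]:
    """Slope (and its p) of |residual| on fitted values; a significant
    positive slope triggers the log10-transform recommendation."""
    res = fitres.result
    fitted = np.asarray(res.fittedvalues, dtype=float)
    resid = np.abs(np.asarray(res.resid, dtype=float))
    slope, _, _, p, _ = stats.linregress(fitted, resid)
    return float(slope), float(p)


@dataclass
class DVAnalysis:
    dv: str
    fits: dict[str, FitResult]
    comparisons: dict[str, ComparisonResult]
    contrasts: list[ContrastResult] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


def analyze_dv(
    data: pd.DataFrame,
    dv: str,
    short_slope: bool = False,
    with_adptf: bool = True,
    run_posthoc: bool = True,
) -> DVAnalysis:
    """The per-DV model-comparison battery.

    Fits (ML): null, Session-only, Group-only, Group + Group:Session, and
    (optionally) the AdpTF three-way model; runs the table comparisons
    (null vs Session; Group vs Group+Group:Session; Session vs
    Group+Group:Session) and, when the Group:Session term is significant,
    REML post hoc contrasts with FDR adjustment.
    """
    mk = lambda fixed, est="ML": ModelSpec(dv=dv, fixed=fixed,
                                           short_slope=short_slope, estimation=est)
    fits = {
        "null": fit(mk("1"), data),
        "session": fit(mk("1 + Session"), data),
        "group": fit(mk("1 + Group"), data),
        "group_session": fit(mk(EQ_NO_ADPTF), data),
    }
    comparisons = {
        "session_vs_null": likelihood_ratio_test(fits["null"], fits["session"]),
        "group_session_vs_group": likelihood_ratio_test(fits["group"], fits["group_session"]),
        "group_session_vs_session": likelihood_ratio_test(fits["session"], fits["group_session"]),
    }
    if with_adptf and "AdpTF" in data.columns:
        fits["full_adptf"] = fit(mk(EQ_BEHAVIOR), data)
        comparisons["adptf_vs_group_session"] = likelihood_ratio_test(
            fits["group_session"], fits["full_adptf"])

    analysis = DVAnalysis(dv=dv, fits=fits, comparisons=comparisons)
    analysis.notes.append(
        "contrast family: 5 between-group + 6 within-group = 11 enumerated comparisons")
    if run_posthoc and comparisons["group_session_vs_group"].p < 0.05:
        reml = fit(mk(EQ_NO_ADPTF, est="REML"), data)
        slope, p_het = heteroscedasticity_check(reml)
        if p_het < 0.05 and slope > 0:
            analysis.notes.append(
                f"heteroscedasticity check fired (slope={slope:.3g}, p={p_het:.3g}); "
                "consider log10-transforming the response")
        analysis.contrasts = adjust_contrasts(planned_contrasts(reml))
    return analysis
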