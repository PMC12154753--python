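"""Refitting reference equations: penalized GAMLSS-type estimation.

Each distribution parameter (mu, sigma, nu and, for BCPE, tau) gets its
own linear model on the link scale in ln(height) and ln(age), optionally
plus a P-spline smooth in age.  Fitting follows the classical
Rigby-Stasinopoulos backfitting scheme: cycle over the distribution
parameters, updating each by penalized weighted least squares on its
link scale with working responses and weights built from derivatives of
the log-likelihood, until the penalized deviance stabilises.  Smooth
terms use a cubic B-spline basis (20 interior knots over the observed
age range) with a second-order difference penalty whose strength is
chosen each cycle to hit a fixed effective-df target; effective df are
the trace of the smoother.  Model choice uses the Schwarz Bayesian
criterion, SBC = -2*loglik + df*ln(n), with a small-difference window
resolved toward fewer degrees of freedom and a residual-moment screen —
the conventions of reference-equation practice.

Derivatives of the log-likelihood with respect to each linear predictor
are computed by central finite differences (the families are smooth and
the predictors well scaled, so this is accurate to ~1e-7); where the
numerical second derivative is not usably negative the squared score is
used as the weight, the standard quasi-Newton fallback.  Spline-free
fits are finished with a BFGS polish of the exact likelihood.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.interpolate import BSpline

from .distributions import (
    BCCGParams,
    BCPEParams,
    bccg_logpdf,
    bcpe_logpdf,
    quantile,
    zscore,
)
from .equations import (
    INDICES,
    EquationSet,
    IndexModel,
    ParameterModel,
    SplineTable,
    normalize_index,
)

__all__ = [
    "TermSpec",
    "ModelSpec",
    "FitResult",
    "fit_gamlss",
    "sbc",
    "select_model",
    "choose_from",
    "default_menu",
    "quantile_residuals",
    "worm_plot_data",
    "centile_curves",
    "assemble_equation_set",
    "fit_report",
]

_INDEX_COLUMN = {
    "fev1": "fev1_l",
    "fvc": "fvc_l",
    "fev1_fvc": "ratio",
    "fef2575": "fef2575_ls",
}

_FAMILY_PARAMS = {
    "normal": ("mu", "sigma"),
    "BCCG": ("mu", "sigma", "nu"),
    "BCPE": ("mu", "sigma", "nu", "tau"),
}

_DEFAULT_LINKS = {"mu": "log", "sigma": "log", "nu": "identity", "tau": "log"}
_MEDIAN_HEIGHT = {"male": 174.0, "female": 157.0}

_N_INTERIOR_KNOTS = 20
_SPLINE_DEGREE = 3


# ---------------------------------------------------------------------------
# model specification

@dataclass(frozen=True)
class TermSpec:
    """Terms and link for one distribution parameter.

    ``terms`` is a subset of {"intercept", "log_height", "log_age",
    "spline_age"}; ``spline_df`` is the extra effective df granted to the
    age smooth beyond the parametric columns.
    """

    terms: tuple = ("intercept",)
    link: str | None = None  # None -> family default link for the parameter
    spline_df: float = 3.0

    def __post_init__(self):
        allowed = {"intercept", "log_height", "log_age", "spline_age"}
        bad = set(self.terms) - allowed
        if bad:
            raise ValueError(f"unknown terms {sorted(bad)}; allowed: {sorted(allowed)}")
        if self.spline_df <= 0:
            raise ValueError("spline_df must be > 0")

    @property
    def has_spline(self) -> bool:
        return "spline_age" in self.terms

    @property
    def parametric_terms(self) -> tuple:
        order = ("intercept", "log_height", "log_age")
        return tuple(t for t in order if t in self.terms)


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: family plus per-parameter term specifications."""

    family: str
    index: str
    mu: TermSpec = TermSpec(("intercept", "log_height", "log_age"))
    sigma: TermSpec = TermSpec(("intercept",))
    nu: TermSpec | None = None
    tau: TermSpec | None = None
    name: str = ""

    def __post_init__(self):
        if self.family not in _FAMILY_PARAMS:
            raise ValueError(f"unknown family {self.family!r}")
        object.__setattr__(self, "index", normalize_index(self.index))
        if "intercept" not in self.mu.terms:
            raise ValueError("mu terms must include the intercept")
        for pname in ("nu", "tau"):
            ts = getattr(self, pname)
            if ts is not None and ts.has_spline:
                raise ValueError(f"age splines are not allowed on {pname}")
        needed = _FAMILY_PARAMS[self.family]
        if "nu" in needed and self.nu is None:
            object.__setattr__(self, "nu", TermSpec(("intercept",)))
        if "tau" in needed and self.tau is None:
            object.__setattr__(self, "tau", TermSpec(("intercept",)))
        if not self.name:
            object.__setattr__(self, "name", self._auto_name())

    def _auto_name(self) -> str:
        short = {"intercept": "1", "log_height": "lh", "log_age": "la", "spline_age": "s(a)"}
        parts = [self.family]
        for pname in _FAMILY_PARAMS[self.family]:
            ts = getattr(self, pname)
            parts.append(f"{pname}~" + "+".join(short[t] for t in ts.terms))
        return " ".join(parts)

    def term_spec(self, pname: str) -> TermSpec:
        return getattr(self, pname)

    def link(self, pname: str) -> str:
        ts = self.term_spec(pname)
        return ts.link if ts.link is not None else _DEFAULT_LINKS[pname]


@dataclass
class FitResult:
    """A fitted candidate: exported models, likelihood, df and SBC."""

    spec: ModelSpec
    index: str
    family: str
    parameter_models: dict
    edf: dict
    total_df: float
    loglik: float
    sbc: float
    n: int
    converged: bool
    n_iter: int
    message: str
    residual_mean: float
    residual_var: float
    lambdas: dict = field(default_factory=dict)

    @property
    def index_model(self) -> IndexModel:
        return IndexModel(
            family=self.family,
            mu=self.parameter_models["mu"],
            sigma=self.parameter_models["sigma"],
            nu=self.parameter_models.get("nu"),
            tau=self.parameter_models.get("tau"),
        )

    def summary_dict(self) -> dict:
        return {
            "model": self.spec.name,
            "index": self.index,
            "family": self.family,
            "sbc": self.sbc,
            "loglik": self.loglik,
            "total_df": self.total_df,
            "edf": dict(self.edf),
            "n": self.n,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "residual_mean": self.residual_mean,
            "residual_var": self.residual_var,
        }


def sbc(loglik: float, total_df: float, n: int) -> float:
    """Schwarz Bayesian criterion: -2*loglik + df*ln(n) (lower is better)."""
    return -2.0 * loglik + total_df * np.log(n)


# ---------------------------------------------------------------------------
# likelihood plumbing

def _normal_logpdf(y, mu, sigma):
    z = (y - mu) / sigma
    return -0.5 * z * z - np.log(sigma) - 0.5 * np.log(2.0 * np.pi)


def _loglik_terms(family, y, params):
    """Per-observation log-likelihood; -inf where parameters are invalid."""
    mu, sigma = params["mu"], params["sigma"]
    bad = (~np.isfinite(mu)) | (~np.isfinite(sigma)) | (mu <= 0) | (sigma <= 0)
    if family == "BCPE":
        tau = params["tau"]
        bad |= (~np.isfinite(tau)) | (tau <= 0)
    if family != "normal":
        bad |= ~np.isfinite(params["nu"])
    out = np.full(y.shape, -np.inf)
    ok = ~bad
    if not np.any(ok):
        return out
    try:
        if family == "normal":
            out[ok] = _normal_logpdf(y[ok], mu[ok], sigma[ok])
        elif family == "BCCG":
            out[ok] = bccg_logpdf(y[ok], BCCGParams(mu[ok], sigma[ok], params["nu"][ok]))
        else:
            out[ok] = bcpe_logpdf(
                y[ok], BCPEParams(mu[ok], sigma[ok], params["nu"][ok], params["tau"][ok])
            )
    except FloatingPointError:
        return np.full(y.shape, -np.inf)
    out[~np.isfinite(out)] = -np.inf
    return out


def _invlink(eta, link):
    return np.exp(np.clip(eta, -700, 700)) if link == "log" else eta


def _link(x, link):
    return np.log(x) if link == "log" else x


# ---------------------------------------------------------------------------
# design matrices

def _bspline_basis(ages):
    """Cubic B-spline basis with equally spaced interior knots over the age range."""
    lo, hi = float(np.min(ages)), float(np.max(ages))
    pad = 1e-6 * max(hi - lo, 1.0)
    breaks = np.linspace(lo - pad, hi + pad, _N_INTERIOR_KNOTS + 2)
    t = np.concatenate(
        [np.repeat(breaks[0], _SPLINE_DEGREE), breaks, np.repeat(breaks[-1], _SPLINE_DEGREE)]
    )
    B = BSpline.design_matrix(np.asarray(ages, dtype=float), t, _SPLINE_DEGREE).toarray()
    return B, t


def _difference_penalty(ncols, order=2):
    D = np.diff(np.eye(ncols), n=order, axis=0)
    return D.T @ D


def _solve(M, rhs):
    try:
        return np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(M) @ rhs


class _ParamDesign:
    """Design, penalty and coefficient bookkeeping for one distribution parameter."""

    def __init__(self, pname, term_spec: TermSpec, link, height, ages):
        self.pname = pname
        self.term_spec = term_spec
        self.link = link
        cols, names = [], []
        for t in term_spec.parametric_terms:
            if t == "intercept":
                cols.append(np.ones_like(ages))
            elif t == "log_height":
                cols.append(np.log(height))
            else:
                cols.append(np.log(ages))
            names.append(t)
        self.X = np.column_stack(cols) if cols else np.empty((len(ages), 0))
        self.term_names = names
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            sds = self.X.std(axis=0)
            culprit = names[int(np.argmin(sds[1:]) + 1)] if len(names) > 1 else names[0]
            raise ValueError(
                f"singular design for {pname}: column {culprit!r} carries no variation"
            )
        self.has_spline = term_spec.has_spline
        if self.has_spline:
            Braw, self.knot_vector = _bspline_basis(ages)
            # orthogonalize the smooth against the parametric columns so the
            # exported intercept/slope coefficients stay identifiable
            self.A = np.linalg.lstsq(self.X, Braw, rcond=None)[0]
            self.B = Braw - self.X @ self.A
            self.Braw = Braw
            self.P = _difference_penalty(Braw.shape[1])
            self.target_edf = self.X.shape[1] + term_spec.spline_df
        else:
            self.B = np.empty((len(ages), 0))
            self.P = np.empty((0, 0))
            self.target_edf = float(self.X.shape[1])
        self.C = np.hstack([self.X, self.B])
        self.n_par = self.X.shape[1]
        self.n_spl = self.B.shape[1]
        self.coef = np.zeros(self.n_par + self.n_spl)
        self.lam = 0.0

    def eta(self):
        return self.C @ self.coef

    def penalty_full(self, lam):
        if not self.has_spline:
            return np.zeros((self.coef.size, self.coef.size))
        Pf = np.zeros((self.coef.size, self.coef.size))
        Pf[self.n_par :, self.n_par :] = lam * self.P
        return Pf

    def roughness(self):
        if not self.has_spline:
            return 0.0
        s = self.coef[self.n_par :]
        return float(self.lam * s @ self.P @ s)

    def _ridge(self, CtWC):
        scale = np.trace(CtWC) / CtWC.shape[0] + 1.0
        return 1e-8 * scale * np.eye(CtWC.shape[0])

    def edf(self, W):
        if not self.has_spline:
            return float(self.n_par)
        CtWC = self.C.T @ (W[:, None] * self.C)
        M = CtWC + self.penalty_full(self.lam) + self._ridge(CtWC)
        return float(np.trace(_solve(M, CtWC)))

    def solve_lambda(self, W):
        """Pick lambda so the smoother's effective df hits the target."""
        CtWC = self.C.T @ (W[:, None] * self.C)
        ridge = self._ridge(CtWC)

        def edf_at(loglam):
            M = CtWC + self.penalty_full(10.0 ** loglam) + ridge
            return float(np.trace(_solve(M, CtWC)))

        lo, hi = -8.0, 12.0
        if edf_at(hi) > self.target_edf:
            return 10.0 ** hi
        if edf_at(lo) < self.target_edf:
            return 10.0 ** lo
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            if edf_at(mid) > self.target_edf:
                lo = mid
            else:
                hi = mid
        return 10.0 ** (0.5 * (lo + hi))


# ---------------------------------------------------------------------------
# the fitter

def _prepare(cohort: pd.DataFrame, spec: ModelSpec):
    col = _INDEX_COLUMN[spec.index]
    needed = [col, "height_cm", "age_years"]
    df = cohort.loc[:, needed].dropna()
    # canonical record order makes the fit bit-exactly invariant to shuffling
    df = df.sort_values(["age_years", "height_cm", col], kind="stable")
    y = df[col].to_numpy(dtype=float)
    keep = y > 0
    y = y[keep]
    height = df["height_cm"].to_numpy(dtype=float)[keep]
    ages = df["age_years"].to_numpy(dtype=float)[keep]
    if y.size <= 50:
        raise ValueError(
            f"need more than 50 usable records to fit {spec.index}; got {y.size}"
        )
    return y, height, ages


def _initialize(designs, family, y):
    dmu = designs["mu"]
    target = _link(y, dmu.link)
    dmu.coef[: dmu.n_par] = np.linalg.lstsq(dmu.X, target, rcond=None)[0]
    mu0 = _invlink(dmu.eta(), dmu.link)
    mu0 = np.maximum(mu0, 1e-8)
    resid = np.log(y) - np.log(mu0)
    s0 = float(np.clip(np.std(resid), 1e-3, 2.0))
    dsig = designs["sigma"]
    dsig.coef[:] = 0.0
    dsig.coef[0] = _link(s0, dsig.link)
    if "nu" in designs:
        dnu = designs["nu"]
        dnu.coef[:] = 0.0
        dnu.coef[0] = _link(1.0, dnu.link) if dnu.link == "log" else 1.0
    if "tau" in designs:
        dtau = designs["tau"]
        dtau.coef[:] = 0.0
        dtau.coef[0] = _link(2.0, dtau.link) if dtau.link == "log" else 2.0


def _params_from(designs, family):
    return {p: _invlink(d.eta(), d.link) for p, d in designs.items()}


def _pen_deviance(designs, family, y):
    ll = _loglik_terms(family, y, _params_from(designs, family))
    dev = -2.0 * np.sum(ll)
    return dev + sum(d.roughness() for d in designs.values())


def _score_and_weights(designs, family, y, pname):
    """Central-difference score and (quasi-)Fisher weights w.r.t. one predictor."""
    etas = {p: d.eta() for p, d in designs.items()}
    links = {p: d.link for p, d in designs.items()}

    def ll_at(eta_p):
        params = {
            p: _invlink(eta_p if p == pname else etas[p], links[p]) for p in designs
        }
        return _loglik_terms(family, y, params)

    eta = etas[pname]
    h = 1e-3 * (1.0 + np.abs(eta))
    l0 = ll_at(eta)
    lp = ll_at(eta + h)
    lm = ll_at(eta - h)
    finite = np.isfinite(l0) & np.isfinite(lp) & np.isfinite(lm)
    u = np.zeros_like(eta)
    d2 = np.zeros_like(eta)
    u[finite] = (lp[finite] - lm[finite]) / (2.0 * h[finite])
    d2[finite] = (lp[finite] - 2.0 * l0[finite] + lm[finite]) / (h[finite] ** 2)
    w = -d2
    bad = ~np.isfinite(w) | (w <= 1e-10)
    w[bad] = np.maximum(u[bad] ** 2, 1e-8)
    w = np.clip(w, 1e-8, 1e8)
    return u, w


def fit_gamlss(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    *,
    tol: float = 1e-6,
    max_iter: int = 200,
    polish: bool = True,
) -> FitResult:
    """Fit one candidate model to a cohort by penalized backfitting.

    Returns a :class:`FitResult` whose ``converged`` flag is honest: a
    fit that exhausts ``max_iter`` without meeting the deviance tolerance
    is returned flagged, never silently.
    """
    np.seterr(over="ignore", invalid="ignore")
    y, height, ages = _prepare(cohort, spec)
    family = spec.family
    designs = {
        p: _ParamDesign(p, spec.term_spec(p), spec.link(p), height, ages)
        for p in _FAMILY_PARAMS[family]
    }
    _initialize(designs, family, y)

    pen_dev = _pen_deviance(designs, family, y)
    converged = False
    it = 0
    message = ""
    for it in range(1, max_iter + 1):
        dev_cycle_start = pen_dev
        for pname, d in designs.items():
            u, w = _score_and_weights(designs, family, y, pname)
            adj = np.clip(u / w, -100.0, 100.0)
            zw = d.eta() + adj
            if d.has_spline:
                d.lam = d.solve_lambda(w)
            CtWC = d.C.T @ (w[:, None] * d.C)
            M = CtWC + d.penalty_full(d.lam) + d._ridge(CtWC)
            rhs = d.C.T @ (w * zw)
            coef_new = _solve(M, rhs)
            old = d.coef.copy()
            step = 1.0
            improved = False
            for _ in range(10):
                d.coef = old + step * (coef_new - old)
                cand = _pen_deviance(designs, family, y)
                if np.isfinite(cand) and cand <= pen_dev + 1e-10:
                    pen_dev = cand
                    improved = True
                    break
                step *= 0.5
            if not improved:
                d.coef = old
        if abs(dev_cycle_start - pen_dev) < tol and it > 1:
            converged = True
            break
    if not converged:
        message = f"outer loop did not meet tol={tol:g} in {max_iter} cycles"

    any_spline = any(d.has_spline for d in designs.values())
    if polish and not any_spline:
        converged = _polish(designs, family, y) or converged
        if converged:
            message = ""

    params = _params_from(designs, family)
    ll_terms = _loglik_terms(family, y, params)
    loglik = float(np.sum(ll_terms))
    weights_now = {p: _score_and_weights(designs, family, y, p)[1] for p in designs}
    edf = {p: d.edf(weights_now[p]) for p, d in designs.items()}
    total_df = float(sum(edf.values()))

    resid = _insample_residuals(family, y, params)
    pmodels = {p: _export_parameter(d) for p, d in designs.items()}
    return FitResult(
        spec=spec,
        index=spec.index,
        family=family,
        parameter_models=pmodels,
        edf=edf,
        total_df=total_df,
        loglik=loglik,
        sbc=sbc(loglik, total_df, y.size),
        n=int(y.size),
        converged=converged,
        n_iter=it,
        message=message,
        residual_mean=float(np.mean(resid)),
        residual_var=float(np.var(resid)),
        lambdas={p: d.lam for p, d in designs.items() if d.has_spline},
    )


def _polish(designs, family, y) -> bool:
    """BFGS refinement of the exact likelihood for spline-free fits."""
    order = list(designs)
    sizes = [designs[p].coef.size for p in order]
    x0 = np.concatenate([designs[p].coef for p in order])

    def unpack(x):
        out, i = {}, 0
        for p, s in zip(order, sizes):
            out[p] = x[i : i + s]
            i += s
        return out

    def negll(x):
        pieces = unpack(x)
        params = {
            p: _invlink(designs[p].C @ pieces[p], designs[p].link) for p in order
        }
        ll = _loglik_terms(family, y, params)
        val = -np.sum(ll)
        return val if np.isfinite(val) else 1e12

    res = optimize.minimize(negll, x0, method="BFGS", options={"gtol": 1e-6, "maxiter": 500})
    if res.fun <= negll(x0) + 1e-9:
        for p, piece in unpack(res.x).items():
            designs[p].coef = np.asarray(piece, dtype=float)
    return bool(res.success)


def _insample_residuals(family, y, params):
    if family == "normal":
        return (y - params["mu"]) / params["sigma"]
    if family == "BCCG":
        return zscore(y, BCCGParams(params["mu"], params["sigma"], params["nu"]))
    return zscore(y, BCPEParams(params["mu"], params["sigma"], params["nu"], params["tau"]))


def _export_parameter(d: _ParamDesign) -> ParameterModel:
    beta = {name: 0.0 for name in ("intercept", "log_height", "log_age")}
    par = d.coef[: d.n_par].copy()
    spline_tab = None
    if d.has_spline:
        s = d.coef[d.n_par :]
        par = par - d.A @ s  # undo the orthogonalization shift
        # sample the fitted smooth onto integer-year knots
        lo = float(d.knot_vector[_SPLINE_DEGREE])
        hi = float(d.knot_vector[-_SPLINE_DEGREE - 1])
        knots = np.arange(np.ceil(lo), np.floor(hi) + 1.0)
        if knots.size < 2:
            knots = np.array([lo, hi])
        basis = BSpline.design_matrix(
            np.clip(knots, lo, hi - 1e-9), d.knot_vector, _SPLINE_DEGREE
        ).toarray()
        spline_tab = SplineTable(tuple(knots.tolist()), tuple((basis @ s).tolist()))
    for name, value in zip(d.term_names, par):
        beta[name] = float(value)
    return ParameterModel(
        link=d.link,
        intercept=beta["intercept"],
        beta_log_height=beta["log_height"],
        beta_log_age=beta["log_age"],
        spline=spline_tab,
        spline_declared=d.has_spline,
    )


# ---------------------------------------------------------------------------
# model selection

def select_model(
    cohort: pd.DataFrame,
    menu: Sequence[ModelSpec],
    *,
    delta_sbc: float = 2.0,
    residual_mean_tol: float = 0.1,
    residual_var_tol: float = 0.15,
    **fit_kwargs,
):
    """Fit every candidate and choose by SBC with a parsimony tie rule.

    Candidates are ranked by ascending SBC; any candidate within
    ``delta_sbc`` of the best with strictly fewer total df displaces it
    ("not worth a mention" evidence window), and a residual-moment
    screen (|mean| and |var-1| bounds) can veto a winner.  Returns
    ``(selected, ranked)`` with the full ranking kept for audit.
    """
    menu = list(menu)
    if not menu:
        raise ValueError("model menu is empty")
    fits = [fit_gamlss(cohort, spec, **fit_kwargs) for spec in menu]
    usable = [f for f in fits if f.converged]
    if not usable:
        raise RuntimeError("no candidate model converged; cannot select")
    return choose_from(
        usable,
        delta_sbc=delta_sbc,
        residual_mean_tol=residual_mean_tol,
        residual_var_tol=residual_var_tol,
    )


def choose_from(
    fits,
    *,
    delta_sbc: float = 2.0,
    residual_mean_tol: float = 0.1,
    residual_var_tol: float = 0.15,
):
    """Apply the SBC ranking, parsimony window and residual screen to fitted candidates."""
    ranked = sorted(fits, key=lambda f: f.sbc)

    def passes_screen(f):
        return abs(f.residual_mean) < residual_mean_tol and abs(f.residual_var - 1.0) < residual_var_tol

    def pick(cands):
        best = cands[0]
        window = [f for f in cands if f.sbc <= best.sbc + delta_sbc]
        return min(window, key=lambda f: (f.total_df, f.sbc))

    screened = [f for f in ranked if passes_screen(f)]
    if screened:
        selected = pick(screened)
    else:
        warnings.warn("no candidate passed the residual-moment screen; selecting by SBC only")
        selected = pick(ranked)
    return selected, ranked


def default_menu(index: str, families: Sequence[str] = ("BCCG", "BCPE")) -> list:
    """The configurable candidate menu spanning the shipped equation forms.

    Crosses family x {no spline, mu spline, mu+sigma spline} x
    {nu constant, nu ~ log(age)} x (BCPE only: tau constant, tau ~
    log(age)); mu always carries log(height) and log(age), sigma always
    log(age).
    """
    menu = []
    spline_opts = (
        ("intercept", "log_height", "log_age"),
        ("intercept", "log_height", "log_age", "spline_age"),
    )
    sigma_opts = (
        ("intercept", "log_age"),
        ("intercept", "log_age", "spline_age"),
    )
    for family in families:
        for mu_terms, sigma_terms in (
            (spline_opts[0], sigma_opts[0]),
            (spline_opts[1], sigma_opts[0]),
            (spline_opts[1], sigma_opts[1]),
        ):
            for nu_terms in (("intercept",), ("intercept", "log_age")):
                tau_choices = (
                    (("intercept",), ("intercept", "log_age"))
                    if family == "BCPE"
                    else (None,)
                )
                for tau_terms in tau_choices:
                    menu.append(
                        ModelSpec(
                            family=family,
                            index=index,
                            mu=TermSpec(mu_terms),
                            sigma=TermSpec(sigma_terms),
                            nu=TermSpec(nu_terms),
                            tau=TermSpec(tau_terms) if tau_terms else None,
                        )
                    )
    return menu


# ---------------------------------------------------------------------------
# diagnostics

def quantile_residuals(fit: FitResult, cohort: pd.DataFrame) -> np.ndarray:
    """Quantile residuals: the z-score of each record under the fitted model.

    For continuous responses these are exactly Phi^-1(F(y)); data
    generated from the fitted model itself yield standard-normal
    residuals.
    """
    col = _INDEX_COLUMN[fit.index]
    df = cohort.loc[:, [col, "height_cm", "age_years"]].dropna()
    y = df[col].to_numpy(dtype=float)
    p = fit.index_model.params_at(
        df["height_cm"].to_numpy(dtype=float), df["age_years"].to_numpy(dtype=float)
    )
    if fit.family == "normal":
        return (y - np.asarray(p.mu)) / np.asarray(p.sigma)
    return np.asarray(zscore(y, p))


def worm_plot_data(residuals, ages, n_bins: int = 4) -> pd.DataFrame:
    """Detrended QQ coordinates per age bin (equal counts +/- 1).

    Columns: bin, age_lo, age_hi, theoretical, empirical, deviation
    (= empirical - theoretical).  ``n_bins = 1`` is a global detrended
    QQ plot.
    """
    residuals = np.asarray(residuals, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if residuals.shape != ages.shape:
        raise ValueError("residuals and ages must have equal length")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    order = np.argsort(ages, kind="stable")
    chunks = np.array_split(order, n_bins)
    frames = []
    for b, idx in enumerate(chunks):
        r = np.sort(residuals[idx])
        m = r.size
        theo = special.ndtri((np.arange(1, m + 1) - 0.5) / m)
        frames.append(
            pd.DataFrame(
                {
                    "bin": b,
                    "age_lo": float(np.min(ages[idx])),
                    "age_hi": float(np.max(ages[idx])),
                    "theoretical": theo,
                    "empirical": r,
                    "deviation": r - theo,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def centile_curves(
    eq: EquationSet,
    index: str,
    centiles: Sequence[float] = (0.05, 0.25, 0.5, 0.75, 0.95),
    age_grid: Sequence[float] | None = None,
    height_policy="median",
) -> pd.DataFrame:
    """Reference centile curves over age at a fixed height.

    ``height_policy`` is either a height in cm or ``"median"`` (the sex
    median height).  Curves cannot cross: they are quantiles of one
    distribution per age.
    """
    index = normalize_index(index)
    if age_grid is None:
        lo, hi = eq.valid_age_range
        age_grid = np.linspace(lo, hi, 53)
    ages = np.asarray(age_grid, dtype=float)
    height = _MEDIAN_HEIGHT[eq.sex] if height_policy == "median" else float(height_policy)
    model = eq[index]
    out = {"age_years": ages, "height_cm": np.full_like(ages, height)}
    p = model.params_at(np.full_like(ages, height), ages)
    for c in centiles:
        out[f"p{round(c * 100):g}"] = np.asarray(quantile(c, p))
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# assembly / reporting

def assemble_equation_set(fits: dict, name: str, sex: str) -> EquationSet:
    """Combine per-index FitResults into a full EquationSet."""
    missing = [k for k in INDICES if k not in fits]
    if missing:
        raise ValueError(f"missing fitted indices: {missing}")
    return EquationSet(
        name=name,
        sex=sex,
        indices={k: fits[k].index_model for k in INDICES},
        acknowledge_missing_splines=True,
    )


def fit_report(ranked, selected=None) -> dict:
    """Machine-readable model-comparison report (per-candidate SBC/df/moments)."""
    doc = {"candidates": [f.summary_dict() for f in ranked]}
    if selected is not None:
        doc["selected"] = selected.spec.name
    return doc


def write_fit_report(ranked, selected, sink) -> None:
    doc = fit_report(ranked, selected)
    if hasattr(sink, "write"):
        json.dump(doc, sink, indent=2, sort_keys=True)
    else:
        with open(str(sink), "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")
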