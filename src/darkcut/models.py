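"""Risk models for dark cutting: logistic and mixed-logistic fits.

The base production-factor model is an ordinary logistic regression of
the DC indicator on days on feed (per 10-day increment), HGP treatment,
sex, abattoir and feedlot (all fixed effects). The three climatic
models are logistic regressions with crossed random intercepts for
feedlot and slaughter date:

* model 1 — raw weather exposures (SR, WS, rain, RH, T_A),
* model 2 — SR, WS, rain plus the temperature–humidity index,
* model 3 — rain plus heat-load-index summaries,

each in mean/range/max/min (or HLI-threshold) variants, with sex and
HGP as fixed effects throughout. Coefficients are reported as log-odds
with Wald standard errors, odds ratios with 95% CIs, and Wald p-values.

The mixed fits maximise the Laplace-approximate marginal likelihood:
for fixed random-effect standard deviations the joint penalised
log-likelihood is maximised over fixed effects and random intercepts by
Newton iteration, and the profiled Laplace objective is then optimised
over the standard deviations. With an estimated variance at zero the
fit collapses exactly to the plain logistic model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "FitResult",
    "build_design",
    "fit_logistic",
    "fit_mixed_logistic",
    "run_model_suite",
    "base_model_spec",
    "climate_model_specs",
    "CLIMATE_FEEDLOTS_EXCLUDED",
]

#: feedlots whose station data were excluded from the climatic models
CLIMATE_FEEDLOTS_EXCLUDED = ("A", "E", "F")

_REFERENCE_LEVELS = {"feedlot": "A", "abattoir": "1", "hgp": "no", "sex": "F"}


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one risk model.

    ``continuous`` maps design-column labels to ``(source column,
    divisor)`` — e.g. DOF enters per 10-day increment as
    ``{"dof_per_10d": ("dof", 10.0)}``. ``categorical`` maps columns to
    ``(reference level, levels merged into the baseline)``; merged
    levels cover factor levels that are exactly aliased with other
    terms (under the study's supply structure the feedlot-E indicator
    is collinear with the abattoir indicators, so E carries no separate
    coefficient). ``random_terms`` name grouping columns that receive
    crossed random intercepts.
    """

    name: str
    variant: str = ""
    continuous: dict = field(default_factory=dict)
    categorical: dict = field(default_factory=dict)
    random_terms: tuple = ()

    @property
    def key(self) -> tuple:
        return (self.name, self.variant)


def base_model_spec(include_morbidity: bool = False) -> ModelSpec:
    """The production-factor model: DOF/10 + HGP + sex + abattoir + feedlot.

    Morbidity is available as an optional extra term (it is significant
    when added) but is off by default.
    """
    continuous = {"dof_per_10d": ("dof", 10.0)}
    categorical = {
        "hgp": ("no", ()),
        "sex": ("F", ()),
        "abattoir": ("1", ()),
        "feedlot": ("A", ("E",)),
    }
    if include_morbidity:
        categorical["morbidity"] = ("no", ())
    return ModelSpec(
        name="base", continuous=continuous, categorical=categorical
    )


def climate_model_specs() -> list[ModelSpec]:
    """The twelve climatic model/variant combinations.

    Variants follow the published table layouts: model 1 and 2 keep SR
    and WS at their window means except where the variant replaces them
    (max models use the maxima, the min models use the WS minimum);
    model 3 has mean, max, hours-at-or-above-HLI-86 and
    cold-days (HLI ≤ 70 for ≥ 6 h) variants, each with rain.
    """
    c1 = {
        "mean": ["sr_mean", "ws_mean", "rain_total_7", "rh_mean", "ta_mean"],
        "range": ["sr_mean", "ws_mean", "rain_total_7", "rh_range", "ta_range"],
        "max": ["sr_max", "ws_max", "rain_total_7", "rh_max", "ta_max"],
        "min": ["sr_mean", "ws_min", "rain_total_7", "rh_min", "ta_min"],
    }
    c2 = {
        "mean": ["sr_mean", "ws_mean", "rain_total_7", "thi_mean"],
        "range": ["sr_mean", "ws_mean", "rain_total_7", "thi_range"],
        "max": ["sr_max", "ws_max", "rain_total_7", "thi_max"],
        "min": ["sr_mean", "ws_min", "rain_total_7", "thi_min"],
    }
    c3 = {
        "mean": ["hli_mean", "rain_total_7"],
        "max": ["hli_max", "rain_total_7"],
        "hli86": ["hours_hli_ge86_per_day", "rain_total_7"],
        "lt70": ["days_hli_le70_ge6h", "rain_total_7"],
    }
    specs = []
    for name, table in (("climate1", c1), ("climate2", c2), ("climate3", c3)):
        for variant, cols in table.items():
            specs.append(ModelSpec(
                name=name,
                variant=variant,
                continuous={c: (c, 1.0) for c in cols},
                categorical={"hgp": ("no", ()), "sex": ("F", ())},
                random_terms=("feedlot", "kill_date"),
            ))
    return specs


@dataclass
class FitResult:
    """Coefficient table plus fit diagnostics for one model.

    ``terms`` is indexed by design-column label with columns
    ``estimate`` (log-odds), ``se``, ``or``, ``ci_low``, ``ci_high``
    and ``p`` (Wald). ``random_variances`` holds the estimated
    random-intercept variances per grouping factor (empty for plain
    logistic fits).
    """

    terms: pd.DataFrame
    loglik: float
    n_obs: int
    converged: bool
    random_variances: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    n_dropped: int = 0

    def odds_ratio(self, term: str) -> float:
        return float(self.terms.loc[term, "or"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.terms.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])

    def to_frame(self) -> pd.DataFrame:
        out = self.terms.reset_index().rename(columns={"index": "term"})
        return out


def _term_table(names, est, se, z: float = 1.959963984540054) -> pd.DataFrame:
    from scipy.stats import norm

    est = np.asarray(est, dtype=float)
    se = np.asarray(se, dtype=float)
    zstat = np.divide(est, se, out=np.zeros_like(est), where=se > 0)
    p = 2.0 * norm.sf(np.abs(zstat))
    return pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "or": np.exp(est),
            "ci_low": np.exp(est - z * se),
            "ci_high": np.exp(est + z * se),
            "p": p,
        },
        index=pd.Index(names, name="term"),
    )


def build_design(
    records: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, pd.DataFrame, dict, int]:
    """Build the outcome vector, design matrix and grouping codes.

    Records missing any required covariate (e.g. animals without a
    climate exposure under a climatic spec) are dropped with a count.
    Categorical factors expand to indicator columns against the spec's
    reference levels, in sorted level order; the design carries an
    explicit intercept as its first column and has a deterministic
    column order. Rank deficiency and single-level factors raise.

    Returns ``(y, X, groups, n_dropped)`` where ``groups`` maps each
    random term to an integer code array plus its level index.
    """
    needed = ["dc"] + [c for c, _ in spec.continuous.values()] + \
        list(spec.categorical) + list(spec.random_terms)
    missing_cols = [c for c in needed if c not in records.columns]
    if missing_cols:
        raise KeyError(f"records missing required columns: {missing_cols}")
    sub = records.dropna(subset=needed)
    n_dropped = len(records) - len(sub)
    if len(sub) == 0:
        raise ValueError("no complete records available for this model")

    X = pd.DataFrame(index=sub.index)
    X["intercept"] = 1.0
    for label, (col, divisor) in spec.continuous.items():
        X[label] = sub[col].to_numpy(dtype=float) / divisor
    for col, (ref, merged) in spec.categorical.items():
        levels = sorted(str(v) for v in sub[col].astype(str).unique())
        if len(levels) < 2:
            raise ValueError(f"factor {col!r} has a single level: {levels}")
        if ref not in levels and not set(levels) <= set(merged) | {ref}:
            # tolerate an absent reference only if other levels remain
            pass
        for lev in levels:
            if lev == ref or lev in merged:
                continue
            X[f"{col}[{lev}]"] = (sub[col].astype(str) == lev).astype(float)

    arr = X.to_numpy(dtype=float)
    _, r = np.linalg.qr(arr)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps
    if (diag <= tol).any():
        aliased = [X.columns[i] for i in np.flatnonzero(diag <= tol)]
        raise ValueError(f"design is rank deficient; aliased columns: {aliased}")

    groups = {}
    for term in spec.random_terms:
        codes, levels = pd.factorize(sub[term].astype(str), sort=True)
        if len(levels) < 2:
            raise ValueError(
                f"random term {term!r} needs >= 2 levels, found {len(levels)}"
            )
        groups[term] = (codes, list(levels))

    y = sub["dc"].to_numpy(dtype=float)
    return y, X, groups, n_dropped


def fit_logistic(y, X: pd.DataFrame, warn_threshold: float = 15.0) -> FitResult:
    """Maximum-likelihood logistic regression with Wald inference.

    Backed by an iteratively reweighted least-squares GLM fit; standard
    errors come from the inverse observed information. Coefficients
    whose magnitude on the standardised-covariate scale exceeds
    ``warn_threshold`` flag probable separation on the result rather
    than raising.
    """
    y = np.asarray(y, dtype=float)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(tol=1e-10, maxiter=200)
    table = _term_table(list(X.columns), res.params, res.bse)
    warnings_ = []
    sds = X.std(ddof=0)
    for name in X.columns:
        if name == "intercept":
            continue
        scaled = abs(res.params[name]) * (sds[name] if sds[name] > 0 else 1.0)
        if scaled > warn_threshold:
            warnings_.append(f"possible separation on term {name!r}")
    return FitResult(
        terms=table,
        loglik=float(res.llf),
        n_obs=int(len(y)),
        converged=bool(res.converged),
        warnings=warnings_,
    )


# ---------------------------------------------------------------------------
# Laplace-approximate mixed logistic (crossed random intercepts)
# ---------------------------------------------------------------------------

def _sigmoid(eta):
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    ez = np.exp(eta[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bernoulli_ll(y, eta):
    # numerically stable sum of y*eta - log(1 + exp(eta))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


class _LaplaceProblem:
    """Penalised Newton fits and Laplace objectives for fixed sigmas.

    For crossed random intercepts the weighted cross-products Z'WZ,
    X'WZ and Z'r decompose into per-factor ``bincount`` reductions and
    per-factor-pair dense cell-count blocks, so no explicit (sparse)
    indicator matrix is ever materialised; each Newton iteration costs
    O(n·p + q**2).
    """

    def __init__(self, y, X, group_codes, group_sizes):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        self.codes = [np.asarray(c, dtype=np.intp) for c in group_codes]
        self.sizes = [int(s) for s in group_sizes]
        self.q = int(sum(self.sizes))
        self._warm: dict = {}  # per-active-set warm starts for Newton

    # -- structured linear algebra over the random-effect design --

    def _zu(self, u, active):
        """Z @ u without materialising Z."""
        out = np.zeros(self.n)
        off = 0
        for i in active:
            out += u[off:off + self.sizes[i]][self.codes[i]]
            off += self.sizes[i]
        return out

    def _ztv(self, v, active):
        """Z' @ v."""
        return np.concatenate(
            [np.bincount(self.codes[i], v, self.sizes[i]) for i in active]
        )

    def _ztwz(self, w, active, pen):
        """Z'WZ + diag(pen) as a dense (q_active, q_active) matrix."""
        sizes = [self.sizes[i] for i in active]
        offs = np.concatenate([[0], np.cumsum(sizes)])
        q = int(offs[-1])
        C = np.zeros((q, q))
        for a, i in enumerate(active):
            d = np.bincount(self.codes[i], w, self.sizes[i])
            idx = np.arange(offs[a], offs[a + 1])
            C[idx, idx] = d
            for b, j in enumerate(active[a + 1:], start=a + 1):
                blk = np.zeros((self.sizes[i], self.sizes[j]))
                np.add.at(blk, (self.codes[i], self.codes[j]), w)
                C[offs[a]:offs[a + 1], offs[b]:offs[b + 1]] = blk
                C[offs[b]:offs[b + 1], offs[a]:offs[a + 1]] = blk.T
        C[np.diag_indices(q)] += pen
        return C

    def _xtwz(self, w, active):
        """X'WZ as a dense (p, q_active) matrix."""
        cols = []
        for i in active:
            blk = np.empty((self.p, self.sizes[i]))
            for j in range(self.p):
                blk[j] = np.bincount(
                    self.codes[i], w * self.X[:, j], self.sizes[i]
                )
            cols.append(blk)
        return np.hstack(cols)

    def _pen(self, sigmas, active):
        return np.concatenate(
            [np.full(self.sizes[i], 1.0 / sigmas[i] ** 2) for i in active]
        ) if active else np.empty(0)

    @staticmethod
    def _active(sigmas):
        return [i for i, s in enumerate(sigmas) if s > 0]

    # -- fits --

    def inner_fit(self, sigmas, beta0=None, u0=None, tol=1e-8, maxiter=100):
        """Maximise the joint penalised log-likelihood over (beta, u)."""
        active = self._active(sigmas)
        pen = self._pen(sigmas, active)
        q = int(pen.size)

        if beta0 is None or u0 is None:
            wb, wu = self._warm.get(tuple(active), (None, None))
            beta0 = beta0 if beta0 is not None else wb
            u0 = u0 if u0 is not None else wu
        beta = np.zeros(self.p) if beta0 is None else np.asarray(beta0).copy()
        u = np.zeros(q) if u0 is None or len(u0) != q else np.asarray(u0).copy()

        def pll(b, uu):
            eta = self.X @ b + self._zu(uu, active)
            return _bernoulli_ll(self.y, eta) - 0.5 * float(np.sum(pen * uu**2))

        cur = pll(beta, u)
        H = None
        delta = 0.0
        for _ in range(maxiter):
            eta = self.X @ beta + self._zu(u, active)
            mu = _sigmoid(eta)
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            resid = self.y - mu
            gb = self.X.T @ resid
            XtWX = self.X.T @ (self.X * w[:, None])
            if active:
                gu = self._ztv(resid, active) - pen * u
                XtWZ = self._xtwz(w, active)
                C = self._ztwz(w, active, pen)
                H = np.block([[XtWX, XtWZ], [XtWZ.T, C]])
                g = np.concatenate([gb, gu])
            else:
                H = XtWX
                g = gb
            H_reg = H + np.eye(H.shape[0]) * 1e-10
            try:
                step = np.linalg.solve(H_reg, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H_reg, g, rcond=None)[0]
            t = 1.0
            for _ in range(30):  # step halving
                nb = beta + t * step[: self.p]
                nu = u + t * step[self.p:]
                new = pll(nb, nu)
                if new >= cur - 1e-12:
                    break
                t *= 0.5
            delta = float(np.max(np.abs(t * step))) if step.size else 0.0
            beta, u, cur = nb, nu, new
            if delta < tol:
                break
        converged = delta < max(tol * 10, 1e-6)
        self._warm[tuple(active)] = (beta.copy(), u.copy())
        return beta, u, cur, H, pen, active, converged

    def u_mode(self, beta, sigmas, u0=None, tol=1e-9, maxiter=50):
        """Newton maximisation of the penalised likelihood over u only."""
        active = self._active(sigmas)
        pen = self._pen(sigmas, active)
        q = int(pen.size)
        u = np.zeros(q) if u0 is None or len(u0) != q else np.asarray(u0).copy()
        xb = self.X @ beta
        C = np.empty((0, 0))
        for _ in range(maxiter):
            eta = xb + self._zu(u, active)
            mu = _sigmoid(eta)
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            g = self._ztv(self.y - mu, active) - pen * u
            C = self._ztwz(w, active, pen)
            step = np.linalg.solve(C, g)
            u = u + step
            if np.max(np.abs(step)) < tol:
                break
        return u, C, active, pen

    def marginal_objective(self, beta, sigmas, u0=None):
        """True Laplace marginal log-likelihood at (beta, sigmas),
        integrating the random effects only."""
        if not self._active(sigmas):
            return _bernoulli_ll(self.y, self.X @ beta), np.empty(0)
        u, C, active, pen = self.u_mode(beta, sigmas, u0=u0)
        eta = self.X @ beta + self._zu(u, active)
        obj = _bernoulli_ll(self.y, eta) - 0.5 * float(np.sum(pen * u**2))
        for i in active:
            obj -= self.sizes[i] * np.log(sigmas[i])
        sign, logdet = np.linalg.slogdet(C)
        if sign <= 0:
            return -np.inf, u
        obj -= 0.5 * logdet
        return obj, u

    def joint_hessian(self, beta, sigmas):
        """Joint observed information over (beta, u) at the u mode."""
        if not self._active(sigmas):
            eta = self.X @ beta
            mu = _sigmoid(eta)
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            return self.X.T @ (self.X * w[:, None])
        u, C, active, pen = self.u_mode(beta, sigmas)
        eta = self.X @ beta + self._zu(u, active)
        mu = _sigmoid(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        XtWX = self.X.T @ (self.X * w[:, None])
        XtWZ = self._xtwz(w, active)
        return np.block([[XtWX, XtWZ], [XtWZ.T, C]])

    def laplace_objective(self, sigmas, state=None):
        """Laplace log-marginal-likelihood with beta profiled at the
        joint penalised mode (used for the variance search)."""
        beta, u, pl, H, pen, active, conv = self.inner_fit(sigmas)
        obj = pl
        if active:
            quu = H[self.p:, self.p:]
            sign, logdet = np.linalg.slogdet(quu)
            if sign <= 0:
                return -np.inf, (beta, u, H, conv)
            # prior normalisation contributes -q_f/2*log(2*pi*sigma^2)
            # per factor and the Gaussian integral +q/2*log(2*pi); the
            # 2*pi terms cancel, leaving sigma and curvature terms.
            for i in active:
                obj -= self.sizes[i] * np.log(sigmas[i])
            obj -= 0.5 * logdet
        return obj, (beta, u, H, conv)


def fit_mixed_logistic(
    y,
    X: pd.DataFrame,
    groups: dict,
    sigma_bounds: tuple[float, float] = (0.0, 5.0),
) -> FitResult:
    """Logistic regression with crossed random intercepts (Laplace ML).

    ``groups`` maps grouping-factor names to ``(codes, levels)`` as
    produced by :func:`build_design`. The random-effect standard
    deviations are profiled out by bounded derivative-free
    optimisation of the Laplace objective; at a zero variance the fit
    reduces exactly to the plain logistic model. Fixed-effect standard
    errors come from the fixed-effect block of the inverse joint
    observed information at the mode.
    """
    if not groups:
        raise ValueError("fit_mixed_logistic requires at least one random term")
    names = list(groups)
    codes = [np.asarray(groups[g][0], dtype=int) for g in names]
    sizes = [len(groups[g][1]) for g in names]
    for g, q in zip(names, sizes):
        if q < 2:
            raise ValueError(f"random term {g!r} has fewer than 2 levels")
    prob = _LaplaceProblem(y, X.to_numpy(dtype=float), codes, sizes)

    def negobj(sig):
        sig = np.clip(sig, 0.0, None)
        val, _ = prob.laplace_objective(list(sig))
        return -val

    x0 = np.full(len(names), float(np.clip(0.3, *sigma_bounds)))
    res = optimize.minimize(
        negobj,
        x0,
        method="Powell",
        bounds=[sigma_bounds] * len(names),
        options={"xtol": 1e-3, "ftol": 1e-7, "maxiter": 100},
    )
    sig_hat = np.clip(res.x, 0.0, None)
    # a standard deviation this small is numerically zero (variance
    # < 1e-6): collapse it so the fit reduces to the simpler model
    sig_hat[sig_hat < 1e-3] = 0.0
    obj, (beta, u, H, inner_conv) = prob.laplace_objective(list(sig_hat))

    # refine beta against the true Laplace marginal objective (the
    # profiled joint mode ignores the beta-dependence of the log-det
    # curvature term; the refinement recovers lme4-style estimates)
    if sig_hat.max() > 0:
        ucache = {"u": None}

        def neg_marginal(b):
            val, uhat = prob.marginal_objective(b, list(sig_hat),
                                                u0=ucache["u"])
            ucache["u"] = uhat
            return -val

        ref = optimize.minimize(
            neg_marginal, beta, method="BFGS",
            options={"gtol": 1e-5, "maxiter": 60},
        )
        if np.isfinite(ref.fun):
            beta = ref.x
            obj = -ref.fun
            H = prob.joint_hessian(beta, list(sig_hat))

    p = prob.p
    H_reg = H + np.eye(H.shape[0]) * 1e-10
    cov = np.linalg.inv(H_reg)
    se = np.sqrt(np.clip(np.diag(cov)[:p], 0.0, None))
    table = _term_table(list(X.columns), beta, se)
    return FitResult(
        terms=table,
        loglik=float(obj),
        n_obs=int(len(y)),
        converged=bool(res.success and inner_conv),
        random_variances={g: float(s**2) for g, s in zip(names, sig_hat)},
    )


def run_model_suite(
    records: pd.DataFrame,
    specs: list[ModelSpec] | None = None,
) -> dict:
    """Fit the base model plus the twelve climatic variants.

    Climatic specs are restricted to feedlots outside the excluded set
    and to records carrying climate exposures. Per-fit failures are
    collected as string notices rather than aborting the suite.

    Returns a dict keyed by ``(model name, variant)`` whose values are
    :class:`FitResult` on success or an error string on failure.
    """
    if specs is None:
        specs = [base_model_spec()] + climate_model_specs()
    results: dict = {}
    for spec in specs:
        sub = records
        if spec.random_terms:  # climatic model
            sub = records[~records["feedlot"].isin(CLIMATE_FEEDLOTS_EXCLUDED)]
        try:
            y, X, groups, n_dropped = build_design(sub, spec)
            if groups:
                fit = fit_mixed_logistic(y, X, groups)
            else:
                fit = fit_logistic(y, X)
            fit.n_dropped = n_dropped
            results[spec.key] = fit
        except (ValueError, KeyError) as err:
            results[spec.key] = f"skipped: {err}"
    return results
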