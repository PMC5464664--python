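"""Weighted quantile sum (WQS) regression.

The model relates a binary outcome y to a single weighted index of c scored
components q_i and adjustment covariates z:

    logit(mu) = beta0 + beta1 * (sum_i w_i q_i) + z' phi,
    sum_i w_i = 1,  0 <= w_i <= 1.

The simplex constraint on w resolves the scale ambiguity of the bilinear term
and absorbs collinearity among the correlated components; w_i is read as the
relative importance of component i.  Estimation follows the standard two-stage
ensemble recipe: on each of B bootstrap resamples of the training split the
constrained likelihood is maximised jointly over (beta0, beta1, phi, w); the
final weights are the average of the bootstrap weight vectors, weighted by the
strength of each bootstrap's beta1 test statistic (restricted to bootstraps
estimating the hypothesised positive direction).  The index built from the
averaged weights is then carried to the held-out validation split, where an
ordinary logistic regression gives the reported odds ratio, Wald CI and AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit, logit

from . import assembly, scoring
from .specs import IndexSpec

SIGNALS = ("abs_t", "t2", "significant")


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion: -2*loglik + 2*k."""
    return -2.0 * float(loglik) + 2.0 * int(k)


@dataclass
class BootstrapEstimate:
    """One bootstrap sample's constrained fit."""

    w: np.ndarray  # simplex weight vector
    beta0: float
    beta1: float
    phi: np.ndarray
    t_stat: float  # Wald z statistic for beta1 at the fitted weights
    loglik: float
    converged: bool


@dataclass
class WQSWeights:
    """Final component weights: signal-weighted average over bootstraps."""

    components: list[str]
    w: np.ndarray
    B: int = 0
    n_contributing: int = 0

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (len(self.components),):
            raise ValueError("weight vector length must match component names")
        if np.any(self.w < -1e-9) or abs(self.w.sum() - 1.0) > 1e-6:
            raise ValueError("weights must lie on the simplex")
        self.w = np.clip(self.w, 0.0, 1.0)
        self.w = self.w / self.w.sum()

    def to_dict(self) -> dict:
        return {
            "components": list(self.components),
            "w": [float(x) for x in self.w],
            "B": int(self.B),
            "n_contributing": int(self.n_contributing),
        }


@dataclass
class WQSOptions:
    """Tuning knobs for one end-to-end WQS run."""

    mode: str = "quantile"  # "quantile" | "zscore"
    n_quantiles: int = 4
    B: int = 100
    fraction: float = 0.5
    split_seed: int = 0
    bootstrap_seed: int = 1
    equal_weights: bool = False
    signal: str = "abs_t"  # "abs_t" | "t2" | "significant"


@dataclass
class WQSFit:
    """A fitted index model: weights, validation coefficients, OR, CI, AIC."""

    spec_name: str
    mode: str
    weight_mode: str  # "estimated" | "equal"
    weights: WQSWeights
    beta0: float
    beta1: float
    se_beta1: float
    phi: dict[str, float]
    odds_ratio: float
    ci_low: float
    ci_high: float
    pvalue: float
    loglik: float
    k: int
    aic: float
    n_validation: int
    converged: bool
    coef_table: pd.DataFrame  # term, coef, se, odds_ratio, ci_low, ci_high, pvalue
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "spec_name": self.spec_name,
            "mode": self.mode,
            "weight_mode": self.weight_mode,
            "weights": self.weights.to_dict(),
            "beta0": float(self.beta0),
            "beta1": float(self.beta1),
            "se_beta1": float(self.se_beta1),
            "phi": {k: float(v) for k, v in self.phi.items()},
            "odds_ratio": float(self.odds_ratio),
            "ci_low": float(self.ci_low),
            "ci_high": float(self.ci_high),
            "pvalue": float(self.pvalue),
            "loglik": float(self.loglik),
            "k": int(self.k),
            "aic": float(self.aic),
            "n_validation": int(self.n_validation),
            "converged": bool(self.converged),
            "coef_table": self.coef_table.to_dict(orient="records"),
            "provenance": self.provenance,
        }


def _as_matrix(x, ncol_hint: int | None = None) -> np.ndarray:
    a = x.to_numpy(dtype=float) if isinstance(x, pd.DataFrame) else np.asarray(x, dtype=float)
    if a.ndim == 1:
        a = a.reshape(-1, ncol_hint or 1) if a.size else a.reshape(0, ncol_hint or 1)
    return a


def _glm_logistic(X: np.ndarray, y: np.ndarray):
    """Plain logistic fit; returns the statsmodels results object."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        return model.fit(maxiter=100)


def fit_constrained(
    q, z, y, init_weights: np.ndarray | None = None
) -> BootstrapEstimate:
    """Maximise the Bernoulli likelihood jointly over (beta0, beta1, phi, w)
    subject to w on the simplex.

    The optimum is refined by refitting an ordinary logistic regression with
    the index fixed at the optimal weights (the exact conditional maximiser),
    which also provides the Wald test statistic for beta1.  Non-convergence or
    apparent separation flags the estimate rather than raising.
    """
    q = _as_matrix(q)
    z = _as_matrix(z, ncol_hint=0) if z is not None else np.empty((len(y), 0))
    y = np.asarray(y, dtype=float)
    n, c = q.shape
    if n != len(y) or (z.size and z.shape[0] != n):
        raise ValueError("q, z and y must have aligned rows")
    if c < 1:
        raise ValueError("need at least one component")
    p = z.shape[1]

    if c == 1:
        w_hat = np.array([1.0])
    else:
        if init_weights is None:
            w0 = np.full(c, 1.0 / c)
        else:
            w0 = np.asarray(init_weights, dtype=float)
            w0 = w0 / w0.sum()
        # warm-start betas from a fit at the initial weights
        X0 = np.column_stack([np.ones(n), q @ w0, z])
        try:
            pre = _glm_logistic(X0, y)
            b0_init, b1_init = pre.params[0], pre.params[1]
            phi_init = pre.params[2:]
        except Exception:
            b0_init, b1_init, phi_init = float(logit(np.clip(y.mean(), 0.01, 0.99))), 0.1, np.zeros(p)
        if not np.all(np.isfinite([b0_init, b1_init])) or not np.all(np.isfinite(phi_init)):
            b0_init, b1_init, phi_init = 0.0, 0.1, np.zeros(p)
        theta0 = np.concatenate([[b0_init, max(b1_init, 0.01)], phi_init, w0])

        def negll(theta: np.ndarray):
            b0, b1 = theta[0], theta[1]
            phi = theta[2 : 2 + p]
            w = theta[2 + p :]
            idx = q @ w
            eta = b0 + b1 * idx + (z @ phi if p else 0.0)
            ll = np.sum(y * eta - np.logaddexp(0.0, eta))
            r = y - expit(eta)
            grad = np.empty_like(theta)
            grad[0] = r.sum()
            grad[1] = r @ idx
            if p:
                grad[2 : 2 + p] = z.T @ r
            grad[2 + p :] = b1 * (q.T @ r)
            return -ll, -grad

        bounds = [(None, None)] * (2 + p) + [(0.0, 1.0)] * c
        cons = {
            "type": "eq",
            "fun": lambda th: th[2 + p :].sum() - 1.0,
            "jac": lambda th: np.concatenate([np.zeros(2 + p), np.ones(c)]),
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize(
                negll, theta0, jac=True, method="SLSQP", bounds=bounds,
                constraints=[cons], options={"maxiter": 300, "ftol": 1e-8},
            )
        w_hat = np.clip(res.x[2 + p :], 0.0, 1.0)
        s = w_hat.sum()
        w_hat = np.full(c, 1.0 / c) if s <= 0 else w_hat / s
        opt_ok = bool(res.success)

    # conditional refit at the fitted weights: exact betas + Wald statistics
    X = np.column_stack([np.ones(n), q @ w_hat, z])
    try:
        glm = _glm_logistic(X, y)
        params, bse, tvals = glm.params, glm.bse, glm.tvalues
        llf = float(glm.llf)
        fit_ok = bool(np.all(np.isfinite(params)) and np.all(np.isfinite(bse)))
        # implausibly large coefficients / SEs indicate (quasi-)separation
        if fit_ok and (np.max(np.abs(params)) > 30 or bse[1] > 50):
            fit_ok = False
    except Exception:
        params = np.zeros(2 + p)
        bse = np.full(2 + p, np.inf)
        tvals = np.zeros(2 + p)
        llf = -np.inf
        fit_ok = False

    converged = fit_ok and (c == 1 or opt_ok)
    return BootstrapEstimate(
        w=w_hat,
        beta0=float(params[0]),
        beta1=float(params[1]),
        phi=np.asarray(params[2:], dtype=float),
        t_stat=float(tvals[1]) if np.isfinite(tvals[1]) else 0.0,
        loglik=llf,
        converged=converged,
    )


def _resample_indices(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, n, size=n)


def bootstrap_weights(
    q, z, y, B: int = 100, seed: int = 0, init_weights: np.ndarray | None = None
) -> list[BootstrapEstimate]:
    """Fit the constrained model on B size-n resamples (with replacement)."""
    if B < 1:
        raise ValueError("B must be >= 1")
    q = _as_matrix(q)
    z = _as_matrix(z, ncol_hint=0) if z is not None else np.empty((len(y), 0))
    y = np.asarray(y, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    estimates = []
    for _ in range(B):
        idx = _resample_indices(rng, n)
        estimates.append(fit_constrained(q[idx], z[idx], y[idx], init_weights=init_weights))
    if not any(e.converged for e in estimates):
        raise RuntimeError("no bootstrap fit converged")
    return estimates


def average_weights(
    estimates: list[BootstrapEstimate],
    components: list[str] | None = None,
    signal: str = "abs_t",
) -> WQSWeights:
    """Signal-weighted average of bootstrap weight vectors.

    Converged bootstraps whose beta1 has the hypothesised positive sign are
    averaged with signal s_b (|t|, t^2, or a significance indicator); if none
    qualify, all converged bootstraps contribute with s_b = |t|.
    """
    if not estimates:
        raise ValueError("no bootstrap estimates to average")
    if signal not in SIGNALS:
        raise ValueError(f"unknown signal {signal!r}; choose from {SIGNALS}")
    usable = [e for e in estimates if e.converged and e.beta1 > 0]
    if not usable:
        usable = [e for e in estimates if e.converged]
        signal = "abs_t"
    if not usable:
        raise ValueError("no converged bootstrap estimates")
    t = np.array([abs(e.t_stat) for e in usable])
    if signal == "abs_t":
        s = t
    elif signal == "t2":
        s = t**2
    else:
        s = (t > 1.96).astype(float)
    if s.sum() <= 0:
        s = np.ones_like(s)
    W = np.stack([e.w for e in usable])
    w_bar = (s[:, None] * W).sum(axis=0) / s.sum()
    c = W.shape[1]
    if components is None:
        components = [f"c{i}" for i in range(c)]
    return WQSWeights(components=list(components), w=w_bar, B=len(estimates),
                      n_contributing=len(usable))


def compute_wqs(q, weights: WQSWeights) -> np.ndarray:
    """The index: row-wise weighted sum of scored components."""
    if isinstance(q, pd.DataFrame):
        q = q[weights.components]
    return _as_matrix(q) @ weights.w


def fit_validation(
    wqs: np.ndarray,
    z,
    y,
    weights: WQSWeights | None = None,
    spec_name: str = "index",
    mode: str = "quantile",
    weight_mode: str = "estimated",
    provenance: dict | None = None,
) -> WQSFit:
    """Ordinary logistic fit of the validation model on the held-out split.

    Reports OR = exp(beta1) with a 95% Wald CI, the validation log-likelihood
    and AIC with k = 2 + dim(phi) fitted parameters (the weights are
    training-split quantities and are not counted).
    """
    z_names = list(z.columns) if isinstance(z, pd.DataFrame) else [
        f"z{i}" for i in range(_as_matrix(z, 0).shape[1])
    ]
    z = _as_matrix(z, ncol_hint=0)
    wqs = np.asarray(wqs, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = np.column_stack([np.ones(n), wqs, z])
    converged = True
    try:
        glm = _glm_logistic(X, y)
        params, bse, pvals = glm.params, glm.bse, glm.pvalues
        llf = float(glm.llf)
        if not (np.all(np.isfinite(params)) and np.all(np.isfinite(bse))):
            converged = False
    except Exception:
        params = np.zeros(X.shape[1])
        bse = np.full(X.shape[1], np.inf)
        pvals = np.ones(X.shape[1])
        llf = -np.inf
        converged = False

    k = 2 + z.shape[1]
    beta1, se1 = float(params[1]), float(bse[1])
    terms = ["intercept", "ses_index"] + z_names
    coef = pd.DataFrame(
        {
            "term": terms,
            "coef": params,
            "se": bse,
            "odds_ratio": np.exp(params),
            "ci_low": np.exp(params - 1.96 * bse),
            "ci_high": np.exp(params + 1.96 * bse),
            "pvalue": pvals,
        }
    )
    if weights is None:
        weights = WQSWeights(components=["index"], w=np.array([1.0]))
    return WQSFit(
        spec_name=spec_name,
        mode=mode,
        weight_mode=weight_mode,
        weights=weights,
        beta0=float(params[0]),
        beta1=beta1,
        se_beta1=se1,
        phi=dict(zip(z_names, map(float, params[2:]))),
        odds_ratio=float(np.exp(beta1)),
        ci_low=float(np.exp(beta1 - 1.96 * se1)),
        ci_high=float(np.exp(beta1 + 1.96 * se1)),
        pvalue=float(pvals[1]),
        loglik=llf,
        k=k,
        aic=aic(llf, k),
        n_validation=n,
        converged=converged,
        coef_table=coef,
        provenance=provenance or {},
    )


def fit_equal_weights(
    q, z, y, components: list[str] | None = None, **kwargs
) -> WQSFit:
    """Validation fit with every component weighted 1/c (no bootstrap stage)."""
    qm = _as_matrix(q)
    c = qm.shape[1]
    if components is None:
        components = list(q.columns) if isinstance(q, pd.DataFrame) else [
            f"c{i}" for i in range(c)
        ]
    weights = WQSWeights(components=list(components), w=np.full(c, 1.0 / c))
    kwargs.setdefault("weight_mode", "equal")
    return fit_validation(compute_wqs(q, weights), z, y, weights=weights, **kwargs)


def run_wqs(
    individuals: pd.DataFrame,
    area_tables: dict[str, pd.DataFrame],
    spec: IndexSpec,
    options: WQSOptions | None = None,
) -> WQSFit:
    """End-to-end WQS analysis of one index specification.

    Split -> join components across scales -> fit scoring rules on the
    training split and score everyone -> bootstrap-estimate and average the
    weights on the training split (skipped with ``options.equal_weights``) ->
    build the index and fit the validation model on the held-out split.

    Covariate indicator columns with zero variance in the sample (levels not
    present) are dropped before fitting, since their coefficients are not
    identifiable.
    """
    options = options or WQSOptions()
    n = len(individuals)
    split = assembly.make_split(n, fraction=options.fraction, seed=options.split_seed)
    components = assembly.join_components(individuals, area_tables, spec)
    rules = scoring.fit_index_rules(
        components, spec, mode=options.mode, n_quantiles=options.n_quantiles,
        training_mask=split.training,
    )
    q = scoring.score_index(components, spec, rules)
    z = assembly.encode_covariates(individuals)
    dropped = [c for c in z.columns if z[c].std() == 0.0]
    z = z.drop(columns=dropped)
    y = individuals["outcome"].to_numpy(dtype=float)

    tr, va = split.training, ~split.training
    q_tr, z_tr, y_tr = q[tr], z[tr], y[tr]
    q_va, z_va, y_va = q[va], z[va], y[va]

    provenance = {
        "spec": spec.name,
        "n_total": int(n),
        "n_training": int(tr.sum()),
        "split_seed": options.split_seed,
        "fraction": options.fraction,
        "bootstrap_seed": options.bootstrap_seed,
        "B": options.B,
        "n_quantiles": options.n_quantiles,
        "mode": options.mode,
        "signal": options.signal,
        "equal_weights": options.equal_weights,
        "dropped_covariates": dropped,
    }

    if options.equal_weights:
        return fit_equal_weights(
            q_va, z_va, y_va, components=spec.component_names,
            spec_name=spec.name, mode=options.mode, provenance=provenance,
        )
    estimates = bootstrap_weights(
        q_tr, z_tr, y_tr, B=options.B, seed=options.bootstrap_seed
    )
    weights = average_weights(estimates, components=spec.component_names,
                              signal=options.signal)
    return fit_validation(
        compute_wqs(q_va, weights), z_va, y_va, weights=weights,
        spec_name=spec.name, mode=options.mode, weight_mode="estimated",
        provenance=provenance,
    )
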