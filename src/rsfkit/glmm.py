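"""Binomial (logit) mixed models with crossed / nested random intercepts.

The fitter maximizes the Laplace-approximated marginal likelihood:

* inner loop: Newton (penalized IRLS) maximization of the joint
  penalized log-likelihood over fixed effects and random-effect modes,
  which is strictly concave for the Bernoulli-logit family;
* outer loop: bounded quasi-Newton (L-BFGS-B) over the log standard
  deviations of the random-intercept variance components.

The marginal log-likelihood for variance parameters theta is

    l(theta) = l_pen(beta_hat, u_hat) - 1/2 log|Z'WZ + D^-1| - 1/2 log|D|

with D the random-effect covariance (diagonal, one variance per
grouping factor) and W the IRLS weights at the joint mode. This mirrors
the standard Laplace GLMM estimator used throughout the habitat-selection
literature. AIC = -2 logLik + 2 df with df = n fixed effects + n
variance components.

Model structures follow the hypothesis-set naming used for
resource-selection analyses: a generic set (G), spatially adjusted (S:
covariates interacted with the inside/outside-protected-area factor),
temporally adjusted (T: interacted with moon illumination) and
spatio-temporal (ST), each as forage (f), risk (r) or trade-off (fr)
covariate blocks, plus a woody-cover-only null model "0".
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "ModelSpec",
    "DesignMatrices",
    "FitResult",
    "build_model_matrix",
    "fit_glmm",
    "aic",
    "simulate_binomial_mixed",
    "LANDSCAPE_RANDOM",
    "HOMERANGE_RANDOM",
    "MODEL_NAMES",
]

_FORAGE = ("WC", "SVD", "NDVI")
_RISK = ("WC", "ProxW", "TRI")
_ALL = ("WC", "SVD", "NDVI", "ProxW", "TRI")

#: fixed-effect structure per hypothesis model: (covariates, interaction factors)
_STRUCTURES: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "0": (("WC",), ()),
    "Gf": (_FORAGE, ()),
    "Gr": (_RISK, ()),
    "Gfr": (_ALL, ()),
    "Sf": (_FORAGE, ("InOut",)),
    "Sr": (_RISK, ("InOut",)),
    "Sfr": (_ALL, ("InOut",)),
    "Tf": (_FORAGE, ("Moon",)),
    "Tr": (_RISK, ("Moon",)),
    "Tfr": (_ALL, ("Moon",)),
    "STf": (_FORAGE, ("InOut", "Moon")),
    "STr": (_RISK, ("InOut", "Moon")),
    "STfr": (_ALL, ("InOut", "Moon")),
}

MODEL_NAMES = tuple(_STRUCTURES)

#: random-intercept grouping factors by analysis level; "season nested in
#: year" is coded as the two factors year and year x season.
LANDSCAPE_RANDOM = ("area_id", "individual_id")
HOMERANGE_RANDOM = ("area_id", "individual_id", "year", "season_year")


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """One hypothesis-model structure: fixed terms plus random intercepts."""

    name: str
    covariates: tuple[str, ...]
    interactions: tuple[str, ...]
    random_intercepts: tuple[str, ...]

    @classmethod
    def from_name(cls, name: str, level: str = "homerange") -> "ModelSpec":
        if name not in _STRUCTURES:
            raise KeyError(f"unknown model structure {name!r}")
        covs, inter = _STRUCTURES[name]
        random = LANDSCAPE_RANDOM if level == "landscape" else HOMERANGE_RANDOM
        if level == "landscape" and "Moon" in inter:
            raise ValueError(f"model {name!r} is home-range only (Moon term)")
        return cls(name=name, covariates=covs, interactions=inter, random_intercepts=random)

    @property
    def n_fixed(self) -> int:
        k = len(self.covariates)
        return 1 + k + len(self.interactions) * (1 + k)

    def fixed_term_names(self) -> list[str]:
        names = ["(Intercept)", *self.covariates]
        for f in self.interactions:
            names.append(f)
        for f in self.interactions:
            names.extend(f"{c}:{f}" for c in self.covariates)
        return names


@dataclasses.dataclass
class DesignMatrices:
    """Dense fixed-effect design plus sparse random-intercept indicators."""

    X: np.ndarray
    y: np.ndarray
    columns: list[str]
    Z: sparse.csr_matrix
    factors: list[str]
    factor_slices: list[slice]
    factor_levels: dict[str, list]
    scaling: dict[str, tuple[float, float]]
    spec: ModelSpec

    @property
    def n_obs(self) -> int:
        return len(self.y)


def _season_year(table: pd.DataFrame) -> pd.Series:
    return table["year"].astype(str) + ":" + table["season"].astype(str)


def build_model_matrix(
    table: pd.DataFrame,
    spec: ModelSpec,
    scaling: Mapping[str, tuple[float, float]] | None = None,
) -> DesignMatrices:
    """Assemble fixed and random design matrices for a use-availability table.

    Continuous covariates are z-scored over the pooled used+available
    rows (or with externally supplied ``scaling``, e.g. the training
    scaling when scoring held-out data). InOut enters as a 0/1 indicator
    with inside as the reference; Moon as illumination percent / 100.
    """
    for col in spec.covariates:
        if col not in table.columns:
            raise KeyError(f"missing covariate column {col!r}")
    if "InOut" in spec.interactions and "in_out" not in table.columns:
        raise KeyError("missing column 'in_out'")
    if "Moon" in spec.interactions and "moon_pct" not in table.columns:
        raise KeyError("missing column 'moon_pct'")

    n = len(table)
    scale = {}
    zcov = {}
    for c in spec.covariates:
        x = table[c].to_numpy(dtype=float)
        if scaling is not None:
            m, s = scaling[c]
        else:
            m, s = float(x.mean()), float(x.std())
        s = s if s > 0 else 1.0
        scale[c] = (m, s)
        zcov[c] = (x - m) / s

    cols = [np.ones(n)] + [zcov[c] for c in spec.covariates]
    names = ["(Intercept)", *spec.covariates]
    mods = {}
    if "InOut" in spec.interactions:
        mods["InOut"] = (table["in_out"].astype(str) == "outside").to_numpy(dtype=float)
    if "Moon" in spec.interactions:
        mods["Moon"] = table["moon_pct"].to_numpy(dtype=float) / 100.0
    for f in spec.interactions:
        cols.append(mods[f])
        names.append(f)
    for f in spec.interactions:
        for c in spec.covariates:
            cols.append(zcov[c] * mods[f])
            names.append(f"{c}:{f}")
    X = np.column_stack(cols)
    y = table["response"].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("response must be binary 0/1")

    blocks, slices, levels = [], [], {}
    q0 = 0
    for f in spec.random_intercepts:
        if f == "season_year" and f not in table.columns:
            col = _season_year(table)
        elif f not in table.columns:
            raise KeyError(f"missing random-effect column {f!r}")
        else:
            col = table[f]
        codes, lev = pd.factorize(col.astype(str), sort=True)
        q = len(lev)
        blocks.append(
            sparse.csr_matrix(
                (np.ones(n), (np.arange(n), codes)), shape=(n, q)
            )
        )
        slices.append(slice(q0, q0 + q))
        levels[f] = list(lev)
        q0 += q
    Z = sparse.hstack(blocks, format="csr") if blocks else sparse.csr_matrix((n, 0))

    return DesignMatrices(
        X=X, y=y, columns=names, Z=Z, factors=list(spec.random_intercepts),
        factor_slices=slices, factor_levels=levels, scaling=scale, spec=spec,
    )


@dataclasses.dataclass
class FitResult:
    """Fitted GLMM: coefficients, variance components, likelihood, AIC."""

    spec: ModelSpec
    coefficients: pd.DataFrame  # estimate, se, z, p (standardized covariates)
    vcov: np.ndarray
    variance_components: dict[str, float]
    conditional_modes: dict[str, pd.Series]
    loglik: float
    df: int
    n_obs: int
    converged: bool
    boundary: list[str]
    scaling: dict[str, tuple[float, float]]

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.df

    def coef(self, term: str) -> float:
        return float(self.coefficients.loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.coefficients.loc[term, "se"])

    def wald_ci(self, term: str, level: float = 0.95) -> tuple[float, float]:
        zq = norm.ppf(0.5 + level / 2.0)
        est, se = self.coef(term), self.se(term)
        return est - zq * se, est + zq * se

    def raw_coefficients(self) -> pd.DataFrame:
        """Back-transform to the covariates' original (unstandardized) scale.

        Exact affine transform: for z = (x - m)/s a slope b_z becomes
        b_z/s and the intercept (and modulator main effects) absorb
        -b_z m/s. Standard errors transform through the same linear map.
        """
        terms = list(self.coefficients.index)
        p = len(terms)
        T = np.zeros((p, p))
        for j, t in enumerate(terms):
            if t in self.scaling:
                T[j, j] = 1.0 / self.scaling[t][1]
            elif ":" in t:
                cov = t.split(":", 1)[0]
                T[j, j] = 1.0 / self.scaling[cov][1]
            else:
                T[j, j] = 1.0
                suffix = "" if t == "(Intercept)" else f":{t}"
                for i, t2 in enumerate(terms):
                    base = t2[: -len(suffix)] if suffix and t2.endswith(suffix) else (
                        t2 if not suffix else None
                    )
                    if suffix == "" and t2 in self.scaling:
                        m, s = self.scaling[t2]
                        T[j, i] = -m / s
                    elif suffix and base in self.scaling:
                        m, s = self.scaling[base]
                        T[j, i] = -m / s
        est = T @ self.coefficients["estimate"].to_numpy()
        cov = T @ self.vcov @ T.T
        se = np.sqrt(np.diag(cov))
        return pd.DataFrame({"estimate": est, "se": se}, index=terms)

    def to_json(self, path=None) -> str:
        d = {
            "model": self.spec.name,
            "coefficients": self.coefficients.reset_index()
            .rename(columns={"index": "term"})
            .to_dict(orient="records"),
            "variance_components": self.variance_components,
            "loglik": self.loglik,
            "df": self.df,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "boundary": self.boundary,
        }
        s = json.dumps(d, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


# ---------------------------------------------------------------------
# Laplace fitting machinery
# ---------------------------------------------------------------------

_LOG_SD_BOUNDS = (-8.0, 3.0)


def _bernoulli_loglik(y, eta):
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _joint_mode(X, Z, y, prec_vec, beta, u, max_iter=60, tol=1e-10):
    """Newton maximization of the penalized log-likelihood over (beta, u).

    Returns the mode, the u-block Hessian (dense) and the penalized and
    data log-likelihoods at the mode.
    """
    n, p = X.shape
    q = Z.shape[1]

    def pen_ll(beta, u):
        eta = X @ beta + Z @ u
        return _bernoulli_loglik(y, eta) - 0.5 * float(u @ (prec_vec * u)), eta

    ll, eta = pen_ll(beta, u)
    converged = False
    Huu = None
    for _ in range(max_iter):
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        r = y - mu
        gb = X.T @ r
        gu = Z.T @ r - prec_vec * u
        Xw = X * w[:, None]
        A = X.T @ Xw
        Zw = Z.multiply(w[:, None]).tocsr()
        C = (Z.T @ Xw)  # q x p, dense
        Huu = (Zw.T @ Z).toarray() + np.diag(prec_vec)
        H = np.block([[A, np.asarray(C).T], [np.asarray(C), Huu]])
        g = np.concatenate([gb, gu])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # step halving
        t = 1.0
        for _ in range(30):
            nb, nu = beta + t * step[:p], u + t * step[p:]
            nll, neta = pen_ll(nb, nu)
            if nll >= ll - 1e-12:
                break
            t *= 0.5
        improved = nll - ll
        beta, u, eta = nb, nu, neta
        ll = nll
        if abs(improved) < tol * (abs(ll) + 1.0) and float(np.max(np.abs(g))) < 1e-5 * (
            1.0 + abs(ll)
        ):
            converged = True
            break
    # refresh Hessian blocks at the final mode
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    Xw = X * w[:, None]
    A = X.T @ Xw
    Zw = Z.multiply(w[:, None]).tocsr()
    C = np.asarray(Z.T @ Xw)
    Huu = (Zw.T @ Z).toarray() + np.diag(prec_vec)
    ll_data = _bernoulli_loglik(y, eta)
    return beta, u, A, C, Huu, ll, ll_data, converged


def _laplace_loglik(design, theta, state):
    """Profile (beta profiled at the joint mode) Laplace log-likelihood."""
    q = design.Z.shape[1]
    sig2 = np.empty(q)
    for th, sl in zip(theta, design.factor_slices):
        sig2[sl] = np.exp(2.0 * th)
    prec = 1.0 / sig2
    beta, u, A, C, Huu, ll_pen, ll_data, conv = _joint_mode(
        design.X, design.Z, design.y, prec, state["beta"].copy(), state["u"].copy()
    )
    state["beta"], state["u"] = beta, u
    state["inner_converged"] = conv
    sign, logdet = np.linalg.slogdet(Huu)
    if sign <= 0:
        return np.inf, None
    ll = ll_pen - 0.5 * logdet + 0.5 * float(np.sum(np.log(prec)))
    return ll, (beta, u, A, C, Huu)


def fit_glmm(design: DesignMatrices, method: str = "laplace") -> FitResult:
    """Fit the binomial mixed model by Laplace-approximated ML.

    ``method="glm"`` delegates to a plain fixed-effects logistic
    regression (statsmodels) as an external cross-check backend; the
    native Laplace fitter is the default and the tested path.
    """
    if method == "glm":
        return _fit_plain_glm(design)
    if method != "laplace":
        raise ValueError(f"unknown method {method!r}")
    X, y = design.X, design.y
    n, p = X.shape
    m = len(design.factors)
    for f, sl in zip(design.factors, design.factor_slices):
        if sl.stop - sl.start < 1:
            raise ValueError(f"random factor {f!r} has no levels")

    ybar = min(max(y.mean(), 1e-6), 1 - 1e-6)
    state = {
        "beta": np.concatenate([[np.log(ybar / (1 - ybar))], np.zeros(p - 1)]),
        "u": np.zeros(design.Z.shape[1]),
        "inner_converged": False,
    }

    def nll(theta):
        ll, _ = _laplace_loglik(design, theta, state)
        return -ll

    x0 = np.full(m, np.log(0.5))
    res = optimize.minimize(
        nll,
        x0,
        method="L-BFGS-B",
        bounds=[_LOG_SD_BOUNDS] * m,
        options={"ftol": 1e-10, "gtol": 1e-6, "maxiter": 200},
    )
    theta = res.x
    ll, parts = _laplace_loglik(design, theta, state)
    beta, u, A, C, Huu = parts

    # fixed-effect covariance: Schur complement of the u-block
    try:
        HinvC = np.linalg.solve(Huu, C)
        vcov = np.linalg.inv(A - C.T @ HinvC)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(A)
    se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))
    zval = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pval = 2.0 * norm.sf(np.abs(zval))
    coeffs = pd.DataFrame(
        {"estimate": beta, "se": se, "z": zval, "p": pval}, index=design.columns
    )

    sigmas = np.exp(theta)
    boundary = [
        f
        for f, th in zip(design.factors, theta)
        if th <= _LOG_SD_BOUNDS[0] + 1e-3
    ]
    modes = {
        f: pd.Series(u[sl], index=design.factor_levels[f])
        for f, sl in zip(design.factors, design.factor_slices)
    }
    converged = bool(res.success and state["inner_converged"])
    if not converged:
        warnings.warn(
            f"GLMM fit for model {design.spec.name!r} flagged non-convergent: "
            f"{res.message}",
            RuntimeWarning,
        )
    return FitResult(
        spec=design.spec,
        coefficients=coeffs,
        vcov=vcov,
        variance_components={f: float(s**2) for f, s in zip(design.factors, sigmas)},
        conditional_modes=modes,
        loglik=float(ll),
        df=p + m,
        n_obs=n,
        converged=converged,
        boundary=boundary,
        scaling=design.scaling,
    )


def _fit_plain_glm(design: DesignMatrices) -> FitResult:
    import statsmodels.api as sm

    fit = sm.GLM(design.y, design.X, family=sm.families.Binomial()).fit()
    coeffs = pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse,
            "z": fit.tvalues,
            "p": fit.pvalues,
        },
        index=design.columns,
    )
    return FitResult(
        spec=design.spec,
        coefficients=coeffs,
        vcov=np.asarray(fit.cov_params()),
        variance_components={f: 0.0 for f in design.factors},
        conditional_modes={
            f: pd.Series(0.0, index=design.factor_levels[f]) for f in design.factors
        },
        loglik=float(fit.llf),
        df=design.X.shape[1] + len(design.factors),
        n_obs=design.n_obs,
        converged=bool(fit.converged),
        boundary=[],
        scaling=design.scaling,
    )


def aic(fit: FitResult) -> float:
    """AIC = -2 logLik + 2 df; raises for a non-converged fit."""
    if not fit.converged:
        raise ValueError(f"model {fit.spec.name!r} did not converge; AIC undefined")
    return fit.aic


def design_from_frame(
    df: pd.DataFrame,
    fixed: Sequence[str],
    random: Sequence[str],
    name: str = "custom",
    standardize: bool = False,
) -> DesignMatrices:
    """Build design matrices for an arbitrary frame (intercept prepended).

    Bypasses the hypothesis-set structures; used for calibration
    experiments and oracle comparisons on generic simulated data.
    """
    n = len(df)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    scale = {}
    for c in fixed:
        x = df[c].to_numpy(dtype=float)
        if standardize:
            m, s = float(x.mean()), float(x.std()) or 1.0
            scale[c] = (m, s)
            x = (x - m) / s
        cols.append(x)
        names.append(c)
    X = np.column_stack(cols)
    y = df["response"].to_numpy(dtype=float)
    blocks, slices, levels = [], [], {}
    q0 = 0
    for f in random:
        codes, lev = pd.factorize(df[f].astype(str), sort=True)
        q = len(lev)
        blocks.append(sparse.csr_matrix((np.ones(n), (np.arange(n), codes)), shape=(n, q)))
        slices.append(slice(q0, q0 + q))
        levels[f] = list(lev)
        q0 += q
    Z = sparse.hstack(blocks, format="csr") if blocks else sparse.csr_matrix((n, 0))
    spec = ModelSpec(name=name, covariates=tuple(fixed), interactions=(),
                     random_intercepts=tuple(random))
    return DesignMatrices(X=X, y=y, columns=names, Z=Z, factors=list(random),
                          factor_slices=slices, factor_levels=levels,
                          scaling=scale, spec=spec)


# ---------------------------------------------------------------------
# Small self-contained simulator for calibration experiments
# ---------------------------------------------------------------------

def simulate_binomial_mixed(
    n: int,
    beta: Sequence[float],
    group_sizes: Mapping[str, int],
    sigmas: Mapping[str, float],
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate Bernoulli data from a random-intercept logistic model.

    Covariates are iid standard normal named x1..x{k-1} (beta[0] is the
    intercept); each grouping factor assigns observations uniformly to
    its levels with a N(0, sigma^2) intercept per level.
    """
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)
    k = len(beta) - 1
    X = rng.standard_normal((n, k))
    eta = beta[0] + X @ beta[1:]
    df = pd.DataFrame(X, columns=[f"x{i + 1}" for i in range(k)])
    for f, g in group_sizes.items():
        idx = rng.integers(0, g, size=n)
        u = rng.normal(0.0, sigmas[f], size=g)
        eta = eta + u[idx]
        df[f] = [f"{f}{j}" for j in idx]
    df["response"] = (rng.uniform(size=n) < expit(eta)).astype(int)
    return df
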