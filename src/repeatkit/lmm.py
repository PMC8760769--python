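"""Gaussian linear mixed models by restricted maximum likelihood.

Two random-effect structures are supported, matching what repeated-measures
repeatability analyses need:

* a random intercept per individual (the variance-decomposition model behind
  repeatability, R = v_between / (v_between + v_within)); and
* a random intercept plus a categorical random slope with fully unstructured
  covariance (the structure used when each individual's response profile
  over sampling times is allowed its own shape).

Estimation profiles the fixed effects and the residual scale out of the
restricted likelihood. For the random-intercept model the criterion is a
smooth function of the single variance ratio lambda = v_between / v_within
and is minimised by a bracketed scalar search; for the unstructured model
the relative covariance factor is optimised on the log-Cholesky scale with
multiple restarts (small studies make singular fits likely).

Inference for fixed-effect contrasts uses the Satterthwaite approximation:
df = 2 (c' C(theta) c)^2 / Var(c' C(theta) c), where C(theta) is the
fixed-effect covariance at the variance parameters theta and the variance in
the denominator comes from the delta method through the asymptotic
covariance of theta (inverse observed information of the restricted
likelihood, obtained by finite differences). Estimated marginal means are
predictions on a reference grid crossing all categorical fixed factors with
equal weights and holding continuous covariates at their in-model means.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .errors import ConvergenceError, DegenerateDataError, DesignError

__all__ = [
    "FixedTerm", "continuous", "categorical", "RandomStructure", "ModelSpec",
    "model_spec_from_dict",
    "FittedLMM", "ContrastResult", "EMMSet",
    "fit_reml", "satterthwaite", "emmeans", "pairwise_contrasts",
    "fixed_effects_table",
]


# ----------------------------------------------------------------------
# model specification

@dataclass(frozen=True)
class FixedTerm:
    """One fixed-effect term: a continuous covariate or a categorical factor.

    Continuous covariates are mean-centered by default (the centering mean is
    learned from the analysis rows). Categorical factors use treatment
    contrasts with ``reference`` as the baseline level (first level in sorted
    order if not given).
    """

    name: str
    kind: str = "continuous"          # "continuous" | "categorical"
    center: bool = True
    reference: Optional[str] = None


def continuous(name: str, center: bool = True) -> FixedTerm:
    return FixedTerm(name, "continuous", center=center)


def categorical(name: str, reference: Optional[str] = None) -> FixedTerm:
    return FixedTerm(name, "categorical", reference=reference)


@dataclass(frozen=True)
class RandomStructure:
    """Random-effect structure per grouping level.

    ``intercept``: one random intercept per group. ``slope``: intercept plus
    per-level offsets of a categorical ``factor``, with fully unstructured
    (q x q) covariance, q = 1 + (levels - 1).
    """

    kind: str = "intercept"           # "intercept" | "slope"
    factor: Optional[str] = None


@dataclass(frozen=True)
class ModelSpec:
    """Response, transform, fixed terms, grouping and random structure."""

    response: str
    transform: str = "identity"       # "identity" | "log"
    fixed: Tuple[FixedTerm, ...] = ()
    interactions: Tuple[Tuple[str, str], ...] = ()
    group: str = "individual_id"
    random: RandomStructure = RandomStructure("intercept")

    def __post_init__(self):
        if self.transform not in ("identity", "log"):
            raise DesignError(f"unknown transform {self.transform!r}")
        if self.random.kind not in ("intercept", "slope"):
            raise DesignError(f"unknown random structure {self.random.kind!r}")
        if self.random.kind == "slope" and not self.random.factor:
            raise DesignError("random slope structure requires a factor name")
        object.__setattr__(self, "fixed", tuple(self.fixed))
        object.__setattr__(self, "interactions",
                           tuple(tuple(p) for p in self.interactions))


def model_spec_from_dict(d: dict) -> ModelSpec:
    """Build a ModelSpec from a YAML-style mapping.

    Expected shape::

        response: cortisol_resp_2h
        transform: log                  # optional, default identity
        group: individual_id            # optional
        fixed:                          # optional
          - {name: rank_index, kind: continuous, center: true}
          - {name: measurement, kind: categorical, reference: "2"}
        interactions:                   # optional
          - [sampling_time, rank_index]
        random: {kind: slope, factor: sampling_time}   # optional
    """
    if "response" not in d:
        raise DesignError("model config needs a 'response' key")
    fixed = []
    for item in d.get("fixed", []):
        if isinstance(item, str):
            item = {"name": item}
        fixed.append(FixedTerm(
            name=item["name"],
            kind=item.get("kind", "continuous"),
            center=bool(item.get("center", True)),
            reference=item.get("reference"),
        ))
    rnd = d.get("random", {})
    if isinstance(rnd, str):
        rnd = {"kind": rnd}
    return ModelSpec(
        response=d["response"],
        transform=d.get("transform", "identity"),
        fixed=tuple(fixed),
        interactions=tuple(tuple(p) for p in d.get("interactions", [])),
        group=d.get("group", "individual_id"),
        random=RandomStructure(kind=rnd.get("kind", "intercept"),
                               factor=rnd.get("factor")),
    )


# ----------------------------------------------------------------------
# design-matrix construction

class _TermEncoder:
    """Learned encoding of one term: centering mean or factor levels."""

    def __init__(self, term: FixedTerm):
        self.term = term
        self.mean_: Optional[float] = None
        self.levels_: Optional[List[str]] = None

    def fit(self, values: pd.Series) -> "_TermEncoder":
        if values.isna().any():
            raise ValueError(
                f"missing values in column {self.term.name!r}; repeatkit "
                "does not drop rows silently"
            )
        if self.term.kind == "continuous":
            self.mean_ = float(pd.to_numeric(values).mean())
        else:
            levels = sorted(values.astype(str).unique())
            ref = self.term.reference
            if ref is not None:
                ref = str(ref)
                if ref not in levels:
                    raise DesignError(
                        f"reference level {ref!r} not found in factor "
                        f"{self.term.name!r} (levels: {levels})"
                    )
                levels = [ref] + [l for l in levels if l != ref]
            self.levels_ = levels
        return self

    def encode(self, values: pd.Series) -> Tuple[List[str], np.ndarray]:
        """Columns for this term (excluding the intercept)."""
        name = self.term.name
        if self.term.kind == "continuous":
            x = pd.to_numeric(values).to_numpy(dtype=float)
            if self.term.center:
                x = x - self.mean_
            return [name], x[:, None]
        vals = values.astype(str).to_numpy()
        unknown = set(vals) - set(self.levels_)
        if unknown:
            raise DesignError(
                f"factor {name!r}: unknown level(s) {sorted(unknown)}"
            )
        cols, names = [], []
        for level in self.levels_[1:]:
            names.append(f"{name}[{level}]")
            cols.append((vals == level).astype(float))
        return names, np.column_stack(cols) if cols else np.empty((len(vals), 0))


class DesignInfo:
    """Fixed-effect design builder learned from the analysis rows."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.encoders: Dict[str, _TermEncoder] = {}
        self.column_names: List[str] = []

    def fit(self, df: pd.DataFrame) -> "DesignInfo":
        for term in self.spec.fixed:
            if term.name not in df.columns:
                raise DesignError(f"column {term.name!r} not in data")
            self.encoders[term.name] = _TermEncoder(term).fit(df[term.name])
        for a, b in self.spec.interactions:
            for nm in (a, b):
                if nm not in self.encoders:
                    raise DesignError(
                        f"interaction term {nm!r} must also appear as a "
                        "main fixed effect"
                    )
        self.column_names = self._matrix(df)[0]
        return self

    def _matrix(self, df: pd.DataFrame) -> Tuple[List[str], np.ndarray]:
        n = len(df)
        names = ["(Intercept)"]
        cols = [np.ones(n)]
        encoded: Dict[str, Tuple[List[str], np.ndarray]] = {}
        for term in self.spec.fixed:
            nm, mat = self.encoders[term.name].encode(df[term.name])
            encoded[term.name] = (nm, mat)
            names.extend(nm)
            cols.append(mat)
        for a, b in self.spec.interactions:
            na, ma = encoded[a]
            nb, mb = encoded[b]
            for i, ani in enumerate(na):
                for j, bnj in enumerate(nb):
                    names.append(f"{ani}:{bnj}")
                    cols.append((ma[:, i] * mb[:, j])[:, None])
        X = np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols])
        return names, X

    def matrix(self, df: pd.DataFrame) -> np.ndarray:
        names, X = self._matrix(df)
        return X

    def levels(self, factor: str) -> List[str]:
        enc = self.encoders.get(factor)
        if enc is None or enc.levels_ is None:
            raise DesignError(f"{factor!r} is not a categorical fixed effect")
        return list(enc.levels_)

    def categorical_terms(self) -> List[str]:
        return [t.name for t in self.spec.fixed if t.kind == "categorical"]

    def covariate_means(self) -> Dict[str, float]:
        return {t.name: self.encoders[t.name].mean_
                for t in self.spec.fixed if t.kind == "continuous"}


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    q, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        aliased = [names[j] for j in piv[rank:]]
        raise DesignError(
            f"fixed design is rank deficient; aliased column(s): {aliased}"
        )


# ----------------------------------------------------------------------
# fitted model container

@dataclass
class ContrastResult:
    """A single fixed-effect contrast with Satterthwaite inference."""

    name: str
    estimate: float
    se: float
    df: float
    t_value: float
    p_value: float


@dataclass
class FittedLMM:
    """A converged (or flagged) REML fit."""

    spec: ModelSpec
    beta: pd.Series
    se_beta: pd.Series
    vcov_beta: np.ndarray
    G: np.ndarray                 # (q, q) random-effect covariance
    v_within: float
    loglik_reml: float
    converged: bool
    boundary: bool                # a variance component at / near zero
    n_obs: int
    n_groups: int
    column_names: List[str]
    design: DesignInfo
    _X: np.ndarray = field(repr=False, default=None)
    _y: np.ndarray = field(repr=False, default=None)
    _groups: np.ndarray = field(repr=False, default=None)
    _Z: Optional[np.ndarray] = field(repr=False, default=None)
    _Lambda: Optional[np.ndarray] = field(repr=False, default=None)
    _vcov_theta: Optional[np.ndarray] = field(repr=False, default=None)

    # -- convenience -----------------------------------------------------
    @property
    def v_between(self) -> float:
        """Between-group variance: the random-intercept variance G[0, 0]."""
        return float(self.G[0, 0])

    @property
    def q_random(self) -> int:
        return self.G.shape[0]

    @property
    def theta(self) -> np.ndarray:
        """Natural-scale variance parameters: vech(G) then v_within."""
        q = self.q_random
        tri = [self.G[i, j] for i in range(q) for j in range(i + 1)]
        return np.array(tri + [self.v_within])

    # -- full-scale GLS pieces, as functions of theta --------------------
    def _G_from_theta(self, theta: np.ndarray) -> Tuple[np.ndarray, float]:
        q = self.q_random
        G = np.zeros((q, q))
        k = 0
        for i in range(q):
            for j in range(i + 1):
                G[i, j] = G[j, i] = theta[k]
                k += 1
        return G, float(theta[-1])

    def _group_blocks(self):
        order = np.argsort(self._groups, kind="stable")
        g = self._groups[order]
        bounds = np.flatnonzero(np.r_[True, g[1:] != g[:-1], True])
        return order, bounds

    def _gls(self, theta: np.ndarray):
        """(A, b, q, logdetV) at full-scale variance parameters theta."""
        G, s2 = self._G_from_theta(theta)
        X, y, Z = self._X, self._y, self._Z
        p = X.shape[1]
        A = np.zeros((p, p))
        bvec = np.zeros(p)
        quad = 0.0
        logdet = 0.0
        order, bounds = self._group_blocks()
        for k in range(len(bounds) - 1):
            idx = order[bounds[k]:bounds[k + 1]]
            Xi, yi = X[idx], y[idx]
            Zi = Z[idx] if Z is not None else np.ones((len(idx), 1))
            Vi = Zi @ G @ Zi.T + s2 * np.eye(len(idx))
            c, low = linalg.cho_factor(Vi, lower=True)
            logdet += 2.0 * np.log(np.diag(c)).sum()
            ViX = linalg.cho_solve((c, low), Xi)
            Viy = linalg.cho_solve((c, low), yi)
            A += Xi.T @ ViX
            bvec += Xi.T @ Viy
            quad += yi @ Viy
        return A, bvec, quad, logdet

    def neg2_reml(self, theta: np.ndarray) -> float:
        """-2 restricted log-likelihood at natural-scale theta (full scale)."""
        A, bvec, quad, logdet = self._gls(theta)
        cA, lowA = linalg.cho_factor(A)
        beta = linalg.cho_solve((cA, lowA), bvec)
        ypy = quad - bvec @ beta
        n, p = self._X.shape
        return (logdet + 2.0 * np.log(np.diag(cA)).sum() + ypy
                + (n - p) * np.log(2.0 * np.pi))

    def se2_of_contrast(self, cvec: np.ndarray, theta: np.ndarray) -> float:
        A, _, _, _ = self._gls(theta)
        return float(cvec @ linalg.solve(A, cvec, assume_a="pos"))

    def vcov_theta(self) -> np.ndarray:
        """Asymptotic covariance of theta: inverse observed REML information."""
        if self._vcov_theta is None:
            H = _num_hessian(self.neg2_reml, self.theta)
            self._vcov_theta = 2.0 * linalg.inv(H)
        return self._vcov_theta

    # -- Cholesky-scale parameterization (variance parameters as the
    # relative covariance factor Lambda plus sigma). Satterthwaite df is
    # invariant to smooth reparameterization, but at a rank-deficient G the
    # information on this scale keeps usable curvature where the natural
    # (vech G) scale does not, so slope models differentiate here.
    @property
    def phi(self) -> np.ndarray:
        if self._Lambda is None:
            raise linalg.LinAlgError("no Cholesky-scale parameters stored")
        q = self.q_random
        tri = [self._Lambda[i, j] for i in range(q) for j in range(i + 1)]
        return np.array(tri + [np.sqrt(self.v_within)])

    def _theta_from_phi(self, phi: np.ndarray) -> np.ndarray:
        q = self.q_random
        L = np.zeros((q, q))
        k = 0
        for i in range(q):
            for j in range(i + 1):
                L[i, j] = phi[k]
                k += 1
        sigma2 = float(phi[-1]) ** 2
        G = sigma2 * (L @ L.T)
        tri = [G[i, j] for i in range(q) for j in range(i + 1)]
        return np.array(tri + [sigma2])

    def neg2_reml_phi(self, phi: np.ndarray) -> float:
        return self.neg2_reml(self._theta_from_phi(phi))

    def se2_of_contrast_phi(self, cvec: np.ndarray, phi: np.ndarray) -> float:
        return self.se2_of_contrast(cvec, self._theta_from_phi(phi))

    def vcov_phi(self) -> np.ndarray:
        H = _num_hessian(self.neg2_reml_phi, self.phi)
        try:
            return 2.0 * linalg.inv(H)
        except linalg.LinAlgError:
            return 2.0 * linalg.pinvh(H)


def _num_hessian(f, x: np.ndarray, rel: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian with per-coordinate relative steps.

    The step floor scales with the overall parameter magnitude so that
    variance parameters far from unit scale (e.g. raw-concentration models)
    keep usable finite-difference resolution.
    """
    x = np.asarray(x, dtype=float)
    floor = rel * max(1e-3, float(np.abs(x).max()) * 1e-2)
    h = np.maximum(np.abs(x) * rel, floor)
    m = len(x)
    H = np.empty((m, m))
    f0 = f(x)
    for i in range(m):
        ei = np.zeros(m); ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i):
            ej = np.zeros(m); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej)
                - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


# ----------------------------------------------------------------------
# random-intercept REML: profiled scalar search

class InterceptREMLWorkspace:
    """Sufficient statistics for repeated random-intercept REML fits.

    The fixed design and grouping are fixed; :meth:`fit_y` refits for a new
    response vector, which is what parametric bootstrap and residual
    permutation need. The profiled criterion depends only on the variance
    ratio lambda = v_between / v_within, evaluated in O(G p^2) via the
    Woodbury identity per group.
    """

    _T_LO, _T_HI = -30.0, 30.0

    def __init__(self, X: np.ndarray, groups: np.ndarray):
        self.X = np.asarray(X, dtype=float)
        self.groups = np.asarray(groups)
        self.n, self.p = self.X.shape
        self.G = int(self.groups.max()) + 1
        self.n_i = np.bincount(self.groups, minlength=self.G).astype(float)
        if (self.n_i == 0).any():
            keep = self.n_i > 0   # re-code empty group levels away
            code = np.cumsum(keep) - 1
            self.groups = code[self.groups]
            self.G = int(keep.sum())
            self.n_i = np.bincount(self.groups, minlength=self.G).astype(float)
        self.Sx = np.column_stack([
            np.bincount(self.groups, weights=self.X[:, j], minlength=self.G)
            for j in range(self.p)
        ])
        self.XtX = self.X.T @ self.X

    # -- per-response pieces -------------------------------------------
    def _stats(self, y: np.ndarray):
        Sy = np.bincount(self.groups, weights=y, minlength=self.G)
        return self.X.T @ y, float(y @ y), Sy

    def _crit(self, lam: float, Xty, yty, Sy):
        """Profiled -2 restricted log-likelihood at variance ratio lam."""
        w = lam / (1.0 + self.n_i * lam) if lam > 0 else np.zeros(self.G)
        A = self.XtX - (self.Sx * w[:, None]).T @ self.Sx
        b = Xty - self.Sx.T @ (w * Sy)
        quad = yty - w @ Sy ** 2
        if self.p == 1:                      # scalar fast path
            a00 = A[0, 0]
            beta = b / a00
            rss = quad - b[0] * beta[0]
            logdetA = np.log(a00)
        else:
            cA, low = linalg.cho_factor(A)
            beta = linalg.cho_solve((cA, low), b)
            rss = quad - b @ beta
            logdetA = 2.0 * np.log(np.diag(cA)).sum()
        dfres = self.n - self.p
        rss = max(rss, 1e-300)
        s2 = rss / dfres
        crit = (np.log1p(self.n_i * lam).sum()
                + logdetA
                + dfres * (1.0 + np.log(2.0 * np.pi * s2)))
        return crit, beta, s2, A

    def fit_y(self, y: np.ndarray):
        """REML fit for response y.

        Returns dict with v_between, v_within, beta, vcov_beta_unscaled
        (A(lambda)^-1, multiply by s2 for the covariance), loglik, boundary.
        """
        y = np.asarray(y, dtype=float)
        if float(np.var(y)) <= 1e-300:
            raise DegenerateDataError(
                "response has zero total variance; variance components "
                "are not identifiable"
            )
        Xty, yty, Sy = self._stats(y)

        def crit_t(t):
            return self._crit(np.exp(t), Xty, yty, Sy)[0]

        ts = np.linspace(self._T_LO, self._T_HI, 25)
        vals = [crit_t(t) for t in ts]
        k = int(np.argmin(vals))
        if k == len(ts) - 1:
            # optimum running to lambda -> infinity: responses (after fixed
            # effects) constant within every group, v_within at the boundary
            if self._within_rss(y) <= 1e-12 * yty + 1e-300:
                return self._fit_collapsed(y)
        lo = ts[max(0, k - 1)]
        hi = ts[min(len(ts) - 1, k + 1)]
        res = optimize.minimize_scalar(
            crit_t, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        lam = float(np.exp(res.x))
        crit0 = self._crit(0.0, Xty, yty, Sy)[0]
        boundary = False
        if crit0 <= res.fun or res.x <= self._T_LO + 1e-6:
            lam, boundary = 0.0, True
        crit, beta, s2, A = self._crit(lam, Xty, yty, Sy)
        return {
            "v_between": s2 * lam,
            "v_within": s2,
            "beta": beta,
            "A": A,                      # X' V0^-1 X at the optimum
            "loglik": -0.5 * crit,
            "boundary": boundary,
            "converged": True,
        }

    def _within_rss(self, y: np.ndarray) -> float:
        """Residual SS of within-group-centered y on within-group-centered X."""
        ybar = np.bincount(self.groups, weights=y, minlength=self.G) / self.n_i
        yc = y - ybar[self.groups]
        Xc = self.X - (self.Sx / self.n_i[:, None])[self.groups]
        coef, rss, rank, sv = np.linalg.lstsq(Xc, yc, rcond=None)
        resid = yc - Xc @ coef
        return float(resid @ resid)

    def _fit_collapsed(self, y: np.ndarray):
        """v_within -> 0: REML on the group-mean regression."""
        ybar = np.bincount(self.groups, weights=y, minlength=self.G) / self.n_i
        Xbar = self.Sx / self.n_i[:, None]
        coef, _, rank, _ = np.linalg.lstsq(Xbar, ybar, rcond=None)
        resid = ybar - Xbar @ coef
        dof = max(self.G - rank, 1)
        v_b = float(resid @ resid) / dof
        A = Xbar.T @ Xbar / max(v_b, 1e-300)
        return {
            "v_between": v_b,
            "v_within": 0.0,
            "beta": coef,
            "A": A * 1.0,   # already at full scale; flagged via v_within=0
            "loglik": np.nan,
            "boundary": True,
            "converged": True,
            "_collapsed": True,
        }


def _fit_intercept_model(X, y, groups, spec, design, names) -> FittedLMM:
    work = InterceptREMLWorkspace(X, groups)
    out = work.fit_y(y)
    s2 = out["v_within"]
    if out.get("_collapsed"):
        vcov_beta = linalg.inv(out["A"])
        loglik = out["loglik"]
    else:
        vcov_beta = s2 * linalg.inv(out["A"])
        loglik = out["loglik"]
    se = np.sqrt(np.diag(vcov_beta))
    return FittedLMM(
        spec=spec,
        beta=pd.Series(out["beta"], index=names),
        se_beta=pd.Series(se, index=names),
        vcov_beta=vcov_beta,
        G=np.array([[out["v_between"]]]),
        v_within=s2,
        loglik_reml=loglik,
        converged=out["converged"],
        boundary=out["boundary"],
        n_obs=len(y),
        n_groups=work.G,
        column_names=list(names),
        design=design,
        _X=X, _y=y, _groups=work.groups, _Z=None,
    )


# ----------------------------------------------------------------------
# unstructured random intercept + slope: log-Cholesky optimisation

def _chol_from_logchol(theta: np.ndarray, q: int) -> np.ndarray:
    L = np.zeros((q, q))
    k = 0
    for i in range(q):
        for j in range(i + 1):
            L[i, j] = np.exp(theta[k]) if i == j else theta[k]
            k += 1
    return L


def _fit_slope_model(X, y, groups, Z, spec, design, names,
                     n_restarts: int = 5, random_state: int = 0) -> FittedLMM:
    n, p = X.shape
    q = Z.shape[1]
    npar = q * (q + 1) // 2
    order = np.argsort(groups, kind="stable")
    g = groups[order]
    bounds = np.flatnonzero(np.r_[True, g[1:] != g[:-1], True])
    blocks = [order[bounds[k]:bounds[k + 1]] for k in range(len(bounds) - 1)]
    Xb = [X[idx] for idx in blocks]
    yb = [y[idx] for idx in blocks]
    Zb = [Z[idx] for idx in blocks]
    dfres = n - p

    # balanced fast path: all groups share block size and Z pattern, so one
    # m x m factorisation serves every group
    balanced = (len({len(idx) for idx in blocks}) == 1
                and all(np.array_equal(Zi, Zb[0]) for Zi in Zb[1:]))
    if balanced:
        Xs = np.stack(Xb)            # (G, m, p)
        ys = np.stack(yb)            # (G, m)
        Z0 = Zb[0]                   # (m, q)
        m = Z0.shape[0]
        nblocks = len(blocks)

    def _gls_pieces(Gamma):
        """(A, bvec, quad, logdet) at relative covariance Gamma, or None."""
        if balanced:
            V0 = Z0 @ Gamma @ Z0.T + np.eye(m)
            try:
                c = np.linalg.cholesky(V0)
            except np.linalg.LinAlgError:
                return None
            W = linalg.cho_solve((c, True), np.eye(m))
            logdet = nblocks * 2.0 * np.log(np.diag(c)).sum()
            WX = np.einsum("mn,gnp->gmp", W, Xs)
            A = np.einsum("gmp,gmq->pq", Xs, WX)
            bvec = np.einsum("gmp,gm->p", WX, ys)
            quad = float(np.einsum("gm,mn,gn->", ys, W, ys))
            return A, bvec, quad, logdet
        A = np.zeros((p, p))
        bvec = np.zeros(p)
        quad = 0.0
        logdet = 0.0
        for Xi, yi, Zi in zip(Xb, yb, Zb):
            V0 = Zi @ Gamma @ Zi.T + np.eye(len(yi))
            try:
                c, low = linalg.cho_factor(V0, lower=True)
            except linalg.LinAlgError:
                return None
            logdet += 2.0 * np.log(np.diag(c)).sum()
            A += Xi.T @ linalg.cho_solve((c, low), Xi)
            bvec += Xi.T @ linalg.cho_solve((c, low), yi)
            quad += yi @ linalg.cho_solve((c, low), yi)
        return A, bvec, quad, logdet

    def crit(theta):
        L = _chol_from_logchol(theta, q)
        pieces = _gls_pieces(L @ L.T)
        if pieces is None:
            return np.inf
        A, bvec, quad, logdet = pieces
        try:
            cA, lowA = linalg.cho_factor(A)
        except linalg.LinAlgError:
            return np.inf
        beta = linalg.cho_solve((cA, lowA), bvec)
        rss = max(quad - bvec @ beta, 1e-300)
        s2 = rss / dfres
        return (logdet + 2.0 * np.log(np.diag(cA)).sum()
                + dfres * (1.0 + np.log(2.0 * np.pi * s2)))

    # starting value from the intercept-only fit of the same design
    work = InterceptREMLWorkspace(X, groups)
    base = work.fit_y(y)
    lam0 = base["v_between"] / max(base["v_within"], 1e-12)
    d0 = 0.5 * np.log(max(lam0, 1e-3))
    theta0 = np.zeros(npar)
    k = 0
    for i in range(q):
        for j in range(i + 1):
            if i == j:
                theta0[k] = d0
            k += 1

    rng = np.random.default_rng(random_state)
    best = None
    starts = [theta0] + [theta0 + rng.normal(0, 0.7, size=npar)
                         for _ in range(max(n_restarts - 1, 0))]
    for x0 in starts:
        res = optimize.minimize(
            crit, x0, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-10,
                     "maxiter": 4000 * npar, "maxfev": 4000 * npar},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("random-slope REML failed from all starts")
    converged = bool(best.success) and np.isfinite(best.fun)

    theta = best.x
    L = _chol_from_logchol(theta, q)
    Gamma = L @ L.T
    A, bvec, quad, logdet = _gls_pieces(Gamma)
    beta = linalg.solve(A, bvec, assume_a="pos")
    rss = max(quad - bvec @ beta, 1e-300)
    s2 = rss / dfres
    vcov_beta = s2 * linalg.inv(A)
    scale = np.sqrt(np.trace(Gamma) / q) if np.trace(Gamma) > 0 else 0.0
    boundary = bool((np.diag(L) < 1e-5 * max(scale, 1e-8)).any())
    if not converged:
        warnings.warn("random-slope REML did not report convergence; "
                      "estimates returned with converged=False")

    return FittedLMM(
        spec=spec,
        beta=pd.Series(beta, index=names),
        se_beta=pd.Series(np.sqrt(np.diag(vcov_beta)), index=names),
        vcov_beta=vcov_beta,
        G=s2 * Gamma,
        v_within=s2,
        loglik_reml=-0.5 * best.fun,
        converged=converged,
        boundary=boundary,
        n_obs=n,
        n_groups=len(blocks),
        column_names=list(names),
        design=design,
        _X=X, _y=y, _groups=groups, _Z=Z, _Lambda=L,
    )


# ----------------------------------------------------------------------
# public fitting interface

def _response_vector(df: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    if spec.response not in df.columns:
        raise DesignError(f"response column {spec.response!r} not in data")
    y = pd.to_numeric(df[spec.response])
    if y.isna().any():
        raise ValueError(
            f"missing values in response {spec.response!r}; repeatkit does "
            "not drop rows silently"
        )
    y = y.to_numpy(dtype=float)
    if spec.transform == "log":
        if (y <= 0).any():
            raise ValueError(
                f"log transform requested but {spec.response!r} has "
                "non-positive values"
            )
        y = np.log(y)
    return y


def _group_codes(df: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    if spec.group not in df.columns:
        raise DesignError(f"grouping column {spec.group!r} not in data")
    codes, uniques = pd.factorize(df[spec.group], sort=True)
    if len(uniques) < 2:
        raise DesignError("grouping variable must have at least 2 levels")
    return codes.astype(np.int64)


def fit_reml(df: pd.DataFrame, spec: ModelSpec,
             n_restarts: int = 5, random_state: int = 0) -> FittedLMM:
    """Fit a Gaussian mixed model by REML.

    Fixed effects are profiled out of the restricted likelihood; variance
    estimates are truncated at the zero boundary and boundary fits are
    flagged, not rejected. Raises :class:`DesignError` for rank-deficient
    designs (naming the aliased columns) and :class:`DegenerateDataError`
    when the response carries no variance.
    """
    y = _response_vector(df, spec)
    design = DesignInfo(spec).fit(df)
    X = design.matrix(df)
    _check_rank(X, design.column_names)
    groups = _group_codes(df, spec)

    if spec.random.kind == "intercept":
        return _fit_intercept_model(X, y, groups, spec, design,
                                    design.column_names)

    factor = spec.random.factor
    enc = design.encoders.get(factor)
    if enc is None or enc.levels_ is None:
        enc = _TermEncoder(categorical(factor)).fit(df[factor])
    _, dummies = enc.encode(df[factor])
    Z = np.column_stack([np.ones(len(df)), dummies])
    return _fit_slope_model(X, y, groups, Z, spec, design,
                            design.column_names,
                            n_restarts=n_restarts, random_state=random_state)


# ----------------------------------------------------------------------
# Satterthwaite inference

def satterthwaite(fit: FittedLMM, contrast: np.ndarray,
                  name: str = "contrast") -> ContrastResult:
    """t-test of a fixed-effect contrast with Satterthwaite df.

    df = 2 (se^2)^2 / Var(se^2), with Var(se^2) from the delta method
    through the asymptotic covariance of the variance parameters. At a
    boundary fit (zero variance component) the information matrix is
    singular; the residual df ``n - p`` is used instead, with a warning.
    """
    c = np.asarray(contrast, dtype=float)
    if c.shape != (len(fit.beta),):
        raise DesignError(
            f"contrast has length {c.shape}, expected {len(fit.beta)}"
        )
    est = float(c @ fit.beta.to_numpy())
    se2 = float(c @ fit.vcov_beta @ c)
    se = np.sqrt(se2)
    dfres = fit.n_obs - len(fit.beta)

    # At an exact zero random-intercept variance the model collapses to
    # ordinary regression and the residual df is the honest answer; for
    # richer structures the information matrix is attempted even at
    # near-singular fits, as a rank-deficient G rarely kills the curvature
    # in vech(G) coordinates.
    attempt = fit.v_within > 0 and (fit.q_random > 1 or fit.v_between > 0)
    df_val = None
    if attempt:
        try:
            if fit.q_random > 1 and fit._Lambda is not None:
                theta = fit.phi
                Vt = fit.vcov_phi()
                se2_fun = fit.se2_of_contrast_phi
            else:
                theta = fit.theta
                Vt = fit.vcov_theta()
                se2_fun = fit.se2_of_contrast
            floor = 1e-4 * max(1e-3, float(np.abs(theta).max()) * 1e-2)
            h = np.maximum(np.abs(theta) * 1e-4, floor)
            grad = np.empty_like(theta)
            for j in range(len(theta)):
                ej = np.zeros(len(theta)); ej[j] = h[j]
                grad[j] = (se2_fun(c, theta + ej)
                           - se2_fun(c, theta - ej)) / (2 * h[j])
            denom = float(grad @ Vt @ grad)
            if np.isfinite(denom) and denom > 0:
                df_val = 2.0 * se2 ** 2 / denom
        except linalg.LinAlgError:
            df_val = None
    if df_val is None or not np.isfinite(df_val) or df_val <= 0:
        warnings.warn(
            "Satterthwaite information singular (boundary fit?); "
            f"falling back to residual df = {dfres}"
        )
        df_val = float(dfres)
    t = est / se if se > 0 else np.inf * np.sign(est)
    p = float(2.0 * stats.t.sf(abs(t), df_val)) if np.isfinite(t) else 0.0
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return ContrastResult(name=name, estimate=est, se=se,
                          df=float(df_val), t_value=float(t), p_value=p)


def fixed_effects_table(fit: FittedLMM) -> pd.DataFrame:
    """Per-coefficient estimates with Satterthwaite t-tests (model summary)."""
    rows = []
    p = len(fit.beta)
    for k, nm in enumerate(fit.column_names):
        c = np.zeros(p); c[k] = 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = satterthwaite(fit, c, name=nm)
        rows.append((nm, r.estimate, r.se, r.df, r.t_value, r.p_value))
    return pd.DataFrame(
        rows, columns=["term", "estimate", "se", "df", "t_value", "p_value"]
    )


# ----------------------------------------------------------------------
# estimated marginal means

@dataclass
class EMMSet:
    """Marginal means of one factor over an equally weighted reference grid."""

    factor: str
    levels: List[str]
    emmean: np.ndarray
    se: np.ndarray
    L: np.ndarray                  # (levels, p) averaged design vectors
    grid_description: str
    fit: FittedLMM = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "level": self.levels, "emmean": self.emmean, "se": self.se,
        })


def emmeans(fit: FittedLMM, factor: str) -> EMMSet:
    """Estimated marginal means for the levels of a categorical fixed effect.

    The reference grid crosses the levels of every categorical fixed factor
    with equal weights; continuous covariates sit at their in-model means
    (i.e. zero on the centered scale). Each level's EMM is the average
    prediction over the grid cells at that level.
    """
    design = fit.design
    cat_terms = design.categorical_terms()
    if factor not in cat_terms:
        raise DesignError(
            f"{factor!r} is not a categorical fixed effect of this model"
        )
    level_sets = {t: design.levels(t) for t in cat_terms}
    means = design.covariate_means()

    rows = []
    for combo in itertools.product(*[level_sets[t] for t in cat_terms]):
        row = dict(zip(cat_terms, combo))
        row.update(means)
        rows.append(row)
    grid = pd.DataFrame(rows)
    Xg = design.matrix(grid)

    levels = level_sets[factor]
    p = Xg.shape[1]
    L = np.zeros((len(levels), p))
    for i, lev in enumerate(levels):
        mask = (grid[factor].astype(str) == lev).to_numpy()
        L[i] = Xg[mask].mean(axis=0)
    emm = L @ fit.beta.to_numpy()
    se = np.sqrt(np.einsum("ip,pq,iq->i", L, fit.vcov_beta, L))
    desc = (f"levels of {factor} averaged over "
            f"{[t for t in cat_terms if t != factor]} (equal weights), "
            f"covariates at means {means}")
    return EMMSet(factor=factor, levels=list(levels), emmean=emm, se=se,
                  L=L, grid_description=desc, fit=fit)


def pairwise_contrasts(emms: EMMSet,
                       fit: Optional[FittedLMM] = None) -> List[ContrastResult]:
    """All pairwise level contrasts of an EMM set, later minus earlier level.

    Satterthwaite df per contrast; no multiplicity adjustment.
    """
    fit = fit or emms.fit
    out = []
    for i, j in itertools.combinations(range(len(emms.levels)), 2):
        c = emms.L[j] - emms.L[i]
        name = f"{emms.levels[j]} - {emms.levels[i]}"
        out.append(satterthwaite(fit, c, name=name))
    return out
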