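"""Multilevel meta-analytic model: REML estimation with known sampling variances.

Model
-----
For effect sizes ``y_i`` (Fisher's Z) with known sampling variances ``v_i``,

    y = X beta + sum_k u_k + e,      e ~ N(0, diag(v)),
    u_k ~ N(0, sigma2_k * Z_k G_k Z_k'),

where each random term k is a set of intercepts over the levels of a
grouping factor (species, article, study type, observation) with either an
identity correlation ``G_k = I`` or, for the phylogenetic term, the
Brownian-motion species correlation matrix ``G_k = C``.  Species therefore
enters twice: an exchangeable species term and a phylogenetically
structured one, so their variance shares can be reported separately.

Variance components are estimated by restricted maximum likelihood,
minimizing

    -2 l_R = log|V| + log|X' V^{-1} X| + (y - X b)' V^{-1} (y - X b),

with ``V = diag(v) + sum_k sigma2_k Z_k G_k Z_k'`` and ``b`` the GLS
solution.  Optimization is quasi-Newton on ``log(sigma2_k)`` (enforcing
nonnegativity without boundary pathologies) with multiple starts.

The fitter is exposed as a scikit-learn style estimator
(:class:`MultilevelMetaRegression`); :func:`reml_fit` and
:func:`fit_dataset` are thin wrappers returning a :class:`MetaFit`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .dataio import DataError, Dataset
from .phylo import PhyloCorrelation, correlation_matrix

__all__ = [
    "RandomTerm",
    "MultilevelMetaRegression",
    "MetaFit",
    "QMTest",
    "CellEstimate",
    "reml_fit",
    "reml_neg2_criterion",
    "wald_qm",
    "cell_means",
    "build_design",
    "build_random_terms",
    "fit_dataset",
]

Z975 = 1.959963984540054

# log-sigma2 box for the optimizer: wide enough to represent "zero" and any
# plausible Fisher-Z variance while avoiding exp overflow
_THETA_MIN, _THETA_MAX = -30.0, 10.0

#: Default random structure of the full model, in reporting order.
DEFAULT_RANDOM = ("species", "phylo", "article", "study_type", "obs")


@dataclass(frozen=True)
class RandomTerm:
    """One random-intercept term: a grouping factor plus its level correlation.

    ``groups`` holds the factor level of each observation; ``corr`` is an
    optional level-by-level correlation matrix (identity when None).  The
    phylogenetic term uses the species factor with ``corr`` set to the
    Brownian correlation matrix.
    """

    name: str
    groups: tuple
    corr: Optional[PhyloCorrelation] = None

    def zgz(self) -> np.ndarray:
        """The n-by-n contribution matrix Z G Z' of this term."""
        groups = np.asarray(self.groups, dtype=object)
        levels, idx = np.unique(groups, return_inverse=True)
        if self.corr is None:
            return (idx[:, None] == idx[None, :]).astype(float)
        corr = self.corr.reorder([str(l) for l in levels])
        return corr.matrix[np.ix_(idx, idx)]


def _neg2_reml_components(V, X, y, want_p=False):
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return None
    logdet_v = 2.0 * np.log(np.diag(L)).sum()
    Vinv_X = np.linalg.solve(V, X)
    Vinv_y = np.linalg.solve(V, y)
    xtvx = X.T @ Vinv_X
    sign, logdet_x = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return None
    beta = np.linalg.solve(xtvx, X.T @ Vinv_y)
    resid = y - X @ beta
    quad = float(resid @ np.linalg.solve(V, resid))
    value = logdet_v + logdet_x + quad
    if not want_p:
        return value, beta, xtvx
    # REML projection matrix P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1 and Py,
    # needed for the analytic gradient d(-2lR)/ds2_k = tr(P M_k) - y'P M_k P y.
    Vinv = np.linalg.solve(V, np.eye(V.shape[0]))
    P = Vinv - Vinv_X @ np.linalg.solve(xtvx, Vinv_X.T)
    Py = P @ y
    return value, beta, xtvx, P, Py


def reml_neg2_criterion(
    y: np.ndarray,
    v: np.ndarray,
    X: np.ndarray,
    random_terms: Sequence[RandomTerm],
    sigma2: Sequence[float],
) -> float:
    """-2 restricted log-likelihood at fixed variance components.

    Public so that independent oracles (grid or golden-section searches)
    can probe the exact surface the fitter minimizes.
    """
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    X = np.atleast_2d(np.asarray(X, float))
    V = np.diag(v).astype(float)
    for s2, term in zip(sigma2, random_terms):
        V += float(s2) * term.zgz()
    out = _neg2_reml_components(V, X, y)
    if out is None:
        return np.inf
    return out[0]


class MultilevelMetaRegression(BaseEstimator):
    """REML meta-regression with known sampling variances (sklearn-style).

    Parameters
    ----------
    max_iter : int
        Iteration cap per optimizer start.
    ftol : float
        Relative criterion-change convergence tolerance.
    starts : tuple of float
        Multipliers of var(y) used as multi-start values for every
        variance component; the literal 1e-4 start is always included.

    Attributes (after ``fit``)
    --------------------------
    coef_, coef_se_ : ndarray
        GLS fixed-effect estimates and their standard errors.
    sigma2_ : dict
        Variance component per random term (empty when none were given).
    vcov_ : ndarray
        Covariance matrix of ``coef_``: ``(X' V^{-1} X)^{-1}``.
    loglik_reml_ : float
        Restricted log-likelihood at the optimum.
    converged_ : bool
    """

    def __init__(self, max_iter: int = 500, ftol: float = 1e-12, starts=(0.01, 0.1)):
        self.max_iter = max_iter
        self.ftol = ftol
        self.starts = starts

    def fit(self, X, y, *, v, random_terms: Sequence[RandomTerm] = ()):
        X = np.atleast_2d(np.asarray(X, float))
        y = np.asarray(y, float).ravel()
        v = np.asarray(v, float).ravel()
        n, p = X.shape
        if len(y) != n or len(v) != n:
            raise DataError(f"shape mismatch: X has {n} rows, y {len(y)}, v {len(v)}")
        if np.any(v <= 0):
            raise DataError("all sampling variances must be positive")
        if np.linalg.matrix_rank(X) < p:
            raise DataError("design matrix is rank deficient")
        if n <= p:
            raise DataError("more coefficients than observations")
        terms = list(random_terms)
        for t in terms:
            if len(t.groups) != n:
                raise DataError(f"random term {t.name!r} has {len(t.groups)} groups for {n} rows")
        zgzs = [t.zgz() for t in terms]
        base = np.diag(v)

        def criterion(theta):
            sigma2 = np.exp(np.clip(theta, _THETA_MIN, _THETA_MAX))
            V = base.copy()
            for s2, zgz in zip(sigma2, zgzs):
                V += s2 * zgz
            out = _neg2_reml_components(V, X, y, want_p=True)
            if out is None:
                return np.inf, np.zeros_like(theta)
            value, _, _, P, Py = out
            grad = np.array(
                [
                    s2 * (float((P * zgz).sum()) - float(Py @ zgz @ Py))
                    for s2, zgz in zip(sigma2, zgzs)
                ]
            )
            return value, grad

        if not terms:
            sigma2 = np.empty(0)
            self.converged_ = True
            self.n_iter_ = 0
        else:
            var_y = max(float(np.var(y)), 1e-8)
            start_values = [1e-4] + [m * var_y for m in self.starts]
            best = None
            for s0 in start_values:
                theta0 = np.full(len(terms), np.log(s0))
                res = optimize.minimize(
                    criterion,
                    theta0,
                    jac=True,
                    method="L-BFGS-B",
                    bounds=[(_THETA_MIN, _THETA_MAX)] * len(terms),
                    options={"maxiter": self.max_iter, "ftol": self.ftol, "gtol": 1e-9},
                )
                if best is None or res.fun < best.fun:
                    best = res
            sigma2 = np.exp(best.x)
            self.converged_ = bool(best.success) or best.fun < np.inf
            self.n_iter_ = int(best.nit)

        V = base.copy()
        for s2, zgz in zip(sigma2, zgzs):
            V += s2 * zgz
        value, beta, xtvx = _neg2_reml_components(V, X, y)
        self.coef_ = beta
        self.vcov_ = np.linalg.inv(xtvx)
        self.coef_se_ = np.sqrt(np.diag(self.vcov_))
        self.sigma2_ = {t.name: float(s2) for t, s2 in zip(terms, sigma2)}
        self.loglik_reml_ = -0.5 * (value + (n - p) * np.log(2.0 * np.pi))
        self.criterion_ = float(value)
        self.random_terms_ = tuple(terms)
        self.n_features_in_ = p
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, float))
        return X @ self.coef_


@dataclass
class MetaFit:
    """Fitted multilevel meta-analysis: coefficients, variance components, metadata."""

    coef: pd.Series
    se: pd.Series
    vcov: pd.DataFrame
    sigma2: dict[str, float]
    loglik_reml: float
    converged: bool
    n: int
    v: np.ndarray
    X: pd.DataFrame
    criterion: float = np.nan

    @property
    def coef_names(self) -> list[str]:
        return list(self.coef.index)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.coef,
                "se": self.se,
                "ci_low": self.coef - Z975 * self.se,
                "ci_high": self.coef + Z975 * self.se,
            }
        )


@dataclass(frozen=True)
class QMTest:
    """Wald-type omnibus chi-square test of a set of moderator coefficients."""

    statistic: float
    df: int
    p: float


@dataclass(frozen=True)
class CellEstimate:
    cell: tuple[str, str]
    mean_z: float
    se: float
    ci_low: float
    ci_high: float

    @property
    def mean_r(self) -> float:
        return float(np.tanh(self.mean_z))


def reml_fit(
    y,
    v,
    X,
    random_terms: Sequence[RandomTerm] = (),
    coef_names: Optional[Sequence[str]] = None,
    **estimator_kwargs,
) -> MetaFit:
    """Fit the multilevel model; wrapper over :class:`MultilevelMetaRegression`."""
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xdf = X
    else:
        X = np.atleast_2d(np.asarray(X, float))
        names = list(coef_names) if coef_names is not None else [f"b{i}" for i in range(X.shape[1])]
        Xdf = pd.DataFrame(X, columns=names)
    est = MultilevelMetaRegression(**estimator_kwargs).fit(
        Xdf.to_numpy(float), np.asarray(y, float), v=np.asarray(v, float),
        random_terms=random_terms,
    )
    return MetaFit(
        coef=pd.Series(est.coef_, index=names),
        se=pd.Series(est.coef_se_, index=names),
        vcov=pd.DataFrame(est.vcov_, index=names, columns=names),
        sigma2=dict(est.sigma2_),
        loglik_reml=float(est.loglik_reml_),
        converged=bool(est.converged_),
        n=len(np.asarray(y).ravel()),
        v=np.asarray(v, float).ravel(),
        X=Xdf,
        criterion=float(est.criterion_),
    )


def wald_qm(fit: MetaFit, tested: Optional[Sequence] = None) -> QMTest:
    """Joint Wald chi-square (QM) test of the moderator coefficients.

    ``tested`` selects coefficients by name or position; defaults to every
    non-intercept coefficient.
    """
    names = fit.coef_names
    if tested is None:
        tested = [nm for nm in names if nm != "intercept"]
    idx = [names.index(t) if isinstance(t, str) else int(t) for t in tested]
    if not idx:
        raise DataError("no coefficients selected for the QM test")
    if any(names[i] == "intercept" for i in idx):
        raise DataError("QM test must not include the intercept")
    b = fit.coef.to_numpy()[idx]
    sub = fit.vcov.to_numpy()[np.ix_(idx, idx)]
    try:
        stat = float(b @ np.linalg.solve(sub, b))
    except np.linalg.LinAlgError as exc:
        raise DataError("singular coefficient covariance in QM test") from exc
    df = len(idx)
    return QMTest(statistic=stat, df=df, p=float(stats.chi2.sf(stat, df)))


MODERATOR_CELLS = (("loser", "high"), ("winner", "high"), ("loser", "low"), ("winner", "low"))


def _design_row(role: str, cost: str) -> np.ndarray:
    w = 1.0 if role == "winner" else 0.0
    l = 1.0 if cost == "low" else 0.0
    return np.array([1.0, w, l, w * l])


def build_design(frame: pd.DataFrame, moderators: bool = True) -> pd.DataFrame:
    """Treatment-coded design for the role-by-cost moderator structure.

    Reference cell is (loser, high); columns are intercept, role[winner],
    cost[low] and their interaction, so the omnibus moderator test has
    three degrees of freedom.  With ``moderators=False`` only the intercept
    column is returned (the overall-mean model).
    """
    if not moderators:
        return pd.DataFrame({"intercept": np.ones(len(frame))}, index=frame.index)
    for col in ("role", "cost_category"):
        if col not in frame.columns:
            raise DataError(f"design needs a {col!r} column")
    rows = np.stack([
        _design_row(role, cost)
        for role, cost in zip(frame["role"], frame["cost_category"])
    ])
    return pd.DataFrame(
        rows,
        columns=["intercept", "role[winner]", "cost[low]", "role[winner]:cost[low]"],
        index=frame.index,
    )


def cell_means(fit: MetaFit, cells: Sequence[tuple[str, str]] = MODERATOR_CELLS) -> list[CellEstimate]:
    """Estimated marginal mean Fisher's Z per (role, cost) cell with 95% CIs.

    Each cell mean is the linear combination ``L beta`` of the treatment
    coded coefficients, with CI ``mean ± 1.96 sqrt(L Vcov L')``; ``mean_r``
    back-transforms through tanh.
    """
    names = fit.coef_names
    vcov = fit.vcov.to_numpy()
    beta = fit.coef.to_numpy()
    out = []
    for cell in cells:
        role, cost = cell
        if names == ["intercept"]:
            L = np.array([1.0])
        elif len(names) == 4:
            L = _design_row(role, cost)
        else:
            raise DataError(f"cell {cell} not representable in this design")
        mean = float(L @ beta)
        se = float(np.sqrt(L @ vcov @ L))
        out.append(
            CellEstimate(
                cell=(role, cost), mean_z=mean, se=se,
                ci_low=mean - Z975 * se, ci_high=mean + Z975 * se,
            )
        )
    return out


def dataset_frame(dataset: Dataset) -> pd.DataFrame:
    """Model frame: one row per derived effect with moderators and grouping factors."""
    rows = []
    for rec in dataset.records:
        if rec.z is None or rec.v is None:
            raise DataError(f"{rec.effect_id}: derive z and v before fitting")
        prof = dataset.profiles.get(rec.species)
        if prof is None:
            raise DataError(f"{rec.effect_id}: no contest profile for {rec.species}")
        rows.append(
            {
                "effect_id": rec.effect_id,
                "species": rec.species,
                "article_id": rec.article_id,
                "study_type": rec.study_type,
                "role": rec.role,
                "cost_category": prof.cost_category,
                "z": rec.z,
                "v": rec.v,
            }
        )
    return pd.DataFrame(rows)


def build_random_terms(
    frame: pd.DataFrame,
    random: Sequence[str] = DEFAULT_RANDOM,
    phylo_corr: Optional[PhyloCorrelation] = None,
) -> list[RandomTerm]:
    """Random-intercept terms for the requested factors.

    ``species`` and ``phylo`` both group by species; the latter carries the
    phylogenetic correlation matrix.  ``study_type`` has only two levels
    (field/laboratory), so its variance component is weakly identified; it
    is kept for fidelity to the full model and a warning is emitted.
    """
    terms = []
    for name in random:
        if name == "species":
            terms.append(RandomTerm("species", tuple(frame["species"])))
        elif name == "phylo":
            if phylo_corr is None:
                raise DataError("phylo random term requested but no phylogenetic correlation given")
            terms.append(RandomTerm("phylo", tuple(frame["species"]), corr=phylo_corr))
        elif name == "article":
            terms.append(RandomTerm("article", tuple(frame["article_id"])))
        elif name == "study_type":
            if frame["study_type"].nunique() < 2:
                warnings.warn("study_type has a single level; its variance is not identified")
            else:
                warnings.warn(
                    "study_type has only 2 levels; its variance component is weakly identified",
                    stacklevel=2,
                )
            terms.append(RandomTerm("study_type", tuple(frame["study_type"])))
        elif name == "obs":
            terms.append(RandomTerm("obs", tuple(frame["effect_id"])))
        else:
            raise DataError(f"unknown random term {name!r}")
    return terms


def fit_dataset(
    dataset: Dataset,
    tree=None,
    moderators: bool = True,
    random: Sequence[str] = DEFAULT_RANDOM,
    phylo_corr: Optional[PhyloCorrelation] = None,
    **estimator_kwargs,
) -> MetaFit:
    """Fit the full moderated multilevel model to a derived dataset.

    The phylogenetic correlation is taken from ``phylo_corr`` or built from
    ``tree`` (Grafen-ultrametricized if topology-only) when the ``phylo``
    random term is requested.
    """
    frame = dataset_frame(dataset)
    if "phylo" in random and phylo_corr is None:
        if tree is None:
            raise DataError("phylo random term requires a tree or a correlation matrix")
        dataset.validate_against_tree(tree)
        phylo_corr = correlation_matrix(tree, species_order=sorted(set(frame["species"])))
    X = build_design(frame, moderators=moderators)
    terms = build_random_terms(frame, random=random, phylo_corr=phylo_corr)
    return reml_fit(frame["z"].to_numpy(), frame["v"].to_numpy(), X, terms, **estimator_kwargs)
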