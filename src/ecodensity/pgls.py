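"""Phylogenetic generalized least squares, AIC dredging, model averaging.

The model is y = X beta + e with e ~ N(0, sigma^2 V), where V is the
Brownian variance-covariance matrix implied by the phylogeny.  Fitting is
by maximum likelihood: V is Cholesky-factored once, data are whitened,
and

    beta_hat   = (X' V^-1 X)^-1 X' V^-1 y
    sigma2_ML  = (y - X beta_hat)' V^-1 (y - X beta_hat) / n
    logLik     = -1/2 [ n ln(2 pi sigma2_ML) + ln|V| + n ]

Standard errors use the df-corrected variance sigma2_ML * n / (n - p), so
single-model t-tests match ordinary GLS output.  AIC counts sigma^2 as an
estimated parameter (k = p + 1).  ML (not REML) is the default because
AIC comparisons across fixed-effect structures require it.

Dredging fits every subset of the full model's terms (factor blocks enter
or leave as a unit, the intercept is always present).  Models within
``delta_cut`` AIC units of the best are retained and full-model averaged:
a term absent from a model contributes a coefficient of 0 (with zero
standard error) to its Akaike-weighted average.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg, stats

from . import phylo

Z975 = stats.norm.ppf(0.975)

INTERCEPT = "(Intercept)"


@dataclass(frozen=True)
class Term:
    """A named model term spanning one or more design columns.

    A factor block (e.g. nest type) lists all its dummy columns and is
    added or dropped as a unit during dredging.
    """

    name: str
    columns: tuple[str, ...]

    @classmethod
    def single(cls, name: str) -> "Term":
        return cls(name, (name,))


@dataclass(frozen=True)
class ModelSpec:
    """Response plus a set of terms; the intercept is always included."""

    response: str
    terms: tuple[Term, ...]

    def __post_init__(self):
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate term names: {names}")
        if {"ssPC", "sfPC"} <= set(names):
            raise ValueError(
                "ssPC and sfPC are too correlated to enter one model; "
                "use separate model sets"
            )


@dataclass(eq=False)
class PGLSFit:
    response: str
    term_names: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    sigma2: float
    loglik: float
    aic: float
    n: int
    k: int
    df_resid: int
    method: str = "ML"

    @property
    def label(self) -> str:
        return " + ".join(self.term_names) if self.term_names else "(null)"


@dataclass
class AveragedModel:
    """Full (zero-substitution) Akaike-weighted average over a model set."""

    coef: pd.DataFrame
    models: pd.DataFrame
    delta_cut: float
    n_candidates: int


def design_matrix(
    data: pd.DataFrame, terms: tuple[Term, ...]
) -> tuple[np.ndarray, list[str]]:
    names = [INTERCEPT]
    cols = [np.ones(len(data))]
    for term in terms:
        for col in term.columns:
            if col not in data.columns:
                raise ValueError(f"term column {col!r} not in data")
            names.append(col)
            cols.append(data[col].to_numpy(dtype=float))
    return np.column_stack(cols), names


def _check_alignment(data: pd.DataFrame, V: pd.DataFrame) -> np.ndarray:
    missing = [s for s in data.index if s not in V.index]
    if missing:
        raise ValueError(f"species absent from V: {missing}")
    V = V.loc[data.index, data.index]
    return V.to_numpy(dtype=float)


def _whiten(V: np.ndarray) -> tuple[np.ndarray, float]:
    """Lower Cholesky factor of V and ln|V|."""
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "V is not positive definite (check the tree and species subset)"
        ) from exc
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return L, logdet


def _name_collinear(Xw: np.ndarray, names: list[str]) -> list[str]:
    _, R, piv = linalg.qr(Xw, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xw.shape) * np.finfo(float).eps
    return [names[piv[i]] for i in range(len(names)) if diag[i] <= tol]


def _fit_whitened(
    yw: np.ndarray,
    Xw: np.ndarray,
    logdet: float,
    names: list[str],
    response: str,
    term_names: tuple[str, ...],
    method: str,
) -> PGLSFit:
    n, p = Xw.shape
    if n <= p:
        raise ValueError(f"n = {n} too small for {p} coefficients")
    if np.linalg.matrix_rank(Xw) < p:
        raise ValueError(f"singular design; collinear columns: {_name_collinear(Xw, names)}")
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    XtX_inv = np.linalg.inv(Xw.T @ Xw)

    sigma2_ml = rss / n
    if method == "ML":
        loglik = (
            -0.5 * (n * math.log(2 * math.pi * sigma2_ml) + logdet + n)
            if sigma2_ml > 0
            else math.inf
        )
        sigma2 = sigma2_ml
    elif method == "REML":
        sigma2_reml = rss / (n - p)
        sign, logdet_xx = np.linalg.slogdet(Xw.T @ Xw)
        loglik = (
            -0.5 * (
                (n - p) * math.log(2 * math.pi * sigma2_reml)
                + logdet + logdet_xx + (n - p)
            )
            if sigma2_reml > 0
            else math.inf
        )
        sigma2 = sigma2_reml
    else:
        raise ValueError(f"unknown method {method!r}")

    # df-corrected residual variance for the t-tests
    s2_t = rss / (n - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        bse = np.sqrt(s2_t * np.diag(XtX_inv))
        tvals = np.where(bse > 0, beta / np.where(bse > 0, bse, 1.0), np.inf * np.sign(beta))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - p)
    k = p + 1
    return PGLSFit(
        response=response,
        term_names=term_names,
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        tvalues=pd.Series(tvals, index=names),
        pvalues=pd.Series(pvals, index=names),
        sigma2=sigma2,
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * k,
        n=n,
        k=k,
        df_resid=n - p,
        method=method,
    )


def fit_pgls(
    spec: ModelSpec, data: pd.DataFrame, V: pd.DataFrame, method: str = "ML"
) -> PGLSFit:
    """Fit one PGLS model by (restricted) maximum likelihood."""
    Vm = _check_alignment(data, V)
    X, names = design_matrix(data, spec.terms)
    y = data[spec.response].to_numpy(dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in response or predictors")
    L, logdet = _whiten(Vm)
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    return _fit_whitened(
        yw, Xw, logdet, names, spec.response,
        tuple(t.name for t in spec.terms), method,
    )


def single_predictor_suite(
    data: pd.DataFrame,
    V: pd.DataFrame,
    predictors: tuple[str, ...] = ("log_body_mass", "ssi_habitat", "ssi_diet"),
    responses: tuple[str, ...] = ("geo_density", "eco_density"),
    method: str = "ML",
) -> pd.DataFrame:
    """Single-predictor PGLS fits, one per (response, predictor) pair.

    Output is a long table with intercept and slope rows per model,
    mirroring a classic regression summary (estimate, SE, t, p).
    """
    rows = []
    for response in responses:
        for pred in predictors:
            spec = ModelSpec(response=response, terms=(Term.single(pred),))
            fit = fit_pgls(spec, data, V, method=method)
            for coef in fit.params.index:
                rows.append(
                    {
                        "response": response,
                        "predictor": pred,
                        "coefficient": coef,
                        "estimate": fit.params[coef],
                        "se": fit.bse[coef],
                        "t_value": fit.tvalues[coef],
                        "p_value": fit.pvalues[coef],
                        "n": fit.n,
                    }
                )
    return pd.DataFrame(rows)


MAX_DREDGE_TERMS = 20


def dredge(
    full_spec: ModelSpec,
    data: pd.DataFrame,
    V: pd.DataFrame,
    method: str = "ML",
) -> list[PGLSFit]:
    """Fit all 2^m submodels of the full model, sorted by AIC.

    Factor blocks are atomic; the intercept is always included.  Ties in
    AIC are broken by fewer parameters, then by term names, so the order
    is deterministic.
    """
    m = len(full_spec.terms)
    if m > MAX_DREDGE_TERMS:
        raise ValueError(f"refusing to dredge {m} terms (2^{m} models)")
    Vm = _check_alignment(data, V)
    L, logdet = _whiten(Vm)
    X_full, names_full = design_matrix(data, full_spec.terms)
    y = data[full_spec.response].to_numpy(dtype=float)
    if np.isnan(X_full).any() or np.isnan(y).any():
        raise ValueError("missing values in response or predictors")
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw_full = linalg.solve_triangular(L, X_full, lower=True)

    col_of = {name: i for i, name in enumerate(names_full)}
    fits = []
    for r in range(m + 1):
        for subset in combinations(range(m), r):
            terms = tuple(full_spec.terms[i] for i in subset)
            names = [INTERCEPT] + [c for t in terms for c in t.columns]
            cols = [col_of[nm] for nm in names]
            fit = _fit_whitened(
                yw, Xw_full[:, cols], logdet, names, full_spec.response,
                tuple(t.name for t in terms), method,
            )
            fits.append(fit)
    fits.sort(key=lambda f: (f.aic, f.k, f.term_names))
    return fits


def select_and_average(
    fits: list[PGLSFit],
    delta_cut: float = 2.0,
    conditional: bool = False,
) -> AveragedModel:
    """Retain models with delta AIC < ``delta_cut`` and average them.

    Full averaging (default): a coefficient absent from a model enters its
    Akaike-weighted average as 0 with zero SE.  ``conditional=True``
    averages only over the models containing each coefficient.

    The unconditional standard error is
    ``SE(b_j) = sum_i w_i * sqrt(SE_ij^2 + (b_ij - b_j)^2)``; the adjusted
    variant replaces each SE_ij by ``SE_ij * t(df_i, 0.975) / z(0.975)``
    to account for small residual degrees of freedom.  z-scores and
    p-values for averaged coefficients are standard normal.
    """
    if not fits:
        raise ValueError("no fitted models to average")
    fits = sorted(fits, key=lambda f: (f.aic, f.k, f.term_names))
    best = fits[0].aic
    retained = [f for f in fits if f.aic - best < delta_cut]
    rel = np.array([math.exp(-(f.aic - best) / 2.0) for f in retained])
    weights = rel / rel.sum()

    # coefficient universe ordered by the widest retained/candidate model
    widest = max(fits, key=lambda f: f.k)
    coef_names = list(widest.params.index)
    for f in fits:
        for nm in f.params.index:
            if nm not in coef_names:
                coef_names.append(nm)

    rows = {}
    for nm in coef_names:
        present = np.array([nm in f.params.index for f in retained])
        if conditional and present.any():
            w = weights[present] / weights[present].sum()
            sub = [f for f, keep in zip(retained, present) if keep]
        else:
            w = weights
            sub = retained
        beta = np.array(
            [f.params.get(nm, 0.0) for f in sub]
        )
        se = np.array([f.bse.get(nm, 0.0) for f in sub])
        dfs = np.array([f.df_resid for f in sub])
        bbar = float(w @ beta)
        se_bar = float(w @ np.sqrt(se**2 + (beta - bbar) ** 2))
        adj = se * stats.t.ppf(0.975, dfs) / Z975
        adj_se_bar = float(w @ np.sqrt(adj**2 + (beta - bbar) ** 2))
        with np.errstate(divide="ignore"):
            z = abs(bbar) / adj_se_bar if adj_se_bar > 0 else math.inf
        rows[nm] = {
            "estimate": bbar,
            "se": se_bar,
            "adjusted_se": adj_se_bar,
            "z_value": z,
            "p_value": 2.0 * stats.norm.sf(z),
        }

    models = pd.DataFrame(
        {
            "model": [f.label for f in fits],
            "k": [f.k for f in fits],
            "loglik": [f.loglik for f in fits],
            "aic": [f.aic for f in fits],
            "delta_aic": [f.aic - best for f in fits],
            "weight": [
                weights[retained.index(f)] if f in retained else np.nan
                for f in fits
            ],
            "retained": [f.aic - best < delta_cut for f in fits],
        }
    )
    coef = pd.DataFrame.from_dict(rows, orient="index").loc[coef_names]
    coef.index.name = "coefficient"
    return AveragedModel(
        coef=coef, models=models, delta_cut=delta_cut, n_candidates=len(fits)
    )


def dredge_over_trees(
    full_spec: ModelSpec,
    data: pd.DataFrame,
    trees,
    delta_cut: float = 2.0,
    consensus: "pd.DataFrame | None" = None,
    method: str = "ML",
) -> pd.DataFrame:
    """Repeat dredge + average over a tree sample; summarize stability.

    Returns one row per coefficient of the full model with the
    consensus-tree averaged estimate, the across-tree mean, SD and 2.5/97.5
    percentiles, and the fraction of trees whose averaged estimate has the
    same sign as the consensus one.
    """
    species = list(data.index)
    if consensus is None:
        cons_tree = phylo.consensus_tree(list(trees))
        consensus = phylo.brownian_vcv(cons_tree, species)
    cons_avg = select_and_average(
        dredge(full_spec, data, consensus, method=method), delta_cut
    )
    per_tree = []
    for tree in trees:
        V = phylo.brownian_vcv(tree, species)
        avg = select_and_average(
            dredge(full_spec, data, V, method=method), delta_cut
        )
        per_tree.append(avg.coef["estimate"])
    mat = pd.concat(per_tree, axis=1)
    cons_est = cons_avg.coef["estimate"]
    sign_agree = (np.sign(mat).eq(np.sign(cons_est), axis=0)).mean(axis=1)
    report = pd.DataFrame(
        {
            "consensus_estimate": cons_est,
            "mean": mat.mean(axis=1),
            "sd": mat.std(axis=1, ddof=1) if mat.shape[1] > 1 else 0.0,
            "q025": mat.quantile(0.025, axis=1),
            "q975": mat.quantile(0.975, axis=1),
            "sign_agreement": sign_agree,
        }
    )
    report.index.name = "coefficient"
    return report
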