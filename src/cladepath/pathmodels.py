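"""Phylogenetic confirmatory path analysis.

A causal hypothesis is a DAG over named variables.  Its testable content is
Shipley's d-separation basis set: one conditional-independence claim per
non-adjacent variable pair, each tested as a partial regression — by GLS
under a Brownian-motion correlation structure for raw cross-species data, or
by OLS through the origin for phylogenetic independent contrasts.  Claims
combine into Fisher's C = -2 sum ln p, chi-square distributed with 2k df
under the hypothesized DAG, and competing DAGs are ranked by the
small-sample information criterion CICc = C + 2qn/(n - q - 1).

The same engine fits the DAG as a recursive linear-Gaussian path model:
per-equation regressions give standardized (SMD) edge coefficients with
standard errors, the system log-likelihood gives AIC, and the implied-vs-
observed covariance discrepancy gives a chi-square goodness of fit.  Direct,
indirect and total effects follow the path-tracing rules: an indirect effect
is the product of coefficients along each directed path, summed over paths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .trees import Tree

__all__ = [
    "CausalDAG",
    "Claim",
    "basis_set",
    "ci_test",
    "c_statistic",
    "cicc",
    "PathModel",
    "fit_path_model",
    "decompose_effects",
    "compare_models",
    "quantile_normalize",
    "QuantileNormalizer",
]

MODES = ("gls-bm", "contrasts-ols", "ols")


class PathModelError(ValueError):
    pass


# ------------------------------------------------------------------ DAGs

class CausalDAG:
    """Directed acyclic graph of named variables, with optional free
    correlations between exogenous variables."""

    def __init__(
        self,
        nodes: Sequence[str],
        edges: Iterable[tuple[str, str]] = (),
        correlations: Iterable[tuple[str, str]] = (),
        name: str | None = None,
    ):
        self.nodes = list(dict.fromkeys(nodes))
        self.graph = nx.DiGraph()
        self.graph.add_nodes_from(self.nodes)
        for u, v in edges:
            if u not in self.nodes or v not in self.nodes:
                raise PathModelError(f"edge {u}->{v} uses undeclared variable")
            self.graph.add_edge(u, v)
        if not nx.is_directed_acyclic_graph(self.graph):
            raise PathModelError("graph contains a directed cycle")
        self.correlations = []
        exog = {v for v in self.nodes if self.graph.in_degree(v) == 0}
        for u, v in correlations:
            if u not in exog or v not in exog:
                raise PathModelError(
                    f"correlation {u}~~{v} must link two exogenous variables"
                )
            self.correlations.append(frozenset((u, v)))
        self.name = name

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    def parents(self, v: str) -> list[str]:
        return sorted(self.graph.predecessors(v), key=self.nodes.index)

    @property
    def endogenous(self) -> list[str]:
        return [v for v in self.nodes if self.graph.in_degree(v) > 0]

    @property
    def exogenous(self) -> list[str]:
        return [v for v in self.nodes if self.graph.in_degree(v) == 0]

    def causal_order(self) -> list[str]:
        return list(
            nx.lexicographical_topological_sort(self.graph, key=self.nodes.index)
        )

    def adjacent(self, u: str, v: str) -> bool:
        return (
            self.graph.has_edge(u, v)
            or self.graph.has_edge(v, u)
            or frozenset((u, v)) in self.correlations
        )

    # -- text format: "A -> B" and "A ~~ B" lines ----------------------
    @classmethod
    def from_text(cls, text: str, name: str | None = None) -> "CausalDAG":
        nodes, edges, corrs = [], [], []
        for line in text.splitlines():
            line = line.split("#")[0].strip()
            if not line:
                continue
            if "->" in line:
                u, v = (s.strip() for s in line.split("->"))
                edges.append((u, v))
            elif "~~" in line:
                u, v = (s.strip() for s in line.split("~~"))
                corrs.append((u, v))
            else:
                nodes.append(line)
                continue
            for w in (u, v):
                if w not in nodes:
                    nodes.append(w)
        return cls(nodes, edges, corrs, name=name)

    def to_text(self) -> str:
        lines = [v for v in self.nodes if self.graph.degree(v) == 0]
        lines += [f"{u} -> {v}" for u, v in self.edges]
        lines += [f"{u} ~~ {v}" for u, v in (sorted(c) for c in self.correlations)]
        return "\n".join(lines) + "\n"

    def __repr__(self) -> str:
        return f"<CausalDAG {self.name or ''} {len(self.nodes)} vars, {len(self.edges)} edges>"


@dataclass(frozen=True)
class Claim:
    """A conditional-independence claim X ⟂ Y | Z implied by a DAG."""

    x: str
    y: str
    given: tuple[str, ...]


def basis_set(dag: CausalDAG) -> list[Claim]:
    """Shipley's d-separation basis: one claim per non-adjacent ordered pair
    (earlier variable first in causal order), conditioning on the union of
    both variables' parents."""
    order = dag.causal_order()
    claims = []
    for i, x in enumerate(order):
        for y in order[i + 1 :]:
            if dag.adjacent(x, y):
                continue
            given = sorted(
                (set(dag.parents(x)) | set(dag.parents(y))) - {x, y},
                key=dag.nodes.index,
            )
            claims.append(Claim(x, y, tuple(given)))
    return claims


# ------------------------------------------------------- regression core

def _bm_sigma(tree: Tree, index) -> np.ndarray:
    V = tree.tip_covariance()
    order = [tree.tip_labels.index(lbl) for lbl in index]
    return V[np.ix_(order, order)]


def _regress(y: np.ndarray, X: np.ndarray, mode: str, V: np.ndarray | None):
    """Fit one structural equation; returns the statsmodels results."""
    if mode == "gls-bm":
        return sm.GLS(y, sm.add_constant(X, has_constant="add"), sigma=V).fit()
    if mode == "ols":
        return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    if mode == "contrasts-ols":
        return sm.OLS(y, X).fit()  # contrasts regress through the origin
    raise PathModelError(f"unknown mode {mode!r}")


def ci_test(
    claim: Claim,
    data: pd.DataFrame,
    mode: str = "contrasts-ols",
    tree: Tree | None = None,
) -> float:
    """p-value of the partial coefficient of X in Y ~ X + Z.

    ``gls-bm`` fits by GLS under the Brownian-motion tip covariance of
    ``tree`` (rows of ``data`` must be tip labels); ``contrasts-ols`` fits
    OLS through the origin (for independent contrasts); ``ols`` is ordinary
    iid regression.
    """
    cols = [claim.x, *claim.given]
    missing = [c for c in (claim.y, *cols) if c not in data.columns]
    if missing:
        raise PathModelError(f"variables absent from data: {missing}")
    y = data[claim.y].to_numpy(dtype=float)
    X = data[cols].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise PathModelError("rank-deficient design in independence test")
    V = None
    if mode == "gls-bm":
        if tree is None:
            raise PathModelError("gls-bm mode requires a tree")
        V = _bm_sigma(tree, data.index)
    res = _regress(y, X, mode, V)
    i = 1 if mode != "contrasts-ols" else 0  # position of X after intercept
    return float(res.pvalues[i])


def c_statistic(p_values: Sequence[float]) -> tuple[float, int, float]:
    """Fisher's C = -2 sum ln p over the basis-set tests.

    Returns (C, df, overall p) where df = 2k; an empty claim list (saturated
    model) gives C = 0 with p = 1.  Zero p-values are clamped at 1e-300.
    """
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size == 0:
        return 0.0, 0, 1.0
    if np.any((ps < 0) | (ps > 1)):
        raise PathModelError("p-values must lie in [0, 1]")
    if np.any(ps == 0):
        warnings.warn("clamping zero p-values at 1e-300", stacklevel=2)
        ps = np.maximum(ps, 1e-300)
    C = float(-2.0 * np.log(ps).sum())
    df = 2 * ps.size
    return C, df, float(stats.chi2.sf(C, df))


def cicc(C: float, q: int, n: int) -> float:
    """Small-sample C-statistic information criterion
    CICc = C + 2q·n/(n - q - 1)."""
    if n <= q + 1:
        raise PathModelError(f"n={n} too small for q={q} parameters")
    return float(C + 2.0 * q * n / (n - q - 1))


# ------------------------------------------------------------- normalizer

def quantile_normalize(x) -> np.ndarray:
    """Rank-based ordered-quantile transform to approximate standard
    normality: Phi^{-1}((rank - 1/2)/n).  Strictly monotone in the input;
    ties stay tied."""
    v = np.asarray(x, dtype=float)
    if len(np.unique(v)) < 3:
        raise PathModelError("need at least 3 distinct values to normalize")
    r = stats.rankdata(v, method="average")
    return stats.norm.ppf((r - 0.5) / len(v))


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Column-wise ordered-quantile (rank-to-normal) transformer.

    ``fit`` memorizes each column's empirical quantile function; ``transform``
    maps values to normal scores by monotone interpolation, so transforming
    the training data reproduces :func:`quantile_normalize` exactly.
    """

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        self.columns_ = list(X.columns)
        self.reference_ = {}
        for c in self.columns_:
            v = X[c].to_numpy(dtype=float)
            self.reference_[c] = (np.sort(v), np.sort(quantile_normalize(v)))
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        out = X.copy().astype(float)
        for c in self.columns_:
            xs, zs = self.reference_[c]
            out[c] = np.interp(X[c].to_numpy(dtype=float), xs, zs)
        return out


# ------------------------------------------------------------ path model

class PathModel(BaseEstimator):
    """Confirmatory path model for one causal DAG.

    Parameters
    ----------
    dag : CausalDAG
        The causal hypothesis.
    mode : {"contrasts-ols", "gls-bm", "ols"}
        Estimation mode: OLS through the origin on independent contrasts,
        GLS under Brownian-motion covariance from ``tree`` (raw tip or
        genus data), or ordinary iid regression.
    tree : Tree, optional
        Required for ``gls-bm``; rows of the fitted data must be its tips.
    standardize : bool
        Scale variables to unit variance before fitting so coefficients are
        on the SMD scale (centering is skipped in contrasts mode, which
        passes through the origin).

    Fitted attributes (trailing underscore) include per-edge standardized
    coefficients with standard errors (``coefficients_``), Fisher's C and
    its p-value, CICc, the system log-likelihood and AIC, and the implied-
    covariance chi-square goodness of fit.
    """

    def __init__(self, dag=None, mode="contrasts-ols", tree=None, standardize=True):
        self.dag = dag
        self.mode = mode
        self.tree = tree
        self.standardize = standardize

    # -- helpers -------------------------------------------------------
    def _prepare(self, X: pd.DataFrame) -> pd.DataFrame:
        dag = self.dag
        missing = [v for v in dag.nodes if v not in X.columns]
        if missing:
            raise PathModelError(f"data lacks variables: {missing}")
        D = X[dag.nodes].dropna().astype(float)
        if len(D) < len(dag.nodes) + 2:
            raise PathModelError("too few complete cases")
        sd = D.std(ddof=0)
        if (sd == 0).any():
            raise PathModelError(
                f"degenerate (constant) variables: {sd.index[sd == 0].tolist()}"
            )
        if self.standardize:
            if self.mode == "contrasts-ols":
                D = D / sd
            else:
                D = (D - D.mean()) / sd
        return D

    def fit(self, X: pd.DataFrame, y=None) -> "PathModel":
        if self.dag is None:
            raise PathModelError("a CausalDAG is required")
        if self.mode not in MODES:
            raise PathModelError(f"mode must be one of {MODES}")
        dag = self.dag
        D = self._prepare(pd.DataFrame(X))
        n, p = len(D), len(dag.nodes)
        V = Vinv = None
        logdetV = 0.0
        if self.mode == "gls-bm":
            if self.tree is None:
                raise PathModelError("gls-bm mode requires a tree")
            V = _bm_sigma(self.tree, D.index)
            sign, logdetV = np.linalg.slogdet(V)
            Vinv = np.linalg.inv(V)

        center = self.mode != "contrasts-ols"

        def _mean(v: np.ndarray) -> float:
            if not center:
                return 0.0
            if V is None:
                return float(v.mean())
            ones = np.ones(n)
            return float(ones @ Vinv @ v / (ones @ Vinv @ ones))

        def _cov(a: np.ndarray, b: np.ndarray) -> float:
            if V is None:
                return float(a @ b / n)
            return float(a @ Vinv @ b / n)

        # structural equations
        rows = []
        loglik = 0.0
        resid_var: dict[str, float] = {}
        means = {v: _mean(D[v].to_numpy()) for v in dag.nodes}
        cdata = {v: D[v].to_numpy() - means[v] for v in dag.nodes}
        for v in dag.endogenous:
            pa = dag.parents(v)
            yv = D[v].to_numpy()
            Xv = D[pa].to_numpy()
            if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
                raise PathModelError(f"rank-deficient parents for {v}")
            res = _regress(yv, Xv, self.mode, V)
            off = 0 if self.mode == "contrasts-ols" else 1
            for j, u in enumerate(pa):
                rows.append(
                    {
                        "from": u,
                        "to": v,
                        "coef": float(res.params[off + j]),
                        "se": float(res.bse[off + j]),
                        "p": float(res.pvalues[off + j]),
                    }
                )
            e = yv - res.fittedvalues
            s2 = _cov(e, e)
            resid_var[v] = s2
            loglik += -0.5 * (n * np.log(2 * np.pi * s2) + logdetV + n)

        # exogenous marginals (jointly for declared correlated pairs)
        exog = dag.exogenous
        corr_pairs = [tuple(sorted(c, key=dag.nodes.index)) for c in dag.correlations]
        in_pair = {w for pr in corr_pairs for w in pr}
        exog_var = {v: _cov(cdata[v], cdata[v]) for v in exog}
        exog_cov = {}
        for u, w in corr_pairs:
            exog_cov[(u, w)] = _cov(cdata[u], cdata[w])
        for v in exog:
            if v in in_pair:
                continue
            loglik += -0.5 * (n * np.log(2 * np.pi * exog_var[v]) + logdetV + n)
        for u, w in corr_pairs:
            S2 = np.array(
                [
                    [exog_var[u], exog_cov[(u, w)]],
                    [exog_cov[(u, w)], exog_var[w]],
                ]
            )
            sgn, ld = np.linalg.slogdet(S2)
            loglik += -0.5 * (n * (2 * np.log(2 * np.pi) + ld) + 2 * logdetV + 2 * n)

        self.coefficients_ = pd.DataFrame(
            rows, columns=["from", "to", "coef", "se", "p"]
        )
        self.n_ = n
        self.loglik_ = float(loglik)

        # parameter counts
        n_edges = len(dag.edges)
        n_corr = len(corr_pairs)
        n_means = p if center else 0
        k_full = n_edges + p + n_corr + n_means  # + all variances
        self.aic_ = float(-2 * loglik + 2 * k_full)
        self.q_ = n_edges + len(exog) + n_corr  # Shipley convention for CICc

        # d-separation test
        claims = basis_set(dag)
        self.claims_ = claims
        self.claim_p_values_ = [
            ci_test(c, D, mode=self.mode, tree=self.tree) for c in claims
        ]
        self.c_statistic_, self.c_df_, self.c_p_value_ = c_statistic(
            self.claim_p_values_
        )
        self.cicc_ = cicc(self.c_statistic_, self.q_, n)
        self.missing_path_ = bool(self.c_p_value_ < 0.05)

        # implied-vs-observed covariance chi-square
        idx = {v: i for i, v in enumerate(dag.nodes)}
        B = np.zeros((p, p))
        for r in rows:
            B[idx[r["to"]], idx[r["from"]]] = r["coef"]
        Psi = np.zeros((p, p))
        for v in exog:
            Psi[idx[v], idx[v]] = exog_var[v]
        for v in dag.endogenous:
            Psi[idx[v], idx[v]] = resid_var[v]
        for (u, w), c in exog_cov.items():
            Psi[idx[u], idx[w]] = Psi[idx[w], idx[u]] = c
        A = np.linalg.inv(np.eye(p) - B)
        Sigma = A @ Psi @ A.T
        S = np.empty((p, p))
        for a in dag.nodes:
            for b in dag.nodes:
                S[idx[a], idx[b]] = _cov(cdata[a], cdata[b])
        t_cov = n_edges + p + n_corr
        df = p * (p + 1) // 2 - t_cov
        if df < 0:
            raise PathModelError("over-parameterized model (negative df)")
        sgn_s, ld_s = np.linalg.slogdet(S)
        sgn_i, ld_i = np.linalg.slogdet(Sigma)
        fml = float(ld_i + np.trace(S @ np.linalg.inv(Sigma)) - ld_s - p)
        self.chi2_ = max(0.0, n * fml)
        self.chi2_df_ = int(df)
        self.chi2_p_ = 1.0 if df == 0 else float(stats.chi2.sf(self.chi2_, df))
        self.implied_cov_ = pd.DataFrame(Sigma, index=dag.nodes, columns=dag.nodes)
        self.sample_cov_ = pd.DataFrame(S, index=dag.nodes, columns=dag.nodes)
        self.residual_variances_ = resid_var
        self.converged_ = True
        return self

    # -- reporting -----------------------------------------------------
    def coefficient_map(self) -> dict[tuple[str, str], float]:
        return {
            (r["from"], r["to"]): r["coef"]
            for r in self.coefficients_.to_dict("records")
        }

    def effects(self, pairs=None) -> pd.DataFrame:
        return decompose_effects(self.dag, self.coefficient_map(), pairs=pairs)

    def summary(self) -> dict:
        return {
            "name": self.dag.name,
            "n": self.n_,
            "q": self.q_,
            "C": self.c_statistic_,
            "C_p": self.c_p_value_,
            "CICc": self.cicc_,
            "loglik": self.loglik_,
            "AIC": self.aic_,
            "chi2": self.chi2_,
            "chi2_df": self.chi2_df_,
            "chi2_p": self.chi2_p_,
            "missing_path": self.missing_path_,
        }


def fit_path_model(
    dag: CausalDAG,
    data: pd.DataFrame,
    mode: str = "contrasts-ols",
    tree: Tree | None = None,
    standardize: bool = True,
) -> PathModel:
    """Thin functional wrapper: fit a :class:`PathModel` and return it."""
    return PathModel(dag=dag, mode=mode, tree=tree, standardize=standardize).fit(data)


def decompose_effects(
    dag: CausalDAG,
    coefficients: Mapping[tuple[str, str], float],
    pairs: Iterable[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Direct / indirect / total effects between variable pairs.

    direct = the edge coefficient (0 if the edge is absent); indirect = the
    sum over directed paths of length >= 2 of the product of coefficients
    along the path; total = direct + indirect.
    """
    for (u, v) in coefficients:
        if not dag.graph.has_edge(u, v):
            raise PathModelError(f"coefficient for non-edge {u}->{v}")
    for u, v in dag.edges:
        if (u, v) not in coefficients:
            raise PathModelError(f"missing coefficient for edge {u}->{v}")
    if pairs is None:
        order = dag.causal_order()
        pairs = [
            (x, y)
            for i, x in enumerate(order)
            for y in order[i + 1 :]
            if nx.has_path(dag.graph, x, y)
        ]
    rows = []
    for x, y in pairs:
        if x not in dag.nodes or y not in dag.nodes:
            raise PathModelError(f"unknown variable pair ({x}, {y})")
        direct = float(coefficients.get((x, y), 0.0))
        indirect = 0.0
        for path in nx.all_simple_paths(dag.graph, x, y):
            if len(path) < 3:
                continue
            prod = 1.0
            for u, v in zip(path[:-1], path[1:]):
                prod *= coefficients[(u, v)]
            indirect += prod
        rows.append(
            {
                "from": x,
                "to": y,
                "direct": direct,
                "indirect": indirect,
                "total": direct + indirect,
            }
        )
    return pd.DataFrame(rows, columns=["from", "to", "direct", "indirect", "total"])


def compare_models(fits: Sequence[PathModel], criterion: str = "cicc") -> pd.DataFrame:
    """Rank fitted models by CICc or AIC (ascending), with a delta column
    relative to the best model."""
    if len(fits) < 2:
        raise PathModelError("need at least two fitted models to compare")
    ns = {f.n_ for f in fits}
    if len(ns) != 1:
        raise PathModelError(f"models fitted to different n: {sorted(ns)}")
    key = {"cicc": "CICc", "aic": "AIC"}.get(criterion.lower())
    if key is None:
        raise PathModelError("criterion must be 'cicc' or 'aic'")
    rows = [f.summary() for f in fits]
    for i, r in enumerate(rows):
        r["name"] = r["name"] or f"model_{i+1}"
    df = pd.DataFrame(rows).sort_values(key, kind="stable").reset_index(drop=True)
    df["delta"] = df[key] - df[key].iloc[0]
    return df
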