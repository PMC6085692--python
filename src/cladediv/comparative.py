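"""Phylogenetic comparative statistics.

Implements the model-fitting layer of the analysis:

* species (clade) ages read off an ultrametric chronogram — stem age (time of
  the split from the sister lineage) by default, crown age on request;
* a Brownian-motion covariance matrix among clades, built either from an
  ultrametric tree directly or from a pairwise genetic distance matrix via
  UPGMA ultrametrization (``C_ij = T − u_ij / 2`` with ``T = max(u)/2``);
* generalized least squares under that covariance (PGLS) with the residual
  variance profiled out by maximum likelihood, sequential (type-I) F tests,
  likelihood-ratio tests between nested fits, and backward stepwise model
  reduction driven by those LRTs;
* the Pearson correlation t-test used for collinearity diagnostics.

ML (not REML) estimation is used throughout because the LRTs compare
fixed-effect structures.
"""
from __future__ import annotations

import itertools
import logging
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from typing import NamedTuple

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, stats

from .distance import DistanceMatrix
from .trees import is_ultrametric, node_depths

__all__ = [
    "CovarianceSpec",
    "PGLSFit",
    "LRTResult",
    "StepwiseResult",
    "CorrelationResult",
    "species_age",
    "brownian_covariance",
    "brownian_covariance_from_tree",
    "pgls_fit",
    "lrt",
    "backward_stepwise",
    "correlation_test",
    "pearson_correlation",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Species ages
# ---------------------------------------------------------------------------

def species_age(
    chronogram: dendropy.Tree,
    clade_map: Mapping[str, str],
    mode: str = "stem",
) -> pd.Series:
    """Age (time units of the chronogram) of each clade.

    ``clade_map`` maps chronogram tip labels to clade ids; tips absent from
    the map are ignored. Stem age is the height of the parent of the clade's
    MRCA (the split from its sister lineage); crown age is the height of the
    MRCA itself. Each clade must be monophyletic in the chronogram.
    """
    if mode not in ("stem", "crown"):
        raise ValueError(f"mode must be 'stem' or 'crown', got {mode!r}")
    depths = node_depths(chronogram)
    leaves = list(chronogram.leaf_node_iter())
    tip_depth = {leaf.taxon.label: depths[leaf] for leaf in leaves}
    depth = max(tip_depth.values())
    if depth <= 0:
        raise ValueError("chronogram has zero depth")
    if (max(tip_depth.values()) - min(tip_depth.values())) > 1e-6 * depth:
        raise ValueError("chronogram is not ultrametric (tip depth spread > 1e-6 x depth)")
    missing = sorted(set(clade_map) - set(tip_depth))
    if missing:
        raise KeyError(f"clade map references tips absent from chronogram: {missing}")
    clades: dict[str, list[str]] = {}
    for tip, clade in clade_map.items():
        clades.setdefault(str(clade), []).append(tip)

    ages: dict[str, float] = {}
    for clade in sorted(clades):
        tips = set(clades[clade])
        mrca = chronogram.mrca(taxon_labels=list(tips))
        under = {leaf.taxon.label for leaf in mrca.leaf_iter()}
        intruders = sorted(under - tips)
        if intruders:
            raise ValueError(f"clade {clade!r} is not monophyletic; intruding tips: {intruders}")
        use_mode = mode
        if mode == "crown" and len(tips) == 1:
            warnings.warn(
                f"crown age undefined for single-tip clade {clade!r}; using stem age",
                stacklevel=2,
            )
            use_mode = "stem"
        if use_mode == "crown":
            ages[clade] = depth - depths[mrca]
        else:
            parent = mrca.parent_node
            ages[clade] = depth if parent is None else depth - depths[parent]
    return pd.Series(ages, name=f"{mode}_age").sort_index()


# ---------------------------------------------------------------------------
# Brownian covariance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovarianceSpec:
    """Brownian trait covariance among clades plus construction metadata."""

    labels: tuple[str, ...]
    matrix: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.labels):
            raise ValueError("covariance matrix shape does not match labels")
        scale = max(1.0, float(np.abs(m).max()))
        if not np.allclose(m, m.T, rtol=0.0, atol=1e-10 * scale):
            raise ValueError("covariance matrix is not symmetric")
        diag = np.diagonal(m)
        if (diag.max() - diag.min()) > 1e-6 * max(diag.max(), 1e-300):
            raise ValueError("covariance diagonal is not constant (tree not ultrametric)")
        if np.linalg.eigvalsh(m).min() < -1e-10 * scale:
            raise ValueError("covariance matrix is not positive semi-definite")
        m = m.copy()
        m.flags.writeable = False
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        object.__setattr__(self, "matrix", m)

    @property
    def depth(self) -> float:
        """Root-to-tip path length T (the constant diagonal)."""
        return float(np.diagonal(self.matrix).mean())

    def submatrix(self, labels: Sequence[str]) -> "CovarianceSpec":
        idx = [self.labels.index(x) for x in labels]
        return CovarianceSpec(tuple(labels), self.matrix[np.ix_(idx, idx)], dict(self.meta))


def upgma_cophenetic(dm: DistanceMatrix) -> np.ndarray:
    """Cophenetic (ultrametric) distances from UPGMA clustering.

    Average linkage with merge height d/2; tied merge candidates are resolved
    by the lexicographically smallest pair of cluster labels (each cluster
    is identified by its smallest member label), so the result is fully
    deterministic.
    """
    n = dm.n
    if n < 2:
        raise ValueError("UPGMA needs at least 2 labels")
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    minlab: dict[int, str] = {i: dm.labels[i] for i in range(n)}
    dist: dict[frozenset[int], float] = {
        frozenset((i, j)): float(dm.values[i, j]) for i, j in itertools.combinations(range(n), 2)
    }
    coph = np.zeros((n, n), dtype=float)
    active = set(range(n))
    next_id = n
    while len(active) > 1:
        best_key, best_d, best_labpair = None, np.inf, None
        for key, d in dist.items():
            a, b = sorted(key, key=lambda c: minlab[c])
            labpair = (minlab[a], minlab[b])
            if d < best_d or (d == best_d and labpair < best_labpair):
                best_key, best_d, best_labpair = key, d, labpair
        a, b = tuple(best_key)
        for i in members[a]:
            for j in members[b]:
                coph[i, j] = coph[j, i] = best_d
        na, nb = len(members[a]), len(members[b])
        new = next_id
        next_id += 1
        members[new] = members[a] + members[b]
        minlab[new] = min(minlab[a], minlab[b])
        active -= {a, b}
        for k in active:
            dist[frozenset((new, k))] = (
                na * dist.pop(frozenset((a, k))) + nb * dist.pop(frozenset((b, k)))
            ) / (na + nb)
        del dist[best_key]
        active.add(new)
    return coph


def brownian_covariance(dm: DistanceMatrix) -> CovarianceSpec:
    """Brownian covariance from a pairwise genetic distance matrix.

    The distances are first made ultrametric by UPGMA; with cophenetic
    distances ``u`` and tree depth ``T = max(u)/2``, the shared path length
    from the root is ``C_ij = T − u_ij/2`` and ``C_ii = T``.
    """
    u = upgma_cophenetic(dm)
    t = float(u.max()) / 2.0
    c = t - u / 2.0
    np.fill_diagonal(c, t)
    return CovarianceSpec(dm.labels, c, {"method": "upgma", "depth": t})


def brownian_covariance_from_tree(
    tree: dendropy.Tree, clade_map: Mapping[str, str] | None = None
) -> CovarianceSpec:
    """Brownian covariance directly from an ultrametric tree.

    ``C_ij`` is the root-to-MRCA depth shared by tips i and j. With
    ``clade_map`` the tree is restricted to the mapped tips and relabeled to
    clade ids (one tip per clade required).
    """
    if clade_map is not None:
        inv: dict[str, str] = {}
        for tip, clade in clade_map.items():
            if clade in inv.values():
                raise ValueError("brownian_covariance_from_tree requires one tip per clade")
            inv[tip] = str(clade)
        tree = tree.extract_tree_with_taxa_labels(list(inv))
        for leaf in tree.leaf_node_iter():
            leaf.taxon.label = inv[leaf.taxon.label]
    if not is_ultrametric(tree):
        raise ValueError("tree is not ultrametric")
    depths = node_depths(tree)
    leaves = list(tree.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in leaves]
    index = {leaf: i for i, leaf in enumerate(leaves)}
    n = len(leaves)
    c = np.zeros((n, n), dtype=float)
    for i, leaf in enumerate(leaves):
        c[i, i] = depths[leaf]
    for node in tree.postorder_internal_node_iter():
        kids = node.child_nodes()
        tip_sets = [[index[lf] for lf in child.leaf_iter()] for child in kids]
        for sa, sb in itertools.combinations(tip_sets, 2):
            for i in sa:
                for j in sb:
                    c[i, j] = c[j, i] = depths[node]
    order = np.argsort(labels)
    labels = [labels[i] for i in order]
    c = c[np.ix_(order, order)]
    # enforce an exactly constant diagonal (ultrametric to 1e-6 already)
    t = float(np.diagonal(c).mean())
    np.fill_diagonal(c, t)
    return CovarianceSpec(tuple(labels), c, {"method": "tree", "depth": t})


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

def _is_categorical(col: pd.Series) -> bool:
    return col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == bool


def _factor_columns(data: pd.DataFrame, name: str) -> tuple[list[str], np.ndarray]:
    if name not in data.columns:
        raise KeyError(f"model term {name!r} not a column of the data")
    col = data[name]
    if _is_categorical(col):
        levels = sorted(col.astype(str).unique())
        ref = levels[0]  # reference level: alphabetically first
        names = [f"{name}[{lv}]" for lv in levels[1:]]
        mat = np.column_stack([(col.astype(str) == lv).to_numpy(float) for lv in levels[1:]])
        if not names:
            raise ValueError(f"categorical term {name!r} has a single level ({ref!r})")
        return names, mat
    return [name], col.to_numpy(dtype=float)[:, None]


def _term_columns(data: pd.DataFrame, term: str) -> tuple[list[str], np.ndarray]:
    parts = term.split(":")
    names, mat = _factor_columns(data, parts[0])
    for part in parts[1:]:
        pnames, pmat = _factor_columns(data, part)
        names = [f"{a}:{b}" for a in names for b in pnames]
        mat = np.concatenate(
            [mat[:, [i]] * pmat[:, [j]] for i in range(mat.shape[1]) for j in range(pmat.shape[1])],
            axis=1,
        )
    return names, mat


def build_design(
    data: pd.DataFrame, terms: Sequence[str]
) -> tuple[list[str], np.ndarray, list[int]]:
    """Design matrix with intercept; returns (column names, X, df per term)."""
    names = ["(Intercept)"]
    blocks = [np.ones((len(data), 1))]
    dfs: list[int] = []
    for term in terms:
        tnames, tmat = _term_columns(data, term)
        names.extend(tnames)
        blocks.append(tmat)
        dfs.append(tmat.shape[1])
    return names, np.concatenate(blocks, axis=1), dfs


@dataclass(frozen=True)
class PGLSFit:
    """A fitted phylogenetic GLS model."""

    terms: tuple[str, ...]
    response: str
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    anova: pd.DataFrame  # sequential (type-I) F tests, one row per term
    loglik: float
    n: int
    n_params: int
    sigma2_ml: float
    s2: float
    rss: float
    tss: float
    cov_meta: dict

    @property
    def df_resid(self) -> int:
        return self.n - self.n_params

    @property
    def saturated(self) -> bool:
        """True when the model fits perfectly to machine precision.

        Likelihoods (hence LRTs) are meaningless between saturated models:
        the residual sum of squares is numerical noise.
        """
        return self.rss <= 1e-20 * max(self.tss, 1e-300)

    def summary(self) -> str:
        lines = [
            f"PGLS fit: {self.response} ~ {' + '.join(self.terms) if self.terms else '1'}",
            f"n = {self.n}, parameters = {self.n_params}, "
            f"log-likelihood (ML) = {self.loglik:.6f}",
            "",
            "Coefficients:",
            pd.DataFrame(
                {
                    "estimate": self.params,
                    "std_error": self.bse,
                    "t": self.tvalues,
                    "p": self.pvalues,
                }
            ).to_string(float_format=lambda v: f"{v:.6g}"),
        ]
        if len(self.anova):
            lines += ["", "Sequential (type-I) F tests:",
                      self.anova.to_string(index=False, float_format=lambda v: f"{v:.6g}")]
        return "\n".join(lines)


def _whiten(cov: CovarianceSpec, jitter: float = 1e-10) -> tuple[np.ndarray, float]:
    """Cholesky factor of the correlation-scaled covariance and its log-det."""
    cstar = cov.matrix / cov.depth
    try:
        chol = linalg.cholesky(cstar, lower=True)
    except linalg.LinAlgError:
        logger.warning("covariance not positive definite; adding diagonal jitter %.1e", jitter)
        chol = linalg.cholesky(cstar + jitter * np.eye(cov.matrix.shape[0]), lower=True)
    logdet = 2.0 * float(np.sum(np.log(np.diagonal(chol))))
    return chol, logdet


def pgls_fit(
    data: pd.DataFrame,
    terms: Sequence[str],
    cov: CovarianceSpec,
    *,
    response: str = "avg_divergence",
    clade_col: str = "clade",
) -> PGLSFit:
    """Fit a PGLS regression of ``response`` on ``terms`` under covariance ``cov``.

    Terms are column names of ``data``; ``a:b`` denotes an interaction.
    Categorical columns are dummy-coded against the alphabetically first
    level. β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y with σ² profiled out by ML; standard errors
    and t/F statistics use the df-corrected residual variance so that with an
    identity covariance the output coincides with OLS.
    """
    df = data.set_index(data[clade_col].astype(str)) if clade_col in data.columns else data
    missing = [lbl for lbl in cov.labels if lbl not in df.index]
    if missing:
        raise KeyError(f"data rows missing for clades: {missing}")
    df = df.loc[list(cov.labels)]
    if df[response].isna().any():
        raise ValueError(f"missing values in response {response!r}")
    y = df[response].to_numpy(dtype=float)
    names, x, term_dfs = build_design(df, terms)
    n, p = x.shape
    if n <= p:
        raise ValueError(f"n={n} is not greater than the number of parameters ({p})")
    chol, logdet = _whiten(cov)
    xw = linalg.solve_triangular(chol, x, lower=True)
    yw = linalg.solve_triangular(chol, y, lower=True)
    if np.linalg.matrix_rank(xw) < p:
        raise ValueError(f"singular design matrix; check collinearity among terms {list(terms)}")
    xtx = xw.T @ xw
    beta = linalg.solve(xtx, xw.T @ yw, assume_a="pos")
    resid = yw - xw @ beta
    rss = float(resid @ resid)
    b0 = float(np.linalg.lstsq(xw[:, [0]], yw, rcond=None)[0][0])
    ybar = yw - xw[:, 0] * b0
    tss = float(ybar @ ybar)
    sigma2_ml = rss / n
    s2 = rss / (n - p)
    loglik = -0.5 * n * np.log(2.0 * np.pi * sigma2_ml) - 0.5 * logdet - 0.5 * n
    cov_beta = s2 * linalg.inv(xtx)
    bse = np.sqrt(np.diagonal(cov_beta))
    tvals = beta / bse
    pvals = 2.0 * stats.t.sf(np.abs(tvals), n - p)

    # sequential (type-I) F tests: terms added in formula order
    rss_seq = []
    for k in range(len(terms) + 1):
        ncols = 1 + sum(term_dfs[:k])
        xk = xw[:, :ncols]
        bk, rss_k, *_ = np.linalg.lstsq(xk, yw, rcond=None)
        rk = yw - xk @ bk
        rss_seq.append(float(rk @ rk))
    rows = []
    for k, term in enumerate(terms):
        dfk = term_dfs[k]
        fstat = ((rss_seq[k] - rss_seq[k + 1]) / dfk) / s2
        rows.append(
            {
                "term": term,
                "df": dfk,
                "F": fstat,
                "p": float(stats.f.sf(fstat, dfk, n - p)),
            }
        )
    anova = pd.DataFrame(rows, columns=["term", "df", "F", "p"])
    idx = pd.Index(names, name="coef")
    return PGLSFit(
        terms=tuple(terms),
        response=response,
        params=pd.Series(beta, index=idx),
        bse=pd.Series(bse, index=idx),
        tvalues=pd.Series(tvals, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        anova=anova,
        loglik=float(loglik),
        n=n,
        n_params=p,
        sigma2_ml=sigma2_ml,
        s2=s2,
        rss=rss,
        tss=tss,
        cov_meta=dict(cov.meta),
    )


class LRTResult(NamedTuple):
    statistic: float
    df: int
    p: float


def lrt(full: PGLSFit, reduced: PGLSFit) -> LRTResult:
    """Likelihood-ratio test between nested ML fits on identical data."""
    if not set(reduced.terms) <= set(full.terms):
        raise ValueError(
            f"models are not nested: {sorted(set(reduced.terms) - set(full.terms))} "
            "present only in the reduced model"
        )
    if full.n != reduced.n or full.response != reduced.response:
        raise ValueError("models were fitted to different data")
    df = full.n_params - reduced.n_params
    if full.saturated and reduced.saturated:
        # both fits are perfect to machine precision; the dropped term adds nothing
        return LRTResult(0.0, df, 1.0)
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -1e-8 * max(1.0, abs(full.loglik)):
        raise ValueError("reduced model has higher likelihood; models are not nested as fitted")
    stat = max(stat, 0.0)
    if df == 0:
        return LRTResult(stat, 0, 1.0)
    return LRTResult(stat, df, float(stats.chi2.sf(stat, df)))


@dataclass(frozen=True)
class StepwiseResult:
    final: PGLSFit
    full: PGLSFit
    trace: pd.DataFrame  # columns: step, term, statistic, df, p, rule


def _droppable(current: Sequence[str]) -> list[str]:
    """Terms removable now: interactions always; mains only when free of them."""
    out = []
    for t in current:
        if ":" in t:
            out.append(t)
        else:
            in_interaction = any(t in o.split(":") for o in current if ":" in o and o != t)
            if not in_interaction:
                out.append(t)
    return out


def backward_stepwise(
    data: pd.DataFrame,
    full_terms: Sequence[str],
    cov: CovarianceSpec,
    alpha: float = 0.05,
    *,
    response: str = "avg_divergence",
    clade_col: str = "clade",
) -> StepwiseResult:
    """Backward model reduction by likelihood-ratio tests.

    At each step the droppable term with the largest LRT p-value above
    ``alpha`` is removed (interaction terms before the main effects they
    contain). A main effect kept only because a retained interaction contains
    it is finally dropped unless it was itself significant in the full model
    (judged by the LRT of removing it alone from the full model).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")

    def fit(terms: Sequence[str]) -> PGLSFit:
        return pgls_fit(data, terms, cov, response=response, clade_col=clade_col)

    full_fit = fit(full_terms)
    full_drop_p = {}
    for term in full_terms:
        reduced = fit([t for t in full_terms if t != term])
        full_drop_p[term] = lrt(full_fit, reduced).p

    current = list(full_terms)
    cur_fit = full_fit
    trace_rows = []
    step = 0
    while current:
        candidates = []
        for term in _droppable(current):
            reduced_fit = fit([t for t in current if t != term])
            res = lrt(cur_fit, reduced_fit)
            candidates.append((res.p, term, res, reduced_fit))
        candidates.sort(key=lambda c: (-c[0], c[1]))
        best_p, term, res, reduced_fit = candidates[0]
        if best_p <= alpha:
            break
        step += 1
        trace_rows.append(
            {
                "step": step, "term": term, "statistic": res.statistic,
                "df": res.df, "p": res.p, "rule": "lrt",
            }
        )
        current = [t for t in current if t != term]
        cur_fit = reduced_fit
    # main effects retained only through an interaction must have been
    # significant in the full model to stay
    for term in [t for t in current if ":" not in t]:
        in_interaction = any(term in o.split(":") for o in current if ":" in o)
        if in_interaction and full_drop_p[term] > alpha:
            step += 1
            trace_rows.append(
                {
                    "step": step, "term": term, "statistic": np.nan, "df": 0,
                    "p": full_drop_p[term], "rule": "not-significant-in-full-model",
                }
            )
            current = [t for t in current if t != term]
    final_fit = fit(current) if trace_rows else cur_fit
    trace = pd.DataFrame(trace_rows, columns=["step", "term", "statistic", "df", "p", "rule"])
    return StepwiseResult(final=final_fit, full=full_fit, trace=trace)


# ---------------------------------------------------------------------------
# Correlation diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    r: float
    df: int
    t: float
    p: float


def correlation_test(r: float, df: int) -> CorrelationResult:
    """t-test of a Pearson correlation: t = r·sqrt(df)/sqrt(1−r²), two-sided p.

    |r| ≥ 1 yields an infinite t and p = 0 (documented convention).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if abs(r) >= 1.0:
        return CorrelationResult(float(r), int(df), float(np.sign(r)) * np.inf, 0.0)
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return CorrelationResult(float(r), int(df), float(t), p)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation of paired data with its t-test (df = n − 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    r = float(np.corrcoef(x, y)[0, 1])
    return correlation_test(r, len(x) - 2)
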