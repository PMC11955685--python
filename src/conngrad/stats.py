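"""Group comparison statistics for gradient maps.

The workhorse is a multivariate general linear model: for responses Y
(subjects x k gradient scores) and design X (intercept, group, age, sex),
the group effect across the k gradients jointly is tested with Hotelling's
T-squared on the group contrast, referenced to an exact F distribution under
Gaussian errors.  Univariate (single-gradient) comparisons use the same
design with OLS t-tests.  Families of tests are corrected with
Benjamini-Hochberg FDR; per-gradient post-hoc contributions use Bonferroni
over the number of gradients analyzed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .io import CORTICAL_NETWORKS, RegionTable

__all__ = [
    "DesignMatrix",
    "StatMap",
    "design_matrix",
    "network_average",
    "hotelling_test",
    "univariate_test",
    "fdr_bh",
    "posthoc_bonferroni",
    "decode_term_maps",
    "multivariate_map",
    "univariate_map",
]


@dataclass
class DesignMatrix:
    """Columns: intercept, group (patient=1), age, sex (male=1)."""

    values: np.ndarray
    columns: list = field(default_factory=lambda: ["intercept", "group", "age", "sex"])
    group_col: int = 1

    def __post_init__(self):
        x = np.asarray(self.values, dtype=float)
        if x.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError("design matrix is rank deficient")
        g = x[:, self.group_col]
        if not np.isin(g, (0.0, 1.0)).all():
            raise ValueError("group column must be binary 0/1")
        self.values = x

    @property
    def n(self):
        return self.values.shape[0]

    @property
    def rank(self):
        return self.values.shape[1]


def design_matrix(manifest_table: pd.DataFrame, covariates=True) -> DesignMatrix:
    """Build the standard design from a cohort manifest table.

    Coding: patient=1/control=0, male=1/female=0 (coefficient signs depend
    on this, so it is fixed here rather than left to the caller).
    """
    t = manifest_table
    group = (t["group"].to_numpy() == "patient").astype(float)
    cols = [np.ones(len(t)), group]
    names = ["intercept", "group"]
    if covariates:
        cols.append(t["age"].to_numpy(float))
        cols.append((t["sex"].to_numpy() == "male").astype(float))
        names += ["age", "sex"]
    return DesignMatrix(np.column_stack(cols), columns=names)


@dataclass
class StatMap:
    """Per-unit statistic / p / q / significance for one comparison family."""

    table: pd.DataFrame  # columns: unit, statistic, p, q, significant
    family: str = ""
    alpha: float = 0.05

    def to_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False, float_format="%.17g")
        return path


# ---------------------------------------------------------------------------
# primitives


def network_average(coordinates, region_table: RegionTable, networks=CORTICAL_NETWORKS):
    """Mean gradient score over the regions of each functional network.

    Returns a networks x k array in the canonical network order.
    """
    coords = np.asarray(coordinates, dtype=float)
    labels = region_table.cortical().networks
    if len(labels) != coords.shape[0]:
        raise ValueError("coordinate rows must match cortical region count")
    out = np.empty((len(networks), coords.shape[1]))
    for i, net in enumerate(networks):
        mask = labels == net
        if not mask.any():
            raise ValueError(f"network {net!r} has no regions")
        out[i] = coords[mask].mean(axis=0)
    return out


def hotelling_test(Y, design: DesignMatrix):
    """Hotelling's T-squared for the group contrast in a multivariate GLM.

    Fits Y = X beta + E by least squares; with c the group contrast,
    ``T2 = (c beta)' [c (X'X)^-1 c' * Sigma]^-1 (c beta)`` where
    ``Sigma = E'E / (n - rank(X))``.  The exact F reference is
    ``F = T2 (n - p - k + 1) / (k (n - p))`` with (k, n - p - k + 1) df.
    With no covariates this reduces to the classical two-sample T-squared.

    Returns (T2, F, p).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    X = design.values
    n, k = Y.shape
    p = design.rank
    if n <= p + k:
        raise ValueError("need n_subjects > rank(X) + n_responses")
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    sigma = resid.T @ resid / (n - p)
    c = np.zeros(p)
    c[design.group_col] = 1.0
    d = c @ beta  # estimated group effect across the k responses
    g = float(c @ xtx_inv @ c)
    try:
        sol = np.linalg.solve(sigma, d)
    except np.linalg.LinAlgError:
        raise ValueError(
            "singular error covariance: add subjects or reduce responses"
        ) from None
    cond = np.linalg.cond(sigma)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError("singular error covariance: add subjects or reduce responses")
    t2 = float(d @ sol / g)
    df2 = n - p - k + 1
    f = t2 * df2 / (k * (n - p))
    pval = float(sstats.f.sf(f, k, df2))
    return t2, f, pval


def univariate_test(y, design: DesignMatrix):
    """OLS t-test (two-sided) for the group coefficient on one response."""
    y = np.asarray(y, dtype=float).ravel()
    X = design.values
    n, p = X.shape
    if len(y) != n:
        raise ValueError("response length must match design rows")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - p
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = rss / df
    # rss at roundoff scale relative to the response magnitude means an
    # exactly-fitted (e.g. constant) response
    if rss <= n * np.finfo(float).eps ** 2 * max(1.0, float(y @ y)):
        raise ValueError("zero residual variance: t statistic undefined")
    se = np.sqrt(sigma2 * xtx_inv[design.group_col, design.group_col])
    t = float(beta[design.group_col] / se)
    pval = float(2 * sstats.t.sf(abs(t), df))
    return t, pval


def fdr_bh(p):
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def posthoc_bonferroni(p, n_tests=3, alpha=0.05):
    """Significance flags at the Bonferroni-corrected alpha/n_tests level."""
    p = np.asarray(p, dtype=float)
    return p < alpha / n_tests


def decode_term_maps(thresholded_map, term_maps, term_names=None, top_n=15):
    """Rank externally supplied term maps by correlation with a stat map.

    ``thresholded_map`` is the region-level statistic map with non-significant
    regions already set to zero.  Constant term maps (undefined correlation)
    are excluded with a warning.  Returns a list of (term, r) sorted by
    descending correlation, truncated to ``top_n``.
    """
    tmap = np.asarray(thresholded_map, dtype=float)
    maps = np.atleast_2d(np.asarray(term_maps, dtype=float))
    if maps.shape[1] != tmap.size:
        raise ValueError("term maps must have one column per region")
    if term_names is None:
        term_names = [f"term_{i}" for i in range(maps.shape[0])]
    if np.std(tmap) == 0:
        raise ValueError("thresholded map is constant; correlation undefined")
    out = []
    for name, m in zip(term_names, maps):
        if np.std(m) == 0:
            warnings.warn(f"term map {name!r} is constant; excluded from decoding")
            continue
        out.append((name, float(sstats.pearsonr(tmap, m).statistic)))
    out.sort(key=lambda kv: -kv[1])
    return out[:top_n]


# ---------------------------------------------------------------------------
# map-level wrappers


def multivariate_map(scores, design: DesignMatrix, unit_labels, family="", alpha=0.05):
    """Hotelling test per unit over a subjects x units x k score stack."""
    scores = np.asarray(scores, dtype=float)
    n_units = scores.shape[1]
    if len(unit_labels) != n_units:
        raise ValueError("unit label count mismatch")
    t2s, ps = np.empty(n_units), np.empty(n_units)
    for u in range(n_units):
        t2, _, pv = hotelling_test(scores[:, u, :], design)
        t2s[u], ps[u] = t2, pv
    q = fdr_bh(ps)
    df = pd.DataFrame(
        {
            "unit": list(unit_labels),
            "statistic": t2s,
            "p": ps,
            "q": q,
            "significant": q < alpha,
        }
    )
    return StatMap(df, family=family, alpha=alpha)


def univariate_map(scores, design: DesignMatrix, unit_labels, family="", alpha=0.05):
    """OLS group t-test per unit over a subjects x units score matrix."""
    scores = np.asarray(scores, dtype=float)
    n_units = scores.shape[1]
    ts, ps = np.empty(n_units), np.empty(n_units)
    for u in range(n_units):
        ts[u], ps[u] = univariate_test(scores[:, u], design)
    q = fdr_bh(ps)
    df = pd.DataFrame(
        {
            "unit": list(unit_labels),
            "statistic": ts,
            "p": ps,
            "q": q,
            "significant": q < alpha,
        }
    )
    return StatMap(df, family=family, alpha=alpha)
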