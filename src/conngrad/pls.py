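"""Partial least squares linking gene expression to a spatial response map.

Single-response PLS regression: components are extracted sequentially, each
weight vector maximizing covariance between the expression projection and
the response, with deflation of the predictor matrix between components
(NIPALS-equivalent for one response; the first component weight vector is
proportional to X'y, which serves as a closed-form cross-check).

Inference layers:

* component variance explained, with a permutation test (spin or shuffle
  null on the response map);
* spatial correlation of component region scores with the response,
  spin-tested;
* per-gene bootstrap Z (weight / SD over region resamples, with mandatory
  sign re-alignment of each bootstrap component against the original —
  without it component sign flips inflate the SD and destroy calibration);
* signed significant gene sets (two-sided normal test on Z, BH-FDR), with
  the realized |Z| threshold at the FDR boundary reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .nulls import spin_correlation_test, spin_permutations
from .stats import fdr_bh

__all__ = [
    "PLSResult",
    "fit_pls",
    "permutation_test_varexp",
    "spatial_correlation_of_scores",
    "bootstrap_weights",
    "select_genes",
    "standardize_columns",
]

logger = logging.getLogger(__name__)


@dataclass
class PLSResult:
    """Weights, region scores and variance explained of a fitted PLS model."""

    weights: np.ndarray  # genes x n_components, unit norm per component
    region_scores: np.ndarray  # regions x n_components
    varexp: np.ndarray  # per-component incremental R^2 of the response
    weight_norms: np.ndarray | None = None  # covariance-scale norm per component
    perm_p: dict = field(default_factory=dict)
    boot_z: np.ndarray | None = None
    selected_component: int | None = None

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def select_component(self):
        """Pick the component explaining the most response variance."""
        self.selected_component = int(np.argmax(self.varexp))
        return self.selected_component


def standardize_columns(x):
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    if (sd == 0).any():
        raise ValueError("constant column cannot be standardized")
    return (x - mu) / sd


def fit_pls(X, y, n_components=2) -> PLSResult:
    """Fit single-response PLS with sequential deflation.

    ``varexp[c]`` is the incremental R^2 of y on scores 1..c+1, so cumulative
    variance explained is ``varexp.cumsum()``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, g = X.shape
    if len(y) != n:
        raise ValueError("response length must match region count")
    if np.std(y) == 0:
        raise ValueError("constant response: PLS undefined")
    Xd = X - X.mean(axis=0)
    yd = y - y.mean()
    weights = np.zeros((g, n_components))
    scores = np.zeros((n, n_components))
    norms = np.zeros(n_components)
    for c in range(n_components):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm == 0:
            logger.warning("deflated covariance vanished at component %d", c)
            break
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        if tt == 0:
            break
        p_load = Xd.T @ t / tt
        Xd = Xd - np.outer(t, p_load)
        weights[:, c] = w
        scores[:, c] = t
        norms[c] = norm
    varexp = _incremental_r2(scores, yd)
    return PLSResult(weights, scores, varexp, weight_norms=norms)


def _incremental_r2(scores, y_centered):
    tss = float(y_centered @ y_centered)
    k = scores.shape[1]
    r2 = np.zeros(k)
    prev = 0.0
    for c in range(k):
        T = scores[:, : c + 1]
        beta, *_ = np.linalg.lstsq(T, y_centered, rcond=None)
        resid = y_centered - T @ beta
        cum = 1.0 - float(resid @ resid) / tss
        r2[c] = cum - prev
        prev = cum
    return r2


def permutation_test_varexp(
    X, y, n_components=2, n_perm=1000, null="spin",
    centroids=None, hemispheres=None, seed=None,
):
    """Permutation p-values for PLS variance explained.

    The null refits the model on permuted responses — spin permutations by
    default (preserving the map's spatial autocorrelation), plain shuffles
    optionally — and compares cumulative variance explained.  Returns a dict
    with the joint (cumulative over all components) p and per-component ps,
    all with the +1 correction.
    """
    y = np.asarray(y, dtype=float).ravel()
    obs = fit_pls(X, y, n_components)
    if null == "spin":
        if centroids is None:
            raise ValueError("spin null requires centroids")
        if hemispheres is None:
            hemispheres = np.asarray(["L"] * len(y))
        perms = spin_permutations(centroids, hemispheres, n_perm, seed)
    elif null == "shuffle":
        rng = np.random.default_rng(seed)
        perms = np.asarray([rng.permutation(len(y)) for _ in range(n_perm)])
    else:
        raise ValueError(f"unknown null {null!r}")
    null_cum = np.empty(n_perm)
    null_comp = np.empty((n_perm, n_components))
    for i, perm in enumerate(perms):
        res = fit_pls(X, y[perm], n_components)
        null_comp[i] = res.varexp
        null_cum[i] = res.varexp.sum()
    joint = (1.0 + np.sum(null_cum >= obs.varexp.sum())) / (1.0 + n_perm)
    per_comp = [
        float((1.0 + np.sum(null_comp[:, c] >= obs.varexp[c])) / (1.0 + n_perm))
        for c in range(n_components)
    ]
    return {"joint": float(joint), "per_component": per_comp}


def spatial_correlation_of_scores(
    result: PLSResult, component, y, centroids, hemispheres=None,
    n_perm=1000, seed=None,
):
    """Spin-tested Pearson correlation of component region scores with y."""
    scores = result.region_scores[:, component]
    if hemispheres is None:
        hemispheres = np.asarray(["L"] * len(scores))
    return spin_correlation_test(
        scores, np.asarray(y, float), centroids, hemispheres,
        n_perm=n_perm, seed=seed,
    )


def bootstrap_weights(X, y, component=0, n_boot=2000, seed=None, max_redraw=100):
    """Bootstrap Z score per gene for one PLS component.

    Regions are resampled with replacement; the model is refitted and each
    bootstrap weight vector re-signed to correlate positively with the
    original before the SD is accumulated.  Degenerate resamples (constant
    response or fewer than two distinct regions) are redrawn and counted.

    Z = original weight / bootstrap SD, with both taken on the
    covariance scale (unit weight times its extraction norm).  Bootstrapping
    the unit-normalized vectors instead would shrink every component's SD by
    the systematic noise inflation of the resampled vector norm (norm
    accumulated over all genes, sizeable when genes outnumber regions) and
    leave the null Z overdispersed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    n_components = component + 1
    orig = fit_pls(X, y, n_components)
    w0 = orig.weights[:, component] * orig.weight_norms[component]
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, len(w0)))
    redraws = 0
    for b in range(n_boot):
        for _ in range(max_redraw):
            idx = rng.integers(0, n, n)
            if len(np.unique(idx)) >= 2 and np.std(y[idx]) > 0:
                break
            redraws += 1
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap resample")
        res = fit_pls(X[idx], y[idx], n_components)
        wb = res.weights[:, component] * res.weight_norms[component]
        if wb @ w0 < 0:
            wb = -wb
        boots[b] = wb
    if redraws:
        logger.info("bootstrap: %d degenerate resamples redrawn", redraws)
    sd = boots.std(axis=0, ddof=1)
    tiny = np.finfo(float).tiny
    return w0 / np.maximum(sd, tiny)


def select_genes(boot_z, gene_ids=None, alpha=0.05):
    """Signed significant gene sets from bootstrap Z scores.

    Two-sided normal p per gene, BH-FDR across genes; significant genes are
    split by the sign of Z.  Returns (plus_ids, minus_ids, z_threshold) where
    z_threshold is the smallest |Z| among selected genes (inf if none).
    """
    z = np.asarray(boot_z, dtype=float)
    if gene_ids is None:
        gene_ids = np.arange(len(z))
    gene_ids = np.asarray(gene_ids)
    p = 2.0 * sstats.norm.sf(np.abs(z))
    q = fdr_bh(p)
    sig = q < alpha
    plus = gene_ids[sig & (z > 0)]
    minus = gene_ids[sig & (z < 0)]
    z_threshold = float(np.min(np.abs(z[sig]))) if sig.any() else float("inf")
    return plus, minus, z_threshold
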