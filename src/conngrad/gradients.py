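"""Connectome gradient mapping.

Pipeline: connectivity-profile affinity -> anisotropic diffusion-map
embedding -> group template -> orthogonal Procrustes alignment of individual
gradients to the template.

The embedding follows the standard diffusion-maps construction.  Given a
non-negative symmetric affinity W with degree diagonal D:

    W' = D^(-alpha) W D^(-alpha)          (anisotropic normalization)
    P  = D'^(-1) W'                        (row-stochastic random walk)

The gradients are the leading nontrivial right eigenvectors of P, scaled by
``lambda^t`` for diffusion time t >= 1 and by the multi-scale weight
``lambda / (1 - lambda)`` for t = 0.  ``alpha`` interpolates between graph
Laplacian (0) and Laplace-Beltrami (1) normalization; ``alpha = 0.5``
approximates the Fokker-Planck operator and preserves global relationships.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from scipy.linalg import eigh, svd
from scipy.sparse.csgraph import connected_components

from .io import Connectome, RegionTable, sparsify

__all__ = [
    "AffinityMatrix",
    "GradientSet",
    "AlignmentTransform",
    "compute_affinity",
    "diffusion_map_embed",
    "build_template",
    "procrustes_align",
    "align_cohort",
]

logger = logging.getLogger(__name__)

KERNELS = ("cosine", "spearman", "normalized_angle")


@dataclass
class AffinityMatrix:
    """Region x region connectivity-profile similarity in [0, 1]."""

    values: np.ndarray
    kernel: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("affinity must be square")
        if np.abs(v - v.T).max(initial=0.0) > 1e-10:
            raise ValueError("affinity must be symmetric")
        if (v < 0).any():
            raise ValueError("affinity must be non-negative")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("affinity diagonal must be 1")
        self.values = v


@dataclass
class GradientSet:
    """Low-dimensional embedding coordinates plus spectrum.

    ``coordinates`` is regions x k with gradients in descending order of
    explained variance (columns 0..2 are G1, G2, G3 in downstream analyses).
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    explained_variance: np.ndarray
    alpha: float = 0.5
    t: int = 0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be sorted non-increasing")
        ev = self.explained_variance
        if ((ev < -1e-12) | (ev > 1 + 1e-12)).any() or ev.sum() > 1 + 1e-8:
            raise ValueError("explained variance fractions must lie in [0, 1]")

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class AlignmentTransform:
    """Orthogonal rotation/reflection mapping one gradient basis onto another."""

    rotation: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        if np.abs(r.T @ r - np.eye(r.shape[1])).max() > 1e-8:
            raise ValueError("alignment transform must be orthogonal")
        self.rotation = r


# ---------------------------------------------------------------------------
# affinity


def compute_affinity(connectome: Connectome, kernel="cosine", sparsity=0.0):
    """Similarity of connectivity profiles between every pair of regions.

    For a pair (i, j) the profiles are rows i and j of the connectome with
    the entries at positions i and j removed, so that the (zero) diagonal
    never dilutes the similarity.  Negative similarities (possible for the
    rank-correlation kernel) are clipped to zero because the diffusion
    operator needs non-negative edge weights.

    The main analysis uses the raw, unthresholded connectome (``sparsity=0``);
    sparsity in (0, 1) first zeros that fraction of the weakest edges, a
    robustness variant.
    """
    if kernel not in KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}; choose from {KERNELS}")
    w = connectome.weights
    if sparsity:
        w = sparsify(w, sparsity)
    zero_rows = np.flatnonzero(~w.any(axis=1))
    if zero_rows.size:
        raise ValueError(
            f"disconnected region(s) with all-zero connectivity profile: "
            f"{zero_rows.tolist()}"
        )
    if kernel in ("cosine", "normalized_angle"):
        aff = _pairwise_cosine_excluding(w)
        if kernel == "normalized_angle":
            aff = 1.0 - np.arccos(np.clip(aff, -1.0, 1.0)) / np.pi
    else:
        aff = _pairwise_spearman_excluding(w)
    np.clip(aff, 0.0, None, out=aff)
    aff = 0.5 * (aff + aff.T)
    np.clip(aff, 0.0, 1.0, out=aff)
    np.fill_diagonal(aff, 1.0)
    return AffinityMatrix(aff, kernel)


def _pairwise_cosine_excluding(w):
    # with zero diagonal, excluding columns {i, j} leaves the dot product
    # untouched and subtracts w_ij^2 from each squared norm
    dot = w @ w.T
    sq = np.einsum("ij,ij->i", w, w)
    nsq = sq[:, None] - w**2
    denom = np.sqrt(nsq * nsq.T)
    with np.errstate(divide="ignore", invalid="ignore"):
        aff = dot / denom
    aff[~np.isfinite(aff)] = 0.0
    return aff


def _pairwise_spearman_excluding(w):
    n = w.shape[0]
    aff = np.eye(n)
    idx = np.arange(n)
    for i in range(n):
        for j in range(i + 1, n):
            keep = (idx != i) & (idx != j)
            r = sstats.spearmanr(w[i, keep], w[j, keep]).statistic
            if not np.isfinite(r):
                r = 0.0
            aff[i, j] = aff[j, i] = r
    return aff


# ---------------------------------------------------------------------------
# embedding


def diffusion_map_embed(
    affinity: AffinityMatrix,
    n_components: int = 10,
    alpha: float = 0.5,
    t: int = 0,
    variance_power: int = 2,
) -> GradientSet:
    """Diffusion-map embedding of an affinity graph.

    Eigenvectors come from the symmetrized conjugate operator
    ``D'^(1/2) P D'^(-1/2)`` (dense, exact); right eigenvectors of P are
    recovered by conjugation and normalized against the trivial constant
    eigenvector, which is discarded.

    ``explained_variance[i] = lambda_i^q / sum_j lambda_j^q`` over the
    retained nontrivial spectrum, with ``q = variance_power`` (default 2;
    set 1 for first-power weighting).
    """
    w = np.asarray(getattr(affinity, "values", affinity), dtype=float)
    n = w.shape[0]
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    if t < 0 or int(t) != t:
        raise ValueError("diffusion time t must be a non-negative integer")
    if n_components >= n:
        raise ValueError("n_components must be smaller than the region count")
    n_comp_graph, labels = connected_components(w > 0, directed=False)
    if n_comp_graph > 1:
        comps = [np.flatnonzero(labels == c).tolist() for c in range(n_comp_graph)]
        raise ValueError(f"affinity graph is disconnected; components: {comps}")

    d = w.sum(axis=1)
    if alpha > 0:
        da = d**-alpha
        w1 = w * np.outer(da, da)
    else:
        w1 = w
    d1 = w1.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d1)
    sym = w1 * np.outer(inv_sqrt, inv_sqrt)
    sym = 0.5 * (sym + sym.T)
    evals, evecs = eigh(sym)
    order = _stable_eig_order(evals, evecs)
    evals = evals[order]
    evecs = evecs[:, order]

    # right eigenvectors of the walk operator; normalize so the trivial
    # eigenvector is the constant 1, then drop it
    psi = evecs * inv_sqrt[:, None]
    psi = psi / psi[:, [0]]
    lambdas = evals[1 : n_components + 1]
    vectors = psi[:, 1 : n_components + 1]
    if t == 0:
        scale = lambdas / (1.0 - lambdas)
    else:
        scale = lambdas**t
    coords = vectors * scale
    lam_pos = np.clip(lambdas, 0.0, None)
    denom = np.sum(lam_pos**variance_power)
    varexp = lam_pos**variance_power / denom if denom > 0 else np.zeros_like(lambdas)
    return GradientSet(coords, lambdas, varexp, alpha=alpha, t=int(t))


def _stable_eig_order(evals, evecs):
    """Descending eigenvalue order with a deterministic tie-break.

    Degenerate (tied) eigenvalues are ordered by the sign of the first
    nonzero eigenvector element; ties are logged since the subspace is then
    only defined up to rotation.
    """
    order = np.argsort(-evals, kind="stable")
    sorted_vals = evals[order]
    ties = np.flatnonzero(np.abs(np.diff(sorted_vals)) < 1e-12)
    if ties.size:
        logger.warning("degenerate eigenvalues detected at positions %s", ties.tolist())
        order = list(order)
        for k in ties:
            a, b = order[k], order[k + 1]
            if _first_sign(evecs[:, a]) > _first_sign(evecs[:, b]):
                order[k], order[k + 1] = b, a
        order = np.asarray(order)
    return order


def _first_sign(v):
    nz = np.flatnonzero(np.abs(v) > 1e-12)
    return np.sign(v[nz[0]]) if nz.size else 0.0


# ---------------------------------------------------------------------------
# template + alignment


def build_template(
    connectomes,
    kernel="cosine",
    sparsity=0.0,
    n_components=10,
    alpha=0.5,
    t=0,
    region_table: RegionTable | None = None,
    variance_power: int = 2,
) -> GradientSet:
    """Group-level gradient template from the element-wise mean connectome.

    The template's gradient signs are fixed against the parcel geometry:
    gradient g_i is flipped so that its correlation with the centroid x, y, z
    coordinate (cycling for i >= 3) is non-negative.  Individual subjects
    inherit orientation through Procrustes alignment, so the whole cohort is
    reported in one deterministic frame.
    """
    connectomes = list(connectomes)
    if not connectomes:
        raise ValueError("need at least one connectome")
    if region_table is None:
        region_table = connectomes[0].region_table
    mean_w = np.mean([c.weights for c in connectomes], axis=0)
    mean_conn = Connectome(mean_w, region_table)
    aff = compute_affinity(mean_conn, kernel=kernel, sparsity=sparsity)
    gs = diffusion_map_embed(
        aff, n_components=n_components, alpha=alpha, t=t, variance_power=variance_power
    )
    coords = gs.coordinates.copy()
    axes = region_table.cortical().centroids
    for i in range(coords.shape[1]):
        ref = axes[:, i % 3]
        c = np.dot(coords[:, i] - coords[:, i].mean(), ref - ref.mean())
        if c < 0:
            coords[:, i] = -coords[:, i]
    return GradientSet(coords, gs.eigenvalues, gs.explained_variance, alpha=alpha, t=int(t))


def procrustes_align(source: GradientSet, template: GradientSet):
    """Orthogonal Procrustes alignment of gradients to a template.

    Finds the rotation/reflection S minimizing ``||G S - M||_F`` (no scaling,
    no translation) from the SVD of ``G^T M``; returns the aligned gradient
    set and the transform.
    """
    g = source.coordinates
    m = template.coordinates
    if g.shape != m.shape:
        raise ValueError(f"shape mismatch: source {g.shape} vs template {m.shape}")
    u, _, vt = svd(g.T @ m)
    s = u @ vt
    aligned = GradientSet(
        g @ s,
        source.eigenvalues,
        source.explained_variance,
        alpha=source.alpha,
        t=source.t,
    )
    return aligned, AlignmentTransform(s)


def align_cohort(gradient_sets, template: GradientSet):
    """Procrustes-align every subject's gradients to the template."""
    aligned = []
    for gs in gradient_sets:
        a, _ = procrustes_align(gs, template)
        aligned.append(a)
    return aligned
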