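"""Subcortical-weighted gradients.

A subcortical structure's "weighted gradient" is the element-wise product of
a cortical gradient with that structure's cortical connectivity profile; its
mean over cortical regions is the structure's degree on that gradient.
Degrees are computed per subject from the subject's own aligned gradients
and own subcortical connectivity, then compared between groups with the same
multivariate / univariate machinery as the cortical maps.
"""

from __future__ import annotations

import numpy as np

from .io import volume_scale_rect
from .stats import DesignMatrix, StatMap, multivariate_map, univariate_map

__all__ = [
    "weighted_gradient",
    "degree",
    "subject_degrees",
    "cohort_degrees",
    "compare_subcortical",
]


def weighted_gradient(gradient, subcortical_row):
    """Element-wise product of a cortical gradient and a connectivity row."""
    g = np.asarray(gradient, dtype=float)
    r = np.asarray(subcortical_row, dtype=float)
    if g.shape != r.shape:
        raise ValueError("gradient and connectivity row must have equal length")
    return g * r


def degree(weighted):
    """Nodal degree of a weighted gradient: its mean over cortical regions."""
    return float(np.mean(np.asarray(weighted, dtype=float)))


def subject_degrees(aligned_coordinates, subcortical_weights,
                    row_volumes=None, col_volumes=None, scale_rule=None):
    """Degrees for one subject: structures x gradients matrix.

    ``degrees[s, g] = mean_i(W[s, i] * G[i, g])``, vectorized as
    ``W @ G / n_cortical``.  If ``scale_rule`` is given the connectivity rows
    are first volume-scaled with the same rule used for cortical edges.
    """
    g = np.asarray(aligned_coordinates, dtype=float)
    w = np.asarray(subcortical_weights, dtype=float)
    if w.shape[1] != g.shape[0]:
        raise ValueError("connectivity columns must match gradient rows")
    if scale_rule is not None:
        w = volume_scale_rect(w, row_volumes, col_volumes, rule=scale_rule)
    return w @ g / g.shape[0]


def cohort_degrees(aligned_gradient_sets, subcortical_list, n_gradients=3, **kw):
    """Stack of per-subject degree matrices: subjects x structures x k."""
    out = []
    for gs, sc in zip(aligned_gradient_sets, subcortical_list):
        out.append(subject_degrees(gs.coordinates[:, :n_gradients], sc.weights, **kw))
    return np.asarray(out)


def compare_subcortical(degrees, design: DesignMatrix, structure_labels, alpha=0.05):
    """Group comparison of subcortical degrees.

    Returns the multivariate (Hotelling across the k gradients) StatMap plus
    one univariate StatMap per gradient, each FDR-corrected across the
    family of subcortical structures.
    """
    degrees = np.asarray(degrees, dtype=float)
    multi = multivariate_map(
        degrees, design, structure_labels,
        family="subcortical_multivariate", alpha=alpha,
    )
    per_gradient = []
    for g in range(degrees.shape[2]):
        per_gradient.append(
            univariate_map(
                degrees[:, :, g], design, structure_labels,
                family=f"subcortical_univariate_g{g + 1}", alpha=alpha,
            )
        )
    return multi, per_gradient
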