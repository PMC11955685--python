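"""Synthetic cohorts with known ground truth.

Every downstream stage (gradients, group statistics, subcortical degrees,
transcriptomic PLS) is exercised on data from this module, so each generator
states exactly what it emulates:

* Parcels live on the unit sphere, mirrored across x=0 into two hemispheres,
  with functional networks assigned as spatially contiguous caps (spatially
  autocorrelated labels, as in real parcellations).
* Connectome weights decay exponentially with great-circle distance and are
  boosted within network — the modular, distance-dependent structure of
  tractography-derived connectomes — with multiplicative log-normal edge
  noise per subject.
* The patient group's effect multiplies the within-network edges of
  designated networks by (1 + effect_size), reshaping those regions'
  connectivity profiles and shifting the networks along the gradients.
* Subcortical profiles decay with Euclidean distance from interior anchor
  points.
* Gene expression maps are Gaussian random fields on the parcel centroids
  (squared-exponential kernel in great-circle distance); a planted subset of
  "signal" genes additionally tracks a target spatial map.

None of this emulates tractography biases, streamline counts, or realistic
cortical folding; it provides parameter-recovery targets, not realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CORTICAL_NETWORKS,
    SUBCORTICAL_STRUCTURES,
    CohortManifest,
    Connectome,
    RegionTable,
    SubcorticalConnectivity,
    write_matrix,
)

__all__ = [
    "SimulationParams",
    "place_parcels",
    "generate_connectome",
    "generate_subcortical",
    "generate_expression",
    "generate_autocorrelated_map",
    "simulate_cohort",
    "write_cohort",
    "CohortData",
]


@dataclass
class SimulationParams:
    """Study conditions for one synthetic cohort.

    Defaults are sized so the full pipeline runs in about a minute:
    100 regions, 2 x 25 subjects, 500 genes.
    """

    n_regions: int = 100
    n_networks: int = 7
    n_subjects_per_group: int = 25
    edge_length_scale: float = 0.75  # radians of arc; distance-decay constant
    within_network_boost: float = 2.0
    noise_sd: float = 0.3  # log-normal sigma of edge noise
    effect_networks: tuple = ("Smn",)
    effect_size: float = 0.3  # multiplicative perturbation in patients
    n_subcortical: int = 16
    subcortical_effect_structures: tuple = ()
    subcortical_effect_size: float = 0.0
    n_genes: int = 500
    n_signal_genes: int = 20
    expression_autocorr_scale: float = 0.2  # radians; GRF length scale
    signal_noise: float = 1.0  # field-noise amplitude added to signal genes
    seed: int = 0

    def __post_init__(self):
        if self.n_signal_genes > self.n_genes:
            raise ValueError("n_signal_genes cannot exceed n_genes")
        nets = set(CORTICAL_NETWORKS[: self.n_networks])
        bad = set(self.effect_networks) - nets
        if bad:
            raise ValueError(f"effect networks not defined: {bad}")
        if self.n_regions < 2 * self.n_networks:
            raise ValueError("need at least 2 regions per network")


# ---------------------------------------------------------------------------
# geometry


def _fibonacci_sphere(n):
    """Quasi-uniform lattice of n points on the unit sphere."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def place_parcels(n_regions=100, n_networks=7, seed=0, n_subcortical=16):
    """Build a bilateral parcel table on the unit sphere.

    Each hemisphere occupies its own full sphere — the geometry spherical
    registration gives real cortical hemispheres and the one the spin test
    rotates.  Left-hemisphere centroids are a quasi-uniform Fibonacci lattice
    (parcellations tile the sphere with near-equal-area parcels) under a
    random rotation; the right hemisphere is its x-mirror, so hemispheric
    correspondence is exact.  Network labels are nearest-anchor caps, giving
    every network at least one left parcel (hence two bilaterally).  Volumes
    are log-normal with unit median.  Subcortical anchor points sit in the
    sphere interior.
    """
    if n_regions % 2:
        raise ValueError("n_regions must be even (bilateral mirroring)")
    if n_regions < 2 * n_networks:
        raise ValueError("need at least 2 regions per network")
    rng = np.random.default_rng(seed)
    n_l = n_regions // 2
    q, r_ = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q * np.sign(np.diag(r_))
    xyz = _fibonacci_sphere(n_l) @ q.T

    anchors = rng.standard_normal((n_networks, 3))
    anchors /= np.linalg.norm(anchors, axis=1, keepdims=True)
    labels = np.argmax(xyz @ anchors.T, axis=1)
    # every network must own at least one left parcel: steal the closest
    # parcel from the currently largest network
    for net in range(n_networks):
        while np.sum(labels == net) < 1:
            counts = np.bincount(labels, minlength=n_networks)
            donor = np.argmax(counts)
            cand = np.flatnonzero(labels == donor)
            best = cand[np.argmax(xyz[cand] @ anchors[net])]
            labels[best] = net

    net_names = np.asarray(CORTICAL_NETWORKS[:n_networks])[labels]
    vols = np.exp(rng.normal(0.0, 0.3, size=n_regions))

    rows = []
    for i in range(n_l):
        rows.append(("L", net_names[i], *xyz[i]))
    for i in range(n_l):
        rows.append(("R", net_names[i], -xyz[i, 0], xyz[i, 1], xyz[i, 2]))
    df = pd.DataFrame(rows, columns=["hemisphere", "network", "x", "y", "z"])
    df.insert(0, "region_id", np.arange(n_regions))
    df.insert(
        1,
        "name",
        [f"{h}_{n}_{i}" for i, (h, n) in enumerate(zip(df["hemisphere"], df["network"]))],
    )
    df["volume"] = vols
    df["is_cortical"] = True

    if n_subcortical:
        sub_rows = []
        n_struct = len(SUBCORTICAL_STRUCTURES)
        for s in range(n_subcortical):
            struct = SUBCORTICAL_STRUCTURES[s % n_struct]
            hemi = "L" if s < n_subcortical // 2 or n_subcortical == 1 else "R"
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            direction[0] = -abs(direction[0]) if hemi == "L" else abs(direction[0])
            radius = rng.uniform(0.2, 0.5)
            p = direction * radius
            sub_rows.append(
                {
                    "region_id": n_regions + s,
                    "name": f"{struct}-{hemi}",
                    "hemisphere": hemi,
                    "network": struct,
                    "volume": float(np.exp(rng.normal(0.0, 0.3))),
                    "x": p[0],
                    "y": p[1],
                    "z": p[2],
                    "is_cortical": False,
                }
            )
        df = pd.concat([df, pd.DataFrame(sub_rows)], ignore_index=True)
    return RegionTable(df)


def _great_circle(a, b=None):
    b = a if b is None else b
    cosd = np.clip(np.asarray(a) @ np.asarray(b).T, -1.0, 1.0)
    return np.arccos(cosd)


def _lognormal_noise(rng, sigma, shape):
    """Multiplicative noise with mean exactly 1 (E[exp(sZ - s^2/2)] = 1)."""
    if sigma == 0:
        return np.ones(shape)
    return np.exp(rng.normal(0.0, sigma, size=shape) - sigma**2 / 2)


# ---------------------------------------------------------------------------
# connectivity


def generate_connectome(region_table, params: SimulationParams, group="control", seed=0):
    """One subject's cortical connectome.

    Expected weight(i, j) = exp(-d_ij / edge_length_scale) * boost if i and j
    share a network, times (1 + effect_size) for patient-group edges WITHIN
    an effect network, times unit-mean log-normal edge noise.

    The group effect multiplies within-network edges (both endpoints in an
    effect network) rather than all incident edges: scaling a region's whole
    connectivity row is invisible to the scale-invariant cosine profile
    similarity, whereas reweighting its within-community edges changes the
    profile shape and genuinely shifts the network along the gradients.
    """
    rng = np.random.default_rng(seed)
    cort = region_table.cortical()
    xyz = cort.centroids
    nets = cort.networks
    n = len(xyz)
    d = _great_circle(xyz)
    w = np.exp(-d / params.edge_length_scale)
    same = nets[:, None] == nets[None, :]
    w = np.where(same, w * params.within_network_boost, w)
    if group == "patient" and params.effect_size and params.effect_networks:
        hit = np.isin(nets, list(params.effect_networks))
        within = hit[:, None] & hit[None, :]
        w = np.where(within, w * (1.0 + params.effect_size), w)
    noise = _lognormal_noise(rng, params.noise_sd, (n, n))
    noise = np.triu(noise, 1)
    noise = noise + noise.T
    w = w * noise
    np.fill_diagonal(w, 0.0)
    w = 0.5 * (w + w.T)
    return Connectome(w, region_table)


def generate_subcortical(region_table, n_subcortical, params, group="control", seed=0):
    """Subcortical-to-cortical profiles from the table's interior anchors.

    Each structure's row decays exponentially with Euclidean distance from
    its anchor to the cortical centroids, with log-normal noise; patient
    rows of designated structures are multiplied by
    (1 + subcortical_effect_size).
    """
    rng = np.random.default_rng(seed)
    cort = region_table.cortical()
    sub = region_table.subcortical()
    if len(sub) < n_subcortical:
        raise ValueError("region table has fewer subcortical rows than requested")
    sub = sub.iloc[:n_subcortical]
    anchors = sub[["x", "y", "z"]].to_numpy(float)
    xyz = cort.centroids
    d = np.linalg.norm(anchors[:, None, :] - xyz[None, :, :], axis=2)
    w = np.exp(-d / params.edge_length_scale)
    if group == "patient" and params.subcortical_effect_size:
        hit = np.isin(sub["name"].to_numpy(), list(params.subcortical_effect_structures))
        w = np.where(hit[:, None], w * (1.0 + params.subcortical_effect_size), w)
    w = w * _lognormal_noise(rng, params.noise_sd, w.shape)
    return SubcorticalConnectivity(w, structures=sub["name"].tolist())


# ---------------------------------------------------------------------------
# expression


def _grf_cholesky(centroids, scale, hemispheres=None, jitter=1e-8):
    """Cholesky factor of a squared-exponential kernel on the sphere.

    For bilateral tables the right hemisphere is mirrored onto the left
    sphere before distances are computed, so homotopic (mirror-paired)
    locations are maximally correlated and the field distribution is exactly
    invariant under the mirrored spin rotations.
    """
    xyz = np.asarray(centroids, dtype=float)
    if hemispheres is not None:
        xyz = xyz.copy()
        xyz[np.asarray(hemispheres) == "R", 0] *= -1.0
    d = _great_circle(xyz)
    k = np.exp(-(d**2) / (2.0 * scale**2))
    k[np.diag_indices_from(k)] += jitter
    return np.linalg.cholesky(k)


def generate_autocorrelated_map(region_table, autocorr_scale=0.2, seed=0):
    """One Gaussian-random-field map over the table's regions, z-scored."""
    rng = np.random.default_rng(seed)
    chol = _grf_cholesky(
        _centroids_of(region_table), autocorr_scale, _hemis_of(region_table)
    )
    m = chol @ rng.standard_normal(chol.shape[0])
    return (m - m.mean()) / m.std()


def _centroids_of(region_table):
    if isinstance(region_table, RegionTable):
        return region_table.centroids
    return np.asarray(region_table, dtype=float)


def _hemis_of(region_table):
    return region_table.hemispheres if isinstance(region_table, RegionTable) else None


def generate_expression(
    region_table,
    target_map,
    n_genes=500,
    n_signal_genes=20,
    autocorr_scale=0.2,
    seed=0,
    signal_noise=1.0,
):
    """Regions x genes expression with planted signal genes.

    Background genes are independent smooth random fields on the centroids;
    signal genes equal the standardized target map plus ``signal_noise``
    times an independent field.  All columns are standardized (mean 0, SD 1).

    Returns (matrix, signal_gene_indices).
    """
    rng = np.random.default_rng(seed)
    centroids = _centroids_of(region_table)
    target = np.asarray(target_map, dtype=float)
    if len(target) != len(centroids):
        raise ValueError("target map length must match region count")
    tz = (target - target.mean()) / target.std()
    chol = _grf_cholesky(centroids, autocorr_scale, _hemis_of(region_table))
    n = len(centroids)
    fields = chol @ rng.standard_normal((n, n_genes))
    signal_idx = np.sort(rng.choice(n_genes, size=n_signal_genes, replace=False))
    expr = fields.copy()
    expr[:, signal_idx] = tz[:, None] + signal_noise * fields[:, signal_idx]
    expr = expr - expr.mean(axis=0)
    sd = expr.std(axis=0)
    sd[sd == 0] = 1.0
    expr = expr / sd
    return expr, signal_idx


# ---------------------------------------------------------------------------
# whole cohorts


@dataclass
class CohortData:
    """In-memory synthetic cohort with its ground truth."""

    params: SimulationParams
    region_table: RegionTable
    manifest: pd.DataFrame
    connectomes: list = field(default_factory=list)
    subcortical: list = field(default_factory=list)
    expression: np.ndarray | None = None
    signal_genes: np.ndarray | None = None
    expression_regions: np.ndarray | None = None  # indices into cortical rows

    @property
    def ground_truth(self):
        return {
            "effect_networks": list(self.params.effect_networks),
            "effect_size": self.params.effect_size,
            "subcortical_effect_structures": list(self.params.subcortical_effect_structures),
            "subcortical_effect_size": self.params.subcortical_effect_size,
            "signal_genes": [] if self.signal_genes is None else [int(i) for i in self.signal_genes],
            "seed": self.params.seed,
        }


def simulate_cohort(params: SimulationParams, expression=True) -> CohortData:
    """Generate a full cohort: parcels, subjects, matrices, expression.

    Ages are Normal(62, 8) truncated to [45, 80] and sex is Bernoulli(0.5),
    independent of group (no covariate-group confound by default).  The
    expression target map is the standardized left-hemisphere indicator of
    effect-network membership — the topology in which the group effect was
    injected.
    """
    rng = np.random.default_rng(params.seed)
    table = place_parcels(
        params.n_regions, params.n_networks, seed=int(rng.integers(2**31)),
        n_subcortical=params.n_subcortical,
    )
    rows = []
    connectomes = []
    subcortical = []
    for group in ("control", "patient"):
        for i in range(params.n_subjects_per_group):
            sid = f"sub-{group[:3]}{i:03d}"
            age = float(np.clip(rng.normal(62.0, 8.0), 45.0, 80.0))
            sex = "male" if rng.random() < 0.5 else "female"
            connectomes.append(
                generate_connectome(table, params, group, seed=int(rng.integers(2**31)))
            )
            subcortical.append(
                generate_subcortical(
                    table, params.n_subcortical, params, group,
                    seed=int(rng.integers(2**31)),
                )
            )
            rows.append((sid, group, age, sex, "", ""))
    manifest = pd.DataFrame(
        rows,
        columns=["subject_id", "group", "age", "sex", "connectome_path", "subcortical_path"],
    )
    data = CohortData(params, table, manifest, connectomes, subcortical)
    if expression and params.n_genes:
        cort = table.cortical()
        left = np.flatnonzero(cort.hemispheres == "L")
        in_effect = np.isin(cort.networks[left], list(params.effect_networks)).astype(float)
        if in_effect.std() == 0:  # no effect networks: arbitrary smooth target
            target = generate_autocorrelated_map(
                cort.centroids[left], params.expression_autocorr_scale,
                seed=int(rng.integers(2**31)),
            )
        else:
            target = in_effect
        expr, sig = generate_expression(
            cort.centroids[left],
            target,
            n_genes=params.n_genes,
            n_signal_genes=params.n_signal_genes,
            autocorr_scale=params.expression_autocorr_scale,
            seed=int(rng.integers(2**31)),
            signal_noise=params.signal_noise,
        )
        data.expression = expr
        data.signal_genes = sig
        data.expression_regions = left
    return data


def write_cohort(data: CohortData, outdir) -> Path:
    """Write a cohort to disk as TSV matrices plus a ground-truth JSON."""
    outdir = Path(outdir)
    (outdir / "connectomes").mkdir(parents=True, exist_ok=True)
    (outdir / "subcortical").mkdir(parents=True, exist_ok=True)
    data.region_table.to_tsv(outdir / "regions.tsv")
    manifest = data.manifest.copy()
    for i, sid in enumerate(manifest["subject_id"]):
        cpath = outdir / "connectomes" / f"{sid}.tsv"
        spath = outdir / "subcortical" / f"{sid}.tsv"
        data.connectomes[i].to_tsv(cpath)
        data.subcortical[i].to_tsv(spath)
        manifest.loc[i, "connectome_path"] = str(cpath.relative_to(outdir))
        manifest.loc[i, "subcortical_path"] = str(spath.relative_to(outdir))
    CohortManifest(manifest).to_tsv(outdir / "manifest.tsv")
    if data.expression is not None:
        write_matrix(outdir / "expression.tsv", data.expression)
        np.savetxt(
            outdir / "expression_regions.tsv",
            data.expression_regions, fmt="%d",
        )
    gt = dict(data.ground_truth)
    gt["params"] = asdict(data.params)
    for key in ("effect_networks", "subcortical_effect_structures"):
        gt["params"][key] = list(gt["params"][key])
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(gt, fh, indent=2, sort_keys=True)
    return outdir
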