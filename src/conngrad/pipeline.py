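"""End-to-end orchestration: simulate -> gradients -> compare -> subcortical -> pls.

Each stage writes plain-text artifacts into the output directory and the run
ends with a manifest recording the configuration, every per-stage seed, and
a SHA-256 hash of every written file — rerunning with the same configuration
and seed reproduces the manifest bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import gradients as gr
from . import pls as plsmod
from . import simulate as sim
from . import stats as st
from . import subcortical as sub
from .io import (
    CohortManifest,
    Connectome,
    RegionTable,
    SubcorticalConnectivity,
    read_matrix,
    write_matrix,
)
from .nulls import spin_correlation_test

__all__ = ["PipelineError", "default_config", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


def default_config():
    return {
        "stages": ["simulate", "gradients", "compare", "subcortical", "pls"],
        "simulate": {},  # SimulationParams overrides; omit to load from paths
        "paths": {},  # manifest, regions, expression, expression_regions
        "gradients": {
            "kernel": "cosine",
            "sparsity": 0.0,
            "alpha": 0.5,
            "t": 0,
            "n_components": 10,
            "n_analyze": 3,
        },
        "stats": {"alpha": 0.05},
        "nulls": {"n_perm": 1000, "n_boot": 1000},
        "seed": 0,
    }


def _merge(base, override):
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _stage_seeds(seed):
    ss = np.random.SeedSequence(seed)
    names = ["simulate", "gradients", "compare", "subcortical", "pls"]
    return {n: int(c.generate_state(1)[0] % 2**31) for n, c in zip(names, ss.spawn(len(names)))}


def run_pipeline(config=None, outdir="conngrad_out"):
    """Run the configured stages; returns the run manifest dict."""
    cfg = _merge(default_config(), config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(cfg["stages"])
    seeds = _stage_seeds(int(cfg["seed"]))
    written = []

    # ---- validation before any compute
    simulate = "simulate" in stages
    if not simulate:
        paths = cfg["paths"]
        for key in ("manifest", "regions"):
            if not paths.get(key):
                raise PipelineError(f"config: paths.{key} required when not simulating")
        if "pls" in stages and not paths.get("expression"):
            raise PipelineError("config: paths.expression required for the pls stage")

    # ---- stage: simulate or load -----------------------------------------
    if simulate:
        sim_cfg = dict(cfg["simulate"])
        sim_cfg.setdefault("seed", seeds["simulate"])
        params = sim.SimulationParams(**sim_cfg)
        cohort = sim.simulate_cohort(params, expression="pls" in stages)
        cohort_dir = outdir / "cohort"
        sim.write_cohort(cohort, cohort_dir)
        written += sorted(p for p in cohort_dir.rglob("*") if p.is_file())
        region_table = cohort.region_table
        manifest_df = cohort.manifest
        connectomes = cohort.connectomes
        subcortical_list = cohort.subcortical
        expression = cohort.expression
        expr_regions = cohort.expression_regions
    else:
        paths = cfg["paths"]
        try:
            region_table = RegionTable.read_tsv(paths["regions"])
            cm = CohortManifest.read_tsv(paths["manifest"])
        except Exception as exc:
            raise PipelineError(f"load: {exc}") from exc
        manifest_df = cm.table
        base = Path(paths["manifest"]).parent
        connectomes, subcortical_list = [], []
        for _, row in manifest_df.iterrows():
            try:
                connectomes.append(
                    Connectome.read_tsv(base / row["connectome_path"], region_table)
                )
                subcortical_list.append(
                    SubcorticalConnectivity.read_tsv(base / row["subcortical_path"])
                )
            except Exception as exc:
                raise PipelineError(
                    f"load: subject {row['subject_id']}: {exc}"
                ) from exc
        expression = expr_regions = None
        if paths.get("expression"):
            expression = read_matrix(paths["expression"])
            if paths.get("expression_regions"):
                expr_regions = np.loadtxt(
                    paths["expression_regions"], dtype=int, ndmin=1
                )
            else:
                cort = region_table.cortical()
                expr_regions = np.flatnonzero(cort.hemispheres == "L")

    cort = region_table.cortical()
    summary = {}

    # ---- stage: gradients -------------------------------------------------
    gcfg = cfg["gradients"]
    n_analyze = int(gcfg["n_analyze"])
    template = aligned = None
    if "gradients" in stages:
        try:
            template = gr.build_template(
                connectomes,
                kernel=gcfg["kernel"],
                sparsity=gcfg["sparsity"],
                n_components=gcfg["n_components"],
                alpha=gcfg["alpha"],
                t=gcfg["t"],
                region_table=region_table,
            )
            individual = [
                gr.diffusion_map_embed(
                    gr.compute_affinity(c, kernel=gcfg["kernel"], sparsity=gcfg["sparsity"]),
                    n_components=gcfg["n_components"],
                    alpha=gcfg["alpha"],
                    t=gcfg["t"],
                )
                for c in connectomes
            ]
            aligned = gr.align_cohort(individual, template)
        except Exception as exc:
            raise PipelineError(f"gradients: {exc}") from exc
        gdir = outdir / "gradients"
        gdir.mkdir(exist_ok=True)
        written.append(write_matrix(gdir / "template.tsv", template.coordinates))
        written.append(
            write_matrix(
                gdir / "template_spectrum.tsv",
                np.column_stack([template.eigenvalues, template.explained_variance]),
                header=["eigenvalue", "explained_variance"],
            )
        )
        for sid, gs in zip(manifest_df["subject_id"], aligned):
            written.append(write_matrix(gdir / f"{sid}_aligned.tsv", gs.coordinates))
        summary["template_varexp_top3_pct"] = float(
            100.0 * template.explained_variance[:n_analyze].sum()
        )

    design = st.design_matrix(manifest_df)
    alpha = float(cfg["stats"]["alpha"])
    nulls_cfg = cfg["nulls"]

    # ---- stage: compare ---------------------------------------------------
    if "compare" in stages:
        if aligned is None:
            raise PipelineError("compare: requires the gradients stage")
        cdir = outdir / "compare"
        cdir.mkdir(exist_ok=True)
        coords = np.asarray([g.coordinates[:, :n_analyze] for g in aligned])
        net_scores = np.asarray(
            [st.network_average(c, region_table) for c in coords]
        )
        net_labels = list(st.CORTICAL_NETWORKS[: len(net_scores[0])])
        net_multi = st.multivariate_map(
            net_scores, design, net_labels, family="network_multivariate", alpha=alpha
        )
        written.append(net_multi.to_tsv(cdir / "network_multivariate.tsv"))
        families = {"network_multivariate": net_labels}
        for g in range(n_analyze):
            m = st.univariate_map(
                net_scores[:, :, g], design, net_labels,
                family=f"network_univariate_g{g + 1}", alpha=alpha,
            )
            written.append(m.to_tsv(cdir / f"network_univariate_g{g + 1}.tsv"))
            families[m.family] = net_labels
        region_labels = cort.table["name"].tolist()
        reg_multi = st.multivariate_map(
            coords, design, region_labels, family="region_multivariate", alpha=alpha
        )
        written.append(reg_multi.to_tsv(cdir / "region_multivariate.tsv"))
        # post-hoc per-gradient contributions on multivariate-significant regions,
        # Bonferroni over the number of gradients analyzed
        posthoc_rows = []
        for g in range(n_analyze):
            uni = st.univariate_map(
                coords[:, :, g], design, region_labels,
                family=f"region_univariate_g{g + 1}", alpha=alpha,
            )
            written.append(uni.to_tsv(cdir / f"region_univariate_g{g + 1}.tsv"))
            flags = st.posthoc_bonferroni(uni.table["p"].to_numpy(), n_tests=n_analyze)
            for lab, t, p, fl, multi_sig in zip(
                region_labels, uni.table["statistic"], uni.table["p"], flags,
                reg_multi.table["significant"],
            ):
                posthoc_rows.append((lab, g + 1, t, p, bool(fl and multi_sig)))
        pd.DataFrame(
            posthoc_rows, columns=["unit", "gradient", "statistic", "p", "significant"]
        ).to_csv(cdir / "region_posthoc.tsv", sep="\t", index=False, float_format="%.17g")
        written.append(cdir / "region_posthoc.tsv")
        with open(cdir / "families.json", "w") as fh:
            json.dump(
                {"alpha": alpha, "families": {k: len(v) for k, v in families.items()}},
                fh, indent=2, sort_keys=True,
            )
        written.append(cdir / "families.json")

        # spatial association of the last analyzed gradient's t-map with the
        # control-group mean gradient, spin-tested
        g3 = n_analyze - 1
        t_map = st.univariate_map(
            coords[:, :, g3], design, region_labels
        ).table["statistic"].to_numpy()
        ctrl = manifest_df["group"].to_numpy() == "control"
        ctrl_mean = coords[ctrl, :, g3].mean(axis=0)
        r, p = spin_correlation_test(
            t_map, ctrl_mean, cort.centroids, cort.hemispheres,
            n_perm=int(nulls_cfg["n_perm"]), seed=seeds["compare"],
        )
        summary["tmap_vs_control_mean_r"] = r
        summary["tmap_vs_control_mean_p"] = p
        summary["n_significant_networks"] = int(net_multi.table["significant"].sum())
        summary["top_network"] = str(
            net_multi.table.loc[net_multi.table["statistic"].idxmax(), "unit"]
        )
        _store = {"net_multi": net_multi, "reg_multi": reg_multi}
    else:
        _store = {}

    # ---- stage: subcortical ----------------------------------------------
    if "subcortical" in stages:
        if aligned is None:
            raise PipelineError("subcortical: requires the gradients stage")
        sdir = outdir / "subcortical"
        sdir.mkdir(exist_ok=True)
        labels = region_table.subcortical()["name"].tolist()
        degrees = sub.cohort_degrees(aligned, subcortical_list, n_gradients=n_analyze)
        multi, per_grad = sub.compare_subcortical(degrees, design, labels, alpha=alpha)
        written.append(multi.to_tsv(sdir / "multivariate.tsv"))
        for g, m in enumerate(per_grad):
            written.append(m.to_tsv(sdir / f"univariate_g{g + 1}.tsv"))
        flat = degrees.reshape(degrees.shape[0], -1)
        cols = [f"{lab}_g{g + 1}" for lab in labels for g in range(degrees.shape[2])]
        deg_df = pd.DataFrame(flat, columns=cols)
        deg_df.insert(0, "subject_id", manifest_df["subject_id"])
        deg_df.to_csv(sdir / "degrees.tsv", sep="\t", index=False, float_format="%.17g")
        written.append(sdir / "degrees.tsv")
        summary["top_subcortical_structure"] = str(
            multi.table.loc[multi.table["statistic"].idxmax(), "unit"]
        )

    # ---- stage: pls -------------------------------------------------------
    if "pls" in stages:
        if expression is None:
            raise PipelineError("pls: no expression matrix available")
        if "reg_multi" not in _store:
            raise PipelineError("pls: requires the compare stage")
        pdir = outdir / "pls"
        pdir.mkdir(exist_ok=True)
        t2_map = _store["reg_multi"].table["statistic"].to_numpy()
        y = t2_map[expr_regions]
        y = (y - y.mean()) / y.std()
        centroids = cort.centroids[expr_regions]
        hemis = cort.hemispheres[expr_regions]
        X = expression
        result = plsmod.fit_pls(X, y, n_components=2)
        result.perm_p = plsmod.permutation_test_varexp(
            X, y, n_components=2, n_perm=int(nulls_cfg["n_perm"]),
            null="spin", centroids=centroids, hemispheres=hemis,
            seed=seeds["pls"],
        )
        comp = result.select_component()
        r, p = plsmod.spatial_correlation_of_scores(
            result, comp, y, centroids, hemis,
            n_perm=int(nulls_cfg["n_perm"]), seed=seeds["pls"] + 1,
        )
        boot_z = plsmod.bootstrap_weights(
            X, y, component=comp, n_boot=int(nulls_cfg["n_boot"]),
            seed=seeds["pls"] + 2,
        )
        result.boot_z = boot_z
        gene_ids = np.arange(X.shape[1])
        plus, minus, z_thr = plsmod.select_genes(boot_z, gene_ids, alpha=alpha)
        plus_set, minus_set = set(plus.tolist()), set(minus.tolist())
        q = st.fdr_bh(2.0 * _norm_sf(np.abs(boot_z)))
        table = pd.DataFrame(
            {
                "gene_id": gene_ids,
                "weight": result.weights[:, comp],
                "Z": boot_z,
                "q": q,
                "set": [
                    "plus" if i in plus_set else "minus" if i in minus_set else "ns"
                    for i in gene_ids
                ],
            }
        )
        table.to_csv(pdir / "genes.tsv", sep="\t", index=False, float_format="%.17g")
        written.append(pdir / "genes.tsv")
        pls_summary = {
            "varexp_pct": [float(100 * v) for v in result.varexp],
            "perm_p": result.perm_p,
            "selected_component": comp + 1,
            "spatial_r": r,
            "spatial_p": p,
            "n_plus_genes": int(len(plus)),
            "n_minus_genes": int(len(minus)),
            "z_threshold": z_thr if np.isfinite(z_thr) else None,
        }
        with open(pdir / "summary.json", "w") as fh:
            json.dump(pls_summary, fh, indent=2, sort_keys=True)
        written.append(pdir / "summary.json")
        summary["pls"] = pls_summary

    # ---- run manifest -----------------------------------------------------
    cfg_serializable = json.loads(json.dumps(cfg, default=str))
    run_manifest = {
        "config": cfg_serializable,
        "seeds": seeds,
        "summary": summary,
        "files": {
            str(Path(p).relative_to(outdir)): _sha256(p) for p in sorted(set(map(Path, written)))
        },
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2, sort_keys=True)
    return run_manifest


def _sha256(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _norm_sf(x):
    from scipy.stats import norm

    return norm.sf(x)
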