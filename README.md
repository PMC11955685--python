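# conngrad

Structural connectome **gradient** analysis for case–control studies, with a
fully synthetic test bench.

Diffusion MRI tractography yields, per subject, a symmetric non-negative
matrix of structural connectivity between cortical parcels.  `conngrad`
compresses each connectome into a few continuous spatial axes ("gradients"),
compares those axes between a patient and a control group, relates the
group-difference map to subcortical connectivity and to gene-expression
profiles, and ships a synthetic-cohort generator with known ground truth so
every stage has a parameter-recovery test that runs in seconds — no imaging
data or atlas downloads required.

The pipeline was built around the analysis style used in studies of
age-related hearing loss and similar clinical connectomics work:

1. **Gradients** — cosine (or rank / normalized-angle) similarity between
   regional connectivity profiles gives an affinity matrix W; diffusion map
   embedding of the anisotropically normalized walk operator
   `P = D'⁻¹ D⁻ᵅ W D⁻ᵅ` (α = 0.5, diffusion time t = 0) yields gradients
   G1, G2, G3 … ordered by explained variance.  Individual gradients are
   aligned to a group-template embedding by orthogonal Procrustes
   (no scaling): `S = argmin ‖G S − M‖_F`, S orthogonal.
2. **Group statistics** — Hotelling's T² for the group contrast across the
   first three gradients jointly, in a multivariate GLM with age and sex
   covariates (`T² = (cβ̂)ᵀ[c(XᵀX)⁻¹cᵀ Σ̂]⁻¹(cβ̂)`, exact F reference), at
   network level (seven canonical systems) and region level, with
   Benjamini–Hochberg FDR and per-gradient Bonferroni post-hocs.
3. **Subcortical-weighted gradients** — a structure's cortical connectivity
   row multiplies a gradient element-wise; the mean of that product is the
   structure's degree, compared between groups with the same machinery.
4. **Spatial nulls** — spin permutations: random rotations of the parcel
   centroids on the sphere (mirrored across hemispheres), values reassigned
   by nearest original centroid, preserving spatial autocorrelation.
5. **Imaging transcriptomics** — single-response PLS regression of a
   regions × genes expression matrix on the left-hemisphere group-difference
   map; component significance by (spin-)permutation of the response,
   per-gene bootstrap Z = weight / bootstrap SD over region resamples, and
   signed significant gene sets (PLS+/PLS−) under FDR.

## Worked example

Simulate a default cohort (100 parcels, 25 patients + 25 controls, a
connectivity effect planted in the somatomotor network, 500 genes of which
20 track the effect topology) and run every stage:

```bash
cat > example.yaml <<EOF
simulate:
  n_regions: 100
  n_subjects_per_group: 25
nulls:
  n_perm: 1000
  n_boot: 1000
seed: 1
EOF
conngrad run-all --config example.yaml --out example_run
```

which prints (abridged):

```json
{
  "template_varexp_top3_pct": 92.83,
  "top_network": "Smn",
  "n_significant_networks": 1,
  "tmap_vs_control_mean_r": -0.278,
  "pls": {
    "varexp_pct": [87.36, 11.00],
    "spatial_r": 0.935,
    "spatial_p": 0.002,
    "n_plus_genes": 0,
    "n_minus_genes": 0
  }
}
```

Reading the numbers: the first three template gradients carry ~93% of the
embedded variance on this compact synthetic geometry; the top-ranked (and
only FDR-significant) network-level multivariate effect is `Smn` — exactly
the network in which the generator planted the patient effect
(`example_run/cohort/ground_truth.json`).  The selected PLS component's
region scores track the group-difference map almost perfectly
(r = 0.935, spin p = 0.002).  No individual genes pass the bootstrap-Z
selection here because the default cohort exposes only 50 left-hemisphere
regions to the PLS stage — at 100 regions the same machinery recovers 100%
of planted genes (see the acceptance script below).

Stage outputs land in `example_run/` as TSV tables (`gradients/`,
`compare/`, `subcortical/`, `pls/`) plus `run_manifest.json` recording the
configuration, all derived seeds, and a SHA-256 hash of every artifact;
rerunning the same config reproduces the manifest byte for byte.

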