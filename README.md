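# ctnetwb

Individual morphological similarity networks of cortical thickness, and
their association with well-being.

`ctnetwb` is for researchers who ask whether the *topology* of a person's
cortical-thickness network relates to a behavioral trait. It implements the
full analysis chain for a 65-subject, 32-parcel study design:

1. **Similarity networks.** For each subject and each pair of cortical
   parcels (the 32 Yeo-7 parcels with ≥ 50 vertices; a bundled table gives
   their names and vertex counts), the vertex-wise thickness values of both
   parcels are binned into 30 equal-width bins over the pair's pooled range,
   and the edge weight is |Pearson r| of the two 30-bin frequency vectors —
   a 32 × 32 similarity matrix per subject.
2. **OMST sparsification.** Orthogonal minimal spanning trees: successive
   edge-disjoint MSTs (on distances d = 1/w) are aggregated until global
   cost efficiency, GCE = E_glob(selected) − cost, is maximal; the selected
   union is binarized. Threshold-free and connectivity-preserving.
3. **Topology.** Seven measures per binary network: global, nodal and local
   efficiency (E_glob, E_nodal, E_local), and degree (DC), betweenness (BC,
   ordered-pair convention), eigenvector (EC) and pagerank (PC, d = 0.85)
   centrality.
4. **Association.** For every (parcel, metric, well-being dimension) an OLS
   fit of

   `wellbeing = α₁·age + α₂·sex + α₃·education + α₄·ICV + α₅·CT_mean + β·metric + γ`

   with the effect reported as the partial correlation
   r = sign(t)·√(t²/(t² + df)), and Benjamini–Hochberg FDR (q < 0.05)
   applied within each family of 32 parcel tests.

Well-being is measured by the 14-item Mental Health Continuum – Short Form
(MHC-SF): emotional (3 items, max 15), social (5 items, max 25) and
psychological (6 items, max 30) subscales plus the total (max 70) under
0–5 item coding; Cronbach's α and Table-style cohort descriptives are
included.

Because vertex-level MRI data for such a study cannot be redistributed, the
package ships a **synthetic-cohort generator** that emulates the study
conditions (65 subjects, the bundled atlas parcel vertex counts, covariate
correlation structure, 6-point item responses driven by a latent well-being
factor) and can *plant* a topology–behavior effect of a chosen partial
correlation at a chosen parcel — the basis of the package's calibration and
power studies.

## Worked example

```python
from ctnetwb import SimulationConfig, simulate_cohort, WellbeingTopologyModel

cfg = SimulationConfig(effect_parcel="RH_Default_PCC", effect_size=0.4, seed=7)
cohort = simulate_cohort(cfg)
results = WellbeingTopologyModel.from_cohort(cohort).fit()
print(results.summary())
```

```
Well-being ~ topology GLM association results
==============================================
subjects: 65   parcels: 32   metrics: 6   FDR q < 0.05
fits: 768 (6 metrics x 4 dimensions x 32 parcels)

10 FDR-significant association(s):
   Enodal in RH_Default_PCC             ~ psychological partial r = -0.4340, q = 0.0170
   Enodal in RH_Default_PCC             ~ social        partial r = -0.4203, q = 0.0265
   Enodal in RH_Default_PCC             ~ total         partial r = -0.4378, q = 0.0150
   Elocal in RH_Default_PCC             ~ emotional     partial r = +0.4680, q = 0.0052
   Elocal in RH_Default_PCC             ~ psychological partial r = +0.4275, q = 0.0210
   Elocal in RH_Default_PCC             ~ social        partial r = +0.4091, q = 0.0375
   Elocal in RH_Default_PCC             ~ total         partial r = +0.4570, q = 0.0077
       EC in RH_Default_PCC             ~ psychological partial r = -0.4058, q = 0.0414
       EC in RH_Default_PCC             ~ social        partial r = -0.4300, q = 0.0194
       EC in RH_Default_PCC             ~ total         partial r = -0.4305, q = 0.0191

Global efficiency (graph-level, uncorrected):
  Eglob ~ emotional     partial r = +0.0515, p = 0.6958
  Eglob ~ psychological partial r = -0.1839, p = 0.1596
  Eglob ~ social        partial r = -0.0881, p = 0.5033
  Eglob ~ total         partial r = -0.1064, p = 0.4184
```

The effect was planted on local efficiency at RH_Default_PCC with a target
partial correlation of 0.4; the fitted value at that parcel is +0.457
(q = 0.008) for the total score, and the family's top hit is the planted
parcel. Co-significance of E_nodal and EC at the same parcel is expected —
topology measures of one node covary. `results.dimension_effect_sizes()`
breaks a total-score hit into the three per-dimension partial correlations.

The same analysis runs from the shell on TSV/CSV files:

```bash
ctnetwb simulate --out cohort --seed 7
ctnetwb run-all --config config.yaml --out results
```

with per-stage subcommands (`score`, `build-net`, `omst`, `metrics`,
`associate`) reading and writing the documented interchange formats.

## Layout

| Module | Contents |
| --- | --- |
| `ctnetwb.simulate` | synthetic cohorts, planted effects |
| `ctnetwb.behavior` | MHC-SF scoring, Cronbach's α, descriptives |
| `ctnetwb.thickness` | parcel tables, thickness IO, vertex filter, mean CT |
| `ctnetwb.simnet` | pair histograms, similarity matrices |
| `ctnetwb.omst` | orthogonal MSTs, global cost efficiency, binarization |
| `ctnetwb.topology` | the seven graph measures |
| `ctnetwb.association` | `WellbeingTopologyModel` / `WellbeingTopologyResults`, FDR |
| `ctnetwb.studies` | null-calibration and planted-recovery Monte-Carlo studies |
| `ctnetwb.pipeline`, `ctnetwb.cli` | end-to-end orchestration and the `ctnetwb` CLI |

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
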