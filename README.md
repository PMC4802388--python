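# lobeconn

Weighted functional-connectome analysis for longitudinal surgical cohorts:
pre-/post-resection resting-state networks, cost-thresholded graph metrics,
targeted-attack resilience, a 2×2 mixed-design ANOVA screen, and a surgical
damage score.

## The problem

In drug-resistant mesial temporal lobe epilepsy, anterior temporal lobectomy
leaves roughly 30% of patients with recurrent seizures, and no single
presurgical marker separates the future seizure-free (SF) from
non-seizure-free (NSF) patients. Treating the disorder as a *network*
disease suggests different questions: is the SF brain network more resilient
to the simulated removal of its most central regions before surgery? Which
edges and regions reorganise differently after surgery in the two outcome
groups? And does the functional importance of the resected tissue predict the
post-operative network?

`lobeconn` implements that full analysis as a tested, reusable pipeline, and
ships a synthetic-cohort generator with *planted, known-ground-truth effects*
(an outcome × treatment connectivity interaction, outcome-dependent hub
concentration, damage-coupled post-operative degradation) so every stage can
be validated end-to-end without patient data.

## The model

For each subject-session, regional time series are detrended, band-pass
filtered (0.01–0.08 Hz), residualised against 24 motion regressors, CSF/WM
stand-ins and the global signal; right-lateralised subjects are flipped onto
a canonical orientation by homotopic ROI relabeling. Edge weights are
absolute Fisher-Z correlations,

```
w_ij = |atanh(r_ij)|,
```

and a network at cost κ keeps the `round(κ·N(N−1)/2)` strongest edges. On
each thresholded graph the package computes total strength `S_net`, Onnela
weighted clustering (`C_i`, `C_net`), efficiency on `1/w` path lengths
(`E_i`, `E_net`), betweenness centrality `BC_i`, and small-worldness

```
σ = (C_net / C_rand) / (L_net / L_rand)
```

against degree-preserving rewired nulls. Three analyses follow:

1. **Resilience** — nodes are removed one at a time, either at random
   (averaged over many orders) or by highest recomputed betweenness; the
   surviving largest component, `C_net` and `E_net` are tracked, normalised
   to the intact network, compared per step at the `p < 1/n_steps`
   false-positive threshold, and summarised by AUC.
2. **Reorganisation** — a 2×2 mixed ANOVA (between factor: outcome; within
   factor: pre/post) over edge Fisher-Z values, nodal metric AUCs and global
   metric AUCs across costs 0.10–0.35, excluding every ROI damaged in any
   subject, with `p < 1/n` correction. For a 2×2 design the interaction F
   is exactly the squared pooled t on per-subject difference scores — the
   package exploits (and tests) this identity.
3. **Damage score** — `DS = Σ_i fraction_i × C.E._i` over resected ROIs,
   where `C.E._i` is the pre-operative nodal clustering or efficiency of
   ROI i, correlated with post-operative σ AUC (Pearson).

## Worked example

```python
from lobeconn import GeneratorConfig
from lobeconn.pipeline import RunConfig, run_all

config = RunConfig(
    cohort=GeneratorConfig(n_rois=30, n_modules=3, n_sf_pre=10, n_nsf_pre=8,
                           n_sf_post=8, n_nsf_post=6, n_damaged_range=(2, 4),
                           rng_seed=42),
    cost=0.20, cost_grid_start=0.20, cost_grid_stop=0.40, cost_grid_step=0.02,
    n_null=5, random_reps=50, rng_seed=42,
)
report = run_all(config)

res = report["resilience"]["targeted"]["auc"]
print("targeted-attack AUC (SF vs NSF):")
print(res.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
reorg = report["reorganization"]
print(f"\nscreened edges: {reorg['n_screened_edges']}  "
      f"(interaction threshold 1/n = {reorg['edge_threshold']:.2e})")
print(f"undamaged ROIs entering the ANOVA: {reorg['n_kept_nodes']} of 30")
for basis, (r, p) in report["damage"]["correlation"].items():
    print(f"{basis}-based damage score vs post-op sigma AUC: r = {r:+.2f}, p = {p:.3f}")
```

prints:

```
targeted-attack AUC (SF vs NSF):
          measure  auc_mean_SF  auc_mean_NSF      t     df     p
largest_component        0.277         0.245  2.845 16.000 0.012
            C_net        0.321         0.337 -0.319 16.000 0.754
            E_net        0.241         0.219  1.508 16.000 0.151

screened edges: 192  (interaction threshold 1/n = 5.21e-03)
undamaged ROIs entering the ANOVA: 21 of 30
C_i-based damage score vs post-op sigma AUC: r = -0.56, p = 0.035
E_i-based damage score vs post-op sigma AUC: r = -0.77, p = 0.001
```

Read: the seizure-free group's largest connected component survives targeted
hub removal significantly better (AUC 0.277 vs 0.245, p = 0.012) while
clustering resilience does not differ; 9 of 30 regions overlapped someone's
resection and were excluded from the ANOVA; and subjects whose resections
removed functionally more important tissue (higher damage score) have less
small-world post-operative networks (negative r) — exactly the planted
structure the generator encodes.

The same stages are available from a shell:

```sh
lobeconn simulate --config cohort.yaml --out cohort/ --seed 1
lobeconn run-all  --config cohort.yaml --out report/ --seed 1
lobeconn resilience --cohort cohort/ --out res/ --cost 0.14 --mode targeted --seed 1
```

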