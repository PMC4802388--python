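# Methods

This note documents the models, conventions and deliberate design choices
behind `lobeconn`, in the spirit of a package reference: what is computed,
under which assumptions, and where the genuinely open choices were settled.

## Synthetic cohort model

The generator (`lobeconn.synth`) emulates the *statistical structure* of a
two-group (seizure-free SF / non-seizure-free NSF), two-session (pre-/
post-resection) resting-state study. It makes no attempt at hemodynamic or
scanner-noise realism; its purpose is to give every downstream stage a known
ground truth.

**Parcellation.** `n_rois` regions (default 110, i.e. 55 per hemisphere) in
mirror-image left/right pairs; homotopic pairs are assigned to `n_modules`
(default 6) contiguous functional modules, so partners always share a
module. A reduced parcellation of any even size is available for fast tests.

**Covariance.** Each group-cell's population correlation matrix is a factor
model `ΛΛ' + Ψ` with unit diagonal — positive semi-definite by construction,
which is why the generator parameterises *loadings* rather than raw
correlation entries (arbitrary block-ρ matrices can be indefinite). Factors:

* one factor per module; every member loads `√rho_within_module`
  (default `√0.30`);
* a weak global factor (`√rho_between_module`, default `√0.05`). Note that
  global-signal regression downstream removes most of this factor again —
  deliberately so, since that is what the regression does to real data;
* *connector* cross-loadings: the first homotopic pair of each module (the
  primary connector) also loads `√rho_connector` (default `√0.45`) on the
  next module's factor, arranged in a ring over modules; the second pair
  (secondary connector) loads on the previous module's factor at
  `secondary_connector_scale` (default 1/3) of that strength. Because this
  mechanism lives in the module factors, it survives global-signal
  regression, and cross-module shortest paths route through connectors,
  giving them high betweenness.

**Planted effects.**

* *Outcome × treatment interaction*: SF post sessions add one dedicated pair
  factor per planted edge with loading `√interaction_delta` on both
  endpoints, raising that edge's population correlation by exactly
  `interaction_delta` (default 0.60). The default edges are a homotopic
  cross-module pair far from the lesion set.
* *Hub concentration*: NSF subjects scale the secondary connector
  cross-loadings by `hub_concentration_factor` (default 3, restoring them to
  primary strength). Under proportional cost thresholding the edge budget is
  fixed, so the NSF network spends more of it on strong hub-mediated edges
  and less on distributed within-module edges; targeted removal of its
  high-betweenness nodes therefore fragments it earlier. The SF network is
  the relatively redundant one and degrades more slowly — the planted
  resilience contrast. (The naive alternative — scaling *SF* hub loadings
  up — was tried first and produces the *opposite* ordering for exactly this
  budget reason; redundancy at fixed cost is a relative, compositional
  property, not an absolute edge-strength one.)
* *Damage coupling*: post sessions scale all structural loadings by
  `√(1 − damage_attenuation · burden)` with `burden = Σ fractions /
  |lesion set|` (default attenuation 2.0), and damaged regions additionally
  lose `lesion_signal_loss · fraction` of their loading variance. Heavier
  resections therefore leave a less modular, less small-world post-operative
  network, which is what the damage-score correlation is meant to recover.

**Subjects and lesions.** Group sizes default to 23/14 pre and 14/10 post.
Each post subject damages 3–6 regions drawn from a 14-region left-hemisphere
"temporal" subset (non-connector regions of the lowest modules), with
Beta(2,2) fractions; right-lateralised subjects are mirrored. Cavity volumes
are Normal(5.0, 1.8) cm³ truncated at 1 cm³ — the scale reported for real
lobectomy series. Time series are Gaussian with AR(1) innovations
(coefficient 0.3) so the band-pass filter has realistic work to do, plus two
smooth nuisance series (CSF/WM stand-ins) mixed into the data and a random-
walk motion trace per session. A per-subject loading jitter shared across
sessions induces the within-subject correlation a mixed design assumes.

**Effect-size calibration.** No empirical effect sizes exist for these
contrasts, so defaults were chosen once so that the planted effects are
detectable at the default sample sizes: band-pass filtering at TR = 2 s
reduces the effective temporal dof to ≈70, making the per-edge Fisher-Z
difference-score SD ≈0.2; `interaction_delta = 0.60` then puts the planted
interaction t around 6 against a `1/n`-corrected critical value of ≈4.3.
What a passing recovery test shows is that the *pipeline* recovers effects of
this size under these noise conditions — not that real surgical cohorts carry
effects this large.

## Preprocessing conventions

Fixed order: linear detrend → band-pass → nuisance regression. The band-pass
is a Butterworth applied forward-backward (`sosfiltfilt`; two second-order
sections, effective order 4, zero phase). Nuisance regressors are the
24-parameter motion expansion `[m, m², m₋₁, m₋₁²]`, the generator's CSF/WM
series, and the global signal defined as the unweighted mean over all ROI
series (no voxel data exists at this level). Frame-wise displacement uses
the standard 50 mm rotation-to-translation conversion. Hemisphere flipping
is a pure permutation by the homotopic partner map, applied to
right-lateralised subjects only.

## Network conventions

* Correlations are clipped to `|r| ≤ 1 − 1e−7` before `atanh` (degenerate
  synthetic inputs can reach |r| = 1).
* Cost thresholding keeps `⌊κ·N(N−1)/2 + 0.5⌋` edges (nearest-integer
  rounding minimises |achieved − requested| cost); ties at the cut are
  broken by ascending (i, j) order purely for determinism — they have
  measure zero on real data.
* Clustering is the Onnela geometric-mean form with weights normalised by
  the network-wide maximum; nodes with degree < 2 contribute 0; the global
  coefficient is the mean over all nodes. It is scale-invariant under
  uniform weight multiplication.
* Path lengths are shortest paths over `1/w`. Nodal efficiency is
  closeness-type: `E_i = (1/(N−1)) Σ_j 1/d_ij` with unreachable pairs
  contributing 0 (a local-subgraph "local efficiency" variant was
  deliberately not used; the nodal measure is kept on the same footing as
  global efficiency). The characteristic path length used inside σ averages
  finite distances over reachable ordered pairs, which keeps σ defined at
  low costs where graphs may disconnect.
* Betweenness is unnormalised Brandes betweenness, endpoints excluded, each
  unordered pair counted once (computed by igraph; verified against both
  networkx and exhaustive geodesic counting).
* Small-worldness nulls are Maslov–Sneppen degree-preserving rewirings
  (10·|E| swap attempts) with the weight multiset randomly permuted over
  the rewired topology; 100 nulls by default, fewer in desk-scale runs. The
  rewiring core is written in-package (numba-accelerated with a pure-Python
  fallback) because the analysis requires per-call seeded reproducibility.

All of these conventions are isolated behind `lobeconn.metrics` so an
alternative definition can be swapped without touching the analyses.

## Statistics

The 2×2 mixed ANOVA uses the difference-score / subject-mean decomposition,
which is exact (Type III) for a two-level within factor and handles the
unbalanced groups natively: interaction = squared pooled two-sample t on
post−pre differences; treatment = t on the unweighted grand mean of the
group difference means; outcome = squared pooled t on subject means. The
interaction identity is enforced by test against scipy and cross-checked
against pingouin's mixed ANOVA.

The edge screen retains edges whose Fisher-Z values differ from zero
(two-sided one-sample t, α = 0.05) in at least one of the four group×session
cells; the retained count n sets the `1/n` interaction threshold. The `1/n`
rule ("fewer than one false positive per analysis") is used wherever the
number of simultaneous tests defines n (removal steps, edges, nodes); no FDR
machinery is layered on top of it by default.

Clinical-table utilities expose both pooled and Welch t (group summaries in
the literature are sometimes reported with either; both are available from
raw data or from printed mean/SD/n), and Pearson χ² with Yates correction
off by default and available behind a flag.

The damage score sums `fraction_i × C.E._i` over damaged regions (a mean
variant is available behind a flag; the sum is the default because each
damaged region contributes "one value" that is then aggregated, and summing
preserves linearity in both the damage fractions and the nodal metric —
properties the tests rely on). "Percentage" is stored as a fraction in
[0, 1]; ×100 is a display convention. Volumetric profiles are computed in
label-volume voxel space with no resampling (synthetic volumes are aligned
by construction).

## Problem sizes in the shipped runs

Desk-scale runs deliberately shrink the Monte-Carlo components while keeping
the study-sized data: random-failure averages default to 100 repetitions in
the pipeline (1000 remains the `AttackConfig` default and is what a full
reproduction would use), and the recovery suites use 3–5 σ nulls per cost
instead of 100. These choices affect only Monte-Carlo precision, not the
planted-effect directions; the acceptance checks that depend on exact
expectations (e.g. the 0.68 star-graph step-1 expectation at 10,000
repetitions) use their stated sizes.

## Known limitations

* The generator's time series are Gaussian and stationary; no hemodynamic
  response, scanner drift, motion artefacts coupled to the data, or
  non-Gaussian tails. Passing recovery tests validate the pipeline's
  statistics, not its robustness to artefacts.
* Lesion "volumes" are toy block geometries; the volumetric damage path is
  exercised for correctness (label counting, NIfTI IO), not anatomy.
* Negative-correlation structure is discarded by `w = |Z|` per the analysis
  definition; no signed-network variant is provided.
* The σ null model assumes the graph has triangles at the chosen cost;
  excessively sparse costs raise an explicit error rather than returning a
  degenerate value.
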