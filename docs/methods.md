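# Methods

This note documents the models, estimators and numerical choices behind
`bbbkit`, and what the synthetic-data generators do and do not emulate.

## Transwell permeability

**Model.** A monolayer grown on a Transwell insert separates an upper
chamber (volume $V_U$, tracer concentration $C_U$) from a lower chamber
($V_L$, $C_L$). Solute flux across the composite barrier of area $S$ is
$J = P_t\,S\,(C_U - C_L)$, and the apparent permeability follows from
lower-chamber accumulation:

$$P_t = \frac{\Delta C_L}{\Delta t}\cdot\frac{V_L}{C_U\,S}.$$

Because the bare insert also resists transport, permeabilities in series
add as reciprocals, and the monolayer-only value is

$$\frac{1}{P_t} = \frac{1}{P_\text{barrier}} + \frac{1}{P_\text{insert}}
\quad\Rightarrow\quad
P_\text{barrier} = \left(\frac{1}{P_t}-\frac{1}{P_\text{insert}}\right)^{-1}.$$

**Sampling correction.** The assay draws a sample volume $V_s$ from the
lower chamber at every timepoint and replaces it with fresh medium, which
dilutes the accumulating tracer by $f = V_s/V_L$ per draw (3.3% for
50 uL from 1.5 mL). `corrected_cumulative` restores the undiluted
cumulative concentration, $C^{corr}_k = C_k + f\sum_{j<k} C_j$; for a
constant influx the corrected series is exactly linear in time.

**Depletion correction.** With the default geometry (0.5 mL upper
chamber) the driving concentration is *not* constant over a 90-minute
assay: at $P = 2\times10^{-5}$ cm/s roughly 19% of the upper-chamber
tracer leaves, and the plain least-squares slope underestimates $P$ by
~10%. `permeability_total` therefore reconstructs $C_U(t)$ at every
sampling time by mass balance (whatever is missing from the upper
chamber is in the lower chamber or was withdrawn — both recorded by the
sampled series), and regresses the transferred mass $V_L C^{corr}_k$
against the trapezoid integral $S\!\int (C_U - C_L)\,dt$. The regression
slope is $P_t$ directly. This estimator reduces exactly to the formula
above when the sink condition holds, needs no iterative model fitting,
and is unbiased (to quadrature error $\sim(\kappa\Delta t)^2/12 \approx
10^{-4}$ relative) when it does not. `assume_sink=True` selects the
literal slope-over-time estimator; a warning is emitted whenever the
corrected lower concentration exceeds 10% of $C_U$.

**Units.** Volumes in mL (= cm^3), concentrations in uM, areas in cm^2,
time in seconds internally; permeability comes out in cm/s.

## TEER

Raw chopstick-electrode readings measure monolayer plus blank filter;
the blank-filter reading is subtracted and the net resistance multiplied
by the membrane area: $\text{TEER} = (R_{total}-R_{blank})\cdot S$ in
$\Omega\,\mathrm{cm}^2$. A net resistance $\le 0$ is rejected as "no
barrier formed".

## Group comparisons

Patient (DEL) vs control (WT) comparisons use the exact two-sided
Wilcoxon matched-pairs signed-rank test: zeros dropped, mid-ranks for
tied magnitudes, and for $n \le 20$ the exact null distribution of
$W^+$ computed by subset-sum dynamic programming over doubled ranks;
the p-value is $P(|W^+-\mathbb{E}W^+| \ge |w_{obs}-\mathbb{E}W^+|)$.
Beyond $n=20$ the normal approximation is used. Ratios are reported
both as percent-of-control and fold change, and — because the two
reductions differ — both the ratio of group means and the mean of
per-pair ratios are returned. A Student's t (paired, pooled, or Welch)
is provided for densitometry-style comparisons.

## Junction and glycocalyx imaging

Junction stacks are reduced by maximum-intensity projection (the signal
is sparse and bright; sum/mean projection is available). For each
annotated border segment, 3–5 lines of ~3 um perpendicular to the
segment, equally spaced along its interior, are sampled by bilinear
interpolation at 0.25-px steps and averaged into a single profile; the
junction's score is the profile maximum (no peak fitting). Background is
the median intensity of pixels farther than 2 um from every segment
(median rather than mean for robustness), subtracted with clamping at
zero. Scores are normalised to the mean of the WT group, so the WT
normalised mean is 1 by construction; distribution shapes are compared
with Fisher excess kurtosis $g_2 = m_4/m_2^2 - 3$ on population moments.

Glycocalyx (heparan sulfate) signal is diffuse, so fields are reduced by
*mean* projection and scored by the field-mean intensity after
subtracting a user-supplied background constant (default 0; field-mean
ratios are only unbiased once background has been removed). Field means
are averaged per sample, samples per group, and DEL is normalised to the
WT mean.

## Differential expression

Counts are modelled as negative binomial with $\mathrm{Var} = \mu +
\alpha\mu^2$. The in-repo test is deliberately minimal — its purpose is
to let synthetic counts flow end-to-end, and an externally produced DEG
table can be substituted for real data:

* size factors by median-of-ratios against per-gene geometric means;
* per-gene dispersion by Bessel-corrected method of moments pooled over
  the two groups, moderated as $\alpha = \max(\alpha_{gene},
  \alpha_{pooled})$ where the pooled value aggregates all genes with
  normalised means above 5 in both groups. At $n=3$ per group gene-wise
  moment estimates are extremely noisy and anticonservative; the max
  rule keeps the null distribution of the Wald statistic close to
  standard normal (measured type-I fraction at $p<0.05$ on null
  simulations: ~0.04–0.05) while still guarding against over-dispersed
  outliers;
* Wald $z = \ln(\mu_{DEL}/\mu_{WT}) / \sqrt{\sum_g (1/\mu_g +
  \alpha)/n_g}$ against the normal reference, Benjamini–Hochberg across
  genes.

Significant DEGs use the strict rule FDR $< 0.01$ and baseMean $> 100$,
split into up (FC $> 2$) and down (FC $< 0.5$) with the in-between set
reported separately (the up/down lists are nested subsets of the
significant list). Deletion-region genes act as positive controls: the
fraction of significant deletion genes that are down-regulated is
reported, with an explicit "not applicable" result when the list is
empty or none are significant. Sample-level PCA runs on
$\log_2(\text{normalised count}+1)$ with genes centred; variance
fractions sum to 1.

Enrichment is the one-sided hypergeometric upper tail per term with BH
across terms; the universe is an explicit argument (recommended: genes
present in both the annotation and the tested matrix).

## Network topology

Analysis is restricted to the largest connected component (with a
warning when the input was disconnected), unweighted. The catalog has 13
measures: degree, closeness, harmonic, betweenness, eigenvector, Katz
(attenuation $0.85/\lambda_{max}$), PageRank (damping 0.85), subgraph,
semi-local, leverage, lobby (h-degree) and Laplacian centrality, plus
diffusion degree

$$DD(v) = \lambda\, d(v) + \sum_{u \in N(v)} \lambda\, d(u),$$

with $\lambda = 1$ by default, constant across nodes ($\lambda$ rescales
scores linearly and never changes the ranking). Columns are z-scored
(min–max optional); a column whose spread is below $10^{-12}$ relative
is treated as constant, which prevents numerical jitter on
vertex-transitive graphs from being amplified into full-range noise.

The "most informative" measure is the one with the largest absolute
loading on PC1 of the node x measure matrix, with PC1 sign-aligned to
correlate positively with degree; exact ties are reported and broken by
catalog order. Nodes are clustered with Ward-linkage agglomerative
clustering, choosing $k$ by maximal mean silhouette over $k \in
[2, \min(10, n-1)]$ (degenerate $k$ excluded by the definition of the
silhouette). Clusterings are compared by the Jaccard index on
co-clustered pairs, $|$pairs together in both$|/|$pairs together in
either$|$, defined as 1 when neither partition co-clusters any pair.
Final ranking sorts by the selected measure, descending, ties broken
lexicographically by node id; the top-ranked deletion-flagged node is
the nominated influential gene.

## Synthetic data: what it emulates, and what it does not

* **Transwell series** integrate the two-compartment mass balance with
  explicit $\le 1$ s sub-steps, transferring identical mass increments
  between chambers so tracer mass is conserved to $<10^{-10}$ relative.
  Draws are instantaneous and perfectly mixed. Measurement noise is
  additive Gaussian on recorded values only. Defaults follow the
  standard protocol (0.9 cm^2, 30 uM tracer, 50 uL draws every 10 min
  for 90 min). No osmotic/hydrostatic flux, no multi-solute effects.
* **Junction stacks** are Voronoi cell mosaics whose borders carry a
  ridge with Gaussian cross-section (FWHM 1.0 um — sub-resolution
  junctions appear PSF-widened) and a flat crest plateau of 1.5 px
  half-width modelling finite rasterisation; the crest sits exactly
  amplitude x deficit above background, which makes deficit recovery
  exactly verifiable. No optical PSF simulation, no cell-shape dynamics.
* **Glycocalyx stacks** are smooth random textures whose spatial mean is
  exactly amplitude x deficit (the texture is mean-centred before
  scaling); background defaults to 0 for these fields.
* **Counts** are NB with one dispersion parameter, log-normal baseline
  means (deletion genes drawn from a higher, tighter distribution — the
  positive controls are well-expressed), a deterministic number of DE
  genes with log-normal $|\log_2 FC|$, and uniform library-size factors.
  No read-level simulation, no GC/length biases, no per-gene dispersion
  trends.
* **Networks** are Barabási–Albert graphs; in planted-hub mode extra
  edges raise the hub's degree to at least 3x the median, 1.5x the
  largest base-graph degree, and 0.4n, making it the unambiguous
  high-influence node (diffusion-degree rank 1 in 100/100 seed-varied
  graphs at n=50).

Passing tests on these generators show the estimators are correct under
the stated noise models; they do not validate segmentation of real
confocal fields (junction segments are ground truth here,
user-annotated on real data), nor a full DESeq2-grade dispersion model.

## Problem sizes and noise defaults

The noise magnitudes are package choices: assay noise
0.005 uM (~1–2% of a typical final concentration), TEER noise 3 Ohm,
imaging noise 5% of ridge amplitude. The demo pipeline uses 6
patient-control pairs for TEER/permeability, 3 samples x 3 fields per
group for imaging (field 128 px at 0.5 um/px for glycocalyx, 256 px at
0.25 um/px for junctions), 2000 genes x 3+3 samples with a 40-gene
deletion block, and 80-node networks. These sizes keep a full run around
two seconds while leaving every group statistic well-determined.

## Known limitations

* The NB Wald test's power at $n=3$/group for a 2-fold change at
  dispersion 0.05 is ceiling-limited near 60% at FDR 0.01 for any
  correctly calibrated test; the deletion-block positive control relies
  on direction consistency (all significant deletion genes down), not on
  detecting every gene.
* Junction quantification requires border annotations; there is no
  automatic junction tracing, colocalisation, or deconvolution.
* The permeability estimator assumes a well-mixed two-compartment
  system; unstirred boundary layers are absorbed into $P$.
* Which exact centrality set the original topology analysis used is not
  recoverable; the catalog here is documented and extensible, and
  diffusion degree — the measure used for the final ranking — is fixed.
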