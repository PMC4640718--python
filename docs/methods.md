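# Methods

## The problem

Relative qPCR quantification reports a target gene's expression as a
ratio to a normalization factor derived from reference genes measured in
the same cDNA sample. Any per-sample bias shared by all genes — input
RNA amount, reverse-transcription efficiency, pipetting ("loading
effects") — cancels in that ratio, but instability of the reference
genes themselves propagates directly into every result. The package
implements the two standard stability estimators plus the upstream
screening used to nominate candidates from transcriptome compendia, and
a simulator that generates Ct data with known ground truth so all of it
can be validated end to end.

## Ct, efficiency and relative quantities

A threshold cycle Ct is the PCR cycle at which fluorescence crosses a
fixed threshold; with amplification efficiency E (ideally 2, one doubling
per cycle) the starting template scales as E^(−Ct). `preprocess`
transforms Ct to linear relative quantities Q(g,s) = E_g^(minCt_g −
Ct(g,s)), anchored per gene at the sample with minimal Ct (Q = 1). The
anchor is arbitrary: both stability algorithms operate on ratios or
centered logs, where any per-gene rescaling cancels (tested). Efficiency
defaults to 2 for every gene because the emulated workflow applies no
efficiency correction; per-gene efficiencies can be supplied.

Fold differences between genes are computed transparently as
E^(ΔmeanCt). Note that with the published mean Cts of the emulated study
(rRNA genes 7.82/8.36/13.19, protein-coding mean 22.31) no single
convention reproduces the "~850-fold" rRNA-vs-mRNA figure sometimes
quoted for such panels: 2^(22.31−13.19) ≈ 557 for the least abundant
rRNA alone, and far more for the others. The function implements the
definition and leaves interpretation to the caller.

## geNorm

For genes j,k with quantities a: V_jk = SD over samples of log2(a_j/a_k)
(n−1 denominator), M_j = mean over k≠j of V_jk. Stepwise exclusion
removes the highest-M gene and recomputes until two genes remain; the
final pair is intrinsically unordered (a single ratio cannot separate
its two members) and is reported as joint rank 1–2. Normalization
factors NF_n are per-sample geometric means of the n most stable genes
of the final ranking (final pair first, then reverse exclusion order —
one of two subtly different conventions in circulation; this one is
documented and fixed). V(n/n+1) = SD of log2(NF_n/NF_{n+1}); the optimal
gene count is the smallest n with V(n/n+1) < 0.15, falling back to all k
genes (flagged) when no n qualifies. M < 1.5 is the conventional
usability cutoff; both cutoffs are strict inequalities and configurable.

Numerical choices: log base 2 throughout (base only rescales M); ties at
the maximal M are broken by removing the lexicographically last gene id,
and every tie-break is recorded; missing Ct values are never imputed —
callers drop incomplete samples explicitly.

## NormFinder

Model on y = log2 Q: y_igs = α_i + μ_gs + d_ig + ε_igs with per-sample
loading μ shared by all genes, group-specific deviations d_ig, and noise
ε ~ N(0, σ²_ig). Per-sample centering z = y − mean over genes removes α
and μ exactly but leaks 1/k of every gene's noise and shift into every
other gene, so:

* Intra-group variances invert the moment relation
  E[v_ig] = (1−2/k)σ²_ig + (1/k²)Σ_l σ²_lg, where v_ig is the naive
  within-group variance of z: Σ̂_g = Σ_i v_ig/(1−1/k), then
  σ̂²_ig = (v_ig − Σ̂_g/k²)/(1−2/k), clamped at 0 (moment estimators go
  negative at small n). This needs k ≥ 3 and group sizes ≥ 2.
* Inter-group differences d̂_ig (group means of z, centered across
  groups; they sum to zero over genes within each group and over groups
  within each gene) are shrunk by γ̂²/(γ̂² + σ̂²_ig/n_g) with
  γ̂² = max(0, mean(d̂²) − mean(σ̂²_ig/n_g)). Because the d̂ have exact
  zero mean by construction, their "empirical variance" is computed as
  the mean of squares. |d̃| ≤ |d̂| always; pure-noise differences shrink
  to zero.
* Stability: ρ_i = (1/G) Σ_g (|d̃_ig| + √(σ̂²_ig/n_g)); with a single
  group (ungrouped mode) ρ_i = √σ̂²_i. Ranks ascend from 1; ties share
  the lower rank and order lexicographically.

Two properties of this model are worth knowing before reading results.
First, a planted group shift on one gene reappears, reflected with
opposite sign and magnitude shift/k, on every other gene — this is not a
bug but the geometry of centering: the normalization basis itself moved.
Second, in ungrouped mode the ranking is a monotone function of the
naive centered variances, so genes whose true variances differ by less
than the sampling noise of a variance estimate (≈ Var·√(2/(n−1))) cannot
be ordered reliably at any implementation quality; at n = 30–50 this
applies to noise SDs 0.05 vs 0.1 in a panel that also contains an
SD-0.8 gene. Validation therefore targets rank correlation and
worst-gene identification rather than exact full-order recovery.

## Candidate screening

Per dataset: mean (MV), SD (n−1) and CV = SD/MV per gene; keep CV
strictly < 0.2 (genes with zero mean are excluded and logged). Survivors
are intersected across datasets — a gene absent from a dataset fails
that dataset, since absence is not evidence of stability. The intensity
filter keeps genes within ±3 log2-folds (boundary-inclusive,
configurable) of an anchor gene's MV on a designated dataset; the window
interpretation is a design choice — the emulated study only says
"proper expression intensity" — and ±3 log2-folds spans the accepted
housekeeping range while excluding rRNA-scale abundance. Genes with more
than 2 annotated isoforms are dropped (splice variants defeat one primer
pair); genes without annotation are retained and logged. Every filter is
contractive and records its parameters in the result's provenance.

## Synthetic data

Ct(i,s) = base_i + shift_i,group(s) + load_s + ε_is, ε ~ N(0,
noise_sd_i²), load ~ N(0, loading_sd²) drawn once per sample — noise
lives on the Ct (log2) scale where multiplicative expression noise is
additive, making planted SDs directly comparable to geNorm M magnitudes.
Ground truth records all planted parameters and a declared stability
order (ascending noise_sd + mean |shift|). The expression generator
plants exact population CVs via the log-normal identity σ_log =
√ln(1+CV²).

Scenario presets use 13 genes mirroring a rice endosperm panel: three
rRNA-scale genes (base Ct 7.8–13.2, matching published mean Cts), two
novel candidates and eight classic housekeeping genes at Ct 19–25.
Defaults where the emulated study states none, chosen once as realistic
for qPCR on a stable tissue: per-gene noise SD 0.10–0.40 cycles for
genes reported stable, 0.55–0.90 for the classically condition-dependent
trio (UBQ10, GAPDH, β-tubulin); a 1.5-cycle heat shift on that trio in
heat groups; loading SD 0.5 cycles. Sample designs: short-term 0/1/6/12 h
(7 samples, heat vs control), long-term 7/9/12/14 DAP (8 samples),
development control-only (4 samples, analyzed ungrouped).

What a green test does and does not establish: the generator realizes
exactly the model the estimators assume (Gaussian Ct noise, shared
loading, no amplification inhibition, no Ct censoring unless enabled, no
correlation between genes beyond loading). Recovery on this data
validates the algebra and the statistical behavior of the estimators; it
does not certify performance on real plates with melt-curve failures,
efficiency heterogeneity, or replicate structure — the loader
deliberately leaves technical-replicate averaging to the user.

## Degenerate inputs and tolerances

Duplicate gene/sample ids, samples without metadata, non-numeric cells
(other than the configured missing token, default "NA") and negative
expression values are hard errors naming the offending entry. geNorm
needs ≥ 3 genes and ≥ 2 samples; NormFinder ≥ 3 genes and groups of ≥ 2.
Exactness tests assert 1e-12 on closed-form examples and 1e-9 on
invariance properties (the looser bound absorbs accumulation across the
exp/log round trip at Ct-shift magnitudes of ±5 cycles, i.e. 32-fold
loading distortions).

## Known limitations

* NormFinder here is a fixed, internally consistent estimator faithful
  to the published model's structure; it is validated by simulation
  recovery, not bit-agreement with the original Excel applet.
* No inter-run calibration, standard-curve efficiency estimation, or
  instrument-native file formats.
* The candidate screen's published gene counts (hundreds of genes from
  real RNA-seq/microarray matrices) are not reproducible without those
  matrices; the screen is validated on planted synthetic truth.
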