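# refstab

Reference-gene stability analysis for RT-qPCR normalization.

Accurate qPCR quantification divides every target-gene measurement by a
normalization factor built from one or more *reference genes* assumed to
be stably expressed. Picking those genes is itself a statistical problem:
classic housekeeping genes (Actin, GAPDH, β-tubulin …) drift under many
conditions, including heat stress in developing rice endosperm — the
setting this package's simulation presets emulate. `refstab` implements
the standard computational workflow for nominating and validating
reference genes from threshold-cycle (Ct) data and expression compendia:

* **Candidate screening** — per-dataset coefficient of variation
  (CV = SD/mean, keep CV < 0.2), cross-dataset intersection, expression
  intensity relative to an anchor gene, and isoform-count filtering.
* **geNorm** — pairwise variation `V_jk = SD_s[log2(a_j/a_k)]`, stability
  value `M_j = mean_{k≠j} V_jk`, stepwise exclusion of the highest-M
  gene, geometric-mean normalization factors `NF_n`, and the pairwise
  variation `V(n/n+1) = SD_s[log2(NF_n/NF_{n+1})]` with the 0.15 rule for
  the optimal number of reference genes (M < 1.5 marks a usable gene).
* **NormFinder** — a variance-decomposition model on per-sample-centered
  log2 expression: moment-corrected intra-group variances σ̂²·ig,
  shrunken inter-group differences d̃·ig, combined into the stability
  value ρ·i = mean over groups of (|d̃·ig| + √(σ̂²·ig/n·g)); lower is more
  stable.
* **Synthetic Ct data** — a seeded generator
  `Ct(i,s) = base_i + shift_i,group(s) + load_s + ε_is` with planted
  ground truth, including 13-gene presets mirroring a rice endosperm
  heat-stress design (rRNA-scale genes near Ct 8, mRNA-scale near 19–25;
  short-term hour series, long-term days-after-pollination series, and a
  control-only development series).

## Worked example

Simulate the short-term heat scenario and run both stability methods:

```sh
refstab run --scenario short-term --seed 3 -o out/
```

prints

```
condition: short-term
optimal number of reference genes: 2
geNorm top-2: 17S_rRNA, eIF-4a
NormFinder top-2: eIF-4a, 17S_rRNA
agreed genes: 17S_rRNA, eIF-4a (concordance 2/2)
```

Reading this: the V(2/3) pairwise variation fell below 0.15, so two
reference genes suffice for this design; geNorm's never-excluded final
pair (reported as joint rank 1–2, here M = 0.087) and NormFinder's two
lowest stability values name the same two genes, so both algorithms
agree on the pair to normalize with. `out/ranking.tsv`,
`out/stability.tsv`, `out/v_series.tsv` and `out/m_values.tsv` hold the
per-gene M values, ρ values, the V series and the full exclusion
trajectory; `out/summary.txt` repeats the text report with the
provenance of every threshold used.

The same analyses run on real data exported as TSV:

```sh
refstab genorm --ct ct.tsv --meta meta.tsv -o out/
refstab normfinder --ct ct.tsv --meta meta.tsv -o out/
```

where `ct.tsv` has genes as rows and one column per sample, and
`meta.tsv` maps `sample_id` to `group`. The library API mirrors the CLI
(`refstab.genorm_analysis`, `refstab.stability_values`,
`refstab.select_candidates`, `refstab.generate_ct_dataset`, …).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch — simulating each of the three
scenario presets from the given seed, running geNorm and NormFinder, and
writing the combined recommendation reports per scenario alongside the
JSON output.
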