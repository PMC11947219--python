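# antoni

Spatial single-cell analysis of multiplexed tissue imaging data from the
Antoni A/B histomorphic niches of NF2-related vestibular schwannoma — and,
more generally, of any segmented imaging-mass-cytometry (IMC) study with
1 µm²-pixel regions of interest.

Vestibular schwannomas are organised into hypercellular, structured
**Antoni A** regions and hypocellular, loose **Antoni B** regions. The
package implements the quantitative pipeline needed to ask how Schwann
cell, myeloid, lymphoid and vascular populations compartmentalise across
those niches:

- **Per-cell quantification** from a nuclear label mask and a channel
  stack, using a one-pixel-expansion measurement, with per-cell Jaccard
  indices for segmentation QC.
- **Phenotyping**: 99.9th-percentile marker normalisation, a
  batch-balanced kNN graph across cases, Leiden clustering, assignment of
  coarse clusters to four parent groups by canonical markers, per-group
  reclustering, and rule-based population annotation (YAML-configurable).
- **Spatial statistics**: the cross-pair correlation function
  ĝ_AB(r) out to 20 µm with exact rectangular edge correction,
  summarised by **gr20** (the [19, 20) µm bin); adjacency cell network
  (ACN) contact statistics; label-permutation significance;
  Benjamini–Hochberg FDR across pairs; consensus interaction networks per
  region class.
- **Cellular neighbourhoods (CNs)**: hop-aggregated features on a trimmed
  Delaunay graph, Gaussian-mixture clustering with Fowlkes–Mallows (FMI)
  stability selection of K, CN×cell-type enrichment, CN abundance, CN×CN
  proximity z-scores and covariate correlation.
- **Receptor–ligand scoring**: CellPhoneDB-style mean-of-means
  interaction scores with complex (subunit-minimum) handling, one-sided
  permutation p-values, the 5% expressed-fraction filter, BH FDR and
  top-20 ranking.
- **Case-level statistics**: Shapiro–Wilk-gated two-group (t / Welch t /
  Mann–Whitney U) and three-group (ANOVA+Tukey / Kruskal–Wallis+Dunnett
  T3) comparisons on case averages, plus cross-modal match accounting.
- A **synthetic tissue generator** that emulates the study conditions
  (1000×1000 µm ROIs, populations in four parent groups, Thomas-clustered
  Schwann cells, perivascular niches, TAM–T cell aggregates, per-case
  batch effects, negative-binomial expression with planted
  ligand–receptor pairs), so every stage is testable without acquired
  data.

## The statistics at the core

For an ordered pair of cell types (A, B) in a rectangular window W, the
cross-pair correlation function is estimated per radial bin [r, r+dr) as

    ĝ_AB(r) = (1/n_A) Σ_{i∈A} c_i(r) / (ρ_B · a_i(r))

where c_i counts B cells at that distance from A-cell i, ρ_B = n_B/|W|,
and a_i is the annulus area clipped to W (closed-form geometry). Under
complete spatial randomness ĝ = 1; **gr20** > 1 means co-localisation at
direct-interaction range. Significance comes from shuffling population
labels with positions fixed: p = (1 + #{|g*−1| ≥ |ĝ−1|})/(n_perm+1).

CN stability uses the Fowlkes–Mallows index FMI = TP/√((TP+FP)(TP+FN))
over co-clustered item pairs: for each K the GMM is fitted R = 10 times
and K* maximises the mean pairwise FMI among repeats (ties go to the
smaller K).

## Worked example

Run the bundled demo study (6 synthetic cases, 3 ROIs each) end to end:

```bash
antoni demo-config demo.yaml
antoni all --config demo.yaml --outdir out --seed 1
```

This writes, among other artefacts, `out/network_edges_AntoniA.csv` — the
consensus ACN interaction network of the dense region class:

```
             type_a           type_b  frac_significant_rois  weight_gr20
0      Schwann_PDL1     Schwann_core               1.000000     0.949147
...
8   TAM_alternative    TAM_classical               0.916667     0.894366
```

Each row is a type pair whose contact statistic was BH-significant in
more than half of the Antoni A ROIs; `weight_gr20` is the mean gr20
(co-localisation strength) across those ROIs. The planted TAM–T cell
aggregates and the Schwann-cell architecture of the generator reappear as
edges. `out/lr_results.csv` holds the significant receptor–ligand
interactions:

```
     pair_id sender       receiver     score   p_value   q_value direction
0  LIGA_RECA  T_CD8  TAM_classical  2.052222  0.000999  0.010989    sender
```

— the planted fold-8 pair, recovered with its lymphocyte-as-sender
orientation, and `out/match_accounting.json` reports the cross-modal
integration arithmetic (90.24% of cells aligned, 83.1% of those matched
at the 0.3 score threshold).

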