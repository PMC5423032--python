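# glycoserum

Serum glycopattern profiling and lectin-captured glycoprotein analysis for
two-group (case vs control) comparisons — built around the workflow used to
compare serum glycosylation between children with autism spectrum disorder
(ASD) and typically developing (TD) controls, but applicable to any paired
two-group lectin-microarray / LC-MS/MS / antibody-microarray study.

## What it does

Glycosylation changes are read out at four levels, each with its own module:

1. **Lectin microarrays** (`glycoserum.lectin_array`). Spot-level
   fluorescence tables are background-filtered (spots with foreground below
   `mean(bg) + 2·SD(bg)` per block are discarded), background-subtracted,
   and normalized per block to *normalized fluorescence intensities*:
   `NFI(l) = median(net_l) / Σ_l' median(net_l')`, so each block's NFIs sum
   to 1. NFIs are averaged over replicate blocks per sample (9 = 3 blocks ×
   3 slides in the emulated design). Differential glycopatterns use
   fold change = mean(case)/mean(control), gated at ≥ 1.5 (up) or ≤ 0.67
   (down) with a paired two-sided t-test (p < 0.05) over subgroup-matched
   samples. Average-linkage hierarchical clustering on 1 − Pearson distance
   produces Newick dendrograms.
2. **Label-free spectral-count quantification** (`glycoserum.spectral_quant`).
   Raw spectral counts are depth-normalized as `N_i = R_i · C̄ / C_i` where
   `C_i` is run *i*'s total count and `C̄` the mean total over all runs under
   comparison; the per-group *spectral index* (SI) is the mean normalized
   count over the group's runs, and proteins are classified by the SI ratio
   (≥ 1.5 up, ≤ 0.67 down, one-sided identifications flagged). Set
   accounting (union / intersection / group-specific counts) covers the
   identification lists.
3. **Glyco-category assignment** (`glycoserum.glyco_annotation`). Proteins
   are labelled known N-/O-glycoproteins from annotation flags, or
   *predicted* via the built-in N-sequon scanner (N-X-S/T, X ≠ P) and
   supplied O-site prediction flags, with explicit tally denominators.
4. **Glycosite motif enrichment** (`glycoserum.motif_enrichment`).
   Fixed-width windows (±13 residues) around candidate sites are mined for
   over-represented position-specific residues by iterative exact binomial
   enrichment (motif-x style); each motif reports a score (Σ −log10 p over
   its steps) and a *fold increase* (foreground vs background match-fraction
   ratio) on the original window sets.
5. **Biomarker validation** (`glycoserum.validation_roc`). Antibody-array
   signals are median-summarized per sample after the same ±2 SD background
   filter, compared between groups (paired or Welch t-test), and scored by
   an empirical ROC curve: Mann–Whitney AUC (ties ½) and a Youden-optimal
   operating point.

`glycoserum.synthetic` generates every input with known ground truth
(planted lectin folds, protein abundance ratios, motif positions, binormal
biomarker effect sizes), and `glycoserum.cli` ties the stages into a
command-line pipeline.

## Worked example

```python
import glycoserum as gs

cfg = gs.SimulationConfig(seed=1)

# lectin microarrays: 5 pooled subgroups per group, 9 blocks each
spots, meta, truth = gs.simulate_lectin_arrays(cfg)
means = gs.mean_nfi_matrix(gs.sample_profiles(spots))
diff = gs.differential_lectins(means, meta)
hits = diff[diff.direction != "unchanged"]
for row in hits.itertuples():
    print(f"{row.lectin:7s} fold={row.fold_change:5.2f} p={row.p_value:.2e} {row.direction}")

# spectral counts: triplicate runs per group, unequal depths
cm, _ = gs.simulate_spectral_counts(cfg)
quant = gs.quantify(cm)
print("up:", (quant.regulation == "up").sum(), " down:", (quant.regulation == "down").sum())

# glycosite motifs
fg, bg, _ = gs.simulate_windows(cfg)
for m in gs.extract_motifs(fg, bg):
    print(f"motif {m.pattern(6)} score={m.motif_score:.1f} fold_increase={m.fold_increase:.1f}")

# biomarker validation on 15 + 15 individual samples
sspots, smeta, _ = gs.simulate_serum_spots(cfg)
sig = gs.lgam_signals(sspots, smeta)
apod = sig[sig.antibody == "APOD"]
roc = gs.roc_curve(apod["median_signal"], apod["group"])
print(f"APOD AUC={roc.auc:.2f} sensitivity={roc.sensitivity_star:.1%} "
      f"specificity={roc.specificity_star:.1%}")
```

prints

```
MAL-I   fold= 1.92 p=3.87e-06 up
MAL-II  fold= 3.11 p=3.38e-06 up
PNA     fold= 1.68 p=2.05e-06 up
STL     fold= 0.47 p=9.20e-06 down
up: 3  down: 2
motif xxxxxKNxYxxxx score=32.0 fold_increase=210.0
APOD AUC=0.88 sensitivity=73.3% specificity=100.0%
```

The four differential lectins are the planted effects (true folds 2.20,
3.33, 1.90 and 0.54); the MAL-II estimate (3.11) sits slightly below its
true fold because NFIs are compositional — raising one lectin inflates the
block's normalization denominator. The planted lectin ACA (true fold 1.65)
falls just under the 1.5 gate for the same reason. The recovered motif is
the planted two-position enrichment (K at −1, Y at +2, penetrance 0.7), and
the APOD antibody carries the planted glycosylation shift that the ROC
analysis detects.

The same flow is available from the shell:

```bash
glycoserum all --seed 1 --outdir out/       # simulate + every stage + report.json
glycoserum lectin --spots spots.tsv --metadata meta.tsv --outdir out/lectin
```

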