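# tilescreen

Analysis pipeline for focused CRISPR dropout screens and high-density
gene-tiling screens, together with the downstream analyses that turn screen
hits into mechanism: per-residue essentiality profiles, sequence-conservation
scoring, and occupancy-based classification of transcription-factor targets.
It is aimed at functional-genomics analysts who need a tested, reproducible
implementation of these steps, exercised end to end on synthetic data with
known ground truth.

## What it computes

**Guide quantification.** Amplicon reads carry the 20-nt sgRNA spacer between
the vector cloning scar `CACCG` and the scaffold start `GTTT`. Spacers are
extracted by anchoring on those flanks, matched exactly against the library,
and converted to per-sample relative frequencies
*f<sub>g</sub> = c<sub>g</sub> / Σ<sub>g</sub> c<sub>g</sub>*.

**CRISPR scores.** For each guide and replicate, the raw score is
log₁₀(*f*<sub>final</sub>/*f*<sub>initial</sub>) (with a one-read pseudocount).
Two control-anchored normalizations are provided:

* *panel scheme* — subtract the per-replicate mean of the negative-control
  (non-essential) guides, pinning their average at 0.0;
* *dual-anchor scheme* (tiling screens) — rescale per replicate so the
  negative-control median sits at 0.0 and the positive-control (common
  essential) median at −1.0.

**Gene ranking.** Genes are ranked for negative selection by a single-level
α-RRA: guide scores become depletion percentiles *u = rank/N*; a gene with
selected percentiles *u₍₁₎ ≤ … ≤ u₍ⱼ₎ ≤ α* scores
ρ = min<sub>k</sub> P(Beta(k, j−k+1) ≤ u₍ₖ₎), with significance from
permuting guide-to-gene labels.

**Tiling profiles.** Each tiling guide maps to the protein residue containing
its Cas9 cut site (3 bp 5′ of the PAM, codon ⌈nt/3⌉); scores are averaged per
residue and smoothed with a Gaussian Nadaraya–Watson kernel (σ = 5 residues)
to give a per-residue essentiality profile, summarized over annotated domains.

**Conservation.** Alignment columns are scored by Jensen–Shannon divergence
(base 2) between the column's amino-acid distribution and the BLOSUM62
marginal background, with gap down-weighting and a ±1-column window, projected
onto the reference sequence.

**Target classification.** Significant occupancy peaks (FDR ≤ 0.05) are summed
over promoter windows (−1 kb .. +100 bp of the TSS, strand-aware). A gene is a
*bound target* when factor occupancy drops ≥ 2-fold upon knockdown; bound
targets are *CoREST-dependent* when LSD1 occupancy drops or H3K4me1/H3K4me2/
H3K27ac rises ≥ 2-fold, otherwise *CoREST-independent*; classes are then
intersected with ≥ 2-fold expression changes.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on synthetic
inputs with planted truth and write their tables under `results/`:

```bash
python analysis/01_simulate_inputs.py
python analysis/02_panel_screen.py
python analysis/03_tiling_domains.py
python analysis/04_conservation.py
python analysis/05_target_classes.py
```

`02_panel_screen.py` scores a simulated 963-guide focused screen (36 genes ×
25 guides + 41 negative + 22 positive controls; 3 replicates at 1000×
coverage over ~12.3 population doublings) in which GENE01 is essential at
−0.5 per doubling. It prints:

```
top depleted gene: GENE01 (rra_score=1.63e-33, p=0.0001) — the planted essential gene is GENE01
controls: positive median -2.96 vs negative median 0.00 (one-sided p=4.1e-11)
```

i.e. the planted essential gene tops the depletion ranking, essential
positive controls deplete by ~3 orders of magnitude in frequency, and the
negative-control anchor holds at 0. `03_tiling_domains.py` recovers the
planted essential blocks along the protein:

```
            label  start_res  end_res  mean_score  min_score  rank
       ZF_block_N         40      380   -0.949075  -0.983932     1
     ZF_block_mid        420      700   -0.852287  -0.901681     2
proline_rich_tail        820     1040   -0.000003  -0.032341     3
```

(planted effects −1.0, −0.8 and 0.0 on the dual-anchor scale, where −1 is
the positive-control median), and finds no correlation between CRISPR scores
and independently drawn on-target efficacy scores (Pearson r = 0.007,
p = 0.89). `05_target_classes.py` recovers 97.3% of planted target classes
at log-normal occupancy noise sd 0.2, with 65% of bound targets classified
CoREST-independent — matching the planted two-thirds split.

A `tilescreen` console script exposes the same steps for shell use
(`tilescreen library|count|score|tile|conserve|classify|simulate --help`).

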