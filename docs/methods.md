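# Methods

## Screen model and scoring

A dropout screen measures guide abundance at an *initial* point (shortly
after transduction and selection) and a *final* point (after the population
has expanded ~5,000–10,000-fold, i.e. ~12.3–13.3 doublings). A guide that
disrupts an essential gene depletes; its raw score is the log₁₀ fold change
of its relative library frequency between the two points, computed per
replicate.

**Pseudocount.** Frequencies are offset by ε = 1/(total matched reads of the
sample) — one read's worth of frequency — before taking logs, so a guide
that drops to zero gets a finite, maximally negative score rather than −∞.
The offset is configurable; any choice small relative to 1/N<sub>guides</sub>
changes scores of surviving guides negligibly.

**Control anchoring.** Raw log-fold changes drift with amplification depth
and sequencing composition, so scores are anchored on controls. The panel
scheme subtracts the per-replicate negative-control mean (anchor 0.0) — a
pure shift, preserving distances. The dual-anchor scheme used for tiling
screens additionally divides by the distance between the negative- and
positive-control medians, mapping "no effect" to 0.0 and "fully essential"
to −1.0; it is invariant to any affine transformation of the raw scores.
Medians are used for the dual scheme because the positive-control set is
small (22 guides) and a single outlier should not move the anchor. Both
identities hold exactly by construction and are verified to 1e−9.

**Replicate aggregation.** Normalized scores are combined across replicates
by arithmetic mean (sd reported, ddof = 1). Aggregation happens after
normalization so each replicate is anchored on its own controls. Guides
with zero counts at both timepoints carry no information and are dropped
and reported rather than scored.

## Spacer extraction and counting

The vector places the spacer between the `CACCG` cloning scar and the
`GTTT` scaffold start. Extraction takes the 20 nt after the *first*
`CACCG` and requires the next 4 nt to be `GTTT`; anything else is tallied
`no_anchor`. Extracted spacers are matched exactly (hash lookup) against
the library — with anchored extraction there is no alignment ambiguity to
resolve, and counting is deterministic and order-independent. A Hamming≤1
rescue (rejecting multi-hits) and a reverse-complement scan exist behind
flags, both off by default. Read accounting (matched + unmatched +
no_anchor = total) is an enforced invariant.

## Gene ranking (α-RRA)

Guides are ranked ascending by aggregated score (most depleted first), with
average ranks on ties, and converted to percentiles u = rank/N over all
scored guides. For a gene whose guides have j percentiles ≤ α (default
α = 0.25), the score is ρ = min₁≤k≤j P(Beta(k, j−k+1) ≤ u₍ₖ₎) — the
probability that the k-th smallest of j uniform draws would be that
extreme — and genes with no guide passing α get ρ = 1. Significance comes
from B permutations of the guide-to-gene assignment (p ∈ [1/(B+1), 1]);
default B = 10,000. This is a deliberately simple single-level
implementation of the robust-rank-aggregation idea; it does not model
count overdispersion and is not a drop-in replacement for full screen
analysis suites. Gene *rank* depends only on ρ (p-values break ties), so
recovery experiments use B = 100 to keep 50-seed sweeps fast; reported
p-values in the analysis scripts use B = 10,000.

## Tiling profiles

The Cas9 blunt cut sits between protospacer positions 17 and 18 (3 bp 5′ of
the NGG PAM); each guide is assigned the coding-strand coordinate of the
5′ side of the cut, minus-strand guides projected onto the coding strand so
all guides share one protein axis. Residue = ⌈nt/3⌉ (1-based, closed
coordinates throughout).

Scores are first averaged within each residue, then smoothed with a
Gaussian Nadaraya–Watson kernel over observed residues:
score(t) = Σⱼ w(t,j)s̄ⱼ / Σⱼ w(t,j), w = exp(−(t−j)²/2σ²). Averaging first
prevents densely tiled codons from out-voting their neighbors by guide
count; the guide-level alternative is available via `smooth_first=True` and
a regression test pins the default order. The kernel renormalizes itself at
the boundaries (truncated kernel, no reflection), which preserves constants
and keeps the output inside the input range. Default σ = 5 residues —
roughly the scale of a zinc-finger motif, wide enough to bridge the ~2.5-aa
median guide spacing without washing out domain boundaries; it is a free
parameter and declared in every output. The per-residue `support` field
counts guides cutting within ±2σ of each residue, an effective local sample
size for judging profile reliability.

## Conservation scoring

Each alignment column's amino-acid distribution (pseudocount 1e−7,
renormalized) is compared to the BLOSUM62 marginal amino-acid frequencies
by Jensen–Shannon divergence with base-2 logs, which is symmetric and
bounded in [0,1]. With the gap penalty on (default) the score is multiplied
by (1 − gap fraction); all-gap columns score 0. A sequence window blends
each column with the mean of its w−1 flanking columns
((1−λ)·base + λ·flank mean; defaults w = 3, λ = 0.5, truncated at the
ends). Columns where the reference sequence is gapped are omitted and the
rest re-indexed to reference residue numbering — conservation is only
meaningful where the reference has a residue. Alignment construction is out
of scope: input must be pre-aligned.

## Target classification

Promoters are −1 kb .. +100 bp around the TSS, strand-aware, clipped at
position 1. narrowPeak input (0-based half-open, column 9 = −log₁₀ FDR) is
converted to 1-based closed coordinates on read. Only peaks with
FDR ≤ 0.05 contribute; a gene's signal per factor and condition is the sum
of overlapping peak signals (closed-interval overlap), with a hook for
user-supplied extra regulatory intervals per gene.

The classification rule is threshold-based, not a statistical test: with
floor = 1 pseudo-signal, a gene is **bound** when the factor has control
signal > 0 and (kd+floor)/(ctrl+floor) ≤ δ_bind (default 0.5, i.e. ≥2-fold
loss). Bound genes are **CoREST-dependent** when LSD1 satisfies the same
rule at δ_mark, or any of H3K4me1/H3K4me2/H3K27ac *rises* ≥ 1/δ_mark-fold;
the remainder are **CoREST-independent**. DE status requires the table's
significance flag plus a fold change ≥ fc (up) or ≤ 1/fc (down), fc = 2 by
default. All thresholds are echoed in the output. Partition conservation
(dependent + independent = bound) is enforced.

## Synthetic data

The generators reproduce the screens' design parameters: the focused
library is 36 genes × 25 guides + 41 negative + 22 positive controls (963
guides); the tiling fixture plants exactly 416 PAM sites over a 3,120-nt
fabricated CDS (7.5 bp, 2.5 aa per guide) plus 40 negative and 22 positive
controls. The CDS backbone avoids GG/CC dinucleotides entirely (hence
contains no PAM on either strand) and GG pairs are planted at evenly spaced
positions, so the guide count is forced by construction — the trade-off is
that all planted guides are plus-strand; minus-strand projection is covered
by the enumeration tests instead.

Screen simulation: per-guide initial abundances are log-normal (sd 0.5,
typical library skew), shared across replicates up to log-normal jitter
(sd 0.1); final abundance multiplies in 2^(effect × doublings) with
doublings = log₂ 5000 ≈ 12.3 (the lower bound of the stated amplification
range); each sample draws coverage × library-size reads multinomially
(default coverage 1000×). The exact multinomial draw is emitted as truth,
which makes read counting exactly checkable. FASTQ output wraps each spacer
in a constant 75-nt vector context with constant quality — no sequencing
error model, so read-level tests verify bookkeeping, not error tolerance.

Alignment simulation plants invariant columns (one residue shared by all
rows) among columns drawn i.i.d. from the BLOSUM62 background; occupancy
simulation plants bound/dependent/independent classes as noiseless signal
ratios (factor 0.1×, LSD1 0.15×, H3K27ac 4× on dependent genes) times
log-normal noise (default sd 0.2), and the DE table is drawn consistently
with planted up/down status.

What passing these tests shows — and does not. The simulations have clean
anchors, independent guides, no PCR jackpots, no off-target effects, no
copy-number artifacts and symmetric noise; recovery rates measured here are
upper bounds on what identical settings would achieve on real screens.

## Problem sizes

Test and analysis runs use the study's design sizes (963- and 478-guide
libraries, 1000× coverage, 3 replicates) for single runs; multi-seed
recovery sweeps use 200–300 genes for occupancy and B = 100 permutations
for rank recovery, sizes at which the measured properties are already
stable. Numerical tolerances: anchor identities 1e−9; oracle equivalences
1e−10 (kernel smoothing) and 1e−12 (JSD).

## Known limitations

- RRA is single-level and permutation-calibrated; no mean–variance
  modeling, no positive-selection ranking.
- Exact spacer matching by default diverges from aligner-based mapping for
  reads with sequencing errors in the spacer.
- Occupancy classification is promoter-only; distal regulatory elements
  enter only through the explicit extra-intervals hook.
- Conservation scoring is alignment-column-based, not phylogeny-aware: it
  treats the eight sequences as exchangeable draws.
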