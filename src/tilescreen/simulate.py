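"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the designs of a focused dropout screen and a
high-density gene-tiling screen: a 963-guide focused library (36 genes x 25
guides + 41 negative + 22 positive controls), a 478-guide tiling library
(416 tiling + 40 negative + 22 positive), dropout over ~12.3 population
doublings (log2 of the 5,000-fold lower bound of the amplification range)
sampled at >= 1000x library coverage in 3 replicates, an 8-sequence protein
alignment with planted invariant columns, and promoter occupancy / DE
tables with planted dependent / independent / unbound target classes.

Every generator is deterministic given (parameters, seed) and emits a
machine-readable truth object alongside its files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .conservation import AMINO_ACIDS, BLOSUM62_BACKGROUND, ProteinAlignment
from .library import SgRNALibrary, SgRNARecord, enumerate_tiling_guides
from .quantify import ANCHOR_3, ANCHOR_5, CountTable, SampleCounts
from .targets import CONDITIONS, FACTORS, GeneModel, promoter_window

DOUBLINGS_DEFAULT = math.log2(5000)  # lower bound of the amplification range
COVERAGE_DEFAULT = 1000
REPLICATES_DEFAULT = 3

READ_PREFIX = "TTGTGGAAAG"  # vector context 5' of the cloning scar
READ_LENGTH = 75
_SUFFIX_FILL = "AGAGCTAAGC" * 8


# ---------------------------------------------------------------------------
# libraries


def _random_spacers(n: int, rng: np.random.Generator, taken: set[str] | None = None) -> list[str]:
    taken = set() if taken is None else set(taken)
    out: list[str] = []
    bases = np.array(list("ACGT"))
    while len(out) < n:
        sp = "".join(bases[rng.integers(0, 4, 20)])
        if sp not in taken:
            taken.add(sp)
            out.append(sp)
    return out


def make_panel_library(
    n_genes: int = 36,
    guides_per_gene: int = 25,
    n_negative: int = 41,
    n_positive: int = 22,
    seed: int = 0,
) -> SgRNALibrary:
    """Focused-screen library: per-gene guide sets plus both control sets."""
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i + 1:02d}" for i in range(n_genes)]
    spacers = iter(_random_spacers(n_genes * guides_per_gene + n_negative + n_positive, rng))
    records = []
    for gene in genes:
        for k in range(guides_per_gene):
            records.append(SgRNARecord(f"{gene}_g{k + 1:02d}", next(spacers), "gene_panel", gene))
    for k in range(n_negative):
        records.append(SgRNARecord(f"NEG_{k + 1:02d}", next(spacers), "negative_control"))
    for k in range(n_positive):
        records.append(SgRNARecord(f"POS_{k + 1:02d}", next(spacers), "positive_control"))
    return SgRNALibrary(records, name="panel")


def make_tiling_cds(n_pams: int = 416, density_bp: float = 7.5, seed: int = 0) -> str:
    """Fabricate a coding sequence carrying exactly ``n_pams`` NGG protospacer
    sites, all on the plus strand, by construction.

    The backbone avoids GG and CC dinucleotides entirely (so it contains no
    PAM on either strand); GG dinucleotides are then planted at evenly spaced
    positions, each yielding exactly one plus-strand guide.
    """
    rng = np.random.default_rng(seed)
    length = int(round(n_pams * density_bp))
    length += (3 - length % 3) % 3
    if length < n_pams * 3 + 25:
        raise ValueError("cds too short for the requested PAM count")

    bases = "ACGT"
    seq = []
    prev = ""
    for _ in range(length):
        choices = [b for b in bases if not (b == prev and b in "GC")]
        b = choices[rng.integers(0, len(choices))]
        seq.append(b)
        prev = b
    # plant GG pairs: PAM triplet occupies 0-based [m, m+3), GG at m+1, m+2
    span = length - 25 - 21
    positions = [21 + round(i * span / max(1, n_pams - 1)) for i in range(n_pams)]
    for m in positions:
        seq[m + 1] = "G"
        seq[m + 2] = "G"
        if seq[m] == "G":
            seq[m] = "A"
        if seq[m + 3] == "G":
            seq[m + 3] = "A"
    cds = "".join(seq)
    found = sum(1 for rec in enumerate_tiling_guides(cds) if rec.strand == "+")
    assert found == n_pams, f"planted {n_pams} PAMs but found {found}"
    return cds


def make_tiling_library(
    n_tiling: int = 416,
    n_negative: int = 40,
    n_positive: int = 22,
    density_bp: float = 7.5,
    seed: int = 0,
) -> tuple[SgRNALibrary, str]:
    """Tiling library over a fabricated CDS, plus both control sets."""
    rng = np.random.default_rng(seed)
    cds = make_tiling_cds(n_tiling, density_bp, seed)
    records = list(enumerate_tiling_guides(cds, gene="TILE"))
    taken = {r.spacer for r in records}
    spacers = iter(_random_spacers(n_negative + n_positive, rng, taken))
    for k in range(n_negative):
        records.append(SgRNARecord(f"NEG_{k + 1:02d}", next(spacers), "negative_control"))
    for k in range(n_positive):
        records.append(SgRNARecord(f"POS_{k + 1:02d}", next(spacers), "positive_control"))
    return SgRNALibrary(records, name="tiling"), cds


# ---------------------------------------------------------------------------
# dropout screen


@dataclass
class ScreenTruth:
    """Ground truth of a simulated dropout screen.

    ``effects``: per-guide fitness effect per population doubling (log2
    units, <= 0 for depleting guides; negative controls must be 0).
    """

    effects: pd.Series
    doublings: float = DOUBLINGS_DEFAULT
    coverage: int = COVERAGE_DEFAULT
    replicates: int = REPLICATES_DEFAULT
    abundance_sd: float = 0.5
    replicate_jitter_sd: float = 0.1
    seed: int = 0


def make_screen_truth(
    library: SgRNALibrary,
    essential_genes: Mapping[str, float] | None = None,
    positive_effect: float = -1.0,
    tiling_effects: Optional[pd.Series] = None,
    **kwargs,
) -> ScreenTruth:
    """Assemble per-guide effects: panel guides inherit their gene's effect,
    tiling guides take ``tiling_effects``, positive controls deplete at
    ``positive_effect`` per doubling, negative controls are neutral."""
    essential_genes = essential_genes or {}
    effects = {}
    for rec in library:
        if rec.category == "negative_control":
            effects[rec.guide_id] = 0.0
        elif rec.category == "positive_control":
            effects[rec.guide_id] = positive_effect
        elif rec.category == "tiling":
            effects[rec.guide_id] = (
                float(tiling_effects[rec.guide_id]) if tiling_effects is not None else 0.0
            )
        else:
            effects[rec.guide_id] = float(essential_genes.get(rec.target_gene, 0.0))
    return ScreenTruth(effects=pd.Series(effects).reindex([r.guide_id for r in library]), **kwargs)


def simulate_counts(library: SgRNALibrary, truth: ScreenTruth) -> tuple[CountTable, pd.DataFrame]:
    """Simulate the count table of a dropout screen.

    Initial abundances are log-normal (shared across replicates up to
    log-normal jitter); final abundance multiplies in 2^(effect x doublings);
    reads are multinomial at coverage x library size per sample.  Returns the
    count table and a truth frame with the expected frequencies per sample.
    """
    if truth.coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(truth.seed)
    gids = [r.guide_id for r in library]
    effects = truth.effects.reindex(gids).to_numpy()
    if np.isnan(effects).any():
        raise ValueError("truth.effects missing guides present in the library")
    n = len(gids)
    base = rng.lognormal(0.0, truth.abundance_sd, n)
    n_reads = truth.coverage * n
    fold = np.exp2(effects * truth.doublings)

    samples, expected = [], {}
    for rep in range(1, truth.replicates + 1):
        jitter = rng.lognormal(0.0, truth.replicate_jitter_sd, n)
        init_ab = base * jitter
        for point, ab in (("initial", init_ab), ("final", init_ab * fold)):
            f = ab / ab.sum()
            name = f"rep{rep}_{point}"
            draws = rng.multinomial(n_reads, f)
            samples.append(SampleCounts(name, pd.Series(draws, index=gids, name=name)))
            expected[name] = f
    counts = CountTable.from_samples(samples)
    truth_freq = pd.DataFrame(expected, index=pd.Index(gids, name="guide_id"))
    return counts, truth_freq


def default_pairing(replicates: int) -> dict[str, tuple[str, str]]:
    return {f"rep{r}": (f"rep{r}_initial", f"rep{r}_final") for r in range(1, replicates + 1)}


def reads_for_spacer(spacer: str) -> str:
    """One synthetic amplicon read: fixed vector context around the cassette."""
    core = READ_PREFIX + ANCHOR_5 + spacer + ANCHOR_3
    return (core + _SUFFIX_FILL)[:READ_LENGTH]


def simulate_screen(
    library: SgRNALibrary,
    truth: ScreenTruth,
    out_dir: str | Path,
) -> tuple[CountTable, pd.DataFrame, dict[str, Path]]:
    """Simulate a screen down to FASTQ files (one per sample).

    Reads carry the spacer between the CACCG / GTTT anchors inside a
    constant 75-nt vector context, with constant quality strings.  The
    returned count table is the exact per-sample multinomial draw, the
    bookkeeping oracle for read counting.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts, truth_freq = simulate_counts(library, truth)
    spacer_of = {r.guide_id: r.spacer for r in library}
    paths: dict[str, Path] = {}
    qual = "I" * READ_LENGTH
    for sample in counts.values.columns:
        path = out_dir / f"{sample}.fastq"
        with open(path, "w") as fh:
            i = 0
            for gid, k in counts.values[sample].items():
                read = reads_for_spacer(spacer_of[gid])
                for _ in range(int(k)):
                    i += 1
                    fh.write(f"@{sample}_{i}\n{read}\n+\n{qual}\n")
        paths[sample] = path
    counts.values.rename_axis("guide_id").to_csv(out_dir / "truth_counts.tsv", sep="\t")
    truth_freq.to_csv(out_dir / "truth_frequencies.tsv", sep="\t")
    return counts, truth_freq, paths


# ---------------------------------------------------------------------------
# tiling truth


def simulate_tiling_truth(
    library: SgRNALibrary,
    protein_length: int,
    features: pd.DataFrame,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.Series:
    """Per-guide fitness effects for a tiling library: the effect of the
    feature containing the guide's cut residue (0 outside all features) plus
    Gaussian noise.  ``features``: columns label, start_res, end_res, effect
    (non-overlapping 1-based closed intervals)."""
    from .tiling import cut_to_residue

    iv = features.sort_values("start_res")
    if (iv["start_res"].iloc[1:].to_numpy() <= iv["end_res"].iloc[:-1].to_numpy()).any():
        raise ValueError("feature intervals overlap")
    rng = np.random.default_rng(seed)
    effects = {}
    for rec in library.guides_in("tiling"):
        residue = cut_to_residue(rec.cds_cut_nt, protein_length)
        hit = iv[(iv["start_res"] <= residue) & (iv["end_res"] >= residue)]
        effect = float(hit["effect"].iloc[0]) if len(hit) else 0.0
        effects[rec.guide_id] = effect + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
    return pd.Series(effects, name="effect")


# ---------------------------------------------------------------------------
# protein alignment


SPECIES_8 = ("human", "chimpanzee", "rhesus_monkey", "horse",
             "pig", "cat", "chinese_hamster", "mouse")


def simulate_alignment(
    n_sequences: int = 8,
    length: int = 500,
    fraction_invariant: float = 0.5,
    gap_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[ProteinAlignment, np.ndarray]:
    """Planted-truth alignment: invariant columns share one residue across
    all rows; variable columns draw every row independently from the
    BLOSUM62 background.  Optional gaps are injected into non-reference rows.
    Returns the alignment and a boolean per-column invariance vector."""
    if not 0 <= fraction_invariant <= 1:
        raise ValueError("fraction_invariant must be in [0, 1]")
    rng = np.random.default_rng(seed)
    names = list(SPECIES_8[:n_sequences])
    if len(names) < n_sequences:
        names += [f"sp{k}" for k in range(len(names), n_sequences)]
    aa = np.array(list(AMINO_ACIDS))
    invariant = rng.random(length) < fraction_invariant
    cols = np.empty((length, n_sequences), dtype="<U1")
    for i in range(length):
        if invariant[i]:
            cols[i, :] = aa[_draw_background(rng)]
        else:
            cols[i, :] = aa[[_draw_background(rng) for _ in range(n_sequences)]]
    if gap_fraction > 0:
        gap_mask = rng.random((length, n_sequences)) < gap_fraction
        gap_mask[:, 0] = False  # reference row stays gapless
        cols[gap_mask] = "-"
    seqs = ["".join(cols[:, j]) for j in range(n_sequences)]
    return ProteinAlignment(names, seqs, reference_id=names[0]), invariant


def _draw_background(rng: np.random.Generator) -> int:
    return int(rng.choice(20, p=BLOSUM62_BACKGROUND))


# ---------------------------------------------------------------------------
# occupancy and differential expression


@dataclass
class PlantedClassification:
    """Planted truth for the target-classification workflow."""

    table: pd.DataFrame  # index gene_id; columns true_class, true_de
    noise_sd: float = 0.2
    seed: int = 0


def make_planted_genes(
    n_genes: int = 300,
    frac_bound: float = 0.4,
    frac_dependent_of_bound: float = 1 / 3,
    frac_up: float = 0.15,
    frac_down: float = 0.1,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[list[GeneModel], PlantedClassification]:
    """Gene models on one synthetic chromosome with planted classes and DE
    states, drawn independently per gene."""
    rng = np.random.default_rng(seed)
    genes = [
        GeneModel(f"G{i + 1:04d}", "chrS", 5_000 + 10_000 * i, "+" if i % 2 == 0 else "-")
        for i in range(n_genes)
    ]
    u = rng.random(n_genes)
    cls = np.where(
        u < frac_bound * frac_dependent_of_bound,
        "corest_dependent",
        np.where(u < frac_bound, "corest_independent", "unbound"),
    )
    v = rng.random(n_genes)
    de = np.where(v < frac_up, "up", np.where(v < frac_up + frac_down, "down", "none"))
    table = pd.DataFrame(
        {"true_class": cls, "true_de": de},
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
    )
    return genes, PlantedClassification(table, noise_sd=noise_sd, seed=seed)


#: noiseless occupancy ratios (kd / control) per planted class
_BASE_SIGNAL = 100.0
_BOUND_DROP = 0.1      # ZNF217 loss on bound genes
_LSD1_DROP = 0.15      # LSD1 loss on dependent genes
_MARK_GAIN = 4.0       # H3K27ac gain on dependent genes


def simulate_occupancy_and_de(
    genes: Sequence[GeneModel],
    planted: PlantedClassification,
    fc_threshold: float = 2.0,
    decoy_peaks: bool = True,
) -> tuple[dict[tuple[str, str], pd.DataFrame], pd.DataFrame]:
    """Promoter peak tables (factor x condition, 1-based closed, with fdr)
    and a DE table consistent with the planted classes.

    Dependent genes lose LSD1 and gain H3K27ac upon knockdown; bound genes
    lose the factor itself; every signal is multiplied by log-normal noise
    of sd ``planted.noise_sd``.  Decoy peaks above the FDR threshold are
    added to exercise the significance filter.
    """
    rng = np.random.default_rng(planted.seed)
    sd = planted.noise_sd
    truth = planted.table

    def noisy(x: float) -> float:
        return float(x * rng.lognormal(0.0, sd)) if sd else float(x)

    peak_rows: dict[tuple[str, str], list] = {(f, c): [] for f in FACTORS for c in CONDITIONS}
    for gene in genes:
        lo, hi = promoter_window(gene)
        mid = (lo + hi) // 2
        cls = truth.loc[gene.gene_id, "true_class"]
        ratios = {f: 1.0 for f in FACTORS}
        if cls != "unbound":
            ratios["ZNF217"] = _BOUND_DROP
        if cls == "corest_dependent":
            ratios["LSD1"] = _LSD1_DROP
            ratios["H3K27ac"] = _MARK_GAIN
        for factor in FACTORS:
            for cond in CONDITIONS:
                signal = _BASE_SIGNAL * (ratios[factor] if cond == "kd" else 1.0)
                peak_rows[(factor, cond)].append(
                    (gene.chromosome, mid - 50, mid + 50,
                     f"{factor}_{cond}_{gene.gene_id}", noisy(signal), 0.01)
                )
    peaks = {}
    for key, rows in peak_rows.items():
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "signal", "fdr"])
        if decoy_peaks:
            decoys = df.iloc[::10].copy()
            decoys["name"] = decoys["name"] + "_decoy"
            decoys["signal"] = 10 * _BASE_SIGNAL
            decoys["fdr"] = 0.2  # above threshold: must never contribute
            df = pd.concat([df, decoys], ignore_index=True)
        peaks[key] = df

    fc = np.ones(len(truth))
    for i, de in enumerate(truth["true_de"]):
        if de == "up":
            fc[i] = fc_threshold * float(rng.uniform(1.25, 4.0))
        elif de == "down":
            fc[i] = 1.0 / (fc_threshold * float(rng.uniform(1.25, 4.0)))
        else:
            fc[i] = float(rng.uniform(1 / (0.9 * fc_threshold), 0.9 * fc_threshold))
    de_table = pd.DataFrame(
        {
            "gene_id": truth.index,
            "fold_change": fc,
            "significant": (truth["true_de"] != "none").to_numpy(),
        }
    )
    return peaks, de_table


def write_narrowpeak(df: pd.DataFrame, path: str | Path) -> None:
    """Write a 1-based-closed peak frame as a standard narrowPeak file."""
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(int) - 1,
            "end": df["end"].astype(int),
            "name": df["name"],
            "score": df["signal"].round().astype(int),
            "strand": ".",
            "signal": df["signal"],
            "neglog10_p": -1,
            "neglog10_q": -np.log10(df["fdr"]),
            "summit": -1,
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)
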