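"""Transcription-factor target classification from occupancy and expression.

Workflow: assign significant occupancy peaks (factor x condition) to gene
promoters (-1 kb .. +100 bp around the TSS, strand-aware); call a gene
"bound" when factor occupancy at its promoter drops sharply upon factor
knockdown; stratify bound genes into corepressor-dependent targets (LSD1
loss, or a gain in H3K4me1/H3K4me2/H3K27ac) versus corepressor-independent
targets; intersect with the differential-expression table.

Peak inputs follow ENCODE narrowPeak conventions (0-based half-open
intervals, column 7 signalValue, column 9 -log10 FDR); they are converted to
1-based closed coordinates on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

FACTORS = ("ZNF217", "LSD1", "H3K4me1", "H3K4me2", "H3K27ac")
CONDITIONS = ("control", "kd")
MARKS = ("H3K4me1", "H3K4me2", "H3K27ac")

PROMOTER_UP = 1000   # bp upstream of the TSS
PROMOTER_DOWN = 100  # bp downstream


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chromosome: str
    tss: int      # 1-based
    strand: str   # '+' or '-'


def load_gene_models(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    genes = [GeneModel(r.gene_id, r.chrom, int(r.tss), r.strand) for r in df.itertuples()]
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene_id in gene model table")
    return genes


def promoter_window(gene: GeneModel, upstream: int = PROMOTER_UP, downstream: int = PROMOTER_DOWN) -> tuple[int, int]:
    """1-based closed promoter interval, strand-aware, clipped at position 1."""
    if gene.strand == "+":
        lo, hi = gene.tss - upstream, gene.tss + downstream
    elif gene.strand == "-":
        lo, hi = gene.tss - downstream, gene.tss + upstream
    else:
        raise ValueError(f"{gene.gene_id}: bad strand {gene.strand!r}")
    return max(1, lo), hi


def read_narrowpeak(path: str | Path) -> pd.DataFrame:
    """Read a narrowPeak file into 1-based closed coordinates with an ``fdr``
    column derived from the -log10 q-value field."""
    cols = ["chrom", "start", "end", "name", "score", "strand",
            "signal", "neglog10_p", "neglog10_q", "summit"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, dtype={"chrom": str})
    log.info("%s: converting 0-based half-open BED intervals to 1-based closed", path)
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    df["fdr"] = np.power(10.0, -df["neglog10_q"].astype(float))
    return df


def assign_signal(
    peaks: pd.DataFrame,
    genes: list[GeneModel],
    peak_fdr: float = 0.05,
    extra_intervals: Mapping[str, list[tuple[int, int]]] | None = None,
) -> pd.Series:
    """Summed signal of significant peaks (FDR <= ``peak_fdr``) overlapping
    each gene's promoter window (closed-interval overlap).

    ``peaks`` needs columns chrom/start/end/signal/fdr in 1-based closed
    coordinates (see :func:`read_narrowpeak`).  ``extra_intervals`` adds
    user-supplied regulatory intervals per gene on the gene's chromosome.
    """
    if (peaks["start"] > peaks["end"]).any():
        bad = peaks.index[peaks["start"] > peaks["end"]].tolist()
        raise ValueError(f"malformed peak intervals (start > end) at rows {bad}")
    passing = peaks[peaks["fdr"] <= peak_fdr]
    signal = pd.Series(0.0, index=pd.Index([g.gene_id for g in genes], name="gene_id"))
    by_chrom = {str(c): sub for c, sub in passing.groupby("chrom")}
    for gene in genes:
        sub = by_chrom.get(gene.chromosome)
        if sub is None:
            continue
        intervals = [promoter_window(gene)]
        if extra_intervals and gene.gene_id in extra_intervals:
            intervals.extend(extra_intervals[gene.gene_id])
        total = 0.0
        for lo, hi in intervals:
            hit = (sub["start"] <= hi) & (sub["end"] >= lo)
            total += float(sub.loc[hit, "signal"].sum())
        signal[gene.gene_id] = total
    return signal


def build_occupancy(
    peak_files: Mapping[tuple[str, str], str | Path] | Mapping[tuple[str, str], pd.DataFrame],
    genes: list[GeneModel],
    peak_fdr: float = 0.05,
) -> pd.DataFrame:
    """OccupancySet: genes x (factor, condition) summed promoter signals."""
    cols = {}
    for factor in FACTORS:
        for cond in CONDITIONS:
            src = peak_files.get((factor, cond))
            if src is None:
                raise ValueError(f"missing peaks for factor {factor!r}, condition {cond!r}")
            peaks = src if isinstance(src, pd.DataFrame) else read_narrowpeak(src)
            cols[(factor, cond)] = assign_signal(peaks, genes, peak_fdr)
    occ = pd.DataFrame(cols)
    occ.columns = pd.MultiIndex.from_tuples(occ.columns, names=["factor", "condition"])
    return occ


def classify_targets(
    occupancy: pd.DataFrame,
    delta_bind: float = 0.5,
    delta_mark: float = 0.5,
    floor: float = 1.0,
) -> pd.DataFrame:
    """Classify genes as bound / unbound and split bound genes into
    corest_dependent vs corest_independent.

    bound: factor signal present in control and
    (kd + floor) / (control + floor) <= delta_bind.
    corest_dependent: LSD1 drops by the same rule with delta_mark, or any of
    H3K4me1/H3K4me2/H3K27ac rises by >= 1/delta_mark fold.
    """
    for factor in FACTORS:
        for cond in CONDITIONS:
            if (factor, cond) not in occupancy.columns:
                raise ValueError(f"occupancy missing ({factor}, {cond})")

    def ratio(factor):
        return (occupancy[(factor, "kd")] + floor) / (occupancy[(factor, "control")] + floor)

    bound = (occupancy[("ZNF217", "control")] > 0) & (ratio("ZNF217") <= delta_bind)
    lsd1_loss = ratio("LSD1") <= delta_mark
    mark_gain = pd.concat([ratio(m) >= 1.0 / delta_mark for m in MARKS], axis=1).any(axis=1)
    dependent = bound & (lsd1_loss | mark_gain)

    cls = pd.Series("unbound", index=occupancy.index, name="class")
    cls[bound & dependent] = "corest_dependent"
    cls[bound & ~dependent] = "corest_independent"
    return pd.DataFrame({"bound": bound, "class": cls})


def integrate_de(
    classification: pd.DataFrame,
    de_table: pd.DataFrame,
    fc_threshold: float = 2.0,
) -> tuple[pd.DataFrame, dict]:
    """Attach DE status (up / down / none at ``fc_threshold``-fold, significant
    calls only) and emit the partition counts of the bound-target analysis.

    ``de_table``: columns gene_id, fold_change, significant.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must exceed 1")
    de = de_table.set_index("gene_id") if "gene_id" in de_table.columns else de_table
    fc = de["fold_change"].reindex(classification.index)
    sig = de["significant"].reindex(classification.index).fillna(False).astype(bool)

    status = pd.Series("none", index=classification.index, name="de_status")
    status[sig & (fc >= fc_threshold)] = "up"
    status[sig & (fc <= 1.0 / fc_threshold)] = "down"

    out = classification.copy()
    out["de_status"] = status
    bound = out["bound"]
    indep = out["class"] == "corest_independent"
    counts = {
        "bound": int(bound.sum()),
        "corest_dependent": int((out["class"] == "corest_dependent").sum()),
        "corest_independent": int(indep.sum()),
        "bound_up": int((bound & (status == "up")).sum()),
        "independent_up": int((indep & (status == "up")).sum()),
        "bound_down": int((bound & (status == "down")).sum()),
        "independent_down": int((indep & (status == "down")).sum()),
    }
    assert counts["corest_dependent"] + counts["corest_independent"] == counts["bound"]
    return out, counts
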