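"""Per-residue essentiality profiles from tiling-guide CRISPR scores.

Each tiling guide's aggregated score is assigned to the protein residue
containing its cut site (codon arithmetic), scores sharing a residue are
averaged, and the sparse residue map is smoothed with a Gaussian
(Nadaraya-Watson) kernel over the full protein axis.  Averaging precedes
smoothing so that densely tiled codons do not out-vote their neighbors by
guide count alone; ``smooth_first=True`` flips the order for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .library import SgRNALibrary


@dataclass
class TilingProfile:
    residue_scores: pd.Series  # index 1..protein_length
    sigma: float               # kernel bandwidth, residues
    support: pd.Series         # guides with a cut within +/- 2 sigma of each residue
    protein_length: int


@dataclass
class FeatureAnnotation:
    """Named 1-based closed intervals on the protein (domains, motifs)."""

    table: pd.DataFrame  # columns label, start_res, end_res

    def __post_init__(self) -> None:
        t = self.table
        if t["label"].duplicated().any():
            raise ValueError("feature labels must be unique")
        if ((t["start_res"] < 1) | (t["start_res"] > t["end_res"])).any():
            raise ValueError("features need 1 <= start_res <= end_res")

    @classmethod
    def from_tsv(cls, path) -> "FeatureAnnotation":
        return cls(pd.read_csv(path, sep="\t"))


def cut_to_residue(cds_cut_nt: int, protein_length: int) -> int:
    """Residue containing a coding-strand nucleotide: ceil(nt / 3)."""
    if not 1 <= cds_cut_nt <= 3 * protein_length:
        raise ValueError(
            f"cds_cut_nt {cds_cut_nt} outside coding range 1..{3 * protein_length}"
        )
    return math.ceil(cds_cut_nt / 3)


def guide_residues(library: SgRNALibrary, protein_length: int) -> pd.Series:
    """Cut residue per tiling guide (minus-strand guides use their projected
    coding-strand coordinate, so one shared axis)."""
    recs = library.guides_in("tiling")
    if not recs:
        raise ValueError("library has no tiling guides")
    return pd.Series(
        {r.guide_id: cut_to_residue(r.cds_cut_nt, protein_length) for r in recs},
        name="residue",
    )


def per_residue_average(scores: pd.Series, residues: pd.Series) -> pd.Series:
    """Mean aggregated score per residue over the guides cutting there;
    residues with no guide are absent."""
    common = scores.index.intersection(residues.index)
    if len(common) == 0:
        raise ValueError("no guides shared between scores and residue assignment")
    return scores[common].groupby(residues[common]).mean().sort_index()


def smooth_profile(
    residue_means: pd.Series,
    sigma: float,
    protein_length: int,
    support_counts: pd.Series | None = None,
) -> TilingProfile:
    """Gaussian Nadaraya-Watson smoothing of a sparse residue score map onto
    residues 1..protein_length.

    score(t) = sum_j w(t,j) s_j / sum_j w(t,j), w(t,j) = exp(-(t-j)^2 / 2 sigma^2)
    over observed residues j; weights renormalize themselves at the
    boundaries (truncated kernel, no padding).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if len(residue_means) == 0:
        raise ValueError("empty residue score map")
    t = np.arange(1, protein_length + 1, dtype=float)
    j = residue_means.index.to_numpy(dtype=float)
    s = residue_means.to_numpy(dtype=float)
    w = np.exp(-((t[:, None] - j[None, :]) ** 2) / (2.0 * sigma**2))
    smoothed = (w @ s) / w.sum(axis=1)

    counts = support_counts if support_counts is not None else pd.Series(1, index=residue_means.index)
    cj = counts.reindex(residue_means.index).fillna(0).to_numpy(dtype=float)
    near = np.abs(t[:, None] - j[None, :]) <= 2.0 * sigma
    support = (near * cj).sum(axis=1).astype(int)

    idx = pd.RangeIndex(1, protein_length + 1, name="residue")
    return TilingProfile(
        residue_scores=pd.Series(smoothed, index=idx, name="score"),
        sigma=sigma,
        support=pd.Series(support, index=idx, name="support"),
        protein_length=protein_length,
    )


def profile_from_scores(
    scores: pd.Series,
    library: SgRNALibrary,
    protein_length: int,
    sigma: float = 5.0,
    smooth_first: bool = False,
) -> TilingProfile:
    """Aggregated guide scores -> smoothed per-residue profile."""
    residues = guide_residues(library, protein_length)
    if smooth_first:
        # alternative order: every guide is its own observation at its residue
        common = scores.index.intersection(residues.index)
        means = scores[common].copy()
        means.index = pd.Index(residues[common], name="residue")
        # smooth over the multiset of guide observations directly
        t = np.arange(1, protein_length + 1, dtype=float)
        jj = means.index.to_numpy(dtype=float)
        w = np.exp(-((t[:, None] - jj[None, :]) ** 2) / (2.0 * sigma**2))
        smoothed = (w @ means.to_numpy()) / w.sum(axis=1)
        idx = pd.RangeIndex(1, protein_length + 1, name="residue")
        near = np.abs(t[:, None] - jj[None, :]) <= 2.0 * sigma
        return TilingProfile(
            residue_scores=pd.Series(smoothed, index=idx, name="score"),
            sigma=sigma,
            support=pd.Series(near.sum(axis=1).astype(int), index=idx, name="support"),
            protein_length=protein_length,
        )
    residues_used = residues[scores.index.intersection(residues.index)]
    means = per_residue_average(scores, residues)
    counts = residues_used.value_counts().sort_index()
    return smooth_profile(means, sigma, protein_length, support_counts=counts)


def annotate_profile(profile: TilingProfile, features: FeatureAnnotation) -> pd.DataFrame:
    """Per-feature mean and minimum smoothed score, ranked ascending by mean
    (most essential feature first)."""
    if (features.table["end_res"] > profile.protein_length).any():
        raise ValueError("feature interval extends beyond protein length")
    rows = []
    for row in features.table.itertuples(index=False):
        window = profile.residue_scores.loc[row.start_res : row.end_res]
        rows.append((row.label, row.start_res, row.end_res, window.mean(), window.min()))
    out = pd.DataFrame(rows, columns=["label", "start_res", "end_res", "mean_score", "min_score"])
    out = out.sort_values("mean_score", kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def efficacy_correlation(scores: pd.Series, efficacy: pd.Series) -> dict:
    """Pearson and Spearman correlation between guide CRISPR scores and
    predicted on-target efficacy scores, with two-sided p-values.

    Constant inputs leave the correlation undefined (NaN, flagged)."""
    common = scores.index.intersection(efficacy.index)
    x = scores[common].astype(float)
    y = efficacy[common].astype(float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 finite score/efficacy pairs")
    if x.nunique() == 1 or y.nunique() == 1:
        return {"n": len(x), "degenerate": True, "pearson_r": float("nan"),
                "pearson_p": float("nan"), "spearman_rho": float("nan"),
                "spearman_p": float("nan")}
    pr = stats.pearsonr(x, y)
    sp = stats.spearmanr(x, y)
    return {
        "n": len(x),
        "degenerate": False,
        "pearson_r": float(pr.statistic),
        "pearson_p": float(pr.pvalue),
        "spearman_rho": float(sp.statistic),
        "spearman_p": float(sp.pvalue),
    }
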