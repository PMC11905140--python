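"""Per-guide CRISPR scores and gene-level depletion ranking.

The CRISPR score of a guide is the log10 fold change of its library
frequency from the screen's initial to its final sampling point, anchored on
the control guides:

* panel scheme — subtract the per-replicate mean log10 fold change of the
  negative-control (non-essential) guides, pinning their average at 0.0;
* dual-anchor (tiling) scheme — affinely rescale per replicate so that the
  negative-control median sits at 0.0 and the positive-control (common
  essential) median at -1.0.

Genes are ranked for negative selection with a single-level alpha-RRA:
guides are converted to depletion percentiles, each gene is scored by the
minimum Beta order-statistic tail probability over its guides passing the
alpha cutoff, and significance is calibrated by permuting guide-to-gene
labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .library import SgRNALibrary
from .quantify import CountTable, FrequencyTable

Pairing = Mapping[str, tuple[str, str]]  # replicate -> (initial sample, final sample)


@dataclass
class ScoreTable:
    raw_lfc: pd.DataFrame          # guide x replicate log10 fold changes
    normalized: pd.DataFrame       # guide x replicate CRISPR scores
    aggregated: pd.DataFrame       # columns: score_mean, score_sd
    pseudocount: Union[float, Mapping[str, float]]
    scheme: str                    # 'panel_anchor' or 'dual_anchor'
    dropped: list[str]             # guides unscored (zero counts at both timepoints)


def auto_pseudocount(counts: CountTable) -> dict[str, float]:
    """Frequency offset of one read: 1 / total matched reads per sample."""
    totals = counts.values.sum(axis=0)
    return {s: (1.0 / t if t > 0 else 1.0) for s, t in totals.items()}


def log10_fold_change(
    freq: FrequencyTable,
    pairing: Pairing,
    pseudocount: Union[float, Mapping[str, float]] = 0.0,
) -> pd.DataFrame:
    """raw_lfc(g, r) = log10((f_final + eps_final) / (f_initial + eps_initial)).

    ``pseudocount`` is a single frequency offset or a per-sample mapping
    (see :func:`auto_pseudocount`).
    """
    cols = {}
    for rep, pair in pairing.items():
        try:
            initial, final = pair
        except (TypeError, ValueError) as exc:
            raise ValueError(f"replicate {rep!r}: pairing must be (initial, final)") from exc
        for s in (initial, final):
            if s not in freq.values.columns:
                raise ValueError(f"replicate {rep!r}: sample {s!r} missing from frequency table")
        eps_i = pseudocount[initial] if isinstance(pseudocount, Mapping) else pseudocount
        eps_f = pseudocount[final] if isinstance(pseudocount, Mapping) else pseudocount
        with np.errstate(divide="ignore"):
            cols[rep] = np.log10(
                (freq.values[final] + eps_f) / (freq.values[initial] + eps_i)
            )
    return pd.DataFrame(cols, index=freq.values.index)


def _control_mask(raw_lfc: pd.DataFrame, library: SgRNALibrary, category: str) -> pd.Index:
    ids = [r.guide_id for r in library.guides_in(category)]
    present = raw_lfc.index.intersection(ids)
    if len(present) == 0:
        raise ValueError(f"no {category} guides present in score table")
    return present


def normalize_panel(raw_lfc: pd.DataFrame, library: SgRNALibrary) -> pd.DataFrame:
    """Subtract the per-replicate negative-control mean (anchor at 0.0)."""
    neg = _control_mask(raw_lfc, library, "negative_control")
    anchor = raw_lfc.loc[neg].mean(axis=0)
    if not np.isfinite(anchor).all():
        raise ValueError("negative-control mean is not finite in some replicate")
    return raw_lfc - anchor


def normalize_tiling(raw_lfc: pd.DataFrame, library: SgRNALibrary) -> pd.DataFrame:
    """Dual-anchor rescale: negative-control median -> 0.0, positive-control
    median -> -1.0, per replicate."""
    neg = _control_mask(raw_lfc, library, "negative_control")
    pos = _control_mask(raw_lfc, library, "positive_control")
    m_neg = raw_lfc.loc[neg].median(axis=0)
    m_pos = raw_lfc.loc[pos].median(axis=0)
    span = m_neg - m_pos
    if (span == 0).any() or not np.isfinite(span).all():
        bad = [str(r) for r in span.index[(span == 0) | ~np.isfinite(span)]]
        raise ValueError(f"degenerate control anchors (equal medians) in replicates {bad}")
    return raw_lfc.sub(m_neg, axis=1).div(span, axis=1)


def aggregate_replicates(normalized: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean and sample sd (ddof=1) of scores across replicates."""
    if normalized.shape[1] == 0:
        raise ValueError("need at least one replicate")
    return pd.DataFrame(
        {
            "score_mean": normalized.mean(axis=1),
            "score_sd": normalized.std(axis=1, ddof=1),
        }
    )


def score_screen(
    counts: CountTable,
    pairing: Pairing,
    library: SgRNALibrary,
    scheme: str = "panel_anchor",
    pseudocount: Union[float, Mapping[str, float], str] = "auto",
) -> ScoreTable:
    """Counts -> frequencies -> raw log10 FC -> normalized scores -> aggregate.

    Guides with zero counts at both timepoints of every replicate carry no
    information and are dropped from the table (reported in ``dropped``).
    """
    from .quantify import frequencies

    if pseudocount == "auto":
        pseudocount = auto_pseudocount(counts)
    freq = frequencies(counts)
    raw = log10_fold_change(freq, pairing, pseudocount)
    used = [s for pair in pairing.values() for s in pair]
    dead = counts.values[used].sum(axis=1) == 0
    dropped = [str(g) for g in raw.index[dead]]
    raw = raw.loc[~dead]
    if scheme == "panel_anchor":
        normalized = normalize_panel(raw, library)
    elif scheme == "dual_anchor":
        normalized = normalize_tiling(raw, library)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return ScoreTable(
        raw_lfc=raw,
        normalized=normalized,
        aggregated=aggregate_replicates(normalized),
        pseudocount=pseudocount,
        scheme=scheme,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# alpha-RRA gene ranking


def _rho(percentiles: np.ndarray, alpha: float) -> np.ndarray:
    """Robust rank aggregation score for each row of ``percentiles``.

    rho = min over the k-th smallest percentiles u_(k) <= alpha of
    P(Beta(k, j-k+1) <= u_(k)), with j the number of percentiles passing
    alpha; rows with j = 0 score 1.
    """
    u = np.sort(np.atleast_2d(percentiles), axis=-1)
    n = u.shape[-1]
    j = (u <= alpha).sum(axis=-1)
    k = np.arange(1, n + 1)
    valid = k <= j[..., None]
    b = np.where(valid, j[..., None] - k + 1, 1)
    cdf = stats.beta.cdf(u, k, b)
    rho = np.where(valid, cdf, np.inf).min(axis=-1)
    return np.where(j > 0, rho, 1.0)


@dataclass
class GeneRanking:
    table: pd.DataFrame  # index gene; columns rra_score, p_value, rank
    alpha: float
    permutations: int
    seed: int


def rra_gene_rank(
    aggregated: pd.Series,
    library: SgRNALibrary,
    alpha: float = 0.25,
    permutations: int = 10_000,
    seed: int = 0,
) -> GeneRanking:
    """Rank gene-panel genes for negative selection.

    Depletion percentiles u = rank/N are computed over every scored guide
    (controls included; ties get average ranks).  Each gene's rho is the
    alpha-RRA order-statistic minimum over its guides; its p-value is the
    tail probability of rho under ``permutations`` random reassignments of
    guides to genes.  Output is ranked ascending by rho, ties broken by
    p-value then gene id.
    """
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if permutations < 100:
        raise ValueError("need at least 100 permutations")

    scores = aggregated.dropna()
    u_all = stats.rankdata(scores.to_numpy()) / len(scores)
    u = pd.Series(u_all, index=scores.index)

    gene_guides: dict[str, list[str]] = {}
    for rec in library.guides_in("gene_panel"):
        if rec.guide_id in u.index:
            gene_guides.setdefault(rec.target_gene, []).append(rec.guide_id)
    if not gene_guides:
        raise ValueError("no gene_panel guides with scores")

    genes = sorted(gene_guides)
    sizes = {g: len(gene_guides[g]) for g in genes}
    obs_rho = {}
    for n in sorted(set(sizes.values())):
        group = [g for g in genes if sizes[g] == n]
        mat = np.array([u[gene_guides[g]].to_numpy() for g in group])
        obs_rho.update(dict(zip(group, _rho(mat, alpha))))

    # permutation null: reassign guide labels, i.e. draw each gene's guides
    # as a slice of a fresh permutation of the full percentile pool
    rng = np.random.default_rng(seed)
    B = permutations
    pool = u.to_numpy()
    perms = rng.permuted(np.broadcast_to(pool, (B, len(pool))).copy(), axis=1)
    p_values = {}
    offset = 0
    for g in genes:
        n = sizes[g]
        null_rho = _rho(perms[:, offset : offset + n], alpha)
        offset += n
        p_values[g] = (1 + int((null_rho <= obs_rho[g]).sum())) / (B + 1)

    table = pd.DataFrame(
        {"rra_score": [obs_rho[g] for g in genes], "p_value": [p_values[g] for g in genes]},
        index=pd.Index(genes, name="gene"),
    )
    # genes enter lexically sorted, so a stable sort breaks ties by gene id
    table = table.sort_values(["rra_score", "p_value"], kind="stable")
    table["rank"] = np.arange(1, len(table) + 1)
    return GeneRanking(table=table, alpha=alpha, permutations=B, seed=seed)


def control_behavior_report(aggregated: pd.Series, library: SgRNALibrary) -> dict:
    """Summarize control-guide behavior: per-category mean/median and a
    one-sided rank-sum test of positives being more depleted than negatives."""
    pos_ids = [r.guide_id for r in library.guides_in("positive_control")]
    neg_ids = [r.guide_id for r in library.guides_in("negative_control")]
    pos = aggregated.reindex(pos_ids).dropna()
    neg = aggregated.reindex(neg_ids).dropna()
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both control categories must be present and scored")
    stat, p = stats.mannwhitneyu(pos, neg, alternative="less")
    return {
        "positive_control": {"n": len(pos), "mean": float(pos.mean()), "median": float(pos.median())},
        "negative_control": {"n": len(neg), "mean": float(neg.mean()), "median": float(neg.median())},
        "rank_sum_statistic": float(stat),
        "p_value_one_sided": float(p),
    }
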