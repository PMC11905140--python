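"""Per-residue conservation scoring from a multi-species protein alignment.

Each alignment column is scored by the Jensen-Shannon divergence (base-2
logs, bounded in [0, 1]) between the column's amino-acid distribution and a
fixed background — the BLOSUM62 marginal amino-acid frequencies — optionally
down-weighted by the column's gap fraction and blended with the mean score
of flanking columns (sequence-window smoothing).  Columns where the
reference sequence carries a gap are dropped, and the remaining scores are
re-indexed to reference residue numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
GAP = "-"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

# BLOSUM62 marginal amino-acid frequencies (order ARNDCQEGHILKMFPSTWYV),
# normalized to sum 1 below.
_BLOSUM62_MARGINALS = np.array(
    [0.078, 0.051, 0.041, 0.052, 0.024, 0.034, 0.059, 0.083, 0.025, 0.062,
     0.092, 0.056, 0.024, 0.044, 0.043, 0.059, 0.055, 0.014, 0.034, 0.072]
)
BLOSUM62_BACKGROUND = _BLOSUM62_MARGINALS / _BLOSUM62_MARGINALS.sum()


class AlignmentError(ValueError):
    pass


@dataclass
class ProteinAlignment:
    names: list[str]
    sequences: list[str]  # aligned, equal length, 20 AAs + '-'
    reference_id: str

    def __post_init__(self) -> None:
        if len(self.names) != len(self.sequences) or not self.names:
            raise AlignmentError("names and sequences must be non-empty and parallel")
        L = len(self.sequences[0])
        allowed = set(AMINO_ACIDS + GAP)
        for name, seq in zip(self.names, self.sequences):
            if len(seq) != L:
                raise AlignmentError(f"{name}: row length {len(seq)} != {L}")
            bad = set(seq) - allowed
            if bad:
                raise AlignmentError(f"{name}: disallowed characters {sorted(bad)}")
        if self.reference_id not in self.names:
            raise AlignmentError(f"reference {self.reference_id!r} not in alignment")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def reference(self) -> str:
        return self.sequences[self.names.index(self.reference_id)]

    def column(self, i: int) -> str:
        return "".join(seq[i] for seq in self.sequences)

    @classmethod
    def from_fasta(cls, path: str | Path, reference_id: str) -> "ProteinAlignment":
        from Bio import SeqIO

        names, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            names.append(rec.id)
            seqs.append(str(rec.seq).upper().replace(".", GAP))
        return cls(names, seqs, reference_id)


@dataclass
class ConservationProfile:
    scores: pd.DataFrame        # index ref residue 1..L_ref; columns ref_aa, score
    omitted_columns: list[int]  # 0-based alignment columns where the reference is gapped
    window: int
    window_weight: float
    pseudocount: float
    gap_penalty: bool


def column_distribution(column: str, pseudocount: float = 0.0):
    """Amino-acid distribution of one alignment column.

    Returns ``(probs, gap_fraction)``: relative frequencies over non-gap
    residues with a uniform pseudocount, renormalized.  An all-gap column is
    degenerate: probs is None.
    """
    if not column:
        raise AlignmentError("empty column")
    gaps = column.count(GAP)
    gap_fraction = gaps / len(column)
    if gaps == len(column):
        return None, 1.0
    counts = np.zeros(20)
    for aa in column:
        if aa != GAP:
            counts[_AA_INDEX[aa]] += 1
    probs = counts / counts.sum()
    if pseudocount:
        probs = probs + pseudocount
        probs = probs / probs.sum()
    return probs, gap_fraction


def jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence with base-2 logs: 0.5 KL(p||m) + 0.5 KL(q||m),
    m = (p+q)/2.  Symmetric, bounded in [0, 1]; 0 log 0 := 0."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = 0.5 * (p + q)

    def _kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))

    return 0.5 * _kl(p, m) + 0.5 * _kl(q, m)


def conservation_profile(
    aln: ProteinAlignment,
    background: Optional[np.ndarray] = None,
    window: int = 3,
    window_weight: float = 0.5,
    pseudocount: float = 1e-7,
    gap_penalty: bool = True,
) -> ConservationProfile:
    """Score every reference residue's conservation in [0, 1].

    Per column: base = JSD(column distribution, background), times
    (1 - gap fraction) when ``gap_penalty``.  The windowed score blends the
    base score with the mean base score of the (window - 1) flanking columns
    (truncated at the alignment ends): (1-w_l) * base + w_l * flank_mean.
    Columns gapped in the reference are omitted and reported.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if not 0 <= window_weight <= 1:
        raise ValueError("window_weight must be in [0, 1]")
    bg = BLOSUM62_BACKGROUND if background is None else np.asarray(background, float)

    base = np.zeros(aln.length)
    for i in range(aln.length):
        probs, gap_fraction = column_distribution(aln.column(i), pseudocount)
        if probs is None:
            base[i] = 0.0
            continue
        score = jsd(probs, bg)
        if gap_penalty:
            score *= 1.0 - gap_fraction
        base[i] = score

    if window == 1:
        windowed = base
    else:
        half = (window - 1) // 2
        windowed = np.empty_like(base)
        for i in range(len(base)):
            lo, hi = max(0, i - half), min(len(base), i + half + 1)
            flank = np.concatenate([base[lo:i], base[i + 1 : hi]])
            flank_mean = flank.mean() if flank.size else base[i]
            windowed[i] = (1 - window_weight) * base[i] + window_weight * flank_mean

    ref = aln.reference
    omitted = [i for i, aa in enumerate(ref) if aa == GAP]
    kept = [i for i, aa in enumerate(ref) if aa != GAP]
    scores = pd.DataFrame(
        {
            "ref_aa": [ref[i] for i in kept],
            "score": windowed[kept],
        },
        index=pd.RangeIndex(1, len(kept) + 1, name="ref_residue"),
    )
    return ConservationProfile(
        scores=scores,
        omitted_columns=omitted,
        window=window,
        window_weight=window_weight,
        pseudocount=pseudocount,
        gap_penalty=gap_penalty,
    )
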