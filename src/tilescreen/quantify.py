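"""Spacer extraction from screen reads and guide counting.

Amplicon reads carry the integrated sgRNA cassette: the 20-nt spacer sits
between the vector cloning scar ``CACCG`` (5') and the scaffold start
``GTTT`` (3').  Extraction anchors on the first ``CACCG`` in the read and
accepts the following 20 nt only when they are immediately followed by
``GTTT``; extracted spacers are matched exactly against the library.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from .library import SPACER_LEN, SgRNALibrary, revcomp

log = logging.getLogger(__name__)

ANCHOR_5 = "CACCG"
ANCHOR_3 = "GTTT"


@dataclass
class SampleCounts:
    """Per-guide read counts for one sample, with read accounting.

    Invariant: matched + unmatched + no_anchor == total reads processed,
    where matched = counts.sum().
    """

    sample: str
    counts: pd.Series  # index: guide_id, non-negative ints
    unmatched: int = 0
    no_anchor: int = 0

    @property
    def matched(self) -> int:
        return int(self.counts.sum())

    @property
    def total(self) -> int:
        return self.matched + self.unmatched + self.no_anchor


@dataclass
class CountTable:
    """Guide x sample read-count matrix plus per-sample accounting."""

    values: pd.DataFrame            # index guide_id, columns sample names
    accounting: pd.DataFrame        # index sample, columns matched/unmatched/no_anchor

    @classmethod
    def from_samples(cls, samples: Iterable[SampleCounts]) -> "CountTable":
        samples = list(samples)
        values = pd.DataFrame({s.sample: s.counts for s in samples})
        acct = pd.DataFrame(
            {
                "matched": [s.matched for s in samples],
                "unmatched": [s.unmatched for s in samples],
                "no_anchor": [s.no_anchor for s in samples],
            },
            index=[s.sample for s in samples],
        )
        return cls(values, acct)

    def to_tsv(self, counts_path: str | Path, accounting_path: Optional[str | Path] = None) -> None:
        self.values.rename_axis("guide_id").to_csv(counts_path, sep="\t")
        if accounting_path is not None:
            self.accounting.rename_axis("sample").to_csv(accounting_path, sep="\t")


@dataclass
class FrequencyTable:
    """Per-sample relative guide frequencies (columns sum to 1 unless a
    sample matched zero reads, in which case the column is all-zero and
    listed in ``degenerate``)."""

    values: pd.DataFrame
    degenerate: list[str] = field(default_factory=list)


def extract_spacer(read: str) -> Optional[str]:
    """Return the 20-nt spacer between the first ``CACCG`` and a following
    ``GTTT``, or None when the read does not conform."""
    i = read.find(ANCHOR_5)
    if i < 0:
        return None
    start = i + len(ANCHOR_5)
    end = start + SPACER_LEN
    if read[end : end + len(ANCHOR_3)] != ANCHOR_3:
        return None
    return read[start:end]


def _read_fastq_sequences(path: str | Path) -> Iterator[str]:
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            yield str(rec.seq).upper()


def count_reads(
    reads: Iterable[str] | str | Path,
    library: SgRNALibrary,
    sample: str = "sample",
    max_mismatch: int = 0,
    scan_revcomp: bool = False,
) -> SampleCounts:
    """Count library guides in a FASTQ file (or an iterable of read strings).

    Matching is exact by default.  With ``max_mismatch=1`` a spacer missing
    from the library is assigned to a guide at Hamming distance 1 when that
    assignment is unique; ambiguous multi-hits stay unmatched.  Spacers
    containing N never match.
    """
    if library is None or len(library) == 0:
        raise ValueError("count_reads requires a non-empty library")
    if isinstance(reads, (str, Path)):
        reads = _read_fastq_sequences(reads)

    index = library.spacer_index()
    counts = {gid: 0 for gid in library.guide_ids}
    unmatched = 0
    no_anchor = 0
    n_reads = 0
    for read in reads:
        n_reads += 1
        spacer = extract_spacer(read)
        if spacer is None and scan_revcomp:
            spacer = extract_spacer(revcomp(read))
        if spacer is None:
            no_anchor += 1
            continue
        gid = index.get(spacer)
        if gid is None and max_mismatch >= 1 and "N" not in spacer:
            gid = _hamming1_unique(spacer, index)
        if gid is None:
            unmatched += 1
        else:
            counts[gid] += 1
    if n_reads == 0:
        log.warning("sample %s: empty read stream, emitting zero counts", sample)
    return SampleCounts(
        sample=sample,
        counts=pd.Series(counts, name=sample, dtype=int),
        unmatched=unmatched,
        no_anchor=no_anchor,
    )


def _hamming1_unique(spacer: str, index: dict[str, str]) -> Optional[str]:
    hits = []
    for pos in range(len(spacer)):
        for base in "ACGT":
            if base == spacer[pos]:
                continue
            cand = spacer[:pos] + base + spacer[pos + 1 :]
            gid = index.get(cand)
            if gid is not None:
                hits.append(gid)
                if len(hits) > 1:
                    return None
    return hits[0] if len(hits) == 1 else None


def frequencies(counts: CountTable) -> FrequencyTable:
    """Per-sample relative frequency: count / total matched reads of the
    library in that sample."""
    totals = counts.values.sum(axis=0)
    degenerate = [str(s) for s in totals.index[totals == 0]]
    if degenerate:
        log.warning("samples with zero matched reads: %s", degenerate)
    safe = totals.replace(0, 1)
    values = counts.values.div(safe, axis=1).astype(float)
    return FrequencyTable(values=values, degenerate=degenerate)
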