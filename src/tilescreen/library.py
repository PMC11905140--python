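"""sgRNA library representation, validation, I/O, and tiling-guide enumeration.

A library is an ordered set of 20-nt spacers, each tagged with a category:
``gene_panel`` (targets a gene in the focused screen), ``tiling`` (targets a
protospacer inside a single gene's coding sequence), ``positive_control``
(common essential genes, expected to deplete) or ``negative_control``
(non-essential sequences, the normalization anchor).

Tiling guides carry the coding-strand coordinate of their predicted Cas9 cut
site so that per-guide scores can later be projected onto a single protein
axis.  Coordinates are 1-based and closed throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

CATEGORIES = ("gene_panel", "tiling", "positive_control", "negative_control")

SPACER_LEN = 20
PAM_LEN = 3
#: distance (nt) from the PAM-proximal end of the protospacer to the blunt
#: Cas9 cut: the cut falls between protospacer positions 17 and 18.
CUT_OFFSET = 3

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

LIBRARY_COLUMNS = ["guide_id", "spacer", "category", "target_gene", "cds_cut_nt", "strand"]


class LibraryError(ValueError):
    """Raised when a library violates its structural invariants."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SgRNARecord:
    """One guide: 20-nt spacer plus category / target annotation."""

    guide_id: str
    spacer: str
    category: str
    target_gene: str = ""
    cds_cut_nt: Optional[int] = None  # tiling only, 1-based coding-strand nt
    strand: Optional[str] = None      # tiling only, '+' or '-'

    def validate(self) -> None:
        if len(self.spacer) != SPACER_LEN:
            raise LibraryError(
                f"{self.guide_id}: spacer length {len(self.spacer)} != {SPACER_LEN}"
            )
        if set(self.spacer) - set("ACGT"):
            raise LibraryError(f"{self.guide_id}: spacer contains non-ACGT characters")
        if self.category not in CATEGORIES:
            raise LibraryError(f"{self.guide_id}: unknown category {self.category!r}")
        is_tiling = self.category == "tiling"
        if is_tiling and (self.cds_cut_nt is None or self.strand not in "+-"):
            raise LibraryError(f"{self.guide_id}: tiling record needs cds_cut_nt and strand")
        if not is_tiling and self.cds_cut_nt is not None:
            raise LibraryError(f"{self.guide_id}: cds_cut_nt only allowed on tiling records")


@dataclass
class SgRNALibrary:
    """Ordered, validated guide catalog."""

    records: list[SgRNARecord]
    name: str = "library"

    def __post_init__(self) -> None:
        seen_ids: dict[str, str] = {}
        seen_spacers: dict[str, str] = {}
        for rec in self.records:
            rec.validate()
            if rec.guide_id in seen_ids:
                raise LibraryError(f"duplicate guide_id {rec.guide_id!r}")
            seen_ids[rec.guide_id] = rec.guide_id
            if rec.spacer in seen_spacers:
                raise LibraryError(
                    "duplicate spacer shared by guides "
                    f"{seen_spacers[rec.spacer]!r} and {rec.guide_id!r}"
                )
            seen_spacers[rec.spacer] = rec.guide_id

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def guide_ids(self) -> list[str]:
        return [r.guide_id for r in self.records]

    def spacer_index(self) -> dict[str, str]:
        """spacer -> guide_id lookup (spacers are unique by invariant)."""
        return {r.spacer: r.guide_id for r in self.records}

    def guides_in(self, category: str) -> list[SgRNARecord]:
        return [r for r in self.records if r.category == category]

    def require_negative_controls(self) -> None:
        if not self.guides_in("negative_control"):
            raise LibraryError(f"library {self.name!r} has no negative_control guides")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                r.guide_id,
                r.spacer,
                r.category,
                r.target_gene,
                "" if r.cds_cut_nt is None else r.cds_cut_nt,
                "" if r.strand is None else r.strand,
            )
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=LIBRARY_COLUMNS)


def load_library(path: str | Path, name: Optional[str] = None) -> SgRNALibrary:
    """Read a library TSV (columns ``guide_id spacer category target_gene
    cds_cut_nt strand``; the last three may be empty) and validate it."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("guide_id", "spacer", "category") if c not in df.columns]
    if missing:
        raise LibraryError(f"{path}: missing required columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        cut = getattr(row, "cds_cut_nt", "")
        strand = getattr(row, "strand", "")
        records.append(
            SgRNARecord(
                guide_id=row.guide_id,
                spacer=row.spacer.upper(),
                category=row.category,
                target_gene=getattr(row, "target_gene", ""),
                cds_cut_nt=int(float(cut)) if cut != "" else None,
                strand=strand if strand != "" else None,
            )
        )
    return SgRNALibrary(records, name=name or path.stem)


def write_library(library: SgRNALibrary, path: str | Path) -> None:
    library.to_frame().to_csv(path, sep="\t", index=False)


def enumerate_tiling_guides(cds: str, gene: str = "", cut_offset: int = CUT_OFFSET) -> list[SgRNARecord]:
    """Enumerate every SpCas9 guide (20-nt protospacer + NGG PAM) on both
    strands of a coding sequence.

    The cut site is placed ``cut_offset`` bp 5' of the PAM (default 3: between
    protospacer nt 17 and 18) and reported as ``cds_cut_nt``, the coding-strand
    coordinate of the nucleotide on the 5' side of the cut.  Records are sorted
    by cut position, then strand.
    """
    cds = cds.upper()
    if set(cds) - set("ACGT"):
        raise LibraryError("cds contains ambiguity codes; only A/C/G/T allowed")
    if len(cds) < SPACER_LEN + PAM_LEN:
        raise LibraryError(f"cds too short ({len(cds)} nt) for a 23-nt guide window")
    if len(cds) % 3 != 0:
        raise LibraryError(f"cds length {len(cds)} is not a multiple of 3")

    hits: list[tuple[int, str, str]] = []  # (cut_nt, strand, spacer)
    # plus strand: protospacer at 0-based [i, i+20), PAM at [i+20, i+23)
    for i in range(len(cds) - SPACER_LEN - PAM_LEN + 1):
        if cds[i + SPACER_LEN + 1 : i + SPACER_LEN + 3] == "GG":
            cut_nt = i + SPACER_LEN - cut_offset  # 1-based: nt (20 - offset) of protospacer
            hits.append((cut_nt, "+", cds[i : i + SPACER_LEN]))
        # minus strand: coding-strand "CCN" at [i, i+3), protospacer revcomp at [i+3, i+23)
        if cds[i : i + 2] == "CC":
            spacer = revcomp(cds[i + PAM_LEN : i + PAM_LEN + SPACER_LEN])
            # cut between coding positions (i+3+offset, i+3+offset+1); 5' side, 1-based
            cut_nt = i + PAM_LEN + cut_offset
            hits.append((cut_nt, "-", spacer))
    hits.sort(key=lambda h: (h[0], h[1]))
    return [
        SgRNARecord(
            guide_id=f"{gene or 'tile'}_{k + 1:03d}_{strand}",
            spacer=spacer,
            category="tiling",
            target_gene=gene,
            cds_cut_nt=cut_nt,
            strand=strand,
        )
        for k, (cut_nt, strand, spacer) in enumerate(hits)
    ]


def tiling_density(library: SgRNALibrary | Iterable[SgRNARecord], cds_length: int) -> float:
    """Average tiling density in bp per guide: cds_length / n_tiling_guides."""
    records = library.records if isinstance(library, SgRNALibrary) else list(library)
    n = sum(1 for r in records if r.category == "tiling")
    if n == 0:
        raise LibraryError("tiling_density requires at least one tiling record")
    return cds_length / n


def composition_summary(library: SgRNALibrary) -> dict:
    """Counts per category and per target gene; category counts partition the
    library."""
    by_category = {c: 0 for c in CATEGORIES}
    by_gene: dict[str, int] = {}
    for r in library:
        by_category[r.category] += 1
        if r.target_gene:
            by_gene[r.target_gene] = by_gene.get(r.target_gene, 0) + 1
    by_category = {c: n for c, n in by_category.items() if n or not library.records}
    return {"total": len(library), "by_category": by_category, "by_gene": by_gene}
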