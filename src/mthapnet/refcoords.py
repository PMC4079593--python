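"""Circular mitochondrial reference coordinates and aligned-column bookkeeping.

Mitochondrial genomes are circular, and amplicon studies routinely span the
origin (e.g. a control-region fragment running from position 15,308 through
16,357 and on to 109).  This module provides a 1-based, closed-interval
coordinate system that wraps modulo the reference length, a position type
that can name alignment columns absent from the reference (insertion columns
such as 15581.1 = first inserted column after base 15581), and an alignment
container that keeps a per-column map back to reference positions.

It also implements the gap-exclusion policy used before network analysis:
every alignment column containing a gap in any sequence is dropped, except
for explicitly whitelisted indel columns, which are retained as multistate
characters over {absent, A, C, G, T}.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from functools import total_ordering
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO

from .errors import CoordinateError, InputError

DNA = set("ACGTN")
ALIGNED = DNA | {"-"}


@total_ordering
@dataclass(frozen=True)
class RefPosition:
    """A coordinate on the reference: 1-based anchor plus insertion sub-index.

    ``ins_index == 0`` names the anchored reference base itself;
    ``ins_index == k >= 1`` names the k-th alignment column inserted after
    that base (written ``anchor.k``, e.g. ``15581.1``).
    """

    anchor: int
    ins_index: int = 0

    def __post_init__(self) -> None:
        if self.anchor < 1:
            raise CoordinateError(f"anchor must be >= 1, got {self.anchor}")
        if self.ins_index < 0:
            raise CoordinateError(f"ins_index must be >= 0, got {self.ins_index}")

    @property
    def is_insertion(self) -> bool:
        return self.ins_index > 0

    def __str__(self) -> str:
        if self.ins_index:
            return f"{self.anchor}.{self.ins_index}"
        return str(self.anchor)

    def __lt__(self, other: "RefPosition") -> bool:
        return (self.anchor, self.ins_index) < (other.anchor, other.ins_index)

    @classmethod
    def parse(cls, text: str) -> "RefPosition":
        """Parse ``"15581"`` or ``"15581.1"`` into a RefPosition."""
        text = str(text).strip()
        if "." in text:
            a, k = text.split(".", 1)
            return cls(int(a), int(k))
        return cls(int(text))


@dataclass(frozen=True)
class CircularReference:
    """A circular reference sequence with 1-based, wrapping position access."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq.upper()) - DNA
        if bad:
            raise InputError(f"reference contains non-ACGTN characters: {sorted(bad)}")
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)

    def base(self, anchor: int) -> str:
        """Base at a 1-based position; wraps modulo the reference length."""
        if anchor < 1:
            raise CoordinateError(f"position {anchor} is not 1-based")
        return self.seq[(anchor - 1) % len(self.seq)]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "CircularReference":
        rec = next(SeqIO.parse(str(path), "fasta"))
        return cls(id=rec.id, seq=str(rec.seq).upper())


def _as_pos(x: "RefPosition | int | str") -> RefPosition:
    if isinstance(x, RefPosition):
        return x
    if isinstance(x, int):
        return RefPosition(x)
    return RefPosition.parse(x)


@dataclass(frozen=True)
class RefInterval:
    """A closed interval [start, end] of reference positions.

    When ``start.anchor > end.anchor`` the interval wraps through the origin,
    e.g. (15308, 109) on a 16,357 bp circle covers 15,308..16,357 then 1..109.
    """

    start: RefPosition
    end: RefPosition

    def __init__(self, start, end):
        object.__setattr__(self, "start", _as_pos(start))
        object.__setattr__(self, "end", _as_pos(end))

    @property
    def wraps(self) -> bool:
        return self.start.anchor > self.end.anchor

    def contains_anchor(self, anchor: int) -> bool:
        s, e = self.start.anchor, self.end.anchor
        if self.wraps:
            return anchor >= s or anchor <= e
        return s <= anchor <= e

    def contains(self, pos: RefPosition) -> bool:
        """Membership by anchor: insertion columns belong to the interval
        that contains their anchoring base."""
        return self.contains_anchor(pos.anchor)

    def __str__(self) -> str:
        return f"{self.start}-{self.end}"


def interval_length(interval: RefInterval, ref_length: int) -> int:
    """Number of reference positions in a closed interval on a circle.

    Insertion sub-indices are ignored: only anchored reference bases count.
    """
    s, e = interval.start.anchor, interval.end.anchor
    if not (1 <= s <= ref_length and 1 <= e <= ref_length):
        raise CoordinateError(
            f"interval {interval} has anchors outside 1..{ref_length}"
        )
    if s <= e:
        return e - s + 1
    return (ref_length - s + 1) + e


@dataclass
class HaplotypeAlignment:
    """Labeled aligned sequences with a column -> RefPosition map.

    ``meta`` carries optional per-label attributes (geography, era,
    haplogroup tag).  ``ref_length`` enables wrap-aware validation of the
    column map: columns must be strictly increasing along the circle,
    unwrapped from the first column's anchor.
    """

    labels: list[str]
    rows: list[str]
    colmap: list[RefPosition]
    meta: dict[str, dict] = field(default_factory=dict)
    ref_length: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise InputError("labels and rows differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise InputError("duplicate labels in alignment")
        if self.rows:
            n = len(self.rows[0])
            if any(len(r) != n for r in self.rows):
                raise InputError("alignment rows have unequal lengths")
            if len(self.colmap) != n:
                raise InputError(
                    f"colmap length {len(self.colmap)} != alignment width {n}"
                )
            bad = set("".join(self.rows).upper()) - ALIGNED
            if bad:
                raise InputError(f"rows contain non-ACGTN- characters: {sorted(bad)}")
        self.rows = [r.upper() for r in self.rows]
        self._check_colmap()

    def _check_colmap(self) -> None:
        keys = [self._unwrap_key(p) for p in self.colmap]
        for a, b in zip(keys, keys[1:]):
            if not a < b:
                raise InputError("colmap is not strictly increasing")

    def _unwrap_key(self, pos: RefPosition):
        if self.ref_length and self.colmap:
            origin = self.colmap[0].anchor
            return ((pos.anchor - origin) % self.ref_length, pos.ins_index)
        return (pos.anchor, pos.ins_index)

    @property
    def ncols(self) -> int:
        return len(self.colmap)

    def __len__(self) -> int:
        return len(self.labels)

    def sequence(self, label: str) -> str:
        return self.rows[self.labels.index(label)]

    def column(self, i: int) -> str:
        return "".join(row[i] for row in self.rows)

    def subset_columns(self, indices: Sequence[int]) -> "HaplotypeAlignment":
        idx = list(indices)
        return replace(
            self,
            rows=["".join(r[i] for i in idx) for r in self.rows],
            colmap=[self.colmap[i] for i in idx],
        )

    @classmethod
    def from_fasta(
        cls,
        path: str | Path,
        colmap: Optional[Sequence[RefPosition]] = None,
        reference_label: Optional[str] = None,
        first_anchor: int = 1,
        meta: Optional[Mapping[str, dict]] = None,
        ref_length: Optional[int] = None,
    ) -> "HaplotypeAlignment":
        """Read an aligned FASTA.

        The column map comes either from ``colmap`` (e.g. a sidecar TSV read
        with :func:`read_colmap_tsv`) or is derived from a reference row
        inside the FASTA named ``reference_label``: its non-gap columns are
        numbered consecutively from ``first_anchor`` and its gap columns
        become insertion columns anchored to the preceding base.
        """
        labels, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            labels.append(rec.id)
            rows.append(str(rec.seq).upper())
        if not labels:
            raise InputError(f"no sequences in {path}")
        if colmap is None:
            if reference_label is None:
                raise InputError("either colmap or reference_label is required")
            if reference_label not in labels:
                raise InputError(f"reference row {reference_label!r} not in FASTA")
            refrow = rows[labels.index(reference_label)]
            colmap = colmap_from_reference_row(refrow, first_anchor=first_anchor)
            keep = [i for i, lab in enumerate(labels) if lab != reference_label]
            labels = [labels[i] for i in keep]
            rows = [rows[i] for i in keep]
        return cls(
            labels=labels,
            rows=rows,
            colmap=list(colmap),
            meta=dict(meta or {}),
            ref_length=ref_length,
        )

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for lab, row in zip(self.labels, self.rows):
                fh.write(f">{lab}\n{row}\n")


def colmap_from_reference_row(refrow: str, first_anchor: int = 1) -> list[RefPosition]:
    """Derive a column map from an aligned reference row: bases advance the
    anchor, gaps become insertion columns after the preceding base."""
    out: list[RefPosition] = []
    anchor = first_anchor - 1
    ins = 0
    for ch in refrow.upper():
        if ch == "-":
            if anchor < first_anchor:
                raise InputError("reference row begins with a gap; cannot anchor")
            ins += 1
            out.append(RefPosition(anchor, ins))
        else:
            anchor += 1
            ins = 0
            out.append(RefPosition(anchor))
    return out


def read_colmap_tsv(path: str | Path) -> list[RefPosition]:
    """Read a sidecar column map: TSV with columns column_index, anchor,
    ins_index (header row required); rows may appear in any order."""
    entries: list[tuple[int, RefPosition]] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            entries.append(
                (
                    int(row["column_index"]),
                    RefPosition(int(row["anchor"]), int(row.get("ins_index") or 0)),
                )
            )
    entries.sort(key=lambda e: e[0])
    if [i for i, _ in entries] != list(range(len(entries))):
        raise InputError("colmap TSV column_index must cover 0..n-1")
    return [p for _, p in entries]


def write_colmap_tsv(colmap: Sequence[RefPosition], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("column_index\tanchor\tins_index\n")
        for i, p in enumerate(colmap):
            fh.write(f"{i}\t{p.anchor}\t{p.ins_index}\n")


def extract_region(aln: HaplotypeAlignment, interval: RefInterval) -> HaplotypeAlignment:
    """Columns whose reference position falls in the closed interval,
    including insertion columns anchored inside it.  Row order and labels
    are preserved."""
    idx = [i for i, p in enumerate(aln.colmap) if interval.contains(p)]
    if not idx:
        raise CoordinateError(f"interval {interval} is disjoint from the alignment")
    return aln.subset_columns(idx)


def apply_gap_policy(
    aln: HaplotypeAlignment,
    exceptions: Iterable[RefPosition | int | str] = (),
) -> tuple[HaplotypeAlignment, list[RefPosition]]:
    """Remove every column containing a gap in any row, unless its position
    is whitelisted in ``exceptions`` (kept as an indel character with states
    {absent, A, C, G, T}).  Returns the filtered alignment and the list of
    dropped positions.  'N' is missing data, never cause for removal."""
    exc = {_as_pos(e) for e in exceptions}
    keep, dropped = [], []
    for i, pos in enumerate(aln.colmap):
        if "-" in aln.column(i) and pos not in exc:
            dropped.append(pos)
        else:
            keep.append(i)
    return aln.subset_columns(keep), dropped


def write_drop_report(dropped: Sequence[RefPosition], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_position\treason\n")
        for p in dropped:
            fh.write(f"{p}\tgap_column\n")
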