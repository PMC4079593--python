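"""Nucleotide-misincorporation spectra for ancient-DNA authentication.

Post-mortem cytosine deamination produces an excess of C→T (and, read on the
complementary strand, G→A) changes over the symmetric background of
polymerase error.  Counting, for every clonal group, the read-vs-consensus
differences in each of the 12 directed base changes and comparing the
"type 2" transition class (C→T/G→A) with the "type 1" class (A→G/T→C) gives
a cheap authenticity signal: a type2/type1 ratio well above 1 is typical of
authentic ancient templates.

Raw counts are scaled to compensate base-composition bias: when C+G is the
underrepresented origin class in a fragment, changes originating from C or G
are multiplied by (A+T)/(G+C); mirrored when A+T is underrepresented.
Insertions, deletions and N columns are excluded throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .consensus_variants import CloneGroup
from .errors import CompositionError, InputError

BASES = "ACGT"
#: the 12 directed base changes, origin -> observed
CHANGES: tuple[tuple[str, str], ...] = tuple(
    (a, b) for a in BASES for b in BASES if a != b
)
#: the 6 complementary pairings
PAIRS: tuple[tuple[tuple[str, str], tuple[str, str]], ...] = (
    (("A", "G"), ("T", "C")),
    (("A", "T"), ("T", "A")),
    (("A", "C"), ("T", "G")),
    (("C", "T"), ("G", "A")),
    (("C", "G"), ("G", "C")),
    (("C", "A"), ("G", "T")),
)
TYPE1 = (("A", "G"), ("T", "C"))
TYPE2 = (("C", "T"), ("G", "A"))


def change_label(change: tuple[str, str]) -> str:
    return f"{change[0]}>{change[1]}"


def count_misincorporations(
    group: CloneGroup, consensus: str
) -> dict[tuple[str, str], int]:
    """Raw counts of directed consensus→read base changes across all reads.

    Columns where either the consensus or the read carries N or a gap are
    skipped, as are consensus ambiguity codes.
    """
    if len(consensus) != len(group.reads[0]):
        raise InputError("consensus length does not match read length")
    raw = {c: 0 for c in CHANGES}
    cons = consensus.upper()
    for read in group.reads:
        for c, r in zip(cons, read):
            if c in BASES and r in BASES and c != r:
                raw[(c, r)] += 1
    return raw


def base_composition(consensus: str) -> dict[str, int]:
    """A/C/G/T counts over the analyzed (unambiguous, non-indel) columns of
    a fragment consensus."""
    cons = consensus.upper()
    return {b: cons.count(b) for b in BASES}


def scale_spectrum(
    raw: dict[tuple[str, str], int], composition: dict[str, int]
) -> dict[tuple[str, str], float]:
    """Composition-bias scaling of raw counts.

    With at = A+T and gc = G+C in the fragment: if gc < at, changes
    originating from C or G are multiplied by at/gc; if at < gc, changes
    originating from A or T are multiplied by gc/at; balanced composition
    leaves everything unchanged.
    """
    at = composition.get("A", 0) + composition.get("T", 0)
    gc = composition.get("G", 0) + composition.get("C", 0)
    if at == 0 or gc == 0:
        raise CompositionError(f"degenerate composition A+T={at}, G+C={gc}")
    scaled = {c: float(n) for c, n in raw.items()}
    if gc < at:
        r = at / gc
        for c in CHANGES:
            if c[0] in "CG":
                scaled[c] = raw[c] * r
    elif at < gc:
        r = gc / at
        for c in CHANGES:
            if c[0] in "AT":
                scaled[c] = raw[c] * r
    return scaled


@dataclass
class MisincorporationSpectrum:
    """Raw and composition-scaled counts of the 12 base changes for one
    clonal group, folded to the 6 complementary pairs, with type-1/type-2
    transition sums and their ratio."""

    group_id: str
    raw: dict[tuple[str, str], int]
    composition: dict[str, int]
    scaled: dict[tuple[str, str], float] = field(init=False)
    pairs: dict[str, float] = field(init=False)
    type1: float = field(init=False)
    type2: float = field(init=False)
    ratio21: Optional[float] = field(init=False)

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.raw.values()):
            raise InputError("negative raw counts")
        self.scaled = scale_spectrum(self.raw, self.composition)
        self.pairs = {
            f"{change_label(a)}/{change_label(b)}": self.scaled[a] + self.scaled[b]
            for a, b in PAIRS
        }
        self.type1 = sum(self.scaled[c] for c in TYPE1)
        self.type2 = sum(self.scaled[c] for c in TYPE2)
        self.ratio21 = self.type2 / self.type1 if self.type1 > 0 else None

    @property
    def raw_type1(self) -> int:
        return sum(self.raw[c] for c in TYPE1)

    @property
    def raw_type2(self) -> int:
        return sum(self.raw[c] for c in TYPE2)

    @classmethod
    def from_group(
        cls, group: CloneGroup, consensus: str
    ) -> "MisincorporationSpectrum":
        return cls(
            group_id=group.group_id,
            raw=count_misincorporations(group, consensus),
            composition=base_composition(consensus),
        )


def type_ratio(
    spectra: Sequence[MisincorporationSpectrum],
) -> tuple[float, float, Optional[float], pd.DataFrame]:
    """Pool scaled type-1 and type-2 sums across clonal groups.

    Returns (pooled_type1, pooled_type2, ratio21_or_None, per_group_table).
    The table also carries the raw-count ratio for transparency.
    """
    if not spectra:
        raise InputError("no spectra to pool")
    t1 = sum(s.type1 for s in spectra)
    t2 = sum(s.type2 for s in spectra)
    ratio = t2 / t1 if t1 > 0 else None
    rows = [
        {
            "group_id": s.group_id,
            "type1_scaled": s.type1,
            "type2_scaled": s.type2,
            "ratio21_scaled": s.ratio21,
            "type1_raw": s.raw_type1,
            "type2_raw": s.raw_type2,
            "ratio21_raw": (s.raw_type2 / s.raw_type1 if s.raw_type1 else None),
        }
        for s in spectra
    ]
    return t1, t2, ratio, pd.DataFrame(rows)


def spectra_to_table(spectra: Sequence[MisincorporationSpectrum]) -> pd.DataFrame:
    """Per-group spectrum table: the 12 changes (raw and scaled), the 6
    pairs, type sums and ratio."""
    rows = []
    for s in spectra:
        row: dict = {"group_id": s.group_id}
        for c in CHANGES:
            row[f"raw_{change_label(c)}"] = s.raw[c]
        for c in CHANGES:
            row[f"scaled_{change_label(c)}"] = s.scaled[c]
        row.update(s.pairs)
        row["type1"] = s.type1
        row["type2"] = s.type2
        row["ratio21"] = s.ratio21
        rows.append(row)
    return pd.DataFrame(rows)
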