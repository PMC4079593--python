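"""Per-amplicon consensus building and reference-anchored variant tables.

Deep-sequencing reads from one PCR amplicon are treated as clones of that
product ("clonal groups").  A majority-rule consensus is called per group;
the consensus is then compared column-by-column with the circular reference
to tabulate substitutions, insertions (named ``anchor.k`` after the
preceding reference base) and deletions, mirroring a classic ancient-DNA
polymorphism table.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import CoordinateError, InputError
from .refcoords import CircularReference, RefInterval, RefPosition

# IUPAC codes for 2-4-way base ties
IUPAC = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("ACG"): "V", frozenset("ACT"): "H", frozenset("AGT"): "D",
    frozenset("CGT"): "B", frozenset("ACGT"): "N",
}
IUPAC_EXPAND = {v: set(k) for k, v in IUPAC.items()}
IUPAC_EXPAND.update({b: {b} for b in "ACGT"})


@dataclass
class CloneGroup:
    """Aligned reads from one amplicon, with their reference column map."""

    group_id: str
    interval: RefInterval
    reads: list[str]
    colmap: list[RefPosition]

    def __post_init__(self) -> None:
        if not self.reads:
            raise InputError(f"clone group {self.group_id!r} has no reads")
        n = len(self.reads[0])
        if any(len(r) != n for r in self.reads):
            raise InputError(f"clone group {self.group_id!r} has ragged reads")
        if len(self.colmap) != n:
            raise InputError(
                f"clone group {self.group_id!r}: colmap length != read length"
            )
        self.reads = [r.upper() for r in self.reads]

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    @classmethod
    def from_fasta(
        cls,
        path: str | Path,
        group_id: str,
        interval: RefInterval,
        colmap: Sequence[RefPosition],
    ) -> "CloneGroup":
        reads = [str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")]
        return cls(group_id=group_id, interval=interval, reads=reads,
                   colmap=list(colmap))


@dataclass(frozen=True)
class VariantRecord:
    """One consensus-vs-reference difference.

    kind=substitution: both states are bases and differ.
    kind=insertion: ref_state is None (column absent from the reference).
    kind=deletion: obs_state is None (reference base absent from consensus).
    """

    position: RefPosition
    ref_state: Optional[str]
    obs_state: Optional[str]
    kind: Literal["substitution", "insertion", "deletion"]

    def __post_init__(self) -> None:
        if self.kind == "substitution":
            ok = (self.ref_state in set("ACGT") and self.obs_state in set("ACGT")
                  and self.ref_state != self.obs_state)
        elif self.kind == "insertion":
            ok = self.ref_state is None and self.obs_state in set("ACGT")
        else:
            ok = self.obs_state is None and self.ref_state in set("ACGT")
        if not ok:
            raise InputError(f"inconsistent variant record {self}")


TieRule = Literal["ambiguity", "reference"]


def build_consensus(
    group: CloneGroup,
    tie_rule: TieRule = "ambiguity",
    ref: Optional[CircularReference] = None,
) -> tuple[str, list[int]]:
    """Majority-rule consensus and per-column depth for a clone group.

    Per column the majority state among non-N read states wins; the gap
    character counts as a state (so a true deletion can reach consensus).
    Ties between bases are resolved by ``tie_rule``: ``"ambiguity"`` emits
    the IUPAC code of the tied bases, ``"reference"`` picks the reference
    base when it is among the tied states (falling back to the IUPAC code
    otherwise).  A tie involving the gap state resolves to the tied bases'
    code — the gap wins only on strict majority.  Depth is the count of
    non-N states per column.
    """
    if tie_rule == "reference" and ref is None:
        raise InputError("tie_rule='reference' requires a reference")
    cons, depth = [], []
    for i in range(len(group.colmap)):
        states = [r[i] for r in group.reads if r[i] != "N"]
        depth.append(len(states))
        if not states:
            cons.append("N")
            continue
        counts = Counter(states)
        top = max(counts.values())
        tied = sorted(s for s, c in counts.items() if c == top)
        if len(tied) == 1:
            cons.append(tied[0])
            continue
        bases = [s for s in tied if s != "-"]
        if not bases:
            cons.append("-")
        elif len(bases) == 1:
            cons.append(bases[0])
        elif tie_rule == "reference" and not group.colmap[i].is_insertion:
            rb = ref.base(group.colmap[i].anchor)
            cons.append(rb if rb in bases else IUPAC[frozenset(bases)])
        else:
            cons.append(IUPAC[frozenset(bases)])
    return "".join(cons), depth


def call_variants(
    consensus: str,
    colmap: Sequence[RefPosition],
    ref: CircularReference,
    region: Optional[RefInterval] = None,
) -> tuple[list[VariantRecord], list[RefPosition]]:
    """Tabulate consensus-vs-reference differences over a region.

    Returns (records, ambiguous_positions).  IUPAC ambiguity codes produce
    no record when compatible with the reference base; incompatible codes
    are reported in the ambiguity list rather than invented as a call.
    'N' columns produce nothing.
    """
    if len(consensus) != len(colmap):
        raise InputError("consensus length != colmap length")
    records: list[VariantRecord] = []
    ambiguous: list[RefPosition] = []
    for state, pos in zip(consensus.upper(), colmap):
        if region is not None and not region.contains(pos):
            raise CoordinateError(f"position {pos} outside region {region}")
        if state == "N":
            continue
        if pos.is_insertion:
            if state == "-":
                continue
            if state in "ACGT":
                records.append(VariantRecord(pos, None, state, "insertion"))
            else:
                ambiguous.append(pos)
            continue
        rb = ref.base(pos.anchor)
        if state == rb:
            continue
        if state == "-":
            records.append(VariantRecord(pos, rb, None, "deletion"))
        elif state in "ACGT":
            records.append(VariantRecord(pos, rb, state, "substitution"))
        elif rb not in IUPAC_EXPAND.get(state, set()):
            ambiguous.append(pos)
    return records, ambiguous


def apply_variants(
    ref: CircularReference,
    colmap: Sequence[RefPosition],
    records: Sequence[VariantRecord],
) -> str:
    """Reconstruct the consensus over ``colmap`` by applying variant records
    to the reference (the round-trip inverse of :func:`call_variants`)."""
    by_pos = {r.position: r for r in records}
    out = []
    for pos in colmap:
        rec = by_pos.get(pos)
        if pos.is_insertion:
            out.append(rec.obs_state if rec else "-")
        elif rec is None:
            out.append(ref.base(pos.anchor))
        elif rec.kind == "deletion":
            out.append("-")
        else:
            out.append(rec.obs_state)
    return "".join(out)


def group_summary(groups: Sequence[CloneGroup]) -> tuple[pd.DataFrame, dict]:
    """Per-group read counts and mean per-column depth, plus grand means."""
    rows = []
    for g in groups:
        depths = [sum(r[i] != "N" for r in g.reads) for i in range(len(g.colmap))]
        rows.append(
            {
                "group_id": g.group_id,
                "n_reads": g.n_reads,
                "mean_depth": sum(depths) / len(depths) if depths else 0.0,
            }
        )
    df = pd.DataFrame(rows, columns=["group_id", "n_reads", "mean_depth"])
    grand = {
        "mean_reads": float(df["n_reads"].mean()) if len(df) else float("nan"),
        "mean_depth": float(df["mean_depth"].mean()) if len(df) else float("nan"),
    }
    return df, grand


def variants_to_table(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Polymorphism table: position, reference state, observed state."""
    rows = []
    for r in sorted(records, key=lambda r: (r.position.anchor, r.position.ins_index)):
        pos = str(r.position.anchor)
        if r.kind == "insertion":
            pos = f"{r.position.anchor} ins"
        elif r.kind == "deletion":
            pos = f"{r.position.anchor} del"
        rows.append(
            {
                "position": pos,
                "reference": r.ref_state or "-",
                "observed": r.obs_state or "-",
            }
        )
    return pd.DataFrame(rows, columns=["position", "reference", "observed"])


def variants_to_vcf_like(
    records: Sequence[VariantRecord], ref_id: str
) -> pd.DataFrame:
    """VCF-style records (CHROM, POS, REF, ALT) for interoperability; indels
    use the anchor position with dot placeholders for the absent side."""
    rows = []
    for r in sorted(records, key=lambda r: (r.position.anchor, r.position.ins_index)):
        rows.append(
            {
                "CHROM": ref_id,
                "POS": r.position.anchor,
                "REF": r.ref_state or ".",
                "ALT": r.obs_state or ".",
            }
        )
    return pd.DataFrame(rows, columns=["CHROM", "POS", "REF", "ALT"])
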