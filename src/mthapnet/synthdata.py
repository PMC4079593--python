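"""Synthetic data with known ground truth for every analysis stage.

Two generators:

* :func:`simulate_haplotypes` emulates a haplogroup-structured control-region
  alignment: star-like clusters of haplotypes (a founder plus leaves carrying
  private mutations) joined to a common ancestor by multi-mutation stems,
  optionally with recurrent "hotspot" mutations shared across clusters and a
  multistate insertion column.  The returned truth record is sufficient to
  score haplotype collapsing, network reconstruction, mutation-frequency and
  motif recovery.

* :func:`simulate_clone_group` emulates an amplicon read pool: reads drawn
  independently from a template with a symmetric per-change polymerase error
  rate ε and an extra miscoding-lesion rate δ on C→T and G→A.  The scaled
  expected type2/type1 transition ratio has the closed form 1 + δ/ε,
  independent of template composition (composition scaling cancels the
  base-count imbalance exactly), so parameter recovery can be scored
  analytically.

Both generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import json
import numpy as np

from .consensus_variants import CloneGroup
from .errors import ConfigError
from .refcoords import (
    HaplotypeAlignment,
    RefInterval,
    RefPosition,
    write_colmap_tsv,
)

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class HaploSimConfig:
    """Configuration for the haplogroup-structured alignment generator.

    ``star_size`` counts haplotypes per haplogroup including the founder;
    each non-founder leaf carries ``private_mutations`` private transitions.
    Stems carry ``stem_length`` mutations each.  ``n_hotspots`` positions are
    mutated recurrently on ``hotspot_recurrence`` independent terminal
    branches (spread over different haplogroups).  With ``indel_column`` an
    insertion column is added that carries two independent insertion events
    with different bases, emulating a shared-indel character.
    """

    n_haplogroups: int = 3
    star_size: int = 4
    stem_length: int = 3
    private_mutations: int = 1
    n_hotspots: int = 0
    hotspot_recurrence: int = 2
    length: int = 327
    first_anchor: int = 15573
    indel_column: bool = False
    missing_rate: float = 0.0
    include_ancestor: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_haplogroups < 1 or self.star_size < 1 or self.stem_length < 0:
            raise ConfigError("non-positive haplogroup structure")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.n_hotspots and self.hotspot_recurrence < 2:
            raise ConfigError("hotspot recurrence must be >= 2")
        n_leaves = self.n_haplogroups * (self.star_size - 1)
        needed = (
            self.n_haplogroups * self.stem_length
            + n_leaves * self.private_mutations
            + self.n_hotspots
        )
        if needed > self.length:
            raise ConfigError(
                f"{needed} mutated positions do not fit in length {self.length}"
            )
        if self.n_hotspots and self.hotspot_recurrence > n_leaves:
            raise ConfigError("not enough leaves to place hotspot recurrences")


def simulate_haplotypes(
    cfg: HaploSimConfig,
) -> tuple[HaplotypeAlignment, dict]:
    """Generate the alignment and a ground-truth record.

    Truth keys: ``groups`` (label -> haplogroup tag), ``stems`` (haplogroup
    -> list of stem position strings), ``hotspots`` (list of
    [position, recurrence]), ``private`` (label -> positions),
    ``ancestor_label``, ``indel_position``.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.length
    ancestor = rng.choice(_BASES, size=L)
    anchors = list(range(cfg.first_anchor, cfg.first_anchor + L))

    free_cols = list(rng.permutation(L))
    n_leaves_per_group = cfg.star_size - 1

    def take(k: int) -> list[int]:
        cols = free_cols[:k]
        del free_cols[:k]
        return cols

    stems: dict[str, list[int]] = {}
    privates: dict[str, list[int]] = {}
    labels: list[str] = []
    rows: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}

    if cfg.include_ancestor:
        labels.append("ANC")
        rows["ANC"] = ancestor.copy()
        groups["ANC"] = "ancestral"

    leaf_labels: list[str] = []
    for g in range(cfg.n_haplogroups):
        hg = f"HG{g}"
        stem_cols = take(cfg.stem_length)
        stems[hg] = stem_cols
        founder = ancestor.copy()
        for c in stem_cols:
            founder[c] = _TRANSITION[str(founder[c])]
        flab = f"{hg}_F"
        labels.append(flab)
        rows[flab] = founder.copy()
        groups[flab] = hg
        for i in range(n_leaves_per_group):
            lab = f"{hg}_L{i + 1}"
            cols = take(cfg.private_mutations)
            leaf = founder.copy()
            for c in cols:
                leaf[c] = _TRANSITION[str(leaf[c])]
            labels.append(lab)
            rows[lab] = leaf
            groups[lab] = hg
            privates[lab] = cols
            leaf_labels.append(lab)

    hotspot_truth: list[tuple[int, int]] = []
    if cfg.n_hotspots:
        # round-robin over haplogroups so recurrences land on independent
        # terminal branches in different clusters
        rr = [
            f"HG{g}_L{i + 1}"
            for i in range(n_leaves_per_group)
            for g in range(cfg.n_haplogroups)
        ]
        for h in range(cfg.n_hotspots):
            col = take(1)[0]
            off = (h * cfg.hotspot_recurrence) % len(rr)
            chosen = (rr[off:] + rr[:off])[: cfg.hotspot_recurrence]
            for lab in chosen:
                rows[lab][col] = _TRANSITION[str(rows[lab][col])]
            hotspot_truth.append((col, len(chosen)))

    colmap = [RefPosition(a) for a in anchors]
    out_rows = {lab: list(map(str, rows[lab])) for lab in labels}

    indel_pos = None
    if cfg.indel_column:
        # one inserted column after the middle anchor; two independent
        # insertion events with different bases, everyone else absent
        anchor = anchors[L // 2]
        indel_pos = RefPosition(anchor, 1)
        insert_at = anchors.index(anchor) + 1
        carriers_t = [lab for lab in labels if groups[lab] == "HG0"]
        carrier_g = next(
            (lab for lab in labels if groups[lab] == "HG1"), None
        )
        for lab in labels:
            if lab in carriers_t:
                ch = "T"
            elif lab == carrier_g:
                ch = "G"
            else:
                ch = "-"
            out_rows[lab].insert(insert_at, ch)
        colmap.insert(insert_at, indel_pos)

    if cfg.missing_rate > 0:
        for lab in labels:
            if lab == "ANC":
                continue
            mask = rng.random(len(out_rows[lab])) < cfg.missing_rate
            for i in np.flatnonzero(mask):
                out_rows[lab][i] = "N"

    aln = HaplotypeAlignment(
        labels=labels,
        rows=["".join(out_rows[lab]) for lab in labels],
        colmap=colmap,
        meta={lab: {"haplogroup": groups[lab], "era": "modern"} for lab in labels},
    )
    truth = {
        "groups": groups,
        "stems": {
            hg: sorted(str(RefPosition(anchors[c])) for c in cols)
            for hg, cols in stems.items()
        },
        "private": {
            lab: sorted(str(RefPosition(anchors[c])) for c in cols)
            for lab, cols in privates.items()
        },
        "hotspots": [
            [str(RefPosition(anchors[c])), r] for c, r in hotspot_truth
        ],
        "ancestor_label": "ANC" if cfg.include_ancestor else None,
        "indel_position": str(indel_pos) if indel_pos else None,
    }
    return aln, truth


@dataclass
class ReadSimConfig:
    """Configuration for the amplicon read-pool generator.

    ``error_rate`` ε is the per-site probability of each of the three
    erroneous bases (symmetric polymerase error, total 3ε per site);
    ``lesion_rate`` δ is the extra probability of the deamination-driven
    changes C→T and G→A at C/G sites.  ``missing_rate`` converts calls to N.
    """

    template: str = ""
    n_reads: int = 100
    lesion_rate: float = 0.0
    error_rate: float = 0.001
    missing_rate: float = 0.0
    group_id: str = "sim"
    first_anchor: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ConfigError("n_reads must be >= 1")
        for r in (self.lesion_rate, self.error_rate, self.missing_rate):
            if not (0 <= r < 1):
                raise ConfigError("rates must be in [0, 1)")
        if 3 * self.error_rate + self.lesion_rate >= 1:
            raise ConfigError("3*error_rate + lesion_rate must be < 1")
        self.template = self.template.upper()
        if set(self.template) - set("ACGT"):
            raise ConfigError("template must be over ACGT")


def random_template(length: int, seed: int = 0, gc: float = 0.5) -> str:
    """Random template with a given expected GC fraction."""
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=length, p=p))


def expected_ratio21(cfg: ReadSimConfig) -> Optional[float]:
    """Closed-form expectation of the scaled type2/type1 ratio.

    Scaled E[type2] ∝ (δ+ε) and scaled E[type1] ∝ ε with the same
    composition factor, hence the ratio is 1 + δ/ε; undefined for ε = 0.
    """
    if cfg.error_rate == 0:
        return None
    return 1.0 + cfg.lesion_rate / cfg.error_rate


def simulate_clone_group(cfg: ReadSimConfig) -> tuple[CloneGroup, dict]:
    """Draw a read pool and return it with the analytic truth record."""
    if not cfg.template:
        raise ConfigError("empty template")
    rng = np.random.default_rng(cfg.seed)
    L = len(cfg.template)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    tcode = np.array([base_idx[b] for b in cfg.template])

    eps, delta = cfg.error_rate, cfg.lesion_rate
    # per-template-base substitution matrix rows (A, C, G, T)
    P = np.full((4, 4), eps)
    for i in range(4):
        P[i, i] = 0.0
    P[1, 3] += delta  # C -> T
    P[2, 0] += delta  # G -> A
    for i in range(4):
        P[i, i] = 1.0 - P[i].sum()

    probs = P[tcode]  # L x 4
    cum = np.cumsum(probs, axis=1)
    u = rng.random((cfg.n_reads, L))
    calls = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
    reads_arr = _BASES[calls]
    if cfg.missing_rate > 0:
        miss = rng.random((cfg.n_reads, L)) < cfg.missing_rate
        reads_arr = np.where(miss, "N", reads_arr)
    reads = ["".join(row) for row in reads_arr]

    interval = RefInterval(cfg.first_anchor, cfg.first_anchor + L - 1)
    colmap = [RefPosition(cfg.first_anchor + i) for i in range(L)]
    group = CloneGroup(
        group_id=cfg.group_id, interval=interval, reads=reads, colmap=colmap
    )
    truth = {
        "expected_ratio21": expected_ratio21(cfg),
        "lesion_rate": delta,
        "error_rate": eps,
        "template": cfg.template,
        "n_reads": cfg.n_reads,
    }
    return group, truth


def random_haplotype_vectors(
    seed: int,
    max_haplotypes: int = 5,
    length: int = 8,
) -> list[tuple[str, ...]]:
    """Small random haplotype instances for exhaustive cross-checks.

    Haplotypes evolve from a random root along a random attachment order:
    each new haplotype copies a random existing one and mutates 1-3 random
    positions to random different bases, so instances carry realistic
    tree structure plus occasional recurrent (homoplasic) changes.
    Returns the distinct state vectors restricted to variable columns.
    """
    rng = np.random.default_rng(seed)
    root = rng.choice(_BASES, size=length)
    haps = [root.copy()]
    n = int(rng.integers(3, max_haplotypes + 1))
    while len(haps) < n:
        child = haps[int(rng.integers(len(haps)))].copy()
        k = int(rng.integers(1, 4))
        for pos in rng.choice(length, size=k, replace=False):
            cur = str(child[pos])
            child[pos] = rng.choice([b for b in "ACGT" if b != cur])
        haps.append(child)
    vecs = sorted({tuple(map(str, h)) for h in haps})
    var = [i for i in range(length) if len({v[i] for v in vecs}) > 1]
    return [tuple(v[i] for i in var) for v in vecs]


def write_haplotype_fixture(
    aln: HaplotypeAlignment, truth: dict, outdir: str | Path
) -> None:
    """Write an alignment fixture bundle: FASTA, colmap TSV, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aln.to_fasta(outdir / "alignment.fasta")
    write_colmap_tsv(aln.colmap, outdir / "colmap.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    with open(outdir / "meta.json", "w") as fh:
        json.dump(aln.meta, fh, indent=2)


def write_clone_group_fixture(
    group: CloneGroup, truth: dict, outdir: str | Path
) -> None:
    """Write a clone-group fixture: reads FASTA plus truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / f"{group.group_id}.fasta", "w") as fh:
        for i, r in enumerate(group.reads):
            fh.write(f">{group.group_id}_read{i}\n{r}\n")
    with open(outdir / f"{group.group_id}.truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
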