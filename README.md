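# mthapnet

Ancient-mitochondrial-DNA haplotyping: damage-spectrum authentication of
amplicon read pools, reference-anchored variant tables on a circular
mitochondrial coordinate system, and position-weighted median-joining
haplotype networks with hotspot and haplogroup-motif inference.

## Who this is for

Researchers analysing short mitochondrial amplicons — typically
control-region (D-loop) and cytochrome *b* fragments — from archaeological
or museum specimens, who need to (a) check that their sequences carry the
damage signature of authentic ancient templates, (b) tabulate polymorphisms
against a circular reference, and (c) place haplotypes in a median-joining
network alongside published modern and ancient haplotypes, reading
haplogroup-diagnostic motifs and mutational hotspots off the network.
All stages are also exercised end-to-end by a synthetic-data module with
known ground truth, so the pipeline is fully testable without any
sequence downloads.

## The methods in brief

**Damage spectra.** Reads from one PCR amplicon are treated as clones of
that product. Against the group's majority-rule consensus, the counts
n(X→Y) of the 12 directed base changes are accumulated and folded into 6
complementary pairs. Counts are scaled for base composition: with
*r* = (A+T)/(G+C) in the fragment, changes originating from the
underrepresented origin class are multiplied by the corresponding ratio.
The type 2 class (C→T/G→A, driven post mortem by cytosine deamination) is
compared with the type 1 class (A→G/T→C):

&nbsp;&nbsp;&nbsp;&nbsp;ratio₂₁ = Σ scaled(C→T, G→A) / Σ scaled(A→G, T→C)

A ratio well above 1 (classically ≈ 2:1) is typical of authentic ancient
templates; symmetric polymerase error alone gives ≈ 1.

**Median-joining networks.** Haplotypes identical over the analysed region
are collapsed into clusters ("revised haplotypes"). Distances are weighted
Hamming distances d(u,v) = Σᵢ wᵢ·[uᵢ ≠ vᵢ] with integer position weights;
the ε-relaxed minimum spanning network (a link u–v is feasible iff
d(u,v) ≤ b(u,v) + ε, where b is the minimax-path bottleneck) is augmented
with median vectors — column-wise majority consensus of node triplets,
with quasi-median branching on three-way ties — whenever they reduce the
connection cost, and synthetic nodes that neither keep three links nor
shorten the network are pruned. Position weights are assigned inversely to
observed mutation frequency, w = clamp(round(scale/f), 1, 99), in a
two-pass scheme (unit-weight network → frequencies → weights → final
network), so recurrent "hotspot" positions count less. Haplogroup motifs
are the frequency-1 positions on the stem cut separating a haplogroup's
nodes from the rest of the network.

On small instances the construction is cross-checked against an exact
Steiner-tree oracle (Dreyfus–Wagner enumeration over the product space of
observed column states) that shares no code with the network builder.

## Worked example

```python
from mthapnet import *
from mthapnet import synthdata

# 1. coordinate arithmetic on the circular reference (L = 16,357)
print("cytb amplicon:", interval_length(RefInterval(14162, 15301), 16357), "bp")
print("CR alignment:", interval_length(RefInterval(15573, 15899), 16357), "bp")

# 2. a three-haplotype median-joining network
clusters = [HaplotypeCluster(s, [s], tuple(s)) for s in ("GAA", "AGA", "AAG")]
net = build_mj_network(clusters, weights=[1, 1, 1])
print("median vectors:", [(m, "".join(net.node_vector(m))) for m in net.median_nodes])
print("tree length:", net.spanning_length())

# 3. damage authentication on a simulated amplicon pool
tmpl = synthdata.random_template(300, seed=0, gc=0.42)
cfg = ReadSimConfig(template=tmpl, n_reads=500, lesion_rate=0.002,
                    error_rate=0.002, seed=1)
group, truth = simulate_clone_group(cfg)
consensus, depth = build_consensus(group)
spectrum = MisincorporationSpectrum.from_group(group, consensus)
print("type1 =", round(spectrum.type1, 1), " type2 =", round(spectrum.type2, 1),
      " ratio21 =", round(spectrum.ratio21, 2))
```

prints

```
cytb amplicon: 1140 bp
CR alignment: 327 bp
median vectors: [('MV1', 'AAA')]
tree length: 3
type1 = 187.0  type2 = 401.5  ratio21 = 2.15
```

The two region lengths are the closed-interval sizes of the cytochrome *b*
and control-region amplicons on the circular reference. The three
haplotypes GAA/AGA/AAG are resolved by a single inferred median vector
AAA — a hypothetical ancestral haplotype — into a star of three unit
branches (total length 3, the parsimony minimum). The simulated read pool
carries a deamination lesion rate equal to its polymerase error rate, for
which the scaled type2/type1 ratio has expectation 1 + δ/ε = 2; the
estimate 2.15 recovers it within sampling error.

## Command line

The `mthapnet` console script orchestrates the two analytical strands from
a YAML config: `mthapnet damage --config cfg.yaml` (per-group spectra,
pooled ratio, exit 3 when the ratio is undefined), `mthapnet network
--config cfg.yaml` (gap policy, collapsing, two-pass weighted network,
frequency/hotspot/motif/placement reports, GraphML export), `mthapnet all`
to chain them, and `mthapnet simulate` to emit a ground-truth fixture
bundle. All reports are TSV/JSON stamped with the config hash.

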