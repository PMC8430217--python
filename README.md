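# ssnmtf — semi-supervised tri-factorization for protein complex detection

Protein complexes are groups of physically associating proteins that show up
as densely connected modules in protein–protein interaction (PPI) networks.
Purely topological detection struggles on real PPI data: networks are sparse,
up to half the edges may be false positives, and curated knowledge about
known complexes is ignored. `ssnmtf` detects complexes by fitting a
**semi-supervised non-negative matrix tri-factorization** that combines the
network's topology with *must-link* prior knowledge — pairs of proteins known
to co-occur in a complex, e.g. taken from a curated catalog such as CORUM.

Given a symmetric adjacency matrix `A` (n×n, weighted or unweighted), the
model seeks non-negative factors `F` (n×k, node-to-module membership) and `G`
(k×k, module-relationship matrix) minimizing

```
J(F, G) = ||A − F G Fᵀ||²_F  +  Tr((F G)ᵀ L (F G))  +  Tr(Fᵀ L F)
```

where `L = D − M` is the Laplacian of the must-link constraint matrix
(`m_ij = α` for constrained pairs, α = 10 by default). The second term pulls
the *reconstructed* propensities `R = F G` of constrained pairs together,
which produces a diagonally dominant `G` — a clear module structure — while
the third pulls their raw membership rows together. `J` is minimized by
alternating multiplicative updates that preserve non-negativity.

Two detectors read complexes off the fitted `F`:

* **non-overlapping (NSSNMTF)** — each node joins its row-argmax module;
* **overlapping (OSSNMTF)** — for each column, entries are ranked descending
  and accumulated until the running sum reaches the module-size estimate
  `(FᵀF)_cc`; the prefix's nodes form the complex, so nodes may join several.

The module budget `k` is set generously (1000 for real PPI networks) and
adapts downward automatically: empty modules and complexes with fewer than
three members are discarded.

The package also ships the complex-evaluation suite used in this field
(neighborhood affinity, precision/recall/F1, Sn/PPV/Acc, MMR, partition and
overlapping-cover NMI, hypergeometric enrichment p-values) and an LFR-style
synthetic benchmark generator with planted, optionally overlapping, modules.

## Worked example

```python
import math
from ssnmtf import (SSNMTF, LFRConfig, generate_lfr, mustlinks_from_truth,
                    nmi_partition, assign_nonoverlapping)

# a benchmark network with planted modules, blurry structure (mu = 0.7)
net, truth = generate_lfr(LFRConfig(N=1000, ad=15, d_max=50,
                                    m_min=20, m_max=50, mu=0.7, seed=11))
# 7% of the ground-truth must-link pairs as prior knowledge
ml = mustlinks_from_truth(truth, fraction=0.07, alpha=10.0, seed=12)

model = SSNMTF(net, ml, k=math.ceil(1.5 * len(truth)))
res = model.fit(max_iter=1000, seed=11)
pred = assign_nonoverlapping(res.factors, net.nodes)
print(len(truth), len(ml), res.iterations,
      round(nmi_partition(pred.complexes, truth.complexes, universe=net.nodes), 3))
```

prints

```
31 1178 1000 0.95
```

— the generator planted 31 modules, 1178 must-link pairs were sampled, the
optimizer ran to its 1000-iteration cap, and the detected partition agrees
with the planted truth at NMI 0.95 despite 70% of every node's edges leaving
its module. Without the must-links the same fit scores far lower (the
`benchmark` command below quantifies the gain).

The same workflow runs from the shell on user-supplied files:

```bash
ssnmtf simulate --preset lfr-nonoverlap-mu70 --seed 1 --mustlink-fraction 0.07 \
    --out-prefix scratch/bench
ssnmtf detect --network scratch/bench.edges.tsv --mustlink scratch/bench.mustlinks.tsv \
    --k 50 --mode overlap --out-dir scratch/run
ssnmtf evaluate --pred scratch/run/complexes.txt --ref scratch/bench.truth.txt
ssnmtf benchmark --preset lfr-nonoverlap-mu70 --replicates 10 --fractions 0,0.03,0.07
```

`detect` accepts any edge list (`node_a node_b [weight]`) and any flat
complex catalog (one complex per line), so real PPI networks and CORUM/PCDq
style references can be supplied directly; `--reference FILE
--mustlink-fraction 0.1` samples must-links from a catalog using the
single-complex-membership rule.

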