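# temponet

Temporal process-network analysis of time-series expression data: find the
biological processes perturbed at each time point of an experiment, connect
them through shared genes, and enumerate the high-perturbation **temporal
paths** that link early perturbations to late ones.

Diseases like obesity and diabetes develop gradually: the processes
perturbed on day 1 of a dietary intervention are not the ones perturbed at
week 18, but they are connected — genes shared between processes carry the
perturbation forward. Given a gene × time-point log2 fold-change matrix (or
the probe-level replicate table it comes from) and a gene-set library (GMT),
`temponet` scores, links and ranks those connections.

## The method

**Per-time-point enrichment.** At each time point genes are ranked by
descending |log2 FC|. For a process *S* with *N_H* genes inside a ranked
list of *N* genes with weights *r_j*, the running sum is

```
P_hit(S, i)  = Σ_{g_j ∈ S, j ≤ i} |r_j| / N_R        N_R = Σ_{g_j ∈ S} |r_j|
P_miss(S, i) = Σ_{g_j ∉ S, j ≤ i} 1 / (N − N_H)
```

and the enrichment score is **es = max_i(P_hit − P_miss) + min_i(P_hit −
P_miss)** — the maximum *plus* the minimum of the curve, not the classic
single max-deviation statistic (that variant is available via
`statistic="max_deviation"`). A gene-label permutation null (default 1000
draws) yields the normalized score `nes = es / mean(sign-matched null
portion)` and a tail p-value. Repeating this for every process and time
point gives the nes matrix.

**Process network.** Processes are nodes; an edge joins two processes that
share at least one gene (the edge remembers which). Degree-preserving
double-edge-swap randomization estimates, for each observed edge, the
probability of occurring by degree alone.

**Path search.** A temporal path visits one process per time point, with
consecutive processes adjacent in the network. The systematic search is
greedy with branching: at time 1 the candidate pool is all processes,
afterwards the neighbors of the previous process; at each of the *T*
selection instances the top-2 candidates by nes each spawn a branch, giving
2^T paths (2^10 = 1024). The same procedure on the *lowest*-nes candidates
builds the unperturbed control set, and uniform random walks give the
baseline.

**Overlap factor.** Branching paths converge. The overlap factor of a
path's edge is the set of other paths using the same process pair at the
same transition; the path's overlap factor is the union over its edges,
reported as a cardinality. Resampled random-path sets calibrate chance
overlap, and an exhaustive pair search picks the 1–2 paths whose overlap
sets cover most of the population.

**Precision.** A path selected in one dataset is scored in others by
recomputing its mean nes there (suffix-aligned when a dataset has fewer
time points); comparison values at least as high as the source value count
as false positives.

A synthetic-data generator (`temponet.synthetic`) plants a connected chain
of perturbed processes — one per time point, consecutive members sharing a
connector gene — inside probe-level data, so the entire pipeline is testable
end to end without downloads.

## Worked example

```python
import numpy as np
from temponet import (SyntheticSpec, simulate, preprocess_pipeline, nes_matrix,
                      build_network, systematic_paths, overlap_summary,
                      compare_overlap_distributions, best_covering)

spec = SyntheticSpec(seed=7)                       # 2000 genes, 120 processes, 10 time points
library, matrix, probes, truth = simulate(spec)
fc = preprocess_pipeline(probes, merge_pair=None)  # probe triplets -> gene x time matrix
print(f"final matrix: {fc.shape[0]} genes x {fc.shape[1]} time points")

nm = nes_matrix(fc, library, n_perm=300, seed=7)   # es/nes/p for every process x time
net = build_network(library)

greedy = systematic_paths(nm, net, branch=1)[0]
print(f"greedy path recovers planted chain: {greedy.processes == truth.chain}")

perturbed = systematic_paths(nm, net, branch=2)              # 1024 paths
control = systematic_paths(nm, net, branch=2, direction="min")
print(f"perturbed paths: {len(perturbed)}, mean nes {np.mean(perturbed.mean_nes_values()):.2f}")
print(f"control paths:   {len(control)}, mean nes {np.mean(control.mean_nes_values()):.2f}")

s = overlap_summary(perturbed)
rep = compare_overlap_distributions(perturbed, control)
print(f"mean overlap factor {s.mean_overlap_factor:.1f} "
      f"(vs control, Mann-Whitney p = {rep.p_overlap:.3g})")
pair = best_covering(perturbed, k=2)
print(f"best path pair covers {pair.covered}/1024 paths ({100*pair.fraction:.0f}%)")
```

Output:

```
final matrix: 1915 genes x 10 time points
greedy path recovers planted chain: True
perturbed paths: 1024, mean nes 1.28
control paths:   1024, mean nes 0.84
mean overlap factor 608.8 (vs control, Mann-Whitney p = 2.56e-297)
best path pair covers 972/1024 paths (95%)
```

Reading it: after preprocessing, 1915 of 2000 genes show a >2-fold change at
some time point. The pure greedy path through the nes grid is exactly the
planted 10-process chain. The 1024 top-branching paths score far above the
bottom-branching control set (mean nes 1.28 vs 0.84), they converge heavily
(each path shares edges with ~609 others on average, while random path sets
overlap by ~3), and two representative paths already cover 95% of the
population — the structure the path search is designed to expose.

The same pipeline runs from the shell on real files:

```bash
temponet all --seed 7 --outdir run/           # synthetic end-to-end demo
temponet preprocess --probes probes.tsv --mapping mapping.json --outdir pre/
temponet gsea --matrix pre/fc_matrix.tsv --gmt go_bp.gmt --outdir gsea/
temponet network --gmt go_bp.gmt --outdir net/
temponet paths --nes gsea/nes_long.tsv --edges net/edges.tsv --outdir paths/
temponet overlap --paths paths/paths_max.jsonl --control paths/paths_min.jsonl --outdir overlap/
```

Each stage writes TSV/JSONL artifacts plus a manifest (parameters, seed,
input checksums) so any number is reproducible from its run directory.

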