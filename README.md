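# ifndirect

Find **direct, IFNAR-independent DNA-sensing macrophages** in single-cell
RNA-seq by gene-set scoring and condition-contrast clustering.

## The problem

Cytosolic double-stranded DNA activates macrophages through two routes.  A
few cells sense the DNA directly (cGAS → STING → IRF3); the type I
interferons they secrete then bind IFNAR on every other cell and drive a
much larger *secondary* wave of interferon-stimulated gene (ISG)
expression through ISGF3.  Bulk assays cannot separate the two.  With
single-cell profiling of bone-marrow-derived macrophages (BMDMs) under
three arms — vehicle control, dsDNA, and dsDNA plus an IFNAR-neutralizing
antibody — the separation becomes a contrast: blocking IFNAR removes the
secondary wave, so any cell that is still ISG-high must be a direct
responder.  `ifndirect` implements that analysis end to end, for
bioinformaticians who want a reproducible, scriptable version of the
workflow and for methodologists who want a generator with planted ground
truth to benchmark rare-subpopulation recovery.

## The core quantities

Per-cell gene-set scores on **raw** UMI counts,

```
ISG Score_c    = 1e4 · Σ_{g∈ISG panel}    x_gc / Σ_g x_gc
Direct Score_c = 1e4 · Σ_{g∈Direct panel} x_gc / Σ_g x_gc
```

with the 18-gene ISG panel (Ifi204, Isg15, Irf7, Ifit1, Rsad2, Oasl2,
Oas3, Gpb5, Bst2, Ifit2, Ifit3, Oas2, Isg20, Cxcl10, Oasl1, Gpb2, Ccl5,
Ccl3) and the 4-gene Direct panel (Ccl5, Cdk8, Cxcl2, Cd74), embedded in
the standard droplet toolchain: QC (200–2,000 genes, < 1 % mito),
scale-to-10,000 log normalization, 3,000 variance-stabilized HVGs, CCA +
mutual-nearest-neighbor anchor integration across conditions, PCA → SNN
graph (Jaccard weights) → Louvain clustering, Wilcoxon marker discovery.
A direct responder is a blocked-condition cell in a cluster whose median
ISG Score exceeds the pooled 95th percentile and whose membership is > 80 %
blocked-condition (with a cluster-free contrast threshold as fallback).
Details, defaults and design rationale are in [docs/methods.md](docs/methods.md).

A negative-binomial simulator (`ifndirect.simulate`) generates 10x-style
count matrices with the full planted structure — six BMDM subsets, uniform
ISG induction under dsDNA, a rare Ccl5-high direct-responder population
under blockade, deliberate QC failures — and ground-truth labels for every
cell, so the whole pipeline is testable without any external download.

## Worked example

Simulate the three-arm study at its default size (3,000 cells × 5,000
genes per arm) and run everything:

```bash
ifndirect run-all --seed 1 --out-dir demo/
```

which logs the stages and finishes with

```
run-all: finished in 72.4s, 15 direct cells, report at demo/report.json
```

Key fields of `demo/report.json` from that run:

```json
"clustering": {"n_clusters": 6, "n_clusters_phase_merged": 6,
               "cluster_sizes": [2039, 1652, 1255, 1246, 1217, 895]},
"isg_score_by_condition": {"control":       {"median": 32.5},
                           "dsDNA":         {"median": 245.7},
                           "dsDNA_IFNARAb": {"median": 33.0}},
"direct": {"n_direct": 15, "host_cluster": "Fabp4posMHCIIneg",
           "top_discriminant": "Ccl5",
           "direct_panel": ["Ccl5", "Cdk8", "Ifi204", "Oas2"]},
"truth_metrics": {"ari_subsets": 0.9997,
                  "direct_precision": 1.0, "direct_recall": 1.0,
                  "n_true_direct": 15}
```

Reading: integrated clustering of the 8,300 QC-passing cells recovers the
six planted macrophage subsets essentially perfectly (adjusted Rand index
1.00 against ground truth); dsDNA raises the median ISG Score ~8-fold and
IFNAR blockade abolishes the rise; all 15 planted direct responders are
recovered with no false positives, they sit inside the Fabp4⁺MHCII⁻
subset, and Ccl5 tops the discriminant ranking — so the 4-gene Direct
panel begins with Ccl5, as designed.

Every stage is also available separately (`simulate`, `qc`, `hvg`,
`integrate`, `cluster`, `score`, `markers`, `direct`), reading and writing
Matrix-Market triplets and TSV tables, and the whole API is importable
(`from ifndirect import run_full_workflow, isg_score, ...`).  All
randomness flows from `--seed`; a fixed config + seed reproduces
`report.json` byte for byte.

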