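# mignet

Genome-scale gene co-expression network inference from expression
matrices, with seed-driven subnetwork extraction — for computational
biologists who want to reconstruct and mine regulatory association
networks from large cross-experiment microarray (or other bulk
expression) compendia.

## What it computes

**Network inference.** For every pair of genes *i*, *j* with expression
profiles of length *m*, the package estimates mutual information

&nbsp;&nbsp;&nbsp;&nbsp;I(X_i, X_j) = H(X_i) + H(X_j) − H(X_i, X_j)

with the B-spline estimator: each observation distributes unit weight
over up to *k* adjacent bins through B-spline basis functions (defaults:
10 bins, order 3), giving smoother probability estimates than a hard
histogram. Profiles are first **rank-transformed** (each value replaced by
its rank, making every profile a permutation of 1..m). Because MI is
invariant under monotone transformations, nothing is lost — and one pool
of *P* random-permutation MI values becomes a valid permutation null for
*every* pair at once, reducing the cost of permutation testing for all
n(n−1)/2 pairs by a factor of n². An edge is kept when its MI beats at
least a fraction 1−ε of the pooled null. The all-pairs computation is
organised over the block-partition schedule a distributed run would use,
so results are independent of worker count.

**Indirect-edge pruning.** The data processing inequality (for a Markov
chain X→Y→Z, I(X,Z) ≤ min(I(X,Y), I(Y,Z))) flags the weakest edge of
each triangle as a candidate indirect interaction; pruning is
mark-and-sweep on the input network, so it is iteration-order free.

**Subnetwork extraction.** Given seed genes from a partially known
pathway, edge MIs are row-normalised into a Markov chain and every gene
is scored by a random walk with restart,

&nbsp;&nbsp;&nbsp;&nbsp;R(j) = r·P(j) + (1−r)·Σ_i R(i)·w_ij,

where P is uniform over the seeds and r (default 0.3) is the probability
of returning to them. Genes are added in rank order until the induced
subgraph first becomes connected.

**Network statistics.** Density, average degree, diameter, characteristic
path length, clustering coefficient with random-graph expectations
(small-world diagnostics), hub lists, betweenness, a weighted
least-squares power-law fit of the degree distribution (scale-free
diagnostics), and a permutation test for the functional modularity of a
gene set (connected components of its induced subgraph vs random sets).

**Synthetic benchmark.** A generator produces scale-free ground-truth
networks and expression data in which each regulated gene is a linear,
sigmoidal or steep function of its regulators plus noise; predictions are
scored by precision/recall/F and AUROC/AUPR, including a challenge-style
combined score for externally supplied gold standards.

## Worked example

`examples/infer_network.py` simulates a 40-gene regulatory network with
120 observations, infers and prunes the network, and prints:

```
truth edges:     39
edges called:    780 (MI threshold 0.1527 nats)
after DPI:       39
precision 1.000  recall 1.000  F 1.000
density 0.0500  average degree 1.95  clustering 0.000
```

With low noise nearly every gene pair in a 40-gene cascade is
statistically dependent (all 780 pairs beat the permutation null), and it
is the data-processing-inequality step that strips the dependencies down
to the 39 direct regulatory links — here recovering the truth exactly.

`examples/extract_subnetwork.py` seeds two co-regulated genes that do not
interact directly and recovers their shared regulator:

```
seeds: G01, G05  (restart probability 0.3, 67 iterations to converge)
genes added in rank order: ['G00']
subnetwork: 3 genes, 2 interactions
  G00: walk score 0.1925
```

The other examples demonstrate preprocessing (QC, log-centering, quantile
normalization, IQR filtering) and the recovery benchmark across the three
interaction families.

The same pipeline is available from the shell:

```sh
mignet preprocess --expr raw.tsv --qc qc.tsv --iqr 0.65 --out norm.tsv
mignet infer --expr norm.tsv --epsilon 1e-4 --perms 100000 --seed 42 --out net.tsv
mignet dpi --net net.tsv --out net.dpi.tsv
mignet stats --net net.dpi.tsv --out summary.json
mignet extract --net net.dpi.tsv --seeds seeds.txt --out sub.sif
```

All formats are plain tab-separated text (edge lists, SIF for Cytoscape,
expression matrices with chip/experiment header rows); every output embeds
the parameters that produced it.

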