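# dirleiden

Leiden community detection for **directed and undirected** weighted graphs,
with an LFR-style planted-community benchmark suite for validating detected
communities against ground truth.

Graph-based clustering is the workhorse of single-cell analysis: cells (from
scRNA-seq or mass-cytometry panels) become nodes of a similarity graph and
communities become putative cell types and subtypes. The Leiden algorithm is
the current standard for this step, improving on Louvain by guaranteeing
well-connected communities. Most implementations, however, only handle
undirected graphs — discarding the directionality that matters in regulatory
and causal networks. This package implements Leiden over a compressed
sparse-row (CSR) core in both modes, with the directed case built on an
offset-based counting-scatter transposition that produces in-neighbor
adjacency without any comparison sort.

## The quality function

For an undirected graph with adjacency weights $A_{ij}$, strengths
$k_i = \sum_j A_{ij}$ and total weight $m$, the package maximizes modularity
with resolution $\gamma$ (default 1):

$$Q = \sum_C \left[ \frac{\Sigma_{in}(C)}{2m}
      - \gamma\left(\frac{\Sigma_{tot}(C)}{2m}\right)^2 \right]$$

For directed graphs it uses the Leicht–Newman form, whose null model pairs
out-strength with in-strength:

$$Q = \sum_C \left[ \frac{\Sigma_{in}(C)}{m}
      - \gamma\,\frac{S_{out}(C)\,S_{in}(C)}{m^2} \right]$$

Moves are scored incrementally. The directed gain of inserting node $i$ into
community $C$ is

$$\Delta Q = \frac{k_{i,out\to C} + k_{i,in\to C}}{m}
  - \gamma\,\frac{k_i^{out} S_{in}(C) + k_i^{in} S_{out}(C)}{m^2},$$

and the undirected gain is the standard Blondel form; both are validated in
the test suite against full-recompute oracles to 1e-12.

The engine runs the three Leiden phases — greedy local moving, refinement of
each community into well-connected pieces, and aggregation into supernodes —
repeatedly on successive coarser graphs, restarting from the original graph,
until the structure fully converges. Runs are deterministic given a seed.

## Worked example

Generate a planted-community benchmark, cluster it, and score the result
against the ground truth:

```bash
$ dirleiden benchmark generate --n 2000 --mu 0.3 --avg-degree 12 \
      --max-degree 40 --min-comm 20 --max-comm 80 --seed 42 --outdir bench
n=2000 communities=47 realized_mu=0.299

$ dirleiden cluster bench/edges.tsv --seed 1 -o membership.tsv
communities=45 Q=0.675881 passes=10

$ dirleiden eval --pred membership.tsv --truth bench/truth.tsv \
      --graph bench/edges.tsv -o metrics.json
{
  "nmi": 0.9947302235684113,
  "rand": 0.9991745872936468,
  "structural_rand": 0.999089667728721,
  "agreement_pct": 97.45,
  "n_communities_a": 45,
  "n_communities_b": 47,
  ...
}

$ dirleiden stability bench/edges.tsv --runs 10 --seed 1 -o stability.json
mean_pairwise_nmi=1.0000 over 10 runs
```

Reading the numbers: the generator planted 47 communities with a realized
mixing fraction of 0.299 (about 30% of each node's edges leave its
community). Clustering recovers 45 communities at modularity Q = 0.676;
against the planted truth the normalized mutual information is 0.995 and
99.9% of adjacent node pairs receive the same same-community/split decision
(the edge-restricted "structural" Rand index). Label-matched vertex accuracy
is 97.45% — two small true communities were absorbed by neighbors. Repeating
the clustering with ten different seeds reproduces the identical partition
(mean pairwise NMI 1.0) on this easy instance; on harder graphs the score
drops below 1 and quantifies run-to-run stability.

The same pipeline is available as a library:

```python
from dirleiden import GeneratorParams, lfr_like, run_leiden, nmi

bundle = lfr_like(GeneratorParams(n=2000, mu=0.3, seed=42))
result = run_leiden(bundle.graph, seed=1)
print(result.q_trace[-1], nmi(result.membership, bundle.truth))
```

Directed graphs use the same entry points with `--directed`
(`GeneratorParams(..., directed=True)`); the engine then maintains both the
out-neighbor CSR and its counting-scatter transpose.

## File formats

* Edge lists: whitespace-separated `src dst [weight]`, `#` comments,
  0-based ids (`--one-based` shifts), duplicates weight-summed.
* MatrixMarket coordinate files: `symmetric` storage reads as undirected,
  `general` as directed.
* Memberships: `node_id<TAB>community_id`, one line per node.
* Reports: JSON conforming to the schemas in `src/dirleiden/schemas/`.
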