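# historygraph

A unified parsimony model of genome evolution by **replication**,
**substitution** and **double-cut-and-join (DCJ) rearrangement**, for
people reconstructing ancestral genomes from whole-genome alignments.

## The model

A *history graph* G = (V, E, B) couples the two relationships between
segments of DNA:

* **vertices** are oriented segments with an optional allele label over
  {A, C, G, T}; each has a *head* and a *tail* side;
* **adjacencies** (E) are bidirected edges pairing sides — the covalent
  bonds of chromosomes; connected components of E are *threads* (linear
  or circular chromosomes / fragments);
* **branches** (B) are directed ancestry edges between homologous
  vertices; contracting all adjacencies must leave a DAG.

A fully explicit scenario — a *simple history* — layers the graph into
*n*-way replication epochs and rearrangement epochs.  Its substitution
cost *s* counts branches whose endpoint labels differ; its rearrangement
cost *r* sums rearrangement-cycle sizes, which equals the number of DCJ
operations.  The cost of an arbitrary history graph is the minimum cost
of any simple history extending it — an NP-hard quantity that this
package brackets with four trivially computable bounds derived from the
*lifted graph* (descendant labels and adjacencies projected onto their
most recent informative ancestors):

* `lbsc`/`ubsc` — lower/upper bound substitution cost,
* `lbrc` = Σ_M (⌈|V_M|/2⌉ − 1) over modules M (components of real plus
  lifted adjacencies), and `ubrc` from non-trivial lifted adjacencies.

The bounds coincide exactly on *ancestral variation graphs* (AVGs):
graphs with zero ambiguity (at most one non-trivial lifted label per
vertex and incidence per side).  For a seed graph G, the finite set of
*G-bounded* extensions — reachable by characteristic attachment and
detachment operations, and limited in size by the closed forms
max(0, 10n−8) and max(0, 2m−2, 20n−16, 20n+2m−18) — contains every
parsimony-optimal AVG, so sampling it explores all most-parsimonious
interpretations of G.

## Worked example

```python
from historygraph import bounds_report
from historygraph.fixtures import fixture

b = bounds_report(fixture("fig2b").graph)
print(b.as_dict())
```

prints

```
{'u_s': 1, 'u_r': 5, 's_l': 4, 's_u': 5, 'r_l': 3, 'r_u': 6,
 'is_avg': False}
```

— this ambiguous alignment graph needs between 4 and 5 substitutions
and between 3 and 6 DCJ operations; one vertex has an uncertain
ancestral allele (`u_s = 1`) and five excess non-trivial lifted
adjacency incidences (`u_r = 5`) measure the rearrangement uncertainty.
The `examples/` scripts walk through the other capabilities: simulating
and degrading simple histories, sampling G-bounded AVGs with
branch-and-bound pruning, and realising an AVG as an explicit scenario
whose costs meet the lower bounds exactly.

A thin CLI mirrors the library:

```sh
histgraph --seed 7 simulate            # history.json + seed_graph.json
histgraph bounds seed_graph.json
histgraph --seed 7 sample seed_graph.json --starts 200
histgraph realise avg.json --out history.json
histgraph export-dot seed_graph.json --annot lifted
```

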