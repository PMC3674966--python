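# steinersub

Steiner tree extraction of seed-gene sub-networks from unweighted molecular
interaction networks.

## The problem

A recurring task in systems biology is to connect a list of seed genes or
proteins — a GWAS hit list, an expression signature — inside a large
protein-protein interaction network, in order to see how the seeds might
interact. When no credible node or edge weighting is available (most
interaction databases carry no confidence scores), the natural formalization
is the classical **minimum Steiner tree problem**: given an unweighted graph
*G* = (*V*, *E*) and terminals *S* ⊆ *V*, find a connected sub-graph
*G*′ = (*V*′, *E*′) with *S* ⊆ *V*′ and |*E*′| minimal. The problem is
NP-complete, so practical work needs approximation heuristics — and, because
minimal Steiner trees are generally not unique, ways to present *all*
equally-sized solutions rather than an arbitrary one.

## What the package provides

| method | kind | idea |
|---|---|---|
| `exact` | exact tree | enumerate non-terminal subsets *A* by increasing size; first connected *S* ∪ *A* wins (|*S*|+|*A**|−1 edges) |
| `exact-merged` | merged sub-graph | union of **all** minimal Steiner trees |
| `sp` | heuristic tree | shortest-paths growth (Takahashi–Matsuyama) with spanning-tree + leaf-strip clean-up (Rayward-Smith & Clare) and random restarts; within (2 − 2/|*S*|) of optimal |
| `kb` | heuristic tree | Kruskal-like merging of closest terminal components |
| `rsp` | heuristic tree | randomized node removal/insertion on the union of all terminal-pair geodesics |
| `asp` | baseline sub-graph | union of one shortest path per terminal pair |
| `stm` | merged sub-graph | SP growth taking *all* tied terminals via *all* their geodesics; merges the best runs over start terminals |

Distances are hop counts throughout; on an unweighted graph every spanning
tree is a minimum spanning tree, which both the exact search and the
clean-up step exploit. Solution quality is measured by the edge count
|*E*′| and the terminal frequency |*S* ∩ *V*′|/|*V*′|.

A simulation module benchmarks the methods the way one would on a real
interaction network: synthetic scale-free networks, random-walk terminal
sampling (each first-visited node becomes a terminal with probability θ),
neighborhood-absorbing sub-network sampling for exact comparisons, and
paired Wilcoxon signed-rank tests with Holm correction between methods.

## Worked example: AR–HDAC9

HDAC9 is associated with male pattern baldness; its indirect coupling to the
androgen receptor (AR) runs through seven shared interactors. With terminals
{AR, HDAC9} there are seven distinct two-edge Steiner trees — a textbook
case of solution non-uniqueness, bundled as the `fig2` toy graph:

```sh
steinersub fixtures --name fig2 --out fig2.sif
printf "AR\nHDAC9\n" > seeds.txt
steinersub solve --graph fig2.sif --terminals seeds.txt --method stm --out-prefix ar_hdac9
cat ar_hdac9.metrics.json
```

```json
{
  "method": "stm",
  "n_nodes": 9,
  "n_edges": 14,
  "terminal_frequency": 0.2222222222222222,
  "runtime_seconds": 0.0004711859999133594,
  "seed": 0,
  "minimal_tree_size": 2
}
```

The merged sub-graph contains all 9 nodes and 14 edges: every one of the
seven minimal trees AR–*x*–HDAC9 (*x* ∈ {NRPI1, HDAC1, HDAC3, NCOR1, SUMO1,
NCOR12, HDAC4}) survives, each of size `minimal_tree_size = 2`. Running
`--method exact-merged` returns the identical sub-graph; `--method sp`
returns one optimal two-edge tree. The solution itself is written as SIF to
`ar_hdac9.sif`.

The same `solve` command works on any SIF or edge-list network with any
newline-delimited terminal list; `steinersub benchmark --config FILE` drives
full method comparisons from a flat `key = value` config file.

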