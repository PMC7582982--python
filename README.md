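# motifsync

Tools for asking *why some small patterns of ties are common and others rare*
in directed networks of collaborative problem-solving (engineering design
tasks, product development, and similar information-dependency networks, but
the machinery applies to any directed network): do subgraphs that
**synchronize** easily occur more often than chance?

`motifsync` implements the full analysis chain:

1. **Subgraph catalog** — all isomorphism classes of weakly-connected
   directed graphs on 3 nodes (13 classes) and 4 nodes (199 classes),
   canonicalized by brute force over node permutations.
2. **Problem-solving dynamics** — an asynchronous stochastic process on a
   digraph in which each node (a subproblem) is *open* or *closed*. At each
   step one node is picked uniformly at random; a closed node with `k` open
   in-neighbors reopens with probability `1 − (1−β)^k`, and an open node
   closes with probability `(1−β)^k · δ` (it must escape each open
   in-neighbor's influence, probability `1−β` each, then resolve itself with
   the self-directed probability `δ`). The all-closed state — *full
   synchronization* — is absorbing.
3. **SM scores** — the synchronizability metric of a subgraph: its
   probability of full synchronization within `T` updates, averaged over
   `(β, δ) ~ Uniform(0,1)²` (`S` parameter samples × `R` realizations per
   sample, all-open start). Quartiles of the SM scores split classes into
   four synchronizability classes.
4. **Census** — induced-subgraph counts of every class in a network
   (ESU-style enumeration of connected node subsets, each subset counted
   once).
5. **Null significance** — Erdős–Rényi `G(n, m)` ensembles matched on nodes
   and arcs; per-class Z-scores `Z = (N_real − ⟨N_rand⟩)/σ_rand`, unit-norm
   significance profiles, and bounded relative-difference scores
   `RD = (N_real − ⟨N_rand⟩)/(N_real + ⟨N_rand⟩)`.
6. **Rank statistics** — Spearman correlations between SM score and
   frequency, Kruskal–Wallis tests of abundance across synchronizability
   classes (overall and within edge-count density classes), and box-plot
   summaries.

Networks are read from two-column edge lists (TSV/CSV) or binary
Dependency-Structure-Matrix (DSM) CSV files; a synthetic module generates
seeded ER and planted-motif networks so everything runs self-contained.

## Worked example

Score every 3-node subgraph class (1,000 parameter samples × 100
realizations × 120 single-node updates):

```bash
motifsync sm --size 3 --samples 1000 --realizations 100 --seed 7
```

```
rank	name	sm_score	sm_se	sm_class
1	out-star	0.94187	0.006108692104	4
2	in-star	0.93995	0.005893915145	4
3	cascade	0.93389	0.006459852754	4
4	feedforward loop	0.92906	0.006660576528	4
5	mutual-out	0.80554	0.01012895375	3
6	regulating mutual	0.79926	0.009936799907	3
7	regulated mutual	0.79875	0.01034952415	3
8	mutual-in	0.79414	0.01049580976	2
9	feedback loop	0.76173	0.01110555899	2
10	mutual cascade	0.68502	0.01212442169	2
11	double mutual	0.67077	0.0125434463	1
12	semi-clique	0.6398	0.01283650793	1
13	clique	0.54847	0.01340933143	1
```

Reading: feedback-free structures (stars, cascade, feedforward loop) top the
ranking with SM ≈ 0.93–0.94 — they synchronize over most of the `(β, δ)`
square. Each mutual dyad or longer feedback loop added drops the score; the
fully bidirectional 3-clique is last (SM ≈ 0.55). `sm_se` is the Monte-Carlo
standard error: ranks 1–4 and 5–8 are near-tied blocks whose internal order
is not resolvable at this protocol, while the tier structure (tops, middles,
feedback loop, semi-clique, clique) is stable. `sm_class` is the quartile
synchronizability class (4 = high).

From Python, the same pieces compose directly:

```python
import motifsync as ms

cat = ms.enumerate_classes(3)
net = ms.gen_er(60, 230, seed=1)                    # or ms.read_edgelist(...)
census = ms.count_subgraphs(net.graph, cat)
ens = ms.er_ensemble(60, 230, 500, cat, seed=2)
profile = ms.z_scores(census, ens)                  # Z, unit-norm SP, flags
```

A whole study (catalog + SM + census + significance + statistics, with a
replayable manifest) runs from a YAML config:

```bash
motifsync run-study --config study.yaml --seed 1 --out results/
```

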