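# pagdiscover

Bootstrap-ensembled causal discovery on **Partial Ancestral Graphs (PAGs)**
for modest cross-sectional cohorts — the setting typical of clinical
research, where a few hundred subjects are measured on a dozen-plus
heterogeneous instruments (symptom scales, cognitive batteries, functioning
scores) and the question is which variables plausibly *drive* which,
allowing for unmeasured confounders.

From a subjects × variables table the pipeline:

1. estimates a PAG with **GFCI** — a score-based forward/backward search
   (FGES) over the penalized Gaussian BIC builds a CPDAG "supergraph",
   which constraint-based FCI refinement then prunes with Fisher-Z
   conditional-independence tests and orients with the standard final rules
   (R1–R4, R8–R10; selection bias is assumed absent, so R5–R7 and
   undirected edges never arise);
2. repeats the estimate on **B subsamples** (default 1,000 draws of 90% of
   the rows, without replacement) and tallies, per variable pair, how often
   an edge appears and in which classified form;
3. **classifies** every PAG edge into a seven-type taxonomy crossing
   directness with latent confounding, and
4. retains pairs present in strictly more than half the replicates,
   assigning each its most frequent signature — an edge-stability consensus
   graph plus a frequency report.

A linear Gaussian SEM simulator with pure latent confounders — including a
16-variable clinical-cohort preset with a known oracle PAG — makes every
stage testable end to end without access to patient data.

## The statistics underneath

**Fisher-Z test.** For variables $x, y$ given a set $S$, the partial
correlation $r$ comes from the inverse of the correlation submatrix over
$\{x, y\} \cup S$; the statistic
$z = \tfrac12 \ln\frac{1+r}{1-r}\sqrt{n - |S| - 3}$
is compared to a standard normal (two-sided, $\alpha = 0.05$ by default).

**Penalized BIC.** The local score of node $y$ with parents $P$ is
$-n \ln \hat\sigma^2_{y|P} - c\,|P| \ln n$ with the maximum-likelihood
residual variance computed on the correlation scale and penalty discount
$c = 2$ by default. The score is decomposable and score-equivalent, so all
DAGs in one Markov equivalence class tie exactly.

**Edge taxonomy.** Directed PAG edges are *visible* (type "NLC": provably
no latent confounder, by Zhang's criterion) or not ("PLC"), and *definitely
direct* ("DD": removing the edge leaves no semi-directed path between its
endpoints) or only *possibly direct* ("PD"). Together with circle–arrow,
circle–circle and bidirected patterns this gives types N.1–N.7.

## Worked example

Simulate a 215-subject cohort from the clinical preset, then run the
discovery pipeline with 100 replicates:

```sh
pagdiscover simulate --preset clinical --n 215 --seed 7 --out sim
# wrote 215×16 cohort and ground truth to sim
pagdiscover run --data sim/data.csv --out results --reps 100 --seed 42
# pagdiscover.io  INFO  consensus: 14 pairs tallied, 11 retained
```

`results/report.tsv` begins (columns beyond the fourth are the frequencies
of each edge type ever observed for the pair; `-` marks a frequency below
0.0005):

```text
Variable A  Most frequent edge  Variable B  Presence probability  N.1 --> DD NLC  N.5 o->  N.6 o-o  N.7 <->
Dis         N.5 o->             RLFunc      1.000                 -               1.000    -        -
Avl         N.6 o-o             ExD         1.000                 -               -        0.940    0.060
Avl         N.5 o->             RLFunc      1.000                 -               0.940    -        0.060
SoP         N.6 o-o             VerL        1.000                 0.450           -        0.550    -
```

Reading the first row: in every one of the 100 replicates some edge joined
conceptual disorganization (Dis) and real-life functioning (RLFunc), and
the dominant signature was `Dis o-> RLFunc` — RLFunc cannot be a cause of
Dis, while Dis may be a cause of RLFunc, or they may share a latent
confounder. The consensus graph itself is written to
`results/consensus.edges.txt` (text) and `results/consensus.dot`
(Graphviz), with `params.json` capturing the seed and an input hash so the
run is exactly reproducible; rerunning with the same seed yields
byte-identical outputs.

Other subcommands: `pagdiscover oracle sim/truth.edges.txt` prints the
population PAG of a ground-truth DAG, and `pagdiscover classify` re-derives
the seven-type labels of any edges-text PAG.

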