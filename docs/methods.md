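# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind `pagdiscover`. It is written for a reader who wants to
judge what the package's tests do and do not establish.

## Graphical model and assumptions

The pipeline targets cross-sectional, continuous, approximately Gaussian
data generated by an acyclic linear structural equation model in which some
common causes are unobserved. Under the causal Markov condition and
faithfulness, the observable signature of such a system is its **maximal
ancestral graph (MAG)**: the projection of the causal DAG onto the observed
margin, where a directed edge means "ancestor", a bidirected edge means
"latent confounding only", and adjacency means "not separable by any
observed subset". What a constraint-based algorithm can identify from
independence facts alone is the Markov equivalence class of that MAG,
summarized by a **partial ancestral graph (PAG)** whose circle marks flag
undetermined endpoints.

Selection bias is assumed absent throughout: tail–tail (undirected) edges
are rejected at graph construction, and the orientation rules that exist
only to handle selection (R5–R7) are omitted. Cyclic models, interventional
semantics and non-Gaussian or discrete data are out of scope.

## Separation, projection and classification

*m-separation* is decided by a breadth-first walk over (previous, current)
edge states; a connecting walk implies a connecting path, so walk semantics
are sound and complete for separation. *Latent projection* decides
adjacency of observed $x, y$ by testing the single candidate separator
$(\mathrm{An}(x) \cup \mathrm{An}(y)) \cap O \setminus \{x, y\}$ — if any
observed subset separates the pair, that ancestral set does. An exhaustive
all-subsets search (`method="exhaustive"`) is retained and the two are
asserted equal on random DAGs; the shortcut exists because the exhaustive
search is exponential and becomes the hot path on 16-variable graphs.

Directed PAG edges are classified on two axes. **Visibility** follows
Zhang's criterion (a vertex outside the head's adjacency with an edge into
the tail, or a collider path into the tail whose interior vertices are all
parents of the head); a visible edge cannot be produced by latent
confounding alone. **Definite directness** is operationalized as the
absence of any alternative semi-directed path after removing the edge.
This is the Tetrad-style reading of "no mediator": a MAG adjacency already
rules out *full* mediation by observed variables, so the thin/thick
distinction is interpreted as "an observed semi-directed channel could
carry part of the effect", and that interpretive gap is acknowledged here
rather than hidden. Both predicates are path searches bounded only by
graph size — fixtures and the clinical preset are small, so no depth caps
are applied.

## FGES

The score is the penalized Gaussian BIC on the **correlation scale**:
$s(y, P) = -n\ln\hat\sigma^2_{y|P} - c|P|\ln n$, with ML (divide-by-$n$)
residual variance so the score-equivalence identity holds exactly, and the
constant intercept/variance parameter omitted from the penalty (it is
identical across models on the same node set and cannot change any
decision). Working on correlations makes every decision invariant to
affine rescaling of the columns — the input variables come from instruments
with arbitrary units — and this invariance is asserted by test.

The search applies Chickering's Insert/Delete operators. After each move
the PDAG is re-closed by extending it to a consistent DAG (Dor–Tarsi) and
rebuilding the CPDAG from that DAG's v-structures plus the Meek rules.
Equal-score candidates are broken lexicographically by node order, making
the search deterministic given the column order of the input table;
determinism was preferred over fidelity to Tetrad's unspecified internal
ordering. Candidate generation rescans all pairs each iteration — at 16
variables the simplicity is worth more than incremental bookkeeping, and a
per-(y, parents) score cache removes the redundant regressions. Node
degree is unbounded by default; `faithfulness_assumed` (off by default, the
safer choice) restricts insertions to marginally score-improving pairs.

## GFCI refinement

Phase two prunes FGES adjacencies by Fisher-Z tests over subsets of current
adjacency sets, ascending in size with lexicographic order within size; the
first separating set wins and is recorded. All endpoints are then reset to
circles and unshielded colliders $x \,{*}\!\to z \leftarrow\!{*}\, y$ are
oriented **only from recorded evidence**: either the phase-one CPDAG
already had both arrows into $z$, or $z$ is absent from the recorded
separating set of $(x, y)$. Pairs that were never adjacent contribute no
orientation — an earlier draft searched for separating sets on demand at
this step, and borderline acceptances planted spurious colliders whose
arrows then propagated through R1; the restriction to recorded sepsets
removed that failure mode entirely. A possible-d-sep pass (simple-path
semantics; a walk-based search provably overshoots and is avoided) then
removes any remaining separable pairs, orientation restarts from circles,
and the final rules R1–R4 and R8–R10 run to a fixed point. Orientation
conflicts are logged and resolved first-writer-wins; no majority heuristic
is applied.

`oracle_gfci` runs the same refinement with graphical separation as the
independence oracle and the complete graph as the phase-one supergraph, so
its output is determined by the refinement alone; soundness against the
projected MAG (adjacencies exact, every non-circle mark matching) is
verified over random latent-variable DAGs. Removal in phase two uses tests
only, never score differences — the conservative reading of the hybrid
design; a score-assisted removal variant was considered and not built.

## Bootstrap consensus

Replicates draw $\lfloor 0.9\,n \rfloor$ rows **without replacement** — the
protocol is subsampling, not the classic bootstrap, though
`--with-replacement` exposes the latter. Replicate $r$ derives its
generator from the pair (master seed, $r$), so enlarging $B$ never
reshuffles earlier replicates, and a failed replicate (singular submatrix)
is redrawn with a sub-keyed seed; more than 5% failures aborts. Presence
probabilities use $B$ as the denominator, including any redrawn slots.

Per pair, signatures (canonical oriented pair + edge type) are counted
with integer arithmetic, so frequency identities are exact. Consensus
retains pairs with presence **strictly** above the threshold (0.5 by
default: exactly half is out), assigns the most frequent signature, and
breaks count ties toward the *less informative* signature — circle–circle
over circle–arrow over bidirected over directed, and among directed types
the higher number (weaker claim) — with a logged warning. The consensus
graph is an edge-wise assembly and is deliberately **not** coerced into a
globally valid PAG; an ancestrality/cycle check runs and violations are
logged, because most-frequent-per-pair aggregation has no global validity
guarantee. The report lists every pair ever seen, sorted by presence
descending, probabilities fixed to three decimals, frequencies below
0.0005 rendered as a dash; outputs are UTF-8 with LF endings so identical
(input, parameters) reruns are byte-identical.

## Synthetic data

`sample_sem` draws $X_j = \sum_k b_{jk} X_k + \varepsilon_j$ in topological
order with independent Gaussian noises, drops latent columns and affinely
rescales observed columns to instrument-like means and SDs using the
*population* SD (so rescaling is data-independent and provably decision-
neutral). `random_sem` samples sparse DAGs with latents as pure
confounders — roots with exactly two observed children, matching the
interpretation of confounded edges as shared causes rather than latent
mediators — and rejects parameterizations whose population partial
correlations come within $10^{-3}$ of zero on small conditioning sets
(near-unfaithful cancellations).

The **clinical preset** emulates a 215-subject, 16-variable cohort
(symptom factors, MCCB-style cognitive percentiles, metacognition, insight,
functioning; marginal means/SDs matched to published instrument scales).
Its ground truth: eleven directed effects (visual/verbal learning → working
memory → processing speed/metacognition → reasoning/functioning, plus
symptom→functioning paths), six of those pairs additionally confounded by
a pure latent, two pairs (visual–verbal learning; the two insight scores)
associated through a latent common cause only, and three isolated variables
(positive symptoms, depression, social cognition).

Two consequences of this structure deserve emphasis. First, the preset's
MAG has **more adjacencies than the intended skeleton** (18 vs 13):
overlapping confounders around working memory create inducing paths (e.g.
verbal learning–metacognition) that no observed subset separates. These
are genuine features of latent projection, not bugs. Second, those
inducing-path dependencies are high-order products of coefficients, and
under uniform coefficient values their weakest population partial
correlation lands between 0.003 and 0.017 — below what any test can see at
n = 50,000. The per-edge coefficients were therefore **calibrated against
the model-implied covariance only** (randomized search maximizing the
weakest MAG-adjacent partial correlation, no sampled data involved),
landing at ≈ 0.037: strongly detectable at n = 50,000, far below
detectability at n = 215. That preserves the intended regime — the full
structure is recoverable in principle at large n, while at cohort scale
only the stronger direct associations survive the bootstrap, mimicking the
uncertainty a real study faces. The 70% direct-pair retention floor
checked at n = 215 is a property of this calibration, chosen for this
artifact, not an external claim.

What the simulator does **not** emulate: ordinal/Likert measurement,
floor/ceiling effects and skew of real instruments, missing data,
measurement error, and selection into the cohort. Passing tests therefore
demonstrate algorithmic correctness and calibration under the stated
model, not performance on real clinical data.

## Problem sizes and determinism

Default test and acceptance workloads use n = 215 and n = 50,000 samples
on 16 variables, 10,000 replicates for test calibration, 100 random DAGs
(≤6 observed, ≤2 latent) for oracle soundness, and 60–100 bootstrap
replicates where full production runs would use 1,000 — sizes chosen so
the whole suite completes in minutes on one core while keeping every
binomial tolerance meaningful. All randomness flows through explicit
`numpy` generators seeded from user-visible integers; no global state is
touched.

## Known limitations

- Fisher-Z assumes linear-Gaussian margins; heavy tails or nonlinear
  effects degrade both size and power (no rank/robust variant is built).
- Complete-case deletion is the only missing-data policy.
- The possible-d-sep subset search is exponential in the pds set size when
  `max_cond_size` is unlimited; this is acceptable at 16 variables but
  will not scale far beyond.
- The consensus graph may violate PAG axioms (warned, by design).
- First-writer-wins conflict handling makes rule output order-dependent in
  the (rare, logged) inconsistent-test regime; node order is the
  tie-break everywhere, so results remain deterministic for a fixed input.
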