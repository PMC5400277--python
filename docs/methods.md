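# Methods

## Model and update scheme

The packaged circuit is a synchronous deterministic Boolean network:
every node holds a value in {0, 1} and all nodes are updated in
parallel by their rules.  Synchronous update was chosen because the
modeled circuit is reported to settle into a single fixed steady
expression state, which the synchronous formalism reproduces exactly
and checks exhaustively; asynchronous and probabilistic semantics are
out of scope.  With n nodes the state space has 2^n states, so every
trajectory enters a cycle; a length-1 cycle is a fixed point.

Environmental conditions (cytokinin presence, SPT expression) are
represented by *input nodes* whose rule is the identity on themselves.
This keeps the fixed-point formalism uniform: inputs hold whatever the
initial state or a clamp gives them, and a "wild-type condition" is
expressed by clamping CK=1, SPT=1 before enumerating the free
subspace.

### Encoding choices

- **ARR1 is split into two nodes** — the transcript `ARR1` (activated
  by SPT) and the active phosphorylated protein `ARR1P = ARR1 AND CK` —
  because transcriptional activation and phosphorelay-dependent
  activation are separate control points with distinct knockout
  signatures: without SPT the transcript disappears, without CK the
  transcript stays but the protein is inactive.  Motif analysis
  collapses the pair back into one gene via an explicit alias table in
  the model metadata (`{"ARR1P": "ARR1"}`), never by name heuristics.
- **The two AND-gates** `TAA1 = SPT AND ARR1P` and
  `PIN3 = SPT AND ARR1P` encode cooperative regulation: the target is
  active only if both regulators are.
- **AUX is a produced species** with rule `AUX = TAA1`.  PIN3 models
  transport *capacity*; it does not consume AUX, because a Boolean
  layer cannot represent flux.  The "auxin drainage" reading of PIN3
  activity is interpretation, not dynamics.
- **"CK signaling off" is clamping the CK input to 0.**  The node is
  the hormone signal; receptors and phosphotransfer proteins are not
  individual nodes in the medial variants.
- **Not instantiated:** ARR10 (no reduction observed in the relevant
  mutant background) and hypothetical SPT links to further
  cytokinin-signaling components are recorded as model metadata notes
  only.
- **Knockouts are clamps, not node deletions.**  Clamping preserves
  the state-space dimension, makes wild-type and perturbed steady
  states directly comparable node-by-node, and subsumes deletion for
  steady-state questions (a clamped-to-0 node has no influence).

The exact Boolean equations behind the original in silico analysis are
not published — only the topology and the two AND-gates are stated —
so the packaged rules are the minimal faithful encoding of that
wiring.  An alternative with an external auxin source
(`AUX = TAA1 OR AUXext`) was considered and not adopted: it adds a
free parameter without changing any reported outcome.

### Variants

- `core_medial` (default): the 7-node circuit above.
- `extended_medial`: adds `ARR12 = SPT` as a sink node (a second
  SPT-activated type-B regulator with no modeled targets).  Adding a
  sink cannot change upstream dynamics, and the tests verify the
  knockout panel projects exactly onto the core result.
- `lateral`: adds the repressors AHP6 and ARR16 and routes the
  phosphorelay through `CKSIG = CK AND NOT (AHP6 OR ARR16)`;
  `ARR1P = ARR1 AND CKSIG`.  AHP6 is a self-sustaining input by
  default; the option `ahp6_source="auxin"` wires `AHP6 = AUX`
  (the hypothesized auxin-activated source).  That option closes a
  negative feedback loop and makes the clamped circuit multistable —
  `wildtype_steady_state` then raises `UnstableModelError` rather than
  silently picking an attractor.

For the lateral variant, `wildtype_steady_state` clamps the extra
declared inputs (AHP6, ARR16) to caller-supplied values, default 0, so
the unique-attractor contract remains well-defined; the lateral
condition proper is AHP6=1.

## Attractor enumeration and canonical form

`enumerate_attractors` builds the full successor table over 2^n
states, discovers every terminal cycle by path-following, and assigns
each state to the attractor its trajectory reaches, so basin sizes
partition the state space by construction.  Enumeration refuses models
with more than 24 nodes (2^24 successor evaluations is the desk-scale
ceiling) with an explicit error rather than degrading.  Cycles are
canonicalized by rotating the lexicographically smallest bitstring
first (the encoding puts the first declared node in the most
significant bit, so bitstring order equals integer order), and
attractors are sorted by that representative — output is reproducible
across runs and platforms.  Truncated simulations return a flagged
partial trajectory instead of raising, so interactive exploration with
small step bounds stays usable.

## Motif classification

The signed gene graph carries one edge per (regulator, target) pair
with sign +1/-1 taken from the literal's polarity in the target's
rule; a regulator appearing with both polarities on one collapsed
target raises an ambiguity error.  Self-loops (input identities, the
intra-gene transcript->protein edge) are not materialized as edges —
input-ness is kept as a node attribute — since motif scans exclude
them by definition.  A feed-forward loop is any ordered triple of
distinct nodes with the three required edges; additional edges do not
disqualify a triple (standard motif convention).  Coherence follows
the sign-product rule (direct sign = product of the indirect signs)
and types 1–4 within each family follow the standard sign-pattern
numbering; the packaged circuit's two loops are coherent type 1
(all-activating).  Motif-enrichment statistics against random
ensembles are deliberately not implemented; the degree-preserving
rewiring in `synthetic` is the null-model hook only.

## Penetrance and concordance

Penetrance is `100 * affected / total`, rounded half-up to one decimal
(`decimal.Decimal`, `ROUND_HALF_UP`) — one decimal because the
reported percentages carry one decimal.  Percentages reported without
their underlying counts (e.g. 78.2% of n=330) are stored as reported
values, flagged `counts_printed=false`, and never recomputed.
Concordance is qualitative — the Boolean model predicts altered vs.
unaltered development, nothing quantitative — so a row is concordant
iff the model's altered flag equals the reported phenotype call.  No
single "CK signaling off" genotype exists; the CK knockout is mapped
to the *arr1 arr10 arr12* triple-mutant record with an explanatory
note in the fixture.  The fixture (`data/observations.json`) is
versioned and validated by the test suite against the recomputable
percentages.

## Synthetic networks

The generator emulates Kauffman-style random Boolean networks: n
nodes, fixed or per-node in-degree k, parents sampled without
replacement excluding self, and one of four rule classes
(`random_truth_table` via random DNF, AND/OR of literals with a
negation probability, nested canalyzing).  Defaults for the engine
cross-check suite are n in 3..10, k=2 — small enough that a
brute-force oracle (simulate from every one of the 2^n states) is
exact.  Each call draws from a single private `random.Random(seed)`
stream; equal specs produce byte-identical serialized models, and
there is no global random state.  `negation_probability` is ignored by
`random_truth_table` because a uniformly random output column already
spans all polarities.

These random ensembles validate the *engine*, not biology: they share
the packaged circuit's formal class (small Boolean networks) but none
of its structure, so passing the oracle-equivalence suite demonstrates
correctness of enumeration, not anything about real gynoecium
regulation.  Degree-preserving rewiring performs double-edge swaps
(rejecting self-loops and duplicate edges, signs traveling with their
source half); when the attempt budget is exhausted the graph
accumulated so far is returned with a recorded shortfall and a
warning, never an exception.

## File formats and CLI

Model files use the plain-text dialect standard in the Boolean-network
tool ecosystem (`targets, factors` header, `&`/`|`/`!`, `0`/`1`
constants, `#` comments); round-trip stability (identical node order,
rules and state-transition graph) is tested for the packaged and for
random models.  Qualitative-SBML export is deferred.  Graph export is
DOT only, with activation as a normal arrowhead and repression as a
tee.  Run configs are JSON validated by a pydantic model whose JSON
Schema is exported (`gynogrn.config.config_schema`).  CLI exit codes:
0 success, 1 runtime failure, 2 invalid usage or config.

## Problem sizes and limitations

The verification suites use 100 seeded random networks with n ≤ 10 for
oracle equivalence and 100 + 3 models for round-trip checks; both
complete in seconds because exhaustive enumeration at n ≤ 10 touches
at most 1024 states per model.  Known limitations: no asynchronous or
multi-valued semantics; no spatial coupling between medial and lateral
compartments (the lateral variant is a separate model, not a tissue);
the Boolean layer cannot express auxin flux, dosage, or the partial
redundancy among type-B ARRs beyond the single merged ARR1 node; and
style/stigma regulation, which differs from the ovary program, is not
modeled.
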