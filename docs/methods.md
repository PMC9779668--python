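# Methods

## Model and assumptions

hybridra treats a cell as two coupled layers. The regulatory layer is a
Boolean network: components (ligands, receptors, transcription factors,
enzymes, metabolite presence/absence flags) take values in {0,1} and update
asynchronously, one component at a time, by rules built from AND/OR/NOT.
The metabolic layer is a constraint-based model at steady state: a flux
vector `v` with `S·v = 0` and bounds `l ≤ v ≤ u`, analyzed by linear
programming against a maximal-ATP objective.

The coupling is deliberately one-directional and conservative. Only
regulatory components whose asymptotic value is *provably zero* — value 0
in every minimal trap space of the condition-reduced network — generate
metabolic constraints (zero flux through catalyzed or producing
reactions). An active or undetermined component generates nothing, because
Boolean activity carries no magnitude information. Consequences of this
choice: the framework never fabricates flux levels from qualitative
states (unlike interval-discretization approaches, which need per-node
calibration), but conditions that leave few components provably OFF yield
few constraints and hence mild metabolic effects. Feedback from metabolism
to regulation is out of scope (the regulatory layer is upstream by
assumption).

## Value propagation

`propagate` computes the least fixpoint of constant propagation from the
caller's fixed assignments. Clamped components keep their clamped value
even where their own rule disagrees — a condition is an external clamp
describing the cellular context, not a seed state. The fixpoint is
idempotent, and monotone under consistent extension; contradictory
caller inputs are rejected when conditions are merged, and cannot arise
from propagation itself. By default clamps stay fixed through the
trap-space search; `unclamp=True` keeps only their propagated consequences
(both behaviors are defensible because a clamp is an assumption about the
environment, and the flag makes the choice explicit).

## Minimal trap spaces

A partial state is a trap space iff for every fixed component `x = v`,
the rule of `x` restricted to the subspace is constantly `v` (so no
asynchronous update can leave). `minimal_trapspaces` works symbolically:

1. percolate constants and reduce the network;
2. compute all prime implicants of every free rule and its negation by
   Quine–McCluskey over the rule's support;
3. enumerate *stable motifs*: inclusion-minimal, consistent literal sets
   in which every literal is backed by a prime implicant lying entirely
   inside the set (a depth-first search branching over implicant choices);
4. recurse into each motif after percolating it; a branch with no motif
   left has reached a minimal trap space.

Correctness rests on three facts: a supported literal set is a trap
space; every proper trap space contains a stable motif; and percolation
never discards a minimal trap space. The search is deterministic
(literals and motifs processed in sorted order; output ordered
lexicographically with 0 < 1 < free per component) and capped by a node
budget (default 500 000) that raises an explicit error instead of
returning a partial answer. An independent exhaustive enumerator over all
`3^n` partial states (`brute_force_minimal_trapspaces`, capped at n = 10)
pins the semantics in the test suite; the two routes agree on every
instance of a 100-network random battery.

## Name matching and constraint extraction

Metabolite base IDs are metabolite IDs with one trailing compartment tag
stripped (default suffix set `_c, _m, _e, _i, _x`, overridable per model);
enzyme matching strips a reaction prefix (default `R_`). Matching is
case-insensitive, the exclusion list (common intermediates such as ATP or
CO2 that appear as metabolites in the model but carry no regulatory
specificity) is applied before metabolite matching, and a name matching
both a metabolite and a reaction aborts with an error — a silent priority
would corrupt every downstream number. A metabolite component constrains
the producing reactions of *all* its compartment instances, because the
regulatory layer is compartment-blind. Constraining a reaction sets both
bounds to zero, including reversible reactions that produce the target
only in reverse: the conservative reading of "this flux will not occur".

## FBA and reports

The LP is solved with GLPK through cobrapy (feasibility tolerance 1e-9,
deterministic given identical input). FBA optima can be degenerate in the
flux vector; the objective value — and therefore the ATP-source split,
which is computed from the positive contributions of the objective terms —
is unique regardless. A parsimonious post-step (minimize total |v| at the
fixed optimum) is available behind a flag, off by default to match plain
FBA. C-flux weights each boundary reaction by carbon atoms × |flux| under
a single normalized exchange convention (positive flux = export);
metabolites without a parseable formula are flagged carbon-unknown and
refused by C-flux computation rather than guessed at. Fold-change
comparison uses a 2-fold default threshold and an activity epsilon of
1e-6 for the switched-on/off classes, since a ratio is undefined at zero.
When the optimum is exactly zero ATP, the source split is undefined and
reported blank (not 0/0).

## The toy pair

The generator builds a 10-component regulatory network (hypoxia-like
input, HIF1-like master factor, glycolytic enzymes, an oxidative-branch
enzyme and its product metabolite, and a two-node negative-feedback
toggle that keeps two minimal trap spaces alive) paired with a
13-reaction metabolic model: glucose uptake capped at 10, a glycolytic
lump yielding 2 ATP and 2 pyruvate per glucose, a lactate exit, and an
oxidative branch yielding 36 ATP per glucose — the textbook 2-vs-36
stoichiometry, chosen integer so every optimum is rational. The expected
outcomes are closed-form LP results on the branch structure, computed in
the generator, never by the pipeline under test. The `variant` argument
selects the shipped condition (warburg = hypoxia ON, control = OFF) over
one shared topology; generation is fully deterministic, with the seed
recorded for interface parity with the random-network generator. Fixture
files are always written to standard SBML-qual/SBML and routed through the
real loaders so that I/O is exercised by every end-to-end test.

What the toy does *not* emulate: network size (hundreds of nodes),
realistic kinetics or flux magnitudes, multi-compartment transport chains,
or the noisy name conventions of curated models. Passing tests therefore
demonstrate correctness of the algorithms and plumbing, not biological
fidelity of any particular large model.

## Problem sizes and numerics

The test battery uses random Boolean networks of 6–10 components with
in-degree ≤ 3–4 (where the exhaustive oracle is exact and fast), and the
acceptance script uses 60 seven-node networks plus the toy pair; the LP
vertex-enumeration oracle is run on models up to 13 reactions.
Tolerances: mass balance 1e-6, zeroed fluxes 1e-9, LP-vs-oracle 1e-8,
percentage identities 1e-6.

## Known limitations

* Trap-space search is worst-case exponential; the budget makes failure
  explicit but very large, weakly-reduced networks may need a raised cap.
* Enzyme matching is by reaction-ID name, not gene–protein–reaction rules.
* Only strictly Boolean models are accepted; multi-valued logical models
  are refused at load.
* No flux variability, thermodynamic or loopless analysis; absolute flux
  values are not interpreted, only distributions and ratios.
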