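# Methods

## Qualitative model and scope

All analyses operate on the support lattice L = {supp v | v ∈ C} of the
steady-state flux cone C = {v | Sv = 0, v_Irr ≥ 0}.  The package answers
*qualitative* questions — which reactions can carry flux at all, and which
knockouts silence which reactions — not quantitative ones: no growth-rate
objective is optimized, no flux ratios are computed.  Consequently "fully
coupled" reactions (fixed flux ratio) are not distinguished from partially
coupled ones; the lattice cannot express ratios, and partial coupling is
the finest relation reported.

Cone semantics is the default for SBML input: finite flux bounds are used
only for orientation.  Lower bound ≥ 0 marks a reaction irreversible;
upper bound ≤ 0 marks it irreversible *backward*, in which case the column
is negated so the forward direction is the feasible one; magnitudes are
discarded because C has no finite bounds.  An opt-in `honor_bounds` mode
keeps the (orientation-adjusted) finite bounds in the LPs for users who
want the truncated cone; it changes blocked/coupling results only when a
bound is exactly zero on one side, since supports are invariant under
scaling.

## FindPath and numerical choices

Membership questions are decided by the LPs max{±v_t | Sv = 0, v_Irr ≥ 0,
v_K = 0} over a box −M ≤ v ≤ M (0 ≤ v ≤ M for irreversible reactions),
M = 1000 by default.  The box makes every LP bounded and numerically
well-behaved; supports are scale-invariant, so the support of a bounded
optimizer witnesses lattice membership just as an unbounded ray would.
Two tolerances are deliberately separated:

* decision tolerance 1e−6 — "does the target carry flux?"  A false
  negative here would wrongly mark a reaction blocked, the one error class
  that corrupts results, so it is kept far above solver noise.
* support-extraction tolerance 1e−9 — which entries of the optimizer count
  as active.  A spurious member merely adds a valid-but-larger lattice
  element to the witness pool and is harmless; a dropped member only costs
  an extra LP later.

Reversible targets are probed forward first, backward only if the forward
maximum is zero.  The backend is scipy's HiGHS interface, single-threaded
and deterministic, so witness supports, LP counts and all outputs are
reproducible run-to-run.  Solver failure raises, and is never conflated
with "no pathway exists".

## Maximal elements, witnesses, couplings

The maximal element 1_{L⊥K} is computed by bound refinement: an upper
bound ub (reactions not yet proven blocked; initialized to 1_L ∖ K when
1_L is known) and a lower bound lb (union of witness pathways disjoint
from K).  The smallest reaction in ub ∖ lb is queried through FindPath;
success merges the returned support into lb and stores it in the witness
pool, failure removes the target from ub.  Sorted-order target selection
makes iteration order, results and LP counts deterministic.  The witness
pool is FIFO-bounded at 10000 pathways (the cap is standard; the eviction
policy is our choice, as any policy preserves correctness — witnesses
affect cost only, never results, which the tests assert).

Coupling analysis discovers classes incrementally: the smallest unassigned
unblocked reaction r becomes a representative; every s missing from
1_{L⊥{r}} whose own single-knockout maximal element (memoized) also lacks
r is a classmate.  Representatives are therefore always the
lexicographically smallest class members.  Per-representative maximal
elements answer all directional-coupling queries; classmates share them
exactly, which the suite verifies by explicit recomputation.

The double-knockout simulation iterates over uncoupled representative
pairs only (pairs containing a coupling are redundant), computes
1_{L⊥{r,s}} with the shared pool, and reports targets via the
set-difference characterization (1_{L⊥{r}} ∩ 1_{L⊥{s}}) ∖ 1_{L⊥{r,s}}.
Empty-target records are kept, flagged, so joint-effect ratios are
computable from the emitted records alone.  Two variants exist for cost
comparison and cross-validation: iterating all uncoupled unblocked pairs
instead of representatives, and additionally running without witnesses;
both must (and do) reproduce the same class-mapped joint couplings.
Candidate sets for deeper knockouts are generated by the analogous filters
(no internal directional coupling at order 1, additionally no internal
joint coupling at order 2); exhaustive analyses of order ≥ 3 are left to
explicit `multi_knockout` calls on chosen sets, since the candidate count
grows combinatorially.

For a multiple knockout K, targets follow the generalized
characterization over the (|K|−1)-subsets; minimality over *all* proper
subsets is equivalent because plain blocking is monotone in K.  The
degenerate |K| = 1 call returns the single reaction's directional
couplings rather than erroring, keeping the recursion uniform; knocked-out
reactions are never reported as their own targets.

## Gene knockouts

The gene-to-reaction map evaluates each GPR boolean tree under "Γ off,
everything else on"; reactions without a rule are untouchable by gene
knockouts.  The grammar includes negation, so a reaction can be associated
to a single gene but not to a superset — for this reason double-gene
results are deliberately *not* filtered against single-gene results, and
the monotonicity property (Γ ⊆ Γ′ ⇒ coupled(Γ) ⊆ coupled(Γ′)) is tested
only for negation-free rule sets.  Gene classes analogous to reaction
classes do not exist; instead results are memoized on the induced
unblocked knockout set, which distinct gene sets frequently share.
Blocked associated reactions are dropped before the lattice call (they are
absent from every pathway already).  Rule evaluation walks the parsed tree
directly; rules are parsed once at load time, never re-parsed per query.

## Brute-force oracle

For networks of ≤ 12 reactions the full lattice is enumerated: a subset
belongs to L iff the maximal support achievable inside its sub-cone equals
it.  Subsets are visited by increasing size, so the union-closure law
certifies most candidates from already-confirmed elements without LPs;
the rest are decided by per-target feasibility calls.  Every coupling
notion is then derived by exhaustive iteration over lattice elements,
straight from the definitions — the only primitive shared with the
production path is the raw LP call, so agreement between the two routes is
a meaningful check.  The same machinery exposes `LatticeModel`, which runs
the production algorithms over an explicitly specified lattice; it serves
as the extension hook for alternative pathway semantics and lets abstract
qualitative models be analyzed without any stoichiometry.

## Synthetic networks and what the tests show

The random-network generator emulates the *shape* of metabolic
stoichiometry only: unit coefficients at a chosen density, a chosen
reversible fraction, plus single-metabolite exchange columns so flux can
cross the boundary.  It does not emulate biomass compositions, cofactor
coupling, compartments or realistic degree distributions — so passing the
cross-validation battery demonstrates algorithmic correctness on arbitrary
cone geometries (including fully blocked and degenerate ones), not
biological realism.  Realism is covered separately by the E. coli core
validation, where the pipeline reproduces the published coupling
statistics of that network (87 unblocked reactions, 55 classes, single
impact 1.96 classes / 3.58 reactions, conditional double impact 15.7 /
24.5, 12% joint-effect ratio, 6.92 / 132 knockout options).

The battery used in the tests holds 30 networks with ≤ 8 reactions and
≤ 6 metabolites, mixed reversibility (0–50%) and densities around 0.4–0.5
— sizes chosen so the 2^R oracle enumeration stays exact and the whole
suite runs in about a minute and a half on one CPU.

## Statistics conventions

Impact means are taken over representatives (single) and over candidate
pairs *with a joint effect* (double): the conditional reading is the one
consistent with published per-network tables — under the unconditional
reading the reported conditional mean of the core network would exceed its
total class count, which is impossible.  Single-knockout impact excludes
the knocked-out reaction's own class.  Knockout-option counts are
reaction-level and reflexive: every reaction whose knockout silences the
target counts, including the target itself and its classmates (this
reflexive convention is what reproduces the published per-target option
numbers exactly; the non-reflexive count is lower by exactly 1).
Biomass-blocker counts exclude the biomass's own class for single
knockouts and any pair containing a reaction directionally coupled to the
biomass for double knockouts, with class-to-reaction expansion by class
sizes.  A model may carry several biomass reactions; the function takes
the reaction id explicitly.

## Known limitations

* No quantitative (FBA) impact measure; candidate sets can feed one, but
  none is implemented.
* No thermodynamic loop-law or other refined pathway semantics beyond the
  `LatticeModel` hook.
* No minimal-cut-set computation; joint couplings answer a different
  question (synergy, not minimal blocking sets).
* SBML support covers stoichiometry, reversibility/bounds and gene
  associations only — no compartments, units or annotations.
* Exhaustive knockout enumeration beyond pairs is exponential; the package
  generates filtered candidates but does not run them by default.
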