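# Methods

## The model

A Flexible Net couples two tripartite graphs over a shared set of places
`P` (state variables holding tokens, `m`) and transitions `T` (processes
holding actions, produced at speed `λ`):

* the **event net** routes executed actions into token changes through
  *event handlers*: each handler `v_k` carries linear inequalities
  `A_k Δm_f ≤ B_k a_f` between the amounts it executes on its transition
  edges and the token changes on its place arcs;
* the **intensity net** routes *active* tokens into speed changes through
  *intensity handlers*: `C_l Δλ_w ≤ D_l μ_w` relates active tokens on the
  handler's place edges to intensity increases/decreases on its transition
  arcs.

Uncertainty enters only through linear inequalities: handler blocks (e.g.
`x ≤ b ≤ 2x` — one action produces between one and two tokens; `0.9a ≤ r ≤
1.1a` — a rate proportional to a marking within ±10%), an initial-marking
block `J_m m0 ≤ K_m`, and a default-intensity block `J_λ λ0 ≤ K_λ`.  Any
solution of the blocks is an admissible behaviour; no distributional
assumptions are made.

Cumulative bookkeeping gives the linear **state equations**

    σ = a_T + Y_σ a_E        A Δm ≤ B a_E        m = m0 + Z_m Δm
    m = μ_P + Y_m μ_E        C Δλ ≤ D μ_E        λ = λ0 + Z_λ Δλ

plus, for the timed net, `Δσ(τ) = ∫ Δλ` and `σ(τ) = λ0 τ + Z_λ Δσ(τ)`.
These are **necessary** conditions for reachability only: they track
cumulative amounts, not firing order, so they admit spurious solutions.
Nothing in the package claims sufficiency, and one test exhibits the
containment (graph-reachable sets ⊆ state-equation sets) as containment
only.

Conventions that matter for reproducing printed matrices:

* global matrices stack handler blocks diagonally; columns are ordered by
  handler declaration order, then label declaration order.  Equalities
  expand to (`≤`, `≥`) row pairs and chains split pairwise, in source
  order;
* an event handler with no transition edge gets an explicit fake
  transition (`<id>__fake`, default intensity 0, zero column in `B`), so
  silent token movements remain action-indexed; fake labels are excluded
  from the all-labels-equal omission convention;
* an intensity handler with no place edge gets a zero-width `D` block (no
  fake place is materialized — nothing downstream indexes it).

## Discrete semantics

Event handlers fire in discrete amounts when the net is analysed as a
partially observed discrete system.  Enabling asks for a witness
`(a_f, Δm_f)` with `a_f ≤ a_T`, `A_k Δm_f ≤ B_k a_f`, consumption bounded
by the marking, and strictly positive total change.  Choices:

* **unit firings** for graph generation: `a_f ∈ {0,1}` per edge with at
  least one 1; a transition-free handler fires with total consumption 1.
  Output amounts are enumerated over the integer solutions of the handler
  block inside LP-derived boxes (an unbounded box raises rather than
  truncating silently).  This keeps the branching finite and reproduces
  the marking graphs of the small examples;
* the strict `> 0` of enabling is replaced by `≥ 1e-9` in continuous mode
  (an LP cannot express strict inequalities); the continuous check
  maximizes the total change capped at 1 and compares against that margin,
  so solver feasibility tolerances cannot fake a zero witness;
* graph nodes are deduplicated on `(m, a_T)`; execution histories are not
  part of the node, matching marking-level reachability graphs;
* between observed events the marking set is closed under silent firings
  (handlers with no real transition edge), and each observation executes
  exactly one action of the observed transition.  Whether silent firings
  may interleave arbitrarily between observations is not constrained
  further — the closure is taken before the first and after every
  observation;
* `consistent_markings` enumerates all integer solutions of the event
  state equations with produced/leftover actions pinned, by depth-first
  branching with LP bound pruning (complete on bounded polytopes).  The
  graph route above is an independent second implementation used for
  cross-checks.

## Timed transcription

On a grid `0 = τ_0 < … < τ_n`, intensity changes `Δλ_k` are
piecewise-constant per interval.  That makes the action integral exact
(`Δσ_{k+1} = Δσ_k + Δλ_k (τ_{k+1} − τ_k)`), and the remaining coupling is
closed with the **interval-average marking** `m̄_k = (m_k + m_{k+1})/2`:
token allocation and intensity-handler rows are written at `m̄_k`.  For
linear rate laws the scheme is the implicit midpoint rule (second-order);
a test verifies one step against the hand-integrated trapezoidal update
and convergence to the matrix-exponential solution of the controlled
cycle (relative error 1.4e-3 at dt=0.1, ~4x smaller per halving).

The event side adds nonnegative per-interval increments with
`A δΔm_k ≤ B δa_E,k` plus cumulative boundary balances; because the
boundary balance `σ_{k+1} = a_T,k+1 + Y_σ a_E,k+1` holds with `a_T ≥ 0`,
actions produced within an interval may be executed within it — no
artificial one-step delay.  Forced-execution rows (`a_T = 0`) apply at
every boundary after the first, forced-activity rows (`μ_P = 0`) on every
interval.  Uncertain parameters (`λ0` inside its block, handler slack) are
decision variables resolved by the optimizer — the optimistic/control
reading; robust (adversarial) resolution is a non-goal.

Horizon-average markings in objectives are **length-weighted** averages of
the interval means (on the uniform grids used by the case studies both
readings coincide).

**A property that does *not* hold.**  One might expect that refining the
grid can only increase a maximized objective (coarse piecewise-constant
controls remain feasible).  Under midpoint coupling the opposite is true:
intensity rows evaluated at a coarse interval average are *looser* than at
fine averages, so refinement tightens the relaxation and maximized
objectives decrease monotonically toward the continuous value (the small
combined net gives 4.000 → 3.918 → … → 4(1−e⁻³) ≈ 3.801 for the final
marking of its sink).  The suite asserts this convergence rather than a
false monotonicity-under-nesting claim.

The single-instant state-equation system (`fn_polytope_at`) relaxes the
integral to `Δσ ≥ 0` free; no `Δσ ≤ τ·max Δλ` bound is added there, since
any such bound belongs to the interval-coupled transcription.

## MPC

The receding-horizon driver re-transcribes from the current `(m, a_T)`
over a short horizon, solves, applies the first interval, and rolls
forward; `λ0` and handler slack are re-resolved every step, which makes
the applied `λ0` trace the control signal.  Convergence is declared when
the applied marking moves less than `1e-4` (∞-norm) over 10 consecutive
steps — the underlying narrative reports "steady state" without a
criterion, so this one is the package's own; the reported fixed point is
the converged state regardless of step count, and idempotence (re-solving
from the fixed point returns it) is tested.

With a one-step horizon and a strictly convex target-tracking objective,
the fixed point is *not* the constrained optimum of the steady-state
problem; it is the state where the one-step-greedy control reproduces
itself.  For the controlled cycle (dt=0.1) this lands at equal steady
intensities ≈ 2.73 and applied control ≈ 0.805 — sensitive at the
percent level to the transcription rule, which is why the corresponding
checks carry ±0.05 tolerances.

## Numerical choices

* LPs: `scipy.optimize.linprog`, HiGHS backend, default tolerances
  (~1e-9 feasibility); deterministic, so repeated runs are byte-stable.
* Convex QPs (sum-of-squared-affine objectives): `trust-constr` with
  analytic gradient/Hessian, `gtol=1e-10`, `xtol=1e-12`, warm-started
  from the previous MPC step's solution (first step: an LP feasibility
  point).  Maximization of quadratics is rejected (nonconvex).
* Integer enumeration tolerance `1e-6` for rounding LP bounds to integer
  ranges; firing arithmetic is exact on integers.
* Degenerate inputs: empty variable systems solve trivially; unbounded
  enumeration boxes and non-increasing grids raise; infeasible
  observations return the empty set (not an error); an infeasible MPC
  step aborts with the step index.
* Alternative optima: LP vertices are solver-deterministic but not
  canonical; time-valued readouts (switch/depletion times) therefore
  carry one-grid-step tolerances in the checks.

## Example nets and what the tests show

All analyses run on the printed example nets, regenerated by
`flexnets.fixtures` (a two-reaction chemistry with uncertain
stoichiometry, the basic event net, a partially observable event net, four
small intensity nets, an uncertain linear system, a resource-allocation
system, and a controlled cycle).  These are *desk-scale* nets — a handful
of vertices, interval uncertainties, known invariants — chosen because
their behaviour is verifiable by hand or closed form.  Passing tests show
the formalism's bookkeeping, transcription accuracy and optimizer
plumbing are right; they do not exercise large or stiff networks,
noise-driven data, or model misspecification, and say nothing about
identifiability of real kinetic parameters.

Known limitations: no robust resolution of uncertainty; no integrality in
transcriptions (discrete analysis lives in the event-net semantics); no
sufficiency/realizability check on transcribed trajectories; the
one-reaction-per-handler fixtures do not test handlers spanning many
transitions with heterogeneous blocks under MPC.

One printed inconsistency is preserved as such: the chemistry example
states an initial-concentration interval whose bounds are inverted
("[9.9, 1.1]"); the fixture defaults to the evident correction [0.9, 1.1]
and offers the literal reading behind a flag.
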