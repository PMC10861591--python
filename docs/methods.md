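# Methods

## Model

A biochemical network is a J × Ī integer stoichiometry number matrix S:
rows are reactants/products, columns are reaction vectors r_i ∈ ℤ^J with
negative entries for consumed and positive entries for produced species.
A weighting v ∈ ℝ^Ī of the reactions with S·v = 0 balances every species
— the network at steady state. The algorithm's premise is that the set of
such weightings, enriched by combinatorial sums, carries enough
information to assign every reaction a dominant direction and a positive
scalar (the probable dissociation constant η) playing the role of an
empirical Kd.

The membership contract is implemented as S·v = 0 with v ∈ ℝ^Ī (a
reaction weighting balancing every reactant); the transposed form is
dimensionally inconsistent for a J × Ī matrix.

### Validity requirements

A network is processed only if, after removing duplicate reaction
columns: J ≥ 4, Ī ≥ 6, Ī − J ≥ 2, no reaction column is the zero vector,
and the nullity Ī − rank(S) is at least 1. The J and Ī bounds come from
requiring the partition count Θ̄(J) = Σ_{t=2}^{J−2} C(J, t) to be defined
(smallest J = 4) and Ī ≥ Θ̄(4) = 6. Only *duplicate* columns are removed,
not all linearly dependent ones: removing every dependence would force
full column rank and a trivial null space, destroying the algorithm's own
premise.

## Subspace generation

- **u = 0.** An orthonormal basis of N(S) from an SVD
  (`scipy.linalg.null_space`), sign-canonicalised: each basis vector is
  flipped so its largest-magnitude component (ties: lowest index) is
  positive. This makes runs reproducible, but the basis of the fully
  degenerate singular subspace is otherwise arbitrary — exact η values
  are therefore a property of (matrix, basis convention), while the
  forward/reverse/equivalent labels are the robust comparison surface.
  Permuting reaction columns permutes the labels with their ids; η values
  may shift because the SVD is free to rotate the permuted basis.
- **Iteration u.** All subset sums (sizes 2 … K) of the current K vectors
  are enumerated in lexicographic order and unioned with the u = 0 basis;
  the candidate count is exactly Σ_{q=2}^{K} C(K, q).
- **Screening.** Candidates with infinity norm ≤ `tol_zero` (default
  1e−9) are dropped and counted; the rest are quantised onto a `tol_dup`
  grid (default 1e−9) of their sign-canonical form, and each cell keeps
  its first member *in its as-generated orientation*. Canonicalising the
  keys only — not the stored vectors — matters: storing canon forms lets
  a nullity-2 pool close on the fixed point {v₁, v₂, −(v₁+v₂)} and stop
  growing. Θ counts the collapsed identical groups per iteration.

### Resolution criterion

Iteration stops advancing the "resolved" flag of row i once its extremes
have left the unit interval: max(row) > 1 (positive divergence),
min(row) < −1 (negative divergence), or both (a mixed-sign alternating
sequence). Requiring *every* term beyond unit magnitude is impossible by
construction: the u = 0 basis is unioned into every iteration, so every
row permanently retains its small basis coordinates and structural zeros
(in the toy network, row A has minimum exactly 0 at every iteration while
its maximum grows without bound). M is the first iteration at which all
rows are resolved; annotation is attempted at u = M and at every
subsequent iteration until binning is unambiguous for all reactions.

As a diagnostic, for a resolved row with sum φ the quantities
1 + e^{min(row) − φ} and 1 + e^{φ − max(row)} both approach 1 as |φ|
grows (exponents clamped at ±700 to avoid overflow).

## Binning, mapping, classification

For row i with mean μ and *population* standard deviation σ (denominator
K, not K−1):

- 𝓕 = {a : a > μ + 2σ, a > 0}, 𝓑 = {a : a < 0, |a| > |μ + 2σ|}.
- **Equivalent** when both are non-empty, |#𝓕 − #𝓑| ≤ max(1,
  ⌈0.1(#𝓕+#𝓑)⌉) (configurable `balance_tol`), and |φ_𝓕 + φ_𝓑| ≤
  `eps_equiv`·(|φ_𝓕| + |φ_𝓑|) with `eps_equiv` = 0.05. 𝓔 is the
  alternating merge of 𝓑 and 𝓕 and φ_𝓔 = φ_𝓕 + φ_𝓑.
- Otherwise **forward** if φ_𝓕 + φ_𝓑 > 0, **reverse** if < 0.
- 𝓕 ∪ 𝓑 empty (e.g. σ = 0) is **ambiguous** and triggers further
  iterations.

Exactly one case populates the outcome vector (y_𝓕, y_𝓑, y_𝓔): summing
all three whenever all subsets were non-empty would add y_𝓔 ≈ 1 to every
reverse η and contradict the classification rule. The reverse map
y_𝓑 = e^{φ_𝓑} ignores φ_𝓕 by design; the asymmetry with the forward map
(which adds e^{φ_𝓑}) is deliberate and kept. η = y_𝓕 + y_𝓑 + y_𝓔;
labels: equivalent within `eps_one` = 0.05 of 1, else forward (η > 1) or
reverse. Map exponents are clamped at ±700 so η stays inside (0, ∞) in
floating point even for strongly diverging sums.

## Caps and complexity

Per-iteration work is O(2^K). Guards:

- `max_subset_size` (default unbounded) limits q per iteration;
- `max_subspace` (default 500 000) caps the per-iteration candidate
  count: the engine uses the largest q whose cumulative binomial sum
  fits. The default admits the ≈4×10⁵-candidate pairwise step that the
  bundled 17×20 network's two weakest-supported rows (the citrate
  transport and lyase columns) need before resolving; with the cap an
  annotation run on the bundled networks takes ≈1–2 s.
- `max_iterations` (default 25).

When even pairwise sums do not fit, or iterations are exhausted, an
`IncompleteAnnotationError` carries the partial state — the enumeration
is genuinely intractable for large or weakly coupled networks, and about
half of the small random networks from the bundled generator end this
way under default caps.

## Kinetics scaffolding

`rate_law_eval` returns the rate constant λ = R / Π[A_j]^{l_j} and order
ψ = Σ l_j. `classify_kd` adds the fourth, non-productive outcome
(Kd ≤ `eps_zero`, default 1e−6) that the η pipeline never emits — its
maps target (0, ∞). `compare_reactions` ranks rates within one outcome
class only (forward: larger Kd faster; reverse: smaller Kd faster;
equivalent: tied). `mass_action_kd` evaluates Π reactants / Π products
with real exponents; the printed convention puts reactants in the
numerator (the common biochemical convention is the inverse and is
available via a flag).

## Fractional extension

The Caputo power rule D^α x^β = Γ(β+1)/Γ(β−α+1) x^{β−α} (α ∈ (β−1, β))
supplies per-species weights ω_j = sign(m_j)·Γ(β+1)/Γ(β−α+1)·|m_j|^{β−α}
for a reaction vector — the signed-magnitude convention keeps fractional
powers of negative stoichiometry numbers real while preserving polarity —
and an element-wise gradient step r′ = r − γ·D^α(r^β) with learning rate
γ ∈ (0, 1). `kd_from_weights` feeds |ω| into the mass-action ratio,
partitioned by sign (negative → reactant side). This module is a
standalone extension; the weights do not feed back into the η pipeline.

## Bundled networks and the synthetic generator

- **Toy cycle:** species A–D, reactions A→B, B→C, C→D, D→A, A→C, B→D as
  signed unit columns; rank 3, nullity 3; the minimal valid instance.
- **Aerobic glycolysis (synthetic reconstruction):** the 17 × 20 matrix
  in `data/ag_synthetic.csv` rebuilds the pathway topology — glucose →
  glucose-6-P, the lumped oxidative
  and non-oxidative hexose monophosphate shunt, lower glycolysis, lactate
  dehydrogenase, the pyruvate/citrate/mitochondrial-PEP transports,
  pyruvate dehydrogenase and carboxylase, the lumped TCA span, PEPCK, the
  oxaloacetate–malate shuttle and the lumped Cori cycle, with _m/_c
  compartment suffixes. The lumped integer coefficients are this
  package's own choices (carbon is deliberately not conserved where a
  lumped step sheds CO₂ or acetyl groups, which keeps the matrix full row
  rank, nullity 3, with every reaction supported in the null space).
  Results on this fixture characterise the reconstruction, not any
  curated reference model of the pathway.
- **Generator:** seeded sparse integer matrices with per-column density
  0.3 (≥ 2 non-zeros), coefficients in ±3, every column consuming and
  producing at least one species (a flag disables the mixed-sign
  guarantee), no duplicate or zero columns; specs that cannot validate
  (J < 4, Ī < max(6, J+2)) are refused. Generated matrices always
  validate; they emulate the *shape* constraints of curated networks, not
  their biochemical structure (no conservation moieties, no transport
  chains), so passing property tests on them demonstrates the engine's
  contracts (closure, cardinality growth, screening correctness), not
  biological fidelity.

## Numerical choices

Tolerances `tol_zero` = `tol_dup` = 1e−9 (infinity norm; the source
material specifies none); duplicate grouping is grid-quantised, with an
O(n²) pairwise scan as the test oracle on small pools; ties in the sign
canon break to the lowest index; all enumeration orders are
deterministic, so identical input and config give byte-identical output.

## Known limitations

Exponential enumeration bounds practical nullity to single digits;
η values are basis-convention dependent (labels are not, in all observed
runs); the equivalent label is rare on the bundled fixtures because the
cancellation test at `eps_equiv` = 0.05 is strict; the steady-state
premise itself is an assumption of the method.
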