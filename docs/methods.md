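# Methods

## Model and assumptions

The pathway is modelled as a closed, linear, mass-action system over three
states of a single damaged locus — substrate S, intermediate I, product P —
with five rate constants: `k1` (S→I), `k−1` (I→S), `k2` (I→P), `k−2`
(P→I) and `k3` (S→P, the compensatory route). Written as `dx/dt = Q x`
with columns of the generator `Q` indexed by source state, this is a
continuous-time Markov chain; because the system is linear and closed,
normalised concentrations and single-locus state probabilities are the
same object, and we work with probabilities throughout. Time units are
arbitrary: uniformly rescaling all five rates rescales time and leaves
every long-time distribution unchanged (a tested invariant).

Assumptions worth making explicit: enzymes act far from saturation (rates
are genotype constants, not functions of state); the toxic consequence of
I is modelled only through its occupancy, not through an explicit death
process; and the final, irreversible locking-in of the repaired product
that a fuller pathway description would include is deliberately omitted to
keep the three-state system minimal. That omission matters in exactly one
place (suppressor epistasis, below).

## Long-time limits and why not just a stationary solve

Knockouts set a rate to zero and can disconnect the chain, creating
absorbing states — the kinetic traps that produce death fates. A reducible
chain has no unique stationary distribution, so "steady state" is defined
as the exact t → ∞ limit from freshly damaged DNA (S = 1). It is computed
as the spectral projection of the initial vector onto the null space of
`Q`: `x∞ = V (WᵀV)⁻¹ Wᵀ x0`, with V and W orthonormal bases of the right
and left null spaces. The zero eigenvalue of a CTMC generator is
semisimple and all other eigenvalues have negative real part, so this
projection is the limit for every rate set, reducible or not; `Q` is first
divided by its largest rate so the solve is well-conditioned regardless of
units. A residual bound of 1e−10 on `‖Q x∞‖` guards the solve. The test
suite checks this route against two independent ones — the Markov-chain
tree theorem (spanning in-tree weights enumerated by hand for the 5-edge
graph) and matrix-exponential integration to t = 1e5 over the smallest
positive rate — at 1e−8 on 100 random rate sets.

Time courses use `expm(Q t)` directly (exact for a linear system).
Repair time is the first t with p(t) ≥ threshold, found by geometric
bracketing (growth factor 1.5 from t = 1/max rate) plus Brent's method;
it is ∞ when the limiting repaired probability is below the threshold.

## Fate classification

From the limit `d` (start S = 1), with strict thresholds at 0.5: repaired
when `d.p > 0.5` — labelled COMPENSATED when the first passage into P uses
the direct S→P edge with probability > ½, REPAIRED_MAIN otherwise; DD when
`d.s > 0.5`; DT when `d.i > 0.5`; DEAD_MIXED otherwise. The first-passage
route probability has the closed form `q = a/(1 − bc)` with
`a = k3/(k1+k3)`, `b = k1/(k1+k3)`, `c = k−1/(k2+k−1)` (first-step
analysis; `k−2` cannot matter because the walk stops at its first entry
into P). DEAD_MIXED is an honest extra label: the absolute >50% death
rules and the relative phase-diagram colouring disagree on boundary cases,
and conflating them would hide that.

The phase-diagram colour rule is kept separate and relative: RED when
`p > 0.5`, else GREEN when `i > s`, else BLUE.

Control parameters are defined as `r1 = k1/k−1`, `r2 = k2/k−2`,
`rb = k−1/k−2`. These are the forward/backward ratio of each step plus the
backward/backward ratio; they are consistent with the degenerate sweeps
(the `k−1 = 0` slice varies only `r2`; the `k1 = 0` slice needs a
replacement first axis, for which we use `k3/k−1` — a reconstruction,
flagged in exported metadata). Ratios with a zero denominator and positive
numerator are +∞; 0/0 is reported as undefined rather than raised, since a
genotype with both rates of a step deleted is still classifiable.

## Reference baselines and the scenario catalogue

Two reference parameterizations anchor all genotype scenarios, both in the
normal regime where each forward step outruns its own back-reaction:

* NR (Normal Robust): `k1=1, k−1=0.1, k2=1, k−2=0.001, k3=0.1` (rb = 100);
* NF (Normal Fragile): `k1=1, k−1=0.1, k2=1, k−2=0.1, k3=0.1` (rb = 1).

These values are this package's own choice, fixed analytically before any
simulation: NR survives all five single knockouts (worst case P^s = 0.893
under F2 deletion) while NF fails exactly the F2 knockout
(P^s = 0.077, I^s = 0.846), and the NR/NF distinction is carried entirely
by rb, which the classification tests confirm switches the label at a
single crossing along a `k−2` sweep.

The catalogue's default overexpression factor is 20. At factor 10 the two
R2-overexpression genotypes on NF sit in the mixed boundary zone
(I^s ≈ 0.48); factor 20 puts them clearly past the 50% bound
(I^s = 0.627 and 0.625) without changing any other scenario's label. The
F2-knockout-rescued-by-R1-overexpression scenario lives on the NR
baseline: on NF the rescued repaired fraction is `k−1/(2k−1 + 1.1)`, which
approaches ½ from below and can never clear the bound. The
R2-overexpression-rescued-by-F1-deletion scenario is marked
parameter-sensitive (P^s = 0.216 at reference rates — a partial rescue)
and is reported, never asserted.

### Suppressor epistasis and the futile-cycle caveat

The trap genotype (R1 and F2 deleted) is lethal by toxicity; biologically,
additionally preventing pathway entry (F1 deletion) suppresses the
lethality because damage is bypassed to the compensatory route. In the
three-state model this suppression is visible in the routing — with F1
gone, every first passage into P goes through the compensatory edge
(probability exactly 1) — but the strict t → ∞ state is still all-I,
because the retained P→I back-reaction slowly leaks the product into the
absorbing trap. That futile cycle is precisely what the omitted
irreversible final step would shut off. The package therefore tests the
suppression as: routing probability 1 for the triple knockout, and fate
COMPENSATED when the second step's back-reaction is absent (`k−2 = 0`).
The eventual-trapping behaviour of the minimal model is itself asserted,
not hidden.

## Phase diagrams

Default grids are 41 log-spaced points per axis over [1e−2, 1e2], with
regimes selected by rb ∈ {0.1, 1, 100} realized through anchors
`k−1 = 0.1`, `k−2 = k−1/rb`, `k3 = 0.1`. Every cell inverts the ratio map
(`k1 = r1 k−1`, `k2 = r2 k−2`), takes the exact limit from S = 1 and
applies the colour rule; diagrams are deterministic and invariant to
uniform rate rescaling. Tested structural properties: once a fixed-r1 row
turns RED along increasing r2 it stays RED; fast forward steps with rb ≥ 1
give RED; a stalled second step with fast entry gives GREEN.

## The enrichment statistic

Negative interactions are records with `ε < εmax` and `p < pmax`;
defaults `εmax = −0.12`, `pmax = 0.05` (the conventional stringent cutoff
for genome-wide yeast screens), both configurable. Pairs are unordered;
duplicates collapse to the most negative measurement. Per pathway of size
S, the statistic counts negative pairs with both genes in the pathway,
subtracts those co-occurring in at least one molecular complex, and
divides by `S(S−1)/2`. Ranking is by proportion descending with ties
broken by size then identifier; a ≥1% display filter is applied by
default. A pair belonging to several pathways contributes to each
pathway's count but only once to the global within-complex fraction.
Identifier matching is exact and case-sensitive.

## The synthetic screen generator

The generator emulates the statistical skeleton of a stringently filtered
genome-wide screen: 250 genes; disjoint pathways of sizes (20, 15, 12,
10); the first pathway planted with per-pair negative probability
27/190 ≈ 0.142 — chosen so a 20-gene pathway expects ~27 negative pairs,
the scale of the top-ranked DNA-repair pathway in real yeast data — decoys
at the 1% background; and a 4-gene complex nested in the planted pathway
whose pairs are negative at 50%. Negative pairs draw ε uniformly from
[−0.6, −0.15] and p from [0, 0.01] (strictly inside the default filter);
5% of the remaining pairs are emitted with mild ε in [−0.08, 0.08] and
uniform p to exercise filtering. All draws flow from one seed through a
fixed SeedSequence, so outputs are byte-identical across runs.

What the generator does **not** emulate: colony-size measurement noise,
correlated errors across arrays, overlapping pathway membership, gene
aliasing, or essential-gene censoring. Passing tests therefore demonstrate
that the statistic recovers planted enrichment under idealised
independence, not that it is robust to real screens' artefacts.
`expected_proportions` gives the closed-form expectation
`rate · (T − E)/T` (T total pairs, E complex pairs), and a 100-seed
consistency test holds the mean observed proportion within three standard
errors of it.

## Numerical choices and degenerate inputs

Probability vectors must conserve mass to 1e−9 and are clipped only within
that tolerance; the steady-state residual bound is 1e−10; repair-time
root-finding uses relative tolerance better than 1e−6. Rate sets must be
finite, nonnegative, and not all zero. A genotype whose product state is
unreachable raises a routing error rather than returning 0; statistics
with empty denominators (singleton pathways, no within-pathway negatives)
raise rather than return a silent 0.

## Problem sizes

Test and acceptance runs use the sizes above by design: 3-state analytic
solves are microseconds, so the oracle-equivalence suite uses 100 random
rate sets, phase-diagram tests use 5–13 point grids (the default 41-point
grid is for interactive use), and the screen-statistic suites use 100
seeded replicates of the 250-gene screen.

## Known limitations

Linear (unsaturated) kinetics only; no stochastic simulation; no explicit
cell-death dynamics; the minimal model's missing irreversible final step
makes the long-run fate of futile-cycle genotypes pessimistic (see the
suppressor note); the enrichment stage ingests real screen/gene-set files
but ships no curated biological data.
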