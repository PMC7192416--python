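# Methods

## Model and anchoring

A pathway is a Generalized Mass Action (GMA) system: dependent species
`x_d` evolve as `dx_d/dt = N v(x_d, x_i)` with power-law rates
`v_i = γ_i ∏_j x_j^{f_ij}` over both dependent and independent species.
Kinetic orders `f_ij` are real numbers (log-log slopes of the rate law);
independent species are held constant.  Rate constants are never sampled:
they are *anchored* so that a given reference flux `v0` and concentration
profile (`x_d0`, `x_i0`) is exactly a steady state,
`γ_i = v0_i / ∏_j x_j0^{f_ij}`.  The anchoring round-trip is exact to
machine precision and is enforced by property tests.

The analytic Jacobian at any positive state is
`J = N diag(v) F_d diag(1/x_d)` with `F_d` the dependent block of the
kinetic-order matrix.  Steady-state responses in log space follow from
`A = N diag(v0) F_d`:

    S_x = -A⁻¹ N diag(v0)          (to rate constants)
    L_x = -A⁻¹ N diag(v0) F_i      (to independent variables)
    S_v = F_d S_x + I,  L_v = F_d L_x + F_i

These depend only on the kinetic orders and the flux *ratios* — not on the
anchoring concentrations — which is what makes the independent screening of
the k-subspace sound.  Designs with singular `A` (relative determinant below
1e-10) are structurally degenerate; they are dropped and counted.  The
algebra is verified against a finite-difference steady-state re-solve
(`scipy.optimize.root` in log concentrations) on batches of random designs.

Moiety conservations are not supported: no dummy-variable mechanism is
implemented, so models must have no conserved cycles among dependent
species.  Saturable (Michaelis–Menten/Hill) kinetics and SBML exchange are
out of scope.

## Case study and the synthetic generator

The built-in benchmark is the three-step unbranched chain with end-product
inhibition: `x0 → x1 → x2 → x3 →` (demand), feedback order `f_{1,3}` of the
product on the first step.  The generator's defaults *are* the study
conditions, and they are not tuning knobs:

| quantity | default | rationale |
| --- | --- | --- |
| reference flux | 31.5 mM/min on all reactions | plausible biosynthetic flux for a bacterium doubling in ~20 min |
| concentrations | i.i.d. uniform 0.1 µM – 10 mM (linear scale) | realistic cytosolic range |
| forward orders | uniform [0, 1] | basic enzyme far from saturation |
| backward orders | uniform [−1, 0] | product sensitivity of a reversible step |
| feedback `f_{1,3}` | uniform [−7, 0] | magnitudes beyond ~2 emulate longer pathways |
| demand order `f_{4,4}` | fixed 1 | demand enters as a linear term |
| equilibrium constants | 1 (per-reaction overridable) | neutral thermodynamic background |
| precursor `x0` | 10 mM (the upper sampling bound) | makes the feasible region the full ordering simplex; configurable |

The generator emulates the sampling design of the study, not real data: it
has no measurement noise, no correlation between kinetic orders, no enzyme
saturation beyond what a constant kinetic order expresses, and no moiety
constraints.  Passing tests therefore demonstrate the correctness and the
internal consistency of the screening machinery under these idealized
conditions, not the biology of any particular organism.

The naming of the sampled entries follows the 1-based convention
`f_{reaction, species-subscript}` with subscripts taken from the declared
species order (`x0 … x4`); the backward order of the third reaction is
`f_{3,3}` and the precursor order of the first reaction is `f_{1,0}`.

## Thermodynamic feasibility

For a reaction carrying flux in its declared direction the distance to
equilibrium is `θ = (product/substrate)/K_eq`, and feasibility requires
`θ < 1`: the mass-action ratio must stay *below* the equilibrium constant.
A numerical guard keeps the downstream cost finite: samples must satisfy
`θ < 1 − 1e-6`, and θ is additionally capped at `1 − 1e-9` before the
`Σ 1/(1−θ)` cost is evaluated.  The irreversible demand step carries no
`K_eq`; it is excluded from θ and would only add the constant 1 to the cost,
so the cost sums over the reversible reactions only.  With all `K_eq = 1`
and the precursor at the upper bound, feasibility reduces to the ordering
`x0 > x1 > x2 > x3`, an exchangeable event of probability `1/3! = 1/6` that
serves as an exact oracle for the filter.

## Criteria

x-criteria (all minimized): total concentration `Σ x_i`; draft
`(Σ intermediates)/end-product`, one value per linear segment (segments are
the connected components of the dependent-metabolite adjacency graph after
removing species with connectivity > 2, ordered along the flux direction);
thermodynamic cost; transition time `Σ x_i / v0`.  Transition time is
proportional to the total here (single flux) and is reported but not used
for front construction.

k-criteria: `APS = Σ_i Σ_j |S(x_i, γ_j)|` over intermediates and the
pathway-proper reactions (the sink step excluded); `ISD = |Σ_i L(x_i, x4)|`
and `ISS = |Σ_i L(x_i, x0)|` over intermediates — the absolute value is
deliberate, because the raw sums are signed (a demand surge *depletes*
intermediates) and robustness means small magnitude; `PDG = L(x3, x4)` is
kept signed and maximized (values near zero mean the product barely drops
when demand rises); `FDG = L(v4, x4)`, `PSG = L(x3, x0)`,
`FSG = L(v4, x0)` maximized.  Without end-product feedback the steady flux
is pinned by the upstream irreversible step, so ISD and FDG are exactly
zero — the feedback loop is what buys demand responsiveness.

## Selection

*Pareto front*: all criteria are converted internally to minimization; the
exact non-dominated set equals an O(n²) dominance oracle by construction
(tested).  Exact duplicates keep their first occurrence, the rest are
flagged.  *ε-front*: each criterion is min-max normalized to [0, 1] over the
current table, and a design is ε-dominated if another is better by more
than ε in every criterion; ε = 0 recovers the exact front, ε = 1 retains
everything.  The published analysis states no ε values, so defaults are
configuration.  *Behavioral classes*: per-criterion percentile cutoffs,
inclusive ("at or better"), computed on the full table so masks are
order-independent.  The robust class is the top 50% for {APS, ISS, ISD};
the demand class adds {PDG, FDG}; the supply class is the top 50% for
{APS, ISD, PSG, FSG} with only the worst 3% of ISS removed (a full median
split on ISS would eliminate the supply-responsive designs themselves).
*Enrichment*: new candidates are convex combinations `λ d_a + (1−λ) d_b` of
a random front member and its nearest neighbor in normalized criterion
space (one neighbor per member), re-evaluated through the criteria module
and kept only if ε-efficient against the combined set; retained points are
flagged synthetic.  *Composite axis*: for a two-criterion front, a total
least squares line is fitted to the front in the orientation-aligned plane;
the axis weights are its unit normal, signed so the utopian corner scores
highest.  This turns, e.g., the FDG–PDG tradeoff into a single "demand
performance" score that ranks the front's extreme edge (negligible flux
gains, drastic product losses) below balanced designs.

## Back-mapping

Per-criterion logistic classifiers (scikit-learn, L2 penalty at default
strength C = 1) are trained to recognize the top-50% performers
(orientation-aware) from z-scored kinetic orders; the reported normal has
unit Euclidean norm so coefficient magnitudes are comparable across
parameters.  Criterion and parameter coefficient profiles are clustered by
average-linkage hierarchical clustering on Euclidean distances
(`scipy.cluster.hierarchy`).  PCA of front designs is centered but not
variance-scaled (kinetic orders share a natural scale).  Segment-wise
synthesis orders the front by PC1, splits it with an exhaustive two-piece
least-squares scan (manual segmentation supported), regresses every other
PC on PC1 per segment, and holds PCs with R² < 0.5 (configurable) at the
segment mean; synthesized designs run PC1 over a grid, follow the fitted
relations, are clipped to the sampling intervals and re-evaluated.  The
printed PC relation coefficients of any particular run depend on the random
sample; the structure (which PCs vary, their signs) is what is reproducible.

## Stability and dynamics

A recombined model is stable iff every Jacobian eigenvalue at the anchored
reference has real part < −1e-9; marginal cases count as unstable
(conservative screening).  The screen evaluates `N diag(v0) F_d` once per
k-vector and rescales columns per x-profile, batching the small
eigenproblems in chunks of ≤200k so multi-million-model products never
materialize.  Step-response simulations integrate the full nonlinear ODE
(LSODA, rtol 1e-8) in minutes; the demand variable is multiplied by the
step factor at t = 1 and integration stops at `‖dx/dt‖∞ < 1e-8` or the
horizon.  Reported traces are normalized to the reference state.  For
perturbation factors → 1 the simulated steady-state log-response converges
to the analytic log-gain (first-order agreement, tested at 1%).

## Problem sizes and observations

The default analysis uses 10,000 feasible concentration profiles and
10,000 kinetic-order vectors; the acceptance script averages the front size
over 20 replicate samples (the count is stochastic with a spread of roughly
±10%, so replicate averaging measures its mean) and screens the full
recombined demand ensemble (~10⁵ models).  Two findings worth noting:

* the concentration-profile front of 10,000 feasible samples has a mean
  size of ~148 (spread ~125–170 across seeds);
* the demand-driven class concentrates strong feedback
  (`f_{1,3}` median near −5), and its recombined ensemble shows an unstable
  fraction of ~2–3%, an order of magnitude above the supply-driven
  ensemble's (~0.1–0.3%).  Instability rises steeply with feedback
  intensity, and flagged models genuinely diverge under integration, so
  class selection *enriches* instability rather than diluting it — the
  stability screen after recombination is not a formality.

## Known limitations

Flux-ensemble generation (FBA or thermodynamic flux sampling) is upstream
of this package; the v-ensemble accepts externally supplied distributions
and checks conservation only.  Sensitivity independence from concentrations
holds only far from equilibrium; reactions operating close to equilibrium
would need pathway shortening, which is not implemented.  Classifiers are
linear by design — interaction terms and nonlinear methods would classify
better at the cost of interpretability.  Hypervolume indicators,
bifurcation analysis and limit-cycle characterization are out of scope.
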