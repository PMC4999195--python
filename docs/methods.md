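# Methods

This note documents the model, its parameterization, the numerical choices,
and the limits of what the packaged defaults can show.  It states nothing
that the test suite or `scripts/acceptance.py` does not itself compute.

## Compartmental tumor microenvironment

Oxygen decays exponentially with distance from the nearest vessel at rate
0.0385 per distance unit.  The tumor is discretized into K = 32
compartments at partial pressures 2.5·i mmHg (i = 1..32); percent O2 uses
the 760 mmHg atmospheric reference, giving 0.33% for the deepest and 10.5%
for the best-oxygenated compartment.  The distance origin is anchored at
the 80 mmHg compartment (distance 0); other distances follow by inverting
the decay law, so the deepest compartment sits at ln(32)/0.0385 ≈ 90
distance units.  Compartments evolve independently — there is no migration,
no re-oxygenation, and no spatial PDE.

Compartment weights come from a histogram of pO2 relative frequencies.
Because no measured histogram is packaged, a synthetic generator stands in:
frequencies ∝ exp(−pO2/scale) on the 2.5·i grid, with optional seeded
log-normal jitter.  The default scale of 12 mmHg puts ~57% of tumor volume
at pO2 ≤ 10 mmHg and the weight median near 8 mmHg, matching the
hypoxia-dominated character of published oxygen-electrode surveys of solid
tumors.  (A scale of 15 mmHg, an alternative sometimes quoted for such
fits, puts the hypoxic mass just *below* one half; 12 was chosen once so
that the documented "majority hypoxic" property holds, and is not revisited.)
Every quantitative endpoint downstream of the weights is sensitive to this
choice.

The initial M = 1.6·10⁶ sensitive cells are split across compartments by
largest-remainder rounding of M·wᵢ (ties to the lowest index): the counts
are integers summing exactly to M and the allocation is deterministic.

## Pharmacokinetics

Erlotinib: plasma concentration (7·D₁ + 365)·e^(−0.0307t) ng/mL after a
D₁ mg dose; arbitrary dose histories superpose linearly (fixed-period
dosing is the special case used for steady-state arithmetic, which has a
geometric-series closed form).  Tissue concentration attenuates as
e^(−0.0173·d) with distance d.  Conversion to molarity uses erlotinib's
molar mass 393.44 g/mol (1 ng/mL = 1/393.44 μM); this value reproduces the
2.357 μM steady-state peak of the 25 mg × 3 days/week pattern to three
decimals, which pins down the unit convention.

Evofosfamide: after a D₂ mg/m² dose the concentration ramps linearly to
cmax(D₂) over half an hour, then decays at rate k(D₂); both cmax and k are
cubic fits over the trial dose range [7.5, 940] mg/m².  The fits are only
physical (positive) above ~85 mg/m²; the package raises for doses where
either cubic is non-positive rather than producing negative concentrations.
Because the half-life is < 1 h, only the most recent dose contributes when
doses are ≥ 6 h apart; a full-superposition mode exists purely to test that
approximation (residual < 10⁻⁴ of cmax at 6 h).

## Rates and the default calibration

Erlotinib is modeled as purely cytostatic: it multiplies the birth rate by
1 − I·C^h/(C^h + EC50^h) and leaves death at its control value.
Evofosfamide is purely cytotoxic: birth stays at the control rate and death
becomes μᶜ − ½·ln v(C₂) with viability v.  During a combination cycle,
births always track the (residual) erlotinib concentration while deaths
switch to the evofosfamide response from each evofosfamide dose until the
next erlotinib dose — the two-phase structure of the per-cycle rate
definition, generalized to arbitrary dose lists.  The printed two-phase
form assigns the sensitive control birth rate to resistant cells during the
evofosfamide phase; since both genotypes are assumed to respond identically
to evofosfamide, the package uses each genotype's own control birth rate
and offers a `literal_eq9` flag to reproduce the printed form.

The original live/dead-count regression fits behind the rate functions are
not published, so the package ships a parametric stand-in whose
coefficients are smooth functions of compartment oxygen o (percent), with
every constraint below enforced by `validate_calibration` at load time:

| quantity | form | default |
|---|---|---|
| control death μᶜ | constant | 0.01 /h |
| control net growth | 0.018 + 0.010·o/(o+2) | 0.019–0.026 /h |
| sensitive max inhibition | 0.70 + 0.25·o/(o+1) | 0.76–0.93 |
| sensitive EC50 | 0.06·(1 + 0.5/(o+0.5)) μM | 0.06–0.10 μM |
| resistant max inhibition | 0.5·(o−o₁)/(o₃₂−o₁) | 0 → 0.5 |
| resistant EC50 / Hill | 1.0 μM, h = 2 | |
| viability | exp(−A(o)·C₂/(C₂+4)), A(o)=6·0.4/(o+0.4) | |
| mutation rate u | constant | 10⁻⁷ |

Constraints: (i) positive control net growth, larger at higher oxygen;
(ii) sensitive net growth strictly decreasing in erlotinib, strongly near
the vessel (negative at saturation everywhere) and more weakly at depth;
(iii) resistant cells exactly unaffected in the deepest compartment and
only partially inhibited at the vessel; (iv) viability decreasing in
evofosfamide concentration, strictly more potent at lower oxygen.

Two deliberate magnitudes: the sensitive EC50 is set in the tens of
nanomolar, consistent with the extreme in-vitro erlotinib sensitivity of
EGFR-mutant HCC827 cells; this also makes the low-dose (7 mg twice daily)
base regimen meaningfully active at tumor depth, without which low-dose
combination classes could not outperform monotherapy.  The viability depth
(A up to ≈ 3.3 under deep hypoxia) makes one 575 mg/m² dose remove ≈ 1.6
natural-log units of the hypoxic population — a strong but short-lived
kill, so weekly evofosfamide alone loses to regrowth.  Everything in
Fig-4/6-style comparisons (exact probabilities, means, optimal n,
recurrence delays) depends on this calibration; only orderings are asserted.

## Numerics

The production evaluator lays a graded time grid over the horizon:
segment boundaries at every dose instant and every evofosfamide ramp end
(so each segment has a fixed active-dose set and smooth integrands), with
0.02 h steps for 4 h after each evofosfamide dose (the death spike decays
at 1–3 /h) and 0.25 h elsewhere.  All inner integrals are cumulative
composite Simpson per segment, chained; the double integrals for E[Y] and
P[Y > 0] are rewritten as products of cached cumulative arrays, making each
compartment O(grid).  Exponentials of cumulative net-death integrals are
clipped at e±500 — far beyond any regime where their precise value matters
— so extinction weights reach their correct 0/1 limits without overflow.
Halving both steps moves nine-week endpoints by ~10⁻⁵ relative.  The
resistance probability costs O(grid) per output time and is therefore
evaluated on a decimated output grid (41 points by default, always
including the horizon).

The callable-based operations (`mean_sensitive`, `extinction_prob`, …) use
adaptive quadrature (`scipy.integrate.quad`, tolerances 10⁻¹²/10⁻¹¹) split
at declared rate discontinuities; they match piecewise-exponential and
linear-birth–death closed forms to 10⁻⁸/10⁻⁶ and serve as the reference
for small problems.

Mean recurrence time is the first return of E[X+Y] to M after first
dropping below M (schedules that never respond are reported as
non-recurrent, not as recurring at t = 0); crossings are located by linear
interpolation of log E.  The conditional tumor burden uses the
approximation E[X] + E[Y]/P[Y>0], exact only when the sensitive population
is independent of the resistance event; the simulator's conditional mean
over resistant replicates is the reference where the approximation matters,
and both are reported side by side.

## Stochastic simulator

The simulator is statistically exact: events are proposed at per-interval
upper bounds on the total event rate (bounds from dense sampling of each
inter-dose interval with a 0.5% safety factor, including 0.05 h sampling
through the post-dose death spike) and accepted with probability
true/bound; an assertion at every proposal guards the bound.  Mutation is
implemented at division — a sensitive birth yields a resistant daughter
with probability u — so the simulated sensitive process grows at
λ_X(1−u) − μ_X while the analytic formulas use the 1 − u ≈ 1 shortcut.
Cross-validation therefore evaluates the analytic side without the
shortcut (birth thinned by u, influx kept at the full division rate);
with u scaled to 10⁻²–10⁻³ on desk-size instances the gap would otherwise
be tens of Monte-Carlo standard errors.  One master seed spawns
independent streams per replicate and compartment; identical seeds give
bit-identical output.  Replicates exceeding the population cap (default
10⁷) are truncated, flagged, and excluded from summaries — the analytic
means reach 10¹⁵⁺ under monotherapy, which no stochastic simulator should
attempt.

A caveat the cross-validation respects: the seeding formula for
P[Y > 0] treats mutant arrivals as a Poisson process with intensity
b(t)(1 − Pᵉˣᵗ), i.e. it conditions on the *mean* sensitive trajectory.  At
desk scale (M ≤ 100) sensitive-population fluctuations over-disperse the
arrivals, and the formula overestimates P when the cumulative intensity is
large (P → 1).  Validation instances are therefore chosen with moderate
cumulative intensity (P ≈ 0.3–0.8), the regime where the approximation is
quantitatively valid; at the production scale M = 1.6·10⁶ the relative
fluctuations are negligible.

## Schedules, toxicity, and optimization

The built-in library encodes the ten comparison schedules (A–J) over one
21-day cycle, with daily doses at hour 0 and twice-daily doses at hours 0
and 12 (the source table does not state clock times).  Monotherapy checks
count each drug's doses in 21-day windows aligned to the cycle start and
test the maximum per-dose amount against the MTD curve; "on the curve" uses
a 1% relative tolerance that absorbs printed rounding (e.g. the curve value
150.01 vs the printed 150 mg, and the 2.36 μM steady-state trough of the
7 mg twice-daily pattern vs the printed 2.357 μM threshold).

Optimized combination cycles of length L = 504/n h are built in four steps:
MTD-curve dose (floored to an integer mg/m², with a 10⁻³ cushion so the
574.9998 curve value maps to the printed 575), evofosfamide placed at
L − 24 h (classes 1–2) or L − 6 h (class 3), base erlotinib slots filling
the cycle (a slot is kept only if its base spacing to the next cycle
start is respected, so gaps never shrink across the boundary), then
latest-first removal of erlotinib doses until the *periodic steady-state*
erlotinib concentration at the infusion instant meets the threshold.
Steady-state evaluation (rather than first-cycle) is deliberate: the
evaluation horizons span many cycles.  A consequence is that for class 1
the washout cannot be satisfied once cycles are shorter than ≈ 46 h, so the
class-1 grid transitions to evofosfamide-only schedules above n = 10; the
class caps are N = 21 (classes 1–2, cycles ≥ 24 h) and N = 28 (class 3,
additionally bounded by the smallest dose where the evofosfamide PK cubics
stay positive).  Optimization is an exhaustive grid search over integer n —
the endpoint profiles genuinely exhibit two local minima, which descent
would miss.

Under the packaged defaults the optimum is strictly interior for every
class and endpoint (n = 10 / 17 / 14 for classes 1 / 2 / 3 on tumor size),
and evofosfamide monotherapy is always the worst resistance endpoint
(P = 1.00 at nine weeks) — the alternating-schedule conclusion, which the
acceptance tests assert as orderings.

## Known limitations

- The rate calibration is a documented stand-in, not a fit to the original
  cell-count data; exact published endpoint values (e.g. a 0.16 erlotinib
  resistance probability, a 40.54% recurrence delay, specific optimal n)
  are calibration-sensitive and not reproduced — only their orderings.
- The pO2 histogram is synthetic; weights, and everything downstream, move
  with its shape parameter.
- No migration between compartments, no bystander effect of activated
  prodrug, no pre-existing resistance, no inter-patient PK variability;
  time scales and population sizes are those of the in-vitro
  parameterization, not a patient.
- The combination washout check uses this package's steady-state PK
  arithmetic; the source's own arithmetic for the same check is not fully
  specified, and three of the library's combination schedules (H, I, J)
  fail the strict threshold under it while remaining valid monotherapy-wise.
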