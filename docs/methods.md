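# Methods

## The decomposition model

Litter carbon is tracked in five pools: four labile compound groups
defined by solubility — A (acid-hydrolyzeable), W (water-soluble),
E (soluble in a non-polar solvent), N (neither) — and a recalcitrant
humus pool H formed as a by-product of labile decomposition. The state
x = (A, W, E, N, H) of a cohort (kg C m⁻²) obeys the linear system

    dx/dt = M x + b

with b the annual litter input. Column *i* of M carries the decomposition
rate k_i on its diagonal; fixed fractions p(i→j) of the decomposed mass
are routed to the other labile pools, a fixed fraction p_H to humus, and
the column deficit leaves the system as CO₂.

Rates respond to climate through the dimensionless factor

    f(T, P) = exp(β₁T + β₂T²) · (1 − exp(γP)),

with T in °C, P the annual precipitation in metres (stored in mm, converted
only inside this expression) and γ < 0. f is convex in T and concave in P,
saturating near 1500–2000 mm — the curvature that makes climate
aggregation biased (see below). Optionally the temperature term is
averaged over twelve monthly temperatures reconstructed by a sinusoid of
amplitude (t_max − t_min)/2; both modes are implemented because the
published worked factor value (1.031 at 3.5 °C / 1150 mm) is reproduced
by the annual-mean form (we obtain 1.033), and that form is the package
default. Woody litter decomposes more slowly by the size modifier
h(d) = min(1, (1 + φ₁d + φ₂d²)^r) at d = 2 cm (branches, coarse roots)
and d = 10 cm (stems, stumps); d = 0 means no woody features apply. Humus
is climate-modified but not size-modified.

Parameter values are the published maximum a posteriori estimate of the
Yasso07 parameterization, shipped as an editable flat key/value file
(`src/socagg/data/yasso07_map.txt`); every function accepts an alternative
set. With the shipped constants, β₁ = 0.096 °C⁻¹, β₂ = −0.0014 °C⁻²,
γ = −1.21 m⁻¹, h(2) ≈ 0.994, h(10) ≈ 0.273.

### Numerics

Because climate is piecewise constant year by year and the system is
linear, each annual step is solved exactly: x(t+1) = e^M x + ∫₀¹e^(Ms)ds·b,
evaluated with an augmented matrix exponential (valid for singular M; no
explicit inverse). This removes step-size error entirely. For plot
networks the rate matrix factorizes as M(c) = cK for a scalar climate
factor c, so K is diagonalized once per woody size class and thousands of
plot-years are stepped with one vectorized expression (`AnnualPropagator`);
tests pin this path to the reference exponential at 1e-9. Steady states
solve Mx = −b directly; matrices with condition number above 1e12 (e.g. a
zero rate) raise rather than return a meaningless solution. Off-diagonal
entries of M are non-negative, so non-negative states remain non-negative;
mass balance per step (Δstock = input − export) is checked against an
integrated-outflux computation to 1e-10.

A caveat the code surfaces explicitly: the humus rate is α_H·c with
α_H = 0.0033 yr⁻¹, so under low climate factors (c ≲ 0.85) a 5000-year
spin-up is *not* fully converged — the residual is e^(−5000·α_H·c) of the
humus steady state, up to ~3% at c = 0.2. `spin_up` measures its true
distance to the fixed point and warns when it exceeds 1e-6; the pipeline
therefore initializes from the analytic steady state (proven equal to the
converged spin-up), and the spin-up itself is kept as the validated
reference procedure.

## Litter input

Annual litter from living vegetation is biomass × component turnover rate
(per species: spruce / pine / deciduous; foliage, branches + coarse roots,
fine roots; plus four ground-vegetation classes with separate above/below
rates). Two ratio rules close inventory gaps: fine roots = 0.3 × foliage
biomass; below-ground ground vegetation = 2 × above-ground (moss and
lichen have no defined below-ground turnover and contribute none). Natural
mortality transfers all components of the dying share, including stems and
stumps at 10 cm; commercial harvest leaves everything except stems, which
exit as product. Chemical partitions (A/W/E/N fractions per species ×
component) are a shipped editable table with values in the range of
litter-chemistry compilations — configuration defaults, not measurements.
Litter input is constant within each 5-year inventory cycle; harvest
residues of a cycle are spread evenly over its five years. Birch stumps
use the pine rule simply by sharing table rows.

## Initialization

Each plot starts from steady state under its 1961–1990 climate normal and
the mean first-inventory litter of its (species × site-class) group, then
receives a deterministic reconstructed litter history for the 30
pre-simulation years before its first inventory, by rule class: mature
stands (age > 34) back-projected geometrically with a per-cycle change
rate (default 0.10 per 5 years); young unproductive stands held constant;
young productive stands with continuous forest cover get a previous
rotation reconstructed at a recommended harvest age (configurable lookup)
ending in a harvest-residue pulse at stand establishment; land-use-change
plots get a configured prior litter level (default 0.15 kg C m⁻² yr⁻¹,
non-woody); northern low-productivity plots are scaled back to age zero
and held constant (ground vegetation constant throughout). The back-cast
is a pure, seedless function of plot attributes and the rules config.
After the pre-simulation the pools are deliberately no longer at steady
state whenever climate or litter trend — the state the experiment probes.

## The aggregation experiment

Five simulations share litter input and differ only in climate input
(Table in `experiment.py`): spatial scale plot / district / country
(unweighted per-variable means over member plots — no weighting is
applied because none is implied by the design), temporal scale long-term
(fixed 1991–2008 mean applied to every year), 5-year (means over the
years between consecutive plot inventories, windows anchored on each
plot's own cycle and extended back over the pre-simulation), or annual.
The spin-up always uses the 30-year 1961–1990 normal — never 5-year or
annual values — but at the simulation's spatial scale, since constant
climate after initialization differs between spatial schemes in exactly
the same way. District means are computed per climate variable before the
sinusoid transformation. Only plots with organic-layer thickness strictly
below 0.4 m (upland, mineral-soil forest) are simulated. Stocks are
reported as 2008–2012 means, changes over 2000–2012, and national change
as Σ(plot change × representation area, default 900 ha) in Gg C yr⁻¹ over
the full series — all periods parameterized.

Why the directions are what they are: stock ≈ input/rate is convex in the
climate factor, and the factor itself is concave in precipitation below
its asymptote, so the mean of plot-level stocks exceeds the stock at the
mean climate (Jensen's inequality) — country-scale climate input lowers
the national stock estimate. Under a sustained post-1990 warming trend,
annual climate late in the series is warmer than the fixed 1991–2008
mean, so annually resolved decomposition exceeds the long-term-mean run
and cumulative stock change is lower. Both directions are asserted on the
synthetic landscape; the magnitudes (here ~19% stock lowering at country
scale and ~36% lower cumulative change under annual climate, printed by
`analysis/03_aggregation_effects.py`) are properties of the synthetic
landscape, not estimates for any real inventory.

## The synthetic landscape

The generator emulates the structure such an analysis needs, not any real
geography: three climatic regions (warm-wet coastal southwest ~6 °C /
2000 mm; colder, drier southeast ~3 °C / 700 mm; cold north ~0 °C /
600 mm — plausible defaults, not measured values), 19 districts, per-plot
baselines, a linear post-1990 trend (+0.04 °C yr⁻¹, +3 mm yr⁻¹) with
independent interannual noise (0.7 °C, 10%), logistic age–biomass curves
per species × site class with component shares, occasional clear-cuts
past a species harvest age, and a small annual mortality fraction.
Component shares are set so the implied mean annual litter input at first
inventory is ≈ 0.23 kg C m⁻² (≈ 0.21 excluding harvest residues), the
magnitude reported for boreal upland forest networks, and so spruce
stands out-litter pine and deciduous stands at equal age. Landscape,
climate and biomass use independently spawned streams from one seed and
are bit-reproducible.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: spatial autocorrelation of weather beyond the
region/district structure, measurement error and design changes of a real
inventory, species mixtures within a plot, drainage/peatland dynamics, or
vertical soil structure. On this landscape the national change series is
slightly negative (decomposition under the recent warm climate outpaces
the litter trend); the aggregation *differences* between simulations, not
the sign of the change, are the quantities of interest.

## Default problem sizes

Tests exercise the full pipeline on a 200-plot landscape; the acceptance
checks and the analysis scripts use 2000 plots over 1956–2012, a size at
which every reported quantity is stable (the batched propagator steps all
plots and years of one simulation in ~10 s). All tolerances quoted above
(1e-6 solver equivalence, 1e-10 mass balance, 1e-9 propagator agreement)
are asserted in the suite.
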