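# Methods

## Scope and model overview

`rhizoflow` models a single wheat plant's root system as a forest of
cylindrical segments attached at the collar and computes its hydraulic
conductance *K*rs — the water flow at the collar per unit water-potential
difference between a uniform external medium and the collar xylem
(m³ MPa⁻¹ s⁻¹).  The uniform-medium assumption mirrors hydroponic
conditions; there is no soil domain, no water-content feedback on growth,
no cavitation and no osmotic component.  Statistics modules analyse
plant-level trait tables from a six-cultivar panel spanning release years
1895–2002.

## Growth model

Three root types are simulated.

* **Seminal axes.** The per-plant count is drawn from a normal
  distribution (panel mean ± plant-level sd recovered from the tabulated
  SE at the midpoint n) and rounded; emergence is staggered by 0.5 d per
  root starting one day after sowing.
* **Crown axes.** Crown roots appear in cohorts tied to tillering.  All
  cultivars were sampled at the end of tillering simultaneously, so
  cohorts span a common window (day 10 to day 65); the per-cultivar
  phyllochron is that window divided by the cultivar's final tiller count,
  making low-tillering cultivars produce cohorts more slowly rather than
  stopping earlier.  Each cohort contributes `crown_roots_per_tiller`
  roots, the ratio of panel crown-count to tiller-count means (e.g.
  15.4/6.6 ≈ 2.33 for the 1895 cultivar).
* **First-order laterals.** Initiated behind an apical unbranched zone at
  an inter-branch spacing of 1/branching density (panel means, ≈0.9 cm),
  with a 2 d emergence delay; laterals do not branch further, matching the
  first-order composition of the young measured root systems.

Every axis elongates by the negative-exponential rule
L(t) = Lmax·(1 − exp(−r₀·t/Lmax)), which is monotone and never exceeds
Lmax.  Growth increments below 0.5 mm are carried over to keep segment
counts bounded (a 70-d plant holds ~5×10⁴ segments at dt = 0.5 d).
Diameters are mean-preserving lognormal around the per-type panel means
(CV 0.1); lateral maximum lengths are lognormal with CV 0.3 to mimic the
broad lateral-length spread of real systems.  3D coordinates are not
simulated — *K*rs depends only on topology, lengths, radii and ages — and
are fabricated as straight lines on RSML export.

Growth constants that field phenotyping cannot deliver are packaged
defaults fixed by `scripts/calibrate.py` (below): axis maximum lengths
(seminal 150 cm, crown 130 cm, laterals 7 cm mean), elongation rates
(3.0/3.2/1.5 cm d⁻¹), unbranched zones (8 cm apical, 1 cm basal).  The
modern cultivar (Tommi) carries a calibrated 0.72 multiplier on axis
maximum lengths, reflecting its smaller measured root system (e.g. lower
young-plant surface area and total length in the panel table).

## Hydraulic solver

Radial conductivity kr(age) [m MPa⁻¹ s⁻¹] and axial conductance
kx(age) [m⁴ MPa⁻¹ s⁻¹] are piecewise-linear per root type, clamped outside
the knots.  A segment of length l, radius r feeding a distal subtree of
conductance K_d has the exact transmission-line conductance

    tau   = sqrt(2*pi*r*kr/kx)
    kappa = sqrt(2*pi*r*kr*kx)
    K     = kappa*(K_d + kappa*tanh(tau*l)) / (kappa + K_d*tanh(tau*l))

with the kr = 0 limit handled as the series combination of kx/l with K_d.
The tree is folded tip-to-collar in one topologically ordered pass (child
conductances add at branch points; the collar is an ideal node), compiled
with numba for the daily-trajectory workload.  Because growth only appends
segments, each segment carries a single creation time and ages are exact
per segment — no further age splitting is needed at the growth
discretisation (0.5 d).

An independent oracle builds the explicit resistor network (axial
resistors kx/Δl, radial conductances kr·2πr·Δl with trapezoidal end
weights) and solves the sparse Dirichlet problem.  With 1000 nodes per
segment its discretisation error is O((τΔl)²) ≈ 10⁻⁷ relative, and the
analytic fold agrees with it to < 10⁻⁶ on random trees — this equivalence,
not formula provenance, is the correctness argument.

## Calibration of packaged defaults

Absolute kr/kx levels for wheat segments are not measurable by the
pipeline's own inputs, so the packaged knots follow the canonical shapes
(kr peaks in young tissue, ~2.6×10⁻⁷ m MPa⁻¹ s⁻¹ at 5 d for axes,
declining ~10-fold by 60 d; kx rises with xylem maturation from 8×10⁻¹³
to 1.8×10⁻¹¹ m⁴ MPa⁻¹ s⁻¹ for axes, laterals ~30-fold lower) and the
levels are fixed by `scripts/calibrate.py` against four anchors:

1. simulated mean *K*rs over days 10–12 equals the measured cultivar means
   (1.3×10⁻¹⁰ oldest, 0.7×10⁻¹⁰ most modern) — achieved exactly by
   per-cultivar joint kr&kx multipliers (0.495 and 0.337; scaling both by
   c scales *K*rs by exactly c, leaving τ unchanged);
2. the 70-d *K*rs trajectory spans ≈3 orders of magnitude;
3. day-70 total root length exceeds 120 m (oldest) and 63 m (modern);
4. the day-5–70 mean percent *K*rs deficit of the modern cultivar is ≈50%.

With the shipped defaults the 6-seed means are ≈2.93 orders, ≈146 m,
≈72 m and ≈49.5% deficit.  The deficit trajectory runs from ≈35% at day 5
to ≈58% at day 70, i.e. the contrast grows with age as older cultivars
keep adding crown cohorts for longer.

## Pressure-chamber chain

*K*rs is the OLS slope of sap flow on applied pressure over the protocol
sequence 0.16, 0.24, 0.1, 0.32, 0.24 MPa; the duplicate 0.24 MPa reading
enters as its own point, and the intercept is left free because
pre-pressurisation can leave a flow offset.  QC requires r² ≥ 0.95
(configurable) and a positive slope.  Outlier flagging is per cultivar:
a sample must fall outside the 1.5×IQR fences for *all three* of *K*rs,
*K*rs_area and *K*rs_length (a disjunctive mode is available), and an
iterative two-sided Grubbs test (α = 0.05, at most one removal per
iteration, two iterations) on *K*rs must confirm it.  Flags annotate;
nothing is dropped silently, and groups of fewer than three QC-passing
samples fall back to the IQR rule with a warning.

## Trend statistics

Traits are analysed on plant averages, log-transformed.  Field traits use
a linear mixed model log(y) ~ release_year with the growing season as a
random intercept (REML; two seasons), falling back to OLS with a warning
when the season variance component collapses; hydroponic *K*rs traits use
plain OLS.  The yearly slope is back-transformed to percent change per
century as (exp(100·slope) − 1)·100; the widely printed shorthand
"exp(slope − 1)·100" is a garbling of this and is not used.  Residual
normality is reported via Shapiro–Wilk.  Cultivar contrasts use one-way
ANOVA on logs with Tukey HSD adjustment; no multiplicity correction is
applied across traits, which are reported per-trait.  Wald-based p-values
from the two-season mixed model are very slightly anticonservative
(empirical type-I ≈ 0.055 at nominal 0.05 in the packaged null
simulation) — a known small-sample property of variance-component
estimation with few groups.

## Synthetic data

The generator draws plant-level trait values lognormally around
per-cultivar means — either the packaged panel means (`table1_defaults`)
or a log-linear release-year trend (`trend_config`) — with an additive
per-season random effect on the log scale (sd 0.05–0.08) and
plant-to-plant log sds implied by the tabulated SEs (field n midpoint
29.5, chamber n 10).  Count traits are rounded.  Chamber sweeps follow
the pressure protocol with Jv = intercept + *K*rs·P + Gaussian flow noise
(sd 1.2×10⁻¹² m³ s⁻¹, ~3% of full-scale flow).  A configured fraction of
sweeps is saturating (Jv ∝ tanh(P/0.09), linear r² ≈ 0.7) to exercise the
linearity QC, and a fraction is planted as joint outliers: *K*rs pinned at
5× the cultivar mean with geometry at the mean, so all three measures are
extreme — emulating a seal leak rather than biological spread.  The truth
record carries every generating parameter.

What passing these simulations shows — and what it does not: the
generator is exactly the model the statistics assume (lognormal,
log-linear trends, linear sweeps), so recovery tests validate the
estimation chain, not the adequacy of those assumptions for field data;
real shovelomics tables carry measurement error, spatial block structure
and trait correlations that are not emulated.

## Numerical choices and limitations

* dt = 0.5 d growth step; *K*rs evaluated daily along trajectories;
  6 replicate seeds for simulation summaries (seed-to-seed CV of day-70
  length ≈ 10%).
* Segment minimum length 0.5 mm (carry-over elongation); axis growth
  stops within 10⁻⁴ of Lmax.
* The solver excludes segments created after the evaluation time; an
  empty system yields zero conductance rather than an error.
* Grubbs critical values use the exact t-quantile formula; with sd = 0
  (all equal) no outlier is declared.
* Laterals attach hydraulically at the end node of the parent segment
  containing their initiation position (position error below one segment
  length); the oracle uses the same topology, so the comparison is exact.
* The panel is six cultivars from one breeding history; trend slopes over
  release year should not be extrapolated outside 1895–2002, and the
  hydroponic *K*rs levels need not transfer to soil-grown plants.
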