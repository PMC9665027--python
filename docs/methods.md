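# Methods

`rrmsim` simulates relapsing-remitting multiple sclerosis (RRMS) as an
emergent property of a small mechanistic immune system, and wraps that
model in a virtual-trial pipeline.  This note records the model, its
assumptions, the calibration philosophy, the numerical choices, and what
the shipped tests do and do not demonstrate.

## The immune core

The immune system is an agent-based model in the Celada–Seiden
tradition: every cell is an individually tracked agent with a type
(B cell, CD4 helper T cell, regulatory T cell, cytotoxic T cell, NK
cell, antigen-presenting cell, or antibody-secreting plasma cell), an
activation state (resting / activated / duplicating / anergic), a
position, and — for the clonotypic lineages — a receptor.

**Receptors and binding.**  Receptors and antigen epitopes are binary
strings of length L = 12, stored as integers.  Affinity is the fraction
of complementary bit positions, `popcount(a XOR b) / L`; a receptor
binds an epitope when at least 11 of 12 positions are complementary.
This makes cognate recognition rare (13 of 4096 random receptors bind a
given epitope), so clonal structure emerges naturally.  Repertoires are
drawn uniformly at birth, with a configurable autoreactive bias
(`p_auto`): a small fraction of new B/TH/CTL receptors are drawn one bit
away from the exact complement of the oligodendrocyte self-epitope.
T-lineage receptors pass thymic negative selection, which deletes exact
complements of self (`neg_threshold = 1`); the weakly self-reactive
near-complements escape, as in the biological escape of low-avidity
autoreactive clones.

**Space.**  Two compartments — periphery and white matter — each a
16 x 16 toroidal grid.  Agents random-walk one site per step; receptor-
mediated interactions require co-location on a site.  Three cytokine
fields (IL-2, IFN-γ, TGF-β) live on the grids with mass-conserving
nearest-neighbour diffusion and exponential decay; antibody titers
(IgM/IgG/IgA) are scalar because only totals are reported.

**The step.**  One timestep is one simulated day.  Phase order is fixed:
movement (including activated-effector migration periphery → white
matter) → interactions (antigen presentation, IL-2-gated TH/CTL
activation, TH-licensed B activation, bystander TREG activation,
TGF-β-gated TREG suppression, viral dynamics, autoimmune attack) →
secretion → cytokine diffusion/decay → class switch and duplication →
aging/death → hematopoiesis.  All randomness flows from one per-patient
generator, so a (seed, parameter set) pair fully determines the
trajectory; the test suite asserts bit-level reproducibility and exact
per-step conservation bookkeeping (Δcount = births − deaths + migration
± class switch, per lineage and compartment).

A timestep of one day (rather than a few hours) was chosen because every
process the model must resolve — the 28-day dosing interval, the 14-day
relapse-detection window, clonal expansion over ~2 weeks — is slow on
the cell-movement timescale, and daily steps make 5-year histories cheap
enough to run hundreds of patients on one CPU (~1 s per patient-5-years).

**Homeostasis.**  Hematopoiesis adds Poisson(death-rate × set-point) new
resting cells per lineage per step, which balances resting turnover
exactly at the set-point; activated cells die faster (2.5-week scale in
the periphery, 2 weeks in tissue).  Clonal expansion on activation is
limited to a 10-day window per clone, after which the clone persists but
no longer divides — this yields acute bursts that resolve rather than
runaway growth, with a crowding guard as backstop.

## The RRMS layer

White matter holds 200 oligodendrocytes sharing one self-epitope.
Disease is triggered once per patient by an EBV-like infection at a
uniform random day in the first simulated year: a viral epitope with
`mimicry_flips` bits of Hamming distance from the self-epitope (default
0 — maximal molecular mimicry; negative values draw an unrelated
epitope for null experiments) replicates, is presented by APCs, and
drives an anti-viral response.  Cross-reactive effectors that traffic
into the white matter kill co-located oligodendrocytes; each kill feeds
a myelin-debris pool.

**The chronic loop.**  Debris drives continued APC presentation of the
self-epitope with a Hill-type (cooperative, exponent 2) dose response.
This creates an ignition threshold: trivial damage fizzles out, while a
genuine relapse-scale attack lights a self-sustaining
presentation → activation → attack → debris loop.  The lit state decays
over months (debris half-life ≈ 350 days) unless new attacks replenish
it, producing the relapsing-remitting phenotype: discrete episodes of
oligodendrocyte loss separated by remissions, with slow remyelination
(0.8%/day per lost cell) restoring the baseline between episodes.
Whether a patient ever ignites — and hence whether they are
"symptomatic" — is decided by the stochastic coincidence of autoreactive
clones with the infection window, which is what makes the population
fractions below meaningful calibration targets rather than inputs.

**Relapse definition.**  A relapse is an episode in which the
oligodendrocyte count falls by at least θ = 5% of baseline within a
trailing 14-day window; the episode tracks its running trough and closes
after 30 days without further loss (episodes closer than 30 days merge).
The detector is a pure function of the count trajectory and is asserted
to be insensitive to appended flat tails.  θ, window and gap were chosen
so that calibrated symptomatic patients accumulate 1–9 relapses over
five years.

**Base characteristics.**  Lesion load (high vs low/medium), oligoclonal
band status, and age-of-onset category enter exclusively through the
shipped calibration table (`data/calibration.yaml`), which maps each of
the 12 combinations to engine-parameter overrides generated from six
interpretable factors: high lesion load raises the autoreactive
repertoire bias and effector kill rates; OCB presence extends plasma-
cell persistence (intrathecal antibody production); younger onset scales
the B/TH homeostatic set-points up (immune vigour) and the TREG
set-point slightly.  The same profile always maps to the same overrides.

## Treatments

Each drug carries a unitless effect envelope in [0, 1]: at every
administration it jumps to a dose-saturating peak (≈ 0.99 at label
doses) and decays exponentially between doses.  Mechanisms perturb
engine parameters or populations, never endpoints:

* **natalizumab** multiplies periphery → white-matter migration by
  `1 − effect` (the only mechanism the modelled system prescribes);
* **ocrelizumab** kills circulating B cells (not plasma cells) at
  `0.5 × effect` per day;
* **IFNβ-1a** scales lymphocyte activation and duplication by
  `1 − 0.5 × effect` and TGF-β secretion by `1 + 0.5 × effect`;
* **teriflunomide** scales duplication of activated lymphocytes by
  `1 − 0.6 × effect`.

The natalizumab envelope half-life is 120 days: the envelope proxies
α4-integrin receptor occupancy, which at 300 mg every 4 weeks remains
high through the trough rather than following the serum concentration.
Under this envelope the drug effectively starves the white matter of new
effectors; because kills stop, the debris pool decays and the chronic
loop extinguishes — the mechanistic counterpart of the near-complete
suppression of relapse activity.  Dosing windows are half-open
`[start_week, end_week)`, so 104 weeks of a 28-day regimen is exactly 26
administrations.

## The trial pipeline

A trial configuration declares the population's base-characteristic
distributions, the disease-activity inclusion rule, the arms with
treatment plans and target sizes, the allocation ratio, and the
timelines.  The pipeline samples candidates i.i.d. (each patient's RNG
seed is a hash of the population seed and patient index, so results are
independent of batching and worker scheduling), runs a 5-year pre-trial
history per candidate, applies the inclusion rule at screening (end of
run-in; an episode counts as "in" a window when its start falls inside;
lookback year = 365 days, final month = 30 days), randomizes the
included patients to exact arm sizes with permuted blocks in a canonical
patient order, and continues each included patient's simulation through
the trial under the arm's plan.  Trial clocks are synchronized (week 0 =
screening); nobody is censored before trial end.  Candidate batches are
oversampled at 1.15 × the expected inclusion rate and whole batches are
always processed, so the included set is reproducible for any `--jobs`
value.

## Endpoint statistics

Kaplan–Meier product-limit estimation and Greenwood's variance are
implemented from their closed forms (ties: events before censorings),
with 95% bounds on the plain survival scale clipped to [0, 1]; where the
curve reaches zero the Greenwood sum diverges and the bounds are pinned
to [0, S].  A log-log transform is deliberately not the default.  The
implementation is cross-checked in the tests against lifelines and
against hand-worked examples to 1e-12.  Two-sample Kolmogorov–Smirnov
and Wilcoxon rank-sum tests delegate to scipy, using exact small-sample
p-values (asserted in the tests to equal full enumeration over label
assignments for min(n, m) ≤ 8); p-values are reported at machine
precision.  The annualized relapse rate is total trial episodes per
patient-year.  Per-patient "mean over trial" immune variables are
time-averages of per-day totals.

## Calibration

The model's rate constants are not measurable quantities; the published
anchors are population statistics.  The calibration harness
(`rrmsim.calibration`) therefore scores a candidate table on:

1. the fraction of 5-year treatment-naive histories with ≥ 1 relapse in
   the two documented populations (targets 58% and 59%);
2. the 1–9 span of relapse counts among symptomatic patients;
3. the untreated-arm relapse-free fraction at 104 weeks in the
   historical-trial recreation (target ≈ 40%), with the treated arm
   ≥ 90%.

The shipped table is the product of a staged search: coarse manual
bracketing of the infection and chronic-loop scales, then randomized
refinement of the six factors at batch sizes of 100–150 patients.  The
decisive structural choices found during calibration were the Hill
ignition threshold on debris presentation (separating "ever symptomatic"
from "chronically active") and the occupancy-like natalizumab envelope
(separating the arms).  All shipped values live in versioned YAML
(`engine_defaults.yaml` version 3, `calibration.yaml`); they are
calibration products, not measurements.

## What the synthetic populations do and do not show

The generator emulates the *designs* reported for the use cases:
base-characteristic distributions (e.g. the 49.4 : 36.2 : 14.4 onset
split), symptomatic selection, the relapse-in-prior-year /
none-in-final-month rule, 2:1-style randomization and fixed trial
horizons.  It does not emulate real-data features such as measurement
noise, dropout and censoring, MRI endpoints, disability scores,
treatment-history effects, or inter-patient parameter variability beyond
the 12 calibration categories and simulation stochasticity.  Passing
tests therefore demonstrate internal consistency and reproduction of the
documented population statistics under the shipped calibration — not
clinical validity for any individual patient.

## Numerical and degenerate-input choices

* Exact integer bookkeeping of agents; cytokine fields are float64 and
  asserted non-negative at every step.
* The empty immune state with hematopoiesis disabled is a fixed point of
  the step function (only the clock advances).
* Relapse detection on an empty trajectory returns no events; a zero- or
  negative-length trial is a configuration error; randomization with too
  few included patients raises an error naming the shortfall.
* State snapshots serialize the full agent table including slot layout
  and the RNG state, so a restored simulation continues bit-identically.
* Scaled-down problem sizes used by the shipped acceptance runs: 100
  patients per naive population and a 40/40 trial (the treated arm
  halved from 80), the package's documented desk-scale defaults.

## Known limitations

* One active drug per arm; no PK compartments, anti-drug antibodies, or
  combination effects.
* No MHC diversity, somatic hypermutation, or germinal-centre anatomy;
  antibodies affect viral clearance but not oligodendrocyte protection.
* Lesion load is a parameter class (input), not a simulated readout; no
  spatial lesion geometry or MRI synthesis; no disability (EDSS) layer.
* The binomial noise of the documented sample sizes is inherited by
  every reproduction: at n = 40 per arm the relapse-free fraction has a
  ±15-point 95% interval, which is why the acceptance checks quote
  binomial tolerances.
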