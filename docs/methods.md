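# Methods

This note documents the models, conventions and numerical choices behind
`vbesim`, and what the synthetic study conditions do and do not represent.

## Dissolution similarity and release model

The similarity factor is computed on replicate-mean profiles,
f2 = 50·log10(100·[1 + (1/n)Σ(Rₜ−Tₜ)²]^(−1/2)), with the similarity band
50–100 inclusive. No truncation of late time points is applied by default;
the regulatory convention of keeping at most one point after both profiles
exceed 85% dissolved is available as an opt-in flag (`truncate_85`), and a
replicate-level f2 (all reference×test replicate pairings) as another.

Release is modelled as F(t) = Fmax·(1 − exp(−((t−lag)/α)^β)). α is the
time scale: at t = lag + α the curve reaches (1 − e⁻¹) ≈ 63.2% of Fmax for
any β. The alternative convention F = Fmax·(1 − exp(−(t−lag)^β / a))
maps to this one by a = α^β (β identical).

Fitting minimises ordinary squared residuals against the replicate-mean
profile with `scipy.optimize.least_squares` (trust-region reflective,
bounds Fmax ∈ (0, 110], lag ∈ [0, t_max], α ∈ (0, 20·t_max], β ∈ [0.05, 12])
from three starts: a data heuristic (Fmax from the plateau, α from the time
to 63% of plateau, β = 1, lag = 0) plus two seeded jittered variants,
keeping the lowest-RSS converged solution. Four-parameter Weibull surfaces
are multimodal; three starts were sufficient for exact recovery on
noise-free profiles in all tested corners. Standard errors are the usual
asymptotic (JᵀJ)⁻¹·s² diagonal.

**Identifiability.** On the 9-point protocol grid (1–24 h, first sample at
1 h) the lag of a promptly releasing formulation is intrinsically weakly
identified: at additive noise of 2 percentage points the Cramér–Rao bound
on a single profile already implies a median relative lag error of ~50%
(and ~20% on a 7-replicate mean), while Fmax, α and β recover to within a
few percent. Parameter-recovery claims in the tests are therefore stated
for the pooled median across parameters and per-parameter for Fmax/α/β;
users who need tight lag estimates should sample earlier time points.

## Reduced PK model

The simulator is deliberately a *reduced surrogate*, not an organ-level
PBPK model: per dose event a Weibull depot feeds a dissolved-gut
compartment, absorbed first-order (ka) into a one-compartment central
volume, eliminated by well-stirred hepatic clearance plus renal clearance.
For a BCS-1 compound neither solubility nor permeability limit absorption,
so defaults make release rate-limiting: ka = 2 h⁻¹, fraction absorbed 1
(both configurable). There is no colonic absorption cutoff by default — a
24-h release is treated as fully absorbable; an absorption-window variant
would be a straightforward extension of the gut compartment (stop the
absorption term after a configurable time).

Competitive CYP inhibition is static: the pathway-resolved intrinsic
clearance is scaled by fm_i/(1 + Iu/(Ki_i·fu_inc,i)) with the inhibitor at
a constant steady-state unbound concentration (µM). This matches the
steady-state endpoints of interest; a time-course inhibitor would require
co-simulating the inhibitor's PK and is out of scope.

Numerics: the two-state ODE is integrated with LSODA at rtol 1e-8 / atol
1e-10 on a grid of ≥ 4 points/h, split at every dose time and lag offset so
no forcing discontinuity is stepped over. The gut state is integrated as
u = A_gut − R(t) with R(t) the analytic cumulative release, so the forcing
is bounded by the total dose; this keeps the solver stable even for
near-instantaneous release (α → 0), which is how the Bateman-limit check is
run. Linearity of the system makes superposition over dose events exact;
the implementation still integrates the full multi-dose system in one pass
and superposition is verified, not assumed, in the tests.

Units: dose mg, time h, volume L, clearance L/h, concentration ng/mL
(1 mg/L = 1000 ng/mL). Molecular weight is carried in the compound config
but only needed if inhibitor concentrations must be converted to µM.

## Virtual populations

Varied parameters are drawn independently, log-normally, with median equal
to the base value and log-SD √ln(1+CV²) — positivity by construction and
the median (not the mean) preserved, standard pharmacometric practice. The
release parameters default to CV 10% each (the in-vivo inter-individual
variability assigned to dissolution); which disposition parameters vary,
and how much, is an explicit configuration knob (the trial scenarios use
clearance CV where stated). Correlated sampling is available as a hook
taking a user-supplied log-scale correlation matrix; no correlation is
imposed by default because none is publicly specified. Parallel-trial arms
are drawn from decorrelated `SeedSequence` sub-streams, which is what makes
the parallel design the worst case: the two arms share no subject-level
randomness, so inter-occasion variability effectively equals
inter-individual variability.

## NCA conventions

Cmax/Tmax from the observed maximum; AUC0–t by linear trapezoid to the last
positive sample (profiles are dense simulated curves, so linear-up/log-down
would change results negligibly; a log-down option is a documented
extension); λz by log-linear least squares over the terminal window with
the best adjusted R², candidates being windows of ≥ 3 points after Tmax
ending at the last positive sample, thinned to 40 evenly spaced starts on
dense grids; adjusted-R² ties (at 1e-6 resolution) resolve toward more
points. AUC0–∞ = AUC0–t + Clast/λz, flagged missing (NaN) when no negative
terminal slope is identifiable.

## BE statistics

Per endpoint, the log-scale mean difference test − reference gets a Welch
two-sample CI (unequal variances, Satterthwaite df; pooled-variance option
available), exponentiated to a GMR and CI in percent. BE passes when the CI
lies within 80–125% inclusive — "falls within 80.00–125.00%" in the
regulatory phrasing — and the overall call requires all endpoints to pass.
The CI decision is exactly dual to two one-sided tests at α = 0.05 because
both use the same standard error and df. Zero-variance (fully
deterministic) arms yield a degenerate point interval at the GMR. A study
in which more than 10% of an arm lacks a usable endpoint value is flagged
invalid. Replicate studies run on sequential logged sub-seeds so
diagnostics are reproducible study by study.

## Study power

The power procedure is difference-detection, not equivalence, power: both
endpoints' populations are taken normal on the raw scale, the two-sided
critical region |x̄ − μ₁| > z₀.₉₇₅·σ₁/√n₁ is built from Population 1, and
the power is Population 2's sampling-distribution mass in that region. In
the null case the power equals α identically. One-sided and log-scale
variants are provided (PK endpoints are typically closer to log-normal; the
raw-scale default mirrors the normality assumption of the procedure being
reproduced). Population summaries (μ, σ²) are estimated with ddof = 1 from
endpoint samples produced by the simulation pipeline itself.

## Synthetic study conditions

The generator emulates a 24-h modified-release dissolution protocol:
9 sampling times (1, 2, 4, 6, 8, 12, 16, 20, 24 h), 7 replicates for the
reference and 3 per test formulation, additive Gaussian noise (default SD
1.5 percentage points, reflecting the low variability of in vitro
dissolution) truncated at 0 and capped at 105%. The three shipped
formulations are synthetic: a reference (Fmax 92, lag 0.5 h, α 9 h,
β 1.15), a similar test formulation (93, 0.4, 9.8, 1.10; f2 ≈ 86,
bioequivalent) and a faster test formulation (92, 0.4, 7.2, 2.0; f2 ≈ 51 —
above the similarity threshold — but Cmax GMR ≈ 1.36, failing BE on Cmax
with AUC unchanged). The compound file is a synthetic BCS-1,
dopamine-agonist-like parameter set (V 525 L, CLint 97 L/h, fu 0.85,
Q 90 L/h, fm CYP1A2/3A4 = 0.65/0.25, renal CL 4 L/h, CL/F ≈ 47 L/h,
t½ ≈ 8 h); the inhibitor file uses Ki 2 µM (CYP1A2) and 1.5 µM (CYP3A4)
with incubation unbound fractions 0.92 and 1 at a steady-state unbound
concentration of 3 µM. None of these numbers are claims about any marketed
product.

What passing tests show — and do not. The synthetic conditions exercise the
full machinery (fit → f2 → population → ODE → NCA → BE → power) with known
ground truth, so they validate the *computations*. They do not validate
organ-level absorption physiology (no multi-segment gut, no tissue
partitioning, no demographic covariates), parameter correlations across
subjects, assay error structure beyond additive Gaussian noise, or the
in-vitro/in-vivo correlation assumption itself; conclusions about a real
formulation require a verified compound model and real dissolution data.

## Problem sizes and defaults

Trial scenarios default to 125 subjects per arm (the size at which the
power sweep of a typical scenario reaches ~80% for the AUC endpoints) with
a single replicate study; the replicate diagnostic uses 10 studies.
Single-dose simulations run on a 4-points/h grid to 120 h post dose
(~15 half-lives of the default compound). The recovery Monte Carlo uses
100 replications. The power sweep covers 8–200 subjects per arm.
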