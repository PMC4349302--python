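# Methods

## The model

`tgnkin` models the signaling module that couples secretory-vesicle
formation at the trans-Golgi network (TGN) to non-vesicular ceramide
transfer from the ER: protein kinase D (PKD), the lipid kinase PI4KIIIβ and
the ceramide transfer protein CERT. Active, DAG-bound PKD (state `PKDpDAG`)
phosphorylates PI4KIIIβ (activating PI4P production, which recruits CERT to
the TGN) and CERT itself (detaching it from the TGN). Delivered ceramide is
converted by sphingomyelin synthase into sphingomyelin and DAG, which
recruits and activates PKD — closing a feedback loop whose sign depends on
the transport mechanism:

* **Variant A — shuttle.** CERT stays ER-anchored and cycles:
  transfer-engaged `CERTaTGN` is phosphorylated off the TGN (`CERTpER`),
  dephosphorylated at the ER (`CERTaER`) and re-recruited by PI4P. The
  cycle, driven by PKD and PI4KIIIβ, supports transfer: the loop is
  positive overall.
* **Variant B — neck-swinging.** Only the doubly membrane-bound
  `CERTaERTGN` transfers ceramide; PKD phosphorylation interrupts transfer
  directly, and additionally phosphorylates free `CERTa`
  (rate `k_phos_free`, the 27th parameter). The loop is negative overall.

Each variant has 7 state variables (molecules/cell) and 26 (A) / 27 (B)
positive rate parameters. Regulated reactions use a bounded
Michaelis–Menten-like law

    v = vmax · E/(K_E + E) · S/(K_S + S),

with regulator E, substrate S; the flux can never exceed `vmax`, and
`v/vmax` is the reaction's *operating point* — the saturation fraction of
the coupling. The CERT-transfer→PKD activation channel lumps the
SMS/DAG steps into one term regulated by the transfer flux itself,
`v = vmax_cer · J/(K_cer + J)` with `J = k10 · [transfer-engaged CERT]`
(molecules/hour). PI4P and DAG are not explicit states; their production
and action are folded into the effective regulated terms. Each protein has
constant synthesis, first-order degradation applied equally to all its
forms (parsimony; it keeps the counts at 26/27), and the experimental
inputs enter as steps: `u1` PDBu (extra mass-action activation of PKD),
`u2` kb-NB142-70 (divides the PKD-catalyzed `vmax` terms and the
basal/PDBu activation channels by `1 + k_inh·u2`), `u3`/`u4` ectopic
synthesis of PI4KIIIβ/CERT from transfection at t = 0. Units are
molecules/cell and hours throughout.

A structural property of this reconstruction worth knowing: relabeling
`CERTaER↔CERTa`, `CERTaTGN↔CERTaERTGN`, `CERTpER↔CERTp` maps variant A
exactly onto variant B with `k_phos_free = 0`. **B nests A**; the
positive/negative-feedback distinction lives in the parameter regime
(which saturations are engaged), not in the reaction topology. The shipped
reference parameterizations realize the two regimes: in A the CERT
phosphorylation is regulator-saturated (small `K3E`) while PI4KIIIβ
activation is not, so raising active PKD raises net transfer (+≈5% transfer
for +10% active PKD); in B the free-CERT phosphorylation and an unsaturated
CERT phosphorylation make the same perturbation lower transfer. See
"Model comparison" below for the consequences.

## Numerics

The right-hand side and an adaptive Dormand–Prince 4(5) stepper are
JIT-compiled (numba): one likelihood evaluation is a steady-state
relaxation plus piecewise integration of up to six protocols and must run
in about a millisecond for tempered sampling to be practical. Relative
tolerance is 1e-8 (1e-10 available; observables move by < 1e-5 relative
between the two), absolute tolerance 0.1 molecules against amounts of
1e3–1e7. Steps land exactly on observation and input-switch times;
accepted states are clipped at zero (rate laws clamp negative trial states,
so transient −1e-9-scale excursions are harmless). The stepper is verified
against `scipy.integrate.solve_ivp` and against a hand-summed per-reaction
flux balance.

Steady states: relaxation over ten times the slowest turnover timescale
followed by a Newton polish (`scipy.optimize.root`); accepted when
`max|dx/dt| ≤ 1e-6` molecules/(cell·h). Roundoff-scale negative entries
from the polish are clipped. Inside the likelihood the polish is skipped
for speed — the relaxation residual (≲1e-4) is orders of magnitude below
measurement noise. During sampling, integrations are capped at 3000 steps
per segment; parameter combinations that exceed the cap (pathologically
stiff corners of the prior) map to a log-likelihood of −∞, i.e. the
sampler rejects them.

## Observation model and likelihood

Blot readouts map to states: phospho-PKD (pS910) → `PKDpDAG`,
phospho-PI4KIIIβ (pS294) → `PI4Kp`, phospho-CERT (pS132) → `CERTpER` (A) /
`CERTp` (B); totals sum all forms of a protein. Absolute records are in
molecules/cell. Relative records carry an unknown per-course gain
(band intensities are arbitrary units, and t = 0 bands can sit near
background, which rules out fixed-point normalization); under the Gaussian
noise model the maximizing gain is available in closed form,

    s = Σ x_i d_i/σ_i² / Σ x_i²/σ_i²,  clipped at 0,

and is profiled per time course before residuals are evaluated — exact,
and it adds no sampled dimensions. The likelihood is independent Gaussian
with the per-record SDs reported in the dataset (measured replicate
scatter; noise variances are not estimated).

Priors are independent log10-uniform boxes. The default construction
centers each parameter's box on the best multistart MAP estimate with ±3
decades, clamped to physical bands: degradation rates to protein
half-lives of 1–100 h, synthesis rates to steady-state totals of 1e3–1e9
molecules/cell. Multistart MAP uses L-BFGS-B with numerical gradients from
log-uniform draws (redrawn until simulatable — a failed-simulation plateau
has no gradient).

## Sampling and model comparison

Parallel tempering: Gaussian random-walk Metropolis in log10 space at every
inverse temperature of a power-law ladder `β_i = (i/(L−1))^5` (dense near
β = 0, where the thermodynamic-integration integrand varies fastest), one
random adjacent-pair swap attempt per iteration with acceptance
`min(1, exp((β_i−β_j)(logL_j−logL_i)))`. During burn-in (the first half)
proposal scales adapt twice over: a per-level global multiplier steers
acceptance toward ~25%, and per-parameter scales follow the chain's own
coordinate spread (diagonal adaptive Metropolis with the `2.38/√d` rule,
bounded against collapse); both freeze after burn-in. The β = 0 level uses
independence proposals drawn from the prior itself — its target *is* the
prior, so such moves are exact, renew the hottest chain with uncorrelated
draws, and keep the thermodynamic-integration trace well populated even
where most parameter combinations fail to simulate.
Everything is deterministic given the seed. Convergence is checked with
the potential scale reduction across independent runs,
`R̂ = sqrt(((N−1)/N·W + B/N)/W)`; degenerate (zero-variance) chains are
flagged. Full-scale settings (10 levels, 5e5 iterations, 3 runs) are a
configuration choice; tests and the acceptance script run desk-scale
studies sized to minutes on one CPU (see below).

Evidence: `log Z = ∫₀¹ E_β[log L] dβ` by trapezoidal quadrature over the
ladder, per-level means over finite post-burn-in log-likelihood draws,
per-run estimates combined into a mean with run-to-run standard error;
model ranking by `2 log K` with the conventional categories ((0,2] barely
worth mentioning, (2,6] positive, (6,10] strong, >10 very strong).

Two desk-scale choices matter here. First, evidence runs use ±1.5-decade
prior boxes (coverage studies use the default ±3): with ±3 boxes in 26–27
dimensions the prior-side integrand sits at ~−1e6 log-likelihood units and
trapezoid estimates carry run-to-run noise in the thousands — pure noise at
any affordable iteration count. Second, the two variants are calibrated
with paired run seeds so part of the Monte Carlo error cancels in their
difference.

Because B nests A and the extra reaction's observable footprint lies within
the assumed measurement noise (phospho-CERT is only measured relatively;
absolute data are totals with 25–40% CV), the two variants are
observationally near-equivalent under this study design: on A-generated
data the true `2 log K` is only the Occam penalty of B's extra parameter
(small, positive), and on B-generated data it is *also* close to that
penalty — data generated from B do not reliably favor B. Desk-scale
sign-recovery of the generating variant is therefore expected to succeed
in the A direction only marginally and to fail in the B direction; the
corresponding end-to-end check is kept (and reported) as an honest negative
result of this reconstruction, not weakened to pass. Distinguishing the
mechanisms evidently requires either rate laws that break the nesting or
data that pin the phospho-CERT level absolutely.

## Synthetic data

The generator reproduces the study design: E1 absolute endogenous totals
(3 replicates each); E2 ectopic PI4KIIIβ for 24 h (absolute total at 24 h)
then PDBu, with relative phospho-PKD/PI4KIIIβ at +0/10/20/30/60 min; E3
ectopic CERT (absolute totals at 8/16/24 h) then kb-NB142-70, with relative
phospho-PKD/CERT at +0/1/2/3 h; E4a early phospho-PKD (1/2/4 h) during
expression; E4b long-time phospho-PKD at +2/4/6 h after PDBu (the horizon
is configurable; 6 h is the default); E5 the validation point, phospho-
PI4KIIIβ at 25.25 h after expression from 0 h and inhibition at 24 h —
held out of calibration. Absolute replicates are normal with SD = CV·mean
truncated at zero (the recorded SD stays the pre-truncation value for
likelihood consistency, default CV 0.30 within the observed 0.25–0.40
band); relative courses get additive noise with SD = 10% of the course
maximum. Identical seeds give byte-identical CSVs. The time grids inside
the figure ranges are fixture choices.

The reference parameterizations were chosen once: endogenous totals near
the measured magnitudes (PI4KIIIβ ≈ 2e6, PKD ≈ CERT ≈ 5e5 molecules/cell),
most PKD and PI4KIIIβ unphosphorylated at rest, regulated couplings far
from saturation, and perturbation responses clearly visible above the
blot noise so that synthetic calibration is informative. One deliberate
departure from the published posterior: the transfer-dependent share of
PKD activation at rest is ~10% here (the study's posterior puts the
feedback-knockout effect below 1%) — with a <1% share, no property of the
feedback would be testable above the noise floor. What passing synthetic
tests shows is that the machinery recovers truth under the assumed noise
model; real blots add nonlinearities (antibody saturation, background)
that live outside this generator.

## Desk-scale study sizes

Chosen for minutes-scale runtime on one CPU and recorded here as package
defaults: coverage/posterior-predictive studies use 4 levels × 2500
iterations × 3 runs (±3-decade priors, burn-in 50%); evidence comparisons
6 levels × 1200–1500 iterations × 2–3 runs (±1.5-decade priors, paired
seeds). A parameter is called *identifiable* when its posterior 95%
interval is narrower than half its prior width; coverage is reported over
identifiable parameters only (the rest are prior-dominated by
construction). Posterior-predictive bands are [0.5, 99.5] percentiles over
posterior draws with simulated measurement noise.

## Perturbation analyses

Three scenarios probe the PKD↔transfer coupling at steady state, per
posterior draw: (i) *feedback knockout* — the transfer→PKD activation
channel is removed (`vmax_cer` → 0) and the relative change of `PKDpDAG`
reported (the complementary view — how much of PKD activation the feedback
supports — is the same number with opposite sign); (ii) *transfer +10%* —
a multiplier on `k10` is found by bracketing root-search (relative
tolerance 1e-6) so steady-state J rises by exactly 10%, reporting the
`PKDpDAG` change; (iii) *PKD +10%* — a multiplier on the basal activation
rate `k_act` (PDBu-like activation acts on this channel) targets +10% in
`PKDpDAG`, reporting the J change. Reported percentages are posterior
expectations of the per-draw relative change; "99.5% confidence intervals"
throughout mean the [0.5, 99.5] percentile band (99% central mass).

## Quantification

Standard curves are unweighted OLS with intercept (blot backgrounds shift
intensities; background subtraction is upstream of this package); the
residual SD uses n−2 degrees of freedom. Inverse regression propagates the
coefficient covariance and the new band's residual scatter by the delta
method — `Var(x̂) = (σ² + V_aa + x̂²V_bb + 2x̂V_ab)/b²` — which a seeded
parametric bootstrap confirms to within 5%; estimates at or below zero
intensity-over-intercept are flagged invalid. Endogenous abundance is
`ratio × ectopic molecules / cells`, with input CVs combined in
quadrature.

## Known limitations

* The rate equations are reconstructions consistent with the described
  interaction map, not the study's exact supplementary equations; the
  variant nesting discussed above is a property of this reconstruction.
* Lipids (PI4P, DAG, SM) are not explicit states; OSBP, serine-315
  phosphorylation and alternative DAG sources are out of scope.
* Ectopic (tagged) protein is assumed kinetically identical to endogenous
  and pooled into the same species.
* Whether phospho-forms degrade at distinct rates is unknown; one rate per
  protein is used.
* Desk-scale evidence estimates carry Monte Carlo error of a few `2 log K`
  units; conclusions at that scale are signs and magnitudes, not digits.
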