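# Model and methods

`hepatam` simulates the growth of a tumor seeded in liver tissue as a
hybrid of continuum fields on a 2D lattice and discrete macrophage
agents. The study design it supports contrasts primary-type versus
metastatic-type tumor cells growing on matrix from healthy liver
("control ECM", cECM) versus matrix remodeled by chronic alcohol
exposure ("transitional ECM", tECM), with tumor-associated macrophages
either kept naive or allowed to polarize to the pro-inflammatory M1 or
trophic M2 phenotype.

## Continuum component

All fields live on an `n × n` node-centered square lattice (default
61 × 61 over a 2 mm panel). Lengths are in mm, time in days;
concentrations are normalized to [0, 1].

**Tissue mechanics.** Tumor tissue moves with a Darcy velocity
`v_c = −µ∇P + χ_E∇E`, where `P` is the oncotic/solid pressure, `E` the
ECM density, `µ` the tissue mobility, and `χ_E` the haptotaxis
coefficient. Mass balance for incompressible tissue gives
`∇·v_c = λ_p`, the net proliferation rate, so the pressure solves a
Neumann Poisson problem `−µ∇²P = λ_p − mean(λ_p) − χ_E∇²E` (the mean
subtraction makes the singular system compatible; the pressure carries
a zero-mean gauge). The discretization is the 5-point Laplacian with
mirror (zero-flux) ghosts, and the velocity used to advance the
interface is evaluated on cell faces with the same forward differences
as the Poisson stencil. This staggered form matters: it makes the
discrete divergence identity `∇·v_c = λ_p − mean(λ_p)` exact, and it
makes the haptotaxis term inside and outside the solve cancel
consistently. With node-centered central differences instead, the sharp
ECM dip at the tumor edge produces a spurious inward velocity of the
same magnitude as the physical growth velocity. A corollary of the
conservative closed-box form: when `λ_p ≡ 0` the solve returns
`µP = χ_E E + const` exactly and the *net* face velocity vanishes — a
pure haptotactic drift cannot exist in a closed domain, whatever `µ`.

**Oxygen.** Quasi-steady diffusion
`0 = ∇·(D_σ∇σ) − λ^σ(x)σ + s(x)(1−σ)` with region-wise uptake
(normal tissue 8, proliferating tumor 30, hypoxic tumor `q_σ·σ` with
`q_σ` = 25, necrotic 3; metastatic tumors use 50/45, see below). The
vessel source conductance is
`s = 1_vessel · λ_supply · h · max(0, 1 − P/P_eff)` with hematocrit
`h = 0.45`; writing the source as `s(1−σ)` keeps the linear system an
M-matrix, so the solution lies in [0, 1] by the discrete maximum
principle and any excursion is treated as an error, never clipped.
The pressure modulation `max(0, 1 − P/P_eff)` is the mechanism that
starves large lesions: interior pressure chokes intratumoral
extravasation, oxygen then falls with distance from the rim, and a
hypoxic band and (for primary tumors) a necrotic core develop.

**Cytokines.** Every diffusible signal (TNF-α, TGF-β1, TAF, the M2
growth factor F) obeys one quasi-steady balance
`0 = ∇·(D∇C) + λ_prod(1−C)·1_Ω − λ_circ·1_vessel·C − λ_decay·C`.
The circulation washout is applied proportionally to `C` (a constant
sink could drive the field negative). Production regions: viable tumor
for TNF-α and TGF-β1, hypoxic tumor for TAF, M2-agent-occupied nodes
for F. TAF is treated as a cytokine because no separate transport law
is given for it in the source model family.

**ECM and MDE.** Matrix density evolves by saturating production on
viable tumor and sprout tips (`λ_prod/(1+k_p E)`) and enzyme-mediated
degradation (`λ_deg·E·M/(1+k_d E)`); the matrix-degrading enzyme `M`
diffuses (explicit Euler under its CFL bound `dt ≤ h²/(4D_M)`), is
produced with `(1−M)` saturation by viable tumor and sprout tips, and
decays. With the default constants the interior tumor steady state is
E* = 0.25 on control matrix — deliberately *below* the far-field 0.5,
so the invading rim runs up an outward ECM gradient (haptotaxis aids
invasion) while the interior is partially cleared, as matrix-remodeling
tumors do.

## Vasculature

A pre-existing capillary grid occupies every 10th lattice line for
primary tumors and every 6th for metastatic tumors (the hepatic bed is
more vascular); both spacings divide the grid so capillaries pass
through the seeded lesion. Hypoxic tissue releases TAF; vessel nodes
above the TAF threshold launch sprout tips (0.2/day) that climb the
local TAF gradient on the lattice, with a small random perturbation,
and anastomose when they come within one node of another vessel.
Neovasculature supplies oxygen at a reduced rate (30 vs 150) — sprouts
are leaky and poorly perfused — which also keeps the growth dynamics
from being dominated by the stochastic sprout count.

## Macrophage agents

Naive monocytes extravasate at vessel nodes with probability
`min(1, rate·|∇TAF|·dt)` per step, walk the lattice with 4-neighbor
steps sampled `∝ exp(Δscore)` (chemoattractant up, oxygen and pressure
down, plus a concentric center bias for M1 agents that reproduces the
deeper M1 infiltration), and, inside the tumor microenvironment (mask
plus a 5-node margin), polarize terminally: TNF-α above its threshold
drives M1, TGF-β1 above its threshold drives M2, both-above resolved by
the larger normalized excess `(C−θ)/θ` with ties to M1, at rate 2/day.

Effectors: each M1 agent contributes `λ_NO` to a kill-rate field over a
Chebyshev radius of 2 nodes (~65 µm, consistent with the short NO
diffusion distance); the field subtracts from the proliferation rate in
viable tissue. M2 agents source the growth factor F, which (i) raises a
proliferation boost `λ_M2` by `dλ_M2/dt = λ_F·F·(1−(λ_M+λ_M2))` and
(ii) transiently lowers the local quiescence oxygen threshold
`dQ_OL/dt = λ_OL(1−F)(Q̄_OL−Q_OL) − λ_OT·F·(Q_OL−Q_OL,min)`, clamped to
`[Q_OL,min, Q̄_OL]`.

The net proliferation rate is region-wise: 0 in normal tissue,
`(λ_M+λ_M2)σ − (λ_A+λ_M1)` in proliferating tissue,
`λ_M2σ − (λ_A+λ_M1)` in hypoxic tissue, `−G_N` in necrotic debris.
Necrosis (σ below the necrotic threshold) is irreversible; hypoxic
tissue may recover. The interface advances by converting normal
neighbors of boundary tumor nodes with probability `min(1, v_n dt/h)`
for outward face velocity `v_n`, and retreats through cumulative
bookkeeping: a boundary node whose accumulated `λ_p dt` reaches −1
reverts to normal (the source model family does not specify a shrinkage
rule; this is the package's choice).

## Case calibration

Absolute parameter values for this model family live in supplementary
material that is not available, so the shipped defaults are the
package's own calibration, constrained by the qualitative statements of
the study and its printed endpoints:

* **Metastatic tumors**: TNF-α production 10× the primary baseline (the
  co-culture fold), denser capillary grid, lower necrotic threshold
  (0.15 vs 0.25), higher oxygen demand (uptake 50/45 vs 30/25), and a
  weaker pressure choke (P_eff 0.05 vs 0.01). Together these produce
  hypoxic, barely-necrotic metastatic nodules and necrotic-cored
  primary lesions of comparable naive-case size.
* **Transitional ECM**: far-field density 0.75 vs 0.5 and a
  degradation rate reduced by the same ratio, so the scalar
  production/degradation balance sits 1.5× higher (`calibrate_ecm`
  solves this balance for any requested ratio and the shipped case
  values agree with it).
* **Polarization geometry.** The M1/M2 split emerges from the spatial
  structure of the two cytokine fields rather than from per-agent
  randomness. TNF-α is short-ranged (D 0.05, decay 20 → ~50 µm decay
  length) and strongly washed out at vessels (λ_circ 60); TGF-β1 is
  long-ranged (D 0.5, decay 10). In primary lesions the necrotic core
  produces no TNF-α, so the core and the outer halo are TGF-dominant
  (M2 ≈ 34%) while the viable annulus is TNF-dominant (M1 ≈ 23%). In
  metastatic lesions the hypoxic core remains viable and TNF-rich, so
  M1 dominates (~65%); the small M2 population (~4–5%) arises at
  margin vessel nodes where washout pulls TNF-α below threshold and in
  the outer TGF ring.
* **Growth restriction.** λ_NO is the single knob behind the polarized
  radius difference: metastatic lesions recruit ~4× as many M1 agents,
  so the same per-agent kill rate shrinks them ~15–18% relative to
  polarized primary lesions while primary lesions lose only a few
  percent. Setting λ_NO = 0 removes the difference entirely (the
  ablation test), isolating NO cytotoxicity as the mechanism.

## Numerical and design choices

* Quasi-steady solves use sparse LU (`spsolve`) on the 5-point Neumann
  Laplacian; they agree with a dense reference solve to 1e−8 and better.
* The singular pressure system is gauge-fixed by pinning one node after
  demeaning the right-hand side, then re-centering to zero mean.
* Operator splitting per step (dt = 0.025 d): oxygen → region
  classification → cytokines → sprouting → agent extravasation,
  migration, polarization → effector updates → MDE/ECM → proliferation
  → pressure/velocity → interface advance. Quasi-steady fields must
  precede classification and agent decisions; the rest of the order is
  a fixed convention. dt = 0.025 halves the replicate-to-replicate
  spread of the final radius relative to dt = 0.05 by averaging the
  stochastic interface conversions more finely.
* Problem size: the shipped default grid is 61 × 61 (2 mm panel,
  h ≈ 33 µm), which resolves the oxygen diffusion length (~0.35 mm in
  normal tissue) with ~10 nodes and keeps a full replicate set of the
  four polarized cases within minutes on one CPU; the lattice geometry
  and all operators are resolution-independent.

## What the synthetic assays emulate

`generate_elisa` reproduces the *fold structure* of the indirect
co-culture ELISA — TNF-α 5× higher with M1 than M2 in every tumor
condition, 10× higher for metastatic than primary co-cultures, TGF-β1
flat except a ≤1.3× elevation for primary-with-M1 — with mean-preserving
lognormal replicate noise. Absolute units are arbitrary; only ratios
enter the simulation. `calibrate_cytokines` pools the metastatic:primary
ratio over the three macrophage states (geometric mean), which is
unbiased for the configured fold and three times as replicated as a
single-state ratio. The transwell normalization divides counts by their
control-group mean. What passing these tests shows is that the
calibration pipeline recovers the designed fold structure from noisy
replicates — not that the generator captures plate effects, detection
limits, or biological covariance between cytokines, which it does not
model.

## Limitations

* 2D domain; no vessel regression or flow-dependent remodeling;
  hematocrit is a constant, not a transported quantity.
* Macrophages neither die nor emigrate, so population fractions are
  cumulative over the whole recruitment history.
* The polarization rule is a binary terminal switch with fixed
  thresholds; real TAM phenotypes form a spectrum.
* Replicate-to-replicate spread of the day-13 radius is a few percent;
  the percent-difference endpoints between tumor types carry an n=3
  standard error of ~2–3 percentage points, so individual replicate
  sets can land a few points from the central values.
* The angiogenesis rule set (lattice tips, gradient ascent,
  one-node anastomosis) is a deliberate simplification of full
  flow-coupled network models.
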