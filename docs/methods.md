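# Methods

## The model

`hergcycle` implements a deterministic, mean-field kinetic model of how
adhesion signaling controls the surface expression of the hERG1
potassium channel. Cells seeded on fibronectin (FN) engage β1
integrins; active integrins drive *herg1* transcription; the channel is
translated in the ER (core-glycosylated form R), matures through the
Golgi (fully glycosylated form G), reaches the plasma membrane (closed
S_c / open S_o states), and forms a complex X with active integrins —
closed channels only. Free surface channels are internalized to
endosomes (E), from which they recycle or are degraded; complexed
channels are shielded from that route. Two coarse-grained signaling
modules shape the kinetics:

- a *balanced-inactivation* module: the complex X catalytically turns on
  a fast activator A* (standing in for the girdin–Gαi3–PI3K–Akt
  pathway) and, more slowly, an inhibitor I* that quenches the
  activator. The activator transiently boosts translation, Golgi
  import/export and membrane delivery, producing the pulse that peaks
  near 90 min and then subsides;
- an *internalization* module N* that drives endocytosis of the free
  channel and is itself catalytically inhibited by the activator, so
  endosomal filling dips during the pulse and resumes afterwards.

All species are continuous copy numbers (molecules/cell) in a single
well-mixed compartment; every rate law is polynomial mass action, with
catalysts entering the rate law but not the stoichiometry. Time is
seconds internally; user-facing grids are minutes, with the canonical
reporting grid {0, 5, 15, 30, 45, 60, 90, 120, 180, 240, 300} min.

The network ships as a declarative JSON document
(`data/herg1_integrin_v1.json`, 16 species, 25 reactions) and the
published best-fit rate constants for the three cell lines (HEK-hERG1,
PANC-1, HCT116) as `data/params_table2.csv`. The stoichiometric matrix
has exactly five conservation laws — total integrin, FN binding sites,
activator, inhibitor and internalization-module pools — detected by
exact rational elimination and verified numerically along every
trajectory.

## Reconstruction constants

The published parameter table does not fully determine a closed model;
four constants close the gaps. They are deliberate modeling choices,
fixed (never floated in fits):

- `g_dose = 1` (#/cell): a gene-dosage unit carrier in the
  integrin-catalyzed transcription law, absorbing the concentration
  unit of its second-order rate constant (the one unit inconsistency
  `validate_units` reports for the default model);
- `N0 = 1e3` molecules: the internalization-module pool size;
- `phi0 = 0.25`: the fraction of FN binding sites effectively available
  to cells *before* seeding. Because the integrin pool far exceeds the
  FN-site pool, the fold change of the engaged-integrin moiety after
  seeding equals 1/phi0 exactly, and every integrin-driven fold
  observable saturates near that value at late times. The assays put
  the resting readouts within roughly fourfold of their peaks, which
  pins the resting engagement near 25% of peak; phi0 = 0.25 encodes
  that. (A much smaller phi0 forces ~1/phi0-fold responses,
  irreconcilable with the printed curves.)
- `k_dd = 1e-4 s⁻¹`: direct (endosome-independent) degradation of the
  free closed surface channel, a route the study describes
  qualitatively. It is kinetically essential here: at basal complex
  counts the activator module saturates ON, which shuts the N-module
  endocytic sink; without any activator-independent membrane turnover
  the resting state would have no reachable steady state. The value
  (~2.8 h turnover) is a typical constitutive membrane-protein
  turnover scale.

## Basal state and seeding

The resting (BSA, no-FN) condition is the steady state reached from an
unengaged start — pools loaded (B0, A0, I0, N0, E0, phi0·F0 of FN
sites), pathway empty. `pre_equilibrate` integrates with LSODA over
expanding horizons (to 1e7 s by default, BDF fallback if the corrector
stalls) until the scaled rate residual falls below 1e-8 s⁻¹; the
integration tolerances are looser than trajectory defaults because only
the endpoint matters and the residual check is the accuracy guarantee.
The basal fixed-point equations can have more than one branch
(activator ON/OFF); the unengaged start selects the physically
meaningful one, which is why basal states are always equilibrated from
scratch rather than warm-started. Seeding is an instantaneous
availability step: the withheld (1 − phi0)·F0 FN sites are added to the
free-FN pool at t = 0 with every other species continuous.

## Numerics

- Production integration: LSODA (via `scipy.integrate.odeint`) with an
  analytic Jacobian assembled from the same flattened reaction arrays
  as the right-hand side; rtol 1e-6, atol 1e-3 molecules. The rate
  constants span ~11 orders of magnitude, so a stiff-capable method is
  mandatory.
- Kernels are JIT-compiled with numba when available and fall back to
  identical pure-Python code otherwise.
- Negative states: excursions within the solver error weight
  (atol + rtol·|y|) are clipped to zero; anything larger raises.
- The independent cross-check integrator is a fixed-step classical RK4.
  Its step (5e-6 s on the 60 s check horizon) is dictated by the fastest
  basal eigenvalue (~2.4e5 s⁻¹ from the activator-driven
  internalization shutdown), which puts the popular 1e-4 s step outside
  the explicit stability region.
- Conservation-law detection uses sympy's exact rational null space,
  scaled to primitive integer vectors; tests verify the basis against
  an independent SVD rank computation.

## Synthetic data

No raw data are deposited, so the generator emulates the *printed*
kinetic anchors. Pulse readouts (membrane hERG1, open channels,
complex, fully glycosylated pool) follow a gamma-type pulse
p(t) = (t/t_p)^h · exp(h(1 − t/t_p)) blended with a baseline drifting
from 1 to the late plateau, so curves start exactly at 1 and hit the
peak fold exactly at t_p = 90 min. Defaults (HEK): peak fold 4.0;
plateaus 1.3 (membrane, complex, glycosylated) and 1.8 (open channels,
encoding the partial current relaxation); h = 3. mRNA is saturating,
passing 2.0-fold at 120 min and plateauing at 2.3. The endosomal
readout dips to 0.4 at 90 min and refills. Cancer profiles reuse the
shapes with faster post-peak relaxation (h = 4, plateaus 1.15/1.4).
Replicates are i.i.d. multiplicative Gaussian (CV 0.10, truncated at
zero), n = 3 — the s.e.m. scale of the plotted data. The generator
does *not* emulate assay-specific nonlinearities (antibody saturation,
densitometry floors) or replicate pairing; passing tests therefore
validate the kinetic machinery, not instrument models.

The WB-derived anchor is the fold of the fully glycosylated pool, not
of the glycosylated *fraction*: a ratio bounded by 1 cannot quadruple.
The fraction itself is exposed as an (unnormalized) observable.

## Fitting

The cost is a weighted sum of squared deviations between the model's
fold-change observables and replicate means on the dataset grid
(weights default to equal; simulation failures score +inf and are
simply rejected). The search is the study's stochastic Monte-Carlo
procedure: each iteration perturbs a random pair of floating parameters
multiplicatively — log-space steps of half-width ln(1.1), since
parameters span ten decades — and accepts only strict improvements
(zero-temperature). Stopping: relative best-score decrease below
`rel_tol` per `patience`-iteration window, or the iteration cap. Fixed
parameters (open/close rates, pools, reconstruction constants) are
never touched. Everything is reproducible from one seed.

The end-to-end anchor pipeline starts the search from a documented
educated guess rather than the raw published values, mirroring the
study's own manual-exploration step. The published constants encode
second-scale mRNA turnover (k_dm ≈ 0.105 s⁻¹) and inhibitor relaxation
(k_ie+ ≈ 0.13 s⁻¹) that cannot express a 90-minute pulse in this
reconstruction, and the greedy search cannot cross the flat cost
plateau that separates the pulseless compromise it finds there from the
pulsed regime. The guess re-reads five timescales directly off the
assays: mRNA lifetime ~3.5 h (saturating fold over the 5 h window),
ER→Golgi ~3 min, Golgi→membrane ~30 min, inhibitor build-up over ~3 h
(pulse duration ~90 min), and the basal activation/inactivation balance
of the activator at the basal complex count. Because a greedy
stochastic search can still stall by chance, the pipeline restarts with
a reseeded stream (up to twice) if the fitted membrane course has no
interior maximum, keeping the best pulsed result.

### Parameter recovery

Full 22-parameter identifiability is not claimed — the model is sloppy.
The recovery harness instead refits five designated constants (k_on,
k_off, k_a, k_e, k_tg) on noiseless model-generated data in a testbed
regime where each is individually rate-limiting: complex lifetime on
the assay timescale (k_off = 5e-4 s⁻¹) so binding and unbinding
separate instead of collapsing into their ratio; sub-saturated complex
(small g_dose) so the binding constants move the readouts;
trafficking-limited delivery (small k_tg, boost constants lowered so
the basal route dominates); and endocytosis comparable to constitutive
turnover (k_e·N* ≈ k_dd) with a functioning activator pulse modulating
N*. In saturated regimes — including the published parameter set —
several of these constants have essentially no effect on fold
observables (verified by direct cost scans), so recovery there would be
meaningless. Starts are offset ×2/×0.5 from truth; 6000 iterations
recover all five within 10%.

## Sensitivity

Ensembles perturb every floating parameter independently and uniformly
within ±10% of its best-fit value (linear scale, the natural reading of
the study's convention), 100 members by default, seeded. Envelopes are
pointwise min/max across surviving members (percentile bands optional);
members that fail to simulate are dropped and counted, with >10%
failures an error.

## Interventions

Virtual perturbations are parameter-override presets: scDb (complex
formation blocked, k_on = 0), PTX and girdin siRNA (activator branch
silenced: k_a = k_c+ = k_g+ = k_tg+ = 0), E4031 (channel trapped open
and integrin-incompetent: k_o− = 0, open-channel readout flagged
blocked). These are deliberate coarse simplifications of the drug
mechanisms, adequate for the qualitative contrasts they are tested
against.

## Problem sizes

Default workloads are sized for a single CPU: the anchor pipeline runs
25,000 cost evaluations of the 16-species stiff system (a few minutes),
the recovery harness 6,000, the ensemble 100 simulations. All are
parameters, not constants, and scale up transparently.

## Known limitations

- The parameter→reaction mapping is a reconstruction from the published
  rate-constant table, its units, and the qualitative description of
  the network; the original equation set was not available to check
  against. The network is data (JSON), so corrections are edits, not
  code changes.
- With the published constants verbatim, the reconstruction does not
  produce the biphasic membrane response; the pulse regime is reached
  by refitting from the educated guess. Cell-line contrasts of the
  published table (e.g., faster complex dissociation in cancer lines)
  are preserved and reported by the comparison tool regardless.
- The complex fold observable saturates at 1/phi0 whenever the FN-site
  moiety is exhausted, a structural ceiling of the
  integrin-pool ≫ FN-pool assignment.
- Deterministic mean field only: no stochastic simulation, no spatial
  compartments, no delay terms.
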