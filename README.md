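# hergcycle

Kinetic modeling of integrin-driven hERG1 membrane cycling.

In many cancer cells the hERG1 potassium channel forms a macromolecular
complex with β1 integrins on the plasma membrane. Seeding cells on
fibronectin triggers a striking biphasic response: hERG1 current,
surface channel density and hERG1/β1 complex all rise about fourfold,
peak near 90 minutes, and relax back over five hours, while *herg1*
mRNA roughly doubles and stays up. `hergcycle` is a reusable
implementation of a whole-cell mass-action model of this cycle —
transcription, ER/Golgi maturation, membrane delivery, open/closed
gating, complex formation, endocytic recycling and degradation, wired
to a balanced-inactivation signaling module (a fast activator standing
in for the girdin–Gαi3–PI3K–Akt pathway, quenched by a slower
inhibitor) — together with the study-style analysis tools around it:

- a generic reaction-network engine (declarative JSON networks, stiff
  LSODA integration with analytic Jacobians, steady-state
  pre-equilibration, exact conservation-law detection);
- the concrete 16-species hERG1/β1 network with the published best-fit
  rate constants for HEK-hERG1, PANC-1 and HCT116 cells, plus virtual
  interventions (PTX, scDb antibody, E4031, girdin siRNA);
- observable mappings to the assay readouts (flow cytometry/IF membrane
  signal, patch-clamp open-channel count via I = γ·N_open·(V_m − E_K),
  co-IP complex, western-blot glycosylation, RQ-PCR mRNA, Rab5
  endosomal signal), all as fold change over seeding time;
- a seeded synthetic-data generator reproducing the printed kinetic
  anchors with replicate noise (no raw data were deposited);
- the stochastic Monte-Carlo pairwise-perturbation least-squares fitter;
- ±10% parameter-perturbation ensembles and trajectory envelopes;
- a `hergcycle` command-line interface (simulate, generate-data, fit,
  sensitivity, compare, recover).

The model is deterministic mean-field: continuous copy numbers x
(molecules/cell) obey dx/dt = S·v(x), with S the stoichiometric matrix
and v_j = k_j ∏ x_i^(s_ij) ∏ x_m^(o_mj) mass-action fluxes in which
catalytic modifiers (orders o) enter the rate but not the
stoichiometry. See `docs/methods.md` for the science, parameter
conventions and numerical choices.

## Worked example

Fit the reconstructed network to a synthetic HEK time course built from
the study's kinetic anchors, then inspect the fitted kinetics:

```python
from hergcycle.workflows import anchor_fit_pipeline

summary = anchor_fit_pipeline(cell_line="HEK-hERG1", seed=1)
print(f"cost {summary.fit.score_history[0]:.1f} -> {summary.fit.best_score:.1f}")
print(f"membrane peak {summary.peak_fold['membrane_total']:.2f}-fold "
      f"at {summary.peak_time_min['membrane_total']:.0f} min")
print(f"half-decay of the membrane elevation at "
      f"{summary.half_decay_time_min:.0f} min")
```

```
cost 126.2 -> 48.5
membrane peak 3.66-fold at 91 min
half-decay of the membrane elevation at 212 min
```

The fitted model rises from its resting state after the fibronectin
step, peaks close to fourfold near 90 minutes, and has shed half of its
peak elevation by ~210 minutes — the biphasic membrane cycle, within
the 300-minute window of the experiments.

Cross-cell-line contrasts of the published parameters:

```bash
hergcycle compare --out-dir out/
```

prints, among all parameters, the complex dissociation rate k_off with
ratios PANC-1/HEK ≈ 3.23 and HCT116/HEK ≈ 2.19 (faster dissociation in
the cancer lines) and a recycling rate k_te slower in both.

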