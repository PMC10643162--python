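# backdoorflux

Kinetics and pathway analysis of inorganic-phosphate (P_i) release from
actin filaments.

After polymerization, actin hydrolyzes its ATP quickly but releases the
cleaved phosphate slowly (half-time of minutes) through a transiently
opening "backdoor" between the nucleotide site and the filament
surface, gated by the R177–N111 hydrogen bond.  This package implements
the computational analyses that establish and quantify that mechanism,
for structural biologists and cytoskeleton biophysicists who want to
run the same pipeline on their own (or synthetic) data:

- **Bulk kinetics** (`bulk_kinetics`) — two-channel (pyrene + phosphate
  sensor) fluorescence timecourses interpreted with the scheme
  A →(k_poly) B ⇌(k−Pi / k+Pi) C + P_i, where A is monomeric ATP-actin,
  B filamentous ADP-P_i-actin and C filamentous ADP-actin.  Fits
  I(t) = 1 − e^(−k_poly t) to the pyrene channel, then the single free
  rate k−Pi to the sensor channel, and derives lower bounds on the rate
  enhancement of fast-releasing mutants.
- **Single-filament kinetics** (`filament_kinetics`) — depolymerization
  velocity versus filament age τ = t + (L₀ − L_t)/v_pol, fitted with
  1/v_depol = a·e^(−bτ) + c, where b = k−Pi, c = 1/v_depol,ADP and
  a + c = 1/v_depol,ADP·Pi; the barbed-end release rate follows as
  k−Pi,BE = v_ADP (k_off^ADP·Pi − v_ADP·Pi)/(v_ADP·Pi − v_ADP) with
  k_off^ADP·Pi fixed at 0.2 s⁻¹.
- **Egress-path analysis** (`egress_paths`) — escape detection at a
  1.4-nm cutoff, B-spline smoothing and 100-point arc-length
  discretization, hierarchical path clustering (k = 4), and the
  longitudinal path collective variable
  s = [Σᵢ (i−1) e^(−λ‖x−xᵢ‖²) / Σᵢ e^(−λ‖x−xᵢ‖²)]/(N−1) with λ = 325 nm⁻².
- **Backdoor classifier** (`backdoor_classifier`) — 48-residue × 4-bin
  contact-occupancy maps (0.75-nm cutoff, bins over pathCV s) feeding a
  logistic regression that labels escapes through the R177–N111 gate;
  p_BD is the fraction of a swarm so labeled.
- **Structure observables** (`structure_observables`) — backdoor and
  loop distances, χ1 torsions, the ΔRMSD steering coordinate with its
  moving harmonic restraint U(x,t), and helical rise/twist from
  consecutive subunits by Kabsch superposition + screw decomposition.
- **Synthetic data** (`synthetic_data`) — generators for every input:
  noisy bulk traces, Gillespie-style filament cohorts with nucleotide
  aging and optional pauses, and a metadynamics-biased Langevin sampler
  escaping a gated toy landscape with ground-truth channel labels.

## Worked example

```bash
python examples/filament_aging.py
```

```
k_release core  = 0.0062 1/s (planted 0.006)
v_depol,ADP     = 6.55 subunits/s (planted 6.7)
v_depol,ADP-Pi  = 1.74 subunits/s (predicted 1.69)
k_release BE    = 2.09 1/s (planted 2.0)
```

A cohort of 100 simulated filaments grows as ADP-P_i actin, then
depolymerizes; the measured velocity matures from the slow ADP-P_i
value to the fast ADP value as interior subunits release their
phosphate.  The aging fit recovers the planted interior release rate
(b ≈ 0.006 s⁻¹, the same order as the bulk-assay rate 0.0065 s⁻¹, half-time
≈ 107 s), the ADP depolymerization velocity 1/c and the observed
ADP-P_i velocity 1/(a+c), from which the ~300-fold faster barbed-end
release rate is derived.

The other scripts in `examples/` demonstrate the bulk-assay fits, the
biased escape swarms with path clustering, the classifier benchmark
(300 trajectories / 70 positives, 75-sample stratified test set,
accuracy ≥ 0.9) and the helical-parameter estimator (rise 27.58 Å,
twist −166.5° recovered to machine precision from an ideal stack).

A thin CLI mirrors the library:

```bash
backdoorflux simulate-filaments --out traces/ --seed 1
backdoorflux fit-depol --traces traces/ --v-pol 15
backdoorflux simulate-swarm --out swarm/ --seed 1
backdoorflux helical --pdb model.pdb --chains A,B,C,D,E
```

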