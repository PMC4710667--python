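# itlie — transition-aware iterative LIE binding free energies

`itlie` computes protein–ligand binding free energies with the linear
interaction energy (LIE) method from per-frame ligand–surroundings
interaction-energy trajectories, combining multiple short parallel MD
simulations with Boltzmann weights and — the part that gives the package its
name — automatically restricting the energy averages to *stationary* parts of
each trajectory, i.e. time windows free of configurational transitions.

It is aimed at computational chemists running iterative LIE campaigns on
flexible targets (the motivating system is ligand binding to Cytochrome P450
enzymes, where multiple binding poses and active-site rearrangements are the
rule): the package consumes the energy time series that MD engines such as
GROMACS export as XVG text, not trajectories or coordinates.

## The model

For one simulation, the LIE estimate with van der Waals and electrostatic
scaling parameters α and β (no offset term) is

    ΔG_calc = α (⟨V_vdW⟩_bound − ⟨V_vdW⟩_free) + β (⟨V_el⟩_bound − ⟨V_el⟩_free)

When N parallel simulations of one complex sample different local parts of
conformational space, their results are combined with Boltzmann weights

    W_i = exp(−ΔG_calc,i / k_B T) / Σ_j exp(−ΔG_calc,j / k_B T)

    ΔG_calc = α Σ_i W_i ΔV_vdW,i + β Σ_i W_i ΔV_el,i

The bound-state averages ⟨V⟩_bound,i are only meaningful over a local part of
conformational space, so each trajectory is screened for configurational
transitions first: each energy channel is low-pass filtered by Fourier
truncation (15 retained elements by default), a degree-1 smoothing spline
(s = 999) is fitted to the filtered signal, and frames where the absolute
spline gradient exceeds 0.2 kJ mol⁻¹ ps⁻¹ in either channel are marked
transitional.  The averaging span is then chosen from the stationary windows
by a three-step protocol with minimal window length L: take the earliest
window of length ≥ L, truncate it to its first L ps (the `filter_ext` variant
keeps the whole window), and if no window reaches L fall back to the longest
window with a warning.  α and β are calibrated against experimental
affinities by deterministic RMSE minimisation, with leave-one-out SDEP as the
generalisation estimate.

## Worked example

```python
from itlie import (StateSegment, TrajectorySpec, gen_trajectory,
                   detect_transitions, select_span, average_over_span,
                   gen_lie_dataset, calibrate, sdep_loo)

# a 1 ns synthetic bound-state run: one configurational transition at 500 ps
spec = TrajectorySpec(
    segments=(StateSegment(500.0, -160.0, -80.0),
              StateSegment(480.0, -120.0, -80.0)),
    transition_width=20.0, noise_sd=5.0, seed=7)
traj, truth = gen_trajectory(spec)

tset = detect_transitions(traj)
span = select_span(tset.windows, L=200.0, mode="filtered")
mean_el, mean_vdw = average_over_span(traj, span)

ds = gen_lie_dataset(12, 4, alpha_true=0.45, beta_true=0.09, seed=1)
report = calibrate(ds)
```

which prints, with the formatting of the example script:

```
transitions: [(472, 534)]
windows:     [(0, 472), (534, 1000)]
span: 0-200 ps  <V_el>=-160.86  <V_vdW>=-80.80 kJ/mol
alpha=0.4500  beta=0.0900  RMSE=1.84e-13  SDEP=1.84e-13 kJ/mol
```

The detector brackets the true transition (500–520 ps) with a smear set by
the low-pass passband; the protocol then averages over the first 200 ps of
the first stationary window, recovering the first segment's mean energies to
within the thermal-noise standard error.  On the noise-free synthetic
calibration set the fitted α and β match the generating parameters and both
error measures vanish to numerical precision.

The same workflow is scriptable from the shell:

```
itlie simulate --spec spec.yaml --seed 3 --out sims/
itlie detect   --xvg sims/stepper.xvg
itlie select   --xvg sims/stepper.xvg --free-el -100 --free-vdw -20 -L 200 --out rec.json
itlie stats    --records records/
itlie calibrate --dataset dataset.csv --records records/ --out model.json
itlie predict  --model model.json --records records/
```

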