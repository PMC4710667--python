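# Methods

## Problem setting

End-point LIE predictions hinge on average ligand–surroundings interaction
energies, ⟨V_el⟩ and ⟨V_vdW⟩, taken from bound-state MD.  For flexible
targets a single trajectory may visit several protein–ligand configurations;
averaging across a configurational change mixes energy levels that belong to
distinct local minima and biases the estimate.  The iterative LIE framework
sidesteps exhaustive sampling by running several short simulations from
different starting poses and combining their per-simulation estimates with
Boltzmann weights — but that combination is only valid when each average
covers a single local part of conformational space.  `itlie` therefore
detects transitions inside each trajectory from the energies themselves
(ligand reorientation and active-site rearrangement show up as rapid shifts
in the channel means, whereas structural observables would need a case-by-
case definition) and averages only over stationary windows.

## Transition detection

Per channel (electrostatic and van der Waals, treated independently and
combined by union):

1. **Low-pass Fourier filter.**  The one-sided spectrum is truncated after
   `n_fourier` = 15 elements (DC retained, so the mean is preserved
   exactly) and inverse-transformed.  With the default 500-frame, 2-ps
   series this keeps periods ≳ 71 ps — slow enough to suppress thermal
   fluctuation but fast enough to keep genuine level shifts.
   `n_fourier` is an absolute count, chosen for 1 ns / 500-frame series;
   for substantially different trajectory lengths it should be rescaled to
   keep the passband comparable.
2. **Smoothing spline.**  A degree-1 (`spline_degree`) smoothing spline with
   smoothing factor `spline_smooth` = 999 (kJ mol⁻¹)² is fitted to the
   filtered series.  The factor bounds the spline's total squared residual:
   for a stationary 500-frame channel whose filtered noise is ≈1–2 kJ mol⁻¹
   the budget is loose and the fit collapses to a near-horizontal line,
   while any real level shift (tens of kJ mol⁻¹, residual ≫ 999) forces the
   spline to follow it.  This is what makes the gradient test quiet on
   stationary data.
3. **Gradient threshold.**  The spline values at the frame times are
   differentiated by central differences (one-sided at the ends, so output
   length equals input length); frames with |dV/dt| >
   `gradient_cutoff` = 0.2 kJ mol⁻¹ ps⁻¹ in *either* channel are
   transitional (an intersection rule is available via
   `FilterSettings.channel_rule`).  Maximal runs of transitional frames
   become half-open transition intervals [t_first, t_last + dt); the
   complementary intervals are the stationary windows, and the two sets
   tile the trajectory's time range exactly.

**Boundary handling.**  Truncating the spectrum of the raw series treats it
as periodic; when a trajectory starts and ends on different energy levels,
the wrap-around seam acts like an extra step and rings into both ends of the
series.  On synthetic one-step trajectories at step/σ = 8 this produced
spurious transition intervals at the edges in every single run.  The
detector therefore filters an even (mirror) extension of the series, which
is continuous at both seams, retaining 2·`n_fourier` − 1 bins of the doubled
spectrum — the same physical cutoff frequency as `n_fourier` bins of the
original.  The raw periodic truncation remains available as
`lowpass_fourier(..., extension="periodic")` and via
`FilterSettings(extension="periodic")`.

**Resolution.**  The retained passband smears a sharp step over roughly
±35 ps, so detected transition intervals are wider than the underlying
event and window edges carry an uncertainty of that order.  On 200 seeded
one-ramp trajectories (step/σ = 8, presets above) the pipeline recovers
exactly one transition containing the true midpoint in ≈97 % of runs, and
the median worst-edge deviation from a brute-force two-segment
least-squares changepoint is ≈36 ps.  A per-run guarantee much below the
smear width is not achievable without widening the passband, which would
admit more thermal noise.

Degenerate inputs: series shorter than 2·`n_fourier` frames skip the filter
with a logged warning (truncation would remove nothing meaningful); fewer
than 4 frames is an error.

## Window selection and averaging

Given the stationary windows and a minimal length L (ps):

1. the earliest window with length ≥ L is selected;
2. in `filtered` mode the window is truncated to its first L ps; in
   `filter_ext` mode the full window is kept (more frames, same locality);
3. if no window reaches L, the longest window is used in full, ties broken
   by earliest start, and the selection is flagged (`fallback=True`) with a
   logged warning.

All intervals are half-open on the file's own time axis (no re-zeroing), so
windows 0–230/500–1000 ps with L = 200 give span 0–200 ps, and with L = 400
give 500–900 ps (`filtered`) or 500–1000 ps (`filter_ext`).  Averages are
plain arithmetic means of the **raw** energies over frames with
t_start ≤ t < t_end — the filter only decides *where* to average, never what
is averaged.  The `unfiltered` baseline averages the first L ps regardless
of transitions.

Time accounting per simulation: `used_time` runs from the first production
frame to the end of the chosen span (a span ending at 900 ps costs 900 ps of
simulation, even if averaging started at 500 ps).  `corrected_time` equals
`used_time` except under fallback, where it charges the full trajectory
length: only a completed run can prove that no window of length L exists.
The ensemble summary reports mean used time, mean corrected time and the
fraction of simulations for which a window ≥ L was found.

## LIE model and calibration

* Single simulation: ΔG = α·ΔV_vdW + β·ΔV_el, no offset term.
* Weights: W_i = exp(−ΔG_i/k_BT)/Σ_j exp(−ΔG_j/k_BT), computed with
  max-subtraction so arbitrarily favourable simulations cannot overflow;
  weights always renormalise to 1 within 1e-12.
* Weighted model: ΔG = α·Σ W_i ΔV_vdW,i + β·Σ W_i ΔV_el,i; N = 1 reduces
  exactly to the single-simulation equation.

Temperature defaults to 300 K with k_B = 0.0083145 kJ mol⁻¹ K⁻¹; both are
fields of `LIEParameters`.  The weights are a *direct* function of the
candidate (α, β) — ΔG_i in the weight formula is the single-simulation value
at those parameters — so the three equations close without an inner
fixed-point iteration; the "iterative" character lives in the outer
optimisation, which re-evaluates the weights at every candidate.

**Optimizer.**  Calibration minimises the RMSE between weighted predictions
and experimental ΔG over ligands.  Because the weights make the objective
non-linear in (α, β), a deterministic two-stage scheme is used: a vectorised
coarse grid over α, β ∈ [−1, 1] in steps of 0.01 (generous for the ≈0.4/0.1
values typical of CYP models), then Nelder–Mead refinement from the best
grid point to 1e-6 on the parameters.  No stochastic optimizer is involved,
so calibration is bit-reproducible.

**Validation.**  SDEP is the root-mean-square leave-one-out prediction
error with denominator N (each ligand held out, the model recalibrated from
scratch on the rest); the per-fold (α, β, RMSE) table is returned alongside.
On noise-free synthetic datasets generated at known (α*, β*), calibration
recovers the parameters to <1e-3 and SDEP vanishes — parameter recovery is
the primary correctness surface for the modeling half, since the original
MD energy data behind published CYP calibrations is not redistributable.

## Synthetic data

`gen_trajectory` emulates the detector's own model of reality: channel
means constant within a conformational state, linear ramps of
`transition_width` (default 20 ps) between states, and i.i.d. Gaussian
per-frame noise (`noise_sd`, default 5 kJ mol⁻¹) on each channel, optionally
AR(1)-correlated (`ar1`) since real MD energies are autocorrelated.
Defaults produce a 1 ns trajectory at dt = 2 ps (500 frames).  Ground-truth
transition intervals (the ramps) are returned with the trajectory.

What this does *not* emulate: energy drift within a state, non-Gaussian
tails, correlated el/vdW fluctuations, and transitions faster or slower
than the ramp model.  Passing tests therefore demonstrate that the pipeline
is correct under its own stationarity assumption, not that the presets are
optimal for any particular protein.

`gen_lie_dataset` draws per-simulation ΔV pairs uniformly (defaults span
magnitudes typical of drug-like ligands in a CYP site) and sets each
ligand's "experimental" ΔG to the weighted-model value at known (α*, β*)
plus optional Gaussian noise, turning calibration into a recovery problem
with an exact answer.

## Known limitations

* The filter presets (15 elements, s = 999, cutoff 0.2) were designed for
  1 ns / 500-frame energy series; other sampling regimes need rescaled
  settings, which the package exposes but does not auto-tune.
* Window-edge placement is uncertain at the ±35 ps scale of the passband
  smear; downstream averages are robust to this because window interiors
  dominate, but the edges should not be over-interpreted.
* Only two energy channels are considered; transitions visible in neither
  (e.g. iso-energetic reorientations) are invisible by construction.
* The equilibration phase is assumed to be removed upstream; the protocol
  counts time from the first frame present in the file.
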