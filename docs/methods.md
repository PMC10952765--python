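# Methods

Numerical model, conventions, and limitations of the `blochsim` solver.

## Physical model

Each phantom is a set of non-interacting isochromats (point
magnetizations) with position `(x, y, z)` m, equilibrium magnetization
`M0`, relaxation times `T1`, `T2` s, off-resonance `Δω` rad/s, and an
optional displacement field `motion(t)`. In the rotating frame the
effective field seen by a spin is

```
B_eff = (Re B1, Im B1, G(t)·x(t) + Δω/γ)
```

with `B1` the complex RF envelope (T), `G` the gradient vector (T/m),
and `γ = 2π × 42.58e6 rad/s/T` by default (the value that reproduces the
printed conversion constant `gamma_scaled(γ) = γ × 1e−9 =
0.267538 rad/µs/mT`; override `Scanner.gamma` for CODATA).

Sign convention: a positive field rotates transverse magnetization
clockwise, i.e. the phase accrued over a step is `φ = −γ B Δt`.

## Operator splitting

Each time step applies (1) the exact rotation generated by the field,
then (2) exact T1/T2 relaxation over the step. This is first-order
splitting with a locally third-order rotation, so the global error is
second order in the step size during shaped RF
(`tests/test_acceptance.py::test_08` measures a slope ≥ 2) and the
rotation itself is exact whenever the field is constant over the step.

Two regimes:

- **Excitation** (any node in the step span has `B1 ≠ 0`): the rotation
  is applied in SU(2) spinor form with Cayley–Klein parameters

  ```
  α = cos(φ/2) − i n_z sin(φ/2),   β = −i (n_x + i n_y) sin(φ/2)
  ```

  where `n` is the unit field direction and `φ = −γ|B|Δt`. Per step the
  kernel uses the left-node B1 sample (sample-and-hold envelope), the
  step-average gradient (trapezoid-consistent), and the midpoint
  position for moving spins.

- **Free precession** (`B1 = 0` over the whole block): the transverse
  phase is the exact integral `φ_k = −γ ∫ B_z dt` accumulated with the
  trapezoidal rule, which is *exact* for piecewise-linear gradients
  because every gradient vertex is a node. T2 decay is applied at each
  needed node; T1 recovery once per block (z is not observed inside a
  precession block). For static phantoms the phase separates into
  per-node scalars times spin coordinates (an outer product), evaluated
  only at ADC nodes.

## Sequence-aware time stepping

`discretize.critical_times` builds the node grid from:

- block boundaries,
- every gradient vertex (trapezoid exactness),
- RF envelope *change points* — boundaries between raster samples with
  different values; runs of equal samples carry no field transition, so
  the node set depends only on the field, not on how finely the pulse is
  rasterized (this makes a Pulseq round trip, which re-rasterizes RF to
  the 1 µs raster, simulate identically),
- subdivision of nonzero RF runs at spacing ≤ `dt_rf` (default 10 µs),
- every ADC sample time,
- fill-in nodes so no gap exceeds `dt` (default 1 ms; only required for
  moving spins, since static precession is exact on vertices).

`partition` splits the node axis into ~`n_blocks` spans tagged
excitation/precession. Boundaries are pushed forward so they never
bisect an RF pulse's node run or one ADC event's sample span; with the
step-average-gradient convention above, results are invariant to
`n_blocks` and to the spin-chunk count `n_threads` to ≤ 1e−12 relative
(acceptance criterion 5).

## Phantoms and sequences

- `column_phantom`: four 50 mm segments along y, `M0 = [1, 0.5, 1, 0.5]`,
  `T1 = T2 = [100, 50, 100, 50] ms`, 1 mm spacing (200 spins).
- `circles_phantom`: 50 mm disc with a 25 mm inner disc
  (`T1 = T2 = 50 ms`, `Δω = 200 rad/s`) inside an annulus
  (`T1 = T2 = 100 ms`, on-resonance).
- `pseudo_brain_phantom`: seeded multi-ellipse stand-in with three
  tissue classes and an optional smooth off-resonance field.
- `epi_sequence`: single-shot GRE or SE EPI, hard RF pulse, serpentine
  flat-top sampling (no ramp sampling), echo spacing recorded in
  `definitions`.
- `spiral_sequence`: Archimedean spiral, piecewise-linear arbitrary
  gradients with vertices chosen so trapezoid areas reproduce the exact
  k-space increments (`g_next = 2Δk/(cΔt) − g_prev`), 0.9× amplitude and
  slew margins, per-interleave rewinders so each shot starts at k = 0.
- `mrf_bssfp_sequence` + `mrf_schedule`: inversion-prepared bSSFP train
  with seeded flip patterns (smooth gradient-noise "perlin", sinusoid,
  or a two-segment `paper_mix`), TRs uniform in [14.5, 18] ms rounded to 1 µs,
  TE = 5 ms, TI = 50 ms, balanced gradients each TR.

## Reconstruction and MRF

- `recon_cartesian_epi`: reverse odd rows, centered 2-D inverse FFT.
- `recon_adjoint`: conjugate-phase adjoint
  `img(r) = (1/N) Σ w_j s_j exp(+2πi k_j·r)` with uniform or ramp
  (|k|) weights; the k-trajectory `k(t) = (γ/2π)∫G dτ` is attached to
  each readout by the engine (with refocusing-time negation for SE).
- MRF dictionary: ideal-pulse fingerprint recursion using the production
  spinor/relaxation kernels (invert, relax TI, then per TR: rotate,
  relax to TE, record, relax to TR). Grids: T1 = 300:10:2500 ms (221),
  T2 = 40:4:348 ms (78; the last step that fits under 350 ms). Matching
  maximizes |complex dot| of unit-norm fingerprints, with a 5 %
  first-frame magnitude mask.

## Validation oracle

`oracle.reference_simulate` is a deliberately independent brute-force
integrator: uniform 1 µs grid plus exact ADC times, midpoint field
sampling, explicit 3×3 Rodrigues rotation matrices, its own sequence
field sampler. It shares only the data types with the production solver,
so the ≤ 0.1 % MAD agreement (measured ≈ 2.2e−4 %) is evidence of
correctness rather than a tautology. `convergence_order` fits the
log-log error slope of the excitation kernel against a 16× refined
Rodrigues reference and returns `inf` when all errors sit below the
reference's own roundoff floor (`4 eps × n_ref_steps`).

## File formats

- **Pulseq** (`.seq` text, v1.4; v1.2/1.3 read with [DELAYS] and legacy
  column layouts): [BLOCKS]/[RF]/[TRAP]/[GRADIENTS]/[ADC]/[SHAPES]/
  [DEFINITIONS]. Shapes use the RLE derivative codec with samples
  quantized to 1e−9 before differencing (a repeated value followed by a
  count means count+2 repeats; a stored stream as long as `num_samples`
  is taken as uncompressed). Shape values are written with `repr()` so
  the text round trip is bit exact. RF is expanded onto the 1 µs raster;
  amplitudes are stored in Hz (`γ/2π` scaling). Trapezoids and
  3-vertex triangles go to [TRAP]; other piecewise-linear gradients to
  [GRADIENTS] with time shapes. Round-trip fidelity is limited only by
  raster quantization (timing stored in integer µs, delays in integer
  µs, shape samples quantized at 1e−9 relative to peak).
- **Raw data** (HDF5): `/header` attributes (dicts/lists JSON-encoded),
  `/acq{i}/data`, `/t`, `/traj`. Exact round trip.

## Parameters and defaults

| parameter | default | meaning |
| --- | --- | --- |
| `SimConfig.dt` | 1e−3 s | max node gap (motion accuracy) |
| `SimConfig.dt_rf` | 1e−5 s | max step during nonzero RF |
| `SimConfig.n_blocks` | 20 | target simulation-block count |
| `SimConfig.n_threads` | 1 | spin-chunk count (results invariant) |
| `Scanner.B0` | 1.5 T | static field (informational) |
| `Scanner.Gmax` | 60 mT/m | gradient amplitude limit |
| `Scanner.Smax` | 500 T/m/s | slew-rate limit |
| `Scanner.raster_time` | 1 µs | RF/timing raster |

## Limitations / open decisions

- 2-D phantoms and sequences only in the generators (the solver itself
  is 3-D); no slice-selective excitation design.
- No ramp sampling in EPI; ADC samples on flat tops only.
- First-order splitting: relaxation *during* an RF pulse is interleaved,
  not jointly integrated; error is O(dt_rf/T2) per pulse and is covered
  by the oracle comparison.
- The adjoint recon is unweighted conjugate phase (uniform or ramp
  density compensation), not an iterative or NUFFT recon.
- Raw-data HDF5 profile is a simplified ISMRMRD-flavored layout, not the
  full ISMRMRD schema.
- No GPU or process-level parallelism; `n_threads` is a deterministic
  chunking parameter.
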