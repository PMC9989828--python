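# ldtransfer

Quantitative analysis of neutral-lipid transfer between lipid droplets
(LDs) and of the geometry of LD–LD interfaces.

In cells expressing Cidec, adjacent LDs form close contacts through which
triacylglycerol flows from the smaller droplet (the **donor**) to the
larger one (the **acceptor**) until the donor disappears — a facilitated,
pressure-driven analogue of Ostwald ripening that produces the few giant
droplets of white adipocytes. `ldtransfer` provides, for researchers
working with 3D time-lapse fluorescence of stained LDs and with
electron-cryo-tomograms of LD interfaces:

* **Detection and tracking** of LDs in `(t, z, y, x)` stacks with
  anisotropic voxels, including watershed separation of touching droplets,
  merge-aware greedy linking, and per-frame contact flags.
* **Transfer-event kinetics.** A transfer event completes at time *t*ₘₐₓ,
  when the donor track merges into the acceptor track. Volumes follow
  exponential kinetics — slow at first, accelerating toward completion:

  $$V_d(t) = V_{d0}\,\bigl(1 - e^{R_d (t - t_{max})}\bigr), \qquad
    V_a(t) = V_{a0} + (V_{a\max} - V_{a0})\,e^{R_a (t - t_{max})}$$

  With *t*ₘₐₓ fixed by event detection, the five free parameters
  (*V*<sub>d0</sub>, *R*<sub>d</sub>, *V*<sub>a0</sub>, *V*<sub>amax</sub>,
  *R*<sub>a</sub>) are recovered by nonlinear least squares. A droplet
  engaged in a single transfer must show concordant rate constants on both
  sides, so events with |log₁₀*R*<sub>a</sub>/log₁₀*R*<sub>d</sub> − 1| ≥ 0.4
  are excluded as likely multi-transfer participants. Manual-style average
  rates (ΔV/Δt in µm³/h), sphere volumes from measured diameters, and
  median/IQR cohort summaries are included.
* **Interface geometry.** Traced monolayer control points are interpolated
  onto a 2-nm grid; inter-monolayer distances are nearest-neighbour
  distances between the gridded surfaces, summarized per interface by
  their median (the distributions are not Gaussian). Droplet radii are
  recovered from two parallel tomographic cross-sections via
  *r* = √(a² + ((a² − b² − z²)/2z)²), exact for a sphere, and interface
  asymmetry by the large-to-small diameter ratio.
* **A ground-truthed synthetic-data generator** — confocal-like transfer
  movies (sphere rasterization, Gaussian PSF, shot + read noise, volume
  conservation), analytic monolayer surface pairs, and sphere
  cross-sections — so every stage is tested against known truth.

## Worked example

Simulate one transfer event (donor 4 µm³, acceptor 8 µm³,
*R*<sub>d</sub> = 0.01/s, completion at 600 s), track it, and fit it:

```python
from ldtransfer.synthetic import SimulationConfig, GroundTruthEvent, generate_timelapse
from ldtransfer.detection import segment_stack, link_tracks, detect_contacts
from ldtransfer.kinetics import detect_events, TransferEventModel

event = GroundTruthEvent(
    donor_center=(3.0, 4.0, 3.0), acceptor_center=(6.6, 4.0, 3.0),
    Vd0=4.0, Va0=8.0, Rd=0.01, t_contact=100.0, tmax=600.0,
)
config = SimulationConfig(image_shape=(15, 80, 80), n_frames=35,
                          events=[event], rng_seed=5)
stack, truth = generate_timelapse(config)

detections, labels = segment_stack(stack)
tracks, summary = link_tracks(detections)
contacts = detect_contacts(tracks, labels)
events = detect_events(tracks, summary, contacts)

results = TransferEventModel(events[0]).fit()
print(results.summary())
```

```
TransferEvent donor=1 acceptor=0 t_contact=80s tmax=600s
DonorFitResults
  n obs      : 21
  tmax (s)   : 600
  SSE (µm⁶)  : 0.0810664
  converged  : True
  Vd0 (µm³)  : 4.30159 (se 0.031)
  Rd (1/s)   : 0.00958345 (se 0.000226)
AcceptorFitResults
  n obs      : 21
  tmax (s)   : 600
  SSE (µm⁶)  : 0.0170045
  converged  : True
  Va0 (µm³)  : 8.49314 (se 0.0168)
  Vamax (µm³) : 12.779 (se 0.0381)
  Ra (1/s)   : 0.00957146 (se 0.000172)
filter |log10Ra/log10Rd - 1| = 0.0002693 -> pass
average rate = 31.21 µm³/h
```

The event is found from the track merge at frame 30 (*t*ₘₐₓ = 600 s,
exactly the generating value). The fitted rate constants (0.0096/s on both
sides, truth 0.01/s) agree to within the volume-measurement noise, the
concordance metric is ≈ 0, so the event passes the single-transfer filter,
and the average donor shrinkage over the fitted window is 31 µm³/h.
Fitted volumes carry a small positive bias relative to truth (~5%) from
the threshold-based segmentation of PSF-blurred spheres; the rate
constants, which depend on relative volume change, are unaffected.

The same stages are available from the shell for staged, manifest-tracked
runs:

```sh
ldtransfer simulate --config run.yaml --output-dir out --seed 5
ldtransfer track    --config run.yaml --output-dir out
ldtransfer kinetics --config run.yaml --output-dir out   # writes events.csv
ldtransfer geometry --config geo.yaml --output-dir out   # distance maps
```

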