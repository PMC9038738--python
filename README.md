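# radialign

Quantitative analytics for radially organized fibrous-tissue cultures:

- **orientation** — weighted structure-tensor orientation and coherency of
  2D microscopy-like textures, with an independent brute-force
  directional-energy oracle and tiled orientation maps;
- **directionality** — axial orientation histograms with a periodic
  Gaussian-peak fit whose goodness (in [0, 1]) serves as an alignment score;
- **radial** — radial-organization scoring around a center and comparison of
  a sample orientation field against radial and isotropic controls;
- **protocol** — a spherical-cap membrane model mapping reservoir volume
  change to average radial strain, plus a compiler turning two-phase
  mechanical stimulation protocols (slow ramp; cyclic stretch training) into
  strain/volume waveforms with per-stretch event logs and a hardware
  capability check (30% strain, 16 cycles/min);
- **calcium** — dF/F0 calcium-transient quantification against a
  pre-stimulus baseline window;
- **synthetic** — seeded generators (gratings, fiber fields with axial
  von Mises orientations, radial spoke patterns, elongated-nucleus images,
  calcium transients) that return their ground truth, so every stage is
  testable without external data.

## Conventions

Angles are axial (period 180°), in degrees in `[-90, 90)`, measured
counter-clockwise from +x with y pointing up. In-memory images are stored
y-up (row 0 = bottom); file readers/writers flip rows so on-disk TIFF/PNG
keep the usual top-row-first layout. For striped textures the structure
tensor's dominant eigenvector is the *gradient* axis; the reported fiber
orientation `theta_deg` is that axis rotated by 90°, and the raw gradient
axis is exposed alongside it.

## CLI

```sh
radialign synth grating --out out/g --seed 3 --angle 30
radialign orient out/g/grating.tif --out out/g/omap --window 16
radialign directionality out/g/grating.tif --out out/g/dir
radialign radial sample.tif radial_ctrl.tif iso_ctrl.tif --out out/r
radialign protocol protocol.yaml --out out/p
radialign calcium trace.csv --out out/c --baseline-start 0 --baseline-end 5
```

Protocol YAML:

```yaml
phases:
  - {type: ramp, start_strain_percent: 0, end_strain_percent: 10, duration_s: 25200}
  - {type: rest, duration_s: 61200}
  - {type: cyclic, strain_percent: 5, stretches_per_cycle: 10,
     cycle_duration_s: 600, cycles_per_day: 3, days: 1}
membrane: {membrane_diameter_mm: 22}
dt_s: 1.0
```

Each subcommand writes CSV/JSON artifacts plus a `manifest.json` recording
the config, seeds, versions, and the angle/coordinate conventions. Runs are
deterministic for a fixed config and seed.

## Notes

The strain-volume map is a kinematic spherical-cap surrogate, not a
finite-element membrane solution; it is exact for the stated cap geometry
(strain at the hemisphere limit is (π − 2)/2) and strictly increasing up to
that limit. Elastic modulus and thickness parameters are carried as
metadata only.
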