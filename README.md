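# simscope

A desk-scale software model of a video-rate structured-illumination
microscope (2D two-beam SIM, 3 angles × 3 phases): synthetic raw-data
generation, illumination-parameter estimation, generalized-Wiener SIM
reconstruction with optional background attenuation, multicolor SLM
phase-grating pattern search, acquisition-timing planning, and a streaming
real-time reconstruction pipeline. No hardware or external datasets are
needed — a built-in virtual microscope emulates everything the pipeline
consumes.

## Modules

| module | what it does |
| --- | --- |
| `simscope.optics` | frequency grids, diffraction cutoff `2·NA/λ`, ideal incoherent 2D OTF/PSF |
| `simscope.phantoms` | ground-truth scenes (points, bead clusters, lines, Siemens star) |
| `simscope.microscope` | forward model: sinusoidal illumination, OTF blur, sCMOS noise, multi-channel streams |
| `simscope.estimation` | band separation and recovery of pattern wave vector, start phase, modulation depth |
| `simscope.reconstruction` | wide-field + super-resolved reconstruction (2× output sampling, Wiener, apodization, OTF attenuation) |
| `simscope.slm` | binary phase gratings, diffraction-order prediction, Fourier-mask scoring, multicolor pattern search |
| `simscope.timing` | interleaved SLM/camera/laser schedules, achievable frame rates, duty cycles, timestamps |
| `simscope.stream` | wire protocol, 9-frame set assembly, ring buffers, affine channel registration, live pipeline |
| `simscope.simio` / `simscope.config` / `simscope.cli` | TIFF + parameter-file I/O, validated config, CLI |

## CLI

```sh
# synthetic 9-frame raw stack (+ truth sidecar JSON)
simscope simulate --phantom bead_clusters --shape 512 --seed 7 --out raw.tif

# estimate illumination parameters, then reconstruct (512² -> 1024²)
simscope estimate --raw raw.tif --out params.json
simscope reconstruct --raw raw.tif --params params.json --out sim.tif --widefield-out wf.tif

# acquisition planning (prints the frame-rate table; 1 ch/1 ms/512 lines -> 31 fps)
simscope plan-timing --channels 3 --exposure 1 --lines 512 --events-csv events.csv

# multicolor SLM pattern search + mask export
simscope pattern-search --wavelengths 488,568,647 --target-radius 30 --tolerance 1 --out-dir patterns/

# serve a synthetic stream over TCP and reconstruct it live
simscope stream --shape 128 --timepoints 5 --port 5555 &
simscope stream-recon --port 5555 --params params.json --archive raw_archive.tif
```

All commands accept `--config run.yaml` (validated; unknown keys rejected);
outputs embed the config hash and seed, so identical invocations reproduce
identical files.

## Conventions

- Spatial frequencies in cycles/µm, lengths in µm, 0-based pixel coordinates,
  DC at the array corner (numpy FFT layout); centered views only for display.
- Raw sets are 9 frames, angle-major (`a1p1, a1p2, a1p3, a2p1, …`), 16-bit.
- Default geometry: 512×512 frames at 80 nm projected pixels, NA 1.33,
  pattern at 0.8 of the detection cutoff (support ratio 1.8).
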