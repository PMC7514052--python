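# fociq

Quantitative analysis of **intra-transcript multiplex in-situ
hybridization** — probing the 5' and 3' ends of one very long mRNA in the
same tissue section — with a synthetic-field generator that stands in for
the microscopy data.

The motivating system is full-length muscle dystrophin (dp427): a
2.3 Mbp gene transcribed at a near-constant ~40 bases·s⁻¹, so a single
transcript takes ~16 h to complete. A 5' probe labels both nascent and
mature transcripts; a 3' probe, whose target sequence emerges minutes
before termination, labels essentially mature transcripts only. In
fluorescence images this produces three quantifiable populations:

* **small foci** (0.5–10 μm² apparent area): single transcripts,
  sarcoplasmic when mature, with 5' and 3' foci of the same molecule
  co-localized within ~1 μm;
* **large 5'-only nuclear foci** (10–100 μm²): tens of nascent
  transcripts arrayed along the genomic locus of one expressing nucleus;
* background / non-specific signal, removed by thresholding.

From these the package measures focus counts per compartment, 5'↔3'
co-localization against rotation and random-point null models,
fluorescence-calibrated nascent-transcript counts per nucleus, and — via
the steady-state relation

```
5'/3' = (nascent + mature) / mature = (T_transcript + T_lifetime) / T_lifetime
T_1/2 = 0.693 · T_lifetime
```

— the half-life of the mature message from the 5'/3' abundance ratio and
the inter-probe transcription time (1,550 kbp ≈ 11 h at the 16 h / 2.3 Mbp
rate).

## Who this is for

Anyone quantifying single-molecule ISH (e.g. branched-amplification
chemistry) on tissue sections, especially for long genes where probe
position encodes transcript maturity: the same operations apply to real
TIFF stacks (threshold → connected components → size classes →
compartment masks → nearest-neighbour statistics) and every stage is
testable against the generator's exhaustive ground truth.

## Worked example

```bash
python examples/04_half_life.py
```

prints

```
elongation rate: 39.9 bases/s; inter-probe transcription time: 10.8 h
5'/3' ratio 3.21 -> mean lifetime 4.9 h, half-life 3.4 h, nascent fraction 69%
synthetic cohort generated at lifetime 5.0 h -> recovered 5.23 h from 9 noisy replicates
```

Reading: with ~2500 5'-region and ~780 3'-region transcripts per ng of
muscle RNA, the steady-state ratio of 3.21 implies a mature transcript
survives ~4.9 h on average (half-life ~3.4 h) — far less than the 16 h
invested in making it — and that ~69% of all transcripts present are
still nascent. The second line shows the estimator recovering a known
lifetime from the package's own noisy steady-state simulator.

The other examples each exercise one capability:

| script | shows |
| --- | --- |
| `examples/01_simulate_and_detect.py` | field simulation, nucleus segmentation, size/compartment counts |
| `examples/02_colocalization_nulls.py` | ~40% of healthy-muscle foci pair within 1 μm vs <1% under both nulls |
| `examples/03_intensity_calibration.py` | single-transcript unit intensity; 20–40 nascent transcripts per expressing nucleus |
| `examples/05_cohort_comparison.py` | healthy vs dystrophic cohorts: mature pool collapses, nascent persists |

A thin CLI wraps the same stages
(`fociq simulate|detect|coloc|kinetics`, see `fociq --help`).

## Layout

```
src/fociq/
  geometry.py     field geometry and pixel/μm/mass/RNA conversions
  synthetic.py    scene configs, field/exposure-series/steady-state generators
  detect.py       Huang & Yen thresholds, watershed nuclei, focus detection
  compartments.py nuclear vs sarcoplasmic masking and per-field summaries
  coloc.py        nearest-neighbour distances, rotation & random nulls
  calibrate.py    exposure linearity, unit intensity, nascent counts
  kinetics.py     gene model, steady-state ratio → lifetime/half-life
  pipeline.py     cohort orchestration, Mann-Whitney / correlation stats
  cli.py, io.py   thin shell front-end; TIFF + CSV + JSON round trips
```

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
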