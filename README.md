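# xldoublet

Computational core for analyzing MS-cleavable crosslinkers that release
peptide "stub" fragments: stub/delta-mass modeling, signature-doublet
detection with MS3-trigger selection, stub-vs-backbone spectrum annotation,
dataset-level comparison statistics, and a seeded synthetic-spectrum
generator with per-peak ground truth.

## What it does

MS-cleavable crosslinkers (bundled configs: a UVPD-cleavable reagent
"UCCL", plus DSSO and DSBU) break in the mass spectrometer, leaving each
crosslinked peptide carrying one of several small stub remnants. Peaks from
the same peptide with two different stubs form a *doublet* with a
characteristic mass difference (plus hydrogen-shift variants); these
doublets are the signature used to pick MS3 precursors. The package
implements:

- `xldoublet.chem` — exact elemental-composition arithmetic, peptide and
  stub fragment masses, doublet delta-mass sets with hydrogen-shift
  variants. Crosslinkers are editable JSON configs (`src/xldoublet/data/`).
- `xldoublet.spectra` — immutable centroided peak lists, MGF read/write
  (gzip supported), precursor removal, intensity ranking, median-ppm-error
  estimation and recalibration.
- `xldoublet.doublets` — doublet search at a ppm tolerance over assumed
  charges and delta variants, greedy ±m/z-window trigger dedup (exclusion
  list emulation), MS3 precursor selection, and trigger evaluation against
  ground truth.
- `xldoublet.annotate` — theoretical a/b/c/x/y/z and stub fragments, greedy
  one-to-one spectrum annotation, stub/backbone intensity sums, precursor
  cleavage efficiency.
- `xldoublet.metrics` — median stub/backbone ratio and related
  orthogonality statistics, doublet prevalence, intensity-rank cutoff
  curves, MS3 triggers per spectrum class with 0.95 CIs, trigger
  sensitivity, Weiszfeld geometric median and representative-spectrum
  selection, bootstrap CIs.
- `xldoublet.synthetic` — seeded generator of crosslinked / linear /
  crosslinker-modified linear MS2 spectra with configurable stub-to-backbone
  intensity partition, hydrogen-shift satellites, doublet dropout, noise and
  calibration jitter, plus full per-peak provenance for evaluation.
- `xldoublet.pipeline` — glue running preprocess → detect → trigger →
  annotate per spectrum into per-CSM records.

## CLI

```sh
# generate a synthetic dataset (MGF + per-peak truth + CSM table)
xldoublet simulate --config gen.json --out-prefix sim

# detect stub doublets and emit MS3 trigger selections
xldoublet detect --mgf sim.mgf --crosslinker UCCL \
    --tol-ppm 5 --shifts 0,1,2 --window 1.5 --max-triggers 5 \
    --out triggers.tsv

# annotate spectra with stub + backbone fragments
xldoublet annotate --mgf sim.mgf --csms sim.csms.tsv \
    --crosslinker UCCL --series a,b,y --out annotated.tsv

# dataset-level statistics from a per-record table
xldoublet metrics --records records.tsv --out report.json
```

`--crosslinker` accepts a bundled name (UCCL, DSSO, DSBU) or a path to a
JSON config of the same shape.

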