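# gazemux

Eye-tracking studies produce gaze recordings — where a subject looked on a
video stimulus, sample by sample — that usually travel separately from the
stimulus, in per-vendor text formats that every downstream tool has to
re-parse. `gazemux` bundles a study into **one standard Matroska (MKV)
file** by reusing the container's own track types:

* **subtitle tracks** carry the visualization — one track per subject, so
  switching subjects works like switching subtitle languages in any player;
* **audio tracks** carry sonified EEG (the alpha-band power of a raw trace
  rendered as a modulated 220 Hz tone);
* **attachments** carry the raw gaze CSVs, the lossless carrier and the run
  config, so expert analysis never loses access to the original numbers.

It is aimed at visual-behavior researchers who want their data instantly
viewable with stock media players and still fully recoverable by scripts.

## What's inside

| concern | approach |
| --- | --- |
| lossless carrier | USF-style XML subtitle documents extended with `shape` elements (point / rectangle / polygon); non-visual payload (raw timestamp, pupil size, event label) rides in per-shape comment children, so decoding reproduces the recording to 6 decimals |
| playable encoding | ASS (Advanced Sub Station Alpha) tracks with vector drawing commands (`m`/`l`/`b`): rectangles and polygons as move/line walks, gaze circles as four cubic Bézier quadrants with control-point factor 0.5523·r |
| per-sample placement | each sample is drawn over the half-open display interval `[n/fps, (n+1)/fps)` of its frame; trackers faster than the frame rate yield multiple co-timed shapes per frame |
| event detection | dispersion-threshold (I-DT) classification: maximal windows with `(max x − min x) + (max y − min y) ≤ D` lasting `≥ T_min` are fixations (drawn as squares), the rest saccades (circles scaled by relative pupil size) |
| reference rendering | offline rasterizer with Bresenham lines, midpoint circles and even-odd scan-line polygon fill, exported as transparent PNGs |
| sonification | alpha band (8–13 Hz) → zero-phase Butterworth band-pass → squared-signal moving average → envelope `e(t) ∈ [0,1]`; FM: `s(t) = sin(2π ∫ (220 + 110·e) dt)`, AM: `s(t) = e(t)·sin(2π·220·t)`; written as 16-bit PCM WAV |
| container I/O | mkvmerge/mkvextract or ffmpeg when installed, plus a built-in pure-Python Matroska subset writer/reader (`backend="native"`) that needs no external binary |
| synthetic data | seeded generators for gaze (known fixation/saccade ground truth), moving annotations, alpha-burst EEG and a procedural MJPEG stimulus video |

## Worked example

Everything below runs offline on generated data:

```
$ gazemux simulate --seed 7 --subjects 2 --duration 1.0 --out-dir fixtures
fixtures in fixtures: 2 gaze CSVs, eeg.txt, stimulus.mkv, config.ini

$ gazemux convert fixtures/subject0.csv fixtures/subject1.csv \
      --config fixtures/config.ini --out-dir converted
fixtures/subject0.csv -> converted/subject0.usf + converted/subject0.ass
fixtures/subject1.csv -> converted/subject1.usf + converted/subject1.ass

$ gazemux merge converted/subject0.ass converted/subject1.ass --out merged.ass
wrote merged.ass (860 events from 2 tracks)

$ gazemux sonify fixtures/eeg.txt --fs 250 --mode fm --out alpha.wav
wrote alpha.wav (fm, 1.00 s)

$ gazemux bundle fixtures/subject0.csv fixtures/subject1.csv \
      --video fixtures/stimulus.mkv --config fixtures/config.ini \
      --audio alpha.wav --backend native --out study
wrote study-ass.mkv
wrote study-usf.mkv
```

`convert` writes, per subject, the lossless USF document and the playable
ASS track. `merge` combines per-subject tracks into a single track (here
2 × 430 sample shapes = 860 events), restyled with one distinct color per
subject, because players render only one subtitle track at a time.
`bundle` produces the two container variants: `study-ass.mkv` plays out of
the box, `study-usf.mkv` additionally attaches the lossless USF carrier.
Both attach the raw CSVs and the config. Extraction is exact:

```
$ gazemux extract study-ass.mkv --out-dir extracted --backend native
...
attachment: extracted/subject0.csv
$ cmp extracted/subject0.csv fixtures/subject0.csv && echo BYTE-IDENTICAL
BYTE-IDENTICAL
```

A single frame can be rendered without any player via the reference
rasterizer:

```
$ gazemux overlay converted/subject0.usf --time 0.5 --out frame.png
wrote frame.png (177 px drawn)
```

## Layout

```
src/gazemux/
  model.py          gaze domain types, CSV parsing, frame alignment, I-DT
  usf.py            lossless USF shape codec
  ass.py            lossy ASS codec + track merging
  raster.py         Bresenham / scan-line reference rasterizer, PNG export
  mkv.py            native Matroska (EBML) subset writer/reader
  container.py      mux / demux / inspect over mkvmerge, ffmpeg or native
  sonification.py   alpha power envelope, FM/AM synthesis, WAV output
  synthetic.py      seeded generators for gaze, annotations, EEG, video
  cli.py            gazemux convert|bundle|extract|merge|sonify|overlay|simulate
```

See `docs/methods.md` for the model details, parameter defaults and known
limitations.
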