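# hipscreen

Developmental dysplasia of the hip (DDH) affects 1–3 % of infants and leads
to premature osteoarthritis when missed, yet it is reliably treatable (Pavlik
harness) when caught by ultrasound in the first months of life.  Universal
screening founders on cost: conventionally an expert sonographer acquires the
standard Graf coronal view and an expert reader measures it.  `hipscreen`
implements, end to end and fully testable without clinical data, the software
side of an AI-assisted alternative in which a lightly trained primary-care
user sweeps a handheld probe across each hip and decision support does the
rest.

The pipeline:

1. **Phantom simulation** (`hipscreen.phantom`) — synthetic Graf-plane frames
   and cine sweeps with exact known geometry: a bright iliac baseline echo, a
   bony acetabular roof meeting it at a configurable alpha angle, a
   hypoechoic femoral head at configurable coverage, plus speckle, blur,
   acoustic shadow and out-of-plane landmark decay.
2. **Landmark segmentation** (`hipscreen.segmentation`) — a U-Net-like
   convolutional segmenter (pure NumPy, CPU-trainable in minutes) trained
   with a DICE loss under a subject-disjoint 80/20 split, selecting the
   checkpoint with the highest validation DICE; plus a deterministic
   reference segmenter for phantoms.
3. **Graf geometry** (`hipscreen.geometry`) — total-least-squares baseline
   and roof lines (Hough-seeded two-line decomposition) and a least-squares
   head circle, yielding the two clinical indices
   * alpha angle `α` — the angle between the iliac baseline and the bony
     roof line at the rim (`α ≥ 60°` conventionally normal);
   * femoral head coverage `FHC = (r + s) / 2r` — the fraction of the head
     diameter medial to the baseline (`≥ 50 %` conventionally normal).
4. **Decision support** (`hipscreen.decision`) — per-frame landmark-adequacy
   gating, a capture loop that stops when enough adequate frames are
   acquired, median aggregation over a sweep, and the 3-way management call:
   *Healthy*, *FU Recommended*, or *Inconclusive, Repeat Scan*.
5. **Program statistics** (`hipscreen.screenstats`) — per-infant screening
   ledger, cohort summary with count-consistent percentages, referral
   confirmation rate, and rolling follow-up-rate learning curves.

See `docs/methods.md` for the model details and design rationale.

## Worked example

Screen one cine sweep of a borderline-dysplastic phantom hip (true
`α = 55°`, true coverage 0.40) with two of the eight frames swept off the
standard plane:

```python
from hipscreen.phantom import PhantomSpec, SweepSpec, render_sweep
from hipscreen.segmentation import reference_segment
from hipscreen.decision import decide_sweep

spec = PhantomSpec(alpha_true=55.0, head_radius_px=30.0, head_offset_px=-6.0, seed=42)
sweep = SweepSpec(phantom=spec, plane_offsets=[0, 2, -3, 5, -6, 8, 20, -30])
frames, truths = render_sweep(sweep)

decision = decide_sweep([reference_segment(f) for f in frames])
print(decision.to_text_report())
```

```
HIP SCREENING REPORT
====================
Result: FU Recommended

Frames analyzed:   8
Frames adequate:   6
Alpha angle (agg): 54.8 deg
Head coverage:     40%

Per-frame: [0:ok] [1:ok] [2:ok] [3:ok] [4:ok] [5:ok] [6:x] [7:x]
```

The two off-plane frames (offsets 20 and −30 px) are rejected by the
adequacy gate; the median over the six adequate frames recovers the
constructed geometry (54.8° vs 55°, 0.40 vs 0.40), and since `α < 60°` the
hip is flagged for follow-up.  Had fewer than five frames passed the gate,
the result would have been *Inconclusive, Repeat Scan* instead.

The same workflow is available from the shell:

```bash
hipscreen simulate --out cohort --n-subjects 10 --seed 1
hipscreen train --dataset cohort --out run --epochs 20
hipscreen scan cohort/S0000 --out scan0 --reference-segmenter
hipscreen summarize path/to/ledger.csv --out stats --window 20
```

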