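# p300ifce

Brain-computer-interface-driven color object extraction: a **P300 speller**
selects *which* object an operator wants, and an **improved fuzzy color
extractor (IFCE)** segments that object from a cluttered scene robustly
under illumination change.

## Who this is for

Researchers prototyping BCI-assisted machine vision — e.g. letting an
operator whose hands (or motor pathways) are unavailable designate a
navigation target for a robot — and anyone who needs an
illumination-robust, single-seed color segmenter with interpretable
parameters.

## The method

**Color pattern.** A pixel is a vector in RGB space: its length is
illumination intensity, its direction is color. Two pixels are compared by
the angle between their vectors,

    d(p, q) = arccos( p·q / (|p||q|) ) ∈ [0, π/2],

which is invariant under multiplicative illumination change.

**Fuzzy extraction.** The angle to a per-object seed pixel is fuzzified
(zero/positive sets with breakpoints α₁ < α₂), mapped to matched/unmatched
rule weights (ω_m + ω_u = 1), and defuzzified by the centroid of the clipped
output envelope over [0, π/2] (matched ramp ending at ρ_U, unmatched ramp
starting at ρ_M, ρ_M + ρ_U = π/2). The pixel is extracted iff the crisp
output Δρ_F < σ. Region growing proceeds from the minimal-angle pixel
through a 4- or 8-neighborhood, new subregions start only while the
candidate passes the squared-RGB-distance gate Σ(pᵢ−qᵢ)² < r, the largest
subregion is the object, and sub-threshold gaps are filled row- then
column-wise.

**P300 selection.** A 3×3 speller (7 trained objects + 2 reserved cells)
flashes its 3 rows and 3 columns in random order (200 ms flash, 300 ms
onset spacing, 1.8 s per repetition). EEG (30 channels, 1 kHz) is band-pass
filtered 0.1–30 Hz; per flash the 50–800 ms window is mean-removed and
reduced 50-fold to a 450-length feature vector; a shrinkage-regularized
Fisher linear discriminant scores target vs nontarget flashes; the attended
cell is (argmax row, argmax column), with majority voting over 3 online
repetitions. The selected object's seed pixel and fuzzy parameters are
handed to the extractor.

Human EEG and photographs are replaced by tested synthetic generators
(cluttered blob scenes under multiplicative illumination; oddball EEG with
a parametric P300-like deflection). See `docs/methods.md` for assumptions
and limitations.

## Worked example

```python
from p300ifce import run_end_to_end

report = run_end_to_end(n_selections=18, rng_seed=42)
print(f"online selection accuracy: {report.selection_accuracy:.2f}%")
for oid in sorted(report.iou):
    print(f"  {oid}: mask IoU {report.iou[oid]:.4f}, mask pixels {int(report.masks[oid].sum())}")
```

prints

```
online selection accuracy: 100.00%
  O1: mask IoU 1.0000, mask pixels 576
  O2: mask IoU 1.0000, mask pixels 448
  O3: mask IoU 1.0000, mask pixels 576
  O4: mask IoU 1.0000, mask pixels 448
  O5: mask IoU 1.0000, mask pixels 576
  O6: mask IoU 1.0000, mask pixels 448
  O7: mask IoU 1.0000, mask pixels 576
```

That is: an FLDA was trained on a simulated offline session (18 trials × 6
repetitions), 18 online selections (3 repetitions each, voting) all picked
the attended target, and each selected object's parameters extracted its
blob from a 7-object cluttered scene with perfect overlap against the
generator's ground-truth masks (576 px rectangles, 448 px ellipses). At
zero ERP amplitude the same pipeline drops to the 1/9 chance level — the
selection signal is the evoked response, not leakage.

The same stages are scriptable from a shell:

```sh
p300ifce speller-schedule --repetitions 1 --seed 7 --out sched.tsv
p300ifce simulate --seed 3 --selections 9 --out report.tsv
p300ifce extract --image scene.png --object O1 --out mask.png
```

e.g. the first command writes the flash event log

```
repetition	onset_ms	kind	index
0	0	col	2
0	300	row	2
0	600	row	0
0	900	col	1
0	1200	row	1
0	1500	col	0
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's full computation from scratch — offline FLDA
training on synthetic EEG, online P300 selections, and fuzzy extraction of
all seven trained objects from a synthetic scene — printing the selection
accuracy and per-object mask IoU it measured, and writes the results file.
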