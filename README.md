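# tnkit

Quantitative analysis of CD8+ T cell / NK cell crosstalk from live-cell
imaging and expression data.

When an activated CD8+ T cell meets an NK cell, the pair forms a stable,
synapse-like contact: the T cell decelerates sharply, the cells exchange
membrane fragments (trogocytosis), and signaling on both sides shifts.
`tnkit` packages the quantitative machinery needed to measure this from
time-lapse microscopy and companion molecular readouts:

- **Contact kinetics** (`tnkit.tracking`): each tracked cell's trajectory is
  split into three phases around a contact episode — Ph1 (before contact),
  Ph2 (during contact), Ph3 (after) — with per-phase mean velocities
  v = total displacement / elapsed time (μm/s) and a deceleration ratio
  v(Ph2)/v(Ph1). A ratio ≤ 0.2 marks a ≥ 5-fold slow-down on engagement.
- **Speed–Distance Index** (`tnkit.interaction`): the per-frame pair metric
  SDI(t) = v_rel(t) / (d(t) + ε), where v_rel is the norm of the velocity
  difference of the two cells and d their centroid distance; aggregated as
  median ± IQR per time bin and interaction modality (NK–NK, NK–T, T–T).
  Also classifies pair distances as close (≤ 250 px) vs distant and builds
  the 10-px-bin distance histogram.
- **Membrane-transfer quantification** (`tnkit.imaging`): channel
  segmentation (Otsu or fixed threshold + 8-connected components), centroid
  extraction, greedy nearest-first frame linking, and counting of
  above-threshold donor-channel pixels inside each recipient cell mask.
- **Ligand–receptor screen** (`tnkit.lr_screen`): filters CellChat-style
  L–R pair tables by per-cell-type TPM thresholds (≥ 2 and ≥ 10 TPM by
  default) under the all-subunits rule for multi-subunit complexes such as
  [ITGAL/ITGB2]–[CD226]; ships a curated 16-pair T–NK crosstalk reference
  table.
- **Phospho-flow fold changes** (`tnkit.flow`): the co-culture/monoculture
  ratio-of-ratios (pX_co/X_co)/(pX_mono/X_mono) per marker and population.
- **Synthetic data with ground truth** (`tnkit.simulate`): a seeded
  two-population random-walk simulator with scripted contact windows,
  per-cell deceleration factors, rendered two-channel TIFF stacks with
  painted transfer pixels, expression tables realizing prescribed screen
  outcomes, and flow tables with known fold changes — so every analysis
  stage can be validated end to end.

## Worked example

Simulate a 40-cell co-culture movie (20 T, 20 NK; every T cell is scripted
into one NK contact during which its speed is scaled by 0.1, with 10%
step-speed noise), then run the kinetics pipeline and the reference L–R
count:

```bash
$ tnkit simulate --seed 1 --out-dir demo/sim
wrote 40 tracks to demo/sim

$ tnkit kinetics demo/sim/tracks.csv --out-dir demo/kin
20 cells rated; 95.0% with ratio <= 0.2

$ tnkit lr-screen --out-dir demo/lr
pairs passing >=2 TPM: 16, >=10 TPM: 9
```

`demo/kin/kinetics.csv` holds one row per tracked T cell, ranked by
increasing deceleration ratio:

```
track_id,v_ph1,v_ph2,v_ph3,ratio,rank
T002,0.1567,0.0149,0.1486,0.0951,1
T006,0.1513,0.0145,0.1488,0.0962,2
T005,0.1533,0.0149,0.1515,0.0972,3
...
```

Here `v_ph1 ≈ 0.15` μm/s is the free-migration speed before contact,
`v_ph2 ≈ 0.015` μm/s the speed during NK contact, and `ratio ≈ 0.1` the
recovered per-cell deceleration factor — a ten-fold slow-down. The "95.0%
with ratio <= 0.2" line is the fraction of rated cells showing at least a
five-fold motility reduction. The L–R command counts the packaged 16-pair
crosstalk table at the two TPM thresholds (16 pairs at ≥ 2 TPM, 9 at
≥ 10 TPM).

Other subcommands: `tnkit sdi` (SDI series, time-binned medians, proximity
histogram), `tnkit transfer` (render + segment + transfer pixel counts),
`tnkit flow-ratio` (phospho/total fold changes). Every command writes a
JSON summary echoing its configuration and seed.

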