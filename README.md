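# kaedeflux

Quantification of **local translation in axonal growth cones** from
photoconvertible-Kaede timelapse imaging, with a ground-truthed synthetic
imaging simulator, 3-D apoptotic-cell spot counting, and a bipartite zipcode
motif scanner.

## The problem and who this is for

Kaede is a photoconvertible fluorescent protein: 405 nm light irreversibly
switches its emission from green to red. Photoconverting all Kaede in a
retinal ganglion cell axon zeroes the green signal, so any green that
reappears is *newly synthesized* protein. If the Kaede mRNA carries the
β-actin 3'UTR (which contains the zipcode element bound by Igf2bp1/ZBP1),
green reappears preferentially in the growth cone — the signature of local
translation. This package implements the full quantification chain for that
assay, for labs running ratiometric photoconversion timelapses *in vivo*:

1. **ratio_pipeline** — per timepoint, a binary mask from the red z-stack
   confines the green channel to the axon; SUM projections of the edited
   green and raw red stacks are divided into a green/red **ratio image**.
2. **trace_quant** — the ratio is read along a 1-pixel retrograde trace
   (150 pixels = 32 µm, tip first), and every 10 consecutive pixels are
   averaged into **15 bin means** per axon per timepoint.
3. **gradient_stats** — the two-level statistic:

   - per timepoint: OLS slope of bin mean vs. distance from the growth cone
     (bin centres 5.5, 15.5, …, 145.5 px) — the **spatial gradient** *g(t)*;
   - per axon: OLS slope of *g(t)* vs. time — the **gradient rate**,
     d*g*/d*t* (ratio·px⁻¹·min⁻¹). A negative rate means growth-cone
     enrichment of new protein increases over the timelapse.

   Conditions are compared with an **exact two-sided Mann-Whitney U test**
   (full enumeration of rank assignments for combined n ≤ 16) on the
   per-axon rates, and with one-way ANOVA + Tukey HSD on growth-cone vs.
   proximal region means at 90 min.
4. **synthetic_data** — a reaction-advection-diffusion simulator of green
   and red Kaede on the axon's arc length, rendered into noisy two-channel
   z-stacks with PSF blur, shot/read noise and an advancing growth cone,
   providing ground truth for every stage (see `docs/methods.md`).
5. **cytometry** — multi-scale Laplacian-of-Gaussian 3-D blob detection for
   acridine-orange-positive (apoptotic) cell counting with exclusion-region
   bookkeeping, and the axon-to-soma labelling percentage.
6. **zipcode** — scanner for the bipartite zipcode element
   (GGACT … ACA with a configurable spacer) in 3'UTR sequences.

## Worked example

Simulate a cohort at the study design (10 +UTR vs 6 −UTR axons, 10 z-stacks
at 10-minute intervals) and run the full quantification:

```python
from dataclasses import replace
from kaedeflux import RunConfig, run_end_to_end

cfg = RunConfig(seed=1, out_dir="demo")
cfg = replace(cfg, sim=replace(cfg.sim, rng_seed=1))
report = run_end_to_end(cfg)
```

Output (`demo/stats.json`) with these settings:

```
n +UTR: 10   mean gradient rate: -2.741e-05  (ratio·px⁻¹·min⁻¹)
n -UTR: 6    mean gradient rate: -4.234e-06
Mann-Whitney U = 0.0, exact two-sided p = 0.00024975
ANOVA (90 min regions) F = 255.68, p = 1.9e-20
Tukey: +UTR growth cone ≠ every other group (p_adj ≤ 1.1e-16)
```

Reading this: every simulated +UTR axon develops a steeper negative ratio
gradient than every −UTR axon (complete separation, hence the minimal exact
p-value 2/8008 for a 10-vs-6 design), and at 90 min the +UTR growth-cone
ratio is elevated over both the +UTR proximal axon and the −UTR growth cone
— the pattern expected when the 3'UTR drives growth-cone-local synthesis.

The same stages are available from the shell:

```bash
kaede-flux simulate --out dataset/ --seed 42 --n-plus 10 --n-minus 6
kaede-flux ratio --stack dataset/axon00.tif --out ratio_t{t}.tif
kaede-flux profile --stack dataset/axon00.tif --traces dataset/axon00_traces.csv --out profiles.csv
kaede-flux run-all --out results/ --seed 42
kaede-flux count-spots --stack ao.tif --scale-um 2:6 --out counts.json
kaede-flux axon-ratio --counts counts.csv
kaede-flux scan-zipcode --fasta utr.fa --spacer 5:15 --out hits.tsv
```

## Conventions

Coordinates are 0-based `(y, x)` with origin top-left; sub-pixel values are
accepted. Stacks are canonical `(T, C, Z, Y, X)`. Default calibration is
32/150 ≈ 0.2133 µm/px and 10 min/frame. Bin labels in outputs are 1-based
("pixels 1–10" is the growth cone) to match the field's convention.
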