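# uvrfret

FRET quantification of photoreceptor dimer/monomer status from confocal
images — the sensitized-emission intensity ratio and the
acceptor-photobleaching donor-dequenching assay — together with a
physics-based synthetic image generator that makes every stage of the
pipeline verifiable by parameter recovery, without any microscope data.

## Who it is for

Plant photobiologists and cell biologists who tag a dimer/monomer-cycling
protein (the motivating case is a UV-B photoreceptor that dissociates from a
homodimer into signaling-active monomers) with a GFP/mCherry FRET pair in
tobacco epidermis and need reproducible, statistically honest quantification
of the resulting multi-channel images — plus anyone who wants a seeded,
fully ground-truthed simulator of such experiments for method validation.

## The measurements

With donor D and acceptor A at distance *r*, transfer efficiency follows the
Förster law

    E = R0^6 / (R0^6 + r^6)

and a donor facing several acceptors combines them rate-additively,
`E = Σo_i / (1 + Σo_i)` with `o_i = e_i/(1−e_i)`.

**Sensitized emission.** The per-region FRET proxy is the mean-intensity
ratio of the acceptor-band to donor-band channel under donor excitation,
`fret_488 / donor_488`, sampled over 20 random regions per image, 10 images
per experiment, 5 independent experiments per condition. The donor channel
measures the post-FRET (quenched) signal, and the FRET channel includes
spectral bleed-through (β) and direct acceptor excitation (α), so for mean
efficiency Ē the expected ratio is

    ratio = (g_A/g_D)·Ē/(1−Ē) + β + α·(g_A/g_D)·(ā/d̄)/(1−Ē)

**Acceptor photobleaching.** Five donor scans, a 552 nm bleach confined to a
region, five more donor scans; the donor intensity at ~100 points along the
bleached cell's periphery gives

    percent increase = 100 · (I_Pb − I_Pre) / I_Pre

which at complete bleach equals `100·Ē/(1−Ē)`. An unbleached control region
is always quantified alongside.

Experiment-level inference is a two-way ANOVA (genotype × UV-B, Type II) with
Šídák-adjusted pairwise comparisons, reported as mean ± SE bar tables with
stars or compact letters.

Two labelling schemes are supported: a single dual-tagged fusion
(acceptor-N…C-donor, reporting intramolecular plus inter-monomer transfer)
and 1:1 co-expressed donor-only/acceptor-only homotags (inter-monomer
transfer only). See `docs/methods.md` for the full model.

## Worked example

Run a full sensitized-emission study on synthetic data and test the UV-B
response of the wild type against the constitutive dimer (W285F-like) and
constitutive monomer (D96N,D107N-like) mutants:

```python
from uvrfret.cli import RunConfig, run_ratio_study, stats_run

cfg = RunConfig(seed=42)                     # full default protocol
ratio = run_ratio_study("NcCg", cfg)         # 6 conditions x 5 experiments
anova, posthoc, summary = stats_run(ratio, threshold=0.05)
print(summary.to_string(index=False))
wt = posthoc[(posthoc.cell_a == ("WT", False)) & (posthoc.cell_b == ("WT", True))]
print(f"\nWT -UV vs +UV: Sidak-adjusted p = {wt['p_adj'].iloc[0]:.2e}")
```

prints

```
            genotype    uv     mean  n       se annotation
                  WT False 0.630609  5 0.010267
                  WT  True 0.352256  5 0.012988         **
  constitutive_dimer False 0.665394  5 0.003816
  constitutive_dimer  True 0.667774  5 0.002607
constitutive_monomer False 0.274957  5 0.002939
constitutive_monomer  True 0.275323  5 0.003837

WT -UV vs +UV: Sidak-adjusted p = 0.00e+00
```

Read: dark-adapted wild type sits with the constitutive dimer (ratio ≈
0.63–0.67, dominated by dimer FRET), UV-B drops the wild type to 0.35
(monomerization; starred as significant), and both mutants ignore UV-B, with
the constitutive monomer's ratio (≈0.27) reflecting only intramolecular
transfer plus bleed-through.

The same pipeline runs from the shell:

```bash
uvrfret simulate --out scratch/run --seed 42 --construct NcCg
uvrfret quantify --input scratch/run --out scratch/ratio
uvrfret bleach   --input scratch/run --out scratch/bleach
uvrfret stats    --input scratch/ratio/experiments.csv --out scratch/stats
uvrfret report   --input scratch/stats/summary.csv --out scratch/report
```

Every run writes a manifest (resolved config, seed, checksums); identical
seeds give bit-identical outputs.

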