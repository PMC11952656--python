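# glomquant

Quantification and screening toolkit for glomerular targeting phenotypes in
3D fluorescence stacks, plus a transcriptome-based inverse-expression
candidate screen. Everything runs end-to-end on a built-in synthetic-data
generator with recorded ground truth, so the full pipeline is testable
offline.

## What it does

- **`glomquant.synthetic`** — renders multi-channel 3D stacks (neuropil /
  neurite label / protein channels) over an ellipsoid glomerulus atlas with
  a planted off-target ("mistargeting") volume fraction, PSF blur, and
  Poisson + Gaussian noise; simulates cohorts with a planted phenotype
  probability; generates negative-binomial genes × cell-types count tables
  with planted inverse ligand–receptor pairs. Every planted parameter is
  echoed into a JSON manifest.
- **`glomquant.quant`** — per-slice Gaussian blur, global Otsu
  thresholding (strict `>` foreground), ROI-masked mean fluorescence
  density, the preference index `(a−b)/(a+b)`, per-glomerulus targeting
  volumes with off-target/reference mistargeting ratios, and a
  minimum-evidence-volume phenotype call.
- **`glomquant.screen`** — CPM normalization, `log2(CPM+1)`, expression
  preference indices, inverse-pair scoring (`score = −PI_L·PI_R`), ranked
  candidate screening with CPM/PI filters, and a three-cue coverage
  summary (third cue = max of two genes).
- **`glomquant.stats`** — penetrance with exact Clopper–Pearson CIs,
  one-sample t vs zero, tie-corrected Kruskal–Wallis with
  Bonferroni-adjusted pairwise follow-up (Mann–Whitney default, Dunn
  optional), geometric-mean group summaries with quartiles.
- **`glomquant.io` / `glomquant.cli` / `glomquant.pipeline`** — TIFF/JSON/
  TSV/JSONL formats and the command surface.

## CLI

```sh
# simulate a cohort of synthetic stacks with ground truth
glomquant simulate --config config.yaml --out sim/ --seed 1 --n 20

# quantify every sample in a directory
glomquant quantify --stack-dir sim/ --atlas sim/atlas.tif --names sim/names.json \
    --reference VA1d --others VA1v --protein-pair VA1d,VA1v --out results.jsonl

# rank ligand-receptor pairs by inverse-expression score
glomquant screen --table expr.tsv --meta types.tsv --ligands ligands.txt \
    --receptors receptors.txt --sender VA1v-ORN,VA1d-ORN \
    --receiver VA1v-PN,VA1d-PN --out ranked.tsv

# statistics
glomquant stats penetrance --counts counts.tsv
glomquant stats compare --results results.jsonl --group-by genotype \
    --value mistarget.ratios.VA1v

# end-to-end: simulate -> quantify -> aggregate
glomquant report --config config.yaml --out run/ --seed 1 --n 20
```

All seeded commands are deterministic: identical (config, seed) reproduce
byte-identical outputs, and every artifact embeds the config hash and seed.

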