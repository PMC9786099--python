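# igwo

A grey wolf optimizer (GWO) toolkit with two niching extensions — genetic-
algorithm population seeding and fitness-sharing leader ranking — applied to:

- **wrapper feature selection**: stochastic binarization of wolf positions
  into feature flag vectors, scored by
  `alpha * accuracy + (1 - alpha) * (N - L) / N` with a built-in
  leave-one-out nearest-neighbour evaluator (the evaluator is pluggable:
  any `flags -> accuracy` callable works);
- **denoising-filter optimization**: PSNR-guided search over a two-family
  filter space (sliding median, center-weighted local mean);
- **nodule segmentation**: global threshold, disk dilation, marker-based
  watershed on the distance transform, and closed clockwise boundary traces;
- **synthetic data**: seeded generators for three-class feature tables with
  planted informative columns and disk phantoms with ground-truth masks, so
  everything is testable without external datasets.

## CLI

All subcommands honor `--seed` and write a JSON run manifest beside their
outputs; identical invocations are bit-identical.

```bash
# synthetic inputs
igwo simulate features --out data.csv --seed 0
igwo simulate phantom --out phantom.png --mask mask.png
igwo simulate noisy-phantom --out noisy.png --ref clean.png --level 0.05

# wrapper feature selection (CSV with a label column)
igwo select --data data.csv --label-column class --seed 0 --out results/

# PSNR-guided filter optimization (calibration setting: clean reference given)
igwo denoise --in noisy.png --ref clean.png --out filtered.png

# watershed nodule segmentation + boundary traces
igwo segment --in phantom.png --out labels.png --boundaries boundaries.csv

# variant comparison on the planted-feature benchmark
igwo benchmark --variants igwo,gwo,ga,random --seeds 10 --out results/
```

Configuration is a flat YAML file (`--config config.yml`); defaults are
population 8, 100 iterations, domain [0, 1], GA crossover 0.8 / mutation
0.01, fitness alpha 0.99, 10x10-fold cross-validation. CLI flags override
the file, the file overrides defaults. Keys belonging to a deep-learning
classifier (momentum, batch size, learning rate, dropout, ...) are accepted
and echoed in the manifest but unused — subset evaluation here is the
k-NN stand-in or your own evaluator.

A note on the fitness formula: the printed source expression for the
selection objective is typographically broken; this package implements
`alpha * P + beta * (N - L) / N` with `beta = 1 - alpha`, the standard
accuracy-vs-subset-size trade-off matching the stated semantics. Maximizing
this form ranks subsets identically to minimizing
`alpha * (1 - P) + beta * L / N`.

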