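# seedbox

RGB-image phenotyping of planthopper damage in rice seedling seed-box
screens. The package turns per-patch photographs (or simulated colour
trajectories) into resistance calls:

1. **imaging** — load patch photographs, segment seedling foreground from
   the frame/soil background by nearest-seed colour thresholding, and
   summarize foreground pixels into per-channel means (0–255 histogram
   scale).
2. **colorspace** — normalized RGB, hue/saturation/brightness, chroma and
   luminosity from channel means (all index math runs on proportions,
   i.e. value/255).
3. **indices** — GMR, GDR, NGRDI, VARI, GLI, TGI and DGCI with explicit
   handling of degenerate denominators, a means-first convention, and an
   optional `--table1-literal` mode that reproduces the typographically
   defective printed formulas for auditability.
4. **scoring** — proportional-time standardization (nearest 0.1),
   final-day damage tables with pooled control arms, ΔIndex /
   relative-condition-change statistics against a susceptible check
   variety, 0–9 damage-score banding (0–3 resistant, 4–6 moderately
   resistant, 7–9 susceptible), and weight-loss estimates.
5. **stats** — Spearman/Pearson correlations, one-factor PERMANOVA-style
   pseudo-F on RGB triplets with permutation p-values, pairwise
   permutation tests (Holm-adjusted), a many-to-one permutation analogue
   of post-hoc comparisons against the check, and principal-coordinates
   ordination. Classical repeated-measures GLMs and Duncan/Tukey post-hoc
   procedures are deliberately replaced by these permutation analogues;
   constrained ordination is replaced by unconstrained PCoA.
6. **synthetic** — a first-class generator of screening experiments
   (logistic latent damage severity scaled by variety resistance, shared
   control arm, check sub-replication, rising red/blue reflectance under
   infestation, mid-test greening of controls, inflated whitebacked-arm
   variance, final-day damage records) plus a patch-image renderer with
   exact ground-truth masks. All stochastic stages draw from named
   substreams of one root seed.

## CLI

```sh
seedbox simulate --seed 1 --out-dir out/ --n-varieties 39
seedbox render   --seed 1 --out-dir imgs/ --n-patches 10
seedbox extract  --images imgs/manifest.csv --out summary.csv
seedbox indices  --summary summary.csv --out indices.csv [--table1-literal]
seedbox score    --observations out/observations.csv --check TN1 --index gli --out-dir out/
seedbox stats    --observations out/observations.csv --n-perm 999 --out out/stats.csv
seedbox run      --seed 1 --out-dir out/          # simulate -> score -> stats
```

Every artifact is a CSV with a `#`-prefixed provenance header (package
version, root seed, config hash); re-running a stage with the same seed
reproduces its outputs byte-identically. A YAML config passed via
`--config` supplies simulation parameters (fields of
`seedbox.synthetic.SimulationConfig`, plus `n_varieties`).

## Acceptance

Acceptance is property-based (colour-space and index oracles, segmentation
recovery on rendered ground truth, qualitative trajectory reproduction,
resistance-parameter recovery, permutation-test calibration, scoring
arithmetic, end-to-end determinism) and lives in
`tests/test_acceptance.py`. The report script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs an end-to-end smoke subset of those properties and writes the (empty)
numeric-target object, since no desk-scale numeric targets exist for this
build.
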