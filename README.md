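# dimorphtrade

Comparative-analysis pipeline for testing whether **sexual dimorphism in a
trophic trait is predicted by parental care strategy and trophic ecology** —
the motivating system being gill raker length in Lake Tanganyika cichlid
fishes, where only one sex incubates the brood in uni-parental mouthbrooders
and the gill rakers therefore face a sex-specific functional trade-off
between feeding and brooding.

The package is aimed at evolutionary ecologists who have (a) a specimen
table (body size, repeated gill raker measurements, δ¹³C/δ¹⁵N stable
isotopes, sex, breeding mode) and (b) a rooted, branch-length phylogeny of
the species, and want the full inference chain with honest resampling-based
uncertainty. A synthetic-data generator with known ground truth stands in
for restricted-access field data and backs every stage with
parameter-recovery tests.

## What it computes

1. **Trophic axis** — PCA of standardized (δ¹³C, δ¹⁵N). For two
   standardized variables the loadings are forced to ±1/√2 ≈ ±0.71 and PC1
   explains (1 + |r|)/2 of the variance; the axis is oriented so δ¹⁵N loads
   positive (higher score = more pelagic / higher trophic level).
2. **Size correction** — residuals of gill raker length on standard length
   (SL): a common model across all specimens (shifted back to a nonnegative
   mm scale) for phenotype–environment analyses, and species-specific
   models (sexes pooled) for sex comparisons.
3. **Phenotype–environment correlation** — Pearson's r between species-mean
   size-corrected raker length and trophic PC1, with a 10 000-permutation
   p-value, plus PGLS with Pagel's λ estimated by maximum likelihood:
   β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y with V = σ²C_λ, C the Brownian-motion covariance
   (shared root-to-ancestor branch lengths) and C_λ its off-diagonal scaled
   by λ.
4. **Sexual dimorphism** — per species, the female − male mean difference
   of size-corrected raker length (signed, and absolute = "extent"), with
   within-species label-permutation p-values and bootstrap CIs; per
   breeding mode, grand means with species-level bootstrap CIs and
   sign-flip tests of "mean = 0".
5. **Breeding-mode comparison** — permutation one-way ANOVA (+ pairwise) on
   the extent of dimorphism, and a simulation-based phylogenetic ANOVA
   whose null F distribution comes from Brownian-motion traits simulated on
   the tree (Holm-adjusted pairwise tests).
6. **Breakpoint analysis** — Davies test for a change in slope of
   dimorphism extent vs trophic PC1 within uni-parental mouthbrooders,
   segmented (broken-line) regression estimating the breakpoint ψ by the
   Muggeo iteration, and a phylogenetic ANOVA between the trophic groups
   above/below ψ̂.

## Worked example

```bash
dimorphtrade run --config config.yaml --out results/
```

with `config.yaml`:

```yaml
seed: 1
simulate: {}          # default synthetic study: 65 species x 10 specimens
```

prints (abridged; numbers from this exact run):

```
## Trophic axis
PC1 explains 77.5% of isotope variance; loadings d13C = -0.71, d15N = 0.71.

## Phenotype-environment correlation
Pearson r = 0.96 over 65 species (permutation p = 9.999e-05).
PGLS: R^2 = 0.93, lambda = 0.17, slope p = 2.554e-37.

## Extent of dimorphism across breeding modes
Permutation ANOVA: F = 3.15, p = 0.0407.
Phylogenetic ANOVA: F = 3.15, p = 0.04795.

## Breakpoint in uni-parental mouthbrooders
Davies test p = 8.192e-19; segmented breakpoint psi = 0.700 (SE 0.147),
slopes 0.020 -> 0.389.
Breakpoint groups (phylogenetic ANOVA): F = 28.06, p = 0.000999.
```

Reading: the isotope axis is recovered with the analytic ±0.71 loadings;
size-corrected raker length tracks the trophic score strongly (the
generator injects that slope directly, hence r far above what field data
show); dimorphism extent differs among breeding modes (p ≈ 0.04 with and
without phylogenetic correction); and within uni-parental mouthbrooders
dimorphism kicks in above a trophic breakpoint (true value 0.34; the
estimate ψ̂ = 0.70 ± 0.15 is pulled right by the |noise| floor of the
per-species differences), with a clearly dimorphic "above" group
(F = 28.1). Machine-readable outputs (`axis.json`, `phenotype_env.json`,
`dimorphism.csv`, `anova.json`, `segmented.json`, `groups.json`,
`bundle.json`) land in `results/`.

Other subcommands: `dimorphtrade simulate` (write a synthetic dataset +
ground truth), `dimorphtrade validate` (data-quality report for a specimen
table/tree), `dimorphtrade report` (re-render a stored bundle). To analyse
real data, replace the `simulate:` block with
`input: {specimens: specimens.csv, tree: tree.nwk}`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the complete pipeline from scratch on the default synthetic
study under the given seed (the run bundle is written next to the output
file) and writes the result JSON to `--out`.
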