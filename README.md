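# lipidsat

Targeted-lipidomics saturation analysis: from a raw species × samples
amount table to phospholipid saturation statistics.

Neurodegeneration research has repeatedly implicated the balance between
saturated and polyunsaturated fatty acyl chains (PUFAs) in neuronal
membranes. Targeted platforms such as the Lipidyzer report hundreds of
lipid species in C:n shorthand — `PC(18:0/20:4)` is a phosphatidylcholine
carrying stearate and arachidonate — and the analytic question is whether a
disease condition shifts phospholipids toward saturation. `lipidsat`
implements that analysis for practitioners working with such tables:

- **Nomenclature** — parse shorthand names (both `PC(18:0/20:4)` and
  `PC 18:0_20:4` dialects, ether `O-`/`P-` prefixes, ω-position suffixes,
  total-composition names like `PC 38:4`) and classify species as
  SFA / MUFA / PUFA by the double-bond count of their most unsaturated
  chain, with the *highly unsaturated* (≥4 double bonds) flag used
  throughout.
- **Preprocessing** — the fixed pipeline filter → impute → normalize
  (→ center): a species is kept when detected in ≥80% of all samples or
  ≥60% of any one group *and* its mean is ≥2× the blank average; missing
  cells become within-group medians; amounts become proportions of total
  lipid or of each lipid class; per-induction centering to the control mean
  removes multiplicative batch effects.
- **Differential saturation** — per-species log2 fold-changes with
  two-sided Student's t-tests on class-normalized proportions,
  saturation-binned volcano/heatmap exports, and class-proportion checks.
- **Unsaturation index** — per sample,

  U = Σ proportions(species with 4–6 double bonds in their most
  unsaturated chain) / Σ proportions(species with 0–3),

  over the phospholipid classes after class normalization, followed by a
  region × disease two-way ANOVA (type III), Šídák-adjusted per-region
  post-hoc contrasts (p_adj = 1 − (1 − p)^m) and D'Agostino–Pearson
  normality checks.
- **Assay statistics** — two-group log-rank test with hypergeometric tie
  handling, median-survival percent change, Pearson χ² for cold-stress
  recovery categories, and the feeding-proportion estimator
  (events / (flies × vials × observations)).
- **Synthetic data** — a generator producing Lipidyzer-style tables with
  known ground truth (log-normal abundances, abundance-dependent dropout,
  blanks, batch shifts, and a depletion δ of highly unsaturated species)
  plus discrete-day survival datasets, so every stage is testable without
  real data.

## Worked example

Simulate a case/control experiment in which species with ≥4 double bonds
are halved (δ = 0.5) in the case group, run the pipeline and measure what
comes out:

```python
import lipidsat as L

table, truth = L.generate_lipidome(L.SimConfig(seed=7, depletion=0.5))
res = L.preprocess(table)                       # filter -> impute -> normalize
rows = L.group_fold_changes(res.final, "case", "control")
hu = rows[rows["highly_unsaturated"]]
print(f"mean log2 fold-change (highly unsaturated): {hu['log2_fc'].mean():.3f}")
idx = L.compute_index(res.normalized)
print(idx.groupby("group")["unsaturation_index"].mean().round(3))
print("percent extension 15 d -> 25 d:", L.median_survival_change(15, 25))
```

prints

```
mean log2 fold-change (highly unsaturated): -0.914
group
case       0.051
control    0.097
Name: unsaturation_index, dtype: float64
percent extension 15 d -> 25 d: 67
```

The recovered fold-change sits near log2(0.5) = −1 (the residual gap is
the closure effect of per-class normalization; see `docs/methods.md`), the
unsaturation index of the depleted group drops to roughly 0.5× control,
and a median lifespan moving from 15 to 25 days is a 67% extension.

The same operations are scriptable from a shell:

```sh
lipidsat simulate --seed 7 --out sim/
lipidsat diff sim/matrix.csv sim/metadata.csv --case case --ref control --out diff.csv
lipidsat parse "PC(18:0/20:4)"
```

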