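# trophiso

Stable-isotope trophic ecology along elevational gradients: who eats what,
and where did an animal acquire its diet?

`trophiso` implements the statistical chain used to infer the diet and
elevational origin of small mammals (the motivating system is the
leaf-eared mouse *Phyllotis vaccarum*, which lives from the Atacama Desert
up to the summits of >6700 m Andean volcanoes) from liver stable-isotope
ratios (δ¹³C, δ¹⁵N, δ³⁴S) and plant baselines:

1. **Lipid normalisation of δ¹³C.** Liver lipid content varies among
   individuals, and lipids are ¹³C-depleted.  Bulk values are corrected per
   animal with the log-linear C:N model
   `δ¹³C_corr = δ¹³C_bulk + β₀ + β₁·ln(C:N)` (δ¹⁵N and δ³⁴S are never
   corrected).
2. **Plant baselines by elevational bin** (2000–3000, 3000–4000, 4000–5000,
   > 5000 m), with an optimal two-group δ¹³C split for bins that mix C3 and
   C4/CAM photosynthetic pathways (≈ −27 ‰ vs −13 ‰).
3. **Bayesian trophic position (TP).** `TP = λ + (δ¹⁵N_cons −
   δ¹⁵N_base)/Δ¹⁵N`, with λ = 1 (plants) and a liver trophic discrimination
   factor Δ¹⁵N = 4.3 ± 0.2 ‰.  Three models: a population one-baseline
   model, a two-source ("twoBaselines full") mixing model that also uses
   baseline δ¹³C and estimates the diet proportion α, and an
   individual-level one-baseline model for singletons (e.g. a lone summit
   animal).  TP = 2 is a strict herbivore; 2–3 omnivory; > 3 a diet
   dominated by animal prey.
4. **PERMANOVA** (permutation pseudo-F on Euclidean distances, with
   pairwise post hoc tests) for among-site differences.
5. **CAP** (canonical analysis of principal coordinates): a distance-based
   discriminant analysis that assigns individuals to 1000-m elevational
   zones, with leave-one-out cross-validation, a permutation test of the
   trace statistic, and Gower add-a-point projection of held-out animals —
   a mismatch between captured and assigned zone is evidence of recent
   up- or downslope movement.

A seeded synthetic-data module generates surveys with the study's
statistical structure (site means/SDs, a truncated-normal C:N distribution,
bimodal mid-elevation plant δ¹³C), so the whole pipeline runs and is
testable without any external data.

## Worked example

```sh
python examples/03_trophic_position.py
```

builds a high-elevation plant baseline (δ¹⁵N ≈ 2 ‰, n = 20), simulates five
consumers ~1.2 trophic steps above it, and prints:

```
deterministic point estimate: 2.14
population model: mode 2.1, 95% CI (2.0, 2.3), mean ± SD 2.1 ± 0.1, max R-hat 1.002
summit animal (δ15N = 7.0 ‰ vs plants 2.1 ‰): TP mode 2.2, 95% CI (0.8, 5.6)
```

The population posterior tracks the deterministic estimate while carrying
baseline, TDF and residual uncertainty; the individual model gives the same
mode for a single animal but a much wider interval — one datum cannot pin
the residual spread.  The other scripts in `examples/` cover the lipid
correction, site summary tables, PERMANOVA, CAP assignment (on the default
synthetic survey: trace = 1.81, p = 0.0001, 98% leave-one-out success, and
the 6739 m summit singleton assigned to the 4000–5000 m zone) and the full
pipeline.  A thin CLI wraps the same functions:

```sh
trophiso simulate --out bundle --seed 42
trophiso run --config bundle/config.yaml --out report
```

`report/` then holds `site_summary.tsv`, `tp_estimates.tsv/json`,
`permanova.json`, `cap_summary.json`, `confusion.tsv`, `assignments.tsv`
and a run log; reruns with the same seed are byte-identical.

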