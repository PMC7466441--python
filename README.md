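# dsrna-forge

A toolkit for designing species-specific insecticidal double-stranded RNA
(dsRNA) and for analysing the laboratory and field trials that validate it.
It was built around the Colorado potato beetle (*Leptinotarsa
decemlineata*) use case — silencing the midgut septate-junction gene
*mesh* by foliar dsRNA spraying — but every component is generic: any
target transcript, any non-target panel, any treatment-arm layout.

It is aimed at researchers developing RNAi-based pest control who need,
in one tested package:

1. **Off-target screening** — enumerate every 21-mer of a target
   transcript and flag those with a perfect exact match of ≥ 20 nt, on
   either strand, anywhere in a panel of non-target transcriptomes
   (pollinators, beneficial insects, human). Flagged footprints form an
   exclusion mask; its complement is the species-specific sequence space.
2. **dsRNA design** — select the longest specific region and rank
   candidate 350–500-nt dsRNA windows by the fraction of their 19-mer
   siRNAs passing a Reynolds-style efficiency rubric.
3. **Survival analysis** — Kaplan–Meier curves
   S(t) = ∏<sub>t<sub>i</sub>≤t</sub>(1 − d<sub>i</sub>/n<sub>i</sub>)
   and Cox proportional-hazards regression (Newton–Raphson on the partial
   likelihood, Efron tie correction) for right-censored feeding-trial data.
4. **Field efficacy** — Henderson–Tilton corrected mortality
   100·(1 − T<sub>a</sub>C<sub>b</sub>/(T<sub>b</sub>C<sub>a</sub>)),
   leaf-damage increase and adult emergence rates.
5. **qPCR quantification** — standard-curve fits (efficiency
   E = 10<sup>−1/slope</sup>, R², limit of quantification), inhibition QC,
   normalization to three endogenous control genes, and group knockdown
   percent.
6. **Synthetic data** — seeded generators with exact ground truth for all
   four data kinds, used throughout the test suite.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Generate a synthetic study with known ground truth and run the whole
pipeline (`--seed` makes every step reproducible):

```sh
$ dsrna-forge simulate transcriptomes --seed 11 --out demo
$ dsrna-forge screen --target demo/target.fa --panel demo/panel.fa \
      --out demo/hits.tsv --bed demo/excluded.bed
20 flagged 21-mers; excluded 220/2000 nt
```

Ten 20-mers were planted in the non-target panel; each is covered by two
overlapping 21-mers, and the screen flags exactly those 20 positions.
Design a dsRNA inside what remains:

```sh
$ dsrna-forge design --target demo/target.fa --panel demo/panel.fa \
      --min-len 200 --max-len 300 --report demo/report.json
specific region 766-1034 (268 nt); best candidate 826-1026 efficient_fraction=0.253
```

The best 200-nt window has 25.3% of its 19-mer siRNAs scoring ≥ 6 on the
design rubric. Analyse a simulated feeding trial (true hazard ratio 5,
water control vs dsMESH, 40 larvae per arm, censored at day 14):

```sh
$ dsrna-forge simulate trial --seed 11 --out demo
$ dsrna-forge cox --in demo/trial.csv --ref water
term    beta    se      hr      wald_p
dsMESH  1.7099  0.3243  5.5283  1.35e-07
LR stat 31.893 (p=1.63e-08); converged=True
```

The fitted hazard ratio 5.53 ± (SE on log scale 0.32) brackets the true
value 5. Finally, quantify gene silencing from simulated Cq tables with a
true knockdown of 70%:

```sh
$ dsrna-forge simulate qpcr --seed 11 --out demo
$ dsrna-forge qpcr --curves demo/standards.csv --samples demo/samples.csv \
      --target mesh --refs LdRP4,rRNA18S,LdSmt3 \
      --treated dsMESH --control dsEGFP
curve LdRP4: slope=-3.3430 E=1.991 R2=0.9982 LOQ=0.0001
curve mesh: slope=-3.2995 E=2.009 R2=0.9974 LOQ=0.0001
...
knockdown 71.7% (n=4 vs 4, Welch t=-18.39, p=6.51e-05)
```

Each standard curve is fitted over five 10-fold dilutions (slope ≈ −3.32
means ~100% amplification efficiency); *mesh* copy numbers are normalized
to the geometric mean of the three reference genes, and the treated group
shows 71.7% knockdown against the non-specific dsEGFP control — within
noise of the simulated 70%.

All of the above is also available as library calls
(`dsrna_forge.screen_and_mask`, `dsrna_forge.cox_fit`, …).

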