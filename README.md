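# mgcscan

Comparative-genomics toolkit for discovering and classifying ***mlp* gene
clusters (MGCs)** — gene clusters that encode MtaA-like corrinoid
methyltransferases (Mlps) related to the soluble coenzyme M
methyltransferases of methylotrophic methanogens — plus the enzyme-kinetics
analysis used to characterise the methyl-transfer activity of an Mlp2.

It is aimed at microbial comparative genomicists and enzymologists who
want a scriptable, auditable re-implementation of this analysis: no
webservers, every decision logged, and a synthetic-data generator that
makes every stage verifiable at desk scale.

## What it computes

**Gene-cluster rules.** A candidate MGC must satisfy four genomic-context
criteria:

1. it encodes at least two Mlps, a corrinoid protein and a Ram/RACE
   corrinoid reductive activase;
2. these genes are co-directional with no intervening
   divergently-transcribed genes;
3. adjacent core genes are separated by at most 2 kb of intergenic DNA;
4. no tetrahydrofolate-methylase homolog lies within 20 kb of any core
   gene.

Roles are assigned by Smith–Waterman local alignment (BLOSUM62, gap
open 11 / extend 1) against seed protein sets, with Karlin–Altschul
E-values (λ = 0.267, K = 0.041 for this scoring regime) or bit scores as
thresholds. A cluster is **type 1** when its Mlps include at least one
Mlp2 and one Mlp3, where subfamilies (Mlp1/2/3) come from connected
components of a sequence similarity network (SSN: 200–470 aa length
window, 50% repnode collapse, alignment score −log₁₀E ≥ 40) seeded with
labelled references. Each Mlp's Zn²⁺ coordination triad is read off a
reference alignment and classified His-Cys-Cys (S/Se-type) versus
carboxylate-substituted (O-type), and host genomes are profiled for
selenium-utilization machinery (selA/selB/selD, glycine reductase) to
split selenium-associated from non-selenium clusters.

**Kinetics.** Initial rates extracted from A₅₂₅ absorbance traces (with
an A₄₈₅ isosbestic-drift QC) are fitted to the substrate-inhibition
model

    v / E₀ = k_cat · S / (K_M + S + S²/K_I)

by seeded multi-start nonlinear least squares in log-parameter space,
following a statsmodels-style Model/Results API.

## Worked example

Generate a ground-truthed synthetic genome with one planted cluster and
scan it:

```
$ mgc synth genome spec.yaml --seed 7 --out-prefix demo   # spec.yaml may be '{}'
$ mgc scan --genome demo.gbk
genome_id contig_id  span_start  span_end strand  n_core  n_mlps  max_internal_gap subfamilies     label                                          core_ids
      syn    syn_c1         473      5717      +       5       3               100             other_mgc syn_cluster0_mlp1,syn_cluster0_mlp2,...
```

The five planted core genes are recovered as one candidate spanning
473–5,717 bp with three Mlps and a maximum internal gap of 100 bp
(`mgc scan` leaves the subfamily-dependent type 1 label to the full
pipeline, `mgc run config.yaml`, which adds SSN typing, Zn-site calls
and selenium context).

Fit the substrate-inhibition model to a simulated selenide titration
(truth: k_cat 0.778 min⁻¹, K_M 79.8 μM, K_I 3830 μM; 3 replicates, 3%
noise):

```python
from mgcscan import fit_substrate_inhibition
from mgcscan.synthetic import generate_kinetic_dataset

S = [20, 40, 80, 160, 320, 640, 1000, 1600, 2200, 2800, 3200, 3500]
ds = generate_kinetic_dataset(0.778, 79.8, 3830, S, replicates=3,
                              noise_cv=0.03, seed=42)
print(fit_substrate_inhibition(ds, seed=1).summary())
```

```
Substrate-inhibition kinetics fit
  model: v/E0 = kcat*S / (KM + S + S^2/KI)
  n obs: 36   distinct S levels: 12
  RSS:   0.00389961

  param      estimate      std err  unit
  kcat         0.7802      0.00989  1/min
  KM             80.4         2.81  uM
  KI             3864          146  uM
  rate maximum at S = sqrt(KM*KI) = 557.3 uM
```

All three constants are recovered within their standard errors, and the
reported rate optimum (√(K_M·K_I) ≈ 557 μM) marks where substrate
inhibition takes over.

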