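# cargbend

Quantitative desk analyses around MADS-domain transcription-factor/DNA
interaction, built for regulatory-genomics work on AGAMOUS-clade factors in
ripening fruit (and any other system where a MADS-box protein binds and
bends a CArG box):

* **Motif scanning** — degenerate CArG-box consensus classes (canonical
  C(C/T)(A/T)₆(A/G)G, SRF-like CC(A/T)₆GG, MEF2/N10-like CTA(A/T)₄TAG, and
  the intermediate C(A/T)₆AG) scanned over promoter FASTA with a
  configurable "atypical" mismatch budget, BED6-like output.
* **Circular permutation analysis** — gel mobilities of protein-DNA
  complexes with the binding site permuted along an identical-length probe
  are fit to a cosine flexure profile; the protein-induced bend angle α
  follows from the fitted mobility extremes via μ_M/μ_E = cos(α/2).
* **Phasing analysis** — relative mobility vs the spacing between an
  intrinsic A-tract bend and the protein-induced bend, fit to a sinusoid at
  the B-DNA helical repeat (10.5 bp/turn), yielding the in-phase spacing
  and in/out-of-phase classification.
* **Circularization kinetics** — first-order fits of ligase-mediated
  minicircle formation time courses, and the in-phase vs out-of-phase rate
  comparison.
* **Saturation binding** — one-site isotherm bound = B_MAX·x/(K_D + x)
  fitted by nonlinear least squares.
* **Synthetic data** — seeded generators for every assay with known ground
  truth, so the full pipeline is testable without wet-lab data.

Each analysis is a statsmodels-style pair: a Model built from data whose
`fit()` returns a Results object with estimates, standard errors,
`summary()`, `predict()` and `plot()`.

## Worked example

```python
from cargbend import (SimulationConfig, gen_permutation_series,
                      CircularPermutationModel)

cfg = SimulationConfig(seed=1, mobility_sigma=0.0)   # noiseless demo
series, truth = gen_permutation_series(cfg)          # 8 lanes, 230 bp probe
res = CircularPermutationModel(series).fit()
print(res.summary())
```

```
==========================================================
             Circular permutation cosine fit
----------------------------------------------------------
No. observations: 8          RSS: 3.57453e-31
----------------------------------------------------------
parameter                   estimate       std err
----------------------------------------------------------
mu_M (slowest)               0.55068            --
mu_E (fastest)                   0.8            --
bend_center [bp]                 115     8.252e-14
bend_angle [deg]                  93     1.071e-13
==========================================================
```

The slowest complex runs at 0.55 of the free-probe mobility, the fastest at
0.80; their ratio 0.688 = cos(α/2) gives an induced bend of α = 93°, centred
at 115 bp (mid-probe), exactly the generator's truth. With gel-scale noise
(`mobility_sigma=0.005`, the default) the same fit recovers the angle with a
spread of about 2°.

The same workflow from the shell:

```sh
cargbend simulate permutation --seed 1 --out-dir sim/
cargbend permutation --table sim/permutation.tsv --probe-length 230 --out fit.json
cargbend scan --fasta promoters.fasta --max-atypical 2 --out hits.bed
```

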