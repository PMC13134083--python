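# ddclock

Multiplex droplet digital PCR (ddPCR) DNA methylation quantification with
Poisson limiting-dilution statistics, plus six-CpG epigenetic clocks for
chronological-age prediction — including a from-scratch Klemera–Doubal
biological-age estimator.

## The problem

Amplitude-multiplexed ddPCR can quantify DNA methylation at six
age-associated CpG sites (*ASPA*, *C1orf132*, *CCDC102B*, *EDARADD*,
*ELOVL2*, *FHL2*) in a single reaction: each fluorescence channel shows a
negative cluster, a single-positive cluster (target present, unlabeled
allele only) and a high-positive cluster (labeled allele present). Two
amplitude thresholds per channel turn droplets into counts, and the
methylation fraction is a droplet-count ratio:

    beta = M / (M + U)

where M and U are methylated- and unmethylated-droplet counts (channels
labeling the unmethylated allele use the equivalent form
`1 − U/(M+U)`). Counting is only accurate at limiting dilution, which
Poisson statistics make precise: with a fraction *p* of positive
droplets, the per-droplet occupancy is λ = −ln(1 − p) and the chance
that a positive droplet holds exactly one molecule is

    P(K = 1 | K ≥ 1) = λ e^{−λ} / (1 − e^{−λ}).

Keeping p ≤ 10% per target keeps single-molecule occupancy near 95%,
the assay's recommended operating range; the package evaluates both
gates as a QC verdict on every channel.

On top of the quantification layer, the package trains and compares five
clock families on cohort tables (age, sex, six beta values): elastic
net, gradient-boosted trees, linear and RBF support-vector regression,
and Klemera–Doubal regression (KDR). KDR regresses each marker on age,
x_j = q_j + k_j·CA + ε (residual SD s_j), and combines the inverted
regressions with inverse-variance weights:

    BA_E  = Σ_j (x_j − q_j) k_j / s_j²  /  Σ_j (k_j / s_j)²
    BA_EC = [ Σ_j (x_j − q_j) k_j / s_j² + CA / s_BA² ]
            / [ Σ_j (k_j / s_j)² + 1 / s_BA² ]

The EC variant shrinks toward chronological age (CA) and requires it at
prediction time. Two synthetic-data generators — droplet wells with full
ground-truth bookkeeping, and cohorts with the blood-like signed,
partly nonlinear age trajectories of the six CpGs — make the whole
pipeline testable end to end without instrument data.

## Worked example

```python
from ddclock import (AssaySimConfig, simulate_well, quantify_well,
                     simulate_cohort, split_cohort, fit_clock, evaluate)

# a simulated six-channel well at limiting dilution
cfg = AssaySimConfig(seed=1)
sim = simulate_well(cfg)
for r in quantify_well(sim.well, cfg.thresholds()):
    print(r.cpg, round(r.beta, 4), round(r.qc.p_positive, 4), r.qc.passed)
```

prints (true betas 0.49, 0.56, 0.44, 0.30, 0.57, 0.34):

```
ASPA       beta=0.4708  p=0.0720  single=0.9631  pass=True
C1orf132   beta=0.5426  p=0.0722  single=0.9630  pass=True
CCDC102B   beta=0.4228  p=0.0725  single=0.9628  pass=True
EDARADD    beta=0.2958  p=0.0723  single=0.9629  pass=True
ELOVL2     beta=0.5974  p=0.0722  single=0.9630  pass=True
FHL2       beta=0.3236  p=0.0718  single=0.9632  pass=True
```

Every channel sits in the QC-pass regime (7% positive droplets, 96%
single-molecule occupancy) and recovers its true methylation level to
within counting noise. Continuing with a clock:

```python
cohort = simulate_cohort(n=351, seed=1)          # ages 0-95
train, test = split_cohort(cohort, test_fraction=0.25, seed=1)
clock = fit_clock("kdr", train, transform=True, seed=1, kdr_variant="BA_E")
print(evaluate(clock, test))
```

```
train r=0.9796 R2=0.958 MAE=4.43 RMSE=5.65
test  r=0.9790 R2=0.955 MAE=4.57 RMSE=5.69
```

i.e. the age-blind Klemera–Doubal clock predicts age on held-out
synthetic samples to ~4.6 years mean absolute error over a 0–95-year
range.

## Command line

```bash
ddclock simulate-droplets --seed 7 --wells 2 --out-droplets d.csv \
    --out-truth t.csv --out-thresholds thr.csv
ddclock quantify --droplets d.csv --thresholds thr.csv --out results.csv
ddclock simulate-cohort --n 351 --seed 1 --out cohort.csv
ddclock train --cohort cohort.csv --family kdr --model-out clock.json
ddclock predict --model clock.json --cohort cohort.csv --out pred.csv
ddclock subset-search --cohort cohort.csv --families kdr,enr --out search.csv
```

`quantify` accepts long (`well,channel,amplitude`) or wide droplet CSVs
(auto-detected) and appends Poisson QC columns to its output.
`subset-search` fits every 2–6 CpG combination (57 per family) and
ranks them by test MAE.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's two closed-form anchor quantities — the
percentage of positive droplets containing exactly one target molecule
at 13.17% and at 0.08% positive droplets — from the Poisson
limiting-dilution machinery, and writes them as JSON.
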