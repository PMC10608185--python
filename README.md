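# hoconn

Pairwise and high-order functional connectivity analysis of multivariate
time series on a single-recording basis, with full statistical validation.

Given an `M x Q` matrix of synchronous channel recordings (e.g. ROI BOLD
series), the package estimates:

* **Pairwise coupling** via Gaussian mutual information (MI, in nats),
  computed through linear-regression residual covariances, with per-pair
  significance thresholds from iAAFT surrogate ensembles (phase-randomized
  series that keep each channel's amplitude distribution exactly and its
  power spectrum approximately, while destroying cross-channel coupling).
* **High-order interactions** via the O-information of multiplets (groups
  of N >= 3 channels): positive values indicate redundancy-dominated
  groups, negative values synergy-dominated ones. Per-target O-information
  increments quantify what each channel adds. Confidence intervals and
  significance come from a coupling-preserving block bootstrap (the same
  random block draw applied to all channels), with a zero-in-CI rule for
  the O-information, unpaired Student t-tests for order-to-order
  increments, and t-tests between conditions for difference maps.
* **Network densities**: global percentage of significant links and local
  within/between percentages for channels grouped into named networks.

A fully specified 7-node linear benchmark network (three independent
sources feeding a common child, a chain, and a common driver with two
sinks) ships as a simulator with its exact population covariance, and a
generic Gaussian generator produces synthetic test data of any covariance.

## CLI

```bash
# generate benchmark data (CSV + JSON sidecar)
hoconn simulate --seed 1 -m 500 --out-dir out/

# surrogate-validated MI network (writes mi_matrix.csv, mi_mask.csv,
# densities.json)
hoconn pairwise out/timeseries.csv --seed 2 --ns 300 --block-length 50 \
    --out-dir out/

# bootstrap-validated O-information for a multiplet collection
# (oi_table.csv, doi_table.csv, significance_rates.json)
hoconn hoi out/timeseries.csv --multiplets multiplets.json --seed 3 \
    --nb 300 --block-length 50 --out-dir out/

# or sample a cross-network multiplet hierarchy from an RSN map
hoconn hoi bold.csv --rsn-map rsn.csv --counts 3:56,4:40,5:30,6:20,7:5,8:1 \
    --seed 3 --out-dir out/

# between-condition differences (comparison.csv)
hoconn compare pre.csv post.csv --rsn-map rsn.csv --seed 4 --out-dir out/

# densities from a saved significance mask
hoconn densities out/mi_mask.csv --rsn-map rsn.csv --out densities.json
```

Input time series are delimited text with a header row of channel labels,
one row per time point. Network maps are two-column `label,network` CSV.
Resampling options can also be supplied as a JSON/YAML config file
(`--config`); explicit flags override it. All analyses standardize each
channel (zero mean, unit sample standard deviation) first; results are
invariant to channel-wise affine rescaling.

## Python API

```python
from hoconn import (SimulationConfig, simulate_benchmark_network,
                    ResamplingConfig, run_pairwise, run_hoi)
from hoconn.hoi import enumerate_multiplets

ts = simulate_benchmark_network(SimulationConfig(seed=1))
cfg = ResamplingConfig(seed=2, n_surrogates=300, n_bootstrap=300,
                       block_length=50, alpha=0.05)
pairwise = run_pairwise(ts, cfg)          # MI matrix, mask, densities
hoi = run_hoi(ts, {3: enumerate_multiplets(7, 3)}, cfg)
```

## Reproducibility

Every stochastic operation derives a child generator from one master seed
keyed by (operation, measure, replicate), so ensembles, reports and CLI
outputs are bit-reproducible for a fixed seed and configuration.
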