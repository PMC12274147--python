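# ipsipanel

Incremental propensity-score interventions for **recurring binary exposures**
in wide-format longitudinal panels.

Instead of contrasting "always exposed" with "never exposed", the target
quantity here is the average outcome at each wave when every individual's
*odds* of exposure are multiplied by a shift factor `delta` at every wave
(`delta = 1` reproduces the observed world; `delta < 1` lowers exposure odds).
The shifted propensity is `q = delta*pi / (1 + (delta-1)*pi)`, which requires
no positivity assumption: individuals with propensity 0 or 1 stay there.

## What's in the box

| module | purpose |
|---|---|
| `ipsipanel.panel` | wide-panel data model, history (`H_t`) construction under both within-wave orderings, CSV/schema I/O, complete-case filtering, centering |
| `ipsipanel.synthetic` | seeded synthetic cohorts (continuous or fully discrete) with exact-enumeration / Monte-Carlo structural truth for every estimator test |
| `ipsipanel.propensity` | per-wave logistic propensity models (main effects + all pairwise interactions, ridge fallback on separation), the odds shift, delta grids, overlap and shifted-propensity diagnostics |
| `ipsipanel.outcomes` | jointly fitted linear system for time-varying covariates and outcomes, with cross-time equality constraints and *fixed* exposure-outcome residual correlations (the unmeasured-confounding sensitivity parameter) |
| `ipsipanel.estimation` | three estimation routes (Hajek/HT IPW, g-formula simulation, exact enumeration on discrete supports), bootstrap percentile CIs with per-replicate refits, CI-overlap flagging, sensitivity sweep |
| `ipsipanel.cli` | `ipsipanel simulate / estimate / sensitivity / diagnose` with YAML configs and reproducibility manifests |

## Python API in 20 lines

```python
import ipsipanel as ip

# synthetic cohort with known truth
cfg = ip.default_config(n=1000, T=3, seed=1)
panel = ip.generate_panel(cfg)
truth = ip.true_ipsice(cfg, delta=0.25, outcome_time=3,
                       method="monte_carlo", mc_size=100_000)

# estimate the whole curve with bootstrap CIs (models refitted per replicate)
curves = ip.ipsice_curve(panel, grid=ip.default_delta_grid(),
                         outcome_times=[1, 2, 3], method="gformula",
                         B=200, seed=7, mc_size=2000)
print(ip.curves_to_frame(curves))

# unmeasured-confounding sensitivity: refit with fixed residual correlations
sweep = ip.sensitivity_sweep(panel, rho_grid=[0.0, 0.1, 0.2, 0.3],
                             outcome_times=[3], seed=7)
```

For real data, provide a CSV plus a schema (YAML/JSON) mapping columns to
roles; `name` expands to `name_1..name_T` by suffix convention:

```yaml
id: ID
T: 3
C: [Gender, Race, Age, Income]
L: L      # L_1..L_3
X: X
Y: Y
```

Rows with a missing value in any declared column are dropped (complete-case,
logged). Exposure columns must be 0/1.

## CLI

```sh
ipsipanel simulate    -c sim.yaml          # panel.csv + schema.yaml + truth.csv
ipsipanel estimate    -c run.yaml --plots  # curve.csv, diagnostics, figures
ipsipanel sensitivity -c run.yaml          # sensitivity.csv over rho_grid
ipsipanel diagnose    -c run.yaml          # overlap / shifted-propensity tables
```

Example `run.yaml`:

```yaml
panel: out/panel.csv
schema: out/schema.yaml
ordering: exposure_first
deltas: default          # 2^-9 .. 2^9
outcome_times: [1, 2, 3]
method: [gformula, ipw]
B: 500
mc_size: 2000
seed: 11
out_dir: out/run1
```

Every output directory gets a `manifest.json` (config echo, seed, version,
config hash) sufficient to reproduce the run bit-for-bit. Exit codes:
0 success, 1 user/config error, 2 numerical failure.

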