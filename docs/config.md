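# Configuration schema

CLI commands accept `--config` pointing to a YAML (or JSON) file; flags
override config keys. Model parameters may alternatively come from a named
`--preset` (`esophagus-lrig1`, `esophagus-ahyfp`, `paw`, `ear`, `dorsum`).

```yaml
# single-progenitor model parameters (all rates /week, durations in days)
lambda_week: 2.9      # average division rate
r: 0.10               # symmetric division probability (PP and DD), in [0, 0.5]
rho: 0.65             # progenitor fraction of basal cells, in (0, 1)
family: shifted_gamma # cycle-time law: exponential | shifted_gamma | deterministic
shape: 8.0            # gamma shape k (ignored for exponential/deterministic)
t_min_days: 0.5       # refractory minimum cycle time
```

The stratification rate is always derived from the homeostatic identity
`Gamma = rho * lambda / (1 - rho)`.

Every command writes `<out>.manifest.json` beside its output with the
resolved config, seed, package version and wall time. Exit codes: 0 success,
2 usage error, 3 validation error, 4 numerical failure.

## Table formats

Clone table (CSV canonical, TSV accepted; extra columns preserved):

| column       | meaning                                   |
|--------------|-------------------------------------------|
| mouse_id     | animal identifier                          |
| time_days    | days post induction                        |
| clone_id     | clone identifier                           |
| n_basal      | basal cells in the clone (>= 0)            |
| n_suprabasal | suprabasal cells in the clone (>= 0)       |

Intensity table:

| column       | meaning                                   |
|--------------|--------------------------------------------|
| mouse_id     | animal identifier                          |
| time_days    | chase time (days)                          |
| fov_id       | field of view                              |
| cell_id      | nucleus identifier                         |
| intensity    | fluorescence (arbitrary units, > 0)        |
| is_leukocyte | CD45+ flag; excluded from statistics       |
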