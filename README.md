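# cumulair

Cumulative air-pollution exposure assessment at a fine spatial scale,
accounting for residential mobility.

Epidemiological studies of long-term pollutant effects (cancer,
cardiovascular disease) need cumulative exposure over a latency window of
10–20 years, assigned at a fine spatial unit such as a census block. Two
sources of misclassification get in the way: modelled concentration fields
rarely reach far enough back in time, and people move. `cumulair`
implements a complete pipeline addressing both, for exposure assessors and
environmental epidemiologists working with semi-ecological designs:

1. **Station assignment** — units and fixed monitoring stations are grouped
   by hierarchical agglomerative clustering of their standardized annual
   concentration profiles (correlation distance, average linkage), and each
   unit is assigned the spatially nearest station of its cluster as its
   *index monitor*.
2. **Retrospective reconstruction** — per-series log-linear trends and a
   per-unit log-log calibration on the index monitor,
   `log E_N(y) = a_N + b_N · log S_m(y)`, back-cast unit annual means into
   years before the modelled period, with hold-out validation to quantify
   the error of the chain.
3. **Mobility-weighted exposure** — a row-stochastic residence-transition
   matrix (with an absorbing outside-area category C) propagates each
   unit's population backwards in time. The weighted exposure at lag L is

       W[E_i(j−L)] = P_NN·E_N(j−L) + Σ_u P_uN·E_u(j−L) + P_cN·E_c(j−L)

   and the cumulative exposure over the window is the average of the
   weighted terms for L = 0…Lmax. Contrasting it with the plain average of
   the unit's own series quantifies the bias of ignoring mobility.

A synthetic-data generator (`simulate_area`) produces full input bundles
with known ground truth — cluster-specific log-linear trends, seasonal
daily monitor series, distance-decaying mobility — so every stage is
testable without any external data. A reference dataset for the 20 Paris
arrondissements (2006 census mobility, five-year window) is bundled.

## Worked example

```python
from cumulair import (SimulationSpec, simulate_area, cumulative_exposure,
                      area_report, render_report)

synth = simulate_area(SimulationSpec(
    n_units=8, n_stations=4, n_clusters_true=3,
    trend_slopes=(0.92, 1.05, 0.99), mobility_intensity=0.25,
    outside_fraction=0.6, period_years=1, rng_seed=6))
b = synth.bundle
results = [cumulative_exposure(u, 2012, 5, b.mobility, b.field, b.outside)
           for u in b.mobility.unit_ids]
print(render_report(area_report(results)))
```

prints

```
unit          mobility %     without        with      diff
----------------------------------------------------------
U002                30.3       54.67       51.77      2.90
U008                24.9       47.26       46.68      0.59
U003                24.8       62.97       58.11      4.86
U001                24.8       68.64       59.32      9.31
...
```

Each row is one spatial unit, ranked by its degree of mobility (the share
of current residents who lived elsewhere one census period earlier). The
two exposure columns are the 5-year cumulative NO₂ exposure (µg/m³)
without and with residential mobility; `diff` is the exposure that plain
residence-at-reference-year assignment would mis-attribute. Unit U001, for
instance, sits in a high-concentration cluster but a quarter of its
residents arrived from cleaner places, so ignoring mobility overstates its
cumulative exposure by 9.3 µg/m³.

The `examples/` directory has one short script per capability (simulation,
clustering, back-casting, mobility weighting, the Paris table), and the
same pipeline is scriptable from the shell:

```sh
cumulair simulate --out data --seed 5
cumulair cluster --data data --k 7 --out out
cumulair reconstruct --data data --index-map out/index_map.csv \
    --from 1992 --to 2001 --out out
cumulair cumexp --data data --ref-year 2012 --lmax 5 --out out/cumexp.csv
cumulair report out/cumexp.csv
```

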