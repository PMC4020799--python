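# pengdisp

Post-fledging dispersal analysis for satellite-tracked king penguins
(*Aptenodytes patagonicus*): Argos track filtering and migratory
statistics, environmental gridding with moving-window gradients, masked
pseudo-absence habitat modelling with a 100-replicate binomial-GLM
ensemble, and categorized habitat-probability maps.

Juvenile king penguins fledge from colonies in the Southwest Atlantic
and disperse for months across the Southern Ocean before anyone sees
them again. Satellite transmitters on a 4 h on / 20 h off duty cycle
produce Argos fixes of mixed quality (location classes 0–3); this
package turns such tracks into per-bird migratory parameters and into a
species-distribution model that asks which environmental conditions —
bathymetry, chlorophyll-a, sea-surface temperature, sea-surface height,
and their local gradients — predict where the birds spend their time.
It is aimed at movement ecologists working with Argos-class telemetry
and gridded oceanographic covariates.

## The model

Presence/absence of a bird in a 0.04° grid cell is modelled as

    logit P(presence) = β₀ + Σⱼ βⱼ xⱼ

with standardized covariates xⱼ drawn from {BAT, BAT.G3, CHLa, CHLa.G3,
SST, SST.G3, SSH, SSH.G3}. Gradients (`.G3`) are the proportional
change PC = (max − min)·100/max over a 3×3-cell moving window.
Pseudo-absences equal in number to the presences are sampled from
data-complete cells outside a 3×3 mask around every presence. Terms
are selected by backward–forward stepwise AIC from the full model;
competing models within ΔAIC ≤ 2 are reported with Akaike weights
wᵢ = exp(−Δᵢ/2)/Σⱼ exp(−Δⱼ/2). The whole fit is replicated 100 times
(fresh pseudo-absence set and stratified 70/30 train/validation split
per replicate) and validated by the rank-based AUC on the held-out 30%,
with mean AUC ≥ 0.7 marking a usable model. A selected model projects
to a probability map, masked outside its environmental envelope and
optionally cut into low / medium / high classes at 0.33 and 0.66.

Because the original tracking data and satellite layers are not public,
the package ships a synthetic study generator (smoothed-noise
environmental fields in realistic ranges, habitat-biased correlated
random walks, duty-cycled Argos observation with class-dependent error)
whose known logistic ground truth makes every stage testable.

## Worked example

Migratory statistics of the 2007 fledgling cohort (18 birds, two
colonies), from the bundled reference table:

```python
>>> from pengdisp import load_reference_cohort, cohort_stats
>>> ref = load_reference_cohort()
>>> s = cohort_stats(ref)
>>> round(s["duration_days_mean"], 2), round(s["duration_days_sd"], 2)
(117.28, 57.91)
>>> int(s["duration_days_total"])
2111
>>> int(cohort_stats(ref, group="FI")["duration_days_total"])
1066
```

The birds were tracked for 2111 days in total — 1066 from the Falkland
Islands, 1045 from South Georgia — a mean tracking period of 117 ± 58
days per bird.

A full synthetic study, from simulation to fitted ensemble:

```python
>>> from pengdisp.pipeline import run_recovery_study, desk_grid
>>> study = run_recovery_study(seed=42, grid=desk_grid(0.5), n_rep=100)
>>> round(study.summary.mean_auc, 3), study.summary.usable
(0.709, True)
>>> study.true_term_recovery()["BAT"]
{'selected': 100, 'correct_sign': 100}
```

Here the ground truth prefers deep, cool, chlorophyll-rich water
(BAT +1, SST −1, CHLa +1 on standardized scales); all 100 replicates
recover every true term with the correct sign, and the ensemble's mean
held-out AUC of 0.709 clears the usability threshold.

The same chain is scriptable from the shell:

```
pengdisp simulate --cell 0.5 --days 110 --seed 3 --out sim/
pengdisp tracks --input sim/fixes.csv --colonies colonies.csv --out summary.csv
pengdisp occurrences --tracks daily.csv --stack sim/stack.nc --sets 100 --seed 5 --out occ.csv
pengdisp fit --occurrences occ.csv --stack sim/stack.nc --replicates 100 --seed 5
pengdisp map --model fit_manifest.json --stack sim/stack.nc --out map.nc
```

See `docs/methods.md` for the modelling conventions, the synthetic
generator's assumptions, and known limitations.

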