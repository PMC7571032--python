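# aarisk

Occurrence-survey analysis and deterministic dietary risk assessment for
acrylamide in baked products.

Acrylamide (AA) is a process contaminant formed by the Maillard reaction in
foods cooked above 120 °C. It is a probable human carcinogen (IARC group
2A), and bread — eaten daily in large amounts — can be a major dietary
source. `aarisk` is for food-safety analysts who run market surveys of AA
occurrence and need to turn per-sample concentrations into (i) summary
tables screened against the EU Regulation 2017/2158 benchmark levels and
(ii) a deterministic exposure and risk characterization by the margin of
exposure (MOE) approach.

## The model

Chronic daily intake for a (product, age group, consumer percentile,
concentration scenario) cell is

```
DI = C · Q / BW        [ng/kg bw/day]
```

with `C` the occurrence concentration (µg/kg ≡ ng/g), `Q` the daily
consumption (g/day) and `BW` the body weight (kg). Two concentration
scenarios are crossed with two consumer percentiles: the best scenario (BS)
uses the median concentration observed in the samples, the worst scenario
(WS) the 95th percentile; consumption enters at the median and
95th-percentile consumer.

Risk is characterized per toxicological endpoint as

```
MOE = BMDL10 / DI
```

with BMDL10 the benchmark-dose lower confidence limit for a 10% response
(0.43 mg/kg bw/day, peripheral-nerve axonal degeneration in rats; 0.17
mg/kg bw/day, Harderian-gland adenocarcinomas in mice). An MOE of 125 or
above means low concern for neurotoxicity; carcinogenicity requires an MOE
strictly above 10,000.

Around this core the package provides: censoring-aware occurrence
summaries; strict benchmark exceedance screening; one-way ANOVA with Tukey
HSD and a compact letter display (insert-and-absorb); Spearman
moisture–concentration correlation and a local-linear smoother with a 95%
confidence band; ICH-style method QC (calibration fit, LOD = 3.3 σ/S,
LOQ = 3 LOD, recovery, intra/inter-day RSD); and a seeded synthetic-data
generator calibrated to a 200-sample survey of ten Italian baked products,
whose published intake grid the pipeline reproduces as a regression
surface.

## Worked example

Exposure of adolescent soft-bread consumers in the built-in calibrated
study (median concentration 55 µg/kg, 95th percentile 82 µg/kg; body
weight 55 kg):

```python
from aarisk import defaults, exposure

summary = [s for s in defaults.reference_summaries() if s.product == "Bread"]
profile = [p for p in defaults.calibrated_consumption()
           if (p.product, p.age_group) == ("Bread", "adolescents")]
for cell in exposure.scenario_grid(summary, profile):
    for ep in defaults.endpoints():
        res = exposure.margin_of_exposure(cell.di, ep, cell=cell)
        print(f"{cell.consumer_percentile:>6} consumer {cell.scenario}: "
              f"DI = {exposure.round_half_away(cell.di):>3} ng/kg bw/day, "
              f"MOE_{ep.name} = {exposure.round_half_away(res.moe):>5} ({res.concern})")
```

prints

```
median consumer BS: DI =  84 ng/kg bw/day, MOE_neurotoxic =  5119 (low_concern)
median consumer BS: DI =  84 ng/kg bw/day, MOE_carcinogenic =  2024 (concern)
median consumer WS: DI = 125 ng/kg bw/day, MOE_neurotoxic =  3434 (low_concern)
median consumer WS: DI = 125 ng/kg bw/day, MOE_carcinogenic =  1357 (concern)
   p95 consumer BS: DI = 236 ng/kg bw/day, MOE_neurotoxic =  1822 (low_concern)
   p95 consumer BS: DI = 236 ng/kg bw/day, MOE_carcinogenic =   720 (concern)
   p95 consumer WS: DI = 352 ng/kg bw/day, MOE_neurotoxic =  1222 (low_concern)
   p95 consumer WS: DI = 352 ng/kg bw/day, MOE_carcinogenic =   483 (concern)
```

Reading: a median adolescent consumer eating 84 g of soft bread a day at
the median concentration ingests 84 ng of AA per kg body weight per day.
Every neurotoxic MOE is comfortably above 125 (low concern); every
carcinogenic MOE is far below 10,000, i.e. the carcinogenic margin of
safety is insufficient across all scenarios — the survey's headline
finding.

The full pipeline (summaries → screening → letters → correlation → intake
grid → MOE report → QC) runs from the shell:

```sh
aarisk -v report --seed 1 --outdir out/
```

and writes a deterministic report bundle (CSV tables plus `report.json`).

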