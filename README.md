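# n2otrace

Rate inference for ¹⁵N-labeled N₂O incubation studies in estuarine and
coastal waters: gross N-transformation and N₂O-production rates from
time-course incubations (with ⁴⁴/⁴⁵/⁴⁶N₂O isotopologue accounting), air–sea
N₂O flux, N₂O yields and oxidative/reductive source partitioning, and
particle size-spectrum summaries — plus a synthetic-data generator with
known ground truth for end-to-end validation.

## What it computes

- **`isotope_model`** — ¹⁵N atom fractions, binomial isotopologue pairing
  probabilities, inference of the unlabeled (mass-44) N₂O production rate
  from the doubly labeled (mass-46) channel, totals in molecule and N
  units, and a binomial-consistency QC diagnostic.
- **`rate_estimation`** — pooled-replicate OLS slopes of labeled-product
  accumulation vs time (hours in, per-day out), tracer-dilution correction
  (slope / atom fraction), below-detection flagging, first-order error
  propagation for the isotopologue sum, per-station rate tables.
- **`gas_exchange`** — N₂O solubility (Weiss & Price 1980 moist-air
  function), percent saturation, Schmidt number (Wanninkhof 2014 N₂O
  polynomials with linear fresh/seawater interpolation), transfer velocity
  k = 0.251 u²(Sc/660)^-0.5, flux in µmol m⁻² d⁻¹, and dissolved-oxygen
  unit conversion with hypoxia flagging (threshold 62.5 µmol L⁻¹).
- **`partitioning`** — N₂O yields (per NO₂⁻ produced), fractional
  oxidative vs reductive contributions with delta-method (or Monte-Carlo)
  uncertainties, PN-normalized size-spectrum rates, nir:amoA gene ratios,
  a Pearson correlation screen with p < 0.05 masking, Student's t-tests,
  and depth-integrated production-to-flux ratios.
- **`synthetic_data`** — seeded forward simulation of all six incubation
  experiments, station/profile tables, a brute-force molecule-pairing
  oracle, and a hybrid (two-pool) pairing mode for robustness checks.
- **`cli_io`** — documented CSV dialects, YAML run configuration, and the
  `n2otrace` command line.

## Command line

```sh
n2otrace simulate --seed 3 --out run/            # synthetic fixtures
n2otrace rates --incubation run/incubation.csv --out run/rates.csv
n2otrace flux --stations run/stations.csv --out run/flux.csv
n2otrace partition --rates run/rates.csv --stations run/stations.csv \
    --flux run/flux.csv --out run/partition.csv
n2otrace report --config config.yaml --seed 3 --out run/report.json
```

Input formats are documented in `src/n2otrace/cli_io.py`. All commands log
to stderr and only `report --stdout` writes results to stdout.

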