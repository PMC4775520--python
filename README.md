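# sizespectra

Body-size spectrum analysis of terrestrial mammal assemblages: how fast
does species diversity fall as body mass rises, and does that rate — and
the skewness and modal size of the mass distribution — depend on the
spatial scale (one locality versus a whole continent) at which the
assemblage is delimited?

The package is written for macroecologists who work with species lists
and body-mass compilations. It takes a long-format locality table
(`locality_id, continent, species_id`) plus a species→mass lookup
(grams), and computes for every assemblage:

* **diversity/size slope** *b*: OLS of log₁₀ *S(m)/w* on log₁₀ *m*, where
  species are counted in log₂ mass classes, each count is divided by the
  class's linear width *w* in grams (wider log classes catch more species
  by chance alone), and the class boundaries are placed by three rounding
  conventions of log₂ mass — floor, ceil and round-half-up — whose three
  fitted slopes are averaged to cancel the boundary-phase bias of any one
  binning. The fractal-niche prediction is *b* = −2/3 on mass (−2 on
  length); a slope *b* means each halving of body mass multiplies species
  number by 2^|b|.
* **g1 skewness** on raw and on log₂-transformed masses:
  g1 = n Σ(xᵢ−x̄)³ / [(n−1)(n−2)s³]. Positive values = assemblage
  dominated by small species; the two scales respond to different parts
  of the distribution and are reported separately.
* **half-sample mode** on raw and log₂ scales: recursively narrow to the
  tightest contiguous half of the sorted sample — an analytic, binning-free
  modal body size.
* median mass, richness, and % of species under 100 g.

A comparative layer then tests slopes against −2/3 (one-sample *t*),
contrasts continents (Kruskal–Wallis plus pairwise Mood median tests with
a compact-letter display), regresses slope on richness and compares the
residuals, computes Spearman **semi-partial** correlations of each shape
parameter on median size, richness and continent, and tabulates
continental-vs-local means for all seven parameters.

Because real locality lists are compiled from literature and are not
redistributable, the package ships a seeded synthetic study: skew-normal
log₂-mass pools (grams to megafauna) in which each species' per-locality
occupancy probability is logistic in log₂ mass. A positive mass
coefficient encodes the observation that large species have large
geographic ranges; small species then turn over faster in space, so the
continental pool accumulates proportionally more small species than any
one locality — reproducing the empirical contrast: steeper continental
slopes, higher continental skewness, smaller continental modes.

## Worked example

```python
import sizespectra as sz

pool = sz.generate_continent_pool(sz.turnover_protocol_config(), seed=3)
assemblages = sz.sample_localities(pool, seed=4)
summaries = sz.summarize_assemblages(assemblages, pools=[pool])

cont = summaries[summaries["scale"] == "continental"].iloc[0]
loc = summaries[summaries["scale"] == "local"]
print(f"continental: slope {cont.slope:.2f}  skew(lin) {cont.skew_linear:.1f}  "
      f"skew(log2) {cont.skew_log2:.2f}  mode {cont.mode_linear_g:.0f} g  "
      f"%<100 g {cont.pct_under_100g:.0f}%")
print(f"local mean : slope {loc.slope.mean():.2f}  skew(lin) {loc.skew_linear.mean():.1f}  "
      f"skew(log2) {loc.skew_log2.mean():.2f}  mode {loc.mode_linear_g.mean():.0f} g  "
      f"%<100 g {loc.pct_under_100g.mean():.0f}%")
print(f"halving gain at continental slope: "
      f"{sz.fractal_expected_increase(cont.slope):.0f}%")
```

prints

```
continental: slope -1.26  skew(lin) 36.0  skew(log2) 0.70  mode 21 g  %<100 g 32%
local mean : slope -1.17  skew(lin) 16.1  skew(log2) 0.49  mode 494 g  %<100 g 1%
halving gain at continental slope: 140%
```

The continental assemblage loses diversity faster with size (−1.26 vs
−1.17), is more right-skewed, peaks at a smaller modal mass and holds a
far larger share of sub-100 g species than the average locality sampled
from it — the signature of size-dependent spatial turnover, produced here
with no local competition at all. A slope of −1.26 means each halving of
body mass brings ~140 % more species, against the 59 % the fractal-niche
slope of −2/3 would predict.

## Command line

```sh
sizespectra run --out results --seed 0            # full bundled study
sizespectra simulate --config my.yaml --out DIR   # pools + locality CSVs
sizespectra summarize --localities F --masses F --out DIR
sizespectra compare --summaries F --out DIR
```

`run` executes the bundled three-continent design (30 + 35 + 28
localities) end to end and writes the assemblage CSVs, a 96-row summary
CSV (93 localities + 3 continents), a JSON report with the contrast
tables, residuals and a run log. Exit codes: 0 ok, 1 input/configuration
error, 2 computation error.

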