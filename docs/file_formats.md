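# File formats

All tabular output is TSV with a header row and `NA` for undefined cells.
Window and track coordinates are BED-style half-open 0-based; variant
positions are VCF 1-based.  Conversion between the two conventions happens in
one place (`tepop.cli_io` / `tepop.popgen_windows.assign_windows`).

## TE call VCF (MELT-style dialect)

One record per insertion; `REF=N`, `ALT=<INS:ME>`, genotypes as plain `GT`
(`0/0`, `0/1`, `1/1`, `./.`).  INFO keys:

| key | type | meaning | required |
| --- | --- | --- | --- |
| `SVTYPE` | String | always `INS` | yes |
| `MEINFO` | String | TE clade (e.g. `L1`, `CR1`, `SINE2`) | yes |
| `SVLEN` | Integer | insertion length, bp | yes |
| `DIV` | Float | divergence to the clade consensus (fraction) | yes |
| `CR` | Float | calling rate before filtering (fraction) | yes |
| `CAT` | String | category (`nLTR-RT`, `SINE`, `LTR-RT`, `DNA`) | no |
| `CSTART`/`CEND` | Float | element start/end on its consensus, bp | no |

Unknown INFO keys are ignored with a logged warning; a record missing a
required key is rejected with its coordinates in the message.

## SNP VCF

Standard VCF with `GT` genotypes.  The two outgroup individuals used for
polarization are ordinary sample columns, designated through the population
map.

## Population map

Two-column TSV without header: `individual<TAB>cluster`.  Outgroup clusters
are named `outgroup_*` by default (configurable).

## Window tables and score tracks

BED3(+): `chrom  start  end  [name  score]`.  Window tables must tile without
overlap; candidate-window tracks are plain interval sets.

## Simulation output (`tepop simulate`)

Per replicate:

* `repNNN.variants.tsv` — one row per segregating or fixed variant:
  `position  type(SNP|TE)  length_class(-1|0|1)  sel_code  count
  fixed_in_population`; `count` is the population allele count (2N for fixed
  rows).
* `repNNN.sample.tsv` — the sampled diploids' dosages: `position  type
  length_class  sel_code  dip0..dipK`.
* `repNNN.regions.tsv` — region intervals: `start  end  class  rec_rate`.
* `manifest.json` — command, config echo, root seed, package version, input
  digests, timestamp.

## Summary tables

`tepop summarize` emits one row per (replicate, region, TE length class):
`replicate  region  length_class  mean_freq  poly_density  fixed_density
snp_mean_freq` (densities per Mb; `mean_freq` NA when no polymorphic variant
of that class segregates in the region).  `tepop classify` emits
`length_class  freq_sign  poly_sign  fixed_sign  freq_level  label`.
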