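# trafficlines

Genetic calculus for *Arabidopsis thaliana* **traffic lines** — stocks that
carry a pair of linked seed-expressed fluorescent transgenes (*pNAP::eGFP*,
green, and *pNAP::DsRed*, red) in cis on one chromosome. Seed fluorescence
then reports inheritance of that chromosome segment: a doubly marked
chromosome works like a balancer for whatever sits in trans to it, and the
dosage sensitivity of the reporters (0/1/2 copies → nonfluorescent / moderate
/ strong) lets homozygotes and heterozygotes be told apart by eye in dry
seeds, before planting.

The package is for plant geneticists planning or interpreting crosses with
these stocks. It provides:

- **`trafficlines.catalog`** — the published table of 162 short-interval
  marker pairs (ABRC ID, insertion coordinates on the Col reference,
  testcross seed-class counts, printed cM and cM/Mb), shipped as a TSV,
  with integrity checking, interval-containment queries ("which lines span
  my locus?"), coverage summaries, and BED export.
- **`trafficlines.linkage`** — recombination-fraction estimation from the
  four fluorescence-classed testcross counts. In repulsion phase the
  recombinant classes are the double-fluorescent and nonfluorescent seeds,
  so with recombinant count R out of N seeds the map distance is the direct
  rule cM = 100·R/N, with a Wilson score interval, plus exact 2×2
  between-line comparisons and exact binomial segregation-distortion tests.
- **`trafficlines.crosscalc`** — an exact probability engine for the
  crossing schemes these lines enable: gamete laws with a coefficient of
  coincidence *c* on adjacent-segment double crossovers, offspring and
  seed-class distributions, genotype posteriors given a fluorescence class,
  balancer double-recombination leakage (c·r₁·r₂ / (1 − r₁ − r₂ + 2c·r₁·r₂)),
  rescue- and separation-scheme calculators, and screening sample sizes.
- **`trafficlines.meiosim`** — a stochastic meiosis simulator (stationary
  gamma-renewal crossovers, shape ν, ν = 1 ⇒ Poisson/Haldane) that generates
  synthetic seed populations and count tables and serves as a brute-force
  cross-check of the exact engine.
- **`tl`** — a command-line front end over all of the above.

## Worked example

Which lines span the *MYB75* region on chromosome 1, and what does the
catalog say genome-wide?

```text
$ tl catalog span --chrom 1 --pos 21600000
# trafficlines 0.1.0 command=catalog span chrom=1 pos=21600000
line_id  upper_pos  lower_pos  interval_nt  cM
1.68     21509119   22359854   850735       3.6
1.55     21089182   22097069   1007887      21.4
```

(line 1.55 spans the locus with an unusually high 21.4 cM; 1.68 is the
shorter, better-behaved balancer for it.)

```text
$ tl catalog summary
# trafficlines 0.1.0 command=catalog summary rows=162
mean interval: 1.2 Mb (1.2423)
mean distance: 6.9 cM (6.8691)
rate candidates: column mean 6.2660 cM/Mb, ratio of means 5.5295 cM/Mb
```

The averages say a typical line marks ~1.2 Mb ≈ 6.9 cM, and two defensible
genome-wide cM/Mb summaries are printed because they disagree.

Estimating a map distance from testcross counts (the counts file holds the
four seed classes dsRed / GFP / both / nonfluorescent and the phase):

```text
$ tl estimate --counts counts.tsv        # 196 194 21 12, repulsion
# trafficlines 0.1.0 command=estimate level=0.95 rule=direct
r_hat      cM   se       ci_low     ci_high   n
0.0780142  7.8  0.01304  0.0560873  0.107537  423
```

i.e. 33 recombinant seeds out of 423 give 7.8 cM with a 95% Wilson interval
of roughly 5.6–10.8 cM.

Exact scheme expectations, e.g. selfing a balanced lethal heterozygote
(lethal mutation in trans to the markers, recombination neglected):

```python
>>> from trafficlines import rescue_scheme
>>> rescue_scheme(0.0, 0.0, tau=0.0)["fluorescent_viable"]
0.75
```

Three quarters of the seeds fluoresce (homozygous-TL strong, heterozygous
moderate) and the nonfluorescent quarter is the dead mutant-homozygote
class — the fingerprint that the balanced stock is behaving.

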