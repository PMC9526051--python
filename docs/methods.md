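# Methods

## The system

A traffic line (TL) carries a *pNAP::eGFP* and a *pNAP::DsRed* T-DNA
insertion in cis, a short distance apart on one Arabidopsis chromosome. The
Napin promoter expresses the reporters in dry seed, and intensity tracks
copy number: 0 copies → nonfluorescent, 1 → moderate, 2 → strong, per
channel. Two uses follow. As a *recombination screen*, seeds whose two
channels differ in dosage mark exchanges inside the interval. As a
*balancer*, the nonfluorescent seeds segregating from a TL/+ parent carry
the unmarked homolog — contaminated only by double recombination within the
interval, which is rare when the interval is short.

## Catalog handling

The packaged table (`data/catalog.tsv`) is a verbatim transcription of the
published 162-row resource, thousands separators and inconsistencies
included. Design choices:

- **Sample size.** All recomputation uses the sum of the four seed-class
  counts, never the printed "Total" column. The table contains rows (1.70,
  5.21) where the two disagree, and in 1.70 the printed cM is consistent
  only with the class sum. Printed totals are retained and checked.
- **Rounding.** Printed values are 1-decimal; recomputed values are rounded
  half-up and compared with a ±0.1 cM / ±0.2 cM/Mb band, because the table
  itself mixes rounding conventions. cM/Mb is recomputed from the *rounded*
  cM (verified on row 3.49: 16.5 = 2.0/0.121308, not 16.8 from the raw
  fraction).
- **Flags, not errors.** Internal contradictions (interval length vs
  coordinates, totals, cM, rates, duplicated count vectors) are reported by
  `check_integrity` as a closed set of flag kinds; loading never fails on
  them. On the packaged table the flagged rows are 1.29, 2.17, 3.38, 5.21
  (cM), 1.29, 3.38, 5.21 (rate), 1.70, 2.36, 5.21 (total), 1.42 (length),
  and 5.38 (counts identical to 5.34).
- **Coordinates.** Spanning queries treat marker positions as 1-based
  closed intervals; BED export is standard 0-based half-open.
- The genome-wide cM/Mb average is reported two ways (column mean 6.27,
  ratio of means 5.53) because the two summaries genuinely disagree and
  neither is canonical; no single value is asserted.

## Linkage estimation

With markers in repulsion in the testcross parent, the double-fluorescent
and nonfluorescent classes are recombinant; in coupling the single-colour
classes are. The estimator is the pooled recombinant proportion r̂ = R/N
with the direct rule cM = 100·r̂ — the convention the catalog's own
arithmetic follows; Haldane (−50·ln(1−2r)) and Kosambi conversions exist
only for simulator calibration. The interval is the Wilson score interval
(default 95%), which is well behaved at the small recombinant counts
typical of short intervals; r̂ > 0.5 is reported as computed but flagged as
suspected phase mis-specification. Between-line comparison is a two-sided
Fisher exact test on (recombinant, non-recombinant); within-pair 1:1
distortion uses the exact two-sided binomial. All of these come from scipy;
the test suite re-derives the exact p-values by brute-force tail
enumeration as an independent route.

## Exact cross engine

Gametes are enumerated per chromosome from per-segment exchange indicators.
For up to three segments the joint law is fixed by its moments: marginals
r_i, adjacent pairs c·r_i·r_j, non-adjacent pairs independent, triple
c²·r₁·r₂·r₃; pattern probabilities follow by inclusion–exclusion and each
pattern yields its two strand-phases at probability ½. The scalar
coefficient of coincidence c ∈ [0,1] is the entire interference model here —
the minimal choice when interference is known only qualitatively. Public
maps allow at most 3 linked loci per chromosome; the 4-locus mutation-
separation scheme uses the same engine internally, and anything longer is
delegated to the simulator. Unlinked chromosomes multiply.

Derived closed forms: double-recombinant gamete frequency c·r₁·r₂; balancer
leakage P(TL allele at an interior locus | gamete carries neither marker) =
c·r₁·r₂ / (1 − r₁ − r₂ + 2c·r₁·r₂), maximal at the interval midpoint for
fixed r₁+r₂.

Seed classes: dosage is counted on the diploid embryo (triploid endosperm
dosage is not modelled). Misclassification ε moves a seed's intensity to an
adjacent class per channel, independently between channels; the middle
class splits its ε evenly between both neighbours, the end classes put all
of it on their single neighbour. ε defaults to 0 and is a free parameter,
not fitted — observed scoring concordance could reflect misreading, double
recombination, or both. Lethality is evaluated on the true genotype after
fertilisation; dead seeds remain observable as a class (shriveled seeds are
scored). In the rescue calculator, transformation hits each T1 seed
independently at rate τ and rescues homozygous lethality; the category list
includes the small fluorescent-dead and wild-type-homozygote classes that
appear as soon as r > 0, so the distribution always sums to 1.

Scheme setup from physical coordinates assumes a uniform local rate
(fractions proportional to physical length within an interval); callers may
always pass explicit segment fractions instead. The worked
mutation-separation example uses 0.6 Mb / 45 kb / 0.6 Mb.

## Simulator

Crossover points along a chromosome are a stationary gamma renewal process
with shape ν and rate 2ν per Morgan (events on the bivalent), each point
retained with probability ½ (chromatid sampling), so retained crossover
density is 1/Morgan for every ν. ν = 1 gives Poisson crossovers and exactly
Haldane's map function; larger ν spaces events more regularly and
suppresses nearby doubles. Stationarity is implemented by drawing the first
arrival as U·Gamma(ν+1) (uniform fraction of a length-biased interval).
Segment lengths default to the Haldane inversion of the map's fractions, so
at ν = 1 simulated two-point fractions equal the map's r exactly. The
mapping between ν and the engine's scalar c is empirical only (estimated ĉ
per simulation); no closed form is claimed. Obligate chiasma, gene
conversion, and sex-specific maps are not modelled.

The synthetic-data generator emulates the study's data shapes — repulsion-
or coupling-phase multinomial count tables at a true r, and F2 seed
populations with dosage-coded intensities, optional adjacent-class
misreading, and optional lethality. It does not emulate transgene
silencing, local rearrangements that suppress recombination, or variable
expressivity of the reporters, so passing tests validate the calculus and
the estimators, not those biological failure modes of real stocks.

## Numerical and testing choices

- All distributions are required to sum to 1 within 1e-12.
- Comparisons against printed values use round-half-up at 1 decimal.
- Stochastic tests are seeded (fixed constants in the suite) and use
  3-standard-error bands; the oracle-equivalence checks run 10⁶ gametes per
  configuration on the grid r₁, r₂ ∈ {0.01, 0.035, 0.1}, estimator
  calibration uses 2000 replicates of N = 300 at r = 0.069, and
  smaller-scale unit checks use 10⁴–10⁵ draws — sizes chosen so the whole
  suite runs in seconds while keeping the bands meaningful.
- Dual routes are kept separate everywhere: the exact engine is validated
  against the independent simulator, scipy's exact tests against brute-force
  enumeration, and closed forms against grid evaluation.

## Known limitations

- Interference is a single scalar c (engine) or a single shape ν
  (simulator); no chi-square/two-pathway likelihoods, no position-dependent
  rates within a segment.
- One marker locus per channel per map; no polyploidy, no X-linkage, no
  fitness effects beyond the declared lethal set.
- The catalog ships exactly what the published table prints: two lines used
  in the original demonstrations (4.22, 2.32) are absent from it and are not
  invented, so scheme examples involving them use nearby parameter values.
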