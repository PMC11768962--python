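# Methods

## Model and assumptions

The package studies one biallelic locus in a synthetic variety (SV)
formed by random mating of `l` unrelated parental lines, each with
inbreeding coefficient `F` (the probability its two alleles A1 and A2
are identical by descent) and each represented by `m` plants from its
selfed progeny. Assumptions throughout:

* diploid, monoecious, random-mating reproduction (maize-like); mating
  pairs are ordered and drawn with replacement, so selfing is included
  — the denominator of the inbreeding formula counts all m²l ordered
  within-line pairs;
* no migration, mutation or selection; a single generation of mating
  (Hardy–Weinberg frequencies are reached in one generation);
* lines are unrelated, so cross-line matings contribute no identity by
  descent; the SV-level coefficient is the per-line value divided by l;
* sampling of plants is with replacement from the selfed-progeny array
  GA4 = (1/4, 1/4, 1/4, 1/4) over the ordered genotypes
  (A1A1, A1A2, A2A1, A2A2), or its collapsed 3-class form
  GA3 = (1/4, 1/2, 1/4).

The two heterozygote orderings are deliberately kept distinct —
they are distinct sampling outcomes — and merging them
(`collapse_to_ga3`) is an explicit operation, never implicit.

## The grouped sample behind the inbreeding formula

The closed formula for F_SynL decomposes the m plants of a line into
g = ⌊m/4⌋ *complete groups*, each containing one plant of every GA4
genotype, plus e = m mod 4 leftovers of distinct genotypes. That
structure matters: within a complete group the 12 ordered crosses are
crosses of *distinct* genotypes, whose average progeny inbreeding is
(5+7F)/12, strictly below the independent-pair average (1+F)/2. The
grouped construction is therefore a genuine stratification of the
sample, not mere bookkeeping. Had the m plants been drawn i.i.d. from
GA4, the coefficient would be [m(3+F)/4 + m(m−1)(1+F)/2]/(m²l) —
9/16 instead of 1/2 at m=4, F=0, l=1.

The gene-dropping simulator consequently offers both constructions:
`sampling="grouped"` (default) reproduces the formula; `sampling="iid"`
exists to quantify the modelling difference, and a regression test pins
the gap. The retention and allele statistics, by contrast, are defined
on i.i.d. multinomial samples and simulated as such — the two model
readings coexist in the source material and the package keeps both
explicit rather than reconciling them silently.

## Exact arithmetic and dual-route verification

Every analytic module works in `fractions.Fraction`; floats appear only
in the simulator and at presentation boundaries. Each headline quantity
has two independent routes, asserted equal as rationals:

* F_SynL: closed formula vs brute-force averaging of the per-mating
  coefficients over all m² ordered matings (m ≤ 12), with leftover
  genotypes averaged over all ordered selections of e distinct
  genotypes;
* inclusion probability: partition/permutation enumeration vs
  inclusion–exclusion over genotype subsets
  (Σ_S (−1)^|S| (1−p_S)^m), for m ≤ 30 on both arrays, plus direct
  enumeration of all ordered samples for m ≤ 7;
* equal-allele-frequency probability: genotype-count enumeration vs the
  central-binomial identity C(2m, m)/4^m (the 2m gene copies are
  i.i.d. fair draws).

This dual-route design is what certifies cells of the source tables
whose printed figures disagree with their own defining expressions
(see Limitations).

## Numerical and presentation conventions

* Decimal rendering rounds half-away-from-zero (`_rounding.py`), the
  convention under which the reference inbreeding grid reproduces digit
  for digit (0.9375 → 0.94, 0.5833 → 0.58). A truncation helper exists
  because some published probability cells are truncations rather than
  roundings (0.0225531 printed as 0.0225; 0.1409568 as 0.140956; the
  gene-loss 0.001953 as 0.0019).
* JSON output always carries the exact numerator/denominator next to
  the decimal string, so serialization never loses exactness.
* `inclusion_probability` returns 0 for m < arity (the event is
  impossible); `inclusion_breakdown` raises instead, since an empty
  table would be ill-formed.
* g and e are always derived from m (`decompose_sample`), never
  supplied independently, ruling out inconsistent (m, g, e) triples.
* Monomorphic samples are accepted by `progeny_ic_from_sample` and give
  coefficient 1 (fixation), the correct degenerate limit.

## Simulator design

One seeded `numpy` generator per run; identical configurations produce
byte-identical results. For the inbreeding target, each replicate
builds the grouped sample implicitly: parent positions are drawn
uniformly with replacement over the ml plants, positions inside
complete groups map deterministically to genotypes, and the e leftover
genotypes are a fresh random ordered selection per replicate (only the
shared line's assignment can matter, since cross-line pairs are never
IBD). Each parent contributes one uniformly chosen gamete allele; the
two founder alleles of a line are declared IBD with probability F per
replicate. Proportion targets report the binomial standard error
√(p̂(1−p̂)/n) and the z-score against the exact value; the validation
suite requires |z| < 4 at 100,000 replicates over the grid
m ∈ {1..16} × F ∈ {0, 1/2, 1} × l ∈ {1, 4} plus representative sizes
for the retention and allele targets. With the estimator vectorised,
the whole grid runs in seconds; default replicate counts were chosen
so the standard error at proportions near 0.5 is ~0.0016, small enough
to resolve every grid cell difference that the formulas predict.

What the simulator does *not* emulate: real founder panels (related
lines, more than two alleles, multiple loci, linkage, selection during
seed increase), sampling without replacement, or multi-generation
recurrence. Passing tests certify the mathematics of the stated model,
not the field behaviour of any particular variety.

## Known limitations and documented discrepancies

* Scope is a single biallelic locus in lines all sharing one F; the
  three-way-hybrid founder case and performance–heterozygosity
  relations are out of scope.
* Several printed figures in the source tables are inconsistent with
  their own defining expressions; the package computes exactly and its
  tests pin the computed values instead: the 3-class m=15 grand total
  is 0.9733 (printed 0.979), the m=9 value is 0.8498 (printed 0.845),
  the equal-allele-frequency probability at m=4 is 35/128 = 0.2734
  (printed 0.2968), the {2,4,9} set total evaluates to 0.0744 (printed
  0.0722), and the multiple-of-4 grid value at F=0.875 is 0.9375
  (narrative text says 0.975, conflicting with the table's own 0.94).
* The equal-allele-frequency enumeration is O(m³) in terms; fine for
  the design range (m ≤ a few hundred). The partition enumeration is
  exact and fast for the m ≤ 100 range a breeder would consider.
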