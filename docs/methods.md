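# Methods

## Identification model

The reference library is an aligned multi-FASTA whose headers encode
species names (by default, everything before the last underscore-delimited
token; an explicit id→species TSV map overrides this).  Identification is
nearest-neighbour by genetic distance.  Leave-one-out takes each reference
sequence as a query against all others; the tied best-match set keeps every
record within 1e-12 of the minimum defined distance.  The tolerance only
guards against floating-point summation noise — identical site patterns
produce bit-identical distances.

Acceptance at threshold *t* is inclusive (*d* ≤ *t*), so at *t* = 0 only
exact matches (distance zero) identify — the most restrictive setting.
Queries whose tied set mixes species are ambiguous (FP_ambiguous) below
the threshold; above it they are classed FN when the correct species was in
the set, TN otherwise (the above-threshold ambiguous corner is not covered
by the classical TP/FP/TN/FN dichotomy; this resolution treats "a correct
assignment was available and ignored" as FN).  Singleton species stay in
the query set deliberately: a singleton's best match is necessarily
allospecific, which is exactly the incomplete-coverage error the threshold
is meant to control.  Queries with no defined distance to any other record
are reported as undefined and excluded from all metric denominators.

## Distances

Uncorrected *p*, Jukes–Cantor (−¾·ln(1 − 4p/3)) and Kimura 2-parameter
(−½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q), with P and Q the transition and
transversion proportions).  Sites with N or a gap in either sequence are
excluded pair by pair (pairwise deletion); this keeps short or ragged
records usable and is fixed, not configurable.  IUPAC ambiguity codes other
than N are collapsed to N on import, since the models only distinguish
A/C/G/T from missing data.  Pairs outside a correction's log domain
(saturation) or with no overlapping sites get an undefined marker, are
listed in the QC output, and never enter best-match search or the sweep —
silent NaN propagation would corrupt the regression.  The library default
model is K2P, the conventional barcoding choice; the QC and scalar
functions accept all three.

## Threshold calibration

RE = FP/(TP+FP) is computed at `n_thresholds` (default 30, worth raising
when time permits) equally spaced values from 0 to the largest
query–best-match distance, endpoints included.  Thresholds where nothing is
accepted (TP+FP = 0) have no error rate and are dropped from the fit.
Ordinary least squares fits a polynomial of degree 1 (`linear`, default) or
degree ≥ 1 (`polynomial`, default degree 2); points are unweighted.  The
fitted curve is inverted at the target RE (default 0.05): among real roots
inside the swept domain the smallest is returned — conservative thresholds
reject more, never accept more — and the curve is never extrapolated beyond
the largest swept threshold.  No in-domain root means the target error is
unreachable for the library (typically: very low taxon coverage, so RE
exceeds the target even at *t* = 0) and the result carries a warning
message instead of a number.

Ambiguity handling (`incorrect` default, `ignored`, `correct`) is applied
in the metrics layer only; raw per-query outcomes stay auditable.  Under
`correct`, note that all species tied in one ambiguity are effectively
treated as a single species — use with caution.

## Synthetic libraries

The generator emulates a single-locus alignment with cluster-structured
species and incomplete coverage: a uniform random root sequence; one
ancestor per species mutated from the root at rate `inter_p/2` per site
(realized ancestor divergence ≈ 2q(1−q) + 2q²/3 with q = `inter_p/2`, i.e.
approximately `inter_p`); each sequence mutated from its ancestor at rate
`intra_p`; substitutions uniform over the three alternative bases.
Coverage gaps are produced by reducing a fraction
`missing_species_fraction` of species to one record; optional `n_rate`
masking exercises pairwise deletion.  Defaults: 20 species × 5 sequences,
600 sites, intra_p 0.01, inter_p 0.2, missing fraction 0.2, no masking —
a well-separated, mid-sized library with realistic incompleteness.  Test
problem sizes (tens of species, hundreds of sites, tens of replicate
seeds) keep the whole suite in the seconds-to-minutes range.

What the generator does **not** emulate: phylogenetic structure among
species (all ancestors are equidistant from the root, so interspecific
distances are homogeneous), transition/transversion bias, rate variation
across sites, indels (gaps arise only via masking), and deep intraspecific
splits.  Passing tests therefore show correctness of the machinery and
behaviour under idealized cluster-plus-gap conditions, not performance on
real libraries, where intra/inter distributions overlap and distances are
heterogeneous.

## Known limitations

* **Sharp-gap libraries defeat OLS inversion.**  When intra- and
  interspecific best-match distances are separated by a wide empty gap,
  the RE curve is a step located near the top of the sweep domain (the
  domain ends at the largest best-match distance, which is itself an
  allospecific distance).  An OLS polynomial fitted to such a curve crosses
  any mid-step target within the step's rise — at or slightly beyond the
  gap's upper edge — or has no in-domain root at all.  The solved threshold
  is then either unreachable or marginally above the first allospecific
  distance, not inside the gap.  This is a geometric property of
  regression inversion on step data, not a numerical bug; the regression
  approach is aimed at real libraries whose RE rises gradually.  For
  sharply gapped data, the empirical gap bounds reported by the QC output
  are the more informative quantity.
* The regression is unweighted and has no special handling for
  non-monotone RE curves; polynomial fits of higher degree can oscillate.
* No bootstrap confidence interval on the threshold.
* Haplotype counting uses exact string identity of the normalized aligned
  sequences (gaps and N compared literally); pre-mask if that is too
  strict.
* Species delimitation is out of scope: the threshold optimizes
  identification against a given taxonomy and should not be read as a
  species boundary.
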