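# Methods

## The problem

Temperate *pac*-type phages of *Staphylococcus aureus* (80α, φ11) and
*Salmonella* Typhimurium (P22) can move large blocks of host chromosome by
**lateral transduction (LT)**: a prophage that stays integrated after
induction replicates in situ and serves as a packaging substrate, the
terminase initiating at the embedded *pac* site and filling successive
capsids processively along the chromosome.  This package quantifies how
that mechanism compares with the classical mobilome (conjugative and
mobilisable plasmids, ICEs/conjugative transposons, phage lysogenisation,
phage-inducible chromosomal islands, and generalized transduction) and
provides the supporting geometry and a mechanism simulator.

## Mobility statistics (`ltmob.metrics`)

Three statistics put all transfer mechanisms on one scale:

* **Transfer frequency (TE/donor)** — transductant/lysogen titres (TrU/ml)
  divided by the donor density at induction.  Two calibrations are packaged:
  *S. aureus* lysogens induced at OD540 0.15 ≡ 6.5×10⁷ CFU/ml, *Salmonella*
  at OD600 0.20 ≡ 1.0×10⁸ CFU/ml.
* **Cargo capacity rate** — accessory ORFs utilisable by the recipient
  (virulence factors, AMR genes, …) over total ORFs in the transferred
  sequence.  Counts have 0.5 granularity because a headful boundary can cut
  an ORF in half.
* **Relative frequency of genetic mobility** — transfer frequency × cargo
  capacity rate.

All arithmetic is exact-rational (`fractions.Fraction`); cell values like
3.05×10⁻⁵ only reproduce from the exact ORF fraction (6.0×10⁻⁵ × 28/55),
not from the 2-decimal rate 0.51.  Rendering is a separate step: three
significant figures for frequencies/mobilities, two decimals for cargo
rates, **half-up** rounding of the exact value (an exact 3.845×10⁻⁴ prints
as 3.85×10⁻⁴; half-even would disagree with the published tables).

One subtlety: for rows whose frequency is derived from a titre measured in
this-work strain experiments, the comparative tables carry — and their
derived cells multiply — the *rounded* 3-s.f. TE/donor value.  The φ11 row
is the witness: 4.62×10⁻¹ × 3/53 = 2.62×10⁻², whereas the full-precision
6/13 × 3/53 would print 2.61×10⁻².  `build_mobility_ledger` therefore
defines the table frequency of titre-based rows as the 3-s.f. rounding of
the normalisation; `normalize_transfer_frequency` itself stays
full-precision.

Ranking is dense on the upper endpoint of each (possibly range-valued)
statistic, descending, ties broken deterministically by element id, ND rows
ranked jointly last; ranges are closed intervals and scale endpoint-wise;
any statistic with an ND input is ND, never 0.

### The packaged fixture

`ltmob.fixture.paper_fixture()` ships the comparative tables transcribed
cell-for-cell: raw inputs plus the printed derived cells plus a `flags`
column.  Three printed cells are internally inconsistent and are stored
verbatim with flags rather than corrected:

* **Tn916** — printed upper relative mobility 6.25×10⁻¹¹ does not follow
  from 3.4×10⁻⁸ × 2/24 (= 2.83×10⁻⁹); the lower endpoint 5.00×10⁻¹⁰ does
  reproduce.
* **SaPI2** — printed rate 0.04 and mobility 2.20×10⁻² do not follow from
  the printed counts 2/24 and frequency 2.20×10⁻¹ (which give 0.08 and
  1.83×10⁻²).
* **P22 strain-table TE/donor** — printed 1.567 vs 1.57×10⁸/1.0×10⁸ = 1.57
  (the comparative table prints 1.57); most plausibly computed from
  unrounded replicate means that are not published.

## Headful geometry (`ltmob.geometry`)

Coordinates are 0-based half-open, modulo the genome length L; packaging
direction is ±1 (the published maps use arrows, so a numeric convention had
to be chosen).  The headful index of a position is
`floor(directed_distance / H) + 1`, distance measured **from the attB
site** along the packaging direction — packaging actually initiates at the
internal *pac* site, but published headful numbering is attachment-site-
relative; a `pac_offset` field shifts the origin for users who want
pac-relative windows (default 0).

* `headful_windows` tiles the reach with n_max disjoint consecutive windows
  of H bp; a reach exceeding the full circle is truncated at L with a
  warning (this only arises for degenerate test genomes).
* `lt_reach_span` = n_max × H: 45 kb × 7 = 315 kb for 80α-class phages,
  43 kb × 12 = 516 kb for P22.
* `polylysogen_coverage` takes the union of per-site reach intervals on the
  circle; n_max is per site because the demonstrated headful counts differ
  between phages and need not be uniform across integration sites.
* `locus_headful_range` maps **both edges** of a locus span (not its
  midpoint), so a locus straddling a boundary reports "HF 5-6" as the
  compatibility tables do; loci partially beyond the reach are truncated to
  the in-reach indices and fully unreachable loci render "—".
* HF1 phage carryover: during LT the first capsid packages the remainder of
  the prophage before chromosomal DNA.  Geometrically this is
  `hf1_phage_carryover` bp removed from the attB-proximal edge of window 1;
  it defaults to 0 (pure geometry) and is set explicitly for HF1-cargo
  accounting and in the simulator.

Reproducing the published poly-lysogen coverage percentages (≈58% of the
*S. aureus* and ≈72% of the LT2 chromosome) requires the real attB
coordinates, which are not printed in the source and must be supplied by the
user as a registry CSV; the operation itself is validated base-for-base
against a brute-force oracle on synthetic layouts instead.

## Annotation I/O (`ltmob.annotations`)

GenBank parsing uses Biopython, GFF3 uses gffutils, with both converted to
the same wrap-aware representation (an origin-spanning CDS — a compound
location in GenBank, two lines sharing an ID in GFF3 — becomes one wrapped
interval).  The published accessory-ORF calls were made by manual
inspection; here they are reproducible `AccessoryRuleSet`s (explicit
include/exclude id lists, with precedence exclude > include > keyword, plus
a default keyword list: toxin, enterotoxin, leukotoxin, resistance,
virulence, adhesin, lipoprotein).  ORFs straddling a window edge count 0.5
by default (configurable), matching the half-ORF convention of the printed
totals; strand is recorded but ignored for counting.

## The LT/GT simulator (`ltmob.simulate`)

Per induced donor there are `particles_per_donor` packaging-series slots
(an abstraction of in situ replication amplifying packaging capacity — the
mechanism's replication step motivates amplification but published rates do
not exist).  Each slot initiates an LT series on the integrated prophage
with probability `p_in_situ`, otherwise yields an infectious phage
particle; GT series additionally initiate at each explicit pseudo-pac site
with its per-site relative efficiency (no genome-wide motif model — ppac
positions are user/synthetic inputs).

**Series-length law.** A series packages 1 + Geometric(q) headfuls,
truncated at n_max, so P(length ≥ k) = q^(k−1).  The mechanism is only
described qualitatively ("many processive headfuls", "seven or more"); this
one-parameter law is the simplest decaying mechanism consistent with the
observed per-headful decline and is a modelling choice of this package, not
a published claim.  The simulator makes no attempt to fit q to the
published per-headful profiles as a headline result; `recover_continuation_
probability` is provided as a tool.

A marker transfers when a particle's chromosomal interval fully contains
its span and a Bernoulli(r) recombination succeeds; recipient-side homology
requirements are out of scope.  Phage particles lysogenise with a fixed
probability.  All frequencies are per donor.  Randomness flows from one
integer seed through named `numpy.random.Generator` streams (seed, 0 for
the lysate; seed, 1 for transduction), so runs are bit-reproducible.

**Estimation.** `recover_continuation_probability` treats per-headful event
counts as c_k ~ Poisson(A·q^(k−1)), profiles out A, solves the score
equation T/C = q S′(q)/S(q) by bracketing, and reports the SE from the
numerically evaluated observed information of the profile log-likelihood.
Boundaries: flat profile → q̂ = 1; all events in HF1 → q̂ = 0 (SE reported
as nan at boundaries).

## Synthetic data (`ltmob.synth`)

`generate_toy_genome` builds circular genomes (default 1 Mb, 200 ORFs, 25%
accessory, two attB sites of opposite direction, an 80α-like 45 kb × 7
prophage model) with ORFs placed in equal slots under a random global
rotation (so origin-spanning ORFs occur), product strings drawn from
accessory/core vocabularies that the default keyword rules recognise, and
markers placed strictly inside their requested headful window so the
geometry recovers the requested index exactly.  Over-constrained specs
(markers beyond the reach or not fitting their window) are rejected.
`generate_element_panel` draws transfer frequencies log-uniform over
[10⁻⁹, 1] — the span the comparative tables cover, from conjugative
transposons up to PICIs — with half-granular cargo fractions and stores the
ground-truth relative mobilities alongside.

What the generator does **not** emulate: real gene content or motif
structure (sequence is uniform random), ppac sequence homology, burst-size
or MOI dynamics, superinfection immunity, host range.  Tests passing on
synthetic data therefore validate the arithmetic, the geometry and the
sampling laws — not biological realism of any particular genome.

## Problem sizes and tolerances

The test suite exercises the simulator at 10⁵ packaging series (statistical
checks use 3 standard errors; unit-level smoke checks use 4 at smaller n),
geometry oracles on ≥100 random layouts of ≤100 kb genomes with per-base
numpy verification, and the full fixture tables for exact cell
reproduction.  These sizes keep the default suite in the tens of seconds
while leaving the statistical assertions well-powered.

## Known limitations

* The three flagged fixture cells cannot be reproduced from the printed
  inputs; they are carried verbatim with flags.
* Range-valued frequencies are treated as closed intervals with no
  distributional meaning; no meta-analytic weighting of literature sources
  and no significance testing between element classes is attempted (none
  exists in the source analysis).
* `summarize_replicates` with a single value returns SD 0.0 by convention.
* The simulator's per-donor frequencies can exceed 1 when
  `particles_per_donor × p_in_situ > 1`; they are event rates per donor,
  not probabilities.
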