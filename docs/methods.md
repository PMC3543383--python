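# Methods

This note documents the models implemented by pelokit, their
assumptions, the defaults that matter, and the choices made where the
design was genuinely open.

## Cofactor-ledger stoichiometry

A pathway is scored by a signed ledger over seven currencies — ATP,
NADH, NADPH, Fd2e (doubly reduced ferredoxin), PEP, hydrogen/formate,
and transmembrane cations — with every coefficient an exact
`fractions.Fraction`. Exactness is the point: printed yields such as
0.4 or 0.7 ATP are small differences of small rationals, and floating
arithmetic would force tolerance bookkeeping where none is needed.
Ledgers add component-wise, so gross ATP is additive under pathway
concatenation, and per-substrate yields are the total ledger divided
by the substrate multiplicity.

Conventions that make the packaged pathways balance:

* **Electron pairs.** NADH, NADPH, Fd2e and hydrogen/formate each
  carry exactly one electron pair; hydrogen and formate are treated as
  one interchangeable export species, since the organism can dispose
  of electrons as either depending on its partner's uptake machinery.
* **PTS import.** Phosphotransferase sugar import is modelled as
  PEP + external sugar → sugar-phosphate + pyruvate. The pyruvate
  credited to the pathway therefore arises from *import*, not pyruvate
  kinase, and the PEP regenerated by the triose-phosphate leg cancels
  the import debit. This is the accounting under which the printed
  1.5 ATP per 2-deoxyribose and 1 ATP per ribose come out exactly.
* **Cations.** A sodium-symport uptake step debits one cation,
  priced at 3/C ATP in net mode only. This single debit is what takes
  the aspartate route from 1 gross to 0.7 net ATP at C = 10; the
  uptake charge is the natural reading of the route but the exact
  term is a modelling choice recorded here.

## The chemiosmotic cation model

Parameters: the ATP synthase c-ring size `C` (integer, 10–15 — the
span observed across c-subunit sequences) and the Rnf cation count `r`
(positive integer, default grid 1–5). Fixed machinery: Nfn exchanges
1 NADH + 1 Fd2e ⇌ 2 NADPH at zero cation cost; the NADPH-coupled
hydrogenases / formate dehydrogenase convert 1 NADPH ⇌ 1
hydrogen-or-formate freely. One cation is worth exactly 3/C ATP.

**Export costing.** To export `a` NADH and `b` Fd2e pairs, matched
pairs leave free through Nfn. A surplus `s = |a − b|` of either
species needs `s/2` Rnf conversions (each forward conversion spends
one surplus NADH *and* enables Nfn pairing of another; reverse
conversions earn the same), for a cost or gain of `(s/2)·r·(3/C)` ATP.
Fractional surpluses (e.g. the 0.5 NADH per 2-deoxyribose) take
fractional conversions — per-substrate ledgers are already
fractional. Net mode fails loudly, naming the species, if a residual
is negative (a pathway that consumes reducing power it never made) or
if PEP does not balance; the Rnf/Nfn/hydrogenase rules cannot repair
either.

**Fitting.** The predicted cell-yield ratio of an NADH-generating
versus an H₂-oxidizing electron donor is `(C/3)/r`. The fit minimises
the sum of squared differences to the observed ratios over the full
integer grid. Squared error on the ratio scale is a choice (the
source experiments report no uncertainties that would justify
weighting); the grid is small enough that the search is exhaustive and
deterministic. Exact ties — `(10, 2)` and `(15, 3)` both predict
5/3 — are broken toward the lexicographically smallest `(C, r)` and
all minima are reported in the results object. With the packaged
ratios (1.49, 1.83) the minimum is `(10, 2)`.

## The residue demand index

For a residue occurring `n ≥ 2` times at 1-based positions
`p₁ < … < pₙ`, the spacings are the **consecutive** differences
`sᵢ = pᵢ₊₁ − pᵢ` (adjacent residues have spacing 1), the harmonic mean
is `H = (n−1)/Σ 1/sᵢ`, and the index is `D = n/H`. Consecutive rather
than all-pairwise distances were chosen because they make `D` scale
with local clustering: `D = n` exactly for an adjacent run, and
spreading any occurrence away from its neighbours can only lower `D`.
Proteins with fewer than two occurrences get `D = 0` — they cannot
exhibit closely spaced residues and must not enter the index tally.
Sequences are uppercased, a trailing `*` is stripped, and the
ambiguity letters X/B/Z/U count toward length but never match a target
residue. Threshold comparisons are strict (> 50 occurrences,
> 7.0 index), and both tallies are recomputed from the per-protein
list, never cached.

## Active-site conservation

Profiles are ordered `(position-label, residue)` lists taken as
pre-aligned; the comparison is positional Hamming distance, which on
equal-length profiles is symmetric and satisfies the triangle
inequality. Stereospecificity assignment returns the annotation of
the nearest reference and **declares ties instead of breaking them**:
such annotations are tentative by nature and a silent tie-break would
manufacture confidence. The packaged table covers the
(2S,3S)-specific *C. glutamicum* and meso-specific *K. pneumoniae*
references plus BudY, BudZ and Ppro_3110; mismatches are recomputed
from the residues, never transcribed. (By this distance BudY is
identical to the (2S,3S) reference at all 11 sites; note that BudZ is
nearer the (2S,3S) reference (2 mismatches) than the meso one (3),
so a nearest-neighbour call for BudZ would not by itself support a
meso annotation — context beyond these 11 sites has to decide.)

## tRNA mutation classification

Legal stem pairs are Watson–Crick plus the G·U wobble: the question a
stem asks is whether the fold survives, and RNA helices tolerate G·U.
Categories partition the alignment columns: gap → `indel`; equal
bases → `identical`; stem pair with both partners changed and still
legal → one `compensatory` event (both positions labelled); stem pair
rendered illegal → `pair_breaking` on the substituted position(s);
everything else → `unpaired_substitution`. One case the category
names do not cover cleanly — a single-sided stem substitution that
leaves a legal pair, e.g. G-C → G-U — is filed under
`unpaired_substitution`, since it is neither reciprocal nor
fold-breaking; the synthetic generator never plants such events, so
ground-truth recovery is unambiguous. Summary counts for
compensatory and pair-breaking are *events* (stem pairs), matching
how one counts "reciprocal mutations" on a cloverleaf diagram. When
position 33 (the frameshift-control base) is mapped, its bases in
both sequences are reported as a flag; no functional inference is
made. The acceptor-end check is deliberately literal: terminal CCA,
internal CCA only (buried site), or absent.

Anticodon decoding reverse-complements the 5′→3′ anticodon to the
codon and translates by the standard code (via Biopython's table);
the test suite checks all 64 anticodons against an independent
reverse-complement-and-translate route.

## Synthetic data

**Proteomes.** Defaults: 100 proteins of length 200–600 (uniform),
target residue N at marginal frequency f = 0.04 — a typical
asparagine usage for a mesophilic proteome — uniform background over
the other 19 letters, κ = 0. Target placements follow a renewal
process whose gaps are a two-component geometric mixture: a cluster
component with mean `max(1, (1/f)/(1+κ))` drawn with weight
`κ/(1+κ)`, and a between-cluster component whose mean is solved so
the overall mean gap is exactly `1/f`. Hence κ = 0 degenerates to
plain Geometric(f) (uniform placement, mean spacing 1/f) and larger κ
shortens within-cluster gaps geometrically *at unchanged
composition* — the one-parameter knob moves the demand index
monotonically without touching residue frequency. The first gap is
drawn from the stationary (length-biased) mixture — for geometric
components the forward recurrence time is geometric again — so the
expected occurrence count is exactly `L·f`; starting the process cold
at the origin would overshoot the composition when the
between-cluster gaps have high variance. What the generator does
*not* emulate: real codon usage, GC content, domain structure, or
compositional heterogeneity along a protein; a test passing on this
generator shows the statistic behaves as designed, not that any
particular genome is enriched or depleted.

**tRNA pairs.** A 76-base template with the canonical cloverleaf
map (acceptor stem 1–7/66–72, D stem 10–13/22–25, anticodon stem
27–31/39–43, T stem 49–53/61–65, anticodon 34–36, control base 33)
is generated with all stem pairs legal and a terminal CCA; planted
events are position-disjoint, avoid the anticodon, position 33, the
CCA and any region removed by an acceptor deletion, and are returned
as ground truth. An acceptor deletion of 7 reproduces the situation
where the aminoacylation site is no longer terminal.

All randomness flows from one `numpy.random.default_rng(seed)` per
generator call; there is no hidden global state, and fixed seeds give
byte-identical FASTA output.

## Numerical and interface choices

* Ledger arithmetic, yields, export costs and fit losses are exact
  rationals; floats appear only at reporting boundaries. The CLI
  prints yields at one decimal (the conventional reporting precision
  for such estimates) with `--full-precision` exposing the exact value.
* Pathway configs are YAML with integer or string-rational
  coefficients; bare floats are rejected to keep exactness honest.
* FASTA I/O goes through Biopython; duplicate ids are suffixed
  `_2, _3, …` deterministically and logged.
* Degenerate inputs fail early with named errors: empty sequences,
  non-standard residues as query targets, overlapping stem pairs,
  out-of-range c-ring sizes, empty ratio lists, more planted events
  than available positions.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
pathway evaluations are closed-form rational arithmetic (instant);
oracle-agreement checks use 1,000 random proteins; parameter-recovery
simulations use 100 replicates of two noisy ratios (σ = 0.05);
clustering-effect checks use 150–500 proteins per proteome across 20
seeded replicates. These sizes give stable verdicts for the
properties tested while keeping the whole suite in a few seconds.

## Known limitations

* The pathway library encodes one curated route per substrate;
  alternative routes (e.g. 3-hydroxypropanoate excretion during
  glycerol disproportionation in some strains) are not enumerated.
* The cation model treats proton and sodium gradients as one
  interconvertible cation pool (the organism's antiporters justify
  this at steady state, but transients are out of scope), assumes
  electron transfer to S° yields no energy, and prices no
  thermodynamic (ΔG) constraints — it is stoichiometric, not kinetic.
* Active-site comparison requires pre-aligned profiles; no alignment
  is computed, so it cannot rescue mis-specified site tables.
* The mutation classifier trusts the supplied alignment and pairing
  map; it does not predict secondary structure.
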