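# Methods

## Matching model

A *fragment* is a length-L window of a section's sequence, taken at every
offset (step 1 nt). Two sections A and B match at an ordered offset pair
(i, j) when A[i:i+L] equals B[j:j+L] directly or equals its reverse
complement; a palindromic fragment satisfying both is counted once. Counting
ordered offset pairs with multiplicity makes the pair table exactly
symmetric and gives a conservation law used throughout the tests: the sum
of per-fragment occurrence numbers (NO) equals the total match count.

Fragments are keyed by canonical form, `min(f, revcomp(f))`, merging the
two strands. With that convention the pair count factorizes as
`sum_c dA[c]·dB[c]` over canonical fragments, where `dX[c]` counts windows
of X with canonical form c. The production matcher is therefore a
dictionary scan plus an inverted index (canonical fragment → sections
carrying it); for patterns of one fixed length this is exactly what a
multi-pattern automaton reduces to, and it is O(total sequence) instead of
O(|A|·|B|). The naive double-loop count remains in the test suite as an
independent oracle and the two are compared on a thousand random pairs.

Matching is exact by design: the screening statistic is defined on perfect
identity, and no mismatch tolerance is offered.

### Low-complexity filter

A fragment is excluded when it *contains*, at any offset, a run of at
least u identical m-mers for some rule (m, u); the default rules are
(1, 4), (2, 3), (3, 2) — four mononucleotides, three dinucleotides or two
trinucleotides in a row. The containment reading (rather than "the whole
fragment is a repeat") is deliberate: a 50-mer carrying an internal
`aaaa` is as unspecific as the run itself. The filter is applied to the
enumerated windows of both sections symmetrically, which keeps counts
symmetric. Fragments containing `n` (including all IUPAC ambiguity codes,
normalized to `n` on input) are always excluded; this prevents ambiguity
codes from creating spurious identities.

Separately, `classify_microsatellite` labels a fragment as a
microsatellite when some period p ≤ 6 tiles it with at least two complete
units; the literal head motif is reported (so `tcccagtcccag…` reports
`tcccag`). This is a reporting classifier, not the exclusion filter.

## FMF normalization

Raw counts grow with the product of section lengths, so the count for
(A, B) is first divided by `w_A·w_B` with `w_X = len(X)/10 kb`, giving a
density per 10 kb × 10 kb, then divided by the mean density over unordered
off-diagonal pairs so the mean FMF is exactly 1. The global constant
cancels in rank correlations (asserted by a test), so the choice of
global-vs-per-chunk averaging affects only the displayed scale; the
per-pair density step is what corrects unequal section lengths. `w` is
real-valued — no rounding to whole chunks — to avoid discontinuities for
sections shorter than 10 kb. An all-zero table yields all-zero FMF with an
explicit flag rather than a division error.

## Correlation screen

Spearman ρ uses midranks for ties and the two-sided t approximation with
n − 2 degrees of freedom (FEC matrices are small non-negative integers, so
ties are the norm, not the exception). An estimate is invalid when either
vector is constant or fewer than `min_n = 5` partners exist; the zone
analysis reaches n = D − 1 = 9 at its smallest default D, and below 5 the
t approximation is meaningless. Invalid estimates are excluded from both R
and P denominators — a section whose FMF row is all zero at large L is "no
test", not "no correlation".

Specific estimates use partners B ≠ A (n = N − 1): the anchor's self-pair
(FEC = FMF = 0 by construction) is excluded, since including a constant
artificial point in both vectors would only inject a spurious concordant
tie. Unspecific estimates for the ordered pair (A, B) use common partners
C ∉ {A, B} (n = N − 2) so both vectors range over the same partner set.

Raw p < α (default 0.05) defines significance throughout — the screen is
deliberately uncorrected, being a calibrated-by-control design (the
unspecific P is the empirical chance level); a Benjamini–Hochberg helper
exists but is off by default. R is the mean of significant ρ values with
`sd/√n` as its error; P is `n_signif/n_valid` with the binomial standard
error.

## Zones

For zone length D, the N − D + 1 windows of D consecutive sections each
yield their own specific (anchors in the zone, partners restricted to the
zone) and unspecific summaries; per D the zone values form samplings whose
means give R_DIFF and P_DIFF. Zones with zero valid estimates contribute
missing values, never zeros, to avoid dragging proportions down where FMF
vanishes at large L. The D step defaults to 1 and the D range to 10…N−3,
both configurable; at D = N the single zone reproduces the global summary
exactly (tested).

## Group tests

Mann–Whitney U is exact (full enumeration) when min(n, m) ≤ 8 and the
pooled data are tie-free, otherwise the normal approximation with tie
correction and **no continuity correction** — identical samplings must
give p = 1 exactly, and the continuity shift would break that. Fully tied
data return p = 1. Whole-chromosome R comparisons use the significant-ρ
samplings per condition; zone comparisons use the per-zone R and P
samplings. P proportions are compared with the plain 2×2 χ² (df = 1,
Yates correction off by default, available as a flag). One factor varies
per comparison row; along the L axis only contrasts against the L = 50
reference are emitted.

## Fragment ranking

Fragments with NO ≤ 10 are dropped, equal-NO groups keep their
lexicographically smallest canonical fragment (a deterministic tie-break),
and the top 50 survive. NO counts match events, not genome occurrences,
which is what makes the conservation law exact. When restricting to the
sections with significant specific correlations, a match event counts if
at least one of its two sections is in the subset (the subset names
anchors, and an anchor's matches extend to all partners); a strict
both-in-subset mode is available.

## Synthetic data

The generator emulates the study design, not Drosophila sequence
statistics: i.i.d. background bases at 42% GC (the fly euchromatic
ballpark), satellite monomers planted as tandem arrays (default 359 nt,
the length scale of the 1.688-family repeats; tandem rather than dispersed
placement mirrors satellite biology and produces the L-monotone match
structure the matcher must handle), and contact counts drawn independently
per unordered pair as `Poisson(λ0 + λ1·shared(A,B))` with defaults λ0 = 1,
λ1 = 10. Poisson is the minimal model reproducing the small, zero-heavy
integer FEC matrices the correlation layer must tolerate — counts
aggregated over a few hundred nuclei with low per-nucleus probability.
Insertions replace background sequence at a uniform offset (section
lengths are preserved) and never overlap within a section. All randomness
flows from one integer seed; identical seeds give byte-identical fixtures.

What it does not emulate: realistic base composition or repeat landscape,
transposons, under-replication, distance decay of contacts, or
measurement error in contact scoring. Passing recovery tests therefore
demonstrate the pipeline's statistical behaviour under its own model, not
biological conclusions about real chromosomes.

## Test problem sizes

The recovery study runs 50 seeded replicates of the reference condition —
20 sections × 50 kb, one 359-nt monomer × 10 tandem copies planted in 4
sections, λ0 = 1, λ1 = 10, L = 50 — and requires ≥ 90% of planted-section
tests significant. Under this condition unplanted sections have all-zero
FMF rows (no background 50-mer collisions at these sizes), so they produce
invalid estimates rather than null tests; their false-positive rate is
checked against the chance ceiling and is typically exactly 0. Null
calibration uses 10 genomes × 10 independent contact draws × 20 sections
(2000 section-level tests) at L = 10 on 10-kb sections, where background
matching makes every estimate valid; the observed significant share is
required to sit in the 99% binomial band around 0.05 — 99% rather than
95% because tests sharing a genome or a draw are dependent and the nominal
binomial variance understates batch variance. The oracle-equivalence check
uses 1000 random pairs of length ≤ 200 at L ∈ 2…12, alternating the
repeat filter and injecting `n` bases in every fifth pair.

## Known limitations

- Exact matching only; a single substitution in a repeat copy splits its
  contribution across shorter coincidences.
- The FMF normalization constant is a whole-matrix property; per-chunk
  (sub-section) FMF maps are out of scope.
- The per-pair fragment lists needed by catalog restriction are memory
  heavy at chromosome scale; `build_match_tables` and the CLI disable them
  unless requested.
- Unspecific zone sweeps cost O(D²) Spearman calls per zone and are the
  dominant runtime at chromosome scale; restrict the D grid or L list when
  exploring.
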