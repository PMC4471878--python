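# Methods

## Sponge site and cassette model

A mature miRNA *m* is an RNA string of length *L* (18–30 nt at parse
time), positions numbered 1..*L* from the 5′ end. Constructs are DNA on
the transcript sense strand with 0-based half-open coordinates; miRNAs
are stored as RNA and converted on demand, so all cross-module sequence
comparison happens in DNA space.

**Bulged binding site.** The site is rc(*m*) in DNA except at site
positions opposite miRNA positions 9–12 (site position *j* pairs miRNA
position *L* − *j* + 1). There the base is replaced by the
*self-mismatch* base: the DNA equivalent of the miRNA base itself
(A→A, C→C, G→G, U→T). This rule is used because it provably excludes
both Watson–Crick and G·U wobble pairing for all four bases — A·A, C·C,
G·G and U·U are none of them pairs — whereas, e.g., swapping to the
wobble partner would not. The substitution table is a parameter for
groups that prefer a different bulge chemistry. Mismatch spans
extending past the miRNA 3′ end are clipped with a warning; an empty
span degenerates to the perfect reverse complement.

**Seed-match site types.** Off-target screening uses the canonical
taxonomy: 6mer = rc(*m*[2..7]), 7mer-m8 = rc(*m*[2..8]),
7mer-A1 = rc(*m*[2..7])+A, 8mer = rc(*m*[2..8])+A. The default enabled
set is {7mer-A1, 7mer-m8, 8mer} — the 7–8-nt windows — with the 6mer
available but off by default, as 6-nt matches are too frequent to
design around and too weak to matter for a multivalent construct.
Whether a screen of this kind should use positions 1–8 or 2–8 windows
is not settled; the taxonomy is configurable for that reason. Seed
*families* group miRNAs by identical extended seed (positions 2–8);
family members are functionally redundant for targeting and are treated
as equivalent to the target during design.

**Linker selection.** Candidates are the 4^linker_length strings over
{A,C,G,T} (default 256 4-mers), enumerated lexicographically or in a
seeded-random permutation; the first candidate is accepted whose
junction string (≥7 terminal nt of the upstream block + linker + ≥7
initial nt of the downstream block) contains, in any window overlapping
the linker, no enabled site type of a non-exempt registry miRNA and no
flank-enzyme recognition sequence. Seven context nucleotides suffice
because the widest window (8) can reach at most 7 nt past the linker
boundary. First-accept lexicographic order is the default because the
published constructs' linker-choice rule is not recorded; the
seeded-random mode diversifies linkers (they were "variable" in the
original designs) while remaining deterministic given the seed. If all
candidates are rejected the error lists one blocking collision per
candidate.

**Cassette assembly.** One site is designed and repeated *N* times
(default 20); the *N* − 1 linkers are selected independently
left-to-right. The exemption set is the target plus its seed family —
the cassette is deliberately saturated with the target's own seed
sites. Flanks default to NotI (GCGGCCGC) 5′ and XbaI (TCTAGA) 3′; which
enzyme sits on which side is an assumption, configurable. The block
coordinate table (flank/site/linker, 0-based half-open) reconstructs
the full sequence exactly and is validated at construction. Junction
collisions are guaranteed absent by selection; *site-internal* cryptic
seed matches or restriction sites — fixed by the target's own sequence
and not removable by design — are reported as warnings on the cassette,
not errors. A fixed-linker legacy assembler (no screening, no flanks)
reproduces first-generation constructs such as the 246-nt miR-1 sponge
(10 × 21-nt site + 9 × CGCG).

**Scramble control.** A seeded shuffle of the template site is accepted
when every enabled-width window misses the *entire* registry (no
exemptions — a control must match nothing) and no flank site occurs;
after `scramble_max_attempts` (default 10,000) shuffles the search
fails loudly, reporting the best candidate and its residual collisions.
For ~20-nt templates against ~150-miRNA registries the first shuffle
almost always succeeds.

## Scanning

`scan_sequence` slides every enabled window width and looks windows up
in a k-mer index; `naive_scan` recomputes the same report by direct
substring search per miRNA and serves as the independent oracle in
equivalence tests (the two are compared, hit list for hit list, on
randomized instances). Only the sense strand is scanned. Overlapping
hits are all reported; a narrower hit contained in a wider hit of the
same miRNA is flagged `nested`, not merged. With a cassette block
table, hits are labelled junction (overlaps ≥1 linker base), flank,
site_internal, or other, in that priority.

## Screen statistics

**Viability.** Percent viability = 100 × (experimental / balancer
sibling counts) / correction factor, where the factor (non-balancer :
balancer ratio from a wild-type cross) removes the balancer's own
contribution to lethality; it is applied globally by default with a
per-batch option, since the original bookkeeping is ambiguous between
the two. Values above 100% are allowed. The collection cutoff is
mean − 1 × sample s.d. (n − 1 denominator throughout), hits inclusive
at the cutoff ("equal or less than"). A zero-variance collection makes
the cutoff degenerate (everything would tie at it); this is flagged
with a warning and returns no hits. Phenotype bins resolve the
published overlapping bin edges as half-open intervals: lethal [0, 5],
semilethal (5, 50], subviable (50, 70], viable (70, ∞) — a partition,
so every percent maps to exactly one class.

**Flight.** Non-flier fraction = 100 × (inner + middle circle counts) /
flies dropped. The candidate threshold is 2 × sample s.d. of the
scramble control's replicate fractions (the threshold is the 2-s.d.
value itself, as stated for the assay). Candidates are confirmed by
one-way fixed-effects ANOVA across all lines including scramble
followed by a Tukey–Kramer comparison (statsmodels `pairwise_tukeyhsd`,
which handles unequal group sizes) of the line against scramble, with
α = 0.001 for flight and 0.01 exposed for viability-style comparisons.
α ≤ 0 disables hit-calling entirely (nothing is significant at level
zero). A zero pooled-variance edge case (all replicates constant)
yields NaN p-values; it is resolved by direct mean comparison.

**Benchmark concordance.** A gene is comparable when a null allele
exists, the null does not delete a multi-miRNA cluster, the locus was
genetically validated (non-complementation over a deficiency,
represented as a boolean), and the null was tested for lethality.
"Impaired" collapses lethal/semilethal/subviable, since the benchmark
source reports lethality only. Categories: same impairment status →
confirmed; viable sponge over impaired null → false_negative; impaired
sponge over viable null → family when any same-family member's null is
impaired, else false_positive. Family evidence is drawn from *all*
entries, comparable or not: what matters is the null phenotype on
record, not that member's own comparability. Percentages are reported
to one decimal over the comparable set.

## Synthetic data

Generators are pure functions of a `FixtureSpec`; RNG streams are
namespaced per generator (seed ⊕ generator tag) so adding one call
never shifts another's draws.

- *Registry*: n random RNA sequences (default 141, lengths 21–23 nt,
  uniform), ids `syn-miR-1..n`. Emulates registry size and mature
  lengths only — real miRNA registries have biased base composition and
  shared seeds, which random sequences rarely produce, so family-logic
  tests use hand-built registries instead.
- *Viability table*: default 143 lines, 13 planted hits. Non-hit lines
  eclose at ~100% of the balancer class (Gaussian, s.d. 5 points);
  planted hits are reduced by 90 points (≈10% viability); counts are
  realized as integers with Poisson(100) control broods. At these
  effect sizes the mean − 1 s.d. cutoff separates planted from
  non-planted lines with sensitivity and specificity 1.0.
- *Flight table*: default 58 lines, 14 planted, 3 replicates × 20
  flies, age 30 days. Baseline per-fly non-flier probability 0.01
  (controls show essentially no non-fliers); planted lines 0.90
  (essentially flightless). Binomial zone counts always sum to the
  drop total.
- *Benchmark table*: inverse-constructed — rows are fabricated so the
  classifier reproduces requested category counts exactly, with the
  family category's evidence carried by an excluded same-family row,
  plus rows exercising each exclusion rule. Classifier tests therefore
  need no real phenotype table.

What passing fixture tests do **not** show: recovery on real screen
data, where viability percentages are not Gaussian around 100, flight
baselines drift with age, replicate counts vary, and hit effects span a
continuum down to the threshold. The fixtures validate the scoring
rules, not the biology.

## Problem sizes and numerical choices

The randomized guarantees are exercised at fixed scales chosen to be
decisive yet quick: 200 random registries (20–200 miRNAs) for the
junction-collision guarantee, 1,000 (sequence, registry) pairs for
scanner/oracle equivalence, 1,000 random miRNAs for the bulge pairing
property. All randomness in tests and in `scripts/acceptance.py` is
seed-derived; identical seeds reproduce identical outputs byte for
byte. Sample (n−1) standard deviations are used throughout; percentage
rounding is half-even to one decimal via Python's `round`.

## Known limitations

- No thermodynamic or context scoring of sites (no ΔG, no 3′
  supplementary pairing); site quality is purely seed-match based.
- No RNA secondary-structure screening of assembled cassettes; a
  highly structured array could occlude sites in vivo.
- Scramble search is rejection sampling; pathological templates (e.g.
  low-complexity sequences whose every permutation hits a registry
  k-mer) fail after the attempt budget rather than being solved
  combinatorially.
- The flight ANOVA treats replicates as independent; cage, batch or
  gender effects are not modelled.
- Benchmark "validated" status is an input boolean; the underlying
  deficiency-complementation genetics is out of scope.
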