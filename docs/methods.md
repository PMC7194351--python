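# Methods

This note records the models, conventions and numerical choices behind
`epimap`, and what the synthetic-data validation does and does not show.

## Motif model and census conventions

A motif is an ordered run of slots, each a fixed residue or a wildcard.
Wildcards match any of the 20 canonical residues and nothing else: the
ambiguity/rare codes X, B, Z, U, O satisfy neither slot kind, so a window
containing one never matches, while the record itself stays in the census.
This is the conservative reading — an ambiguous position is never credited
with a match.

Coordinates are 0-based and half-open. A hit is C-terminal iff its end
index equals the protein length, which makes "C-terminal" equivalent to
"nothing follows the motif" with no off-by-one ambiguity.

Occurrence counts include overlaps: every window position that matches is
a hit. For motifs that cannot self-overlap (such as `NNI`, whose proper
prefixes and suffixes share no residue) the two conventions coincide; for
self-overlapping motifs the overlap count is the declared and
oracle-tested behaviour.

The census is two-stage: first the motif-ome (proteins with ≥ 1 motif
occurrence) is formed, then every other statistic — sub-motif counts,
short proteins, the methionine pool, anchored windows, the exclusion
filter — is computed *within* it. "Initiator methionine" is
operationalized as the residue at position 0 of each record; no
signal-peptide prediction is attempted, because any predictor would
introduce a model dependence the census arithmetic does not need.

### Method of Exclusion

Candidate windows are the M-initial 11-mers at every non-initiator
methionine with ten residues of trailing sequence. A window is excluded
when positions 2–11 contain any canonical residue outside the allowed set
(default `MKPLTGVEF`, the residue complement of the reference 11-mer), a
second M (position 1 consumes the only M), or an ambiguity code. The
survivor score is the number of *distinct* allowed residues in the full
11-mer, repeats counted once; ties in the descending ranking break by
(protein id, start) for determinism. The maximum attainable score is 9
(all allowed residues present) but an 11-mer using one M and ten positions
over 8 remaining letters can reach at most 9 only by using every letter;
in practice top candidates score 8. One published candidate list includes
an 11-mer (`MLKKTPVLKKG`) credited with 8 distinct allowed residues that
contains only 7 ({M,L,K,T,P,V,G}) under this — or any — counting we
could construct; the discrepancy is noted here rather than silently
absorbed, and the scoring is the one that reproduces the other published
candidates (e.g. `MLKTGEKPVEP` → 8).

## Chance-match probability calculus

The null model is i.i.d. residues with composition π, uniform 1/20 by
default. The defaults are uniform because the published odds they
reproduce (1 in 146,000; 1 in 11) are uniform-alphabet figures; empirical
compositions can be passed everywhere but are not required.

* Per-window probability: product of fixed-slot frequencies (wildcards
  contribute 1).
* Per-protein probability: `1 − (1 − p)^(L−k+1)`, treating windows as
  independent. For the short motifs and small p in scope, the error of
  the independence approximation is far below the rendering granularity;
  a vectorized Monte-Carlo oracle (10⁵ random 619-mers) confirms this in
  the tests.
* Combined odds: independent probabilities multiply.
* Partial anagram: the number of distinct ordered k-mers drawing their
  letters (with multiplicity) from a reference multiset is
  Σ over count vectors c ≤ m, Σc = k of k!/Πcᵢ!, computed exactly in
  integer arithmetic; each ordered string determines its own count vector,
  so nothing is double-counted. Probability = count / A^k. The headline
  9-of-11 case gives 3,507,840 / 20⁹ ≈ 1/145,959, rendered "1 in
  146,000". This is a *per-window* probability; reading it per-protein
  would need a length convention the calculus deliberately leaves to the
  caller via the window operations.
* Conditional initial residue: drawing k items without replacement and
  reading them in order makes the first item uniform on the multiset, so
  P(first = r) = multiplicity(r)/size — 1/11 for the single M of the
  11-residue reference. Verified by exhaustive enumeration of labelled
  permutations in the tests.

"1 in N" renderings coarsen with magnitude — nearest million for
N ≥ 10⁷, nearest hundred-thousand for N ≥ 10⁶, nearest thousand for
N ≥ 10⁵, else nearest integer — matching how such odds are quoted in
practice; parsing inverts rendering to within the granularity.

Published per-protein odds whose derivations are not reconstructable from
any stated convention (the 5,247 / 2,636 theoretical and 6,201 / 4,378
database figures) are treated as *inputs* to the combination step, not as
quantities this package re-derives.

## Conformer distance comparison

The statistic is Σ(O−E)²/E over the shared, explicitly aligned pair
labels, with E the reference (embedded-epitope) table. Degrees of freedom
are pairs − 1. The statistic is dimensionally a descriptive index on
Ångström-valued measurements, not a count-based χ²; it is nevertheless
referred to the χ² distribution for the similar/dissimilar verdict
because that is the convention of the measurement protocol it reproduces,
and the verdict should be read as a calibrated similarity call, not a
formal hypothesis test. The quantile is scipy's `chi2.ppf`, checked in the
tests against an independent numerical inversion of the integrated
density to 1e-6. The big-difference proportion counts pairs with
(O−E)² strictly above a configurable threshold (default 10 Ų).

Pair alignment is always by label; there is no positional guessing, and a
mismatched label set raises an error listing the symmetric difference.
Which of the 55 possible pairs of 11 atoms enter a comparison is taken
from the input file — the published 46-pair subset's exclusion rule is not
stated anywhere reconstructable, so the pair list is data, not code.

## Preabsorption analysis

Area fraction is the proportion of pixels strictly above a fixed
intensity threshold. Percent-of-control divides each area by the mean
peptide-free control area (×100), so the control's own mean is exactly
100 and the normalisation is invariant to global intensity scaling. SEM
is sample SD (n−1 denominator)/√n, 0 when n = 1.

The default t-test is the pooled-variance Student test, with Welch
selectable; both accept raw replicates or (n, mean, SEM) summaries and
give identical answers when the summaries come from the raw values, since
the tests depend on the data only through (n, mean, SD). Published
p-values for this experimental design could not be reproduced from the
published summary statistics under either variant (the comparison
structure behind them is not stated), so no test asserts them.

IC50 is reported as a bound over tested doses — the smallest tested
concentration whose mean response is ≤ 50% of control ("≤ c"; "< cmin"
when the lowest dose is already at or below half; "not reached"
otherwise) — because titrations at log-spaced doses support a bound, not
a midpoint. A fixed-asymptote logistic fit (floor 0, ceiling 100) is
provided for synthetic-data validation only.

### Suffix-pattern inference

The inference enumerates every C-terminally anchored fixed/wildcard
pattern up to `max_len` slots and scores the rule "blocks iff the pattern
matches the peptide's C terminus" by accuracy on the panel, with
sensitivity and specificity reported alongside. Candidate fixed residues
at each slot are those actually observed at that C-terminal offset in the
panel: any other fixed choice matches no peptide at that slot and is
dominated by patterns in the enumerated set, so the restriction loses no
optimum while keeping the search exact and fast (bitmask set algebra over
panel membership). Ranking is total and deterministic: accuracy
descending, fixed-slot count descending, length ascending, then pattern
string. A panel with no blockers or no non-blockers cannot separate
anything and returns a flagged degenerate result (the implicit
all-wildcard rule) rather than a spurious pattern.

Partial blockers count as blockers by default. Peptides that block only
at the highest tested concentration are excluded from the core inference
(their evidence is qualitatively weaker) and can be folded in via a
sensitivity mode. Single-substitution variants of a panel peptide do not
enter the suffix search at all; they feed a second pass, the substitution
scan, which marks each substituted position as required (blockade lost)
or tolerant (blockade retained). Positions required by the scan but
outside the best pattern's fixed slots are classified
"required-non-contiguous" — the signature of a mixed
contiguous/non-contiguous epitope.

## Synthetic data: what it emulates, what it does not

The proteome generator draws background residues i.i.d. from the stated
composition, plants occurrences (internal, C-terminal, or anchored
M+10-wildcard+NNI windows realized with composition-drawn fills) at
non-overlapping coordinates, and *rejection-samples*: a protein is
redrawn until scanning every planted pattern finds exactly the planted
coordinates, and a realized window is redrawn if its wildcard fill creates
an occurrence beyond what the pattern itself mandates. Manifest counts are
therefore exact, not expected values; expected retries are few at the
default sizes (50 proteins × 80–400 aa; per-window chance of a stray NNI
≈ L/8000) and a retry cap turns pathological plans into a clear error.
Defaults plant 12 internal + 2 C-terminal NNIs and 3 anchored windows.

Distance-table jitter adds independent N(0, σ²) per entry, redrawing any
draw that would make a distance non-positive. Panels follow
percent = 100/(1 + (c/IC50)^slope) for blockers (floor 0 after noise) and
100 for non-blockers, with Gaussian replicate noise (default SD 5
percentage points, 4 replicates, doses 0.1–1000 ng/ml) — a 4-parameter
logistic with fixed asymptotes, the standard form for preabsorption
titrations, since no functional form is prescribed by the protocol.
Images plant an exact above-threshold pixel count at zero noise.

Passing the recovery experiments therefore shows the *pipeline* is
correct under its own declared noise models. It does not show robustness
to what real data add: non-i.i.d. proteome composition and homology
structure, systematic (non-Gaussian) measurement error in modelled
distances, staining heterogeneity, section-to-section variation, or
antibody-binding nonlinearity. Proteome census figures for any real
database snapshot are version-dependent and are bundled as documented
reference values only, never asserted by tests.

## Problem sizes and determinism

Every stochastic experiment is seeded and derandomised: oracle
equivalence runs 20 random proteomes (≤ 100 proteins × ≤ 200 residues);
planted-count recovery 20 generator seeds; panel-rule recovery 100 seeded
panels; type-I error 500 null simulations (n = 8 per arm); IC50 ordering
50 seeds × 3 planted potencies; jitter monotonicity 200 tables at each of
σ ∈ {0.1, 0.5, 1.0, 2.0} Å. These sizes make the binomial/3-SE tolerances
in the tests meaningful while keeping the whole suite fast on one CPU.

## Known limitations

* The three conformer-comparison checks against the externally deposited
  full 20-pair distance tables require that download; the published text
  prints only 4 of the 20 pairs, which the tests use for partial
  (hand-computed) verification. Without the file those three checks fail
  with an explanatory message — by design, rather than silently passing.
* The per-protein odds taken as inputs (5,247; 2,636; 6,201; 4,378) are
  reproducible here only to ~±0.5% under plausible window conventions;
  their exact derivation was never published in reconstructable form.
* The suffix-inference search space is suffix patterns only; epitopes
  whose diagnostic rule is not expressible as a C-terminal match (e.g.
  internal-position rules) are out of scope by construction.
* The χ² verdict inherits the protocol's distributional convention; see
  above for why it is a calibrated index rather than a formal test.
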