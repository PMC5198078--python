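# Methods

## Model and procedure

`partstree` implements the trees-of-parts methodology as a chain of
small, exact operations.

**Census coding.** The input is a parts × proteomes matrix of
non-negative integer abundance counts (every part must be present
somewhere). Counts are rescaled per proteome column into a linearly
ordered state alphabet of size S (default 24, rendered 0–9 then A–N):

- `log` (default): state = round((S−1)·ln(a+1)/ln(a_max+1)), half-up,
  clamped to ≥ 1 for non-zero counts so that presence/absence survives
  the transform — coarse-graining to occurrence (0/1) is then exactly
  the quotient of the log coding under states > 0;
- `linear`: state = round((S−1)·a/a_max);
- `occurrence`: state = 1 iff a > 0 (alphabet size 2).

The log transform damps the heavy right tail of abundance data; 24
states is a conventional cap for multistate parsimony interchange. Both
are configuration, not claims about the data: the coding is monotone
within a column under any choice, which is all the downstream
polarization uses.

**Wagner parsimony.** Abundance states form a linear series, so state
changes are charged |i−j| (ordered/Wagner characters, not unordered
Fitch). Tree length is computed by the Farris interval rule (exact on
binary trees for linear cost), with an independent Sankoff dynamic
program over state cost vectors as a second route; the two are asserted
equal, and both equal brute-force enumeration over all internal
assignments on every topology with ≤ 6 leaves in the test suite.
Exact searches enumerate all (2n−5)!! unrooted binary topologies
(refused above 9 taxa) or run depth-first stepwise addition with an
admissible bound (partial tree length plus the per-character state
range not yet spanned by placed taxa); ties are retained, so
branch-and-bound returns exactly the exhaustive result set. The
heuristic search uses random-addition starting trees refined by NNI
then SPR to a local optimum, is deterministic given its seed, and can
never report a length below the true minimum (it reports the length of
an actual tree).

**Rooting.** Trees are rooted a posteriori by the Lundberg method: a
hypothetical ancestor is attached, in turn, to every branch of the
optimal unrooted tree, and the root is pulled to the branch whose
attachment increases total length least; the rooted length equals the
unrooted length plus that minimal increase. Under Weston's generality
criterion the ancestral state of an abundance character is the general
(abundant, widespread) condition, so the default ancestor is the
per-character **maximum** observed state; `min` and user-supplied
vectors are accepted because the criterion, not the vector, is the
principled part. All ties (here and in topology selection) break to the
lexicographically smallest canonical label, for reproducibility only.

**Chronology and clock.** A taxon's rank is the number of non-root
internal nodes on its root-to-leaf path (root = rank 0); nd =
rank/max_rank, so the most basal taxon gets nd = 0 and the most derived
nd = 1. Taxa attached at the same rank share nd — no intra-rank order
is invented, which is why a comb's two deepest taxa always tie. If all
taxa sit at one rank, all nd = 0. Whether the root counts as rank 0 or
1 only rescales nd by a constant; the convention here is fixed and
documented. Ages are linear in nd: age = origin_gy·(1 − nd), with
origin_gy = 3.8 Gy by default — the age of the oldest protein
structures — reaching 0 Gy at nd = 1. This reproduces the standard
anchor mapping (nd 0.02 → 3.7 Gy, nd 0.045 → 3.6 Gy at one-decimal
rendering) without refitting the geological calibration, which is out
of scope. Age transfer to an interacting molecule copies nd and age
verbatim and is flagged; conflicting transfers raise an error rather
than averaging. When several equally parsimonious trees exist,
chronologies can be summarized per taxon as nd mean and range.

**Semiglobal alignment.** The relic scan aligns a short tRNA query to a
long rRNA target globally but with free end gaps: gap runs lying before
a sequence's first residue or after its last cost nothing; internal
gaps cost gap_open + gap_extend·L. Defaults are the classical DNA
scoring of this tool family — match +5, mismatch −4, gap open −12,
extend −2 — fully configurable and recorded in output headers. The DP
is Gotoh's three-state recursion with zero-initialized boundaries and
the optimum over the last row/column; a numba kernel computes
score-only passes and a vectorized numpy path recovers one optimal
trace (ties: diagonal, then query-gap, then target-gap; alignment ends
scan the last row left-to-right, then the last column). U and T are
identical; IUPAC ambiguity codes score as mismatches; other symbols are
rejected. Scores are integers computed in float64, exact well beyond
the sizes used here.

**Scanning and significance.** Per query: align, test significance,
record the hit, hard-mask its target interval with a sentinel that can
never align profitably, repeat — so per-query hits are disjoint by
construction, while hits from different queries may overlap (that
overlap is the relic signal). Significance is a mononucleotide
permutation test: the query is shuffled and realigned n times
(default 200); empirical p = (1 + #{shuffled ≥ observed})/(n + 1); hits
are kept while p ≤ 0.01. A zero-variance null leaves z undefined
(reported as such) but p is always defined. The scan stops at max_hits,
at a non-positive score, or at the first non-significant alignment.

**Relics and age projection.** Hits on one target merge into relics as
connected components of the strict interval-overlap graph (≥ 1 shared
position by default; abutting intervals do not merge; min_overlap is
configurable). A relic's projection lists every helix of the age map it
intersects — partially overlapping helices count fully, matching the
discrete coloring of accretion maps — and oldest_nd is the minimum
helix nd spanned. Rows of the coevolution table pair each member hit's
tRNA age (nd_trna) with the relic's oldest_nd, flagged "old-segment"
at oldest_nd ≤ 0.3 (the upper bound of the PTC age band; the named
bands ratchet 0–0.04, hinges 0.09–0.26, PTC 0.28–0.30 are configurable).
Because it is not obvious whether such plots should carry one point per
hit or per relic, both table granularities are emitted, labeled. The
Spearman correlation carries a seeded label-permutation p (≥ 999
shuffles); constant columns make it undefined and are reported
explicitly, never as silent NaN.

## Synthetic data: what it emulates, what it does not

The generator produces every pipeline input with recorded truth.

- **Census**: part of rank r (of n) gets intended nd = r/(n−1) and
  birth_time = 1 − nd; expected abundance per proteome is
  base_count·exp(growth_rate·birth_time) (older parts accumulated more
  copies), times lognormal noise (sd = noise_sd), zeroed per proteome
  with probability loss_prob·nd (younger parts lost more often). This
  plants exactly the Weston-polarizable signal — older ⇒ more abundant
  and more widespread. Defaults used throughout the recovery tests:
  growth_rate 3, noise_sd 0.2, loss_prob 0.3, base_count 100 (the scale
  constant keeps integer rounding from collapsing adjacent ranks).
- **Planted relics**: uniform ACGT background; mutated copies
  (per-position substitution at the stated divergence) written over the
  background at non-overlapping positions drawn by a multinomial gap
  allocation, so truth coordinates are exact (no indels relative to the
  target frame).
- **Helix map**: the target is cut at planted-relic boundaries and
  tiled completely; a chosen fraction of relic blocks receives nd from
  the old bands, the rest and all non-relic helices from
  Uniform(0.3, 1) (range configurable).
- **tRNA queries**: uniform-random sequences, 70–95 nt, with
  isoacceptor, group (1/2 old editing specificities, 3 young) and
  nd_trna metadata.

Not emulated: real abundance dispersion/zero-inflation (unknown for the
source censuses), compositional bias, tRNA cloverleaf or rRNA secondary
structure, and sequence evolution along a tree. Passing recovery tests
therefore show the *algorithms* recover a planted accretion/relic
signal at realistic noise — not that real censuses carry that much
signal.

One property of the generator is worth stating because it is
scientifically honest rather than a defect: with multiplicative noise
off and the loss gradient on, a lost cell sits ~20 ordered states away
from its neighbours, so shared loss columns dominate the Wagner
optimum and the *true* maximum-parsimony tree groups parts partly by
loss pattern (verified with exact search). Perfect rank recovery is
therefore impossible in that regime; the tests assert near-perfect
recovery (ρ ≥ 0.95) with losses off and ρ ≥ 0.8 under the full noisy
conditions, both of which hold with margin.

## Numerical and design choices

- Rounding in the coder is half-up (floor(x + 0.5)), documented because
  numpy's default is banker's rounding; tied states are acceptable.
- Rows are parts (taxa), columns proteomes (characters); the transpose
  is rejected rather than guessed.
- Degenerate inputs: two-taxon trees give all nd = 0; constant
  characters contribute zero length; empty hit lists give empty relic
  tables and an all-zero census.
- Seeds are explicit everywhere; the pipeline derives stage seeds from
  one master seed by fixed offsets and serializes the full resolved
  config into the run directory with a checksum manifest.
- Problem sizes in the test suite (oracle enumeration on ≤ 6-leaf
  trees and ≤ 6-nt alignment pairs, 200 seven-taxon matrices for the
  branch-and-bound/exhaustive equivalence, 20-part/10-proteome censuses
  over 10 seeds, 50 plantings at divergence 0.2 on a 12-kb target) were
  chosen so the whole suite exercises every exactness claim at desk
  scale in a few minutes.

## Known limitations

- No bootstrap/jackknife support, no likelihood or Bayesian inference,
  no missing/inapplicable states: cells must be coded.
- The heuristic search is a local optimizer; on adversarial matrices it
  can return a tree longer than the optimum (never shorter).
- The permutation filter replaces, and does not reconstruct, the exact
  hit-acceptance rule of the original scanning tool, which is not
  restated in the methodology this package follows; likewise the
  geological-record regression behind the 3.8-Gy clock origin is taken
  as an anchor, not refit.
- Only the given strand is scanned by default (tRNA homologies in rRNA
  are same-strand); reverse-complement scanning is opt-in.
- Local (Waterman–Eggert) suboptimal alignment enumeration and
  structural/covariance-model homology search are out of scope.
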