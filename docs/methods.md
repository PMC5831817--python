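# Methods

This note documents the models, parameters and design choices behind
`hoxmap`, in the spirit of a methods supplement: what is computed, what
the defaults mean, what the synthetic data does and does not emulate,
and where the genuinely open choices were made.

## 1. Domain retrieval: fixed-length log-odds profile

The homeodomain detector is a position-specific scoring matrix over the
match columns of a seed multiple alignment — deliberately *not* a full
profile HMM. The pipeline needs only the presence and count of a
fixed-length (~60 aa) domain per protein, never a per-residue alignment,
so insert/delete states buy nothing here. Columns with more than 50%
gaps are dropped from the match states; per kept column

    log_odds[c][a] = ln( (count_a + pc·bg_a) / (n_eff + pc) / bg_a )

with pseudocount `pc = 1` and a background `bg` estimated from the
alignment with a Laplace floor (so unseen residues keep finite odds).

**Threshold calibration** is empirical: the reporting threshold is the
`(1 − fpr)` quantile of best-window scores over 1000 i.i.d. sequences of
length 500 drawn from the background composition (`fpr = 1e-3` by
default, i.e. about one false domain call per thousand unrelated
proteins of that length). The calibration is seeded and fully
reproducible. Overlapping candidate windows are resolved best-first
(ties to the smaller start), which is deterministic and independent of
scan order. Sequences with **two or more** domains are excluded as
probable mis-annotations or concatenations; zero-hit sequences are kept
but flagged, since a candidate set that came from a domain search should
not contain them.

## 2. Pairwise similarity: exact Smith–Waterman + Karlin–Altschul

Scores are exact affine-gap local alignment (Gotoh recursion; the
computation is delegated to Biopython's C `PairwiseAligner`) under
BLOSUM62 with gap costs `open = 11`, `extend = 1` (a gap of length k
costs `11 + k`). `X` scores 0 against everything; other non-standard
codes are rejected. At the package's scale — a few hundred proteins of a
few hundred residues — the full dynamic program is affordable, and it
removes the seeding heuristics and nondeterminism of database-search
tools. The test suite holds an independently coded plain three-matrix
DP against which the production path is checked for exact equality.

E-values use fixed gapped-BLOSUM62 Karlin–Altschul constants
(λ = 0.267, K = 0.041): `E = K·m·n·exp(−λS)`. No per-pair composition
adjustment is made; E-values are used **comparatively** (ordering,
thresholding, `−log10 E` weights), never as calibrated significance
claims. E-values are floored at `1e-300` before `−log10` so edge weights
stay finite for near-identical long sequences. Because the raw score and
`m·n` are symmetric, the two directions of a pair carry equal E-values;
the edge weight is defined as the mean of `−log10 E` over the directions
that meet the cutoff, which is the simplest symmetric combiner of
"reciprocal hit" significance.

All-against-all hits are materialized once at a permissive report cutoff
(default `1e-2`); every analysis cutoff at or below it (defaults `1e-33`
and `1e-40`) is then a pure edge filter — tightening can only remove
edges, never requires re-alignment, and the monotonicity is asserted in
tests.

## 3. The map: force-directed layout

Nodes start uniform in the unit square/cube and relax under

* attraction along each edge: `a · (w / w_max) · distance`, with
  `a = 1` and weights normalized by the map's maximum `−log10 E` (so the
  geometry is insensitive to the cutoff's absolute scale), and
* repulsion between every node pair: `r / distance²`, `r = 0.01`.

Positions move by `step × net force` with `step = 0.05` cooled by ×0.995
per iteration; convergence is declared when the mean displacement drops
below `1e-4` (at most 1500 iterations). Two nodes joined by a
maximal-weight edge therefore equilibrate at distance `(r/a)^{1/3} ≈
0.215`, which sets the map's natural length unit. Coincident points are
jittered by ~1e-6 using draws from the same seeded RNG stream, so the
determinism contract (same graph, parameters, dims and seed ⇒ bitwise
identical coordinates) survives degenerate starts.

Only *relative* geometry is consumed downstream: cluster adjacency,
intra/inter distance ratios, and per-group mean distance from the global
centroid ("center distance", the divergence signal). All of these are
invariant under rigid motions of the embedding, which is tested
explicitly. No claim is made that the layout reproduces any particular
visualization tool's geometry — the force constants above are this
package's own, chosen for stable convergence at n ≈ 50–500, and are
config-exposed and logged in the map file header.

## 4. Group assignment: density-weighted connectivity

The published-style judgement ("number of connections and darkest
lines") is formalized per (ParaHox group, Hox bin) pair and per analysis
cutoff as

* `connection_density = edges / possible_pairs`,
* `mean_weight` over existing edges, and
* `density_weighted_score = Σ weights / possible_pairs`,

the last combining both visual cues in one number (both components are
also reported). Hox bins are PG1, PG2, PG3 individually plus central
(PG4–8) and posterior (PG9–13); unknown/OTHER sequences stay in the
graph but are excluded from pair counts. The score is invariant under
uniform duplication of all members of both groups — a control against
database redundancy bias — and under relabeling of sequence ids.

The **final assignment** for a ParaHox group is read at the most
stringent cutoff at which the group retains any Hox connection,
mirroring the tighten-until-resolution procedure. Adjacent bins whose
scores differ by less than a relative **tie margin** merge into a tie
set. The margin's design rule: the two-sister synthetic scenario (Gsx
between PG2 and PG3) must report a tie while single-sister cases (Pdx,
Cdx) must not. Under the simulator's default conditions the
between-replicate spread of the realized divergence on the stems that
the two tie partners do *not* share gives the Gsx score ratio a standard
deviation of 6–9%, while the single-sister runner-up gap is ≥ 40%;
`tie_margin = 0.25` separates the two regimes with wide margins on both
sides. It is reported in every output as this package's formalization —
no quantitative tie criterion exists to inherit.

## 5. The synthetic paralog family

Each simulated protein is `left flank + 60-residue domain + right
flank`, flanks 80–110 residues each. Evolution proceeds down a rooted
guide topology whose branch lengths are expected substitutions per flank
site; per site, a substitution event fires with probability
`1 − exp(−t·rate)` and redraws the residue from the stationary
composition (BLOSUM62 background) — so a fraction of events is silent
and the expected changed-site fraction is `(1−e^{−t})(1−π_parent)`,
which the tests verify against simulation. Domain sites evolve at 0.2×
the flank rate and receive no indels; flanks take indels at 0.03
events/site/unit branch length (geometric lengths). This two-tier
structure is the point: a conserved, always-detectable domain inside
flanks variable enough to carry the classification signal — the
structure of the real family. There is no among-site Gamma, no
exchangeability structure, no codon level; the scientific argument needs
controlled *rate heterogeneity between groups*, not a realistic
replacement process.

The default scenario has eight groups × six species (48 sequences). The
guide topology of the `paper_supported`/`lba` preset is

    ((PG1:1.0, (Gsx:0.1, (PG2:0.5, (PG3:0.15, Pdx:0.15):0.35):0.05):0.15):0.25,
     ((central:0.3, Cdx:0.4):0.25, posterior:0.7):0.25);

with species tips of 0.05. These lengths were designed (by forward
calculation of expected identities and local-alignment scores, then
verified by simulation during generator design) to place the scenario in
the regime the method is about:

* partner pairs (Pdx–PG3, Gsx–PG2, Gsx–PG3, Cdx–central) well inside
  the stringent `1e-40` cutoff, with the two Gsx paths exactly equal in
  expectation (the tie);
* the runner-up and cross-clade pairs between the cutoffs or beyond
  them, so the 1e-33 → 1e-40 tightening is informative;
* PG1 long enough that a 25%-wide tie set never captures it.

The `severity` parameter multiplies all branch rates inside the Cdx and
posterior subtrees independently (the two-fast-groups hypothesis). At
severity 1 there is no rate heterogeneity; at severity 8 both groups are
saturated: the similarity graph simply disconnects them (zero
Cdx–posterior edges at `1e-40`), while neighbor joining on uncorrected
domain p-distances groups them together — the row-sum correction in the
Q-criterion overcompensates when saturated distances stop growing
additively, which *is* the LBA mechanism, demonstrated rather than
merely asserted. A `traditional` preset encodes the alternative
hypothesis (Gsx with PG1/PG2, Cdx with posterior) for contrast
experiments.

What the simulator does **not** emulate — and hence what passing tests
do not show about real data: database-scale redundancy and annotation
noise, domain-adjacent conserved motifs (hexapeptide), compositional
bias, heterotachy, alignment ambiguity inside the domain, and real
clade sampling structure. Recovery rates on this generator measure the
pipeline's internal consistency under its stated model, not field
performance on NCBI-scale data.

## 6. Neighbor joining

Textbook Saitou–Nei agglomeration on the Q-criterion, deterministic via
lexicographically-smallest-label tie-breaking, negative branch lengths
clamped to zero (recorded in provenance). Distances are **uncorrected
p-distances** over the best-scoring 60-column domain window of each
sequence — extraction by a fixed-length profile hit is an implicit
alignment, so no multiple alignment is ever built. Uncorrected distances
saturate for fast groups, which is deliberate: it is the mechanism whose
artifact the package demonstrates. A 20-state distance
correction (`corrected=True`) exists but is off by default. p-distances
need not satisfy additivity or the triangle inequality; that is a
property of the statistic, not an error. NJ correctness is pinned by an
exhaustive-search oracle (all 105 six-taxon topologies, least-squares
branch fits) and cross-checked against an independent library
implementation.

## 7. Numerical and serialization choices

* Identity for redundancy clustering: matches / alignment-columns of a
  global alignment with match 1, mismatch 0, linear gap −1; greedy
  longest-first clustering, length ties broken by lexicographic id.
  Default threshold 0.95 — the collapse is fully reversible via the
  member→representative map ("re-inflation"), so the choice only
  affects intermediate compute, not the final dataset.
* Map files are plain text with `[params] [sequences] [groups]
  [coordinates] [edges]` sections; floats print with `repr`, so a
  write→read→write cycle is byte-identical. Parse errors name file and
  line.
* Domain hit coordinates are 0-based half-open in memory and 1-based
  closed in TSV, with an exact round trip.
* The pipeline manifest records config, seeds, stage in/out counts and
  SHA-256 checksums of every artifact; it is written on success *and*
  failure (with the failing stage named). SVG export pins matplotlib's
  hash salt and drops the date so reruns are checksum-identical.

## 8. Problem sizes

Defaults throughout target desk scale: 48-sequence scenarios, ≤ 500
residues, all-against-all in ~1 s, full pipeline in ~4 s, the whole test
suite (including twenty end-to-end recovery replicates and forty LBA
replicates) in a few minutes on one CPU. The acceptance script uses 10
replicates per rate estimate, 200 domain-scan replicates and 20 layout
seeds.
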