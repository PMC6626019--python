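# Methods

## The annotation problem

Glycoside hydrolases (GHs) — the CAZy enzyme families that cleave
glycosidic bonds in cellulose, xylan, chitin and other polysaccharides —
occur as single-domain proteins (SDGH), as multi-domain proteins carrying
accessory modules such as carbohydrate-binding modules, dockerins or
fibronectin-III domains (MDGH), and, rarely, as multi-activity proteins
combining two or more catalytic domains (MAGH).  Annotating a large
protein collection for a *specific* set of GH families, while still
recovering the complete domain architecture of every positive protein, is
the problem this package addresses.

## The two-stage sequential strategy

A direct scan of N proteins against a full profile database of F families
costs N x F profile-sequence comparisons.  glycoscan instead:

1. **Stage 1 (targeted, permissive).** Every protein is searched with only
   the T target profiles ("domains of interest", T << F) at a permissive
   E-value threshold `stage1_evalue` (default 10).  Only the best local
   alignment per (protein, target) is examined.  A protein with any hit at
   E <= `stage1_evalue` becomes a candidate; its stage-1 coordinates are
   discarded.
2. **Stage 2 (full, strict).** Each candidate is re-scanned against the
   *entire* database with iterative domain extraction at a strict
   per-domain threshold `stage2_evalue` (default 1e-5).  This reveals all
   associated domains — including families outside the target set — and
   any candidate left without a target-family domain is dropped.

**Equivalence guarantee.**  Provided `stage1_evalue >= stage2_evalue` and
both stages share one E-value database size, the sequential output is
*identical* (same proteins, hits, coordinates, scores) to the direct scan
restricted to proteins retaining a target-family domain: any protein with
a target domain at E <= `stage2_evalue` necessarily has a stage-1 best-hit
E-value at least as good, so it can never be missed at stage 1, and stage
2 recomputes everything from scratch.  The test suite asserts this
equality hit-for-hit, and that the sequential route issues strictly fewer
(protein x profile) scoring calls whenever the candidate set is a proper
subset of the proteome.  Work saved is
`1 - (N·T + C·F) / (N·F)` for C candidates, so the strategy pays off
exactly when the target families are rare in the collection — the
intended use case.

## The scoring model

Each family is a profile hidden Markov model with M match states, per-node
insert and delete states, and the seven standard transitions.  Scoring
uses a *unihit local* alignment model: the aligner enters any match state
with probability 1/M, exits freely after any match state, and reports the
log2-odds of the alignment against an i.i.d. background (null) model.
Viterbi (best path) and forward (sum over paths) recurrences run in
natural-log space in numba-compiled kernels; sequence coordinates come
from a full Viterbi traceback.  This deliberately diverges from HMMER's
multihit plan-7 architecture: multiple domains per protein are found by
iteratively masking each accepted alignment with a score-neutral symbol
and re-running the aligner, which directly yields mutually non-overlapping
hits.  Masked-region handling clips any later alignment to its longest
unmasked run, so the non-overlap invariant holds unconditionally.

Ambiguity codes (X, B, Z, U, O) map to the same score-neutral symbol
(log-odds 0 in every state); a `*` stop codon truncates the sequence with
a warning.  Internally coordinates are 0-based half-open; every dataclass
field and output file is 1-based inclusive.

## E-values

Bit scores are converted to E-values through a Gumbel law fitted by the
method of moments (`lambda = pi/(sd*sqrt(6))`, `mu = mean - gamma/lambda`)
to the Viterbi scores of `n >= 200` random background sequences of length
M (default n = 500).  `E = db_size * (1 - exp(-exp(-lambda (s - mu))))`.
Because a local alignment can start at ~L positions in a length-L
sequence, the Gumbel location for a search against a sequence of length L
is shifted by `ln(L / M) / lambda` — the standard search-space correction;
without it every long protein looks significant against every profile and
the stage-1 candidate set degenerates to the whole proteome.  The moment
fit is adequate for per-domain thresholds down to ~1e-5 at desk scale; the
test suite bounds the empirical background false-hit rate at E <= t by
2t/db_size.

## Profile construction and storage

Profiles are estimated from seed alignments: columns with >= 50 % residue
occupancy (ties count) become match states; emissions and transitions are
smoothed with background-proportional pseudocounts
`(count + w·bg) / (n + w)` (default w = 1, uniform background, uniform
group prior for transitions).  Dirichlet-mixture priors are deliberately
out of scope — the single-parameter rule is closed-form and directly
testable.  Models are stored in a HMMER3-ASCII-compatible subset (NAME /
ACC / LENG / ALPH headers, optional `STATS LOCAL VITERBI mu lambda`, one
three-line block per node, `//` terminator) with negative natural-log
values at 7 decimal places and `*` for probability zero; a COMPO line
carries the null model so round trips are self-contained.  Emission rows
and transition groups are renormalized on read, keeping round-trip error
below 1e-6 while restoring the exact sum-to-1 invariants.

## Architecture reconstruction and classification

Per protein, hits are resolved greedily by descending bit score (ties:
lower E-value, lower start, lexicographic accession); a hit is kept iff
its overlap with every kept hit is at most half the shorter hit (the 0.5
tolerance is configurable).  Classification against the family catalog:
SDGH = exactly one domain, role catalytic GH; MDGH = >= 2 domains with >=
1 catalytic GH; MAGH = MDGH with >= 2 catalytic domains, counting
carbohydrate esterases and same-family repeats (multi-GHx).  Unknown
accessions degrade to accessory with a warning rather than failing a run.

Synergy typing of catalytic pairs is a catalog rule, declared as this
package's convention: **PPS** for distinct substrates with both domains
backbone hydrolases (cellulase:xylanase), **DS** for same substrate with
exactly one side-group-cleaving domain (xylanase:esterase), **LPS** for
same substrate pairing a backbone hydrolase with an oligosaccharidase
(endo-cellulase:beta-glucosidase), `none` otherwise, including
same-family repeats.

## Co-occurrence networks

Families are nodes (attribute: total instance count); a protein
containing families a and b adds 1 to edge (a, b) — once per protein,
however many instance pairs — and a protein with >= 2 copies of f adds 1
to the self-edge (f, f).  Counting proteins rather than instance pairs is
a declared convention (both are computable from the architectures).  The
association-map filter keeps edges with weight >= 2 ("observed more than
once"); self-edges are exported explicitly in the edge-list CSV because
some graph formats drop loops silently.

## The synthetic benchmark

The generator invents `n_families` = 10 families (roles round-robin:
catalytic GH cycling over cellulose/xylan/chitin, carbohydrate esterase,
accessory), each a random 30–60-residue consensus with a 10-row seed
alignment at 5 % per-residue substitution.  Proteins (default 1,000) draw
an archetype from the class mix 0.60 SDGH / 0.20 MDGH-with-accessory /
0.10 MAGH / 0.05 repeated-domain / 0.05 background, emit domains from the
profiles' match emissions joined by uniform-random 10–30-residue linkers
(background proteins are 80–200 i.i.d. residues), and record every planted
interval exactly.  Truth labels are produced by running the classifier on
the planted domain lists, so generator and classifier can never disagree
by construction.  Everything is deterministic per seed.

What the generator does *not* emulate — and therefore what passing tests
do not demonstrate about real data: insert-state emission inside domains
(planted coordinates stay unambiguous), indels in linkers, homology
between families, compositional bias, or the heavy-tailed family
abundances of real databases.  Recovery rates on this benchmark are upper
bounds for real proteomes.

## Numerical and degenerate-input choices

- Internal DP in natural log; bits at the API boundary; log(0) is a
  -1e30 sentinel so kernel arithmetic never produces NaN.
- Viterbi tie-breaks: entry preferred over continuation, M over I over D,
  earliest end position — fixed, so reruns are byte-identical.
- Empty proteome: the pipeline returns an empty result and the end-to-end
  driver still writes every declared output file (empty-bodied).
- A calibration with zero score variance raises rather than producing
  infinite lambda.
- Stage-1 thresholds above the E-value ceiling (`db_size`) are rejected as
  configuration errors; an empty target set is "nothing to hunt".

## Problem sizes

The bundled tests and the acceptance script use a 200-protein proteome
for the equivalence comparison, the 1,000-protein default benchmark for
recovery, 2,000 draws for the Gumbel-recovery check, and 400–500
background sequences for the false-hit bound; the exhaustive DP check
covers every sequence of length <= 6 over a 4-letter alphabet against
models with up to 3 nodes.  These sizes were chosen so the whole suite
runs in well under a minute on one CPU while keeping binomial error on
every rate far below the asserted margins.

## Known limitations

- The unihit local model scores each domain independently; no J-state
  multihit correction, no glocal mode, no posterior decoding.
- Moment-fit Gumbel calibration is approximate in the extreme tail;
  E-values below ~1e-10 are order-of-magnitude indicators.
- The default family catalog covers the cellulolytic, xylanolytic and
  chitinolytic families plus common accessory domains; proteins from
  families outside it classify correctly only if a catalog is supplied.
- Synergy types are catalog conventions about *potential* cooperation;
  no enzymatic activity is predicted.
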