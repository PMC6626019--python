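# glycoscan

Sequential profile-HMM annotation of glycoside hydrolase (GH) domain
architectures.

Glycoside hydrolases — the CAZy enzymes that deconstruct cellulose, xylan
and chitin — occur as single-domain proteins (SDGH), as multi-domain
proteins with accessory modules such as carbohydrate-binding modules
(MDGH), and occasionally as multi-activity proteins combining several
catalytic domains (MAGH), which are attractive scaffolds for biomass
conversion.  Finding the members of specific GH families in a large
protein collection *and* resolving their complete domain architecture is
expensive if every protein is scanned against every profile.

glycoscan implements a two-stage strategy for this: a fast, permissive
first pass searches only the small set of target-family profiles
(`hmmsearch`-style) to select candidate proteins; the candidates are then
re-scanned against the entire profile database (`hmmscan`-style) at a
strict per-domain threshold, revealing every associated domain and
discarding first-pass false positives.  When the permissive threshold is
at least as loose as the strict one, the result is provably identical to
a direct all-vs-all scan — at a fraction of the scoring work whenever the
target families are rare.  Downstream modules classify each protein
(SDGH / MDGH / MAGH / non-GH), type potential catalytic synergies
(parallel-pathway, debranching, linear-pathway), and build the domain
co-occurrence network with the observed-more-than-once edge filter.

The scoring core is a unihit local profile HMM: entry into any of the M
match states with probability 1/M, free exit after any match state,
Viterbi/forward dynamic programming in log space, bit scores converted to
E-values through a moment-fitted Gumbel law with the standard
`ln(L/M)/lambda` search-space correction.  Multiple domains per protein
come from iterative score-neutral masking.  Profiles are built from seed
alignments with background-proportional pseudocounts and stored in a
HMMER3-ASCII-compatible dialect, so nothing external is downloaded.  A
bundled generator produces synthetic proteomes with planted, labelled
architectures for benchmarking; see `docs/methods.md` for the model
details and its limitations.

## Worked example

Generate a 120-protein synthetic study (10 families, planted
architectures) and run the full pipeline:

```sh
glycoscan simulate --out study --seed 7 --n-proteins 120
glycoscan run --fasta study/proteome.fasta --profiles study/profiles.hmm \
              --targets study/targets.txt --catalog study/catalog.tsv \
              --out results
```

which prints

```
stage1: 112/120 candidates
111 annotated proteins -> results
```

112 of 120 proteins passed the permissive first pass (the study plants
GH-family domains in most proteins; 6 background proteins and 2 others
were screened out), and one candidate was dropped at stage 2 as a false
positive.  `results/` then contains the hit table, the architecture table,
the co-occurrence edge list and filtered GraphML, per-family summaries,
the multi-activity report and a run log.  The multi-activity report
begins:

```
protein_id  arch_string              n_catalytic  synergy_calls
P000017     FAM08-FAM08-FAM08-FAM08  4            FAM08:FAM08=none
P000064     FAM08-FAM08-FAM08        3            FAM08:FAM08=none
```

— P000017 is a planted multi-GHx protein: four copies of the same
catalytic family make it a MAGH, but same-family repeats are never typed
as a synergistic pair.  The same analysis is available as a library:

```python
import glycoscan as gs

cfg = gs.GeneratorConfig(n_proteins=120, seed=7)
fams = gs.generate_family_set(cfg)
proteins, truth = gs.generate_proteome(cfg, fams)
pipe = gs.PipelineConfig(
    target_accessions=fams.catalog.accessions_for_role("catalytic_GH"))
hits = gs.run_sequential(proteins, fams.models, pipe)
archs = gs.build_architectures(
    [h for hs in hits.values() for h in hs], fams.catalog)
print(gs.score_recovery(truth, archs).summary())
# 120 proteins | exact architecture 100.0% | labels 100.0% |
# mean coord err 0.10 | ends within 3: 100.0%
```

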