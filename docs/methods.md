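# Methods

This note documents the models, defaults and numerical choices behind
`lbd-bridge`, what the synthetic generators do and do not emulate, and
the known limitations of the shipped reference fixtures.

## Co-occurrence model and closed discovery

The corpus model is a bag of documents, each reduced to a *set* of
concept annotations. Co-occurrence is document-level and binary: a pair
(A, B) is counted once per document containing both, regardless of how
often either term appears inside the document. This matches per-record
subject-heading indexing, where a concept is either assigned to a
record or not; within-document multiplicity carries no information at
this granularity.

Closed discovery fixes X and a list of end concepts Z and emits every
concept Y of the requested semantic type with `Freq(X,Y) ≥ min_freq`
and, depending on the combine mode, `Freq(Y,Z) ≥ min_freq` for **some**
Z (`union`, default) or **every** Z (`intersection`). The default is
union because pooling two per-end-concept candidate lists of sizes 72
and 111 into 128 candidates is only arithmetically possible as a
(deduplicated) union, whatever the pooling was called; intersection
remains available by flag for the stricter reading. The combined FreqYZ
of a candidate is the sum of its per-Z document counts over end
concepts it actually co-occurs with — the simplest reduction consistent
with reporting a single FreqYZ column — and the per-Z counts are
retained on each record. The rank score is the plain product
`FreqXY × FreqYZ`.

Tie-breaking in every sorted output is: primary key score/frequency
descending, secondary key symbol (or concept id) ascending. `min_freq`
defaults to 1: the reference analysis applied no frequency floor.

## Differential expression stage

* **Test.** Per probe, a two-sided two-sample t-test. Default variant
  is Welch (Satterthwaite df) because case/control microarray groups
  are small and rarely variance-matched; the pooled test
  (df = n₁+n₂−2) is available by flag. Moderated (limma-style)
  statistics are deliberately out of scope. Zero variance in both
  groups with equal means is defined as t = 0, p = 1; with unequal
  means as |t| = ∞, p = 0. Probes with non-finite values are excluded
  with a warning, not fatal.
* **Multiplicity.** Benjamini–Hochberg step-up adjusted p-values are
  computed over all tested probes and reported, but selection is by
  *rank*: the top `n_top` probes by raw p (default 250, the published
  choice), with all probes tied at the boundary p-value retained —
  a deterministic superset beats an arbitrary truncation. No FDR
  cutoff is applied by default.
* **Mapping.** Selected probes are mapped to gene symbols via the
  platform annotation; alias fields are split on `///`, `;`, `,`;
  unannotated probes (empty, `-`, `---`) contribute nothing. Symbols
  are normalized (uppercase; hyphens, spaces, periods removed) so that
  variant renderings of one symbol unify.
* **Pooling.** Per-dataset gene sets are combined by set union. Values
  are tested as they arrive; log transformation is the caller's
  responsibility.

The pipeline config also accepts precomputed per-dataset DEG gene
lists in place of raw matrices. This is how the shipped reference run
works: the published per-series overlap gene lists are themselves the
input, since reprocessing the original GEO series is out of scope.

## Ambiguity screen

Manual literature inspection is not reproducible by definition. It is
formalised as (a) an ambiguity lexicon mapping normalized symbols to a
reason, and (b) an explicit per-gene override file (`keep`/`drop`)
whose decisions beat the lexicon. The shipped 14-symbol lexicon records
the symbols removed in the reference analysis; it is an audit artifact
of that screen, not a claim about ambiguity semantics in general.

## Tissue filter

The reference analysis judged expression "anatograms" by eye, with no
printed threshold. The filter here is an explicit, configurable
stand-in: a gene passes a tissue group when

    max(expr over group tissues) ≥ absolute_floor
    max(expr over group tissues) ≥ relative_floor × max(expr over all tissues)

with defaults `absolute_floor = 0` and `relative_floor = 0.5` — "the
gene's expression in this organ reaches at least half its best tissue
anywhere". Genes absent from the atlas fail closed by default (the
reference screen excluded what it could not confirm); a flag turns
absence into a hard error instead. Required groups default to
`[heart, brain]`; requiring only heart reproduces the weaker reading
in which brain expression was not explicitly gated.

The shipped atlas (`tissue_atlas_synthetic.tsv`) is **constructed, not
measured**: values were chosen so that the nine screened genes
reproduce the published verdicts (LCAT, CD4, SERPINA1, IL6, PPBP fail
heart; GNB3, CNR1, MTHFR, NCAM1 pass heart and brain). A green tissue
test therefore establishes that the filter logic reproduces the
published decisions, not anything about real human expression.

## Reference fixtures

* The 23 published candidate rows (gene, FreqXY, FreqYZ, product) and
  the per-series overlap gene lists ship as TSVs with a sha256
  manifest. The orbital-prefrontal series' CD4 row is included: the
  accompanying prose counts sixteen depression-overlap genes but the
  table lists seventeen, and the downstream 23 → 9 counts require CD4.
* The full 128-candidate list was never published. The fixture pads
  the 23 known genes with 105 `CIMFILL###` placeholders that appear in
  no DEG fixture, so every downstream count is unaffected. Any result
  that depends on the identity of the other 105 genes is outside what
  these fixtures can support.
* The reference corpus is *regenerated* from the published scores: each
  candidate is planted as exactly FreqXY documents {X, gene} and FreqYZ
  documents {gene, Z₁} (the published single FreqYZ is assigned to the
  first end concept — whether it was per-concept or combined is not
  recoverable). Corpus-scale figures tied to live literature and GEO
  snapshots (72, 111, 128 discovered from raw text; 2750 DEGs) are
  inherently irreproducible offline and are not asserted anywhere.

## Synthetic generators

All generators are pure functions of their spec, seed included.

* **Corpus.** Planted bridges are combinatorial: exactly `freq_xy`
  documents {X, g} and exactly `freq_yz[z]` documents {g, z}, so
  discovery tests are exact. Background noise concepts are added to the
  remaining documents, each included independently with probability
  `noise_cooccurrence_rate` (background pairs therefore co-occur at the
  squared rate); noise never touches X, Z or bridge genes, keeping
  planted counts exact. Defaults: 50 documents, 10 background concepts,
  noise rate 0.1.
* **Expression.** Null probes are i.i.d. Gaussian N(0, noise_sd²) in
  both groups (the simplest null consistent with t-testing; heavier
  tails are out of scope); a planted gene's probes are shifted upward
  in cases by `effect_size × noise_sd`. Defaults: 1000 probes, 10
  samples per group, noise_sd 1, one probe per gene — small-series
  sizes typical of the reference GEO sets. The generator does not
  emulate normalization artifacts, probe cross-hybridisation or
  correlated genes.
* **Atlas.** Per-gene patterns (`heart+brain-high`, `brain-only`,
  `uniform-low`, …) place `high_level` (default 8) on the named groups
  and `baseline_level` (default 1) elsewhere, plus a small non-negative
  jitter so group maxima never fall below the stated level. With the
  default 8:1 contrast, a `brain-only` gene fails the heart group at
  `relative_floor = 0.5` by construction.
* **Linked scenario.** `generate_linked_scenario` plants four genes
  with every property (bridge, DE at 2 SD with n = 10/group, heart+brain
  expression, unambiguous symbol) and one violator per property, plus
  20 filler bridges with no expression support. The pipeline on this
  scenario (top 250 of 1000 probes) recovers the planted genes and
  fails each violator at its own stage; this was verified across 60
  seeds before the test seeds were frozen. A green scenario test
  establishes stage attribution and recovery under the planted model,
  not performance on real text or arrays.

## Numerical and engineering choices

* t statistics come from `scipy.stats.ttest_ind`, BH from
  `statsmodels.multipletests(method="fdr_bh")`; the test suite checks
  both against hand-derived values and an independent brute-force
  step-up oracle.
* Report files are deterministic: stable orderings everywhere, floats
  at 6 significant digits, timestamps confined to the run manifest.
* Pipeline outputs are removed on failure; an empty final candidate
  set is a valid success, exit code 0.
* Duplicate discovery symbols (two concept ids normalizing to one
  symbol) keep the higher-scoring record in the cascade.

## Limitations

* No live MEDLINE/GEO access, no entity recognition, no MeSH tree
  traversal: annotations and expression matrices arrive pre-extracted.
* No cross-dataset meta-analysis; pooling is set union by design.
* The ambiguity lexicon and the tissue atlas fixtures encode one
  historical screen; applying the pipeline to new disease pairs
  requires supplying both for that domain.
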