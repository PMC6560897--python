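# lbd-bridge

Closed literature-based discovery (LBD) with expression-based filtering,
for finding candidate genes shared between two diseases. The package
implements the full pipeline that linked myocardial infarction (MI) and
depression through intermediate gene concepts, and ships the reference
tables needed to reproduce that analysis end to end without any
downloads.

## The method

**Closed ABC discovery.** Given a document corpus where each record is a
set of concept annotations, fix a start concept *X* (e.g. "Myocardial
Infarction", semantic type *Disease or Syndrome*) and end concepts *Z*
(e.g. "Major Depressive Disorder", "Depressive disorder", type *Mental
or Behavioral Dysfunction*). An intermediate *Y* restricted to the type
*Gene or Gene Product* is a candidate when it co-occurs with both ends:

    Freq(A, B) = #documents annotated with both A and B
    candidate Y:  Freq(X, Y) ≥ 1  and  Freq(Y, Z) ≥ 1 for some Z
    score(Y)   =  Freq(X, Y) × Freq(Y, Z)

Counting is document-level and binary (one count per document). The
per-Z candidate lists are pooled by union by default; intersection is
available by flag. Candidates are ranked by the product score.

**Filter cascade.** Three ordered filters, each only removing genes:

1. *DEG overlap* — keep candidates that are differentially expressed in
   at least one case/control dataset of either disease. Per dataset,
   every probe gets a two-sample t-test (Welch by default; pooled
   optional), Benjamini–Hochberg adjusted p-values are reported, the top
   250 probes by raw p are kept (boundary ties included), and probes are
   mapped to normalized gene symbols. Per-dataset gene sets are pooled
   by union.
2. *Ambiguity* — drop symbols that are unreliable as text-mining terms
   (common words, non-gene abbreviations), via a lexicon plus explicit
   keep/drop overrides.
3. *Tissue* — keep genes expressed in every required tissue group
   (heart **and** brain here): the gene's maximum over the group's
   tissues must reach an absolute floor and a configurable fraction
   (default 0.5) of its maximum across all tissues.

Every gene receives a per-stage audit trail; survivor counts are
non-increasing by construction.

## Worked example: the shipped reference analysis

```python
from lbd_bridge.pipeline import run_reference_pipeline

reports, counts = run_reference_pipeline(out_dir="demo")
print(counts)
```

prints

```
{'discovery': 128, 'deg_overlap': 23, 'ambiguity': 9, 'tissue': 4}
```

Discovery proposes 128 gene candidates (the corpus is regenerated from
the packaged co-occurrence scores); 23 of them are differentially
expressed in at least one of the 15 MI/depression GEO series; 9 survive
the ambiguity screen; 4 pass the dual heart/brain tissue requirement.
The top of `demo/discovery.tsv`:

```
gene_symbol	freq_xy	freq_yz	product_score
IL6	99	20	1980
CD4	11	16	176
MTHFR	40	4	160
```

IL6 co-occurs with MI in 99 documents and with depression in 20, giving
the highest product score — yet it fails the tissue filter; the final
candidates in `demo/cascade_report.tsv` are **GNB3, CNR1, MTHFR and
NCAM1**, e.g.

```
gene	freq_xy	freq_yz	product_score	deg_overlap	deg_datasets	ambiguity	...	final_status	failing_stage
MTHFR	40	4	160	pass	GSE54572	pass	...	pass
IL6	99	20	1980	pass	GSE83500	pass	...	fail	tissue
```

The shipped tissue atlas is a **constructed stand-in**
(`tissue_atlas_synthetic.tsv`), not measured human expression data, and
105 of the 128 candidate symbols are `CIMFILL###` placeholders because
the full candidate list was never published; see `docs/methods.md`.

## Command line

Each stage is a subcommand over plain-text files (TSV/JSONL/YAML):

```sh
lbd-bridge discover --corpus corpus.jsonl --vocabulary vocab.tsv \
    --start C:MI --end C:MDD --end C:DD --out discovery.tsv
lbd-bridge deg --matrix m.tsv --groups g.tsv --platform p.tsv \
    --out-table deg.tsv --out-genes genes.txt
lbd-bridge cascade --discovery discovery.tsv --deg-genes genes.txt \
    --lexicon lexicon.tsv --atlas atlas.tsv --tissue-groups groups.tsv \
    --out report.tsv
lbd-bridge run --config config.yaml        # whole pipeline from YAML
lbd-bridge validate --config config.yaml   # dry-run config check
lbd-bridge simulate --spec sim.yaml --out dir/   # synthetic data
```

`run` expects a YAML config naming the corpus/vocabulary, start and end
concepts, either expression dataset triplets or precomputed per-dataset
DEG gene lists, the lexicon/overrides, the atlas with its tissue-group
file, required groups and floors, and an output directory (see
`tests/test_pipeline_cli.py` for a complete example).

## Synthetic data

`lbd_bridge.synthetic_data` generates corpora with exact planted X–Y–Z
bridge frequencies, case/control expression matrices with planted
effects in units of the noise SD, and tissue atlases with per-gene
patterns such as `heart+brain-high` or `brain-only` — all pure
functions of their spec (seed included). `generate_linked_scenario`
plants a jointly consistent corpus + expression + atlas with known
ground truth, including one violator per pipeline property.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the reference cascade from scratch (corpus regeneration →
discovery → DEG overlap → ambiguity → tissue) and runs a seeded
synthetic end-to-end scenario, printing the survivor counts, the final
candidate set, and the planted-gene recovery rate.
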