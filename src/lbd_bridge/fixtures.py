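"""Packaged reference tables for the MI / depression candidate-gene cascade.

The package ships small TSV fixtures encoding the published
intermediate-concept scores, the per-GEO-series DEG overlaps, the
128-symbol candidate list, the 14-symbol manual drop list, and a
**constructed** tissue atlas.  Notes on provenance:

* the full 128-candidate list was never published; the fixture pads the
  23 published genes with 105 ``CIMFILL###`` placeholder symbols that
  appear in no DEG fixture, so every downstream count is unaffected;
* the tissue atlas (``tissue_atlas_synthetic.tsv``) is a synthetic
  stand-in constructed to reproduce the published heart/brain verdicts
  for the nine manually screened genes — it is **not** measured human
  expression data.

All symbols are normalized at load time, so loaded fixtures are
canonical even where the source tables print variants ("IL-6", "HLA-B").
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .concept_graph import IntermediateRecord
from .deg_stage import split_aliases
from .filter_cascade import AmbiguityLexicon, TissueAtlas, normalize_symbol
from .synthetic_data import CorpusSpec, PlantedBridge, X_CONCEPT, Z_CONCEPTS

__all__ = [
    "ReferenceFixtures",
    "load_reference_fixtures",
    "reference_corpus_spec",
    "fixture_path",
    "verify_manifest",
]


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture file."""
    return Path(resources.files("lbd_bridge").joinpath("data", name))


def verify_manifest() -> dict[str, str]:
    """Check every packaged fixture against its recorded sha256; return the manifest."""
    manifest = json.loads(fixture_path("manifest.json").read_text())
    for name, expected in manifest.items():
        actual = hashlib.sha256(fixture_path(name).read_bytes()).hexdigest()
        if actual != expected:
            raise RuntimeError(f"fixture {name} does not match its manifest sha256")
    return manifest


@dataclass
class ReferenceFixtures:
    """The loaded reference tables, symbols normalized."""

    table2_records: list[IntermediateRecord]
    deg_map: dict[str, list[str]]  # series id -> overlap gene symbols
    series_info: pd.DataFrame
    mi_series: list[str]
    depression_series: list[str]
    cim_list: list[str]
    drop_lexicon: AmbiguityLexicon
    atlas: TissueAtlas


def load_reference_fixtures() -> ReferenceFixtures:
    """Load every packaged reference table into domain objects."""
    z_main = Z_CONCEPTS[0].concept_id

    scores = pd.read_csv(fixture_path("discovery_scores.tsv"), sep="\t")
    records = []
    for row in scores.itertuples(index=False):
        sym = normalize_symbol(row.gene)
        records.append(
            IntermediateRecord(
                gene_symbol=sym,
                concept_id=f"G:{sym}",
                freq_xy=int(row.freq_xy),
                freq_yz_per_z={z_main: int(row.freq_yz)},
                freq_yz_combined=int(row.freq_yz),
                product_score=int(row.product_score),
            )
        )

    series = pd.read_csv(fixture_path("deg_overlap_by_series.tsv"), sep="\t")
    series["genes"] = series["genes"].fillna("")
    deg_map = {
        row.series: sorted(normalize_symbol(g) for g in split_aliases(row.genes))
        for row in series.itertuples(index=False)
    }
    mi = series.loc[series["disease"] == "myocardial_infarction", "series"].tolist()
    dep = series.loc[series["disease"] == "depression", "series"].tolist()

    cims = [
        normalize_symbol(g)
        for g in pd.read_csv(fixture_path("cim_list.tsv"), sep="\t")["gene"]
    ]

    lex = pd.read_csv(fixture_path("ambiguity_lexicon.tsv"), sep="\t")
    lexicon = AmbiguityLexicon(
        {normalize_symbol(r.symbol): r.reason for r in lex.itertuples(index=False)}
    )

    atlas_values = pd.read_csv(
        fixture_path("tissue_atlas_synthetic.tsv"), sep="\t", index_col="gene"
    )
    atlas_values.index = [normalize_symbol(g) for g in atlas_values.index]
    groups = pd.read_csv(fixture_path("tissue_groups.tsv"), sep="\t")
    atlas = TissueAtlas(
        values=atlas_values,
        tissue_groups=dict(zip(groups["tissue"], groups["group"])),
    )

    return ReferenceFixtures(
        table2_records=records,
        deg_map=deg_map,
        series_info=series,
        mi_series=mi,
        depression_series=dep,
        cim_list=cims,
        drop_lexicon=lexicon,
        atlas=atlas,
    )


def reference_corpus_spec(noise_rate: float = 0.0, seed: int = 0) -> CorpusSpec:
    """A corpus spec whose planted bridges encode the published scores.

    Building the corpus and running closed discovery (union mode,
    ``min_freq=1``) reproduces every published FreqXY / FreqYZ / product
    row, with the 105 placeholder candidates planted at frequency 1.
    The single published FreqYZ is planted entirely against the first
    end concept.
    """
    fx = load_reference_fixtures()
    z_main = Z_CONCEPTS[0].concept_id
    bridges = [
        PlantedBridge(r.gene_symbol, r.freq_xy, {z_main: r.freq_yz_combined})
        for r in fx.table2_records
    ]
    published = {r.gene_symbol for r in fx.table2_records}
    bridges += [
        PlantedBridge(sym, 1, {z_main: 1}) for sym in fx.cim_list if sym not in published
    ]
    n_docs = sum(b.freq_xy + sum(b.freq_yz.values()) for b in bridges)
    if noise_rate > 0:
        n_docs += 50
    return CorpusSpec(
        n_docs=n_docs,
        n_background_concepts=10,
        planted_bridges=bridges,
        noise_cooccurrence_rate=noise_rate,
        seed=seed,
        x=X_CONCEPT,
        z=Z_CONCEPTS,
    )
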