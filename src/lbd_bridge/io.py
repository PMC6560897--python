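"""Readers and writers for the pipeline's plain-text interchange formats.

Formats:

* corpus — JSONL (``{"doc_id": ..., "concepts": [...]}`` per line) or
  2-column TSV ``doc_id<TAB>concept_id`` with one row per annotation;
* vocabulary — TSV with columns ``concept_id, name, semantic_type``;
* expression — matrix TSV (first column ``probe_id``, remaining columns
  samples), 2-column sample-group TSV, 2-column platform TSV
  (``probe_id, gene_symbols`` with ``///`` aliases);
* lexicon / overrides / atlas / reports — TSV as documented per reader.

All writers emit deterministic output for deterministic input: stable
row ordering and fixed 6-significant-digit float formatting.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .concept_graph import AnnotatedDocument, Concept, IntermediateRecord
from .deg_stage import ExpressionDataset
from .filter_cascade import AmbiguityLexicon, CandidateReport, TissueAtlas, normalize_symbol

__all__ = [
    "read_corpus",
    "write_corpus_jsonl",
    "read_vocabulary",
    "write_vocabulary",
    "read_expression_dataset",
    "write_expression_dataset",
    "read_lexicon",
    "read_overrides",
    "read_atlas",
    "write_atlas",
    "read_gene_list",
    "write_gene_list",
    "write_discovery_tsv",
    "read_discovery_tsv",
    "write_deg_table",
    "write_cascade_report",
]

_FLOAT_FMT = "%.6g"


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


# --------------------------------------------------------------------------
# corpus / vocabulary


def read_corpus(path: str | Path) -> list[AnnotatedDocument]:
    """Read a corpus from JSONL (``.jsonl``/``.json``) or annotation TSV."""
    path = Path(path)
    docs: list[AnnotatedDocument] = []
    if path.suffix in (".jsonl", ".json"):
        with path.open() as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                    docs.append(AnnotatedDocument(obj["doc_id"], obj["concepts"]))
                except (json.JSONDecodeError, KeyError) as exc:
                    raise ValueError(f"{path}:{lineno}: malformed corpus record: {exc}") from exc
    else:
        frame = pd.read_csv(path, sep="\t", dtype=str)
        if list(frame.columns[:2]) != ["doc_id", "concept_id"]:
            raise ValueError(f"{path}: corpus TSV needs columns doc_id, concept_id")
        for doc_id, group in frame.groupby("doc_id", sort=True):
            docs.append(AnnotatedDocument(doc_id, set(group["concept_id"])))
    seen: set[str] = set()
    for doc in docs:
        if doc.doc_id in seen:
            raise ValueError(f"{path}: duplicate doc_id {doc.doc_id!r}")
        seen.add(doc.doc_id)
    return docs


def write_corpus_jsonl(docs: Iterable[AnnotatedDocument], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for doc in docs:
            fh.write(json.dumps({"doc_id": doc.doc_id, "concepts": sorted(doc.concepts)}) + "\n")


def read_vocabulary(path: str | Path) -> dict[str, Concept]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"concept_id", "name", "semantic_type"}
    if not required <= set(frame.columns):
        raise ValueError(f"{path}: vocabulary TSV needs columns {sorted(required)}")
    vocab: dict[str, Concept] = {}
    for row in frame.itertuples(index=False):
        if row.concept_id in vocab:
            raise ValueError(f"{path}: duplicate concept_id {row.concept_id!r}")
        vocab[row.concept_id] = Concept(row.concept_id, row.name, row.semantic_type)
    return vocab


def write_vocabulary(vocabulary: Mapping[str, Concept], path: str | Path) -> None:
    rows = [
        (c.concept_id, c.name, c.semantic_type)
        for c in sorted(vocabulary.values(), key=lambda c: c.concept_id)
    ]
    pd.DataFrame(rows, columns=["concept_id", "name", "semantic_type"]).to_csv(
        path, sep="\t", index=False
    )


# --------------------------------------------------------------------------
# expression datasets


def read_expression_dataset(
    matrix_path: str | Path,
    groups_path: str | Path,
    platform_path: str | Path,
    dataset_id: str | None = None,
) -> ExpressionDataset:
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    groups_frame = pd.read_csv(groups_path, sep="\t", dtype=str)
    if list(groups_frame.columns[:2]) != ["sample_id", "group"]:
        raise ValueError(f"{groups_path}: needs columns sample_id, group")
    platform_frame = pd.read_csv(platform_path, sep="\t", dtype=str).fillna("")
    if list(platform_frame.columns[:2]) != ["probe_id", "gene_symbols"]:
        raise ValueError(f"{platform_path}: needs columns probe_id, gene_symbols")
    return ExpressionDataset(
        dataset_id=dataset_id or Path(matrix_path).stem,
        matrix=matrix,
        sample_groups=dict(zip(groups_frame["sample_id"], groups_frame["group"])),
        platform=dict(zip(platform_frame["probe_id"], platform_frame["gene_symbols"])),
    )


def write_expression_dataset(dataset: ExpressionDataset, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / f"{dataset.dataset_id}_matrix.tsv",
        "groups": out / f"{dataset.dataset_id}_groups.tsv",
        "platform": out / f"{dataset.dataset_id}_platform.tsv",
    }
    dataset.matrix.to_csv(paths["matrix"], sep="\t", index_label="probe_id",
                          float_format=_FLOAT_FMT)
    pd.DataFrame(
        sorted(dataset.sample_groups.items()), columns=["sample_id", "group"]
    ).to_csv(paths["groups"], sep="\t", index=False)
    pd.DataFrame(
        sorted(dataset.platform.items()), columns=["probe_id", "gene_symbols"]
    ).to_csv(paths["platform"], sep="\t", index=False)
    return paths


# --------------------------------------------------------------------------
# cascade inputs


def read_lexicon(path: str | Path) -> AmbiguityLexicon:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if list(frame.columns[:2]) != ["symbol", "reason"]:
        raise ValueError(f"{path}: lexicon TSV needs columns symbol, reason")
    return AmbiguityLexicon(
        {normalize_symbol(r.symbol): r.reason for r in frame.itertuples(index=False)}
    )


def read_overrides(path: str | Path) -> dict[str, str]:
    """Overrides TSV: columns symbol, action (keep|drop), optional note."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if list(frame.columns[:2]) != ["symbol", "action"]:
        raise ValueError(f"{path}: overrides TSV needs columns symbol, action")
    return {normalize_symbol(r.symbol): r.action for r in frame.itertuples(index=False)}


def read_atlas(matrix_path: str | Path, groups_path: str | Path) -> TissueAtlas:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = [normalize_symbol(g) for g in values.index]
    groups_frame = pd.read_csv(groups_path, sep="\t", dtype=str)
    if list(groups_frame.columns[:2]) != ["tissue", "group"]:
        raise ValueError(f"{groups_path}: needs columns tissue, group")
    return TissueAtlas(
        values=values,
        tissue_groups=dict(zip(groups_frame["tissue"], groups_frame["group"])),
    )


def write_atlas(atlas: TissueAtlas, matrix_path: str | Path, groups_path: str | Path) -> None:
    atlas.values.to_csv(matrix_path, sep="\t", index_label="gene", float_format=_FLOAT_FMT)
    pd.DataFrame(
        sorted(atlas.tissue_groups.items()), columns=["tissue", "group"]
    ).to_csv(groups_path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> set[str]:
    """One symbol per line (or first TSV column); normalized on read."""
    genes: set[str] = set()
    for line in Path(path).read_text().splitlines():
        token = line.split("\t")[0].strip()
        if token and token.lower() not in ("gene", "symbol", "none"):
            genes.add(normalize_symbol(token))
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


# --------------------------------------------------------------------------
# stage outputs


def write_discovery_tsv(records: Sequence[IntermediateRecord], path: str | Path) -> None:
    rows = [
        (r.gene_symbol, r.freq_xy, r.freq_yz_combined, r.product_score) for r in records
    ]
    pd.DataFrame(rows, columns=["gene_symbol", "freq_xy", "freq_yz", "product_score"]).to_csv(
        path, sep="\t", index=False
    )


def read_discovery_tsv(path: str | Path) -> list[IntermediateRecord]:
    frame = pd.read_csv(path, sep="\t")
    return [
        IntermediateRecord(
            gene_symbol=row.gene_symbol,
            concept_id=f"G:{normalize_symbol(row.gene_symbol)}",
            freq_xy=int(row.freq_xy),
            freq_yz_per_z={},
            freq_yz_combined=int(row.freq_yz),
            product_score=int(row.product_score),
        )
        for row in frame.itertuples(index=False)
    ]


def write_deg_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_cascade_report(reports: Sequence[CandidateReport], path: str | Path) -> None:
    rows = []
    for r in reports:
        rows.append(
            {
                "gene": r.gene,
                "freq_xy": r.record.freq_xy,
                "freq_yz": r.record.freq_yz_combined,
                "product_score": r.record.product_score,
                "deg_overlap": r.deg_overlap.status,
                "deg_datasets": r.deg_overlap.detail,
                "ambiguity": r.ambiguity.status,
                "ambiguity_reason": r.ambiguity.detail,
                "tissue": r.tissue.status,
                "tissue_detail": r.tissue.detail,
                "tissue_value": "" if r.tissue.value is None or np.isnan(r.tissue.value)
                else _fmt(r.tissue.value),
                "final_status": r.final_status,
                "failing_stage": r.failing_stage or "",
            }
        )
    columns = ["gene", "freq_xy", "freq_yz", "product_score", "deg_overlap",
               "deg_datasets", "ambiguity", "ambiguity_reason", "tissue",
               "tissue_detail", "tissue_value", "final_status", "failing_stage"]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
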