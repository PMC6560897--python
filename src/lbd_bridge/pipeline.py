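"""End-to-end orchestration: discovery -> DEG calling -> filter cascade.

A single YAML config drives the whole run; each stage writes its
intermediate table so stages can also be run in isolation (see the
``lbd-bridge`` CLI).  The DEG stage accepts either raw expression
dataset triplets (matrix / groups / platform TSVs) or precomputed
per-dataset gene lists — the latter covers the common situation where
differential expression was called elsewhere and only the overlap gene
lists are available.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .concept_graph import closed_discovery, build_index
from .deg_stage import call_degs, union_deg_sets
from .filter_cascade import (
    AmbiguityLexicon,
    CandidateReport,
    run_cascade,
    stage_survivor_counts,
)
from .fixtures import load_reference_fixtures, reference_corpus_spec
from .synthetic_data import GENE_SEMANTIC_TYPE, generate_corpus
from . import io as lbio

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "validate_config",
    "run_pipeline",
    "write_report",
    "run_reference_pipeline",
]


@dataclass
class PipelineConfig:
    """Validated description of a full pipeline run."""

    corpus: str
    vocabulary: str
    start_concept: str
    end_concepts: list[str]
    out_dir: str
    y_semantic_type: str = GENE_SEMANTIC_TYPE
    combine_mode: str = "union"
    min_freq: int = 1
    expression_datasets: list[dict[str, str]] = field(default_factory=list)
    deg_gene_lists: list[dict[str, str]] = field(default_factory=list)
    n_top: int = 250
    test_variant: str = "welch"
    lexicon: str | None = None
    overrides: str | None = None
    atlas: str | None = None
    tissue_groups: str | None = None
    required_groups: list[str] = field(default_factory=lambda: ["heart", "brain"])
    relative_floor: float = 0.5
    absolute_floor: float = 0.0
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config fields {sorted(unknown)}")
        config = cls(**raw)
        config._resolve_paths(path.parent)
        return config

    def _resolve_paths(self, base: Path) -> None:
        def resolve(p: str | None) -> str | None:
            if p is None:
                return None
            q = Path(p)
            return str(q if q.is_absolute() else base / q)

        self.corpus = resolve(self.corpus)
        self.vocabulary = resolve(self.vocabulary)
        self.lexicon = resolve(self.lexicon)
        self.overrides = resolve(self.overrides)
        self.atlas = resolve(self.atlas)
        self.tissue_groups = resolve(self.tissue_groups)
        self.out_dir = resolve(self.out_dir)
        for entry in self.expression_datasets:
            for key in ("matrix", "groups", "platform"):
                entry[key] = resolve(entry.get(key))
        for entry in self.deg_gene_lists:
            entry["path"] = resolve(entry.get("path"))

    def problems(self) -> list[str]:
        """Constraint violations, each naming the offending field."""
        issues: list[str] = []

        def need_file(name: str, p: str | None) -> None:
            if p is None:
                issues.append(f"{name}: path missing")
            elif not Path(p).is_file():
                issues.append(f"{name}: file not found: {p}")

        need_file("corpus", self.corpus)
        need_file("vocabulary", self.vocabulary)
        if not self.end_concepts:
            issues.append("end_concepts: must be non-empty")
        if self.start_concept in self.end_concepts:
            issues.append("start_concept: must not appear in end_concepts")
        if self.combine_mode not in ("union", "intersection"):
            issues.append("combine_mode: must be union or intersection")
        if self.min_freq < 1:
            issues.append("min_freq: must be >= 1")
        if self.n_top < 1:
            issues.append("n_top: must be >= 1")
        if self.test_variant not in ("welch", "pooled"):
            issues.append("test_variant: must be welch or pooled")
        if not self.expression_datasets and not self.deg_gene_lists:
            issues.append("expression_datasets/deg_gene_lists: at least one DEG input required")
        for i, entry in enumerate(self.expression_datasets):
            for key in ("matrix", "groups", "platform"):
                need_file(f"expression_datasets[{i}].{key}", entry.get(key))
        for i, entry in enumerate(self.deg_gene_lists):
            need_file(f"deg_gene_lists[{i}].path", entry.get("path"))
        if self.lexicon:
            need_file("lexicon", self.lexicon)
        if self.overrides:
            need_file("overrides", self.overrides)
        need_file("atlas", self.atlas)
        need_file("tissue_groups", self.tissue_groups)
        if not self.required_groups:
            issues.append("required_groups: must be non-empty")
        if not 0.0 <= self.relative_floor <= 1.0:
            issues.append("relative_floor: must lie in [0, 1]")
        return issues


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    config: dict[str, Any]
    input_checksums: dict[str, str]
    survivor_counts: dict[str, int]
    version: str
    timestamp: str

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def validate_config(path: str | Path) -> list[str]:
    """Problems that would prevent :func:`run_pipeline`; empty means runnable."""
    try:
        config = PipelineConfig.from_yaml(path)
    except (OSError, ValueError, TypeError, yaml.YAMLError) as exc:
        return [f"config: {exc}"]
    return config.problems()


def _sha256(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> tuple[list[CandidateReport], RunManifest]:
    """Execute discovery, DEG calling, and the filter cascade; write reports.

    Partial outputs are removed if any stage fails.  An empty final gene
    set is a valid outcome, not an error.
    """
    issues = config.problems()
    if issues:
        raise ValueError("invalid pipeline config: " + "; ".join(issues))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    try:
        corpus = lbio.read_corpus(config.corpus)
        vocabulary = lbio.read_vocabulary(config.vocabulary)
        index = build_index(corpus, vocabulary)
        records = closed_discovery(
            index,
            config.start_concept,
            config.end_concepts,
            config.y_semantic_type,
            config.combine_mode,
            config.min_freq,
        )
        discovery_path = out_dir / "discovery.tsv"
        lbio.write_discovery_tsv(records, discovery_path)
        created.append(discovery_path)

        deg_sets: dict[str, set[str]] = {}
        for entry in config.expression_datasets:
            dataset = lbio.read_expression_dataset(
                entry["matrix"], entry["groups"], entry["platform"],
                dataset_id=entry.get("id"),
            )
            table, genes = call_degs(dataset, config.n_top, config.test_variant)
            deg_path = out_dir / f"deg_{dataset.dataset_id}.tsv"
            lbio.write_deg_table(table, deg_path)
            created.append(deg_path)
            deg_sets[dataset.dataset_id] = genes
        for entry in config.deg_gene_lists:
            ds_id = entry.get("id") or Path(entry["path"]).stem
            deg_sets[ds_id] = lbio.read_gene_list(entry["path"])
        deg_union = union_deg_sets(deg_sets.values())

        lexicon = lbio.read_lexicon(config.lexicon) if config.lexicon else AmbiguityLexicon({})
        overrides = lbio.read_overrides(config.overrides) if config.overrides else None
        atlas = lbio.read_atlas(config.atlas, config.tissue_groups)

        reports = run_cascade(
            records,
            deg_union,
            lexicon,
            overrides,
            atlas,
            config.required_groups,
            config.relative_floor,
            config.absolute_floor,
            deg_sets_by_dataset=deg_sets,
        )
        counts = stage_survivor_counts(reports)

        checks = {"corpus": _sha256(config.corpus), "vocabulary": _sha256(config.vocabulary)}
        for name in ("lexicon", "overrides", "atlas", "tissue_groups"):
            value = getattr(config, name)
            if value:
                checks[name] = _sha256(value)
        manifest = RunManifest(
            config={k: v for k, v in config.__dict__.items()},
            input_checksums=checks,
            survivor_counts=counts,
            version=__version__,
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )
        created += write_report(reports, manifest, out_dir)
    except Exception:
        for path in created:
            path.unlink(missing_ok=True)
        raise
    for stage, n in manifest.survivor_counts.items():
        logger.info("stage %s: %d survivors", stage, n)
    return reports, manifest


def write_report(
    reports: list[CandidateReport],
    manifest: RunManifest,
    out_dir: str | Path,
) -> list[Path]:
    """Write the cascade report TSV, summary JSON and manifest JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report_path = out_dir / "cascade_report.tsv"
    summary_path = out_dir / "summary.json"
    manifest_path = out_dir / "manifest.json"
    lbio.write_cascade_report(reports, report_path)
    summary_path.write_text(json.dumps(manifest.survivor_counts, indent=2, sort_keys=True) + "\n")
    manifest_path.write_text(manifest.to_json() + "\n")
    return [report_path, summary_path, manifest_path]


def run_reference_pipeline(
    out_dir: str | Path | None = None,
) -> tuple[list[CandidateReport], dict[str, int]]:
    """Run the full cascade on the packaged reference fixtures.

    The corpus is regenerated from the published co-occurrence scores, so
    discovery proposes 128 candidates; the per-series DEG gene lists, the
    14-symbol drop lexicon and the constructed atlas then narrow them to
    23 -> 9 -> 4.  Returns the per-gene reports and the survivor counts.
    """
    fx = load_reference_fixtures()
    corpus, vocabulary = generate_corpus(reference_corpus_spec())
    index = build_index(corpus, vocabulary)
    spec = reference_corpus_spec()
    records = closed_discovery(
        index,
        spec.x.concept_id,
        [z.concept_id for z in spec.z],
        GENE_SEMANTIC_TYPE,
        "union",
        1,
    )
    deg_union = union_deg_sets(fx.deg_map.values())
    reports = run_cascade(
        records,
        deg_union,
        fx.drop_lexicon,
        None,
        fx.atlas,
        ["heart", "brain"],
        deg_sets_by_dataset=fx.deg_map,
    )
    counts = stage_survivor_counts(reports)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        lbio.write_discovery_tsv(records, out_dir / "discovery.tsv")
        lbio.write_cascade_report(reports, out_dir / "cascade_report.tsv")
        (out_dir / "summary.json").write_text(json.dumps(counts, indent=2, sort_keys=True) + "\n")
    return reports, counts
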