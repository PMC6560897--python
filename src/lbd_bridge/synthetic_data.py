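"""Generators for corpora, expression datasets and tissue atlases with planted structure.

Every generator is a pure function of its spec (seed included), so
identical specs give byte-identical artifacts.  Planted co-occurrence
frequencies are constructed combinatorially — exactly the requested
number of documents carry each planted pair — so discovery tests are
exact rather than stochastic.  Expression noise is Gaussian, the
simplest null consistent with t-testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .concept_graph import AnnotatedDocument, Concept
from .deg_stage import ExpressionDataset
from .filter_cascade import AmbiguityLexicon, TissueAtlas

__all__ = [
    "SpecError",
    "PlantedBridge",
    "CorpusSpec",
    "ExpressionSpec",
    "AtlasSpec",
    "generate_corpus",
    "generate_expression",
    "generate_atlas",
    "LinkedScenario",
    "generate_linked_scenario",
    "X_CONCEPT",
    "Z_CONCEPTS",
    "GENE_SEMANTIC_TYPE",
]

GENE_SEMANTIC_TYPE = "Gene or Gene Product"

#: default start concept: the index disease
X_CONCEPT = Concept("C:MI", "Myocardial Infarction", "Disease or Syndrome")
#: default end concepts: the linked disease, under two vocabulary entries
Z_CONCEPTS = (
    Concept("C:MDD", "Major Depressive Disorder", "Mental or Behavioral Dysfunction"),
    Concept("C:DD", "Depressive disorder", "Mental or Behavioral Dysfunction"),
)


class SpecError(ValueError):
    """A generator spec is internally inconsistent or infeasible."""


@dataclass(frozen=True)
class PlantedBridge:
    """A gene planted as an X-Y-Z literature bridge at exact frequencies."""

    gene: str
    freq_xy: int
    freq_yz: Mapping[str, int] = field(default_factory=dict)  # z concept_id -> count


@dataclass
class CorpusSpec:
    """Blueprint for a concept-annotated corpus with planted bridges.

    Planted documents are deterministic; the remaining documents carry
    background concepts, each included independently with probability
    ``noise_cooccurrence_rate`` (so background pairs co-occur at the
    squared rate, and never involve X, Z or bridge genes — planted
    counts stay exact).
    """

    n_docs: int = 50
    n_background_concepts: int = 10
    planted_bridges: Sequence[PlantedBridge] = ()
    noise_cooccurrence_rate: float = 0.1
    seed: int = 0
    x: Concept = X_CONCEPT
    z: Sequence[Concept] = Z_CONCEPTS

    def validate(self) -> None:
        if not 0.0 <= self.noise_cooccurrence_rate <= 1.0:
            raise SpecError("noise_cooccurrence_rate must lie in [0, 1]")
        z_ids = {z.concept_id for z in self.z}
        needed = 0
        for b in self.planted_bridges:
            if b.freq_xy < 0 or any(f < 0 for f in b.freq_yz.values()):
                raise SpecError(f"negative planted frequency for {b.gene}")
            unknown = set(b.freq_yz) - z_ids
            if unknown:
                raise SpecError(f"bridge {b.gene} names unknown end concepts {sorted(unknown)}")
            needed += b.freq_xy + sum(b.freq_yz.values())
        if needed > self.n_docs:
            raise SpecError(
                f"planted documents ({needed}) exceed n_docs ({self.n_docs})"
            )


def generate_corpus(
    spec: CorpusSpec,
) -> tuple[list[AnnotatedDocument], dict[str, Concept]]:
    """Materialise a corpus and vocabulary from a :class:`CorpusSpec`.

    For each planted bridge gene g, exactly ``freq_xy`` documents are
    ``{X, g}`` and exactly ``freq_yz[z]`` documents are ``{g, z}``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    vocabulary: dict[str, Concept] = {spec.x.concept_id: spec.x}
    for z in spec.z:
        vocabulary[z.concept_id] = z
    for bridge in spec.planted_bridges:
        cid = f"G:{bridge.gene}"
        vocabulary[cid] = Concept(cid, bridge.gene, GENE_SEMANTIC_TYPE)
    background = [f"BG{i:04d}" for i in range(spec.n_background_concepts)]
    for cid in background:
        vocabulary[cid] = Concept(cid, cid, "Background Concept")

    docs: list[AnnotatedDocument] = []

    def emit(concepts: set[str]) -> None:
        docs.append(AnnotatedDocument(f"D{len(docs):06d}", concepts))

    for bridge in spec.planted_bridges:
        gid = f"G:{bridge.gene}"
        for _ in range(bridge.freq_xy):
            emit({spec.x.concept_id, gid})
        for z_id, count in bridge.freq_yz.items():
            for _ in range(count):
                emit({gid, z_id})
    while len(docs) < spec.n_docs:
        mask = rng.random(len(background)) < spec.noise_cooccurrence_rate
        emit({cid for cid, hit in zip(background, mask) if hit})
    return docs, vocabulary


@dataclass
class ExpressionSpec:
    """Blueprint for a case/control expression dataset with planted DE genes.

    Null probes are N(0, noise_sd) in both groups; a planted gene's
    probes are shifted upward in cases by ``effect_size * noise_sd``.
    Every gene (planted and filler) receives ``probes_per_gene`` probes.
    """

    n_probes: int = 1000
    n_case: int = 10
    n_control: int = 10
    planted_de_genes: Sequence[tuple[str, float]] = ()  # (gene, effect size in sd)
    noise_sd: float = 1.0
    probes_per_gene: int = 1
    seed: int = 0
    dataset_id: str = ""

    def validate(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise SpecError("need at least 2 samples per group")
        if self.noise_sd <= 0:
            raise SpecError("noise_sd must be positive")
        if self.probes_per_gene < 1:
            raise SpecError("probes_per_gene must be >= 1")
        if not all(np.isfinite(e) for _, e in self.planted_de_genes):
            raise SpecError("effect sizes must be finite")
        if len(self.planted_de_genes) * self.probes_per_gene > self.n_probes:
            raise SpecError("planted probes exceed n_probes")


def generate_expression(spec: ExpressionSpec) -> ExpressionDataset:
    """Materialise an :class:`~lbd_bridge.deg_stage.ExpressionDataset`."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    probe_ids: list[str] = []
    platform: dict[str, str] = {}
    planted_rows: list[tuple[int, float]] = []
    for gene, effect in spec.planted_de_genes:
        for j in range(spec.probes_per_gene):
            planted_rows.append((len(probe_ids), effect))
            pid = f"{gene}_p{j + 1}"
            probe_ids.append(pid)
            platform[pid] = gene
    filler_idx = 0
    while len(probe_ids) < spec.n_probes:
        gene = f"NULLG{filler_idx:05d}"
        for j in range(spec.probes_per_gene):
            if len(probe_ids) >= spec.n_probes:
                break
            pid = f"{gene}_p{j + 1}"
            probe_ids.append(pid)
            platform[pid] = gene
        filler_idx += 1

    n_samples = spec.n_case + spec.n_control
    values = rng.normal(0.0, spec.noise_sd, size=(spec.n_probes, n_samples))
    for row, effect in planted_rows:
        values[row, : spec.n_case] += effect * spec.noise_sd

    samples = [f"CASE{i + 1:03d}" for i in range(spec.n_case)] + [
        f"CTRL{i + 1:03d}" for i in range(spec.n_control)
    ]
    groups = {s: ("case" if s.startswith("CASE") else "control") for s in samples}
    return ExpressionDataset(
        dataset_id=spec.dataset_id or f"SYN-{spec.seed}",
        matrix=pd.DataFrame(values, index=probe_ids, columns=samples),
        sample_groups=groups,
        platform=platform,
    )


#: atlas pattern aliases -> which tissue groups get the high level
_PATTERN_ALIASES = {
    "uniform-low": frozenset(),
    "uniform-high": None,  # all groups, resolved at generation time
}


@dataclass
class AtlasSpec:
    """Blueprint for a gene x tissue atlas with per-gene expression patterns.

    ``patterns`` maps gene -> pattern; a pattern is ``"uniform-low"``,
    ``"uniform-high"`` or ``"<group>[+<group>...]-high"`` (e.g.
    ``"heart+brain-high"``, ``"brain-only"`` is accepted as shorthand for
    ``"brain-high"``).  High-group tissues get ``high_level`` (plus a
    small non-negative jitter), everything else ``baseline_level``.
    """

    tissue_groups: Mapping[str, str] = field(
        default_factory=lambda: {
            "heart_atrium": "heart",
            "heart_ventricle": "heart",
            "cerebral_cortex": "brain",
            "cerebellum": "brain",
            "amygdala": "brain",
            "liver": "other",
            "blood": "other",
        }
    )
    patterns: Mapping[str, str] = field(default_factory=dict)
    baseline_level: float = 1.0
    high_level: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if self.baseline_level < 0 or self.high_level < 0:
            raise SpecError("expression levels must be non-negative")
        groups = set(self.tissue_groups.values())
        for gene, pattern in self.patterns.items():
            self.high_groups(pattern, groups)

    @staticmethod
    def high_groups(pattern: str, known_groups: set[str]) -> frozenset[str]:
        if pattern == "uniform-low":
            return frozenset()
        if pattern == "uniform-high":
            return frozenset(known_groups)
        stem = pattern
        for suffix in ("-high", "-only"):
            if pattern.endswith(suffix):
                stem = pattern[: -len(suffix)]
                break
        groups = frozenset(stem.split("+"))
        unknown = groups - known_groups
        if unknown:
            raise SpecError(f"pattern {pattern!r} names unknown groups {sorted(unknown)}")
        return groups


def generate_atlas(spec: AtlasSpec) -> TissueAtlas:
    """Materialise a :class:`~lbd_bridge.filter_cascade.TissueAtlas`."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    tissues = list(spec.tissue_groups)
    known = set(spec.tissue_groups.values())
    rows = {}
    for gene in sorted(spec.patterns):
        high = spec.high_groups(spec.patterns[gene], known)
        level = np.array(
            [
                spec.high_level if spec.tissue_groups[t] in high else spec.baseline_level
                for t in tissues
            ]
        )
        # jitter is non-negative so group maxima never drop below the stated level
        rows[gene] = level + rng.uniform(0, 0.05 * max(spec.baseline_level, 1e-9), len(tissues))
    values = pd.DataFrame.from_dict(rows, orient="index", columns=tissues)
    return TissueAtlas(values=values, tissue_groups=dict(spec.tissue_groups))


@dataclass
class LinkedScenario:
    """Jointly planted corpus + expression + atlas + lexicon with known truth.

    ``expected_final`` genes carry all four planted properties (literature
    bridge, differential expression, heart+brain expression, unambiguous
    symbol); each gene in ``expected_stage_failures`` violates exactly one
    property and must fail at the named cascade stage (or, for
    ``"discovery"``, never be proposed at all).
    """

    corpus: list[AnnotatedDocument]
    vocabulary: dict[str, Concept]
    dataset: ExpressionDataset
    atlas: TissueAtlas
    lexicon: AmbiguityLexicon
    x_id: str
    z_ids: list[str]
    expected_final: set[str]
    expected_stage_failures: dict[str, str]  # gene -> stage


def generate_linked_scenario(
    seed: int = 0,
    effect_size: float = 2.0,
    n_per_group: int = 10,
    n_filler_bridges: int = 20,
) -> LinkedScenario:
    """Plant a full end-to-end scenario with one violator per property.

    Good genes satisfy every pipeline requirement; ``NOBRIDGEA`` is
    differentially expressed but absent from the literature, ``NODEA``
    bridges but is not differentially expressed, ``AMBIGA`` is flagged by
    the ambiguity lexicon, and ``NOHEARTA`` is expressed only in brain.
    Filler bridge genes emulate literature candidates with no expression
    support.
    """
    good = ["GOODA", "GOODB", "GOODC", "GOODD"]
    fillers = [f"FILLER{i:02d}" for i in range(n_filler_bridges)]
    z1 = Z_CONCEPTS[0].concept_id
    z2 = Z_CONCEPTS[1].concept_id

    bridges = [PlantedBridge(g, 4, {z1: 2, z2: 1}) for g in good]
    bridges += [
        PlantedBridge("NODEA", 3, {z1: 2}),
        PlantedBridge("AMBIGA", 5, {z2: 3}),
        PlantedBridge("NOHEARTA", 2, {z1: 1}),
    ]
    bridges += [PlantedBridge(g, 1, {z1: 1}) for g in fillers]
    n_planted_docs = sum(b.freq_xy + sum(b.freq_yz.values()) for b in bridges)
    corpus, vocabulary = generate_corpus(
        CorpusSpec(
            n_docs=n_planted_docs + 30,
            n_background_concepts=15,
            planted_bridges=bridges,
            noise_cooccurrence_rate=0.1,
            seed=seed,
        )
    )

    de_genes = [(g, effect_size) for g in good + ["AMBIGA", "NOHEARTA", "NOBRIDGEA"]]
    dataset = generate_expression(
        ExpressionSpec(
            n_probes=1000,
            n_case=n_per_group,
            n_control=n_per_group,
            planted_de_genes=de_genes,
            noise_sd=1.0,
            probes_per_gene=1,
            seed=seed + 1,
            dataset_id=f"SYN-E2E-{seed}",
        )
    )

    patterns = {g: "heart+brain-high" for g in good + ["NODEA", "AMBIGA", "NOBRIDGEA"]}
    patterns["NOHEARTA"] = "brain-only"
    patterns.update({g: "uniform-high" for g in fillers})
    atlas = generate_atlas(AtlasSpec(patterns=patterns, seed=seed + 2))

    lexicon = AmbiguityLexicon({"AMBIGA": "planted ambiguous abbreviation"})
    return LinkedScenario(
        corpus=corpus,
        vocabulary=vocabulary,
        dataset=dataset,
        atlas=atlas,
        lexicon=lexicon,
        x_id=X_CONCEPT.concept_id,
        z_ids=[z1, z2],
        expected_final=set(good),
        expected_stage_failures={
            "NOBRIDGEA": "discovery",
            "NODEA": "deg_overlap",
            "AMBIGA": "ambiguity",
            "NOHEARTA": "tissue",
        },
    )
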