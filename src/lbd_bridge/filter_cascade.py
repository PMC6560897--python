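"""Sequential candidate filters: DEG overlap, symbol ambiguity, dual-tissue expression.

Discovery over co-occurrence counts produces candidate intermediate
molecules (CIMs); three ordered filters then narrow them, each only
removing genes:

1. **DEG overlap** — keep genes that are differentially expressed in at
   least one case/control dataset of either disease;
2. **ambiguity** — drop symbols that are ambiguous as text-mining terms
   (common words, non-gene abbreviations), formalised as a lexicon plus
   explicit per-gene keep/drop overrides;
3. **tissue** — keep genes expressed in every required tissue group
   (heart and brain for a cardiac/psychiatric disease pair), judged
   against a gene x tissue atlas with a dual floor rule.

Every gene gets a :class:`CandidateReport` audit trail recording the
stage at which it terminated; stages after a failure are marked
not-evaluated.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .concept_graph import IntermediateRecord

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_symbol",
    "AmbiguityLexicon",
    "TissueAtlas",
    "StageVerdict",
    "CandidateReport",
    "overlap_cims_degs",
    "ambiguity_filter",
    "tissue_pass",
    "tissue_filter",
    "run_cascade",
    "stage_survivor_counts",
]

_STRIP = re.compile(r"[-. ]")


def normalize_symbol(raw: str) -> str:
    """Canonicalise a gene symbol: uppercase, strip hyphens/spaces/periods.

    Reconciles variant renderings of the same symbol across sources
    (``"IL-6"`` vs ``"IL6"``).  Idempotent.
    """
    if not raw or not raw.strip():
        raise ValueError("cannot normalize an empty gene symbol")
    return _STRIP.sub("", raw.strip().upper())


@dataclass
class AmbiguityLexicon:
    """Map of normalized symbol -> reason the symbol is ambiguous as a term."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        for symbol, reason in self.entries.items():
            if symbol != normalize_symbol(symbol):
                raise ValueError(f"lexicon key {symbol!r} is not normalized")
            if not reason:
                raise ValueError(f"lexicon reason for {symbol!r} is empty")

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.entries

    def reason(self, symbol: str) -> str:
        return self.entries[symbol]


@dataclass
class TissueAtlas:
    """Gene x tissue expression values plus a tissue -> group labelling."""

    values: pd.DataFrame  # index: gene symbols, columns: tissues
    tissue_groups: dict[str, str]

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("atlas expression values must be non-negative")
        missing = set(self.values.columns) - set(self.tissue_groups)
        if missing:
            raise ValueError(f"tissues without a group label: {sorted(missing)}")

    def group_tissues(self, group: str) -> list[str]:
        return [t for t in self.values.columns if self.tissue_groups.get(t) == group]

    def __contains__(self, gene: str) -> bool:
        return gene in self.values.index


def overlap_cims_degs(cims: Iterable[str], deg_union: Iterable[str]) -> set[str]:
    """Intersection of the discovery candidates with the pooled DEG set."""
    return set(cims) & set(deg_union)


def ambiguity_filter(
    genes: Iterable[str],
    lexicon: AmbiguityLexicon,
    overrides: Mapping[str, str] | None = None,
) -> tuple[set[str], list[tuple[str, str]]]:
    """Drop symbols flagged ambiguous; explicit overrides beat the lexicon.

    *overrides* maps symbol -> ``"keep"`` or ``"drop"``.  Returns
    ``(kept set, removed list of (symbol, reason))``; kept and removed
    partition the input exactly.
    """
    genes = set(genes)
    overrides = dict(overrides or {})
    for sym, action in overrides.items():
        if action not in ("keep", "drop"):
            raise ValueError(f"override action for {sym!r} must be keep or drop")
        if sym not in genes:
            logger.warning("override for %s ignored: gene not among candidates", sym)
    kept: set[str] = set()
    removed: list[tuple[str, str]] = []
    for gene in sorted(genes):
        action = overrides.get(gene)
        if action == "keep":
            kept.add(gene)
        elif action == "drop":
            removed.append((gene, "dropped by explicit override"))
        elif gene in lexicon:
            removed.append((gene, lexicon.reason(gene)))
        else:
            kept.add(gene)
    return kept, removed


def tissue_pass(
    gene: str,
    atlas: TissueAtlas,
    group: str,
    relative_floor: float = 0.5,
    absolute_floor: float = 0.0,
    missing_fails: bool = True,
) -> tuple[bool, float]:
    """Does *gene* show expression in tissue *group*?

    Passes iff the maximum over the group's tissues is >= *absolute_floor*
    and >= *relative_floor* times the gene's maximum over all tissues.
    Returns ``(verdict, group maximum)``.  A gene absent from the atlas
    fails closed by default (``missing_fails=True``) with a warning,
    otherwise raises ``KeyError``.
    """
    if not 0.0 <= relative_floor <= 1.0:
        raise ValueError("relative_floor must lie in [0, 1]")
    if gene not in atlas:
        if missing_fails:
            logger.warning("gene %s absent from tissue atlas: fail-closed", gene)
            return False, math.nan
        raise KeyError(f"gene {gene!r} absent from tissue atlas")
    tissues = atlas.group_tissues(group)
    if not tissues:
        raise ValueError(f"tissue group {group!r} has no tissues in the atlas")
    row = atlas.values.loc[gene]
    group_max = float(row[tissues].max())
    global_max = float(row.max())
    ok = group_max >= absolute_floor and group_max >= relative_floor * global_max
    return ok, group_max


def tissue_filter(
    genes: Iterable[str],
    atlas: TissueAtlas,
    required_groups: Sequence[str],
    relative_floor: float = 0.5,
    absolute_floor: float = 0.0,
    missing_fails: bool = True,
) -> tuple[set[str], list[tuple[str, str]]]:
    """Keep genes passing :func:`tissue_pass` for every required group.

    The removal record names the first failing group in *required_groups*
    order.
    """
    if not required_groups:
        raise ValueError("required_groups must be non-empty")
    kept: set[str] = set()
    removed: list[tuple[str, str]] = []
    for gene in sorted(set(genes)):
        failing = None
        for group in required_groups:
            ok, _ = tissue_pass(
                gene, atlas, group, relative_floor, absolute_floor, missing_fails
            )
            if not ok:
                failing = group
                break
        if failing is None:
            kept.add(gene)
        else:
            removed.append((gene, failing))
    return kept, removed


@dataclass
class StageVerdict:
    """Outcome of one cascade stage for one gene."""

    status: str  # "pass" | "fail" | "not-evaluated"
    detail: str = ""
    value: float | None = None


@dataclass
class CandidateReport:
    """Per-gene audit trail through the filter cascade."""

    gene: str
    record: IntermediateRecord
    deg_overlap: StageVerdict
    ambiguity: StageVerdict
    tissue: StageVerdict
    final_status: str  # "pass" | "fail"
    failing_stage: str | None


def run_cascade(
    intermediates: Sequence[IntermediateRecord],
    deg_union: Iterable[str],
    lexicon: AmbiguityLexicon,
    overrides: Mapping[str, str] | None,
    atlas: TissueAtlas,
    required_groups: Sequence[str],
    relative_floor: float = 0.5,
    absolute_floor: float = 0.0,
    deg_sets_by_dataset: Mapping[str, Iterable[str]] | None = None,
    missing_fails: bool = True,
) -> list[CandidateReport]:
    """Run DEG overlap -> ambiguity -> tissue over the discovery candidates.

    Stage order is fixed.  Output is sorted passes-first, then product
    score descending, then symbol; verdicts are invariant to input order.
    When *deg_sets_by_dataset* is given, each DEG-overlap pass records the
    contributing dataset ids.
    """
    if not required_groups:
        raise ValueError("required_groups must be non-empty")
    by_gene: dict[str, IntermediateRecord] = {}
    for rec in intermediates:
        sym = normalize_symbol(rec.gene_symbol)
        # duplicate symbols keep the higher-scoring record
        if sym not in by_gene or rec.product_score > by_gene[sym].product_score:
            by_gene[sym] = rec

    deg_union = {normalize_symbol(g) for g in deg_union}
    deg_sets = {
        ds: {normalize_symbol(g) for g in genes}
        for ds, genes in (deg_sets_by_dataset or {}).items()
    }

    survivors = overlap_cims_degs(by_gene, deg_union)
    amb_kept, amb_removed = ambiguity_filter(survivors, lexicon, overrides)
    amb_reason = dict(amb_removed)
    tis_kept, tis_removed = tissue_filter(
        amb_kept, atlas, required_groups, relative_floor, absolute_floor, missing_fails
    )
    tis_failgroup = dict(tis_removed)

    not_run = StageVerdict("not-evaluated")
    reports: list[CandidateReport] = []
    for gene, rec in by_gene.items():
        if gene not in survivors:
            deg_v = StageVerdict("fail", "not differentially expressed in any dataset")
            amb_v, tis_v = not_run, not_run
            failing = "deg_overlap"
        else:
            contributing = sorted(ds for ds, genes in deg_sets.items() if gene in genes)
            deg_v = StageVerdict("pass", ",".join(contributing))
            if gene not in amb_kept:
                amb_v = StageVerdict("fail", amb_reason[gene])
                tis_v = not_run
                failing = "ambiguity"
            else:
                amb_v = StageVerdict("pass")
                if gene in tis_kept:
                    tis_v = StageVerdict("pass")
                    failing = None
                else:
                    group = tis_failgroup[gene]
                    _, value = tissue_pass(
                        gene, atlas, group, relative_floor, absolute_floor, True
                    )
                    tis_v = StageVerdict("fail", f"low expression in {group}", value)
                    failing = "tissue"
        reports.append(
            CandidateReport(
                gene=gene,
                record=rec,
                deg_overlap=deg_v,
                ambiguity=amb_v,
                tissue=tis_v,
                final_status="pass" if failing is None else "fail",
                failing_stage=failing,
            )
        )
    reports.sort(
        key=lambda r: (r.final_status != "pass", -r.record.product_score, r.gene)
    )
    return reports


def stage_survivor_counts(reports: Sequence[CandidateReport]) -> dict[str, int]:
    """Survivor counts after each cascade stage (non-increasing)."""
    n_deg = sum(r.deg_overlap.status == "pass" for r in reports)
    n_amb = sum(r.ambiguity.status == "pass" for r in reports)
    n_tis = sum(r.final_status == "pass" for r in reports)
    return {
        "discovery": len(reports),
        "deg_overlap": n_deg,
        "ambiguity": n_amb,
        "tissue": n_tis,
    }
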