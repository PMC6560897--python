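"""Per-dataset differential expression calling on case/control matrices.

Each expression dataset is a probe x sample matrix with a case/control
label per sample and a platform annotation mapping probes to gene
symbols.  Probes are scored with a two-sample t-test (Welch by default,
pooled optional), adjusted with Benjamini-Hochberg, ranked by raw
p-value, truncated to the top N ranks, and mapped to normalized gene
symbols.  Gene sets from multiple datasets are pooled by union — the
study design pools gene lists, not statistics, so no meta-analysis is
performed here.

Values are tested as they arrive; log transformation is the caller's
responsibility (the synthetic generator emits log-scale values).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .filter_cascade import normalize_symbol

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "two_sample_t",
    "bh_adjust",
    "rank_probes",
    "select_top",
    "map_probes_to_genes",
    "call_degs",
    "union_deg_sets",
    "split_aliases",
]

#: alias separators seen in platform annotation "gene symbol" columns
ALIAS_SEPARATORS = ("///", ";", ",")

#: columns of the DEG table returned by :func:`rank_probes`
DEG_TABLE_COLUMNS = [
    "probe_id",
    "gene_symbols",
    "t_statistic",
    "degrees_of_freedom",
    "p_value",
    "adjusted_p",
    "rank",
]


@dataclass
class ExpressionDataset:
    """A case/control expression dataset with platform annotation.

    ``matrix`` is probes x samples (index = probe ids, columns = sample
    ids); ``sample_groups`` maps every sample to ``"case"`` or
    ``"control"``; ``platform`` maps probe id -> raw gene-symbol string
    (possibly alias-delimited, possibly empty).
    """

    dataset_id: str
    matrix: pd.DataFrame
    sample_groups: dict[str, str]
    platform: dict[str, str]

    def __post_init__(self) -> None:
        if self.matrix.index.has_duplicates:
            raise ValueError(f"{self.dataset_id}: duplicate probe ids")
        unlabelled = set(self.matrix.columns) - set(self.sample_groups)
        if unlabelled:
            raise ValueError(f"{self.dataset_id}: samples without group: {sorted(unlabelled)}")
        bad = {g for g in self.sample_groups.values()} - {"case", "control"}
        if bad:
            raise ValueError(f"{self.dataset_id}: invalid group labels {sorted(bad)}")
        if len(self.case_samples) < 2 or len(self.control_samples) < 2:
            raise ValueError(f"{self.dataset_id}: need >= 2 samples per group")

    @property
    def case_samples(self) -> list[str]:
        return [s for s in self.matrix.columns if self.sample_groups[s] == "case"]

    @property
    def control_samples(self) -> list[str]:
        return [s for s in self.matrix.columns if self.sample_groups[s] == "control"]


def _degenerate_t(case: np.ndarray, control: np.ndarray, variant: str) -> tuple[float, float, float]:
    """t for the zero-variance-in-both-groups corner: equal means -> (0, df, 1)."""
    n1, n2 = len(case), len(control)
    df = n1 + n2 - 2 if variant == "pooled" else float(n1 + n2 - 2)
    if math.isclose(case.mean(), control.mean()):
        return 0.0, float(df), 1.0
    sign = 1.0 if case.mean() > control.mean() else -1.0
    return sign * math.inf, float(df), 0.0


def two_sample_t(
    case_values: Sequence[float],
    control_values: Sequence[float],
    variant: str = "welch",
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test: returns (t, degrees of freedom, p).

    ``variant="pooled"`` assumes equal variances (df = n1 + n2 - 2);
    ``"welch"`` uses the Satterthwaite approximation.  Zero variance in
    both groups with equal means is a defined result (t=0, p=1), not an
    error.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size < 2 or control.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(case).all() and np.isfinite(control).all()):
        raise ValueError("expression values must be finite")
    if case.std(ddof=1) == 0.0 and control.std(ddof=1) == 0.0:
        return _degenerate_t(case, control, variant)
    res = stats.ttest_ind(case, control, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, aligned to input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rank_probes(dataset: ExpressionDataset, variant: str = "welch") -> pd.DataFrame:
    """Score every probe and return the ranked DEG table.

    One row per (finite-valued) probe, sorted by p ascending with ties
    broken by \\|t\\| descending then probe id ascending; ``rank`` is 1..n
    and ``adjusted_p`` is BH over all tested probes.  Probes with
    non-finite values are excluded with a warning, not fatal.
    """
    case = dataset.matrix[dataset.case_samples].to_numpy(dtype=float)
    control = dataset.matrix[dataset.control_samples].to_numpy(dtype=float)
    finite = np.isfinite(case).all(axis=1) & np.isfinite(control).all(axis=1)
    if not finite.all():
        dropped = dataset.matrix.index[~finite]
        logger.warning(
            "%s: excluding %d probes with non-finite values (e.g. %s)",
            dataset.dataset_id, len(dropped), dropped[0],
        )
    probes = dataset.matrix.index[finite]
    case, control = case[finite], control[finite]

    res = stats.ttest_ind(case, control, axis=1, equal_var=(variant == "pooled"))
    t = np.asarray(res.statistic, dtype=float)
    df = np.asarray(res.df, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups -> scipy yields nan; define the result
    degenerate = np.isnan(t)
    if degenerate.any():
        eq = np.isclose(case.mean(axis=1), control.mean(axis=1))
        t[degenerate & eq] = 0.0
        p[degenerate & eq] = 1.0
        up = degenerate & ~eq
        t[up] = np.sign(case.mean(axis=1) - control.mean(axis=1))[up] * np.inf
        p[up] = 0.0
        df[degenerate] = case.shape[1] + control.shape[1] - 2

    table = pd.DataFrame(
        {
            "probe_id": probes,
            "gene_symbols": [dataset.platform.get(pr, "") for pr in probes],
            "t_statistic": t,
            "degrees_of_freedom": df,
            "p_value": p,
            "adjusted_p": bh_adjust(p),
        }
    )
    table["abs_t"] = table["t_statistic"].abs()
    table = table.sort_values(
        ["p_value", "abs_t", "probe_id"], ascending=[True, False, True]
    ).drop(columns="abs_t")
    table["rank"] = np.arange(1, len(table) + 1)
    return table.reset_index(drop=True)[DEG_TABLE_COLUMNS]


def select_top(table: pd.DataFrame, n: int) -> set[str]:
    """Probe ids of the *n* best-ranked rows, keeping boundary p-value ties.

    If the p-value at the cut is shared by rows beyond it, all tied rows
    are included (the result may exceed *n*).  ``n`` larger than the
    table returns everything with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n >= len(table):
        if n > len(table):
            logger.warning("requested top %d of only %d probes", n, len(table))
        return set(table["probe_id"])
    cutoff = table["p_value"].iloc[n - 1]
    return set(table.loc[table["p_value"] <= cutoff, "probe_id"])


def split_aliases(raw: str) -> list[str]:
    """Split a platform gene-symbol field on the common alias separators."""
    parts = [raw]
    for sep in ALIAS_SEPARATORS:
        parts = [piece for chunk in parts for piece in chunk.split(sep)]
    return [p.strip() for p in parts if p.strip() and p.strip() not in ("-", "---")]


def map_probes_to_genes(
    probes: Iterable[str],
    platform: Mapping[str, str],
) -> set[str]:
    """Union of normalized gene symbols annotated on the given probes.

    Unannotated probes contribute nothing; probes absent from the
    platform map are skipped with a warning; multi-alias annotations
    contribute every alias.
    """
    genes: set[str] = set()
    for probe in probes:
        if probe not in platform:
            logger.warning("probe %s absent from platform annotation: skipped", probe)
            continue
        for alias in split_aliases(platform[probe]):
            genes.add(normalize_symbol(alias))
    return genes


def call_degs(
    dataset: ExpressionDataset,
    n_top: int = 250,
    variant: str = "welch",
) -> tuple[pd.DataFrame, set[str]]:
    """Rank probes, take the top *n_top*, and map them to gene symbols."""
    table = rank_probes(dataset, variant)
    top = select_top(table, n_top)
    genes = map_probes_to_genes(top, dataset.platform)
    logger.info(
        "%s: %d probes tested, %d selected, %d gene symbols",
        dataset.dataset_id, len(table), len(top), len(genes),
    )
    return table, genes


def union_deg_sets(per_dataset_sets: Iterable[Iterable[str]]) -> set[str]:
    """Pool per-dataset DEG gene sets by union after symbol normalization."""
    pooled: set[str] = set()
    for genes in per_dataset_sets:
        pooled.update(normalize_symbol(g) for g in genes)
    return pooled
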