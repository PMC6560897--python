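"""Shared fixtures: packaged reference tables, random corpora, oracles.

The random-corpus helper here is deliberately independent of the
package's own corpus generator so that discovery tests have a second,
trivially-auditable route to the same counts.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from lbd_bridge.concept_graph import AnnotatedDocument, Concept
from lbd_bridge.fixtures import load_reference_fixtures
from lbd_bridge.synthetic_data import generate_linked_scenario


@pytest.fixture(scope="session")
def ref():
    """The packaged reference tables (scores, DEG map, lexicon, atlas)."""
    return load_reference_fixtures()


@pytest.fixture(scope="session")
def linked_scenario():
    """A jointly planted corpus + expression + atlas with known truth."""
    return generate_linked_scenario(seed=3)


def make_random_corpus(seed, n_docs=60, n_genes=10, n_other=8, p_concept=0.12):
    """A random annotated corpus with an X, two Z's, genes and noise concepts.

    Documents include each concept independently, so co-occurrence
    structure is arbitrary; used only with brute-force oracles.
    """
    rng = np.random.default_rng(seed)
    concepts = [
        Concept("X", "Disease X", "Disease or Syndrome"),
        Concept("Z1", "Disorder Z1", "Mental or Behavioral Dysfunction"),
        Concept("Z2", "Disorder Z2", "Mental or Behavioral Dysfunction"),
    ]
    concepts += [Concept(f"G{i}", f"GENE{i}", "Gene or Gene Product") for i in range(n_genes)]
    concepts += [Concept(f"O{i}", f"Other {i}", "Finding") for i in range(n_other)]
    vocabulary = {c.concept_id: c for c in concepts}
    ids = list(vocabulary)
    docs = []
    for d in range(n_docs):
        mask = rng.random(len(ids)) < p_concept
        docs.append(AnnotatedDocument(f"D{d}", {c for c, m in zip(ids, mask) if m}))
    return docs, vocabulary


def brute_force_pair_counts(docs):
    """Oracle: enumerate every unordered concept pair per document."""
    counts = {}
    for doc in docs:
        for a, b in itertools.combinations(sorted(doc.concepts), 2):
            key = frozenset((a, b))
            counts[key] = counts.get(key, 0) + 1
    return counts


def brute_force_closed_discovery(docs, vocabulary, x, z_list, y_type, mode, min_freq):
    """Oracle: exhaustive X-Y-Z triple enumeration over the vocabulary.

    Returns {y: (freq_xy, freq_yz_combined)} for every qualifying
    intermediate, counting documents directly.
    """

    def ndocs_with(*cids):
        return sum(1 for doc in docs if all(c in doc.concepts for c in cids))

    out = {}
    for y, concept in vocabulary.items():
        if concept.semantic_type != y_type or y == x or y in z_list:
            continue
        fxy = ndocs_with(x, y)
        if fxy < min_freq:
            continue
        per_z = {z: ndocs_with(y, z) for z in z_list}
        qualifying = [z for z in z_list if per_z[z] >= min_freq]
        hit = bool(qualifying) if mode == "union" else len(qualifying) == len(z_list)
        if not hit:
            continue
        fyz = sum(f for f in per_z.values() if f > 0)
        if fyz >= 1:
            out[y] = (fxy, fyz)
    return out


def bh_step_up_oracle(p):
    """Oracle: literal BH step-up, adj_(i) = min_{j>=i} p_(j) * n / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        adjusted[idx] = min(running, 1.0)
    return adjusted
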