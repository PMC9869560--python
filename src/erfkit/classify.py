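"""Subfamily and subgroup assignment for AP2/ERF genes.

The decision ladder mirrors the classical family rules:

1. an AP2 domain together with a B3 domain -> RAV;
2. two or more AP2 domains -> AP2 when any domain carries a long internal
   insertion (nominally 10 residues), otherwise ANT;
3. a single AP2 domain -> ERF when the two diagnostic columns (default 14
   and 19) read Ala/Asp, DREB when they read Val/Glu, otherwise the nearest
   bundled profile among ERF/DREB/Soloist (unalignable domains go to
   Soloist).

Subgroups: ERF genes map to B1-B4 by the residues at model columns 49/56
(F/L, L/T, F/T, M/L), falling back to the nearest B profile; DREB genes map
to A1-A4 by nearest profile (the literature gives no residue key for the A
subgroups); the remaining subfamilies map to the identically named
subgroup.  A neighbor-joining coherence check stands in for full
maximum-likelihood phylogenetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import ModelAlignment, align_to_model
from .domains import Architecture
from .profiles import (
    AP2_MODEL_WIDTH,
    SUBFAMILY_CONSENSUS,
    SUBGROUP_CONSENSUS,
)


class NotFamilyError(ValueError):
    """The gene has no retained AP2 domain: not an AP2/ERF gene."""


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable rules of the classifier.

    ``d1``/``d2`` are the 1-based diagnostic columns within the aligned AP2
    domain.  The published descriptions disagree on whether these are
    columns 14/19 or 15/20; both readings are supported through this
    config, with 14/19 (the original rule) as the default.  The insertion
    threshold is set slightly below the nominal 10 residues to tolerate
    alignment slop.
    """

    d1: int = 14
    d2: int = 19
    erf_pattern: tuple[str, str] = ("A", "D")
    dreb_pattern: tuple[str, str] = ("V", "E")
    insertion_threshold: int = 8
    key_columns: tuple[int, int] = (49, 56)
    subgroup_key: Mapping[str, tuple[str, str]] = field(
        default_factory=lambda: {"B1": ("F", "L"), "B2": ("L", "T"),
                                 "B3": ("F", "T"), "B4": ("M", "L")})
    score_floor: float = 0.0

    def validate(self) -> None:
        if not 1 <= self.d1 < self.d2 <= AP2_MODEL_WIDTH:
            raise ValueError("need 1 <= d1 < d2 <= model width")
        pairs = list(self.subgroup_key.values())
        if len(set(pairs)) != len(pairs):
            raise ValueError("subgroup key pairs must be pairwise distinct")


@dataclass
class FamilyCall:
    """Classification of one gene with the evidence that produced it."""

    gene: str
    subfamily: str
    subgroup: str | None = None
    evidence: dict = field(default_factory=dict)


_A_SUBGROUPS = ("A1", "A2", "A3", "A4")
_B_SUBGROUPS = ("B1", "B2", "B3", "B4")


def _nearest(aligned: ModelAlignment, profiles: Mapping[str, str]) -> tuple[str, dict[str, int]]:
    distances = {name: aligned.distance_to(consensus)
                 for name, consensus in profiles.items()}
    best = min(profiles, key=lambda name: (distances[name],
                                           list(profiles).index(name)))
    return best, distances


def classify_subfamily(arch: Architecture,
                       aligned_domains: Sequence[ModelAlignment],
                       config: ClassifierConfig | None = None) -> FamilyCall:
    """Assign one of the six subfamilies from architecture plus residues.

    ``aligned_domains`` holds one :class:`ModelAlignment` per retained AP2
    hit, in hit order.
    """
    config = config or ClassifierConfig()
    config.validate()
    if not arch.is_family:
        raise NotFamilyError(f"{arch.gene or '<gene>'}: no retained domains")
    evidence: dict = {"n_ap2": arch.n_ap2, "has_b3": arch.has_b3}
    if arch.n_ap2 == 0:
        # B3 without any AP2 domain does not qualify for the family.
        raise NotFamilyError(f"{arch.gene}: B3 domain without an AP2 domain")
    if len(aligned_domains) != arch.n_ap2:
        raise ValueError("one model alignment required per retained AP2 hit")

    if arch.has_b3:
        return FamilyCall(arch.gene, "RAV", evidence=evidence)

    if arch.n_ap2 >= 2:
        insertion = max(a.max_internal_insertion for a in aligned_domains)
        evidence["insertion_len"] = insertion
        subfamily = "AP2" if insertion >= config.insertion_threshold else "ANT"
        return FamilyCall(arch.gene, subfamily, evidence=evidence)

    aligned = aligned_domains[0]
    evidence["insertion_len"] = aligned.max_internal_insertion
    if aligned.unalignable:
        evidence["unalignable"] = True
        return FamilyCall(arch.gene, "Soloist", evidence=evidence)
    r1, r2 = aligned.residue(config.d1), aligned.residue(config.d2)
    evidence["residues_d1_d2"] = (r1, r2)
    ambiguous = "X" in (r1, r2)
    if not ambiguous and (r1, r2) == tuple(config.erf_pattern):
        return FamilyCall(arch.gene, "ERF", evidence=evidence)
    if not ambiguous and (r1, r2) == tuple(config.dreb_pattern):
        return FamilyCall(arch.gene, "DREB", evidence=evidence)
    best, distances = _nearest(aligned, SUBFAMILY_CONSENSUS)
    evidence["profile_distances"] = distances
    return FamilyCall(arch.gene, best, evidence=evidence)


def assign_subgroup(call: FamilyCall, aligned: ModelAlignment,
                    config: ClassifierConfig | None = None) -> FamilyCall:
    """Refine a subfamily call to one of the twelve subgroups."""
    config = config or ClassifierConfig()
    if call.subfamily in ("AP2", "ANT", "RAV", "Soloist"):
        call.subgroup = call.subfamily
        return call
    c1, c2 = config.key_columns
    r49, r56 = aligned.residue(c1), aligned.residue(c2)
    call.evidence["residues_key"] = (r49, r56)
    if call.subfamily == "ERF":
        for name, pair in config.subgroup_key.items():
            if (r49, r56) == tuple(pair):
                call.subgroup = name
                return call
        profiles = {n: SUBGROUP_CONSENSUS[n] for n in _B_SUBGROUPS}
    elif call.subfamily == "DREB":
        profiles = {n: SUBGROUP_CONSENSUS[n] for n in _A_SUBGROUPS}
    else:  # pragma: no cover - exhaustive over subfamilies
        raise ValueError(f"unknown subfamily {call.subfamily!r}")
    best, distances = _nearest(aligned, profiles)
    call.evidence["subgroup_distances"] = distances
    call.subgroup = best
    return call


def classify_gene(arch: Architecture, protein: str,
                  config: ClassifierConfig | None = None) -> FamilyCall:
    """Full classification of one gene from its architecture and sequence."""
    config = config or ClassifierConfig()
    aligned = [align_to_model(protein[h.start - 1:h.end],
                              score_floor=config.score_floor)
               for h in arch.hits if h.kind == "AP2"]
    call = classify_subfamily(arch, aligned, config)
    return assign_subgroup(call, aligned[0], config)


def calls_to_frame(calls: Sequence[FamilyCall]) -> pd.DataFrame:
    """Serialize calls as a flat table (one row per gene)."""
    rows = []
    for call in calls:
        ev = call.evidence
        d1d2 = ev.get("residues_d1_d2", ("", ""))
        key = ev.get("residues_key", ("", ""))
        rows.append({
            "gene": call.gene,
            "subfamily": call.subfamily,
            "subgroup": call.subgroup,
            "residue_d1": d1d2[0],
            "residue_d2": d1d2[1],
            "residue_49": key[0],
            "residue_56": key[1],
            "insertion_len": ev.get("insertion_len", 0),
            "n_ap2": ev.get("n_ap2", 0),
            "has_b3": ev.get("has_b3", False),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Neighbor joining + subgroup coherence
# ---------------------------------------------------------------------------

def p_distance_matrix(sequences: Sequence[str]) -> np.ndarray:
    """Pairwise p-distances over columns where both sequences have residues."""
    n = len(sequences)
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("sequences must share one aligned length")
    arr = np.array([list(s) for s in sequences])
    gaps = arr == "-"
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = ~(gaps[i] | gaps[j])
            total = int(valid.sum())
            if total == 0:
                d = 0.0
            else:
                d = float((arr[i][valid] != arr[j][valid]).sum()) / total
            D[i, j] = D[j, i] = d
    return D


def neighbor_joining(D: np.ndarray, ids: Sequence[str]
                     ) -> tuple[str, dict[int, list[tuple[int, float]]], dict[int, str]]:
    """Canonical neighbor joining (Saitou-Nei Q criterion).

    Ties in Q are broken by the lowest (i, j) node-index pair.  Returns the
    newick string plus the adjacency map and leaf labels used to compute
    path lengths.
    """
    n = len(ids)
    if len(set(ids)) != n:
        raise ValueError("duplicate sequence ids")
    if n < 2:
        raise ValueError("need at least 2 taxa")
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D[i, j])

    def d(i: int, j: int) -> float:
        if i == j:
            return 0.0
        return dist[(min(i, j), max(i, j))]

    active = list(range(n))
    adjacency: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n)}
    children: dict[int, list[tuple[int, float]]] = {}
    next_node = n
    while len(active) > 2:
        m = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        best_q = np.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d(i, j) - r[i] - r[j]
                pair = (min(i, j), max(i, j))
                if q < best_q - 1e-12 or (abs(q - best_q) <= 1e-12
                                          and (best is None or pair < best)):
                    best_q = q
                    best = pair
        i, j = best
        vi = d(i, j) / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = d(i, j) - vi
        u = next_node
        next_node += 1
        adjacency[u] = []
        for child, length in ((i, vi), (j, vj)):
            adjacency[u].append((child, length))
            adjacency[child].append((u, length))
        children[u] = [(i, vi), (j, vj)]
        for k in active:
            if k in (i, j):
                continue
            new_d = (d(i, k) + d(j, k) - d(i, j)) / 2.0
            dist[(min(u, k), max(u, k))] = new_d
        active = [k for k in active if k not in (i, j)] + [u]
    a, b = active
    final = d(a, b)
    adjacency[a].append((b, final))
    adjacency[b].append((a, final))

    labels = {i: ids[i] for i in range(n)}
    root = max(adjacency)  # arbitrary rooting at the last join
    tree = newick_string(adjacency, labels, root)
    return tree, adjacency, labels


def newick_string(adjacency: Mapping[int, list[tuple[int, float]]],
                  labels: Mapping[int, str], root: int) -> str:
    def rec(node: int, parent: int | None) -> str:
        neighbors = [(c, l) for c, l in adjacency[node] if c != parent]
        if not neighbors:
            return labels[node]
        inner = ",".join(f"{rec(c, node)}:{l:.6f}" for c, l in neighbors)
        return f"({inner})"

    return rec(root, None) + ";"


def _leaf_path_lengths(adjacency: Mapping[int, list[tuple[int, float]]],
                       n_leaves: int) -> np.ndarray:
    """Leaf-to-leaf path lengths over the unrooted NJ tree."""
    out = np.zeros((n_leaves, n_leaves))
    for start in range(n_leaves):
        seen = {start: 0.0}
        stack = [start]
        while stack:
            node = stack.pop()
            for child, length in adjacency[node]:
                if child not in seen:
                    seen[child] = seen[node] + length
                    stack.append(child)
        for leaf in range(n_leaves):
            out[start, leaf] = seen[leaf]
    return out


def nj_tree(sequences: Mapping[str, str], labels: Mapping[str, str]
            ) -> tuple[str, float]:
    """NJ tree over aligned domains plus a subgroup coherence score.

    Coherence is the fraction of leaves whose nearest leaf (by tree path
    length; ties resolved to the lowest input index) shares their subgroup
    label.
    """
    ids = list(sequences)
    if len(ids) < 4:
        raise ValueError("need at least 4 sequences")
    D = p_distance_matrix([sequences[i] for i in ids])
    tree, adjacency, _ = neighbor_joining(D, ids)
    paths = _leaf_path_lengths(adjacency, len(ids))
    agree = 0
    for i in range(len(ids)):
        candidates = [j for j in range(len(ids)) if j != i]
        nearest = min(candidates, key=lambda j: (paths[i, j], j))
        if labels[ids[i]] == labels[ids[nearest]]:
            agree += 1
    return tree, agree / len(ids)
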