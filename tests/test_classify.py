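"""Classifier ladder, model alignment (vs a DP oracle), and NJ coherence."""

import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from erfkit.align import align_to_model, global_score
from erfkit.classify import (ClassifierConfig, NotFamilyError, assign_subgroup,
                             classify_gene, classify_subfamily,
                             neighbor_joining, nj_tree, p_distance_matrix)
from erfkit.domains import DomainHit, Architecture, filter_hits
from erfkit.profiles import (AP2_MODEL_CONSENSUS, AP2_SUBFAMILY_INSERTION,
                             SUBGROUP_CONSENSUS)

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _gotoh_score(a: str, b: str, open_cost=10.0, extend_cost=1.0) -> float:
    """Independent affine-gap global alignment score (Gotoh DP).

    Gap of length L costs open + (L-1)*extend, matching the package's
    scoring convention.
    """
    n, m = len(a), len(b)
    neg = -1e9
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), neg)  # gap in a (consumes b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -open_cost - (i - 1) * extend_cost
    for j in range(1, m + 1):
        Y[0, j] = -open_cost - (j - 1) * extend_cost
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1],
                          Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - open_cost, X[i - 1, j] - extend_cost,
                          Y[i - 1, j] - open_cost)
            Y[i, j] = max(M[i, j - 1] - open_cost, Y[i, j - 1] - extend_cost,
                          X[i, j - 1] - open_cost)
    return float(max(M[n, m], X[n, m], Y[n, m]))


class TestAlignToModel:
    def test_consensus_aligns_to_identity(self):
        al = align_to_model(AP2_MODEL_CONSENSUS)
        assert al.model_residues == AP2_MODEL_CONSENSUS
        assert al.insertions == ()

    def test_ten_residue_insertion_reported_as_one_run(self):
        seq = (AP2_MODEL_CONSENSUS[:20] + AP2_SUBFAMILY_INSERTION
               + AP2_MODEL_CONSENSUS[20:])
        al = align_to_model(seq)
        assert al.insertions == ((20, 10),)
        assert al.max_internal_insertion == 10

    def test_three_mismatches_no_insertions(self):
        m = AP2_MODEL_CONSENSUS
        seq = m[:10] + "W" + m[11:30] + "W" + m[31:50] + "W" + m[51:]
        al = align_to_model(seq)
        mismatches = sum(1 for x, y in zip(al.model_residues, m) if x != y)
        assert mismatches == 3
        assert al.insertions == ()

    def test_scores_match_independent_dp_oracle(self):
        rng = np.random.default_rng(0)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(25):
            a = "".join(rng.choice(list(aas), size=rng.integers(4, 12)))
            b = "".join(rng.choice(list(aas), size=rng.integers(4, 12)))
            assert global_score(a, b) == pytest.approx(_gotoh_score(a, b))


def _arch(gene, *spans):
    return filter_hits([DomainHit(gene, kind, s, e, evalue=1e-20)
                        for kind, s, e in spans])


def _aligned(seq):
    return align_to_model(seq)


class TestSubfamilyLadder:
    def test_erf_and_dreb_diagnostics(self):
        for sub, expected in (("B1", "ERF"), ("A1", "DREB")):
            arch = _arch("g", ("AP2", 1, 57))
            call = classify_subfamily(arch,
                                      [_aligned(SUBGROUP_CONSENSUS[sub])])
            assert call.subfamily == expected

    def test_b3_plus_ap2_is_rav(self):
        arch = _arch("g", ("AP2", 1, 57), ("B3", 70, 119))
        call = classify_subfamily(arch,
                                  [_aligned(SUBGROUP_CONSENSUS["RAV"])])
        assert call.subfamily == "RAV"

    def test_two_domains_with_insertion_is_ap2_without_is_ant(self):
        with_ins = (SUBGROUP_CONSENSUS["AP2"][:20] + AP2_SUBFAMILY_INSERTION
                    + SUBGROUP_CONSENSUS["AP2"][20:])
        arch = _arch("g", ("AP2", 1, 67), ("AP2", 70, 126))
        call = classify_subfamily(
            arch, [_aligned(with_ins), _aligned(SUBGROUP_CONSENSUS["AP2"])])
        assert call.subfamily == "AP2"
        arch2 = _arch("g", ("AP2", 1, 57), ("AP2", 70, 126))
        call2 = classify_subfamily(
            arch2, [_aligned(SUBGROUP_CONSENSUS["ANT"])] * 2)
        assert call2.subfamily == "ANT"

    def test_soloist_profile_routes_to_soloist(self):
        arch = _arch("g", ("AP2", 1, 57))
        call = classify_subfamily(arch,
                                  [_aligned(SUBGROUP_CONSENSUS["Soloist"])])
        assert call.subfamily == "Soloist"

    def test_ambiguous_diagnostic_residue_uses_nearest_profile(self):
        seq = list(SUBGROUP_CONSENSUS["B1"])
        seq[13] = "X"  # diagnostic column 14 unreadable
        call = classify_subfamily(_arch("g", ("AP2", 1, 57)),
                                  [_aligned("".join(seq))])
        assert call.subfamily == "ERF"
        assert "profile_distances" in call.evidence

    def test_no_retained_domains_raises(self):
        with pytest.raises(NotFamilyError):
            classify_subfamily(Architecture(gene="g", hits=()), [])

    def test_b3_only_is_not_family(self):
        arch = _arch("g", ("B3", 1, 50))
        with pytest.raises(NotFamilyError):
            classify_subfamily(arch, [])


class TestSubgroups:
    @pytest.mark.parametrize("sub", ["B1", "B2", "B3", "B4"])
    def test_erf_key_columns_pick_subgroup(self, sub):
        arch = _arch("g", ("AP2", 1, 57))
        aligned = _aligned(SUBGROUP_CONSENSUS[sub])
        call = classify_subfamily(arch, [aligned])
        call = assign_subgroup(call, aligned)
        assert call.subgroup == sub

    @pytest.mark.parametrize("sub", ["A1", "A2", "A3", "A4"])
    def test_dreb_nearest_profile_recovers_subgroup(self, sub):
        arch = _arch("g", ("AP2", 1, 57))
        aligned = _aligned(SUBGROUP_CONSENSUS[sub])
        call = classify_subfamily(arch, [aligned])
        call = assign_subgroup(call, aligned)
        assert call.subgroup == sub

    def test_single_subfamilies_map_to_same_named_subgroup(self):
        arch = _arch("g", ("AP2", 1, 57), ("B3", 70, 119))
        aligned = _aligned(SUBGROUP_CONSENSUS["RAV"])
        call = assign_subgroup(classify_subfamily(arch, [aligned]), aligned)
        assert call.subgroup == "RAV"


class TestTruthRecovery:
    def test_all_planted_labels_recovered(self, small_dataset,
                                          small_architectures):
        truth = small_dataset.truth
        for sp in truth.config.species_names:
            fam = truth.family_genes(sp).set_index("gene")
            for gene, row in fam.iterrows():
                call = classify_gene(small_architectures[sp][gene],
                                     small_dataset.sequences[sp][gene])
                assert call.subfamily == row["subfamily"]
                assert call.subgroup == row["subgroup"]

    def test_one_off_diagnostic_substitution_keeps_subfamily(self,
                                                             small_dataset,
                                                             small_architectures):
        """One residue substitution outside the diagnostic columns must not
        change the subfamily call."""
        rng = np.random.default_rng(42)
        truth = small_dataset.truth
        planted = truth.domains.set_index("gene")
        fam = truth.family_genes("ca").set_index("gene")
        protected = {13, 18, 48, 55}
        for gene, row in fam.iterrows():
            seq = list(small_dataset.sequences["ca"][gene])
            hit = planted.loc[[gene]].iloc[0]
            width = int(hit["end"]) - int(hit["start"]) + 1
            while True:
                offset = int(rng.integers(width))
                if offset not in protected:
                    break
            pos = int(hit["start"]) - 1 + offset
            current = seq[pos]
            seq[pos] = "W" if current != "W" else "F"
            call = classify_gene(small_architectures["ca"][gene],
                                 "".join(seq))
            assert call.subfamily == row["subfamily"], gene


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def _random_additive_instance(rng, n_taxa):
    """Random unrooted binary tree with positive lengths -> distance matrix."""
    # star-decomposition construction: start with 3 taxa, attach the rest
    # to random edges.  Edges as dict id -> (node_a, node_b, length).
    nodes = [f"t{i}" for i in range(n_taxa)]
    adjacency = {}

    def add_edge(a, b, w):
        adjacency.setdefault(a, []).append((b, w))
        adjacency.setdefault(b, []).append((a, w))

    internal = ["x0"]
    for t in nodes[:3]:
        add_edge(t, "x0", float(rng.uniform(0.5, 3.0)))
    for k, t in enumerate(nodes[3:], start=1):
        # pick an existing edge, split it with a new internal node
        edges = [(a, b, w) for a in adjacency for b, w in adjacency[a]
                 if a < b]
        a, b, w = edges[rng.integers(len(edges))]
        adjacency[a] = [(c, x) for c, x in adjacency[a] if c != b or x != w]
        adjacency[b] = [(c, x) for c, x in adjacency[b] if c != a or x != w]
        new = f"x{k}"
        internal.append(new)
        split = float(rng.uniform(0.2, 0.8)) * w
        add_edge(a, new, split)
        add_edge(b, new, w - split)
        add_edge(t, new, float(rng.uniform(0.5, 3.0)))
    D = np.zeros((n_taxa, n_taxa))
    for i, src in enumerate(nodes):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            cur = stack.pop()
            for nxt, w in adjacency[cur]:
                if nxt not in seen:
                    seen[nxt] = seen[cur] + w
                    stack.append(nxt)
        for j, dst in enumerate(nodes):
            D[i, j] = seen[dst]
    splits = _tree_splits(adjacency, set(nodes))
    return D, nodes, splits


def _canonical_split(side, leaves):
    """Represent a bipartition by its lexicographically smaller side."""
    side = frozenset(side)
    other = frozenset(leaves) - side
    return min(side, other, key=lambda s: tuple(sorted(s)))


def _tree_splits(adjacency, leaves):
    """Non-trivial bipartitions induced by internal edges."""
    splits = set()
    for a in adjacency:
        for b, _ in adjacency[a]:
            if a >= b:
                continue
            # leaves on a's side when edge (a, b) is removed
            side = set()
            stack = [a]
            seen = {a, b}
            while stack:
                cur = stack.pop()
                if cur in leaves:
                    side.add(cur)
                for nxt, _ in adjacency[cur]:
                    if nxt not in seen:
                        seen.add(nxt)
                        stack.append(nxt)
            if 1 < len(side) < len(leaves) - 1:
                splits.add(_canonical_split(side, leaves))
    return splits


def _nj_splits(newick, leaves):
    import re
    # parse newick into an adjacency over anonymous internal nodes
    tokens = re.findall(r"\(|\)|,|[^(),:;]+(?::[0-9.eE+-]+)?", newick)
    counter = itertools.count()
    adjacency = {}

    def add_edge(a, b):
        adjacency.setdefault(a, []).append((b, 1.0))
        adjacency.setdefault(b, []).append((a, 1.0))

    stack = []
    root = f"i{next(counter)}"
    current = root
    for tok in tokens:
        if tok == "(":
            new = f"i{next(counter)}"
            add_edge(current, new)
            stack.append(current)
            current = new
        elif tok == ")":
            current = stack.pop()
        elif tok == ",":
            pass
        else:
            name = tok.split(":")[0]
            if name:
                add_edge(current, name)
    return _tree_splits(adjacency, set(leaves))


def _minimum_evolution_splits(D, ids):
    """Brute force: OLS-fit tree length over all unrooted topologies."""
    n = len(ids)
    best = None
    for splits, paths in _all_topologies(n):
        lengths, *_ = np.linalg.lstsq(paths, _condensed(D), rcond=None)
        total = float(lengths.sum())
        err = float(((paths @ lengths - _condensed(D)) ** 2).sum())
        key = (round(err, 8), round(total, 8))
        if best is None or key < best[0]:
            best = (key, splits)
    return {_canonical_split((ids[i] for i in side), ids)
            for side in best[1]}


def _condensed(D):
    n = D.shape[0]
    return np.array([D[i, j] for i in range(n) for j in range(i + 1, n)])


def _all_topologies(n):
    """Enumerate unrooted binary topologies for n in {4, 5} as
    (splits, pair x edge path-incidence matrix)."""
    assert n in (4, 5)
    out = []
    if n == 4:
        for a, b in [(0, 1), (0, 2), (0, 3)]:
            edges = [frozenset((i,)) for i in range(4)] + [frozenset((a, b))]
            out.append(([frozenset((a, b))], _paths_from_edges(n, edges)))
    else:
        # every unrooted binary 5-taxon tree is a caterpillar with two
        # disjoint cherries; 15 topologies in total
        seen = set()
        for first in itertools.combinations(range(5), 2):
            rest = [x for x in range(5) if x not in first]
            for second in itertools.combinations(rest, 2):
                key = frozenset((frozenset(first), frozenset(second)))
                if key in seen:
                    continue
                seen.add(key)
                edges = [frozenset((i,)) for i in range(5)] + \
                        [frozenset(first), frozenset(second)]
                out.append(([frozenset(first), frozenset(second)],
                            _paths_from_edges(5, edges)))
        assert len(out) == 15
    return out


def _paths_from_edges(n, edges):
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            rows.append([1.0 if (i in side) != (j in side) else 0.0
                         for side in edges])
    return np.array(rows)


class TestNeighborJoining:
    def test_recovers_additive_quartets_and_quintets(self):
        rng = np.random.default_rng(1)
        for n_taxa in (4, 5):
            for _ in range(20):
                D, ids, true_splits = _random_additive_instance(rng, n_taxa)
                newick, adjacency, labels = neighbor_joining(D, ids)
                got = _nj_splits(newick, ids)
                assert got == true_splits

    def test_nj_matches_minimum_evolution_on_additive_instances(self):
        rng = np.random.default_rng(2)
        for n_taxa in (4, 5):
            for _ in range(10):
                D, ids, true_splits = _random_additive_instance(rng, n_taxa)
                newick, *_ = neighbor_joining(D, ids)
                me = _minimum_evolution_splits(
                    D, ids)
                me = {s for s in me if 1 < len(s) < n_taxa - 1}
                assert _nj_splits(newick, ids) == me

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(np.zeros((2, 2)), ["a", "a"])

    def test_identical_sequences_star_tree_full_coherence(self):
        seqs = {f"s{i}": "ACDEFGHIK" for i in range(5)}
        labels = {k: "B2" for k in seqs}
        _, coherence = nj_tree(seqs, labels)
        assert coherence == 1.0

    def test_two_separated_subgroups_fully_coherent(self):
        a = SUBGROUP_CONSENSUS["B1"]
        b = SUBGROUP_CONSENSUS["Soloist"]
        seqs = {}
        labels = {}
        for i in range(10):
            sa = a[:i] + a[i] + a[i + 1:]  # identical copies are fine
            seqs[f"a{i}"] = a
            labels[f"a{i}"] = "B1"
            seqs[f"b{i}"] = b
            labels[f"b{i}"] = "Soloist"
        _, coherence = nj_tree(seqs, labels)
        assert coherence == 1.0

    def test_p_distance_ignores_gap_columns(self):
        D = p_distance_matrix(["AC-T", "ACG-", "TCGT"])
        assert D[0, 1] == 0.0  # only columns 1-2 comparable, both equal
        assert D[0, 2] == pytest.approx(1.0 / 3.0)
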