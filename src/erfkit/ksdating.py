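"""Synonymous substitution rates (Ks) for duplicate gene pairs.

Implements the Nei-Gojobori (1986) counting method: per-codon synonymous
site fractions from single-nucleotide neighbor enumeration, difference
counting averaged over all minimal mutation paths (paths through stop
codons excluded), and the Jukes-Cantor correction
Ks = -(3/4) ln(1 - (4/3) pS).  Duplication recency is classified against
the speciation thresholds of the pepper/tomato/potato comparison
(pepper-*Solanum* split at Ks 0.3, tomato-potato split at Ks 0.1) and
pairs with Ks >= 3 are flagged as saturated/not retained.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .align import global_alignment, global_score
from .comparative import GeneLocus, rbh_orthologs

_BASES = "ACGT"
_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)
_AA = dict(_TABLE.forward_table)


def _translate(codon: str) -> str | None:
    """Amino acid for a sense codon, None for a stop codon."""
    return _AA.get(codon)


def codon_synonymous_sites(codon: str) -> float:
    """NG86 synonymous site count of one sense codon.

    Each position contributes the fraction of its single-nucleotide changes
    that are synonymous; changes creating stop codons are excluded from
    both numerator and denominator.
    """
    if codon in _STOPS:
        raise ValueError(f"stop codon {codon}")
    aa = _translate(codon)
    total = 0.0
    for pos in range(3):
        syn = valid = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            neighbor = codon[:pos] + base + codon[pos + 1:]
            if neighbor in _STOPS:
                continue
            valid += 1
            if _translate(neighbor) == aa:
                syn += 1
        if valid:
            total += syn / valid
    return total


_SITES_CACHE = {c: codon_synonymous_sites(c)
                for c in map("".join, itertools.product(_BASES, repeat=3))
                if c not in _STOPS}


def _path_differences(codon1: str, codon2: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous differences averaged over mutation paths.

    All orderings of the differing positions are enumerated with equal
    weight; paths passing through a stop codon are dropped (if every path
    does, all paths are kept with stop steps counted as nonsynonymous).
    """
    diff_positions = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff_positions:
        return 0.0, 0.0
    path_results = []
    fallback = []
    for order in itertools.permutations(diff_positions):
        current = codon1
        syn = non = 0.0
        valid = True
        for pos in order:
            nxt = current[:pos] + codon2[pos] + current[pos + 1:]
            if nxt in _STOPS:
                valid = False
                non += 1.0
            elif current in _STOPS:
                non += 1.0
            elif _translate(current) == _translate(nxt):
                syn += 1.0
            else:
                non += 1.0
            current = nxt
        (path_results if valid else fallback).append((syn, non))
    chosen = path_results or fallback
    s = sum(p[0] for p in chosen) / len(chosen)
    n = sum(p[1] for p in chosen) / len(chosen)
    return s, n


@dataclass(frozen=True)
class KsEstimate:
    """NG86 estimate for one pair of aligned coding sequences."""

    gene1: str
    gene2: str
    n_codons: int
    s_sites: float
    n_sites: float
    syn_diff: float
    nonsyn_diff: float

    @property
    def ps(self) -> float:
        return self.syn_diff / self.s_sites if self.s_sites > 0 else 0.0

    @property
    def pn(self) -> float:
        return self.nonsyn_diff / self.n_sites if self.n_sites > 0 else 0.0

    @property
    def ks(self) -> float | None:
        """Jukes-Cantor-corrected synonymous rate; None when saturated."""
        return _jukes_cantor(self.ps)

    @property
    def ka(self) -> float | None:
        return _jukes_cantor(self.pn)


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def codon_align(cds1: str, cds2: str, name1: str = "seq1",
                name2: str = "seq2") -> list[tuple[str, str]]:
    """Thread two coding sequences through their protein alignment.

    Both CDS must translate cleanly (length divisible by 3, no internal
    stop).  Columns containing an alignment gap or an ambiguous base are
    dropped.
    """
    codon_lists = []
    for name, cds in ((name1, cds1), (name2, cds2)):
        cds = cds.upper().rstrip()
        if len(cds) % 3 != 0:
            raise ValueError(f"{name}: CDS length {len(cds)} not divisible by 3")
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        if codons and codons[-1] in _STOPS:
            codons = codons[:-1]
        for i, codon in enumerate(codons):
            if codon in _STOPS:
                raise ValueError(f"{name}: internal stop codon at codon {i + 1}")
        codon_lists.append(codons)
    prot1 = str(Seq("".join(codon_lists[0])).translate())
    prot2 = str(Seq("".join(codon_lists[1])).translate())
    row1, row2, _ = global_alignment(prot1, prot2)
    paired = []
    i = j = 0
    for a, b in zip(row1, row2):
        if a != "-" and b != "-":
            c1, c2 = codon_lists[0][i], codon_lists[1][j]
            if all(base in _BASES for base in c1 + c2):
                paired.append((c1, c2))
        if a != "-":
            i += 1
        if b != "-":
            j += 1
    return paired


def ng86(paired_codons: Sequence[tuple[str, str]], gene1: str = "seq1",
         gene2: str = "seq2", min_codons: int = 30) -> KsEstimate:
    """NG86 site and difference counts over paired codon columns."""
    if len(paired_codons) < min_codons:
        raise ValueError(f"need >= {min_codons} paired codons, "
                         f"got {len(paired_codons)}")
    s1 = sum(_SITES_CACHE[c1] for c1, _ in paired_codons)
    s2 = sum(_SITES_CACHE[c2] for _, c2 in paired_codons)
    s_sites = (s1 + s2) / 2.0
    n_sites = 3.0 * len(paired_codons) - s_sites
    syn = non = 0.0
    for c1, c2 in paired_codons:
        ds, dn = _path_differences(c1, c2)
        syn += ds
        non += dn
    return KsEstimate(gene1=gene1, gene2=gene2, n_codons=len(paired_codons),
                      s_sites=s_sites, n_sites=n_sites, syn_diff=syn,
                      nonsyn_diff=non)


def ng86_ks(cds1: str, cds2: str, gene1: str = "seq1", gene2: str = "seq2",
            min_codons: int = 30) -> KsEstimate:
    """Convenience wrapper: codon-align two CDS and run NG86."""
    paired = codon_align(cds1, cds2, gene1, gene2)
    return ng86(paired, gene1, gene2, min_codons=min_codons)


@dataclass(frozen=True)
class RecencyCall:
    """Recency classification of one duplicate pair."""

    recency: str  # post_tomato_potato_split | post_pepper_split | older
    retained: bool
    headline: bool  # recent under the species' own speciation threshold


def classify_recency(ks: float, species: str | None = None,
                     thresholds: tuple[float, float] = (0.3, 0.1),
                     retention: float = 3.0) -> RecencyCall:
    """Bin a Ks value against the speciation thresholds (strict '<').

    ``thresholds`` is (pepper-*Solanum* split, tomato-potato split).  The
    headline flag marks pairs recent relative to the threshold relevant to
    ``species`` ('ca' uses the first threshold, 'sl'/'st' the second; other
    labels use the first).
    """
    pepper_split, solanum_split = thresholds
    if ks < solanum_split:
        recency = "post_tomato_potato_split"
    elif ks < pepper_split:
        recency = "post_pepper_split"
    else:
        recency = "older"
    own = solanum_split if species in ("sl", "st") else pepper_split
    return RecencyCall(recency=recency, retained=ks < retention,
                       headline=ks < own)


@dataclass(frozen=True)
class DuplicatePair:
    gene1: str
    gene2: str
    score: float
    tandem: bool


def duplicate_pairs(proteome: Mapping[str, str],
                    loci: Mapping[str, GeneLocus],
                    family_genes: Sequence[str],
                    max_gene_gap: int = 10) -> list[DuplicatePair]:
    """Within-species duplicate candidates among family genes.

    Reciprocal best hits of the family proteome against itself (self-hits
    excluded); each pair is tagged tandem when both genes share a
    chromosome with at most ``max_gene_gap`` intervening genes.
    """
    fam = sorted(set(family_genes))
    sub = {g: proteome[g] for g in fam}
    best: dict[str, tuple[str, float]] = {}
    for g in fam:
        scores = [(global_score(sub[g], sub[h]), h) for h in fam if h != g]
        if not scores:
            continue
        top = max(s for s, _ in scores)
        winners = [h for s, h in scores if s == top]
        if len(winners) == 1:
            best[g] = (winners[0], top)
    pairs = []
    for g, (h, score) in sorted(best.items()):
        if g < h and best.get(h, (None,))[0] == g:
            lg, lh = loci[g], loci[h]
            tandem = (lg.chromosome == lh.chromosome
                      and abs(lg.rank - lh.rank) - 1 <= max_gene_gap)
            pairs.append(DuplicatePair(gene1=g, gene2=h, score=float(score),
                                       tandem=tandem))
    return pairs
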