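"""Cross-species comparison: orthologs, collinear blocks, specificity, tandems.

Orthologous pairs come from reciprocal best hits (RBH) over all-vs-all
global alignment scores.  Collinear blocks chain RBH pairs that preserve
gene order (rank) between two chromosomes, re-implementing the standard
synteny-chaining idea with explicit, testable dynamic programming.  A
gene's species-specificity status is defined by block membership, not bare
RBH, because the reference analysis derives "no orthologous relationship"
from synteny.  Tandem arrays are runs of same-subgroup genes separated by
at most a configurable number of intervening genes on one chromosome.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd

from .align import global_score


@dataclass(frozen=True)
class GeneLocus:
    """One gene's position; ``rank`` is the 0-based order along its chromosome."""

    gene: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: str
    rank: int


def read_gff3_loci(path: str | Path, species: str,
                   keep_chromosomes: str | None = None) -> list[GeneLocus]:
    """Gene loci from a GFF3 file, ranked by start position per chromosome.

    ``keep_chromosomes`` is an optional regular expression; chromosomes not
    matching it (e.g. unanchored scaffolds) are excluded before ranking.
    Ties in start position are broken by gene id.
    """
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    pattern = re.compile(keep_chromosomes) if keep_chromosomes else None
    raw = []
    for feature in db.features_of_type("gene"):
        if pattern and not pattern.search(feature.seqid):
            continue
        gene = feature.attributes.get("ID", [feature.id])[0]
        raw.append((feature.seqid, feature.start, gene, feature.end,
                    feature.strand or "+"))
    loci = []
    by_chrom: dict[str, list] = {}
    for rec in sorted(raw):
        by_chrom.setdefault(rec[0], []).append(rec)
    for chrom, records in by_chrom.items():
        for rank, (seqid, start, gene, end, strand) in enumerate(
                sorted(records, key=lambda r: (r[1], r[2]))):
            loci.append(GeneLocus(gene=gene, species=species,
                                  chromosome=seqid, start=start, end=end,
                                  strand=strand, rank=rank))
    return loci


def rbh_orthologs(proteome_a: Mapping[str, str], proteome_b: Mapping[str, str]
                  ) -> list[tuple[str, str, float]]:
    """Reciprocal best hits between two proteomes.

    A pair is kept only when each gene is the other's unique best-scoring
    match (a tie for best hit disqualifies the gene).  The result is
    independent of input ordering.
    """
    genes_a = sorted(proteome_a)
    genes_b = sorted(proteome_b)
    if not genes_a or not genes_b:
        return []
    scores = np.empty((len(genes_a), len(genes_b)))
    for i, ga in enumerate(genes_a):
        seq_a = proteome_a[ga]
        for j, gb in enumerate(genes_b):
            scores[i, j] = global_score(seq_a, proteome_b[gb])

    def unique_argmax(row: np.ndarray) -> int | None:
        best = row.max()
        where = np.flatnonzero(row == best)
        return int(where[0]) if len(where) == 1 else None

    best_a = [unique_argmax(scores[i]) for i in range(len(genes_a))]
    best_b = [unique_argmax(scores[:, j]) for j in range(len(genes_b))]
    pairs = []
    for i, j in enumerate(best_a):
        if j is not None and best_b[j] == i:
            pairs.append((genes_a[i], genes_b[j], float(scores[i, j])))
    return pairs


@dataclass(frozen=True)
class Block:
    """One collinear block between two chromosomes."""

    block_id: str
    species: tuple[str, str]
    chromosomes: tuple[str, str]
    orientation: int  # +1 / -1 on the second genome
    pairs: tuple[tuple[str, str], ...]

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def genes(self) -> tuple[set, set]:
        return ({a for a, _ in self.pairs}, {b for _, b in self.pairs})


def _chain_once(ranks: list[tuple[int, int, int]], orientation: int,
                max_rank_gap: int) -> list[int]:
    """Longest valid chain via DP over pairs sorted by first-genome rank.

    ``ranks`` holds (rank_a, rank_b, pair_index) sorted by rank_a.  A chain
    must be strictly increasing in rank_a, strictly monotone (per
    ``orientation``) in rank_b, with consecutive gaps at most
    ``max_rank_gap`` on both genomes.  Ties prefer the chain starting
    earliest (smallest rank_a of the first member).
    """
    n = len(ranks)
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            ra_j, rb_j, _ = ranks[j]
            ra_i, rb_i, _ = ranks[i]
            if ra_i <= ra_j or ra_i - ra_j > max_rank_gap + 1:
                continue
            step_b = (rb_i - rb_j) * orientation
            if step_b <= 0 or step_b > max_rank_gap + 1:
                continue
            if best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    if n == 0:
        return []
    end = max(range(n), key=lambda i: (best_len[i], -ranks[i][0]))
    chain = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    return list(reversed(chain))


def collinear_blocks(pairs: Sequence[tuple[str, str] | tuple[str, str, float]],
                     loci_a: Mapping[str, GeneLocus],
                     loci_b: Mapping[str, GeneLocus],
                     min_block: int = 5, max_rank_gap: int = 25
                     ) -> list[Block]:
    """Chain ortholog pairs into collinear blocks per chromosome pair.

    Within each chromosome pair, maximal chains (strictly increasing rank on
    genome A, monotone in either direction on genome B, consecutive rank
    gaps bounded on both genomes) are extracted greedily by decreasing
    length; chains shorter than ``min_block`` are discarded.
    """
    by_chrom: dict[tuple[str, str], list[tuple[int, int, tuple[str, str]]]] = {}
    species = None
    for pair in pairs:
        a, b = pair[0], pair[1]
        la, lb = loci_a[a], loci_b[b]
        species = (la.species, lb.species)
        by_chrom.setdefault((la.chromosome, lb.chromosome), []).append(
            (la.rank, lb.rank, (a, b)))
    blocks: list[Block] = []
    counter = 0
    for (ca, cb), items in sorted(by_chrom.items()):
        remaining = sorted(items)
        while True:
            candidates = []
            for orientation in (1, -1):
                chain = _chain_once(remaining, orientation, max_rank_gap)
                if chain:
                    candidates.append((len(chain),
                                       -remaining[chain[0]][0],
                                       orientation, chain))
            if not candidates:
                break
            length, _, orientation, chain = max(candidates)
            if length < min_block:
                break
            counter += 1
            members = [remaining[i] for i in chain]
            blocks.append(Block(
                block_id=f"block{counter}",
                species=species,
                chromosomes=(ca, cb),
                orientation=orientation,
                pairs=tuple(pair for _, _, pair in members),
            ))
            used = set(chain)
            remaining = [item for i, item in enumerate(remaining)
                         if i not in used]
    return blocks


def specificity_status(blocks_by_pair: Mapping[tuple[str, str], Sequence[Block]],
                       family_genes: Mapping[str, Sequence[str]]
                       ) -> pd.DataFrame:
    """Per-gene ortholog status across exactly three species.

    A gene is ``three_species`` when it sits in collinear blocks against
    both other species, ``two_species`` with exactly one, and
    ``species_specific`` with none (block membership, not bare RBH, defines
    orthology here).
    """
    species = sorted(family_genes)
    if len(species) != 3:
        raise ValueError("specificity status is defined for exactly 3 species")
    in_blocks: dict[str, set[str]] = {}
    for (sp_a, sp_b), blocks in blocks_by_pair.items():
        if sp_a not in family_genes or sp_b not in family_genes:
            raise ValueError(f"unknown species pair {(sp_a, sp_b)!r}")
        for block in blocks:
            genes_a, genes_b = block.genes
            for g in genes_a:
                in_blocks.setdefault(g, set()).add(sp_b)
            for g in genes_b:
                in_blocks.setdefault(g, set()).add(sp_a)
    rows = []
    for sp in species:
        for gene in family_genes[sp]:
            partners = in_blocks.get(gene, set()) - {sp}
            status = {2: "three_species", 1: "two_species",
                      0: "species_specific"}[min(len(partners), 2)]
            rows.append({"gene": gene, "species": sp, "status": status,
                         "partner_species": ",".join(sorted(partners))})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TandemArray:
    chromosome: str
    subgroup: str
    genes: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.genes)


def tandem_arrays(subgroup_of: Mapping[str, str],
                  loci: Mapping[str, GeneLocus],
                  max_gene_gap: int = 10) -> list[TandemArray]:
    """Maximal same-subgroup runs along each chromosome.

    Consecutive members may be separated by at most ``max_gene_gap``
    intervening genes of any family; runs need at least two members.
    ``loci`` must cover every gene on the chromosomes (family or not) so
    the intervening-gene count is meaningful.
    """
    by_chrom: dict[str, list[GeneLocus]] = {}
    for locus in loci.values():
        by_chrom.setdefault(locus.chromosome, []).append(locus)
    arrays: list[TandemArray] = []
    for chrom in sorted(by_chrom):
        members = sorted((l for l in by_chrom[chrom]
                          if l.gene in subgroup_of),
                         key=lambda l: l.rank)
        by_sub: dict[str, list[GeneLocus]] = {}
        for locus in members:
            by_sub.setdefault(subgroup_of[locus.gene], []).append(locus)
        for sub in sorted(by_sub):
            run: list[GeneLocus] = []
            for locus in by_sub[sub]:
                if run and locus.rank - run[-1].rank - 1 > max_gene_gap:
                    if len(run) >= 2:
                        arrays.append(TandemArray(chrom, sub,
                                                  tuple(l.gene for l in run)))
                    run = []
                run.append(locus)
            if len(run) >= 2:
                arrays.append(TandemArray(chrom, sub,
                                          tuple(l.gene for l in run)))
    return arrays
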