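"""Labeled synthetic inputs for the AP2/ERF analysis pipeline.

This module generates, from one seeded configuration, everything the
downstream stages consume: per-species protein FASTA files with planted
AP2/B3 domains, InterProScan-style domain-hit TSVs (including decoy and
overlapping hits for filter testing), GFF3 gene models with planted tandem
arrays and cross-species collinear blocks, duplicate CDS pairs with
controlled synonymous divergence, negative-binomial count matrices with
planted fold changes, and GO annotation tables with one planted enriched
term.  Every emitted record is mirrored in a :class:`TruthTable` so tests
can score recovery exactly.

Determinism contract: the configuration (including its seed) fully
determines every emitted byte.  All random draws come from
``numpy.random.default_rng([seed, stream])`` with a fixed stream id per
generator, so the generators may be called in any order.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .profiles import (
    AMINO_ACIDS,
    AP2_SUBFAMILY_INSERTION,
    AP2_SUBFAMILY_INSERTION_AFTER,
    B3_DOMAIN_CONSENSUS,
    DIAGNOSTIC_COLUMNS,
    SUBFAMILY_TO_SUBGROUPS,
    SUBGROUP_CONSENSUS,
    SUBGROUP_TO_SUBFAMILY,
    SUBGROUPS,
)


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


class ConsistencyError(ValueError):
    """Truth table does not match the supplied configuration."""


class GenerationError(RuntimeError):
    """A requested dataset cannot be generated."""


_FLANK_LEN = 30
_LINKER = "GGSGG"
_STREAM_PROTEOME = 1
_STREAM_CDS = 3
_STREAM_COUNTS = 4
_STREAM_GO = 5
_STREAM_EFFECTS = 6

#: Codon prefixes whose third position is four-fold degenerate and whose
#: first/second-position single-nucleotide changes are never synonymous
#: (Ala, Gly, Thr, Val, Pro).  Restricting simulated coding sequence to these
#: families makes the NG86 synonymous-site count exactly one per codon.
FOURFOLD_PREFIXES = ("GC", "GG", "AC", "GT", "CC")
_BASES = "ACGT"


def default_tandem_arrays(genes_per_species: int
                          ) -> tuple[tuple[str, str, int], ...]:
    """Planted-array defaults scaled to the proteome size.

    The stock arrays (B2 on chr1, B3 on chr4) need enough species-specific
    genes of their subgroup; below ~40 genes per species none are planted.
    """
    if genes_per_species >= 150:
        return (("chr1", "B2", 5), ("chr4", "B3", 4))
    if genes_per_species >= 40:
        return (("chr1", "B2", 4), ("chr4", "B3", 3))
    return ()


def default_species_names(n: int) -> tuple[str, ...]:
    base = ["ca", "sl", "st"]
    while len(base) < n:
        base.append(f"sp{len(base) + 1}")
    return tuple(base[:n])


def _normalize_mix(mix: Mapping[str, float], allowed: Sequence[str],
                   what: str) -> dict[str, float]:
    out = {}
    for key, value in mix.items():
        if key not in allowed:
            raise ConfigurationError(f"unknown {what} {key!r}")
        if not 0.0 <= value <= 1.0:
            raise ConfigurationError(f"{what} proportion for {key!r} not in [0,1]")
        out[key] = float(value)
    total = sum(out.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"{what} proportions sum to {total}, expected 1")
    return out


def apportion(n: int, mix: Mapping[str, float],
              order: Sequence[str] = SUBGROUPS) -> dict[str, int]:
    """Largest-remainder apportionment of ``n`` items among mix keys.

    Deterministic: ties in remainders are broken by position in ``order``.
    """
    keys = [k for k in order if mix.get(k, 0.0) > 0.0]
    quotas = {k: n * mix[k] for k in keys}
    counts = {k: int(math.floor(quotas[k])) for k in keys}
    short = n - sum(counts.values())
    by_rem = sorted(keys, key=lambda k: (-(quotas[k] - counts[k]), order.index(k)))
    for k in by_rem[:short]:
        counts[k] += 1
    return {k: counts.get(k, 0) for k in order}


@dataclass(frozen=True)
class TruthConfig:
    """Study conditions for the synthetic datasets.

    Defaults emulate the three-Solanaceae comparison: three species, an
    ERF-dominated subfamily mix, half of the family genes species-specific,
    B2/B3 tandem expansions on dedicated chromosomes of the first species,
    a grid of planted synonymous divergences, and a 5-time-point,
    3-replicate abiotic-stress count design.
    """

    n_species: int = 3
    genes_per_species: int = 200
    background_genes: int = 50
    subfamily_mix: Mapping[str, float] | None = None
    subgroup_mix: Mapping[str, float] | None = None
    tandem_arrays: Sequence[tuple[str, str, int]] = (("chr1", "B2", 5),
                                                     ("chr4", "B3", 4))
    n_chromosomes: int = 4
    collinear_block_fraction: float = 1.0
    species_specific_fraction: float = 0.5
    two_species_fraction: float = 0.1
    ks_targets: Sequence[float] = (0.05, 0.1, 0.2, 0.3, 0.5)
    de_effects: Sequence[tuple[str, str, float]] | None = None
    dispersion: float = 0.1
    replicates: int = 3
    conditions: Sequence[str] = ("cold", "heat", "salt", "mannitol")
    time_points: Sequence[int] = (3, 6, 12, 24, 72)
    domain_noise: float = 0.0
    seed: int = 0

    @property
    def species_names(self) -> tuple[str, ...]:
        return default_species_names(self.n_species)

    @property
    def chromosome_names(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(self.n_chromosomes))

    def resolved_subgroup_mix(self) -> dict[str, float]:
        """Twelve-subgroup mix; subfamily shares split uniformly if needed."""
        if self.subgroup_mix is not None:
            return _normalize_mix(self.subgroup_mix, SUBGROUPS, "subgroup")
        subfam = self.subfamily_mix
        if subfam is None:
            subfam = {"ERF": 0.55, "DREB": 0.20, "AP2": 0.08,
                      "ANT": 0.05, "RAV": 0.08, "Soloist": 0.04}
        subfam = _normalize_mix(subfam, tuple(SUBFAMILY_TO_SUBGROUPS), "subfamily")
        default_erf = {"B1": 0.20, "B2": 0.35, "B3": 0.20, "B4": 0.25}
        mix: dict[str, float] = {}
        for family, share in subfam.items():
            subs = SUBFAMILY_TO_SUBGROUPS[family]
            if family == "ERF":
                for sub in subs:
                    mix[sub] = share * default_erf[sub]
            else:
                for sub in subs:
                    mix[sub] = share / len(subs)
        return {k: mix.get(k, 0.0) for k in SUBGROUPS}

    def validate(self) -> None:
        if self.n_species < 1:
            raise ConfigurationError("n_species must be >= 1")
        if self.genes_per_species < 1:
            raise ConfigurationError("genes_per_species must be >= 1")
        if self.background_genes < 0:
            raise ConfigurationError("background_genes must be >= 0")
        for name, value in (
            ("collinear_block_fraction", self.collinear_block_fraction),
            ("species_specific_fraction", self.species_specific_fraction),
            ("two_species_fraction", self.two_species_fraction),
            ("domain_noise", self.domain_noise),
        ):
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1]")
        self.resolved_subgroup_mix()
        chroms = set(self.chromosome_names)
        for chrom, sub, size in self.tandem_arrays:
            if chrom not in chroms:
                raise ConfigurationError(f"tandem array chromosome {chrom!r} unknown")
            if sub not in SUBGROUPS:
                raise ConfigurationError(f"tandem array subgroup {sub!r} unknown")
            if size < 2:
                raise ConfigurationError("tandem array size must be >= 2")
        for target in self.ks_targets:
            if target < 0:
                raise ConfigurationError("ks_targets must be >= 0")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")


@dataclass
class TruthTable:
    """Ground truth for one generated dataset.

    ``genes`` holds one row per emitted gene (family and background) with
    species, chromosome, rank, genomic coordinates, true subfamily/subgroup,
    ortholog group ("" when species-specific), tandem array id ("" when not
    in an array) and a collinearity flag.  ``domains`` holds the planted
    domain coordinates (1-based inclusive, protein space).
    """

    genes: pd.DataFrame
    domains: pd.DataFrame
    config: TruthConfig

    def check_invariants(self) -> None:
        if self.genes["gene"].duplicated().any():
            raise ConsistencyError("duplicate gene ids in truth table")
        fam = self.genes[self.genes["is_family"]]
        grouped = fam[fam["ortholog_group"] != ""]
        bad = grouped.groupby("ortholog_group")["subgroup"].nunique()
        if (bad > 1).any():
            raise ConsistencyError("ortholog groups mix subgroups across species")

    def family_genes(self, species: str | None = None) -> pd.DataFrame:
        out = self.genes[self.genes["is_family"]]
        if species is not None:
            out = out[out["species"] == species]
        return out


@dataclass
class ProteomeSet:
    """Generated proteomes plus their domain-hit tables and truth."""

    config: TruthConfig
    truth: TruthTable
    sequences: dict[str, dict[str, str]]
    hits: dict[str, pd.DataFrame]

    def write(self, outdir: str | Path) -> dict[str, dict[str, Path]]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, dict[str, Path]] = {}
        for sp in self.config.species_names:
            fasta = outdir / f"{sp}.proteins.fasta"
            records = [SeqRecord(Seq(seq), id=gene, description="")
                       for gene, seq in self.sequences[sp].items()]
            SeqIO.write(records, str(fasta), "fasta")
            tsv = outdir / f"{sp}.domains.tsv"
            self.hits[sp].to_csv(tsv, sep="\t", header=False, index=False)
            paths[sp] = {"proteins": fasta, "domains": tsv}
        return paths


def _draw_labels(k: int, mix: Mapping[str, float],
                 capacity: Mapping[str, int]) -> list[str]:
    """Apportion ``k`` subgroup labels under per-subgroup capacity."""
    if k == 0:
        return []
    want = apportion(k, mix)
    counts = {s: min(want[s], capacity.get(s, 0)) for s in SUBGROUPS}
    deficit = k - sum(counts.values())
    order = sorted(SUBGROUPS, key=lambda s: (-mix.get(s, 0.0), SUBGROUPS.index(s)))
    while deficit > 0:
        progressed = False
        for s in order:
            if deficit == 0:
                break
            if counts[s] < capacity.get(s, 0):
                counts[s] += 1
                deficit -= 1
                progressed = True
        if deficit > 0 and not progressed:
            raise ConfigurationError(
                "cannot allocate subgroup labels within the per-species budget")
    return [s for s in SUBGROUPS for _ in range(counts[s])]


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate_positions(rng: np.random.Generator, seq: list[str],
                      positions: np.ndarray) -> None:
    for pos in positions:
        current = seq[pos]
        choices = [aa for aa in AMINO_ACIDS if aa != current]
        seq[pos] = choices[rng.integers(len(choices))]


def _noisy_domain(rng: np.random.Generator, consensus: str, noise: float,
                  protect: Sequence[int]) -> str:
    if noise <= 0:
        return consensus
    chars = list(consensus)
    protected = set(p - 1 for p in protect)
    for i in range(len(chars)):
        if i in protected:
            continue
        if rng.random() < noise:
            choices = [aa for aa in AMINO_ACIDS if aa != chars[i]]
            chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


def _assemble_protein(subgroup: str, flank_n: str, flank_c: str,
                      rng: np.random.Generator, noise: float
                      ) -> tuple[str, list[tuple[str, int, int]]]:
    """Build a family protein and return it with planted (kind, start, end)."""
    domains: list[tuple[str, str]] = []
    if subgroup == "RAV":
        domains.append(("AP2", _noisy_domain(rng, SUBGROUP_CONSENSUS["RAV"],
                                             noise, DIAGNOSTIC_COLUMNS)))
        domains.append(("B3", _noisy_domain(rng, B3_DOMAIN_CONSENSUS, noise, ())))
    elif subgroup in ("AP2", "ANT"):
        first = SUBGROUP_CONSENSUS[subgroup]
        if subgroup == "AP2":
            cut = AP2_SUBFAMILY_INSERTION_AFTER
            first = first[:cut] + AP2_SUBFAMILY_INSERTION + first[cut:]
        domains.append(("AP2", _noisy_domain(rng, first, noise,
                                             DIAGNOSTIC_COLUMNS)))
        domains.append(("AP2", _noisy_domain(rng, SUBGROUP_CONSENSUS[subgroup],
                                             noise, DIAGNOSTIC_COLUMNS)))
    else:
        domains.append(("AP2", _noisy_domain(rng, SUBGROUP_CONSENSUS[subgroup],
                                             noise, DIAGNOSTIC_COLUMNS)))
    seq = flank_n
    hits: list[tuple[str, int, int]] = []
    for i, (kind, dom) in enumerate(domains):
        if i > 0:
            seq += _LINKER
        start = len(seq) + 1
        seq += dom
        hits.append((kind, start, len(seq)))
    seq += flank_c
    return seq, hits


def generate_proteomes(config: TruthConfig) -> ProteomeSet:
    """Generate per-species proteomes, domain-hit tables and the truth table.

    Family genes embed subgroup-specific AP2 (and, for RAV, B3) domains with
    diagnostic residues set by the true label.  The hit tables list the
    planted domains at e-values <= 1e-6 plus two kinds of injected noise:
    decoy hits at e-values > 1e-5 and overlapping duplicates of true hits at
    worse (but passing) e-values, so the downstream filter can be scored.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STREAM_PROTEOME])
    mix = config.resolved_subgroup_mix()
    n = config.n_species
    g = config.genes_per_species
    species = config.species_names
    chroms = config.chromosome_names

    budget = apportion(g, mix)
    n_specific = round(g * config.species_specific_fraction)
    if n >= 3:
        pairs = [(i, (i + 1) % n) for i in range(n)]
        m_pair = round(g * config.two_species_fraction / 2)
        per_species_two = 2 * m_pair
    elif n == 2:
        pairs = [(0, 1)]
        m_pair = round(g * config.two_species_fraction)
        per_species_two = m_pair
    else:
        pairs = []
        m_pair = 0
        per_species_two = 0
        n_specific = g
    n_three = g - n_specific - per_species_two
    if n_three < 0:
        raise ConfigurationError(
            "species_specific_fraction + two_species_fraction exceed 1")

    three_labels = _draw_labels(n_three, mix, budget)
    remaining_template = dict(budget)
    for lab in three_labels:
        remaining_template[lab] -= 1
    remaining = {s: dict(remaining_template) for s in range(n)}
    pair_labels: list[list[str]] = []
    for a, b in pairs:
        cap = {sub: min(remaining[a][sub], remaining[b][sub]) for sub in SUBGROUPS}
        labs = _draw_labels(m_pair, mix, cap)
        pair_labels.append(labs)
        for lab in labs:
            remaining[a][lab] -= 1
            remaining[b][lab] -= 1

    # Species-specific label pools; tandem arrays consume from species 0.
    specific_pool = {s: dict(remaining[s]) for s in range(n)}
    array_specs = list(config.tandem_arrays)
    excluded: dict[str, set[str]] = {}
    for chrom, sub, size in array_specs:
        # A chromosome hosting an array keeps no other gene of the same
        # subgroup, so the planted array is recoverable exactly.
        if sub in excluded.get(chrom, set()):
            raise ConfigurationError(
                f"two tandem arrays of {sub} on {chrom} would merge")
        excluded.setdefault(chrom, set()).add(sub)
    for chrom, sub, size in array_specs:
        if specific_pool[0].get(sub, 0) < size:
            raise ConfigurationError(
                f"tandem array ({chrom}, {sub}, {size}) needs {size} "
                f"species-specific {sub} genes but only "
                f"{specific_pool[0].get(sub, 0)} are available; increase "
                "species_specific_fraction or the subgroup's share")
        specific_pool[0][sub] -= size
        if sum(range(size)) > 2 * _FLANK_LEN:
            raise ConfigurationError(f"tandem array size {size} too large")

    # Backbone ortholog groups in a global conserved order, split over
    # chromosomes; each group carries one label and a member-species set.
    groups: list[dict] = []
    for i, lab in enumerate(three_labels):
        groups.append({"id": f"og{i + 1:04d}", "subgroup": lab,
                       "members": frozenset(range(n))})
    offset = len(groups)
    for (a, b), labs in zip(pairs, pair_labels):
        for lab in labs:
            offset += 1
            groups.append({"id": f"og{offset:04d}", "subgroup": lab,
                           "members": frozenset((a, b))})
    order = rng.permutation(len(groups))
    ordered_groups = [groups[i] for i in order]
    chrom_chunks = np.array_split(np.arange(len(ordered_groups)),
                                  len(chroms))
    # Keep backbone genes of an array's subgroup off the array chromosome:
    # swap offending groups with compatible groups from other chromosomes.
    chunk_of = np.empty(len(ordered_groups), dtype=int)
    for ci, chunk in enumerate(chrom_chunks):
        chunk_of[chunk] = ci
    for idx in range(len(ordered_groups)):
        chrom = chroms[chunk_of[idx]]
        sub = ordered_groups[idx]["subgroup"]
        if sub not in excluded.get(chrom, set()):
            continue
        swapped = False
        for jdx in range(len(ordered_groups)):
            if chunk_of[jdx] == chunk_of[idx]:
                continue
            other = ordered_groups[jdx]["subgroup"]
            chrom_j = chroms[chunk_of[jdx]]
            if (other not in excluded.get(chrom, set())
                    and sub not in excluded.get(chrom_j, set())):
                ordered_groups[idx], ordered_groups[jdx] = (
                    ordered_groups[jdx], ordered_groups[idx])
                swapped = True
                break
        if not swapped:
            raise ConfigurationError(
                f"cannot keep subgroup {sub!r} off array chromosome {chrom}")

    # Shared flanks per ortholog group (the gene "barcode"): orthologs are
    # sequence-identical across species, paralogs share only the domain.
    for grp in groups:
        grp["flank_n"] = _random_peptide(rng, _FLANK_LEN)
        grp["flank_c"] = _random_peptide(rng, _FLANK_LEN)
    # Species-specific genes of one subgroup are modeled as recent identical
    # duplicates: one flank barcode per (species, subgroup).  This mirrors
    # their origin by recent expansion and keeps cross-species best hits
    # between unrelated specific genes tied (hence discarded by RBH).
    specific_flanks = [
        {sub: (_random_peptide(rng, _FLANK_LEN),
               _random_peptide(rng, _FLANK_LEN)) for sub in SUBGROUPS}
        for _ in range(n)]

    # Per-species gene placement: backbone order, then planted arrays, then
    # free species-specific genes, then background genes.
    per_species_rows: dict[str, list[dict]] = {}
    sequences: dict[str, dict[str, str]] = {}
    domain_rows: list[dict] = []

    for s, sp in enumerate(species):
        chrom_lists: dict[str, list[dict]] = {c: [] for c in chroms}
        for ci, chrom in enumerate(chroms):
            for gi in chrom_chunks[ci]:
                grp = ordered_groups[gi]
                if s in grp["members"]:
                    chrom_lists[chrom].append({
                        "subgroup": grp["subgroup"],
                        "ortholog_group": grp["id"],
                        "tandem_array": "",
                        "collinear": True,
                        "flank_n": grp["flank_n"],
                        "flank_c": grp["flank_c"],
                        "is_family": True,
                    })
        def allowed_chroms(subgroup: str) -> list[str]:
            # Species 0 hosts the arrays; keep same-subgroup genes off the
            # array chromosomes there.
            if s != 0:
                return list(chroms)
            out = [c for c in chroms
                   if subgroup not in excluded.get(c, set())]
            if not out:
                raise ConfigurationError(
                    f"no chromosome left for subgroup {subgroup!r}")
            return out

        free_labels = [lab for lab in SUBGROUPS
                       for _ in range(specific_pool[s][lab])]
        for lab in free_labels:
            options = allowed_chroms(lab)
            chrom = options[rng.integers(len(options))]
            pos = int(rng.integers(0, len(chrom_lists[chrom]) + 1))
            chrom_lists[chrom].insert(pos, {
                "subgroup": lab,
                "ortholog_group": "",
                "tandem_array": "",
                "collinear": False,
                "flank_n": specific_flanks[s][lab][0],
                "flank_c": specific_flanks[s][lab][1],
                "is_family": True,
            })
        # Optionally break collinearity for a fraction of backbone genes.
        if config.collinear_block_fraction < 1.0:
            backbone = [(chrom, i) for chrom in chroms
                        for i, rec in enumerate(chrom_lists[chrom])
                        if rec["ortholog_group"] != ""]
            k_move = round((1.0 - config.collinear_block_fraction)
                           * len(backbone))
            if k_move:
                chosen = rng.choice(len(backbone), size=k_move, replace=False)
                moved = []
                for idx in sorted(chosen, reverse=True):
                    chrom, i = backbone[idx]
                    rec = chrom_lists[chrom].pop(i)
                    rec["collinear"] = False
                    moved.append(rec)
                for rec in moved:
                    options = allowed_chroms(rec["subgroup"])
                    chrom = options[rng.integers(len(options))]
                    pos = int(rng.integers(0, len(chrom_lists[chrom]) + 1))
                    chrom_lists[chrom].insert(pos, rec)
        for _ in range(config.background_genes):
            chrom = chroms[rng.integers(len(chroms))]
            pos = int(rng.integers(0, len(chrom_lists[chrom]) + 1))
            length = int(rng.integers(120, 200))
            chrom_lists[chrom].insert(pos, {
                "subgroup": "",
                "ortholog_group": "",
                "tandem_array": "",
                "collinear": False,
                "sequence": _random_peptide(rng, length),
                "is_family": False,
            })
        if s == 0:
            # Arrays go in last, as atomic blocks, so members end up at
            # strictly consecutive ranks.
            for ai, (chrom, sub, size) in enumerate(array_specs):
                array_id = f"ta{ai + 1}"
                founder_n = _random_peptide(rng, _FLANK_LEN)
                founder_c = _random_peptide(rng, _FLANK_LEN)
                flanks = list(founder_n + founder_c)
                unused = list(range(len(flanks)))
                members = []
                for j in range(size):
                    if j > 0:
                        picks = rng.choice(len(unused), size=j, replace=False)
                        positions = np.array([unused[p] for p in sorted(picks)])
                        for p in sorted(picks, reverse=True):
                            unused.pop(p)
                        _mutate_positions(rng, flanks, positions)
                    joined = "".join(flanks)
                    members.append({
                        "subgroup": sub,
                        "ortholog_group": "",
                        "tandem_array": array_id,
                        "collinear": False,
                        "flank_n": joined[:_FLANK_LEN],
                        "flank_c": joined[_FLANK_LEN:],
                        "is_family": True,
                    })
                pos = int(rng.integers(0, len(chrom_lists[chrom]) + 1))
                chrom_lists[chrom][pos:pos] = members

        # Name genes by chromosomal order ("<sp>AP2_<n>" for family genes),
        # build sequences and planted-domain records.
        rows: list[dict] = []
        seqs: dict[str, str] = {}
        fam_counter = 0
        bg_counter = 0
        for chrom in chroms:
            for rank, rec in enumerate(chrom_lists[chrom]):
                if rec["is_family"]:
                    fam_counter += 1
                    gene = f"{sp}AP2_{fam_counter}"
                    seq, hits = _assemble_protein(
                        rec["subgroup"], rec["flank_n"], rec["flank_c"],
                        rng, config.domain_noise)
                    for kind, start, end in hits:
                        domain_rows.append({"gene": gene, "kind": kind,
                                            "start": start, "end": end})
                else:
                    bg_counter += 1
                    gene = f"{sp}G_{bg_counter}"
                    seq = rec["sequence"]
                seqs[gene] = seq
                start = 10_000 + rank * 5_000
                end = start + 3 * len(seq) + 2
                rows.append({
                    "gene": gene,
                    "species": sp,
                    "chromosome": chrom,
                    "rank": rank,
                    "start": start,
                    "end": end,
                    "strand": "+",
                    "subfamily": SUBGROUP_TO_SUBFAMILY.get(rec["subgroup"], ""),
                    "subgroup": rec["subgroup"],
                    "ortholog_group": rec["ortholog_group"],
                    "tandem_array": rec["tandem_array"],
                    "collinear": rec["collinear"],
                    "is_family": rec["is_family"],
                })
        per_species_rows[sp] = rows
        sequences[sp] = seqs

    genes_df = pd.DataFrame([row for sp in species
                             for row in per_species_rows[sp]])
    domains_df = pd.DataFrame(domain_rows,
                              columns=["gene", "kind", "start", "end"])
    truth = TruthTable(genes=genes_df, domains=domains_df, config=config)
    truth.check_invariants()

    hits = {sp: _hit_table(rng, sp, sequences[sp], truth) for sp in species}
    return ProteomeSet(config=config, truth=truth, sequences=sequences,
                       hits=hits)


_IPS_COLUMNS = ["protein", "md5", "length", "analysis", "accession",
                "description", "start", "stop", "evalue", "status", "date"]
_ACCESSION = {"AP2": "PF00847", "B3": "PF02362"}
_DESCRIPTION = {"AP2": "AP2 domain", "B3": "B3 DNA binding domain"}


def _hit_table(rng: np.random.Generator, species: str,
               seqs: dict[str, str], truth: TruthTable) -> pd.DataFrame:
    """InterProScan-style rows: planted hits + decoys + overlap duplicates."""
    planted = truth.domains.set_index("gene")
    rows: list[list] = []

    def add(gene, kind, start, stop, evalue):
        rows.append([gene, "-", len(seqs[gene]), "Pfam", _ACCESSION[kind],
                     _DESCRIPTION[kind], start, stop, f"{evalue:.3E}", "T",
                     "01-01-2023"])

    for gene in seqs:
        if gene in planted.index:
            sub = planted.loc[[gene]]
            for _, hit in sub.iterrows():
                evalue = 10.0 ** (-rng.uniform(10, 30))
                add(gene, hit["kind"], int(hit["start"]), int(hit["end"]),
                    evalue)
                if rng.random() < 0.5:  # overlapping duplicate, worse e-value
                    shift = int(rng.integers(1, 4))
                    dup_start = max(1, int(hit["start"]) + shift)
                    dup_end = min(len(seqs[gene]), int(hit["end"]) + shift)
                    add(gene, hit["kind"], dup_start, dup_end,
                        10.0 ** (-rng.uniform(6, 9)))
        if rng.random() < 0.3 and len(seqs[gene]) >= 60:  # decoy, fails filter
            start = int(rng.integers(1, len(seqs[gene]) - 56))
            add(gene, "AP2", start, start + 56,
                10.0 ** (-rng.uniform(1.0, 4.5)))
    return pd.DataFrame(rows, columns=_IPS_COLUMNS)


def generate_gene_models(config: TruthConfig, truth: TruthTable
                         ) -> dict[str, pd.DataFrame]:
    """Per-species GFF3-shaped gene tables (1-based, end-inclusive)."""
    if truth.config is not config and truth.config != config:
        raise ConsistencyError("truth table was generated from a different config")
    out = {}
    for sp in config.species_names:
        sub = truth.genes[truth.genes["species"] == sp]
        sub = sub.sort_values(["chromosome", "start", "gene"])
        out[sp] = sub[["chromosome", "start", "end", "strand", "gene"]].copy()
    return out


def write_gff3(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in table.iterrows():
            attrs = f"ID={row['gene']};Name={row['gene']}"
            fh.write(f"{row['chromosome']}\terfkit\tgene\t{row['start']}\t"
                     f"{row['end']}\t.\t{row['strand']}\t.\t{attrs}\n")
    return path


@dataclass
class CdsPairSet:
    """Duplicate CDS pairs with planted synonymous divergence."""

    pairs: pd.DataFrame  # pair_id, target, seq ids
    sequences: dict[str, str]

    def write(self, fasta_path: str | Path, truth_path: str | Path | None = None):
        records = [SeqRecord(Seq(self.sequences[name]), id=name, description="")
                   for name in self.sequences]
        SeqIO.write(records, str(Path(fasta_path)), "fasta")
        if truth_path is not None:
            self.pairs.to_csv(truth_path, sep="\t", index=False)


def generate_cds_pairs(config: TruthConfig, n_codons: int = 300,
                       pairs_per_target: int = 1) -> CdsPairSet:
    """Codon-sequence pairs whose NG86 Ks expectation equals each target.

    Sequences use only codon families whose third position is four-fold
    degenerate and whose other positions admit no synonymous change, so each
    codon contributes exactly one synonymous site.  Third positions mutate
    under a Jukes-Cantor process at divergence ``target``: a site differs
    with probability (3/4)(1 - exp(-4K/3)) and, when it does, the new base
    is uniform over the other three.  All changes are synonymous and no stop
    codon can arise.
    """
    if len(config.ks_targets) == 0:
        raise ConfigurationError("ks_targets must be nonempty")
    if n_codons < 30:
        raise ConfigurationError("n_codons must be >= 30")
    rng = np.random.default_rng([config.seed, _STREAM_CDS])
    rows = []
    seqs: dict[str, str] = {}
    counter = 0
    for target in config.ks_targets:
        if target < 0:
            raise GenerationError("negative Ks target")
        p_diff = 0.75 * (1.0 - math.exp(-4.0 * target / 3.0))
        if p_diff >= 0.75:
            raise GenerationError(
                f"target {target} implies pS >= 3/4; Jukes-Cantor "
                "correction undefined")
        for _ in range(pairs_per_target):
            counter += 1
            pair_id = f"pair{counter:04d}"
            prefixes = rng.choice(len(FOURFOLD_PREFIXES), size=n_codons)
            thirds = rng.choice(list(_BASES), size=n_codons)
            codons1 = [FOURFOLD_PREFIXES[p] + t
                       for p, t in zip(prefixes, thirds)]
            codons2 = list(codons1)
            for i in range(n_codons):
                if rng.random() < p_diff:
                    others = [b for b in _BASES if b != codons1[i][2]]
                    codons2[i] = codons1[i][:2] + others[rng.integers(3)]
            name1, name2 = f"{pair_id}_a", f"{pair_id}_b"
            seqs[name1] = "".join(codons1)
            seqs[name2] = "".join(codons2)
            rows.append({"pair_id": pair_id, "gene1": name1, "gene2": name2,
                         "target_ks": target})
    return CdsPairSet(pairs=pd.DataFrame(rows), sequences=seqs)


@dataclass
class CountSet:
    """Generated count matrix with design, lengths and planted effects."""

    counts: pd.DataFrame  # genes x samples
    design: pd.DataFrame  # sample, condition, time, replicate
    lengths: pd.Series
    effects: pd.DataFrame  # gene, condition, log2fc

    def write(self, counts_path, design_path, lengths_path,
              effects_path=None):
        self.counts.to_csv(counts_path, sep="\t")
        self.design.to_csv(design_path, sep="\t", index=False)
        self.lengths.rename("length").to_csv(lengths_path, sep="\t")
        if effects_path is not None:
            self.effects.to_csv(effects_path, sep="\t", index=False)


def resolved_de_effects(config: TruthConfig, truth: TruthTable
                        ) -> list[tuple[str, str, float]]:
    """Planted differential-expression effects, keyed by ortholog group
    (shared across species) or by gene id (species-specific genes).

    When the config lists explicit effects they are returned verbatim;
    otherwise ~15% of family subjects receive a |log2FC| in {2, 3} per
    stress condition, drawn deterministically from the config seed.
    """
    if config.de_effects is not None:
        return [tuple(e) for e in config.de_effects]
    rng = np.random.default_rng([config.seed, _STREAM_EFFECTS])
    fam = truth.family_genes()
    subjects = sorted(set(fam.loc[fam["ortholog_group"] != "",
                                  "ortholog_group"]))
    first = config.species_names[0]
    subjects += list(fam[(fam["species"] == first)
                         & (fam["ortholog_group"] == "")]["gene"])
    effects = []
    for cond in config.conditions:
        for subject in subjects:
            if rng.random() < 0.15:
                lfc = float(rng.choice([-3.0, -2.0, 2.0, 3.0]))
                effects.append((subject, cond, lfc))
    return effects


def generate_counts(config: TruthConfig, truth: TruthTable,
                    species: str | None = None,
                    time_course: bool | None = None) -> CountSet:
    """Negative-binomial count matrix with planted fold changes.

    The first species gets the full stress x time-point x replicate layout
    (control carries the same layout so contrasts pool matched samples);
    other species default to a single unspecified time point per condition.
    """
    if config.replicates < 2:
        raise ConfigurationError("replicates must be >= 2")
    species = species or config.species_names[0]
    if species not in config.species_names:
        raise ConsistencyError(f"unknown species {species!r}")
    sp_index = config.species_names.index(species)
    if time_course is None:
        time_course = sp_index == 0
    rng = np.random.default_rng([config.seed, _STREAM_COUNTS, sp_index])

    genes = truth.genes[truth.genes["species"] == species]
    genes = genes.sort_values(["chromosome", "rank"])
    gene_ids = list(genes["gene"])
    lengths = pd.Series((genes["end"] - genes["start"] + 1).to_numpy(),
                        index=gene_ids, name="length")
    if (lengths <= 0).any():
        raise ConsistencyError("non-positive gene length")

    effects = resolved_de_effects(config, truth)
    key_of = dict(zip(genes["gene"],
                      np.where(genes["ortholog_group"] != "",
                               genes["ortholog_group"], genes["gene"])))
    lfc_map: dict[tuple[str, str], float] = {}
    for subject, cond, lfc in effects:
        lfc_map[(subject, cond)] = float(lfc)

    times = list(config.time_points) if time_course else [0]
    conditions = ["control", *config.conditions]
    samples = []
    for cond in conditions:
        for t in times:
            for r in range(1, config.replicates + 1):
                name = (f"{cond}_t{t}_r{r}" if time_course
                        else f"{cond}_r{r}")
                samples.append({"sample": name, "condition": cond,
                                "time": t, "replicate": r})
    design = pd.DataFrame(samples)

    baseline = rng.lognormal(mean=math.log(300.0), sigma=1.0,
                             size=len(gene_ids))
    lib_factor = rng.lognormal(mean=0.0, sigma=0.1, size=len(design))
    r_nb = 1.0 / config.dispersion
    effect_rows = []
    matrix = np.zeros((len(gene_ids), len(design)), dtype=np.int64)
    fold = np.ones((len(gene_ids), len(conditions)))
    for gi, gene in enumerate(gene_ids):
        for ci, cond in enumerate(conditions):
            lfc = lfc_map.get((key_of[gene], cond))
            if lfc is not None and cond != "control":
                fold[gi, ci] = 2.0 ** lfc
                effect_rows.append({"gene": gene, "condition": cond,
                                    "log2fc": lfc})
    cond_index = {c: i for i, c in enumerate(conditions)}
    for si, sample in design.iterrows():
        ci = cond_index[sample["condition"]]
        mean = baseline * fold[:, ci] * lib_factor[si]
        p = r_nb / (r_nb + mean)
        matrix[:, si] = rng.negative_binomial(r_nb, p)
    counts = pd.DataFrame(matrix, index=pd.Index(gene_ids, name="gene"),
                          columns=design["sample"])
    effects_df = pd.DataFrame(effect_rows,
                              columns=["gene", "condition", "log2fc"])
    return CountSet(counts=counts, design=design, lengths=lengths,
                    effects=effects_df)


def generate_go_annotations(truth: TruthTable, species: str | None = None,
                            enriched_term: str = "GO:0050794",
                            enriched_subgroup: str = "B2",
                            background_rate: float = 0.1,
                            n_background_terms: int = 15) -> pd.DataFrame:
    """Gene -> GO-term table with one planted enriched term.

    Every family gene of ``enriched_subgroup`` is annotated with
    ``enriched_term``; generic background terms are assigned to all genes at
    a uniform rate.
    """
    if truth.genes.empty:
        raise ConsistencyError("empty truth table")
    config = truth.config
    species = species or config.species_names[0]
    rng = np.random.default_rng([config.seed, _STREAM_GO])
    genes = truth.genes[truth.genes["species"] == species]
    rows = []
    bg_terms = [f"GO:{7000000 + i}" for i in range(n_background_terms)]
    for _, row in genes.iterrows():
        if row["is_family"] and row["subgroup"] == enriched_subgroup:
            rows.append({"gene": row["gene"], "go_id": enriched_term})
        for term in bg_terms:
            if rng.random() < background_rate:
                rows.append({"gene": row["gene"], "go_id": term})
    return pd.DataFrame(rows, columns=["gene", "go_id"])


def generate_profile_shapes(n_per_cluster: int = 25, n_time: int = 5,
                            noise: float = 0.05, seed: int = 0
                            ) -> tuple[pd.DataFrame, pd.Series]:
    """Four well-separated time-course shapes for clustering checks.

    Shapes: monotone induction, monotone repression, transient peak,
    transient dip; Gaussian noise of scale ``noise`` is added per point.
    """
    rng = np.random.default_rng([seed, 7])
    t = np.linspace(0.0, 1.0, n_time)
    shapes = np.stack([
        2.0 * t - 1.0,
        1.0 - 2.0 * t,
        np.sin(np.pi * t) * 2.0 - 1.0,
        1.0 - 2.0 * np.sin(np.pi * t),
    ])
    rows, labels, names = [], [], []
    for k in range(4):
        for i in range(n_per_cluster):
            rows.append(shapes[k] + rng.normal(0.0, noise, size=n_time))
            labels.append(k)
            names.append(f"g{k}_{i}")
    X = pd.DataFrame(rows, index=names,
                     columns=[f"t{i}" for i in range(n_time)])
    return X, pd.Series(labels, index=names, name="cluster")
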