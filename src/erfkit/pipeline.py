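"""End-to-end orchestration: scan -> classify -> conserve -> compare -> ks
-> express, with a manifest of checksummed outputs.

The pipeline consumes per-species protein FASTA + InterProScan-style TSV +
GFF3 files, a FASTA of duplicate CDS pairs, and a count matrix with its
design/length/GO tables; every stage writes plain TSV outputs into the run
directory and records a sha256 checksum plus row count in the manifest, so
a rerun with the same inputs and seed is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .align import align_to_model
from .classify import ClassifierConfig, calls_to_frame, classify_gene
from .comparative import (collinear_blocks, rbh_orthologs, read_gff3_loci,
                          specificity_status, tandem_arrays)
from .conservation import column_frequencies, divisions
from .domains import architectures_from_hits, parse_interproscan_tsv
from .expression import (ExpressionMatrix, call_degs, cluster_profiles,
                         fpkm, go_enrichment,
                         ortholog_expression_correlation)
from .ksdating import classify_recency, ng86_ks


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending record."""


@dataclass
class SpeciesInputs:
    proteins: Path
    domains: Path
    gff3: Path


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run."""

    outdir: Path
    species: dict[str, SpeciesInputs]
    cds_pairs: Path | None = None
    counts: Path | None = None
    design: Path | None = None
    lengths: Path | None = None
    go_annotations: Path | None = None
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    evalue_cutoff: float = 1e-5
    ks_thresholds: tuple[float, float] = (0.3, 0.1)
    ks_retention: float = 3.0
    deg_lfc: float = 1.0
    deg_alpha: float = 0.05
    enrichment_fdr: float = 0.01
    min_block: int = 5
    max_rank_gap: int = 25
    max_gene_gap: int = 10
    n_clusters: int = 4
    seed: int = 0

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)

        def convert(value):
            if isinstance(value, Path):
                return str(value)
            if isinstance(value, dict):
                return {k: convert(v) for k, v in value.items()}
            if isinstance(value, (list, tuple)):
                return [convert(v) for v in value]
            return value

        return convert(out)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        data["outdir"] = Path(data["outdir"])
        data["species"] = {
            sp: SpeciesInputs(**{k: Path(v) for k, v in paths.items()})
            for sp, paths in data["species"].items()}
        for key in ("cds_pairs", "counts", "design", "lengths",
                    "go_annotations"):
            if data.get(key):
                data[key] = Path(data[key])
        if isinstance(data.get("classifier"), dict):
            cc = dict(data["classifier"])
            for tup in ("erf_pattern", "dreb_pattern", "key_columns"):
                if tup in cc:
                    cc[tup] = tuple(cc[tup])
            if "subgroup_key" in cc:
                cc["subgroup_key"] = {k: tuple(v)
                                      for k, v in cc["subgroup_key"].items()}
            data["classifier"] = ClassifierConfig(**cc)
        for tup in ("ks_thresholds",):
            if tup in data:
                data[tup] = tuple(data[tup])
        return cls(**data)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict, stage: str,
           index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
    manifest["stages"][stage]["outputs"][path.name] = _sha256(path)
    manifest["stages"][stage]["rows"][path.name] = int(len(df))


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order; returns (and writes) the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "version": __version__,
                      "stages": {}}

    def stage(name):
        manifest["stages"][name] = {"outputs": {}, "rows": {}}
        return name

    for sp, inputs in config.species.items():
        for label in ("proteins", "domains", "gff3"):
            path = getattr(inputs, label)
            if not Path(path).exists():
                stage_name = "comparative" if label == "gff3" else "scan"
                raise PipelineError(
                    f"stage {stage_name}: missing {label} file for "
                    f"species {sp!r}: {path}")

    # --- scan ------------------------------------------------------------
    name = stage("scan")
    sequences: dict[str, dict[str, str]] = {}
    architectures: dict[str, dict] = {}
    arch_rows = []
    for sp, inputs in config.species.items():
        sequences[sp] = {rec.id: str(rec.seq)
                         for rec in SeqIO.parse(str(inputs.proteins), "fasta")}
        try:
            hits = parse_interproscan_tsv(inputs.domains)
        except Exception as exc:
            raise PipelineError(f"stage scan: {inputs.domains}: {exc}") from exc
        archs = architectures_from_hits(hits)
        architectures[sp] = {g: a for g, a in archs.items() if a.is_family}
        for gene, arch in sorted(architectures[sp].items()):
            for hit in arch.hits:
                arch_rows.append({"species": sp, "gene": gene,
                                  "kind": hit.kind, "start": hit.start,
                                  "end": hit.end, "evalue": hit.evalue})
    _write(pd.DataFrame(arch_rows), outdir / "architectures.tsv", manifest,
           name)

    # --- classify --------------------------------------------------------
    name = stage("classify")
    calls: dict[str, dict] = {}
    frames = []
    aligned_domains: dict[str, str] = {}
    for sp in config.species:
        sp_calls = {}
        for gene, arch in sorted(architectures[sp].items()):
            if gene not in sequences[sp]:
                raise PipelineError(f"stage classify: {gene} has domain hits "
                                    "but no protein sequence")
            if arch.n_ap2 == 0:
                continue  # B3-only: logged as dropped below
            call = classify_gene(arch, sequences[sp][gene],
                                 config.classifier)
            sp_calls[gene] = call
            first = next(h for h in arch.hits if h.kind == "AP2")
            aligned_domains[gene] = align_to_model(
                sequences[sp][gene][first.start - 1:first.end]).model_residues
        calls[sp] = sp_calls
        frame = calls_to_frame(list(sp_calls.values()))
        frame.insert(0, "species", sp)
        frames.append(frame)
    calls_df = pd.concat(frames, ignore_index=True)
    _write(calls_df, outdir / "family_calls.tsv", manifest, name)

    # --- conserve --------------------------------------------------------
    name = stage("conserve")
    aligned = [aligned_domains[g] for g in sorted(aligned_domains)]
    profile = column_frequencies(aligned)
    _write(profile.to_frame(), outdir / "conservation_columns.tsv",
           manifest, name)
    ratios = profile.division_ratios(divisions(profile.width))
    _write(pd.DataFrame({"division": list(ratios),
                         "consensus_ratio": list(ratios.values())}),
           outdir / "conservation_divisions.tsv", manifest, name)

    # --- comparative -----------------------------------------------------
    name = stage("comparative")
    loci = {}
    for sp, inputs in config.species.items():
        try:
            loci[sp] = {l.gene: l for l in read_gff3_loci(inputs.gff3, sp)}
        except Exception as exc:
            raise PipelineError(
                f"stage comparative: {inputs.gff3}: {exc}") from exc
    species_list = list(config.species)
    family_proteomes = {sp: {g: sequences[sp][g] for g in calls[sp]}
                        for sp in species_list}
    pair_rows, block_rows = [], []
    blocks_by_pair = {}
    for i in range(len(species_list)):
        for j in range(i + 1, len(species_list)):
            sp_a, sp_b = species_list[i], species_list[j]
            pairs = rbh_orthologs(family_proteomes[sp_a],
                                  family_proteomes[sp_b])
            blocks = collinear_blocks(pairs, loci[sp_a], loci[sp_b],
                                      min_block=config.min_block,
                                      max_rank_gap=config.max_rank_gap)
            blocks_by_pair[(sp_a, sp_b)] = blocks
            for a, b, score in pairs:
                pair_rows.append({"species_a": sp_a, "species_b": sp_b,
                                  "gene_a": a, "gene_b": b, "score": score})
            for block in blocks:
                for a, b in block.pairs:
                    block_rows.append({"block": block.block_id,
                                       "species_a": sp_a, "species_b": sp_b,
                                       "gene_a": a, "gene_b": b})
    _write(pd.DataFrame(pair_rows), outdir / "ortholog_pairs.tsv",
           manifest, name)
    _write(pd.DataFrame(block_rows), outdir / "collinear_blocks.tsv",
           manifest, name)
    status_df = pd.DataFrame()
    if len(species_list) == 3:
        status_df = specificity_status(
            blocks_by_pair, {sp: sorted(calls[sp]) for sp in species_list})
        _write(status_df, outdir / "specificity.tsv", manifest, name)
    tandem_rows = []
    for sp in species_list:
        subgroup_of = {g: c.subgroup for g, c in calls[sp].items()}
        for array in tandem_arrays(subgroup_of, loci[sp],
                                   max_gene_gap=config.max_gene_gap):
            tandem_rows.append({"species": sp,
                                "chromosome": array.chromosome,
                                "subgroup": array.subgroup,
                                "size": len(array),
                                "genes": ",".join(array.genes)})
    _write(pd.DataFrame(tandem_rows), outdir / "tandem_arrays.tsv",
           manifest, name)

    # --- ks --------------------------------------------------------------
    name = stage("ks")
    ks_rows = []
    if config.cds_pairs is not None:
        cds = {rec.id: str(rec.seq)
               for rec in SeqIO.parse(str(config.cds_pairs), "fasta")}
        prefixes = sorted({gid[:-2] for gid in cds
                           if gid.endswith(("_a", "_b"))})
        for prefix in prefixes:
            g1, g2 = f"{prefix}_a", f"{prefix}_b"
            if g1 not in cds or g2 not in cds:
                raise PipelineError(f"stage ks: incomplete pair {prefix!r}")
            try:
                est = ng86_ks(cds[g1], cds[g2], g1, g2)
            except ValueError as exc:
                raise PipelineError(f"stage ks: {prefix}: {exc}") from exc
            ks = est.ks
            rec = (classify_recency(ks, thresholds=config.ks_thresholds,
                                    retention=config.ks_retention)
                   if ks is not None else None)
            ks_rows.append({
                "gene1": g1, "gene2": g2, "S": est.s_sites, "N": est.n_sites,
                "sd": est.syn_diff, "pS": est.ps,
                "Ks": ks if ks is not None else np.nan,
                "recency": rec.recency if rec else "undefined",
                "retained": rec.retained if rec else False,
            })
    _write(pd.DataFrame(ks_rows), outdir / "ks_estimates.tsv", manifest, name)

    # --- expression ------------------------------------------------------
    name = stage("expression")
    deg_frames = []
    cluster_frames = []
    enrich_frames = []
    if config.counts is not None:
        try:
            counts = pd.read_csv(config.counts, sep="\t", index_col=0)
            design = pd.read_csv(config.design, sep="\t")
            lengths = pd.read_csv(config.lengths, sep="\t",
                                  index_col=0)["length"]
        except Exception as exc:
            raise PipelineError(f"stage expression: {exc}") from exc
        matrix = ExpressionMatrix(counts=counts, lengths=lengths,
                                  design=design)
        values = fpkm(matrix)
        annotations = None
        if config.go_annotations is not None:
            annotations = pd.read_csv(config.go_annotations, sep="\t")
        conditions = [c for c in design["condition"].unique()
                      if c != "control"]
        times = sorted(design.loc[design["condition"] != "control",
                                  "time"].unique())
        for cond in conditions:
            degs = call_degs(matrix, cond, lfc_threshold=config.deg_lfc,
                             alpha=config.deg_alpha)
            degs = degs.reset_index()
            deg_frames.append(degs)
            called = degs.loc[degs["call"] != "none", "gene"]
            if len(called) >= config.n_clusters and len(times) > 1:
                profile_cols = []
                for t in times:
                    samples = design.loc[(design["condition"] == cond)
                                         & (design["time"] == t), "sample"]
                    profile_cols.append(values.loc[called,
                                                   list(samples)].mean(axis=1))
                profiles = pd.concat(profile_cols, axis=1)
                profiles.columns = [f"t{t}" for t in times]
                members, _, _ = cluster_profiles(
                    profiles, k=config.n_clusters, seed=config.seed)
                members = members.reset_index(names="gene")
                members.insert(0, "condition", cond)
                cluster_frames.append(members)
                if annotations is not None:
                    for cl in sorted(members["cluster"].unique()):
                        cluster_genes = members.loc[members["cluster"] == cl,
                                                    "gene"]
                        enr = go_enrichment(cluster_genes, counts.index,
                                            annotations,
                                            fdr=config.enrichment_fdr)
                        enr.insert(0, "cluster", cl)
                        enr.insert(0, "condition", cond)
                        enrich_frames.append(enr.head(5))
    for frames_list, fname in ((deg_frames, "degs.tsv"),
                               (cluster_frames, "deg_clusters.tsv"),
                               (enrich_frames, "go_enrichment.tsv")):
        df = (pd.concat(frames_list, ignore_index=True)
              if frames_list else pd.DataFrame())
        _write(df, outdir / fname, manifest, name)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def annotation_summary(table: pd.DataFrame) -> dict:
    """Totals and derived percentages for a per-species annotation table.

    ``table`` needs columns ``species``, ``previously_annotated`` and
    ``newly_annotated``.  Returns the grand totals, the share of newly
    annotated genes (percent, rounded to the nearest integer as it would be
    reported), and the per-species min/max totals.
    """
    required = {"species", "previously_annotated", "newly_annotated"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    totals = table["previously_annotated"] + table["newly_annotated"]
    prev_total = int(table["previously_annotated"].sum())
    new_total = int(table["newly_annotated"].sum())
    grand = prev_total + new_total
    return {
        "previously_annotated_total": prev_total,
        "newly_annotated_total": new_total,
        "grand_total": grand,
        "newly_annotated_pct": round(100.0 * new_total / grand),
        "min_species_total": int(totals.min()),
        "max_species_total": int(totals.max()),
        "n_species": int(len(table)),
    }


def summarize(outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Summary count tables from a completed run directory."""
    outdir = Path(outdir)
    calls = pd.read_csv(outdir / "family_calls.tsv", sep="\t")
    out: dict[str, pd.DataFrame] = {}
    out["subfamily_counts"] = (calls.groupby(["species", "subfamily"])
                               .size().unstack(fill_value=0))
    out["subfamily_proportions"] = out["subfamily_counts"].div(
        out["subfamily_counts"].sum(axis=1), axis=0)
    out["subgroup_counts"] = (calls.groupby(["species", "subgroup"])
                              .size().unstack(fill_value=0))
    spec_path = outdir / "specificity.tsv"
    if spec_path.exists():
        status = pd.read_csv(spec_path, sep="\t")
        out["specificity_counts"] = (status.groupby(["species", "status"])
                                     .size().unstack(fill_value=0))
    ks_path = outdir / "ks_estimates.tsv"
    if ks_path.exists():
        ks = pd.read_csv(ks_path, sep="\t")
        if len(ks):
            retained = ks[ks["Ks"] < 3.0]["Ks"].dropna()
            bins = np.arange(0.0, 3.0 + 0.05, 0.05)
            hist, edges = np.histogram(retained, bins=bins)
            out["ks_histogram"] = pd.DataFrame({
                "bin_left": edges[:-1], "bin_right": edges[1:],
                "count": hist})
    degs_path = outdir / "degs.tsv"
    if degs_path.exists():
        degs = pd.read_csv(degs_path, sep="\t")
        if len(degs):
            called = degs[degs["call"] != "none"]
            out["deg_counts"] = (called.groupby(["condition", "call"])
                                 .size().unstack(fill_value=0))
    return out
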