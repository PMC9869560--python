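"""Write a full synthetic input set and the matching pipeline RunConfig."""

from __future__ import annotations

from pathlib import Path

from .pipeline import RunConfig, SpeciesInputs
from .synthetic import (TruthConfig, TruthTable, generate_cds_pairs,
                        generate_counts, generate_gene_models,
                        generate_go_annotations, generate_proteomes,
                        write_gff3)


def simulate_run_inputs(config: TruthConfig, outdir: str | Path,
                        run_dir: str | Path | None = None
                        ) -> tuple[RunConfig, TruthTable]:
    """Generate and write every pipeline input under ``outdir``.

    Emits per-species proteins/domain-hits/GFF3, a CDS-pair FASTA, the
    first species' count matrix with design and lengths, and GO
    annotations; returns a ready :class:`RunConfig` plus the truth table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteomes = generate_proteomes(config)
    paths = proteomes.write(outdir)
    truth = proteomes.truth
    models = generate_gene_models(config, truth)
    species_inputs = {}
    for sp in config.species_names:
        gff = write_gff3(models[sp], outdir / f"{sp}.gff3")
        species_inputs[sp] = SpeciesInputs(proteins=paths[sp]["proteins"],
                                           domains=paths[sp]["domains"],
                                           gff3=gff)
    pair_set = generate_cds_pairs(config, pairs_per_target=3)
    cds_path = outdir / "cds_pairs.fasta"
    pair_set.write(cds_path, outdir / "cds_pairs.truth.tsv")
    counts = generate_counts(config, truth)
    counts.write(outdir / "counts.tsv", outdir / "design.tsv",
                 outdir / "lengths.tsv", outdir / "effects.truth.tsv")
    go = generate_go_annotations(truth)
    go_path = outdir / "go_annotations.tsv"
    go.to_csv(go_path, sep="\t", index=False)
    truth.genes.to_csv(outdir / "genes.truth.tsv", sep="\t", index=False)
    truth.domains.to_csv(outdir / "domains.truth.tsv", sep="\t", index=False)
    run_config = RunConfig(
        outdir=Path(run_dir) if run_dir is not None else outdir / "run",
        species=species_inputs,
        cds_pairs=cds_path,
        counts=outdir / "counts.tsv",
        design=outdir / "design.tsv",
        lengths=outdir / "lengths.tsv",
        go_annotations=go_path,
        seed=config.seed,
    )
    return run_config, truth
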