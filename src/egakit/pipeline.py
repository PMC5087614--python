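"""End-to-end pipeline on synthetic data: simulate -> DE -> targets ->
overlap -> motif, with a reproducibility manifest.

Every stage's randomness derives from ``RunConfig.seed`` through labelled
sub-streams, so a rerun with the same config writes byte-identical tables.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import io
from .config import RunConfig
from .motif import extract_promoters, motif_enrichment
from .overlap import multi_dataset_overlap, venn_counts
from .simulate import (
    plant_motifs,
    simulate_embryo_profiles,
    simulate_experiment,
    simulate_genome_annotation,
    synthetic_ega_motif,
)
from .targets import intersect_calls, run_comparisons, summarize_regions
from .tfe import tfe_to_gene
from .utils import child_seed

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    pass


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run all stages on a fresh synthetic experiment; returns in-memory
    results and writes result tables plus a manifest under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    manifest = {"config": config.to_dict(), "stages": []}
    stage = "simulate"
    try:
        cfg = config.sim
        annotation = simulate_genome_annotation(cfg)
        utr5_ids = [t.id for t in annotation.tfes if t.category == "utr5_coding"]
        matrix, sheet, truth = simulate_experiment(
            cfg, tfe_ids=[t.id for t in annotation.tfes], planting_pool=utr5_ids
        )
        tfe_gene = dict(zip(annotation.tss_table["tfe_id"], annotation.tss_table["gene_id"]))
        first = config.constructs[0]
        planted_genes = {tfe_gene[t] for t in truth.planted_up.get(first, set()) if tfe_gene.get(t)}
        profiles, activated = simulate_embryo_profiles(
            cfg,
            gene_ids=[g.gene_id for g in annotation.genes if g.biotype == "coding"],
            planted_targets=planted_genes,
        )
        truth.planted_activated["4cell_to_8cell"] = activated
        io.write_count_matrix(matrix, out / "counts.tsv")
        io.write_sample_sheet(sheet, out / "samples.tsv")
        io.write_tfe_bed(annotation.tfes, out / "tfes.bed")
        io.write_gene_models_bed12(annotation.genes, out / "genes.bed")
        profiles.to_csv(out / "embryo_profiles.tsv", sep="\t")
        truth.to_json(out / "truth.json")
        manifest["stages"].append({"name": stage, "rows": int(matrix.counts.shape[0])})
        results.update(matrix=matrix, sheet=sheet, truth=truth, annotation=annotation,
                       profiles=profiles, activated=activated)

        stage = "de"
        target_sets = {}
        de_rows = 0
        for construct in config.constructs:
            comparisons = run_comparisons(
                matrix, sheet, construct,
                D=config.n_resamplings, B=config.n_permutations,
                seed=child_seed(config.seed, "de", construct),
            )
            for name, res in comparisons.items():
                res.table.to_csv(out / f"de_{construct}_{name}.tsv", sep="\t")
                de_rows += len(res.table)
            stage = "targets"
            ts = intersect_calls(
                comparisons, tfes=annotation.tfes, q_threshold=config.q_threshold,
                construct=construct,
                require_direction_concordance=config.require_direction_concordance,
            )
            target_sets[construct] = ts
            rows = [{"gene_id": g, "direction": "up"} for g in sorted(ts.up)]
            rows += [{"gene_id": g, "direction": "down"} for g in sorted(ts.down)]
            pd.DataFrame(rows, columns=["gene_id", "direction"]).to_csv(
                out / f"targets_{construct}.tsv", sep="\t", index=False
            )
            summarize_regions(ts, annotation.tfes).to_csv(
                out / f"regions_{construct}.tsv", sep="\t"
            )
        manifest["stages"].append({"name": "de", "rows": de_rows})
        manifest["stages"].append(
            {"name": "targets",
             "targets": {c: {"up": len(t.up), "down": len(t.down)} for c, t in target_sets.items()}}
        )
        results["target_sets"] = target_sets

        stage = "overlap"
        detected = set(matrix.counts.sum(axis=1)[lambda s: s > 0].index)
        annotated = {t.id: t for t in annotation.tfes}
        universe = tfe_to_gene(
            [annotated[i] for i in detected if i in annotated], restrict=("utr5_coding",)
        )
        named_sets = {}
        for c, ts in target_sets.items():
            named_sets[f"{c}_up"] = ts.up & universe
            named_sets[f"{c}_down"] = ts.down & universe
        overlap_table = multi_dataset_overlap(
            named_sets, {"embryo_sim": activated & universe}, universe,
            alpha=config.overlap_alpha,
        )
        overlap_table.to_csv(out / "overlap.tsv", sep="\t", index=False)
        second = config.constructs[1] if len(config.constructs) > 1 else first
        venn = venn_counts(
            target_sets[first].up,
            target_sets[second].down if second != first else set(),
            activated,
        )
        io.write_json(venn, out / "venn.json")
        manifest["stages"].append({"name": stage, "tests": len(overlap_table)})
        results.update(overlap=overlap_table, venn=venn, universe=universe)

        stage = "motif"
        pwm = synthetic_ega_motif()
        io.write_meme_motif(pwm, out / "motif.meme")
        utr5_tfes = [t for t in annotation.tfes if t.category == "utr5_coding"]
        promoters = extract_promoters(
            utr5_tfes, annotation.sequences,
            upstream=config.window_upstream, downstream=config.window_downstream,
        )
        planted_ids = truth.planted_up.get(first, set())
        promoters, occurrences = plant_motifs(
            promoters, pwm, cfg.motif_rate_target, cfg.motif_rate_background,
            planted_ids, seed=child_seed(config.seed, "motif_plant"),
        )
        truth.motif_occurrences = occurrences
        truth.to_json(out / "truth.json")  # rewrite with occurrences
        recovered = target_sets[first].up_tfes
        target_windows = [w for w in promoters if w.id in recovered]
        control_windows = [w for w in promoters if w.id not in planted_ids and w.id not in recovered]
        if target_windows:
            report = motif_enrichment(
                target_windows, control_windows, pwm,
                p_threshold=config.motif_p_threshold,
                seed=child_seed(config.seed, "motif_enrich"),
            )
            io.write_json(report.to_dict(), out / "motif_enrichment.json")
            report.sweep.to_csv(out / "motif_sweep.tsv", sep="\t", index=False)
            results["motif_report"] = report
        manifest["stages"].append({"name": stage, "target_windows": len(target_windows)})
    except Exception as exc:
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["seed"] = config.seed
    manifest["versions"] = _versions()
    io.write_json(manifest, out / "manifest.json")
    results["manifest"] = manifest
    return results


def _versions() -> dict:
    import numpy, pandas, scipy  # noqa: PLC0415

    from . import __version__

    return {
        "egakit": __version__,
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "scipy": scipy.__version__,
    }
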