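"""End-to-end orchestration: simulate/load -> filter -> stats/tree -> scan -> ssr.

Every run writes a manifest listing each produced file with its SHA-256
hash plus the variant-count funnel after each filtering stage, so that two
runs with the same config and seed can be diffed at a glance (they are
byte-identical).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity_stats, divergence_scan, io_formats, phylogeny, ssr_mining
from .divergence_scan import Contrast
from .synthetic_data import SimConfig, generate_dataset
from .variant_filtering import FilterParams, LdParams, filter_sites, ld_prune

log = logging.getLogger("popscan")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (simulated or provided inputs)."""

    outdir: Path
    sim: SimConfig | None = None
    vcf: Path | None = None
    fasta: Path | None = None
    gff: Path | None = None
    assignments: Path | None = None
    filter_params: FilterParams = field(default_factory=FilterParams)
    ld_params: LdParams = field(default_factory=LdParams)
    window: int = diversity_stats.DEFAULT_WINDOW
    step: int = diversity_stats.DEFAULT_STEP
    contrasts: list[Contrast] = field(default_factory=list)
    bootstrap_reps: int = 200
    seed: int = 0
    outgroup: str | None = None
    locus: str | None = None

    def __post_init__(self) -> None:
        if self.sim is None and self.vcf is None:
            raise ValueError("config needs either a SimConfig or an input VCF")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages in dependency order; return (and write) the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    counts: dict[str, int] = {}
    stage = "setup"
    try:
        # -- simulate or load --------------------------------------------
        if config.sim is not None:
            stage = "simulate"
            paths = generate_dataset(config.sim, outdir / "sim")
            vcf_path = paths["vcf"]
            fasta_path = paths["fasta"]
            gff_path = paths["gff"]
            assign_path = paths["assignments"]
            outputs.update({f"sim_{k}": v for k, v in paths.items()})
        else:
            vcf_path = Path(config.vcf)
            fasta_path = Path(config.fasta) if config.fasta else None
            gff_path = Path(config.gff) if config.gff else None
            assign_path = Path(config.assignments) if config.assignments else None

        stage = "load"
        dataset = io_formats.read_vcf(vcf_path)
        counts["input_sites"] = dataset.n_sites
        log.info("loaded %d sites x %d samples", dataset.n_sites, dataset.n_samples)

        # -- filter -------------------------------------------------------
        stage = "filter"
        filtered, report = filter_sites(dataset, config.filter_params)
        counts["after_site_filters"] = filtered.n_sites
        for rule, n in report.removed.items():
            counts[f"removed_{rule}"] = n
        keep = ld_prune(filtered, config.ld_params)
        pruned = filtered.take_sites(keep)
        counts["after_ld_prune"] = pruned.n_sites
        log.info(
            "filter funnel: %d -> %d (site filters) -> %d (LD prune)",
            dataset.n_sites,
            filtered.n_sites,
            pruned.n_sites,
        )
        outputs["filtered_vcf"] = outdir / "filtered.vcf"
        io_formats.write_vcf(pruned, outputs["filtered_vcf"])
        outputs["filter_report"] = outdir / "filter_report.tsv"
        pd.DataFrame(report.as_rows(), columns=["metric", "count"]).to_csv(
            outputs["filter_report"], sep="\t", index=False
        )

        # -- diversity stats ----------------------------------------------
        stage = "stats"
        windows = diversity_stats.windowed_pi(pruned, config.window, config.step)
        outputs["windows_pi"] = outdir / "windows_pi.tsv"
        pd.DataFrame(
            [
                (w.interval.chrom, w.interval.start, w.interval.end, w.n_snps, w.pi)
                for w in windows
            ],
            columns=["chrom", "start", "end", "n_snps", "pi"],
        ).to_csv(outputs["windows_pi"], sep="\t", index=False, float_format="%.8g")
        het = diversity_stats.all_individual_f(pruned)
        outputs["samples_f"] = outdir / "samples_f.tsv"
        pd.DataFrame(
            [(h.sample, h.observed_hom, h.expected_hom, h.n_sites, h.f_is) for h in het],
            columns=["sample", "obs_hom", "exp_hom", "n_sites", "f_is"],
        ).to_csv(outputs["samples_f"], sep="\t", index=False, float_format="%.6f")
        if assign_path is not None:
            assignments = io_formats.read_assignments(assign_path)
            summary = diversity_stats.cluster_summary(
                pruned, assignments, config.window, config.step
            )
            outputs["cluster_summary"] = outdir / "cluster_summary.tsv"
            pd.DataFrame(summary).T.to_csv(
                outputs["cluster_summary"], sep="\t", float_format="%.6g"
            )

        # -- phylogeny ------------------------------------------------------
        stage = "tree"
        if pruned.n_samples >= 4:
            dm = phylogeny.p_distance(pruned)
            outputs["distances"] = outdir / "distances.phy"
            dm.to_phylip(outputs["distances"])
            tree = phylogeny.bootstrap_support(
                pruned, n_reps=config.bootstrap_reps, seed=config.seed
            )
            if config.outgroup:
                tree = phylogeny.root_with_outgroup(tree, config.outgroup)
            outputs["tree"] = outdir / "tree.nwk"
            io_formats.write_newick(tree, outputs["tree"])
        else:
            log.info("tree stage skipped: fewer than 4 samples")

        # -- divergence scan ------------------------------------------------
        stage = "scan"
        if config.contrasts:
            per_contrast = {}
            for contrast in config.contrasts:
                w = divergence_scan.windowed_fst(
                    pruned, contrast, config.window, config.step
                )
                tops = divergence_scan.quantile_thresholds(w)
                regions = divergence_scan.build_outlier_regions(
                    w, tops[0.99].members, tops[0.95].members, contrast.name
                )
                per_contrast[contrast.name] = (w, tops, regions)
                counts[f"regions_{contrast.name}"] = len(regions)
                key = f"windows_fst_{contrast.name}"
                outputs[key] = outdir / f"{key}.tsv"
                pd.DataFrame(
                    [
                        (x.interval.chrom, x.interval.start, x.interval.end, x.n_snps, x.fst)
                        for x in w
                    ],
                    columns=["chrom", "start", "end", "n_snps", "fst"],
                ).to_csv(outputs[key], sep="\t", index=False, float_format="%.8g")
                key = f"regions_{contrast.name}"
                outputs[key] = outdir / f"{key}.bed"
                io_formats.write_bed(
                    [(r.interval, f"{contrast.name};max_fst={r.max_fst:.4f}") for r in regions],
                    outputs[key],
                )
            if len(config.contrasts) == 2:
                (wa, ta, ra), (wb, tb, rb) = (
                    per_contrast[c.name] for c in config.contrasts
                )
                tiered = divergence_scan.cross_compare(ra, rb, wa, wb, ta, tb)
                counts["tiered_candidates"] = sum(1 for t in tiered if t.tier)
                outputs["candidates"] = outdir / "candidates.bed"
                io_formats.write_bed(
                    [
                        (t.interval, f"tier={t.tier if t.tier else 'NA'}")
                        for t in tiered
                    ],
                    outputs["candidates"],
                )
                if gff_path is not None:
                    genes = io_formats.read_gff(gff_path)
                    all_regions = ra + rb
                    divergence_scan.intersect_genes(all_regions, genes)
                    outputs["candidate_genes"] = outdir / "candidate_genes.tsv"
                    rows = []
                    for r in all_regions:
                        for g in r.genes:
                            rows.append(
                                (
                                    r.interval.chrom,
                                    r.interval.start,
                                    r.interval.end,
                                    r.contrast,
                                    g.gene_id,
                                    g.description,
                                )
                            )
                    pd.DataFrame(
                        rows,
                        columns=["chrom", "start", "end", "contrast", "gene_id", "description"],
                    ).to_csv(outputs["candidate_genes"], sep="\t", index=False)
                if config.locus:
                    locus = divergence_scan.parse_locus(config.locus)
                    hit, _ = divergence_scan.check_locus_overlap(tiered, locus)
                    counts["locus_overlap"] = int(hit)
        else:
            log.info("scan stage skipped: no contrasts configured")

        # -- SSR mining -------------------------------------------------------
        stage = "ssr"
        if fasta_path is not None:
            seqs = io_formats.read_fasta(fasta_path)
            ssrs = ssr_mining.find_ssrs_genome(seqs)
            counts["n_ssrs"] = len(ssrs)
            outputs["ssrs"] = outdir / "ssrs.tsv"
            pd.DataFrame(
                [
                    (r.chrom, r.start, r.end, r.motif, r.canonical_motif, r.n_repeats)
                    for r in ssrs
                ],
                columns=["chrom", "start", "end", "motif", "canonical", "n_repeats"],
            ).to_csv(outputs["ssrs"], sep="\t", index=False)
            summary = ssr_mining.summarise_ssrs(ssrs)
            outputs["ssr_summary"] = outdir / "ssr_summary.tsv"
            pd.DataFrame(
                [(k, v) for k, v in summary.by_unit_length.items()],
                columns=["unit_length", "fraction"],
            ).to_csv(outputs["ssr_summary"], sep="\t", index=False, float_format="%.6f")
        else:
            log.info("ssr stage skipped: no FASTA input")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "counts": counts,
        "outputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in outputs.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
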