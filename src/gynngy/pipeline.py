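"""Stage drivers wiring the modules into a file-based pipeline.

Each stage reads the previous stage's TSV outputs from the working
directory and writes its own, so stages are pure functions of files plus
configuration and the whole chain is reproducible from the seeds.  The
CLI subcommands and the numbered analysis scripts are thin wrappers
around these functions.
"""

from __future__ import annotations

import json
import logging
import os

import numpy as np
import pandas as pd

from gynngy import catalog as cat
from gynngy import consequences as cons
from gynngy import junctions as junc
from gynngy import regulation as reg
from gynngy import scoring
from gynngy import summaries as summ
from gynngy.config import PipelineConfig, SimConfig
from gynngy.models import read_fasta, read_gtf
from gynngy.simulate import generate_genome_and_models, simulate_junction_reads, write_simulation

logger = logging.getLogger(__name__)


def _write_log(out_dir: str, stage: str, params: dict) -> None:
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, f"{stage}.log.json"), "w") as fh:
        json.dump({"stage": stage, **params}, fh, indent=2, default=str)


def run_simulate(sim_cfg: SimConfig, out_dir: str) -> dict[str, str]:
    """Generate genome/models/reads and the emitted count table."""
    sim = generate_genome_and_models(sim_cfg)
    paths = write_simulation(sim, out_dir)
    sam_by_tissue, counts = simulate_junction_reads(sim_cfg, sim, out_dir)
    counts_path = os.path.join(out_dir, "emitted_counts.tsv")
    counts.to_csv(counts_path, sep="\t", index=False)
    paths.update(sam_by_tissue=sam_by_tissue, emitted_counts=counts_path)
    _write_log(out_dir, "simulate", {"seed": sim_cfg.seed, "n_genes": sim_cfg.n_genes})
    return paths


def run_extract(cfg: PipelineConfig, out_dir: str) -> str:
    """Junction extraction from per-tissue SAM files."""
    genome = read_fasta(cfg.genome)
    sam_by_tissue = {
        os.path.splitext(os.path.basename(p))[0]: p for p in cfg.alignments
    }
    table = junc.extract_junction_counts(
        sam_by_tissue,
        genome,
        strand_specific=cfg.strand_specific,
        max_shift=cfg.max_shift,
    )
    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, "junctions.tsv")
    junc.junction_table_to_tsv(table, path)
    junc.junctions_to_bed12(table, os.path.join(out_dir, "junctions.bed"))
    _write_log(out_dir, "extract", {"n_sam": len(cfg.alignments), "max_shift": cfg.max_shift})
    return path


def run_catalog(cfg: PipelineConfig, junctions_path: str, out_dir: str) -> tuple[str, str]:
    """GYNNGY site catalog and per-tissue donor counts."""
    genome = read_fasta(cfg.genome)
    models = read_gtf(cfg.gene_models) if cfg.gene_models else None
    table = junc.junction_table_from_tsv(junctions_path)
    catalog, counts = cat.find_gynngy_sites(
        table, genome, gene_models=models, min_support=cfg.min_support
    )
    os.makedirs(out_dir, exist_ok=True)
    cat_path = os.path.join(out_dir, "catalog.tsv")
    counts_path = os.path.join(out_dir, "site_counts.tsv")
    catalog.to_csv(cat_path, sep="\t", index=False)
    counts.to_csv(counts_path, sep="\t", index=False)
    _write_log(out_dir, "catalog", {"min_support": cfg.min_support, "n_sites": len(catalog)})
    return cat_path, counts_path


def run_usage(counts_path: str, out_dir: str, min_tissue_reads: int = 1) -> tuple[str, str]:
    """Per-site usage profiles (minor donor, mean/max/delta UMS)."""
    counts = pd.read_csv(counts_path, sep="\t")
    profiles, ums_long = cat.usage_profiles(counts, min_tissue_reads=min_tissue_reads)
    os.makedirs(out_dir, exist_ok=True)
    prof_path = os.path.join(out_dir, "usage_profiles.tsv")
    ums_path = os.path.join(out_dir, "ums_by_tissue.tsv")
    profiles.to_csv(prof_path, sep="\t", index=False)
    ums_long.to_csv(ums_path, sep="\t", index=False)
    _write_log(out_dir, "usage", {"min_tissue_reads": min_tissue_reads})
    return prof_path, ums_path


def run_test(cfg: PipelineConfig, counts_path: str, catalog_path: str, out_dir: str) -> str:
    """Permutation chi-squared test + BH FDR + classification (AS sites)."""
    counts = pd.read_csv(counts_path, sep="\t")
    catalog = pd.read_csv(catalog_path, sep="\t")
    as_sites = set(catalog.loc[catalog["as_flag"], "site_id"])
    results = reg.analyze_regulation(
        counts[counts["site_id"].isin(as_sites)],
        n_permutations=cfg.n_permutations,
        seed=cfg.seed,
        min_reads_per_tissue=cfg.min_reads_per_tissue,
        fdr_threshold=cfg.fdr_threshold,
        delta_bins=cfg.delta_bins,
    )
    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, "regulation.tsv")
    results.to_csv(path, sep="\t", index=False)
    _write_log(
        out_dir,
        "test",
        {
            "n_permutations": cfg.n_permutations,
            "seed": cfg.seed,
            "min_reads_per_tissue": cfg.min_reads_per_tissue,
        },
    )
    return path


def run_extrapolate(
    cfg: PipelineConfig, counts_path: str, catalog_path: str, out_dir: str,
    n_permutations: int | None = None,
) -> str:
    """Strongly-regulated proportion vs tissue number, with model fits."""
    counts = pd.read_csv(counts_path, sep="\t")
    catalog = pd.read_csv(catalog_path, sep="\t")
    as_sites = set(catalog.loc[catalog["as_flag"], "site_id"])
    counts = counts[counts["site_id"].isin(as_sites)]
    T = counts["tissue"].nunique()
    n_perm = n_permutations or min(cfg.n_permutations, 10_000)
    rows = []
    for k in range(2, T + 1):
        prop = reg.tissue_subsample_curve(
            counts,
            k,
            n_subsets=cfg.n_subsets,
            seed=cfg.seed,
            n_permutations=n_perm,
            min_reads_per_tissue=cfg.min_reads_per_tissue,
            fdr_threshold=cfg.fdr_threshold,
            delta_bins=cfg.delta_bins,
        )
        rows.append({"k": k, "strong_proportion": prop})
    curve = pd.DataFrame(rows)
    os.makedirs(out_dir, exist_ok=True)
    curve_path = os.path.join(out_dir, "subsample_curve.tsv")
    curve.to_csv(curve_path, sep="\t", index=False)
    fit_rows = []
    if curve["strong_proportion"].notna().sum() >= 4:
        fits = reg.fit_extrapolation(curve["k"], curve["strong_proportion"])
        for key in ("model1", "model2"):
            f = fits[key]
            fit_rows.append(
                {
                    "model": f.model,
                    "params": ",".join(f"{v:.6g}" for v in f.params),
                    "aic": f.aic,
                    "asymptote": f.asymptote,
                    "best": fits["best"].model == f.model,
                }
            )
    pd.DataFrame(fit_rows).to_csv(
        os.path.join(out_dir, "extrapolation_fits.tsv"), sep="\t", index=False
    )
    _write_log(out_dir, "extrapolate", {"n_subsets": cfg.n_subsets, "n_permutations": n_perm})
    return curve_path


def run_score(cfg: PipelineConfig, catalog_path: str, out_dir: str) -> str:
    """Donor scores for every GYNNGY site with WMM and MM1 models
    trained on the constitutive donor 9-mers of the input data."""
    genome = read_fasta(cfg.genome)
    catalog = pd.read_csv(catalog_path, sep="\t")
    training = []
    for row in catalog[~catalog["as_flag"]].itertuples():
        try:
            training.append(
                scoring.extract_9mer(genome, row.chrom, row.strand, row.distal_donor)
            )
        except ValueError:
            continue
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    if training:
        for kind in ("WMM", "MM1"):
            model = scoring.train_donor_model(training, kind=kind)
            for row in catalog.itertuples():
                try:
                    pair = scoring.score_pair(
                        genome, row.chrom, row.strand, row.distal_donor, model,
                        site_id=row.site_id,
                    )
                except ValueError:
                    continue
                rows.append(
                    {
                        "site_id": pair.site_id,
                        "method": kind,
                        "ss_distal": pair.ss_distal,
                        "ss_proximal": pair.ss_proximal,
                        "abs_diff": pair.abs_diff,
                    }
                )
    path = os.path.join(out_dir, "splice_scores.tsv")
    pd.DataFrame(
        rows, columns=["site_id", "method", "ss_distal", "ss_proximal", "abs_diff"]
    ).to_csv(path, sep="\t", index=False)
    _write_log(out_dir, "score", {"n_training": len(training)})
    return path


def run_consequences(
    cfg: PipelineConfig, catalog_path: str, profiles_path: str, out_dir: str
) -> str:
    """Coding-consequence records for AS sites in CDS."""
    genome = read_fasta(cfg.genome)
    models = read_gtf(cfg.gene_models)
    by_gene: dict[tuple[str, str], list] = {}
    for t in models:
        by_gene.setdefault((t.chrom, t.strand), []).append(t)
    catalog = pd.read_csv(catalog_path, sep="\t")
    profiles = pd.read_csv(profiles_path, sep="\t").set_index("site_id")
    rows = []
    for row in catalog[(catalog["as_flag"]) & (catalog["region"] == "CDS")].itertuples():
        candidates = [
            t
            for t in by_gene.get((row.chrom, row.strand), [])
            if t.has_cds and row.distal_donor in t.donor_positions()
        ]
        if not candidates:
            continue
        tx = max(candidates, key=lambda t: t.cds_length())
        minor = (
            profiles.loc[row.site_id, "minor"] if row.site_id in profiles.index else "proximal"
        )
        try:
            rec = cons.consequence_record(tx, row.distal_donor, genome, minor=minor)
        except ValueError as exc:
            logger.warning("consequence skipped for %s: %s", row.site_id, exc)
            continue
        rec["site_id"] = row.site_id
        rows.append(rec)
    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, "consequences.tsv")
    cols = [
        "site_id",
        "transcript_id",
        "frameshift",
        "stop_next_exon",
        "stop_affected_tail",
        "category",
        "rel_pos",
        "decile",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    _write_log(out_dir, "consequences", {"n_records": len(rows)})
    return path


def run_summarize(
    catalog_path: str,
    regulation_path: str,
    consequences_path: str | None,
    ums_path: str | None,
    out_dir: str,
) -> str:
    """Headline proportion tables and contrasts over the pipeline output."""
    catalog = pd.read_csv(catalog_path, sep="\t")
    regulation = pd.read_csv(regulation_path, sep="\t")
    os.makedirs(out_dir, exist_ok=True)
    report_lines = []

    assigned = catalog[catalog["region"].isin(["CDS", "UTR"])]
    as_by_region = summ.proportion_summary(assigned, "region", "as_flag")
    for gc in as_by_region:
        report_lines.append(f"AS proportion, {gc}")
    if assigned["region"].nunique() == 2:
        tab = [
            [
                int(assigned[(assigned.region == r) & assigned.as_flag].shape[0]),
                int(assigned[(assigned.region == r) & ~assigned.as_flag].shape[0]),
            ]
            for r in ("CDS", "UTR")
        ]
        if all(sum(row) > 0 for row in tab):
            chi2, p = summ.contingency_test(tab, method="chisq")
            report_lines.append(
                f"AS-by-region chi-squared = {chi2:.3f}, p = {summ.format_p(p)}"
            )

    merged = regulation.merge(catalog[["site_id", "region"]], on="site_id", how="left")
    testable = merged[merged["testable"] == True]  # noqa: E712
    if not testable.empty:
        testable = testable.assign(strong=testable["class"] == "strong")
        for gc in summ.proportion_summary(
            testable[testable.region.isin(["CDS", "UTR"])], "region", "strong"
        ):
            report_lines.append(f"Strongly regulated, {gc}")
        total = summ.GroupCounts("all_testable", int(testable.strong.sum()), len(testable))
        report_lines.append(f"Strongly regulated, {total}")

    if consequences_path and os.path.exists(consequences_path):
        cq = pd.read_csv(consequences_path, sep="\t")
        if not cq.empty:
            stop = summ.GroupCounts(
                "stop_in_next_exon", int(cq.stop_next_exon.sum()), len(cq), decimals=0
            )
            report_lines.append(f"Consequences, {stop}")

    if ums_path and os.path.exists(ums_path):
        ums_long = pd.read_csv(ums_path, sep="\t")
        dist = summ.max_ums_tissue_distribution(ums_long)
        dist.rename("sites").to_csv(
            os.path.join(out_dir, "max_ums_by_tissue.tsv"), sep="\t"
        )

    path = os.path.join(out_dir, "summary.txt")
    with open(path, "w") as fh:
        fh.write("\n".join(report_lines) + "\n")
    _write_log(out_dir, "summarize", {"n_lines": len(report_lines)})
    return path


def run_all(sim_cfg: SimConfig, cfg: PipelineConfig, out_dir: str) -> dict[str, str]:
    """simulate -> extract -> catalog -> usage -> test -> score ->
    consequences -> summarize, all under one output directory."""
    sim_dir = os.path.join(out_dir, "sim")
    paths = run_simulate(sim_cfg, sim_dir)
    cfg.genome = paths["fasta"]
    cfg.gene_models = paths["gtf"]
    cfg.alignments = sorted(paths["sam_by_tissue"].values())
    cfg.strand_specific = sim_cfg.strand_specific
    junctions_path = run_extract(cfg, out_dir)
    cat_path, counts_path = run_catalog(cfg, junctions_path, out_dir)
    prof_path, ums_path = run_usage(counts_path, out_dir)
    regulation_path = run_test(cfg, counts_path, cat_path, out_dir)
    score_path = run_score(cfg, cat_path, out_dir)
    cons_path = run_consequences(cfg, cat_path, prof_path, out_dir)
    summary_path = run_summarize(cat_path, regulation_path, cons_path, ums_path, out_dir)
    return {
        "junctions": junctions_path,
        "catalog": cat_path,
        "site_counts": counts_path,
        "usage_profiles": prof_path,
        "ums_by_tissue": ums_path,
        "regulation": regulation_path,
        "splice_scores": score_path,
        "consequences": cons_path,
        "summary": summary_path,
        **paths,
    }
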