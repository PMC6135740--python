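"""End-to-end orchestration: simulate → assign → balance → variance →
difftest → TRENI, with every intermediate written through :mod:`io` and a
single markdown report.

The pipeline is deterministic given the config seed. Isoform-level FPKM for
the TRENI lineage test is taken from the synthetic gene matrix re-indexed by
TRENI id (the test path is identical for genes and isoforms; only row names
differ).
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import balance, difftest, io, lineage, simulate, treni, variance

log = logging.getLogger("rainbowseq")

STAGE_ALIASES = {"4cell": "four_cell", "8cell": "eight_cell",
                 "four_cell": "four_cell", "eight_cell": "eight_cell"}


def load_config(path: str | Path | None, seed: int | None = None,
                **overrides) -> simulate.SyntheticConfig:
    """Build a SyntheticConfig from an optional YAML file plus overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    if seed is not None:
        data["seed"] = seed
    if "junction_frac_range" in data:
        data["junction_frac_range"] = tuple(data["junction_frac_range"])
    return simulate.SyntheticConfig(**data)


def simulate_to_dir(config: simulate.SyntheticConfig, out_dir: str | Path) -> dict:
    """Run all three generators and write every pipeline input."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells, fpkm, gene_truth = simulate.simulate_cells_and_expression(config)
    image = simulate.simulate_image_counts(config)
    transcripts, repeats, reads, treni_truth = (
        simulate.simulate_annotation_and_reads(config)
    )
    io.write_cells(cells, out / "cells.tsv")
    io.write_matrix(fpkm, out / "fpkm.tsv")
    gene_truth.to_csv(out / "truth_lineage_genes.tsv", sep="\t", index=False)
    io.write_image_counts(image, out / "image_counts.tsv")
    io.write_gtf(transcripts, out / "transcripts.gtf")
    io.write_repeat_bed(repeats, out / "repeats.bed")
    io.write_read_blocks_bed12(reads, out / "reads.bed")
    treni_truth.to_csv(out / "truth_treni.tsv", sep="\t", index=False)
    return dict(cells=cells, fpkm=fpkm, gene_truth=gene_truth, image=image,
                transcripts=transcripts, repeats=repeats, reads=reads,
                treni_truth=treni_truth)


def top_genes_report(
    matrix: pd.DataFrame, cells, tests: pd.DataFrame, n_top: int = 10
) -> pd.DataFrame:
    """Per-embryo lineage mean FPKM of the top-ranked features."""
    top = tests.nsmallest(n_top, "q")["feature_id"]
    rows = []
    for gid in top:
        for eid in sorted({c.embryo_id for c in cells}):
            for lin in ("A", "B"):
                ids = [c.cell_id for c in cells
                       if c.embryo_id == eid and c.lineage == lin]
                if not ids:
                    continue
                rows.append(
                    dict(feature_id=gid, embryo_id=eid, lineage=lin,
                         mean_fpkm=float(matrix.loc[gid, ids].mean()))
                )
    return pd.DataFrame(rows)


def run_all(
    config: simulate.SyntheticConfig,
    out_dir: str | Path,
    stages: tuple[str, ...] = ("four_cell", "eight_cell"),
    n_shuffles: int = 1,
    q_star: float = 0.01,
) -> dict:
    """Run the full synthetic pipeline; returns the key result objects.

    Writes per-stage TSV tables and ``report.md`` under ``out_dir``. Any
    stage failure raises with the stage named in the log.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    report: list[str] = ["# rainbowseq synthetic pipeline report", ""]
    report.append(f"seed: {config.seed}")

    def stage_timer(name):
        log.info("stage %s ...", name)
        return time.perf_counter()

    t0 = stage_timer("simulate")
    data = simulate_to_dir(config, out)
    log.info("stage simulate done in %.1fs", time.perf_counter() - t0)

    # lineage assignment + QC
    t0 = stage_timer("assign-lineage")
    assigned = lineage.assign_all(data["cells"])
    kept, dropped = lineage.qc_filter(assigned)
    io.write_cells(assigned, out / "cells_lineage.tsv")
    results["cells"] = kept
    n_res = sum(1 for c in kept if c.lineage in "AB")
    report += ["", "## lineage assignment",
               f"- {len(assigned)} cells, {len(dropped)} failed QC, "
               f"{n_res} lineage-resolved"]
    log.info("stage assign-lineage done in %.1fs", time.perf_counter() - t0)

    # balance
    t0 = stage_timer("balance")
    bal = balance.classify_all(data["image"])
    summary = balance.summarize(bal)
    summary.to_csv(out / "balance_summary.tsv", sep="\t", index=False)
    results["balance_summary"] = summary
    report += ["", "## blastocyst balance (per counting method)",
               summary.to_string(index=False)]
    log.info("stage balance done in %.1fs", time.perf_counter() - t0)

    for stage in stages:
        tag = {"four_cell": "4cell", "eight_cell": "8cell"}[stage]
        stage_cells = [c for c in kept if c.stage == stage]
        if not any(c.lineage in "AB" for c in stage_cells):
            log.warning("stage %s: no resolved cells, skipping", stage)
            continue

        # expressed genes
        ids = [c.cell_id for c in stage_cells]
        per_cell, union = lineage.call_expressed_genes(data["fpkm"][ids])
        report += ["", f"## stage {tag}",
                   f"- mean expressed genes/cell: {per_cell.mean():.0f}; "
                   f"union: {union}"]

        # variance partition
        t0 = stage_timer(f"variance[{tag}]")
        r = variance.empirical_R(data["fpkm"], kept, stage)
        r.to_frame().to_csv(out / f"r_values_{tag}.tsv", sep="\t")
        comps = variance.compare_to_beta(r.values)
        beta_rows = []
        for comp in comps:
            for delta, emp, ana in comp.tail_pairs:
                beta_rows.append(dict(alpha=comp.alpha, beta=comp.beta,
                                      ks=comp.ks_distance, delta=delta,
                                      empirical_tail=emp, beta_tail=ana))
        pd.DataFrame(beta_rows).to_csv(
            out / f"beta_tails_{tag}.tsv", sep="\t", index=False)
        qq = pd.DataFrame(
            [(c.alpha, c.beta, bq, eq) for c in comps for bq, eq in c.qq_points],
            columns=["alpha", "beta", "beta_quantile", "empirical_quantile"],
        )
        qq.to_csv(out / f"qq_{tag}.tsv", sep="\t", index=False)
        results[f"r_{tag}"] = r
        results[f"beta_{tag}"] = comps
        report += [f"- {len(r)} genes with defined r; "
                   + "; ".join(f"KS vs Beta({c.alpha:g},{c.beta:g})="
                               f"{c.ks_distance:.3f}" for c in comps)]
        log.info("stage variance[%s] done in %.1fs", tag,
                 time.perf_counter() - t0)

        # lineage difference test + background
        t0 = stage_timer(f"difftest[{tag}]")
        tests = difftest.test_features(data["fpkm"], kept, stage)
        bg = difftest.shuffle_background(
            data["fpkm"], kept, stage, n_shuffles=n_shuffles,
            seed=config.seed,
        )
        comp = difftest.compare_distributions(tests["q"].values, bg,
                                              q_star=q_star)
        tests.to_csv(out / f"tests_{tag}.tsv", sep="\t", index=False)
        pd.DataFrame({"q": bg}).to_csv(
            out / f"background_{tag}.tsv", sep="\t", index=False)
        top = top_genes_report(data["fpkm"], stage_cells, tests)
        top.to_csv(out / f"top_genes_{tag}.tsv", sep="\t", index=False)
        results[f"difftest_{tag}"] = (tests, bg, comp)
        report += [f"- lineage test: KS={comp.ks_stat:.3f} "
                   f"(p={comp.ks_p:.3g}); q<{q_star}: real "
                   f"{comp.n_real_below}, shuffled {comp.n_shuffled_below}"]
        log.info("stage difftest[%s] done in %.1fs", tag,
                 time.perf_counter() - t0)

    # TRENI
    t0 = stage_timer("treni")
    transcripts = data["transcripts"]
    reference = [t for t in transcripts if not t.is_novel]
    candidates = [t for t in transcripts if t.is_novel]
    novel = treni.find_novel(candidates, reference)
    records = treni.call_treni(novel, data["repeats"])
    by_id = {t.transcript_id: t for t in transcripts}
    records = treni.annotate_placements(records, by_id)
    ref_exons_by_gene: dict[str, list] = {}
    for t in reference:
        ref_exons_by_gene.setdefault(t.gene_id, []).extend(t.exons)
    for rec in records:
        host = by_id[rec.transcript_id]
        for rep, _ in rec.repeat_hits:
            rec.jr[rep] = treni.junction_ratio(
                rep, host, ref_exons_by_gene[rec.gene_id], data["reads"]
            )
    all_jr = {rep: rec.jr[rep] for rec in records for rep, _ in rec.repeat_hits}
    high_conf = treni.jr_filter(all_jr)
    treni_reps = set(all_jr)
    fam = treni.family_enrichment(data["repeats"], treni_reps)
    utr_fam = treni.utr_family_enrichment(data["repeats"], records)
    treni.records_to_frame(records).to_csv(out / "treni.tsv", sep="\t",
                                           index=False)
    treni.enrichment_to_frame(fam).to_csv(out / "families.tsv", sep="\t",
                                          index=False)
    treni.enrichment_to_frame(utr_fam).to_csv(
        out / "utr_families.tsv", sep="\t", index=False)
    results["novel"] = novel
    results["treni_records"] = records
    results["families"] = fam
    results["utr_families"] = utr_fam
    n_utr = sum(1 for rec in records
                if treni.FIVE_PRIME_UTR in rec.placement)
    defined = [v for v in all_jr.values() if v is not None]
    report += ["", "## TRENIs",
               f"- {len(novel)} novel isoforms, {len(records)} TRENIs "
               f"({n_utr} with a 5'UTR repeat)",
               f"- {len(all_jr)} embedded repeats, {len(high_conf)} with "
               f"JR >= {treni.DEFAULT_JR_THRESHOLD}"]
    if fam and fam[0].odds_ratio is not None:
        report += [f"- top enriched family: {fam[0].family} "
                   f"(OR={fam[0].odds_ratio:.2f})"]
    log.info("stage treni done in %.1fs", time.perf_counter() - t0)

    # TRENI lineage tests on an isoform-level matrix
    if records:
        treni_ids = [rec.transcript_id for rec in records]
        iso = data["fpkm"].iloc[: len(treni_ids)].copy()
        iso.index = treni_ids
        for stage in stages:
            tag = {"four_cell": "4cell", "eight_cell": "8cell"}[stage]
            if f"difftest_{tag}" not in results:
                continue
            tests, bg, comp = treni.treni_lineage_tests(
                iso, kept, stage, n_shuffles=n_shuffles, seed=config.seed,
                q_star=q_star,
            )
            tests.to_csv(out / f"treni_tests_{tag}.tsv", sep="\t", index=False)
            results[f"treni_difftest_{tag}"] = (tests, bg, comp)
            report += [f"- TRENI lineage test ({tag}): q<{q_star}: real "
                       f"{comp.n_real_below}, shuffled {comp.n_shuffled_below}"]

    (out / "report.md").write_text("\n".join(report) + "\n")
    results["report"] = "\n".join(report)
    return results
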