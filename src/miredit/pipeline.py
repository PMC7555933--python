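"""End-to-end pipeline driver: simulation/ingest -> cleaning -> mapping ->
normalization & differential expression -> editing calls -> reports.

Every intermediate is written as TSV under the configured output
directory, parameters and seeds are logged and dumped to a run manifest,
and re-running with the same configuration reproduces byte-identical
outputs. All position columns are 1-based reference coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import editcall, mirmap, normde, qpcr as qpcr_mod, readproc, sanger as sanger_mod, simulate
from .config import PipelineConfig, save_config
from .core import (
    AGE_GROUPS_MONTHS,
    MirnaReference,
    ReadSet,
    SampleDesign,
    group_label,
    read_clones,
    write_tsv,
)

log = logging.getLogger("miredit")

STAGES = ("simulate", "clean", "map", "de", "edit", "qpcr", "sanger")


@dataclass
class RunReport:
    """What a pipeline run produced, stage by stage."""

    output_dir: Path
    outputs: dict[str, Path] = field(default_factory=dict)
    clean_stats: list[readproc.CleanStats] = field(default_factory=list)
    map_summaries: list[mirmap.AssignmentSummary] = field(default_factory=list)
    n_de_comparisons: int = 0
    n_editing_calls: int = 0

    def add(self, name: str, path: Path) -> Path:
        self.outputs[name] = path
        return path


def _comparisons(design: SampleDesign) -> list[tuple[str, list[str], list[str]]]:
    """The study's contrasts: each older age vs 3 months within sex, and
    male vs female at each age. Only groups with >= 2 samples qualify."""
    out = []
    baseline_age = AGE_GROUPS_MONTHS[0]
    for sex in ("M", "F"):
        ctrl = design.samples_in_group(sex, baseline_age)
        if len(ctrl) < 2:
            continue
        for age in AGE_GROUPS_MONTHS[1:]:
            grp = design.samples_in_group(sex, age)
            if len(grp) >= 2:
                out.append(
                    (f"{sex}_{age}_vs_{sex}_{baseline_age}", ctrl, grp)
                )
    for age in AGE_GROUPS_MONTHS:
        m = design.samples_in_group("M", age)
        f = design.samples_in_group("F", age)
        if len(m) >= 2 and len(f) >= 2:
            out.append((f"F_{age}_vs_M_{age}", m, f))
    return out


def run_pipeline(config: PipelineConfig, through: str = "sanger") -> RunReport:
    """Run the pipeline up to (and including) ``through``.

    The qPCR and Sanger stages run only when their inputs are configured;
    they do not depend on the sequencing stages.
    """
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}; choose from {STAGES}")
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(output_dir=out)
    save_config(config, out / "run_manifest.yaml")
    last = STAGES.index(through)

    # --- inputs: load or simulate -----------------------------------------
    truth = None
    if config.simulate_mode:
        sim = config.simulate
        params = simulate.SimParams(
            n_de=sim.n_de,
            log2fc=sim.log2fc,
            n_edited_sites=sim.n_edited_sites,
            fraction_range=sim.fraction_range,
            baseline_mean_range=sim.baseline_mean_range,
            dispersion=sim.dispersion,
            error_rate=sim.error_rate,
            read_length=sim.read_length,
        )
        reference = simulate.gen_reference(
            sim.n_mirnas, sim.length_range, seed=config.seed
        )
        design = SampleDesign.full_factorial(
            sim.n_replicates, sexes=sim.sexes, ages=sim.ages
        )
        truth = simulate.gen_truth(reference, design, params, seed=config.seed)
        reference.to_fasta(report.add("reference", out / "reference.fasta"))
        design.to_tsv(report.add("design", out / "design.tsv"))
        truth.to_tsvs(out)
        report.add("truth_editing", out / "truth_editing_sites.tsv")
        report.add("truth_abundance", out / "truth_abundance.tsv")
        reads = simulate.simulate_study(truth, reference, design, depth=sim.depth)
        log.info(
            "simulated %d samples x ~%d reads (%d miRNAs, seed %d)",
            len(design.sample_ids), sim.depth, sim.n_mirnas, config.seed,
        )
        if config.write_reads:
            reads_dir = out / "reads"
            reads_dir.mkdir(exist_ok=True)
            for sid, rs in reads.items():
                rs.to_fastq(reads_dir / f"{sid}.fastq")
            report.add("reads", reads_dir)
    else:
        reference = MirnaReference.from_fasta(config.reference_fasta)
        design = SampleDesign.from_tsv(config.design_tsv)
        reads = {}
        for sid in design.sample_ids:
            fq = Path(config.reads_dir) / f"{sid}.fastq"
            fa = Path(config.reads_dir) / f"{sid}.fasta"
            if fq.exists():
                reads[sid] = ReadSet.from_fastq(fq, sid)
            elif fa.exists():
                reads[sid] = ReadSet.from_fasta(fa, sid)
            else:
                raise FileNotFoundError(
                    f"no reads for sample {sid}: expected {fq} or {fa}"
                )
    if last < STAGES.index("clean"):
        return report

    # --- cleaning & collapsing --------------------------------------------
    tables: dict[str, readproc.UniqueReadTable] = {}
    stat_rows = []
    uniq_dir = out / "unique_reads"
    uniq_dir.mkdir(exist_ok=True)
    for sid in design.sample_ids:
        cleaned, stats = readproc.clean_reads(
            reads[sid],
            adapter=config.clean.adapter,
            min_len=config.clean.min_len,
            max_len=config.clean.max_len,
            max_fraction_n=config.clean.max_fraction_n,
            min_mean_quality=config.clean.min_mean_quality,
        )
        table = readproc.collapse_reads(cleaned)
        assert table.total_reads == stats.passed, "collapse lost reads"
        tables[sid] = table
        table.to_tsv(uniq_dir / f"{sid}.tsv")
        stat_rows.append(stats.as_row())
        report.clean_stats.append(stats)
        log.info(
            "clean %s: %d -> %d reads (no_adapter %d, bad_length %d)",
            sid, stats.total, stats.passed, stats.no_adapter, stats.bad_length,
        )
    write_tsv(pd.DataFrame(stat_rows), report.add("clean_stats", out / "clean_stats.tsv"))
    if last < STAGES.index("map"):
        return report

    # --- mapping -----------------------------------------------------------
    assignments: dict[str, list[mirmap.ReadAssignment]] = {}
    summary_rows = []
    asg_dir = out / "assignments"
    asg_dir.mkdir(exist_ok=True)
    for sid in design.sample_ids:
        asg, summary = mirmap.assign_sample(
            tables[sid], reference,
            max_mm=config.mapping.max_mm,
            max_3prime_slack=config.mapping.max_3prime_slack,
        )
        assert summary.total == tables[sid].total_reads, "mapping lost reads"
        assignments[sid] = asg
        report.map_summaries.append(summary)
        summary_rows.append(
            {
                "sample_id": sid,
                "assigned": summary.assigned,
                "ambiguous": summary.ambiguous,
                "unassigned": summary.unassigned,
            }
        )
        write_tsv(mirmap.assignments_to_frame(asg), asg_dir / f"{sid}.tsv")
        log.info(
            "map %s: assigned %d / ambiguous %d / unassigned %d",
            sid, summary.assigned, summary.ambiguous, summary.unassigned,
        )
    write_tsv(pd.DataFrame(summary_rows), report.add("map_summary", out / "mapping_summary.tsv"))
    matrix, side = mirmap.build_count_matrix(assignments, design, reference)
    write_tsv(
        matrix.reset_index(names="mirna_id"),
        report.add("counts_raw", out / "counts_raw.tsv"),
    )
    write_tsv(side, report.add("excluded_reads", out / "excluded_reads.tsv"))
    if last < STAGES.index("de"):
        return report

    # --- normalization & differential expression ---------------------------
    factors = normde.norm_factors(matrix)
    norm = normde.normalize(matrix, factors)
    write_tsv(
        factors.rename_axis("sample_id").reset_index(),
        report.add("norm_factors", out / "norm_factors.tsv"),
    )
    write_tsv(
        norm.reset_index(names="mirna_id"),
        report.add("counts_normalized", out / "counts_normalized.tsv"),
    )
    de_opts = normde.DEOptions(
        pseudocount=config.de.pseudocount,
        log_scale=config.de.log_scale,
        equal_var=config.de.equal_var,
        tiers=config.de.tiers,
    )
    de_tables = {}
    for name, ga, gb in _comparisons(design):
        table = normde.de_test(norm, ga, gb, de_opts)
        de_tables[name] = table
        write_tsv(table, report.add(f"de_{name}", out / f"de_{name}.tsv"))
    report.n_de_comparisons = len(de_tables)
    if de_tables:
        cm = normde.comparison_matrix(de_tables)
        write_tsv(
            cm.rename_axis("mirna_id").reset_index(),
            report.add("de_signed_log10p", out / "de_signed_log10p.tsv"),
        )
    log.info("DE: %d comparisons on %d miRNAs", len(de_tables), len(norm))
    if last < STAGES.index("edit"):
        return report

    # --- editing detection --------------------------------------------------
    all_calls = []
    for sex, age in design.groups():
        glabel = group_label(sex, age)
        sids = design.samples_in_group(sex, age)
        pooled = [a for sid in sids for a in assignments[sid]]
        calls_by_mirna = {}
        for mid in reference.ids:
            profile = editcall.mismatch_profile(pooled, mid, reference)
            if profile.total_reads == 0:
                continue
            calls = editcall.call_editing_sites(
                profile,
                error_rate=config.edit.error_rate,
                min_fraction_factor=config.edit.min_fraction_factor,
                min_edited_reads=config.edit.min_edited_reads,
            )
            if calls:
                calls_by_mirna[mid] = calls
                all_calls.extend(calls)
        frame = editcall.calls_to_frame(
            [c for calls in calls_by_mirna.values() for c in calls]
        )
        frame.insert(0, "group", glabel)
        write_tsv(frame, report.add(f"editing_calls_{glabel}", out / f"editing_calls_{glabel}.tsv"))
        summary = editcall.summarize_edited(
            calls_by_mirna, pooled, norm, glabel,
            min_avg_reads=config.edit.min_avg_reads,
        )
        st = summary.table.copy()
        st.insert(0, "group", glabel)
        st["in_top"] = st["mirna_id"].isin(summary.top)
        write_tsv(st, report.add(f"edited_summary_{glabel}", out / f"edited_summary_{glabel}.tsv"))
        if config.plots and len(summary.table):
            from .plots import doughnut_chart

            doughnut_chart(summary, out / f"doughnut_{glabel}.png")
        log.info(
            "edit %s: %d called sites on %d miRNAs (retained %d)",
            glabel,
            sum(len(c) for c in calls_by_mirna.values()),
            len(calls_by_mirna),
            len(summary.table),
        )
    report.n_editing_calls = len(all_calls)
    if last < STAGES.index("qpcr"):
        return report

    # --- qPCR ---------------------------------------------------------------
    if config.ct_table_tsv is not None:
        ct = pd.read_csv(config.ct_table_tsv, sep="\t")
        per_sample, per_group = qpcr_mod.pfaffl_fold(
            ct, control_age_months=config.qpcr.control_age_months
        )
        per_group["flag"] = qpcr_mod.classify_array_folds(per_group["fold"])
        write_tsv(per_sample, report.add("qpcr_per_sample", out / "qpcr_fold_per_sample.tsv"))
        write_tsv(per_group, report.add("qpcr_per_group", out / "qpcr_fold_per_group.tsv"))
        anova_rows = []
        for target, sub in per_sample.groupby("target", sort=False):
            labels = [
                group_label(s, a)
                for s, a in zip(sub["sex"], sub["age_months"])
            ]
            res = qpcr_mod.anova_tukey(sub["delta_ct"], labels)
            anova_rows.append({"target": target, "F": res.f, "p": res.p})
            tk = res.tukey.copy()
            tk.insert(0, "target", target)
            write_tsv(tk, report.add(f"qpcr_tukey_{target}", out / f"qpcr_tukey_{target}.tsv"))
        write_tsv(pd.DataFrame(anova_rows), report.add("qpcr_anova", out / "qpcr_anova.tsv"))
        log.info("qPCR: %d targets analyzed", len(anova_rows))
    if last < STAGES.index("sanger"):
        return report

    # --- Sanger clone validation -------------------------------------------
    if config.clones_fasta is not None:
        clones = read_clones(config.clones_fasta, config.clones_meta_tsv)
        ref_id = config.sanger.reference_id or reference.ids[0]
        ref_seq = reference.sequence(ref_id)
        calls, not_found = sanger_mod.call_all_clones(
            clones, ref_seq, min_identity=config.sanger.min_identity
        )
        frame = sanger_mod.calls_to_frame(calls)
        write_tsv(frame, report.add("sanger_calls", out / "sanger_calls.tsv"))
        summary = sanger_mod.summarize_clone_editing(
            calls, clones, min_recurrence=config.sanger.min_recurrence
        )
        write_tsv(summary.per_group, report.add("sanger_by_group", out / "sanger_by_group.tsv"))
        write_tsv(summary.per_position, report.add("sanger_by_position", out / "sanger_by_position.tsv"))
        write_tsv(summary.per_animal, report.add("sanger_by_animal", out / "sanger_by_animal.tsv"))
        if not_found:
            log.warning("clones with no locatable insert: %s", not_found)
        log.info(
            "sanger: %d clones, %d substitution calls vs %s",
            len(clones), len(calls), ref_id,
        )
    return report
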