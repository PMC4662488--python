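"""End-to-end orchestration: simulate -> annotate -> count -> DA -> summarize
-> overtarget -> census filter -> enrichment -> network -> correlate.

Every stochastic stage consumes a seed derived deterministically from the
single config seed, so re-running with the same config reproduces identical
outputs. The manifest records the config hash, per-stage seeds, audit counts
for every filter, and a checksum for each written file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann
from . import clinical, da, io, overtargeting as ot, simulate
from .config import PipelineConfig
from .core import DAResult

logger = logging.getLogger(__name__)

_STAGES = (
    "simulate", "annotate", "count", "da", "summarize",
    "overtarget", "census", "enrichment", "network", "correlate",
)


def _derive_seeds(seed: int, n: int) -> list:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: PipelineConfig, outdir) -> dict:
    """Run the full synthetic-bundle pipeline into ``outdir``.

    Returns the manifest dictionary (also written to ``manifest.json``).
    External interaction/census tables are used when configured; otherwise
    the simulate stage provides synthetic stand-ins with known ground truth.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(_STAGES, _derive_seeds(config.seed, len(_STAGES))))
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "audit": {},
        "outputs": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    sp = config.simulate
    stage = "simulate"
    try:
        features = simulate.gen_annotation(seed=seeds[stage])
        io.write_annotation(features, outdir / "annotation.tsv")
        # group-specific class mixes: miRNA share rises, tRNA/YRNA fall in cases
        case_mix = {"miRNA": 0.66, "YRNA": 0.30, "tRNA": 0.03, "rRNA": 0.01}
        control_mix = {"miRNA": 0.40, "YRNA": 0.44, "tRNA": 0.15, "rRNA": 0.01}
        n_per_sample = max(1, sp.n_reads // (2 * sp.n_per_group))
        sample_reads = {}
        sub_seeds = _derive_seeds(seeds[stage] + 1, 2 * sp.n_per_group)
        for i in range(sp.n_per_group):
            sample_reads[f"T{i + 1}"] = simulate.gen_alignments(
                features, n_per_sample, class_mix=case_mix, seed=sub_seeds[i]
            )
        for i in range(sp.n_per_group):
            sample_reads[f"N{i + 1}"] = simulate.gen_alignments(
                features, n_per_sample, class_mix=control_mix,
                seed=sub_seeds[sp.n_per_group + i],
            )
        for sample, reads in sample_reads.items():
            io.write_bed(reads, outdir / f"alignments_{sample}.bed")
        counts, truth = simulate.gen_count_matrix(
            sp.n_features, sp.n_per_group, sp.frac_da, sp.log2fc_magnitude,
            sp.dispersion, sp.libsize_range, seed=seeds[stage] + 2,
        )
        counts.to_tsv(outdir / "counts.tsv")
        manifest["audit"]["n_reads_simulated"] = sum(len(r) for r in sample_reads.values())

        stage = "annotate"
        ap = config.annotation
        classified = {}
        for sample, reads in sample_reads.items():
            classified[sample] = ann.classify_reads(
                reads, features, min_overlap_frac=ap.min_overlap_frac,
                end_window=ap.end_window,
            )
        pooled = [cr for sub in classified.values() for cr in sub]
        profile = ann.length_distribution(pooled)
        pd.DataFrame(
            [{"sncrna_class": c, "length": l, "count": n} for (c, l), n in sorted(profile.counts.items())]
        ).to_csv(outdir / "length_distribution.tsv", sep="\t", index=False)
        case_totals = ann.length_distribution(
            [cr for s, sub in classified.items() if s.startswith("T") for cr in sub]
        ).totals
        control_totals = ann.length_distribution(
            [cr for s, sub in classified.items() if s.startswith("N") for cr in sub]
        ).totals
        case_totals.pop("unannotated", None)
        control_totals.pop("unannotated", None)
        chi2, df_, p_chi = ann.compare_class_distribution(case_totals, control_totals)
        manifest["audit"]["class_chi2"] = {"chi2": chi2, "df": df_, "pvalue": p_chi}
        manifest["audit"]["class_percentages"] = profile.percentages

        stage = "count"
        sample_of = {
            cr.alignment.read_id: s for s, sub in classified.items() for cr in sub
        }
        group = {s: ("case" if s.startswith("T") else "control") for s in classified}
        trna_counts = ann.aggregate_counts(pooled, sample_of, "tRNA", "five_prime", group)
        yrna5 = ann.aggregate_counts(pooled, sample_of, "YRNA", "five_prime", group)
        yrna3 = ann.aggregate_counts(pooled, sample_of, "YRNA", "three_prime", group)
        trna_counts.to_tsv(outdir / "counts_trna_5p.tsv")
        yrna5.to_tsv(outdir / "counts_yrna_5p.tsv")
        yrna3.to_tsv(outdir / "counts_yrna_3p.tsv")

        stage = "da"
        dp = config.da
        results = da.run_da(
            counts, fdr_threshold=config.thresholds.fdr_known,
            prior_df=dp.prior_df, trim_m=dp.trim_m, trim_a=dp.trim_a,
            prior_count=dp.prior_count,
        )
        io.write_da_results(results, outdir / "da_results.tsv")
        f = da.tmm_factors(counts, trim_m=dp.trim_m, trim_a=dp.trim_a)
        coords = da.mds_leading_logfc(counts, f, top_k=dp.top_k, prior_count=dp.prior_count)
        pd.DataFrame(
            coords, index=counts.sample_ids,
            columns=[f"dim{k + 1}" for k in range(coords.shape[1])],
        ).to_csv(outdir / "mds_coordinates.tsv", sep="\t")

        stage = "summarize"
        table = pd.DataFrame(
            {
                "id": [r.feature_id for r in results],
                "fc": [r.fc_signed for r in results],
                "pvalue": [r.pvalue for r in results],
                "fdr": [r.fdr for r in results],
            }
        )
        summary = da.summarize_da_table(
            table, p_threshold=config.thresholds.p_da,
            fdr_threshold=config.thresholds.fdr_known,
        )
        manifest["audit"]["da_summary"] = {
            k: v for k, v in summary.items() if k.startswith("n_")
        }
        manifest["audit"]["da_truth_planted"] = len(truth.da_features)

        stage = "overtarget"
        # map DA count features onto universe miRNA identifiers by index
        def to_mirna(fid: str) -> str | None:
            idx = int(fid.replace("feat", ""))
            return f"MIR-{idx:03d}" if idx < sp.n_mirnas else None

        da_up = {to_mirna(i) for i in summary["up_ids"] if to_mirna(i)}
        da_down = {to_mirna(i) for i in summary["down_ids"] if to_mirna(i)}
        if config.pred_a_path and config.pred_b_path:
            universe = ot.build_universe(
                io.read_pairs(config.pred_a_path),
                io.read_pairs(config.pred_b_path),
                io.read_pairs(config.validated_path) if config.validated_path else set(),
            )
            planted = set()
        else:
            universe, u_truth = simulate.gen_universe(
                sp.n_mirnas, sp.n_genes, sp.density, sp.n_planted,
                da_set=(da_up | da_down) or None,
                boost=sp.boost, seed=seeds[stage],
            )
            planted = u_truth.overtargeted_genes
        up_hits, down_hits = ot.screen_overtargeted(
            universe, da_up, da_down,
            p_cut=config.thresholds.overtarget_p,
            fdr_cut=config.thresholds.overtarget_fdr,
        )
        manifest["audit"]["overtarget"] = {
            "universe_edges": len(universe),
            "n_da_up": len(da_up),
            "n_da_down": len(da_down),
            "flagged_up": len(up_hits),
            "flagged_down": len(down_hits),
            "planted": len(planted),
        }

        stage = "census"
        if config.census_path:
            census = io.read_gene_list(config.census_path)
        else:
            # synthetic census stand-in: planted genes plus a background slice
            rng = np.random.default_rng(seeds[stage])
            background = sorted(universe.gene_universe - planted)
            extra = rng.choice(len(background), size=min(30, len(background)), replace=False)
            census = planted | {background[i] for i in extra}
        up_census = ot.census_filter(up_hits, census)
        down_census = ot.census_filter(down_hits, census)
        pd.DataFrame(
            [dataclasses.asdict(r) for r in up_census + down_census]
        ).to_csv(outdir / "overtargeted_census.tsv", sep="\t", index=False)
        manifest["audit"]["census"] = {
            "census_size": len(census),
            "retained_up": len(up_census),
            "retained_down": len(down_census),
        }

        stage = "enrichment"
        genes_sorted = sorted(universe.gene_universe)
        third = max(1, len(genes_sorted) // 3)
        collections = {
            "planted_block": set(genes_sorted[:third]),
            "middle_block": set(genes_sorted[third : 2 * third]),
            "tail_block": set(genes_sorted[2 * third :]),
        }
        query = {r.gene_id for r in up_census + down_census}
        enr = ot.geneset_enrichment(query, collections, set(genes_sorted)) if query else pd.DataFrame()
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

        stage = "network"
        da_lookup = {r.feature_id: r for r in results}
        net_da = []
        for r in results:
            mir = to_mirna(r.feature_id)
            if mir:
                net_da.append(dataclasses.replace(r, feature_id=mir))
        category_map = {g: name for name, members in collections.items() for g in members}
        graph = ot.build_network(universe, net_da, up_census + down_census, category_map)
        ot.export_network(graph, outdir / "network.graphml", "graphml")
        ot.export_network(graph, outdir / "network.sif", "sif")
        manifest["audit"]["network"] = {
            "nodes": graph.number_of_nodes(),
            "edges": graph.number_of_edges(),
        }

        stage = "correlate"
        cohort = simulate.gen_cohort(
            sp.n_per_group, sp.n_per_group, seed=seeds[stage]
        )
        io.write_cohort(cohort, outdir / "cohort.tsv")
        corr = None
        if summary["up_ids"]:
            top = summary["up_ids"][0]
            idx = counts.feature_ids.index(top)
            lc = da.log2_cpm(counts, f, prior_count=dp.prior_count)
            case_samples = [s for s in counts.sample_ids if counts.group[s] == "case"]
            levels = {s: lc[idx, counts.sample_ids.index(s)] for s in case_samples}
            stages_map = {r.subject_id: r.t_stage for r in cohort if r.group == "case"}
            try:
                corr = clinical.correlate_with_stage(levels, stages_map)
                corr["feature"] = top
            except Exception as exc:  # degenerate synthetic draw
                logger.warning("correlation skipped: %s", exc)
        manifest["audit"]["correlation"] = corr
        manifest["audit"]["cohort_summary"] = clinical.cohort_summary(cohort)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    for path in sorted(outdir.iterdir()):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][path.name] = _sha(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
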