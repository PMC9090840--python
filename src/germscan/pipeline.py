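"""End-to-end driver: scan -> assign -> classify -> stats -> report.

run_pipeline executes the full inference chain on either a synthetic bundle
(the config's `simulate` block) or real input files, and returns a
machine-readable report with every computed quantity and a full parameter
echo.  The same (config, seed) always produces the identical report; stage
progress is logged to stderr, never into the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import assign as assign_mod
from . import expression as expr_mod
from . import scan as scan_mod
from ._rng import substream
from .config import RunConfig, config_to_dict
from .formats import (
    BedRecord,
    read_bedgraph,
    read_counts,
    read_gff3_genes,
    read_seqdict,
    write_bed,
)
from .simulate import TruthBundle, generate_bundle
from .stats import (
    STAGE_POOLS,
    fisher_or,
    genome_stage_comparison,
    mf_distribution,
    stage_proportions,
)

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("germscan")


class PipelineError(RuntimeError):
    """A stage failed; message carries the stage name and cause."""


def _hash_df(df: pd.DataFrame | pd.Series) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df, index=True).to_numpy().tobytes()
    ).hexdigest()


def _hash_track(track) -> str:
    h = hashlib.sha256()
    for name in track.seqdict:
        h.update(name.encode())
        h.update(track[name].tobytes())
    return h.hexdigest()


def _stage(name: str):
    log.info("stage %s", name)


def run_pipeline(config: RunConfig, bundle: TruthBundle | None = None) -> dict:
    """Run the full pipeline described by `config` and return the report.

    A pre-generated TruthBundle may be passed to skip regeneration (it must
    match the config's simulate block).  When config.outdir is set, tables
    and the report are written there.
    """
    checksums: dict[str, str] = {}
    stage = "load"
    try:
        if config.simulate is not None:
            _stage("simulate")
            if bundle is None:
                bundle = generate_bundle(config.simulate, config.seed)
            seqdict = bundle.seqdict
            sperm, blood = bundle.sperm, bundle.blood
            genes = bundle.genes
            counts, sheet = bundle.counts, bundle.sheet
            embryo_counts, embryo_sheet = bundle.embryo_counts, bundle.embryo_sheet
        else:
            _stage("load")
            paths = config.inputs
            seqdict = read_seqdict(paths.genome)
            sperm = read_bedgraph(paths.sperm, seqdict, sample="sperm")
            blood = read_bedgraph(paths.blood, seqdict, sample="blood")
            genes = read_gff3_genes(paths.genes, seqdict)
            counts, sheet = read_counts(paths.counts, paths.sheet, mode="gonad")
            embryo_counts = embryo_sheet = None
            if paths.embryo_counts and paths.embryo_sheet:
                embryo_counts, embryo_sheet = read_counts(
                    paths.embryo_counts, paths.embryo_sheet, mode="embryo"
                )
        checksums["sperm"] = _hash_track(sperm)
        checksums["blood"] = _hash_track(blood)
        checksums["counts"] = _hash_df(counts)

        # ---------------- scan ----------------
        stage = "scan"
        _stage("scan")
        scan_params = config.scan
        if scan_params.dmax is None and config.simulate is not None:
            # repeat guard: 10x the larger expected depth
            d = config.simulate.depth
            scan_params = scan_mod.ScanParams(
                **{
                    **{f: getattr(scan_params, f) for f in (
                        "V", "dmin", "psi", "tau", "alpha", "min_width", "n_perm", "seed"
                    )},
                    "dmax": int(10 * max(d.lambda_g, d.lambda_s)),
                }
            )
        afr = scan_mod.compute_afr(sperm, blood, scan_params)
        intervals = scan_mod.make_intervals(sperm, blood, scan_params, afr=afr)
        seg_rng = substream(config.seed, "segmentation")
        segments = scan_mod.segment(intervals, scan_params, rng=seg_rng)
        enriched, enriched_span = scan_mod.call_enriched(segments, scan_params.tau)
        seq_labels = scan_mod.classify_sequences(segments, seqdict, scan_params.tau)
        label_tally = {
            lab: sum(1 for v in seq_labels.values() if v == lab)
            for lab in ("germline", "somatic", "mixed")
        }

        # ---------------- assign ----------------
        stage = "assign"
        _stage("assign")
        deduped = assign_mod.dedupe_canonical(genes)
        table = assign_mod.assign_compartment(deduped, enriched)
        families = assign_mod.family_summary(table)
        gsr_ids = table.index[table["compartment"] == "GSR"]
        gsr_families = families[families["gsr_copies"] >= 1]

        # ---------------- classify ----------------
        stage = "classify"
        _stage("classify")
        shared = counts.index.intersection(table.index)
        counts_used = counts.loc[counts.index]  # full matrix for normalization
        sf = expr_mod.size_factors(counts_used)
        norm = expr_mod.normalize_counts(counts_used, sf)
        cls_params = config.classifier
        bias = expr_mod.classify_male_biased(norm, sheet, cls_params)
        summary = expr_mod.group_summary(
            norm,
            sheet,
            pooled={
                "male": cls_params.male_groups,
                "female": cls_params.female_groups,
            },
        )
        mf = expr_mod.log2_mf(
            norm, sheet, cls_params.c1, cls_params.male_groups, cls_params.female_groups
        )

        # ---------------- stats ----------------
        stage = "stats"
        _stage("stats")
        comp = table.loc[shared, "compartment"]
        strong = bias.loc[shared, "strong"]
        a = int((strong & (comp == "GSR")).sum())
        b = int((~strong & (comp == "GSR")).sum())
        c = int((strong & (comp == "somatic")).sum())
        d = int((~strong & (comp == "somatic")).sum())
        if min(a + b, c + d, a + c, b + d) == 0:
            # no strong genes (or a one-compartment genome): association
            # untestable, treat as the null rather than aborting
            or_result = None
        else:
            or_result = fisher_or(a, b, c, d)

        props, n_dropped = stage_proportions(norm, sheet, genes=shared)
        perm_rng = substream(config.seed, "permutation")
        comparable = comp.loc[props.index]
        if comparable.nunique() == 2:
            comparison = genome_stage_comparison(
                props,
                comp,
                n_perm=config.stats.n_perm,
                seed=perm_rng,
                alpha=config.stats.alpha,
            )
        else:
            comparison = None

        mf_modes = {}
        for label in ("GSR", "somatic"):
            vals = mf.loc[shared][comp == label]
            if len(vals) >= 2:
                mf_modes[label] = mf_distribution(vals).mode

        embryo_report = None
        if embryo_counts is not None:
            stage = "embryo"
            _stage("embryo")
            emb = expr_mod.embryo_classify(embryo_counts, embryo_sheet)
            emb_gsr = emb.loc[emb.index.intersection(gsr_ids)]
            embryo_report = {
                "n_gsr_genes_scored": int(len(emb_gsr)),
                "expressed_pre": int(emb_gsr["expressed_pre"].sum()),
                "expressed_post": int(emb_gsr["expressed_post"].sum()),
                "high_pre": int(emb_gsr["high_pre"].sum()),
                "high_post": int(emb_gsr["high_post"].sum()),
            }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    report = {
        "config": config_to_dict(config),
        "seed": config.seed,
        "afr": float(afr),
        "n_intervals": len(intervals),
        "n_segments": len(segments),
        "enriched_segments": len(enriched),
        "enriched_span": int(enriched_span),
        "sequence_classes": label_tally,
        "sequence_labels": seq_labels,
        "n_genes_input": len(genes),
        "n_genes_canonical": len(deduped),
        "n_genes_retained": int(len(table)),
        "gsg_count": int(len(gsr_ids)),
        "n_families_gsr": int(len(gsr_families)),
        "n_families_single_copy": int(gsr_families["single_copy_gsr"].sum()),
        "n_families_with_somatic_paralog": int(gsr_families["has_somatic_paralog"].sum()),
        "funnel": {
            "n_genes": int(len(bias)),
            "n_candidates": int(bias["candidate"].sum()),
            "n_passing": int(bias["passes_filter"].sum()),
            "n_strong": int(bias["strong"].sum()),
        },
        "two_by_two": {"a": a, "b": b, "c": c, "d": d},
        "odds_ratio": (
            or_result.odds_ratio if or_result is not None else float("nan")
        ),
        "fisher_p": or_result.p_value if or_result is not None else 1.0,
        "fisher_log10_p": or_result.log10_p if or_result is not None else 0.0,
        "fisher_note": None if or_result is not None else "zero margin: no test",
        "stage_comparison": comparison,
        "stage_proportions_dropped": int(n_dropped),
        "mf_mode": mf_modes,
        "checksums": checksums,
    }

    if config.outdir:
        _write_outputs(
            Path(config.outdir), report, intervals, segments, table, families,
            sf, norm, summary, bias,
        )
    return report


def _write_outputs(
    outdir: Path, report, intervals, segments, table, families, sf, norm, summary, bias
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "seq": iv.seq, "start": iv.start, "end": iv.end,
                "n_valid": iv.n_valid, "d1": iv.d1, "d2": iv.d2, "score": iv.score,
            }
            for iv in intervals
        ]
    ).to_csv(outdir / "intervals.tsv", sep="\t", index=False, lineterminator="\n")
    write_bed(
        [
            BedRecord(s.seq, s.start, s.end, f"seg{i + 1}", round(s.score, 6))
            for i, s in enumerate(segments)
        ],
        outdir / "segments.bed",
    )
    pd.Series(report["sequence_labels"], name="label").rename_axis("seq").to_csv(
        outdir / "sequence_classes.tsv", sep="\t", lineterminator="\n"
    )
    table.to_csv(outdir / "compartments.tsv", sep="\t", lineterminator="\n")
    families.to_csv(outdir / "families.tsv", sep="\t", lineterminator="\n")
    sf.rename_axis("sample_id").to_csv(
        outdir / "size_factors.tsv", sep="\t", lineterminator="\n"
    )
    norm.to_csv(outdir / "normalized_counts.tsv", sep="\t", lineterminator="\n")
    summary.to_csv(outdir / "group_summary.tsv", sep="\t", lineterminator="\n")
    bias.to_csv(outdir / "bias_result.tsv", sep="\t", lineterminator="\n")
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def setup_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    log.handlers[:] = [handler]
    log.setLevel(level.upper())
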