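"""End-to-end orchestration: simulate -> differential -> joint -> TE
association -> APA, with deterministic TSV outputs and a run manifest."""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__, apa, differential, jointclass, simulate, teassoc
from .genome import write_gff3, write_partition_bed

__all__ = ["RunConfig", "run_pipeline", "write_report", "PipelineError"]

FLOAT_FORMAT = "%.6g"


class PipelineError(RuntimeError):
    """Wraps a stage failure with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    synthetic: simulate.SyntheticConfig
    out_dir: Path
    padj_max: float = 0.05
    fc_min: float = 1.2
    max_d: int = 1000
    step: int = 100
    n_resample: int = 200
    n_random: int = 200

    @property
    def seed(self) -> int:
        return self.synthetic.seed


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Run every stage on synthetic data; write stage TSVs plus a summary.

    Any stage failure raises :class:`PipelineError` naming the stage;
    outputs of completed stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: Dict[str, object] = {}

    # --- simulate -----------------------------------------------------------
    stage = "simulate"
    try:
        cfg = config.synthetic
        annotation, truth = simulate.generate_annotation(cfg)
        rna_counts, rna_samples, truth = simulate.generate_count_matrix(
            cfg, annotation, "rna", truth
        )
        k9_counts, k9_samples, truth = simulate.generate_count_matrix(
            cfg, annotation, "chip_k9", truth
        )
        h3_counts, h3_samples, _ = simulate.generate_count_matrix(
            cfg, annotation, "chip_h3", truth
        )
        apa_ds, apa_truth = simulate.generate_apa_dataset(cfg)

        write_gff3(annotation, out / "annotation.gff3")
        write_partition_bed(annotation.partition, out / "partition.bed")
        for name, counts, samples in (
            ("rna", rna_counts, rna_samples),
            ("k9", k9_counts, k9_samples),
            ("h3", h3_counts, h3_samples),
        ):
            _write_tsv(counts, out / f"counts_{name}.tsv")
            _write_tsv(samples.drop(columns=["true_size_factor"]), out / f"samples_{name}.tsv")
        truth_df = pd.DataFrame(
            {
                "feature": list(truth.rna_direction),
                "rna_true": list(truth.rna_direction.values()),
                "k9_true": [truth.k9_direction[f] for f in truth.rna_direction],
            }
        ).set_index("feature")
        _write_tsv(truth_df, out / "truth.tsv")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError(stage, exc) from exc

    # --- differential -------------------------------------------------------
    stage = "differential"
    try:
        diff = {}
        for name, counts, samples in (
            ("rna", rna_counts, rna_samples),
            ("k9", k9_counts, k9_samples),
        ):
            filt = differential.filter_expressed(counts)
            sf = differential.estimate_size_factors(filt)
            res = differential.nb_wald_test(filt, samples, sf)
            res = differential.call_differential(
                res, padj_max=config.padj_max, fc_min=config.fc_min
            )
            diff[name] = res
            _write_tsv(res, out / f"diff_{name}.tsv")
        qc = differential.replicate_spearman(rna_counts, rna_samples)
        _write_tsv(qc, out / "qc_spearman.tsv", index=False)
        results["diff"] = diff
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- joint classification ----------------------------------------------
    stage = "joint"
    try:
        joint = jointclass.classify_joint(diff["rna"], diff["k9"])
        quad_df = pd.DataFrame(
            [
                {"rna_call": r, "k9_call": k, "count": v}
                for (r, k), v in sorted(joint.quadrants.items())
            ]
        )
        _write_tsv(quad_df, out / "joint_quadrants.tsv", index=False)

        gene_ids = [g.id for g in annotation.genes]
        cats = pd.DataFrame(
            [
                {"feature": g.id, "category": c}
                for g in annotation.genes
                for c in sorted(g.categories)
            ]
        )
        balance = jointclass.category_balance(
            diff["rna"].loc[diff["rna"].index.intersection(gene_ids), "call"], cats
        )
        _write_tsv(balance, out / "balance.tsv", index=False)
        results["joint"] = joint
        results["balance"] = balance
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- TE association -----------------------------------------------------
    stage = "te_association"
    try:
        nlr = [g for g in annotation.genes if g.is_nlr]
        non_nlr = [g for g in annotation.genes if not g.is_nlr]
        curve = teassoc.association_curve(
            nlr,
            non_nlr,
            annotation.tes,
            chrom_lengths=annotation.chrom_lengths,
            max_d=config.max_d,
            step=config.step,
            n_resample=config.n_resample,
            seed=config.seed,
        )
        _write_tsv(curve, out / "association_curve.tsv", index=False)

        focal = [g for g in annotation.genes if g.is_focal]
        rest_nlr = [g for g in annotation.genes if g.is_nlr and not g.is_focal]
        mean_a, mean_b, p_dist = teassoc.nearest_distance_ttest(
            focal, rest_nlr, annotation.tes
        )

        k9_up_tes = set(diff["k9"].index[diff["k9"]["call"] == "up"])
        focal_tes = [t for t in annotation.tes if t.id in k9_up_tes]
        rows = []
        for compartment in ("arm", "pericentromere"):
            for fam in sorted({t.superfamily for t in annotation.tes}):
                row = teassoc.randomized_fisher_enrichment(
                    focal_tes,
                    annotation.tes,
                    annotation.partition,
                    fam,
                    compartment,
                    n_random=config.n_random,
                    seed=config.seed,
                )
                rows.append(row.as_dict())
        enrich = pd.DataFrame(rows)
        _write_tsv(enrich, out / "enrichment.tsv", index=False)
        results["curve"] = curve
        results["nearest"] = (mean_a, mean_b, p_dist)
        results["enrichment"] = enrich
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- APA ----------------------------------------------------------------
    stage = "apa"
    try:
        sites = apa.PolyASiteSet(
            gene_id=apa_ds.gene_id,
            chrom=apa_ds.chrom,
            strand=apa_ds.strand,
            sites=apa_ds.sites,
        )
        tracks = {
            sid: apa.coverage_cpm(
                apa.CoverageTrack(
                    apa_ds.chrom, apa_ds.track_start, vals, apa_ds.total_reads[sid]
                )
            )
            for sid, vals in apa_ds.tracks.items()
        }
        seg = apa.segment_counts(tracks, sites)
        _write_tsv(seg, out / "apa_segments.tsv")
        wt_cols = [s for s in tracks if "_WT_" in s]
        mut_cols = [s for s in tracks if "_mutant_" in s]
        usage = apa.differential_segment_usage(
            seg[["seg_start", "seg_end"] + wt_cols], seg[["seg_start", "seg_end"] + mut_cols]
        )
        _write_tsv(usage, out / "apa_usage.tsv")
        wt_comb = apa.combine_and_subtract([tracks[s] for s in wt_cols])
        mut_comb = apa.combine_and_subtract([tracks[s] for s in mut_cols])
        drop = apa.detect_drop_site(wt_comb, mut_comb, sites)
        results["apa_usage"] = usage
        results["apa_drop_site"] = drop
        results["apa_truth"] = apa_truth
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- report -------------------------------------------------------------
    stage = "report"
    try:
        summary = write_report(results, out / "summary.tsv")
        results["summary"] = summary
        manifest = {
            "tool": "k9balance",
            "version": __version__,
            "seed": config.seed,
            "config_hash": hashlib.sha256(
                simulate.config_to_text(config.synthetic).encode()
            ).hexdigest(),
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    return results


def summarize_counts(up: int, down: int) -> Dict[str, float]:
    """Headline numbers from an up/down pair: total and integer percents."""
    pct_up, pct_down = jointclass.proportion_summary(up, down)
    return {"up": up, "down": down, "total": up + down, "percent_up": pct_up, "percent_down": pct_down}


def write_report(results: Dict[str, object], path: Optional[Path] = None) -> pd.DataFrame:
    """One summary row per headline quantity across the enabled stages."""
    rows = []
    diff = results.get("diff")
    if diff:
        for name, res in diff.items():
            up = int((res["call"] == "up").sum())
            down = int((res["call"] == "down").sum())
            s = summarize_counts(up, down) if up + down else {"up": 0, "down": 0, "total": 0, "percent_up": float("nan"), "percent_down": float("nan")}
            rows.append({"metric": f"{name}_n_up", "value": s["up"]})
            rows.append({"metric": f"{name}_n_down", "value": s["down"]})
            rows.append({"metric": f"{name}_n_total", "value": s["total"]})
            rows.append({"metric": f"{name}_percent_up", "value": s["percent_up"]})
    balance = results.get("balance")
    if balance is not None and len(balance):
        nlr_rows = balance[balance["category"] == "NLR"]
        if len(nlr_rows):
            r = nlr_rows.iloc[0]
            rows.append({"metric": "nlr_up", "value": int(r["up"])})
            rows.append({"metric": "nlr_down", "value": int(r["down"])})
            rows.append({"metric": "nlr_balance_p", "value": r["p"]})
    curve = results.get("curve")
    if curve is not None:
        d0 = curve[curve["distance"] == 0].iloc[0]
        rows.append(
            {
                "metric": "te_bp_excess_d0",
                "value": d0["mean_focal"] - d0["mean_background"],
            }
        )
    if "apa_drop_site" in results:
        drop = results["apa_drop_site"]
        rows.append({"metric": "apa_drop_site", "value": -1 if drop is None else drop})
    summary = pd.DataFrame(rows, columns=["metric", "value"])
    if path is not None:
        summary.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return summary
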