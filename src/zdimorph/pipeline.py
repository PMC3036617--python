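"""End-to-end orchestration: simulate -> preprocess -> filter -> SAM ->
collapse -> enrichment -> cross-species comparison.

One :class:`PipelineConfig` drives the whole run.  Every stage draws its
randomness from a child seed derived from the global seed and the stage
name, so stages can be re-run independently and a full run is reproducible
byte-for-byte.  `run_all` writes every intermediate artifact as TSV/JSON
next to the report so any downstream stage can be re-run from disk.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_model, filtering, preprocess
from .collapse import GeneCall, collapse, summarize_table1
from .cross_species import compare, overlap_check
from .enrichment import distribution_report
from .sam import SamConfig, SAMTwoClass
from .simulate import SimConfig, simulate_experiment, write_truth

logger = logging.getLogger("zdimorph")

__all__ = ["PipelineConfig", "run_all", "run_species", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (stage-name-salted, < 2**31)."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Declarative configuration for a full synthetic two-species run."""

    sim: SimConfig = field(default_factory=SimConfig)
    sam: SamConfig = field(default_factory=SamConfig)
    sd_threshold: float = 0.30
    min_probes: int = 8
    qc_threshold: float = 0.9
    drop_flagged: bool = False
    seed: int = 0
    outdir: str = "zdimorph_run"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        sam_raw = raw.pop("sam", {})
        if "delta_grid" in sam_raw:
            sam_raw["delta_grid"] = np.asarray(sam_raw["delta_grid"], dtype=float)
        sam = SamConfig(**sam_raw)
        return cls(sim=sim, sam=sam, **raw)

    def to_yaml(self, path) -> None:
        def _clean(obj):
            d = dataclasses.asdict(obj)
            return {
                k: (v.tolist() if isinstance(v, np.ndarray) else list(v) if isinstance(v, tuple) else v)
                for k, v in d.items()
            }

        payload = {
            "sim": _clean(self.sim),
            "sam": _clean(self.sam),
            "sd_threshold": self.sd_threshold,
            "min_probes": self.min_probes,
            "qc_threshold": self.qc_threshold,
            "drop_flagged": self.drop_flagged,
            "seed": self.seed,
            "outdir": str(self.outdir),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


def run_species(
    probes: pd.DataFrame,
    design: data_model.ArrayDesign,
    sheet: data_model.SampleSheet,
    species: str,
    sam_config: SamConfig,
    cgh_mask=None,
    sd_threshold: float = 0.30,
    min_probes: int = 8,
    qc_threshold: float = 0.9,
    drop_flagged: bool = False,
) -> dict:
    """Run one species through normalize -> summarize -> filter -> SAM -> collapse.

    Returns a dict with the expression matrix, filter report, fitted
    :class:`SAMResults`, per-EST call table, gene calls and summaries.
    """
    t0 = time.time()
    normalized = preprocess.quantile_normalize(probes)
    expr = preprocess.median_polish_summarize(normalized, design)
    qc = preprocess.sample_qc(expr, sheet, threshold=qc_threshold)
    dropped = [s for s in qc.flagged if s in expr.columns]
    if drop_flagged and dropped:
        logger.info("%s: dropping %d flagged sample(s): %s", species, len(dropped), dropped)
        expr = expr.drop(columns=dropped)
    filtered, filter_report = filtering.filter_expression(
        expr, design, cgh_mask=cgh_mask, sd_threshold=sd_threshold, min_probes=min_probes
    )
    model = SAMTwoClass.from_frames(filtered, sheet, group_by="sex", species=species)
    results = model.fit(sam_config)
    direction = results.direction()
    fc = results.fold_changes()
    est_calls = pd.DataFrame({"direction": direction, "fold_change": fc})
    gene_calls, collapse_summary = collapse(est_calls, design)
    table1 = summarize_table1(gene_calls, est_calls)
    enrich = distribution_report(gene_calls, design)
    logger.info(
        "%s: %d/%d ESTs significant, %d genes, %.1fs",
        species,
        results.n_called,
        len(filtered),
        collapse_summary.n_genes,
        time.time() - t0,
    )
    return {
        "species": species,
        "expression": expr,
        "filtered": filtered,
        "qc": qc,
        "filter_report": filter_report,
        "sam": results,
        "est_calls": est_calls,
        "gene_calls": gene_calls,
        "collapse_summary": collapse_summary,
        "table1": table1,
        "enrichment": enrich,
    }


def _recovery_metrics(est_calls: pd.DataFrame, truth: pd.DataFrame, tested_ests, species_col: str) -> dict:
    """Truth-table comparison for one species' calls."""
    direction_col = f"direction_{species_col}"
    tested = truth.loc[[e for e in tested_ests if e in truth.index]]
    planted = tested[tested[direction_col] != "none"]
    called = set(est_calls.index)
    tp = [e for e in planted.index if e in called]
    sensitivity = len(tp) / len(planted) if len(planted) else float("nan")
    wrong_direction = sum(
        1 for e in tp if est_calls.at[e, "direction"] != planted.at[e, direction_col]
    )
    false_calls = [e for e in called if e in tested.index and tested.at[e, direction_col] == "none"]
    return {
        "n_planted_testable": int(len(planted)),
        "n_called": int(len(called)),
        "n_true_positive": int(len(tp)),
        "sensitivity": sensitivity,
        "n_false_positive": int(len(false_calls)),
        "false_direction_rate": (wrong_direction / len(tp)) if tp else 0.0,
    }


def run_all(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full synthetic two-species analysis; returns the report."""
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "seed": config.seed}
    t_start = time.time()

    # ------------------------------------------------------------------ simulate
    sim_cfg = dataclasses.replace(config.sim, seed=stage_seed(config.seed, "simulate"))
    exp = simulate_experiment(sim_cfg)
    sp_a, sp_b = sim_cfg.species_labels
    data_model.write_design(exp.design, outdir / "design.tsv")
    data_model.write_sample_sheet(exp.samples, outdir / "samples.tsv")
    for sp in (sp_a, sp_b):
        data_model.write_probe_matrix(exp.probes[sp], outdir / f"probes_{sp}.tsv")
    (outdir / "cgh_mask.txt").write_text("\n".join(exp.cgh_mask) + "\n")
    write_truth(exp.truth, outdir / "truth.tsv")
    report["stages"]["simulate"] = {
        "n_ests": exp.design.n_ests,
        "n_probes": exp.design.n_probes,
        "n_masked_probes": len(exp.cgh_mask),
        "seed": sim_cfg.seed,
    }

    # ------------------------------------------------------------ per species
    species_out: dict[str, dict] = {}
    for sp, mask in ((sp_a, None), (sp_b, exp.cgh_mask)):
        sam_cfg = dataclasses.replace(config.sam, seed=stage_seed(config.seed, f"sam_{sp}"))
        out = run_species(
            exp.probes[sp],
            exp.design,
            exp.samples,
            sp,
            sam_cfg,
            cgh_mask=mask,
            sd_threshold=config.sd_threshold,
            min_probes=config.min_probes,
            qc_threshold=config.qc_threshold,
            drop_flagged=config.drop_flagged,
        )
        species_out[sp] = out
        data_model.write_expression(out["expression"], outdir / f"expression_{sp}.tsv")
        data_model.write_expression(out["filtered"], outdir / f"filtered_{sp}.tsv")
        out["sam"].save_tsv(outdir / f"sam_{sp}.tsv")
        tag = "a" if sp == sp_a else "b"
        recovery = _recovery_metrics(
            out["est_calls"], exp.truth, out["filtered"].index, tag
        )
        report["stages"][f"analysis_{sp}"] = {
            "filter": out["filter_report"].to_dict(),
            "qc_flagged": out["qc"].flagged,
            "sam": {
                "s0": out["sam"].s0,
                "delta": out["sam"].delta,
                "fdr": out["sam"].fdr,
                "n_significant": out["sam"].n_called,
                "seed": sam_cfg.seed,
            },
            "table1": out["table1"],
            "enrichment": out["enrichment"],
            "recovery": recovery,
        }

    # --------------------------------------------- population cross-check (B)
    pops = exp.samples.for_species(sp_b)["population"].unique()
    pop_report = None
    if len(pops) == 2:
        sam_cfg = dataclasses.replace(config.sam, seed=stage_seed(config.seed, "sam_population"))
        pop_model = SAMTwoClass.from_frames(
            species_out[sp_b]["filtered"],
            exp.samples,
            group_by="population",
            control=str(pops[0]),
            treatment=str(pops[1]),
            species=sp_b,
        )
        pop_results = pop_model.fit(sam_cfg)
        n_overlap, overlap_ids = overlap_check(
            pop_results.significant, species_out[sp_b]["est_calls"].index
        )
        pop_report = {
            "n_population_biased_ests": pop_results.n_called,
            "fdr": pop_results.fdr,
            "delta": pop_results.delta,
            "overlap_with_sex_biased": n_overlap,
            "overlap_ids": overlap_ids,
        }
    report["stages"]["population_check"] = pop_report

    # ------------------------------------------------------------- comparison
    fp = exp.design.fingerprint()
    filtered_b_ests = set(species_out[sp_b]["filtered"].index)
    gene_of = exp.design.effective_gene_ids()
    testable_b_genes = {str(gene_of[e]) for e in filtered_b_ests}
    untestable = {
        g.gene_id
        for g in species_out[sp_a]["gene_calls"]
        if g.gene_id not in testable_b_genes
    }
    comparison = compare(
        species_out[sp_a]["gene_calls"],
        species_out[sp_b]["gene_calls"],
        untestable_in_b=untestable,
        design_fingerprint_a=fp,
        design_fingerprint_b=fp,
    )
    report["stages"]["comparison"] = comparison.to_dict()
    report["elapsed_seconds"] = round(time.time() - t_start, 2)

    config.to_yaml(outdir / "resolved_config.yaml")
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (set, tuple)):
        return sorted(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
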