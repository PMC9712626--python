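"""End-to-end orchestration: gate -> filters -> taxonomy -> clip -> miRNA.

Every stage is a pure function of (inputs, config); outputs are TSV/JSON
files listed in a manifest with sha256 checksums, so a rerun with the same
config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, io_formats
from .clip_enrichment import define_regions, build_hit_matrix, group_enrichment, enrichment_frame, significant_rbps
from .expression_gate import call_expressed
from .ir_classification import classify_nirt_cirt, prevalence_filter
from .mirna_activity import group_pir_shift_test, target_concordance_test, target_shift_test
from .taxonomy import SpatiotemporalTaxonomy, assignments_frame

log = logging.getLogger("irtax")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Paths plus every threshold of the pipeline; the seed is mandatory."""

    # inputs
    sample_sheet: str
    pir_table: str
    intron_bed: str
    crosslink_beds: dict  # rbp name -> path
    expression_tsv: str
    gmt: str
    de_tables: list  # paths; first = time contrast, second = mutant contrast
    out_dir: str
    seed: int
    # thresholds
    min_pir: float = 10.0
    min_prevalent_samples: int = 3
    nuc_min: float = 20.0
    cyt_cirt_min: float = 15.0
    cyt_nirt_max: float = 5.0
    min_delta: float = 15.0
    gate_alpha: float = 0.01
    enrich_alpha: float = 0.01
    # taxonomy
    n_components: int = 3
    k_clusters: int = 3
    centering: str = "row_center"
    focus_div: int = 14  # time point for the genotype PIR-shift tests

    def __post_init__(self) -> None:
        if self.seed is None:
            raise PipelineError("a seed is mandatory")
        for name, val, lo, hi in (
            ("min_pir", self.min_pir, 0, 100),
            ("nuc_min", self.nuc_min, 0, 100),
            ("cyt_cirt_min", self.cyt_cirt_min, 0, 100),
            ("cyt_nirt_max", self.cyt_nirt_max, 0, 100),
            ("min_delta", self.min_delta, 0, 100),
            ("gate_alpha", self.gate_alpha, 0, 1),
            ("enrich_alpha", self.enrich_alpha, 0, 1),
        ):
            if not lo <= val <= hi:
                raise PipelineError(f"{name}={val} outside [{lo},{hi}]")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _expression_conditions(columns) -> pd.Series:
    """Column naming convention <condition>_r<k>; the suffix is the replicate."""
    conds = {}
    for c in columns:
        stem, _, rep = c.rpartition("_r")
        if not stem or not rep.isdigit():
            raise PipelineError(f"expression column {c!r} does not end in _r<k>")
        conds[c] = stem
    return pd.Series(conds)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns the manifest dict (also written)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    timings = {}

    def _stage(name):
        log.info("stage %s", name)
        timings[name] = time.time()
        return name

    def _done(name):
        timings[name] = round(time.time() - timings[name], 3)

    # ---- io ----------------------------------------------------------------
    stage = _stage("io")
    try:
        samples = io_formats.read_sample_sheet(config.sample_sheet)
        pir = io_formats.read_pir_table(config.pir_table, samples)
        introns = io_formats.read_intron_bed(config.intron_bed)
        tracks = [
            io_formats.read_crosslink_bed(path, rbp)
            for rbp, path in sorted(config.crosslink_beds.items())
        ]
        expr = pd.read_csv(config.expression_tsv, sep="\t", comment="#", index_col=0)
        target_sets = io_formats.read_gmt(config.gmt)
        de_tables = [io_formats.read_de_table(p) for p in config.de_tables]
    except Exception as exc:
        raise PipelineError(f"stage io failed: {exc}") from exc
    _done(stage)

    # ---- gate --------------------------------------------------------------
    stage = _stage("gate")
    by_cond, universe, fits = call_expressed(
        expr, _expression_conditions(expr.columns), alpha=config.gate_alpha
    )
    gate_df = pd.DataFrame(
        {cond: expr.index.isin(sorted(genes)) for cond, genes in sorted(by_cond.items())},
        index=expr.index,
    )
    p = out / "expressed_by_condition.tsv"
    with open(p, "w") as fh:
        fh.write(f"# irtax {__version__} seed={config.seed}\n")
        gate_df.to_csv(fh, sep="\t")
    written.append(p)
    log.info("gate: %d/%d genes expressed somewhere", len(universe), len(expr))
    _done(stage)

    # ---- filters / classification -------------------------------------------
    stage = _stage("classify")
    prevalent = prevalence_filter(
        pir, config.min_pir, config.min_prevalent_samples, "nucleus"
    )
    calls = classify_nirt_cirt(
        pir,
        nuc_min=config.nuc_min,
        cyt_cirt_min=config.cyt_cirt_min,
        cyt_nirt_max=config.cyt_nirt_max,
    )
    calls_df = pd.DataFrame(
        {
            "intron_id": [c.intron_id for c in calls],
            "class": [c.ir_class for c in calls],
            "max_pir_nucleus": [c.max_pir_nucleus for c in calls],
            "max_pir_cytoplasm": [c.max_pir_cytoplasm for c in calls],
            "condition_of_max": [c.condition_of_max for c in calls],
            "prevalent": [c.intron_id in prevalent for c in calls],
        }
    )
    p = out / "ir_calls.tsv"
    with open(p, "w") as fh:
        fh.write(f"# irtax {__version__} seed={config.seed}\n")
        calls_df.to_csv(fh, sep="\t", index=False)
    written.append(p)
    _done(stage)

    # ---- taxonomy ------------------------------------------------------------
    stage = _stage("taxonomy")
    pir_nuc = pir.subset_samples(fraction="nucleus")
    pir_cyt = pir.subset_samples(fraction="cytoplasm")
    tax = SpatiotemporalTaxonomy(
        n_components=config.n_components,
        k_clusters=config.k_clusters,
        centering=config.centering,
        seed=config.seed,
    ).fit(pir_nuc, pir_cyt)
    tax_df = assignments_frame(tax.assignments_)
    p = out / "taxonomy.tsv"
    with open(p, "w") as fh:
        fh.write(f"# irtax {__version__} seed={config.seed}\n")
        tax_df.to_csv(fh, sep="\t", index=False)
    written.append(p)
    groups = {
        g: set(tax_df.loc[tax_df["group"] == g, "intron_id"])
        for g in sorted(tax_df["group"].unique())
        if g != "unassigned"
    }
    _done(stage)

    # ---- clip ------------------------------------------------------------------
    stage = _stage("clip")
    annotated = {iv.intron_id for iv in introns}
    region_sets = [define_regions(iv) for iv in introns if iv.intron_id in annotated]
    hits = build_hit_matrix(tracks, region_sets, introns)
    background = set(hits.intron_ids)
    enr_rows = []
    sig = {}
    for g, members in sorted(groups.items()):
        members = members & background
        if not members:
            continue
        rows = group_enrichment(hits, members, background, "whole_intron", group_label=g)
        enr_rows.extend(rows)
        sig[g] = sorted(significant_rbps(rows, alpha=config.enrich_alpha))
    enr_df = enrichment_frame(enr_rows)
    p = out / "clip_enrichment.tsv"
    with open(p, "w") as fh:
        fh.write(f"# irtax {__version__} seed={config.seed}\n")
        enr_df.to_csv(fh, sep="\t", index=False)
    written.append(p)
    _done(stage)

    # ---- mirna ---------------------------------------------------------------
    stage = _stage("mirna")
    mirna_rows = []
    de_a = de_tables[0]
    de_b = de_tables[1] if len(de_tables) > 1 else de_tables[0]
    for ts in target_sets:
        ts_u = ts.restricted_to(universe)
        shift = target_shift_test(de_b, ts_u, universe)
        conc = target_concordance_test(de_a, de_b, ts_u, "negative", "positive", universe)
        mirna_rows.append(
            {
                "set_name": ts.set_name,
                "is_control": ts.is_control,
                "shift_t": shift.t_statistic,
                "shift_p": shift.p_value,
                "mean_target_log2fc": shift.mean_target,
                "mean_background_log2fc": shift.mean_background,
                "concordance_odds": conc.odds_ratio,
                "concordance_p": conc.p_value,
            }
        )
    mirna_df = pd.DataFrame(mirna_rows)
    # genotype PIR shift per recovered cytoplasmic group at the focus time point
    pir_shift = {}
    cyt14 = pir.subset_samples(fraction="cytoplasm", div_day=config.focus_div)
    for g, members in sorted(groups.items()):
        if not g.startswith("C"):
            continue
        res = group_pir_shift_test(cyt14, members)
        pir_shift[g] = {
            "effect": round(res.effect, 4),
            "p_value": res.p_value,
            "method": res.method,
            "n_introns": len(members),
        }
    p = out / "mirna_activity.tsv"
    with open(p, "w") as fh:
        fh.write(f"# irtax {__version__} seed={config.seed}\n")
        mirna_df.to_csv(fh, sep="\t", index=False)
    written.append(p)
    _done(stage)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "timings_s": timings,
        "counts": {
            "introns": len(pir.intron_ids),
            "samples": len(samples),
            "prevalent": len(prevalent),
            "cirt": int((calls_df["class"] == "CIRT").sum()),
            "nirt": int((calls_df["class"] == "NIRT").sum()),
            "assigned": int((tax_df["group"] != "unassigned").sum()),
            "expressed_genes": len(universe),
        },
        "significant_rbps": sig,
        "group_pir_shift": pir_shift,
        "outputs": {str(p.name): _sha256(p) for p in written},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
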