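"""End-to-end orchestration: simulate -> normalize -> enrich -> decay -> stability.

A run is driven by a :class:`PipelineConfig` (flat YAML file; unknown keys
rejected) and writes plain TSV outputs plus a JSON run report recording the
effective parameters, per-stage filter survival counts, a config hash and
the package version. Identical config + seed produces byte-identical
outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import decay as decay_mod
from . import enrichment as enrich_mod
from . import simulate as sim_mod
from . import spikein as spikein_mod
from .io import read_tsv, write_tsv

ALL_STAGES = ("simulate", "normalize", "enrich", "decay", "stability")


@dataclass
class PipelineConfig:
    """Flat configuration for one pipeline run."""

    outdir: str = "lysorna_run"
    seed: int = 0
    stages: List[str] = field(default_factory=lambda: list(ALL_STAGES))
    # spike normalization
    rpk: bool = False
    min_reads: float = 10.0
    min_sample_fraction: float = 0.75
    # decay
    alpha: float = 0.05
    cap_h: float = decay_mod.HALFLIFE_CAP_H
    floor: float = decay_mod.BACKGROUND_FLOOR
    background_mode: str = "log_offset"
    z_mode: str = "max_then_divide"
    wt_genotype: str = "WT"
    ko_genotype: str = "ATG7_KO"
    # enrichment
    topscore_edges: List[float] = field(
        default_factory=lambda: list(enrich_mod.DEFAULT_TOPSCORE_EDGES)
    )
    # generator overrides (merged into SimulationConfig)
    simulation: Dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def effective(self) -> Dict[str, Any]:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation_config().to_dict()
        # the output location is run metadata, not an analysis parameter:
        # identical parameters + seed must hash (and report) identically
        d.pop("outdir", None)
        return d

    def simulation_config(self) -> sim_mod.SimulationConfig:
        params = dict(self.simulation)
        params.setdefault("seed", self.seed)
        return sim_mod.SimulationConfig(**params)


def _config_hash(effective: Dict[str, Any]) -> str:
    blob = json.dumps(effective, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: PipelineConfig) -> Dict[str, Any]:
    """Execute the enabled stages in fixed order and write a run report.

    Returns the report dictionary (also written to ``report.json`` in the
    output directory).
    """
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    effective = config.effective()
    report: Dict[str, Any] = {
        "version": __version__,
        "config_hash": _config_hash(effective),
        "effective_config": effective,
        "stages": {},
    }
    simcfg = config.simulation_config()

    truth = counts = spikes = design = norm = enrichment = None
    timecourse = mock = fits = retained = None

    if "simulate" in config.stages:
        truth = sim_mod.simulate_transcriptome(simcfg)
        design = sim_mod.default_design(
            genotypes=sorted(simcfg.torin_effect_by_genotype),
            n_replicates=simcfg.n_replicates,
        )
        counts, spikes = sim_mod.simulate_fraction_counts(truth, design, simcfg)
        timecourse, mock = sim_mod.simulate_pulse_chase(truth, simcfg)
        annotation = sim_mod.annotation_from_truth(truth)
        write_tsv(truth, outdir / "truth.tsv")
        write_tsv(design, outdir / "design.tsv")
        write_tsv(counts, outdir / "counts.tsv")
        write_tsv(spikes, outdir / "spikein_reads.tsv")
        write_tsv(timecourse, outdir / "timecourse.tsv")
        write_tsv(mock, outdir / "mock.tsv")
        write_tsv(annotation, outdir / "annotation.tsv")
        report["stages"]["simulate"] = {
            "n_genes": int(len(truth)),
            "n_samples": int(len(design)),
            "n_spikes": int(len(spikes)),
            "n_timecourse_rows": int(len(timecourse)),
        }

    if "normalize" in config.stages:
        if counts is None:
            counts = read_tsv(outdir / "counts.tsv")
            spikes = read_tsv(outdir / "spikein_reads.tsv")
            design = read_tsv(outdir / "design.tsv")
        norm, norm_spikes, slopes = spikein_mod.normalize_counts(
            counts, spikes, design,
            rpk=config.rpk,
            min_reads=config.min_reads,
            min_sample_fraction=config.min_sample_fraction,
        )
        write_tsv(norm, outdir / "normalized.tsv")
        write_tsv(norm_spikes, outdir / "normalized_spikes.tsv")
        report["stages"]["normalize"] = {
            "spikes_in": int(len(spikes)),
            "spikes_retained": int(len(norm_spikes)),
            "slopes": {k: float(v) for k, v in slopes.items()},
        }

    if "enrich" in config.stages:
        if norm is None:
            norm = read_tsv(outdir / "normalized.tsv")
            design = read_tsv(outdir / "design.tsv")
        annotation = read_tsv(outdir / "annotation.tsv") if (outdir / "annotation.tsv").exists() else None
        enrichment = enrich_mod.enrichment_table(norm, design)
        write_tsv(enrichment, outdir / "enrichment.tsv")
        e_cols = [c for c in enrichment.columns if c.startswith("E_")]
        summaries = []
        if annotation is not None:
            for col in e_cols:
                summary = enrich_mod.class_summary(
                    pd.Series(
                        enrichment[col].to_numpy(), index=enrichment["gene_id"]
                    ),
                    annotation,
                    grouping="rna_class",
                    topscore_edges=config.topscore_edges,
                )
                summary.insert(0, "condition", col)
                summaries.append(summary)
            write_tsv(pd.concat(summaries, ignore_index=True), outdir / "summaries.tsv")
        report["stages"]["enrich"] = {
            "conditions": e_cols,
            "genes_total": int(len(enrichment)),
            "genes_defined": {
                c: int(enrichment[c].notna().sum()) for c in e_cols
            },
        }

    if "decay" in config.stages:
        if timecourse is None:
            timecourse = read_tsv(outdir / "timecourse.tsv")
            mock = read_tsv(outdir / "mock.tsv")
        fits = decay_mod.fit_timecourse(
            timecourse, mock,
            nluc_id=simcfg.nluc_id,
            floor=config.floor,
            cap_h=config.cap_h,
            background_mode=config.background_mode,
            z_mode=config.z_mode,
        )
        retained = decay_mod.filter_fits(fits, alpha=config.alpha)
        write_tsv(fits, outdir / "fits.tsv")
        write_tsv(retained, outdir / "fits_retained.tsv")
        halflives = decay_mod.average_replicates(retained)
        write_tsv(halflives, outdir / "halflives.tsv")
        report["stages"]["decay"] = {
            "fits_total": int(len(fits)),
            "fits_converged": int(fits["converged"].sum()) if len(fits) else 0,
            "fits_retained": int(len(retained)),
            "genes_with_halflife": int(halflives["gene_id"].nunique()) if len(halflives) else 0,
        }

    if "stability" in config.stages:
        halflives = read_tsv(outdir / "halflives.tsv")
        stability = decay_mod.stability_table(
            halflives, wt_genotype=config.wt_genotype, ko_genotype=config.ko_genotype
        )
        write_tsv(stability, outdir / "stability.tsv")
        report["stages"]["stability"] = {
            "genes_total": int(len(stability)),
            "genes_defined": int(stability["stability"].notna().sum()),
        }

    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return report


def validate_tables(
    counts: Optional[pd.DataFrame] = None,
    design: Optional[pd.DataFrame] = None,
    spikes: Optional[pd.DataFrame] = None,
    annotation: Optional[pd.DataFrame] = None,
    timecourse: Optional[pd.DataFrame] = None,
    mock: Optional[pd.DataFrame] = None,
) -> List[Dict[str, str]]:
    """Schema, uniqueness, positivity and design-completeness checks.

    Returns a list of findings (empty when all supplied tables are clean);
    never coerces or repairs.
    """
    findings: List[Dict[str, str]] = []

    def add(table: str, rule: str, detail: str) -> None:
        findings.append({"table": table, "rule": rule, "detail": detail})

    def check_unique(table: str, df: pd.DataFrame, col: str) -> None:
        dup = df[col][df[col].duplicated()].unique()
        if len(dup):
            add(table, "unique_" + col, f"duplicated {col}: {list(dup[:10])}")

    if counts is not None:
        if "gene_id" not in counts.columns:
            add("counts", "schema", "missing gene_id column")
        else:
            check_unique("counts", counts, "gene_id")
        from .quantify import sample_columns

        for col in sample_columns(counts):
            vals = pd.to_numeric(counts[col], errors="coerce")
            if vals.isna().any():
                add("counts", "numeric", f"non-numeric values in column {col}")
            elif (vals < 0).any():
                add("counts", "nonnegative", f"negative counts in column {col}")
        if "length_nt" in counts.columns:
            bad = counts.loc[
                pd.to_numeric(counts["length_nt"], errors="coerce").fillna(0) <= 0,
                "gene_id",
            ]
            if len(bad):
                add("counts", "positive_length", f"nonpositive lengths: {list(bad[:10])}")

    if design is not None:
        required = {"sample_id", "genotype", "treatment", "fraction", "replicate", "capture_factor"}
        missing = required - set(design.columns)
        if missing:
            add("design", "schema", f"missing columns: {sorted(missing)}")
        else:
            check_unique("design", design, "sample_id")
            key = design[["genotype", "treatment", "fraction", "replicate"]]
            if key.duplicated().any():
                add("design", "unique_condition", "duplicated (genotype, treatment, fraction, replicate)")
            if (design["capture_factor"] <= 0).any():
                bad = design.loc[design["capture_factor"] <= 0, "sample_id"]
                add("design", "positive_capture", f"nonpositive capture factors: {list(bad)}")
            bad_frac = set(design["fraction"]) - {"whole_cell", "lyso", "mock"}
            if bad_frac:
                add("design", "fraction_values", f"unknown fractions: {sorted(bad_frac)}")
            for (genotype, treatment), grp in design.groupby(["genotype", "treatment"]):
                fr = set(grp["fraction"])
                if "lyso" in fr and "whole_cell" not in fr:
                    add(
                        "design", "completeness",
                        f"condition ({genotype}, {treatment}) has lyso but no whole_cell samples",
                    )

    if spikes is not None:
        if "spike_id" not in spikes.columns or "known_concentration" not in spikes.columns:
            add("spikes", "schema", "missing spike_id or known_concentration")
        else:
            check_unique("spikes", spikes, "spike_id")
            if (spikes["known_concentration"] <= 0).any():
                bad = spikes.loc[spikes["known_concentration"] <= 0, "spike_id"]
                add("spikes", "positive_concentration", f"nonpositive concentrations: {list(bad)}")

    if annotation is not None:
        if "gene_id" not in annotation.columns:
            add("annotation", "schema", "missing gene_id column")
        else:
            check_unique("annotation", annotation, "gene_id")

    if timecourse is not None:
        required = {"gene_id", "genotype", "treatment", "replicate", "time_h", "count"}
        missing = required - set(timecourse.columns)
        if missing:
            add("timecourse", "schema", f"missing columns: {sorted(missing)}")
        else:
            if (timecourse["time_h"] < 0).any():
                add("timecourse", "nonnegative_time", "negative timepoints present")
            if (timecourse["count"] < 0).any():
                add("timecourse", "nonnegative_count", "negative counts present")

    if mock is not None:
        if "gene_id" not in mock.columns or "t0_reads" not in mock.columns:
            add("mock", "schema", "missing gene_id or t0_reads")
        else:
            check_unique("mock", mock, "gene_id")
            if (mock["t0_reads"] <= 0).any():
                bad = mock.loc[mock["t0_reads"] <= 0, "gene_id"]
                add("mock", "positive_t0", f"nonpositive t0 reads: {list(bad[:10])}")

    if counts is not None and design is not None and "sample_id" in design.columns:
        from .quantify import sample_columns

        extra = set(design["sample_id"]) - set(sample_columns(counts))
        if "gene_id" in counts.columns and extra:
            add("cross", "design_samples_in_counts", f"design samples absent from counts: {sorted(extra)}")

    return findings
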