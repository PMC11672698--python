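"""End-to-end orchestration: load -> QC -> group -> scan -> annotate -> enrich.

Every stage writes its table before the next begins, failures abort with the
stage name attached, and a rerun with identical config and inputs reproduces
byte-identical TSVs (wall-clock timings live only in the JSON manifest).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import genes_near_markers, hypergeometric_enrichment, read_gmt
from .env_grouping import GROUP_UNASSIGNED, assign_groups
from .fst_scan import ScanParams, run_scan
from .io_formats import (
    read_flock_table,
    read_gtf_genes,
    read_ped_map,
    read_station_table,
    write_tsv,
)
from .qc import QcThresholds, apply_qc, ibs_mds

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Effective configuration of one pipeline run (CLI > file > defaults)."""

    ped: str = ""
    map: str = ""
    flocks_csv: str = ""
    stations_csv: str = ""
    gtf: str = ""
    gmt: str = ""
    out_dir: str = "fstscan_out"
    # qc
    sample_call_rate_min: float = 0.95
    snp_call_rate_min: float = 0.975
    hwe_p_min: float = 1e-5
    maf_min: float = 0.02
    mds_k: int = 2
    run_mds: bool = True
    # grouping
    breaking_temp: float = 21.0
    max_distance_km: float = 50.0
    # scan
    span_snps: int = 20
    sd_multiplier: float = 3.0
    sd_estimator: str = "sample"
    signature_max_gap_bp: int = 1_000_000
    weighting: str = "equal"
    # annotation
    window_bp: int = 250_000
    anchors: str = "outliers"  # or "peaks": annotate signature peak SNPs only
    seed: int = 0

    @classmethod
    def from_file(cls, path, overrides: dict | None = None) -> "PipelineConfig":
        """Flat ``key = value`` config file; unknown keys are an error."""
        values: dict = {}
        if path:
            types = {f.name: f.type for f in fields(cls)}
            defaults = cls()
            with open(path) as fh:
                for lineno, raw in enumerate(fh, start=1):
                    line = raw.split("#", 1)[0].strip()
                    if not line:
                        continue
                    if "=" not in line:
                        raise ValueError(f"{path} line {lineno}: expected key = value")
                    key, value = (t.strip() for t in line.split("=", 1))
                    if key not in types:
                        raise ValueError(f"{path} line {lineno}: unknown key {key!r}")
                    current = getattr(defaults, key)
                    if isinstance(current, bool):
                        values[key] = value.lower() in {"1", "true", "yes"}
                    elif isinstance(current, int):
                        values[key] = int(value)
                    elif isinstance(current, float):
                        values[key] = float(value)
                    else:
                        values[key] = value
        for key, value in (overrides or {}).items():
            if value is not None:
                values[key] = value
        return cls(**values)

    def qc_thresholds(self) -> QcThresholds:
        return QcThresholds(
            sample_call_rate_min=self.sample_call_rate_min,
            snp_call_rate_min=self.snp_call_rate_min,
            hwe_p_min=self.hwe_p_min,
            maf_min=self.maf_min,
        )

    def scan_params(self) -> ScanParams:
        return ScanParams(
            span_snps=self.span_snps,
            sd_multiplier=self.sd_multiplier,
            sd_estimator=self.sd_estimator,
            signature_max_gap_bp=self.signature_max_gap_bp,
            weighting=self.weighting,
        )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write outputs under ``config.out_dir``, return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "fstscan",
        "version": __version__,
        "config": asdict(config),
        "stages": {},
    }

    def stage(name):
        def wrap(fn):
            start = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"].setdefault(name, {})["seconds"] = round(
                time.perf_counter() - start, 3
            )
            return result

        return wrap

    # load ------------------------------------------------------------------
    def _load():
        for path in (config.ped, config.map):
            if not path or not Path(path).exists():
                raise FileNotFoundError(f"genotype input not found: {path!r}")
        return read_ped_map(config.ped, config.map)

    dataset = stage("load")(_load)
    manifest["stages"]["load"].update(
        samples=dataset.n_samples, markers=dataset.n_markers
    )

    # qc --------------------------------------------------------------------
    def _qc():
        clean, report = apply_qc(dataset, config.qc_thresholds())
        write_tsv(report.to_frame(), out / "qc_report.tsv")
        (out / "qc_log.txt").write_text("\n".join(report.summary_lines()) + "\n")
        return clean, report

    clean, qc_report = stage("qc")(_qc)
    manifest["stages"]["qc"].update(
        samples_retained=qc_report.samples_retained,
        markers_retained=qc_report.markers_retained,
        markers_removed=qc_report.removal_counts(),
    )

    if config.run_mds:
        def _mds():
            coords = ibs_mds(clean, k=config.mds_k)
            write_tsv(coords, out / "mds.tsv")
            return coords

        stage("mds")(_mds)

    # group -----------------------------------------------------------------
    def _group():
        flocks = read_flock_table(config.flocks_csv)
        stations = read_station_table(config.stations_csv)
        assignments = assign_groups(
            clean.samples,
            flocks,
            stations,
            breaking_temp=config.breaking_temp,
            max_distance_km=config.max_distance_km,
        )
        write_tsv(assignments, out / "assignments.tsv")
        return assignments

    assignments = stage("group")(_group)
    counts = assignments["group"].value_counts().to_dict()
    manifest["stages"]["group"].update(group_sizes=counts)

    # scan ------------------------------------------------------------------
    def _scan():
        usable = assignments[assignments["group"] != GROUP_UNASSIGNED]
        keep = clean.samples["sample_id"].isin(usable["sample_id"]).to_numpy()
        result = run_scan(clean.subset(sample_mask=keep), assignments, config.scan_params())
        write_tsv(result.scan_table, out / "scan.tsv")
        write_tsv(result.signatures, out / "signatures.tsv")
        chart = pd.DataFrame(
            [
                (c.chromosome, c.mean_smoothed, c.sd_smoothed, c.upper_limit,
                 len(c.flagged_snp_ids))
                for c in result.outlier_calls
            ],
            columns=["chromosome", "mean_smoothed", "sd_smoothed", "upper_limit", "n_outliers"],
        )
        write_tsv(chart, out / "control_chart.tsv")
        return result

    scan_result = stage("scan")(_scan)
    manifest["stages"]["scan"].update(
        outlier_snps=int(scan_result.scan_table["outlier"].sum()),
        signatures=len(scan_result.signatures),
    )

    # annotate --------------------------------------------------------------
    gene_list: list = []
    if config.gtf:
        def _annotate():
            genes = read_gtf_genes(config.gtf)
            if config.anchors == "peaks":
                peaks = scan_result.signatures["peak_snp_id"]
                anchors = scan_result.scan_table[
                    scan_result.scan_table["snp_id"].isin(peaks)
                ]
            else:
                anchors = scan_result.scan_table[scan_result.scan_table["outlier"]]
            hits, unique_genes = genes_near_markers(
                anchors[["snp_id", "chromosome", "position"]],
                genes,
                window=config.window_bp,
            )
            write_tsv(hits, out / "gene_hits.tsv")
            return hits, unique_genes

        hits, gene_list = stage("annotate")(_annotate)
        manifest["stages"]["annotate"].update(
            gene_hits=len(hits), unique_genes=len(gene_list)
        )
    else:
        manifest["stages"]["annotate"] = {"skipped": True}

    # enrich ----------------------------------------------------------------
    if config.gmt and config.gtf:
        def _enrich():
            terms = read_gmt(config.gmt)
            universe = [g.gene_id for g in read_gtf_genes(config.gtf)]
            result = hypergeometric_enrichment(gene_list, terms, universe)
            write_tsv(result, out / "enrichment.tsv")
            return result

        enrichment = stage("enrich")(_enrich)
        manifest["stages"]["enrich"].update(terms_tested=len(enrichment))
    else:
        manifest["stages"]["enrich"] = {"skipped": True}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
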