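"""End-to-end orchestration: simulate -> assign -> strata -> dosage -> qPCR.

Stages communicate through plain files (TSV / VCF / JSON), so any stage
can be re-run from its persisted inputs or fed externally produced data.
Each stage logs one structured line with its parameters, input hashes and
row counts; the final product is a machine-readable JSON summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import coverage, dosage, qpcr, strata
from .simulate import SimConfig, simulate_all

log = logging.getLogger("zwstrata")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs: simulation settings plus thresholds."""

    simulate: dict = field(default_factory=dict)  # SimConfig fields
    min_len: int = 5000
    zone: str = "default"
    polarity: str = "ZW"
    center: str = "mean"
    min_depth: int = 10
    min_qual: float = 20.0
    min_snps: int = 10
    min_prop: float = 0.20
    cutoff: float = 1.0
    alpha: float = 0.05
    reverse_control: bool = True
    outdir: str = "zwstrata_out"

    def __post_init__(self) -> None:
        if self.zone not in coverage.ZONE_PRESETS:
            raise ValueError(f"unknown zone preset {self.zone!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.min_prop <= 1:
            raise ValueError("min_prop must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _md5(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()[:12]


def _stage(name: str, inputs: dict[str, Path], **params) -> None:
    hashes = {k: _md5(Path(p)) for k, p in inputs.items()}
    log.info("stage=%s inputs=%s params=%s", name, hashes, params)


def _jsonable(obj):
    if isinstance(obj, strata.EnrichmentResult):
        return {k: _jsonable(v) for k, v in asdict(obj).items()} | {"fold": obj.fold}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and obj != obj:  # NaN
        return None
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in dependency order and write the summary JSON.

    Returns the summary dict (also written to ``<outdir>/summary.json``).
    All per-stage tables are persisted under ``outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_cfg = SimConfig.from_dict(config.simulate)

    try:
        paths = simulate_all(sim_cfg, outdir)
    except Exception as err:
        raise RuntimeError(f"[simulate] failed in {outdir}: {err}") from err
    _stage("simulate", paths, seed=sim_cfg.seed)

    # --- coverage assignment -------------------------------------------------
    try:
        cov = pd.read_csv(paths["coverage"], sep="\t")
        zones = coverage.ZONE_PRESETS[config.zone]
        assignments, median = coverage.assign_coverage(
            cov, min_len=config.min_len, zones=zones,
            polarity=config.polarity, center=config.center)
    except Exception as err:
        raise RuntimeError(f"[covassign] failed on {paths['coverage']}: {err}") from err
    assignments.to_csv(outdir / "assignments.tsv", sep="\t", index=False,
                       float_format="%.6g")
    tmap = pd.read_csv(paths["transcript_map"], sep="\t")
    transcripts, class_counts = coverage.map_transcripts(assignments, tmap)
    transcripts.to_csv(outdir / "transcript_classes.tsv", sep="\t", index=False)
    _stage("covassign", {"coverage": paths["coverage"]},
           min_len=config.min_len, zone=config.zone, median=round(median, 4),
           n_scaffolds=len(assignments))

    # --- SNP strata ----------------------------------------------------------
    try:
        sheet = pd.read_csv(paths["samples"], sep="\t")
        table = strata.read_vcf(paths["vcf"], sheet)
        kwargs = dict(min_depth=config.min_depth, min_qual=config.min_qual,
                      min_snps=config.min_snps, min_prop=config.min_prop)
        if config.reverse_control:
            snp_report = strata.reverse_control(table, assignments, **kwargs)
        else:
            snp_report = {"ZW": strata.run_polarity(table, assignments, "ZW", **kwargs)}
    except Exception as err:
        raise RuntimeError(f"[snpstrata] failed on {paths['vcf']}: {err}") from err
    for pol, rep in snp_report.items():
        if not isinstance(rep, dict):
            continue
        rep.pop("site_classes").to_csv(outdir / f"site_classes_{pol}.tsv",
                                       sep="\t", index=False)
        rep.pop("scaffold_summary").to_csv(outdir / f"scaffold_snp_summary_{pol}.tsv",
                                           sep="\t", index=False, float_format="%.6g")
    _stage("snpstrata", {"vcf": paths["vcf"]}, **kwargs,
           n_sites=snp_report["ZW"]["n_sites"])

    # --- dosage compensation -------------------------------------------------
    try:
        counts = pd.read_csv(paths["counts"], sep="\t", index_col=0)
        design = pd.read_csv(paths["design"], sep="\t")
        lengths = tmap.set_index("transcript")["length"]
        tr_classes = transcripts.set_index("transcript")["class"]
        dose_report = dosage.dosage_report(counts, lengths, design, tr_classes,
                                           cutoff=config.cutoff, alpha=config.alpha)
    except Exception as err:
        raise RuntimeError(f"[dosagex] failed on {paths['counts']}: {err}") from err
    _stage("dosagex", {"counts": paths["counts"]}, cutoff=config.cutoff,
           alpha=config.alpha)

    # --- qPCR validation -----------------------------------------------------
    try:
        cq = pd.read_csv(paths["qpcr"], sep="\t")
        qpcr_calls = qpcr.analyze_qpcr(cq)
    except Exception as err:
        raise RuntimeError(f"[qpcrval] failed on {paths['qpcr']}: {err}") from err
    qpcr_calls.to_csv(outdir / "qpcr_calls.tsv", sep="\t", index=False,
                      float_format="%.4g")
    _stage("qpcrval", {"qpcr": paths["qpcr"]}, n_genes=len(qpcr_calls))

    summary = {
        "seed": sim_cfg.seed,
        "scaffold_classes": assignments["class"].value_counts().to_dict(),
        "median_log2_fm": median,
        "transcript_classes": class_counts.to_dict(),
        "snp_strata": snp_report,
        "dosage": dose_report,
        "qpcr": {
            "n_z_linked": int((qpcr_calls["call"] == "Z_linked").sum()),
            "n_autosomal": int((qpcr_calls["call"] == "autosomal").sum()),
            "n_indeterminate": int((qpcr_calls["call"] == "indeterminate").sum()),
        },
    }
    summary = _jsonable(summary)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
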