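"""End-to-end orchestration: demux -> align -> consensus -> signatures.

A run is described by a declarative TOML config plus CLI overrides.  The
stages are executed per sample; parental samples (sequenced template
strand, carrying damage but no polymerase errors) are processed with the
identical pipeline and their mean signature is subtracted as the
parental background from every non-parental sample, together with an
optional user-supplied gapping-background table.  Every stage reports
record counts in/out, so attrition is auditable:
``total = short_read + unassigned + failed_alignment + passed`` and
``molecules = retained + discarded_low_copies``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from .consensus import ConsensusConfig, call_all_molecules, tabulate_errors
from .readprep import BarcodeLayout, process_paired_fastq, read_sample_sheet
from .roi import read_roi_fasta
from .signatures import (
    BackgroundEstimate,
    ErrorSignature,
    collapse_strand,
    compute_signature,
    scale_pdf,
    subtract_background,
    total_error_frequency,
)


@dataclass
class RunConfig:
    fastq1: str
    fastq2: str
    roi_fasta: str
    sample_sheet: str
    outdir: str
    roi_name: Optional[str] = None
    methylation_mode: str = "mock"
    parental_samples: List[str] = field(default_factory=list)
    gapping_background: Optional[str] = None
    max_mismatch: int = 0
    max_mismatch_frac: float = 0.10
    max_n_frac: float = 0.50
    min_phred: int = 20
    layout: BarcodeLayout = field(default_factory=BarcodeLayout)
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as f:
            raw = tomllib.load(f)
        layout = BarcodeLayout(**raw.pop("layout", {}))
        cons = ConsensusConfig(**raw.pop("consensus", {}))
        return cls(layout=layout, consensus=cons, **raw)


def validate_config(cfg: RunConfig) -> List[str]:
    """Collect config violations (empty list = ok). Never mutates."""
    problems: List[str] = []
    for name in ("fastq1", "fastq2", "roi_fasta", "sample_sheet"):
        p = getattr(cfg, name)
        if not p or not Path(p).exists():
            problems.append(f"{name}: path {p!r} does not exist")
    if cfg.gapping_background and not Path(cfg.gapping_background).exists():
        problems.append(f"gapping_background: path {cfg.gapping_background!r} does not exist")
    if cfg.methylation_mode not in ("mock", "m_sssi"):
        problems.append(f"methylation_mode: unknown value {cfg.methylation_mode!r}")
    for frac_name in ("max_mismatch_frac", "max_n_frac"):
        v = getattr(cfg, frac_name)
        if not (0 <= v <= 1):
            problems.append(f"{frac_name}: {v} outside [0, 1]")
    try:
        ConsensusConfig(
            cfg.consensus.copy_read_agreement,
            cfg.consensus.molecule_copy_agreement,
            cfg.consensus.min_linear_copies,
            cfg.consensus.min_reads_per_copy,
        )
    except (ValueError, TypeError) as e:
        problems.append(f"consensus: {e}")
    return problems


def run_perseq(cfg: RunConfig) -> dict:
    """Execute the full pipeline and write per-sample outputs + report.

    Returns the machine-readable run report (also written to
    ``<outdir>/report.json``).  Deterministic given identical inputs.
    """
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rois = read_roi_fasta(cfg.roi_fasta, cfg.methylation_mode)
    roi_name = cfg.roi_name or next(iter(rois))
    annotation = rois[roi_name]
    sheet = read_sample_sheet(cfg.sample_sheet)

    batches, demux_report = process_paired_fastq(
        cfg.fastq1, cfg.fastq2, cfg.layout, sheet, annotation,
        max_mismatch=cfg.max_mismatch, max_mismatch_frac=cfg.max_mismatch_frac,
        max_n_frac=cfg.max_n_frac, min_phred=cfg.min_phred,
    )

    gapping = np.zeros(192)
    if cfg.gapping_background:
        gapping = ErrorSignature.from_tsv(cfg.gapping_background).frequencies

    per_sample: Dict[str, dict] = {}
    raw_signatures: Dict[str, ErrorSignature] = {}
    for sample, batch in batches.items():
        mcs = call_all_molecules(batch, annotation, cfg.consensus)
        channels = tabulate_errors(mcs, annotation)
        sig = compute_signature(channels)
        raw_signatures[sample] = sig
        sdir = outdir / sample
        sdir.mkdir(exist_ok=True)
        mcs.to_frame().to_csv(sdir / "molecules.tsv", sep="\t", index=False)
        channels.to_csv(sdir / "channels.tsv", sep="\t", index=False)
        per_sample[sample] = {
            "reads_passed": int(demux_report.passed[sample]),
            "molecules_total": mcs.n_molecules_total,
            "molecules_retained": mcs.n_retained,
            "molecules_discarded_low_copies": mcs.n_discarded,
            "variants_called": int(len(mcs.variants)),
            "raw_total_error_frequency": total_error_frequency(sig),
        }

    parental = np.zeros(192)
    if cfg.parental_samples:
        mats = [raw_signatures[s].frequencies for s in cfg.parental_samples
                if s in raw_signatures]
        if mats:
            parental = np.mean(mats, axis=0)
    bg = BackgroundEstimate(parental=parental, gapping=gapping)

    for sample, sig in raw_signatures.items():
        sdir = outdir / sample
        sig.to_tsv(sdir / "signature_192_raw.tsv")
        if sample in cfg.parental_samples:
            continue
        sub = subtract_background(sig, bg)
        sub.to_tsv(sdir / "signature_192.tsv")
        collapse_strand(sub).to_tsv(sdir / "signature_96.tsv")
        if sub.frequencies.sum() > 0:
            scale_pdf(collapse_strand(sub)).to_tsv(sdir / "signature_96_pdf.tsv")
        per_sample[sample]["total_error_frequency"] = total_error_frequency(sub)

    report = {
        "roi": roi_name,
        "roi_length": len(annotation),
        "methylation_mode": cfg.methylation_mode,
        "demux": demux_report.to_dict(),
        "samples": per_sample,
        "parental_samples": list(cfg.parental_samples),
    }
    with open(outdir / "report.json", "w") as f:
        json.dump(report, f, indent=2, sort_keys=True)
    return report
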