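"""End-to-end orchestration of the four analysis stages.

A :class:`PipelineConfig` (typically loaded from YAML) names the inputs and
thresholds; :func:`run_pipeline` executes whichever stages have inputs,
writes plain-text TSV/JSON reports into the output directory, and records
every threshold, the seed and per-stage status in a run manifest.  Stages are
independent: one failing stage is recorded but does not abort the others
unless ``strict``.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .class_signature import scan_signature_positions
from .identity_stats import (
    DEFAULT_MIN_OCCUPANCY,
    identity_summary,
    pairwise_identity_matrix,
    trim_alignment,
)
from .io_formats import read_fasta_alignment
from .selection_pressure import dnds_table, read_codon_alignment
from .structure_screen import (
    DEFAULT_MIN_CONTACTS,
    DEFAULT_MIN_IDENTITY,
    DEFAULT_WINDOW,
    ScreenConfig,
    screen_structures,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str
    alignment: Optional[str] = None
    class_map: Optional[str] = None
    studied_class: Optional[str] = None
    reference_id: Optional[str] = None
    top_n: int = 10
    identity_alignments: dict[str, str] = field(default_factory=dict)
    min_occupancy: float = DEFAULT_MIN_OCCUPANCY
    codon_alignments: dict[str, str] = field(default_factory=dict)
    structures: list[str] = field(default_factory=list)
    window: tuple[int, int] = DEFAULT_WINDOW
    min_identity: float = DEFAULT_MIN_IDENTITY
    min_contacts: int = DEFAULT_MIN_CONTACTS
    seed: int = 0
    strict: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "window" in data:
            data["window"] = tuple(data["window"])
        return cls(**data)

    def validate(self) -> None:
        for p in ([self.alignment, self.class_map]
                  + list(self.identity_alignments.values())
                  + list(self.codon_alignments.values())
                  + list(self.structures)):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")
        if not (0.0 <= self.min_occupancy <= 1.0 and 0.0 <= self.min_identity <= 1.0):
            raise ValueError("thresholds out of range")


def _write_tsv(frame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns the manifest dict (also written to
    ``out_dir/manifest.json``).  Exit semantics: manifest["failed"] truthy iff
    any requested stage failed."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}

    def run_stage(name: str, func) -> None:
        t0 = time.perf_counter()
        try:
            outputs = func()
            stages[name] = {"status": "ok", "outputs": outputs,
                            "seconds": round(time.perf_counter() - t0, 3)}
        except Exception as exc:
            logger.exception("stage %s failed", name)
            stages[name] = {"status": "failed", "error": str(exc),
                            "seconds": round(time.perf_counter() - t0, 3)}
            if config.strict:
                raise

    if config.alignment and config.studied_class and config.reference_id:
        def signature_stage() -> list[str]:
            aln = read_fasta_alignment(config.alignment, class_map=config.class_map)
            report = scan_signature_positions(
                aln, config.studied_class, config.reference_id, config.top_n
            )
            _write_tsv(report.to_frame(), out / "signature_report.tsv")
            _write_tsv(report.track_frame(), out / "signature_track.tsv")
            return ["signature_report.tsv", "signature_track.tsv"]
        run_stage("signature", signature_stage)

    if config.identity_alignments:
        def identity_stage() -> list[str]:
            import pandas as pd
            rows = []
            for label, path in config.identity_alignments.items():
                aln = trim_alignment(read_fasta_alignment(path), config.min_occupancy)
                matrix = pairwise_identity_matrix(aln)
                _write_tsv(matrix.to_frame().reset_index(names="id"),
                           out / f"identity_matrix_{label}.tsv")
                rows.append(identity_summary(matrix, label).__dict__)
            _write_tsv(pd.DataFrame(rows), out / "identity_summary.tsv")
            return ["identity_summary.tsv"] + [
                f"identity_matrix_{label}.tsv" for label in config.identity_alignments
            ]
        run_stage("identity", identity_stage)

    if config.codon_alignments:
        def dnds_stage() -> list[str]:
            import pandas as pd
            outputs = []
            summary_rows = []
            for label, path in config.codon_alignments.items():
                table = dnds_table(read_codon_alignment(path))
                name = f"dnds_{label}.tsv"
                _write_tsv(table, out / name)
                outputs.append(name)
                pooled = table.iloc[-1]
                summary_rows.append({
                    "class_label": label,
                    "dN": pooled["dN"], "dS": pooled["dS"], "ratio": pooled["ratio"],
                    "purifying": (pooled["ratio"] < 1.0) if pooled["ratio"] == pooled["ratio"] else None,
                    "method": "counting (NG86-style)",
                })
            _write_tsv(pd.DataFrame(summary_rows), out / "dnds_summary.tsv")
            return outputs + ["dnds_summary.tsv"]
        run_stage("dnds", dnds_stage)

    if config.structures and config.alignment and config.reference_id:
        def screen_stage() -> list[str]:
            import pandas as pd
            aln = read_fasta_alignment(config.alignment, class_map=config.class_map)
            summary = screen_structures(
                config.structures, aln,
                ScreenConfig(reference_id=config.reference_id, window=config.window,
                             min_identity=config.min_identity,
                             min_contacts=config.min_contacts),
            )
            hist = pd.DataFrame(
                sorted(summary.strand_histogram.items()),
                columns=["strand_length", "n_structures"],
            )
            _write_tsv(hist, out / "screen_histogram.tsv")
            _write_tsv(summary.details, out / "screen_details.tsv")
            disc = pd.DataFrame(summary.discarded, columns=["structure", "reason"])
            _write_tsv(disc, out / "screen_discarded.tsv")
            return ["screen_histogram.tsv", "screen_details.tsv", "screen_discarded.tsv"]
        run_stage("screen", screen_stage)

    manifest = {
        "famsig_version": __version__,
        "seed": config.seed,
        "thresholds": {
            "min_occupancy": config.min_occupancy,
            "min_identity": config.min_identity,
            "min_contacts": config.min_contacts,
            "window": list(config.window),
            "top_n": config.top_n,
        },
        "config": {k: v for k, v in asdict(config).items()},
        "stages": stages,
        "failed": sorted(n for n, s in stages.items() if s["status"] != "ok"),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
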