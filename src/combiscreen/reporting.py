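"""Run configuration, CSV report rendering, and small published-formula helpers."""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .triage import ScreenResult

__all__ = [
    "RunConfig",
    "tumor_volume",
    "log2_fold_change",
    "write_reports_csv",
    "write_hits_csv",
    "write_class_summary_csv",
    "write_surface_csvs",
]


@dataclass
class RunConfig:
    """End-to-end run settings; mirrors the CLI flags and the YAML config."""

    readout: str = "viability"
    ci_max: float = 0.5
    beta_max: float = 1.0
    ci_policy: str = "median_in_band"
    dose_ceiling: float = 1e-5
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.ci_max <= 0 or self.beta_max <= 0:
            raise ValueError("thresholds must be positive")
        self.seed = int(self.seed)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (output paths excluded, so
        identical analyses produce identical file headers wherever written)."""
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def header_comment(self) -> str:
        return f"combiscreen v{__version__} config={self.config_hash()}"


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper tumor volume V = 1/2 * length * width^2 (mm^3).

    Length is the longer axis by convention; arguments violating
    length >= width are swapped with a warning.
    """
    if length_mm < 0 or width_mm < 0:
        raise ValueError("tumor dimensions must be nonnegative")
    if length_mm < width_mm:
        warnings.warn(
            f"length ({length_mm:g}) < width ({width_mm:g}); swapping to keep "
            "length as the long axis",
            stacklevel=2,
        )
        length_mm, width_mm = width_mm, length_mm
    return 0.5 * length_mm * width_mm**2


def log2_fold_change(treated: float, control: float) -> float:
    """log2(treated / control); both inputs must be positive."""
    if treated <= 0 or control <= 0:
        raise ValueError("treated and control must be positive")
    return float(np.log2(treated / control))


def _write_frame(frame: pd.DataFrame, path, header: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# {header}\n")
        frame.to_csv(fh, index=False, float_format="%.10g")


def write_reports_csv(result: ScreenResult, path, config: RunConfig) -> None:
    """One row per scored pair: sums, CI (+ the fa and well it was read at),
    beta, hit flag and QC flags."""
    _write_frame(result.to_frame(), path, config.header_comment())


def write_hits_csv(result: ScreenResult, path, config: RunConfig) -> None:
    frame = result.to_frame()
    _write_frame(frame[frame["hit"]].reset_index(drop=True), path, config.header_comment())


def write_class_summary_csv(result: ScreenResult, path, config: RunConfig) -> None:
    if result.class_summary is None:
        raise ValueError("class summary has not been computed; run aggregate_by_class")
    _write_frame(result.class_summary, path, config.header_comment())


def write_surface_csvs(result: ScreenResult, out_dir, config: RunConfig) -> list[Path]:
    """Heatmap-ready wide CSVs of the Excess-HSA and delta-Bliss surfaces,
    one file per pair per surface, doses rendered in nM."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for report in result.reports:
        for surface, tag in ((report.excess_hsa, "excess_hsa"), (report.delta_bliss, "delta_bliss")):
            safe = report.pair_id.replace("|", "_")
            path = out_dir / f"{safe}.{tag}.csv"
            frame = pd.DataFrame(surface)
            frame.index.name = "row_dose_level"
            _write_frame(frame.reset_index(), path, config.header_comment())
            written.append(path)
    return written
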