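"""Plate/matrix data model, CSV readers/writers, and signal normalization.

A combination screen is a collection of dose-matrix blocks: one block per
drug pair, holding a full factorial grid of raw readout over the two dose
series (each series includes a vehicle level at dose 0) and replicates.
All concentrations are stored in molar; reports render nM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CompoundRecord",
    "DoseMatrixBlock",
    "NormalizedMatrix",
    "ScreenDataset",
    "FormatError",
    "StructuralError",
    "NormalizationError",
    "read_screen_table",
    "write_screen_table",
    "normalize_block",
    "normalize_activity_to_viability",
]

ASSAYS = ("viability", "caspase")

#: Default viability floor below which activity/viability ratios are masked.
VIABILITY_FLOOR = 0.01


class FormatError(ValueError):
    """Input table does not conform to the expected CSV schema."""


class StructuralError(ValueError):
    """Dose grid is ragged or shapes are incongruent."""


class NormalizationError(ValueError):
    """Vehicle wells cannot anchor a percent-of-control normalization."""


@dataclass(frozen=True)
class CompoundRecord:
    """One library compound and its dose-series design.

    ``n_dose_levels`` counts the nonzero doses plus the vehicle level, so a
    6x6 block built from 5-fold serial dilutions has ``n_dose_levels = 6``.
    """

    compound_id: str
    name: str = ""
    moa_class: str = "unannotated"
    top_dose: float = 1e-5
    dilution_factor: float = 5.0
    n_dose_levels: int = 6

    def __post_init__(self) -> None:
        if self.top_dose <= 0:
            raise ValueError(f"top_dose must be > 0, got {self.top_dose}")
        if self.dilution_factor <= 1:
            raise ValueError(
                f"dilution_factor must be > 1, got {self.dilution_factor}"
            )
        if self.n_dose_levels < 2:
            raise ValueError(f"n_dose_levels must be >= 2, got {self.n_dose_levels}")

    def doses(self) -> np.ndarray:
        """Ascending dose vector in molar, vehicle (0) first."""
        n_nonzero = self.n_dose_levels - 1
        steps = self.top_dose / self.dilution_factor ** np.arange(
            n_nonzero - 1, -1, -1, dtype=float
        )
        return np.concatenate([[0.0], steps])


@dataclass
class DoseMatrixBlock:
    """Raw replicate signal grid for one drug pair.

    ``signal`` is indexed ``[i over dosesA, j over dosesB, r over replicates]``
    and holds the raw (nonnegative) readout of the chosen assay.
    """

    block_id: str
    drugA: CompoundRecord
    drugB: CompoundRecord
    dosesA: np.ndarray
    dosesB: np.ndarray
    signal: np.ndarray
    assay: str = "viability"

    def __post_init__(self) -> None:
        self.dosesA = np.asarray(self.dosesA, dtype=float)
        self.dosesB = np.asarray(self.dosesB, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.assay not in ASSAYS:
            raise ValueError(f"assay must be one of {ASSAYS}, got {self.assay!r}")
        for name, doses in (("dosesA", self.dosesA), ("dosesB", self.dosesB)):
            if doses.ndim != 1 or doses.size < 2:
                raise StructuralError(f"{name} must be a vector of >= 2 levels")
            if doses[0] != 0.0:
                raise StructuralError(f"{name}[0] must be the vehicle (0), got {doses[0]}")
            if np.any(np.diff(doses) <= 0):
                raise StructuralError(f"{name} must be strictly increasing")
        if self.signal.ndim != 3:
            raise StructuralError("signal must be a 3-axis grid [i, j, replicate]")
        expected = (self.dosesA.size, self.dosesB.size)
        if self.signal.shape[:2] != expected:
            raise StructuralError(
                f"signal grid {self.signal.shape[:2]} does not match dose vectors {expected}"
            )
        if self.signal.shape[2] < 1:
            raise StructuralError("at least one replicate is required")
        if np.any(self.signal < 0):
            raise ValueError("raw signal must be nonnegative")

    @property
    def n_replicates(self) -> int:
        return self.signal.shape[2]

    @property
    def pair_id(self) -> str:
        return f"{self.drugA.compound_id}|{self.drugB.compound_id}"


@dataclass
class NormalizedMatrix:
    """Fraction-of-control viability grid and derived fraction affected.

    ``v`` is the replicate-mean fraction of vehicle control (dimensionless,
    >= 0, may exceed 1); ``fa = clip(1 - v, 0, 1)`` is the fraction affected
    used by the median-effect machinery; ``v_rep`` keeps per-replicate grids
    for QC.
    """

    v: np.ndarray
    sem: np.ndarray
    fa: np.ndarray
    v_rep: np.ndarray
    dosesA: np.ndarray
    dosesB: np.ndarray
    block: DoseMatrixBlock | None = field(default=None, repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.v.shape


@dataclass
class ScreenDataset:
    """A screen: dose-matrix blocks plus the compound annotation table."""

    blocks: list[DoseMatrixBlock]
    compounds: dict[str, CompoundRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.blocks)

    def annotation_for(self, compound_id: str) -> CompoundRecord:
        rec = self.compounds.get(compound_id)
        if rec is None:
            rec = CompoundRecord(compound_id=compound_id, name=compound_id)
        return rec


LONG_COLUMNS = [
    "block_id",
    "drugA_id",
    "doseA",
    "drugB_id",
    "doseB",
    "replicate",
    "signal",
    "assay",
]

ANNOTATION_COLUMNS = ["compound_id", "name", "moa_class"]


def _read_annotations(annotation_path) -> dict[str, CompoundRecord]:
    ann = pd.read_csv(annotation_path, comment="#", float_precision="round_trip")
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise FormatError(f"annotation table is missing column(s): {', '.join(missing)}")
    records: dict[str, CompoundRecord] = {}
    for row in ann.itertuples(index=False):
        cid = str(row.compound_id)
        kwargs = {}
        for opt in ("top_dose", "dilution_factor", "n_dose_levels"):
            if hasattr(row, opt) and pd.notna(getattr(row, opt)):
                kwargs[opt] = getattr(row, opt)
        if "n_dose_levels" in kwargs:
            kwargs["n_dose_levels"] = int(kwargs["n_dose_levels"])
        records[cid] = CompoundRecord(
            compound_id=cid,
            name=str(row.name),
            moa_class=str(row.moa_class) if pd.notna(row.moa_class) else "unannotated",
            **kwargs,
        )
    return records


def _record_from_doses(compound_id: str, doses: np.ndarray) -> CompoundRecord:
    """Infer a minimal annotation record from an observed dose series."""
    nonzero = doses[doses > 0]
    factor = float(nonzero[-1] / nonzero[-2]) if nonzero.size >= 2 else 5.0
    return CompoundRecord(
        compound_id=compound_id,
        name=compound_id,
        moa_class="unannotated",
        top_dose=float(nonzero[-1]) if nonzero.size else 1e-5,
        dilution_factor=max(factor, 1.0 + 1e-9),
        n_dose_levels=int(doses.size),
    )


def read_screen_table(path, annotation_path=None) -> ScreenDataset:
    """Read a long-format screen CSV (plus optional compound annotations).

    One :class:`DoseMatrixBlock` is built per ``(block_id, assay)``. Doses are
    deduplicated and sorted ascending; every (doseA, doseB, replicate) cell
    must be present exactly once or a :class:`StructuralError` lists the
    missing wells. Compound ids absent from the annotation table are carried
    with ``moa_class = "unannotated"``.
    """
    table = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in LONG_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"screen table is missing column(s): {', '.join(missing)}")
    if len(table) and np.any(table["signal"].to_numpy(dtype=float) < 0):
        raise ValueError("screen table contains negative signal values")

    compounds = _read_annotations(annotation_path) if annotation_path is not None else {}

    blocks: list[DoseMatrixBlock] = []
    for (block_id, assay), grp in table.groupby(["block_id", "assay"], sort=True):
        a_ids = grp["drugA_id"].unique()
        b_ids = grp["drugB_id"].unique()
        if len(a_ids) != 1 or len(b_ids) != 1:
            raise StructuralError(
                f"block {block_id!r} mixes compound ids: {a_ids.tolist()} x {b_ids.tolist()}"
            )
        dosesA = np.sort(grp["doseA"].unique())
        dosesB = np.sort(grp["doseB"].unique())
        reps = np.sort(grp["replicate"].unique())
        idxA = {d: i for i, d in enumerate(dosesA)}
        idxB = {d: j for j, d in enumerate(dosesB)}
        idxR = {r: k for k, r in enumerate(reps)}
        grid = np.full((dosesA.size, dosesB.size, reps.size), np.nan)
        for row in grp.itertuples(index=False):
            grid[idxA[row.doseA], idxB[row.doseB], idxR[row.replicate]] = row.signal
        if np.any(np.isnan(grid)):
            holes = np.argwhere(np.isnan(grid))
            wells = ", ".join(
                f"(doseA={dosesA[i]:g}, doseB={dosesB[j]:g}, rep={reps[r]})"
                for i, j, r in holes[:10]
            )
            more = "" if holes.shape[0] <= 10 else f" and {holes.shape[0] - 10} more"
            raise StructuralError(
                f"block {block_id!r} has a ragged grid; missing wells: {wells}{more}"
            )
        cid_a, cid_b = str(a_ids[0]), str(b_ids[0])
        rec_a = compounds.get(cid_a) or _record_from_doses(cid_a, dosesA)
        rec_b = compounds.get(cid_b) or _record_from_doses(cid_b, dosesB)
        blocks.append(
            DoseMatrixBlock(
                block_id=str(block_id),
                drugA=rec_a,
                drugB=rec_b,
                dosesA=dosesA,
                dosesB=dosesB,
                signal=grid,
                assay=str(assay),
            )
        )
    return ScreenDataset(blocks=blocks, compounds=compounds)


def write_screen_table(dataset: ScreenDataset, path, header_comment: str | None = None) -> None:
    """Write a dataset as the canonical long-format CSV.

    Doses and signals are rendered with `repr` round-trip precision so that
    ``read_screen_table(write_screen_table(ds))`` is the identity on doses,
    signals and replicate labels.
    """
    rows = []
    for blk in dataset.blocks:
        nA, nB, nR = blk.signal.shape
        for i in range(nA):
            for j in range(nB):
                for r in range(nR):
                    rows.append(
                        (
                            blk.block_id,
                            blk.drugA.compound_id,
                            blk.dosesA[i],
                            blk.drugB.compound_id,
                            blk.dosesB[j],
                            r + 1,
                            blk.signal[i, j, r],
                            blk.assay,
                        )
                    )
    frame = pd.DataFrame(rows, columns=LONG_COLUMNS)
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False, float_format="%.17g")


def write_annotations(dataset: ScreenDataset, path, header_comment: str | None = None) -> None:
    """Write the compound annotation table next to a screen CSV."""
    rows = [
        (
            rec.compound_id,
            rec.name,
            rec.moa_class,
            rec.top_dose,
            rec.dilution_factor,
            rec.n_dose_levels,
        )
        for rec in dataset.compounds.values()
    ]
    frame = pd.DataFrame(
        rows,
        columns=ANNOTATION_COLUMNS + ["top_dose", "dilution_factor", "n_dose_levels"],
    )
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False, float_format="%.17g")


def normalize_block(block: DoseMatrixBlock) -> NormalizedMatrix:
    """Percent-of-control normalization against the vehicle/vehicle well.

    Every replicate well is divided by the replicate-mean vehicle signal, so
    the mean of ``v`` at (0, 0) is exactly 1. Viability above control is kept
    in ``v``; ``fa`` clamps to [0, 1] because it feeds log(fa/fu).
    """
    vehicle = block.signal[0, 0, :]
    vmean = float(np.mean(vehicle))
    if not np.isfinite(vmean) or vmean <= 0:
        raise NormalizationError(
            f"block {block.block_id!r}: vehicle mean {vmean:g} is not positive"
        )
    v_rep = block.signal / vmean
    v = v_rep.mean(axis=2)
    n_rep = block.n_replicates
    if n_rep > 1:
        sem = v_rep.std(axis=2, ddof=1) / np.sqrt(n_rep)
    else:
        sem = np.zeros_like(v)
    fa = np.clip(1.0 - v, 0.0, 1.0)
    return NormalizedMatrix(
        v=v,
        sem=sem,
        fa=fa,
        v_rep=v_rep,
        dosesA=block.dosesA.copy(),
        dosesB=block.dosesB.copy(),
        block=block,
    )


def normalize_activity_to_viability(
    activity: NormalizedMatrix,
    viability: NormalizedMatrix,
    floor: float = VIABILITY_FLOOR,
) -> np.ndarray:
    """Express a normalized activity readout per unit of surviving cells.

    Elementwise ``activity.v / viability.v``; wells whose viability falls
    below ``floor`` are masked (NaN) with a warning, since the ratio is
    dominated by noise once essentially no cells remain.
    """
    if activity.shape != viability.shape:
        raise StructuralError(
            f"activity grid {activity.shape} and viability grid {viability.shape} differ"
        )
    if not (
        np.array_equal(activity.dosesA, viability.dosesA)
        and np.array_equal(activity.dosesB, viability.dosesB)
    ):
        raise StructuralError("activity and viability blocks use different dose vectors")
    low = viability.v < floor
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = activity.v / viability.v
    if np.any(low):
        warnings.warn(
            f"{int(low.sum())} well(s) below viability floor {floor:g} masked in "
            "activity-to-viability ratio",
            stacklevel=2,
        )
        ratio = ratio.copy()
        ratio[low] = np.nan
    return ratio
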