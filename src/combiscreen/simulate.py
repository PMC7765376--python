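"""In-silico combination screens with known ground truth.

Single agents follow a 4-parameter logistic viability curve
``v(d) = emax + (1 - emax) / (1 + (d/ec50)^slope)``; for the interaction
surface three generative modes are supported:

* ``bliss_independent`` — the null: v = vA * vB.
* ``hsa_equal`` — the combination exactly matches the better single agent:
  v = min(vA, vB).
* ``potency_shift`` — Loewe-style synergy of strength psi >= 1: the interior
  surface satisfies the dose-equivalence relation
  ``psi * (dA/DxA(fa) + dB/DxB(fa)) = 1``, i.e. both agents' required doses
  are divided by psi at fixed ratio. psi = 1 is exact Loewe additivity (the
  sham/self-combination surface), and the combination index recovered by the
  analysis pipeline has the closed-form expected value 1/psi at every interior
  well below the efficacy cap.

The shift applies to interior (both-drugs-present) wells only; the matrix
edges always show the unshifted single-agent curves. Replicate noise is
multiplicative lognormal (keeps signals positive) with unit mean and the
requested coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .screen_io import CompoundRecord, DoseMatrixBlock, ScreenDataset

__all__ = [
    "HillParams",
    "MatrixDesign",
    "GroundTruth",
    "ANCHOR_PARAMS",
    "ANCHOR_ID",
    "single_agent_viability",
    "simulate_combination_block",
    "simulate_library",
    "SIX_BY_SIX",
    "TEN_BY_TEN",
]

INTERACTIONS = ("bliss_independent", "hsa_equal", "potency_shift")

#: Raw-signal scale for simulated wells (arbitrary luminescence units).
SIGNAL_SCALE = 1000.0


@dataclass(frozen=True)
class HillParams:
    """Ground-truth single-agent curve: ec50 (molar), slope, emax (viability floor)."""

    ec50: float
    slope: float
    emax: float = 0.0

    def __post_init__(self) -> None:
        if self.ec50 <= 0 or self.slope <= 0:
            raise ValueError("ec50 and slope must be positive")
        if not 0.0 <= self.emax < 1.0:
            raise ValueError("emax must lie in [0, 1)")


@dataclass(frozen=True)
class MatrixDesign:
    """Dose-matrix layout: level count, serial-dilution factor, top doses.

    ``n_levels`` counts the vehicle, so the screen's 6x6 blocks use 5 serial
    5-fold dilutions plus vehicle and the 10x10 confirmation blocks use 9
    serial steps (default factor sqrt(10), configurable) plus vehicle.
    """

    n_levels: int = 6
    dilution_factor: float = 5.0
    top_doseA: float = 1e-5
    top_doseB: float = 1e-5
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("a design needs >= 2 levels (vehicle + 1 dose)")
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must be > 1")
        if self.top_doseA <= 0 or self.top_doseB <= 0:
            raise ValueError("top doses must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def doses(self, axis: str) -> np.ndarray:
        top = self.top_doseA if axis == "A" else self.top_doseB
        n_nonzero = self.n_levels - 1
        steps = top / self.dilution_factor ** np.arange(n_nonzero - 1, -1, -1, dtype=float)
        return np.concatenate([[0.0], steps])


SIX_BY_SIX = MatrixDesign(n_levels=6, dilution_factor=5.0)
TEN_BY_TEN = MatrixDesign(n_levels=10, dilution_factor=float(np.sqrt(10.0)))

#: The screen's fixed anchor drug (the SMAC-mimetic role): weak but fittable
#: single-agent activity.
ANCHOR_ID = "ANCHOR"
ANCHOR_PARAMS = HillParams(ec50=1e-6, slope=1.5, emax=0.1)


def single_agent_viability(dose, p: HillParams) -> np.ndarray:
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.power(np.where(dose > 0, dose / p.ec50, 0.0), p.slope)
    return p.emax + (1.0 - p.emax) * (1.0 / (1.0 + ratio))


def _dx_pure(fa: float, p: HillParams) -> float:
    """Median-effect dose-for-effect on the pure (full-efficacy) scale."""
    return p.ec50 * (fa / (1.0 - fa)) ** (1.0 / p.slope)


def _loewe_fa(dA: float, dB: float, pA: HillParams, pB: HillParams, psi: float) -> float:
    """Solve psi*(dA/DxA(fa) + dB/DxB(fa)) = 1 for the combination's pure fa.

    Dx uses the pure median-effect inversion of each agent's (ec50, slope), so
    an analysis pipeline with exact single-agent fits recovers CI = 1/psi at
    every interior well.
    """
    if dA == 0 and dB == 0:
        return 0.0

    def g(fa: float) -> float:
        return psi * (dA / _dx_pure(fa, pA) + dB / _dx_pure(fa, pB)) - 1.0

    lo, hi = 1e-12, 1.0 - 1e-12
    if g(lo) <= 0.0:  # even a vanishing effect needs more dose than present
        return 0.0
    if g(hi) >= 0.0:  # doses beyond the grid's reach: full effect
        return 1.0
    return float(optimize.brentq(g, lo, hi, xtol=1e-15, rtol=1e-14))


def noise_free_surface(
    pA: HillParams,
    pB: HillParams,
    dosesA: np.ndarray,
    dosesB: np.ndarray,
    interaction: str,
    psi: float = 1.0,
) -> np.ndarray:
    """Deterministic viability surface over the full dose grid."""
    if interaction not in INTERACTIONS:
        raise ValueError(f"unknown interaction {interaction!r}; choose from {INTERACTIONS}")
    if psi < 1.0:
        raise ValueError(f"psi must be >= 1, got {psi}")
    vA = single_agent_viability(dosesA, pA)
    vB = single_agent_viability(dosesB, pB)
    if interaction == "bliss_independent":
        v = np.outer(vA, vB)
    elif interaction == "hsa_equal":
        v = np.minimum.outer(vA, vB)
    else:  # potency_shift
        # Interior wells follow the Loewe dose-equivalence surface on the pure
        # median-effect scale; the combination's efficacy floor deepens to the
        # Bliss-like product of the single-agent floors, so strong synergists
        # also beat the best single agent's maximal effect (beta < 1).
        e_pair = pA.emax * pB.emax
        v = np.empty((dosesA.size, dosesB.size))
        v[:, 0] = vA
        v[0, :] = vB
        for i in range(1, dosesA.size):
            for j in range(1, dosesB.size):
                fa_pure = _loewe_fa(dosesA[i], dosesB[j], pA, pB, psi)
                v[i, j] = e_pair + (1.0 - e_pair) * (1.0 - fa_pure)
    return v


def _lognormal_factors(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Unit-mean multiplicative noise with the requested CV."""
    if cv == 0.0:
        return np.ones(shape)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=shape)


def simulate_combination_block(
    truthA: HillParams,
    truthB: HillParams,
    interaction: str,
    design: MatrixDesign,
    seed: int | np.random.Generator,
    *,
    psi: float = 1.0,
    noise_cv: float = 0.0,
    block_id: str = "B0001",
    drugA: CompoundRecord | None = None,
    drugB: CompoundRecord | None = None,
    assay: str = "viability",
) -> DoseMatrixBlock:
    """Simulate one dose-matrix block of raw signal for a drug pair.

    The noise-free viability surface is scaled to raw signal (x1000) and each
    replicate well, vehicle included, receives independent multiplicative
    lognormal noise of the given CV. Fully reproducible given the seed.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dosesA = design.doses("A")
    dosesB = design.doses("B")
    v = noise_free_surface(truthA, truthB, dosesA, dosesB, interaction, psi)
    shape = (dosesA.size, dosesB.size, design.replicates)
    signal = SIGNAL_SCALE * v[:, :, None] * _lognormal_factors(rng, noise_cv, shape)
    if drugA is None:
        drugA = CompoundRecord(
            "drugA", "drugA", "unannotated",
            design.top_doseA, design.dilution_factor, design.n_levels,
        )
    if drugB is None:
        drugB = CompoundRecord(
            "drugB", "drugB", "unannotated",
            design.top_doseB, design.dilution_factor, design.n_levels,
        )
    return DoseMatrixBlock(
        block_id=block_id,
        drugA=drugA,
        drugB=drugB,
        dosesA=dosesA,
        dosesB=dosesB,
        signal=signal,
        assay=assay,
    )


@dataclass
class GroundTruth:
    """Simulator parameters and truth labels for a simulated library screen."""

    compounds: dict[str, HillParams]
    anchor: HillParams
    psi: dict[str, float]
    labels: dict[str, bool]
    interaction: dict[str, str]
    noise_cv: float
    replicates: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                cid,
                p.ec50,
                p.slope,
                p.emax,
                self.interaction[cid],
                self.psi[cid],
                self.labels[cid],
            )
            for cid, p in self.compounds.items()
        ]
        return pd.DataFrame(
            rows,
            columns=["compound_id", "ec50", "slope", "emax", "interaction", "psi", "synergist"],
        )


# MoA classes used to make class membership correlate with planted synergy,
# mirroring the drug families the screen's confirmed hits clustered into.
SYNERGY_CLASSES = (
    "taxane",
    "proteasome inhibitor",
    "HDAC inhibitor",
    "PLK1 inhibitor",
    "topoisomerase inhibitor",
)
NULL_CLASSES = (
    "kinase inhibitor",
    "antimetabolite",
    "alkylating agent",
    "nuclear receptor ligand",
    "antibiotic",
)


def simulate_library(
    n_compounds: int,
    fraction_synergists: float,
    design: MatrixDesign = SIX_BY_SIX,
    noise_cv: float = 0.1,
    seed: int = 0,
    *,
    anchor: HillParams = ANCHOR_PARAMS,
    psi_range: tuple[float, float] = (2.0, 8.0),
    assay: str = "viability",
) -> tuple[ScreenDataset, GroundTruth]:
    """Simulate a one-anchor library screen with planted synergists.

    Exactly ``round(n_compounds * fraction_synergists)`` compounds are labeled
    synergists and given a potency-shift interaction with psi drawn uniformly
    from ``psi_range``; the rest are Bliss-independent. Compound curves are
    sampled with log-uniform ec50 across the design's nonzero dose span, slope
    in [0.5, 3] and emax in [0, 0.4]. As in real matrix screens, each
    compound's dilution range is centered on its own single-agent activity:
    the compound's top dose is ``ec50 * dilution_factor**k`` (k = half the
    nonzero-level count), capped at the design top dose, so every ec50 falls
    inside its compound's dose range by construction. The anchor drug keeps
    the design's fixed range on the B axis. MoA class labels are drawn so
    synergists concentrate in a handful of classes.
    """
    if n_compounds < 1:
        raise ValueError("n_compounds must be >= 1")
    if not 0.0 <= fraction_synergists <= 1.0:
        raise ValueError("fraction_synergists must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_syn = int(round(n_compounds * fraction_synergists))
    syn_idx = set(rng.choice(n_compounds, size=n_syn, replace=False).tolist())

    dosesA = design.doses("A")
    lo, hi = dosesA[1], dosesA[-1]

    anchor_rec = CompoundRecord(
        ANCHOR_ID, "anchor", "SMAC mimetic",
        design.top_doseB, design.dilution_factor, design.n_levels,
    )
    compounds: dict[str, HillParams] = {}
    psi_map: dict[str, float] = {}
    labels: dict[str, bool] = {}
    interaction_map: dict[str, str] = {}
    records: dict[str, CompoundRecord] = {ANCHOR_ID: anchor_rec}
    blocks = []

    half_span = (design.n_levels - 2) // 2
    for idx in range(n_compounds):
        cid = f"C{idx + 1:04d}"
        params = HillParams(
            ec50=float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
            slope=float(rng.uniform(0.5, 3.0)),
            emax=float(rng.uniform(0.0, 0.4)),
        )
        is_syn = idx in syn_idx
        psi = float(rng.uniform(*psi_range)) if is_syn else 1.0
        interaction = "potency_shift" if is_syn else "bliss_independent"
        if is_syn:
            moa = str(rng.choice(SYNERGY_CLASSES))
        elif rng.uniform() < 0.15:
            moa = str(rng.choice(SYNERGY_CLASSES))
        else:
            moa = str(rng.choice(NULL_CLASSES))
        top_a = min(params.ec50 * design.dilution_factor**half_span, design.top_doseA)
        compound_design = MatrixDesign(
            n_levels=design.n_levels,
            dilution_factor=design.dilution_factor,
            top_doseA=top_a,
            top_doseB=design.top_doseB,
            replicates=design.replicates,
        )
        rec = CompoundRecord(
            cid, f"compound-{idx + 1}", moa,
            top_a, design.dilution_factor, design.n_levels,
        )
        compounds[cid] = params
        psi_map[cid] = psi
        labels[cid] = is_syn
        interaction_map[cid] = interaction
        records[cid] = rec
        blocks.append(
            simulate_combination_block(
                params,
                anchor,
                interaction,
                compound_design,
                rng,
                psi=psi,
                noise_cv=noise_cv,
                block_id=f"B{idx + 1:04d}",
                drugA=rec,
                drugB=anchor_rec,
                assay=assay,
            )
        )

    truth = GroundTruth(
        compounds=compounds,
        anchor=anchor,
        psi=psi_map,
        labels=labels,
        interaction=interaction_map,
        noise_cv=noise_cv,
        replicates=design.replicates,
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
    )
    return ScreenDataset(blocks=blocks, compounds=records), truth
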