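"""Per-well synergy surfaces and per-pair scalar scores.

Two reference-model surfaces are computed on the viability scale, where
negative values indicate synergy:

* Excess HSA: observed combination viability minus the better (lower
  viability) single agent at matched doses.
* Delta Bliss: observed viability minus the Bliss-independence expectation
  v_exp(i, j) = vA(i) * vB(j).

Two scalar co-filters drive triage: the Chou-Talalay combination index

    CI(i, j) = dA(i) / DxA(fa_obs) + dB(j) / DxB(fa_obs)

evaluated from the fitted single-agent median-effect curves at the observed
combination effect (two-term, mutually-exclusive form), and a maximal-efficacy
ratio beta = combination viability at top doses / best single-agent viability
at its top dose (beta < 1 means the combination beats the best single agent's
maximal effect).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dose_response import MedianEffectFit
from .screen_io import NormalizedMatrix

__all__ = [
    "SynergyReport",
    "excess_hsa",
    "delta_bliss",
    "combination_index",
    "beta_parameter",
    "summarize_pair",
    "CI_POLICIES",
    "CI_FA_BAND",
    "BETA_FLOOR",
]

#: fa band within which per-well CI values are considered for the scalar.
CI_FA_BAND = (0.25, 0.75)

#: Best-single-agent viability below this floor leaves beta undefined.
BETA_FLOOR = 0.01

CI_POLICIES = ("median_in_band", "min_in_band", "nearest_half_diag")


@dataclass
class SynergyReport:
    """All per-pair synergy surfaces, scalars and QC flags."""

    pair_id: str
    drugA_id: str
    drugB_id: str
    excess_hsa: np.ndarray
    delta_bliss: np.ndarray
    sum_neg_hsa: float
    sum_neg_bliss: float
    ci: float = np.nan
    ci_fa_at: float = np.nan
    ci_well: tuple[int, int] | None = None
    ci_policy: str = "median_in_band"
    beta: float = np.nan
    hit: bool = False
    flags: tuple[str, ...] = ()

    @property
    def ci_defined(self) -> bool:
        return np.isfinite(self.ci)

    @property
    def beta_defined(self) -> bool:
        return np.isfinite(self.beta)


def _interior(nm: NormalizedMatrix) -> np.ndarray:
    if nm.shape[0] < 2 or nm.shape[1] < 2:
        raise ValueError("a dose matrix needs at least one nonzero dose per axis")
    return nm.v[1:, 1:]


def excess_hsa(nm: NormalizedMatrix) -> tuple[np.ndarray, float]:
    """Excess-over-highest-single-agent surface (interior wells) and its
    negative-well sum."""
    combo = _interior(nm)
    best_single = np.minimum.outer(nm.v[1:, 0], nm.v[0, 1:])
    grid = combo - best_single
    return grid, float(np.minimum(grid, 0.0).sum())


def delta_bliss(nm: NormalizedMatrix) -> tuple[np.ndarray, float]:
    """Observed-minus-Bliss-expected surface (interior wells) and its
    negative-well sum.

    On the viability scale the Bliss expectation is multiplicative,
    v_exp = vA * vB, equivalent to fa_exp = faA + faB - faA*faB.
    """
    combo = _interior(nm)
    v_exp = np.outer(nm.v[1:, 0], nm.v[0, 1:])
    grid = combo - v_exp
    return grid, float(np.minimum(grid, 0.0).sum())


def ci_surface(
    nm: NormalizedMatrix, fitA: MedianEffectFit, fitB: MedianEffectFit
) -> np.ndarray:
    """Per-well combination index over interior wells (NaN where fa_obs is
    outside (0, 1) and Dx is undefined)."""
    dA = nm.dosesA[1:]
    dB = nm.dosesB[1:]
    fa = nm.fa[1:, 1:]
    grid = np.full(fa.shape, np.nan)
    inside = (fa > 0.0) & (fa < 1.0)
    if np.any(inside):
        ratio = fa[inside] / (1.0 - fa[inside])
        dx_a = fitA.Dm * ratio ** (1.0 / fitA.m)
        dx_b = fitB.Dm * ratio ** (1.0 / fitB.m)
        ii, jj = np.nonzero(inside)
        grid[ii, jj] = dA[ii] / dx_a + dB[jj] / dx_b
    return grid


def combination_index(
    nm: NormalizedMatrix,
    fitA: MedianEffectFit | None,
    fitB: MedianEffectFit | None,
    policy: str = "median_in_band",
    fa_band: tuple[float, float] = CI_FA_BAND,
) -> tuple[float, float, tuple[int, int] | None, list[str]]:
    """Collapse the per-well CI surface to one scalar.

    The evaluation band is ``fa_band`` with its upper edge additionally capped
    at the largest fa either single agent reached on its own axis: CI at
    effect levels beyond both singles' observed reach would rest entirely on
    extrapolating the median-effect line, which is unreliable for
    partial-efficacy drugs.

    Policies: ``median_in_band`` (default) reports the median CI over interior
    wells in the band — robust to per-well noise; ``min_in_band`` reports the
    band minimum (most synergistic well, noise-sensitive); ``nearest_half_diag``
    reports the CI at the diagonal well whose fa is nearest 0.5. When the band
    is empty because every well is *deeper* than the band (an over-effective
    combination), the band policies fall back to the well with fa nearest 0.5
    and flag "band-fallback"; a combination with no measurable effect anywhere
    is flagged "no-effect-band" with CI undefined.

    Returns ``(ci, fa_at, (i, j), flags)`` with well indices on the full
    matrix; an undefined CI is returned as NaN with an explanatory flag.
    """
    if policy not in CI_POLICIES:
        raise ValueError(f"unknown CI policy {policy!r}; choose from {CI_POLICIES}")
    if fitA is None or fitB is None:
        return np.nan, np.nan, None, ["unfittable-single"]
    grid = ci_surface(nm, fitA, fitB)
    fa = nm.fa[1:, 1:]
    fa_max_singles = min(nm.fa[1:, 0].max(), nm.fa[0, 1:].max())
    flags: list[str] = []

    if policy == "nearest_half_diag":
        n_diag = min(fa.shape)
        diag_fa = np.array([fa[k, k] for k in range(n_diag)])
        diag_ok = np.isfinite(np.array([grid[k, k] for k in range(n_diag)]))
        if not np.any(diag_ok):
            return np.nan, np.nan, None, ["no-effect-band"]
        dist = np.where(diag_ok, np.abs(diag_fa - 0.5), np.inf)
        k = int(np.argmin(dist))
        i = j = k
        return float(grid[i, j]), float(fa[i, j]), (i + 1, j + 1), flags

    lo, hi = fa_band
    hi = min(hi, float(fa_max_singles))
    mask = np.isfinite(grid) & (fa >= lo) & (fa <= hi)
    if np.any(mask):
        if policy == "median_in_band":
            target = float(np.median(grid[mask]))
            # report the band well whose CI is closest to the median
            dist = np.where(mask, np.abs(grid - target), np.inf)
        else:  # min_in_band
            dist = np.where(mask, grid, np.inf)
        i, j = np.unravel_index(np.argmin(dist), grid.shape)
        ci = target if policy == "median_in_band" else float(grid[i, j])
        return ci, float(fa[i, j]), (int(i) + 1, int(j) + 1), flags

    finite = np.isfinite(grid)
    if np.any(finite & (fa > hi)):
        # every scoreable well is deeper than the band: over-effective
        # combination; score the well nearest fa = 0.5 rather than discard
        dist = np.where(finite, np.abs(fa - 0.5), np.inf)
        i, j = np.unravel_index(np.argmin(dist), grid.shape)
        flags.append("band-fallback")
        return float(grid[i, j]), float(fa[i, j]), (int(i) + 1, int(j) + 1), flags
    return np.nan, np.nan, None, ["no-effect-band"]


def beta_parameter(
    nm: NormalizedMatrix, floor: float = BETA_FLOOR
) -> tuple[float, list[str]]:
    """Maximal-efficacy ratio at the top-dose corner of the matrix.

    beta = v(top, top) / min(v(top, 0), v(0, top)); values < 1 mean the
    combination is deeper than the best single agent at its top dose. When the
    best single agent already reduces viability below ``floor`` there is no
    headroom to measure and beta is undefined ("singles-saturating").
    """
    best_single = min(nm.v[-1, 0], nm.v[0, -1])
    if best_single < floor:
        return np.nan, ["singles-saturating"]
    return float(nm.v[-1, -1] / best_single), []


def summarize_pair(
    nm: NormalizedMatrix,
    fitA: MedianEffectFit | None,
    fitB: MedianEffectFit | None,
    *,
    ci_max: float = 0.5,
    beta_max: float = 1.0,
    ci_policy: str = "median_in_band",
    fa_band: tuple[float, float] = CI_FA_BAND,
    beta_floor: float = BETA_FLOOR,
) -> SynergyReport:
    """Assemble every surface and scalar for one pair and apply the hit rule.

    A hit requires a defined CI strictly below ``ci_max`` AND a defined beta
    strictly below ``beta_max``; undefined scalars never produce hits but are
    carried with flags rather than dropped.
    """
    block = nm.block
    drugA_id = block.drugA.compound_id if block is not None else "drugA"
    drugB_id = block.drugB.compound_id if block is not None else "drugB"
    hsa_grid, hsa_sum = excess_hsa(nm)
    bliss_grid, bliss_sum = delta_bliss(nm)
    ci, fa_at, well, ci_flags = combination_index(nm, fitA, fitB, ci_policy, fa_band)
    beta, beta_flags = beta_parameter(nm, beta_floor)
    hit = bool(
        np.isfinite(ci) and ci < ci_max and np.isfinite(beta) and beta < beta_max
    )
    return SynergyReport(
        pair_id=f"{drugA_id}|{drugB_id}",
        drugA_id=drugA_id,
        drugB_id=drugB_id,
        excess_hsa=hsa_grid,
        delta_bliss=bliss_grid,
        sum_neg_hsa=hsa_sum,
        sum_neg_bliss=bliss_sum,
        ci=ci,
        ci_fa_at=fa_at,
        ci_well=well,
        ci_policy=ci_policy,
        beta=beta,
        hit=hit,
        flags=tuple(ci_flags + beta_flags),
    )
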