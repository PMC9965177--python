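"""Across-batch evolutionary accounting.

Adaptive laboratory evolution progresses on the timescale of cell divisions
rather than wall-clock hours.  From the soft sensor's per-batch biomass
trajectories this module derives cell numbers (via an average single-cell
dry mass), generations per batch n_i = log2(N_i/N_{0,i}), and the cumulative
number of cell divisions

    CCD = Σ_i N_{0,i}·(2^{n_i} − 1) ,

which algebraically equals Σ_i (N_i − N_{0,i}) — the identity is used as an
internal cross-check.  A *stable phenotype* is declared once a window of
consecutive per-batch growth-rate estimates has a standard deviation below a
threshold and no further upward trend; the relative fitness of an evolved
population is its stable growth rate divided by that of a reference group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CellMassConstant",
    "AleRunResult",
    "cell_count",
    "generations",
    "ccd",
    "detect_stable",
    "relative_fitness",
]

#: Average dry mass of a single E. coli cell, grams.
ECOLI_CELL_MASS_G = 2.90e-13


@dataclass(frozen=True)
class CellMassConstant:
    """Average dry mass of a single cell in grams."""

    m_cell: float = ECOLI_CELL_MASS_G

    def __post_init__(self) -> None:
        if self.m_cell <= 0:
            raise ValueError("cell mass must be > 0")


@dataclass
class AleRunResult:
    """Across-batch summary of one evolution run.

    Sequences are aligned over the evaluated (kept) batches.  ``ccd_trajectory``
    holds the running CCD after each batch; ``stable_index`` is the 0-based
    index (within the kept sequence) of the batch at which the stability
    criterion is first met, or None; ``mu_stable`` averages μ̂ over that
    stable window.  ``relative_fitness`` is μ_stable divided by a reference
    group's stable growth rate, when a reference is configured.
    """

    batch_numbers: list[int]
    mu_sequence: np.ndarray
    durations: np.ndarray
    n0_sequence: np.ndarray
    n_end_sequence: np.ndarray
    generations_sequence: np.ndarray
    ccd_trajectory: np.ndarray
    stable_index: int | None
    mu_stable: float | None
    relative_fitness: float | None
    discarded_batches: list[int] = field(default_factory=list)

    @property
    def ccd_total(self) -> float:
        return float(self.ccd_trajectory[-1]) if len(self.ccd_trajectory) else 0.0


def cell_count(cx: float, v_reactor: float, m_cell: float = ECOLI_CELL_MASS_G) -> float:
    """Number of cells N = cx·Vr/m_cell from a biomass concentration."""
    if m_cell <= 0:
        raise ValueError("cell mass must be > 0")
    if v_reactor < 0:
        raise ValueError("reactor volume must be >= 0")
    return cx * v_reactor / m_cell


def generations(n0: float, n_end: float) -> float:
    """Generations n = log2(n_end/n0) over one batch.

    Negative values (population shrank) are allowed; callers flag them.
    """
    if n0 <= 0 or n_end <= 0:
        raise ValueError("cell counts must be > 0")
    return float(np.log2(n_end / n0))


def ccd(batches: Sequence[tuple[float, float]]) -> float:
    """Cumulative cell divisions over (n0, n_end) batch pairs.

    Σ n0_i·(2^{n_i} − 1) with n_i = log2(n_end_i/n0_i); algebraically equal
    to Σ (n_end_i − n0_i).
    """
    total = 0.0
    for n0, n_end in batches:
        total += n0 * (2.0 ** generations(n0, n_end) - 1.0)
    return total


def detect_stable(
    mu_sequence,
    window: int = 3,
    sd_threshold: float = 0.01,
    trend_threshold: float = 0.005,
    check_suffix: bool = True,
) -> int | None:
    """Earliest batch index at which the growth rate has stabilised.

    A trailing window of ``window`` consecutive μ̂ values ending at index i
    is *stable* when (a) its standard deviation is below ``sd_threshold``
    h⁻¹, (b) its least-squares slope does not exceed ``trend_threshold``
    h⁻¹ per batch, and (c) — *no further upward trend* — the mean of all
    later values does not exceed the window mean by more than
    ``sd_threshold`` (skipped with ``check_suffix=False``; the suffix test
    is what rejects quiet windows that merely interrupt an ongoing
    adaptation ramp).  Returns the earliest such i, or None.
    """
    mu = np.asarray(mu_sequence, dtype=float)
    if window < 2:
        raise ValueError("window must be >= 2")
    if len(mu) < window:
        return None
    x = np.arange(window, dtype=float)
    for i in range(window - 1, len(mu)):
        w = mu[i - window + 1 : i + 1]
        if np.std(w) >= sd_threshold:
            continue
        if np.polyfit(x, w, 1)[0] > trend_threshold:
            continue
        later = mu[i + 1 :]
        if check_suffix and later.size and later.mean() > w.mean() + sd_threshold:
            continue
        return i
    return None


def relative_fitness(mu_stable: float, mu_reference: float) -> float:
    """Stable growth rate relative to a reference group's stable rate."""
    if mu_stable <= 0 or mu_reference <= 0:
        raise ValueError("growth rates must be > 0")
    return mu_stable / mu_reference
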