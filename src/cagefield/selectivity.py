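"""Trajectory selectivity analytics and Boltzmann barrier-ratio estimates.

Distance populations from unbiased equilibrium sampling are summarised as
normalised histograms (under equilibrium sampling the empirical histogram
*is* the Boltzmann population; no reweighting is applied).  Contact
occupancy is the fraction of frames with a distance strictly below a
cutoff.  Enantiomeric ratios and spin-state preferences come from
two-state Boltzmann statistics on barrier differences; barriers are
consumed as inputs, never computed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import R_GAS_KCAL
from .errors import ParameterError, SelectionError
from .structure_io import ChargedFrame, Selection, Trajectory, resolve_selection

__all__ = [
    "PopulationHistogram", "SelectivityRatio",
    "distance_series", "population_hist", "most_populated_frame",
    "contact_occupancy", "enantiomer_ratio", "spin_state_preference",
]


@dataclass(frozen=True)
class PopulationHistogram:
    """Normalised distance population (density integrates to 1).

    ``mode`` is the center of the highest-density bin; ties break toward
    the smaller distance (the closer-approach bin is the chemically
    relevant one).
    """

    bin_edges: np.ndarray    # Å, len nbins + 1
    density: np.ndarray      # 1/Å, len nbins
    n_samples: int
    mode: float              # Å

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class SelectivityRatio:
    """Two-state Boltzmann product ratio from a barrier difference."""

    dd_barrier: float        # kcal/mol, |ΔΔE‡|
    temperature: float       # K
    ratio: float             # ≥ 1
    major: str               # "R", "S" or "tie"
    percent_major: float     # 100·ratio/(1+ratio)


def distance_series(
    traj: Trajectory,
    sel_a: Selection | str,
    sel_b: Selection | str,
) -> np.ndarray:
    """Per-frame Euclidean distance (Å) between two single-atom selections."""
    out = np.empty(len(traj))
    for i, frame in enumerate(traj):
        ia = resolve_selection(frame, sel_a)
        ib = resolve_selection(frame, sel_b)
        if len(ia) != 1 or len(ib) != 1:
            raise SelectionError(
                f"distance selections must resolve to exactly one atom each "
                f"(got {len(ia)} and {len(ib)} at frame {i})"
            )
        out[i] = np.linalg.norm(frame.positions[ia[0]] - frame.positions[ib[0]])
    return out


def population_hist(series: np.ndarray, bin_width: float = 0.1) -> PopulationHistogram:
    """Normalised histogram of a distance series with fixed bin width (Å)."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ParameterError("cannot histogram an empty series")
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    lo = math.floor(series.min() / bin_width) * bin_width
    hi = math.ceil(series.max() / bin_width) * bin_width
    nbins = max(1, int(round((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(nbins + 1)
    # guard against values landing exactly on the top edge
    if edges[-1] < series.max():
        edges = np.append(edges, edges[-1] + bin_width)
    density, edges = np.histogram(series, bins=edges, density=True)
    mode_bin = int(np.argmax(density))  # argmax takes the first (smallest-d) tie
    mode = 0.5 * (edges[mode_bin] + edges[mode_bin + 1])
    return PopulationHistogram(edges, density, series.size, float(mode))


def most_populated_frame(
    traj: Trajectory,
    series: np.ndarray,
    hist: PopulationHistogram,
) -> int:
    """Earliest frame whose distance falls in the histogram's mode bin.

    This is the representative snapshot: the frame realising the most
    populated distance bin; among candidates the earliest is returned.
    """
    series = np.asarray(series, dtype=float)
    if len(series) != len(traj):
        raise ParameterError(
            f"series length {len(series)} does not match trajectory length {len(traj)}"
        )
    mode_bin = int(np.argmax(hist.density))
    lo, hi = hist.bin_edges[mode_bin], hist.bin_edges[mode_bin + 1]
    # np.histogram uses half-open bins except the last, which is closed
    closed_top = mode_bin == len(hist.density) - 1
    in_bin = (series >= lo) & ((series <= hi) if closed_top else (series < hi))
    idx = np.flatnonzero(in_bin)
    if len(idx) == 0:
        raise ParameterError("no frame falls in the mode bin (series/hist mismatch)")
    return int(idx[0])


def contact_occupancy(series: np.ndarray, cutoff: float) -> float:
    """Fraction of samples strictly below ``cutoff`` (boundary exclusive).

    A sample at exactly the cutoff does not count as a contact.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ParameterError("cannot compute occupancy of an empty series")
    return float(np.mean(series < cutoff))


def enantiomer_ratio(
    barrier_r: float,
    barrier_s: float,
    temperature: float = 298.15,
) -> SelectivityRatio:
    """Product ratio from the pro-R vs pro-S barrier difference.

    ratio = exp(|ΔΔE‡| / (R T)) with R = 1.98720425×10⁻³ kcal mol⁻¹ K⁻¹;
    the major enantiomer is the one with the lower abstraction barrier.
    Equal barriers give ratio 1 and major ``"tie"``.
    """
    if temperature <= 0:
        raise ParameterError("temperature must be positive")
    dd = barrier_s - barrier_r
    ratio = math.exp(abs(dd) / (R_GAS_KCAL * temperature))
    if dd > 0:
        major = "R"
    elif dd < 0:
        major = "S"
    else:
        major = "tie"
    return SelectivityRatio(
        dd_barrier=abs(dd),
        temperature=temperature,
        ratio=ratio,
        major=major,
        percent_major=100.0 * ratio / (1.0 + ratio),
    )


def spin_state_preference(
    barrier_a: float,
    barrier_b: float,
    temperature: float = 298.15,
) -> float:
    """Boltzmann two-state fraction of flux through surface *a*.

    Returns 1/(1 + exp(−ΔΔE/(R T))) with ΔΔE = barrier_b − barrier_a, i.e.
    the population of the lower-barrier surface when *a* is lower; 0.5 when
    the barriers are equal, and fractions for swapped inputs sum to 1.
    """
    if temperature <= 0:
        raise ParameterError("temperature must be positive")
    dd = barrier_b - barrier_a
    return 1.0 / (1.0 + math.exp(-dd / (R_GAS_KCAL * temperature)))
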