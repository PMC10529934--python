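"""Group dipole moments and field–dipole stabilization energies.

A group's dipole from its partial charges is μ = k_D Σᵢ qᵢ (rᵢ − origin)
with k_D = 4.80320 D per e·Å.  For a neutral group μ is independent of the
origin; for a charged group it is origin-dependent, so the record carries
the origin used and a warning flag.

The interaction of the local field with a group dipole is scored per axis
as ΔE_a = k_E · F_a · μ_a, k_E = 4.8009 kcal mol⁻¹ D⁻¹ (V Å⁻¹)⁻¹, or from
full vectors as ΔE = k_E |F||μ| cos θ.  Signs follow the Gaussian
program's convention for field and dipole directions, under which a
negative ΔE is stabilizing; with that convention a reaction-axis field
anti-parallel to z acting on a dipole with positive μ_z gives a negative
(stabilizing) ΔE_z, and a misoriented lateral dipole a positive
(destabilizing) ΔE_y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import DEBYE_PER_E_ANGSTROM, FIELD_DIPOLE_K
from .errors import SelectionError
from .structure_io import AxisFrame, ChargedFrame, Selection, resolve_selection

__all__ = ["DipoleRecord", "StabilizationResult", "group_dipole",
           "stabilization_energy", "table1_report"]


@dataclass(frozen=True)
class DipoleRecord:
    """A group dipole in Debye with its axis-frame projections.

    ``charged`` flags a non-neutral group, whose dipole depends on the
    reported ``origin``.
    """

    group: str
    mu: np.ndarray            # lab frame, Debye
    mu_y: float
    mu_z: float
    origin: np.ndarray        # Å
    net_charge: float         # e

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.mu))

    @property
    def charged(self) -> bool:
        return abs(self.net_charge) > 1e-6


@dataclass(frozen=True)
class StabilizationResult:
    """Per-axis field–dipole energies (kcal mol⁻¹) and alignment angle.

    ``theta`` is the angle in degrees between the full field and dipole
    vectors, or ``None`` when either vanishes.
    """

    dE_z: float
    dE_y: float
    theta: float | None
    F_used: np.ndarray
    mu_used: np.ndarray

    @property
    def dE_total(self) -> float:
        """Full-vector form k_E |F||μ| cos θ (0 if either vector vanishes)."""
        return FIELD_DIPOLE_K * float(np.dot(self.F_used, self.mu_used))


def group_dipole(
    frame: ChargedFrame,
    sel: Selection | str,
    origin: str | np.ndarray = "geometric_center",
    axis: AxisFrame | None = None,
    label: str | None = None,
) -> DipoleRecord:
    """Dipole moment of a selected group from its point charges.

    ``origin`` is ``"geometric_center"`` (default), ``"charge_center"``
    (|q|-weighted centroid) or an explicit 3-vector in Å.  Projections
    ``mu_y``/``mu_z`` use ``axis`` when given, else lab y/z.
    """
    idx = resolve_selection(frame, sel)
    if len(idx) == 0:
        expr = sel.expression if isinstance(sel, Selection) else sel
        raise SelectionError(f"empty selection for dipole: {expr!r}")
    pos = frame.positions[idx]
    q = frame.charges[idx]
    if isinstance(origin, str):
        if origin == "geometric_center":
            org = pos.mean(axis=0)
        elif origin == "charge_center":
            w = np.abs(q)
            org = pos.mean(axis=0) if w.sum() < 1e-12 else (w @ pos) / w.sum()
        else:
            raise ValueError(f"unknown origin mode {origin!r}")
    else:
        org = np.asarray(origin, dtype=float)
    mu = DEBYE_PER_E_ANGSTROM * (q @ (pos - org))
    if axis is not None:
        _, mu_y, mu_z = axis.project(mu)
    else:
        mu_y, mu_z = float(mu[1]), float(mu[2])
    if label is None:
        label = sel.expression if isinstance(sel, Selection) else str(sel)
    return DipoleRecord(label, mu, mu_y, mu_z, org, float(q.sum()))


def stabilization_energy(
    F: np.ndarray | Sequence[float],
    mu: np.ndarray | Sequence[float],
) -> StabilizationResult:
    """Field–dipole interaction energies per axis, in kcal mol⁻¹.

    ``F`` is a field vector in V Å⁻¹ and ``mu`` a dipole vector in Debye,
    both expressed in the reaction-axis frame (x, y, z); scalar per-axis
    inputs can be passed as vectors with zeros elsewhere.  Negative
    energies are stabilizing.
    """
    F = np.asarray(F, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if F.shape != (3,) or mu.shape != (3,):
        raise ValueError("F and mu must be 3-vectors in the axis frame")
    if not (np.all(np.isfinite(F)) and np.all(np.isfinite(mu))):
        raise ValueError("F and mu must be finite")
    dE_z = FIELD_DIPOLE_K * F[2] * mu[2]
    dE_y = FIELD_DIPOLE_K * F[1] * mu[1]
    nF, nmu = np.linalg.norm(F), np.linalg.norm(mu)
    if nF < 1e-15 or nmu < 1e-15:
        theta = None
    else:
        c = float(np.clip(F @ mu / (nF * nmu), -1.0, 1.0))
        theta = math.degrees(math.acos(c))
    return StabilizationResult(float(dE_z), float(dE_y), theta, F, mu)


def stabilization_from_components(
    F_z: float = 0.0, mu_z: float = 0.0,
    F_y: float = 0.0, mu_y: float = 0.0,
) -> StabilizationResult:
    """Convenience wrapper taking the per-axis components a report prints."""
    return stabilization_energy([0.0, F_y, F_z], [0.0, mu_y, mu_z])


def table1_report(
    states: Sequence[tuple[str, "FieldRecord", Sequence[DipoleRecord]]],
) -> pd.DataFrame:
    """Per-state stabilization table: |μ|, F_z, μ_z, ΔE_z, F_y, μ_y, ΔE_y.

    Each state is (label, field record, dipole records); the dipole
    records of a state are summed vectorially (the composite group
    dipole).  All records of a state must share one axis frame; a
    mismatch raises ``ValueError``.  Rows follow input order.
    """
    from .lef import FieldRecord  # local import to avoid a cycle at import time

    rows = []
    for label, fld, dips in states:
        if not isinstance(fld, FieldRecord):
            raise TypeError(f"state {label!r}: expected a FieldRecord")
        if fld.axis is not None:
            for d in dips:
                # projection consistency: re-projecting the lab dipole must
                # reproduce the stored components
                _, my, mz = fld.axis.project(d.mu)
                if abs(my - d.mu_y) > 1e-8 or abs(mz - d.mu_z) > 1e-8:
                    raise ValueError(
                        f"state {label!r}: dipole {d.group!r} was projected in a "
                        "different axis frame than the field record"
                    )
        mu_vec = np.sum([d.mu for d in dips], axis=0)
        mu_y = float(sum(d.mu_y for d in dips))
        mu_z = float(sum(d.mu_z for d in dips))
        charged = any(d.charged for d in dips)
        res = stabilization_from_components(
            F_z=fld.F_z, mu_z=mu_z, F_y=fld.F_y, mu_y=mu_y
        )
        rows.append({
            "state": label,
            "mu_total_D": float(np.linalg.norm(mu_vec)),
            "F_z_VA": fld.F_z,
            "mu_z_D": mu_z,
            "dE_z_kcal": res.dE_z,
            "F_y_VA": fld.F_y,
            "mu_y_D": mu_y,
            "dE_y_kcal": res.dE_y,
            "net_charge_warning": charged,
        })
    return pd.DataFrame(rows)
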