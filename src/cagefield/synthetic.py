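"""Synthetic cage systems, distance/contact series and steered-work traces.

Everything downstream (field series, dipoles, populations, occupancy, PMF
stitching) is exercised on data generated here with *known* ground truth:

* :func:`gen_cage_system` builds an abstract caged iron-oxo model — a
  central Fe–O axis, a symmetric ring of charged peripheral sites, a
  neutral shell of polar (dipolar) cage pairs, a thin shell of neutral
  polar solvent pairs, a small neutral substrate ring carrying the pro-R
  and pro-S hydrogens, and far-field counter-ions that neutralise the
  system.  Frame 0 is jitter-free; subsequent frames add isotropic,
  frame-uncorrelated Gaussian displacements.  Geometry and charges only:
  no force field, no dynamics, no chemically valid topology.
* :func:`gen_distance_series` draws pro-R/pro-S oxygen–hydrogen distances
  from two-component Gaussian mixtures with mirrored weights, emulating a
  near/far two-population structure.
* :func:`gen_contact_series` draws a stacking-contact distance series
  with a prescribed below-cutoff occupancy.
* :func:`gen_work_traces` draws staged steered-work curves whose Gaussian
  per-stage increments carry a βσ²/2 dissipation offset, so Jarzynski
  averaging recovers the input free-energy profile exactly in expectation.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.stats import truncnorm

from .constants import COULOMB_K, DEBYE_PER_E_ANGSTROM, R_GAS_KCAL
from .errors import GeometryError, ParameterError
from .pmf import WorkTraces
from .structure_io import Atom, ChargedFrame, Trajectory

__all__ = [
    "CageSpec", "GroundTruth", "PmfSpec",
    "gen_cage_system", "gen_distance_series", "gen_contact_series",
    "gen_work_traces",
]

_MIN_PLACEMENT_DIST = 0.8  # Å, between independently placed sites


@dataclass(frozen=True)
class PmfSpec:
    """Analytic free-energy profile used as steered-work ground truth.

    ``kind`` is ``"linear"`` (params: slope kcal/mol/Å, referenced to the
    first breakpoint) or ``"harmonic"`` (params: k kcal/mol/Å², x0 Å).
    """

    kind: str
    params: dict

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        if self.kind == "linear":
            return self.params["slope"] * (x - self.params.get("x0", 0.0))
        if self.kind == "harmonic":
            return 0.5 * self.params["k"] * (x - self.params["x0"]) ** 2
        raise ParameterError(f"unknown PMF kind {self.kind!r}")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "params": dict(self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "PmfSpec":
        return cls(d["kind"], dict(d["params"]))


@dataclass
class CageSpec:
    """Parameters of the synthetic caged-oxidant system.

    Geometry defaults sketch a host–guest complex at roughly the scale of
    a porphyrin-in-cage model: an Fe=O bond of 1.65 Å at the center, four
    +1 e peripheral sites (the cationic periphery of the oxidant) on an
    8 Å ring, two dozen neutral polar pairs on a 12 Å cage shell, a thin
    14–16 Å solvent shell, and counter-ions far outside.  Per-frame
    positional jitter of 0.1 Å produces fluctuating field time series
    without any dynamics.
    """

    n_periphery: int = 4
    periphery_charge: float = 1.0       # e per site
    periphery_radius: float = 8.0       # Å
    n_cage_dipoles: int = 24
    shell_radius: float = 12.0          # Å
    n_solvent: int = 30                 # solvent sites (each a ± pair)
    solvent_shell: tuple[float, float] = (14.0, 16.0)  # Å
    feo_length: float = 1.65            # Å
    positional_sigma: float = 0.1       # Å
    n_frames: int = 50
    seed: int = 0
    frame_stride: float = 10.0          # ps between frames
    # two-population pro-R / pro-S distance structure (Å)
    p_near: float = 0.7
    mu_near: float = 2.6
    mu_far: float = 3.4
    sigma_dist: float = 0.2
    # π-stacking contact structure (Å)
    occupancy: float = 0.88
    contact_in: float = 3.8
    contact_out: float = 6.5
    contact_cutoff: float = 5.0

    def __post_init__(self) -> None:
        r_min, r_max = self.solvent_shell
        if not (0 < r_min < r_max):
            raise ParameterError("solvent_shell radii must satisfy 0 < r_min < r_max")
        if self.n_frames < 1:
            raise ParameterError("n_frames must be at least 1")
        if self.periphery_radius <= 0 or self.shell_radius <= 0:
            raise ParameterError("radii must be positive")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ParameterError("occupancy must lie in [0, 1]")
        if not self.mu_near < self.mu_far:
            raise ParameterError("mu_near must be below mu_far")


@dataclass
class GroundTruth:
    """Analytic/statistical targets for a generated system.

    Every field is recomputable from the jitter-free base geometry and
    the spec parameters alone.
    """

    expected_field_at_origin: np.ndarray          # V/Å, jitter-free, non-Fe/O sources
    expected_group_dipoles: dict[str, np.ndarray]  # group -> Debye vector (lab frame)
    occupancy: float
    pmf_curve: PmfSpec | None = None

    def to_dict(self) -> dict:
        return {
            "expected_field_at_origin": list(map(float, self.expected_field_at_origin)),
            "expected_group_dipoles": {
                g: list(map(float, v)) for g, v in self.expected_group_dipoles.items()
            },
            "occupancy": self.occupancy,
            "pmf_curve": None if self.pmf_curve is None else self.pmf_curve.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            np.array(d["expected_field_at_origin"]),
            {g: np.array(v) for g, v in d["expected_group_dipoles"].items()},
            d["occupancy"],
            None if d.get("pmf_curve") is None else PmfSpec.from_dict(d["pmf_curve"]),
        )


# ---------------------------------------------------------------------------
# Series generators
# ---------------------------------------------------------------------------

def gen_distance_series(
    n: int,
    p_near: float,
    mu_near: float,
    mu_far: float,
    sigma: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Pro-R and pro-S distance series from mirrored two-Gaussian mixtures.

    The pro-R series puts weight ``p_near`` on the near component
    N(mu_near, σ²) and the rest on N(mu_far, σ²); the pro-S series swaps
    the weights.  Sample means converge to the mixture means as n grows.
    """
    if not 0.0 <= p_near <= 1.0:
        raise ParameterError("p_near must lie in [0, 1]")
    if not mu_near < mu_far:
        raise ParameterError("mu_near must be below mu_far")
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    rng = np.random.default_rng(seed)

    def mixture(p_on_near: float) -> np.ndarray:
        comp = rng.random(n) < p_on_near
        means = np.where(comp, mu_near, mu_far)
        return rng.normal(means, sigma)

    return mixture(p_near), mixture(1.0 - p_near)


def gen_contact_series(
    n: int,
    occupancy: float,
    d_in: float,
    d_out: float,
    cutoff: float,
    seed: int,
) -> np.ndarray:
    """Stacking-distance series whose below-cutoff fraction converges to ``occupancy``.

    Contact samples come from a normal centered at ``d_in`` truncated to
    (0, cutoff); non-contact samples from one centered at ``d_out``
    truncated to (cutoff, ∞).  The truncation widths are a quarter of the
    respective distance to the cutoff, so the two populations are well
    separated.
    """
    if not 0.0 <= occupancy <= 1.0:
        raise ParameterError("occupancy must lie in [0, 1]")
    if not d_in < cutoff < d_out:
        raise ParameterError("need d_in < cutoff < d_out")
    rng = np.random.default_rng(seed)
    is_contact = rng.random(n) < occupancy
    out = np.empty(n)
    s_in = 0.25 * (cutoff - d_in)
    s_out = 0.25 * (d_out - cutoff)
    n_in = int(is_contact.sum())
    if n_in:
        a, b = (0.0 - d_in) / s_in, (cutoff - d_in) / s_in
        out[is_contact] = truncnorm.rvs(a, b, loc=d_in, scale=s_in,
                                        size=n_in, random_state=rng)
    if n - n_in:
        a, b = (cutoff - d_out) / s_out, np.inf
        out[~is_contact] = truncnorm.rvs(a, b, loc=d_out, scale=s_out,
                                         size=n - n_in, random_state=rng)
    return out


def gen_work_traces(
    pmf: PmfSpec | Callable[[np.ndarray], np.ndarray],
    n_traj: int,
    sigma_w: float,
    stages: np.ndarray,
    temperature: float,
    seed: int,
) -> WorkTraces:
    """Staged steered-work curves with Jarzynski-unbiased Gaussian noise.

    Per stage, each trajectory's work increment is Gaussian with mean
    ΔPMF(stage) + βσ²/2 and variance σ².  The βσ²/2 dissipation offset
    makes the Jarzynski average recover the input PMF exactly in
    expectation (Gaussian-work closed form ΔG = ⟨W⟩ − βσ²/2), so the
    generated ensemble is an exact recovery target, not an approximate
    one.  With σ = 0 every trace equals the PMF curve itself.
    """
    stages = np.asarray(stages, dtype=float)
    if np.any(np.diff(stages) <= 0):
        raise ParameterError("stage breakpoints must be strictly increasing")
    if sigma_w < 0:
        raise ParameterError("sigma_w must be non-negative")
    rng = np.random.default_rng(seed)
    beta = 1.0 / (R_GAS_KCAL * temperature)
    pmf_vals = np.asarray(pmf(stages), dtype=float)
    d_pmf = np.diff(pmf_vals)
    n_stages = len(stages) - 1
    increments = (
        d_pmf + 0.5 * beta * sigma_w**2
        + sigma_w * rng.standard_normal((n_traj, n_stages))
    )
    traces = np.concatenate(
        [np.zeros((n_traj, 1)), np.cumsum(increments, axis=1)], axis=1
    )
    return WorkTraces(stages, stages.copy(), traces, temperature)


# ---------------------------------------------------------------------------
# Cage-system generator
# ---------------------------------------------------------------------------

def _uniform_shell_point(rng: np.random.Generator,
                         r_min: float, r_max: float) -> np.ndarray:
    u = rng.standard_normal(3)
    u /= np.linalg.norm(u)
    r = (rng.uniform(r_min**3, r_max**3)) ** (1.0 / 3.0)
    return r * u


def _place_with_retries(existing: list[np.ndarray],
                        propose: Callable[[], np.ndarray]) -> np.ndarray:
    for _ in range(100):
        p = propose()
        if all(np.linalg.norm(p - q) >= _MIN_PLACEMENT_DIST for q in existing):
            return p
    raise GeometryError("could not place a site without overlap after 100 attempts")


def gen_cage_system(spec: CageSpec) -> tuple[list[Atom], Trajectory, GroundTruth]:
    """Generate a caged iron-oxo point-charge system with known ground truth.

    Layout (all groups label-selectable downstream):

    * ``FE``/``O1``: the Fe=O axis along z, midpoint at the origin, with
      small ± partial charges (excluded from default field sources).
    * ``HM1``: ``n_periphery`` charged sites equally spaced on a ring of
      radius ``periphery_radius`` in the z = 0 plane — the symmetric
      placement makes their field vanish at the origin analytically.
      ``P1`` additionally anchors the stacking-contact probe ``ST1``.
    * ``CAGE``: neutral ±0.2 e polar pairs on the ``shell_radius`` shell.
    * ``SOLV``: neutral ±0.1 e polar pairs in the solvent shell.
    * ``TLN``: a small neutral 6-ring at (0, 4, 0) Å with alternating
      ±0.05 e charges (the lateral reference fixing the y-axis) plus the
      chargeless pro-R/pro-S hydrogens ``HR``/``HS`` whose distances to
      ``O1`` follow the two-population mixture of the spec.
    * ``CION``: counter-ions on a far ring that neutralise the periphery.

    Frame 0 is jitter-free and reproduces ``GroundTruth``; later frames
    add N(0, positional_sigma²) displacements per atom per frame.
    """
    rng = np.random.default_rng(spec.seed)
    atoms: list[Atom] = []
    placed: list[np.ndarray] = []

    def add(name: str, group: str, pos: np.ndarray, charge: float,
            radius: float = 1.5) -> None:
        atoms.append(Atom(len(atoms), name, group, np.asarray(pos, float),
                          charge, radius))

    # Fe=O axis, midpoint at the origin
    half = 0.5 * spec.feo_length
    add("FE", "FE", [0.0, 0.0, -half], 0.25)
    add("O1", "O", [0.0, 0.0, +half], -0.25)

    # charged periphery, symmetric ring in the z = 0 plane
    for k in range(spec.n_periphery):
        ang = 2.0 * math.pi * k / spec.n_periphery
        pos = spec.periphery_radius * np.array([math.cos(ang), math.sin(ang), 0.0])
        add(f"P{k + 1}", "HM1", pos, spec.periphery_charge)
        placed.append(pos)

    # neutral polar cage pairs on the shell
    for k in range(spec.n_cage_dipoles):
        center = _place_with_retries(
            placed, lambda: _uniform_shell_point(
                rng, spec.shell_radius - 0.5, spec.shell_radius + 0.5)
        )
        placed.append(center)
        orient = rng.standard_normal(3)
        orient /= np.linalg.norm(orient)
        add(f"CD{k + 1}A", "CAGE", center + 0.5 * orient, +0.2)
        add(f"CD{k + 1}B", "CAGE", center - 0.5 * orient, -0.2)

    # thin neutral polar solvent shell
    r_min, r_max = spec.solvent_shell
    for k in range(spec.n_solvent):
        center = _place_with_retries(
            placed, lambda: _uniform_shell_point(rng, r_min, r_max))
        placed.append(center)
        orient = rng.standard_normal(3)
        orient /= np.linalg.norm(orient)
        add(f"SV{k + 1}A", "SOLV", center + 0.48 * orient, +0.1)
        add(f"SV{k + 1}B", "SOLV", center - 0.48 * orient, -0.1)

    # neutral substrate ring: the lateral (y-axis) reference
    sub_center = np.array([0.0, 4.0, 0.0])
    for k in range(6):
        ang = 2.0 * math.pi * k / 6
        pos = sub_center + 1.4 * np.array([math.cos(ang), 0.0, math.sin(ang)])
        add(f"C{k + 1}", "TLN", pos, 0.05 if k % 2 == 0 else -0.05)

    # pro-R / pro-S hydrogens: positions are set per frame from the
    # generated distance series; base positions use the frame-0 draws
    u_r = np.array([0.0, 0.6, -0.8])
    u_s = np.array([0.0, -0.6, -0.8])
    d_r, d_s = gen_distance_series(
        spec.n_frames, spec.p_near, spec.mu_near, spec.mu_far,
        spec.sigma_dist, seed=int(rng.integers(2**31)),
    )
    o_base = np.array([0.0, 0.0, +half])
    add("HR", "TLN", o_base + d_r[0] * u_r, 0.0, radius=1.1)
    add("HS", "TLN", o_base + d_s[0] * u_s, 0.0, radius=1.1)

    # stacking-contact probe: rides above periphery site P1
    d_c = gen_contact_series(
        spec.n_frames, spec.occupancy, spec.contact_in, spec.contact_out,
        spec.contact_cutoff, seed=int(rng.integers(2**31)),
    )
    p1_base = atoms[2].position  # first periphery site
    add("ST1", "CAGE", p1_base + np.array([0.0, 0.0, d_c[0]]), 0.0)

    # far counter-ions neutralising the periphery, symmetric ring
    r_cion = 4.0 * r_max
    for k in range(spec.n_periphery):
        ang = 2.0 * math.pi * (k + 0.5) / spec.n_periphery
        pos = r_cion * np.array([math.cos(ang), math.sin(ang), 0.0])
        add(f"CL{k + 1}", "CION", pos, -spec.periphery_charge)

    base = np.array([a.position for a in atoms])
    charges = np.array([a.charge for a in atoms])
    names = [a.name for a in atoms]
    groups = [a.group for a in atoms]
    radii = np.array([a.radius for a in atoms])
    i_o = names.index("O1")
    i_hr, i_hs = names.index("HR"), names.index("HS")
    i_p1, i_st = names.index("P1"), names.index("ST1")

    frames = []
    for t in range(spec.n_frames):
        if t == 0:
            pos = base.copy()
        else:
            pos = base + rng.normal(0.0, spec.positional_sigma, base.shape)
        # re-pin the scripted atoms so their distances match the series
        pos[i_hr] = pos[i_o] + d_r[t] * u_r
        pos[i_hs] = pos[i_o] + d_s[t] * u_s
        pos[i_st] = pos[i_p1] + np.array([0.0, 0.0, d_c[t]])
        frames.append(ChargedFrame(pos, charges, names, groups,
                                   time=t * spec.frame_stride, radii=radii))
    traj = Trajectory(frames, stride=spec.frame_stride)

    # ground truth: inline Coulomb sum over the jitter-free base geometry,
    # sources = everything except the probed Fe/O pair
    src = np.array([g not in ("FE", "O") for g in groups])
    disp = -base[src]                              # probe at the origin
    r2 = np.einsum("ij,ij->i", disp, disp)
    ef = COULOMB_K * (charges[src] * r2**-1.5) @ disp

    dipoles: dict[str, np.ndarray] = {}
    for g in ("HM1", "CAGE", "SOLV", "TLN"):
        mask = np.array([gg == g for gg in groups])
        if not mask.any():
            continue
        center = base[mask].mean(axis=0)
        dipoles[g] = DEBYE_PER_E_ANGSTROM * (charges[mask] @ (base[mask] - center))

    truth = GroundTruth(ef, dipoles, spec.occupancy)
    return atoms, traj, truth
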