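"""Point-charge topologies, trajectories, selections and reaction-axis frames.

This module owns the on-disk dialects (whitespace-delimited PQR,
multi-frame XYZ with optional ``time=<ps>`` comment tags, single-structure
PDB) and the in-memory containers the rest of the package computes on.

Conventions
-----------
* Positions in Å, charges in e; right-handed Cartesian axes.
* Atom indices are 0-based internally; file serial numbers are 1-based.
* The reaction axis frame puts z along Fe→O, y along a user-chosen lateral
  reference (projected orthogonal to z) and x = y × z, so the frame is
  right-handed.  The frame origin defaults to the Fe–O midpoint.
* Distance-shell selections use a closed boundary: ``within R`` includes
  atoms at exactly R.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import FormatError, GeometryError, SelectionError, StructureError

__all__ = [
    "Atom",
    "ChargedFrame",
    "Trajectory",
    "AxisFrame",
    "Selection",
    "read_pqr",
    "write_pqr",
    "read_pdb",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "resolve_selection",
    "build_axis_frame",
]


@dataclass(frozen=True)
class Atom:
    """One labeled point charge.

    Attributes
    ----------
    index : int
        0-based position within its frame.
    name : str
        Atom name (e.g. ``"FE"``, ``"O1"``, ``"C1"``).
    group : str
        Group label, taken from the residue-name column on file input
        (e.g. ``"HM1"``, ``"CAGE"``, ``"SOLV"``, ``"TLN"``).
    position : numpy.ndarray, shape (3,)
        Cartesian position in Å.
    charge : float
        Partial charge in e.
    radius : float
        Atomic radius in Å (PQR column; carried through, not used in
        field computation).
    """

    index: int
    name: str
    group: str
    position: np.ndarray
    charge: float
    radius: float = 0.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.index}: position must be a finite 3-vector")
        if not np.isfinite(self.charge):
            raise ValueError(f"atom {self.index}: charge must be finite")
        object.__setattr__(self, "position", pos)


class ChargedFrame:
    """One time point of a labeled point-charge ensemble.

    Stores positions/charges as numpy arrays for vectorised Coulomb sums;
    :meth:`atoms` materialises :class:`Atom` records on demand.
    """

    def __init__(
        self,
        positions: np.ndarray,
        charges: np.ndarray,
        names: Sequence[str],
        groups: Sequence[str],
        time: float = 0.0,
        radii: np.ndarray | None = None,
    ) -> None:
        self.positions = np.atleast_2d(np.asarray(positions, dtype=float))
        self.charges = np.asarray(charges, dtype=float)
        self.names = list(names)
        self.groups = list(groups)
        self.time = float(time)
        n = len(self.positions)
        self.radii = (
            np.zeros(n) if radii is None else np.asarray(radii, dtype=float)
        )
        if not (len(self.charges) == len(self.names) == len(self.groups) == n):
            raise StructureError("positions, charges, names and groups must agree in length")

    @classmethod
    def from_atoms(cls, atoms: Sequence[Atom], time: float = 0.0) -> "ChargedFrame":
        if not atoms:
            return cls(np.zeros((0, 3)), np.zeros(0), [], [], time)
        return cls(
            np.array([a.position for a in atoms]),
            np.array([a.charge for a in atoms]),
            [a.name for a in atoms],
            [a.group for a in atoms],
            time,
            np.array([a.radius for a in atoms]),
        )

    def atoms(self) -> list[Atom]:
        return [
            Atom(i, self.names[i], self.groups[i], self.positions[i],
                 float(self.charges[i]), float(self.radii[i]))
            for i in range(len(self))
        ]

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def label_set(self) -> set[str]:
        return set(self.groups)


class Trajectory:
    """Ordered sequence of :class:`ChargedFrame` with strictly increasing times."""

    def __init__(self, frames: Sequence[ChargedFrame], stride: float = 1.0) -> None:
        self.frames = list(frames)
        self.stride = float(stride)
        counts = {len(f) for f in self.frames}
        if len(counts) > 1:
            raise StructureError(f"atom count varies across frames: {sorted(counts)}")
        times = [f.time for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise StructureError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> ChargedFrame:
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


@dataclass(frozen=True)
class AxisFrame:
    """Reaction-coordinate frame: origin + right-handed orthonormal triad.

    ``z_hat`` points Fe→O (the reaction axis); ``y_hat`` is the lateral
    selectivity axis; ``x_hat = y_hat × z_hat`` completes the frame.
    """

    origin: np.ndarray
    z_hat: np.ndarray
    y_hat: np.ndarray
    x_hat: np.ndarray

    def __post_init__(self) -> None:
        for nm in ("origin", "z_hat", "y_hat", "x_hat"):
            object.__setattr__(self, nm, np.asarray(getattr(self, nm), dtype=float))
        for nm in ("z_hat", "y_hat", "x_hat"):
            if abs(np.linalg.norm(getattr(self, nm)) - 1.0) > 1e-10:
                raise GeometryError(f"{nm} is not a unit vector")
        for a, b in (("x_hat", "y_hat"), ("x_hat", "z_hat"), ("y_hat", "z_hat")):
            if abs(np.dot(getattr(self, a), getattr(self, b))) > 1e-10:
                raise GeometryError(f"{a} and {b} are not orthogonal")
        if abs(np.dot(self.x_hat, np.cross(self.y_hat, self.z_hat)) - 1.0) > 1e-10:
            raise GeometryError("axis frame is not right-handed")

    def project(self, vec: np.ndarray) -> tuple[float, float, float]:
        """Signed (x, y, z) components of a lab-frame vector in this frame."""
        v = np.asarray(vec, dtype=float)
        return (float(v @ self.x_hat), float(v @ self.y_hat), float(v @ self.z_hat))


# ---------------------------------------------------------------------------
# PQR / PDB / XYZ dialects
# ---------------------------------------------------------------------------

def read_pqr(path: str | Path) -> list[Atom]:
    """Read a whitespace-delimited PQR file into a list of :class:`Atom`.

    Expected record layout (free-format PQR dialect)::

        ATOM  serial  name  resname  resid  x  y  z  charge  radius

    The group label is taken from the residue name.  Charges are in e,
    positions and radii in Å.  Raises :class:`FormatError` naming the
    offending line for malformed or truncated records.
    """
    atoms: list[Atom] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            fields = line.split()
            if len(fields) < 10:
                raise FormatError(
                    f"{path}:{lineno}: PQR record has {len(fields)} fields, "
                    "expected 10 (serial name resname resid x y z charge radius)"
                )
            try:
                x, y, z = (float(fields[5]), float(fields[6]), float(fields[7]))
                charge, radius = float(fields[8]), float(fields[9])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field ({exc})") from exc
            atoms.append(
                Atom(len(atoms), fields[2], fields[3], np.array([x, y, z]), charge, radius)
            )
    return atoms


def write_pqr(atoms: Iterable[Atom], path: str | Path) -> None:
    """Write atoms in the same whitespace-delimited PQR dialect read_pqr reads.

    Positions are written to 1e-3 Å, charges to 1e-4 e.
    """
    with open(path, "w") as fh:
        for i, a in enumerate(atoms):
            fh.write(
                f"ATOM {i + 1:6d} {a.name:<4s} {a.group:<4s} {1:4d} "
                f"{a.position[0]:10.3f} {a.position[1]:10.3f} {a.position[2]:10.3f} "
                f"{a.charge:9.4f} {a.radius:7.3f}\n"
            )


def read_pdb(path: str | Path, charge_map: Sequence[Atom] | None = None) -> ChargedFrame:
    """Read a single-structure PDB; charges come from ``charge_map`` if given.

    PDB carries no charges, so without a charge map every charge is 0.
    """
    names, groups, rows = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            try:
                names.append(line[12:16].strip())
                groups.append(line[17:21].strip())
                rows.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed PDB coordinates") from exc
    positions = np.array(rows) if rows else np.zeros((0, 3))
    if charge_map is not None:
        if len(charge_map) != len(rows):
            raise StructureError(
                f"charge map has {len(charge_map)} atoms, PDB has {len(rows)}"
            )
        charges = np.array([a.charge for a in charge_map])
        names = [a.name for a in charge_map]
        groups = [a.group for a in charge_map]
    else:
        charges = np.zeros(len(rows))
    return ChargedFrame(positions, charges, names, groups)


_TIME_RE = re.compile(r"time\s*=\s*([-+0-9.eE]+)")


def read_xyz_trajectory(
    path: str | Path,
    charge_map: Sequence[Atom],
    stride: float = 1.0,
) -> Trajectory:
    """Read a multi-frame XYZ file, joining charges/groups from ``charge_map``.

    The join is positional: record *i* of every frame takes the charge and
    group of ``charge_map[i]``.  Frame times are parsed from a
    ``time=<ps>`` tag on the comment line when present; otherwise frames
    are stamped 0, stride, 2·stride, … ps.

    Raises :class:`StructureError` on any atom-count mismatch, either
    between frames or against the charge map.
    """
    charges = np.array([a.charge for a in charge_map])
    names = [a.name for a in charge_map]
    groups = [a.group for a in charge_map]
    radii = np.array([a.radius for a in charge_map])
    frames: list[ChargedFrame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    fidx = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(f"{path}: expected atom count at line {i + 1}") from exc
        if n != len(charge_map):
            raise StructureError(
                f"{path}: frame {fidx} has {n} atoms, charge map has {len(charge_map)}"
            )
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        m = _TIME_RE.search(comment)
        time = float(m.group(1)) if m else fidx * stride
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n:
            raise StructureError(f"{path}: frame {fidx} truncated")
        rows = []
        for j, rec in enumerate(body):
            parts = rec.split()
            if len(parts) < 4:
                raise FormatError(f"{path}: malformed XYZ record at line {i + 3 + j}")
            rows.append([float(parts[1]), float(parts[2]), float(parts[3])])
        frames.append(ChargedFrame(np.array(rows), charges, names, groups, time, radii))
        i += 2 + n
        fidx += 1
    return Trajectory(frames, stride=stride)


def write_xyz_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-frame XYZ file with ``time=<ps>`` comment tags.

    Positions are written to 1e-4 Å (round-trips within the declared
    1e-3 Å precision).
    """
    with open(path, "w") as fh:
        for frame in traj:
            fh.write(f"{len(frame)}\n")
            fh.write(f"time={frame.time:.4f} ps\n")
            for name, pos in zip(frame.names, frame.positions):
                fh.write(f"{name:<4s} {pos[0]:12.4f} {pos[1]:12.4f} {pos[2]:12.4f}\n")


# ---------------------------------------------------------------------------
# Selection mini-language
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Selection:
    """A selection expression over group labels, atom names and indices.

    Grammar (case-insensitive keywords, labels case-sensitive)::

        expr     := or_expr
        or_expr  := and_expr ("or" and_expr)*
        and_expr := shell ("and" shell)*
        shell    := unary ("within" FLOAT "of" shell)?
        unary    := "not" unary | "(" expr ")" | primary
        primary  := "group" LABEL | "name" LABEL | "index" INT("-"INT)? | "all"

    ``A within R of B`` selects atoms of A whose minimum distance to any
    atom of B is ≤ R (closed boundary; ties at exactly R included).
    """

    expression: str

    def resolve(self, frame: ChargedFrame) -> np.ndarray:
        return resolve_selection(frame, self)


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(expr: str) -> list[str]:
    return _TOKEN_RE.findall(expr)


class _SelParser:
    """Recursive-descent parser producing a frame → boolean-mask closure."""

    def __init__(self, tokens: list[str], expression: str) -> None:
        self.toks = tokens
        self.pos = 0
        self.expression = expression

    def peek(self) -> str | None:
        return self.toks[self.pos] if self.pos < len(self.toks) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError(f"unexpected end of selection: {self.expression!r}")
        self.pos += 1
        return tok

    def parse(self) -> Callable[[ChargedFrame], np.ndarray]:
        node = self.or_expr()
        if self.peek() is not None:
            raise SelectionError(
                f"trailing tokens {self.toks[self.pos:]} in {self.expression!r}"
            )
        return node

    def or_expr(self):
        left = self.and_expr()
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            right = self.and_expr()
            left = (lambda l, r: lambda f: l(f) | r(f))(left, right)
        return left

    def and_expr(self):
        left = self.shell()
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            right = self.shell()
            left = (lambda l, r: lambda f: l(f) & r(f))(left, right)
        return left

    def shell(self):
        left = self.unary()
        if self.peek() is not None and self.peek().lower() == "within":
            self.next()
            try:
                radius = float(self.next())
            except ValueError as exc:
                raise SelectionError(
                    f"'within' needs a numeric radius in {self.expression!r}"
                ) from exc
            if self.next().lower() != "of":
                raise SelectionError(f"expected 'of' after 'within {radius}'")
            ref = self.shell()
            def within(f: ChargedFrame, l=left, r=ref, R=radius) -> np.ndarray:
                lmask, rmask = l(f), r(f)
                out = np.zeros(len(f), dtype=bool)
                if lmask.any() and rmask.any():
                    d = cdist(f.positions[lmask], f.positions[rmask])
                    out[np.flatnonzero(lmask)] = d.min(axis=1) <= R
                return out
            return within
        return left

    def unary(self):
        tok = self.peek()
        if tok is None:
            raise SelectionError(f"unexpected end of selection: {self.expression!r}")
        if tok.lower() == "not":
            self.next()
            inner = self.unary()
            return lambda f: ~inner(f)
        if tok == "(":
            self.next()
            inner = self.or_expr()
            if self.next() != ")":
                raise SelectionError(f"unbalanced parentheses in {self.expression!r}")
            return inner
        return self.primary()

    def primary(self):
        tok = self.next().lower()
        if tok == "all":
            return lambda f: np.ones(len(f), dtype=bool)
        if tok == "group":
            label = self.next()
            def by_group(f: ChargedFrame, lab=label) -> np.ndarray:
                if lab not in f.label_set:
                    raise SelectionError(
                        f"unknown group {lab!r}; valid groups: {sorted(f.label_set)}"
                    )
                return np.array([g == lab for g in f.groups])
            return by_group
        if tok == "name":
            label = self.next()
            def by_name(f: ChargedFrame, lab=label) -> np.ndarray:
                if lab not in set(f.names):
                    raise SelectionError(
                        f"unknown atom name {lab!r}; valid names: {sorted(set(f.names))}"
                    )
                return np.array([n == lab for n in f.names])
            return by_name
        if tok == "index":
            spec = self.next()
            try:
                if "-" in spec:
                    lo, hi = (int(s) for s in spec.split("-", 1))
                else:
                    lo = hi = int(spec)
            except ValueError as exc:
                raise SelectionError(f"bad index range {spec!r}") from exc
            def by_index(f: ChargedFrame, lo=lo, hi=hi) -> np.ndarray:
                mask = np.zeros(len(f), dtype=bool)
                mask[lo : hi + 1] = True
                return mask
            return by_index
        raise SelectionError(f"unexpected token {tok!r} in {self.expression!r}")


def _compile_selection(sel: Selection | str) -> Callable[[ChargedFrame], np.ndarray]:
    expr = sel.expression if isinstance(sel, Selection) else sel
    return _SelParser(_tokenize(expr), expr).parse()


def resolve_selection(frame: ChargedFrame, sel: Selection | str) -> np.ndarray:
    """Resolve a selection to a sorted array of 0-based atom indices.

    Deterministic and order-independent: the result depends only on the
    frame content and the expression, never on evaluation order.
    """
    mask = _compile_selection(sel)(frame)
    return np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# Reaction-axis frame
# ---------------------------------------------------------------------------

def build_axis_frame(
    frame: ChargedFrame,
    fe: Selection | str,
    o: Selection | str,
    lateral_ref: Selection | str,
    origin: str = "midpoint",
) -> AxisFrame:
    """Construct the reaction-axis frame from Fe, O and a lateral reference.

    z points Fe→O; y is the component of (lateral-reference centroid −
    origin) orthogonal to z, normalised; x = y × z.  ``origin`` is
    ``"midpoint"`` (default), ``"fe"`` or ``"o"``.

    Raises
    ------
    SelectionError
        If ``fe`` or ``o`` resolve to anything but exactly one atom.
    GeometryError
        If |O − Fe| < 0.5 Å, or the lateral centroid is collinear with
        the Fe–O axis (degenerate frame).
    """
    fe_idx = resolve_selection(frame, fe)
    o_idx = resolve_selection(frame, o)
    if len(fe_idx) != 1 or len(o_idx) != 1:
        raise SelectionError(
            f"fe and o must each resolve to exactly one atom "
            f"(got {len(fe_idx)} and {len(o_idx)})"
        )
    lat_idx = resolve_selection(frame, lateral_ref)
    if len(lat_idx) == 0:
        raise SelectionError("lateral_ref selection is empty")
    fe_pos = frame.positions[fe_idx[0]]
    o_pos = frame.positions[o_idx[0]]
    bond = o_pos - fe_pos
    bond_len = np.linalg.norm(bond)
    if bond_len < 0.5:
        raise GeometryError(f"|O − Fe| = {bond_len:.3f} Å < 0.5 Å")
    z_hat = bond / bond_len
    if origin == "midpoint":
        org = 0.5 * (fe_pos + o_pos)
    elif origin == "fe":
        org = fe_pos
    elif origin == "o":
        org = o_pos
    else:
        raise ValueError(f"origin must be midpoint/fe/o, got {origin!r}")
    lateral = frame.positions[lat_idx].mean(axis=0) - org
    y_raw = lateral - (lateral @ z_hat) * z_hat
    y_norm = np.linalg.norm(y_raw)
    if y_norm < 1e-6:
        raise GeometryError("lateral reference is collinear with the Fe–O axis")
    y_hat = y_raw / y_norm
    x_hat = np.cross(y_hat, z_hat)
    return AxisFrame(org, z_hat, y_hat, x_hat)
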