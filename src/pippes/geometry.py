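"""Molecular geometries, interatomic distances and the Morse transform.

Coordinates are stored in bohr.  XYZ files are assumed to be in Angstrom
(the de facto XYZ convention) unless the comment line mentions ``bohr`` or
the caller overrides; the plain-text dataset format used for fitting is
always in bohr/hartree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .symmetry import SymmetrySpec
from .units import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM, mass_of

__all__ = [
    "Geometry",
    "interatomic_distances",
    "morse_transform",
    "read_xyz",
    "write_xyz",
]


@dataclass
class Geometry:
    """Element labels plus Cartesian coordinates in bohr."""

    elements: list[str]
    coords: np.ndarray  # (N, 3) bohr
    masses: np.ndarray | None = field(default=None)  # electron masses

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.elements) != len(self.coords):
            raise ValueError(
                f"{len(self.elements)} element labels but {len(self.coords)} coordinates"
            )
        if self.n_atoms < 2:
            raise ValueError("a geometry needs at least two atoms")
        if self.masses is None:
            self.masses = np.array([mass_of(el) for el in self.elements])
        else:
            self.masses = np.asarray(self.masses, dtype=float)
            if len(self.masses) != self.n_atoms:
                raise ValueError("masses length must equal atom count")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def check_layout(self, sym: SymmetrySpec) -> None:
        """Verify the atom ordering is class-by-class for ``sym``.

        Atoms of each symmetry class must be contiguous and share an element
        label, in the class order of the spec string.
        """
        if self.n_atoms != sym.n_atoms:
            raise ValueError(
                f"geometry has {self.n_atoms} atoms; symmetry {sym} needs {sym.n_atoms}"
            )
        k = 0
        for label, cnt in sym.classes:
            block = set(self.elements[k : k + cnt])
            if len(block) != 1:
                raise ValueError(
                    f"atoms {k}..{k + cnt - 1} must all belong to symmetry class "
                    f"{label!r} but have elements {sorted(block)}"
                )
            k += cnt

    def permuted(self, atom_perm: np.ndarray) -> "Geometry":
        """Geometry with atom i moved to position atom_perm[i]."""
        inv = np.argsort(atom_perm)
        return Geometry(
            elements=[self.elements[i] for i in inv],
            coords=self.coords[inv],
            masses=self.masses[inv],
        )


def interatomic_distances(geom: Geometry | np.ndarray) -> np.ndarray:
    """All pair distances r_ij (i<j, lexicographic) in bohr."""
    coords = geom.coords if isinstance(geom, Geometry) else np.asarray(geom)
    i, j = np.triu_indices(len(coords), k=1)
    return np.linalg.norm(coords[i] - coords[j], axis=1)


def batch_distances(coords: np.ndarray) -> np.ndarray:
    """Pair distances for a batch of configurations, shape (n, n_pairs)."""
    coords = np.asarray(coords, dtype=float)
    i, j = np.triu_indices(coords.shape[-2], k=1)
    return np.linalg.norm(coords[..., i, :] - coords[..., j, :], axis=-1)


def morse_transform(r: np.ndarray, a: float = 3.0) -> np.ndarray:
    """Morse variables y = exp(-r/a); ``a`` is the range parameter in bohr.

    Maps [0, inf) monotonically into (0, 1]; the default a = 3.0 bohr is the
    range parameter used for the Zundel-cation fits.
    """
    if a <= 0:
        raise ValueError(f"range parameter a must be positive, got {a}")
    return np.exp(-np.asarray(r, dtype=float) / a)


# ---------------------------------------------------------------------------
# XYZ I/O


def read_xyz(path, units: str | None = None) -> Geometry:
    """Read a standard XYZ file into a :class:`Geometry` (coords in bohr).

    ``units`` may be ``"angstrom"`` or ``"bohr"``; if omitted, Angstrom is
    assumed unless the comment line contains the word "bohr".
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}: line 1: expected an atom count") from None
    comment = lines[1] if len(lines) > 1 else ""
    if units is None:
        units = "bohr" if "bohr" in comment.lower() else "angstrom"
    if units not in ("angstrom", "bohr"):
        raise ValueError(f"units must be 'angstrom' or 'bohr', got {units!r}")
    body = lines[2 : 2 + n]
    if len(body) < n:
        raise ValueError(
            f"{path}: header declares {n} atoms but only {len(body)} atom lines present"
        )
    elements, coords = [], []
    for k, line in enumerate(body):
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: line {k + 3}: expected 'element x y z'")
        elements.append(parts[0])
        try:
            coords.append([float(x) for x in parts[1:4]])
        except ValueError:
            raise ValueError(f"{path}: line {k + 3}: bad coordinate in {line!r}") from None
    coords = np.asarray(coords)
    if units == "angstrom":
        coords = coords * ANGSTROM_TO_BOHR
    return Geometry(elements=elements, coords=coords)


def write_xyz(geom: Geometry, path, comment: str = "", units: str = "angstrom") -> None:
    """Write ``geom`` as XYZ.  Bohr output is flagged in the comment line."""
    if units not in ("angstrom", "bohr"):
        raise ValueError(f"units must be 'angstrom' or 'bohr', got {units!r}")
    coords = geom.coords if units == "bohr" else geom.coords * BOHR_TO_ANGSTROM
    if units == "bohr" and "bohr" not in comment.lower():
        comment = (comment + " [bohr]").strip()
    lines = [str(geom.n_atoms), comment]
    for el, (x, y, z) in zip(geom.elements, coords):
        lines.append(f"{el:<3s} {x:20.12f} {y:20.12f} {z:20.12f}")
    Path(path).write_text("\n".join(lines) + "\n")
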