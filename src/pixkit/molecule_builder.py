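"""Build complete molecules from the asymmetric unit under symmetry.

Growth proceeds by breadth-first bond search over symmetry images of the
asymmetric-unit sites; atoms landing on special positions (coincident
images) are merged, and infinite (polymeric) connectivity is detected
exactly: a finite molecule can never contain two atoms that are pure
lattice translates of the same generated position.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import elements
from .cif_io import CrystalStructure, frac_to_cart
from .errors import CapacityError, DisorderError, PixkitError, PolymericError

__all__ = [
    "Atom",
    "Molecule",
    "HNormalizationTable",
    "DEFAULT_H_TABLE",
    "infer_bonds",
    "complete_molecules",
    "drop_coincident",
    "normalize_h",
    "mass_weighted_centroid",
    "check_pixel_capacity",
]

BOND_SLACK = 0.40          # added to covalent-radius sum, Angstrom
COINCIDENCE_TOL = 0.15     # special-position merge tolerance, Angstrom
PIXEL_ATOM_LIMIT = 200
PIXEL_RESIDUE_LIMIT = 2


@dataclass(frozen=True)
class Atom:
    element: str
    cart: tuple[float, float, float]
    mass: float
    source_site: str = ""
    # (operation index, integer cell translation) that generated this atom
    generator: tuple[int, tuple[int, int, int]] = (1, (0, 0, 0))

    def __post_init__(self):
        if self.mass <= 0:
            raise PixkitError(f"non-positive mass for atom {self.source_site!r}")

    @property
    def pos(self) -> np.ndarray:
        return np.array(self.cart)


@dataclass
class Molecule:
    atoms: list[Atom]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    residue_id: int = 1

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.cart for a in self.atoms])

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def centroid(self) -> np.ndarray:
        return mass_weighted_centroid(self)

    def is_connected(self) -> bool:
        if len(self.atoms) <= 1:
            return True
        adj: dict[int, set[int]] = {i: set() for i in range(len(self.atoms))}
        for i, j in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        seen = {0}
        stack = [0]
        while stack:
            for k in adj[stack.pop()]:
                if k not in seen:
                    seen.add(k)
                    stack.append(k)
        return len(seen) == len(self.atoms)


# X-H target bond lengths from neutron diffraction surveys; overridable.
DEFAULT_H_TABLE: dict[str, float] = {"C": 1.089, "N": 1.015, "O": 0.993, "B": 1.180}


class HNormalizationTable(dict):
    """Map donor element -> target X-H bond length in Angstrom."""

    def __init__(self, mapping: dict[str, float] | None = None):
        super().__init__(mapping if mapping is not None else DEFAULT_H_TABLE)
        for el, length in self.items():
            if not 0.8 < length < 1.3:
                raise PixkitError(
                    f"X-H target {length} A for {el} outside the plausible (0.8, 1.3) range"
                )


def infer_bonds(atoms: list[Atom], slack: float = BOND_SLACK) -> list[tuple[int, int]]:
    """Distance-based connectivity: d < r_cov(i) + r_cov(j) + slack.

    Hydrogen is capped at a single bond (its nearest heavy atom).
    """
    if not atoms:
        raise PixkitError("infer_bonds needs at least one atom")
    coords = np.array([a.cart for a in atoms])
    radii = np.array([elements.covalent_radius(a.element) for a in atoms])
    is_h = np.array([a.element == "H" for a in atoms])
    n = len(atoms)
    bonds: list[tuple[int, int]] = []
    h_partner: dict[int, tuple[int, float]] = {}
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    cut = radii[:, None] + radii[None, :] + slack
    for i in range(n):
        for j in range(i + 1, n):
            d = dist[i, j]
            if d >= cut[i, j] or d < 1e-6:
                continue
            if is_h[i] and is_h[j]:
                continue
            if is_h[i] or is_h[j]:
                h, x = (i, j) if is_h[i] else (j, i)
                best = h_partner.get(h)
                if best is None or d < best[1]:
                    h_partner[h] = (x, d)
            else:
                bonds.append((i, j))
    for h, (x, _) in sorted(h_partner.items()):
        bonds.append(tuple(sorted((h, x))))
    return sorted(set(bonds))


def drop_coincident(atoms: list[Atom], tolerance: float = COINCIDENCE_TOL):
    """Remove later-listed atoms closer than ``tolerance`` to a survivor.

    Returns (survivors, n_dropped).
    """
    if tolerance <= 0:
        raise PixkitError("coincidence tolerance must be positive")
    survivors: list[Atom] = []
    coords: list[np.ndarray] = []
    dropped = 0
    for atom in atoms:
        p = atom.pos
        if any(np.linalg.norm(p - q) < tolerance for q in coords):
            dropped += 1
            continue
        survivors.append(atom)
        coords.append(p)
    return survivors, dropped


def mass_weighted_centroid(molecule: Molecule) -> np.ndarray:
    """Mass-weighted centroid: sum m_i (r_i - c) = 0."""
    if not molecule.atoms:
        raise PixkitError("empty molecule has no centroid")
    m = molecule.masses
    return (m[:, None] * molecule.coords).sum(axis=0) / m.sum()


def normalize_h(molecule: Molecule,
                table: HNormalizationTable | dict[str, float] | None = None) -> Molecule:
    """Move each H along its existing X-H vector to the neutron target length.

    Heavy atoms are untouched; H atoms bonded to elements absent from the
    table are left in place. Idempotent.
    """
    if table is None:
        table = HNormalizationTable()
    adj: dict[int, list[int]] = {i: [] for i in range(len(molecule.atoms))}
    for i, j in molecule.bonds:
        adj[i].append(j)
        adj[j].append(i)
    new_atoms = list(molecule.atoms)
    for i, atom in enumerate(molecule.atoms):
        if atom.element != "H":
            continue
        heavies = [j for j in adj[i] if molecule.atoms[j].element != "H"]
        if len(heavies) != 1:
            raise PixkitError(
                f"H atom {atom.source_site or i} has {len(heavies)} bonded heavy atoms; "
                "expected exactly one"
            )
        x = molecule.atoms[heavies[0]]
        target = table.get(x.element)
        if target is None:
            continue
        vec = atom.pos - x.pos
        norm = np.linalg.norm(vec)
        if norm < 1e-6:
            raise PixkitError(f"degenerate X-H bond at {atom.source_site or i}")
        new_pos = x.pos + vec * (target / norm)
        new_atoms[i] = replace(atom, cart=tuple(new_pos))
    return Molecule(atoms=new_atoms, bonds=list(molecule.bonds),
                    residue_id=molecule.residue_id)


def check_pixel_capacity(molecules: list[Molecule]) -> None:
    """Enforce the Pixel-export limits: <= 200 atoms and <= 2 residues."""
    if len(molecules) > PIXEL_RESIDUE_LIMIT:
        raise CapacityError(
            f"{len(molecules)} residues exceed the {PIXEL_RESIDUE_LIMIT}-molecule "
            "asymmetric-unit limit for Pixel export"
        )
    for mol in molecules:
        if len(mol) > PIXEL_ATOM_LIMIT:
            raise CapacityError(
                f"residue {mol.residue_id} has {len(mol)} atoms, above the "
                f"{PIXEL_ATOM_LIMIT}-atom Pixel capacity"
            )


# ---------------------------------------------------------------------------
# Molecule completion under symmetry
# ---------------------------------------------------------------------------

def _site_images(structure: CrystalStructure):
    """Precompute R_k x_s + t_k for every (operation k, site s)."""
    base = {}
    for op in structure.operations:
        for si, site in enumerate(structure.sites):
            base[(op.index, si)] = op.rot_array @ np.asarray(site.frac) + op.trans_array
    return base


def complete_molecules(structure: CrystalStructure, *,
                       allow_disorder: bool = False,
                       slack: float = BOND_SLACK,
                       tolerance: float = COINCIDENCE_TOL) -> list[Molecule]:
    """Grow chemically complete molecules from the asymmetric unit.

    Every atom is an image of an asymmetric-unit site under one of the
    structure's operations plus an integer cell translation; its generator
    is retained. Coincident images (special positions) are merged keeping
    the first generator encountered. Raises PolymericError on infinite
    connectivity, naming the bridging bond.
    """
    if structure.has_disorder() and not allow_disorder:
        raise DisorderError(
            "structure has partially occupied sites; pass allow_disorder=True "
            "to proceed anyway"
        )
    cellmat = structure.cell.matrix
    sites = structure.sites
    base = _site_images(structure)
    radii = [elements.covalent_radius(s.element) for s in sites]
    is_h = [s.element == "H" for s in sites]

    # Each grown atom: dict with frac, cart, site index, generator (k, n).
    atoms: list[dict] = []
    visited: dict[tuple, int] = {}   # (k, si, n) -> atom index (incl. merged aliases)
    assigned: list[int | None] = [None] * len(sites)  # site -> component seed atom

    def add_atom(k: int, si: int, n: tuple[int, int, int], frac: np.ndarray,
                 component: list[int]) -> int | None:
        """Register an image; returns new atom index or None if coincident."""
        cart = cellmat @ frac
        for ai in component:
            if np.linalg.norm(cart - atoms[ai]["cart"]) < tolerance:
                visited[(k, si, n)] = ai
                atoms[ai]["merged"] += 1
                return None
        # exact polymer test: same site, same rotation, different translation
        rot = structure.operation(k).rotation
        for ai in component:
            if atoms[ai]["site"] == si and atoms[ai]["rot"] == rot:
                diff = frac - atoms[ai]["frac"]
                nint = np.rint(diff)
                if np.allclose(diff, nint, atol=1e-6) and np.any(np.abs(nint) > 0.5):
                    raise PolymericError(
                        "infinite (polymeric) connectivity detected",
                        bridging_bond=(sites[si].label, sites[si].label),
                    )
        atoms.append({
            "frac": frac, "cart": cart, "site": si, "gen": (k, n), "rot": rot,
            "merged": 0,
        })
        idx = len(atoms) - 1
        visited[(k, si, n)] = idx
        component.append(idx)
        return idx

    id_index = structure.identity_index
    molecules: list[Molecule] = []
    residue = 0
    for seed_si in range(len(sites)):
        if assigned[seed_si] is not None:
            continue
        component: list[int] = []
        seed_frac = np.asarray(sites[seed_si].frac, dtype=float)
        seed_idx = add_atom(id_index, seed_si, (0, 0, 0), seed_frac, component)
        if seed_idx is None:
            continue
        queue = [seed_idx]
        while queue:
            ai = queue.pop()
            a = atoms[ai]
            f = a["frac"]
            r_a = radii[a["site"]]
            for (k, si2), b in base.items():
                n0 = np.rint(f - b).astype(int)
                for dn in itertools.product((-1, 0, 1), repeat=3):
                    n = tuple(int(v) for v in (n0 + dn))
                    key = (k, si2, n)
                    if key in visited:
                        continue
                    frac2 = b + np.asarray(n)
                    cart2 = cellmat @ frac2
                    d = float(np.linalg.norm(cart2 - a["cart"]))
                    if d >= r_a + radii[si2] + slack:
                        continue
                    if is_h[a["site"]] and is_h[si2] and d > tolerance:
                        continue
                    new_idx = add_atom(k, si2, n, frac2, component)
                    if new_idx is not None:
                        queue.append(new_idx)
            if len(component) > 50 * len(sites) * len(structure.operations):
                raise PolymericError("molecule growth failed to close")
        residue += 1
        mol_atoms = []
        for ai in component:
            a = atoms[ai]
            site = sites[a["site"]]
            if assigned[a["site"]] is None:
                assigned[a["site"]] = residue
            mol_atoms.append(Atom(
                element=site.element,
                cart=tuple(a["cart"]),
                mass=elements.mass_of(site.element),
                source_site=site.label,
                generator=(a["gen"][0], a["gen"][1]),
            ))
        bonds = infer_bonds(mol_atoms, slack=slack)
        mol = Molecule(atoms=mol_atoms, bonds=bonds, residue_id=residue)
        if not mol.is_connected():
            # can only happen if an isolated single atom or odd tolerance; accept
            # single atoms, refuse fragmented growth
            if len(mol_atoms) > 1:
                raise PixkitError(
                    f"residue {residue} grew into a disconnected bond graph"
                )
        molecules.append(mol)
    return molecules
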