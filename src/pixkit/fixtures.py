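"""Synthetic test inputs with independently computed ground truth.

Toy crystals cover the symmetry situations that matter for pair
enumeration and molecule completion: a P1 point lattice, an inversion
dimer, P2_1/c at a general position, a half-molecule on an inversion
centre, an atom on a twofold axis, a 2_1-screw hydrogen-bond chain, a
translation stack, a Z'=4 cell, and a deliberately disordered negative
test. Ground-truth pair distances come from ``brute_force_pairs``, a
supercell expansion that shares no code with the production enumerator
(atoms expanded, coincidences merged, connected components found,
centroids measured). Gaussian-blob density cubes come with closed-form
Coulomb interactions, and a full tripalmitin molecule is built
programmatically as the 155-atom capacity test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.special import erf

from . import elements
from .cif_io import (AtomSite, CrystalStructure, UnitCell, parse_symop_xyz,
                     write_cif)
from .density_pixels import COULOMB_K, DensityCube
from .errors import PixkitError
from .molecule_builder import Atom, Molecule

__all__ = [
    "FixtureSpec",
    "ToyCrystal",
    "make_toy_crystal",
    "FIXTURE_NAMES",
    "brute_force_pairs",
    "make_gaussian_cube",
    "analytic_coulomb",
    "gaussian_radius_of_gyration",
    "build_tripalmitin",
]


# ---------------------------------------------------------------------------
# Toy crystals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a toy crystal: cell, operator list, atoms in Cartesian A."""

    name: str
    cell: UnitCell
    symops: tuple[str, ...]
    # (label, element, cartesian position, occupancy)
    atoms_cart: tuple[tuple[str, str, tuple[float, float, float], float], ...]
    seed: int = 0


@dataclass
class ToyCrystal:
    spec: FixtureSpec
    structure: CrystalStructure
    cif_text: str


def _build(spec: FixtureSpec) -> ToyCrystal:
    ops = [parse_symop_xyz(s, index=i + 1) for i, s in enumerate(spec.symops)]
    if not any(op.is_identity() for op in ops):
        raise PixkitError(f"fixture {spec.name}: operator list lacks identity")
    inv = spec.cell.inverse_matrix
    sites = [
        AtomSite(label=label, element=el, frac=tuple(inv @ np.asarray(cart)),
                 occupancy=occ)
        for label, el, cart, occ in spec.atoms_cart
    ]
    structure = CrystalStructure(cell=spec.cell, operations=ops, sites=sites,
                                 space_group_name="?")
    return ToyCrystal(spec=spec, structure=structure,
                      cif_text=write_cif(structure, data_name=spec.name))


def _cubic(a: float) -> UnitCell:
    return UnitCell(a, a, a, 90.0, 90.0, 90.0)


_P21C_OPS = ("x, y, z", "-x, 1/2+y, 1/2-z", "-x, -y, -z", "x, 1/2-y, 1/2+z")


def _spec_p1_atom() -> FixtureSpec:
    return FixtureSpec(
        name="p1_atom", cell=_cubic(5.0), symops=("x, y, z",),
        atoms_cart=(("C1", "C", (0.0, 0.0, 0.0), 1.0),),
    )


def _spec_inversion_dimer() -> FixtureSpec:
    # antiparallel CO pair across the inversion centre at the origin,
    # interplanar separation ~3.2 A: a pure inversion contact, no 1D motif
    cell = UnitCell(7.0, 8.0, 9.0, 90.0, 95.0, 90.0)
    return FixtureSpec(
        name="inversion_dimer", cell=cell, symops=("x, y, z", "-x, -y, -z"),
        atoms_cart=(
            ("C1", "C", (-0.56, 1.60, 0.00), 1.0),
            ("O1", "O", (0.57, 1.60, 0.00), 1.0),
        ),
    )


def _spec_p21c_small() -> FixtureSpec:
    # formaldehyde-like molecule at a general position of P2_1/c
    cell = UnitCell(6.5, 7.5, 8.5, 90.0, 100.0, 90.0)
    p0 = np.array(cell.matrix @ np.array([0.23, 0.11, 0.17]))
    atoms = (
        ("C1", "C", tuple(p0), 1.0),
        ("O1", "O", tuple(p0 + np.array([1.21, 0.0, 0.0])), 1.0),
        ("H1", "H", tuple(p0 + np.array([-0.57, 0.93, 0.0])), 1.0),
        ("H2", "H", tuple(p0 + np.array([-0.57, -0.93, 0.0])), 1.0),
    )
    return FixtureSpec(name="p21c_small", cell=cell, symops=_P21C_OPS,
                       atoms_cart=atoms)


def _spec_inversion_half() -> FixtureSpec:
    # centrosymmetric O=C-C=O molecule on the inversion centre: the
    # asymmetric unit holds half the molecule
    cell = UnitCell(8.0, 9.0, 10.0, 90.0, 90.0, 90.0)
    return FixtureSpec(
        name="inversion_half", cell=cell, symops=("x, y, z", "-x, -y, -z"),
        atoms_cart=(
            ("C1", "C", (0.70, 0.00, 0.00), 1.0),
            ("O1", "O", (1.35, 1.00, 0.00), 1.0),
        ),
    )


def _spec_axis_mol() -> FixtureSpec:
    # C-O-C molecule bisected by the twofold axis along b: the O sits on
    # the axis and must appear once after completion
    cell = UnitCell(8.0, 6.0, 9.0, 90.0, 90.0, 90.0)
    return FixtureSpec(
        name="axis_mol", cell=cell, symops=("x, y, z", "-x, y, -z"),
        atoms_cart=(
            ("O1", "O", (0.00, 1.50, 0.00), 1.0),
            ("C1", "C", (1.00, 2.30, 0.30), 1.0),
        ),
    )


def _spec_screw_chain() -> FixtureSpec:
    # methanol-like C-O-H whose O-H donates to the 2_1-screw image's O,
    # giving an infinite hydrogen-bond chain along b with period 2
    cell = UnitCell(8.0, 5.0, 9.0, 90.0, 90.0, 90.0)
    o = np.array([0.60, 0.00, 0.00])
    o_img = np.array([-0.60, 2.50, 0.00])        # screw image of o
    v = o_img - o
    h = o + 0.99 * v / np.linalg.norm(v)
    c = o + np.array([0.0, 0.0, 1.43])
    return FixtureSpec(
        name="screw_chain", cell=cell, symops=("x, y, z", "-x, 1/2+y, -z"),
        atoms_cart=(
            ("O1", "O", tuple(o), 1.0),
            ("H1", "H", tuple(h), 1.0),
            ("C1", "C", tuple(c), 1.0),
        ),
    )


def _spec_translation_stack() -> FixtureSpec:
    # planar ethylene-like molecule in the bc plane of a short-a P1 cell:
    # every atom is in vdW contact with the a-translated image (stack along a)
    cell = UnitCell(3.5, 11.0, 11.0, 90.0, 90.0, 90.0)
    atoms = (
        ("C1", "C", (0.00, 0.667, 0.00), 1.0),
        ("C2", "C", (0.00, -0.667, 0.00), 1.0),
        ("H1", "H", (0.00, 1.240, 0.92), 1.0),
        ("H2", "H", (0.00, 1.240, -0.92), 1.0),
        ("H3", "H", (0.00, -1.240, 0.92), 1.0),
        ("H4", "H", (0.00, -1.240, -0.92), 1.0),
    )
    return FixtureSpec(name="translation_stack", cell=cell,
                       symops=("x, y, z",), atoms_cart=atoms)


def _spec_zprime4() -> FixtureSpec:
    # four independent CO molecules in a P1 cell (Z' = 4)
    cell = _cubic(8.0)
    anchors = [
        np.array([0.8, 0.8, 0.8]),
        np.array([4.8, 1.2, 1.6]),
        np.array([1.2, 4.8, 2.4]),
        np.array([3.2, 3.6, 5.2]),
    ]
    directions = [
        np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]),
        np.array([0.0, 0.0, 1.0]),
        np.array([1.0, 1.0, 0.0]) / math.sqrt(2.0),
    ]
    atoms = []
    for i, (p, u) in enumerate(zip(anchors, directions), start=1):
        atoms.append((f"C{i}", "C", tuple(p), 1.0))
        atoms.append((f"O{i}", "O", tuple(p + 1.13 * u), 1.0))
    return FixtureSpec(name="zprime4", cell=cell, symops=("x, y, z",),
                       atoms_cart=tuple(atoms))


def _spec_disordered() -> FixtureSpec:
    cell = _cubic(6.0)
    return FixtureSpec(
        name="disordered", cell=cell, symops=("x, y, z",),
        atoms_cart=(
            ("C1", "C", (0.0, 0.0, 0.0), 1.0),
            ("O1", "O", (1.2, 0.0, 0.0), 0.5),
        ),
    )


_SPECS = {
    "p1_atom": _spec_p1_atom,
    "inversion_dimer": _spec_inversion_dimer,
    "p21c_small": _spec_p21c_small,
    "inversion_half": _spec_inversion_half,
    "axis_mol": _spec_axis_mol,
    "screw_chain": _spec_screw_chain,
    "translation_stack": _spec_translation_stack,
    "zprime4": _spec_zprime4,
    "disordered": _spec_disordered,
}

FIXTURE_NAMES = tuple(n for n in _SPECS if n != "disordered")


def make_toy_crystal(name_or_spec: str | FixtureSpec) -> ToyCrystal:
    if isinstance(name_or_spec, FixtureSpec):
        return _build(name_or_spec)
    try:
        spec = _SPECS[name_or_spec]()
    except KeyError:
        raise PixkitError(f"unknown fixture {name_or_spec!r}; "
                          f"known: {', '.join(sorted(_SPECS))}") from None
    return _build(spec)


# ---------------------------------------------------------------------------
# Brute-force supercell oracle
# ---------------------------------------------------------------------------

def brute_force_pairs(structure: CrystalStructure, cutoff: float,
                      extent_margin: float = 4.0):
    """Reference pair distances by explicit supercell expansion.

    Expands every site over all operations and enough cell translations,
    merges coincident atoms, finds bonded connected components, and
    measures mass-weighted-centroid distances from each reference molecule
    (the components holding the identity images of the asymmetric unit) to
    every other component. Returns {reference index: sorted distances}.
    """
    cellmat = structure.cell.matrix
    inv = structure.cell.inverse_matrix
    row_norms = np.linalg.norm(inv, axis=1)
    au_cart = np.array([cellmat @ np.asarray(s.frac) for s in structure.sites])
    spread = 0.0
    if len(au_cart) > 1:
        spread = float(np.sqrt(((au_cart[:, None] - au_cart[None]) ** 2)
                               .sum(-1)).max())
    reach = cutoff + 2.0 * (spread + extent_margin)
    ncells = [int(math.ceil(reach * rn)) + 1 for rn in row_norms]

    fracs, elems, ids = [], [], []
    for op in structure.operations:
        for si, site in enumerate(structure.sites):
            base = op.rot_array @ np.asarray(site.frac) + op.trans_array
            for n in itertools.product(*[range(-m, m + 1) for m in ncells]):
                fracs.append(base + np.asarray(n))
                elems.append(site.element)
                ids.append((op.index, si, n))
    fracs = np.array(fracs)
    carts = fracs @ cellmat.T
    masses = np.array([elements.mass_of(e) for e in elems])
    radii = np.array([elements.covalent_radius(e) for e in elems])
    is_h = np.array([e == "H" for e in elems])

    tree = cKDTree(carts)
    # merge coincident atoms (special positions): earlier op/site wins
    order = {rec: k for k, rec in enumerate(ids)}
    alive = np.ones(len(carts), dtype=bool)
    for i, j in sorted(tree.query_pairs(r=0.15)):
        a, b = (i, j) if order[ids[i]] <= order[ids[j]] else (j, i)
        if alive[a]:
            alive[b] = False
    idx_map = np.flatnonzero(alive)
    carts = carts[idx_map]
    masses = masses[idx_map]
    radii = radii[idx_map]
    is_h = is_h[idx_map]
    fracs = fracs[idx_map]
    kept_ids = [ids[k] for k in idx_map]

    tree = cKDTree(carts)
    max_bond = 2.0 * radii.max() + 0.40
    rows, cols = [], []
    for i, j in tree.query_pairs(r=max_bond):
        if is_h[i] and is_h[j]:
            continue
        d = np.linalg.norm(carts[i] - carts[j])
        if d < radii[i] + radii[j] + 0.40:
            rows.append(i)
            cols.append(j)
    adj = sparse.coo_matrix((np.ones(len(rows)), (rows, cols)),
                            shape=(len(carts), len(carts)))
    ncomp, labels = connected_components(adj + adj.T, directed=False)

    centroids = np.zeros((ncomp, 3))
    total_mass = np.zeros(ncomp)
    np.add.at(total_mass, labels, masses)
    for ax in range(3):
        np.add.at(centroids[:, ax], labels, masses * carts[:, ax])
    centroids /= total_mass[:, None]

    id_index = structure.identity_index
    zero = (0, 0, 0)
    ref_comps: dict[int, int] = {}
    for k, rec in enumerate(kept_ids):
        opi, si, n = rec
        if opi == id_index and n == zero:
            ref_comps.setdefault(int(labels[k]), len(ref_comps))

    out: dict[int, list[float]] = {}
    for comp, ref_idx in sorted(ref_comps.items(), key=lambda kv: kv[1]):
        c = centroids[comp]
        dists = np.linalg.norm(centroids - c, axis=1)
        sel = (dists > 1e-6) & (dists <= cutoff + 1e-9)
        out[ref_idx + 1] = sorted(float(d) for d in dists[sel])
    return out


# ---------------------------------------------------------------------------
# Gaussian density cubes with analytic electrostatics
# ---------------------------------------------------------------------------

def make_gaussian_cube(centers, sigmas, electrons, *, origin, spacing,
                       shape, nuclei=None, comment="gaussian blob fixture"
                       ) -> DensityCube:
    """Cube sampling a sum of normalized isotropic Gaussians.

    ``electrons[k]`` is the (positive) electron count of blob k with width
    ``sigmas[k]`` at ``centers[k]``; values are e/A^3 on a uniform grid.
    Errors out if the narrowest blob is resolved by fewer than 6 grid
    steps per standard deviation.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    sigmas = np.atleast_1d(np.asarray(sigmas, dtype=float))
    electrons = np.atleast_1d(np.asarray(electrons, dtype=float))
    if spacing > sigmas.min() / 6.0 + 1e-12:
        raise PixkitError(
            f"grid spacing {spacing} A under-resolves sigma={sigmas.min()} A "
            "(need >= 6 steps per standard deviation)")
    nx, ny, nz = shape
    origin = np.asarray(origin, dtype=float)
    xs = origin[0] + spacing * np.arange(nx)
    ys = origin[1] + spacing * np.arange(ny)
    zs = origin[2] + spacing * np.arange(nz)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    rho = np.zeros(shape)
    for c, s, q in zip(centers, sigmas, electrons):
        r2 = (gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2
        rho += q / ((2.0 * math.pi) ** 1.5 * s ** 3) * np.exp(-r2 / (2.0 * s * s))
    axes = np.diag([spacing] * 3)
    return DensityCube(origin=origin, axes=axes, counts=tuple(shape),
                       values=rho, nuclei=list(nuclei or []), comment=comment)


def gaussian_radius_of_gyration(sigma: float) -> float:
    return math.sqrt(3.0) * sigma


def _pair_term(qa, sa, qb, sb, r) -> float:
    """Coulomb energy of two spherical Gaussian charges (sigma=0 -> point)."""
    s = math.sqrt(sa * sa + sb * sb)
    if r < 1e-12:
        if s < 1e-12:
            raise PixkitError("point charges at zero separation")
        return COULOMB_K * qa * qb * math.sqrt(2.0 / math.pi) / s
    if s < 1e-12:
        return COULOMB_K * qa * qb / r
    return COULOMB_K * qa * qb * float(erf(r / (math.sqrt(2.0) * s))) / r


def analytic_coulomb(components_a, components_b) -> float:
    """Closed-form interaction between two sets of (charge, sigma, center).

    Charges in e (electron blobs negative, nuclei positive with sigma 0);
    result in kJ/mol — the exact value the pixel sum approximates.
    """
    total = 0.0
    for qa, sa, ca in components_a:
        for qb, sb, cb in components_b:
            r = float(np.linalg.norm(np.asarray(ca, float) - np.asarray(cb, float)))
            total += _pair_term(qa, sa, qb, sb, r)
    return total


# ---------------------------------------------------------------------------
# Tripalmitin capacity fixture
# ---------------------------------------------------------------------------

TRIPALMITIN_SMILES = ("CCCCCCCCCCCCCCCC(=O)OCC(OC(=O)CCCCCCCCCCCCCCC)"
                      "COC(=O)CCCCCCCCCCCCCCC")


def build_tripalmitin(seed: int = 20260903) -> Molecule:
    """Glycerol tripalmitate with explicit hydrogens and idealized 3D
    geometry (155 atoms, acyclic: 154 bonds)."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.AddHs(Chem.MolFromSmiles(TRIPALMITIN_SMILES))
    embedded = False
    for attempt in range(8):   # a given seed can fail at 155 atoms; retry nearby
        params = AllChem.ETKDGv3()
        params.randomSeed = seed + attempt
        params.useRandomCoords = True
        params.maxIterations = 500
        if AllChem.EmbedMolecule(mol, params) == 0:
            embedded = True
            break
    if not embedded:
        raise PixkitError("3D embedding of tripalmitin failed")
    AllChem.MMFFOptimizeMolecule(mol, maxIters=5000)
    conf = mol.GetConformer()
    counters: dict[str, int] = {}
    atoms = []
    for i, a in enumerate(mol.GetAtoms()):
        sym = a.GetSymbol()
        counters[sym] = counters.get(sym, 0) + 1
        pos = conf.GetAtomPosition(i)
        atoms.append(Atom(element=sym, cart=(pos.x, pos.y, pos.z),
                          mass=elements.mass_of(sym),
                          source_site=f"{sym}{counters[sym]}"))
    bonds = sorted(tuple(sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx())))
                   for b in mol.GetBonds())
    return Molecule(atoms=atoms, bonds=bonds, residue_id=1)
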