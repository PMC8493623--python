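"""Symmetry-related molecular pairs, ORTEP-type codes, and centroid matching.

An ORTEP-type code packs the three unit-cell translations (each + 5) and
the 1-based symmetry-operation number into one integer string: ``55501``
is the identity operation with no translation. Operation numbering follows
the CIF loop order of the parsed structure — which may differ from the
numbering used by other programs for the same space group.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np

from .cif_io import CrystalStructure, SymmetryOperation, format_symop_xyz
from .errors import PixkitError
from .molecule_builder import Atom, Molecule, infer_bonds, mass_weighted_centroid

__all__ = [
    "OrtepCode",
    "MolecularPair",
    "PairTable",
    "encode_ortep",
    "decode_ortep",
    "ortep_to_standard",
    "enumerate_pairs",
    "match_centroids",
    "pair_multiplicities",
    "inverse_code",
    "image_molecule",
    "EnergyBreakdown",
]

REMEDY_MESSAGE = ("no pair within tolerance of an external centroid distance; "
                  "the default 20 A limit on the centroid scan should be increased")


@dataclass(frozen=True)
class OrtepCode:
    tx: int
    ty: int
    tz: int
    op_index: int

    def __post_init__(self):
        if self.op_index < 1:
            raise PixkitError(f"operation index {self.op_index} must be >= 1")

    @property
    def translation(self) -> tuple[int, int, int]:
        return (self.tx, self.ty, self.tz)

    def encodable(self) -> bool:
        """True when all translations fit the single-digit ORTEP range."""
        return (all(-4 <= t <= 4 for t in self.translation)
                and self.op_index <= 99)

    def encode(self) -> str:
        return encode_ortep(self.translation, self.op_index)

    def __str__(self) -> str:
        if self.encodable():
            return self.encode()
        # shifts beyond +/-4 cells cannot be packed into single digits
        return f"t({self.tx},{self.ty},{self.tz})op{self.op_index}"


def encode_ortep(t, op_index: int) -> str:
    """(translations, op number) -> digit string, e.g. (0,0,0), 1 -> '55501'."""
    tx, ty, tz = (int(v) for v in t)
    for v in (tx, ty, tz):
        if not -4 <= v <= 4:
            raise PixkitError(f"translation {v} outside the ORTEP range [-4, 4]")
    if not 1 <= int(op_index) <= 99:
        raise PixkitError(f"operation index {op_index} outside 1..99")
    return f"{tx + 5}{ty + 5}{tz + 5}{int(op_index):02d}"


def decode_ortep(code: str) -> tuple[tuple[int, int, int], int]:
    """Exact inverse of encode_ortep."""
    s = str(code).strip()
    if not s.isdigit() or len(s) < 5:
        raise PixkitError(f"ORTEP code must be >= 5 digits, got {code!r}")
    t = (int(s[0]) - 5, int(s[1]) - 5, int(s[2]) - 5)
    op_index = int(s[3:])
    if op_index < 1:
        raise PixkitError(f"ORTEP code {code!r} has operation number {op_index}")
    return t, op_index


def ortep_to_standard(code: OrtepCode | str, structure: CrystalStructure) -> str:
    """Translate an ORTEP code into a standard xyz symmetry string."""
    if isinstance(code, str):
        t, k = decode_ortep(code)
        code = OrtepCode(*t, k)
    op = structure.operation(code.op_index)
    return format_symop_xyz(op, extra_translation=code.translation)


@dataclass
class EnergyBreakdown:
    coulomb: float
    polarization: float
    dispersion: float
    repulsion: float
    total: float

    def component_sum(self) -> float:
        return self.coulomb + self.polarization + self.dispersion + self.repulsion


@dataclass
class MolecularPair:
    ref_residue: int
    neighbor_residue: int
    code: OrtepCode
    centroid_distance: float
    multiplicity: int = 1
    energy: EnergyBreakdown | None = None
    match_error: float | None = None

    def __post_init__(self):
        if self.centroid_distance <= 0:
            raise PixkitError("pair centroid distance must be positive")
        if self.multiplicity < 1:
            raise PixkitError("pair multiplicity must be >= 1")
        if self.match_error is not None and self.match_error < 0:
            raise PixkitError("match error must be non-negative")


@dataclass
class PairTable:
    pairs: list[MolecularPair]
    cutoff: float
    structure: CrystalStructure
    molecules: list[Molecule] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.pairs.sort(key=lambda p: (p.centroid_distance, p.ref_residue,
                                       p.neighbor_residue, str(p.code)))

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def _affine_of(op: SymmetryOperation, n) -> tuple[tuple, tuple]:
    """Hashable exact affine map (R, t + n) of an (operation, shift) image."""
    t = tuple(op.translation[i] + int(n[i]) for i in range(3))
    return op.rotation, t


def image_molecule(structure: CrystalStructure, mol: Molecule,
                   op_index: int, n) -> Molecule:
    """Apply (operation, integer cell translation) to a molecule's atoms."""
    op = structure.operation(op_index)
    cellmat = structure.cell.matrix
    inv = structure.cell.inverse_matrix
    shift = np.asarray(n, dtype=float)
    new_atoms = []
    for atom in mol.atoms:
        frac = inv @ atom.pos
        frac2 = op.rot_array @ frac + op.trans_array + shift
        new_atoms.append(replace(atom, cart=tuple(cellmat @ frac2)))
    return Molecule(atoms=new_atoms, bonds=list(mol.bonds), residue_id=mol.residue_id)


def _atom_signature(structure: CrystalStructure, mol: Molecule,
                    op: SymmetryOperation, n) -> tuple:
    inv = structure.cell.inverse_matrix
    shift = np.asarray(n, dtype=float)
    pts = []
    for atom in mol.atoms:
        frac2 = op.rot_array @ (inv @ atom.pos) + op.trans_array + shift
        pts.append((atom.element,) + tuple(np.round(frac2, 5)))
    return tuple(sorted(pts))


def enumerate_pairs(structure: CrystalStructure, molecules: list[Molecule],
                    cutoff: float = 20.0) -> PairTable:
    """Enumerate every symmetry image whose centroid lies within ``cutoff``.

    For each reference residue, each image molecule generated by an
    (operation, cell translation) appears exactly once; coincident images
    (special positions) are kept once under the first generator; the
    self-image (identity, zero shift) is excluded. The per-axis translation
    search bound ceil(cutoff / interplanar spacing) + 1 provably covers all
    images for any cell skew.
    """
    if cutoff <= 0:
        raise PixkitError("cutoff must be positive")
    cellmat = structure.cell.matrix
    inv = structure.cell.inverse_matrix
    cent_cart = [mass_weighted_centroid(m) for m in molecules]
    cent_frac = [inv @ c for c in cent_cart]
    # row norms of the inverse matrix: |delta frac_i| <= ||B_i|| * |delta cart|
    row_norms = np.linalg.norm(inv, axis=1)
    bounds = [int(math.ceil(cutoff * rn)) + 1 for rn in row_norms]

    pairs: list[MolecularPair] = []
    warnings: list[str] = []
    for i, mi in enumerate(molecules):
        seen_affines: set = set()
        seen_sigs: dict[tuple, tuple] = {}
        for op in structure.operations:
            for j, mj in enumerate(molecules):
                base = op.rot_array @ cent_frac[j] + op.trans_array
                n0 = np.rint(cent_frac[i] - base).astype(int)
                ranges = [range(n0[ax] - bounds[ax], n0[ax] + bounds[ax] + 1)
                          for ax in range(3)]
                for n in itertools.product(*ranges):
                    if j == i and op.is_identity() and n == (0, 0, 0):
                        continue
                    img_frac = base + np.asarray(n, dtype=float)
                    d = float(np.linalg.norm(cellmat @ img_frac - cent_cart[i]))
                    if d > cutoff + 1e-9 or d < 1e-6:
                        continue
                    aff = (j,) + _affine_of(op, n)
                    if aff in seen_affines:
                        continue
                    seen_affines.add(aff)
                    # coincident-image dedup (molecules on special positions)
                    key = (j, tuple(np.round(img_frac, 5)))
                    sig = _atom_signature(structure, mj, op, n)
                    if seen_sigs.get(key) == sig:
                        continue
                    seen_sigs[key] = sig
                    pairs.append(MolecularPair(
                        ref_residue=mi.residue_id,
                        neighbor_residue=mj.residue_id,
                        code=OrtepCode(int(n[0]), int(n[1]), int(n[2]), op.index),
                        centroid_distance=d,
                    ))
    if not pairs:
        warnings.append(f"no pairs found within the {cutoff} A cutoff")
    return PairTable(pairs=pairs, cutoff=cutoff, structure=structure,
                     molecules=list(molecules), warnings=warnings)


def inverse_code(code: OrtepCode, structure: CrystalStructure) -> OrtepCode:
    """The code of the inverse affine map g^-1 for g = (R_k, t_k + n)."""
    op = structure.operation(code.op_index)
    rot = np.array(op.rotation, dtype=object)
    rot_inv = np.rint(np.linalg.inv(op.rot_array)).astype(int)
    t = [op.translation[i] + code.translation[i] for i in range(3)]
    t_inv = [-sum(Fraction(int(rot_inv[i][j])) * t[j] for j in range(3))
             for i in range(3)]
    for cand in structure.operations:
        if cand.rotation != tuple(tuple(int(v) for v in row) for row in rot_inv):
            continue
        shift = [t_inv[i] - cand.translation[i] for i in range(3)]
        if all(s.denominator == 1 for s in shift):
            return OrtepCode(int(shift[0]), int(shift[1]), int(shift[2]), cand.index)
    raise PixkitError(
        f"no operation in the structure realizes the inverse of code {code}"
    )


def match_centroids(table: PairTable, external_distances: list[float],
                    tolerance: float = 0.01) -> PairTable:
    """Greedy nearest-distance matching of external centroid distances.

    Each external distance claims the closest unclaimed table row within
    ``tolerance``; matched rows get match_error = |d_table - d_external|.
    Unmatched externals produce the cutoff-increase remedy warning.
    """
    available = list(range(len(table.pairs)))
    for d_ext in sorted(external_distances):
        best, best_err = None, None
        for idx in available:
            err = abs(table.pairs[idx].centroid_distance - d_ext)
            if best_err is None or err < best_err:
                best, best_err = idx, err
        if best is not None and best_err <= tolerance:
            table.pairs[best].match_error = best_err
            available.remove(best)
        else:
            table.warnings.append(f"external distance {d_ext:.3f} A: {REMEDY_MESSAGE}")
    return table


def pair_multiplicities(table: PairTable, distance_tol: float = 1e-4) -> PairTable:
    """Group symmetry-equivalent rows and fill multiplicities.

    Rows with the same unordered residue pair and the same centroid distance
    (within ``distance_tol``; forward/inverse codes are images of one
    another) collapse to a single representative whose multiplicity is the
    group size.
    """
    groups: dict[tuple, list[MolecularPair]] = {}
    for p in table.pairs:
        key = (tuple(sorted((p.ref_residue, p.neighbor_residue))),
               round(p.centroid_distance / distance_tol))
        groups.setdefault(key, []).append(p)
    new_pairs = []
    for key, members in groups.items():
        rep = replace(members[0], multiplicity=len(members))
        new_pairs.append(rep)
    return PairTable(pairs=new_pairs, cutoff=table.cutoff,
                     structure=table.structure, molecules=table.molecules,
                     warnings=list(table.warnings))
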