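"""Indicative structure analysis.

Quick, geometry-only screening of a crystal packing: hydrogen bonds found
inside the van der Waals radii with an exponential energy estimate, van
der Waals contact fractions (atoms within the vdW-radius sum + 1 A of a
partner molecule), 1D chain/stack motif detection in the quotient graph of
molecule images, a driver list of the pairs worth computing properly, and
a half-sum lattice-energy estimate when pair energies are available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import elements
from .cif_io import CrystalStructure
from .errors import MissingEnergyError, PixkitError
from .molecule_builder import Molecule
from .symmetry_pairs import (MolecularPair, OrtepCode, PairTable,
                             image_molecule, pair_multiplicities)

__all__ = [
    "HydrogenBond",
    "HBondModel",
    "ContactRecord",
    "MotifReport",
    "IndicativeReport",
    "detect_hbonds",
    "hbond_energy",
    "contact_fraction",
    "detect_1d_motifs",
    "build_driver_list",
    "lattice_energy_estimate",
    "weak_hbond_warning",
    "run_indicative",
]

HBOND_DONORS = frozenset({"N", "O", "S", "F", "Cl"})
HBOND_ACCEPTORS = frozenset({"N", "O", "S", "F", "Cl"})
HBOND_ANGLE_MIN = 120.0       # degrees, D-H...A
CONTACT_MARGIN = 1.0          # A beyond the vdW-radius sum
STACK_THRESHOLD = 0.30        # min contact fraction for a stack edge
DRIVER_THRESHOLD = 0.20       # min contact fraction to enter the driver list


@dataclass(frozen=True)
class HydrogenBond:
    donor_label: str
    h_label: str
    acceptor_label: str
    donor_residue: int
    acceptor_residue: int
    d_ha: float
    d_da: float
    angle_dha: float
    estimated_energy: float
    code: OrtepCode

    def __post_init__(self):
        if not self.d_ha < self.d_da:
            raise PixkitError("H...A distance must be shorter than D...A")
        if not 0 < self.angle_dha <= 180:
            raise PixkitError("D-H...A angle outside (0, 180]")
        if self.estimated_energy > 0:
            raise PixkitError("H-bond energy estimate must be <= 0")


def _default_hbond_model():
    # anchored at E(1.7 A) = -30 and E(2.2 A) = -10 kJ/mol
    b = math.log(3.0) / 0.5
    a = 30.0 * math.exp(1.7 * b)
    return a, b


@dataclass(frozen=True)
class HBondModel:
    """Exponential distance-energy model E(d) = -A exp(-B d)."""

    A: float = _default_hbond_model()[0]
    B: float = _default_hbond_model()[1]
    weak_threshold: float = 10.0

    def __post_init__(self):
        if self.A <= 0 or self.B <= 0:
            raise PixkitError("HBondModel requires positive A and B")


def hbond_energy(d_ha: float, model: HBondModel | None = None) -> float:
    """Estimated H-bond energy in kJ/mol (negative, decaying to 0 with distance)."""
    if d_ha <= 0:
        raise PixkitError("H...A distance must be positive")
    if model is None:
        model = HBondModel()
    return -model.A * math.exp(-model.B * d_ha)


@dataclass(frozen=True)
class ContactRecord:
    code: OrtepCode
    ref_residue: int
    neighbor_residue: int
    fraction_ref: float
    fraction_neighbor: float
    margin: float

    def __post_init__(self):
        for f in (self.fraction_ref, self.fraction_neighbor):
            if not 0.0 <= f <= 1.0:
                raise PixkitError("contact fraction outside [0, 1]")


@dataclass(frozen=True)
class MotifReport:
    kind: str                       # "hbond-chain" | "vdw-stack"
    direction: tuple[int, int, int]
    period: int
    codes: tuple[str, ...]

    def __post_init__(self):
        if self.direction == (0, 0, 0):
            raise PixkitError("motif direction must be nonzero")


@dataclass
class IndicativeReport:
    hbonds: list[HydrogenBond]
    contacts: list[ContactRecord]
    motifs: list[MotifReport]
    warnings: list[str]
    drivers: list[tuple[str, str]]      # (pair code, reason)
    lattice_energy_estimate: float | None = None


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def _h_donor_map(mol: Molecule) -> list[tuple[int, int]]:
    """(H index, donor heavy index) for every H bonded to a donor element."""
    adj: dict[int, list[int]] = {i: [] for i in range(len(mol.atoms))}
    for i, j in mol.bonds:
        adj[i].append(j)
        adj[j].append(i)
    out = []
    for i, atom in enumerate(mol.atoms):
        if atom.element != "H":
            continue
        heavies = [j for j in adj[i] if mol.atoms[j].element != "H"]
        if len(heavies) == 1 and mol.atoms[heavies[0]].element in HBOND_DONORS:
            out.append((i, heavies[0]))
    return out


def _scan_hbonds(donor_mol: Molecule, acceptor_mol: Molecule,
                 code: OrtepCode, model: HBondModel,
                 vdw_table=None) -> list[HydrogenBond]:
    found = []
    r_h = elements.vdw_radius("H", vdw_table)
    for hi, di in _h_donor_map(donor_mol):
        h = donor_mol.atoms[hi]
        d = donor_mol.atoms[di]
        for aj, acc in enumerate(acceptor_mol.atoms):
            if acc.element not in HBOND_ACCEPTORS:
                continue
            d_ha = float(np.linalg.norm(h.pos - acc.pos))
            if d_ha >= r_h + elements.vdw_radius(acc.element, vdw_table):
                continue
            v1 = d.pos - h.pos
            v2 = acc.pos - h.pos
            cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if angle < HBOND_ANGLE_MIN:
                continue
            d_da = float(np.linalg.norm(d.pos - acc.pos))
            found.append(HydrogenBond(
                donor_label=d.source_site, h_label=h.source_site,
                acceptor_label=acc.source_site,
                donor_residue=donor_mol.residue_id,
                acceptor_residue=acceptor_mol.residue_id,
                d_ha=d_ha, d_da=d_da, angle_dha=angle,
                estimated_energy=hbond_energy(d_ha, model),
                code=code,
            ))
    return found


def detect_hbonds(pairs: PairTable, model: HBondModel | None = None,
                  vdw_table: dict[str, float] | None = None) -> list[HydrogenBond]:
    """Find intermolecular hydrogen bonds across every enumerated pair.

    A bond requires H...A inside the van der Waals radius sum, donor and
    acceptor among N/O/S/F/Cl, and a D-H...A angle of at least 120 degrees.
    Both directions (reference donates / neighbor donates) are scanned and
    tagged with the pair's ORTEP code.
    """
    if model is None:
        model = HBondModel()
    mols = {m.residue_id: m for m in pairs.molecules}
    out: list[HydrogenBond] = []
    for p in pairs:
        ref = mols[p.ref_residue]
        img = image_molecule(pairs.structure, mols[p.neighbor_residue],
                             p.code.op_index, p.code.translation)
        out.extend(_scan_hbonds(ref, img, p.code, model, vdw_table))
        out.extend(_scan_hbonds(img, ref, p.code, model, vdw_table))
    out.sort(key=lambda hb: hb.estimated_energy)
    return out


# ---------------------------------------------------------------------------
# Contact fractions
# ---------------------------------------------------------------------------

def contact_fraction(mol_a: Molecule, mol_b: Molecule, margin: float = CONTACT_MARGIN,
                     vdw_table: dict[str, float] | None = None) -> tuple[float, float]:
    """Fractions of each molecule's atoms in vdW contact (+ margin) with the other."""
    if margin < 0:
        raise PixkitError("contact margin must be >= 0")
    ra = np.array([elements.vdw_radius(e, vdw_table) for e in mol_a.elements])
    rb = np.array([elements.vdw_radius(e, vdw_table) for e in mol_b.elements])
    diff = mol_a.coords[:, None, :] - mol_b.coords[None, :, :]
    gap = np.sqrt((diff ** 2).sum(axis=2)) - ra[:, None] - rb[None, :]
    close = gap < margin
    return (float(close.any(axis=1).mean()), float(close.any(axis=0).mean()))


# ---------------------------------------------------------------------------
# 1D motifs
# ---------------------------------------------------------------------------

def _compose(aff_a, aff_b):
    """(Ra, ta) o (Rb, tb): x -> Ra(Rb x + tb) + ta. Exact rational arithmetic."""
    ra, ta = aff_a
    rb, tb = aff_b
    r = tuple(tuple(sum(ra[i][k] * rb[k][j] for k in range(3)) for j in range(3))
              for i in range(3))
    t = tuple(sum(ra[i][k] * tb[k] for k in range(3)) + ta[i] for i in range(3))
    return r, t


_IDENT_ROT = ((1, 0, 0), (0, 1, 0), (0, 0, 1))


def _primitive(t: tuple[int, int, int]) -> tuple[int, int, int]:
    g = math.gcd(math.gcd(abs(t[0]), abs(t[1])), abs(t[2]))
    v = tuple(x // g for x in t)
    # canonical sign: first nonzero component positive
    for x in v:
        if x != 0:
            return v if x > 0 else tuple(-y for y in v)
    return v


def detect_1d_motifs(pairs: PairTable,
                     hbonds: list[HydrogenBond] | None = None,
                     contacts: list[ContactRecord] | None = None,
                     stack_threshold: float = STACK_THRESHOLD,
                     max_period: int = 6) -> list[MotifReport]:
    """Detect infinite 1D chains/stacks in the molecule-image graph.

    Edges are pairs carrying at least one hydrogen bond (chain motifs) or a
    contact fraction >= ``stack_threshold`` (stack motifs). Starting from a
    reference molecule, qualifying edges are composed as exact affine maps;
    reaching the same residue under a pure nonzero lattice translation t
    proves an infinite 1D motif with direction = primitive(t) and period =
    the number of molecules per translational repeat.
    """
    hb_codes: dict[int, set] = {}
    for hb in hbonds or []:
        key = str(hb.code)
        hb_codes.setdefault(hb.donor_residue, set()).add((hb.acceptor_residue, key))
        hb_codes.setdefault(hb.acceptor_residue, set()).add((hb.donor_residue, key))
    stack_codes: set = set()
    for c in contacts or []:
        if max(c.fraction_ref, c.fraction_neighbor) >= stack_threshold:
            stack_codes.add((c.ref_residue, c.neighbor_residue, str(c.code)))

    edge_sets = {
        "hbond-chain": set(),
        "vdw-stack": set(),
    }
    for p in pairs:
        key = str(p.code)
        if (p.neighbor_residue, key) in hb_codes.get(p.ref_residue, set()):
            edge_sets["hbond-chain"].add((p.ref_residue, p.neighbor_residue, key, p.code))
        if (p.ref_residue, p.neighbor_residue, key) in stack_codes:
            edge_sets["vdw-stack"].add((p.ref_residue, p.neighbor_residue, key, p.code))

    structure = pairs.structure
    reports: list[MotifReport] = []
    seen: set[tuple] = set()
    for kind, edges in edge_sets.items():
        if not edges:
            continue
        by_ref: dict[int, list] = {}
        for ref, nbr, key, code in edges:
            op = structure.operation(code.op_index)
            aff = (op.rotation,
                   tuple(op.translation[i] + code.translation[i] for i in range(3)))
            by_ref.setdefault(ref, []).append((nbr, aff, key))
        residues = sorted({m.residue_id for m in pairs.molecules})
        for start in residues:
            # BFS over images: state = (residue, affine map from start)
            ident = (_IDENT_ROT, (0, 0, 0))
            frontier = [(start, ident, ())]
            visited = {(start, ident)}
            for depth in range(1, max_period + 1):
                next_frontier = []
                for res, aff, path in frontier:
                    for nbr, edge_aff, key in by_ref.get(res, []):
                        new_aff = _compose(aff, edge_aff)
                        new_path = path + (key,)
                        if nbr == start and new_aff[0] == _IDENT_ROT:
                            t = new_aff[1]
                            if all(x == int(x) for x in t) and any(t):
                                tint = tuple(int(x) for x in t)
                                direction = _primitive(tint)
                                sig = (kind, direction)
                                if sig not in seen:
                                    seen.add(sig)
                                    reports.append(MotifReport(
                                        kind=kind, direction=direction,
                                        period=depth,
                                        codes=tuple(sorted(set(new_path))),
                                    ))
                                continue
                        state = (nbr, new_aff)
                        if state not in visited:
                            visited.add(state)
                            next_frontier.append((nbr, new_aff, new_path))
                frontier = next_frontier
    reports.sort(key=lambda r: (r.kind, r.direction))
    return reports


# ---------------------------------------------------------------------------
# Driver list and lattice-energy estimate
# ---------------------------------------------------------------------------

def build_driver_list(hbonds: list[HydrogenBond],
                      contacts: list[ContactRecord],
                      driver_threshold: float = DRIVER_THRESHOLD
                      ) -> list[tuple[str, str]]:
    """Pairs worth an explicit energy calculation, strongest first.

    Union of H-bonded codes and codes whose contact fraction reaches the
    driver threshold; ranked by H-bond energy magnitude, then contact
    fraction.
    """
    scores: dict[str, list] = {}   # code -> [best hbond E, best fraction, reasons]
    for hb in hbonds:
        key = str(hb.code)
        entry = scores.setdefault(key, [0.0, 0.0, set()])
        entry[0] = min(entry[0], hb.estimated_energy)
        entry[2].add("hydrogen bond")
    for c in contacts:
        frac = max(c.fraction_ref, c.fraction_neighbor)
        if frac >= driver_threshold:
            key = str(c.code)
            entry = scores.setdefault(key, [0.0, 0.0, set()])
            entry[1] = max(entry[1], frac)
            entry[2].add("vdW contact")
    ranked = sorted(scores.items(), key=lambda kv: (kv[1][0], -kv[1][1], kv[0]))
    return [(code, " + ".join(sorted(reasons))) for code, (_, _, reasons) in ranked]


def lattice_energy_estimate(pairs: PairTable | list[MolecularPair]) -> float:
    """Half-sum lattice energy: half the multiplicity-weighted pair-energy sum
    per reference molecule, averaged over residues."""
    rows = list(pairs)
    if not rows:
        return 0.0
    for p in rows:
        if p.energy is None:
            raise MissingEnergyError(f"pair {p.code} has no attached energy")
    residues = {p.ref_residue for p in rows} | {p.neighbor_residue for p in rows}
    total = sum(p.multiplicity * p.energy.total for p in rows)
    return 0.5 * total / len(residues)


def weak_hbond_warning(hbonds: list[HydrogenBond],
                       model: HBondModel | None = None) -> list[str]:
    """One warning per detected bond weaker than the model threshold (strict)."""
    if model is None:
        model = HBondModel()
    out = []
    for hb in hbonds:
        if abs(hb.estimated_energy) < model.weak_threshold:
            out.append(
                f"weak hydrogen bond {hb.donor_label}-{hb.h_label}...{hb.acceptor_label} "
                f"({hb.estimated_energy:.1f} kJ/mol, pair {hb.code})"
            )
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_indicative(structure: CrystalStructure, molecules: list[Molecule],
                   cutoff: float = 20.0,
                   model: HBondModel | None = None,
                   vdw_table: dict[str, float] | None = None,
                   margin: float = CONTACT_MARGIN,
                   stack_threshold: float = STACK_THRESHOLD,
                   driver_threshold: float = DRIVER_THRESHOLD,
                   contact_distance: float | None = None) -> IndicativeReport:
    """Full indicative analysis of completed, H-normalized molecules."""
    from .symmetry_pairs import enumerate_pairs

    if model is None:
        model = HBondModel()
    table = enumerate_pairs(structure, molecules, cutoff=cutoff)
    grouped = pair_multiplicities(table)
    hbonds = detect_hbonds(table, model=model, vdw_table=vdw_table)

    mols = {m.residue_id: m for m in molecules}
    # atom-atom contacts only matter for nearby pairs; bound by molecular extents
    max_radius = max(
        (float(np.linalg.norm(m.coords - m.centroid(), axis=1).max()) if len(m) > 1 else 0.0)
        for m in molecules
    )
    limit = contact_distance if contact_distance is not None else (
        2 * max_radius + 6.0)
    contacts: list[ContactRecord] = []
    for p in table:
        if p.centroid_distance > limit:
            continue
        ref = mols[p.ref_residue]
        img = image_molecule(structure, mols[p.neighbor_residue],
                             p.code.op_index, p.code.translation)
        fr, fn = contact_fraction(ref, img, margin=margin, vdw_table=vdw_table)
        if fr > 0 or fn > 0:
            contacts.append(ContactRecord(
                code=p.code, ref_residue=p.ref_residue,
                neighbor_residue=p.neighbor_residue,
                fraction_ref=fr, fraction_neighbor=fn, margin=margin,
            ))
    motifs = detect_1d_motifs(table, hbonds, contacts, stack_threshold=stack_threshold)
    warnings = list(table.warnings) + weak_hbond_warning(hbonds, model)
    drivers = build_driver_list(hbonds, contacts, driver_threshold=driver_threshold)
    if not drivers:
        warnings.append("no qualifying pairs for the driver list")

    estimate = None
    if all(p.energy is not None for p in grouped) and len(grouped) > 0:
        estimate = lattice_energy_estimate(grouped)
    return IndicativeReport(hbonds=hbonds, contacts=contacts, motifs=motifs,
                            warnings=warnings, drivers=drivers,
                            lattice_energy_estimate=estimate)
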