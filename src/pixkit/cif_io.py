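"""CIF reading/writing, symmetry-operation strings, and coordinate frames.

Supports the CSD dialect of CIF 1.1 plus the historical (SHELXL-era) tag
spellings, an exact rational representation of symmetry operations so that
strings such as ``1-x, 1-y, 2-z`` round-trip, and the conventional
Cartesian frame with **a** along x and **b** in the xy-plane.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np

from .elements import normalize_symbol
from .errors import CifParseError, DegenerateCellError, SymopParseError

__all__ = [
    "UnitCell",
    "SymmetryOperation",
    "AtomSite",
    "CrystalStructure",
    "parse_cif",
    "write_cif",
    "parse_symop_xyz",
    "format_symop_xyz",
    "normalize_shelxl_cif",
    "NormalizationResult",
]


# ---------------------------------------------------------------------------
# Unit cell and coordinate frames
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitCell:
    """Lattice parameters: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self):
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise DegenerateCellError(f"cell length {name} must be positive")
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0.0 < v < 180.0:
                raise DegenerateCellError(f"cell angle {name} must lie in (0, 180)")
        ca, cb, cg = (math.cos(math.radians(getattr(self, n)))
                      for n in ("alpha", "beta", "gamma"))
        disc = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if disc <= 0.0:
            raise DegenerateCellError("cell angles give non-positive volume")

    @property
    def matrix(self) -> np.ndarray:
        """Fractional -> Cartesian matrix (columns are a, b, c vectors)."""
        a, b, c = self.a, self.b, self.c
        ca = math.cos(math.radians(self.alpha))
        cb = math.cos(math.radians(self.beta))
        cg = math.cos(math.radians(self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = math.sqrt(1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg)
        return np.array([
            [a, b * cg, c * cb],
            [0.0, b * sg, c * (ca - cb * cg) / sg],
            [0.0, 0.0, c * v / sg],
        ])

    @property
    def inverse_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    @property
    def metric_tensor(self) -> np.ndarray:
        m = self.matrix
        return m.T @ m

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.matrix)))


def frac_to_cart(cell: UnitCell, p) -> np.ndarray:
    """Fractional coordinates -> Cartesian Angstrom (a along x, b in xy)."""
    return cell.matrix @ np.asarray(p, dtype=float)


def cart_to_frac(cell: UnitCell, r) -> np.ndarray:
    return cell.inverse_matrix @ np.asarray(r, dtype=float)


# ---------------------------------------------------------------------------
# Symmetry operations
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(
    r"\s*([+-]?)\s*(?:"
    r"(\d+(?:\.\d+)?)(?:\s*/\s*(\d+))?\s*\*?\s*([xyzXYZ])?"
    r"|([xyzXYZ])"
    r")"
)


def _parse_component(comp: str, source: str) -> tuple[list[int], Fraction]:
    """Parse one affine expression like '1/2-x' into (coefficients, constant)."""
    coeffs = [0, 0, 0]
    const = Fraction(0)
    pos = 0
    comp = comp.strip()
    if not comp:
        raise SymopParseError("empty component", item=source)
    while pos < len(comp):
        m = _TERM_RE.match(comp, pos)
        if m is None or m.end() == pos:
            raise SymopParseError(
                f"cannot parse symmetry expression {source!r}", item=source, position=pos
            )
        sign = -1 if m.group(1) == "-" else 1
        number, denom, var_after_num, bare_var = m.group(2), m.group(3), m.group(4), m.group(5)
        if bare_var is not None:
            coeffs["xyz".index(bare_var.lower())] += sign
        elif number is not None:
            if denom is not None:
                value = Fraction(int(number), int(denom))
            elif "." in number:
                value = Fraction(number).limit_denominator(48)
            else:
                value = Fraction(int(number))
            if var_after_num is not None:
                coef = value
                if coef.denominator != 1:
                    raise SymopParseError(
                        f"non-integer variable coefficient in {source!r}", item=source
                    )
                coeffs["xyz".index(var_after_num.lower())] += sign * int(coef)
            else:
                const += sign * value
        else:
            raise SymopParseError(f"cannot parse {source!r}", item=source, position=pos)
        pos = m.end()
    return coeffs, const


@dataclass(frozen=True)
class SymmetryOperation:
    """An affine symmetry operation x' = R x + t in fractional coordinates.

    ``translation`` is reduced to [0, 1); ``raw_shift`` preserves the integer
    parts as written (so ``1-x, 1-y, 2-z`` formats back identically).
    """

    rotation: tuple[tuple[int, int, int], ...]
    translation: tuple[Fraction, Fraction, Fraction]
    index: int = 1
    raw_shift: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self):
        det = round(np.linalg.det(np.array(self.rotation, dtype=float)))
        if det not in (-1, 1):
            raise SymopParseError(f"rotation determinant {det}, expected +/-1")
        if any(not (0 <= t < 1) for t in self.translation):
            raise SymopParseError("translation not reduced to [0, 1)")
        if self.index < 1:
            raise SymopParseError("operation index must be >= 1")

    @property
    def rot_array(self) -> np.ndarray:
        return np.array(self.rotation, dtype=float)

    @property
    def trans_array(self) -> np.ndarray:
        return np.array([float(t) for t in self.translation])

    def apply(self, frac) -> np.ndarray:
        return self.rot_array @ np.asarray(frac, dtype=float) + self.trans_array

    def is_identity(self) -> bool:
        return (self.rotation == ((1, 0, 0), (0, 1, 0), (0, 0, 1))
                and all(t == 0 for t in self.translation))

    def xyz(self, extra_translation=(0, 0, 0)) -> str:
        return format_symop_xyz(self, extra_translation)


def parse_symop_xyz(s: str, index: int = 1) -> SymmetryOperation:
    """Parse an xyz triplet like ``'1/2+x, 1/2-y, z'`` into a SymmetryOperation."""
    parts = s.split(",")
    if len(parts) != 3:
        raise SymopParseError(f"expected 3 comma-separated components in {s!r}", item=s)
    rows = []
    trans = []
    shifts = []
    for comp in parts:
        coeffs, const = _parse_component(comp, s)
        shift = const.numerator // const.denominator  # floor
        reduced = const - shift
        rows.append(tuple(coeffs))
        trans.append(reduced)
        shifts.append(int(shift))
    return SymmetryOperation(
        rotation=tuple(rows), translation=tuple(trans),
        index=index, raw_shift=tuple(shifts),
    )


def _fmt_fraction(f: Fraction) -> str:
    if f.denominator == 1:
        return str(f.numerator)
    return f"{f.numerator}/{f.denominator}"


def format_symop_xyz(op: SymmetryOperation, extra_translation=(0, 0, 0)) -> str:
    """Format an operation back to an xyz string, adding unit-cell shifts.

    The operation's own ``raw_shift`` (integer parts as originally written)
    is combined with ``extra_translation`` so parsed strings round-trip and
    ORTEP cell shifts can be folded in.
    """
    comps = []
    for i in range(3):
        const = op.translation[i] + op.raw_shift[i] + int(extra_translation[i])
        terms = ""
        for j, var in enumerate("xyz"):
            c = op.rotation[i][j]
            if c == 0:
                continue
            sign = "-" if c < 0 else "+"
            body = var if abs(c) == 1 else f"{abs(c)}{var}"
            terms += sign + body
        if const == 0:
            comp = terms.lstrip("+") if terms else "0"
        else:
            comp = _fmt_fraction(const) + terms
        comps.append(comp)
    return ", ".join(comps)


# ---------------------------------------------------------------------------
# CIF document model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomSite:
    label: str
    element: str
    frac: tuple[float, float, float]
    occupancy: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.occupancy <= 1.0:
            raise CifParseError(
                f"occupancy {self.occupancy} outside (0, 1]", item=self.label
            )


@dataclass
class CrystalStructure:
    cell: UnitCell
    operations: list[SymmetryOperation]
    sites: list[AtomSite]
    space_group_name: str = "?"
    z_prime_hint: int | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.operations:
            raise CifParseError("structure has no symmetry operations")
        indices = [op.index for op in self.operations]
        if indices != list(range(1, len(indices) + 1)):
            raise CifParseError("operation indices are not 1..N in order")
        if not any(op.is_identity() for op in self.operations):
            raise CifParseError("operation list lacks the identity")
        labels = [s.label for s in self.sites]
        if len(labels) != len(set(labels)):
            raise CifParseError("duplicate atom-site labels")

    @property
    def identity_index(self) -> int:
        for op in self.operations:
            if op.is_identity():
                return op.index
        raise CifParseError("no identity operation")  # unreachable

    def operation(self, index: int) -> SymmetryOperation:
        if not 1 <= index <= len(self.operations):
            raise CifParseError(
                f"operation index {index} out of range 1..{len(self.operations)}; "
                "note the operation numbering follows this file's loop order and "
                "may not match numbering used elsewhere"
            )
        return self.operations[index - 1]

    def has_disorder(self) -> bool:
        return any(s.occupancy < 1.0 for s in self.sites)


# ---------------------------------------------------------------------------
# CIF tokenizer / parser
# ---------------------------------------------------------------------------

def _tokenize_cif(text: str):
    """Yield CIF tokens: (value, is_tag). Handles quotes, semicolon blocks, comments."""
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith(";"):
            block = [line[1:]]
            i += 1
            while i < len(lines) and not lines[i].startswith(";"):
                block.append(lines[i])
                i += 1
            if i >= len(lines):
                raise CifParseError("unterminated semicolon text block", position=i)
            yield "\n".join(block), False
            i += 1
            continue
        pos = 0
        n = len(line)
        while pos < n:
            ch = line[pos]
            if ch in " \t":
                pos += 1
                continue
            if ch == "#":
                break
            if ch in "'\"":
                end = pos + 1
                while end < n:
                    if line[end] == ch and (end + 1 == n or line[end + 1] in " \t"):
                        break
                    end += 1
                if end >= n:
                    raise CifParseError("unterminated quoted string", position=i + 1)
                yield line[pos + 1:end], False
                pos = end + 1
                continue
            end = pos
            while end < n and line[end] not in " \t":
                end += 1
            tok = line[pos:end]
            yield tok, tok.startswith("_") or tok.lower() in (
                "loop_",) or tok.lower().startswith(("data_", "save_", "global_", "stop_"))
            pos = end
        i += 1


_NUMERIC_SU_RE = re.compile(r"^([+-]?\d*\.?\d+(?:[eE][+-]?\d+)?)(\(\d+\))?$")


def _cif_number(value: str, item: str) -> float:
    m = _NUMERIC_SU_RE.match(value)
    if m is None:
        raise CifParseError(f"expected a number, got {value!r}", item=item)
    return float(m.group(1))


_CELL_TAGS = {
    "_cell_length_a": "a", "_cell_length_b": "b", "_cell_length_c": "c",
    "_cell_angle_alpha": "alpha", "_cell_angle_beta": "beta",
    "_cell_angle_gamma": "gamma",
}

_SYMOP_TAGS = ("_space_group_symop_operation_xyz", "_symmetry_equiv_pos_as_xyz")
_SG_NAME_TAGS = ("_space_group_name_h-m_alt", "_symmetry_space_group_name_h-m",
                 "_space_group_name_h-m")


def _parse_document(text: str):
    """First pass: a flat dict of scalar items and a list of loops."""
    scalars: dict[str, str] = {}
    loops: list[tuple[list[str], list[str]]] = []
    tokens = list(_tokenize_cif(text))
    i = 0
    n = len(tokens)
    while i < n:
        value, is_tag = tokens[i]
        low = value.lower()
        if is_tag and low == "loop_":
            i += 1
            headers = []
            while i < n and tokens[i][1] and tokens[i][0].startswith("_"):
                headers.append(tokens[i][0].lower())
                i += 1
            body = []
            while i < n and not tokens[i][1]:
                body.append(tokens[i][0])
                i += 1
            if headers:
                loops.append((headers, body))
        elif is_tag and low.startswith(("data_", "global_")):
            i += 1
        elif is_tag and value.startswith("_"):
            if i + 1 < n and not tokens[i + 1][1]:
                scalars[low] = tokens[i + 1][0]
                i += 2
            else:
                scalars[low] = ""
                i += 1
        else:
            i += 1
    return scalars, loops


def parse_cif(text: str) -> CrystalStructure:
    """Parse a CSD-style (or SHELXL-style) CIF into a CrystalStructure.

    Symmetry operations are taken verbatim in file order with 1-based
    indices; fractional coordinates are not modified.
    """
    scalars, loops = _parse_document(text)
    warnings: list[str] = []

    cell_vals = {}
    for tag, name in _CELL_TAGS.items():
        if tag not in scalars:
            raise CifParseError("missing cell parameter", item=tag)
        cell_vals[name] = _cif_number(scalars[tag], tag)
    cell = UnitCell(**cell_vals)

    # symmetry operations
    operations: list[SymmetryOperation] = []
    used_tag = None
    for headers, body in loops:
        for tag in _SYMOP_TAGS:
            if tag in headers:
                used_tag = tag
                ncol = len(headers)
                col = headers.index(tag)
                rows = [body[k:k + ncol] for k in range(0, len(body), ncol)]
                for row in rows:
                    if len(row) == ncol:
                        operations.append(
                            parse_symop_xyz(row[col], index=len(operations) + 1))
                break
        if used_tag:
            break
    if not operations:
        raise CifParseError(
            "missing symmetry loop",
            item="_space_group_symop_operation_xyz / _symmetry_equiv_pos_as_xyz",
        )
    if used_tag == "_symmetry_equiv_pos_as_xyz":
        warnings.append("historical symmetry loop tag _symmetry_equiv_pos_as_xyz")

    sg_name = "?"
    for tag in _SG_NAME_TAGS:
        if tag in scalars and scalars[tag] not in ("", ".", "?"):
            sg_name = scalars[tag]
            break
    if sg_name == "?":
        warnings.append("space-group name missing; identified by operator list only")

    # atom sites
    sites: list[AtomSite] = []
    for headers, body in loops:
        if "_atom_site_fract_x" not in headers:
            continue
        ncol = len(headers)
        need = ["_atom_site_fract_x", "_atom_site_fract_y", "_atom_site_fract_z"]
        for tag in need:
            if tag not in headers:
                raise CifParseError("incomplete atom-site loop", item=tag)
        ix, iy, iz = (headers.index(t) for t in need)
        ilabel = headers.index("_atom_site_label") if "_atom_site_label" in headers else None
        itype = headers.index("_atom_site_type_symbol") if "_atom_site_type_symbol" in headers else None
        iocc = headers.index("_atom_site_occupancy") if "_atom_site_occupancy" in headers else None
        rows = [body[k:k + ncol] for k in range(0, len(body), ncol)]
        for row in rows:
            if len(row) != ncol:
                raise CifParseError("ragged atom-site loop", item=" ".join(row))
            label = row[ilabel] if ilabel is not None else f"X{len(sites) + 1}"
            type_raw = row[itype] if itype is not None else label
            element = normalize_symbol(type_raw)
            frac = tuple(_cif_number(row[k], f"fract of {label}") for k in (ix, iy, iz))
            occ = 1.0
            if iocc is not None and row[iocc] not in (".", "?"):
                occ = _cif_number(row[iocc], f"occupancy of {label}")
            sites.append(AtomSite(label=label, element=element, frac=frac, occupancy=occ))
        break
    if not sites:
        raise CifParseError("missing atom-site loop", item="_atom_site_fract_x")
    for s in sites:
        if s.occupancy < 1.0:
            warnings.append(f"site {s.label} has occupancy {s.occupancy} (disorder)")

    return CrystalStructure(cell=cell, operations=operations, sites=sites,
                            space_group_name=sg_name, warnings=warnings)


# ---------------------------------------------------------------------------
# CIF writing and SHELXL normalization
# ---------------------------------------------------------------------------

def _quote(value: str) -> str:
    if value == "" or any(ch in value for ch in " \t'\""):
        return f"'{value}'" if "'" not in value else f'"{value}"'
    return value


def write_cif(structure: CrystalStructure, data_name: str = "pixkit") -> str:
    """Emit a CSD-style CIF (current symmetry tag spellings)."""
    cell = structure.cell
    out = [f"data_{data_name}"]
    if structure.space_group_name not in ("", "?"):
        out.append(f"_space_group_name_H-M_alt {_quote(structure.space_group_name)}")
    out += [
        f"_cell_length_a {cell.a:.6f}",
        f"_cell_length_b {cell.b:.6f}",
        f"_cell_length_c {cell.c:.6f}",
        f"_cell_angle_alpha {cell.alpha:.6f}",
        f"_cell_angle_beta {cell.beta:.6f}",
        f"_cell_angle_gamma {cell.gamma:.6f}",
        "loop_",
        "_space_group_symop_id",
        "_space_group_symop_operation_xyz",
    ]
    for op in structure.operations:
        out.append(f"{op.index} {_quote(op.xyz())}")
    out += [
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
        "_atom_site_occupancy",
    ]
    for s in structure.sites:
        out.append(
            f"{s.label} {s.element} {s.frac[0]:.9f} {s.frac[1]:.9f} "
            f"{s.frac[2]:.9f} {s.occupancy:.4f}"
        )
    return "\n".join(out) + "\n"


@dataclass
class NormalizationResult:
    text: str
    warnings: list[str]


def normalize_shelxl_cif(text: str) -> NormalizationResult:
    """Rewrite a SHELXL-dialect CIF into CSD form.

    Handles the historical symmetry-loop tag, missing space-group name
    (recovered as '?' with a warning, since only the operator list is
    trusted), and atom-type annotations with charges. Idempotent: output
    re-normalizes to itself.
    """
    structure = parse_cif(text)
    warnings = list(structure.warnings)
    if structure.space_group_name in ("", "?"):
        # keep '?'; downstream code never trusts the name anyway
        pass
    out = write_cif(structure)
    return NormalizationResult(text=out, warnings=warnings)
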