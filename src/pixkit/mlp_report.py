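"""Interaction-energy tables: parsing, ORTEP annotation, and CSV output.

Parses whitespace-delimited per-pair energy tables (the .MLP dialect:
centroid distance, Coulombic, polarization, dispersion, repulsion, total,
optional trailing symmetry text) plus a labeled total-lattice-energy line,
matches rows to an enumerated PairTable by centroid distance, and writes a
spreadsheet-friendly CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import TableParseError
from .symmetry_pairs import (EnergyBreakdown, OrtepCode, PairTable,
                             REMEDY_MESSAGE, ortep_to_standard,
                             pair_multiplicities)

__all__ = [
    "MlpDialect",
    "InteractionRow",
    "AnnotatedTable",
    "parse_energy_table",
    "annotate",
    "verify_toto",
    "write_csv",
    "parse_csv",
]

COMPONENT_CLOSURE_TOL = 0.15   # kJ/mol; printed tables round to 0.1


@dataclass(frozen=True)
class MlpDialect:
    """Column layout and labels of a whitespace energy table."""

    columns: tuple[str, ...] = ("distance", "coulomb", "polarization",
                                "dispersion", "repulsion", "total")
    toto_label: str = "toto"
    comment_prefixes: tuple[str, ...] = ("#", "!")


@dataclass
class InteractionRow:
    centroid_distance: float
    energy: EnergyBreakdown
    symop_text: str | None = None
    code: OrtepCode | None = None
    standard_symop: str | None = None
    match_error: float | None = None
    multiplicity: int | None = None

    def __post_init__(self):
        if self.centroid_distance <= 0:
            raise TableParseError("row centroid distance must be positive")


@dataclass
class AnnotatedTable:
    rows: list[InteractionRow]
    toto: float | None = None
    provenance: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.rows.sort(key=lambda r: r.centroid_distance)


def parse_energy_table(text: str, dialect: MlpDialect | None = None
                       ) -> AnnotatedTable:
    """Parse a PixelC-style energy table. Bad rows are reported, not fatal."""
    if dialect is None:
        dialect = MlpDialect()
    ncol = len(dialect.columns)
    rows: list[InteractionRow] = []
    toto = None
    warnings: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip().replace("−", "-")  # unicode minus
        if not stripped or stripped.startswith(dialect.comment_prefixes):
            continue
        tokens = stripped.split()
        if tokens[0].lower() == dialect.toto_label.lower():
            try:
                toto = float(tokens[1])
            except (IndexError, ValueError):
                warnings.append(f"line {lineno}: unreadable {dialect.toto_label} value")
            continue
        numbers = []
        for tok in tokens:
            try:
                numbers.append(float(tok))
            except ValueError:
                break
        if len(numbers) < ncol:
            if numbers:  # looked numeric but too short -> report
                warnings.append(f"line {lineno}: malformed row ({len(numbers)} of "
                                f"{ncol} numeric columns)")
            continue
        vals = dict(zip(dialect.columns, numbers))
        trailing = tokens[len(numbers):]
        symop_text = " ".join(trailing).strip() or None
        energy = EnergyBreakdown(
            coulomb=vals.get("coulomb", 0.0),
            polarization=vals.get("polarization", 0.0),
            dispersion=vals.get("dispersion", 0.0),
            repulsion=vals.get("repulsion", 0.0),
            total=vals.get("total", 0.0),
        )
        if abs(energy.total - energy.component_sum()) > COMPONENT_CLOSURE_TOL:
            warnings.append(
                f"line {lineno}: total {energy.total} differs from component sum "
                f"{energy.component_sum():.2f} by more than {COMPONENT_CLOSURE_TOL}")
        try:
            rows.append(InteractionRow(centroid_distance=vals["distance"],
                                       energy=energy, symop_text=symop_text))
        except TableParseError as exc:
            warnings.append(f"line {lineno}: {exc}")
    if not rows:
        raise TableParseError("no numeric interaction rows found")
    if toto is None:
        warnings.append(f"no '{MlpDialect().toto_label}' total-energy line found")
    return AnnotatedTable(rows=rows, toto=toto, warnings=warnings)


def annotate(table: AnnotatedTable, pairs: PairTable,
             tolerance: float = 0.01) -> AnnotatedTable:
    """Fill ORTEP codes on rows by nearest-centroid-distance matching.

    The grouped pair table supplies code, standard symop string,
    multiplicity, and the match residual; matched energies are copied back
    onto the pairs so downstream sums can use them.
    """
    grouped = pair_multiplicities(pairs)
    available = list(range(len(grouped.pairs)))
    for row in sorted(table.rows, key=lambda r: r.centroid_distance):
        best, best_err = None, None
        for idx in available:
            err = abs(grouped.pairs[idx].centroid_distance - row.centroid_distance)
            if best_err is None or err < best_err:
                best, best_err = idx, err
        if best is not None and best_err <= tolerance:
            pair = grouped.pairs[best]
            row.code = pair.code
            row.standard_symop = ortep_to_standard(pair.code, pairs.structure)
            row.match_error = best_err
            row.multiplicity = pair.multiplicity
            pair.energy = row.energy
            available.remove(best)
        else:
            table.warnings.append(
                f"row at {row.centroid_distance:.3f} A: {REMEDY_MESSAGE}")
    # propagate energies to the ungrouped pairs as well
    for row in table.rows:
        if row.code is None:
            continue
        grp = next(g for g in grouped.pairs if g.code == row.code)
        gres = tuple(sorted((grp.ref_residue, grp.neighbor_residue)))
        for p in pairs.pairs:
            if (tuple(sorted((p.ref_residue, p.neighbor_residue))) == gres
                    and abs(p.centroid_distance - grp.centroid_distance) < 2e-4):
                p.energy = row.energy
    table.rows.sort(key=lambda r: r.centroid_distance)
    return table


@dataclass
class TotoReport:
    toto: float | None
    recomputed: float
    difference: float | None
    n_rows_used: int


def verify_toto(table: AnnotatedTable, n_residues: int = 1) -> TotoReport:
    """Recompute the half-sum lattice energy from matched rows and compare."""
    used = [r for r in table.rows if r.multiplicity is not None]
    recomputed = 0.5 * sum(r.multiplicity * r.energy.total for r in used) / max(1, n_residues)
    diff = None if table.toto is None else table.toto - recomputed
    return TotoReport(toto=table.toto, recomputed=recomputed,
                      difference=diff, n_rows_used=len(used))


CSV_HEADER = ("distance_A,coulomb_kJmol,polarization_kJmol,dispersion_kJmol,"
              "repulsion_kJmol,total_kJmol,multiplicity,code,standard_symop,"
              "match_error_A")


def write_csv(table: AnnotatedTable) -> str:
    """Spreadsheet-compatible CSV: fixed decimals, no padding."""
    lines = [CSV_HEADER]
    for r in table.rows:
        e = r.energy
        lines.append(",".join([
            f"{r.centroid_distance:.3f}",
            f"{e.coulomb:.4f}", f"{e.polarization:.4f}", f"{e.dispersion:.4f}",
            f"{e.repulsion:.4f}", f"{e.total:.4f}",
            "" if r.multiplicity is None else str(r.multiplicity),
            "" if r.code is None else str(r.code),
            "" if r.standard_symop is None else f'"{r.standard_symop}"',
            "" if r.match_error is None else f"{r.match_error:.6f}",
        ]))
    if table.toto is not None:
        lines.append(f"# toto,{table.toto:.4f}")
    return "\n".join(lines) + "\n"


def parse_csv(text: str) -> AnnotatedTable:
    """Read back a CSV written by write_csv (used for round-trip checks)."""
    import csv as _csv
    import io as _io

    rows: list[InteractionRow] = []
    toto = None
    reader = _csv.reader(_io.StringIO(text))
    header = next(reader)
    if header[0] != "distance_A":
        raise TableParseError("unrecognized CSV header")
    for rec in reader:
        if not rec:
            continue
        if rec[0].startswith("#"):
            if "toto" in rec[0]:
                toto = float(rec[1])
            continue
        energy = EnergyBreakdown(coulomb=float(rec[1]), polarization=float(rec[2]),
                                 dispersion=float(rec[3]), repulsion=float(rec[4]),
                                 total=float(rec[5]))
        code = None
        if rec[7]:
            from .symmetry_pairs import decode_ortep
            t, k = decode_ortep(rec[7])
            code = OrtepCode(*t, k)
        rows.append(InteractionRow(
            centroid_distance=float(rec[0]), energy=energy,
            code=code,
            standard_symop=rec[8] or None,
            match_error=float(rec[9]) if rec[9] else None,
            multiplicity=int(rec[6]) if rec[6] else None,
        ))
    return AnnotatedTable(rows=rows, toto=toto)
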