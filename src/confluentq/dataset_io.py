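"""Reading, writing, and sanity-checking tables of net atomic charges (NACs).

A NAC table holds one row per atom-in-molecule and one column per
charge-assignment method, together with the integer net charge of every
molecule.  Because each molecule's charges must sum to that integer, running
sums over blocks of whole molecules provide a cheap cross-method consistency
check that localizes missing or erroneously reported values.  Physical
bounds (an atom cannot hold a negative number of electrons, and its spin
moment cannot exceed its electron count) provide a second, per-cell check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._elements import atomic_number
from .errors import FormatError, ValidationError

#: Columns every NAC table file must provide, in this order, before the
#: method columns.
REQUIRED_COLUMNS = ("molecule_id", "atom_index", "element", "net_charge")

#: Default block-sum tolerances in elementary charge units.  Residuals at or
#: below the negligible level are attributed to numerical integration noise;
#: residuals above the fatal level indicate a wrong or missing value.
DEFAULT_TOL_NEGLIGIBLE = 0.01
DEFAULT_TOL_FATAL = 0.05


@dataclass
class NACTable:
    """Atoms-by-methods matrix of net atomic charges with molecule grouping.

    Attributes
    ----------
    atoms:
        One row per atom with columns ``molecule_id`` (str), ``atom_index``
        (int, 0-based within its molecule), and ``element`` (symbol).
    values:
        Float matrix aligned row-wise with ``atoms``; one column per method,
        in elementary charge units.  Missing entries are NaN.
    net_charges:
        Integer net charge (e) of every molecule appearing in ``atoms``.
    """

    atoms: pd.DataFrame
    values: pd.DataFrame
    net_charges: dict[str, int]

    def __post_init__(self) -> None:
        if len(self.atoms) != len(self.values):
            raise ValidationError("atoms and values row counts differ")
        missing = set(self.atoms["molecule_id"]) - set(self.net_charges)
        if missing:
            raise ValidationError(f"molecules without net charge: {sorted(missing)}")
        self.atoms = self.atoms.reset_index(drop=True)
        self.values = self.values.reset_index(drop=True).astype(float)

    @property
    def method_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_atoms(self) -> int:
        return len(self.values)

    @property
    def n_methods(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def molecule_ids(self) -> list[str]:
        """Molecule ids in first-appearance (file) order."""
        return list(dict.fromkeys(self.atoms["molecule_id"]))

    def molecule_sizes(self) -> dict[str, int]:
        return self.atoms["molecule_id"].value_counts(sort=False).to_dict()

    def subset_methods(self, keep: Sequence[str]) -> "NACTable":
        unknown = [m for m in keep if m not in self.values.columns]
        if unknown:
            raise ValidationError(f"unknown methods: {unknown}")
        return NACTable(self.atoms.copy(), self.values[list(keep)].copy(),
                        dict(self.net_charges))

    def drop_molecules(self, molecule_ids: Iterable[str]) -> "NACTable":
        drop = set(molecule_ids)
        keep = ~self.atoms["molecule_id"].isin(drop)
        charges = {m: q for m, q in self.net_charges.items() if m not in drop}
        return NACTable(self.atoms[keep].copy(), self.values[keep].copy(), charges)

    def copy(self) -> "NACTable":
        return NACTable(self.atoms.copy(), self.values.copy(), dict(self.net_charges))


@dataclass
class Flag:
    block_id: int
    method: str
    residual: float
    severity: str  # "suspect" | "fatal"


@dataclass
class ConsistencyReport:
    """Outcome of the block running-sum consistency procedure."""

    block_definitions: list[tuple[int, list[str]]]
    residuals: pd.DataFrame  # blocks x methods, |sum - nearest integer|
    flags: list[Flag]
    missing_entries: list[tuple[str, int, str]]

    @property
    def clean(self) -> bool:
        return not self.flags and not self.missing_entries

    def to_dict(self) -> dict:
        return {
            "blocks": [
                {"block_id": b, "molecule_ids": mols}
                for b, mols in self.block_definitions
            ],
            "flags": [
                {"block_id": f.block_id, "method": f.method,
                 "residual": f.residual, "severity": f.severity}
                for f in self.flags
            ],
            "missing_entries": [
                {"molecule_id": m, "atom_index": i, "method": meth}
                for m, i, meth in self.missing_entries
            ],
        }


@dataclass
class BoundsReport:
    """Per-cell physical-bounds violations (NAC vs Z, NAC vs spin moment)."""

    violations: list[tuple[str, int, str, str, str]] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.violations

    def to_dict(self) -> dict:
        return {
            "violations": [
                {"molecule_id": m, "atom_index": i, "method": meth,
                 "rule": rule, "detail": detail}
                for m, i, meth, rule, detail in self.violations
            ]
        }


def load_corrections(path: str | Path) -> list[dict]:
    """Load a declarative corrections file (YAML or JSON list of actions)."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if not isinstance(data, list):
        raise FormatError("corrections file must contain a list of actions")
    return data


def apply_corrections(table: NACTable, corrections: Sequence[Mapping]) -> NACTable:
    """Apply ``set_value`` / ``drop_molecule`` actions to a table copy.

    Corrections are explicit and auditable: the input table is never edited
    in place and unknown targets raise instead of silently doing nothing.
    """
    out = table.copy()
    for corr in corrections:
        action = corr.get("action")
        mol = corr.get("molecule_id")
        if action == "drop_molecule":
            if mol not in out.net_charges:
                raise ValidationError(f"drop_molecule: unknown molecule {mol!r}")
            out = out.drop_molecules([mol])
        elif action == "set_value":
            method = corr.get("method")
            idx = corr.get("atom_index")
            if method not in out.values.columns:
                raise ValidationError(f"set_value: unknown method {method!r}")
            mask = (out.atoms["molecule_id"] == mol) & (out.atoms["atom_index"] == idx)
            if not mask.any():
                raise ValidationError(f"set_value: no atom ({mol!r}, {idx})")
            out.values.loc[mask, method] = float(corr["value"])
        else:
            raise ValidationError(f"unknown correction action: {action!r}")
    return out


def read_nac_table(
    path: str | Path,
    *,
    one_based_indices: bool = False,
    corrections: Sequence[Mapping] | str | Path | None = None,
) -> NACTable:
    """Read a NAC table from CSV.

    Expected header: ``molecule_id,atom_index,element,net_charge,<method>...``
    Empty method cells become missing entries (recorded in the table's
    missing mask, never imputed).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"molecule_id": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    method_names = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    if not method_names:
        raise FormatError(f"no method columns found in {path}")

    charges = df["net_charge"].to_numpy()
    if not np.all(np.equal(np.mod(charges, 1), 0)):
        bad = df.loc[np.mod(charges, 1) != 0, "molecule_id"].unique()
        raise ValidationError(f"non-integer net_charge for molecules {list(bad)}")
    net_charges: dict[str, int] = {}
    for mol, grp in df.groupby("molecule_id", sort=False):
        qs = set(int(q) for q in grp["net_charge"])
        if len(qs) > 1:
            raise ValidationError(f"inconsistent net_charge within molecule {mol!r}")
        net_charges[mol] = qs.pop()

    atom_index = df["atom_index"].astype(int) - (1 if one_based_indices else 0)
    atoms = pd.DataFrame({
        "molecule_id": df["molecule_id"],
        "atom_index": atom_index,
        "element": df["element"].astype(str),
    })
    if atoms.duplicated(["molecule_id", "atom_index"]).any():
        dup = atoms[atoms.duplicated(["molecule_id", "atom_index"])].iloc[0]
        raise ValidationError(
            f"duplicate atom ({dup['molecule_id']!r}, {int(dup['atom_index'])})")

    table = NACTable(atoms, df[method_names].astype(float), net_charges)
    if corrections is not None:
        if isinstance(corrections, (str, Path)):
            corrections = load_corrections(corrections)
        table = apply_corrections(table, corrections)
    return table


def write_nac_table(table: NACTable, path: str | Path,
                    *, one_based_indices: bool = False) -> None:
    """Write a NAC table as CSV (inverse of :func:`read_nac_table`)."""
    df = table.atoms.copy()
    df["atom_index"] = df["atom_index"] + (1 if one_based_indices else 0)
    df["net_charge"] = df["molecule_id"].map(table.net_charges)
    df = df[["molecule_id", "atom_index", "element", "net_charge"]]
    out = pd.concat([df, table.values], axis=1)
    out.to_csv(path, index=False)


def partition_blocks(table: NACTable, target_size: int = 500
                     ) -> list[tuple[int, list[str]]]:
    """Greedily pack whole molecules into contiguous blocks of ~target_size atoms.

    Molecules are never split across blocks; a block closes as soon as it
    reaches ``target_size`` atoms, so every block except possibly the last
    holds at least ``target_size`` atoms.
    """
    if target_size < 1:
        raise ValidationError("target_size must be >= 1")
    sizes = table.molecule_sizes()
    blocks: list[tuple[int, list[str]]] = []
    current: list[str] = []
    count = 0
    for mol in table.molecule_ids:
        current.append(mol)
        count += sizes[mol]
        if count >= target_size:
            blocks.append((len(blocks), current))
            current, count = [], 0
    if current:
        blocks.append((len(blocks), current))
    return blocks


def check_block_sums(
    table: NACTable,
    tol_negligible: float = DEFAULT_TOL_NEGLIGIBLE,
    tol_fatal: float = DEFAULT_TOL_FATAL,
    *,
    target_size: int = 500,
    blocks: list[tuple[int, list[str]]] | None = None,
) -> ConsistencyReport:
    """Run the integer running-sum consistency check per block and method.

    For each (block, method) pair the sum of NACs should land on an integer
    — specifically on the summed net charge of the block's molecules.  The
    distance to the nearest integer is graded against the two tolerances;
    landing on the *wrong* integer is always fatal.  Missing cells are
    reported separately and excluded from the sums.
    """
    if not tol_negligible < tol_fatal:
        raise ValidationError("require tol_negligible < tol_fatal")
    if blocks is None:
        blocks = partition_blocks(table, target_size)

    mol_of_row = table.atoms["molecule_id"].to_numpy()
    flags: list[Flag] = []
    missing_entries: list[tuple[str, int, str]] = []
    residual_rows = []

    mask = table.missing_mask
    if mask.to_numpy().any():
        where = np.argwhere(mask.to_numpy())
        for r, c in where:
            missing_entries.append((
                str(table.atoms.iloc[r]["molecule_id"]),
                int(table.atoms.iloc[r]["atom_index"]),
                table.method_names[c],
            ))

    for block_id, mols in blocks:
        in_block = np.isin(mol_of_row, mols)
        expected = sum(table.net_charges[m] for m in mols)
        sums = table.values[in_block].sum(axis=0, skipna=True)
        row = {}
        for method in table.method_names:
            s = float(sums[method])
            residual = abs(s - round(s))
            row[method] = residual
            if round(s) != expected:
                flags.append(Flag(block_id, method, abs(s - expected), "fatal"))
            elif residual > tol_fatal:
                flags.append(Flag(block_id, method, residual, "fatal"))
            elif residual > tol_negligible:
                flags.append(Flag(block_id, method, residual, "suspect"))
        residual_rows.append(row)

    flags.sort(key=lambda f: -abs(f.residual))
    residuals = pd.DataFrame(residual_rows,
                             index=[b for b, _ in blocks])[table.method_names]
    return ConsistencyReport(blocks, residuals, flags, missing_entries)


def validate_physical_bounds(
    table: NACTable,
    z_map: Mapping[str, int] | None = None,
    asm: Sequence[float] | None = None,
    tol: float = 1e-9,
) -> BoundsReport:
    """Flag NACs implying a negative electron count or contradicting spin moments.

    An atom with nuclear charge Z assigned NAC q holds Z - q electrons, so
    q > Z is unphysical.  With an atomic spin moment (ASM) given, the atom
    needs at least \\|ASM\\| electrons, so (Z - q) < \\|ASM\\| is flagged as
    chemically inconsistent.
    """
    if asm is not None and len(asm) != table.n_atoms:
        raise ValidationError("asm length must match the number of atoms")
    z_per_row = np.array([
        z_map[el] if z_map is not None else atomic_number(el)
        for el in table.atoms["element"]
    ], dtype=float)

    report = BoundsReport()
    values = table.values.to_numpy()
    for c, method in enumerate(table.method_names):
        q = values[:, c]
        with np.errstate(invalid="ignore"):
            over = np.where(q > z_per_row + tol)[0]
        for r in over:
            report.violations.append((
                str(table.atoms.iloc[r]["molecule_id"]),
                int(table.atoms.iloc[r]["atom_index"]),
                method, "negative_electron_count",
                f"NAC {q[r]:.4f} > Z {int(z_per_row[r])}: "
                f"{z_per_row[r] - q[r]:.4f} electrons assigned",
            ))
        if asm is not None:
            spins = np.abs(np.asarray(asm, dtype=float))
            with np.errstate(invalid="ignore"):
                bad = np.where((z_per_row - q) + tol < spins)[0]
            for r in bad:
                report.violations.append((
                    str(table.atoms.iloc[r]["molecule_id"]),
                    int(table.atoms.iloc[r]["atom_index"]),
                    method, "nac_asm_inconsistent",
                    f"{z_per_row[r] - q[r]:.4f} electrons < |ASM| {spins[r]:.4f}",
                ))
    return report


def report_to_json(report: ConsistencyReport | BoundsReport) -> str:
    return json.dumps(report.to_dict(), indent=2)
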