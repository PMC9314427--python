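"""Data model and curation for stability-constant measurements.

A measurement couples a metal cation M (symbol + charge) and a ligand L
(SMILES + molecular charge in aqueous solution) with the coordination count
``n`` and the overall stability constant ``beta_n`` on the log10 scale,
beta_n = log10 [M-L_n] / ([M][L]^n), plus the experimental conditions
(temperature in Celsius, ionic strength in mol/L).

Curation mirrors standard practice for stability-constant compilations:
records for a handful of heavy actinide cations and for ligands containing
elements whose descriptors are unreliable are excluded, and duplicate
measurements of the same (cation, ligand, n) key are resolved by a fixed
condition-priority rule (25 degC and I = 0.1 mol/L preferred) with the
largest beta winning within a priority tier.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

#: Cations excluded outright (element symbols).
EXCLUDED_CATIONS = frozenset({"Am", "Cm", "Cf", "Bk", "Es", "Fm", "Md"})

#: A ligand containing any of these elements is excluded.
EXCLUDED_LIGAND_ELEMENTS = frozenset(
    {"Te", "Se", "As", "Mn", "Co", "Fe", "W", "Mo", "Cr", "Re"}
)

#: CSV schema, in column order.
CSV_COLUMNS = (
    "cation",
    "charge",
    "smiles",
    "ligand_charge",
    "n",
    "beta",
    "temp_c",
    "ionic_strength",
    "source",
)

# Duplicate-resolution reference conditions with rounding tolerances:
# measurements are reported rounded, so tier membership is a small window
# around the nominal 25 degC / 0.1 mol/L.
REFERENCE_TEMP_C = 25.0
REFERENCE_IONIC_STRENGTH = 0.1
TEMP_TOL = 0.5
IONIC_TOL = 0.005


class SchemaError(ValueError):
    """The input table is missing a required column."""


class RecordValidationError(ValueError):
    """One or more rows failed validation; ``.errors`` lists (row, message)."""

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        lines = "; ".join(f"row {i}: {msg}" for i, msg in errors[:10])
        extra = "" if len(errors) <= 10 else f" (+{len(errors) - 10} more)"
        super().__init__(f"{len(errors)} invalid row(s): {lines}{extra}")


def canonical_smiles(smiles: str) -> str:
    """Canonical SMILES via RDKit; raises ValueError on unparsable input."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def cation_key(symbol: str, charge: int) -> str:
    """Conventional ion label, e.g. ``Cu2+``, ``Ag+``."""
    mag = "" if abs(charge) == 1 else str(abs(charge))
    return f"{symbol}{mag}{'+' if charge > 0 else '-'}"


@dataclass(frozen=True)
class StabilityRecord:
    """One stability-constant measurement."""

    cation_symbol: str
    cation_charge: int
    ligand_smiles: str
    ligand_charge: int
    n: int
    beta: float
    temperature_c: float
    ionic_strength: float
    source_id: str = ""
    # canonical form cached at construction; keys always use it
    canonical_ligand: str = field(default="", compare=False)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.cation_charge < 1:
            raise ValueError(
                f"cation charge must be >= +1, got {self.cation_charge}"
            )
        if self.ionic_strength < 0:
            raise ValueError(
                f"ionic strength must be >= 0, got {self.ionic_strength}"
            )
        if not _finite(self.beta):
            raise ValueError(f"beta must be finite, got {self.beta}")
        if not self.canonical_ligand:
            object.__setattr__(
                self, "canonical_ligand", canonical_smiles(self.ligand_smiles)
            )

    @property
    def cation(self) -> str:
        return cation_key(self.cation_symbol, self.cation_charge)

    @property
    def key(self) -> tuple[str, str, int]:
        """Deduplication key: (cation label, canonical ligand, n)."""
        return (self.cation, self.canonical_ligand, self.n)

    @property
    def pair(self) -> tuple[str, str]:
        """(cation label, canonical ligand) — the M-L pair."""
        return (self.cation, self.canonical_ligand)

    @property
    def complex_charge(self) -> int:
        """Charge of the M-L_n complex: cation charge + n * ligand charge.

        For the cascade descriptor the paper-style definition (cation charge
        plus molecular charge of one ligand) is used instead; see
        :func:`stabgp.cascade.complex_charge`.
        """
        return self.cation_charge + self.n * self.ligand_charge


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


def parse_records(
    source: str | Path | io.TextIOBase, *, strict: bool = True
) -> list[StabilityRecord]:
    """Parse delimited text (CSV with header) into validated records.

    Parameters
    ----------
    source
        Path, raw CSV text (must contain a newline), or an open text stream.
    strict
        If True (default) any invalid row raises
        :class:`RecordValidationError` listing every offending row index.
        If False, invalid rows are dropped silently.

    Raises
    ------
    SchemaError
        If a required column is missing from the header.
    """
    if isinstance(source, io.TextIOBase):
        fh = source
        close = False
    elif isinstance(source, str) and "\n" in source:
        fh = io.StringIO(source)
        close = True
    else:
        fh = open(source, newline="", encoding="utf-8")
        close = True
    try:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in CSV_COLUMNS:
            if col not in header:
                raise SchemaError(f"missing required column: {col!r}")
        records: list[StabilityRecord] = []
        errors: list[tuple[int, str]] = []
        for i, row in enumerate(reader):
            try:
                records.append(
                    StabilityRecord(
                        cation_symbol=row["cation"].strip(),
                        cation_charge=int(row["charge"]),
                        ligand_smiles=row["smiles"].strip(),
                        ligand_charge=int(row["ligand_charge"]),
                        n=int(row["n"]),
                        beta=float(row["beta"]),
                        temperature_c=float(row["temp_c"]),
                        ionic_strength=float(row["ionic_strength"]),
                        source_id=(row.get("source") or "").strip(),
                    )
                )
            except (ValueError, KeyError) as exc:
                errors.append((i, str(exc)))
        if errors and strict:
            raise RecordValidationError(errors)
        return records
    finally:
        if close:
            fh.close()


def write_records(records: Iterable[StabilityRecord], path: str | Path) -> None:
    """Write records to CSV in the package schema (header row included)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.cation_symbol,
                    r.cation_charge,
                    r.ligand_smiles,
                    r.ligand_charge,
                    r.n,
                    repr(r.beta),
                    repr(r.temperature_c),
                    repr(r.ionic_strength),
                    r.source_id,
                ]
            )


@dataclass(frozen=True)
class Dropped:
    """A record removed by :func:`apply_exclusions`, with the reason."""

    record: StabilityRecord
    reason: str


def _ligand_elements(record: StabilityRecord) -> set[str]:
    mol = Chem.MolFromSmiles(record.canonical_ligand)
    return {atom.GetSymbol() for atom in mol.GetAtoms()}


def apply_exclusions(
    records: Sequence[StabilityRecord],
) -> tuple[list[StabilityRecord], list[Dropped]]:
    """Partition records into (kept, dropped-with-reason).

    Drops records whose cation is an excluded heavy actinide or whose ligand
    contains an element for which reliable descriptors cannot be built.
    """
    kept: list[StabilityRecord] = []
    dropped: list[Dropped] = []
    for r in records:
        if r.cation_symbol in EXCLUDED_CATIONS:
            dropped.append(Dropped(r, f"excluded cation {r.cation_symbol}"))
            continue
        bad = _ligand_elements(r) & EXCLUDED_LIGAND_ELEMENTS
        if bad:
            el = sorted(bad)[0]
            dropped.append(Dropped(r, f"excluded ligand element {el}"))
            continue
        kept.append(r)
    return kept, dropped


def _condition_tier(record: StabilityRecord) -> int:
    """Priority tier, smaller is better: (1) 25 degC & I=0.1, (2) 25 degC,
    (3) I=0.1, (4) everything else."""
    at_t = abs(record.temperature_c - REFERENCE_TEMP_C) <= TEMP_TOL
    at_i = abs(record.ionic_strength - REFERENCE_IONIC_STRENGTH) <= IONIC_TOL
    if at_t and at_i:
        return 1
    if at_t:
        return 2
    if at_i:
        return 3
    return 4


def resolve_duplicates(
    records: Sequence[StabilityRecord],
) -> list[StabilityRecord]:
    """Keep one record per (cation, ligand, n) key.

    Within a key the winner is the record in the best condition tier; ties
    within a tier go to the largest beta, then to the first-seen record.
    Output preserves the order in which keys first appear.
    """
    best: dict[tuple[str, str, int], StabilityRecord] = {}
    order: list[tuple[str, str, int]] = []
    for r in records:
        k = r.key
        if k not in best:
            best[k] = r
            order.append(k)
            continue
        cur = best[k]
        tier_new, tier_cur = _condition_tier(r), _condition_tier(cur)
        if tier_new < tier_cur or (
            tier_new == tier_cur and r.beta > cur.beta
        ):
            best[k] = r
    return [best[k] for k in order]


def prepare(
    records: Sequence[StabilityRecord],
) -> tuple[list[StabilityRecord], list[Dropped]]:
    """Full curation: exclusions then duplicate resolution."""
    kept, dropped = apply_exclusions(records)
    return resolve_duplicates(kept), dropped
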