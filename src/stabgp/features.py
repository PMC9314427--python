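"""Descriptor construction and the three-stage feature-pruning pipeline.

The descriptor of a measurement concatenates three blocks:

* 12 element-level cation features (charge, atomic number, melting point,
  molar heat capacity, ionic radius, polarizability, electron affinity,
  Pauling electronegativity, unfilled s/p/d/f electrons),
* ligand compositional/topological descriptors computed from SMILES with
  RDKit's 2-D descriptor set, plus the molecular charge of the ligand in
  aqueous solution,
* the experimental conditions (temperature, ionic strength).

Ligand features are pruned in a fixed order before assembly:
``drop_degenerate`` (constant or incomplete columns) ->
``correlation_filter`` (|Pearson r| > 0.7 drops the later column) ->
``vif_filter`` (iteratively remove the largest variance inflation factor
until all VIF < 4).
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .records import StabilityRecord, canonical_smiles

CATION_FEATURES = (
    "charge",
    "atomic_number",
    "melting_point_k",
    "molar_heat_capacity",
    "ionic_radius_pm",
    "polarizability_a3",
    "electron_affinity_ev",
    "electronegativity",
    "unfilled_s",
    "unfilled_p",
    "unfilled_d",
    "unfilled_f",
)

CONDITION_FEATURES = ("temp_c", "ionic_strength")


def load_cation_reference() -> pd.DataFrame:
    """Bundled element-level feature table for common cations.

    Indexed by ion label (``Cu2+``); one row per (element, charge) with the
    12 cation features. Melting points, heat capacities, Shannon ionic radii,
    atomic polarizabilities, electron affinities and Pauling
    electronegativities are standard reference values; unfilled s/p/d/f
    counts are vacancies in the frontier subshells of the ion configuration.
    """
    ref = importlib.resources.files("stabgp.data") / "cation_features.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return df.set_index("cation")


@dataclass
class DescriptorTable:
    """A named feature matrix with provenance and standardization metadata.

    ``data`` holds one row per entity (record or ligand); ``provenance``
    maps each column to its block (``cation`` | ``ligand`` | ``condition``
    | ``cascade``). After :meth:`standardized`, ``means``/``scales`` record
    the per-column statistics of the fit rows so held-out rows and inverse
    transforms use fit-set statistics only.
    """

    data: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)
    means: pd.Series | None = None
    scales: pd.Series | None = None

    def __post_init__(self):
        self.provenance = {
            c: self.provenance.get(c, "ligand") for c in self.data.columns
        }

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def is_standardized(self) -> bool:
        return self.means is not None

    def copy(self) -> "DescriptorTable":
        return DescriptorTable(
            self.data.copy(),
            dict(self.provenance),
            None if self.means is None else self.means.copy(),
            None if self.scales is None else self.scales.copy(),
        )

    def select(self, columns: Sequence[str]) -> "DescriptorTable":
        """Column subset, preserving metadata."""
        cols = list(columns)
        return DescriptorTable(
            self.data[cols].copy(),
            {c: self.provenance[c] for c in cols},
            None if self.means is None else self.means[cols],
            None if self.scales is None else self.scales[cols],
        )

    def standardized(self, fit_rows=None) -> "DescriptorTable":
        """Z-score every column using statistics from ``fit_rows`` only.

        ``fit_rows`` is an index/boolean selection into ``data`` (default:
        all rows). Raises on zero-variance fit columns, which should have
        been removed by :func:`drop_degenerate`.
        """
        fit = self.data if fit_rows is None else self.data.loc[fit_rows]
        if len(fit) == 0:
            raise ValueError("fit_rows selects no rows")
        means = fit.mean(axis=0)
        scales = fit.std(axis=0, ddof=0)
        zero = scales[scales <= 0]
        if len(zero):
            raise ValueError(
                f"zero-variance columns in fit rows: {list(zero.index)}"
            )
        return DescriptorTable(
            (self.data - means) / scales, dict(self.provenance), means, scales
        )

    def transform(self, raw: pd.DataFrame) -> pd.DataFrame:
        """Standardize new raw rows with the stored fit statistics."""
        if not self.is_standardized:
            raise ValueError("table carries no standardization metadata")
        return (raw[self.columns] - self.means) / self.scales

    def inverse(self) -> pd.DataFrame:
        """Undo standardization (fit-set statistics)."""
        if not self.is_standardized:
            raise ValueError("table carries no standardization metadata")
        return self.data * self.scales + self.means

    # -- serialization: CSV + JSON sidecar ---------------------------------
    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.data.to_csv(path, index=True)
        meta = {
            "provenance": self.provenance,
            "means": None if self.means is None else self.means.to_dict(),
            "scales": None if self.scales is None else self.scales.to_dict(),
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=1, sort_keys=True)
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "DescriptorTable":
        path = Path(path)
        data = pd.read_csv(path, index_col=0)
        meta = json.loads(
            path.with_suffix(path.suffix + ".meta.json").read_text()
        )
        means = meta["means"]
        scales = meta["scales"]
        return cls(
            data,
            meta["provenance"],
            None if means is None else pd.Series(means)[data.columns],
            None if scales is None else pd.Series(scales)[data.columns],
        )


# ---------------------------------------------------------------------------
# ligand descriptors


def ligand_descriptors(
    smiles: Sequence[str], charges: Sequence[int] | None = None
) -> DescriptorTable:
    """2-D compositional/topological descriptors, one row per ligand.

    Rows are indexed by canonical SMILES. If ``charges`` is given, the
    molecular charge in aqueous solution is appended as column
    ``mol_charge``. Descriptor failures become missing values, to be
    resolved by :func:`drop_degenerate`.
    """
    canon: list[str] = []
    rows: list[dict[str, float]] = []
    charge_map: dict[str, int] = {}
    for i, smi in enumerate(smiles):
        c = canonical_smiles(smi)
        if c in charge_map or c in canon:
            continue
        mol = Chem.MolFromSmiles(c)
        try:
            desc = Descriptors.CalcMolDescriptors(mol)
        except Exception:  # pragma: no cover - per-molecule failure
            desc = {}
        rows.append(desc)
        canon.append(c)
        if charges is not None:
            charge_map[c] = int(charges[i])
    df = pd.DataFrame(rows, index=canon)
    df = df.apply(pd.to_numeric, errors="coerce")
    # infinities from ill-conditioned descriptors count as missing
    df = df.replace([np.inf, -np.inf], np.nan)
    if charges is not None:
        df["mol_charge"] = pd.Series(charge_map)
    return DescriptorTable(df, {c: "ligand" for c in df.columns})


# ---------------------------------------------------------------------------
# pruning pipeline


def drop_degenerate(table: DescriptorTable) -> DescriptorTable:
    """Remove columns that are constant or contain any missing value."""
    df = table.data
    keep = [
        c
        for c in df.columns
        if df[c].notna().all() and df[c].nunique() > 1
    ]
    return table.select(keep)


def correlation_filter(
    table: DescriptorTable, threshold: float = 0.7
) -> DescriptorTable:
    """Drop the later column of any pair with |Pearson r| > threshold.

    Columns are scanned in stable input order; when columns i < j are both
    still present and |r(i, j)| > threshold, j is dropped. The comparison
    carries a 1e-12 guard so a pair at exactly the threshold is retained.
    """
    df = table.data
    cols = list(df.columns)
    corr = np.corrcoef(df.to_numpy(dtype=float), rowvar=False)
    corr = np.atleast_2d(corr)
    alive = np.ones(len(cols), dtype=bool)
    for i in range(len(cols)):
        if not alive[i]:
            continue
        for j in range(i + 1, len(cols)):
            if alive[j] and abs(corr[i, j]) - threshold > 1e-12:
                alive[j] = False
    return table.select([c for c, a in zip(cols, alive) if a])


def variance_inflation_factors(X: np.ndarray) -> np.ndarray:
    """VIF_k = 1/(1 - R^2_k) from regressing column k on the others.

    An intercept is included in each auxiliary regression. Perfect
    collinearity yields +inf.
    """
    n, d = X.shape
    out = np.empty(d)
    ones = np.ones((n, 1))
    for k in range(d):
        y = X[:, k]
        others = np.hstack([ones, np.delete(X, k, axis=1)])
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        tss = np.sum((y - y.mean()) ** 2)
        if tss <= 0:
            out[k] = np.inf
            continue
        r2 = 1.0 - np.sum(resid**2) / tss
        out[k] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_filter(table: DescriptorTable, threshold: float = 4.0) -> DescriptorTable:
    """Iteratively remove the largest-VIF column until all VIF < threshold."""
    cols = list(table.data.columns)
    if len(cols) < 2:
        return table.select(cols)
    X = table.data.to_numpy(dtype=float)
    alive = list(range(len(cols)))
    while len(alive) >= 2:
        vifs = variance_inflation_factors(X[:, alive])
        worst = int(np.argmax(vifs))
        if vifs[worst] < threshold:
            break
        del alive[worst]
    return table.select([cols[i] for i in alive])


def prune_features(
    table: DescriptorTable,
    corr_threshold: float = 0.7,
    vif_threshold: float = 4.0,
) -> DescriptorTable:
    """The full pipeline: degenerate -> correlation -> VIF."""
    return vif_filter(
        correlation_filter(drop_degenerate(table), corr_threshold),
        vif_threshold,
    )


# ---------------------------------------------------------------------------
# assembly


def assemble_beta1_descriptor(
    records: Sequence[StabilityRecord],
    cation_table: pd.DataFrame,
    ligand_table: DescriptorTable,
) -> DescriptorTable:
    """Concatenate cation + ligand + condition blocks, one row per record.

    ``cation_table`` is indexed by ion label and must carry the 12 cation
    features; ``ligand_table`` is indexed by canonical SMILES (already
    pruned). Raises KeyError naming any cation absent from the table.
    """
    missing = sorted(
        {r.cation for r in records} - set(cation_table.index)
    )
    if missing:
        raise KeyError(f"unknown cation(s): {', '.join(missing)}")
    cat_cols = [c for c in CATION_FEATURES if c in cation_table.columns]
    if len(cat_cols) != len(CATION_FEATURES):
        lost = set(CATION_FEATURES) - set(cat_cols)
        raise KeyError(f"cation table missing feature(s): {sorted(lost)}")

    cat_block = cation_table.loc[
        [r.cation for r in records], cat_cols
    ].to_numpy(dtype=float)
    lig_block = ligand_table.data.loc[
        [r.canonical_ligand for r in records]
    ].to_numpy(dtype=float)
    cond_block = np.array(
        [[r.temperature_c, r.ionic_strength] for r in records], dtype=float
    )
    cat_named = [f"cation_{c}" for c in cat_cols]
    cols = cat_named + ligand_table.columns + list(CONDITION_FEATURES)
    df = pd.DataFrame(
        np.hstack([cat_block, lig_block, cond_block]),
        columns=cols,
        index=pd.RangeIndex(len(records)),
    )
    prov = {c: "cation" for c in cat_named}
    prov.update({c: "ligand" for c in ligand_table.columns})
    prov.update({c: "condition" for c in CONDITION_FEATURES})
    return DescriptorTable(df, prov)


def standardize(
    table: DescriptorTable, fit_rows=None
) -> DescriptorTable:
    """Functional alias for :meth:`DescriptorTable.standardized`."""
    return table.standardized(fit_rows)
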