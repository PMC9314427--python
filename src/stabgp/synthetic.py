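"""Synthetic stability-constant datasets with planted structure.

The generator emulates the statistical shape of a large curated
stability-constant compilation — tens of cations, thousands of ligands,
first constants driven by a sparse set of electronegativity- and
charge-like features — while making every downstream stage testable:

* cations get 12 element-level feature rows spanning realistic ranges and
  real (non-excluded) metal ion labels;
* ligands are built from a small template grammar (polyamines,
  carboxylates, polyols, mixed chelators) so fragment descriptors such as
  -NH- and -O- counts vary meaningfully; aqueous molecular charge is -1
  per carboxylate group;
* the first stepwise constant log K_1 is a fixed sparse function of the
  planted active features plus Gaussian noise, shifted and clipped to be
  positive; stepwise constants decay geometrically,
  log K_i = rho^(i-1) * log K_1 with rho drawn per M-L pair from (0, 1),
  so beta_n = sum_{i<=n} log K_i satisfies beta_{n-1} < beta_n < n*beta_1
  by construction;
* off-condition duplicate families are injected at a configurable rate to
  exercise duplicate resolution; each family is internally consistent and
  loses the tier-1 priority contest to its 25 degC / 0.1 mol/L original.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .features import CATION_FEATURES
from .records import StabilityRecord, canonical_smiles, cation_key

__all__ = ["SyntheticSpec", "generate_entities", "generate_beta",
           "generate_dataset"]

# real (symbol, charge) metal ions, none in the excluded-cation set
_CATION_POOL: list[tuple[str, int]] = [
    ("Li", 1), ("Na", 1), ("K", 1), ("Rb", 1), ("Cs", 1), ("Cu", 1),
    ("Ag", 1), ("Tl", 1), ("Au", 1),
    ("Mg", 2), ("Ca", 2), ("Sr", 2), ("Ba", 2), ("Mn", 2), ("Fe", 2),
    ("Co", 2), ("Ni", 2), ("Cu", 2), ("Zn", 2), ("Pd", 2), ("Cd", 2),
    ("Sn", 2), ("Hg", 2), ("Pb", 2), ("Pt", 2), ("Be", 2), ("Ra", 2),
    ("Eu", 2), ("Sm", 2), ("V", 2),
    ("Al", 3), ("Sc", 3), ("Cr", 3), ("Fe", 3), ("Ga", 3), ("Y", 3),
    ("In", 3), ("La", 3), ("Ce", 3), ("Pr", 3), ("Nd", 3), ("Sm", 3),
    ("Eu", 3), ("Gd", 3), ("Tb", 3), ("Dy", 3), ("Ho", 3), ("Er", 3),
    ("Tm", 3), ("Yb", 3), ("Lu", 3), ("Bi", 3), ("Tl", 3), ("Au", 3),
    ("Ti", 3), ("V", 3),
    ("Zr", 4), ("Hf", 4), ("Th", 4), ("Ce", 4), ("Sn", 4), ("Ti", 4),
    ("U", 4), ("Pu", 4),
]

_ATOMIC_NUMBER = {
    "Li": 3, "Be": 4, "Na": 11, "Mg": 12, "Al": 13, "K": 19, "Ca": 20,
    "Sc": 21, "Ti": 22, "V": 23, "Cr": 24, "Mn": 25, "Fe": 26, "Co": 27,
    "Ni": 28, "Cu": 29, "Zn": 30, "Ga": 31, "Rb": 37, "Sr": 38, "Y": 39,
    "Zr": 40, "Pd": 46, "Ag": 47, "Cd": 48, "In": 49, "Sn": 50, "Cs": 55,
    "Ba": 56, "La": 57, "Ce": 58, "Pr": 59, "Nd": 60, "Sm": 62, "Eu": 63,
    "Gd": 64, "Tb": 65, "Dy": 66, "Ho": 67, "Er": 68, "Tm": 69, "Yb": 70,
    "Lu": 71, "Hf": 72, "Pt": 78, "Au": 79, "Hg": 80, "Tl": 81, "Pb": 82,
    "Bi": 83, "Ra": 88, "Th": 90, "U": 92, "Pu": 94,
}

# ligand template grammar: head/tail donors and chain units
_HEADS = ["N", "O", "OC(=O)"]
_TAILS = ["N", "O", "C(=O)O"]
_LINKERS = ["CC", "CCC", "C(C)C", "CCCC"]
_MIDS = ["N", "O"]


@dataclass
class SyntheticSpec:
    """Generation conditions; defaults mirror the real compilation's scale."""

    n_cations: int = 57
    n_ligands: int = 2706
    pairs_per_ligand: int = 5
    max_n: int = 6
    # indices into CATION_FEATURES: charge (0) and electronegativity (7)
    active_cation_features: tuple[int, ...] = (0, 7)
    # ligand-level drivers: molecular charge and donor-site count
    effect_weights: dict = field(
        default_factory=lambda: {
            "electronegativity": 2.5,
            "charge": 1.2,
            "donors": 0.8,
            "mol_charge": -1.5,
            "intercept": -2.0,
        }
    )
    nonlinear: bool = True
    noise_sd: float = 0.5
    rho_range: tuple[float, float] = (0.3, 0.8)
    duplicate_rate: float = 0.1
    # probability of the maximum coordination number 1..max_n
    n_max_probs: tuple[float, ...] = (0.60, 0.18, 0.10, 0.07, 0.03, 0.02)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.rho_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("rho_range must satisfy 0 < lo < hi < 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.max_n < 1 or self.max_n > len(self.n_max_probs):
            raise ValueError("max_n must be in [1, len(n_max_probs)]")


def _enumerate_ligands(limit: int) -> list[str]:
    """Deterministic template enumeration of chelator-like SMILES."""
    out: list[str] = []
    seen: set[str] = set()
    units = list(itertools.product(_LINKERS, _MIDS))
    for repeats in range(0, 4):
        if repeats == 0:
            combos = (
                (h, "CC", t) for h, t in itertools.product(_HEADS, _TAILS)
            )
        else:
            combos = (
                (h, "".join(link + don for link, don in mid) + "CC", t)
                for h, mid, t in itertools.product(
                    _HEADS, itertools.product(units, repeat=repeats), _TAILS
                )
            )
        for head, body, tail in combos:
            smi = head + body + tail
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                continue
            canon = Chem.MolToSmiles(mol)
            if canon in seen:
                continue
            seen.add(canon)
            out.append(canon)
            if len(out) >= limit:
                return out
    return out


_CARBOXYL = Chem.MolFromSmarts("[CX3](=O)[OX2H1]")
_DONOR = Chem.MolFromSmarts("[#7,#8]")


def _ligand_charge(smiles: str) -> int:
    """Aqueous molecular charge: -1 per carboxylic-acid group."""
    mol = Chem.MolFromSmiles(smiles)
    return -len(mol.GetSubstructMatches(_CARBOXYL))


def _donor_count(smiles: str) -> int:
    mol = Chem.MolFromSmiles(smiles)
    return len(mol.GetSubstructMatches(_DONOR))


def generate_entities(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cation feature table and ligand set for a spec.

    Returns ``(cation_table, ligands)``: the cation table is indexed by ion
    label with the 12 cation features (charge and atomic number real,
    remaining features sampled from realistic element ranges); ``ligands``
    has columns ``smiles`` (canonical), ``mol_charge`` and ``donors``.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n_cations > len(_CATION_POOL):
        raise ValueError(
            f"n_cations must be <= {len(_CATION_POOL)}"
        )
    pick = rng.choice(len(_CATION_POOL), size=spec.n_cations, replace=False)
    rows = []
    for i in sorted(pick):
        sym, q = _CATION_POOL[i]
        rows.append(
            {
                "cation": cation_key(sym, q),
                "symbol": sym,
                "charge": float(q),
                "atomic_number": float(_ATOMIC_NUMBER[sym]),
                "melting_point_k": rng.uniform(250.0, 2200.0),
                "molar_heat_capacity": rng.uniform(23.0, 38.0),
                "ionic_radius_pm": rng.uniform(50.0, 170.0) / q**0.3,
                "polarizability_a3": rng.uniform(4.0, 60.0),
                "electron_affinity_ev": rng.uniform(0.0, 2.3),
                "electronegativity": rng.uniform(0.7, 2.4),
                "unfilled_s": float(rng.integers(0, 3)),
                "unfilled_p": float(rng.integers(0, 7)),
                "unfilled_d": float(rng.integers(0, 11)),
                "unfilled_f": float(rng.integers(0, 15)),
            }
        )
    cation_table = pd.DataFrame(rows).set_index("cation")

    smiles = _enumerate_ligands(spec.n_ligands)
    if len(smiles) < spec.n_ligands:
        raise ValueError(
            f"template grammar yields only {len(smiles)} ligands; "
            f"requested {spec.n_ligands}"
        )
    ligands = pd.DataFrame(
        {
            "smiles": smiles,
            "mol_charge": [_ligand_charge(s) for s in smiles],
            "donors": [_donor_count(s) for s in smiles],
        }
    )
    return cation_table, ligands


def _log_k1(
    cat_row: pd.Series, lig_row: pd.Series, spec: SyntheticSpec, rng
) -> float:
    w = spec.effect_weights
    chi = cat_row["electronegativity"]
    val = (
        w["electronegativity"] * chi
        + w["charge"] * cat_row["charge"]
        + w["donors"] * lig_row["donors"]
        + w["mol_charge"] * lig_row["mol_charge"]
        + w["intercept"]
    )
    if spec.nonlinear:
        val += 0.6 * chi * (-lig_row["mol_charge"])
    val += rng.normal(0.0, spec.noise_sd)
    return max(0.1, float(val))


def generate_beta(
    entities: tuple[pd.DataFrame, pd.DataFrame], spec: SyntheticSpec
) -> list[StabilityRecord]:
    """Records for randomly paired cations and ligands.

    Each ligand is paired with ``pairs_per_ligand`` distinct cations; each
    pair gets a maximum coordination number drawn from ``n_max_probs`` and
    a full family beta_1..beta_{n_max} built from geometrically decaying
    stepwise constants, at 25 degC / 0.1 mol/L. With probability
    ``duplicate_rate`` an off-condition duplicate family is also emitted.
    """
    cation_table, ligands = entities
    rng = np.random.default_rng(spec.seed + 1)
    probs = np.array(spec.n_max_probs[: spec.max_n], dtype=float)
    probs /= probs.sum()
    records: list[StabilityRecord] = []
    cations = list(cation_table.index)
    for _, lig in ligands.iterrows():
        k = min(spec.pairs_per_ligand, len(cations))
        for ci in rng.choice(len(cations), size=k, replace=False):
            cat = cation_table.iloc[ci]
            sym, q = cat["symbol"], int(cat["charge"])
            logk1 = _log_k1(cat, lig, spec, rng)
            rho = rng.uniform(*spec.rho_range)
            n_max = int(rng.choice(spec.max_n, p=probs)) + 1
            fams = [(25.0, 0.1, logk1, "syn")]
            if rng.random() < spec.duplicate_rate:
                t = float(rng.choice([20.0, 30.0, 37.0]))
                i_s = float(rng.choice([0.5, 1.0]))
                fams.append(
                    (t, i_s, max(0.1, logk1 + rng.normal(0.0, 0.3)),
                     "syn-dup")
                )
            for temp, ionic, k1, src in fams:
                beta = 0.0
                for n in range(1, n_max + 1):
                    beta += k1 * rho ** (n - 1)
                    records.append(
                        StabilityRecord(
                            cation_symbol=sym,
                            cation_charge=q,
                            ligand_smiles=lig["smiles"],
                            ligand_charge=int(lig["mol_charge"]),
                            n=n,
                            beta=beta,
                            temperature_c=temp,
                            ionic_strength=ionic,
                            source_id=src,
                            canonical_ligand=lig["smiles"],
                        )
                    )
    return records


def generate_dataset(
    spec: SyntheticSpec | None = None, **overrides
) -> tuple[list[StabilityRecord], pd.DataFrame, pd.DataFrame]:
    """One-call generator: ``(records, cation_table, ligands)``."""
    if spec is None:
        spec = SyntheticSpec(**overrides)
    elif overrides:
        raise TypeError("pass either a spec or keyword overrides, not both")
    entities = generate_entities(spec)
    return generate_beta(entities, spec), entities[0], entities[1]
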