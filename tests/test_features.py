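"""Ligand descriptors, the pruning pipeline and descriptor assembly."""

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from stabgp.features import (
    DescriptorTable,
    assemble_beta1_descriptor,
    correlation_filter,
    drop_degenerate,
    ligand_descriptors,
    load_cation_reference,
    prune_features,
    standardize,
    variance_inflation_factors,
    vif_filter,
)
from stabgp.records import StabilityRecord


def table(df, **kw):
    return DescriptorTable(pd.DataFrame(df), **kw)


class TestLigandDescriptors:
    def test_methane_forced_values(self):
        t = ligand_descriptors(["C"])
        row = t.data.iloc[0]
        assert row["HeavyAtomCount"] == 1
        assert row["RingCount"] == 0

    def test_benzene_aromatic_ring(self):
        t = ligand_descriptors(["c1ccccc1"])
        assert t.data.iloc[0]["NumAromaticRings"] == 1

    def test_secondary_amine_count_matches_substructure_oracle(self):
        # diethylenetriamine: one -NH-, two -NH2
        smi = "NCCNCCN"
        t = ligand_descriptors([smi])
        mol = Chem.MolFromSmiles(smi)
        oracle = len(
            mol.GetSubstructMatches(Chem.MolFromSmarts("[NX3;H1](C)C"))
        )
        assert oracle == 1
        assert t.data.iloc[0]["fr_NH1"] == oracle
        assert t.data.iloc[0]["fr_NH2"] == 2

    def test_molecular_charge_appended(self):
        t = ligand_descriptors(["OC(=O)CN"], charges=[-1])
        assert t.data.iloc[0]["mol_charge"] == -1
        assert t.provenance["mol_charge"] == "ligand"


class TestDropDegenerate:
    def test_rules(self):
        t = table(
            {
                "const": [0.0, 0.0, 0.0],
                "has_nan": [1.0, np.nan, 2.0],
                "binary": [0.0, 1.0, 1.0],
            }
        )
        out = drop_degenerate(t)
        assert out.columns == ["binary"]


class TestCorrelationFilter:
    def test_duplicate_column_drops_later_copy(self, rng):
        a = rng.normal(size=50)
        out = correlation_filter(table({"a": a, "b": a.copy(), "c": rng.normal(size=50)}))
        assert out.columns == ["a", "c"]

    def test_pair_at_exactly_threshold_kept(self):
        # construct sample correlation of exactly 0.7 via orthonormal parts
        a = np.array([1.0, 1.0, -1.0, -1.0]) / 2.0
        c = np.array([1.0, -1.0, 1.0, -1.0]) / 2.0
        b = 0.7 * a + np.sqrt(1.0 - 0.49) * c
        out = correlation_filter(table({"a": a, "b": b}), threshold=0.7)
        assert out.columns == ["a", "b"]
        out = correlation_filter(table({"a": a, "b": b}), threshold=0.699)
        assert out.columns == ["a"]

    def test_independent_columns_all_kept(self, rng):
        # exactly orthogonal, zero-mean columns: population r = 0
        q, _ = np.linalg.qr(rng.normal(size=(40, 5)))
        q -= q.mean(axis=0)
        out = correlation_filter(
            table({f"c{i}": q[:, i] for i in range(5)}), threshold=0.7
        )
        assert len(out.columns) == 5

    def test_earlier_column_wins_chain(self, rng):
        a = rng.normal(size=200)
        b = a + 0.01 * rng.normal(size=200)  # r(a,b) ~ 1 -> b dropped
        c = rng.normal(size=200)
        out = correlation_filter(table({"a": a, "b": b, "c": c}))
        assert out.columns == ["a", "c"]


def brute_force_vif_filter(df: pd.DataFrame, threshold: float) -> list[str]:
    """Independent re-implementation: OLS per column via statsmodels."""
    import statsmodels.api as sm

    cols = list(df.columns)
    while len(cols) >= 2:
        vifs = []
        for k, col in enumerate(cols):
            others = sm.add_constant(df[[c for c in cols if c != col]])
            r2 = sm.OLS(df[col], others).fit().rsquared
            vifs.append(np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2))
        worst = int(np.argmax(vifs))
        if vifs[worst] < threshold:
            break
        cols.pop(worst)
    return cols


class TestVifFilter:
    def test_orthonormal_columns_untouched(self, rng):
        # orthonormal AND orthogonal to the intercept: VIF exactly 1
        full, _ = np.linalg.qr(
            np.hstack([np.ones((30, 1)), rng.normal(size=(30, 4))])
        )
        q = full[:, 1:]
        t = table({f"c{i}": q[:, i] for i in range(4)})
        assert vif_filter(t).columns == t.columns
        assert np.allclose(variance_inflation_factors(q), 1.0, atol=1e-8)

    def test_perfect_collinearity_removed_first(self, rng):
        a = rng.normal(size=40)
        b = rng.normal(size=40)
        out = vif_filter(table({"a": a, "b": b, "c": a + b}))
        assert len(out.columns) == 2
        vifs = variance_inflation_factors(out.values)
        assert np.all(vifs < 4)

    def test_matches_independent_oracle_on_random_table(self, rng):
        # 10 columns with built-in collinearity structure
        base = rng.normal(size=(60, 6))
        mix = base @ rng.normal(size=(6, 4)) + 0.3 * rng.normal(size=(60, 4))
        df = pd.DataFrame(
            np.hstack([base, mix]), columns=[f"f{i}" for i in range(10)]
        )
        ours = vif_filter(table(df), threshold=4.0).columns
        assert ours == brute_force_vif_filter(df, 4.0)
        assert np.all(
            variance_inflation_factors(df[ours].to_numpy()) < 4.0
        )

    def test_pipeline_order_and_value_preservation(self, rng):
        a = rng.normal(size=50)
        df = pd.DataFrame(
            {
                "const": np.ones(50),
                "a": a,
                "dup": a.copy(),
                "b": rng.normal(size=50),
            }
        )
        out = prune_features(table(df))
        assert "const" not in out.columns and "dup" not in out.columns
        # filters remove columns, never modify values
        for c in out.columns:
            assert np.array_equal(out.data[c], df[c])


class TestStandardize:
    def test_two_point_column(self):
        t = standardize(table({"x": [0.0, 2.0]}))
        assert np.allclose(t.data["x"], [-1.0, 1.0])
        assert abs(t.data["x"].mean()) < 1e-9

    def test_held_out_rows_use_fit_statistics(self):
        t = table({"x": [0.0, 2.0, 100.0]})
        std = t.standardized(fit_rows=[0, 1])
        # row 2 transformed with fit stats (mean 1, scale 1), not its own
        assert std.data["x"].iloc[2] == pytest.approx(99.0)
        new = std.transform(pd.DataFrame({"x": [4.0]}))
        assert new["x"].iloc[0] == pytest.approx(3.0)

    def test_round_trip(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        std = standardize(table(df))
        assert np.allclose(std.inverse().to_numpy(), df.to_numpy(), atol=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero-variance"):
            standardize(table({"x": [1.0, 1.0]}))


class TestAssembly:
    def _records(self):
        return [
            StabilityRecord("Cu", 2, "NCCN", 0, 1, 10.5, 25.0, 0.1),
            StabilityRecord("Ni", 2, "NCCN", 0, 1, 7.3, 20.0, 0.5),
            StabilityRecord("Ag", 1, "OCCO", 0, 1, 2.1, 25.0, 0.1),
        ]

    def test_dimensionality_is_sum_of_blocks(self):
        recs = self._records()
        lig = drop_degenerate(
            ligand_descriptors(["NCCN", "OCCO"], charges=[0, 0])
        )
        tab = assemble_beta1_descriptor(recs, load_cation_reference(), lig)
        assert len(tab.columns) == 12 + len(lig.columns) + 2
        tags = set(tab.provenance.values())
        assert tags == {"cation", "ligand", "condition"}

    def test_shared_ligand_rows_identical(self):
        recs = self._records()
        lig = drop_degenerate(
            ligand_descriptors(["NCCN", "OCCO"], charges=[0, 0])
        )
        tab = assemble_beta1_descriptor(recs, load_cation_reference(), lig)
        lig_cols = [c for c, p in tab.provenance.items() if p == "ligand"]
        assert tab.data.loc[0, lig_cols].equals(tab.data.loc[1, lig_cols])

    def test_unknown_cation_named_in_error(self):
        recs = [StabilityRecord("Zr", 4, "NCCN", 0, 1, 3.0, 25.0, 0.1)]
        lig = ligand_descriptors(["NCCN"], charges=[0])
        with pytest.raises(KeyError, match="Zr4"):
            assemble_beta1_descriptor(recs, load_cation_reference(), lig)


class TestSerialization:
    def test_csv_sidecar_round_trip(self, tmp_path, rng):
        df = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        t = standardize(
            DescriptorTable(df, {"a": "cation", "b": "ligand", "c": "condition"})
        )
        path = tmp_path / "table.csv"
        t.to_csv(path)
        back = DescriptorTable.from_csv(path)
        assert back.provenance == t.provenance
        assert np.allclose(back.data.to_numpy(), t.data.to_numpy())
        assert np.allclose(back.means, t.means)
        assert np.allclose(back.scales, t.scales)
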