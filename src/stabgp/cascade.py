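"""Two-stage (cascaded) prediction of overall stability constants.

Stage one is a GP model for the first overall stability constant beta_1,
built on cation + ligand + condition features. Stage two predicts the
multi-order beta_n (n >= 2) of an M-L_n complex from a descriptor whose
leading entries are the stage-one model's *predicted* beta_1 and its 1-sigma
uncertainty for the same M-L pair (never a lookup of a measured beta_1 —
many M-L pairs with multi-order data have no measured beta_1), the charge
of the M-L complex (cation charge + ligand molecular charge), the number of
additional ligands n-1, and any ligand features that the final stage-one
model does not use.

The module also houses the thermodynamic consistency check
beta_{n-1} < beta_n < n * beta_1 (a universal inequality following from
K_1 > K_2 > ... > K_n) and the per-n Pearson correlation between predicted
beta_1 and measured beta_n.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .features import (
    DescriptorTable,
    assemble_beta1_descriptor,
    ligand_descriptors,
    prune_features,
)
from .gpr import GaussianProcess, GPResults
from .records import StabilityRecord
from .relevance import (
    RelevanceReport,
    feature_relevance_kl,
    optimize_feature_count,
    select_validation_ligands,
)

CASCADE_FEATURES = ("pred_beta1", "pred_beta1_std", "complex_charge", "n_minus_1")


def complex_charge(record: StabilityRecord) -> int:
    """Charge of the M-L complex: cation charge + ligand molecular charge."""
    return record.cation_charge + record.ligand_charge


# ---------------------------------------------------------------------------
# consistency checks


@dataclass(frozen=True)
class InequalityViolation:
    kind: str  # "monotonicity" | "upper_bound"
    n: int
    message: str


def check_inequality(
    betas: dict[int, float], beta1: float | None = None
) -> list[InequalityViolation]:
    """Check beta_{n-1} < beta_n < n*beta_1 over a family of constants.

    ``betas`` maps coordination count n to beta_n (log10 scale); beta_1 is
    taken from the map if present, else from ``beta1``. An empty return
    means the family is consistent.
    """
    betas = dict(betas)
    if beta1 is not None:
        betas.setdefault(1, beta1)
    b1 = betas.get(1)
    out: list[InequalityViolation] = []
    ns = sorted(betas)
    for prev, cur in zip(ns, ns[1:]):
        if betas[prev] >= betas[cur]:
            out.append(
                InequalityViolation(
                    "monotonicity",
                    cur,
                    f"beta_{prev}={betas[prev]:g} >= beta_{cur}={betas[cur]:g}",
                )
            )
    if b1 is not None:
        for n in ns:
            if n >= 2 and betas[n] >= n * b1:
                out.append(
                    InequalityViolation(
                        "upper_bound",
                        n,
                        f"beta_{n}={betas[n]:g} >= {n}*beta_1={n * b1:g}",
                    )
                )
    return out


def check_records(
    records: Sequence[StabilityRecord],
) -> list[tuple[tuple, InequalityViolation]]:
    """Run :func:`check_inequality` per (cation, ligand, conditions) family."""
    fams: dict[tuple, dict[int, float]] = {}
    for r in records:
        k = (r.cation, r.canonical_ligand, r.temperature_c, r.ionic_strength)
        fams.setdefault(k, {})[r.n] = r.beta
    out = []
    for k, betas in fams.items():
        for v in check_inequality(betas):
            out.append((k, v))
    return out


def beta1_betan_correlation(
    pred_beta1: np.ndarray, records: Sequence[StabilityRecord]
) -> dict[int, float]:
    """Per-n Pearson correlation between predicted beta_1 and measured beta_n.

    ``pred_beta1[i]`` is the stage-one prediction for the M-L pair of
    ``records[i]`` (all records must have n >= 2). Strata with fewer than 3
    records or zero variance report NaN.
    """
    pred_beta1 = np.asarray(pred_beta1, dtype=float)
    byn: dict[int, list[int]] = {}
    for i, r in enumerate(records):
        if r.n < 2:
            raise ValueError("correlation is defined for n >= 2 records")
        byn.setdefault(r.n, []).append(i)
    out: dict[int, float] = {}
    for n, idx in sorted(byn.items()):
        x = pred_beta1[idx]
        y = np.array([records[i].beta for i in idx])
        if len(idx) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            out[n] = float("nan")
        else:
            out[n] = float(pearsonr(x, y).statistic)
    return out


# ---------------------------------------------------------------------------
# configuration


@dataclass
class CascadeConfig:
    """Tunables of the two-stage fit; defaults follow the printed method."""

    corr_threshold: float = 0.7
    vif_threshold: float = 4.0
    delta: float = 0.001
    n_restarts: int = 5
    maxiter: int = 200
    oof_folds: int = 5
    select_features: bool = True
    feature_grid: list[int] | None = None
    validation_count: int = 20
    selection_max_rows: int | None = 500
    selection_restarts: int = 2
    max_rows: int | None = None
    relevance_rows: int | None = 400
    seed: int = 0


# ---------------------------------------------------------------------------
# descriptor assembly for stage two


def assemble_betan_descriptor(
    records: Sequence[StabilityRecord],
    beta1_predictor,
    ligand_table: DescriptorTable,
    unused_ligand: Sequence[str],
) -> DescriptorTable:
    """Stage-two descriptor: cascade features + unused ligand features.

    ``beta1_predictor(records) -> (mean, std)`` supplies the stage-one
    prediction for each record's M-L pair at the record's own conditions.
    Raises on any record with n = 1 (those belong to stage one).
    """
    for r in records:
        if r.n < 2:
            raise ValueError(
                f"record with n={r.n} belongs to the beta_1 model"
            )
    mu, sd = beta1_predictor(records)
    df = pd.DataFrame(
        {
            "pred_beta1": np.asarray(mu, dtype=float),
            "pred_beta1_std": np.asarray(sd, dtype=float),
            "complex_charge": [float(complex_charge(r)) for r in records],
            "n_minus_1": [float(r.n - 1) for r in records],
        },
        index=pd.RangeIndex(len(records)),
    )
    if unused_ligand:
        lig = ligand_table.data.loc[
            [r.canonical_ligand for r in records], list(unused_ligand)
        ]
        lig.index = df.index
        df = pd.concat([df, lig], axis=1)
    prov = {c: "cascade" for c in CASCADE_FEATURES}
    prov.update({c: "ligand" for c in unused_ligand})
    return DescriptorTable(df, prov)


# ---------------------------------------------------------------------------
# the shared prediction engine


@dataclass
class CascadePredictor:
    """Everything needed to predict from a fitted two-stage model.

    ``beta1_meta``/``betan_meta`` carry the standardization metadata of the
    two descriptor spaces; ``ligand_table`` holds raw pruned ligand features
    for known ligands and is extended on the fly (same columns) for ligands
    never seen in training. ``oof`` optionally substitutes out-of-fold
    beta_1 predictions for M-L pairs whose measured beta_1 was in stage-one
    training.
    """

    beta1_results: GPResults
    beta1_meta: DescriptorTable
    beta1_feature_names: list[str]
    ligand_table: DescriptorTable
    cation_table: pd.DataFrame
    betan_results: GPResults | None = None
    betan_meta: DescriptorTable | None = None
    betan_extra_feature_names: list[str] = field(default_factory=list)
    oof: dict | None = None

    def _ligand_rows(self, records) -> DescriptorTable:
        known = set(self.ligand_table.data.index)
        new: dict[str, int] = {}
        for r in records:
            if r.canonical_ligand not in known:
                new.setdefault(r.canonical_ligand, r.ligand_charge)
        if not new:
            return self.ligand_table
        smiles = list(new)
        fresh = ligand_descriptors(smiles, [new[s] for s in smiles])
        cols = self.ligand_table.columns
        missing = [c for c in cols if c not in fresh.columns]
        if missing:
            raise ValueError(
                f"cannot compute ligand feature(s) {missing} for new ligands"
            )
        data = pd.concat([self.ligand_table.data, fresh.data[cols]])
        return DescriptorTable(data, dict(self.ligand_table.provenance))

    def predict_beta1(
        self, records: Sequence[StabilityRecord], use_oof: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        """Stage-one prediction for each record's M-L pair at its conditions.

        Always a model prediction, never a lookup of a measured beta_1.
        """
        lig = self._ligand_rows(records)
        raw = assemble_beta1_descriptor(records, self.cation_table, lig)
        Xz = self.beta1_meta.transform(
            raw.data[self.beta1_meta.columns]
        )[self.beta1_feature_names]
        mu, sd = self.beta1_results.predict(Xz)
        if use_oof and self.oof:
            for i, r in enumerate(records):
                if r.pair in self.oof:
                    mu[i], sd[i] = self.oof[r.pair]
        return mu, sd

    def betan_descriptor(
        self, records: Sequence[StabilityRecord], use_oof: bool = False
    ) -> DescriptorTable:
        unused = [
            c for c in self.betan_extra_feature_names
            if c not in CASCADE_FEATURES
        ]
        lig = self._ligand_rows(records)
        return assemble_betan_descriptor(
            records,
            lambda rr: self.predict_beta1(rr, use_oof=use_oof),
            lig,
            unused,
        )

    def predict(self, records: Sequence[StabilityRecord]) -> pd.DataFrame:
        """Predict beta_n with 1-sigma uncertainty for each record.

        n=1 records go through stage one; n>=2 through the cascade.
        """
        out = pd.DataFrame(
            index=pd.RangeIndex(len(records)),
            columns=["beta_pred", "beta_std"],
            dtype=float,
        )
        idx1 = [i for i, r in enumerate(records) if r.n == 1]
        idxn = [i for i, r in enumerate(records) if r.n >= 2]
        if idx1:
            mu, sd = self.predict_beta1([records[i] for i in idx1])
            out.iloc[idx1, 0], out.iloc[idx1, 1] = mu, sd
        if idxn:
            if self.betan_results is None:
                raise ValueError("no beta_n stage in this predictor")
            tab = self.betan_descriptor([records[i] for i in idxn])
            Xz = self.betan_meta.transform(
                tab.data[self.betan_meta.columns]
            )
            mu, sd = self.betan_results.predict(Xz)
            out.iloc[idxn, 0], out.iloc[idxn, 1] = mu, sd
        return out

    # -- serialization ------------------------------------------------------
    @staticmethod
    def _meta_payload(meta: DescriptorTable) -> dict:
        return {
            "columns": meta.columns,
            "provenance": meta.provenance,
            "means": meta.means.to_dict(),
            "scales": meta.scales.to_dict(),
        }

    @staticmethod
    def _meta_from(payload: dict) -> DescriptorTable:
        cols = payload["columns"]
        return DescriptorTable(
            pd.DataFrame(columns=cols, dtype=float),
            payload["provenance"],
            pd.Series(payload["means"])[cols],
            pd.Series(payload["scales"])[cols],
        )

    def to_dict(self) -> dict:
        return {
            "schema": "stabgp.cascade/1",
            "beta1": self.beta1_results.to_dict(),
            "betan": None
            if self.betan_results is None
            else self.betan_results.to_dict(),
            "beta1_meta": self._meta_payload(self.beta1_meta),
            "betan_meta": None
            if self.betan_meta is None
            else self._meta_payload(self.betan_meta),
            "beta1_feature_names": self.beta1_feature_names,
            "betan_extra_feature_names": self.betan_extra_feature_names,
            "ligand_table": {
                "index": list(self.ligand_table.data.index),
                "columns": self.ligand_table.columns,
                "values": self.ligand_table.values.tolist(),
            },
            "cation_table": self.cation_table.reset_index().to_dict(
                orient="list"
            ),
            "oof": None
            if self.oof is None
            else [[list(k), list(v)] for k, v in self.oof.items()],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, payload: dict) -> "CascadePredictor":
        if payload.get("schema") != "stabgp.cascade/1":
            raise ValueError("unrecognized model schema")
        lt = payload["ligand_table"]
        ligand_table = DescriptorTable(
            pd.DataFrame(
                np.array(lt["values"], dtype=float).reshape(
                    len(lt["index"]), len(lt["columns"])
                ),
                index=lt["index"],
                columns=lt["columns"],
            )
        )
        cation_table = pd.DataFrame(payload["cation_table"]).set_index(
            "cation"
        )
        return cls(
            beta1_results=GPResults.from_dict(payload["beta1"]),
            beta1_meta=cls._meta_from(payload["beta1_meta"]),
            beta1_feature_names=payload["beta1_feature_names"],
            ligand_table=ligand_table,
            cation_table=cation_table,
            betan_results=None
            if payload["betan"] is None
            else GPResults.from_dict(payload["betan"]),
            betan_meta=None
            if payload["betan_meta"] is None
            else cls._meta_from(payload["betan_meta"]),
            betan_extra_feature_names=payload["betan_extra_feature_names"],
            oof=None
            if payload["oof"] is None
            else {
                (k[0], k[1]): (v[0], v[1]) for k, v in payload["oof"]
            },
        )

    @classmethod
    def load(cls, path: str | Path) -> "CascadePredictor":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# the model


class StabilityCascade:
    """Two-stage stability-constant model over curated records.

    Parameters
    ----------
    records
        Curated records (post exclusion/deduplication) containing both an
        n=1 stratum and an n>=2 stratum.
    cation_table
        Feature table indexed by ion label with the 12 cation features
        (e.g. :func:`stabgp.features.load_cation_reference` or the
        synthetic generator's table).
    config
        :class:`CascadeConfig`; defaults mirror the printed thresholds
        (|r| > 0.7, VIF < 4, delta = 0.001, 20 validation ligands).
    """

    def __init__(
        self,
        records: Sequence[StabilityRecord],
        cation_table: pd.DataFrame,
        config: CascadeConfig | None = None,
    ):
        self.records = list(records)
        self.cation_table = cation_table
        self.config = config or CascadeConfig()
        self.n1_records = [r for r in self.records if r.n == 1]
        self.nn_records = [r for r in self.records if r.n >= 2]
        if not self.n1_records:
            raise ValueError("no n=1 records: cannot fit the beta_1 stage")
        if not self.nn_records:
            raise ValueError("no n>=2 records: cannot fit the beta_n stage")

    def _ligand_table(self) -> DescriptorTable:
        seen: dict[str, int] = {}
        for r in self.records:
            seen.setdefault(r.canonical_ligand, r.ligand_charge)
        smiles = list(seen)
        table = ligand_descriptors(smiles, [seen[s] for s in smiles])
        return prune_features(
            table, self.config.corr_threshold, self.config.vif_threshold
        )

    def fit(self, seed: int | None = None) -> "CascadeResults":
        """Fit stage one, generate out-of-fold beta_1 features, fit stage two."""
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        ligand_table = self._ligand_table()

        tab = assemble_beta1_descriptor(
            self.n1_records, self.cation_table, ligand_table
        )
        keep = [c for c in tab.columns if tab.data[c].nunique() > 1]
        beta1_std = tab.select(keep).standardized()
        y1 = np.array([r.beta for r in self.n1_records])

        selected = beta1_std.columns
        curve = None
        if cfg.select_features:
            selected, curve = self._select_beta1_features(
                beta1_std, y1, seed
            )
        beta1_results = GaussianProcess(
            beta1_std.data[selected],
            y1,
            column_names=selected,
            max_rows=cfg.max_rows,
            subsample_seed=seed,
        ).fit(n_restarts=cfg.n_restarts, seed=seed, maxiter=cfg.maxiter)

        used_ligand = {
            c for c in selected if beta1_std.provenance.get(c) == "ligand"
        }
        unused_ligand = [
            c for c in ligand_table.columns if c not in used_ligand
        ]
        oof = self._oof_beta1(beta1_std, selected, y1, beta1_results, seed)

        predictor = CascadePredictor(
            beta1_results=beta1_results,
            beta1_meta=beta1_std,
            beta1_feature_names=list(selected),
            ligand_table=ligand_table,
            cation_table=self.cation_table,
            betan_extra_feature_names=list(CASCADE_FEATURES) + unused_ligand,
            oof=oof,
        )
        betan_tab = predictor.betan_descriptor(self.nn_records, use_oof=True)
        keep = [c for c in betan_tab.columns
                if betan_tab.data[c].nunique() > 1]
        betan_std = betan_tab.select(keep).standardized()
        yn = np.array([r.beta for r in self.nn_records])
        betan_results = GaussianProcess(
            betan_std.data,
            yn,
            column_names=betan_std.columns,
            max_rows=cfg.max_rows,
            subsample_seed=seed,
        ).fit(n_restarts=cfg.n_restarts, seed=seed, maxiter=cfg.maxiter)
        predictor.betan_results = betan_results
        predictor.betan_meta = betan_std

        return CascadeResults(
            model=self,
            predictor=predictor,
            feature_curve=curve,
            seed=seed,
        )

    # -- helpers ------------------------------------------------------------
    def _select_beta1_features(self, beta1_std, y1, seed):
        cfg = self.config
        lig_of_row = [r.canonical_ligand for r in self.n1_records]
        ligands = sorted(set(lig_of_row))
        count = min(cfg.validation_count, max(1, len(ligands) // 4))
        lig_means = beta1_std.data.groupby(
            pd.Index(lig_of_row, name="ligand")
        ).mean()
        held_out, _ = select_validation_ligands(
            lig_means, count=count, seed=seed
        )
        held = set(held_out)
        mask = np.array([l in held for l in lig_of_row])
        X_tr, X_va = beta1_std.data[~mask], beta1_std.data[mask]
        y_tr, y_va = y1[~mask], y1[mask]
        probe = GaussianProcess(
            X_tr,
            y_tr,
            column_names=beta1_std.columns,
            max_rows=cfg.selection_max_rows,
            subsample_seed=seed,
        ).fit(n_restarts=cfg.selection_restarts, seed=seed)
        report = feature_relevance_kl(probe, delta=cfg.delta)
        best_k, curve = optimize_feature_count(
            report.ranked_features,
            X_tr,
            y_tr,
            X_va,
            y_va,
            grid=cfg.feature_grid,
            seed=seed,
            n_restarts=cfg.selection_restarts,
            max_rows=cfg.selection_max_rows,
        )
        return report.ranked_features[:best_k], curve

    def _oof_beta1(self, beta1_std, selected, y1, beta1_results, seed):
        """Out-of-fold beta_1 predictions per M-L pair of the n=1 stratum.

        Folds are over n=1 records; each fold's posterior is recomputed at
        the full model's hyperparameters (no re-optimization). The beta_n
        stage therefore never sees an in-sample beta_1 fit for a pair whose
        measured beta_1 was in stage-one training.
        """
        cfg = self.config
        n = len(self.n1_records)
        rng = np.random.default_rng(seed)
        fold = rng.integers(0, cfg.oof_folds, size=n)
        X = beta1_std.data[list(selected)].to_numpy(dtype=float)
        out: dict[tuple, tuple[float, float]] = {}
        for f in range(cfg.oof_folds):
            test = fold == f
            if not test.any() or test.all():
                continue
            sub = GaussianProcess(
                X[~test], y1[~test], column_names=list(selected)
            )
            res = sub.fit(params=beta1_results.params)
            mu, sd = res.predict(X[test])
            for i, idx in enumerate(np.flatnonzero(test)):
                out[self.n1_records[idx].pair] = (float(mu[i]), float(sd[i]))
        return out


# ---------------------------------------------------------------------------
# results


@dataclass
class CascadeResults:
    """Fitted two-stage model: both GP results plus the feature partition."""

    model: StabilityCascade
    predictor: CascadePredictor
    feature_curve: object | None = None
    seed: int = 0
    _relevance: RelevanceReport | None = field(default=None, repr=False)

    @property
    def beta1_results(self) -> GPResults:
        return self.predictor.beta1_results

    @property
    def betan_results(self) -> GPResults:
        return self.predictor.betan_results

    @property
    def beta1_feature_names(self) -> list[str]:
        return self.predictor.beta1_feature_names

    @property
    def betan_extra_feature_names(self) -> list[str]:
        return self.predictor.betan_extra_feature_names

    def predict(self, records: Sequence[StabilityRecord]) -> pd.DataFrame:
        return self.predictor.predict(records)

    def predict_beta1(self, records: Sequence[StabilityRecord]):
        return self.predictor.predict_beta1(records)

    def betan_relevance(self, delta: float | None = None) -> RelevanceReport:
        """KL sensitivity report of the stage-two model."""
        if self._relevance is None or delta is not None:
            cfg = self.model.config
            d = cfg.delta if delta is None else delta
            X_eval = None
            n = self.betan_results.model.nobs
            if cfg.relevance_rows is not None and n > cfg.relevance_rows:
                rng = np.random.default_rng(self.seed)
                idx = np.sort(
                    rng.choice(n, size=cfg.relevance_rows, replace=False)
                )
                X_eval = self.betan_results.model.X[idx]
            self._relevance = feature_relevance_kl(
                self.betan_results, X_eval=X_eval, delta=d
            )
        return self._relevance

    def correlation_by_n(self) -> dict[int, float]:
        """Per-n Pearson r between predicted beta_1 and measured beta_n on
        the training records (out-of-fold beta_1 where available)."""
        mu, _ = self.predictor.predict_beta1(
            self.model.nn_records, use_oof=True
        )
        return beta1_betan_correlation(mu, self.model.nn_records)

    def summary(self) -> str:
        lines = [
            "Two-Stage Stability-Constant Model",
            "=" * 52,
            f"beta_1 stage: {self.beta1_results.model.nobs} records, "
            f"{len(self.beta1_feature_names)} features",
            f"beta_n stage: {self.betan_results.model.nobs} records, "
            f"{len(self.predictor.betan_meta.columns)} features",
            f"beta_n cascade features: {list(CASCADE_FEATURES)}",
            "",
            "Per-n Pearson r (predicted beta_1 vs measured beta_n):",
        ]
        for n, r in self.correlation_by_n().items():
            lines.append(f"  n={n}: r = {r:.3f}")
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        self.predictor.save(path)


def fit_cascade(
    records: Sequence[StabilityRecord],
    cation_table: pd.DataFrame,
    config: CascadeConfig | None = None,
    seed: int | None = None,
) -> CascadeResults:
    """Convenience wrapper: build and fit a :class:`StabilityCascade`."""
    return StabilityCascade(records, cation_table, config).fit(seed=seed)
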