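"""Feature-relevance analysis for fitted GP models.

Relevance is measured by sensitivity analysis rather than by inverse
length scales: each (standardized) feature column is perturbed by a small
delta (default 0.001) at every evaluation row, and the Kullback-Leibler
divergence from the unperturbed univariate predictive Gaussian to the
perturbed one is averaged over rows. Scores are normalized to sum to 1
("standardized relevance") and ranked.

The module also provides the MAE/R^2 evaluation helpers, the
applicability-domain-aware validation-ligand selection (held-out ligands
biased toward the edge of the training domain), and the feature-count
optimization that refits the GP on the top-k ranked features and tracks
validation performance as a function of k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import mean_absolute_error, r2_score

from .gpr import GaussianProcess, GPResults, _ard_distance

__all__ = [
    "RelevanceReport",
    "FeatureCurve",
    "feature_relevance_kl",
    "evaluate",
    "select_validation_ligands",
    "optimize_feature_count",
    "default_feature_grid",
]


@dataclass
class RelevanceReport:
    """Per-feature relevance scores with ranking.

    ``standardized`` is non-negative and sums to 1; ``rank_order`` lists
    feature indices in descending relevance.
    """

    feature_names: list[str]
    raw: np.ndarray
    standardized: np.ndarray
    rank_order: np.ndarray
    delta: float

    @property
    def ranked_features(self) -> list[str]:
        return [self.feature_names[i] for i in self.rank_order]

    def top(self, k: int) -> list[str]:
        return self.ranked_features[:k]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "feature": self.feature_names,
                "raw_relevance": self.raw,
                "standardized_relevance": self.standardized,
            }
        )
        # rank of feature i = its position in rank_order
        pos = np.empty(len(self.feature_names), dtype=int)
        pos[self.rank_order] = np.arange(len(self.feature_names))
        df["rank"] = pos + 1
        return df.sort_values("rank").reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def bar_summary(self, k: int = 10, width: int = 40) -> str:
        """Plain-text ranked-bar chart of the top-k features."""
        df = self.to_frame().head(k)
        top = df["standardized_relevance"].max() or 1.0
        lines = [f"Top {len(df)} features by standardized relevance "
                 f"(delta={self.delta})"]
        for _, row in df.iterrows():
            bar = "#" * max(1, int(width * row.standardized_relevance / top))
            lines.append(
                f"{row['feature']:<32s} {row.standardized_relevance:7.4f} {bar}"
            )
        return "\n".join(lines)


def _kl_gaussian(mu0, s0, mu1, s1) -> np.ndarray:
    """KL(N(mu0, s0^2) || N(mu1, s1^2)), elementwise."""
    return (
        np.log(s1 / s0) + (s0**2 + (mu0 - mu1) ** 2) / (2.0 * s1**2) - 0.5
    )


def feature_relevance_kl(
    results: GPResults, X_eval=None, delta: float = 0.001
) -> RelevanceReport:
    """KL-divergence sensitivity of the predictive distribution per feature.

    For each feature m, column m of ``X_eval`` (default: the training
    rows) is shifted by +delta in standardized units; the raw score is the
    mean over rows of KL(unperturbed || perturbed) between the univariate
    predictive Gaussians. Standardized relevance normalizes raw scores to
    sum to 1.
    """
    model = results.model
    X0 = model.X if X_eval is None else results._coerce(X_eval)
    mu0, s0 = results.predict(X0)
    s0 = np.maximum(s0, 1e-300)
    d = model.dim
    raw = np.empty(d)
    for m in range(d):
        Xp = X0.copy()
        Xp[:, m] += delta
        mu1, s1 = results.predict(Xp)
        s1 = np.maximum(s1, 1e-300)
        raw[m] = float(np.mean(_kl_gaussian(mu0, s0, mu1, s1)))
    raw = np.maximum(raw, 0.0)  # clip fp noise; KL >= 0
    total = raw.sum()
    # typical per-feature KL at delta=1e-3 is >= 1e-10; anything below the
    # floor is round-off from a model flat in every direction
    if total <= d * 1e-16:
        raise ValueError("model insensitive to all features")
    standardized = raw / total
    rank_order = np.argsort(-standardized, kind="stable")
    names = model.column_names or [f"x{m}" for m in range(d)]
    return RelevanceReport(list(names), raw, standardized, rank_order, delta)


def evaluate(predictions, truth) -> tuple[float, float]:
    """(MAE, R^2) of predictions against truth."""
    predictions = np.asarray(predictions, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if predictions.size != truth.size or truth.size < 2:
        raise ValueError("need equal-length arrays with >= 2 entries")
    if np.ptp(truth) == 0:
        raise ValueError("R^2 undefined: truth has zero variance")
    return (
        float(mean_absolute_error(truth, predictions)),
        float(r2_score(truth, predictions)),
    )


def select_validation_ligands(
    ligand_features: pd.DataFrame,
    count: int = 20,
    seed: int = 0,
    length_scales=None,
    n_strata: int = 5,
    min_top_stratum: int = 4,
) -> tuple[list[str], pd.Series]:
    """Pick held-out validation ligands spanning the applicability domain.

    Per ligand, the mean ARD distance to all other ligands (in the given
    standardized ligand-feature space; ``length_scales`` default to 1) is
    computed, ligands are stratified into ``n_strata`` quantile bands of
    that distance, and ``count`` ligands are sampled near-uniformly across
    bands with the top (most distant, i.e. edge-of-domain) band guaranteed
    at least ``min_top_stratum`` picks, always including the single most
    distant ligand. Returns (selected ligand ids, the distance series).
    """
    ids = list(ligand_features.index)
    if count >= len(ids):
        raise ValueError(
            f"count={count} must be < number of ligands ({len(ids)})"
        )
    X = ligand_features.to_numpy(dtype=float)
    l = (
        np.ones(X.shape[1])
        if length_scales is None
        else np.asarray(length_scales, dtype=float)
    )
    D = _ard_distance(X, X, l)
    mean_dist = pd.Series(
        (D.sum(axis=1)) / (len(ids) - 1), index=ids, name="mean_ard_distance"
    )
    order = np.argsort(mean_dist.to_numpy(), kind="stable")
    strata = np.array_split(order, n_strata)

    per = [count // n_strata] * n_strata
    for i in range(count % n_strata):
        per[-1 - i] += 1
    per[-1] = max(per[-1], min_top_stratum)
    while sum(per) > count:
        for i in range(n_strata):  # shave from the bottom strata
            if sum(per) == count:
                break
            if per[i] > 0 and i < n_strata - 1:
                per[i] -= 1

    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    farthest = int(order[-1])
    for s, k in zip(strata, per):
        pool = [i for i in s if i != farthest]
        k_here = min(k, len(pool))
        if k_here > 0:
            chosen.extend(rng.choice(pool, size=k_here, replace=False))
    chosen.append(farthest)  # edge of the applicability domain, always in
    while len(chosen) > count:
        chosen.pop(0)
    # top up from unused ligands if strata were too small
    if len(chosen) < count:
        unused = [i for i in range(len(ids)) if i not in set(chosen)]
        chosen.extend(
            rng.choice(unused, size=count - len(chosen), replace=False)
        )
    selected = [ids[i] for i in chosen]
    return selected, mean_dist


@dataclass
class FeatureCurve:
    """Validation MAE/R^2 as a function of the feature count k."""

    table: pd.DataFrame  # columns: k, mae, r2, failed

    def best_k(self) -> int:
        ok = self.table[~self.table["failed"]]
        if ok.empty:
            raise ValueError("every feature-count fit failed")
        best_mae = ok["mae"].min()
        return int(ok.loc[ok["mae"] <= best_mae, "k"].min())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def default_feature_grid(d: int) -> list[int]:
    """Every k in 1..min(d, 20) plus multiples of 5 up to d."""
    grid = set(range(1, min(d, 20) + 1))
    grid.update(range(5, d + 1, 5))
    grid.add(d)
    return sorted(grid)


def optimize_feature_count(
    ranked_features: list[str],
    X_train: pd.DataFrame,
    y_train,
    X_valid: pd.DataFrame,
    y_valid,
    grid: list[int] | None = None,
    *,
    seed: int = 0,
    n_restarts: int = 3,
    max_rows: int | None = None,
) -> tuple[int, FeatureCurve]:
    """Refit on top-k ranked features for each k; pick the min-MAE k.

    Ties in MAE break toward smaller k. A k whose fit fails is recorded
    with ``failed=True`` and skipped by :meth:`FeatureCurve.best_k`.
    """
    d = len(ranked_features)
    grid = sorted(set(grid)) if grid else default_feature_grid(d)
    if any(k < 1 or k > d for k in grid):
        raise ValueError("grid entries must lie in [1, d]")
    rows = []
    for k in grid:
        cols = ranked_features[:k]
        try:
            res = GaussianProcess(
                X_train[cols],
                y_train,
                column_names=cols,
                max_rows=max_rows,
                subsample_seed=seed,
            ).fit(n_restarts=n_restarts, seed=seed)
            mu, _ = res.predict(X_valid[cols])
            mae, r2 = evaluate(mu, y_valid)
            rows.append({"k": k, "mae": mae, "r2": r2, "failed": False})
        except (np.linalg.LinAlgError, ValueError):
            rows.append(
                {"k": k, "mae": np.nan, "r2": np.nan, "failed": True}
            )
    curve = FeatureCurve(pd.DataFrame(rows))
    return curve.best_k(), curve
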