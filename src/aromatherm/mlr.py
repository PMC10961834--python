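"""Reparameterization of group-contribution values by multiple linear regression.

The group-additivity model is y = X w with y the (magnitudes of)
formation enthalpies, X the molecules-by-features count matrix (Benson
groups plus positional correction columns) and w the per-feature
contributions.  There is no intercept: pure additivity has no free
constant (an optional intercept flag exists for sensitivity analysis).

Evaluation follows a single hold-out split (default 70/30, via
scikit-learn's ``train_test_split`` so published seeds reproduce the
same partitions) with R^2, MAE and RMSE on both sides.  Exactly aliased
(linearly dependent) columns are dropped deterministically — the later
column goes — before fitting; remaining rank deficiency is an error
naming the offending columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import mean_absolute_error, r2_score
from sklearn.model_selection import train_test_split

from .benson import GroupVector
from .quantities import ThermoError

_RANK_TOL = 1e-10


@dataclass(frozen=True)
class GCDataset:
    """Molecules-by-groups design with target formation enthalpies.

    ``X`` has one row per molecule and one column per feature label;
    ``y`` is in kJ/mol on the -dfH magnitude convention.
    """

    molecules: tuple[str, ...]
    features: tuple[str, ...]
    X: np.ndarray
    y: np.ndarray
    phase: str = "gas"

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ThermoError("X rows must match y length")
        if X.shape[0] != len(self.molecules):
            raise ThermoError("molecule list must match X rows")
        if X.shape[1] != len(self.features):
            raise ThermoError("feature list must match X columns")
        if len(set(self.features)) != len(self.features):
            raise ThermoError("feature labels must be unique")
        if np.any(~X.any(axis=1)):
            raise ThermoError("all-zero design rows are not allowed")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def subset(self, idx: np.ndarray) -> "GCDataset":
        return GCDataset(
            molecules=tuple(self.molecules[i] for i in idx),
            features=self.features,
            X=self.X[idx],
            y=self.y[idx],
            phase=self.phase,
        )


@dataclass(frozen=True)
class RegressionResult:
    """Fitted weights plus split bookkeeping and train/test metrics."""

    weights: dict[str, float]
    metrics_train: dict[str, float]
    metrics_test: dict[str, float]
    train_molecules: tuple[str, ...] = ()
    test_molecules: tuple[str, ...] = ()
    seed: int | None = None
    dropped_features: tuple[str, ...] = ()
    intercept: float = 0.0


class MulticollinearityError(ThermoError):
    """The design matrix is rank-deficient beyond exact aliasing."""


def holdout_split(
    ds: GCDataset, test_fraction: float = 0.3, seed: int = 0
) -> tuple[GCDataset, GCDataset]:
    """Deterministic hold-out partition; |test| = ceil(n * test_fraction)."""
    if not 0 < test_fraction < 1:
        raise ThermoError("test_fraction must be in (0, 1)")
    if ds.n < 4:
        raise ThermoError("need at least 4 molecules to split")
    idx = np.arange(ds.n)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, shuffle=True
    )
    if len(train_idx) == 0 or len(test_idx) == 0:
        raise ThermoError("degenerate split: one side is empty")
    return ds.subset(np.sort(train_idx)), ds.subset(np.sort(test_idx))


def _drop_aliased(X: np.ndarray, features: tuple[str, ...]):
    """Keep a maximal prefix-greedy independent column set (later columns drop)."""
    kept: list[int] = []
    dropped: list[str] = []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial, tol=_RANK_TOL * max(1.0, np.abs(X).max())) == len(kept) + 1:
            kept.append(j)
        else:
            dropped.append(features[j])
    return kept, dropped


def fit_ols(
    train: GCDataset,
    test: GCDataset | None = None,
    seed: int | None = None,
    intercept: bool = False,
) -> RegressionResult:
    """Ordinary least squares minimizing the summed squared residuals.

    Exact linear dependencies are dropped (later column first) before
    the solve; if the retained design is still rank-deficient the fit
    aborts with :class:`MulticollinearityError`.
    """
    X = train.X
    kept, dropped = _drop_aliased(X, train.features)
    Xk = X[:, kept]
    design = np.column_stack([Xk, np.ones(len(Xk))]) if intercept else Xk
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise MulticollinearityError(
            f"design rank {rank} < {design.shape[1]} columns after alias dropping"
        )
    coef, _, _, _ = np.linalg.lstsq(design, train.y, rcond=None)
    if intercept:
        w, b = coef[:-1], float(coef[-1])
    else:
        w, b = coef, 0.0
    weights = {train.features[j]: float(wj) for j, wj in zip(kept, w)}

    def _predict(ds: GCDataset) -> np.ndarray:
        return ds.X[:, kept] @ w + b

    m_train = metrics(train.y, _predict(train))
    m_test = (
        metrics(test.y, _predict(test))
        if test is not None
        else {"R2": float("nan"), "MAE": float("nan"), "RMSE": float("nan")}
    )
    return RegressionResult(
        weights=weights,
        metrics_train=m_train,
        metrics_test=m_test,
        train_molecules=train.molecules,
        test_molecules=test.molecules if test is not None else (),
        seed=seed,
        dropped_features=tuple(dropped),
        intercept=b,
    )


def metrics(y_true, y_pred) -> dict[str, float]:
    """R^2 (about the mean of y_true), MAE and RMSE."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ThermoError("metrics need equal nonzero-length inputs")
    if np.allclose(y_true, y_true[0]):
        raise ThermoError("R^2 undefined: zero variance in y_true")
    err = y_true - y_pred
    return {
        "R2": float(r2_score(y_true, y_pred)),
        "MAE": float(mean_absolute_error(y_true, y_pred)),
        "RMSE": float(math.sqrt(np.mean(err**2))),
    }


def predict(res: RegressionResult, gv: GroupVector | dict[str, int]) -> float:
    """Dot product of feature counts with fitted weights.

    A nonzero count on a feature the fit never retained is an
    extrapolation error (the model carries no value for it).
    """
    if isinstance(gv, GroupVector):
        counts: dict[str, float] = dict(gv.counts)
        for (kind, pos), c in gv.pair_corrections.items():
            counts[f"{kind} {pos}"] = c
    else:
        counts = dict(gv)
    total = res.intercept
    for feature, count in counts.items():
        if count == 0:
            continue
        if feature not in res.weights:
            raise ThermoError(
                f"feature {feature!r} has nonzero count but no fitted weight "
                "(dropped or unseen); refusing to extrapolate"
            )
        total += count * res.weights[feature]
    return float(total)


def collinearity_report(ds: GCDataset) -> dict:
    """Condition number, maximal pairwise correlation and aliased column sets."""
    X = ds.X
    sv = np.linalg.svd(X, compute_uv=False)
    nonzero = sv[sv > _RANK_TOL * sv.max()] if sv.max() > 0 else sv
    cond = float(nonzero.max() / nonzero.min()) if nonzero.size else float("inf")

    max_corr = 0.0
    max_pair: tuple[str, str] | None = None
    flagged: list[tuple[str, str, float]] = []
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    for i in range(X.shape[1]):
        for j in range(i + 1, X.shape[1]):
            rho = abs(float(corr[i, j])) if np.isfinite(corr[i, j]) else 0.0
            if rho > max_corr:
                max_corr, max_pair = rho, (ds.features[i], ds.features[j])
            if rho > 0.95:
                flagged.append((ds.features[i], ds.features[j], rho))

    # exact-alias sets: columns identical up to scale
    alias_sets: list[tuple[str, ...]] = []
    assigned: set[int] = set()
    for i in range(X.shape[1]):
        if i in assigned:
            continue
        group = [i]
        for j in range(i + 1, X.shape[1]):
            if j in assigned:
                continue
            a, b = X[:, i], X[:, j]
            denom = float(b @ b)
            scale = float(a @ b) / denom if denom else 0.0
            if denom and np.allclose(a, scale * b, atol=1e-12):
                group.append(j)
                assigned.add(j)
        if len(group) > 1:
            alias_sets.append(tuple(ds.features[k] for k in group))
    return {
        "condition_number": cond,
        "max_pairwise_correlation": max_corr,
        "max_pairwise_correlation_pair": max_pair,
        "flagged_pairs": flagged,
        "aliased_sets": alias_sets,
    }


def read_dataset_csv(path, phase: str = "gas") -> GCDataset:
    """Load ``molecule, <feature counts...>, y_kJ_per_mol`` CSV."""
    df = pd.read_csv(path)
    if "y_kJ_per_mol" not in df.columns:
        raise ThermoError("dataset CSV must end with a y_kJ_per_mol column")
    id_col = df.columns[0]
    features = [c for c in df.columns if c not in (id_col, "y_kJ_per_mol")]
    return GCDataset(
        molecules=tuple(df[id_col].astype(str)),
        features=tuple(features),
        X=df[features].to_numpy(dtype=float),
        y=df["y_kJ_per_mol"].to_numpy(dtype=float),
        phase=phase,
    )
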