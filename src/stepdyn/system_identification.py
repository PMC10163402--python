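"""Least-squares estimation of the per-participant, per-day-type ARX model.

Design rows use outputs at lags 1..5 and the three message inputs at lags
0..5 (24 coefficients including the intercept).  A row is emitted only when
the target epoch and all lagged epochs are valid and belong to the same
day, so message effects are never modeled across days.  Weekday and
weekend models are fit on disjoint row sets (switched structure).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from .arx import CHANNELS, DEFAULT_ORDER, ArxCoefficients, n_coefficients
from .preprocessing import EpochSeries


class InsufficientDataError(ValueError):
    pass


def design_column_names(order: int = DEFAULT_ORDER) -> list[str]:
    names = ["intercept"] + [f"y_lag{i}" for i in range(1, order + 1)]
    for ch in CHANNELS:
        names += [f"u_{ch}_lag{i}" for i in range(0, order + 1)]
    return names


@dataclass
class RegressionDesign:
    X: np.ndarray  # (n_rows, n_coefficients)
    y_target: np.ndarray  # (n_rows,)
    order: int = DEFAULT_ORDER
    column_names: list[str] = field(default_factory=design_column_names)

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


@dataclass
class ArxModel:
    coeffs: ArxCoefficients
    sigma2: float
    cov: np.ndarray  # (p, p) coefficient covariance, zeros for dropped columns
    n_rows: int
    fit_rmse: float
    flags: list[str] = field(default_factory=list)
    dropped_columns: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coeffs.to_dict(),
            "sigma2": self.sigma2,
            "cov": self.cov.tolist(),
            "n_rows": self.n_rows,
            "fit_rmse": self.fit_rmse,
            "flags": self.flags,
            "dropped_columns": self.dropped_columns,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArxModel":
        return cls(
            coeffs=ArxCoefficients.from_dict(d["coefficients"]),
            sigma2=float(d["sigma2"]),
            cov=np.asarray(d["cov"], dtype=float),
            n_rows=int(d["n_rows"]),
            fit_rmse=float(d["fit_rmse"]),
            flags=list(d.get("flags", [])),
            dropped_columns=list(d.get("dropped_columns", [])),
        )

    def save(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: Path | str) -> "ArxModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_design(
    series: list[EpochSeries], order: int = DEFAULT_ORDER
) -> RegressionDesign:
    """Stack regression rows from all days of one participant/day-type.

    A row targets epoch ``k`` iff ``k >= order`` within its day and epochs
    ``k-order..k`` are all valid.
    """
    if not series:
        raise InsufficientDataError("no epoch series supplied")
    day_types = {s.day_type for s in series}
    if len(day_types) > 1:
        raise ValueError("series mix weekday and weekend days")
    rows, targets = [], []
    for s in series:
        n = s.n_epochs
        for k in range(order, n):
            if not s.valid[k - order : k + 1].all():
                continue
            row = [1.0]
            row.extend(s.y[k - i] for i in range(1, order + 1))
            for j in range(len(CHANNELS)):
                row.extend(s.u[j, k - i] for i in range(0, order + 1))
            rows.append(row)
            targets.append(s.y[k])
    if not rows:
        raise InsufficientDataError("insufficient data: no eligible rows")
    return RegressionDesign(
        X=np.asarray(rows, dtype=float),
        y_target=np.asarray(targets, dtype=float),
        order=order,
        column_names=design_column_names(order),
    )


def fit_least_squares(design: RegressionDesign, ridge: float = 0.0) -> ArxModel:
    """Ordinary least squares via QR, with flagged column-dropping.

    Columns that are identically zero (e.g. a message type never delivered
    on that day type) are dropped, their coefficients set to 0 and the
    model flagged ``rank_deficient``.  Residual variance uses an
    ``n - p_used`` denominator; ``cov = sigma2 * (X'X)^-1`` on the kept
    columns (zero elsewhere).  ``ridge > 0`` adds an L2 penalty for stress
    cases and is flagged.
    """
    X, y = design.X, design.y_target
    n, p = X.shape
    if n < p:
        raise InsufficientDataError(f"only {n} rows for {p} coefficients")
    flags: list[str] = []

    keep = np.ptp(X, axis=0) > 0
    keep[0] = True  # intercept
    dropped = [design.column_names[i] for i in range(p) if not keep[i]]
    if dropped:
        flags.append("rank_deficient")
    Xk = X[:, keep]

    # drop further columns until full rank (pivoted QR)
    while True:
        p_used = Xk.shape[1]
        if n < p_used:
            raise InsufficientDataError(
                f"only {n} rows for {p_used} coefficients"
            )
        rank = np.linalg.matrix_rank(Xk)
        if rank == p_used:
            break
        _, _, piv = scipy.linalg.qr(Xk, mode="economic", pivoting=True)
        worst = piv[-1]
        kept_idx = np.flatnonzero(keep)
        dropped.append(design.column_names[kept_idx[worst]])
        keep[kept_idx[worst]] = False
        Xk = X[:, keep]
        if "rank_deficient" not in flags:
            flags.append("rank_deficient")

    if ridge > 0:
        flags.append("ridge")
        A = Xk.T @ Xk + ridge * np.eye(Xk.shape[1])
        beta_k = np.linalg.solve(A, Xk.T @ y)
    else:
        beta_k, *_ = np.linalg.lstsq(Xk, y, rcond=None)

    resid = y - Xk @ beta_k
    rss = float(resid @ resid)
    p_used = Xk.shape[1]
    dof = max(n - p_used, 1)
    sigma2 = rss / dof
    xtx_inv = np.linalg.inv(Xk.T @ Xk)
    cov_k = sigma2 * xtx_inv

    beta = np.zeros(p)
    beta[keep] = beta_k
    cov = np.zeros((p, p))
    cov[np.ix_(keep, keep)] = cov_k

    coeffs = ArxCoefficients.from_vector(beta, order=design.order)
    if not coeffs.is_stable():
        flags.append("unstable")
    return ArxModel(
        coeffs=coeffs,
        sigma2=sigma2,
        cov=cov,
        n_rows=n,
        fit_rmse=float(np.sqrt(rss / n)),
        flags=flags,
        dropped_columns=dropped,
    )


def predict(model: ArxModel, design: RegressionDesign) -> tuple[np.ndarray, np.ndarray]:
    """One-step-ahead predictions and residuals on a design."""
    beta = model.coeffs.to_vector()
    if design.X.shape[1] != beta.shape[0]:
        raise ValueError("design/model dimension mismatch")
    yhat = design.X @ beta
    return yhat, design.y_target - yhat


def standard_errors(model: ArxModel) -> np.ndarray:
    return np.sqrt(np.diag(model.cov))


def fit_participant(
    series: list[EpochSeries], order: int = DEFAULT_ORDER, ridge: float = 0.0
) -> dict[str, ArxModel]:
    """Fit the switched weekday/weekend models for one participant."""
    from .preprocessing import split_day_type

    models: dict[str, ArxModel] = {}
    for day_type, group in split_day_type(series).items():
        if not group:
            continue
        design = build_design(group, order=order)
        models[day_type] = fit_least_squares(design, ridge=ridge)
    return models
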