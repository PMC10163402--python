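"""Core ARX (autoregressive with exogenous inputs) primitives.

The epoch-level model shared by the simulator, the estimator, and the
response simulator:

    y(k) = a0 + sum_{i=1..p} a_i * y(k-i)
              + sum_j sum_{i=0..p} b_{j,i} * u_j(k-i) + eps(k)

with p = 5 output lags, three binary input channels (one per message
library) at lags 0..5, and a 15-minute sampling interval.  Lags that fall
before the start of a day are treated as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical message-channel order used everywhere (arrays, CSV columns).
CHANNELS: tuple[str, str, str] = ("affective", "social_cognitive", "quote")

#: Default model order (output lags; inputs use lags 0..ORDER).
DEFAULT_ORDER = 5

#: Sampling interval in minutes.
EPOCH_MINUTES = 15


@dataclass(frozen=True)
class ArxCoefficients:
    """Coefficient set of one ARX model.

    Parameters
    ----------
    a0
        Intercept.
    a
        Output-lag coefficients, shape ``(order,)`` for lags 1..order.
    b
        Input coefficients, shape ``(3, order + 1)`` for the three message
        channels at lags 0..order (channel order :data:`CHANNELS`).
    """

    a0: float
    a: np.ndarray
    b: np.ndarray
    order: int = DEFAULT_ORDER
    d: int = EPOCH_MINUTES

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.shape != (self.order,):
            raise ValueError(f"a must have shape ({self.order},), got {a.shape}")
        if b.shape != (len(CHANNELS), self.order + 1):
            raise ValueError(
                f"b must have shape (3, {self.order + 1}), got {b.shape}"
            )
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    # -- stability ---------------------------------------------------------
    def spectral_radius(self) -> float:
        """Spectral radius of the companion matrix of the output lags."""
        comp = np.zeros((self.order, self.order))
        comp[0, :] = self.a
        comp[1:, :-1] = np.eye(self.order - 1)
        return float(np.max(np.abs(np.linalg.eigvals(comp))))

    def is_stable(self, tol: float = 0.0) -> bool:
        return self.spectral_radius() < 1.0 - tol

    def dc_gain(self, channel: int) -> float:
        """Steady-state cumulative effect of a unit impulse on ``channel``.

        Equals ``sum_i b[channel, i] / (1 - sum_i a_i)`` for stable models.
        """
        return float(self.b[channel].sum() / (1.0 - self.a.sum()))

    # -- (de)serialisation -------------------------------------------------
    def to_vector(self) -> np.ndarray:
        """Flatten as ``[a0, a_1..a_p, b_ch0 lags 0..p, b_ch1 ..., b_ch2 ...]``."""
        return np.concatenate([[self.a0], self.a, self.b.ravel()])

    @classmethod
    def from_vector(cls, beta: np.ndarray, order: int = DEFAULT_ORDER) -> "ArxCoefficients":
        beta = np.asarray(beta, dtype=float)
        n_expected = 1 + order + len(CHANNELS) * (order + 1)
        if beta.shape != (n_expected,):
            raise ValueError(f"expected {n_expected} coefficients, got {beta.shape}")
        a0 = float(beta[0])
        a = beta[1 : 1 + order]
        b = beta[1 + order :].reshape(len(CHANNELS), order + 1)
        return cls(a0=a0, a=a, b=b, order=order)

    def to_dict(self) -> dict:
        return {
            "a0": self.a0,
            "a": self.a.tolist(),
            "b": {ch: self.b[j].tolist() for j, ch in enumerate(CHANNELS)},
            "order": self.order,
            "d": self.d,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArxCoefficients":
        order = int(d.get("order", DEFAULT_ORDER))
        b = np.array([d["b"][ch] for ch in CHANNELS], dtype=float)
        return cls(
            a0=float(d["a0"]),
            a=np.asarray(d["a"], dtype=float),
            b=b,
            order=order,
            d=int(d.get("d", EPOCH_MINUTES)),
        )


def n_coefficients(order: int = DEFAULT_ORDER) -> int:
    """Total number of free coefficients: 1 + order + 3*(order+1)."""
    return 1 + order + len(CHANNELS) * (order + 1)


def simulate_arx(
    coeffs: ArxCoefficients,
    u: np.ndarray,
    noise: np.ndarray | None = None,
) -> np.ndarray:
    """Run the ARX recursion over one day of epochs.

    Parameters
    ----------
    coeffs
        Model coefficients.
    u
        Binary inputs, shape ``(3, n_epochs)``.
    noise
        Optional additive noise per epoch, shape ``(n_epochs,)``.

    Pre-day lags (indices < 0) are zero.  The output is the *latent* epoch
    series and is not clipped at zero.
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 2 or u.shape[0] != len(CHANNELS):
        raise ValueError(f"u must have shape (3, n), got {u.shape}")
    n = u.shape[1]
    p = coeffs.order
    y = np.zeros(n)
    eps = np.zeros(n) if noise is None else np.asarray(noise, dtype=float)
    for k in range(n):
        acc = coeffs.a0
        for i in range(1, p + 1):
            if k - i >= 0:
                acc += coeffs.a[i - 1] * y[k - i]
        for j in range(len(CHANNELS)):
            for i in range(0, p + 1):
                if k - i >= 0:
                    acc += coeffs.b[j, i] * u[j, k - i]
        y[k] = acc + eps[k]
    return y


def impulse_response(
    coeffs: ArxCoefficients, channel: int, horizon: int
) -> np.ndarray:
    """Deviation response to a single unit input on ``channel`` at epoch 0.

    The intercept cancels out of the deviation-from-baseline trajectory, so
    only the output lags and the channel's input coefficients enter.
    """
    p = coeffs.order
    y = np.zeros(horizon)
    bc = coeffs.b[channel]
    for k in range(horizon):
        acc = bc[k] if k <= p else 0.0
        for i in range(1, p + 1):
            if k - i >= 0:
                acc += coeffs.a[i - 1] * y[k - i]
        y[k] = acc
    return y


def impulse_response_batch(
    a: np.ndarray, b_channel: np.ndarray, horizon: int
) -> np.ndarray:
    """Vectorised impulse responses for a batch of coefficient draws.

    ``a`` has shape ``(B, order)``; ``b_channel`` shape ``(B, order + 1)``.
    Returns an array of shape ``(B, horizon)``.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b_channel = np.atleast_2d(np.asarray(b_channel, dtype=float))
    B, p = a.shape
    y = np.zeros((B, horizon))
    for k in range(horizon):
        acc = b_channel[:, k].copy() if k <= p else np.zeros(B)
        for i in range(1, p + 1):
            if k - i >= 0:
                acc += a[:, i - 1] * y[:, k - i]
        y[:, k] = acc
    return y
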