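"""Boxcar paradigm, canonical HRF and the 12-parameter fNIRS signal model.

The observed per-channel oxy-hemoglobin series is modelled as

    y(k) = a0 + a1 * (h * u)(k)
         + a_c sin(2 pi f_c t_k) + a_r sin(2 pi f_r t_k) + a_m sin(2 pi f_m t_k)
         + noise

where ``u`` is the 0/1 task boxcar, ``h`` the canonical double-gamma HRF,
``a0`` a baseline, ``a1`` the activity-strength coefficient and the three
sinusoids model cardiac, respiratory and Mayer-wave physiological
oscillations.  Time ``t_k = k / fs`` is in seconds so that the frequency
parameters are in Hz (the cardiac bound of 0.5-1.5 only makes sense in Hz).

Twelve parameters are free, in the canonical ordering

    (alpha1, alpha2, beta1, beta2, a0, a1, a_c, a_m, a_r, f_c, f_r, f_m)

with the box constraints returned by :func:`default_bounds`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma as _gamma_fn

__all__ = [
    "PARAM_NAMES",
    "Paradigm",
    "ModelParameters",
    "canonical_hrf",
    "evoked_response",
    "model_signal",
    "cost",
    "default_bounds",
]

#: Canonical parameter ordering used for every 12-vector in the package.
PARAM_NAMES = (
    "alpha1",
    "alpha2",
    "beta1",
    "beta2",
    "a0",
    "a1",
    "a_c",
    "a_m",
    "a_r",
    "f_c",
    "f_r",
    "f_m",
)

# Box constraints on the 12 free parameters.
_DEFAULT_BOUNDS = {
    "alpha1": (2.0, 10.0),
    "alpha2": (6.0, 20.0),
    "beta1": (0.5, 2.0),
    "beta2": (0.0, 1.5),
    "a0": (0.0, 20.0),
    "a1": (0.0, 15.0),
    "a_c": (0.0, 2.0),
    "a_m": (0.0, 2.0),
    "a_r": (0.0, 2.0),
    "f_c": (0.5, 1.5),
    "f_r": (0.2, 0.3),
    "f_m": (0.09, 0.1),
}


def default_bounds(as_dict: bool = False):
    """Return the 12 (lower, upper) box constraints in canonical order.

    Parameters
    ----------
    as_dict
        If True return ``{name: (lo, hi)}``, otherwise an array of shape
        ``(12, 2)`` ordered like :data:`PARAM_NAMES`.
    """
    if as_dict:
        return dict(_DEFAULT_BOUNDS)
    return np.array([_DEFAULT_BOUNDS[name] for name in PARAM_NAMES])


@dataclass(frozen=True)
class Paradigm:
    """Block-design rest/task/rest stimulus on a fixed sampling grid.

    The default 10 s rest / 10 s task / 30 s rest at 1.81 Hz gives 90 samples
    over 50 s.  ``n_trials`` repeats the block back-to-back with a continuous
    time axis (phase of the physiological sinusoids carries across blocks).
    """

    fs: float = 1.81
    rest_pre: float = 10.0
    task: float = 10.0
    rest_post: float = 30.0
    n_trials: int = 1

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate fs must be positive")
        if min(self.rest_pre, self.task, self.rest_post) < 0:
            raise ValueError("paradigm durations must be nonnegative")
        if self.n_trials < 1:
            raise ValueError("n_trials must be at least 1")
        if self.n_samples < 1:
            raise ValueError("empty paradigm: no samples on the grid")
        # cache the sample grid; frozen dataclass, so bypass __setattr__
        t = np.arange(self.n_samples) / self.fs
        t_in_block = t % self.block_duration
        on = (t_in_block >= self.rest_pre) & (t_in_block < self.rest_pre + self.task)
        u = on.astype(float)
        t.setflags(write=False)
        u.setflags(write=False)
        object.__setattr__(self, "_times", t)
        object.__setattr__(self, "_u", u)

    @property
    def block_duration(self) -> float:
        return self.rest_pre + self.task + self.rest_post

    @property
    def samples_per_block(self) -> int:
        return int(round(self.fs * self.block_duration))

    @property
    def n_samples(self) -> int:
        return self.samples_per_block * self.n_trials

    @property
    def times(self) -> np.ndarray:
        """Sample times t_k = k / fs in seconds (read-only array)."""
        return self._times

    @property
    def u(self) -> np.ndarray:
        """Binary stimulus: 1 during task, 0 during rest, on the sample grid
        (read-only array)."""
        return self._u


@dataclass(frozen=True)
class ModelParameters:
    """The 12 free parameters of the signal model, in canonical order.

    alpha1/alpha2 are delays of the response and the undershoot, beta1/beta2
    their dispersions; a0 is the baseline and a1 the activity strength; the
    remaining six are amplitudes and frequencies (Hz) of the cardiac,
    Mayer-wave and respiratory sinusoids.
    """

    alpha1: float
    alpha2: float
    beta1: float
    beta2: float
    a0: float
    a1: float
    a_c: float
    a_m: float
    a_r: float
    f_c: float
    f_r: float
    f_m: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x: np.ndarray) -> "ModelParameters":
        x = np.asarray(x, dtype=float).ravel()
        if x.size != len(PARAM_NAMES):
            raise ValueError(f"expected {len(PARAM_NAMES)} parameters, got {x.size}")
        return cls(**dict(zip(PARAM_NAMES, x)))

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}


def canonical_hrf(
    t: np.ndarray, alpha1: float, alpha2: float, beta1: float, beta2: float
) -> np.ndarray:
    """Double-gamma canonical hemodynamic response function.

        h(t) = t^(a1-1) b1^a1 e^(-b1 t) / Gamma(a1)
             - t^(a2-1) b2^a2 e^(-b2 t) / (6 Gamma(a2))

    The first term is the positive response (a gamma density, unit integral),
    the second the post-stimulus undershoot scaled by 1/6.  ``beta2 = 0`` is
    taken as the continuous limit in which the undershoot vanishes
    identically (b2^a2 -> 0 for a2 >= 6).
    """
    for name, v in (
        ("alpha1", alpha1),
        ("alpha2", alpha2),
        ("beta1", beta1),
        ("beta2", beta2),
    ):
        if not np.isfinite(v):
            raise ValueError(f"non-finite HRF shape parameter {name}={v!r}")
    if beta1 <= 0:
        raise ValueError("beta1 must be positive")
    if beta2 < 0:
        raise ValueError("beta2 must be nonnegative")
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        response = (
            np.power(t, alpha1 - 1.0)
            * beta1**alpha1
            * np.exp(-beta1 * t)
            / _gamma_fn(alpha1)
        )
    response = np.where(t == 0.0, 0.0 if alpha1 > 1 else response, response)
    if beta2 == 0.0:
        undershoot = np.zeros_like(t)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            undershoot = (
                np.power(t, alpha2 - 1.0)
                * beta2**alpha2
                * np.exp(-beta2 * t)
                / (6.0 * _gamma_fn(alpha2))
            )
        undershoot = np.where(t == 0.0, 0.0 if alpha2 > 1 else undershoot, undershoot)
    return response - undershoot


def evoked_response(
    paradigm: Paradigm,
    alpha1: float,
    alpha2: float,
    beta1: float,
    beta2: float,
    u: np.ndarray | None = None,
) -> np.ndarray:
    """Task-evoked response: causal discrete convolution HRF(k) = (h * u)(k).

    ``h`` is sampled on the paradigm's own grid (no separate truncation
    window) and the convolution is truncated to the paradigm length.  No
    sample-interval scaling is applied; the same raw convolution is used by
    the simulator and the fitter so the scale of a1 is internally consistent.
    """
    h = canonical_hrf(paradigm.times, alpha1, alpha2, beta1, beta2)
    stim = paradigm.u if u is None else np.asarray(u, dtype=float)
    if stim.shape != h.shape:
        raise ValueError("stimulus length must match the paradigm grid")
    return np.convolve(h, stim)[: paradigm.n_samples]


def model_signal(
    params: ModelParameters | np.ndarray, paradigm: Paradigm
) -> np.ndarray:
    """Predicted noiseless signal of the full 12-parameter model."""
    x = params.to_array() if isinstance(params, ModelParameters) else np.asarray(params, dtype=float)
    if x.size != 12:
        raise ValueError("parameter vector must have 12 entries")
    alpha1, alpha2, beta1, beta2, a0, a1, a_c, a_m, a_r, f_c, f_r, f_m = x
    t = paradigm.times
    hrf = evoked_response(paradigm, alpha1, alpha2, beta1, beta2)
    return (
        a0
        + a1 * hrf
        + a_c * np.sin(2.0 * np.pi * f_c * t)
        + a_r * np.sin(2.0 * np.pi * f_r * t)
        + a_m * np.sin(2.0 * np.pi * f_m * t)
    )


def cost(
    params: ModelParameters | np.ndarray,
    observed: np.ndarray,
    paradigm: Paradigm,
) -> float:
    """Sum-of-squares cost J = sum_k (y_obs(k) - y_model(k))^2."""
    y = np.asarray(observed, dtype=float).ravel()
    if y.size != paradigm.n_samples:
        raise ValueError(
            f"observed series length {y.size} does not match the paradigm "
            f"grid ({paradigm.n_samples} samples)"
        )
    r = y - model_signal(params, paradigm)
    return float(r @ r)
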