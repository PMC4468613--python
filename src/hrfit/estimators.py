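"""Scikit-learn style estimators wrapping the model fit and MBLL conversion.

:class:`HRFRegression` is the package's main entry point: given a matrix of
per-channel oxy-hemoglobin series (samples x channels), it fits the
12-parameter hemodynamic signal model to each channel with the bounded
Nelder-Mead simplex and exposes the fitted parameters, costs and activation
statistics as trailing-underscore attributes.  It follows the sklearn
estimator contract (``get_params``/``set_params``, ``fit``/``predict``,
clonable constructor), so it composes with sklearn model-selection tooling.

:class:`MBLLTransformer` is a stateless transformer for the optical-density
to hemoglobin conversion step.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .hrf import PARAM_NAMES, Paradigm, cost, default_bounds, model_signal
from .mbll import ExtinctionTable, OpticalDensitySeries, od_to_hb
from .simplex import FitResult, NMConfig, minimize
from .stats import standard_error_a1, t_test_a1

__all__ = ["HRFRegression", "MBLLTransformer", "default_x0", "fit_single_channel"]


def default_x0(y: np.ndarray) -> np.ndarray:
    """Default initial parameter vector for one channel.

    Canonical HRF literature values for the shape (alpha1=6, alpha2=16,
    beta1=beta2=1), the channel mean for the baseline, unit activity
    strength, amplitude 0.5 for each sinusoid, and the admissible-band
    midpoints for the frequencies.
    """
    return np.array(
        [6.0, 16.0, 1.0, 1.0, float(np.mean(y)), 1.0,
         0.5, 0.5, 0.5, 1.0, 0.25, 0.095]
    )


def _band_scan(resid: np.ndarray, t: np.ndarray, lo: float, hi: float,
               step: float, n_best: int = 1) -> list[float]:
    """Frequencies in [lo, hi] whose sampled sine best explains ``resid``.

    Scores every grid frequency by the squared projection of the residual
    onto the (sampled) sine regressor.  Works beyond Nyquist, where the
    sampled sine simply aliases, so no folding logic is needed.  Returns the
    ``n_best`` top-scoring well-separated frequencies.
    """
    grid = np.arange(lo, hi + 0.5 * step, step)
    S = np.sin(2.0 * np.pi * np.outer(grid, t))  # (n_freq, n_t)
    num = S @ resid
    den = np.einsum("ij,ij->i", S, S)
    score = np.where(den > 1e-12, num**2 / np.where(den > 1e-12, den, 1.0), 0.0)
    order = np.argsort(score)[::-1]
    picks: list[float] = []
    min_sep = max(10 * step, 0.02)
    for k in order:
        fk = float(grid[k])
        if all(abs(fk - p) >= min_sep for p in picks):
            picks.append(fk)
        if len(picks) == n_best:
            break
    return picks


def spectral_frequency_guess(
    y: np.ndarray, paradigm: Paradigm, bounds: np.ndarray
) -> tuple[list[float], float, float]:
    """Data-driven initial guesses for the three sinusoid frequencies.

    After projecting out the baseline and a default-shape evoked response,
    each frequency is located by a grid scan of its admissible band
    (:func:`_band_scan`).  The cardiac band is wide and its cost valley
    narrow, so the two best-scoring cardiac frequencies are returned as
    alternative starts; the respiratory and Mayer bands are narrow and get
    one guess each.
    """
    from .hrf import evoked_response

    y = np.asarray(y, dtype=float).ravel()
    t = paradigm.times
    b = dict(zip(PARAM_NAMES, bounds))
    hrf = evoked_response(paradigm, 6.0, 16.0, 1.0, 1.0)
    X0 = np.column_stack([np.ones_like(t), hrf])
    coef, *_ = np.linalg.lstsq(X0, y, rcond=None)
    resid = y - X0 @ coef
    fc_candidates = _band_scan(resid, t, *b["f_c"], step=0.002, n_best=2)
    f_r = _band_scan(resid, t, *b["f_r"], step=0.002)[0]
    f_m = _band_scan(resid, t, *b["f_m"], step=0.0005)[0]
    return fc_candidates, f_r, f_m


def informed_starts(
    y: np.ndarray, paradigm: Paradigm, bounds: np.ndarray
) -> np.ndarray:
    """Stack of candidate start vectors for the simplex restarts.

    The first start is :func:`default_x0`.  One further start per cardiac
    candidate uses the periodogram frequencies with the five linear
    coefficients (a0, a1 and the sinusoid amplitudes) replaced by their
    ordinary-least-squares values at the default HRF shape, clipped to the
    box.  These are initial guesses only; the bounded simplex fits all 12
    parameters jointly from every start.
    """
    y = np.asarray(y, dtype=float).ravel()
    starts = [default_x0(y)]
    fc_candidates, f_r, f_m = spectral_frequency_guess(y, paradigm, bounds)
    t = paradigm.times
    from .hrf import evoked_response

    hrf = evoked_response(paradigm, 6.0, 16.0, 1.0, 1.0)
    idx = {n: i for i, n in enumerate(PARAM_NAMES)}
    for f_c in fc_candidates:
        X = np.column_stack(
            [
                np.ones_like(t),
                hrf,
                np.sin(2 * np.pi * f_c * t),
                np.sin(2 * np.pi * f_m * t),
                np.sin(2 * np.pi * f_r * t),
            ]
        )
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        x = default_x0(y)
        for name, val in zip(("a0", "a1", "a_c", "a_m", "a_r"), coef):
            x[idx[name]] = val
        x[idx["f_c"]] = f_c
        x[idx["f_r"]] = f_r
        x[idx["f_m"]] = f_m
        starts.append(x)
    return np.clip(np.asarray(starts), bounds[:, 0], bounds[:, 1])


def _make_cost(y: np.ndarray, paradigm: Paradigm):
    """Specialised sum-of-squares cost closure (identical to hrf.cost, with
    the paradigm grid hoisted out of the per-evaluation path)."""
    from scipy.special import gamma as G

    t = paradigm.times
    u = paradigm.u
    n = t.size
    two_pi_t = 2.0 * np.pi * t
    t_pos = np.where(t > 0, t, 1.0)  # placeholder at t=0; h[0] fixed below
    logt = np.log(t_pos)
    t0_is_zero = bool(t[0] == 0.0)

    def _at_zero(alpha: float, scale: float) -> float:
        # value of scale * t^(alpha-1) e^(-b t) at t = 0
        if alpha > 1.0:
            return 0.0
        return scale if alpha == 1.0 else np.inf

    def f(x: np.ndarray) -> float:
        alpha1, alpha2, beta1, beta2, a0, a1, a_c, a_m, a_r, f_c, f_r, f_m = x
        c1 = beta1**alpha1 / G(alpha1)
        h = np.exp((alpha1 - 1.0) * logt - beta1 * t) * c1
        if t0_is_zero:
            h[0] = _at_zero(alpha1, c1)
        if beta2 > 0.0:
            c2 = beta2**alpha2 / (6.0 * G(alpha2))
            under = np.exp((alpha2 - 1.0) * logt - beta2 * t) * c2
            if t0_is_zero:
                under[0] = _at_zero(alpha2, c2)
            h = h - under
        hrf = np.convolve(h, u)[:n]
        r = (
            y
            - a0
            - a1 * hrf
            - a_c * np.sin(f_c * two_pi_t)
            - a_r * np.sin(f_r * two_pi_t)
            - a_m * np.sin(f_m * two_pi_t)
        )
        return float(r @ r)

    return f


def fit_single_channel(
    y: np.ndarray,
    paradigm: Paradigm,
    bounds: np.ndarray | None = None,
    x0: np.ndarray | None = None,
    nm_config: NMConfig | None = None,
    seed: int | None = None,
) -> FitResult:
    """Fit the 12-parameter model to one observed series.

    Wraps :func:`hrfit.simplex.minimize` with the model's sum-of-squares
    cost.  Unless an explicit ``x0`` is given, the restart stack from
    :func:`informed_starts` is used (default literature start plus
    periodogram/OLS-informed starts); remaining restarts draw uniformly
    inside the box.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size != paradigm.n_samples:
        raise ValueError(
            f"series length {y.size} does not match the paradigm grid "
            f"({paradigm.n_samples})"
        )
    bounds = bounds if bounds is not None else default_bounds()
    cfg = nm_config if nm_config is not None else NMConfig()
    if seed is not None:
        cfg = NMConfig(**{**cfg.__dict__, "seed": int(seed)})
    start_sizes = None
    if x0 is None:
        x0 = informed_starts(y, paradigm, bounds)
        # spectrally informed starts sit close to their basin: use a small
        # initial simplex so narrow frequency valleys are not stepped over
        start_sizes = np.full(len(x0), 0.01)
        start_sizes[0] = cfg.simplex_size
    x0 = np.clip(np.atleast_2d(np.asarray(x0, dtype=float)), bounds[:, 0], bounds[:, 1])
    return minimize(_make_cost(y, paradigm), x0, bounds, cfg, start_sizes=start_sizes)


class HRFRegression(BaseEstimator):
    """Per-channel hemodynamic response model fitted by bounded Nelder-Mead.

    Parameters
    ----------
    fs, rest_pre, task, rest_post, n_trials
        Sampling rate (Hz) and block structure (seconds) of the boxcar
        paradigm; defaults are the 10/10/30 s block at 1.81 Hz.
    bounds
        Optional (12, 2) array overriding the default parameter box.
    n_restarts, max_iter, tol_x, tol_f, simplex_size
        Nelder-Mead settings (see :class:`hrfit.simplex.NMConfig`).
    alpha
        Significance level of the one-sided activation t-test.
    random_state
        Master seed; split deterministically across channels and restarts.

    Attributes
    ----------
    params_ : pandas.DataFrame, (n_channels, 12)
        Fitted parameters, one row per channel, canonical column order.
    cost_, n_iter_, converged_, restart_index_ : arrays, (n_channels,)
    se_a1_, t_values_, p_values_, significant_ : arrays, (n_channels,)
        Activation statistics of the activity-strength coefficient.
    dof_ : int
        Residual degrees of freedom (N - 12).
    results_ : list of FitResult
        Full per-channel optimizer output (trace etc.).
    """

    def __init__(
        self,
        fs: float = 1.81,
        rest_pre: float = 10.0,
        task: float = 10.0,
        rest_post: float = 30.0,
        n_trials: int = 1,
        bounds: np.ndarray | None = None,
        n_restarts: int = 10,
        max_iter: int = 5000,
        tol_x: float = 1e-6,
        tol_f: float = 1e-10,
        simplex_size: float = 0.1,
        alpha: float = 0.05,
        random_state: int = 0,
    ):
        self.fs = fs
        self.rest_pre = rest_pre
        self.task = task
        self.rest_post = rest_post
        self.n_trials = n_trials
        self.bounds = bounds
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol_x = tol_x
        self.tol_f = tol_f
        self.simplex_size = simplex_size
        self.alpha = alpha
        self.random_state = random_state

    def _paradigm(self) -> Paradigm:
        return Paradigm(
            fs=self.fs,
            rest_pre=self.rest_pre,
            task=self.task,
            rest_post=self.rest_post,
            n_trials=self.n_trials,
        )

    def _nm_config(self, seed: int) -> NMConfig:
        return NMConfig(
            simplex_size=self.simplex_size,
            max_iter=self.max_iter,
            tol_x=self.tol_x,
            tol_f=self.tol_f,
            n_restarts=self.n_restarts,
            seed=seed,
        )

    def fit(self, X, y=None, channel_ids=None):
        """Fit the model to each column of ``X`` (samples x channels)."""
        X = check_array(X, ensure_2d=False, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        paradigm = self._paradigm()
        if X.shape[0] != paradigm.n_samples:
            raise ValueError(
                f"X has {X.shape[0]} samples but the paradigm grid has "
                f"{paradigm.n_samples}"
            )
        n_channels = X.shape[1]
        if channel_ids is None:
            channel_ids = [f"CH{i + 1:02d}" for i in range(n_channels)]
        bounds = (
            np.asarray(self.bounds, dtype=float)
            if self.bounds is not None
            else default_bounds()
        )
        seeds = np.random.SeedSequence(self.random_state).generate_state(
            n_channels
        ) % (2**31)

        self.results_ = []
        stats_rows = []
        for i in range(n_channels):
            yi = X[:, i]
            res = fit_single_channel(
                yi,
                paradigm,
                bounds=bounds,
                nm_config=self._nm_config(int(seeds[i])),
            )
            a1_hat = res.x_opt[PARAM_NAMES.index("a1")]
            se, dof = standard_error_a1(yi, res.x_opt, paradigm, ssr=res.j_opt)
            t, p, sig = t_test_a1(a1_hat, se, dof, alpha=self.alpha)
            self.results_.append(res)
            stats_rows.append((se, t, p, sig, dof))

        self.channel_ids_ = list(channel_ids)
        self.params_ = pd.DataFrame(
            [r.x_opt for r in self.results_],
            columns=list(PARAM_NAMES),
            index=self.channel_ids_,
        )
        self.cost_ = np.array([r.j_opt for r in self.results_])
        self.n_iter_ = np.array([r.n_iter for r in self.results_])
        self.converged_ = np.array([r.converged for r in self.results_])
        self.restart_index_ = np.array([r.restart_index for r in self.results_])
        self.se_a1_ = np.array([s[0] for s in stats_rows])
        self.t_values_ = np.array([s[1] for s in stats_rows])
        self.p_values_ = np.array([s[2] for s in stats_rows])
        self.significant_ = np.array([s[3] for s in stats_rows])
        self.dof_ = int(stats_rows[0][4])
        self.n_features_in_ = n_channels
        return self

    def predict(self, X=None) -> np.ndarray:
        """Fitted model signals, one column per channel (samples x channels).

        ``X`` is accepted for pipeline compatibility and ignored: the model
        is a fixed-design curve fit, so the prediction depends only on the
        fitted parameters and the paradigm grid.
        """
        check_is_fitted(self, "params_")
        paradigm = self._paradigm()
        cols = [
            model_signal(self.params_.loc[cid].to_numpy(), paradigm)
            for cid in self.channel_ids_
        ]
        return np.column_stack(cols)

    def score(self, X, y=None) -> float:
        """Mean negative residual sum of squares over channels (higher is better)."""
        check_is_fitted(self, "cost_")
        return float(-np.mean(self.cost_))


class MBLLTransformer(TransformerMixin, BaseEstimator):
    """Optical-density to hemoglobin-concentration transformer.

    Input ``X`` has shape ``(n_samples, 2 * n_channels)`` with the first
    ``n_channels`` columns holding the 760 nm optical densities and the rest
    the 830 nm ones.  ``transform`` returns the same layout with dHbO in the
    first block and dHbR in the second.  Stateless: ``fit`` only records the
    input width.
    """

    def __init__(
        self,
        extinction: ExtinctionTable | None = None,
        dpf_l1: float = 7.25,
        dpf_l2: float = 6.38,
        separation: float = 3.0,
        fs: float = 1.81,
    ):
        self.extinction = extinction
        self.dpf_l1 = dpf_l1
        self.dpf_l2 = dpf_l2
        self.separation = separation
        self.fs = fs

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if X.shape[1] % 2:
            raise ValueError(
                "X must stack the two wavelength blocks: even column count required"
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_features_in_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("column count changed between fit and transform")
        half = X.shape[1] // 2
        od = OpticalDensitySeries(
            od_l1=X[:, :half].T,
            od_l2=X[:, half:].T,
            fs=self.fs,
            dpf_l1=self.dpf_l1,
            dpf_l2=self.dpf_l2,
            separation=self.separation,
        )
        ext = self.extinction if self.extinction is not None else ExtinctionTable()
        dhbo, dhbr = od_to_hb(od, ext)
        return np.hstack([dhbo.T, dhbr.T])
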