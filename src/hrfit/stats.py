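"""Channel activation statistics: t-test on the activity-strength coefficient.

A channel is declared active when the fitted activity strength a1 is
significantly greater than zero.  The standard error of a1 is obtained from
the model linearized at the fitted nonlinear parameters: with the HRF shape
and the sinusoid frequencies fixed at their optima, the model is ordinary
least squares in the five linear coefficients

    X = [1, HRF*(k), sin(2 pi f_c* t), sin(2 pi f_r* t), sin(2 pi f_m* t)]

and SE(a1*) = sqrt(sigma2 * [(X'X)^-1]_HRF) with sigma2 = SSR / (N - p),
p = 12 (all fitted parameters, a conservative residual dof).  The test is
one-sided (activation means a1 > 0; the fit constrains a1 >= 0): a channel
is significant iff t > t_critical AND p < alpha (strict inequalities).

Caveat: because the fit constrains a1 >= 0, the null distribution of a1* is
truncated at zero; the nominal one-sided t-test ignores this.  The
linearized (unconstrained OLS) route is exact under the null and is what the
calibration tests exercise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .hrf import PARAM_NAMES, Paradigm, evoked_response
from .simplex import FitResult

__all__ = [
    "CollinearityError",
    "IncompleteLayoutError",
    "ChannelFit",
    "ActivationMap",
    "linearized_design",
    "standard_error_a1",
    "t_test_a1",
    "build_tmap",
    "default_layout",
]

#: Number of fitted parameters charged to the residual degrees of freedom.
N_FITTED_PARAMS = 12

#: Column index of the evoked-HRF regressor in the linearized design.
_HRF_COL = 1


class CollinearityError(ValueError):
    """The linearized design is rank deficient (e.g. two equal frequencies)."""


class IncompleteLayoutError(ValueError):
    """A channel present in the layout has no fit."""


@dataclass
class ChannelFit:
    """Per-channel fit with its activation statistics."""

    channel_id: str
    fit: FitResult | None
    se_a1: float
    t_value: float
    p_value: float
    dof: int


@dataclass
class ActivationMap:
    """Per-channel t-values and significance flags on the optode grid."""

    layout: pd.DataFrame  # columns: channel_id, grid_row, grid_col
    t_values: pd.Series
    p_values: pd.Series
    significant: pd.Series
    t_critical: float
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        out = self.layout.copy()
        out["t"] = self.t_values.reindex(out["channel_id"]).to_numpy()
        out["p"] = self.p_values.reindex(out["channel_id"]).to_numpy()
        out["significant"] = (
            self.significant.reindex(out["channel_id"]).to_numpy()
        )
        return out

    def render(self, path=None, ax=None):
        """Draw the t-map as a colour-coded grid; returns the axes."""
        import matplotlib

        if path is not None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        frame = self.to_frame()
        n_rows = int(frame["grid_row"].max()) + 1
        n_cols = int(frame["grid_col"].max()) + 1
        grid = np.full((n_rows, n_cols), np.nan)
        for _, row in frame.iterrows():
            grid[int(row["grid_row"]), int(row["grid_col"])] = row["t"]
        if ax is None:
            _, ax = plt.subplots(figsize=(1.2 * n_cols, 1.2 * n_rows))
        im = ax.imshow(grid, cmap="hot")
        ax.figure.colorbar(im, ax=ax, label="t-value")
        for _, row in frame.iterrows():
            marker = "*" if row["significant"] else ""
            ax.text(
                int(row["grid_col"]),
                int(row["grid_row"]),
                f"{row['channel_id']}{marker}",
                ha="center",
                va="center",
                fontsize=7,
                color="tab:blue",
            )
        ax.set_title(f"t-map (alpha={self.alpha}, t_crit={self.t_critical:.2f})")
        ax.set_xticks([])
        ax.set_yticks([])
        if path is not None:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(ax.figure)
        return ax


def default_layout(n_channels: int = 16, n_cols: int = 4) -> pd.DataFrame:
    """Default optode grid: CH01..CH16 row-major on a 4x4 grid."""
    ids = [f"CH{i + 1:02d}" for i in range(n_channels)]
    return pd.DataFrame(
        {
            "channel_id": ids,
            "grid_row": [i // n_cols for i in range(n_channels)],
            "grid_col": [i % n_cols for i in range(n_channels)],
        }
    )


def linearized_design(params, paradigm: Paradigm) -> np.ndarray:
    """OLS design at fixed nonlinear parameters: [1, HRF*, sin_c, sin_r, sin_m]."""
    x = np.asarray(
        params.to_array() if hasattr(params, "to_array") else params, dtype=float
    )
    d = dict(zip(PARAM_NAMES, x))
    t = paradigm.times
    hrf = evoked_response(
        paradigm, d["alpha1"], d["alpha2"], d["beta1"], d["beta2"]
    )
    X = np.column_stack(
        [
            np.ones_like(t),
            hrf,
            np.sin(2 * np.pi * d["f_c"] * t),
            np.sin(2 * np.pi * d["f_r"] * t),
            np.sin(2 * np.pi * d["f_m"] * t),
        ]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError(
            "linearized design is rank deficient; check for coincident "
            "sinusoid frequencies or a degenerate evoked response"
        )
    return X


def standard_error_a1(
    observed: np.ndarray,
    params,
    paradigm: Paradigm,
    ssr: float | None = None,
    n_params: int = N_FITTED_PARAMS,
) -> tuple[float, int]:
    """Standard error of the fitted activity strength and its residual dof.

    ``ssr`` defaults to the residual sum of squares of the full nonlinear
    fit evaluated at ``params``; pass ``FitResult.j_opt`` to reuse it.
    """
    y = np.asarray(observed, dtype=float).ravel()
    N = y.size
    if N <= n_params:
        raise ValueError(f"need more than {n_params} samples, got {N}")
    X = linearized_design(params, paradigm)
    if ssr is None:
        from .hrf import cost

        ssr = cost(params, y, paradigm)
    dof = N - n_params
    sigma2 = ssr / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[_HRF_COL, _HRF_COL]))
    return se, dof


def t_test_a1(
    a1: float, se_a1: float, dof: int, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """One-sided t-test of H0: a1 = 0 against a1 > 0.

    Returns ``(t, p, significant)``.  A perfect fit (SE = 0) is reported with
    the sentinel t = +inf (p = 0) for a1 > 0, and t = 0 (p = 0.5) for a1 = 0.
    """
    if se_a1 < 0:
        raise ValueError("standard error must be nonnegative")
    if se_a1 == 0.0:
        t = np.inf if a1 > 0 else 0.0
    else:
        t = a1 / se_a1
    p = float(sps.t.sf(t, dof))
    t_crit = float(sps.t.ppf(1.0 - alpha, dof))
    significant = bool(t > t_crit and p < alpha)
    return float(t), p, significant


def build_tmap(
    fits: list[ChannelFit],
    layout: pd.DataFrame | None = None,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> ActivationMap:
    """Assemble an :class:`ActivationMap` from per-channel fits.

    Every channel in the layout must have exactly one fit; extra fits are
    ignored.  The map is invariant to the ordering of ``fits``.  No
    multiple-comparison correction is applied by default; ``bonferroni``
    divides alpha by the number of layout channels.
    """
    layout = layout if layout is not None else default_layout(len(fits))
    by_id = {cf.channel_id: cf for cf in fits}
    missing = [c for c in layout["channel_id"] if c not in by_id]
    if missing:
        raise IncompleteLayoutError(
            f"layout channels without a fit: {', '.join(missing)}"
        )
    ids = list(layout["channel_id"])
    if bonferroni:
        alpha = alpha / len(ids)
    dof = by_id[ids[0]].dof
    t_crit = float(sps.t.ppf(1.0 - alpha, dof))
    t_vals = pd.Series({c: by_id[c].t_value for c in ids})
    p_vals = pd.Series({c: by_id[c].p_value for c in ids})
    sig = pd.Series(
        {c: bool(t_vals[c] > t_crit and p_vals[c] < alpha) for c in ids}
    )
    return ActivationMap(
        layout=layout.reset_index(drop=True),
        t_values=t_vals,
        p_values=p_vals,
        significant=sig,
        t_critical=t_crit,
        alpha=alpha,
    )
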