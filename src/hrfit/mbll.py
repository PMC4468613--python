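"""Modified Beer-Lambert law (MBLL) conversion of optical densities to hemoglobin.

Continuous-wave NIRS measures optical-density changes ``dOD`` at two
wavelengths.  Assuming constant scattering, the change in optical density at
wavelength ``lam_j`` over channel ``i`` is

    dOD_j = l_i * DPF_j * (eps_HbO_j * dHbO + eps_HbR_j * dHbR)

where ``l_i`` is the source-detector separation, ``DPF_j`` the differential
pathlength factor and ``eps`` the chromophore extinction coefficients.  With
two wavelengths this is a 2x2 linear system per sample; :func:`od_to_hb`
implements its closed-form solution.

The extinction coefficients are used as printed by the instrument literature
without units; the resulting concentration changes are therefore in arbitrary
relative units, which is all the downstream model fitting requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExtinctionTable",
    "OpticalDensitySeries",
    "DegenerateWavelengthPairError",
    "od_to_hb",
    "hb_to_od",
]

#: Extinction coefficients at 760 nm / 830 nm for HbO and HbR (relative units).
DEFAULT_EXTINCTION = {
    "eps_hbo_l1": 1.486,
    "eps_hbr_l1": 3.843,
    "eps_hbo_l2": 2.231,
    "eps_hbr_l2": 1.791,
}

#: Default differential pathlength factors (dimensionless) per wavelength.
DEFAULT_DPF = (7.25, 6.38)

#: Default source-detector separation in cm.
DEFAULT_SEPARATION = 3.0


class DegenerateWavelengthPairError(ValueError):
    """The extinction matrix of the two wavelengths is singular.

    Raised when ``eps_hbr_l1*eps_hbo_l2 - eps_hbr_l2*eps_hbo_l1`` vanishes,
    i.e. the two wavelengths do not discriminate HbO from HbR.
    """


@dataclass(frozen=True)
class ExtinctionTable:
    """Extinction coefficients of HbO and HbR at the two wavelengths."""

    eps_hbo_l1: float = DEFAULT_EXTINCTION["eps_hbo_l1"]
    eps_hbr_l1: float = DEFAULT_EXTINCTION["eps_hbr_l1"]
    eps_hbo_l2: float = DEFAULT_EXTINCTION["eps_hbo_l2"]
    eps_hbr_l2: float = DEFAULT_EXTINCTION["eps_hbr_l2"]

    def __post_init__(self) -> None:
        vals = (self.eps_hbo_l1, self.eps_hbr_l1, self.eps_hbo_l2, self.eps_hbr_l2)
        if not all(np.isfinite(v) and v > 0 for v in vals):
            raise ValueError("extinction coefficients must be finite and positive")
        if abs(self.determinant) < 1e-12:
            raise DegenerateWavelengthPairError(
                "degenerate wavelength pair: extinction determinant "
                f"{self.determinant!r} is (near) zero"
            )

    @property
    def determinant(self) -> float:
        """The shared denominator term eps_HbR^l1*eps_HbO^l2 - eps_HbR^l2*eps_HbO^l1."""
        return self.eps_hbr_l1 * self.eps_hbo_l2 - self.eps_hbr_l2 * self.eps_hbo_l1

    def as_matrix(self) -> np.ndarray:
        """2x2 matrix mapping (dHbO, dHbR) to pathlength-normalised dOD."""
        return np.array(
            [
                [self.eps_hbo_l1, self.eps_hbr_l1],
                [self.eps_hbo_l2, self.eps_hbr_l2],
            ]
        )


@dataclass
class OpticalDensitySeries:
    """Dual-wavelength optical-density change series for a set of channels.

    Parameters
    ----------
    od_l1, od_l2
        Arrays of shape ``(n_channels, n_samples)`` with the dOD series at the
        first (760 nm) and second (830 nm) wavelength.
    fs
        Sampling rate in Hz.
    dpf_l1, dpf_l2
        Differential pathlength factors, one per wavelength.
    separation
        Source-detector separation in cm; scalar or one value per channel.
    wavelengths
        The two wavelengths in nm (metadata only).
    """

    od_l1: np.ndarray
    od_l2: np.ndarray
    fs: float = 1.81
    dpf_l1: float = DEFAULT_DPF[0]
    dpf_l2: float = DEFAULT_DPF[1]
    separation: float | np.ndarray = DEFAULT_SEPARATION
    wavelengths: tuple[float, float] = (760.0, 830.0)

    def __post_init__(self) -> None:
        self.od_l1 = np.atleast_2d(np.asarray(self.od_l1, dtype=float))
        self.od_l2 = np.atleast_2d(np.asarray(self.od_l2, dtype=float))
        if self.od_l1.shape != self.od_l2.shape:
            raise ValueError(
                f"optical-density series shapes differ across wavelengths: "
                f"{self.od_l1.shape} vs {self.od_l2.shape}"
            )
        if len(self.wavelengths) != 2:
            raise ValueError("exactly two wavelengths are required")
        if not self.fs > 0:
            raise ValueError("sampling rate fs must be positive")
        if not (self.dpf_l1 > 0 and self.dpf_l2 > 0):
            raise ValueError("differential pathlength factors must be positive")
        sep = np.atleast_1d(np.asarray(self.separation, dtype=float))
        if np.any(sep <= 0):
            raise ValueError("source-detector separation must be positive")
        if sep.size not in (1, self.od_l1.shape[0]):
            raise ValueError(
                "separation must be scalar or give one value per channel"
            )

    @property
    def n_channels(self) -> int:
        return self.od_l1.shape[0]

    @property
    def n_samples(self) -> int:
        return self.od_l1.shape[1]


def od_to_hb(
    od: OpticalDensitySeries, ext: ExtinctionTable | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Convert dual-wavelength dOD series to (dHbO, dHbR) concentration changes.

    Implements the closed-form two-wavelength MBLL solution: with
    pathlength-normalised densities ``v_j = dOD_j / DPF_j`` the numerators are
    the cross-weighted differences and the shared denominator is
    ``l * (eps_HbR^l1 eps_HbO^l2 - eps_HbR^l2 eps_HbO^l1)``.

    Returns
    -------
    (dhbo, dhbr)
        Two arrays of shape ``(n_channels, n_samples)`` in relative
        concentration units.
    """
    ext = ext if ext is not None else ExtinctionTable()
    sep = np.atleast_1d(np.asarray(od.separation, dtype=float)).reshape(-1, 1)
    denom = sep * ext.determinant
    v1 = od.od_l1 / od.dpf_l1
    v2 = od.od_l2 / od.dpf_l2
    dhbo = (ext.eps_hbr_l1 * v2 - ext.eps_hbr_l2 * v1) / denom
    dhbr = (ext.eps_hbo_l2 * v1 - ext.eps_hbo_l1 * v2) / denom
    return dhbo, dhbr


def hb_to_od(
    dhbo: np.ndarray,
    dhbr: np.ndarray,
    ext: ExtinctionTable | None = None,
    dpf_l1: float = DEFAULT_DPF[0],
    dpf_l2: float = DEFAULT_DPF[1],
    separation: float | np.ndarray = DEFAULT_SEPARATION,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward Beer-Lambert map: concentration changes to dOD at both wavelengths.

    The exact inverse of :func:`od_to_hb`; mainly useful for simulation and
    round-trip validation.
    """
    ext = ext if ext is not None else ExtinctionTable()
    dhbo = np.atleast_2d(np.asarray(dhbo, dtype=float))
    dhbr = np.atleast_2d(np.asarray(dhbr, dtype=float))
    if dhbo.shape != dhbr.shape:
        raise ValueError("dHbO and dHbR must have identical shapes")
    sep = np.atleast_1d(np.asarray(separation, dtype=float)).reshape(-1, 1)
    od_l1 = sep * dpf_l1 * (ext.eps_hbo_l1 * dhbo + ext.eps_hbr_l1 * dhbr)
    od_l2 = sep * dpf_l2 * (ext.eps_hbo_l2 * dhbo + ext.eps_hbr_l2 * dhbr)
    return od_l1, od_l2
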