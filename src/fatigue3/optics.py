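"""Modified Beer-Lambert law conversion between optical density and hemoglobin.

The three-wavelength system is overdetermined for the two chromophores, so
concentrations are recovered through the Moore-Penrose pseudoinverse of the
extinction matrix (a least-squares fit per sample).  The same matrix and
pathlengths drive the simulator's forward model, which makes the pair
exactly invertible on noise-free data.
"""
from __future__ import annotations

import numpy as np

from .config import OpticsConfig


def extinction_matrix(optics: OpticsConfig) -> np.ndarray:
    """2x3 matrix E: rows (HbO, HbR), columns the three wavelengths, 1/(mM*cm)."""
    return np.array([optics.extinction_hbo, optics.extinction_hbr], float)


def pathlengths_cm(optics: OpticsConfig, short: bool = False) -> np.ndarray:
    """Effective photon pathlength L = DPF * source-detector distance, per wavelength."""
    r = optics.short_distance_cm if short else optics.long_distance_cm
    return np.full(3, optics.dpf * r)


def mbll_inverse(od: np.ndarray, optics: OpticsConfig, short: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Concentration changes (dHbO, dHbR) in umol/L from dOD at three wavelengths.

    Parameters
    ----------
    od : array, shape (n_samples, 3)
        Optical-density change per wavelength (735, 805, 850 nm order).
    """
    od = np.asarray(od, float)
    if od.ndim != 2 or od.shape[1] != 3:
        raise ValueError("od must have shape (n_samples, 3)")
    L = pathlengths_cm(optics, short=short)
    E = extinction_matrix(optics)
    conc_mM = (od / L) @ np.linalg.pinv(E)  # (n, 2): columns HbO, HbR
    conc_uM = conc_mM * 1000.0
    return conc_uM[:, 0], conc_uM[:, 1]


def mbll_forward(hbo_um: np.ndarray, hbr_um: np.ndarray, optics: OpticsConfig, short: bool = False) -> np.ndarray:
    """Optical-density change (n, 3) generated by the given concentration changes."""
    c = np.stack([np.asarray(hbo_um, float), np.asarray(hbr_um, float)], axis=1) / 1000.0
    L = pathlengths_cm(optics, short=short)
    E = extinction_matrix(optics)
    return (c @ E) * L


def derive_hbt_coe(hbo: np.ndarray, hbr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total hemoglobin and cerebral oxygen exchange: HbT = HbO+HbR, COE = HbR-HbO."""
    hbo = np.asarray(hbo, float)
    hbr = np.asarray(hbr, float)
    return hbo + hbr, hbr - hbo
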