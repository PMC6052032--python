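"""Receptor-noise-limited (RNL) colour discrimination.

The chain is: quantum catch of each receptor class for target and background,
log receptor contrasts, then the opponent combination whose unit is the Just
Noticeable Difference (JND).  A chromatic distance of 1 JND is the threshold
at which two colours are discriminable under ideal conditions.

Chromatic distance depends only on log catch *ratios*, so it is invariant to
any uniform scaling of reflectance or illumination; von Kries adaptation to
the background (dividing each catch by the background catch) therefore leaves
JNDs unchanged and is applied only when exporting adapted coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, GridMismatchError
from .photoreceptor import Phenotype, luminance_sensitivity, phenotype_sensitivities
from .spectra import Spectrum

#: Relative floor applied to catches before taking logs.
EPS_REL = 1e-9


@dataclass
class Illuminant:
    """Relative photon flux on a wavelength grid."""

    grid: np.ndarray
    irradiance: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.irradiance = np.asarray(self.irradiance, dtype=float)
        if np.any(self.irradiance < 0):
            raise DegenerateInputError("illuminant irradiance must be non-negative")

    @classmethod
    def flat(cls, grid) -> "Illuminant":
        """Equal-photon (flat) illuminant: the neutral default."""
        grid = np.asarray(grid, dtype=float)
        return cls(grid, np.ones_like(grid))

    @classmethod
    def from_csv(cls, path, grid=None) -> "Illuminant":
        """Load an illuminant from a two-column CSV (wavelength, irradiance),
        optionally interpolated onto ``grid``."""
        df = pd.read_csv(path)
        wl = df.iloc[:, 0].to_numpy(float)
        ir = df.iloc[:, 1].to_numpy(float)
        if grid is not None:
            grid = np.asarray(grid, dtype=float)
            ir = np.interp(grid, wl, ir)
            wl = grid
        return cls(wl, ir)


@dataclass
class CatchVector:
    """Quantum catches of one stimulus for one phenotype.

    ``catches`` is ordered like ``phenotype_sensitivities`` (S first, then
    L/M ascending); ``lum`` is the catch through the achromatic channel.
    """

    phenotype: str
    catches: np.ndarray
    lum: float | None = None

    def __post_init__(self):
        self.catches = np.asarray(self.catches, dtype=float)
        if np.any(self.catches < 0):
            raise DegenerateInputError("quantum catches must be non-negative")


def _check_grid(*grids):
    g0 = grids[0]
    for g in grids[1:]:
        if g.shape != g0.shape or not np.allclose(g, g0):
            raise GridMismatchError("spectrum, template and illuminant grids differ")


def quantum_catch(reflectance: Spectrum, template, illuminant: Illuminant) -> float:
    """Photon catch Q = integral of R * I * S over 400-700 nm (trapezoid).

    Negative reflectance readings (instrument noise around the dark floor)
    are clipped to zero.
    """
    _check_grid(reflectance.wavelengths, template.grid, illuminant.grid)
    r = np.clip(reflectance.values, 0.0, None)
    integrand = r * illuminant.irradiance * template.sensitivity
    return float(np.trapezoid(integrand, reflectance.wavelengths))


def catch_vector(
    reflectance: Spectrum,
    p: Phenotype,
    illuminant: Illuminant | None = None,
    with_lum: bool = True,
) -> CatchVector:
    """All receptor catches (plus the luminance catch) for one stimulus."""
    if illuminant is None:
        illuminant = Illuminant.flat(reflectance.wavelengths)
    templates = phenotype_sensitivities(p, reflectance.wavelengths)
    q = np.array([quantum_catch(reflectance, t, illuminant) for t in templates])
    lum = None
    if with_lum:
        lum_t = luminance_sensitivity(p, reflectance.wavelengths)
        lum = quantum_catch(reflectance, lum_t, illuminant)
    return CatchVector(p.name, q, lum)


def von_kries(c: CatchVector, background: CatchVector) -> CatchVector:
    """Adapt catches to the background (each divided by the background catch).

    This changes coordinates only; log-contrast differences, and hence every
    JND downstream, are unchanged.
    """
    q = _floored(np.stack([c.catches, background.catches]))
    lum = None
    if c.lum is not None and background.lum is not None and background.lum > 0:
        lum = c.lum / background.lum
    return CatchVector(c.phenotype, q[0] / q[1], lum)


def _floored(arr):
    arr = np.asarray(arr, dtype=float)
    m = arr.max()
    if m <= 0:
        raise DegenerateInputError("all quantum catches are zero")
    return np.maximum(arr, EPS_REL * m)


def receptor_contrast(target: CatchVector, background: CatchVector) -> np.ndarray:
    """Log receptor contrasts: delta f_i = ln(Q_i,target / Q_i,background).

    Catches are floored at ``1e-9 * max(catch in the comparison)`` before the
    log so dark-corrected zeros stay finite.
    """
    if target.catches.size != background.catches.size:
        raise DegenerateInputError("catch vectors of different length")
    stacked = _floored(np.stack([target.catches, background.catches]))
    return np.log(stacked[0]) - np.log(stacked[1])


def chromatic_jnd(df: np.ndarray, p: Phenotype) -> float:
    """Chromatic distance (in JND) from log receptor contrasts.

    Dichromat (S, L/M)::

        dS = |df1 - df2| / sqrt(w1^2 + w2^2)

    Trichromat (S, M, L)::

        dS = sqrt( (w1^2 (df3-df2)^2 + w2^2 (df3-df1)^2 + w3^2 (df1-df2)^2)
                   / ((w1 w2)^2 + (w1 w3)^2 + (w2 w3)^2) )

    with w_i the channel Weber fractions.
    """
    df = np.asarray(df, dtype=float)
    w = p.weber_fractions()
    if df.size != w.size:
        raise DegenerateInputError(
            f"{df.size} contrasts for {w.size} receptors of {p.name!r}"
        )
    if df.size == 2:
        return float(abs(df[0] - df[1]) / np.hypot(w[0], w[1]))
    if df.size == 3:
        num = (
            w[0] ** 2 * (df[2] - df[1]) ** 2
            + w[1] ** 2 * (df[2] - df[0]) ** 2
            + w[2] ** 2 * (df[0] - df[1]) ** 2
        )
        den = (w[0] * w[1]) ** 2 + (w[0] * w[2]) ** 2 + (w[1] * w[2]) ** 2
        return float(np.sqrt(num / den))
    raise DegenerateInputError(f"unsupported receptor count {df.size}")


def luminance_contrast(
    target: CatchVector, background: CatchVector, p: Phenotype
) -> float:
    """Achromatic contrast |ln(Q_lum,t / Q_lum,b)| / omega_lum."""
    if target.lum is None or background.lum is None:
        raise DegenerateInputError("catch vectors carry no luminance catch")
    q = _floored(np.array([target.lum, background.lum]))
    return float(abs(np.log(q[0] / q[1])) / p.omega_lum)


def chromaticity_coords(
    c: CatchVector, p: Phenotype, include_lightness: bool = False
) -> np.ndarray:
    """Log-ratio chromaticity coordinates of one stimulus.

    Dichromat: the single opponent axis ``ln(Q_LM / Q_S)``.  Trichromat: the
    red-green axis ``ln(Q_L / Q_M)`` and the blue-yellow axis
    ``ln(Q_S / sqrt(Q_L Q_M))``.  With ``include_lightness`` the log
    luminance catch ``ln(Q_lum)`` is appended.  The chromatic coordinates are
    invariant to uniform scaling of the catches.
    """
    q = _floored(c.catches)
    if q.size == 2:
        coords = [np.log(q[1] / q[0])]
    elif q.size == 3:
        coords = [
            np.log(q[2] / q[1]),
            np.log(q[0] / np.sqrt(q[1] * q[2])),
        ]
    else:
        raise DegenerateInputError(f"unsupported receptor count {q.size}")
    if include_lightness:
        if c.lum is None:
            raise DegenerateInputError("no luminance catch for lightness coordinate")
        coords.append(np.log(max(c.lum, 1e-12)))
    return np.array(coords)


def jnd_pair(
    target: Spectrum,
    background: Spectrum,
    p: Phenotype,
    illuminant: Illuminant | None = None,
) -> tuple:
    """Convenience: (chromatic JND, achromatic contrast) of target vs background."""
    if illuminant is None:
        illuminant = Illuminant.flat(target.wavelengths)
    ct = catch_vector(target, p, illuminant)
    cb = catch_vector(background, p, illuminant)
    df = receptor_contrast(ct, cb)
    return chromatic_jnd(df, p), luminance_contrast(ct, cb, p)
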