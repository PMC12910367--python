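"""Photon-flux accounting for horticultural light recipes.

Computes the quantities a light recipe is summarised by in controlled
environment agriculture: photon flux density (PFD = PPFD + far-red), daily
light integral (DLI), total photon flux per day (TPFD), the red:far-red
ratio and the phytochrome photostationary state (PSS), plus the
percent-change convention used for treatment contrasts.

A recipe is the pair of photon fluxes in 400-700 nm (PPFD) and 700-800 nm
(far-red), a photoperiod, and optionally a relative spectral photon
distribution.  DLI/TPFD integrate a flux over the photoperiod:

    integral [mol m-2 d-1] = flux [umol m-2 s-1] x photoperiod [h] x 3600 / 1e6

PSS is the equilibrium fraction of phytochrome in its active (Pfr) form
under a given spectrum N(lambda):

    PSS = sum sigma_R(l) N(l) / sum (sigma_R(l) + sigma_FR(l)) N(l)

using a bundled table of photoconversion cross-sections (see
:func:`load_cross_sections`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "LightRecipe",
    "PhotonSummary",
    "daily_integral",
    "red_farred_ratio",
    "pss",
    "percent_change",
    "round_half_away",
    "load_cross_sections",
]


def daily_integral(flux: float, photoperiod_h: float) -> float:
    """Integrate a photon flux over a daily photoperiod.

    Parameters
    ----------
    flux : float
        Photon flux density in umol m-2 s-1 (>= 0).  Applied to PPFD this
        yields the DLI; applied to PFD (PPFD + far-red) it yields the TPFD.
    photoperiod_h : float
        Hours of light per 24-h cycle, in (0, 24].

    Returns
    -------
    float
        Daily photon integral in mol m-2 d-1.
    """
    if flux < 0:
        raise ValueError(f"flux must be >= 0, got {flux}")
    if not 0 < photoperiod_h <= 24:
        raise ValueError(f"photoperiod_h must be in (0, 24], got {photoperiod_h}")
    return flux * photoperiod_h * 3600.0 / 1e6


def red_farred_ratio(spectrum: dict[float, float]) -> float:
    """Red (600-700 nm) to far-red (700-800 nm) photon-flux ratio.

    ``spectrum`` maps wavelength (nm) to relative photon flux.  Red counts
    wavelengths in [600, 700), far-red in [700, 800].
    """
    red = sum(v for w, v in spectrum.items() if 600 <= w < 700)
    farred = sum(v for w, v in spectrum.items() if 700 <= w <= 800)
    if farred <= 0:
        raise ValueError("R:FR undefined: no photon flux in 700-800 nm")
    return red / farred


def load_cross_sections() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Load the bundled phytochrome photoconversion cross-section table.

    Returns ``(wavelength_nm, sigma_r, sigma_fr)`` arrays covering
    300-800 nm at 2-nm steps.  The table is a synthetic Gaussian-mixture
    stand-in for published phytochrome cross-sections, calibrated to
    reproduce the standard photoequilibrium anchors (monochromatic 660 nm
    around 0.89, low values in the far-red, and 0.82 for a deep-red/white
    plus far-red recipe with R:FR 3.5); see the data-file header and
    docs/methods.md for its construction.
    """
    import pandas as pd

    ref = resources.files("clgrow.data").joinpath(
        "phytochrome_cross_sections_synthetic.csv"
    )
    with ref.open("r") as fh:
        tab = pd.read_csv(fh, comment="#")
    return (
        tab["wavelength_nm"].to_numpy(float),
        tab["sigma_r"].to_numpy(float),
        tab["sigma_fr"].to_numpy(float),
    )


_CROSS_SECTIONS: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None


def _cross_sections() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    global _CROSS_SECTIONS
    if _CROSS_SECTIONS is None:
        _CROSS_SECTIONS = load_cross_sections()
    return _CROSS_SECTIONS


def pss(spectrum: dict[float, float]) -> float:
    """Phytochrome photostationary state of a relative spectrum.

    ``spectrum`` maps wavelength (nm) to relative photon flux; the result
    is invariant to overall scaling.  Wavelengths outside the bundled
    cross-section range (300-800 nm) carry no weight; a spectrum entirely
    outside that range is a domain error.
    """
    lam, sig_r, sig_fr = _cross_sections()
    lo, hi = lam[0], lam[-1]
    wav = np.array([w for w in spectrum if lo <= w <= hi], dtype=float)
    if wav.size == 0:
        raise ValueError(
            f"spectrum lies entirely outside the cross-section range "
            f"[{lo:.0f}, {hi:.0f}] nm"
        )
    flux = np.array([spectrum[w] for w in spectrum if lo <= w <= hi], dtype=float)
    sr = np.interp(wav, lam, sig_r)
    sf = np.interp(wav, lam, sig_fr)
    denom = float(np.sum(flux * (sr + sf)))
    if denom <= 0:
        raise ValueError("spectrum has no phytochrome-absorbed photon flux")
    return float(np.sum(flux * sr) / denom)


def percent_change(reference: float, treatment: float) -> float:
    """Percent change of ``treatment`` relative to ``reference``.

    Returns ``100 * (treatment - reference) / reference`` at full
    precision; callers that print integers round half away from zero
    (:func:`round_half_away`), matching the treatment-contrast convention
    of the emulated study's tables.
    """
    if reference == 0:
        raise ValueError("percent change undefined for zero reference")
    return 100.0 * (treatment - reference) / reference


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (5 rounds up in magnitude)."""
    scale = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


@dataclass(frozen=True)
class LightRecipe:
    """Photon fluxes, photoperiod and (optional) spectrum of one treatment.

    Attributes
    ----------
    ppfd : photon flux 400-700 nm, umol m-2 s-1
    fr : photon flux 700-800 nm, umol m-2 s-1
    photoperiod_h : hours of light per 24-h cycle, (0, 24]
    spectrum : optional relative photon-flux distribution (nm -> fraction),
        normalised to 1 over 400-800 nm
    """

    ppfd: float
    fr: float = 0.0
    photoperiod_h: float = 24.0
    spectrum: dict[float, float] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.ppfd < 0 or self.fr < 0:
            raise ValueError("photon fluxes must be >= 0")
        if not 0 < self.photoperiod_h <= 24:
            raise ValueError("photoperiod_h must be in (0, 24]")
        if self.spectrum is not None:
            total = sum(self.spectrum.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"spectrum fractions must sum to 1, got {total}")

    @property
    def pfd(self) -> float:
        """Total photon flux density 400-800 nm (PPFD + far-red)."""
        return self.ppfd + self.fr

    def summary(self) -> "PhotonSummary":
        """Compute the full photon summary of this recipe."""
        r_fr = math.nan
        pss_val = math.nan
        if self.spectrum is not None:
            r_fr = red_farred_ratio(self.spectrum)
            pss_val = pss(self.spectrum)
        return PhotonSummary(
            pfd=self.pfd,
            dli=daily_integral(self.ppfd, self.photoperiod_h),
            tpfd=daily_integral(self.pfd, self.photoperiod_h),
            r_fr=r_fr,
            pss=pss_val,
        )


@dataclass(frozen=True)
class PhotonSummary:
    """Derived photon metrics of a light recipe.

    ``tpfd >= dli`` always (far-red adds photons); ``pss`` in [0, 1].
    """

    pfd: float
    dli: float
    tpfd: float
    r_fr: float
    pss: float

    def __post_init__(self) -> None:
        if self.tpfd < self.dli - 1e-12:
            raise ValueError("TPFD cannot be smaller than DLI")
        if not math.isnan(self.pss) and not 0 <= self.pss <= 1:
            raise ValueError("PSS must lie in [0, 1]")
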