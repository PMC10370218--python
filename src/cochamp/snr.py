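"""Signal-to-noise profiles along the cochlea and on/off enhancement.

The headline analysis: with the stapes-driven response P(x) = 2i P(0)
k(0) G(x, 0) as the signal and the incoherent-source quadrature

    N_rms(x) = gamma * sqrt( int_0^L |G(x, x')|^2 dx' )

as the noise, the narrowband SNR profile is

    R(x) ~ |G(x, 0)| / sqrt( int_0^x |G|^2 dx' + int_x^L |G|^2 dx' ),

the two integrals being the propagated contributions of basal and apical
noise sources.  The on/off enhancement R_on(x) / R_off(x) isolates what
spatially distributed amplification does for sensitivity; absolute SNRs
require a stimulus level and noise strength that the analysis never
fixes, so only ratios and normalized curves are reported.

Narrowband profiles follow the local characteristic frequency (one
frequency per place, zero bandwidth, excluding any amplifier-induced
bandwidth-reduction effects); broadband profiles sum signal and noise
powers incoherently over log-spaced frequencies spanning the model's CF
range (white spectra).  Near the cochlear entrance CF waves do not
travel far enough to be substantially amplified; such locations are
flagged and excluded from peak reporting, as is a short apical margin
inside the absorbing termination zone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from .cochlea2d import Cochlea2DModel
from .waveguide import CochlearModel

__all__ = [
    "GreensProvider",
    "WKBProvider",
    "FD1DProvider",
    "FD2DProvider",
    "make_provider",
    "SNRProfile",
    "EnhancementProfile",
    "BroadbandProfile",
    "narrowband_noise_rms",
    "basal_apical_decomposition",
    "snr_profile",
    "enhancement_profile_narrowband",
    "enhancement_profile_broadband",
    "normalized_signal_noise_curves",
]


def _db(ratio: np.ndarray | float) -> np.ndarray | float:
    """Amplitude ratio in dB (20 log10)."""
    return 20.0 * np.log10(ratio)


# ---------------------------------------------------------------------------
# Green's-function providers


class GreensProvider(Protocol):
    """Anything that yields a Green's matrix over a common spatial grid."""

    x: np.ndarray
    model: CochlearModel

    def green_matrix(
        self, frequency: float, active: bool, ablate_cutoff: bool = ...
    ) -> np.ndarray: ...


class _CachedProvider:
    """Green's matrices are expensive; memoize per (frequency, mode)."""

    def __init__(self) -> None:
        self._cache: dict[tuple[float, bool, bool], np.ndarray] = {}

    def _get(self, key, compute):
        if key not in self._cache:
            self._cache[key] = compute()
        return self._cache[key]


class WKBProvider(_CachedProvider):
    """Reflectionless WKB Green's function of the 1-D waveguide."""

    def __init__(self, model: CochlearModel | None = None) -> None:
        super().__init__()
        self.model = model or CochlearModel()
        self.x = self.model.geometry.x

    def green_matrix(self, frequency, active, ablate_cutoff=False):
        return self._get(
            (frequency, active, ablate_cutoff),
            lambda: self.model.wkb_green_matrix(
                frequency, active, ablate_cutoff=ablate_cutoff
            )[0],
        )


class FD1DProvider(_CachedProvider):
    """Finite-difference Green's function of the 1-D waveguide."""

    def __init__(self, model: CochlearModel | None = None) -> None:
        super().__init__()
        self.model = model or CochlearModel()
        self.x = self.model.geometry.x

    def green_matrix(self, frequency, active, ablate_cutoff=False):
        if ablate_cutoff:
            raise NotImplementedError("cut-off ablation is a WKB-only variant")
        return self._get(
            (frequency, active, False),
            lambda: self.model.fd_green_matrix(frequency, active)[0],
        )


class FD2DProvider(_CachedProvider):
    """Partition-pressure Green's function of the 2-D box model."""

    def __init__(self, model2d: Cochlea2DModel) -> None:
        super().__init__()
        self.model2d = model2d
        self.model = model2d.line
        self.x = model2d.x

    def green_matrix(self, frequency, active, ablate_cutoff=False):
        if ablate_cutoff:
            raise NotImplementedError("cut-off ablation is a WKB-only variant")
        return self._get(
            (frequency, active, False),
            lambda: self.model2d.greens_matrix(frequency, active)[0],
        )


def make_provider(name: str, model: CochlearModel | None = None, model2d=None):
    if name == "wkb":
        return WKBProvider(model)
    if name == "fd1d":
        return FD1DProvider(model)
    if name == "fd2d":
        if model2d is None:
            raise ValueError("provider 'fd2d' needs a Cochlea2DModel")
        return FD2DProvider(model2d)
    raise ValueError(f"unknown provider {name!r}; choose wkb, fd1d or fd2d")


def _signal_amplitude(provider, G: np.ndarray, frequency: float) -> np.ndarray:
    """Stapes-driven pressure magnitude |P(x)| = |2 k(0) G(x, 0)| (P(0)=1)."""
    k0 = provider.model.wavenumber(
        np.array([0.0]), 2 * np.pi * frequency, True
    )  # entrance wavenumber, amplification-independent by assumption
    return np.abs(2.0 * k0[0] * G[:, 0])


# ---------------------------------------------------------------------------
# Narrowband quantities


@dataclass(frozen=True)
class SNRProfile:
    frequency: float
    positions: np.ndarray
    signal_rms: np.ndarray
    noise_rms: np.ndarray
    basal_noise_power: np.ndarray
    apical_noise_power: np.ndarray
    mode: str  # "on" | "off"

    @property
    def snr(self) -> np.ndarray:
        return self.signal_rms / self.noise_rms


def narrowband_noise_rms(
    provider: GreensProvider, frequency: float, active: bool, gamma: float = 1.0
) -> np.ndarray:
    """Quadrature noise rms gamma * sqrt(int |G(x, x')|^2 dx')."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    G = provider.green_matrix(frequency, active)
    dx = provider.x[1] - provider.x[0]
    return gamma * np.sqrt(np.trapezoid(np.abs(G) ** 2, dx=dx, axis=1))


def basal_apical_decomposition(
    provider: GreensProvider, frequency: float, active: bool, gamma: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Split the noise-power integral at each x into basal and apical parts.

    Returns (basal, apical) power arrays; their sum is the total Eq.-13
    power.  The split uses trapezoid weights so basal + apical equals the
    full quadrature to round-off.
    """
    G = provider.green_matrix(frequency, active)
    dx = provider.x[1] - provider.x[0]
    p = np.abs(G) ** 2
    n = provider.x.size
    cum = np.concatenate(
        [np.zeros((n, 1)), np.cumsum(0.5 * (p[:, 1:] + p[:, :-1]) * dx, axis=1)],
        axis=1,
    )
    total = cum[:, -1]
    basal = cum[np.arange(n), np.arange(n)]
    return gamma**2 * basal, gamma**2 * (total - basal)


def snr_profile(
    provider: GreensProvider,
    frequency: float,
    active: bool,
    gamma: float = 1.0,
    signal_rms_in: float = 1.0,
) -> SNRProfile:
    """Signal, noise and SNR along the cochlea at one frequency."""
    G = provider.green_matrix(frequency, active)
    basal, apical = basal_apical_decomposition(provider, frequency, active, gamma)
    sig = signal_rms_in * _signal_amplitude(provider, G, frequency)
    return SNRProfile(
        frequency=frequency,
        positions=provider.x,
        signal_rms=sig,
        noise_rms=np.sqrt(basal + apical),
        basal_noise_power=basal,
        apical_noise_power=apical,
        mode="on" if active else "off",
    )


# ---------------------------------------------------------------------------
# Enhancement profiles


@dataclass(frozen=True)
class EnhancementPoint:
    frequency: float
    position: float  # evaluation place (characteristic place when defined)
    enhancement_db: float
    on_snr_db: float
    signal_gain_db: float  # on/off signal gain at the evaluation place
    has_crossing: bool
    near_base_flag: bool = field(default=False)


@dataclass(frozen=True)
class EnhancementProfile:
    """CF-following narrowband enhancement, one point per probe frequency."""

    points: list[EnhancementPoint]
    band: tuple[float, float]

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([p.frequency for p in self.points])

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.points])

    @property
    def enhancement_db(self) -> np.ndarray:
        return np.array([p.enhancement_db for p in self.points])

    @property
    def flags(self) -> np.ndarray:
        return np.array([p.near_base_flag for p in self.points])

    def unflagged(self) -> list[EnhancementPoint]:
        return [p for p in self.points if not p.near_base_flag]

    @property
    def peak_enhancement_db(self) -> float:
        """Largest enhancement outside the flagged near-base region."""
        return max(p.enhancement_db for p in self.unflagged())

    @property
    def most_sensitive_enhancement_db(self) -> float:
        """Enhancement where the on-mode SNR is maximal (unflagged points)."""
        return max(self.unflagged(), key=lambda p: p.on_snr_db).enhancement_db

    @property
    def near_base_extent(self) -> float:
        """Apical-most flagged position in the basal half (0 if none)."""
        flagged = [p.position for p in self.points if p.near_base_flag]
        basal_half = [x for x in flagged if x < 0.5 * max(p.position for p in self.points)]
        return max(basal_half, default=0.0)


def enhancement_profile_narrowband(
    provider: GreensProvider,
    frequencies: np.ndarray | None = None,
    num_freqs: int = 33,
    band_margin: float = 1.05,
    gain_fraction: float = 0.5,
) -> EnhancementProfile:
    """On/off SNR enhancement at the characteristic place, following CF.

    One probe frequency per point; each is evaluated at the active
    model's characteristic place (the Im(k) crossing) or, where none
    exists, at the active response peak.  A point is flagged near-base
    when (i) there is no crossing, (ii) its on/off CF signal gain in dB
    is below ``gain_fraction`` of the band maximum, or (iii) its
    enhancement is <= 0 dB -- operationalizing "CF waves near the
    entrance do not travel far enough to be substantially amplified".
    Frequencies outside the model's CF band are rejected.
    """
    part = provider.model.partition
    lo, hi = part.cf_apex, part.cf_base
    if frequencies is None:
        frequencies = np.geomspace(lo * band_margin, hi / band_margin, num_freqs)
    frequencies = np.asarray(frequencies, dtype=float)
    if np.any(frequencies < lo) or np.any(frequencies > hi):
        raise ValueError(
            f"probe frequencies outside the CF band {lo / 1e3:.3g}-{hi / 1e3:.3g} kHz"
        )
    pts: list[EnhancementPoint] = []
    x = provider.x
    for f in frequencies:
        on = snr_profile(provider, f, True)
        off = snr_profile(provider, f, False)
        try:
            xh = provider.model.characteristic_place(f, active=True)
            has_crossing = True
        except ValueError:
            # no active Im(k) crossing: evaluate at the tonotopic place
            L = provider.model.geometry.length
            xh = L * np.log(part.cf_base / f) / np.log(part.cf_base / part.cf_apex)
            has_crossing = False
        j = int(np.argmin(np.abs(x - xh)))
        pts.append(
            EnhancementPoint(
                frequency=f,
                position=xh,
                enhancement_db=float(_db(on.snr[j] / off.snr[j])),
                on_snr_db=float(_db(on.snr[j])),
                signal_gain_db=float(_db(on.signal_rms[j] / off.signal_rms[j])),
                has_crossing=has_crossing,
            )
        )
    max_gain = max(p.signal_gain_db for p in pts)
    flagged = [
        EnhancementPoint(
            p.frequency,
            p.position,
            p.enhancement_db,
            p.on_snr_db,
            p.signal_gain_db,
            p.has_crossing,
            near_base_flag=(
                (not p.has_crossing)
                or p.signal_gain_db < gain_fraction * max_gain
                or p.enhancement_db <= 0.0
            ),
        )
        for p in pts
    ]
    return EnhancementProfile(points=flagged, band=(float(lo), float(hi)))


@dataclass(frozen=True)
class BroadbandProfile:
    """Per-location broadband (white-spectrum) SNR enhancement."""

    positions: np.ndarray
    enhancement_db: np.ndarray
    signal_gain_db: np.ndarray
    noise_gain_db: np.ndarray
    band: tuple[float, float]
    num_freqs: int
    near_base_extent: float  # basal exclusion from the narrowband flags
    apical_margin: float  # absorbing-termination exclusion

    @property
    def reporting_mask(self) -> np.ndarray:
        L = self.positions[-1]
        return (self.positions > self.near_base_extent) & (
            self.positions < L - self.apical_margin
        )

    @property
    def peak_enhancement_db(self) -> float:
        return float(np.max(self.enhancement_db[self.reporting_mask]))

    @property
    def peak_position(self) -> float:
        masked = np.where(self.reporting_mask, self.enhancement_db, -np.inf)
        return float(self.positions[int(np.argmax(masked))])


def enhancement_profile_broadband(
    provider: GreensProvider,
    band: tuple[float, float] = (4e3, 70e3),
    num_freqs: int = 64,
    apical_margin: float = 0.25e-3,
    narrowband: EnhancementProfile | None = None,
) -> BroadbandProfile:
    """Broadband on/off enhancement for white signal and noise spectra.

    Signal and noise powers are summed incoherently over ``num_freqs``
    log-spaced frequencies (white spectra, unspecified phases).  The
    near-base exclusion is inherited from the narrowband flags (computed
    here unless supplied); the apical margin excludes the absorbing
    termination zone from peak reporting.  A single-frequency band
    reduces to the narrowband result at that frequency.
    """
    part = provider.model.partition
    lo, hi = band
    if lo < part.cf_apex * (1 - 1e-9) or hi > part.cf_base * (1 + 1e-9):
        raise ValueError(
            f"band {lo / 1e3:.3g}-{hi / 1e3:.3g} kHz outside the model CF map "
            f"({part.cf_apex / 1e3:.3g}-{part.cf_base / 1e3:.3g} kHz)"
        )
    freqs = (
        np.geomspace(lo, hi, num_freqs) if num_freqs > 1 else np.array([float(lo)])
    )
    n = provider.x.size
    sig = {True: np.zeros(n), False: np.zeros(n)}
    noz = {True: np.zeros(n), False: np.zeros(n)}
    for f in freqs:
        for active in (True, False):
            G = provider.green_matrix(f, active)
            sig[active] += _signal_amplitude(provider, G, f) ** 2
            noz[active] += narrowband_noise_rms(provider, f, active) ** 2
    if narrowband is None:
        narrowband = enhancement_profile_narrowband(provider)
    # power ratios -> amplitude-gain dB (20 log10 of the amplitude ratio)
    sgain = 10.0 * np.log10(sig[True] / sig[False])
    ngain = 10.0 * np.log10(noz[True] / noz[False])
    return BroadbandProfile(
        positions=provider.x,
        enhancement_db=sgain - ngain,
        signal_gain_db=sgain,
        noise_gain_db=ngain,
        band=(float(lo), float(hi)),
        num_freqs=num_freqs,
        near_base_extent=narrowband.near_base_extent,
        apical_margin=apical_margin,
    )


# ---------------------------------------------------------------------------
# Normalized signal/noise curves (postmortem-equality convention)


@dataclass(frozen=True)
class NormalizedCurves:
    frequency: float
    positions: np.ndarray
    characteristic_place: float
    signal_on: np.ndarray
    signal_off: np.ndarray
    noise_on: np.ndarray
    noise_off: np.ndarray
    response: str  # "pressure" | "velocity"


def normalized_signal_noise_curves(
    provider: GreensProvider, frequency: float, response: str = "pressure"
) -> NormalizedCurves:
    """Paired on/off signal and noise magnitude curves at one frequency.

    The noise curves (both modes, same physical noise strength) are
    rescaled by a single factor so that signal and noise are equal at the
    characteristic place in the postmortem (off) state; with the
    amplifier on, the signal then exceeds the noise near the peak while
    the noise is relatively more amplified toward the entrance.  With
    ``response='velocity'`` all four curves are converted to partition
    velocity through the local admittance magnitude (the conversion is
    common to signal and noise, so SNR ratios are unchanged).
    """
    on = snr_profile(provider, frequency, True)
    off = snr_profile(provider, frequency, False)
    xh = provider.model.characteristic_place(frequency, active=True)
    j = int(np.argmin(np.abs(provider.x - xh)))
    conv_on = np.ones_like(provider.x)
    conv_off = np.ones_like(provider.x)
    if response == "velocity":
        omega = 2 * np.pi * frequency
        conv_on = np.abs(provider.model.admittance(provider.x, omega, True))
        conv_off = np.abs(provider.model.admittance(provider.x, omega, False))
    elif response != "pressure":
        raise ValueError("response must be 'pressure' or 'velocity'")
    scale = off.signal_rms[j] / off.noise_rms[j]
    return NormalizedCurves(
        frequency=frequency,
        positions=provider.x,
        characteristic_place=xh,
        signal_on=conv_on * on.signal_rms,
        signal_off=conv_off * off.signal_rms,
        noise_on=conv_on * scale * on.noise_rms,
        noise_off=conv_off * scale * off.noise_rms,
        response=response,
    )
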