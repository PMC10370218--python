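"""One-dimensional active cochlear waveguide.

The cochlea is modelled as a fluid-loaded transmission line: the pressure
difference P across the cochlear partition obeys

    (1/A) d/dx (A dP/dx) + k(x, w)^2 P = 0,

where A(x) is the scalae cross-sectional area and the local complex
wavenumber follows from the series fluid impedance Z = i*w*M and the
partition admittance Y (velocity per unit pressure),

    k^2 = w^2 (M / m_p) / (w_c^2 - w^2 + i * delta * w * w_c),

with w_c(x) = 2*pi*CF(x) the local resonance of a single-degree-of-freedom
partition oscillator of surface mass m_p and dimensionless damping delta.
The tonotopic map CF(x) is exponential, high frequencies basal.

Conventions: time dependence e^{+iwt}; forward (base-to-apex) waves go as
exp(-i int k dx), so Im(k) > 0 means gain per unit length and Im(k) < 0
attenuation.  With the amplifier off, delta = delta_passive > 0 and Im(k)
is negative everywhere.  With the amplifier on, the damping is blended
smoothly from delta_active < 0 below the local resonance to
delta_passive above it, which yields exactly one + -> - crossing of
Im(k): waves are amplified up to the characteristic place x_hat and cut
off sharply beyond it.  Two further ingredients shape the ends of the
duct: an activity-onset ramp at the base (amplification needs space to
build up, so waves with very basal characteristic places are barely
amplified) and a helicotrema-like damping zone at the apex that absorbs
the lowest-frequency waves in both modes.

Solvers: a WKB Green's function (amplitude prefactor times the
accumulated phase integral) and a second-order finite-difference
discretization of the transmission-line equation with radiation
(reflectionless) boundary conditions, used as a numeric oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.linalg import solve_banded
from scipy.optimize import brentq

__all__ = [
    "CochlearGeometry",
    "PartitionModel",
    "WaveField",
    "CochlearModel",
    "cf_map",
    "SingularWKBWarning",
    "GradientWarning",
]

Activity = Literal["on", "off"]


class SingularWKBWarning(UserWarning):
    """Raised when |k| is close to zero somewhere along a WKB path."""


class GradientWarning(UserWarning):
    """Raised when |dk/dx| / |k|^2 exceeds the gentle-gradient threshold."""


@dataclass(frozen=True)
class CochlearGeometry:
    """Duct geometry: length, cross-section profile and spatial grid.

    ``area_taper`` is the exponential taper exponent over the full
    length: A(x) = area_base * exp(-area_taper * x / length).  The
    default is an untapered (box) duct matching the 2-D model.
    """

    length: float = 5e-3  # m
    height: float = 0.5e-3  # m, fluid-chamber height (used by the 2-D model)
    grid: int = 1024
    area_base: float = 2.5e-7  # m^2
    area_taper: float = 0.0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.height <= 0 or self.area_base <= 0:
            raise ValueError("length, height and area_base must be > 0")
        if self.grid < 16:
            raise ValueError("grid must have at least 16 samples")

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, self.length, self.grid)

    @property
    def dx(self) -> float:
        return self.length / (self.grid - 1)

    def area(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.area_base * np.exp(-self.area_taper * np.asarray(x) / self.length)


@dataclass(frozen=True)
class PartitionModel:
    """Tonotopic map and oscillator admittance of the cochlear partition.

    ``fluid_mass_density`` M (series acoustic mass of the scalae fluids
    per unit length and area, default 2*rho/H) and ``partition_mass``
    m_p (partition mass per unit area) enter only through the wavenumber
    scale sqrt(M/m_p) ~ 1.7e4 /m, which sets the ~0.24 mm wavelength at
    the response peak.  Damping ratios are dimensionless: negative when
    the amplifier injects power, positive when it dissipates.
    """

    cf_base: float = 70e3  # Hz, CF at x = 0 (stapes)
    cf_apex: float = 4e3  # Hz, CF at x = L
    fluid_mass_density: float = 4.0e6  # kg/m^4, M = 2*rho/H for the default box
    partition_mass: float = 4.0e6 / 17000.0**2  # kg/m^2 -> sqrt(M/m_p) = 17000/m
    damping_active: float = -0.08
    damping_passive: float = 0.20
    activity_steepness: float = 16.0  # sigmoid power p in the on-mode damping blend
    activity_center: float = 1.0  # blend centered at w/w_c = activity_center
    onset_length: float = 0.4e-3  # m, basal ramp over which activity switches on
    helicotrema_damping: float = 3.0  # extra damping at the apical termination
    helicotrema_length: float = 0.5e-3  # m, e-folding length of that zone

    def __post_init__(self) -> None:
        if not self.cf_base > self.cf_apex > 0:
            raise ValueError("need cf_base > cf_apex > 0")
        if self.damping_active >= 0 or self.damping_passive <= 0:
            raise ValueError("need damping_active < 0 < damping_passive")
        if self.fluid_mass_density <= 0 or self.partition_mass <= 0:
            raise ValueError("masses must be > 0")

    @property
    def wavenumber_scale(self) -> float:
        """sqrt(M / m_p), the long-wave wavenumber per unit (w / w_c)."""
        return float(np.sqrt(self.fluid_mass_density / self.partition_mass))


def cf_map(x: np.ndarray | float, length: float, cf_base: float, cf_apex: float):
    """Exponential tonotopic map CF(x) = cf_base * (cf_apex/cf_base)**(x/L)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < -1e-12) or np.any(x > length * (1 + 1e-12)):
        raise ValueError("position outside [0, L]")
    return cf_base * (cf_apex / cf_base) ** (x / length)


@dataclass(frozen=True)
class WaveField:
    """Complex pressure sampled on the spatial grid at one frequency."""

    frequency: float  # Hz
    positions: np.ndarray  # m
    pressure: np.ndarray  # complex
    wavenumber: np.ndarray | None = None  # complex k(x), None for 2-D fields

    @property
    def magnitude_db(self) -> np.ndarray:
        return 20.0 * np.log10(np.abs(self.pressure) + 1e-300)

    @property
    def phase_cycles(self) -> np.ndarray:
        return np.unwrap(np.angle(self.pressure)) / (2.0 * np.pi)

    def energy_flux(self) -> np.ndarray:
        """Wave energy flux ~ -Im(P* dP/dx); peaks where gain turns to loss."""
        dp = np.gradient(self.pressure, self.positions)
        return -np.imag(np.conj(self.pressure) * dp)


class CochlearModel:
    """1-D cochlear waveguide bundling geometry, partition and solvers."""

    #: WKB validity threshold on |dk/dx|/|k|^2 used for graceful-degradation
    #: warnings; above it the expected WKB-vs-FD error exceeds ~1 dB.  The
    #: calibrated default model stays below it everywhere in band.
    gentle_gradient_threshold: float = 0.75

    def __init__(
        self,
        geometry: CochlearGeometry | None = None,
        partition: PartitionModel | None = None,
    ) -> None:
        self.geometry = geometry or CochlearGeometry()
        self.partition = partition or PartitionModel()

    # -- maps and material functions -------------------------------------

    def cf(self, x: np.ndarray | float):
        g, p = self.geometry, self.partition
        return cf_map(x, g.length, p.cf_base, p.cf_apex)

    def in_band(self, frequency: float) -> bool:
        return self.partition.cf_apex <= frequency <= self.partition.cf_base

    def damping(self, x, omega: float, active: bool) -> np.ndarray:
        """Effective dimensionless damping delta_eff(x, w)."""
        p = self.partition
        x = np.asarray(x, dtype=float)
        heli = p.helicotrema_damping * np.exp(
            (x - self.geometry.length) / p.helicotrema_length
        )
        if not active:
            return p.damping_passive + heli
        r = omega / (2.0 * np.pi * self.cf(x))
        blend = 1.0 / (1.0 + (r / p.activity_center) ** p.activity_steepness)
        ramp = 1.0 - np.exp(-((x / p.onset_length) ** 2))
        return (
            p.damping_passive
            + (p.damping_active - p.damping_passive) * blend * ramp
            + heli
        )

    def admittance(self, x, omega: float, active: bool) -> np.ndarray:
        """Partition admittance Y = V_CP / P0 of the oscillator model."""
        p = self.partition
        wc = 2.0 * np.pi * self.cf(x)
        delta = self.damping(x, omega, active)
        denom = wc**2 - omega**2 + 1j * delta * omega * wc
        return 1j * omega / (p.partition_mass * denom)

    def wavenumber(
        self, x, omega: float, active: bool, ablate_cutoff: bool = False
    ) -> np.ndarray:
        """Complex k(x, w); principal square root of the oscillator dispersion.

        ``ablate_cutoff`` is a synthetic variant for ablation studies: it
        forces Im(k) >= 0 apical to the characteristic place (no
        evanescent cut-off), leaving Re(k) untouched.
        """
        x = np.asarray(x, dtype=float)
        wc = 2.0 * np.pi * self.cf(x)
        delta = self.damping(x, omega, active)
        denom = wc**2 - omega**2 + 1j * delta * omega * wc
        if np.any(np.abs(denom) < 1e-12 * np.max(wc) ** 2):
            raise FloatingPointError(
                "admittance pole encountered; frequency/position combination invalid"
            )
        k = self.partition.wavenumber_scale * omega / np.sqrt(denom)
        if ablate_cutoff:
            im = np.imag(k)
            crossing = np.where((im[:-1] > 0) & (im[1:] <= 0))[0]
            if crossing.size:
                j = crossing[0] + 1
                k = k.copy()
                k[j:] = np.real(k[j:]) + 1j * np.maximum(im[j:], 0.0)
        return k

    def characteristic_place(self, frequency: float, active: bool = True) -> float:
        """Location x_hat where Im(k) crosses zero from + to -.

        Raises ValueError when no sign change exists in [0, L] (frequency
        effectively out of the amplified band, e.g. very basal CFs where
        the activity onset ramp keeps the partition dissipative).
        """
        omega = 2.0 * np.pi * frequency
        x = self.geometry.x
        im = np.imag(self.wavenumber(x, omega, active))
        idx = np.where((im[:-1] > 0) & (im[1:] <= 0))[0]
        if idx.size == 0:
            raise ValueError(
                f"no Im(k) sign change in [0, L] at {frequency / 1e3:.3g} kHz; "
                "frequency outside the amplified band"
            )
        j = idx[0]
        f = lambda xx: float(np.imag(self.wavenumber(np.array([xx]), omega, active))[0])
        return brentq(f, x[j], x[j + 1], xtol=self.geometry.dx * 1e-3)

    # -- resolution contract ---------------------------------------------

    def points_per_wavelength(self, omega: float, active: bool) -> float:
        k = self.wavenumber(self.geometry.x, omega, active)
        re = np.abs(np.real(k))
        lam_min = 2.0 * np.pi / re.max()
        return lam_min / self.geometry.dx

    def validate_resolution(self, frequency: float, active: bool = True, minimum: float = 20.0) -> None:
        ppw = self.points_per_wavelength(2 * np.pi * frequency, active)
        if ppw < minimum:
            raise ValueError(
                f"grid resolution contract violated: {ppw:.1f} points per "
                f"shortest wavelength at {frequency / 1e3:.3g} kHz (need >= {minimum}); "
                "increase CochlearGeometry.grid"
            )

    # -- WKB solver -------------------------------------------------------

    def _phase_integral(self, k: np.ndarray) -> np.ndarray:
        dx = self.geometry.dx
        return np.concatenate([[0.0], np.cumsum(0.5 * (k[1:] + k[:-1]) * dx)])

    def wkb_green_matrix(
        self, frequency: float, active: bool, ablate_cutoff: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        """Green's function G(x_i, x_j) on the grid, and k(x) alongside.

        G(x, x') = (1/2i) sqrt(A(x')/A(x)) / sqrt(k(x) k(x'))
                   * exp(-i * int_{min}^{max} k dx),
        the reflectionless-boundary WKB form; the phase integral uses the
        composite trapezoid on the grid.
        """
        omega = 2.0 * np.pi * frequency
        x = self.geometry.x
        k = self.wavenumber(x, omega, active, ablate_cutoff=ablate_cutoff)
        if np.min(np.abs(k)) < 1e-6 * np.max(np.abs(k)):
            j = int(np.argmin(np.abs(k)))
            warnings.warn(
                f"k nearly zero at x = {x[j] * 1e3:.3f} mm; WKB form singular there",
                SingularWKBWarning,
            )
        grad = np.abs(np.gradient(k, x)) / np.abs(k) ** 2
        if np.max(grad) > self.gentle_gradient_threshold:
            warnings.warn(
                "wavenumber gradient exceeds the gentle-gradient threshold "
                f"(max |dk/dx|/k^2 = {np.max(grad):.2f}); WKB accuracy degrades",
                GradientWarning,
            )
        cum = self._phase_integral(k)
        diff = cum[:, None] - cum[None, :]
        ordered = np.where(
            np.arange(x.size)[:, None] >= np.arange(x.size)[None, :], diff, -diff
        )
        sk = np.sqrt(k)
        amp = 1.0 / (2j * np.outer(sk, sk))
        area = np.asarray(self.geometry.area(x), dtype=float)
        if self.geometry.area_taper != 0.0:
            amp = amp * np.sqrt(area[None, :] / area[:, None])
        return amp * np.exp(-1j * ordered), k

    def wkb_green(
        self, x_obs: float, x_src: float, frequency: float, active: bool
    ) -> complex:
        """Pointwise WKB Green's function between two locations (on-grid)."""
        x = self.geometry.x
        i = int(np.argmin(np.abs(x - x_obs)))
        j = int(np.argmin(np.abs(x - x_src)))
        G, _ = self.wkb_green_matrix(frequency, active)
        return complex(G[i, j])

    def stapes_response(
        self,
        frequency: float,
        active: bool,
        p0: complex = 1.0,
        method: str = "wkb",
        ablate_cutoff: bool = False,
    ) -> WaveField:
        """Pressure response to a stapes drive of entrance pressure p0.

        The WKB route evaluates P(x) = 2i P(0) k(0) G(x, 0); the "fd"
        route solves the transmission-line equation with a prescribed
        entrance pressure and an absorbing apex.
        """
        if method == "fd":
            return self.solve_fd(frequency, active, source="stapes", p0=p0)
        G, k = self.wkb_green_matrix(frequency, active, ablate_cutoff=ablate_cutoff)
        pressure = 2j * p0 * k[0] * G[:, 0]
        return WaveField(frequency, self.geometry.x, pressure, k)

    # -- finite-difference solver ------------------------------------------

    def solve_fd(
        self,
        frequency: float,
        active: bool,
        source: str = "stapes",
        source_position: float | None = None,
        p0: complex = 1.0,
        check_resolution: bool = True,
    ) -> WaveField:
        """Second-order FD solve of (1/A)(A P')' + k^2 P = 0.

        ``source='stapes'`` prescribes P(0) = p0 (Dirichlet drive);
        ``source='point'`` injects a unit point source at
        ``source_position`` with a radiation condition at the base.  The
        apex always carries a radiation (one-way) condition matched to
        the local k, emulating reflectionless termination; the cut-off
        region makes apical reflections negligible in-band.  One banded
        complex linear system is solved per call.
        """
        if check_resolution:
            self.validate_resolution(frequency, active)
        omega = 2.0 * np.pi * frequency
        x = self.geometry.x
        n = x.size
        h = self.geometry.dx
        k = self.wavenumber(x, omega, active)
        area = np.broadcast_to(
            np.asarray(self.geometry.area(x), dtype=float), x.shape
        ).copy()
        a_half = 0.5 * (area[1:] + area[:-1])  # A at i +/- 1/2
        lower = np.zeros(n, dtype=complex)
        diag = np.zeros(n, dtype=complex)
        upper = np.zeros(n, dtype=complex)
        rhs = np.zeros(n, dtype=complex)
        # interior rows of the self-adjoint form (A P')' + k^2 A P = f
        lower[1:-1] = a_half[:-1]
        upper[1:-1] = a_half[1:]
        diag[1:-1] = -(a_half[:-1] + a_half[1:]) + (k[1:-1] * h) ** 2 * area[1:-1]
        if source == "stapes":
            diag[0] = 1.0
            rhs[0] = p0
        elif source == "point":
            if source_position is None:
                raise ValueError("source='point' requires source_position")
            j = int(np.argmin(np.abs(x - source_position)))
            # radiation at the base: P' = +i k(0) P (outgoing basal wave)
            diag[0] = -2.0 * area[0] + (k[0] * h) ** 2 * area[0] - 2j * k[0] * h * area[0]
            upper[0] = 2.0 * area[0]
            # discrete delta: (A G')' + k^2 A G = -A(x') * delta -> rhs -A_j h
            rhs[j] += -area[j] * h
            if j == 0:
                raise ValueError("point source at the basal boundary is not supported")
        else:
            raise ValueError("source must be 'stapes' or 'point'")
        # radiation at the apex: P' = -i k(L) P (outgoing apical wave)
        diag[-1] = -2.0 * area[-1] + (k[-1] * h) ** 2 * area[-1] - 2j * k[-1] * h * area[-1]
        lower[-1] = 2.0 * area[-1]
        ab = np.zeros((3, n), dtype=complex)
        ab[0, 1:] = upper[:-1]
        ab[1] = diag
        ab[2, :-1] = lower[1:]
        with np.errstate(all="raise"):
            try:
                pressure = solve_banded((1, 1), ab, rhs)
            except FloatingPointError as exc:  # pragma: no cover - defensive
                raise RuntimeError(
                    f"FD system singular or ill-conditioned at {frequency} Hz: {exc}"
                ) from exc
        if not np.all(np.isfinite(pressure)):
            raise RuntimeError(
                f"FD solve produced non-finite values at {frequency} Hz "
                "(near-singular discretized operator; jitter the frequency)"
            )
        return WaveField(frequency, x, pressure, k)

    def fd_green_matrix(
        self, frequency: float, active: bool, check_resolution: bool = True
    ) -> tuple[np.ndarray, np.ndarray]:
        """Numeric Green's matrix: one banded solve with all-columns RHS.

        Column j is the response to a unit point source at x_j, with
        radiation conditions at both ends, normalized consistently with
        the WKB convention (uniform-medium limit e^{-ik|x-x'|} / 2ik).
        """
        if check_resolution:
            self.validate_resolution(frequency, active)
        omega = 2.0 * np.pi * frequency
        x = self.geometry.x
        n = x.size
        h = self.geometry.dx
        k = self.wavenumber(x, omega, active)
        area = np.broadcast_to(
            np.asarray(self.geometry.area(x), dtype=float), x.shape
        ).copy()
        a_half = 0.5 * (area[1:] + area[:-1])
        lower = np.zeros(n, dtype=complex)
        diag = np.zeros(n, dtype=complex)
        upper = np.zeros(n, dtype=complex)
        lower[1:-1] = a_half[:-1]
        upper[1:-1] = a_half[1:]
        diag[1:-1] = -(a_half[:-1] + a_half[1:]) + (k[1:-1] * h) ** 2 * area[1:-1]
        diag[0] = -2.0 * area[0] + (k[0] * h) ** 2 * area[0] - 2j * k[0] * h * area[0]
        upper[0] = 2.0 * area[0]
        diag[-1] = -2.0 * area[-1] + (k[-1] * h) ** 2 * area[-1] - 2j * k[-1] * h * area[-1]
        lower[-1] = 2.0 * area[-1]
        ab = np.zeros((3, n), dtype=complex)
        ab[0, 1:] = upper[:-1]
        ab[1] = diag
        ab[2, :-1] = lower[1:]
        rhs = np.diag(-area * h).astype(complex)
        G = solve_banded((1, 1), ab, rhs)
        return G, k
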