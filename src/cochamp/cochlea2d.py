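"""Frequency-domain 2-D "box" cochlea.

An incompressible fluid occupies a rectangular chamber 0 <= x <= L,
0 <= y <= H above the cochlear partition (the mirror-image lower chamber
is folded in through the pressure-difference symmetry, giving the
factor-of-two partition boundary condition).  The pressure difference
P(x, y) satisfies Laplace's equation with

* partition (y = 0):  dP/dy = 2 i w rho Y(x, w) P, the admittance Y
  linking the normal pressure gradient to partition acceleration
  (V_CP = Y P0);
* rigid top wall (y = H):  dP/dy = 0;
* stapes (x = 0): either a prescribed piston drive dP/dx = -2 i w rho v_st
  or a mixed (impedance) condition realizing a wave reflectance R_st for
  basally travelling waves;
* apex (x = L): radiation condition matched to the local 1-D wavenumber
  (absorbing termination).

In the long-wavelength (shallow-fluid) limit |k| H << 1 the depth-averaged
solution reduces to the 1-D transmission line of
:mod:`cochamp.waveguide`, which serves as a cross-solver oracle.  Near
the response peak |k| H >> 1 and the 2-D model develops its own
(deep-fluid) dispersion, as in more realistic cochlear geometries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu, spsolve

from .waveguide import CochlearGeometry, CochlearModel, PartitionModel

__all__ = ["Cochlea2DConfig", "BMResponse", "Cochlea2DModel"]

RHO_FLUID = 1000.0  # kg/m^3


@dataclass(frozen=True)
class Cochlea2DConfig:
    geometry: CochlearGeometry = field(default_factory=CochlearGeometry)
    partition: PartitionModel = field(default_factory=PartitionModel)
    stapes_reflectance: complex = 0.0
    grid_nx: int = 768
    grid_ny: int = 48

    def __post_init__(self) -> None:
        if abs(self.stapes_reflectance) >= 1:
            raise ValueError("|stapes_reflectance| must be < 1")
        if self.grid_nx < 32 or self.grid_ny < 8:
            raise ValueError("grid too coarse (need nx >= 32, ny >= 8)")


@dataclass(frozen=True)
class BMResponse:
    """Partition-level response of the 2-D model at one frequency."""

    frequency: float
    positions: np.ndarray
    pressure_at_partition: np.ndarray  # complex P0(x)
    bm_velocity: np.ndarray  # complex V_CP(x) = Y * P0
    fluid_pressure: np.ndarray  # complex P(x, y), shape (nx, ny)


class Cochlea2DModel:
    """Sparse finite-difference solver for the 2-D box cochlea."""

    def __init__(self, config: Cochlea2DConfig | None = None) -> None:
        self.config = config or Cochlea2DConfig()
        # The 1-D companion provides CF map, admittance and the local
        # wavenumber used by the radiation boundary conditions.
        geo = self.config.geometry
        self.line = CochlearModel(
            CochlearGeometry(
                length=geo.length,
                height=geo.height,
                grid=self.config.grid_nx,
                area_base=geo.area_base,
                area_taper=geo.area_taper,
            ),
            self.config.partition,
        )

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, self.config.geometry.length, self.config.grid_nx)

    @property
    def y(self) -> np.ndarray:
        return np.linspace(0.0, self.config.geometry.height, self.config.grid_ny)

    def validate_resolution(self, frequency: float, active: bool = True, minimum: float = 10.0) -> None:
        """Both grid directions must resolve the shortest in-band scale."""
        k = self.line.wavenumber(self.x, 2 * np.pi * frequency, active)
        lam_min = 2.0 * np.pi / np.abs(np.real(k)).max()
        hx = self.x[1] - self.x[0]
        hy = self.y[1] - self.y[0]
        if lam_min / hx < minimum:
            raise ValueError(
                f"x-resolution contract violated: {lam_min / hx:.1f} points per "
                f"wavelength at {frequency / 1e3:.3g} kHz (need >= {minimum})"
            )
        if hy > self.config.geometry.height / 8:
            raise ValueError("y-resolution contract violated: need >= 8 cells over H")

    # -- assembly ----------------------------------------------------------

    def _assemble(
        self,
        frequency: float,
        active: bool,
        drive: str,
        source_position: float | None,
        stapes_velocity: complex,
    ) -> tuple[sp.csr_matrix, np.ndarray]:
        cfg = self.config
        nx, ny = cfg.grid_nx, cfg.grid_ny
        x, y = self.x, self.y
        hx, hy = x[1] - x[0], y[1] - y[0]
        omega = 2.0 * np.pi * frequency
        Y = self.line.admittance(x, omega, active)
        kb = self.line.wavenumber(np.array([0.0]), omega, active)[0]
        ka = self.line.wavenumber(np.array([x[-1]]), omega, active)[0]
        idx = lambda i, j: i * ny + j

        rows: list[int] = []
        cols: list[int] = []
        vals: list[complex] = []
        rhs = np.zeros(nx * ny, dtype=complex)

        def add(i, j, ii, jj, v):
            rows.append(idx(i, j))
            cols.append(idx(ii, jj))
            vals.append(v)

        cx, cy = 1.0 / hx**2, 1.0 / hy**2
        R = cfg.stapes_reflectance
        # mixed stapes condition: dP/dx = i k_b (1 - R)/(1 + R) P reflects a
        # basally travelling wave with amplitude reflectance R (R = 0 absorbs)
        alpha_st = 1j * kb * (1.0 - R) / (1.0 + R)

        for i in range(nx):
            for j in range(ny):
                diag = -2.0 * (cx + cy)
                # x neighbours (ghost elimination at the two ends)
                if i == 0:
                    add(i, j, 1, j, 2.0 * cx)
                    if drive == "stapes":
                        # piston: dP/dx = -2 i w rho v_st;
                        # ghost P_{-1} = P_1 + 2 hx * 2 i w rho v_st
                        rhs[idx(i, j)] += -2.0 * cx * hx * (
                            2j * omega * RHO_FLUID * stapes_velocity
                        )
                    else:
                        diag += -2.0 * cx * hx * alpha_st
                elif i == nx - 1:
                    add(i, j, nx - 2, j, 2.0 * cx)
                    diag += -2.0 * cx * hx * (1j * ka)  # dP/dx = -i k_a P
                else:
                    add(i, j, i - 1, j, cx)
                    add(i, j, i + 1, j, cx)
                # y neighbours
                if j == 0:
                    add(i, j, i, 1, 2.0 * cy)
                    diag += -2.0 * cy * hy * (2j * omega * RHO_FLUID * Y[i])
                elif j == ny - 1:
                    add(i, j, i, ny - 2, 2.0 * cy)
                else:
                    add(i, j, i, j - 1, cy)
                    add(i, j, i, j + 1, cy)
                add(i, j, i, j, diag)

        if drive == "point":
            if source_position is None:
                raise ValueError("point drive requires source_position")
            js = int(np.argmin(np.abs(x - source_position)))
            # volume-velocity injection through the partition at one cell,
            # normalized so the depth-averaged equation carries -delta(x-x')
            rhs[idx(js, 0)] += -2.0 * cy * hy * (cfg.geometry.height / hx)
        elif drive == "zero":
            pass
        elif drive != "stapes":
            raise ValueError("drive must be 'stapes', 'point' or 'zero'")

        mat = sp.csr_matrix(
            (vals, (rows, cols)), shape=(nx * ny, nx * ny), dtype=complex
        )
        return mat, rhs

    # -- solves ------------------------------------------------------------

    def solve(
        self,
        frequency: float,
        active: bool,
        drive: str = "stapes",
        source_position: float | None = None,
        stapes_velocity: complex = 1e-3,
        check_resolution: bool = True,
    ) -> BMResponse:
        """Solve the 2-D field for a stapes piston or a partition point source."""
        if check_resolution:
            self.validate_resolution(frequency, active)
        mat, rhs = self._assemble(
            frequency, active, drive, source_position, stapes_velocity
        )
        field2d = spsolve(mat, rhs).reshape(self.config.grid_nx, self.config.grid_ny)
        if not np.all(np.isfinite(field2d)):
            raise RuntimeError(
                f"2-D solve produced non-finite values at {frequency} Hz "
                "(near-singular system)"
            )
        omega = 2.0 * np.pi * frequency
        Y = self.line.admittance(self.x, omega, active)
        p0 = field2d[:, 0]
        return BMResponse(
            frequency=frequency,
            positions=self.x,
            pressure_at_partition=p0,
            bm_velocity=Y * p0,
            fluid_pressure=field2d,
        )

    def greens_partition(
        self,
        x_src: float,
        frequency: float,
        active: bool,
        check_resolution: bool = True,
    ) -> np.ndarray:
        """Partition-pressure Green's function column G(x, x_src).

        Response at the partition to a unit point source at ``x_src``,
        normalized to match the 1-D/WKB convention in the shallow-fluid
        limit.  With a reflective stapes (R_st != 0) the basal-side
        response develops an interference ripple.
        """
        res = self.solve(
            frequency,
            active,
            drive="point",
            source_position=x_src,
            check_resolution=check_resolution,
        )
        return res.pressure_at_partition

    def greens_matrix(
        self, frequency: float, active: bool, check_resolution: bool = True
    ) -> tuple[np.ndarray, None]:
        """Full partition Green's matrix (one sparse factorization, nx solves)."""
        if check_resolution:
            self.validate_resolution(frequency, active)
        mat, _ = self._assemble(frequency, active, "zero", None, 0.0)
        nx, ny = self.config.grid_nx, self.config.grid_ny
        hx = self.x[1] - self.x[0]
        hy = self.y[1] - self.y[0]
        amp = -2.0 / hy * (self.config.geometry.height / hx)
        lu = splu(mat.tocsc())
        G = np.empty((nx, nx), dtype=complex)
        block = 64  # bound the dense RHS memory footprint
        for start in range(0, nx, block):
            stop = min(start + block, nx)
            rhs = np.zeros((nx * ny, stop - start), dtype=complex)
            for col, js in enumerate(range(start, stop)):
                rhs[js * ny + 0, col] = amp
            sol = lu.solve(rhs)
            G[:, start:stop] = sol.reshape(nx, ny, stop - start)[:, 0, :]
        return G, None

    def boundary_flux_balance(self, response: BMResponse) -> float:
        """Net boundary flux of the Laplace field, relative to gross flux.

        For an incompressible fluid the fluxes through the stapes, the
        partition, the apex and the (rigid) top wall must cancel; the
        residual measures solver consistency.
        """
        P = response.fluid_pressure
        x, y = self.x, self.y
        hx, hy = x[1] - x[0], y[1] - y[0]
        # one-sided derivatives, outward normals
        stapes = -np.trapezoid((P[1, :] - P[0, :]) / hx, dx=hy)
        apex = np.trapezoid((P[-1, :] - P[-2, :]) / hx, dx=hy)
        bottom = -np.trapezoid((P[:, 1] - P[:, 0]) / hy, dx=hx)
        top = np.trapezoid((P[:, -1] - P[:, -2]) / hy, dx=hx)
        gross = abs(stapes) + abs(apex) + abs(bottom) + abs(top)
        if gross == 0:
            return 0.0
        return abs(stapes + apex + bottom + top) / gross
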