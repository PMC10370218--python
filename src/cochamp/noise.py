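"""Spatially incoherent internal-noise source ensembles.

Within a narrow frequency band, internal cochlear noise is represented by
independent sinusoidal sources distributed along the partition: phases
i.i.d. uniform on [0, 2pi), magnitudes i.i.d. draws of a non-negative
random variable with mean mu and variance sigma^2.  Only the effective
strength gamma^2 = mu^2 + sigma^2 (the mean-square magnitude) enters the
expected noise power, so the magnitude law is a user-visible knob whose
irrelevance the Monte-Carlo machinery can demonstrate:

* ``rayleigh`` (default): one-parameter law scaled so E[m^2] = gamma^2
  (the individual mu and sigma are matched only when sigma/mu happens to
  equal the Rayleigh ratio sqrt(4/pi - 1));
* ``lognormal``: matches mu and sigma individually;
* ``fixed``: degenerate law, magnitude identically gamma.

Propagated through a Green's-function provider, the ensemble rms
converges to the quadrature form gamma * sqrt(int |G(x, x')|^2 dx')
(one source per grid cell, amplitudes scaled by sqrt(dx) so the result
is grid-independent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NoiseEnsemble", "sample_noise_sources", "ensemble_noise_pressure"]

_RAYLEIGH_RATIO = np.sqrt(4.0 / np.pi - 1.0)  # sigma/mu of a Rayleigh variable


@dataclass(frozen=True)
class NoiseEnsemble:
    """One realization of the incoherent source ensemble."""

    positions: np.ndarray  # m
    amplitudes: np.ndarray  # complex, per-source a = m * exp(i*phi)
    magnitude_mean: float
    magnitude_sd: float
    magnitude_law: str
    seed: int | None

    @property
    def effective_strength(self) -> float:
        """gamma = sqrt(mu^2 + sigma^2)."""
        return float(np.hypot(self.magnitude_mean, self.magnitude_sd))


def _draw_magnitudes(
    rng: np.random.Generator, n: int, mu: float, sigma: float, law: str
) -> np.ndarray:
    gamma2 = mu * mu + sigma * sigma
    if law == "fixed":
        if sigma != 0:
            raise ValueError("law='fixed' requires sigma = 0")
        return np.full(n, mu)
    if law == "rayleigh":
        # E[m^2] = 2 s^2 for scale s; match the effective strength exactly
        return rng.rayleigh(scale=np.sqrt(gamma2 / 2.0), size=n)
    if law == "lognormal":
        if mu <= 0:
            raise ValueError("law='lognormal' requires mu > 0")
        if sigma == 0:
            return np.full(n, mu)
        s2 = np.log1p((sigma / mu) ** 2)
        return rng.lognormal(mean=np.log(mu) - s2 / 2.0, sigma=np.sqrt(s2), size=n)
    raise ValueError(f"unknown magnitude law {law!r}")


def sample_noise_sources(
    positions: np.ndarray,
    magnitude_mean: float,
    magnitude_sd: float = 0.0,
    magnitude_law: str = "rayleigh",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> NoiseEnsemble:
    """Draw one realization of complex source amplitudes.

    For sigma = 0 the ensemble degenerates to fixed magnitudes mu with
    random phases; for mu = sigma = 0 it is silent.  Reproducible for a
    fixed seed; pass ``rng`` instead to draw several realizations from
    one stream.
    """
    if magnitude_mean < 0 or magnitude_sd < 0:
        raise ValueError("mu and sigma must be >= 0")
    positions = np.asarray(positions, dtype=float)
    if rng is None:
        rng = np.random.default_rng(seed)
    n = positions.size
    if magnitude_mean == 0 and magnitude_sd == 0:
        mags = np.zeros(n)
    elif magnitude_sd == 0:
        mags = np.full(n, magnitude_mean)
    else:
        mags = _draw_magnitudes(rng, n, magnitude_mean, magnitude_sd, magnitude_law)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return NoiseEnsemble(
        positions=positions,
        amplitudes=mags * np.exp(1j * phases),
        magnitude_mean=magnitude_mean,
        magnitude_sd=magnitude_sd,
        magnitude_law=magnitude_law,
        seed=seed,
    )


def ensemble_noise_pressure(
    greens: np.ndarray,
    positions: np.ndarray,
    magnitude_mean: float,
    magnitude_sd: float = 0.0,
    magnitude_law: str = "rayleigh",
    num_realizations: int = 200,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo rms noise pressure at every observation point.

    ``greens`` is the (n_obs, n_src) Green's matrix of any provider
    (WKB, 1-D FD or 2-D FD) over the source grid ``positions``.  Each
    realization sums G(x, x') a(x') sqrt(dx) over the sources; the rms
    over realizations converges to the quadrature
    gamma * sqrt(int |G|^2 dx').  Returns (rms, standard error of rms).
    """
    positions = np.asarray(positions, dtype=float)
    if greens.shape[1] != positions.size:
        raise ValueError(
            f"provider/grid mismatch: greens has {greens.shape[1]} source "
            f"columns but positions has {positions.size} points"
        )
    if num_realizations < 2:
        raise ValueError("need at least 2 realizations for a standard error")
    dx = positions[1] - positions[0] if positions.size > 1 else 1.0
    rng = np.random.default_rng(seed)
    power = np.zeros((num_realizations, greens.shape[0]))
    for r in range(num_realizations):
        ens = sample_noise_sources(
            positions, magnitude_mean, magnitude_sd, magnitude_law, rng=rng
        )
        field = greens @ (ens.amplitudes * np.sqrt(dx))
        power[r] = np.abs(field) ** 2
    mean_p = power.mean(axis=0)
    se_p = power.std(axis=0, ddof=1) / np.sqrt(num_realizations)
    rms = np.sqrt(mean_p)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(rms > 0, se_p / (2.0 * rms), 0.0)
    return rms, se
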