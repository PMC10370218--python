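"""Reproducible pipeline runs, figure-table regeneration and fixtures.

``run_pipeline`` executes the analysis stages in dependency order and
writes one tidy CSV per figure panel analogue plus a JSON run manifest
(config snapshot, seeds, provider choices, software version, per-file
SHA-256 checksums).  Deterministic stages reproduce byte-identical
outputs when re-run with an identical manifest; seeded stochastic stages
reproduce identical streams.

Every numeric CSV starts with commented header lines stating units and
the dB convention (20*log10 of amplitude ratios).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chain import (
    ChainConfig,
    bidirectional_enhancement,
    bidirectional_node_response,
    monte_carlo_chain,
    one_way_enhancement,
    optimal_gain_profile,
)
from .config import ConfigError, build_model, build_model_2d, load_config, validate_band
from .noise import ensemble_noise_pressure
from .snr import (
    basal_apical_decomposition,
    enhancement_profile_broadband,
    enhancement_profile_narrowband,
    make_provider,
    normalized_signal_noise_curves,
)

__all__ = [
    "RunManifest",
    "run_pipeline",
    "make_fixtures",
    "export_wavefield_csv",
    "export_scan_h5",
    "export_field2d_h5",
]

_HEADER = (
    "# units: positions m, frequencies Hz, pressures arbitrary (stimulus-"
    "normalized); dB = 20*log10(amplitude ratio)\n"
)


@dataclass(frozen=True)
class RunManifest:
    config: dict
    seeds: dict
    provider: str
    version: str
    checksums: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "provider": self.provider,
                "seeds": self.seeds,
                "checksums": self.checksums,
                "config": self.config,
            },
            indent=2,
            sort_keys=True,
        )


def _write_csv(path: Path, frame: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER)
        frame.to_csv(fh, index=False, float_format="%.10g")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def export_wavefield_csv(path: Path, field) -> None:
    """WaveField export: x, Re P, Im P, |P| dB, phase cycles, Re k, Im k."""
    df = pd.DataFrame(
        {
            "x_m": field.positions,
            "re_pressure": np.real(field.pressure),
            "im_pressure": np.imag(field.pressure),
            "magnitude_db": field.magnitude_db,
            "phase_cycles": field.phase_cycles,
            "re_k": np.real(field.wavenumber) if field.wavenumber is not None else np.nan,
            "im_k": np.imag(field.wavenumber) if field.wavenumber is not None else np.nan,
        }
    )
    _write_csv(path, df)


def export_scan_h5(path: Path | str, fields) -> None:
    """Multi-frequency 1-D scan to HDF5: complex pressure and wavenumber.

    ``fields`` is a sequence of WaveField objects sharing one grid.
    """
    import h5py

    fields = list(fields)
    with h5py.File(path, "w") as h5:
        h5.attrs["units"] = "positions m, frequencies Hz, pressure arbitrary"
        h5.attrs["db_convention"] = "20*log10(amplitude ratio)"
        h5.create_dataset("positions", data=fields[0].positions)
        h5.create_dataset("frequencies", data=[f.frequency for f in fields])
        h5.create_dataset("pressure", data=np.stack([f.pressure for f in fields]))
        if fields[0].wavenumber is not None:
            h5.create_dataset(
                "wavenumber", data=np.stack([f.wavenumber for f in fields])
            )


def export_field2d_h5(path: Path | str, response) -> None:
    """2-D complex fluid-pressure field of a BMResponse to HDF5."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["units"] = "positions m, frequency Hz, pressure arbitrary"
        h5.attrs["frequency_hz"] = response.frequency
        h5.create_dataset("x", data=response.positions)
        h5.create_dataset("fluid_pressure", data=response.fluid_pressure)
        h5.create_dataset("pressure_at_partition", data=response.pressure_at_partition)
        h5.create_dataset("bm_velocity", data=response.bm_velocity)


def run_pipeline(
    config: dict | str | Path | None = None,
    out_dir: str | Path = "cochamp_out",
    seed: int = 0,
    stages: tuple[str, ...] = ("chain", "wave1d", "noise", "snr"),
) -> RunManifest:
    """Run the requested stages and write CSV outputs plus a manifest."""
    cfg = load_config(config) if not isinstance(config, dict) else config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    band = validate_band(cfg)
    provider_name = cfg["solver"]["provider"]
    model = build_model(cfg)
    if provider_name == "fd2d":
        provider = make_provider("fd2d", model2d=build_model_2d(cfg))
    else:
        provider = make_provider(provider_name, model)
    files: list[Path] = []

    if "chain" in stages:
        # one-way enhancement vs gain at two chain lengths
        gains = np.geomspace(0.25, 4.0, 33)
        rows = [
            {
                "gain": g,
                "num_stages": n,
                "enhancement_db": one_way_enhancement(g, n).enhancement_db,
            }
            for n in (10, 20)
            for g in gains
        ]
        p = out / "chain_one_way_enhancement.csv"
        _write_csv(p, pd.DataFrame(rows))
        files.append(p)
        # bidirectional chain with the optimal profile for node 5
        n_chain = cfg["chain"]["num_nodes"]
        profile = optimal_gain_profile(n_chain, min(5, n_chain))
        cc = ChainConfig(
            num_nodes=n_chain,
            gain=profile,
            noise_strength=cfg["chain"]["noise_strength"],
            signal_rms_in=cfg["chain"]["signal_rms_in"],
        )
        enh = bidirectional_enhancement(cc)
        resp = bidirectional_node_response(cc)
        mc = monte_carlo_chain(cc, cfg["chain"]["trials"], seed)
        p = out / "chain_bidirectional.csv"
        _write_csv(
            p,
            pd.DataFrame(
                {
                    "node": [r.node_index for r in resp],
                    "signal_rms": [r.signal_rms for r in resp],
                    "noise_rms": [r.noise_rms for r in resp],
                    "snr": [r.snr for r in resp],
                    "enhancement_db": 20 * np.log10(enh),
                    "mc_noise_rms": mc.noise_rms,
                    "mc_noise_rms_se": mc.noise_rms_se,
                }
            ),
        )
        files.append(p)

    if "wave1d" in stages:
        for f in (10e3, 30e3):
            for active in (True, False):
                field = model.stapes_response(f, active)
                p = out / f"wave1d_{int(f / 1e3)}kHz_{'on' if active else 'off'}.csv"
                export_wavefield_csv(p, field)
                files.append(p)

    if "noise" in stages:
        f = 10e3
        for active in (True, False):
            basal, apical = basal_apical_decomposition(provider, f, active)
            p = out / f"noise_decomposition_10kHz_{'on' if active else 'off'}.csv"
            _write_csv(
                p,
                pd.DataFrame(
                    {
                        "x_m": provider.x,
                        "basal_noise_power": basal,
                        "apical_noise_power": apical,
                    }
                ),
            )
            files.append(p)
        G = provider.green_matrix(f, True)
        rms, se = ensemble_noise_pressure(
            G,
            provider.x,
            cfg["noise"]["mu"],
            cfg["noise"]["sigma"],
            cfg["noise"]["law"],
            num_realizations=cfg["noise"]["realizations"],
            seed=seed,
        )
        p = out / "noise_montecarlo_10kHz_on.csv"
        _write_csv(
            p, pd.DataFrame({"x_m": provider.x, "mc_rms": rms, "mc_rms_se": se})
        )
        files.append(p)

    summary: dict = {}
    if "snr" in stages:
        curves = normalized_signal_noise_curves(provider, 10e3)
        p = out / "normalized_curves_10kHz.csv"
        _write_csv(
            p,
            pd.DataFrame(
                {
                    "x_m": curves.positions,
                    "signal_on": curves.signal_on,
                    "signal_off": curves.signal_off,
                    "noise_on": curves.noise_on,
                    "noise_off": curves.noise_off,
                }
            ),
        )
        files.append(p)
        nb = enhancement_profile_narrowband(
            provider,
            num_freqs=cfg["snr"]["num_freqs_narrowband"],
            gain_fraction=cfg["snr"]["gain_fraction"],
        )
        p = out / "enhancement_narrowband.csv"
        _write_csv(
            p,
            pd.DataFrame(
                {
                    "frequency_hz": nb.frequencies,
                    "x_m": nb.positions,
                    "enhancement_db": nb.enhancement_db,
                    "near_base_flag": nb.flags.astype(int),
                }
            ),
        )
        files.append(p)
        bb = enhancement_profile_broadband(
            provider,
            band=band,
            num_freqs=cfg["snr"]["num_freqs_broadband"],
            apical_margin=cfg["snr"]["apical_margin"],
            narrowband=nb,
        )
        p = out / "enhancement_broadband.csv"
        _write_csv(
            p,
            pd.DataFrame(
                {
                    "x_m": bb.positions,
                    "enhancement_db": bb.enhancement_db,
                    "reported": bb.reporting_mask.astype(int),
                }
            ),
        )
        files.append(p)
        summary = {
            "peak_broadband_enhancement_db": bb.peak_enhancement_db,
            "peak_broadband_position_mm": bb.peak_position * 1e3,
            "narrowband_most_sensitive_db": nb.most_sensitive_enhancement_db,
            "narrowband_peak_db": nb.peak_enhancement_db,
            "near_base_extent_mm": nb.near_base_extent * 1e3,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        files.append(out / "summary.json")

    manifest = RunManifest(
        config=cfg,
        seeds={"pipeline": seed, "chain": seed, "noise": seed},
        provider=provider_name,
        version=__version__,
        checksums={f.name: _checksum(f) for f in files},
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def make_fixtures(seed: int, out_dir: str | Path) -> dict:
    """Generate the small test-input bundles used by the unit suite.

    Three fixture sets -- chain-only, coarse 1-D, coarse 2-D -- written
    as CSV with a JSON schema sidecar; deterministic for a fixed seed.
    """
    from .cochlea2d import Cochlea2DConfig, Cochlea2DModel
    from .waveguide import CochlearGeometry, CochlearModel

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    cc = ChainConfig(num_nodes=10, gain=optimal_gain_profile(10, 5), noise_strength=1.0)
    mc = monte_carlo_chain(cc, num_trials=100, seed=seed)
    df = pd.DataFrame(
        {
            "node": mc.node_index,
            "signal_rms": mc.signal_rms,
            "noise_rms": mc.noise_rms,
            "noise_rms_se": mc.noise_rms_se,
        }
    )
    p = out / "fixture_chain.csv"
    _write_csv(p, df)
    written["chain"] = _checksum(p)

    coarse = CochlearModel(CochlearGeometry(grid=256))
    field = coarse.stapes_response(10e3, True)
    p = out / "fixture_wave1d.csv"
    export_wavefield_csv(p, field)
    written["wave1d"] = _checksum(p)

    model2d = Cochlea2DModel(Cochlea2DConfig(grid_nx=96, grid_ny=12))
    resp = model2d.solve(6e3, True, check_resolution=False)
    p = out / "fixture_cochlea2d.csv"
    _write_csv(
        p,
        pd.DataFrame(
            {
                "x_m": resp.positions,
                "re_p0": np.real(resp.pressure_at_partition),
                "im_p0": np.imag(resp.pressure_at_partition),
                "re_vcp": np.real(resp.bm_velocity),
                "im_vcp": np.imag(resp.bm_velocity),
            }
        ),
    )
    written["cochlea2d"] = _checksum(p)

    schema = {
        "seed": seed,
        "files": {
            "fixture_chain.csv": ["node", "signal_rms", "noise_rms", "noise_rms_se"],
            "fixture_wave1d.csv": [
                "x_m",
                "re_pressure",
                "im_pressure",
                "magnitude_db",
                "phase_cycles",
                "re_k",
                "im_k",
            ],
            "fixture_cochlea2d.csv": ["x_m", "re_p0", "im_p0", "re_vcp", "im_vcp"],
        },
        "checksums": written,
    }
    (out / "fixtures.json").write_text(json.dumps(schema, indent=2))
    return schema
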