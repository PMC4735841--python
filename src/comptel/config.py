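"""Run configuration, the end-to-end pipeline driver and test-fixture
generation.

A run is fully described by one YAML document (every physical quantity
carries its unit in the key name) and one integer seed.  The seed is
expanded into per-stage child seeds with ``numpy.random.SeedSequence``
(spawn order: simulate, process, reconstruct, analyze), so each stage is
independently reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import analysis, events, reconstruction, simulator
from .instrument import TelescopeGeometry, default_prototype
from .physics import labr3_attenuation, scattered_energy, cos_scatter_angle

__all__ = ["RunConfig", "run_pipeline", "make_fixture", "stage_rngs"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    geometry: TelescopeGeometry = field(default_factory=default_prototype)
    source: simulator.SourceSpec = None
    seed: int = 1
    n_decays: int = 1_000_000
    sum_window_kev: tuple = events.DEFAULT_SUM_WINDOW
    mlem: reconstruction.MLEMConfig = field(
        default_factory=reconstruction.MLEMConfig)
    grid: reconstruction.VoxelGrid = None
    out_prefix: str = "run"

    def __post_init__(self):
        if self.source is None:
            self.source = simulator.default_na22_source(
                self.geometry.source_to_layer1_mm)
        if self.grid is None:
            self.grid = reconstruction.default_source_plane_grid(
                self.geometry.source_z_mm)

    def to_dict(self) -> dict:
        return {
            "geometry": self.geometry.to_dict(),
            "source": {
                "position_mm": list(self.source.position_mm),
                "activity_bq": self.source.activity_bq,
                "diameter_mm": self.source.diameter_mm,
                "lines": [list(l) for l in self.source.lines],
                "annihilation": self.source.annihilation,
                "annihilation_intensity": self.source.annihilation_intensity,
            },
            "simulation": {"seed": self.seed, "n_decays": self.n_decays},
            "processing": {"sum_window_kev": list(self.sum_window_kev)},
            "reconstruction": {
                "n_iterations": self.mlem.n_iterations,
                "sigma_floor_rad": self.mlem.sigma_floor_rad,
                "sensitivity_mode": self.mlem.sensitivity_mode,
                "grid_origin_mm": list(self.grid.origin_mm),
                "grid_voxel_size_mm": self.grid.voxel_size_mm,
                "grid_dims": [int(d) for d in self.grid.dims],
            },
            "paths": {"out_prefix": self.out_prefix},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        geo = TelescopeGeometry.from_dict(d["geometry"])
        s = d["source"]
        src = simulator.SourceSpec(
            position_mm=tuple(s["position_mm"]),
            activity_bq=s["activity_bq"], diameter_mm=s["diameter_mm"],
            lines=[tuple(l) for l in s["lines"]],
            annihilation=s["annihilation"],
            annihilation_intensity=s["annihilation_intensity"])
        r = d["reconstruction"]
        grid = reconstruction.VoxelGrid(tuple(r["grid_origin_mm"]),
                                        r["grid_voxel_size_mm"],
                                        tuple(r["grid_dims"]))
        mlem = reconstruction.MLEMConfig(
            n_iterations=r["n_iterations"],
            sigma_floor_rad=r["sigma_floor_rad"],
            sensitivity_mode=r["sensitivity_mode"])
        return cls(geometry=geo, source=src,
                   seed=d["simulation"]["seed"],
                   n_decays=d["simulation"]["n_decays"],
                   sum_window_kev=tuple(d["processing"]["sum_window_kev"]),
                   mlem=mlem, grid=grid,
                   out_prefix=d["paths"]["out_prefix"])

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def stage_rngs(seed: int) -> dict:
    """Deterministic per-stage generators spawned from the global seed."""
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("simulate", "process", "reconstruct", "analyze")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def run_pipeline(config: RunConfig, write_files: bool = True) -> dict:
    """simulate -> process -> reconstruct -> analyze; returns the report.

    Intermediate products (list-mode events, truth, cones, image) are
    written under ``config.out_prefix`` when ``write_files`` is true.
    """
    prefix = config.out_prefix if write_files else None
    try:
        ev, truth, summary = simulator.run_experiment(
            config.geometry, config.source, config.n_decays, config.seed,
            out_prefix=prefix)
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'simulate' failed: {err}") from err
    log.info("simulate: %d decays -> %d triples", config.n_decays,
             summary["n_triples"])

    try:
        cones = events.cones_from_listmode(ev, config.geometry,
                                           config.sum_window_kev)
        if write_files:
            events.write_cones(cones, f"{config.out_prefix}_cones.csv")
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'process' failed: {err}") from err
    log.info("process: %d cones", len(cones))

    report = {"summary": summary, "n_cones": int(len(cones))}

    spec = analysis.sum_spectrum(ev)
    peaks = analysis.find_photopeaks(spec, [511.0, 1275.0])
    report["sum_spectrum_peaks"] = {
        str(k): (None if v is None else
                 {"centroid_kev": v.centroid, "fwhm_percent": v.fwhm_percent})
        for k, v in peaks.items()}

    eff = analysis.compute_efficiency(summary, ev, truth,
                                      sum_window=config.sum_window_kev)
    report["efficiency"] = {
        "per_incident_1275_photon": eff.efficiency_per_incident_1275,
        "per_emitted_1275_photon": eff.efficiency_per_emitted_1275,
        "binomial_sigma": eff.binomial_sigma,
        "in_sum_window": eff.efficiency_in_window,
        "per_decay": eff.efficiency_per_decay,
        "n_triples": eff.n_triples,
    }

    if len(cones):
        try:
            img = reconstruction.mlem_reconstruct(cones, config.grid,
                                                  config.mlem)
            if write_files:
                img.save(config.out_prefix)
        except Exception as err:
            raise RuntimeError(
                f"pipeline stage 'reconstruct' failed: {err}") from err
        xs, ys, sl = reconstruction.extract_plane(
            img, config.geometry.source_z_mm)
        prof = analysis.profile_fwhm(xs, ys, sl, "x")
        report["image"] = {
            "profile_fwhm_mm": prof.fwhm_mm,
            "profile_centroid_mm": prof.centroid_mm,
            "iterations": img.iteration_count,
            "final_log_likelihood": img.log_likelihood[-1],
        }
    else:
        report["image"] = None

    if write_files:
        with open(f"{config.out_prefix}_report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=float)
    return report


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def make_fixture(kind: str, params: dict | None = None, seed: int = 0):
    """Deterministic test fixtures with known ground truth.

    kinds:
      - ``noise_free_triples``: 1275 keV photons through the default
        telescope with response blur off, thresholds at zero and true
        interaction coordinates, restricted to correctly ordered
        single-photon triples.  E0 recovery on these is exact.
      - ``analytic_cones``: cones constructed so that every cone surface
        passes exactly through ``params['point_mm']``.
      - ``gaussian_image``: a 2D Gaussian of known sigma on the default
        source-plane grid.
    """
    params = dict(params or {})
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    if kind == "noise_free_triples":
        # triple chains are ~1e-6 per emitted photon, so tens of millions of
        # photons are needed for a usable fixture; the forward-cone
        # restriction keeps this fast
        n_photons = int(params.get("n_photons", 90_000_000))
        geo = default_prototype()
        for l in geo.layers:
            l.threshold_kev = 0.0
        # ideal point source (zero spot size): the cone-surface oracle is
        # then exact to float precision
        src = simulator.SourceSpec(position_mm=(0.0, 0.0, geo.source_z_mm),
                                   diameter_mm=0.0,
                                   lines=[(1275.0, 1.0)], annihilation=False)
        photons, _ = simulator.emit_decays(
            src, n_photons, rng, aim_cos=simulator.aim_cone_cos(geo, src))
        inter, _ = simulator.transport_photons(photons, geo,
                                               labr3_attenuation(), rng)
        meas = simulator.digitize(inter, geo, rng, blur=False)
        ev, truth = simulator.build_coincidences(meas, geo)
        if ev.empty:
            return pd.DataFrame()
        good = truth.drop_duplicates("event_id")
        good = good[good.ordered_flag & ~good.accidental_flag
                    & ~good.pileup_flag].event_id
        ev = ev[ev.event_id.isin(good)]
        truth = truth[truth.event_id.isin(good)]
        # use true coordinates/energies: the noise-free kinematics oracle
        ev = ev.copy()
        ev[["x_mm", "y_mm", "z_mm", "e_kev"]] = truth[
            ["true_x_mm", "true_y_mm", "true_z_mm", "true_e_kev"]].to_numpy()
        return events.listmode_to_triples(ev)

    if kind == "analytic_cones":
        p = np.asarray(params.get("point_mm", (0.0, 0.0, -35.0)), float)
        n = int(params.get("n_cones", 100))
        sigma = float(params.get("sigma_rad", 0.02))
        apex = np.column_stack([rng.uniform(-12, 12, n),
                                rng.uniform(-12, 12, n),
                                np.full(n, 2.5)])
        w = p[None, :] - apex
        w /= np.linalg.norm(w, axis=1, keepdims=True)
        beta = rng.uniform(np.deg2rad(10), np.deg2rad(60), n)
        # rotate w by beta within a random plane containing it
        helper = rng.standard_normal((n, 3))
        v = np.cross(w, helper)
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        axis = np.cos(beta)[:, None] * w + np.sin(beta)[:, None] * v
        axis /= np.linalg.norm(axis, axis=1, keepdims=True)
        return pd.DataFrame({
            "event_id": np.arange(n),
            "apex_x_mm": apex[:, 0], "apex_y_mm": apex[:, 1],
            "apex_z_mm": apex[:, 2],
            "axis_x": axis[:, 0], "axis_y": axis[:, 1], "axis_z": axis[:, 2],
            "half_angle_rad": beta,
            "sigma_rad": np.full(n, sigma),
            "e0_kev": np.full(n, 1275.0)})

    if kind == "gaussian_image":
        sigma = float(params.get("sigma_mm", 3.312))
        center = params.get("center_mm", (0.0, 0.0))
        grid = params.get("grid") or reconstruction.default_source_plane_grid()
        xs, ys = grid.x_axis(), grid.y_axis()
        gx = np.exp(-0.5 * ((xs - center[0]) / sigma) ** 2)
        gy = np.exp(-0.5 * ((ys - center[1]) / sigma) ** 2)
        vals = np.outer(gy, gx)[None, :, :]  # (nz=1, ny, nx)
        return reconstruction.Image(grid, vals.ravel(), 0)

    raise ValueError(f"unknown fixture kind: {kind}")
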