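"""From calibrated triple coincidences to Compton cones.

A triple event is one measured interaction in each of the three layers,
assumed to be the first, second and third interaction of one photon in that
order.  The second-scatter angle, measured purely from geometry, closes the
kinematics: together with the deposits e1 and e2 it yields the incident
energy E0 without requiring full absorption, which is the point of a
three-layer telescope.  The first-scatter angle then defines a cone with
apex at the layer-1 interaction whose surface contains the source direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .instrument import TelescopeGeometry, energy_fwhm_kev, fwhm_to_sigma
from .physics import ELECTRON_REST_ENERGY_KEV as MEC2

__all__ = [
    "TripleEvent",
    "ConeEvent",
    "select_events",
    "geometric_cos_angle",
    "incident_energy_from_triple",
    "cone_from_triple",
    "cones_from_listmode",
    "listmode_to_triples",
    "write_cones",
    "read_cones",
    "DEFAULT_SUM_WINDOW",
]

log = logging.getLogger(__name__)

#: Total-energy acceptance window (keV) used for imaging; brackets the
#: 1275 keV line and excludes the 511 keV population.
DEFAULT_SUM_WINDOW = (800.0, 1400.0)

#: cos(theta2) closer to 1 than this is treated as straight-through
#: (degenerate kinematics: the inferred E0 diverges as 1/(1 - cos)).
COS_THETA2_EPS = 1e-6


@dataclass
class TripleEvent:
    e1: float
    e2: float
    e3: float
    r1: np.ndarray
    r2: np.ndarray
    r3: np.ndarray

    @property
    def total_energy(self) -> float:
        return self.e1 + self.e2 + self.e3


@dataclass
class ConeEvent:
    apex: np.ndarray          # layer-1 interaction position
    axis: np.ndarray          # unit vector pointing back toward the source
    half_angle: float         # first-scatter angle theta1, radians
    half_angle_sigma: float   # propagated angular uncertainty, radians
    e0_estimate: float        # inferred incident energy, keV

    def __post_init__(self):
        if not 0.0 < self.half_angle < np.pi:
            raise ValueError("half angle must lie in (0, pi)")
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-12:
            raise ValueError("axis must be a unit vector")
        if self.half_angle_sigma <= 0:
            raise ValueError("half_angle_sigma must be positive")


# ---------------------------------------------------------------------------
# Selection and kinematics
# ---------------------------------------------------------------------------

def select_events(triples: pd.DataFrame, sum_window=DEFAULT_SUM_WINDOW):
    """Keep triples whose summed energy lies inside ``sum_window`` (inclusive)."""
    lo, hi = sum_window
    if not lo < hi:
        raise ValueError("sum window must satisfy lo < hi")
    if triples.empty:
        return triples
    tot = triples[["e1", "e2", "e3"]].sum(axis=1)
    keep = (tot >= lo) & (tot <= hi)
    log.info("select_events: %d of %d triples pass the [%g, %g] keV sum window",
             int(keep.sum()), len(triples), lo, hi)
    return triples[keep]


def geometric_cos_angle(r1, r2, r3):
    """Cosine of the angle between segments r1->r2 and r2->r3 (vectorized)."""
    scalar = np.asarray(r1).ndim == 1
    r1 = np.atleast_2d(np.asarray(r1, float))
    r2 = np.atleast_2d(np.asarray(r2, float))
    r3 = np.atleast_2d(np.asarray(r3, float))
    u = r2 - r1
    v = r3 - r2
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    if np.any(nu == 0) or np.any(nv == 0):
        raise ValueError("degenerate geometry: coincident interaction points")
    c = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1.0, 1.0)
    return float(c[0]) if scalar else c


def incident_energy_from_triple(e1, e2, cos_theta2):
    """Incident energy from the first two deposits and the second-scatter angle.

    The photon energy after the first scatter, E1 = E0 - e1, is fixed by the
    second scatter: Compton kinematics with deflection theta2 and deposit e2
    give E1 = e2/2 + sqrt(e2^2/4 + e2 mc^2 / (1 - cos theta2)), hence

        E0 = e1 + e2/2 + sqrt(e2^2/4 + e2 mc^2 / (1 - cos theta2)).

    The third deposit e3 enters only through the total-energy selection; the
    estimate is therefore robust against incomplete absorption in layer 3.
    """
    e1 = np.asarray(e1, float)
    e2 = np.asarray(e2, float)
    c2 = np.asarray(cos_theta2, float)
    if np.any(e1 <= 0) or np.any(e2 <= 0):
        raise ValueError("deposits must be positive")
    if np.any(c2 >= 1.0 - COS_THETA2_EPS):
        raise ValueError("degenerate kinematics: cos(theta2) too close to 1")
    e0 = e1 + e2 / 2.0 + np.sqrt(e2 ** 2 / 4.0 + e2 * MEC2 / (1.0 - c2))
    return float(e0) if e0.ndim == 0 else e0


# ---------------------------------------------------------------------------
# Cone construction with uncertainty propagation
# ---------------------------------------------------------------------------

def _half_angle(e0, e1):
    """First-scatter angle: cos(theta1) = 1 - mc^2 (1/(E0 - e1) - 1/E0)."""
    c1 = 1.0 - MEC2 * (1.0 / (e0 - e1) - 1.0 / e0)
    return c1


def _cone_arrays(e1, e2, r1, r2, r3, sigma_e1, sigma_e2, sigma_xy, sigma_z):
    """Vectorized cone computation; returns dict of arrays plus a reject mask.

    Uncertainty model (first-order delta method, correlations neglected):
    theta1 is differentiated by central finite differences with respect to
    the two energy deposits and all nine interaction coordinates.  The
    coordinate sigmas are the transverse position blur (``sigma_xy``) and
    the depth-of-interaction uncertainty ``sigma_z`` per layer (the
    reported z is the layer mid-plane, so the residual depth spread is
    ~thickness/sqrt(12), which dominates over the transverse blur for the
    5-10 mm crystals).  The angular jitter of the cone axis (r2 -> r1)
    from the same coordinate errors is added in quadrature, since it
    displaces the cone on the sky exactly like a half-angle error.
    """
    r1 = np.atleast_2d(np.asarray(r1, float))
    r2 = np.atleast_2d(np.asarray(r2, float))
    r3 = np.atleast_2d(np.asarray(r3, float))
    e1 = np.atleast_1d(np.asarray(e1, float))
    e2 = np.atleast_1d(np.asarray(e2, float))
    c2 = np.atleast_1d(geometric_cos_angle(r1, r2, r3))
    ok = c2 < 1.0 - COS_THETA2_EPS

    def theta1_of(e1v, e2v, c2v):
        c2v = np.minimum(c2v, 1.0 - COS_THETA2_EPS)
        e0 = e1v + e2v / 2.0 + np.sqrt(e2v ** 2 / 4.0 + e2v * MEC2 / (1.0 - c2v))
        return e0, _half_angle(e0, e1v)

    e0, c1 = theta1_of(e1, e2, c2)
    ok &= (c1 >= -1.0) & (c1 <= 1.0)
    c1c = np.clip(c1, -1.0, 1.0)
    theta1 = np.arccos(c1c)
    ok &= (theta1 > 1e-9) & (theta1 < np.pi - 1e-9)

    def th(e1v, e2v, ra, rb, rc):
        cc = np.atleast_1d(geometric_cos_angle(ra, rb, rc))
        _, c = theta1_of(e1v, e2v, cc)
        return np.arccos(np.clip(c, -1.0, 1.0))

    # energy partials
    de = 0.5
    var = ((th(e1 + de, e2, r1, r2, r3)
            - th(np.maximum(e1 - de, 1e-9), e2, r1, r2, r3)) / (2 * de)
           * sigma_e1) ** 2
    var += ((th(e1, e2 + de, r1, r2, r3)
             - th(e1, np.maximum(e2 - de, 1e-9), r1, r2, r3)) / (2 * de)
            * sigma_e2) ** 2

    # coordinate partials: x, y with the transverse blur, z with the
    # depth-of-interaction sigma of the respective layer
    dq = 0.05  # mm
    sig_z1, sig_z2, sig_z3 = (np.broadcast_to(np.asarray(s, float), e1.shape)
                              for s in sigma_z)
    coord_sigmas = [
        (0, sigma_xy), (1, sigma_xy), (2, sig_z1),   # r1
        (3, sigma_xy), (4, sigma_xy), (5, sig_z2),   # r2
        (6, sigma_xy), (7, sigma_xy), (8, sig_z3),   # r3
    ]
    for flat_idx, sig in coord_sigmas:
        which, k = divmod(flat_idx, 3)
        bump = np.zeros((len(e1), 3))
        bump[:, k] = dq
        rs = [r1, r2, r3]
        hi = [r + bump if i == which else r for i, r in enumerate(rs)]
        lo = [r - bump if i == which else r for i, r in enumerate(rs)]
        d = (th(e1, e2, *hi) - th(e1, e2, *lo)) / (2 * dq)
        var += (d * sig) ** 2

    # axis angular jitter: axis = unit(r1 - r2); a coordinate error delta_k
    # tilts it by sqrt(1 - axis_k^2) * delta_k / L12
    axis = r1 - r2
    L12 = np.linalg.norm(axis, axis=1)
    axis = axis / L12[:, None]
    sig_ax2 = np.zeros_like(L12)
    for k, s1_, s2_ in ((0, sigma_xy, sigma_xy), (1, sigma_xy, sigma_xy),
                        (2, sig_z1, sig_z2)):
        sig_ax2 += (1.0 - axis[:, k] ** 2) * (
            np.asarray(s1_) ** 2 + np.asarray(s2_) ** 2) / L12 ** 2
    sigma_theta = np.sqrt(var + sig_ax2)

    return {"apex": r1, "axis": axis, "half_angle": theta1,
            "half_angle_sigma": sigma_theta, "e0": e0}, ok


def cone_from_triple(event: TripleEvent, geometry: TelescopeGeometry) -> ConeEvent:
    """Build the Compton cone of one triple; raises ValueError when the
    measured energies are kinematically inconsistent."""
    layers = geometry.layers
    se1 = fwhm_to_sigma(energy_fwhm_kev(layers[0], event.e1))
    se2 = fwhm_to_sigma(energy_fwhm_kev(layers[1], event.e2))
    sp = fwhm_to_sigma(layers[0].position_resolution_fwhm_mm)
    sz = tuple(l.thickness_mm / np.sqrt(12.0) for l in layers)
    arrs, ok = _cone_arrays(np.atleast_1d(float(event.e1)),
                            np.atleast_1d(float(event.e2)),
                            event.r1, event.r2, event.r3,
                            np.atleast_1d(se1), np.atleast_1d(se2), sp, sz)
    if not ok[0]:
        raise ValueError("kinematically inconsistent triple (|cos theta1| > 1 "
                         "or degenerate geometry)")
    return ConeEvent(apex=arrs["apex"][0], axis=arrs["axis"][0],
                     half_angle=float(arrs["half_angle"][0]),
                     half_angle_sigma=float(arrs["half_angle_sigma"][0]),
                     e0_estimate=float(arrs["e0"][0]))


# ---------------------------------------------------------------------------
# List-mode plumbing
# ---------------------------------------------------------------------------

def listmode_to_triples(events: pd.DataFrame) -> pd.DataFrame:
    """Pivot the 3-rows-per-event list-mode table into one row per triple."""
    if events.empty:
        return pd.DataFrame(columns=[
            "event_id", "e1", "e2", "e3",
            "x1", "y1", "z1", "x2", "y2", "z2", "x3", "y3", "z3"])
    piv = events.pivot(index="event_id", columns="layer",
                       values=["x_mm", "y_mm", "z_mm", "e_kev"])
    out = pd.DataFrame({"event_id": piv.index})
    for li in (1, 2, 3):
        out[f"e{li}"] = piv[("e_kev", li)].to_numpy()
        out[f"x{li}"] = piv[("x_mm", li)].to_numpy()
        out[f"y{li}"] = piv[("y_mm", li)].to_numpy()
        out[f"z{li}"] = piv[("z_mm", li)].to_numpy()
    out["total_energy"] = out.e1 + out.e2 + out.e3
    return out.reset_index(drop=True)


def cones_from_listmode(events: pd.DataFrame, geometry: TelescopeGeometry,
                        sum_window=DEFAULT_SUM_WINDOW) -> pd.DataFrame:
    """Full selection + cone-building pass over a list-mode event table.

    Applies the total-energy window, computes per-event cones with
    propagated angular uncertainties, and drops kinematically inconsistent
    events (counts logged).  Returns the cone table (one row per cone).
    """
    tr = listmode_to_triples(events)
    if sum_window is not None and not tr.empty:
        lo, hi = sum_window
        keep = (tr.total_energy >= lo) & (tr.total_energy <= hi)
        log.info("sum window [%g, %g] keV: %d of %d triples pass",
                 lo, hi, int(keep.sum()), len(tr))
        tr = tr[keep].reset_index(drop=True)
    if tr.empty:
        return pd.DataFrame(columns=[
            "event_id", "apex_x_mm", "apex_y_mm", "apex_z_mm",
            "axis_x", "axis_y", "axis_z", "half_angle_rad", "sigma_rad",
            "e0_kev"])
    r1 = tr[["x1", "y1", "z1"]].to_numpy()
    r2 = tr[["x2", "y2", "z2"]].to_numpy()
    r3 = tr[["x3", "y3", "z3"]].to_numpy()
    e1 = tr.e1.to_numpy(); e2 = tr.e2.to_numpy()
    layers = geometry.layers
    se1 = fwhm_to_sigma(energy_fwhm_kev(layers[0], e1))
    se2 = fwhm_to_sigma(energy_fwhm_kev(layers[1], e2))
    sp = fwhm_to_sigma(layers[0].position_resolution_fwhm_mm)
    sz = tuple(l.thickness_mm / np.sqrt(12.0) for l in layers)
    arrs, ok = _cone_arrays(e1, e2, r1, r2, r3, se1, se2, sp, sz)
    n_rej = int((~ok).sum())
    if n_rej:
        log.info("cone building: rejected %d of %d triples as kinematically "
                 "inconsistent", n_rej, len(tr))
    cones = pd.DataFrame({
        "event_id": tr.event_id.to_numpy()[ok],
        "apex_x_mm": arrs["apex"][ok, 0],
        "apex_y_mm": arrs["apex"][ok, 1],
        "apex_z_mm": arrs["apex"][ok, 2],
        "axis_x": arrs["axis"][ok, 0],
        "axis_y": arrs["axis"][ok, 1],
        "axis_z": arrs["axis"][ok, 2],
        "half_angle_rad": arrs["half_angle"][ok],
        "sigma_rad": arrs["half_angle_sigma"][ok],
        "e0_kev": arrs["e0"][ok],
    })
    return cones


def write_cones(cones: pd.DataFrame, path) -> None:
    cones.to_csv(path, index=False, float_format="%.9g")


def read_cones(path) -> pd.DataFrame:
    return pd.read_csv(path)
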