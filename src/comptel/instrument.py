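"""Prototype geometry and parametric detector response.

The telescope is three LaBr3 slabs on a common optical axis.  Coordinates are
right-handed, in millimetres, with the origin at the centre of the layer-1
entrance face and +z pointing from the source toward layer 3; the source sits
at z = -source_to_layer1.  Inter-layer distances are face-to-face gaps by
default (exit face of one crystal to entrance face of the next); a flag
switches to centre-to-centre spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = [
    "LayerSpec",
    "TelescopeGeometry",
    "ChannelGainMap",
    "default_prototype",
    "fwhm_to_sigma",
    "energy_fwhm_kev",
    "apply_energy_response",
    "apply_position_response",
    "passes_threshold",
]

FWHM_OVER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


def fwhm_to_sigma(fwhm):
    return fwhm / FWHM_OVER_SIGMA


@dataclass
class LayerSpec:
    """One LaBr3 crystal layer and its measured response figures."""

    index: int
    size_x_mm: float
    size_y_mm: float
    thickness_mm: float
    z_front_mm: float            # entrance face, telescope frame (layer 1 at 0)
    energy_resolution_511: float  # FWHM fraction at 511 keV
    position_resolution_fwhm_mm: float
    threshold_kev: float

    def __post_init__(self):
        if self.thickness_mm <= 0 or self.size_x_mm <= 0 or self.size_y_mm <= 0:
            raise ValueError("layer dimensions must be positive")
        if not 0.0 < self.energy_resolution_511 < 1.0:
            raise ValueError("energy resolution must be a fraction in (0, 1)")
        if self.threshold_kev < 0:
            raise ValueError("threshold must be non-negative")

    @property
    def z_back_mm(self) -> float:
        return self.z_front_mm + self.thickness_mm

    @property
    def z_mid_mm(self) -> float:
        return self.z_front_mm + 0.5 * self.thickness_mm

    def contains(self, xyz) -> np.ndarray:
        """Boolean mask: points inside the crystal volume (faces inclusive)."""
        p = np.atleast_2d(np.asarray(xyz, dtype=float))
        return ((np.abs(p[:, 0]) <= self.size_x_mm / 2)
                & (np.abs(p[:, 1]) <= self.size_y_mm / 2)
                & (p[:, 2] >= self.z_front_mm) & (p[:, 2] <= self.z_back_mm))


@dataclass
class TelescopeGeometry:
    layers: list
    source_to_layer1_mm: float
    layer1_to_layer2_mm: float
    layer2_to_layer3_mm: float
    coincidence_window_ns: float
    spacing_convention: str = "face_to_face"  # or "center_to_center"

    def __post_init__(self):
        if len(self.layers) != 3:
            raise ValueError("telescope has exactly three layers")
        zf = [l.z_front_mm for l in self.layers]
        if not (zf[0] < zf[1] < zf[2]):
            raise ValueError("layers must be ordered by increasing z_front")
        if self.coincidence_window_ns <= 0:
            raise ValueError("coincidence window must be positive")

    @property
    def source_z_mm(self) -> float:
        return -self.source_to_layer1_mm

    def to_dict(self) -> dict:
        return {
            "source_to_layer1_mm": self.source_to_layer1_mm,
            "layer1_to_layer2_mm": self.layer1_to_layer2_mm,
            "layer2_to_layer3_mm": self.layer2_to_layer3_mm,
            "coincidence_window_ns": self.coincidence_window_ns,
            "spacing_convention": self.spacing_convention,
            "layers": [asdict(l) for l in self.layers],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TelescopeGeometry":
        layers = [LayerSpec(**ld) for ld in d["layers"]]
        return cls(layers=layers,
                   source_to_layer1_mm=d["source_to_layer1_mm"],
                   layer1_to_layer2_mm=d["layer1_to_layer2_mm"],
                   layer2_to_layer3_mm=d["layer2_to_layer3_mm"],
                   coincidence_window_ns=d["coincidence_window_ns"],
                   spacing_convention=d.get("spacing_convention", "face_to_face"))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "TelescopeGeometry":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ChannelGainMap:
    """Per-channel multiplicative gains of one 8x8 SiPM readout grid."""

    layer_index: int
    gains: np.ndarray = field(default_factory=lambda: np.ones((8, 8)))

    def __post_init__(self):
        g = np.asarray(self.gains, dtype=float)
        if g.shape != (8, 8):
            raise ValueError("gain map must be 8x8")
        if np.any(g <= 0):
            raise ValueError("gains must be positive")
        self.gains = g

    @property
    def uniformity(self) -> float:
        """Relative spread stdev/mean of the channel gains."""
        return float(np.std(self.gains) / np.mean(self.gains))


def default_prototype() -> TelescopeGeometry:
    """The measured prototype configuration.

    Layer 1: 27.2 x 26.8 x 5 mm, 6.4% FWHM at 511 keV.
    Layers 2/3: 32 x 36 mm, 5 and 10 mm thick, 7.4% / 7.2% FWHM.
    Position blur 1 mm FWHM transverse in every layer, 50 keV thresholds,
    source-to-layer-1 35 mm, inter-layer gaps 60 and 65 mm (face-to-face),
    25 ns coincidence window.
    """
    t1, t2, t3 = 5.0, 5.0, 10.0
    gap12, gap23 = 60.0, 65.0
    z1 = 0.0
    z2 = z1 + t1 + gap12
    z3 = z2 + t2 + gap23
    layers = [
        LayerSpec(1, 27.2, 26.8, t1, z1, 0.064, 1.0, 50.0),
        LayerSpec(2, 32.0, 36.0, t2, z2, 0.074, 1.0, 50.0),
        LayerSpec(3, 32.0, 36.0, t3, z3, 0.072, 1.0, 50.0),
    ]
    return TelescopeGeometry(layers, 35.0, gap12, gap23, 25.0)


# ---------------------------------------------------------------------------
# Response models
# ---------------------------------------------------------------------------

def energy_fwhm_kev(layer: LayerSpec, e_kev):
    """Energy-resolution model: FWHM(E) = R_511 * 511 * sqrt(E/511).

    Photostatistics-driven scaling (relative resolution ~ 1/sqrt(E)),
    anchored at the measured 511 keV fractional resolution.
    """
    e = np.asarray(e_kev, dtype=float)
    return layer.energy_resolution_511 * 511.0 * np.sqrt(np.maximum(e, 0.0) / 511.0)


def apply_energy_response(layer: LayerSpec, e_true, rng):
    """Gaussian energy blur; negative fluctuations are clamped to zero."""
    e = np.asarray(e_true, dtype=float)
    if np.any(e < 0):
        raise ValueError("true energy must be non-negative")
    sigma = fwhm_to_sigma(energy_fwhm_kev(layer, e))
    out = np.maximum(e + sigma * rng.standard_normal(e.shape), 0.0)
    # zero deposit stays exactly zero (sigma is 0 there anyway)
    return float(out) if out.ndim == 0 else out


def apply_position_response(layer: LayerSpec, xyz_true, rng):
    """Transverse Gaussian blur, clamped to the crystal; z set to the mid-plane.

    The readout estimates only the transverse impact point; no
    depth-of-interaction information is available, so the reported z is the
    layer mid-plane.
    """
    p = np.atleast_2d(np.asarray(xyz_true, dtype=float)).copy()
    if not np.all(layer.contains(p)):
        raise ValueError("true position outside the layer volume")
    sig = fwhm_to_sigma(layer.position_resolution_fwhm_mm)
    p[:, 0] = np.clip(p[:, 0] + sig * rng.standard_normal(len(p)),
                      -layer.size_x_mm / 2, layer.size_x_mm / 2)
    p[:, 1] = np.clip(p[:, 1] + sig * rng.standard_normal(len(p)),
                      -layer.size_y_mm / 2, layer.size_y_mm / 2)
    p[:, 2] = layer.z_mid_mm
    return p[0] if np.asarray(xyz_true).ndim == 1 else p


def passes_threshold(layer: LayerSpec, e_measured) -> np.ndarray:
    """Trigger comparator on the measured energy, inclusive at the boundary."""
    return np.asarray(e_measured, dtype=float) >= layer.threshold_kev
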