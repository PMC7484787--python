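"""Synthetic TPE-FLIM data with the statistical structure of the study cohort.

Two generation modes are provided:

* **fast / feature mode** (:func:`generate_cohort`): draws per-cell decay
  parameters (tau1, tau2, a1/a2, intensity, diameter, shape) from
  independent truncated normal distributions — one distribution table row
  per cell class and measurement context — and synthesizes the cell's
  noiseless, peak-normalized 256-channel decay curve.  This is the input
  for the decision-tree classification experiments.

* **image mode** (:func:`render_scene`): renders a full 3-D photon-count
  cube: elastin-dominated extracellular background (tau_m 1,600 +- 110 ps),
  optional near-zero-lifetime blood capillaries (Hb photoproducts,
  modelled mono-exponential at 80 ps), and placed cells with 0.5-1.5 um
  granule texture, all convolved with the IRF and Poisson-sampled.

Intensities follow the acquisition convention of the study: photons per mW
summed over the 49-pixel binned neighborhood (binning value 3); the
renderer divides by 49 to obtain per-pixel expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .decay import (
    CHANNEL_WIDTH_PS,
    N_CHANNELS,
    DecayCube,
    IRF,
    gaussian_irf,
    mean_lifetime,
    model_decay,
)

#: pixels summed by the binning-3 intensity convention
BINNED_PIXELS = 49

LABEL_ACTIVATED = 0
LABEL_RESTING = 1
LABEL_OTHER = 2
LABEL_MC = 0
LABEL_NOT_MC = 1


@dataclass(frozen=True)
class CellClassSpec:
    """Per-class parameter distributions (mean, sd pairs; lifetimes in ps,
    intensity in photons/mW over the 49-pixel neighborhood, diameter in um)."""

    class_name: str
    context: str  # in_vitro | ex_vivo | in_vivo
    condition: str  # none | healthy | mastocytosis | allergy
    tau1_mean: float
    tau1_sd: float
    tau2_mean: float
    tau2_sd: float
    ratio_mean: float
    ratio_sd: float
    intensity_mean: float
    intensity_sd: float
    diameter_mean: float
    diameter_sd: float
    circular_prob: float
    label3: int

    def __post_init__(self):
        vals = [self.tau1_mean, self.tau2_mean, self.ratio_mean,
                self.intensity_mean, self.diameter_mean]
        sds = [self.tau1_sd, self.tau2_sd, self.ratio_sd,
               self.intensity_sd, self.diameter_sd]
        if not all(np.isfinite(vals)) or not all(np.isfinite(sds)):
            raise ValueError(f"{self.class_name}: non-finite spec values")
        if any(v <= 0 for v in vals):
            raise ValueError(f"{self.class_name}: all means must be positive")
        if any(s < 0 for s in sds):
            raise ValueError(f"{self.class_name}: sd must be >= 0")
        if self.tau1_mean >= self.tau2_mean:
            raise ValueError(f"{self.class_name}: tau1 mean must be below tau2 mean")
        if not 0.0 <= self.circular_prob <= 1.0:
            raise ValueError(f"{self.class_name}: circular_prob outside [0, 1]")

    @property
    def key(self) -> str:
        if self.condition == "none":
            return f"{self.class_name}/{self.context}"
        return f"{self.class_name}/{self.context}/{self.condition}"


def _spec(name, context, condition, t1, t1s, t2, t2s, r, rs, i, isd, d, ds, circ, label3):
    return CellClassSpec(name, context, condition, t1, t1s, t2, t2s, r, rs,
                         i, isd, d, ds, circ, label3)


# Distribution table of the nine cultured / ex vivo / in vivo cell classes.
# Lifetime, amplitude-ratio and intensity rows follow the study's published
# per-class mean +- sd values; diameters come from the reported cell sizes
# (resting MCs 10.2 +- 0.8 um shrinking to 8.7 +- 0.4 um on activation,
# dermal fibroblasts > 20 um, other dermal cells ~10 um); circularity
# probabilities encode the described morphologies (resting MCs round,
# activated/degranulated and ex vivo MCs elongated, fibroblasts spindly).
CLASS_SPECS: dict[str, CellClassSpec] = {s.key: s for s in [
    # in vitro cultures
    _spec("resting_mc", "in_vitro", "none", 533, 266, 2289, 317, 1.5, 0.5, 1300, 400, 10.2, 0.8, 0.9, LABEL_RESTING),
    _spec("activated_mc", "in_vitro", "none", 288, 130, 1920, 287, 2.5, 2.0, 900, 200, 8.7, 0.4, 0.2, LABEL_ACTIVATED),
    _spec("ige_resting_mc", "in_vitro", "none", 412, 83, 2427, 256, 1.9, 0.3, 800, 80, 10.2, 0.8, 0.9, LABEL_RESTING),
    _spec("ige_activated_mc", "in_vitro", "none", 217, 21, 1877, 117, 2.1, 0.6, 1000, 120, 8.7, 0.4, 0.2, LABEL_ACTIVATED),
    _spec("macrophage_short", "in_vitro", "none", 225, 84, 1289, 278, 4.8, 3.4, 3000, 500, 11.0, 1.5, 0.5, LABEL_OTHER),
    _spec("macrophage_long", "in_vitro", "none", 1016, 220, 2432, 239, 2.6, 1.0, 800, 200, 11.0, 1.5, 0.5, LABEL_OTHER),
    _spec("dendritic", "in_vitro", "none", 434, 188, 2578, 328, 1.6, 0.2, 538, 258, 10.0, 1.5, 0.3, LABEL_OTHER),
    _spec("fibroblast", "in_vitro", "none", 429, 51, 1983, 137, 0.5, 0.1, 469, 137, 22.0, 2.0, 0.1, LABEL_OTHER),
    _spec("neutrophil", "in_vitro", "none", 714, 250, 1795, 600, 1.5, 0.5, 500, 115, 9.0, 1.0, 0.7, LABEL_OTHER),
    # ex vivo cryo-sections (all MCs there presented elongated, below 10 um)
    _spec("resting_mc", "ex_vivo", "none", 417, 86, 2181, 166, 1.7, 1.0, 1600, 300, 8.5, 1.0, 0.1, LABEL_RESTING),
    _spec("activated_mc", "ex_vivo", "none", 243, 43, 1743, 167, 2.4, 0.7, 2000, 300, 8.5, 1.0, 0.1, LABEL_ACTIVATED),
    _spec("macrophage_short", "ex_vivo", "none", 225, 84, 1289, 278, 4.8, 3.4, 3000, 500, 11.0, 1.5, 0.5, LABEL_OTHER),
    _spec("macrophage_long", "ex_vivo", "none", 1016, 220, 2432, 239, 2.6, 1.0, 800, 200, 11.0, 1.5, 0.5, LABEL_OTHER),
    # in vivo papillary dermis
    _spec("resting_mc", "in_vivo", "healthy", 344, 49, 2301, 77, 1.5, 0.3, 300, 40, 10.0, 1.0, 0.9, LABEL_RESTING),
    _spec("activated_mc", "in_vivo", "healthy", 241, 59, 1947, 230, 3.0, 1.1, 800, 100, 9.0, 1.0, 0.2, LABEL_ACTIVATED),
    _spec("resting_mc", "in_vivo", "mastocytosis", 360, 76, 2243, 141, 1.3, 0.2, 280, 40, 10.0, 1.0, 0.9, LABEL_RESTING),
    _spec("activated_mc", "in_vivo", "mastocytosis", 173, 31, 1902, 206, 3.5, 0.8, 700, 100, 9.0, 1.0, 0.2, LABEL_ACTIVATED),
    _spec("resting_mc", "in_vivo", "allergy", 310, 58, 2204, 103, 1.8, 0.7, 320, 120, 10.0, 1.0, 0.9, LABEL_RESTING),
    _spec("activated_mc", "in_vivo", "allergy", 185, 20, 1925, 147, 4.6, 1.1, 840, 160, 9.0, 1.0, 0.2, LABEL_ACTIVATED),
    # in vivo "other" dermal cells reuse the cultured distributions
    _spec("macrophage_short", "in_vivo", "healthy", 225, 84, 1289, 278, 4.8, 3.4, 3000, 500, 11.0, 1.5, 0.5, LABEL_OTHER),
    _spec("macrophage_long", "in_vivo", "healthy", 1016, 220, 2432, 239, 2.6, 1.0, 800, 200, 11.0, 1.5, 0.5, LABEL_OTHER),
]}

#: study cohort composition: 85 MCs in vitro, 17 MCs ex vivo, 148 MCs in vivo,
#: 116 macrophages, 14 dendritic cells, 6 fibroblasts, 21 neutrophils = 407.
DEFAULT_COHORT_COUNTS: dict[str, int] = {
    "resting_mc/in_vitro": 43,
    "activated_mc/in_vitro": 13,
    "ige_resting_mc/in_vitro": 14,
    "ige_activated_mc/in_vitro": 15,
    "resting_mc/ex_vivo": 9,
    "activated_mc/ex_vivo": 8,
    "resting_mc/in_vivo/healthy": 71,
    "activated_mc/in_vivo/healthy": 48,
    "resting_mc/in_vivo/mastocytosis": 9,
    "activated_mc/in_vivo/mastocytosis": 3,
    "resting_mc/in_vivo/allergy": 8,
    "activated_mc/in_vivo/allergy": 9,
    "macrophage_short/in_vitro": 34,
    "macrophage_long/in_vitro": 20,
    "macrophage_short/ex_vivo": 2,
    "macrophage_long/ex_vivo": 2,
    "macrophage_short/in_vivo/healthy": 36,
    "macrophage_long/in_vivo/healthy": 22,
    "dendritic/in_vitro": 14,
    "fibroblast/in_vitro": 6,
    "neutrophil/in_vitro": 21,
}


@dataclass
class CohortSpec:
    """Composition of a labeled synthetic cohort."""

    counts: dict = field(default_factory=lambda: dict(DEFAULT_COHORT_COUNTS))
    label_scheme: str = "three_class"  # or "binary"

    def __post_init__(self):
        for key, n in self.counts.items():
            if key not in CLASS_SPECS:
                raise ValueError(f"unknown cell class {key!r}")
            if n < 0:
                raise ValueError(f"negative count for {key!r}")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))


def _truncated_normal(rng, mean, sd, size, low=0.0):
    """Draw from a normal truncated (strictly) below at ``low`` by rejection."""
    if sd == 0:
        return np.full(size, float(mean))
    x = rng.normal(mean, sd, size)
    bad = x <= low
    while bad.any():
        x[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = x <= low
    return x


def sample_cell_params(spec: CellClassSpec, rng: np.random.Generator, size: int | None = None):
    """Sample (tau1, tau2, ratio, intensity, diameter, shape_flag) for a class.

    Each parameter is an independent truncated normal (positive support);
    (tau1, tau2) pairs violating tau1 < tau2 are jointly redrawn.
    """
    n = 1 if size is None else size
    tau1 = _truncated_normal(rng, spec.tau1_mean, spec.tau1_sd, n)
    tau2 = _truncated_normal(rng, spec.tau2_mean, spec.tau2_sd, n)
    bad = tau1 >= tau2
    while bad.any():
        m = int(bad.sum())
        tau1[bad] = _truncated_normal(rng, spec.tau1_mean, spec.tau1_sd, m)
        tau2[bad] = _truncated_normal(rng, spec.tau2_mean, spec.tau2_sd, m)
        bad = tau1 >= tau2
    ratio = _truncated_normal(rng, spec.ratio_mean, spec.ratio_sd, n)
    intensity = _truncated_normal(rng, spec.intensity_mean, spec.intensity_sd, n)
    diameter = _truncated_normal(rng, spec.diameter_mean, spec.diameter_sd, n)
    shape_flag = (rng.random(n) < spec.circular_prob).astype(int)
    out = (tau1, tau2, ratio, intensity, diameter, shape_flag)
    if size is None:
        return tuple(float(v[0]) if v.dtype.kind == "f" else int(v[0]) for v in out)
    return out


def _decay_curve(tau1, tau2, ratio, irf: IRF) -> np.ndarray:
    """Noiseless, peak-normalized model decay for unit total amplitude."""
    a1 = ratio / (1.0 + ratio)
    a2 = 1.0 / (1.0 + ratio)
    curve = model_decay(a1, tau1, a2, tau2, irf)
    return curve / curve.max()


def generate_cohort(spec: CohortSpec | None = None, rng: np.random.Generator | None = None,
                    irf: IRF | None = None) -> pd.DataFrame:
    """Generate a feature-level labeled cohort (no image rendering).

    Returns one row per cell with the sampled parameters, derived tau_m and
    amplitude asymmetry, the peak-normalized 256-bin decay curve (columns
    ``d000`` ... ``d255``) and labels under both schemes (``label3``:
    0 activated MC / 1 resting MC / 2 other; ``label2``: 0 MC / 1 other).
    """
    if spec is None:
        spec = CohortSpec()
    if rng is None:
        rng = np.random.default_rng(0)
    if irf is None:
        irf = gaussian_irf()

    rows = []
    curves = []
    cell_id = 0
    for key in spec.counts:  # insertion order: deterministic
        cls = CLASS_SPECS[key]
        n = spec.counts[key]
        if n == 0:
            continue
        tau1, tau2, ratio, intensity, diameter, shape_flag = sample_cell_params(cls, rng, size=n)
        for i in range(n):
            a1 = ratio[i] / (1.0 + ratio[i])
            a2 = 1.0 / (1.0 + ratio[i])
            tau_m = mean_lifetime(a1, tau1[i], a2, tau2[i])
            rows.append({
                "cell_id": cell_id,
                "class_name": cls.class_name,
                "context": cls.context,
                "condition": cls.condition,
                "tau1": tau1[i],
                "tau2": tau2[i],
                "ratio": ratio[i],
                "a1": a1,
                "a2": a2,
                "asym": a1 - a2,
                "tau_m": tau_m,
                "intensity": intensity[i],
                "diameter": diameter[i],
                "shape_flag": int(shape_flag[i]),
                "label3": cls.label3,
                "label2": LABEL_MC if cls.label3 != LABEL_OTHER else LABEL_NOT_MC,
            })
            curves.append(_decay_curve(tau1[i], tau2[i], ratio[i], irf))
            cell_id += 1

    df = pd.DataFrame(rows)
    curve_df = pd.DataFrame(np.asarray(curves), columns=[f"d{k:03d}" for k in range(N_CHANNELS)])
    return pd.concat([df.reset_index(drop=True), curve_df], axis=1)


# --------------------------------------------------------------------------
# image mode

@dataclass
class CellPlacement:
    """A cell to render: class key, center (x, y) in um, optional fixed params."""

    spec_key: str
    center_um: tuple
    params: tuple | None = None  # (tau1, tau2, ratio, intensity, diameter, shape_flag)


@dataclass
class CapillarySpec:
    """Blood capillary cross-section rendered as an ultrashort mono-exponential."""

    center_um: tuple
    radius_um: float = 3.0
    tau_ps: float = 80.0
    intensity: float = 600.0  # photons/mW, 49-pixel convention


@dataclass
class SceneConfig:
    """Geometry, photophysics and noise settings of a rendered field of view."""

    image_size: tuple = (512, 512)
    field_of_view_um: tuple = (150.0, 150.0)
    depth_um: float = 90.0
    excitation_power_mw: float = 50.0
    n_time_channels: int = N_CHANNELS
    channel_width_ps: float = CHANNEL_WIDTH_PS
    elastin_tau_m_mean: float = 1600.0
    elastin_tau_m_sd: float = 110.0
    elastin_tau1: float = 800.0
    elastin_tau2: float = 2400.0
    elastin_intensity: float = 450.0  # photons/mW, 49-pixel convention
    capillaries: Sequence[CapillarySpec] = ()
    cells: Sequence[CellPlacement] = ()
    granule_size_range_um: tuple = (0.5, 1.5)
    granule_contrast: float = 2.0
    irf_fwhm_ps: float = 150.0
    irf_peak_channel: int = 10
    poisson_noise: bool = True

    def __post_init__(self):
        if self.n_time_channels * self.channel_width_ps <= 0:
            raise ValueError("invalid time axis")

    @property
    def pixel_pitch_um(self) -> float:
        return self.field_of_view_um[0] / self.image_size[1]


@dataclass
class GroundTruth:
    """Placed-cell table plus an integer label image (0 background, -1 capillary)."""

    table: pd.DataFrame
    labels: np.ndarray


def _disc_mask(shape, center_px, radius_px):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center_px[0]) ** 2 + (xx - center_px[1]) ** 2 <= radius_px**2


def granule_texture(mask: np.ndarray, pitch_um: float, rng: np.random.Generator,
                    size_range_um=(0.5, 1.5), contrast=2.0) -> np.ndarray:
    """Multiplicative amplitude field emulating cytoplasmic granules.

    Discs of diameter U(size_range) are dropped with Poisson-disc-like
    spacing inside the mask at ~40% coverage, raised to ``contrast`` over the
    cytoplasm, lightly smoothed, and normalized to unit mean over the mask.
    """
    field_img = np.ones(mask.shape)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return field_img
    area_um2 = ys.size * pitch_um**2
    mean_d = 0.5 * (size_range_um[0] + size_range_um[1])
    n_granules = max(1, int(0.4 * area_um2 / (np.pi * (mean_d / 2) ** 2)))
    placed = []
    attempts = 0
    while len(placed) < n_granules and attempts < 50 * n_granules:
        attempts += 1
        k = rng.integers(ys.size)
        cy, cx = ys[k], xs[k]
        d_um = rng.uniform(*size_range_um)
        r_px = max(d_um / 2 / pitch_um, 0.5)
        if any((cy - py) ** 2 + (cx - px) ** 2 < (r_px + pr) ** 2 for py, px, pr in placed):
            continue
        placed.append((cy, cx, r_px))
        field_img[_disc_mask(mask.shape, (cy, cx), r_px)] = contrast
    field_img = ndimage.gaussian_filter(field_img, sigma=max(0.15 / pitch_um, 0.5))
    inside = field_img[mask]
    field_img = field_img / inside.mean()
    out = np.ones(mask.shape)
    out[mask] = field_img[mask]
    return out


def render_scene(config: SceneConfig, rng: np.random.Generator) -> tuple[DecayCube, GroundTruth]:
    """Render a synthetic TCSPC decay cube and its ground truth.

    Every pixel's expected decay is the IRF-convolved bi-exponential model of
    the structure covering it (elastin background with per-pixel tau_m drawn
    from the elastin distribution, mono-exponential capillaries, placed cells
    with granule texture), scaled to the structure's expected photon count,
    then Poisson-sampled per channel.
    """
    H, W = config.image_size
    T = config.n_time_channels
    pitch = config.pixel_pitch_um
    irf = gaussian_irf(T, config.channel_width_ps, config.irf_fwhm_ps, config.irf_peak_channel)
    power = config.excitation_power_mw

    # elastin background: shared component lifetimes, per-pixel amplitude ratio
    # chosen so the pixel's tau_m matches its draw from the elastin distribution
    t1, t2 = config.elastin_tau1, config.elastin_tau2
    tau_m_map = rng.normal(config.elastin_tau_m_mean, config.elastin_tau_m_sd, (H, W))
    tau_m_map = np.clip(tau_m_map, t1 + 1.0, t2 - 1.0)
    ratio_map = (t2 - tau_m_map) / (tau_m_map - t1)  # a1/a2
    a1_map = ratio_map / (1.0 + ratio_map)
    a2_map = 1.0 / (1.0 + ratio_map)
    b1 = model_decay(1.0, t1, 0.0, t2, irf, T, config.channel_width_ps)
    b2 = model_decay(0.0, t1, 1.0, t2, irf, T, config.channel_width_ps)
    norm = a1_map * b1.sum() + a2_map * b2.sum()
    scale = config.elastin_intensity / BINNED_PIXELS * power / norm
    expected = (a1_map * scale)[:, :, None] * b1 + (a2_map * scale)[:, :, None] * b2

    labels = np.zeros((H, W), dtype=int)

    for cap in config.capillaries:
        cy = cap.center_um[1] / pitch
        cx = cap.center_um[0] / pitch
        m = _disc_mask((H, W), (cy, cx), cap.radius_um / pitch)
        curve = model_decay(1.0, cap.tau_ps, 0.0, 1.0, irf, T, config.channel_width_ps)
        curve = curve / curve.sum() * cap.intensity / BINNED_PIXELS * power
        expected[m] = curve
        labels[m] = -1

    records = []
    for idx, placement in enumerate(config.cells, start=1):
        cls = CLASS_SPECS[placement.spec_key]
        params = placement.params or sample_cell_params(cls, rng)
        tau1, tau2, ratio, intensity, diameter, shape_flag = params
        cy = placement.center_um[1] / pitch
        cx = placement.center_um[0] / pitch
        r_px = diameter / 2.0 / pitch
        if shape_flag:
            ry = rx = r_px
        else:  # elongated: 3:1 axis-aligned ellipse of equal area
            ry, rx = r_px / np.sqrt(3.0), r_px * np.sqrt(3.0)
        if not (rx <= cx <= W - 1 - rx and ry <= cy <= H - 1 - ry):
            raise ValueError(f"cell {idx} placed outside the field of view")
        if shape_flag:
            m = _disc_mask((H, W), (cy, cx), r_px)
        else:
            yy, xx = np.ogrid[:H, :W]
            m = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        if np.any(labels[m] != 0):
            raise ValueError(f"cell {idx} overlaps a previously placed structure")
        a1 = ratio / (1.0 + ratio)
        a2 = 1.0 / (1.0 + ratio)
        curve = model_decay(a1, tau1, a2, tau2, irf, T, config.channel_width_ps)
        curve = curve / curve.sum() * intensity / BINNED_PIXELS * power
        texture = granule_texture(m, pitch, rng, config.granule_size_range_um,
                                  config.granule_contrast)
        expected[m] = texture[m, None] * curve
        labels[m] = idx
        records.append({
            "cell_id": idx, "spec_key": placement.spec_key,
            "class_name": cls.class_name, "context": cls.context,
            "condition": cls.condition,
            "center_x_um": placement.center_um[0], "center_y_um": placement.center_um[1],
            "tau1": tau1, "tau2": tau2, "ratio": ratio,
            "tau_m": mean_lifetime(a1, tau1, a2, tau2),
            "intensity": intensity, "diameter": diameter,
            "shape_flag": int(shape_flag), "label3": cls.label3,
        })

    counts = rng.poisson(expected).astype(np.int32) if config.poisson_noise else expected
    cube = DecayCube(counts=counts, channel_width_ps=config.channel_width_ps,
                     power_mw=power, pixel_pitch_um=pitch, irf=irf,
                     depth_um=config.depth_um,
                     meta={"poisson_noise": config.poisson_noise})
    truth = GroundTruth(table=pd.DataFrame(records), labels=labels)
    return cube, truth
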