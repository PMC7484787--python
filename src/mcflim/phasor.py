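"""First-harmonic phasor representation of TCSPC decays.

A decay histogram c_k over channel-center times t_k is mapped to the
normalized first Fourier component

    g = sum_k c_k cos(n w t_k) / sum_k c_k
    s = sum_k c_k sin(n w t_k) / sum_k c_k

with w = 2 pi f_rep (80 MHz) and harmonic n = 1, then calibrated by complex
division with the phasor of the recorded IRF (convolution with the IRF is a
multiplication in phasor space, so the IRF itself calibrates to (1, 0)).
Mono-exponential decays land on the universal semicircle
(g - 1/2)^2 + s^2 = 1/4; mixtures fall on chords inside it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decay import CHANNEL_WIDTH_PS, DecayCube, IRF, bin_decays, time_axis

#: angular frequency of the first harmonic in rad/ps (80 MHz repetition)
OMEGA_PER_PS = 2.0 * np.pi * 80e6 * 1e-12


@dataclass
class PhasorConfig:
    omega: float = OMEGA_PER_PS
    harmonic: int = 1
    intensity_threshold_fraction: float = 0.7
    binning: int = 3

    def __post_init__(self):
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if not 0.0 < self.intensity_threshold_fraction <= 1.0:
            raise ValueError("intensity threshold fraction must be in (0, 1]")


@dataclass
class PhasorCloud:
    """Per-pixel phasor coordinates for pixels retained by the intensity gate."""

    g: np.ndarray
    s: np.ndarray
    pixel_index: np.ndarray  # (n, 2) row, col
    intensity: np.ndarray
    retained: np.ndarray  # (H, W) bool
    empty: bool = False

    def centroid(self) -> tuple:
        return float(np.mean(self.g)), float(np.mean(self.s))


def phasor_transform(counts: np.ndarray, irf: IRF | None = None,
                     config: PhasorConfig | None = None,
                     channel_width: float = CHANNEL_WIDTH_PS):
    """Phasor (g, s) of one decay histogram, IRF-calibrated when an IRF is given.

    ``counts`` may be (T,) or (..., T); the transform maps the trailing axis.
    """
    if config is None:
        config = PhasorConfig()
    c = np.asarray(counts, dtype=float)
    total = c.sum(axis=-1)
    if np.any(total <= 0):
        raise ValueError("phasor undefined for an all-zero histogram")
    t = time_axis(c.shape[-1], channel_width)
    phase = config.harmonic * config.omega * t
    z = (c * np.exp(1j * phase)).sum(axis=-1) / total
    if irf is not None:
        z_irf = phasor_transform(irf.kernel, None, config, channel_width)
        z = z / complex(z_irf[0], z_irf[1])
    g = np.real(z)
    s = np.imag(z)
    if np.ndim(g) == 0:
        return float(g), float(s)
    return g, s


def mono_exponential_phasor(tau_ps: float, omega: float = OMEGA_PER_PS) -> tuple:
    """Closed-form phasor of a continuous mono-exponential decay."""
    wt = omega * tau_ps
    return 1.0 / (1.0 + wt**2), wt / (1.0 + wt**2)


def phasor_image(cube: DecayCube, irf: IRF | None = None,
                 config: PhasorConfig | None = None) -> PhasorCloud:
    """Phasor cloud of an image after binning and the 70% intensity gate.

    Only pixels whose binned total intensity reaches
    ``intensity_threshold_fraction`` of the image maximum contribute points.
    """
    if config is None:
        config = PhasorConfig()
    if irf is None:
        irf = cube.irf
    binned = bin_decays(cube.counts, config.binning)
    intensity = binned.sum(axis=2)
    retained = intensity >= config.intensity_threshold_fraction * intensity.max()
    idx = np.argwhere(retained)
    if idx.size == 0:
        return PhasorCloud(g=np.array([]), s=np.array([]),
                           pixel_index=idx, intensity=np.array([]),
                           retained=retained, empty=True)
    g, s = phasor_transform(binned[retained], irf, config, cube.channel_width_ps)
    return PhasorCloud(g=np.atleast_1d(g), s=np.atleast_1d(s), pixel_index=idx,
                       intensity=intensity[retained], retained=retained)
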