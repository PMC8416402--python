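"""Full-reference image quality: PSNR, SSIM and FSIM, with batch reporting.

PSNR is the dB-scaled peak-to-MSE ratio.  SSIM is shared with the training
loss (:func:`ldctgan.losses.ssim`).  FSIM scores feature similarity: local
phase congruency (computed from a log-Gabor filter bank over scales and
orientations) and gradient magnitude are compared pointwise, and the
similarity map is pooled with the maximal phase congruency as weight —
regions with salient features dominate the score.  Constants and filter-bank
defaults follow the published FSIM formulation (T1 = 0.85, T2 = 160 on a
0-255 intensity scale; 4 scales, 4 orientations, minimum wavelength 6,
scale factor 2, sigmaOnf 0.55).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .losses import SSIMConfig, ssim
from .phantom import CTImage

__all__ = ["psnr", "fsim", "phase_congruency", "FSIMConfig",
           "MetricReport", "evaluate_pairs", "PSNR_CAP"]

#: Sentinel PSNR reported for identical images (MSE = 0).
PSNR_CAP = math.inf


def _pixels(x) -> np.ndarray:
    if isinstance(x, CTImage):
        return x.pixels
    return np.asarray(x, dtype=np.float64)


def psnr(x, y, data_range: float = 1.0) -> float:
    """10 * log10(data_range^2 / MSE); identical inputs return the +inf
    cap sentinel."""
    a, b = _pixels(x), _pixels(y)
    if a.shape != b.shape:
        raise ValueError("psnr inputs must be shape-matched")
    if data_range <= 0:
        raise ValueError("data_range must be > 0")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return PSNR_CAP
    return 10.0 * math.log10(data_range ** 2 / mse)


@dataclass
class FSIMConfig:
    """Log-Gabor bank and similarity constants for FSIM."""

    n_scales: int = 4
    n_orientations: int = 4
    min_wavelength: float = 6.0
    mult: float = 2.0
    sigma_onf: float = 0.55
    d_theta_on_sigma: float = 1.2
    noise_k: float = 2.0
    epsilon: float = 1e-4
    t1: float = 0.85      # phase-congruency similarity constant
    t2: float = 160.0     # gradient similarity constant (0-255 scale)
    data_range: float = 1.0

    def __post_init__(self):
        if self.n_scales < 2 or self.n_orientations < 4:
            raise ValueError("need >= 2 scales and >= 4 orientations")
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("similarity constants must be > 0")


def _freq_grid(rows: int, cols: int):
    def axis(n):
        if n % 2:
            return np.arange(-(n - 1) / 2, (n - 1) / 2 + 1) / (n - 1)
        return np.arange(-n / 2, n / 2) / n
    x, y = np.meshgrid(axis(cols), axis(rows))
    radius = np.fft.ifftshift(np.hypot(x, y))
    theta = np.fft.ifftshift(np.arctan2(-y, x))
    radius[0, 0] = 1.0
    return radius, theta


def _lowpass(radius: np.ndarray, cutoff: float = 0.45, order: int = 15) -> np.ndarray:
    return 1.0 / (1.0 + (radius / cutoff) ** (2 * order))


def phase_congruency(im: np.ndarray, cfg: FSIMConfig) -> np.ndarray:
    """Kovesi-style phase congruency map via a log-Gabor quadrature bank,
    with the standard Rayleigh-statistics noise compensation."""
    rows, cols = im.shape
    radius, theta = _freq_grid(rows, cols)
    lp = _lowpass(radius)
    sintheta, costheta = np.sin(theta), np.cos(theta)
    theta_sigma = np.pi / cfg.n_orientations / cfg.d_theta_on_sigma
    imfft = np.fft.fft2(im)

    log_gabors = []
    for s in range(cfg.n_scales):
        fo = 1.0 / (cfg.min_wavelength * cfg.mult ** s)
        lg = np.exp(-(np.log(radius / fo)) ** 2 / (2 * np.log(cfg.sigma_onf) ** 2)) * lp
        lg[0, 0] = 0.0
        log_gabors.append(lg)

    energy_all = np.zeros_like(im)
    an_all = np.zeros_like(im)
    for o in range(cfg.n_orientations):
        angl = o * np.pi / cfg.n_orientations
        ds = sintheta * np.cos(angl) - costheta * np.sin(angl)
        dc = costheta * np.cos(angl) + sintheta * np.sin(angl)
        spread = np.exp(-np.arctan2(np.abs(ds), dc) ** 2 / (2 * theta_sigma ** 2))
        # NB: arctan2(|ds|, dc) == |arctan2(ds, dc)| for dc of either sign
        sum_e = np.zeros_like(im)
        sum_o = np.zeros_like(im)
        sum_an = np.zeros_like(im)
        eos = []
        tau = None
        for s in range(cfg.n_scales):
            eo = np.fft.ifft2(imfft * (log_gabors[s] * spread))
            eos.append(eo)
            an = np.abs(eo)
            sum_an += an
            sum_e += eo.real
            sum_o += eo.imag
            if s == 0:
                tau = np.median(an) / np.sqrt(np.log(4.0))
        x_energy = np.hypot(sum_e, sum_o) + cfg.epsilon
        mean_e, mean_o = sum_e / x_energy, sum_o / x_energy
        energy = np.zeros_like(im)
        for eo in eos:
            e, od = eo.real, eo.imag
            energy += e * mean_e + od * mean_o - np.abs(e * mean_o - od * mean_e)
        total_tau = tau * (1 - (1 / cfg.mult) ** cfg.n_scales) / (1 - 1 / cfg.mult)
        noise_mean = total_tau * np.sqrt(np.pi / 2)
        noise_sigma = total_tau * np.sqrt((4 - np.pi) / 2)
        t = (noise_mean + cfg.noise_k * noise_sigma) / 1.7   # empirical correction
        energy_all += np.maximum(energy - t, 0.0)
        an_all += sum_an
    return energy_all / an_all


_SCHARR_X = np.array([[3, 0, -3], [10, 0, -10], [3, 0, -3]]) / 16.0


def _scharr_gradient(im: np.ndarray) -> np.ndarray:
    # symmetric extension keeps the gradient of a constant image exactly
    # zero at the borders, so FSIM is brightness-invariant everywhere
    from scipy.signal import convolve2d
    gx = convolve2d(im, _SCHARR_X, mode="same", boundary="symm")
    gy = convolve2d(im, _SCHARR_X.T, mode="same", boundary="symm")
    return np.hypot(gx, gy)


def fsim(x, y, cfg: FSIMConfig | None = None) -> float:
    """Feature similarity index in [0, 1].

    Inputs are rescaled to the 0-255 intensity convention of the published
    constants; images whose shorter side exceeds 256 are average-pooled
    first (the standard viewing-distance adjustment).
    """
    cfg = cfg or FSIMConfig()
    a, b = _pixels(x), _pixels(y)
    if a.shape != b.shape:
        raise ValueError("fsim inputs must be shape-matched")
    scale = 255.0 / cfg.data_range
    a = a * scale
    b = b * scale
    f = max(1, int(round(min(a.shape) / 256.0)))
    if f > 1:
        from scipy.ndimage import uniform_filter
        a = uniform_filter(a, size=f, mode="constant")[::f, ::f]
        b = uniform_filter(b, size=f, mode="constant")[::f, ::f]
    if min(a.shape) < 2 * cfg.min_wavelength:
        raise ValueError("image smaller than the log-Gabor filter support")
    pc1 = phase_congruency(a, cfg)
    pc2 = phase_congruency(b, cfg)
    g1 = _scharr_gradient(a)
    g2 = _scharr_gradient(b)
    s_pc = (2 * pc1 * pc2 + cfg.t1) / (pc1 ** 2 + pc2 ** 2 + cfg.t1)
    s_g = (2 * g1 * g2 + cfg.t2) / (g1 ** 2 + g2 ** 2 + cfg.t2)
    pcm = np.maximum(pc1, pc2)
    return float(np.sum(s_pc * s_g * pcm) / np.sum(pcm))


# ---------------------------------------------------------------------------
# batch evaluation
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    """Per-image PSNR/SSIM/FSIM plus dataset means and standard deviations."""

    psnr_db: list[float]
    ssim: list[float]
    fsim: list[float]
    labels: list[str] = field(default_factory=list)

    @property
    def n_images(self) -> int:
        return len(self.psnr_db)

    def _finite_mean_sd(self, vals):
        arr = np.asarray(vals, dtype=np.float64)
        return float(np.mean(arr)), float(np.std(arr))

    def summary(self) -> dict:
        out = {"n_images": self.n_images}
        for name, vals in (("psnr_db", self.psnr_db), ("ssim", self.ssim),
                           ("fsim", self.fsim)):
            m, s = self._finite_mean_sd(vals)
            out[f"{name}_mean"] = m
            out[f"{name}_sd"] = s
        return out

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["file", "psnr_db", "ssim", "fsim"])
            for i in range(self.n_images):
                label = self.labels[i] if self.labels else str(i)
                w.writerow([label, self.psnr_db[i], self.ssim[i], self.fsim[i]])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"summary": self.summary(),
                       "per_image": {"labels": self.labels or list(map(str, range(self.n_images))),
                                     "psnr_db": self.psnr_db, "ssim": self.ssim,
                                     "fsim": self.fsim}}, fh, indent=2, default=str)


def evaluate_pairs(pairs, data_range: float = 1.0,
                   ssim_cfg: SSIMConfig | None = None,
                   fsim_cfg: FSIMConfig | None = None,
                   labels: list[str] | None = None) -> MetricReport:
    """Score (predicted, reference) image pairs; stable input ordering."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("evaluate_pairs needs at least one pair")
    ssim_cfg = ssim_cfg or SSIMConfig(data_range=data_range)
    fsim_cfg = fsim_cfg or FSIMConfig(data_range=data_range)
    ps, ss, fs = [], [], []
    for i, (pred, ref) in enumerate(pairs):
        a, b = _pixels(pred), _pixels(ref)
        if a.shape != b.shape:
            raise ValueError(f"pair {i}: shape mismatch {a.shape} vs {b.shape}")
        ps.append(psnr(a, b, data_range))
        ss.append(ssim(a, b, ssim_cfg))
        fs.append(fsim(a, b, fsim_cfg))
    return MetricReport(psnr_db=ps, ssim=ss, fsim=fs,
                        labels=labels or [str(i) for i in range(len(pairs))])
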