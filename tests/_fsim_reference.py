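"""Synthetic reference FSIM: an independent, deliberately literal
transcription of the published feature-similarity algorithm (log-Gabor
phase congruency + Scharr gradient, similarity constants T1=0.85, T2=160 on
a 0-255 scale), written loop-by-loop from the published description for use
as a test oracle only.  Shares the package implementation's declared
convention of symmetric boundary extension for the gradient operator."""

import numpy as np
from scipy.signal import convolve2d


def _axis_freqs(n):
    if n % 2 == 1:
        vals = np.arange(-(n - 1) // 2, (n - 1) // 2 + 1) / (n - 1)
    else:
        vals = np.arange(-n // 2, n // 2) / n
    return vals


def reference_phase_congruency(im, nscale=4, norient=4, min_wavelength=6.0,
                               mult=2.0, sigma_onf=0.55, d_theta_on_sigma=1.2,
                               k=2.0, eps=1e-4):
    rows, cols = im.shape
    fx = _axis_freqs(cols)
    fy = _axis_freqs(rows)
    x, y = np.meshgrid(fx, fy)
    radius = np.fft.ifftshift(np.sqrt(x * x + y * y))
    theta = np.fft.ifftshift(np.arctan2(-y, x))
    radius[0, 0] = 1.0
    lowpass = 1.0 / (1.0 + (radius / 0.45) ** 30)
    theta_sigma = np.pi / norient / d_theta_on_sigma
    imfft = np.fft.fft2(im)

    energy_total = np.zeros((rows, cols))
    an_total = np.zeros((rows, cols))
    for o in range(norient):
        angl = o * np.pi / norient
        ds = np.sin(theta) * np.cos(angl) - np.cos(theta) * np.sin(angl)
        dc = np.cos(theta) * np.cos(angl) + np.sin(theta) * np.sin(angl)
        dtheta = np.abs(np.arctan2(ds, dc))
        spread = np.exp(-dtheta ** 2 / (2 * theta_sigma ** 2))

        eo_list = []
        sum_e = np.zeros((rows, cols))
        sum_o = np.zeros((rows, cols))
        sum_an = np.zeros((rows, cols))
        tau = 0.0
        for s in range(nscale):
            wavelength = min_wavelength * mult ** s
            fo = 1.0 / wavelength
            log_gabor = np.exp(-(np.log(radius / fo)) ** 2
                               / (2.0 * np.log(sigma_onf) ** 2))
            log_gabor = log_gabor * lowpass
            log_gabor[0, 0] = 0.0
            eo = np.fft.ifft2(imfft * log_gabor * spread)
            eo_list.append(eo)
            an = np.abs(eo)
            sum_an = sum_an + an
            sum_e = sum_e + np.real(eo)
            sum_o = sum_o + np.imag(eo)
            if s == 0:
                tau = np.median(an) / np.sqrt(np.log(4.0))
        x_energy = np.sqrt(sum_e ** 2 + sum_o ** 2) + eps
        mean_e = sum_e / x_energy
        mean_o = sum_o / x_energy
        energy = np.zeros((rows, cols))
        for eo in eo_list:
            e, oo = np.real(eo), np.imag(eo)
            energy = energy + e * mean_e + oo * mean_o \
                - np.abs(e * mean_o - oo * mean_e)
        total_tau = tau * (1.0 - (1.0 / mult) ** nscale) / (1.0 - 1.0 / mult)
        noise_mean = total_tau * np.sqrt(np.pi / 2.0)
        noise_sigma = total_tau * np.sqrt((4.0 - np.pi) / 2.0)
        threshold = (noise_mean + k * noise_sigma) / 1.7
        energy = np.where(energy - threshold > 0.0, energy - threshold, 0.0)
        energy_total = energy_total + energy
        an_total = an_total + sum_an
    return energy_total / an_total


def reference_fsim(img1, img2, data_range=1.0):
    a = np.asarray(img1, dtype=np.float64) * (255.0 / data_range)
    b = np.asarray(img2, dtype=np.float64) * (255.0 / data_range)
    t1, t2 = 0.85, 160.0
    pc1 = reference_phase_congruency(a)
    pc2 = reference_phase_congruency(b)
    scharr = np.array([[3.0, 0.0, -3.0],
                       [10.0, 0.0, -10.0],
                       [3.0, 0.0, -3.0]]) / 16.0
    g1x = convolve2d(a, scharr, mode="same", boundary="symm")
    g1y = convolve2d(a, scharr.T, mode="same", boundary="symm")
    g2x = convolve2d(b, scharr, mode="same", boundary="symm")
    g2y = convolve2d(b, scharr.T, mode="same", boundary="symm")
    g1 = np.sqrt(g1x ** 2 + g1y ** 2)
    g2 = np.sqrt(g2x ** 2 + g2y ** 2)

    rows, cols = a.shape
    num = 0.0
    den = 0.0
    for i in range(rows):
        for j in range(cols):
            s_pc = (2.0 * pc1[i, j] * pc2[i, j] + t1) \
                / (pc1[i, j] ** 2 + pc2[i, j] ** 2 + t1)
            s_g = (2.0 * g1[i, j] * g2[i, j] + t2) \
                / (g1[i, j] ** 2 + g2[i, j] ** 2 + t2)
            pcm = max(pc1[i, j], pc2[i, j])
            num += s_pc * s_g * pcm
            den += pcm
    return num / den
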