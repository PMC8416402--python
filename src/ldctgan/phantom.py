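"""Synthetic paired NDCT/LDCT data via an ellipse-phantom CT pipeline.

Low-dose CT noise originates in the projection domain: each detector bin
records a photon count whose mean is set by the attenuated beam (quantum
Poisson statistics) plus additive electronic readout noise (Gaussian).
Reconstructing those noisy line integrals with filtered back-projection
produces the spatially correlated, non-uniform image-domain noise (streaks,
center/edge variance differences) that characterizes real low-dose scans —
noise that no i.i.d. image-domain model reproduces.

This module builds ellipse phantoms on a unit square, forward-projects them
(parallel-beam Radon transform), injects count-domain noise at a chosen tube
output ``I0``, and reconstructs both the clean and the noisy sinograms to
form aligned (NDCT, LDCT) training pairs.

Conventions: pixel centers lie on a uniform grid over [-1, 1]^2; projection
angles are degrees in the half-open interval [0, 180); line integrals are in
pixel-length units (an attenuation-mu disk of radius r pixels has peak
projection 2*r*mu).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import radon as _sk_radon, iradon as _sk_iradon

__all__ = [
    "Ellipse", "PhantomSpec", "CTImage", "Sinogram", "DoseParams",
    "PairedDataset", "SHEPP_LOGAN_ELLIPSES",
    "make_phantom", "forward_project", "apply_low_dose", "fbp_reconstruct",
    "build_dataset", "random_phantom_spec",
]

FBP_FILTERS = {"ramp", "shepp-logan", "hann"}


@dataclass(frozen=True)
class Ellipse:
    """One additive ellipse: center in [-1,1]^2, semi-axes in (0,1],
    rotation counterclockwise in degrees, additive attenuation value."""

    center_x: float
    center_y: float
    semi_axis_a: float
    semi_axis_b: float
    rotation_deg: float = 0.0
    attenuation: float = 1.0

    def __post_init__(self):
        if not (self.semi_axis_a > 0 and self.semi_axis_b > 0):
            raise ValueError("ellipse semi-axes must be strictly positive")
        if not (-1 <= self.center_x <= 1 and -1 <= self.center_y <= 1):
            raise ValueError("ellipse center must lie in [-1, 1]^2")


@dataclass
class PhantomSpec:
    ellipses: list[Ellipse] = field(default_factory=list)
    grid_size: int = 128

    def __post_init__(self):
        if self.grid_size < 16:
            raise ValueError("grid_size must be >= 16")
        self.ellipses = [e if isinstance(e, Ellipse) else Ellipse(*e) for e in self.ellipses]


@dataclass
class CTImage:
    """A 2-D attenuation/intensity grid with a declared value range.

    ``value_range`` is the (lo, hi) data range metrics should use; it is a
    property of the dataset, not recomputed per image.
    """

    pixels: np.ndarray
    value_range: tuple[float, float] = (0.0, 1.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("CTImage must be 2-D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("CTImage must be finite")
        lo, hi = self.value_range
        if not lo < hi:
            raise ValueError("value_range must satisfy lo < hi")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class Sinogram:
    """Projection-domain data: rows are angles, columns detector bins."""

    values: np.ndarray
    angles_deg: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.angles_deg.size:
            raise ValueError("sinogram rows must match number of angles")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram must be finite")
        if self.angles_deg.size > 1 and not np.all(np.diff(self.angles_deg) > 0):
            raise ValueError("angles must be strictly increasing")
        if np.any(self.angles_deg < 0) or np.any(self.angles_deg >= 180):
            raise ValueError("angles must lie in [0, 180)")

    @property
    def n_angles(self):
        return self.values.shape[0]

    @property
    def n_bins(self):
        return self.values.shape[1]


@dataclass(frozen=True)
class DoseParams:
    """Tube output and detector noise.

    ``incident_photons`` (I0) is the unattenuated photon count per detector
    bin (1e5 is a normal-dose ballpark, 2.5e4 the matching quarter dose);
    ``electronic_sigma`` is the std of additive Gaussian counts noise.
    """

    incident_photons: float = 1e5
    electronic_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.incident_photons > 0:
            raise ValueError("incident_photons must be > 0")
        if self.electronic_sigma < 0:
            raise ValueError("electronic_sigma must be >= 0")


@dataclass
class PairedDataset:
    train: list[tuple[CTImage, CTImage]]   # (ndct, ldct)
    test: list[tuple[CTImage, CTImage]]
    seed: int = 0
    value_range: tuple[float, float] = (0.0, 1.0)
    meta: dict = field(default_factory=dict)

    @property
    def pairs(self):
        return self.train + self.test


# Standard Shepp-Logan head phantom ellipse table
# (x0, y0, a, b, rotation_deg, attenuation), toned classic values.
SHEPP_LOGAN_ELLIPSES = [
    (0.0, 0.0, 0.69, 0.92, 90.0, 2.0),
    (0.0, -0.0184, 0.6624, 0.874, 90.0, -0.98),
    (0.22, 0.0, 0.11, 0.31, 72.0, -0.02),
    (-0.22, 0.0, 0.16, 0.41, 108.0, -0.02),
    (0.0, 0.35, 0.21, 0.25, 90.0, 0.01),
    (0.0, 0.1, 0.046, 0.046, 0.0, 0.01),
    (0.0, -0.1, 0.046, 0.046, 0.0, 0.01),
    (-0.08, -0.605, 0.046, 0.023, 0.0, 0.01),
    (0.0, -0.605, 0.023, 0.023, 0.0, 0.01),
    (0.06, -0.605, 0.023, 0.046, 90.0, 0.01),
]


def make_phantom(spec: PhantomSpec, seed: int | None = None,
                 jitter: float = 0.0) -> CTImage:
    """Rasterize an additive ellipse phantom onto an N x N grid.

    Pixel (i, j) receives the summed attenuation of every ellipse whose
    interior contains the pixel center.  With a seed and ``jitter`` > 0,
    ellipse geometry is perturbed reproducibly (relative normal jitter),
    giving a family of distinct but anatomically similar phantoms.
    """
    n = spec.grid_size
    coords = (np.arange(n) + 0.5) / n * 2.0 - 1.0
    xx, yy = np.meshgrid(coords, coords[::-1])        # row 0 = top (y = +1)
    img = np.zeros((n, n))
    rng = np.random.default_rng(seed) if seed is not None else None
    for e in spec.ellipses:
        cx, cy, a, b, rot, mu = (e.center_x, e.center_y, e.semi_axis_a,
                                 e.semi_axis_b, e.rotation_deg, e.attenuation)
        if rng is not None and jitter > 0:
            cx += rng.normal(0, jitter)
            cy += rng.normal(0, jitter)
            a = max(a * (1 + rng.normal(0, jitter)), 1e-3)
            b = max(b * (1 + rng.normal(0, jitter)), 1e-3)
            rot += rng.normal(0, jitter * 90.0)
        th = np.deg2rad(rot)
        u = (xx - cx) * np.cos(th) + (yy - cy) * np.sin(th)
        v = -(xx - cx) * np.sin(th) + (yy - cy) * np.cos(th)
        img[(u / a) ** 2 + (v / b) ** 2 <= 1.0] += mu
    lo, hi = float(img.min()), float(img.max())
    vr = (lo, hi) if hi > lo else (0.0, 1.0)
    return CTImage(img, value_range=vr, meta={"seed": seed, "grid_size": n})


def default_n_bins(n: int) -> int:
    """Smallest even bin count whose inscribed circle covers the N x N square."""
    b = int(np.ceil(n * np.sqrt(2.0)))
    return b + (b % 2)


def forward_project(image: CTImage, n_angles: int, n_bins: int | None = None) -> Sinogram:
    """Parallel-beam Radon transform of an image (line integrals in
    pixel-length units), at ``n_angles`` equispaced angles over [0, 180)."""
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    n = image.shape[0]
    if image.shape[0] != image.shape[1]:
        raise ValueError("square images only")
    if n_bins is None:
        n_bins = default_n_bins(n)
    if n_bins < n:
        raise ValueError("n_bins must be >= image width")
    pad = n_bins - n
    lo_pad, hi_pad = pad // 2, pad - pad // 2
    padded = np.pad(image.pixels, ((lo_pad, hi_pad), (lo_pad, hi_pad)))
    angles = np.arange(n_angles) * 180.0 / n_angles
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")           # content near circle boundary
        sino = _sk_radon(padded, theta=angles, circle=True)   # (n_bins, n_angles)
    return Sinogram(sino.T, angles)


def apply_low_dose(sino: Sinogram, dose: DoseParams) -> Sinogram:
    """Inject quantum (Poisson) and electronic (Gaussian) noise in the
    count domain and return the re-log-transformed noisy line integrals.

    Counts: N = Poisson(I0 * exp(-p)) + Normal(0, sigma_e^2), clamped at 1
    photon before the log (photon starvation guard); noisy integral:
    p_hat = -ln(N / I0).  Deterministic for a fixed ``dose.seed``.
    """
    i0 = float(dose.incident_photons)
    if i0 <= 0:
        raise ValueError("incident_photons must be > 0")
    rng = np.random.default_rng(dose.seed)
    expected = i0 * np.exp(-sino.values)
    counts = rng.poisson(expected).astype(np.float64)
    if dose.electronic_sigma > 0:
        counts += rng.normal(0.0, dose.electronic_sigma, size=counts.shape)
    counts = np.maximum(counts, 1.0)
    return Sinogram(-np.log(counts / i0), sino.angles_deg.copy())


def fbp_reconstruct(sino: Sinogram, filter_name: str = "ramp",
                    output_size: int | None = None) -> CTImage:
    """Filtered back-projection onto an ``output_size``-square grid
    (default: the detector width), cropping centrally from the full
    reconstruction circle.  Linear in the sinogram."""
    if filter_name not in FBP_FILTERS:
        raise ValueError(f"unknown filter {filter_name!r}; choose from {sorted(FBP_FILTERS)}")
    recon = _sk_iradon(sino.values.T, theta=sino.angles_deg,
                       filter_name=filter_name, circle=True,
                       interpolation="cubic", output_size=sino.n_bins)
    if output_size is not None and output_size != recon.shape[0]:
        if output_size > recon.shape[0]:
            raise ValueError("output_size exceeds detector width")
        pad = recon.shape[0] - output_size
        lo = pad // 2
        recon = recon[lo:lo + output_size, lo:lo + output_size]
    lo_v, hi_v = float(recon.min()), float(recon.max())
    vr = (lo_v, hi_v) if hi_v > lo_v else (0.0, 1.0)
    return CTImage(recon, value_range=vr)


def random_phantom_spec(rng: np.random.Generator, grid_size: int) -> PhantomSpec:
    """A body-like phantom: large soft-tissue ellipse plus 3-8 internal
    structures of varied size, orientation and contrast."""
    body = Ellipse(rng.uniform(-0.05, 0.05), rng.uniform(-0.05, 0.05),
                   rng.uniform(0.7, 0.85), rng.uniform(0.55, 0.8),
                   rng.uniform(0, 180), rng.uniform(0.8, 1.2))
    ellipses = [body]
    for _ in range(int(rng.integers(3, 9))):
        a = rng.uniform(0.03, 0.3)
        b = rng.uniform(0.03, 0.3)
        r = 0.6 * min(body.semi_axis_a, body.semi_axis_b)
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, r)
        ellipses.append(Ellipse(
            float(np.clip(body.center_x + rad * np.cos(ang), -1, 1)),
            float(np.clip(body.center_y + rad * np.sin(ang), -1, 1)),
            a, b, rng.uniform(0, 180),
            rng.uniform(-0.4, 0.6)))
    return PhantomSpec(ellipses=ellipses, grid_size=grid_size)


def build_dataset(n_train: int, n_test: int, dose: DoseParams,
                  spec_family: PhantomSpec | None = None, seed: int = 0,
                  grid_size: int = 64, n_angles: int = 180,
                  filter_name: str = "ramp") -> PairedDataset:
    """Generate aligned (NDCT, LDCT) pairs from random phantoms.

    For each phantom: the NDCT image is the FBP of the noiseless sinogram,
    the LDCT image the FBP of the same sinogram after count-domain noise at
    ``dose``.  Line integrals are rescaled to physical units (pixel pitch
    2/N on the unit square) so attenuation-1 tissue yields integrals of
    order 1-3 — the regime where quantum noise matters.  All images are then
    jointly min-max normalized to [0, 1] (per dataset, not per image).
    """
    if n_train < 1 or n_test < 0:
        raise ValueError("need at least one training pair")
    rng = np.random.default_rng(seed)
    pixel_pitch = 2.0 / grid_size
    raw_pairs = []
    n_total = n_train + n_test
    for k in range(n_total):
        if spec_family is not None:
            spec = PhantomSpec(list(spec_family.ellipses), grid_size)
            phantom = make_phantom(spec, seed=int(rng.integers(2**31)), jitter=0.03)
        else:
            phantom = make_phantom(random_phantom_spec(rng, grid_size))
        sino = forward_project(phantom, n_angles=n_angles)
        sino_phys = Sinogram(sino.values * pixel_pitch, sino.angles_deg)
        noisy = apply_low_dose(sino_phys, DoseParams(
            dose.incident_photons, dose.electronic_sigma,
            seed=int(rng.integers(2**31))))
        ndct = fbp_reconstruct(sino_phys, filter_name, output_size=grid_size)
        ldct = fbp_reconstruct(noisy, filter_name, output_size=grid_size)
        raw_pairs.append((ndct, ldct))

    all_pix = np.concatenate([np.stack([p[0].pixels, p[1].pixels]) for p in raw_pairs])
    lo, hi = float(all_pix.min()), float(all_pix.max())
    span = hi - lo if hi > lo else 1.0

    def norm(img: CTImage, role: str, idx: int) -> CTImage:
        return CTImage(np.clip((img.pixels - lo) / span, 0.0, 1.0),
                       value_range=(0.0, 1.0),
                       meta={"role": role, "index": idx, "raw_range": (lo, hi),
                             "i0": dose.incident_photons})

    pairs = [(norm(nd, "ndct", i), norm(ld, "ldct", i))
             for i, (nd, ld) in enumerate(raw_pairs)]
    return PairedDataset(train=pairs[:n_train], test=pairs[n_train:], seed=seed,
                         value_range=(0.0, 1.0),
                         meta={"raw_range": (lo, hi), "grid_size": grid_size,
                               "n_angles": n_angles, "i0": dose.incident_photons,
                               "electronic_sigma": dose.electronic_sigma})
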