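"""Image/dataset I/O, strict run configuration, and run manifests.

Formats: NPZ (float arrays + metadata, the primary interchange format),
16-bit TIFF (quantized over the declared value range), 8-bit PNG previews,
and read-only single-slice DICOM (rescale slope/intercept applied).
"""

from __future__ import annotations

import hashlib
import json
import time
import uuid
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .phantom import CTImage, PairedDataset

__all__ = ["load_image", "save_image", "save_dataset", "load_dataset",
           "RunConfig", "Manifest", "write_manifest"]


class FormatError(ValueError):
    """Unreadable or unsupported image file."""


def load_image(path, value_range: tuple[float, float] | None = None) -> CTImage:
    """Read a single 2-D image; format chosen by suffix
    (.npz/.npy/.tif/.tiff/.png/.dcm)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix == ".npz":
            with np.load(path) as z:
                pix = z["pixels"] if "pixels" in z.files else z[z.files[0]]
                vr = tuple(z["value_range"]) if "value_range" in z.files else None
            return CTImage(np.asarray(pix, dtype=np.float64),
                           value_range=value_range or vr or (0.0, 1.0))
        if suffix == ".npy":
            pix = np.load(path)
            return CTImage(np.asarray(pix, dtype=np.float64),
                           value_range=value_range or (0.0, 1.0))
        if suffix in (".tif", ".tiff"):
            import tifffile
            arr = tifffile.imread(path)
            return _dequantize(arr, value_range)
        if suffix == ".png":
            from PIL import Image
            arr = np.asarray(Image.open(path).convert("I" if value_range else "L"))
            return _dequantize(arr, value_range)
        if suffix == ".dcm":
            import pydicom
            dcm = pydicom.dcmread(path)
            arr = dcm.pixel_array.astype(np.float64)
            slope = float(getattr(dcm, "RescaleSlope", 1.0))
            intercept = float(getattr(dcm, "RescaleIntercept", 0.0))
            arr = arr * slope + intercept
            vr = value_range or (float(arr.min()), float(arr.max()) or 1.0)
            if vr[0] >= vr[1]:
                vr = (vr[0], vr[0] + 1.0)
            return CTImage(arr, value_range=vr)
    except FormatError:
        raise
    except Exception as e:
        raise FormatError(f"cannot read {path}: {e}") from e
    raise FormatError(f"unsupported image format: {path}")


def _dequantize(arr: np.ndarray, value_range) -> CTImage:
    arr = np.asarray(arr, dtype=np.float64)
    if value_range is None:
        info_max = 65535.0 if arr.max() > 255 else 255.0
        return CTImage(arr / info_max, value_range=(0.0, 1.0))
    lo, hi = value_range
    denom = 65535.0 if arr.max() > 255 else 255.0
    return CTImage(lo + arr / denom * (hi - lo), value_range=value_range)


def save_image(img: CTImage, path) -> Path:
    """Write an image; format by suffix.  TIFF is 16-bit quantized over the
    declared value range (round trips of the quantized values are exact);
    PNG is an 8-bit preview; NPZ stores the float array losslessly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffix = path.suffix.lower()
    lo, hi = img.value_range
    if suffix == ".npz":
        np.savez(path, pixels=img.pixels, value_range=np.array([lo, hi]))
    elif suffix in (".tif", ".tiff"):
        import tifffile
        q = np.clip((img.pixels - lo) / (hi - lo), 0, 1)
        tifffile.imwrite(path, (q * 65535.0 + 0.5).astype(np.uint16))
    elif suffix == ".png":
        from PIL import Image
        q = np.clip((img.pixels - lo) / (hi - lo), 0, 1)
        Image.fromarray((q * 255.0 + 0.5).astype(np.uint8)).save(path)
    else:
        raise FormatError(f"unsupported output format: {path}")
    return path


def save_dataset(ds: PairedDataset, out_dir) -> list[Path]:
    """Write every pair as NPZ plus PNG previews; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for split in ("train", "test"):
        for i, (nd, ld) in enumerate(getattr(ds, split)):
            stem = out_dir / f"{split}_{i:04d}"
            np.savez(stem.with_suffix(".npz"),
                     ndct=nd.pixels, ldct=ld.pixels,
                     value_range=np.array(ds.value_range))
            written.append(stem.with_suffix(".npz"))
            written.append(save_image(nd, out_dir / f"{split}_{i:04d}_ndct.png"))
            written.append(save_image(ld, out_dir / f"{split}_{i:04d}_ldct.png"))
    meta = dict(ds.meta, seed=ds.seed, n_train=len(ds.train), n_test=len(ds.test),
                value_range=list(ds.value_range))
    meta_path = out_dir / "dataset.json"
    meta_path.write_text(json.dumps(meta, indent=2, default=float))
    written.append(meta_path)
    return written


def load_dataset(in_dir) -> PairedDataset:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "dataset.json").read_text())
    vr = tuple(meta.get("value_range", (0.0, 1.0)))

    def read_split(split):
        pairs = []
        for f in sorted(in_dir.glob(f"{split}_*.npz")):
            with np.load(f) as z:
                pairs.append((CTImage(z["ndct"], value_range=vr),
                              CTImage(z["ldct"], value_range=vr)))
        return pairs

    return PairedDataset(train=read_split("train"), test=read_split("test"),
                         seed=int(meta.get("seed", 0)), value_range=vr, meta=meta)


# ---------------------------------------------------------------------------
# strict run configuration
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateSection(_Strict):
    n_train: int = 16
    n_test: int = 4
    size: int = 64
    i0: float = 1e3
    sigma_e: float = 0.0
    angles: int = 180
    seed: int = 0


class GeneratorSection(_Strict):
    total_layers: int = 17
    base_channels: int = 8
    dilation_schedule: list[int] | None = None
    zero_init_reconstruction: bool = True


class DiscriminatorSection(_Strict):
    conv_channels: list[int] = Field(default_factory=lambda: [8] * 6)
    kernel: int = 3
    fc_sizes: list[int] = Field(default_factory=lambda: [128, 64, 1])


class WeightsSection(_Strict):
    alpha: float = 0.005
    beta: float = 0.0995
    gamma: float = 0.95
    omega: float = 0.95
    gp_lambda: float = 10.0


class TrainingSection(_Strict):
    profile: str = "desk"            # desk | paper
    patch_size: int | None = None
    patches_per_image: int | None = None
    batch_size: int | None = None
    epochs_phase1: int | None = None
    epochs_phase2: int | None = None
    lr1: float | None = None
    lr2: float | None = None
    critic_steps: int | None = None
    max_generator_steps: int | None = None
    extractor: str | None = None
    dtype: str | None = None
    seed: int = 0


class MetricsSection(_Strict):
    data_range: float = 1.0
    ssim_mode: str = "windowed"


class RunConfig(_Strict):
    """Strict, versioned configuration; unknown keys are rejected and the
    YAML round trip is lossless."""

    schema_version: int = 1
    tags: dict[str, str] = Field(default_factory=dict)
    simulate: SimulateSection = Field(default_factory=SimulateSection)
    generator: GeneratorSection = Field(default_factory=GeneratorSection)
    discriminator: DiscriminatorSection = Field(default_factory=DiscriminatorSection)
    weights: WeightsSection = Field(default_factory=WeightsSection)
    training: TrainingSection = Field(default_factory=TrainingSection)
    metrics: MetricsSection = Field(default_factory=MetricsSection)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()).hexdigest()[:16]

    def build(self):
        """Materialize the library-level config objects."""
        from .losses import LossWeights
        from .networks import GeneratorConfig, DiscriminatorConfig
        from .training import TrainConfig
        gen_cfg = GeneratorConfig(**self.generator.model_dump())
        disc_cfg = DiscriminatorConfig(**self.discriminator.model_dump())
        weights = LossWeights(**self.weights.model_dump())
        t = self.training
        base = (TrainConfig.desk_profile if t.profile == "desk"
                else TrainConfig.paper_profile)
        over = {k: v for k, v in t.model_dump().items()
                if k not in ("profile",) and v is not None}
        cfg = base(weights=weights, **over)
        return gen_cfg, disc_cfg, cfg


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class Manifest:
    run_id: str
    config_hash: str
    files: dict[str, str] = field(default_factory=dict)    # relpath -> sha256
    package_version: str = ""
    created: str = ""

    def verify(self, base_dir) -> bool:
        base = Path(base_dir)
        return all(_sha256(base / rel) == digest
                   for rel, digest in self.files.items())


def write_manifest(out_dir, config_hash: str, files) -> Manifest:
    """Inventory every output file of a run with checksums."""
    from . import __version__
    out_dir = Path(out_dir)
    man = Manifest(run_id=uuid.uuid4().hex[:12], config_hash=config_hash,
                   files={str(Path(f).relative_to(out_dir)): _sha256(Path(f))
                          for f in files},
                   package_version=__version__,
                   created=time.strftime("%Y-%m-%dT%H:%M:%S"))
    (out_dir / "manifest.json").write_text(
        json.dumps(man.__dict__, indent=2))
    return man
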