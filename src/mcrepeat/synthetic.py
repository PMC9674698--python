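"""Synthetic ordinal-severity test-retest image benchmark.

Emulates the structure of severity-graded medical image datasets without
any download: each patient has a continuous latent disease severity
``s in [0, k-1]`` that is binned into k ordinal classes, with label noise
concentrated at class boundaries (inter-rater-style disagreement), and
>= 2 images per patient-visit that differ only by benign acquisition
jitter (horizontal flip, small rotation, brightness, sub-pixel
translation). Images are 32x32 grayscale textures carrying lesion-like
Gaussian blobs whose number and contrast grow with severity, so a small
CNN can recover ``s`` while the boundary noise keeps decisions genuinely
ambiguous near the cuts — the regime in which test-time MC dropout helps.

Two retest variants mirror common evaluation settings: ``flip_retest_mode``
pairs each image with its horizontal mirror (a knee-radiograph-style
emulated retest), and ``domain_shift`` pushes the retest views outside the
training augmentation family (an unseen-view setting).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "JitterSpec",
    "GeneratorConfig",
    "SyntheticDataset",
    "load_dataset",
    "render",
    "assign_label",
    "generate_dataset",
]

#: training augmentation bounds; domain-shift retest transforms must exceed these
TRAIN_AUG_ROTATION = 15.0
TRAIN_AUG_BRIGHTNESS = (0.85, 1.15)


@dataclass(frozen=True)
class JitterSpec:
    """Benign acquisition jitter applied independently to each view."""

    flip_prob: float = 0.5
    rotation_deg: float = 10.0
    brightness: tuple[float, float] = (0.92, 1.08)
    translate_px: int = 2

    def __post_init__(self) -> None:
        if self.rotation_deg > TRAIN_AUG_ROTATION:
            raise ValueError(f"view rotation {self.rotation_deg} exceeds the "
                             f"training augmentation bound {TRAIN_AUG_ROTATION}")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be in [0, 1]")

    @property
    def is_zero(self) -> bool:
        return (self.flip_prob == 0 and self.rotation_deg == 0
                and self.brightness == (1.0, 1.0) and self.translate_px == 0)


ZERO_JITTER = JitterSpec(flip_prob=0.0, rotation_deg=0.0, brightness=(1.0, 1.0), translate_px=0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic benchmark dataset."""

    n_patients: int = 300
    k: int = 3
    class_probs: tuple[float, ...] | None = None  # default: uniform
    images_per_patient: int = 2
    image_size: int = 32
    boundary_noise_sd: float = 0.25
    jitter: JitterSpec = field(default_factory=JitterSpec)
    domain_shift: bool = False
    flip_retest_mode: bool = False
    split_fractions: tuple[float, float, float] = (0.65, 0.10, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.images_per_patient < 2:
            raise ValueError("images_per_patient must be >= 2")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.boundary_noise_sd < 0:
            raise ValueError("boundary_noise_sd must be >= 0")
        probs = self.resolved_class_probs
        if len(probs) != self.k or abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
            raise ValueError("class_probs must be a length-k simplex vector")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split_fractions must sum to 1")

    @property
    def resolved_class_probs(self) -> tuple[float, ...]:
        if self.class_probs is None:
            return tuple([1.0 / self.k] * self.k)
        return tuple(self.class_probs)


@dataclass
class SyntheticDataset:
    """In-memory dataset: images (n, 1, H, W) in [0, 1] plus a manifest.

    Manifest columns: patient_id, image_id, view_index, split, label,
    latent_s. Row order matches the leading axis of ``images``.
    """

    images: np.ndarray
    manifest: pd.DataFrame
    config: GeneratorConfig

    def split(self, name: str) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
        """(images, labels, manifest rows) for one of train/val/test."""
        m = self.manifest[self.manifest["split"] == name]
        return self.images[m.index.to_numpy()], m["label"].to_numpy(), m.reset_index(drop=True)

    def write(self, out_dir: str | Path) -> Path:
        """Write PNG images and the CSV manifest to ``out_dir``."""
        from PIL import Image

        out = Path(out_dir)
        img_dir = out / "images"
        img_dir.mkdir(parents=True, exist_ok=True)
        for row, img in zip(self.manifest.itertuples(), self.images):
            arr = np.clip(img[0] * 255.0, 0, 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(img_dir / f"{row.image_id}.png")
        manifest = self.manifest.copy()
        manifest["path"] = ["images/" + i + ".png" for i in manifest["image_id"]]
        manifest.to_csv(out / "manifest.csv", index=False)
        return out / "manifest.csv"


def load_dataset(manifest_csv: str | Path, config: GeneratorConfig | None = None) -> SyntheticDataset:
    """Load a dataset previously written with :meth:`SyntheticDataset.write`."""
    from PIL import Image

    path = Path(manifest_csv)
    manifest = pd.read_csv(path, dtype={"patient_id": str, "image_id": str})
    root = path.parent
    imgs = []
    for rel in manifest["path"]:
        arr = np.asarray(Image.open(root / rel), dtype=np.float32) / 255.0
        imgs.append(arr[None])
    images = np.stack(imgs)
    manifest = manifest.drop(columns=["path"])
    if config is None:
        k = int(manifest["label"].max()) + 1
        size = images.shape[-1]
        n_pat = manifest["patient_id"].nunique()
        views = len(manifest) // n_pat
        config = GeneratorConfig(n_patients=n_pat, k=max(k, 2), images_per_patient=max(views, 2),
                                 image_size=size)
    return SyntheticDataset(images=images, manifest=manifest, config=config)


def render(s: float, rng: np.random.Generator, size: int = 32) -> np.ndarray:
    """Render one grayscale image for latent severity ``s``.

    The image is a noisy low-intensity texture plus ``round(3 s)`` (in
    expectation-preserving Poisson-jittered number) lesion-like Gaussian
    blobs whose amplitude also grows with s, so total lesion area and
    contrast are strictly increasing in expectation with severity;
    ``s = 0`` renders a lesion-free texture. Deterministic given the rng
    state.
    """
    if s < 0:
        raise ValueError("severity must be >= 0")
    img = 0.25 + 0.06 * rng.standard_normal((size, size))
    # deterministic mean count round(3s) plus Poisson jitter of +/- a blob
    n_blobs = int(round(3.0 * s))
    if s > 0:
        n_blobs = max(1, n_blobs + int(rng.integers(-1, 2)))
    yy, xx = np.mgrid[0:size, 0:size]
    amp = 0.35 + 0.10 * s
    for _ in range(n_blobs):
        cy, cx = rng.uniform(4, size - 4, size=2)
        sigma = rng.uniform(1.3, 2.4)
        img += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
    return np.clip(img, 0.0, 1.0)


def assign_label(s: float, k: int, boundary_noise_sd: float, rng: np.random.Generator) -> int:
    """Ordinal label: nearest-integer bin of ``s + eps``, clipped to 0..k-1.

    ``eps ~ Normal(0, boundary_noise_sd)`` models inter-rater noise: a
    severity exactly on a class boundary is labeled either adjacent class
    with probability ~1/2, and the flip probability decays with the
    Gaussian tail as s moves away from the boundary. ``sd = 0`` is exact
    binning.
    """
    eps = rng.normal(0.0, boundary_noise_sd) if boundary_noise_sd > 0 else 0.0
    return int(np.clip(np.rint(s + eps), 0, k - 1))


def _jitter_view(base: np.ndarray, jit: JitterSpec, rng: np.random.Generator) -> np.ndarray:
    img = base
    if jit.flip_prob > 0 and rng.random() < jit.flip_prob:
        img = img[:, ::-1]
    if jit.rotation_deg > 0:
        angle = rng.uniform(-jit.rotation_deg, jit.rotation_deg)
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="nearest")
    if jit.translate_px > 0:
        dy, dx = rng.integers(-jit.translate_px, jit.translate_px + 1, size=2)
        img = np.roll(np.roll(img, dy, axis=0), dx, axis=1)
    bl, bh = jit.brightness
    if (bl, bh) != (1.0, 1.0):
        img = img * rng.uniform(bl, bh)
    return np.clip(img, 0.0, 1.0)


#: retest transform used in domain-shift mode: rotation and brightness
#: chosen OUTSIDE the training augmentation family
DOMAIN_SHIFT_ROTATION = 25.0
DOMAIN_SHIFT_BRIGHTNESS = 0.75

assert DOMAIN_SHIFT_ROTATION > TRAIN_AUG_ROTATION
assert DOMAIN_SHIFT_BRIGHTNESS < TRAIN_AUG_BRIGHTNESS[0]


def _domain_shift_view(base: np.ndarray) -> np.ndarray:
    img = ndimage.rotate(base, DOMAIN_SHIFT_ROTATION, reshape=False, order=1, mode="nearest")
    return np.clip(img * DOMAIN_SHIFT_BRIGHTNESS, 0.0, 1.0)


def _stratified_split(labels: np.ndarray, fractions: tuple[float, float, float],
                      rng: np.random.Generator) -> np.ndarray:
    """Patient-level split preserving class proportions within +/-1 patient
    per class (largest-remainder allocation)."""
    names = np.array(["train", "val", "test"])
    out = np.empty(labels.size, dtype=object)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n = idx.size
        quota = np.array([f * n for f in fractions])
        counts = np.floor(quota).astype(int)
        rem = quota - counts
        for _ in range(n - counts.sum()):
            j = int(np.argmax(rem))
            counts[j] += 1
            rem[j] = -1
        start = 0
        for name, c in zip(names, counts):
            out[idx[start : start + c]] = name
            start += c
    return out


def generate_dataset(cfg: GeneratorConfig, out_dir: str | Path | None = None) -> SyntheticDataset:
    """Generate a full test-retest benchmark dataset.

    Per patient: a class is drawn from ``class_probs`` and a latent
    severity uniformly within that class's unit bin (clipped to
    [0, k-1]); the observed label applies boundary noise on top of the
    latent severity; a base image is rendered once and each of the
    ``images_per_patient`` views is an independently jittered copy of it
    (so zero jitter gives pixel-identical views). ``flip_retest_mode``
    instead pairs the base image with its horizontal mirror;
    ``domain_shift`` replaces the jitter of all retest views (view index
    >= 1) with a fixed out-of-training-family transform. Patients are
    split train/val/test preserving class proportions. Same seed, same
    bytes.
    """
    rng = np.random.default_rng(cfg.seed)
    probs = np.asarray(cfg.resolved_class_probs)
    size = cfg.image_size
    n_views = 2 if cfg.flip_retest_mode else cfg.images_per_patient

    images = np.empty((cfg.n_patients * n_views, 1, size, size), dtype=np.float32)
    rows = []
    labels = np.empty(cfg.n_patients, dtype=int)
    width = len(str(cfg.n_patients - 1))
    for i in range(cfg.n_patients):
        cls = int(rng.choice(cfg.k, p=probs))
        s = float(np.clip(rng.uniform(cls - 0.5, cls + 0.5), 0.0, cfg.k - 1))
        label = assign_label(s, cfg.k, cfg.boundary_noise_sd, rng)
        labels[i] = label
        base = render(s, rng, size)
        pid = f"P{i:0{width}d}"
        for v in range(n_views):
            if cfg.flip_retest_mode:
                view = base if v == 0 else base[:, ::-1].copy()
            elif cfg.domain_shift and v >= 1:
                view = _domain_shift_view(base)
            else:
                view = _jitter_view(base, cfg.jitter, rng)
            images[i * n_views + v, 0] = view
            rows.append({"patient_id": pid, "image_id": f"{pid}_v{v}", "view_index": v,
                         "label": label, "latent_s": s})

    splits = _stratified_split(labels, cfg.split_fractions, rng)
    manifest = pd.DataFrame(rows)
    manifest["split"] = np.repeat(splits, n_views)
    manifest = manifest[["patient_id", "image_id", "view_index", "split", "label", "latent_s"]]
    ds = SyntheticDataset(images=images, manifest=manifest, config=cfg)
    if out_dir is not None:
        ds.write(out_dir)
    return ds
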