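"""Synthetic sonographic phantoms for end-to-end testing without clinical data.

Each case is an 8-bit speckle image with a convex-polygon lesion ROI.  The
two classes emulate the sonographic contrast the classifier exploits:

* *tendinopathy* — relatively hyperechoic (bright), fibrillar and
  heterogeneous: a bright mean field modulated by oblique sinusoidal bands
  plus a few random hypoechoic patches;
* *tear* — hypoechoic (dark) and uniform, with a focal anechoic core
  covering a fraction of the lesion.

Pixels are ``clip(round(mu(r, c) * S(r, c)))`` where ``S`` is a
Gaussian-smoothed multiplicative gamma speckle field with unit mean — a
desk-scale stand-in for ultrasound speckle, with no beamforming physics.
Default class means (117 vs 43) anchor the echogenicity contrast between
the two lesion types; the structural terms are kept modest so that
echogenicity separation dominates class separability.

All randomness flows from one integer seed; case ``k`` uses the
substream ``default_rng([seed, k])``, so any single case can be
regenerated bit-exactly in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io import LABELS, CaseRecord, rasterize_polygon, write_gray_image


@dataclass(frozen=True)
class PhantomConfig:
    """Generator settings; the defaults define the reference study conditions."""

    dims: tuple = (128, 128)
    n_per_class: int = 50
    tendinopathy_mean: float = 117.0  # echogenicity anchors for the two classes
    tear_mean: float = 43.0
    band_amplitude: float = 25.0  # fibrillar heterogeneity of tendinopathy
    band_period: float = 16.0  # pixels
    core_fraction: float = 0.10  # area fraction of the anechoic tear core
    core_level: float = 15.0
    speckle_shape: float = 4.0  # gamma shape k of the multiplicative speckle
    psf_sigma: float = 1.0  # Gaussian smoothing scale of the speckle
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.tendinopathy_mean <= 255 and 0 <= self.tear_mean <= 255):
            raise ValueError("class means must lie in [0, 255]")
        if self.speckle_shape <= 0:
            raise ValueError("gamma shape must be positive")


def speckle_field(dims, shape_k: float, psf_sigma: float, rng) -> np.ndarray:
    """Unit-mean multiplicative speckle: smoothed gamma noise."""
    s = rng.gamma(shape=shape_k, scale=1.0 / shape_k, size=dims)
    if psf_sigma > 0:
        s = gaussian_filter(s, psf_sigma, mode="nearest")
    return s


def _random_convex_roi(dims, rng, area_range=(0.2, 0.6)) -> np.ndarray:
    """Vertices of a random convex polygon covering 20-60% of the frame."""
    h, w = dims
    target = rng.uniform(*area_range) * h * w
    center = np.array([h / 2, w / 2]) + rng.uniform(-0.08, 0.08, 2) * (h, w)
    pts = center + rng.normal(scale=(h / 4, w / 4), size=(24, 2))
    # convex hull by angular sort of the hull of sampled points
    from scipy.spatial import ConvexHull

    hull = ConvexHull(pts)
    verts = pts[hull.vertices]
    # rescale about the centroid so the hull area matches the target,
    # then clamp into the frame (clamping may shave a little area)
    hull_area = hull.volume  # 2-D hull: "volume" is the area
    verts = center + (verts - center) * np.sqrt(target / hull_area)
    verts[:, 0] = np.clip(verts[:, 0], 0, h - 1)
    verts[:, 1] = np.clip(verts[:, 1], 0, w - 1)
    return verts


def _tendinopathy_mu(cfg: PhantomConfig, dims, rng) -> np.ndarray:
    h, w = dims
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    # oblique fibrillar banding
    tilt = rng.uniform(-0.35, 0.35)
    phase = rng.uniform(0, 2 * np.pi)
    mu = cfg.tendinopathy_mean + cfg.band_amplitude * np.sin(
        2 * np.pi * (rr + tilt * cc) / cfg.band_period + phase
    )
    # a few random hypoechoic patches (loss of homogeneous texture); their
    # depth scales with the heterogeneity knob so band_amplitude = 0 is the
    # noise-free limit
    for _ in range(rng.integers(1, 3)):
        pr, pc = rng.uniform(0, h), rng.uniform(0, w)
        sig = rng.uniform(6, 12)
        depth = cfg.band_amplitude * rng.uniform(0.4, 1.2)
        mu -= depth * np.exp(-(((rr - pr) ** 2 + (cc - pc) ** 2) / (2 * sig**2)))
    return mu


def _tear_mu(cfg: PhantomConfig, dims, mask: np.ndarray, rng) -> np.ndarray:
    h, w = dims
    mu = np.full(dims, cfg.tear_mean)
    if cfg.core_fraction <= 0:
        return mu
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    rows, cols = np.nonzero(mask)
    k = rng.integers(len(rows))
    pr, pc = rows[k], cols[k]
    # disk with the same area as core_fraction of the lesion
    radius = np.sqrt(cfg.core_fraction * mask.sum() / np.pi)
    core = (rr - pr) ** 2 + (cc - pc) ** 2 <= radius**2
    mu[core] = cfg.core_level
    return mu


def generate_case(label: str, cfg: PhantomConfig, rng, case_id: str = "case",
                  patient_id: str | None = None) -> CaseRecord:
    """One labelled phantom case drawn from the given random stream."""
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}")
    dims = tuple(cfg.dims)
    verts = _random_convex_roi(dims, rng)
    mask = rasterize_polygon(verts, dims)
    if label == "tendinopathy":
        mu = _tendinopathy_mu(cfg, dims, rng)
    else:
        mu = _tear_mu(cfg, dims, mask, rng)
    s = speckle_field(dims, cfg.speckle_shape, cfg.psf_sigma, rng)
    pixels = np.clip(np.rint(mu * s), 0, 255).astype(np.uint8)
    return CaseRecord(
        case_id=case_id,
        patient_id=patient_id if patient_id is not None else case_id,
        image=pixels,
        mask=mask,
        label=label,
    )


def generate_dataset(cfg: PhantomConfig) -> tuple[list[CaseRecord], pd.DataFrame]:
    """A full labelled dataset plus its manifest (n_per_class cases per class).

    Case ``k`` (over the concatenated class lists) is generated from the
    substream ``default_rng([seed, k])``, so the dataset is bit-exactly
    reproducible from the config alone.
    """
    records = []
    rows = []
    index = 0
    for label in LABELS:
        for k in range(cfg.n_per_class):
            case_id = f"{label[:4]}_{k:03d}"
            rng = np.random.default_rng([cfg.seed, index])
            rec = generate_case(label, cfg, rng, case_id=case_id)
            records.append(rec)
            rows.append(
                {
                    "case_id": case_id,
                    "patient_id": rec.patient_id,
                    "image_file": f"{case_id}.png",
                    "roi_file": f"{case_id}_mask.png",
                    "label": label,
                }
            )
            index += 1
    return records, pd.DataFrame(rows)


def write_dataset(records, manifest: pd.DataFrame, out_dir) -> Path:
    """Write images, masks and the manifest CSV in the package's I/O formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec, row in zip(records, manifest.itertuples(index=False)):
        write_gray_image(out / row.image_file, rec.image)
        write_gray_image(out / row.roi_file, rec.mask.astype(np.uint8) * 255)
    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def config_with_separation(cfg: PhantomConfig, separation: float) -> PhantomConfig:
    """Same config with the tear mean moved to ``tendinopathy_mean - separation``."""
    return replace(cfg, tear_mean=float(np.clip(cfg.tendinopathy_mean - separation, 0, 255)))
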