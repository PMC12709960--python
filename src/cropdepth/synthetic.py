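"""Seeded synthetic crop scenes for exercising the depth pipeline.

A scene emulates the structure of a monocular-depth-model output for a
top-down crop photo: a background ground plane at a low depth intensity,
crops as smooth raised blobs of positive depth contrast, an optional
separable additive background gradient (the in-field "background drop-off"
failure mode of bimodal thresholding), and additive Gaussian pixel noise.
Depth values are kept real in memory and quantized only when written.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import imgio
from .errors import ParameterError

__all__ = ["SceneSpec", "Scene", "generate_scene", "generate_batch"]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic crop scene.

    ``blob_height`` is the crop-over-background depth contrast at the blob
    plateau; ``row_slope``/``col_slope`` add ``slope * index`` to the
    background, emulating the depth drop-off of oblique in-field shots;
    ``coverage`` optionally requests a ground-truth crop fraction (met
    within +/- 0.05 by re-sampling blob placements).
    """

    height: int = 192
    width: int = 192
    n_blobs: int = 4
    radius_range: tuple[float, float] = (16.0, 28.0)
    shoulder: float = 1.0
    blob_height: float = 90.0
    background: float = 40.0
    row_slope: float = 0.0
    col_slope: float = 0.0
    noise_sigma: float = 1.5
    coverage: float | None = None
    seed: int = 0

    def validate(self) -> "SceneSpec":
        if self.height < 3 or self.width < 3:
            raise ParameterError("scene must be at least 3x3")
        if self.n_blobs < 0:
            raise ParameterError("n_blobs must be >= 0")
        if self.radius_range[0] > self.radius_range[1] or self.radius_range[0] <= 0:
            raise ParameterError("need 0 < radius_min <= radius_max")
        if not 0 < self.blob_height <= 255:
            raise ParameterError("blob_height must be in (0, 255]")
        if not 0 <= self.background < 255:
            raise ParameterError("background must be in [0, 255)")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if self.coverage is not None and not 0 < self.coverage < 1:
            raise ParameterError("coverage target must be in (0, 1)")
        bias_lo = min(self.row_slope * (self.height - 1), 0) + min(
            self.col_slope * (self.width - 1), 0
        )
        bias_hi = max(self.row_slope * (self.height - 1), 0) + max(
            self.col_slope * (self.width - 1), 0
        )
        if self.background + bias_lo < 0 or self.background + bias_hi + self.blob_height > 255:
            raise ParameterError(
                "background + bias extremes + blob_height must stay within [0, 255]"
            )
        return self

    @classmethod
    def biased(cls, **overrides) -> "SceneSpec":
        """In-field condition: strong separable background drop-off.

        The background gradient spans roughly the same intensity range as
        the crop contrast, the regime where plain bimodal thresholding
        splits the background instead of the crops.
        """
        base = dict(background=20.0, blob_height=80.0, row_slope=0.45, col_slope=0.1)
        base.update(overrides)
        return cls(**base)


@dataclass
class Scene:
    """One generated scene: depth map, ground-truth mask, cosmetic RGB."""

    depth: np.ndarray
    mask: np.ndarray
    rgb: np.ndarray
    spec: SceneSpec


def _blob_profile(
    shape: tuple[int, int], centers: np.ndarray, radii: np.ndarray, shoulder: float
) -> tuple[np.ndarray, np.ndarray]:
    """Raised plateaus with smooth cosine shoulders; support is the full disc."""
    h, w = shape
    ii, jj = np.mgrid[0:h, 0:w]
    profile = np.zeros(shape, dtype=float)
    for (ci, cj), r in zip(centers, radii):
        dist = np.hypot(ii - ci, jj - cj)
        plateau = dist <= r - shoulder
        ramp = (dist > r - shoulder) & (dist <= r)
        local = np.zeros(shape)
        local[plateau] = 1.0
        if shoulder > 0:
            local[ramp] = 0.5 * (1 + np.cos(np.pi * (dist[ramp] - (r - shoulder)) / shoulder))
        profile = np.maximum(profile, local)
    mask = (profile > 0).astype(np.uint8)
    return profile, mask


def _place_blobs(spec: SceneSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    margin = spec.radius_range[1] + 1
    ci = rng.uniform(margin, spec.height - margin, size=spec.n_blobs)
    cj = rng.uniform(margin, spec.width - margin, size=spec.n_blobs)
    radii = rng.uniform(*spec.radius_range, size=spec.n_blobs)
    return np.column_stack([ci, cj]), radii


def generate_scene(spec: SceneSpec) -> Scene:
    """Generate one scene deterministically from its spec (seed included).

    depth = clip(background + row_slope*i + col_slope*j + blob_height*profile
    + noise, 0, 255); the ground-truth mask is the union of blob supports.
    """
    spec = spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)

    if spec.n_blobs == 0:
        profile = np.zeros(shape)
        mask = np.zeros(shape, dtype=np.uint8)
    else:
        profile, mask = _blob_profile(
            shape, *_place_blobs(spec, rng), spec.shoulder
        )
        if spec.coverage is not None:
            want = spec.n_blobs
            for _ in range(200):
                cov = mask.mean()
                if abs(cov - spec.coverage) <= 0.05:
                    break
                # Boolean-model update: coverage ~ 1 - exp(-n * area / HW),
                # so rescale the blob count on the lambda scale
                cov_c = min(max(cov, 1e-3), 0.999)
                factor = np.log1p(-spec.coverage) / np.log1p(-cov_c)
                want = int(np.clip(round(want * factor), 1, 2000))
                profile, mask = _blob_profile(
                    shape,
                    *_place_blobs(replace(spec, n_blobs=want), rng),
                    spec.shoulder,
                )
            else:
                raise ParameterError(
                    f"could not reach coverage {spec.coverage} within 200 placements"
                )

    ii, jj = np.mgrid[0 : spec.height, 0 : spec.width]
    depth = (
        spec.background
        + spec.row_slope * ii
        + spec.col_slope * jj
        + spec.blob_height * profile
    )
    if spec.noise_sigma > 0:
        depth = depth + rng.normal(0.0, spec.noise_sigma, size=shape)
    depth = depth.clip(0, 255)

    # cosmetic RGB: green-ish crops on brown-ish ground
    rgb = np.empty((*shape, 3), dtype=np.uint8)
    rgb[..., 0], rgb[..., 1], rgb[..., 2] = 120, 90, 60
    fg = mask == 1
    rgb[fg] = (40, 160, 60)
    return Scene(depth=depth, mask=mask, rgb=rgb, spec=spec)


def generate_batch(
    template: SceneSpec,
    n: int,
    base_seed: int,
    outdir: str | Path | None = None,
) -> tuple[list[Scene], imgio.DatasetManifest]:
    """Generate n scenes with seeds base_seed..base_seed+n-1.

    When ``outdir`` is given, depth/mask/RGB PNGs and a CSV manifest are
    written there; otherwise the manifest holds relative names only.
    """
    if n < 1:
        raise ParameterError(f"batch size must be >= 1, got {n}")
    scenes = [generate_scene(replace(template, seed=base_seed + k)) for k in range(n)]
    records = []
    for k, scene in enumerate(scenes):
        sid = f"scene{k:04d}"
        records.append(
            imgio.ManifestRecord(
                id=sid,
                depth=f"{sid}_depth.png",
                rgb=f"{sid}_rgb.png",
                mask=f"{sid}_gt.png",
                scenario="in-field",
            )
        )
    manifest = imgio.DatasetManifest(records=records)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest.root = outdir
        for scene, rec in zip(scenes, manifest):
            imgio.write_depth(scene.depth, outdir / rec.depth)
            imgio.write_rgb(scene.rgb, outdir / rec.rgb)
            imgio.write_mask(scene.mask, outdir / rec.mask)
        manifest.save(outdir / "manifest.csv")
    return scenes, manifest
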