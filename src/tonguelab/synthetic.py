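"""Synthetic post-segmentation tongue images with known class structure.

The clinical corpus behind the method is not public, so every stage is
exercised on generated images that reproduce the structure the method
relies on:

* an elliptical tongue on an exact-black background (segmentation has
  already happened; (0, 0, 0) is reserved for non-tongue pixels);
* a class-conditional body colour — light-red and red body means sit
  inside their respective colour-range boxes ((62, 25, 17) and
  (50, 35, 8)); the deep-red mean (35, 20, 2) is darker and less
  chromatic, i.e. nearer Lab black, which is exactly the property the
  max-distance identifier exploits;
* a more-chromatic accent band at the tip and bilateral edges (a* + 4
  relative to the body), giving the image genuine multi-cluster colour
  structure so k = 4 clustering is non-degenerate;
* a transitional rim between tongue and background (body colour scaled
  towards black), the fourth natural cluster;
* i.i.d. Gaussian pixel noise added in Lab (default sd 2.0 — noise
  effects stay interpretable against the colour-range box widths of
  4-7 Lab units), then 8-bit sRGB quantisation (<= 1 RGB unit extra
  rounding error).

Not emulated: papillae/coating texture, specular highlights and
illumination gradients — the acquisition box provides stable, colour-
corrected lighting, and the classifier consumes only cluster-level
colour summaries, so the generator targets colour structure, not
photorealism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .colorspace import lab_to_rgb
from .labels import TongueColor

__all__ = ["GeneratorParams", "SyntheticImage", "Corpus", "make_tongue_image", "make_corpus"]

REGIONS = ("background", "body", "accent", "transitional")


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the tongue-image generator.

    Geometry is sampled per image: semi-axes as fractions of the image
    size and a small centre jitter.  ``accent_shift`` is added to the
    body mean inside the accent band; the transitional rim colour is
    the body mean scaled by ``transitional_scale`` towards black.
    ``noise_sd`` is the per-channel Gaussian sd in Lab units.
    """

    height: int = 256
    width: int = 256
    semi_axis_x: tuple[float, float] = (0.30, 0.38)  # fraction of width
    semi_axis_y: tuple[float, float] = (0.38, 0.46)  # fraction of height
    center_jitter: float = 0.04  # fraction of image size
    class_means: dict = field(
        default_factory=lambda: {
            TongueColor.LIGHT_RED: (62.0, 25.0, 17.0),
            TongueColor.RED: (50.0, 35.0, 8.0),
            TongueColor.DEEP_RED: (35.0, 20.0, 2.0),
        }
    )
    accent_shift: tuple[float, float, float] = (0.0, 4.0, 0.0)
    transitional_scale: float = 0.6
    transitional_rim: float = 0.82  # normalised squared radius where the rim starts
    accent_tip_frac: float = 0.55  # tip accent beyond this fraction of the lower semi-axis
    accent_edge_frac: float = 0.78  # edge accent beyond this fraction of the x semi-axis
    noise_sd: float = 2.0
    mixture: dict = field(
        default_factory=lambda: {
            TongueColor.LIGHT_RED: 1 / 3,
            TongueColor.RED: 1 / 3,
            TongueColor.DEEP_RED: 1 / 3,
        }
    )


@dataclass(frozen=True)
class SyntheticImage:
    rgb: np.ndarray
    label: TongueColor
    #: region name -> boolean mask; the four masks partition the image.
    masks: dict
    seed: int

    @property
    def background_mask(self) -> np.ndarray:
        return self.masks["background"]


@dataclass(frozen=True)
class Corpus:
    images: list[SyntheticImage]
    manifest: pd.DataFrame
    params: GeneratorParams
    seed: int

    @property
    def labels(self) -> list[TongueColor]:
        return [im.label for im in self.images]


def _region_masks(params: GeneratorParams, rng: np.random.Generator):
    h, w = params.height, params.width
    cy = h / 2 + rng.uniform(-1, 1) * params.center_jitter * h
    cx = w / 2 + rng.uniform(-1, 1) * params.center_jitter * w
    ay = rng.uniform(*params.semi_axis_y) * h
    ax = rng.uniform(*params.semi_axis_x) * w

    yy, xx = np.mgrid[0:h, 0:w]
    xn = (xx - cx) / ax
    yn = (yy - cy) / ay
    r2 = xn**2 + yn**2

    inside = r2 <= 1.0
    transitional = inside & (r2 > params.transitional_rim)
    inner = inside & ~transitional
    # Tip = lower part of the ellipse (the tongue tip points down);
    # edges = bilateral margins of the inner region.
    accent = inner & (
        (yn > params.accent_tip_frac) | (np.abs(xn) > params.accent_edge_frac)
    )
    body = inner & ~accent
    background = ~inside
    return {
        "background": background,
        "body": body,
        "accent": accent,
        "transitional": transitional,
    }


def make_tongue_image(
    cls: TongueColor, params: GeneratorParams | None = None, seed: int = 0
) -> SyntheticImage:
    """Generate one labelled tongue image; deterministic per seed."""
    params = params or GeneratorParams()
    cls = TongueColor(cls)
    if cls not in params.class_means:
        raise ValueError(f"no colour distribution configured for class {cls}")
    rng = np.random.default_rng(seed)
    masks = _region_masks(params, rng)

    body_mean = np.asarray(params.class_means[cls], dtype=np.float64)
    region_means = {
        "body": body_mean,
        "accent": body_mean + np.asarray(params.accent_shift),
        "transitional": body_mean * params.transitional_scale,
    }

    lab = np.zeros((params.height, params.width, 3))
    for name, mean in region_means.items():
        m = masks[name]
        n = int(m.sum())
        if n == 0:
            continue
        lab[m] = mean + rng.normal(0.0, params.noise_sd, size=(n, 3))

    foreground = ~masks["background"]
    lab[foreground, 0] = np.clip(lab[foreground, 0], 0.5, 100.0)

    rgb = lab_to_rgb(lab)
    rgb[masks["background"]] = 0
    # (0,0,0) is the background sentinel; nudge any foreground pixel
    # that quantised to exact black.
    collided = foreground & np.all(rgb == 0, axis=-1)
    rgb[collided] = 1
    return SyntheticImage(rgb=rgb, label=cls, masks=masks, seed=seed)


def _class_counts(n: int, mixture: dict) -> dict:
    """Largest-remainder apportionment of n images to classes."""
    classes = [c for c in TongueColor if mixture.get(c, 0.0) > 0]
    total = sum(mixture[c] for c in classes)
    quotas = {c: n * mixture[c] / total for c in classes}
    counts = {c: int(np.floor(quotas[c])) for c in classes}
    remainder = n - sum(counts.values())
    by_frac = sorted(classes, key=lambda c: (-(quotas[c] - counts[c]), c.value))
    for c in by_frac[:remainder]:
        counts[c] += 1
    return counts


def make_corpus(
    n: int, params: GeneratorParams | None = None, seed: int = 0
) -> Corpus:
    """Generate a labelled corpus of n images.

    Class counts follow the mixture by largest-remainder rounding;
    per-image seeds derive from the corpus seed, and image order is a
    deterministic shuffle so folds of any split mix the classes.
    """
    params = params or GeneratorParams()
    counts = _class_counts(n, params.mixture)
    if n < len(counts):
        raise ValueError(
            f"n={n} is smaller than the number of classes with nonzero weight"
        )

    labels: list[TongueColor] = []
    for c in TongueColor:
        labels.extend([c] * counts.get(c, 0))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0]))
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]

    image_seeds = np.random.SeedSequence(seed).generate_state(n).astype(np.int64)
    images = [
        make_tongue_image(lab, params, seed=int(s))
        for lab, s in zip(labels, image_seeds)
    ]
    manifest = pd.DataFrame(
        {
            "image_id": [f"synthetic_{i:04d}" for i in range(n)],
            "label": [str(lab) for lab in labels],
            "seed": image_seeds,
        }
    )
    return Corpus(images=images, manifest=manifest, params=params, seed=seed)


def write_corpus(corpus: Corpus, out_dir: str | Path, masks: bool = False) -> Path:
    """Write PNGs + manifest CSV (and optionally ground-truth masks)."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for img, image_id in zip(corpus.images, corpus.manifest["image_id"]):
        p = out / f"{image_id}.png"
        Image.fromarray(img.rgb).save(p)
        paths.append(p.name)
        if masks:
            for name, m in img.masks.items():
                Image.fromarray((m * 255).astype(np.uint8)).save(
                    out / f"{image_id}_mask_{name}.png"
                )
    manifest = corpus.manifest.copy()
    manifest.insert(0, "path", paths)
    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path
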