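"""Factorial face stimulus set.

Builds the 64-item face bank used throughout the simulations: every face is
one of 4 eye types x 4 nose types x 4 lip types.  Each facial feature carries
two verbal labels (eyes: drooping/slanted, noses: long/button, lips:
thick/downturned) and each label covers two subordinate glyph variants (big /
small), so a verbal label triple is shared by exactly 2 x 2 x 2 = 8 faces.

Per item three representations are produced:

* a 70 x 60 binary image (1 = black) — the target of the visual image layer,
* a Gaussian-smoothed copy in [0, 1] — the retinotopic input,
* a 6-bit localist verbal vector with exactly one active unit per label pair.

Half of the items (32) are marked as trained ("old"); the rest are the
untrained ("new") generalization faces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "IMAGE_SHAPE",
    "N_PIXELS",
    "N_ITEMS",
    "VERBAL_UNIT_NAMES",
    "DEFAULT_SMOOTHING_SD",
    "FaceSpec",
    "GlyphBank",
    "GlyphConfigError",
    "StimulusSet",
    "default_glyph_bank",
    "enumerate_face_specs",
    "render_face_image",
    "make_retinotopic_input",
    "verbal_vector",
    "build_stimulus_set",
    "subset_stimulus_set",
]

IMAGE_SHAPE = (70, 60)  # rows x columns
N_PIXELS = IMAGE_SHAPE[0] * IMAGE_SHAPE[1]  # 4200
N_ITEMS = 64
N_TRAINED = 32

#: localist verbal unit order; one unit per label, one active per feature pair
VERBAL_UNIT_NAMES = ("drooping", "slanted", "long", "button", "thick", "downturned")

#: width (pixels) of the Gaussian used to degrade images into retinotopic input
DEFAULT_SMOOTHING_SD = 0.2

# feature regions on the canvas, half-open row ranges, full width
EYE_ROWS = (10, 29)
NOSE_ROWS = (30, 47)
LIP_ROWS = (48, 63)


class GlyphConfigError(ValueError):
    """Raised when a glyph bank violates the disjoint-region layout."""


@dataclass(frozen=True)
class FaceSpec:
    """One of the 64 factorial faces.

    Subordinate feature types run 0-3; the verbal label of a feature is
    ``type // 2``, so types {0, 1} share one label and {2, 3} the other.
    """

    item_id: int  # 1-based, 1..64
    eye_type: int
    nose_type: int
    lip_type: int

    def __post_init__(self) -> None:
        if not 1 <= self.item_id <= N_ITEMS:
            raise ValueError(f"item_id must be in 1..{N_ITEMS}, got {self.item_id}")
        for name in ("eye_type", "nose_type", "lip_type"):
            v = getattr(self, name)
            if not 0 <= v <= 3:
                raise ValueError(f"{name} must be in 0..3, got {v}")

    @property
    def verbal_labels(self) -> tuple[int, int, int]:
        """(eye, nose, lip) label indices, each 0 or 1."""
        return (self.eye_type // 2, self.nose_type // 2, self.lip_type // 2)


def enumerate_face_specs() -> list[FaceSpec]:
    """All 64 faces in item-id order (eye major, then nose, then lip)."""
    specs = []
    i = 1
    for e in range(4):
        for n in range(4):
            for l in range(4):
                specs.append(FaceSpec(item_id=i, eye_type=e, nose_type=n, lip_type=l))
                i += 1
    return specs


def verbal_vector(spec: FaceSpec) -> np.ndarray:
    """6-bit localist verbal code: one active unit per feature label pair."""
    v = np.zeros(6, dtype=np.uint8)
    e, n, l = spec.verbal_labels
    v[e] = 1
    v[2 + n] = 1
    v[4 + l] = 1
    return v


# ---------------------------------------------------------------------------
# glyph bank
# ---------------------------------------------------------------------------

def _filled_ellipse(shape, center, semi_axes, angle=0.0):
    """Boolean mask of a filled, rotated ellipse on a region canvas."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    r = rr - center[0]
    c = cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * c + sa * r
    v = -sa * c + ca * r
    a_r, a_c = semi_axes
    return (u / a_c) ** 2 + (v / a_r) ** 2 <= 1.0


def _frown_arc(shape, center, half_width, depth, half_thickness):
    """Downward-curving parabolic stroke (ends lower than the middle)."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    c = cc - center[1]
    curve = center[0] + depth * (c / half_width) ** 2
    return (np.abs(rr - curve) <= half_thickness) & (np.abs(c) <= half_width)


@dataclass(frozen=True)
class GlyphBank:
    """Binary glyphs for the three features, one region per feature.

    ``eyes``/``noses``/``lips`` hold four glyph arrays each (types 0-3 where
    types 0, 1 are the big/small variants of label 0 and types 2, 3 of
    label 1).  Regions are half-open row ranges on the 70 x 60 canvas and
    must be pairwise disjoint.
    """

    eyes: np.ndarray  # (4, rows, 60) bool
    noses: np.ndarray
    lips: np.ndarray
    eye_rows: tuple[int, int] = EYE_ROWS
    nose_rows: tuple[int, int] = NOSE_ROWS
    lip_rows: tuple[int, int] = LIP_ROWS
    version: str = "ellipse-bank-1"

    def __post_init__(self) -> None:
        regions = [self.eye_rows, self.nose_rows, self.lip_rows]
        arrays = [self.eyes, self.noses, self.lips]
        for (r0, r1), arr in zip(regions, arrays):
            if not (0 <= r0 < r1 <= IMAGE_SHAPE[0]):
                raise GlyphConfigError(f"region rows {r0}:{r1} outside canvas")
            if arr.shape != (4, r1 - r0, IMAGE_SHAPE[1]):
                raise GlyphConfigError(
                    f"glyph array shape {arr.shape} does not match region {r0}:{r1}"
                )
        for i, (a0, a1) in enumerate(zip(regions, regions[1:])):
            if a0[1] > a1[0]:
                raise GlyphConfigError(f"feature regions {a0} and {a1} overlap")


def default_glyph_bank() -> GlyphBank:
    """Parametric stroke glyphs.

    Glyphs sharing a verbal label belong to one shape family (same stroke
    and orientation); the small variant is a concentric shrink of the big
    one, so label-sharing faces overlap heavily in pixels and the
    within-label contrast rests on the outer ring of the big variant.  This
    gives the graded visual-similarity structure the recognition
    simulations rely on: faces sharing a verbal triple are close in pixel
    space, faces sharing no label are far.
    """
    w = IMAGE_SHAPE[1]
    eh = EYE_ROWS[1] - EYE_ROWS[0]
    eyes = np.zeros((4, eh, w), dtype=bool)
    centers = ((9, 16), (9, 44))
    for t in range(4):
        label, small = t // 2, t % 2
        axes = (3.5, 6.0) if small else (5.5, 9.5)
        for k, ctr in enumerate(centers):
            # drooping: outer corner down; slanted: outer corner up
            sign = 1 if k == 0 else -1
            angle = sign * (0.35 if label == 0 else -0.35)
            eyes[t] |= _filled_ellipse((eh, w), ctr, axes, angle)

    nh = NOSE_ROWS[1] - NOSE_ROWS[0]
    noses = np.zeros((4, nh, w), dtype=bool)
    for t in range(4):
        label, small = t // 2, t % 2
        if label == 0:  # long: vertical bar
            axes = (5.5, 1.8) if small else (7.5, 2.5)
        else:  # button: round blob
            axes = (3.0, 3.0) if small else (4.5, 4.5)
        noses[t] = _filled_ellipse((nh, w), (8, 30), axes)

    lh = LIP_ROWS[1] - LIP_ROWS[0]
    lips = np.zeros((4, lh, w), dtype=bool)
    for t in range(4):
        label, small = t // 2, t % 2
        if label == 0:  # thick: filled horizontal ellipse
            axes = (2.5, 9.0) if small else (3.8, 13.0)
            lips[t] = _filled_ellipse((lh, w), (7, 30), axes)
        else:  # downturned: frown arc
            if small:
                lips[t] = _frown_arc((lh, w), (5, 30), 9.0, 3.5, 1.2)
            else:
                lips[t] = _frown_arc((lh, w), (5, 30), 13.0, 5.0, 1.6)
    return GlyphBank(eyes=eyes, noses=noses, lips=lips)


def render_face_image(spec: FaceSpec, glyphs: GlyphBank | None = None) -> np.ndarray:
    """Compose the three feature glyphs on a white canvas.

    Returns a (70, 60) uint8 array, 1 = black pixel.
    """
    if glyphs is None:
        glyphs = default_glyph_bank()
    img = np.zeros(IMAGE_SHAPE, dtype=np.uint8)
    img[glyphs.eye_rows[0] : glyphs.eye_rows[1]] |= glyphs.eyes[spec.eye_type]
    img[glyphs.nose_rows[0] : glyphs.nose_rows[1]] |= glyphs.noses[spec.nose_type]
    img[glyphs.lip_rows[0] : glyphs.lip_rows[1]] |= glyphs.lips[spec.lip_type]
    return img


def make_retinotopic_input(image: np.ndarray, sd: float = DEFAULT_SMOOTHING_SD) -> np.ndarray:
    """Gaussian-degrade a binary image into the retinotopic input.

    2-D convolution with a normalized Gaussian kernel (``sd`` in pixels,
    reflect-padded borders), clipped to [0, 1].  ``sd = 0`` is the identity.
    """
    if sd < 0:
        raise ValueError("smoothing sd must be non-negative")
    smoothed = ndimage.gaussian_filter(image.astype(np.float64), sigma=sd, mode="reflect")
    return np.clip(smoothed, 0.0, 1.0)


# ---------------------------------------------------------------------------
# stimulus set
# ---------------------------------------------------------------------------

@dataclass
class StimulusSet:
    """The full item bank with all three representations per item.

    ``images``/``retinotopic`` are (n_items, 4200) row-major flattenings
    (0-based coordinates); ``verbal`` is (n_items, 6); ``trained_mask`` marks
    the "old" items.
    """

    specs: list[FaceSpec]
    images: np.ndarray  # (n, 4200) uint8
    retinotopic: np.ndarray  # (n, 4200) float64
    verbal: np.ndarray  # (n, 6) uint8
    trained_mask: np.ndarray  # (n,) bool
    rng_seed: int
    smoothing_sd: float = DEFAULT_SMOOTHING_SD
    glyph_version: str = "ellipse-bank-1"

    @property
    def n_items(self) -> int:
        return len(self.specs)

    @property
    def item_ids(self) -> np.ndarray:
        return np.array([s.item_id for s in self.specs])

    @property
    def trained_indices(self) -> np.ndarray:
        return np.flatnonzero(self.trained_mask)

    @property
    def untrained_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.trained_mask)

    def index_of(self, item_id: int) -> int:
        ids = self.item_ids
        hits = np.flatnonzero(ids == item_id)
        if hits.size != 1:
            raise KeyError(f"item_id {item_id} not in set")
        return int(hits[0])

    # -- serialization ------------------------------------------------------

    def save(self, out_dir: str | Path) -> None:
        """Write CSV vectors plus a JSON manifest (lossless round-trip)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        spec_df = pd.DataFrame(
            {
                "item_id": [s.item_id for s in self.specs],
                "eye_type": [s.eye_type for s in self.specs],
                "nose_type": [s.nose_type for s in self.specs],
                "lip_type": [s.lip_type for s in self.specs],
                "trained": self.trained_mask.astype(int),
            }
        )
        spec_df.to_csv(out / "faces.csv", index=False)
        np.savetxt(out / "images.csv", self.images, fmt="%d", delimiter=",")
        np.savetxt(out / "retinotopic.csv", self.retinotopic, fmt="%.17g", delimiter=",")
        np.savetxt(out / "verbal.csv", self.verbal, fmt="%d", delimiter=",")
        manifest = {
            "rng_seed": self.rng_seed,
            "smoothing_sd": self.smoothing_sd,
            "glyph_version": self.glyph_version,
            "image_shape": list(IMAGE_SHAPE),
            "layout": "0-based row-major flattening, pixel value 1 = black",
            "verbal_units": list(VERBAL_UNIT_NAMES),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, in_dir: str | Path) -> "StimulusSet":
        src = Path(in_dir)
        manifest = json.loads((src / "manifest.json").read_text())
        spec_df = pd.read_csv(src / "faces.csv")
        specs = [
            FaceSpec(int(r.item_id), int(r.eye_type), int(r.nose_type), int(r.lip_type))
            for r in spec_df.itertuples()
        ]
        return cls(
            specs=specs,
            images=np.loadtxt(src / "images.csv", dtype=np.uint8, delimiter=",", ndmin=2),
            retinotopic=np.loadtxt(src / "retinotopic.csv", delimiter=",", ndmin=2),
            verbal=np.loadtxt(src / "verbal.csv", dtype=np.uint8, delimiter=",", ndmin=2),
            trained_mask=spec_df["trained"].to_numpy().astype(bool),
            rng_seed=int(manifest["rng_seed"]),
            smoothing_sd=float(manifest["smoothing_sd"]),
            glyph_version=manifest["glyph_version"],
        )

    def export_images(self, out_dir: str | Path, fmt: str = "pgm") -> None:
        """Export per-item images as PGM (P5) or PNG for visual inspection."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for spec, flat in zip(self.specs, self.images):
            img = flat.reshape(IMAGE_SHAPE)
            path = out / f"face_{spec.item_id:02d}.{fmt}"
            if fmt == "pgm":
                header = f"P5\n{IMAGE_SHAPE[1]} {IMAGE_SHAPE[0]}\n255\n".encode()
                path.write_bytes(header + ((1 - img) * 255).astype(np.uint8).tobytes())
            elif fmt == "png":
                from PIL import Image

                Image.fromarray(((1 - img) * 255).astype(np.uint8)).save(path)
            else:
                raise ValueError(f"unknown image format {fmt!r}")


def build_stimulus_set(
    seed: int,
    sd: float = DEFAULT_SMOOTHING_SD,
    glyphs: GlyphBank | None = None,
) -> StimulusSet:
    """Assemble the 64-item set and sample the 32/32 trained/untrained split.

    The split is drawn uniformly without replacement from ``seed``; the whole
    set is bit-identical when regenerated with the same seed and glyph bank.
    """
    if glyphs is None:
        glyphs = default_glyph_bank()
    specs = enumerate_face_specs()
    images = np.stack([render_face_image(s, glyphs).ravel() for s in specs])
    retino = np.stack([make_retinotopic_input(img.reshape(IMAGE_SHAPE), sd).ravel() for img in images])
    verbal = np.stack([verbal_vector(s) for s in specs])
    rng = np.random.default_rng(seed)
    trained = np.zeros(N_ITEMS, dtype=bool)
    trained[rng.choice(N_ITEMS, size=N_TRAINED, replace=False)] = True
    return StimulusSet(
        specs=specs,
        images=images.astype(np.uint8),
        retinotopic=retino,
        verbal=verbal.astype(np.uint8),
        trained_mask=trained,
        rng_seed=seed,
        smoothing_sd=sd,
        glyph_version=glyphs.version,
    )


def subset_stimulus_set(stimuli: StimulusSet, indices, trained_mask=None) -> StimulusSet:
    """Restrict a set to selected item indices (used for desk-scale runs).

    All items are marked trained unless an explicit mask is given.
    """
    idx = np.asarray(indices)
    if trained_mask is None:
        trained = np.ones(idx.size, dtype=bool)
    else:
        trained = np.asarray(trained_mask, dtype=bool)
    return StimulusSet(
        specs=[stimuli.specs[i] for i in idx],
        images=stimuli.images[idx].copy(),
        retinotopic=stimuli.retinotopic[idx].copy(),
        verbal=stimuli.verbal[idx].copy(),
        trained_mask=trained,
        rng_seed=stimuli.rng_seed,
        smoothing_sd=stimuli.smoothing_sd,
        glyph_version=stimuli.glyph_version,
    )
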