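"""Synthetic multi-domain, AU-parameterized face benchmark generator.

Licensed micro-expression corpora cannot be redistributed, so every test
and demo in this toolkit runs on synthetic data that reproduces the two
*structural* properties the method targets:

* **domain shift** — each synthetic "site" applies its own appearance bias
  (brightness, contrast, tint, effective resolution, sensor noise), so
  pixel features cluster by source domain exactly as composite
  micro-expression training sets do;
* **AU-driven expressions** — a parametric face (oval, brows, eyes, mouth
  as control-point curves) whose control points are displaced linearly by
  the 17 facial Action Unit intensities (AU1/AU2 raise inner/outer brows,
  AU4 lowers them, AU5 widens the eye aperture, AU45 closes the eyes,
  AU6+AU12 raise the mouth corners, AU9/AU15 lower them, AU25/AU26 open
  the mouth, ...), giving three emotion classes that are linearly
  separable in AU space by construction.

Alongside each rendered apex image the generator emits the analytic pixel
displacement field between the neutral (all-zero AU) face and the rendered
expression — a stand-in for onset->apex optical flow. Images are float RGB
in [0, 1], origin top-left; displacement fields are (dy, dx) in pixels.

The module also provides the bundled :class:`SyntheticBackend` that
fulfills augmentation plans by rendering samples conditioned on a
category's AU centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np

from .au_cluster import AUCentroid
from .manifests import (AU_IDS, LABELS, SampleRecord, as_au_vector,
                        write_au_table, write_manifest)

_AU_INDEX = {k: i for i, k in enumerate(AU_IDS)}


@dataclass(frozen=True)
class DomainSpec:
    """Appearance bias of one synthetic acquisition site.

    Transforms apply in order: contrast gain (around mid-gray), additive
    brightness offset, per-channel tint, resolution degradation
    (box-downsample by ``round(1/resolution_factor)`` then nearest
    upsample), additive Gaussian noise; the result is clipped to [0, 1].
    """

    name: str
    brightness_offset: float = 0.0
    contrast_gain: float = 1.0
    tint: tuple[float, float, float] = (1.0, 1.0, 1.0)
    resolution_factor: float = 1.0
    noise_sd: float = 0.0
    counts: tuple[int, int, int] = (0, 0, 0)   # per category, LABELS order

    def __post_init__(self) -> None:
        if not (0.0 < self.resolution_factor <= 1.0):
            raise ValueError("resolution_factor must be in (0, 1]")
        if self.noise_sd < 0 or self.contrast_gain <= 0:
            raise ValueError("noise_sd must be >= 0 and contrast_gain > 0")


IDENTITY_DOMAIN = DomainSpec(name="identity")


@dataclass(frozen=True)
class ClassPrototype:
    """Mean AU intensity pattern of one emotion class, with per-AU spread."""

    category: str
    prototype: np.ndarray
    spread: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "prototype", as_au_vector(self.prototype))
        spread = np.broadcast_to(np.asarray(self.spread, dtype=float),
                                 self.prototype.shape).copy()
        if (spread < 0).any():
            raise ValueError("spread must be >= 0")
        object.__setattr__(self, "spread", spread)


def _proto(pairs: Mapping[int, float], base: float = 0.3) -> np.ndarray:
    v = np.full(len(AU_IDS), base)
    for au, inten in pairs.items():
        v[_AU_INDEX[au]] = inten
    return v


#: FACS-informed default class prototypes: smiles (AU6+12) for Positive,
#: brow lowering / nose wrinkle / corner depression for Negative, raised
#: brows + widened eyes + parted lips for Surprise.
DEFAULT_PROTOTYPES: dict[str, ClassPrototype] = {
    "Positive": ClassPrototype("Positive", _proto({6: 3.5, 12: 4.0}), 0.3),
    "Negative": ClassPrototype("Negative", _proto({4: 3.5, 7: 2.5, 9: 2.0, 15: 3.0}), 0.3),
    "Surprise": ClassPrototype("Surprise", _proto({1: 3.5, 2: 3.5, 5: 3.0, 25: 3.0, 26: 2.5}), 0.3),
}


def sample_au_vector(proto: ClassPrototype, rng_seed: int) -> np.ndarray:
    """Prototype + independent per-AU Gaussian noise, clipped to [0, 5]."""
    rng = np.random.default_rng(rng_seed)
    draw = proto.prototype + rng.normal(0.0, 1.0, proto.prototype.shape) * proto.spread
    return np.clip(draw, 0.0, 5.0)


# ---------------------------------------------------------------------------
# Parametric face renderer
# ---------------------------------------------------------------------------

_SKIN = np.array([0.70, 0.56, 0.46])
_FEATURE = np.array([0.12, 0.10, 0.10])
_BACKGROUND = np.array([0.18, 0.18, 0.20])


def _soft(d: np.ndarray, edge: float = 1.0) -> np.ndarray:
    """Anti-aliased inside mask from a signed 'distance' (negative inside)."""
    return np.clip(0.5 - d / edge, 0.0, 1.0)


def _ellipse_d(yy, xx, cy, cx, ry, rx):
    # approximate signed distance in pixels to an axis-aligned ellipse
    f = np.sqrt(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2)
    return (f - 1.0) * min(ry, rx)


def _au(au: np.ndarray, k: int) -> float:
    return float(au[_AU_INDEX[k]])


def _face_geometry(au: np.ndarray, size: int) -> dict:
    """Control-point layout and AU-driven displacements, in pixels.

    All displacements are linear in the AU intensities (0-5 scale); the
    unit step ``u`` scales with image size so geometry is resolution
    independent.
    """
    s = float(size)
    u = s / 64.0
    g: dict = {}

    # brows: (inner, outer) endpoints per side, y grows downward
    brow_dy_inner = -0.8 * u * _au(au, 1) + 0.7 * u * _au(au, 4)
    brow_dy_outer = -0.8 * u * _au(au, 2) + 0.7 * u * _au(au, 4)
    g["brow_l"] = {"inner": (0.34 * s + brow_dy_inner, 0.41 * s),
                   "outer": (0.32 * s + brow_dy_outer, 0.27 * s)}
    g["brow_r"] = {"inner": (0.34 * s + brow_dy_inner, 0.59 * s),
                   "outer": (0.32 * s + brow_dy_outer, 0.73 * s)}
    g["brow_thick"] = 0.018 * s

    # eyes: vertical aperture opens with AU5, narrows with AU7, closes with AU45
    ry0 = 0.030 * s
    d_ry = 0.25 * u * _au(au, 5) - 0.12 * u * _au(au, 7) - ry0 * _au(au, 45) / 5.0
    g["eye_ry0"] = ry0
    g["eye_ry"] = max(0.15 * ry0, ry0 + d_ry)
    g["eye_rx"] = 0.065 * s
    g["eye_l"] = (0.42 * s, 0.35 * s)
    g["eye_r"] = (0.42 * s, 0.65 * s)
    g["eye_d_ry"] = d_ry

    # mouth: corners move with AU6/12 (up), AU9/15 (down), widen with
    # AU12/14/20; lips part with AU25/26; center lifts with AU10/17
    corner_dy = (-(0.4 * _au(au, 6) + 0.9 * _au(au, 12))
                 + (0.3 * _au(au, 9) + 0.9 * _au(au, 15))) * u
    corner_dx = (0.2 * _au(au, 12) + 0.3 * _au(au, 14) + 0.4 * _au(au, 20)) * u
    center_dy = -(0.3 * _au(au, 10) + 0.2 * _au(au, 17)) * u
    opening = (0.5 * _au(au, 25) + 0.7 * _au(au, 26)) * u
    thick = max(0.4 * 0.022 * s, 0.022 * s - 0.1 * u * _au(au, 23))
    g["mouth_c"] = (0.70 * s, 0.50 * s)
    g["mouth_halfw"] = 0.13 * s + corner_dx
    g["mouth_corner_dy"] = corner_dy
    g["mouth_corner_dx"] = corner_dx
    g["mouth_center_dy"] = center_dy
    g["mouth_opening"] = opening
    g["mouth_thick"] = thick
    return g


def _segment_d(yy, xx, p0, p1, thick):
    # distance to a segment band
    p0 = np.asarray(p0); p1 = np.asarray(p1)
    d = p1 - p0
    L2 = float(d @ d)
    t = np.clip(((yy - p0[0]) * d[0] + (xx - p0[1]) * d[1]) / L2, 0.0, 1.0)
    py = p0[0] + t * d[0]
    px = p0[1] + t * d[1]
    return np.sqrt((yy - py) ** 2 + (xx - px) ** 2) - thick / 2.0


def _compose(img, mask, color):
    return img * (1.0 - mask[..., None]) + mask[..., None] * color


def render_template(au: np.ndarray, size: int) -> np.ndarray:
    """Render the bare (domain-free) face for an AU configuration."""
    if size < 32:
        raise ValueError("size must be >= 32 to resolve the face template")
    au = as_au_vector(au)
    s = float(size)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    g = _face_geometry(au, size)

    img = np.broadcast_to(_BACKGROUND, (size, size, 3)).copy()
    img = _compose(img, _soft(_ellipse_d(yy, xx, 0.52 * s, 0.50 * s, 0.40 * s, 0.32 * s)), _SKIN)

    for side in ("brow_l", "brow_r"):
        img = _compose(img, _soft(_segment_d(yy, xx, g[side]["inner"],
                                             g[side]["outer"], g["brow_thick"])), _FEATURE)
    for eye in ("eye_l", "eye_r"):
        cy, cx = g[eye]
        img = _compose(img, _soft(_ellipse_d(yy, xx, cy, cx, g["eye_ry"], g["eye_rx"])), _FEATURE)

    # mouth band around a quadratic corner-lift curve
    cy_m, cx_m = g["mouth_c"]
    halfw = g["mouth_halfw"]
    xi = (xx - cx_m) / halfw
    ycurve = cy_m + g["mouth_center_dy"] + g["mouth_corner_dy"] * xi ** 2
    h = g["mouth_thick"] + g["mouth_opening"] * np.clip(1.0 - xi ** 2, 0.0, 1.0)
    d_vert = np.abs(yy - ycurve) - h / 2.0
    d_lat = (np.abs(xi) - 1.0) * halfw
    img = _compose(img, _soft(np.maximum(d_vert, d_lat)), _FEATURE)
    return np.clip(img, 0.0, 1.0)


def displacement_field(au: np.ndarray, size: int) -> np.ndarray:
    """Analytic pixel displacement neutral -> expression, channels (dy, dx).

    Control-point displacements are splatted with Gaussian weights
    (sd = 4 px at size 64) around their neutral positions; all-zero AU
    gives the identically zero field.
    """
    au = as_au_vector(au)
    g0 = _face_geometry(np.zeros(len(AU_IDS)), size)
    g1 = _face_geometry(au, size)
    sigma = 4.0 * size / 64.0
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    flow = np.zeros((size, size, 2))

    def splat(p_neutral, dy, dx):
        w = np.exp(-((yy - p_neutral[0]) ** 2 + (xx - p_neutral[1]) ** 2)
                   / (2.0 * sigma ** 2))
        flow[..., 0] += w * dy
        flow[..., 1] += w * dx

    for side in ("brow_l", "brow_r"):
        for end in ("inner", "outer"):
            splat(g0[side][end], g1[side][end][0] - g0[side][end][0],
                  g1[side][end][1] - g0[side][end][1])
    for eye in ("eye_l", "eye_r"):
        cy, cx = g0[eye]
        splat((cy - g0["eye_ry0"], cx), -g1["eye_d_ry"], 0.0)   # upper lid
    cy_m, cx_m = g0["mouth_c"]
    hw0, hw1 = g0["mouth_halfw"], g1["mouth_halfw"]
    splat((cy_m, cx_m - hw0), g1["mouth_corner_dy"], -(hw1 - hw0))
    splat((cy_m, cx_m + hw0), g1["mouth_corner_dy"], hw1 - hw0)
    splat((cy_m - g0["mouth_thick"] / 2.0, cx_m),
          g1["mouth_center_dy"] - g1["mouth_opening"] / 2.0, 0.0)
    splat((cy_m + g0["mouth_thick"] / 2.0, cx_m),
          g1["mouth_center_dy"] + g1["mouth_opening"] / 2.0, 0.0)
    return flow


def apply_domain(img: np.ndarray, domain: DomainSpec, rng: np.random.Generator,
                 clip: bool = True) -> np.ndarray:
    """Apply a site's appearance bias to a rendered face."""
    out = img
    if domain.contrast_gain != 1.0:
        out = 0.5 + domain.contrast_gain * (out - 0.5)
    if domain.brightness_offset != 0.0:
        out = out + domain.brightness_offset
    if tuple(domain.tint) != (1.0, 1.0, 1.0):
        out = out * np.asarray(domain.tint)
    if domain.resolution_factor < 1.0:
        stride = max(1, int(round(1.0 / domain.resolution_factor)))
        if stride > 1:
            s = out.shape[0]
            pad = (-s) % stride
            padded = np.pad(out, ((0, pad), (0, pad), (0, 0)), mode="edge")
            pooled = padded.reshape(padded.shape[0] // stride, stride,
                                    padded.shape[1] // stride, stride, 3).mean(axis=(1, 3))
            out = np.repeat(np.repeat(pooled, stride, 0), stride, 1)[:s, :s]
    if domain.noise_sd > 0:
        out = out + rng.normal(0.0, domain.noise_sd, out.shape)
    return np.clip(out, 0.0, 1.0) if clip else out


def render_face(au: np.ndarray, domain: DomainSpec, size: int,
                rng_seed: int, clip: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Render one face under a domain bias; returns (image, displacement).

    Deterministic per seed (the seed only feeds the domain's sensor noise).
    The displacement field describes facial motion and is not affected by
    the appearance transform.
    """
    img = render_template(au, size)
    rng = np.random.default_rng(rng_seed)
    return apply_domain(img, domain, rng, clip=clip), displacement_field(au, size)


# ---------------------------------------------------------------------------
# Benchmark generation
# ---------------------------------------------------------------------------

def _sample_seed(master_seed: int, *index: int) -> int:
    return int(np.random.SeedSequence((master_seed, *index)).generate_state(1)[0] % (2**31))


@dataclass
class Benchmark:
    records: list[SampleRecord]
    au_map: dict[str, np.ndarray]
    images: dict[str, np.ndarray] = field(default_factory=dict)
    flows: dict[str, np.ndarray] = field(default_factory=dict)
    manifest_path: Path | None = None
    au_table_path: Path | None = None


def generate_benchmark(domains: Sequence[DomainSpec],
                       protos: Mapping[str, ClassPrototype] | None = None,
                       out_dir: str | Path | None = None,
                       seed: int = 0, size: int = 64,
                       write_flow: bool = True,
                       return_arrays: bool = False) -> Benchmark:
    """Generate a multi-domain benchmark: images, flow surrogates, AU table,
    and a manifest, with per-(domain, category) counts from the DomainSpecs.

    With ``out_dir=None`` nothing is written and image/flow references stay
    empty; pass ``return_arrays=True`` to keep the rendered images and
    displacement fields in memory (``Benchmark.images`` / ``.flows``).
    """
    if len(domains) < 2:
        raise ValueError("need at least 2 domains")
    protos = DEFAULT_PROTOTYPES if protos is None else protos
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        (out / "images").mkdir(parents=True, exist_ok=True)
        if write_flow:
            (out / "flow").mkdir(parents=True, exist_ok=True)

    records: list[SampleRecord] = []
    au_map: dict[str, np.ndarray] = {}
    images: dict[str, np.ndarray] = {}
    flows: dict[str, np.ndarray] = {}
    for di, dom in enumerate(domains):
        for ci, cat in enumerate(LABELS):
            for j in range(dom.counts[ci]):
                sid = f"{dom.name}_{cat}_{j:04d}"
                au_seed = _sample_seed(seed, di, ci, j, 0)
                px_seed = _sample_seed(seed, di, ci, j, 1)
                au = sample_au_vector(protos[cat], au_seed)
                img_ref = flow_ref = None
                if out is not None or return_arrays:
                    img, flow = render_face(au, dom, size, px_seed)
                    if return_arrays:
                        images[sid] = img
                        flows[sid] = flow
                if out is not None:
                    img_ref = str(out / "images" / f"{sid}.png")
                    iio.imwrite(img_ref, (np.round(img * 255)).astype(np.uint8))
                    if write_flow:
                        flow_ref = str(out / "flow" / f"{sid}.npz")
                        np.savez_compressed(flow_ref, flow=flow.astype(np.float32))
                records.append(SampleRecord(
                    sample_id=sid, source_dataset=dom.name, label=cat,
                    image_ref=img_ref, flow_ref=flow_ref, au=au, split="train",
                ))
                au_map[sid] = au

    bench = Benchmark(records=records, au_map=au_map, images=images, flows=flows)
    if out is not None:
        bench.manifest_path = write_manifest(records, out / "manifest.csv")
        bench.au_table_path = write_au_table(au_map, out / "au_table.csv")
    return bench


# --- presets ---------------------------------------------------------------

_SITE_BIASES = [
    dict(name="siteA", brightness_offset=-0.12, contrast_gain=0.90,
         tint=(1.00, 0.95, 0.90), resolution_factor=1.0, noise_sd=0.020),
    dict(name="siteB", brightness_offset=0.10, contrast_gain=1.10,
         tint=(0.95, 1.00, 1.05), resolution_factor=0.5, noise_sd=0.010),
    dict(name="siteC", brightness_offset=0.00, contrast_gain=1.25,
         tint=(1.05, 1.00, 0.95), resolution_factor=1.0, noise_sd=0.030),
    dict(name="siteD", brightness_offset=-0.05, contrast_gain=0.80,
         tint=(0.90, 0.90, 1.00), resolution_factor=0.33, noise_sd=0.015),
    dict(name="siteE", brightness_offset=0.05, contrast_gain=1.00,
         tint=(1.00, 1.05, 1.00), resolution_factor=0.66, noise_sd=0.025),
]

#: Per-category counts of the five public micro-expression datasets.
_TABLE_SHAPED_COUNTS = [(51, 70, 43), (9, 53, 21), (32, 72, 25),
                        (26, 80, 15), (36, 109, 89)]


def preset_domains(preset: str = "desk") -> list[DomainSpec]:
    """Bundled domain presets.

    ``desk``    five sites x 20 samples/category (60 per site) — the scale
                used by the package's own experiments;
    ``table1``  five sites with the count matrix of the five public
                micro-expression datasets (grand total 731);
    ``toy2``    two sites x 4 samples/category, for smoke tests.
    """
    if preset == "desk":
        return [DomainSpec(counts=(20, 20, 20), **b) for b in _SITE_BIASES]
    if preset == "table1":
        return [DomainSpec(counts=c, **b)
                for b, c in zip(_SITE_BIASES, _TABLE_SHAPED_COUNTS)]
    if preset == "toy2":
        counts = [(4, 4, 4), (3, 4, 2)]     # mildly imbalanced second site
        return [DomainSpec(counts=c, **b)
                for b, c in zip(_SITE_BIASES[:2], counts)]
    raise ValueError(f"unknown preset {preset!r}; have desk, table1, toy2")


# ---------------------------------------------------------------------------
# Bundled augmentation backend
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBackend:
    """Bundled `GeneratorInterface` backend rendering AU-conditioned faces.

    Samples AU vectors around the conditioning centroid (Gaussian,
    sd ``jitter``) and renders them under the target dataset's domain bias
    (identity appearance if the dataset has no registered DomainSpec).
    """

    out_dir: Path | None = None
    size: int = 64
    domain_specs: dict[str, DomainSpec] = field(default_factory=dict)
    jitter: float = 0.25
    write_flow: bool = False

    def generate(self, dataset: str, category: str, centroid: AUCentroid,
                 count: int, seed: int) -> list[SampleRecord]:
        dom = self.domain_specs.get(dataset, IDENTITY_DOMAIN)
        proto = ClassPrototype(category, centroid.centroid, self.jitter)
        out = Path(self.out_dir) if self.out_dir is not None else None
        if out is not None:
            (out / "images").mkdir(parents=True, exist_ok=True)
            if self.write_flow:
                (out / "flow").mkdir(parents=True, exist_ok=True)
        records = []
        for j in range(count):
            sid = f"syn_{dataset}_{category}_{j:04d}"
            au = sample_au_vector(proto, _sample_seed(seed, j, 0))
            img_ref = flow_ref = None
            if out is not None:
                img, flow = render_face(au, dom, self.size, _sample_seed(seed, j, 1))
                img_ref = str(out / "images" / f"{sid}.png")
                iio.imwrite(img_ref, (np.round(img * 255)).astype(np.uint8))
                if self.write_flow:
                    flow_ref = str(out / "flow" / f"{sid}.npz")
                    np.savez_compressed(flow_ref, flow=flow.astype(np.float32))
            records.append(SampleRecord(
                sample_id=sid, source_dataset=dataset, label=category,
                image_ref=img_ref, flow_ref=flow_ref, au=au,
                split="train", synthetic=True,
            ))
        return records
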