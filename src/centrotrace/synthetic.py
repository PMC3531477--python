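"""Seeded synthetic two-channel microscopy scenes with ground truth.

Generates GFP + DNA image pairs emulating centromeric spot patterns in
sperm nuclei, late (S5-stage) spermatocytes with three chromosome
territories, metaphase fields of early embryos with paternal/maternal
half-sets, and wing-disc nuclei with a single clustered signal.  Every
rendered spot is recorded in a ground-truth table so downstream
quantification can be validated against known integrated signals.

Conventions: 0-based pixel indices, (row, col) order, origin top-left.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.special import erf


class SceneOverflowError(ValueError):
    """Requested nuclei/landmarks cannot fit into the image ("scene overflow")."""


class DynamicRangeError(ValueError):
    """Pixel values exceed the 16-bit output range ("dynamic-range error")."""


STAGES = ("sperm", "spermatocyte_S5", "embryo_metaphase", "wing_disc")

CHROMOSOME_CLASSES = ("A2or3", "pair4", "X", "Y", "unassigned")

LANDMARK_CLASSES = ("bright_dot_chr4", "irregular_X_region", "homogeneous_territory")

#: Empirical distribution of resolvable spot counts in sperm nuclei
#: (fractions with 4, 3 and 2 signals).
DEFAULT_CLUSTERING = {4: 0.46, 3: 0.42, 2: 0.12}

#: Per-chromosome-class intensity multipliers.  The paired-4 spot holds two
#: centromeres and the Y centromere carries an elevated load; the X is the
#: weakest.  These are generator inputs, not measurement claims.
DEFAULT_RELATIVE_INTENSITY = {"A2or3": 1.0, "pair4": 2.0, "X": 0.8, "Y": 2.0}

# Nucleus radii (pixels) per stage; chosen so default layouts keep spots
# resolvable at the default PSF width.
_NUCLEUS_RADIUS = {
    "sperm": 16,
    "spermatocyte_S5": 48,
    "embryo_metaphase": 42,
    "wing_disc": 20,
}
_PLACEMENT_MARGIN = 6


@dataclass
class SceneConfig:
    """Parameters controlling one synthetic scene."""

    stage: str = "sperm"
    image_size: tuple[int, int] = (512, 512)
    spot_sigma: float = 2.0
    base_intensity: float = 5000.0
    relative_intensity_map: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RELATIVE_INTENSITY)
    )
    background_level: float = 10.0
    diffuse_nuclear_level: float = 0.5
    noise_sd: float = 1.5
    n_nuclei: int = 4
    clustering_probabilities: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CLUSTERING)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        h, w = self.image_size
        if h < 64 or w < 64:
            raise ValueError("image_size must be at least 64x64")
        if self.spot_sigma <= 0:
            raise ValueError("spot_sigma must be positive")
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        for name in ("base_intensity", "background_level", "diffuse_nuclear_level", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        total = sum(self.clustering_probabilities.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("clustering_probabilities must sum to 1")
        for k in self.clustering_probabilities:
            if not 1 <= int(k) <= 4:
                raise ValueError("clustering counts must lie in 1..4")

    @classmethod
    def from_yaml(cls, path) -> "SceneConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "image_size" in raw:
            raw["image_size"] = tuple(raw["image_size"])
        if "clustering_probabilities" in raw:
            raw["clustering_probabilities"] = {
                int(k): float(v) for k, v in raw["clustering_probabilities"].items()
            }
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            "stage": self.stage,
            "image_size": list(self.image_size),
            "spot_sigma": self.spot_sigma,
            "base_intensity": self.base_intensity,
            "relative_intensity_map": dict(self.relative_intensity_map),
            "background_level": self.background_level,
            "diffuse_nuclear_level": self.diffuse_nuclear_level,
            "noise_sd": self.noise_sd,
            "n_nuclei": self.n_nuclei,
            "clustering_probabilities": dict(self.clustering_probabilities),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass(frozen=True)
class Spot:
    """One rendered blob: a centromeric signal or a merged cluster."""

    nucleus_id: int
    chromosome_class: str
    center: tuple[float, float]  # (row, col)
    true_signal: float
    parental_origin: str = "na"  # paternal | maternal | na
    n_members: int = 1


@dataclass(frozen=True)
class Landmark:
    """A DNA-channel feature used for chromosome assignment."""

    nucleus_id: int
    landmark_class: str
    center: tuple[float, float]


@dataclass
class GroundTruthScene:
    gfp_image: np.ndarray
    dna_image: np.ndarray
    spots: list[Spot]
    nucleus_masks: np.ndarray
    dna_landmarks: list[Landmark]
    config: Optional[SceneConfig] = None

    def spots_frame(self) -> pd.DataFrame:
        rows = [
            {
                "nucleus_id": s.nucleus_id,
                "chromosome_class": s.chromosome_class,
                "row": s.center[0],
                "col": s.center[1],
                "true_signal": s.true_signal,
                "parental_origin": s.parental_origin,
                "n_members": s.n_members,
            }
            for s in self.spots
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "nucleus_id",
                "chromosome_class",
                "row",
                "col",
                "true_signal",
                "parental_origin",
                "n_members",
            ],
        )

    def landmarks_frame(self) -> pd.DataFrame:
        rows = [
            {
                "nucleus_id": lm.nucleus_id,
                "landmark_class": lm.landmark_class,
                "row": lm.center[0],
                "col": lm.center[1],
            }
            for lm in self.dna_landmarks
        ]
        return pd.DataFrame(rows, columns=["nucleus_id", "landmark_class", "row", "col"])


def _render_spot(image: np.ndarray, center: tuple[float, float], sigma: float, signal: float) -> None:
    """Add a pixel-integrated isotropic Gaussian of total mass ``signal``.

    Pixel values are the integral of the Gaussian over the unit pixel, so
    the rendered mass equals ``signal`` up to window truncation (the window
    spans +-6 sigma; truncation < 1e-8 of the mass).
    """
    r0, c0 = center
    rad = int(math.ceil(6.0 * sigma)) + 1
    h, w = image.shape
    rlo = max(int(math.floor(r0)) - rad, 0)
    rhi = min(int(math.floor(r0)) + rad + 1, h)
    clo = max(int(math.floor(c0)) - rad, 0)
    chi = min(int(math.floor(c0)) + rad + 1, w)
    if rlo >= rhi or clo >= chi:
        return
    rr = np.arange(rlo, rhi)
    cc = np.arange(clo, chi)
    s = sigma * math.sqrt(2.0)
    fr = 0.5 * (erf((rr + 0.5 - r0) / s) - erf((rr - 0.5 - r0) / s))
    fc = 0.5 * (erf((cc + 0.5 - c0) / s) - erf((cc - 0.5 - c0) / s))
    image[rlo:rhi, clo:chi] += signal * np.outer(fr, fc)


def _place_nuclei(config: SceneConfig, radius: int, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Non-overlapping nucleus centers on a jittered grid."""
    h, w = config.image_size
    cell = 2 * (radius + _PLACEMENT_MARGIN)
    n_rows, n_cols = h // cell, w // cell
    if n_rows * n_cols < config.n_nuclei:
        raise SceneOverflowError(
            f"scene overflow: {config.n_nuclei} nuclei of radius {radius} "
            f"do not fit into a {h}x{w} image"
        )
    centers = []
    jitter = 2.0
    for i in range(config.n_nuclei):
        gr, gc = divmod(i, n_cols)
        r = (gr + 0.5) * cell + rng.uniform(-jitter, jitter)
        c = (gc + 0.5) * cell + rng.uniform(-jitter, jitter)
        centers.append((r, c))
    return centers


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


_SPERM_PARTITIONS = {4: (1, 1, 1, 1), 3: (2, 1, 1), 2: (2, 2), 1: (4,)}


def _sperm_nucleus(nid, center, config, rng):
    counts = sorted(config.clustering_probabilities)
    probs = [config.clustering_probabilities[k] for k in counts]
    k = int(rng.choice(counts, p=probs))
    partition = _SPERM_PARTITIONS[k]
    # k blob positions within the nucleus, min pairwise separation 5 px
    positions = []
    while len(positions) < k:
        ang = rng.uniform(0, 2 * math.pi)
        rad = rng.uniform(0, 8.0)
        cand = (center[0] + rad * math.sin(ang), center[1] + rad * math.cos(ang))
        if all(math.dist(cand, p) >= 5.0 for p in positions):
            positions.append(cand)
    spots = [
        Spot(nid, "unassigned", pos, m * config.base_intensity, "na", n_members=m)
        for pos, m in zip(positions, partition)
    ]
    return spots, []


def _s5_nucleus(nid, center, config, rng):
    rel = config.relative_intensity_map
    base = config.base_intensity
    theta0 = rng.uniform(0, 2 * math.pi)
    territory_centers = [
        (
            center[0] + 26.0 * math.sin(theta0 + i * 2 * math.pi / 3),
            center[1] + 26.0 * math.cos(theta0 + i * 2 * math.pi / 3),
        )
        for i in range(3)
    ]
    spots, landmarks = [], []
    # two major-autosome territories: two spots each, homogeneous DNA
    for tc in territory_centers[:2]:
        phi = rng.uniform(0, 2 * math.pi)
        for sign in (+1, -1):
            pos = (tc[0] + sign * 8.5 * math.sin(phi), tc[1] + sign * 8.5 * math.cos(phi))
            spots.append(Spot(nid, "A2or3", pos, base * rel["A2or3"], "na"))
        landmarks.append(Landmark(nid, "homogeneous_territory", tc))
    # X-Y-4 territory: three spots on a triangle (side ~17 px)
    tc = territory_centers[2]
    phi = rng.uniform(0, 2 * math.pi)
    tri = [
        (tc[0] + 10.0 * math.sin(phi + i * 2 * math.pi / 3), tc[1] + 10.0 * math.cos(phi + i * 2 * math.pi / 3))
        for i in range(3)
    ]
    pos4, posx, posy = tri
    spots.append(Spot(nid, "pair4", pos4, base * rel["pair4"], "na", n_members=2))
    spots.append(Spot(nid, "X", posx, base * rel["X"], "na"))
    spots.append(Spot(nid, "Y", posy, base * rel["Y"], "na"))
    # the bright DNA dot sits adjacent to the paired-4 spot, the irregular
    # intense region near the X; the Y spot has no intense DNA neighbour
    off = rng.uniform(0, 2 * math.pi)
    landmarks.append(
        Landmark(nid, "bright_dot_chr4", (pos4[0] + 3.0 * math.sin(off), pos4[1] + 3.0 * math.cos(off)))
    )
    off = rng.uniform(0, 2 * math.pi)
    landmarks.append(
        Landmark(nid, "irregular_X_region", (posx[0] + 3.0 * math.sin(off), posx[1] + 3.0 * math.cos(off)))
    )
    return spots, landmarks


_EMBRYO_HALFSET = ("A2or3", "A2or3", "pair4", "X")


def _embryo_nucleus(nid, center, config, rng, paternal_scale=1.0):
    rel = config.relative_intensity_map
    base = config.base_intensity
    theta = rng.uniform(0, 2 * math.pi)
    ct, st = math.cos(theta), math.sin(theta)
    spots = []
    for origin, yoff, scale in (("paternal", -9.0, paternal_scale), ("maternal", +9.0, 1.0)):
        for cls, xoff in zip(_EMBRYO_HALFSET, (-24.0, -8.0, 8.0, 24.0)):
            dr = yoff * ct + xoff * st
            dc = -yoff * st + xoff * ct
            n_members = 2 if cls == "pair4" else 1
            spots.append(
                Spot(
                    nid,
                    cls,
                    (center[0] + dr, center[1] + dc),
                    base * rel[cls] * scale,
                    origin,
                    n_members=n_members,
                )
            )
    return spots, []


def _wing_disc_nucleus(nid, center, config, rng):
    # one clustered chromocenter-like signal per nucleus
    spot = Spot(nid, "unassigned", center, config.base_intensity, "na")
    return [spot], []


def generate_scene(config: SceneConfig, paternal_scale: float = 1.0) -> GroundTruthScene:
    """Render one seeded scene; deterministic for a fixed config.

    ``paternal_scale`` multiplies the true signals of the paternal half-set
    in embryo_metaphase scenes (see :func:`generate_cross_panel`).
    """
    rng = np.random.default_rng(config.seed)
    radius = _NUCLEUS_RADIUS[config.stage]
    centers = _place_nuclei(config, radius, rng)

    h, w = config.image_size
    masks = np.zeros((h, w), dtype=np.uint16)
    spots: list[Spot] = []
    landmarks: list[Landmark] = []
    for i, center in enumerate(centers, start=1):
        masks[_disk_mask((h, w), center, radius)] = i
        if config.stage == "sperm":
            sp, lm = _sperm_nucleus(i, center, config, rng)
        elif config.stage == "spermatocyte_S5":
            sp, lm = _s5_nucleus(i, center, config, rng)
        elif config.stage == "embryo_metaphase":
            sp, lm = _embryo_nucleus(i, center, config, rng, paternal_scale)
        else:
            sp, lm = _wing_disc_nucleus(i, center, config, rng)
        spots.extend(sp)
        landmarks.extend(lm)

    gfp = np.full((h, w), float(config.background_level))
    gfp[masks > 0] += config.diffuse_nuclear_level
    for s in spots:
        _render_spot(gfp, s.center, config.spot_sigma, s.true_signal)

    dna = np.full((h, w), float(config.background_level))
    dna[masks > 0] += 20.0  # nuclear DNA counterstain
    for lm in landmarks:
        if lm.landmark_class == "bright_dot_chr4":
            _render_spot(dna, lm.center, 1.5, 8000.0)
        elif lm.landmark_class == "irregular_X_region":
            # a few overlapping blobs: intense but irregular, weaker than chr4 dot
            for _ in range(3):
                jit = (lm.center[0] + rng.uniform(-2, 2), lm.center[1] + rng.uniform(-2, 2))
                _render_spot(dna, jit, 2.5, 1500.0)
        else:  # homogeneous territory: broad faint blob
            _render_spot(dna, lm.center, 8.0, 4000.0)

    if config.noise_sd > 0:
        gfp = np.clip(gfp + rng.normal(0.0, config.noise_sd, gfp.shape), 0.0, None)
        dna = np.clip(dna + rng.normal(0.0, config.noise_sd, dna.shape), 0.0, None)

    return GroundTruthScene(gfp, dna, spots, masks, landmarks, config)


def generate_cross_panel(
    father_perturbation: float, n_embryos: int, config: SceneConfig
) -> list[GroundTruthScene]:
    """Embryo scenes whose paternal half-set signals are scaled by a factor.

    The maternal half-set is left unscaled, so in ground truth the
    per-nucleus total is (1 + factor)/2 times the unperturbed total.
    """
    if father_perturbation <= 0:
        raise ValueError("father_perturbation must be > 0")
    if n_embryos < 1:
        raise ValueError("n_embryos must be >= 1")
    cfg = replace(config, stage="embryo_metaphase")
    scenes = []
    for i in range(n_embryos):
        scenes.append(generate_scene(replace(cfg, seed=cfg.seed + i), paternal_scale=father_perturbation))
    return scenes


_TRUTH_HEADER = (
    "# ground-truth spots; 0-based pixel indices, (row, col) order, origin top-left\n"
    "# columns: nucleus_id, chromosome_class, row, col, true_signal, parental_origin, n_members\n"
)


def write_scene(scene: GroundTruthScene, prefix) -> dict[str, Path]:
    """Write GFP/DNA channels as 16-bit TIFF plus ground-truth CSV tables.

    Images are rounded to the nearest integer; values above 65535 raise
    :class:`DynamicRangeError` (the caller must rescale).
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "gfp": prefix.with_name(prefix.name + "_gfp.tif"),
        "dna": prefix.with_name(prefix.name + "_dna.tif"),
        "masks": prefix.with_name(prefix.name + "_masks.tif"),
        "truth": prefix.with_name(prefix.name + "_truth.csv"),
        "landmarks": prefix.with_name(prefix.name + "_landmarks.csv"),
    }
    for img, key in ((scene.gfp_image, "gfp"), (scene.dna_image, "dna")):
        quantized = np.rint(img)
        if quantized.max(initial=0) > 65535 or quantized.min(initial=0) < 0:
            raise DynamicRangeError(
                "dynamic-range error: pixel values outside the 16-bit range; rescale before writing"
            )
        tifffile.imwrite(paths[key], quantized.astype(np.uint16))
    tifffile.imwrite(paths["masks"], scene.nucleus_masks.astype(np.uint16))
    with open(paths["truth"], "w") as fh:
        fh.write(_TRUTH_HEADER)
        scene.spots_frame().to_csv(fh, index=False)
    with open(paths["landmarks"], "w") as fh:
        fh.write("# DNA-channel landmarks; 0-based (row, col), origin top-left\n")
        scene.landmarks_frame().to_csv(fh, index=False)
    return paths


def read_scene(prefix) -> GroundTruthScene:
    """Load a scene previously written by :func:`write_scene`."""
    prefix = Path(prefix)
    gfp = tifffile.imread(prefix.with_name(prefix.name + "_gfp.tif")).astype(float)
    dna = tifffile.imread(prefix.with_name(prefix.name + "_dna.tif")).astype(float)
    masks = tifffile.imread(prefix.with_name(prefix.name + "_masks.tif"))
    truth = pd.read_csv(prefix.with_name(prefix.name + "_truth.csv"), comment="#")
    lms = pd.read_csv(prefix.with_name(prefix.name + "_landmarks.csv"), comment="#")
    spots = [
        Spot(
            int(r.nucleus_id),
            str(r.chromosome_class),
            (float(r.row), float(r.col)),
            float(r.true_signal),
            str(r.parental_origin),
            int(r.n_members),
        )
        for r in truth.itertuples()
    ]
    landmarks = [
        Landmark(int(r.nucleus_id), str(r.landmark_class), (float(r.row), float(r.col)))
        for r in lms.itertuples()
    ]
    return GroundTruthScene(gfp, dna, spots, masks, landmarks, None)
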