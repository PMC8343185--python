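"""Synthetic two-channel microwell-array scenes with ground truth.

Emulates spinning-disk confocal fields of a dextran-in-PEG droplet array:
a square lattice of cylindrical microwells, one bright dextran-channel disc
per well (the rhodamine-dextran probe), and zero or more DNA-channel
particles per well (Oligreen-stained hydrogel) sitting on the droplet rim,
over a diffuse unbound-DNA background. Defaults follow the imaging setup
the pipeline is meant to quantify: a 1.8 mm x 1.8 mm field at 3.5 um/pixel
(514 x 514 grid).

Coordinates are 0-based row-major pixel indices with a pixel-center
convention: physical = (index + 0.5) * pixel_size.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ChannelIntensities",
    "NoiseModel",
    "ArraySpec",
    "GroundTruth",
    "SceneImage",
    "generate_truth",
    "render_channels",
    "add_noise",
    "write_dataset",
    "read_dataset",
    "scene_preset",
    "PRESET_NAMES",
]

M_PER_UM = 1e-6


@dataclass(frozen=True)
class ChannelIntensities:
    """Per-channel grey levels (arbitrary units, before noise).

    ``dna_droplet`` is the dim droplet-wide level from unbound motifs;
    ``dna_particle`` the bright gel signal. Contributions add on top of the
    channel background.
    """

    dex_background: float = 10.0
    dex_droplet: float = 200.0
    dna_background: float = 10.0
    dna_droplet: float = 30.0
    dna_particle: float = 200.0


@dataclass(frozen=True)
class NoiseModel:
    """Sensor noise: Gaussian read noise plus optional Poisson shot noise."""

    gaussian_sd: float = 0.0
    shot_noise: bool = False

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0:
            raise ValueError(f"gaussian_sd must be >= 0, got {self.gaussian_sd}")


@dataclass(frozen=True)
class ArraySpec:
    """Full description of a synthetic scene. All lengths in meters."""

    field_size: float = 1.8e-3
    pixel_size: float = 3.5e-6
    lattice_pitch: float = 100e-6
    well_diameter: float = 50e-6
    droplet_radius_distribution: tuple[float, float] = (24e-6, 1.0e-6)  # mean, sd
    particle_count_distribution: dict[int, float] = field(
        default_factory=lambda: {0: 0.02, 1: 0.93, 2: 0.05}
    )
    particle_radius_distribution: tuple[float, float] = (5.4e-6, 0.6e-6)
    particle_placement: str = "rim"  # "rim" | "center"
    intensities: ChannelIntensities = field(default_factory=ChannelIntensities)
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size >= self.well_diameter:
            raise ValueError("pixel_size must be smaller than well_diameter")
        if self.lattice_pitch < self.well_diameter:
            raise ValueError("lattice_pitch must be >= well_diameter")
        probs = np.array(list(self.particle_count_distribution.values()), dtype=float)
        if probs.size == 0 or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("particle_count_distribution probabilities must sum to 1")
        if any(k < 0 for k in self.particle_count_distribution):
            raise ValueError("particle counts must be >= 0")
        for name in ("droplet_radius_distribution", "particle_radius_distribution"):
            mean, sd = getattr(self, name)
            if mean <= 0 or sd < 0:
                raise ValueError(f"{name} needs mean > 0 and sd >= 0")
        if self.particle_placement not in ("rim", "center"):
            raise ValueError("particle_placement must be 'rim' or 'center'")

    @property
    def grid_shape(self) -> tuple[int, int]:
        n = round(self.field_size / self.pixel_size)
        return (n, n)

    @property
    def wells_per_side(self) -> int:
        # tolerant floor: 1.8e-3 / 100e-6 must give 18, not 17
        return int(math.floor(self.field_size / self.lattice_pitch + 1e-9))

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["particle_count_distribution"] = {
            str(k): v for k, v in self.particle_count_distribution.items()
        }
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "ArraySpec":
        d = dict(d)
        d["particle_count_distribution"] = {
            int(k): v for k, v in d["particle_count_distribution"].items()
        }
        d["intensities"] = ChannelIntensities(**d["intensities"])
        d["noise"] = NoiseModel(**d["noise"])
        for key in ("droplet_radius_distribution", "particle_radius_distribution"):
            d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class GroundTruth:
    """Machine-readable truth for one scene.

    ``wells``: one row per well (well_id, cx_m, cy_m, droplet_r_m);
    ``particles``: one row per particle (particle_id, well_id, px_m, py_m,
    r_m). Particle centers lie on the droplet rim circle (placement 'rim')
    or at its center.
    """

    wells: pd.DataFrame
    particles: pd.DataFrame

    @property
    def counts_per_well(self) -> pd.Series:
        counts = self.particles.groupby("well_id").size()
        return counts.reindex(self.wells["well_id"], fill_value=0)

    @property
    def mean_occupancy(self) -> float:
        return len(self.particles) / len(self.wells)

    def droplets_table_um(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_um": self.wells["cx_m"] / M_PER_UM,
                "y_um": self.wells["cy_m"] / M_PER_UM,
                "r_um": self.wells["droplet_r_m"] / M_PER_UM,
            }
        )

    def particles_table_um(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_um": self.particles["px_m"] / M_PER_UM,
                "y_um": self.particles["py_m"] / M_PER_UM,
                "r_um": self.particles["r_m"] / M_PER_UM,
            }
        )


class SceneImage(NamedTuple):
    dextran: np.ndarray
    dna: np.ndarray


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int,
                      low: float, high: float) -> np.ndarray:
    """Normal samples rejected outside (low, high]; falls back to clipping."""
    if sd == 0:
        return np.full(n, float(np.clip(mean, low + 1e-12, high)))
    out = rng.normal(mean, sd, size=n)
    for _ in range(100):
        bad = (out <= low) | (out > high)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(out, low + 1e-12, high)


def _rim_angles(rng: np.random.Generator, k: int, min_sep: float) -> np.ndarray:
    """k angles on the rim with pairwise circular separation >= min_sep."""
    if k == 1:
        return rng.uniform(0, 2 * math.pi, size=1)
    for _ in range(200):
        ang = np.sort(rng.uniform(0, 2 * math.pi, size=k))
        gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * math.pi]]))
        if (gaps >= min_sep).all():
            return ang
    # deterministic fallback: evenly spaced with a random phase
    return rng.uniform(0, 2 * math.pi) + np.arange(k) * 2 * math.pi / k


def generate_truth(spec: ArraySpec) -> GroundTruth:
    """Sample the well lattice, droplet radii and particle placements.

    Deterministic for a fixed ``spec.seed``; droplet and particle draws use
    independent substreams so changing one distribution does not perturb the
    other. Particles within a well are kept angularly separated so their
    rendered discs never merge.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_drop, rng_count, rng_part, rng_angle = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    n_side = spec.wells_per_side
    pitch = spec.lattice_pitch
    centers = [(pitch * (i + 0.5), pitch * (j + 0.5)) for j in range(n_side) for i in range(n_side)]
    n_wells = len(centers)
    well_r = spec.well_diameter / 2

    drop_r = _truncated_normal(
        rng_drop, *spec.droplet_radius_distribution, n_wells, 0.0, well_r
    )
    counts_dist = spec.particle_count_distribution
    ks = rng_count.choice(
        np.array(list(counts_dist.keys())), size=n_wells, p=list(counts_dist.values())
    )

    wells = pd.DataFrame(
        {
            "well_id": np.arange(n_wells),
            "cx_m": [c[0] for c in centers],
            "cy_m": [c[1] for c in centers],
            "droplet_r_m": drop_r,
        }
    )

    rows = []
    pid = 0
    pr_mean, pr_sd = spec.particle_radius_distribution
    for w in range(n_wells):
        k = int(ks[w])
        if k == 0:
            continue
        radii = _truncated_normal(rng_part, pr_mean, pr_sd, k, 0.0, np.inf)
        cx, cy, R = wells.loc[w, "cx_m"], wells.loc[w, "cy_m"], drop_r[w]
        if spec.particle_placement == "rim":
            # keep discs resolvable: chord between centers > r_i + r_j plus a
            # 3-pixel guard band so anti-aliased edges cannot bridge under
            # 8-connectivity labelling
            min_sep = 2 * math.asin(
                min(1.0, (2 * radii.max() + 3 * spec.pixel_size) / (2 * R))
            )
            angles = _rim_angles(rng_angle, k, min_sep)
            px = cx + R * np.cos(angles)
            py = cy + R * np.sin(angles)
        else:
            px = np.full(k, cx)
            py = np.full(k, cy)
        for i in range(k):
            rows.append(
                {
                    "particle_id": pid,
                    "well_id": w,
                    "px_m": px[i],
                    "py_m": py[i],
                    "r_m": radii[i],
                }
            )
            pid += 1
    particles = pd.DataFrame(
        rows, columns=["particle_id", "well_id", "px_m", "py_m", "r_m"]
    )
    return GroundTruth(wells=wells, particles=particles)


def _accumulate_discs(
    canvas: np.ndarray, xs_m, ys_m, radii_m, pixel_size: float
) -> None:
    """Add anti-aliased disc coverage (0..1 per disc) to *canvas* in place.

    A pixel's coverage of one disc is approximated linearly from the
    distance of its center to the disc edge: clip(r_px + 0.5 - d_px, 0, 1),
    which integrates to the disc area to sub-pixel accuracy.
    """
    h, w = canvas.shape
    for x_m, y_m, r_m in zip(np.asarray(xs_m), np.asarray(ys_m), np.asarray(radii_m)):
        cx = x_m / pixel_size - 0.5  # pixel-center coordinates
        cy = y_m / pixel_size - 0.5
        r = r_m / pixel_size
        c0 = max(0, int(math.floor(cx - r - 1)))
        c1 = min(w, int(math.ceil(cx + r + 2)))
        r0 = max(0, int(math.floor(cy - r - 1)))
        r1 = min(h, int(math.ceil(cy + r + 2)))
        if c0 >= c1 or r0 >= r1:
            continue
        cols = np.arange(c0, c1)
        rows = np.arange(r0, r1)
        dist = np.hypot(cols[None, :] - cx, rows[:, None] - cy)
        canvas[r0:r1, c0:c1] += np.clip(r + 0.5 - dist, 0.0, 1.0)


def render_channels(truth: GroundTruth, spec: ArraySpec) -> SceneImage:
    """Render noiseless dextran and DNA channels as float32 images."""
    shape = spec.grid_shape
    drop_cov = np.zeros(shape, dtype=np.float64)
    _accumulate_discs(
        drop_cov,
        truth.wells["cx_m"],
        truth.wells["cy_m"],
        truth.wells["droplet_r_m"],
        spec.pixel_size,
    )
    np.clip(drop_cov, 0.0, 1.0, out=drop_cov)

    part_cov = np.zeros(shape, dtype=np.float64)
    if len(truth.particles):
        _accumulate_discs(
            part_cov,
            truth.particles["px_m"],
            truth.particles["py_m"],
            truth.particles["r_m"],
            spec.pixel_size,
        )
        np.clip(part_cov, 0.0, 1.0, out=part_cov)

    ints = spec.intensities
    dex = ints.dex_background + (ints.dex_droplet - ints.dex_background) * drop_cov
    dna = (
        ints.dna_background
        + (ints.dna_droplet - ints.dna_background) * drop_cov
        + (ints.dna_particle - ints.dna_background) * part_cov
    )
    return SceneImage(dextran=dex.astype(np.float32), dna=dna.astype(np.float32))


def add_noise(image: np.ndarray, spec: ArraySpec, stream: int = 0) -> np.ndarray:
    """Apply the spec's noise model; seeded, clipped at zero.

    ``stream`` decorrelates the noise of different channels of the same
    scene while staying reproducible from ``spec.seed``.
    """
    if spec.noise.gaussian_sd < 0:
        raise ValueError("gaussian_sd must be >= 0")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(1000 + stream,))
    )
    out = np.asarray(image, dtype=np.float64)
    if spec.noise.shot_noise:
        out = rng.poisson(np.clip(out, 0, None)).astype(np.float64)
    if spec.noise.gaussian_sd > 0:
        out = out + rng.normal(0.0, spec.noise.gaussian_sd, size=out.shape)
    return np.clip(out, 0.0, None).astype(np.float32)


def write_dataset(
    image: SceneImage, truth: GroundTruth, spec: ArraySpec, path_prefix: str | Path
) -> dict[str, Path]:
    """Write the scene: one TIFF per channel, truth CSV, spec JSON.

    Output is byte-stable for identical inputs. The truth CSV has one row
    per (well, particle) pair in micrometers; particle columns are empty
    for unoccupied wells.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "dex": prefix.parent / (prefix.name + "_dex.tif"),
        "dna": prefix.parent / (prefix.name + "_dna.tif"),
        "truth": prefix.parent / (prefix.name + "_truth.csv"),
        "spec": prefix.parent / (prefix.name + "_spec.json"),
    }
    tifffile.imwrite(paths["dex"], image.dextran, photometric="minisblack")
    tifffile.imwrite(paths["dna"], image.dna, photometric="minisblack")

    wells_um = truth.wells.copy()
    for col in ("cx_m", "cy_m", "droplet_r_m"):
        wells_um[col.replace("_m", "_um")] = wells_um[col] / M_PER_UM
    parts_um = truth.particles.copy()
    for col in ("px_m", "py_m", "r_m"):
        parts_um[col.replace("_m", "_um") if col != "r_m" else "particle_r_um"] = (
            parts_um[col] / M_PER_UM
        )
    merged = wells_um.merge(parts_um, on="well_id", how="left")
    merged = merged.rename(columns={"cx_um": "cx_um", "cy_um": "cy_um", "droplet_r_um": "droplet_r_um"})
    out = merged[
        ["well_id", "cx_um", "cy_um", "droplet_r_um", "particle_id", "px_um", "py_um", "particle_r_um"]
    ]
    out.to_csv(paths["truth"], index=False, float_format="%.6f", lineterminator="\n")
    paths["spec"].write_text(json.dumps(spec.to_json_dict(), indent=2, sort_keys=True) + "\n")
    return paths


def read_dataset(path_prefix: str | Path) -> tuple[SceneImage, GroundTruth, ArraySpec]:
    """Read back a dataset written by :func:`write_dataset`."""
    prefix = Path(path_prefix)
    dex = tifffile.imread(prefix.parent / (prefix.name + "_dex.tif"))
    dna = tifffile.imread(prefix.parent / (prefix.name + "_dna.tif"))
    spec = ArraySpec.from_json_dict(
        json.loads((prefix.parent / (prefix.name + "_spec.json")).read_text())
    )
    table = pd.read_csv(prefix.parent / (prefix.name + "_truth.csv"))
    wells = (
        table[["well_id", "cx_um", "cy_um", "droplet_r_um"]]
        .drop_duplicates("well_id")
        .reset_index(drop=True)
    )
    wells = pd.DataFrame(
        {
            "well_id": wells["well_id"].astype(int),
            "cx_m": wells["cx_um"] * M_PER_UM,
            "cy_m": wells["cy_um"] * M_PER_UM,
            "droplet_r_m": wells["droplet_r_um"] * M_PER_UM,
        }
    )
    parts = table.dropna(subset=["particle_id"])
    particles = pd.DataFrame(
        {
            "particle_id": parts["particle_id"].astype(int).to_numpy(),
            "well_id": parts["well_id"].astype(int).to_numpy(),
            "px_m": parts["px_um"].to_numpy() * M_PER_UM,
            "py_m": parts["py_um"].to_numpy() * M_PER_UM,
            "r_m": parts["particle_r_um"].to_numpy() * M_PER_UM,
        }
    )
    return SceneImage(dex, dna), GroundTruth(wells, particles), spec


PRESET_NAMES = ("microwell_50", "microwell_100", "single_phase", "two_phase_bulk")


def scene_preset(name: str, seed: int = 0, noise: NoiseModel | None = None) -> ArraySpec:
    """Parameter bundles for the canonical imaging conditions.

    * ``microwell_50`` — 50-um wells, tight droplet sizes, ~one rim particle
      per well.
    * ``microwell_100`` — 100-um wells whose droplets underfill the well
      (70-90 um across) and spread more, larger particles.
    * ``single_phase`` — bulk dextran: many small particles over a high
      unbound-DNA background (no real well structure to resolve).
    * ``two_phase_bulk`` — agitation emulsion: strongly polydisperse
      droplets and particles.
    """
    noise = noise or NoiseModel()
    if name == "microwell_50":
        return ArraySpec(
            lattice_pitch=100e-6,
            well_diameter=50e-6,
            droplet_radius_distribution=(24e-6, 1.0e-6),
            particle_count_distribution={0: 0.02, 1: 0.93, 2: 0.05},
            particle_radius_distribution=(5.4e-6, 0.6e-6),
            particle_placement="rim",
            noise=noise,
            seed=seed,
        )
    if name == "microwell_100":
        return ArraySpec(
            lattice_pitch=200e-6,
            well_diameter=100e-6,
            droplet_radius_distribution=(40e-6, 5.0e-6),
            particle_count_distribution={0: 0.02, 1: 0.93, 2: 0.05},
            particle_radius_distribution=(7.0e-6, 1.5e-6),
            particle_placement="rim",
            noise=noise,
            seed=seed,
        )
    if name == "single_phase":
        return ArraySpec(
            lattice_pitch=100e-6,
            well_diameter=90e-6,
            droplet_radius_distribution=(44e-6, 1.0e-6),
            particle_count_distribution={3: 0.3, 4: 0.4, 5: 0.3},
            particle_radius_distribution=(1.8e-6, 0.3e-6),
            particle_placement="rim",
            intensities=ChannelIntensities(dna_droplet=90.0),  # strong unbound signal
            noise=noise,
            seed=seed,
        )
    if name == "two_phase_bulk":
        return ArraySpec(
            lattice_pitch=150e-6,
            well_diameter=140e-6,
            droplet_radius_distribution=(40e-6, 15e-6),
            particle_count_distribution={1: 0.6, 2: 0.4},
            particle_radius_distribution=(6.0e-6, 2.5e-6),
            particle_placement="rim",
            noise=noise,
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
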