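"""Fluorescence-image quantification of droplets and hydrogel particles.

Mirrors a classic ImageJ "Analyze Particles" workflow: apply one global
threshold per channel (a pixel equal to the threshold counts as
foreground), label connected components (8-connectivity by default),
discard components below a physical area cutoff of 1 um^2 to suppress
noise, and convert each remaining component's area to an equivalent
projected-circle radius r = sqrt(A / pi). The same radius formula applies
to both channels: a cylindrical droplet seen from above and a spherical
particle both project to a disc.

The per-well statistic "particles per well" is the number of detected
DNA-channel particles divided by the number of detected dextran droplets
in the same field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops

__all__ = [
    "ParticleRecord",
    "SummaryStats",
    "RecoveryReport",
    "auto_threshold",
    "segment",
    "measure",
    "radius_from_area",
    "particles_per_well",
    "summarize",
    "match_to_truth",
    "records_to_frame",
]


@dataclass(frozen=True)
class ParticleRecord:
    """One segmented object with measurements in physical units (um)."""

    label: int
    pixel_count: int
    area_um2: float
    radius_um: float
    centroid_um: tuple[float, float]  # (x, y)
    channel: str = "dna"


@dataclass(frozen=True)
class SummaryStats:
    """Distribution summary of detected radii; NaN marks undefined stats."""

    n: int
    mean_radius_um: float
    sd_radius_um: float
    particles_per_well: float = float("nan")


@dataclass(frozen=True)
class RecoveryReport:
    """Detection-vs-truth matching result."""

    n_truth: int
    n_detected: int
    n_matched: int
    precision: float
    recall: float
    matches: pd.DataFrame = field(repr=False)  # truth_idx, det_idx, dist_um, radius_error_um

    @property
    def mean_abs_radius_error_um(self) -> float:
        if self.n_matched == 0:
            return float("nan")
        return float(self.matches["radius_error_um"].abs().mean())

    @property
    def matched_mean_radius_um(self) -> float:
        if self.n_matched == 0:
            return float("nan")
        return float(self.matches["detected_radius_um"].mean())


def auto_threshold(image: np.ndarray) -> float:
    """Global Otsu threshold on the channel histogram."""
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("cannot threshold an empty image")
    return float(threshold_otsu(image))


def segment(
    channel_image: np.ndarray,
    threshold: float | None = None,
    connectivity: int = 8,
) -> np.ndarray:
    """Threshold and label one channel.

    Foreground is ``pixel >= threshold`` (``threshold=None`` selects Otsu's
    value). Components are labelled 1..n in raster order of their first
    pixel, which makes labelling deterministic.
    """
    image = np.asarray(channel_image)
    if image.size == 0:
        raise ValueError("cannot segment an empty image")
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    thr = auto_threshold(image) if threshold is None else float(threshold)
    mask = image >= thr
    return sk_label(mask, connectivity=1 if connectivity == 4 else 2)


def radius_from_area(area_um2: float, mode: str = "projected_circle") -> float:
    """Equivalent radius of a projected circle of the given area."""
    if mode != "projected_circle":
        raise ValueError(f"unknown mode {mode!r}")
    if area_um2 < 0:
        raise ValueError(f"area must be >= 0, got {area_um2}")
    return math.sqrt(area_um2 / math.pi)


def measure(
    labels: np.ndarray,
    pixel_size_um: float,
    min_area_um2: float = 1.0,
    channel: str = "dna",
) -> list[ParticleRecord]:
    """Per-component measurements, dropping objects below ``min_area_um2``.

    Centroids use the pixel-center convention, physical = (index + 0.5) *
    pixel_size, matching the synthetic generator's coordinates.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    px_area = pixel_size_um**2
    out: list[ParticleRecord] = []
    for prop in regionprops(np.asarray(labels)):
        area = prop.num_pixels * px_area
        if area < min_area_um2:
            continue
        row_c, col_c = prop.centroid
        out.append(
            ParticleRecord(
                label=int(prop.label),
                pixel_count=int(prop.num_pixels),
                area_um2=float(area),
                radius_um=radius_from_area(area),
                centroid_um=((col_c + 0.5) * pixel_size_um, (row_c + 0.5) * pixel_size_um),
                channel=channel,
            )
        )
    return out


def particles_per_well(
    dna_records: Sequence[ParticleRecord], dextran_records: Sequence[ParticleRecord]
) -> float:
    """DNA particle count divided by dextran droplet count."""
    if len(dextran_records) == 0:
        raise ValueError("no dextran droplets detected; particles-per-well undefined")
    return len(dna_records) / len(dextran_records)


def summarize(
    records: Sequence[ParticleRecord], particles_per_well_value: float = float("nan")
) -> SummaryStats:
    """Mean and sample standard deviation (n-1) of detected radii."""
    radii = np.array([r.radius_um for r in records], dtype=float)
    n = radii.size
    mean = float(radii.mean()) if n else float("nan")
    sd = float(radii.std(ddof=1)) if n > 1 else float("nan")
    return SummaryStats(
        n=int(n),
        mean_radius_um=mean,
        sd_radius_um=sd,
        particles_per_well=particles_per_well_value,
    )


def match_to_truth(
    records: Sequence[ParticleRecord],
    truth_table_um: pd.DataFrame,
    max_dist_um: float,
) -> RecoveryReport:
    """Greedy nearest-centroid matching of detections to ground truth.

    ``truth_table_um`` needs columns ``x_um``, ``y_um``, ``r_um``. Candidate
    pairs within ``max_dist_um`` are assigned closest-first, each truth
    object and each detection at most once; the result is independent of
    the input record order.
    """
    n_truth = len(truth_table_um)
    n_det = len(records)
    cols = ["truth_idx", "det_idx", "dist_um", "true_radius_um", "detected_radius_um", "radius_error_um"]
    if n_truth == 0 or n_det == 0:
        matches = pd.DataFrame(columns=cols)
        return RecoveryReport(
            n_truth=n_truth,
            n_detected=n_det,
            n_matched=0,
            precision=0.0 if n_det else float("nan"),
            recall=0.0 if n_truth else float("nan"),
            matches=matches,
        )
    det_xy = np.array([r.centroid_um for r in records])
    det_r = np.array([r.radius_um for r in records])
    truth_xy = truth_table_um[["x_um", "y_um"]].to_numpy(dtype=float)
    truth_r = truth_table_um["r_um"].to_numpy(dtype=float)
    dists = np.hypot(
        truth_xy[:, None, 0] - det_xy[None, :, 0],
        truth_xy[:, None, 1] - det_xy[None, :, 1],
    )
    ti, di = np.nonzero(dists <= max_dist_um)
    # closest-first greedy; ties broken by (truth, detection) index for determinism
    order = np.lexsort((di, ti, dists[ti, di]))
    used_t: set[int] = set()
    used_d: set[int] = set()
    rows = []
    for idx in order:
        t, d = int(ti[idx]), int(di[idx])
        if t in used_t or d in used_d:
            continue
        used_t.add(t)
        used_d.add(d)
        rows.append(
            {
                "truth_idx": t,
                "det_idx": d,
                "dist_um": float(dists[t, d]),
                "true_radius_um": float(truth_r[t]),
                "detected_radius_um": float(det_r[d]),
                "radius_error_um": float(det_r[d] - truth_r[t]),
            }
        )
    matches = pd.DataFrame(rows, columns=cols)
    n_matched = len(matches)
    return RecoveryReport(
        n_truth=n_truth,
        n_detected=n_det,
        n_matched=n_matched,
        precision=n_matched / n_det,
        recall=n_matched / n_truth,
        matches=matches,
    )


def records_to_frame(records: Iterable[ParticleRecord]) -> pd.DataFrame:
    """Tabulate records with the CSV column layout used by the CLI."""
    return pd.DataFrame(
        [
            {
                "channel": r.channel,
                "label": r.label,
                "pixel_count": r.pixel_count,
                "area_um2": r.area_um2,
                "radius_um": r.radius_um,
                "cx_um": r.centroid_um[0],
                "cy_um": r.centroid_um[1],
            }
            for r in records
        ],
        columns=["channel", "label", "pixel_count", "area_um2", "radius_um", "cx_um", "cy_um"],
    )
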