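"""Chromatographic fingerprint handling.

Peak detection, cross-sample peak matching on retention time, construction of
the simulative median reference chromatogram, cosine similarity indexing
against that reference, and identification of common peaks (those detected in
every sample of a cohort).  This is the front end of the spectrum-effect
workflow: it turns per-sample HPLC-DAD traces into the samples x peaks area
matrix that the regression models consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks


@dataclass(frozen=True)
class Chromatogram:
    """A single-wavelength HPLC-DAD trace for one sample.

    ``time`` is in minutes and must be strictly increasing; ``intensity`` is
    in mAU on the same grid.
    """

    sample_id: str
    time: np.ndarray
    intensity: np.ndarray
    wavelength: float = 280.0

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "intensity", intensity)
        if time.ndim != 1 or time.size == 0:
            raise ValueError("time grid must be a non-empty 1-D array")
        if np.any(np.diff(time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if intensity.shape != time.shape:
            raise ValueError("time and intensity must have the same length")
        if not np.all(np.isfinite(intensity)):
            raise ValueError("intensities must be finite")


@dataclass(frozen=True)
class Peak:
    """One detected chromatographic peak (times in minutes, area in mAU*min)."""

    retention_time: float
    height: float
    area: float
    left: float
    right: float

    def __post_init__(self) -> None:
        if not (self.left < self.retention_time < self.right):
            raise ValueError("peak bounds must bracket the apex")
        if self.area < 0:
            raise ValueError("peak area must be non-negative")


@dataclass
class PeakTable:
    """Samples x matched-peaks area matrix with consensus retention times.

    ``areas`` holds one row per sample and one column per matched peak; a NaN
    entry marks a peak absent from that sample (never encoded as zero, so that
    "common peak" stays well defined).  ``consensus_rt`` gives the per-column
    consensus retention time, strictly increasing left to right.
    """

    areas: pd.DataFrame
    consensus_rt: pd.Series

    def __post_init__(self) -> None:
        if list(self.areas.columns) != list(self.consensus_rt.index):
            raise ValueError("areas columns and consensus_rt index must match")
        rts = self.consensus_rt.to_numpy(dtype=float)
        if rts.size > 1 and np.any(np.diff(rts) <= 0):
            raise ValueError("consensus retention times must be strictly increasing")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.areas.index)

    @property
    def peak_ids(self) -> list[str]:
        return list(self.areas.columns)

    def to_csv(self, path) -> None:
        out = self.areas.copy()
        out.loc["consensus_rt"] = self.consensus_rt
        out.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path) -> "PeakTable":
        df = pd.read_csv(path, index_col="sample_id")
        rt = df.loc["consensus_rt"]
        areas = df.drop(index="consensus_rt")
        return cls(areas=areas.astype(float), consensus_rt=rt.astype(float))


@dataclass(frozen=True)
class SimilarityResult:
    sample_id: str
    similarity: float


def detect_peaks(
    chrom: Chromatogram,
    min_height: float = 1.0,
    min_prominence: float = 1.0,
) -> list[Peak]:
    """Find local maxima above height and prominence thresholds.

    Peak bounds are the flanking minima delimiting each peak's prominence
    base; the area is the trapezoidal integral of the trace between them.
    """
    if min_height < 0 or min_prominence < 0:
        raise ValueError("thresholds must be non-negative")
    if chrom.time.size < 3:
        raise ValueError("chromatogram must have at least 3 points")
    idx, props = find_peaks(
        chrom.intensity, height=min_height, prominence=min_prominence
    )
    peaks: list[Peak] = []
    for k, i in enumerate(idx):
        lo = int(props["left_bases"][k])
        hi = int(props["right_bases"][k])
        area = float(
            np.trapezoid(chrom.intensity[lo : hi + 1], chrom.time[lo : hi + 1])
        )
        peaks.append(
            Peak(
                retention_time=float(chrom.time[i]),
                height=float(chrom.intensity[i]),
                area=max(area, 0.0),
                left=float(chrom.time[lo]),
                right=float(chrom.time[hi]),
            )
        )
    return peaks


def match_peaks(
    per_sample_peaks: Sequence[Sequence[Peak]],
    rt_tolerance: float = 0.2,
    sample_ids: Sequence[str] | None = None,
) -> PeakTable:
    """Match peaks across samples into columns by retention-time proximity.

    Greedy agglomeration ordered by peak height: tall peaks seed clusters
    first, and each subsequent peak joins the nearest cluster whose running
    mean retention time lies within ``rt_tolerance`` and which does not yet
    hold a peak from the same sample; otherwise it opens a new cluster.
    Deterministic for a fixed input order.
    """
    if rt_tolerance <= 0:
        raise ValueError("rt_tolerance must be positive")
    if len(per_sample_peaks) == 0:
        raise ValueError("no samples to match")
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(len(per_sample_peaks))]

    entries = [
        (p.height, p.retention_time, si, p)
        for si, plist in enumerate(per_sample_peaks)
        for p in plist
    ]
    # tallest first; rt then sample index break ties deterministically
    entries.sort(key=lambda t: (-t[0], t[1], t[2]))

    clusters: list[dict] = []  # {"rt_sum", "n", "members": {sample_idx: Peak}}
    for _, rt, si, peak in entries:
        best = None
        best_dist = rt_tolerance
        for c in clusters:
            if si in c["members"]:
                continue
            dist = abs(rt - c["rt_sum"] / c["n"])
            if dist <= best_dist:
                best, best_dist = c, dist
        if best is None:
            clusters.append({"rt_sum": rt, "n": 1, "members": {si: peak}})
        else:
            best["rt_sum"] += rt
            best["n"] += 1
            best["members"][si] = peak

    clusters.sort(key=lambda c: c["rt_sum"] / c["n"])
    n_samples = len(per_sample_peaks)
    width = max(2, len(str(len(clusters))))
    peak_ids = [f"P{k + 1:0{width}d}" for k in range(len(clusters))]
    areas = np.full((n_samples, len(clusters)), np.nan)
    rts = np.empty(len(clusters))
    for j, c in enumerate(clusters):
        rts[j] = c["rt_sum"] / c["n"]
        for si, peak in c["members"].items():
            areas[si, j] = peak.area
    return PeakTable(
        areas=pd.DataFrame(areas, index=list(sample_ids), columns=peak_ids),
        consensus_rt=pd.Series(rts, index=peak_ids, name="consensus_rt"),
    )


def _shared_grid(chroms: Sequence[Chromatogram]) -> np.ndarray:
    grid = chroms[0].time
    for c in chroms[1:]:
        if c.time.shape != grid.shape or not np.allclose(c.time, grid):
            raise ValueError(
                "chromatograms are on different time grids; resample first "
                "(see resample_chromatograms)"
            )
    return grid


def resample_chromatograms(
    chroms: Sequence[Chromatogram], grid: np.ndarray | None = None
) -> list[Chromatogram]:
    """Linearly interpolate all traces onto one grid.

    Default grid: the union of all time points clipped to the overlapping
    time range of the inputs.
    """
    if len(chroms) == 0:
        raise ValueError("no chromatograms to resample")
    if grid is None:
        lo = max(c.time[0] for c in chroms)
        hi = min(c.time[-1] for c in chroms)
        if hi <= lo:
            raise ValueError("chromatograms have no overlapping time range")
        union = np.unique(np.concatenate([c.time for c in chroms]))
        grid = union[(union >= lo) & (union <= hi)]
    grid = np.asarray(grid, dtype=float)
    return [
        Chromatogram(
            sample_id=c.sample_id,
            time=grid,
            intensity=np.interp(grid, c.time, c.intensity),
            wavelength=c.wavelength,
        )
        for c in chroms
    ]


def median_reference(chroms: Sequence[Chromatogram]) -> Chromatogram:
    """Pointwise median trace (the simulative median chromatogram).

    For an even number of samples the mean of the two middle values is used.
    """
    if len(chroms) == 0:
        raise ValueError("no chromatograms supplied")
    grid = _shared_grid(chroms)
    stack = np.vstack([c.intensity for c in chroms])
    return Chromatogram(
        sample_id="median_reference",
        time=grid,
        intensity=np.median(stack, axis=0),
        wavelength=chroms[0].wavelength,
    )


def similarity_index(
    sample: Chromatogram, reference: Chromatogram, mode: str = "cosine"
) -> SimilarityResult:
    """Similarity of a sample trace to the reference.

    ``cosine`` is the congruence coefficient (dot product over norms),
    invariant to positive rescaling of either trace; ``correlation`` is the
    Pearson coefficient on the mean-centered traces.
    """
    _shared_grid([sample, reference])
    x = sample.intensity.astype(float)
    y = reference.intensity.astype(float)
    if mode == "correlation":
        x = x - x.mean()
        y = y - y.mean()
    elif mode != "cosine":
        raise ValueError(f"unknown similarity mode {mode!r}")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("similarity undefined for a zero-norm intensity vector")
    sim = float(np.clip(np.dot(x, y) / (nx * ny), -1.0, 1.0))
    return SimilarityResult(sample_id=sample.sample_id, similarity=sim)


def similarity_report(
    chroms: Sequence[Chromatogram],
    reference: Chromatogram | None = None,
    mode: str = "cosine",
) -> pd.DataFrame:
    """Similarity of every sample against the (median) reference as a table."""
    if reference is None:
        reference = median_reference(chroms)
    rows = [similarity_index(c, reference, mode=mode) for c in chroms]
    return pd.DataFrame(
        {"sample_id": [r.sample_id for r in rows],
         "similarity": [r.similarity for r in rows]}
    )


def common_peaks(table: PeakTable) -> list[str]:
    """Peak ids detected in every sample (columns with no missing entry)."""
    mask = table.areas.notna().all(axis=0)
    return [pid for pid in table.peak_ids if mask[pid]]


def read_chromatograms_csv(path) -> list[Chromatogram]:
    """Read long-format chromatograms (sample_id, time_min, intensity_mau)."""
    df = pd.read_csv(path)
    chroms = []
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("time_min")
        chroms.append(
            Chromatogram(
                sample_id=str(sid),
                time=grp["time_min"].to_numpy(float),
                intensity=grp["intensity_mau"].to_numpy(float),
            )
        )
    return chroms


def write_chromatograms_csv(chroms: Iterable[Chromatogram], path) -> None:
    frames = [
        pd.DataFrame(
            {"sample_id": c.sample_id, "time_min": c.time, "intensity_mau": c.intensity}
        )
        for c in chroms
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
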