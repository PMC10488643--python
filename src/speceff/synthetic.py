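"""Seeded synthetic cohorts with known ground truth.

The study this package emulates compared wild chrysanthemum (YJH,
Chrysanthemum indicum L.) against cultivated Flos Chrysanthemum (JH):
16 batches, two sample classes, a shared set of 16 common chromatographic
peaks, class-specific extra peaks (many low-abundance ones in YJH, fewer
high-abundance ones in JH), bioactivity endpoints driven by a small subset
of common peaks, 4PL dose-response curves, CAA fluorescence kinetics, and
two-group metabolomics feature tables.  Because the study's raw data are
unreleased, every generator here produces data with those structural
features plus an explicit truth record, so each downstream stage can be
tested against a known answer.

Peak areas are log-normal within class (a standing assumption: the source
gives no distributional information), peaks are symmetric Gaussians, and
retention times receive a per-sample Gaussian jitter so peak matching is
non-trivially exercised.  All randomness flows through one seeded generator
per call; nothing touches global random state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bioassay import DoseResponseData, four_pl, CAAKinetics
from .fingerprint import Chromatogram, PeakTable
from .metabolomics import FeatureTable

GAUSS_AREA = np.sqrt(2.0 * np.pi)  # area of a unit-height, unit-sigma Gaussian


@dataclass(frozen=True)
class PeakSpec:
    """Design of one synthetic chromatographic peak.

    ``group_mean_area`` maps each class that carries this peak to its mean
    area (mAU*min); ``group_cv`` the within-class coefficient of variation
    of the log-normal area distribution.
    """

    retention_time: float
    height: float
    width_sigma: float
    group_mean_area: Mapping[str, float] = field(default_factory=dict)
    group_cv: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.retention_time <= 0:
            raise ValueError("retention time must be positive")
        if self.width_sigma <= 0:
            raise ValueError("peak width must be positive")
        if self.height < 0 or any(v < 0 for v in self.group_mean_area.values()):
            raise ValueError("heights and areas must be non-negative")


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort.

    Causal peaks are always a subset of the common peaks, mirroring the
    marker-search assumption that candidate markers are common peaks.
    """

    causal_peak_indices: list[int]
    causal_weights: list[float]
    common_peak_indices: list[int]
    class_labels: list[str]
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if not set(self.causal_peak_indices) <= set(self.common_peak_indices):
            raise ValueError("causal peaks must be a subset of the common peaks")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def simulate_chromatogram(
    peaks: Sequence[PeakSpec] | Sequence[tuple],
    grid: np.ndarray,
    baseline_drift: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_id: str = "sim",
    heights: Sequence[float] | None = None,
) -> Chromatogram:
    """Render Gaussian peaks onto a time grid with drift and iid noise.

    intensity(t) = sum_k h_k * exp(-(t - rt_k)^2 / (2 sigma_k^2))
                   + baseline_drift * t + N(0, noise_sd^2)

    ``heights`` overrides each PeakSpec's nominal height (used when a
    sample's peak area, hence height, is drawn per sample).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("time grid must be non-empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("time grid must be strictly increasing")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    intensity = baseline_drift * grid.astype(float).copy()
    for k, p in enumerate(peaks):
        h = p.height if heights is None else heights[k]
        intensity = intensity + h * np.exp(
            -((grid - p.retention_time) ** 2) / (2.0 * p.width_sigma**2)
        )
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=grid.size)
    return Chromatogram(sample_id=sample_id, time=grid, intensity=intensity)


def default_peak_library(
    common_count: int = 16,
    class_extra_peaks: Mapping[str, int] | None = None,
    rt_start: float = 5.0,
    rt_end: float = 70.0,
    width_sigma: float = 0.12,
    cv: float = 0.4,
    common_mean_area: float = 60.0,
    jh_abundance_ratio: float = 1.3,
    extra_mean_area: Mapping[str, float] | None = None,
    seed: int = 0,
) -> list[PeakSpec]:
    """Build a peak library with shared and class-specific peaks.

    Common peaks carry areas in both classes, with the JH-like class
    ``jh_abundance_ratio`` times more abundant (cultivated samples show
    fewer but larger peaks).  Class-specific extras appear only in their
    class: many low-abundance peaks for YJH-like samples, few higher ones
    for JH-like.  Retention times are evenly spread with a small seeded
    perturbation, spaced widely enough that peaks do not overlap.
    """
    if class_extra_peaks is None:
        class_extra_peaks = {"YJH": 10, "JH": 2}
    if extra_mean_area is None:
        extra_mean_area = {"YJH": 20.0, "JH": 80.0}
    rng = np.random.default_rng(seed)
    total = common_count + sum(class_extra_peaks.values())
    slots = np.linspace(rt_start, rt_end, total)
    step = (rt_end - rt_start) / max(total - 1, 1)
    rts = slots + rng.uniform(-0.15, 0.15, size=total) * step
    order = rng.permutation(total)

    library: list[PeakSpec] = []
    pos = 0
    for _ in range(common_count):
        rt = float(rts[order[pos]])
        pos += 1
        mean_yjh = float(common_mean_area * rng.uniform(0.5, 1.5))
        library.append(
            PeakSpec(
                retention_time=rt,
                height=mean_yjh / (width_sigma * GAUSS_AREA),
                width_sigma=width_sigma,
                group_mean_area={"YJH": mean_yjh, "JH": mean_yjh * jh_abundance_ratio},
                group_cv={"YJH": cv, "JH": cv},
            )
        )
    for cls, count in class_extra_peaks.items():
        base = extra_mean_area.get(cls, 30.0)
        for _ in range(count):
            rt = float(rts[order[pos]])
            pos += 1
            mean = float(base * rng.uniform(0.5, 1.5))
            library.append(
                PeakSpec(
                    retention_time=rt,
                    height=mean / (width_sigma * GAUSS_AREA),
                    width_sigma=width_sigma,
                    group_mean_area={cls: mean},
                    group_cv={cls: cv},
                )
            )
    library.sort(key=lambda p: p.retention_time)
    return library


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    if mean == 0:
        return 0.0
    if cv <= 0:
        return mean
    sigma2 = np.log(1.0 + cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def simulate_cohort(
    n_per_class: Mapping[str, int] | None = None,
    peak_library: Sequence[PeakSpec] | None = None,
    common_count: int = 16,
    class_extra_peaks: Mapping[str, int] | None = None,
    seed: int = 0,
    n_causal: int = 3,
    noise_sd: float = 0.1,
    causal_latent_sd: float = 0.8,
    rt_jitter_sd: float = 0.05,
    grid: np.ndarray | None = None,
    chromatogram_noise_sd: float = 0.3,
    baseline_drift: float = 0.0,
    with_chromatograms: bool = True,
) -> tuple[list[Chromatogram], PeakTable, CohortTruth]:
    """Simulate a two-class cohort with known common and causal peaks.

    Returns the per-sample chromatograms (empty list when
    ``with_chromatograms`` is False), the ground-truth peak-area table
    (NaN where a class does not carry a peak) and the truth record.  Causal
    peaks are drawn among the common peaks with positive weights
    U(0.8, 1.5); ``noise_sd`` is the response-scale noise later applied by
    :func:`simulate_bioactivity`.

    The causal peaks share a per-sample latent activity factor with log-scale
    loading ``causal_latent_sd``: bioactive compounds of one biosynthetic
    family co-vary across batches, so the peaks that drive the response are
    mutually correlated rather than independent.  This is what makes each
    individual marker's abundance track the activity strongly (generous
    signal-to-noise); set ``causal_latent_sd=0`` for fully independent areas.
    """
    if n_per_class is None:
        n_per_class = {"YJH": 8, "JH": 8}
    if any(c < 1 for c in n_per_class.values()):
        raise ValueError("every class needs at least one sample")
    if class_extra_peaks is None:
        class_extra_peaks = {"YJH": 10, "JH": 2}
    rng = np.random.default_rng(seed)
    if peak_library is None:
        peak_library = default_peak_library(
            common_count=common_count,
            class_extra_peaks=class_extra_peaks,
            seed=int(rng.integers(2**31)),
        )
    classes = list(n_per_class)
    common_idx = [
        i for i, p in enumerate(peak_library)
        if all(c in p.group_mean_area for c in classes)
    ]
    if len(common_idx) < common_count:
        raise ValueError(
            f"peak library has only {len(common_idx)} peaks shared by all "
            f"classes; {common_count} requested"
        )
    if n_causal > len(common_idx):
        raise ValueError("cannot have more causal peaks than common peaks")
    causal_idx = sorted(rng.choice(common_idx, size=n_causal, replace=False).tolist())
    causal_w = rng.uniform(0.8, 1.5, size=n_causal).tolist()
    causal_set = set(causal_idx)

    sample_ids: list[str] = []
    labels: list[str] = []
    for cls in classes:
        for k in range(n_per_class[cls]):
            sample_ids.append(f"{cls}{k + 1:02d}")
            labels.append(cls)

    n_peaks = len(peak_library)
    areas = np.full((len(sample_ids), n_peaks), np.nan)
    chroms: list[Chromatogram] = []
    if grid is None:
        grid = np.arange(0.0, 75.0 + 1e-9, 0.02)
    latent = rng.normal(0.0, 1.0, size=len(sample_ids))
    for si, (sid, cls) in enumerate(zip(sample_ids, labels)):
        shift = rng.normal(0.0, rt_jitter_sd)
        present: list[PeakSpec] = []
        heights: list[float] = []
        for j, p in enumerate(peak_library):
            if cls not in p.group_mean_area:
                continue
            area = _lognormal(rng, p.group_mean_area[cls], p.group_cv.get(cls, 0.0))
            if j in causal_set and causal_latent_sd > 0:
                # mean-preserving latent-factor modulation of the causal family
                area *= np.exp(
                    causal_latent_sd * latent[si] - causal_latent_sd**2 / 2.0
                )
            areas[si, j] = area
            present.append(
                PeakSpec(
                    retention_time=p.retention_time + shift,
                    height=p.height,
                    width_sigma=p.width_sigma,
                )
            )
            heights.append(area / (p.width_sigma * GAUSS_AREA))
        if with_chromatograms:
            chroms.append(
                simulate_chromatogram(
                    present,
                    grid,
                    baseline_drift=baseline_drift,
                    noise_sd=chromatogram_noise_sd,
                    seed=int(rng.integers(2**31)),
                    sample_id=sid,
                    heights=heights,
                )
            )

    width = max(2, len(str(n_peaks)))
    peak_ids = [f"P{j + 1:0{width}d}" for j in range(n_peaks)]
    table = PeakTable(
        areas=pd.DataFrame(areas, index=sample_ids, columns=peak_ids),
        consensus_rt=pd.Series(
            [p.retention_time for p in peak_library], index=peak_ids,
            name="consensus_rt",
        ),
    )
    truth = CohortTruth(
        causal_peak_indices=causal_idx,
        causal_weights=causal_w,
        common_peak_indices=common_idx,
        class_labels=labels,
        noise_sd=noise_sd,
        seed=seed,
    )
    return chroms, table, truth


def simulate_bioactivity(
    peak_table: PeakTable,
    truth: CohortTruth,
    endpoints: Sequence[str] = (
        "dpph", "abts", "frap", "caa_unit", "glucosidase_inhibition",
        "lipase_inhibition",
    ),
    link: str | None = None,
) -> pd.DataFrame:
    """Bioactivity endpoints driven by the cohort's causal peak areas.

    Each endpoint is an affine function of the shared causal signal — the
    weighted sum of the standardized causal peak areas — plus Gaussian noise
    with sd ``truth.noise_sd``; all endpoints share the causal signal the
    way the study's correlated activity panel does.  With ``noise_sd = 0``
    and no link the response is exactly linear in the causal areas.
    ``link="sigmoid"`` passes the signal through a logistic saturation.
    """
    X = peak_table.areas.to_numpy(dtype=float)
    n_peaks = X.shape[1]
    if any(not 0 <= i < n_peaks for i in truth.causal_peak_indices):
        raise IndexError("causal peak index out of range for this peak table")
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 915]))
    causal = X[:, truth.causal_peak_indices]
    mean = causal.mean(axis=0)
    sd = causal.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    signal = (causal - mean) / sd @ np.asarray(truth.causal_weights)
    if link == "sigmoid":
        signal = 1.0 / (1.0 + np.exp(-signal))
    elif link is not None:
        raise ValueError(f"unknown link {link!r}")
    out = {}
    for e in endpoints:
        beta = rng.uniform(0.8, 1.2)
        alpha = rng.uniform(-0.5, 0.5)
        noise = (
            rng.normal(0.0, truth.noise_sd, size=len(signal))
            if truth.noise_sd > 0 else 0.0
        )
        out[e] = alpha + beta * signal + noise
    return pd.DataFrame(out, index=peak_table.sample_ids)


def simulate_dose_response(
    ec50: float,
    hill: float = 1.0,
    floor: float = 0.0,
    ceiling: float = 100.0,
    doses: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DoseResponseData:
    """4PL responses at the given doses, plus optional Gaussian noise."""
    if ec50 <= 0:
        raise ValueError("ec50 must be positive")
    if doses is None:
        doses = ec50 * np.logspace(-1.5, 1.5, 8)
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be strictly positive")
    rng = np.random.default_rng(seed)
    resp = four_pl(doses, floor, ceiling, ec50, hill)
    if noise_sd > 0:
        resp = resp + rng.normal(0.0, noise_sd, size=doses.shape)
    return DoseResponseData(doses=doses, responses=resp)


def simulate_caa_kinetics(
    caa_unit_true: float = 0.5,
    time: np.ndarray | None = None,
    control_peak: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CAAKinetics:
    """Fluorescence kinetics whose area ratio yields the requested CAA unit.

    The control curve rises with saturating oxidation kinetics over the
    hour-long recording (readings every 5 min); the sample curve is the
    control scaled by ``1 - caa_unit_true``.
    """
    if time is None:
        time = np.arange(0.0, 61.0, 5.0)
    time = np.asarray(time, dtype=float)
    rng = np.random.default_rng(seed)
    ca = control_peak * (1.0 - np.exp(-time / 25.0))
    sa = (1.0 - caa_unit_true) * ca
    if noise_sd > 0:
        ca = np.clip(ca + rng.normal(0.0, noise_sd, time.shape), 0.0, None)
        sa = np.clip(sa + rng.normal(0.0, noise_sd, time.shape), 0.0, None)
    return CAAKinetics(time=time, sample_fluorescence=sa, control_fluorescence=ca)


def simulate_metabolome(
    n_per_group: int = 10,
    n_features: int = 200,
    n_differential: int = 20,
    fold_change: float = 2.0,
    missing_rate: float = 0.1,
    score_range: tuple[float, float] = (0.0, 60.0),
    seed: int = 0,
    cv: float = 0.3,
    groups: tuple[str, str] = ("control", "treated"),
) -> tuple[FeatureTable, dict]:
    """Two-group feature table with planted differential features.

    Exactly ``n_differential`` features have their second-group mean equal to
    ``fold_change`` times the first-group mean; intensities are log-normal
    with coefficient of variation ``cv``; zeros are injected completely at
    random at ``missing_rate``; identification scores are uniform on
    ``score_range``.  Returns the table plus a truth dict with the planted
    feature ids and the pre-missingness intensity matrix.
    """
    if n_differential > n_features:
        raise ValueError("n_differential cannot exceed n_features")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    if fold_change <= 0:
        raise ValueError("fold_change must be positive")
    rng = np.random.default_rng(seed)
    feature_ids = [f"M{j + 1:04d}" for j in range(n_features)]
    sample_ids = [f"{g}{k + 1:02d}" for g in groups for k in range(n_per_group)]
    labels = pd.Series(
        [groups[0]] * n_per_group + [groups[1]] * n_per_group, index=sample_ids
    )
    base_mean = rng.lognormal(np.log(1e5), 0.8, size=n_features)
    diff_idx = np.sort(rng.choice(n_features, size=n_differential, replace=False))
    values = np.empty((2 * n_per_group, n_features))
    for j in range(n_features):
        m1 = base_mean[j]
        m2 = m1 * fold_change if j in set(diff_idx.tolist()) else m1
        sigma2 = np.log(1.0 + cv**2)
        for gi, m in enumerate((m1, m2)):
            mu = np.log(m) - sigma2 / 2.0
            rows = slice(gi * n_per_group, (gi + 1) * n_per_group)
            values[rows, j] = rng.lognormal(mu, np.sqrt(sigma2), size=n_per_group)
    clean = values.copy()
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        values[mask] = 0.0
    scores = rng.uniform(score_range[0], score_range[1], size=n_features)
    ion_mode = pd.Series(
        ["pos" if j < n_features // 2 else "neg" for j in range(n_features)],
        index=feature_ids,
    )
    table = FeatureTable(
        intensities=pd.DataFrame(values, index=sample_ids, columns=feature_ids),
        groups=labels,
        id_score=pd.Series(scores, index=feature_ids),
        ion_mode=ion_mode,
    )
    truth = {
        "differential_features": [feature_ids[j] for j in diff_idx],
        "fold_change": fold_change,
        "missing_rate": missing_rate,
        "clean_intensities": pd.DataFrame(
            clean, index=sample_ids, columns=feature_ids
        ),
        "seed": seed,
    }
    return table, truth
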