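"""Synthetic dynamic metabolite images and voxel-wise kPL analysis.

The digital phantom stands in for interleaved pyruvate/lactate dynamic
volumes of a small-animal kidney experiment: two ellipsoid "kidney" regions
with elevated conversion rates on a zero-conversion background, every voxel
following the forward model at its own kPL with shared bolus/field
parameters, plus i.i.d. complex Gaussian noise. The analysis half mirrors
the in vivo processing chain: voxel-wise dictionary matching inside
anatomy/SNR masks, AUC and lactate-to-pyruvate AUC ratio images, dynamic
(cumulative) AUC SNR ratios with lactate time-to-peak alignment, and
Pearson/Bland-Altman agreement between kPL maps.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dictionary import Dictionary
from .kinetics import simulate_signal_batch
from .matching import match_batch
from .params import BolusParams, FieldConditions, KineticParams
from .sequences import SequenceSchedule, build_schedule

__all__ = [
    "DynamicImageSeries",
    "PhantomSpec",
    "ParamMap",
    "generate_phantom",
    "fit_voxelwise",
    "snr_mask",
    "auc_maps",
    "dynamic_auc_snr_ratio",
    "time_to_peak",
    "compare_maps",
    "save_series_nifti",
    "load_series_nifti",
]


@dataclass
class DynamicImageSeries:
    """Per-metabolite complex 4D image stacks plus timing metadata."""

    pyr: np.ndarray  # (x, y, z, t) complex
    lac: np.ndarray
    times_pyr: np.ndarray  # s
    times_lac: np.ndarray
    voxel_size_mm: tuple = (2.5, 2.5, 21.0)
    noise_sd: float | None = None  # known for phantoms
    design_id: str = ""

    def __post_init__(self):
        if self.pyr.shape[:3] != self.lac.shape[:3]:
            raise ValueError("pyruvate and lactate grids must be congruent")
        for t in (self.times_pyr, self.times_lac):
            if np.any(np.diff(t) <= 0):
                raise ValueError("time stamps must be strictly increasing")

    @property
    def shape(self) -> tuple:
        return self.pyr.shape[:3]

    def voxel_signals(self, mask: np.ndarray) -> np.ndarray:
        """(n_voxels, n_pyr + n_lac) concatenated complex series inside mask."""
        return np.concatenate([self.pyr[mask], self.lac[mask]], axis=1)


@dataclass
class ParamMap:
    """Voxel-wise kPL map with its match scores and masks."""

    kpl: np.ndarray  # (x, y, z), NaN outside mask
    score: np.ndarray
    mask: np.ndarray  # fitted voxels

    def values(self, mask=None) -> np.ndarray:
        m = self.mask if mask is None else (self.mask & mask)
        return self.kpl[m]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and conditions of the synthetic two-kidney phantom."""

    design_id: str = "mrf_sigmoid"
    shape: tuple = (24, 16, 3)
    #: per-ROI (center_xyz, semi_axes_xyz, kpl) ellipsoids
    rois: tuple = (
        ((6.0, 8.0, 1.0), (4.0, 5.0, 1.2), 0.02),
        ((17.0, 8.0, 1.0), (4.0, 5.0, 1.2), 0.05),
    )
    kpl_background: float = 0.0
    sigma: float = 0.1
    seed: int = 0
    kin: KineticParams = field(default_factory=KineticParams)
    bolus: BolusParams = field(default_factory=BolusParams)
    cond: FieldConditions = field(default_factory=FieldConditions)

    def kpl_map(self) -> np.ndarray:
        """Ground-truth kPL image; ROIs must not overlap."""
        kpl = np.full(self.shape, self.kpl_background)
        idx = np.indices(self.shape, dtype=float)
        claimed = np.zeros(self.shape, bool)
        for center, axes, k in self.rois:
            r2 = sum(
                ((idx[i] - center[i]) / axes[i]) ** 2 for i in range(3)
            )
            inside = r2 <= 1.0
            if np.any(inside & claimed):
                raise ValueError("phantom ROIs overlap")
            claimed |= inside
            kpl[inside] = k
        return kpl

    def roi_masks(self) -> list:
        idx = np.indices(self.shape, dtype=float)
        return [
            sum(((idx[i] - c[i]) / a[i]) ** 2 for i in range(3)) <= 1.0
            for c, a, _ in self.rois
        ]


def generate_phantom(
    spec: PhantomSpec, schedule: SequenceSchedule | None = None
) -> tuple:
    """Simulate a noisy dynamic image series plus its ground-truth map.

    Every voxel's time series is the fingerprint at that voxel's true kPL
    (simulated once per unique kPL value), with independent complex Gaussian
    noise of SD ``spec.sigma`` per voxel, channel and frame. Deterministic
    under ``spec.seed``.
    """
    schedule = schedule or build_schedule(spec.design_id)
    kpl_true = spec.kpl_map()
    uniq, inverse = np.unique(kpl_true, return_inverse=True)
    signals, times, (n_p, n_l) = simulate_signal_batch(
        schedule, spec.kin, spec.bolus, spec.cond, kPL=uniq
    )
    clean = signals[inverse].reshape(spec.shape + (n_p + n_l,))
    rng = np.random.default_rng(spec.seed)
    noisy = clean + spec.sigma * (
        rng.standard_normal(clean.shape) + 1j * rng.standard_normal(clean.shape)
    )
    series = DynamicImageSeries(
        pyr=noisy[..., :n_p],
        lac=noisy[..., n_p:],
        times_pyr=times[:n_p],
        times_lac=times[n_p:],
        noise_sd=spec.sigma,
        design_id=schedule.design_id,
    )
    truth = ParamMap(kpl=kpl_true, score=np.zeros(spec.shape), mask=np.ones(spec.shape, bool))
    return series, truth


def fit_voxelwise(
    series: DynamicImageSeries, dictionary: Dictionary, mask: np.ndarray | None = None
) -> ParamMap:
    """Template-match every masked voxel's concatenated pyr+lac series."""
    n_t = series.pyr.shape[3] + series.lac.shape[3]
    if n_t != dictionary.signal_length:
        raise ValueError(
            f"series has {n_t} time samples but dictionary entries have "
            f"{dictionary.signal_length}"
        )
    if mask is None:
        mask = np.ones(series.shape, bool)
    signals = series.voxel_signals(mask)
    scores = np.abs(signals @ dictionary.entries.conj().T)
    idx = np.argmax(scores, axis=1)
    kpl = np.full(series.shape, np.nan)
    score = np.full(series.shape, np.nan)
    kpl[mask] = dictionary.kpl_grid[idx]
    score[mask] = scores[np.arange(len(idx)), idx]
    return ParamMap(kpl=kpl, score=score, mask=mask.copy())


def snr_mask(
    series: DynamicImageSeries,
    metabolite: str = "pyruvate",
    threshold: float = 5.0,
    noise_sd: float | None = None,
) -> np.ndarray:
    """Voxels whose peak-over-time magnitude SNR meets the threshold.

    ``noise_sd`` defaults to the series' known noise level; it must be given
    for measured data (e.g. estimated from a signal-free region).
    """
    sd = series.noise_sd if noise_sd is None else noise_sd
    if sd is None:
        raise ValueError("noise_sd unknown: pass it explicitly")
    img = series.pyr if metabolite == "pyruvate" else series.lac
    if sd == 0:
        return np.ones(series.shape, bool) if threshold <= 0 else np.abs(img).max(axis=3) > 0
    peak = np.abs(img).max(axis=3)
    return peak / sd >= threshold


def auc_maps(series: DynamicImageSeries) -> dict:
    """Per-voxel AUC images and the lactate-to-pyruvate AUC ratio.

    AUC is the sum over time of the magnitude signal; the ratio is NaN where
    the pyruvate AUC is zero.
    """
    auc_p = np.abs(series.pyr).sum(axis=3)
    auc_l = np.abs(series.lac).sum(axis=3)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(auc_p > 0, auc_l / np.where(auc_p > 0, auc_p, 1.0), np.nan)
    return {"auc_pyr": auc_p, "auc_lac": auc_l, "ratio": ratio}


def time_to_peak(img: np.ndarray, times: np.ndarray, mask: np.ndarray | None = None):
    """Per-voxel time of maximum magnitude, plus the mask mean.

    All-zero voxels get NaN. Returns ``(ttp_map, mean_ttp)``.
    """
    if img.shape[3] < 3:
        raise ValueError("need at least 3 time points")
    mag = np.abs(img)
    ttp = times[np.argmax(mag, axis=3)].astype(float)
    ttp[mag.max(axis=3) == 0] = np.nan
    if mask is None:
        mask = np.ones(img.shape[:3], bool)
    vals = ttp[mask]
    mean = float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else np.nan
    return ttp, mean


def _dynamic_auc_snr(img: np.ndarray, noise_sd: float) -> np.ndarray:
    """|cumulative complex sum| over time divided by the real-channel noise SD."""
    return np.abs(np.cumsum(img, axis=3)) / noise_sd


def dynamic_auc_snr_ratio(
    series_a: DynamicImageSeries,
    series_b: DynamicImageSeries,
    mask: np.ndarray,
    metabolite: str = "pyruvate",
    noise_sd_a: float | None = None,
    noise_sd_b: float | None = None,
):
    """Masked-mean ratio of dynamic AUC SNR time courses, TTP-aligned.

    Both series' cumulative-sum SNR images are computed; series b is shifted
    by a whole number of frames so that its mean lactate time-to-peak matches
    series a's, and the per-frame masked mean of (a / shifted b) is returned
    together with series a's time stamps for the overlapping frames.
    """
    sd_a = series_a.noise_sd if noise_sd_a is None else noise_sd_a
    sd_b = series_b.noise_sd if noise_sd_b is None else noise_sd_b
    if sd_a is None or sd_b is None:
        raise ValueError("noise SDs required")
    _, ttp_a = time_to_peak(series_a.lac, series_a.times_lac, mask)
    _, ttp_b = time_to_peak(series_b.lac, series_b.times_lac, mask)
    if not (np.isfinite(ttp_a) and np.isfinite(ttp_b)):
        raise ValueError("lactate time-to-peak undefined")
    # frame index of the mean TTP on each series' own grid
    fa = int(np.argmin(np.abs(series_a.times_lac - ttp_a)))
    fb = int(np.argmin(np.abs(series_b.times_lac - ttp_b)))
    shift = fb - fa
    img_a = series_a.pyr if metabolite == "pyruvate" else series_a.lac
    img_b = series_b.pyr if metabolite == "pyruvate" else series_b.lac
    snr_a = _dynamic_auc_snr(img_a, sd_a)
    snr_b = _dynamic_auc_snr(img_b, sd_b)
    na, nb = snr_a.shape[3], snr_b.shape[3]
    frames_a, frames_b = [], []
    for i in range(na):
        j = i + shift
        if 0 <= j < nb:
            frames_a.append(i)
            frames_b.append(j)
    if not frames_a:
        raise ValueError("no overlapping frames after TTP alignment")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = snr_a[mask][:, frames_a] / snr_b[mask][:, frames_b]
    times = (series_a.times_pyr if metabolite == "pyruvate" else series_a.times_lac)[frames_a]
    return np.nanmean(ratio, axis=0), times


@dataclass
class MapComparison:
    """Voxel-wise agreement between two kPL maps."""

    n: int
    pearson_r: float
    p_value: float
    df: int
    slope: float
    bias: float  # mean(a - b)
    loa_low: float  # bias - 1.96 SD
    loa_high: float
    frac_within_loa: float
    r_defined: bool


def compare_maps(map_a: ParamMap, map_b: ParamMap, mask: np.ndarray | None = None) -> MapComparison:
    """Pearson correlation, least-squares slope and Bland-Altman agreement.

    Operates on voxels common to both maps' masks (optionally intersected
    with ``mask``). For a constant map the correlation is undefined and
    flagged via ``r_defined=False``.
    """
    m = map_a.mask & map_b.mask
    if mask is not None:
        m = m & mask
    a, b = map_a.kpl[m], map_b.kpl[m]
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 shared voxels")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=0))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    frac = float(np.mean((diff >= lo) & (diff <= hi)))
    r_defined = a.std() > 0 and b.std() > 0
    if r_defined:
        r, p = stats.pearsonr(a, b)
        slope = float(np.polyfit(b, a, 1)[0])
    else:
        r, p, slope = np.nan, np.nan, np.nan
    return MapComparison(
        n=n, pearson_r=float(r), p_value=float(p), df=n - 2, slope=slope,
        bias=bias, loa_low=lo, loa_high=hi, frac_within_loa=frac,
        r_defined=bool(r_defined),
    )


# --------------------------------------------------------------------------
# NIfTI input/output
# --------------------------------------------------------------------------

def save_series_nifti(series: DynamicImageSeries, prefix) -> list:
    """Write the series as real/imag NIfTI pairs per metabolite.

    Creates ``<prefix>_<met>_real.nii.gz`` / ``_imag.nii.gz`` and a small
    ``<prefix>_times_<met>.txt`` per metabolite; returns the written paths.
    """
    import nibabel as nib

    affine = np.diag(list(series.voxel_size_mm) + [1.0])
    written = []
    for met, img, times in (
        ("pyruvate", series.pyr, series.times_pyr),
        ("lactate", series.lac, series.times_lac),
    ):
        for part, data in (("real", img.real), ("imag", img.imag)):
            p = f"{prefix}_{met}_{part}.nii.gz"
            nib.save(nib.Nifti1Image(np.asarray(data, np.float32), affine), p)
            written.append(p)
        p = f"{prefix}_times_{met}.txt"
        np.savetxt(p, times)
        written.append(p)
    return written


def load_series_nifti(prefix, design_id: str = "", noise_sd: float | None = None) -> DynamicImageSeries:
    """Load a series written by :func:`save_series_nifti`."""
    import nibabel as nib

    parts = {}
    for met in ("pyruvate", "lactate"):
        re_ = nib.load(f"{prefix}_{met}_real.nii.gz").get_fdata()
        im_ = nib.load(f"{prefix}_{met}_imag.nii.gz").get_fdata()
        parts[met] = re_ + 1j * im_
        parts[met + "_t"] = np.loadtxt(f"{prefix}_times_{met}.txt")
    vox = nib.load(f"{prefix}_pyruvate_real.nii.gz").header.get_zooms()[:3]
    return DynamicImageSeries(
        pyr=parts["pyruvate"], lac=parts["lactate"],
        times_pyr=parts["pyruvate_t"], times_lac=parts["lactate_t"],
        voxel_size_mm=tuple(float(v) for v in vox),
        noise_sd=noise_sd, design_id=design_id,
    )


def save_map_nifti(pmap: ParamMap, prefix, voxel_size_mm=(2.5, 2.5, 21.0)) -> list:
    """Write a kPL map + mask as NIfTI (map float32, mask uint8)."""
    import nibabel as nib

    affine = np.diag(list(voxel_size_mm) + [1.0])
    paths = []
    for name, data, dtype in (
        ("kpl", pmap.kpl, np.float32),
        ("score", pmap.score, np.float32),
        ("mask", pmap.mask, np.uint8),
    ):
        p = f"{prefix}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(data, dtype), affine), p)
        paths.append(p)
    return paths
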