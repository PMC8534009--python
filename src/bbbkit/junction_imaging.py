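"""Junction-protein profile and glycocalyx field-intensity quantification.

Tight-junction signal is quantified from maximum-intensity projections:
for each annotated cell-cell border, several short lines perpendicular
to the border are sampled, averaged into one intensity profile, and the
profile's background-subtracted peak is the junction's score. Glycocalyx
(heparan-sulfate) signal is diffuse, so whole-field mean intensities are
used instead. Both statistics are reported normalised to the mean of the
control (WT) group, and distribution shapes are compared by Fisher
excess kurtosis.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .barrier_assay import compare_groups
from .datatypes import ImageStack

__all__ = [
    "JunctionProfileSet",
    "NormalizedIntensityReport",
    "project_stack",
    "sample_junction_profiles",
    "subtract_background",
    "normalize_to_control",
    "kurtosis_stat",
    "esg_field_intensity",
]


@dataclass
class JunctionProfileSet:
    """Averaged perpendicular-line profiles, one row per junction.

    ``profiles`` is (n_junctions, n_samples); ``positions_um`` is the
    signed offset of each sample from the border; ``peaks`` is the max of
    each averaged profile; ``clipped`` flags junctions whose lines left
    the image and were sampled with edge padding. ``background`` is
    filled in by :func:`subtract_background`.
    """

    profiles: np.ndarray
    positions_um: np.ndarray
    peaks: np.ndarray
    clipped: np.ndarray
    pixel_size_um: float
    background: float | None = None

    @property
    def junction_count(self) -> int:
        return int(self.profiles.shape[0])


@dataclass
class NormalizedIntensityReport:
    """Per-group intensities normalised so the WT mean equals 1."""

    normalized_wt: np.ndarray
    normalized_del: np.ndarray
    wt_reference_mean: float
    del_mean: float
    del_se: float
    wt_kurtosis: float | None = None
    del_kurtosis: float | None = None
    wilcoxon_p: float | None = None

    @property
    def wt_mean(self) -> float:
        return float(self.normalized_wt.mean())  # 1.0 by construction

    @property
    def del_percent_of_wt(self) -> float:
        return 100.0 * self.del_mean


def project_stack(stack: ImageStack, method: str = "max") -> np.ndarray:
    """Project a z-stack to 2-D (default maximum-intensity projection)."""
    if stack.voxels.shape[0] < 1:
        raise ValueError("empty stack")
    if method == "max":
        return stack.voxels.max(axis=0)
    if method == "mean":
        return stack.voxels.mean(axis=0)
    if method == "sum":
        return stack.voxels.sum(axis=0)
    raise ValueError("projection method must be 'max', 'mean' or 'sum'")


def sample_junction_profiles(image: np.ndarray, segments, pixel_size_um: float,
                             line_length_um: float = 3.0,
                             lines_per_junction: int = 3,
                             step_px: float = 0.25) -> JunctionProfileSet:
    """Sample perpendicular intensity lines along each junction segment.

    For each segment, ``lines_per_junction`` lines of ``line_length_um``
    are placed at equal spacings along its interior (fractions
    (i+1)/(lines+1)), sampled by bilinear interpolation at ``step_px``
    spacing, and averaged into one profile. Lines that exit the image are
    sampled with edge padding and the junction is flagged as clipped.
    """
    if not 3 <= lines_per_junction <= 5:
        raise ValueError("lines_per_junction must be in 3..5")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    image = np.asarray(image, dtype=float)
    h, w = image.shape

    half_px = 0.5 * line_length_um / pixel_size_um
    n_side = int(np.floor(half_px / step_px))
    offsets = np.arange(-n_side, n_side + 1) * step_px
    positions_um = offsets * pixel_size_um

    profiles, clipped = [], []
    for (x0, y0, x1, y1) in segments:
        dx, dy = x1 - x0, y1 - y0
        length = float(np.hypot(dx, dy))
        if length < 2.0:
            raise ValueError("segment shorter than 2 px")
        ux, uy = dx / length, dy / length
        nx_, ny_ = -uy, ux  # unit normal
        lines = []
        was_clipped = False
        for i in range(lines_per_junction):
            t = (i + 1) / (lines_per_junction + 1)
            cx, cy = x0 + t * dx, y0 + t * dy
            xs = cx + offsets * nx_
            ys = cy + offsets * ny_
            if xs.min() < 0 or ys.min() < 0 or xs.max() > w - 1 or ys.max() > h - 1:
                was_clipped = True
            lines.append(ndimage.map_coordinates(image, [ys, xs], order=1,
                                                 mode="nearest"))
        profiles.append(np.mean(lines, axis=0))
        clipped.append(was_clipped)

    profiles = np.asarray(profiles)
    return JunctionProfileSet(
        profiles=profiles,
        positions_um=positions_um,
        peaks=profiles.max(axis=1) if profiles.size else np.empty(0),
        clipped=np.asarray(clipped, dtype=bool),
        pixel_size_um=pixel_size_um,
    )


def estimate_background(image: np.ndarray, segments, pixel_size_um: float,
                        margin_um: float = 2.0) -> float:
    """Median intensity of the non-border region.

    Non-border pixels are those farther than ``margin_um`` from every
    annotated segment (distance transform on a rasterised segment mask).
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    mask = np.zeros((h, w), dtype=bool)
    for (x0, y0, x1, y1) in segments:
        n_pts = max(2, int(np.ceil(np.hypot(x1 - x0, y1 - y0) * 2)))
        xs = np.clip(np.rint(np.linspace(x0, x1, n_pts)).astype(int), 0, w - 1)
        ys = np.clip(np.rint(np.linspace(y0, y1, n_pts)).astype(int), 0, h - 1)
        mask[ys, xs] = True
    dist_px = ndimage.distance_transform_edt(~mask)
    non_border = dist_px > margin_um / pixel_size_um
    if not non_border.any():
        raise ValueError("segments cover the entire image; no background region")
    return float(np.median(image[non_border]))


def subtract_background(profile_set: JunctionProfileSet, image: np.ndarray,
                        segments, margin_um: float = 2.0) -> JunctionProfileSet:
    """Subtract the non-border median background, clamping at zero."""
    bg = estimate_background(image, segments, profile_set.pixel_size_um, margin_um)
    return JunctionProfileSet(
        profiles=np.clip(profile_set.profiles - bg, 0.0, None),
        positions_um=profile_set.positions_um,
        peaks=np.clip(profile_set.peaks - bg, 0.0, None),
        clipped=profile_set.clipped,
        pixel_size_um=profile_set.pixel_size_um,
        background=bg,
    )


def kurtosis_stat(values) -> float:
    """Fisher excess kurtosis g2 = m4/m2^2 - 3 (population moments)."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values")
    if np.var(v) == 0:
        raise ValueError("constant input has undefined kurtosis")
    return float(stats.kurtosis(v, fisher=True, bias=True))


def normalize_to_control(del_peaks, wt_peaks) -> NormalizedIntensityReport:
    """Normalise both groups to the WT mean and summarise.

    The WT-group mean of the normalised values is 1 by construction;
    excess kurtosis is reported per group when it is defined (>= 4
    values with nonzero variance).
    """
    dv = np.asarray(del_peaks, dtype=float)
    wv = np.asarray(wt_peaks, dtype=float)
    if dv.size == 0 or wv.size == 0:
        raise ValueError("both groups must be non-empty")
    ref = float(wv.mean())
    if ref <= 0:
        raise ValueError("control mean must be positive")
    ndv, nwv = dv / ref, wv / ref

    def _kurt(x):
        try:
            return kurtosis_stat(x)
        except ValueError:
            return None

    return NormalizedIntensityReport(
        normalized_wt=nwv,
        normalized_del=ndv,
        wt_reference_mean=ref,
        del_mean=float(ndv.mean()),
        del_se=float(ndv.std(ddof=1) / np.sqrt(ndv.size)) if ndv.size > 1 else 0.0,
        wt_kurtosis=_kurt(nwv),
        del_kurtosis=_kurt(ndv),
    )


def esg_field_intensity(wt_stacks, del_stacks, background: float = 0.0,
                        projection: str = "mean") -> NormalizedIntensityReport:
    """Glycocalyx quantification from per-sample field stacks.

    ``wt_stacks`` and ``del_stacks`` are lists (one entry per sample) of
    lists of :class:`ImageStack` fields. Each field contributes its
    projected mean intensity minus ``background``; fields are averaged
    per sample, DEL samples are normalised to the WT sample mean, and a
    paired Wilcoxon test compares the groups when sizes match.

    Mean projection is the default here: the glycocalyx fills the volume,
    so averaging is the unbiased field statistic (in contrast to the
    sparse, bright junction signal where a max projection is used).
    """
    def sample_means(groups_of_fields):
        means = []
        for fields in groups_of_fields:
            if len(fields) == 0:
                raise ValueError("a sample has no fields")
            means.append(np.mean([
                project_stack(f, method=projection).mean() - background
                for f in fields]))
        return np.asarray(means)

    wt = sample_means(wt_stacks)
    dl = sample_means(del_stacks)
    report = normalize_to_control(dl, wt)
    if wt.size == dl.size and wt.size >= 1:
        cmp_ = compare_groups(dl, wt, paired=True)
        report.wilcoxon_p = cmp_["wilcoxon_p"]
    return report
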