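"""Pixel-wise lifetime imaging and condensate phenotyping.

Lifetime images are built by accumulating photons per pixel across scan
frames and tail-fitting a mono-exponential wherever the pixel passes the
photon gate (100 photons in cells, 30 in vitro); ungated pixels carry an
exact 0 sentinel.  Condensate statistics ignore sentinel pixels, classify
crowding against the 1.44 ns boundary (below which the local density exceeds
~30% FVO for mCherry), and populations of condensate means are compared with
two-sided T and F tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "LifetimeImage",
    "CondensateStats",
    "PopulationComparison",
    "build_lifetime_image",
    "condensate_statistics",
    "pixel_lifetime_histogram",
    "compare_populations",
    "lifetime_intensity_correlation",
    "propose_rois",
    "p_value_stars",
    "CROWDING_BOUNDARY_NS",
]

CROWDING_BOUNDARY_NS = 1.44
"""Default mCherry lifetime boundary (ns) below which crowding exceeds ~30% FVO."""


@dataclass
class LifetimeImage:
    """Per-pixel lifetime map with its photon-count map.

    ``lifetime`` is in ns with an exact 0 for pixels without an estimate
    (photon gate failed or fit degenerate); ``counts`` holds accumulated
    photons per pixel.
    """

    lifetime: np.ndarray
    counts: np.ndarray
    min_photons: int
    pixel_size_um: float | None = None
    dwell_time_ms: float | None = None

    def __post_init__(self) -> None:
        if self.lifetime.shape != self.counts.shape:
            raise ValueError("lifetime and counts maps must share a shape")

    @property
    def gated(self) -> np.ndarray:
        """Boolean mask of pixels carrying a lifetime estimate."""
        return self.lifetime > 0


@dataclass
class CondensateStats:
    """Per-ROI lifetime statistics over gated (nonzero) pixels."""

    roi_id: int
    n_pixels: int
    mean_lifetime: float
    sd_lifetime: float
    fraction_below_boundary: float
    crowding_class: str  # "above_30pct_FVO" | "below_30pct_FVO" | "empty"

    @property
    def empty(self) -> bool:
        return self.n_pixels == 0


@dataclass
class PopulationComparison:
    """Two-sided T/F comparison of two condensate-mean populations."""

    t_statistic: float
    t_p: float
    f_statistic: float
    f_p: float
    t_stars: str
    f_stars: str


def p_value_stars(p: float) -> str:
    """Significance connotation: n.s. / * / ** / *** at 0.05 / 0.01 / 0.001."""
    if p > 0.05:
        return "n.s."
    if p > 0.01:
        return "*"
    if p > 0.001:
        return "**"
    return "***"


def _tail_mle_binned(counts: np.ndarray, edges: np.ndarray) -> float:
    """Truncated-exponential lifetime MLE from binned tail counts."""
    e_cache: dict[float, float] = {}

    def nll(tau: float) -> float:
        e = np.exp(-edges / tau)
        p = e[:-1] - e[1:]
        norm = e[0] - e[-1]
        with np.errstate(divide="ignore"):
            logp = np.log(p / norm)
        mask = counts > 0
        return -float(np.sum(counts[mask] * logp[mask]))

    bw = edges[1] - edges[0]
    res = optimize.minimize_scalar(
        nll,
        bounds=(bw / 20.0, 10.0 * (edges[-1] - edges[0])),
        method="bounded",
        options={"xatol": 1e-7},
    )
    return float(res.x)


def build_lifetime_image(
    stream: pd.DataFrame,
    shape: tuple[int, int],
    min_photons: int = 100,
    frames_to_accumulate: int | None = None,
    bin_width: float = 50.0 / 512,
    window: float = 50.0,
    tail_start_offset: float = 0.2,
    pixel_size_um: float | None = None,
    dwell_time_ms: float | None = None,
) -> LifetimeImage:
    """Build a lifetime image from a photon-record scan stream.

    Photons are accumulated across frames per (y, x) pixel; each pixel with
    at least ``min_photons`` photons is tail-fitted (mono-exponential binned
    Poisson MLE starting ``tail_start_offset`` ns after the pooled-histogram
    peak).  Everywhere else the lifetime map holds the 0 sentinel.
    """
    h, w = shape
    lifetime = np.zeros((h, w), dtype=float)
    counts_map = np.zeros((h, w), dtype=np.int64)
    if len(stream) == 0:
        return LifetimeImage(lifetime, counts_map, min_photons, pixel_size_um, dwell_time_ms)
    s = stream
    if frames_to_accumulate is not None:
        s = s[s["frame"] < frames_to_accumulate]
    x = s["x"].to_numpy()
    y = s["y"].to_numpy()
    if np.any((x < 0) | (x >= w) | (y < 0) | (y >= h)):
        raise ValueError("stream contains pixels outside the image shape")
    t = s["microtime_ns"].to_numpy()

    np.add.at(counts_map, (y, x), 1)

    n_bins = int(round(window / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    # tail start from the pooled histogram peak (IRF position is global)
    pooled, _ = np.histogram(t, bins=edges)
    peak_t = 0.5 * (edges[:-1] + edges[1:])[int(np.argmax(pooled))]
    start = peak_t + tail_start_offset
    start_bin = int(np.searchsorted(edges, start, side="left"))
    tail_edges = edges[start_bin:] - edges[start_bin]

    gated_mask = counts_map >= max(min_photons, 1)
    if not gated_mask.any():
        return LifetimeImage(lifetime, counts_map, min_photons, pixel_size_um, dwell_time_ms)

    pix = y.astype(np.int64) * w + x.astype(np.int64)
    tbin = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, n_bins - 1)
    gated_ids = np.flatnonzero(gated_mask.ravel())
    id_map = -np.ones(h * w, dtype=np.int64)
    id_map[gated_ids] = np.arange(gated_ids.size)
    row = id_map[pix]
    keep = (row >= 0) & (tbin >= start_bin)
    mat = np.zeros((gated_ids.size, n_bins - start_bin), dtype=np.float64)
    np.add.at(mat, (row[keep], tbin[keep] - start_bin), 1.0)

    taus = np.zeros(gated_ids.size)
    for i in range(gated_ids.size):
        c = mat[i]
        if np.count_nonzero(c) < 3:
            continue
        taus[i] = _tail_mle_binned(c, tail_edges)
    lifetime.ravel()[gated_ids] = taus
    return LifetimeImage(lifetime, counts_map, min_photons, pixel_size_um, dwell_time_ms)


def condensate_statistics(
    image: LifetimeImage,
    mask: np.ndarray,
    boundary: float = CROWDING_BOUNDARY_NS,
) -> list[CondensateStats]:
    """Per-ROI mean/sd lifetime over gated pixels and crowding class.

    ``mask`` is an integer label image (0 = background).  Sentinel (0 ns)
    pixels are always excluded.  A ROI is classed ``above_30pct_FVO`` iff
    its mean lifetime is strictly below the boundary.
    """
    mask = np.asarray(mask)
    if mask.shape != image.lifetime.shape:
        raise ValueError("mask shape must match the image")
    out = []
    for roi_id in np.unique(mask):
        if roi_id == 0:
            continue
        vals = image.lifetime[(mask == roi_id) & image.gated]
        if vals.size == 0:
            out.append(CondensateStats(int(roi_id), 0, np.nan, np.nan, np.nan, "empty"))
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        frac = float(np.mean(vals < boundary))
        cls = "above_30pct_FVO" if mean < boundary else "below_30pct_FVO"
        out.append(CondensateStats(int(roi_id), int(vals.size), mean, sd, frac, cls))
    return out


def pixel_lifetime_histogram(
    image: LifetimeImage,
    mask: np.ndarray | None = None,
    bin_width: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of pixel lifetimes over gated (nonzero) pixels.

    Returns (bin_edges, counts).  ``mask`` restricts to nonzero-label pixels.
    """
    sel = image.gated
    if mask is not None:
        sel = sel & (np.asarray(mask) > 0)
    vals = image.lifetime[sel]
    if vals.size == 0:
        return np.array([0.0, bin_width]), np.array([0])
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.ceil(vals.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(vals, bins=edges)
    return edges, counts


def compare_populations(
    means_a: np.ndarray,
    means_b: np.ndarray,
    t_variant: str = "welch",
) -> PopulationComparison:
    """Two-sided T test on means and two-sided F test on variances.

    The T test is Welch's by default (Student's with ``t_variant="student"``);
    the F test uses p = 2 min(P(F<=f), P(F>=f)) with (nA-1, nB-1) dof.
    """
    a = np.asarray(means_a, dtype=float)
    b = np.asarray(means_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each population needs at least 2 values")
    t_stat, t_p = stats.ttest_ind(a, b, equal_var=(t_variant == "student"))
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0 and va == 0:
        f_stat, f_p = 1.0, 1.0
    else:
        f_stat = va / vb if vb > 0 else np.inf
        dfn, dfd = a.size - 1, b.size - 1
        cdf = stats.f.cdf(f_stat, dfn, dfd)
        f_p = float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))
    if a.size == b.size and np.allclose(np.sort(a), np.sort(b)):
        t_stat, t_p = 0.0, 1.0
    return PopulationComparison(
        t_statistic=float(t_stat),
        t_p=float(t_p),
        f_statistic=float(f_stat),
        f_p=float(f_p),
        t_stars=p_value_stars(float(t_p)),
        f_stars=p_value_stars(float(f_p)),
    )


def lifetime_intensity_correlation(image: LifetimeImage) -> float:
    """Pearson correlation of pixel lifetime vs photon count over gated pixels.

    Returns NaN when either variable is constant (undefined correlation).
    """
    sel = image.gated
    if sel.sum() < 3:
        raise ValueError("need at least 3 gated pixels")
    life = image.lifetime[sel]
    cnt = image.counts[sel].astype(float)
    if life.std() == 0 or cnt.std() == 0:
        return float("nan")
    return float(stats.pearsonr(life, cnt)[0])


def propose_rois(
    counts: np.ndarray, min_area: int = 10
) -> np.ndarray:
    """Convenience Otsu-threshold + connected-components ROI proposer.

    Intended for exploration only; analyses normally take externally
    supplied label masks (ROIs are typically drawn manually).
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label
    from skimage.morphology import remove_small_objects

    thr = threshold_otsu(counts.astype(float))
    lab = label(counts > thr)
    lab = remove_small_objects(lab, min_size=min_area)
    return lab.astype(np.int32)
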