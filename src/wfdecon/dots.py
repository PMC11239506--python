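"""Detection and characterization of (near-)diffraction-limited dots.

Candidate dots are strict local maxima under 6-connectivity: a voxel counts
only if it is brighter than every existing face neighbor (border voxels
compare against the neighbors they have).  Candidates are ranked either by
raw brightness (intensity mode) or by their value after a difference-of-
Gaussians band-pass (DoG mode), refined to sub-pixel positions with a
3-point parabolic fit per axis, and characterized by a lateral FWHM
(Gaussian + constant fit through the peak), a contrast-to-noise ratio

    CNR = (signal - background) / noise

where background and noise are the mean and population standard deviation
of 100 bilinearly interpolated samples on a circle of radius 5 px around
the dot in its z-plane, and optionally a nuclear-contrast ratio.  Tables
from two images (e.g. raw vs deconvolved) are compared by nearest-neighbor
matching with a physical distance threshold (260 nm by default upstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde

from .deconv import VolumeImage

__all__ = [
    "DetectParams",
    "DotTable",
    "local_maxima_6",
    "dog_filter",
    "detect",
    "fwhm_lateral",
    "cnr",
    "ncr",
    "match_dots",
    "MatchResult",
    "auto_threshold",
    "default_dog_sigma",
]

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...
CNR_RING_RADIUS_PX = 5.0
CNR_RING_POINTS = 100


def default_dog_sigma(na: float, lambda_em: float, dxy: float) -> float:
    """Blob scale expected from the optics, lambda/(4 NA) in pixels."""
    return lambda_em / (4.0 * na) / dxy


@dataclass(frozen=True)
class DetectParams:
    """Detection settings.

    ``sigma1``/``sigma2`` are the DoG scales in pixels (sigma2 defaults to
    1.6 sigma1, the classic blob-detector ratio); ``n_metrics`` limits how
    many top-ranked dots get the (comparatively expensive) FWHM and CNR
    measurements; ``max_dots`` truncates the returned table.
    """

    sigma1: float = 1.0
    sigma2: float | None = None
    subpixel: bool = True
    n_metrics: int = 0
    max_dots: int | None = None
    voxel: tuple[float, float, float] = (130.0, 130.0, 130.0)

    @property
    def dog_sigmas(self) -> tuple[float, float]:
        s2 = 1.6 * self.sigma1 if self.sigma2 is None else self.sigma2
        if not (s2 > self.sigma1 > 0):
            raise ValueError("require sigma2 > sigma1 > 0")
        return self.sigma1, s2


@dataclass
class DotTable:
    """Ranked dot records.

    ``records`` columns: x, y, z (sub-pixel, 0-based, voxel-center
    convention), value (raw intensity at the maximum), dog (DoG value),
    fwhm (nm, NaN when not measured), cnr (NaN when not measured), label.
    Sorted descending by the active ranking value with deterministic
    (z, y, x) tie-breaking.
    """

    records: pd.DataFrame
    ranking: str
    source: str = ""
    params: DetectParams = field(default_factory=DetectParams)

    def __len__(self) -> int:
        return len(self.records)

    def positions(self) -> np.ndarray:
        return self.records[["x", "y", "z"]].to_numpy()


def local_maxima_6(image: VolumeImage | np.ndarray) -> np.ndarray:
    """Voxel positions strictly brighter than all existing face neighbors.

    Returns an (n, 3) integer array of (z, y, x) indices in deterministic
    (z, y, x) scan order.  Plateaus (ties) are not maxima.
    """
    d = image.data if isinstance(image, VolumeImage) else image
    m = np.ones(d.shape, dtype=bool)
    for ax in range(3):
        hi = [slice(None)] * 3
        lo = [slice(None)] * 3
        hi[ax] = slice(1, None)
        lo[ax] = slice(None, -1)
        hi, lo = tuple(hi), tuple(lo)
        m[hi] &= d[hi] > d[lo]
        m[lo] &= d[lo] > d[hi]
    return np.argwhere(m)


def dog_filter(
    image: VolumeImage | np.ndarray, sigma1: float, sigma2: float
) -> np.ndarray:
    """Difference-of-Gaussians band-pass, separable, reflective borders."""
    if not (sigma2 > sigma1 > 0):
        raise ValueError("require sigma2 > sigma1 > 0")
    d = image.data if isinstance(image, VolumeImage) else image
    d = d.astype(np.float32, copy=False)
    return gaussian_filter(d, sigma1, mode="reflect") - gaussian_filter(
        d, sigma2, mode="reflect"
    )


def _parabolic_offset(vm: np.ndarray, v0: np.ndarray, vp: np.ndarray) -> np.ndarray:
    """Sub-pixel offset of the vertex of a parabola through 3 samples."""
    denom = vm - 2.0 * v0 + vp
    with np.errstate(divide="ignore", invalid="ignore"):
        off = 0.5 * (vm - vp) / denom
    off = np.where(np.isfinite(off), off, 0.0)
    return np.clip(off, -0.5, 0.5)


def detect(
    image: VolumeImage,
    mode: str = "intensity",
    params: DetectParams | None = None,
    source: str = "",
) -> DotTable:
    """Find, rank and characterize dots in one z-stack.

    ``mode="intensity"`` takes maxima of (and ranks by) the raw image;
    ``mode="dog"`` takes maxima of the DoG-filtered volume and ranks by the
    filtered value.  FWHM and CNR are measured for the top
    ``params.n_metrics`` records only; the rest carry NaN.
    """
    if mode not in ("intensity", "dog"):
        raise ValueError(f"unknown ranking mode {mode!r}")
    params = params or DetectParams()
    raw = image.data
    s1, s2 = params.dog_sigmas
    dog = dog_filter(raw, s1, s2)
    rank_vol = raw if mode == "intensity" else dog
    peaks = local_maxima_6(rank_vol)
    if peaks.size == 0:
        cols = ["x", "y", "z", "value", "dog", "fwhm", "cnr", "label"]
        return DotTable(pd.DataFrame(columns=cols), ranking=mode, source=source, params=params)

    zi, yi, xi = peaks.T
    rank_val = rank_vol[zi, yi, xi].astype(np.float64)
    # descending by rank value; stable sort keeps (z, y, x) order among ties
    order = np.argsort(-rank_val, kind="stable")
    if params.max_dots is not None:
        order = order[: params.max_dots]
    zi, yi, xi, rank_val = zi[order], yi[order], xi[order], rank_val[order]

    pos = np.column_stack([xi, yi, zi]).astype(np.float64)
    if params.subpixel:
        for col, idx, ax_n in ((0, xi, 2), (1, yi, 1), (2, zi, 0)):
            interior = (idx > 0) & (idx < rank_vol.shape[ax_n] - 1)
            if not np.any(interior):
                continue
            z0, y0, x0 = zi[interior], yi[interior], xi[interior]
            shift = np.zeros(3, dtype=int)
            shift[ax_n] = 1
            vm = rank_vol[z0 - shift[0], y0 - shift[1], x0 - shift[2]].astype(np.float64)
            vp = rank_vol[z0 + shift[0], y0 + shift[1], x0 + shift[2]].astype(np.float64)
            v0 = rank_vol[z0, y0, x0].astype(np.float64)
            pos[interior, col] += _parabolic_offset(vm, v0, vp)

    df = pd.DataFrame(
        {
            "x": pos[:, 0],
            "y": pos[:, 1],
            "z": pos[:, 2],
            "value": raw[zi, yi, xi].astype(np.float64),
            "dog": dog[zi, yi, xi].astype(np.float64),
            "fwhm": np.nan,
            "cnr": np.nan,
            "label": "",
        }
    )
    table = DotTable(df, ranking=mode, source=source, params=params)
    if params.n_metrics:
        dxy = params.voxel[0]
        n = min(params.n_metrics, len(df))
        for i in range(n):
            rec = df.iloc[i]
            try:
                df.iat[i, df.columns.get_loc("fwhm")] = fwhm_lateral(image, rec, dxy=dxy)
            except (RuntimeError, ValueError):
                pass
            try:
                df.iat[i, df.columns.get_loc("cnr")] = cnr(image, rec)
            except ValueError:
                pass
    return table


def _gauss_const(x, amp, mu, sigma, const):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2) + const


def fwhm_lateral(image: VolumeImage, dot, dxy: float = 130.0, half_window: int = 4) -> float:
    """Lateral FWHM (nm) of a dot: Gaussian + constant fit along x and y.

    Fits the 1D profiles through the maximum voxel in its z-plane and
    averages the two fitted sigmas; FWHM = 2 sqrt(2 ln 2) sigma dxy.
    Raises when the fit fails or the dot is too close to a lateral border.
    """
    d = image.data
    xc, yc, zc = int(round(dot["x"])), int(round(dot["y"])), int(round(dot["z"]))
    nz, ny, nx = d.shape
    if not (half_window <= xc < nx - half_window and half_window <= yc < ny - half_window):
        raise ValueError("dot too close to a lateral border for FWHM")
    grid = np.arange(-half_window, half_window + 1, dtype=np.float64)
    sigmas = []
    for prof in (
        d[zc, yc, xc - half_window : xc + half_window + 1].astype(np.float64),
        d[zc, yc - half_window : yc + half_window + 1, xc].astype(np.float64),
    ):
        base = prof.min()
        p0 = (max(prof.max() - base, 1e-6), 0.0, 1.0, base)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # singular covariance is fine here
            popt, _ = curve_fit(_gauss_const, grid, prof, p0=p0, maxfev=5000)
        sigmas.append(abs(popt[2]))
    return FWHM_FACTOR * float(np.mean(sigmas)) * dxy


def cnr(image: VolumeImage, dot) -> float:
    """Contrast-to-noise ratio of one dot.

    Signal is the value at the maximum; background and noise are the mean
    and population standard deviation of 100 points sampled by bilinear
    interpolation on the lateral circle of radius 5 px around the (refined)
    center in the dot's z-plane.  A zero-noise ring yields +inf.
    """
    d = image.data
    nz, ny, nx = d.shape
    x, y = float(dot["x"]), float(dot["y"])
    zc = int(round(float(dot["z"])))
    r = CNR_RING_RADIUS_PX
    if not (r <= x <= nx - 1 - r and r <= y <= ny - 1 - r and 0 <= zc < nz):
        raise ValueError("5-px CNR ring does not fit inside the lateral field")
    theta = 2.0 * np.pi * np.arange(CNR_RING_POINTS) / CNR_RING_POINTS
    xs = x + r * np.cos(theta)
    ys = y + r * np.sin(theta)
    samples = map_coordinates(d[zc].astype(np.float64), [ys, xs], order=1)
    background = float(samples.mean())
    noise = float(samples.std())  # population sd: the ring is the population
    signal = float(dot["value"])
    # guard: interpolation of a flat ring leaves O(eps) jitter, not exact 0
    if noise <= 1e-9 * max(1.0, abs(background)):
        return float("inf")
    return (signal - background) / noise


def ncr(dot_value: float, nucleus_mean: float) -> float:
    """Nuclear-contrast ratio: dot peak intensity / mean nuclear intensity."""
    if nucleus_mean <= 0:
        raise ValueError("nucleus mean intensity must be positive")
    return dot_value / nucleus_mean


@dataclass(frozen=True)
class MatchResult:
    """Nearest-neighbor matching of two dot tables at a physical radius.

    ``a_matched``/``b_matched`` are boolean masks; ``a_nn``/``b_nn`` the
    index of each dot's nearest neighbor in the other table; counts follow
    the New/Lost naming: dots only in b are "new", only in a are "lost".
    """

    a_matched: np.ndarray
    b_matched: np.ndarray
    a_nn: np.ndarray
    b_nn: np.ndarray
    n_matched_a: int
    n_matched_b: int
    n_lost: int
    n_new: int


def match_dots(
    a: DotTable | np.ndarray,
    b: DotTable | np.ndarray,
    radius_nm: float = 260.0,
    voxel: tuple[float, float, float] = (130.0, 130.0, 130.0),
    mutual: bool = False,
) -> MatchResult:
    """Match dots between two tables by nearest neighbor within a radius.

    Positions are scaled by the voxel size to nm before the Euclidean
    nearest-neighbor search (each query dot greedily takes its nearest
    neighbor; ``mutual=True`` additionally requires the pair to be mutual
    nearest neighbors, which makes matched counts symmetric).
    """
    pa = (a.positions() if isinstance(a, DotTable) else np.asarray(a, float)).reshape(-1, 3)
    pb = (b.positions() if isinstance(b, DotTable) else np.asarray(b, float)).reshape(-1, 3)
    scale = np.asarray(voxel, dtype=np.float64)
    qa, qb = pa * scale, pb * scale
    if len(qa) == 0 or len(qb) == 0:
        return MatchResult(
            np.zeros(len(qa), bool), np.zeros(len(qb), bool),
            np.full(len(qa), -1), np.full(len(qb), -1),
            0, 0, len(qa), len(qb),
        )
    ta, tb = cKDTree(qa), cKDTree(qb)
    da, ia = tb.query(qa)
    db, ib = ta.query(qb)
    ma = da < radius_nm
    mb = db < radius_nm
    if mutual:
        ma &= ib[ia] == np.arange(len(qa))
        mb &= ia[ib] == np.arange(len(qb))
    return MatchResult(
        a_matched=ma, b_matched=mb, a_nn=ia, b_nn=ib,
        n_matched_a=int(ma.sum()), n_matched_b=int(mb.sum()),
        n_lost=int((~ma).sum()), n_new=int((~mb).sum()),
    )


def fwhm_filter(
    table: DotTable,
    dxy: float = 130.0,
    lo_px: float = 0.5,
    hi_px: float = 5.0,
) -> DotTable:
    """Keep dots with a plausible size: FWHM between ``lo_px`` and ``hi_px``
    pixel sides (records without a measured FWHM are dropped).  Used in the
    tissue workflow to reject camera speckle and large autofluorescent
    blobs before thresholding."""
    f = table.records["fwhm"]
    keep = (f >= lo_px * dxy) & (f <= hi_px * dxy)
    return DotTable(
        records=table.records[keep.fillna(False)].reset_index(drop=True),
        ranking=table.ranking,
        source=table.source,
        params=table.params,
    )


def auto_threshold(values: np.ndarray, grid_points: int = 512) -> float | None:
    """Threshold separating high- from low-quality dots, or None.

    A Gaussian KDE of the log-transformed (positive) ranking values is
    scanned for the deepest local minimum between the two highest modes;
    a unimodal density returns None (no reliable threshold exists, the
    situation seen on low-magnification raw images).
    """
    values = np.asarray(values, dtype=np.float64)
    values = values[np.isfinite(values) & (values > 0)]
    if values.size < 100:
        raise ValueError("need at least 100 positive values for thresholding")
    logs = np.log(values)
    kde = gaussian_kde(logs)
    lo, hi = logs.min(), logs.max()
    pad = 0.05 * (hi - lo + 1e-12)
    grid = np.linspace(lo - pad, hi + pad, grid_points)
    dens = kde(grid)
    interior = np.arange(1, grid_points - 1)
    is_max = (dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])
    is_min = (dens[interior] < dens[interior - 1]) & (dens[interior] <= dens[interior + 1])
    maxima = interior[is_max]
    minima = interior[is_min]
    if maxima.size < 2:
        return None
    top2 = maxima[np.argsort(dens[maxima])[-2:]]
    lo_i, hi_i = int(top2.min()), int(top2.max())
    between = minima[(minima > lo_i) & (minima < hi_i)]
    if between.size == 0:
        return None
    best = between[np.argmin(dens[between])]
    return float(np.exp(grid[best]))
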