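"""Individualized frequency-band detection via generalized eigendecomposition.

At each frequency on a grid, the recording is Gaussian-narrowband filtered
and the narrowband covariance S is contrasted against the broadband
covariance R by solving S W = R W L. The top eigenvector per frequency
captures the spatial pattern of any rhythm there; clustering eigenvector
similarity across frequencies yields contiguous individualized band
intervals, which are then mapped onto canonical band names.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.signal import find_peaks, welch
from sklearn.cluster import DBSCAN

from .io_preprocess import EpochSet, Recording, epoch

CANONICAL_RANGES = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}


class GEDError(RuntimeError):
    pass


@dataclass
class GEDSweep:
    """GED results across a frequency grid."""

    grid: np.ndarray  # strictly increasing, constant step (Hz)
    lambda_max: np.ndarray  # top generalized eigenvalue per frequency
    eigvecs: np.ndarray  # frequencies x channels, top eigenvector per frequency
    labels: list[str] = field(default_factory=list)


@dataclass
class BandBoundaries:
    """Detected intervals plus their canonical assignment."""

    intervals: list[tuple[float, float]]
    cluster_ids: list[int] = field(default_factory=list)
    canonical: dict[str, tuple[float, float] | None] = field(default_factory=dict)
    flagged: bool = False  # set when detection degenerated to the whole grid


def clean_mean_covariance(epochs: EpochSet) -> np.ndarray:
    """Mean epoch covariance after dropping outlier epochs.

    Per-epoch covariances are compared to the grand mean by Frobenius
    distance; epochs whose z-scored distance exceeds 3 are discarded and the
    mean recomputed over the survivors.
    """
    X = epochs.data
    if X.shape[0] < 4:
        raise GEDError("need at least 4 epochs for outlier screening")
    Xc = X - X.mean(axis=2, keepdims=True)
    covs = np.einsum("eit,ejt->eij", Xc, Xc) / (X.shape[2] - 1)
    grand = covs.mean(axis=0)
    dists = np.linalg.norm(covs - grand, axis=(1, 2))
    sd = dists.std()
    z = (dists - dists.mean()) / sd if sd > 0 else np.zeros_like(dists)
    keep = np.abs(z) <= 3
    assert keep.any(), "outlier screen rejected every epoch"
    return covs[keep].mean(axis=0)


def _regularize(R: np.ndarray, shrinkage: float) -> np.ndarray:
    if shrinkage <= 0:
        return R
    mean_eig = np.trace(R) / R.shape[0]
    return (1 - shrinkage) * R + shrinkage * mean_eig * np.eye(R.shape[0])


def gaussian_narrowband(
    data: np.ndarray, fs: float, f: float, fwhm: float
) -> np.ndarray:
    """Gaussian spectral-domain filter centered at ``f`` with the given FWHM."""
    n = data.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1 / fs)
    sd = fwhm / (2 * np.sqrt(2 * np.log(2)))
    gain = np.exp(-0.5 * ((freqs - f) / sd) ** 2)
    return np.fft.irfft(np.fft.rfft(data, axis=-1) * gain, n=n, axis=-1)


def default_fwhm(f: float) -> float:
    return max(1.0, 0.1 * f)


def _solve_ged(S: np.ndarray, R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    try:
        evals, evecs = linalg.eigh(S, R)
    except linalg.LinAlgError as exc:
        raise GEDError(
            "generalized eigensolve failed; R is singular even after shrinkage — "
            "increase the shrinkage parameter or supply more data"
        ) from exc
    assert np.all(np.isfinite(evals)) and np.isrealobj(evals)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # Sign convention: largest-magnitude component positive.
    for j in range(evecs.shape[1]):
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    return evals, evecs


def ged_at_frequency(
    rec: Recording,
    f: float,
    fwhm: float | None = None,
    shrinkage: float = 0.01,
    epoch_len: float = 2.0,
    R: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the narrowband-vs-broadband generalized eigenproblem at one
    frequency. Returns (eigenvalues descending, eigenvectors as columns);
    eigenvectors are R-orthogonal. A precomputed regularized broadband
    covariance may be passed to avoid rework in sweeps."""
    if not 0 < f < rec.fs / 2:
        raise GEDError(f"target frequency {f} Hz outside filterable range")
    if fwhm is None:
        fwhm = default_fwhm(f)
    if R is None:
        R = _regularize(clean_mean_covariance(epoch(rec, epoch_len)), shrinkage)
    narrow = rec.copy_with(gaussian_narrowband(rec.data, rec.fs, f, fwhm))
    S = clean_mean_covariance(epoch(narrow, epoch_len))
    return _solve_ged(S, R)


def ged_sweep(
    rec: Recording,
    f_lo: float = 2.0,
    f_hi: float = 45.0,
    step: float = 0.5,
    shrinkage: float = 0.01,
    epoch_len: float = 2.0,
) -> GEDSweep:
    """Run :func:`ged_at_frequency` across a uniform grid."""
    if not 0 < f_lo < f_hi < rec.fs / 2:
        raise GEDError(f"grid ({f_lo}, {f_hi}) Hz outside (0, fs/2)")
    grid = np.arange(f_lo, f_hi + step / 2, step)
    if grid.size == 0:
        raise GEDError("empty frequency grid")
    R = _regularize(clean_mean_covariance(epoch(rec, epoch_len)), shrinkage)
    lam = np.empty(grid.size)
    vecs = np.empty((grid.size, rec.n_channels))
    for i, f in enumerate(grid):
        evals, evecs = ged_at_frequency(rec, f, shrinkage=shrinkage, epoch_len=epoch_len, R=R)
        # Normalize by the narrowband filter's bandwidth: wider filters pass
        # proportionally more broadband power, which would tilt lambda_max
        # upward with frequency even for featureless input.
        lam[i] = evals[0] / default_fwhm(f)
        vecs[i] = evecs[:, 0]
    return GEDSweep(grid=grid, lambda_max=lam, eigvecs=vecs, labels=list(rec.labels))


def similarity_matrix(sweep: GEDSweep) -> np.ndarray:
    """Squared Pearson correlation between top eigenvectors of every
    frequency pair; symmetric with unit diagonal."""
    V = sweep.eigvecs
    if V.shape[0] < 2:
        raise GEDError("need at least 2 frequencies")
    Vc = V - V.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Vc, axis=1)
    ok = norms > 0
    U = np.zeros_like(Vc)
    U[ok] = Vc[ok] / norms[ok, None]
    sim = (U @ U.T) ** 2
    sim[~ok, :] = 0.0
    sim[:, ~ok] = 0.0
    np.fill_diagonal(sim, 1.0)
    return np.clip(sim, 0.0, 1.0)


def _contiguous_runs(mask_labels: np.ndarray) -> list[tuple[int, int, int]]:
    """(start, stop_inclusive, label) runs of identical non-noise labels."""
    runs = []
    start = 0
    for i in range(1, len(mask_labels) + 1):
        if i == len(mask_labels) or mask_labels[i] != mask_labels[start]:
            if mask_labels[start] >= 0:
                runs.append((start, i - 1, int(mask_labels[start])))
            start = i
    return runs


def _trim_run(run: tuple[int, int, int], lam: np.ndarray) -> tuple[int, int, int]:
    """Shrink a cluster run to where the eigenvalue contrast is substantial.

    Eigenvector similarity alone can bleed past a rhythm's spectral edge
    (the narrowband filter leaks); the run is trimmed to frequencies with
    lambda_max above baseline + 15% of the run's peak contrast, where the
    baseline is the grid-wide median.
    """
    a, b, cid = run
    baseline = float(np.median(lam))
    peak = lam[a : b + 1].max()
    if peak <= baseline:
        return run
    thr = baseline + 0.15 * (peak - baseline)
    idx = np.arange(a, b + 1)
    above = lam[idx] >= thr
    if not above.any():
        return run
    return (int(idx[above][0]), int(idx[above][-1]), cid)


def cluster_bands(
    sim: np.ndarray,
    grid: np.ndarray,
    method: str = "dbscan",
    lambda_max: np.ndarray | None = None,
    min_pts: int = 3,
) -> BandBoundaries:
    """Derive band intervals from the frequency-similarity matrix.

    ``dbscan``: cluster frequency points on distance 1 - similarity, scanning
    epsilon and keeping the solution with the most clusters; clusters are
    split into frequency-contiguous runs and each run becomes an interval.
    ``trough``: smooth the top-eigenvalue spectrum, find prominent peaks, and
    cut at the minima between adjacent peaks (requires ``lambda_max``).
    """
    grid = np.asarray(grid)
    if method == "dbscan":
        D = 1.0 - sim
        best: np.ndarray | None = None
        best_count = 0
        for eps in np.linspace(0.05, 0.9, 18):
            labels = DBSCAN(eps=eps, min_samples=min_pts, metric="precomputed").fit(D).labels_
            runs = [r for r in _contiguous_runs(labels) if r[1] - r[0] + 1 >= min_pts]
            if len(runs) >= 1 and len(runs) > best_count:
                best, best_count = labels, len(runs)
        if best is None:
            return BandBoundaries(
                intervals=[(float(grid[0]), float(grid[-1]))], cluster_ids=[0], flagged=True
            )
        runs = [r for r in _contiguous_runs(best) if r[1] - r[0] + 1 >= min_pts]
        if lambda_max is not None:
            lam = np.asarray(lambda_max, dtype=float)
            runs = [_trim_run(r, lam) for r in runs]
            runs = [r for r in runs if r[1] - r[0] + 1 >= min_pts]
            # Discard clusters with negligible eigenvalue contrast: eigenvector
            # similarity can form spurious runs where no rhythm exists.
            baseline = float(np.median(lam))
            gpeak = float(lam.max())
            if gpeak > baseline:
                thr = baseline + 0.1 * (gpeak - baseline)
                runs = [r for r in runs if lam[r[0] : r[1] + 1].max() >= thr]
        intervals = [(float(grid[a]), float(grid[b])) for a, b, _ in runs]
        ids = list(range(len(runs)))
        return BandBoundaries(intervals=intervals, cluster_ids=ids)
    if method == "trough":
        if lambda_max is None:
            raise GEDError("trough method needs the lambda_max spectrum")
        lam = np.asarray(lambda_max, dtype=float)
        win = min(5, len(lam))
        kernel = np.ones(win) / win
        smooth = np.convolve(lam, kernel, mode="same")
        rng_ = smooth.max() - smooth.min()
        peaks, _ = find_peaks(smooth, prominence=0.1 * rng_ if rng_ > 0 else None)
        if len(peaks) == 0:
            return BandBoundaries(
                intervals=[(float(grid[0]), float(grid[-1]))], cluster_ids=[0], flagged=True
            )
        cuts = [0]
        for a, b in zip(peaks[:-1], peaks[1:]):
            cuts.append(int(a + np.argmin(smooth[a : b + 1])))
        cuts.append(len(grid) - 1)
        # Trim each peak's interval to its eigenvalue support so the outermost
        # intervals do not sprawl to the grid edges.
        runs = [
            _trim_run((cuts[i], cuts[i + 1], i), lam) for i in range(len(peaks))
        ]
        intervals = [(float(grid[a]), float(grid[b])) for a, b, _ in runs if b > a]
        return BandBoundaries(intervals=intervals, cluster_ids=list(range(len(intervals))))
    raise GEDError(f"unknown clustering method {method!r}")


def assign_canonical(bounds: BandBoundaries) -> BandBoundaries:
    """Assign each interval to the canonical band containing its midpoint;
    multiple intervals in one range merge to their envelope. Bands with no
    interval stay ``None`` (unassigned)."""
    canonical: dict[str, tuple[float, float] | None] = {k: None for k in CANONICAL_RANGES}
    for lo, hi in bounds.intervals:
        mid = (lo + hi) / 2
        for name, (clo, chi) in CANONICAL_RANGES.items():
            if clo <= mid < chi:
                cur = canonical[name]
                canonical[name] = (
                    (lo, hi) if cur is None else (min(cur[0], lo), max(cur[1], hi))
                )
                break
    bounds.canonical = canonical
    return bounds


def detect_bands(
    rec: Recording,
    f_lo: float = 2.0,
    f_hi: float = 45.0,
    step: float = 0.5,
    method: str = "dbscan",
) -> BandBoundaries:
    """Full pipeline: sweep -> similarity -> cluster -> canonical assignment."""
    sweep = ged_sweep(rec, f_lo, f_hi, step)
    sim = similarity_matrix(sweep)
    bounds = cluster_bands(sim, sweep.grid, method=method, lambda_max=sweep.lambda_max)
    return assign_canonical(bounds)


def individualized_band_power(
    rec: Recording, bounds: BandBoundaries
) -> pd.DataFrame:
    """Welch band power (uV^2/Hz mean PSD) per channel over each assigned
    individualized interval. Unassigned bands yield missing values."""
    if not bounds.canonical or all(v is None for v in bounds.canonical.values()):
        raise GEDError("no canonical band assigned")
    nperseg = min(int(2 * rec.fs), rec.n_samples)
    freqs, psd = welch(rec.data, fs=rec.fs, nperseg=nperseg, axis=1)
    rows = []
    subject = rec.meta.get("subject", "")
    for band, interval in bounds.canonical.items():
        for ch, label in enumerate(rec.labels):
            if interval is None:
                power = np.nan
            else:
                mask = (freqs >= interval[0]) & (freqs <= interval[1])
                power = float(psd[ch, mask].mean()) if mask.any() else np.nan
            rows.append(dict(subject=subject, band=band, channel=label, power=power))
    return pd.DataFrame(rows)
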