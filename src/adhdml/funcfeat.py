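"""Functional features from resting-state time series.

Fisher-z Pearson connectivity matrices and their lower-triangle edge
features, nodal amplitude spectra, voxelwise global connectivity (mean
Fisher-z correlation with all other in-mask voxels) and voxelwise regional
homogeneity (Kendall's coefficient of concordance W over each voxel's
26-neighborhood).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "R_MAX",
    "ConnectivityMatrix",
    "fisher_z",
    "connectivity_matrix",
    "vectorize_connectivity",
    "devectorize_connectivity",
    "power_spectrum",
    "global_connectivity",
    "regional_homogeneity",
    "kendalls_w",
]

# Correlations are capped at R_MAX before atanh so perfectly correlated
# series map to a large finite z rather than infinity.
R_MAX = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    """R x R symmetric Fisher-z connectivity matrix.

    The diagonal is stored as 0 and excluded from features.
    """

    z: np.ndarray
    roi_names: list[str]

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        R = self.z.shape[0]
        if self.z.ndim != 2 or self.z.shape[1] != R or R < 2:
            raise ValueError("z must be square with R >= 2")
        if len(self.roi_names) != R:
            raise ValueError("roi_names length must match matrix size")
        if not np.allclose(self.z, self.z.T, atol=1e-8):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.isfinite(self.z).all():
            raise ValueError("connectivity matrix must be finite")

    @property
    def n_rois(self) -> int:
        return self.z.shape[0]


def fisher_z(r):
    """Fisher z-transform atanh(r), with |r| capped at ``R_MAX``.

    Odd and monotone in r; raises for |r| > 1.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlations must satisfy |r| <= 1")
    z = np.arctanh(np.clip(r, -R_MAX, R_MAX))
    return z if z.ndim else float(z)


def connectivity_matrix(
    ts: np.ndarray | pd.DataFrame, roi_names: list[str] | None = None
) -> ConnectivityMatrix:
    """Fisher-z Pearson connectivity matrix of a T x R time-series array.

    Constant columns cannot be correlated; their rows/columns are set to 0
    with a warning.
    """
    if isinstance(ts, pd.DataFrame):
        if roi_names is None:
            roi_names = [str(c) for c in ts.columns]
        ts = ts.to_numpy(dtype=float)
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("ts must be a T x R array")
    T, R = ts.shape
    if T < 3:
        raise ValueError("need at least 3 time points")
    if roi_names is None:
        roi_names = [f"roi{r:03d}" for r in range(R)]
    constant = ts.max(axis=0) == ts.min(axis=0)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant column(s); their connectivity "
            "entries are set to 0",
            stacklevel=2,
        )
        ts = ts.copy()
        ts[:, constant] = np.random.default_rng(0).standard_normal(T)[:, None]
    r = np.corrcoef(ts, rowvar=False)
    z = np.arctanh(np.clip(r, -R_MAX, R_MAX))
    z[constant, :] = 0.0
    z[:, constant] = 0.0
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2
    return ConnectivityMatrix(z=z, roi_names=list(roi_names))


def vectorize_connectivity(m: ConnectivityMatrix) -> pd.Series:
    """Lower-triangle edge features of a connectivity matrix.

    Returns R(R-1)/2 values named ``roi_i__roi_j`` with i < j in atlas
    order (duplicates and self-correlations removed).
    """
    iu, ju = np.triu_indices(m.n_rois, k=1)
    names = [f"{m.roi_names[i]}__{m.roi_names[j]}" for i, j in zip(iu, ju)]
    return pd.Series(m.z[iu, ju], index=names)


def devectorize_connectivity(
    vec: pd.Series, roi_names: list[str]
) -> ConnectivityMatrix:
    """Rebuild the symmetric matrix from its lower-triangle edge vector."""
    R = len(roi_names)
    if len(vec) != R * (R - 1) // 2:
        raise ValueError("edge vector length does not match ROI count")
    z = np.zeros((R, R))
    iu, ju = np.triu_indices(R, k=1)
    z[iu, ju] = vec.to_numpy()
    z[ju, iu] = z[iu, ju]
    return ConnectivityMatrix(z=z, roi_names=list(roi_names))


def power_spectrum(
    ts: np.ndarray | pd.DataFrame, TR: float = 2.0, exponent: float = 1.0
) -> pd.DataFrame:
    """One-sided amplitude spectrum per ROI via the discrete Fourier transform.

    Amplitude is the modulus sqrt(Re^2 + Im^2) of each Fourier coefficient
    (``exponent=2`` gives squared power instead). Rows are indexed by
    frequency in Hz; columns follow the input ROI columns. No detrending or
    windowing is applied.
    """
    if isinstance(ts, pd.DataFrame):
        cols = [str(c) for c in ts.columns]
        arr = ts.to_numpy(dtype=float)
    else:
        arr = np.asarray(ts, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        cols = [f"roi{r:03d}" for r in range(arr.shape[1])]
    T = arr.shape[0]
    if T < 4:
        raise ValueError("need at least 4 time points")
    amp = np.abs(np.fft.rfft(arr, axis=0)) ** exponent
    freqs = np.fft.rfftfreq(T, d=TR)
    return pd.DataFrame(amp, index=pd.Index(freqs, name="freq_hz"), columns=cols)


# ---------------------------------------------------------------------------
# Voxelwise maps


def _flatten_masked(data: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    data = np.asarray(data, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if data.ndim != 4:
        raise ValueError("voxel data must be 4D (x, y, z, t)")
    if mask.shape != data.shape[:3]:
        raise ValueError("mask shape must match the spatial grid")
    series = data[mask]  # n_vox x T
    return series, mask


def global_connectivity(data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-voxel mean Fisher-z correlation with every other in-mask voxel.

    Constant voxels contribute a z of 0 to their neighbors' averages (with a
    warning) and get value 0 themselves. Returns a 3D map, NaN outside the
    mask.
    """
    series, mask = _flatten_masked(data, mask)
    n_vox, T = series.shape
    if n_vox < 2:
        raise ValueError("need at least 2 voxels in the mask")
    if T < 3:
        raise ValueError("need at least 3 time points")
    constant = series.max(axis=1) == series.min(axis=1)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant voxel(s) contribute z=0",
            stacklevel=2,
        )
    centered = series - series.mean(axis=1, keepdims=True)
    norm = np.sqrt((centered**2).sum(axis=1))
    norm[constant] = 1.0
    unit = centered / norm[:, None]
    r = unit @ unit.T
    np.clip(r, -R_MAX, R_MAX, out=r)
    z = np.arctanh(r)
    z[constant, :] = 0.0
    z[:, constant] = 0.0
    np.fill_diagonal(z, 0.0)
    values = z.sum(axis=1) / (n_vox - 1)
    out = np.full(mask.shape, np.nan)
    out[mask] = values
    return out


def kendalls_w(series: np.ndarray, tie_correction: bool = False) -> float:
    """Kendall's coefficient of concordance over m series of length n.

    ``W = 12 S / (m^2 (n^3 - n))`` where S is the sum of squared deviations
    of per-timepoint rank sums from their mean; ties get average ranks. With
    ``tie_correction`` the denominator subtracts the standard tie term.
    """
    series = np.asarray(series, dtype=float)
    m, n = series.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 series of length >= 2")
    ranks = np.apply_along_axis(rankdata, 1, series)
    rank_sums = ranks.sum(axis=0)
    S = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    denom = m**2 * (n**3 - n)
    if tie_correction:
        tie_term = 0.0
        for row in series:
            _, counts = np.unique(row, return_counts=True)
            tie_term += float((counts**3 - counts).sum())
        denom -= m * tie_term
    if denom <= 0:
        return 1.0  # every series fully tied: perfectly concordant by convention
    return min(1.0, 12.0 * S / denom)


_NEIGHBOR_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
    ]
)


def regional_homogeneity(
    data: np.ndarray, mask: np.ndarray, tie_correction: bool = False
) -> np.ndarray:
    """Regional homogeneity map: Kendall's W over each voxel's neighborhood.

    For each in-mask voxel, W is computed over the voxel and its in-mask
    26-connected neighbors (m <= 27 series; edge-of-mask voxels simply use
    fewer). Voxels with no in-mask neighbor are masked out (NaN). Values lie
    in [0, 1]; being rank-based, the map is invariant under monotone
    transformations of each series.
    """
    data = np.asarray(data, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if data.ndim != 4:
        raise ValueError("voxel data must be 4D (x, y, z, t)")
    if data.shape[3] < 3:
        raise ValueError("need at least 3 time points")
    if mask.shape != data.shape[:3]:
        raise ValueError("mask shape must match the spatial grid")
    shape = mask.shape
    out = np.full(shape, np.nan)
    coords = np.argwhere(mask)
    for x, y, z in coords:
        neigh = _NEIGHBOR_OFFSETS + (x, y, z)
        ok = (
            (neigh >= 0).all(axis=1)
            & (neigh[:, 0] < shape[0])
            & (neigh[:, 1] < shape[1])
            & (neigh[:, 2] < shape[2])
        )
        neigh = neigh[ok]
        in_mask = mask[neigh[:, 0], neigh[:, 1], neigh[:, 2]]
        neigh = neigh[in_mask]
        if len(neigh) < 2:
            continue  # isolated voxel: W undefined
        block = data[neigh[:, 0], neigh[:, 1], neigh[:, 2], :]
        out[x, y, z] = kendalls_w(block, tie_correction=tie_correction)
    return out
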