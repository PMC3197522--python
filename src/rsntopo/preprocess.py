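"""Per-subject cleaning: overlap exclusion, optional smoothing, nuisance
regression with temporal derivatives, and band-pass filtering.

The fixed pipeline order is: overlap exclusion → (optional Gaussian
smoothing) → time-series extraction → nuisance regression → band-pass.
Spectral analysis consumes the regressed-but-unfiltered series; graph
construction consumes the fully filtered series.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .simulate import BoldDataset, RSNAtlas, DEFAULT_BAND

__all__ = [
    "VoxelTimeSeriesSet",
    "NuisanceDesign",
    "exclude_overlap",
    "smooth_volumes",
    "extract_timeseries",
    "build_nuisance_design",
    "regress_nuisance",
    "bandpass",
    "preprocess_subject",
]

log = logging.getLogger(__name__)

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ≈ 2.3548


class PreprocessError(ValueError):
    pass


@dataclass
class VoxelTimeSeriesSet:
    """Voxel×time matrix of one network for one subject."""

    network: str
    subject_id: str
    voxel_ids: np.ndarray        # (k, 3) int voxel coordinates
    data: np.ndarray             # (k, t)
    tr: float
    regressed: bool = False
    filtered: bool = False

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def mean_timecourse(self) -> np.ndarray:
        return self.data.mean(axis=0)

    def replace(self, **kw) -> "VoxelTimeSeriesSet":
        return dataclasses.replace(self, **kw)


@dataclass
class NuisanceDesign:
    """Regression design: intercept, 9 nuisance sources, 9 derivatives."""

    columns: np.ndarray          # (t, p)
    column_names: list[str]

    @property
    def n_columns(self) -> int:
        return self.columns.shape[1]


def exclude_overlap(atlas: RSNAtlas) -> dict[str, np.ndarray]:
    """Exclusive voxel sets: voxels carrying more than one network label
    are dropped from every network.  Returned coordinate arrays are
    pairwise disjoint subsets of the original masks.
    """
    counts = atlas.label_counts()
    out: dict[str, np.ndarray] = {}
    for name, mask in atlas.masks.items():
        keep = mask & (counts == 1)
        if not keep.any():
            raise PreprocessError(
                f"network {name!r} has no voxels left after overlap exclusion"
            )
        out[name] = np.argwhere(keep)
    return out


def smooth_volumes(dataset: BoldDataset, fwhm_mm: float,
                   voxel_size_mm: float = 3.0) -> BoldDataset:
    """Isotropic Gaussian smoothing of every volume.

    sigma per axis = fwhm / (2·√(2·ln 2)) / voxel size, in voxel units;
    ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise PreprocessError("fwhm_mm must be ≥ 0")
    if voxel_size_mm <= 0:
        raise PreprocessError("voxel_size_mm must be positive")
    if fwhm_mm == 0:
        return dataset
    sigma_vox = fwhm_mm / FWHM_TO_SIGMA / voxel_size_mm
    vol = ndimage.gaussian_filter(
        dataset.volumes.astype(np.float64),
        sigma=(sigma_vox, sigma_vox, sigma_vox, 0.0),
        mode="nearest",
    ).astype(dataset.volumes.dtype)
    return dataclasses.replace(dataset, volumes=vol)


def extract_timeseries(dataset: BoldDataset, network: str,
                       voxel_ids: np.ndarray) -> VoxelTimeSeriesSet:
    """Pull the (k, t) matrix for one network's exclusive voxels."""
    data = dataset.volumes[
        voxel_ids[:, 0], voxel_ids[:, 1], voxel_ids[:, 2], :
    ].astype(np.float64)
    return VoxelTimeSeriesSet(
        network=network, subject_id=dataset.subject_id,
        voxel_ids=voxel_ids, data=data, tr=dataset.tr,
    )


def build_nuisance_design(dataset: BoldDataset) -> NuisanceDesign:
    """The 19-column design: intercept, 6 motion parameters, white-matter,
    ventricular and global signals, and their backward-difference temporal
    derivatives (first entry 0).  Source and derivative columns are
    mean-centred; the intercept is not.
    """
    t = dataset.n_timepoints
    sources: list[tuple[str, np.ndarray]] = []
    if dataset.motion is None:
        raise PreprocessError("missing regressor: motion")
    for j in range(6):
        sources.append((f"mot{j + 1}", dataset.motion[:, j]))
    for name, attr in (("wm", "wm_signal"), ("ventricle", "ventricle_signal"),
                       ("global", "global_signal")):
        sig = getattr(dataset, attr, None)
        if sig is None:
            raise PreprocessError(f"missing regressor: {name}")
        sources.append((name, np.asarray(sig, dtype=float)))

    cols = [np.ones(t)]
    names = ["intercept"]
    for name, s in sources:
        cols.append(s - s.mean())
        names.append(name)
    for name, s in sources:
        d = np.zeros(t)
        d[1:] = np.diff(s)
        cols.append(d - d.mean())
        names.append(f"d_{name}")
    design = NuisanceDesign(columns=np.column_stack(cols), column_names=names)
    assert design.n_columns == 2 * len(sources) + 1
    return design


def regress_nuisance(ts: VoxelTimeSeriesSet,
                     design: NuisanceDesign) -> VoxelTimeSeriesSet:
    """Replace every voxel row by its least-squares residual against the
    full design (computed via lstsq, which handles rank deficiency by the
    pseudoinverse)."""
    X = design.columns
    if X.shape[0] != ts.n_timepoints:
        raise PreprocessError("design rows must match series length")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        log.warning("nuisance design is rank deficient (rank %d of %d); "
                    "using pseudoinverse", rank, X.shape[1])
    beta, *_ = np.linalg.lstsq(X, ts.data.T, rcond=None)
    resid = ts.data - (X @ beta).T
    return ts.replace(data=resid, regressed=True)


def bandpass(ts: VoxelTimeSeriesSet, low_hz: float = DEFAULT_BAND[0],
             high_hz: float = DEFAULT_BAND[1]) -> VoxelTimeSeriesSet:
    """Zero-phase band-pass: order-2 Butterworth applied forward and
    backward (filtfilt), so the effective magnitude response is squared
    and the phase response is exactly zero."""
    fs = 1.0 / ts.tr
    nyq = fs / 2.0
    if not 0 <= low_hz < high_hz <= nyq:
        raise PreprocessError(
            f"band [{low_hz}, {high_hz}] Hz must satisfy "
            f"0 ≤ low < high ≤ Nyquist ({nyq} Hz)"
        )
    b, a = signal.butter(2, [low_hz, high_hz], btype="bandpass", fs=fs)
    # demean first (DC is outside the passband), then filter with
    # Gustafsson initial conditions, which minimise the slow edge
    # transients the 0.01 Hz corner would otherwise smear over ~100 samples
    centred = ts.data - ts.data.mean(axis=1, keepdims=True)
    out = signal.filtfilt(b, a, centred, axis=1, method="gust")
    return ts.replace(data=out, filtered=True)


def preprocess_subject(dataset: BoldDataset, atlas: RSNAtlas,
                       smooth_fwhm_mm: float = 0.0,
                       voxel_size_mm: float = 3.0,
                       band: tuple[float, float] = DEFAULT_BAND,
                       exclusive: dict[str, np.ndarray] | None = None):
    """Full per-subject pipeline.

    Returns ``(filtered, regressed)``: two dicts network → series set,
    the first regressed + band-passed (for graph construction), the
    second regressed only (for spectral analysis).
    """
    if exclusive is None:
        exclusive = exclude_overlap(atlas)
    ds = smooth_volumes(dataset, smooth_fwhm_mm, voxel_size_mm)
    design = build_nuisance_design(ds)
    regressed: dict[str, VoxelTimeSeriesSet] = {}
    filtered: dict[str, VoxelTimeSeriesSet] = {}
    for name, vox in exclusive.items():
        ts = extract_timeseries(ds, name, vox)
        ts = regress_nuisance(ts, design)
        regressed[name] = ts
        filtered[name] = bandpass(ts, band[0], band[1])
    return filtered, regressed
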