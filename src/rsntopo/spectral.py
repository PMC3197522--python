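"""Spectral summaries of network time-courses.

Power is estimated with the raw one-sided periodogram (no taper, no
segment averaging), normalised so that the ordinates sum to the series'
sum of squares (Parseval).  "Energy" is the sum of periodogram power over
discrete positive frequencies; the DC bin is excluded from every ratio.
Spectra are computed on regressed-but-unfiltered series, since the
analysis covers the full 0–Nyquist range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.fft import rfft, rfftfreq

from .preprocess import VoxelTimeSeriesSet
from .simulate import DEFAULT_BAND

__all__ = [
    "SpectralSummary",
    "RSNCrossCorrelation",
    "nyquist",
    "periodogram",
    "band_contribution",
    "band_power_summary",
    "falff",
    "rsn_cross_correlation",
]


class SpectralError(ValueError):
    pass


def nyquist(tr: float) -> float:
    """Highest detectable frequency for sampling interval ``tr`` seconds."""
    if tr <= 0:
        raise SpectralError("tr must be positive")
    return 1.0 / (2.0 * tr)


@dataclass
class SpectralSummary:
    network: str
    subject_id: str
    freqs: np.ndarray            # Hz, 0..Nyquist
    relative_power: np.ndarray   # periodogram / max, in [0, 1]
    band_contribution: float     # in-band / total positive-frequency power
    falff: float                 # voxel-wise variant, averaged over voxels


@dataclass
class RSNCrossCorrelation:
    networks: list[str]
    matrix: np.ndarray           # across-subject mean, 6×6
    per_subject: np.ndarray      # (n_subjects, 6, 6)


def periodogram(x: np.ndarray, tr: float):
    """One-sided periodogram with Parseval normalisation.

    Returns ``(freqs, power)`` where ``power.sum() == (x**2).sum()``:
    interior bins carry ``2|X_k|²/n``, the DC and (even-n) Nyquist bins
    ``|X_k|²/n``.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    freqs = rfftfreq(n, d=tr)
    X = rfft(x, axis=-1)
    p = (np.abs(X) ** 2) / n
    scale = np.full(len(freqs), 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    return freqs, p * scale


def band_contribution(x: np.ndarray, tr: float,
                      band: tuple[float, float] = DEFAULT_BAND) -> float:
    """Fraction of positive-frequency power inside ``band`` (inclusive)."""
    low, high = band
    if not 0 < low < high <= nyquist(tr) + 1e-12:
        raise SpectralError("band must lie within (0, Nyquist]")
    freqs, p = periodogram(x, tr)
    pos = freqs > 0
    total = float(p[..., pos].sum(axis=-1))
    if total <= 0:
        raise SpectralError("degenerate spectrum: series has no power")
    sel = (freqs >= low) & (freqs <= high)
    return float(p[..., sel].sum(axis=-1)) / total


def band_power_summary(ts: VoxelTimeSeriesSet,
                       band: tuple[float, float] = DEFAULT_BAND,
                       falff_mode: str = "power") -> SpectralSummary:
    """Relative power of the voxel-averaged time-course plus the low-band
    contribution and the voxel-wise fALFF."""
    mean_tc = ts.mean_timecourse()
    freqs, p = periodogram(mean_tc, ts.tr)
    pmax = p.max()
    if pmax <= 0:
        raise SpectralError(
            f"degenerate spectrum for {ts.network}/{ts.subject_id}"
        )
    return SpectralSummary(
        network=ts.network, subject_id=ts.subject_id,
        freqs=freqs, relative_power=p / pmax,
        band_contribution=band_contribution(mean_tc, ts.tr, band),
        falff=falff(ts, band, mode=falff_mode),
    )


def falff(ts: VoxelTimeSeriesSet, band: tuple[float, float] = DEFAULT_BAND,
          mode: str = "power") -> float:
    """Fractional low-frequency amplitude, per voxel, averaged over the
    network's voxels.

    ``mode="power"`` uses the power ratio (default); ``mode="amplitude"``
    uses the ratio of summed square-root amplitudes.
    """
    low, high = band
    if not 0 < low < high <= nyquist(ts.tr) + 1e-12:
        raise SpectralError("band must lie within (0, Nyquist]")
    freqs, p = periodogram(ts.data, ts.tr)
    if mode == "amplitude":
        p = np.sqrt(p)
    elif mode != "power":
        raise SpectralError(f"unknown fALFF mode {mode!r}")
    pos = freqs > 0
    sel = (freqs >= low) & (freqs <= high)
    totals = p[:, pos].sum(axis=1)
    if np.any(totals <= 0):
        raise SpectralError("degenerate spectrum in at least one voxel")
    ratios = p[:, sel].sum(axis=1) / totals
    return float(ratios.mean())


def rsn_cross_correlation(
    mean_timecourses: list[dict[str, np.ndarray]],
    networks: list[str] | None = None,
) -> RSNCrossCorrelation:
    """Across-network correlation structure.

    ``mean_timecourses`` holds, per subject, the network-averaged cleaned
    time-courses.  Returns per-subject Pearson matrices and their
    across-subject mean.
    """
    if not mean_timecourses:
        raise SpectralError("no subjects provided")
    if networks is None:
        networks = list(mean_timecourses[0])
    stack = []
    for sub in mean_timecourses:
        missing = [n for n in networks if n not in sub]
        if missing:
            raise SpectralError(f"subject lacks networks: {missing}")
        rows = np.stack([np.asarray(sub[n], dtype=float) for n in networks])
        if np.any(rows.std(axis=1) == 0):
            raise SpectralError("constant network time-course")
        stack.append(np.corrcoef(rows))
    per_subject = np.stack(stack)
    return RSNCrossCorrelation(
        networks=list(networks),
        matrix=per_subject.mean(axis=0),
        per_subject=per_subject,
    )
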