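"""Signal-level preprocessing: confound regression, detrend, band-pass.

Stage order is confounds -> linear detrend -> band-pass, mirroring standard
resting-state denoising.  All three operations are linear maps of the input
series, so downstream correlations are unaffected by their ordering with any
other linear step.  The band-pass is an ideal (boxcar) frequency-domain
filter: deterministic, parameter-free beyond the band edges, and exactly
testable — correlations are insensitive to the phase behavior that
distinguishes filter families.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core import TimeSeriesPanel

__all__ = [
    "PreprocessConfig",
    "regress_confounds",
    "detrend_linear",
    "bandpass",
    "confound_derivatives",
    "preprocess_panel",
]


@dataclasses.dataclass(frozen=True)
class PreprocessConfig:
    """Band edges in Hz (defaults 0.008-0.09) and a detrend toggle."""

    band_low_hz: float = 0.008
    band_high_hz: float = 0.09
    detrend: bool = True

    def validate(self, tr_seconds: float) -> None:
        nyquist = 1.0 / (2.0 * tr_seconds)
        if not 0 < self.band_low_hz < self.band_high_hz < nyquist:
            raise ValueError(
                f"band ({self.band_low_hz}, {self.band_high_hz}) Hz invalid for "
                f"TR {tr_seconds}s (Nyquist {nyquist} Hz)"
            )


def regress_confounds(series: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """Residualise each node series on [intercept | confounds].

    ``series`` is nodes x timepoints, ``confounds`` timepoints x k.  Raises
    if the design matrix is rank-deficient, naming the collinear columns.
    """
    series = np.asarray(series, dtype=float)
    confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
    if confounds.shape[0] != series.shape[1]:
        raise ValueError("confound rows must equal the number of timepoints")
    design = np.column_stack([np.ones(series.shape[1]), confounds])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _collinear_columns(design)
        raise ValueError(f"confound design is rank-deficient (columns {bad})")
    beta, *_ = np.linalg.lstsq(design, series.T, rcond=None)
    return series - (design @ beta).T


def _collinear_columns(design: np.ndarray) -> list[int]:
    # columns (0 = intercept) whose removal restores full rank
    full = np.linalg.matrix_rank(design)
    bad = []
    for j in range(design.shape[1]):
        reduced = np.delete(design, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full:
            bad.append(j)
    return bad


def confound_derivatives(confounds: np.ndarray) -> np.ndarray:
    """Backward differences of each confound column, first element 0."""
    confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
    d = np.diff(confounds, axis=0, prepend=confounds[:1])
    return d


def detrend_linear(series: np.ndarray) -> np.ndarray:
    """Remove mean and linear trend from each node series."""
    series = np.asarray(series, dtype=float)
    t = series.shape[-1]
    if t < 3:
        raise ValueError("need at least 3 timepoints to detrend")
    ramp = np.arange(t, dtype=float)
    ramp -= ramp.mean()
    demeaned = series - series.mean(axis=-1, keepdims=True)
    slope = (demeaned @ ramp) / (ramp @ ramp)
    return demeaned - slope[..., None] * ramp


def bandpass(
    series: np.ndarray, cfg: PreprocessConfig, tr_seconds: float
) -> np.ndarray:
    """Ideal boxcar band-pass on the discrete Fourier spectrum.

    Frequencies strictly above ``band_low_hz`` and up to (inclusive)
    ``band_high_hz`` are retained; DC and Nyquist are always removed.
    """
    cfg.validate(tr_seconds)
    series = np.asarray(series, dtype=float)
    t = series.shape[-1]
    freqs = np.fft.rfftfreq(t, d=tr_seconds)
    keep = (freqs > cfg.band_low_hz) & (freqs <= cfg.band_high_hz)
    keep[0] = False
    if t % 2 == 0:
        keep[-1] = False  # Nyquist bin
    if not keep.any():
        raise ValueError(
            f"band ({cfg.band_low_hz}, {cfg.band_high_hz}) Hz retains no Fourier "
            f"bins at {t} timepoints / TR {tr_seconds}s"
        )
    spectrum = np.fft.rfft(series, axis=-1)
    spectrum[..., ~keep] = 0.0
    return np.fft.irfft(spectrum, n=t, axis=-1)


def preprocess_panel(
    panel: TimeSeriesPanel,
    cfg: PreprocessConfig | None = None,
    confounds: dict[str, np.ndarray] | None = None,
) -> TimeSeriesPanel:
    """Apply confound regression (optional), detrend and band-pass per
    subject/condition; returns a new panel."""
    cfg = cfg or PreprocessConfig()
    cfg.validate(panel.tr_seconds)
    out = np.empty_like(panel.data)
    for si, subject in enumerate(panel.subject_ids):
        for ci in range(2):
            series = panel.data[si, ci]
            if confounds and subject in confounds:
                series = regress_confounds(series, confounds[subject])
            if cfg.detrend:
                series = detrend_linear(series)
            out[si, ci] = bandpass(series, cfg, panel.tr_seconds)
    return TimeSeriesPanel(
        data=out,
        condition_names=panel.condition_names,
        tr_seconds=panel.tr_seconds,
        subject_ids=panel.subject_ids,
    )
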