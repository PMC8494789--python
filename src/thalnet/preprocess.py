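"""Per-subject preprocessing: frame trimming, highpass filtering, confound regression.

Only the stages the pipeline itself owns live here; motion correction,
slice-timing correction and spatial registration are assumed done upstream,
and no spatial smoothing is applied anywhere in the pipeline.

The fixed stage order is trim -> highpass -> confound regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .volume_io import Volume4D

#: Confound column names expected by the pipeline: six rigid-body motion
#: parameters plus mean white-matter and CSF signals.
STANDARD_CONFOUNDS = (
    "trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z", "wm", "csf",
)


@dataclass
class ConfoundTable:
    """Named nuisance time series: motion parameters, WM and CSF means."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.isna().any().any():
            bad = [c for c in self.table.columns if self.table[c].isna().any()]
            raise ValueError(f"confound columns contain NaN: {bad}")

    @property
    def n_timepoints(self) -> int:
        return len(self.table)

    @property
    def matrix(self) -> np.ndarray:
        return self.table.to_numpy(dtype=np.float64)

    @classmethod
    def read(cls, path: str | Path) -> "ConfoundTable":
        """Read a whitespace- or tab-delimited confound file with a header row."""
        return cls(pd.read_csv(path, sep=r"\s+"))

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def trim_initial_frames(vol: Volume4D, k: int) -> Volume4D:
    """Drop the first ``k`` frames (dummy scans before steady-state)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= vol.n_frames:
        raise ValueError(f"cannot trim {k} frames from a {vol.n_frames}-frame volume")
    return Volume4D(data=vol.data[..., k:].copy(), affine=vol.affine,
                    frame_axis_meaning=vol.frame_axis_meaning)


def highpass_filter(vol: Volume4D, cutoff_hz: float, tr_s: float) -> Volume4D:
    """Remove fluctuations slower than ``cutoff_hz`` from each voxel series.

    Frequency-domain filter with a raised-cosine rolloff of width 0.002 Hz
    around the cutoff; the per-voxel temporal mean is restored afterwards so
    the DC level is preserved. Output length equals input length.
    """
    if vol.frame_axis_meaning != "time":
        raise ValueError("highpass filtering requires a time axis")
    if cutoff_hz <= 0 or tr_s <= 0:
        raise ValueError("cutoff and TR must be positive")
    nyquist = 0.5 / tr_s
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist:.4f} Hz")
    n = vol.n_frames
    freqs = np.fft.rfftfreq(n, d=tr_s)
    width = 0.002
    lo, hi = cutoff_hz - width / 2.0, cutoff_hz + width / 2.0
    gain = np.ones_like(freqs)
    gain[freqs <= lo] = 0.0
    ramp = (freqs > lo) & (freqs < hi)
    gain[ramp] = 0.5 * (1.0 - np.cos(np.pi * (freqs[ramp] - lo) / width))

    flat = vol.data.reshape(-1, n)
    means = flat.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(flat - means, axis=1)
    filtered = np.fft.irfft(spec * gain, n=n, axis=1) + means
    return Volume4D(data=filtered.reshape(vol.data.shape), affine=vol.affine,
                    frame_axis_meaning="time")


def regress_confounds(vol: Volume4D, conf: ConfoundTable) -> Volume4D:
    """Replace each voxel series by its OLS residual against the confounds.

    The design is [intercept | confound columns]; residuals are orthogonal to
    every confound column and to the constant (the data come out demeaned in
    time, which is immaterial for the correlation analysis downstream).
    """
    if conf.n_timepoints != vol.n_frames:
        raise ValueError(
            f"confounds have {conf.n_timepoints} rows, volume has {vol.n_frames} frames")
    # constant columns duplicate the intercept and carry no information
    mat = conf.matrix
    varying = mat.std(axis=0) > 0
    mat = mat[:, varying]
    cols = [c for c, keep in zip(conf.table.columns, varying) if keep]
    X = np.column_stack([np.ones(vol.n_frames), mat])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = np.corrcoef(mat, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"confound matrix is rank-deficient (rank {rank} < {X.shape[1]}); "
            f"most collinear pair: {cols[i]!r}, {cols[j]!r}")
    flat = vol.data.reshape(-1, vol.n_frames).T  # time x voxels
    beta, *_ = np.linalg.lstsq(X, flat, rcond=None)
    resid = flat - X @ beta
    return Volume4D(data=resid.T.reshape(vol.data.shape), affine=vol.affine,
                    frame_axis_meaning=vol.frame_axis_meaning)


def preprocess_subject(vol: Volume4D, conf: ConfoundTable, *, trim: int = 4,
                       highpass_hz: float | None = 0.01, tr_s: float = 3.5
                       ) -> Volume4D:
    """Apply the full in-scope preprocessing chain to one subject.

    Trims ``trim`` initial frames (the confound table may cover either the
    full or the trimmed series), highpass-filters above ``highpass_hz``
    (skipped when None), then regresses out the confounds.
    """
    out = trim_initial_frames(vol, trim) if trim else vol
    if conf.n_timepoints == vol.n_frames and trim:
        conf = ConfoundTable(conf.table.iloc[trim:].reset_index(drop=True))
    if highpass_hz is not None:
        out = highpass_filter(out, highpass_hz, tr_s)
    return regress_confounds(out, conf)
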