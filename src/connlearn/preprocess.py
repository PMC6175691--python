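"""Temporal preprocessing of regional fMRI time series.

Order of operations mirrors standard resting-state practice: nuisance
regression (white-matter / CSF signals plus the six rigid-body motion
parameters), then an ideal band-pass filter in the 0.01-0.1 Hz range.
Head motion is summarized per frame as framewise displacement (FD) with
rotations projected onto a 50 mm sphere; scrubbing deletes frames above an
FD threshold and flags subjects whose spike count exceeds a fixed fraction
of the run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PreprocessConfig",
    "CollinearityError",
    "framewise_displacement",
    "regress_nuisance",
    "bandpass",
    "scrub",
    "preprocess_timeseries",
]

#: Condition number above which a nuisance design is treated as rank deficient.
CONDITION_LIMIT = 1e8


class CollinearityError(ValueError):
    pass


@dataclass(frozen=True)
class PreprocessConfig:
    """Temporal preprocessing settings.

    band_low, band_high : Hz, pass band of the ideal filter.
    fd_radius : mm, sphere radius converting rotations to displacements.
    scrub_threshold : mm, FD above which a frame is deleted when scrubbing.
    exclusion_fraction : subjects whose deleted-frame fraction exceeds this
        are flagged for exclusion.
    """

    band_low: float = 0.01
    band_high: float = 0.1
    fd_radius: float = 50.0
    scrub_threshold: float = 0.5
    exclusion_fraction: float = 0.10

    def validate(self, tr: float) -> None:
        nyquist = 1.0 / (2.0 * tr)
        if not 0.0 < self.band_low < self.band_high:
            raise ValueError(f"need 0 < band_low < band_high, got ({self.band_low}, {self.band_high})")
        if self.band_high >= nyquist:
            raise ValueError(
                f"band_high={self.band_high} Hz must be below the Nyquist frequency {nyquist} Hz (TR={tr} s)"
            )


def framewise_displacement(motion: np.ndarray, fd_radius: float = 50.0) -> tuple[np.ndarray, float]:
    """Per-frame framewise displacement and its mean.

    ``motion`` is (frames, 6): three translations in mm followed by three
    rotations in radians. FD at frame t (t >= 1) is the sum of absolute
    backward differences of the translations plus ``fd_radius`` times the
    summed absolute rotation differences; FD of the first frame is 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be (frames, 6), got {motion.shape}")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 frames to form displacements")
    diffs = np.abs(np.diff(motion, axis=0))
    fd = np.zeros(motion.shape[0])
    fd[1:] = diffs[:, :3].sum(axis=1) + fd_radius * diffs[:, 3:].sum(axis=1)
    return fd, float(fd.mean())


def regress_nuisance(ts: np.ndarray, nuisance: np.ndarray) -> np.ndarray:
    """Residualize every node series on [intercept + nuisance columns].

    Residuals are orthogonal to each regressor up to numerical precision.
    Raises :class:`CollinearityError` naming the offending columns when the
    design is effectively rank deficient (condition number > 1e8).
    """
    ts = np.asarray(ts, dtype=float)
    nuisance = np.asarray(nuisance, dtype=float)
    if nuisance.ndim == 1:
        nuisance = nuisance[:, None]
    if nuisance.shape[0] != ts.shape[0]:
        raise ValueError(
            f"nuisance has {nuisance.shape[0]} frames but the time series has {ts.shape[0]}"
        )
    design = np.column_stack([np.ones(ts.shape[0]), nuisance])
    cond = np.linalg.cond(design)
    if cond > CONDITION_LIMIT:
        # identify columns that are nearly explained by the preceding ones
        bad: list[int] = []
        for j in range(1, design.shape[1]):
            sub = design[:, : j + 1]
            if np.linalg.matrix_rank(sub, tol=sub.shape[0] * np.finfo(float).eps * 1e4) <= np.linalg.matrix_rank(design[:, :j]):
                bad.append(j - 1)  # nuisance column index
        raise CollinearityError(
            f"nuisance design is rank deficient (cond={cond:.3g}); offending nuisance columns: {bad}"
        )
    beta, *_ = np.linalg.lstsq(design, ts, rcond=None)
    return ts - design @ beta


def bandpass(ts: np.ndarray, tr: float, band_low: float = 0.01, band_high: float = 0.1) -> np.ndarray:
    """Ideal (rectangular) frequency-domain band-pass filter.

    DFT components with frequency in [band_low, band_high] Hz are retained,
    everything else — including the DC component — is zeroed. Idempotent by
    construction.
    """
    ts = np.asarray(ts, dtype=float)
    nyquist = 1.0 / (2.0 * tr)
    if not 0.0 < band_low < band_high:
        raise ValueError("need 0 < band_low < band_high")
    if band_high >= nyquist:
        raise ValueError(f"band_high={band_high} Hz is at or above Nyquist ({nyquist} Hz)")
    squeeze = ts.ndim == 1
    if squeeze:
        ts = ts[:, None]
    n = ts.shape[0]
    freqs = np.fft.rfftfreq(n, d=tr)
    keep = (freqs >= band_low) & (freqs <= band_high)
    spec = np.fft.rfft(ts, axis=0)
    spec[~keep] = 0.0
    out = np.fft.irfft(spec, n=n, axis=0)
    return out[:, 0] if squeeze else out


def scrub(
    ts: np.ndarray,
    fd: np.ndarray,
    scrub_threshold: float = 0.5,
    exclusion_fraction: float = 0.10,
) -> tuple[np.ndarray, int, bool]:
    """Delete frames with FD above threshold.

    Returns (censored series, number of frames removed, exclude_subject flag).
    The flag fires when the removed fraction strictly exceeds
    ``exclusion_fraction`` of the total frames.
    """
    ts = np.asarray(ts, dtype=float)
    fd = np.asarray(fd, dtype=float)
    if fd.shape[0] != ts.shape[0]:
        raise ValueError(f"fd has {fd.shape[0]} frames but the series has {ts.shape[0]}")
    keep = fd <= scrub_threshold
    removed = int((~keep).sum())
    if removed == ts.shape[0]:
        raise ValueError("scrubbing removed every frame")
    exclude = removed / ts.shape[0] > exclusion_fraction
    return ts[keep], removed, exclude


def preprocess_timeseries(
    ts: np.ndarray,
    motion: np.ndarray,
    nuisance: np.ndarray | None,
    tr: float,
    config: PreprocessConfig | None = None,
) -> tuple[np.ndarray, float]:
    """Nuisance regression (motion parameters + optional WM/CSF-like
    regressors) followed by band-pass filtering.

    Returns the filtered series and the subject's mean FD (used downstream
    as a covariate of non-interest).
    """
    config = config or PreprocessConfig()
    config.validate(tr)
    fd, mean_fd = framewise_displacement(motion, config.fd_radius)
    regs = motion if nuisance is None else np.column_stack([motion, nuisance])
    resid = regress_nuisance(ts, regs)
    filtered = bandpass(resid, tr, config.band_low, config.band_high)
    return filtered, mean_fd
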