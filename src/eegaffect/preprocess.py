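"""Preprocessing: FIR band-pass, downsampling, epoch cleaning, rank reduction.

The chain mirrors standard affective-EEG practice: band-pass the continuous
recording 0.5–45 Hz with windowed-sinc FIR filters (zero net phase), then
downsample to 512 Hz, extract 6-s stimulus epochs, reject and interpolate
noisy channels, drop artifact epochs, re-reference to the channel average,
and reduce dimensionality to the data rank before ICA.  Visual inspection is
replaced by explicit robust statistics: channels at robust |z| > 5 of
log-variance are interpolated; epochs with peak-to-peak above 200 µV or
variance z above 4 are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal


class PipelineAbort(RuntimeError):
    """A stage cannot produce usable output; carries a diagnostic."""


@dataclass
class EpochedData:
    """Trials × channels × samples with channel geometry and bookkeeping."""

    data: np.ndarray
    sampling_rate: float
    channel_names: list[str]
    channel_positions: np.ndarray          # unit vectors, (n_channels, 3)
    stimulus_ids: np.ndarray
    reference: str = "none"
    interpolated: list[int] = field(default_factory=list)
    retained_epochs: np.ndarray | None = None   # indices into the schedule

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("EpochedData.data must be (epochs, channels, samples)")
        if self.retained_epochs is None:
            self.retained_epochs = np.arange(self.data.shape[0])

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class CleaningReport:
    """Per-participant cleaning bookkeeping (channels rejected, epochs removed)."""

    n_channels_interpolated: int
    interpolated_channels: list[str]
    n_epochs_removed: int
    fraction_epochs_removed: float
    removed_epochs: list[int]

    def as_dict(self) -> dict:
        return {
            "n_channels_interpolated": self.n_channels_interpolated,
            "interpolated_channels": list(self.interpolated_channels),
            "n_epochs_removed": self.n_epochs_removed,
            "fraction_epochs_removed": self.fraction_epochs_removed,
            "removed_epochs": list(map(int, self.removed_epochs)),
        }


# ----------------------------------------------------------------------
# filtering and resampling


def design_fir(
    sampling_rate: float, cutoff_hz: float, kind: str, transition_hz: float
) -> np.ndarray:
    """Windowed-sinc FIR taps (Hamming window, odd length, linear phase)."""
    nyq = sampling_rate / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz outside (0, {nyq}) Hz")
    # Hamming main-lobe rule: transition width ~ 3.3 / numtaps (normalized)
    numtaps = int(np.ceil(3.3 * sampling_rate / transition_hz))
    numtaps += (numtaps + 1) % 2  # odd -> integer group delay
    return signal.firwin(
        numtaps, cutoff_hz, window="hamming", pass_zero=(kind == "lowpass"), fs=sampling_rate
    )


def fir_filter(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR along the last axis with zero net delay."""
    shape = x.shape
    flat = x.reshape(-1, shape[-1])
    out = signal.fftconvolve(flat, taps[None, :], mode="same", axes=-1)
    return out.reshape(shape)


def preprocess_raw(
    raw: np.ndarray,
    sampling_rate: float,
    highpass_hz: float = 0.5,
    lowpass_hz: float = 45.0,
    target_rate_hz: float = 512.0,
    highpass_transition_hz: float = 0.5,
    lowpass_transition_hz: float = 5.0,
) -> tuple[np.ndarray, float]:
    """Band-pass filter and downsample a continuous multichannel recording.

    Parameters
    ----------
    raw : ndarray (..., n_samples)
        Continuous data; filtering acts on the last axis.

    Returns
    -------
    (filtered_downsampled, target_rate_hz)
    """
    nyq_target = target_rate_hz / 2.0
    if lowpass_hz >= nyq_target:
        raise ValueError(
            f"lowpass {lowpass_hz} Hz must be below target Nyquist {nyq_target} Hz"
        )
    if highpass_hz >= lowpass_hz:
        raise ValueError("highpass must be below lowpass")
    hp = design_fir(sampling_rate, highpass_hz, "highpass", highpass_transition_hz)
    lp = design_fir(sampling_rate, lowpass_hz, "lowpass", lowpass_transition_hz)
    y = fir_filter(fir_filter(raw, hp), lp)
    frac = Fraction(target_rate_hz / sampling_rate).limit_denominator(1000)
    if frac.numerator == frac.denominator:
        return y, sampling_rate
    # the 45 Hz lowpass already anti-aliases; resample_poly adds its own guard
    y = signal.resample_poly(y, frac.numerator, frac.denominator, axis=-1)
    return y, sampling_rate * frac.numerator / frac.denominator


def extract_epochs(
    continuous: np.ndarray,
    sampling_rate: float,
    onsets_s: np.ndarray,
    duration_s: float = 6.0,
) -> np.ndarray:
    """Cut (epochs, channels, samples) windows out of continuous data."""
    n = int(round(duration_s * sampling_rate))
    out = []
    for t0 in np.asarray(onsets_s, dtype=float):
        i0 = int(round(t0 * sampling_rate))
        if i0 < 0 or i0 + n > continuous.shape[-1]:
            raise ValueError(f"epoch at {t0} s exceeds recording bounds")
        out.append(continuous[..., i0 : i0 + n])
    return np.stack(out, axis=0)


# ----------------------------------------------------------------------
# cleaning


def _robust_z(values: np.ndarray) -> np.ndarray:
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    scale = 1.4826 * mad
    if scale == 0:
        return np.zeros_like(values)
    return (values - med) / scale


def interpolate_channels(
    data: np.ndarray, positions: np.ndarray, bad: list[int], power: float = 2.0
) -> np.ndarray:
    """Replace bad channels by inverse-distance averages on the sphere.

    Weights are 1/angle**power over the good channels, using the great-circle
    angle between unit-sphere electrode positions.
    """
    bad = sorted(set(bad))
    good = [i for i in range(data.shape[1]) if i not in bad]
    if len(good) < 4:
        raise PipelineAbort(f"only {len(good)} good channels left; need >= 4")
    out = data.copy()
    pos = positions / np.linalg.norm(positions, axis=1, keepdims=True)
    for b in bad:
        ang = np.arccos(np.clip(pos[good] @ pos[b], -1.0, 1.0))
        w = 1.0 / np.maximum(ang, 1e-6) ** power
        w /= w.sum()
        out[:, b, :] = np.tensordot(w, data[:, good, :], axes=(0, 1))
    return out


def clean_epochs(
    epoched: EpochedData,
    channel_z_thresh: float = 5.0,
    epoch_ptp_thresh: float = 200.0,
    epoch_z_thresh: float = 4.0,
) -> tuple[EpochedData, CleaningReport]:
    """Flag/interpolate noisy channels, then drop artifact epochs.

    Channels whose log-variance robust z exceeds ``channel_z_thresh`` in
    magnitude are interpolated; epochs whose peak-to-peak amplitude exceeds
    ``epoch_ptp_thresh`` (µV) or whose log-variance z exceeds
    ``epoch_z_thresh`` are removed.  Epochs that are not flagged are
    returned bit-identical except on interpolated channels.
    """
    if epoched.n_channels < 4:
        raise PipelineAbort("need at least 4 channels")
    if epoched.n_epochs < 2:
        raise PipelineAbort("need at least 2 epochs")
    x = np.asarray(epoched.data)

    ch_logvar = np.log(x.var(axis=(0, 2), dtype=np.float64) + 1e-30)
    ch_z = _robust_z(ch_logvar)
    bad_channels = [int(i) for i in np.flatnonzero(np.abs(ch_z) > channel_z_thresh)]
    data = (
        interpolate_channels(x, epoched.channel_positions, bad_channels)
        if bad_channels
        else x
    )

    ptp = data.max(axis=(1, 2)) - data.min(axis=(1, 2))
    ep_logvar = np.log(data.var(axis=(1, 2), dtype=np.float64) + 1e-30)
    ep_z = _robust_z(ep_logvar)
    drop = (ptp > epoch_ptp_thresh) | (ep_z > epoch_z_thresh)
    if drop.all():
        raise PipelineAbort(
            f"all {epoched.n_epochs} epochs rejected "
            f"(max ptp {ptp.max():.1f} µV, max variance z {ep_z.max():.1f})"
        )
    keep = np.flatnonzero(~drop)

    cleaned = replace(
        epoched,
        data=data[keep],
        interpolated=sorted(set(epoched.interpolated) | set(bad_channels)),
        stimulus_ids=np.asarray(epoched.stimulus_ids)[keep],
        retained_epochs=np.asarray(epoched.retained_epochs)[keep],
    )
    report = CleaningReport(
        n_channels_interpolated=len(bad_channels),
        interpolated_channels=[epoched.channel_names[i] for i in bad_channels],
        n_epochs_removed=int(drop.sum()),
        fraction_epochs_removed=float(drop.mean()),
        removed_epochs=list(np.flatnonzero(drop)),
    )
    return cleaned, report


# ----------------------------------------------------------------------
# average reference and rank reduction


def average_reference(data: np.ndarray) -> np.ndarray:
    """Subtract the channel mean at every sample (channels on axis -2)."""
    return data - data.mean(axis=-2, keepdims=True)


@dataclass
class IcaReady:
    """Concatenated, average-referenced, rank-reduced data for ICA.

    ``scores`` is (rank, total_samples) in the principal subspace;
    ``basis`` is (n_channels, rank) with orthonormal columns, so channel
    topographies of ICA components are ``basis @ mixing_column``.
    """

    scores: np.ndarray
    basis: np.ndarray
    rank: int
    n_epochs: int
    n_samples_per_epoch: int
    channel_names: list[str]
    channel_positions: np.ndarray
    stimulus_ids: np.ndarray

    def epochs_of(self, activations: np.ndarray) -> np.ndarray:
        """Reshape (k, total_samples) activations to (k, epochs, samples)."""
        k = activations.shape[0]
        return activations.reshape(k, self.n_epochs, self.n_samples_per_epoch)


def prepare_for_ica(epoched: EpochedData) -> IcaReady:
    """Concatenate epochs, average-reference, and project to the data rank.

    The rank is channels − 1 (average reference) − interpolated channels;
    the projection keeps the top-rank principal directions of the
    referenced data.
    """
    e, c, t = epoched.data.shape
    rank = c - 1 - len(set(epoched.interpolated))
    if rank < 4:
        raise PipelineAbort(f"data rank {rank} too low for decomposition")
    x = average_reference(np.asarray(epoched.data))
    flat = np.ascontiguousarray(np.transpose(x, (1, 0, 2)).reshape(c, e * t))
    # principal directions of the channel covariance
    cov = (flat @ flat.T).astype(np.float64) / flat.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    basis = evecs[:, ::-1][:, :rank]
    scores = basis.T.astype(flat.dtype) @ flat
    return IcaReady(
        scores=scores,
        basis=basis,
        rank=rank,
        n_epochs=e,
        n_samples_per_epoch=t,
        channel_names=list(epoched.channel_names),
        channel_positions=epoched.channel_positions,
        stimulus_ids=np.asarray(epoched.stimulus_ids),
    )
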