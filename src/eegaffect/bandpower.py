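"""Welch spectra and log band-power features.

PSDs use 512-point (1 s at 512 Hz) Hann-windowed segments with a 128-point
overlap, averaged across the segments of a 6-s epoch (7 segments).  Band
power is the mean of the PSD bins inside a band, edges inclusive, and the
feature is its natural logarithm.  When one participant contributes several
ICs to a cluster, their PSDs are averaged bin-wise *before* the log — the
order matters and is asserted by tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not self.lo_hz < self.hi_hz:
            raise ValueError(f"band {self.name}: need lo < hi, got ({self.lo_hz}, {self.hi_hz})")


DEFAULT_BANDS = (
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 14.0, 30.0),
    BandDefinition("gamma", 31.0, 45.0),
)

BAND_NAMES = tuple(b.name for b in DEFAULT_BANDS)


def welch_psd(
    x: np.ndarray,
    sampling_rate: float = 512.0,
    nfft: int = 512,
    overlap: int = 128,
    window: str = "hann",
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD over the last axis.

    Segments of ``nfft`` samples advance by ``nfft - overlap``; each segment
    is Hann-windowed and window-power normalized (density scaling), and the
    per-segment periodograms are averaged.  At 512 Hz with nfft=512 the
    frequency resolution is 1 Hz and a 6-s epoch yields 7 segments.

    Returns
    -------
    freqs : ndarray, shape (nfft // 2 + 1,)
    psd : ndarray, broadcast shape of ``x`` with last axis replaced
    """
    x = np.asarray(x)
    if x.shape[-1] < nfft:
        raise ValueError(f"signal length {x.shape[-1]} shorter than nfft={nfft}")
    freqs, psd = signal.welch(
        x,
        fs=sampling_rate,
        window=window,
        nperseg=nfft,
        noverlap=overlap,
        nfft=nfft,
        detrend=False,
        scaling="density",
        axis=-1,
    )
    return freqs, psd


def n_welch_segments(n_samples: int, nfft: int = 512, overlap: int = 128) -> int:
    """Number of averaged segments for a signal of ``n_samples``."""
    if n_samples < nfft:
        raise ValueError(f"signal length {n_samples} shorter than nfft={nfft}")
    step = nfft - overlap
    return (n_samples - nfft) // step + 1


def band_power(freqs: np.ndarray, psd: np.ndarray, band: BandDefinition) -> np.ndarray:
    """Mean PSD over in-band bins, both edges inclusive."""
    mask = (freqs >= band.lo_hz) & (freqs <= band.hi_hz)
    if not mask.any():
        raise ValueError(f"no PSD bins inside band {band.name} ({band.lo_hz}-{band.hi_hz} Hz)")
    return psd[..., mask].mean(axis=-1)


def log_band_powers(
    freqs: np.ndarray, psd: np.ndarray, bands=DEFAULT_BANDS
) -> np.ndarray:
    """Natural-log band power for each band, stacked on a new last axis."""
    return np.stack([np.log(band_power(freqs, psd, b)) for b in bands], axis=-1)


def aggregate_cluster_features(
    member_activations: dict[str, np.ndarray],
    sampling_rate: float = 512.0,
    bands=DEFAULT_BANDS,
    cluster_index: int = 0,
    stimulus_ids: dict[str, np.ndarray] | None = None,
    nfft: int = 512,
    overlap: int = 128,
) -> pd.DataFrame:
    """One feature row per (participant, epoch) for one IC cluster.

    Parameters
    ----------
    member_activations : dict
        participant_id -> array (n_member_ics, n_epochs, n_samples) holding
        the epoch-wise activations of that participant's ICs in the cluster.
    stimulus_ids : dict, optional
        participant_id -> (n_epochs,) stimulus ids, recorded per row.

    Notes
    -----
    PSDs of a participant's member ICs are averaged bin-wise before the log
    transform; a single member IC therefore reduces to its own log band
    power, and duplicated identical ICs change nothing.
    """
    rows = []
    for pid, acts in member_activations.items():
        acts = np.asarray(acts)
        if acts.ndim != 3:
            raise ValueError("member activations must be (n_ics, n_epochs, n_samples)")
        freqs, psd = welch_psd(acts, sampling_rate, nfft=nfft, overlap=overlap)
        mean_psd = psd.mean(axis=0)  # average PSDs across member ICs first
        feats = log_band_powers(freqs, mean_psd, bands)  # (n_epochs, n_bands)
        sids = None if stimulus_ids is None else np.asarray(stimulus_ids[pid])
        for e in range(feats.shape[0]):
            row = {
                "participant_id": pid,
                "cluster_index": cluster_index,
                "epoch_id": e,
            }
            if sids is not None:
                row["stimulus_id"] = int(sids[e])
            row.update({b.name: float(feats[e, i]) for i, b in enumerate(bands)})
            rows.append(row)
    out = pd.DataFrame(rows)
    if len(out) and not np.isfinite(out[[b.name for b in bands]].to_numpy()).all():
        raise ValueError("non-finite band-power feature encountered")
    return out
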