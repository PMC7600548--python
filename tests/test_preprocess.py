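"""Filtering, downsampling, epoch cleaning, and rank reduction."""

import numpy as np
import pytest

from eegaffect.headmodel import HeadModel
from eegaffect.preprocess import (
    EpochedData,
    PipelineAbort,
    average_reference,
    clean_epochs,
    extract_epochs,
    interpolate_channels,
    prepare_for_ica,
    preprocess_raw,
)


def _sine(freq, fs, dur=12.0):
    t = np.arange(int(dur * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


def test_stopband_attenuation_at_60hz():
    fs = 2048.0
    x = _sine(60.0, fs)[None, :]
    y, fs_out = preprocess_raw(x, fs)
    # compare RMS in the central half (away from edge effects)
    n = y.shape[-1]
    sl = slice(n // 4, 3 * n // 4)
    rms_out = np.sqrt(np.mean(y[0, sl] ** 2))
    rms_in = np.sqrt(0.5)
    atten_db = 20 * np.log10(rms_in / max(rms_out, 1e-30))
    assert atten_db >= 40.0


def test_passband_preserves_10hz_within_5pct():
    fs = 2048.0
    x = _sine(10.0, fs)[None, :]
    y, fs_out = preprocess_raw(x, fs)
    n = y.shape[-1]
    sl = slice(n // 4, 3 * n // 4)
    rms_out = np.sqrt(np.mean(y[0, sl] ** 2))
    assert abs(rms_out - np.sqrt(0.5)) / np.sqrt(0.5) < 0.05


def test_downsampling_length_and_duration():
    fs = 2048.0
    x = np.zeros((3, int(12.0 * fs)))
    y, fs_out = preprocess_raw(x, fs)
    assert fs_out == 512.0
    assert y.shape == (3, 6144)


def test_filtering_commutes_with_epoch_extraction_in_the_interior(rng):
    """Low-pass filtering then epoching equals epoching then filtering, away
    from the epoch edges (within one filter length)."""
    from eegaffect.preprocess import design_fir, fir_filter

    fs = 512.0
    cont = rng.standard_normal(int(20 * fs))
    taps = design_fir(fs, 45.0, "lowpass", 5.0)
    onsets = [2.0, 9.0]
    a = extract_epochs(fir_filter(cont, taps), fs, onsets)
    b = np.stack([fir_filter(e, taps) for e in extract_epochs(cont, fs, onsets)])
    half = len(taps) // 2 + 1
    interior = slice(half, -half)
    assert np.allclose(a[:, interior], b[:, interior], atol=1e-8)


def test_cutoff_above_target_nyquist_rejected():
    with pytest.raises(ValueError):
        preprocess_raw(np.zeros((1, 4096)), 2048.0, lowpass_hz=300.0)


def test_extract_epochs_shapes_and_bounds():
    fs = 512.0
    cont = np.arange(2 * int(20 * fs), dtype=float).reshape(2, -1)
    ep = extract_epochs(cont, fs, onsets_s=[0.0, 6.0, 12.0], duration_s=6.0)
    assert ep.shape == (3, 2, 3072)
    with pytest.raises(ValueError):
        extract_epochs(cont, fs, onsets_s=[18.0], duration_s=6.0)


# ----------------------------------------------------------------------


def _epoched(rng, n_epochs=20, n_channels=16, n_samples=512):
    head = HeadModel.standard(n_channels)
    data = rng.standard_normal((n_epochs, n_channels, n_samples))
    return EpochedData(
        data=data,
        sampling_rate=512.0,
        channel_names=list(head.channel_names),
        channel_positions=head.channel_positions,
        stimulus_ids=np.arange(n_epochs),
    )


def test_planted_noisy_channel_flagged_and_interpolated(rng):
    ep = _epoched(rng)
    ep.data[:, 5, :] *= 100.0
    cleaned, report = clean_epochs(ep)
    assert report.interpolated_channels == [ep.channel_names[5]]
    assert report.n_channels_interpolated == 1
    # the flagged channel was replaced, all others untouched
    kept = cleaned.retained_epochs
    others = [i for i in range(ep.data.shape[1]) if i != 5]
    assert np.array_equal(cleaned.data[:, others, :], ep.data[kept][:, others, :])
    assert not np.allclose(cleaned.data[:, 5, :], ep.data[kept][:, 5, :])


def test_clean_data_passes_untouched(rng):
    ep = _epoched(rng)
    original = ep.data.copy()
    cleaned, report = clean_epochs(ep)
    assert report.n_channels_interpolated == 0
    assert report.n_epochs_removed == 0
    assert np.array_equal(cleaned.data, original)


def test_high_amplitude_epoch_removed(rng):
    ep = _epoched(rng)
    ep.data[7] += 500.0 * np.sin(np.linspace(0, 20, ep.data.shape[-1]))
    cleaned, report = clean_epochs(ep)
    assert 7 in report.removed_epochs
    assert 7 not in cleaned.retained_epochs
    # unflagged epochs are bit-identical
    for i, orig_idx in enumerate(cleaned.retained_epochs):
        assert np.array_equal(cleaned.data[i], ep.data[orig_idx])


def test_report_bookkeeping_fields(rng):
    ep = _epoched(rng)
    _, report = clean_epochs(ep)
    d = report.as_dict()
    assert set(d) == {
        "n_channels_interpolated",
        "interpolated_channels",
        "n_epochs_removed",
        "fraction_epochs_removed",
        "removed_epochs",
    }
    assert d["fraction_epochs_removed"] == report.n_epochs_removed / ep.n_epochs


def test_all_epochs_rejected_aborts(rng):
    ep = _epoched(rng, n_epochs=4)
    ep.data += 1e4
    ep.data[:, :, 0] -= 2e4  # huge peak-to-peak everywhere
    with pytest.raises(PipelineAbort):
        clean_epochs(ep)


def test_interpolation_reconstructs_smooth_field(rng):
    """A clean channel, interpolated anyway, correlates > 0.9 with itself."""
    head = HeadModel.standard(64)
    src = rng.standard_normal((40, 3))
    # smooth spatial field: random superposition of three dipole topographies
    topo = np.stack(
        [head.lead_field(np.array(p), m) for p, m in
         [((10.0, -40.0, 30.0), (1.0, 0, 0)),
          ((-30.0, 20.0, 40.0), (0, 1.0, 0)),
          ((0.0, 0.0, 50.0), (0, 0, 1.0))]],
        axis=1,
    )
    t = np.linspace(0, 1, 256)
    carrier = np.stack([np.sin(2 * np.pi * f * t) for f in (5, 9, 20)])
    data = np.einsum("cs,es,st->ect", topo, src, carrier)
    target = 10
    interp = interpolate_channels(data, head.channel_positions, [target])
    a = interp[:, target, :].ravel()
    b = data[:, target, :].ravel()
    r = np.corrcoef(a, b)[0, 1]
    assert r > 0.9


def test_average_reference_identity(rng):
    x = rng.standard_normal((4, 16, 100))
    y = average_reference(x)
    assert np.abs(y.mean(axis=1)).max() < 1e-10 * np.sqrt(np.mean(x**2))


@pytest.mark.parametrize("n_interp,expected_rank", [(0, 63), (2, 61)])
def test_rank_rule_and_principal_subspace(rng, n_interp, expected_rank):
    head = HeadModel.standard(64)
    data = rng.standard_normal((10, 64, 256))
    ep = EpochedData(
        data=data,
        sampling_rate=512.0,
        channel_names=list(head.channel_names),
        channel_positions=head.channel_positions,
        stimulus_ids=np.arange(10),
        interpolated=list(range(n_interp)),
    )
    if n_interp:
        ep.data = interpolate_channels(data, head.channel_positions, list(range(n_interp)))
    prep = prepare_for_ica(ep)
    assert prep.rank == expected_rank
    # oracle: singular values of the referenced (possibly interpolated) data
    flat = average_reference(ep.data).transpose(1, 0, 2).reshape(64, -1)
    sv = np.linalg.svd(flat, compute_uv=False)
    numeric_rank = int((sv > sv[0] * 1e-8).sum())
    assert numeric_rank == expected_rank
    assert prep.scores.shape == (expected_rank, 10 * 256)
    # orthonormal basis
    assert np.allclose(prep.basis.T @ prep.basis, np.eye(expected_rank), atol=1e-10)


def test_low_rank_aborts(rng):
    ep = _epoched(rng, n_channels=4)
    with pytest.raises(PipelineAbort):
        prepare_for_ica(ep)
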