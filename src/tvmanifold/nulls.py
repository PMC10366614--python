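"""Surrogate-data null models: connectivity randomization and phase randomization.

Connectivity randomization permutes row order independently within each tvFC
column, destroying the row-to-connection correspondence while preserving each
column's value multiset. Phase randomization replaces each ROI's Fourier phase
spectrum with i.i.d. uniform draws while keeping the amplitude spectrum, which
preserves the autocorrelation function (Wiener-Khinchin) but destroys timing.
"""

from __future__ import annotations

import numpy as np

from .containers import RoiTimeseries, TvfcMatrix


def randomize_connectivity(tvfc: TvfcMatrix, seed: int) -> TvfcMatrix:
    """Independently permute the rows of every tvFC column."""
    rng = np.random.default_rng(seed)
    vals = tvfc.values
    shuffled = np.empty_like(vals)
    for c in range(vals.shape[1]):
        shuffled[:, c] = vals[rng.permutation(vals.shape[0]), c]
    return TvfcMatrix(
        values=shuffled,
        connection_index=tvfc.connection_index,
        window_starts=tvfc.window_starts,
        spec=tvfc.spec,
        window_labels=list(tvfc.window_labels),
        normalized=tvfc.normalized,
        subject_id=tvfc.subject_id,
        meta={**tvfc.meta, "null_model": "connectivity", "null_seed": seed},
    )


def phase_randomize(ts: RoiTimeseries, seed: int) -> RoiTimeseries:
    """Per-ROI Fourier phase randomization preserving the amplitude spectrum.

    Positive-frequency phases are replaced by i.i.d. Uniform(0, 2*pi) draws;
    Hermitian symmetry is enforced (DC and, for even length, Nyquist components
    kept real) so the inverse transform is real-valued.
    """
    rng = np.random.default_rng(seed)
    n = ts.n_acq
    spec = np.fft.rfft(ts.data, axis=1)
    n_pos = spec.shape[1]
    # indices of strictly positive, non-Nyquist frequencies
    last = n_pos - 1 if n % 2 == 0 else n_pos
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(ts.n_rois, last - 1))
    new_spec = spec.copy()
    new_spec[:, 1:last] = np.abs(spec[:, 1:last]) * np.exp(1j * phases)
    # DC stays as-is (real); even-length Nyquist magnitude kept, made real
    if n % 2 == 0:
        new_spec[:, -1] = np.abs(spec[:, -1]) * np.sign(spec[:, -1].real + (spec[:, -1].real == 0))
    data = np.fft.irfft(new_spec, n=n, axis=1)
    return RoiTimeseries(
        data=data,
        tr=ts.tr,
        roi_names=list(ts.roi_names),
        subject_id=ts.subject_id,
    )
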