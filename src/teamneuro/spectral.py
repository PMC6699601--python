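"""Per-second band power from raw multichannel recordings.

Each whole second of the recording is treated as one non-overlapping epoch:
a tapered periodogram is computed over the second and its power summed into
1-Hz bins centered at 1..40 Hz. One-second epochs give exactly 1-Hz
spectral resolution, so each bin collects the periodogram ordinates whose
frequency lies within +/- 0.5 Hz of the bin center. The trailing partial
second is dropped; a second containing any NaN sample is marked missing.

The default taper is Hann. Note the resolution trade-off at 1-s epochs:
the Hann main lobe spans ~4 Hz, so even an on-bin sinusoid spreads ~1/6 of
its power into each neighboring bin; the boxcar taper concentrates an
on-bin sinusoid entirely in its bin but leaks badly off-bin. For
rank-based tertile discretization downstream the choice is immaterial
(any common rescaling of a stream leaves its levels unchanged).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import signal as sps

from .containers import DEFAULT_FREQS, PowerTensor, RawRecording
from .containers import align_members  # re-exported: alignment lives with containers
from .errors import ConfigError

__all__ = ["band_power_per_second", "align_members"]


def band_power_per_second(
    rec: RawRecording,
    bins: Sequence[int] = DEFAULT_FREQS,
    taper: str = "hann",
) -> PowerTensor:
    """Per-second power in 1-Hz bins for every channel of one recording.

    Returns a single-member :class:`PowerTensor` whose seconds axis starts
    at the recording's task-clock offset. The sampling rate must resolve
    the highest requested bin (Nyquist) and must be an integer number of
    samples per second so epochs align with the task clock.
    """
    bins = tuple(int(b) for b in bins)
    max_bin = max(bins)
    if rec.fs < 2 * max_bin:
        raise ConfigError(
            f"sampling rate {rec.fs} Hz aliases the {max_bin}-Hz bin "
            f"(need >= {2 * max_bin} Hz)"
        )
    n_per = int(round(rec.fs))
    if abs(rec.fs - n_per) > 1e-9:
        raise ConfigError(
            f"sampling rate must be an integer number of samples per second, got {rec.fs}"
        )
    n_sec = rec.n_samples // n_per
    if n_sec < 1:
        raise ValueError("recording shorter than one second")

    segs = rec.samples[:, : n_sec * n_per].reshape(len(rec.channels), n_sec, n_per)
    bad = np.isnan(segs).any(axis=2)  # (channel, second)
    safe = np.where(np.isnan(segs), 0.0, segs)
    freqs, psd = sps.periodogram(
        safe, fs=rec.fs, window=taper, axis=2, scaling="density", detrend=False
    )
    df = freqs[1] - freqs[0]

    values = np.empty((1, len(rec.channels), len(bins), n_sec))
    for k, hz in enumerate(bins):
        sel = (freqs > hz - 0.5) & (freqs <= hz + 0.5)
        if not sel.any():
            raise ConfigError(f"no periodogram ordinate falls in the {hz}-Hz bin")
        values[0, :, k, :] = psd[:, :, sel].sum(axis=2) * df
    values[0][bad[:, None, :].repeat(len(bins), axis=1)] = np.nan
    return PowerTensor(
        values,
        members=(rec.member,),
        sensors=rec.channels,
        freqs=bins,
        start_second=int(round(rec.start_s)),
    )
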