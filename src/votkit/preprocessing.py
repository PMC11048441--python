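"""Signal conditioning for VOT recordings.

The cardiac pulse rides on every optical channel at ~1-2 Hz, far above the
occlusion/hyperemia dynamics of interest (<0.2 Hz), so every channel is
low-pass filtered with a zero-phase FIR whose passband ends at 1 Hz and
whose stopband (>=60 dB) starts at 1.3 Hz.  The blood-flow index, whose
shot-to-shot noise is large, is additionally bin-averaged to 1 Hz.  The
tissue saturation index is the percentage ratio 100*O2Hb/(O2Hb+HHb),
computed sample-wise from the (by default, filtered) chromophores.

The filter is a Kaiser-window FIR, designed per sampling rate, normalized
to exact unit DC gain, and applied in a single pass by centred convolution
of the symmetric taps — exactly zero phase.  Edges are handled by
reflect-padding one filter length on each side.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import signal

from .trace_io import ChannelStream, VotRecording

__all__ = [
    "FilterSpec",
    "PreprocessingError",
    "design_lowpass",
    "apply_lowpass",
    "bin_average",
    "compute_tsi",
    "preprocess_recording",
    "DEFAULT_FILTER",
]


class PreprocessingError(ValueError):
    pass


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass contract: unity gain below ``f_pass``, at least ``stop_atten``
    dB of attenuation above ``f_stop``, zero phase."""

    f_pass: float = 1.0
    f_stop: float = 1.3
    stop_atten: float = 60.0
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if not (0 < self.f_pass < self.f_stop < fs / 2):
            raise PreprocessingError(
                f"require 0 < f_pass < f_stop < fs/2; got f_pass={self.f_pass}, "
                f"f_stop={self.f_stop}, fs={fs}"
            )


DEFAULT_FILTER = FilterSpec()

#: dB of design margin over the contracted stopband attenuation
_DESIGN_MARGIN_DB = 6.0


@lru_cache(maxsize=32)
def design_lowpass(fs: float, spec: FilterSpec = DEFAULT_FILTER) -> np.ndarray:
    """Kaiser-window FIR taps for ``spec`` at sampling rate ``fs``.

    Taps are odd-length, symmetric (linear phase) and normalized to unit sum
    so the DC gain is exactly 1.
    """
    spec.validate(fs)
    width = (spec.f_stop - spec.f_pass) / (fs / 2)
    numtaps, beta = signal.kaiserord(spec.stop_atten + _DESIGN_MARGIN_DB, width)
    numtaps |= 1  # odd length -> integer group delay, exact zero-phase use
    taps = signal.firwin(
        numtaps,
        (spec.f_pass + spec.f_stop) / 2,
        window=("kaiser", beta),
        fs=fs,
    )
    return taps / taps.sum()


def _filter_finite(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Zero-phase filtering of a finite signal with reflect padding."""
    pad = taps.size
    if x.size <= pad:
        raise PreprocessingError(
            f"too short to filter: {x.size} samples, need > {pad}"
        )
    xp = np.pad(x, pad, mode="symmetric")
    y = signal.fftconvolve(xp, taps, mode="same")
    return y[pad:-pad]


def apply_lowpass(stream: ChannelStream, spec: FilterSpec = DEFAULT_FILTER) -> ChannelStream:
    """Zero-phase low-pass a stream; missing samples are interpolated before
    filtering and re-masked afterwards."""
    taps = design_lowpass(stream.fs, spec)
    x = stream.values
    mask = ~np.isfinite(x)
    if mask.all():
        raise PreprocessingError(f"stream {stream.name!r} is entirely missing")
    if mask.any():
        idx = np.arange(x.size)
        x = np.interp(idx, idx[~mask], x[~mask])
    y = _filter_finite(x, taps)
    if mask.any():
        y = y.copy()
        y[mask] = np.nan
    return replace(stream, values=y)


def bin_average(stream: ChannelStream, out_fs: float) -> ChannelStream:
    """Average into non-overlapping bins of width 1/out_fs aligned to t0.

    Each output sample is the mean of the non-missing samples in its bin; a
    fully missing bin yields a missing sample.  Only complete bins are kept;
    the output timestamps are the bin centres.
    """
    if not 0 < out_fs < stream.fs:
        raise PreprocessingError(
            f"out_fs must be in (0, fs); got out_fs={out_fs}, fs={stream.fs}"
        )
    n_bins = int(np.floor(stream.n / stream.fs * out_fs + 1e-9))
    if n_bins == 0:
        raise PreprocessingError("stream shorter than one output bin")
    k = np.arange(stream.n)
    bin_idx = np.floor(k / stream.fs * out_fs + 1e-9).astype(int)
    keep = bin_idx < n_bins
    bin_idx = bin_idx[keep]
    vals = stream.values[keep]
    finite = np.isfinite(vals)
    sums = np.bincount(bin_idx[finite], weights=vals[finite], minlength=n_bins)
    counts = np.bincount(bin_idx[finite], minlength=n_bins)
    out = np.full(n_bins, np.nan)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    return ChannelStream(
        name=stream.name,
        unit=stream.unit,
        fs=out_fs,
        t0=stream.t0 + 0.5 / out_fs,
        values=out,
    )


def compute_tsi(o2hb: ChannelStream, hhb: ChannelStream) -> ChannelStream:
    """Tissue saturation index, sample-wise 100*O2Hb/(O2Hb+HHb) in percent.

    Samples where the total hemoglobin O2Hb+HHb is non-positive (no physical
    interpretation) become missing.
    """
    if o2hb.fs != hhb.fs or o2hb.t0 != hhb.t0 or o2hb.n != hhb.n:
        raise PreprocessingError(
            "O2HB and HHB must share sampling rate, start time and length"
        )
    total = o2hb.values + hhb.values
    with np.errstate(divide="ignore", invalid="ignore"):
        tsi = 100.0 * o2hb.values / total
    tsi = np.where(total > 0, tsi, np.nan)
    return ChannelStream(name="TSI", unit="%", fs=o2hb.fs, t0=o2hb.t0, values=tsi)


def preprocess_recording(
    rec: VotRecording,
    spec: FilterSpec = DEFAULT_FILTER,
    *,
    dcs_out_fs: float = 1.0,
    tsi_stage: str = "post_filter",
) -> VotRecording:
    """Produce the analysis-ready recording.

    O2HB/HHB are filtered at their native rate; TSI is computed from the
    filtered chromophores (``tsi_stage='post_filter'``, the default) or
    computed raw and then filtered (``'pre_filter'``); BFI is filtered and
    then bin-averaged to ``dcs_out_fs``.  A recording lacking either the
    NIRS pair or BFI simply omits the corresponding outputs.
    """
    if tsi_stage not in ("post_filter", "pre_filter"):
        raise PreprocessingError(f"unknown tsi_stage {tsi_stage!r}")
    streams: dict[str, ChannelStream] = {}
    if rec.has("O2HB", "HHB"):
        o2hb = apply_lowpass(rec.get("O2HB"), spec)
        hhb = apply_lowpass(rec.get("HHB"), spec)
        streams["O2HB"] = o2hb
        streams["HHB"] = hhb
        if tsi_stage == "post_filter":
            streams["TSI"] = compute_tsi(o2hb, hhb)
        else:
            streams["TSI"] = apply_lowpass(
                compute_tsi(rec.get("O2HB"), rec.get("HHB")), spec
            )
    if rec.has("BFI"):
        bfi = apply_lowpass(rec.get("BFI"), spec)
        streams["BFI"] = bin_average(bfi, dcs_out_fs)
    if not streams:
        raise PreprocessingError(
            "recording has neither the O2HB/HHB pair nor a BFI stream"
        )
    return VotRecording(meta=rec.meta, streams=streams, events=rec.events)
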