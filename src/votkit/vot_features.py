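"""Phase segmentation and per-subject VOT parameter extraction.

The test has three phases: baseline (BA), occlusion (OC, cuff inflated
above limb occlusion pressure) and reactive hyperemia (HY, after release).
From the preprocessed, baseline-normalized channels this module extracts
the full per-subject parameter set:

* BA: 1-min means of O2Hb, HHb, TSI and BFI;
* OC: 20-s initial slopes of the chromophore/TSI deltas, their occlusion
  extrema and times-to-extremum, and the relative-blood-flow floor (mean
  rBF of the last 10 s before release);
* HY: hyperemic peak deltas and times-to-peak, 10-s post-release NIRS
  slopes, the release-to-peak rBF slope, and the half-time to recovery
  (HTR) of each channel.

All times-to-extremum are reported relative to the cuff release, which
makes every OC time non-positive and every HY time non-negative.  HTR is
the time from release to the first crossing (linear interpolation between
samples) of half the hyperemic height, and is therefore never larger than
the corresponding time-to-peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trace_io import ChannelStream, CuffEvents, VotRecording

__all__ = [
    "PhaseWindows",
    "BaselineValues",
    "VotFeatureSet",
    "FeatureError",
    "FEATURE_NAMES",
    "FEATURE_UNITS",
    "segment_phases",
    "compute_baseline",
    "normalize",
    "fit_window_slope",
    "find_extremum",
    "oc_rbf_min",
    "compute_htr",
    "hy_rbf_slope",
    "extract_features",
]


class FeatureError(ValueError):
    pass


#: Table-style feature catalogue, in report order.
FEATURE_UNITS: dict[str, str] = {
    "ba_o2hb": "uM",
    "ba_hhb": "uM",
    "ba_tsi": "%",
    "ba_bfi": "cm^2/s",
    "oc_d_o2hb_slope": "uM/s",
    "oc_d_hhb_slope": "uM/s",
    "oc_d_tsi_slope": "%/s",
    "oc_d_o2hb_min": "uM",
    "oc_d_hhb_max": "uM",
    "oc_d_tsi_min": "%",
    "oc_rbf_min": "%",
    "oc_d_o2hb_tmin": "s",
    "oc_d_hhb_tmax": "s",
    "oc_d_tsi_tmin": "s",
    "hy_d_o2hb_max": "uM",
    "hy_d_hhb_min": "uM",
    "hy_d_tsi_max": "%",
    "hy_rbf_max": "%",
    "hy_d_o2hb_tmax": "s",
    "hy_d_hhb_tmin": "s",
    "hy_d_tsi_tmax": "s",
    "hy_rbf_tmax": "s",
    "hy_d_o2hb_slope": "uM/s",
    "hy_d_hhb_slope": "uM/s",
    "hy_d_tsi_slope": "%/s",
    "hy_rbf_slope": "%/s",
    "hy_d_o2hb_htr": "s",
    "hy_d_hhb_htr": "s",
    "hy_d_tsi_htr": "s",
    "hy_rbf_htr": "s",
}

FEATURE_NAMES: tuple[str, ...] = tuple(FEATURE_UNITS)


@dataclass(frozen=True)
class PhaseWindows:
    """Absolute closed time intervals of the three VOT phases."""

    ba: tuple[float, float]
    oc: tuple[float, float]
    hy: tuple[float, float]


@dataclass(frozen=True)
class BaselineValues:
    ba_o2hb: float = math.nan
    ba_hhb: float = math.nan
    ba_tsi: float = math.nan
    ba_bfi: float = math.nan


@dataclass
class VotFeatureSet:
    """The full per-subject parameter set plus extraction findings."""

    subject_id: str
    group: str
    values: dict[str, float]
    findings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [n for n in FEATURE_NAMES if n not in self.values]
        if missing:
            raise FeatureError(f"feature set incomplete, missing {missing}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_series(self) -> pd.Series:
        s = pd.Series({n: self.values[n] for n in FEATURE_NAMES})
        s["subject_id"] = self.subject_id
        s["group"] = self.group
        return s[["subject_id", "group", *FEATURE_NAMES]]


def features_to_frame(feature_sets: list[VotFeatureSet]) -> pd.DataFrame:
    """One wide row per subject: id, group, then the feature columns."""
    return pd.DataFrame([fs.to_series() for fs in feature_sets]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# segmentation and normalization


def segment_phases(
    events: CuffEvents,
    ba_window: float = 60.0,
    hy_window: float = 180.0,
    *,
    ba_guard: float = 15.0,
) -> PhaseWindows:
    """Place the BA/OC/HY analysis windows from the cuff annotations.

    The 60-s baseline window ends ``ba_guard`` seconds before inflation when
    a pre-occlusion light contraction is annotated (so its transient cannot
    contaminate the baseline), and ends at inflation otherwise.
    """
    if ba_window <= 0 or hy_window <= 0:
        raise FeatureError("windows must be positive")
    ba_end = events.t_inflate - (ba_guard if events.t_contract is not None else 0.0)
    ba_start = ba_end - ba_window
    if ba_start < -1e-9:
        raise FeatureError(
            f"BA phase too short: baseline window would start at {ba_start:g} s"
        )
    hy_end = events.t_release + hy_window
    if hy_end > events.end_time + 1e-9:
        raise FeatureError(
            f"HY phase too short: window ends at {hy_end:g} s but recording "
            f"ends at {events.end_time:g} s"
        )
    return PhaseWindows(
        ba=(ba_start, ba_end),
        oc=(events.t_inflate, events.t_release),
        hy=(events.t_release, hy_end),
    )


def _window_mean(
    stream: ChannelStream, window: tuple[float, float], max_missing_frac: float
) -> float:
    _, v = stream.window(*window)
    if v.size == 0:
        raise FeatureError(f"{stream.name}: no samples in window {window}")
    finite = np.isfinite(v)
    if 1 - finite.mean() > max_missing_frac:
        raise FeatureError(
            f"{stream.name}: more than {max_missing_frac:.0%} missing in "
            f"window {window}"
        )
    return float(v[finite].mean())


def compute_baseline(
    rec: VotRecording, windows: PhaseWindows, *, max_missing_frac: float = 0.2
) -> BaselineValues:
    """Per-channel arithmetic means over the baseline window."""
    vals = {}
    for key, name in (
        ("ba_o2hb", "O2HB"),
        ("ba_hhb", "HHB"),
        ("ba_tsi", "TSI"),
        ("ba_bfi", "BFI"),
    ):
        vals[key] = (
            _window_mean(rec.get(name), windows.ba, max_missing_frac)
            if rec.has(name)
            else math.nan
        )
    return BaselineValues(**vals)


def normalize(rec: VotRecording, base: BaselineValues) -> VotRecording:
    """Add baseline-delta NIRS streams and the relative blood flow stream.

    rBF expresses BFI as a percentage of its baseline mean
    (rBF = 100 * BFI / BA-BFI).
    """
    streams = dict(rec.streams)
    for name, ba in (
        ("O2HB", base.ba_o2hb),
        ("HHB", base.ba_hhb),
        ("TSI", base.ba_tsi),
    ):
        if rec.has(name) and np.isfinite(ba):
            s = rec.get(name)
            streams["D_" + name] = ChannelStream(
                name="D_" + name, unit=s.unit, fs=s.fs, t0=s.t0,
                values=s.values - ba,
            )
    if rec.has("BFI"):
        if not base.ba_bfi > 0:
            raise FeatureError(
                f"non-positive baseline flow: BA-BFI = {base.ba_bfi!r}"
            )
        s = rec.get("BFI")
        streams["RBF"] = ChannelStream(
            name="RBF", unit="%baseline", fs=s.fs, t0=s.t0,
            values=100.0 * s.values / base.ba_bfi,
        )
    return VotRecording(meta=rec.meta, streams=streams, events=rec.events)


# ---------------------------------------------------------------------------
# primitive feature operations


def fit_window_slope(
    stream: ChannelStream, window: tuple[float, float], *, min_samples: int = 5
) -> float:
    """Ordinary-least-squares slope of value vs time inside the closed window."""
    t, v = stream.window(*window)
    finite = np.isfinite(v)
    t, v = t[finite], v[finite]
    if t.size < min_samples:
        raise FeatureError(
            f"{stream.name}: window underpopulated "
            f"({t.size} samples in {window}, need {min_samples})"
        )
    tc = t - t.mean()
    return float(tc @ (v - v.mean()) / (tc @ tc))


def find_extremum(
    stream: ChannelStream,
    window: tuple[float, float],
    mode: str,
    t_ref: float,
) -> tuple[float, float]:
    """Extremal sample in the closed window; time reported relative to t_ref.

    Ties are broken to the earliest occurrence.  With ``t_ref`` set to the
    cuff release, occlusion extrema get non-positive times and hyperemic
    extrema non-negative ones.
    """
    if mode not in ("min", "max"):
        raise FeatureError(f"mode must be 'min' or 'max', got {mode!r}")
    t, v = stream.window(*window)
    finite = np.isfinite(v)
    if not finite.any():
        raise FeatureError(f"{stream.name}: all samples missing in {window}")
    t, v = t[finite], v[finite]
    i = int(np.argmin(v) if mode == "min" else np.argmax(v))
    return float(v[i]), float(t[i] - t_ref)


def oc_rbf_min(
    rbf: ChannelStream, t_release: float, *, tail_s: float = 10.0
) -> float:
    """Occlusion rBF floor: mean over the last ``tail_s`` seconds before release."""
    t, v = rbf.window(t_release - tail_s, t_release)
    finite = np.isfinite(v)
    expected = tail_s * rbf.fs
    if finite.sum() < 0.8 * expected:
        raise FeatureError(
            f"RBF: occlusion tail [{t_release - tail_s:g}, {t_release:g}] s "
            f"insufficiently covered ({int(finite.sum())} samples)"
        )
    return float(v[finite].mean())


def compute_htr(
    stream: ChannelStream,
    t_release: float,
    peak_value: float,
    peak_time_rel: float,
) -> float:
    """Half-time to recovery: release to half the hyperemic height.

    The height is the peak value minus the value at release (first
    non-missing sample at/after release); the crossing time of the half
    level, moving toward the peak, is linearly interpolated between the
    bracketing samples.  For a channel whose hyperemic response is a fall
    (HHb) the crossing is downward.
    """
    t, v = stream.window(t_release, t_release + peak_time_rel)
    finite = np.isfinite(v)
    t, v = t[finite], v[finite]
    if t.size == 0:
        raise FeatureError(f"{stream.name}: no samples between release and peak")
    v0 = float(v[0])
    height = peak_value - v0
    # a "peak" indistinguishable from the release value (relative to the
    # numbers involved) means there was no hyperemic response to halve
    if abs(height) <= 1e-9 * max(1.0, abs(peak_value), abs(v0)):
        raise FeatureError(f"{stream.name}: degenerate hyperemia (zero height)")
    half = v0 + height / 2.0
    sign = 1.0 if height > 0 else -1.0
    crossed = sign * (v - half) >= 0
    if not crossed.any():
        raise FeatureError(
            f"{stream.name}: half level not reached before the hyperemic peak"
        )
    i = int(np.argmax(crossed))
    if i == 0:
        return float(t[0] - t_release)
    # linear interpolation between the bracketing samples
    f = (half - v[i - 1]) / (v[i] - v[i - 1])
    t_cross = t[i - 1] + f * (t[i] - t[i - 1])
    return float(t_cross - t_release)


def hy_rbf_slope(
    rbf: ChannelStream, t_release: float, peak_time_rel: float
) -> float:
    """OLS slope of rBF from cuff release to its hyperemic peak."""
    return fit_window_slope(
        rbf, (t_release, t_release + peak_time_rel), min_samples=3
    )


# ---------------------------------------------------------------------------
# full extraction


def extract_features(
    rec: VotRecording,
    *,
    ba_window_s: float = 60.0,
    hy_window_s: float = 180.0,
    ba_guard_s: float = 15.0,
    oc_slope_s: float = 20.0,
    hy_slope_s: float = 10.0,
    rbf_tail_s: float = 10.0,
) -> VotFeatureSet:
    """Extract the full parameter set from a preprocessed recording.

    The recording must carry the analysis-ready streams (filtered O2HB/HHB
    and TSI at the NIRS rate and/or the 1 Hz BFI); baseline-delta and rBF
    streams are added here if absent.  Features whose source stream is
    absent, and hyperemia features of a channel with no hyperemic response,
    are returned missing (NaN) with an explanatory finding.
    """
    windows = segment_phases(
        rec.events, ba_window_s, hy_window_s, ba_guard=ba_guard_s
    )
    base = compute_baseline(rec, windows)
    if "D_O2HB" not in rec.streams and "RBF" not in rec.streams:
        rec = normalize(rec, base)

    t_rel = rec.events.t_release
    vals: dict[str, float] = {n: math.nan for n in FEATURE_NAMES}
    findings: list[str] = []
    vals["ba_o2hb"] = base.ba_o2hb
    vals["ba_hhb"] = base.ba_hhb
    vals["ba_tsi"] = base.ba_tsi
    vals["ba_bfi"] = base.ba_bfi

    oc_slope_win = (windows.oc[0], windows.oc[0] + oc_slope_s)
    hy_slope_win = (t_rel, t_rel + hy_slope_s)

    nirs_channels = (
        ("o2hb", "D_O2HB", "min", "max"),  # OC extremum is a minimum, HY a maximum
        ("hhb", "D_HHB", "max", "min"),
        ("tsi", "D_TSI", "min", "max"),
    )
    for tag, name, oc_mode, hy_mode in nirs_channels:
        if not rec.has(name):
            findings.append(f"{name} absent; NIRS {tag} features missing")
            continue
        s = rec.get(name)
        vals[f"oc_d_{tag}_slope"] = fit_window_slope(s, oc_slope_win)
        ext, t_ext = find_extremum(s, windows.oc, oc_mode, t_rel)
        vals[f"oc_d_{tag}_{oc_mode}"] = ext
        vals[f"oc_d_{tag}_t{oc_mode}"] = t_ext
        peak, t_peak = find_extremum(s, windows.hy, hy_mode, t_rel)
        vals[f"hy_d_{tag}_{hy_mode}"] = peak
        vals[f"hy_d_{tag}_t{hy_mode}"] = t_peak
        vals[f"hy_d_{tag}_slope"] = fit_window_slope(s, hy_slope_win)
        try:
            vals[f"hy_d_{tag}_htr"] = compute_htr(s, t_rel, peak, t_peak)
        except FeatureError as exc:
            findings.append(f"hy_d_{tag}_htr missing: {exc}")

    if rec.has("RBF"):
        rbf = rec.get("RBF")
        vals["oc_rbf_min"] = oc_rbf_min(rbf, t_rel, tail_s=rbf_tail_s)
        peak, t_peak = find_extremum(rbf, windows.hy, "max", t_rel)
        vals["hy_rbf_max"] = peak
        vals["hy_rbf_tmax"] = t_peak
        try:
            vals["hy_rbf_slope"] = hy_rbf_slope(rbf, t_rel, t_peak)
        except FeatureError as exc:
            findings.append(f"hy_rbf_slope missing: {exc}")
        try:
            vals["hy_rbf_htr"] = compute_htr(rbf, t_rel, peak, t_peak)
        except FeatureError as exc:
            findings.append(f"hy_rbf_htr missing: {exc}")
    else:
        findings.append("BFI/RBF absent; rBF features missing")

    return VotFeatureSet(
        subject_id=rec.meta.subject_id,
        group=rec.meta.group,
        values=vals,
        findings=findings,
    )
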