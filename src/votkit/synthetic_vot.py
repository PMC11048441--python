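"""Synthetic VOT recordings with known ground truth.

Single traces and two-group cohorts are generated from a piecewise channel
model whose parameters *are* the extracted features, so the whole pipeline
can be exercised and checked for parameter recovery without any external
data:

* baseline: constant level with a cardiac-frequency sinusoid and white
  noise, plus an optional 5-s light-contraction transient just before
  inflation;
* occlusion: chromophore deltas follow an exact linear segment at the
  prescribed 20-s slope, then drift exponentially toward a shoulder one
  nadir-depth short of the prescribed extremum, with a smooth raised-cosine
  nadir (zenith for HHb) centred on the prescribed time-to-extremum — this
  keeps the drawn slope, extremum value and extremum time all exactly
  realized while leaving the extremum identifiable under noise; the
  blood-flow index decays exponentially to the prescribed floor;
* hyperemia: a saturating-exponential rise to the prescribed peak at the
  prescribed time-to-peak, with the rise constant solved so the half-height
  crossing lands exactly at the prescribed half-time to recovery, followed
  by exponential relaxation toward baseline (fixed 60-s constant).

TSI is not drawn: it emerges from the chromophores, and its ground-truth
features (like the hyperemic 10-s slopes, which are fixed by the rise
geometry) are derived numerically from the clean noise-free trace.

Default cohort parameters are the observed climber / non-climber group
means and SDs; draws are independent truncated normals (per-subject
resampling until mutually consistent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .preprocessing import bin_average, compute_tsi
from .trace_io import ChannelStream, CuffEvents, SubjectMeta, VotRecording
from .vot_features import (
    FEATURE_NAMES,
    compute_htr,
    find_extremum,
    fit_window_slope,
)

__all__ = [
    "ProtocolTiming",
    "VotGroundTruth",
    "GroupParams",
    "SyntheticError",
    "solve_rise_constant",
    "simulate_trace",
    "simulate_cohort",
    "default_truth",
    "CLIMBER_PARAMS",
    "NONCLIMBER_PARAMS",
]


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class ProtocolTiming:
    """Cuff protocol: 3-min baseline, ~5-min occlusion at supra-systolic
    pressure, 3-min recovery; light 5-s contraction just before inflation."""

    ba_s: float = 180.0
    oc_s: float = 300.0
    hy_s: float = 180.0
    contraction: bool = True
    contraction_s: float = 5.0
    fs_nirs: float = 50.0
    fs_dcs: float = 38.5

    @property
    def t_inflate(self) -> float:
        return self.ba_s

    @property
    def t_release(self) -> float:
        return self.ba_s + self.oc_s

    @property
    def end_time(self) -> float:
        return self.ba_s + self.oc_s + self.hy_s

    def events(self) -> CuffEvents:
        return CuffEvents(
            t_inflate=self.t_inflate,
            t_release=self.t_release,
            end_time=self.end_time,
            t_contract=(self.t_inflate - self.contraction_s)
            if self.contraction
            else None,
        )


#: half-width over which the occlusion extremum is shaped (s)
NADIR_HALFWIDTH_S = 4.0
#: depth of the localized occlusion nadir/zenith, as a fraction of the
#: channel's occlusion-to-hyperemia dynamic range
NADIR_DEPTH_FRAC = 0.05
#: post-peak hyperemic relaxation constant (s); not a measured quantity
HY_RELAX_TAU_S = 60.0
#: occlusion BFI decay constant (s)
OC_BFI_TAU_S = 4.0
#: arterial transit latency between cuff release and the BFI upstroke (s)
RBF_DELAY_S = 1.0


@dataclass
class VotGroundTruth:
    """Controlled generator parameters (== the true feature values) for one
    subject, plus nuisance settings (cardiac oscillation, noise, seed)."""

    # baseline levels
    ba_o2hb: float = 43.6
    ba_hhb: float = 24.9
    ba_bfi: float = 1.70e-9
    # occlusion chromophore kinetics (deltas relative to baseline)
    oc_o2hb_slope: float = -0.1
    oc_hhb_slope: float = 0.1
    oc_o2hb_min: float = -6.5
    oc_hhb_max: float = 14.9
    oc_o2hb_tmin: float = -22.2
    oc_hhb_tmax: float = -3.5
    oc_rbf_min: float = 12.3
    # hyperemia
    hy_o2hb_max: float = 16.6
    hy_hhb_min: float = -5.5
    hy_rbf_max: float = 873.7
    hy_o2hb_tmax: float = 14.4
    hy_hhb_tmin: float = 32.0
    hy_rbf_tmax: float = 13.0
    hy_o2hb_htr: float = 4.8
    hy_hhb_htr: float = 7.1
    hy_rbf_htr: float = 5.4
    # nuisance parameters
    cardiac_freq: float = 1.2
    cardiac_amp_nirs: float = 0.0
    cardiac_amp_bfi_frac: float = 0.0
    noise_sd: dict[str, float] = field(default_factory=dict)
    contraction_dip_o2hb: float = 2.0
    seed: int = 0

    def dynamic_range(self) -> dict[str, float]:
        """Peak-to-trough span of each raw channel over the whole test."""
        return {
            "O2HB": self.hy_o2hb_max - self.oc_o2hb_min,
            "HHB": self.oc_hhb_max - self.hy_hhb_min,
            "BFI": self.ba_bfi * (self.hy_rbf_max - self.oc_rbf_min) / 100.0,
        }

    def with_noise(self, frac: float, cardiac_amp_nirs: float = 1.0,
                   cardiac_amp_bfi_frac: float = 0.1) -> "VotGroundTruth":
        """Copy with white noise at ``frac`` of each channel's dynamic range
        and a cardiac oscillation."""
        rng_sd = {k: frac * v for k, v in self.dynamic_range().items()}
        return replace(
            self,
            noise_sd=rng_sd,
            cardiac_amp_nirs=cardiac_amp_nirs,
            cardiac_amp_bfi_frac=cardiac_amp_bfi_frac,
        )

    # -- consistency -------------------------------------------------------

    def validate(self, protocol: ProtocolTiming) -> None:
        errs = []
        w = NADIR_HALFWIDTH_S
        depth = {
            "o2hb": NADIR_DEPTH_FRAC * (self.hy_o2hb_max - self.oc_o2hb_min),
            "hhb": NADIR_DEPTH_FRAC * (self.oc_hhb_max - self.hy_hhb_min),
        }
        if not self.ba_bfi > 0:
            errs.append("ba_bfi must be positive")
        if not self.oc_o2hb_slope < 0:
            errs.append("oc_o2hb_slope must be negative")
        if not self.oc_hhb_slope > 0:
            errs.append("oc_hhb_slope must be positive")
        if not self.oc_o2hb_min < 20 * self.oc_o2hb_slope - depth["o2hb"]:
            errs.append("oc_o2hb_min must undershoot the 20-s ramp end")
        if not self.oc_hhb_max > 20 * self.oc_hhb_slope + depth["hhb"]:
            errs.append("oc_hhb_max must overshoot the 20-s ramp end")
        for name, t_ext in (("oc_o2hb_tmin", self.oc_o2hb_tmin),
                            ("oc_hhb_tmax", self.oc_hhb_tmax)):
            if not -(protocol.oc_s - 20 - w - 1) <= t_ext <= -0.1:
                errs.append(f"{name}={t_ext:g} outside the occlusion phase")
        if not 0 < self.oc_rbf_min < 100:
            errs.append("oc_rbf_min must lie in (0, 100)")
        if not self.hy_o2hb_max > self.oc_o2hb_min + depth["o2hb"] + 0.5:
            errs.append("hy_o2hb_max leaves no hyperemic height")
        if not self.hy_hhb_min < self.oc_hhb_max - depth["hhb"] - 0.5:
            errs.append("hy_hhb_min leaves no hyperemic height")
        if not self.hy_rbf_max > self.oc_rbf_min + 10:
            errs.append("hy_rbf_max leaves no hyperemic height")
        for tag in ("o2hb", "hhb", "rbf"):
            tp = getattr(self, f"hy_{tag}_tmax" if tag != "hhb" else "hy_hhb_tmin")
            htr = getattr(self, f"hy_{tag}_htr")
            delay = RBF_DELAY_S if tag == "rbf" else 0.0
            if not delay + 1.0 <= tp <= protocol.hy_s - 20:
                errs.append(f"hy_{tag} time-to-peak {tp:g} outside hyperemia")
            elif not delay < htr <= delay + (tp - delay) / 2:
                errs.append(
                    f"hy_{tag}_htr={htr:g} incompatible with time-to-peak "
                    f"{tp:g} (need delay < htr <= delay + (t_peak-delay)/2)"
                )
        if self.cardiac_amp_nirs and self.cardiac_freq < 1.1:
            errs.append("cardiac frequency must be >= 1.1 Hz (filter stopband)")
        if errs:
            raise SyntheticError("inconsistent ground truth: " + "; ".join(errs))


def solve_rise_constant(t_peak: float, htr: float) -> tuple[float, bool]:
    """Rise constant tau of the saturating-exponential hyperemic rise
    r(t) = (1 - exp(-t/tau)) / (1 - exp(-t_peak/tau)) such that the
    half-height crossing r(htr) = 1/2.

    A concave rise always crosses half height before t_peak/2; as
    htr -> t_peak/2 the solution degenerates to the linear rise
    (tau -> inf), returned with the ``linear`` flag set.
    """
    if not 0 < htr < t_peak:
        raise SyntheticError(f"need 0 < htr < t_peak, got htr={htr}, t_peak={t_peak}")
    if htr >= t_peak / 2 * (1 - 1e-9):
        return math.inf, True

    def gap(tau: float) -> float:
        return (1 - math.exp(-htr / tau)) / (1 - math.exp(-t_peak / tau)) - 0.5

    lo, hi = t_peak * 1e-3, t_peak * 1e3
    # gap(lo) ~ +0.5 (instant saturation), gap(hi) ~ htr/t_peak - 0.5 < 0
    tau = optimize.brentq(gap, lo, hi, xtol=1e-6)
    return float(tau), False


def _rise(w: np.ndarray, t_peak: float, tau: float, linear: bool) -> np.ndarray:
    """Normalized rise, 0 at release and 1 at the peak time."""
    if linear:
        return w / t_peak
    return (1 - np.exp(-w / tau)) / (1 - math.exp(-t_peak / tau))


def _chromophore_delta(
    t: np.ndarray,
    protocol: ProtocolTiming,
    *,
    slope: float,
    ext: float,
    t_ext: float,
    hy_peak: float,
    hy_tpeak: float,
    hy_htr: float,
    depth: float,
    sign: float,
) -> np.ndarray:
    """Clean delta path of one chromophore; ``sign`` is +1 when the
    occlusion extremum is a maximum (HHb) and -1 when it is a minimum."""
    ti, tr = protocol.t_inflate, protocol.t_release
    u_ext = protocol.oc_s + t_ext  # extremum position within the occlusion
    w = NADIR_HALFWIDTH_S
    v20 = 20.0 * slope
    shoulder = ext - sign * depth
    # exponential drift from the ramp end toward the shoulder, slope-matched
    tau_a = (shoulder - v20) / slope  # positive by the validity constraints

    d = np.zeros_like(t)
    u = t - ti

    oc = (t >= ti) & (t <= tr)
    ramp = oc & (u <= 20.0)
    d[ramp] = slope * u[ramp]
    drift_m = oc & (u > 20.0)
    drift = shoulder + (v20 - shoulder) * np.exp(-(u[drift_m] - 20.0) / tau_a)
    # raised-cosine nadir/zenith pinning the extremum value at its time
    drift_at_ext = shoulder + (v20 - shoulder) * math.exp(-(u_ext - 20.0) / tau_a)
    amp = ext - drift_at_ext  # signed: negative for O2Hb, positive for HHb
    phase = (u[drift_m] - u_ext) / (2 * w)
    bump = np.where(np.abs(phase) <= 0.5, 0.5 * (1 + np.cos(2 * np.pi * phase)), 0.0)
    d[drift_m] = drift + amp * bump

    # value carried into the hyperemia
    u_rel = protocol.oc_s
    phase_rel = (u_rel - u_ext) / (2 * w)
    bump_rel = 0.5 * (1 + math.cos(2 * math.pi * phase_rel)) if abs(phase_rel) <= 0.5 else 0.0
    v_rel = (
        shoulder
        + (v20 - shoulder) * math.exp(-(u_rel - 20.0) / tau_a)
        + amp * bump_rel
    )

    hy = t > tr
    wv = t[hy] - tr
    tau, linear = solve_rise_constant(hy_tpeak, hy_htr)
    rising = wv <= hy_tpeak
    seg = np.empty_like(wv)
    seg[rising] = v_rel + (hy_peak - v_rel) * _rise(wv[rising], hy_tpeak, tau, linear)
    seg[~rising] = hy_peak * np.exp(-(wv[~rising] - hy_tpeak) / HY_RELAX_TAU_S)
    d[hy] = seg
    return d


def _bfi_path(t: np.ndarray, protocol: ProtocolTiming, truth: VotGroundTruth) -> np.ndarray:
    ti, tr = protocol.t_inflate, protocol.t_release
    ba = truth.ba_bfi
    floor = ba * truth.oc_rbf_min / 100.0
    peak = ba * truth.hy_rbf_max / 100.0
    v = np.full_like(t, ba)
    oc = (t >= ti) & (t <= tr)
    v[oc] = floor + (ba - floor) * np.exp(-(t[oc] - ti) / OC_BFI_TAU_S)
    v_rel = floor + (ba - floor) * math.exp(-protocol.oc_s / OC_BFI_TAU_S)
    hy = t > tr
    # the upstroke starts one arterial transit latency after release; the
    # drawn time-to-peak and half-time are measured from release as always
    wv = t[hy] - tr - RBF_DELAY_S
    tp = truth.hy_rbf_tmax - RBF_DELAY_S
    tau, linear = solve_rise_constant(tp, truth.hy_rbf_htr - RBF_DELAY_S)
    seg = np.full_like(wv, v_rel)
    rising = (wv > 0) & (wv <= tp)
    seg[rising] = v_rel + (peak - v_rel) * _rise(wv[rising], tp, tau, linear)
    after = wv > tp
    seg[after] = ba + (peak - ba) * np.exp(-(wv[after] - tp) / HY_RELAX_TAU_S)
    v[hy] = seg
    return v


def _cardiac_envelope(t: np.ndarray, protocol: ProtocolTiming) -> np.ndarray:
    """Pulsatility envelope: full at baseline, vanishing during occlusion
    (no flow, no pulse), re-established early in hyperemia.  Transitions are
    raised-cosine ramps: sharp amplitude gating of the cardiac carrier would
    put modulation sidebands below the filter passband edge."""
    ti, tr = protocol.t_inflate, protocol.t_release
    ramp = 8.0
    env = np.ones_like(t)
    down = (t >= ti) & (t < ti + ramp)
    env[down] = 0.5 * (1 + np.cos(np.pi * (t[down] - ti) / ramp))
    env[(t >= ti + ramp) & (t <= tr)] = 0.0
    up = (t > tr) & (t < tr + ramp)
    env[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - tr) / ramp))
    return env


def _contraction_dip(t: np.ndarray, protocol: ProtocolTiming, amp: float) -> np.ndarray:
    if not protocol.contraction or amp == 0:
        return np.zeros_like(t)
    t0 = protocol.t_inflate - protocol.contraction_s
    inside = (t >= t0) & (t <= protocol.t_inflate)
    dip = np.zeros_like(t)
    dip[inside] = amp * np.sin(np.pi * (t[inside] - t0) / protocol.contraction_s)
    return dip


def _clean_streams(
    truth: VotGroundTruth, protocol: ProtocolTiming
) -> dict[str, ChannelStream]:
    """Noise-free, cardiac-free channel paths at native rates."""
    n_nirs = int(round(protocol.end_time * protocol.fs_nirs)) + 1
    t_nirs = np.arange(n_nirs) / protocol.fs_nirs
    n_dcs = int(round(protocol.end_time * protocol.fs_dcs)) + 1
    t_dcs = np.arange(n_dcs) / protocol.fs_dcs

    rng_span = truth.dynamic_range()
    d_o2hb = _chromophore_delta(
        t_nirs, protocol,
        slope=truth.oc_o2hb_slope, ext=truth.oc_o2hb_min, t_ext=truth.oc_o2hb_tmin,
        hy_peak=truth.hy_o2hb_max, hy_tpeak=truth.hy_o2hb_tmax, hy_htr=truth.hy_o2hb_htr,
        depth=NADIR_DEPTH_FRAC * rng_span["O2HB"], sign=-1.0,
    )
    d_hhb = _chromophore_delta(
        t_nirs, protocol,
        slope=truth.oc_hhb_slope, ext=truth.oc_hhb_max, t_ext=truth.oc_hhb_tmax,
        hy_peak=truth.hy_hhb_min, hy_tpeak=truth.hy_hhb_tmin, hy_htr=truth.hy_hhb_htr,
        depth=NADIR_DEPTH_FRAC * rng_span["HHB"], sign=+1.0,
    )
    dip = _contraction_dip(t_nirs, protocol, truth.contraction_dip_o2hb)
    o2hb = truth.ba_o2hb + d_o2hb - dip
    hhb = truth.ba_hhb + d_hhb + 0.5 * dip
    bfi = _bfi_path(t_dcs, protocol, truth)
    return {
        "O2HB": ChannelStream("O2HB", "uM", protocol.fs_nirs, 0.0, o2hb),
        "HHB": ChannelStream("HHB", "uM", protocol.fs_nirs, 0.0, hhb),
        "BFI": ChannelStream("BFI", "cm^2/s", protocol.fs_dcs, 0.0, bfi),
    }


def _derived_truth(
    truth: VotGroundTruth,
    protocol: ProtocolTiming,
    clean: dict[str, ChannelStream],
) -> dict[str, float]:
    """Ground truth of the emergent features (TSI set, hyperemic slopes),
    measured on the clean noise-free trace."""
    ti, tr, end = protocol.t_inflate, protocol.t_release, protocol.end_time
    out: dict[str, float] = {}

    tsi = compute_tsi(clean["O2HB"], clean["HHB"])
    ba_tsi = 100.0 * truth.ba_o2hb / (truth.ba_o2hb + truth.ba_hhb)
    out["ba_tsi"] = ba_tsi
    d_tsi = ChannelStream("D_TSI", "%", tsi.fs, tsi.t0, tsi.values - ba_tsi)
    out["oc_d_tsi_slope"] = fit_window_slope(d_tsi, (ti, ti + 20.0))
    ext, t_ext = find_extremum(d_tsi, (ti, tr), "min", tr)
    out["oc_d_tsi_min"], out["oc_d_tsi_tmin"] = ext, t_ext
    peak, t_peak = find_extremum(d_tsi, (tr, end), "max", tr)
    out["hy_d_tsi_max"], out["hy_d_tsi_tmax"] = peak, t_peak
    out["hy_d_tsi_slope"] = fit_window_slope(d_tsi, (tr, tr + 10.0))
    out["hy_d_tsi_htr"] = compute_htr(d_tsi, tr, peak, t_peak)

    for tag, name in (("o2hb", "O2HB"), ("hhb", "HHB")):
        s = clean[name]
        ba = getattr(truth, f"ba_{tag}")
        d = ChannelStream("D", s.unit, s.fs, s.t0, s.values - ba)
        out[f"hy_d_{tag}_slope"] = fit_window_slope(d, (tr, tr + 10.0))

    # the rBF release-to-peak slope is defined on the 1 Hz analysis basis,
    # so its truth uses the peak located on the clean 1 Hz stream (the drawn
    # continuous-time peak can sit between bins)
    rbf_1hz = bin_average(clean["BFI"], 1.0)
    rbf = ChannelStream(
        "RBF", "%baseline", 1.0, rbf_1hz.t0, 100.0 * rbf_1hz.values / truth.ba_bfi
    )
    _, t_peak_1hz = find_extremum(rbf, (tr, end), "max", tr)
    out["hy_rbf_slope"] = fit_window_slope(
        rbf, (tr, tr + t_peak_1hz), min_samples=3
    )
    return out


def _truth_features(
    truth: VotGroundTruth, protocol: ProtocolTiming, clean: dict[str, ChannelStream]
) -> dict[str, float]:
    """Full 30-feature ground-truth vector (controlled + derived)."""
    controlled = {
        "ba_o2hb": truth.ba_o2hb,
        "ba_hhb": truth.ba_hhb,
        "ba_bfi": truth.ba_bfi,
        "oc_d_o2hb_slope": truth.oc_o2hb_slope,
        "oc_d_hhb_slope": truth.oc_hhb_slope,
        "oc_d_o2hb_min": truth.oc_o2hb_min,
        "oc_d_hhb_max": truth.oc_hhb_max,
        "oc_d_o2hb_tmin": truth.oc_o2hb_tmin,
        "oc_d_hhb_tmax": truth.oc_hhb_tmax,
        "oc_rbf_min": truth.oc_rbf_min,
        "hy_d_o2hb_max": truth.hy_o2hb_max,
        "hy_d_hhb_min": truth.hy_hhb_min,
        "hy_rbf_max": truth.hy_rbf_max,
        "hy_d_o2hb_tmax": truth.hy_o2hb_tmax,
        "hy_d_hhb_tmin": truth.hy_hhb_tmin,
        "hy_rbf_tmax": truth.hy_rbf_tmax,
        "hy_d_o2hb_htr": truth.hy_o2hb_htr,
        "hy_d_hhb_htr": truth.hy_hhb_htr,
        "hy_rbf_htr": truth.hy_rbf_htr,
    }
    feats = {**controlled, **_derived_truth(truth, protocol, clean)}
    return {name: feats[name] for name in FEATURE_NAMES}


def simulate_trace(
    truth: VotGroundTruth,
    protocol: ProtocolTiming = ProtocolTiming(),
    *,
    subject_id: str = "synthetic",
    group: str = "climber",
) -> tuple[VotRecording, dict[str, float]]:
    """Build one synthetic recording; returns it with the full ground-truth
    feature vector (NaN-free, exact for controlled features, measured on the
    clean trace for emergent ones)."""
    truth.validate(protocol)
    clean = _clean_streams(truth, protocol)
    features = _truth_features(truth, protocol, clean)

    rng = np.random.default_rng(truth.seed)
    t_nirs = clean["O2HB"].times()
    t_dcs = clean["BFI"].times()
    env_nirs = _cardiac_envelope(t_nirs, protocol)
    env_dcs = _cardiac_envelope(t_dcs, protocol)

    streams: dict[str, ChannelStream] = {}
    card_o = truth.cardiac_amp_nirs * env_nirs * np.sin(
        2 * np.pi * truth.cardiac_freq * t_nirs
    )
    card_h = 0.5 * truth.cardiac_amp_nirs * env_nirs * np.sin(
        2 * np.pi * truth.cardiac_freq * t_nirs + np.pi / 3
    )
    for name, card, t in (("O2HB", card_o, t_nirs), ("HHB", card_h, t_nirs)):
        base = clean[name].values
        noise = rng.normal(0.0, truth.noise_sd.get(name, 0.0), base.size)
        streams[name] = replace(clean[name], values=base + card + noise)
    bfi = clean["BFI"].values
    card_b = truth.cardiac_amp_bfi_frac * bfi * env_dcs * np.sin(
        2 * np.pi * truth.cardiac_freq * t_dcs
    )
    noise_b = rng.normal(0.0, truth.noise_sd.get("BFI", 0.0), bfi.size)
    streams["BFI"] = replace(clean["BFI"], values=bfi + card_b + noise_b)

    rec = VotRecording(
        meta=SubjectMeta(subject_id=subject_id, group=group),
        streams=streams,
        events=protocol.events(),
    )
    return rec, features


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class GroupParams:
    """Per-feature (mean, sd) of the controlled generator parameters for one
    group, plus the cohort size."""

    group: str
    n: int
    means: dict[str, float]
    sds: dict[str, float]

    def __post_init__(self) -> None:
        if self.n < 2:
            raise SyntheticError("cohort size must be >= 2")
        if set(self.means) != set(self.sds):
            raise SyntheticError("means and sds must cover the same features")
        if any(sd < 0 for sd in self.sds.values()):
            raise SyntheticError("sds must be non-negative")


def _params(group: str, n: int, table: dict[str, tuple[float, float]]) -> GroupParams:
    return GroupParams(
        group=group,
        n=n,
        means={k: v[0] for k, v in table.items()},
        sds={k: v[1] for k, v in table.items()},
    )


#: observed climber group summaries (mean, SD)
CLIMBER_PARAMS = _params("climber", 17, {
    "ba_o2hb": (43.6, 10.7),
    "ba_hhb": (24.9, 4.0),
    "ba_bfi": (1.70e-9, 9.12e-10),
    "oc_o2hb_slope": (-0.1, 0.1),
    "oc_hhb_slope": (0.1, 0.0),
    "oc_o2hb_min": (-6.5, 6.4),
    "oc_hhb_max": (14.9, 4.1),
    "oc_o2hb_tmin": (-22.2, 43.6),
    "oc_hhb_tmax": (-3.5, 12.8),
    "oc_rbf_min": (12.3, 7.1),
    "hy_o2hb_max": (16.6, 3.9),
    "hy_hhb_min": (-5.5, 2.4),
    "hy_rbf_max": (873.7, 440.3),
    "hy_o2hb_tmax": (14.4, 4.2),
    "hy_hhb_tmin": (32.0, 7.8),
    "hy_rbf_tmax": (13.0, 6.5),
    "hy_o2hb_htr": (4.8, 1.8),
    "hy_hhb_htr": (7.1, 3.1),
    "hy_rbf_htr": (5.4, 4.3),
})

#: observed non-climber group summaries (mean, SD)
NONCLIMBER_PARAMS = _params("nonclimber", 15, {
    "ba_o2hb": (39.1, 11.7),
    "ba_hhb": (19.1, 4.1),
    "ba_bfi": (1.40e-9, 4.25e-10),
    "oc_o2hb_slope": (-0.1, 0.1),
    "oc_hhb_slope": (0.1, 0.0),
    "oc_o2hb_min": (-8.6, 5.4),
    "oc_hhb_max": (15.0, 6.0),
    "oc_o2hb_tmin": (-3.9, 7.8),
    "oc_hhb_tmax": (-2.8, 8.8),
    "oc_rbf_min": (12.0, 4.1),
    "hy_o2hb_max": (11.3, 4.4),
    "hy_hhb_min": (-3.3, 1.9),
    "hy_rbf_max": (712.4, 151.0),
    "hy_o2hb_tmax": (16.3, 4.6),
    "hy_hhb_tmin": (33.9, 9.1),
    "hy_rbf_tmax": (15.6, 5.9),
    "hy_o2hb_htr": (5.3, 1.9),
    "hy_hhb_htr": (7.6, 2.7),
    "hy_rbf_htr": (4.0, 2.1),
})


def default_truth(group: str = "climber", seed: int = 0) -> VotGroundTruth:
    """Noise-free single-subject truth at a group's mean parameters."""
    params = CLIMBER_PARAMS if group == "climber" else NONCLIMBER_PARAMS
    fields = {k: v for k, v in params.means.items()}
    return VotGroundTruth(**fields, seed=seed)


def _draw_trunc(
    rng: np.random.Generator, mean: float, sd: float,
    lo: float = -math.inf, hi: float = math.inf, max_tries: int = 10_000,
) -> float:
    if sd == 0:
        if not lo <= mean <= hi:
            raise SyntheticError(
                f"constant parameter {mean:g} violates bounds [{lo:g}, {hi:g}]"
            )
        return mean
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise SyntheticError(
        f"could not draw a valid value from N({mean:g}, {sd:g}) in "
        f"[{lo:g}, {hi:g}]"
    )


def _draw_subject_truth(
    rng: np.random.Generator, params: GroupParams, protocol: ProtocolTiming
) -> VotGroundTruth:
    """One subject's controlled parameters, drawn as truncated normals in an
    order that lets each bound condition on already-drawn values."""
    m, s = params.means, params.sds
    w = NADIR_HALFWIDTH_S
    t_ext_lo = -(protocol.oc_s - 20 - w - 2)
    tp_hi = protocol.hy_s - 21

    ba_o2hb = _draw_trunc(rng, m["ba_o2hb"], s["ba_o2hb"], lo=10.0)
    ba_hhb = _draw_trunc(rng, m["ba_hhb"], s["ba_hhb"], lo=5.0)
    ba_bfi = _draw_trunc(rng, m["ba_bfi"], s["ba_bfi"], lo=2e-10)
    oc_o2hb_slope = _draw_trunc(rng, m["oc_o2hb_slope"], s["oc_o2hb_slope"], hi=-0.01)
    oc_hhb_slope = _draw_trunc(rng, m["oc_hhb_slope"], s["oc_hhb_slope"], lo=0.01)
    hy_o2hb_max = _draw_trunc(rng, m["hy_o2hb_max"], s["hy_o2hb_max"], lo=2.0)
    hy_hhb_min = _draw_trunc(rng, m["hy_hhb_min"], s["hy_hhb_min"], hi=0.0)
    # occlusion extrema: leave room for the 20-s ramp, the nadir depth, and
    # a positive hyperemic height
    depth_o = NADIR_DEPTH_FRAC * (hy_o2hb_max - m["oc_o2hb_min"])
    oc_o2hb_min = _draw_trunc(
        rng, m["oc_o2hb_min"], s["oc_o2hb_min"],
        hi=min(20 * oc_o2hb_slope - depth_o - 0.3, hy_o2hb_max - depth_o - 1.0),
    )
    depth_h = NADIR_DEPTH_FRAC * (m["oc_hhb_max"] - hy_hhb_min)
    oc_hhb_max = _draw_trunc(
        rng, m["oc_hhb_max"], s["oc_hhb_max"],
        lo=max(20 * oc_hhb_slope + depth_h + 0.3, hy_hhb_min + depth_h + 1.0),
    )
    oc_rbf_min = _draw_trunc(rng, m["oc_rbf_min"], s["oc_rbf_min"], lo=2.0, hi=60.0)
    hy_rbf_max = _draw_trunc(
        rng, m["hy_rbf_max"], s["hy_rbf_max"], lo=oc_rbf_min + 50.0, hi=4000.0
    )
    kw = dict(
        ba_o2hb=ba_o2hb, ba_hhb=ba_hhb, ba_bfi=ba_bfi,
        oc_o2hb_slope=oc_o2hb_slope, oc_hhb_slope=oc_hhb_slope,
        oc_o2hb_min=oc_o2hb_min, oc_hhb_max=oc_hhb_max,
        oc_o2hb_tmin=_draw_trunc(rng, m["oc_o2hb_tmin"], s["oc_o2hb_tmin"],
                                 lo=t_ext_lo, hi=-0.25),
        oc_hhb_tmax=_draw_trunc(rng, m["oc_hhb_tmax"], s["oc_hhb_tmax"],
                                lo=t_ext_lo, hi=-0.25),
        oc_rbf_min=oc_rbf_min,
        hy_o2hb_max=hy_o2hb_max, hy_hhb_min=hy_hhb_min, hy_rbf_max=hy_rbf_max,
    )
    for tag, tp_key, htr_key in (
        ("o2hb", "hy_o2hb_tmax", "hy_o2hb_htr"),
        ("hhb", "hy_hhb_tmin", "hy_hhb_htr"),
        ("rbf", "hy_rbf_tmax", "hy_rbf_htr"),
    ):
        delay = RBF_DELAY_S if tag == "rbf" else 0.0
        tp = _draw_trunc(rng, m[tp_key], s[tp_key], lo=delay + 2.0, hi=tp_hi)
        htr = _draw_trunc(
            rng, m[htr_key], s[htr_key],
            lo=delay + 0.3, hi=delay + 0.495 * (tp - delay),
        )
        kw[tp_key] = tp
        kw[htr_key] = htr
    return VotGroundTruth(**kw)


def simulate_cohort(
    climber: GroupParams = CLIMBER_PARAMS,
    nonclimber: GroupParams = NONCLIMBER_PARAMS,
    seed: int = 0,
    protocol: ProtocolTiming = ProtocolTiming(),
    *,
    noise_frac: float = 0.05,
    cardiac_amp_nirs: float = 1.0,
    cardiac_amp_bfi_frac: float = 0.1,
    cardiac_freq: float = 1.2,
) -> tuple[list[VotRecording], pd.DataFrame]:
    """Draw a two-group cohort; returns the recordings and the per-subject
    ground-truth feature table (subject_id, group, 30 feature columns)."""
    rng = np.random.default_rng(seed)
    recordings: list[VotRecording] = []
    rows: list[dict] = []
    for params in (climber, nonclimber):
        for i in range(params.n):
            truth = _draw_subject_truth(rng, params, protocol)
            truth = replace(
                truth,
                cardiac_freq=cardiac_freq,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            if noise_frac > 0 or cardiac_amp_nirs > 0:
                truth = truth.with_noise(
                    noise_frac, cardiac_amp_nirs, cardiac_amp_bfi_frac
                )
            sid = f"{params.group[:2]}{i + 1:02d}"
            rec, feats = simulate_trace(
                truth, protocol, subject_id=sid, group=params.group
            )
            recordings.append(rec)
            rows.append({"subject_id": sid, "group": params.group, **feats})
    truth_table = pd.DataFrame(rows, columns=["subject_id", "group", *FEATURE_NAMES])
    return recordings, truth_table
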