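"""QRS detection and fiducial-point delineation.

R peaks are found on the cross-scale product of a Mexican-hat continuous
wavelet transform at scales spanning the QRS band (5-15 Hz), thresholded
adaptively against a rolling RMS.  Around each R peak the remaining
fiducials are located with window/slope rules:

* Q and S: nearest local extremum of polarity opposite to R within 80 ms
  before/after the R peak;
* QRS onset (the "I point") and end (J point): the first sample, moving
  outward from Q/S (at most 60 ms), where the absolute slope falls below
  10% of the maximum QRS slope;
* T peak: largest excursion relative to a late-window baseline, in a
  window from J + 80 ms to J + 0.6 RR; T onset/end by a slope-fraction
  rule on the flanks.

All constants live in :class:`DelineatorConfig`; none are clinical claims,
every one is testable against the synthetic generator's ground truth.
Indices are 0-based; amplitudes are read at the index, not interpolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

logger = logging.getLogger(__name__)

#: central frequency of the Mexican-hat wavelet as parametrized by pywt
_MEXH_FC = pywt.central_frequency("mexh")


@dataclass(frozen=True)
class DelineatorConfig:
    qrs_band_hz: tuple = (5.0, 8.0, 11.0, 15.0)  # CWT scales span 5-15 Hz
    threshold_frac: float = 0.4       # of the rolling RMS of the product
    rms_window_s: float = 2.0
    refractory_s: float = 0.2
    r_refine_s: float = 0.015         # re-centre R on the raw signal; the
                                      # product peak is already R-centred, so
                                      # a narrow window cannot drift to Q/S
    qs_window_s: float = 0.08
    onset_slope_frac: float = 0.10    # of max |QRS slope|
    onset_search_s: float = 0.06      # wide enough that a broad
                                      # pathological Q reaches its foot
    t_window_start_s: float = 0.08    # after the J point
    t_window_frac_rr: float = 0.6
    t_slope_frac: float = 0.40        # of max flank slope
    p_window_frac_rr: float = 0.25
    p_gap_s: float = 0.04
    cross_lead_match_s: float = 0.15


@dataclass
class Fiducials:
    """Per-beat 0-based sample indices and their amplitudes (mV)."""

    P_pos: int | None
    I_pos: int
    Q_pos: int
    R_pos: int
    S_pos: int
    J_pos: int
    Tstart_pos: int
    T_pos: int
    Tend_pos: int
    P_amp: float | None = None
    I_amp: float = 0.0
    Q_amp: float = 0.0
    R_amp: float = 0.0
    S_amp: float = 0.0
    J_amp: float = 0.0
    Tstart_amp: float = 0.0
    T_amp: float = 0.0
    Tend_amp: float = 0.0

    ORDERED = ("I_pos", "Q_pos", "R_pos", "S_pos", "J_pos",
               "Tstart_pos", "T_pos", "Tend_pos")

    def ordering_ok(self) -> bool:
        vals = [getattr(self, k) for k in self.ORDERED]
        nondecr = all(a <= b for a, b in zip(vals, vals[1:]))
        return nondecr and self.J_pos < self.Tstart_pos

    def read_amplitudes(self, x: np.ndarray) -> "Fiducials":
        for name in ("I", "Q", "R", "S", "J", "Tstart", "T", "Tend"):
            setattr(self, f"{name}_amp", float(x[getattr(self, f"{name}_pos")]))
        if self.P_pos is not None:
            self.P_amp = float(x[self.P_pos])
        return self


@dataclass
class MatchReport:
    """Detection-vs-truth matching counts and percentages."""

    TP: int
    FP: int
    FN: int
    Se: float    # TP/(TP+FN) * 100
    pp: float    # +p = TP/(TP+FP) * 100
    Acc: float   # TP/(TP+FP+FN) * 100


def detect_r_peaks(x: np.ndarray, fs: float,
                   config: DelineatorConfig = DelineatorConfig()
                   ) -> np.ndarray:
    """R-peak indices from the Mexican-hat cross-scale product.

    The product of |CWT| magnitudes across QRS-band scales is thresholded
    at ``threshold_frac`` times its rolling RMS; local maxima separated by
    the refractory period become R peaks, re-centred on the raw signal's
    largest absolute excursion within ``r_refine_s``.  The threshold is
    relative, so detections are invariant to overall amplitude scaling.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2 * fs:
        raise ValueError("need at least 2 seconds of signal for detection")
    scales = [_MEXH_FC * fs / f for f in config.qrs_band_hz]
    coefs, _ = pywt.cwt(x, scales, "mexh", method="fft")
    prod = np.prod(np.abs(coefs), axis=0)
    win = max(3, int(round(config.rms_window_s * fs)))
    rms = np.sqrt(uniform_filter1d(prod ** 2, size=win, mode="nearest"))
    if not np.any(prod > 0):
        return np.array([], dtype=int)
    peaks, _ = sps.find_peaks(prod, distance=max(1, int(config.refractory_s * fs)))
    peaks = peaks[prod[peaks] > config.threshold_frac * rms[peaks]]
    # re-centre each detection on the raw waveform
    half = int(round(config.r_refine_s * fs))
    refined = []
    med = np.median(x)
    for p in peaks:
        lo, hi = max(0, p - half), min(n, p + half + 1)
        refined.append(lo + int(np.argmax(np.abs(x[lo:hi] - med))))
    refined = np.unique(np.asarray(refined, dtype=int))
    return refined


def _nearest_opposite_extremum(x: np.ndarray, r: int, polarity: float,
                               lo: int, hi: int, prominence: float) -> int:
    """Nearest local extremum of polarity opposite to R inside [lo, hi).

    A prominence floor (a small fraction of the R excursion) keeps noise
    ripples on the QRS flanks from being mistaken for the Q/S trough.
    """
    seg = polarity * x[lo:hi]
    if seg.size < 3:
        return lo + int(np.argmin(seg))
    cand, _ = sps.find_peaks(-seg, prominence=prominence)
    if cand.size == 0:
        return lo + int(np.argmin(seg))
    cand = cand + lo
    return int(cand[np.argmin(np.abs(cand - r))])


def _slope_edge(slope: np.ndarray, start: int, stop: int, step: int,
                thr: float) -> int | None:
    """First index from ``start`` toward ``stop`` where |slope| < thr."""
    for i in range(start, stop, step):
        if abs(slope[i]) < thr:
            return i
    return None


def delineate_beat(x: np.ndarray, r_pos: int, rr_prev: float, rr_next: float,
                   fs: float, config: DelineatorConfig = DelineatorConfig()
                   ) -> Fiducials | None:
    """Locate all fiducials for the beat whose R peak is ``r_pos``.

    Returns None (with a logged reason) when a search window leaves the
    record or the ordering invariant cannot be satisfied.
    """
    n = x.size
    qs_w = int(round(config.qs_window_s * fs))
    onset_w = int(round(config.onset_search_s * fs))
    med = np.median(x)
    polarity = 1.0 if x[r_pos] >= med else -1.0

    lo = r_pos - qs_w
    t_hi = r_pos + int(round((config.t_window_start_s
                              + config.t_window_frac_rr * rr_next) * fs))
    if lo - onset_w < 0 or t_hi >= n:
        logger.debug("beat at %d dropped: search window out of bounds", r_pos)
        return None

    prom = 0.02 * abs(x[r_pos] - med)
    q_pos = _nearest_opposite_extremum(x, r_pos, polarity, lo, r_pos, prom)
    s_pos = _nearest_opposite_extremum(x, r_pos, polarity, r_pos + 1,
                                       r_pos + qs_w + 1, prom)

    slope = np.gradient(x) * fs
    max_slope = np.max(np.abs(slope[q_pos:s_pos + 1]))
    thr = config.onset_slope_frac * max_slope
    # start each search at the steepest point of the outer Q/S flank, so
    # the near-zero slope at the Q/S trough itself cannot end it early;
    # cap the threshold at half the flank's own peak slope so broad,
    # gentle waves (whose flank never reaches 10% of the R slope) still
    # terminate at their foot rather than at their steepest point
    i_lo = max(q_pos - onset_w, 0)
    i_start = i_lo + int(np.argmax(np.abs(slope[i_lo:q_pos + 1])))
    i_pos = _slope_edge(slope, i_start, i_lo - 1, -1,
                        min(thr, 0.5 * abs(slope[i_start])))
    if i_pos is None:
        i_pos = i_lo
    j_hi = min(s_pos + onset_w, n - 1)
    j_start = s_pos + int(np.argmax(np.abs(slope[s_pos:j_hi + 1])))
    j_pos = _slope_edge(slope, j_start, j_hi + 1, 1,
                        min(thr, 0.5 * abs(slope[j_start])))
    if j_pos is None:
        j_pos = j_hi

    w0 = j_pos + int(round(config.t_window_start_s * fs))
    w1 = j_pos + int(round(config.t_window_frac_rr * rr_next * fs))
    if w1 >= n or w1 - w0 < 4:
        logger.debug("beat at %d dropped: T window out of bounds", r_pos)
        return None
    # baseline for T-peak selection: median of the last 30% of the search
    # window, which lies past the T end for physiologic RR — unlike the
    # single sample at QRS onset it is immune to noise and Q-wave tails,
    # and unlike the full-window median it is not pulled toward an
    # elevated ST plateau
    tail = x[w0 + int(0.7 * (w1 - w0)):w1]
    base = float(np.median(tail))
    t_pos = w0 + int(np.argmax(np.abs(x[w0:w1] - base)))

    # T onset/end: slope-fraction rule on each flank.  The anchor is the
    # first slope-magnitude peak moving outward from the T apex (the T
    # wave's own flank), not the window-wide maximum, which could belong
    # to a neighbouring wave.
    def flank_edge(limit: int, outward: int) -> int:
        a = np.abs(slope)
        win_max = a[min(t_pos, limit):max(t_pos, limit) + 1].max()
        floor = 0.05 * win_max
        m = None
        i = t_pos + outward
        while 0 < i < n - 1 and (outward > 0) == (i < limit):
            if a[i] >= a[i - outward] and a[i] >= a[i + outward] and a[i] > floor:
                m = i
                break
            i += outward
        if m is None:
            return limit
        fthr = config.t_slope_frac * a[m]
        e = _slope_edge(slope, m, limit + outward, outward, fthr)
        return e if e is not None else limit

    tstart_pos = flank_edge(w0, -1)
    tend_pos = flank_edge(w1 - 1, +1)

    # P wave: optional, search window before QRS onset
    p_lo = i_pos - int(round(config.p_window_frac_rr * rr_prev * fs))
    p_hi = i_pos - int(round(config.p_gap_s * fs))
    p_pos = None
    if p_lo >= 0 and p_hi - p_lo >= 3:
        p_pos = p_lo + int(np.argmax(np.abs(x[p_lo:p_hi] - base)))

    fid = Fiducials(P_pos=p_pos, I_pos=i_pos, Q_pos=q_pos, R_pos=r_pos,
                    S_pos=s_pos, J_pos=j_pos, Tstart_pos=tstart_pos,
                    T_pos=t_pos, Tend_pos=tend_pos)
    if not fid.ordering_ok():
        logger.debug("beat at %d dropped: fiducial ordering violated", r_pos)
        return None
    return fid.read_amplitudes(x)


def delineate_lead(x: np.ndarray, fs: float,
                   config: DelineatorConfig = DelineatorConfig()
                   ) -> list[Fiducials]:
    """Detect R peaks then delineate every beat on one lead.

    Boundary beats whose search windows leave the record are dropped.
    """
    r_peaks = detect_r_peaks(x, fs, config)
    if r_peaks.size == 0:
        return []
    rr = np.diff(r_peaks) / fs
    med_rr = float(np.median(rr)) if rr.size else 0.8
    out = []
    for i, r in enumerate(r_peaks):
        rr_prev = rr[i - 1] if i > 0 else med_rr
        rr_next = rr[i] if i < rr.size else med_rr
        fid = delineate_beat(x, int(r), float(rr_prev), float(rr_next), fs,
                             config)
        if fid is not None:
            out.append(fid)
    return out


def match_detections(detected, truth, tolerance_ms: float, fs: float
                     ) -> MatchReport:
    """Greedy one-to-one matching of detections to truth within tolerance.

    Se = TP/(TP+FN), +p = TP/(TP+FP), Acc = TP/(TP+FP+FN), each in percent
    (the wave-detection accuracy convention, not classification accuracy).
    """
    if tolerance_ms < 0:
        raise ValueError("tolerance must be non-negative")
    det = np.sort(np.asarray(detected, dtype=float))
    tru = np.sort(np.asarray(truth, dtype=float))
    tol = tolerance_ms * fs / 1000.0
    tp = 0
    i = j = 0
    while i < det.size and j < tru.size:
        d = det[i] - tru[j]
        if abs(d) <= tol:
            tp += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    fp = det.size - tp
    fn = tru.size - tp
    se = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    pp = 100.0 * tp / (tp + fp) if tp + fp else float("nan")
    acc = 100.0 * tp / (tp + fp + fn) if tp + fp + fn else float("nan")
    return MatchReport(TP=tp, FP=fp, FN=fn, Se=se, pp=pp, Acc=acc)


def match_beats_across_leads(per_lead: dict[str, list[Fiducials]],
                             fs: float,
                             reference_lead: str = "II",
                             tolerance_s: float = 0.15
                             ) -> list[dict[str, Fiducials]]:
    """Match beats across leads by nearest R peak within the tolerance.

    Beats missing on any lead are dropped whole (feature purity over
    yield).  Returns one dict lead->Fiducials per matched beat.
    """
    if reference_lead not in per_lead:
        reference_lead = next(iter(per_lead))
    ref = per_lead[reference_lead]
    tol = tolerance_s * fs
    matched = []
    for fid_ref in ref:
        row = {}
        for lead, fids in per_lead.items():
            if not fids:
                row = None
                break
            rs = np.array([f.R_pos for f in fids])
            k = int(np.argmin(np.abs(rs - fid_ref.R_pos)))
            if abs(rs[k] - fid_ref.R_pos) > tol:
                row = None
                break
            row[lead] = fids[k]
        if row is not None:
            matched.append(row)
    return matched


def plot_fiducials(x: np.ndarray, fs: float, fids: list[Fiducials], ax=None):
    """Render one lead with its fiducial marks (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    t = np.arange(x.size) / fs
    ax.plot(t, x, lw=0.8, color="0.3")
    marks = {"R_pos": "r^", "Q_pos": "bv", "S_pos": "gv", "I_pos": "k<",
             "J_pos": "k>", "T_pos": "mo", "Tstart_pos": "m<",
             "Tend_pos": "m>"}
    for attr, style in marks.items():
        idx = [getattr(f, attr) for f in fids]
        ax.plot(np.asarray(idx) / fs, x[idx], style, ms=4,
                label=attr.replace("_pos", ""))
    ax.legend(ncol=8, fontsize=7)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("mV")
    return ax


def fiducials_table(matched: list[dict[str, Fiducials]]) -> "object":
    """Tab-separated-ready annotation table (one row per lead-beat)."""
    import pandas as pd

    rows = []
    for b, row in enumerate(matched):
        for lead, f in row.items():
            rows.append({
                "beat": b, "lead": lead,
                "I_pos": f.I_pos, "Q_pos": f.Q_pos, "R_pos": f.R_pos,
                "S_pos": f.S_pos, "J_pos": f.J_pos,
                "Tstart_pos": f.Tstart_pos, "T_pos": f.T_pos,
                "Tend_pos": f.Tend_pos,
            })
    return pd.DataFrame(rows)
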