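"""Filtering, Pan-Tompkins R-peak detection and R-centred segmentation.

The pipeline is offline: the band-pass filter is applied forward-backward
(zero phase) by default so R-peak latency is not shifted; a causal mode is
available.  Beats are cut as half-open windows [r - fs/2, r + fs/2) of
exactly k = fs samples, so k = 200 at the 200 Hz sampling rate the feature
model assumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .synthetic import ECGRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    low_cut_hz: float = 0.5
    high_cut_hz: float = 40.0
    order: int = 4
    mode: str = "zero-phase"  # or "causal"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if not 0 < self.low_cut_hz < self.high_cut_hz:
            raise ValueError("need 0 < low_cut < high_cut")
        if self.mode not in ("zero-phase", "causal"):
            raise ValueError("mode must be 'zero-phase' or 'causal'")


@dataclass
class HeartbeatMatrix:
    """n beats of k samples each (rows are observations), with optional labels."""

    beats: np.ndarray  # (n, k) mV
    subject_ids: np.ndarray | None = None
    abnormal: np.ndarray | None = None
    r_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beats = np.atleast_2d(np.asarray(self.beats, dtype=float))

    @property
    def n(self) -> int:
        return self.beats.shape[0]

    @property
    def k(self) -> int:
        return self.beats.shape[1]

    def subset(self, idx) -> "HeartbeatMatrix":
        pick = lambda a: None if a is None else np.asarray(a)[idx]
        return HeartbeatMatrix(self.beats[idx], pick(self.subject_ids),
                               pick(self.abnormal), pick(self.r_indices))

    @staticmethod
    def vstack(mats) -> "HeartbeatMatrix":
        mats = list(mats)
        beats = np.vstack([m.beats for m in mats])
        def cat(attr):
            parts = [getattr(m, attr) for m in mats]
            if any(p is None for p in parts):
                return None
            return np.concatenate(parts)
        return HeartbeatMatrix(beats, cat("subject_ids"), cat("abnormal"),
                               cat("r_indices"))


def bandpass_filter(record: ECGRecord, spec: FilterSpec | None = None) -> ECGRecord:
    """Butterworth band-pass of the stated order and cutoffs (default 0.5-40 Hz)."""
    spec = spec if spec is not None else FilterSpec()
    if spec.high_cut_hz >= record.fs / 2:
        raise ValueError("high_cut must be below the Nyquist frequency")
    if len(record.samples) <= 3 * spec.order:
        raise ValueError("record too short for the filter order")
    sos = signal.butter(spec.order, [spec.low_cut_hz, spec.high_cut_hz],
                        btype="band", fs=record.fs, output="sos")
    if spec.mode == "zero-phase":
        filtered = signal.sosfiltfilt(sos, record.samples)
    else:
        filtered = signal.sosfilt(sos, record.samples)
    return ECGRecord(filtered, record.fs, record.subject_id,
                     record.truth_r.copy(), record.truth_abnormal.copy())


# ---------------------------------------------------------------------------
# Pan-Tompkins QRS detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanTompkinsParams:
    """Internal stage parameters, following the original publication."""

    band: tuple = (5.0, 15.0)  # Hz, QRS-emphasising band-pass
    integration_window_s: float = 0.150
    refractory_s: float = 0.200
    search_back_factor: float = 1.66  # of the running average RR
    signal_update: float = 0.125
    noise_update: float = 0.125
    threshold_fraction: float = 0.25  # THR = NPK + f * (SPK - NPK)
    refine_window_s: float = 0.050


def detect_r_peaks(record: ECGRecord,
                   params: PanTompkinsParams | None = None) -> np.ndarray:
    """Pan-Tompkins stages: band-pass, derivative, squaring, moving-window
    integration, adaptive dual thresholds with search-back and refractory
    blanking.  Returned indices are refined to the local signal maximum
    within +/-50 ms and are strictly increasing.
    """
    params = params or PanTompkinsParams()
    fs = record.fs
    x = np.asarray(record.samples, dtype=float)
    if len(x) < 2 * fs:
        raise ValueError("record shorter than 2 s: thresholds cannot initialise")
    if np.ptp(x) < 1e-12:
        return np.empty(0, dtype=np.int64)  # constant record: no QRS energy

    # QRS-band emphasis (zero-phase: offline pipeline, keeps peaks aligned)
    sos = signal.butter(2, list(params.band), btype="band", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, x)

    # five-point derivative, group delay 2 samples (compensated by shifting)
    kern = np.array([2.0, 1.0, 0.0, -1.0, -2.0]) * fs / 8.0
    dfull = np.convolve(bp, kern)[: len(x)]  # causal, delay 2
    deriv = np.zeros_like(dfull)
    deriv[:-2] = dfull[2:]

    squared = deriv**2

    # moving-window integration, centred (delay (nwin-1)/2 compensated)
    nwin = max(1, int(round(params.integration_window_s * fs)))
    mfull = np.convolve(squared, np.ones(nwin) / nwin)[: len(x)]
    shift = (nwin - 1) // 2
    mwi = np.zeros_like(mfull)
    mwi[: len(x) - shift] = mfull[shift:]

    refractory = int(round(params.refractory_s * fs))
    cand, _ = signal.find_peaks(mwi, distance=max(1, refractory))
    if cand.size == 0:
        return np.empty(0, dtype=np.int64)

    # adaptive dual thresholds on the integrated signal
    init = mwi[: int(2 * fs)]
    spk = float(init.max()) / 3.0
    npk = float(init.mean()) / 2.0
    f = params.threshold_fraction
    thr1 = npk + f * (spk - npk)

    accepted: list[int] = []
    rr_hist: list[float] = []
    last_qrs: int | None = None
    noise_since_last: list[int] = []

    for c in cand:
        peak = mwi[c]
        # search-back: long gap since the last QRS -> revisit skipped peaks
        if last_qrs is not None and rr_hist:
            rr_avg = float(np.mean(rr_hist[-8:]))
            if (c - last_qrs) > params.search_back_factor * rr_avg and noise_since_last:
                back = [b for b in noise_since_last
                        if mwi[b] > 0.5 * thr1 and b - last_qrs > refractory]
                if back:
                    b = max(back, key=lambda i: mwi[i])
                    spk = 0.25 * mwi[b] + 0.75 * spk
                    rr_hist.append(b - last_qrs)
                    accepted.append(b)
                    last_qrs = b
                    noise_since_last = []
                    thr1 = npk + f * (spk - npk)
        if peak > thr1 and (last_qrs is None or c - last_qrs > refractory):
            spk = params.signal_update * peak + (1 - params.signal_update) * spk
            if last_qrs is not None:
                rr_hist.append(c - last_qrs)
            accepted.append(c)
            last_qrs = c
            noise_since_last = []
        else:
            npk = params.noise_update * peak + (1 - params.noise_update) * npk
            noise_since_last.append(c)
        thr1 = npk + f * (spk - npk)

    if not accepted:
        return np.empty(0, dtype=np.int64)

    # refine each detection to the local maximum of the input signal
    half = int(round(params.refine_window_s * fs))
    refined = []
    for c in accepted:
        lo = max(0, c - half)
        hi = min(len(x), c + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.unique(np.asarray(refined, dtype=np.int64))
    # enforce the refractory period after refinement (keep the larger peak)
    keep = []
    for r in refined:
        if keep and r - keep[-1] <= refractory:
            if x[r] > x[keep[-1]]:
                keep[-1] = r
        else:
            keep.append(r)
    return np.asarray(keep, dtype=np.int64)


def segment_heartbeats(record: ECGRecord, r_peaks) -> HeartbeatMatrix:
    """Cut half-open windows [r - fs/2, r + fs/2); out-of-bounds beats dropped."""
    fs = record.fs
    half = int(fs) // 2
    k = 2 * half
    x = record.samples
    rows, kept_r = [], []
    dropped = 0
    for r in np.asarray(r_peaks, dtype=np.int64):
        lo, hi = r - half, r + half
        if lo < 0 or hi > len(x):
            dropped += 1
            continue
        rows.append(x[lo:hi])
        kept_r.append(r)
    if dropped:
        log.info("segment_heartbeats: dropped %d out-of-bounds beats", dropped)
    beats = np.asarray(rows, dtype=float).reshape(len(rows), k)
    subj = np.full(len(rows), record.subject_id, dtype=object)
    return HeartbeatMatrix(beats, subject_ids=subj,
                           r_indices=np.asarray(kept_r, dtype=np.int64))


def label_beats_from_truth(record: ECGRecord, r_peaks,
                           tol_s: float = 0.040) -> tuple[np.ndarray, np.ndarray]:
    """Match detections to ground-truth beats within a tolerance.

    Returns (is_abnormal, matched) per detection; unmatched detections are
    marked abnormal=False, matched=False.
    """
    r_peaks = np.asarray(r_peaks, dtype=np.int64)
    tol = int(round(tol_s * record.fs))
    is_abn = np.zeros(len(r_peaks), dtype=bool)
    matched = np.zeros(len(r_peaks), dtype=bool)
    if record.truth_r.size == 0:
        return is_abn, matched
    for i, r in enumerate(r_peaks):
        j = int(np.argmin(np.abs(record.truth_r - r)))
        if abs(int(record.truth_r[j]) - int(r)) <= tol:
            matched[i] = True
            is_abn[i] = bool(record.truth_abnormal[j])
    return is_abn, matched


# ---------------------------------------------------------------------------
# Beat-matrix CSV I/O (one beat per row, sidecar label CSV)
# ---------------------------------------------------------------------------

def write_beats_csv(mat: HeartbeatMatrix, path, labels_path=None) -> None:
    with open(path, "w") as fh:
        fh.write(",".join(f"s{i}" for i in range(mat.k)) + "\n")
        for row in mat.beats:
            fh.write(",".join(f"{v:.9g}" for v in row) + "\n")
    if labels_path is not None:
        with open(labels_path, "w") as fh:
            fh.write("subject_id,is_abnormal\n")
            for i in range(mat.n):
                sid = "" if mat.subject_ids is None else mat.subject_ids[i]
                abn = "" if mat.abnormal is None else int(mat.abnormal[i])
                fh.write(f"{sid},{abn}\n")


def read_beats_csv(path, labels_path=None) -> HeartbeatMatrix:
    beats = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    subject_ids = abnormal = None
    if labels_path is not None:
        import csv

        sids, abns = [], []
        with open(labels_path) as fh:
            for row in csv.DictReader(fh):
                sids.append(row["subject_id"])
                abns.append(bool(int(row["is_abnormal"])) if row["is_abnormal"] else False)
        subject_ids = np.asarray(sids, dtype=object)
        abnormal = np.asarray(abns, dtype=bool)
    return HeartbeatMatrix(beats, subject_ids, abnormal)
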