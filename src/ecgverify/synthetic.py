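"""Synthetic single-lead ECG with per-subject morphology and ground truth.

Each subject is parameterised by a sum-of-Gaussians beat template (one bump
per fiducial wave P, Q, R, S, T), a mean heart rate in the physiological
1-1.5 beats/s band, and beat-to-beat jitter.  Records add the classic
single-lead contaminants: respiratory baseline wander (0.15-0.30 Hz),
powerline interference (50/60 Hz), electrode-movement noise (1-10 Hz) and
broadband sensor noise.  A controllable fraction of beats is morphologically
abnormal (wave dropped / inverted / rescaled) and flagged in the ground
truth, which records the R sample index of every scheduled beat.

All generation is deterministic in the integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

WAVES = ("P", "Q", "R", "S", "T")

# Prior ranges for make_subject: (amplitude mV, centre offset ms, width ms).
# Amplitudes/latencies bracket textbook lead-I adult morphology; R is fixed
# at offset 0 and dominates every other wave by construction.
_WAVE_PRIORS = {
    #         amp lo, amp hi,  c lo,  c hi,  w lo, w hi
    "P": (0.06, 0.20, -220.0, -160.0, 18.0, 30.0),
    "Q": (-0.20, -0.06, -45.0, -30.0, 7.0, 12.0),
    "R": (0.80, 1.60, 0.0, 0.0, 8.0, 14.0),
    "S": (-0.35, -0.10, 28.0, 45.0, 8.0, 14.0),
    "T": (0.15, 0.45, 220.0, 320.0, 40.0, 70.0),
}


@dataclass(frozen=True)
class SubjectTemplate:
    """Ground-truth morphology parameters for one synthetic subject."""

    subject_id: str
    wave_params: dict  # wave -> (amplitude mV, centre offset ms, width ms)
    heart_rate_hz: float
    hr_jitter: float  # coefficient of variation of the inter-beat interval
    amp_jitter: float  # per-beat multiplicative amplitude noise s.d.

    def __post_init__(self) -> None:
        if not 0 < self.heart_rate_hz:
            raise ValueError("heart_rate_hz must be positive")
        amps = {w: self.wave_params[w][0] for w in WAVES}
        if not all(amps["R"] > abs(amps[w]) for w in ("P", "Q", "S", "T")):
            raise ValueError("R amplitude must dominate |P|,|Q|,|S|,|T|")
        centres = [self.wave_params[w][1] for w in WAVES]
        if not all(a < b for a, b in zip(centres, centres[1:])):
            raise ValueError("wave centres must be ordered P<Q<R<S<T")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive contaminant levels; all-zero amplitudes give a clean record.

    Amplitudes are in mV: sinusoid amplitude for baseline wander and
    powerline, RMS for the band-limited electrode-movement noise, standard
    deviation for the broadband term.
    """

    baseline_wander: tuple = (0.22, 0.05)  # (Hz in [0.15, 0.30], mV)
    powerline: tuple = (60.0, 0.02)  # (50 or 60 Hz, mV)
    electrode_movement: tuple = ((1.0, 10.0), 0.02)  # ((lo, hi) Hz, mV RMS)
    broadband_sd: float = 0.02  # mV

    def __post_init__(self) -> None:
        if min(self.baseline_wander[1], self.powerline[1],
               self.electrode_movement[1], self.broadband_sd) < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if not 0.15 <= self.baseline_wander[0] <= 0.30:
            raise ValueError("baseline wander frequency outside 0.15-0.30 Hz")

    @classmethod
    def clean(cls) -> "NoiseSpec":
        return cls((0.22, 0.0), (60.0, 0.0), ((1.0, 10.0), 0.0), 0.0)


@dataclass
class ECGRecord:
    """A voltage sequence plus the generator's ground-truth beat channel."""

    samples: np.ndarray  # mV
    fs: float  # Hz
    subject_id: str
    truth_r: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    truth_abnormal: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.truth_r = np.asarray(self.truth_r, dtype=np.int64)
        self.truth_abnormal = np.asarray(self.truth_abnormal, dtype=bool)
        if self.truth_r.size and np.any(np.diff(self.truth_r) <= 0):
            raise ValueError("truth R indices must be strictly increasing")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


def make_subject(seed: int, subject_id: str | None = None) -> SubjectTemplate:
    """Draw a subject morphology from the prior ranges; deterministic in seed."""
    rng = np.random.default_rng(seed)
    wave_params = {}
    for w in WAVES:
        alo, ahi, clo, chi, wlo, whi = _WAVE_PRIORS[w]
        wave_params[w] = (
            float(rng.uniform(alo, ahi)),
            float(rng.uniform(clo, chi)),
            float(rng.uniform(wlo, whi)),
        )
    return SubjectTemplate(
        subject_id=subject_id if subject_id is not None else f"S{seed:06d}",
        wave_params=wave_params,
        heart_rate_hz=float(rng.uniform(1.0, 1.5)),
        hr_jitter=float(rng.uniform(0.03, 0.08)),
        amp_jitter=float(rng.uniform(0.03, 0.07)),
    )


def _beat_waveform(t: np.ndarray, wave_params: dict) -> np.ndarray:
    """Sum-of-Gaussians beat evaluated at times t (seconds, R at 0)."""
    out = np.zeros_like(t)
    for amp, centre_ms, width_ms in wave_params.values():
        c, w = centre_ms / 1000.0, width_ms / 1000.0
        out += amp * np.exp(-0.5 * ((t - c) / w) ** 2)
    return out


def _perturb_abnormal(wave_params: dict, rng: np.random.Generator) -> dict:
    """Morphology perturbation well beyond normal jitter."""
    mode = rng.integers(0, 4)
    wp = dict(wave_params)
    if mode == 0:  # inverted T wave
        a, c, w = wp["T"]
        wp["T"] = (-a, c, w)
    elif mode == 1:  # P wave dropped, T halved
        a, c, w = wp["P"]
        wp["P"] = (0.0, c, w)
        a, c, w = wp["T"]
        wp["T"] = (0.5 * a, c, w)
    elif mode == 2:  # deep, widened S (bundle-branch-like QRS)
        a, c, w = wp["S"]
        wp["S"] = (2.5 * a, c, 2.0 * w)
    else:  # global amplitude surge
        wp = {k: (1.7 * a, c, w) for k, (a, c, w) in wp.items()}
    return wp


def synthesize_record(
    template: SubjectTemplate,
    duration: float,
    fs: float,
    noise: NoiseSpec | None = None,
    abnormal_fraction: float = 0.0,
    seed: int = 0,
) -> ECGRecord:
    """Render a record of `duration` seconds at `fs` Hz; deterministic in seed.

    Beats are laid out with lognormal inter-beat jitter around the template
    heart rate (truncated so consecutive beats never overlap); abnormal beats
    are round(abnormal_fraction * B) of the B beats, chosen uniformly.
    """
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    if duration <= 2.0 / template.heart_rate_hz:
        raise ValueError("duration must cover more than two beats")
    if fs < 100:
        raise ValueError("fs must be at least 100 Hz")
    if not 0.0 <= abnormal_fraction <= 1.0:
        raise ValueError("abnormal_fraction must be in [0, 1]")
    noise = noise if noise is not None else NoiseSpec()

    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    clean = np.zeros(n)

    # Beat schedule: lognormal IBI with the template's CV, clipped so beats
    # stay separated by at least 55% of the mean interval.
    mean_ibi = 1.0 / template.heart_rate_hz
    cv = template.hr_jitter
    sigma = np.sqrt(np.log1p(cv**2))
    r_times = []
    t_r = 0.45 * mean_ibi
    margin = 0.35  # leave room for the trailing T wave
    while t_r < duration - margin:
        r_times.append(t_r)
        ibi = mean_ibi * np.exp(sigma * rng.standard_normal() - 0.5 * sigma**2)
        ibi = float(np.clip(ibi, 0.55 * mean_ibi, 1.8 * mean_ibi))
        t_r = t_r + ibi
    r_times = np.asarray(r_times)
    n_beats = len(r_times)

    n_abn = int(round(abnormal_fraction * n_beats))
    abn_idx = rng.choice(n_beats, size=n_abn, replace=False) if n_abn else np.empty(0, int)
    is_abn = np.zeros(n_beats, dtype=bool)
    is_abn[abn_idx] = True

    truth_r = np.round(r_times * fs).astype(np.int64)
    for b in range(n_beats):
        wp = template.wave_params
        if is_abn[b]:
            wp = _perturb_abnormal(wp, rng)
        # per-beat variability: one amplitude multiplier plus small latency
        # jitter on the non-R waves
        scale = 1.0 + template.amp_jitter * rng.standard_normal()
        wp = {
            k: (scale * a,
                c if k == "R" else c + 2.0 * rng.standard_normal(),
                w)
            for k, (a, c, w) in wp.items()
        }
        lo = max(0, int((r_times[b] - 0.6) * fs))
        hi = min(n, int((r_times[b] + 0.6) * fs) + 1)
        clean[lo:hi] += _beat_waveform(t[lo:hi] - r_times[b], wp)

    # truth R = sample of maximum R-wave amplitude before noise: refine the
    # rounded beat centre to the rendered clean-signal peak (sub-sample beat
    # centres plus neighbouring-wave tails can shift the sampled maximum)
    for b in range(n_beats):
        lo = max(0, truth_r[b] - 3)
        hi = min(n, truth_r[b] + 4)
        if hi > lo:
            truth_r[b] = lo + int(np.argmax(clean[lo:hi]))

    samples = clean.copy()
    bw_f, bw_a = noise.baseline_wander
    if bw_a > 0:
        samples += bw_a * np.sin(2 * np.pi * bw_f * t + rng.uniform(0, 2 * np.pi))
    pl_f, pl_a = noise.powerline
    if pl_a > 0:
        samples += pl_a * np.sin(2 * np.pi * pl_f * t + rng.uniform(0, 2 * np.pi))
    (em_lo, em_hi), em_a = noise.electrode_movement
    if em_a > 0:
        white = rng.standard_normal(n)
        sos = signal.butter(2, [em_lo, em_hi], btype="band", fs=fs, output="sos")
        em = signal.sosfilt(sos, white)
        rms = np.sqrt(np.mean(em**2))
        if rms > 0:
            samples += em_a / rms * em
    if noise.broadband_sd > 0:
        samples += noise.broadband_sd * rng.standard_normal(n)

    keep = truth_r < n
    return ECGRecord(
        samples=samples,
        fs=fs,
        subject_id=template.subject_id,
        truth_r=truth_r[keep],
        truth_abnormal=is_abn[keep],
    )


# ---------------------------------------------------------------------------
# CSV I/O (one sample per row, header comment carries the sampling rate)
# ---------------------------------------------------------------------------

def write_record_csv(record: ECGRecord, path, truth_path=None) -> None:
    """Write `# fs=<Hz>` header + `mV` column; truth as a sidecar CSV."""
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs:g}\n")
        fh.write(f"# subject_id={record.subject_id}\n")
        fh.write("mV\n")
        for v in record.samples:
            fh.write(f"{v:.9g}\n")
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            fh.write("sample_index,is_abnormal\n")
            for r, a in zip(record.truth_r, record.truth_abnormal):
                fh.write(f"{r},{int(a)}\n")


def read_record_csv(path, truth_path=None) -> ECGRecord:
    fs = None
    subject_id = "unknown"
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if body.startswith("fs="):
                    fs = float(body[3:])
                elif body.startswith("subject_id="):
                    subject_id = body[len("subject_id="):]
                continue
            if line == "mV":
                continue
            rows.append(float(line))
    if fs is None:
        raise ValueError(f"{path}: missing '# fs=<Hz>' header")
    truth_r = np.empty(0, dtype=np.int64)
    truth_abn = np.empty(0, dtype=bool)
    if truth_path is not None:
        data = np.genfromtxt(truth_path, delimiter=",", names=True, dtype=None)
        data = np.atleast_1d(data)
        truth_r = data["sample_index"].astype(np.int64)
        truth_abn = data["is_abnormal"].astype(bool)
    return ECGRecord(np.asarray(rows), fs, subject_id, truth_r, truth_abn)
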