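"""Expert ECG features for premature ventricular contraction (PVC) detection.

A PVC (ventricular extrasystole) shows three hallmark features on a
single-lead ECG, each extracted here from a *beat triad* — the beat under
examination together with its preceding and following beats:

1. **Absent P wave**: no atrial deflection in the PR window before the QRS.
2. **Widened QRS**: complex duration >= 120 ms (the guideline threshold).
3. **Full compensatory pause**: the RR intervals flanking the ectopic beat
   satisfy ``RRprev + RRnext ~= 2 * RRn`` within a tolerance, where RRn is
   the mean RR interval between normal beats.  When an extrasystole is
   immediately followed by another extrasystole, the pause cannot be read
   off the rhythm and the feature is marked ``not_evaluated``; only the last
   extrasystole of a run is evaluated.

All detectors are deterministic threshold rules on the smoothed signal, with
every constant exposed in the config dataclasses.  R-peak annotations are
authoritative when present; a simple built-in detector covers unannotated
synthetic records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.signal import find_peaks

from .matrices import FeatureMatrix
from .rules import Interval, IntervalRule

__all__ = [
    "BeatTriad", "BeatFeatures", "EcgRecord",
    "PWaveConfig", "QrsConfig", "PauseConfig", "EcgConfig",
    "detect_p_wave", "qrs_duration", "compensatory_pause", "mean_rr",
    "extract_beat_features", "classify_pvc", "default_pvc_rule",
    "detect_r_peaks", "BEAT_FEATURE_COLUMNS",
]

# numeric encoding of the tri-state pause feature in matrix B
PAUSE_ENCODING = {"full": 1.0, "not_full": 0.0, "not_evaluated": 0.5}

BEAT_FEATURE_COLUMNS = [
    "p_absent", "qrs_ms", "qrs_wide", "comp_pause_full",
    "rr_prev_s", "rr_next_s",
]

#: MIT-BIH-style annotation symbols -> coarse beat classes.  Configurable;
#: only "normal" vs extrasystole matters for the pause rule, and "pvc" for
#: the planted-class bookkeeping.
DEFAULT_SYMBOL_MAP = {
    "N": "normal", "V": "pvc", "/": "paced", "R": "rbbb", "L": "lbbb",
    "A": "apb", "F": "fusion_v", "f": "fusion_p",
    "normal": "normal", "pvc": "pvc",
}


@dataclass
class PWaveConfig:
    window_s: tuple[float, float] = (0.28, 0.06)  # search [r-0.28 s, r-0.06 s]
    smooth_ms: float = 20.0
    amplitude_frac: float = 0.08  # min prominence relative to R amplitude


@dataclass
class QrsConfig:
    threshold_frac: float = 0.15  # onset/offset crossing rel. to R amplitude
    window_s: float = 0.2         # search at most +-200 ms around the R peak
    smooth_ms: float = 20.0
    wide_ms: float = 120.0        # guideline PVC width threshold (inclusive)


@dataclass
class PauseConfig:
    tolerance_mode: str = "relative"   # "relative" (x 2*RRn) or "absolute" (s)
    tolerance_value: float = 0.10


@dataclass
class EcgConfig:
    pwave: PWaveConfig = field(default_factory=PWaveConfig)
    qrs: QrsConfig = field(default_factory=QrsConfig)
    pause: PauseConfig = field(default_factory=PauseConfig)
    symbol_map: dict = field(default_factory=lambda: dict(DEFAULT_SYMBOL_MAP))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EcgConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for section, obj in (("pwave", cfg.pwave), ("qrs", cfg.qrs),
                             ("pause", cfg.pause)):
            for key, val in (raw.get(section) or {}).items():
                if not hasattr(obj, key):
                    raise KeyError(f"unknown config key {section}.{key}")
                setattr(obj, key, tuple(val) if isinstance(val, list) else val)
        if "symbol_map" in raw:
            cfg.symbol_map.update(raw["symbol_map"])
        return cfg


@dataclass
class BeatTriad:
    """A beat with its neighbours; indices point into ``signal``."""

    signal: np.ndarray
    fs: float
    r_prev: int
    r_main: int
    r_next: int
    label: str | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        if not (0 <= self.r_prev < self.r_main < self.r_next < len(self.signal)):
            raise ValueError(
                f"R indices must satisfy 0 <= r_prev < r_main < r_next < "
                f"len(signal); got {self.r_prev}, {self.r_main}, {self.r_next} "
                f"in a signal of {len(self.signal)} samples"
            )


@dataclass
class BeatFeatures:
    p_absent: bool
    qrs_ms: float
    qrs_wide: bool
    comp_pause: str  # "full" | "not_full" | "not_evaluated"
    rr_prev_s: float
    rr_next_s: float
    rr_n_s: float

    def as_row(self) -> dict[str, float]:
        return {
            "p_absent": float(self.p_absent),
            "qrs_ms": float(self.qrs_ms),
            "qrs_wide": float(self.qrs_wide),
            "comp_pause_full": PAUSE_ENCODING[self.comp_pause],
            "rr_prev_s": float(self.rr_prev_s),
            "rr_next_s": float(self.rr_next_s),
        }


@dataclass
class EcgRecord:
    """A single-lead ECG with R-peak annotations and per-beat labels."""

    signal: np.ndarray
    fs: float
    r_peaks: list[int] | None = None
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float).ravel()
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.r_peaks is not None and self.labels is not None \
                and len(self.r_peaks) != len(self.labels):
            raise ValueError("r_peaks and labels lengths differ")

    # ------------------------------------------------------------------ I/O
    def save(self, signal_csv: str | Path, ann_json: str | Path) -> None:
        np.savetxt(signal_csv, self.signal, fmt="%.17g")
        Path(ann_json).write_text(json.dumps({
            "fs": self.fs,
            "r_peaks": self.r_peaks,
            "labels": self.labels,
        }))

    @classmethod
    def load(cls, signal_csv: str | Path, ann_json: str | Path) -> "EcgRecord":
        signal = np.loadtxt(signal_csv)
        meta = json.loads(Path(ann_json).read_text())
        return cls(signal=signal, fs=meta["fs"],
                   r_peaks=meta.get("r_peaks"), labels=meta.get("labels"))


# ---------------------------------------------------------------------------
# signal primitives
# ---------------------------------------------------------------------------

def _smooth(x: np.ndarray, fs: float, ms: float) -> np.ndarray:
    """Centered moving average of width ``ms`` milliseconds (>= 1 sample)."""
    w = max(1, int(round(ms * fs / 1000.0)))
    if w <= 1:
        return x.astype(float)
    kernel = np.ones(w) / w
    return np.convolve(x, kernel, mode="same")


def detect_r_peaks(signal: np.ndarray, fs: float,
                   min_rr_s: float = 0.25,
                   height_frac: float = 0.4) -> list[int]:
    """Naive R-peak detector for unannotated (synthetic) records.

    Peaks of the rectified, baseline-removed signal above ``height_frac`` of
    the global maximum, separated by at least ``min_rr_s``.
    """
    x = np.abs(np.asarray(signal, dtype=float) - np.median(signal))
    if x.max() == 0:
        return []
    peaks, _ = find_peaks(x, height=height_frac * x.max(),
                          distance=max(1, int(min_rr_s * fs)))
    return peaks.tolist()


def detect_p_wave(triad: BeatTriad,
                  config: PWaveConfig | None = None) -> dict:
    """Look for a P wave in the PR window before the main R peak.

    Present iff a local maximum with prominence >= ``amplitude_frac`` of the
    R amplitude exists in ``[r_main - window_s[0], r_main - window_s[1]]``.
    """
    config = config or PWaveConfig()
    fs = triad.fs
    lo = triad.r_main - int(round(config.window_s[0] * fs))
    hi = triad.r_main - int(round(config.window_s[1] * fs))
    clipped = lo < 0
    lo = max(lo, 0)
    if hi <= lo + 2:
        return {"present": False, "amplitude": 0.0, "position": None,
                "window_clipped": True}
    window = _smooth(triad.signal, fs, config.smooth_ms)[lo:hi]
    baseline = float(np.median(window))
    r_amp = abs(float(triad.signal[triad.r_main]) - baseline)
    if r_amp <= 0:
        return {"present": False, "amplitude": 0.0, "position": None,
                "window_clipped": clipped}
    peaks, props = find_peaks(window - baseline,
                              prominence=config.amplitude_frac * r_amp)
    if len(peaks) == 0:
        return {"present": False, "amplitude": 0.0, "position": None,
                "window_clipped": clipped}
    best = int(np.argmax(props["prominences"]))
    return {
        "present": True,
        "amplitude": float(window[peaks[best]] - baseline),
        "position": int(lo + peaks[best]),
        "window_clipped": clipped,
    }


def qrs_duration(triad: BeatTriad, config: QrsConfig | None = None) -> dict:
    """QRS width by threshold crossing on the smoothed rectified signal.

    Onset (offset) is the first sample before (after) the R peak where the
    smoothed envelope drops below ``threshold_frac`` of the R envelope
    amplitude, searched within ``window_s`` of the peak.  Thresholds are
    relative, so the measurement is invariant to amplitude scaling.
    """
    config = config or QrsConfig()
    fs = triad.fs
    half = int(round(config.window_s * fs))
    lo = max(0, triad.r_main - half)
    hi = min(len(triad.signal), triad.r_main + half + 1)
    segment = triad.signal[lo:hi]
    # smooth the signed signal first so zero-mean noise averages out, then
    # rectify around the local baseline
    smoothed = _smooth(segment, fs, config.smooth_ms)
    baseline = float(np.median(smoothed))
    env = np.abs(smoothed - baseline)
    center = triad.r_main - lo
    amp = float(env[center])
    if amp <= 0:
        raise ValueError("flat signal at the R peak; QRS duration undefined")
    thr = config.threshold_frac * amp

    below_left = np.nonzero(env[:center] < thr)[0]
    below_right = np.nonzero(env[center + 1:] < thr)[0]
    if len(below_left) == 0 or len(below_right) == 0:
        raise ValueError(
            f"QRS onset/offset not found within +-{config.window_s * 1000:.0f} ms "
            f"of the R peak"
        )
    onset = int(below_left[-1]) + 1
    offset = center + 1 + int(below_right[0]) - 1
    qrs_ms = (offset - onset) / fs * 1000.0
    return {"qrs_ms": float(qrs_ms), "qrs_wide": bool(qrs_ms >= config.wide_ms)}


def compensatory_pause(rr_prev_s: float, rr_next_s: float, rr_n_s: float,
                       tolerance_s: float) -> dict:
    """Full compensatory pause: |2*RRn - (RRprev + RRnext)| < tolerance.

    The inequality is strict, so ``tolerance_s = 0`` never declares a full
    pause.
    """
    for name, v in (("rr_prev_s", rr_prev_s), ("rr_next_s", rr_next_s),
                    ("rr_n_s", rr_n_s)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    if tolerance_s < 0:
        raise ValueError(f"tolerance must be nonnegative, got {tolerance_s}")
    deficit = abs(2.0 * rr_n_s - (rr_prev_s + rr_next_s))
    return {"full": bool(deficit < tolerance_s), "deficit_s": float(deficit)}


def mean_rr(r_peaks: Sequence[int], fs: float) -> float:
    """Mean RR interval (seconds) over successive R peaks."""
    peaks = np.asarray(r_peaks, dtype=float)
    if len(peaks) < 2:
        raise ValueError("need at least 2 R peaks to measure an RR interval")
    return float(np.mean(np.diff(peaks)) / fs)


# ---------------------------------------------------------------------------
# record-level extraction
# ---------------------------------------------------------------------------

def _pause_tolerance(cfg: PauseConfig, rr_n_s: float) -> float:
    if cfg.tolerance_mode == "relative":
        return cfg.tolerance_value * 2.0 * rr_n_s
    if cfg.tolerance_mode == "absolute":
        return cfg.tolerance_value
    raise ValueError(f"unknown tolerance_mode {cfg.tolerance_mode!r}")


def _normal_rr_mean(r_peaks: Sequence[int], classes: Sequence[str],
                    fs: float) -> float:
    """Mean RR over *consecutive pairs of normal beats* (RRn)."""
    intervals = [
        (r_peaks[i + 1] - r_peaks[i]) / fs
        for i in range(len(r_peaks) - 1)
        if classes[i] == "normal" and classes[i + 1] == "normal"
    ]
    if not intervals:
        raise ValueError(
            "no consecutive normal-beat pairs; cannot estimate the normal "
            "RR interval"
        )
    return float(np.mean(intervals))


def _beat_features_pass(record: EcgRecord, classes: list[str],
                        rr_n: float, config: EcgConfig) -> list[BeatFeatures]:
    feats = []
    r = record.r_peaks
    tol = _pause_tolerance(config.pause, rr_n)
    for i in range(1, len(r) - 1):
        triad = BeatTriad(record.signal, record.fs, r[i - 1], r[i], r[i + 1],
                          label=classes[i])
        rr_prev = (r[i] - r[i - 1]) / record.fs
        rr_next = (r[i + 1] - r[i]) / record.fs
        p = detect_p_wave(triad, config.pwave)
        q = qrs_duration(triad, config.qrs)
        is_extra = classes[i] != "normal"
        next_extra = classes[i + 1] != "normal"
        if is_extra and next_extra:
            # run of extrasystoles: only the last one has a readable pause
            pause = "not_evaluated"
        else:
            pause = "full" if compensatory_pause(rr_prev, rr_next, rr_n,
                                                 tol)["full"] else "not_full"
        feats.append(BeatFeatures(
            p_absent=not p["present"], qrs_ms=q["qrs_ms"],
            qrs_wide=q["qrs_wide"], comp_pause=pause,
            rr_prev_s=rr_prev, rr_next_s=rr_next, rr_n_s=rr_n,
        ))
    return feats


def extract_beat_features(record: EcgRecord,
                          config: EcgConfig | None = None,
                          allow_detection: bool = True) -> FeatureMatrix:
    """Build the expert feature matrix B: one row per interior beat.

    Columns: ``p_absent`` (0/1), ``qrs_ms``, ``qrs_wide`` (0/1),
    ``comp_pause_full`` (1 full / 0 not full / 0.5 not evaluated),
    ``rr_prev_s``, ``rr_next_s``.  The first and last annotated beats have no
    complete triad and are skipped; row order follows beat order so the
    output pairs with a latent matrix over the same beats.

    When the record has no beat labels, a two-pass scheme is used: a first
    pass with RRn over all beats tags PVC-like beats, and RRn is then
    re-estimated over the remaining (presumed normal) beats.
    """
    config = config or EcgConfig()
    if record.r_peaks is None:
        if not allow_detection:
            raise ValueError("record has no R-peak annotations and detection "
                             "is disabled")
        record = EcgRecord(record.signal, record.fs,
                           r_peaks=detect_r_peaks(record.signal, record.fs),
                           labels=record.labels)
    r = record.r_peaks
    if len(r) < 3:
        return FeatureMatrix(values=np.empty((0, len(BEAT_FEATURE_COLUMNS))),
                             sample_ids=[], feature_names=BEAT_FEATURE_COLUMNS,
                             source="expert")

    if record.labels is not None:
        classes = [config.symbol_map.get(sym, "other") for sym in record.labels]
        rr_n = _normal_rr_mean(r, classes, record.fs)
        feats = _beat_features_pass(record, classes, rr_n, config)
    else:
        # two-pass: provisional RRn over all beats, classify, re-estimate
        provisional = [ "normal" ] * len(r)
        rr_n0 = mean_rr(r, record.fs)
        first = _beat_features_pass(record, provisional, rr_n0, config)
        classes = ["normal"]
        classes += ["pvc" if classify_pvc(f) == "PVC" else "normal"
                    for f in first]
        classes.append("normal")
        rr_n = _normal_rr_mean(r, classes, record.fs)
        feats = _beat_features_pass(record, classes, rr_n, config)

    values = np.array([[f.as_row()[c] for c in BEAT_FEATURE_COLUMNS]
                       for f in feats])
    ids = [f"beat{i}" for i in range(1, len(r) - 1)]
    return FeatureMatrix(values=values, sample_ids=ids,
                         feature_names=BEAT_FEATURE_COLUMNS, source="expert")


def default_pvc_rule() -> IntervalRule:
    """PVC iff: P wave absent AND QRS >= 120 ms AND pause full-or-unevaluated.

    Operates on the numeric encoding of :data:`BEAT_FEATURE_COLUMNS`; the
    0.5 lower bound on ``comp_pause_full`` admits both ``full`` (1) and
    ``not_evaluated`` (0.5) — a run-interior extrasystole is exempt from the
    pause criterion — while ``not_full`` (0) fails it.
    """
    return IntervalRule(
        conditions={
            "p_absent": Interval(low=0.5),
            "qrs_ms": Interval(low=120.0),
            "comp_pause_full": Interval(low=0.5),
        },
        positive_class="PVC", negative_class="not_PVC",
    )


def classify_pvc(features: BeatFeatures | Mapping[str, float],
                 rule: IntervalRule | None = None) -> str:
    """Apply the expert interval rule to one beat's feature row."""
    rule = rule or default_pvc_rule()
    row = features.as_row() if isinstance(features, BeatFeatures) else features
    return rule.decide(row)
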