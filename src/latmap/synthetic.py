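"""Synthetic inputs with analytic ground truth for every pipeline stage.

Three generators, all pure functions of their spec (seed included):

* :func:`gen_latent_pair` — paired latent/expert feature matrices with a
  known linear (or mildly nonlinear) link, emulating a network's
  penultimate-layer activations over class-clustered interpretable features.
* :func:`gen_ecg_triads` — single-lead ECG rhythm strips built from Gaussian
  bumps (P, QRS, T per beat) with PVC morphology planted exactly: absent
  P wave, QRS width >= 120 ms, and timing with a full compensatory pause
  (RRprev + RRnext = 2 x RRn).
* :func:`gen_cardiac_phantom` — ED/ES label volumes whose structures are
  digitized cylinders/ellipsoids with analytically known volumes, ejection
  fractions, and wall thicknesses.

The planted QRS width is defined as the full width of the R bump at 15% of
its peak amplitude — the same definition the duration measurement uses — so
``sigma = width / (2 * sqrt(2 * ln(1/0.15)))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ecg import BeatTriad, EcgRecord
from .matrices import FeatureMatrix
from .mri import CardiacStudy, DEFAULT_LABEL_MAP

__all__ = [
    "LatentPairSpec", "EcgSimSpec", "PhantomSpec",
    "gen_latent_pair", "gen_ecg_triads", "gen_cardiac_phantom",
    "lv_radius_for_volume", "center_split_rule",
]

# full width of a Gaussian at 15% of peak: w = 2*sqrt(2*ln(1/0.15)) * sigma
WIDTH_AT_15PCT = 2.0 * np.sqrt(2.0 * np.log(1.0 / 0.15))


# ---------------------------------------------------------------------------
# paired latent/expert matrices
# ---------------------------------------------------------------------------

@dataclass
class LatentPairSpec:
    m: int = 500
    k: int = 64
    l: int = 6
    link: str = "linear"          # or "linear_plus_tanh"
    noise_sd: float = 0.1
    cluster_count: int = 2
    seed: int = 0
    cluster_sep: float = 3.0      # scale of class-center spread
    within_sd: float = 0.5        # within-class spread of expert features

    def validate(self) -> None:
        if min(self.m, self.k, self.l, self.cluster_count) < 1:
            raise ValueError("m, k, l and cluster_count must all be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.link not in ("linear", "linear_plus_tanh"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.link == "linear" and self.k < self.l:
            raise ValueError(
                f"k ({self.k}) must be >= l ({self.l}) for a linear link: "
                "the random expansion must not lose rank"
            )


def gen_latent_pair(spec: LatentPairSpec) -> dict:
    """Paired (A, B) with B exactly recoverable from A when noise is zero.

    Expert rows B sit around class-specific centers; latent rows are a
    random full-rank expansion ``A = B W_r + noise`` (optionally passed
    through a mild tanh mix).  ``W_true = pinv(W_r)`` (k x l) is the exact
    minimum-norm map A -> B in the noise-free linear case.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    centers = rng.normal(size=(spec.cluster_count, spec.l)) * spec.cluster_sep
    # balanced classes, order shuffled reproducibly
    labels = np.arange(spec.m) % spec.cluster_count
    rng.shuffle(labels)
    B = centers[labels] + rng.normal(scale=spec.within_sd,
                                     size=(spec.m, spec.l))
    W_r = rng.normal(size=(spec.l, spec.k)) / np.sqrt(spec.l)
    Z = B @ W_r
    if spec.link == "linear_plus_tanh":
        Z = 0.7 * Z + 0.3 * np.tanh(Z)
    A = Z + rng.normal(scale=spec.noise_sd, size=(spec.m, spec.k)) \
        if spec.noise_sd > 0 else Z
    ids = [f"s{i:05d}" for i in range(spec.m)]
    return {
        "A": FeatureMatrix(A, sample_ids=ids,
                           feature_names=[f"z{j}" for j in range(spec.k)],
                           source="latent"),
        "B": FeatureMatrix(B, sample_ids=ids,
                           feature_names=[f"e{j}" for j in range(spec.l)],
                           source="expert"),
        "W_true": np.linalg.pinv(W_r),
        "W_r": W_r,
        "labels": np.array([f"c{c}" for c in labels]),
        "centers": centers,
    }


def center_split_rule(centers: np.ndarray, feature_names: Sequence[str]):
    """Expert-style interval rule separating the first two cluster centers.

    Thresholds the single expert feature with the widest center separation
    at the midpoint between the two centers — the synthetic analogue of an
    expert picking the most discriminative feature and its clinical cutoff.
    Positive class is ``"c1"``-side of the midpoint.
    """
    from .rules import Interval, IntervalRule

    if centers.shape[0] < 2:
        raise ValueError("need at least two cluster centers")
    gaps = np.abs(centers[1] - centers[0])
    j = int(np.argmax(gaps))
    mid = 0.5 * (centers[0, j] + centers[1, j])
    if centers[1, j] >= centers[0, j]:
        iv = Interval(low=mid, closed_low=False)
    else:
        iv = Interval(high=mid, closed_high=False)
    return IntervalRule(conditions={feature_names[j]: iv},
                        positive_class="c1", negative_class="c0")


# ---------------------------------------------------------------------------
# ECG rhythm strips with planted PVC morphology
# ---------------------------------------------------------------------------

@dataclass
class EcgSimSpec:
    n_normal: int = 10
    n_pvc: int = 5
    fs: float = 360.0
    rr_mean_s: float = 0.8
    pvc_qrs_ms: float = 150.0
    normal_qrs_ms: float = 80.0
    p_amplitude: float = 0.15
    noise_sd: float = 0.05
    seed: int = 0
    coupling: float = 0.8          # PVC prematurity: RRprev = coupling * RRn
    beat_classes: Sequence[str] | None = None  # explicit override, e.g. runs

    def validate(self) -> None:
        if self.n_normal < 0 or self.n_pvc < 0:
            raise ValueError("beat counts must be nonnegative")
        if self.fs < 100:
            raise ValueError(
                f"fs = {self.fs} Hz is too low to resolve QRS morphology "
                "(need >= 100 Hz)"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0 < self.coupling < 1:
            raise ValueError("coupling must lie in (0, 1)")
        if self.pvc_qrs_ms < 120:
            raise ValueError(
                "pvc_qrs_ms must be >= 120 ms (the planted PVC criterion)"
            )


def _beat_sequence(spec: EcgSimSpec) -> list[str]:
    if spec.beat_classes is not None:
        return list(spec.beat_classes)
    if spec.n_pvc == 0:
        return ["normal"] * spec.n_normal
    if spec.n_normal < spec.n_pvc + 1:
        raise ValueError(
            "cannot isolate every PVC between normal beats "
            f"(n_normal={spec.n_normal}, n_pvc={spec.n_pvc}); pass "
            "beat_classes explicitly for runs of extrasystoles"
        )
    # insert each PVC after evenly spaced normals; never first or last
    insert_after = [(j + 1) * spec.n_normal // (spec.n_pvc + 1)
                    for j in range(spec.n_pvc)]
    seq: list[str] = []
    for i in range(spec.n_normal):
        seq.append("normal")
        seq.extend("pvc" for j in insert_after if j == i + 1)
    return seq


def _gaussian(t: np.ndarray, center: float, sigma: float,
              amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def gen_ecg_triads(spec: EcgSimSpec) -> dict:
    """Synthesize a rhythm strip and slice it into beat triads.

    PVC beats have no P bump, a wide R bump (``pvc_qrs_ms``), and premature
    timing with an exactly full compensatory pause: the PVC falls at
    ``coupling * RRn`` after its predecessor and the following normal beat
    at ``2 * RRn`` after it, so RRprev + RRnext = 2 x RRn identically.
    Returns the full record, the triads, and a truth table of every planted
    value.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    classes = _beat_sequence(spec)
    rr = spec.rr_mean_s

    # beat times: normal->normal RRn; ->pvc coupling*RRn; pvc->normal fills
    # the pause to 2*RRn; pvc->pvc repeats the coupling interval (a run)
    times = [0.5]
    for i in range(1, len(classes)):
        if classes[i] == "pvc":
            dt = spec.coupling * rr
        elif classes[i - 1] == "pvc":
            dt = (2.0 - spec.coupling) * rr
        else:
            dt = rr
        times.append(times[-1] + dt)
    times = np.asarray(times)

    duration = times[-1] + 0.6
    n = int(round(duration * spec.fs))
    t = np.arange(n) / spec.fs
    signal = np.zeros(n)
    for tc, cls in zip(times, classes):
        qrs_ms = spec.pvc_qrs_ms if cls == "pvc" else spec.normal_qrs_ms
        sigma_r = qrs_ms / 1000.0 / WIDTH_AT_15PCT
        r_amp = 1.1 if cls == "pvc" else 1.0
        signal += _gaussian(t, tc, sigma_r, r_amp)                 # QRS
        if cls != "pvc" and spec.p_amplitude > 0:
            signal += _gaussian(t, tc - 0.16, 0.025, spec.p_amplitude)  # P
        signal += _gaussian(t, tc + 0.25, 0.04, 0.25)              # T
    if spec.noise_sd > 0:
        signal = signal + rng.normal(scale=spec.noise_sd, size=n)

    r_peaks = [int(round(tc * spec.fs)) for tc in times]
    record = EcgRecord(signal=signal, fs=spec.fs, r_peaks=r_peaks,
                       labels=list(classes))

    triads, rows = [], []
    for i in range(1, len(classes) - 1):
        triads.append(BeatTriad(signal, spec.fs, r_peaks[i - 1], r_peaks[i],
                                r_peaks[i + 1], label=classes[i]))
        rr_prev = times[i] - times[i - 1]
        rr_next = times[i + 1] - times[i]
        rows.append({
            "beat": i,
            "label": classes[i],
            "qrs_ms": spec.pvc_qrs_ms if classes[i] == "pvc"
                      else spec.normal_qrs_ms,
            "p_amplitude": 0.0 if classes[i] == "pvc" else spec.p_amplitude,
            "rr_prev_s": rr_prev,
            "rr_next_s": rr_next,
            "rr_n_s": rr,
            "in_run": classes[i] == "pvc" and classes[i + 1] == "pvc",
        })
    truth = pd.DataFrame(rows)
    return {"record": record, "triads": triads, "truth": truth}


# ---------------------------------------------------------------------------
# cardiac mask phantoms
# ---------------------------------------------------------------------------

def lv_radius_for_volume(vol_ml: float, height_mm: float) -> float:
    """Cylinder radius (mm) whose volume over ``height_mm`` equals ``vol_ml``."""
    return float(np.sqrt(vol_ml * 1000.0 / (np.pi * height_mm)))


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (192, 128, 10)
    spacing: tuple[float, float, float] = (1.0, 1.0, 8.0)
    lv_radius_ed: float = 24.43   # -> ~150 mL over the default 80 mm stack
    lv_radius_es: float = 15.45   # -> ~60 mL
    wall_thickness: float | Sequence[float] = 10.0  # scalar or per slice
    rv_volume_target_ml: float = 120.0
    rv_es_fraction: float = 0.5   # RV ESV as a fraction of its EDV
    seed: int = 0

    def wall_per_slice(self) -> np.ndarray:
        nz = self.shape[2]
        w = np.broadcast_to(np.asarray(self.wall_thickness, dtype=float),
                            (nz,)).copy() \
            if np.ndim(self.wall_thickness) == 0 \
            else np.asarray(self.wall_thickness, dtype=float)
        if w.shape != (nz,):
            raise ValueError(
                f"wall_thickness must be scalar or length {nz}, got shape {w.shape}"
            )
        return w

    def validate(self) -> None:
        if self.lv_radius_ed <= 0 or self.lv_radius_es <= 0:
            raise ValueError("LV radii must be positive")
        if np.any(self.wall_per_slice() <= 0):
            raise ValueError("wall_thickness must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.rv_volume_target_ml <= 0:
            raise ValueError("rv_volume_target_ml must be positive")


def _digitize_phase(spec: PhantomSpec, lv_radius: float,
                    rv_vol_ml: float) -> np.ndarray:
    nx, ny, nz = spec.shape
    dx, dy, dz = spec.spacing
    wall = spec.wall_per_slice()
    # voxel-center coordinates in mm
    x = (np.arange(nx) + 0.5) * dx
    y = (np.arange(ny) + 0.5) * dy
    xx, yy = np.meshgrid(x, y, indexing="ij")

    lv_cx, lv_cy = 0.22 * nx * dx, 0.5 * ny * dy
    r_lv_outer = lv_radius + wall.max()
    # RV: ellipsoid east of the LV, never overlapping the outer LV ring
    c_z = 0.4 * nz * dz
    a = np.sqrt(3.0 * rv_vol_ml * 1000.0 / (4.0 * np.pi * c_z))
    rv_cx = lv_cx + r_lv_outer + a + 3.0
    rv_cy = lv_cy
    rv_cz = 0.5 * nz * dz
    if rv_cx + a > nx * dx or lv_cx - r_lv_outer < 0 \
            or lv_cy + r_lv_outer > ny * dy or rv_cy + a > ny * dy:
        raise ValueError("phantom structures do not fit inside the volume")

    vol = np.zeros(spec.shape, dtype=np.int16)
    r2 = (xx - lv_cx) ** 2 + (yy - lv_cy) ** 2
    z_centers = (np.arange(nz) + 0.5) * dz
    for z in range(nz):
        cavity = r2 <= lv_radius ** 2
        annulus = (r2 <= (lv_radius + wall[z]) ** 2) & ~cavity
        sl = vol[:, :, z]
        sl[cavity] = DEFAULT_LABEL_MAP["lv_cavity"]
        sl[annulus] = DEFAULT_LABEL_MAP["myocardium"]
        rv = ((xx - rv_cx) ** 2 / a ** 2 + (yy - rv_cy) ** 2 / a ** 2
              + (z_centers[z] - rv_cz) ** 2 / c_z ** 2) <= 1.0
        if np.any(rv & (sl > 0)):
            raise ValueError("RV ellipsoid overlaps the LV structures")
        sl[rv] = DEFAULT_LABEL_MAP["rv_cavity"]
    return vol


def gen_cardiac_phantom(spec: PhantomSpec) -> dict:
    """Digitized ED/ES study plus the analytic truth of every feature."""
    spec.validate()
    rv_ed_ml = spec.rv_volume_target_ml
    rv_es_ml = spec.rv_es_fraction * rv_ed_ml
    ed = _digitize_phase(spec, spec.lv_radius_ed, rv_ed_ml)
    es = _digitize_phase(spec, spec.lv_radius_es, rv_es_ml)
    study = CardiacStudy(ed_mask=ed, es_mask=es, spacing=spec.spacing,
                         study_id=f"phantom{spec.seed}")

    height = spec.shape[2] * spec.spacing[2]
    wall = spec.wall_per_slice()
    dz = spec.spacing[2]

    def cyl(r: float) -> float:
        return float(np.pi * r ** 2 * height / 1000.0)

    def shell(r: float) -> float:
        return float(np.sum(np.pi * ((r + wall) ** 2 - r ** 2) * dz) / 1000.0)

    lv_ed_ml, lv_es_ml = cyl(spec.lv_radius_ed), cyl(spec.lv_radius_es)
    truth = {
        "lv_vol_ed_ml": lv_ed_ml,
        "lv_vol_es_ml": lv_es_ml,
        "rv_vol_ed_ml": rv_ed_ml,
        "rv_vol_es_ml": rv_es_ml,
        "myo_vol_ed_ml": shell(spec.lv_radius_ed),
        "myo_vol_es_ml": shell(spec.lv_radius_es),
        "lv_ef_pct": (lv_ed_ml - lv_es_ml) / lv_ed_ml * 100.0,
        "rv_ef_pct": (rv_ed_ml - rv_es_ml) / rv_ed_ml * 100.0,
        "wall_thickness_per_slice_mm": wall,
    }
    return {"study": study, "truth": truth}
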