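r"""Transition-matrix fitting between latent and expert feature spaces.

Given a latent feature matrix :math:`A` (m samples x k latent features) and an
expert feature matrix :math:`B` (m x l interpretable features) over the *same*
samples, the transition matrix :math:`T` is the k x l least-squares solution of

.. math:: A T \approx B, \qquad T = A^{+} B,

where :math:`A^{+}` is the Moore–Penrose pseudo-inverse computed from the SVD
:math:`A = U \Sigma V^{T}` by inverting the retained singular values and
zeroing the rest.  A new latent row vector ``a`` is then translated into the
interpretable space as ``b = a @ T`` (row-vector, right-multiplication
convention throughout).

The pseudo-inverse construction is implemented here directly from the SVD
factors — it is the core primitive of the package, and ``T`` is formed as
``V_r @ (U_r.T @ B / s_r)`` without ever materializing the dense k x m
pseudo-inverse when only the fit is needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .matrices import FeatureMatrix

__all__ = [
    "SvdPseudoInverse",
    "TransitionMatrix",
    "pseudo_inverse",
    "fit_transition",
    "map_features",
    "reconstruction_error",
]


def _default_rcond(shape: tuple[int, int]) -> float:
    # cutoff = rcond * sigma_1 with rcond = max(m, k) * machine epsilon
    return max(shape) * np.finfo(float).eps


@dataclass
class SvdPseudoInverse:
    """Moore–Penrose pseudo-inverse of a feature matrix, with SVD diagnostics.

    ``A_plus`` is k x m for an m x k input.  ``singular_values`` are
    nonincreasing; ``kept_mask[i]`` marks sigma_i treated as nonzero
    (sigma_i > cutoff); the rest are mapped to zero in the inversion,
    the finite-precision reading of the "invert nonzero singular values"
    rule.
    """

    A_plus: np.ndarray
    singular_values: np.ndarray
    kept_mask: np.ndarray
    rcond: float
    cutoff: float

    @property
    def effective_rank(self) -> int:
        return int(self.kept_mask.sum())


def _svd_of(A: FeatureMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    values = A.values if isinstance(A, FeatureMatrix) else np.asarray(A, dtype=float)
    if values.ndim != 2 or values.size == 0:
        raise ValueError(f"need a nonempty 2-D matrix, got shape {values.shape}")
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(f"non-finite entry at row {bad[0]}, column {bad[1]}")
    U, s, Vt = np.linalg.svd(values, full_matrices=False)
    return U, s, Vt


def pseudo_inverse(A: FeatureMatrix | np.ndarray,
                   rcond: float | None = None) -> SvdPseudoInverse:
    """Compute A+ = V Sigma+ U^T with small singular values zeroed.

    Parameters
    ----------
    A
        m x k matrix (or FeatureMatrix).
    rcond
        Relative cutoff: singular values <= ``rcond * sigma_1`` are treated
        as zero.  ``None`` selects ``max(m, k) * eps``.
    """
    U, s, Vt = _svd_of(A)
    m_k = (U.shape[0], Vt.shape[1])
    if rcond is None:
        rcond = _default_rcond(m_k)
    if rcond < 0:
        raise ValueError(f"rcond must be nonnegative, got {rcond}")
    cutoff = rcond * (s[0] if s.size else 0.0)
    kept = s > cutoff
    s_inv = np.where(kept, 1.0 / np.where(kept, s, 1.0), 0.0)
    A_plus = (Vt.T * s_inv) @ U.T
    return SvdPseudoInverse(A_plus=A_plus, singular_values=s,
                            kept_mask=kept, rcond=float(rcond),
                            cutoff=float(cutoff))


@dataclass
class TransitionMatrix:
    """The fitted k x l latent-to-expert map with fit diagnostics."""

    T: np.ndarray
    k: int
    l: int
    residual_frobenius: float
    effective_rank: int
    rcond: float
    expert_feature_names: list[str] = field(default_factory=list)
    # optional column standardization (off by default): stored moments
    standardize: bool = False
    a_mean: np.ndarray | None = None
    a_scale: np.ndarray | None = None
    b_mean: np.ndarray | None = None
    b_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        if self.T.shape != (self.k, self.l):
            raise ValueError(
                f"T has shape {self.T.shape}, expected ({self.k}, {self.l})"
            )
        if self.residual_frobenius < 0:
            raise ValueError("residual_frobenius must be nonnegative")

    # ------------------------------------------------------------------ I/O
    def save(self, path: str | Path) -> None:
        """NPY matrix + JSON sidecar with the metadata."""
        path = Path(path)
        np.save(path, self.T)
        meta = {
            "k": self.k,
            "l": self.l,
            "residual_frobenius": self.residual_frobenius,
            "effective_rank": self.effective_rank,
            "rcond": self.rcond,
            "expert_feature_names": self.expert_feature_names,
            "standardize": self.standardize,
        }
        if self.standardize:
            meta.update({
                "a_mean": self.a_mean.tolist(), "a_scale": self.a_scale.tolist(),
                "b_mean": self.b_mean.tolist(), "b_scale": self.b_scale.tolist(),
            })
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TransitionMatrix":
        path = Path(path)
        T = np.load(path if path.suffix == ".npy" else path.with_suffix(".npy"))
        meta = json.loads(path.with_suffix(".json").read_text())
        kwargs = {}
        if meta.get("standardize"):
            kwargs = {k: np.asarray(meta[k], dtype=float)
                      for k in ("a_mean", "a_scale", "b_mean", "b_scale")}
        return cls(T=T, k=meta["k"], l=meta["l"],
                   residual_frobenius=meta["residual_frobenius"],
                   effective_rank=meta["effective_rank"], rcond=meta["rcond"],
                   expert_feature_names=meta.get("expert_feature_names", []),
                   standardize=bool(meta.get("standardize", False)), **kwargs)


def _standardize_moments(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)  # constant columns pass through
    return mean, scale


def fit_transition(A: FeatureMatrix, B: FeatureMatrix,
                   rcond: float | None = None,
                   standardize: bool = False) -> TransitionMatrix:
    """Fit T = A+ B, the Frobenius-optimal linear map from A-rows to B-rows.

    ``A`` and ``B`` must be paired (identical sample ids, identical order):
    both matrices must describe the same samples.  With ``standardize=True``
    both matrices are z-scored column-wise before the fit and the stored
    moments are re-applied by :func:`map_features`; latent and expert
    features often live on incommensurate scales.
    """
    A.require_paired(B)
    Av, Bv = A.values, B.values

    a_mean = a_scale = b_mean = b_scale = None
    if standardize:
        a_mean, a_scale = _standardize_moments(Av)
        b_mean, b_scale = _standardize_moments(Bv)
        Av = (Av - a_mean) / a_scale
        Bv = (Bv - b_mean) / b_scale

    U, s, Vt = _svd_of(Av)
    if rcond is None:
        rcond = _default_rcond(Av.shape)
    cutoff = rcond * (s[0] if s.size else 0.0)
    kept = s > cutoff
    # T = V_r diag(1/s_r) U_r^T B without materializing the k x m pseudo-inverse
    Ur = U[:, kept]
    Vr = Vt[kept].T
    T = Vr @ ((Ur.T @ Bv) / s[kept, None]) if kept.any() \
        else np.zeros((Av.shape[1], Bv.shape[1]))

    residual = float(np.linalg.norm(Av @ T - Bv, ord="fro"))
    return TransitionMatrix(
        T=T, k=Av.shape[1], l=Bv.shape[1],
        residual_frobenius=residual, effective_rank=int(kept.sum()),
        rcond=float(rcond), expert_feature_names=list(B.feature_names),
        standardize=standardize, a_mean=a_mean, a_scale=a_scale,
        b_mean=b_mean, b_scale=b_scale,
    )


def map_features(a: np.ndarray, T: TransitionMatrix) -> np.ndarray:
    """Translate latent row vector(s) ``a`` into expert features: b = a @ T."""
    a = np.asarray(a, dtype=float)
    single = a.ndim == 1
    a2 = np.atleast_2d(a)
    if a2.shape[1] != T.k:
        raise ValueError(
            f"latent vector has length {a2.shape[1]}, expected k = {T.k}"
        )
    if T.standardize:
        b = ((a2 - T.a_mean) / T.a_scale) @ T.T * T.b_scale + T.b_mean
    else:
        b = a2 @ T.T
    return b[0] if single else b


def reconstruction_error(A: FeatureMatrix, B: FeatureMatrix,
                         T: TransitionMatrix) -> dict:
    """Residual of the fitted approximation A T ~= B.

    Returns the Frobenius norm of ``A T - B`` and the per-sample Euclidean
    residual ``||a_i T - b_i||_2`` (both in the original feature units, also
    when the fit standardized internally).
    """
    A.require_paired(B)
    if A.n_features != T.k or B.n_features != T.l:
        raise ValueError(
            f"shape mismatch: A is m x {A.n_features}, B is m x {B.n_features}, "
            f"T is {T.k} x {T.l}"
        )
    diff = map_features(A.values, T) - B.values
    per_sample = np.linalg.norm(diff, axis=1)
    return {
        "frobenius": float(np.linalg.norm(diff, ord="fro")),
        "per_sample_euclidean": per_sample,
    }
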