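"""Visual-analytics alignment check before fitting the transition matrix.

Latent and expert feature rows are projected to 2–3 dimensions (exact PCA,
or seeded t-SNE) and the class structure of the two projections is compared:
per-embedding silhouette over the class labels, plus the orthogonal
Procrustes disparity between the two point clouds after centering and
scaling.  The report is advisory — concordant cluster structure supports
the assumption that a linear map between the spaces exists, but nothing
here blocks the fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import procrustes as _procrustes
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .matrices import FeatureMatrix

__all__ = ["EmbeddingResult", "embed", "alignment_report"]


@dataclass
class EmbeddingResult:
    coords: np.ndarray
    method: str
    explained_variance: np.ndarray | None = None  # pca only
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.coords.shape[1] not in (2, 3):
            raise ValueError("embedding dimension must be 2 or 3")


def _fix_signs(coords: np.ndarray, components: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|loading| positive per axis."""
    flips = np.ones(components.shape[0])
    for i, comp in enumerate(components):
        j = int(np.argmax(np.abs(comp)))
        if comp[j] < 0:
            flips[i] = -1.0
    return coords * flips


def embed(X: FeatureMatrix, method: str = "pca", d: int = 2,
          seed: int | None = None, **params) -> EmbeddingResult:
    """Project feature rows to ``d`` in {2, 3} dimensions.

    PCA is the exact eigendecomposition of the column-centered covariance
    (deterministic up to the fixed sign convention); t-SNE is stochastic and
    requires ``seed``.
    """
    if d not in (2, 3):
        raise ValueError("d must be 2 or 3")
    if X.n_samples < d + 1:
        raise ValueError(f"need at least {d + 1} samples to embed into {d}-D")
    if method == "pca":
        if X.n_features < d:
            raise ValueError(
                f"cannot extract {d} principal components from "
                f"{X.n_features} feature column(s)"
            )
        if np.allclose(X.values.std(axis=0), 0):
            raise ValueError("constant matrix: PCA undefined (zero variance)")
        pca = PCA(n_components=d, svd_solver="full")
        coords = pca.fit_transform(X.values)
        coords = _fix_signs(coords, pca.components_)
        return EmbeddingResult(coords=coords, method="pca",
                               explained_variance=pca.explained_variance_ratio_,
                               params={"d": d})
    if method == "tsne":
        if seed is None:
            raise ValueError("t-SNE is stochastic: a seed is required")
        perplexity = params.pop("perplexity", min(30.0, (X.n_samples - 1) / 3))
        tsne = TSNE(n_components=d, random_state=seed, perplexity=perplexity,
                    init="pca", **params)
        coords = tsne.fit_transform(X.values)
        return EmbeddingResult(coords=coords, method="tsne",
                               params={"d": d, "perplexity": perplexity,
                                       "seed": seed})
    raise ValueError(f"unknown embedding method {method!r}")


def alignment_report(embA: EmbeddingResult, embB: EmbeddingResult,
                     labels, out_json: str | Path | None = None,
                     out_figure: str | Path | None = None) -> dict:
    """Quantify whether the two embeddings show concordant class structure.

    Silhouette (per embedding, over ``labels``) measures class separation;
    Procrustes disparity (similarity-invariant) measures how well one point
    cloud matches the other after optimal rotation/translation/scaling.
    """
    labels = np.asarray(labels)
    if len(labels) != embA.coords.shape[0] or len(labels) != embB.coords.shape[0]:
        raise ValueError("labels must match the number of embedded samples")
    if embA.coords.shape != embB.coords.shape:
        raise ValueError("embeddings must have the same shape for comparison")
    report: dict = {"n": int(len(labels))}
    if len(np.unique(labels)) < 2:
        report["silhouette_A"] = None
        report["silhouette_B"] = None
        report["silhouette_note"] = "single class: silhouette undefined"
    else:
        report["silhouette_A"] = float(silhouette_score(embA.coords, labels))
        report["silhouette_B"] = float(silhouette_score(embB.coords, labels))
    _, _, disparity = _procrustes(embA.coords, embB.coords)
    report["procrustes_disparity"] = float(disparity)

    if out_figure is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        for ax, emb, title in ((axes[0], embA, "latent (A)"),
                               (axes[1], embB, "expert (B)")):
            for cls in np.unique(labels):
                sel = labels == cls
                ax.scatter(emb.coords[sel, 0], emb.coords[sel, 1], s=8,
                           label=str(cls))
            ax.set_title(f"{title} [{emb.method}]")
            ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out_figure, dpi=120)
        plt.close(fig)
        report["figure"] = str(out_figure)
    if out_json is not None:
        Path(out_json).write_text(json.dumps(report, indent=1))
    return report
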