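r"""Cohen's kappa agreement between two label sequences.

Kappa corrects observed agreement :math:`P_o` for the agreement
:math:`P_e` expected from the raters' marginal label frequencies:

.. math:: \kappa = \frac{P_o - P_e}{1 - P_e}

with :math:`P_o = \mathrm{trace}(C)/N` and
:math:`P_e = \sum_i r_i c_i / N^2` for a K x K confusion matrix :math:`C`
with row/column marginals :math:`r_i, c_i`.  For K = 2 these reduce to the
familiar (TP+TN)/N and ((TP+FP)(TP+FN) + (TN+FN)(TN+FP))/N^2 forms.

The analytic 95% CI uses the Fleiss–Cohen–Everitt large-sample standard
error; the p-value tests H0: kappa = 0 with the null-hypothesis standard
error (two-sided Wald).  A percentile bootstrap over label pairs is
available as an alternative CI for sparse tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "KappaResult",
    "DegenerateAgreementError",
    "confusion",
    "observed_agreement",
    "expected_agreement",
    "cohens_kappa",
    "read_labels_csv",
]


class DegenerateAgreementError(ValueError):
    """Both raters are constant and identical: Pe = 1, kappa undefined."""


@dataclass
class ConfusionMatrix:
    """K x K cross-tabulation; rows = rater 1, columns = rater 2."""

    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError(f"confusion matrix must be square, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if len(self.class_names) != self.counts.shape[0]:
            raise ValueError("class_names length must match matrix size")
        if self.counts.sum() < 1:
            raise ValueError("empty confusion matrix (N = 0)")

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class KappaResult:
    kappa: float
    po: float
    pe: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    se: float
    method: str = "analytic"

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "kappa": self.kappa, "po": self.po, "pe": self.pe,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p_value": self.p_value, "n": self.n, "se": self.se,
            "method": self.method,
        }, indent=1)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def confusion(labels_1: Sequence, labels_2: Sequence,
              classes: Sequence | None = None) -> ConfusionMatrix:
    """Cross-tabulate two equal-length label sequences.

    The class universe is the sorted union of observed labels plus any
    declared ``classes`` (so absent-but-possible classes keep their rows).
    """
    labels_1, labels_2 = list(labels_1), list(labels_2)
    if len(labels_1) != len(labels_2):
        raise ValueError(
            f"label sequences differ in length: {len(labels_1)} vs {len(labels_2)}"
        )
    if not labels_1:
        raise ValueError("need at least one labelled sample")
    universe = set(labels_1) | set(labels_2) | set(classes or [])
    names = sorted(universe, key=str)
    index = {c: i for i, c in enumerate(names)}
    counts = np.zeros((len(names), len(names)), dtype=np.int64)
    for a, b in zip(labels_1, labels_2):
        counts[index[a], index[b]] += 1
    return ConfusionMatrix(counts=counts, class_names=[str(c) for c in names])


def observed_agreement(cm: ConfusionMatrix) -> float:
    """Po: proportion of samples where the two raters agree."""
    return float(np.trace(cm.counts) / cm.n)


def expected_agreement(cm: ConfusionMatrix) -> float:
    """Pe: agreement expected by chance from the marginal distributions."""
    n = cm.n
    rows = cm.counts.sum(axis=1)
    cols = cm.counts.sum(axis=0)
    return float((rows @ cols) / (n * n))


def _analytic_se(cm: ConfusionMatrix, po: float, pe: float) -> float:
    """Fleiss–Cohen–Everitt large-sample SE of kappa-hat."""
    n = cm.n
    p = cm.counts / n
    pr = p.sum(axis=1)  # rater-1 marginals
    pc = p.sum(axis=0)  # rater-2 marginals
    k = (po - pe) / (1.0 - pe)
    diag = np.diag(p)
    term1 = float(np.sum(diag * ((1 - pe) - (pr + pc) * (1 - po)) ** 2))
    # off-diagonal term: sum_{i!=j} p_ij (p_+i + p_j+)^2
    K = p.shape[0]
    term2 = 0.0
    for i in range(K):
        for j in range(K):
            if i != j:
                term2 += p[i, j] * (pc[i] + pr[j]) ** 2
    term2 *= (1 - po) ** 2
    term3 = (po * pe - 2 * pe + po) ** 2
    var = (term1 + term2 - term3) / (n * (1 - pe) ** 4)
    return float(np.sqrt(max(var, 0.0)))


def _null_se(cm: ConfusionMatrix, pe: float) -> float:
    """SE of kappa-hat under H0: kappa = 0 (for the Wald test)."""
    n = cm.n
    p = cm.counts / n
    pr = p.sum(axis=1)
    pc = p.sum(axis=0)
    num = pe + pe ** 2 - float(np.sum(pr * pc * (pr + pc)))
    return float(np.sqrt(max(num, 0.0) / n) / (1 - pe))


def cohens_kappa(cm: ConfusionMatrix, ci_level: float = 0.95,
                 method: str = "analytic", n_boot: int = 2000,
                 seed: int = 0) -> KappaResult:
    """Kappa with CI and two-sided p-value for H0: kappa = 0.

    ``method="analytic"`` (default) uses the large-sample normal CI;
    ``method="bootstrap"`` resamples label pairs (percentile CI, seeded).
    Raises :class:`DegenerateAgreementError` when both raters are constant
    and identical (Pe = 1; chance correction is undefined because the
    marginals leave no room for disagreement).
    """
    if cm.n < 2:
        raise ValueError("kappa needs at least 2 samples")
    po = observed_agreement(cm)
    pe = expected_agreement(cm)
    if pe >= 1.0 - 1e-15:
        raise DegenerateAgreementError(
            "both raters assigned a single identical class to every sample; "
            "Pe = 1 and kappa = (Po-Pe)/(1-Pe) is undefined"
        )
    kappa = (po - pe) / (1.0 - pe)
    se = _analytic_se(cm, po, pe)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)

    if method == "analytic":
        ci_low, ci_high = kappa - z * se, kappa + z * se
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        # reconstruct label pairs from the table and resample with replacement
        pairs = [(i, j) for i in range(len(cm.class_names))
                 for j in range(len(cm.class_names))
                 for _ in range(int(cm.counts[i, j]))]
        pairs_arr = np.asarray(pairs)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, len(pairs_arr), size=len(pairs_arr))
            sample = pairs_arr[idx]
            c = np.zeros_like(cm.counts)
            np.add.at(c, (sample[:, 0], sample[:, 1]), 1)
            tot = c.sum()
            po_b = np.trace(c) / tot
            pe_b = (c.sum(axis=1) @ c.sum(axis=0)) / tot ** 2
            boots[b] = np.nan if pe_b >= 1 else (po_b - pe_b) / (1 - pe_b)
        boots = boots[np.isfinite(boots)]
        alpha = 1 - ci_level
        ci_low, ci_high = np.percentile(boots, [100 * alpha / 2,
                                                100 * (1 - alpha / 2)])
    else:
        raise ValueError(f"unknown CI method {method!r}")

    se0 = _null_se(cm, pe)
    if se0 > 0:
        p_value = float(2 * stats.norm.sf(abs(kappa) / se0))
        p_value = min(max(p_value, np.nextafter(0, 1)), 1.0)
    else:
        p_value = 1.0

    return KappaResult(
        kappa=float(kappa), po=po, pe=pe,
        ci_low=float(np.clip(ci_low, -1.0, 1.0)),
        ci_high=float(np.clip(ci_high, -1.0, 1.0)),
        p_value=p_value, n=cm.n, se=se, method=method,
    )


def read_labels_csv(path: str | Path) -> tuple[list[str], list[str]]:
    """Read a two-column (sample_id, label) CSV; returns (ids, labels)."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns (sample_id, label)")
    return df.iloc[:, 0].tolist(), df.iloc[:, 1].tolist()
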