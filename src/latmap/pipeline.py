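"""End-to-end evaluation: can mapped features replicate expert decisions?

The core fidelity question for a transition matrix is not the numeric
residual but whether *decisions* made from the mapped features agree with
decisions made from the true expert features.  This module runs that
experiment on synthetic data: generate a paired (A, B) sample, fit T on a
training split, translate the held-out latent rows, interval-classify both
the mapped and the true expert rows with the same rule, and report Cohen's
kappa between the two decision sequences.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .agreement import KappaResult, cohens_kappa, confusion
from .synthetic import LatentPairSpec, center_split_rule, gen_latent_pair
from .transition import fit_transition, map_features

__all__ = ["mapped_decision_agreement"]


def mapped_decision_agreement(spec: LatentPairSpec,
                              train_frac: float = 0.8,
                              seed: int | None = None) -> KappaResult:
    """Kappa between decisions from mapped vs true expert features.

    The split is drawn from ``seed`` (defaults to the generator seed); the
    interval rule thresholds the most class-separating expert feature at the
    midpoint between the first two cluster centers.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie in (0, 1)")
    if seed is not None:
        spec = replace(spec, seed=seed)
    res = gen_latent_pair(spec)
    A, B = res["A"], res["B"]
    rng = np.random.default_rng(spec.seed + 1)
    perm = rng.permutation(A.n_samples)
    n_train = int(round(train_frac * A.n_samples))
    train, test = perm[:n_train].tolist(), perm[n_train:].tolist()

    T = fit_transition(A.subset(train), B.subset(train))
    mapped = map_features(A.subset(test).values, T)
    true = B.subset(test).values

    rule = center_split_rule(res["centers"], B.feature_names)
    names = B.feature_names
    dec_true = [rule.decide(dict(zip(names, row))) for row in true]
    dec_mapped = [rule.decide(dict(zip(names, row))) for row in mapped]
    cm = confusion(dec_true, dec_mapped, classes=["c0", "c1"])
    return cohens_kappa(cm)
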