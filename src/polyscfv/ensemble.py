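"""Meta-learning combiners over trained base classifiers.

Two combiners: AVG (unweighted mean of member probabilities) and LR
(intercept-free least-squares stacking on the members' training-set
probabilities, output clipped to [0, 1]).  Member selection follows two
schemes: A-schemes take the top-k of the whole model pool by a ranking
score; B-schemes first keep the best model per descriptor set and then the
top-k of those.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import SelectionError
from .modeling import TrainedModel


@dataclass
class EnsembleModel:
    members: list[TrainedModel]
    combiner: str  # "AVG" | "LR"
    scheme: str
    weights: np.ndarray | None = None
    manifest: dict = field(default_factory=dict)

    def predict_proba_from_members(self, member_probs: np.ndarray) -> np.ndarray:
        return predict(self, member_probs)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        probs = np.column_stack([m.predict_proba(X) for m in self.members])
        return predict(self, probs)


def _parse_scheme(scheme: str) -> tuple[str, int]:
    kind = scheme[0].upper()
    if kind not in ("A", "B") or not scheme[1:].isdigit():
        raise ValueError(f"unknown selection scheme {scheme!r}")
    return kind, int(scheme[1:])


def select_members(
    models: list[TrainedModel],
    scheme: str,
    ranking_scores: list[float],
) -> list[TrainedModel]:
    """Pick ensemble members per the A/B selection schemes.

    A<k>: top-k of the whole pool by ``ranking_scores`` (descending).
    B<k>: the best model of each descriptor set, then the top-k of those.
    Ties break towards the earlier model in the pool.
    """
    if len(models) != len(ranking_scores):
        raise ValueError("models and ranking_scores must align")
    kind, k = _parse_scheme(scheme)
    indexed = list(enumerate(ranking_scores))
    if kind == "A":
        pool = indexed
    else:
        best_per_set: dict[str, tuple[int, float]] = {}
        for i, score in indexed:
            ds = models[i].descriptor_set
            if ds not in best_per_set or score > best_per_set[ds][1]:
                best_per_set[ds] = (i, score)
        pool = sorted(best_per_set.values(), key=lambda t: t[0])
    if k > len(pool):
        raise SelectionError(
            f"scheme {scheme}: k={k} exceeds pool of {len(pool)}"
        )
    ranked = sorted(pool, key=lambda t: (-t[1], t[0]))
    chosen = sorted(i for i, _ in ranked[:k])
    return [models[i] for i in chosen]


def fit_combiner(
    member_probs: np.ndarray,
    y: np.ndarray,
    combiner: str,
    members: list[TrainedModel] | None = None,
    scheme: str = "",
) -> EnsembleModel:
    """Fit an AVG or LR combiner on aligned member probabilities.

    LR solves ``argmin ||P w - y||^2`` with no intercept via least squares
    (minimum-norm solution, with a warning, when P is rank deficient).
    """
    P = np.asarray(member_probs, dtype=float)
    if P.ndim != 2:
        raise ValueError("member probabilities must be (n_rows, n_members)")
    combiner = combiner.upper()
    if combiner == "AVG":
        weights = None
    elif combiner == "LR":
        yv = np.asarray(y, dtype=float)
        weights, _, rank, _ = np.linalg.lstsq(P, yv, rcond=None)
        if rank < P.shape[1]:
            warnings.warn(
                "rank-deficient member probability matrix; "
                "minimum-norm stacking weights returned"
            )
    else:
        raise ValueError(f"combiner must be AVG or LR, got {combiner!r}")
    return EnsembleModel(
        members=list(members or []),
        combiner=combiner,
        scheme=scheme,
        weights=weights,
        manifest={
            "combiner": combiner,
            "scheme": scheme,
            "n_members": P.shape[1],
            "weights": None if weights is None else weights.tolist(),
        },
    )


def predict(ensemble: EnsembleModel, member_probs: np.ndarray) -> np.ndarray:
    """Combine member probabilities: mean (AVG) or clipped weighted sum (LR)."""
    P = np.asarray(member_probs, dtype=float)
    if P.ndim != 2:
        raise ValueError("member probabilities must be (n_rows, n_members)")
    n_expected = (
        len(ensemble.members)
        if ensemble.members
        else ensemble.manifest.get("n_members", P.shape[1])
    )
    if P.shape[1] != n_expected:
        raise ValueError(
            f"expected {n_expected} member columns, got {P.shape[1]}"
        )
    if ensemble.combiner == "AVG":
        return P.mean(axis=1)
    return np.clip(P @ ensemble.weights, 0.0, 1.0)
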