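"""Classical (ipsative) point-assignment scoring of forced-choice responses.

Each binary paired comparison awards points to the traits of the two items
involved, depending on the items' keyed signs and which item was preferred:

====  ====  ==========  ==========
sign  sign  y=1 awards  y=0 awards
i     k     (i, k)      (i, k)
====  ====  ==========  ==========
+     +     (1, 0)      (0, 1)
+     -     (1, 1)      (0, 0)
-     +     (0, 0)      (1, 1)
-     -     (0, 1)      (1, 0)
====  ====  ==========  ==========

Preferring a positively keyed item (or rejecting a negatively keyed one) is
evidence for a high trait value.  With equally keyed items every comparison
awards exactly one point in total, so per-person score totals are constant
(fully ipsative scores); mixed keying breaks that conservation.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .design import QuestionnaireDesign
from .simulate import ResponseData, rank_to_pairwise

__all__ = ["ScoreMatrix", "score_pair", "score_person", "standardize"]


@dataclasses.dataclass(frozen=True)
class ScoreMatrix:
    """Estimated (or true) trait scores, persons x traits."""

    theta: np.ndarray
    method: str  # classical_raw | classical_z | tirt_eap
    posterior_sd: Optional[np.ndarray] = None

    @property
    def n_persons(self) -> int:
        return self.theta.shape[0]

    @property
    def n_traits(self) -> int:
        return self.theta.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.theta, columns=[f"trait_{t}" for t in range(self.n_traits)]
        )
        df.insert(0, "person", np.arange(self.n_persons))
        return df


def score_pair(sign_i: int, sign_k: int, y_ik: int) -> Tuple[int, int]:
    """Points awarded to the traits of items i and k for one comparison."""
    if y_ik not in (0, 1):
        raise ValueError("y_ik must be 0 or 1")
    pos_i, pos_k = sign_i > 0, sign_k > 0
    chosen = bool(y_ik)
    pts_i = int(pos_i == chosen)
    pts_k = int(pos_k != chosen)
    return pts_i, pts_k


def score_person(design: QuestionnaireDesign, responses: ResponseData) -> ScoreMatrix:
    """Sum the pairwise point awards into raw classical trait scores."""
    y = rank_to_pairwise(responses, design)  # (P, B, n_pairs)
    pairs = design.pair_index()  # (B, n_pairs, 2)
    signs = np.sign(design.loadings)
    traits = design.trait_of_item
    p = responses.n_persons
    theta = np.zeros((p, design.n_traits), dtype=float)
    pos_i = signs[pairs[..., 0]] > 0  # (B, n_pairs)
    pos_k = signs[pairs[..., 1]] > 0
    chosen = y.astype(bool)  # (P, B, n_pairs)
    pts_i = (pos_i[None, :, :] == chosen).astype(int)
    pts_k = (pos_k[None, :, :] != chosen).astype(int)
    trait_i = traits[pairs[..., 0]].ravel()  # (B * n_pairs,)
    trait_k = traits[pairs[..., 1]].ravel()
    flat_i = pts_i.reshape(p, -1)
    flat_k = pts_k.reshape(p, -1)
    for t in range(design.n_traits):
        theta[:, t] = flat_i[:, trait_i == t].sum(axis=1) + flat_k[:, trait_k == t].sum(
            axis=1
        )
    return ScoreMatrix(theta=theta, method="classical_raw")


def standardize(scores: ScoreMatrix) -> ScoreMatrix:
    """Column-wise z-transform (population-SD convention).

    Squared correlations with the truth — the reliability — are unaffected;
    this only puts classical scores on the z-scale on which RMSE is read.
    Zero-variance columns carry no ordering information and are set to zero
    with a warning.
    """
    theta = scores.theta.astype(float)
    mean = theta.mean(axis=0)
    sd = theta.std(axis=0)
    z = np.zeros_like(theta)
    degenerate = sd <= 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance score column(s) set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    ok = ~degenerate
    z[:, ok] = (theta[:, ok] - mean[ok]) / sd[ok]
    return ScoreMatrix(theta=z, method="classical_z")
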