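"""Thurstonian response generation.

Latent utilities ``t_pi = mu_i + lambda_i * eta_{a(i),p} + eps_pi`` with
``eps_pi ~ N(0, psi2_i)`` drawn once per person x item; each block's items
are ranked by descending utility and the ranking is re-expressed as binary
paired comparisons ``y_pik = 1{t_pi >= t_pk}``.  Because one error draw is
shared by all comparisons an item enters within its block, outcomes in a
block are dependent — the residual dependency a Thurstonian IRT estimator
must absorb — but always transitive.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import QuestionnaireDesign, TraitCorrelationMatrix

__all__ = [
    "PersonSample",
    "ResponseData",
    "draw_traits",
    "simulate_responses",
    "choice_probability",
    "rank_to_pairwise",
    "pairwise_to_rank",
    "pairwise_frame",
]


@dataclasses.dataclass(frozen=True)
class PersonSample:
    """True latent trait scores eta, persons x traits, MVN(0, Phi)."""

    eta: np.ndarray

    @property
    def n_persons(self) -> int:
        return self.eta.shape[0]

    @property
    def n_traits(self) -> int:
        return self.eta.shape[1]


@dataclasses.dataclass(frozen=True)
class ResponseData:
    """Observed forced-choice responses.

    ``rankings[p, b]`` lists the items of block ``b`` in person ``p``'s
    preference order (best first).  Binary outcomes are derived on demand via
    :func:`rank_to_pairwise` for the design's canonical pair order.
    """

    rankings: np.ndarray  # (n_persons, n_blocks, block_size) item indices

    @property
    def n_persons(self) -> int:
        return self.rankings.shape[0]

    @property
    def n_blocks(self) -> int:
        return self.rankings.shape[1]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ResponseData":
        """Rebuild responses from the long (person, block, item, rank) format."""
        p = int(df["person"].max()) + 1
        b = int(df["block"].max()) + 1
        s = int(df["rank"].max()) + 1
        rankings = np.full((p, b, s), -1, dtype=int)
        rankings[df["person"], df["block"], df["rank"]] = df["item"]
        if (rankings < 0).any():
            raise ValueError("incomplete response table")
        return cls(rankings=rankings)

    def to_frame(self) -> pd.DataFrame:
        """Long format (person, block, item, rank)."""
        p, b, s = self.rankings.shape
        persons, blocks, ranks = np.meshgrid(
            np.arange(p), np.arange(b), np.arange(s), indexing="ij"
        )
        return pd.DataFrame(
            {
                "person": persons.ravel(),
                "block": blocks.ravel(),
                "item": self.rankings.ravel(),
                "rank": ranks.ravel(),
            }
        )


def pairwise_frame(responses: ResponseData, design: QuestionnaireDesign) -> pd.DataFrame:
    """Derived binary-outcome table: (person, item_i, item_k, y) per pair."""
    y = rank_to_pairwise(responses, design)  # (P, B, n_pairs)
    pairs = design.pair_index()  # (B, n_pairs, 2)
    p = responses.n_persons
    n_rows = y.size
    person = np.repeat(np.arange(p), y.shape[1] * y.shape[2])
    item_i = np.tile(pairs[..., 0].ravel(), p)
    item_k = np.tile(pairs[..., 1].ravel(), p)
    return pd.DataFrame(
        {"person": person, "item_i": item_i, "item_k": item_k, "y": y.reshape(n_rows)}
    )


def draw_traits(
    phi: TraitCorrelationMatrix, n_persons: int, rng: np.random.Generator
) -> PersonSample:
    """Draw person traits i.i.d. MVN(0, Phi) via the Cholesky factor of Phi."""
    if n_persons < 2:
        raise ValueError("need at least 2 persons")
    chol = phi.cholesky()
    z = rng.standard_normal((n_persons, phi.n_traits))
    return PersonSample(eta=z @ chol.T)


def simulate_responses(
    design: QuestionnaireDesign, persons: PersonSample, rng: np.random.Generator
) -> ResponseData:
    """Generate block rankings from latent utilities.

    Utilities are drawn once per person x item; exact ties (a measure-zero
    event with continuous errors) are broken in favour of the lower item
    index, which the stable descending sort guarantees because block item
    lists are stored in ascending order.
    """
    if persons.n_traits != design.n_traits:
        raise ValueError("design and persons disagree on the number of traits")
    eta_items = persons.eta[:, design.trait_of_item]  # (P, I)
    sd = np.sqrt(design.error_variances)
    eps = rng.standard_normal(eta_items.shape) * sd
    t = design.item_means + design.loadings * eta_items + eps
    t_blocks = t[:, design.blocks]  # (P, B, S)
    order = np.argsort(-t_blocks, axis=2, kind="stable")
    rankings = np.take_along_axis(
        np.broadcast_to(design.blocks, t_blocks.shape), order, axis=2
    )
    return ResponseData(rankings=np.ascontiguousarray(rankings))


def choice_probability(
    gamma_ik: float,
    lam_i: float,
    lam_k: float,
    eta_a: float,
    eta_b: float,
    psi2_i: float,
    psi2_k: float,
) -> float:
    """Probit probability that item i is preferred over item k.

    ``P(y=1) = Phi((-gamma_ik + lambda_i * eta_a - lambda_k * eta_b) /
    sqrt(psi2_i + psi2_k))`` — the marginal preference probability for one
    paired comparison given the two trait values.
    """
    denom = psi2_i + psi2_k
    if denom <= 0:
        raise ValueError("psi2_i + psi2_k must be positive")
    return float(norm.cdf((-gamma_ik + lam_i * eta_a - lam_k * eta_b) / np.sqrt(denom)))


def rank_to_pairwise(responses: ResponseData, design: QuestionnaireDesign) -> np.ndarray:
    """Binary outcomes for the canonical ordered pairs of each block.

    Returns an array ``(n_persons, n_blocks, n_pairs)`` with ``y=1`` iff the
    pair's first item is ranked above its second.
    """
    p, b, s = responses.rankings.shape
    # item -> slot within its block (blocks partition the items)
    slot_of = np.empty(design.n_items, dtype=int)
    slot_of[design.blocks] = np.arange(s)[None, :]
    slots = slot_of[responses.rankings]  # (P, B, S): slot occupying each rank
    rank_of_slot = np.empty((p, b, s), dtype=int)
    np.put_along_axis(
        rank_of_slot, slots, np.broadcast_to(np.arange(s), (p, b, s)), axis=2
    )
    combos = [(a, c) for a in range(s) for c in range(a + 1, s)]
    y = np.stack(
        [rank_of_slot[:, :, a] < rank_of_slot[:, :, c] for a, c in combos], axis=2
    )
    return y.astype(np.int8)


def pairwise_to_rank(y: np.ndarray, design: QuestionnaireDesign) -> ResponseData:
    """Invert :func:`rank_to_pairwise` (valid for transitive outcomes).

    Each item's within-block win count determines its rank; for transitive
    triples the win counts are a permutation of {0, .., block_size-1}.
    """
    p, b, n_pairs = y.shape
    s = design.block_size
    combos = [(a, c) for a in range(s) for c in range(a + 1, s)]
    wins = np.zeros((p, b, s), dtype=int)
    for j, (a, c) in enumerate(combos):
        wins[:, :, a] += y[:, :, j]
        wins[:, :, c] += 1 - y[:, :, j]
    if not np.all(np.sort(wins, axis=2) == np.arange(s)):
        raise ValueError("intransitive pairwise outcomes cannot form a ranking")
    order = np.argsort(-wins, axis=2, kind="stable")
    rankings = np.take_along_axis(
        np.broadcast_to(design.blocks, (p, b, s)), order, axis=2
    )
    return ResponseData(rankings=np.ascontiguousarray(rankings))
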