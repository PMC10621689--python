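"""Questionnaire construction for forced-choice simulation studies.

A forced-choice questionnaire is a set of blocks (triplets by default) of
items, each item loading on exactly one latent trait.  Under the Thurstonian
utility model an item i is characterised by a mean utility ``mu_i``, a signed
standardized factor loading ``lambda_i`` and an error variance
``psi2_i = 1 - lambda_i**2``.  Pairwise intercepts are derived as
``gamma_ik = -(mu_i - mu_k)``; sampling item means rather than per-pair
intercepts keeps the gammas additive within a block, which utility-based
response generation requires.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "QuestionnaireDesign",
    "TraitCorrelationMatrix",
    "ConditionSpec",
    "DesignError",
    "sample_loadings",
    "apply_keying",
    "build_blocks",
    "sample_item_means",
    "make_correlation",
    "make_design",
    "neo_like_matrix",
    "nearest_correlation",
]

LOADING_DISTS = ("high_uniform", "realistic_truncnorm")
KEYINGS = ("equal", "mixed")
CORR_STRUCTURES = ("zero", "matrix_file", "neo_like")

#: domain/facet layout assumed for realistic (NEO-style) correlation matrices
N_DOMAINS = 5
FACETS_PER_DOMAIN = 6


class DesignError(ValueError):
    """Raised for invalid questionnaire configurations."""


@dataclasses.dataclass(frozen=True)
class TraitCorrelationMatrix:
    """Latent trait intercorrelation matrix Phi (unit diagonal, PD)."""

    phi: np.ndarray

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi, dtype=float)
        object.__setattr__(self, "phi", phi)
        if phi.ndim != 2 or phi.shape[0] != phi.shape[1]:
            raise DesignError("Phi must be a square matrix")
        if not np.allclose(phi, phi.T, atol=1e-10):
            raise DesignError("Phi must be symmetric")
        if not np.allclose(np.diag(phi), 1.0, atol=1e-10):
            raise DesignError("Phi must have a unit diagonal")
        if np.linalg.eigvalsh(phi).min() <= 1e-8:
            raise DesignError("Phi must be positive definite")

    @property
    def n_traits(self) -> int:
        return self.phi.shape[0]

    def cholesky(self) -> np.ndarray:
        return np.linalg.cholesky(self.phi)


@dataclasses.dataclass(frozen=True)
class QuestionnaireDesign:
    """A forced-choice questionnaire: blocks, trait map and item parameters.

    Attributes
    ----------
    n_traits:
        Number of latent traits measured.
    trait_of_item:
        Integer array, length ``n_items``; trait index of each item.
    loadings:
        Signed standardized loadings ``lambda_i``.
    item_means:
        Latent utility means ``mu_i``.
    blocks:
        ``(n_blocks, block_size)`` array of item indices; each row sorted
        ascending so the canonical within-block pair order is well defined.
    keying:
        ``"equal"`` (all loadings positive) or ``"mixed"`` (half negative).
    """

    n_traits: int
    trait_of_item: np.ndarray
    loadings: np.ndarray
    item_means: np.ndarray
    blocks: np.ndarray
    keying: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "trait_of_item", np.asarray(self.trait_of_item, dtype=int))
        object.__setattr__(self, "loadings", np.asarray(self.loadings, dtype=float))
        object.__setattr__(self, "item_means", np.asarray(self.item_means, dtype=float))
        object.__setattr__(self, "blocks", np.asarray(self.blocks, dtype=int))

    @property
    def n_items(self) -> int:
        return self.trait_of_item.size

    @property
    def n_blocks(self) -> int:
        return self.blocks.shape[0]

    @property
    def block_size(self) -> int:
        return self.blocks.shape[1]

    @property
    def error_variances(self) -> np.ndarray:
        """psi2_i = 1 - lambda_i**2 (standardized utilities)."""
        return 1.0 - self.loadings**2

    def pair_index(self) -> np.ndarray:
        """Canonical ordered item pairs, shape ``(n_blocks, n_pairs, 2)``.

        For triplets the pair order per block is (0,1), (0,2), (1,2) in the
        block's ascending item order.
        """
        s = self.block_size
        combos = [(a, b) for a in range(s) for b in range(a + 1, s)]
        return np.stack(
            [self.blocks[:, [a for a, _ in combos]], self.blocks[:, [b for _, b in combos]]],
            axis=-1,
        )

    def gammas(self) -> np.ndarray:
        """Pair intercepts gamma_ik = -(mu_i - mu_k) per canonical pair."""
        pairs = self.pair_index()
        return self.item_means[pairs[..., 1]] - self.item_means[pairs[..., 0]]

    def validate(self, blocks_per_trait: Optional[int] = None) -> None:
        """Audit all design invariants; raise :class:`DesignError` on failure."""
        lam = np.abs(self.loadings)
        if np.any(lam < 0.1 - 1e-12) or np.any(lam > 0.95 + 1e-12):
            raise DesignError("loading magnitudes must lie in [0.1, 0.95]")
        if np.any(self.error_variances < 0):
            raise DesignError("error variances must be non-negative")
        for row in self.blocks:
            if len(set(self.trait_of_item[row])) != len(row):
                raise DesignError("block items must load on distinct traits")
        counts = np.bincount(self.trait_of_item[self.blocks.ravel()], minlength=self.n_traits)
        if blocks_per_trait is not None and np.any(counts != blocks_per_trait):
            raise DesignError(f"each trait must appear in exactly {blocks_per_trait} blocks")
        if self.keying == "equal":
            if np.any(self.loadings <= 0):
                raise DesignError("equal keying requires all positive loadings")
        elif self.keying == "mixed":
            if int(np.sum(self.loadings < 0)) != self.n_items // 2:
                raise DesignError("mixed keying requires exactly floor(n/2) negative loadings")
        else:
            raise DesignError(f"unknown keying {self.keying!r}")
        g = self.gammas()
        if np.any(np.abs(g) >= 1.0):
            raise DesignError("pair intercepts must lie in (-1, 1)")
        if self.block_size == 3 and not np.allclose(g[:, 1], g[:, 0] + g[:, 2]):
            raise DesignError("gamma_13 must equal gamma_12 + gamma_23 within each block")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, keying: Optional[str] = None) -> "QuestionnaireDesign":
        """Rebuild a design from its :meth:`to_frame` serialization."""
        df = df.sort_values("item_id").reset_index(drop=True)
        n_blocks = int(df["block_id"].max()) + 1
        block_size = int(df["position"].max()) + 1
        blocks = np.full((n_blocks, block_size), -1, dtype=int)
        blocks[df["block_id"].to_numpy(), df["position"].to_numpy()] = df[
            "item_id"
        ].to_numpy()
        if (blocks < 0).any():
            raise DesignError("incomplete block table")
        loadings = df["loading"].to_numpy(float)
        if keying is None:
            keying = "mixed" if (loadings < 0).any() else "equal"
        return cls(
            n_traits=int(df["trait"].max()) + 1,
            trait_of_item=df["trait"].to_numpy(int),
            loadings=loadings,
            item_means=df["item_mean"].to_numpy(float),
            blocks=np.sort(blocks, axis=1),
            keying=keying,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format item table: item_id, trait, loading, item_mean, block_id, position."""
        block_of = np.empty(self.n_items, dtype=int)
        pos_of = np.empty(self.n_items, dtype=int)
        for b, row in enumerate(self.blocks):
            for p, item in enumerate(row):
                block_of[item] = b
                pos_of[item] = p
        return pd.DataFrame(
            {
                "item_id": np.arange(self.n_items),
                "trait": self.trait_of_item,
                "loading": self.loadings,
                "item_mean": self.item_means,
                "block_id": block_of,
                "position": pos_of,
            }
        )


@dataclasses.dataclass(frozen=True)
class ConditionSpec:
    """One cell x replication of the simulation grid."""

    scoring: str
    n_traits: int
    n_persons: int
    keying: str
    loading_dist: str
    corr_structure: str
    replication: int
    seed: int


def sample_loadings(n_items: int, dist: str, rng: np.random.Generator) -> np.ndarray:
    """Draw positive loading magnitudes.

    ``high_uniform`` draws from U(0.65, 0.95); ``realistic_truncnorm`` draws
    from N(0.5, 0.16^2) truncated to [0.1, 0.9] (rejection sampling; the
    acceptance rate is ~0.98 so the loop terminates almost immediately).
    """
    if n_items < 3:
        raise DesignError("need at least 3 items")
    if dist == "high_uniform":
        return rng.uniform(0.65, 0.95, size=n_items)
    if dist == "realistic_truncnorm":
        out = np.empty(n_items)
        filled = 0
        while filled < n_items:
            draw = rng.normal(0.5, 0.16, size=n_items - filled)
            keep = draw[(draw >= 0.1) & (draw <= 0.9)]
            out[filled : filled + keep.size] = keep
            filled += keep.size
        return out
    raise DesignError(f"unknown loading distribution {dist!r}")


def apply_keying(magnitudes: np.ndarray, keying: str, rng: np.random.Generator) -> np.ndarray:
    """Attach signs: ``equal`` keeps all positive, ``mixed`` negates a random
    subset of exactly floor(n/2) items."""
    mags = np.asarray(magnitudes, dtype=float)
    if np.any(mags <= 0):
        raise DesignError("loading magnitudes must be positive")
    if keying == "equal":
        return mags.copy()
    if keying == "mixed":
        signed = mags.copy()
        neg = rng.choice(mags.size, size=mags.size // 2, replace=False)
        signed[neg] *= -1.0
        return signed
    raise DesignError(f"unknown keying {keying!r}")


def build_blocks(
    n_traits: int,
    blocks_per_trait: int,
    rng: np.random.Generator,
    block_size: int = 3,
    max_retries: int = 1000,
) -> np.ndarray:
    """Randomly assemble blocks of trait-distinct items.

    Returns a ``(n_blocks, block_size)`` array of *trait* indices per block
    (items are numbered afterwards).  Trait pairings are deliberately left
    unbalanced: blocks are filled one at a time with distinct traits drawn
    with probability proportional to their remaining quota.  Any trait whose
    remaining quota equals the number of remaining blocks is forced into the
    current block, which keeps the assignment feasible throughout; a bounded
    retry loop guards the degenerate corner cases.
    """
    if n_traits < block_size:
        raise DesignError("need at least block_size traits")
    total = n_traits * blocks_per_trait
    if total % block_size:
        raise DesignError("n_traits * blocks_per_trait must be divisible by block size")
    n_blocks = total // block_size
    for _ in range(max_retries):
        remaining = np.full(n_traits, blocks_per_trait)
        blocks = np.empty((n_blocks, block_size), dtype=int)
        ok = True
        for b in range(n_blocks):
            left = n_blocks - b
            forced = np.flatnonzero(remaining >= left)
            if forced.size > block_size:
                ok = False
                break
            chosen = list(forced)
            pool = np.flatnonzero(remaining > 0)
            pool = pool[~np.isin(pool, forced)]
            need = block_size - len(chosen)
            if need > pool.size:
                ok = False
                break
            if need:
                probs = remaining[pool] / remaining[pool].sum()
                chosen.extend(rng.choice(pool, size=need, replace=False, p=probs))
            remaining[chosen] -= 1
            blocks[b] = sorted(chosen)
        if ok:
            # shuffle block order so forced placements leave no positional trace
            return blocks[rng.permutation(n_blocks)]
    raise DesignError("could not assemble trait-distinct blocks after retries")


def sample_item_means(n_items: int, rng: np.random.Generator) -> np.ndarray:
    """Item utility means mu_i ~ U(-0.5, 0.5).

    Every derived pair intercept gamma_ik = -(mu_i - mu_k) then lies in
    (-1, 1) and is additive within a block (gamma_13 = gamma_12 + gamma_23).
    """
    return rng.uniform(-0.5, 0.5, size=n_items)


def nearest_correlation(a: np.ndarray, n_iter: int = 100, eps: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the nearest correlation matrix
    (alternating projections onto the PSD cone and the unit-diagonal set)."""
    y = np.array(a, dtype=float, copy=True)
    ds = np.zeros_like(y)
    for _ in range(n_iter):
        r = y - ds
        w, v = np.linalg.eigh((r + r.T) / 2.0)
        x = (v * np.maximum(w, eps)) @ v.T
        ds = x - r
        y = x.copy()
        np.fill_diagonal(y, 1.0)
        if np.abs(x - y).max() < 1e-10:
            break
    # final symmetrize + tiny ridge to guarantee strict PD
    y = (y + y.T) / 2.0
    w = np.linalg.eigvalsh(y).min()
    if w <= eps:
        y = (y + (2 * eps - w) * np.eye(y.shape[0])) / (1.0 + 2 * eps - w)
        np.fill_diagonal(y, 1.0)
    return y


def neo_like_matrix(rng: np.random.Generator) -> np.ndarray:
    """Synthetic stand-in for a realistic 30-facet intercorrelation matrix.

    Five domains of six facets each; within-domain correlations drawn from
    U(0.3, 0.6), between-domain from U(-0.2, 0.3); the draw is projected to
    the nearest correlation matrix.  This is a synthetic surrogate with the
    hierarchical structure of broad-band personality inventories, not the
    empirical matrix of any published instrument.
    """
    n = N_DOMAINS * FACETS_PER_DOMAIN
    domain = np.repeat(np.arange(N_DOMAINS), FACETS_PER_DOMAIN)
    same = domain[:, None] == domain[None, :]
    raw = np.where(
        same,
        rng.uniform(0.3, 0.6, size=(n, n)),
        rng.uniform(-0.2, 0.3, size=(n, n)),
    )
    raw = (raw + raw.T) / 2.0
    np.fill_diagonal(raw, 1.0)
    return nearest_correlation(raw)


def _balanced_facets(n_traits: int, replication: int, n_source: int) -> np.ndarray:
    """Deterministic facet selection balancing domains, rotated by replication.

    The source matrix is assumed to follow the 5-domain x 6-facet layout in
    consecutive order.  Facet counts per domain differ by at most one; the
    rotation offset ``(replication - 1) mod 6`` makes the six replicate
    submatrices within a condition differ.
    """
    if n_source < n_traits:
        raise DesignError("source correlation matrix smaller than n_traits")
    if n_source != N_DOMAINS * FACETS_PER_DOMAIN:
        # non-NEO layout: take a rotated contiguous slice
        off = (replication - 1) % n_source
        return (off + np.arange(n_traits)) % n_source
    off = (replication - 1) % FACETS_PER_DOMAIN
    base, rem = divmod(n_traits, N_DOMAINS)
    dom_rot = (replication - 1) % N_DOMAINS
    idx = []
    for d in range(N_DOMAINS):
        count = base + (1 if ((d - dom_rot) % N_DOMAINS) < rem else 0)
        for j in range(count):
            facet = (off + j) % FACETS_PER_DOMAIN
            idx.append(d * FACETS_PER_DOMAIN + facet)
    return np.array(sorted(idx), dtype=int)


def make_correlation(
    corr_structure: str,
    n_traits: int,
    replication: int = 1,
    source_file: Optional[str] = None,
    rng: Optional[np.random.Generator] = None,
) -> TraitCorrelationMatrix:
    """Build the trait intercorrelation matrix for one condition replication.

    ``zero`` gives the identity; ``matrix_file`` extracts a domain-balanced
    principal submatrix of a user-supplied headerless CSV matrix;
    ``neo_like`` does the same from a synthetic realistic matrix drawn with
    ``rng`` (see :func:`neo_like_matrix`).
    """
    if corr_structure == "zero":
        return TraitCorrelationMatrix(np.eye(n_traits))
    if corr_structure == "matrix_file":
        if source_file is None:
            raise DesignError("matrix_file structure requires source_file")
        full = np.loadtxt(source_file, delimiter=",")
    elif corr_structure == "neo_like":
        if rng is None:
            raise DesignError("neo_like structure requires an rng")
        full = neo_like_matrix(rng)
    else:
        raise DesignError(f"unknown correlation structure {corr_structure!r}")
    TraitCorrelationMatrix(full)  # validates the source
    idx = _balanced_facets(n_traits, replication, full.shape[0])
    return TraitCorrelationMatrix(full[np.ix_(idx, idx)])


def make_design(
    n_traits: int,
    keying: str,
    loading_dist: str,
    rng: np.random.Generator,
    blocks_per_trait: int = 9,
) -> QuestionnaireDesign:
    """Draw a full questionnaire for one simulation replication.

    Triplet blocks, ``blocks_per_trait`` (default 9) blocks per trait, one
    item per block slot; loadings from ``loading_dist`` signed by ``keying``;
    item means from U(-0.5, 0.5).
    """
    trait_blocks = build_blocks(n_traits, blocks_per_trait, rng)
    n_blocks, block_size = trait_blocks.shape
    n_items = n_blocks * block_size
    trait_of_item = trait_blocks.ravel()
    blocks = np.arange(n_items).reshape(n_blocks, block_size)
    mags = sample_loadings(n_items, loading_dist, rng)
    loadings = apply_keying(mags, keying, rng)
    means = sample_item_means(n_items, rng)
    design = QuestionnaireDesign(
        n_traits=n_traits,
        trait_of_item=trait_of_item,
        loadings=loadings,
        item_means=means,
        blocks=blocks,
        keying=keying,
    )
    design.validate(blocks_per_trait=blocks_per_trait)
    return design
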