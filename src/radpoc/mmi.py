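"""Multi-model inference: Akaike weights and allocation of realisations.

Instead of committing to a single "best" risk model, predictions are
averaged over a set of plausible models weighted by their Akaike
information criterion: w_i = exp(-dAIC_i/2) / sum_k exp(-dAIC_k/2).
Some cancer groups additionally use a fixed hierarchical split (e.g. 50%
to sex-specific and 50% to sex-averaged model sets) on top of the
AIC-weighted leaves.  Monte Carlo realisations are distributed over models
either stratified (exact largest-remainder counts, reproducing e.g.
6000/4000 for weights 0.6/0.4 at N = 10,000) or by per-iteration random
selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = ["WeightTree", "aic_weights", "allocate_realizations", "select_model"]


@dataclass
class WeightTree:
    """Weighted tree whose leaves are AIC-weighted model lists.

    A leaf node has ``model_ids`` and either ``aics`` (converted to Akaike
    weights) or explicit ``leaf_weights``.  An internal node has
    ``branches`` as (weight, WeightTree) pairs whose weights sum to 1.
    """

    model_ids: list = field(default_factory=list)
    aics: list | None = None
    leaf_weights: list | None = None
    branches: list = field(default_factory=list)  # [(weight, WeightTree), ...]

    def __post_init__(self):
        if self.branches and self.model_ids:
            raise ConfigurationError("a tree node is either a leaf or internal")
        if self.branches:
            total = sum(w for w, _ in self.branches)
            if abs(total - 1.0) > 1e-12 or any(w < 0 for w, _ in self.branches):
                raise ConfigurationError("branch weights must be >=0 and sum to 1")
        else:
            if not self.model_ids:
                raise ConfigurationError("leaf node needs at least one model id")
            if self.leaf_weights is not None:
                w = np.asarray(self.leaf_weights, dtype=float)
                if len(w) != len(self.model_ids):
                    raise ConfigurationError("leaf weights do not match model ids")
                if abs(w.sum() - 1.0) > 1e-12 or np.any(w < 0):
                    raise ConfigurationError("leaf weights must be >=0 and sum to 1")

    @property
    def is_leaf(self) -> bool:
        return not self.branches

    def weights(self) -> np.ndarray:
        """Leaf weights: explicit if given, else Akaike weights from AICs."""
        if not self.is_leaf:
            raise ConfigurationError("weights() is defined on leaf nodes")
        if self.leaf_weights is not None:
            return np.asarray(self.leaf_weights, dtype=float)
        if self.aics is None:
            # no information -> equal weights
            n = len(self.model_ids)
            return np.full(n, 1.0 / n)
        return aic_weights(self.aics)

    def flat_weights(self) -> dict:
        """Product weights per model id over the whole tree."""
        out: dict = {}

        def walk(node: "WeightTree", mult: float):
            if node.is_leaf:
                for mid, w in zip(node.model_ids, node.weights()):
                    out[mid] = out.get(mid, 0.0) + mult * float(w)
            else:
                for w, child in node.branches:
                    walk(child, mult * w)

        walk(self, 1.0)
        return out

    def all_model_ids(self) -> list:
        return list(self.flat_weights())


def aic_weights(aics) -> np.ndarray:
    """Akaike weights exp(-dAIC/2) normalised; invariant to a common shift."""
    aics = np.asarray(aics, dtype=float)
    if aics.size == 0:
        raise ConfigurationError("need at least one model AIC")
    rel = np.exp(-0.5 * (aics - aics.min()))
    return rel / rel.sum()


def allocate_realizations(weights, n: int) -> np.ndarray:
    """Integer counts summing to N, proportional to weights.

    Largest-remainder rounding: each count differs from w_i * N by less
    than 1.
    """
    weights = np.asarray(weights, dtype=float)
    if n < 1:
        raise ConfigurationError("need at least one realisation")
    if abs(weights.sum() - 1.0) > 1e-9 or np.any(weights < 0):
        raise ConfigurationError("weights must be >=0 and sum to 1")
    exact = weights * n
    counts = np.floor(exact).astype(int)
    short = n - counts.sum()
    if short:
        order = np.argsort(-(exact - counts))
        counts[order[:short]] += 1
    return counts


def select_model(tree: WeightTree, rng: np.random.Generator) -> str:
    """Random walk down the tree: branch by weight, then leaf by AIC weight."""
    node = tree
    while not node.is_leaf:
        probs = np.array([w for w, _ in node.branches])
        idx = rng.choice(len(node.branches), p=probs)
        node = node.branches[idx][1]
    w = node.weights()
    return node.model_ids[rng.choice(len(node.model_ids), p=w)]
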