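"""All-pairs metanetwork prediction, pruning, and rewiring capacity.

The metanetwork is the complete matrix of predicted interaction
probabilities between every resource and every consumer in the species
pool, regardless of co-occurrence.  Pruning at a probability threshold
yields the binary feasible-interaction network from which each species'
fundamental interaction niche — and hence its rewiring capacity — is
quantified as the standardized functional richness of its partners.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import CONSUMER, RESOURCE, TraitTable
from .linkmodel import LinkModel, build_features
from .traitspace import TraitSpace, fric_standardized


def all_pairs_index(resource_ids, consumer_ids) -> pd.DataFrame:
    """The complete |resources| x |consumers| pair index."""
    ridx = pd.Index(resource_ids, name="resource_id")
    cidx = pd.Index(consumer_ids, name="consumer_id")
    return pd.MultiIndex.from_product([ridx, cidx]).to_frame(index=False)


@dataclass
class ProbMetanetwork:
    resource_ids: list
    consumer_ids: list
    p: np.ndarray  # |resources| x |consumers| probabilities

    def __post_init__(self) -> None:
        if self.p.shape != (len(self.resource_ids), len(self.consumer_ids)):
            raise ValueError("probability matrix shape does not match id lists")
        if np.isnan(self.p).any():
            raise ValueError("metanetwork must be complete (no missing entries)")
        if self.p.min() < 0 or self.p.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def n_pairs(self) -> int:
        return len(self.resource_ids) * len(self.consumer_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p, index=self.resource_ids, columns=self.consumer_ids)


@dataclass
class BinaryMetanetwork:
    resource_ids: list
    consumer_ids: list
    a: np.ndarray  # boolean adjacency
    threshold: float

    def partners_of(self, species_id, level: str) -> set:
        """Predicted partner set (species of the opposite level)."""
        if level == CONSUMER:
            j = self.consumer_ids.index(species_id)
            return {self.resource_ids[i] for i in np.nonzero(self.a[:, j])[0]}
        if level == RESOURCE:
            i = self.resource_ids.index(species_id)
            return {self.consumer_ids[j] for j in np.nonzero(self.a[i, :])[0]}
        raise ValueError(f"unknown trophic level {level!r}")

    @property
    def n_links(self) -> int:
        return int(self.a.sum())

    def degrees(self, level: str) -> pd.Series:
        if level == RESOURCE:
            return pd.Series(self.a.sum(axis=1), index=self.resource_ids)
        return pd.Series(self.a.sum(axis=0), index=self.consumer_ids)


def predict_metaweb(model: LinkModel, resource: TraitTable, consumer: TraitTable) -> ProbMetanetwork:
    """Predict interaction probabilities for every possible pair."""
    pairs = all_pairs_index(resource.species_ids, consumer.species_ids)
    x, _ = build_features(pairs, resource, consumer, encoders=model.encoders)
    scores = model.predict(x)
    p = scores.reshape(len(resource.species_ids), len(consumer.species_ids))
    return ProbMetanetwork(resource.species_ids, consumer.species_ids, p)


def prune(metaweb: ProbMetanetwork, threshold: float) -> BinaryMetanetwork:
    """Keep links with probability strictly above the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return BinaryMetanetwork(
        metaweb.resource_ids, metaweb.consumer_ids, metaweb.p > threshold, threshold
    )


def rewiring_capacity(
    level: str,
    network: BinaryMetanetwork,
    partner_space: TraitSpace,
) -> pd.DataFrame:
    """Species-level rewiring capacity for one trophic level.

    For each focal species, the capacity is the standardized functional
    richness of its predicted partners in the partner level's trait
    space: 1 means the partners span the whole partner trait space, 0 a
    degenerate (too small or flat) or empty partner set.

    Returns a DataFrame indexed by species_id with columns
    ``n_partners, fric_raw, fric_std, degenerate, isolated``.
    """
    focal_ids = network.consumer_ids if level == CONSUMER else network.resource_ids
    rows = []
    for sp in focal_ids:
        partners = sorted(network.partners_of(sp, level))
        if not partners:
            rows.append((sp, 0, 0.0, 0.0, True, True))
            continue
        res = fric_standardized(partners, partner_space)
        rows.append((sp, len(partners), res.raw, res.value, res.degenerate, False))
    return pd.DataFrame(
        rows, columns=["species_id", "n_partners", "fric_raw", "fric_std", "degenerate", "isolated"]
    ).set_index("species_id")
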