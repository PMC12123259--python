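"""End-to-end study runner: simulate -> model -> metanetwork -> maps.

Convenience orchestration of the full rewiring-capacity analysis on a
synthetic ecosystem, mirroring how the framework is applied to real
trait, network and occurrence tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import dataio, linkmodel, metaweb, rewiring, synthdata, traitspace
from .dataio import CONSUMER, RESOURCE


@dataclass
class StudyResult:
    ecosystem: synthdata.Ecosystem
    pairs: pd.DataFrame
    cv: linkmodel.CVResult | None
    model: linkmodel.LinkModel
    metaweb: metaweb.ProbMetanetwork
    network: metaweb.BinaryMetanetwork
    spaces: dict  # focal level -> partner-level TraitSpace
    capacity: dict  # level -> capacity DataFrame
    map: pd.DataFrame
    summary: dict


def run_study(
    config: synthdata.SynthConfig,
    threshold: float = 0.4,
    m_max: int = 4,
    cv_folds: int = 10,
    run_cv: bool = True,
    model_params: dict | None = None,
) -> StudyResult:
    """Run the full pipeline on one synthetic ecosystem.

    Stages: generate the ecosystem; pool site networks into training
    pairs (presences + inferred absences); optionally cross-validate and
    then fit the boosted-tree link model; predict and prune the all-pairs
    metanetwork; build both trait spaces; compute species rewiring
    capacities and the per-cell rewiring-potential map.
    """
    eco = synthdata.simulate(config)
    resource = dataio.impute_traits(eco.resource)
    consumer = dataio.impute_traits(eco.consumer)
    pairs = dataio.assemble_training_pairs(eco.networks)
    cv = (
        linkmodel.cross_validate(pairs, resource, consumer, k=cv_folds,
                                 params=model_params, seed=config.seed)
        if run_cv
        else None
    )
    model = linkmodel.fit(pairs, resource, consumer, params=model_params, seed=config.seed)
    prob = metaweb.predict_metaweb(model, resource, consumer)
    net = metaweb.prune(prob, threshold)
    # each level's niches are measured in the *partner* level's trait space
    spaces = {
        CONSUMER: traitspace.build_trait_space(resource, m_max=m_max),
        RESOURCE: traitspace.build_trait_space(consumer, m_max=m_max),
    }
    capacity = {
        CONSUMER: metaweb.rewiring_capacity(CONSUMER, net, spaces[CONSUMER]),
        RESOURCE: metaweb.rewiring_capacity(RESOURCE, net, spaces[RESOURCE]),
    }
    rmap, summary = rewiring.potential_map(eco.grid, net, spaces)
    return StudyResult(eco, pairs, cv, model, prob, net, spaces, capacity, rmap, summary)


def sigma_capacity_spearman(result: StudyResult) -> float:
    """Spearman correlation between each consumer's true kernel tolerance
    and its estimated rewiring capacity (the key parameter-recovery check)."""
    cap = result.capacity[CONSUMER]["fric_std"]
    sigma = result.ecosystem.truth.sigma.loc[cap.index]
    return float(sigma.corr(cap, method="spearman"))
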