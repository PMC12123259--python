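"""Synthetic two-level ecosystems with known interaction feasibility.

The generator emulates a plant/pollinator-style study system: two trophic
levels with mixed numeric + categorical traits, a latent trait-matching
feasibility kernel, disk-shaped geographic ranges on a regular grid, and
site networks sampled from co-occurring pairs with imperfect detection.

The feasibility kernel is Gaussian in the matching-trait difference with
one categorical penalty:

    p_ij = p_max * exp(-(corolla_i - bill_j)^2 / (2 sigma_j^2))
                 * (1 - delta_cat * 1[colour mismatch])

so each consumer j has a matching optimum (its bill length) and a niche
breadth (tolerance sigma_j).  Auxiliary traits influence nothing in the
truth; a fitted interaction model should therefore rank the matching
traits highest in variable importance.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from . import dataio
from .dataio import CONSUMER, RESOURCE, OccurrenceGrid, SiteNetwork, TraitTable, cell_id_of

#: fixed per-operation offsets deriving independent RNG sub-streams
_STREAM = {"traits": 1, "sigma": 2, "ranges": 3, "sites": 4}

COLOR_LEVELS = ("red", "white", "yellow")


class ConfigError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic ecosystem.

    Defaults describe the desk-scale study system used throughout the
    test suite: 60 resources x 40 consumers on a 20 x 20 grid of 0.5-degree
    cells, 30 sampled sites.  ``sigma_log_mean``/``sigma_log_sd``
    parameterise the log-normal spread of per-consumer tolerance;
    ``delta_cat`` is the categorical mismatch penalty and ``p_detect``
    the per-site detection probability of a feasible interaction.
    """

    seed: int = 0
    n_resource: int = 60
    n_consumer: int = 40
    grid_nx: int = 20
    grid_ny: int = 20
    cell_size: float = 0.5
    n_sites: int = 30
    p_max: float = 0.9
    sigma_log_mean: float = math.log(3.0)
    sigma_log_sd: float = 0.8
    delta_cat: float = 0.5
    p_detect: float = 0.7
    # matching traits: log-normal "corolla" / "bill" lengths (mm); the
    # resource spread exceeds the consumer spread, as for community-level
    # corolla vs. bill variation, so per-consumer tolerance dominates
    # niche breadth
    corolla_log_mean: float = math.log(15.0)
    corolla_log_sd: float = 0.5
    bill_log_mean: float = math.log(15.0)
    bill_log_sd: float = 0.2
    # disk ranges: log-normal radius (degrees) per level; sized so that a
    # sampled site holds roughly 15 resources x 12 consumers, the typical
    # richness of the plant/hummingbird networks this generator emulates
    radius_log_mean_resource: float = math.log(3.3)
    radius_log_sd_resource: float = 0.2
    radius_log_mean_consumer: float = math.log(3.6)
    radius_log_sd_consumer: float = 0.2
    n_groups: int = 4

    def __post_init__(self) -> None:
        for name in ("n_resource", "n_consumer", "grid_nx", "grid_ny", "n_sites", "n_groups"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("p_max", "delta_cat", "p_detect"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.cell_size <= 0:
            raise ConfigError("cell_size must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent, reproducible sub-stream for one generation stage."""
        return np.random.default_rng([self.seed, _STREAM[stream]])


@dataclass
class GroundTruth:
    """The latent feasibility structure behind one synthetic ecosystem."""

    p: pd.DataFrame  # resource x consumer feasibility probabilities
    sigma: pd.Series  # per-consumer tolerance
    optimum: pd.Series  # per-consumer matching optimum (its bill length)

    def niche_breadth(self, threshold: float = 0.5) -> pd.DataFrame:
        """Per-consumer true niche: partner count and matching-trait span
        of resources with feasibility >= threshold."""
        rows = []
        for c in self.p.columns:
            partners = self.p.index[self.p[c] >= threshold]
            rows.append((c, len(partners)))
        return pd.DataFrame(rows, columns=["species_id", "n_feasible"]).set_index("species_id")


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def _assign_groups(numeric: np.ndarray, k: int, rng: np.random.Generator, prefix: str) -> np.ndarray:
    k = min(k, numeric.shape[0])
    z = (numeric - numeric.mean(axis=0)) / numeric.std(axis=0)
    km = KMeans(n_clusters=k, n_init=10, random_state=int(rng.integers(2**31)))
    labels = km.fit_predict(z)
    return np.array([f"{prefix}{g + 1}" for g in labels])


def gen_traits(config: SynthConfig) -> tuple[TraitTable, TraitTable]:
    """Draw resource and consumer trait tables.

    Resources carry a matching trait (``corolla_length``), two auxiliary
    numeric traits and a colour; consumers a ``bill_length`` analogue,
    two auxiliary numeric traits and a colour preference.  Taxon groups
    are assigned by k-means clustering of the numeric traits, mimicking
    clades of trait-similar species.
    """
    rng = config.rng("traits")
    rids = [f"R{i:03d}" for i in range(config.n_resource)]
    cids = [f"C{i:03d}" for i in range(config.n_consumer)]

    corolla = rng.lognormal(config.corolla_log_mean, config.corolla_log_sd, config.n_resource)
    height = rng.lognormal(math.log(1.5), 0.5, config.n_resource)  # m
    nectar = np.clip(rng.normal(20.0, 5.0, config.n_resource), 1.0, None)  # % sugar
    color = rng.choice(COLOR_LEVELS, config.n_resource)
    res = pd.DataFrame(
        {
            "taxon_group": _assign_groups(np.column_stack([np.log(corolla), np.log(height), nectar]),
                                          config.n_groups, rng, "PF"),
            "corolla_length": corolla,
            "plant_height": height,
            "nectar_concentration": nectar,
            "flower_color": color,
        },
        index=pd.Index(rids, name="species_id"),
    )
    res_schema = {
        "corolla_length": {"kind": "numeric", "units": "mm"},
        "plant_height": {"kind": "numeric", "units": "m"},
        "nectar_concentration": {"kind": "numeric", "units": "percent"},
        "flower_color": {"kind": "categorical", "levels": list(COLOR_LEVELS)},
    }

    bill = rng.lognormal(config.bill_log_mean, config.bill_log_sd, config.n_consumer)
    mass = rng.lognormal(math.log(5.0), 0.3, config.n_consumer)  # g
    wing = np.clip(rng.normal(60.0, 8.0, config.n_consumer), 20.0, None)  # mm
    pref = rng.choice(COLOR_LEVELS, config.n_consumer)
    con = pd.DataFrame(
        {
            "taxon_group": _assign_groups(np.column_stack([np.log(bill), np.log(mass), wing]),
                                          config.n_groups, rng, "HC"),
            "bill_length": bill,
            "body_mass": mass,
            "wing_length": wing,
            "color_preference": pref,
        },
        index=pd.Index(cids, name="species_id"),
    )
    con_schema = {
        "bill_length": {"kind": "numeric", "units": "mm"},
        "body_mass": {"kind": "numeric", "units": "g"},
        "wing_length": {"kind": "numeric", "units": "mm"},
        "color_preference": {"kind": "categorical", "levels": list(COLOR_LEVELS)},
    }
    return (TraitTable(res, RESOURCE, res_schema), TraitTable(con, CONSUMER, con_schema))


# ---------------------------------------------------------------------------
# feasibility kernel
# ---------------------------------------------------------------------------

def true_link_prob(
    resource: pd.Series,
    consumer: pd.Series,
    config: SynthConfig,
    sigma: float,
) -> float:
    """Feasibility of one resource/consumer pair under the Gaussian kernel."""
    if sigma <= 0:
        raise ConfigError(f"tolerance sigma must be positive, got {sigma}")
    gap = float(resource["corolla_length"]) - float(consumer["bill_length"])
    mismatch = resource["flower_color"] != consumer["color_preference"]
    p = config.p_max * math.exp(-(gap**2) / (2.0 * sigma**2))
    if mismatch:
        p *= 1.0 - config.delta_cat
    return p


def make_ground_truth(resource: TraitTable, consumer: TraitTable, config: SynthConfig) -> GroundTruth:
    """Draw per-consumer tolerances and evaluate the kernel for all pairs."""
    rng = config.rng("sigma")
    sigma = pd.Series(
        rng.lognormal(config.sigma_log_mean, config.sigma_log_sd, len(consumer.data)),
        index=consumer.data.index,
        name="sigma",
    )
    corolla = resource.data["corolla_length"].to_numpy(dtype=float)
    bill = consumer.data["bill_length"].to_numpy(dtype=float)
    mism = (
        resource.data["flower_color"].to_numpy()[:, None]
        != consumer.data["color_preference"].to_numpy()[None, :]
    )
    gap = corolla[:, None] - bill[None, :]
    p = config.p_max * np.exp(-(gap**2) / (2.0 * sigma.to_numpy()[None, :] ** 2))
    p = p * np.where(mism, 1.0 - config.delta_cat, 1.0)
    pdf = pd.DataFrame(p, index=resource.data.index, columns=consumer.data.index)
    return GroundTruth(pdf, sigma, consumer.data["bill_length"].rename("optimum"))


# ---------------------------------------------------------------------------
# ranges and site networks
# ---------------------------------------------------------------------------

def gen_ranges(config: SynthConfig, resource: TraitTable, consumer: TraitTable) -> OccurrenceGrid:
    """Disk ranges of log-normal radius around uniform centroids.

    A species is present in every cell whose centroid lies within its
    radius of the range centre; the centre is itself a cell centroid, so
    every species occupies at least one cell (radius 0 keeps exactly the
    centroid cell).
    """
    rng = config.rng("ranges")
    nx, ny, s = config.grid_nx, config.grid_ny, config.cell_size
    lon = np.arange(nx) * s
    lat = np.arange(ny) * s
    lon_min, lat_min = np.meshgrid(lon, lat, indexing="ij")
    lon_min, lat_min = lon_min.ravel(), lat_min.ravel()
    cids = [cell_id_of(x, y) for x, y in zip(lon_min, lat_min)]
    cx, cy = lon_min + s / 2, lat_min + s / 2
    cells = pd.DataFrame({"cell_id": cids, "lon_min": lon_min, "lat_min": lat_min})

    presence = {}
    for table, mu, sd in (
        (resource, config.radius_log_mean_resource, config.radius_log_sd_resource),
        (consumer, config.radius_log_mean_consumer, config.radius_log_sd_consumer),
    ):
        ids = table.species_ids
        centre_idx = rng.integers(len(cids), size=len(ids))
        radii = rng.lognormal(mu, sd, len(ids))
        dist2 = (cx[None, :] - cx[centre_idx][:, None]) ** 2 + (cy[None, :] - cy[centre_idx][:, None]) ** 2
        mat = dist2 <= radii[:, None] ** 2
        mat[np.arange(len(ids)), centre_idx] = True  # centroid cell always occupied
        presence[table.trophic_level] = pd.DataFrame(mat, index=ids, columns=cids)
    return OccurrenceGrid(cells, s, presence)


def gen_site_networks(
    grid: OccurrenceGrid, truth: GroundTruth, config: SynthConfig
) -> list[SiteNetwork]:
    """Sample study sites and observe interactions with imperfect detection.

    Sites are grid cells (sampled without replacement) holding at least
    one species of each level; for each locally co-occurring pair an edge
    is observed with probability ``p_ij * p_detect``, independently per
    site.
    """
    rng = config.rng("sites")
    res_pres, con_pres = grid.presence[RESOURCE], grid.presence[CONSUMER]
    viable = [c for c in grid.cell_ids if res_pres[c].any() and con_pres[c].any()]
    if not viable:
        raise GenerationError("no cell holds species of both trophic levels")
    if config.n_sites > len(viable):
        raise GenerationError(
            f"n_sites={config.n_sites} exceeds the {len(viable)} cells with both levels present"
        )
    chosen = rng.choice(len(viable), size=config.n_sites, replace=False)
    networks = []
    for k, idx in enumerate(sorted(chosen)):
        cid = viable[idx]
        res_ids = sorted(res_pres.index[res_pres[cid]])
        con_ids = sorted(con_pres.index[con_pres[cid]])
        p_local = truth.p.loc[res_ids, con_ids].to_numpy()
        seen = rng.random(p_local.shape) < p_local * config.p_detect
        edges = frozenset(
            (res_ids[i], con_ids[j]) for i, j in zip(*np.nonzero(seen))
        )
        x, y = grid.centroid(cid)
        networks.append(
            SiteNetwork(f"site_{k:03d}", x, y, frozenset(res_ids), frozenset(con_ids), edges)
        )
    return networks


# ---------------------------------------------------------------------------
# one-call ecosystem + disk output
# ---------------------------------------------------------------------------

@dataclass
class Ecosystem:
    config: SynthConfig
    resource: TraitTable
    consumer: TraitTable
    truth: GroundTruth
    grid: OccurrenceGrid
    networks: list


def simulate(config: SynthConfig) -> Ecosystem:
    """Generate a complete synthetic ecosystem from one config + seed."""
    resource, consumer = gen_traits(config)
    truth = make_ground_truth(resource, consumer, config)
    grid = gen_ranges(config, resource, consumer)
    networks = gen_site_networks(grid, truth, config)
    return Ecosystem(config, resource, consumer, truth, grid, networks)


def write_ecosystem(eco: Ecosystem, outdir: str | Path) -> None:
    """Write every artefact in the standard CSV schemas plus a ground-truth CSV."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dataio.write_traits(eco.resource, out / "resource_traits.csv")
    dataio.write_traits(eco.consumer, out / "consumer_traits.csv")
    dataio.write_networks(eco.networks, out / "site_occurrences.csv", out / "site_edges.csv")
    dataio.write_occurrences(eco.grid, out / "grid_occurrences.csv")
    truth_long = eco.truth.p.stack().rename("p_true").rename_axis(["resource_id", "consumer_id"])
    truth_long.reset_index().to_csv(out / "ground_truth.csv", index=False)
    (out / "config.json").write_text(json.dumps(asdict(eco.config), indent=1))
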