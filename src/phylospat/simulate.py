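"""Synthetic phylogenies, community assembly, and spatial landscapes.

The generator produces data with the statistical structure the analysis
assumes, so every stage can be exercised without external downloads:

* ``simulate_yule_tree`` — pure-birth (Yule) phylogeny with exponential
  waiting times; the stand-in species pool.
* ``simulate_assembly`` — communities assembled from a tree under three
  regimes: *neutral* (uniform richness-matched subsets), *filtering*
  (membership probability decays exponentially with cophenetic distance to a
  focal species → phylogenetically clustered, positive NRI/NTI), and
  *repulsion* (sequential selection favouring species far from those already
  chosen → overdispersed, negative NRI/NTI).
* ``simulate_landscape`` — site coordinates, a 5-level spatially contiguous
  bedrock mosaic, an elevation gradient, a deliberately collinear climate
  block, and a response generated from the spatial-lag model
  y = (I - rho W)^(-1) (X beta + eps) on k-NN weights.
* ``simulate_dataset`` — the defaults mirror a subtropical montane survey of
  75 community plots, a 594-species pool, 5 bedrock classes and an elevation
  span of 0–869.7 m, wiring tree + landscape + assembly into one bundle the
  full pipeline can consume.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .metrics import mntd_batch, mpd_batch  # noqa: F401  (re-exported convenience)
from .spatial import knn_weights
from .trees import Phylogeny, cophenetic_matrix

__all__ = [
    "AssemblyScenario",
    "LandscapeScenario",
    "simulate_yule_tree",
    "simulate_assembly",
    "simulate_landscape",
    "simulate_dataset",
    "BEDROCK_LEVELS",
]

BEDROCK_LEVELS = ("granite", "rhyolite", "pyroclastic rock", "pyroclastic lava", "quartz sandstone")


# --------------------------------------------------------------------- trees
def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0, seed=None) -> Phylogeny:
    """Pure-birth tree with exponential waiting times between speciations.

    Starting from a single lineage at the root, with k extant lineages the
    next split occurs after Exp(k * birth_rate) time on a uniformly chosen
    lineage; after the n-th lineage appears one further Exp(n * birth_rate)
    interval runs to the present, so tip branches have positive length.
    Tips are labelled t1..tn in birth order.
    """
    if n_tips < 2:
        raise ValueError("need n_tips >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    birth_time = {id(root): 0.0}
    active = [root]
    t = 0.0
    label_counter = 0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        node = active.pop(int(rng.integers(k)))
        node.edge.length = (t - birth_time[id(node)]) if node is not root else None
        # a node that splits stops being a candidate tip; record its span
        node_split_time = t
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            birth_time[id(child)] = node_split_time
            active.append(child)
        if node is not root:
            node.edge.length = node_split_time - birth_time[id(node)]
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    for node in active:
        node.edge.length = t - birth_time[id(node)]
        label_counter += 1
        node.taxon = taxa.new_taxon(label=f"t{label_counter}")
    return Phylogeny(tree)


# ------------------------------------------------------------------ assembly
@dataclass(frozen=True)
class AssemblyScenario:
    """Community assembly regime on a phylogeny.

    ``strength`` is the kernel scale tau in branch-length units: under
    filtering, inclusion probability ~ exp(-d(focal, .)/tau), so smaller tau
    means tighter phylogenetic clustering.
    """

    mode: str = "neutral"            # neutral | filtering | repulsion
    strength: float = 1.0            # tau > 0 (ignored for neutral)
    richness: int | np.ndarray = 10  # scalar or per-site vector
    n_sites: int = 75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("neutral", "filtering", "repulsion"):
            raise ValueError(f"unknown assembly mode {self.mode!r}")
        if self.mode != "neutral" and self.strength <= 0:
            raise ValueError("kernel scale (strength) must be > 0")


def _weighted_subset(rng: np.random.Generator, weights: np.ndarray, size: int) -> np.ndarray:
    p = weights / weights.sum()
    return rng.choice(len(weights), size=size, replace=False, p=p)


def simulate_assembly(tree: Phylogeny, scenario: AssemblyScenario) -> pd.DataFrame:
    """Presence/absence site x species table assembled under a scenario.

    Sites are rows (site_1..site_n), species columns follow the tree's tip
    order.  Per-site random streams derive from (seed, site index).
    """
    n_tips = tree.n_tips
    richness = np.broadcast_to(np.asarray(scenario.richness, dtype=int), (scenario.n_sites,))
    if richness.min() < 2:
        raise ValueError("per-site richness must be >= 2")
    if richness.max() > n_tips:
        raise ValueError("richness cannot exceed the species pool size")
    d = cophenetic_matrix(tree).values if scenario.mode != "neutral" else None

    M = np.zeros((scenario.n_sites, n_tips), dtype=int)
    for s in range(scenario.n_sites):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=scenario.seed, spawn_key=(s,)))
        r = int(richness[s])
        if scenario.mode == "neutral":
            chosen = rng.choice(n_tips, size=r, replace=False)
        elif scenario.mode == "filtering":
            focal = int(rng.integers(n_tips))
            w = np.exp(-d[focal] / scenario.strength)
            w[focal] = 0.0
            chosen = np.concatenate([[focal], _weighted_subset(rng, w, r - 1)])
        else:  # repulsion
            chosen_list = [int(rng.integers(n_tips))]
            for _ in range(r - 1):
                dmin = d[:, chosen_list].min(axis=1)
                dmin[chosen_list] = 0.0   # already selected: weight 0
                chosen_list.append(int(_weighted_subset(rng, dmin, 1)[0]))
            chosen = np.asarray(chosen_list)
        M[s, chosen] = 1
    index = [f"site_{s + 1}" for s in range(scenario.n_sites)]
    return pd.DataFrame(M, index=pd.Index(index, name="site_id"), columns=list(tree.tip_labels))


# ----------------------------------------------------------------- landscape
@dataclass(frozen=True)
class LandscapeScenario:
    """Spatial environment generator settings.

    Defaults emulate a ~6 x 11 km coastal massif surveyed at 75 plots:
    elevation 0–869.7 m, five spatially contiguous bedrock patches, a
    climate block derived from elevation/coastal latent factors with at
    least one engineered near-duplicate pair (|r| > 0.95, exercising the
    collinearity screen), and spatially autocorrelated responses.
    """

    n_sites: int = 75
    elevation_range: tuple[float, float] = (0.0, 869.7)
    bbox: tuple[float, float, float, float] = (114.52, 22.492, 114.623, 22.556)  # lon/lat degrees
    rho_true: float = 0.4
    noise_sd: float = 1.0
    beta_elevation: float = 2.0
    beta_climate: float = 1.5
    bedrock_effects: tuple[float, ...] = (0.0, 0.6, -0.4, 1.0, -0.8)  # per BEDROCK_LEVELS
    k_neighbours: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.rho_true < 1.0:
            raise ValueError("rho_true must lie in (-1, 1)")


@dataclass
class SimulatedLandscape:
    coords: pd.DataFrame        # site_id -> lon, lat
    env: pd.DataFrame           # site_id -> elevation, slope, aspect, bedrock, BIO*
    y: pd.Series                # spatially autocorrelated response
    X_true: pd.DataFrame        # the true design (normalized) behind y
    beta_true: pd.Series
    weights: object             # SpatialWeights used in the generating model
    richness_signal: pd.Series  # latent per-site richness surface (for assembly)


def simulate_landscape(scenario: LandscapeScenario) -> SimulatedLandscape:
    """Generate coordinates, environment and a spatial-lag response.

    y = (I - rho W)^(-1) (X beta_true + eps) on the k-NN weights of the
    generated coordinates.  The climate block includes BIO1/BIO5 as an
    engineered near-duplicate pair (|r| > 0.95 by construction).
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_sites
    lon0, lat0, lon1, lat1 = scenario.bbox
    lon = rng.uniform(lon0, lon1, n)
    lat = rng.uniform(lat0, lat1, n)
    ids = [f"site_{i + 1}" for i in range(n)]
    coords = pd.DataFrame({"lon": lon, "lat": lat}, index=pd.Index(ids, name="site_id"))

    # elevation: single peak near the centre of the bbox + roughness, clipped
    u = (lon - lon0) / (lon1 - lon0)
    v = (lat - lat0) / (lat1 - lat0)
    peak = np.exp(-(((u - 0.45) ** 2 + (v - 0.55) ** 2) / 0.08))
    e_lo, e_hi = scenario.elevation_range
    elevation = e_lo + (e_hi - e_lo) * np.clip(peak + 0.08 * rng.normal(size=n), 0, 1)

    slope = np.clip(rng.normal(22, 8, n), 2, 45)
    aspect = rng.uniform(0, 360, n)

    # bedrock: Voronoi mosaic of 5 contiguous patches, all levels present
    centers = np.column_stack([rng.uniform(lon0, lon1, 5), rng.uniform(lat0, lat1, 5)])
    d2 = ((lon[:, None] - centers[None, :, 0]) ** 2 + (lat[:, None] - centers[None, :, 1]) ** 2)
    bedrock_idx = d2.argmin(axis=1)
    for lev in range(5):  # guarantee every level occurs
        if not (bedrock_idx == lev).any():
            bedrock_idx[rng.integers(n)] = lev
    bedrock = pd.Categorical.from_codes(bedrock_idx, categories=list(BEDROCK_LEVELS))

    # climate block from two latent factors: thermal (elevation-driven) and
    # moisture (coastal-distance-driven); BIO5 duplicates BIO1 up to tiny noise
    f_temp = -(elevation - elevation.mean()) / elevation.std()
    f_wet = (v - v.mean()) / v.std()
    nz = lambda s: rng.normal(scale=s, size=n)
    climate = pd.DataFrame({
        "BIO1": 215 + 8 * f_temp + nz(0.5),          # mean annual T (degC*10)
        "BIO2": 62 + 3 * f_temp - 2 * f_wet + nz(1.5),   # mean diurnal range
        "BIO3": 330 + 10 * f_wet + nz(3.0),          # isothermality (*10)
        "BIO4": 480 - 18 * f_wet + 6 * f_temp + nz(6.0),  # T seasonality / annual range proxy
        "BIO5": 215 + 8 * f_temp + nz(0.05),         # near-duplicate of BIO1 (|r|>0.95)
        "BIO12": 2280 + 140 * f_wet + nz(40.0),      # annual precipitation (mm)
        "BIO13": 420 + 45 * f_wet + nz(12.0),        # precipitation of wettest month
        "BIO14": 28 + 6 * f_wet - 2 * f_temp + nz(1.5),   # precipitation of driest month
        "BIO15": 78 - 5 * f_wet + 3 * f_temp + nz(1.5),   # precipitation seasonality
    }, index=coords.index)

    env = pd.DataFrame({
        "elevation": elevation,
        "slope": slope,
        "aspect": aspect,
        "bedrock": bedrock,
    }, index=coords.index).join(climate)

    w = knn_weights(coords, k=scenario.k_neighbours)

    elev01 = (elevation - e_lo) / (e_hi - e_lo)
    clim = (climate["BIO14"] - climate["BIO14"].mean()) / climate["BIO14"].std()
    dummies = pd.get_dummies(env["bedrock"], dtype=float).reindex(columns=list(BEDROCK_LEVELS))
    X_true = pd.DataFrame({"elev01": elev01, "BIO14z": clim.to_numpy()}, index=coords.index)
    beta = pd.Series({"elev01": scenario.beta_elevation, "BIO14z": scenario.beta_climate})
    xb = X_true.to_numpy() @ beta.to_numpy()
    xb = xb + dummies.to_numpy() @ np.asarray(scenario.bedrock_effects)
    eps = rng.normal(scale=scenario.noise_sd, size=n)
    A = np.eye(n) - scenario.rho_true * w.W
    yv = np.linalg.solve(A, xb + eps)
    y = pd.Series(yv, index=coords.index, name="y")

    # latent richness surface: mid-to-high-elevation maximum + bedrock offsets
    rich = 18 + 46 * np.clip(elev01 * 1.35, 0, 1) + 6 * dummies.to_numpy() @ np.array([0, 0.5, -0.5, 1.0, -1.0])
    richness_signal = pd.Series(np.clip(np.round(rich), 4, None).astype(int),
                                index=coords.index, name="richness")

    return SimulatedLandscape(coords=coords, env=env, y=y, X_true=X_true,
                              beta_true=beta, weights=w, richness_signal=richness_signal)


# ------------------------------------------------------------------- dataset
@dataclass
class SimulatedDataset:
    tree: Phylogeny
    community: pd.DataFrame
    env: pd.DataFrame
    coords: pd.DataFrame
    landscape: SimulatedLandscape


def simulate_dataset(
    n_species: int = 594,
    landscape: LandscapeScenario | None = None,
    assembly_mode: str = "filtering",
    assembly_strength: float | None = None,
    seed: int = 0,
) -> SimulatedDataset:
    """Full survey-like bundle: tree + landscape + assembled communities.

    Per-site richness follows the landscape's latent surface (elevation and
    bedrock structured), and communities are assembled under the requested
    regime, so richness carries spatial/environmental signal while the SES
    indices carry the assembly signal.
    """
    scen = landscape or LandscapeScenario(seed=seed)
    tree = simulate_yule_tree(n_species, seed=seed + 1)
    land = simulate_landscape(scen)
    depth_scale = float(np.median(cophenetic_matrix(tree).values))
    strength = assembly_strength if assembly_strength is not None else 0.25 * depth_scale
    # richness capped well below the pool so the taxa-label null stays
    # non-degenerate even for small demonstration pools
    richness = np.minimum(land.richness_signal.to_numpy(), max(2, int(0.6 * n_species)))
    comm = simulate_assembly(tree, AssemblyScenario(
        mode=assembly_mode,
        strength=strength,
        richness=richness,
        n_sites=scen.n_sites,
        seed=seed + 2,
    ))
    comm.index = land.env.index
    return SimulatedDataset(tree=tree, community=comm, env=land.env,
                            coords=land.coords, landscape=land)
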