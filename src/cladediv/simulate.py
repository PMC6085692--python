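"""Synthetic datasets with known ground truth for the full analysis chain.

The generator emulates an island-scale comparative study of among-population
genetic divergence:

* an ultrametric species chronogram from a Yule (pure-birth) process, node
  heights rescaled so the root sits at ``root_age`` (default 95 Myr);
* spatially structured sampling localities: each species occupies a random
  sub-box of the island, its localities drawn uniformly inside it;
* 20 environmental variables (19 bioclim-style + percent tree cover) as
  island-wide linear gradients of the coordinates mixed with white noise —
  ``env_autocorr`` is the fraction of variance carried by the gradient;
* per-species average genetic divergence generated by the linear model
  ``mu = beta_age*age + beta_geo*geodist + beta_env*envhet`` plus a residual
  that is a ``lambda_signal``-weighted mix of a Brownian draw on the
  chronogram and white noise, truncated at zero;
* a within-species population tree per species realizing that divergence
  exactly: a star of locality subtrees with stem length divergence/2, so
  every between-locality patristic distance equals the generated divergence.

Geographic distance, environmental heterogeneity, and species age are
computed with the same modules the analysis pipeline uses, so a synthetic run
exercises the real code path end to end. All randomness flows from one seed
via fixed per-purpose/per-species sub-streams, so results are bit-reproducible
and adding a species does not perturb earlier species' locality draws.
"""
from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from .comparative import species_age
from .distance import DistanceMatrix
from .environment import ENV_COLUMNS, clade_env_heterogeneity, env_dissimilarity, pca_scores
from .geodesy import EARTH_RADIUS_KM, geographic_matrix, mean_pairwise
from .trees import write_newick

__all__ = ["ECOMORPHS", "SimConfig", "SimTruth", "simulate_chronogram",
           "simulate_localities", "simulate_clade_dataset", "write_dataset"]

logger = logging.getLogger(__name__)

#: Ecomorph labels with frequencies matching a 26-clade island assemblage.
ECOMORPHS = ("crown-giant", "grass-bush", "trunk-crown", "trunk-ground",
             "twig", "unique-1", "unique-2")
_ECOMORPH_WEIGHTS = np.array([3, 3, 5, 7, 3, 3, 2], dtype=float)

_KM_PER_DEG = np.pi * EARTH_RADIUS_KM / 180.0

# plausible (mean, sd) per variable: temperatures in 0.1 deg C, precipitation
# in mm, tree cover in percent (clipped to [0, 100])
_ENV_BASE: tuple[tuple[str, float, float], ...] = (
    ("env01", 252, 8), ("env02", 105, 12), ("env03", 78, 5), ("env04", 680, 90),
    ("env05", 318, 10), ("env06", 185, 12), ("env07", 133, 15), ("env08", 256, 9),
    ("env09", 248, 9), ("env10", 263, 8), ("env11", 238, 10),
    ("env12", 1320, 260), ("env13", 210, 60), ("env14", 35, 15), ("env15", 58, 12),
    ("env16", 520, 130), ("env17", 140, 45), ("env18", 430, 110), ("env19", 160, 50),
    ("tree_cover", 55, 18),
)

# fixed sub-stream offsets: adding draws for one purpose never shifts another
_STREAM_CHRONOGRAM = 1
_STREAM_ENV_COEF = 2
_STREAM_BROWNIAN = 3
_STREAM_ECOMORPH = 4
_STREAM_SPECIES = 100       # (seed, 100, i): locality/environment draws
_STREAM_WHITE = 200         # (seed, 200, i): white residual component


def _rng(*entropy: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(entropy)))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the target study design: 26 clades on a 95-Myr
    chronogram, 3–8 localities per clade, divergence responding to stem age
    (0.0015 substitutions/site per Myr) and mean geographic distance
    (2e-5 per km), residual sd 0.005 with half its variance phylogenetically
    structured.
    """

    n_species: int = 26
    birth_rate: float = 0.1            # speciations per lineage per Myr
    root_age: float = 95.0             # Myr
    n_localities_range: tuple[int, int] = (3, 8)
    beta_age: float = 0.0015           # substitutions/site per Myr
    beta_geo: float = 2e-5             # substitutions/site per km
    beta_env: float = 0.0              # substitutions/site per PCA-distance unit
    noise_sd: float = 0.005            # substitutions/site
    lambda_signal: float = 0.5         # fraction of residual variance on the tree
    seed: int = 0
    extent_km: float = 1000.0          # island bounding-box side
    species_range_km: tuple[float, float] = (100.0, 600.0)
    env_autocorr: float = 0.7          # spatial-gradient fraction of env variance
    samples_per_locality: int = 2
    within_locality_branch: float = 0.0
    pca_axes: int = 5

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        if self.birth_rate <= 0 or self.root_age <= 0 or self.extent_km <= 0:
            raise ValueError("birth_rate, root_age and extent_km must be positive")
        if min(self.beta_age, self.beta_geo, self.beta_env) < 0 or self.noise_sd < 0:
            raise ValueError("effect sizes and noise_sd must be non-negative")
        if not 0.0 <= self.lambda_signal <= 1.0:
            raise ValueError("lambda_signal must be in [0, 1]")
        lo, hi = self.n_localities_range
        if lo < 1 or hi < lo:
            raise ValueError("n_localities_range must be an increasing pair of positive ints")
        if self.samples_per_locality < 1 or self.within_locality_branch < 0:
            raise ValueError("invalid within-species tree settings")


@dataclass(frozen=True)
class SimTruth:
    """Generated dataset plus the ground truth that produced it."""

    config: SimConfig
    chronogram: dendropy.Tree
    ages: pd.Series                      # stem age per species, Myr
    clade_summary: pd.DataFrame          # clade, avg_divergence, avg_geodist, env_het, age, ...
    population_trees: dict[str, dendropy.Tree]
    localities: pd.DataFrame
    sample_map: pd.DataFrame
    expected_divergence: pd.Series       # mu before residual/truncation
    residuals: pd.Series


def simulate_chronogram(
    n_species: int,
    birth_rate: float = 0.1,
    root_age: float = 95.0,
    seed: int = 0,
    *,
    rng: np.random.Generator | None = None,
) -> dendropy.Tree:
    """Ultrametric binary chronogram from a Yule process, root at ``root_age``."""
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if birth_rate <= 0 or root_age <= 0:
        raise ValueError("birth_rate and root_age must be positive")
    if rng is None:
        rng = _rng(seed, _STREAM_CHRONOGRAM)
    tree = dendropy.Tree()
    tree.is_rooted = True
    root = tree.seed_node
    pending: list[tuple[dendropy.Node, float]] = [
        (root.new_child(), 0.0),
        (root.new_child(), 0.0),
    ]
    t = 0.0
    while len(pending) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(pending)))
        idx = int(rng.integers(len(pending)))
        node, born = pending.pop(idx)
        node.edge.length = t - born
        pending.append((node.new_child(), t))
        pending.append((node.new_child(), t))
    t_end = t + rng.exponential(1.0 / (birth_rate * n_species))
    width = len(str(n_species))
    for i, (node, born) in enumerate(pending):
        node.edge.length = t_end - born
        node.taxon = tree.taxon_namespace.new_taxon(label=f"S{i + 1:0{width}d}")
    factor = root_age / t_end
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return tree


def _env_coefficients(rng: np.random.Generator) -> np.ndarray:
    """Unit gradient direction (a, b) per environmental variable."""
    coef = rng.standard_normal((len(_ENV_BASE), 2))
    return coef / np.linalg.norm(coef, axis=1, keepdims=True)


def _env_values(
    xy_std: np.ndarray, coeffs: np.ndarray, autocorr: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Environment table from standardized island coordinates.

    Each variable mixes a unit-variance linear spatial gradient (weight
    ``autocorr``) with white noise (weight ``1 − autocorr``), then shifts to
    its field-plausible mean/sd.
    """
    trend = xy_std @ coeffs.T                       # (n, 20), unit variance
    eps = rng.standard_normal(trend.shape)
    z = np.sqrt(autocorr) * trend + np.sqrt(1.0 - autocorr) * eps
    out = {}
    for j, (name, mu, sd) in enumerate(_ENV_BASE):
        vals = mu + sd * z[:, j]
        if name == "tree_cover":
            vals = np.clip(vals, 0.0, 100.0)
        out[name] = vals
    return pd.DataFrame(out)


def _island_box(extent_km: float, center: tuple[float, float]) -> tuple[float, float, float, float]:
    lat_c, lon_c = center
    dlat = extent_km / _KM_PER_DEG
    dlon = extent_km / (_KM_PER_DEG * np.cos(np.radians(lat_c)))
    return lat_c - dlat / 2, lat_c + dlat / 2, lon_c - dlon / 2, lon_c + dlon / 2


def _standardize_coords(
    lat: np.ndarray, lon: np.ndarray, box: tuple[float, float, float, float]
) -> np.ndarray:
    lat0, lat1, lon0, lon1 = box
    x = (lon - lon0) / (lon1 - lon0)
    y = (lat - lat0) / (lat1 - lat0)
    # uniform-in-box coordinates mapped to mean 0, variance 1
    return np.column_stack([(x - 0.5), (y - 0.5)]) * np.sqrt(12.0)


def simulate_localities(
    n_localities: int,
    extent_km: float = 1000.0,
    env_autocorr: float = 0.7,
    seed: int = 0,
    *,
    rng: np.random.Generator | None = None,
    center: tuple[float, float] = (21.5, -79.5),
    id_prefix: str = "L",
) -> pd.DataFrame:
    """Georeferenced localities with 20 environmental variables.

    Coordinates are uniform inside a square bounding box of side
    ``extent_km`` centered on ``center``.
    """
    if n_localities < 1:
        raise ValueError("n_localities must be >= 1")
    if extent_km <= 0:
        raise ValueError("extent_km must be positive")
    if not 0.0 <= env_autocorr <= 1.0:
        raise ValueError("env_autocorr must be in [0, 1]")
    if rng is None:
        rng = _rng(seed, _STREAM_SPECIES, 0)
    box = _island_box(extent_km, center)
    coeffs = _env_coefficients(rng)
    lat = rng.uniform(box[0], box[1], n_localities)
    lon = rng.uniform(box[2], box[3], n_localities)
    env = _env_values(_standardize_coords(lat, lon, box), coeffs, env_autocorr, rng)
    width = max(3, len(str(n_localities)))
    out = pd.DataFrame(
        {
            "locality": [f"{id_prefix}{i + 1:0{width}d}" for i in range(n_localities)],
            "lat": lat,
            "lon": lon,
        }
    )
    return pd.concat([out, env], axis=1)


def _assign_ecomorphs(n: int, rng: np.random.Generator) -> np.ndarray:
    """Ecomorph labels in study-like proportions (largest-remainder), shuffled.

    Proportional allocation keeps every sufficiently frequent class present,
    so dummy-coded designs stay full rank at realistic n.
    """
    quota = _ECOMORPH_WEIGHTS / _ECOMORPH_WEIGHTS.sum() * n
    counts = np.floor(quota).astype(int)
    for idx in np.argsort(-(quota - counts), kind="stable")[: n - counts.sum()]:
        counts[idx] += 1
    labels = np.repeat(ECOMORPHS, counts)
    return labels[rng.permutation(n)]


def _brownian_tip_values(tree: dendropy.Tree, rng: np.random.Generator) -> pd.Series:
    """Unit-rate Brownian motion along the tree; one value per tip."""
    vals: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            vals[node] = 0.0
        else:
            step = rng.standard_normal() * np.sqrt(node.edge.length or 0.0)
            vals[node] = vals[node.parent_node] + step
    return pd.Series(
        {leaf.taxon.label: vals[leaf] for leaf in tree.leaf_node_iter()}
    ).sort_index()


def _star_population_tree(
    localities: list[str], stem_length: float, n_samples: int, within_length: float
) -> tuple[dendropy.Tree, list[tuple[str, str]]]:
    """Star of locality subtrees; cross-locality patristic = 2*stem + 2*within."""
    tree = dendropy.Tree()
    tree.is_rooted = True
    root = tree.seed_node
    samples: list[tuple[str, str]] = []
    for loc in localities:
        node = root.new_child(edge_length=stem_length)
        for s in range(n_samples):
            tip = node.new_child(edge_length=within_length)
            label = f"{loc}_s{s + 1}"
            tip.taxon = tree.taxon_namespace.new_taxon(label=label)
            samples.append((label, loc))
    return tree, samples


def simulate_clade_dataset(config: SimConfig) -> SimTruth:
    """Generate a complete synthetic study under ``config``.

    Covariates (mean geographic distance, environmental heterogeneity, stem
    age) are measured with the package's own geodesy/environment/comparative
    modules, then divergence is drawn from the configured linear model and
    realized as within-species population trees.
    """
    cfg = config
    seed = cfg.seed
    chronogram = simulate_chronogram(
        cfg.n_species, cfg.birth_rate, cfg.root_age, rng=_rng(seed, _STREAM_CHRONOGRAM)
    )
    species = sorted(leaf.taxon.label for leaf in chronogram.leaf_node_iter())
    ages = species_age(chronogram, {s: s for s in species}, mode="stem")

    coeffs = _env_coefficients(_rng(seed, _STREAM_ENV_COEF))
    island = _island_box(cfg.extent_km, (21.5, -79.5))
    lo, hi = cfg.n_localities_range
    loc_frames = []
    species_locs: dict[str, list[str]] = {}
    for i, sp in enumerate(species):
        srng = _rng(seed, _STREAM_SPECIES, i)
        k = int(srng.integers(lo, hi + 1))
        ext = srng.uniform(*cfg.species_range_km)
        dlat = ext / _KM_PER_DEG
        dlon = ext / (_KM_PER_DEG * np.cos(np.radians(21.5)))
        lat_c = srng.uniform(island[0] + dlat / 2, island[1] - dlat / 2)
        lon_c = srng.uniform(island[2] + dlon / 2, island[3] - dlon / 2)
        lat = srng.uniform(lat_c - dlat / 2, lat_c + dlat / 2, k)
        lon = srng.uniform(lon_c - dlon / 2, lon_c + dlon / 2, k)
        env = _env_values(
            _standardize_coords(lat, lon, island), coeffs, cfg.env_autocorr, srng
        )
        ids = [f"{sp}_L{j + 1:02d}" for j in range(k)]
        species_locs[sp] = ids
        loc_frames.append(
            pd.concat([pd.DataFrame({"locality": ids, "lat": lat, "lon": lon}), env], axis=1)
        )
    localities = pd.concat(loc_frames, ignore_index=True)

    scores = pca_scores(localities, cfg.pca_axes)
    env_dm = env_dissimilarity(scores)
    geo_dm = geographic_matrix(localities)
    avg_geo = {sp: mean_pairwise(geo_dm, ids) for sp, ids in species_locs.items()}
    env_het = {sp: clade_env_heterogeneity(env_dm, ids) for sp, ids in species_locs.items()}

    bm = _brownian_tip_values(chronogram, _rng(seed, _STREAM_BROWNIAN))
    bm = bm / np.sqrt(cfg.root_age) * cfg.noise_sd  # marginal sd = noise_sd per tip
    white = pd.Series(
        {sp: _rng(seed, _STREAM_WHITE, i).normal(0.0, cfg.noise_sd) for i, sp in enumerate(species)}
    )
    resid = np.sqrt(cfg.lambda_signal) * bm + np.sqrt(1.0 - cfg.lambda_signal) * white
    mu = pd.Series(
        {
            sp: cfg.beta_age * ages[sp] + cfg.beta_geo * avg_geo[sp] + cfg.beta_env * env_het[sp]
            for sp in species
        }
    )
    raw = mu + resid
    if (raw < 0).mean() > 0.5:
        logger.warning(
            "configuration yields negative expected divergence for %.0f%% of species; "
            "values truncated at 0", 100 * (raw < 0).mean(),
        )
    divergence = raw.clip(lower=0.0)

    erng = _rng(seed, _STREAM_ECOMORPH)
    ecomorph = _assign_ecomorphs(len(species), erng)
    body_size = np.where(
        ecomorph == "crown-giant", erng.normal(145.0, 10.0, len(species)),
        erng.normal(50.0, 8.0, len(species)),
    )

    trees: dict[str, dendropy.Tree] = {}
    sample_rows = []
    for sp in species:
        tree, samples = _star_population_tree(
            species_locs[sp],
            stem_length=float(divergence[sp]) / 2.0,
            n_samples=cfg.samples_per_locality,
            within_length=cfg.within_locality_branch,
        )
        trees[sp] = tree
        for sample, loc in samples:
            sample_rows.append(
                {"sample": sample, "clade": sp, "locality": loc, "excluded": False, "reason": ""}
            )
    sample_map = pd.DataFrame(sample_rows, columns=["sample", "clade", "locality", "excluded", "reason"])

    clade_summary = pd.DataFrame(
        {
            "clade": species,
            "avg_divergence": [divergence[sp] for sp in species],
            "avg_geodist": [avg_geo[sp] for sp in species],
            "env_het": [env_het[sp] for sp in species],
            "age": [ages[sp] for sp in species],
            "ecomorph": ecomorph,
            "body_size": body_size,
        }
    )
    return SimTruth(
        config=cfg,
        chronogram=chronogram,
        ages=ages,
        clade_summary=clade_summary,
        population_trees=trees,
        localities=localities,
        sample_map=sample_map,
        expected_divergence=mu,
        residuals=resid,
    )


def write_dataset(truth: SimTruth, outdir: str | Path) -> dict[str, Path]:
    """Materialize a synthetic dataset as Newick + CSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trees_dir = outdir / "trees"
    trees_dir.mkdir(exist_ok=True)
    paths = {
        "chronogram": outdir / "chronogram.nwk",
        "localities": outdir / "localities.csv",
        "samples": outdir / "samples.csv",
        "clade_summary_truth": outdir / "clade_summary_truth.csv",
        "ecomorphs": outdir / "ecomorphs.csv",
        "config": outdir / "sim_config.yaml",
        "trees_dir": trees_dir,
    }
    write_newick(truth.chronogram, paths["chronogram"])
    for clade, tree in truth.population_trees.items():
        write_newick(tree, trees_dir / f"{clade}.nwk")
    truth.localities.to_csv(paths["localities"], index=False)
    truth.sample_map.to_csv(paths["samples"], index=False)
    truth.clade_summary.to_csv(paths["clade_summary_truth"], index=False)
    truth.clade_summary[["clade", "ecomorph", "body_size"]].to_csv(paths["ecomorphs"], index=False)
    cfg = asdict(truth.config)
    cfg["n_localities_range"] = list(cfg["n_localities_range"])
    cfg["species_range_km"] = list(cfg["species_range_km"])
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=True))
    return paths
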