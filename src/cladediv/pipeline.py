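"""End-to-end orchestration: from trees and tables to the final PGLS model.

The pipeline materializes every intermediate as CSV so each stage can be
re-run and checked on its own: clade divergences, geographic means,
environmental heterogeneity, species ages, the assembled clade summary, and
the full/final PGLS reports with the stepwise elimination trace.
"""
from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparative import (
    StepwiseResult,
    backward_stepwise,
    brownian_covariance,
    brownian_covariance_from_tree,
    species_age,
)
from .distance import DistanceMatrix
from .divergence import (
    CladeRules,
    apply_clade_rules,
    divergence_table,
    exclusion_report,
    read_sample_map,
    retained_clades,
)
from .environment import clade_env_heterogeneity, env_dissimilarity, pca_scores
from .geodesy import geographic_matrix, mean_pairwise
from .simulate import SimConfig, simulate_clade_dataset, write_dataset
from .trees import patristic_matrix, read_newick

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run_pipeline", "make_fixtures"]

logger = logging.getLogger(__name__)

DEFAULT_FULL_MODEL = (
    "avg_geodist",
    "age",
    "env_het",
    "ecomorph",
    "avg_geodist:age",
    "avg_geodist:env_het",
    "avg_geodist:ecomorph",
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""


@dataclass
class PipelineConfig:
    """One structured configuration for a full (real or synthetic) run."""

    out_dir: Path
    seed: int = 0
    synthetic: SimConfig | None = None
    # real-input paths (ignored in synthetic mode, which writes then reads them)
    chronogram: Path | None = None
    trees_dir: Path | None = None
    localities: Path | None = None
    samples: Path | None = None
    ecomorphs: Path | None = None
    rules: Path | None = None
    chronogram_map: Path | None = None
    species_distances: Path | None = None
    # analysis settings
    covariance_source: str = "chronogram"  # or "distances"
    pca_axes: int = 5
    age_mode: str = "stem"
    alpha: float = 0.05
    weighting: str = "locality-pairs"
    full_model: tuple[str, ...] = DEFAULT_FULL_MODEL
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.covariance_source not in ("chronogram", "distances"):
            raise ValueError("covariance_source must be 'chronogram' or 'distances'")
        self.full_model = tuple(self.full_model)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        raw.update(overrides)
        sim = raw.pop("synthetic", None)
        if sim is not None:
            if "n_localities_range" in sim:
                sim["n_localities_range"] = tuple(sim["n_localities_range"])
            if "species_range_km" in sim:
                sim["species_range_km"] = tuple(sim["species_range_km"])
            sim.setdefault("seed", raw.get("seed", 0))
            raw["synthetic"] = SimConfig(**sim)
        for key in ("out_dir", "chronogram", "trees_dir", "localities", "samples",
                    "ecomorphs", "rules", "chronogram_map", "species_distances"):
            if raw.get(key) is not None:
                p = Path(raw[key])
                raw[key] = p if p.is_absolute() else path.parent / p
        if "full_model" in raw:
            raw["full_model"] = tuple(raw["full_model"])
        return cls(**raw)


@dataclass
class PipelineResult:
    config: PipelineConfig
    clade_summary: pd.DataFrame
    stepwise: StepwiseResult
    exclusions: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


_PATH_FIELDS = ("out_dir", "chronogram", "trees_dir", "localities", "samples",
                "ecomorphs", "rules", "chronogram_map", "species_distances")


def _config_hash(cfg: PipelineConfig) -> str:
    """Hash of the analysis/simulation settings; path fields are excluded so
    identical runs into different directories hash identically."""

    def enc(v):
        if isinstance(v, SimConfig):
            return {k: enc(x) for k, x in vars(v).items()}
        if isinstance(v, tuple):
            return list(v)
        return v

    fields = {k: enc(v) for k, v in vars(cfg).items() if k not in _PATH_FIELDS}
    payload = json.dumps(fields, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage; on failure, move partial outputs to ``quarantine/``."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"

    def emit(name: str, path: Path) -> Path:
        written.append(path)
        paths[name] = path
        return path

    paths: dict[str, Path] = {}
    try:
        if cfg.synthetic is not None:
            stage = "simulate"
            truth = simulate_clade_dataset(cfg.synthetic)
            inputs = write_dataset(truth, out / "inputs")
            cfg.chronogram = inputs["chronogram"]
            cfg.trees_dir = inputs["trees_dir"]
            cfg.localities = inputs["localities"]
            cfg.samples = inputs["samples"]
            cfg.ecomorphs = inputs["ecomorphs"]

        stage = "read-inputs"
        for key in ("chronogram", "trees_dir", "localities", "samples", "ecomorphs"):
            if getattr(cfg, key) is None:
                raise PipelineError(f"stage {stage}: missing required input {key!r}")
        samples = read_sample_map(cfg.samples)
        localities = pd.read_csv(cfg.localities, dtype={"locality": str})
        chronogram = read_newick(cfg.chronogram)
        ecomorphs = pd.read_csv(cfg.ecomorphs, dtype={"clade": str})

        stage = "clade-rules"
        rules = CladeRules.from_yaml(cfg.rules) if cfg.rules else CladeRules()
        samples = apply_clade_rules(samples, rules)
        exclusions = exclusion_report(samples)
        exclusions.to_csv(emit("exclusions", out / "exclusions.csv"), index=False)
        clades = retained_clades(samples)
        if not clades:
            raise PipelineError("stage clade-rules: no clades retained")

        stage = "divergence"
        matrices = {}
        for clade in clades:
            tree_path = Path(cfg.trees_dir) / f"{clade}.nwk"
            if not tree_path.exists():
                raise PipelineError(f"stage divergence: no tree for clade {clade!r} at {tree_path}")
            matrices[clade] = patristic_matrix(read_newick(tree_path))
        div = divergence_table(matrices, samples, weighting=cfg.weighting)
        div.to_csv(emit("divergence", out / "clade_divergence.csv"), index=False)

        stage = "geodesy"
        geo_dm = geographic_matrix(localities)
        geo_dm.to_csv(emit("geo_matrix", out / "geo_matrix.csv"))
        active = samples[~samples["excluded"]]
        clade_locs = {c: sorted(g["locality"].unique()) for c, g in active.groupby("clade")}
        geo = pd.DataFrame(
            {"clade": clades, "avg_geodist": [mean_pairwise(geo_dm, clade_locs[c]) for c in clades]}
        )
        geo.to_csv(emit("geo", out / "clade_geodist.csv"), index=False)

        stage = "environment"
        scores = pca_scores(localities, cfg.pca_axes)
        scores.scores.to_csv(emit("env_scores", out / "env_scores.csv"))
        env_dm = env_dissimilarity(scores)
        env = pd.DataFrame(
            {
                "clade": clades,
                "env_het": [clade_env_heterogeneity(env_dm, clade_locs[c]) for c in clades],
            }
        )
        env.to_csv(emit("env", out / "clade_env_het.csv"), index=False)

        stage = "ages"
        if cfg.chronogram_map:
            cmap_df = pd.read_csv(cfg.chronogram_map, dtype=str)
            clade_map = dict(zip(cmap_df["tip"], cmap_df["clade"]))
        else:
            tips = {leaf.taxon.label for leaf in chronogram.leaf_node_iter()}
            missing = sorted(set(clades) - tips)
            if missing:
                raise PipelineError(
                    f"stage ages: clades absent from chronogram tips: {missing} "
                    "(provide chronogram_map)"
                )
            clade_map = {c: c for c in clades}
        clade_map = {tip: cl for tip, cl in clade_map.items() if cl in clades}
        ages = species_age(chronogram, clade_map, mode=cfg.age_mode)
        ages.rename("age").to_frame().to_csv(emit("ages", out / "clade_ages.csv"), index_label="clade")

        stage = "assemble"
        summary = (
            div[["clade", "n_localities", "avg_divergence"]]
            .merge(geo, on="clade")
            .merge(env, on="clade")
            .merge(ages.rename("age"), left_on="clade", right_index=True)
            .merge(ecomorphs, on="clade", how="left")
        )
        if summary["ecomorph"].isna().any():
            bad = sorted(summary.loc[summary["ecomorph"].isna(), "clade"])
            raise PipelineError(f"stage assemble: no ecomorph assignment for clades {bad}")
        summary.to_csv(emit("clade_summary", out / "clade_summary.csv"), index=False)

        stage = "covariance"
        if cfg.covariance_source == "chronogram":
            cov = brownian_covariance_from_tree(chronogram, clade_map)
        else:
            if cfg.species_distances is None:
                raise PipelineError("stage covariance: species_distances path required")
            dm = DistanceMatrix.from_csv(cfg.species_distances).submatrix(clades)
            cov = brownian_covariance(dm)
        cov = cov.submatrix(sorted(clades))

        stage = "pgls"
        step = backward_stepwise(
            summary, list(cfg.full_model), cov, alpha=cfg.alpha, response="avg_divergence"
        )
        _coef_table(step.full).to_csv(emit("full_model", out / "full_model.tsv"), sep="\t", index=False)
        step.full.anova.to_csv(emit("full_anova", out / "full_anova.tsv"), sep="\t", index=False)
        _coef_table(step.final).to_csv(emit("final_model", out / "final_model.tsv"), sep="\t", index=False)
        step.final.anova.to_csv(emit("final_anova", out / "final_anova.tsv"), sep="\t", index=False)
        step.trace.to_csv(emit("trace", out / "elimination_trace.tsv"), sep="\t", index=False)
        summary_txt = "\n\n".join(
            ["=== Full model ===", step.full.summary(), "=== Final model ===", step.final.summary()]
        )
        emit("summary_txt", out / "summary.txt").write_text(summary_txt + "\n")

        stage = "metadata"
        meta = {
            "config_hash": _config_hash(cfg),
            "seed": cfg.seed,
            "cladediv_version": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "n_clades": len(clades),
            "final_terms": list(step.final.terms),
        }
        emit("metadata", out / "run_metadata.json").write_text(json.dumps(meta, indent=2) + "\n")
    except Exception as exc:
        qdir = out / "quarantine"
        qdir.mkdir(exist_ok=True)
        for p in written:
            if p.exists():
                shutil.move(str(p), qdir / p.name)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    return PipelineResult(
        config=cfg, clade_summary=summary, stepwise=step, exclusions=exclusions, paths=paths
    )


def _coef_table(fit) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "coef": fit.params.index,
            "estimate": fit.params.to_numpy(),
            "std_error": fit.bse.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )


FIXTURE_FULL_MODEL = ("avg_geodist", "age", "env_het", "avg_geodist:age")


def make_fixtures(outdir: str | Path, seed: int = 20) -> dict[str, Path]:
    """Write a small worked dataset (8 clades, ~25 localities) plus the
    pipeline outputs it produces, for integration tests and examples."""
    outdir = Path(outdir)
    sim = SimConfig(n_species=8, n_localities_range=(3, 4), seed=seed)
    cfg = PipelineConfig(
        out_dir=outdir / "expected",
        seed=seed,
        synthetic=sim,
        full_model=FIXTURE_FULL_MODEL,
    )
    result = run_pipeline(cfg)
    paths = dict(result.paths)
    paths["dataset"] = outdir / "expected" / "inputs"
    return paths
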