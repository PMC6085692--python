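"""Clade membership rules and among-population genetic divergence.

The sample map links each sequenced individual to a clade (usually a
species, sometimes a monophyletic subdivision of one) and a sampling
locality. Clade rules encode the curation steps typical of this kind of
comparative study: splitting a paraphyletic species into monophyletic
clades, excluding putative hybrids, and dropping clades sampled at fewer
than a minimum number of localities (default 3).

A clade's average genetic divergence is computed from a patristic distance
matrix over its samples: for every unordered pair of localities, the mean
distance over all cross-locality sample pairs; the clade average is the
unweighted mean of those locality-pair means. Within-locality pairs never
enter the average — divergence is an among-population quantity.
"""
from __future__ import annotations

import itertools
import logging
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .distance import DistanceMatrix

__all__ = [
    "SAMPLE_COLUMNS",
    "CladeRuleError",
    "CladeExcludedError",
    "CladeSplit",
    "CladeRules",
    "CladeDivergence",
    "read_sample_map",
    "write_sample_map",
    "apply_clade_rules",
    "exclusion_report",
    "retained_clades",
    "locality_mean_divergence",
    "divergence_table",
]

logger = logging.getLogger(__name__)

SAMPLE_COLUMNS = ("sample", "clade", "locality", "excluded", "reason")


class CladeRuleError(ValueError):
    """A rule references unknown species, samples, or localities."""


class CladeExcludedError(ValueError):
    """An operation was requested on a clade flagged as excluded."""


def read_sample_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample": str, "clade": str, "locality": str})
    return normalize_sample_map(df)


def normalize_sample_map(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in ("sample", "clade", "locality"):
        if col not in df.columns:
            raise ValueError(f"sample map missing column {col!r}")
        df[col] = df[col].astype(str)
        if (df[col] == "").any():
            raise ValueError(f"empty values in sample map column {col!r}")
    if df["sample"].duplicated().any():
        raise ValueError("duplicate sample ids in sample map")
    if "excluded" not in df.columns:
        df["excluded"] = False
    df["excluded"] = df["excluded"].fillna(False).astype(bool)
    if "reason" not in df.columns:
        df["reason"] = ""
    df["reason"] = df["reason"].fillna("").astype(str)
    if (df["excluded"] & (df["reason"] == "")).any():
        raise ValueError("every excluded sample needs a reason")
    return df[list(SAMPLE_COLUMNS)]


def write_sample_map(df: pd.DataFrame, path: str | Path) -> None:
    normalize_sample_map(df).to_csv(path, index=False)


@dataclass(frozen=True)
class CladeSplit:
    """Split one species' samples into named clades by locality sets."""

    species: str
    clades: Mapping[str, frozenset[str]]


@dataclass(frozen=True)
class CladeRules:
    splits: tuple[CladeSplit, ...] = ()
    exclude_samples: Mapping[str, str] = field(default_factory=dict)  # sample -> reason
    exclude_clades: Mapping[str, str] = field(default_factory=dict)  # clade -> reason
    min_localities: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CladeRules":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        splits = tuple(
            CladeSplit(
                species=str(s["species"]),
                clades={
                    str(name): frozenset(str(x) for x in locs)
                    for name, locs in s["clades"].items()
                },
            )
            for s in raw.get("splits", [])
        )
        return cls(
            splits=splits,
            exclude_samples={
                str(e["sample"]): str(e.get("reason", "excluded")) for e in raw.get("exclude_samples", [])
            },
            exclude_clades={
                str(e["clade"]): str(e.get("reason", "excluded")) for e in raw.get("exclude_clades", [])
            },
            min_localities=int(raw.get("min_localities", 3)),
        )


def apply_clade_rules(samples: pd.DataFrame, rules: CladeRules) -> pd.DataFrame:
    """Return a new sample map with splits applied and exclusions flagged.

    After sample/clade exclusions, any clade left with fewer than
    ``rules.min_localities`` distinct sampled localities is flagged excluded
    with reason ``"min-localities"``.
    """
    out = normalize_sample_map(samples)
    for split in rules.splits:
        mask = out["clade"] == split.species
        if not mask.any():
            raise CladeRuleError(f"split references unknown species {split.species!r}")
        known = set(out.loc[mask, "locality"])
        loc_to_clade: dict[str, str] = {}
        for new_clade, locs in split.clades.items():
            unknown = locs - known
            if unknown:
                raise CladeRuleError(
                    f"split of {split.species!r} references unknown localities {sorted(unknown)}"
                )
            for loc in locs:
                loc_to_clade[loc] = new_clade
        uncovered = known - set(loc_to_clade)
        if uncovered:
            raise CladeRuleError(
                f"split of {split.species!r} leaves localities unassigned: {sorted(uncovered)}"
            )
        out.loc[mask, "clade"] = out.loc[mask, "locality"].map(loc_to_clade)
    for sample, reason in rules.exclude_samples.items():
        mask = out["sample"] == sample
        if not mask.any():
            raise CladeRuleError(f"exclusion references unknown sample {sample!r}")
        out.loc[mask, ["excluded", "reason"]] = [True, reason]
    for clade, reason in rules.exclude_clades.items():
        mask = out["clade"] == clade
        if not mask.any():
            raise CladeRuleError(f"exclusion references unknown clade {clade!r}")
        out.loc[mask, ["excluded", "reason"]] = [True, f"excluded-clade: {reason}"]
    active = out[~out["excluded"]]
    n_loc = active.groupby("clade")["locality"].nunique()
    for clade in n_loc.index[n_loc < rules.min_localities]:
        mask = (out["clade"] == clade) & ~out["excluded"]
        out.loc[mask, ["excluded", "reason"]] = [True, "min-localities"]
        logger.warning(
            "clade %s excluded: %d localities < %d required",
            clade, int(n_loc[clade]), rules.min_localities,
        )
    return out


def exclusion_report(samples: pd.DataFrame) -> pd.DataFrame:
    """One row per clade: retained flag plus the exclusion reasons seen."""
    rows = []
    for clade, grp in samples.groupby("clade", sort=True):
        retained = bool((~grp["excluded"]).any())
        reasons = sorted(set(grp.loc[grp["excluded"], "reason"]))
        rows.append({"clade": clade, "retained": retained, "reasons": "; ".join(reasons)})
    return pd.DataFrame(rows, columns=["clade", "retained", "reasons"])


def retained_clades(samples: pd.DataFrame) -> list[str]:
    return sorted(samples.loc[~samples["excluded"], "clade"].unique())


@dataclass(frozen=True)
class CladeDivergence:
    """Average between-locality divergence for one clade."""

    clade: str
    n_localities: int
    pair_means: pd.DataFrame  # columns: locality_a, locality_b, mean_distance, n_sample_pairs
    avg_divergence: float
    n_sample_pairs: int


def locality_mean_divergence(
    dm: DistanceMatrix,
    samples: pd.DataFrame,
    clade: str,
    *,
    weighting: str = "locality-pairs",
) -> CladeDivergence:
    """Average between-locality patristic distance for one clade.

    ``weighting="locality-pairs"`` (default) averages the locality-pair means
    with equal weight; ``"sample-pairs"`` averages all cross-locality sample
    pairs directly, weighting locality pairs by their sample-pair counts.
    """
    if weighting not in ("locality-pairs", "sample-pairs"):
        raise ValueError(f"unknown weighting {weighting!r}")
    sub = samples[samples["clade"] == clade]
    if sub.empty:
        raise KeyError(f"no samples for clade {clade!r}")
    active = sub[~sub["excluded"]]
    if active.empty:
        reasons = "; ".join(sorted(set(sub["reason"])))
        raise CladeExcludedError(f"clade {clade!r} is excluded ({reasons})")
    by_loc = {loc: list(grp["sample"]) for loc, grp in active.groupby("locality", sort=True)}
    if len(by_loc) < 2:
        raise ValueError(f"clade {clade!r} has fewer than 2 sampled localities")
    rows = []
    for loc_a, loc_b in itertools.combinations(sorted(by_loc), 2):
        vals = [dm[i, j] for i in by_loc[loc_a] for j in by_loc[loc_b]]
        rows.append(
            {
                "locality_a": loc_a,
                "locality_b": loc_b,
                "mean_distance": sum(vals) / len(vals),
                "n_sample_pairs": len(vals),
            }
        )
    pair_means = pd.DataFrame(rows)
    if weighting == "locality-pairs":
        avg = float(pair_means["mean_distance"].mean())
    else:
        avg = float(
            (pair_means["mean_distance"] * pair_means["n_sample_pairs"]).sum()
            / pair_means["n_sample_pairs"].sum()
        )
    return CladeDivergence(
        clade=clade,
        n_localities=len(by_loc),
        pair_means=pair_means,
        avg_divergence=avg,
        n_sample_pairs=int(pair_means["n_sample_pairs"].sum()),
    )


def divergence_table(
    matrices: Mapping[str, DistanceMatrix],
    samples: pd.DataFrame,
    *,
    weighting: str = "locality-pairs",
) -> pd.DataFrame:
    """Per-clade divergence summary over clade-keyed patristic matrices."""
    rows = []
    for clade in retained_clades(samples):
        if clade not in matrices:
            raise KeyError(f"no distance matrix for retained clade {clade!r}")
        cd = locality_mean_divergence(matrices[clade], samples, clade, weighting=weighting)
        rows.append(
            {
                "clade": clade,
                "n_localities": cd.n_localities,
                "avg_divergence": cd.avg_divergence,
                "n_pairs": cd.n_sample_pairs,
            }
        )
    return pd.DataFrame(rows, columns=["clade", "n_localities", "avg_divergence", "n_pairs"])
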