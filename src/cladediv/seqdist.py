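"""Pairwise nucleotide distances between aligned sequences.

Selectable models: uncorrected p-distance, Jukes–Cantor (JC69) and Kimura
two-parameter (K2P). Columns containing gaps or ambiguous bases are removed
before counting, either across the whole alignment (``deletion="complete"``,
the default) or per pair (``"pairwise"``).
"""
from __future__ import annotations

import itertools
import math
from collections.abc import Mapping
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .distance import DistanceMatrix

__all__ = ["DistanceModelError", "read_fasta_alignment", "sequence_distance"]

_VALID = set("ACGT-N")
_PURINES = ("A", "G")
_PYRIMIDINES = ("C", "T")


class DistanceModelError(ValueError):
    """Raised when a distance model is undefined for a sequence pair."""


def read_fasta_alignment(path: str | Path) -> dict[str, str]:
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def _encode(alignment: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    names = list(alignment)
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError(f"sequences are not aligned: lengths {sorted(lengths)}")
    arr = np.array([list(alignment[n].upper()) for n in names])
    bad = set(arr.ravel()) - _VALID
    if bad:
        raise ValueError(f"invalid characters in alignment: {sorted(bad)}")
    return names, arr


def _pair_distance(a: np.ndarray, b: np.ndarray, model: str, pair: tuple[str, str]) -> float:
    ok = np.isin(a, list("ACGT")) & np.isin(b, list("ACGT"))
    n_sites = int(ok.sum())
    if n_sites == 0:
        raise DistanceModelError(f"no shared ungapped sites for pair {pair}")
    a, b = a[ok], b[ok]
    diff = a != b
    p = float(diff.sum()) / n_sites
    if model == "p":
        return p
    if model == "JC69":
        arg = 1.0 - 4.0 * p / 3.0
        if arg <= 0.0:
            raise DistanceModelError(f"JC69 undefined for pair {pair} (p={p:.4f})")
        return -0.75 * math.log(arg)
    if model == "K2P":
        transitions = diff & (
            (np.isin(a, _PURINES) & np.isin(b, _PURINES))
            | (np.isin(a, _PYRIMIDINES) & np.isin(b, _PYRIMIDINES))
        )
        pr = float(transitions.sum()) / n_sites
        q = p - pr
        arg1 = 1.0 - 2.0 * pr - q
        arg2 = 1.0 - 2.0 * q
        if arg1 <= 0.0 or arg2 <= 0.0:
            raise DistanceModelError(f"K2P undefined for pair {pair} (P={pr:.4f}, Q={q:.4f})")
        return -0.5 * math.log(arg1) - 0.25 * math.log(arg2)
    raise ValueError(f"unknown model {model!r}; choose from 'p', 'JC69', 'K2P'")


def sequence_distance(
    alignment: Mapping[str, str] | str | Path,
    model: str = "JC69",
    *,
    deletion: str = "complete",
) -> DistanceMatrix:
    """Pairwise distance matrix from an aligned set of sequences.

    ``deletion="complete"`` removes every column containing a gap or N in any
    sequence before any pair is compared; ``"pairwise"`` removes such columns
    per pair only.
    """
    if not isinstance(alignment, Mapping):
        alignment = read_fasta_alignment(alignment)
    if deletion not in ("complete", "pairwise"):
        raise ValueError(f"unknown deletion mode {deletion!r}")
    names, arr = _encode(alignment)
    if deletion == "complete":
        keep = np.all(np.isin(arr, list("ACGT")), axis=0)
        arr = arr[:, keep]
    n = len(names)
    d = np.zeros((n, n), dtype=float)
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = _pair_distance(arr[i], arr[j], model, (names[i], names[j]))
    return DistanceMatrix(tuple(names), d)
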