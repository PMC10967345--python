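"""Factorial-deviation ranking, percent-change conversion and cross-paradigm scoring.

A usage ratio R measures accumulation (R > 1) or depletion (R < 1)
relative to a reference. The factorial deviation d = max(R, 1/R) treats
both directions symmetrically, so a halving and a doubling are equally
strong effects. Amino acids are ranked per paradigm by decreasing d
(rank 1 = strongest effect); the four strongest per paradigm are flagged,
and amino acids flagged in at least two paradigms receive a cross-paradigm
hash mark.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._aa import AMINO_ACIDS
from .errors import ConfigurationError, DataError


def factorial_distance(ratio: float) -> float:
    """Distance of a positive ratio from unity: d = max(R, 1/R)."""
    if math.isnan(ratio):
        return math.nan
    if ratio <= 0:
        raise DataError(f"ratio must be positive, got {ratio}")
    return max(ratio, 1.0 / ratio)


def direction(ratio: float) -> str:
    """'up' for accumulation, 'down' for depletion, 'neutral' at unity."""
    if math.isnan(ratio):
        return "undefined"
    if ratio > 1:
        return "up"
    if ratio < 1:
        return "down"
    return "neutral"


@dataclass
class RankVector:
    """Per-amino-acid ranks by factorial deviation, 1 = largest deviation."""

    ranks: dict[str, int]
    distances: dict[str, float]
    directions: dict[str, str]
    tied: set[str] = field(default_factory=set)

    def tie_groups(self, tolerance: float = 0.0) -> list[set[str]]:
        """Maximal groups of amino acids whose distances chain within `tolerance`.

        Useful when ranking printed (rounded) ratios: amino acids whose
        unrounded deviations differed below printing precision appear here
        as groups within which the published rank order is not recoverable.
        """
        defined = [(aa, d) for aa, d in self.distances.items()
                   if not math.isnan(d)]
        defined.sort(key=lambda kv: -kv[1])
        groups: list[list[tuple[str, float]]] = []
        for aa, d in defined:
            if groups and groups[-1][-1][1] - d <= tolerance:
                groups[-1].append((aa, d))
            else:
                groups.append([(aa, d)])
        return [{aa for aa, _ in g} for g in groups]


def rank_amino_acids(ratios: Mapping[str, float]) -> RankVector:
    """Rank amino acids by decreasing factorial deviation from unity.

    Exact ties are broken alphabetically and tie-marked; undefined ratios
    (NaN) are ranked last.
    """
    dists = {aa: factorial_distance(r) for aa, r in ratios.items()}
    if all(math.isnan(d) for d in dists.values()):
        raise DataError("no defined ratios to rank")
    order = sorted(dists, key=lambda aa: (math.isnan(dists[aa]),
                                          -dists[aa] if not math.isnan(dists[aa]) else 0.0,
                                          aa))
    ranks = {aa: i + 1 for i, aa in enumerate(order)}
    by_value: dict[float, list[str]] = {}
    for aa, d in dists.items():
        if not math.isnan(d):
            by_value.setdefault(d, []).append(aa)
    tied = {aa for group in by_value.values() if len(group) > 1 for aa in group}
    dirs = {aa: direction(r) for aa, r in ratios.items()}
    return RankVector(ranks=ranks, distances=dists, directions=dirs, tied=tied)


def percent_change(ratio: float) -> int:
    """Signed integer percent change 100*(R-1), rounded half away from zero."""
    if math.isnan(ratio):
        raise DataError("cannot convert an undefined ratio to percent change")
    if ratio <= 0:
        raise DataError(f"ratio must be positive, got {ratio}")
    raw = 100.0 * (ratio - 1.0)
    # epsilon guards against binary representation of decimal ratios
    # (e.g. 1.005 - 1 = 0.00499...) flipping the half-away rounding
    return int(math.copysign(math.floor(abs(raw) + 0.5 + 1e-9), raw))


def format_percent(value: int) -> str:
    """Render a percent change with an explicit sign (``+114``, ``-59``, ``0``)."""
    return f"{value:+d}" if value else "0"


@dataclass
class ScoreFlags:
    """Top-4 flags per paradigm and cross-paradigm hash flags."""

    top4: dict[str, set[str]]      # paradigm -> amino acids among 4 strongest
    significant: dict[str, set[str]]  # paradigm -> top4 with p < threshold
    hash_set: set[str]             # top-4 in >= 2 paradigms


def score_tables(
    ratio_tables: Mapping[str, Mapping[str, float]],
    p_tables: Mapping[str, Mapping[str, float]] | None = None,
    p_threshold: float = 1e-3,
    percent_subset: Sequence[str] = ("C", "M", "W", "Y"),
) -> tuple[ScoreFlags, pd.DataFrame, pd.DataFrame]:
    """Cross-paradigm scoring of several ratio tables.

    Returns the flag set, a rank matrix (amino acid x paradigm) and a
    percent-change matrix for `percent_subset` (default: the redox-active
    amino acids C, M, W and Y).
    """
    if len(ratio_tables) < 1:
        raise ConfigurationError("score_tables needs at least one paradigm")
    rank_matrix = {}
    top4: dict[str, set[str]] = {}
    significant: dict[str, set[str]] = {}
    for pid, ratios in ratio_tables.items():
        rv = rank_amino_acids(ratios)
        rank_matrix[pid] = rv.ranks
        top4[pid] = {aa for aa, r in rv.ranks.items() if r <= 4}
        if p_tables is not None and pid in p_tables:
            significant[pid] = {aa for aa in top4[pid]
                                if p_tables[pid].get(aa, 1.0) < p_threshold}
        else:
            significant[pid] = set()
    counts: dict[str, int] = {}
    for aas in top4.values():
        for aa in aas:
            counts[aa] = counts.get(aa, 0) + 1
    hash_set = {aa for aa, n in counts.items() if n >= 2}
    flags = ScoreFlags(top4=top4, significant=significant, hash_set=hash_set)
    ranks_df = pd.DataFrame(rank_matrix, index=list(AMINO_ACIDS))
    pct = {pid: {aa: percent_change(ratios[aa]) for aa in percent_subset}
           for pid, ratios in ratio_tables.items()}
    pct_df = pd.DataFrame(pct, index=list(percent_subset))
    return flags, ranks_df, pct_df
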