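"""Per-species paradigm comparisons, cross-species averaging and group statistics.

A paradigm contrasts an oxidant-exposed protein set (numerator) with a
reference set (denominator). Within-species paradigms (peroxisome,
mitochondrion, respiratory chain) form one TMD-normalized usage-ratio
vector per species and average across species; group paradigms
(aerobicity and the prokaryote comparisons) divide the mean frequencies
of two species groups directly, without TMD normalization. Per-amino-acid
significance comes from Kruskal-Wallis rank tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._aa import AMINO_ACIDS
from .composition import CPolicy, SegmentedComposition, normalized_usage_ratio
from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParadigmSpec:
    """Definition of one comparison paradigm.

    For within-species paradigms `numerator` and `denominator` name
    compartments; for group paradigms `group_a` (oxidative condition, by
    convention the numerator) and `group_b` name species-group labels.
    """

    id: str
    numerator: str = ""
    denominator: str = ""
    group_a: str = ""
    group_b: str = ""
    tmd_normalize: bool = False

    @property
    def is_group_paradigm(self) -> bool:
        return bool(self.group_a)


#: The study's paradigm set: oxidative condition in the numerator, TMD
#: normalization for the within-species compartment comparisons only.
DEFAULT_PARADIGMS: dict[str, ParadigmSpec] = {
    "I": ParadigmSpec(id="I", numerator="peroxisome", denominator="whole",
                      tmd_normalize=True),
    "II": ParadigmSpec(id="II", numerator="mitochondrion", denominator="whole",
                       tmd_normalize=True),
    "III": ParadigmSpec(id="III", numerator="respiratory_chain",
                        denominator="mitochondrion", tmd_normalize=True),
    "V": ParadigmSpec(id="V", group_a="aerobic", group_b="anaerobic"),
}


def species_ratio_table(
    spec: ParadigmSpec,
    compositions: Mapping[str, Mapping[str, SegmentedComposition]],
    c_policy: CPolicy = "mean",
) -> pd.DataFrame:
    """One usage-ratio vector per species for a within-species paradigm.

    `compositions` maps species id -> compartment -> SegmentedComposition.
    Species lacking either protein set are excluded with a warning.
    Returns a DataFrame (species x amino acid); NaN marks undefined ratios.
    """
    if spec.is_group_paradigm:
        raise ConfigurationError(
            f"paradigm {spec.id} is a group paradigm; use group_ratio")
    rows = {}
    for sid, comps in compositions.items():
        if spec.numerator not in comps or spec.denominator not in comps:
            logger.warning("species %s lacks %s or %s; excluded from paradigm %s",
                           sid, spec.numerator, spec.denominator, spec.id)
            continue
        policy = c_policy if spec.tmd_normalize else 0.0
        if spec.tmd_normalize:
            rv = normalized_usage_ratio(comps[spec.numerator],
                                        comps[spec.denominator],
                                        c_policy=policy)
            rows[sid] = rv.ratios
        else:
            f_num = comps[spec.numerator].raw_freqs()
            f_den = comps[spec.denominator].raw_freqs()
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.where((f_den > 0) & (f_num > 0), f_num / f_den, np.nan)
            rows[sid] = r
    if not rows:
        raise DataError(f"no species usable for paradigm {spec.id}")
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(AMINO_ACIDS))


def average_ratios(table: pd.DataFrame,
                   mode: Literal["arith", "geom"] = "arith") -> pd.Series:
    """Average per-species ratios over species, per amino acid.

    The default is the arithmetic mean on the ratio scale; the geometric
    mean is available since ratios combine multiplicatively. Undefined
    (NaN) per-species entries are skipped; an all-undefined amino acid
    stays NaN.
    """
    if mode == "arith":
        return table.mean(axis=0, skipna=True)
    if mode == "geom":
        return np.exp(np.log(table).mean(axis=0, skipna=True))
    raise ConfigurationError(f"unknown averaging mode {mode!r}")


def group_ratio(freqs_a: pd.DataFrame, freqs_b: pd.DataFrame) -> pd.Series:
    """Effect-size ratios mean_A(f_a) / mean_B(f_a) between two species groups.

    Group A is the oxidative condition by convention. Frequencies are raw
    (un-normalized); each group needs at least one species.
    """
    if len(freqs_a) == 0 or len(freqs_b) == 0:
        raise DataError("both groups must be non-empty")
    mean_a = freqs_a.mean(axis=0)
    mean_b = freqs_b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = mean_a / mean_b
    return r.where(mean_b > 0, np.nan)


def kruskal_wallis(values_a: Sequence[float], values_b: Sequence[float],
                   exact: bool = False,
                   mid_p: bool = False) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and p value for two samples.

    The p value comes from the chi-square approximation with 1 degree of
    freedom, or from full permutation enumeration when ``exact=True``
    (feasible for small samples, n <= ~10 per group). The exact p is
    inclusive, P(H >= h_obs); ``mid_p=True`` instead counts half of the
    probability atom at the observed H. For tiny samples the discrete
    null carries large atoms, and a continuous approximation can only be
    expected to land within the interval [mid-p, inclusive-p]. Identical
    samples yield H = 0, p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("each sample needs at least 2 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h_obs, p_chi2 = stats.kruskal(a, b)
    if not exact:
        return float(h_obs), float(p_chi2)
    n = pooled.size
    greater = 0
    equal = 0
    total = 0
    for combo in combinations(range(n), a.size):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        h = _kw_h(pooled[mask], pooled[~mask])
        total += 1
        if h > h_obs + 1e-12:
            greater += 1
        elif h >= h_obs - 1e-12:
            equal += 1
    if mid_p:
        return float(h_obs), (greater + 0.5 * equal) / total
    return float(h_obs), (greater + equal) / total


def _kw_h(a: np.ndarray, b: np.ndarray) -> float:
    """Tie-corrected Kruskal-Wallis H for two samples (internal)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n = pooled.size
    ra = ranks[:a.size].sum()
    rb = ranks[a.size:].sum()
    h = 12.0 / (n * (n + 1)) * (ra**2 / a.size + rb**2 / b.size) - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    if tie_corr == 0:
        return 0.0
    return h / tie_corr


def paradigm_result(
    spec: ParadigmSpec,
    compositions: Mapping[str, Mapping[str, SegmentedComposition]],
    c_policy: CPolicy = "mean",
    avg_mode: Literal["arith", "geom"] = "arith",
) -> pd.DataFrame:
    """Mean ratio and per-amino-acid Kruskal-Wallis p for a within-species paradigm.

    The mean ratio averages the per-species TMD-normalized ratios. The p
    value treats, per amino acid, the per-species frequencies of the
    numerator sets and of the denominator sets (both at the common TMD
    content of each species pair) as two samples of n species each and
    applies the Kruskal-Wallis rank test.
    """
    table = species_ratio_table(spec, compositions, c_policy=c_policy)
    means = average_ratios(table, mode=avg_mode)
    from .composition import blended_freqs  # local import to avoid cycle noise
    freqs_num, freqs_den = [], []
    for sid in table.index:
        comps = compositions[sid]
        num, den = comps[spec.numerator], comps[spec.denominator]
        if spec.tmd_normalize:
            c, _ = _common_c(num, den, c_policy)
            freqs_num.append(blended_freqs(num, c))
            freqs_den.append(blended_freqs(den, c))
        else:
            freqs_num.append(num.raw_freqs())
            freqs_den.append(den.raw_freqs())
    fa = np.array(freqs_num)
    fb = np.array(freqs_den)
    pvals = {}
    for i, aa in enumerate(AMINO_ACIDS):
        if fa.shape[0] < 2:
            pvals[aa] = np.nan
        else:
            _, p = kruskal_wallis(fa[:, i], fb[:, i])
            pvals[aa] = p
    out = pd.DataFrame({"ratio": means, "p": pd.Series(pvals),
                        "n": table.notna().sum(axis=0)})
    out.index.name = "amino_acid"
    return out


def _common_c(num: SegmentedComposition, den: SegmentedComposition,
              c_policy: CPolicy) -> tuple[float, str]:
    from .composition import _resolve_c
    return _resolve_c(num, den, c_policy)


def group_paradigm_result(freqs_a: pd.DataFrame,
                          freqs_b: pd.DataFrame) -> pd.DataFrame:
    """Effect-size ratios with per-amino-acid Kruskal-Wallis p for two groups."""
    ratios = group_ratio(freqs_a, freqs_b)
    pvals = {}
    for aa in freqs_a.columns:
        va = freqs_a[aa].dropna().to_numpy()
        vb = freqs_b[aa].dropna().to_numpy()
        if va.size < 2 or vb.size < 2:
            pvals[aa] = np.nan
        else:
            _, p = kruskal_wallis(va, vb)
            pvals[aa] = p
    out = pd.DataFrame({"ratio": ratios, "p": pd.Series(pvals),
                        "n_a": freqs_a.notna().sum(axis=0),
                        "n_b": freqs_b.notna().sum(axis=0)})
    out.index.name = "amino_acid"
    return out
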