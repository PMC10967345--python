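"""Lifespan association analyses.

Lifespan correlates of amino-acid usage are assessed four ways, mirroring
standard comparative-biology practice:

* log-log Pearson correlation of usage (ratios or frequencies) with
  lifespan in years;
* first-order partial correlation controlling for body mass, the dominant
  allometric predictor of lifespan;
* phylogenetically independent contrasts (Felsenstein pruning) followed by
  through-origin correlation, removing shared-ancestry covariance;
* a multilinear fit of log lifespan on all 20 frequencies, summarized as
  fractional contributions q (in %) per amino acid;

plus a median-longevity split that compares group mean frequencies
directly as effect-size ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from ._aa import AMINO_ACIDS
from .errors import ConfigurationError, DataError


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def loglog_pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation of log x with log y (two-sided t-test p value).

    Both variables must be strictly positive; the log base is irrelevant
    to r and p. Zero variance in either log-variable is rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be 1-d arrays of equal length")
    if x.size < 3:
        raise DataError("need at least 3 observations")
    if (x <= 0).any() or (y <= 0).any():
        raise DataError("log-log correlation requires strictly positive values")
    lx, ly = np.log10(x), np.log10(y)
    if np.ptp(lx) == 0 or np.ptp(ly) == 0:
        raise DataError("zero variance after log transform; r undefined")
    r, p = stats.pearsonr(lx, ly)
    return CorrelationResult(r=float(r), p=float(p), n=x.size)


def partial_correlation(x: Sequence[float], y: Sequence[float],
                        z: Sequence[float]) -> CorrelationResult:
    """First-order partial correlation of x and y controlling for z.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)); the p
    value uses a t distribution with n - 3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = x.size
    if n < 4:
        raise DataError("partial correlation needs at least 4 observations")
    r_xy = stats.pearsonr(x, y)[0]
    r_xz = stats.pearsonr(x, z)[0]
    r_yz = stats.pearsonr(y, z)[0]
    denom = (1 - r_xz**2) * (1 - r_yz**2)
    if denom <= 0:
        raise DataError("control variable collinear with x or y; "
                        "partial correlation undefined")
    r = (r_xy - r_xz * r_yz) / math.sqrt(denom)
    r = max(-1.0, min(1.0, r))
    df = n - 3
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1 - r**2))
        p = 2 * stats.t.sf(abs(t), df)
    return CorrelationResult(r=float(r), p=float(p), n=n)


@dataclass
class ContrastSet:
    """Standardized independent contrasts with their standardizing variances."""

    contrasts: np.ndarray
    variances: np.ndarray          # b_i + b_j per contrast
    node_labels: list[str]
    polytomies_resolved: bool = False


def pic_contrasts(tree: dendropy.Tree,
                  tip_values: dict[str, float]) -> ContrastSet:
    """Felsenstein's phylogenetically independent contrasts.

    At each internal node of the (cloned, bifurcated) tree the contrast is
    (x_i - x_j) / sqrt(b_i + b_j); the ancestral value is the
    branch-length-weighted mean of the daughters and the parent branch is
    lengthened by b_i b_j / (b_i + b_j). Daughters are ordered by their
    smallest descendant tip label, fixing the contrast signs. Polytomies
    are resolved as zero-length ladders and flagged. Tip values are
    expected already log-transformed by the caller where appropriate.
    """
    work = tree.clone(depth=1)
    tips = [leaf.taxon.label for leaf in work.leaf_node_iter()]
    missing = set(tips) - set(tip_values)
    if missing:
        raise DataError(f"missing tip values for {sorted(missing)}")
    had_polytomy = any(len(nd.child_nodes()) > 2
                       for nd in work.preorder_internal_node_iter())
    if had_polytomy:
        work.resolve_polytomies()

    contrasts: list[float] = []
    variances: list[float] = []
    labels: list[str] = []
    # postorder pruning; store (value, adjusted branch length, min tip label)
    state: dict[int, tuple[float, float, str]] = {}
    for node in work.postorder_node_iter():
        edge_len = node.edge.length if node.edge.length is not None else 0.0
        if node.is_leaf():
            state[id(node)] = (tip_values[node.taxon.label], edge_len,
                              node.taxon.label)
            continue
        children = node.child_nodes()
        if len(children) != 2:  # root of a resolved ladder may be unary
            if len(children) == 1:
                x, v, lbl = state[id(children[0])]
                state[id(node)] = (x, v + edge_len, lbl)
                continue
            raise DataError("tree could not be reduced to bifurcations")
        c1, c2 = sorted(children, key=lambda ch: state[id(ch)][2])
        x1, v1, l1 = state[id(c1)]
        x2, v2, l2 = state[id(c2)]
        vsum = v1 + v2
        if vsum <= 0:
            raise DataError("non-positive contrast variance; "
                            "check branch lengths")
        contrasts.append((x1 - x2) / math.sqrt(vsum))
        variances.append(vsum)
        labels.append(f"{l1}|{l2}")
        anc = (x1 / v1 + x2 / v2) / (1 / v1 + 1 / v2) if v1 > 0 and v2 > 0 \
            else (x1 + x2) / 2
        state[id(node)] = (anc, edge_len + v1 * v2 / vsum, min(l1, l2))
    return ContrastSet(contrasts=np.array(contrasts),
                       variances=np.array(variances),
                       node_labels=labels,
                       polytomies_resolved=had_polytomy)


def pic_correlation(tree: dendropy.Tree, x_values: dict[str, float],
                    y_values: dict[str, float]) -> CorrelationResult:
    """Correlation of two traits' independent contrasts, through the origin.

    r = sum(u v) / sqrt(sum u^2 sum v^2) over the paired contrasts; the p
    value uses a t distribution with k - 1 degrees of freedom for k
    contrasts (no intercept is estimated).
    """
    cx = pic_contrasts(tree, x_values)
    cy = pic_contrasts(tree, y_values)
    u, v = cx.contrasts, cy.contrasts
    k = u.size
    if k < 2:
        raise DataError("need at least 2 contrasts")
    denom = math.sqrt(float(np.sum(u**2)) * float(np.sum(v**2)))
    if denom == 0:
        raise DataError("zero contrast variance; correlation undefined")
    r = float(np.sum(u * v) / denom)
    r = max(-1.0, min(1.0, r))
    if k < 3:
        return CorrelationResult(r=r, p=float("nan"), n=k)
    df = k - 1
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1 - r**2))
        p = 2 * stats.t.sf(abs(t), df)
    return CorrelationResult(r=r, p=float(p), n=k)


def multilinear_q(freq_matrix: pd.DataFrame | np.ndarray,
                  lifespans: Sequence[float],
                  mode: Literal["beta-share", "r2-share"] = "beta-share",
                  n_orderings: int = 200,
                  seed: int = 0) -> pd.Series:
    """Fractional contributions q (in %) of each amino acid to a multilinear
    prediction of log lifespan from all 20 usage frequencies.

    The 20 frequencies are compositional (they sum to 1), so the design is
    rank-deficient; the fit uses the Moore-Penrose pseudoinverse, keeping
    all 20 coefficients defined. ``beta-share`` (default) reports
    q_a = 100 |beta_a| sd_a / sum(|beta| sd); ``r2-share`` reports the
    average sequential R^2 gain of each predictor over random predictor
    orderings (an LMG-style decomposition, Monte-Carlo sampled).
    """
    X = np.asarray(freq_matrix, dtype=float)
    y = np.log10(np.asarray(lifespans, dtype=float))
    n = X.shape[0]
    if n < 4:
        raise DataError("need at least 4 species")
    if X.shape[1] != 20:
        raise DataError("frequency matrix must have 20 columns")
    names = (list(freq_matrix.columns) if isinstance(freq_matrix, pd.DataFrame)
             else list(AMINO_ACIDS))
    sd = X.std(axis=0, ddof=1)
    if mode == "beta-share":
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        # rcond cuts the compositional null direction (singular value at
        # machine noise) instead of inverting it
        beta = np.linalg.pinv(Xc, rcond=1e-8) @ yc
        weights = np.abs(beta) * sd
    elif mode == "r2-share":
        rng = np.random.default_rng(seed)
        weights = np.zeros(20)
        for _ in range(n_orderings):
            order = rng.permutation(20)
            prev_r2 = 0.0
            cols: list[int] = []
            for j in order:
                cols.append(j)
                r2 = _r2(X[:, cols], y)
                weights[j] += max(r2 - prev_r2, 0.0)
                prev_r2 = r2
        weights /= n_orderings
    else:
        raise ConfigurationError(f"unknown q mode {mode!r}")
    total = weights.sum()
    if total == 0:
        raise DataError("all contributions zero; model fit failed")
    return pd.Series(100.0 * weights / total, index=names)


def _r2(X: np.ndarray, y: np.ndarray) -> float:
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    beta = np.linalg.pinv(Xc, rcond=1e-8) @ yc
    resid = yc - Xc @ beta
    tss = float(np.sum(yc**2))
    return 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 0.0


def median_split(lifespans: pd.Series) -> tuple[list[str], list[str]]:
    """Split species ids into long- and short-lived halves at median longevity.

    Returns (long_ids, short_ids). With an even n the two halves are
    equal-sized; ties at the median are broken by rank order (stable sort
    on lifespan, then id), which is flagged in a warning by the caller if
    relevant.
    """
    n = len(lifespans)
    if n < 4:
        raise DataError("median split needs at least 4 species")
    order = lifespans.sort_values(kind="stable", ascending=False)
    half = n // 2
    long_ids = list(order.index[:half])
    short_ids = list(order.index[half:])
    return long_ids, short_ids


def median_split_effect(freqs: pd.DataFrame,
                        lifespans: pd.Series) -> pd.DataFrame:
    """Per-amino-acid effect-size ratio mean(long) / mean(short).

    `freqs` holds per-species frequency (or ratio) values, one row per
    species; `lifespans` is indexed by the same species ids. Frequencies
    are compared directly, without log transformation.
    """
    long_ids, short_ids = median_split(lifespans)
    mean_long = freqs.loc[long_ids].mean(axis=0)
    mean_short = freqs.loc[short_ids].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mean_long / mean_short
    out = pd.DataFrame({
        "ratio": ratio.where(mean_short > 0, np.nan),
        "mean_long": mean_long,
        "mean_short": mean_short,
    })
    out.attrs["long_ids"] = long_ids
    out.attrs["short_ids"] = short_ids
    return out
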