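"""Amino-acid composition pooled by transmembrane content, and normalized usage ratios.

Protein sets that differ in their share of transmembrane domains (TMDs)
differ systematically in hydrophobic amino-acid content; comparing them
naively would misread hydrophobicity as adaptation. The remedy implemented
here pools TMD and non-TMD residues separately and re-expresses both sets
at a common TMD content c before taking per-amino-acid frequency ratios:

    f_a(c) = c * f_a^TMD + (1 - c) * f_a^nonTMD
    R_a    = f_a^num(c) / f_a^den(c)

With c equal to a set's own TMD fraction tau the blend reproduces the
plain unsegmented frequencies, and when both sets share the same tau the
ratio is independent of the chosen c.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from ._aa import AA_INDEX, AMINO_ACIDS, KYTE_DOOLITTLE
from .errors import ConfigurationError, DataError
from .io import ProteinRecord, TmdAnnotationSet

CPolicy = Literal["mean", "numerator"] | float


@dataclass
class SegmentedComposition:
    """Amino-acid counts pooled over TMD and non-TMD residues of a protein set."""

    counts_tmd: np.ndarray
    counts_nontmd: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.counts_tmd = np.asarray(self.counts_tmd, dtype=np.int64)
        self.counts_nontmd = np.asarray(self.counts_nontmd, dtype=np.int64)
        for v in (self.counts_tmd, self.counts_nontmd):
            if v.shape != (20,) or (v < 0).any():
                raise DataError("count vectors must be length-20 and non-negative")

    @property
    def n_tmd(self) -> int:
        return int(self.counts_tmd.sum())

    @property
    def n_nontmd(self) -> int:
        return int(self.counts_nontmd.sum())

    @property
    def tmd_fraction(self) -> float:
        """tau, the share of counted residues lying inside TMD segments."""
        total = self.n_tmd + self.n_nontmd
        if total == 0:
            raise DataError(f"composition {self.label!r} is empty")
        return self.n_tmd / total

    def raw_freqs(self) -> np.ndarray:
        """Unsegmented frequencies over all counted residues."""
        total = self.counts_tmd + self.counts_nontmd
        return total / total.sum()


@dataclass
class RatioVector:
    """Per-amino-acid usage ratios with provenance of their normalization."""

    ratios: np.ndarray  # NaN marks an undefined entry
    numerator_label: str = ""
    denominator_label: str = ""
    tmd_content: float | None = None
    c_policy: str = ""

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.ratios.shape != (20,):
            raise DataError("ratio vector must have length 20")
        defined = self.ratios[~np.isnan(self.ratios)]
        if (defined <= 0).any():
            raise DataError("defined usage ratios must be positive")

    def as_mapping(self) -> dict[str, float]:
        return {aa: float(self.ratios[i]) for i, aa in enumerate(AMINO_ACIDS)}


def predict_tmds_hydropathy(sequence: str, window: int = 19,
                            threshold: float = 1.6,
                            merge_gap: int = 5) -> list[tuple[int, int]]:
    """Predict transmembrane segments by Kyte-Doolittle sliding-window hydropathy.

    A residue position is a candidate helix center when the mean hydropathy
    of the window around it exceeds `threshold`. Maximal runs of candidate
    centers closer than `merge_gap` are merged, expanded by half a window
    to approximate the full helix span, and clipped to sequence bounds.
    Returns 1-based inclusive segments; sequences shorter than the window
    yield no segments.
    """
    n = len(sequence)
    if n < window:
        return []
    scores = np.array([KYTE_DOOLITTLE.get(ch, 0.0) for ch in sequence])
    kernel = np.ones(window) / window
    means = np.convolve(scores, kernel, mode="valid")  # centers window//2 .. n-1-window//2
    half = window // 2
    centers = np.flatnonzero(means > threshold) + half  # 0-based center indices
    if centers.size == 0:
        return []
    runs: list[list[int]] = [[int(centers[0]), int(centers[0])]]
    for c in centers[1:]:
        if c - runs[-1][1] < merge_gap:
            runs[-1][1] = int(c)
        else:
            runs.append([int(c), int(c)])
    segments = []
    for start, end in runs:
        lo = max(1, start - half + 1)  # to 1-based, expanded by half window
        hi = min(n, end + half + 1)
        segments.append((lo, hi))
    return segments


def pool_composition(proteins: Iterable[ProteinRecord],
                     annotations: TmdAnnotationSet | None = None,
                     label: str = "") -> SegmentedComposition:
    """Count every standard residue once, into the TMD pool iff its position
    lies inside an annotated segment. Ambiguity letters are skipped."""
    counts_tmd = np.zeros(20, dtype=np.int64)
    counts_non = np.zeros(20, dtype=np.int64)
    proteins = list(proteins)
    if annotations is not None:
        annotations.validate_against(proteins)
    for prot in proteins:
        segs = annotations.for_protein(prot.id) if annotations else []
        in_tmd = np.zeros(len(prot.sequence), dtype=bool)
        for start, end in segs:
            in_tmd[start - 1:end] = True
        for pos, ch in enumerate(prot.sequence):
            idx = AA_INDEX.get(ch)
            if idx is None:
                continue
            if in_tmd[pos]:
                counts_tmd[idx] += 1
            else:
                counts_non[idx] += 1
    return SegmentedComposition(counts_tmd, counts_non, label=label)


def blended_freqs(comp: SegmentedComposition, c: float) -> np.ndarray:
    """Frequencies of `comp` re-expressed at TMD content ``c`` in [0, 1]."""
    if not 0.0 <= c <= 1.0:
        raise ConfigurationError(f"TMD content c={c} outside [0, 1]")
    if c > 0 and comp.n_tmd == 0:
        raise DataError(f"TMD pool of {comp.label!r} is empty but c={c} > 0")
    if c < 1 and comp.n_nontmd == 0:
        raise DataError(f"non-TMD pool of {comp.label!r} is empty but c={c} < 1")
    f_tmd = comp.counts_tmd / comp.n_tmd if comp.n_tmd else np.zeros(20)
    f_non = comp.counts_nontmd / comp.n_nontmd if comp.n_nontmd else np.zeros(20)
    return c * f_tmd + (1.0 - c) * f_non


def _resolve_c(num: SegmentedComposition, den: SegmentedComposition,
               policy: CPolicy) -> tuple[float, str]:
    if policy == "mean":
        return (num.tmd_fraction + den.tmd_fraction) / 2.0, "mean"
    if policy == "numerator":
        return num.tmd_fraction, "numerator"
    if isinstance(policy, (int, float)) and not isinstance(policy, bool):
        return float(policy), f"fixed:{float(policy)}"
    raise ConfigurationError(f"unknown c policy {policy!r}")


def normalized_usage_ratio(num: SegmentedComposition,
                           den: SegmentedComposition,
                           c_policy: CPolicy = "mean",
                           combine: Literal["blend", "ratio"] = "blend",
                           ) -> RatioVector:
    """Per-amino-acid usage ratios of two protein sets at a common TMD content.

    The common content c is chosen by `c_policy` (default: the mean of the
    two sets' TMD fractions, which is symmetric in the two sets). With
    ``combine="blend"`` frequencies are blended first and then divided;
    with ``combine="ratio"`` TMD-to-TMD and non-TMD-to-non-TMD frequency
    ratios are formed first and combined with weight c. Entries whose
    denominator frequency is zero are marked undefined (NaN), never
    pseudocounted.
    """
    c, policy_label = _resolve_c(num, den, c_policy)
    if combine == "blend":
        f_num = blended_freqs(num, c)
        f_den = blended_freqs(den, c)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(f_den > 0, f_num / f_den, np.nan)
        ratios = np.where((f_num == 0) & (f_den > 0), np.nan, ratios)
    elif combine == "ratio":
        for comp in (num, den):
            if c > 0 and comp.n_tmd == 0:
                raise DataError(f"TMD pool of {comp.label!r} empty with c > 0")
            if c < 1 and comp.n_nontmd == 0:
                raise DataError(f"non-TMD pool of {comp.label!r} empty with c < 1")
        with np.errstate(divide="ignore", invalid="ignore"):
            r_tmd = np.where(den.counts_tmd > 0,
                             (num.counts_tmd / max(num.n_tmd, 1))
                             / (den.counts_tmd / max(den.n_tmd, 1)), np.nan)
            r_non = np.where(den.counts_nontmd > 0,
                             (num.counts_nontmd / max(num.n_nontmd, 1))
                             / (den.counts_nontmd / max(den.n_nontmd, 1)), np.nan)
        if c == 0:
            ratios = r_non
        elif c == 1:
            ratios = r_tmd
        else:
            ratios = c * r_tmd + (1 - c) * r_non
        ratios = np.where(ratios == 0, np.nan, ratios)
    else:
        raise ConfigurationError(f"unknown combine mode {combine!r}")
    return RatioVector(ratios=ratios, numerator_label=num.label,
                       denominator_label=den.label, tmd_content=c,
                       c_policy=f"{policy_label}/{combine}")
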