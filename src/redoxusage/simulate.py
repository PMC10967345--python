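"""Synthetic study bundles with known ground truth.

The generator emulates the structure of the comparative study so every
downstream stage has a parameter-recovery test: a panel of species with
log-uniform lifespans spanning 0.05-100 years and allometrically coupled
body masses; per-species, per-compartment proteomes whose amino-acid
compositions carry injected usage-ratio multipliers and lifespan-linked
slopes; transmembrane segments of 17-25 residues with hydrophobic-biased
composition placed to hit a target TMD fraction per compartment; and a
pure-birth phylogeny over the panel.

What is emulated is the *effect structure* (ratios, slopes, TMD shares),
not protein evolution: residues are drawn independently from multinomial
compositions, so inter-species noise is purely multinomial.
"""

from __future__ import annotations

import hashlib
import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from ._aa import AMINO_ACIDS, KYTE_DOOLITTLE, aa_array
from .errors import ConfigurationError, DataError
from .io import (ProteinRecord, TmdAnnotationSet, write_fasta,
                 write_species_metadata, write_tmhmm)
from .reference import RATIO_TABLES

#: Average proteome composition used as the baseline (UniProt-style global
#: amino-acid frequencies, normalized to sum 1).
_BASELINE_PCT = {
    "A": 8.25, "C": 1.38, "D": 5.46, "E": 6.72, "F": 3.86,
    "G": 7.07, "H": 2.27, "I": 5.91, "K": 5.80, "L": 9.65,
    "M": 2.41, "N": 4.06, "P": 4.74, "Q": 3.93, "R": 5.53,
    "S": 6.64, "T": 5.35, "V": 6.86, "W": 1.10, "Y": 2.92,
}


def default_baseline_freqs() -> np.ndarray:
    v = aa_array(_BASELINE_PCT)
    return v / v.sum()


def default_tmd_bias() -> np.ndarray:
    """Hydrophobic bias applied inside TMD segments: exp(KD / 2.5), normalized
    against the baseline so TMD pools are enriched in I, L, V, F."""
    kd = aa_array(KYTE_DOOLITTLE)
    return np.exp(kd / 2.5)


def _default_multipliers() -> dict[str, dict[str, float]]:
    """Compartment usage-ratio multipliers mirroring the study's observed
    effects: peroxisome and mitochondrion carry the published paradigm-I/II
    ratio vectors; the respiratory chain compounds the mitochondrial and
    respiratory-chain ratios (it is nested inside the mitochondrion)."""
    mito = RATIO_TABLES["II"]
    rc = {aa: RATIO_TABLES["II"][aa] * RATIO_TABLES["III"][aa]
          for aa in AMINO_ACIDS}
    return {
        "whole": {aa: 1.0 for aa in AMINO_ACIDS},
        "peroxisome": dict(RATIO_TABLES["I"]),
        "mitochondrion": dict(mito),
        "respiratory_chain": rc,
    }


def _default_tmd_fractions() -> dict[str, float]:
    # whole proteomes carry ~10% TMD residues, mitochondrially imported
    # sets ~5%, mitochondrially encoded respiratory-chain sets ~55%
    return {"whole": 0.10, "peroxisome": 0.05, "mitochondrion": 0.05,
            "respiratory_chain": 0.55}


@dataclass
class SimConfig:
    """Generator configuration; defaults reproduce the study conditions."""

    seed: int = 0
    n_species: int = 20
    lifespan_range_years: tuple[float, float] = (0.05, 100.0)
    mass_lifespan_r: float = 0.933
    baseline_freqs: np.ndarray = field(default_factory=default_baseline_freqs)
    compartment_multipliers: dict[str, dict[str, float]] = field(
        default_factory=_default_multipliers)
    lifespan_slopes: dict[str, float] = field(
        default_factory=lambda: {"C": -0.3})
    slope_compartments: tuple[str, ...] = ("respiratory_chain",)
    reference_compartment: str = "whole"
    tmd_fraction: float | dict[str, float] = field(
        default_factory=_default_tmd_fractions)
    proteins_per_set: int = 60
    mean_protein_length: int = 300
    mito_code_id: int = 2

    def __post_init__(self) -> None:
        self.baseline_freqs = np.asarray(self.baseline_freqs, dtype=float)
        if self.baseline_freqs.shape != (20,):
            raise ConfigurationError("baseline_freqs must have length 20")
        if abs(self.baseline_freqs.sum() - 1.0) > 1e-9:
            raise ConfigurationError("baseline_freqs must sum to 1 (1e-9)")
        lo, hi = self.lifespan_range_years
        if not (0 < lo < hi):
            raise ConfigurationError("invalid lifespan range")
        if not -1.0 <= self.mass_lifespan_r <= 1.0:
            raise ConfigurationError("mass_lifespan_r must lie in [-1, 1]")
        for comp, mult in self.compartment_multipliers.items():
            if any(m <= 0 for m in mult.values()):
                raise ConfigurationError(
                    f"non-positive multiplier in compartment {comp!r}")
        for comp in self.compartments:
            if not 0.0 <= self.tmd_fraction_for(comp) < 1.0:
                raise ConfigurationError(
                    f"tmd_fraction for {comp!r} must lie in [0, 1)")
        if self.proteins_per_set < 1:
            raise ConfigurationError("proteins_per_set must be >= 1")

    @property
    def compartments(self) -> list[str]:
        return list(self.compartment_multipliers)

    def tmd_fraction_for(self, compartment: str) -> float:
        if isinstance(self.tmd_fraction, Mapping):
            return float(self.tmd_fraction.get(compartment, 0.0))
        return float(self.tmd_fraction)


def generate_species_table(cfg: SimConfig,
                           rng: np.random.Generator | None = None
                           ) -> pd.DataFrame:
    """Species panel with log-uniform lifespans and allometric body masses.

    Lifespans are log-uniform over the configured range, sorted in
    decreasing order (ids ``sp01``...). Log body mass follows
    a + b log10 L plus Gaussian noise whose variance is solved from the
    target Pearson correlation on the log-log scale (zero noise at |r|=1).
    The group label records the median-longevity half of each species.
    """
    if cfg.n_species < 4:
        raise ConfigurationError("need at least 4 species")
    rng = rng or np.random.default_rng(cfg.seed)
    lo, hi = cfg.lifespan_range_years
    log_l = rng.uniform(np.log10(lo), np.log10(hi), size=cfg.n_species)
    log_l = np.sort(log_l)[::-1]
    # allometric slope/intercept chosen to span realistic masses
    a, b = -5.0, 3.5
    r = cfg.mass_lifespan_r
    sd_x = np.std(log_l, ddof=1)
    if abs(r) == 1.0:
        noise = np.zeros(cfg.n_species)
        b = abs(b) * np.sign(r)
    else:
        sd_eps = abs(b) * sd_x * np.sqrt(1.0 / r**2 - 1.0) if r != 0 else None
        if r == 0:
            b, sd_eps = 0.0, 1.0
        elif r < 0:
            b = -abs(b)
        noise = rng.normal(0.0, sd_eps, size=cfg.n_species)
    log_m = a + b * log_l + noise
    lifespans = 10.0 ** log_l
    n_long = cfg.n_species // 2
    df = pd.DataFrame({
        "species_id": [f"sp{i + 1:02d}" for i in range(cfg.n_species)],
        "name": [f"Synthetic species {i + 1}" for i in range(cfg.n_species)],
        "lifespan_years": lifespans,
        "body_mass_kg": 10.0 ** log_m,
        "group": ["long"] * n_long + ["short"] * (cfg.n_species - n_long),
        "mito_code_id": cfg.mito_code_id,
    })
    return df.set_index("species_id", drop=False)


def generate_tree(species_ids: list[str], seed: int,
                  min_branch: float = 1e-3) -> dendropy.Tree:
    """Pure-birth binary tree over the species ids, positive branch lengths."""
    if len(species_ids) < 2:
        raise DataError("need at least 2 species for a tree")
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=len(species_ids),
        rng=random.Random(seed))
    tree.seed_node.edge.length = None  # drop the root stem
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < min_branch:
            edge.length = min_branch
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    for taxon, sid in zip(taxa, species_ids):
        taxon.label = sid
    return tree


def simulate_brownian(tree: dendropy.Tree, rho: float,
                      rng: np.random.Generator) -> tuple[dict[str, float],
                                                         dict[str, float]]:
    """Two traits evolving by correlated Brownian motion (correlation rho)
    along the tree; returns tip-value dicts keyed by taxon label."""
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)
    values: dict[int, np.ndarray] = {}
    x: dict[str, float] = {}
    y: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = np.zeros(2)
        else:
            bl = node.edge.length or 0.0
            step = chol @ rng.normal(size=2) * np.sqrt(bl)
            values[id(node)] = values[id(node.parent_node)] + step
        if node.is_leaf():
            x[node.taxon.label] = float(values[id(node)][0])
            y[node.taxon.label] = float(values[id(node)][1])
    return x, y


def compose_target_freqs(cfg: SimConfig, lifespan_years: float,
                         compartment: str, pool: str = "nontmd") -> np.ndarray:
    """Exact target composition for one species, compartment and pool.

    Unnormalized weights are baseline * multiplier * L^slope (slopes apply
    only to the configured slope compartments, so they appear in usage
    ratios against the reference compartment), with the hydrophobic TMD
    bias additionally applied for the TMD pool; the result is renormalized
    to sum 1, which makes realized ratios deviate slightly from the
    injected multipliers (use :func:`expected_ratio` for the corrected
    expectation).
    """
    if compartment not in cfg.compartment_multipliers:
        raise ConfigurationError(f"no multipliers for compartment {compartment!r}")
    if pool not in ("nontmd", "tmd"):
        raise ConfigurationError(f"unknown pool {pool!r}")
    mult = aa_array(cfg.compartment_multipliers[compartment], default=1.0)
    w = cfg.baseline_freqs * mult
    if compartment in cfg.slope_compartments and cfg.lifespan_slopes:
        slopes = aa_array(cfg.lifespan_slopes, default=0.0)
        w = w * lifespan_years ** slopes
    if pool == "tmd":
        w = w * default_tmd_bias()
    if (w <= 0).any():
        raise ConfigurationError("non-positive composition weight")
    return w / w.sum()


def expected_ratio(cfg: SimConfig, lifespan_years: float, numerator: str,
                   denominator: str, c_policy: str = "mean") -> np.ndarray:
    """Closed-form expectation of the TMD-normalized usage ratio between two
    compartments under this configuration (renormalization-corrected)."""
    tau_n = cfg.tmd_fraction_for(numerator)
    tau_d = cfg.tmd_fraction_for(denominator)
    if c_policy == "mean":
        c = (tau_n + tau_d) / 2
    elif c_policy == "numerator":
        c = tau_n
    else:
        c = float(c_policy)
    out = []
    for comp in (numerator, denominator):
        f_t = compose_target_freqs(cfg, lifespan_years, comp, "tmd")
        f_n = compose_target_freqs(cfg, lifespan_years, comp, "nontmd")
        out.append(c * f_t + (1 - c) * f_n)
    return out[0] / out[1]


def generate_proteome(freqs_nontmd: np.ndarray, freqs_tmd: np.ndarray,
                      cfg: SimConfig, tmd_fraction: float,
                      rng: np.random.Generator, id_prefix: str = "p",
                      ) -> tuple[list[ProteinRecord], TmdAnnotationSet]:
    """Draw a protein set with annotated TMD segments.

    Residues are drawn independently: non-TMD positions from
    `freqs_nontmd`, positions inside segments from `freqs_tmd`. Segment
    lengths are uniform on 17-25 residues; enough segments are placed
    (disjoint, in equal-width blocks) to hit `tmd_fraction` in
    expectation. Coordinates are 1-based inclusive.
    """
    if not 0.0 <= tmd_fraction < 1.0:
        raise ConfigurationError("tmd_fraction must lie in [0, 1)")
    letters = np.array(list(AMINO_ACIDS))
    records: list[ProteinRecord] = []
    annotations = TmdAnnotationSet()
    mean_seg = 21.0
    for i in range(cfg.proteins_per_set):
        length = max(60, int(rng.poisson(cfg.mean_protein_length)))
        pid = f"{id_prefix}{i + 1:04d}"
        expect_segs = tmd_fraction * length / mean_seg
        k = int(np.floor(expect_segs))
        if rng.random() < expect_segs - k:
            k += 1
        k = min(k, length // 27)  # each block must fit a segment + gap
        segs: list[tuple[int, int]] = []
        if k > 0:
            block = length // k
            for j in range(k):
                seg_len = int(rng.integers(17, 26))
                lo = j * block
                hi = min((j + 1) * block, length) - seg_len - 1
                if hi <= lo:
                    continue
                start0 = int(rng.integers(lo, hi))
                segs.append((start0 + 1, start0 + seg_len))
        in_tmd = np.zeros(length, dtype=bool)
        for start, end in segs:
            in_tmd[start - 1:end] = True
        seq = np.empty(length, dtype="<U1")
        n_t = int(in_tmd.sum())
        if n_t:
            seq[in_tmd] = rng.choice(letters, size=n_t, p=freqs_tmd)
        seq[~in_tmd] = rng.choice(letters, size=length - n_t, p=freqs_nontmd)
        records.append(ProteinRecord(id=pid, description="synthetic protein",
                                     sequence="".join(seq)))
        annotations.segments.setdefault(pid, [])
        for start, end in segs:
            annotations.add(pid, start, end)
    return records, annotations


@dataclass
class GroundTruth:
    """Everything injected into a bundle, serializable and round-trippable."""

    config: dict
    lifespans: dict[str, float]
    body_masses: dict[str, float]
    target_freqs: dict[str, dict[str, dict[str, list[float]]]]
    newick: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def _config_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["baseline_freqs"] = [float(v) for v in cfg.baseline_freqs]
    d["lifespan_range_years"] = list(cfg.lifespan_range_years)
    d["slope_compartments"] = list(cfg.slope_compartments)
    return d


def write_fixture_bundle(cfg: SimConfig, outdir: str | Path) -> GroundTruth:
    """Emit a complete synthetic bundle: per-species/compartment FASTA and
    TMHMM-style annotations, species TSV, Newick tree and ground-truth JSON.
    Re-running with the same configuration is byte-identical."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    species = generate_species_table(cfg, rng)
    tree = generate_tree(list(species.index), seed=cfg.seed)
    newick = tree.as_string(schema="newick").strip()
    target_freqs: dict[str, dict[str, dict[str, list[float]]]] = {}
    for sid, row in species.iterrows():
        target_freqs[sid] = {}
        for comp in cfg.compartments:
            f_non = compose_target_freqs(cfg, row.lifespan_years, comp, "nontmd")
            f_tmd = compose_target_freqs(cfg, row.lifespan_years, comp, "tmd")
            target_freqs[sid][comp] = {
                "nontmd": [float(v) for v in f_non],
                "tmd": [float(v) for v in f_tmd],
            }
            records, annotations = generate_proteome(
                f_non, f_tmd, cfg, cfg.tmd_fraction_for(comp), rng,
                id_prefix=f"{sid}_{comp}_p")
            write_fasta(records, outdir / f"{sid}_{comp}.fasta")
            write_tmhmm(annotations, outdir / f"{sid}_{comp}.tmhmm.txt")
    write_species_metadata(species, outdir / "species.tsv")
    (outdir / "tree.nwk").write_text(newick + "\n")
    truth = GroundTruth(config=_config_dict(cfg),
                        lifespans={s: float(v) for s, v in
                                   species.lifespan_years.items()},
                        body_masses={s: float(v) for s, v in
                                     species.body_mass_kg.items()},
                        target_freqs=target_freqs, newick=newick)
    (outdir / "ground_truth.json").write_text(truth.to_json())
    return truth


def bundle_checksum(outdir: str | Path) -> str:
    """SHA-256 over all bundle files (sorted by name); determinism check."""
    outdir = Path(outdir)
    digest = hashlib.sha256()
    for path in sorted(outdir.iterdir()):
        if path.is_file():
            digest.update(path.name.encode())
            digest.update(path.read_bytes())
    return digest.hexdigest()
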