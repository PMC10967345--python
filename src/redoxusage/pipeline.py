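"""End-to-end orchestration: load a bundle, run the analyses, write results.

A *bundle* is a directory holding per-species, per-compartment FASTA
files (``<species>_<compartment>.fasta``), matching TMHMM-style annotation
files, a ``species.tsv`` metadata table and a ``tree.nwk`` phylogeny —
exactly what :func:`redoxusage.simulate.write_fixture_bundle` emits and
what a practitioner would assemble from real proteomes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import dendropy
import numpy as np
import pandas as pd

from ._aa import AMINO_ACIDS
from .composition import SegmentedComposition, pool_composition
from .codes import summarize_decoding
from .errors import ConfigurationError, DataError
from .io import (parse_tmhmm, read_fasta, read_newick, read_species_metadata,
                 filter_proteins, DEFAULT_EXCLUDE_PATTERNS)
from .longevity import (loglog_pearson, median_split_effect, multilinear_q,
                        partial_correlation, pic_correlation)
from .paradigms import DEFAULT_PARADIGMS, ParadigmSpec, paradigm_result, \
    species_ratio_table
from .ranking import score_tables

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {"bundle_dir", "out_dir", "paradigms", "c_policy", "avg_mode",
               "q_mode", "seed", "exclude_patterns", "apply_filters"}


@dataclass
class RunConfig:
    """Serializable configuration of one analysis run."""

    bundle_dir: str
    out_dir: str
    paradigms: list[str] = field(default_factory=lambda: ["I", "II", "III"])
    c_policy: str | float = "mean"
    avg_mode: Literal["arith", "geom"] = "arith"
    q_mode: Literal["beta-share", "r2-share"] = "beta-share"
    seed: int = 0
    exclude_patterns: list[str] = field(
        default_factory=lambda: list(DEFAULT_EXCLUDE_PATTERNS))
    apply_filters: bool = True

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_bundle(bundle_dir: str | Path,
                exclude_patterns: list[str] | None = None,
                ) -> tuple[pd.DataFrame,
                           dict[str, dict[str, SegmentedComposition]],
                           dendropy.Tree | None]:
    """Read a bundle directory into species metadata, pooled compositions
    per species and compartment, and the phylogeny (None if absent)."""
    bundle_dir = Path(bundle_dir)
    species = read_species_metadata(bundle_dir / "species.tsv")
    compositions: dict[str, dict[str, SegmentedComposition]] = {}
    for fasta in sorted(bundle_dir.glob("*.fasta")):
        stem = fasta.stem
        sid, _, comp = stem.partition("_")
        if sid not in species.index:
            raise DataError(f"FASTA {fasta.name} names unknown species {sid!r}")
        proteins = read_fasta(fasta, species_id=sid)
        if exclude_patterns is not None:
            proteins = filter_proteins(proteins, exclude_patterns)
        ann_path = bundle_dir / f"{stem}.tmhmm.txt"
        annotations = parse_tmhmm(ann_path) if ann_path.exists() else None
        compositions.setdefault(sid, {})[comp] = pool_composition(
            proteins, annotations, label=f"{sid}/{comp}")
    if not compositions:
        raise DataError(f"no FASTA files found in {bundle_dir}")
    tree_path = bundle_dir / "tree.nwk"
    tree = read_newick(tree_path, species.index) if tree_path.exists() else None
    return species, compositions, tree


def run(config: RunConfig) -> dict[str, Path]:
    """Execute the configured stages; returns the written output paths.

    Stages run in dependency order: paradigm comparison tables first, then
    the longevity analyses on the strongest within-species paradigm
    present, the decoding summary, and the cross-paradigm ranking report.
    Every output table carries the configuration hash in a sidecar
    provenance file.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    patterns = config.exclude_patterns if config.apply_filters else None
    species, compositions, tree = load_bundle(config.bundle_dir, patterns)
    written: dict[str, Path] = {}

    ratio_tables: dict[str, dict[str, float]] = {}
    p_tables: dict[str, dict[str, float]] = {}
    longevity_paradigm: ParadigmSpec | None = None
    for pid in config.paradigms:
        spec = DEFAULT_PARADIGMS.get(pid)
        if spec is None or spec.is_group_paradigm:
            raise ConfigurationError(f"unsupported paradigm id {pid!r}")
        have = [sid for sid, comps in compositions.items()
                if spec.numerator in comps and spec.denominator in comps]
        if not have:
            logger.warning("paradigm %s: no species with both %s and %s; skipped",
                           pid, spec.numerator, spec.denominator)
            continue
        result = paradigm_result(spec, compositions, c_policy=config.c_policy,
                                 avg_mode=config.avg_mode)
        path = out_dir / f"paradigm_{pid}.tsv"
        result.to_csv(path, sep="\t")
        written[f"paradigm_{pid}"] = path
        ratio_tables[pid] = result["ratio"].to_dict()
        p_tables[pid] = result["p"].to_dict()
        if pid == "III" or longevity_paradigm is None:
            longevity_paradigm = spec

    if longevity_paradigm is not None:
        table = species_ratio_table(longevity_paradigm, compositions,
                                    c_policy=config.c_policy)
        lifespans = species.loc[table.index, "lifespan_years"]
        masses = species.loc[table.index, "body_mass_kg"]
        rows = {}
        for aa in AMINO_ACIDS:
            vals = table[aa]
            ok = vals.notna()
            if ok.sum() < 4:
                continue
            raw = loglog_pearson(lifespans[ok], vals[ok])
            part = partial_correlation(np.log10(vals[ok]),
                                       np.log10(lifespans[ok]),
                                       np.log10(masses[ok]))
            entry = {"r": raw.r, "p": raw.p,
                     "r_mass_corrected": part.r, "p_mass_corrected": part.p}
            if tree is not None:
                pic = pic_correlation(
                    tree,
                    {s: float(np.log10(vals[s])) for s in vals.index[ok]},
                    {s: float(np.log10(lifespans[s])) for s in vals.index[ok]})
                entry["r_phylo_corrected"] = pic.r
                entry["p_phylo_corrected"] = pic.p
            rows[aa] = entry
        long_df = pd.DataFrame.from_dict(rows, orient="index")
        q = multilinear_q(table.fillna(table.mean()), lifespans,
                          mode=config.q_mode, seed=config.seed)
        long_df["q_percent"] = q
        effect = median_split_effect(table, lifespans)
        long_df["effect_ratio"] = effect["ratio"]
        path = out_dir / "longevity.tsv"
        long_df.to_csv(path, sep="\t")
        written["longevity"] = path
        ratio_tables["IV"] = effect["ratio"].to_dict()

    decoding = summarize_decoding(species)
    path = out_dir / "decoding.json"
    path.write_text(json.dumps(decoding, indent=1, sort_keys=True))
    written["decoding"] = path

    if len(ratio_tables) >= 2:
        flags, ranks_df, pct_df = score_tables(ratio_tables, p_tables)
        ranks_df.to_csv(out_dir / "ranks.tsv", sep="\t")
        pct_df.to_csv(out_dir / "percent_changes.tsv", sep="\t")
        flags_json = {
            "top4": {pid: sorted(v) for pid, v in flags.top4.items()},
            "significant": {pid: sorted(v) for pid, v in
                            flags.significant.items()},
            "hash_set": sorted(flags.hash_set),
        }
        (out_dir / "score_flags.json").write_text(
            json.dumps(flags_json, indent=1))
        written["ranks"] = out_dir / "ranks.tsv"
        written["percent_changes"] = out_dir / "percent_changes.tsv"
        written["score_flags"] = out_dir / "score_flags.json"

    provenance = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "python": platform.python_version(),
        "n_species": int(len(species)),
        "species_included": sorted(compositions),
        "outputs": {k: str(v) for k, v in written.items()},
    }
    prov_path = out_dir / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=1, sort_keys=True,
                                    default=str))
    written["provenance"] = prov_path
    return written
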