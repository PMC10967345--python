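"""Printed reference data from the comparative oxidative-stress study.

This module transcribes the study's published input tables so the analyses
that are derivable on paper — percent-change conversion, factorial ranking,
decoding summaries, the lifespan/body-mass correlation, the median
longevity split — can be recomputed without access to the original
sequence databases.

Contents
--------
``SPECIES``
    The 20-animal reference panel: lifespan (years), body mass (kg),
    phylogenetic group and NCBI mitochondrial genetic-code id per species,
    ordered by decreasing lifespan.
``RATIO_TABLES``
    Mean amino-acid usage ratios (and Kruskal-Wallis p values) for the
    eight published paradigms: peroxisome (I), mitochondrion (II),
    respiratory chain (III), longevity effect size (IV), helminth
    aerobicity (V), and aerobic-vs-anaerobic archaea (VI), Gram-positive
    (VII) and Gram-negative (VIII) bacteria.
``PUBLISHED_RANKS``
    The published factorial-deviation ranks (1 = strongest deviation from
    unity) for the same eight paradigms.
"""

from __future__ import annotations

import pandas as pd

from ._aa import AMINO_ACIDS

#: species_id, name, phylogenetic group, lifespan (y), body mass (kg),
#: NCBI mitochondrial translation-table id. Ordered by decreasing lifespan.
SPECIES: list[dict] = [
    dict(species_id="Hsap", name="Homo sapiens", phylum="Mammalia", lifespan_years=100, body_mass_kg=70, mito_code_id=2),
    dict(species_id="Ecab", name="Equus caballus", phylum="Mammalia", lifespan_years=62, body_mass_kg=1000, mito_code_id=2),
    dict(species_id="Ptro", name="Pan troglodytes", phylum="Mammalia", lifespan_years=60, body_mass_kg=45, mito_code_id=2),
    dict(species_id="Mmul", name="Macaca mulatta", phylum="Mammalia", lifespan_years=35, body_mass_kg=8, mito_code_id=2),
    dict(species_id="Btau", name="Bos taurus", phylum="Mammalia", lifespan_years=30, body_mass_kg=750, mito_code_id=2),
    dict(species_id="Cfam", name="Canis familiaris", phylum="Mammalia", lifespan_years=30, body_mass_kg=40, mito_code_id=2),
    dict(species_id="Ggal", name="Gallus gallus", phylum="Aves", lifespan_years=30, body_mass_kg=2.6, mito_code_id=2),
    dict(species_id="Spur", name="Strongylocentrotus purpuratus", phylum="Echinoidea", lifespan_years=20, body_mass_kg=0.1, mito_code_id=9),
    dict(species_id="Ocun", name="Oryctolagus cuniculus", phylum="Mammalia", lifespan_years=18, body_mass_kg=1.8, mito_code_id=2),
    dict(species_id="Cpor", name="Cavia porcellus", phylum="Mammalia", lifespan_years=15, body_mass_kg=0.73, mito_code_id=2),
    dict(species_id="Mdom", name="Monodelphis domestica", phylum="Mammalia", lifespan_years=6, body_mass_kg=0.11, mito_code_id=2),
    dict(species_id="Mmus", name="Mus musculus", phylum="Mammalia", lifespan_years=6, body_mass_kg=0.021, mito_code_id=2),
    dict(species_id="Amel", name="Apis mellifera", phylum="Insecta", lifespan_years=5, body_mass_kg=9e-5, mito_code_id=5),
    dict(species_id="Drer", name="Danio rerio", phylum="Pisces", lifespan_years=5, body_mass_kg=5e-4, mito_code_id=2),
    dict(species_id="Rnor", name="Rattus norvegicus", phylum="Mammalia", lifespan_years=4, body_mass_kg=0.3, mito_code_id=2),
    dict(species_id="Cint", name="Ciona intestinalis", phylum="Ascidiae", lifespan_years=2, body_mass_kg=1e-4, mito_code_id=13),
    dict(species_id="Tcas", name="Tribolium castaneum", phylum="Insecta", lifespan_years=2, body_mass_kg=2.5e-6, mito_code_id=5),
    dict(species_id="Dmel", name="Drosophila melanogaster", phylum="Insecta", lifespan_years=0.15, body_mass_kg=1e-6, mito_code_id=5),
    dict(species_id="Agam", name="Anopheles gambiae", phylum="Insecta", lifespan_years=0.07, body_mass_kg=2.5e-7, mito_code_id=5),
    dict(species_id="Cele", name="Caenorhabditis elegans", phylum="Nematoda", lifespan_years=0.05, body_mass_kg=2e-9, mito_code_id=5),
]

#: Human-readable paradigm labels.
PARADIGM_LABELS: dict[str, str] = {
    "I": "peroxisome",
    "II": "mitochondrion",
    "III": "respiratory_chain",
    "IV": "longevity",
    "V": "aerobicity",
    "VI": "archaea",
    "VII": "gram_positive",
    "VIII": "gram_negative",
}

# Per-paradigm published mean usage ratios and p values, amino acids in
# fixed A..Y order. Ratio = oxidative condition / reference condition.
_RATIOS_RAW: dict[str, list[tuple[float, float]]] = {
    # Peroxisome vs whole proteome (TMD-normalized).
    "I": [(1.09, 3e-4), (0.86, 3e-5), (0.91, 8e-5), (0.91, 3e-7), (1.12, 2e-6),
          (1.09, 9e-5), (0.97, 1e-2), (1.19, 1e-4), (0.97, 7e-2), (1.05, 1e-2),
          (1.11, 2e-4), (1.03, 2e-1), (0.86, 3e-4), (0.88, 9e-6), (0.92, 2e-3),
          (0.87, 2e-7), (0.99, 6e-1), (1.14, 1e-6), (1.10, 2e-3), (1.10, 4e-3)],
    # Mitochondrion vs whole proteome (TMD-normalized).
    "II": [(1.15, 3e-5), (0.74, 1e-7), (0.93, 4e-4), (0.92, 2e-6), (1.08, 5e-5),
           (1.12, 4e-4), (0.90, 3e-6), (1.12, 2e-3), (1.04, 2e-1), (1.06, 6e-3),
           (1.16, 1e-6), (0.90, 8e-3), (0.86, 3e-4), (0.93, 4e-4), (1.03, 2e-2),
           (0.82, 6e-8), (0.97, 1e-1), (1.10, 1e-6), (1.05, 3e-2), (1.06, 1e-2)],
    # Mitochondrially encoded respiratory chain vs all mitochondrial proteins.
    "III": [(0.57, 1e-7), (0.41, 1e-7), (0.74, 2e-7), (0.63, 6e-8), (1.28, 1e-2),
            (0.73, 1e-6), (1.36, 3e-5), (1.12, 4e-3), (0.79, 4e-5), (1.11, 2e-7),
            (2.14, 2e-7), (1.93, 9e-8), (1.28, 3e-3), (0.81, 2e-5), (0.49, 6e-8),
            (1.29, 3e-6), (1.48, 7e-3), (0.53, 6e-8), (1.81, 6e-8), (1.33, 6e-6)],
    # Long-lived vs short-lived animals, effect-size ratios (median split).
    "IV": [(1.22, 2e-2), (0.53, 3e-4), (1.00, 5e-1), (1.04, 2e-1), (0.74, 2e-2),
           (0.84, 3e-1), (1.17, 3e-2), (1.06, 3e-1), (0.92, 5e-1), (0.97, 5e-1),
           (0.88, 2e-1), (1.04, 6e-1), (1.22, 3e-2), (1.27, 1e-2), (1.02, 6e-1),
           (0.93, 4e-1), (1.52, 7e-3), (0.88, 1e-1), (0.91, 7e-2), (0.98, 8e-1)],
    # Aerobic vs facultatively anaerobic helminths (respiratory chain).
    "V": [(1.77, 6e-5), (0.43, 9e-10), (0.84, 1e-5), (0.99, 6e-1), (0.82, 8e-5),
          (0.83, 8e-6), (1.35, 4e-11), (1.16, 1e-3), (1.39, 5e-5), (1.01, 6e-1),
          (1.51, 2e-6), (1.16, 1e-2), (1.63, 5e-9), (1.77, 9e-12), (1.04, 2e-1),
          (0.93, 5e-5), (1.68, 1e-9), (0.58, 3e-12), (1.03, 6e-1), (0.68, 2e-11)],
    # Aerobic vs anaerobic archaea.
    "VI": [(1.31, 5e-2), (0.73, 2e-2), (1.23, 4e-1), (0.94, 2e-1), (0.91, 2e-1),
           (1.10, 2e-2), (1.07, 3e-1), (0.77, 2e-2), (0.60, 3e-3), (0.97, 3e-1),
           (0.90, 7e-2), (0.77, 3e-2), (1.09, 8e-2), (1.07, 2e-1), (1.24, 3e-2),
           (1.03, 8e-1), (1.16, 5e-2), (1.12, 2e-2), (1.06, 6e-1), (0.92, 5e-1)],
    # Aerobic vs anaerobic Gram-positive bacteria.
    "VII": [(1.06, 6e-1), (0.53, 1e-6), (0.96, 2e-1), (0.99, 1e0), (0.99, 9e-1),
            (1.04, 6e-1), (1.06, 1e-1), (0.92, 6e-1), (0.89, 5e-1), (1.06, 4e-3),
            (0.87, 2e-2), (0.94, 6e-1), (1.10, 6e-1), (1.05, 5e-1), (1.06, 7e-1),
            (0.94, 1e-1), (1.07, 1e-2), (1.04, 3e-1), (1.11, 3e-1), (0.91, 4e-1)],
    # Aerobic vs anaerobic Gram-negative bacteria.
    "VIII": [(1.11, 2e-1), (0.94, 7e-1), (1.01, 9e-1), (0.87, 5e-3), (0.95, 1e-1),
             (0.99, 7e-1), (1.11, 8e-3), (0.90, 1e-1), (0.85, 3e-1), (1.03, 1e-1),
             (0.96, 4e-1), (1.02, 8e-1), (1.04, 6e-1), (1.33, 8e-5), (0.99, 8e-1),
             (1.00, 1e0), (1.02, 4e-1), (1.01, 8e-1), (1.18, 2e-3), (0.91, 4e-1)],
}

#: paradigm id -> {amino acid -> mean usage ratio}.
RATIO_TABLES: dict[str, dict[str, float]] = {
    pid: {aa: r for aa, (r, _) in zip(AMINO_ACIDS, rows)}
    for pid, rows in _RATIOS_RAW.items()
}

#: paradigm id -> {amino acid -> published Kruskal-Wallis / ANOVA-on-ranks p}.
P_TABLES: dict[str, dict[str, float]] = {
    pid: {aa: p for aa, (_, p) in zip(AMINO_ACIDS, rows)}
    for pid, rows in _RATIOS_RAW.items()
}

# Published factorial-deviation ranks, amino acids in fixed A..Y order.
_RANKS_RAW: dict[str, list[int]] = {
    "I": [14, 2, 10, 9, 7, 13, 17, 1, 19, 16, 8, 18, 3, 6, 15, 4, 20, 5, 12, 11],
    "II": [5, 1, 13, 11, 12, 7, 9, 6, 18, 16, 3, 8, 4, 14, 20, 2, 19, 10, 17, 15],
    "III": [7, 1, 12, 8, 15, 10, 11, 19, 17, 20, 2, 4, 16, 18, 3, 14, 9, 5, 6, 13],
    "IV": [5, 1, 20, 16, 3, 7, 8, 14, 12, 17, 10, 15, 6, 4, 18, 13, 2, 9, 11, 19],
    "V": [2, 1, 13, 19, 11, 12, 10, 15, 9, 20, 7, 14, 6, 3, 17, 16, 5, 4, 18, 8],
    "VI": [3, 2, 7, 17, 12, 11, 15, 4, 1, 19, 10, 5, 13, 16, 6, 20, 8, 9, 18, 14],
    "VII": [11, 1, 17, 20, 19, 18, 9, 7, 3, 14, 2, 13, 5, 15, 10, 12, 8, 16, 4, 6],
    "VIII": [7, 9, 16, 4, 10, 18, 5, 6, 3, 13, 12, 14, 11, 1, 17, 20, 15, 19, 2, 8],
}

#: paradigm id -> {amino acid -> published rank (1 = largest deviation)}.
PUBLISHED_RANKS: dict[str, dict[str, int]] = {
    pid: dict(zip(AMINO_ACIDS, ranks)) for pid, ranks in _RANKS_RAW.items()
}

#: Animal paradigms (Table-8 scope) and prokaryote paradigms (Table-9 scope).
ANIMAL_PARADIGMS: tuple[str, ...] = ("I", "II", "III", "IV", "V")
PROKARYOTE_PARADIGMS: tuple[str, ...] = ("VI", "VII", "VIII")


def species_table() -> pd.DataFrame:
    """The 20-animal reference panel as a DataFrame (one row per species)."""
    df = pd.DataFrame(SPECIES)
    return df.set_index("species_id", drop=False)


def ratio_frame() -> pd.DataFrame:
    """All published ratio tables as a 20 x 8 DataFrame (aa x paradigm)."""
    return pd.DataFrame(RATIO_TABLES, index=list(AMINO_ACIDS))
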