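"""Factorial ranking and percent-change report from the published ratios.

Ranks the embedded per-paradigm usage-ratio tables by factorial deviation
from unity, flags the four strongest effects per paradigm, and prints the
percent-change matrix of the redox-active amino acids.
"""

from redoxusage import rank_amino_acids, score_tables
from redoxusage.reference import (ANIMAL_PARADIGMS, PARADIGM_LABELS,
                                  P_TABLES, RATIO_TABLES)

tables = {pid: RATIO_TABLES[pid] for pid in ANIMAL_PARADIGMS}
flags, ranks, pct = score_tables(tables, P_TABLES)

print("top-4 effects per paradigm (asterisk-equivalent):")
for pid in ANIMAL_PARADIGMS:
    rv = rank_amino_acids(RATIO_TABLES[pid])
    top = sorted(flags.top4[pid], key=rv.ranks.get)
    sig = "".join(sorted(flags.significant[pid]))
    print(f"  {PARADIGM_LABELS[pid]:18s} {top}  (p<0.001: {sig or '-'})")

print(f"\nhash-flagged (top-4 in >=2 paradigms): {sorted(flags.hash_set)}")

print("\npercent change of the redox-active amino acids:")
print(pct.rename(columns=PARADIGM_LABELS).to_string())
print("Negative numbers are depletions in the oxidant-exposed condition; "
      "cysteine is depleted in every animal paradigm.")
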