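"""Decoding changes of animal mitochondrial genetic codes.

Compares the vertebrate mitochondrial code with the standard code and
summarizes the decoding changes across the embedded 20-species panel.
"""

from redoxusage import (codon_count, decoding_delta, get_code_table,
                        summarize_decoding)
from redoxusage.reference import species_table

std = get_code_table(1)
vmito = get_code_table(2)

print(f"tryptophan codons: standard {codon_count(std, 'W')}, "
      f"vertebrate mito {codon_count(vmito, 'W')}")
print(f"arginine codons:   standard {codon_count(std, 'R')}, "
      f"vertebrate mito {codon_count(vmito, 'R')}")

delta = decoding_delta(vmito, std)
print("vertebrate mito vs standard:")
for aa in sorted(set(delta.gained) | set(delta.lost)):
    gains = ",".join(sorted(delta.gained.get(aa, ())))
    losses = ",".join(sorted(delta.lost.get(aa, ())))
    print(f"  {aa}: gains [{gains}] losses [{losses}]")

print("\nacross the 20-species panel:")
for aa, text in summarize_decoding(species_table()).items():
    print(f"  {aa}: {text}")
print("Counts are species carrying each codon change; e.g. every species "
      "reads UGA as tryptophan, doubling its codon supply in mitochondria.")
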