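"""End-to-end run on a synthetic bundle with known ground truth.

Generates a small study bundle (proteomes, TMD annotations, metadata,
tree), runs the full analysis pipeline on the files, and compares the
recovered cysteine effects with the injected ones.
"""

import tempfile
from pathlib import Path

import pandas as pd

from redoxusage import SimConfig, write_fixture_bundle
from redoxusage.pipeline import RunConfig, run

cfg = SimConfig(seed=3, n_species=8, proteins_per_set=30)
print("injected: mitochondrial cysteine multiplier "
      f"{cfg.compartment_multipliers['mitochondrion']['C']}, "
      f"respiratory-chain cysteine lifespan slope "
      f"{cfg.lifespan_slopes['C']}")

with tempfile.TemporaryDirectory() as tmp:
    bundle = Path(tmp) / "bundle"
    write_fixture_bundle(cfg, bundle)
    out = Path(tmp) / "results"
    written = run(RunConfig(bundle_dir=str(bundle), out_dir=str(out)))

    p2 = pd.read_csv(written["paradigm_II"], sep="\t", index_col=0)
    print(f"recovered mitochondrial C ratio: {p2.loc['C', 'ratio']:.2f} "
          f"(p = {p2.loc['C', 'p']:.1e}, n = {p2.loc['C', 'n']})")

    lon = pd.read_csv(written["longevity"], sep="\t", index_col=0)
    print(f"respiratory-chain C vs lifespan: r = {lon.loc['C', 'r']:.2f}, "
          f"phylogeny-corrected r = {lon.loc['C', 'r_phylo_corrected']:.2f}")
    print("The negative correlations recover the injected lifespan slope; "
          "the ratio tracks the injected multiplier up to renormalization "
          "and multinomial noise at this small bundle size.")
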