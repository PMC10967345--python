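"""The synthetic-bundle generator: determinism, calibration and recovery."""

import json

import numpy as np
import pytest

from redoxusage._aa import AA_INDEX
from redoxusage.errors import ConfigurationError, DataError
from redoxusage.longevity import loglog_pearson, median_split
from redoxusage.pipeline import load_bundle
from redoxusage.simulate import (GroundTruth, SimConfig, bundle_checksum,
                                 compose_target_freqs, generate_proteome,
                                 generate_species_table, generate_tree,
                                 write_fixture_bundle)


class TestSpeciesTable:
    def test_perfect_correlation_zero_noise(self):
        cfg = SimConfig(seed=1, n_species=12, mass_lifespan_r=1.0)
        df = generate_species_table(cfg)
        r = loglog_pearson(df.lifespan_years, df.body_mass_kg).r
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_noise_calibration(self):
        """At n = 200 the sample log-log correlation lands within 0.05 of
        the configured target (Monte-Carlo check of the variance formula)."""
        cfg = SimConfig(seed=1, n_species=200, mass_lifespan_r=0.9)
        df = generate_species_table(cfg)
        r = loglog_pearson(df.lifespan_years, df.body_mass_kg).r
        assert r == pytest.approx(0.9, abs=0.05)

    def test_lifespans_in_range_and_split(self):
        cfg = SimConfig(seed=3, n_species=20)
        df = generate_species_table(cfg)
        assert df.lifespan_years.between(0.05, 100).all()
        long_ids, short_ids = median_split(df.lifespan_years)
        assert len(long_ids) == len(short_ids) == 10

    def test_determinism(self):
        cfg = SimConfig(seed=5, n_species=10)
        a = generate_species_table(cfg)
        b = generate_species_table(cfg)
        assert a.equals(b)

    def test_invalid_config(self):
        with pytest.raises(ConfigurationError):
            SimConfig(mass_lifespan_r=1.5)
        with pytest.raises(ConfigurationError):
            SimConfig(lifespan_range_years=(5.0, 1.0))
        with pytest.raises(ConfigurationError):
            SimConfig(baseline_freqs=np.full(20, 0.06))


class TestTree:
    def test_two_species_cherry(self):
        tree = generate_tree(["a", "b"], seed=1)
        assert len(list(tree.leaf_node_iter())) == 2

    def test_determinism(self):
        t1 = generate_tree([f"s{i}" for i in range(20)], seed=8)
        t2 = generate_tree([f"s{i}" for i in range(20)], seed=8)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_structure_50_tips(self):
        tree = generate_tree([f"s{i}" for i in range(50)], seed=3)
        tips = list(tree.leaf_node_iter())
        assert len(tips) == 50
        lengths = [e.length for e in tree.preorder_edge_iter()
                   if e.length is not None]
        assert all(l > 0 for l in lengths)
        # binary: every internal node has exactly two children
        for node in tree.preorder_internal_node_iter():
            assert len(node.child_nodes()) == 2

    def test_too_few_species(self):
        with pytest.raises(DataError):
            generate_tree(["only"], seed=1)


class TestComposeTargetFreqs:
    def test_identity_when_no_effects(self):
        cfg = SimConfig(compartment_multipliers={"whole": {}},
                        lifespan_slopes={}, slope_compartments=(),
                        tmd_fraction=0.0)
        f = compose_target_freqs(cfg, 10.0, "whole")
        np.testing.assert_allclose(f, cfg.baseline_freqs)

    def test_hand_renormalization(self):
        """Uniform baseline, C multiplier 0.5: f_C = 0.025/0.975."""
        cfg = SimConfig(baseline_freqs=np.full(20, 0.05),
                        compartment_multipliers={"m": {"C": 0.5}},
                        lifespan_slopes={}, slope_compartments=(),
                        tmd_fraction=0.0)
        f = compose_target_freqs(cfg, 1.0, "m")
        assert f[AA_INDEX["C"]] == pytest.approx(0.025 / 0.975)
        assert f.sum() == pytest.approx(1.0)

    def test_slope_closed_form(self):
        """slope_C = -0.2: the unnormalized weight ratio across a 10-fold
        lifespan difference is 10^-0.2."""
        cfg = SimConfig(compartment_multipliers={"m": {}},
                        lifespan_slopes={"C": -0.2},
                        slope_compartments=("m",), tmd_fraction=0.0)
        f10 = compose_target_freqs(cfg, 10.0, "m")
        f1 = compose_target_freqs(cfg, 1.0, "m")
        i = AA_INDEX["C"]
        # recover the unnormalized ratio by undoing the normalizations
        w10 = f10 / f10[AA_INDEX["L"]]
        w1 = f1 / f1[AA_INDEX["L"]]
        assert w10[i] / w1[i] == pytest.approx(10 ** -0.2)

    def test_slopes_skipped_for_reference(self):
        cfg = SimConfig()
        f_short = compose_target_freqs(cfg, 0.1, "whole")
        f_long = compose_target_freqs(cfg, 100.0, "whole")
        np.testing.assert_allclose(f_short, f_long)


class TestGenerateProteome:
    def test_zero_tmd_fraction_no_annotations(self, rng):
        cfg = SimConfig(proteins_per_set=5)
        recs, ann = generate_proteome(np.full(20, 0.05), np.full(20, 0.05),
                                      cfg, 0.0, rng)
        assert len(recs) == 5
        assert len(ann) == 0

    def test_binomial_frequency_recovery(self, rng):
        """~10^5 residues at f_C = 0.02: observed frequency within 3
        binomial standard deviations."""
        freqs = np.full(20, (1 - 0.02) / 19)
        freqs[AA_INDEX["C"]] = 0.02
        cfg = SimConfig(proteins_per_set=340, mean_protein_length=300)
        recs, _ = generate_proteome(freqs, freqs, cfg, 0.0, rng)
        seq = "".join(r.sequence for r in recs)
        n = len(seq)
        obs = seq.count("C") / n
        sd = np.sqrt(0.02 * 0.98 / n)
        assert abs(obs - 0.02) < 3 * sd

    def test_tmd_fraction_round_trip(self, rng):
        """Pooling the emitted annotations recovers the target TMD share."""
        from redoxusage.composition import pool_composition
        cfg = SimConfig(proteins_per_set=150, mean_protein_length=300)
        recs, ann = generate_proteome(np.full(20, 0.05), np.full(20, 0.05),
                                      cfg, 0.3, rng)
        comp = pool_composition(recs, ann)
        assert comp.tmd_fraction == pytest.approx(0.3, abs=0.02)

    def test_segment_lengths(self, rng):
        cfg = SimConfig(proteins_per_set=40, mean_protein_length=400)
        _, ann = generate_proteome(np.full(20, 0.05), np.full(20, 0.05),
                                   cfg, 0.2, rng)
        lengths = [e - s + 1 for segs in ann.segments.values()
                   for s, e in segs]
        assert lengths and all(17 <= l <= 25 for l in lengths)


class TestBundle:
    def test_byte_identical_rerun(self, small_bundle, tmp_path):
        cfg, outdir, _ = small_bundle
        rerun = tmp_path / "rerun"
        write_fixture_bundle(cfg, rerun)
        assert bundle_checksum(outdir) == bundle_checksum(rerun)

    def test_loads_cleanly(self, small_bundle):
        cfg, outdir, _ = small_bundle
        species, comps, tree = load_bundle(outdir)
        assert len(species) == cfg.n_species
        assert set(comps) == set(species.index)
        for sid in comps:
            assert set(comps[sid]) == set(cfg.compartments)
        assert len(list(tree.leaf_node_iter())) == cfg.n_species

    def test_ground_truth_round_trip(self, small_bundle):
        _, outdir, truth = small_bundle
        text = (outdir / "ground_truth.json").read_text()
        back = GroundTruth.from_json(text)
        assert back == truth
        assert json.loads(back.to_json()) == json.loads(text)

    def test_realized_tmd_fraction_matches_config(self, small_bundle):
        cfg, outdir, _ = small_bundle
        _, comps, _ = load_bundle(outdir)
        taus = [comps[sid]["respiratory_chain"].tmd_fraction
                for sid in comps]
        assert np.mean(taus) == pytest.approx(
            cfg.tmd_fraction_for("respiratory_chain"), abs=0.03)
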