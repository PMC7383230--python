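"""Synthetic-screen generator: library design, count model, planted
effects and read-level noise processes."""

import numpy as np
import pytest

from crispra_screen import SimulationConfig
from crispra_screen.simulate import (
    generate_amplicon_reads,
    generate_cells,
    generate_library,
    generate_repeat_reads,
    generate_repeat_reference,
)

from _oracles import dp_levenshtein
from conftest import small_config


class TestLibrary:
    def test_paper_scale_design_has_475_guides(self):
        cfg = SimulationConfig(n_target_genes=230, sgrnas_per_target=2, n_nontargeting=15)
        assert cfg.total_guides == 475
        lib = generate_library(cfg)
        assert len(lib) == 475
        assert lib.guides["is_targeting"].sum() == 460
        assert (~lib.guides["is_targeting"]).sum() == 15

    def test_single_guide_library(self):
        cfg = small_config(n_target_genes=1, sgrnas_per_target=1, n_nontargeting=0,
                           n_true_hits=0)
        lib = generate_library(cfg)
        assert len(lib) == 1

    def test_min_pairwise_distance_by_brute_force(self):
        lib = generate_library(small_config(n_target_genes=12, n_nontargeting=6))
        seqs = lib.guides["protospacer"].tolist()
        dmin = min(
            dp_levenshtein(seqs[i], seqs[j])
            for i in range(len(seqs))
            for j in range(i + 1, len(seqs))
        )
        assert dmin >= 4

    def test_impossible_distance_constraint_raises(self):
        cfg = small_config(protospacer_length=3, n_target_genes=40)
        with pytest.raises(ValueError):
            generate_library(cfg)


class TestCells:
    def test_seeded_determinism(self):
        cfg = small_config(seed=7)
        lib = generate_library(cfg, np.random.default_rng(7))
        m1, t1 = generate_cells(cfg, lib, np.random.default_rng(8))
        m2, t2 = generate_cells(cfg, lib, np.random.default_rng(8))
        assert np.array_equal(m1.counts, m2.counts)
        assert t1.cell_guides.equals(t2.cell_guides)
        assert m1.repeats.equals(m2.repeats)

    def test_per_gene_mean_matches_configuration(self):
        # law-of-large-numbers check over >= 10,000 baseline cells
        cfg = small_config(
            n_target_genes=2, sgrnas_per_target=1, n_nontargeting=2,
            cells_per_sgrna=3000, n_genes=120, n_signature_genes=20,
            n_true_hits=0, baseline_state_prob=0.0, doublet_rate=0.0,
            lowquality_cell_rate=0.0, activation_log2fc=0.0, seed=5,
        )
        lib = generate_library(cfg, np.random.default_rng(5))
        m, t = generate_cells(cfg, lib, np.random.default_rng(6))
        assert m.n_cells >= 10_000
        expected = (
            t.per_gene_base_mean.to_numpy()
            * np.mean(m.cells["total_umis"].to_numpy() * (1 - m.cells["pct_mito"].to_numpy() / 100))
        )
        observed = m.counts.mean(axis=0)
        regular = ~m.genes["is_mito"].to_numpy()
        big = regular & (expected > np.median(expected[regular]))
        rel = np.abs(observed[big] - expected[big]) / expected[big]
        assert np.max(rel) < 0.05

    def test_hit_state_fraction_near_configured_rate(self):
        cfg = small_config(n_target_genes=2, sgrnas_per_target=2, n_nontargeting=1,
                           cells_per_sgrna=2000, n_genes=60, n_signature_genes=10,
                           n_mito_genes=3, n_true_hits=4, seed=2)
        lib = generate_library(cfg, np.random.default_rng(2))
        _, t = generate_cells(cfg, lib, np.random.default_rng(3))
        hit_cells = t.cell_guides["guide_1"].isin(t.true_hit_sgrnas)
        frac = t.cell_state[hit_cells].mean()
        n = int(hit_cells.sum())
        ci = 3 * np.sqrt(0.0856 * (1 - 0.0856) / n)
        assert abs(frac - 0.0856) < ci

    def test_zero_cells_raises(self):
        cfg = small_config()
        lib = generate_library(cfg)
        bad = small_config(cells_per_sgrna=0)
        with pytest.raises(ValueError):
            generate_cells(bad, lib)

    def test_planted_effect_monotonicity(self):
        """Raising the hit-state probability raises signature expression
        in hit-sgRNA cells."""
        means = []
        for prob in (0.05, 0.5):
            cfg = small_config(hit_state_prob=prob, cells_per_sgrna=200, seed=9)
            lib = generate_library(cfg, np.random.default_rng(9))
            m, t = generate_cells(cfg, lib, np.random.default_rng(10))
            hit_cells = t.cell_guides["guide_1"].isin(t.true_hit_sgrnas).to_numpy()
            sig = m.genes["is_signature"].to_numpy()
            means.append(m.counts[hit_cells][:, sig].mean())
        assert means[1] > means[0]


class TestAmpliconReads:
    def test_noiseless_reads_carry_true_protospacer(self):
        cfg = small_config(base_error_rate=0.0, contamination_rate=0.0, doublet_rate=0.0)
        rng = np.random.default_rng(3)
        lib = generate_library(cfg, rng)
        _, t = generate_cells(cfg, lib, rng)
        reads = generate_amplicon_reads(cfg, t, lib, rng)
        protos = lib.guides.set_index("guide_id")["protospacer"]
        true_guide = t.cell_guides["guide_1"]
        for r in list(reads)[:500]:
            assert r.sequence[23:43] == protos[true_guide[r.cell_barcode]]

    def test_observed_base_error_rate(self):
        cfg = small_config(base_error_rate=0.005, contamination_rate=0.0, doublet_rate=0.0,
                           cells_per_sgrna=60)
        rng = np.random.default_rng(4)
        lib = generate_library(cfg, rng)
        _, t = generate_cells(cfg, lib, rng)
        reads = generate_amplicon_reads(cfg, t, lib, rng)
        protos = lib.guides.set_index("guide_id")["protospacer"]
        contexts = lib.upstream_context + "{}" + lib.downstream_context
        mism = total = 0
        true_guide = t.cell_guides["guide_1"]
        for cb, seq in zip(reads.cell_barcodes, reads.sequences):
            template = contexts.format(protos[true_guide[cb]])
            mism += sum(a != b for a, b in zip(seq, template))
            total += len(seq)
        assert total > 1e5
        rate = mism / total
        assert 0.8 * 0.005 < rate < 1.2 * 0.005

    def test_doublet_cells_emit_two_guides(self):
        cfg = small_config(doublet_rate=0.1, base_error_rate=0.0, contamination_rate=0.0,
                           cells_per_sgrna=100, amplicon_reads_per_cell=40.0)
        rng = np.random.default_rng(6)
        lib = generate_library(cfg, rng)
        _, t = generate_cells(cfg, lib, rng)
        frac = t.cell_guides["is_doublet"].mean()
        assert abs(frac - 0.1) < 0.02
        reads = generate_amplicon_reads(cfg, t, lib, rng)
        proto_to_guide = dict(zip(lib.guides["protospacer"], lib.guides["guide_id"]))
        import pandas as pd

        df = pd.DataFrame({
            "cb": reads.cell_barcodes,
            "guide": [proto_to_guide[s[23:43]] for s in reads.sequences],
        })
        n_guides = df.groupby("cb")["guide"].nunique()
        doublets = t.cell_guides.loc[t.cell_guides["is_doublet"]].index
        assert (n_guides.reindex(doublets).dropna() == 2).mean() > 0.95


class TestRepeatReads:
    def test_round_trip_and_elevated_mervl(self, small_screen):
        cfg = small_config(hit_state_prob=0.5, seed=21)
        rng = np.random.default_rng(21)
        lib = generate_library(cfg, rng)
        m, t = generate_cells(cfg, lib, rng)
        refs = generate_repeat_reference(cfg, rng)
        reads = generate_repeat_reads(cfg, t, refs, rng)
        # noiseless reads are substrings of their family instances
        by_fam = {r.family_name: r.instance_sequences for r in refs}
        for r in list(reads)[:200]:
            assert any(r.sequence in inst for seqs in by_fam.values() for inst in seqs)
        # ZGA-state cells show elevated MERVL molecule counts
        state = t.cell_state.to_numpy()
        mervl = t.repeat_molecules["MERVL"].to_numpy()
        assert mervl[state].mean() > 2 * mervl[~state].mean()

    def test_short_instance_raises(self, small_screen):
        from crispra_screen.repeats import build_repeat_reference

        cfg = small_screen["config"]
        refs = build_repeat_reference([(f, ["ACGT"]) for f in cfg.repeat_families])
        with pytest.raises(ValueError):
            generate_repeat_reads(cfg, small_screen["truth"], refs)

    def test_no_state_no_mervl_difference(self):
        cfg = small_config(baseline_state_prob=0.0, hit_state_prob=0.0,
                           cells_per_sgrna=400, seed=13)
        rng = np.random.default_rng(13)
        lib = generate_library(cfg, rng)
        _, t = generate_cells(cfg, lib, rng)
        hit_cells = t.cell_guides["guide_1"].isin(t.true_hit_sgrnas).to_numpy()
        mervl = t.repeat_molecules["MERVL"].to_numpy()
        m1, m0 = mervl[hit_cells].mean(), mervl[~hit_cells].mean()
        assert abs(m1 - m0) / m0 < 0.1


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config(seed=42)
        cfg.to_yaml(tmp_path / "sim.yaml")
        back = SimulationConfig.from_yaml(tmp_path / "sim.yaml")
        assert back == cfg

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            small_config(contamination_rate=1.5).validate()

    def test_library_size_arithmetic(self):
        cfg = small_config(n_target_genes=11, sgrnas_per_target=3, n_nontargeting=2)
        assert cfg.total_guides == 35
        assert len(generate_library(cfg)) == 35
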