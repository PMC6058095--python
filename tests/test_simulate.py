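"""Synthetic-data generator: effect control, determinism, round trips."""

import numpy as np
import pytest

from stoichseq.nitrogen import Habitat, nitrogen_content
from stoichseq.simulate import (
    NITROGEN_SWAP,
    EnvironmentProfile,
    StudyConfig,
    generate_study,
    make_environment_profiles,
    sample_proteome,
    simulate_alignment,
    simulate_membrane_protein,
    simulate_yule_tree,
)
from stoichseq.jtt import AMINO_ACIDS, jtt_model
from stoichseq.nitrogen import SIDE_CHAIN_NITROGEN
from stoichseq.topology import parse_phobius_short, write_phobius_short
from stoichseq.trees import Tree


SMALL_CONFIG = StudyConfig(
    n_sequences_per_group=60,
    n_membrane_per_group=16,
    n_taxa_per_group=15,
    n_alignment_columns=120,
)


class TestEnvironmentProfiles:
    def test_zero_target_keeps_baseline(self):
        coastal, open_ = make_environment_profiles(target_rel_diff_percent=0.0)
        assert np.allclose(coastal.frequencies, open_.frequencies)

    def test_bisection_hits_target(self):
        coastal, open_ = make_environment_profiles(target_rel_diff_percent=-5.0)
        rel = 100 * (open_.expected_nc - coastal.expected_nc) / coastal.expected_nc
        assert rel == pytest.approx(-5.0, abs=1e-6)

    def test_uniform_baseline(self):
        coastal, open_ = make_environment_profiles(
            baseline=np.full(20, 0.05), target_rel_diff_percent=-5.0
        )
        assert open_.expected_nc / coastal.expected_nc == pytest.approx(0.95, abs=1e-6)

    def test_unattainable_target_rejected(self):
        with pytest.raises(ValueError):
            make_environment_profiles(target_rel_diff_percent=-100.0)

    def test_expected_nc_is_frequency_weighted_nitrogen(self):
        profile = EnvironmentProfile(np.full(20, 0.05), Habitat.COASTAL)
        expected = sum(0.05 * SIDE_CHAIN_NITROGEN[a] for a in AMINO_ACIDS)
        assert profile.expected_nc == pytest.approx(expected)


class TestProteome:
    def test_mean_nc_converges_to_expectation(self):
        coastal, _ = make_environment_profiles()
        records = sample_proteome(coastal, 2000, seed=1)
        values = np.array([nitrogen_content(r.sequence).value for r in records])
        sem = values.std(ddof=1) / np.sqrt(len(values))
        assert abs(values.mean() - coastal.expected_nc) <= 3 * sem

    def test_empty_and_determinism(self):
        coastal, _ = make_environment_profiles()
        assert sample_proteome(coastal, 0, seed=0) == []
        a = sample_proteome(coastal, 5, seed=9)
        b = sample_proteome(coastal, 5, seed=9)
        assert a == b

    def test_lengths_pass_default_filter(self):
        coastal, _ = make_environment_profiles()
        records = sample_proteome(coastal, 50, length_range=(101, 150), seed=2)
        assert min(len(r) for r in records) > 100


class TestMembraneProteins:
    def test_phobius_round_trip(self):
        rng = np.random.default_rng(3)
        coastal, _ = make_environment_profiles()
        records, annotations = [], []
        for i in range(50):
            rec, ann = simulate_membrane_protein(
                rng, f"m{i}", n_tm=int(rng.integers(1, 5)),
                loop_profile=coastal, with_signal=bool(rng.random() < 0.3),
            )
            records.append(rec)
            annotations.append(ann)
        text = write_phobius_short(annotations)
        parsed = parse_phobius_short(text, {r.id: len(r) for r in records})
        assert parsed == annotations

    def test_annotation_matches_sequence_length(self):
        rng = np.random.default_rng(4)
        rec, ann = simulate_membrane_protein(rng, "m0", n_tm=3)
        assert ann.length == len(rec)

    def test_loop_sizes_controllable(self):
        rng = np.random.default_rng(5)
        rec, ann = simulate_membrane_protein(
            rng, "m1", n_tm=1, loop_length_range=(20, 40)
        )
        from stoichseq.topology import dissect_domains, filter_domain_sizes

        assert filter_domain_sizes(dissect_domains(rec.sequence, ann), 15)


class TestYuleTree:
    def test_two_taxa_cherry(self):
        tree = simulate_yule_tree(2, seed=0)
        assert sorted(tree.leaf_names) == ["t1", "t2"]

    def test_leaf_count_and_scaling(self):
        tree = simulate_yule_tree(40, seed=1, mean_root_to_tip=0.8)
        assert len(tree.leaf_names) == 40
        depths = []

        def walk(node, acc):
            if node.is_leaf:
                depths.append(acc)
            for c in node.children:
                walk(c, acc + c.length)

        walk(tree.root, 0.0)
        assert np.mean(depths) == pytest.approx(0.8, rel=1e-9)

    def test_seed_reproducibility(self):
        a = simulate_yule_tree(10, seed=7).to_newick()
        b = simulate_yule_tree(10, seed=7).to_newick()
        assert a == b


class TestAlignmentSimulation:
    def test_null_configuration_groups_equal(self):
        tree = simulate_yule_tree(30, seed=2)
        hab = {n: (Habitat.OPEN_OCEAN if i % 2 else Habitat.COASTAL)
               for i, n in enumerate(tree.leaf_names)}
        sim = simulate_alignment(tree, 300, alpha=1e6, seed=3,
                                 habitat_of_leaf=hab, swap_probability=0.0)
        # near-uniform rates and no injected effect
        assert sim.true_rates.std() < 0.01
        nc = {h: [] for h in (Habitat.OPEN_OCEAN, Habitat.COASTAL)}
        for sid, row in zip(sim.alignment.ids, sim.alignment.rows):
            nc[hab[sid]].append(nitrogen_content(row).value)
        diff = abs(np.mean(nc[Habitat.OPEN_OCEAN]) - np.mean(nc[Habitat.COASTAL]))
        assert diff < 0.02

    def test_no_gaps_all_columns_included(self):
        from stoichseq.site_rates import mask_columns

        tree = simulate_yule_tree(8, seed=4)
        sim = simulate_alignment(tree, 60, alpha=0.7, seed=5)
        assert all("-" not in row for row in sim.alignment.rows)
        assert mask_columns(sim.alignment).all()

    def test_swap_targets_carry_no_nitrogen(self):
        assert all(SIDE_CHAIN_NITROGEN[dst] == 0 for dst in NITROGEN_SWAP.values())
        assert set(NITROGEN_SWAP) == {"N", "Q", "K", "W", "H", "R"}

    def test_effect_localized_to_designated_sites(self):
        tree = simulate_yule_tree(60, seed=6)
        leaves = tree.leaf_names
        hab = {n: (Habitat.OPEN_OCEAN if i < 30 else Habitat.COASTAL)
               for i, n in enumerate(leaves)}
        sim = simulate_alignment(
            tree, 500, alpha=0.7, seed=7, habitat_of_leaf=hab,
            fast_site_fraction=0.2, swap_probability=0.5,
        )
        assert sim.designated_fast.sum() == 100
        enc = sim.alignment.encoded()
        nvec = np.array([SIDE_CHAIN_NITROGEN[a] for a in AMINO_ACIDS])
        open_rows = [i for i, s in enumerate(sim.alignment.ids)
                     if hab[s] is Habitat.OPEN_OCEAN]
        coastal_rows = [i for i, s in enumerate(sim.alignment.ids)
                        if hab[s] is Habitat.COASTAL]

        def mean_nc(rows, cols):
            return nvec[enc[np.ix_(rows, cols)]].mean()

        des = np.nonzero(sim.designated_fast)[0]
        rest = np.nonzero(~sim.designated_fast)[0]
        drop_at_designated = 1 - mean_nc(open_rows, des) / mean_nc(coastal_rows, des)
        drop_elsewhere = 1 - mean_nc(open_rows, rest) / mean_nc(coastal_rows, rest)
        assert drop_at_designated > 0.3          # ~50% injected
        assert abs(drop_elsewhere) < 0.1         # nothing injected


@pytest.fixture(scope="module")
def study(tmp_path_factory):
    return generate_study(tmp_path_factory.mktemp("study"), SMALL_CONFIG, master_seed=5)


class TestGenerateStudy:
    def test_all_files_reparse(self, study):
        from stoichseq.annotation import (
            parse_hmm_table, read_cutoff_table, read_gene_table,
        )
        from stoichseq.nitrogen import read_fasta, read_sample_metadata
        from stoichseq.site_rates import read_alignment_fasta

        records = list(read_fasta(study.paths["proteins"]))
        assert len(records) == 2 * SMALL_CONFIG.n_sequences_per_group
        membrane = list(read_fasta(study.paths["membrane_proteins"]))
        lengths = {r.id: len(r) for r in membrane}
        annotations = parse_phobius_short(
            study.paths["phobius"].read_text(), lengths
        )
        assert annotations == study.annotations
        metadata = read_sample_metadata(study.paths["metadata"])
        assert set(metadata.values()) == {
            Habitat.OPEN_OCEAN, Habitat.COASTAL, Habitat.ESTUARY,
        }
        hits = parse_hmm_table(study.paths["hits"].read_text())
        assert len(hits) == len(study.hits)
        read_cutoff_table(study.paths["cutoffs"])
        read_gene_table(study.paths["gene_map"])
        for gene in ("NtcA", "argF"):
            aln = read_alignment_fasta(study.paths[f"alignment:{gene}"])
            assert aln.n_rows == 2 * SMALL_CONFIG.n_taxa_per_group
            Tree.from_newick(study.paths[f"tree:{gene}"].read_text())

    def test_manifest_records_effects(self, study):
        import yaml

        manifest = yaml.safe_load(study.paths["manifest"].read_text())
        assert manifest["master_seed"] == 5
        assert manifest["true_effect"]["proteome_rel_diff_percent"] == -5.0
        ratio = (
            manifest["true_effect"]["open_expected_nc"]
            / manifest["true_effect"]["coastal_expected_nc"]
        )
        assert ratio == pytest.approx(0.95, abs=1e-6)

    def test_same_seed_is_byte_identical(self, tmp_path):
        a = generate_study(tmp_path / "a", SMALL_CONFIG, master_seed=11)
        b = generate_study(tmp_path / "b", SMALL_CONFIG, master_seed=11)
        for key in a.paths:
            assert a.paths[key].read_bytes() == b.paths[key].read_bytes(), key

    def test_failure_cleans_new_directory(self, tmp_path):
        bad = StudyConfig(target_rel_diff_percent=-99.0)
        target = tmp_path / "bad"
        with pytest.raises(ValueError):
            generate_study(target, bad, master_seed=0)
        assert not target.exists()
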