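import numpy as np
import pytest

from nanosieve.errors import ValidationError
from nanosieve.preprocess import preprocess_batch
from nanosieve.signal_io import read_fast5
from nanosieve.simulate import (
    ClassSpec,
    SimConfig,
    build_pore_model,
    generate_dataset,
    mad_units_to_pA,
    random_sequence,
    shifted_kmer_mask,
    simulate_read,
)


class TestPoreModel:
    def test_table_covers_all_kmers(self):
        assert build_pore_model(6, seed=0).means.size == 4 ** 6

    def test_same_seed_identical(self):
        a, b = build_pore_model(6, seed=4), build_pore_model(6, seed=4)
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.sds, b.sds)

    def test_k1_values_within_declared_bands(self):
        pm = build_pore_model(1, seed=0)
        assert pm.means.size == 4
        assert np.all((pm.means >= 60) & (pm.means <= 120))
        assert np.all((pm.sds > 0.5) & (pm.sds < 3.0))

    @pytest.mark.parametrize("k", [0, 9])
    def test_k_out_of_range(self, k):
        with pytest.raises(ValidationError):
            build_pore_model(k, seed=0)


class TestSimulateRead:
    def test_deterministic_signal_length_without_noise(self):
        pm = build_pore_model(3, seed=1)
        cfg = SimConfig(noise_sd_pA=0.0, fixed_dwell=7, adapter_len_range=(0, 0),
                        scale_jitter=0.0, offset_jitter_pA=0.0)
        seq = random_sequence(100, 0.5, np.random.default_rng(0))
        sq = simulate_read(pm, seq, cfg, np.random.default_rng(1))
        assert len(sq) == (100 - 3 + 1) * 7

    def test_same_seed_identical_reads(self):
        pm = build_pore_model(4, seed=1)
        cfg = SimConfig()
        seq = random_sequence(200, 0.5, np.random.default_rng(3))
        a = simulate_read(pm, seq, cfg, np.random.default_rng(9))
        b = simulate_read(pm, seq, cfg, np.random.default_rng(9))
        np.testing.assert_array_equal(a.raw, b.raw)

    def test_sequence_shorter_than_k_rejected(self):
        pm = build_pore_model(6, seed=1)
        with pytest.raises(ValidationError):
            simulate_read(pm, "ACGT", SimConfig(), np.random.default_rng(0))

    def test_mean_samples_per_base_matches_speed(self):
        # expected sampling_rate / speed = 4000/450 = 8.889 samples/base
        pm = build_pore_model(3, seed=1)
        cfg = SimConfig(adapter_len_range=(0, 0))
        rng = np.random.default_rng(5)
        ratios = []
        for _ in range(200):
            seq = random_sequence(300, 0.5, rng)
            sq = simulate_read(pm, seq, cfg, rng)
            ratios.append(len(sq) / (300 - 3 + 1))
        assert 8.0 <= float(np.mean(ratios)) <= 9.8


@pytest.fixture(scope="module")
def small_corpus(tmp_path_factory):
    out = tmp_path_factory.mktemp("sim")
    pore = build_pore_model(6, seed=6)
    shift = mad_units_to_pA(pore, 1.0)
    cfg = SimConfig(classes=[ClassSpec(), ClassSpec(level_shift_pA=shift)],
                    reads_per_class=50, seed=6)
    container, manifest = generate_dataset(cfg, out, pore_model=pore)
    return container, manifest, cfg, pore


class TestGenerateDataset:
    def test_manifest_counts(self, small_corpus):
        _, manifest, _, _ = small_corpus
        assert len(manifest) == 100
        assert manifest.rows["label"].value_counts().tolist() == [50, 50]

    def test_round_trip_through_signal_io(self, small_corpus):
        container, manifest, _, _ = small_corpus
        reads = read_fast5(container)
        assert len(reads) == 100
        assert sorted(r.read_id for r in reads) == sorted(manifest.rows["read_id"])
        assert all(r.label in (0, 1) for r in reads)

    def test_reads_long_enough_for_default_window(self, small_corpus):
        container, _, _, _ = small_corpus
        reads = read_fast5(container)
        ok = sum(len(r) >= 1500 + 3000 for r in reads)
        assert ok >= 99

    def test_level_shift_moves_mean_current_up(self, small_corpus):
        container, _, _, _ = small_corpus
        reads = read_fast5(container)
        means = {0: [], 1: []}
        for r in reads:
            means[r.label].append(float(r.to_pA()[1500:4500].mean()))
        assert np.mean(means[1]) > np.mean(means[0])

    def test_regeneration_is_byte_identical(self, tmp_path):
        cfgs = [SimConfig(classes=[ClassSpec(), ClassSpec(level_shift_pA=5.0)],
                          reads_per_class=5, seed=13) for _ in range(2)]
        outs = []
        for i, cfg in enumerate(cfgs):
            container, _ = generate_dataset(cfg, tmp_path / f"run{i}")
            outs.append((container, tmp_path / f"run{i}" / "manifest.tsv"))
        assert outs[0][1].read_bytes() == outs[1][1].read_bytes()
        a, b = read_fast5(outs[0][0]), read_fast5(outs[1][0])
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.raw, rb.raw)

    def test_emitted_windows_are_normalizable(self, small_corpus):
        container, _, _, _ = small_corpus
        windows, excluded = preprocess_batch(read_fast5(container),
                                             skip=1500, length=3000)
        assert len(windows) + len(excluded) == 100
        assert len(windows) >= 99


class TestShiftedSubset:
    def test_top_mode_selects_stated_fraction(self):
        pm = build_pore_model(6, seed=0)
        mask = shifted_kmer_mask(pm, ClassSpec(level_shift_pA=1.0,
                                               shift_mode="top",
                                               shifted_fraction=0.25))
        assert mask.mean() == pytest.approx(0.25, abs=0.01)
        # selected k-mers are exactly the highest-level ones
        assert pm.means[mask].min() >= pm.means[~mask].max()

    def test_leading_base_mode_selects_by_prefix(self):
        pm = build_pore_model(3, seed=0)
        mask = shifted_kmer_mask(pm, ClassSpec(shift_mode="leading_base",
                                               shifted_bases="A"))
        assert mask.mean() == pytest.approx(0.25)
        assert mask[:16].all() and not mask[16:].any()

    def test_unknown_mode_rejected(self):
        pm = build_pore_model(2, seed=0)
        with pytest.raises(ValidationError):
            shifted_kmer_mask(pm, ClassSpec(shift_mode="bogus"))
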