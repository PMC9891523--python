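import math

import numpy as np
import pytest

from memnovo.datasets import (
    build_mem,
    build_motm,
    diversity_factor,
    diversity_profile,
    read_dataset_table,
    sample_equal,
    split_dataset,
    terminal_trimers,
    write_dataset_table,
)

from conftest import make_dataset, random_sequence


class TestTrimers:
    def test_shared_prefix_collapses_n_trimers(self):
        ds = make_dataset(["ACDEFK", "ACDGGR"])
        assert terminal_trimers(ds, "N") == {"ACD"}
        assert terminal_trimers(ds, "C") == {"EFK", "GGR"}

    def test_single_peptide_has_one_trimer_each(self):
        ds = make_dataset(["ACDEFK"])
        assert len(terminal_trimers(ds, "N")) == len(terminal_trimers(ds, "C")) == 1

    def test_modifications_are_stripped_before_counting(self):
        ds = make_dataset(["C(cam)ACDEF", "CACDEF"])
        assert terminal_trimers(ds, "N") == {"CAC"}

    def test_short_peptide_is_an_error(self):
        ds = make_dataset(["ACDEF"])  # length 5 < 6
        with pytest.raises(ValueError, match="minimum length"):
            terminal_trimers(ds, "N")

    def test_duplicate_sequences_do_not_inflate_counts(self):
        ds = make_dataset(["ACDEFK", "ACDEFK", "GGDEFK"])
        assert terminal_trimers(ds, "N") == {"ACD", "GGD"}


class TestDiversityFactor:
    def test_balanced_termini_give_zero(self):
        assert diversity_factor(123, 123) == 0.0

    def test_log10_scale(self):
        assert diversity_factor(1000, 100) == pytest.approx(1.0)
        assert diversity_factor(100, 1000) == pytest.approx(-1.0)

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            diversity_factor(0, 10)

    def test_profile_combines_counts_and_df(self):
        ds = make_dataset(["ACDEFK", "ACDGGR", "ACDHHR"])
        p = diversity_profile(ds)
        assert (p.Tn, p.Tc) == (1, 3)
        assert p.DF == pytest.approx(math.log10(1 / 3))
        assert p.n_records == 3


class TestSampling:
    def test_sampling_whole_set_is_identity_up_to_order(self, rng):
        peps = [random_sequence(rng, 8) for _ in range(50)]
        ds = make_dataset(sorted(set(peps)))
        (out,) = sample_equal([ds], len(ds), seed=7)
        assert sorted(r.peptide for r in out.records) == sorted(set(peps))

    def test_same_seed_same_selection(self, rng):
        ds = make_dataset([random_sequence(rng, 8) + str() for _ in range(200)])
        a = sample_equal([ds], 50, seed=3)[0]
        b = sample_equal([ds], 50, seed=3)[0]
        assert [r.peptide for r in a.records] == [r.peptide for r in b.records]
        c = sample_equal([ds], 50, seed=4)[0]
        assert [r.peptide for r in a.records] != [r.peptide for r in c.records]

    def test_insufficient_records_error_names_dataset(self, rng):
        ds = make_dataset([random_sequence(rng, 8) for _ in range(5)], name="tiny")
        with pytest.raises(ValueError, match="tiny"):
            sample_equal([ds], 100, seed=0)

    def test_sampling_is_over_unique_sequences(self):
        ds = make_dataset(["ACDEFK"] * 10 + ["GGDEFK"] * 10)
        (out,) = sample_equal([ds], 2, seed=0)
        assert sorted(r.peptide for r in out.records) == ["ACDEFK", "GGDEFK"]


class TestSplit:
    @pytest.mark.parametrize("n, expected", [(20, (18, 1, 1)), (21492, (19342, 1075, 1075)), (21, (18, 2, 1))])
    def test_split_sizes(self, n, expected):
        ds = make_dataset(["KKKKKK"] * n)  # split acts on records, not unique sequences
        train, valid, test = split_dataset(ds, seed=1)
        assert (len(train), len(valid), len(test)) == expected

    def test_partition_is_disjoint_and_complete(self, rng):
        peps = [random_sequence(rng, 10) for _ in range(97)]
        ds = make_dataset(peps)
        train, valid, test = split_dataset(ds, seed=5)
        ids = [r.spectrum_id for part in (train, valid, test) for r in part.records]
        assert len(ids) == len(set(ids)) == len(ds)
        assert {r.spectrum_id for r in ds.records} == set(ids)
        assert (train.role, valid.role, test.role) == ("train", "valid", "test")


class TestMoTM:
    def test_all_peptides_share_the_terminal_residue(self, rng):
        peps = list({random_sequence(rng, 9) + rng.choice(list("KRAG")) for _ in range(400)})
        ds = make_dataset(peps)
        n_avail = sum(1 for p in peps if p.endswith("R"))
        motm = build_motm(ds, "R", "C", n_avail, seed=2)
        assert len(motm) == n_avail
        assert all(r.bare_sequence.endswith("R") for r in motm.records)

    def test_c_restricted_trimer_count_is_bounded_by_400(self, rng):
        peps = list({random_sequence(rng, 9) + "R" for _ in range(3000)})
        motm = build_motm(make_dataset(peps), "R", "C", len(peps), seed=0)
        assert len(terminal_trimers(motm, "C")) <= 400

    def test_absent_residue_reports_available_count(self, rng):
        ds = make_dataset([random_sequence(rng, 8) + "K" for _ in range(20)])
        with pytest.raises(ValueError, match="only 0"):
            build_motm(ds, "W", "C", 5, seed=0)


class TestMEM:
    def test_union_with_self_is_idempotent(self, rng):
        peps = [random_sequence(rng, 8) for _ in range(60)]
        a = make_dataset(peps, name="a")
        b = make_dataset(peps, name="b")
        merged = build_mem([a, b])
        assert sorted(merged.unique_peptides()) == sorted(set(peps))

    def test_duplicate_names_rejected(self, rng):
        ds = make_dataset([random_sequence(rng, 8) for _ in range(10)], name="x")
        with pytest.raises(ValueError, match="duplicate"):
            build_mem([ds, ds])

    def test_merge_never_decreases_trimer_counts(self, rng):
        parts = [
            make_dataset([random_sequence(rng, 8) for _ in range(150)], name=f"p{i}")
            for i in range(3)
        ]
        merged = build_mem(parts)
        for terminus in "NC":
            merged_count = len(terminal_trimers(merged, terminus))
            for part in parts:
                assert merged_count >= len(terminal_trimers(part, terminus))

    def test_balanced_sample_draws_equally(self, rng):
        parts = [
            make_dataset([random_sequence(rng, 8) for _ in range(100)], name=f"p{i}")
            for i in range(2)
        ]
        merged = build_mem(parts, mode="balanced-sample", n=80, seed=1)
        assert len(merged) == 80
        # provenance via spectrum ids assigned per part
        from_p0 = sum(r.spectrum_id.startswith("p0") for r in merged.records)
        assert from_p0 == 40


class TestTableRoundTrip:
    def test_write_read_preserves_records(self, tmp_path, rng):
        ds = make_dataset(
            [random_sequence(rng, 8) for _ in range(20)], name="rt", enzyme="trypsin"
        )
        path = tmp_path / "ds.tsv"
        write_dataset_table(ds, path)
        back = read_dataset_table(path, name="rt")
        assert [r.peptide for r in back.records] == [r.peptide for r in ds.records]
        assert all(r.source_enzyme == "trypsin" for r in back.records)
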