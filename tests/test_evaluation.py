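import numpy as np
import pytest

from memnovo.evaluation import (
    EquivalencePolicy,
    PredictionRecord,
    evaluate_records,
    peptide_correct,
    peptide_recall,
    recall_grid,
    recall_vs_maxlen,
)
from memnovo.ion_recall import IonRecallRecord
from memnovo.synthetic import SyntheticScenario, simulate_predictions, simulate_spectra
from memnovo.ion_recall import ion_recall_table

from conftest import make_dataset, random_sequence


class TestPeptideCorrect:
    def test_identity(self):
        assert peptide_correct("PEPTIDEK", "PEPTIDEK")

    def test_ile_leu_equivalent_by_default(self):
        assert peptide_correct("LEPTIDE", "IEPTIDE")
        assert not peptide_correct("LEPTIDE", "IEPTIDE", EquivalencePolicy(False))

    def test_length_mismatch_is_incorrect(self):
        assert not peptide_correct("PEPTIDE", "PEPTIDEK")

    def test_modified_tokens_must_match_exactly(self):
        assert not peptide_correct("AM(ox)DEFK", "AMDEFK")
        assert peptide_correct("AM(ox)DEFK", "AM(ox)DEFK")

    def test_near_isobars_are_distinct(self):
        assert not peptide_correct("AQDEFK", "AKDEFK")

    def test_empty_prediction_is_incorrect_not_an_error(self):
        assert not peptide_correct("", "PEPTIDE")

    def test_empty_truth_is_an_error(self):
        with pytest.raises(ValueError):
            peptide_correct("PEPTIDE", "")


def make_predictions(spec, n=40, enzyme=""):
    """spec: fraction correct; wrong predictions get a length-mismatch tail."""
    recs = []
    for i in range(n):
        truth = "PEPTIDEK"
        predicted = truth if i < spec * n else truth + "K"
        recs.append(PredictionRecord(f"s{enzyme}{i}", predicted, truth, enzyme))
    return recs


class TestPeptideRecall:
    def test_all_correct_gives_one(self):
        assert peptide_recall(make_predictions(1.0)) == 1.0

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            peptide_recall([])

    def test_global_equals_size_weighted_mean_of_locals(self):
        records = make_predictions(0.5, 40, "trypsin") + make_predictions(0.75, 20, "gluC")
        records = evaluate_records(records)
        local = peptide_recall(records, group_by="source_enzyme")
        sizes = {"trypsin": 40, "gluC": 20}
        weighted = sum(local[e] * sizes[e] for e in sizes) / sum(sizes.values())
        assert peptide_recall(records) == pytest.approx(weighted)

    def test_surrogate_predictor_probability_recovered(self, rng):
        """Measured recall matches the generator's correctness probability."""
        peps = list({random_sequence(rng, 10) for _ in range(1200)})
        ds = make_dataset(peps, name="p", enzyme="x")
        scenario = SyntheticScenario(seed=17, predictor_base_accuracy=0.6)
        records = simulate_predictions(ds, scenario)
        # +/- 3 binomial SEs at p=0.6
        se = np.sqrt(0.6 * 0.4 / len(peps))
        assert peptide_recall(records) == pytest.approx(0.6, abs=3 * se)


class TestRecallVsMaxLen:
    def test_single_cutoff_covering_everything_equals_global(self):
        records = evaluate_records(make_predictions(0.6))
        curve = recall_vs_maxlen(records, [30])
        assert curve.recall.iloc[0] == pytest.approx(peptide_recall(records))
        assert curve.n.iloc[0] == len(records)

    def test_cutoff_below_all_lengths_is_undefined(self):
        records = make_predictions(1.0)
        curve = recall_vs_maxlen(records, [6])
        assert curve.n.iloc[0] == 0 and np.isnan(curve.recall.iloc[0])

    def test_length_decay_gives_nonincreasing_curve(self, rng):
        peps = list({random_sequence(rng, int(rng.integers(6, 26))) for _ in range(2500)})
        ds = make_dataset(peps, name="decay")
        scenario = SyntheticScenario(
            seed=23, predictor_base_accuracy=0.95, predictor_length_decay=0.8
        )
        records = evaluate_records(simulate_predictions(ds, scenario))
        curve = recall_vs_maxlen(records, range(6, 27, 2))
        vals = curve.recall.dropna().to_numpy()
        assert np.all(np.diff(vals) <= 1e-12)


def ion_record(sid, b, y):
    return IonRecallRecord(sid, "", b, y)


class TestRecallGrid:
    def test_origin_cell_equals_global_recall_exactly(self):
        records = evaluate_records(make_predictions(0.6))
        ions = [ion_record(r.spectrum_id, 0.5, 0.5) for r in records]
        grid = recall_grid(records, ions)
        assert grid.cell_recall[0, 0] == peptide_recall(records)
        assert grid.cell_count[0, 0] == len(records)

    def test_empty_cells_are_nan_with_zero_count(self):
        records = evaluate_records(make_predictions(1.0, 10))
        ions = [ion_record(r.spectrum_id, 0.5, 0.5) for r in records]
        grid = recall_grid(records, ions)
        assert grid.cell_count[-1, -1] == 0
        assert np.isnan(grid.cell_recall[-1, -1])

    def test_counts_nonincreasing_along_both_axes(self, rng):
        records = evaluate_records(make_predictions(0.5, 50))
        ions = [
            ion_record(r.spectrum_id, rng.uniform(), rng.uniform()) for r in records
        ]
        grid = recall_grid(records, ions)
        assert np.all(np.diff(grid.cell_count, axis=0) <= 0)
        assert np.all(np.diff(grid.cell_count, axis=1) <= 0)

    def test_unjoinable_ids_rejected(self):
        records = make_predictions(1.0, 3)
        with pytest.raises(KeyError):
            recall_grid(records, [])

    def test_ionrecall_coupling_gives_monotone_grid(self, rng):
        """Correctness rising with ion recall ⇒ cell recall non-decreasing."""
        peps = list({random_sequence(rng, int(rng.integers(8, 15))) for _ in range(2000)})
        ds = make_dataset(peps, name="g")
        scenario = SyntheticScenario(
            seed=31,
            ion_dropout={"b": 0.3, "y": 0.3},
            predictor_base_accuracy=0.5,
            predictor_ionrecall_coupling=1.0,
        )
        spectra = simulate_spectra(ds, scenario)
        ions = ion_recall_table(spectra, ds)
        records = evaluate_records(simulate_predictions(ds, scenario, ions))
        grid = recall_grid(records, ions)
        # compare only populated cells, tolerating small-sample noise in
        # sparsely populated high-threshold cells
        r = grid.cell_recall
        n = grid.cell_count
        for axis in (0, 1):
            a = np.moveaxis(r, axis, 0)
            c = np.moveaxis(n, axis, 0)
            for i in range(a.shape[0] - 1):
                mask = (c[i] >= 50) & (c[i + 1] >= 50)
                assert np.all(a[i + 1][mask] >= a[i][mask] - 0.05)
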