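"""Synthetic-screen generator: construction, count model, doublets,
ground-truth recoverability and fixture round trips."""

import numpy as np
import pytest
from scipy import stats

import tcrspec as ts
from tcrspec.io import read_screen_tables
from tcrspec.simulate import _default_motifs


def config(**kw):
    base = dict(n_clonotypes=100, n_antigens=4, n_donors=2, n_nc=3,
                n_surface=4, seed=5)
    base.update(kw)
    return ts.ScreenSimConfig(**base)


class TestRepertoire:
    def test_fixed_clone_size_counts(self):
        screen = ts.simulate_repertoire(config(clone_size=("fixed", 3)))
        assert len(screen.cells) == 300
        pairs = {(c.cdr3a, c.cdr3b) for c in screen.cells}
        assert len(pairs) == 100

    def test_zero_mutation_plants_motif_verbatim(self):
        cfg = config(motif_mutation_rate=0.0, clone_size=("fixed", 2))
        screen = ts.simulate_repertoire(cfg)
        motifs = {
            m.antigen_index: m
            for m in _default_motifs(
                np.random.default_rng(cfg.seed), cfg.n_antigens, 0.0
            )
        }
        for cell in screen.cells:
            label = screen.truth[cell.barcode]
            if label is not None:
                m = motifs[label]
                assert cell.cdr3b[m.insert_position:m.insert_position + 4] == m.motif

    def test_same_seed_identical_output(self):
        a = ts.simulate_screen(config(doublet_rate=0.1))
        b = ts.simulate_screen(config(doublet_rate=0.1))
        assert a.cells == b.cells
        assert a.truth == b.truth

    def test_motif_longer_than_min_cdr3_rejected(self):
        with pytest.raises(ValueError):
            config(
                cdr3_length_range=(8, 10),
                motifs=(ts.MotifSpec(0, "AAAAAA", insert_position=3),),
            )

    def test_exact_motif_containment_recovers_truth(self):
        # learnability baseline: with zero mutation, positional motif
        # matching classifies every clonotype correctly
        cfg = config(n_clonotypes=300, motif_mutation_rate=0.0, seed=9)
        screen = ts.simulate_repertoire(cfg)
        motifs = _default_motifs(np.random.default_rng(cfg.seed), cfg.n_antigens, 0.0)
        correct = 0
        for cell in screen.cells:
            hits = [
                m.antigen_index for m in motifs
                if cell.cdr3b[m.insert_position:m.insert_position + len(m.motif)]
                == m.motif
            ]
            predicted = hits[0] if len(hits) == 1 else None
            correct += predicted == screen.truth[cell.barcode]
        assert correct == len(screen.cells)


class TestCounts:
    def test_null_binding_signal_matches_background(self):
        cm = ts.CountModel(binding_mean=0.0, background_mean=2.0)
        screen = ts.simulate_repertoire(config(n_clonotypes=400, count_model=cm))
        ts.simulate_pmhc_counts(screen)
        counts = np.array([c.pmhc_counts for c in screen.cells], dtype=float)
        target_means, other_means = [], []
        for i, cell in enumerate(screen.cells):
            label = screen.truth[cell.barcode]
            if label is not None:
                target_means.append(counts[i, label])
                other_means.append(np.delete(counts[i], label).mean())
        assert np.mean(target_means) == pytest.approx(np.mean(other_means), rel=0.2)

    def test_binarization_recovery_monotone_in_signal_ratio(self):
        rates = []
        for ratio in (1.0, 5.0, 25.0, 100.0):
            cm = ts.CountModel(binding_mean=ratio, background_mean=1.0)
            screen = ts.simulate_repertoire(
                config(n_clonotypes=800, clone_size=("fixed", 1), count_model=cm)
            )
            ts.simulate_pmhc_counts(screen)
            ts.assign_binder_labels(screen.cells)
            truth_pos = [c for c in screen.cells if screen.truth[c.barcode] is not None]
            recovered = sum(
                c.binder_label == screen.truth[c.barcode] for c in truth_pos
            )
            rates.append(recovered / len(truth_pos))
        assert all(b >= a - 0.01 for a, b in zip(rates, rates[1:]))
        assert rates[-1] > 0.9

    def test_uniform_priors_leave_labels_donor_independent(self):
        # chi-square on the donor × label table is non-significant
        pvals = []
        for seed in (1, 2, 3):
            screen = ts.simulate_repertoire(
                config(n_clonotypes=10_000, n_donors=4, clone_size=("fixed", 1),
                       seed=seed)
            )
            donors = np.array([c.donor for c in screen.cells])
            labels = np.array(
                [-1 if screen.truth[c.barcode] is None else screen.truth[c.barcode]
                 for c in screen.cells]
            )
            table = [
                [np.sum((donors == d) & (labels == l)) for l in np.unique(labels)]
                for d in np.unique(donors)
            ]
            pvals.append(stats.chi2_contingency(table).pvalue)
        assert all(p > 0.001 for p in pvals)

    def test_biased_priors_shift_label_frequencies(self):
        screen = ts.simulate_repertoire(
            config(n_clonotypes=4000, n_donors=4, clone_size=("fixed", 1),
                   donor_label_bias=ts.biased_donor_priors(4, 4, 0.9, 0.3))
        )
        donors = np.array([int(c.donor.split("_")[1]) for c in screen.cells])
        labels = np.array(
            [screen.truth[c.barcode] for c in screen.cells], dtype=object
        )
        for d in range(4):
            bound = labels[(donors == d) & (labels != None)]  # noqa: E711
            values, counts = np.unique(bound.astype(int), return_counts=True)
            assert values[np.argmax(counts)] == d % 4


class TestDoublets:
    def test_rate_zero_is_identity(self):
        screen = ts.simulate_repertoire(config())
        before = [tuple(c.cdr3b_list) for c in screen.cells]
        ts.inject_doublets(screen, 0.0)
        assert [tuple(c.cdr3b_list) for c in screen.cells] == before

    def test_flagged_count_matches_rate(self):
        screen = ts.simulate_repertoire(config(n_clonotypes=500, clone_size=("fixed", 2)))
        ts.simulate_pmhc_counts(screen)
        ts.inject_doublets(screen, 0.1)
        assert len(screen.doublet_barcodes) == round(0.1 * 1000)

    def test_doublet_filter_removes_exactly_flagged_cells(self):
        screen = ts.simulate_screen(config(n_clonotypes=300, doublet_rate=0.1))
        kept, removed = ts.filter_doublets(screen.cells)
        assert {c.barcode for c in removed} == screen.doublet_barcodes

    def test_invalid_rate_rejected(self):
        screen = ts.simulate_repertoire(config())
        with pytest.raises(ValueError):
            ts.inject_doublets(screen, 1.5)


class TestPairDatabase:
    def test_each_tcr_in_exactly_one_positive_pair(self):
        pairs = ts.simulate_pair_database(500, 5, seed=0)
        assert len(pairs) == 500
        assert len({p.cdr3b for p in pairs}) == 500
        assert len({p.antigen for p in pairs}) == 5
        assert all(p.label == 1 for p in pairs)

    def test_antigen_peptide_lengths(self):
        pairs = ts.simulate_pair_database(50, 3, seed=1)
        assert all(8 <= len(p.antigen) <= 12 for p in pairs)

    def test_requires_two_antigens(self):
        with pytest.raises(ValueError):
            ts.simulate_pair_database(10, 1)


class TestFixtureFiles:
    def test_write_read_round_trip(self, small_screen, tmp_path):
        matrix, clono = ts.write_fixture_files(small_screen, tmp_path)
        cells, panel = read_screen_tables(matrix, clono)
        assert cells == small_screen.cells
        assert panel.names == small_screen.panel.names

    def test_binder_columns_consistent_with_binarization(self, small_screen, tmp_path):
        import pandas as pd

        matrix, _ = ts.write_fixture_files(small_screen, tmp_path)
        df = pd.read_csv(matrix)
        pmhc = df[list(small_screen.panel.names)].to_numpy()
        nc = df[list(small_screen.panel.nc_names)].to_numpy()
        expected = ts.binarize_table(pmhc, nc)
        binder_cols = df[[f"{a}_binder" for a in small_screen.panel.names]].to_numpy()
        for i in range(len(df)):
            if expected[i] < 0:
                assert not binder_cols[i].any()
            else:
                assert binder_cols[i, expected[i]]

    def test_row_count_matches_cells(self, small_screen, tmp_path):
        matrix, _ = ts.write_fixture_files(small_screen, tmp_path)
        assert sum(1 for _ in open(matrix)) - 1 == len(small_screen.cells)
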