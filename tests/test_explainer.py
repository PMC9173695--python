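"""explainer: backgrounds, SHAP additivity, aggregation, plots."""

import numpy as np
import pytest

import xlnc1d as x
from xlnc1d import cnn_model, explainer


def _dummy_dataset(n_per_class=200, L=8):
    n = 2 * n_per_class
    tensor = np.zeros((n, L, 4), dtype=np.float32)
    tensor[:, :, 0] = 1.0
    labels = np.array([1] * n_per_class + [0] * n_per_class)
    return x.EncodedDataset(tensor, labels, np.full(n, L), [f"s{i}" for i in range(n)])


class TestSelectBackground:
    def test_default_draw_is_350_total(self):
        bg = x.select_background(_dummy_dataset(1000), seed=1)
        assert len(bg) == 350
        assert (bg.labels == 1).sum() == 175 and (bg.labels == 0).sum() == 175

    def test_without_replacement_and_deterministic(self):
        ds = _dummy_dataset(30)
        b1 = x.select_background(ds, n_per_class=10, seed=4)
        b2 = x.select_background(ds, n_per_class=10, seed=4)
        assert b1.ids == b2.ids
        assert len(set(b1.ids)) == 20

    def test_insufficient_class_errors_with_name_and_count(self):
        ds = _dummy_dataset(2)
        with pytest.raises(ValueError, match="lncRNA has 2"):
            x.select_background(ds, n_per_class=3, seed=0)


class TestComputeShap:
    def test_background_equal_to_input_gives_zero_sum(self, tiny_model):
        model, ds, _ = tiny_model
        sole = ds.subset([0])
        bg = explainer.BackgroundSet(sole.tensor, sole.ids, sole.labels[:1], seed=0)
        attrs = x.compute_shap(model, bg, sole, n_steps=10)
        # additivity with x == background: f(x) - f(x) = 0
        assert abs(attrs[0].values.sum()) < 1e-4

    def test_all_zero_input_and_background(self, tiny_model):
        model, ds, _ = tiny_model
        L = ds.input_length
        zeros = x.EncodedDataset(
            np.zeros((1, L, 4), np.float32), np.array([0]), np.array([0]), ["z"]
        )
        bg = explainer.BackgroundSet(zeros.tensor.copy(), ["zb"], np.array([0]), 0)
        attrs = x.compute_shap(model, bg, zeros, n_steps=5)
        assert np.abs(attrs[0].values).max() < 1e-7

    def test_additivity_against_direct_model_evaluation(self, tiny_model):
        model, ds, _ = tiny_model
        bg = x.select_background(ds, n_per_class=4, seed=2)
        subset = ds.subset([0, 1, 30, 31])
        attrs = x.compute_shap(model, bg, subset, n_steps=25)
        probs = cnn_model.predict_proba(model, subset.tensor)[:, 1]
        for attr, p in zip(attrs, probs):
            assert attr.values.sum() + attr.base_value == pytest.approx(p, abs=0.05)

    def test_empty_background_rejected(self, tiny_model):
        model, ds, _ = tiny_model
        bg = explainer.BackgroundSet(
            np.zeros((0, ds.input_length, 4), np.float32), [], np.array([]), 0
        )
        with pytest.raises(ValueError, match="empty"):
            x.compute_shap(model, bg, ds.subset([0]))


class TestCollapseAndCodons:
    def test_channel_sum_row(self):
        attr = explainer.AttributionMatrix(
            values=np.array([[0.1, -0.2, 0.3, 0.0]]), base_value=0.0,
            seq_id="a", seq_length=1,
        )
        assert x.collapse_to_nucleotide(attr).values[0] == pytest.approx(0.2)

    def test_total_conserved_to_machine_precision(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(6, 4))
        attr = explainer.AttributionMatrix(vals, 0.0, "a", 6)
        track = x.collapse_to_nucleotide(attr)
        assert track.values.sum() == pytest.approx(vals.sum(), rel=1e-12)

    def test_codon_frames_worked_example(self):
        track = explainer.NucleotideTrack(np.array([1.0, 2, 3, 4, 5, 6]))
        ct = x.codon_aggregate(track)
        assert np.allclose(ct.frames[0], [6, 15])
        assert np.allclose(ct.frames[1], [9])
        assert np.allclose(ct.frames[2], [12])

    def test_codon_frames_match_window_oracle(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=20)
        ct = x.codon_aggregate(explainer.NucleotideTrack(v))
        for f in range(3):
            expect = [sum(v[f + 3 * j : f + 3 * j + 3]) for j in range((20 - f) // 3)]
            assert np.allclose(ct.frames[f], expect)
            # conservation over the covered extent
            n = (20 - f) // 3
            assert ct.frames[f].sum() == pytest.approx(v[f : f + 3 * n].sum())

    def test_short_track_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            x.codon_aggregate(explainer.NucleotideTrack(np.array([1.0, 2])))


class TestKmerImpact:
    def test_worked_example_atgatg(self):
        # windows over "ATGATG" with track (1,0,0,1,0,0):
        # ATG@0 -> |1+0+0| = 1, TGA@1 -> |0+0+1| = 1, GAT@2 -> |0+1+0| = 1,
        # ATG@3 -> |1+0+0| = 1
        rec = x.SequenceRecord("a", "ATGATG", label=x.MRNA)
        track = explainer.NucleotideTrack(np.array([1.0, 0, 0, 1, 0, 0]), "a")
        table = x.kmer_impact([track], [rec], k=3).set_index("kmer")
        assert table.loc["ATG", "mean_abs_shap_mRNA"] == pytest.approx(1.0)
        assert table.loc["TGA", "mean_abs_shap_mRNA"] == pytest.approx(1.0)
        assert table.loc["GAT", "mean_abs_shap_mRNA"] == pytest.approx(1.0)
        assert table.loc["TTT", "mean_abs_shap_mRNA"] == 0.0
        assert table.loc["ATG", "count_mRNA"] == 2
        assert table.loc["TGA", "count_mRNA"] == 1
        assert len(table) == 64

    def test_zero_tracks_zero_impacts(self):
        rec = x.SequenceRecord("a", "ACGTACGT", label=x.LNCRNA)
        track = explainer.NucleotideTrack(np.zeros(8), "a")
        table = x.kmer_impact([track], [rec], k=2)
        assert (table["mean_abs_shap_lncRNA"] == 0).all()
        assert len(table) == 16

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_brute_force_group_by(self, k):
        rng = np.random.default_rng(8)
        recs, tracks = [], []
        for i, label in enumerate([x.LNCRNA, x.MRNA, x.LNCRNA]):
            seq = "".join(rng.choice(list("ACGT"), size=30))
            recs.append(x.SequenceRecord(f"s{i}", seq, label=label))
            tracks.append(explainer.NucleotideTrack(rng.normal(size=30), f"s{i}"))
        table = x.kmer_impact(tracks, recs, k=k).set_index("kmer")
        # independent tally
        groups: dict[tuple[str, str], list[float]] = {}
        for rec, tr in zip(recs, tracks):
            for p in range(30 - k + 1):
                kmer = rec.residues[p : p + k]
                groups.setdefault((rec.label, kmer), []).append(
                    abs(float(np.sum(tr.values[p : p + k])))
                )
        for (label, kmer), vals in groups.items():
            assert table.loc[kmer, f"mean_abs_shap_{label}"] == pytest.approx(
                np.mean(vals)
            )
            assert table.loc[kmer, f"count_{label}"] == len(vals)

    def test_id_mismatch_rejected(self):
        rec = x.SequenceRecord("a", "ACGTAA", label=x.LNCRNA)
        track = explainer.NucleotideTrack(np.zeros(6), "b")
        with pytest.raises(ValueError, match="mismatch"):
            x.kmer_impact([track], [rec], k=1)


class TestPlot:
    def test_all_positive_track_has_no_red(self, tmp_path):
        rec = x.SequenceRecord("a", "ACGTACGTA", label=x.LNCRNA)
        track = explainer.NucleotideTrack(np.ones(9), "a")
        meta = x.plot_attribution(
            x.codon_aggregate(track), rec, tmp_path / "plot.png"
        )
        assert meta.colors() == {"blue"}
        assert (tmp_path / "plot.png").stat().st_size > 0

    def test_sign_flip_swaps_colors(self, tmp_path):
        rec = x.SequenceRecord("a", "ACGTACGTA", label=x.LNCRNA)
        rng = np.random.default_rng(1)
        v = rng.normal(size=9)
        m1 = x.plot_attribution(
            x.codon_aggregate(explainer.NucleotideTrack(v)), rec, tmp_path / "p1.png"
        )
        m2 = x.plot_attribution(
            x.codon_aggregate(explainer.NucleotideTrack(-v)), rec, tmp_path / "p2.png"
        )
        for f in range(3):
            c1 = [s.color for s in m1.segments[f]]
            c2 = [s.color for s in m2.segments[f]]
            assert [
                "red" if c == "blue" else "blue" for c in c1
            ] == c2


class TestMotifSpecificity:
    def test_no_lncrna_window_beats_motif_signal_in_most_sequences(
        self, study_attributions, study_data
    ):
        """lncRNA-like sequences carry no motif: no 57-nt window should look
        as important as the planted-motif region does in mRNA-like ones,
        for at least 70% of them."""
        anns = study_data["annotations"]
        motif_means = []
        for rec, track in zip(
            study_attributions["records"], study_attributions["tracks"]
        ):
            if rec.label != x.MRNA:
                continue
            a = anns[rec.id]
            motif_means.append(np.abs(track.values[a.start : a.end]).mean())
        motif_level = float(np.mean(motif_means))
        ok = total = 0
        for rec, track in zip(
            study_attributions["records"], study_attributions["tracks"]
        ):
            if rec.label != x.LNCRNA:
                continue
            v = np.abs(track.values)
            wins = np.lib.stride_tricks.sliding_window_view(v, 57).mean(axis=1)
            total += 1
            ok += int(wins.max() <= motif_level)
        assert total > 0
        assert ok / total >= 0.70
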