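"""Energy model, design trajectories/campaigns, forward folding, score files."""

import itertools

import numpy as np
import pytest

from ribodesign import (
    LibraryDefinition,
    PairingMap,
    ToyEnergyModel,
    design_campaign,
    design_trajectory,
    forward_fold,
    read_scorefile,
    toy_energy,
)
from ribodesign.design import write_scorefile


class TestPairingMap:
    def test_from_strands_position_wise(self):
        pm = PairingMap.from_strands(4, 4)
        assert pm.pairs == ((0, 4), (1, 5), (2, 6), (3, 7))
        assert pm.strands == ((0, 1, 2, 3), (4, 5, 6, 7))

    def test_unequal_strands_rejected(self):
        with pytest.raises(ValueError):
            PairingMap.from_strands(4, 3)

    def test_position_in_two_pairs_rejected(self):
        with pytest.raises(ValueError, match="more than one pair"):
            PairingMap(((0, 1), (1, 2)))


class TestToyEnergy:
    def test_no_pairs_scores_zero(self):
        assert toy_energy("acgu", PairingMap(())) == 0.0

    def test_single_wc_pair(self):
        assert toy_energy("cg", PairingMap(((0, 1),))) == -3.0

    def test_single_wobble_pair(self):
        assert toy_energy("gu", PairingMap(((0, 1),))) == -1.5

    def test_worked_duplex_example(self, pairing44):
        # pairs c-g, g-c (WC), g-g, u-c (mismatch): -3-3+1+1 = -4
        # continuity: positions 1-2 of each strand both WC: 2 * -0.5
        assert toy_energy("cggugcgc", pairing44) == -5.0

    def test_perfect_duplex(self, pairing44):
        # 4 WC pairs + 3 adjacent WC-WC steps per strand
        assert toy_energy("gcgucgca", pairing44) == 4 * -3.0 + 6 * -0.5

    def test_invalid_base_rejected(self, pairing44):
        with pytest.raises(ValueError, match="invalid base"):
            toy_energy("cggxgcgc", pairing44)

    def test_hand_summed_oracle_on_random_duplexes(self, pairing44):
        """Cross-check against an independent per-term accumulation."""
        wc = {("a", "u"), ("u", "a"), ("c", "g"), ("g", "c")}
        wob = {("g", "u"), ("u", "g")}
        rng = np.random.default_rng(0)
        for _ in range(50):
            bases = "".join(rng.choice(list("acgu"), 8))
            expected = 0.0
            wc_pos = set()
            for i, j in pairing44.pairs:
                duo = (bases[i], bases[j])
                if duo in wc:
                    expected += -3.0
                    wc_pos |= {i, j}
                elif duo in wob:
                    expected += -1.5
                else:
                    expected += 1.0
            for strand in pairing44.strands:
                for a, b in zip(strand, strand[1:]):
                    if a in wc_pos and b in wc_pos:
                        expected += -0.5
            assert toy_energy(bases, pairing44) == pytest.approx(expected)


class TestTrajectory:
    def test_single_position_finds_argmin(self):
        lib = LibraryDefinition.anything_but_wt("T", [("A", 1, "a")])

        class Table(ToyEnergyModel):
            def score(self, bases):
                return {"c": 2.0, "g": -1.0, "u": 5.0}[bases]

        model = Table(sigma=0.0)
        for seed in range(5):
            res = design_trajectory(lib, model, n_cycles=60, seed=seed)
            assert res.best_bases == "g" and res.best_score == -1.0

    def test_same_seed_is_bit_reproducible(self, h75_like_lib, pairing44):
        model = ToyEnergyModel(pairing=pairing44, sigma=0.7)
        a = design_trajectory(h75_like_lib, model, n_cycles=100, seed=11)
        b = design_trajectory(h75_like_lib, model, n_cycles=100, seed=11)
        assert a == b

    def test_empty_cycles_rejected(self, h75_like_lib, pairing44):
        with pytest.raises(ValueError):
            design_trajectory(h75_like_lib, ToyEnergyModel(pairing=pairing44), n_cycles=0)


class TestCampaign:
    def test_frequency_conservation(self, h75_like_lib, pairing44):
        model = ToyEnergyModel(pairing=pairing44, sigma=1.0)
        table = design_campaign(
            h75_like_lib, model, n_trajectories=50, n_cycles=40, seed=2
        )
        assert int(table.frame["frequency"].sum()) == 50

    def test_noiseless_campaign_matches_exhaustive_enumeration(self):
        """For a small library the campaign's best row must equal the
        global minimum found by brute force."""
        lib = LibraryDefinition.anything_but_wt(
            "T", [("A", 1, "a"), ("A", 2, "u")], strand_lengths=(1, 1)
        )
        pm = PairingMap.from_strands(1, 1)
        model = ToyEnergyModel(pairing=pm, sigma=0.0)
        table = design_campaign(lib, model, n_trajectories=200, n_cycles=30, seed=5)
        alphabets = [sorted(p.allowed) for p in lib.positions]
        brute_best = min(
            (model.score("".join(combo)), "".join(combo))
            for combo in itertools.product(*alphabets)
        )
        assert table.best == (brute_best[1], brute_best[0])

    def test_rows_sorted_by_score_then_bases(self, h75_like_lib, pairing44):
        model = ToyEnergyModel(pairing=pairing44, sigma=1.0)
        table = design_campaign(
            h75_like_lib, model, n_trajectories=60, n_cycles=30, seed=9
        )
        frame = table.frame
        assert frame["score"].is_monotonic_increasing
        for s, sub in frame.groupby("score"):
            assert list(sub["bases"]) == sorted(sub["bases"])

    def test_campaign_reproducible(self, h75_like_lib, pairing44):
        model = ToyEnergyModel(pairing=pairing44, sigma=0.5)
        a = design_campaign(h75_like_lib, model, n_trajectories=20, n_cycles=20, seed=1)
        b = design_campaign(h75_like_lib, model, n_trajectories=20, n_cycles=20, seed=1)
        assert a.frame.equals(b.frame)


class TestForwardFold:
    def test_noiseless_limit_equals_deterministic_score(self, pairing44):
        model = ToyEnergyModel(pairing=pairing44, sigma=0.0)
        seqs = ["cggugcgc", "gcgucgca"]
        frame = forward_fold(seqs, model, n_cycles=10, n_models=5, seed=0)
        by_tag = dict(zip(frame["tag"], frame["score"]))
        for s in seqs:
            assert by_tag[s] == pytest.approx(model.score(s))

    def test_best_of_n_is_prefix_minimum_monotone(self, pairing44):
        """More models under the same seed stream can only lower the best."""
        model = ToyEnergyModel(pairing=pairing44, sigma=1.0)
        seq = ["cggugcgc"]
        best = [
            forward_fold(seq, model, n_cycles=50, n_models=n, seed=3)["score"][0]
            for n in (1, 10, 100, 400)
        ]
        assert all(b2 <= b1 for b1, b2 in zip(best, best[1:]))

    def test_equal_budget_ranking_recovers_true_order(self, pairing44):
        """Two sequences with true score gap > 4 sigma rank correctly in
        >= 95% of seeded repeats under an identical sampling budget."""
        model = ToyEnergyModel(pairing=pairing44, sigma=1.0)
        good, bad = "gcgucgca", "aaaacccc"  # true scores -15 vs > 0
        assert model.score(bad) - model.score(good) > 4 * model.sigma
        correct = 0
        for seed in range(50):
            frame = forward_fold([bad, good], model, n_cycles=30, n_models=10, seed=seed)
            by_tag = dict(zip(frame["tag"], frame["score"]))
            correct += by_tag[good] < by_tag[bad]
        assert correct >= 48  # 0.95 * 50, rounded up

    def test_reproducible_per_seed(self, pairing44):
        model = ToyEnergyModel(pairing=pairing44, sigma=2.0)
        a = forward_fold(["cggugcgc"], model, n_cycles=20, n_models=8, seed=4)
        b = forward_fold(["cggugcgc"], model, n_cycles=20, n_models=8, seed=4)
        assert a.equals(b)


class TestScorefile:
    def test_round_trip_and_sentinel_dialect(self, tmp_path):
        path = tmp_path / "scores.sc"
        path.write_text(
            "SCORE: score description\n"
            "SCORE: -12.5 seq_a\n"
            "SCORE: -8.0 seq_b\n"
            "SCORE: 3.25 seq_c\n"
        )
        records = read_scorefile(path)
        assert {r.tag: r.score for r in records} == {
            "seq_a": -12.5, "seq_b": -8.0, "seq_c": 3.25,
        }

    def test_plain_tsv_dialect(self, tmp_path):
        path = tmp_path / "scores.tsv"
        path.write_text("tag\tscore\nx\t-1.0\ny\t2.0\n")
        records = read_scorefile(path)
        assert {r.tag: r.score for r in records} == {"x": -1.0, "y": 2.0}

    def test_duplicate_tags_keep_minimum(self, tmp_path):
        path = tmp_path / "dup.sc"
        path.write_text(
            "SCORE: score description\nSCORE: -10 s1\nSCORE: -12 s1\n"
        )
        records = read_scorefile(path)
        assert len(records) == 1 and records[0].score == -12.0

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        path = tmp_path / "empty.sc"
        path.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            assert read_scorefile(path) == []

    def test_missing_score_column(self, tmp_path):
        path = tmp_path / "bad.sc"
        path.write_text("SCORE: energy description\nSCORE: -1 x\n")
        with pytest.raises(ValueError, match="score column"):
            read_scorefile(path)

    def test_non_numeric_score_names_line(self, tmp_path):
        path = tmp_path / "bad2.sc"
        path.write_text("SCORE: score description\nSCORE: oops x\n")
        with pytest.raises(ValueError, match=":2"):
            read_scorefile(path)

    def test_writer_reader_closure(self, tmp_path):
        from ribodesign.design import ScoreRecord

        records = [ScoreRecord("a", -1.25), ScoreRecord("b", 0.5)]
        path = tmp_path / "out.sc"
        write_scorefile(records, path)
        back = read_scorefile(path)
        assert {r.tag: r.score for r in back} == {"a": -1.25, "b": 0.5}
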