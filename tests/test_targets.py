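import numpy as np
import pytest

from circsponge import io
from circsponge.targets import (
    MirandaParams,
    MirnaRecord,
    TargetThresholds,
    allen_score,
    duplex_mfe,
    load_duplex_params,
    max_miranda_score,
    miranda_score,
    predict_targets,
    seed_scan,
)
from helpers_oracles import duplex_enumerate, miranda_recursive

LET7 = "UGAGGUAGUAGGUUGUAUAGUU"


def _random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


class TestSeedScan:
    def test_hand_built_site(self):
        # seed (positions 2-8) = GAGGUAG; its reverse complement on a DNA
        # target reads CTACCTC
        mirna = MirnaRecord("let7", LET7)
        target = "A" * 12 + "CTACCTC" + "G" * 10
        assert seed_scan(target, mirna) == [12]

    def test_no_match_gives_empty(self):
        mirna = MirnaRecord("let7", LET7)
        assert seed_scan("A" * 40, mirna) == []

    def test_matches_window_scan_oracle(self):
        rng = np.random.default_rng(5)
        mirna = MirnaRecord("let7", LET7)
        pattern = io.revcomp_rna(mirna.seq[1:8])
        for _ in range(200):
            target = _random_rna(rng, 60)
            expected = [o for o in range(len(target) - 6) if target[o : o + 7] == pattern]
            assert seed_scan(target, mirna) == expected

    def test_gu_seed_option_is_superset(self):
        rng = np.random.default_rng(6)
        mirna = MirnaRecord("let7", LET7)
        for _ in range(50):
            target = _random_rna(rng, 80)
            strict = set(seed_scan(target, mirna, allow_gu_in_seed=False))
            relaxed = set(seed_scan(target, mirna, allow_gu_in_seed=True))
            assert strict <= relaxed


class TestMirandaScore:
    def test_perfect_duplex_arithmetic(self):
        mirna = MirnaRecord("let7", LET7)
        window = io.revcomp_rna(mirna.seq)
        no_weight = MirandaParams(seed_weight=1.0)
        score, trace = miranda_score(window, mirna, no_weight)
        assert score == 22 * 5
        assert trace == "|" * 22
        score_w, _ = miranda_score(window, mirna)
        assert score_w == 22 * 5 + 7 * 5  # 7 seed positions doubled
        assert max_miranda_score(mirna) == 145

    def test_no_complementarity_floors_at_zero(self):
        mirna = MirnaRecord("m", "A" * 22)
        score, trace = miranda_score("A" * 30, mirna)
        assert score == 0.0 and trace == ""

    def test_window_length_limit(self):
        mirna = MirnaRecord("let7", LET7)
        with pytest.raises(ValueError):
            miranda_score("A" * 81, mirna)

    def test_matches_recursion_oracle(self):
        rng = np.random.default_rng(7)
        params = MirandaParams()
        for _ in range(40):
            mirna = MirnaRecord("m", _random_rna(rng, 22))
            window = _random_rna(rng, 40)
            ours, _ = miranda_score(window, mirna, params)
            assert ours == pytest.approx(miranda_recursive(window, mirna.seq, params), abs=1e-9)


class TestDuplexMfe:
    def test_fully_paired_duplex_is_stack_sum_plus_init(self):
        params = load_duplex_params()
        mirna_pad = "GCGC" + "A" * 18  # only the GCGC prefix can pair
        mirna = MirnaRecord("m", mirna_pad)
        window = io.revcomp_rna("GCGC")
        dg = duplex_mfe(window, mirna, params)
        y = mirna.seq[::-1]
        x = window
        # hand-sum the three stacks of the fully paired 4-mer from the table
        expected = params.init + sum(
            params.stacks[(x[i], x[i + 1], y[18 + i], y[18 + i + 1])] for i in range(3)
        )
        assert dg == pytest.approx(expected, abs=1e-9)

    def test_single_pair_costs_initiation_only(self):
        params = load_duplex_params()
        mirna = MirnaRecord("m", "G" + "A" * 21)
        dg = duplex_mfe("C" + "G" * 10, mirna, params)  # G:C or G:U single pairs only
        assert dg >= -1.0
        assert dg == pytest.approx(params.init, abs=1e-9) or dg < params.init

    def test_unpairable_returns_inf(self):
        params = load_duplex_params()
        mirna = MirnaRecord("m", "A" * 22)
        assert duplex_mfe("A" * 10, mirna, params) == float("inf")

    def test_matches_enumeration_oracle_short_duplexes(self):
        rng = np.random.default_rng(8)
        params = load_duplex_params()
        for _ in range(60):
            x = _random_rna(rng, int(rng.integers(2, 9)))
            y = _random_rna(rng, int(rng.integers(2, 9)))
            dp = _duplex_raw(x, y, params)
            ref = duplex_enumerate(x, y, params)
            assert dp == pytest.approx(ref, abs=1e-9)


def _duplex_raw(x, y_53, params):
    """Call the duplex DP on raw strings (bypasses the miRNA length check)."""
    import circsponge.targets as tmod

    class _FakeMirna:
        def __init__(self, seq):
            self.seq = seq

    return tmod.duplex_mfe(x, _FakeMirna(y_53), params)


class TestAllenScore:
    def test_perfect_complement_scores_zero(self):
        mirna = MirnaRecord("let7", LET7)
        assert allen_score(io.revcomp_rna(mirna.seq), mirna) == 0.0

    def test_gu_inside_core_is_doubled(self):
        mirna = MirnaRecord("let7", LET7)
        site = list(io.revcomp_rna(mirna.seq))
        # miRNA position 5 pairs site index L-5; make it a G:U wobble
        L = len(mirna.seq)
        idx = L - 5
        base = mirna.seq[4]  # position 5 (1-based)
        site[idx] = "U" if base == "G" else ("G" if base == "U" else None)
        if site[idx] is None:
            pytest.skip("position 5 cannot form G:U for this miRNA")
        assert allen_score("".join(site), mirna) == pytest.approx(1.0)

    def test_mismatch_outside_core_is_single(self):
        mirna = MirnaRecord("let7", LET7)
        site = list(io.revcomp_rna(mirna.seq))
        L = len(mirna.seq)
        idx = L - 20  # pairs miRNA position 20, outside 2-13
        wc = site[idx]
        # replace with a base that is neither complementary nor G:U
        options = [b for b in "ACGU" if b != wc and (b, mirna.seq[19]) not in
                   {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}]
        site[idx] = options[0]
        assert allen_score("".join(site), mirna) == pytest.approx(1.0)


class TestPredictTargets:
    def _planted_case(self, rng, mirna, n_decoys=3):
        targets = []
        site = io.revcomp_rna(mirna.seq)
        planted = _random_rna(rng, 30) + site + _random_rna(rng, 20)
        targets.append(("planted", planted))
        for d in range(n_decoys):
            targets.append((f"decoy{d}", _random_rna(rng, 70)))
        return targets

    def test_planted_full_complement_passes_all(self):
        rng = np.random.default_rng(9)
        mirna = MirnaRecord("let7", LET7)
        hits = predict_targets(self._planted_case(rng, mirna), [mirna])
        planted_hits = hits[(hits["target_id"] == "planted") & hits["pass_all"]]
        assert len(planted_hits) == 1
        row = planted_hits.iloc[0]
        assert row["align_score"] == 145 and row["duplex_dg"] < -14 and row["allen_score"] == 0

    def test_shuffled_mirna_negative_control(self):
        rng = np.random.default_rng(10)
        mirna = MirnaRecord("let7", LET7)
        targets = self._planted_case(rng, mirna)
        shuffled = MirnaRecord("shuf", "".join(rng.permutation(list(LET7))))
        hits = predict_targets(targets, [shuffled])
        assert not hits["pass_all"].any()

    def test_pass_all_is_conjunction(self):
        rng = np.random.default_rng(11)
        mirna = MirnaRecord("let7", LET7)
        hits = predict_targets(self._planted_case(rng, mirna, n_decoys=10), [mirna])
        assert (
            hits["pass_all"] == (hits["pass_align"] & hits["pass_energy"] & hits["pass_allen"])
        ).all()

    def test_tightening_thresholds_never_enlarges_hits(self, small_data):
        mirnas = [MirnaRecord(m, s) for m, s in small_data.mirnas]
        targets = [(c.circ_id, c.junction_seq) for c in small_data.circs]
        loose = predict_targets(targets, mirnas, thresholds=TargetThresholds())
        tight = predict_targets(
            targets,
            mirnas,
            thresholds=TargetThresholds(align_min=144.0, energy_max=-20.0, allen_max=1.0),
        )
        loose_set = set(map(tuple, loose[loose["pass_all"]][["mirna_id", "target_id", "site_start"]].values))
        tight_set = set(map(tuple, tight[tight["pass_all"]][["mirna_id", "target_id", "site_start"]].values))
        assert tight_set <= loose_set

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            predict_targets([], [MirnaRecord("let7", LET7)])


def test_ground_truth_mre_recovery(small_data):
    """Every planted miRNA-target pair is recovered with pass_all=True and no
    unplanted (decoy) pair passes."""
    mirnas = [MirnaRecord(m, s) for m, s in small_data.mirnas]
    circ_targets = [(c.circ_id, c.junction_seq) for c in small_data.circs]
    utr_targets = small_data.utrs
    planted = {(kind, tid, mid) for kind, tid, mid, _o, _l in small_data.truth.mre_sites}
    for kind, targets in [("circRNA", circ_targets), ("mRNA", utr_targets)]:
        hits = predict_targets(targets, mirnas, kind)
        passed = {(kind, t, m) for _i, (m, t) in hits[hits["pass_all"]][["mirna_id", "target_id"]].iterrows()}
        expected = {p for p in planted if p[0] == kind}
        assert passed == expected
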