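"""Local alignment scoring, calibration, E-values and domain extraction."""

import itertools
import math

import numpy as np
import pytest

from glycoscan import (
    CalibrationError,
    InputError,
    NotCalibratedError,
    ProfileHMM,
    calibrate_gumbel,
    extract_domains,
    forward_local,
    read_hit_table,
    score_to_evalue,
    viterbi_local,
    write_hit_table,
)
from glycoscan.scan import DomainHit, encode_sequence, fit_gumbel_moments

from _oracles import oracle_forward_bits, oracle_viterbi_bits, random_model
from conftest import peaked_model

REDUCED = "ACDE"  # 4-letter test alphabet


def reduced_sequences(max_len):
    from glycoscan.profiles import AA_INDEX

    for length in range(1, max_len + 1):
        for combo in itertools.product(REDUCED, repeat=length):
            yield np.array([AA_INDEX[a] for a in combo], dtype=np.int64)


class TestAgainstEnumeration:
    """Viterbi/forward vs exhaustive path enumeration (tiny models)."""

    @pytest.mark.parametrize("m,seed", [(1, 0), (2, 1), (3, 2)])
    def test_all_reduced_sequences_up_to_length_4(self, m, seed):
        rng = np.random.default_rng(seed)
        model = random_model(rng, m)
        for x in reduced_sequences(4):
            vb, *_ = viterbi_local(model, x)
            assert vb == pytest.approx(oracle_viterbi_bits(model, x), rel=1e-9, abs=1e-9)
            fb = forward_local(model, x)
            assert fb == pytest.approx(oracle_forward_bits(model, x), rel=1e-9, abs=1e-9)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_sampled_length_5_and_6(self, seed):
        rng = np.random.default_rng(seed)
        model = random_model(rng)
        from glycoscan.profiles import AA_INDEX

        idx = np.array([AA_INDEX[a] for a in REDUCED])
        for length in (5, 6):
            for _ in range(30):
                x = rng.choice(idx, size=length)
                vb, *_ = viterbi_local(model, x)
                assert vb == pytest.approx(
                    oracle_viterbi_bits(model, x), rel=1e-9, abs=1e-9
                )
                fb = forward_local(model, x)
                assert fb == pytest.approx(
                    oracle_forward_bits(model, x), rel=1e-9, abs=1e-9
                )

    def test_forward_at_least_viterbi(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            model = random_model(rng, int(rng.integers(1, 6)))
            x = rng.integers(0, 20, size=int(rng.integers(1, 12)))
            vb, *_ = viterbi_local(model, x)
            assert forward_local(model, x) >= vb - 1e-9

    def test_degenerate_single_path_model(self):
        """M=1 model: one match state, a single-residue path per position."""
        me = np.zeros((1, 20))
        me[0, 0] = 1.0
        model = ProfileHMM(
            accession="D1",
            name="deg",
            match_emissions=me,
            insert_emissions=np.full((1, 20), 0.05),
            transitions=np.array([[1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0]]),
        )
        x = np.array([0], dtype=np.int64)  # sequence "A": exactly one path
        vb, *_ = viterbi_local(model, x)
        assert forward_local(model, x) == pytest.approx(vb, rel=1e-12)
        # log2(1.0 / 0.05) with entry log2(1/1) = 0
        assert vb == pytest.approx(math.log2(20.0))


class TestViterbiBehaviour:
    def test_background_model_scores_nonpositive(self):
        """Emissions equal to background: only entry/transition costs remain."""
        me = np.full((4, 20), 0.05)
        model = ProfileHMM(
            accession="BG",
            name="bg",
            match_emissions=me,
            insert_emissions=me.copy(),
            transitions=np.tile([1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0], (4, 1)),
        )
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.integers(0, 20, size=30)
            bits, *_ = viterbi_local(model, x)
            assert bits <= 0.0

    def test_consensus_beats_any_single_mismatch(self):
        consensus = "ACDEFGHIKL"
        model = peaked_model(consensus)
        best, *_ = viterbi_local(model, consensus)
        for pos in range(len(consensus)):
            for sub in "VWY":
                if sub == consensus[pos]:
                    continue
                variant = consensus[:pos] + sub + consensus[pos + 1 :]
                score, *_ = viterbi_local(model, variant)
                assert score < best

    def test_symbol_errors_and_ambiguity(self):
        model = peaked_model("ACDE")
        with pytest.raises(InputError, match="position 3"):
            viterbi_local(model, "AC1E")
        enc = encode_sequence("AXB")
        assert list(enc) == [0, 20, 20]
        with pytest.warns(UserWarning, match="truncated"):
            enc = encode_sequence("AC*DE")
        assert len(enc) == 2


class TestGumbelCalibration:
    def test_moment_fit_recovers_known_gumbel(self):
        """lambda within 10% on 2000 draws from Gumbel(0.69, 2.0)."""
        rng = np.random.default_rng(123)
        lam_true, mu_true = 0.69, 2.0
        scores = mu_true - np.log(-np.log(rng.random(2000))) / lam_true
        lam, mu = fit_gumbel_moments(scores)
        assert abs(lam - lam_true) / lam_true < 0.10
        assert abs(mu - mu_true) < 0.25

    def test_shift_property(self):
        """Shifting scores by +c leaves lambda, shifts mu by +c."""
        rng = np.random.default_rng(7)
        scores = rng.gumbel(3.0, 1.5, size=1000)
        lam0, mu0 = fit_gumbel_moments(scores)
        lam1, mu1 = fit_gumbel_moments(scores + 4.2)
        assert lam1 == pytest.approx(lam0, rel=1e-12)
        assert mu1 == pytest.approx(mu0 + 4.2, rel=1e-12)

    def test_determinism_and_storage(self):
        model = peaked_model("ACDEFGHIKLMNPQRSTVWY")
        a = calibrate_gumbel(model, n_samples=300, seed=5)
        b = calibrate_gumbel(model, n_samples=300, seed=5)
        assert a == b
        assert model.is_calibrated

    def test_minimum_sample_size_enforced(self):
        model = peaked_model("ACDE")
        with pytest.raises(CalibrationError):
            calibrate_gumbel(model, n_samples=100, seed=0)


class TestEvalues:
    def test_closed_form_at_mu(self, calibrated_peaked):
        model = calibrated_peaked
        e = score_to_evalue(model, model.gumbel_mu, db_size=1000)
        assert e == pytest.approx(1000 * (1 - math.exp(-1)), rel=1e-9)

    def test_db_size_one_is_tail_probability(self, calibrated_peaked):
        model = calibrated_peaked
        s = model.gumbel_mu + 2.0
        p = score_to_evalue(model, s, db_size=1)
        z = model.gumbel_lambda * 2.0
        assert p == pytest.approx(1 - math.exp(-math.exp(-z)), rel=1e-9)

    def test_strictly_decreasing_and_bounded(self, calibrated_peaked):
        model = calibrated_peaked
        # stay inside the floating-point-representable part of the tail
        scores = np.linspace(model.gumbel_mu - 4, model.gumbel_mu + 40, 50)
        evals = [score_to_evalue(model, s, db_size=500) for s in scores]
        assert all(a > b for a, b in zip(evals, evals[1:]))
        assert all(0 <= e <= 500 for e in evals)

    def test_uncalibrated_model_refused(self):
        model = peaked_model("ACDE")
        with pytest.raises(NotCalibratedError):
            score_to_evalue(model, 10.0, db_size=10)


class TestExtractDomains:
    def test_two_planted_copies_recovered_in_order(self):
        rng = np.random.default_rng(21)
        consensus = "".join(
            "ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, size=40)
        )
        model = peaked_model(consensus, peak=0.98)
        calibrate_gumbel(model, n_samples=300, seed=3)
        linker = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 20))
        seq = consensus + linker + consensus
        hits = extract_domains(model, seq, threshold_evalue=1e-3, db_size=100,
                               protein_id="two")
        assert len(hits) == 2
        assert hits[0].ali_end < hits[1].ali_start  # coordinate order, no overlap
        assert abs(hits[0].ali_start - 1) <= 3
        assert abs(hits[1].ali_end - len(seq)) <= 3

    def test_background_rarely_hits(self, calibrated_peaked):
        """At E <= 1e-5 with db_size 1000, background sequences almost never hit."""
        n_hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            seq = rng.integers(0, 20, size=120)
            hits = extract_domains(
                calibrated_peaked, seq, threshold_evalue=1e-5, db_size=1000
            )
            n_hits += bool(hits)
        assert n_hits <= 1  # >= 99% of seeds clean

    def test_hits_never_overlap(self, calibrated_peaked):
        rng = np.random.default_rng(33)
        for _ in range(10):
            seq = rng.integers(0, 20, size=150)
            hits = extract_domains(
                calibrated_peaked, seq, threshold_evalue=10.0, db_size=10,
                max_domains=5,
            )
            for a, b in itertools.combinations(hits, 2):
                assert min(a.ali_end, b.ali_end) < max(a.ali_start, b.ali_start)

    def test_max_domains_contract(self, calibrated_peaked):
        with pytest.raises(InputError):
            extract_domains(calibrated_peaked, "ACDE", 1.0, 10, max_domains=0)


class TestHitTable:
    def test_round_trip(self, tmp_path):
        hits = [
            DomainHit("p1", "PF00150", "GH5", 10, 120, 85.1234, 3.2e-20, "stage2"),
            DomainHit("p2", "PF00331", "GH10", 5, 90, 42.5, 1.5e-08, "direct"),
        ]
        path = tmp_path / "hits.tsv"
        write_hit_table(hits, path)
        back = read_hit_table(path)
        assert [h.protein_id for h in back] == ["p1", "p2"]
        assert back[0].ali_start == 10 and back[0].ali_end == 120
        assert back[0].bit_score == pytest.approx(85.1234, abs=1e-4)
        assert back[0].evalue == pytest.approx(3.2e-20, rel=1e-5)
        assert back[1].stage == "direct"
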