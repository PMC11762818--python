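"""Ordinal symbolization, permutation entropy and PCMI estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mssecnn import pcmi
from mssecnn.pcmi import PcmiParams, SymbolSequence

from .oracles import cmi_bruteforce, ordinal_code_bruteforce


def _sym(codes, m=3, tau=1):
    codes = np.asarray(codes)
    return SymbolSequence(
        codes=codes, m=m, tau=tau, source_length=len(codes) + (m - 1) * tau
    )


class TestOrdinalize:
    @pytest.mark.parametrize(
        "x, m, expected",
        [
            ([1.2, 3.4, 2.5], 3, None),       # single window, checked vs oracle
            ([5, 5, 1], 3, None),             # tie broken by temporal order
            ([3.0, 1.0], 2, None),
        ],
    )
    def test_matches_bruteforce_rank(self, x, m, expected):
        got = pcmi.ordinalize(x, m=m, tau=1).codes
        assert got[0] == ordinal_code_bruteforce(x, m)

    def test_monotone_series_gives_identity_pattern(self):
        s = pcmi.ordinalize(np.arange(10.0), m=3, tau=1)
        assert len(s.codes) == 8
        assert np.all(s.codes == 0)

    def test_random_windows_match_bruteforce(self, rng):
        x = rng.normal(size=200)
        for m, tau in [(2, 1), (3, 1), (3, 2), (4, 3)]:
            s = pcmi.ordinalize(x, m=m, tau=tau)
            assert len(s.codes) == 200 - (m - 1) * tau
            for t in [0, 7, 50, len(s.codes) - 1]:
                window = x[t : t + (m - 1) * tau + 1 : tau]
                assert s.codes[t] == ordinal_code_bruteforce(window, m)

    def test_rejects_short_input_and_large_m(self):
        with pytest.raises(ValueError):
            pcmi.ordinalize([1.0, 2.0], m=3, tau=1)
        with pytest.raises(ValueError):
            pcmi.ordinalize(np.arange(100.0), m=8)


class TestPermutationEntropy:
    def test_constant_codes_zero_bits(self):
        assert pcmi.permutation_entropy(_sym([0] * 20)) == 0.0

    def test_uniform_over_six_patterns(self):
        s = _sym(list(range(6)) * 10)
        assert pcmi.permutation_entropy(s) == pytest.approx(np.log2(6), abs=1e-12)

    def test_iid_gaussian_approaches_log2_6(self, rng):
        x = rng.normal(size=100_000)
        s = pcmi.ordinalize(x, m=3, tau=1)
        assert pcmi.permutation_entropy(s) == pytest.approx(np.log2(6), abs=0.05)


class TestPcmiDirected:
    def test_matches_bruteforce_on_many_random_pairs(self, rng):
        """Plug-in CMI equals independent triple-enumeration on short pairs."""
        for _ in range(60):
            n = int(rng.integers(10, 61))
            cx = rng.integers(0, 6, n)
            cy = rng.integers(0, 6, n)
            got = pcmi.pcmi_directed(_sym(cx), _sym(cy), delta_set=(1,))
            want = cmi_bruteforce(cx, cy, 1)
            assert got == pytest.approx(want, abs=1e-12)

    def test_mean_over_delta_set(self, rng):
        cx = rng.integers(0, 6, 80)
        cy = rng.integers(0, 6, 80)
        got = pcmi.pcmi_directed(_sym(cx), _sym(cy), delta_set=(1, 3))
        want = (cmi_bruteforce(cx, cy, 1) + cmi_bruteforce(cx, cy, 3)) / 2
        assert got == pytest.approx(want, abs=1e-12)

    def test_identical_sequences_give_zero(self, rng):
        """Conditioning on y_t makes x_t = y_t redundant: CMI is exactly 0."""
        c = rng.integers(0, 6, 200)
        assert pcmi.pcmi_directed(_sym(c), _sym(c), delta_set=(1,)) == 0.0

    def test_independent_sequences_below_surrogate_null(self, rng):
        x = rng.normal(size=5000)
        y = rng.normal(size=5000)
        sx, sy = pcmi.ordinalize(x), pcmi.ordinalize(y)
        obs = pcmi.pcmi_directed(sx, sy)
        surr = []
        for _ in range(19):
            shift = int(rng.integers(100, 4000))
            rolled = SymbolSequence(
                codes=np.roll(sx.codes, shift), m=sx.m, tau=sx.tau,
                source_length=sx.source_length,
            )
            surr.append(pcmi.pcmi_directed(rolled, sy))
        assert obs <= max(surr)

    def test_monotone_transform_invariance(self, rng):
        """Strictly increasing transforms leave ordinal patterns unchanged."""
        x = rng.normal(size=600)
        y = rng.normal(size=600)
        base = pcmi.pcmi_directed(pcmi.ordinalize(x), pcmi.ordinalize(y))
        fx = np.exp(2.0 * x) + 5.0
        fy = np.arctan(y) * 3.0 - 1.0
        assert pcmi.pcmi_directed(pcmi.ordinalize(fx), pcmi.ordinalize(fy)) == base

    def test_rejects_mismatched_sequences(self, rng):
        a = _sym(rng.integers(0, 6, 30))
        b = _sym(rng.integers(0, 6, 40))
        with pytest.raises(ValueError):
            pcmi.pcmi_directed(a, b)
        c = _sym(rng.integers(0, 2, 30), m=2)
        with pytest.raises(ValueError):
            pcmi.pcmi_directed(a, c)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_nonnegative_on_random_inputs(self, seed):
        r = np.random.default_rng(seed)
        cx = r.integers(0, 6, int(r.integers(8, 120)))
        cy = r.integers(0, 6, len(cx))
        assert pcmi.pcmi_directed(_sym(cx), _sym(cy), delta_set=(1, 2)) >= -1e-9


class TestCouplingMatrix:
    def test_shape_diagonal_and_band(self, coupled_segments):
        M = pcmi.coupling_matrix(coupled_segments[0], "Alpha2")
        assert M.values.shape == (4, 4)
        assert np.all(np.diag(M.values) == 0)
        assert M.band == "Alpha2"

    def test_entries_match_pairwise_pcmi(self, coupled_segments):
        seg = coupled_segments[0]
        params = PcmiParams()
        M = pcmi.coupling_matrix(seg, "Alpha2", params).values
        sx = pcmi.ordinalize(seg.data["Alpha2"][2], params.m, params.tau)
        sy = pcmi.ordinalize(seg.data["Alpha2"][3], params.m, params.tau)
        assert M[2, 3] == pytest.approx(
            pcmi.pcmi_directed(sx, sy, params.delta_set), abs=1e-12
        )

    def test_recovers_injected_direction(self, coupled_segments):
        """Averaged over segments, PCMI(0 -> 1) exceeds PCMI(1 -> 0)."""
        mats = [
            pcmi.coupling_matrix(s, "Alpha2").values for s in coupled_segments[:25]
        ]
        mean = np.mean(mats, axis=0)
        assert mean[0, 1] > mean[1, 0]

    def test_relabeling_equivariance(self, coupled_segments):
        seg = coupled_segments[0]
        M = pcmi.coupling_matrix(seg, "Alpha2").values
        perm = [2, 0, 3, 1]
        seg2 = type(seg)(
            data={b: seg.data[b][perm] for b in seg.band_names},
            fs=seg.fs, band_names=seg.band_names, window_s=seg.window_s,
            start_s=seg.start_s, label=seg.label, subject_id=seg.subject_id,
        )
        M2 = pcmi.coupling_matrix(seg2, "Alpha2").values
        assert np.allclose(M2, M[np.ix_(perm, perm)], atol=1e-12)


class TestFeatureTensor:
    def test_stacks_bands_in_canonical_order(self, coupled_segments):
        ft = pcmi.feature_tensor(coupled_segments[0], ["Gamma", "Delta"])
        assert ft.values.shape == (4, 4, 2)
        assert ft.band_order == ("Delta", "Gamma")

    def test_band_order_input_permutation_irrelevant(self, coupled_segments):
        a = pcmi.feature_tensor(coupled_segments[0], ["Delta", "Gamma"])
        b = pcmi.feature_tensor(coupled_segments[0], ["Gamma", "Delta"])
        assert np.array_equal(a.values, b.values)

    def test_preset_channel_counts(self, coupled_segments):
        assert pcmi.feature_tensor(coupled_segments[0], "full").values.shape[2] == 7
        assert (
            pcmi.feature_tensor(coupled_segments[0], "delta-gamma").values.shape[2]
            == 2
        )
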