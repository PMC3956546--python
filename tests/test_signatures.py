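"""Connectivity scoring (KS enrichment + permutation) and PGSEA."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from pmedkit.crossmap import ZProfile
from pmedkit.signatures import (QuerySet, ResponseSignature, SensitivitySignature,
                                build_query, connectivity_score, ks_enrichment,
                                permutation_p, pgsea_score, run_response_method,
                                run_sensitivity_method)


def profile(values):
    return ZProfile("t", "human-probe", pd.Series(values, dtype=float))


UNIVERSE = tuple(f"g{i:02d}" for i in range(10))


class TestQuery:
    def test_thresholds_inclusive(self):
        zp = profile({"a": 2.5, "b": -2.5, "c": 0.0, "d": 2.0, "e": -2.0})
        q = build_query(zp)
        assert q.up == {"a", "d"}
        assert q.down == {"b", "e"}

    def test_all_moderate_z_gives_empty_query(self):
        q = build_query(profile({"a": 1.9, "b": -1.9}))
        assert not q.up and not q.down

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            QuerySet(frozenset("a"), frozenset("a"))


class TestKsEnrichment:
    def test_hand_worked_top_concentration(self):
        # t=2, n=10, ranks {1,2}: a = max(1/2-1/10, 1-2/10) = 0.8
        es = ks_enrichment({"g00", "g01"}, UNIVERSE)
        assert es == pytest.approx(0.8)

    def test_bottom_concentration_is_mirror_negative(self):
        # mirror symmetry holds up to the discreteness of the rank grid
        top = ks_enrichment({"g00", "g01"}, UNIVERSE)
        bottom = ks_enrichment({"g08", "g09"}, UNIVERSE)
        assert bottom < 0 < top
        assert bottom == pytest.approx(-top, abs=1.0 / len(UNIVERSE) + 1e-12)

    def test_entire_universe_is_weak(self):
        es = ks_enrichment(set(UNIVERSE), UNIVERSE)
        assert abs(es) <= 1.0 / len(UNIVERSE) + 1e-12

    def test_empty_intersection_is_an_error(self):
        with pytest.raises(ValueError):
            ks_enrichment({"zz"}, UNIVERSE)

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_matches_one_sample_ks_statistic(self, data):
        """The enrichment is the signed sup-difference between the empirical
        CDF of the member positions and the uniform CDF — exactly the
        one-sample KS D+/D- statistics, computable independently by scipy."""
        n = data.draw(st.integers(5, 60))
        t = data.draw(st.integers(1, n))
        members = data.draw(st.permutations(range(n))).copy()[:t]
        ranking = tuple(f"x{i}" for i in range(n))
        chosen = {f"x{i}" for i in members}
        es = ks_enrichment(chosen, ranking)
        pts = np.sort((np.array(sorted(members)) + 1) / n)
        d_plus = sps.ks_1samp(pts, sps.uniform.cdf, alternative="greater").statistic
        d_minus = sps.ks_1samp(pts, sps.uniform.cdf, alternative="less").statistic
        expected = d_plus if d_plus > d_minus else -d_minus
        assert es == pytest.approx(expected, abs=1e-12)
        assert -1.0 <= es <= 1.0


class TestConnectivity:
    def test_perfect_reversal_scores_near_minus_one(self):
        # up-set at the signature bottom, down-set at the top
        sig = ResponseSignature("d", UNIVERSE)
        q = QuerySet(frozenset({"g08", "g09"}), frozenset({"g00", "g01"}))
        res = connectivity_score(q, sig)
        assert res.s == pytest.approx(-0.85)  # (ES_up - ES_down)/2 = (-0.9-0.8)/2
        assert res.es_up < 0 < res.es_down

    def test_mirror_query_flips_sign(self):
        sig = ResponseSignature("d", UNIVERSE)
        q = QuerySet(frozenset({"g00", "g01"}), frozenset({"g08", "g09"}))
        assert connectivity_score(q, sig).s == pytest.approx(0.85)

    def test_same_sign_enrichments_score_zero(self):
        sig = ResponseSignature("d", UNIVERSE)
        q = QuerySet(frozenset({"g00"}), frozenset({"g01"}))  # both at top
        assert connectivity_score(q, sig).s == 0.0

    def test_disjoint_query_is_an_error(self):
        sig = ResponseSignature("d", UNIVERSE)
        with pytest.raises(ValueError):
            connectivity_score(QuerySet(frozenset({"zz"}), frozenset()), sig)


class TestPermutation:
    def test_minimum_attainable_p(self):
        p = permutation_p(-1.0, 2, 2, 50, n_perm=999, seed=3)
        assert p == pytest.approx(1.0 / 1000)

    def test_determinism_given_seed(self):
        args = (-0.4, 3, 2, 40)
        assert permutation_p(*args, n_perm=500, seed=9) == \
            permutation_p(*args, n_perm=500, seed=9)

    def test_null_p_is_uniform_in_the_lower_tail(self):
        """Over random queries P(p <= x) ~ x for small x.

        The connectivity score has an atom at 0 (same-sign enrichments),
        so the *full* p distribution piles mass near P(s_null <= 0); the
        calibration-relevant property is lower-tail uniformity, below
        the atom.
        """
        rng = np.random.default_rng(17)
        n = 80
        sig = ResponseSignature("d", tuple(f"x{i}" for i in range(n)))
        ps = []
        for i in range(400):
            pick = rng.choice(n, size=8, replace=False)
            q = QuerySet(frozenset(f"x{j}" for j in pick[:4]),
                         frozenset(f"x{j}" for j in pick[4:]))
            s = connectivity_score(q, sig).s
            ps.append(permutation_p(s, 4, 4, n, n_perm=400, seed=1000 + i))
        ps = np.asarray(ps)
        for x in (0.05, 0.10, 0.20):
            rate = (ps <= x).mean()
            margin = 3 * math.sqrt(x * (1 - x) / len(ps))
            assert abs(rate - x) <= margin + 1.0 / 401


class TestResponseMethod:
    def test_planted_reversal_is_reported(self, rng):
        n = 200
        universe = tuple(f"x{i}" for i in range(n))
        up = set(universe[-10:])    # tumor-up genes at the signature bottom
        down = set(universe[:10])   # tumor-down genes at the top
        z = {g: 0.0 for g in universe}
        z.update({g: 3.0 for g in up})
        z.update({g: -3.0 for g in down})
        sigs = [ResponseSignature("planted", universe),
                ResponseSignature("random", tuple(rng.permutation(universe)))]
        res = run_response_method(profile(z), sigs, n_perm=999, seed=5)
        assert [r.drug for r in res] == ["planted"]
        assert res[0].s < 0 and res[0].p < 0.05
        assert res[0].score == pytest.approx(-math.log10(res[0].p))

    def test_null_profile_reports_nothing(self, rng):
        universe = tuple(f"x{i}" for i in range(50))
        zp = profile({g: 0.0 for g in universe})
        sigs = [ResponseSignature("d", universe)]
        assert run_response_method(zp, sigs, n_perm=99, seed=1) == []


class TestPgsea:
    def test_closed_form_t(self):
        """v = {1,2,3}: t = mean/(sd/sqrt(m)) = 2/(1/sqrt(3)) = 3.464, df=2."""
        sig = SensitivitySignature("d", (("a", 1), ("b", 1), ("c", 1)))
        res = pgsea_score(profile({"a": 1.0, "b": 2.0, "c": 3.0}), sig)
        assert res.t == pytest.approx(2.0 / (1.0 / math.sqrt(3)), rel=1e-9)
        assert res.t == pytest.approx(3.464, abs=1e-3)
        assert res.df == 2
        assert res.p == pytest.approx(sps.t.sf(res.t, 2), rel=1e-12)
        assert res.p == pytest.approx(0.0371, abs=2e-4)

    def test_all_zero_profile_is_midline(self):
        sig = SensitivitySignature("d", (("a", 1), ("b", 1)))
        res = pgsea_score(profile({"a": 0.0, "b": 0.0}), sig)
        assert res.t == 0.0 or res.sd_zero

    def test_flipping_signs_negates_t(self):
        sig = SensitivitySignature("d", (("a", 1), ("b", -1), ("c", 1)))
        flipped = SensitivitySignature("d", (("a", -1), ("b", 1), ("c", -1)))
        z = {"a": 1.2, "b": -0.4, "c": 2.0}
        assert pgsea_score(profile(z), sig).t == pytest.approx(
            -pgsea_score(profile(z), flipped).t)

    def test_insufficient_overlap_gives_no_result(self):
        sig = SensitivitySignature("d", (("a", 1), ("zz", 1)))
        assert pgsea_score(profile({"a": 1.0, "b": 2.0}), sig) is None

    def test_run_method_filters_at_alpha(self):
        sig_hit = SensitivitySignature("hit", tuple((f"h{i}", 1) for i in range(10)))
        sig_null = SensitivitySignature("null", tuple((f"n{i}", 1) for i in range(10)))
        z = {f"h{i}": 3.0 + 0.1 * i for i in range(10)}
        z.update({f"n{i}": 0.1 * ((-1) ** i) for i in range(10)})
        res = run_sensitivity_method(profile(z), [sig_hit, sig_null])
        assert [r.drug for r in res] == ["hit"]
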