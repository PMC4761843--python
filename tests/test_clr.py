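"""Codebook, exact conditional likelihood, Newton fit, and the LRT."""

import math

import numpy as np
import pytest
from scipy import stats

from xtriad.clr import (
    RARE_LABEL,
    build_codebook,
    conditional_log_likelihood,
    dosage,
    fit_clr,
    lrt,
)
from xtriad.errors import DegenerateWindowError, DimensionError
from xtriad.pseudo import RiskSet, build_risk_set
from xtriad.triads import Haplotype

from conftest import H, make_phased


def all_width4_haplotypes():
    return [Haplotype((c >> 3 & 1, c >> 2 & 1, c >> 1 & 1, c & 1)) for c in range(16)]


def phased_with_all_16_common():
    """16 families whose parental haplotypes cover every width-4 haplotype
    with frequency 3/48 >= 0.01."""
    haps = all_width4_haplotypes()
    out = []
    for i, h in enumerate(haps):
        nxt = haps[(i + 1) % 16]
        out.append(make_phased(h.to_string(), h.to_string(), nxt.to_string(),
                               "male", fid=f"f{i}"))
    return out


class TestCodebook:
    def test_low_frequency_haplotype_is_pooled(self):
        # one haplotype on 2 of 300 parental chromosomes: 0.00667 < 0.01
        rare_h, a, b = H("1111"), H("0000"), H("1000")
        fams = [make_phased("0000", "0000", "1000", fid=f"f{i}") for i in range(99)]
        fams.append(make_phased("1111", "1111", "1000", fid="f99"))
        cb = build_codebook(fams, threshold=0.01)
        assert rare_h in cb.rare_group
        assert cb.frequencies[rare_h] == pytest.approx(2 / 300)
        assert a in cb.common_haplotypes and b in cb.common_haplotypes

    def test_all_16_common_gives_df_15(self):
        cb = build_codebook(phased_with_all_16_common(), threshold=0.01)
        assert cb.n_common == 16
        assert not cb.rare_group
        assert cb.df == 15

    def test_five_common_haplotypes_give_df_4(self):
        five = ["0000", "1000", "0100", "0010", "0001"]
        fams = [
            make_phased(five[i % 5], five[(i + 1) % 5], five[(i + 2) % 5], fid=f"f{i}")
            for i in range(50)
        ]
        cb = build_codebook(fams, threshold=0.01)
        assert cb.n_common == 5
        assert cb.df == 4

    def test_reference_is_most_frequent_common(self):
        fams = [make_phased("0000", "0000", "1000", fid=f"f{i}") for i in range(10)]
        cb = build_codebook(fams, threshold=0.01)
        assert cb.reference == H("0000")

    def test_single_rare_haplotype_still_forms_the_pooled_group(self):
        fams = [make_phased("0000", "0000", "1000", fid=f"f{i}") for i in range(99)]
        fams.append(make_phased("1111", "0000", "1000", fid="f99"))
        cb = build_codebook(fams, threshold=0.01)
        assert cb.rare_group == frozenset({H("1111")})
        assert RARE_LABEL in cb.columns

    def test_fewer_than_two_common_is_degenerate(self):
        fams = [make_phased("0000", "0000", "0000", fid=f"f{i}") for i in range(99)]
        fams.append(make_phased("1000", "0000", "0000", fid="f99"))
        with pytest.raises(DegenerateWindowError):
            build_codebook(fams, threshold=0.01)

    def test_frequencies_sum_to_one(self):
        fams = phased_with_all_16_common()
        cb = build_codebook(fams, threshold=0.01)
        assert sum(cb.frequencies.values()) == pytest.approx(1.0)


@pytest.fixture
def simple_codebook():
    """Three common haplotypes (0000 reference) plus a rare 1111."""
    fams = [make_phased("0000", "0000", "1000", fid=f"a{i}") for i in range(40)]
    fams += [make_phased("0100", "0000", "1000", fid=f"b{i}") for i in range(20)]
    fams.append(make_phased("1111", "0000", "1000", fid="r0"))
    return build_codebook(fams, threshold=0.01)


class TestDosage:
    def test_male_double_coding_counts_two(self, simple_codebook):
        x = dosage((H("1000"),), "male", simple_codebook, coding="double")
        assert x[list(simple_codebook.columns).index(H("1000"))] == 2
        assert x.sum() == 2

    def test_male_single_coding_counts_one(self, simple_codebook):
        x = dosage((H("1000"),), "male", simple_codebook, coding="single")
        assert x.sum() == 1

    def test_female_reference_pair_loads_nothing(self, simple_codebook):
        x = dosage((H("0000"), H("0000")), "female", simple_codebook)
        assert not x.any()

    def test_female_common_plus_rare(self, simple_codebook):
        x = dosage((H("1000"), H("1111")), "female", simple_codebook)
        cols = list(simple_codebook.columns)
        assert x[cols.index(H("1000"))] == 1
        assert x[cols.index(RARE_LABEL)] == 1


def naive_conditional_log_likelihood(risk_sets, beta, codebook, coding="double"):
    """Independent oracle: per-stratum multinomial probability by explicit
    enumeration of the alternatives with scalar arithmetic."""
    cols = list(codebook.columns)
    total = 0.0
    for rs in risk_sets:
        weights = []
        for alt in rs.alternatives:
            eta = 0.0
            for hap in alt:
                mult = 2.0 if (coding == "double" and len(alt) == 1) else 1.0
                if hap == codebook.reference:
                    continue
                label = RARE_LABEL if hap in codebook.rare_group else hap
                eta += mult * beta[cols.index(label)]
            weights.append(math.exp(eta))
        total += math.log(weights[rs.case_index] / sum(weights))
    return total


def random_risk_sets(rng, n, sex_mix=0.5, haps=("0000", "1000", "0100", "1111")):
    out = []
    while len(out) < n:
        f, m1, m2 = rng.choice(haps, 3)
        if f == m1 == m2:
            continue
        sex = "male" if rng.random() < sex_mix else "female"
        out.append(build_risk_set(make_phased(f, m1, m2, sex, fid=f"f{len(out)}")))
    return out


class TestConditionalLogLikelihood:
    def test_zero_beta_gives_minus_n_log3(self, simple_codebook, rng):
        rs = random_risk_sets(rng, 25)
        p = len(simple_codebook.columns)
        ll = conditional_log_likelihood(rs, np.zeros(p), simple_codebook)
        assert ll == pytest.approx(-25 * math.log(3), abs=1e-12)

    def test_dimension_mismatch_raises(self, simple_codebook, rng):
        rs = random_risk_sets(rng, 5)
        with pytest.raises(DimensionError):
            conditional_log_likelihood(rs, [0.0], simple_codebook)

    def test_single_male_stratum_closed_form(self, simple_codebook):
        """Case carries h at dosage 2 with beta_h = ln(1.5)/2 and two
        reference controls: contribution is ln(1.5 / (1.5 + 2))."""
        rs = build_risk_set(make_phased("0000", "1000", "0000", "male"))
        assert rs.case == (H("1000"),)
        beta = np.zeros(len(simple_codebook.columns))
        beta[list(simple_codebook.columns).index(H("1000"))] = math.log(1.5) / 2
        ll = conditional_log_likelihood([rs], beta, simple_codebook)
        assert ll == pytest.approx(math.log(1.5 / 3.5), abs=1e-12)

    def test_matches_enumeration_oracle(self, simple_codebook, rng):
        rs = random_risk_sets(rng, 20)
        p = len(simple_codebook.columns)
        for _ in range(5):
            beta = rng.normal(0, 0.7, p)
            fast = conditional_log_likelihood(rs, beta, simple_codebook)
            slow = naive_conditional_log_likelihood(rs, beta, simple_codebook)
            assert fast == pytest.approx(slow, abs=1e-12)

    def test_invariant_to_alternative_order(self, simple_codebook, rng):
        rs = random_risk_sets(rng, 12)
        p = len(simple_codebook.columns)
        beta = rng.normal(0, 0.5, p)
        ll = conditional_log_likelihood(rs, beta, simple_codebook)
        permuted = []
        for s in rs:
            order = rng.permutation(s.n_alternatives)
            alts = tuple(s.alternatives[i] for i in order)
            permuted.append(RiskSet(s.family_id, s.child_sex, alts,
                                    int(np.flatnonzero(order == s.case_index)[0])))
        assert conditional_log_likelihood(permuted, beta, simple_codebook) == \
            pytest.approx(ll, abs=1e-12)


class TestFit:
    def test_null_data_recovers_zero(self, rng):
        """Strata built symmetrically (case uniform over alternatives) keep
        beta near 0 and the log-likelihood near -n ln 3."""
        triple = ["1000", "0100", "0010"]
        rs = []
        for i in range(600):
            f, ma, mb = [triple[j] for j in rng.permutation(3)]
            rs.append(build_risk_set(make_phased(f, ma, mb, "male", fid=f"f{i}")))
        cb = build_codebook([make_phased(f, m1, m2, "male")
                             for f in triple for m1 in triple for m2 in triple
                             if not f == m1 == m2], threshold=0.01)
        fit = fit_clr(rs, cb)
        assert fit.converged
        assert all(abs(b) < 0.35 for b in fit.coefficients.values())
        assert fit.log_likelihood == pytest.approx(-600 * math.log(3), rel=0.02)

    def test_matches_grid_search_oracle(self, rng):
        """On a one-column model the Newton optimum agrees with a dense grid
        search over the same likelihood."""
        fams = []
        for i in range(30):
            m1, m2, f = ("10", "00", "00") if i % 3 else ("00", "10", "00")
            fams.append(make_phased(f, m1, m2, "male", fid=f"f{i}"))
        cb = build_codebook(fams, threshold=0.01)
        assert list(cb.columns) == [H("10")]
        rs = [build_risk_set(ph) for ph in fams]
        fit = fit_clr(rs, cb)
        grid = np.linspace(-2, 2, 40001)
        lls = [conditional_log_likelihood(rs, [b], cb) for b in grid]
        best = grid[int(np.argmax(lls))]
        assert fit.coefficients[H("10")] == pytest.approx(best, abs=1e-4)
        assert fit.log_likelihood >= max(lls) - 1e-10

    def test_matches_statsmodels_conditional_logit(self):
        """Independent cross-check: a general-purpose conditional-logit
        fitter on the long-format expansion of the same strata reaches the
        same optimum."""
        from statsmodels.discrete.conditional_models import ConditionalLogit

        from xtriad.clr import risk_sets_to_arrays

        rng = np.random.default_rng(2)
        haps = ["0000", "1000", "0100", "1100"]
        fams = []
        while len(fams) < 120:
            f, m1, m2 = rng.choice(haps, 3)
            if f == m1 == m2:
                continue
            fams.append(make_phased(f, m1, m2,
                                    "male" if rng.random() < 0.5 else "female",
                                    fid=f"f{len(fams)}"))
        cb = build_codebook(fams, 0.01)
        rs = [build_risk_set(ph) for ph in fams]
        X, _, case = risk_sets_to_arrays(rs, cb, "double")
        n, n_alts, p = X.shape
        y = np.zeros(n * n_alts)
        y[np.arange(n) * n_alts + case] = 1
        sm_fit = ConditionalLogit(
            y, X.reshape(-1, p), groups=np.repeat(np.arange(n), n_alts)
        ).fit(disp=0)
        ours = fit_clr(rs, cb)
        assert ours.log_likelihood == pytest.approx(sm_fit.llf, abs=1e-6)
        np.testing.assert_allclose(
            np.array(list(ours.coefficients.values())), sm_fit.params, atol=1e-4
        )

    def test_constant_rare_column_is_flagged_inestimable(self, rng):
        """Rare haplotypes appearing only in an all-rare male stratum give the
        pooled column dosage 2 in every alternative — no within-stratum
        variation, so its coefficient is reported inestimable."""
        triple = ["0000", "1000", "0100"]
        fams = []
        for i in range(90):
            f, ma, mb = [triple[j] for j in rng.permutation(3)]
            fams.append(make_phased(f, ma, mb, "male", fid=f"f{i}"))
        fams.append(make_phased("1111", "1110", "1101", "male", fid="r0"))
        cb = build_codebook(fams, threshold=0.01)
        assert cb.rare_group == {H("1111"), H("1110"), H("1101")}
        rs = [build_risk_set(ph) for ph in fams]
        fit = fit_clr(rs, cb)
        assert RARE_LABEL in fit.inestimable


class TestLRT:
    def test_chi2_zero_when_no_signal_possible(self):
        """With two common haplotypes and every stratum identical to its
        mirror, alt and null fits coincide up to symmetry; chi2 >= 0 and the
        LRT machinery is self-consistent on a tiny balanced set."""
        fams = []
        for i in range(12):
            f, m1, m2 = ("10", "00", "00") if i % 2 else ("00", "10", "00")
            fams.append(make_phased(f, m1, m2, "male", fid=f"f{i}"))
        cb = build_codebook(fams, threshold=0.01)
        res = lrt([build_risk_set(ph) for ph in fams], cb)
        assert res.chi2 >= 0
        assert res.df == 1
        assert res.p_value == pytest.approx(stats.chi2.sf(res.chi2, 1))

    def test_reference_choice_does_not_change_the_test(self):
        haps = ["0000", "1000", "0100", "0010", "1100", "1111"]
        rng2 = np.random.default_rng(5)
        fams = []
        while len(fams) < 120:
            f, m1, m2 = rng2.choice(haps, 3)
            if f == m1 == m2:
                continue
            fams.append(make_phased(f, m1, m2,
                                    "male" if rng2.random() < 0.5 else "female",
                                    fid=f"f{len(fams)}"))
        rs = [build_risk_set(ph) for ph in fams]
        cb_default = build_codebook(fams, threshold=0.01)
        results = []
        for ref in cb_default.common_haplotypes:
            cb = build_codebook(fams, threshold=0.01, reference=ref)
            results.append(lrt(rs, cb))
        chi2s = [r.chi2 for r in results]
        assert np.ptp(chi2s) < 1e-6
        assert np.ptp([r.p_value for r in results]) < 1e-8

    def test_stratum_order_and_family_ids_do_not_matter(self, rng):
        haps = ["0000", "1000", "0100", "1100"]
        fams = []
        rng2 = np.random.default_rng(9)
        while len(fams) < 80:
            f, m1, m2 = rng2.choice(haps, 3)
            if f == m1 == m2:
                continue
            fams.append(make_phased(f, m1, m2, "female", fid=f"f{len(fams)}"))
        cb = build_codebook(fams, threshold=0.01)
        rs = [build_risk_set(ph) for ph in fams]
        base = lrt(rs, cb)
        shuffled = [rs[i] for i in rng.permutation(len(rs))]
        relabeled = [RiskSet(f"other{i}", s.child_sex, s.alternatives, s.case_index)
                     for i, s in enumerate(shuffled)]
        again = lrt(relabeled, cb)
        assert again.chi2 == pytest.approx(base.chi2, abs=1e-9)

    def test_one_common_haplotype_window_is_degenerate(self):
        fams = [make_phased("0000", "0000", "0000", fid=f"f{i}") for i in range(99)]
        fams.append(make_phased("1000", "0000", "0000", fid="f99"))
        with pytest.raises(DegenerateWindowError):
            build_codebook(fams, threshold=0.01)
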