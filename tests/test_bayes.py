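"""Empirical-Bayes classifier: binning, count tables vs a brute-force
oracle, posterior arithmetic, tie-breaking and serialization."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from efvbayes import PHENOTYPES, Phenotype, bin_concentration, classify, fit_conditional_table
from efvbayes.bayes import (
    BinnedConditionalTable,
    phenotype_concentration_ranges,
    posterior_curve,
    posterior_probability,
)
from tests.conftest import make_cohort

EM, IM, PM = Phenotype.EM, Phenotype.IM, Phenotype.PM


def make_table(counts, priors=None, smoothing=0.0, bin_width=100.0, time=24.0):
    counts = {ph: np.asarray(c, dtype=float) for ph, c in counts.items()}
    n = len(next(iter(counts.values())))
    return BinnedConditionalTable(
        sampling_time=time,
        bin_width=bin_width,
        bin_centers=np.arange(n) * bin_width,
        counts=counts,
        priors=priors or {ph: 1 / 3 for ph in PHENOTYPES},
        smoothing=smoothing,
    )


class TestBinning:
    @pytest.mark.parametrize(
        "conc, expected", [(1234.0, 1200.0), (1250.0, 1300.0), (0.0, 0.0), (49.999, 0.0)]
    )
    def test_examples(self, conc, expected):
        assert bin_concentration(conc) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bin_concentration(-1.0)

    @given(
        conc=st.floats(0, 1e5, allow_nan=False),
        width=st.sampled_from([10.0, 50.0, 100.0, 250.0]),
    )
    def test_nearest_multiple_half_up(self, conc, width):
        b = bin_concentration(conc, width)
        assert b % width == 0
        assert abs(b - conc) <= width / 2 + 1e-6
        if abs(conc / width - round(conc / width)) == 0.5:  # exact midpoint
            assert b > conc


class TestConditionalTable:
    def test_direct_counting_example(self, tiny_24h_cohort):
        # PM concentrations {1130, 1080, 940} round to {1100, 1100, 900}
        table = fit_conditional_table(tiny_24h_cohort, 24.0, smoothing=0.0)
        p = dict(zip(table.bin_centers, table.probabilities(PM)))
        assert p[1100.0] == pytest.approx(2 / 3)
        assert p[900.0] == pytest.approx(1 / 3)
        assert sum(p.values()) == pytest.approx(1.0, abs=1e-9)

    def test_identical_training_data_gives_identical_tables(self):
        rows = []
        for ph in ("EM", "IM", "PM"):
            for i, c in enumerate([150, 840, 330, 1210]):
                rows.append((f"{ph}{i}", ph, 24.0, float(c)))
        table = fit_conditional_table(make_cohort(rows), 24.0, smoothing=0.0)
        for ph in (IM, PM):
            assert np.allclose(table.probabilities(ph), table.probabilities(EM))

    def test_matches_brute_force_counting_oracle(self, specs):
        from efvbayes import simulate_cohort

        cohort = simulate_cohort(
            specs,
            phenotype_mix={ph: 1.0 for ph in PHENOTYPES},
            times=(24.0,),
            n_trials=1,
            n_per_trial=48,
            seed=23,
        )
        table = fit_conditional_table(cohort, 24.0, smoothing=0.0)
        # independent longhand tally over the same records
        tallies = {ph: {} for ph in PHENOTYPES}
        for row in cohort.df.itertuples(index=False):
            ph = Phenotype(row.phenotype)
            b = np.floor(row.conc_ng_ml / 100.0 + 0.5) * 100.0
            tallies[ph][b] = tallies[ph].get(b, 0) + 1
        for ph in PHENOTYPES:
            total = sum(tallies[ph].values())
            probs = dict(zip(table.bin_centers, table.probabilities(ph)))
            for b, n in tallies[ph].items():
                assert probs[b] == pytest.approx(n / total, abs=1e-12)
            assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_missing_phenotype_named_in_error(self, tiny_24h_cohort):
        df = tiny_24h_cohort.df
        cohort = make_cohort(
            [tuple(r) for r in df[df["phenotype"] != "PM"][
                ["subject_id", "phenotype", "time_h", "conc_ng_ml"]
            ].itertuples(index=False)]
        )
        with pytest.raises(ValueError, match="PM"):
            fit_conditional_table(cohort, 24.0)

    def test_unlabelled_records_rejected(self, tiny_24h_cohort):
        df = tiny_24h_cohort.df.copy()
        df.loc[0, "phenotype"] = pd.NA
        with pytest.raises(ValueError, match="label"):
            fit_conditional_table(make_cohort(df[list(df.columns[:4])].values.tolist()), 24.0)


class TestPosterior:
    def test_equal_likelihoods_give_uniform_posterior(self):
        table = make_table({EM: [2, 2], IM: [2, 2], PM: [2, 2]})
        post = posterior_probability(table, 100.0)
        assert all(p == pytest.approx(1 / 3) for p in post.values())

    def test_arithmetic_example(self):
        # likelihoods (0.1, 0.1, 0.2) at bin 0 under equal priors
        table = make_table({EM: [1, 9], IM: [1, 9], PM: [2, 8]})
        post = posterior_probability(table, 0.0)
        assert post[EM] == pytest.approx(0.25)
        assert post[IM] == pytest.approx(0.25)
        assert post[PM] == pytest.approx(0.50)

    @given(
        counts=st.lists(
            st.tuples(*[st.integers(0, 20)] * 3), min_size=2, max_size=6
        ).filter(lambda rows: all(any(r[j] for r in rows) for j in range(3))),
        scale=st.floats(0.1, 10.0),
        bin_idx=st.integers(0, 5),
    )
    def test_prior_scale_invariance_and_normalization(self, counts, scale, bin_idx):
        arr = np.array(counts, dtype=float)
        base = {EM: arr[:, 0], IM: arr[:, 1], PM: arr[:, 2]}
        conc = 100.0 * min(bin_idx, arr.shape[0] - 1)
        p1 = posterior_probability(make_table(base, smoothing=0.5), conc)
        p2 = posterior_probability(
            make_table(base, priors={ph: scale / 3 for ph in PHENOTYPES}, smoothing=0.5),
            conc,
        )
        assert sum(p1.values()) == pytest.approx(1.0, abs=1e-9)
        for ph in PHENOTYPES:
            assert p1[ph] == pytest.approx(p2[ph], abs=1e-9)

    def test_degenerate_prior_forces_its_phenotype(self, small_training):
        table = fit_conditional_table(
            small_training, 24.0, priors={EM: 1.0, IM: 0.0, PM: 0.0}
        )
        for conc in (50.0, 800.0, 1600.0, 4000.0):
            assert classify(table, conc).predicted is EM

    def test_negative_concentration_rejected(self):
        table = make_table({EM: [1], IM: [1], PM: [1]})
        with pytest.raises(ValueError):
            posterior_probability(table, -5.0)

    def test_label_permutation_symmetry(self, tiny_24h_cohort):
        perm = {"EM": "PM", "IM": "EM", "PM": "IM"}
        swapped = tiny_24h_cohort.df.copy()
        swapped["phenotype"] = swapped["phenotype"].map(perm).astype("string")
        t1 = fit_conditional_table(tiny_24h_cohort, 24.0)
        t2 = fit_conditional_table(
            make_cohort(swapped[["subject_id", "phenotype", "time_h", "conc_ng_ml"]].values.tolist()),
            24.0,
        )
        for conc in (100.0, 650.0, 1100.0):
            p1 = posterior_probability(t1, conc)
            p2 = posterior_probability(t2, conc)
            for ph in PHENOTYPES:
                assert p1[ph] == pytest.approx(p2[Phenotype(perm[ph.value])], abs=1e-12)


class TestClassify:
    def test_map_call(self):
        # likelihoods (0.1, 0.2, 0.7) at bin 0 -> posterior (0.1, 0.2, 0.7)
        table = make_table({EM: [1, 9], IM: [2, 8], PM: [7, 3]})
        call = classify(table, 0.0)
        assert call.predicted is PM and not call.tie_flag
        assert call.posterior[PM] == pytest.approx(0.7)

    def test_two_way_tie_prefers_slower_metabolizer(self):
        # EM and IM tie at 0.4 each; IM is the slower of the tied pair
        table = make_table({EM: [2, 3], IM: [2, 3], PM: [1, 4]})
        call = classify(table, 0.0)
        assert call.predicted is IM
        assert call.tie_flag
        assert call.posterior[EM] == pytest.approx(0.4)

    def test_three_way_tie_gives_pm(self):
        call = classify(make_table({EM: [5], IM: [5], PM: [5]}), 0.0)
        assert call.predicted is PM and call.tie_flag

    def test_unseen_bin_fallback_nearest_populated_ties_up(self):
        # populated bins 0 and 400; query 200 is equidistant -> use bin 400
        table = make_table({EM: [9, 0, 0, 0, 1], IM: [5, 0, 0, 0, 5], PM: [1, 0, 0, 0, 9]})
        call = classify(table, 200.0)
        assert call.predicted is PM  # bin 400 likelihoods (0.1, 0.5, 0.9)/norm

    def test_above_range_clamps_to_top_guard_bin(self, small_training):
        table = fit_conditional_table(small_training, 24.0)
        top = table.bin_centers[-1]
        assert (
            classify(table, top + 5000.0).posterior
            == classify(table, top).posterior
        )

    def test_serialization_round_trip_is_bit_stable(self, small_training, tmp_path):
        table = fit_conditional_table(small_training, 24.0)
        path = tmp_path / "model.json"
        table.to_json(path)
        reloaded = BinnedConditionalTable.from_json(path)
        for conc in np.linspace(0, 4000, 41):
            a, b = classify(table, conc), classify(reloaded, conc)
            assert a.predicted is b.predicted
            assert all(a.posterior[ph] == b.posterior[ph] for ph in PHENOTYPES)


class TestRanges:
    def test_intervals_partition_bin_range(self, small_training):
        curve = posterior_curve(fit_conditional_table(small_training, 24.0))
        ranges = phenotype_concentration_ranges(curve)
        covered = sorted(
            iv for spans in ranges.values() for iv in spans
        )
        # contiguous, non-overlapping, covering the full bin span
        assert covered[0][0] == curve.bin_centers[0]
        assert covered[-1][1] == curve.bin_centers[-1]
        for (_, hi), (lo, _) in zip(covered, covered[1:]):
            assert lo == hi + 100.0

    def test_certain_phenotype_spans_whole_range(self, small_training):
        table = fit_conditional_table(
            small_training, 24.0, priors={EM: 0.0, IM: 0.0, PM: 1.0}
        )
        ranges = phenotype_concentration_ranges(posterior_curve(table))
        assert ranges[EM] == [] and ranges[IM] == []
        assert ranges[PM] == [(table.bin_centers[0], table.bin_centers[-1])]
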