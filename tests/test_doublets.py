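import numpy as np
import pytest

from xldoublet.chem import DeltaMassSet, doublet_delta_set
from xldoublet.doublets import (
    DoubletMatch,
    dedupe_window,
    evaluate_triggers,
    find_doublets,
    select_ms3_precursors,
    trigger_mz,
)
from xldoublet.spectra import rank_peaks


def brute_force_doublets(spectrum, deltas, tol_ppm, charges):
    """Exhaustive O(n^2 * |charges| * |variants|) reference enumeration."""
    ranked = rank_peaks(spectrum)
    mz = spectrum.mz
    out = set()
    for z in charges:
        for i in range(len(mz)):
            for j in range(i + 1, len(mz)):
                obs = (mz[j] - mz[i]) * z
                best = min(deltas.variants, key=lambda d: abs(obs - d))
                if abs(obs - best) <= tol_ppm * 1e-6 * mz[j] * z:
                    out.add((i, j, z, round(best, 9)))
    return out


def as_key_set(matches):
    return {
        (m.light_peak_index, m.heavy_peak_index, m.assumed_charge,
         round(m.matched_variant, 9))
        for m in matches
    }


class TestFindDoublets:
    def test_empty_and_single_peak(self, make_spectrum, uccl):
        deltas = doublet_delta_set(uccl, [0])
        assert find_doublets(make_spectrum([]), deltas) == []
        assert find_doublets(make_spectrum([500.0]), deltas) == []

    def test_constructed_uccl_pair(self, make_spectrum, uccl):
        deltas = doublet_delta_set(uccl, [0])
        s = make_spectrum([500.000000, 500.0 + deltas.base_delta])
        (m,) = find_doublets(s, deltas, tol_ppm=5.0, charges=[1])
        assert (m.light_peak_index, m.heavy_peak_index, m.assumed_charge) == (0, 1, 1)
        assert m.ppm_error == pytest.approx(0.0, abs=1e-6)
        assert m.matched_variant == pytest.approx(104.062600, abs=1e-6)

    def test_match_at_higher_charge(self, make_spectrum, uccl):
        deltas = doublet_delta_set(uccl, [0])
        s = make_spectrum([500.0, 500.0 + deltas.base_delta / 2])
        assert find_doublets(s, deltas, 5.0, charges=[1]) == []
        (m,) = find_doublets(s, deltas, 5.0, charges=[2])
        assert m.assumed_charge == 2

    def test_closest_variant_reported(self, make_spectrum, uccl):
        deltas = doublet_delta_set(uccl, [0, 1, 2])
        s = make_spectrum([400.0, 400.0 + deltas.variants[1] + 1e-4])
        (m,) = find_doublets(s, deltas, 5.0, [1])
        assert m.matched_variant == pytest.approx(deltas.variants[1], abs=1e-9)

    def test_summed_intensity_and_rank(self, make_spectrum, uccl):
        deltas = doublet_delta_set(uccl, [0])
        s = make_spectrum(
            [300.0, 500.0, 500.0 + deltas.base_delta], [900.0, 10.0, 20.0]
        )
        (m,) = find_doublets(s, deltas, 5.0, [1])
        assert m.summed_intensity == pytest.approx(30.0)
        assert m.best_rank == 2  # heavy peak is 2nd most intense

    def test_max_rank_filter(self, make_spectrum, uccl):
        deltas = doublet_delta_set(uccl, [0])
        s = make_spectrum(
            [300.0, 500.0, 500.0 + deltas.base_delta], [900.0, 10.0, 20.0]
        )
        assert find_doublets(s, deltas, 5.0, [1], max_rank=1) == []
        assert len(find_doublets(s, deltas, 5.0, [1], max_rank=2)) == 1

    def test_invalid_arguments(self, make_spectrum, uccl):
        deltas = doublet_delta_set(uccl, [0])
        s = make_spectrum([100.0, 204.0626])
        with pytest.raises(ValueError):
            find_doublets(s, deltas, tol_ppm=0.0)
        with pytest.raises(ValueError):
            find_doublets(s, deltas, 5.0, charges=[])
        with pytest.raises(ValueError):
            find_doublets(s, deltas, 5.0, charges=[0])

    def test_oracle_equivalence_random_spectra(self, random_spectrum, uccl):
        rng = np.random.default_rng(41)
        deltas = doublet_delta_set(uccl, [0, 1, 2])
        for _ in range(40):
            n = int(rng.integers(2, 120))
            s = random_spectrum(rng, n_peaks=n, mz_range=(150, 600))
            tol = float(rng.choice([5.0, 20.0, 100.0, 500.0]))
            got = as_key_set(find_doublets(s, deltas, tol, [1, 2, 3]))
            assert got == brute_force_doublets(s, deltas, tol, [1, 2, 3])

    def test_tolerance_monotonicity(self, random_spectrum, uccl):
        rng = np.random.default_rng(43)
        deltas = doublet_delta_set(uccl, [0, 1, 2])
        for _ in range(10):
            s = random_spectrum(rng, n_peaks=150, mz_range=(150, 700))
            prev = set()
            for tol in (5.0, 50.0, 200.0, 1000.0):
                cur = as_key_set(find_doublets(s, deltas, tol, [1, 2]))
                assert prev <= cur
                prev = cur

    def test_variant_set_monotonicity(self, random_spectrum, uccl):
        rng = np.random.default_rng(47)
        for _ in range(10):
            s = random_spectrum(rng, n_peaks=150, mz_range=(150, 700))
            narrow = find_doublets(s, doublet_delta_set(uccl, [0]), 300.0, [1, 2])
            wide = find_doublets(s, doublet_delta_set(uccl, [0, 1, 2]), 300.0, [1, 2])
            narrow_pairs = {
                (m.light_peak_index, m.heavy_peak_index, m.assumed_charge)
                for m in narrow
            }
            wide_pairs = {
                (m.light_peak_index, m.heavy_peak_index, m.assumed_charge)
                for m in wide
            }
            assert narrow_pairs <= wide_pairs


class TestDedupeWindow:
    def _matches_at(self, make_spectrum, mz_pairs, intensities):
        mzs = sorted({m for pair in mz_pairs for m in pair})
        idx = {m: i for i, m in enumerate(mzs)}
        s = make_spectrum(mzs, [1.0] * len(mzs))
        matches = [
            DoubletMatch(
                light_peak_index=idx[lo],
                heavy_peak_index=idx[hi],
                assumed_charge=1,
                matched_variant=hi - lo,
                ppm_error=0.0,
                summed_intensity=inten,
                best_rank=1,
            )
            for (lo, hi), inten in zip(mz_pairs, intensities)
        ]
        return s, matches

    def test_close_triggers_collapse(self, make_spectrum):
        s, matches = self._matches_at(
            make_spectrum, [(400.0, 500.0), (396.0, 500.8)], [10.0, 5.0]
        )
        kept = dedupe_window(matches, s, window_mz=1.5)
        assert len(kept) == 1
        assert kept[0].summed_intensity == 10.0

    def test_distant_triggers_kept(self, make_spectrum):
        s, matches = self._matches_at(
            make_spectrum, [(400.0, 500.0), (399.0, 503.0)], [10.0, 5.0]
        )
        assert len(dedupe_window(matches, s, window_mz=1.5)) == 2

    def test_greedy_oracle_equivalence(self, make_spectrum):
        rng = np.random.default_rng(53)
        for _ in range(30):
            n = int(rng.integers(1, 25))
            pairs = [
                (float(lo), float(lo) + 50.0)
                for lo in rng.uniform(200, 800, n)
            ]
            intens = rng.uniform(1, 100, n).tolist()
            s, matches = self._matches_at(make_spectrum, pairs, intens)
            kept = dedupe_window(matches, s, window_mz=1.5)
            # oracle: greedy over explicitly sorted list
            order = sorted(
                matches,
                key=lambda m: (-m.summed_intensity, trigger_mz(m, s)),
            )
            expected = []
            for m in order:
                t = trigger_mz(m, s)
                if all(abs(t - trigger_mz(k, s)) > 1.5 for k in expected):
                    expected.append(m)
            assert kept == expected
            # pairwise separation of survivors
            kept_mz = [trigger_mz(m, s) for m in kept]
            for i in range(len(kept_mz)):
                for j in range(i + 1, len(kept_mz)):
                    assert abs(kept_mz[i] - kept_mz[j]) > 1.5


class TestSelectMs3Precursors:
    def test_no_matches(self, make_spectrum):
        s = make_spectrum([100.0, 200.0])
        assert len(select_ms3_precursors([], s, max_triggers=5)) == 0

    def test_single_match_targets_heavy_peak(self, make_spectrum, uccl):
        deltas = doublet_delta_set(uccl, [0])
        heavy = 500.0 + deltas.base_delta
        s = make_spectrum([500.0, heavy])
        matches = find_doublets(s, deltas, 5.0, [1])
        triggers = select_ms3_precursors(matches, s, max_triggers=5)
        assert len(triggers) == 1
        assert triggers.triggers[0].precursor_mz == pytest.approx(heavy)
        assert triggers.triggers[0].charge == 1

    def test_light_species_option(self, make_spectrum, uccl):
        deltas = doublet_delta_set(uccl, [0])
        s = make_spectrum([500.0, 500.0 + deltas.base_delta])
        matches = find_doublets(s, deltas, 5.0, [1])
        triggers = select_ms3_precursors(
            matches, s, max_triggers=5, trigger_species="light"
        )
        assert triggers.triggers[0].precursor_mz == pytest.approx(500.0)

    def test_synthetic_csm_gives_two_triggers(self, uccl):
        from xldoublet.synthetic import (
            GeneratorConfig,
            compatible_peptide_pair,
            generate_csm_spectrum,
        )

        config = GeneratorConfig(n_noise_peaks=0, seed=61)
        rng = config.rng()
        alpha, beta = compatible_peptide_pair(config, uccl, rng)
        spectrum, truth = generate_csm_spectrum(alpha, beta, uccl, config, rng)
        matches = find_doublets(
            spectrum, doublet_delta_set(uccl, [0, 1, 2]), 5.0, [1, 2]
        )
        triggers = select_ms3_precursors(matches, spectrum, max_triggers=5)
        assert len(triggers) == 2
        outcome = evaluate_triggers(triggers, truth, 5.0)
        assert outcome.alpha_triggered and outcome.beta_triggered
        assert outcome.n_false_triggers == 0

    def test_max_triggers_cap(self, make_spectrum):
        rng = np.random.default_rng(67)
        mzs = sorted(rng.uniform(200, 1200, 20))
        s = make_spectrum(mzs)
        matches = [
            DoubletMatch(i, i + 1, 1, 1.0, 0.0, float(20 - i), 1)
            for i in range(0, 18, 2)
        ]
        triggers = select_ms3_precursors(matches, s, max_triggers=3, window_mz=None)
        assert len(triggers) == 3
        intens = [t.source_match.summed_intensity for t in triggers]
        assert intens == sorted(intens, reverse=True)

    def test_invalid_max_triggers(self, make_spectrum):
        with pytest.raises(ValueError):
            select_ms3_precursors([], make_spectrum([100.0]), max_triggers=0)


class TestEvaluateTriggers:
    class FakeTruth:
        def __init__(self, alpha=(), beta=()):
            self.true_stub_mz = {}
            if len(alpha):
                self.true_stub_mz["alpha"] = tuple(alpha)
            if len(beta):
                self.true_stub_mz["beta"] = tuple(beta)

    def test_zero_triggers(self):
        from xldoublet.doublets import TriggerList

        out = evaluate_triggers(TriggerList(()), self.FakeTruth([500.0]), 5.0)
        assert (out.n_triggers, out.alpha_triggered, out.beta_triggered,
                out.n_false_triggers) == (0, False, False, 0)

    def test_both_stub_hits(self, make_spectrum, uccl):
        deltas = doublet_delta_set(uccl, [0])
        a_heavy, b_heavy = 604.0626, 800.0
        s = make_spectrum([500.0, a_heavy, b_heavy - deltas.base_delta, b_heavy])
        matches = find_doublets(s, deltas, 5.0, [1])
        triggers = select_ms3_precursors(matches, s, 5)
        truth = self.FakeTruth(alpha=[500.0, a_heavy], beta=[b_heavy])
        out = evaluate_triggers(triggers, truth, 5.0)
        assert out.alpha_triggered and out.beta_triggered
        assert out.n_false_triggers == 0

    def test_brute_force_matching_oracle(self):
        from xldoublet.doublets import Trigger, TriggerList

        rng = np.random.default_rng(71)
        for _ in range(50):
            alpha = rng.uniform(200, 1000, 3)
            beta = rng.uniform(200, 1000, 3)
            trig_mz = rng.uniform(200, 1000, 5)
            # nudge some triggers onto truth positions
            for k in range(2):
                if rng.random() < 0.5:
                    trig_mz[k] = rng.choice(np.concatenate([alpha, beta])) * (
                        1 + rng.uniform(-4e-6, 4e-6)
                    )
            dummy = DoubletMatch(0, 1, 1, 1.0, 0.0, 1.0, 1)
            triggers = TriggerList(
                tuple(Trigger(float(m), 1, dummy) for m in trig_mz)
            )
            truth = self.FakeTruth(alpha, beta)
            out = evaluate_triggers(triggers, truth, 5.0)

            def hit(mz, targets):
                return any(abs(mz - t) <= 5e-6 * t for t in targets)

            exp_alpha = any(hit(m, alpha) for m in trig_mz)
            exp_beta = any(hit(m, beta) for m in trig_mz)
            exp_false = sum(
                1 for m in trig_mz if not hit(m, alpha) and not hit(m, beta)
            )
            assert (out.alpha_triggered, out.beta_triggered, out.n_false_triggers) == (
                exp_alpha, exp_beta, exp_false,
            )
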