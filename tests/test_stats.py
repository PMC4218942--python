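"""Correlation screen, critical-r² inversion, expectation audit, contrasts."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from devsource.data_io import ValidationError
from devsource.stats import (
    correlation_audit,
    critical_r2,
    expected_significant,
    group_contrasts,
    spearman,
)
from devsource.synth import CohortConfig, Coupling, generate_cohort, planted_peak_table


def brute_force_spearman(x, y):
    """Exhaustive rank computation with average ranks for ties."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den


class TestSpearman:
    def test_monotone_increasing_gives_one(self):
        x = np.arange(10.0)
        r, r2, p, n = spearman(x, np.exp(x))
        assert r == pytest.approx(1.0) and r2 == pytest.approx(1.0) and p < 1e-12

    def test_monotone_decreasing_gives_minus_one(self):
        x = np.arange(8.0)
        r, _, _, _ = spearman(x, -(x**3))
        assert r == pytest.approx(-1.0)

    def test_ties_match_brute_force_rank_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 4.0, 3.0, 6.0]
        r, _, _, _ = spearman(x, y)
        assert r == pytest.approx(brute_force_spearman(x, y), abs=1e-12)

    def test_pairwise_deletion_of_missing(self):
        x = [1, 2, np.nan, 4, 5, 6, 7]
        y = [2, 4, 5, np.nan, 10, 12, 14]
        r, _, _, n = spearman(x, y)
        assert n == 5
        assert r == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            spearman([1, 2, 3, 4], [1, 2, 3, 4])

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            spearman([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])


class TestCriticalR2:
    def test_fz_family_inversion_matches_printed_threshold(self):
        assert round(critical_r2(0.05, 30, 42), 2) == 0.22

    def test_source_family_inversion_at_least_028(self):
        assert critical_r2(0.05, 180, 42) >= 0.28

    def test_threshold_decreases_with_n(self):
        vals = [critical_r2(0.05, 30, n) for n in (10, 42, 100, 1000, 100_000)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 0.001

    def test_alpha_too_large_rejected(self):
        with pytest.raises(ValidationError):
            critical_r2(1.0, 1, 42)


class TestExpectedSignificant:
    def test_tau_near_one_gives_near_zero(self):
        assert expected_significant(100, 0.99, 42) < 1e-10

    def test_analytic_within_3se_of_montecarlo(self):
        n_tests, tau, n = 60, 0.10, 42
        n_sims = 100_000
        mc = expected_significant(n_tests, tau, n, method="montecarlo", n_sims=n_sims, seed=7)
        analytic = expected_significant(n_tests, tau, n)
        p_hat = mc / n_tests
        se = n_tests * np.sqrt(p_hat * (1 - p_hat) / n_sims)
        assert abs(analytic - mc) < 3 * se

    def test_monotone_in_tau_and_n(self):
        taus = [0.1, 0.2, 0.3, 0.4, 0.5]
        vals = [expected_significant(60, t, 42) for t in taus]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        ns = [10, 20, 42, 100]
        vals_n = [expected_significant(60, 0.1, n) for n in ns]
        assert all(a > b for a, b in zip(vals_n, vals_n[1:]))

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValidationError):
            expected_significant(10, 0.0, 42)


def noise_tables(seed, n_sz=42, sources=6):
    """Peak table + score table with no real coupling."""
    rng = np.random.default_rng(seed)
    subjects = [f"SZ{i:03d}" for i in range(n_sz)]
    rows = []
    for sid, src, peak in itertools.product(
        subjects, [f"cluster{c}" for c in range(sources)] + ["Fz"], ["MMN", "P3a", "RON"]
    ):
        rows.append(
            {
                "subject": sid,
                "group": "SZ",
                "source": src,
                "peak": peak,
                "latency_ms": rng.uniform(150, 450),
                "amplitude_uv": rng.standard_normal(),
                "edge_flag": 0,
            }
        )
    peaks = pd.DataFrame(rows)
    scores = pd.DataFrame(
        {
            "subject_id": subjects,
            "group": "SZ",
            **{f"V{k}": rng.standard_normal(n_sz) for k in range(10)},
        }
    )
    return peaks, scores


class TestCorrelationAudit:
    def test_family_sizes_under_default_config(self):
        peaks, scores = noise_tables(0)
        audit = correlation_audit(peaks, scores)
        assert audit.family_sizes == {"Fz": 60, "source": 360}

    def test_observed_counts_monotone_in_tau(self):
        peaks, scores = noise_tables(1)
        audit = correlation_audit(peaks, scores)
        for fam in audit.observed:
            for mt in audit.observed[fam]:
                counts = [audit.observed[fam][mt][t] for t in audit.strata]
                assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_invariant_to_monotone_score_transform(self):
        peaks, scores = noise_tables(2)
        a1 = correlation_audit(peaks, scores)
        scores2 = scores.copy()
        for k in range(10):
            scores2[f"V{k}"] = np.exp(scores2[f"V{k}"])
        a2 = correlation_audit(peaks, scores2)
        assert np.allclose(
            a1.correlations["r"].to_numpy(), a2.correlations["r"].to_numpy()
        )

    def test_no_variables_rejected(self):
        peaks, scores = noise_tables(3)
        with pytest.raises(ValidationError):
            correlation_audit(peaks, scores[["subject_id", "group"]])

    def test_null_observed_counts_match_expectation(self):
        """Pure-noise scores: mean observed count ≈ expected (3 SE)."""
        taus = (0.10,)
        counts = []
        expected = None
        for seed in range(60):
            peaks, scores = noise_tables(100 + seed)
            audit = correlation_audit(peaks, scores, strata=taus)
            obs = (
                audit.observed["source"]["amplitude"][0.10]
                + audit.observed["source"]["latency"][0.10]
            )
            counts.append(obs)
            expected = audit.expected["source"][0.10]
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - expected) < 3 * se + 0.5

    def test_planted_coupling_detected_in_most_cohorts(self):
        """A strong planted score↔peak coupling is flagged above the 10 %
        rule in nearly every cohort (power check at the τ=0.10 stratum)."""
        hits = 0
        n_cohorts = 25
        for seed in range(n_cohorts):
            cfg = CohortConfig(
                n_subjects={"SZ": 42},
                seed=3000 + seed,
                couplings=[Coupling("UPSA", "R Superior Temporal", "MMN", 0.48)],
            )
            _, scores, gt = generate_cohort(cfg, signals=False)
            peaks = planted_peak_table(gt)
            audit = correlation_audit(peaks, scores)
            row = audit.correlations[
                (audit.correlations["source"] == "R Superior Temporal")
                & (audit.correlations["peak"] == "MMN")
                & (audit.correlations["measure_type"] == "amplitude")
                & (audit.correlations["variable"] == "UPSA")
            ]
            if float(row["r2"].iloc[0]) > 0.10:
                hits += 1
        assert hits >= 0.9 * n_cohorts


class TestGroupContrasts:
    def _table(self, mean_ncs, mean_sz, sd=1.0, n=40, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, mu, tag in (("NCS", mean_ncs, "N"), ("SZ", mean_sz, "S")):
            for i in range(n):
                rows.append(
                    {
                        "subject": f"{tag}{i}",
                        "group": g,
                        "source": "cluster0",
                        "peak": "P3a",
                        "latency_ms": 280.0 + rng.standard_normal(),
                        "amplitude_uv": mu + sd * rng.standard_normal(),
                        "edge_flag": 0,
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_groups_give_zero_d(self):
        df = self._table(0.0, 0.0, seed=1)
        df.loc[df["group"] == "SZ", "amplitude_uv"] = df[df["group"] == "NCS"][
            "amplitude_uv"
        ].to_numpy()
        out = [c for c in group_contrasts(df) if c.measure_type == "amplitude"]
        assert out[0].cohens_d == pytest.approx(0.0)
        assert out[0].welch_t == pytest.approx(0.0)

    def test_unit_separation_gives_d_about_one(self):
        out = [
            c
            for c in group_contrasts(self._table(1.0, 0.0, sd=1.0, n=40, seed=2))
            if c.measure_type == "amplitude"
        ]
        assert out[0].cohens_d == pytest.approx(1.0, abs=0.35)
        assert out[0].mean_ncs > out[0].mean_sz

    def test_small_cell_skipped_with_warning(self):
        df = self._table(1.0, 0.0, n=1, seed=3)
        with pytest.warns(UserWarning):
            out = group_contrasts(df)
        assert out == []

    def test_planted_group_deficit_ordering(self):
        """Largest planted SZ deficit produces the largest recovered d."""
        cfg = CohortConfig(n_subjects={"NCS": 30, "SZ": 30}, seed=17)
        _, _, gt = generate_cohort(cfg, signals=False)
        peaks = planted_peak_table(gt)
        out = group_contrasts(peaks)
        d = {
            (c.source, c.peak): c.cohens_d
            for c in out
            if c.measure_type == "amplitude"
        }
        # P3a (positive peak, SZ scaled down): d positive, largest for the
        # dorsal mid-cingulate source (strongest planted deficit)
        p3a = {s: v for (s, p), v in d.items() if p == "P3a"}
        assert p3a["Dorsal Mid-Cingulate"] > 0
        assert max(p3a, key=p3a.get) == "Dorsal Mid-Cingulate"
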