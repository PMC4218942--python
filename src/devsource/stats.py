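"""Correlation screen, chance-expectation audit, and group contrasts.

Associations between ERP peak measures and clinical/cognitive scores
use Spearman rank correlations (average ranks on ties), with p-values
from the two-sided t approximation t = r·√(n−2)/√(1−r²).  To control
Type I error the audit (a) only calls a correlation significant when it
explains more than 10 % of the variance, stratified further at r² ≥
0.20/0.30/0.40/0.50; (b) compares the number of observed significant
correlations per stratum with the number expected under the null; and
(c) reports a Bonferroni-corrected critical r² per test family obtained
by inverting the t approximation at the per-test α.  With α = 0.05/30
and n = 42 the critical r² is 0.22; with α = 0.05/180 it is 0.28.

Families under the default 10-variable configuration: Fz measures are
3 peaks × 10 variables × 2 measure types (amplitude, latency) = 60
tests; source-resolved measures are 6 clusters × 3 peaks × 10 × 2 =
360.  Latency and amplitude audits count as separate tests (the reading
under which the expected-count bookkeeping is self-consistent);
missing scores are deleted pairwise, with each pair's own n feeding its
p-value.

Group differences are summarised per (source, peak, measure) as Welch
t-tests plus Cohen's d on the pooled SD, sign convention NCS − SZ.
The study-scale mixed-model machinery is deliberately out of scope; the
report labels these as two-sample contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as st

from .data_io import ValidationError

__all__ = [
    "TAU_STRATA",
    "spearman",
    "critical_r2",
    "expected_significant",
    "CorrelationAudit",
    "correlation_audit",
    "GroupContrast",
    "group_contrasts",
]

TAU_STRATA = (0.10, 0.20, 0.30, 0.40, 0.50)


def spearman(x, y) -> tuple[float, float, float, int]:
    """Spearman correlation with pairwise deletion.

    Returns ``(r, r², p, n_pairs)``; p is the two-sided t approximation.
    Requires ≥ 5 complete pairs; constant vectors are an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 5:
        raise ValidationError(f"need >= 5 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("Spearman correlation undefined for a constant vector")
    rx = st.rankdata(x)  # average ranks on ties
    ry = st.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * st.t.sf(abs(t), n - 2))
    return r, r * r, p, n


def critical_r2(alpha_family: float, n_tests: int, n: int) -> float:
    """Bonferroni critical r²: invert the two-sided t approximation.

    Per-test α = alpha_family / n_tests; t* = t-quantile(1 − α/2, n−2);
    r*² = t*² / (t*² + n − 2).
    """
    if n_tests < 1:
        raise ValidationError("n_tests must be >= 1")
    if n <= 3:
        raise ValidationError("need n > 3")
    alpha = alpha_family / n_tests
    if alpha / 2.0 >= 0.5:
        raise ValidationError("per-test alpha too large to invert")
    df = n - 2
    t_star = st.t.ppf(1.0 - alpha / 2.0, df)
    return float(t_star**2 / (t_star**2 + df))


def _p_exceed_tau(tau: float, n: int) -> float:
    """Null P(R² > τ) under the two-sided t approximation at r = √τ."""
    df = n - 2
    t = np.sqrt(tau) * np.sqrt(df / (1.0 - tau))
    return float(2.0 * st.t.sf(t, df))


def expected_significant(
    n_tests: int,
    tau: float,
    n: int,
    method: str = "analytic",
    n_sims: int = 100_000,
    seed: int = 0,
) -> float:
    """Expected number of null correlations with r² > τ among n_tests.

    ``analytic`` uses the t approximation; ``montecarlo`` simulates
    independent Gaussian pairs and applies the sample Spearman r².
    """
    if not 0.0 < tau < 1.0:
        raise ValidationError("tau must lie in (0, 1)")
    if method == "analytic":
        return n_tests * _p_exceed_tau(tau, n)
    if method != "montecarlo":
        raise ValidationError("method must be 'analytic' or 'montecarlo'")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_sims, n))
    y = rng.standard_normal((n_sims, n))
    r = _rank_corr_rows(x, y)
    return float(n_tests * np.mean(r * r > tau))


def _rank_corr_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Spearman r for continuous data (no ties expected)."""
    rx = np.argsort(np.argsort(x, axis=1), axis=1).astype(float)
    ry = np.argsort(np.argsort(y, axis=1), axis=1).astype(float)
    rx -= rx.mean(axis=1, keepdims=True)
    ry -= ry.mean(axis=1, keepdims=True)
    num = (rx * ry).sum(axis=1)
    den = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    return num / den


@dataclass
class CorrelationAudit:
    """Observed-vs-expected significant-correlation bookkeeping."""

    correlations: pd.DataFrame  # family, source, peak, measure_type, variable, n, r, r2, p, bonferroni
    strata: tuple[float, ...]
    observed: dict[str, dict[str, dict[float, int]]]  # family -> measure_type -> tau -> count
    expected: dict[str, dict[float, float]]  # family -> tau -> expected count
    family_sizes: dict[str, int]
    critical_r2: dict[str, float]
    alpha_family: float

    def as_dict(self) -> dict:
        return {
            "alpha_family": self.alpha_family,
            "strata": list(self.strata),
            "family_sizes": self.family_sizes,
            "critical_r2": self.critical_r2,
            "observed": {
                fam: {mt: {str(t): c for t, c in taus.items()} for mt, taus in mts.items()}
                for fam, mts in self.observed.items()
            },
            "expected": {
                fam: {str(t): e for t, e in taus.items()}
                for fam, taus in self.expected.items()
            },
        }


def correlation_audit(
    peak_table: pd.DataFrame,
    score_table: pd.DataFrame,
    group: str = "SZ",
    variables: list[str] | None = None,
    alpha_family: float = 0.05,
    strata: tuple[float, ...] = TAU_STRATA,
    fz_label: str = "Fz",
    fixed_n: int | None = None,
) -> CorrelationAudit:
    """Run the full correlation screen and chance-expectation audit.

    ``peak_table`` is tidy: subject, group, source (``Fz`` or a cluster
    label), peak, latency_ms, amplitude_uv.  The audit correlates every
    (source, peak, measure_type) against every score variable within
    the requested group, splits the Fz family from the source family,
    tabulates observed counts per r² stratum against analytic expected
    counts, and flags pairs beyond the family's Bonferroni critical r².
    """
    if variables is None:
        variables = [
            c for c in score_table.columns if c not in ("subject_id", "group")
        ]
    if not variables:
        raise ValidationError("score table contains no audit variables")
    scores = score_table[score_table["group"] == group]
    pt = peak_table[peak_table["group"] == group]
    merged_sources = sorted(s for s in pt["source"].unique() if s != fz_label)

    # wide layout: one column per (source, peak, measure type)
    scores_w = scores.set_index("subject_id")[variables].astype(float)
    cells: list[tuple[str, str, str, str]] = []  # family, source, peak, mtype
    meas_cols: dict[tuple, pd.Series] = {}
    for source in ([fz_label] if (pt["source"] == fz_label).any() else []) + merged_sources:
        fam = "Fz" if source == fz_label else "source"
        sub = pt[pt["source"] == source]
        for peak in sorted(sub["peak"].unique()):
            cell = sub[sub["peak"] == peak].set_index("subject")
            for mtype, col in (("amplitude", "amplitude_uv"), ("latency", "latency_ms")):
                cells.append((fam, source, peak, mtype))
                meas_cols[(source, peak, mtype)] = cell[col].astype(float)
    meas_w = pd.DataFrame({k: v for k, v in meas_cols.items()})
    common = meas_w.index.intersection(scores_w.index)
    M = meas_w.loc[common]
    S = scores_w.loc[common]

    complete = (
        len(common) >= 5 and not M.isna().to_numpy().any() and not S.isna().to_numpy().any()
    )
    rows = []
    if complete and fixed_n is None:
        # vectorised complete-case Spearman: rank columns once, then one
        # cross-correlation of the rank matrices
        n = len(common)
        rm = st.rankdata(M.to_numpy(), axis=0)
        rs = st.rankdata(S.to_numpy(), axis=0)
        rm = rm - rm.mean(axis=0)
        rs = rs - rs.mean(axis=0)
        denom = np.sqrt(
            np.outer((rm**2).sum(axis=0), (rs**2).sum(axis=0))
        )
        valid = denom > 0
        R = np.zeros_like(denom)
        np.divide(rm.T @ rs, denom, out=R, where=valid)
        R = np.clip(R, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            T = R * np.sqrt((n - 2) / (1.0 - R * R))
        P = np.where(np.abs(R) >= 1.0, 0.0, 2.0 * st.t.sf(np.abs(T), n - 2))
        for i, (fam, source, peak, mtype) in enumerate(cells):
            for j, var in enumerate(variables):
                if not valid[i, j]:
                    continue
                rij = float(R[i, j])
                rows.append(
                    {
                        "family": fam,
                        "source": source,
                        "peak": peak,
                        "measure_type": mtype,
                        "variable": var,
                        "n": n,
                        "r": rij,
                        "r2": rij * rij,
                        "p": float(P[i, j]),
                    }
                )
    else:
        for fam, source, peak, mtype in cells:
            y_all = M[(source, peak, mtype)]
            for var in variables:
                x = S[var].to_numpy(dtype=float)
                y = y_all.to_numpy(dtype=float)
                try:
                    r, r2, p, n = spearman(x, y)
                except ValidationError:
                    continue
                if fixed_n is not None:
                    n = fixed_n
                    if abs(r) < 1.0:
                        t = r * np.sqrt((n - 2) / (1.0 - r * r))
                        p = float(2.0 * st.t.sf(abs(t), n - 2))
                rows.append(
                    {
                        "family": fam,
                        "source": source,
                        "peak": peak,
                        "measure_type": mtype,
                        "variable": var,
                        "n": n,
                        "r": r,
                        "r2": r2,
                        "p": p,
                    }
                )
    corr = pd.DataFrame(rows)
    if corr.empty:
        raise ValidationError("no correlations could be computed")

    family_sizes = {
        fam: int((corr["family"] == fam).sum()) for fam in corr["family"].unique()
    }
    n_typical = int(corr["n"].median()) if fixed_n is None else fixed_n
    crit = {
        fam: critical_r2(alpha_family, size, n_typical)
        for fam, size in family_sizes.items()
    }
    corr["bonferroni_flag"] = [
        row.r2 > crit[row.family] for row in corr.itertuples()
    ]

    observed: dict[str, dict[str, dict[float, int]]] = {}
    expected: dict[str, dict[float, float]] = {}
    for fam in family_sizes:
        fam_df = corr[corr["family"] == fam]
        observed[fam] = {
            mt: {
                tau: int((fam_df[fam_df["measure_type"] == mt]["r2"] > tau).sum())
                for tau in strata
            }
            for mt in ("amplitude", "latency")
        }
        expected[fam] = {
            tau: expected_significant(family_sizes[fam], tau, n_typical)
            for tau in strata
        }
    return CorrelationAudit(
        correlations=corr,
        strata=strata,
        observed=observed,
        expected=expected,
        family_sizes=family_sizes,
        critical_r2=crit,
        alpha_family=alpha_family,
    )


@dataclass
class GroupContrast:
    source: str
    peak: str
    measure_type: str
    mean_ncs: float
    mean_sz: float
    sd_ncs: float
    sd_sz: float
    n_ncs: int
    n_sz: int
    welch_t: float
    p: float
    cohens_d: float  # pooled SD, NCS − SZ


def group_contrasts(
    peak_table: pd.DataFrame,
    groups: tuple[str, str] = ("NCS", "SZ"),
) -> list[GroupContrast]:
    """Welch t and Cohen's d per (source, peak, measure type).

    Cells with fewer than 2 subjects in either group are skipped with a
    warning.  Subjects missing from a cluster are simply absent rows.
    """
    import warnings

    out: list[GroupContrast] = []
    g1, g2 = groups
    for (source, peak), cell in peak_table.groupby(["source", "peak"]):
        for mtype, col in (("amplitude", "amplitude_uv"), ("latency", "latency_ms")):
            a = cell[cell["group"] == g1][col].dropna().to_numpy()
            b = cell[cell["group"] == g2][col].dropna().to_numpy()
            if a.size < 2 or b.size < 2:
                warnings.warn(
                    f"skipping contrast {source}/{peak}/{mtype}: <2 per group"
                )
                continue
            t, p = st.ttest_ind(a, b, equal_var=False)
            sp = np.sqrt(
                ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
                / (a.size + b.size - 2)
            )
            d = float((a.mean() - b.mean()) / sp) if sp > 0 else 0.0
            out.append(
                GroupContrast(
                    source=str(source),
                    peak=str(peak),
                    measure_type=mtype,
                    mean_ncs=float(a.mean()),
                    mean_sz=float(b.mean()),
                    sd_ncs=float(a.std(ddof=1)),
                    sd_sz=float(b.std(ddof=1)),
                    n_ncs=int(a.size),
                    n_sz=int(b.size),
                    welch_t=float(t),
                    p=float(p),
                    cohens_d=d,
                )
            )
    return out
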