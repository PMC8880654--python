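"""Inferential statistics for change-detection experiments.

Implements, from first principles, the test battery used to compare the
four presentation formats: one-way repeated-measures ANOVA, paired t
tests with JZS (Cauchy-prior) Bayes factors, Pearson correlations with a
stretched-beta-prior Bayes factor, the "N-1" chi-squared comparison of
two proportions, and Steiger's z for two dependent correlations sharing
one variable.  All Bayes factors use numerical integration; the
repeated-measures Bayes factor is a BIC approximation and is labelled as
such in its metadata.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, special, stats


@dataclass
class StatResult:
    """A named statistic with df, p-value and optional Bayes factor."""

    name: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    bf10: float | None = None
    method: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value out of [0, 1]")
        if self.bf10 is not None and not self.bf10 > 0:
            raise ValueError("BF10 must be positive")


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


def rm_anova_oneway(data: np.ndarray, sphericity: str = "none") -> StatResult:
    """One-way repeated-measures ANOVA on an n x k (participants x conditions) matrix.

    F = MS_condition / MS_error with df (k-1, (k-1)(n-1)); the error term
    is the participant-by-condition interaction.  ``sphericity='gg'``
    applies the Greenhouse–Geisser epsilon to the degrees of freedom.
    An approximate Bayes factor (BIC difference between the condition
    model and the subjects-only null) is attached in ``bf10``.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be a 2-D participants x conditions matrix")
    if np.isnan(x).any():
        raise ValueError("missing cells: apply listwise deletion before the ANOVA")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 participants and 2 conditions")

    grand = x.mean()
    subj = x.mean(axis=1, keepdims=True)
    cond = x.mean(axis=0, keepdims=True)
    ss_cond = n * float(np.sum((cond - grand) ** 2))
    ss_err = float(np.sum((x - subj - cond + grand) ** 2))
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err == 0.0:
        f_stat = math.inf if ms_cond > 0 else 0.0
        p = 0.0 if ms_cond > 0 else 1.0
        eps = 1.0
    else:
        f_stat = ms_cond / ms_err
        eps = _gg_epsilon(x) if sphericity == "gg" else 1.0
        p = float(stats.f.sf(f_stat, df1 * eps, df2 * eps))

    # BIC-approximate BF10: condition model vs subjects-only null, both
    # with subject effects absorbed; N observations = n*k.
    n_obs = n * k
    rss_null = float(np.sum((x - subj) ** 2))
    bf10 = None
    if rss_null > 0 and ss_err > 0:
        bic_null = n_obs * math.log(rss_null / n_obs) + (n + 1) * math.log(n_obs)
        bic_alt = n_obs * math.log(ss_err / n_obs) + (n + k) * math.log(n_obs)
        bf10 = float(np.exp(min(700.0, (bic_null - bic_alt) / 2.0)))
    return StatResult(
        name="rm_anova", statistic=float(f_stat), df=(df1 * eps, df2 * eps),
        p_value=p, bf10=bf10,
        method={"sphericity": sphericity, "epsilon": eps, "bf_method": "BIC approximation"},
    )


def _gg_epsilon(x: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from the double-centred covariance."""
    n, k = x.shape
    s = np.cov(x, rowvar=False, ddof=1)
    centred = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) + s.mean()
    num = np.trace(centred) ** 2
    den = (k - 1) * float(np.sum(centred**2))
    return float(num / den) if den > 0 else 1.0


# ---------------------------------------------------------------------------
# paired t and JZS Bayes factor


def paired_t(a, b) -> StatResult:
    """Paired two-tailed t test; df = n - 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    d = a - b
    sd = float(np.std(d, ddof=1))
    mean = float(np.mean(d))
    method: dict = {}
    if sd == 0.0:
        if mean == 0.0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = math.copysign(math.inf, mean), 0.0
            method["degenerate"] = "zero variance of differences"
    else:
        t_stat = mean / (sd / math.sqrt(n))
        p = float(2.0 * stats.t.sf(abs(t_stat), n - 1))
    return StatResult(name="paired_t", statistic=float(t_stat), df=(n - 1,),
                      p_value=p, method=method)


def jzs_ttest_bf(t: float, n: int, cauchy_scale: float = math.sqrt(2) / 2) -> float:
    """Two-sided JZS Bayes factor BF10 for a one-sample / paired t statistic.

    The alternative places a Cauchy(0, ``cauchy_scale``) prior on the
    standardized effect size delta; the marginal likelihood of t under
    H1 integrates the noncentral-t density over that prior, and H0 is the
    central t.  One-dimensional adaptive quadrature, relative tolerance
    1e-8.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    nu = n - 1
    sqrt_n = math.sqrt(n)

    def integrand(delta):
        return stats.nct.pdf(t, nu, delta * sqrt_n) * stats.cauchy.pdf(delta, 0.0, cauchy_scale)

    num, err = integrate.quad(integrand, -np.inf, np.inf,
                              epsrel=1e-8, epsabs=0.0, limit=400)
    if not np.isfinite(num) or num <= 0:
        raise RuntimeError(f"JZS integration failed: integral={num}, abserr={err}")
    return float(num / stats.t.pdf(t, nu))


# ---------------------------------------------------------------------------
# Pearson correlation with Bayes factor


def _corr_kernel(rho: np.ndarray, r: float, n: int) -> np.ndarray:
    """rho-dependent part of the sampling density of r given rho."""
    return ((1.0 - rho**2) ** ((n - 1) / 2.0)
            * (1.0 - rho * r) ** (1.5 - n)
            * special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1.0) / 2.0))


def pearson_r_bf(x, y, kappa: float = 1.0) -> StatResult:
    """Pearson correlation with two-tailed p and a stretched-beta-prior BF10.

    The prior on the population correlation rho is the symmetric
    stretched beta with width ``kappa`` (kappa = 1: uniform on (-1, 1));
    the Bayes factor integrates the exact sampling density of r over it.
    At |r| = 1 the BF diverges and is omitted with a flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("inputs must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    r = float(r)
    method = {"kappa": kappa, "r_squared": r * r}
    bf10 = None
    if abs(r) >= 1.0 - 1e-12:
        method["degenerate"] = "|r| = 1: Bayes factor unbounded"
    else:
        a = 1.0 / kappa

        def integrand(rho):
            prior = (1.0 - rho**2) ** (a - 1.0) / special.beta(a, a) / 2.0 ** (2.0 * a - 1.0)
            return _corr_kernel(np.asarray(rho), r, n) * prior

        num, _ = integrate.quad(integrand, -1.0, 1.0, epsrel=1e-10, limit=200)
        bf10 = float(num / _corr_kernel(np.asarray(0.0), r, n))
    return StatResult(name="pearson_r", statistic=r, df=(n - 2,),
                      p_value=float(p), bf10=bf10, method=method)


# ---------------------------------------------------------------------------
# "N-1" chi-squared for two proportions


def n1_chi2_proportions(p1: float, n1: int, p2: float, n2: int) -> StatResult:
    """Campbell's "N-1" chi-squared test of two independent proportions.

    Builds the 2x2 table with (possibly fractional) counts p_i * n_i and
    computes chi2 = (ad - bc)^2 (N - 1) / (m n r s), i.e. the Pearson
    statistic scaled by (N-1)/N; two-tailed p from chi2 with df = 1.
    Degenerate margins (all successes or all failures) return chi2 = 0
    with a flag.
    """
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError("proportions must lie in [0, 1]")
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    a, b = p1 * n1, (1.0 - p1) * n1
    c, d = p2 * n2, (1.0 - p2) * n2
    big_n = n1 + n2
    col1, col2 = a + c, b + d
    method: dict = {}
    if col1 == 0.0 or col2 == 0.0:
        return StatResult(name="n1_chi2", statistic=0.0, df=(1,), p_value=1.0,
                          method={"degenerate": "empty outcome column"})
    chi2 = (a * d - b * c) ** 2 * (big_n - 1) / (n1 * n2 * col1 * col2)
    p = float(stats.chi2.sf(chi2, 1))
    return StatResult(name="n1_chi2", statistic=float(chi2), df=(1,), p_value=p,
                      method=method)


# ---------------------------------------------------------------------------
# dependent correlations (Steiger / Lee–Preacher)


@dataclass(frozen=True)
class CorrTriple:
    """Correlations among three variables measured on one sample.

    ``r12`` and ``r13`` share variable 1; ``r23`` links the two
    non-shared variables.  The implied 3x3 correlation matrix must be
    positive semi-definite.
    """

    r12: float
    r13: float
    r23: float
    n: int
    labels: tuple[str, str, str] = ("v1", "v2", "v3")

    def __post_init__(self):
        for r in (self.r12, self.r13, self.r23):
            if not -1.0 < r < 1.0:
                raise ValueError("correlations must lie strictly inside (-1, 1)")
        m = np.array([[1.0, self.r12, self.r13],
                      [self.r12, 1.0, self.r23],
                      [self.r13, self.r23, 1.0]])
        if np.linalg.eigvalsh(m).min() < -1e-10:
            raise ValueError("correlation triple is not positive semi-definite")
        if self.n < 4:
            raise ValueError("need n >= 4")


def steiger_dependent_r(triple: CorrTriple) -> StatResult:
    """Steiger's z for H0: rho12 = rho13 (correlations sharing variable 1).

    Fisher-transforms r12 and r13; their covariance under H0 uses the
    pooled correlation r_bar and the between-nonshared correlation r23:

        cov = [r23 (1 - 2 r_bar^2) - r_bar^2 (1 - 2 r_bar^2 - r23^2) / 2]
              / (1 - r_bar^2)^2
        z = (z12 - z13) * sqrt((n - 3) / (2 (1 - cov)))

    Two-tailed p from the standard normal.
    """
    r12, r13, r23, n = triple.r12, triple.r13, triple.r23, triple.n
    rbar = (r12 + r13) / 2.0
    cov = ((r23 * (1.0 - 2.0 * rbar**2)
            - 0.5 * rbar**2 * (1.0 - 2.0 * rbar**2 - r23**2))
           / (1.0 - rbar**2) ** 2)
    z = (math.atanh(r12) - math.atanh(r13)) * math.sqrt((n - 3.0) / (2.0 * (1.0 - cov)))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return StatResult(name="steiger_z", statistic=float(z), df=(), p_value=p,
                      method={"labels": triple.labels, "pooled_r": rbar})


# ---------------------------------------------------------------------------
# full-experiment report


def holm_adjust(p_values: dict[str, float]) -> dict[str, float]:
    """Holm step-down adjustment of a family of p-values."""
    items = sorted(p_values.items(), key=lambda kv: kv[1])
    m = len(items)
    adjusted: dict[str, float] = {}
    running = 0.0
    for rank, (key, p) in enumerate(items):
        running = max(running, min(1.0, (m - rank) * p))
        adjusted[key] = running
    return adjusted


def per_individual_chi2_tally(miss_counts: np.ndarray, n_trials: int,
                              conditions: list[str], alpha: float = 0.05) -> dict:
    """Per-participant "N-1" chi-squared comparisons across condition pairs.

    ``miss_counts`` is participants x conditions.  For every condition
    pair, each participant's two miss proportions (over ``n_trials``
    each) are compared; the tally counts participants with p <= alpha.
    """
    counts = np.asarray(miss_counts, dtype=float)
    n_part = counts.shape[0]
    out = {}
    for i, j in itertools.combinations(range(len(conditions)), 2):
        flagged = []
        for p in range(n_part):
            res = n1_chi2_proportions(counts[p, i] / n_trials, n_trials,
                                      counts[p, j] / n_trials, n_trials)
            if res.p_value <= alpha:
                flagged.append(p)
        out[f"{conditions[i]}_vs_{conditions[j]}"] = {
            "n_significant": len(flagged),
            "n_participants": n_part,
            "flagged": flagged,
        }
    return out


def analyze_experiment(
    summaries,
    chance_model=None,
    alpha: float = 0.05,
    cauchy_scale: float = math.sqrt(2) / 2,
    kappa: float = 1.0,
    adjust: str = "none",
    corr_conditions: tuple[str, ...] = ("horizontal", "vertical", "seq_isi200"),
) -> dict:
    """Run the full analysis sequence on participant-condition summaries.

    Per metric (total miss %, change blindness %, hit detection time):
    omnibus repeated-measures ANOVA and all pairwise paired t tests with
    JZS Bayes factors.  On total-miss counts: per-individual "N-1"
    chi-squared tallies across condition pairs, the between-condition
    Pearson correlation matrix with Bayes factors, and Steiger tests of
    the dependent correlation differences.
    """
    from .scoring import ChanceModel, summaries_to_frame

    if chance_model is None:
        chance_model = ChanceModel()
    df = summaries_to_frame(summaries)
    conditions = sorted(df["condition"].unique())
    if len(conditions) < 2 or df["participant_id"].nunique() < 2:
        raise ValueError("need at least 2 participants and 2 conditions")
    report: dict = {
        "n_participants": int(df["participant_id"].nunique()),
        "conditions": conditions,
        "chance_model": {"p_chance": chance_model.aoi_area_cm2 / chance_model.image_area_cm2,
                         "area_convention": chance_model.area_convention,
                         "aoi_radius_cm": chance_model.aoi_radius_cm},
        "metrics": {},
    }
    for metric in ("pct_total_miss", "pct_change_blindness", "mean_hit_detection_time_s"):
        wide = df.pivot(index="participant_id", columns="condition", values=metric)
        wide = wide.dropna(axis=0)
        entry: dict = {}
        if wide.shape[0] >= 2 and wide.shape[1] >= 2:
            entry["rm_anova"] = rm_anova_oneway(wide.to_numpy())
            entry["pairwise"] = {}
            for c1, c2 in itertools.combinations(wide.columns, 2):
                res = paired_t(wide[c1].to_numpy(), wide[c2].to_numpy())
                if np.isfinite(res.statistic):
                    res.bf10 = jzs_ttest_bf(res.statistic, wide.shape[0], cauchy_scale)
                entry["pairwise"][f"{c1}_vs_{c2}"] = res
            if adjust == "holm" and entry["pairwise"]:
                raw = {k: r.p_value for k, r in entry["pairwise"].items()}
                for k, p_adj in holm_adjust(raw).items():
                    entry["pairwise"][k].method["p_holm"] = p_adj
        report["metrics"][metric] = entry

    # per-individual chi2 tallies and correlation structure on miss counts
    wide = df.pivot(index="participant_id", columns="condition", values="pct_total_miss")
    n_trials = int(df["n_trials"].iloc[0])
    present = [c for c in corr_conditions if c in wide.columns]
    counts = wide[present].to_numpy() / 100.0 * n_trials
    report["per_individual_chi2"] = per_individual_chi2_tally(
        counts, n_trials, present, alpha=alpha)

    corrs: dict = {}
    rmat: dict = {}
    for c1, c2 in itertools.combinations(present, 2):
        res = pearson_r_bf(wide[c1].to_numpy(), wide[c2].to_numpy(), kappa=kappa)
        corrs[f"{c1}_vs_{c2}"] = res
        rmat[(c1, c2)] = res.statistic
    report["correlations"] = corrs
    n_part = wide.shape[0]
    if len(present) == 3 and n_part >= 4 and all(abs(r) < 1.0 for r in rmat.values()):
        h, v, q = present[0], present[1], present[2]
        steiger_tests = {}
        for shared, ra, rb, rc, lab in (
            (h, rmat[(h, v)], rmat[(h, q)], rmat[(v, q)], f"{h}: {v} vs {q}"),
            (v, rmat[(h, v)], rmat[(v, q)], rmat[(h, q)], f"{v}: {h} vs {q}"),
            (q, rmat[(h, q)], rmat[(v, q)], rmat[(h, v)], f"{q}: {h} vs {v}"),
        ):
            triple = CorrTriple(r12=ra, r13=rb, r23=rc, n=n_part,
                                labels=(shared, "a", "b"))
            steiger_tests[lab] = steiger_dependent_r(triple)
        report["steiger"] = steiger_tests
    return report
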