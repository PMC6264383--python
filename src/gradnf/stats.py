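"""Group-level inference for the graded neurofeedback analysis.

Covers the study's statistical layer: per-subject median-PSC aggregation,
2x2 repeated-measures ANOVA (target level x feedback condition) with
omega-squared effect sizes, one-sided paired t-tests with Cohen's d
(d = t / sqrt(n) for paired designs), Bayesian t-tests with informed
half-normal priors on the standardized effect size, and the
physiological-confound analysis (Pearson correlation of convolved
physiological traces with the task predictor, Fisher z transform,
one-sample t-tests with Benjamini-Hochberg FDR correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats
from statsmodels.stats.multitest import multipletests

from .errors import AggregationError, DataError, DegenerateDataError, DesignError
from .glm import PscEstimate
from .hrf import convolve_blocks, task_regressor
from .protocol import LEVELS, RunDesign

CONDITIONS = ("active", "passive")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    d: float
    side: str  # 'less', 'greater' or 'two'
    mean_diff: float
    sem_diff: float


@dataclass(frozen=True)
class BayesResult:
    bf: float
    prior_scale: float
    side: str
    t_input: float
    n_input: int


@dataclass(frozen=True)
class AnovaEffect:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    omega_squared: float


@dataclass(frozen=True)
class PhysioCorrResult:
    kind: str
    region: str
    z_mean: float
    z_sem: float
    t: float
    df: int
    p: float
    p_fdr: float
    d: float
    n: int
    bf: float | None = None


# ---------------------------------------------------------------------------
# aggregation

def aggregate_median_psc(psc_rows: list[PscEstimate] | pd.DataFrame) -> pd.DataFrame:
    """Per-subject median PSC across runs for every region/condition/level cell.

    Returns the group table (one row per subject x region x condition x
    level) that feeds the ANOVA / t-test layer.
    """
    if not isinstance(psc_rows, pd.DataFrame):
        psc_rows = pd.DataFrame([vars(r) for r in psc_rows])
    required = {"subject", "region", "condition", "level", "psc"}
    if not required.issubset(psc_rows.columns):
        raise AggregationError(f"psc rows must have columns {sorted(required)}")
    table = (
        psc_rows.groupby(["subject", "region", "condition", "level"], as_index=False)["psc"]
        .median()
        .rename(columns={"psc": "median_psc"})
    )
    # every subject must contribute every cell
    for subject, sub in table.groupby("subject"):
        cells = set(zip(sub["region"], sub["condition"], sub["level"]))
        for region in psc_rows["region"].unique():
            for condition in CONDITIONS:
                for level in LEVELS:
                    if (region, condition, level) not in cells:
                        raise AggregationError(
                            f"subject {subject!r} is missing cell "
                            f"({region}, {condition}, {level})"
                        )
    return table


# ---------------------------------------------------------------------------
# frequentist tests

def cohens_d_from_t(t: float, n: int) -> float:
    """Paired/one-sample Cohen's d from a t statistic: d = t / sqrt(n)."""
    if n < 2:
        raise DesignError(f"n must be >= 2, got {n}")
    return t / np.sqrt(n)


def _t_p_value(t: float, df: int, side: str) -> float:
    if side == "greater":
        return float(stats.t.sf(t, df))
    if side == "less":
        return float(stats.t.cdf(t, df))
    if side == "two":
        return float(2 * stats.t.sf(abs(t), df))
    raise DesignError(f"unknown side {side!r}")


def one_sample_t(x: np.ndarray, side: str = "two") -> TTestResult:
    """One-sample t-test of the mean against zero."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise DesignError(f"need at least 3 observations, got {n}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("observations have zero variance")
    sem = sd / np.sqrt(n)
    t = float(x.mean() / sem)
    return TTestResult(
        t=t,
        df=n - 1,
        p=_t_p_value(t, n - 1, side),
        d=cohens_d_from_t(t, n),
        side=side,
        mean_diff=float(x.mean()),
        sem_diff=float(sem),
    )


def paired_t(x: np.ndarray, y: np.ndarray, side: str = "two") -> TTestResult:
    """Paired t-test of x - y (subjects matched by position)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("paired samples must have equal length")
    return one_sample_t(x - y, side)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA

def rm_anova_2x2(table: pd.DataFrame, region: str) -> list[AnovaEffect]:
    """2x2 within-subject ANOVA (level x condition) on one region's medians.

    Each effect is tested against its own subject-by-effect interaction
    error term and reported with partial omega-squared
    (see :func:`_partial_omega_squared`).
    """
    sub = table[table["region"] == region]
    if sub.empty:
        raise DesignError(f"no rows for region {region!r}")
    wide = sub.pivot_table(
        index="subject", columns=["condition", "level"], values="median_psc"
    )
    expected = [(c, l) for c in CONDITIONS for l in LEVELS]
    if sorted(wide.columns.tolist()) != sorted(expected) or wide.isna().any().any():
        raise DesignError(f"unbalanced table for region {region!r}")
    data = wide[expected].to_numpy()  # columns: (act,low),(act,high),(pas,low),(pas,high)
    n = data.shape[0]

    # orthogonal contrasts over cells (act_low, act_high, pas_low, pas_high)
    contrasts = {
        "level": np.array([-1.0, 1.0, -1.0, 1.0]) / 2,  # high - low
        "condition": np.array([1.0, 1.0, -1.0, -1.0]) / 2,  # active - passive
        "interaction": np.array([-1.0, 1.0, 1.0, -1.0]) / 2,
    }
    effects = []
    for name, c in contrasts.items():
        scores = data @ c  # per-subject effect scores
        norm = float(c @ c)
        ss_eff = n * scores.mean() ** 2 / norm
        ss_err = np.sum((scores - scores.mean()) ** 2) / norm
        df_num, df_den = 1, n - 1
        ms_err = ss_err / df_den
        F = _f_ratio(ss_eff, ms_err, scale=float(np.abs(data).max()) ** 2)
        p = float(stats.f.sf(F, df_num, df_den)) if np.isfinite(F) else 0.0
        omega = _partial_omega_squared(ss_eff, ms_err, df_num, df_den)
        effects.append(AnovaEffect(name, F, df_num, df_den, p, omega))
    return effects


def _f_ratio(ss_eff: float, ms_err: float, scale: float) -> float:
    """F with a guard for degenerate (zero error variance) tables.

    Sums of squares below floating-point residue (relative to ``scale``,
    the squared magnitude of the data) count as exactly zero.
    """
    tol = 1e-10 * max(scale, 1e-300)
    if ms_err <= tol:
        return np.inf if ss_eff > tol else 0.0
    return float(ss_eff / ms_err)


def _partial_omega_squared(ss_eff: float, ms_err: float, df_num: int, df_den: int) -> float:
    """Partial omega-squared for a within-subject effect.

    omega_p^2 = (SS_eff - df_num * MS_err) / (SS_eff + (df_den + 1) * MS_err),
    clamped at 0.  Equivalently (F - 1) / (F + (df_den + 1) / df_num).
    """
    if ms_err == 0:
        return 1.0 if ss_eff > 0 else 0.0
    omega = (ss_eff - df_num * ms_err) / (ss_eff + (df_den + 1) * ms_err)
    return max(float(omega), 0.0)


def run_difference_trend(psc_rows: list[PscEstimate] | pd.DataFrame, region: str) -> AnovaEffect:
    """One-way repeated-measures ANOVA over run index on high-minus-low scores.

    Uses each subject's *active*-condition runs for the given region; tests
    whether the level separation changes over the course of training.
    """
    if not isinstance(psc_rows, pd.DataFrame):
        psc_rows = pd.DataFrame([vars(r) for r in psc_rows])
    sub = psc_rows[
        (psc_rows["region"] == region) & (psc_rows["condition"] == "active")
    ].copy()
    # training-run position within the subject (run ids differ across
    # subjects because of region-order counterbalancing)
    sub["run_pos"] = sub.groupby("subject")["run_id"].rank(method="dense").astype(int)
    wide = sub.pivot_table(index="subject", columns=["run_pos", "level"], values="psc")
    runs = sorted({r for r, _ in wide.columns})
    if len(runs) < 2:
        raise DesignError("need at least 2 runs per subject")
    diffs = np.column_stack(
        [wide[(r, "high")].to_numpy() - wide[(r, "low")].to_numpy() for r in runs]
    )
    if np.isnan(diffs).any():
        raise DesignError("unbalanced runs across subjects")
    n, k = diffs.shape
    grand = diffs.mean()
    ss_runs = n * np.sum((diffs.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((diffs.mean(axis=1) - grand) ** 2)
    ss_err = np.sum((diffs - grand) ** 2) - ss_runs - ss_subj
    df_num, df_den = k - 1, (k - 1) * (n - 1)
    ms_err = ss_err / df_den
    F = _f_ratio(ss_runs / df_num, ms_err, scale=float(np.abs(diffs).max()) ** 2)
    p = float(stats.f.sf(F, df_num, df_den)) if np.isfinite(F) else 0.0
    omega = _partial_omega_squared(ss_runs, ms_err, df_num, df_den)
    return AnovaEffect("run", F, df_num, df_den, p, omega)


# ---------------------------------------------------------------------------
# Bayesian t-test with informed half-normal prior

def derive_prior_scale(group_psc: float, fraction: float) -> float:
    """Prior scale from a group localizer PSC and a scaling fraction."""
    if group_psc <= 0:
        raise DesignError(f"group_psc must be > 0, got {group_psc}")
    if not 0 < fraction <= 1:
        raise DesignError(f"fraction must be in (0, 1], got {fraction}")
    return group_psc * fraction


def informed_bayes_t(
    t: float, n: int, prior_scale: float, side: str = "greater"
) -> BayesResult:
    """Bayes factor for a paired/one-sample t-test with a half-normal prior.

    The alternative places a half-normal prior (scale ``prior_scale``,
    truncated to the hypothesized direction) on the standardized effect
    size delta; the marginal likelihood integrates the noncentral-t density
    with noncentrality delta * sqrt(n) over that prior.  ``side='two'``
    uses the untruncated normal.  Returns the Bayes factor in favour of the
    directed alternative over the point null.
    """
    if n < 2:
        raise DesignError(f"n must be >= 2, got {n}")
    if prior_scale <= 0:
        raise DesignError(f"prior_scale must be > 0, got {prior_scale}")
    if side not in ("greater", "less", "two"):
        raise DesignError(f"unknown side {side!r}")
    df = n - 1
    sqn = np.sqrt(n)

    # integrate over u = |delta|, with the prior direction folded into t's sign
    t_eff = -t if side == "less" else t

    def integrand(u: float) -> float:
        like = stats.nct.pdf(t_eff, df, u * sqn)
        if side == "two":
            like = 0.5 * (like + stats.nct.pdf(t_eff, df, -u * sqn))
        return like * 2.0 * stats.norm.pdf(u, 0.0, prior_scale)

    # split at the likelihood peak so quad resolves the mass
    peak = max(abs(t_eff) / sqn, prior_scale)
    num = 0.0
    for a, b in ((0.0, peak), (peak, np.inf)):
        val, err = integrate.quad(integrand, a, b, epsabs=0.0, epsrel=1e-9, limit=200)
        num += val
    den = stats.t.pdf(t_eff, df)
    if not np.isfinite(num) or num <= 0:
        raise DataError(f"Bayes factor integration failed (numerator {num})")
    return BayesResult(bf=float(num / den), prior_scale=prior_scale, side=side,
                       t_input=t, n_input=n)


# ---------------------------------------------------------------------------
# physiological confound analysis

def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise DesignError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_adjust(p_values: np.ndarray) -> np.ndarray:
    """Bonferroni-adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise DesignError("p-values must lie in [0, 1]")
    return multipletests(p, method="bonferroni")[1]


def physio_task_correlation(
    trace_values: np.ndarray, design: RunDesign, hrf: np.ndarray
) -> float:
    """Pearson r between the convolved physiological trace and task predictor.

    The trace is demeaned before convolution (its physiological mean level
    carries no task information and would otherwise leak an onset ramp into
    the correlation).  Returns NaN (with a warning) for a constant trace.
    """
    trace_values = np.asarray(trace_values, float)
    conv = convolve_blocks(trace_values - trace_values.mean(), hrf)
    pred = task_regressor(design, hrf)
    if np.std(conv) == 0 or np.std(pred) == 0:
        warnings.warn("constant trace or predictor: correlation undefined", stacklevel=2)
        return np.nan
    return float(np.corrcoef(conv, pred)[0, 1])


def physio_task_analysis(
    records: pd.DataFrame,
    design: RunDesign,
    hrf: np.ndarray,
    side: str = "two",
    prior_scale: float | None = None,
    corrector: str = "fdr",
) -> list[PhysioCorrResult]:
    """Group physiological-confound analysis.

    ``records`` has one row per run with columns ``subject``, ``region``
    (the run's NF target region), ``kind`` and ``values`` (per-TR samples).
    Per run: Pearson r of the convolved trace against the task predictor,
    Fisher z transform; per subject: mean z across runs; per (kind, region):
    one-sample t-test of the subject z values against zero, Cohen's d, and
    multiple-comparison correction across all kind x region tests
    (``corrector``: 'fdr' for Benjamini-Hochberg, 'bonferroni').
    ``prior_scale`` additionally computes an informed Bayes factor.
    """
    if corrector not in ("fdr", "bonferroni"):
        raise DesignError(f"unknown corrector {corrector!r}")
    rows = []
    for (kind, region), grp in records.groupby(["kind", "region"]):
        z_by_subject = []
        for _, subj_grp in grp.groupby("subject"):
            zs = []
            for values in subj_grp["values"]:
                r = physio_task_correlation(values, design, hrf)
                if np.isfinite(r):
                    zs.append(np.arctanh(r))
            if zs:
                z_by_subject.append(float(np.mean(zs)))
        z = np.array(z_by_subject)
        res = one_sample_t(z, side=side)
        bf = None
        if prior_scale is not None:
            bf = informed_bayes_t(res.t, len(z), prior_scale, side=side).bf
        rows.append(
            dict(kind=kind, region=region, z=z, res=res, bf=bf, n=len(z))
        )
    adjust = fdr_adjust if corrector == "fdr" else bonferroni_adjust
    adj = adjust([r["res"].p for r in rows])
    return [
        PhysioCorrResult(
            kind=r["kind"],
            region=r["region"],
            z_mean=float(r["z"].mean()),
            z_sem=float(r["z"].std(ddof=1) / np.sqrt(r["n"])),
            t=r["res"].t,
            df=r["res"].df,
            p=r["res"].p,
            p_fdr=float(pf),
            d=r["res"].d,
            n=r["n"],
            bf=r["bf"],
        )
        for r, pf in zip(rows, adj)
    ]
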