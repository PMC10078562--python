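"""Repeated-measures statistics for the cohort outcome tables.

Implements the analysis layout of a two-factor fully-within design:
subjects are the random blocking factor, the factors are inhalation type
(AIR vs CO2) and inhalation time, and each effect is tested against its
own effect-by-subject interaction.  Sphericity violations are handled by
the Greenhouse-Geisser correction (epsilon from the covariance of the
orthonormalised contrasts, applied when a factor has more than two
levels); effect sizes are partial eta squared; follow-up is
Bonferroni-corrected pairwise paired t tests.  Change-score association
is Pearson correlation with Evans-band interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst
from scipy.linalg import helmert

from .core import DataError, DegenerateInputError, DesignError

EVANS_BANDS = (
    (0.20, "very weak"),
    (0.40, "weak"),
    (0.60, "moderate"),
    (0.80, "strong"),
    (1.0 + 1e-12, "very strong"),
)


def evans_band(r: float) -> str:
    """Evans (1996) verbal label for a correlation magnitude."""
    a = abs(r)
    if a > 1 + 1e-9:
        raise ValueError("correlation magnitude above 1")
    for cut, label in EVANS_BANDS:
        if a < cut:
            return label
    return "very strong"


@dataclass(frozen=True)
class PairwiseComparison:
    level_a: str
    level_b: str
    mean_difference: float
    p_raw: float
    p_bonferroni: float
    n: int


@dataclass(frozen=True)
class EffectResult:
    """One within-subject effect of the two-way RM ANOVA."""

    effect: str
    ss_effect: float
    ss_error: float
    df1: int
    df2: int
    epsilon_gg: float
    df1_corr: float
    df2_corr: float
    F: float
    p: float           # raw degrees of freedom
    p_gg: float        # Greenhouse-Geisser corrected degrees of freedom
    eta_p2: float


@dataclass(frozen=True)
class AnovaResult:
    outcome: str
    effects: dict[str, EffectResult]
    pairwise: dict[str, list[PairwiseComparison]] = field(default_factory=dict)
    level_names: dict[str, tuple[str, ...]] = field(default_factory=dict)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float  # one-tailed, in the direction of the observed association
    band: str


# ---------------------------------------------------------------------------
# outlier screening and aggregation


def screen_outliers(
    values: pd.Series | dict[str, float], z_cut: float = 2.5
) -> tuple[list[str], list[str]]:
    """Single-pass outlier screen on per-subject values.

    A subject is removed when its value deviates from the sample mean by
    strictly more than ``z_cut`` sample standard deviations (ddof=1).  No
    re-screening after removal.  A zero-variance sample removes nobody.
    """
    series = pd.Series(values, dtype=float)
    if len(series) < 3:
        raise DataError("outlier screening needs at least 3 subjects")
    sd = series.std(ddof=1)
    if sd == 0:
        return list(series.index), []
    z = (series - series.mean()).abs() / sd
    removed = list(series.index[z > z_cut])
    retained = list(series.index[z <= z_cut])
    return retained, removed


def aggregate_trials(per_trial: pd.DataFrame) -> pd.DataFrame:
    """Average trial repetitions into one value per design cell.

    Input: long table with columns ``subject, inhalation_type,
    inhalation_time, outcome, value`` (one row per repetition).  Output:
    cohort table with the repetition mean and an ``n_reps`` count per
    (subject, type, time, outcome) cell.
    """
    keys = ["subject", "inhalation_type", "inhalation_time", "outcome"]
    missing = [c for c in keys + ["value"] if c not in per_trial.columns]
    if missing:
        raise DataError(f"per-trial table missing columns {missing}")
    grouped = per_trial.groupby(keys, sort=True)["value"]
    out = grouped.mean().reset_index()
    out["n_reps"] = grouped.count().to_numpy()
    # every (subject, type, time) combination must exist for each outcome
    for outcome, sub in out.groupby("outcome"):
        subjects = sub["subject"].unique()
        types = sub["inhalation_type"].unique()
        times = sub["inhalation_time"].unique()
        expected = len(subjects) * len(types) * len(times)
        if len(sub) != expected:
            have = {tuple(r) for r in sub[keys[:3]].itertuples(index=False)}
            missing_cells = [
                (s, a, b)
                for s in subjects
                for a in types
                for b in times
                if (s, a, b) not in have
            ]
            raise DataError(f"outcome {outcome!r}: missing cells {missing_cells}")
    return out


# ---------------------------------------------------------------------------
# Greenhouse-Geisser and the ANOVA core


def greenhouse_geisser_epsilon(cell_matrix: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon of a subjects-by-levels value matrix.

    Computed from the covariance of the ``k-1`` orthonormalised contrasts
    and clipped to ``[1/(k-1), 1]``.  ``k = 2`` gives exactly 1 (a single
    contrast cannot violate sphericity).
    """
    y = np.asarray(cell_matrix, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise DataError("cell matrix must be subjects x (>=2 levels)")
    k = y.shape[1]
    if k == 2:
        return 1.0
    c = helmert(k, full=False)  # (k-1, k), orthonormal rows
    s = np.cov(y, rowvar=False, ddof=1)
    m = c @ s @ c.T
    trace = np.trace(m)
    denom = (k - 1) * np.trace(m @ m)
    lower = 1.0 / (k - 1)
    if denom <= 0:
        return lower
    return float(np.clip(trace**2 / denom, lower, 1.0))


def _effect_epsilon(cells: np.ndarray, effect: str) -> float:
    """Epsilon for a main effect or the interaction of Y[s, a, b]."""
    n, a, b = cells.shape
    if effect == "type":
        mat = cells.mean(axis=2)
    elif effect == "time":
        mat = cells.mean(axis=1)
    elif effect == "type:time":
        if a < 2 or b < 2:
            return 1.0
        ca = helmert(a, full=False)
        cb = helmert(b, full=False)
        c = np.kron(ca, cb)  # ((a-1)(b-1), a*b), orthonormal rows
        flat = cells.reshape(n, a * b)
        s = np.cov(flat, rowvar=False, ddof=1)
        m = c @ s @ c.T
        df = (a - 1) * (b - 1)
        lower = 1.0 / df
        denom = df * np.trace(m @ m)
        if denom <= 0:
            return lower
        return float(np.clip(np.trace(m) ** 2 / denom, lower, 1.0))
    else:
        raise DesignError(f"unknown effect {effect!r}")
    if mat.shape[1] == 1:
        return 1.0
    return greenhouse_geisser_epsilon(mat)


def partial_eta_squared(F: float, df1: float, df2: float) -> float:
    """Partial eta squared from an F statistic: F df1 / (F df1 + df2)."""
    if F < 0 or df1 <= 0 or df2 <= 0:
        raise ValueError("need F >= 0 and positive degrees of freedom")
    return float(F * df1 / (F * df1 + df2))


def rm_anova_cells(cells: np.ndarray, effect_names: tuple[str, str] = ("type", "time")) -> dict[str, EffectResult]:
    """Two-way fully-within ANOVA on a ``subjects x a x b`` cell array.

    Each effect is tested against its own interaction with subjects.
    Returns raw and Greenhouse-Geisser-corrected results per effect; the
    correction is substantive only for factors with more than 2 levels
    (epsilon is exactly 1 at ``k = 2``).
    """
    y = np.asarray(cells, dtype=float)
    if y.ndim != 3:
        raise DataError("cells must be a subjects x a x b array")
    n, a, b = y.shape
    if n < 2 or a < 2 or b < 2:
        raise DataError("need >= 2 subjects and >= 2 levels per factor")
    if not np.isfinite(y).all():
        raise DataError("cell values must be finite")

    grand = y.mean()
    s_m = y.mean(axis=(1, 2))
    a_m = y.mean(axis=(0, 2))
    b_m = y.mean(axis=(0, 1))
    sa_m = y.mean(axis=2)
    sb_m = y.mean(axis=1)
    ab_m = y.mean(axis=0)

    ss_a = float(b * n * np.sum((a_m - grand) ** 2))
    ss_b = float(a * n * np.sum((b_m - grand) ** 2))
    ss_as = float(b * np.sum((sa_m - s_m[:, None] - a_m[None, :] + grand) ** 2))
    ss_bs = float(a * np.sum((sb_m - s_m[:, None] - b_m[None, :] + grand) ** 2))
    ss_ab = float(n * np.sum((ab_m - a_m[:, None] - b_m[None, :] + grand) ** 2))
    resid = (
        y
        - sa_m[:, :, None]
        - sb_m[:, None, :]
        - ab_m[None, :, :]
        + s_m[:, None, None]
        + a_m[None, :, None]
        + b_m[None, None, :]
        - grand
    )
    ss_abs = float(np.sum(resid**2))

    table = {
        effect_names[0]: (ss_a, ss_as, a - 1, (a - 1) * (n - 1), "type"),
        effect_names[1]: (ss_b, ss_bs, b - 1, (b - 1) * (n - 1), "time"),
        f"{effect_names[0]}:{effect_names[1]}": (
            ss_ab, ss_abs, (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1), "type:time",
        ),
    }
    out: dict[str, EffectResult] = {}
    for name, (ss_e, ss_err, df1, df2, eff_kind) in table.items():
        if ss_err <= 0:
            if ss_e == 0:
                f_val, p, p_gg, eps = 0.0, 1.0, 1.0, 1.0
                out[name] = EffectResult(name, ss_e, ss_err, df1, df2, eps,
                                         df1, df2, f_val, p, p_gg,
                                         0.0)
                continue
            raise DegenerateInputError(f"zero error variance for effect {name!r}")
        ms_e = ss_e / df1
        ms_err = ss_err / df2
        f_val = ms_e / ms_err
        eps = _effect_epsilon(y, eff_kind)
        df1_c, df2_c = df1 * eps, df2 * eps
        p = float(sst.f.sf(f_val, df1, df2))
        p_gg = float(sst.f.sf(f_val, df1_c, df2_c))
        out[name] = EffectResult(
            effect=name,
            ss_effect=ss_e,
            ss_error=ss_err,
            df1=df1,
            df2=df2,
            epsilon_gg=eps,
            df1_corr=df1_c,
            df2_corr=df2_c,
            F=float(f_val),
            p=p,
            p_gg=p_gg,
            eta_p2=partial_eta_squared(f_val, df1, df2) if f_val > 0 else 0.0,
        )
    return out


def _pivot_cells(
    table: pd.DataFrame, outcome: str
) -> tuple[np.ndarray, tuple[str, ...], tuple[str, ...], tuple[str, ...]]:
    """Cohort table -> Y[s, a, b] cell array with level orderings preserved."""
    sub = table[table["outcome"] == outcome] if "outcome" in table.columns else table
    if sub.empty:
        raise DataError(f"no rows for outcome {outcome!r}")
    subjects = tuple(dict.fromkeys(sub["subject"]))
    types = tuple(dict.fromkeys(sub["inhalation_type"]))
    times = tuple(dict.fromkeys(sub["inhalation_time"]))
    pivot = sub.pivot_table(
        index="subject", columns=["inhalation_type", "inhalation_time"],
        values="value", aggfunc="mean", sort=False,
    )
    expected = [(a, b) for a in types for b in times]
    missing = [c for c in expected if c not in pivot.columns]
    if missing or pivot.isna().any().any():
        raise DataError(f"outcome {outcome!r}: incomplete design, missing {missing}")
    pivot = pivot.reindex(index=list(subjects), columns=expected)
    cells = pivot.to_numpy().reshape(len(subjects), len(types), len(times))
    return cells, subjects, types, times


def bonferroni_pairwise(
    cells: np.ndarray,
    types: tuple[str, ...],
    times: tuple[str, ...],
    effect: str,
) -> list[PairwiseComparison]:
    """Bonferroni-corrected paired comparisons for one effect family.

    Main effects compare marginal subject means between level pairs
    (family size = number of level pairs).  The interaction family
    compares the two inhalation types at each time level (family size =
    number of time levels).
    """
    comparisons: list[PairwiseComparison] = []
    if effect == "type":
        levels, mat = types, cells.mean(axis=2)
    elif effect == "time":
        levels, mat = times, cells.mean(axis=1)
    elif effect == "type:time":
        if len(types) != 2:
            raise DesignError("interaction family assumes 2 inhalation types")
        pairs = []
        for j, tp in enumerate(times):
            diff = cells[:, 0, j] - cells[:, 1, j]
            pairs.append(((f"{types[0]}@{tp}", f"{types[1]}@{tp}"), diff))
        m = len(pairs)
        for (la, lb), diff in pairs:
            t, p2 = sst.ttest_1samp(diff, 0.0)
            comparisons.append(
                PairwiseComparison(la, lb, float(diff.mean()), float(p2),
                                   float(min(1.0, m * p2)), len(diff))
            )
        return comparisons
    else:
        raise DesignError(f"unknown effect {effect!r}")
    idx_pairs = [(i, j) for i in range(len(levels)) for j in range(i + 1, len(levels))]
    m = len(idx_pairs)
    for i, j in idx_pairs:
        diff = mat[:, i] - mat[:, j]
        t, p2 = sst.ttest_rel(mat[:, i], mat[:, j])
        comparisons.append(
            PairwiseComparison(levels[i], levels[j], float(diff.mean()),
                               float(p2), float(min(1.0, m * p2)), len(diff))
        )
    return comparisons


def rm_anova_2way(
    table: pd.DataFrame, outcome: str, alpha: float = 0.05
) -> AnovaResult:
    """Two-way repeated-measures ANOVA on one outcome of a cohort table.

    Factors: inhalation type and inhalation time, both within subjects.
    Pairwise Bonferroni families are computed for every significant
    effect (raw-df p below ``alpha``).
    """
    cells, subjects, types, times = _pivot_cells(table, outcome)
    effects = rm_anova_cells(cells)
    pairwise: dict[str, list[PairwiseComparison]] = {}
    for name, eff in effects.items():
        kind = "type:time" if ":" in name else name
        if eff.p < alpha:
            pairwise[name] = bonferroni_pairwise(cells, types, times, kind)
    return AnovaResult(
        outcome=outcome,
        effects=effects,
        pairwise=pairwise,
        level_names={"type": types, "time": times, "subject": subjects},
    )


def change_correlation(
    x_changes: np.ndarray, y_changes: np.ndarray
) -> CorrelationResult:
    """Pearson correlation of paired change scores with Evans banding.

    ``p`` is one-tailed in the direction of the observed association
    (half the two-tailed p of the exact t test on r).
    """
    x = np.asarray(x_changes, dtype=float)
    y = np.asarray(y_changes, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DataError("need >= 3 paired change scores of equal length")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("zero variance in a change-score vector")
    r, p_two = sst.pearsonr(x, y)
    return CorrelationResult(r=float(r), n=len(x), p=float(p_two / 2.0),
                             band=evans_band(float(r)))


def type_one_error_rates(
    n_cohorts: int = 2000,
    n_subjects: int = 10,
    n_a: int = 2,
    n_b: int = 4,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Empirical ANOVA rejection rates on null cohorts (calibration check)."""
    from .simulate import simulate_null_outcomes

    cohorts = simulate_null_outcomes(
        n_cohorts, n_subjects=n_subjects, n_a=n_a, n_b=n_b, seed=seed
    )
    counts = {"type": 0, "time": 0, "type:time": 0}
    for y in cohorts:
        effects = rm_anova_cells(y)
        for name, eff in effects.items():
            if eff.p < alpha:
                counts[name] += 1
    return {k: v / n_cohorts for k, v in counts.items()}
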