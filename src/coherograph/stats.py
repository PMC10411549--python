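"""Correlational validation of coherence scores against clinical outcomes.

Implements the validation layer as report generators: Pearson
correlations between scores and continuous outcomes, partial correlations
for longitudinal outcomes (controlling for their baseline expression, or
for psychopathology factors), and independent t-tests for categorical
covariates. The analyses are exploratory: p-values are descriptive and no
multiple-testing correction is applied (the rendered report says so).

Missing data: plain correlations use pairwise-complete observations;
partial correlations are listwise-complete across x, y and all controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

#: canonical clinical-table columns (any may be missing per participant)
CLINICAL_COLUMNS = {
    "participant_id": "join key",
    "panss_positive": "PANSS factor: positive symptoms",
    "panss_negative": "PANSS factor: negative symptoms",
    "panss_disorganized": "PANSS factor: disorganization",
    "panss_excitement": "PANSS factor: excitement",
    "panss_emotional_distress": "PANSS factor: emotional distress",
    "mini_icf_sum": "MINI-ICF sum score (functional disability)",
    "onset_age": "age at psychosis onset, years",
    "illness_duration": "duration of illness, years",
    "inpatient_days_2_5y_before": "days of inpatient care, 2.5 y before T1",
    "inpatient_days_0_5y_before": "days of inpatient care, 0.5 y before T1",
    "inpatient_days_0_5y_after": "days of inpatient care, 0.5 y after T1",
    "age": "age at T1, years",
    "sex": "sex (male/female)",
    "education_years": "education, years",
    "verbal_iq": "verbal IQ",
    "medication": "currently on antipsychotic medication (bool)",
}

PANSS_FACTORS = [
    "panss_positive",
    "panss_negative",
    "panss_disorganized",
    "panss_excitement",
    "panss_emotional_distress",
]

DEFAULT_OUTCOMES = [
    "illness_duration",
    "onset_age",
    "inpatient_days_2_5y_before",
    "inpatient_days_0_5y_before",
    "inpatient_days_0_5y_after",
    *PANSS_FACTORS,
    "mini_icf_sum",
]

_DAY_COLUMNS = [
    "inpatient_days_2_5y_before",
    "inpatient_days_0_5y_before",
    "inpatient_days_0_5y_after",
]


class StatsInputError(ValueError):
    """Degenerate statistical input (zero variance, too few cases, ...)."""


@dataclass
class CorrelationResult:
    variable_x: str
    variable_y: str
    r: float
    n: int
    p: float
    controls: list[str] = field(default_factory=list)


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def pearson(x, y, name_x: str = "x", name_y: str = "y") -> CorrelationResult:
    """Product-moment correlation on pairwise-complete observations.

    Two-sided p from the t transform with n-2 df, reported descriptively.
    Constant input raises :class:`StatsInputError` naming the variable.
    """
    xc, yc = _pairwise_complete(x, y)
    n = len(xc)
    if n < 3:
        raise StatsInputError(f"pearson({name_x}, {name_y}): need n >= 3, got {n}")
    for name, arr in ((name_x, xc), (name_y, yc)):
        if np.ptp(arr) == 0.0:
            raise StatsInputError(f"variable {name!r} is constant; correlation undefined")
    res = sps.pearsonr(xc, yc)
    return CorrelationResult(name_x, name_y, float(res.statistic), n, float(res.pvalue))


def _residualize(y: np.ndarray, controls: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(y)), controls])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise StatsInputError("controls are collinear (rank-deficient design matrix)")
    return y - design @ beta


def partial_correlation(
    x, y, controls: list, name_x: str = "x", name_y: str = "y",
    control_names: list[str] | None = None,
) -> CorrelationResult:
    """Correlation of x and y after removing the linear effect of controls.

    Both variables are residualized on the controls (least squares with
    intercept); Pearson r of the residuals, p with n-2-k df. Observations
    are listwise-complete across x, y and all controls. With an empty
    control list this reduces exactly to :func:`pearson`.
    """
    if not controls:
        return pearson(x, y, name_x, name_y)
    control_names = control_names or [f"c{i}" for i in range(len(controls))]
    cols = [np.asarray(x, np.float64), np.asarray(y, np.float64)] + [
        np.asarray(c, np.float64) for c in controls
    ]
    mat = np.column_stack(cols)
    mat = mat[np.all(np.isfinite(mat), axis=1)]
    n, k = len(mat), len(controls)
    if n <= k + 2:
        raise StatsInputError(
            f"partial correlation needs n > k + 2 (n={n}, k={k} controls)"
        )
    rx = _residualize(mat[:, 0], mat[:, 2:])
    ry = _residualize(mat[:, 1], mat[:, 2:])
    for name, arr in ((name_x, rx), (name_y, ry)):
        if float(np.linalg.norm(arr)) == 0.0:
            raise StatsInputError(f"residuals of {name!r} are constant")
    r = float(np.dot(rx, ry) / (np.linalg.norm(rx) * np.linalg.norm(ry)))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return CorrelationResult(name_x, name_y, r, n, p, controls=list(control_names))


def independent_t_test(group_a, group_b, equal_var: bool = False) -> TTestResult:
    """Two-sample t-test for a mean difference.

    Welch's unequal-variance form by default; ``equal_var=True`` gives the
    pooled-variance (Student) form. Each group needs n >= 2 and, pooled,
    nonzero within-group variance.
    """
    a = np.asarray(group_a, np.float64)
    b = np.asarray(group_b, np.float64)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise StatsInputError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        raise StatsInputError("both groups have zero variance; t undefined")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=len(a),
        n_b=len(b),
    )


# ---------------------------------------------------------------------------
# Report generation


@dataclass
class ReportBundle:
    """Long-format tables; every correlation row carries r, n, p."""

    correlations: pd.DataFrame  # score x (score + outcome) matrix rows
    partial_longitudinal: pd.DataFrame
    t_tests: pd.DataFrame
    controls_screen: pd.DataFrame
    join_report: dict


def score_columns(scores: pd.DataFrame) -> list[str]:
    return [c for c in scores.columns if c.startswith(("local_", "global_"))]


def _corr_rows(df: pd.DataFrame, variables: list[str], score_cols: list[str]) -> pd.DataFrame:
    rows = []
    for var in variables:
        for sc in score_cols:
            if var == sc:
                rows.append(dict(variable=var, score=sc, r=1.0, n=int(df[sc].notna().sum()), p=0.0))
                continue
            x = df[var].to_numpy(np.float64)
            y = df[sc].to_numpy(np.float64)
            try:
                res = pearson(x, y, var, sc)
                rows.append(dict(variable=var, score=sc, r=res.r, n=res.n, p=res.p))
            except StatsInputError:
                n = int(np.sum(np.isfinite(x) & np.isfinite(y)))
                rows.append(dict(variable=var, score=sc, r=np.nan, n=n, p=np.nan))
    return pd.DataFrame(rows)


def validation_report(
    scores: pd.DataFrame,
    clinical: pd.DataFrame,
    outcomes: list[str] | None = None,
    longitudinal_pairs: list[tuple[str, str]] | None = None,
    categorical: list[str] | None = None,
    control_vars: list[str] | None = None,
    equal_var: bool = False,
) -> ReportBundle:
    """Join scores to the clinical table and emit the validation tables.

    (a) correlation matrix: scores x scores and outcomes x scores;
    (b) partial correlations for (T2 outcome, T1 baseline) pairs,
        controlling each T2 outcome for its T1 expression;
    (c) t-tests of scores across categorical covariates (sex, medication);
    (d) control-variable screen (age, education, verbal IQ, transcript
        length in words).
    Join mismatches are reported in ``join_report``, never silently
    dropped from accounting.
    """
    outcomes = DEFAULT_OUTCOMES if outcomes is None else outcomes
    categorical = ["sex", "medication"] if categorical is None else categorical
    if control_vars is None:
        control_vars = ["age", "education_years", "verbal_iq", "word_count"]
    if longitudinal_pairs is None:
        longitudinal_pairs = [
            (c + "_t2", c) for c in outcomes if c + "_t2" in clinical.columns
        ]

    merged = scores.merge(clinical, on="participant_id", how="inner")
    join_report = {
        "n_joined": len(merged),
        "scores_only": sorted(
            set(scores["participant_id"]) - set(clinical["participant_id"])
        ),
        "clinical_only": sorted(
            set(clinical["participant_id"]) - set(scores["participant_id"])
        ),
    }
    sc_cols = score_columns(scores)
    outcomes = [o for o in outcomes if o in merged.columns]

    correlations = _corr_rows(merged, sc_cols + outcomes, sc_cols)

    partial_rows = []
    for t2_col, t1_col in longitudinal_pairs:
        for sc in sc_cols:
            try:
                res = partial_correlation(
                    merged[sc], merged[t2_col], [merged[t1_col]],
                    name_x=sc, name_y=t2_col, control_names=[t1_col],
                )
                partial_rows.append(
                    dict(outcome=t2_col, score=sc, r=res.r, n=res.n, p=res.p,
                         controls=";".join(res.controls))
                )
            except StatsInputError:
                partial_rows.append(
                    dict(outcome=t2_col, score=sc, r=np.nan, n=0, p=np.nan,
                         controls=t1_col)
                )
    partial_longitudinal = pd.DataFrame(
        partial_rows, columns=["outcome", "score", "r", "n", "p", "controls"]
    )

    tt_rows = []
    for var in categorical:
        if var not in merged.columns:
            continue
        levels = sorted(merged[var].dropna().unique(), key=str)
        if len(levels) != 2:
            continue
        for sc in sc_cols:
            a = merged.loc[merged[var] == levels[0], sc]
            b = merged.loc[merged[var] == levels[1], sc]
            try:
                res = independent_t_test(a, b, equal_var=equal_var)
                tt_rows.append(
                    dict(variable=var, score=sc, group_a=str(levels[0]),
                         group_b=str(levels[1]), t=res.t, df=res.df, p=res.p,
                         mean_a=res.mean_a, mean_b=res.mean_b,
                         n_a=res.n_a, n_b=res.n_b)
                )
            except StatsInputError:
                tt_rows.append(
                    dict(variable=var, score=sc, group_a=str(levels[0]),
                         group_b=str(levels[1]), t=np.nan, df=np.nan, p=np.nan,
                         mean_a=np.nan, mean_b=np.nan, n_a=len(a.dropna()),
                         n_b=len(b.dropna()))
                )
    t_tests = pd.DataFrame(
        tt_rows,
        columns=["variable", "score", "group_a", "group_b", "t", "df", "p",
                 "mean_a", "mean_b", "n_a", "n_b"],
    )

    controls_present = [c for c in control_vars if c in merged.columns]
    controls_screen = _corr_rows(merged, controls_present, sc_cols)

    return ReportBundle(
        correlations=correlations,
        partial_longitudinal=partial_longitudinal,
        t_tests=t_tests,
        controls_screen=controls_screen,
        join_report=join_report,
    )


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def render_report(bundle: ReportBundle, star_thresholds: tuple[float, float] = (0.05, 0.01)) -> str:
    """Plain-text rendering: correlation matrix with significance markers
    (* p<0.05, ** p<0.01 by default), then the remaining tables."""
    lines = [
        "Exploratory correlational analysis",
        "NOTE: p-values are descriptive; no correction for multiple testing",
        "is applied, and the number of output parameters is large — interpret",
        "significance markers with caution.",
        "",
    ]
    corr = bundle.correlations
    scores = list(dict.fromkeys(corr["score"]))
    width = max((len(v) for v in corr["variable"]), default=10) + 2
    lines.append(" " * width + "  ".join(f"{s:>22}" for s in scores))
    for var in dict.fromkeys(corr["variable"]):
        cells = []
        for sc in scores:
            row = corr[(corr["variable"] == var) & (corr["score"] == sc)]
            if row.empty or not np.isfinite(row["r"].iloc[0]):
                cells.append(f"{'NA':>22}")
            elif var == sc:
                cells.append(f"{'—':>22}")
            else:
                r, p, n = row["r"].iloc[0], row["p"].iloc[0], row["n"].iloc[0]
                cells.append(f"{r: .3f}{_stars(p):<2}(n={int(n)})".rjust(22))
        lines.append(f"{var:<{width}}" + "  ".join(cells))
    if not bundle.partial_longitudinal.empty:
        lines += ["", "Partial correlations (T1 scores vs T2 outcomes, controlling T1 outcome):"]
        for _, row in bundle.partial_longitudinal.iterrows():
            r_txt = "NA" if not np.isfinite(row["r"]) else f"{row['r']: .3f}{_stars(row['p'])}"
            lines.append(
                f"  {row['outcome']:<32} {row['score']:<24} r={r_txt} n={int(row['n'])}"
            )
    if not bundle.t_tests.empty:
        lines += ["", "Group differences (independent t-tests):"]
        for _, row in bundle.t_tests.iterrows():
            lines.append(
                f"  {row['variable']:<12} {row['score']:<24} "
                f"t={row['t']: .3f}{_stars(row['p'])} df={row['df']:.1f} "
                f"({row['group_a']}: {row['mean_a']:.3f}, {row['group_b']}: {row['mean_b']:.3f})"
            )
    return "\n".join(lines)


def read_clinical_table(path, panss_range: tuple[float, float] | None = None) -> pd.DataFrame:
    """Read a delimited clinical table (CSV/TSV by extension).

    Validates: participant_id present, day counts nonnegative, PANSS
    factor scores within ``panss_range`` when given.
    """
    import pathlib

    path = pathlib.Path(path)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    if "participant_id" not in df.columns:
        raise StatsInputError(f"{path}: clinical table lacks 'participant_id' column")
    df["participant_id"] = df["participant_id"].astype(str)
    for col in _DAY_COLUMNS:
        if col in df.columns and (df[col].dropna() < 0).any():
            raise StatsInputError(f"{path}: negative day count in column {col!r}")
    if panss_range is not None:
        lo, hi = panss_range
        for col in PANSS_FACTORS:
            if col in df.columns:
                bad = df[col].dropna()
                if ((bad < lo) | (bad > hi)).any():
                    raise StatsInputError(
                        f"{path}: {col!r} outside configured range [{lo}, {hi}]"
                    )
    return df
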