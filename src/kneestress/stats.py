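"""Study statistics: delta referencing, RM-ANOVA + Tukey, ICC, Pearson, power.

Every measure is referenced to the ACL-intact unloaded (d0) cell of the
same specimen: delta_x[status] = x[status] - x[intact, d0].  The six
condition x configuration cells are then compared per measure with a
one-way repeated-measures ANOVA (specimen as the repeated factor, the six
cells flattened into one within-subject factor) followed by a Tukey HSD
post-hoc on the cell means that reuses the ANOVA error mean square and its
degrees of freedom in the studentized-range statistic.  Significance is
judged at a deliberately strict threshold of p <= 0.01 per measure, with
no multiplicity correction across measures.

Two-reader agreement on the 2D measures uses ICC(2,1): two-way random
effects, single measures, absolute agreement.  The a-priori sample-size
computation inverts the power curve of a two-sample two-tailed t-test via
the noncentral t distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .errors import (
    DataError,
    DegenerateDataError,
    DesignError,
    ParameterError,
)
from .volume_io import CONDITIONS, CONFIGURATIONS

STANDARD_GRAVITY = 9.80665  # N per kilopond

#: long-format study-table columns; "reader" is optional
STUDY_COLUMNS = ("specimen", "condition", "configuration", "measure", "value")

_CELLS = [f"{cond}_{conf}" for cond in CONDITIONS for conf in CONFIGURATIONS]


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in STUDY_COLUMNS if c not in table.columns]
    if missing:
        raise DesignError(f"study table is missing columns {missing}")
    return table


# ---------------------------------------------------------------------------
# Delta referencing
# ---------------------------------------------------------------------------

def compute_deltas(table: pd.DataFrame, reference: str = "intact_d0") -> pd.DataFrame:
    """Reference each value against its specimen-matched reference cell.

    ``reference="intact_d0"`` subtracts the ACL-intact unloaded value (the
    study's primary referencing); ``reference="per_condition_d0"`` subtracts
    the same condition's unloaded value (intra-conditional referencing).
    The delta of a reference cell is identically zero.
    """
    table = _check_table(table)
    if reference not in ("intact_d0", "per_condition_d0"):
        raise ParameterError(f"unknown reference scheme {reference!r}")
    if "reader" in table.columns:
        table = table.assign(reader=table["reader"].fillna(""))
    keys = ["specimen", "measure"] + (["reader"] if "reader" in table.columns else [])

    ref_rows = table[table["configuration"] == "d0"]
    if reference == "intact_d0":
        ref_rows = ref_rows[ref_rows["condition"] == "intact"]
        ref = ref_rows.set_index(keys)["value"]
        join_keys = keys
    else:
        ref = ref_rows.set_index(keys + ["condition"])["value"]
        join_keys = keys + ["condition"]

    out = table.copy()
    idx = pd.MultiIndex.from_frame(out[join_keys])
    try:
        ref_values = ref.reindex(idx).to_numpy()
    except Exception as exc:  # non-unique reference cells
        raise DesignError(f"ambiguous reference cells: {exc}") from exc
    if np.isnan(ref_values).any():
        bad = out.loc[np.isnan(ref_values), "specimen"].unique().tolist()
        raise DesignError(f"missing reference cell for specimen(s) {bad}")
    out["value"] = out["value"].to_numpy() - ref_values
    return out


# ---------------------------------------------------------------------------
# RM-ANOVA + Tukey HSD
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    measure: str
    f_value: float
    p_value: float
    df_effect: float
    df_error: float
    ms_error: float
    n_subjects: int
    cell_means: dict[str, float]
    tukey: pd.DataFrame  # columns: cell_a, cell_b, mean_diff, q, p, significant
    threshold: float
    significant: bool = field(init=False)

    def __post_init__(self):
        self.significant = bool(self.p_value <= self.threshold)


def _pivot_cells(table: pd.DataFrame, measure: str) -> pd.DataFrame:
    rows = table[table["measure"] == measure]
    if rows.empty:
        raise DesignError(f"no rows for measure {measure!r}")
    if "reader" in rows.columns:
        rows = (rows.groupby(["specimen", "condition", "configuration"], as_index=False)
                ["value"].mean())  # pool readers
    rows = rows.assign(cell=rows["condition"] + "_" + rows["configuration"])
    wide = rows.pivot(index="specimen", columns="cell", values="value")
    missing_cells = [c for c in _CELLS if c not in wide.columns]
    if missing_cells or wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].tolist() if not missing_cells else "all"
        raise DesignError(
            f"incomplete six-cell design for measure {measure!r}: "
            f"missing cells {missing_cells or bad}")
    return wide[_CELLS]


def rm_anova_tukey(
    table: pd.DataFrame,
    measure: str,
    threshold: float = 0.01,
    sphericity_correction: bool = False,
    with_tukey: bool = True,
) -> AnovaResult:
    """One-way repeated-measures ANOVA over the six study cells + Tukey HSD.

    The within-subject factor is the flattened condition x configuration
    cell; Tukey pairwise p-values use the studentized-range distribution
    with the ANOVA error mean square and error degrees of freedom.
    ``with_tukey=False`` skips the pairwise table (for calibration loops
    that only need the omnibus p-value).
    """
    table = _check_table(table)
    wide = _pivot_cells(table, measure)
    values = wide.to_numpy(dtype=float)
    n, k = values.shape

    if np.allclose(values, values.flat[0]):
        # all-equal degenerate path: F is 0/0, report p = 1 and no pairs
        tukey = _tukey_table(wide.mean(axis=0), np.nan, np.nan, n, threshold, degenerate=True)
        return AnovaResult(measure=measure, f_value=float("nan"), p_value=1.0,
                           df_effect=float(k - 1), df_error=float((n - 1) * (k - 1)),
                           ms_error=0.0, n_subjects=n,
                           cell_means=wide.mean(axis=0).to_dict(),
                           tukey=tukey, threshold=threshold)
    if np.allclose(values.var(axis=0, ddof=0), 0.0):
        raise DegenerateDataError(f"measure {measure!r} has zero variance in every cell")

    long = wide.reset_index().melt(id_vars="specimen", var_name="cell", value_name="value")
    aov = pg.rm_anova(data=long, dv="value", within="cell", subject="specimen",
                      detailed=True, correction=sphericity_correction)
    row = aov.loc[aov["Source"] == "cell"].iloc[0]
    err = aov.loc[aov["Source"] == "Error"].iloc[0]
    p_col = next(c for c in ("p_unc", "p-unc") if c in aov.columns)
    if sphericity_correction:
        for gg in ("p_GG_corr", "p-GG-corr"):
            if gg in aov.columns and np.isfinite(row.get(gg, np.nan)):
                p_col = gg
                break
    p_value = float(row[p_col])
    ms_error = float(err["MS"])
    df_error = float(err["DF"])

    if with_tukey:
        tukey = _tukey_table(wide.mean(axis=0), ms_error, df_error, n, threshold)
    else:
        tukey = pd.DataFrame(columns=["cell_a", "cell_b", "mean_diff", "q", "p",
                                      "significant"])
    return AnovaResult(measure=measure, f_value=float(row["F"]), p_value=p_value,
                       df_effect=float(row["DF"]), df_error=df_error, ms_error=ms_error,
                       n_subjects=n, cell_means=wide.mean(axis=0).to_dict(),
                       tukey=tukey, threshold=threshold)


def _tukey_table(cell_means: pd.Series, ms_error: float, df_error: float,
                 n: int, threshold: float, degenerate: bool = False) -> pd.DataFrame:
    cells = list(cell_means.index)
    rows = []
    se = np.sqrt(ms_error / n) if not degenerate else np.nan
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            diff = float(cell_means.iloc[j] - cell_means.iloc[i])
            if degenerate or se == 0:
                q, p = float("nan"), 1.0
            else:
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, len(cells), df_error))
            rows.append({"cell_a": cells[i], "cell_b": cells[j], "mean_diff": diff,
                         "q": q, "p": p, "significant": bool(p <= threshold)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ICC, Pearson
# ---------------------------------------------------------------------------

def icc_two_readers(reader_a, reader_b) -> float:
    """ICC(2,1): two-way random effects, single measures, absolute agreement."""
    a = np.asarray(reader_a, dtype=float)
    b = np.asarray(reader_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError("reader arrays must be 1D and of equal length")
    if len(a) < 2:
        raise DataError("ICC requires at least 2 paired observations")
    data = pd.DataFrame({
        "target": np.tile(np.arange(len(a)), 2),
        "rater": np.repeat(["A", "B"], len(a)),
        "rating": np.concatenate([a, b]),
    })
    import warnings

    with warnings.catch_warnings():
        # identical readers give a zero residual mean square; the agreement
        # ICC itself is still well defined (1.0)
        warnings.simplefilter("ignore", RuntimeWarning)
        icc = pg.intraclass_corr(data=data, targets="target", raters="rater",
                                 ratings="rating")
    # absolute-agreement single-measures ICC: labeled ICC2 (Shrout & Fleiss)
    # or ICC(A,1) (McGraw & Wong) depending on the pingouin version
    sel = icc["Type"].isin(["ICC2", "ICC(A,1)"])
    return float(icc.loc[sel, "ICC"].iloc[0])


def pearson(values_a, values_b) -> float:
    """Sample Pearson correlation coefficient."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise DataError("Pearson correlation requires >= 3 equal-length paired values")
    if np.std(a) == 0 or np.std(b) == 0:
        raise DegenerateDataError("correlation undefined for zero-variance input")
    return float(sps.pearsonr(a, b)[0])


# ---------------------------------------------------------------------------
# Power / sample size, unit conversion
# ---------------------------------------------------------------------------

def two_sample_t_power(n_per_group: int, effect_size_d: float, alpha: float,
                       tails: str = "two") -> float:
    """Exact power of a two-sample t-test via the noncentral t distribution."""
    df = 2 * n_per_group - 2
    if df < 1:
        return 0.0
    nc = effect_size_d * np.sqrt(n_per_group / 2.0)
    if tails == "two":
        tcrit = sps.t.ppf(1 - alpha / 2, df)
        power = float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))
        if not np.isfinite(power):  # extreme noncentrality: normal limit
            power = float(sps.norm.sf(tcrit - nc) + sps.norm.cdf(-tcrit - nc))
        return power
    tcrit = sps.t.ppf(1 - alpha, df)
    power = float(sps.nct.sf(tcrit, df, nc))
    if not np.isfinite(power):
        power = float(sps.norm.sf(tcrit - nc))
    return power


def required_sample_size(power: float = 0.8, alpha: float = 0.05,
                         effect_size_d: float = 1.6, tails: str = "two",
                         max_n: int = 10000) -> int:
    """Smallest per-group n of a two-sample t-test achieving the target power."""
    if not 0 < power < 1 or not 0 < alpha < 1:
        raise ParameterError("power and alpha must lie in (0, 1)")
    if effect_size_d <= 0:
        raise ParameterError("effect size must be positive")
    if tails not in ("one", "two"):
        raise ParameterError("tails must be 'one' or 'two'")
    for n in range(2, max_n + 1):
        if two_sample_t_power(n, effect_size_d, alpha, tails) >= power:
            return n
    raise ParameterError(
        f"target power {power} unreachable for d={effect_size_d} within n <= {max_n}")


def kilopond_to_newton(kp: float) -> float:
    """Force of standard gravity on ``kp`` kilograms, in newtons."""
    if kp < 0:
        raise ParameterError("kiloponds must be non-negative")
    return kp * STANDARD_GRAVITY
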