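"""Cohort-level stratification, group comparisons and report tables.

Test selection mirrors common catheterization-laboratory practice:
normality is gated by the Shapiro-Wilk test (alpha 0.05, per group), which
chooses between Student's t-test and the Mann-Whitney U test for
independent samples, between the paired t-test and the Wilcoxon signed-rank
test for paired measurements, and between Pearson and Spearman correlation.
2x2 categorical tables use Fisher's exact test when any expected cell count
is below 5, chi-square otherwise. All tests are two-sided; p-values are
reported raw (no multiple-testing correction is applied, and the report
notes this).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateSignalError, DegenerateTableError, PairingError, ParameterError
from .hemodyn import HemoIndexSet
from .wia import WavePeakSet

NORMALITY_ALPHA = 0.05
MIN_EXPECTED_FOR_CHI2 = 5.0


@dataclass
class VesselResult:
    """Full per-vessel analysis output."""

    vessel_id: str
    pre: HemoIndexSet
    post: HemoIndexSet
    wia_rest_pre: WavePeakSet
    wia_hyp_pre: WavePeakSet
    wia_rest_post: WavePeakSet
    wia_hyp_post: WavePeakSet
    group: str  # computed from post indices only
    metadata: dict = field(default_factory=dict)


@dataclass
class ComparisonRow:
    """One statistical comparison with its gate decisions."""

    variable: str
    group_stats: dict  # name -> (n, mean, sd) or (n, count, pct)
    test: str
    p_value: float
    normality_p: dict  # name -> Shapiro-Wilk p (or None)
    flags: list = field(default_factory=list)


def _shapiro_p(x: np.ndarray) -> float:
    """Shapiro-Wilk p-value; degenerate (constant) samples count as
    non-normal with p = 0."""
    if np.ptp(x) == 0:
        return 0.0
    return float(stats.shapiro(x).pvalue)


def compare_independent(x, y, names: tuple = ("x", "y")) -> ComparisonRow:
    """Compare two independent samples with Shapiro-Wilk gating.

    Both samples normal (p >= 0.05) -> Student's (equal-variance) t-test;
    otherwise Mann-Whitney U. Two-sided.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ParameterError(
            f"need n >= 3 per group, got {len(x)} and {len(y)}"
        )
    px, py = _shapiro_p(x), _shapiro_p(y)
    flags = []
    if px >= NORMALITY_ALPHA and py >= NORMALITY_ALPHA:
        test = "student_t"
        if np.ptp(x) == 0 and np.ptp(y) == 0 and x.mean() == y.mean():
            p = 1.0
            flags.append("degenerate_variance")
        else:
            p = float(stats.ttest_ind(x, y, equal_var=True).pvalue)
    else:
        test = "mann_whitney"
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        p = float(res.pvalue)
    return ComparisonRow(
        variable="",
        group_stats={
            names[0]: (len(x), float(x.mean()), float(x.std(ddof=1))),
            names[1]: (len(y), float(y.mean()), float(y.std(ddof=1))),
        },
        test=test, p_value=p,
        normality_p={names[0]: px, names[1]: py},
        flags=flags,
    )


def compare_paired(pre, post) -> ComparisonRow:
    """Compare paired measurements with Shapiro-Wilk gating on differences.

    Normal differences -> paired Student's t-test; otherwise Wilcoxon
    signed-rank. Zero-variance differences are flagged: identical samples
    report p = 1, an exact constant shift reports p = 0.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if len(pre) != len(post):
        raise PairingError(
            f"paired samples must have equal length, got {len(pre)} and {len(post)}"
        )
    if len(pre) < 3:
        raise ParameterError(f"need n >= 3 pairs, got {len(pre)}")
    d = post - pre
    flags = []
    pd_norm = _shapiro_p(d)
    if np.ptp(d) <= 1e-12 * max(1.0, float(np.abs(d).max())):
        # differences constant to rounding: an exact shift (or no change)
        flags.append("degenerate_variance")
        test = "paired_t"
        p = 1.0 if abs(d.mean()) <= 1e-12 * max(1.0, float(np.abs(pre).max())) else 0.0
    elif pd_norm >= NORMALITY_ALPHA:
        test = "paired_t"
        p = float(stats.ttest_rel(post, pre).pvalue)
    else:
        test = "wilcoxon"
        p = float(stats.wilcoxon(post, pre).pvalue)
    return ComparisonRow(
        variable="",
        group_stats={
            "pre": (len(pre), float(pre.mean()), float(pre.std(ddof=1))),
            "post": (len(post), float(post.mean()), float(post.std(ddof=1))),
        },
        test=test, p_value=p,
        normality_p={"diff": pd_norm},
        flags=flags,
    )


def compare_categorical(table) -> ComparisonRow:
    """Compare a 2x2 contingency table.

    Fisher's exact test when any expected cell count is below 5, chi-square
    otherwise. Empty margins are degenerate.
    """
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ParameterError(f"expected a 2x2 table, got shape {table.shape}")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        if np.any(table != np.round(table)) or np.any(table < 0):
            raise ParameterError("table must contain nonnegative integer counts")
        table = table.astype(int)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise DegenerateTableError("contingency table has an empty margin")
    expected = np.outer(rows, cols) / table.sum()
    if np.any(expected < MIN_EXPECTED_FOR_CHI2):
        test = "fisher"
        p = float(stats.fisher_exact(table).pvalue)
    else:
        test = "chi_square"
        p = float(stats.chi2_contingency(table).pvalue)
    n = int(table.sum())
    return ComparisonRow(
        variable="",
        group_stats={
            "row0": (int(rows[0]), int(table[0, 0]),
                     100.0 * table[0, 0] / rows[0]),
            "row1": (int(rows[1]), int(table[1, 0]),
                     100.0 * table[1, 0] / rows[1]),
        },
        test=test, p_value=p, normality_p={},
        flags=[f"n={n}"],
    )


def correlate(x, y, force_method: str | None = None) -> tuple:
    """Correlation with normality-gated method choice.

    Pearson when both samples pass Shapiro-Wilk, Spearman otherwise; the
    method can be forced. Returns ``(coefficient, p_value, method)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise PairingError("samples must have equal length")
    if len(x) < 3:
        raise ParameterError(f"need n >= 3, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateSignalError("zero variance in a correlated sample")
    if force_method is None:
        px, py = _shapiro_p(x), _shapiro_p(y)
        method = ("pearson" if px >= NORMALITY_ALPHA and py >= NORMALITY_ALPHA
                  else "spearman")
    else:
        if force_method not in ("pearson", "spearman"):
            raise ParameterError(f"unknown method {force_method!r}")
        method = force_method
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        r, p = stats.spearmanr(x, y)
    return float(r), float(p), method


# ---------------------------------------------------------------------------
# Study-shaped report tables
# ---------------------------------------------------------------------------

_INDEX_VARS = ("ffr", "cfvr", "hsr", "bmr", "hmr", "bapv", "hapv")
_LESION_VARS = _INDEX_VARS + ("mrr", "rrr")
_WIA_VARS = ("fcw_peak", "bcw_peak", "few_peak", "bew_peak", "tbew_peak",
             "accel_energy_fraction")


@dataclass
class CohortReport:
    """Output of :func:`build_tables`."""

    paired_pre_post: pd.DataFrame  # Table-2 shape
    lesion_groups: pd.DataFrame | None  # Table-3 shape (None if not computable)
    wia_groups: pd.DataFrame | None  # Table-4 shape
    correlations: pd.DataFrame
    notes: list


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[~np.isnan(arr)]


def _group_row(variable, xc, xd) -> dict:
    xc, xd = _clean(xc), _clean(xd)
    if len(xc) < 3 or len(xd) < 3:
        return {
            "variable": variable,
            "concordant_n": len(xc), "discordant_n": len(xd),
            "concordant_mean": float(np.mean(xc)) if len(xc) else np.nan,
            "concordant_sd": float(np.std(xc, ddof=1)) if len(xc) > 1 else np.nan,
            "discordant_mean": float(np.mean(xd)) if len(xd) else np.nan,
            "discordant_sd": float(np.std(xd, ddof=1)) if len(xd) > 1 else np.nan,
            "test": "not_computable", "p_value": np.nan,
        }
    row = compare_independent(xc, xd, names=("concordant", "discordant"))
    return {
        "variable": variable,
        "concordant_n": len(xc), "discordant_n": len(xd),
        "concordant_mean": row.group_stats["concordant"][1],
        "concordant_sd": row.group_stats["concordant"][2],
        "discordant_mean": row.group_stats["discordant"][1],
        "discordant_sd": row.group_stats["discordant"][2],
        "test": row.test, "p_value": row.p_value,
    }


def build_tables(results: list) -> CohortReport:
    """Build the study-level report from per-vessel results.

    Emits (a) a paired pre/post-PCI table of the conventional indices over
    all vessels, (b) a concordant-vs-discordant lesion-level table
    (post-PCI stratification, including MRR and RRR), (c) the
    rest/hyperemia x pre/post net-WI peak table with tBEW and the
    accelerating-energy fraction, and (d) the hyperemic translesional
    pressure-drop correlation block. Output is order-invariant in the input
    list; empty strata are reported as not-computable and the run continues.

    p-values are raw (unadjusted); vessels, not patients, are the unit of
    analysis.
    """
    if len(results) < 2:
        raise ParameterError("need at least 2 vessels to build cohort tables")
    results = sorted(results, key=lambda r: r.vessel_id)
    notes = ["p-values are raw (no multiple-testing correction)",
             "vessels treated as independent observations"]

    # (a) paired pre/post over all vessels
    rows_a = []
    for var in _INDEX_VARS:
        pre = np.array([getattr(r.pre, var) for r in results])
        post = np.array([getattr(r.post, var) for r in results])
        row = compare_paired(pre, post)
        rows_a.append({
            "variable": var,
            "n": len(results),
            "pre_mean": row.group_stats["pre"][1],
            "pre_sd": row.group_stats["pre"][2],
            "post_mean": row.group_stats["post"][1],
            "post_sd": row.group_stats["post"][2],
            "test": row.test, "p_value": row.p_value,
        })
    table_a = pd.DataFrame(rows_a)

    conc = [r for r in results if r.group == "concordant"]
    disc = [r for r in results if r.group == "discordant"]
    n_abn = sum(1 for r in results if r.group == "abnormal_hsr")
    if n_abn:
        notes.append(f"{n_abn} vessel(s) with abnormal post-PCI hSR excluded "
                     "from group tables")

    # (b) lesion-level concordant vs discordant
    if len(conc) >= 2 and len(disc) >= 2:
        rows_b = []
        for phase in ("pre", "post"):
            for var in _LESION_VARS:
                xc = [getattr(getattr(r, phase), var) for r in conc]
                xd = [getattr(getattr(r, phase), var) for r in disc]
                rows_b.append(_group_row(f"{var}_{phase}", xc, xd))
        table_b = pd.DataFrame(rows_b)
    else:
        table_b = None
        notes.append(
            f"lesion-level table not computable: {len(conc)} concordant / "
            f"{len(disc)} discordant vessels"
        )

    # (c) WI peaks by condition x phase; emitted even when one stratum is
    # empty (comparison rows then read not_computable)
    rows_c = []
    for cond, attr in (("rest", "wia_rest"), ("hyperemia", "wia_hyp")):
        for phase in ("pre", "post"):
            for var in _WIA_VARS:
                xc = [getattr(getattr(r, f"{attr}_{phase}"), var) for r in conc]
                xd = [getattr(getattr(r, f"{attr}_{phase}"), var) for r in disc]
                row = _group_row(f"{var}_{cond}_{phase}", xc, xd)
                row["condition"] = cond
                row["phase"] = phase
                rows_c.append(row)
    table_c = pd.DataFrame(rows_c)

    # (d) hyperemic pressure-drop formulation block (post-PCI)
    rows_d = []
    grouped = conc + disc if (conc or disc) else results
    deltap = np.array([r.post.deltap for r in grouped])
    pdpa = np.array([r.post.ffr for r in grouped])
    hapv = np.array([r.post.hapv for r in grouped])
    for name, x, y in (
        ("deltaP_vs_PdPa_post", deltap, pdpa),
        ("deltaP_vs_hAPV_post", deltap, hapv),
    ):
        try:
            r_val, p_val, method = correlate(x, y)
            rows_d.append({"pair": name, "r": r_val, "p_value": p_val,
                           "method": method, "n": len(x)})
        except (DegenerateSignalError, ParameterError) as exc:
            rows_d.append({"pair": name, "r": np.nan, "p_value": np.nan,
                           "method": f"not_computable ({exc})", "n": len(x)})
    table_d = pd.DataFrame(rows_d)

    return CohortReport(
        paired_pre_post=table_a,
        lesion_groups=table_b,
        wia_groups=table_c,
        correlations=table_d,
        notes=notes,
    )
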