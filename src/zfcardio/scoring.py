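"""Anti-Heart-Failure Index (AHFI) scoring and group statistics.

A screen produces a per-fish indicator table with a healthy control group, an
insult ("model") group and any number of treatment groups.  Scoring proceeds
in three steps, each on group means:

1. normalization to control:      B = mean_group / mean_control
2. recovery score per indicator:  RCF = (B_treat - B_model) / (1 - B_model)
   (0 = stuck at the model value, 1 = fully restored to control)
3. composite:                     AHFI = RCF_HR + RCF_EF + RCF_CO + RCF_FAC

HR, EF, CO and FAC are used as the four relatively independent components.
All quantities are dimensionless fractions; percent display is a formatting
concern.  Activity classes: excellent (AHFI >= 1.0), active (>= 0.6),
atypical (< -0.5), inactive otherwise; thresholds configurable.

The RCF denominator vanishes when the insult did not move an indicator off
the control value; such components are flagged invalid and the AHFI of the
group is marked invalid rather than silently mis-scored.  A model value
*above* control (negative denominator) is allowed: the same formula then
scores movement back down toward control, with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .indicators import INDICATOR_FIELDS
from .simulate import CONTROL, MODEL

logger = logging.getLogger(__name__)

#: The four indicators entering the AHFI, in summation order.
AHFI_COMPONENTS = ("hr_bpm", "ef", "co_um3_min", "fac")

#: Pretty names for reports.
COMPONENT_LABELS = {"hr_bpm": "HR", "ef": "EF", "co_um3_min": "CO", "fac": "FAC"}


@dataclass(frozen=True)
class AhfiThresholds:
    """Activity-class cut-offs on the composite score."""

    excellent: float = 1.0
    active: float = 0.6
    atypical: float = -0.5

    def classify(self, ahfi: float) -> str:
        if ahfi >= self.excellent:
            return "excellent"
        if ahfi >= self.active:
            return "active"
        if ahfi < self.atypical:
            return "atypical"
        return "inactive"


@dataclass
class AHFIResult:
    """Composite score of one treatment group."""

    group: str
    ahfi: float
    activity_class: str
    rcf: dict[str, float] = field(default_factory=dict)
    valid: bool = True
    invalid_components: tuple[str, ...] = ()


def summarize_groups(indicator_table: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean, sample SD (n-1) and n for every indicator.

    Expects columns ``group`` plus the indicator fields; returns a frame
    indexed by group with columns ``<field>_mean``, ``<field>_sd`` and ``n``.
    """
    if "group" not in indicator_table.columns:
        raise ConfigurationError("indicator table needs a 'group' column")
    for required in (CONTROL, MODEL):
        if required not in set(indicator_table["group"]):
            raise ConfigurationError(f"missing required group {required!r}")

    fields = [f for f in INDICATOR_FIELDS if f in indicator_table.columns]
    grouped = indicator_table.groupby("group", sort=False)
    out = pd.DataFrame(index=grouped.size().index)
    out["n"] = grouped.size()
    for f in fields:
        out[f"{f}_mean"] = grouped[f].mean()
        out[f"{f}_sd"] = grouped[f].std(ddof=1)
    small = out.index[out["n"] < 3]
    if len(small):
        logger.warning("groups with n < 3: %s", ", ".join(small))
    return out


def normalize_to_control(summary: pd.DataFrame,
                         control: str = CONTROL) -> pd.DataFrame:
    """Normalized panel B = group mean / control mean for the AHFI components.

    Returns a frame indexed by group with one column per component.
    B(control) = 1 by construction.
    """
    if control not in summary.index:
        raise ConfigurationError(f"control group {control!r} not in summary")
    panel = {}
    for comp in AHFI_COMPONENTS:
        ctrl_mean = summary.loc[control, f"{comp}_mean"]
        if not ctrl_mean > 0:
            raise ConfigurationError(
                f"control mean for {COMPONENT_LABELS[comp]} is not positive "
                f"({ctrl_mean}); normalization undefined")
        panel[comp] = summary[f"{comp}_mean"] / ctrl_mean
    return pd.DataFrame(panel, index=summary.index)


def recovery_score(b_treat: float, b_model: float,
                   tolerance: float = 1e-6) -> tuple[float, bool]:
    """RCF = (B_treat - B_model) / (1 - B_model); returns (value, valid).

    Invalid (NaN, False) when the model group sits at the control value
    within ``tolerance`` — the deficit is zero and recovery is undefined.
    """
    denom = 1.0 - b_model
    if abs(denom) <= tolerance:
        return float("nan"), False
    if denom < 0:
        logger.warning("indicator elevated by the insult (B_model=%.4g > 1); "
                       "RCF scores movement back toward control", b_model)
    return (b_treat - b_model) / denom, True


def compute_ahfi(normalized: pd.DataFrame, group: str,
                 model: str = MODEL,
                 thresholds: AhfiThresholds | None = None,
                 tolerance: float = 1e-6) -> AHFIResult:
    """Composite AHFI of one treatment group from the normalized panel."""
    thresholds = thresholds or AhfiThresholds()
    if model not in normalized.index:
        raise ConfigurationError(f"model group {model!r} not in panel")
    if group not in normalized.index:
        raise ConfigurationError(f"group {group!r} not in panel")

    rcf: dict[str, float] = {}
    bad: list[str] = []
    for comp in AHFI_COMPONENTS:
        value, ok = recovery_score(float(normalized.loc[group, comp]),
                                   float(normalized.loc[model, comp]),
                                   tolerance=tolerance)
        rcf[comp] = value
        if not ok:
            bad.append(comp)

    if bad:
        labels = [COMPONENT_LABELS[c] for c in bad]
        logger.warning("%s: AHFI invalid; degenerate components: %s",
                       group, ", ".join(labels))
        return AHFIResult(group=group, ahfi=float("nan"),
                          activity_class="invalid", rcf=rcf, valid=False,
                          invalid_components=tuple(bad))

    ahfi = float(sum(rcf.values()))
    return AHFIResult(group=group, ahfi=ahfi,
                      activity_class=thresholds.classify(ahfi), rcf=rcf)


def score_cohort(indicator_table: pd.DataFrame,
                 thresholds: AhfiThresholds | None = None
                 ) -> list[AHFIResult]:
    """Summarize, normalize and score every non-control, non-model group."""
    summary = summarize_groups(indicator_table)
    normalized = normalize_to_control(summary)
    results = [
        compute_ahfi(normalized, group, thresholds=thresholds)
        for group in normalized.index
        if group not in (CONTROL, MODEL)
    ]
    return rank_treatments(results)


def rank_treatments(results: list[AHFIResult]) -> list[AHFIResult]:
    """Stable descending order by AHFI; ties broken by RCF_EF, then label.

    Invalid results (NaN AHFI) sort to the end.
    """
    def key(r: AHFIResult):
        ahfi = r.ahfi if np.isfinite(r.ahfi) else -np.inf
        ef = r.rcf.get("ef", float("nan"))
        ef = ef if np.isfinite(ef) else -np.inf
        return (-ahfi, -ef, r.group)

    return sorted(results, key=key)


def ahfi_report(results: list[AHFIResult]) -> pd.DataFrame:
    """Tabular AHFI report (one row per treatment, ranked)."""
    rows = []
    for r in results:
        row = {"group": r.group, "ahfi": r.ahfi, "class": r.activity_class,
               "valid": r.valid}
        for comp in AHFI_COMPONENTS:
            row[f"rcf_{COMPONENT_LABELS[comp].lower()}"] = r.rcf.get(comp)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def compare_groups(indicator_table: pd.DataFrame,
                   reference: str = MODEL,
                   fields: tuple[str, ...] = AHFI_COMPONENTS
                   ) -> pd.DataFrame:
    """Two-tailed two-sample t-tests of every group against ``reference``,
    plus a one-way ANOVA across all groups, per indicator.

    Returns a tidy frame with columns group, indicator, test, p_value and
    significance stars ('*' p<0.05, '**' p<0.01).  Groups with n < 2 are
    skipped with a warning.
    """
    if reference not in set(indicator_table["group"]):
        raise ConfigurationError(f"reference group {reference!r} absent")
    ref_rows = indicator_table[indicator_table["group"] == reference]

    rows = []
    for f in fields:
        samples = []
        for group, sub in indicator_table.groupby("group", sort=False):
            values = sub[f].dropna().to_numpy()
            if values.size < 2:
                logger.warning("group %s has n < 2 for %s; comparison skipped",
                               group, f)
                continue
            samples.append(values)
            if group == reference:
                continue
            t, p = stats.ttest_ind(values, ref_rows[f].dropna().to_numpy())
            rows.append({"group": group, "indicator": f, "test": "t_vs_" + reference,
                         "statistic": float(t), "p_value": float(p),
                         "significance": _stars(p)})
        if len(samples) >= 2:
            f_stat, p = stats.f_oneway(*samples)
            rows.append({"group": "(all)", "indicator": f, "test": "anova",
                         "statistic": float(f_stat), "p_value": float(p),
                         "significance": _stars(p)})
    return pd.DataFrame(rows)


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def plot_ahfi(results: list[AHFIResult],
              thresholds: AhfiThresholds | None = None, ax=None):
    """Ranked AHFI bar chart with the activity threshold marked."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    thresholds = thresholds or AhfiThresholds()
    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, 0.8 * len(results)), 4))
    groups = [r.group for r in results]
    values = [r.ahfi for r in results]
    ax.bar(groups, values, color="#4878d0")
    ax.axhline(thresholds.active, linestyle=":", color="black",
               label=f"active ({thresholds.active})")
    ax.set_ylabel("AHFI")
    ax.legend(frameon=False)
    ax.tick_params(axis="x", rotation=45)
    return ax
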