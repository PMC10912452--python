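"""Clinical score derivations and the mixed-model analysis layer.

Score arithmetic follows the MDS-UPDRS Part III item structure: the
symptom laterality index is the left-sided bradykinesia item sum (items
3.4-3.8) minus the right-sided sum (negative = right-dominant), the
bradykinesia sum is the five-item side total (0-20), and the symptom
subtype is the ratio of mean tremor items (3.15-3.18) to mean bradykinesia
items (3.4-3.8 and 3.14) with ratios above 1.5 labelled tremor dominant.

Mixed models use the REML engine in :mod:`finemotor.lmm`: therapy-state
effects on single-trial metrics (random intercepts for subject and
trial-within-subject, Satterthwaite F tests, Tukey-adjusted pairwise
state contrasts) and profile-on-UPDRS prediction models (random intercept
by subject, Nakagawa marginal/conditional R^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import LMMFit, fit_lmm

__all__ = [
    "BRADY_ITEMS",
    "TREMOR_ITEMS",
    "LMEFit",
    "laterality_index",
    "bradykinesia_sum",
    "subtype_classify",
    "exclude_item4_observations",
    "lme_single_trial",
    "tukey_posthoc",
    "lme_profile_on_updrs",
]

BRADY_ITEMS = ("3.4", "3.5", "3.6", "3.7", "3.8")
TREMOR_ITEMS = ("3.15", "3.16", "3.17", "3.18")
STATE_ORDER = ("OFF/OFF", "ON/OFF", "OFF/ON", "ON/ON")


def _require_items(record: dict, items: tuple, sided: bool) -> None:
    present = record.get("items", {})
    for item in items:
        if item not in present:
            raise KeyError(f"missing UPDRS item {item}")
        if sided:
            entry = present[item]
            if not isinstance(entry, dict) or not {"left", "right"} <= entry.keys():
                raise KeyError(f"UPDRS item {item} lacks left/right sub-scores")


def laterality_index(record: dict) -> int:
    """Left-sided bradykinesia item sum minus right-sided (items 3.4-3.8).

    Negative values indicate right-dominant symptoms.
    """
    _require_items(record, BRADY_ITEMS, sided=True)
    items = record["items"]
    left = sum(items[i]["left"] for i in BRADY_ITEMS)
    right = sum(items[i]["right"] for i in BRADY_ITEMS)
    return int(left - right)


def bradykinesia_sum(record: dict, side: str) -> int:
    """Sum of items 3.4-3.8 for one side (range 0-20)."""
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    _require_items(record, BRADY_ITEMS, sided=True)
    total = sum(record["items"][i][side] for i in BRADY_ITEMS)
    if not 0 <= total <= 20:
        raise ValueError("bradykinesia sum out of the 0-20 item range")
    return int(total)


def subtype_classify(record: dict) -> tuple[str, float]:
    """Tremor-dominant vs akinetic-rigid subtype from the item-mean ratio.

    Ratio = mean(items 3.15-3.18) / mean(items 3.4-3.8 both sides, 3.14);
    zero numerator => akinetic-rigid, zero denominator => tremor dominant,
    otherwise > 1.5 => tremor dominant (exactly 1.5 counts as
    akinetic-rigid since only strictly greater ratios indicate tremor
    dominance).
    """
    _require_items(record, TREMOR_ITEMS, sided=False)
    _require_items(record, BRADY_ITEMS, sided=True)
    if "3.14" not in record["items"]:
        raise KeyError("missing UPDRS item 3.14")
    items = record["items"]
    tremor_scores = [float(items[i]) for i in TREMOR_ITEMS]
    brady_scores = [
        float(items[i][side]) for i in BRADY_ITEMS for side in ("left", "right")
    ]
    brady_scores.append(float(items["3.14"]))
    tremor_mean = float(np.mean(tremor_scores))
    brady_mean = float(np.mean(brady_scores))
    if tremor_mean == 0 and brady_mean == 0:
        return "indeterminate", np.nan
    if tremor_mean == 0:
        return "akinetic_rigid_dominant", 0.0
    if brady_mean == 0:
        return "tremor_dominant", np.inf
    ratio = tremor_mean / brady_mean
    return ("tremor_dominant" if ratio > 1.5 else "akinetic_rigid_dominant", ratio)


def exclude_item4_observations(
    data: pd.DataFrame, item_col: str
) -> tuple[pd.DataFrame, int]:
    """Drop rows where the named item column is rated 4 (task failure).

    Returns the filtered frame and the number of removed rows.
    """
    if item_col not in data.columns:
        raise KeyError(f"unknown item column '{item_col}'")
    keep = data[item_col] != 4
    return data.loc[keep].copy(), int((~keep).sum())


@dataclass
class LMEFit:
    """A fitted mixed model plus its primary F test and design bookkeeping."""

    fit: LMMFit
    X: np.ndarray
    term_tests: dict  # term -> (F, ndf, ddf, p)
    emmeans: dict = field(default_factory=dict)
    r2_marginal: float = np.nan
    r2_conditional: float = np.nan

    @property
    def coef(self) -> pd.Series:
        return pd.Series(self.fit.beta, index=self.fit.names)


def _state_design(states: pd.Series) -> tuple[np.ndarray, list, list]:
    """Intercept + treatment dummies for the 4-level therapy-state factor."""
    levels = [s for s in STATE_ORDER if s in set(states)]
    if len(levels) < 2:
        raise ValueError("need at least 2 therapy states")
    X = np.ones((states.size, len(levels)))
    names = ["intercept"]
    for j, lev in enumerate(levels[1:], start=1):
        X[:, j] = (states == lev).to_numpy(dtype=float)
        names.append(f"state[{lev}]")
    return X, names, levels


def lme_single_trial(
    table: pd.DataFrame,
    metric: str,
    include_subject: bool = True,
    include_nested: bool = True,
) -> LMEFit:
    """Therapy-state effect on a single-trial metric.

    ``table`` needs columns ``subject``, ``state`` (med/stim label),
    ``trial`` and the metric. Random intercepts: subject and
    trial-within-subject ("nested random effect"); the state factor is
    tested with a Satterthwaite F.
    """
    needed = {"subject", "state", "trial", metric}
    if not needed <= set(table.columns):
        raise KeyError(f"metric table lacks columns {needed - set(table.columns)}")
    data = table.dropna(subset=[metric])
    if data["subject"].nunique() < 2:
        raise ValueError("at least 2 subjects required")
    X, names, levels = _state_design(data["state"])
    fit = fit_lmm(
        data[metric].to_numpy(dtype=float),
        X,
        data["subject"].to_numpy(),
        nested=data["trial"].to_numpy(),
        names=names,
        include_subject=include_subject,
        include_nested=include_nested,
    )
    q = len(levels) - 1
    L = np.zeros((q, X.shape[1]))
    for j in range(q):
        L[j, j + 1] = 1.0
    term_tests = {"state": fit.wald_f(L)}
    emmeans = {levels[0]: float(fit.beta[0])}
    for j, lev in enumerate(levels[1:], start=1):
        emmeans[lev] = float(fit.beta[0] + fit.beta[j])
    r2m, r2c = fit.variance_explained(X)
    return LMEFit(
        fit=fit,
        X=X,
        term_tests=term_tests,
        emmeans=emmeans,
        r2_marginal=r2m,
        r2_conditional=r2c,
    )


def tukey_posthoc(model: LMEFit) -> pd.DataFrame:
    """All pairwise therapy-state contrasts with Tukey-adjusted p-values.

    The adjusted p comes from the studentized-range distribution with the
    contrast's Satterthwaite df and the number of factor levels.
    """
    levels = list(model.emmeans)
    k = len(levels)
    if k < 2:
        raise ValueError("post-hoc requires at least 2 factor levels")
    rows = []
    p_fixed = model.X.shape[1]
    for a in range(k):
        for b in range(a + 1, k):
            c = np.zeros(p_fixed)
            if a > 0:
                c[a] = 1.0
            if b > 0:
                c[b] -= 1.0
            est, se, t, df = model.fit.contrast_t(c)
            p_adj = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df))
            rows.append(
                {
                    "contrast": f"{levels[a]} - {levels[b]}",
                    "estimate": est,
                    "se": se,
                    "t": t,
                    "df": df,
                    "p_adj": min(p_adj, 1.0),
                }
            )
    return pd.DataFrame(rows)


def lme_profile_on_updrs(
    data: pd.DataFrame,
    outcome: str,
    profile_cols: tuple = ("profile",),
    covariates: tuple = ("laterality_index",),
    interactions: tuple = (),
) -> LMEFit:
    """Predict a clinical outcome from movement profile score(s).

    ``data`` holds one row per subject x therapy state with the profile
    score(s), covariates and the outcome; the model adds a random
    intercept by subject. ``interactions`` are pairs of column names whose
    products enter as fixed effects.
    """
    cols = [*profile_cols, *covariates, outcome, "subject"]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"missing column(s): {missing}")
    data = data.dropna(subset=[*profile_cols, *covariates, outcome])
    terms: list[tuple[str, np.ndarray]] = [
        ("intercept", np.ones(len(data))),
    ]
    for col in (*profile_cols, *covariates):
        terms.append((col, data[col].to_numpy(dtype=float)))
    for a, b in interactions:
        terms.append(
            (f"{a}:{b}", data[a].to_numpy(dtype=float) * data[b].to_numpy(dtype=float))
        )
    names = [t[0] for t in terms]
    X = np.column_stack([t[1] for t in terms])
    fit = fit_lmm(
        data[outcome].to_numpy(dtype=float),
        X,
        data["subject"].to_numpy(),
        names=names,
    )
    term_tests = {}
    for j, name in enumerate(names):
        if name == "intercept":
            continue
        L = np.zeros((1, X.shape[1]))
        L[0, j] = 1.0
        term_tests[name] = fit.wald_f(L)
    r2m, r2c = fit.variance_explained(X)
    return LMEFit(
        fit=fit, X=X, term_tests=term_tests, r2_marginal=r2m, r2_conditional=r2c
    )
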