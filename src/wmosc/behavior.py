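"""Behavioural accuracy and reaction-time analyses, and clinical correlations.

Responses are scored against chance (0.5 for the present/absent judgement)
per memory load with Wilcoxon signed-rank across subjects (Bonferroni over
the three loads) and compared between groups with rank-sum tests. Reaction
times at the high-load condition are summarised by the per-subject median in
the four response categories — correct match (CM), correct non-match (CnM),
error match (EM), error non-match (EnM) — with paired correct-vs-error tests
and low-load control contrasts (correct-error RT difference and right-left
hand difference at load 2) that separate cognitive effort from motor speed.

Clinical linkage: Spearman correlation between a per-subject connectivity
modulation score (the t-value of the load-by-success interaction from the
Granger model) and each neuropsychological z-score, Bonferroni corrected
over the number of tests supplied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import CLINICAL_TESTS, ClinicalScores

__all__ = ["accuracy_by_load", "rt_by_category", "clinical_correlation",
           "response_category"]

LOADS = (2, 4, 6)
CATEGORIES = ("CM", "CnM", "EM", "EnM")


def response_category(meta: pd.DataFrame) -> pd.Series:
    """CM/CnM/EM/EnM per responded trial (NaN where no response was given)."""
    cat = pd.Series(index=meta.index, dtype=object)
    responded = meta["smp"].notna()
    correct = meta["smp"] == 1
    matched = meta["match"] == "match"
    cat[responded & correct & matched] = "CM"
    cat[responded & correct & ~matched] = "CnM"
    cat[responded & ~correct & matched] = "EM"
    cat[responded & ~correct & ~matched] = "EnM"
    return cat


def _signed_rank_vs(values: np.ndarray, null: float,
                    alternative: str = "greater") -> tuple[float, float]:
    d = np.asarray(values, float) - null
    if np.all(d == 0):
        return 0.0, 1.0
    res = stats.wilcoxon(d[d != 0], alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def accuracy_by_load(metas: dict[str, pd.DataFrame],
                     groups: dict[str, str] | None = None,
                     chance: float = 0.5) -> dict:
    """Accuracy per memory load with chance-level and group comparisons.

    ``metas`` maps subject id to the trial metadata table. Returns a report
    with the per-subject accuracy table, one-sided signed-rank tests against
    chance per load (Bonferroni over the 3 loads, pooled across subjects or
    per group when ``groups`` is given), between-group rank-sum tests per
    load, and the per-subject load-2 minus load-6 accuracy drop.
    """
    rows = []
    for subj, meta in metas.items():
        responded = meta[meta["smp"].notna()]
        for load in LOADS:
            sub = responded[responded["ml"] == load]
            acc = float(sub["smp"].mean()) if len(sub) else np.nan
            rows.append({"subject": subj, "ml": load, "accuracy": acc,
                         "n_responded": len(sub),
                         "missing": len(sub) == 0})
    table = pd.DataFrame(rows)
    wide = table.pivot(index="subject", columns="ml", values="accuracy")
    report: dict = {"per_subject": table, "chance": chance,
                    "load2_minus_load6": (wide[2] - wide[6]).rename("drop")}

    group_of = groups or {s: "all" for s in metas}
    labels = sorted(set(group_of.values()))
    vs_chance: dict = {}
    for lab in labels:
        subjects = [s for s in wide.index if group_of[s] == lab]
        per_load = {}
        for load in LOADS:
            vals = wide.loc[subjects, load].dropna().to_numpy()
            if len(vals) == 0:
                per_load[load] = {"skipped": "no responded trials"}
                continue
            stat, p = _signed_rank_vs(vals, chance, "greater")
            per_load[load] = {"statistic": stat, "p": p,
                              "p_bonferroni": min(1.0, p * len(LOADS))}
        vs_chance[lab] = per_load
    report["vs_chance"] = vs_chance

    if len(labels) == 2:
        between = {}
        for load in LOADS:
            a = wide.loc[[s for s in wide.index if group_of[s] == labels[0]],
                         load].dropna()
            b = wide.loc[[s for s in wide.index if group_of[s] == labels[1]],
                         load].dropna()
            res = stats.ranksums(a, b)
            between[load] = {"statistic": float(res.statistic),
                             "p": float(res.pvalue)}
        report["between_groups"] = between
    return report


def rt_by_category(metas: dict[str, pd.DataFrame],
                   groups: dict[str, str] | None = None,
                   load: int = 6) -> dict:
    """Median reaction time per response category at one memory load.

    Within each group, correct and error medians are compared with a paired
    signed-rank test; with two groups, each category is compared between
    groups by rank-sum. Load-2 controls (correct-error RT difference and
    right-left hand difference) are always included.
    """
    if load not in LOADS:
        raise ValueError(f"load must be one of {LOADS}")
    rows = []
    for subj, meta in metas.items():
        cat = response_category(meta)
        at_load = meta["ml"] == load
        for c in CATEGORIES:
            sel = meta.loc[at_load & (cat == c), "rt"].dropna()
            rows.append({"subject": subj, "category": c,
                         "median_rt": float(sel.median()) if len(sel) else np.nan,
                         "n": len(sel), "missing": len(sel) == 0})
        resp2 = meta[(meta["ml"] == 2) & meta["smp"].notna()]
        rows.append({"subject": subj, "category": "load2_correct_minus_error",
                     "median_rt": float(resp2.loc[resp2["smp"] == 1, "rt"].median()
                                        - resp2.loc[resp2["smp"] == 0, "rt"].median()),
                     "n": len(resp2), "missing": False})
        rows.append({"subject": subj, "category": "load2_right_minus_left",
                     "median_rt": float(resp2.loc[resp2["hand"] == "right", "rt"].median()
                                        - resp2.loc[resp2["hand"] == "left", "rt"].median()),
                     "n": len(resp2), "missing": False})
    table = pd.DataFrame(rows)
    wide = table[table["category"].isin(CATEGORIES)].pivot(
        index="subject", columns="category", values="median_rt")
    report: dict = {"per_subject": table, "load": load}

    group_of = groups or {s: "all" for s in metas}
    labels = sorted(set(group_of.values()))
    within = {}
    for lab in labels:
        subjects = [s for s in wide.index if group_of[s] == lab]
        sub = wide.loc[subjects]
        correct = sub[["CM", "CnM"]].mean(axis=1)
        error = sub[["EM", "EnM"]].mean(axis=1)
        d = (error - correct).dropna()
        if len(d) >= 5 and not np.all(d == 0):
            res = stats.wilcoxon(d)
            within[lab] = {"median_diff": float(d.median()),
                           "statistic": float(res.statistic),
                           "p": float(res.pvalue),
                           "p_bonferroni": min(1.0, float(res.pvalue) * len(labels))}
        else:
            within[lab] = {"skipped": "insufficient paired subjects"}
    report["error_vs_correct"] = within

    if len(labels) == 2:
        between = {}
        for c in list(CATEGORIES) + ["load2_correct_minus_error",
                                     "load2_right_minus_left"]:
            vals = table[table["category"] == c]
            a = vals[vals["subject"].map(group_of) == labels[0]]["median_rt"].dropna()
            b = vals[vals["subject"].map(group_of) == labels[1]]["median_rt"].dropna()
            if len(a) >= 2 and len(b) >= 2:
                res = stats.ranksums(a, b)
                between[c] = {"statistic": float(res.statistic),
                              "p": float(res.pvalue)}
        report["between_groups"] = between
    return report


def clinical_correlation(coupling: pd.Series, scores: ClinicalScores,
                         tests: list[str] | None = None) -> dict:
    """Spearman correlation of a coupling score with clinical z-scores.

    ``coupling`` is indexed by subject (typically the t-value of the
    load-by-success interaction from the per-subject Granger model). The
    Bonferroni factor equals the number of clinical tests supplied. Tests
    with fewer than 5 complete pairs are skipped with a reason.
    """
    tests = list(tests) if tests is not None else list(CLINICAL_TESTS)
    k = len(tests)
    out: dict = {"n_tests": k}
    for test in tests:
        if test not in scores.table.columns:
            out[test] = {"skipped": "score not available"}
            continue
        joined = pd.concat([coupling.rename("coupling"),
                            scores.table[test]], axis=1).dropna()
        if len(joined) < 5:
            out[test] = {"skipped": f"only {len(joined)} complete pairs"}
            continue
        if joined["coupling"].nunique() < 2 or joined[test].nunique() < 2:
            out[test] = {"skipped": "constant input"}
            continue
        rho, p = stats.spearmanr(joined["coupling"], joined[test])
        out[test] = {"rho": float(rho), "p": float(p),
                     "p_bonferroni": min(1.0, float(p) * k),
                     "n": len(joined)}
    return out
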