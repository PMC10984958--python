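"""Cohort-level risk-genotype report: the gene-gene interaction summary.

Assembles, per cohort (discovery, replication, combined), the carrier counts
of the three risk genotypes — NAT2 ultraslow acetylator (UA), ATP7B 832R/R,
and their co-occurrence — and runs exact 2x2 inference (conditional-MLE OR,
exact 95% CI, Fisher P) for cases vs treatment-tolerant controls, plus
carrier-frequency comparisons of the combined-cohort cases against a
population control panel.  Prevalence-standardized PPV/NPV are reported for
UA alone and the combined genotype.  The published study counts are packaged
as a fixture so the whole report can be reproduced from printed numbers
alone.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .exact_stats import (
    PredictiveValues,
    Table2x2,
    exact_result,
    fisher_exact_two_sided,
    ppv_comparison_p,
    predictive_values,
)

EXPOSURES = ("nat2_ua", "atp7b_rr", "combined")

# Published carrier counts (cases, controls) per cohort and exposure, and
# the population-panel carrier counts; the unit-level inputs of the report.
STUDY_COUNTS = {
    "discovery": {
        "n_cases": 35,
        "n_controls": 77,
        "nat2_ua": (11, 3),
        "atp7b_rr": (11, 10),
        "combined": (6, 0),
    },
    "replication": {
        "n_cases": 37,
        "n_controls": 128,
        "nat2_ua": (9, 10),
        "atp7b_rr": (9, 22),
        "combined": (4, 1),
    },
    "combined": {
        "n_cases": 72,
        "n_controls": 205,
        "nat2_ua": (20, 13),
        "atp7b_rr": (20, 32),
        "combined": (10, 1),
    },
    "population": {
        "n": 1048,
        "nat2_ua": 129,
        "atp7b_rr": 147,
        "combined": 19,
    },
}

DEFAULT_PREVALENCE = 0.05


def _exposure_flags(calls: pd.DataFrame) -> pd.DataFrame:
    flags = pd.DataFrame(index=calls.index)
    flags["nat2_ua"] = calls["phenotype"] == "UA"
    flags["atp7b_rr"] = calls["atp7b"] == "R/R"
    flags["combined"] = flags["nat2_ua"] & flags["atp7b_rr"]
    flags["sample_id"] = calls["sample_id"].values
    return flags


def counts_from_calls(calls: pd.DataFrame, pheno: pd.DataFrame) -> dict:
    """Carrier counts in the layout of STUDY_COUNTS from per-sample calls."""
    flags = _exposure_flags(calls).set_index("sample_id")
    merged = pheno.join(flags, on="sample_id", how="inner")
    out: dict = {}
    study = merged[merged["cohort"] != "population"]
    for label, sub in [
        ("discovery", study[study["cohort"] == "discovery"]),
        ("replication", study[study["cohort"] == "replication"]),
        ("combined", study),
    ]:
        cases = sub[sub["status"] == "case"]
        ctrls = sub[sub["status"] == "control"]
        if len(cases) == 0 or len(ctrls) == 0:
            continue
        entry = {"n_cases": len(cases), "n_controls": len(ctrls)}
        for exp in EXPOSURES:
            entry[exp] = (int(cases[exp].sum()), int(ctrls[exp].sum()))
        out[label] = entry
    pop = merged[merged["cohort"] == "population"]
    if len(pop):
        out["population"] = {"n": len(pop), **{e: int(pop[e].sum()) for e in EXPOSURES}}
    return out


def build_table2(
    calls: pd.DataFrame | None = None,
    pheno: pd.DataFrame | None = None,
    counts: dict | None = None,
    prevalence: float = DEFAULT_PREVALENCE,
    alpha: float = 0.05,
) -> "RiskGenotypeReport":
    """Run the full exact-inference report.

    Either per-sample calls + phenotypes or a pre-assembled counts dict (the
    packaged study counts by default) can be supplied.
    """
    if counts is None:
        if calls is None or pheno is None:
            counts = STUDY_COUNTS
        else:
            counts = counts_from_calls(calls, pheno)
    rows = []
    for cohort in ("discovery", "replication", "combined"):
        if cohort not in counts:
            continue
        c = counts[cohort]
        for exp in EXPOSURES:
            a, cc = c[exp]
            t = Table2x2(a, c["n_cases"] - a, cc, c["n_controls"] - cc)
            res = exact_result(t, alpha)
            rows.append(
                {
                    "cohort": cohort,
                    "control_set": "tolerant",
                    "exposure": exp,
                    "a": t.a,
                    "b": t.b,
                    "c": t.c,
                    "d": t.d,
                    "case_pct": round(100.0 * t.a / t.n_cases, 1),
                    "control_pct": round(100.0 * t.c / t.n_controls, 1),
                    "or_cmle": res.or_cmle,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p": res.p_two_sided,
                }
            )
    if "population" in counts and "combined" in counts:
        pop, comb = counts["population"], counts["combined"]
        for exp in EXPOSURES:
            a = comb[exp][0]
            c_exposed = pop[exp]
            t = Table2x2(a, comb["n_cases"] - a, c_exposed, pop["n"] - c_exposed)
            res = exact_result(t, alpha)
            rows.append(
                {
                    "cohort": "combined",
                    "control_set": "population",
                    "exposure": exp,
                    "a": t.a,
                    "b": t.b,
                    "c": t.c,
                    "d": t.d,
                    "case_pct": round(100.0 * t.a / t.n_cases, 1),
                    "control_pct": round(100.0 * t.c / t.n_controls, 1),
                    "or_cmle": res.or_cmle,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p": res.p_two_sided,
                }
            )
    table = pd.DataFrame(rows)
    pv = {}
    ppv_p = math.nan
    if "combined" in counts:
        c = counts["combined"]
        tables = {}
        for exp in ("nat2_ua", "combined"):
            a, cc = c[exp]
            tables[exp] = Table2x2(a, c["n_cases"] - a, cc, c["n_controls"] - cc)
            pv[exp] = predictive_values(tables[exp], prevalence)
        try:
            ppv_p = ppv_comparison_p(tables["combined"], tables["nat2_ua"])
        except ValueError:  # no predicted positives for one marker
            ppv_p = math.nan
    return RiskGenotypeReport(table=table, predictive=pv, ppv_comparison_p=ppv_p, prevalence=prevalence)


class RiskGenotypeReport:
    """Exact-inference rows plus predictive-value summaries."""

    def __init__(
        self,
        table: pd.DataFrame,
        predictive: dict[str, PredictiveValues],
        ppv_comparison_p: float,
        prevalence: float,
    ):
        self.table = table
        self.predictive = predictive
        self.ppv_comparison_p = ppv_comparison_p
        self.prevalence = prevalence

    def row(self, cohort: str, exposure: str, control_set: str = "tolerant") -> pd.Series:
        sel = self.table[
            (self.table["cohort"] == cohort)
            & (self.table["exposure"] == exposure)
            & (self.table["control_set"] == control_set)
        ]
        if sel.empty:
            raise KeyError((cohort, exposure, control_set))
        return sel.iloc[0]

    def to_markdown(self) -> str:
        def fmt_or(r):
            if math.isinf(r["or_cmle"]):
                return f"inf [{r['ci_low']:.2f}-inf]"
            return f"{r['or_cmle']:.2f} [{r['ci_low']:.2f}-{r['ci_high']:.2f}]"

        lines = ["| cohort | controls | exposure | cases | controls | OR [95% CI] | P |", "|---|---|---|---|---|---|---|"]
        for _, r in self.table.iterrows():
            lines.append(
                f"| {r['cohort']} | {r['control_set']} | {r['exposure']} | "
                f"{r['a']}/{r['a'] + r['b']} ({r['case_pct']}%) | "
                f"{r['c']}/{r['c'] + r['d']} ({r['control_pct']}%) | "
                f"{fmt_or(r)} | {r['p']:.2g} |"
            )
        if self.predictive:
            lines.append("")
            for exp, pv in self.predictive.items():
                lines.append(
                    f"- {exp}: PPV {100 * pv.ppv:.1f}%, NPV {100 * pv.npv:.1f}% "
                    f"(sens {100 * pv.sensitivity:.1f}%, spec {100 * pv.specificity:.1f}%, "
                    f"prevalence {self.prevalence})"
                )
            lines.append(f"- PPV comparison (combined vs UA alone): P = {self.ppv_comparison_p:.2g}")
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        def clean(v):
            if isinstance(v, float) and math.isinf(v):
                return "inf"
            if isinstance(v, (np.integer,)):
                return int(v)
            if isinstance(v, (np.floating,)):
                return float(v)
            return v

        return {
            "rows": [
                {k: clean(v) for k, v in r.items()} for r in self.table.to_dict("records")
            ],
            "predictive": {
                exp: {
                    "sensitivity": pv.sensitivity,
                    "specificity": pv.specificity,
                    "prevalence": pv.prevalence,
                    "ppv": pv.ppv,
                    "npv": pv.npv,
                }
                for exp, pv in self.predictive.items()
            },
            "ppv_comparison_p": clean(self.ppv_comparison_p),
        }


def cooccurrence_fisher_p(counts: dict | None = None, cohort: str = "combined") -> float:
    """Fisher P for co-occurring risk-genotype carriage, cases vs tolerant
    controls, in the requested cohort (reported, not asserted: the source of
    the published co-occurrence P is ambiguous)."""
    counts = counts or STUDY_COUNTS
    c = counts[cohort]
    a, cc = c["combined"]
    return fisher_exact_two_sided(Table2x2(a, c["n_cases"] - a, cc, c["n_controls"] - cc))
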