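"""Cohort-wide per-variant case-control association scan.

Common variants (MAF above a cutoff computed on the union of the compared
groups) are tested one at a time against a chosen control set with the exact
2x2 machinery — allelic tables by default, dominant/recessive carrier
codings by flag — alongside the Cochran-Armitage trend test on genotype
counts.  Benjamini-Hochberg q-values are computed within each scan.  Helpers
shape the results for volcano plots (log2 OR vs -log10 P with significance
tiers) and QQ plots with the genomic-inflation factor lambda.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .exact_stats import Table2x2, bh_fdr, cochran_armitage_trend, exact_result
from .io_core import MISSING, GenotypeMatrix

VOLCANO_TIERS = ("ns", "P<0.01", "P<0.001")


def _select_groups(pheno: pd.DataFrame, control_set: str):
    cases = pheno.loc[(pheno["status"] == "case") & (pheno["cohort"] != "population"), "sample_id"]
    if control_set == "tolerant":
        controls = pheno.loc[
            (pheno["status"] == "control") & (pheno["cohort"] != "population"), "sample_id"
        ]
    elif control_set == "population":
        controls = pheno.loc[pheno["cohort"] == "population", "sample_id"]
    else:
        raise ValueError(f"unknown control set {control_set!r} (use 'tolerant' or 'population')")
    if len(cases) == 0:
        raise ValueError("no cases in phenotype table")
    if len(controls) == 0:
        raise ValueError(f"no samples in control set {control_set!r}")
    overlap = set(cases) & set(controls)
    if overlap:
        raise ValueError(f"case and control sets overlap: {sorted(overlap)[:3]}...")
    return list(cases), list(controls)


def _genotype_counts(dos: np.ndarray) -> tuple[int, int, int]:
    return int((dos == 0).sum()), int((dos == 1).sum()), int((dos == 2).sum())


def common_variant_scan(
    g: GenotypeMatrix,
    pheno: pd.DataFrame,
    control_set: str = "tolerant",
    maf_min: float = 0.05,
    coding: str = "allelic",
    autosomes_only: bool = True,
    gene_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-variant exact association scan against one control set.

    Returns one row per retained variant with allele/carrier counts, the
    conditional-MLE OR with exact CI, the two-sided Fisher P, the
    Cochran-Armitage trend P, the within-scan BH q-value and the MAF.
    Variants below maf_min (or monomorphic) are excluded before testing.
    """
    if coding not in ("allelic", "dominant", "recessive"):
        raise ValueError(f"unknown coding {coding!r}")
    if autosomes_only:
        g = g.drop_sex_chromosomes()
    case_ids, control_ids = _select_groups(pheno, control_set)
    present = set(g.sample_ids)
    g_case = g.subset(samples=[s for s in case_ids if s in present])
    g_ctrl = g.subset(samples=[s for s in control_ids if s in present])
    if g_case.n_samples == 0 or g_ctrl.n_samples == 0:
        raise ValueError("case or control samples absent from genotype matrix")

    rows = []
    for j, vid in enumerate(g.variant_ids):
        dc = g_case.dosage[:, j]
        dt = g_ctrl.dosage[:, j]
        dc, dt = dc[dc != MISSING], dt[dt != MISSING]
        if dc.size == 0 or dt.size == 0:
            continue
        alt = int(dc.sum() + dt.sum())
        tot = 2 * (dc.size + dt.size)
        maf = min(alt, tot - alt) / tot
        if maf < maf_min or maf == 0.0:
            continue
        if coding == "allelic":
            t = Table2x2(int(dc.sum()), int(2 * dc.size - dc.sum()), int(dt.sum()), int(2 * dt.size - dt.sum()))
        elif coding == "dominant":
            a = int((dc > 0).sum())
            c = int((dt > 0).sum())
            t = Table2x2(a, dc.size - a, c, dt.size - c)
        else:  # recessive
            a = int((dc == 2).sum())
            c = int((dt == 2).sum())
            t = Table2x2(a, dc.size - a, c, dt.size - c)
        res = exact_result(t)
        _, trend_p = cochran_armitage_trend(_genotype_counts(dc), _genotype_counts(dt))
        rows.append(
            {
                "variant_id": vid,
                "gene": (gene_map or {}).get(vid, "."),
                "control_set": control_set,
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "maf": maf,
                "or_cmle": res.or_cmle,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p_fisher": res.p_two_sided,
                "p_trend": trend_p,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q_fisher"] = bh_fdr(out["p_fisher"].to_numpy())
    return out


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready volcano rows: log2 OR, -log10 Fisher P, significance tier.

    Infinite or zero ORs are clamped to one unit beyond the largest finite
    |log2 OR| in the scan and flagged."""
    if results.empty:
        raise ValueError("empty result table")
    ors = results["or_cmle"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log2or = np.log2(ors)
    finite = np.isfinite(log2or)
    cap = (np.abs(log2or[finite]).max() if finite.any() else 0.0) + 1.0
    clamped = ~finite
    log2or = np.clip(log2or, -cap, cap)
    p = results["p_fisher"].to_numpy(dtype=float)
    tier = np.where(p < 0.001, "P<0.001", np.where(p < 0.01, "P<0.01", "ns"))
    return pd.DataFrame(
        {
            "variant_id": results["variant_id"],
            "log2_or": log2or,
            "neg_log10_p": -np.log10(np.clip(p, 1e-300, 1.0)),
            "tier": tier,
            "or_clamped": clamped,
        }
    )


def qq_and_lambda(p_values) -> tuple[pd.DataFrame, float]:
    """Observed vs expected -log10 P quantiles and genomic inflation lambda.

    lambda is the median of the chi-square(1) quantiles implied by the P
    values divided by the null median 0.4549.
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    if p.size == 0:
        raise ValueError("no p-values")
    n = p.size
    expected = (np.arange(1, n + 1) - 0.5) / n
    qq = pd.DataFrame(
        {
            "expected_neg_log10_p": -np.log10(expected),
            "observed_neg_log10_p": -np.log10(np.clip(p, 1e-300, 1.0)),
        }
    )
    chisq = chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    lam = float(np.median(chisq) / chi2.isf(0.5, df=1))
    return qq, lam
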