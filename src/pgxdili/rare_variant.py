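"""Gene-based collapsing of rare functional variants and a burden test.

Variants are retained when their reference-population allele frequency is
below a cutoff and their annotated consequence is protein-altering
(missense, nonsense, frameshift) or splicing within 2 bp of an exon
junction.  Retained variants are collapsed per gene into a per-sample
burden score (minor-allele count across members), and the case-control
difference in mean burden is assessed with a seeded permutation test —
cohorts of this size are too small for the asymptotic score-test null.
Genes are reported only when they contribute more than two qualifying
variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import MISSING, GenotypeMatrix

FUNCTIONAL_CLASSES = ("missense", "nonsense", "frameshift")
SPLICE_JUNCTION_BP = 2
MIN_VARIANTS_REPORTED = 3  # "more than two functional variants"


@dataclass
class GeneSet:
    gene: str
    variant_ids: list[str]
    burden: np.ndarray  # per-sample minor-allele count across members
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if self.burden.max(initial=0) > 2 * len(self.variant_ids):
            raise ValueError("burden exceeds 2 x member count")


def select_functional_rare(
    annotations: pd.DataFrame, variant_ids=None, maf_max: float = 0.05
) -> list[str]:
    """Variant ids passing the functional-consequence and rarity filters.

    Splicing variants qualify only within SPLICE_JUNCTION_BP of an exon
    junction.  Variants lacking an annotation row are excluded (warning via
    the returned set simply omitting them)."""
    ann = annotations.set_index("variant_id")
    universe = list(ann.index) if variant_ids is None else list(variant_ids)
    kept = []
    for vid in universe:
        if vid not in ann.index:
            continue
        row = ann.loc[vid]
        cls = row["functional_class"]
        functional = cls in FUNCTIONAL_CLASSES or (
            cls == "splicing" and float(row.get("junction_distance_bp", np.inf)) <= SPLICE_JUNCTION_BP
        )
        if functional and float(row["population_af"]) < maf_max:
            kept.append(vid)
    return kept


def collapse_genes(
    g: GenotypeMatrix, annotations: pd.DataFrame, selected: list[str]
) -> dict[str, GeneSet]:
    """Per-gene burden scores over the selected variants present in g.

    Missing calls contribute zero burden (carrier information absent)."""
    ann = annotations.set_index("variant_id")
    by_gene: dict[str, list[str]] = {}
    for vid in selected:
        if vid in g.variant_ids:
            by_gene.setdefault(str(ann.loc[vid, "gene"]), []).append(vid)
    out = {}
    for gene, vids in sorted(by_gene.items()):
        cols = np.column_stack([g.dosage_of(v) for v in vids]).astype(np.int64)
        cols[cols == MISSING] = 0
        out[gene] = GeneSet(
            gene=gene, variant_ids=vids, burden=cols.sum(axis=1), sample_ids=list(g.sample_ids)
        )
    return out


def burden_test(
    gs: GeneSet,
    pheno: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Permutation burden test: difference in mean burden, cases vs controls.

    Returns gene, n_variants, carrier counts by group, the observed
    statistic, and the two-sided permutation P ((r+1)/(B+1) with r the count
    of permuted |statistics| at least the observed).  Zero burden variance
    gives P = 1.
    """
    status = pheno.set_index("sample_id").loc[gs.sample_ids, "status"].to_numpy()
    is_case = status == "case"
    n_case = int(is_case.sum())
    if n_case == 0 or n_case == len(status):
        raise ValueError("burden test needs both cases and controls")
    burden = gs.burden.astype(float)
    obs = burden[is_case].mean() - burden[~is_case].mean()
    result = {
        "gene": gs.gene,
        "n_variants": len(gs.variant_ids),
        "carriers_case": int((gs.burden[is_case] > 0).sum()),
        "carriers_control": int((gs.burden[~is_case] > 0).sum()),
        "statistic": float(obs),
    }
    if burden.var() == 0.0:
        result["p_permutation"] = 1.0
        return result
    rng = np.random.default_rng(seed)
    n = len(burden)
    total = burden.sum()
    # permute by drawing case subsets; statistic is affine in the case sum
    exceed = 0
    block = 1000
    done = 0
    while done < n_permutations:
        b = min(block, n_permutations - done)
        perm = np.argsort(rng.random((b, n)), axis=1)[:, :n_case]
        case_sums = burden[perm].sum(axis=1)
        stats = case_sums / n_case - (total - case_sums) / (n - n_case)
        exceed += int((np.abs(stats) >= abs(obs) - 1e-12).sum())
        done += b
    result["p_permutation"] = (exceed + 1) / (n_permutations + 1)
    return result


def burden_scan(
    g: GenotypeMatrix,
    annotations: pd.DataFrame,
    pheno: pd.DataFrame,
    maf_max: float = 0.05,
    n_permutations: int = 10_000,
    seed: int = 0,
    min_variants: int = MIN_VARIANTS_REPORTED,
) -> pd.DataFrame:
    """Filter, collapse and test every gene; report genes with at least
    min_variants qualifying variants."""
    selected = select_functional_rare(annotations, g.variant_ids, maf_max)
    gene_sets = collapse_genes(g, annotations, selected)
    pheno_cohort = pheno[pheno["cohort"] != "population"]
    keep_samples = [s for s in g.sample_ids if s in set(pheno_cohort["sample_id"])]
    rows = []
    for gene, gs in gene_sets.items():
        if len(gs.variant_ids) < min_variants:
            continue
        idx = [gs.sample_ids.index(s) for s in keep_samples]
        sub = GeneSet(gene, gs.variant_ids, gs.burden[idx], keep_samples)
        rows.append(burden_test(sub, pheno_cohort, n_permutations, seed))
    return pd.DataFrame(rows)
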