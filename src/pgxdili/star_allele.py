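"""NAT2 star-allele calling, acetylator phenotype, and risk-genotype flags.

Among Koreans the common NAT2 haplotypes are distinguishable from five
tagging SNPs — rs1041983 (c.282C>T), rs1801280 (c.341T>C), rs1799930
(c.590G>A), rs1208 (c.803A>G) and rs1799931 (c.857G>A).  Unphased dosages at
those sites are resolved into star-allele diplotypes by exhaustive
enumeration over a definition table; phase-ambiguous genotypes are scored by
an EM-estimated haplotype-frequency posterior.  Acetylator phenotype follows
the standard four-class mapping (RA *4/*4; IA *4/x; SA *5/*6, *5/*7; UA
*6/*6, *6/*7, *7/*7), extended by rule to diplotypes outside the printed
list.  The module also classifies the biallelic ATP7B rs1061472 (p.K832R)
and CYP2E1 rs3813867 genotypes and flags the combined NAT2-UA + ATP7B-832R/R
risk genotype, and applies the biochemical drug-induced liver injury (DILI)
criteria to liver-function-test values.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .io_core import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

NAT2_SNPS = ("rs1041983", "rs1801280", "rs1799930", "rs1208", "rs1799931")
ATP7B_SNP = "rs1061472"
CYP2E1_SNP = "rs3813867"

ATP7B_CLASSES = ("K/K", "K/R", "R/R")
CYP2E1_CLASSES = ("*1A/*1A", "*1A/*5", "*5/*5")

# Default star-allele definitions over the five tagging sites (1 = alt
# allele carried).  *4 is the all-reference allele; *5 carries 341C+803G,
# *6 282T+590A, *7 282T+857A, *12 803G alone.  *19 is not resolvable from
# these five sites and is omitted by default.  Override via YAML.
DEFAULT_NAT2_DEFS: dict[str, tuple[int, ...]] = {
    "*4": (0, 0, 0, 0, 0),
    "*5": (0, 1, 0, 1, 0),
    "*6": (1, 0, 1, 0, 0),
    "*7": (1, 0, 0, 0, 1),
    "*12": (0, 0, 0, 1, 0),
}

RAPID_ALLELES = frozenset({"*4", "*12"})  # normal-function alleles
UA_ALLELES = frozenset({"*6", "*7"})

# diplotypes with a literature-assigned phenotype (lexicographic pairs)
_PRINTED_MAPPING = {
    ("*4", "*4"): "RA",
    ("*4", "*5"): "IA",
    ("*4", "*6"): "IA",
    ("*4", "*7"): "IA",
    ("*12", "*4"): "IA",
    ("*19", "*4"): "IA",
    ("*5", "*6"): "SA",
    ("*5", "*7"): "SA",
    ("*6", "*6"): "UA",
    ("*6", "*7"): "UA",
    ("*7", "*7"): "UA",
}


class AlleleDefinitionTable:
    """Star-allele name -> expected alt-allele vector at the tagging sites."""

    def __init__(self, definitions: dict[str, tuple[int, ...]] | None = None):
        defs = dict(definitions or DEFAULT_NAT2_DEFS)
        n_sites = {len(v) for v in defs.values()}
        if len(n_sites) != 1:
            raise ValueError("all allele definitions must span the same sites")
        self.n_sites = n_sites.pop()
        vectors = {}
        for name, vec in defs.items():
            vec = tuple(int(x) for x in vec)
            if any(x not in (0, 1) for x in vec):
                raise ValueError(f"allele {name}: site states must be 0 (ref) or 1 (alt)")
            vectors[name] = vec
        if len(set(vectors.values())) != len(vectors):
            raise ValueError("two star alleles share an identical site vector")
        ref = tuple([0] * self.n_sites)
        if vectors.get("*4") != ref:
            raise ValueError("*4 must be the all-reference allele")
        self.vectors = vectors
        self.alleles = sorted(vectors, key=lambda a: (len(a), a))

    @classmethod
    def from_yaml(cls, path) -> "AlleleDefinitionTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls({name: tuple(vec) for name, vec in raw.items()})

    def pair_dosage(self, h1: str, h2: str) -> tuple[int, ...]:
        v1, v2 = self.vectors[h1], self.vectors[h2]
        return tuple(a + b for a, b in zip(v1, v2))


@dataclass
class StarAlleleCall:
    sample_id: str
    diplotype: tuple[str, str] | None
    phenotype: str  # RA | IA | SA | UA | unknown
    ambiguous: bool = False
    alternatives: list[tuple[tuple[str, str], float]] = field(default_factory=list)
    extended_rule: bool = False
    atp7b: str = "unknown"
    cyp2e1: str = "unknown"
    combined_risk: bool = False
    risk_flag_uncertain: bool = False


def enumerate_diplotypes(
    genotypes_5snp, defs: AlleleDefinitionTable
) -> list[tuple[str, str]]:
    """All unordered star-allele pairs consistent with the unphased dosages.

    Missing sites (dosage MISSING / None) are unconstrained.  Pairs are
    returned in lexicographic order; an empty list signals no-call.
    """
    dos = [MISSING if d is None else int(d) for d in genotypes_5snp]
    if len(dos) != defs.n_sites:
        raise ValueError(f"expected {defs.n_sites} site dosages, got {len(dos)}")
    if any(d not in (0, 1, 2, MISSING) for d in dos):
        raise ValueError("site dosages must be in {0,1,2,missing}")
    out = []
    for h1, h2 in itertools.combinations_with_replacement(defs.alleles, 2):
        summed = defs.pair_dosage(h1, h2)
        if all(d == MISSING or d == s for d, s in zip(dos, summed)):
            out.append(tuple(sorted((h1, h2))))
    return sorted(set(out))


class HaplotypeFrequencies(dict):
    """Star-allele name -> population frequency; residual mass under "other"."""

    def __init__(self, freqs: dict[str, float]):
        total = sum(freqs.values())
        if any(f < 0 for f in freqs.values()):
            raise ValueError("frequencies must be nonnegative")
        if total > 1 + 1e-9:
            raise ValueError("frequencies sum above 1")
        super().__init__(freqs)
        self.other = max(0.0, 1.0 - total)


def estimate_haplotype_frequencies(
    g: GenotypeMatrix,
    defs: AlleleDefinitionTable | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> HaplotypeFrequencies:
    """EM estimate of star-allele frequencies from unphased 5-SNP genotypes.

    Each sample contributes its enumerated diplotype list; the E step
    weights pairs by 2^het * f(h1) * f(h2), the M step recounts expected
    allele copies.  Samples with no consistent diplotype are skipped (error
    if none remain).
    """
    defs = defs or AlleleDefinitionTable()
    g5 = g.subset(variants=list(NAT2_SNPS)) if set(NAT2_SNPS) <= set(g.variant_ids) else g
    # aggregate identical unphased genotype vectors: at most 3^5 distinct
    uniq: dict[tuple, int] = {}
    for i in range(g5.n_samples):
        key = tuple(int(d) for d in g5.dosage[i])
        uniq[key] = uniq.get(key, 0) + 1
    pair_lists: list[tuple[list, int]] = []
    n_informative = 0
    for key, mult in uniq.items():
        pairs = enumerate_diplotypes(key, defs)
        if pairs:
            pair_lists.append((pairs, mult))
            n_informative += mult
    if not pair_lists:
        raise ValueError("no sample has a consistent star-allele diplotype")
    alleles = defs.alleles
    idx = {a: k for k, a in enumerate(alleles)}
    freqs = np.full(len(alleles), 1.0 / len(alleles))
    for _ in range(max_iter):
        counts = np.zeros(len(alleles))
        for pairs, mult in pair_lists:
            w = np.array(
                [(2.0 if h1 != h2 else 1.0) * freqs[idx[h1]] * freqs[idx[h2]] for h1, h2 in pairs]
            )
            tot = w.sum()
            if tot == 0:  # degenerate start; fall back to uniform over pairs
                w = np.ones(len(pairs))
                tot = w.sum()
            w *= mult / tot
            for (h1, h2), wk in zip(pairs, w):
                counts[idx[h1]] += wk
                counts[idx[h2]] += wk
        new = counts / (2.0 * n_informative)
        if np.max(np.abs(new - freqs)) < tol:
            freqs = new
            break
        freqs = new
    return HaplotypeFrequencies({a: float(freqs[idx[a]]) for a in alleles})


def acetylator_phenotype(diplotype: tuple[str, str]) -> tuple[str, bool]:
    """Map a diplotype to {RA, IA, SA, UA}; returns (phenotype, extended).

    Diplotypes outside the printed mapping are classified by rule
    generalization and flagged: both alleles ultraslow (*6/*7 set) -> UA; any
    *5 with another reduced-function allele (incl. *5/*5) -> SA; one
    normal-function allele (*4-like) with a reduced allele -> IA; both
    normal-function -> RA.
    """
    pair = tuple(sorted(diplotype))
    if pair in _PRINTED_MAPPING:
        return _PRINTED_MAPPING[pair], False
    h1, h2 = pair
    if h1 in UA_ALLELES and h2 in UA_ALLELES:
        return "UA", True
    if "*5" in pair and not (set(pair) & RAPID_ALLELES):
        return "SA", True
    n_rapid = (h1 in RAPID_ALLELES) + (h2 in RAPID_ALLELES)
    if n_rapid == 2:
        return "RA", True
    if n_rapid == 1:
        return "IA", True
    # remaining: unusual slow-slow combinations without *5 (e.g. *19/*6)
    return "SA", True


def call_nat2(
    genotypes_5snp,
    defs: AlleleDefinitionTable | None = None,
    freqs: HaplotypeFrequencies | None = None,
    sample_id: str = "",
    ambiguity_threshold: float = 0.01,
) -> StarAlleleCall:
    """Highest-posterior diplotype call and acetylator phenotype.

    The posterior over enumerated pairs is proportional to
    2^het * f(h1) * f(h2); with no frequency estimate a uniform allele
    distribution is used.  Ties go to the lexicographically smallest pair
    with the ambiguity flag set; posteriors of all retained pairs are
    reported.  Empty enumeration yields phenotype "unknown".
    """
    defs = defs or AlleleDefinitionTable()
    pairs = enumerate_diplotypes(genotypes_5snp, defs)
    if not pairs:
        return StarAlleleCall(sample_id=sample_id, diplotype=None, phenotype="unknown")
    if freqs is None:
        f = {a: 1.0 / len(defs.alleles) for a in defs.alleles}
    else:
        f = {a: freqs.get(a, 0.0) for a in defs.alleles}
    w = np.array([(2.0 if h1 != h2 else 1.0) * f[h1] * f[h2] for h1, h2 in pairs])
    if w.sum() == 0:
        w = np.ones(len(pairs))
    post = w / w.sum()
    order = np.argmax(post)
    best_p = post[order]
    # deterministic tie-break: smallest pair among posterior ties
    tied = [pairs[k] for k in range(len(pairs)) if post[k] >= best_p - 1e-12]
    best = sorted(tied)[0]
    phenotype, extended = acetylator_phenotype(best)
    supported = [(pairs[k], float(post[k])) for k in range(len(pairs)) if post[k] > ambiguity_threshold]
    return StarAlleleCall(
        sample_id=sample_id,
        diplotype=best,
        phenotype=phenotype,
        ambiguous=len(supported) > 1 or len(tied) > 1,
        alternatives=sorted(supported, key=lambda x: -x[1]),
        extended_rule=extended,
    )


def call_biallelic_class(dosage, labels) -> str:
    """Map an alt-allele dosage to (hom-ref, het, hom-alt) class labels."""
    if len(labels) != 3:
        raise ValueError("labels must name the three genotype classes")
    if dosage is None or dosage == MISSING:
        return "unknown"
    if dosage not in (0, 1, 2):
        raise ValueError(f"dosage must be 0/1/2/missing, got {dosage!r}")
    return labels[int(dosage)]


def flag_combined_risk(call: StarAlleleCall) -> bool:
    """True iff NAT2 ultraslow acetylator AND ATP7B 832R/R; unknown fields
    yield False with the uncertainty flag set on the call."""
    if call.phenotype == "unknown" or call.atp7b == "unknown":
        call.risk_flag_uncertain = True
        logger.warning("combined-risk flag uncertain for %s (unknown genotype)", call.sample_id)
        return False
    return call.phenotype == "UA" and call.atp7b == "R/R"


def classify_dili(
    alt: float | None = None,
    alt_uln: float | None = None,
    alp: float | None = None,
    alp_uln: float | None = None,
    bilirubin: float | None = None,
    bilirubin_uln: float | None = None,
) -> str:
    """Biochemical DILI call from peak liver-function values.

    DILI iff ALT >= 5x ULN, or ALP >= 2x ULN, or (ALT >= 3x ULN and total
    bilirubin >= 2x ULN).  A criterion with missing inputs evaluates False.
    """
    def ratio(v, u):
        if v is None or u is None or (isinstance(v, float) and np.isnan(v)) or (
            isinstance(u, float) and np.isnan(u)
        ):
            return None
        if u <= 0 or v < 0:
            raise ValueError("LFT values must be positive with positive ULN")
        return v / u

    r_alt = ratio(alt, alt_uln)
    r_alp = ratio(alp, alp_uln)
    r_bil = ratio(bilirubin, bilirubin_uln)
    crit1 = r_alt is not None and r_alt >= 5.0
    crit2 = r_alp is not None and r_alp >= 2.0
    crit3 = r_alt is not None and r_bil is not None and r_alt >= 3.0 and r_bil >= 2.0
    return "DILI" if (crit1 or crit2 or crit3) else "no-DILI"


class Nat2Caller:
    """Cohort-level caller with per-genotype memoization.

    Enumeration depends only on the 5-site dosage vector (243 possibilities),
    so repeated genotypes are resolved once.
    """

    def __init__(self, defs: AlleleDefinitionTable | None = None, freqs=None):
        self.defs = defs or AlleleDefinitionTable()
        self.freqs = freqs
        self._cache: dict[tuple, StarAlleleCall] = {}

    def call(self, genotypes_5snp, sample_id: str = "") -> StarAlleleCall:
        key = tuple(int(d) for d in genotypes_5snp)
        if key not in self._cache:
            self._cache[key] = call_nat2(key, self.defs, self.freqs)
        c = self._cache[key]
        return StarAlleleCall(
            sample_id=sample_id,
            diplotype=c.diplotype,
            phenotype=c.phenotype,
            ambiguous=c.ambiguous,
            alternatives=list(c.alternatives),
            extended_rule=c.extended_rule,
        )


ATP7B_REF, ATP7B_ALT = "A", "C"  # c.2495A>C, coding strand; alt encodes R832


def _risk_allele_dosage(g: GenotypeMatrix, snp: str, canonical_ref: str, canonical_alt: str):
    """Dosage of the canonical risk (alt) allele, normalizing ref/alt
    orientation against the definition when the input VCF is swapped."""
    j = g.variant_index(snp)
    col = g.dosage[:, j].copy()
    if g.ref[j] == canonical_alt and g.alt[j] == canonical_ref:
        mask0, mask2 = col == 0, col == 2
        col[mask0] = 2
        col[mask2] = 0
    return col


def call_cohort(
    g: GenotypeMatrix,
    defs: AlleleDefinitionTable | None = None,
    estimate_freqs: bool = True,
) -> pd.DataFrame:
    """Full per-sample calling for a genotype matrix containing the five NAT2
    SNPs and optionally ATP7B rs1061472 / CYP2E1 rs3813867.

    Returns a tidy calls table (one row per sample) with diplotype,
    acetylator phenotype, ambiguity and extended-rule flags, ATP7B and
    CYP2E1 classes, and the combined risk-genotype flag.
    """
    defs = defs or AlleleDefinitionTable()
    missing_snps = [s for s in NAT2_SNPS if s not in g.variant_ids]
    if missing_snps:
        raise ValueError(f"matrix lacks NAT2 tagging SNPs: {missing_snps}")
    g5 = g.subset(variants=list(NAT2_SNPS))
    freqs = estimate_haplotype_frequencies(g5, defs) if estimate_freqs else None
    caller = Nat2Caller(defs, freqs)
    atp7b = (
        _risk_allele_dosage(g, ATP7B_SNP, ATP7B_REF, ATP7B_ALT)
        if ATP7B_SNP in g.variant_ids
        else None
    )
    cyp2e1 = g.dosage_of(CYP2E1_SNP) if CYP2E1_SNP in g.variant_ids else None
    rows = []
    for i, sid in enumerate(g.sample_ids):
        call = caller.call(g5.dosage[i], sample_id=sid)
        if atp7b is not None:
            call.atp7b = call_biallelic_class(int(atp7b[i]), ATP7B_CLASSES)
        if cyp2e1 is not None:
            call.cyp2e1 = call_biallelic_class(int(cyp2e1[i]), CYP2E1_CLASSES)
        call.combined_risk = flag_combined_risk(call)
        rows.append(
            {
                "sample_id": sid,
                "diplotype": "/".join(call.diplotype) if call.diplotype else ".",
                "phenotype": call.phenotype,
                "ambiguous": call.ambiguous,
                "extended_rule": call.extended_rule,
                "atp7b": call.atp7b,
                "cyp2e1": call.cyp2e1,
                "combined_risk": call.combined_risk,
            }
        )
    return pd.DataFrame(rows)
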