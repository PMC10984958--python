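"""Synthetic case-control cohorts with the study's statistical structure.

The generator draws, per individual, two NAT2 star-allele haplotypes and an
independent biallelic ATP7B genotype under Hardy-Weinberg equilibrium, then
assigns disease status from a multiplicative logistic-odds model

    odds(case) = baseline * OR_UA^[UA] * OR_RR^[R/R] * OR_int^[UA and R/R]

and accumulates cases and controls by rejection until the requested quotas
are met (retrospective case-control design).  Default haplotype and
allele frequencies are back-solved under HWE from the Korean population
reference genotype-class frequencies (ultraslow acetylators ~12.3%, ATP7B
832R/R ~14%, co-occurrence ~1.8%), so a large simulated population
reproduces those percentages.  Peak liver-function values are drawn from
log-normal distributions anchored to the observed case/control medians and
IQRs, truncated so that every case meets at least one biochemical DILI
criterion and every control stays within reference ranges.  Null filler
variants (independent of status) are appended for association-scan tests.

All randomness flows from a single integer seed; outputs are byte-identical
across re-runs at a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import MISSING, GenotypeMatrix, write_genotypes
from .star_allele import (
    ATP7B_ALT,
    ATP7B_REF,
    ATP7B_SNP,
    DEFAULT_NAT2_DEFS,
    NAT2_SNPS,
    UA_ALLELES,
)

# hg19-style coordinates / alleles for the emitted fixture VCFs (plumbing
# metadata only; association math never touches them)
_NAT2_META = {
    "rs1041983": ("8", 18257795, "C", "T"),
    "rs1801280": ("8", 18257854, "T", "C"),
    "rs1799930": ("8", 18258103, "G", "A"),
    "rs1208": ("8", 18258316, "A", "G"),
    "rs1799931": ("8", 18258370, "G", "A"),
}
_ATP7B_META = ("13", 52534322, ATP7B_REF, ATP7B_ALT)

# sqrt(0.123) ~ 0.3507 split across *6/*7; sqrt(0.14) ~ 0.3742
DEFAULT_NAT2_FREQS = {"*4": 0.5993, "*5": 0.045, "*6": 0.2207, "*7": 0.13, "*12": 0.005}
DEFAULT_ATP7B_ALT_FREQ = 0.3742

# log-normal anchors: (median, q1, q3) of peak values; ULNs in IU/L / mg/dL
LFT_ANCHORS = {
    "case": {"alt": (349, 257, 662), "ast": (279, 196, 550), "bilirubin": (1.01, 0.59, 3.2), "alp": (180, 120, 300)},
    "control": {"alt": (17, 12, 26), "ast": (25, 20, 29), "bilirubin": (0.5, 0.40, 0.80), "alp": (70, 55, 90)},
}
ULN = {"alt": 40.0, "ast": 40.0, "bilirubin": 1.2, "alp": 120.0}

_NORM_Q3 = 0.6744897501960817  # z of the 75th percentile


@dataclass
class SimulationConfig:
    """Generating parameters; defaults match the combined study cohort."""

    n_cases: int = 72
    n_controls: int = 205
    n_population: int = 1048
    nat2_freqs: dict = field(default_factory=lambda: dict(DEFAULT_NAT2_FREQS))
    atp7b_alt_freq: float = DEFAULT_ATP7B_ALT_FREQ
    baseline_odds: float = 0.05
    or_ua: float = 5.6
    or_rr: float = 2.0
    or_interaction: float = 2.9
    n_null_variants: int = 50
    null_maf_range: tuple = (0.05, 0.5)
    missing_rate: float = 0.0
    gq_value: int = 99
    dp_value: int = 100
    seed: int = 0
    max_batches: int = 2000

    def __post_init__(self) -> None:
        tot = sum(self.nat2_freqs.values())
        if abs(tot - 1.0) > 1e-6:
            raise ValueError(f"NAT2 haplotype frequencies sum to {tot}, not 1")
        if any(f < 0 for f in self.nat2_freqs.values()):
            raise ValueError("haplotype frequencies must be nonnegative")
        if not 0.0 <= self.atp7b_alt_freq <= 1.0:
            raise ValueError("atp7b_alt_freq must be in [0, 1]")
        for name in ("baseline_odds", "or_ua", "or_rr", "or_interaction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _draw_genotypes(cfg: SimulationConfig, n: int, rng: np.random.Generator):
    """HWE draws: haplotype index pairs, ATP7B dosage, risk indicators."""
    alleles = list(cfg.nat2_freqs)
    probs = np.array([cfg.nat2_freqs[a] for a in alleles])
    h1 = rng.choice(len(alleles), size=n, p=probs)
    h2 = rng.choice(len(alleles), size=n, p=probs)
    atp7b = rng.binomial(2, cfg.atp7b_alt_freq, size=n)
    ua_idx = np.array([a in UA_ALLELES for a in alleles])
    is_ua = ua_idx[h1] & ua_idx[h2]
    is_rr = atp7b == 2
    return alleles, h1, h2, atp7b, is_ua, is_rr


def _case_probability(cfg: SimulationConfig, is_ua, is_rr) -> np.ndarray:
    odds = cfg.baseline_odds * np.where(is_ua, cfg.or_ua, 1.0) * np.where(
        is_rr, cfg.or_rr, 1.0
    ) * np.where(is_ua & is_rr, cfg.or_interaction, 1.0)
    return odds / (1.0 + odds)


def _genotype_matrix(cfg, alleles, h1, h2, atp7b, sample_ids, rng) -> GenotypeMatrix:
    vecs = np.array([DEFAULT_NAT2_DEFS.get(a, (0,) * 5) for a in alleles])
    nat2_dos = vecs[h1] + vecs[h2]  # (n, 5), unphased dosages
    n = len(sample_ids)
    cols = [nat2_dos[:, k] for k in range(5)] + [atp7b]
    ids = list(NAT2_SNPS) + [ATP7B_SNP]
    chrom = [_NAT2_META[s][0] for s in NAT2_SNPS] + [_ATP7B_META[0]]
    pos = [_NAT2_META[s][1] for s in NAT2_SNPS] + [_ATP7B_META[1]]
    ref = [_NAT2_META[s][2] for s in NAT2_SNPS] + [_ATP7B_META[2]]
    alt = [_NAT2_META[s][3] for s in NAT2_SNPS] + [_ATP7B_META[3]]
    if cfg.n_null_variants:
        mafs = rng.uniform(*cfg.null_maf_range, size=cfg.n_null_variants)
        for k in range(cfg.n_null_variants):
            cols.append(rng.binomial(2, mafs[k], size=n))
            ids.append(f"null{k:04d}")
            chrom.append(str(1 + k % 22))
            pos.append(1_000_000 + 100 * k)
            ref.append("A")
            alt.append("G")
    dosage = np.column_stack(cols).astype(np.int16)
    if cfg.missing_rate > 0:
        mask = rng.random(dosage.shape) < cfg.missing_rate
        dosage[mask] = MISSING
    shape = dosage.shape
    return GenotypeMatrix(
        sample_ids=list(sample_ids),
        variant_ids=ids,
        dosage=dosage,
        gq=np.full(shape, cfg.gq_value, dtype=np.int32),
        dp=np.full(shape, cfg.dp_value, dtype=np.int32),
        chrom=chrom,
        pos=np.array(pos),
        ref=ref,
        alt=alt,
    )


def simulate_lft(status: str, rng: np.random.Generator, n: int = 1) -> pd.DataFrame:
    """Log-normal LFT peak values anchored to the cohort medians/IQRs.

    Case ALT is truncated above five times its upper limit of normal, so
    every case meets the first biochemical DILI criterion; control values
    are truncated below their ULNs (reference range), so no control meets
    any criterion.
    """
    if status not in ("case", "control"):
        raise ValueError(f"status must be case or control, got {status!r}")
    anchors = LFT_ANCHORS[status]
    out = {}
    for marker, (med, q1, q3) in anchors.items():
        mu = np.log(med)
        sigma = (np.log(q3) - np.log(q1)) / (2.0 * _NORM_Q3)
        if status == "case" and marker == "alt":
            lo, hi = np.log(5.0 * ULN[marker]), np.inf
        elif status == "control":
            lo, hi = -np.inf, np.log(ULN[marker])
        else:
            lo, hi = -np.inf, np.inf
        from scipy.stats import norm

        u_lo = norm.cdf((lo - mu) / sigma) if np.isfinite(lo) else 0.0
        u_hi = norm.cdf((hi - mu) / sigma) if np.isfinite(hi) else 1.0
        u = rng.uniform(u_lo, u_hi, size=n)
        out[marker] = np.exp(mu + sigma * norm.ppf(u))
        out[f"{marker}_uln"] = np.full(n, ULN[marker])
    return pd.DataFrame(out)


def simulate_cohort(cfg: SimulationConfig):
    """Generate (GenotypeMatrix, phenotype DataFrame, truth dict).

    Cases and controls are accumulated by rejection sampling from the
    population model until both quotas are met; a bounded number of batches
    guards against unattainable configurations.  The phenotype table also
    carries an all-control population panel of size n_population.  The truth
    record stores the generating parameters and every latent diplotype.
    """
    rng = np.random.default_rng(cfg.seed)
    batch = max(1000, 4 * (cfg.n_cases + cfg.n_controls))
    kept: list[dict] = []
    n_cases = n_controls = 0
    for _ in range(cfg.max_batches):
        alleles, h1, h2, atp7b, is_ua, is_rr = _draw_genotypes(cfg, batch, rng)
        p = _case_probability(cfg, is_ua, is_rr)
        case = rng.random(batch) < p
        take_case = np.flatnonzero(case)[: cfg.n_cases - n_cases]
        take_ctrl = np.flatnonzero(~case)[: cfg.n_controls - n_controls]
        for idx, label in ((take_case, "case"), (take_ctrl, "control")):
            for i in idx:
                kept.append(dict(h1=h1[i], h2=h2[i], atp7b=atp7b[i], status=label))
        n_cases += len(take_case)
        n_controls += len(take_ctrl)
        if n_cases == cfg.n_cases and n_controls == cfg.n_controls:
            break
    else:
        raise RuntimeError(
            f"case/control quotas unattainable after {cfg.max_batches} batches "
            f"(got {n_cases}/{cfg.n_cases} cases, {n_controls}/{cfg.n_controls} controls)"
        )
    # population panel: plain HWE draws, no phenotype
    alleles, ph1, ph2, patp, _, _ = _draw_genotypes(cfg, cfg.n_population, rng)

    h1_all = np.array([r["h1"] for r in kept] + list(ph1))
    h2_all = np.array([r["h2"] for r in kept] + list(ph2))
    atp_all = np.array([r["atp7b"] for r in kept] + list(patp))
    n_cohort = len(kept)
    sample_ids = [f"S{i:05d}" for i in range(n_cohort + cfg.n_population)]
    g = _genotype_matrix(cfg, alleles, h1_all, h2_all, atp_all, sample_ids, rng)

    status = [r["status"] for r in kept]
    # deterministic cohort split mirroring the two-stage study design
    cohort_label = []
    case_seen = ctrl_seen = 0
    n_disc_cases = round(cfg.n_cases * 35 / 72)
    n_disc_ctrls = round(cfg.n_controls * 77 / 205)
    for s in status:
        if s == "case":
            cohort_label.append("discovery" if case_seen < n_disc_cases else "replication")
            case_seen += 1
        else:
            cohort_label.append("discovery" if ctrl_seen < n_disc_ctrls else "replication")
            ctrl_seen += 1
    pheno_rows = pd.DataFrame(
        {
            "sample_id": sample_ids[:n_cohort],
            "status": status,
            "cohort": cohort_label,
        }
    )
    lft_parts = []
    for s in ("case", "control"):
        idx = pheno_rows.index[pheno_rows["status"] == s]
        lft = simulate_lft(s, rng, n=len(idx))
        lft.index = idx
        lft_parts.append(lft)
    pheno = pd.concat([pheno_rows, pd.concat(lft_parts).sort_index()], axis=1)
    pop = pd.DataFrame(
        {
            "sample_id": sample_ids[n_cohort:],
            "status": "control",
            "cohort": "population",
        }
    )
    pheno = pd.concat([pheno, pop], ignore_index=True)

    truth = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
        "alleles": alleles,
        "diplotypes": {
            sid: sorted((alleles[int(a)], alleles[int(b)]))
            for sid, a, b in zip(sample_ids, h1_all, h2_all)
        },
        "atp7b_dosage": {sid: int(d) for sid, d in zip(sample_ids, atp_all)},
    }
    return g, pheno, truth


def write_fixture(cfg: SimulationConfig, outdir) -> dict[str, Path]:
    """Emit VCF + phenotype TSV + annotation TSV + truth JSON for a config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g, pheno, truth = simulate_cohort(cfg)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "pheno": outdir / "phenotypes.tsv",
        "annotation": outdir / "annotations.tsv",
        "truth": outdir / "truth.json",
    }
    write_genotypes(g, paths["vcf"], "vcf")
    pheno.to_csv(paths["pheno"], sep="\t", index=False)
    ann = pd.DataFrame(
        {
            "variant_id": g.variant_ids,
            "gene": ["NAT2"] * 5 + ["ATP7B"] + [f"GENE{k % 20:02d}" for k in range(g.n_variants - 6)],
            "functional_class": ["missense"] * 6 + ["other"] * (g.n_variants - 6),
            "junction_distance_bp": 100,
            "population_af": 0.2,
        }
    )
    ann.to_csv(paths["annotation"], sep="\t", index=False)
    paths["truth"].write_text(json.dumps(truth, indent=1, default=str) + "\n")
    return paths
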