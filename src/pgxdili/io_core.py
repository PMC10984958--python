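"""Input/output and genotype-level quality control.

Genotypes enter either as VCF 4.x (GT with optional GQ/DP, read through
cyvcf2) or as a plain sample x variant dosage TSV.  Phenotype and variant
annotation tables are TSVs with headers; run configuration is YAML.  The QC
operation reproduces a standard germline genotype-refinement filter: per-call
GQ/DP thresholds, per-variant missingness, and an exact Hardy-Weinberg
deviation test evaluated on a designated sample group (controls by default,
since cases may deviate under a true association).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exact_stats import hwe_exact_p

logger = logging.getLogger(__name__)

MISSING = -1  # sentinel for missing dosage / unknown GQ / unknown DP

STATUS_VALUES = ("case", "control")
COHORT_VALUES = ("discovery", "replication", "population")
FUNCTIONAL_CLASSES = ("missense", "nonsense", "frameshift", "splicing", "other")


class VcfParseError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Samples x variants unphased diploid dosage matrix with call metadata.

    dosage counts alt alleles per call (0/1/2, MISSING for no-call); gq and
    dp carry per-call genotype quality and depth, MISSING where unknown.
    Positions are 1-based as in VCF.  Variants are keyed by rsID when one is
    present, else "chrom:pos:ref:alt".
    """

    sample_ids: list[str]
    variant_ids: list[str]
    dosage: np.ndarray  # (n_samples, n_variants) int16
    gq: np.ndarray
    dp: np.ndarray
    chrom: list[str]
    pos: np.ndarray  # int64, 1-based
    ref: list[str]
    alt: list[str]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int16)
        self.gq = np.asarray(self.gq, dtype=np.int32)
        self.dp = np.asarray(self.dp, dtype=np.int32)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        ns, nv = len(self.sample_ids), len(self.variant_ids)
        if len(set(self.sample_ids)) != ns:
            raise ValueError("duplicate sample ids")
        if len(set(self.variant_ids)) != nv:
            raise ValueError("duplicate variant ids")
        for arr, name in ((self.dosage, "dosage"), (self.gq, "gq"), (self.dp, "dp")):
            if arr.shape != (ns, nv):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(ns, nv)}")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"dosage values outside {{0,1,2,missing}} at {np.argwhere(bad)[0]}")
        if not (len(self.chrom) == len(self.ref) == len(self.alt) == len(self.pos) == nv):
            raise ValueError("per-variant metadata length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def variant_index(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"variant {variant_id!r} not in matrix") from None

    def dosage_of(self, variant_id: str) -> np.ndarray:
        return self.dosage[:, self.variant_index(variant_id)]

    def subset(self, samples=None, variants=None) -> "GenotypeMatrix":
        si = (
            np.arange(self.n_samples)
            if samples is None
            else np.asarray([self.sample_ids.index(s) for s in samples])
        )
        vi = (
            np.arange(self.n_variants)
            if variants is None
            else np.asarray([self.variant_index(v) for v in variants])
        )
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in si],
            variant_ids=[self.variant_ids[j] for j in vi],
            dosage=self.dosage[np.ix_(si, vi)],
            gq=self.gq[np.ix_(si, vi)],
            dp=self.dp[np.ix_(si, vi)],
            chrom=[self.chrom[j] for j in vi],
            pos=self.pos[vi],
            ref=[self.ref[j] for j in vi],
            alt=[self.alt[j] for j in vi],
        )

    def drop_sex_chromosomes(self) -> "GenotypeMatrix":
        keep = [
            v
            for v, c in zip(self.variant_ids, self.chrom)
            if c.removeprefix("chr").upper() not in ("X", "Y")
        ]
        return self.subset(variants=keep)


@dataclass
class QCReport:
    gq_min: int
    dp_min: int
    max_missing_frac: float
    hwe_alpha: float
    n_calls_masked: int = 0
    removed: dict[str, str] = field(default_factory=dict)  # variant_id -> reason

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


def _variant_key(rsid: str | None, chrom: str, pos: int, ref: str, alt: str) -> str:
    if rsid and rsid not in (".", ""):
        return rsid
    return f"{chrom}:{pos}:{ref}:{alt}"


def read_genotypes(path, format_hint: str | None = None) -> GenotypeMatrix:
    """Read genotypes from VCF (via cyvcf2) or dosage TSV.

    The format is taken from format_hint ("vcf" | "tsv") or inferred from the
    file suffix.  Multi-allelic VCF records are rejected with a parse error
    (split them upstream with e.g. ``bcftools norm``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint or ("vcf" in path.suffix.lower() and "vcf" or "tsv")
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValueError(f"duplicate sample ids in {path}")
    ids, chrom, pos, ref, alt = [], [], [], [], []
    dos_cols, gq_cols, dp_cols = [], [], []
    for i, v in enumerate(vcf):
        if len(v.ALT) != 1:
            raise VcfParseError(
                f"{path}: record {i + 1} ({v.CHROM}:{v.POS}) is not biallelic; "
                "split multi-allelic sites before loading"
            )
        gts = np.array([g[:2] for g in v.genotypes], dtype=np.int16)
        dos = gts.sum(axis=1)
        dos[(gts < 0).any(axis=1)] = MISSING
        try:
            gq = np.nan_to_num(v.gt_quals, nan=float(MISSING)).astype(np.int32)
        except Exception:
            gq = np.full(len(samples), MISSING, dtype=np.int32)
        gq[gq < 0] = MISSING
        dp_raw = v.format("DP")
        if dp_raw is None:
            dp = np.full(len(samples), MISSING, dtype=np.int32)
        else:
            dp = dp_raw.reshape(-1).astype(np.int32)
            dp[dp < 0] = MISSING
        ids.append(_variant_key(v.ID, v.CHROM, v.POS, v.REF, v.ALT[0]))
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        dos_cols.append(dos)
        gq_cols.append(gq)
        dp_cols.append(dp)
    if not ids:
        raise VcfParseError(f"{path}: no variant records")
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate variant ids in {path}")
    return GenotypeMatrix(
        sample_ids=samples,
        variant_ids=ids,
        dosage=np.column_stack(dos_cols),
        gq=np.column_stack(gq_cols),
        dp=np.column_stack(dp_cols),
        chrom=chrom,
        pos=np.array(pos),
        ref=ref,
        alt=alt,
    )


def _read_tsv(path: Path) -> GenotypeMatrix:
    """Dosage TSV: first column sample_id, remaining columns variant ids;
    cells in {0,1,2} or empty/NA for missing.  Variant metadata is synthesized
    (unknown chromosome, position 0) since a bare dosage matrix carries none."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    sample_ids = df.iloc[:, 0].tolist()
    variant_ids = list(df.columns[1:])
    dosage = df.iloc[:, 1:].to_numpy(dtype=float)
    dosage = np.where(np.isnan(dosage), MISSING, dosage).astype(np.int16)
    ns, nv = dosage.shape
    full = np.full((ns, nv), MISSING, dtype=np.int32)
    return GenotypeMatrix(
        sample_ids=sample_ids,
        variant_ids=variant_ids,
        dosage=dosage,
        gq=full.copy(),
        dp=full.copy(),
        chrom=["."] * nv,
        pos=np.zeros(nv, dtype=np.int64),
        ref=["."] * nv,
        alt=["."] * nv,
    )


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=pgxdili
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">
"""

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_genotypes(g: GenotypeMatrix, path, format_hint: str | None = None) -> None:
    path = Path(path)
    fmt = format_hint or ("vcf" in path.suffix.lower() and "vcf" or "tsv")
    if fmt == "tsv":
        df = pd.DataFrame(
            np.where(g.dosage == MISSING, np.nan, g.dosage),
            index=pd.Index(g.sample_ids, name="sample_id"),
            columns=g.variant_ids,
        )
        df.to_csv(path, sep="\t", float_format="%.0f")
        return
    lines = [_VCF_HEADER + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(g.sample_ids)]
    for j, vid in enumerate(g.variant_ids):
        cells = []
        for i in range(g.n_samples):
            gt = _GT_STRINGS[int(g.dosage[i, j])]
            gq = "." if g.gq[i, j] == MISSING else str(int(g.gq[i, j]))
            dp = "." if g.dp[i, j] == MISSING else str(int(g.dp[i, j]))
            cells.append(f"{gt}:{gq}:{dp}")
        rsid = vid if not vid.count(":") else "."
        lines.append(
            f"{g.chrom[j]}\t{g.pos[j]}\t{rsid}\t{g.ref[j]}\t{g.alt[j]}\t.\tPASS\t.\tGT:GQ:DP\t"
            + "\t".join(cells)
        )
    path.write_text("\n".join(lines) + "\n")


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype TSV: sample_id, status (case|control), cohort
    (discovery|replication|population), optional LFT peak values and ULNs
    (alt, ast, bilirubin, alp, *_uln)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "status", "cohort"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return validate_phenotypes(df)


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate phenotype row for sample {dup!r}")
    bad = set(df["status"]) - set(STATUS_VALUES)
    if bad:
        raise ValueError(f"unknown status values: {sorted(bad)}")
    bad = set(df["cohort"]) - set(COHORT_VALUES)
    if bad:
        raise ValueError(f"unknown cohort labels: {sorted(bad)}")
    return df


def read_annotations(path) -> pd.DataFrame:
    """Variant annotation TSV: variant_id, gene, functional_class,
    junction_distance_bp, population_af."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "gene": str})
    required = {"variant_id", "gene", "functional_class", "population_af"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    bad = set(df["functional_class"]) - set(FUNCTIONAL_CLASSES)
    if bad:
        raise ValueError(f"unknown functional classes: {sorted(bad)}")
    af = df["population_af"]
    if ((af < 0) | (af > 1)).any():
        raise ValueError("population_af outside [0, 1]")
    return df


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def apply_genotype_qc(
    g: GenotypeMatrix,
    gq_min: int = 20,
    dp_min: int = 20,
    max_missing_frac: float = 0.10,
    hwe_alpha: float = 1e-6,
    hwe_group: list[str] | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Genotype-refinement QC.

    Calls with known GQ < gq_min or known DP < dp_min are set missing
    (unknown GQ/DP passes).  Variants are then removed when their missing
    fraction exceeds max_missing_frac or the exact HWE P computed on
    hwe_group (all samples when None) falls below hwe_alpha.  The operation
    is idempotent at fixed thresholds.
    """
    if gq_min < 0 or dp_min < 0:
        raise ValueError("GQ/DP thresholds must be nonnegative")
    if not 0 <= max_missing_frac <= 1:
        raise ValueError("max_missing_frac must be in [0, 1]")
    report = QCReport(gq_min, dp_min, max_missing_frac, hwe_alpha)
    dosage = g.dosage.copy()
    low_q = ((g.gq != MISSING) & (g.gq < gq_min)) | ((g.dp != MISSING) & (g.dp < dp_min))
    report.n_calls_masked = int((low_q & (dosage != MISSING)).sum())
    dosage[low_q] = MISSING

    if hwe_group is None:
        grp = np.arange(g.n_samples)
    else:
        if len(hwe_group) == 0:
            raise ValueError("hwe_group must be nonempty")
        grp = np.asarray([g.sample_ids.index(s) for s in hwe_group])

    keep = []
    for j, vid in enumerate(g.variant_ids):
        col = dosage[:, j]
        miss_frac = float((col == MISSING).mean())
        if miss_frac > max_missing_frac:
            report.removed[vid] = "missingness"
            continue
        sub = col[grp]
        sub = sub[sub != MISSING]
        if sub.size:
            counts = (int((sub == 0).sum()), int((sub == 1).sum()), int((sub == 2).sum()))
            if hwe_exact_p(counts) < hwe_alpha:
                report.removed[vid] = "hwe"
                continue
        keep.append(j)

    if not keep:
        logger.warning("QC removed every variant")
    out = GenotypeMatrix(
        sample_ids=list(g.sample_ids),
        variant_ids=[g.variant_ids[j] for j in keep],
        dosage=dosage[:, keep],
        gq=g.gq[:, keep],
        dp=g.dp[:, keep],
        chrom=[g.chrom[j] for j in keep],
        pos=g.pos[keep],
        ref=[g.ref[j] for j in keep],
        alt=[g.alt[j] for j in keep],
    )
    return out, report
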