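"""Readers and writers for every external format the pipeline touches.

Three file families are supported, all plain text:

* **weights table** — TSV with columns ``snp_id, chrom, pos, effect_allele,
  other_allele, or`` defining the risk-allele panel; the per-allele weight is
  the natural log of the odds ratio.
* **genotypes** — either VCF v4.2 (GT field, biallelic records) or a dosage
  TSV (first column ``sample_id``, one column per SNP, cells in
  ``{0, 1, 2, NA}``).  Entries are *effect-allele counts*.
* **phenotypes** — CSV with columns ``sample_id, sex, is_case,
  family_history, early_onset, bilateral, ectopic, recurrence``; binary
  fields coded ``0/1/NA`` (sex: 0 = female, 1 = male).

Effect-allele semantics are strict: a VCF record is matched to a panel SNP by
exact id *and* exact allele set; mismatched alleles raise
:class:`~wgrs.errors.AlleleMismatchError` rather than attempting a strand
flip.  Missing genotypes are ``./.`` or ``.`` in VCF and ``NA`` elsewhere; no
other sentinel is accepted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AlleleMismatchError, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "WeightEntry",
    "WeightPanel",
    "GenotypeMatrix",
    "PhenotypeTable",
    "PHENOTYPE_COLUMNS",
    "BINARY_PHENOTYPES",
    "CASE_ONLY_PHENOTYPES",
    "read_weight_table",
    "write_weight_table",
    "read_genotypes_vcf",
    "write_genotypes_vcf",
    "read_dosage_matrix",
    "write_dosage_matrix",
    "read_phenotypes",
    "write_phenotypes",
]

WEIGHT_COLUMNS = ["snp_id", "chrom", "pos", "effect_allele", "other_allele", "or"]
PHENOTYPE_COLUMNS = [
    "sample_id",
    "sex",
    "is_case",
    "family_history",
    "early_onset",
    "bilateral",
    "ectopic",
    "recurrence",
]
BINARY_PHENOTYPES = PHENOTYPE_COLUMNS[1:]
#: phenotypes defined only for cases (controls carry NA)
CASE_ONLY_PHENOTYPES = ["family_history", "early_onset", "bilateral", "ectopic", "recurrence"]


@dataclass(frozen=True)
class WeightEntry:
    """One panel SNP with its per-effect-allele weight ``ln(OR)``."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    odds_ratio: float
    weight: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise FormatError(f"{self.snp_id}: pos must be a positive 1-based coordinate")
        if not self.effect_allele or not self.other_allele:
            raise FormatError(f"{self.snp_id}: alleles must be non-empty")
        if self.effect_allele == self.other_allele:
            raise FormatError(f"{self.snp_id}: effect and other allele are identical")
        if not (self.odds_ratio > 0):
            raise FormatError(f"{self.snp_id}: odds ratio must be > 0, got {self.odds_ratio}")
        if self.weight is None:
            object.__setattr__(self, "weight", math.log(self.odds_ratio))
        elif abs(self.weight - math.log(self.odds_ratio)) > 1e-12:
            raise FormatError(f"{self.snp_id}: weight is not ln(odds_ratio)")


@dataclass(frozen=True)
class WeightPanel:
    """Ordered SNP panel; ``panel_size`` is the rescaling constant N."""

    entries: tuple[WeightEntry, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        ids = [e.snp_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate snp_id in panel: {dupes}")

    @property
    def panel_size(self) -> int:
        return len(self.entries)

    @property
    def snp_ids(self) -> list[str]:
        return [e.snp_id for e in self.entries]

    @property
    def weights(self) -> np.ndarray:
        return np.array([e.weight for e in self.entries], dtype=float)

    def entry(self, snp_id: str) -> WeightEntry:
        for e in self.entries:
            if e.snp_id == snp_id:
                return e
        raise KeyError(snp_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": [e.snp_id for e in self.entries],
                "chrom": [e.chrom for e in self.entries],
                "pos": [e.pos for e in self.entries],
                "effect_allele": [e.effect_allele for e in self.entries],
                "other_allele": [e.other_allele for e in self.entries],
                "or": [e.odds_ratio for e in self.entries],
            }
        )


@dataclass(frozen=True)
class GenotypeMatrix:
    """Samples x SNPs table of effect-allele counts; NaN marks missing.

    ``counts`` is indexed by sample id with one column per SNP, in panel
    order.  Every non-missing cell is 0, 1 or 2.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise FormatError("duplicate sample_id in genotype matrix")
        vals = c.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"genotype count outside {{0,1,2,NA}}: sample {c.index[i]!r}, "
                f"snp {c.columns[j]!r}, value {vals[i, j]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.counts.columns)

    def n_genotyped(self) -> pd.Series:
        """Number of non-missing SNPs per sample (the score formula's n)."""
        return self.counts.notna().sum(axis=1)


@dataclass(frozen=True)
class PhenotypeTable:
    """Per-sample clinical table; NaN marks missing.

    Indexed by sample id with the seven binary columns of
    :data:`BINARY_PHENOTYPES`.  Diathesis features and recurrence are defined
    only for cases; controls carry NA there by construction.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        if d.index.has_duplicates:
            raise FormatError("duplicate sample_id in phenotype table")
        missing_cols = [c for c in BINARY_PHENOTYPES if c not in d.columns]
        if missing_cols:
            raise FormatError(f"phenotype table missing columns: {missing_cols}")
        for col in BINARY_PHENOTYPES:
            vals = d[col].to_numpy(dtype=float)
            bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0)))
            if bad.any():
                i = int(np.argwhere(bad)[0][0])
                raise FormatError(
                    f"non-binary code in {col!r}: sample {d.index[i]!r}, value {vals[i]!r}"
                )
        controls = d["is_case"] == 0
        for col in CASE_ONLY_PHENOTYPES:
            if d.loc[controls, col].notna().any():
                raise FormatError(f"{col!r} must be NA for controls (case-only phenotype)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def cases(self) -> pd.DataFrame:
        return self.data[self.data["is_case"] == 1]


# ---------------------------------------------------------------------------
# weights table


def read_weight_table(path: str | Path) -> WeightPanel:
    """Read a tab-separated SNP weights table into a :class:`WeightPanel`."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    missing = [c for c in WEIGHT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"weights table {path}: missing columns {missing}")
    entries = []
    for row in df.to_dict("records"):
        entries.append(
            WeightEntry(
                snp_id=str(row["snp_id"]),
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                effect_allele=str(row["effect_allele"]),
                other_allele=str(row["other_allele"]),
                odds_ratio=float(row["or"]),
            )
        )
    return WeightPanel(tuple(entries))


def write_weight_table(panel: WeightPanel, path: str | Path) -> None:
    panel.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes: VCF


def read_genotypes_vcf(path: str | Path, panel: WeightPanel) -> GenotypeMatrix:
    """Read effect-allele counts from a VCF, matched to ``panel``.

    A record is used only when its ID equals a panel ``snp_id`` and
    ``{REF, ALT}`` equals the panel's ``{effect_allele, other_allele}``.
    Panel SNPs absent from the file become all-missing columns (warned).
    Allele mismatches and multiallelic records matching a panel id are hard
    errors — no strand flipping is ever attempted.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    by_id = {e.snp_id: e for e in panel.entries}
    cols: dict[str, np.ndarray] = {}
    for variant in vcf:
        entry = by_id.get(variant.ID)
        if entry is None:
            continue
        if variant.ID in cols:
            raise FormatError(f"VCF {path}: duplicate record for panel SNP {variant.ID}")
        if len(variant.ALT) != 1:
            raise FormatError(
                f"VCF {path}: panel SNP {variant.ID} is multiallelic (ALT={variant.ALT})"
            )
        ref, alt = variant.REF, variant.ALT[0]
        if {ref, alt} != {entry.effect_allele, entry.other_allele}:
            raise AlleleMismatchError(
                f"VCF {path}: SNP {variant.ID} alleles {{{ref},{alt}}} do not match "
                f"panel {{{entry.effect_allele},{entry.other_allele}}}"
            )
        gts = np.asarray([g[:2] for g in variant.genotypes], dtype=int)
        missing = (gts < 0).any(axis=1)
        alt_count = (gts == 1).sum(axis=1).astype(float)
        counts = alt_count if alt == entry.effect_allele else 2.0 - alt_count
        counts[missing] = np.nan
        cols[variant.ID] = counts
    for snp_id in panel.snp_ids:
        if snp_id not in cols:
            logger.warning("panel SNP %s absent from VCF %s; set missing for all samples", snp_id, path)
            cols[snp_id] = np.full(len(samples), np.nan)
    frame = pd.DataFrame({sid: cols[sid] for sid in panel.snp_ids}, index=pd.Index(samples, name="sample_id"))
    return GenotypeMatrix(frame)


def write_genotypes_vcf(matrix: GenotypeMatrix, panel: WeightPanel, path: str | Path) -> None:
    """Write a minimal VCF v4.2 (GT only) with the effect allele as ALT."""
    lines = ["##fileformat=VCFv4.2", '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    chroms = []
    for e in panel.entries:
        if e.chrom not in chroms:
            chroms.append(e.chrom)
    lines.extend(f"##contig=<ID={c}>" for c in chroms)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(matrix.sample_ids))
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for e in panel.entries:
        if e.snp_id not in matrix.counts.columns:
            continue
        col = matrix.counts[e.snp_id]
        calls = ["./." if pd.isna(v) else gt_code[float(v)] for v in col]
        lines.append(
            f"{e.chrom}\t{e.pos}\t{e.snp_id}\t{e.other_allele}\t{e.effect_allele}\t.\tPASS\t.\tGT\t"
            + "\t".join(calls)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# genotypes: dosage TSV


def read_dosage_matrix(path: str | Path, panel: WeightPanel) -> GenotypeMatrix:
    """Read a dosage TSV (sample_id + one {0,1,2,NA} column per SNP)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, na_values=["NA"], keep_default_na=False)
    if "sample_id" not in df.columns:
        raise FormatError(f"dosage matrix {path}: missing sample_id column")
    df = df.set_index("sample_id")
    known = set(panel.snp_ids)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        logger.warning("dosage matrix %s: ignoring unknown SNP columns %s", path, unknown)
        df = df.drop(columns=unknown)
    for snp_id in panel.snp_ids:
        if snp_id not in df.columns:
            logger.warning("panel SNP %s absent from dosage matrix %s; set missing", snp_id, path)
            df[snp_id] = np.nan
    try:
        vals = df[panel.snp_ids].astype(float)
    except ValueError as exc:
        raise FormatError(f"dosage matrix {path}: non-numeric genotype cell ({exc})") from exc
    return GenotypeMatrix(vals)  # cell-domain check happens in the constructor


def write_dosage_matrix(matrix: GenotypeMatrix, path: str | Path) -> None:
    out = matrix.counts.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


# ---------------------------------------------------------------------------
# phenotypes


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read the phenotype CSV; binary fields coded 0/1/NA."""
    df = pd.read_csv(path, dtype={"sample_id": str}, na_values=["NA"], keep_default_na=False)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"phenotype table {path}: missing columns {missing}")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"phenotype table {path}: duplicate sample_id")
    df = df.set_index("sample_id")
    try:
        df = df[BINARY_PHENOTYPES].astype(float)
    except ValueError as exc:
        raise FormatError(f"phenotype table {path}: non-numeric code ({exc})") from exc
    return PhenotypeTable(df)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    out = table.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, na_rep="NA", float_format="%.0f")
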