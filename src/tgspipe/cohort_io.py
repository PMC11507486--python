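"""In-memory cohort containers and readers/writers for the standard file formats.

The central object is :class:`GenotypeMatrix`: an ordered samples x variants
grid of alternate-allele dosages (0, 1, 2, or missing encoded as NaN) together
with per-variant and per-sample metadata.  Dosage counts copies of the VCF
*alt* allele — the only allele orientation available after imputation — so an
odds ratio downstream is always the odds ratio of the alt allele.

Coordinate conventions: VCF positions are 1-based and kept 1-based internally;
BED intervals are 0-based half-open, converted on read.  Multi-allelic VCF
records are rejected rather than split: the candidate panels this package
consumes are rsID-keyed biallelic entries, and silently splitting a record
would change allele semantics.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortIOError",
    "MultiAllelicError",
    "Variant",
    "SampleRecord",
    "GenotypeMatrix",
    "PanelEntry",
    "CandidatePanel",
    "MergeReport",
    "read_genotypes",
    "write_vcf",
    "read_phenotypes",
    "write_phenotypes",
    "read_panel",
    "write_panel",
    "intersect_panel",
    "merge_cohorts",
    "annotate_nearest_gene",
    "attach_phenotypes",
]


class CohortIOError(ValueError):
    """Malformed or inconsistent cohort input."""


class MultiAllelicError(CohortIOError):
    """Multi-allelic VCF record; normalize (split) the file upstream first."""


_PHENOTYPE_TOKENS = {
    "athlete": "case",
    "case": "case",
    "1": "case",
    "control": "control",
    "0": "control",
}

_SEX_TOKENS = {"male": "male", "m": "male", "female": "female", "f": "female"}


@dataclass(frozen=True)
class Variant:
    """A biallelic variant with optional imputation quality and trait labels."""

    rsid: str
    chrom: str
    pos: int
    ref: str
    alt: str
    info_score: float | None = None
    traits: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise CohortIOError(f"{self.rsid}: position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise CohortIOError(f"{self.rsid}: alleles must be non-empty")
        if self.info_score is not None and not (0.0 <= self.info_score <= 1.0):
            raise CohortIOError(
                f"{self.rsid}: info score {self.info_score} outside [0, 1]"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Position/allele identity used when merging cohorts."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != 1 or len(self.alt) != 1


@dataclass(frozen=True)
class SampleRecord:
    """One study participant.

    ``phenotype`` is "case" (athlete) or "control"; it may be None for a
    genotype file read before phenotypes are attached.  ``subgroup`` carries
    labels such as elite/sub-elite as metadata only.
    """

    sample_id: str
    phenotype: str | None = None
    reported_sex: str = "unknown"
    subgroup: str | None = None

    def __post_init__(self) -> None:
        if self.phenotype not in (None, "case", "control"):
            raise CohortIOError(
                f"{self.sample_id}: phenotype must be case/control, got {self.phenotype!r}"
            )
        if self.reported_sex not in ("male", "female", "unknown"):
            raise CohortIOError(
                f"{self.sample_id}: sex must be male/female/unknown, got {self.reported_sex!r}"
            )

    @property
    def is_case(self) -> bool:
        if self.phenotype is None:
            raise CohortIOError(f"{self.sample_id}: phenotype not set")
        return self.phenotype == "case"


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage grid with aligned metadata.

    ``dosage`` is a float array of shape (n_samples, n_variants) whose
    non-missing entries are exactly 0, 1 or 2 (alt-allele copies); missing
    genotypes are NaN.
    """

    samples: list[SampleRecord]
    variants: list[Variant]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise CohortIOError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        finite = self.dosage[~np.isnan(self.dosage)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise CohortIOError("non-missing dosages must all be 0, 1 or 2")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise CohortIOError("duplicate sample ids in cohort")

    # -- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def rsids(self) -> list[str]:
        return [v.rsid for v in self.variants]

    def labels(self) -> np.ndarray:
        """Case/control labels as 1/0; raises if any phenotype is unset."""
        return np.array([1 if s.is_case else 0 for s in self.samples], dtype=int)

    def variant_index(self) -> dict[str, int]:
        return {v.rsid: j for j, v in enumerate(self.variants)}

    # -- subsetting ----------------------------------------------------------
    def subset_variants(self, cols: Sequence[int]) -> "GenotypeMatrix":
        cols = list(cols)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[j] for j in cols],
            dosage=self.dosage[:, cols].copy(),
        )

    def subset_samples(self, rows: Sequence[int]) -> "GenotypeMatrix":
        rows = list(rows)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in rows],
            variants=list(self.variants),
            dosage=self.dosage[rows, :].copy(),
        )

    def keep_sample_ids(self, ids: Iterable[str]) -> "GenotypeMatrix":
        wanted = set(ids)
        rows = [i for i, s in enumerate(self.samples) if s.sample_id in wanted]
        return self.subset_samples(rows)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=list(self.variants),
            dosage=self.dosage.copy(),
        )


@dataclass(frozen=True)
class PanelEntry:
    rsid: str
    traits: frozenset[str]
    effect_allele: str | None = None
    p_source: float | None = None


@dataclass
class CandidatePanel:
    """Deduplicated candidate-variant panel (a GWAS-catalog-style export)."""

    entries: list[PanelEntry]
    n_input_rows: int = 0

    def __post_init__(self) -> None:
        ids = [e.rsid for e in self.entries]
        if len(set(ids)) != len(ids):
            raise CohortIOError("panel entries must have unique rsids")

    @property
    def rsids(self) -> list[str]:
        return [e.rsid for e in self.entries]

    def traits_for(self, rsid: str) -> frozenset[str]:
        for e in self.entries:
            if e.rsid == rsid:
                return e.traits
        raise KeyError(rsid)


@dataclass
class MergeReport:
    """What merge_cohorts dropped: variants private to one cohort and
    chrom/pos collisions with mismatched alleles."""

    only_in_a: list[str] = field(default_factory=list)
    only_in_b: list[str] = field(default_factory=list)
    allele_mismatch: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_genotypes(
    vcf_path: str | Path,
    dosage_source: str = "GT",
    info_key: str | None = None,
) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    dosage_source
        "GT" counts alt alleles from hard calls; any other value names a
        per-sample FORMAT field (e.g. "DS") read directly as dosage and
        rounded to the nearest hard call.
    info_key
        INFO field holding the imputation info score.  When None, "INFO" is
        tried first, then "R2"; a record carrying neither gets
        ``info_score=None``.
    """
    from cyvcf2 import VCF

    path = str(vcf_path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise CohortIOError(f"cannot open VCF {path}: {exc}") from exc

    samples = [SampleRecord(sample_id=s) for s in vcf.samples]
    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    info_keys = (info_key,) if info_key is not None else ("INFO", "R2")

    record_no = 0
    try:
        for rec in vcf:
            record_no += 1
            if len(rec.ALT) != 1:
                raise MultiAllelicError(
                    f"{path}: record {record_no} ({rec.CHROM}:{rec.POS}) is "
                    "multi-allelic; normalize the VCF (e.g. bcftools norm -m-) first"
                )
            score = None
            for key in info_keys:
                val = rec.INFO.get(key)
                if val is not None:
                    score = float(val)
                    break
            rsid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
            variants.append(
                Variant(
                    rsid=rsid,
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=rec.ALT[0],
                    info_score=score,
                )
            )
            if dosage_source == "GT":
                col = np.full(len(samples), np.nan)
                for i, gt in enumerate(rec.genotypes):
                    alleles = [a for a in gt[:-1] if a >= 0]
                    if len(alleles) == len(gt) - 1 and alleles:
                        col[i] = float(sum(alleles))
            else:
                raw = rec.format(dosage_source)
                if raw is None:
                    raise CohortIOError(
                        f"{path}: record {record_no} lacks FORMAT field {dosage_source}"
                    )
                col = np.asarray(raw, dtype=float).reshape(-1)
                col = np.where(np.isnan(col), np.nan, np.rint(col))
            columns.append(col)
    except CohortIOError:
        raise
    except Exception as exc:
        raise CohortIOError(f"{path}: parse error at record {record_no + 1}: {exc}") from exc

    dosage = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write hard-call genotypes as a minimal deterministic VCF 4.2.

    Dosage 0/1/2 becomes GT 0/0, 0/1, 1/1; NaN becomes ./.; the info score is
    emitted under the INFO key ``INFO``.
    """
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    chroms: list[str] = []
    for v in matrix.variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            '##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation info score">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for j, v in enumerate(matrix.variants):
            info = "." if v.info_score is None else f"INFO={v.info_score:.6g}"
            gts = [
                "./." if math.isnan(d) else gt_map[d] for d in matrix.dosage[:, j]
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.rsid}\t{v.ref}\t{v.alt}\t.\t.\t{info}\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(tsv_path: str | Path) -> list[SampleRecord]:
    """Parse a phenotype TSV (sample_id, phenotype, sex[, subgroup]).

    Phenotype tokens are case-insensitive: athlete/case/1 are cases,
    control/0 are controls; anything else is an error.  Duplicate sample ids
    are an error.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    required = {"sample_id", "phenotype", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise CohortIOError(f"{tsv_path}: missing columns {sorted(missing)}")
    records: list[SampleRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        if sid in seen:
            raise CohortIOError(f"{tsv_path}: duplicate sample_id {sid!r}")
        seen.add(sid)
        token = str(row["phenotype"]).strip().lower()
        if token not in _PHENOTYPE_TOKENS:
            raise CohortIOError(
                f"{tsv_path}: unknown phenotype token {row['phenotype']!r} for {sid}"
            )
        sex = _SEX_TOKENS.get(str(row["sex"]).strip().lower(), "unknown")
        subgroup = None
        if "subgroup" in df.columns and pd.notna(row.get("subgroup")):
            subgroup = str(row["subgroup"])
        records.append(
            SampleRecord(
                sample_id=sid,
                phenotype=_PHENOTYPE_TOKENS[token],
                reported_sex=sex,
                subgroup=subgroup,
            )
        )
    return records


def write_phenotypes(records: Sequence[SampleRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "phenotype", "sex", "subgroup"])
        for r in records:
            w.writerow(
                [r.sample_id, r.phenotype or "", r.reported_sex, r.subgroup or ""]
            )


def attach_phenotypes(
    matrix: GenotypeMatrix, records: Sequence[SampleRecord]
) -> GenotypeMatrix:
    """Join phenotype records onto a genotype matrix by sample id.

    Every matrix sample must have a record; extra records are ignored.
    """
    by_id = {r.sample_id: r for r in records}
    joined: list[SampleRecord] = []
    for s in matrix.samples:
        if s.sample_id not in by_id:
            raise CohortIOError(f"no phenotype record for sample {s.sample_id!r}")
        joined.append(by_id[s.sample_id])
    return GenotypeMatrix(samples=joined, variants=list(matrix.variants), dosage=matrix.dosage.copy())


# ---------------------------------------------------------------------------
# Candidate panel
# ---------------------------------------------------------------------------

def read_panel(tsv_path: str | Path) -> CandidatePanel:
    """Read a candidate-variant panel TSV and deduplicate rsids.

    Rows listing the same rsid under several source traits are merged into a
    single entry whose trait set is the union, mirroring how a multi-trait
    catalog export collapses to one testable variant per rsid.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    required = {"rsid", "trait"}
    missing = required - set(df.columns)
    if missing:
        raise CohortIOError(f"{tsv_path}: missing columns {sorted(missing)}")
    if df.empty:
        warnings.warn(f"{tsv_path}: empty candidate panel", stacklevel=2)
        return CandidatePanel(entries=[], n_input_rows=0)

    order: list[str] = []
    traits: dict[str, list[str]] = {}
    effect: dict[str, str | None] = {}
    p_src: dict[str, float | None] = {}
    for _, row in df.iterrows():
        rsid = str(row["rsid"])
        trait = str(row["trait"])
        if rsid not in traits:
            order.append(rsid)
            traits[rsid] = []
            effect[rsid] = None
            p_src[rsid] = None
        if trait not in traits[rsid]:
            traits[rsid].append(trait)
        if "effect_allele" in df.columns and pd.notna(row.get("effect_allele")):
            if row["effect_allele"] != "":
                effect[rsid] = str(row["effect_allele"])
        if "p_source" in df.columns and pd.notna(row.get("p_source")):
            if row["p_source"] != "":
                p_src[rsid] = float(row["p_source"])
    entries = [
        PanelEntry(
            rsid=r,
            traits=frozenset(traits[r]),
            effect_allele=effect[r],
            p_source=p_src[r],
        )
        for r in order
    ]
    return CandidatePanel(entries=entries, n_input_rows=len(df))


def write_panel(panel: CandidatePanel, path: str | Path) -> None:
    """One row per (rsid, trait), deterministic order."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["rsid", "trait", "effect_allele", "p_source"])
        for e in panel.entries:
            for trait in sorted(e.traits):
                w.writerow(
                    [
                        e.rsid,
                        trait,
                        e.effect_allele or "",
                        "" if e.p_source is None else repr(e.p_source),
                    ]
                )


def intersect_panel(
    matrix: GenotypeMatrix, panel: CandidatePanel
) -> tuple[GenotypeMatrix, list[str]]:
    """Restrict the matrix to panel rsids and attach the panel's trait labels.

    Returns the restricted matrix (file order preserved) and the list of
    panel rsids absent from the matrix.  An empty intersection is an error:
    there would be nothing to analyze.
    """
    panel_traits = {e.rsid: e.traits for e in panel.entries}
    cols = [j for j, v in enumerate(matrix.variants) if v.rsid in panel_traits]
    if not cols:
        raise CohortIOError("candidate panel shares no rsids with the genotype matrix")
    present = {matrix.variants[j].rsid for j in cols}
    unmatched = [r for r in panel_traits if r not in present]
    sub = matrix.subset_variants(cols)
    sub.variants = [
        replace(v, traits=frozenset(panel_traits[v.rsid])) for v in sub.variants
    ]
    return sub, unmatched


# ---------------------------------------------------------------------------
# Merge
# ---------------------------------------------------------------------------

def merge_cohorts(
    matrix_a: GenotypeMatrix, matrix_b: GenotypeMatrix
) -> tuple[GenotypeMatrix, MergeReport]:
    """Union of samples over the intersection of variants.

    Variants are matched on (chrom, pos, ref, alt).  A chrom/pos collision
    with different alleles is dropped and reported — with one cohort typically
    sequenced and the other array-genotyped, a strand or representation clash
    is more plausible than a shared site.  Variant order follows cohort A.
    """
    ids_a = set(matrix_a.sample_ids)
    overlap = ids_a & set(matrix_b.sample_ids)
    if overlap:
        raise CohortIOError(
            f"cohorts share sample ids (e.g. {sorted(overlap)[:3]}); ids must be disjoint"
        )

    by_key_b = {v.key: j for j, v in enumerate(matrix_b.variants)}
    pos_b = {(v.chrom, v.pos) for v in matrix_b.variants}
    pos_a = {(v.chrom, v.pos) for v in matrix_a.variants}

    report = MergeReport()
    keep_a: list[int] = []
    keep_b: list[int] = []
    merged_variants: list[Variant] = []
    for j, v in enumerate(matrix_a.variants):
        if v.key in by_key_b:
            jb = by_key_b[v.key]
            vb = matrix_b.variants[jb]
            keep_a.append(j)
            keep_b.append(jb)
            info = v.info_score
            if vb.info_score is not None:
                info = vb.info_score if info is None else min(info, vb.info_score)
            merged_variants.append(replace(v, info_score=info, traits=v.traits | vb.traits))
        elif (v.chrom, v.pos) in pos_b:
            report.allele_mismatch.append(v.rsid)
        else:
            report.only_in_a.append(v.rsid)
    keys_a = {v.key for v in matrix_a.variants}
    for v in matrix_b.variants:
        if v.key not in keys_a:
            if (v.chrom, v.pos) in pos_a:
                if v.rsid not in report.allele_mismatch:
                    report.allele_mismatch.append(v.rsid)
            else:
                report.only_in_b.append(v.rsid)

    if not keep_a:
        raise CohortIOError("cohorts share no variants; nothing to merge")
    dosage = np.vstack(
        [matrix_a.dosage[:, keep_a], matrix_b.dosage[:, keep_b]]
    )
    merged = GenotypeMatrix(
        samples=list(matrix_a.samples) + list(matrix_b.samples),
        variants=merged_variants,
        dosage=dosage,
    )
    return merged, report


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def annotate_nearest_gene(
    variants: Sequence[Variant],
    gene_bed: str | Path | Sequence[tuple[str, int, int, str]],
) -> list[str]:
    """Nearest-gene label per variant from a BED4 interval file.

    A variant inside an interval gets that gene; otherwise the closest
    interval by base-pair gap wins.  Exact distance ties (including several
    overlapping containing genes) are comma-joined in file order, matching
    the "GENE1,GENE2" style used for intergenic variants in annotation
    tables.  No interval on the variant's chromosome (or an empty BED) gives
    "NA".
    """
    if isinstance(gene_bed, (str, Path)):
        rows: list[tuple[str, int, int, str]] = []
        with open(gene_bed) as fh:
            for line_no, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise CohortIOError(
                        f"{gene_bed}: line {line_no}: BED4 needs 4 columns"
                    )
                rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
    else:
        rows = list(gene_bed)

    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, start, end, name in rows:
        by_chrom.setdefault(chrom, []).append((start, end, name))

    labels: list[str] = []
    for v in variants:
        genes = by_chrom.get(v.chrom)
        if not genes:
            labels.append("NA")
            continue
        # BED [start, end) covers 1-based positions start+1 .. end
        best = math.inf
        names: list[str] = []
        for start, end, name in genes:
            if start + 1 <= v.pos <= end:
                dist = 0
            elif v.pos < start + 1:
                dist = start + 1 - v.pos
            else:
                dist = v.pos - end
            if dist < best:
                best = dist
                names = [name]
            elif dist == best and name not in names:
                names.append(name)
        labels.append(",".join(names))
    return labels
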