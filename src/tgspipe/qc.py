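"""Variant- and sample-level quality control.

Replicates the PLINK-style filter battery commonly applied to a merged
case/control training set before association analysis:

variants
    imputation info score < 0.6, missing rate > 0.02, Hardy-Weinberg exact
    p < 0.05, minor allele frequency < 0.05 — all strict inequalities, so a
    variant sitting exactly on a printed threshold is retained.
samples
    missing rate > 0.02, pairwise relatedness PI_HAT > 0.125, heterozygosity
    outside mean +/- 3 SD, reported-vs-inferred sex discrepancy.

Each exclusion is attributed to the first failing filter in the order above
(the retained counts are order-independent; attribution is not), and every
decision is itemized in a :class:`QCReport`.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .cohort_io import GenotypeMatrix

__all__ = [
    "QCThresholds",
    "QCExclusion",
    "QCReport",
    "QCError",
    "maf",
    "hwe_exact_p",
    "genotype_counts",
    "filter_variants",
    "heterozygosity_outliers",
    "relatedness",
    "ld_prune",
    "sex_check",
    "run_sample_qc",
]

_X_LABELS = {"X", "chrX", "x", "23"}


class QCError(ValueError):
    """QC cannot proceed (e.g. every variant or sample excluded)."""


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds; defaults are the conventional strict-inequality set."""

    max_variant_missing: float = 0.02
    hwe_alpha: float = 0.05
    min_maf: float = 0.05
    min_info: float = 0.6
    max_sample_missing: float = 0.02
    max_relatedness: float = 0.125
    het_sd_k: float = 3.0
    hwe_scope: Literal["all", "controls"] = "all"

    def __post_init__(self) -> None:
        for name in ("max_variant_missing", "hwe_alpha", "min_maf", "min_info",
                     "max_sample_missing", "max_relatedness"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise QCError(f"{name} must be in [0, 1], got {v}")
        if self.het_sd_k <= 0:
            raise QCError("het_sd_k must be positive")


@dataclass(frozen=True)
class QCExclusion:
    stage: str
    item_id: str
    statistic: float | None
    detail: str = ""


@dataclass
class QCReport:
    """Per-filter exclusion records plus input/retained counts."""

    kind: str  # "variant" or "sample"
    n_input: int
    exclusions: list[QCExclusion] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return len(self.exclusions)

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_excluded

    def excluded_ids(self, stage: str | None = None) -> list[str]:
        return [e.item_id for e in self.exclusions if stage is None or e.stage == stage]

    def counts_by_stage(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.exclusions:
            out[e.stage] = out.get(e.stage, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": e.stage,
                    "id": e.item_id,
                    "statistic": e.statistic,
                    "detail": e.detail,
                }
                for e in self.exclusions
            ],
            columns=["stage", "id", "statistic", "detail"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "kind": self.kind,
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "counts_by_stage": self.counts_by_stage(),
            "exclusions": [
                {
                    "stage": e.stage,
                    "id": e.item_id,
                    "statistic": e.statistic,
                    "detail": e.detail,
                }
                for e in self.exclusions
            ],
            "warnings": self.warnings,
        }
        text = json.dumps(payload, indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# Per-variant statistics
# ---------------------------------------------------------------------------

def maf(dosages: np.ndarray) -> float:
    """Minor allele frequency from alt-allele dosages (NaN = missing).

    Alt frequency is sum(dosage) / (2 * n_nonmissing); MAF folds it to the
    rarer allele.  All-missing input is undefined and returns NaN.
    """
    d = np.asarray(dosages, dtype=float)
    n = int(np.sum(~np.isnan(d)))
    if n == 0:
        return float("nan")
    f_alt = float(np.nansum(d)) / (2.0 * n)
    return min(f_alt, 1.0 - f_alt)


def genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    """(hom-ref, het, hom-alt) counts over non-missing hard calls."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditional on the observed allele counts, heterozygote counts with the
    same parity as the observed one are enumerated by the standard stable
    recurrence; the p-value is the summed probability of all tables no more
    probable than the observed one (plain, not mid-p).  Monomorphic input has
    a single possible table and returns 1.0.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise QCError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise QCError("need at least one genotyped sample")

    obs_hets = n_Aa
    obs_homr = min(n_AA, n_aa)
    obs_homc = max(n_AA, n_aa)
    rare = 2 * obs_homr + obs_hets
    if rare == 0:
        return 1.0

    # probabilities over het counts sharing the parity of `rare`
    mid = rare * (2 * n - rare) // (2 * n)
    if (mid % 2) != (rare % 2):
        mid += 1
    probs = np.zeros(rare + 1)
    probs[mid] = 1.0

    het, homr, homc = mid, (rare - mid) // 2, n - mid - (rare - mid) // 2
    while het >= 2:
        probs[het - 2] = probs[het] * het * (het - 1) / (4.0 * (homr + 1) * (homc + 1))
        het -= 2
        homr += 1
        homc += 1
    het, homr, homc = mid, (rare - mid) // 2, n - mid - (rare - mid) // 2
    while het <= rare - 2:
        probs[het + 2] = probs[het] * 4.0 * homr * homc / ((het + 2.0) * (het + 1.0))
        het += 2
        homr -= 1
        homc -= 1

    total = probs.sum()
    target = probs[obs_hets]
    # relative guard so genuinely tied tables are included despite fp noise
    p = probs[probs <= target * (1.0 + 1e-12)].sum() / total
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# Variant filters
# ---------------------------------------------------------------------------

def filter_variants(
    matrix: GenotypeMatrix,
    thresholds: QCThresholds = QCThresholds(),
    labels: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the variant filter battery in fixed attribution order.

    Order: info score -> missing rate -> HWE -> MAF; each variant is charged
    to the first filter it fails.  Strict boundary semantics: MAF exactly at
    ``min_maf`` and missing rate exactly at ``max_variant_missing`` are
    retained.  Variants without an info score pass the info filter (the
    filter applies to imputed data that carries one).

    ``labels`` (1 = case) is only needed for ``hwe_scope="controls"``.
    """
    report = QCReport(kind="variant", n_input=matrix.n_variants)
    if thresholds.hwe_scope == "controls":
        if labels is None:
            labels = matrix.labels()
        hwe_rows = np.asarray(labels) == 0
        if not hwe_rows.any():
            raise QCError("hwe_scope='controls' but no control samples present")
    else:
        hwe_rows = np.ones(matrix.n_samples, dtype=bool)

    keep: list[int] = []
    for j, v in enumerate(matrix.variants):
        d = matrix.dosage[:, j]
        if v.info_score is not None and v.info_score < thresholds.min_info:
            report.exclusions.append(
                QCExclusion("info", v.rsid, v.info_score, "info score below minimum")
            )
            continue
        miss = float(np.isnan(d).mean()) if d.size else 1.0
        if miss > thresholds.max_variant_missing:
            report.exclusions.append(
                QCExclusion("missing", v.rsid, miss, "variant missing rate too high")
            )
            continue
        counts = genotype_counts(d[hwe_rows])
        if sum(counts) == 0:
            report.exclusions.append(
                QCExclusion("missing", v.rsid, 1.0, "no genotyped samples in HWE scope")
            )
            continue
        p_hwe = hwe_exact_p(*counts)
        if p_hwe < thresholds.hwe_alpha:
            report.exclusions.append(
                QCExclusion("hwe", v.rsid, p_hwe, "Hardy-Weinberg deviation")
            )
            continue
        f = maf(d)
        if math.isnan(f):
            report.exclusions.append(QCExclusion("maf", v.rsid, None, "MAF undefined"))
            continue
        if f < thresholds.min_maf:
            report.exclusions.append(
                QCExclusion("maf", v.rsid, f, "minor allele frequency below minimum")
            )
            continue
        keep.append(j)

    if not keep:
        raise QCError("variant QC excluded every variant")
    return matrix.subset_variants(keep), report


# ---------------------------------------------------------------------------
# Sample filters
# ---------------------------------------------------------------------------

def _autosomal_cols(matrix: GenotypeMatrix) -> list[int]:
    return [j for j, v in enumerate(matrix.variants) if v.chrom not in _X_LABELS
            and v.chrom not in {"Y", "chrY", "y", "24", "MT", "chrM"}]


def heterozygosity_outliers(
    matrix: GenotypeMatrix, k: float = 3.0
) -> tuple[list[str], dict[str, float]]:
    """Sample ids whose autosomal heterozygosity lies outside mean +/- k*SD.

    Returns (excluded ids, per-sample het rates).  Fewer than 3 samples, or a
    degenerate SD of zero, yields no exclusions (with a warning for the
    former).
    """
    cols = _autosomal_cols(matrix)
    rates: dict[str, float] = {}
    if not cols:
        warnings.warn("no autosomal variants; skipping heterozygosity check", stacklevel=2)
        return [], rates
    sub = matrix.dosage[:, cols]
    nonmiss = (~np.isnan(sub)).sum(axis=1)
    n_het = (sub == 1.0).sum(axis=1)  # NaN == 1.0 is False, so missing never counts
    het = np.where(nonmiss > 0, n_het / np.maximum(nonmiss, 1), np.nan)
    for s, h in zip(matrix.samples, het):
        rates[s.sample_id] = float(h)
    if matrix.n_samples < 3:
        warnings.warn("fewer than 3 samples; heterozygosity check skipped", stacklevel=2)
        return [], rates
    finite = het[~np.isnan(het)]
    mean, sd = float(np.mean(finite)), float(np.std(finite, ddof=1))
    if sd == 0.0 or not math.isfinite(k):
        return [], rates
    lo, hi = mean - k * sd, mean + k * sd
    excluded = [
        s.sample_id
        for s, h in zip(matrix.samples, het)
        if not np.isnan(h) and (h < lo or h > hi)
    ]
    return excluded, rates


def _ibs_expectations(G: np.ndarray) -> dict[str, np.ndarray]:
    """Per-variant P(IBS=i | IBD=z) under random mating.

    Allele-frequency powers are estimated by falling-factorial (unbiased)
    moments of the observed allele counts rather than plugging in p-hat, so
    the expectations — and hence PI_HAT for unrelated pairs — carry no
    small-sample bias.
    """
    X = np.nansum(G, axis=0)                      # alt allele count
    T = 2.0 * (~np.isnan(G)).sum(axis=0)          # total alleles
    Y = T - X

    def ff(a: np.ndarray, k: int) -> np.ndarray:
        out = np.ones_like(a)
        for i in range(k):
            out = out * np.maximum(a - i, 0.0)
        return out

    ff2, ff3, ff4 = ff(T, 2), ff(T, 3), ff(T, 4)
    with np.errstate(divide="ignore", invalid="ignore"):
        p2q2 = ff(X, 2) * ff(Y, 2) / ff4
        p3q = ff(X, 3) * Y / ff4
        pq3 = X * ff(Y, 3) / ff4
        p4 = ff(X, 4) / ff4
        q4 = ff(Y, 4) / ff4
        p2q = ff(X, 2) * Y / ff3
        pq2 = X * ff(Y, 2) / ff3
        p2 = ff(X, 2) / ff2
        q2 = ff(Y, 2) / ff2
    return {
        "e00": 2.0 * p2q2,                  # IBS0 | IBD0
        "e10": 4.0 * p3q + 4.0 * pq3,       # IBS1 | IBD0
        "e20": p4 + q4 + 4.0 * p2q2,        # IBS2 | IBD0
        "e11": 2.0 * p2q + 2.0 * pq2,       # IBS1 | IBD1
        "e21": p2 + q2,                     # IBS2 | IBD1 (= p^3+q^3+p^2q+pq^2)
    }


def ld_prune(
    matrix: GenotypeMatrix, r2_threshold: float = 0.2, window_bp: int = 250_000
) -> list[int]:
    """Greedy LD pruning, returning retained column indices.

    Variants are scanned in genomic order; a variant is dropped when its
    dosage r-squared with any already-retained variant on the same
    chromosome within the window exceeds the threshold.  Used to thin the
    marker set before relatedness estimation, where correlated markers would
    inflate the variance of PI_HAT without adding information.
    """
    from .clump import chrom_sort_key, ld_r2

    order = sorted(
        range(matrix.n_variants),
        key=lambda j: (chrom_sort_key(matrix.variants[j].chrom), matrix.variants[j].pos),
    )
    kept: list[int] = []
    kept_by_chrom: dict[str, list[int]] = {}
    for j in order:
        v = matrix.variants[j]
        ok = True
        for k in reversed(kept_by_chrom.get(v.chrom, [])):
            if abs(matrix.variants[k].pos - v.pos) > window_bp:
                break
            r2 = ld_r2(matrix.dosage[:, j], matrix.dosage[:, k])
            if not math.isnan(r2) and r2 > r2_threshold:
                ok = False
                break
        if ok:
            kept.append(j)
            kept_by_chrom.setdefault(v.chrom, []).append(j)
    return sorted(kept)


def relatedness(
    matrix: GenotypeMatrix,
    max_relatedness: float = 0.125,
    min_variants: int = 50,
) -> tuple[pd.DataFrame, list[str]]:
    """Method-of-moments IBD sharing (PI_HAT) for every sample pair.

    For each pair, observed IBS0/1/2 counts over mutually non-missing
    autosomal variants are equated to their expectations given allele
    frequencies to estimate P(IBD=0/1/2); PI_HAT = P(IBD=2) + P(IBD=1)/2,
    clipped to [0, 1].  Pairs with PI_HAT strictly above ``max_relatedness``
    trigger exclusion of the member with the higher missing rate (ties break
    to the later sample in cohort order).

    Returns a DataFrame (id1, id2, pi_hat, n_variants) over flagged-or-all
    pairs and the exclusion list.
    """
    cols = _autosomal_cols(matrix)
    G = matrix.dosage[:, cols]
    poly = [j for j in range(G.shape[1]) if 0.0 < np.nanmean(G[:, j]) / 2.0 < 1.0]
    if not poly:
        raise QCError("relatedness needs polymorphic variants")
    if len(poly) < min_variants:
        warnings.warn(
            f"only {len(poly)} polymorphic variants; PI_HAT estimates will be noisy",
            stacklevel=2,
        )
    G = G[:, poly]
    n, m = G.shape
    if n < 2:
        raise QCError("relatedness needs at least 2 samples")
    e = _ibs_expectations(G)

    A0 = (G == 0.0).astype(float)
    A1 = (G == 1.0).astype(float)
    A2 = (G == 2.0).astype(float)
    M = (~np.isnan(G)).astype(float)

    N0 = A0 @ A2.T + A2 @ A0.T
    N2 = A0 @ A0.T + A1 @ A1.T + A2 @ A2.T
    Nshared = M @ M.T
    N1 = Nshared - N0 - N2

    E00 = (M * e["e00"]) @ M.T
    E10 = (M * e["e10"]) @ M.T
    E20 = (M * e["e20"]) @ M.T
    E11 = (M * e["e11"]) @ M.T
    E21 = (M * e["e21"]) @ M.T

    # The component estimators are kept unclipped so the final statistic stays
    # unbiased around 0 for unrelated pairs (clipping P(IBD=1/2) at zero first
    # would push every noisy pair upward); only PI_HAT itself is clipped.
    with np.errstate(divide="ignore", invalid="ignore"):
        p0 = N0 / E00
        p1 = (N1 - p0 * E10) / E11
        p2 = (N2 - p0 * E20 - p1 * E21) / Nshared
    p0 = np.nan_to_num(p0)
    p1 = np.nan_to_num(p1)
    p2 = np.nan_to_num(p2)
    pi_hat = np.clip(p2 + 0.5 * p1, 0.0, 1.0)

    miss_rate = np.isnan(matrix.dosage).mean(axis=1)
    ids = matrix.sample_ids
    rows = []
    pairs: list[tuple[int, int, float]] = []
    for i in range(n):
        for j in range(i + 1, n):
            rows.append(
                {
                    "id1": ids[i],
                    "id2": ids[j],
                    "pi_hat": float(pi_hat[i, j]),
                    "n_variants": int(Nshared[i, j]),
                }
            )
            if pi_hat[i, j] > max_relatedness:
                pairs.append((i, j, float(pi_hat[i, j])))

    excluded: list[str] = []
    excluded_idx: set[int] = set()
    for i, j, _ in pairs:
        if i in excluded_idx or j in excluded_idx:
            continue
        # drop the member with more missing data; ties -> later sample order
        drop = j if miss_rate[j] >= miss_rate[i] else i
        excluded_idx.add(drop)
        excluded.append(ids[drop])
    table = pd.DataFrame(rows, columns=["id1", "id2", "pi_hat", "n_variants"])
    return table, excluded


def pi_hat_exclusions(
    pairs: Sequence[tuple[str, str, float]],
    missing_rates: dict[str, float],
    sample_order: Sequence[str],
    max_relatedness: float = 0.125,
) -> list[str]:
    """Exclusion rule applied to precomputed PI_HAT pairs.

    Strictly-greater comparison: a pair sitting exactly at the threshold is
    retained.  Exposed separately so the rule is testable independent of the
    estimator.
    """
    order = {s: k for k, s in enumerate(sample_order)}
    excluded: list[str] = []
    for id1, id2, coef in pairs:
        if coef <= max_relatedness:
            continue
        if id1 in excluded or id2 in excluded:
            continue
        m1, m2 = missing_rates.get(id1, 0.0), missing_rates.get(id2, 0.0)
        if m1 > m2:
            drop = id1
        elif m2 > m1:
            drop = id2
        else:
            drop = id1 if order[id1] > order[id2] else id2
        excluded.append(drop)
    return excluded


def sex_check(
    matrix: GenotypeMatrix, x_chrom_label: str = "X"
) -> tuple[list[str], dict[str, str]]:
    """Flag samples whose X-chromosome inbreeding contradicts reported sex.

    Per sample, F = 1 - observed_het / expected_het over X-labelled variants
    (expected het from cohort allele frequencies).  F > 0.8 infers male,
    F < 0.2 infers female, in between is undetermined and never excluded.
    Samples with reported sex "unknown" are never flagged.  Returns
    (mismatched ids, inferred sex per sample).
    """
    cols = [j for j, v in enumerate(matrix.variants) if v.chrom == x_chrom_label]
    if not cols:
        warnings.warn("no X-chromosome variants; sex check skipped", stacklevel=2)
        return [], {}
    X = matrix.dosage[:, cols]
    freqs = np.nanmean(X, axis=0) / 2.0
    exp_het_per_variant = 2.0 * freqs * (1.0 - freqs)

    inferred: dict[str, str] = {}
    mismatched: list[str] = []
    for i, s in enumerate(matrix.samples):
        row = X[i]
        ok = ~np.isnan(row)
        if not ok.any() or exp_het_per_variant[ok].mean() <= 0:
            inferred[s.sample_id] = "undetermined"
            continue
        obs_het = float((row[ok] == 1.0).mean())
        exp_het = float(exp_het_per_variant[ok].mean())
        f_stat = 1.0 - obs_het / exp_het
        if f_stat > 0.8:
            sex = "male"
        elif f_stat < 0.2:
            sex = "female"
        else:
            sex = "undetermined"
        inferred[s.sample_id] = sex
        if sex != "undetermined" and s.reported_sex in ("male", "female"):
            if sex != s.reported_sex:
                mismatched.append(s.sample_id)
    return mismatched, inferred


def run_sample_qc(
    matrix: GenotypeMatrix,
    thresholds: QCThresholds = QCThresholds(),
    x_chrom_label: str = "X",
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply sample filters in order: missing rate, relatedness,
    heterozygosity, sex check.  Each stage operates on the survivors of the
    previous one and every exclusion is itemized in the report."""
    report = QCReport(kind="sample", n_input=matrix.n_samples)
    current = matrix

    miss = np.isnan(current.dosage).mean(axis=1)
    keep_rows = []
    for i, s in enumerate(current.samples):
        if miss[i] > thresholds.max_sample_missing:
            report.exclusions.append(
                QCExclusion("missing", s.sample_id, float(miss[i]), "sample missing rate too high")
            )
        else:
            keep_rows.append(i)
    current = current.subset_samples(keep_rows)
    if current.n_samples == 0:
        raise QCError("sample QC excluded every sample (missing-rate stage)")

    # Relatedness runs on an LD-pruned marker subset: correlated markers add
    # variance, not information, to the IBD moment estimates.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        auto = current.subset_variants(_autosomal_cols(current))
        pruned = auto.subset_variants(ld_prune(auto))
        table, rel_excluded = relatedness(pruned, thresholds.max_relatedness)
    if rel_excluded:
        pi_by_id = {}
        for _, row in table.iterrows():
            pi_by_id[row["id1"]] = max(pi_by_id.get(row["id1"], 0.0), row["pi_hat"])
            pi_by_id[row["id2"]] = max(pi_by_id.get(row["id2"], 0.0), row["pi_hat"])
        for sid in rel_excluded:
            report.exclusions.append(
                QCExclusion("relatedness", sid, pi_by_id.get(sid), "PI_HAT above maximum")
            )
        current = current.keep_sample_ids(
            [s for s in current.sample_ids if s not in set(rel_excluded)]
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        het_excluded, het_rates = heterozygosity_outliers(current, thresholds.het_sd_k)
    for sid in het_excluded:
        report.exclusions.append(
            QCExclusion("heterozygosity", sid, het_rates.get(sid), "het rate outside mean +/- k*SD")
        )
    if het_excluded:
        current = current.keep_sample_ids(
            [s for s in current.sample_ids if s not in set(het_excluded)]
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sex_excluded, _inferred = sex_check(current, x_chrom_label)
    for sid in sex_excluded:
        report.exclusions.append(
            QCExclusion("sex", sid, None, "inferred sex contradicts reported sex")
        )
    if sex_excluded:
        current = current.keep_sample_ids(
            [s for s in current.sample_ids if s not in set(sex_excluded)]
        )

    if current.n_samples == 0:
        raise QCError("sample QC excluded every sample")
    return current, report
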