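"""Total Genotype Score (TGS).

The TGS aggregates the selected tag variants into one number per sample:

    TGS_j = sum_i S_i * G_ij / (P * M_j)

where S_i is the effect size (the natural log of the tag's odds ratio, so
risk-increasing alleles weigh positive and protective alleles negative),
G_ij is the alt-allele dosage of tag i in sample j, P = 2 is the human
ploidy, and M_j counts the tags with a non-missing dosage in sample j.  A
missing-dosage tag contributes to neither the numerator nor M_j, so the
score is a per-allele average over the variants actually observed — samples
genotyped at different subsets of tags remain comparable.

Weights always come from the training-set association; the validation set
never participates in weight estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clump import TagSet
from .cohort_io import GenotypeMatrix

__all__ = ["PLOIDY", "Weight", "WeightSet", "ScoreVector", "effect_weights",
           "compute_tgs", "standardize_scores"]

PLOIDY = 2  # humans


@dataclass(frozen=True)
class Weight:
    ln_or: float
    effect_allele: str


@dataclass
class WeightSet:
    """Per-tag scoring weights, keyed by rsid."""

    entries: dict[str, Weight]

    def __post_init__(self) -> None:
        for rsid, w in self.entries.items():
            if not np.isfinite(w.ln_or):
                raise ValueError(f"{rsid}: weight must be finite, got {w.ln_or}")

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"rsid": r, "effect_allele": w.effect_allele, "lnOR": w.ln_or}
                for r, w in self.entries.items()
            ],
            columns=["rsid", "effect_allele", "lnOR"],
        )

    def write_tsv(self, path: str | Path) -> None:
        """Score-file-style TSV: rsid, effect_allele, lnOR."""
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class ScoreVector:
    """Per-sample TGS with the non-missing tag count M_j behind each score.

    Samples with M_j = 0 carry NaN and are listed in ``undefined_ids``; they
    must be excluded from any downstream model fit.
    """

    sample_ids: list[str]
    tgs: np.ndarray
    m: np.ndarray
    undefined_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "TGS": self.tgs, "M": self.m}
        )

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        defined = df["TGS"].notna().to_numpy()
        z = np.full(len(df), np.nan)
        vals = df["TGS"].to_numpy()[defined]
        if defined.sum() >= 2 and np.std(vals, ddof=1) > 0:
            z[defined] = (vals - vals.mean()) / np.std(vals, ddof=1)
        df["z"] = z
        df.to_csv(path, sep="\t", index=False)


def effect_weights(tag_set: TagSet) -> WeightSet:
    """lnOR weights from a tag set; every tag must have a converged fit."""
    entries: dict[str, Weight] = {}
    for tag in tag_set:
        r = tag.result
        if not r.converged or not np.isfinite(r.ln_or):
            raise ValueError(
                f"{r.rsid}: non-converged association cannot provide a weight; "
                "exclude it before scoring"
            )
        entries[r.rsid] = Weight(ln_or=r.ln_or, effect_allele=r.effect_allele)
    return WeightSet(entries=entries)


def compute_tgs(matrix: GenotypeMatrix, weights: WeightSet) -> ScoreVector:
    """Score every sample in the matrix with the given weights.

    Weights whose rsid is absent from the matrix are reported via a warning
    and skipped; zero matched weights is an error.  M_j counts matched tags
    with non-missing dosage regardless of weight magnitude (a zero-weight
    tag still enters the denominator).
    """
    col_of = matrix.variant_index()
    matched: list[tuple[int, float]] = []
    unmatched: list[str] = []
    for rsid, w in weights.entries.items():
        if rsid in col_of:
            matched.append((col_of[rsid], w.ln_or))
        else:
            unmatched.append(rsid)
    if not matched:
        raise ValueError("no weight rsids match the scoring matrix")
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} weight rsids absent from scoring matrix: "
            f"{unmatched[:5]}{'...' if len(unmatched) > 5 else ''}",
            stacklevel=2,
        )

    cols = np.array([c for c, _ in matched])
    s = np.array([w for _, w in matched])
    G = matrix.dosage[:, cols]
    observed = ~np.isnan(G)
    m = observed.sum(axis=1)
    numer = np.nansum(G * s[np.newaxis, :], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tgs = np.where(m > 0, numer / (PLOIDY * np.maximum(m, 1)), np.nan)
    undefined = [sid for sid, mm in zip(matrix.sample_ids, m) if mm == 0]
    if undefined:
        warnings.warn(
            f"{len(undefined)} samples have no non-missing tag; their TGS is undefined",
            stacklevel=2,
        )
    return ScoreVector(
        sample_ids=matrix.sample_ids,
        tgs=tgs,
        m=m.astype(int),
        undefined_ids=undefined,
    )


def standardize_scores(scores: np.ndarray) -> np.ndarray:
    """Z-standardize defined scores: (x - mean) / SD with the sample (n-1) SD.

    NaN entries stay NaN.  Fewer than two defined scores, or zero SD, is an
    error.  Applying the function to already-standardized input returns it
    unchanged (up to floating-point round-off).
    """
    x = np.asarray(scores, dtype=float)
    ok = ~np.isnan(x)
    if ok.sum() < 2:
        raise ValueError("need at least 2 defined scores to standardize")
    vals = x[ok]
    sd = float(np.std(vals, ddof=1))
    if sd == 0.0:
        raise ValueError("score SD is zero; standardization undefined")
    out = np.full_like(x, np.nan)
    out[ok] = (vals - vals.mean()) / sd
    return out
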