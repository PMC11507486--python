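"""Clumping-and-thresholding (C+T) tag-variant selection.

Greedy, PLINK-style: among association results with p at or below the
significance tier, the smallest-p variant becomes an index ("tag") variant;
every other candidate on the same chromosome within the window and in high LD
with it (r-squared above the threshold) is assigned to that tag's clump and
removed from candidacy; repeat until no candidates remain.  A variant clumped
into one tag is never re-evaluated for another (single-assignment greedy).

LD here is composite LD: the squared Pearson correlation of unphased
alt-allele dosages over pairwise-complete samples.  This differs slightly
from haplotype-frequency r-squared, but is the natural estimator for
post-imputation dosage data and agrees closely at the 0.2 threshold scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assoc import AssociationResult, AssociationTable
from .cohort_io import GenotypeMatrix

__all__ = ["ClumpConfig", "Tag", "TagSet", "ld_r2", "clump", "chrom_sort_key"]


@dataclass(frozen=True)
class ClumpConfig:
    """C+T parameters: significance tier, LD threshold, physical window."""

    p_threshold: float = 0.05
    r2_threshold: float = 0.2
    window_bp: int = 250_000

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold <= 1.0):
            raise ValueError("p_threshold must be in (0, 1]")
        if not (0.0 < self.r2_threshold <= 1.0):
            raise ValueError("r2_threshold must be in (0, 1]")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")


@dataclass
class Tag:
    """An index variant with the members clumped under it."""

    result: AssociationResult
    members: list[tuple[str, float]] = field(default_factory=list)  # (rsid, r2)


@dataclass
class TagSet:
    """Ordered tags (selection order = ascending p) from one C+T run."""

    tags: list[Tag]
    config: ClumpConfig
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tags)

    def __iter__(self):
        return iter(self.tags)

    @property
    def tag_rsids(self) -> list[str]:
        return [t.result.rsid for t in self.tags]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rsid": t.result.rsid,
                    "chrom": t.result.chrom,
                    "pos": t.result.pos,
                    "OR": t.result.or_hat,
                    "lnOR": t.result.ln_or,
                    "P": t.result.p,
                    "n_members": len(t.members),
                    "members": ";".join(f"{r}:{r2:.4f}" for r, r2 in t.members),
                }
                for t in self.tags
            ],
            columns=["rsid", "chrom", "pos", "OR", "lnOR", "P", "n_members", "members"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def ld_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Squared dosage correlation over pairwise-complete samples.

    Undefined cases — fewer than two complete pairs, or either vector
    constant on the complete subset — return NaN; the clumping loop treats
    NaN as r-squared 0 and records a warning.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    if a.size < 2:
        return float("nan")
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return float("nan")
    r = float(np.corrcoef(a, b)[0, 1])
    return min(r * r, 1.0)


def chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    """Order chromosomes numerically, then X/Y/MT-style names lexically."""
    s = chrom.removeprefix("chr")
    if s.isdigit():
        return (0, int(s), "")
    return (1, 0, s)


def _r2_index_vs(matrix_dosage: np.ndarray, index_col: int, other_cols: np.ndarray) -> np.ndarray:
    """Vectorized composite-LD r2 of one column against several, pairwise-complete."""
    x = matrix_dosage[:, index_col]
    out = np.empty(other_cols.size)
    for k, j in enumerate(other_cols):
        out[k] = ld_r2(x, matrix_dosage[:, j])
    return out


def clump(
    assoc_table: AssociationTable,
    matrix: GenotypeMatrix,
    config: ClumpConfig = ClumpConfig(),
) -> TagSet:
    """Greedy C+T selection over an association table.

    Candidates are converged rows with p <= p_threshold whose rsid maps to a
    matrix variant.  Ties on p break to the smaller chromosome, then
    position, then rsid, for determinism.  The physical window is inclusive
    at exactly ``window_bp`` from the index position.  An empty candidate set
    yields an empty TagSet, not an error.
    """
    col_of = matrix.variant_index()
    notes: list[str] = []
    candidates: list[AssociationResult] = []
    for r in assoc_table:
        if not r.converged:
            continue
        if not (r.p <= config.p_threshold):
            continue
        if r.rsid not in col_of:
            notes.append(f"{r.rsid}: no genotypes in scoring matrix; skipped")
            continue
        candidates.append(r)

    order = sorted(
        range(len(candidates)),
        key=lambda i: (
            candidates[i].p,
            chrom_sort_key(candidates[i].chrom),
            candidates[i].pos,
            candidates[i].rsid,
        ),
    )
    alive = [True] * len(candidates)
    tags: list[Tag] = []
    for i in order:
        if not alive[i]:
            continue
        alive[i] = False
        index = candidates[i]
        tag = Tag(result=index)
        near = [
            k
            for k in order
            if alive[k]
            and candidates[k].chrom == index.chrom
            and abs(candidates[k].pos - index.pos) <= config.window_bp
        ]
        if near:
            cols = np.array([col_of[candidates[k].rsid] for k in near])
            r2 = _r2_index_vs(matrix.dosage, col_of[index.rsid], cols)
            for k, val in zip(near, r2):
                if np.isnan(val):
                    notes.append(
                        f"{candidates[k].rsid}: r2 with {index.rsid} undefined; treated as 0"
                    )
                    continue
                if val > config.r2_threshold:
                    alive[k] = False
                    tag.members.append((candidates[k].rsid, float(val)))
        tags.append(tag)

    if notes:
        warnings.warn(f"clumping: {len(notes)} degenerate LD computations or unmatched rsids", stacklevel=2)
    return TagSet(tags=tags, config=config, warnings=notes)
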