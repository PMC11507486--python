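"""Per-variant univariate logistic association.

Each QC-passing variant is tested one at a time: case/control status is
regressed on alt-allele dosage (intercept + slope), fitted by iteratively
reweighted least squares.  The slope is the log odds ratio lnOR — the effect
size carried forward as the Total Genotype Score weight — and significance is
the Wald p-value, matching the convention of standard GWAS tooling.  No
covariates are included by default: the analysis this mirrors is strictly
univariate (a hook is left for callers that need adjustment).

Missing dosages are handled complete-case per variant; the per-variant sample
count actually used is recorded.  Quasi-complete separation (runaway slope)
and monomorphic dosage are flagged rather than reported as spuriously
significant, and such variants are barred from downstream tag selection
because their lnOR weights would be unstable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .cohort_io import GenotypeMatrix

__all__ = [
    "LogisticFit",
    "AssociationResult",
    "AssociationTable",
    "logistic_irls",
    "fit_variant_logistic",
    "run_association",
    "bonferroni_threshold",
]

_MAX_ITER = 50
_LL_TOL = 1e-10
_SLOPE_CAP = 15.0  # |slope| beyond this is treated as separation


@dataclass(frozen=True)
class LogisticFit:
    """Result of a univariate logistic MLE (intercept + slope)."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    converged: bool
    separated: bool
    n_iter: int
    loglik: float

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return expit(self.intercept + self.slope * np.asarray(x, dtype=float))


def logistic_irls(
    x: np.ndarray,
    y: np.ndarray,
    max_iter: int = _MAX_ITER,
    tol: float = _LL_TOL,
    slope_cap: float = _SLOPE_CAP,
) -> LogisticFit:
    """Fit P(y=1) = expit(b0 + b1*x) by IRLS (Newton scoring).

    Stops when the log-likelihood improves by less than ``tol`` or after
    ``max_iter`` iterations.  A slope escaping ``slope_cap`` in absolute
    value marks (quasi-)separation: the fit is flagged, the slope clamped at
    the cap, and standard errors reported from the capped point — usable for
    emitting probabilities but not for inference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("NaN in logistic input; drop missing values first")
    n1 = y.sum()
    if n1 == 0 or n1 == y.size:
        raise ValueError("both classes must be present")
    if np.all(x == x[0]):
        # degenerate predictor: intercept-only MLE, slope identically zero
        frac = n1 / y.size
        b0 = math.log(frac / (1.0 - frac))
        eta = np.full_like(y, b0)
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        w_sum = y.size * frac * (1.0 - frac)
        return LogisticFit(
            intercept=b0, slope=0.0,
            se_intercept=math.sqrt(1.0 / w_sum), se_slope=float("nan"),
            converged=True, separated=False, n_iter=0, loglik=ll,
        )

    b0, b1 = 0.0, 0.0
    ll_old = -y.size * math.log(2.0)  # log-likelihood at (0, 0)
    converged = False
    separated = False
    it = 0
    se0 = se1 = float("nan")
    for it in range(1, max_iter + 1):
        eta = b0 + b1 * x
        p = expit(eta)
        w = p * (1.0 - p)
        resid = y - p
        g0 = resid.sum()
        g1 = (x * resid).sum()
        s00 = w.sum()
        s01 = (w * x).sum()
        s11 = (w * x * x).sum()
        det = s00 * s11 - s01 * s01
        if det <= 0 or not math.isfinite(det):
            separated = True
            break
        b0 += (s11 * g0 - s01 * g1) / det
        b1 += (s00 * g1 - s01 * g0) / det
        if abs(b1) > slope_cap:
            separated = True
            b1 = math.copysign(slope_cap, b1)
            break
        eta = b0 + b1 * x
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        if abs(ll - ll_old) < tol:
            converged = True
            ll_old = ll
            break
        ll_old = ll

    eta = b0 + b1 * x
    p = expit(eta)
    w = p * (1.0 - p)
    s00 = w.sum()
    s01 = (w * x).sum()
    s11 = (w * x * x).sum()
    det = s00 * s11 - s01 * s01
    if det > 0:
        se0 = math.sqrt(s11 / det)
        se1 = math.sqrt(s00 / det)
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    return LogisticFit(
        intercept=float(b0),
        slope=float(b1),
        se_intercept=float(se0),
        se_slope=float(se1),
        converged=converged and not separated,
        separated=separated,
        n_iter=it,
        loglik=ll,
    )


@dataclass(frozen=True)
class AssociationResult:
    """One variant's association summary: OR, lnOR (the TGS weight), Wald p."""

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    or_hat: float
    ln_or: float
    se: float
    p: float
    n_used: int
    converged: bool
    note: str = ""


@dataclass
class AssociationTable:
    """Ordered per-variant results plus analysis metadata."""

    results: list[AssociationResult]
    n_cases: int = 0
    n_controls: int = 0

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rsid": r.rsid,
                    "chrom": r.chrom,
                    "pos": r.pos,
                    "effect_allele": r.effect_allele,
                    "OR": r.or_hat,
                    "lnOR": r.ln_or,
                    "SE": r.se,
                    "P": r.p,
                    "N": r.n_used,
                    "converged": r.converged,
                }
            for r in self.results],
            columns=["rsid", "chrom", "pos", "effect_allele", "OR", "lnOR", "SE", "P", "N", "converged"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def fit_variant_logistic(
    dosages: np.ndarray,
    labels: np.ndarray,
    rsid: str = "",
    chrom: str = "",
    pos: int = 1,
    effect_allele: str = "",
) -> AssociationResult:
    """Association test for a single variant (complete-case on dosage).

    Constant dosage after dropping missing values is degenerate: the result
    is flagged ``constant_dosage`` with no odds ratio or p-value.  Separation
    yields ``converged=False`` with the p-value reported missing (NaN).
    Labels containing a single class raise, since no contrast exists.
    """
    d = np.asarray(dosages, dtype=float)
    y = np.asarray(labels, dtype=float)
    ok = ~np.isnan(d)
    d, y = d[ok], y[ok]
    n_used = int(d.size)
    if n_used == 0 or y.sum() == 0 or y.sum() == y.size:
        raise ValueError(
            f"{rsid or 'variant'}: need at least one case and one control with "
            "non-missing dosage"
        )
    if np.all(d == d[0]):
        return AssociationResult(
            rsid=rsid, chrom=chrom, pos=pos, effect_allele=effect_allele,
            or_hat=float("nan"), ln_or=float("nan"), se=float("nan"),
            p=float("nan"), n_used=n_used, converged=False, note="constant_dosage",
        )
    fit = logistic_irls(d, y)
    if fit.converged and math.isfinite(fit.se_slope) and fit.se_slope > 0:
        z = fit.slope / fit.se_slope
        p = float(2.0 * norm.sf(abs(z)))
        p = max(p, np.nextafter(0.0, 1.0))  # p in (0, 1]
        return AssociationResult(
            rsid=rsid, chrom=chrom, pos=pos, effect_allele=effect_allele,
            or_hat=math.exp(fit.slope), ln_or=fit.slope, se=fit.se_slope,
            p=p, n_used=n_used, converged=True,
        )
    note = "separation" if fit.separated else "non_convergence"
    return AssociationResult(
        rsid=rsid, chrom=chrom, pos=pos, effect_allele=effect_allele,
        or_hat=math.exp(fit.slope), ln_or=fit.slope, se=fit.se_slope,
        p=float("nan"), n_used=n_used, converged=False, note=note,
    )


def run_association(
    matrix: GenotypeMatrix, labels: np.ndarray | None = None
) -> AssociationTable:
    """Fit every variant in the matrix, in matrix (file) order."""
    if labels is None:
        labels = matrix.labels()
    labels = np.asarray(labels)
    results = [
        fit_variant_logistic(
            matrix.dosage[:, j],
            labels,
            rsid=v.rsid,
            chrom=v.chrom,
            pos=v.pos,
            effect_allele=v.alt,
        )
        for j, v in enumerate(matrix.variants)
    ]
    return AssociationTable(
        results=results,
        n_cases=int(labels.sum()),
        n_controls=int((labels == 0).sum()),
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha/m for m tests."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    return alpha / m
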