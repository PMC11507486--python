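"""Cohort splitting, TGS logistic modelling, AUC, and the end-to-end pipeline.

The evaluation design mirrors a two-stage case/control polygenic study:

1. a stratified 80/20 split fixes training and held-out validation samples
   before anything else touches the data;
2. QC, per-variant association, C+T tag selection and lnOR weights are all
   derived from the training set alone;
3. a univariate logistic model (case status ~ TGS) is fitted on training
   scores and assessed three ways: resubstitution AUC on the training set,
   stratified five-fold cross-validated AUC, and AUC on the untouched
   validation set.

Because the model has no hyperparameters, cross-validation here is purely an
assessment device; the reported validation AUC comes from a model that never
saw a validation label.  The gap between training and validation AUC —
growing with the number of training-selected tags — is the overfitting
signature this layout makes visible.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from . import qc as qc_mod
from .assoc import AssociationTable, LogisticFit, logistic_irls, run_association
from .clump import ClumpConfig, TagSet, clump
from .cohort_io import (
    GenotypeMatrix,
    SampleRecord,
    attach_phenotypes,
    intersect_panel,
    read_genotypes,
    read_panel,
    read_phenotypes,
)
from .qc import QCReport, QCThresholds, filter_variants, run_sample_qc
from .simulate import SimulationConfig, simulate_cohort
from .tgs import ScoreVector, compute_tgs, effect_weights, standardize_scores

__all__ = [
    "SplitSpec",
    "TierReport",
    "EvalReport",
    "RunConfig",
    "PipelineError",
    "split_cohort",
    "fit_tgs_logistic",
    "auc",
    "kfold_cv",
    "run_pipeline",
    "load_run_config",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Training-fraction split, stratified by phenotype by default."""

    train_fraction: float = 0.8
    seed: int = 0
    stratify: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_cohort(
    samples: Sequence[SampleRecord], spec: SplitSpec = SplitSpec()
) -> tuple[list[str], list[str]]:
    """Random stratified partition into (train ids, test ids).

    Per stratum the training count is round-half-up(n * fraction) — e.g.
    0.8 of 211 is 168.8, so 169 train / 42 test — clamped so both sides stay
    non-empty.  Assignment within a stratum is uniformly random under the
    seed; the partition is exact and disjoint.
    """
    if spec.stratify:
        strata: dict[str, list[str]] = {}
        for s in samples:
            if s.phenotype is None:
                raise ValueError(f"{s.sample_id}: phenotype unset; cannot stratify")
            strata.setdefault(s.phenotype, []).append(s.sample_id)
    else:
        strata = {"all": [s.sample_id for s in samples]}
    for name, ids in strata.items():
        if len(ids) < 2:
            raise ValueError(f"stratum {name!r} has {len(ids)} samples; need >= 2")

    rng = np.random.default_rng(spec.seed)
    train: list[str] = []
    test: list[str] = []
    for name in sorted(strata):
        ids = strata[name]
        n_train = _round_half_up(len(ids) * spec.train_fraction)
        n_train = min(max(n_train, 1), len(ids) - 1)
        perm = rng.permutation(len(ids))
        train.extend(ids[k] for k in perm[:n_train])
        test.extend(ids[k] for k in perm[n_train:])
    return train, test


# ---------------------------------------------------------------------------
# Model fit and AUC
# ---------------------------------------------------------------------------

def fit_tgs_logistic(scores: np.ndarray, labels: np.ndarray) -> LogisticFit:
    """Univariate logistic MLE of case status on TGS (same IRLS engine used
    for per-variant association).  Perfect separation is flagged on the
    returned fit; probabilities are still available from the capped slope."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if np.isnan(scores).any():
        raise ValueError("scores contain NaN; drop undefined scores first")
    return logistic_irls(scores, labels)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) formulation.

    Equals the probability that a random case outscores a random control,
    ties counted one half — identical to trapezoidal ROC integration.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if np.isnan(scores).any():
        raise ValueError("scores contain NaN")
    n1 = int(labels.sum())
    n0 = int(labels.size - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass
class CVResult:
    fold_aucs: list[float]
    mean_auc: float


def kfold_cv(
    scores: np.ndarray, labels: np.ndarray, k: int = 5, seed: int = 0
) -> CVResult:
    """Stratified k-fold cross-validated AUC of the univariate TGS model.

    Folds are stratified by label and shuffled under the seed; each fold's
    AUC comes from a model fitted on the other k-1 folds.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if np.isnan(scores).any():
        raise ValueError("scores contain NaN; drop undefined scores first")
    n1 = int(labels.sum())
    n0 = int(labels.size - n1)
    if min(n1, n0) < k:
        raise ValueError(
            f"smallest class has {min(n1, n0)} samples; cannot stratify into {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_aucs: list[float] = []
    for train_idx, test_idx in skf.split(scores.reshape(-1, 1), labels):
        fit = logistic_irls(scores[train_idx], labels[train_idx].astype(float))
        probs = fit.predict_proba(scores[test_idx])
        fold_aucs.append(auc(probs, labels[test_idx]))
    return CVResult(fold_aucs=fold_aucs, mean_auc=float(np.mean(fold_aucs)))


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

@dataclass
class TierReport:
    """Everything measured at one significance tier."""

    p_threshold: float
    n_tags: int
    tag_rsids: list[str]
    intercept: float | None = None
    slope: float | None = None
    train_auc: float | None = None        # resubstitution on the training set
    cv_aucs: list[float] = field(default_factory=list)
    cv_mean_auc: float | None = None
    validation_auc: float | None = None
    n_train_scored: int = 0
    n_validation_scored: int = 0
    roc_validation: list[list[float]] = field(default_factory=list)  # (fpr, tpr, thr)


@dataclass
class EvalReport:
    """Split sizes, QC accounting, and per-tier AUCs for one pipeline run."""

    seed: int
    n_train_cases: int
    n_train_controls: int
    n_test_cases: int
    n_test_controls: int
    n_variants_input: int
    n_variants_after_qc: int
    n_samples_after_qc: int
    n_variants_tested: int
    bonferroni_threshold: float
    tiers: dict[str, TierReport] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Full pipeline configuration.

    Exactly one input source: ``simulate`` (a :class:`SimulationConfig`) or
    the (vcf, phenotypes, panel) path triple.
    """

    simulate: SimulationConfig | None = None
    vcf: str | Path | None = None
    phenotypes: str | Path | None = None
    panel: str | Path | None = None
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    tiers: tuple[float, ...] = (0.05, 0.01)
    r2_threshold: float = 0.2
    window_bp: int = 250_000
    train_fraction: float = 0.8
    k_folds: int = 5
    seed: int = 0
    out_dir: str | Path | None = None
    make_plots: bool = False
    dosage_source: str = "GT"
    info_key: str | None = None

    def __post_init__(self) -> None:
        has_paths = self.vcf is not None or self.phenotypes is not None or self.panel is not None
        if (self.simulate is None) == (not has_paths):
            raise ValueError(
                "exactly one of a simulation config or input file paths must be given"
            )
        if has_paths and not (self.vcf and self.phenotypes and self.panel):
            raise ValueError("file input needs vcf, phenotypes and panel paths together")


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file (see the repo's example config)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = None
    if "simulate" in raw and raw["simulate"] is not None:
        sim_raw = dict(raw["simulate"])
        for key in ("maf_range", "x_maf_range"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        if "causal_spec" in sim_raw and sim_raw["causal_spec"] is not None:
            sim_raw["causal_spec"] = tuple(tuple(c) for c in sim_raw["causal_spec"])
        sim = SimulationConfig(**sim_raw)
    inputs = raw.get("inputs", {}) or {}
    thresholds = QCThresholds(**(raw.get("qc", {}) or {}))
    clump_raw = raw.get("clump", {}) or {}
    return RunConfig(
        simulate=sim,
        vcf=inputs.get("vcf"),
        phenotypes=inputs.get("phenotypes"),
        panel=inputs.get("panel"),
        thresholds=thresholds,
        tiers=tuple(clump_raw.get("tiers", (0.05, 0.01))),
        r2_threshold=float(clump_raw.get("r2_threshold", 0.2)),
        window_bp=int(clump_raw.get("window_bp", 250_000)),
        train_fraction=float((raw.get("split", {}) or {}).get("train_fraction", 0.8)),
        k_folds=int((raw.get("evaluate", {}) or {}).get("k_folds", 5)),
        seed=int(raw.get("seed", 0)),
        out_dir=raw.get("out_dir"),
        make_plots=bool(raw.get("plots", False)),
        dosage_source=str(inputs.get("dosage_source", "GT")),
        info_key=inputs.get("info_key"),
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def _tier_key(p: float) -> str:
    return f"p<={p:g}"


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage named."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> EvalReport:
    """Execute split -> QC -> association -> C+T -> TGS -> evaluation.

    Every random step derives from the single master seed, so identical
    configuration yields byte-identical reports and artifacts.  Validation
    labels are used exactly once, in the final AUC computation.
    """
    ss = np.random.SeedSequence(config.seed)
    sim_seed, split_seed, cv_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )

    with _stage("load"):
        if config.simulate is not None:
            bundle = simulate_cohort(replace(config.simulate, seed=sim_seed))
            matrix, panel = bundle.matrix, bundle.panel
        else:
            matrix = read_genotypes(
                config.vcf, dosage_source=config.dosage_source, info_key=config.info_key
            )
            matrix = attach_phenotypes(matrix, read_phenotypes(config.phenotypes))
            panel = read_panel(config.panel)
        matrix, _unmatched = intersect_panel(matrix, panel)

    with _stage("split"):
        train_ids, test_ids = split_cohort(
            matrix.samples, SplitSpec(train_fraction=config.train_fraction, seed=split_seed)
        )
        train_matrix = matrix.keep_sample_ids(train_ids)
        test_matrix = matrix.keep_sample_ids(test_ids)

    # Sample QC runs first, on the unfiltered training matrix: the sex check
    # needs the X-chromosome variants that variant QC later removes (their
    # male hemizygous coding deliberately fails the autosomal HWE test).
    with _stage("sample_qc"):
        train_matrix, sample_report = run_sample_qc(train_matrix, config.thresholds)

    with _stage("variant_qc"):
        train_matrix, variant_report = filter_variants(
            train_matrix, config.thresholds, labels=train_matrix.labels()
        )

    with _stage("association"):
        assoc_table = run_association(train_matrix)

    from .assoc import bonferroni_threshold as _bonf

    report = EvalReport(
        seed=config.seed,
        n_train_cases=assoc_table.n_cases,
        n_train_controls=assoc_table.n_controls,
        n_test_cases=int(test_matrix.labels().sum()),
        n_test_controls=int((test_matrix.labels() == 0).sum()),
        n_variants_input=variant_report.n_input,
        n_variants_after_qc=variant_report.n_retained,
        n_samples_after_qc=sample_report.n_retained,
        n_variants_tested=len(assoc_table),
        bonferroni_threshold=_bonf(0.05, max(len(assoc_table), 1)),
    )

    tier_artifacts: dict[str, dict] = {}
    for tier in config.tiers:
        key = _tier_key(tier)
        with _stage(f"clump[{key}]"):
            tag_set = clump(
                assoc_table,
                train_matrix,
                ClumpConfig(
                    p_threshold=tier,
                    r2_threshold=config.r2_threshold,
                    window_bp=config.window_bp,
                ),
            )
        tier_report = TierReport(
            p_threshold=tier, n_tags=len(tag_set), tag_rsids=tag_set.tag_rsids
        )
        report.tiers[key] = tier_report
        tier_artifacts[key] = {"tags": tag_set}
        if len(tag_set) == 0:
            continue

        with _stage(f"score[{key}]"):
            weights = effect_weights(tag_set)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                train_scores = compute_tgs(train_matrix, weights)
                val_scores = compute_tgs(test_matrix, weights)

        with _stage(f"evaluate[{key}]"):
            tr_ok = ~np.isnan(train_scores.tgs)
            tr_x = train_scores.tgs[tr_ok]
            tr_y = train_matrix.labels()[tr_ok].astype(float)
            fit = fit_tgs_logistic(tr_x, tr_y)
            tier_report.intercept = fit.intercept
            tier_report.slope = fit.slope
            tier_report.n_train_scored = int(tr_ok.sum())
            tier_report.train_auc = auc(fit.predict_proba(tr_x), tr_y)
            cv = kfold_cv(tr_x, tr_y.astype(int), k=config.k_folds, seed=cv_seed)
            tier_report.cv_aucs = cv.fold_aucs
            tier_report.cv_mean_auc = cv.mean_auc

            va_ok = ~np.isnan(val_scores.tgs)
            va_x = val_scores.tgs[va_ok]
            va_y = test_matrix.labels()[va_ok].astype(float)
            probs = fit.predict_proba(va_x)
            tier_report.n_validation_scored = int(va_ok.sum())
            tier_report.validation_auc = auc(probs, va_y)
            from sklearn.metrics import roc_curve

            fpr, tpr, thr = roc_curve(va_y, probs)
            tier_report.roc_validation = [
                [float(a), float(b), float(c)] for a, b, c in zip(fpr, tpr, thr)
            ]
            tier_artifacts[key].update(
                weights=weights,
                train_scores=train_scores,
                val_scores=val_scores,
                val_labels=va_y,
                val_x=va_x,
            )

    if config.out_dir is not None:
        _write_artifacts(
            Path(config.out_dir),
            config,
            report,
            variant_report,
            sample_report,
            assoc_table,
            tier_artifacts,
        )
    return report


def _write_artifacts(
    out: Path,
    config: RunConfig,
    report: EvalReport,
    variant_report: QCReport,
    sample_report: QCReport,
    assoc_table: AssociationTable,
    tier_artifacts: dict[str, dict],
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    variant_report.to_json(out / "qc_variants.json")
    variant_report.write_tsv(out / "qc_variants.tsv")
    sample_report.to_json(out / "qc_samples.json")
    sample_report.write_tsv(out / "qc_samples.tsv")
    assoc_table.write_tsv(out / "association.tsv")
    for key, art in tier_artifacts.items():
        slug = key.replace("<=", "").replace(".", "_")
        art["tags"].write_tsv(out / f"tags_{slug}.tsv")
        if "weights" in art:
            art["weights"].write_tsv(out / f"weights_{slug}.tsv")
            art["train_scores"].write_tsv(out / f"scores_train_{slug}.tsv")
            art["val_scores"].write_tsv(out / f"scores_validation_{slug}.tsv")
            roc = pd.DataFrame(
                report.tiers[key].roc_validation, columns=["fpr", "tpr", "threshold"]
            )
            roc.to_csv(out / f"roc_validation_{slug}.tsv", sep="\t", index=False)
    report.to_json(out / "eval_report.json")
    if config.make_plots:
        _write_plots(out, report, tier_artifacts)


def _write_plots(out: Path, report: EvalReport, tier_artifacts: dict[str, dict]) -> None:
    """ROC and standardized-TGS-distribution figures (validation set)."""
    import matplotlib

    matplotlib.use("Agg")
    matplotlib.rcParams["svg.hashsalt"] = "tgspipe"
    import matplotlib.pyplot as plt

    for key, art in tier_artifacts.items():
        if "val_scores" not in art:
            continue
        slug = key.replace("<=", "").replace(".", "_")
        tier = report.tiers[key]

        fig, ax = plt.subplots(figsize=(4, 4))
        pts = np.array(tier.roc_validation)
        ax.plot(pts[:, 0], pts[:, 1], drawstyle="steps-post")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.set_title(f"Validation ROC, {key} (AUC = {tier.validation_auc:.3f})")
        fig.tight_layout()
        fig.savefig(out / f"roc_{slug}.svg", metadata={"Date": None})
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        z = standardize_scores(art["val_x"])
        y = art["val_labels"].astype(bool)
        bins = np.linspace(np.nanmin(z), np.nanmax(z), 20)
        ax.hist(z[~y], bins=bins, alpha=0.6, label="controls", density=True)
        ax.hist(z[y], bins=bins, alpha=0.6, label="cases", density=True)
        ax.set_xlabel("Standardized TGS")
        ax.set_ylabel("Density")
        ax.set_title(f"Validation TGS distribution, {key}")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / f"tgs_distribution_{slug}.svg", metadata={"Date": None})
        plt.close(fig)
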