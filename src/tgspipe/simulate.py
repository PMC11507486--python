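"""Synthetic case/control cohort generator.

Every downstream stage of the pipeline — QC, association, clumping, scoring,
evaluation — is exercised on cohorts produced here, so the generator emulates
the statistical structure those stages assume rather than full population
genetics:

* Linkage disequilibrium via a Gaussian copula: a configurable fraction of
  variants form small equicorrelated blocks whose members share a latent
  factor (correlation ``within_block_rho``); the remainder are independent
  singleton loci.  This mirrors a multi-trait candidate panel — most hits are
  isolated loci, a minority cluster tightly within a region — and is enough
  structure to make clumping meaningful at a tiny fraction of the cost of
  coalescent simulation.
* Case/control ascertainment by rejection: each sample's case probability
  follows a logistic liability with a handful of causal loci at modest odds
  ratios, and samples are drawn until the fixed group sizes are reached —
  mirroring a study design that recruits a fixed number of athletes and
  controls rather than sampling prospectively.
* QC foils planted on demand: uniform random missingness, near-duplicate
  "relative" pairs, X-linked variants with sex-specific dosage coding and
  deliberately mis-reported sexes.

Defaults reproduce the study conditions the pipeline targets: 211 cases vs
522 controls, 2075 candidate variants in LD blocks, a minority of truly
associated loci (20 at lnOR 0.5), ~1.5% missingness, two related pairs and
two sex mismatches.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit, logit
from scipy.stats import norm

from .cohort_io import (
    CandidatePanel,
    GenotypeMatrix,
    PanelEntry,
    SampleRecord,
    Variant,
    write_panel,
    write_phenotypes,
    write_vcf,
)

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "SimulationError",
    "simulate_genotypes",
    "assign_phenotypes",
    "inject_missingness",
    "inject_relatives",
    "simulate_cohort",
    "TRAIT_VOCABULARY",
]

# Source-trait vocabulary used for synthetic panel labels: traits related to
# explosive sports performance as curated in GWAS catalog queries.
TRAIT_VOCABULARY: tuple[str, ...] = (
    "physical activity",
    "brisk walking",
    "hand grip strength",
    "lower body strength",
    "reaction time measurement",
    "lean body mass",
    "muscle mass",
    "sarcopenia",
    "IGF-1 measurement",
    "cortisol measurement",
    "myoglobin measurement",
    "testosterone measurement",
    "interleukin-6 measurement",
)


class SimulationError(ValueError):
    """Invalid simulation configuration or exhausted draw budget."""


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for one synthetic cohort.

    ``causal_spec`` is a tuple of (variant index, odds ratio); None derives
    the default of 20 causal loci at OR = e^0.5, one at the start of each of
    the first 20 LD blocks.
    """

    n_cases: int = 211
    n_controls: int = 522
    n_variants: int = 2075
    block_size: int = 5
    within_block_rho: float = 0.8
    ld_block_fraction: float = 0.35
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_spec: tuple[tuple[int, float], ...] | None = None
    base_rate: float = 0.3
    missing_rate: float = 0.015
    n_related_pairs: int = 2
    relative_copy_fidelity: float = 0.95
    n_sex_mismatch: int = 2
    n_x_variants: int = 40
    x_maf_range: tuple[float, float] = (0.2, 0.4)
    low_info_fraction: float = 0.02
    pool_margin: float = 1.4
    draw_budget: int = 0  # 0 -> 30 * (n_cases + n_controls)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SimulationError(f"maf_range {self.maf_range} outside (0, 0.5]")
        if not (0.0 <= self.within_block_rho < 1.0):
            raise SimulationError("within_block_rho must be in [0, 1)")
        if not (0.0 <= self.ld_block_fraction <= 1.0):
            raise SimulationError("ld_block_fraction must be in [0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise SimulationError("missing_rate must be in [0, 1)")
        if not (0.0 < self.base_rate < 1.0):
            raise SimulationError("base_rate must be in (0, 1)")
        for idx, odds in self.resolved_causal_spec():
            if not (0 <= idx < self.n_variants):
                raise SimulationError(f"causal index {idx} >= n_variants")
            if odds <= 0:
                raise SimulationError(f"odds ratio must be > 0, got {odds}")

    def ld_groups(self) -> list[tuple[int, int]]:
        """Contiguous [start, stop) variant index ranges sharing one latent
        LD factor: blocks of ``block_size`` for the first ``ld_block_fraction``
        of variants, singletons for the rest."""
        bs = max(1, self.block_size)
        n_blocked = int(self.ld_block_fraction * self.n_variants / bs) * bs
        groups = [(s, s + bs) for s in range(0, n_blocked, bs)]
        groups += [(j, j + 1) for j in range(n_blocked, self.n_variants)]
        return groups

    def resolved_causal_spec(self) -> tuple[tuple[int, float], ...]:
        if self.causal_spec is not None:
            return self.causal_spec
        groups = self.ld_groups()
        n_causal = min(20, len(groups))
        odds = math.exp(0.5)
        return tuple((groups[i][0], odds) for i in range(n_causal))


@dataclass
class TruthRecord:
    """Ground truth emitted alongside a simulated cohort."""

    causal: list[tuple[str, float]] = field(default_factory=list)  # (rsid, true lnOR)
    related_pairs: list[tuple[str, str]] = field(default_factory=list)
    sex_mismatches: list[str] = field(default_factory=list)
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "causal": [{"rsid": r, "ln_or": w} for r, w in self.causal],
            "related_pairs": [list(p) for p in self.related_pairs],
            "sex_mismatches": list(self.sex_mismatches),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            causal=[(d["rsid"], d["ln_or"]) for d in payload["causal"]],
            related_pairs=[tuple(p) for p in payload["related_pairs"]],
            sex_mismatches=list(payload["sex_mismatches"]),
            seed=payload.get("seed", 0),
        )


# ---------------------------------------------------------------------------
# Variant scaffolding
# ---------------------------------------------------------------------------

_BLOCK_SPACING_BP = 2_000_000  # blocks never interact through the 250 kb window
_VARIANT_SPACING_BP = 10_000   # a 25-variant block spans 240 kb, inside one window


def _make_variants(config: SimulationConfig, rng: np.random.Generator) -> tuple[list[Variant], np.ndarray]:
    """Variant metadata plus per-variant allele frequencies.

    Blocks are laid out round-robin over chromosomes 1..22, far enough apart
    that clumping windows never bridge blocks.  A configurable fraction of
    variants gets a deliberately low info score to exercise the imputation
    filter.
    """
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=config.n_variants)
    low_info = rng.random(config.n_variants) < config.low_info_fraction
    info = rng.uniform(0.7, 1.0, size=config.n_variants)
    info[low_info] = rng.uniform(0.3, 0.6, size=int(low_info.sum()))

    variants: list[Variant] = []
    for g, (start, stop) in enumerate(config.ld_groups()):
        chrom = (g % 22) + 1
        slot = g // 22
        base = 1_000_000 + slot * _BLOCK_SPACING_BP
        for j in range(start, stop):
            variants.append(
                Variant(
                    rsid=f"rs{1_000_000 + j}",
                    chrom=str(chrom),
                    pos=base + (j - start) * _VARIANT_SPACING_BP,
                    ref="A",
                    alt="G",
                    info_score=round(float(info[j]), 6),
                )
            )
    return variants, mafs


def _draw_dosages(
    config: SimulationConfig,
    mafs: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian-copula dosages: two haplotype draws per sample.

    Within a block each haplotype's latent normals share a block factor with
    loading sqrt(rho); the allele indicator thresholds the latent at
    Phi^-1(maf), so marginal allele frequencies are exact by construction.
    """
    rho = config.within_block_rho
    thresholds = norm.ppf(mafs)
    n_variants = config.n_variants
    groups = config.ld_groups()
    multi = [(s, e) for s, e in groups if e - s > 1]
    dosage = np.zeros((n_samples, n_variants))
    for _hap in range(2):
        z = rng.standard_normal((n_samples, n_variants))
        if rho > 0.0 and multi:
            # one shared factor per multi-variant group; singletons untouched
            shared = rng.standard_normal((n_samples, len(multi)))
            w_sh, w_no = math.sqrt(rho), math.sqrt(1.0 - rho)
            for k, (s, e) in enumerate(multi):
                z[:, s:e] = w_sh * shared[:, [k]] + w_no * z[:, s:e]
        dosage += (z < thresholds[np.newaxis, :]).astype(float)
    return dosage


def simulate_genotypes(
    config: SimulationConfig,
    n_samples: int | None = None,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Draw an autosomal genotype matrix for ``n_samples`` unlabeled samples.

    Deterministic under a fixed config seed (or caller-supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n_samples is None:
        n_samples = config.n_cases + config.n_controls
    variants, mafs = _make_variants(config, rng)
    dosage = _draw_dosages(config, mafs, n_samples, rng)
    samples = [SampleRecord(sample_id=f"S{i:05d}") for i in range(n_samples)]
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


# ---------------------------------------------------------------------------
# Phenotype assignment
# ---------------------------------------------------------------------------

def assign_phenotypes(
    matrix: GenotypeMatrix,
    causal_spec: Sequence[tuple[int, float]],
    base_rate: float,
    n_cases: int,
    n_controls: int,
    seed: int | np.random.Generator = 0,
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Label samples by a logistic liability and ascertain fixed group sizes.

    Case probability per sample is
    ``expit(logit(base_rate) + sum_causal lnOR * (g - 2*maf))`` — centering by
    twice the realized allele frequency keeps the population case rate near
    ``base_rate`` so rejection stays efficient.  Samples are scanned in order,
    each realizing a Bernoulli label; the first ``n_cases`` cases and
    ``n_controls`` controls are kept.  The input matrix therefore acts as the
    draw pool and must be large enough.
    """
    if n_cases < 1 or n_controls < 1:
        raise SimulationError("need at least one case and one control")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    eta = np.full(matrix.n_samples, logit(base_rate))
    truth = TruthRecord()
    for idx, odds in causal_spec:
        g = matrix.dosage[:, idx]
        f_alt = np.nanmean(g) / 2.0
        ln_or = math.log(odds)
        eta = eta + ln_or * (np.nan_to_num(g, nan=2.0 * f_alt) - 2.0 * f_alt)
        truth.causal.append((matrix.variants[idx].rsid, ln_or))

    is_case = rng.random(matrix.n_samples) < expit(eta)
    cases: list[int] = []
    controls: list[int] = []
    for i in range(matrix.n_samples):
        if is_case[i] and len(cases) < n_cases:
            cases.append(i)
        elif not is_case[i] and len(controls) < n_controls:
            controls.append(i)
        if len(cases) == n_cases and len(controls) == n_controls:
            break
    else:
        raise SimulationError(
            f"pool of {matrix.n_samples} samples yielded only {len(cases)} cases / "
            f"{len(controls)} controls; enlarge the pool or raise the draw budget"
        )

    rows = sorted(cases + controls)
    case_set = set(cases)
    labelled = matrix.subset_samples(rows)
    labelled.samples = [
        replace(s, phenotype="case" if rows[k] in case_set else "control")
        for k, s in enumerate(labelled.samples)
    ]
    return labelled, truth


# ---------------------------------------------------------------------------
# QC foils
# ---------------------------------------------------------------------------

def inject_missingness(
    matrix: GenotypeMatrix,
    missing_rate: float,
    seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Set each dosage cell missing independently with the given probability."""
    if not (0.0 <= missing_rate <= 1.0):
        raise SimulationError("missing_rate must be in [0, 1]")
    out = matrix.copy()
    if missing_rate == 0.0:
        return out
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = rng.random(out.dosage.shape) < missing_rate
    out.dosage[mask] = np.nan
    return out


def inject_relatives(
    matrix: GenotypeMatrix,
    n_pairs: int,
    copy_fidelity: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Append near-duplicate copies of ``n_pairs`` randomly chosen samples.

    Each copy keeps its donor's genotypes except that every locus is
    independently resampled from the cohort allele frequency with probability
    ``1 - copy_fidelity`` (fidelity 1 gives an exact duplicate, i.e. a
    monozygotic-twin-like pair that relatedness QC must catch).
    """
    if not (0.0 <= copy_fidelity <= 1.0):
        raise SimulationError("copy_fidelity must be in [0, 1]")
    truth = TruthRecord()
    if n_pairs == 0:
        return matrix.copy(), truth
    if n_pairs > matrix.n_samples:
        raise SimulationError("more related pairs requested than samples available")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    freqs = np.nanmean(matrix.dosage, axis=0) / 2.0
    donors = rng.choice(matrix.n_samples, size=n_pairs, replace=False)
    new_rows = []
    new_samples = []
    for d in donors:
        donor = matrix.samples[d]
        row = matrix.dosage[d].copy()
        resample = rng.random(matrix.n_variants) < (1.0 - copy_fidelity)
        if resample.any():
            row[resample] = rng.binomial(2, freqs[resample]).astype(float)
        copy_id = f"{donor.sample_id}R"
        new_rows.append(row)
        new_samples.append(replace(donor, sample_id=copy_id))
        truth.related_pairs.append((donor.sample_id, copy_id))
    out = GenotypeMatrix(
        samples=list(matrix.samples) + new_samples,
        variants=list(matrix.variants),
        dosage=np.vstack([matrix.dosage] + [r[np.newaxis, :] for r in new_rows]),
    )
    return out, truth


def _append_x_variants(
    matrix: GenotypeMatrix,
    true_sex: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    """Add X-chromosome variants with sex-specific coding.

    Males are hemizygous, coded homozygous: dosage in {0, 2}; females follow
    Hardy-Weinberg with dosage in {0, 1, 2}.  The resulting absence of male
    heterozygotes is what the sex-check inbreeding statistic keys on.
    """
    if config.n_x_variants == 0:
        return matrix
    lo, hi = config.x_maf_range
    mafs = rng.uniform(lo, hi, size=config.n_x_variants)
    n = matrix.n_samples
    male = np.array([true_sex[s.sample_id] == "male" for s in matrix.samples])
    cols = np.empty((n, config.n_x_variants))
    for j in range(config.n_x_variants):
        female_dose = rng.binomial(2, mafs[j], size=n).astype(float)
        male_dose = 2.0 * rng.binomial(1, mafs[j], size=n)
        cols[:, j] = np.where(male, male_dose, female_dose)
    x_variants = [
        Variant(
            rsid=f"rsX{2_000_000 + j}",
            chrom="X",
            pos=1_000_000 + j * _VARIANT_SPACING_BP,
            ref="A",
            alt="G",
            info_score=1.0,
        )
        for j in range(config.n_x_variants)
    ]
    return GenotypeMatrix(
        samples=list(matrix.samples),
        variants=list(matrix.variants) + x_variants,
        dosage=np.hstack([matrix.dosage, cols]),
    )


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------

@dataclass
class CohortBundle:
    """A complete simulated input set, in memory and (optionally) on disk."""

    matrix: GenotypeMatrix
    panel: CandidatePanel
    truth: TruthRecord
    paths: dict[str, Path] = field(default_factory=dict)


def simulate_cohort(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> CohortBundle:
    """Generate a full runnable input bundle (VCF, phenotypes, panel, truth).

    Stages, each drawing from one master generator so that identical
    config+seed gives byte-identical outputs: genotype pool -> liability
    phenotypes with case/control ascertainment -> sex assignment and X
    variants -> relative pairs -> missingness -> reported-sex swaps ->
    panel labels.
    """
    rng = np.random.default_rng(config.seed)
    n_target = config.n_cases + config.n_controls
    budget = config.draw_budget or 30 * n_target
    pool_n = math.ceil(
        max(config.n_cases / config.base_rate, config.n_controls / (1.0 - config.base_rate))
        * config.pool_margin
    )
    pool_n = min(max(pool_n, n_target), budget)

    pool = simulate_genotypes(config, n_samples=pool_n, rng=rng)
    matrix, truth = assign_phenotypes(
        pool,
        config.resolved_causal_spec(),
        config.base_rate,
        config.n_cases,
        config.n_controls,
        seed=rng,
    )
    truth.seed = config.seed

    true_sex = {
        s.sample_id: ("male" if rng.random() < 0.5 else "female")
        for s in matrix.samples
    }
    matrix.samples = [replace(s, reported_sex=true_sex[s.sample_id]) for s in matrix.samples]
    matrix = _append_x_variants(matrix, true_sex, config, rng)

    matrix, rel_truth = inject_relatives(
        matrix, config.n_related_pairs, config.relative_copy_fidelity, seed=rng
    )
    truth.related_pairs = rel_truth.related_pairs
    for donor_id, copy_id in rel_truth.related_pairs:
        true_sex[copy_id] = true_sex[donor_id]

    matrix = inject_missingness(matrix, config.missing_rate, seed=rng)

    if config.n_sex_mismatch > matrix.n_samples:
        raise SimulationError("more sex mismatches requested than samples")
    swap_rows = sorted(
        rng.choice(matrix.n_samples, size=config.n_sex_mismatch, replace=False).tolist()
    )
    flip = {"male": "female", "female": "male"}
    for i in swap_rows:
        s = matrix.samples[i]
        matrix.samples[i] = replace(s, reported_sex=flip[s.reported_sex])
        truth.sex_mismatches.append(s.sample_id)

    # Synthetic candidate panel: one trait per variant, a small fraction
    # listed under a second trait as well so panel deduplication is exercised.
    entries: list[PanelEntry] = []
    for v in matrix.variants:
        k = int(rng.integers(len(TRAIT_VOCABULARY)))
        traits = {TRAIT_VOCABULARY[k]}
        if rng.random() < 0.03:
            k2 = int(rng.integers(len(TRAIT_VOCABULARY)))
            traits.add(TRAIT_VOCABULARY[k2])
        entries.append(PanelEntry(rsid=v.rsid, traits=frozenset(traits)))
    panel = CandidatePanel(entries=entries, n_input_rows=sum(len(e.traits) for e in entries))

    bundle = CohortBundle(matrix=matrix, panel=panel, truth=truth)
    if out_dir is not None:
        out = Path(out_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise SimulationError(f"cannot create output directory {out}: {exc}") from exc
        bundle.paths = {
            "vcf": out / "genotypes.vcf",
            "phenotypes": out / "phenotypes.tsv",
            "panel": out / "panel.tsv",
            "truth": out / "truth.json",
        }
        write_vcf(matrix, bundle.paths["vcf"])
        write_phenotypes(matrix.samples, bundle.paths["phenotypes"])
        write_panel(panel, bundle.paths["panel"])
        truth.to_json(bundle.paths["truth"])
    return bundle
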