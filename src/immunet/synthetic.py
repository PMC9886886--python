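"""Synthetic two-group expression cohorts with planted co-expression modules.

The generator provides ground truth for every downstream stage: a genes ×
samples matrix whose modules share a single latent factor (so the
population within-module correlation has the closed form β²/(β²+σ²)),
a PPI graph enriched for within-module edges, gene category labels
(PD / immune / immune-PD / other) assigned per module, and disjoint
signature sets with planted between-group infiltration shifts.

Model for gene g in module m, sample j:

    x_gj = μ_g + β·f_mj + δ·1[j ∈ disease, m shifted] + σ·ε_gj

with f_mj and ε_gj independent standard normal, μ_g a fixed gene baseline.
Genes outside any module are baseline plus noise.  The model makes no claim
about the expression unit (the values are abstract continuous intensities,
already on a log-like scale); probe-level artifacts, batch effects and
count-distribution quirks of real platforms are deliberately out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data_io import CONTROL, DISEASE, ExpressionMatrix, canonical_edge

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_dataset",
    "generate_signature_sets",
    "generate_signature_dataset",
]

CATEGORIES = ("PD", "immune-PD", "immune", "other")

#: default per-module category fractions: enough PD-related (core) genes per
#: module to clear the module-selection core threshold at module_size 10.
DEFAULT_MODULE_PLAN: dict[str, float] = {"PD": 0.4, "immune-PD": 0.3, "immune": 0.2}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a planted-module cohort.

    The defaults mirror the study conditions the pipeline targets: 8 control
    and 14 disease samples, modules of 10 genes with loading β=2 and noise
    σ=1 (population within-module correlation β²/(β²+σ²) = 0.8), and a PPI
    graph strongly enriched within modules.
    """

    n_genes: int = 60
    n_modules: int = 5
    module_size: int = 10
    n_control: int = 8
    n_disease: int = 14
    loading: float = 2.0  # β
    noise_sd: float = 1.0  # σ
    disease_shift: float = 0.0  # δ, per-module mean shift in disease samples
    ppi_within_prob: float = 0.8
    ppi_background_prob: float = 0.02
    category_plan: Mapping[int, Mapping[str, float]] | None = None
    shifted_modules: tuple[int, ...] | None = None
    seed: int = 0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("n_modules * module_size exceeds n_genes")
        for name in ("n_genes", "n_modules", "module_size", "n_control", "n_disease"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("ppi_within_prob", "ppi_background_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.loading < 0:
            raise ValueError("loading must be >= 0")
        if self.category_plan is not None:
            for m, plan in self.category_plan.items():
                if not 0 <= m < self.n_modules:
                    raise ValueError(f"category_plan references module {m}")
                if any(c not in CATEGORIES[:3] for c in plan):
                    raise ValueError(f"unknown category in plan for module {m}")
                if sum(plan.values()) > 1.0 + 1e-9:
                    raise ValueError(f"category fractions for module {m} exceed 1")
        if self.shifted_modules is not None:
            for m in self.shifted_modules:
                if not 0 <= m < self.n_modules:
                    raise ValueError(f"shifted module {m} out of range")

    @property
    def within_module_correlation(self) -> float:
        """Population Pearson r between two genes of the same module."""
        b2 = self.loading**2
        return b2 / (b2 + self.noise_sd**2)

    def effective_shifted_modules(self) -> tuple[int, ...]:
        """Modules receiving the disease shift.

        Defaults to the first ⌈n_modules/2⌉ modules: shifting a strict
        subset keeps the group signal visible to correlation-based sample
        distances (a shift on every gene is a per-sample constant, which
        Pearson distance ignores).
        """
        if self.shifted_modules is not None:
            return tuple(self.shifted_modules)
        if self.disease_shift == 0:
            return ()
        return tuple(range(math.ceil(self.n_modules / 2)))


@dataclass
class GroundTruth:
    """Planted structure of a generated dataset."""

    module_membership: dict[str, int | None]
    true_categories: dict[str, str]
    planted_ppi_edges: list[tuple[str, str]]
    shifted_modules: set[int] = field(default_factory=set)
    signature_sets: dict[str, set[str]] = field(default_factory=dict)
    shifted_sets: set[str] = field(default_factory=set)

    def module_genes(self, m: int) -> set[str]:
        return {g for g, mm in self.module_membership.items() if mm == m}


def _gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:06d}" for i in range(n)]


def _sample_ids(n_control: int, n_disease: int) -> tuple[list[str], dict[str, str]]:
    controls = [f"C{i + 1:02d}" for i in range(n_control)]
    diseases = [f"D{i + 1:02d}" for i in range(n_disease)]
    groups = {s: CONTROL for s in controls} | {s: DISEASE for s in diseases}
    return controls + diseases, groups


def _assign_categories(config: SyntheticConfig, membership: dict[str, int | None]) -> dict[str, str]:
    plan = config.category_plan
    if plan is None:
        plan = {m: DEFAULT_MODULE_PLAN for m in range(config.n_modules)}
    categories: dict[str, str] = {}
    per_module: dict[int, list[str]] = {}
    for g, m in membership.items():
        if m is None:
            categories[g] = "other"
        else:
            per_module.setdefault(m, []).append(g)
    for m, genes in per_module.items():
        genes = sorted(genes)
        module_plan = plan.get(m, {})
        cursor = 0
        # deterministic block assignment in category order PD, immune-PD, immune
        for cat in ("PD", "immune-PD", "immune"):
            frac = module_plan.get(cat, 0.0)
            k = int(round(frac * len(genes)))
            for g in genes[cursor : cursor + k]:
                categories[g] = cat
            cursor += k
        for g in genes[cursor:]:
            categories[g] = "other"
    return categories


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, list[tuple[str, str]], dict[str, str], GroundTruth]:
    """Generate an expression matrix, PPI edge list, categories and truth.

    A single RNG stream seeded from ``config.seed`` drives every draw, so
    identical configurations yield bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    samples, groups = _sample_ids(config.n_control, config.n_disease)
    n_samples = len(samples)
    membership: dict[str, int | None] = {
        g: (i // config.module_size if i < config.n_modules * config.module_size else None)
        for i, g in enumerate(genes)
    }
    shifted = set(config.effective_shifted_modules())

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    factors = rng.standard_normal((config.n_modules, n_samples))
    noise = rng.standard_normal((config.n_genes, n_samples)) * config.noise_sd
    disease_mask = np.array([groups[s] == DISEASE for s in samples], dtype=float)

    x = baseline[:, None] + noise
    for i, g in enumerate(genes):
        m = membership[g]
        if m is None:
            continue
        x[i] += config.loading * factors[m]
        if m in shifted:
            x[i] += config.disease_shift * disease_mask

    ppi: list[tuple[str, str]] = []
    for i in range(config.n_genes):
        for j in range(i + 1, config.n_genes):
            mi, mj = membership[genes[i]], membership[genes[j]]
            same = mi is not None and mi == mj
            p = config.ppi_within_prob if same else config.ppi_background_prob
            if p > 0 and rng.random() < p:
                ppi.append(canonical_edge(genes[i], genes[j]))

    categories = _assign_categories(config, membership)
    em = ExpressionMatrix(pd.DataFrame(x, index=genes, columns=samples), groups)
    truth = GroundTruth(membership, categories, list(ppi), shifted)
    return em, ppi, categories, truth


def generate_signature_sets(
    config: SyntheticConfig, n_sets: int, set_size: int, n_shifted_sets: int
) -> tuple[dict[str, set[str]], GroundTruth]:
    """Disjoint signature sets over the configured gene universe.

    The first ``n_shifted_sets`` sets are marked as carrying a disease-group
    mean shift of ``config.disease_shift``; the expression matrix realising
    those shifts comes from :func:`generate_signature_dataset`.
    """
    if n_sets < 1 or set_size < 1:
        raise ValueError("n_sets and set_size must be positive")
    if n_sets * set_size > config.n_genes:
        raise ValueError("n_sets * set_size exceeds n_genes")
    if not 0 <= n_shifted_sets <= n_sets:
        raise ValueError("n_shifted_sets out of range")
    genes = _gene_ids(config.n_genes)
    sets: dict[str, set[str]] = {}
    for s in range(n_sets):
        name = f"CELL_{s + 1:02d}"
        sets[name] = set(genes[s * set_size : (s + 1) * set_size])
    shifted_names = {f"CELL_{s + 1:02d}" for s in range(n_shifted_sets)}
    truth = GroundTruth(
        module_membership={g: None for g in genes},
        true_categories={g: "other" for g in genes},
        planted_ppi_edges=[],
        signature_sets=dict(sets),
        shifted_sets=shifted_names,
    )
    return sets, truth


def generate_signature_dataset(
    config: SyntheticConfig, n_sets: int, set_size: int, n_shifted_sets: int
) -> tuple[ExpressionMatrix, dict[str, set[str]], GroundTruth]:
    """Expression matrix plus signature sets with planted infiltration shifts.

    Genes are independent (baseline + noise); members of the shifted sets
    gain ``config.disease_shift`` in disease samples, so differential
    infiltration has known positives and the remaining sets are true nulls.
    """
    sets, truth = generate_signature_sets(config, n_sets, set_size, n_shifted_sets)
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    samples, groups = _sample_ids(config.n_control, config.n_disease)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    x = baseline[:, None] + rng.standard_normal((config.n_genes, len(samples))) * config.noise_sd
    shifted_genes = set().union(*(sets[name] for name in truth.shifted_sets)) if truth.shifted_sets else set()
    disease_cols = [j for j, s in enumerate(samples) if groups[s] == DISEASE]
    for i, g in enumerate(genes):
        if g in shifted_genes:
            x[i, disease_cols] += config.disease_shift
    em = ExpressionMatrix(pd.DataFrame(x, index=genes, columns=samples), groups)
    return em, sets, truth
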