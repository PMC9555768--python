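"""Synthetic data with planted ground truth for both analysis stages.

Two generators:

* :func:`simulate_deg_tables` emits a pair of linked DEG tables (mutant
  contrast, treatment contrast) over a shared gene universe with planted
  direction-concordance structure — so rescue classification and the
  enrichment arguments can be checked against known truth.
* :func:`simulate_sections` emits labeled-cell point patterns for serial
  sections. The wild-type-like process is homogeneous Poisson; the
  mutant-like process adds a Neyman-Scott cluster component (a share of
  cells placed as Gaussian offspring around uniformly placed parents),
  emulating the condensation of cells in the arch core, plus an anterior
  count boost emulating increased numerosity.

Both are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .rescue import DEGTable, RescueClassification
from .spatial import SectionPattern

__all__ = [
    "DEGSimConfig",
    "DEGSimTruth",
    "SectionSimConfig",
    "PointSimTruth",
    "simulate_deg_tables",
    "simulate_sections",
    "evaluate_recovery",
]

CATEGORIES = (
    "rescued_up", "rescued_down", "further_up", "further_down",
    "mut_only_up", "mut_only_down", "treat_only_up", "treat_only_down", "null",
)

# sign of the planted log2 fold change in (mutant contrast, treatment contrast);
# 0 = not differentially expressed in that contrast
_SIGNS = {
    "rescued_up": (+1, -1),
    "rescued_down": (-1, +1),
    "further_up": (+1, +1),
    "further_down": (-1, -1),
    "mut_only_up": (+1, 0),
    "mut_only_down": (-1, 0),
    "treat_only_up": (0, +1),
    "treat_only_down": (0, -1),
    "null": (0, 0),
}


@dataclass(frozen=True)
class DEGSimConfig:
    """Planted sizes and noise levels for a linked pair of DEG tables.

    Defaults reproduce the study-scale structure: a 14,488-gene tested
    universe, 851 up / 558 down mutant DEGs, 1862 up / 2092 down treatment
    DEGs, with direction-concordance overlaps 259 (up/down), 85 (down/up),
    59 (up/up) and 65 (down/down).
    """

    universe_n: int = 14488
    n_mut_up: int = 851
    n_mut_down: int = 558
    n_treat_up: int = 1862
    n_treat_down: int = 2092
    n_rescued_up: int = 259
    n_rescued_down: int = 85
    n_further_up: int = 59
    n_further_down: int = 65
    effect_log2fc: float = 1.0
    fc_noise_sd: float = 0.1
    pp_de: float = 0.99
    pp_null: float = 0.1
    seed: int = 0

    def category_sizes(self) -> dict:
        sizes = {
            "rescued_up": self.n_rescued_up,
            "rescued_down": self.n_rescued_down,
            "further_up": self.n_further_up,
            "further_down": self.n_further_down,
            "mut_only_up": self.n_mut_up - self.n_rescued_up - self.n_further_up,
            "mut_only_down": self.n_mut_down - self.n_rescued_down - self.n_further_down,
            "treat_only_up": self.n_treat_up - self.n_rescued_down - self.n_further_up,
            "treat_only_down": self.n_treat_down - self.n_rescued_up - self.n_further_down,
        }
        sizes["null"] = self.universe_n - sum(sizes.values())
        return sizes

    def __post_init__(self) -> None:
        if self.effect_log2fc <= 0:
            raise ValueError("effect_log2fc must be > 0")
        if self.fc_noise_sd < 0:
            raise ValueError("fc_noise_sd must be >= 0")
        for name in ("pp_de", "pp_null"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        bad = {k: v for k, v in self.category_sizes().items() if v < 0}
        if bad:
            raise ValueError(
                f"inconsistent category sizes (negative implied counts): {bad}"
            )


@dataclass(frozen=True)
class DEGSimTruth:
    """Planted category per gene; mutually exclusive, exhaustive over the
    universe."""

    category: Mapping[str, str]

    def genes_in(self, category: str) -> frozenset:
        return frozenset(g for g, c in self.category.items() if c == category)

    def counts(self) -> dict:
        out = {c: 0 for c in CATEGORIES}
        for c in self.category.values():
            out[c] += 1
        return out


def simulate_deg_tables(config: DEGSimConfig) -> tuple:
    """Generate (mutant table, treatment table, truth).

    Planted DE genes get ``|log2fc| = effect_log2fc + N(0, fc_noise_sd)``
    with the category's sign in each contrast and ``pp = pp_de``; genes not
    DE in a contrast get ``log2fc ~ N(0, fc_noise_sd)`` and ``pp = pp_null``.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    sizes = config.category_sizes()
    width = len(str(config.universe_n))
    genes = np.array([f"g{i:0{width}d}" for i in range(1, config.universe_n + 1)])
    rng.shuffle(genes)

    category = np.empty(config.universe_n, dtype=object)
    start = 0
    for cat in CATEGORIES:
        n = sizes[cat]
        category[start:start + n] = cat
        start += n

    mut_sign = np.array([_SIGNS[c][0] for c in category])
    treat_sign = np.array([_SIGNS[c][1] for c in category])

    def contrast(signs: np.ndarray, name: str) -> DEGTable:
        noise = rng.normal(0.0, config.fc_noise_sd, size=config.universe_n)
        de = signs != 0
        log2fc = np.where(de, signs * (config.effect_log2fc + noise), noise)
        pp = np.where(de, config.pp_de, config.pp_null)
        df = pd.DataFrame({"gene_id": genes, "log2fc": log2fc, "pp": pp})
        df = df.sort_values("gene_id").reset_index(drop=True)
        return DEGTable(name, df, universe_size=config.universe_n)

    mut = contrast(mut_sign, "mut_vs_wt")
    treat = contrast(treat_sign, "treated_vs_untreated")
    truth = DEGSimTruth(category=dict(zip(genes.tolist(), category.tolist())))
    return mut, treat, truth


@dataclass(frozen=True)
class SectionSimConfig:
    """Generative settings for serial-section point patterns.

    The region is a ``width x height`` um rectangle (the gridded portion of
    the arch). Per section the total count is Poisson with mean
    ``base_intensity * area / 100`` (intensity in cells per 100 um^2),
    multiplied by ``anterior_boost`` for anterior sections of untreated
    mutant genotypes. A ``cluster_fraction`` share of cells is placed as
    Gaussian offspring (sd ``cluster_sd``) around ``n_cluster_parents``
    uniformly placed parents; the rest is uniform. ``cluster_fraction = 0``
    is the wild-type-like homogeneous process.
    """

    width: float = 200.0
    height: float = 160.0
    n_sections_A: int = 8
    n_sections_P: int = 5
    n_embryos: int = 5
    base_intensity: float = 0.5
    anterior_boost: float = 1.3
    cluster_fraction: float = 0.0
    n_cluster_parents: int = 3
    cluster_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("region must have positive width and height")
        if self.base_intensity < 0 or self.anterior_boost < 0:
            raise ValueError("intensities must be >= 0")
        if not 0 <= self.cluster_fraction <= 1:
            raise ValueError("cluster_fraction must lie in [0, 1]")
        if self.cluster_fraction > 0 and self.n_cluster_parents < 1:
            raise ValueError("cluster_fraction > 0 requires n_cluster_parents >= 1")
        if self.cluster_fraction > 0 and self.cluster_sd <= 0:
            raise ValueError("cluster_sd must be > 0 when clustering")
        if not 8 <= self.n_sections_A <= 10:
            raise ValueError("n_sections_A must lie in [8, 10]")
        if not 4 <= self.n_sections_P <= 7:
            raise ValueError("n_sections_P must lie in [4, 7]")

    @classmethod
    def wt_like(cls, **kwargs) -> "SectionSimConfig":
        """Homogeneous, unclustered process (wild-type phenotype)."""
        kwargs.setdefault("cluster_fraction", 0.0)
        return cls(**kwargs)

    @classmethod
    def mutant_like(cls, **kwargs) -> "SectionSimConfig":
        """Clustered, anterior-boosted process (null-mutant phenotype)."""
        kwargs.setdefault("cluster_fraction", 0.6)
        kwargs.setdefault("n_cluster_parents", 3)
        kwargs.setdefault("cluster_sd", 10.0)
        return cls(**kwargs)


@dataclass(frozen=True)
class PointSimTruth:
    """Per-section cluster parents and per-point cluster-membership flags.

    Keys of both mappings are ``(embryo_id, segment, section_index)``.
    """

    parents: Mapping[tuple, np.ndarray]
    is_clustered: Mapping[tuple, np.ndarray]


# genotypes whose anterior sections get the count boost (untreated mutants)
_BOOSTED = ("het", "null")


def simulate_sections(config: SectionSimConfig, genotype: str = "WT") -> tuple:
    """Generate (patterns, truth) for all embryos of one genotype.

    Returns one :class:`SectionPattern` per section per embryo
    (``n_sections_A`` anterior + ``n_sections_P`` posterior each) and the
    planted :class:`PointSimTruth`. Deterministic given ``config.seed`` and
    the genotype.
    """
    from .spatial import GENOTYPES

    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    # fold the genotype label into the stream so genotypes differ under one seed
    rng = np.random.default_rng([config.seed, GENOTYPES.index(genotype)])
    area_units = config.width * config.height / 100.0
    patterns = []
    parents: dict = {}
    member: dict = {}
    for e in range(1, config.n_embryos + 1):
        embryo_id = f"{genotype}_e{e}"
        for segment, n_sections in (("A", config.n_sections_A),
                                    ("P", config.n_sections_P)):
            boost = (
                config.anterior_boost
                if segment == "A" and genotype in _BOOSTED else 1.0
            )
            for s in range(1, n_sections + 1):
                n = rng.poisson(config.base_intensity * area_units * boost)
                n_clustered = (
                    rng.binomial(n, config.cluster_fraction)
                    if config.cluster_fraction > 0 else 0
                )
                par = rng.uniform(
                    [0.0, 0.0], [config.width, config.height],
                    size=(config.n_cluster_parents, 2),
                )
                pts = np.empty((n, 2))
                flags = np.zeros(n, dtype=bool)
                if n_clustered:
                    which = rng.integers(0, config.n_cluster_parents, size=n_clustered)
                    pts[:n_clustered] = par[which] + rng.normal(
                        0.0, config.cluster_sd, size=(n_clustered, 2)
                    )
                    flags[:n_clustered] = True
                pts[n_clustered:] = rng.uniform(
                    [0.0, 0.0], [config.width, config.height],
                    size=(n - n_clustered, 2),
                )
                patterns.append(
                    SectionPattern(
                        points=pts, section_index=s, embryo_id=embryo_id,
                        genotype=genotype, segment=segment,
                    )
                )
                key = (embryo_id, segment, s)
                parents[key] = par
                member[key] = flags
    return patterns, PointSimTruth(parents=parents, is_clustered=member)


def evaluate_recovery(cls: RescueClassification, truth: DEGSimTruth) -> pd.DataFrame:
    """Per-category sensitivity and specificity of a rescue classification.

    Sensitivity = planted genes of the category that were recovered into it;
    specificity = genes planted in *other* categories (or null) that were
    correctly not placed in it.
    """
    universe = set(truth.category)
    recovered = {
        name: set(getattr(cls, name))
        for name in ("rescued_up", "rescued_down", "further_up", "further_down")
    }
    for name, rec in recovered.items():
        if rec - universe:
            raise ValueError(
                f"classified gene(s) outside the simulated universe in {name}"
            )
    rows = []
    for name, rec in recovered.items():
        planted = truth.genes_in(name)
        others = universe - planted
        tp = len(rec & planted)
        fp = len(rec - planted)
        sens = tp / len(planted) if planted else float("nan")
        spec = (len(others) - fp) / len(others) if others else float("nan")
        rows.append((name, len(planted), tp, fp, sens, spec))
    return pd.DataFrame(
        rows,
        columns=["category", "n_planted", "n_recovered", "n_false", "sensitivity",
                 "specificity"],
    )
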