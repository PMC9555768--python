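"""Rescued-gene classification from paired differential-expression contrasts.

A gene dysregulated by a mutation (mutant-vs-WT contrast) whose expression
moves in the *opposite* direction under treatment (treated-vs-untreated
contrast) is classified as *rescued*: the treatment rebalanced it toward the
wild-type level. Genes moving in the *same* direction in both contrasts are
*further dysregulated*. Whether the observed overlaps between the two DEG
lists exceed chance is assessed with upper-tail hypergeometric tests on a
shared tested-gene universe.

The statsmodels-style entry point is :class:`RescueModel`; the individual
steps (:func:`filter_degs`, :func:`classify_rescue`,
:func:`hypergeom_upper_tail`, :func:`enrichment_report`,
:func:`summarize_counts`) are plain functions usable on their own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "DEGRecord",
    "DEGTable",
    "FilterConfig",
    "SignedGeneSets",
    "RescueClassification",
    "EnrichmentTest",
    "EnrichmentReport",
    "filter_degs",
    "classify_rescue",
    "hypergeom_upper_tail",
    "enrichment_report",
    "summarize_counts",
    "RescueModel",
    "RescueResults",
]


@dataclass(frozen=True)
class DEGRecord:
    """One gene in one contrast: log2 fold change and posterior probability."""

    gene_id: str
    log2fc: float
    pp: float

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not math.isfinite(self.log2fc):
            raise ValueError(f"log2fc must be finite, got {self.log2fc!r} for {self.gene_id}")
        if not 0.0 <= self.pp <= 1.0:
            raise ValueError(f"pp must lie in [0, 1], got {self.pp!r} for {self.gene_id}")


@dataclass
class DEGTable:
    """Per-gene effect sizes and posterior probabilities for one contrast.

    Parameters
    ----------
    contrast_name
        Label for the comparison (e.g. ``"het_vs_wt"``).
    data
        DataFrame with columns ``gene_id``, ``log2fc``, ``pp``. Fold changes
        are on the log2 scale; use :func:`rescuekit.io.read_deg_table` to
        convert linear fold changes on input.
    universe_size
        Number of genes tested in the contrast (defaults to the number of
        records). The enrichment tests condition on this universe.
    """

    contrast_name: str
    data: pd.DataFrame
    universe_size: int | None = None

    def __post_init__(self) -> None:
        required = {"gene_id", "log2fc", "pp"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"DEGTable data missing columns: {sorted(missing)}")
        dup = self.data["gene_id"][self.data["gene_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate gene_id in {self.contrast_name!r}: {dup.iloc[0]!r}")
        if not np.isfinite(self.data["log2fc"].to_numpy(float)).all():
            raise ValueError("non-finite log2fc in table")
        pp = self.data["pp"].to_numpy(float)
        if ((pp < 0) | (pp > 1)).any():
            bad = self.data.loc[(pp < 0) | (pp > 1), "gene_id"].iloc[0]
            raise ValueError(f"pp outside [0, 1] for gene {bad!r}")
        if self.universe_size is None:
            self.universe_size = len(self.data)
        if self.universe_size < len(self.data):
            raise ValueError(
                f"universe_size {self.universe_size} < number of records {len(self.data)}"
            )

    @classmethod
    def from_records(
        cls,
        contrast_name: str,
        records: Iterable[DEGRecord],
        universe_size: int | None = None,
    ) -> "DEGTable":
        recs = list(records)
        df = pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in recs],
                "log2fc": [r.log2fc for r in recs],
                "pp": [r.pp for r in recs],
            }
        )
        return cls(contrast_name, df, universe_size)

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class FilterConfig:
    """DEG thresholds: minimum linear |fold change| and posterior probability.

    Both cuts are inclusive (a gene at exactly the threshold passes). The
    fold-change threshold is given on the linear scale and applied as
    ``|log2fc| >= log2(min_abs_fc)``.
    """

    min_abs_fc: float = 1.2
    min_pp: float = 0.95

    def __post_init__(self) -> None:
        if not self.min_abs_fc > 1:
            raise ValueError(f"min_abs_fc must be > 1, got {self.min_abs_fc}")
        if not 0 < self.min_pp <= 1:
            raise ValueError(f"min_pp must lie in (0, 1], got {self.min_pp}")

    @property
    def min_abs_log2fc(self) -> float:
        return math.log2(self.min_abs_fc)


@dataclass(frozen=True)
class SignedGeneSets:
    """Up- and downregulated DEG identifiers for one contrast."""

    up: frozenset
    down: frozenset

    def __post_init__(self) -> None:
        overlap = self.up & self.down
        if overlap:
            raise ValueError(f"gene(s) in both up and down: {sorted(overlap)[:3]}")

    @property
    def total(self) -> int:
        return len(self.up) + len(self.down)

    @property
    def all_degs(self) -> frozenset:
        return self.up | self.down


@dataclass(frozen=True)
class RescueClassification:
    """Partition of the shared DEGs by direction concordance.

    ``rescued_up``: up in the mutant contrast, down under treatment
    (expression rebalanced from above); ``rescued_down``: the converse;
    ``further_up`` / ``further_down``: same direction in both contrasts.
    """

    rescued_up: frozenset
    rescued_down: frozenset
    further_up: frozenset
    further_down: frozenset

    def __post_init__(self) -> None:
        sets = [self.rescued_up, self.rescued_down, self.further_up, self.further_down]
        for i, a in enumerate(sets):
            for b in sets[i + 1 :]:
                if a & b:
                    raise ValueError("rescue categories must be pairwise disjoint")

    @property
    def shared_total(self) -> int:
        return (
            len(self.rescued_up)
            + len(self.rescued_down)
            + len(self.further_up)
            + len(self.further_down)
        )

    @property
    def rescued_total(self) -> int:
        return len(self.rescued_up) + len(self.rescued_down)

    @property
    def further_total(self) -> int:
        return len(self.further_up) + len(self.further_down)

    def category_of(self) -> dict:
        """Mapping gene_id -> category name, over all shared genes."""
        out: dict = {}
        for name in ("rescued_up", "rescued_down", "further_up", "further_down"):
            for g in getattr(self, name):
                out[g] = name
        return out


@dataclass(frozen=True)
class EnrichmentTest:
    """One upper-tail hypergeometric overlap test.

    ``q`` observed overlap, ``m`` size of set 1, ``k`` size of set 2,
    ``universe_n`` genes tested. ``p_value`` is P(X >= q) for X hypergeometric
    with ``universe_n`` items of which ``m`` are successes and ``k`` drawn.
    """

    q: int
    m: int
    k: int
    universe_n: int
    p_value: float

    def __post_init__(self) -> None:
        if not (0 <= self.q <= min(self.m, self.k)):
            raise ValueError(f"q={self.q} outside [0, min(m={self.m}, k={self.k})]")
        if max(self.m, self.k) > self.universe_n:
            raise ValueError("set sizes exceed the universe")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")

    def as_dict(self) -> dict:
        return {
            "q": self.q,
            "m": self.m,
            "k": self.k,
            "universe_n": self.universe_n,
            "p_value": self.p_value,
        }


@dataclass(frozen=True)
class EnrichmentReport:
    """Overlap test for the shared set plus one test per direction category."""

    overlap_test: EnrichmentTest
    category_tests: Mapping[str, EnrichmentTest]

    def as_dict(self) -> dict:
        return {
            "overlap": self.overlap_test.as_dict(),
            "categories": {k: v.as_dict() for k, v in self.category_tests.items()},
        }


def filter_degs(table: DEGTable, config: FilterConfig | None = None) -> SignedGeneSets:
    """Apply the posterior-probability and fold-change cuts to one contrast.

    A gene is upregulated iff ``pp >= min_pp`` and ``log2fc >= log2(min_abs_fc)``,
    downregulated iff ``pp >= min_pp`` and ``log2fc <= -log2(min_abs_fc)``;
    all other genes are excluded.
    """
    config = config or FilterConfig()
    lo = config.min_abs_log2fc
    df = table.data
    passed = df["pp"].to_numpy(float) >= config.min_pp
    fc = df["log2fc"].to_numpy(float)
    up = df.loc[passed & (fc >= lo), "gene_id"]
    down = df.loc[passed & (fc <= -lo), "gene_id"]
    return SignedGeneSets(up=frozenset(up), down=frozenset(down))


def classify_rescue(mut: SignedGeneSets, treat: SignedGeneSets) -> RescueClassification:
    """Intersect two signed DEG sets and split by direction concordance."""
    return RescueClassification(
        rescued_up=mut.up & treat.down,
        rescued_down=mut.down & treat.up,
        further_up=mut.up & treat.up,
        further_down=mut.down & treat.down,
    )


def hypergeom_upper_tail(q: int, m: int, universe_n: int, k: int) -> float:
    """P(X >= q) for X ~ Hypergeometric(universe_n, m, k).

    The inclusive upper tail: the probability that two fixed-size sets of
    ``m`` and ``k`` genes drawn independently from a universe of
    ``universe_n`` share at least ``q`` members. Evaluated as the survival
    function above ``q - 1``, i.e. R's ``phyper(q - 1, m, universe_n - m, k,
    lower.tail = FALSE)``.
    """
    if not (0 <= q <= min(m, k)):
        raise ValueError(f"q={q} outside [0, min(m={m}, k={k})]")
    if m < 0 or k < 0 or max(m, k) > universe_n:
        raise ValueError(f"invalid sizes m={m}, k={k} for universe {universe_n}")
    return float(hypergeom.sf(q - 1, universe_n, m, k))


def enrichment_report(
    cls: RescueClassification,
    mut: SignedGeneSets,
    treat: SignedGeneSets,
    universe_n: int,
) -> EnrichmentReport:
    """Hypergeometric tests for the shared set and each direction category.

    The overlap test draws the treatment DEG list (set 1, size m) and the
    mutant DEG list (set 2, size k) from the common universe; each category
    test draws the two directional subsets it intersects.
    """
    if len(mut.all_degs | treat.all_degs) > universe_n:
        raise ValueError("gene sets exceed the stated universe")

    def test(q: int, m: int, k: int) -> EnrichmentTest:
        return EnrichmentTest(
            q=q, m=m, k=k, universe_n=universe_n,
            p_value=hypergeom_upper_tail(q, m, universe_n, k),
        )

    overlap = test(cls.shared_total, treat.total, mut.total)
    categories = {
        "rescued_up": test(len(cls.rescued_up), len(mut.up), len(treat.down)),
        "rescued_down": test(len(cls.rescued_down), len(mut.down), len(treat.up)),
        "further_up": test(len(cls.further_up), len(mut.up), len(treat.up)),
        "further_down": test(len(cls.further_down), len(mut.down), len(treat.down)),
    }
    return EnrichmentReport(overlap_test=overlap, category_tests=categories)


def _pct(part: int, whole: int) -> float:
    return round(100.0 * part / whole, 1) if whole else 0.0


def summarize_counts(
    mut: SignedGeneSets, treat: SignedGeneSets, cls: RescueClassification
) -> pd.DataFrame:
    """Headline counts with up/down percentages (one decimal place)."""
    rows = [
        ("mutant_degs", mut.total, len(mut.up), len(mut.down),
         _pct(len(mut.up), mut.total), _pct(len(mut.down), mut.total)),
        ("treatment_degs", treat.total, len(treat.up), len(treat.down),
         _pct(len(treat.up), treat.total), _pct(len(treat.down), treat.total)),
        ("shared", cls.shared_total, None, None, None, None),
        ("rescued", cls.rescued_total, len(cls.rescued_up), len(cls.rescued_down),
         _pct(len(cls.rescued_up), cls.rescued_total),
         _pct(len(cls.rescued_down), cls.rescued_total)),
        ("further_dysregulated", cls.further_total, len(cls.further_up),
         len(cls.further_down), _pct(len(cls.further_up), cls.further_total),
         _pct(len(cls.further_down), cls.further_total)),
    ]
    return pd.DataFrame(
        rows, columns=["set", "total", "n_up", "n_down", "pct_up", "pct_down"]
    )


class RescueModel:
    """Rescued-gene analysis of a mutant contrast and a treatment contrast.

    Parameters
    ----------
    mut, treat
        :class:`DEGTable` for mutant-vs-WT and treated-vs-untreated.
    config
        :class:`FilterConfig` thresholds (default |FC| >= 1.2, PP >= 0.95).
    universe_n
        Common tested-gene universe for the enrichment tests. Defaults to the
        larger of the two tables' ``universe_size``.

    Examples
    --------
    >>> model = RescueModel(mut_table, treat_table, universe_n=14488)
    >>> res = model.fit()
    >>> res.enrichment.overlap_test.p_value  # doctest: +SKIP
    """

    def __init__(
        self,
        mut: DEGTable,
        treat: DEGTable,
        config: FilterConfig | None = None,
        universe_n: int | None = None,
    ) -> None:
        self.mut = mut
        self.treat = treat
        self.config = config or FilterConfig()
        if universe_n is None:
            universe_n = max(mut.universe_size, treat.universe_size)
        self.universe_n = int(universe_n)

    @classmethod
    def from_dataframes(
        cls,
        mut: pd.DataFrame,
        treat: pd.DataFrame,
        config: FilterConfig | None = None,
        universe_n: int | None = None,
    ) -> "RescueModel":
        return cls(
            DEGTable("mut", mut), DEGTable("treat", treat),
            config=config, universe_n=universe_n,
        )

    def fit(self) -> "RescueResults":
        mut_sets = filter_degs(self.mut, self.config)
        treat_sets = filter_degs(self.treat, self.config)
        classification = classify_rescue(mut_sets, treat_sets)
        report = enrichment_report(classification, mut_sets, treat_sets, self.universe_n)
        return RescueResults(self, mut_sets, treat_sets, classification, report)


@dataclass
class RescueResults:
    """Fitted rescue analysis: signed sets, classification, enrichment."""

    model: RescueModel
    mut_sets: SignedGeneSets
    treat_sets: SignedGeneSets
    classification: RescueClassification
    enrichment: EnrichmentReport

    def summary(self) -> pd.DataFrame:
        """Count summary table plus enrichment p-values (two significant
        figures is the conventional display; full precision is kept)."""
        tab = summarize_counts(self.mut_sets, self.treat_sets, self.classification)
        pvals = {
            "shared": self.enrichment.overlap_test.p_value,
            "rescued": None,
            "further_dysregulated": None,
        }
        tab["p_value"] = tab["set"].map(pvals)
        return tab

    def gene_categories(self) -> pd.DataFrame:
        """Long table (gene_id, category) over the shared genes."""
        mapping = self.classification.category_of()
        return (
            pd.DataFrame(
                {"gene_id": list(mapping), "category": list(mapping.values())}
            )
            .sort_values(["category", "gene_id"])
            .reset_index(drop=True)
        )

    def as_dict(self) -> dict:
        return {
            "universe_n": self.model.universe_n,
            "thresholds": {
                "min_abs_fc": self.model.config.min_abs_fc,
                "min_pp": self.model.config.min_pp,
            },
            "counts": {
                "mut_up": len(self.mut_sets.up),
                "mut_down": len(self.mut_sets.down),
                "treat_up": len(self.treat_sets.up),
                "treat_down": len(self.treat_sets.down),
                "shared": self.classification.shared_total,
                "rescued": self.classification.rescued_total,
                "further_dysregulated": self.classification.further_total,
            },
            "enrichment": self.enrichment.as_dict(),
        }
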