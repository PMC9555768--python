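"""Grid-based quantification of labeled-cell patterns in serial sections.

Cells detected in serial sections of a region of interest (here the 1st
pharyngeal arch, anterior/posterior segments) are binned on a rectangular
grid (5 rows x 4 columns = 20 bins by default, anchored at the lateral-distal
corner). Per-bin densities are reported as cells per 100 um^2. Genotypes are
compared with the study's statistical stack:

* chi-square homogeneity test on pooled bin-count compositions,
* per-bin unpaired one-tailed t-tests on per-embryo densities with
  Benjamini-Hochberg correction across the 20 bins,
* Kruskal-Wallis across genotypes on per-embryo cell totals (numerosity),
  followed by one-tailed Mann-Whitney tests against the reference genotype
  (exact for small samples).

:class:`SpatialDensityModel` orchestrates the pipeline; each step is also a
standalone function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GENOTYPES",
    "GridSpec",
    "SectionPattern",
    "BinCounts",
    "DensityMatrix",
    "BinTestResult",
    "NumerosityResult",
    "assign_bins",
    "compute_density",
    "pool_segment",
    "chi2_distribution_test",
    "per_bin_tests",
    "numerosity_tests",
    "heatmap_matrix",
    "plot_heatmap",
    "SpatialDensityModel",
    "SpatialResults",
]

GENOTYPES = ("WT", "het", "null", "het_treated")
SEGMENTS = ("A", "P")


@dataclass(frozen=True)
class GridSpec:
    """Rectangular counting grid anchored at the lateral-distal corner.

    ``origin`` is the (x, y) of the anchor corner in um; ``width`` extends
    along columns (lateral -> medial), ``height`` along rows (distal ->
    proximal). Bins are numbered row-major starting at the anchor: bin 1 is
    the anchor bin, bins 1..n_cols form the first row. Bin areas are equal
    rectangles by default but can be overridden per bin (areas measured on
    the image rather than idealized).
    """

    n_rows: int = 5
    n_cols: int = 4
    origin: tuple = (0.0, 0.0)
    width: float = 200.0
    height: float = 160.0
    bin_areas: tuple | None = None

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("grid region must have positive width and height")
        if self.bin_areas is not None:
            areas = np.asarray(self.bin_areas, float)
            if areas.shape != (self.n_bins,):
                raise ValueError(f"bin_areas must have length {self.n_bins}")
            if (areas <= 0).any():
                raise ValueError("all bin_areas must be > 0")
            object.__setattr__(self, "bin_areas", tuple(areas))

    @property
    def n_bins(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def areas(self) -> np.ndarray:
        """Per-bin areas in um^2 (equal split of the region by default)."""
        if self.bin_areas is not None:
            return np.asarray(self.bin_areas, float)
        return np.full(self.n_bins, self.width * self.height / self.n_bins)


@dataclass
class SectionPattern:
    """Labeled-cell coordinates for one physical section.

    ``points`` is an (N, 2) array of x, y in um. ``segment`` labels the
    anterior (A) or posterior (P) portion of the region of interest along its
    axis; ``thickness`` is the section thickness in um.
    """

    points: np.ndarray
    section_index: int
    embryo_id: str
    genotype: str
    segment: str
    thickness: float = 10.0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, float).reshape(-1, 2)
        if not np.isfinite(pts).all():
            raise ValueError("all points must be finite")
        self.points = pts
        if self.thickness <= 0:
            raise ValueError("thickness must be > 0")
        if self.segment not in SEGMENTS:
            raise ValueError(f"segment must be one of {SEGMENTS}, got {self.segment!r}")
        if self.genotype not in GENOTYPES:
            raise ValueError(
                f"unknown genotype {self.genotype!r}; expected one of {GENOTYPES}"
            )

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class BinCounts:
    """Cell counts per grid bin plus a tally of points outside the region."""

    counts: tuple
    overflow: int = 0

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.counts)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.overflow < 0:
            raise ValueError("overflow must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return sum(self.counts)

    def __add__(self, other: "BinCounts") -> "BinCounts":
        if len(self.counts) != len(other.counts):
            raise ValueError("cannot add BinCounts on different grids")
        return BinCounts(
            counts=tuple(a + b for a, b in zip(self.counts, other.counts)),
            overflow=self.overflow + other.overflow,
        )


@dataclass(frozen=True)
class DensityMatrix:
    """Per-bin cell densities in cells per 100 um^2."""

    densities: tuple

    def __post_init__(self) -> None:
        dens = tuple(float(d) for d in self.densities)
        if any(d < 0 for d in dens):
            raise ValueError("densities must be non-negative")
        object.__setattr__(self, "densities", dens)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.densities, float)


@dataclass(frozen=True)
class BinTestResult:
    """One per-bin comparison: t statistic, raw and BH-adjusted p."""

    bin_index: int  # 1-based, row-major from the anchor corner
    t_statistic: float
    p_raw: float
    p_bh: float


@dataclass(frozen=True)
class NumerosityResult:
    """Kruskal-Wallis across genotypes plus pairwise Mann-Whitney tests."""

    kw_statistic: float
    kw_p: float
    pairwise: tuple  # of (pair label, U statistic, one-tailed p)


def assign_bins(pattern: SectionPattern, grid: GridSpec) -> BinCounts:
    """Count the section's points per grid bin (half-open bin intervals).

    A point on an interior bin boundary belongs to the higher-index bin; a
    point exactly on the far outer edge belongs to the last bin of its
    row/column (so the closed region is fully covered and no point is ever
    double-counted). Points outside the region go to the overflow tally.
    """
    pts = pattern.points
    ox, oy = grid.origin
    if len(pts) == 0:
        return BinCounts(counts=(0,) * grid.n_bins)
    x = pts[:, 0] - ox
    y = pts[:, 1] - oy
    inside = (x >= 0) & (x <= grid.width) & (y >= 0) & (y <= grid.height)
    col_w = grid.width / grid.n_cols
    row_h = grid.height / grid.n_rows
    col = np.minimum(np.floor(x / col_w).astype(int), grid.n_cols - 1)
    row = np.minimum(np.floor(y / row_h).astype(int), grid.n_rows - 1)
    idx = (row * grid.n_cols + col)[inside]
    counts = np.bincount(idx, minlength=grid.n_bins)
    return BinCounts(counts=tuple(counts), overflow=int((~inside).sum()))


def compute_density(counts: BinCounts, grid: GridSpec, n_sections: int = 1) -> DensityMatrix:
    """Densities in cells per 100 um^2: ``100 * counts_i / area_i``.

    For counts pooled over ``n_sections`` sections, each bin's effective area
    is ``area_i * n_sections``, yielding the mean per-section density.
    """
    areas = grid.areas * n_sections
    if (areas <= 0).any():
        raise ValueError("bin areas must be positive")
    if len(counts.counts) != grid.n_bins:
        raise ValueError("counts do not match grid size")
    dens = 100.0 * np.asarray(counts.counts, float) / areas
    return DensityMatrix(densities=tuple(dens))


def pool_segment(
    patterns: Sequence[SectionPattern],
    segment: str,
    grid: GridSpec,
    by: str = "embryo",
) -> tuple:
    """Pool section counts within embryos (or a whole genotype) for a segment.

    Returns ``(pooled, per_unit_counts, per_unit_density)`` where ``pooled``
    is the grand-total :class:`BinCounts` over all matching sections and the
    two dicts are keyed by embryo id (``by="embryo"``) or genotype
    (``by="genotype"``). Per-unit densities are mean per-section densities
    (counts divided by bin area times section count).
    """
    if by not in ("embryo", "genotype"):
        raise ValueError("by must be 'embryo' or 'genotype'")
    selected = [p for p in patterns if p.segment == segment]
    if not selected:
        raise ValueError(f"no sections with segment {segment!r}")
    if by == "embryo":
        genos: dict = {}
        for p in selected:
            genos.setdefault(p.embryo_id, set()).add(p.genotype)
        mixed = {e: g for e, g in genos.items() if len(g) > 1}
        if mixed:
            raise ValueError(f"embryo(s) with mixed genotypes: {sorted(mixed)}")
    key = (lambda p: p.embryo_id) if by == "embryo" else (lambda p: p.genotype)
    unit_counts: dict = {}
    unit_sections: dict = {}
    for p in selected:
        c = assign_bins(p, grid)
        k = key(p)
        unit_counts[k] = unit_counts[k] + c if k in unit_counts else c
        unit_sections[k] = unit_sections.get(k, 0) + 1
    unit_density = {
        k: compute_density(c, grid, n_sections=unit_sections[k])
        for k, c in unit_counts.items()
    }
    pooled = BinCounts(counts=(0,) * grid.n_bins)
    for c in unit_counts.values():
        pooled = pooled + c
    return pooled, unit_counts, unit_density


def chi2_distribution_test(a: BinCounts, b: BinCounts) -> tuple:
    """Chi-square homogeneity test of two bin-count compositions.

    Builds the 2 x n_bins contingency table of pooled counts, drops bins
    empty in both groups (degenerate columns carry no information), and
    tests whether the two groups share one bin-composition. Degrees of
    freedom = number of non-degenerate bins - 1. Warns when any expected
    count falls below 1 (the asymptotic p is then unreliable).
    """
    av = np.asarray(a.counts, float)
    bv = np.asarray(b.counts, float)
    if av.sum() == 0 or bv.sum() == 0:
        raise ValueError("both groups must contain at least one cell")
    keep = (av + bv) > 0
    table = np.vstack([av[keep], bv[keep]])
    if table.shape[1] < 2:
        return 0.0, 1.0
    expected = stats.contingency.expected_freq(table)
    if (expected < 1).any():
        warnings.warn(
            "expected count < 1 in chi-square table; asymptotic p unreliable",
            UserWarning, stacklevel=2,
        )
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def _one_sided_t(b_vals: np.ndarray, a_vals: np.ndarray, alternative: str) -> tuple:
    """Unpaired Student's t of B vs A, degenerate-variance safe."""
    if np.ptp(a_vals) == 0 and np.ptp(b_vals) == 0:
        diff = float(b_vals.mean() - a_vals.mean())
        if diff == 0:
            return 0.0, 0.5 if alternative != "two-sided" else 1.0
        t = np.inf if diff > 0 else -np.inf
        if alternative == "greater":
            return t, 0.0 if diff > 0 else 1.0
        if alternative == "less":
            return t, 0.0 if diff < 0 else 1.0
        return t, 0.0
    res = stats.ttest_ind(b_vals, a_vals, equal_var=True, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def per_bin_tests(
    groupA: Sequence[DensityMatrix],
    groupB: Sequence[DensityMatrix],
    alternative: str = "greater",
) -> list:
    """Per-bin one-tailed t-tests of group B vs group A with BH correction.

    ``alternative="greater"`` tests whether group B (e.g. the mutant) is
    denser than group A (the reference) in each bin; the 20 bins of one
    comparison form one Benjamini-Hochberg family. Units are independent
    replicates (embryos), at least two per group.
    """
    if len(groupA) < 2:
        raise ValueError("group A needs at least 2 units")
    if len(groupB) < 2:
        raise ValueError("group B needs at least 2 units")
    A = np.vstack([d.as_array() for d in groupA])
    B = np.vstack([d.as_array() for d in groupB])
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups use different grids")
    stats_p = [_one_sided_t(B[:, j], A[:, j], alternative) for j in range(A.shape[1])]
    p_raw = np.array([p for _, p in stats_p])
    p_bh = multipletests(p_raw, method="fdr_bh")[1]
    return [
        BinTestResult(bin_index=j + 1, t_statistic=stats_p[j][0],
                      p_raw=float(p_raw[j]), p_bh=float(p_bh[j]))
        for j in range(A.shape[1])
    ]


def numerosity_tests(
    totals: Mapping[str, Sequence[float]],
    reference: str = "WT",
    alternative: str = "greater",
) -> NumerosityResult:
    """Kruskal-Wallis across genotypes, then pairwise one-tailed Mann-Whitney.

    ``totals`` maps genotype -> per-embryo cell totals. Each non-reference
    genotype is tested against the reference with the one-tailed alternative
    (default: genotype > reference). The Mann-Whitney p is exact when both
    group sizes are <= 8 and there are no ties, asymptotic (mid-rank,
    tie-corrected) otherwise.
    """
    if len(totals) < 2:
        raise ValueError("need at least 2 genotypes")
    if reference not in totals:
        raise ValueError(f"reference genotype {reference!r} not in totals")
    for g, vals in totals.items():
        if len(vals) < 2:
            raise ValueError(f"genotype {g!r} has fewer than 2 embryos")
        if len(vals) < 3:
            warnings.warn(
                f"genotype {g!r} has fewer than 3 embryos; tests are weak",
                UserWarning, stacklevel=2,
            )
    groups = [np.asarray(v, float) for v in totals.values()]
    flat = np.concatenate(groups)
    if np.ptp(flat) == 0:
        warnings.warn("all totals identical; Kruskal-Wallis p reported as 1",
                      UserWarning, stacklevel=2)
        kw_stat, kw_p = 0.0, 1.0
    else:
        kw = stats.kruskal(*groups)
        kw_stat, kw_p = float(kw.statistic), float(kw.pvalue)
    ref_vals = np.asarray(totals[reference], float)
    pairwise = []
    for g, vals in totals.items():
        if g == reference:
            continue
        vals = np.asarray(vals, float)
        has_ties = len(np.unique(np.concatenate([vals, ref_vals]))) < len(vals) + len(ref_vals)
        method = "exact" if (len(vals) <= 8 and len(ref_vals) <= 8 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(vals, ref_vals, alternative=alternative, method=method)
        pairwise.append((f"{g}_vs_{reference}", float(res.statistic), float(res.pvalue)))
    return NumerosityResult(kw_statistic=kw_stat, kw_p=kw_p, pairwise=tuple(pairwise))


def heatmap_matrix(
    densities: Sequence[DensityMatrix],
    breaks: Sequence[float] | None = None,
    grid: GridSpec | None = None,
) -> tuple:
    """Mean density per bin across units, and its color-class index matrix.

    ``breaks`` are strictly increasing class boundaries; the class index of
    a bin is the number of breaks strictly below its mean density (so class
    0 is the lightest). Default breaks are the quartiles of the pooled bin
    means, giving four balanced classes. Returns ``(means, classes)`` shaped
    (n_rows, n_cols) when a grid is given, else flat.
    """
    if not densities:
        raise ValueError("need at least one density matrix")
    M = np.vstack([d.as_array() for d in densities])
    means = M.mean(axis=0)
    if breaks is None:
        breaks = np.percentile(means, [25, 50, 75])
    breaks = np.asarray(breaks, float)
    if len(breaks) and (np.diff(breaks) <= 0).any():
        raise ValueError("breaks must be strictly increasing")
    classes = np.searchsorted(breaks, means, side="left")
    if grid is not None:
        means = means.reshape(grid.n_rows, grid.n_cols)
        classes = classes.reshape(grid.n_rows, grid.n_cols)
    return means, classes


def plot_heatmap(
    means: np.ndarray,
    path: str,
    title: str = "",
    vmax: float | None = None,
) -> None:
    """Write a color-coded density heat map (darker = denser) to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3.2, 3.6))
    im = ax.imshow(np.asarray(means, float), cmap="Reds", vmin=0.0, vmax=vmax,
                   origin="upper", aspect="auto")
    ax.set_xlabel("lateral → medial")
    ax.set_ylabel("distal → proximal")
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, label="cells / 100 µm²")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


class SpatialDensityModel:
    """Genotype comparison of labeled-cell density on the counting grid.

    Parameters
    ----------
    patterns
        Section patterns for all embryos and genotypes (both segments).
    grid
        The counting :class:`GridSpec`.
    reference
        Reference genotype for all comparisons (default ``"WT"``).
    alternative
        Direction of the per-bin and numerosity one-tailed tests; the
        default ``"greater"`` tests whether non-reference genotypes are
        denser/more numerous than the reference.
    """

    def __init__(
        self,
        patterns: Sequence[SectionPattern],
        grid: GridSpec | None = None,
        reference: str = "WT",
        alternative: str = "greater",
    ) -> None:
        if not patterns:
            raise ValueError("need at least one section pattern")
        self.patterns = list(patterns)
        self.grid = grid or GridSpec()
        self.reference = reference
        self.alternative = alternative
        self.genotypes = sorted({p.genotype for p in self.patterns})
        if reference not in self.genotypes:
            raise ValueError(
                f"reference genotype {reference!r} not present; found {self.genotypes}"
            )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        grid: GridSpec | None = None,
        **kwargs,
    ) -> "SpatialDensityModel":
        """Build from a long table with columns x_um, y_um, section, embryo,
        genotype, segment (one row per cell)."""
        required = {"x_um", "y_um", "section", "embryo", "genotype", "segment"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"point table missing columns: {sorted(missing)}")
        bad = set(df["genotype"].unique()) - set(GENOTYPES)
        if bad:
            raise ValueError(
                f"unknown genotype label(s) {sorted(bad)}; "
                f"labels found: {sorted(df['genotype'].unique())}"
            )
        patterns = []
        for (emb, geno, seg, sec), sub in df.groupby(
            ["embryo", "genotype", "segment", "section"], sort=True
        ):
            patterns.append(
                SectionPattern(
                    points=sub[["x_um", "y_um"]].to_numpy(float),
                    section_index=int(sec),
                    embryo_id=str(emb),
                    genotype=str(geno),
                    segment=str(seg),
                )
            )
        return cls(patterns, grid=grid, **kwargs)

    def fit(self, breaks: Sequence[float] | None = None) -> "SpatialResults":
        segments = sorted({p.segment for p in self.patterns})
        pooled: dict = {}
        embryo_density: dict = {}
        embryo_totals: dict = {}
        for seg in segments:
            for geno in self.genotypes:
                pats = [p for p in self.patterns
                        if p.segment == seg and p.genotype == geno]
                if not pats:
                    continue
                grand, counts, dens = pool_segment(pats, seg, self.grid, by="embryo")
                pooled[(geno, seg)] = grand
                embryo_density[(geno, seg)] = dens
                embryo_totals[(geno, seg)] = {e: c.total for e, c in counts.items()}

        chi2: dict = {}
        bins: dict = {}
        numerosity: dict = {}
        numerosity_errors: dict = {}
        heatmaps: dict = {}
        for seg in segments:
            ref_key = (self.reference, seg)
            if ref_key not in pooled:
                continue
            for geno in self.genotypes:
                key = (geno, seg)
                if key not in pooled or geno == self.reference:
                    continue
                chi2[key] = chi2_distribution_test(pooled[ref_key], pooled[key])
                ref_dens = list(embryo_density[ref_key].values())
                g_dens = list(embryo_density[key].values())
                if len(ref_dens) >= 2 and len(g_dens) >= 2:
                    bins[key] = per_bin_tests(ref_dens, g_dens, self.alternative)
            totals = {
                g: list(embryo_totals[(g, seg)].values())
                for g in self.genotypes if (g, seg) in embryo_totals
            }
            if len(totals) >= 2:
                # a failed numerosity stage (e.g. single-embryo genotype) is
                # recorded, not fatal: density reporting continues
                try:
                    numerosity[seg] = numerosity_tests(
                        totals, reference=self.reference, alternative=self.alternative
                    )
                except ValueError as exc:
                    numerosity_errors[seg] = str(exc)
            for geno in self.genotypes:
                key = (geno, seg)
                if key in embryo_density:
                    heatmaps[key] = heatmap_matrix(
                        list(embryo_density[key].values()), breaks=breaks, grid=self.grid
                    )
        return SpatialResults(
            model=self, pooled_counts=pooled, embryo_densities=embryo_density,
            embryo_totals=embryo_totals, chi2_tests=chi2, bin_tests=bins,
            numerosity=numerosity, numerosity_errors=numerosity_errors,
            heatmaps=heatmaps,
        )


@dataclass
class SpatialResults:
    """Fitted spatial comparison: pooled counts, densities and all tests.

    Keys of the per-genotype dicts are ``(genotype, segment)`` tuples.
    """

    model: SpatialDensityModel
    pooled_counts: dict
    embryo_densities: dict
    embryo_totals: dict
    chi2_tests: dict
    bin_tests: dict
    numerosity: dict
    numerosity_errors: dict
    heatmaps: dict

    def summary(self) -> pd.DataFrame:
        """One row per comparison: chi-square p, significant bins, numerosity p."""
        rows = []
        for (geno, seg), (stat, p) in sorted(self.chi2_tests.items()):
            n_sig = (
                sum(r.p_bh < 0.05 for r in self.bin_tests[(geno, seg)])
                if (geno, seg) in self.bin_tests else None
            )
            num = self.numerosity.get(seg)
            mw_p = None
            if num is not None:
                ref = self.model.reference
                for label, _, pv in num.pairwise:
                    if label == f"{geno}_vs_{ref}":
                        mw_p = pv
            rows.append((geno, seg, stat, p, n_sig, mw_p))
        return pd.DataFrame(
            rows,
            columns=["genotype", "segment", "chi2_statistic", "chi2_p",
                     "n_bins_bh_significant", "numerosity_mw_p"],
        )

    def plot_heatmaps(self, outdir: str, fmt: str = "png") -> list:
        """Write one heat map per genotype x segment; returns the paths."""
        import os

        vmax = max(
            float(np.max(means)) for means, _ in self.heatmaps.values()
        ) if self.heatmaps else None
        paths = []
        for (geno, seg), (means, _) in sorted(self.heatmaps.items()):
            path = os.path.join(outdir, f"density_{geno}_{seg}.{fmt}")
            plot_heatmap(means, path, title=f"{geno}, segment {seg}", vmax=vmax)
            paths.append(path)
        return paths

    def as_dict(self) -> dict:
        out: dict = {
            "reference": self.model.reference,
            "alternative": self.model.alternative,
            "grid": {
                "n_rows": self.model.grid.n_rows,
                "n_cols": self.model.grid.n_cols,
                "width": self.model.grid.width,
                "height": self.model.grid.height,
            },
            "chi2": {
                f"{g}|{s}": {"statistic": st, "p": p}
                for (g, s), (st, p) in sorted(self.chi2_tests.items())
            },
            "per_bin": {
                f"{g}|{s}": [
                    {"bin": r.bin_index, "t": r.t_statistic,
                     "p_raw": r.p_raw, "p_bh": r.p_bh}
                    for r in res
                ]
                for (g, s), res in sorted(self.bin_tests.items())
            },
            "numerosity": {
                s: {
                    "kw_statistic": n.kw_statistic,
                    "kw_p": n.kw_p,
                    "pairwise": [
                        {"pair": a, "U": u, "p": p} for a, u, p in n.pairwise
                    ],
                }
                for s, n in sorted(self.numerosity.items())
            },
            "numerosity_errors": dict(sorted(self.numerosity_errors.items())),
        }
        return out
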