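"""Digital gene expression from per-contig read counts.

Expression is compared between groups of libraries (or library x tag strata)
by read representation within contigs: counts are normalised to abundance per
10,000 reads of the group, fold change is the ratio of normalised abundances,
significance comes from a two-sided Fisher's exact test on the contig-versus-
rest 2x2 table, and a contig is flagged differential when p < alpha and the
normalised fold is at least `min_fold`. The R statistic of Stekel, Git &
Falciani (a multinomial log-likelihood-ratio heterogeneity measure) is
reported across the libraries of a comparison; for more than two libraries
its p-value uses a chi-square approximation on 2R.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .aio import GENOTYPES, LIBRARIES, STAGES

logger = logging.getLogger(__name__)

PER = 10_000  # abundance scale: reads per 10,000 reads of the group


def normalize(x: float, n_total: float, per: float = PER) -> float:
    """Abundance of a contig per `per` reads of its library or group."""
    if n_total <= 0:
        raise ValueError("library/group total must be positive")
    return per * x / n_total


def fold_change(x1: float, n1: float, x2: float, n2: float) -> float:
    """Normalised fold group1/group2; +inf for one-sided zeros, nan for 0/0."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group totals must be positive")
    if x1 == 0 and x2 == 0:
        return math.nan
    if x2 == 0:
        return math.inf
    return (x1 / n1) / (x2 / n2)


def stekel_r(x: Sequence[float], n: Sequence[float]) -> float:
    """R = sum_j x_j ln(x_j / (N_j f)) with f the pooled frequency.

    Zero-count libraries contribute nothing; an all-zero contig has no
    defined R and raises.
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    if x.shape != n.shape or x.size < 2:
        raise ValueError("need matching count and total vectors of length >= 2")
    if np.any(n <= 0):
        raise ValueError("library totals must be positive")
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("R undefined for an all-zero contig")
    f = total / n.sum()
    nz = x > 0
    return float(np.sum(x[nz] * np.log(x[nz] / (n[nz] * f))))


def stekel_p(x: Sequence[float], n: Sequence[float]) -> float:
    """Chi-square p-value of 2R on (number of libraries - 1) df."""
    r = stekel_r(x, n)
    return float(stats.chi2.sf(2.0 * r, df=len(list(x)) - 1))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p: sum of hypergeometric probabilities no
    larger than the observed table's, at fixed margins. All-zero table -> 1."""
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    if a + b + c + d == 0:
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


@dataclass(frozen=True)
class ComparisonSpec:
    """Two disjoint, non-empty groups of count-table columns."""

    name: str
    group1: tuple[str, ...]
    group2: tuple[str, ...]
    label1: str = "group1"
    label2: str = "group2"

    def __post_init__(self) -> None:
        if not self.group1 or not self.group2:
            raise ValueError(f"{self.name}: both groups must be non-empty")
        if set(self.group1) & set(self.group2):
            raise ValueError(f"{self.name}: groups must be disjoint")


def compare_groups(
    table: pd.DataFrame,
    spec: ComparisonSpec,
    totals: Mapping[str, int] | None = None,
    alpha: float = 0.05,
    min_fold: float = 2.0,
) -> pd.DataFrame:
    """Per-contig differential call for one pairwise comparison.

    `totals` defaults to the table's column sums (reads assembled per
    library); pass raw library totals to normalise against all trimmed reads
    instead. The flag is `group1`/`group2`/`none`: significant (Fisher
    p < alpha) and at least `min_fold` on the normalised scale, with infinite
    fold (one-sided zeros) passing the fold criterion and all-zero contigs
    never flagged.
    """
    missing = [c for c in (*spec.group1, *spec.group2) if c not in table.columns]
    if missing:
        raise ValueError(f"{spec.name}: columns not in table: {missing}")
    cols = list(spec.group1) + list(spec.group2)
    if totals is None:
        tot = table[cols].sum()
    else:
        tot = pd.Series({c: totals[c] for c in cols})
    n1 = int(tot[list(spec.group1)].sum())
    n2 = int(tot[list(spec.group2)].sum())
    if n1 == 0 or n2 == 0:
        raise ValueError(f"{spec.name}: a group has zero total reads")
    x1 = table[list(spec.group1)].sum(axis=1).to_numpy()
    x2 = table[list(spec.group2)].sum(axis=1).to_numpy()

    norm1 = PER * x1 / n1
    norm2 = PER * x2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = norm1 / norm2
    fold[(x1 == 0) & (x2 == 0)] = np.nan
    fold[(x2 == 0) & (x1 > 0)] = np.inf

    pvals = np.ones(len(table))
    for i, (a, c) in enumerate(zip(x1, x2)):
        if a == 0 and c == 0:
            continue
        pvals[i] = fisher_exact_2x2(int(a), n1 - int(a), int(c), n2 - int(c))

    lib_counts = table[cols].to_numpy(dtype=float)
    lib_totals = tot[cols].to_numpy(dtype=float)
    r_stat = np.full(len(table), np.nan)
    nonzero = lib_counts.sum(axis=1) > 0
    f = lib_counts.sum(axis=1, keepdims=True) / lib_totals.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = lib_counts * np.log(lib_counts / (lib_totals[None, :] * f))
    r_stat[nonzero] = np.nansum(np.where(lib_counts > 0, terms, 0.0), axis=1)[nonzero]

    flag = np.full(len(table), "none", dtype=object)
    sig = pvals < alpha
    flag[sig & (fold >= min_fold)] = "group1"
    flag[sig & (fold <= 1.0 / min_fold)] = "group2"

    return pd.DataFrame(
        {
            "contig": table.index,
            "x1": x1,
            "x2": x2,
            "n1": n1,
            "n2": n2,
            "norm1": norm1,
            "norm2": norm2,
            "fold": fold,
            "r_stat": r_stat,
            "p": pvals,
            "flag": flag,
        }
    ).set_index("contig")


def _columns_for(
    table_cols: Sequence[str],
    stage: str | None,
    genotype: str | None,
    tag: str | None,
) -> list[str]:
    """Select library (or library_tag) columns matching the given levels."""
    out = []
    for lib in LIBRARIES:
        if stage is not None and not lib.endswith(stage):
            continue
        if genotype is not None and not lib.startswith(genotype):
            continue
        col = f"{lib}_{tag}" if tag is not None else lib
        if col in table_cols:
            out.append(col)
    return out


def enumerate_comparisons(tagged: bool) -> list[ComparisonSpec]:
    """All pairwise factorial comparisons over stage, genotype and sub-genome
    tag: each factor contrasted overall and nested within every combination of
    levels of the other factors. Tag-involving comparisons need tag-stratified
    columns and are produced only when `tagged`."""
    factors = {"stage": STAGES, "genotype": GENOTYPES, "tag": ("A", "D")}
    specs: list[ComparisonSpec] = []
    for factor, levels in factors.items():
        others = [f for f in factors if f != factor]
        choices = [list(factors[f]) + [None] for f in others]
        for fixed in product(*choices):
            ctx = dict(zip(others, fixed))
            if factor == "tag" or ctx.get("tag") is not None:
                if not tagged:
                    continue
            names = []
            groups = []
            for lvl in levels:
                sel = {"stage": None, "genotype": None, "tag": None, **ctx, factor: lvl}
                part = "".join(
                    str(sel[f]) for f in ("genotype", "stage") if sel[f] is not None
                )
                label = (part or "all") + (f"_{sel['tag']}" if sel["tag"] is not None else "")
                if factor == "tag" and not part:
                    label = lvl
                elif factor == "tag":
                    label = f"{part}_{lvl}"
                names.append(label)
                groups.append(tuple(_columns_for(
                    [f"{l}_{t}" for l in LIBRARIES for t in ("A", "D")] + list(LIBRARIES),
                    sel["stage"], sel["genotype"], sel["tag"],
                )))
            specs.append(
                ComparisonSpec(
                    name=f"{names[0]}_vs_{names[1]}",
                    group1=groups[0],
                    group2=groups[1],
                    label1=names[0],
                    label2=names[1],
                )
            )
    return specs


def comparison_matrix(
    table: pd.DataFrame,
    tag_table: pd.DataFrame | None = None,
    alpha: float = 0.05,
    min_fold: float = 2.0,
    totals: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Differential-contig counts for every pairwise factorial comparison.

    Returns one row per comparison with the number of contigs over-expressed
    on each side and a Fisher test on that pair of counts (against the
    remaining tested contigs). Comparisons whose strata carry no reads are
    skipped with a warning.
    """
    rows = []
    for spec in enumerate_comparisons(tagged=tag_table is not None):
        uses_tags = any("_" in c for c in spec.group1)
        tbl = tag_table if uses_tags else table
        cols = list(spec.group1) + list(spec.group2)
        if any(c not in tbl.columns for c in cols) or tbl[cols].to_numpy().sum() == 0:
            logger.warning("comparison %s skipped: no reads in its strata", spec.name)
            continue
        try:
            res = compare_groups(tbl, spec, totals=totals, alpha=alpha, min_fold=min_fold)
        except ValueError:
            logger.warning("comparison %s skipped: empty group total", spec.name)
            continue
        up1 = int((res["flag"] == "group1").sum())
        up2 = int((res["flag"] == "group2").sum())
        n_tested = int((res[["x1", "x2"]].sum(axis=1) > 0).sum())
        p_pair = fisher_exact_2x2(up1, up2, n_tested - up1, n_tested - up2)
        rows.append(
            {
                "comparison": spec.name,
                "side1": spec.label1,
                "side2": spec.label2,
                "n_up1": up1,
                "n_up2": up2,
                "n_tested": n_tested,
                "p_pair": p_pair,
            }
        )
    return pd.DataFrame(rows)


def platform_concordance(
    pairs: Sequence[tuple[str, str]]
) -> dict[str, float]:
    """Direction concordance between two expression platforms.

    `pairs` holds, per gene measured on both platforms, the differential
    direction on each platform (values ``g1``/``g2``). Returns the common
    count, per-direction concordant counts, discordant count and the rounded
    concordance percentage.
    """
    n = len(pairs)
    same_g1 = sum(1 for a, b in pairs if a == b == "g1")
    same_g2 = sum(1 for a, b in pairs if a == b == "g2")
    discord = n - same_g1 - same_g2
    pct = round(100.0 * (same_g1 + same_g2) / n) if n else 0
    return {
        "n_common": n,
        "n_same_dir_g1": same_g1,
        "n_same_dir_g2": same_g2,
        "n_discordant": discord,
        "n_concordant": same_g1 + same_g2,
        "pct_concordant": pct,
    }
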