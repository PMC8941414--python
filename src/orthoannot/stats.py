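"""Conservation statistics: aligned and common-annotation fractions.

For each annotation category the pipeline reports, over its human bases
(or variant sites):

* *fraction aligned* — the share with an orthologous base in the mouse
  genome under the pairwise alignment;
* *fraction common* — the share whose mouse image carries the same
  annotation category in the mouse map (set membership: the mouse base may
  carry additional categories).

Genome-wide and "non-coding" aggregates are included; non-coding means
every base or site not classified as ExonCDS.  Differences between
proportions are tested with pooled two-proportion z-tests, with extreme
p-values floored at 1e-300 and reported as an inequality.

All base-level counting is interval arithmetic (lengths of intersections
of projected segments); no per-base loops.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .alignment import UNALIGNED, AlignmentIndex
from .annotation import CATEGORIES, CategoryMap
from .intervals import IntervalSet
from .variants import DEFAULT_PRECEDENCE, VariantSite, assign_categories

__all__ = [
    "P_FLOOR",
    "NONCODING_LABEL",
    "GENOME_LABEL",
    "ZTestResult",
    "annotation_conservation",
    "variant_conservation",
    "two_proportion_z",
    "background_comparisons",
    "DEFAULT_COMPARISONS",
]

#: Reported p-values below this are printed as an inequality.
P_FLOOR = 1e-300

GENOME_LABEL = "Genome"
NONCODING_LABEL = "NonCoding"
ALL_LABEL = "All"


# ----------------------------------------------------------------- z-test
@dataclass(frozen=True)
class ZTestResult:
    """Pooled two-proportion z-test between counts x1/n1 and x2/n2."""

    x1: int
    n1: int
    x2: int
    n2: int
    p1: float
    p2: float
    z: Optional[float]
    p: Optional[float]
    p_label: str
    degenerate: bool = False


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> ZTestResult:
    """Test H0: the two binomial proportions are equal.

    Uses the pooled estimate p = (x1+x2)/(n1+n2) and the statistic
    z = (x1/n1 - x2/n2) / sqrt(p(1-p)(1/n1 + 1/n2)), with a two-sided
    p-value from the standard normal.  When the pooled proportion is 0 or 1
    there is no variation under H0 and the statistic is undefined; an
    explicit degenerate result is returned rather than NaN.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("sample sizes must be positive")
        if not 0 <= x <= n:
            raise ValueError(f"count {x} outside [0, {n}]")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return ZTestResult(
            x1, n1, x2, n2, p1, p2,
            z=None, p=None, p_label="undefined (no variation)", degenerate=True,
        )
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    p = 2.0 * float(sps.norm.sf(abs(z)))
    if p < P_FLOOR:
        return ZTestResult(x1, n1, x2, n2, p1, p2, z=z, p=P_FLOOR,
                           p_label=f"< {P_FLOOR:.1e}")
    return ZTestResult(x1, n1, x2, n2, p1, p2, z=z, p=p, p_label=f"{p:.3g}")


# ------------------------------------------------- base-level conservation
def _common_bp_for_category(
    human_set: IntervalSet,
    mouse_set: IntervalSet,
    index: AlignmentIndex,
) -> Tuple[int, int]:
    """(aligned bp, common bp) of a human category's bases.

    Aligned bases are intersected with the chain blocks; their mouse images
    are computed segment-wise and overlapped with the mouse category set.
    Segments are scored individually (not unioned), so reference bases that
    project onto the same mouse base each count once.
    """
    aligned = index.aligned_mask(human_set)
    n_aligned = aligned.total_length
    n_common = 0
    for chrom in aligned.chroms:
        arr = aligned.array(chrom)
        _, _, qc, qs, qe, _ = index.project(chrom, arr[:, 0], arr[:, 1])
        for idx in np.unique(qc):
            sel = qc == idx
            n_common += int(
                mouse_set.overlap_lengths(index.qry_chrom_name(int(idx)), qs[sel], qe[sel]).sum()
            )
    return n_aligned, n_common


def _atomize(cmap: CategoryMap) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Split each chromosome into atoms of constant category membership.

    Returns per chromosome (breakpoint boundaries, n_atoms x 12 bool
    membership matrix); the boundaries cover [0, chrom_length] so every
    base belongs to exactly one atom.
    """
    out = {}
    for chrom, length in cmap.chrom_lengths.items():
        cuts = {0, int(length)}
        for cat in CATEGORIES:
            arr = cmap[cat].array(chrom)
            cuts.update(arr[:, 0].tolist())
            cuts.update(arr[:, 1].tolist())
        bounds = np.array(sorted(c for c in cuts if 0 <= c <= length), dtype=np.int64)
        starts = bounds[:-1]
        member = np.zeros((len(starts), len(CATEGORIES)), dtype=bool)
        for j, cat in enumerate(CATEGORIES):
            member[:, j] = cmap[cat].contains_many(chrom, starts)
        out[chrom] = (bounds, member)
    return out


def _shared_annotation_counts(
    human_map: CategoryMap,
    mouse_map: CategoryMap,
    index: AlignmentIndex,
    exclude: frozenset = frozenset(),
) -> Tuple[int, int, int]:
    """(denominator, aligned, common) over bases outside ``exclude``.

    "Common" here means the mouse image carries at least one of the human
    base's categories.  Bases are grouped into atoms of identical category
    membership, and each group's images are overlapped with the union of
    the corresponding mouse category sets.
    """
    excl_idx = [CATEGORIES.index(c) for c in exclude]
    denominator = n_aligned = n_common = 0
    mouse_union_cache: Dict[Tuple[int, ...], IntervalSet] = {}
    for chrom, (bounds, member) in _atomize(human_map).items():
        starts, ends = bounds[:-1], bounds[1:]
        keep = (
            ~member[:, excl_idx].any(axis=1)
            if excl_idx
            else np.ones(len(starts), dtype=bool)
        )
        if not keep.any():
            continue
        starts, ends, member = starts[keep], ends[keep], member[keep]
        denominator += int((ends - starts).sum())
        keys = np.packbits(member, axis=1)
        key_view = [tuple(k) for k in keys]
        for key in set(key_view):
            sel = np.array([kv == key for kv in key_view])
            cats = [
                c for j, c in enumerate(CATEGORIES)
                if member[np.argmax(sel), j]
            ]
            if key not in mouse_union_cache:
                mouse_union_cache[key] = IntervalSet.union_all(
                    mouse_map[c] for c in cats
                ) if cats else IntervalSet.empty()
            union = mouse_union_cache[key]
            rs, re_, qc, qs, qe, _ = index.project(chrom, starts[sel], ends[sel])
            n_aligned += int((re_ - rs).sum())
            for idx in np.unique(qc):
                s2 = qc == idx
                n_common += int(
                    union.overlap_lengths(index.qry_chrom_name(int(idx)), qs[s2], qe[s2]).sum()
                )
    return denominator, n_aligned, n_common


def _noncoding_exclusion(noncoding_definition: str) -> frozenset:
    if noncoding_definition == "non-cds":
        return frozenset({"ExonCDS"})
    if noncoding_definition == "non-exonic":
        return frozenset({"ExonCDS", "ExonUTR", "ExonOther"})
    raise ValueError(
        f"noncoding_definition must be 'non-cds' or 'non-exonic', got {noncoding_definition!r}"
    )


def annotation_conservation(
    human_map: CategoryMap,
    mouse_map: CategoryMap,
    index: AlignmentIndex,
    include_aggregates: bool = True,
    noncoding_definition: str = "non-cds",
) -> pd.DataFrame:
    """The per-category conservation table over annotated bases.

    One row per category with the bp denominator, aligned and common
    counts, and the two fractions; plus a genome-wide row over all
    autosomal bases and a non-coding row (by default, bases not in
    ExonCDS), for which "common" means sharing at least one annotation
    category.
    """
    if set(index.ref_sizes) and set(human_map.chrom_lengths) - set(index.ref_sizes):
        missing = set(human_map.chrom_lengths) - set(index.ref_sizes)
        raise ValueError(
            f"assembly mismatch: chromosomes {sorted(missing)} absent from the alignment"
        )
    rows = []
    for cat in CATEGORIES:
        hset = human_map[cat]
        denom = hset.total_length
        n_aligned, n_common = _common_bp_for_category(hset, mouse_map[cat], index)
        rows.append(_row(cat, denom, n_aligned, n_common))
    if include_aggregates:
        d, a, c = _shared_annotation_counts(human_map, mouse_map, index)
        rows.append(_row(GENOME_LABEL, d, a, c))
        d, a, c = _shared_annotation_counts(
            human_map, mouse_map, index, _noncoding_exclusion(noncoding_definition)
        )
        rows.append(_row(NONCODING_LABEL, d, a, c))
    return pd.DataFrame(rows)


def _row(category: str, denom: int, n_aligned: int, n_common: int) -> dict:
    if not 0 <= n_common <= n_aligned <= max(denom, 0):
        raise AssertionError(
            f"{category}: invalid counts common={n_common} aligned={n_aligned} n={denom}"
        )
    return {
        "category": category,
        "denominator": denom,
        "n_aligned": n_aligned,
        "n_common": n_common,
        "fraction_aligned": n_aligned / denom if denom else float("nan"),
        "fraction_common": n_common / denom if denom else float("nan"),
    }


# -------------------------------------------------- site-level conservation
def variant_conservation(
    sites: Iterable[VariantSite],
    human_map: CategoryMap,
    mouse_map: CategoryMap,
    index: AlignmentIndex,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
    noncoding_definition: str = "non-cds",
) -> Tuple[pd.DataFrame, List[VariantSite]]:
    """Aligned/common fractions of variant sites, by source and category.

    Sites lacking a category are assigned one by precedence first.  Each
    site is aligned if its base has an orthologous mouse position, and
    common if that mouse position lies in the site's own category in the
    mouse map.  Per-source aggregate rows cover all sites and the
    non-coding subset (category != ExonCDS).  Returns the table and the
    sites annotated with their aligned/common flags.
    """
    sites = list(sites)
    if any(s.category is None for s in sites):
        sites = assign_categories(sites, human_map, precedence)
    flagged: List[VariantSite] = []
    for s in sites:
        image = index.map_position(s.chrom, s.pos)
        if image is UNALIGNED:
            flagged.append(replace(s, aligned=False, common=False))
        else:
            qc, qp = image
            flagged.append(
                replace(s, aligned=True, common=mouse_map[s.category].contains(qc, qp))
            )

    rows = []
    by_source: Dict[str, List[VariantSite]] = {}
    for s in flagged:
        by_source.setdefault(s.source, []).append(s)
    exclude = _noncoding_exclusion(noncoding_definition)
    for source in sorted(by_source):
        group = by_source[source]
        for cat in CATEGORIES:
            sub = [s for s in group if s.category == cat]
            rows.append(_site_row(source, cat, sub))
        rows.append(_site_row(source, ALL_LABEL, group))
        rows.append(
            _site_row(source, NONCODING_LABEL, [s for s in group if s.category not in exclude])
        )
    return pd.DataFrame(rows), flagged


def _site_row(source: str, category: str, sub: List[VariantSite]) -> dict:
    denom = len(sub)
    n_aligned = sum(1 for s in sub if s.aligned)
    n_common = sum(1 for s in sub if s.common)
    row = _row(category, denom, n_aligned, n_common)
    return {"source": source, **row}


# ------------------------------------------------------------- comparisons
#: Default background comparisons.  Each side names a table ('variant' or
#: 'annotation'), a source (variant side only) and a row label; counts are
#: the aligned numerator over the row's denominator.
DEFAULT_COMPARISONS: Tuple[dict, ...] = (
    {
        "name": "mendelian_noncoding_vs_complex_noncoding",
        "a": ("variant", "mendelian", NONCODING_LABEL),
        "b": ("variant", "complex", NONCODING_LABEL),
    },
    {
        "name": "mendelian_noncoding_vs_genome_noncoding",
        "a": ("variant", "mendelian", NONCODING_LABEL),
        "b": ("annotation", None, NONCODING_LABEL),
    },
    {
        "name": "complex_noncoding_vs_genome_noncoding",
        "a": ("variant", "complex", NONCODING_LABEL),
        "b": ("annotation", None, NONCODING_LABEL),
    },
    {
        "name": "complex_introndistal_vs_introndistal_bases",
        "a": ("variant", "complex", "IntronDistal"),
        "b": ("annotation", None, "IntronDistal"),
    },
    {
        "name": "complex_unannotated_vs_unannotated_bases",
        "a": ("variant", "complex", "Unannotated"),
        "b": ("annotation", None, "Unannotated"),
    },
)


def _lookup_counts(
    side: Tuple[str, Optional[str], str],
    variant_table: pd.DataFrame,
    annotation_table: pd.DataFrame,
    pair_name: str,
) -> Tuple[int, int]:
    table, source, label = side
    if table == "variant":
        sel = variant_table[
            (variant_table["source"] == source) & (variant_table["category"] == label)
        ]
    elif table == "annotation":
        sel = annotation_table[annotation_table["category"] == label]
    else:
        raise ValueError(f"comparison {pair_name!r}: unknown table {table!r}")
    if len(sel) != 1:
        raise KeyError(
            f"comparison {pair_name!r}: no unique row for {side!r} "
            f"({len(sel)} matches)"
        )
    row = sel.iloc[0]
    return int(row["n_aligned"]), int(row["denominator"])


def background_comparisons(
    variant_table: pd.DataFrame,
    annotation_table: pd.DataFrame,
    comparisons: Sequence[dict] = DEFAULT_COMPARISONS,
) -> pd.DataFrame:
    """Run the configured enrichment z-tests on aligned-count pairs.

    The Bonferroni column is supplementary output (the headline report is
    the raw z and p, matching how single comparisons are usually quoted).
    """
    rows = []
    for comp in comparisons:
        x1, n1 = _lookup_counts(comp["a"], variant_table, annotation_table, comp["name"])
        x2, n2 = _lookup_counts(comp["b"], variant_table, annotation_table, comp["name"])
        res = two_proportion_z(x1, n1, x2, n2)
        rows.append(
            {
                "comparison": comp["name"],
                "x1": res.x1, "n1": res.n1, "p1": res.p1,
                "x2": res.x2, "n2": res.n2, "p2": res.p2,
                "z": res.z,
                "p": res.p,
                "p_label": res.p_label,
                "p_bonferroni_supplementary": (
                    None if res.p is None else min(1.0, res.p * len(comparisons))
                ),
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ plotting
def plot_conservation(table: pd.DataFrame, path, title: str = "") -> None:
    """Horizontal bar chart: full bar = fraction aligned, filled = common."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table[table["category"].isin(CATEGORIES)].iloc[::-1]
    fig, ax = plt.subplots(figsize=(7, 5))
    y = np.arange(len(df))
    ax.barh(y, df["fraction_aligned"] * 100, color="black", label="aligned, different annotation")
    ax.barh(y, df["fraction_common"] * 100, color="tab:blue", label="aligned, common annotation")
    ax.set_yticks(y)
    ax.set_yticklabels(df["category"])
    ax.set_xlabel("% of human bases/sites")
    if title:
        ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
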