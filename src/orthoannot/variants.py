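"""Disease-variant site sets: ClinVar (Mendelian) and GWAS Catalog (complex).

Two filters produce the single-nucleotide variant (SNV) site sets whose
cross-species conservation is tabulated downstream:

* *Mendelian*: ClinVar SNVs whose clinical significance is Pathogenic or
  Likely pathogenic AND whose review status is one of three accepted
  assertion levels (multiple submitters without conflicts, single
  submitter with criteria, or expert panel);
* *complex*: GWAS Catalog associations whose trait is ontologically a
  disease, disorder or cancer and whose association p-value is below 1e-8.

Both sets are collapsed to unique autosomal sites; a position reported for
several traits or alleles counts once.  Each site is then assigned a single
annotation category by a configurable precedence order (most specific
annotation wins by default).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .annotation import CATEGORIES, AnnotationConfig, CategoryMap
from .intervals import normalize_chrom

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_PRECEDENCE",
    "CLINVAR_SIGNIFICANCE_WHITELIST",
    "CLINVAR_REVIEW_WHITELIST",
    "GWAS_ONTOLOGY_CLASSES",
    "GWAS_P_THRESHOLD",
    "VariantSite",
    "ClinVarRecord",
    "GwasRecord",
    "read_clinvar_vcf",
    "read_clinvar_summary",
    "read_gwas_catalog",
    "read_ontology_map",
    "filter_clinvar",
    "filter_gwas",
    "assign_category",
    "assign_categories",
    "sites_to_frame",
]

#: Category assignment order for sites covered by several annotations,
#: roughly from most to least specific.
DEFAULT_PRECEDENCE: Tuple[str, ...] = (
    "ExonCDS",
    "ExonUTR",
    "ExonOther",
    "Promoter",
    "EnhancerProximal",
    "EnhancerDistal",
    "CTCF",
    "TADBoundary",
    "Miscellaneous",
    "IntronProximal",
    "IntronDistal",
    "Unannotated",
)

CLINVAR_SIGNIFICANCE_WHITELIST = frozenset({"pathogenic", "likely pathogenic"})

CLINVAR_REVIEW_WHITELIST = frozenset(
    {
        "criteria provided, multiple submitters, no conflicts",
        "criteria provided, single submitter",
        "reviewed by expert panel",
    }
)

GWAS_ONTOLOGY_CLASSES = frozenset({"disease", "disorder", "cancer"})

#: Genome-wide significance threshold applied to GWAS associations.
GWAS_P_THRESHOLD = 1e-8


@dataclass(frozen=True)
class VariantSite:
    """A filtered SNV position (0-based) with its provenance and category."""

    chrom: str
    pos: int
    source: str  # 'mendelian' | 'complex'
    category: Optional[str] = None
    aligned: Optional[bool] = None
    common: Optional[bool] = None


@dataclass(frozen=True)
class ClinVarRecord:
    chrom: str
    pos: int  # 1-based, as read
    ref: str
    alt: str
    significance: str
    review_status: str

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref.isalpha()
            and self.alt.isalpha()
        )


@dataclass(frozen=True)
class GwasRecord:
    chrom: str
    pos: int  # 1-based, as read
    trait: str
    ontology_class: Optional[str]
    p_value: Optional[float]


def _norm_label(s: str) -> str:
    """Case-normalize a ClinVar label: underscores become spaces."""
    return " ".join(s.replace("_", " ").split()).lower()


# -------------------------------------------------------------------- readers
def read_clinvar_vcf(path) -> List[ClinVarRecord]:
    """Read ClinVar-dialect VCF records (CLNSIG / CLNREVSTAT INFO keys).

    Multi-allelic rows expand to one record per ALT allele.  VCF INFO
    strings may split the review status on its embedded commas; the pieces
    are rejoined before interpretation.
    """
    from cyvcf2 import VCF

    def info_str(v, key: str) -> str:
        val = v.INFO.get(key)
        if val is None:
            return ""
        if isinstance(val, (tuple, list)):
            val = ",".join(str(x) for x in val)
        return str(val)

    out: List[ClinVarRecord] = []
    for v in VCF(str(path)):
        sig = info_str(v, "CLNSIG")
        rev = info_str(v, "CLNREVSTAT")
        for alt in v.ALT or ["."]:
            out.append(
                ClinVarRecord(
                    chrom=normalize_chrom(v.CHROM),
                    pos=v.POS,
                    ref=v.REF or "",
                    alt=alt,
                    significance=sig,
                    review_status=rev,
                )
            )
    return out


_SUMMARY_COLS = {
    "chrom": ("Chromosome",),
    "pos": ("Start", "PositionVCF"),
    "ref": ("ReferenceAlleleVCF", "ReferenceAllele"),
    "alt": ("AlternateAlleleVCF", "AlternateAllele"),
    "significance": ("ClinicalSignificance",),
    "review": ("ReviewStatus",),
}


def read_clinvar_summary(path, assembly: Optional[str] = None) -> List[ClinVarRecord]:
    """Read the tab-delimited ClinVar variant_summary dialect."""
    df = pd.read_csv(path, sep="\t", dtype=str, low_memory=False)
    df.columns = [c.lstrip("#") for c in df.columns]

    def pick(names: Tuple[str, ...]) -> str:
        for n in names:
            if n in df.columns:
                return n
        raise ValueError(f"{path}: none of columns {names} present")

    if assembly and "Assembly" in df.columns:
        df = df[df["Assembly"] == assembly]
    cols = {k: pick(v) for k, v in _SUMMARY_COLS.items()}
    out = []
    for row in df.to_dict("records"):
        try:
            pos = int(row[cols["pos"]])
        except (TypeError, ValueError):
            continue
        out.append(
            ClinVarRecord(
                chrom=normalize_chrom(str(row[cols["chrom"]])),
                pos=pos,
                ref=str(row[cols["ref"]] or ""),
                alt=str(row[cols["alt"]] or ""),
                significance=str(row[cols["significance"]] or ""),
                review_status=str(row[cols["review"]] or ""),
            )
        )
    return out


def read_ontology_map(path) -> Dict[str, str]:
    """Trait -> ontology-class mapping TSV (columns ``trait``, ``ontology_class``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "trait" not in df.columns or "ontology_class" not in df.columns:
        raise ValueError(f"{path}: expected columns 'trait' and 'ontology_class'")
    return {
        str(t).strip().lower(): str(c).strip().lower()
        for t, c in zip(df["trait"], df["ontology_class"])
    }


def read_gwas_catalog(
    path, ontology_map: Mapping[str, str] | None = None
) -> List[GwasRecord]:
    """Read a GWAS Catalog association TSV.

    The trait label comes from MAPPED_TRAIT (falling back to DISEASE/TRAIT)
    and is looked up, case-insensitively, in the supplied trait-to-class
    mapping; records with no mapping keep ``ontology_class=None`` and fail
    the downstream filter.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, low_memory=False)
    need = {"CHR_ID", "CHR_POS", "P-VALUE"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: missing GWAS Catalog columns {need - set(df.columns)}")
    trait_col = "MAPPED_TRAIT" if "MAPPED_TRAIT" in df.columns else "DISEASE/TRAIT"
    omap = {k.lower(): v for k, v in (ontology_map or {}).items()}
    out: List[GwasRecord] = []
    for row in df.to_dict("records"):
        chrom = normalize_chrom(str(row["CHR_ID"]))
        try:
            pos = int(float(row["CHR_POS"]))
        except (TypeError, ValueError):
            pos = -1  # kept so the filter can count the unparseable record
        try:
            p = float(row["P-VALUE"])
        except (TypeError, ValueError):
            p = None
        trait = str(row.get(trait_col) or "").strip()
        cls = None
        if "ONTOLOGY_CLASS" in df.columns and row.get("ONTOLOGY_CLASS"):
            cls = str(row["ONTOLOGY_CLASS"]).strip().lower()
        elif trait:
            cls = omap.get(trait.lower())
        out.append(GwasRecord(chrom=chrom, pos=pos, trait=trait, ontology_class=cls, p_value=p))
    return out


# -------------------------------------------------------------------- filters
def filter_clinvar(
    records: Iterable[ClinVarRecord],
    config: AnnotationConfig | None = None,
) -> Tuple[Set[VariantSite], Counter]:
    """Apply the Mendelian-variant whitelists and collapse to unique sites.

    A record is kept only if it is an SNV, its clinical significance is on
    the pathogenic whitelist AND its review status is on the accepted-
    assertion whitelist (exact match after case/underscore normalization).
    Returns the site set plus a Counter of drop reasons — unrecognized
    significance strings are counted, never silently discarded.
    """
    config = config or AnnotationConfig()
    dropped: Counter = Counter()
    sites: Set[VariantSite] = set()
    for r in records:
        if not r.is_snv:
            dropped["not_snv"] += 1
            continue
        sig = _norm_label(r.significance)
        if sig not in CLINVAR_SIGNIFICANCE_WHITELIST:
            dropped[f"significance:{sig or '<empty>'}"] += 1
            continue
        if _norm_label(r.review_status) not in CLINVAR_REVIEW_WHITELIST:
            dropped["review_status"] += 1
            continue
        if not config.keeps_chrom(r.chrom):
            dropped["non_autosomal"] += 1
            continue
        sites.add(VariantSite(chrom=normalize_chrom(r.chrom), pos=r.pos - 1, source="mendelian"))
    if dropped:
        logger.info("ClinVar filter dropped records: %s", dict(dropped))
    return sites, dropped


def filter_gwas(
    records: Iterable[GwasRecord],
    config: AnnotationConfig | None = None,
    p_threshold: float = GWAS_P_THRESHOLD,
) -> Tuple[Set[VariantSite], Counter]:
    """Apply the complex-disease filters and collapse to unique sites.

    Keeps associations whose ontology class is disease/disorder/cancer and
    whose p-value is strictly below ``p_threshold``; the same position
    reported for several qualifying traits yields one site.
    """
    config = config or AnnotationConfig()
    dropped: Counter = Counter()
    sites: Set[VariantSite] = set()
    for r in records:
        if r.pos < 1:
            dropped["bad_position"] += 1
            continue
        if r.p_value is None or not math.isfinite(r.p_value):
            dropped["bad_pvalue"] += 1
            continue
        if r.ontology_class not in GWAS_ONTOLOGY_CLASSES:
            dropped[f"ontology:{r.ontology_class or '<unmapped>'}"] += 1
            continue
        if not (0.0 < r.p_value < p_threshold):
            dropped["p_above_threshold"] += 1
            continue
        if not config.keeps_chrom(r.chrom):
            dropped["non_autosomal"] += 1
            continue
        sites.add(VariantSite(chrom=normalize_chrom(r.chrom), pos=r.pos - 1, source="complex"))
    if dropped:
        logger.info("GWAS filter dropped records: %s", dict(dropped))
    return sites, dropped


# --------------------------------------------------------------- assignment
def assign_category(
    site: VariantSite,
    cmap: CategoryMap,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> str:
    """The first category in precedence order covering the site's base.

    Total by construction: Unannotated is the complement of everything
    else, so some category always matches.
    """
    if sorted(precedence) != sorted(CATEGORIES):
        raise ValueError("precedence must be a permutation of the 12 categories")
    for cat in precedence:
        if cmap[cat].contains(site.chrom, site.pos):
            return cat
    raise AssertionError("category map does not cover the site; map is invalid")


def assign_categories(
    sites: Iterable[VariantSite],
    cmap: CategoryMap,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> List[VariantSite]:
    """Assign every site its single display category."""
    return [replace(s, category=assign_category(s, cmap, precedence)) for s in sites]


def sites_to_frame(sites: Iterable[VariantSite]) -> pd.DataFrame:
    """Tabulate sites (sorted by source, chromosome, position)."""
    rows = [
        {
            "chrom": s.chrom,
            "pos": s.pos,
            "source": s.source,
            "category": s.category,
            "aligned": s.aligned,
            "common": s.common,
        }
        for s in sites
    ]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "source", "category", "aligned", "common"])
    if len(df):
        df = df.sort_values(["source", "chrom", "pos"], kind="stable").reset_index(drop=True)
    return df
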