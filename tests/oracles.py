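"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and self-contained: plain text
parsing, per-base loops, and literal restatements of the category rules.
None of it shares code with the package being tested, so agreement between
the two routes is meaningful.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Dict, List, Optional, Set, Tuple

CATEGORY_NAMES = (
    "ExonCDS", "ExonUTR", "ExonOther", "Promoter", "EnhancerProximal",
    "EnhancerDistal", "CTCF", "Miscellaneous", "IntronProximal",
    "IntronDistal", "TADBoundary", "Unannotated",
)

REG_TYPE_TO_CAT = {
    "promoter": "Promoter",
    "promoter_flanking_region": "EnhancerProximal",
    "enhancer": "EnhancerDistal",
    "ctcf_binding_site": "CTCF",
    "tf_binding_site": "Miscellaneous",
    "open_chromatin_region": "Miscellaneous",
}


def strip_chr(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


# ------------------------------------------------------------ naive parsers
def parse_gtf_simple(path) -> Dict[str, dict]:
    """transcript_id -> {chrom, biotype, exons: [(s0,e0)], cds: [(s0,e0)]}."""
    tx: Dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] not in ("exon", "CDS"):
                continue
            attrs = {}
            for part in f[8].split(";"):
                part = part.strip()
                if not part:
                    continue
                k, _, v = part.partition(" ")
                attrs[k] = v.strip('"')
            tid = attrs["transcript_id"]
            rec = tx.setdefault(
                tid,
                {
                    "chrom": strip_chr(f[0]),
                    "biotype": attrs.get("transcript_biotype", attrs.get("gene_biotype", "unknown")),
                    "exons": [],
                    "cds": [],
                },
            )
            span = (int(f[3]) - 1, int(f[4]))  # 1-based inclusive -> half-open
            rec["exons" if f[2] == "exon" else "cds"].append(span)
    return tx


def parse_regulatory_gff(path) -> List[Tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            cat = REG_TYPE_TO_CAT.get(f[2].lower())
            if cat:
                out.append((strip_chr(f[0]), int(f[3]) - 1, int(f[4]), cat))
    return out


def parse_bed3(path) -> List[Tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                f = line.split("\t")
                out.append((strip_chr(f[0]), int(f[1]), int(f[2])))
    return out


def parse_chrom_sizes(path) -> Dict[str, int]:
    out = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                c, n = line.split("\t")
                out[strip_chr(c)] = int(n)
    return out


# ------------------------------------------------------ per-base annotation
def label_genome(
    transcripts: Dict[str, dict],
    regulatory: List[Tuple[str, int, int, str]],
    domains: List[Tuple[str, int, int]],
    chrom_lengths: Dict[str, int],
    splice_window: int,
    tad_flank: int,
) -> Dict[str, List[Set[str]]]:
    """Literal per-base labelling of every chromosome."""
    labels: Dict[str, List[Set[str]]] = {
        c: [set() for _ in range(n)] for c, n in chrom_lengths.items()
    }

    for rec in transcripts.values():
        chrom = rec["chrom"]
        if chrom not in labels:
            continue
        lab = labels[chrom]
        exons = sorted(rec["exons"])
        coding = rec["biotype"] == "protein_coding"
        cds_bases = set()
        for s, e in rec["cds"]:
            cds_bases.update(range(s, e))
        for s, e in exons:
            for p in range(s, e):
                if not coding:
                    lab[p].add("ExonOther")
                elif p in cds_bases:
                    lab[p].add("ExonCDS")
                else:
                    lab[p].add("ExonUTR")
        # merge bookkeeping-identical exons the way any per-base view would
        exon_bases = set()
        for s, e in exons:
            exon_bases.update(range(s, e))
        if exon_bases:
            lo, hi = min(exon_bases), max(exon_bases)
            intron_runs = []
            run_start = None
            for p in range(lo, hi + 1):
                if p not in exon_bases:
                    if run_start is None:
                        run_start = p
                else:
                    if run_start is not None:
                        intron_runs.append((run_start, p))
                        run_start = None
            for s, e in intron_runs:
                for p in range(s, e):
                    dist = min(p - s, e - 1 - p)  # bases from the nearest splice site
                    if dist < splice_window:
                        lab[p].add("IntronProximal")
                    else:
                        lab[p].add("IntronDistal")

    for chrom, s, e, cat in regulatory:
        if chrom in labels:
            for p in range(s, e):
                labels[chrom][p].add(cat)

    for chrom, s, e in domains:
        if chrom not in labels:
            continue
        n = chrom_lengths[chrom]
        for edge in (s, e):
            for p in range(max(0, edge - tad_flank), min(n, edge + tad_flank)):
                labels[chrom][p].add("TADBoundary")

    # residual rules
    for chrom, lab in labels.items():
        for p, cats in enumerate(lab):
            if "IntronDistal" in cats and len(cats) > 1:
                cats.discard("IntronDistal")
            if not cats:
                cats.add("Unannotated")
    return labels


# ----------------------------------------------------------- chain walking
def walk_chain_file(path) -> Dict[Tuple[str, int], Tuple[str, int]]:
    """Per-base human -> mouse forward-strand map by replaying the chains."""
    mapping: Dict[Tuple[str, int], Tuple[str, int]] = {}
    header = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("chain"):
                header = line.split()
                t = int(header[5])
                q = int(header[10])
                continue
            parts = [int(x) for x in line.split()]
            size = parts[0]
            t_chrom = strip_chr(header[2])
            q_chrom = strip_chr(header[7])
            q_size = int(header[8])
            strand = header[9]
            for i in range(size):
                if strand == "+":
                    q_fwd = q + i
                else:
                    q_fwd = q_size - 1 - (q + i)
                key = (t_chrom, t + i)
                assert key not in mapping, f"reference base mapped twice: {key}"
                mapping[key] = (q_chrom, q_fwd)
            if len(parts) == 3:
                t += size + parts[1]
                q += size + parts[2]
            else:
                header = None
    return mapping


# --------------------------------------------------------- conservation
def conservation_rows(
    human_labels: Dict[str, List[Set[str]]],
    mouse_labels: Dict[str, List[Set[str]]],
    mapping: Dict[Tuple[str, int], Tuple[str, int]],
) -> Dict[str, Tuple[int, int, int]]:
    """category (plus Genome/NonCoding) -> (denominator, aligned, common)."""
    denom = defaultdict(int)
    aligned = defaultdict(int)
    common = defaultdict(int)
    for chrom, lab in human_labels.items():
        for pos, cats in enumerate(lab):
            image = mapping.get((chrom, pos))
            mcats = (
                mouse_labels[image[0]][image[1]] if image is not None else set()
            )
            for c in cats:
                denom[c] += 1
                if image is not None:
                    aligned[c] += 1
                    if c in mcats:
                        common[c] += 1
            for agg, active in (("Genome", True), ("NonCoding", "ExonCDS" not in cats)):
                if not active:
                    continue
                denom[agg] += 1
                if image is not None:
                    aligned[agg] += 1
                    if cats & mcats:
                        common[agg] += 1
    return {c: (denom[c], aligned[c], common[c]) for c in denom}


def variant_rows(
    sites: List[Tuple[str, int, str]],  # (chrom, pos0, source)
    human_labels: Dict[str, List[Set[str]]],
    mouse_labels: Dict[str, List[Set[str]]],
    mapping: Dict[Tuple[str, int], Tuple[str, int]],
    precedence: Tuple[str, ...],
) -> Dict[Tuple[str, str], Tuple[int, int, int]]:
    """(source, category) -> (n, aligned, common), plus aggregates."""
    counts: Dict[Tuple[str, str], List[int]] = defaultdict(lambda: [0, 0, 0])
    for chrom, pos, source in sites:
        cats = human_labels[chrom][pos]
        cat = next(c for c in precedence if c in cats)
        image = mapping.get((chrom, pos))
        is_aligned = image is not None
        is_common = is_aligned and cat in mouse_labels[image[0]][image[1]]
        keys = [(source, cat), (source, "All")]
        if cat != "ExonCDS":
            keys.append((source, "NonCoding"))
        for key in keys:
            counts[key][0] += 1
            counts[key][1] += int(is_aligned)
            counts[key][2] += int(is_common)
    return {k: tuple(v) for k, v in counts.items()}


# ------------------------------------------------------------------ z-test
def pooled_z(x1: int, n1: int, x2: int, n2: int) -> float:
    """Textbook pooled two-proportion z statistic."""
    p1, p2 = x1 / n1, x2 / n2
    pool = (x1 + x2) / (n1 + n2)
    return (p1 - p2) / math.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))


# ----------------------------------------------------------- variant files
def naive_clinvar_pass_sites(path) -> Set[Tuple[str, int]]:
    """Hand filter of a ClinVar-dialect VCF, per the published criteria."""
    ok_sig = {"pathogenic", "likely pathogenic"}
    ok_rev = {
        "criteria provided, multiple submitters, no conflicts",
        "criteria provided, single submitter",
        "reviewed by expert panel",
    }
    sites = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f[3]) != 1 or len(f[4]) != 1:
                continue
            info = dict(
                kv.split("=", 1) for kv in f[7].split(";") if "=" in kv
            )
            sig = info.get("CLNSIG", "").replace("_", " ").lower()
            rev = info.get("CLNREVSTAT", "").replace("_", " ").lower()
            if sig in ok_sig and rev in ok_rev:
                sites.add((strip_chr(f[0]), int(f[1]) - 1))
    return sites


def naive_gwas_pass_sites(path, ontology: Dict[str, str]) -> Set[Tuple[str, int]]:
    ok = {"disease", "disorder", "cancer"}
    ontology = {k.lower(): v for k, v in ontology.items()}
    sites = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            trait = f[idx["MAPPED_TRAIT"]]
            if ontology.get(trait.lower()) not in ok:
                continue
            try:
                p = float(f[idx["P-VALUE"]])
            except ValueError:
                continue
            if p < 1e-8:
                sites.add((strip_chr(f[idx["CHR_ID"]]), int(f[idx["CHR_POS"]]) - 1))
    return sites
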