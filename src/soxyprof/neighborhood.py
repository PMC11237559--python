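"""Gene-neighborhood and operon analysis around soxY loci.

Gene models are ingested from GFF3 (1-based inclusive on disk, 0-based
half-open in memory).  Flanking genes are categorized by product-keyword
matching (sulfur / carbon / regulatory / other / hypothetical), operon-like
organization is called as a maximal same-strand run with short intergenic
gaps containing the required sox genes, and synteny between two
neighborhoods is scored by longest common subsequence of category strings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import InvalidAnnotationError, InvalidInputError, InvalidParameterError

CATEGORIES = ("sulfur", "carbon", "regulatory", "other", "hypothetical")

#: ordered (keyword, category) pairs; first match wins, case-insensitive
DEFAULT_CATEGORY_MAP: tuple[tuple[str, str], ...] = (
    # rhodanese-like sulfurtransferases precede the generic sulfur keywords
    ("rhd", "other"),
    ("rhodanese", "other"),
    ("dms", "sulfur"),
    ("dimethyl sulfoxide", "sulfur"),
    ("yeee", "sulfur"),
    ("yede", "sulfur"),
    ("dsr", "sulfur"),
    ("sox", "sulfur"),
    ("sqr", "sulfur"),
    ("sulfide", "sulfur"),
    ("sulfite", "sulfur"),
    ("sulfur", "sulfur"),
    ("thiosulfate", "sulfur"),
    ("tetrathionate", "sulfur"),
    ("adenylylsulfate", "sulfur"),
    ("sulfate adenylyltransferase", "sulfur"),
    ("heterodisulfide", "sulfur"),
    ("adh", "carbon"),
    ("alcohol dehydrogenase", "carbon"),
    ("fdh", "carbon"),
    ("formate dehydrogenase", "carbon"),
    ("xoxf", "carbon"),
    ("methanol dehydrogenase", "carbon"),
    ("luxr", "regulatory"),
    ("histidine kinase", "regulatory"),
    ("sigma-54", "regulatory"),
    ("sigma 54", "regulatory"),
)

SOX_OPERON_GENES = frozenset({"soxA", "soxB", "soxX", "soxY", "soxZ"})
DEFAULT_OPERON_MAX_GAP = 200  # bp
DEFAULT_NEIGHBORHOOD_K = 10   # genes each side


@dataclass
class GeneModel:
    gene_id: str
    contig: str
    start: int  # 0-based half-open
    end: int
    strand: str
    product: str = ""

    def __post_init__(self):
        if not self.start < self.end:
            raise InvalidInputError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise InvalidInputError(f"{self.gene_id}: strand must be + or -")

    def to_gff3_line(self, source: str = "soxyprof_sim") -> str:
        attrs = f"ID={self.gene_id};product={self.product}"
        return "\t".join([self.contig, source, "CDS", str(self.start + 1),
                          str(self.end), ".", self.strand, "0", attrs])


def read_gff3(path) -> list[GeneModel]:
    """Read CDS features from GFF3 into 0-based half-open gene models."""
    from gffutils.feature import feature_from_line

    models = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = feature_from_line(line)
            if f.featuretype != "CDS":
                continue
            product = f.attributes.get("product", [""])[0]
            gid = f.attributes.get("ID", [f.id or ""])[0]
            models.append(GeneModel(gene_id=gid, contig=f.seqid,
                                    start=f.start - 1, end=f.end,
                                    strand=f.strand, product=product))
    return models


def write_gff3(models: list[GeneModel], path,
               sequence_regions: dict[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig, length in (sequence_regions or {}).items():
            fh.write(f"##sequence-region {contig} 1 {length}\n")
        for gm in models:
            fh.write(gm.to_gff3_line() + "\n")


@dataclass
class NeighborhoodGene:
    gene: GeneModel
    category: str | None = None
    is_focal: bool = False


@dataclass
class NeighborhoodMap:
    focal_id: str
    genes: list[NeighborhoodGene]
    truncated_upstream: bool = False
    truncated_downstream: bool = False

    def categories(self) -> list[str]:
        return [g.category or "hypothetical" for g in self.genes]

    @property
    def focal_strand(self) -> str:
        for g in self.genes:
            if g.is_focal:
                return g.gene.strand
        raise InvalidInputError("no focal gene in neighborhood")


@dataclass
class OperonCall:
    focal_id: str
    member_ids: list[str]
    strand: str
    max_internal_gap: int
    verdict: bool
    required_satisfied: bool


def map_hits_to_genes(hits, gene_models: list[GeneModel]):
    """Attach each hit to its gene model by id; returns (loci, unmatched)."""
    by_id: dict[str, GeneModel] = {}
    for gm in gene_models:
        if gm.gene_id in by_id:
            raise InvalidAnnotationError(f"duplicate gene id {gm.gene_id}")
        by_id[gm.gene_id] = gm
    loci, unmatched = [], []
    for h in hits:
        gm = by_id.get(h.protein_id)
        if gm is None:
            unmatched.append(h.protein_id)
        else:
            loci.append((h, gm))
    return loci, unmatched


def extract_neighborhood(locus: GeneModel | str, gene_models: list[GeneModel],
                         k: int = DEFAULT_NEIGHBORHOOD_K) -> NeighborhoodMap:
    """Up to k genes on each side of the focal locus on its contig,
    genome order preserved; truncation at contig edges is flagged."""
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    focal_id = locus if isinstance(locus, str) else locus.gene_id
    contig_genes = None
    focal = None
    for gm in gene_models:
        if gm.gene_id == focal_id:
            focal = gm
            break
    if focal is None:
        raise InvalidInputError(f"locus {focal_id!r} not in gene models")
    contig_genes = sorted((g for g in gene_models if g.contig == focal.contig),
                          key=lambda g: g.start)
    i = next(idx for idx, g in enumerate(contig_genes)
             if g.gene_id == focal_id)
    lo = max(0, i - k)
    hi = min(len(contig_genes), i + k + 1)
    genes = [NeighborhoodGene(gene=g, is_focal=(g.gene_id == focal_id))
             for g in contig_genes[lo:hi]]
    return NeighborhoodMap(focal_id=focal_id, genes=genes,
                           truncated_upstream=(i - lo) < k,
                           truncated_downstream=(hi - 1 - i) < k)


def categorize(nmap: NeighborhoodMap,
               category_map: tuple[tuple[str, str], ...] | None = None
               ) -> NeighborhoodMap:
    """Assign categories by case-insensitive keyword match on the product
    label; "hypothetical" or no match falls through to hypothetical."""
    category_map = category_map if category_map is not None else DEFAULT_CATEGORY_MAP
    if not category_map:
        raise InvalidInputError("category map is empty")
    for g in nmap.genes:
        product = g.gene.product.lower()
        cat = "hypothetical"
        for keyword, category in category_map:
            if keyword.lower() in product:
                cat = category
                break
        g.category = cat
    return nmap


_SOX_SYMBOL = re.compile(r"sox([A-Z]+)")


def sox_labels(product: str) -> set[str]:
    """Extract sox gene symbols from a product label; a multi-letter symbol
    like SoxYZ or SoxAX expands to its component genes."""
    out = set()
    for m in _SOX_SYMBOL.finditer(product.replace("Sox", "sox")):
        for letter in m.group(1):
            out.add(f"sox{letter}")
    return out


def detect_operon(gene_models: list[GeneModel], locus: GeneModel | str,
                  required: frozenset = SOX_OPERON_GENES,
                  max_gap: int = DEFAULT_OPERON_MAX_GAP) -> OperonCall:
    """Grow the maximal same-strand run of consecutive genes around the
    focal locus with all intergenic gaps <= max_gap; the verdict is true iff
    the run's sox labels cover the required set."""
    if max_gap <= 0:
        raise InvalidParameterError("max_gap must be > 0")
    focal_id = locus if isinstance(locus, str) else locus.gene_id
    focal = next((g for g in gene_models if g.gene_id == focal_id), None)
    if focal is None:
        raise InvalidInputError(f"locus {focal_id!r} not in gene models")
    contig_genes = sorted((g for g in gene_models if g.contig == focal.contig),
                          key=lambda g: g.start)
    i = next(idx for idx, g in enumerate(contig_genes)
             if g.gene_id == focal_id)
    lo = i
    while lo > 0:
        prev, cur = contig_genes[lo - 1], contig_genes[lo]
        if prev.strand != focal.strand or cur.start - prev.end > max_gap:
            break
        lo -= 1
    hi = i
    while hi < len(contig_genes) - 1:
        cur, nxt = contig_genes[hi], contig_genes[hi + 1]
        if nxt.strand != focal.strand or nxt.start - cur.end > max_gap:
            break
        hi += 1
    run = contig_genes[lo:hi + 1]
    labels = set()
    for g in run:
        labels |= sox_labels(g.product)
    gaps = [b.start - a.end for a, b in zip(run, run[1:])]
    satisfied = required <= labels
    return OperonCall(focal_id=focal_id,
                      member_ids=[g.gene_id for g in run],
                      strand=focal.strand,
                      max_internal_gap=max(gaps) if gaps else 0,
                      verdict=satisfied, required_satisfied=satisfied)


def _lcs_length(a: list[str], b: list[str]) -> int:
    m, n = len(a), len(b)
    dp = [0] * (n + 1)
    for i in range(1, m + 1):
        prev = 0
        for j in range(1, n + 1):
            cur = dp[j]
            dp[j] = prev + 1 if a[i - 1] == b[j - 1] else max(dp[j], dp[j - 1])
            prev = cur
    return dp[n]


def compare_synteny(a: NeighborhoodMap, b: NeighborhoodMap) -> float:
    """Conservation score in [0, 1]: longest common subsequence of
    strand-normalized category strings over max neighborhood length."""
    ca, cb = a.categories(), b.categories()
    if any(g.category is None for g in a.genes + b.genes):
        raise InvalidInputError("both neighborhoods must be categorized")
    if a.focal_strand == "-":
        ca = ca[::-1]
    if b.focal_strand == "-":
        cb = cb[::-1]
    if not ca or not cb:
        return 0.0
    return _lcs_length(ca, cb) / max(len(ca), len(cb))
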