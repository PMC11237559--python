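"""Seeded synthetic cohorts with planted ground truth.

The generator emulates the statistical structure the analysis assumes:
annotated proteomes in which 0-5 SoxY copies per genome are planted,
spanning six swinging-arm signature variants (canonical S1a "VTIGGC",
single-residue variants S1b/S1c, divergent S2/S3/S4), SoxYZ fusion
proteins for S2/S4, composition-matched decoy proteins, sulfur-gene
homologs, and gene neighborhoods that realise either an operon-like
soxABXYZ architecture or a dispersed three-cluster arrangement.  An
ecology label correlated with divergent-signature presence is attached to
every genome.  Everything is a pure function of (spec, seed).

The non-canonical arm motifs are configurable placeholders: only the
canonical "VTIGGC" arm, the single- vs multiple-change structure of the
variants, and the shared "GGC" core are fixed by the biology this package
models; the exact variant residues are not.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import (InfeasibleTargetError, InvalidInputError,
                     InvalidModelError, InvalidParameterError,
                     LayoutConflictError)
from .neighborhood import GeneModel
from .search import ProteinRecord
from .signatures import SignatureDefinition, SignatureTable

AA = "ACDEFGHIKLMNPQRSTVWY"
CANONICAL_ARM = "VTIGGC"
CYS_POSITION_1BASED = 110  # conserved sulfur-binding cysteine of the canonical
CANONICAL_LENGTH = 150
SOXZ_LENGTH = 100

#: seed used for the package's default reference set and sulfur panel
REFERENCE_SEED = 1042

#: default arm motifs (placeholders except S1a; overridable via config)
DEFAULT_SIGNATURE_SPECS = [
    # name, 6-mer arm motif, max_mismatch, identity range to canonical (%)
    ("S1a", "VTIGGC", 0, (52.2, 64.2)),
    ("S1b", "VTVGGC", 0, (45.0, 55.0)),
    ("S1c", "VSIGGC", 0, (33.0, 44.0)),
    ("S2", "AKMGGC", 1, (24.0, 33.3)),
    ("S3", "TSLGGC", 1, (28.8, 31.6)),
    ("S4", "PNVGGC", 1, (26.0, 36.4)),
]

CLADE_OF_SIGNATURE = {"S1a": 1, "S1b": 1, "S1c": 1, "S2": 2, "S3": 3, "S4": 4}
FUSED_SIGNATURES = frozenset({"S2", "S4"})


# ----------------------------------------------------------------------
# Reference set
# ----------------------------------------------------------------------

@dataclass
class ReferenceSet:
    arm_window: int
    canonical_soxy: str
    canonical_soxz: str
    seed_alignment: list[str]
    signature_exemplars: dict[str, str]
    signatures: SignatureTable
    cys_position_1based: int = CYS_POSITION_1BASED

    @property
    def arm_span(self) -> tuple[int, int]:
        """0-based half-open arm window on the canonical sequence."""
        return (self.cys_position_1based - self.arm_window,
                self.cys_position_1based)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))

def _scrub_motif(seq: list[str], rng: np.random.Generator, motif: str,
                 allowed_start: int | None, protected: tuple[int, int]) -> None:
    """Mutate minimal positions so ``motif`` occurs only at ``allowed_start``."""
    k = len(motif)
    changed = True
    while changed:
        changed = False
        text = "".join(seq)
        pos = text.find(motif)
        while pos != -1:
            if pos != allowed_start:
                # pick a position of this occurrence outside the protected span
                for off in range(k):
                    p = pos + off
                    if not (protected[0] <= p < protected[1]):
                        choices = [a for a in AA if a != seq[p]]
                        seq[p] = rng.choice(choices)
                        changed = True
                        break
            pos = text.find(motif, pos + 1)


def default_signature_table(arm_window: int = 6,
                            canonical: str | None = None) -> SignatureTable:
    """The six named signatures.  For windows wider than 6 the motifs are
    left-padded with the canonical residues upstream of the arm."""
    entries = []
    for name, motif, mm, rng_ in DEFAULT_SIGNATURE_SPECS:
        if arm_window > 6:
            if canonical is None:
                raise InvalidParameterError(
                    "canonical sequence required for arm_window > 6")
            pad = canonical[CYS_POSITION_1BASED - arm_window:
                            CYS_POSITION_1BASED - 6]
            motif = pad + motif
        entries.append(SignatureDefinition(name=name, arm_motif=motif,
                                           max_mismatch=mm,
                                           target_identity_range=rng_))
    return SignatureTable(entries=entries)


def build_reference_set(arm_window: int = 6, seed: int = REFERENCE_SEED) -> ReferenceSet:
    """Deterministic canonical SoxY/SoxZ references, seed alignment and
    per-signature full-length exemplars."""
    if arm_window < 6:
        raise InvalidParameterError("arm_window must be >= 6")
    rng = np.random.default_rng(seed)
    arm_start = CYS_POSITION_1BASED - 6  # canonical 6-mer arm position
    seq = list(_random_protein(rng, CANONICAL_LENGTH))
    seq[arm_start:CYS_POSITION_1BASED] = list(CANONICAL_ARM)
    # exactly one GGC, the one ending at the conserved cysteine
    ggc_start = CANONICAL_ARM.index("GGC") + arm_start
    _scrub_motif(seq, rng, "GGC", ggc_start, (arm_start, CYS_POSITION_1BASED))
    canonical = "".join(seq)
    canonical_soxz = _random_protein(rng, SOXZ_LENGTH)

    table = default_signature_table(arm_window, canonical)
    exemplars: dict[str, str] = {}
    for entry in table:
        lo, hi = entry.target_identity_range
        exemplars[entry.name] = plant_signature(
            canonical, entry, (lo + hi) / 2.0,
            seed=int(rng.integers(2 ** 31)))

    seed_alignment = [canonical]
    for _ in range(5):
        seed_alignment.append(perturb_sequence(
            canonical, float(rng.uniform(90, 96)), int(rng.integers(2 ** 31)),
            protected=(arm_start, CYS_POSITION_1BASED)))
    for entry in table:
        for _ in range(2):
            seed_alignment.append(perturb_sequence(
                exemplars[entry.name], float(rng.uniform(90, 96)),
                int(rng.integers(2 ** 31)),
                protected=(arm_start, CYS_POSITION_1BASED)))
    return ReferenceSet(arm_window=arm_window, canonical_soxy=canonical,
                        canonical_soxz=canonical_soxz,
                        seed_alignment=seed_alignment,
                        signature_exemplars=exemplars, signatures=table)


_DEFAULT_REFS: dict[int, ReferenceSet] = {}


def default_reference_set() -> ReferenceSet:
    if 6 not in _DEFAULT_REFS:
        _DEFAULT_REFS[6] = build_reference_set(6, REFERENCE_SEED)
    return _DEFAULT_REFS[6]


# ----------------------------------------------------------------------
# Sequence-level operations
# ----------------------------------------------------------------------

def shuffle_sequence(seq: str, seed: int) -> str:
    """Uniform (Fisher-Yates) permutation of the residues; composition is
    preserved, positional signal destroyed (the decoy null model)."""
    if len(seq) < 1:
        raise InvalidParameterError("sequence must be non-empty")
    rng = np.random.default_rng(seed)
    return "".join(np.array(list(seq))[rng.permutation(len(seq))])


def _substitute(seq: list[str], positions: np.ndarray,
                rng: np.random.Generator) -> None:
    for p in positions:
        choices = [a for a in AA if a != seq[p]]
        seq[p] = rng.choice(choices)


def perturb_sequence(base: str, identity: float, seed: int,
                     protected: tuple[int, int] | None = None) -> str:
    """Substitution-only mutant of ``base`` at the requested global percent
    identity (exact mismatch count), leaving ``protected`` untouched."""
    if not (0 < identity <= 100):
        raise InvalidParameterError("identity must be in (0, 100]")
    rng = np.random.default_rng(seed)
    L = len(base)
    n_subs = round((100.0 - identity) / 100.0 * L)
    candidates = [i for i in range(L)
                  if protected is None or not (protected[0] <= i < protected[1])]
    if n_subs > len(candidates):
        raise InfeasibleTargetError(
            f"cannot place {n_subs} substitutions in {len(candidates)} positions")
    seq = list(base)
    pos = rng.choice(len(candidates), size=n_subs, replace=False)
    _substitute(seq, np.array(candidates)[pos], rng)
    return "".join(seq)


def plant_signature(base: str, sig: SignatureDefinition, target_identity: float,
                    seed: int,
                    cys_position_1based: int = CYS_POSITION_1BASED) -> str:
    """Rewrite the arm window of ``base`` to ``sig.arm_motif`` and mutate
    outside the arm to hit ``target_identity`` (percent, to ``base``).

    The arm window is excluded from background mutation, so planted arms
    are always exact.
    """
    if not (20 <= target_identity <= 100):
        raise InvalidParameterError("target_identity must be in [20, 100]")
    motif = sig.arm_motif
    arm_start = cys_position_1based - len(motif)
    arm_end = cys_position_1based
    if arm_start < 0 or arm_end > len(base):
        raise InvalidParameterError("arm window outside sequence")
    rng = np.random.default_rng(seed)
    seq = list(base)
    seq[arm_start:arm_end] = list(motif)
    arm_mm = sum(1 for a, b in zip(base[arm_start:arm_end], motif) if a != b)
    L = len(base)
    needed = round((100.0 - target_identity) / 100.0 * L)
    extra = max(0, needed - arm_mm)
    candidates = [i for i in range(L) if not (arm_start <= i < arm_end)]
    if extra > len(candidates):
        raise InfeasibleTargetError(
            f"identity {target_identity}% infeasible for length {L}")
    pos = rng.choice(len(candidates), size=extra, replace=False)
    _substitute(seq, np.array(candidates)[pos], rng)
    return "".join(seq)


# ----------------------------------------------------------------------
# Neighborhood layouts
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class LayoutGene:
    label: str
    product: str
    length_aa: int
    strand: str
    gap_after: int  # bp to the next gene in the layout
    category: str
    role: str = "random"  # focal | soxz | panel:<name> | random


@dataclass(frozen=True)
class NeighborhoodLayout:
    name: str
    genes: tuple[LayoutGene, ...]

    def focal_index(self) -> int:
        idx = [i for i, g in enumerate(self.genes) if g.role == "focal"]
        if len(idx) != 1:
            raise InvalidInputError(f"layout {self.name} needs exactly one focal gene")
        return idx[0]


def _lg(label, product, aa, strand, gap, cat, role="random"):
    return LayoutGene(label=label, product=product, length_aa=aa, strand=strand,
                      gap_after=gap, category=cat, role=role)


def _fillers(n, strand="+", gap=300):
    return tuple(_lg(f"hyp", "hypothetical protein", 180, strand, gap,
                     "hypothetical") for _ in range(n))


DEFAULT_LAYOUTS: dict[str, NeighborhoodLayout] = {}

def _register(name, genes):
    DEFAULT_LAYOUTS[name] = NeighborhoodLayout(name=name, genes=tuple(genes))

_register("sedimenticola_operon", [
    _lg("luxR", "LuxR family transcriptional regulator", 250, "+", 120, "regulatory"),
    _lg("hk", "signal transduction histidine kinase", 400, "+", 140, "regulatory"),
    _lg("soxA", "sulfur oxidation c-type cytochrome SoxA", 280, "+", 100, "sulfur", "panel:soxA"),
    _lg("soxB", "sulfur oxidation protein SoxB", 560, "+", 80, "sulfur", "panel:soxB"),
    _lg("soxX", "sulfur oxidation c-type cytochrome SoxX", 150, "+", 60, "sulfur", "panel:soxX"),
    _lg("soxY", "sulfur oxidation protein SoxY", 150, "+", 50, "sulfur", "focal"),
    _lg("soxZ", "sulfur oxidation protein SoxZ", 100, "+", 300, "sulfur", "soxz"),
])

_register("thiodiazotropha_dispersed", [
    _lg("luxR", "LuxR family transcriptional regulator", 250, "+", 100, "regulatory"),
    _lg("hk", "signal transduction histidine kinase", 400, "+", 120, "regulatory"),
    _lg("soxB", "sulfur oxidation protein SoxB", 560, "+", 350, "sulfur", "panel:soxB"),
    *_fillers(12, "-"),
    _lg("soxA", "sulfur oxidation c-type cytochrome SoxA", 280, "-", 80, "sulfur", "panel:soxA"),
    _lg("soxX", "sulfur oxidation c-type cytochrome SoxX", 150, "-", 350, "sulfur", "panel:soxX"),
    *_fillers(12, "+"),
    _lg("rpoN", "RNA polymerase sigma-54 factor RpoN", 480, "+", 90, "regulatory"),
    _lg("hk2", "signal transduction histidine kinase", 400, "+", 110, "regulatory"),
    _lg("soxY", "sulfur oxidation protein SoxY", 150, "+", 60, "sulfur", "focal"),
    _lg("soxZ", "sulfur oxidation protein SoxZ", 100, "+", 300, "sulfur", "soxz"),
])

_register("soxyz_pair", [
    _lg("soxY", "sulfur oxidation protein SoxY", 150, "+", 60, "sulfur", "focal"),
    _lg("soxZ", "sulfur oxidation protein SoxZ", 100, "+", 300, "sulfur", "soxz"),
])

_register("s1c_dms", [
    _lg("soxY", "sulfur oxidation protein SoxY", 150, "+", 80, "sulfur", "focal"),
    _lg("soxZ", "sulfur oxidation protein SoxZ", 100, "+", 120, "sulfur", "soxz"),
    _lg("dmsA", "dimethyl sulfoxide reductase subunit DmsA", 800, "+", 60, "sulfur"),
    _lg("dmsB", "dimethyl sulfoxide reductase iron-sulfur subunit DmsB", 200, "+", 300, "sulfur"),
    _lg("hyp", "hypothetical protein", 150, "+", 300, "hypothetical"),
])

_register("s2_adh", [
    _lg("soxYZ", "sulfur oxidation protein SoxYZ, fused carrier", 250, "+", 90, "sulfur", "focal"),
    _lg("adh", "zinc-dependent alcohol dehydrogenase AdhP", 340, "+", 70, "carbon"),
    _lg("rhd", "rhodanese-like domain sulfurtransferase", 130, "+", 250, "other"),
    _lg("hyp", "hypothetical protein", 160, "+", 300, "hypothetical"),
])

_register("s3_otr", [
    _lg("soxY", "sulfur oxidation protein SoxY", 150, "+", 70, "sulfur", "focal"),
    _lg("soxZ", "sulfur oxidation protein SoxZ", 100, "+", 100, "sulfur", "soxz"),
    _lg("otr", "octaheme tetrathionate reductase Otr", 450, "+", 90, "sulfur"),
    _lg("yeeE", "YeeE/YedE family thiosulfate uptake transporter", 350, "+", 300, "sulfur"),
])

_register("s4_c1", [
    _lg("soxYZ", "sulfur oxidation protein SoxYZ, fused carrier", 250, "+", 80, "sulfur", "focal"),
    _lg("xoxF", "XoxF-type methanol dehydrogenase", 600, "+", 90, "carbon"),
    _lg("fdhA", "formate dehydrogenase subunit alpha FdhA", 950, "+", 110, "carbon"),
    _lg("hyp", "hypothetical protein", 140, "+", 300, "hypothetical"),
])

#: default layout per signature for planted copies beyond the first S1a
SIGNATURE_LAYOUTS = {"S1a": "soxyz_pair", "S1b": "soxyz_pair", "S1c": "s1c_dms",
                     "S2": "s2_adh", "S3": "s3_otr", "S4": "s4_c1"}


# ----------------------------------------------------------------------
# Sulfur reference panel
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class PanelEntry:
    name: str
    group: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def short(self) -> bool:
        return len(self.seq) < 120


_PANEL_SPEC = [
    ("sqr", "sqr", 430), ("fccA", "fccAB", 250), ("fccB", "fccAB", 420),
    ("soxA", "soxAXB", 280), ("soxX", "soxAXB", 150), ("soxB", "soxAXB", 560),
    ("soxZ", "soxYZ", SOXZ_LENGTH), ("dsrA", "dsrAB", 430), ("dsrB", "dsrAB", 380),
    ("aprA", "aprAB", 650), ("aprB", "aprAB", 150), ("sat", "sat", 400),
    ("aprM", "aprM", 110), ("qmoA", "qmoAB", 410), ("qmoB", "qmoAB", 730),
    ("hdrB", "hdrBC", 300), ("hdrC", "hdrBC", 200),
]

PANEL_PRODUCTS = {
    "sqr": "sulfide:quinone oxidoreductase Sqr",
    "fccA": "sulfide dehydrogenase flavocytochrome c subunit FccA",
    "fccB": "sulfide dehydrogenase flavoprotein subunit FccB",
    "soxA": "sulfur oxidation c-type cytochrome SoxA",
    "soxX": "sulfur oxidation c-type cytochrome SoxX",
    "soxB": "sulfur oxidation protein SoxB",
    "soxZ": "sulfur oxidation protein SoxZ",
    "dsrA": "dissimilatory sulfite reductase subunit DsrA",
    "dsrB": "dissimilatory sulfite reductase subunit DsrB",
    "aprA": "adenylylsulfate reductase subunit AprA",
    "aprB": "adenylylsulfate reductase subunit AprB",
    "sat": "sulfate adenylyltransferase Sat",
    "aprM": "adenylylsulfate reductase membrane anchor AprM",
    "qmoA": "quinone-modifying oxidoreductase subunit QmoA",
    "qmoB": "quinone-modifying oxidoreductase subunit QmoB",
    "hdrB": "heterodisulfide reductase subunit HdrB",
    "hdrC": "heterodisulfide reductase subunit HdrC",
}


def make_sulfur_panel(seed: int = REFERENCE_SEED,
                      refs: ReferenceSet | None = None) -> list[PanelEntry]:
    """Reference sulfur proteins used for presence/absence profiling."""
    refs = refs or default_reference_set()
    rng = np.random.default_rng(seed + 7)
    panel = []
    for name, group, length in _PANEL_SPEC:
        seq = refs.canonical_soxz if name == "soxZ" else _random_protein(rng, length)
        panel.append(PanelEntry(name=name, group=group, seq=seq))
    return panel


_DEFAULT_PANEL: list[PanelEntry] | None = None


def default_sulfur_panel() -> list[PanelEntry]:
    global _DEFAULT_PANEL
    if _DEFAULT_PANEL is None:
        _DEFAULT_PANEL = make_sulfur_panel()
    return _DEFAULT_PANEL


# ----------------------------------------------------------------------
# Genome generation
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedCopy:
    signature: str
    fused: bool
    layout: str


@dataclass
class GenomeSpec:
    genome_id: str
    planted: list[PlantedCopy] = field(default_factory=list)
    decoy_count: int = 35
    label: str = "unlabelled"
    environment: str = "unknown"
    sulfur_genes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not (0 <= len(self.planted) <= 5):
            raise InvalidParameterError("planted copy count must be in [0, 5]")


@dataclass
class SyntheticGenome:
    genome_id: str
    label: str
    environment: str
    proteins: list[ProteinRecord]
    genes: list[GeneModel]
    contig_lengths: dict[str, int]


CORE_SULFUR_GENES = ["sqr", "fccA", "fccB", "soxA", "soxB", "soxX",
                     "dsrA", "dsrB", "aprA", "aprB", "sat"]

TRUTH_COLUMNS = ["genome_id", "gene_id", "signature", "clade", "fused",
                 "layout", "contig", "start", "end", "strand",
                 "identity_to_exemplar"]


def generate_genome(spec: GenomeSpec,
                    layouts: dict[str, NeighborhoodLayout] | None = None,
                    seed: int = 0, refs: ReferenceSet | None = None,
                    panel: list[PanelEntry] | None = None
                    ) -> tuple[SyntheticGenome, pd.DataFrame]:
    """Instantiate one genome: planted soxY copies embedded in their layout
    blocks, standalone sulfur-gene homologs, and shuffled decoys, laid out
    on a single contig with self-consistent GFF3 coordinates."""
    layouts = layouts or DEFAULT_LAYOUTS
    refs = refs or default_reference_set()
    panel = panel or default_sulfur_panel()
    panel_by_name = {p.name: p for p in panel}
    rng = np.random.default_rng(seed)
    arm_span = refs.arm_span

    for copy in spec.planted:
        if copy.layout not in layouts:
            raise InvalidInputError(f"unknown layout {copy.layout!r}")
        if copy.signature not in refs.signature_exemplars:
            raise InvalidInputError(f"unknown signature {copy.signature!r}")

    # each unit is a list of (seq, product, strand, gap_after, truth|None)
    units: list[list[tuple]] = []
    truth_rows: list[dict] = []

    for copy in spec.planted:
        layout = layouts[copy.layout]
        block = []
        for g in layout.genes:
            if g.role == "focal":
                ident = float(rng.uniform(88, 97))
                seq = perturb_sequence(refs.signature_exemplars[copy.signature],
                                       ident, int(rng.integers(2 ** 31)),
                                       protected=arm_span)
                if copy.fused:
                    tail = perturb_sequence(refs.canonical_soxz,
                                            float(rng.uniform(85, 95)),
                                            int(rng.integers(2 ** 31)))
                    seq = seq + tail
                truth = {"signature": copy.signature,
                         "clade": CLADE_OF_SIGNATURE[copy.signature],
                         "fused": copy.fused, "layout": copy.layout,
                         "identity_to_exemplar": round(ident, 2)}
                product = ("sulfur oxidation protein SoxYZ, fused carrier"
                           if copy.fused else g.product)
                block.append((seq, product, g.strand, g.gap_after, truth))
            elif g.role == "soxz":
                seq = perturb_sequence(refs.canonical_soxz,
                                       float(rng.uniform(85, 95)),
                                       int(rng.integers(2 ** 31)))
                block.append((seq, g.product, g.strand, g.gap_after, None))
            elif g.role.startswith("panel:"):
                entry = panel_by_name[g.role.split(":", 1)[1]]
                seq = perturb_sequence(entry.seq, float(rng.uniform(75, 90)),
                                       int(rng.integers(2 ** 31)))
                block.append((seq, g.product, g.strand, g.gap_after, None))
            else:
                seq = _random_protein(rng, g.length_aa)
                block.append((seq, g.product, g.strand, g.gap_after, None))
        units.append(block)

    for name in spec.sulfur_genes:
        if name not in panel_by_name:
            raise InvalidInputError(f"unknown sulfur gene {name!r}")
        entry = panel_by_name[name]
        seq = perturb_sequence(entry.seq, float(rng.uniform(75, 90)),
                               int(rng.integers(2 ** 31)))
        strand = "+" if rng.random() < 0.5 else "-"
        units.append([(seq, PANEL_PRODUCTS[name], strand,
                       int(rng.integers(20, 401)), None)])

    templates = ([refs.canonical_soxy] + list(refs.signature_exemplars.values())
                 + [p.seq for p in panel])
    for _ in range(spec.decoy_count):
        template = templates[int(rng.integers(len(templates)))]
        seq = shuffle_sequence(template, int(rng.integers(2 ** 31)))
        strand = "+" if rng.random() < 0.5 else "-"
        units.append([(seq, "hypothetical protein", strand,
                       int(rng.integers(20, 401)), None)])

    rng.shuffle(units)

    contig = f"{spec.genome_id}_c1"
    proteins: list[ProteinRecord] = []
    genes: list[GeneModel] = []
    cursor = 150
    n = 0
    for block in units:
        for seq, product, strand, gap_after, truth in block:
            n += 1
            gid = f"{spec.genome_id}_gene{n:03d}"
            nt_len = len(seq) * 3 + 3
            start, end = cursor, cursor + nt_len
            if genes and start < genes[-1].end:
                raise LayoutConflictError(f"overlapping loci at {gid}")
            genes.append(GeneModel(gene_id=gid, contig=contig, start=start,
                                   end=end, strand=strand, product=product))
            proteins.append(ProteinRecord(protein_id=gid,
                                          genome_id=spec.genome_id, seq=seq))
            if truth is not None:
                truth_rows.append({"genome_id": spec.genome_id, "gene_id": gid,
                                   "contig": contig, "start": start + 1,
                                   "end": end, "strand": strand, **truth})
            cursor = end + gap_after
    genome = SyntheticGenome(genome_id=spec.genome_id, label=spec.label,
                             environment=spec.environment, proteins=proteins,
                             genes=genes,
                             contig_lengths={contig: cursor + 150})
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return genome, truth


def make_clade_alignment(n_per_clade: int = 6, seed: int = 0,
                         refs: ReferenceSet | None = None
                         ) -> tuple[list[str], list[str], dict[str, int]]:
    """A clean four-clade test set with shared ancestry within each clade.

    Each clade descends from one ancestor (the S1a/S2/S3/S4 exemplars);
    members diverge 4-10% from their ancestor, so every clade stem carries
    the ancestor's derived states.  Clade-1 members rotate through the
    S1a/S1b/S1c arm variants.  Returns (ids, sequences, clade-of-id); the
    ancestors themselves are included as ``REF_*`` tips.
    """
    if n_per_clade < 2:
        raise InvalidParameterError("n_per_clade must be >= 2")
    refs = refs or default_reference_set()
    rng = np.random.default_rng(seed)
    ancestors = {1: "S1a", 2: "S2", 3: "S3", 4: "S4"}
    s1_defs = [e for e in refs.signatures if e.name in ("S1a", "S1b", "S1c")]
    ids, seqs, clade_of = [], [], {}
    for clade, anc_name in ancestors.items():
        anc = refs.signature_exemplars[anc_name]
        ids.append(f"REF_{anc_name}")
        seqs.append(anc)
        clade_of[f"REF_{anc_name}"] = clade
        for k in range(n_per_clade):
            member = perturb_sequence(anc, float(rng.uniform(90, 96)),
                                      int(rng.integers(2 ** 31)),
                                      protected=refs.arm_span)
            if clade == 1:  # the three S1 arm variants share clade-1 ancestry
                sig = s1_defs[k % len(s1_defs)]
                member = plant_signature(member, sig, 100,
                                         int(rng.integers(2 ** 31)))
            sid = f"C{clade}_m{k}"
            ids.append(sid)
            seqs.append(member)
            clade_of[sid] = clade
    return ids, seqs, clade_of


# ----------------------------------------------------------------------
# Cohorts
# ----------------------------------------------------------------------

DEFAULT_ECOLOGY_MODEL = {
    "specialist": {
        "weight": 0.5,
        "kind": "specialist",
        "environments": ["specialized"],
        "hosts": ["Thyasira_cf_gouldii", "Phacoides_pectinatus"],
        "repertoires": [
            (("S1a",), 0.55),
            (("S1b",), 0.20),
            (("S1a", "S1a"), 0.20),
            ((), 0.05),
        ],
    },
    "generalist": {
        "weight": 0.5,
        "kind": "generalist",
        "environments": ["seagrass", "coral_reef", "mangrove"],
        "hosts": ["Codakia_orbicularis", "Ctena_orbiculata", "Loripes_orbiculatus"],
        "repertoires": [
            (("S1a", "S2"), 0.25),
            (("S1a", "S3"), 0.20),
            (("S1a", "S4"), 0.15),
            (("S1a", "S1c", "S3"), 0.15),
            (("S1a", "S2", "S4"), 0.10),
            (("S1a", "S1a", "S2", "S3", "S4"), 0.05),
            (("S1a",), 0.10),
        ],
    },
}

DIVERGENT_SIGNATURES = frozenset({"S1c", "S2", "S3", "S4"})


def _validate_model(model: dict) -> None:
    if not model:
        raise InvalidModelError("empty ecology model")
    total = sum(cfg.get("weight", 0) for cfg in model.values())
    if abs(total - 1.0) > 1e-9:
        raise InvalidModelError("label weights must sum to 1")
    for label, cfg in model.items():
        if cfg.get("kind") not in ("specialist", "generalist"):
            raise InvalidModelError(f"unknown label kind for {label!r}")
        reps = cfg.get("repertoires", [])
        if abs(sum(p for _, p in reps) - 1.0) > 1e-9:
            raise InvalidModelError(f"repertoire probabilities for {label!r} "
                                    "must sum to 1")
        for sigs, _ in reps:
            for s in sigs:
                if s not in CLADE_OF_SIGNATURE:
                    raise InvalidModelError(f"unknown signature {s!r}")
            if cfg["kind"] == "specialist" and any(
                    s in DIVERGENT_SIGNATURES for s in sigs):
                raise InvalidModelError(
                    f"specialist label {label!r} lists a divergent signature")


def cohort_specs(n_genomes: int, ecology_model: dict | None = None,
                 seed: int = 0) -> list[GenomeSpec]:
    """Draw per-genome specs (labels, repertoires, layouts, environments)
    from the ecology model."""
    if n_genomes < 1:
        raise InvalidParameterError("n_genomes must be >= 1")
    model = ecology_model or DEFAULT_ECOLOGY_MODEL
    _validate_model(model)
    rng = np.random.default_rng(seed)
    labels = sorted(model)
    weights = np.array([model[l]["weight"] for l in labels])
    specs = []
    for g in range(n_genomes):
        label = labels[int(rng.choice(len(labels), p=weights))]
        cfg = model[label]
        reps = cfg["repertoires"]
        probs = np.array([p for _, p in reps])
        sigs = reps[int(rng.choice(len(reps), p=probs / probs.sum()))][0]
        planted = []
        first_s1a = True
        for s in sigs:
            if s == "S1a" and first_s1a:
                first_s1a = False
                if cfg["kind"] == "specialist" and rng.random() < 0.5:
                    layout = "sedimenticola_operon"
                else:
                    layout = "thiodiazotropha_dispersed"
            else:
                layout = SIGNATURE_LAYOUTS[s]
            planted.append(PlantedCopy(signature=s, fused=s in FUSED_SIGNATURES,
                                       layout=layout))
        sulfur = list(CORE_SULFUR_GENES)
        if rng.random() < 0.5:
            sulfur.append("aprM")
        else:
            sulfur.extend(["qmoA", "qmoB", "hdrB", "hdrC"])
        specs.append(GenomeSpec(
            genome_id=f"G{g + 1:04d}", planted=planted,
            decoy_count=int(rng.integers(30, 46)), label=label,
            environment=str(rng.choice(cfg["environments"])),
            sulfur_genes=sulfur))
    return specs


def generate_cohort(n_genomes: int, ecology_model: dict | None = None,
                    seed: int = 0, refs: ReferenceSet | None = None,
                    panel: list[PanelEntry] | None = None
                    ) -> tuple[list[SyntheticGenome], pd.DataFrame, pd.DataFrame]:
    """Generate a cohort: genomes, metadata table and combined truth table."""
    refs = refs or default_reference_set()
    panel = panel or default_sulfur_panel()
    specs = cohort_specs(n_genomes, ecology_model, seed)
    rng = np.random.default_rng(seed + 1)
    model = ecology_model or DEFAULT_ECOLOGY_MODEL
    genomes, truths, meta = [], [], []
    for spec in specs:
        genome, truth = generate_genome(spec, seed=int(rng.integers(2 ** 31)),
                                        refs=refs, panel=panel)
        genomes.append(genome)
        truths.append(truth)
        hosts = model[spec.label].get("hosts", [spec.label])
        meta.append({"genome_id": spec.genome_id,
                     "host_label": str(rng.choice(hosts)),
                     "environment": spec.environment,
                     "ecology_label": spec.label})
    metadata = pd.DataFrame(meta)
    truths = [t for t in truths if not t.empty]
    truth = (pd.concat(truths, ignore_index=True) if truths
             else pd.DataFrame(columns=TRUTH_COLUMNS))
    return genomes, metadata, truth


# ----------------------------------------------------------------------
# Writers
# ----------------------------------------------------------------------

def write_cohort(genomes: list[SyntheticGenome], metadata: pd.DataFrame,
                 truth: pd.DataFrame, outdir, seed: int | None = None) -> dict:
    """Write proteins.faa, genes.gff3, metadata.tsv, truth.tsv and a
    run-manifest JSON; returns the manifest dict."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    faa = outdir / "proteins.faa"
    with open(faa, "w") as fh:
        for g in genomes:
            for rec in g.proteins:
                fh.write(f">{rec.protein_id}\n{rec.seq}\n")
    gff = outdir / "genes.gff3"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genomes:
            for contig, length in g.contig_lengths.items():
                fh.write(f"##sequence-region {contig} 1 {length}\n")
        for g in genomes:
            for gm in g.genes:
                fh.write(gm.to_gff3_line() + "\n")
    metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    manifest = {
        "seed": seed,
        "n_genomes": len(genomes),
        "n_planted": int(len(truth)),
        "checksums": {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                      for p in [faa, gff, outdir / "metadata.tsv",
                                outdir / "truth.tsv"]},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
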