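"""Swinging-arm extraction, signature classification, fusion detection.

The substrate-binding "swinging arm" of SoxY is the short C-terminal
region ending at the conserved sulfur-binding cysteine (position 110 in
the canonical reference).  Each homolog's arm window is read off its
profile alignment and classified against a table of named arm motifs
(S1a "VTIGGC" canonical; S1b/S1c single-residue variants; S2/S3/S4
divergent variants) by Hamming distance, gaps counting as mismatches.
SoxYZ fusion proteins are recognised as a SoxY domain followed by a SoxZ
domain, each passing a per-domain e-value cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidInputError, InvalidParameterError
from .search import (Calibration, LocalScoring, local_search)

GAP = "-"


@dataclass(frozen=True)
class SignatureDefinition:
    name: str
    arm_motif: str
    max_mismatch: int
    target_identity_range: tuple[float, float] = (40.0, 100.0)

    def __post_init__(self):
        if "GGC" not in self.arm_motif:
            raise InvalidInputError(f"arm motif {self.arm_motif!r} lacks 'GGC'")


@dataclass
class SignatureTable:
    """Ordered signature definitions; order is classification priority."""

    entries: list[SignatureDefinition]

    def __post_init__(self):
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise InvalidInputError("signature names must be unique")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)


@dataclass(frozen=True)
class ArmDefinition:
    """Arm window relative to the profile's conserved-cysteine anchor.

    The window spans profile columns [anchor - upstream_offset, anchor].
    """

    anchor: int
    upstream_offset: int = 5

    def __post_init__(self):
        if self.anchor < self.upstream_offset:
            raise InvalidParameterError("anchor before start of profile window")

    @property
    def window_length(self) -> int:
        return self.upstream_offset + 1

    @property
    def columns(self) -> range:
        return range(self.anchor - self.upstream_offset, self.anchor + 1)


@dataclass
class ArmExtract:
    arm_string: str
    cys_present: bool
    cys_position_1based: int | None
    resolved: bool = True

    def __post_init__(self):
        if self.cys_present != (self.cys_position_1based is not None):
            raise InvalidInputError("cys position defined iff cys present")


@dataclass
class SignatureCall:
    protein_id: str
    signature: str  # a table name or "unclassified"
    mismatches: int | None
    fused: bool = False
    reason: str = ""


@dataclass
class FusionCall:
    protein_id: str
    fused: bool
    y_bounds: tuple[int, int] | None = None
    z_bounds: tuple[int, int] | None = None
    y_evalue: float | None = None
    z_evalue: float | None = None


@dataclass
class IdentityResult:
    identity: float
    alignment_length: int
    matches: int


def extract_arm(trace, seq: str, arm_def: ArmDefinition) -> ArmExtract:
    """Read the arm window off a profile alignment trace.

    ``trace[j]`` is the residue index aligned to column ``j`` or -1.  The
    arm is the window *ending at* the sulfur-binding cysteine: when the
    anchor column aligns to a cysteine, the window is read directly from
    the ungapped sequence ending at that residue (robust to alignment
    jitter — an insertion inside the window would otherwise shift the
    column-wise readout).  When the anchor is deleted or non-cysteine,
    the column-wise readout with gap symbols is reported.  A trace that
    does not reach the anchor column yields an unresolved extract
    (downstream classification reports "unclassified").
    """
    if len(trace) <= arm_def.anchor:
        return ArmExtract(arm_string="", cys_present=False,
                          cys_position_1based=None, resolved=False)
    anchor_res = int(trace[arm_def.anchor])
    cys = anchor_res >= 0 and seq[anchor_res] == "C"
    if cys and anchor_res >= arm_def.upstream_offset:
        arm = seq[anchor_res - arm_def.upstream_offset:anchor_res + 1]
    else:
        chars = []
        for j in arm_def.columns:
            r = int(trace[j])
            chars.append(GAP if r < 0 else seq[r])
        arm = "".join(chars)
    return ArmExtract(arm_string=arm, cys_present=cys,
                      cys_position_1based=anchor_res + 1 if cys else None)


def hamming(a: str, b: str) -> int:
    """Mismatch count; a gap in either string counts as a mismatch."""
    if len(a) != len(b):
        raise InvalidInputError("arm/motif length mismatch")
    return sum(1 for x, y in zip(a, b) if x != y or x == GAP)


def classify(arm: ArmExtract, table: SignatureTable,
             protein_id: str = "") -> SignatureCall:
    """Assign the best (fewest-mismatch) signature within its tolerance.

    Ties are broken by table order (priority).  Arms farther than every
    entry's ``max_mismatch`` — or unresolved arms — are "unclassified".
    """
    if len(table) == 0:
        raise InvalidInputError("signature table is empty")
    if not arm.resolved:
        return SignatureCall(protein_id=protein_id, signature="unclassified",
                             mismatches=None, reason="arm-unresolved")
    best: SignatureDefinition | None = None
    best_d = None
    for entry in table:
        d = hamming(arm.arm_string, entry.arm_motif)
        if best_d is None or d < best_d:  # strict: earlier entries win ties
            best, best_d = entry, d
    if best is not None and best_d <= best.max_mismatch:
        return SignatureCall(protein_id=protein_id, signature=best.name,
                             mismatches=best_d)
    return SignatureCall(protein_id=protein_id, signature="unclassified",
                         mismatches=best_d, reason="no-motif-within-tolerance")


@dataclass
class DomainQuery:
    """A calibrated reference sequence used as a local-search domain probe."""

    name: str
    seq: str
    cal: Calibration
    scoring: LocalScoring = field(default_factory=LocalScoring)


@dataclass
class FusionConfig:
    evalue_cutoff: float = 1e-5
    overlap_tolerance: int = 10  # aa
    db_size: int = 1


def detect_fusion(seq: str, query_y: DomainQuery, query_z: DomainQuery,
                  cfg: FusionConfig | None = None,
                  protein_id: str = "") -> FusionCall:
    """Call a SoxYZ fusion: both domains significant, Y preceding Z,
    envelope overlap within tolerance."""
    cfg = cfg or FusionConfig()
    hy = local_search(query_y.seq, seq, query_y.scoring, query_y.cal, cfg.db_size)
    hz = local_search(query_z.seq, seq, query_z.scoring, query_z.cal, cfg.db_size)
    y_bounds = (hy.target_start, hy.target_end)
    z_bounds = (hz.target_start, hz.target_end)
    fused = (hy.e_value <= cfg.evalue_cutoff
             and hz.e_value <= cfg.evalue_cutoff
             and y_bounds[0] < z_bounds[0]
             and y_bounds[1] <= z_bounds[0] + cfg.overlap_tolerance)
    return FusionCall(protein_id=protein_id, fused=fused,
                      y_bounds=y_bounds, z_bounds=z_bounds,
                      y_evalue=hy.e_value, z_evalue=hz.e_value)


def global_identity(a: str, b: str,
                    scoring: LocalScoring | None = None) -> IdentityResult:
    """Percent identity over the terminal-gap-trimmed global alignment
    (Needleman-Wunsch, BLOSUM62, gap 11/1)."""
    if not a or not b:
        raise InvalidParameterError("sequences must be non-empty")
    from .search import _make_aligner
    scoring = scoring or LocalScoring()
    aligner = _make_aligner(scoring, "global")
    # canonicalize the pair order: co-optimal alignment choice would
    # otherwise make identity depend on argument order
    if b < a:
        a, b = b, a
    aln = next(iter(aligner.align(a, b)))
    ga, gb = str(aln[0]), str(aln[1])
    # trim terminal gap columns
    start = 0
    end = len(ga)
    while start < end and (ga[start] == "-" or gb[start] == "-"):
        start += 1
    while end > start and (ga[end - 1] == "-" or gb[end - 1] == "-"):
        end -= 1
    length = end - start
    if length == 0:
        return IdentityResult(identity=0.0, alignment_length=0, matches=0)
    matches = sum(1 for i in range(start, end) if ga[i] == gb[i] and ga[i] != "-")
    return IdentityResult(identity=100.0 * matches / length,
                          alignment_length=length, matches=matches)
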