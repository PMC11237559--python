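"""Profile search with empirical e-value calibration, plus local search.

E-value statistics are empirical: a Gumbel (extreme-value) distribution is
fitted by the method of moments to alignment scores of composition-matched
decoy sequences, and the e-value of a hit at score *s* against a database
of *N* sequences is ``N * P(S >= s)`` under that null.  Quality filtering
and deduplication follow the published screening rules for putative SoxY
sequences: minimum length 140 aa (inclusive), the "GGC" functional motif
required anywhere in the sequence, and exact-duplicate collapse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from . import _dp
from .errors import DegenerateCalibrationError, InvalidParameterError
from .profiles import Profile, align_to_profile, batch_scores

EULER_GAMMA = 0.5772156649015329


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    genome_id: str
    seq: str

    def __len__(self):
        return len(self.seq)


@dataclass
class SearchConfig:
    """Thresholds for homolog search and quality screening."""

    soxy_evalue_cutoff: float = 1e-5
    sulfur_evalue_cutoff: float = 1e-30
    sulfur_short_evalue_cutoff: float = 1e-6
    short_length_threshold: int = 120   # aa; panel entries under this use the short cutoff
    min_length: int = 140               # aa; shorter putative SoxY sequences are dropped
    required_motif: str = "GGC"

    def __post_init__(self):
        for f in ("soxy_evalue_cutoff", "sulfur_evalue_cutoff",
                  "sulfur_short_evalue_cutoff"):
            if getattr(self, f) <= 0:
                raise InvalidParameterError(f"{f} must be > 0")
        if self.min_length <= 0:
            raise InvalidParameterError("min_length must be > 0")


@dataclass
class Calibration:
    """Gumbel null fitted to decoy scores (location mu, scale lambda)."""

    mu: float
    lam: float
    n_decoys: int
    db_size_policy: str = "n_sequences"

    def __post_init__(self):
        if self.lam <= 0:
            raise InvalidParameterError("lambda must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Calibration":
        return cls(**d)


@dataclass
class HomologHit:
    protein_id: str
    genome_id: str
    score: float
    e_value: float
    env_start: int  # 0-based half-open envelope on the protein
    env_end: int
    length: int
    seq: str = field(repr=False)
    trace: np.ndarray | None = field(default=None, repr=False, compare=False)
    dedup_rep: str | None = None

    def __post_init__(self):
        if not (0 <= self.env_start < self.env_end <= self.length):
            raise InvalidParameterError("envelope out of bounds")
        if self.e_value < 0:
            raise InvalidParameterError("e-value must be >= 0")


def sample_decoys(lengths, n_decoys: int, seed: int,
                  background: np.ndarray | None = None) -> list[str]:
    """Draw i.i.d.-composition decoy sequences with lengths sampled from
    ``lengths`` (the empirical length distribution of the search database)."""
    rng = np.random.default_rng(seed)
    lengths = np.asarray(lengths, dtype=np.int64)
    if background is None:
        background = np.full(20, 0.05)
    picks = rng.choice(lengths, size=n_decoys, replace=True)
    alphabet = np.frombuffer(_dp.ALPHABET.encode(), dtype=np.uint8)
    residues = rng.choice(alphabet, size=int(picks.sum()), p=background)
    offsets = np.concatenate(([0], np.cumsum(picks)))
    return [residues[offsets[k]:offsets[k + 1]].tobytes().decode()
            for k in range(n_decoys)]


def fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """Method-of-moments Gumbel fit: lambda = pi/(sigma*sqrt(6)),
    mu = mean - gamma/lambda."""
    scores = np.asarray(scores, dtype=np.float64)
    sigma = scores.std(ddof=1)
    if sigma <= 0 or not np.isfinite(sigma):
        raise DegenerateCalibrationError("decoy scores have zero variance")
    lam = math.pi / (sigma * math.sqrt(6.0))
    mu = scores.mean() - EULER_GAMMA / lam
    return mu, lam


def calibrate(profile: Profile, decoy_lengths, n_decoys: int = 1000,
              seed: int = 0) -> Calibration:
    """Fit the Gumbel null for ``profile`` on random decoys."""
    if n_decoys < 1000:
        raise InvalidParameterError("calibration requires >= 1000 decoys")
    decoys = sample_decoys(decoy_lengths, n_decoys, seed, profile.background)
    scores = batch_scores(profile, decoys)
    mu, lam = fit_gumbel(scores)
    return Calibration(mu=mu, lam=lam, n_decoys=n_decoys)


def evalue(score: float, cal: Calibration, db_size: int) -> float:
    """Expected number of decoy hits at >= ``score`` in ``db_size`` sequences.

    ``e = db_size * (1 - exp(-exp(-lambda*(score - mu))))``.
    """
    if db_size < 1:
        raise InvalidParameterError("db_size must be >= 1")
    x = cal.lam * (score - cal.mu)
    if x > 700:
        p = math.exp(-x)  # tail approximation; exact survival underflows
    else:
        p = -math.expm1(-math.exp(-x))
    return db_size * p


def search_proteome(profile: Profile, proteome: list[ProteinRecord],
                    cal: Calibration, cfg: SearchConfig | None = None,
                    db_size: int | None = None) -> list[HomologHit]:
    """One best global profile hit per protein with e <= cutoff.

    Results are ordered by ascending e-value, ties by protein id.
    """
    cfg = cfg or SearchConfig()
    if not proteome:
        return []
    if db_size is None:
        db_size = len(proteome)
    scores = batch_scores(profile, [r.seq for r in proteome])
    hits = []
    for rec, score in zip(proteome, scores):
        e = evalue(float(score), cal, db_size)
        if e <= cfg.soxy_evalue_cutoff:
            s2, trace = align_to_profile(profile, rec.seq)
            aligned = trace[trace >= 0]
            if aligned.size == 0:
                continue
            hits.append(HomologHit(
                protein_id=rec.protein_id, genome_id=rec.genome_id,
                score=float(score), e_value=e,
                env_start=int(aligned.min()), env_end=int(aligned.max()) + 1,
                length=len(rec.seq), seq=rec.seq, trace=trace))
    hits.sort(key=lambda h: (h.e_value, h.protein_id))
    return hits


def quality_filter(hits: list[HomologHit],
                   cfg: SearchConfig | None = None) -> list[HomologHit]:
    """Retain hits with length >= min_length (140 aa inclusive), the
    required "GGC" motif anywhere in the sequence, and e <= cutoff."""
    cfg = cfg or SearchConfig()
    return [h for h in hits
            if h.length >= cfg.min_length
            and cfg.required_motif in h.seq
            and h.e_value <= cfg.soxy_evalue_cutoff]


def deduplicate(hits: list[HomologHit]):
    """Collapse exact full-sequence duplicates.

    The representative of each identical-sequence group is the
    lexicographically smallest protein id.  Returns ``(unique_hits,
    multiplicity)`` where multiplicity maps representative id ->
    sorted list of member ids.  Per-genome copy counting must use the
    pre-dedup hit list.
    """
    groups: dict[str, list[HomologHit]] = {}
    for h in hits:
        groups.setdefault(h.seq, []).append(h)
    unique: list[HomologHit] = []
    multiplicity: dict[str, list[str]] = {}
    for members in groups.values():
        rep = min(members, key=lambda h: h.protein_id)
        rep.dedup_rep = rep.protein_id
        multiplicity[rep.protein_id] = sorted(m.protein_id for m in members)
        unique.append(rep)
    unique.sort(key=lambda h: (h.e_value, h.protein_id))
    return unique, multiplicity


# ----------------------------------------------------------------------
# Local (Smith-Waterman-style) search via Bio.Align, BLOSUM62 11/1
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class LocalScoring:
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0


@dataclass
class LocalHit:
    score: float
    e_value: float | None
    query_start: int
    query_end: int
    target_start: int
    target_end: int


def _make_aligner(scoring: LocalScoring, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def local_search(query: str, target: str, scoring: LocalScoring | None = None,
                 cal: Calibration | None = None, db_size: int = 1) -> LocalHit:
    """Optimal local alignment of ``query`` vs ``target`` (BLOSUM62, affine
    gaps); e-value from a decoy calibration when one is supplied."""
    if not query or not target:
        raise InvalidParameterError("query and target must be non-empty")
    scoring = scoring or LocalScoring()
    aligner = _make_aligner(scoring, "local")
    aln = next(iter(aligner.align(query, target)))
    qb, tb = aln.aligned
    e = evalue(aln.score, cal, db_size) if cal is not None else None
    return LocalHit(score=float(aln.score), e_value=e,
                    query_start=int(qb[0][0]), query_end=int(qb[-1][1]),
                    target_start=int(tb[0][0]), target_end=int(tb[-1][1]))


def local_scores(query: str, targets: list[str],
                 scoring: LocalScoring | None = None) -> np.ndarray:
    """Score-only local alignment of one query against many targets."""
    scoring = scoring or LocalScoring()
    aligner = _make_aligner(scoring, "local")
    return np.array([aligner.score(query, t) for t in targets])


def calibrate_local(query: str, decoy_lengths, n_decoys: int = 1000,
                    seed: int = 0,
                    scoring: LocalScoring | None = None) -> Calibration:
    """Gumbel null for local search with ``query`` against random decoys."""
    if n_decoys < 1000:
        raise InvalidParameterError("calibration requires >= 1000 decoys")
    decoys = sample_decoys(decoy_lengths, n_decoys, seed)
    scores = local_scores(query, decoys, scoring)
    mu, lam = fit_gumbel(scores)
    return Calibration(mu=mu, lam=lam, n_decoys=n_decoys)
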