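"""Position-specific scoring profiles for the SoxY / SoxZ domains.

A :class:`Profile` is a PSSM over the 20 amino acids, in bits, with an
anchor column marking the conserved sulfur-binding cysteine.  Profiles are
built from an ungapped-or-gapped seed alignment; columns with a majority of
gaps are dropped.  Alignment of a sequence to a profile is a global
affine-gap dynamic programme (see :mod:`soxyprof._dp`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import _dp
from .errors import InvalidInputError, InvalidParameterError

GAP_CHARS = frozenset("-.")

#: default gap penalties for profile alignment, in bits
DEFAULT_GAP_OPEN = 4.0
DEFAULT_GAP_EXTEND = 0.25

PROFILE_FORMAT_VERSION = 1


@dataclass
class Profile:
    """Log-odds scoring profile with a conserved-cysteine anchor column."""

    name: str
    emissions: np.ndarray  # (m, 20) bits
    background: np.ndarray  # (20,)
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND
    cys_anchor: int = -1
    _padded: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.emissions = np.asarray(self.emissions, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        m = self.emissions.shape[0]
        if self.emissions.shape != (m, 20):
            raise InvalidInputError("emissions must be (m, 20)")
        expected = self.emissions @ self.background
        if np.any(expected > 1e-9):
            raise InvalidInputError(
                "background-weighted expected log-odds must be <= 0 per column")
        if not (-1 <= self.cys_anchor < m):
            raise InvalidParameterError(f"cys_anchor {self.cys_anchor} outside [0, {m})")
        self._padded = _dp.pad_emissions(self.emissions)

    @property
    def match_columns(self) -> int:
        return self.emissions.shape[0]

    @property
    def consensus(self) -> str:
        """Highest-scoring residue per column."""
        return "".join(_dp.ALPHABET[i] for i in self.emissions.argmax(axis=1))

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "format_version": PROFILE_FORMAT_VERSION,
            "name": self.name,
            "alphabet": _dp.ALPHABET,
            "emissions": self.emissions.tolist(),
            "background": self.background.tolist(),
            "gap_open": self.gap_open,
            "gap_extend": self.gap_extend,
            "cys_anchor": self.cys_anchor,
        })

    @classmethod
    def from_json(cls, text: str) -> "Profile":
        d = json.loads(text)
        if d.get("format_version") != PROFILE_FORMAT_VERSION:
            raise InvalidInputError("unsupported profile format version")
        return cls(name=d["name"], emissions=np.array(d["emissions"]),
                   background=np.array(d["background"]), gap_open=d["gap_open"],
                   gap_extend=d["gap_extend"], cys_anchor=d["cys_anchor"])


def build_profile(msa: list[str], pseudocount: float = 1.0,
                  background: np.ndarray | None = None,
                  cys_position: int | None = None, cys_row: int = 0,
                  name: str = "profile",
                  min_nongap_fraction: float = 0.5) -> Profile:
    """Build a PSSM from an aligned set of protein sequences.

    Per retained column the emission score for residue *a* is::

        log2( (count_a + pseudocount * bg_a) / (n_nongap + pseudocount) / bg_a )

    Columns with non-gap fraction below ``min_nongap_fraction`` are dropped.
    ``cys_position`` (1-based, in the ungapped ``cys_row`` sequence) marks the
    conserved sulfur-binding cysteine; it is mapped through the alignment to
    the retained-column index stored as ``cys_anchor``.
    """
    if len(msa) < 2:
        raise InvalidInputError("profile requires at least 2 aligned sequences")
    width = len(msa[0])
    if width == 0 or any(len(row) != width for row in msa):
        raise InvalidInputError("alignment rows must be non-empty and equal length")
    if background is None:
        background = np.full(20, 0.05)
    background = np.asarray(background, dtype=np.float64)

    rows = [_encode_row(r) for r in msa]
    mat = np.stack(rows)  # (n, width); gap = -1
    nongap = mat >= 0
    keep = nongap.mean(axis=0) >= min_nongap_fraction
    if not keep.any():
        raise InvalidInputError("no columns retained")

    kept_cols = np.flatnonzero(keep)
    m = kept_cols.size
    em = np.empty((m, 20))
    for out_j, j in enumerate(kept_cols):
        col = mat[:, j]
        col = col[col >= 0]
        counts = np.bincount(col, minlength=20).astype(np.float64)
        n = counts.sum()
        freq = (counts + pseudocount * background) / (n + pseudocount)
        em[out_j] = np.log2(freq / background)

    anchor = -1
    if cys_position is not None:
        col = _ungapped_to_column(msa[cys_row], cys_position)
        if not keep[col]:
            raise InvalidInputError("cys anchor column was dropped by gap filtering")
        anchor = int(np.searchsorted(kept_cols, col))
    return Profile(name=name, emissions=em, background=background,
                   cys_anchor=anchor)


def align_to_profile(profile: Profile, seq: str) -> tuple[float, np.ndarray]:
    """Global affine-gap alignment of ``seq`` to the profile columns.

    Returns ``(score_bits, trace)``; ``trace[j]`` is the residue index
    aligned to column ``j`` or ``-1`` for a deletion.
    """
    if len(seq) < 1:
        raise InvalidParameterError("sequence must be non-empty")
    idx = _dp.encode(seq)
    return _dp.global_align(profile._padded, idx, profile.gap_open,
                            profile.gap_extend)


def score_to_profile(profile: Profile, seq: str) -> float:
    """Score-only variant of :func:`align_to_profile` (no traceback)."""
    idx = _dp.encode(seq)
    return float(_dp.global_score(profile._padded, idx, profile.gap_open,
                                  profile.gap_extend))


def batch_scores(profile: Profile, seqs: list[str]) -> np.ndarray:
    """Global alignment scores of many sequences against one profile."""
    if not seqs:
        return np.empty(0)
    concat = np.concatenate([_dp.encode(s) for s in seqs])
    offsets = np.zeros(len(seqs) + 1, dtype=np.int64)
    np.cumsum([len(s) for s in seqs], out=offsets[1:])
    return _dp.batch_global_scores(profile._padded, concat, offsets,
                                   profile.gap_open, profile.gap_extend)


def _encode_row(row: str) -> np.ndarray:
    return np.array([-1 if c in GAP_CHARS else _dp.AA_INDEX.get(c, -1)
                     for c in row], dtype=np.int64)


def _ungapped_to_column(row: str, position_1based: int) -> int:
    """Map a 1-based ungapped position in ``row`` to its alignment column."""
    count = 0
    for j, c in enumerate(row):
        if c not in GAP_CHARS:
            count += 1
            if count == position_1based:
                return j
    raise InvalidParameterError(f"position {position_1based} beyond ungapped length")
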