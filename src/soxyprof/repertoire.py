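"""Per-genome soxY repertoires, sulfur-gene presence/absence, and the
repertoire-ecology association.

Copy numbers count distinct loci per genome before cross-cohort
deduplication (deduplication serves tree building, not repertoires).
Sulfur-gene presence follows the published annotation thresholds: best
local-search e-value <= 1e-30, relaxed to 1e-6 for reference proteins
under 120 aa.  The association between divergent-signature presence and
environment is an explicit addition formalising the qualitative
ecology pattern: a chi-square statistic with a label-permutation p-value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (IncompleteInputError, InvalidInputError,
                     InvalidParameterError, UndefinedAssociationError)
from .search import (Calibration, LocalScoring, SearchConfig, calibrate_local,
                     evalue, local_scores)
from .synthetic import DIVERGENT_SIGNATURES, PanelEntry

SIGNATURE_ORDER = ["S1a", "S1b", "S1c", "S2", "S3", "S4"]


@dataclass
class GenomeRepertoire:
    genome_id: str
    total: int
    per_signature: dict[str, int]
    unclassified: int
    fusion_count: int

    def __post_init__(self):
        if self.total != sum(self.per_signature.values()) + self.unclassified:
            raise InvalidInputError("total must equal signature + unclassified counts")
        if any(v < 0 for v in self.per_signature.values()):
            raise InvalidInputError("counts must be non-negative")


def soxy_repertoire(hits, calls: dict, genome_id: str) -> GenomeRepertoire:
    """Count a genome's soxY loci by signature from quality-filtered,
    pre-dedup hits; ``calls`` maps protein_id -> SignatureCall."""
    mine = [h for h in hits if h.genome_id == genome_id]
    per_sig = {s: 0 for s in SIGNATURE_ORDER}
    unclassified = 0
    fusions = 0
    for h in mine:
        call = calls.get(h.protein_id)
        if call is None:
            raise IncompleteInputError(f"no signature call for {h.protein_id}")
        if call.signature in per_sig:
            per_sig[call.signature] += 1
        else:
            unclassified += 1
        if call.fused:
            fusions += 1
    return GenomeRepertoire(genome_id=genome_id, total=len(mine),
                            per_signature=per_sig, unclassified=unclassified,
                            fusion_count=fusions)


@dataclass
class PresenceRow:
    genome_id: str
    presence: dict[str, bool]
    best_evalue: dict[str, float]


def sulfur_cutoff(entry: PanelEntry, cfg: SearchConfig) -> float:
    """Threshold dispatch: the relaxed cutoff applies to reference proteins
    strictly under the short-length threshold (120 aa)."""
    if entry.length < cfg.short_length_threshold:
        return cfg.sulfur_short_evalue_cutoff
    return cfg.sulfur_evalue_cutoff


def sulfur_presence(proteome, panel: list[PanelEntry],
                    cfg: SearchConfig | None = None,
                    calibrations: dict[str, Calibration] | None = None,
                    genome_id: str | None = None,
                    scoring: LocalScoring | None = None,
                    seed: int = 0) -> PresenceRow:
    """Presence/absence of each panel gene in a proteome by best local
    alignment e-value against the per-query decoy calibration."""
    if not panel:
        raise InvalidInputError("empty sulfur panel")
    cfg = cfg or SearchConfig()
    scoring = scoring or LocalScoring()
    if genome_id is None:
        genome_id = proteome[0].genome_id if proteome else "NA"
    targets = [r.seq for r in proteome]
    if calibrations is None:
        lengths = [len(t) for t in targets] or [300]
        calibrations = {e.name: calibrate_local(e.seq, lengths, 1000, seed,
                                                scoring) for e in panel}
    presence, best_e = {}, {}
    db = max(1, len(targets))
    for entry in panel:
        if not targets:
            presence[entry.name] = False
            best_e[entry.name] = float("inf")
            continue
        scores = local_scores(entry.seq, targets, scoring)
        e = evalue(float(scores.max()), calibrations[entry.name], db)
        presence[entry.name] = e <= sulfur_cutoff(entry, cfg)
        best_e[entry.name] = e
    return PresenceRow(genome_id=genome_id, presence=presence, best_evalue=best_e)


def cohort_matrix(repertoires: list[GenomeRepertoire],
                  presence_rows: list[PresenceRow]) -> pd.DataFrame:
    """One row per genome: soxY copy number first, then per-signature
    counts, fusion count, then sulfur-gene presence flags."""
    rep_ids = {r.genome_id for r in repertoires}
    pres_ids = {p.genome_id for p in presence_rows}
    if rep_ids != pres_ids:
        raise InvalidInputError("repertoires and presence rows cover "
                                "different genome sets")
    pres_by_id = {p.genome_id: p for p in presence_rows}
    rows = []
    for r in sorted(repertoires, key=lambda r: r.genome_id):
        row = {"genome_id": r.genome_id, "soxY_total": r.total}
        for s in SIGNATURE_ORDER:
            row[s] = r.per_signature.get(s, 0)
        row["unclassified"] = r.unclassified
        row["fusions"] = r.fusion_count
        for name, flag in pres_by_id[r.genome_id].presence.items():
            row[name] = int(flag)
        rows.append(row)
    return pd.DataFrame(rows).set_index("genome_id")


def _chi2_from_counts(c1: np.ndarray, totals: np.ndarray,
                      n1: float) -> np.ndarray:
    """Chi-square of 2 x k tables given top-row counts (vectorized over
    leading axes)."""
    n = totals.sum()
    c0 = totals - c1
    e1 = totals * (n1 / n)
    e0 = totals * ((n - n1) / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(e1 > 0, (c1 - e1) ** 2 / e1, 0.0)
        t0 = np.where(e0 > 0, (c0 - e0) ** 2 / e0, 0.0)
    return (t1 + t0).sum(axis=-1)


@dataclass
class EcologyAssociation:
    table: pd.DataFrame
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    note: str = ("permutation chi-square association; an addition of this "
                 "pipeline, not part of the original study design")

    def to_json(self) -> str:
        return json.dumps({
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "table": {str(k): {str(c): int(v) for c, v in row.items()}
                      for k, row in self.table.to_dict(orient="index").items()},
            "note": self.note,
        }, indent=2)


def ecology_crosstab(matrix: pd.DataFrame, metadata: pd.DataFrame,
                     n_permutations: int = 999, seed: int = 0,
                     environment_column: str = "environment") -> EcologyAssociation:
    """Cross-tabulate divergent-signature presence (any of S1c/S2/S3/S4)
    against environment and attach a label-permutation chi-square p-value
    with +1 smoothing: p = (1 + #{perm >= observed}) / (n_permutations + 1)."""
    if n_permutations < 99:
        raise InvalidParameterError("n_permutations must be >= 99")
    meta = metadata.set_index("genome_id")
    missing = set(matrix.index) - set(meta.index)
    if missing:
        raise InvalidInputError(f"metadata missing genomes: {sorted(missing)[:3]}")
    env = meta.loc[matrix.index, environment_column].to_numpy()
    divergent = (matrix[sorted(DIVERGENT_SIGNATURES)].sum(axis=1) > 0).to_numpy()
    levels, env_codes = np.unique(env, return_inverse=True)
    k = levels.size
    if k < 2:
        raise UndefinedAssociationError("need >= 2 environment labels")
    onehot = np.eye(k)[env_codes]  # (n, k)
    totals = onehot.sum(axis=0)
    x = divergent.astype(float)
    obs_c1 = x @ onehot
    obs = float(_chi2_from_counts(obs_c1, totals, x.sum()))
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(x, (n_permutations, 1)), axis=1)
    perm_c1 = perms @ onehot
    perm_stats = _chi2_from_counts(perm_c1, totals, x.sum())
    p = (1 + int(np.sum(perm_stats >= obs - 1e-12))) / (n_permutations + 1)
    table = pd.crosstab(pd.Series(divergent, index=matrix.index,
                                  name="divergent_signature"),
                        pd.Series(env, index=matrix.index, name="environment"))
    return EcologyAssociation(table=table, statistic=obs, p_value=p,
                              n_permutations=n_permutations, seed=seed)
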