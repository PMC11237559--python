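"""End-to-end orchestration: simulate -> search -> classify -> tree ->
profile -> neighborhood -> report.

Every stage is a thin wrapper over the library modules; the pipeline only
wires them together, writes the tab-separated outputs and records a
run manifest (config echo, seed, versions, output checksums) so identical
config+seed reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import SoxyprofError
from .neighborhood import (DEFAULT_NEIGHBORHOOD_K, DEFAULT_OPERON_MAX_GAP,
                           SOX_OPERON_GENES, categorize, detect_operon,
                           extract_neighborhood, map_hits_to_genes, read_gff3)
from .phylo import (assign_clades, bootstrap_support, neighbor_joining,
                    pairwise_distance, stack_alignments, write_newick)
from .profiles import align_to_profile, build_profile
from .repertoire import (SIGNATURE_ORDER, cohort_matrix, ecology_crosstab,
                         soxy_repertoire, sulfur_presence)
from .search import (ProteinRecord, SearchConfig, calibrate, calibrate_local,
                     deduplicate, quality_filter, search_proteome)
from .signatures import (ArmDefinition, DomainQuery, FusionConfig, classify,
                         detect_fusion, extract_arm, global_identity)
from .synthetic import (CYS_POSITION_1BASED, build_reference_set,
                        default_sulfur_panel, generate_cohort, write_cohort)
from .errors import UndefinedAssociationError

STAGES = ("simulate", "search", "classify", "tree", "profile",
          "neighborhood", "report")

CLADE_EXEMPLARS = {1: ["REF_S1a", "REF_S1b", "REF_S1c"], 2: ["REF_S2"],
                   3: ["REF_S3"], 4: ["REF_S4"]}


class StageError(SoxyprofError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All pipeline thresholds; defaults follow the published values where
    one exists (e-value cutoffs 1e-5 / 1e-30 / 1e-6, 120 aa short-protein
    threshold, 140 aa minimum length, required "GGC" motif)."""

    seed: int = 0
    outdir: str | None = None
    simulate: bool = True
    n_genomes: int = 50
    proteins_faa: str | None = None
    genes_gff3: str | None = None
    metadata_tsv: str | None = None
    soxy_evalue_cutoff: float = 1e-5
    sulfur_evalue_cutoff: float = 1e-30
    sulfur_short_evalue_cutoff: float = 1e-6
    short_length_threshold: int = 120
    min_length: int = 140
    required_motif: str = "GGC"
    fusion_evalue_cutoff: float = 1e-5
    fusion_overlap_tolerance: int = 10
    arm_window: int = 6
    distance_model: str = "p"
    bootstrap_replicates: int = 100
    n_permutations: int = 999
    neighborhood_k: int = DEFAULT_NEIGHBORHOOD_K
    operon_max_gap: int = DEFAULT_OPERON_MAX_GAP
    calibration_decoys: int = 1000

    def search_config(self) -> SearchConfig:
        return SearchConfig(
            soxy_evalue_cutoff=self.soxy_evalue_cutoff,
            sulfur_evalue_cutoff=self.sulfur_evalue_cutoff,
            sulfur_short_evalue_cutoff=self.sulfur_short_evalue_cutoff,
            short_length_threshold=self.short_length_threshold,
            min_length=self.min_length,
            required_motif=self.required_motif)


def validate_config(config: RunConfig) -> list[str]:
    """Return all violations, each with the offending field and a hint at
    the published default."""
    errors = []
    for f, default in (("soxy_evalue_cutoff", 1e-5),
                       ("sulfur_evalue_cutoff", 1e-30),
                       ("sulfur_short_evalue_cutoff", 1e-6),
                       ("fusion_evalue_cutoff", 1e-5)):
        v = getattr(config, f)
        if not (isinstance(v, (int, float)) and v > 0):
            errors.append(f"{f}: must be > 0 (published default {default})")
    if config.min_length <= 0:
        errors.append("min_length: must be > 0 (published default 140 aa)")
    if config.short_length_threshold <= 0:
        errors.append("short_length_threshold: must be > 0 (published default 120 aa)")
    if not config.required_motif:
        errors.append('required_motif: must be non-empty (published default "GGC")')
    if config.arm_window < 6:
        errors.append("arm_window: must be >= 6")
    if config.distance_model not in ("p", "poisson"):
        errors.append('distance_model: must be "p" or "poisson"')
    if config.bootstrap_replicates < 1:
        errors.append("bootstrap_replicates: must be >= 1")
    if config.n_permutations < 99:
        errors.append("n_permutations: must be >= 99")
    if config.neighborhood_k < 1:
        errors.append("neighborhood_k: must be >= 1")
    if config.operon_max_gap <= 0:
        errors.append("operon_max_gap: must be > 0 (default 200 bp)")
    if config.calibration_decoys < 1000:
        errors.append("calibration_decoys: must be >= 1000")
    if config.simulate:
        if config.n_genomes < 1:
            errors.append("n_genomes: must be >= 1 when simulating")
    else:
        for f in ("proteins_faa", "genes_gff3", "metadata_tsv"):
            p = getattr(config, f)
            if p is None:
                errors.append(f"{f}: required when simulate is false")
            elif not Path(p).exists():
                errors.append(f"{f}: file not found: {p}")
    return errors


def load_config(path: str | Path, **overrides) -> RunConfig:
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise SoxyprofError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


@dataclass
class RunResult:
    config: RunConfig
    genomes: list = field(default_factory=list)
    metadata: pd.DataFrame | None = None
    truth: pd.DataFrame | None = None
    proteome: list = field(default_factory=list)
    gene_models: list = field(default_factory=list)
    refs: object = None
    profile: object = None
    calibration: object = None
    hits: list = field(default_factory=list)
    filtered: list = field(default_factory=list)
    dedup: list = field(default_factory=list)
    multiplicity: dict = field(default_factory=dict)
    calls: dict = field(default_factory=dict)
    fusion_calls: dict = field(default_factory=dict)
    stacked: object = None
    distances: object = None
    tree: object = None
    bootstrap: object = None
    clades: object = None
    repertoires: list = field(default_factory=list)
    presence: list = field(default_factory=list)
    matrix: pd.DataFrame | None = None
    association: object = None
    neighborhoods: dict = field(default_factory=dict)
    operons: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _read_fasta(path) -> list[ProteinRecord]:
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        genome_id = pid.rsplit("_gene", 1)[0] if "_gene" in pid else "genome"
        records.append(ProteinRecord(protein_id=pid, genome_id=genome_id,
                                     seq=str(rec.seq)))
    return records


def run_pipeline(config: RunConfig, upto: str = "report") -> RunResult:
    """Execute the pipeline through stage ``upto`` (inclusive), writing each
    executed stage's outputs under ``config.outdir`` when set."""
    errors = validate_config(config)
    if errors:
        raise SoxyprofError("invalid config: " + "; ".join(errors))
    if upto not in STAGES:
        raise SoxyprofError(f"unknown stage {upto!r}")
    last = STAGES.index(upto)
    out = Path(config.outdir) if config.outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    res = RunResult(config=config)
    seeds = np.random.default_rng(config.seed).integers(2 ** 31, size=16)
    cfg = config.search_config()

    # ---- simulate / ingest ------------------------------------------
    try:
        if config.simulate:
            genomes, metadata, truth = generate_cohort(
                config.n_genomes, seed=config.seed)
            res.genomes = genomes
            res.metadata = metadata
            res.truth = truth
            res.proteome = [r for g in genomes for r in g.proteins]
            res.gene_models = [gm for g in genomes for gm in g.genes]
            if out:
                write_cohort(genomes, metadata, truth, out / "cohort",
                             seed=config.seed)
        else:
            res.proteome = _read_fasta(config.proteins_faa)
            res.gene_models = read_gff3(config.genes_gff3)
            res.metadata = pd.read_csv(config.metadata_tsv, sep="\t")
            res.truth = None
    except SoxyprofError:
        raise
    except Exception as exc:  # pragma: no cover
        raise StageError("simulate", exc) from exc
    if last == 0:
        return res

    # ---- search ------------------------------------------------------
    try:
        res.refs = build_reference_set(config.arm_window)
        res.profile = build_profile(
            res.refs.seed_alignment, pseudocount=1.0,
            cys_position=CYS_POSITION_1BASED, name="SoxY")
        lengths = [len(r.seq) for r in res.proteome] or [200]
        res.calibration = calibrate(res.profile, lengths,
                                    config.calibration_decoys,
                                    seed=int(seeds[0]))
        res.hits = search_proteome(res.profile, res.proteome,
                                   res.calibration, cfg)
        res.filtered = quality_filter(res.hits, cfg)
        res.dedup, res.multiplicity = deduplicate(res.filtered)
        if out:
            _write_hits(res, out / "hits.tsv")
    except SoxyprofError:
        raise
    except Exception as exc:  # pragma: no cover
        raise StageError("search", exc) from exc
    if last == 1:
        return res

    # ---- classify ----------------------------------------------------
    try:
        arm_def = ArmDefinition(anchor=res.profile.cys_anchor,
                                upstream_offset=config.arm_window - 1)
        decoy_lengths = [len(h.seq) for h in res.filtered] or [200]
        qy = DomainQuery("SoxY", res.refs.canonical_soxy,
                         calibrate_local(res.refs.canonical_soxy,
                                         decoy_lengths, 1000, int(seeds[1])))
        qz = DomainQuery("SoxZ", res.refs.canonical_soxz,
                         calibrate_local(res.refs.canonical_soxz,
                                         decoy_lengths, 1000, int(seeds[2])))
        fcfg = FusionConfig(evalue_cutoff=config.fusion_evalue_cutoff,
                            overlap_tolerance=config.fusion_overlap_tolerance)
        for h in res.filtered:
            arm = extract_arm(h.trace, h.seq, arm_def)
            call = classify(arm, res.refs.signatures, h.protein_id)
            fus = detect_fusion(h.seq, qy, qz, fcfg, h.protein_id)
            call.fused = fus.fused
            res.calls[h.protein_id] = call
            res.fusion_calls[h.protein_id] = fus
        if out:
            _write_calls(res, out / "calls.tsv")
    except SoxyprofError:
        raise
    except Exception as exc:  # pragma: no cover
        raise StageError("classify", exc) from exc
    if last == 2:
        return res

    # ---- tree --------------------------------------------------------
    try:
        entries = [(h.protein_id, h.seq, h.trace) for h in res.dedup]
        for name, seq in res.refs.signature_exemplars.items():
            _, trace = align_to_profile(res.profile, seq)
            entries.append((f"REF_{name}", seq, trace))
        res.stacked = stack_alignments(entries)
        res.distances = pairwise_distance(res.stacked, config.distance_model)
        res.tree = neighbor_joining(res.distances)
        res.bootstrap = bootstrap_support(res.stacked,
                                          config.bootstrap_replicates,
                                          seed=int(seeds[3]),
                                          model=config.distance_model)
        res.clades = assign_clades(res.distances, CLADE_EXEMPLARS, res.tree)
        if out:
            _write_tree(res, out)
    except SoxyprofError:
        raise
    except Exception as exc:  # pragma: no cover
        raise StageError("tree", exc) from exc
    if last == 3:
        return res

    # ---- profile (repertoires, presence, association) ---------------
    try:
        genome_ids = sorted(res.metadata["genome_id"].astype(str))
        panel = default_sulfur_panel()
        lengths = [len(r.seq) for r in res.proteome] or [300]
        calibrations = {e.name: calibrate_local(e.seq, lengths, 1000,
                                                int(seeds[4]))
                        for e in panel}
        by_genome: dict[str, list[ProteinRecord]] = {}
        for r in res.proteome:
            by_genome.setdefault(r.genome_id, []).append(r)
        for gid in genome_ids:
            res.repertoires.append(
                soxy_repertoire(res.filtered, res.calls, gid))
            res.presence.append(
                sulfur_presence(by_genome.get(gid, []), panel, cfg,
                                calibrations, genome_id=gid))
        res.matrix = cohort_matrix(res.repertoires, res.presence)
        try:
            res.association = ecology_crosstab(
                res.matrix, res.metadata, config.n_permutations,
                seed=int(seeds[5]))
        except UndefinedAssociationError:
            res.association = None
        if out:
            _write_profile(res, out)
    except SoxyprofError:
        raise
    except Exception as exc:  # pragma: no cover
        raise StageError("profile", exc) from exc
    if last == 4:
        return res

    # ---- neighborhood ------------------------------------------------
    try:
        loci, unmatched = map_hits_to_genes(res.filtered, res.gene_models)
        for h, gm in loci:
            nmap = categorize(extract_neighborhood(gm, res.gene_models,
                                                   config.neighborhood_k))
            res.neighborhoods[h.protein_id] = nmap
            res.operons[h.protein_id] = detect_operon(
                res.gene_models, gm, SOX_OPERON_GENES, config.operon_max_gap)
        if out:
            _write_neighborhoods(res, out)
    except SoxyprofError:
        raise
    except Exception as exc:  # pragma: no cover
        raise StageError("neighborhood", exc) from exc
    if last == 5:
        return res

    # ---- report ------------------------------------------------------
    try:
        res.manifest = _manifest(res, out)
        if out:
            (out / "run_manifest.json").write_text(
                json.dumps(res.manifest, indent=2, sort_keys=True))
    except Exception as exc:  # pragma: no cover
        raise StageError("report", exc) from exc
    return res


# ----------------------------------------------------------------------
# writers
# ----------------------------------------------------------------------

def _write_hits(res: RunResult, path: Path) -> None:
    filtered_ids = {h.protein_id for h in res.filtered}
    rep_of = {}
    for rep, members in res.multiplicity.items():
        for m in members:
            rep_of[m] = rep
    rows = [{
        "protein_id": h.protein_id, "genome_id": h.genome_id,
        "score_bits": round(h.score, 3), "evalue": f"{h.e_value:.3e}",
        "env_start": h.env_start, "env_end": h.env_end, "length": h.length,
        "passed_filters": int(h.protein_id in filtered_ids),
        "dedup_rep": rep_of.get(h.protein_id, ""),
    } for h in res.hits]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_calls(res: RunResult, path: Path) -> None:
    rows = []
    for h in res.filtered:
        call = res.calls[h.protein_id]
        fus = res.fusion_calls[h.protein_id]
        ident = global_identity(h.seq, res.refs.canonical_soxy)
        rows.append({
            "protein_id": h.protein_id, "genome_id": h.genome_id,
            "signature": call.signature,
            "mismatches": "" if call.mismatches is None else call.mismatches,
            "fused": int(call.fused),
            "y_start": fus.y_bounds[0], "y_end": fus.y_bounds[1],
            "z_start": fus.z_bounds[0], "z_end": fus.z_bounds[1],
            "identity_to_canonical": round(ident.identity, 1),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_tree(res: RunResult, out: Path) -> None:
    (out / "tree.nwk").write_text(write_newick(res.tree))
    ids = res.distances.ids
    pd.DataFrame(res.distances.data, index=ids, columns=ids).to_csv(
        out / "distances.tsv", sep="\t")
    pd.DataFrame(
        [{"sequence_id": sid, "clade": res.clades.assignments[sid]}
         for sid in ids]).to_csv(out / "clades.tsv", sep="\t", index=False)
    rows = [{"bipartition": "|".join(sorted(split)), "support": sup}
            for split, sup in sorted(res.bootstrap.supports.items(),
                                     key=lambda kv: (-kv[1], sorted(kv[0])))]
    pd.DataFrame(rows, columns=["bipartition", "support"]).to_csv(
        out / "supports.tsv", sep="\t", index=False)


def _write_profile(res: RunResult, out: Path) -> None:
    rows = []
    for r in res.repertoires:
        row = {"genome_id": r.genome_id, "soxY_total": r.total,
               "unclassified": r.unclassified, "fusions": r.fusion_count}
        for s in SIGNATURE_ORDER:
            row[s] = r.per_signature.get(s, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "repertoire.tsv", sep="\t", index=False)
    prows = []
    for p in res.presence:
        row = {"genome_id": p.genome_id}
        row.update({k: int(v) for k, v in p.presence.items()})
        prows.append(row)
    pd.DataFrame(prows).to_csv(out / "presence.tsv", sep="\t", index=False)
    res.matrix.to_csv(out / "cohort_matrix.tsv", sep="\t")
    if res.association is not None:
        (out / "association.json").write_text(res.association.to_json())
    else:
        (out / "association.json").write_text(json.dumps(
            {"p_value": None, "note": "undefined: single environment label"}))


def _write_neighborhoods(res: RunResult, out: Path) -> None:
    rows = []
    for focal_id, nmap in sorted(res.neighborhoods.items()):
        for pos, g in enumerate(nmap.genes):
            rows.append({
                "focal_id": focal_id, "position": pos,
                "gene_id": g.gene.gene_id, "contig": g.gene.contig,
                "start": g.gene.start + 1, "end": g.gene.end,
                "strand": g.gene.strand, "category": g.category,
                "is_focal": int(g.is_focal), "product": g.gene.product,
            })
    pd.DataFrame(rows).to_csv(out / "neighborhoods.tsv", sep="\t", index=False)
    orows = [{
        "focal_id": focal_id, "verdict": int(op.verdict),
        "strand": op.strand, "n_members": len(op.member_ids),
        "max_internal_gap": op.max_internal_gap,
        "members": ",".join(op.member_ids),
    } for focal_id, op in sorted(res.operons.items())]
    pd.DataFrame(orows).to_csv(out / "operons.tsv", sep="\t", index=False)


def _manifest(res: RunResult, out: Path | None) -> dict:
    checksums = {}
    if out:
        for p in sorted(out.rglob("*")):
            if p.is_file() and p.name != "run_manifest.json":
                checksums[str(p.relative_to(out))] = hashlib.sha256(
                    p.read_bytes()).hexdigest()
    counts = {
        "proteins": len(res.proteome),
        "gene_models": len(res.gene_models),
        "hits": len(res.hits),
        "filtered_hits": len(res.filtered),
        "dedup_hits": len(res.dedup),
        "signature_calls": len(res.calls),
        "genomes": 0 if res.metadata is None else len(res.metadata),
        "neighborhoods": len(res.neighborhoods),
    }
    return {"version": __version__, "seed": res.config.seed,
            "config": dataclasses.asdict(res.config),
            "counts": counts, "checksums": checksums,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__}
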