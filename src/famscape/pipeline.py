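"""End-to-end orchestration: simulate/scan → tree → introns → summaries.

A single config drives either a fully synthetic run (the bundled generator
plants ground truth for every stage) or a real-data run from user-supplied
files. Every artifact is a TSV/Newick/JSON file carrying a provenance
header (package version, root seed, config hash); all randomness flows from
the one root seed through named substreams, so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .candidate_link import correlate, select_candidates
from .expression import ExpressionMatrix, tissue_max_calls, uv_response, zscore_rows
from .gene_structure import (
    chromosome_summary,
    detect_events,
    extract_introns,
    intron_count_share,
    intron_count_table,
    parse_gene_models,
    project_intron,
)
from .motif import ProteinRecord, scan_proteome
from .phylogeny import MSA, assign_groups, neighbor_joining, pairwise_distance
from .simulate import (
    FamilySimSpec,
    PlantedEvent,
    default_design,
    simulate_expression,
    simulate_family,
    simulate_metabolites,
)

__all__ = ["PipelineConfig", "run_pipeline"]

_REAL_INPUTS = (
    "proteome", "genome", "gff3", "msa", "anchors",
    "expression", "metadata", "metabolites",
)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and seed for one pipeline run."""

    outdir: str
    seed: int = 1
    # synthetic mode (ignored when real-data paths are given)
    simulate: bool = True
    n_family_genes: int = 96
    n_decoy_proteins: int = 100
    n_events: int = 10
    intronless_fraction: float = 0.25
    planted_leaf_frac: float = 45 / 168
    planted_flower_frac: float = 54 / 168
    planted_uv_frac: float = 65 / 168
    n_compounds: int = 12
    n_linked: int = 8
    r_target: float = 0.99
    # real-data mode: paths (all required together)
    inputs: dict = field(default_factory=dict)
    # thresholds
    motif_fraction: float = 0.40
    merge_window: int = 0
    lfc_threshold: float = 1.0
    r_min: float = 0.0
    q_max: float = 0.05

    def __post_init__(self) -> None:
        if self.inputs:
            self.simulate = False
            missing = [k for k in _REAL_INPUTS if k not in self.inputs]
            if missing:
                raise ValueError(f"real-data mode missing inputs: {missing}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        payload = asdict(self)
        payload.pop("outdir")  # the run is defined by inputs, not destination
        return hashlib.sha1(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def _header(config: PipelineConfig) -> str:
    return (f"# famscape {__version__} | seed={config.seed} "
            f"| config={config.digest()}\n")


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the report dict (also written as JSON)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.digest(),
    }

    if config.simulate:
        spec = _default_family_spec(config)
        bundle = simulate_family(spec, seed=config.seed)
        paths = bundle.write(out / "inputs")
        proteome = [ProteinRecord(i, s) for i, s in bundle.proteins]
        motif = spec.motif
        msa = bundle.msa
        truth = bundle.truth
        anchors = _truth_anchors(truth)
        models = parse_gene_models(paths["models"], genome=paths["genome"])
    else:
        from .motif import read_proteome

        paths = {k: Path(v) for k, v in config.inputs.items()}
        proteome = read_proteome(paths["proteome"])
        motif = Path(config.inputs["motif"]).read_text().split()[0] \
            if "motif" in config.inputs else None
        if motif is None:
            from .simulate import PSPG_CONSENSUS as motif  # consensus default
        msa = MSA.from_fasta(paths["msa"])
        truth = None
        anchors = dict(
            pd.read_csv(paths["anchors"], sep="\t")
            .set_index("anchor_id")["group"]
        )
        models = parse_gene_models(paths["gff3"], genome=paths["genome"])

    # --- motif scan ---------------------------------------------------------
    hits = scan_proteome(proteome, motif, threshold=config.motif_fraction)
    hits_df = pd.DataFrame(
        [
            {"protein_id": h.protein_id, "raw_score": h.raw_score,
             "score_fraction": round(h.score_fraction, 4),
             "start": h.span[0], "end": h.span[1],
             "motif_coverage": round(h.motif_coverage, 4)}
            for h in hits
        ]
    )
    _write_tsv(hits_df, out / "motif_hits.tsv", config)
    family = [h.protein_id for h in hits if h.protein_id in set(msa.ids)]
    report["n_proteins_scanned"] = len(proteome)
    report["n_family_called"] = len(hits)

    # --- phylogeny and groups ----------------------------------------------
    fam_msa = msa.subset(sorted(family))
    tree = neighbor_joining(pairwise_distance(fam_msa))
    with open(out / "tree.nwk", "w") as fh:
        fh.write(_header(config))
        fh.write(tree.newick() + "\n")
    assignment = assign_groups(tree, {a: g for a, g in anchors.items()
                                      if a in set(fam_msa.ids)})
    groups = {**assignment.assignments, **assignment.anchors}
    assign_df = pd.DataFrame(
        sorted(groups.items()), columns=["gene_id", "group"]
    )
    assign_df["is_anchor"] = assign_df["gene_id"].isin(assignment.anchors)
    _write_tsv(assign_df, out / "group_assignments.tsv", config)
    group_counts = assign_df.groupby("group").size()
    _write_tsv(group_counts.rename("n_genes").reset_index(),
               out / "group_counts.tsv", config)
    report["group_counts"] = {k: int(v) for k, v in group_counts.items()}
    report["monophyly_violations"] = assignment.monophyly_violations

    # --- intron architecture -------------------------------------------------
    fam_models = [m for m in models if m.gene_id in groups and not m.partial]
    introns = []
    for model in fam_models:
        for rec in extract_introns(model):
            project_intron(rec, msa)
            introns.append(rec)
    introns_df = pd.DataFrame(
        [
            {"gene_id": r.gene_id, "ordinal": r.ordinal, "start": r.start,
             "end": r.end, "length": r.length, "cds_offset": r.cds_offset,
             "phase": r.phase, "residue_index": r.residue_index,
             "alignment_column": r.alignment_column}
            for r in introns
        ]
    )
    _write_tsv(introns_df, out / "introns.tsv", config)

    events = detect_events(introns, window=config.merge_window)
    events_df = pd.DataFrame(
        [
            {"event_id": e.event_id, "column_lo": e.column_lo,
             "column_hi": e.column_hi, "n_introns": e.n_members,
             "n_genes": e.n_genes, "dominant_phase": e.dominant_phase,
             "phase_counts": json.dumps(e.phase_counts, sort_keys=True),
             "flagged": e.flagged}
            for e in events
        ]
    )
    _write_tsv(events_df, out / "events.tsv", config)
    report["n_events"] = len(events)

    counts = {m.gene_id: m.n_introns for m in fam_models}
    table = intron_count_table(counts, groups)
    _write_tsv(table, out / "intron_count_table.tsv", config, index=True)
    report["intronless_percent"] = (
        intron_count_share(table, 0) if 0 in table.columns else 0
    )
    intron_bearing = sum(1 for n in counts.values() if n > 0)
    report["event_summaries"] = {
        e.event_id: {
            "n_genes": e.n_genes,
            "carrier_percent": e.carrier_share(intron_bearing)
            if intron_bearing else 0,
            "dominant_phase": e.dominant_phase,
            "dominant_phase_percent": e.dominant_phase_share(),
        }
        for e in events
    }

    chrom = chromosome_summary(fam_models, groups)
    _write_tsv(chrom, out / "chromosome_summary.tsv", config, index=True)
    report["chromosome_totals"] = {
        str(k): int(v) for k, v in chrom["Total"].items() if k != "Total"
    }

    # --- expression ----------------------------------------------------------
    if config.simulate:
        em, expr_truth = _simulate_expression_stage(config, family)
        _write_tsv(expr_truth, out / "truth_expression.tsv", config)
        uv_em = _simulate_uv_stage(config, family)
    else:
        values = pd.read_csv(paths["expression"], sep="\t", index_col=0)
        meta = pd.read_csv(paths["metadata"], sep="\t", index_col=0)
        em = ExpressionMatrix(values, meta)
        uv_em = em if "treatment" in meta.columns else None

    z, _flagged = zscore_rows(em)
    _write_tsv(z.round(4), out / "expression_zscores.tsv", config, index=True)
    tmax = tissue_max_calls(em)
    _write_tsv(tmax.calls, out / "tissue_max_calls.tsv", config)
    report["tissue_max_counts"] = tmax.counts
    report["tissue_max_percent"] = tmax.percentages

    if uv_em is not None:
        uv = uv_response(uv_em, lfc_threshold=config.lfc_threshold)
        _write_tsv(uv.round(4), out / "uv_calls.tsv", config)
        last_tp = uv["timepoint"].iloc[-1]
        induced = uv[(uv["timepoint"] == last_tp) & (uv["call"] == "induced")]
        report["uv_induced_at_last_timepoint"] = int(len(induced))

    # --- metabolite correlation ----------------------------------------------
    stage_cols = [g for g in em.group_order() if g not in ("leaf", "flower")]
    stage_means = em.group_means()[stage_cols]
    if config.simulate:
        # link genes sharing the S1-peaking stage pattern, so one compound
        # can correlate with all of them (the planted truth names them)
        s1_genes = sorted(expr_truth.loc[
            expr_truth["planted_group"] == "S1", "gene_id"
        ]) or sorted(family)
        linked = [
            (g, "glycoside-A", config.r_target)
            for g in s1_genes[: config.n_linked]
        ]
        metab, metab_truth = simulate_metabolites(
            stage_means, config.n_compounds, linked, seed=config.seed
        )
        _write_tsv(metab_truth, out / "truth_metabolites.tsv", config)
        target_compound = metab_truth["compound_id"].iloc[0]
    else:
        metab = pd.read_csv(paths["metabolites"], sep="\t", index_col=0)
        target_compound = metab.index[0]
    corr = correlate(stage_means, metab)
    _write_tsv(corr.results.round(6), out / "correlations.tsv", config)
    candidates = select_candidates(
        corr, target_compound, r_min=config.r_min, q_max=config.q_max
    )
    _write_tsv(candidates.round(6), out / "candidates.tsv", config)
    report["n_candidates"] = int(len(candidates))
    report["candidate_genes"] = candidates["gene_id"].tolist()

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _default_family_spec(config: PipelineConfig) -> FamilySimSpec:
    # events every 12 columns starting at column 60, all groups carry
    events = tuple(
        PlantedEvent(column=60 + 12 * k, phase=(1, 0, 2)[k % 3])
        for k in range(config.n_events)
    )
    return FamilySimSpec(
        n_family_genes=config.n_family_genes,
        n_decoy_proteins=config.n_decoy_proteins,
        planted_events=events,
        intronless_fraction=config.intronless_fraction,
    )


def _truth_anchors(truth) -> dict[str, str]:
    """First member of each planted group serves as its labelled anchor."""
    anchors: dict[str, str] = {}
    for gid in sorted(truth.genes):
        group = truth.genes[gid].group
        if group not in anchors.values():
            anchors[gid] = group
    return anchors


def _planted_map(config: PipelineConfig, family: list[str]) -> dict[str, str]:
    genes = sorted(family)
    planted: dict[str, str] = {}
    fruit = ["S1", "S2", "S3", "S4", "S4+3d", "S4+6d"]
    n = len(genes)
    n_leaf = int(round(config.planted_leaf_frac * n))
    n_flower = int(round(config.planted_flower_frac * n))
    k = 0
    for _ in range(min(n_leaf, n)):
        planted[genes[k]] = "leaf"
        k += 1
    for _ in range(min(n_flower, n - k)):
        planted[genes[k]] = "flower"
        k += 1
    for j, g in enumerate(genes[k:]):
        planted[g] = fruit[j % len(fruit)]
    return planted


def _simulate_expression_stage(config: PipelineConfig, family: list[str]):
    design = default_design()
    return simulate_expression(
        sorted(family), design, _planted_map(config, family),
        seed=config.seed,
    )


def _simulate_uv_stage(config: PipelineConfig, family: list[str]):
    """Paired treated/control matrix with genes planted induced at 48 h."""
    genes = sorted(family)
    design = pd.DataFrame(
        [
            {"sample": f"{tp}_{tr}_r{r + 1}", "group": f"{tp}_{tr}",
             "treatment": tr, "timepoint": tp}
            for tp in ("6h", "48h")
            for tr in ("control", "treated")
            for r in range(3)
        ]
    )
    n_uv = int(round(config.planted_uv_frac * len(genes)))
    planted = {g: "48h_treated" for g in genes[:n_uv]}
    em, _ = simulate_expression(
        genes, design, planted, effect_size=8.0, seed=config.seed + 1
    )
    return em
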