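"""Synthetic gene-family generator with machine-readable planted truth.

Emulates a duplicated plant gene family (UDP-glycosyltransferase-like):
every family protein carries a diverged copy of a 44-residue C-terminal
consensus motif, genes are laid out on a small multi-chromosome genome on
both strands, and intron insertion events are planted at chosen alignment
columns and phases so that downstream extraction, projection and event
detection can be scored against exact ground truth. Companion generators
produce expression matrices with planted tissue-maximal genes and metabolite
profiles correlated with chosen genes.

All randomness flows from a single seed through named substreams, so a fixed
seed fixes every emitted byte.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from ._util import rng_for
from .expression import ExpressionMatrix
from .gene_structure import GeneModel
from .phylogeny import MSA

__all__ = [
    "PSPG_CONSENSUS",
    "PlantedEvent",
    "FamilySimSpec",
    "FamilyTruth",
    "FamilyBundle",
    "simulate_family",
    "simulate_expression",
    "simulate_metabolites",
    "default_design",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# 44-residue consensus of the plant secondary product glycosyltransferase box
PSPG_CONSENSUS = "WAPQVEVLAHPAVGCFVTHCGWNSTLESIAAGVPMITWPLFAEQ"

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AA2CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(_TABLE.forward_table.items()):
    _AA2CODONS.setdefault(_aa, []).append(_codon)
_STOPS = sorted(_TABLE.stop_codons)

SPACER_NT = 500  # fixed intergenic spacer


@dataclass(frozen=True)
class PlantedEvent:
    """A family-wide intron insertion: alignment column, phase, carriers.

    ``carrier_groups`` of None means every group carries the intron.
    """

    column: int  # 1-based alignment column of the anchor residue
    phase: int
    carrier_groups: tuple[str, ...] | None = None


@dataclass
class FamilySimSpec:
    """Structural parameters of the synthetic family.

    Defaults emulate a mid-sized plant UGT-like family: 16 groups (A–P),
    480-residue proteins with the motif ending 30 residues from the C
    terminus, eight chromosomes, intron lengths drawn uniformly from
    [80, 2000] nt, and modest per-branch divergence.
    """

    n_family_genes: int = 96
    n_decoy_proteins: int = 100
    group_labels: tuple[str, ...] = tuple("ABCDEFGHIJKLMNOP")
    protein_length: int = 480
    motif: str = PSPG_CONSENSUS
    planted_events: tuple[PlantedEvent, ...] = ()
    intronless_fraction: float = 0.0
    n_chromosomes: int = 8
    intron_length_range: tuple[int, int] = (80, 2000)
    substitution_rate: float = 0.05
    indel_mode: bool = False
    cluster_by_group: bool = False

    def __post_init__(self) -> None:
        if len(self.motif) != 44:
            raise ValueError(f"motif must be 44 residues, got {len(self.motif)}")
        if not 0.0 <= self.intronless_fraction <= 1.0:
            raise ValueError("intronless_fraction must lie in [0, 1]")
        for name in ("n_family_genes", "n_decoy_proteins", "n_chromosomes",
                     "protein_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        known = set(self.group_labels)
        cols = sorted(e.column for e in self.planted_events)
        for a, b in zip(cols, cols[1:]):
            if b - a < 3:
                raise ValueError(
                    f"planted event columns {a} and {b} closer than 3 columns"
                )
        if len(cols) != len(set(cols)):
            raise ValueError("planted event columns must be distinct")
        for ev in self.planted_events:
            if ev.column > self.protein_length:
                raise ValueError(
                    f"event column {ev.column} beyond protein length "
                    f"{self.protein_length}"
                )
            if ev.column < 2:
                raise ValueError("event column must be >= 2 (offset must be > 0)")
            if ev.phase not in (0, 1, 2):
                raise ValueError(f"invalid phase {ev.phase}")
            if ev.carrier_groups is not None:
                bad = set(ev.carrier_groups) - known
                if bad:
                    raise ValueError(f"unknown carrier groups: {sorted(bad)}")
        lo, hi = self.intron_length_range
        if lo < 4 or hi < lo:
            raise ValueError("invalid intron_length_range")


@dataclass
class IntronTruth:
    event_id: str
    column: int
    phase: int
    cds_offset: int
    residue_index: int


@dataclass
class GeneTruth:
    gene_id: str
    group: str
    chromosome: str
    strand: str
    introns: list[IntronTruth] = field(default_factory=list)


@dataclass
class FamilyTruth:
    """Planted ground truth: per-gene placements and per-event carrier sets."""

    genes: dict[str, GeneTruth]
    events: dict[str, dict]  # event_id -> {column, phase, carriers}
    tree_newick: str

    def intron_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": g.gene_id,
                "group": g.group,
                "event_id": it.event_id,
                "column": it.column,
                "phase": it.phase,
                "cds_offset": it.cds_offset,
                "residue_index": it.residue_index,
            }
            for g in self.genes.values()
            for it in g.introns
        ]
        return pd.DataFrame(
            rows,
            columns=["gene_id", "group", "event_id", "column", "phase",
                     "cds_offset", "residue_index"],
        )

    def gene_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "group": g.group,
                    "chromosome": g.chromosome,
                    "strand": g.strand,
                    "n_introns": len(g.introns),
                }
                for g in self.genes.values()
            ]
        )


@dataclass
class FamilyBundle:
    """Everything one synthetic family run emits, in memory."""

    genome: dict[str, str]
    models: list[GeneModel]
    proteins: list[tuple[str, str]]  # family genes then decoys
    msa: MSA
    truth: FamilyTruth
    spec: FamilySimSpec
    seed: int

    def write(self, outdir) -> dict[str, Path]:
        """Serialize the bundle to plain-text files; returns the path map."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fa",
            "models": out / "models.gff3",
            "proteins": out / "proteins.faa",
            "msa": out / "alignment.afa",
            "truth_genes": out / "truth_genes.tsv",
            "truth_introns": out / "truth_introns.tsv",
            "tree": out / "tree.nwk",
        }
        with open(paths["genome"], "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for k in range(0, len(seq), 80):
                    fh.write(seq[k : k + 80] + "\n")
        with open(paths["models"], "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom in sorted(self.genome):
                fh.write(f"##sequence-region {chrom} 1 {len(self.genome[chrom])}\n")
            for model in self.models:
                fh.write(_gff3_lines(model))
        with open(paths["proteins"], "w") as fh:
            for pid, seq in self.proteins:
                fh.write(f">{pid}\n{seq}\n")
        self.msa.to_fasta(paths["msa"])
        self.truth.gene_frame().to_csv(paths["truth_genes"], sep="\t", index=False)
        self.truth.intron_frame().to_csv(paths["truth_introns"], sep="\t", index=False)
        paths["tree"].write_text(self.truth.tree_newick + "\n")
        return paths


def _gff3_lines(model: GeneModel) -> str:
    segs = sorted(model.cds_segments)
    lo, hi = segs[0][0], segs[-1][1]
    lines = [
        f"{model.chromosome}\tfamscape\tgene\t{lo}\t{hi}\t.\t{model.strand}\t.\t"
        f"ID={model.gene_id}",
        f"{model.chromosome}\tfamscape\tmRNA\t{lo}\t{hi}\t.\t{model.strand}\t.\t"
        f"ID={model.gene_id}.1;Parent={model.gene_id}",
    ]
    cum = 0
    for a, b in model.cds_segments:  # transcription order for phase bookkeeping
        gphase = (3 - cum % 3) % 3
        lines.append(
            f"{model.chromosome}\tfamscape\tCDS\t{a}\t{b}\t.\t{model.strand}\t"
            f"{gphase}\tID=cds-{model.gene_id};Parent={model.gene_id}.1"
        )
        cum += b - a + 1
    lines.sort(key=lambda ln: int(ln.split("\t")[3]))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# family simulation


def _mutate(row: list[str], prob: np.ndarray, rng: np.random.Generator) -> list[str]:
    hits = np.nonzero(rng.random(len(row)) < prob)[0]
    out = list(row)
    for k in hits:
        if out[k] == "-":
            continue
        choices = AA20.replace(out[k], "")
        out[k] = choices[rng.integers(len(choices))]
    return out


def simulate_family(spec: FamilySimSpec, seed: int) -> FamilyBundle:
    """Generate genome, gene models, proteins, true alignment and truth.

    The alignment template is built first (gap-free by default; in
    ``indel_mode`` a few group-specific three-column blocks are deleted in
    half the groups), proteins are read off the rows, back-translated with
    uniformly drawn synonymous codons, interrupted by the planted introns,
    and laid onto chromosomes round-robin with fixed 500-nt spacers. The
    emitted protein of every gene translates exactly from its spliced CDS.
    """
    labels = list(spec.group_labels)
    n_groups = len(labels)

    # gene -> group assignment (round-robin keeps groups balanced)
    gene_ids = [f"UGT{i + 1:03d}" for i in range(spec.n_family_genes)]
    gene_group = {g: labels[i % n_groups] for i, g in enumerate(gene_ids)}

    # --- alignment template -------------------------------------------------
    L = spec.protein_length
    motif_start = L - len(spec.motif) - 30  # motif sits near the C terminus
    if motif_start < 1:
        raise ValueError("protein_length too short to place the motif")
    motif_cols = set(range(motif_start, motif_start + len(spec.motif)))
    event_cols = {e.column - 1 for e in spec.planted_events}

    rng_root = rng_for(seed, "family:root")
    root = [
        spec.motif[c - motif_start] if c in motif_cols
        else AA20[rng_root.integers(20)]
        for c in range(L)
    ]

    # per-column substitution probabilities: the motif diverges 4x slower
    def prob(scale: float) -> np.ndarray:
        p = np.full(L, spec.substitution_rate * scale)
        p[sorted(motif_cols)] *= 0.25
        return p

    # group-specific deletion blocks (indel mode): alternating groups gap out
    # three-column blocks well away from the motif and planted columns
    gap_cols: dict[str, set[int]] = {lab: set() for lab in labels}
    if spec.indel_mode:
        rng_indel = rng_for(seed, "family:indel")
        avoid = motif_cols | {c + d for c in event_cols for d in (-2, -1, 0, 1, 2)}
        candidates = [c for c in range(5, L - 5) if not (
            set(range(c, c + 3)) & avoid)]
        starts = rng_indel.choice(len(candidates), size=min(3, len(candidates)),
                                  replace=False)
        for bi, si in enumerate(sorted(starts)):
            c0 = candidates[int(si)]
            block = set(range(c0, c0 + 3))
            for gi, lab in enumerate(labels):
                if gi % 2 == bi % 2:
                    gap_cols[lab] |= block

    group_rows = {}
    for lab in labels:
        rng_g = rng_for(seed, f"family:group:{lab}")
        row = _mutate(root, prob(1.0), rng_g)
        for c in gap_cols[lab]:
            row[c] = "-"
        group_rows[lab] = row

    msa_rows, proteins = [], []
    for gid in gene_ids:
        rng_leaf = rng_for(seed, f"family:leaf:{gid}")
        row = _mutate(group_rows[gene_group[gid]], prob(0.5), rng_leaf)
        msa_rows.append("".join(row))
        proteins.append((gid, "".join(row).replace("-", "")))
    msa = MSA(gene_ids, msa_rows)

    # --- intron placement ---------------------------------------------------
    rng_intr = rng_for(seed, "family:introns")
    n_intronless = int(round(spec.intronless_fraction * spec.n_family_genes))
    intronless = set(
        np.array(gene_ids)[
            rng_intr.choice(spec.n_family_genes, size=n_intronless, replace=False)
        ].tolist()
    )

    truth_genes = {
        gid: GeneTruth(gene_id=gid, group=gene_group[gid], chromosome="",
                       strand="")
        for gid in gene_ids
    }
    truth_events: dict[str, dict] = {}
    ordered_events = sorted(spec.planted_events, key=lambda e: e.column)
    for k, ev in enumerate(ordered_events, start=1):
        eid = f"I-{k}"
        carriers = []
        carrier_groups = (
            set(ev.carrier_groups) if ev.carrier_groups is not None else set(labels)
        )
        for gid in gene_ids:
            if gene_group[gid] not in carrier_groups or gid in intronless:
                continue
            row = msa.row(gid)
            if row[ev.column - 1] == "-":
                continue
            residue = ev.column - row[: ev.column].count("-")
            offset = 3 * (residue - 1) + ev.phase
            if offset <= 0 or offset >= 3 * len(row.replace("-", "")):
                continue
            truth_genes[gid].introns.append(
                IntronTruth(eid, ev.column, ev.phase, offset, residue)
            )
            carriers.append(gid)
        truth_events[eid] = {
            "column": ev.column, "phase": ev.phase, "carriers": carriers,
        }
    for g in truth_genes.values():
        g.introns.sort(key=lambda it: it.cds_offset)

    # --- back-translation and genome layout ---------------------------------
    chrom_names = [f"chr{c + 1:02d}" for c in range(spec.n_chromosomes)]
    chrom_seqs: dict[str, list[str]] = {c: [] for c in chrom_names}
    chrom_pos = {c: 0 for c in chrom_names}
    models = []

    layout = sorted(gene_ids, key=lambda g: (gene_group[g], g)) \
        if spec.cluster_by_group else gene_ids
    lo_i, hi_i = spec.intron_length_range
    prot_map = dict(proteins)
    for idx, gid in enumerate(layout):
        rng_gene = rng_for(seed, f"family:dna:{gid}")
        prot = prot_map[gid]
        codons = [
            _AA2CODONS[aa][rng_gene.integers(len(_AA2CODONS[aa]))] for aa in prot
        ]
        codons.append(_STOPS[rng_gene.integers(len(_STOPS))])
        cds = "".join(codons)

        offsets = [it.cds_offset for it in truth_genes[gid].introns]
        pieces, exon_spans, pos, prev = [], [], 0, 0
        for off in offsets:
            exon = cds[prev:off]
            pieces.append(exon)
            exon_spans.append((pos + 1, pos + len(exon)))
            pos += len(exon)
            ilen = int(rng_gene.integers(lo_i, hi_i + 1))
            intron = "GT" + "".join(
                "ACGT"[rng_gene.integers(4)] for _ in range(ilen - 4)
            ) + "AG"
            pieces.append(intron)
            pos += ilen
            prev = off
        exon = cds[prev:]
        pieces.append(exon)
        exon_spans.append((pos + 1, pos + len(exon)))
        gene_seq = "".join(pieces)

        strand = "+" if rng_gene.random() < 0.5 else "-"
        chrom = chrom_names[idx % spec.n_chromosomes]
        spacer = "".join("ACGT"[rng_gene.integers(4)] for _ in range(SPACER_NT))
        chrom_seqs[chrom].append(spacer)
        chrom_pos[chrom] += SPACER_NT
        g0 = chrom_pos[chrom] + 1
        glen = len(gene_seq)
        if strand == "+":
            chrom_seqs[chrom].append(gene_seq)
            segs = [(g0 + a - 1, g0 + b - 1) for a, b in exon_spans]
        else:
            chrom_seqs[chrom].append(_revcomp(gene_seq))
            segs = [(g0 + glen - b, g0 + glen - a) for a, b in exon_spans]
        chrom_pos[chrom] += glen
        models.append(
            GeneModel(gene_id=gid, chromosome=chrom, strand=strand,
                      cds_segments=segs)
        )
        truth_genes[gid].chromosome = chrom
        truth_genes[gid].strand = strand

    order = {g: i for i, g in enumerate(gene_ids)}
    models.sort(key=lambda m: order[m.gene_id])
    genome = {c: "".join(parts) for c, parts in chrom_seqs.items()}

    # --- decoys and truth tree ----------------------------------------------
    rng_decoy = rng_for(seed, "family:decoys")
    decoys = []
    for d in range(spec.n_decoy_proteins):
        dlen = int(rng_decoy.integers(150, 617))
        decoys.append(
            (f"DECOY{d + 1:03d}",
             "".join(AA20[rng_decoy.integers(20)] for _ in range(dlen)))
        )

    clades = []
    for lab in labels:
        members = [g for g in gene_ids if gene_group[g] == lab]
        if members:
            clades.append("(" + ",".join(f"{m}:0.5" for m in members) + "):1.0")
    newick = "(" + ",".join(clades) + ");"

    truth = FamilyTruth(genes=truth_genes, events=truth_events,
                        tree_newick=newick)
    return FamilyBundle(
        genome=genome, models=models, proteins=proteins + decoys, msa=msa,
        truth=truth, spec=spec, seed=seed,
    )


_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# expression simulation


def default_design(n_replicates: int = 3) -> pd.DataFrame:
    """Sample sheet emulating the study design: leaf, flower, four fruit
    development stages and two post-harvest ripening points, replicated."""
    groups = ["leaf", "flower", "S1", "S2", "S3", "S4", "S4+3d", "S4+6d"]
    rows = [
        {"sample": f"{g}_r{r + 1}", "group": g}
        for g in groups
        for r in range(n_replicates)
    ]
    return pd.DataFrame(rows)


def simulate_expression(
    gene_ids: Sequence[str],
    design: pd.DataFrame,
    planted_max: Mapping[str, str],
    effect_size: float = 8.0,
    noise_sd: float = 0.2,
    base_mean: float = 50.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Expression matrix with planted tissue-maximal genes.

    Each planted gene's mean abundance in its planted sample group is
    ``effect_size`` times the baseline before noise; lognormal multiplicative
    noise of the given log-sd is applied per sample. Each gene draws from its
    own named substream of the seed. Returns the matrix plus a truth table of
    the planted argmax group per gene.
    """
    if effect_size <= 1:
        raise ValueError("effect_size must exceed 1")
    groups = list(dict.fromkeys(design["group"]))
    unknown = sorted(set(planted_max.values()) - set(groups))
    if unknown:
        raise ValueError(f"unknown sample groups in planted_max: {unknown}")
    unknown_genes = sorted(set(planted_max) - set(gene_ids))
    if unknown_genes:
        raise ValueError(f"planted genes not in family: {unknown_genes}")

    samples = design["sample"].tolist()
    sample_group = dict(zip(design["sample"], design["group"]))
    data = np.empty((len(gene_ids), len(samples)))
    for gi, gene in enumerate(gene_ids):
        rng = rng_for(seed, f"expr:{gene}")
        target = planted_max.get(gene)
        means = {
            g: base_mean * (effect_size if g == target else 1.0) for g in groups
        }
        noise = rng.normal(0.0, noise_sd, size=len(samples))
        data[gi] = [
            means[sample_group[s]] * np.exp(noise[si])
            for si, s in enumerate(samples)
        ]
    values = pd.DataFrame(data, index=list(gene_ids), columns=samples)
    meta = design.set_index("sample")
    truth = pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "planted_group": [planted_max.get(g, "") for g in gene_ids],
        }
    )
    return ExpressionMatrix(values, meta), truth


# ---------------------------------------------------------------------------
# metabolite simulation


def simulate_metabolites(
    stage_profiles: pd.DataFrame,
    n_compounds: int,
    linked_pairs: Sequence[tuple[str, str, float]],
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compound × stage abundances with planted gene–compound correlations.

    ``stage_profiles`` is the expression matrix collapsed to stage means
    (genes × stages). Each linked compound profile is an affine combination
    of its gene's standardized profile and an orthogonalized noise vector,
    calibrated so the sample Pearson r equals ``r_target`` exactly; unlinked
    compounds are independent. Returns the matrix plus a truth table.
    """
    stages = list(stage_profiles.columns)
    n = len(stages)
    if n < 3:
        raise ValueError("need at least 3 stages")
    linked_compounds = [c for _, c, _ in linked_pairs]
    if len(set(linked_compounds)) > n_compounds:
        raise ValueError(
            f"{len(set(linked_compounds))} linked compounds exceed "
            f"n_compounds={n_compounds}"
        )
    for g, _, r in linked_pairs:
        if g not in stage_profiles.index:
            raise ValueError(f"linked gene {g} not in expression profiles")
        if abs(r) > 1:
            raise ValueError(f"|r_target| > 1 for gene {g}")

    compound_ids = [f"compound{k + 1:03d}" for k in range(n_compounds)]
    name_map = {}
    for k, c in enumerate(dict.fromkeys(linked_compounds)):
        name_map[c] = compound_ids[k]

    profiles: dict[str, np.ndarray] = {}
    rows = []
    # linked compounds may host several genes; the profile is built from the
    # first listed gene and additional links are recorded in the truth table
    for gene, compound, r in linked_pairs:
        cid = name_map[compound]
        if cid not in profiles:
            rng = rng_for(seed, f"metab:{compound}")
            z = _standardize(stage_profiles.loc[gene].to_numpy(float))
            eps = rng.standard_normal(n)
            resid = eps - (eps @ z) / (z @ z) * z
            resid = _standardize(resid)
            y = r * z + np.sqrt(max(0.0, 1.0 - r * r)) * resid
            profiles[cid] = 30.0 * y + 30.0 * np.abs(y).max() + 1.0
        rows.append({"gene_id": gene, "compound_id": cid,
                     "compound_name": compound, "r_target": r})

    rng_null = rng_for(seed, "metab:null")
    for cid in compound_ids:
        if cid not in profiles:
            profiles[cid] = rng_null.lognormal(mean=3.0, sigma=0.5, size=n)

    matrix = pd.DataFrame(
        [profiles[c] for c in compound_ids], index=compound_ids, columns=stages
    )
    return matrix, pd.DataFrame(rows)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("constant profile cannot be standardized")
    return (v - v.mean()) / sd
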