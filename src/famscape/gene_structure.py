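"""Exon–intron architecture of a gene family.

Extracts introns from gene models, classifies their phase relative to the
reading frame, projects intron positions onto a protein multiple alignment,
clusters co-projecting introns into conserved insertion events (I-1, I-2, ...)
and tabulates intron counts per phylogenetic group and per chromosome.

Phase convention: an intron falling between two codons is phase 0; after the
first base of a codon, phase 1; after the second base, phase 2. The phase is
computed from the cumulative coding length upstream of the intron (L mod 3),
never from the GFF3 CDS "phase" column, whose bases-to-skip convention is a
different quantity.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from ._util import percentage

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "IntronRecord",
    "InsertionEvent",
    "parse_gene_models",
    "splice_cds",
    "translate_cds",
    "extract_introns",
    "intron_phase",
    "project_intron",
    "detect_events",
    "intron_count_table",
    "intron_count_share",
    "chromosome_summary",
]


@dataclass
class GeneModel:
    """A gene's coordinate skeleton: chromosome, strand and ordered CDS.

    ``cds_segments`` are 1-based inclusive genomic intervals listed in
    transcription order (descending genomic coordinate on the minus strand).
    Genes whose total CDS length is not a multiple of three, or whose
    translation contains an internal stop, are flagged ``partial`` and are
    excluded from phase analysis.
    """

    gene_id: str
    chromosome: str
    strand: str
    cds_segments: list[tuple[int, int]]
    partial: bool = False
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        ivs = sorted((lo, hi) for lo, hi in self.cds_segments)
        for (a_lo, a_hi), (b_lo, b_hi) in zip(ivs, ivs[1:]):
            if b_lo <= a_hi:
                raise ValueError(
                    f"{self.gene_id}: overlapping CDS segments "
                    f"({a_lo}-{a_hi}, {b_lo}-{b_hi})"
                )
        order = self.cds_segments
        expect = sorted(order, reverse=self.strand == "-")
        if order != expect:
            raise ValueError(
                f"{self.gene_id}: CDS segments not in transcription order"
            )
        if self.cds_length % 3 != 0:
            self.partial = True
            self.notes.append("CDS length not divisible by 3")

    @property
    def segment_lengths(self) -> list[int]:
        return [hi - lo + 1 for lo, hi in self.cds_segments]

    @property
    def cds_length(self) -> int:
        return sum(self.segment_lengths)

    @property
    def n_introns(self) -> int:
        return len(self.cds_segments) - 1


@dataclass
class IntronRecord:
    """One intron: genomic bounds, reading-frame phase and alignment anchor.

    ``cds_offset`` (L) counts coding nucleotides upstream of the intron;
    ``phase`` = L mod 3.  ``residue_index`` is the 1-based anchor residue used
    for alignment projection: the split (host) codon for phase 1/2 introns and
    the residue immediately following the insertion point for phase 0, which
    is floor(L/3) + 1 in every case.  ``alignment_column`` is set by
    :func:`project_intron`.
    """

    gene_id: str
    ordinal: int
    start: int
    end: int
    cds_offset: int
    phase: int
    residue_index: int
    alignment_column: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class InsertionEvent:
    """A conserved intron position shared across family members."""

    event_id: str
    column_lo: int
    column_hi: int
    members: list[IntronRecord]
    phase_counts: dict[int, int]
    dominant_phase: int
    flagged: bool = False

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def n_genes(self) -> int:
        return len({m.gene_id for m in self.members})

    def carrier_share(self, family_size: int) -> int:
        """Integer percentage of the family carrying this intron."""
        return percentage(self.n_genes, family_size)

    def dominant_phase_share(self) -> int:
        """Integer percentage of member introns in the dominant phase."""
        return percentage(self.phase_counts[self.dominant_phase], self.n_members)


# ---------------------------------------------------------------------------
# parsing and sequence checks


def _load_genome(genome) -> Mapping[str, str] | None:
    if genome is None or isinstance(genome, Mapping):
        return genome
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(genome), "fasta")}


def parse_gene_models(gff3, genome=None) -> list[GeneModel]:
    """Read gene models from GFF3 (path or text) into :class:`GeneModel`.

    One mRNA per gene is expected; when several are present the transcript
    with the longest total CDS is kept (and the choice logged). If ``genome``
    (FASTA path or mapping chromosome -> sequence) is supplied, every spliced
    CDS is translated and internal stop codons flag the gene as partial.
    """
    text_mode = isinstance(gff3, str) and "\n" in gff3
    db = gffutils.create_db(
        gff3 if text_mode else str(gff3),
        dbfn=":memory:",
        from_string=text_mode,
        merge_strategy="create_unique",
        keep_order=True,
    )
    seqs = _load_genome(genome)
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            mrnas = [gene]
        if len(mrnas) > 1:
            mrnas.sort(
                key=lambda m: (
                    sum(c.end - c.start + 1 for c in db.children(m, featuretype="CDS")),
                    m.id,
                )
            )
            logger.info(
                "%s: %d transcripts, keeping longest-CDS %s",
                gene.id, len(mrnas), mrnas[-1].id,
            )
        mrna = mrnas[-1]
        cds = sorted(
            (c.start, c.end) for c in db.children(mrna, featuretype="CDS")
        )
        if not cds:
            continue
        if gene.strand == "-":
            cds = cds[::-1]
        model = GeneModel(
            gene_id=gene.id,
            chromosome=gene.seqid,
            strand=gene.strand,
            cds_segments=cds,
        )
        if seqs is not None and not model.partial:
            prot = translate_cds(splice_cds(model, seqs))
            if "*" in prot[:-1]:
                model.partial = True
                model.notes.append("internal stop codon in translation")
        models.append(model)
    return models


def splice_cds(gene: GeneModel, genome: Mapping[str, str]) -> str:
    """Concatenate the CDS segments in transcription order (mRNA sense)."""
    chrom = genome[gene.chromosome]
    parts = []
    for lo, hi in gene.cds_segments:
        seg = chrom[lo - 1 : hi]
        if gene.strand == "-":
            seg = str(Seq(seg).reverse_complement())
        parts.append(seg)
    return "".join(parts)


def translate_cds(cds: str) -> str:
    return str(Seq(cds).translate())


# ---------------------------------------------------------------------------
# intron extraction and phase


def intron_phase(cds_offset: int) -> int:
    """Phase of an intron with ``cds_offset`` coding nucleotides upstream."""
    return cds_offset % 3


def extract_introns(gene: GeneModel) -> list[IntronRecord]:
    """One record per gap between consecutive CDS segments.

    Raises if the gene is flagged partial: phase is undefined off-frame.
    """
    if gene.partial:
        raise ValueError(f"{gene.gene_id}: flagged partial ({'; '.join(gene.notes)})")
    records = []
    offset = 0
    for ordinal, (prev, nxt) in enumerate(
        zip(gene.cds_segments, gene.cds_segments[1:]), start=1
    ):
        offset += prev[1] - prev[0] + 1
        if gene.strand == "+":
            lo, hi = prev[1] + 1, nxt[0] - 1
        else:
            lo, hi = nxt[1] + 1, prev[0] - 1
        phase = intron_phase(offset)
        records.append(
            IntronRecord(
                gene_id=gene.gene_id,
                ordinal=ordinal,
                start=lo,
                end=hi,
                cds_offset=offset,
                phase=phase,
                residue_index=offset // 3 + 1,
            )
        )
    return records


# ---------------------------------------------------------------------------
# projection onto the protein alignment


def project_intron(intron: IntronRecord, msa) -> int:
    """Alignment column of the intron's anchor residue in its gene's row.

    Columns are 1-based; gaps in the row do not count toward the residue
    index. The column is stored on the record and returned.
    """
    row = msa.row(intron.gene_id)
    seen = 0
    for col, ch in enumerate(row, start=1):
        if ch != "-":
            seen += 1
            if seen == intron.residue_index:
                intron.alignment_column = col
                return col
    raise ValueError(
        f"{intron.gene_id}: residue {intron.residue_index} beyond ungapped "
        f"row length {seen} — gene model and alignment disagree"
    )


def detect_events(
    introns: Iterable[IntronRecord],
    window: int = 0,
    min_members: int = 2,
) -> list[InsertionEvent]:
    """Cluster projected introns into conserved insertion events.

    Single-linkage merging along the column axis: adjacent introns whose
    column gap is <= ``window`` join the same event. Events are ordered by
    column and serially labelled I-1, I-2, ...  Events with fewer than
    ``min_members`` introns are still reported but flagged. Input order of
    the introns never affects membership or numbering.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    recs = sorted(introns, key=lambda r: (_col(r), r.gene_id, r.ordinal))
    clusters: list[list[IntronRecord]] = []
    for rec in recs:
        if clusters and _col(rec) - _col(clusters[-1][-1]) <= window:
            clusters[-1].append(rec)
        else:
            clusters.append([rec])
    events = []
    for k, members in enumerate(clusters, start=1):
        phases: dict[int, int] = {}
        for m in members:
            phases[m.phase] = phases.get(m.phase, 0) + 1
        dominant = min(phases, key=lambda p: (-phases[p], p))
        events.append(
            InsertionEvent(
                event_id=f"I-{k}",
                column_lo=_col(members[0]),
                column_hi=_col(members[-1]),
                members=members,
                phase_counts=phases,
                dominant_phase=dominant,
                flagged=len(members) < min_members,
            )
        )
    return events


def _col(rec: IntronRecord) -> int:
    if rec.alignment_column is None:
        raise ValueError(f"{rec.gene_id} intron {rec.ordinal}: not projected")
    return rec.alignment_column


# ---------------------------------------------------------------------------
# family-level tables


def intron_count_table(
    intron_counts: Mapping[str, int],
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Group × intron-count contingency table with Total row and column.

    ``intron_counts`` maps gene id -> number of introns; ``groups`` maps gene
    id -> group label and must cover every gene.
    """
    missing = [g for g in intron_counts if g not in groups]
    if missing:
        raise ValueError(f"genes without a group label: {missing[:5]}")
    labels = sorted(set(groups[g] for g in intron_counts))
    counts = sorted(set(intron_counts.values()))
    table = pd.DataFrame(0, index=labels, columns=counts)
    for gene, n in intron_counts.items():
        table.loc[groups[gene], n] += 1
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    return table


def intron_count_share(
    table: pd.DataFrame, n_introns: int, group: str = "Total"
) -> int:
    """Integer percentage of a group's genes having exactly ``n_introns``."""
    return percentage(table.loc[group, n_introns], table.loc[group, "Total"])


def chromosome_summary(
    genes: Iterable[GeneModel],
    groups: Mapping[str, str] | None = None,
    known_chromosomes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Gene counts per chromosome, overall and per group.

    When ``known_chromosomes`` is given, genes on any other sequence
    (scaffolds) are pooled into an "unplaced" bucket; the grand total is
    preserved either way.
    """
    known = set(known_chromosomes) if known_chromosomes is not None else None
    rows = []
    for g in genes:
        chrom = g.chromosome
        if known is not None and chrom not in known:
            chrom = "unplaced"
        rows.append(
            {"chromosome": chrom,
             "group": groups.get(g.gene_id, "unassigned") if groups else "all"}
        )
    df = pd.DataFrame(rows)
    table = df.pivot_table(
        index="chromosome", columns="group", aggfunc="size", fill_value=0
    )
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    return table
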