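"""Gene-structure analysis of TLP loci from GFF3 gene models.

Covers the CDS/protein length arithmetic, classification of genes into
exon-count groups I-IV, mapping of protein positions (e.g. the thaumatin
signature start) onto exon ordinals, splice-variant summaries, and the
chromosomal distribution with tandem-duplication candidates.

All genomic coordinates are 1-based inclusive (the GFF3 convention);
protein positions are 1-based; exon ordinals are counted 5'->3' of the
transcript, i.e. in reverse genomic order on the minus strand.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio.Seq import Seq

from .protein_features import FeatureRecord

Interval = tuple[int, int]

EXON_GROUP_LABELS = {1: "I", 2: "II", 3: "III", 4: "IV"}


def classify_exon_count(n_exons: int) -> str:
    """Group label for an exon count: I-IV for 1-4 exons, "other" beyond."""
    if n_exons < 1:
        raise ValueError("a transcript has at least one exon")
    return EXON_GROUP_LABELS.get(n_exons, "other")


@dataclasses.dataclass(frozen=True)
class StructureGroup:
    label: str
    exon_count: int


def _check_sorted_disjoint(ivals: Sequence[Interval], what: str) -> None:
    for (s, e) in ivals:
        if s > e:
            raise ValueError(f"{what} interval ({s},{e}) reversed")
    for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
        if s2 <= e1:
            raise ValueError(f"{what} intervals overlap or are unsorted")


@dataclasses.dataclass(frozen=True)
class GeneModel:
    """A chromosome-anchored transcript with ordered exon/CDS intervals.

    Intervals are stored in genomic coordinate order regardless of strand;
    transcript orientation is applied by the position-mapping operations.
    """

    gene_id: str
    transcript_id: str
    chromosome: str
    strand: str
    span: Interval
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        _check_sorted_disjoint(self.exons, "exon")
        _check_sorted_disjoint(self.cds, "CDS")
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {self.cds_length} "
                "not divisible by 3")
        lo = min(s for s, _ in self.exons)
        hi = max(e for _, e in self.exons)
        if not (self.span[0] <= lo and hi <= self.span[1]):
            raise ValueError(f"{self.transcript_id}: span does not cover exons")
        for cs, ce in self.cds:
            if not any(es <= cs and ce <= ee for es, ee in self.exons):
                raise ValueError(
                    f"{self.transcript_id}: CDS ({cs},{ce}) outside exons")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def exon_count(self) -> int:
        return len(self.exons)


def protein_length_from_cds(cds_length_bp: int) -> int:
    """Protein length encoded by a CDS: length/3 minus the stop codon.

    Raises on a length not divisible by 3 or too short to encode one
    residue plus a stop (< 6 bp).
    """
    if cds_length_bp % 3 != 0:
        raise ValueError(f"CDS length {cds_length_bp} not divisible by 3")
    if cds_length_bp < 6:
        raise ValueError(
            f"CDS length {cds_length_bp} too short for one residue + stop")
    return cds_length_bp // 3 - 1


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 file into gene models (one per mRNA feature)."""
    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="error")
    models = []
    for mrna in db.features_of_type("mRNA"):
        exons = sorted((f.start, f.end)
                       for f in db.children(mrna, featuretype="exon"))
        cds = sorted((f.start, f.end)
                     for f in db.children(mrna, featuretype="CDS"))
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.id
        models.append(GeneModel(
            gene_id=gene_id,
            transcript_id=mrna.id,
            chromosome=mrna.seqid,
            strand=mrna.strand,
            span=(mrna.start, mrna.end),
            exons=tuple(exons),
            cds=tuple(cds) if cds else tuple(exons),
        ))
    return models


def classify_by_exons(
    models: Iterable[GeneModel],
) -> tuple[dict[str, StructureGroup], Counter]:
    """Assign every transcript its exon-count group and tally group sizes."""
    assignment = {}
    sizes: Counter = Counter()
    for m in models:
        label = classify_exon_count(m.exon_count)
        assignment[m.transcript_id] = StructureGroup(label, m.exon_count)
        sizes[label] += 1
    return assignment, sizes


def _cds_in_transcript_order(model: GeneModel) -> list[Interval]:
    return list(model.cds) if model.strand == "+" else list(model.cds[::-1])


def map_protein_position_to_exon(model: GeneModel, aa_position: int) -> int:
    """Exon ordinal (1-based, transcript orientation) containing a protein
    position.

    The first nucleotide of residue ``aa_position`` sits at spliced-CDS
    offset 3*(aa_position-1)+1; the ordinal is found from cumulative
    per-exon CDS lengths walked 5'->3' of the transcript.
    """
    if aa_position < 1:
        raise ValueError("protein positions are 1-based")
    nt_offset = 3 * (aa_position - 1) + 1
    if nt_offset > model.cds_length - 3:  # stop codon is not a residue
        raise ValueError(
            f"position {aa_position} beyond CDS of {model.transcript_id}")
    cum = 0
    for ordinal, (s, e) in enumerate(_cds_in_transcript_order(model), 1):
        cum += e - s + 1
        if nt_offset <= cum:
            return ordinal
    raise AssertionError("unreachable: offset checked against CDS length")


def spliced_cds(model: GeneModel, chromosome_seq: str) -> str:
    """Extract and splice the coding sequence from a chromosome string,
    reverse-complemented on the minus strand."""
    parts = [chromosome_seq[s - 1:e] for s, e in model.cds]
    seq = "".join(parts)
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def translate_cds(cds_seq: str) -> str:
    """Translate a spliced CDS (standard code), stripping the final stop."""
    prot = str(Seq(cds_seq).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise ValueError("internal stop codon in CDS")
    return prot


@dataclasses.dataclass(frozen=True)
class SpliceVariantSummary:
    """Per-gene transcript multiplicity report.

    transcripts_per_gene counts all transcripts; additional_variants is
    that count minus one (the "additional splice variants beyond the
    primary isoform").  max_variant_gene is empty when every gene is a
    singleton.
    """

    transcripts_per_gene: dict[str, int]
    additional_variants: dict[str, int]
    zero_variant_genes: tuple[str, ...]
    max_variant_gene: str
    max_variant_count: int


def splice_variant_summary(
    models: Iterable[GeneModel],
) -> SpliceVariantSummary:
    """Summarize transcript multiplicity per gene locus.

    The gene with the most transcripts is reported with a deterministic
    lexicographic tie-break; genes with a single transcript are the
    zero-variant set.
    """
    per_gene: Counter = Counter()
    for m in models:
        per_gene[m.gene_id] += 1
    zero = tuple(sorted(g for g, n in per_gene.items() if n == 1))
    multi = {g: n for g, n in per_gene.items() if n > 1}
    if multi:
        max_gene = min(multi, key=lambda g: (-multi[g], g))
        max_count = multi[max_gene]
    else:
        max_gene, max_count = "", 0
    return SpliceVariantSummary(
        transcripts_per_gene=dict(per_gene),
        additional_variants={g: n - 1 for g, n in per_gene.items()},
        zero_variant_genes=zero,
        max_variant_gene=max_gene,
        max_variant_count=max_count,
    )


@dataclasses.dataclass(frozen=True)
class ChromosomeDistribution:
    """Gene counts and ordering per chromosome, with tandem candidates.

    adjacency_pairs lists consecutive same-chromosome genes whose start
    coordinates differ by less than the threshold — candidates for
    localized (tandem) gene duplication.
    """

    counts: dict[str, int]
    ordered_genes: dict[str, tuple[tuple[str, int, int], ...]]
    adjacency_pairs: tuple[tuple[str, str, str, int], ...]


def chromosome_distribution(
    features: Sequence[FeatureRecord],
    adjacency_threshold_bp: int = 1_000_000,
) -> ChromosomeDistribution:
    """Tally genes per chromosome and flag close same-chromosome neighbours.

    Genes are ordered by start coordinate within each chromosome; pairs of
    consecutive genes closer than ``adjacency_threshold_bp`` (start-to-start,
    default 1 Mb) are reported as candidate tandem duplicates.
    """
    by_chrom: dict[str, list[FeatureRecord]] = {}
    for rec in features:
        by_chrom.setdefault(rec.chromosome, []).append(rec)
    counts = {}
    ordered = {}
    pairs = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda r: r.genomic_span[0])
        counts[chrom] = len(genes)
        ordered[chrom] = tuple(
            (g.gene_symbol, g.genomic_span[0], g.genomic_span[1])
            for g in genes)
        for a, b in zip(genes, genes[1:]):
            gap = b.genomic_span[0] - a.genomic_span[0]
            if gap < adjacency_threshold_bp:
                pairs.append((chrom, a.gene_symbol, b.gene_symbol, gap))
    return ChromosomeDistribution(counts, ordered, tuple(pairs))


# ---------------------------------------------------------------------------
# diagram output
# ---------------------------------------------------------------------------

def gene_structure_svg(
    models: Sequence[GeneModel],
    path: str | Path,
    signature_spans: Mapping[str, Interval] | None = None,
    width: int = 900,
) -> None:
    """Draw exon/intron structures as a simple SVG: exons as boxes,
    introns as lines, the signature span (protein coords mapped to the
    transcript) highlighted when provided."""
    row_h, pad = 34, 60
    height = pad + row_h * len(models)
    out = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
           f'height="{height}">']
    for i, m in enumerate(models):
        y = pad // 2 + i * row_h
        lo, hi = m.span
        scale = (width - 2 * pad) / max(1, hi - lo)

        def gx(coord: int) -> float:
            return pad + (coord - lo) * scale

        out.append(f'<text x="4" y="{y + 4}" font-size="11">'
                   f'{m.transcript_id}</text>')
        out.append(f'<line x1="{gx(lo):.1f}" y1="{y}" x2="{gx(hi):.1f}" '
                   f'y2="{y}" stroke="black"/>')
        for s, e in m.exons:
            out.append(f'<rect x="{gx(s):.1f}" y="{y - 6}" '
                       f'width="{max(1.0, (e - s + 1) * scale):.1f}" '
                       f'height="12" fill="maroon"/>')
        if signature_spans and m.transcript_id in signature_spans:
            aa_s, aa_e = signature_spans[m.transcript_id]
            exon_s = map_protein_position_to_exon(m, aa_s)
            xs = gx(m.exons[exon_s - 1][0] if m.strand == "+"
                    else m.exons[-exon_s][0])
            out.append(f'<polygon points="{xs:.1f},{y - 12} {xs + 5:.1f},'
                       f'{y - 6} {xs - 5:.1f},{y - 6}" fill="gold"/>')
    out.append("</svg>")
    Path(path).write_text("\n".join(out))
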