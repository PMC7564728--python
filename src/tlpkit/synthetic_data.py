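"""Ground-truthed synthetic fixtures for every pipeline stage.

Generates TLP-like proteomes (signature-bearing genes plus signature-free
decoys), genomes as FASTA + GFF3 with 1-4-exon gene models and isoform
sets, homology-hit tables with e-values straddling the cutoff, protein
alignments evolved on known trees, and tissue-structured FPKM matrices —
all deterministic under a fixed seed and each carrying a truth record the
analysis modules can be checked against.

The generator's defaults emulate the barley study conditions: 19 true TLP
loci carrying 32 transcripts in total, proteins of 173-359 residues with
10-24 cysteines, a tandem cluster on chromosome 5H, and an eight-tissue
expression panel.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

from .io_formats import HitRecord, ProteinRecord, write_fasta, write_hit_table
from .gene_structure import GeneModel
from .phylogeny import Alignment, PhyloTree
from .expression import DEFAULT_TISSUES, ExpressionMatrix
from .signature_scan import (
    CBM_CANONICAL, CBM_VARIANT, THAUMATIN_SIGNATURE, parse_prosite, scan,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA19_NO_C = AA20.replace("C", "")
#: residues usable at signature 'x' positions without creating extra
#: cysteines (C excluded so cysteine totals stay controllable)
_X_CHOICES = AA19_NO_C
_SIGNATURE = parse_prosite(THAUMATIN_SIGNATURE)

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in sorted(_STANDARD_TABLE.forward_table.items()):
    _CODONS_FOR.setdefault(aa, []).append(codon)
_STOP_CODONS = tuple(sorted(_STANDARD_TABLE.stop_codons))

_DNA = np.frombuffer(b"ACGT", dtype="S1")


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_DNA, size=length).tobytes().decode()


def _rng_of(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# proteins
# ---------------------------------------------------------------------------

def _signature_instance(rng: np.random.Generator, cbm_class: str) -> str:
    """A concrete 15-residue realization of the thaumatin signature.

    The CQTGDCGG / CQTGDCQG octapeptide occupies the core when a CBM
    class is requested; otherwise the core's 'x' position is kept
    non-glutamine so neither motif can appear.
    """
    x = lambda: str(rng.choice(list(_X_CHOICES)))
    g3 = str(rng.choice(["G", "F"]))
    if cbm_class == "canonical":
        core = CBM_CANONICAL  # C Q T G D C G G
    elif cbm_class == "variant":
        core = CBM_VARIANT  # C Q T G D C Q G
    elif cbm_class == "none":
        x6 = str(rng.choice([c for c in _X_CHOICES if c != "Q"]))
        g8 = str(rng.choice(["G", "A"]))
        g12 = str(rng.choice(["G", "Q"]))
        core = "C" + x6 + "T" + g8 + "DC" + x() + g12
    else:
        raise ValueError(f"unknown cbm_class {cbm_class!r}")
    return "G" + x() + g3 + x() + core + x() + x() + "C"


@dataclasses.dataclass(frozen=True)
class DesignedProtein:
    """A generated protein plus its recorded ground truth."""

    record: ProteinRecord
    has_signature: bool
    signature_span: tuple[int, int] | None
    n_cysteine: int
    cbm_class: str


def design_protein(
    length: int,
    n_cysteine: int,
    with_signature: bool,
    cbm_class: str = "none",
    seed: int | np.random.Generator = 0,
    protein_id: str = "SYN0001.1",
    species_tag: str = "syn",
    break_signature: bool = False,
    end_flank: int = 5,
) -> DesignedProtein:
    """Generate a protein with controlled signature, CBM and cysteine
    content.

    A signature-conforming 15-mer is embedded at a recorded interior
    position when requested (its core carrying the chosen CBM octapeptide)
    and the total cysteine count is adjusted to exactly ``n_cysteine`` by
    placing cysteines outside the reserved span.  ``break_signature``
    plants the signature but mutates its invariant aspartate to lysine,
    yielding a TLP-like decoy that the pattern engine must reject.

    Raises
    ------
    ValueError
        On infeasible constraints (too short, too few/many cysteines).
    """
    rng = _rng_of(seed)
    sig = _signature_instance(rng, cbm_class)
    if break_signature:
        assert sig[8] == "D"
        sig = sig[:8] + "K" + sig[8:][1:]
    flank = 5
    plant = with_signature or break_signature
    if plant and length < len(sig) + flank + end_flank:
        raise ValueError(
            f"length {length} too short for a planted signature")
    n_sig_cys = sig.count("C") if plant else 0
    if n_cysteine < n_sig_cys:
        raise ValueError(
            f"n_cysteine {n_cysteine} below the {n_sig_cys} cysteines of "
            "the planted signature")
    if n_cysteine > length - (len(sig) if plant else 0):
        raise ValueError("more cysteines requested than free positions")

    for _ in range(200):
        seq = list(rng.choice(list(AA19_NO_C), size=length))
        span = None
        reserved: set[int] = set()
        if plant:
            start0 = int(rng.integers(flank,
                                      length - len(sig) - end_flank + 1))
            seq[start0:start0 + len(sig)] = list(sig)
            span = (start0 + 1, start0 + len(sig))
            reserved = set(range(start0, start0 + len(sig)))
        free = [i for i in range(length) if i not in reserved]
        extra = rng.choice(free, size=n_cysteine - n_sig_cys, replace=False)
        for i in extra:
            seq[i] = "C"
        record = ProteinRecord(protein_id=protein_id,
                               sequence="".join(seq),
                               species_tag=species_tag)
        matches = scan(record, _SIGNATURE)
        if with_signature and not any(m.start == span[0] for m in matches):
            continue  # planted cysteines corrupted the site; retry
        if not with_signature and matches:
            continue  # accidental signature in background; retry
        if cbm_class == "none" and (CBM_CANONICAL in record.sequence
                                    or CBM_VARIANT in record.sequence):
            continue
        return DesignedProtein(record, with_signature,
                               span if with_signature else None,
                               n_cysteine, cbm_class)
    raise RuntimeError("could not satisfy protein design constraints")


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def back_translate(protein_seq: str, rng: np.random.Generator) -> str:
    """Back-translate with uniform synonymous-codon choice and append a
    random stop codon (standard nuclear code)."""
    codons = [str(rng.choice(_CODONS_FOR[aa])) for aa in protein_seq]
    codons.append(str(rng.choice(_STOP_CODONS)))
    return "".join(codons)


def build_gene_model(
    protein: ProteinRecord,
    exon_count: int,
    chromosome: str,
    start: int,
    strand: str = "+",
    seed: int | np.random.Generator = 0,
    gene_id: str | None = None,
    cds_override: str | None = None,
) -> tuple[GeneModel, str]:
    """Build a gene model and its genomic (top-strand) locus sequence.

    The protein is back-translated, a stop codon appended, the CDS split
    at ``exon_count - 1`` random points (not necessarily codon
    boundaries), and GT..AG introns of 60-200 bp inserted.  On the minus
    strand the locus sequence is reverse-complemented and the intervals
    mirrored, so extract-splice-translate recovers the protein on either
    strand.  Exon intervals equal CDS intervals (no UTRs are modeled).
    """
    rng = _rng_of(seed)
    if exon_count < 1:
        raise ValueError("exon_count must be >= 1")
    cds_nt = cds_override if cds_override is not None \
        else back_translate(protein.sequence, rng)
    if exon_count > len(cds_nt):
        raise ValueError("more exons than CDS nucleotides")
    cuts = sorted(rng.choice(np.arange(1, len(cds_nt)),
                             size=exon_count - 1, replace=False))
    pieces = [cds_nt[a:b] for a, b in
              zip([0, *cuts], [*cuts, len(cds_nt)])]
    gene_parts: list[str] = []
    offsets: list[tuple[int, int]] = []  # 0-based [start, end) in gene seq
    pos = 0
    for k, piece in enumerate(pieces):
        if k > 0:
            intron = "GT" + _random_dna(rng, int(rng.integers(56, 196))) + "AG"
            gene_parts.append(intron)
            pos += len(intron)
        offsets.append((pos, pos + len(piece)))
        gene_parts.append(piece)
        pos += len(piece)
    gene_seq = "".join(gene_parts)
    total = len(gene_seq)

    if strand == "+":
        ivals = [(start + s, start + e - 1) for s, e in offsets]
    else:
        from Bio.Seq import Seq
        gene_seq = str(Seq(gene_seq).reverse_complement())
        ivals = sorted((start + total - e, start + total - s - 1)
                       for s, e in offsets)
    model = GeneModel(
        gene_id=gene_id or protein.locus_id,
        transcript_id=protein.protein_id,
        chromosome=chromosome,
        strand=strand,
        span=(start, start + total - 1),
        exons=tuple(ivals),
        cds=tuple(ivals),
    )
    return model, gene_seq


def truncate_model(model: GeneModel, protein: ProteinRecord,
                   n_residues: int) -> tuple[GeneModel, ProteinRecord]:
    """Derive a C-terminally truncated isoform from a gene model.

    Keeps the first ``n_residues`` codons of the spliced CDS (transcript
    orientation) and trims the genomic intervals accordingly; the isoform
    CDS carries no stop codon.  Used to plant shorter splice variants at
    a locus while staying consistent with the shared genomic sequence.
    """
    if not 1 <= n_residues < len(protein.sequence):
        raise ValueError("isoform length must be shorter than the protein")
    keep_nt = 3 * n_residues
    order = model.cds if model.strand == "+" else model.cds[::-1]
    kept: list[tuple[int, int]] = []
    remaining = keep_nt
    for s, e in order:
        seg = e - s + 1
        if seg <= remaining:
            kept.append((s, e))
            remaining -= seg
            if remaining == 0:
                break
        else:
            if model.strand == "+":
                kept.append((s, s + remaining - 1))
            else:
                kept.append((e - remaining + 1, e))
            remaining = 0
            break
    kept = sorted(kept)
    iso_id_base = protein.locus_id
    iso_record = ProteinRecord(
        protein_id=protein.protein_id,
        sequence=protein.sequence[:n_residues],
        locus_id=iso_id_base,
        species_tag=protein.species_tag,
    )
    iso_model = GeneModel(
        gene_id=model.gene_id,
        transcript_id=protein.protein_id,
        chromosome=model.chromosome,
        strand=model.strand,
        span=model.span,
        exons=tuple(kept),
        cds=tuple(kept),
    )
    return iso_model, iso_record


# ---------------------------------------------------------------------------
# whole genomes
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TruthEntry:
    """Ground truth for one planted TLP locus."""

    gene_id: str
    transcript_ids: tuple[str, ...]
    longest_transcript: str
    has_signature: bool
    signature_span: tuple[int, int] | None
    n_cysteine: int
    cbm_class: str
    exon_count: int
    chromosome: str
    tandem_cluster_id: int | None


@dataclasses.dataclass(frozen=True)
class SyntheticTruth:
    """Planted-locus truth table plus the decoy identifier list."""

    planted: dict[str, TruthEntry]
    decoy_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        planted_tx = {t for e in self.planted.values()
                      for t in e.transcript_ids}
        if planted_tx & set(self.decoy_ids):
            raise ValueError("planted and decoy ids overlap")

    @property
    def true_loci(self) -> set[str]:
        return set(self.planted)

    @property
    def expected_retained(self) -> set[str]:
        return {e.longest_transcript for e in self.planted.values()}


@dataclasses.dataclass
class SyntheticGenome:
    """A generated genome bundle: sequences, models, hits and truth."""

    proteome: list[ProteinRecord]
    gene_models: dict[str, GeneModel]
    chromosomes: dict[str, str]
    hits: list[HitRecord]
    locus_map: dict[str, str]
    truth: SyntheticTruth

    def write(self, out_dir: str | Path) -> None:
        """Write proteome FASTA, genome FASTA, GFF3 and hit table."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.proteome, out / "proteome.fasta")
        with open(out / "genome.fasta", "w") as fh:
            for chrom in sorted(self.chromosomes):
                fh.write(f">{chrom}\n")
                seq = self.chromosomes[chrom]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
        write_gff3(self.gene_models.values(), out / "models.gff3")
        write_hit_table(self.hits, out / "hits.tsv")
        with open(out / "truth.tsv", "w") as fh:
            fh.write("gene_id\thas_signature\tsignature_start\t"
                     "signature_end\tn_cysteine\tcbm_class\texon_count\t"
                     "chromosome\ttandem_cluster_id\n")
            for gid in sorted(self.truth.planted):
                e = self.truth.planted[gid]
                span = e.signature_span or ("", "")
                fh.write(f"{gid}\t{e.has_signature}\t{span[0]}\t{span[1]}\t"
                         f"{e.n_cysteine}\t{e.cbm_class}\t{e.exon_count}\t"
                         f"{e.chromosome}\t{e.tandem_cluster_id or ''}\n")


def write_gff3(models, path: str | Path) -> None:
    """Write gene models as GFF3 (gene, mRNA, exon, CDS features)."""
    by_gene: dict[str, list[GeneModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(by_gene):
            txs = by_gene[gid]
            chrom, strand = txs[0].chromosome, txs[0].strand
            lo = min(t.span[0] for t in txs)
            hi = max(t.span[1] for t in txs)
            fh.write(f"{chrom}\tsynthetic\tgene\t{lo}\t{hi}\t.\t{strand}\t."
                     f"\tID={gid}\n")
            for t in sorted(txs, key=lambda m: m.transcript_id):
                fh.write(f"{chrom}\tsynthetic\tmRNA\t{t.span[0]}\t"
                         f"{t.span[1]}\t.\t{strand}\t.\t"
                         f"ID={t.transcript_id};Parent={gid}\n")
                for k, (s, e) in enumerate(t.exons, 1):
                    fh.write(f"{chrom}\tsynthetic\texon\t{s}\t{e}\t.\t"
                             f"{strand}\t.\tID={t.transcript_id}.exon{k};"
                             f"Parent={t.transcript_id}\n")
                # phase: bases to skip to the next codon start, walked in
                # transcript (5'->3') order
                order = t.cds if strand == "+" else t.cds[::-1]
                cum = 0
                phased = []
                for s, e in order:
                    phased.append((s, e, (3 - cum % 3) % 3))
                    cum += e - s + 1
                for k, (s, e, phase) in enumerate(sorted(phased), 1):
                    fh.write(f"{chrom}\tsynthetic\tCDS\t{s}\t{e}\t.\t"
                             f"{strand}\t{phase}\t"
                             f"ID={t.transcript_id}.CDS{k};"
                             f"Parent={t.transcript_id}\n")


_CHROMOSOMES = ("1H", "3H", "4H", "5H", "7H")
#: spacing between unrelated loci (beyond the tandem threshold) and
#: within tandem clusters (well inside it)
_FAR_SPACING = (1_200_000, 1_500_000)
_TANDEM_SPACING = (5_000, 50_000)


def make_genome(
    n_true: int = 19,
    n_decoy: int = 13,
    n_isoform_extra: int = 13,
    tandem_spec: Mapping[str, Sequence[int]] | None = None,
    seed: int = 0,
    dense_chromosomes: bool = False,
) -> SyntheticGenome:
    """Generate a genome bundle exercising the whole candidate funnel.

    Defaults mirror the study structure: 19 signature-bearing loci whose
    isoforms total 32 transcripts, 13 TLP-like decoys whose signature
    aspartate is mutated, and a four-gene tandem cluster on 5H.  Hit-table
    e-values straddle the 1e-10 cutoff: every planted transcript draws
    log-uniform from [1e-50, 1e-12]; half the decoys pass the cutoff so
    that only the signature filter can reject them.

    With ``dense_chromosomes`` the intergenic spacing is shrunk so
    chromosome sequences stay small (for fast round-trip tests); tandem
    adjacency structure is preserved only in the default spacing.
    """
    rng = np.random.default_rng(seed)
    tandem_spec = {"5H": [4]} if tandem_spec is None else tandem_spec
    far = (20_000, 40_000) if dense_chromosomes else _FAR_SPACING

    # locus placement plan: tandem clusters first, then round-robin
    placements: list[tuple[str, int | None]] = []  # (chrom, cluster id)
    cluster_id = 0
    for chrom, sizes in sorted(tandem_spec.items()):
        for size in sizes:
            cluster_id += 1
            placements += [(chrom, cluster_id)] * size
    i = 0
    while len(placements) < n_true:
        placements.append((_CHROMOSOMES[i % len(_CHROMOSOMES)], None))
        i += 1
    placements = placements[:n_true]

    proteome: list[ProteinRecord] = []
    gene_models: dict[str, GeneModel] = {}
    hits: list[HitRecord] = []
    locus_map: dict[str, str] = {}
    planted: dict[str, TruthEntry] = {}
    next_pos: dict[str, int] = {}
    chrom_parts: dict[str, list[tuple[int, str]]] = {c: [] for c in
                                                    _CHROMOSOMES}

    # distribute extra isoforms over the true loci
    iso_per_locus = np.zeros(n_true, dtype=int)
    if n_true > 0:
        for _ in range(n_isoform_extra):
            iso_per_locus[rng.integers(0, n_true)] += 1

    def _place(chrom: str, clustered: bool) -> int:
        lo, hi = _TANDEM_SPACING if clustered else far
        pos = next_pos.get(chrom, 1) + int(rng.integers(lo, hi))
        return pos

    cbm_plan = ["canonical"] * 2 + ["variant"] * 1
    for g in range(n_true):
        chrom, clust = placements[g]
        gene_id = f"SYNT{g + 1:03d}G"
        length = int(rng.integers(173, 360))
        n_cys = int(rng.choice([10, 10, 16, 16, 16, 17, 18, 19, 22, 24]))
        cbm = cbm_plan[g] if g < len(cbm_plan) else "none"
        designed = design_protein(
            length, n_cys, with_signature=True, cbm_class=cbm, seed=rng,
            protein_id=f"{gene_id}.1", end_flank=12)
        start = _place(chrom, clust is not None)
        strand = "+" if rng.random() < 0.5 else "-"
        exon_count = int(rng.integers(1, 5))
        model, gseq = build_gene_model(
            designed.record, exon_count, chrom, start, strand, seed=rng,
            gene_id=gene_id)
        chrom_parts[chrom].append((start, gseq))
        next_pos[chrom] = model.span[1]

        tx_ids = [designed.record.protein_id]
        proteome.append(designed.record)
        gene_models[designed.record.protein_id] = model
        locus_map[designed.record.protein_id] = gene_id
        sig_end = designed.signature_span[1]
        for k in range(iso_per_locus[g]):
            # keep the signature inside the truncation so every planted
            # transcript stays signature-positive (the funnel's locus
            # collapse, not the signature filter, merges isoforms)
            lo_res = max(length // 2, min(sig_end, length - 11))
            n_res = int(rng.integers(lo_res, length - 10))
            iso_prot = ProteinRecord(
                protein_id=f"{gene_id}.{k + 2}",
                sequence=designed.record.sequence,
                locus_id=gene_id)
            iso_model, iso_rec = truncate_model(model, iso_prot, n_res)
            proteome.append(iso_rec)
            gene_models[iso_rec.protein_id] = iso_model
            locus_map[iso_rec.protein_id] = gene_id
            tx_ids.append(iso_rec.protein_id)

        for tid in tx_ids:
            e_val = 10.0 ** rng.uniform(-50, -12)
            hits.append(HitRecord(tid, "TLP_domain", e_val))
        planted[gene_id] = TruthEntry(
            gene_id=gene_id,
            transcript_ids=tuple(tx_ids),
            longest_transcript=designed.record.protein_id,
            has_signature=True,
            signature_span=designed.signature_span,
            n_cysteine=n_cys,
            cbm_class=cbm,
            exon_count=exon_count,
            chromosome=chrom,
            tandem_cluster_id=clust,
        )

    decoy_ids = []
    for d in range(n_decoy):
        chrom = _CHROMOSOMES[d % len(_CHROMOSOMES)]
        gene_id = f"SYND{d + 1:03d}G"
        designed = design_protein(
            int(rng.integers(173, 360)), int(rng.choice([8, 10, 16])),
            with_signature=False, cbm_class="none", seed=rng,
            protein_id=f"{gene_id}.1", break_signature=True)
        start = _place(chrom, False)
        model, gseq = build_gene_model(
            designed.record, int(rng.integers(1, 5)), chrom, start,
            "+" if rng.random() < 0.5 else "-", seed=rng, gene_id=gene_id)
        chrom_parts[chrom].append((start, gseq))
        next_pos[chrom] = model.span[1]
        proteome.append(designed.record)
        gene_models[designed.record.protein_id] = model
        locus_map[designed.record.protein_id] = gene_id
        decoy_ids.append(designed.record.protein_id)
        # half the decoys pass the e-value cutoff: the signature filter
        # (not the e-value filter) must be what rejects them
        if d % 2 == 0:
            e_val = 10.0 ** rng.uniform(-30, -11)
        else:
            e_val = 10.0 ** rng.uniform(-9, -3)
        hits.append(HitRecord(designed.record.protein_id, "TLP_domain",
                              e_val))

    chromosomes: dict[str, str] = {}
    for chrom, parts in chrom_parts.items():
        if not parts:
            continue
        end = next_pos[chrom]
        buf = np.frombuffer(_random_dna(rng, end).encode(),
                            dtype="S1").copy()
        for start, gseq in parts:
            buf[start - 1:start - 1 + len(gseq)] = \
                np.frombuffer(gseq.encode(), dtype="S1")
        chromosomes[chrom] = buf.tobytes().decode()

    return SyntheticGenome(
        proteome=proteome,
        gene_models=gene_models,
        chromosomes=chromosomes,
        hits=hits,
        locus_map=locus_map,
        truth=SyntheticTruth(planted=planted, decoy_ids=tuple(decoy_ids)),
    )


# ---------------------------------------------------------------------------
# alignment evolution
# ---------------------------------------------------------------------------

def evolve_alignment(tree, seq_length: int, seed: int = 0) -> Alignment:
    """Evolve a gap-free protein alignment down a tree.

    The root sequence is uniform over the 20 residues; along each branch
    every site receives a Poisson(branch length) number of substitution
    events, each replacing the residue with one of the other 19 uniformly.
    Expected substitutions per site therefore equal the branch length, so
    Poisson-corrected distances estimate path lengths.
    """
    from skbio.tree import TreeNode
    if isinstance(tree, PhyloTree):
        root = tree.root
    elif isinstance(tree, TreeNode):
        root = tree
    else:
        import io
        root = TreeNode.read(io.StringIO(str(tree)))
    rng = np.random.default_rng(seed)
    aa = np.frombuffer(AA20.encode(), dtype="S1")

    names: list[str] = []
    rows: list[str] = []

    def _descend(node, seq: np.ndarray) -> None:
        for child in node.children:
            t = float(child.length or 0.0)
            child_seq = seq.copy()
            if t > 0:
                events = rng.poisson(t, size=seq_length)
                for site in np.nonzero(events)[0]:
                    cur = child_seq[site]
                    for _ in range(events[site]):
                        alt = aa[aa != cur]
                        cur = alt[rng.integers(0, len(alt))]
                    child_seq[site] = cur
            if child.is_tip():
                names.append(str(child.name))
                rows.append(child_seq.tobytes().decode())
            else:
                _descend(child, child_seq)

    root_seq = rng.choice(aa, size=seq_length)
    _descend(root, root_seq)
    return Alignment(tuple(names), tuple(rows))


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def default_expression_profiles(
    n_embryo_high: int = 6,
    n_grain_high: int = 6,
    n_flat: int = 7,
    tissues: Sequence[str] = DEFAULT_TISSUES,
    base_fpkm: float = 5.0,
    fold: float = 8.0,
) -> tuple[dict[str, list[float]], dict[str, str]]:
    """Planted tissue-profile means emulating the observed classes:
    embryo-high genes, developing-grain-high genes, and flat genes, with
    an 8-fold planted difference over the base level."""
    tissues = list(tissues)
    profiles: dict[str, list[float]] = {}
    classes: dict[str, str] = {}
    idx = 1
    for _ in range(n_embryo_high):
        means = [base_fpkm * fold if t == "EMB" else base_fpkm
                 for t in tissues]
        profiles[f"SYNTLP{idx:02d}"] = means
        classes[f"SYNTLP{idx:02d}"] = "embryo_high"
        idx += 1
    for _ in range(n_grain_high):
        means = [base_fpkm * fold if t.startswith("CAR") else base_fpkm
                 for t in tissues]
        profiles[f"SYNTLP{idx:02d}"] = means
        classes[f"SYNTLP{idx:02d}"] = "grain_high"
        idx += 1
    for _ in range(n_flat):
        profiles[f"SYNTLP{idx:02d}"] = [base_fpkm] * len(tissues)
        classes[f"SYNTLP{idx:02d}"] = "flat"
        idx += 1
    return profiles, classes


def make_expression(
    planted_profiles: Mapping[str, Sequence[float]],
    tissues: Sequence[str] = DEFAULT_TISSUES,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """FPKM matrix from planted per-tissue means plus truncated Gaussian
    noise (values clipped at zero, FPKM being non-negative)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    genes = tuple(planted_profiles)
    means = np.array([list(planted_profiles[g]) for g in genes], dtype=float)
    if means.shape[1] != len(tissues):
        raise ValueError("profile length does not match tissue panel")
    values = np.clip(means + rng.normal(0, noise_sd, means.shape), 0, None)
    return ExpressionMatrix(genes, tuple(tissues), values)
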