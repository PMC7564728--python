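"""Physicochemical characterization of TLP proteins.

Computes the per-protein descriptors reported in family-characterization
tables: sequence length, molecular weight, isoelectric point, cysteine
count, carbohydrate-binding-motif flags and the small-TLP class, and merges
externally predicted annotations (subcellular localization, signal peptide,
transmembrane-helix count) into complete feature records.

Molecular weights use average isotopic residue masses plus one water
(monoisotopic masses behind a flag).  Isoelectric points use the Bjellqvist
pKa set with residue-specific terminal adjustments — the convention of the
ExPASy ProtParam tool — and locate the zero of the net-charge curve by
bisection.  The pKa set is a named, swappable configuration.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import AnnotationRecord, ProteinRecord, STANDARD_AA
from .signature_scan import CbmReport

WATER_AVG = 18.0153
WATER_MONO = 18.010565

#: average isotopic residue (= amino acid minus water) masses, Da
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

MONOISOTOPIC_RESIDUE_MASS = {
    "A": 71.03711, "R": 156.10111, "N": 114.04293, "D": 115.02694,
    "C": 103.00919, "E": 129.04259, "Q": 128.05858, "G": 57.02146,
    "H": 137.05891, "I": 113.08406, "L": 113.08406, "K": 128.09496,
    "M": 131.04049, "F": 147.06841, "P": 97.05276, "S": 87.03203,
    "T": 101.04768, "W": 186.07931, "Y": 163.06333, "V": 99.06841,
}


@dataclasses.dataclass(frozen=True)
class PKaSet:
    """An ionizable-group pKa configuration for net-charge computation.

    side_chain_pka covers the acids D/E/C/Y and bases H/K/R;
    nterm_residue_pka / cterm_residue_pka hold residue-specific terminal
    adjustments applied when the protein starts/ends with those residues.
    """

    name: str
    side_chain_pka: Mapping[str, float]
    n_terminus_pka: float
    c_terminus_pka: float
    nterm_residue_pka: Mapping[str, float] = dataclasses.field(
        default_factory=dict)
    cterm_residue_pka: Mapping[str, float] = dataclasses.field(
        default_factory=dict)

    def __post_init__(self) -> None:
        values = [*self.side_chain_pka.values(), self.n_terminus_pka,
                  self.c_terminus_pka, *self.nterm_residue_pka.values(),
                  *self.cterm_residue_pka.values()]
        if any(not 0 < v < 14 for v in values):
            raise ValueError("all pKa values must lie in (0, 14)")


#: Bjellqvist pKa values, the set used by ExPASy ProtParam
BJELLQVIST = PKaSet(
    name="bjellqvist",
    side_chain_pka={"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
                    "H": 5.98, "K": 10.0, "R": 12.0},
    n_terminus_pka=7.50,
    c_terminus_pka=3.55,
    nterm_residue_pka={"A": 7.59, "M": 7.00, "S": 6.93, "P": 8.36,
                       "T": 6.82, "V": 7.44, "E": 7.70},
    cterm_residue_pka={"D": 4.55, "E": 4.75},
)

ACIDIC = ("D", "E", "C", "Y")
BASIC = ("H", "K", "R")


def count_cysteines(sequence: str) -> int:
    """Number of cysteine residues (the disulfide-forming letter C)."""
    return sequence.count("C")


def classify_small_tlp(n_cysteine: int) -> bool:
    """TLPs with exactly 10 conserved cysteines form the small-TLP class;
    the classical full-length class carries 16."""
    if n_cysteine < 0:
        raise ValueError("cysteine count cannot be negative")
    return n_cysteine == 10


def molecular_weight(sequence: str, monoisotopic: bool = False,
                     x_mass: float | None = None) -> float:
    """Protein molecular weight in daltons.

    Sum of residue masses plus one water.  The placeholder letter X has no
    defined mass and is an error unless ``x_mass`` assigns one (a common
    choice is the average residue mass, ~110 Da).
    """
    if not sequence:
        raise ValueError("empty sequence")
    table = MONOISOTOPIC_RESIDUE_MASS if monoisotopic else AVERAGE_RESIDUE_MASS
    water = WATER_MONO if monoisotopic else WATER_AVG
    total = water
    for i, aa in enumerate(sequence):
        if aa == "X":
            if x_mass is None:
                raise ValueError(
                    f"position {i + 1}: X has no defined mass "
                    "(pass x_mass to assign one)")
            total += x_mass
        elif aa in table:
            total += table[aa]
        else:
            raise ValueError(f"position {i + 1}: unknown residue {aa!r}")
    return total


def molecular_weight_kda(sequence: str, **kwargs) -> float:
    """Molecular weight in kDa rounded to 3 decimals (report convention)."""
    return round(molecular_weight(sequence, **kwargs) / 1000.0, 3)


def net_charge(sequence: str, ph: float,
               pka_set: PKaSet = BJELLQVIST) -> float:
    """Net protein charge at a given pH.

    Henderson–Hasselbalch per ionizable group: the N-terminus and H/K/R
    side chains contribute +1/(1+10^(pH-pKa)); the C-terminus and D/E/C/Y
    side chains contribute -1/(1+10^(pKa-pH)).  Strictly decreasing in pH,
    so the isoelectric point is a unique root.
    """
    if not sequence:
        raise ValueError("empty sequence")
    comp = {aa: sequence.count(aa) for aa in ACIDIC + BASIC}
    nterm_pka = pka_set.nterm_residue_pka.get(sequence[0],
                                              pka_set.n_terminus_pka)
    cterm_pka = pka_set.cterm_residue_pka.get(sequence[-1],
                                              pka_set.c_terminus_pka)
    positive = 1.0 / (1.0 + 10.0 ** (ph - nterm_pka))
    for aa in BASIC:
        positive += comp[aa] / (1.0 + 10.0 ** (ph - pka_set.side_chain_pka[aa]))
    negative = 1.0 / (1.0 + 10.0 ** (cterm_pka - ph))
    for aa in ACIDIC:
        negative += comp[aa] / (1.0 + 10.0 ** (pka_set.side_chain_pka[aa] - ph))
    return positive - negative


def isoelectric_point(sequence: str, pka_set: PKaSet = BJELLQVIST,
                      tol: float = 0.002) -> float:
    """Isoelectric point: the pH at which the net charge is zero.

    Found by bisection on [0, 14] to ``tol`` pH units; report convention
    is two decimals (full precision is returned, rounding is the caller's
    concern).
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pka_set) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# feature-record assembly
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class FeatureRecord:
    """One characterization-table row for an identified TLP gene."""

    gene_symbol: str
    accession: str
    cds_length_bp: int
    aa_length: int
    pI: float
    mw_kda: float
    n_cysteine: int
    chromosome: str
    genomic_span: tuple[int, int]
    exon_count: int
    structure_group: str
    cbm_canonical: bool
    cbm_variant: bool
    localization_label: str
    signal_peptide: str
    tm_count: int
    is_small_tlp: bool

    def __post_init__(self) -> None:
        if self.cds_length_bp and self.aa_length != self.cds_length_bp // 3 - 1:
            raise ValueError(
                f"{self.gene_symbol}: aa_length {self.aa_length} inconsistent "
                f"with CDS {self.cds_length_bp} bp (expected "
                f"{self.cds_length_bp // 3 - 1})")
        if self.n_cysteine > self.aa_length:
            raise ValueError(f"{self.gene_symbol}: more cysteines than residues")
        if self.mw_kda <= 0:
            raise ValueError(f"{self.gene_symbol}: non-positive mass")


def _natural_key(symbol: str) -> tuple:
    return tuple(int(p) if p.isdigit() else p
                 for p in re.split(r"(\d+)", symbol))


def assemble_feature_table(
    proteins: Sequence[ProteinRecord],
    gene_models: Mapping[str, "GeneModel"],
    annotations: Mapping[str, AnnotationRecord],
    cbm_reports: Mapping[str, CbmReport],
    gene_symbols: Mapping[str, str] | None = None,
    pka_set: PKaSet = BJELLQVIST,
) -> list[FeatureRecord]:
    """Assemble one FeatureRecord per retained TLP protein.

    ``gene_models`` and ``cbm_reports`` are keyed by protein (transcript)
    identifier; a protein without a gene model is an error, while a
    missing annotation degrades to the "unknown" defaults.  Output is
    sorted by gene symbol (natural numeric order).
    """
    from .gene_structure import classify_exon_count  # late: avoid cycle

    symbols = gene_symbols or {}
    records = []
    for prot in proteins:
        pid = prot.protein_id
        model = gene_models.get(pid)
        if model is None:
            raise KeyError(f"no gene model for protein {pid!r}")
        cbm = cbm_reports.get(pid)
        if cbm is None:
            raise KeyError(f"no CBM report for protein {pid!r}")
        annot = annotations.get(pid, AnnotationRecord(pid))
        n_cys = count_cysteines(prot.sequence)
        cds_bp = model.cds_length
        records.append(FeatureRecord(
            gene_symbol=symbols.get(pid, pid),
            accession=pid,
            cds_length_bp=cds_bp,
            aa_length=len(prot),
            pI=round(isoelectric_point(prot.sequence, pka_set), 2),
            mw_kda=molecular_weight_kda(prot.sequence),
            n_cysteine=n_cys,
            chromosome=model.chromosome,
            genomic_span=model.span,
            exon_count=len(model.exons),
            structure_group=classify_exon_count(len(model.exons)),
            cbm_canonical=cbm.canonical,
            cbm_variant=cbm.variant,
            localization_label=annot.localization_label,
            signal_peptide=annot.signal_peptide,
            tm_count=annot.tm_count,
            is_small_tlp=classify_small_tlp(n_cys),
        ))
    return sorted(records, key=lambda r: _natural_key(r.gene_symbol))


_TABLE_COLUMNS = [
    "gene_symbol", "accession", "cds_length_bp", "aa_length", "pI",
    "mw_kda", "n_cysteine", "chromosome", "genomic_start", "genomic_end",
    "exon_count", "structure_group", "cbm_canonical", "cbm_variant",
    "localization", "signal_peptide", "tm_count", "is_small_tlp",
]


def write_feature_table(records: Iterable[FeatureRecord],
                        path: str | Path) -> None:
    """Write feature records as TSV in characterization-table column order."""
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        start, end = d.pop("genomic_span")
        d["genomic_start"], d["genomic_end"] = start, end
        d["localization"] = d.pop("localization_label")
        rows.append(d)
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(
        path, sep="\t", index=False)


def load_barley_reference_table() -> pd.DataFrame:
    """Load the published characteristics of the 19 barley TLP genes.

    Columns: gene symbol, transcript accession, CDS length (bp), protein
    length (aa), pI, MW (kDa), cysteine count, chromosome, genomic span,
    exon count, subcellular localization, signal peptide, TM-domain count.
    Used as reference input for arithmetic and classification checks.
    """
    path = Path(__file__).parent / "data" / "hvtlp_characteristics.tsv"
    return pd.read_csv(path, sep="\t", comment="#")


def load_family_sizes() -> pd.DataFrame:
    """Load the signature-verified TLP family sizes for the four cereal
    genomes (barley, Brachypodium, sorghum, rice); their pooled proteins
    form the cross-species phylogeny."""
    path = Path(__file__).parent / "data" / "tlp_family_sizes.tsv"
    return pd.read_csv(path, sep="\t", comment="#")
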