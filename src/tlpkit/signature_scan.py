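"""PROSITE-style pattern engine and the TLP candidate-selection funnel.

Thaumatin-like proteins (TLPs, the pathogenesis-related PR-5 family) are
diagnosed by the thaumatin family signature

    G-x-[GF]-x-C-x-T-[GA]-D-C-x(1,2)-[GQ]-x(2,3)-C

This module compiles such expressions, scans protein sequences for them,
detects the carbohydrate-binding CQTGDCGG / CQTGDCQG octapeptides, and runs
the full candidate funnel: homology-hit e-value filter, signature
verification, and collapse to one (longest) isoform per genetic locus.

Grammar subset: ``-``-separated elements; literals, ``x`` (any residue),
``[..]`` residue classes, and ``(n)`` / ``(n,m)`` repeat suffixes, written
attached (``x(2,3)``) or as their own element (``x-(2,3)``).  PROSITE
anchors (``<``, ``>``) and negated ``{..}`` classes are unsupported and
raise a parse error rather than being ignored.  All positions are 1-based
inclusive protein coordinates.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io_formats import HitRecord, ProteinRecord, STANDARD_AA, logger

#: the thaumatin family signature, diagnostic of PR-5 family membership
THAUMATIN_SIGNATURE = "G-x-[GF]-x-C-x-T-[GA]-D-C-x-(1,2)-[GQ]-x-(2,3)-C"
#: carbohydrate-binding motif implicated in beta-glucan binding
CBM_CANONICAL = "CQTGDCGG"
#: CBM variant with the terminal-core glycine replaced by glutamine
CBM_VARIANT = "CQTGDCQG"

DEFAULT_EVALUE_THRESHOLD = 1e-10


class PatternSyntaxError(ValueError):
    """Raised on malformed pattern text; carries the element position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"pattern element {position}: {message}")
        self.position = position


@dataclasses.dataclass(frozen=True)
class PatternElement:
    """One compiled pattern element.

    kind is "literal" (one fixed residue), "any" (x), or "class"
    ([..] alternatives); min_repeat/max_repeat bound how many consecutive
    residues the element may consume.
    """

    kind: str
    residues: frozenset[str]
    min_repeat: int = 1
    max_repeat: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("literal", "any", "class"):
            raise ValueError(f"unknown element kind {self.kind!r}")
        if self.kind == "literal" and len(self.residues) != 1:
            raise ValueError("literal element must hold exactly one residue")
        if self.min_repeat < 1 or self.max_repeat < self.min_repeat:
            raise ValueError("invalid repeat bounds")

    def matches(self, residue: str) -> bool:
        return self.kind == "any" or residue in self.residues


@dataclasses.dataclass(frozen=True)
class PrositePattern:
    """A compiled PROSITE-style pattern with its length bounds."""

    elements: tuple[PatternElement, ...]
    min_len: int
    max_len: int
    source_text: str

    def __post_init__(self) -> None:
        if self.min_len != sum(e.min_repeat for e in self.elements):
            raise ValueError("min_len inconsistent with elements")
        if self.max_len != sum(e.max_repeat for e in self.elements):
            raise ValueError("max_len inconsistent with elements")


@dataclasses.dataclass(frozen=True)
class SignatureMatch:
    """A signature occurrence at [start, end], 1-based inclusive."""

    protein_id: str
    start: int
    end: int
    matched_subsequence: str


def _parse_repeat(spec: str, position: int) -> tuple[int, int]:
    if not spec.endswith(")"):
        raise PatternSyntaxError(f"unbalanced repeat in {spec!r}", position)
    body = spec[1:-1]
    parts = body.split(",")
    try:
        if len(parts) == 1:
            n = int(parts[0])
            bounds = (n, n)
        elif len(parts) == 2:
            bounds = (int(parts[0]), int(parts[1]))
        else:
            raise ValueError
    except ValueError:
        raise PatternSyntaxError(f"malformed repeat {spec!r}", position) from None
    lo, hi = bounds
    if lo < 1 or hi < lo:
        raise PatternSyntaxError(
            f"repeat bounds ({lo},{hi}) require 1 <= n <= m", position
        )
    return lo, hi


def parse_prosite(pattern_text: str) -> PrositePattern:
    """Compile PROSITE-style pattern text.

    Raises
    ------
    PatternSyntaxError
        On unbalanced brackets, empty classes, invalid repeat bounds,
        unsupported anchors/negations, or unknown characters; the message
        names the offending element position.
    """
    tokens = pattern_text.strip().split("-")
    elements: list[PatternElement] = []
    pos = 0
    i = 0
    while i < len(tokens):
        tok = tokens[i].strip()
        pos += 1
        if not tok:
            raise PatternSyntaxError("empty element", pos)
        # a repeat may be written as its own '-'-separated token
        repeat = (1, 1)
        core = tok
        if "(" in tok and not tok.startswith("("):
            cut = tok.index("(")
            core, rep_spec = tok[:cut], tok[cut:]
            repeat = _parse_repeat(rep_spec, pos)
        elif i + 1 < len(tokens) and tokens[i + 1].startswith("("):
            repeat = _parse_repeat(tokens[i + 1].strip(), pos)
            i += 1
        if core.startswith("("):
            raise PatternSyntaxError("repeat with no preceding element", pos)
        if core.startswith("{") or core in ("<", ">"):
            raise PatternSyntaxError(
                f"unsupported PROSITE syntax {core!r}", pos
            )
        if core == "x":
            elem = PatternElement("any", frozenset(), *repeat)
        elif core.startswith("["):
            if not core.endswith("]"):
                raise PatternSyntaxError(f"unbalanced bracket in {core!r}", pos)
            body = core[1:-1].upper()
            if not body:
                raise PatternSyntaxError("empty residue class", pos)
            bad = set(body) - STANDARD_AA
            if bad:
                raise PatternSyntaxError(
                    f"unknown residue(s) {sorted(bad)} in class", pos
                )
            elem = PatternElement("class", frozenset(body), *repeat)
        elif len(core) == 1 and core.upper() in STANDARD_AA:
            elem = PatternElement("literal", frozenset(core.upper()), *repeat)
        else:
            raise PatternSyntaxError(f"unknown element {core!r}", pos)
        elements.append(elem)
        i += 1
    if not elements:
        raise PatternSyntaxError("empty pattern", 0)
    return PrositePattern(
        elements=tuple(elements),
        min_len=sum(e.min_repeat for e in elements),
        max_len=sum(e.max_repeat for e in elements),
        source_text=pattern_text,
    )


def _match_from(seq: str, offset: int, elements: Sequence[PatternElement],
                idx: int, all_ends: bool) -> list[int]:
    """Return end offsets (exclusive) of expansions of elements[idx:] at
    ``offset``; shortest-first.  Stops at the first unless ``all_ends``."""
    if idx == len(elements):
        return [offset]
    elem = elements[idx]
    ends: list[int] = []
    # the mandatory first min_repeat residues must all match
    if offset + elem.min_repeat > len(seq):
        return ends
    if any(not elem.matches(seq[offset + k])
           for k in range(elem.min_repeat)):
        return ends
    # consume min..max repeats, shortest expansion first
    for take in range(elem.min_repeat, elem.max_repeat + 1):
        if take > elem.min_repeat:
            pos = offset + take - 1
            if pos >= len(seq) or not elem.matches(seq[pos]):
                break
        sub = _match_from(seq, offset + take, elements, idx + 1, all_ends)
        ends.extend(sub)
        if ends and not all_ends:
            return ends[:1]
    return ends


def scan(protein: ProteinRecord, pattern: PrositePattern,
         all_expansions: bool = False) -> list[SignatureMatch]:
    """Find pattern occurrences at every start position of a protein.

    For a fixed start, variable repeats are expanded shortest-first and the
    first valid expansion is reported (one match per start, the PROSITE
    convention); ``all_expansions`` reports every valid expansion instead.
    Matches may overlap.  Coordinates are 1-based inclusive.
    """
    seq = protein.sequence
    matches: list[SignatureMatch] = []
    for start0 in range(len(seq) - pattern.min_len + 1):
        ends = _match_from(seq, start0, pattern.elements, 0, all_expansions)
        for end0 in ends:
            matches.append(SignatureMatch(
                protein_id=protein.protein_id,
                start=start0 + 1,
                end=end0,
                matched_subsequence=seq[start0:end0],
            ))
    return matches


@dataclasses.dataclass(frozen=True)
class CbmReport:
    """Presence/positions of the carbohydrate-binding octapeptides."""

    protein_id: str
    canonical: bool
    variant: bool
    canonical_positions: tuple[int, ...]
    variant_positions: tuple[int, ...]


def _find_all(seq: str, motif: str) -> tuple[int, ...]:
    out = []
    i = seq.find(motif)
    while i != -1:
        out.append(i + 1)
        i = seq.find(motif, i + 1)
    return tuple(out)


def detect_cbm(protein: ProteinRecord) -> CbmReport:
    """Detect the exact carbohydrate-binding motifs CQTGDCGG (canonical)
    and CQTGDCQG (G->Q variant); positions are 1-based."""
    can = _find_all(protein.sequence, CBM_CANONICAL)
    var = _find_all(protein.sequence, CBM_VARIANT)
    return CbmReport(protein.protein_id, bool(can), bool(var), can, var)


def filter_hits(hits: Iterable[HitRecord],
                threshold: float = DEFAULT_EVALUE_THRESHOLD) -> list[HitRecord]:
    """Retain hits with e-value <= threshold (inclusive cutoff)."""
    if threshold <= 0:
        raise ValueError("e-value threshold must be positive")
    return [h for h in hits if h.e_value <= threshold]


@dataclasses.dataclass(frozen=True)
class FunnelReport:
    """Per-stage counts of the candidate-selection funnel.

    Counts are distinct proteins surviving each stage and are
    non-increasing: input hits >= e-value pass >= signature-bearing >=
    unique loci retained.
    """

    n_input_hits: int
    n_after_evalue: int
    n_with_signature: int
    n_unique_loci: int
    retained_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = (self.n_input_hits, self.n_after_evalue,
                  self.n_with_signature, self.n_unique_loci)
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValueError(f"funnel counts must be non-increasing: {counts}")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=list)


def candidate_funnel(
    proteome: Sequence[ProteinRecord],
    hits: Sequence[HitRecord],
    pattern: PrositePattern,
    locus_map: Mapping[str, str],
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD,
) -> tuple[list[ProteinRecord], FunnelReport]:
    """Run the full identification funnel on a proteome plus hit table.

    Stages, in order: (1) distinct proteins named as hit queries;
    (2) e-value filter (a protein passes if its best hit passes);
    (3) at least one complete signature match; (4) collapse to one protein
    per locus, keeping the longest isoform (ties broken by
    lexicographically smallest transcript identifier).

    Raises
    ------
    KeyError
        If a hit names a protein absent from the proteome, or a retained
        protein is missing from ``locus_map``.
    """
    by_id = {p.protein_id: p for p in proteome}
    for h in hits:
        if h.query_id not in by_id:
            raise KeyError(f"hit references unknown protein {h.query_id!r}")

    hit_ids = {h.query_id for h in hits}
    passing = {h.query_id for h in filter_hits(hits, evalue_threshold)}

    with_sig = {
        pid for pid in passing if scan(by_id[pid], pattern)
    }

    per_locus: dict[str, ProteinRecord] = {}
    for pid in sorted(with_sig):
        locus = locus_map[pid]
        best = per_locus.get(locus)
        prot = by_id[pid]
        if (best is None or len(prot) > len(best)
                or (len(prot) == len(best) and pid < best.protein_id)):
            per_locus[locus] = prot
    retained = sorted(per_locus.values(), key=lambda p: p.protein_id)

    report = FunnelReport(
        n_input_hits=len(hit_ids),
        n_after_evalue=len(passing),
        n_with_signature=len(with_sig),
        n_unique_loci=len(retained),
        retained_ids=tuple(p.protein_id for p in retained),
    )
    logger.info(
        "funnel: %d hits -> %d pass e-value -> %d with signature -> %d loci",
        report.n_input_hits, report.n_after_evalue,
        report.n_with_signature, report.n_unique_loci,
    )
    return retained, report
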