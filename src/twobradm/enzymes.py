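"""In-silico digestion with type IIB restriction enzymes.

Type IIB enzymes (BcgI, BsaXI, AlfI, ...) cleave double-stranded DNA on
*both* sides of their recognition site, excising a fragment of fixed
length.  Digesting a genome with one of these enzymes therefore yields a
reproducible set of equal-length tags, which is the property that makes
them usable as reduced-representation markers for microbial profiling.

This module finds recognition sites on both strands of a sequence,
extracts the fixed-length tag around each site, and collapses each tag
to a strand-independent *canonical* form (the lexicographic minimum of
the tag and its reverse complement), so that the same physical duplex is
always represented by the same string.

The default :data:`BCGI` geometry uses the BcgI core recognition pattern
``CGANNNNNNTGC`` with 10 nt flanks on either side, giving 32 bp tags
(the double-stranded core of the BcgI excision).  The enzyme registry is
user-extensible: any IUPAC pattern plus flank lengths defines a spec.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

#: IUPAC degenerate nucleotide codes -> the set of concrete bases matched.
IUPAC_CODES: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

_ACGT = frozenset("ACGT")


class EnzymeConfigError(ValueError):
    """Raised for an invalid enzyme specification (bad IUPAC code, negative flank)."""


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes supported)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def canonicalize(sequence: str) -> str:
    """Strand-independent representative of a tag.

    Returns ``min(sequence, reverse_complement(sequence))`` in
    lexicographic order.  Idempotent.  Only unambiguous A/C/G/T strings
    have a well-defined canonical form; anything else raises ValueError.
    """
    if not sequence or not _ACGT.issuperset(sequence):
        raise ValueError(
            f"canonicalize requires a nonempty A/C/G/T string, got {sequence!r}")
    rc = sequence.translate(_COMPLEMENT)[::-1]
    return sequence if sequence <= rc else rc


@dataclass(frozen=True)
class EnzymeSpec:
    """Geometry of a type IIB enzyme: recognition pattern plus flanks.

    ``tag_length = left_flank + len(recognition) + right_flank`` is fixed
    for a given spec; every tag the enzyme produces has exactly this
    length.
    """

    name: str
    recognition: str = "CGANNNNNNTGC"
    left_flank: int = 10
    right_flank: int = 10

    def __post_init__(self) -> None:
        if not self.recognition:
            raise EnzymeConfigError("empty recognition pattern")
        bad = set(self.recognition.upper()) - set(IUPAC_CODES)
        if bad:
            raise EnzymeConfigError(
                f"invalid IUPAC code(s) {sorted(bad)} in recognition pattern "
                f"{self.recognition!r}")
        if self.left_flank < 0 or self.right_flank < 0:
            raise EnzymeConfigError("flank lengths must be >= 0")
        object.__setattr__(self, "recognition", self.recognition.upper())

    @property
    def pattern_length(self) -> int:
        return len(self.recognition)

    @property
    def tag_length(self) -> int:
        return self.left_flank + len(self.recognition) + self.right_flank

    def _compiled(self, pattern: str) -> re.Pattern:
        # lookahead so overlapping sites are all reported
        cls = []
        for code in pattern:
            bases = IUPAC_CODES[code]
            cls.append(bases if len(bases) == 1 else f"[{bases}]")
        return re.compile("(?=" + "".join(cls) + ")")

    @property
    def forward_regex(self) -> re.Pattern:
        return self._compiled(self.recognition)

    @property
    def reverse_regex(self) -> re.Pattern:
        return self._compiled(reverse_complement(self.recognition))


#: Default BcgI spec: CGA(N6)TGC core with 10 nt flanks -> 32 bp tags.
BCGI = EnzymeSpec("BcgI")

#: Known enzyme geometries by name; extensible at run time.
ENZYME_REGISTRY: dict[str, EnzymeSpec] = {"BcgI": BCGI}


def get_enzyme(name: str) -> EnzymeSpec:
    try:
        return ENZYME_REGISTRY[name]
    except KeyError:
        raise EnzymeConfigError(
            f"unknown enzyme {name!r}; registered: {sorted(ENZYME_REGISTRY)}"
        ) from None


@dataclass(frozen=True)
class Tag:
    """One extracted tag: canonical sequence plus its genomic locus.

    ``start`` is the 0-based start of the tag window on the top strand of
    the contig as given (half-open interval of length ``tag_length``);
    ``strand`` is the strand on which the recognition pattern matched.
    """

    sequence: str
    genome_id: str
    contig: str
    start: int
    strand: str


def match_sites(sequence: str, enzyme: EnzymeSpec) -> list[tuple[int, str]]:
    """All recognition-site matches of ``enzyme`` in ``sequence``.

    Returns sorted ``(start, strand)`` pairs, where ``start`` is the
    0-based position of the recognition-pattern match on the top strand.
    Both strands are scanned (the reverse-complement pattern is matched
    against the top strand) and only sites whose full tag window — flanks
    included — lies inside the sequence are reported.  Overlapping
    matches are all reported.  Ambiguous sequence characters (N etc.)
    never match a pattern position.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    plen = enzyme.pattern_length
    n = len(seq)
    hits: list[tuple[int, str]] = []
    for m in enzyme.forward_regex.finditer(seq):
        p = m.start()
        if p >= enzyme.left_flank and p + plen + enzyme.right_flank <= n:
            hits.append((p, "+"))
    for m in enzyme.reverse_regex.finditer(seq):
        p = m.start()
        if p >= enzyme.right_flank and p + plen + enzyme.left_flank <= n:
            hits.append((p, "-"))
    hits.sort()
    return hits


def _iter_contigs(genome) -> Iterator[tuple[str, str]]:
    """Normalize genome input to (contig_id, sequence) pairs.

    Accepts a mapping ``{contig_id: sequence}``, an iterable of such
    pairs, or an iterable of Biopython SeqRecords.
    """
    if isinstance(genome, Mapping):
        yield from genome.items()
        return
    for item in genome:
        if isinstance(item, tuple):
            yield item
        else:  # SeqRecord-like
            yield item.id, str(item.seq)


def extract_tags(genome, enzyme: EnzymeSpec, genome_id: str = "") -> list[Tag]:
    """Extract all canonical tags from a genome.

    One :class:`Tag` per matched site with full flanks; tag windows
    containing any non-ACGT base are dropped (and tallied in the log).
    Contigs shorter than ``tag_length`` contribute no tags.  An empty
    genome (no sequences at all) is an error.
    """
    tags: list[Tag] = []
    n_contigs = 0
    n_dropped = 0
    plen = enzyme.pattern_length
    for contig_id, seq in _iter_contigs(genome):
        n_contigs += 1
        seq = str(seq).upper()
        if len(seq) < enzyme.tag_length:
            continue
        for site_start, strand in match_sites(seq, enzyme):
            if strand == "+":
                w0 = site_start - enzyme.left_flank
            else:
                w0 = site_start - enzyme.right_flank
            window = seq[w0:w0 + enzyme.tag_length]
            if not _ACGT.issuperset(window):
                n_dropped += 1
                continue
            tags.append(Tag(sequence=canonicalize(window), genome_id=genome_id,
                            contig=contig_id, start=w0, strand=strand))
    if n_contigs == 0:
        raise ValueError("empty genome: no sequences to digest")
    if n_dropped:
        logger.info("extract_tags(%s): dropped %d tag(s) overlapping ambiguous bases",
                    genome_id or "<genome>", n_dropped)
    return tags
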