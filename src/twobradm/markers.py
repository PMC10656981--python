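"""Species-specific marker database construction and serialization.

A tag qualifies as a species-specific marker when (i) it occurs exactly
once within every genome of its species in which it occurs at all, and
(ii) it occurs in no genome of any other species.  The resulting
database maps each canonical marker sequence to exactly one species and
records T_i, the number of markers per species, which is the
normalization constant used when converting assigned read counts to
relative abundances.

When one species has several genomes the marker condition is applied
with union-of-genomes semantics: single-copy in each genome where
present, absent from all other species' genomes.
"""

from __future__ import annotations

import hashlib
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .enzymes import EnzymeSpec, Tag

logger = logging.getLogger(__name__)

_RANKS = ("kingdom", "phylum", "class_", "order", "family", "genus", "species")
_TAXONOMY_COLUMNS = ["genome_id", "kingdom", "phylum", "class",
                     "order", "family", "genus", "species"]


@dataclass(frozen=True)
class TaxonomyRecord:
    """Taxonomic lineage of one genome assembly (kingdom -> species)."""

    genome_id: str
    kingdom: str = ""
    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", self.species.strip())
        if not self.species:
            raise ValueError(f"genome {self.genome_id!r}: empty species name")

    @property
    def lineage(self) -> tuple[str, ...]:
        return tuple(getattr(self, r) for r in _RANKS)


def read_taxonomy(path) -> dict[str, TaxonomyRecord]:
    """Read a genome->lineage table (TSV with columns genome_id..species)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(_TAXONOMY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"taxonomy file {path}: missing column(s) {sorted(missing)}")
    dup = df["genome_id"][df["genome_id"].duplicated()]
    if len(dup):
        raise ValueError(f"taxonomy file {path}: duplicate genome_id(s) {sorted(set(dup))}")
    out = {}
    for row in df.to_dict("records"):
        out[row["genome_id"]] = TaxonomyRecord(
            genome_id=row["genome_id"], kingdom=row["kingdom"],
            phylum=row["phylum"], class_=row["class"], order=row["order"],
            family=row["family"], genus=row["genus"], species=row["species"])
    return out


@dataclass
class MarkerDatabase:
    """Canonical marker sequence -> species, with per-species totals T_i.

    ``species`` lists every species present in the build, including those
    that ended up with zero markers (absent from
    ``species_marker_count``).
    """

    markers: dict[str, str]
    species_marker_count: dict[str, int]
    enzyme: EnzymeSpec
    species: tuple[str, ...] = ()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = Counter(self.markers.values())
        if dict(counts) != dict(self.species_marker_count):
            raise ValueError("species_marker_count inconsistent with markers mapping")
        if not self.species:
            self.species = tuple(sorted(counts))

    @property
    def zero_marker_species(self) -> tuple[str, ...]:
        return tuple(s for s in self.species if s not in self.species_marker_count)

    def __len__(self) -> int:
        return len(self.markers)


def within_genome_unique(tags: Iterable[Tag | str]) -> set[str]:
    """Canonical sequences occurring exactly once within one genome's tags."""
    counts = Counter(t.sequence if isinstance(t, Tag) else t for t in tags)
    return {seq for seq, c in counts.items() if c == 1}


def _genome_counters(tags_by_genome) -> dict[str, Counter]:
    if isinstance(tags_by_genome, Mapping):
        items = tags_by_genome.items()
    else:
        items = list(tags_by_genome)
        ids = [g for g, _ in items]
        dups = {g for g in ids if ids.count(g) > 1}
        if dups:
            raise ValueError(f"duplicate genome_id(s): {sorted(dups)}")
    return {gid: Counter(t.sequence if isinstance(t, Tag) else t for t in tags)
            for gid, tags in items}


def build_database(tags_by_genome, taxonomy: Mapping[str, TaxonomyRecord],
                   enzyme: EnzymeSpec) -> MarkerDatabase:
    """Build the species-specific marker database from per-genome tag sets.

    ``tags_by_genome`` maps genome_id to its extracted tags (or canonical
    sequences).  Every genome must have a taxonomy record; a tag becomes
    a marker for species *s* iff it is single-copy in every genome of *s*
    where it occurs and absent from all genomes of other species.
    """
    counters = _genome_counters(tags_by_genome)
    missing = sorted(set(counters) - set(taxonomy))
    if missing:
        raise ValueError(f"genome(s) without taxonomy record: {missing}")

    genome_species = {gid: taxonomy[gid].species for gid in counters}
    all_species = tuple(sorted(set(genome_species.values())))

    # seq -> (set of species, max within-genome multiplicity)
    seen: dict[str, tuple[set, int]] = {}
    for gid, counter in counters.items():
        sp = genome_species[gid]
        for seq, mult in counter.items():
            if seq in seen:
                spset, mx = seen[seq]
                spset.add(sp)
                seen[seq] = (spset, max(mx, mult))
            else:
                seen[seq] = ({sp}, mult)

    markers = {seq: next(iter(spset))
               for seq, (spset, mx) in seen.items()
               if len(spset) == 1 and mx == 1}
    counts = dict(Counter(markers.values()))
    db = MarkerDatabase(markers=markers, species_marker_count=counts,
                        enzyme=enzyme, species=all_species,
                        provenance={"genomes": sorted(counters)})
    if db.zero_marker_species:
        logger.warning("species with zero specific markers: %s",
                       ", ".join(db.zero_marker_species))
    return db


_HEADER_MAGIC = "#twobradm-marker-db\tv1"


def _body_lines(db: MarkerDatabase) -> list[str]:
    return [f"{seq}\t{sp}" for seq, sp in sorted(db.markers.items())]


def save_database(db: MarkerDatabase, path) -> None:
    """Write the database as a sorted two-column TSV with a header block.

    The header records the enzyme geometry, the genome list, the full
    species list, and an MD5 of the body, so diffs are deterministic and
    truncation is detectable.
    """
    body = _body_lines(db)
    digest = hashlib.md5("\n".join(body).encode()).hexdigest()
    genomes = ",".join(db.provenance.get("genomes", []))
    with open(path, "w") as fh:
        fh.write(_HEADER_MAGIC + "\n")
        fh.write(f"#enzyme\t{db.enzyme.name}\n")
        fh.write(f"#recognition\t{db.enzyme.recognition}\n")
        fh.write(f"#left_flank\t{db.enzyme.left_flank}\n")
        fh.write(f"#right_flank\t{db.enzyme.right_flank}\n")
        fh.write(f"#genomes\t{genomes}\n")
        fh.write(f"#species\t{','.join(db.species)}\n")
        fh.write(f"#md5\t{digest}\n")
        fh.write("marker\tspecies\n")
        for line in body:
            fh.write(line + "\n")


def load_database(path) -> MarkerDatabase:
    """Load a database written by :func:`save_database`; validates invariants."""
    path = Path(path)
    header: dict[str, str] = {}
    markers: dict[str, str] = {}
    body: list[str] = []
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _HEADER_MAGIC:
            raise ValueError(f"{path}:1: not a twobradm marker database")
        in_header = True
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            if in_header and line.startswith("#"):
                key, _, val = line[1:].partition("\t")
                header[key] = val
                continue
            if in_header:
                if line != "marker\tspecies":
                    raise ValueError(f"{path}:{lineno}: expected column header "
                                     f"'marker\\tspecies', got {line!r}")
                in_header = False
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            seq, sp = parts
            if seq in markers:
                raise ValueError(
                    f"{path}:{lineno}: marker {seq!r} already mapped to "
                    f"{markers[seq]!r}; a marker must map to exactly one species")
            markers[seq] = sp
            body.append(line)
    for key in ("enzyme", "recognition", "left_flank", "right_flank"):
        if key not in header:
            raise ValueError(f"{path}: missing header field #{key}")
    digest = hashlib.md5("\n".join(body).encode()).hexdigest()
    if "md5" in header and header["md5"] != digest:
        raise ValueError(f"{path}: content hash mismatch (file truncated or edited?)")
    enzyme = EnzymeSpec(name=header["enzyme"], recognition=header["recognition"],
                        left_flank=int(header["left_flank"]),
                        right_flank=int(header["right_flank"]))
    species = tuple(s for s in header.get("species", "").split(",") if s)
    genomes = [g for g in header.get("genomes", "").split(",") if g]
    counts = dict(Counter(markers.values()))
    if not species:
        species = tuple(sorted(counts))
    return MarkerDatabase(markers=markers, species_marker_count=counts,
                          enzyme=enzyme, species=species,
                          provenance={"genomes": genomes})
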