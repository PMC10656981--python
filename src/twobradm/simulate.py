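"""Synthetic genomes, communities, tag reads, and case-control studies.

Everything the pipeline consumes can be generated here with known
ground truth, so every stage is testable without downloading reference
genomes:

* :func:`make_genome` — a random background sequence guaranteed free of
  incidental recognition sites, with an exact number of planted sites.
* :func:`build_synthetic_reference` — a multi-species genome set with
  taxonomy, digested tags, and the resulting marker database.
* :func:`simulate_reads` — tag reads drawn from a community of known
  composition, with optional per-base substitution errors.  The
  per-species read weight is proportion x tag count (a genome-copy
  model: a genome contributes reads in proportion to how many tags it
  carries), which is exactly the bias the S/T marker normalization is
  meant to remove.
* :func:`make_case_control` — a two-group abundance study with planted
  fold changes on selected taxa over log-normal within-group noise.
  The default design mirrors an oral-mycobiome case-control study:
  26 cases vs 18 controls, a rare taxon 10x enriched in cases and the
  dominant taxon 10x depleted, log-noise sigma 0.5.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ecology import AbundanceStudy
from .enzymes import BCGI, EnzymeSpec, IUPAC_CODES, Tag, extract_tags, match_sites
from .markers import MarkerDatabase, TaxonomyRecord, build_database

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class CommunitySpec:
    """Ground-truth species proportions for simulation and recovery tests."""

    proportions: dict[str, float]
    seed: int = 0

    def __post_init__(self) -> None:
        vals = np.array(list(self.proportions.values()), dtype=float)
        if vals.size == 0 or (vals <= 0).any():
            raise ValueError("proportions must be positive")
        if abs(vals.sum() - 1.0) > 1e-12:
            raise ValueError(f"proportions must sum to 1, got {vals.sum()!r}")

    @property
    def species(self) -> list[str]:
        return list(self.proportions)


@dataclass(frozen=True)
class StudyDesign:
    """Design of a synthetic two-group abundance study.

    ``fold_changes`` multiplies the base proportion of selected taxa in
    case samples (values > 1 enrich, < 1 deplete); per-taxon log-normal
    noise with SD ``noise_sigma`` (natural-log scale) is applied to
    every sample before renormalization; ``depth`` reads are drawn
    multinomially per sample to form the count matrix.
    """

    base_proportions: CommunitySpec
    n_case: int = 26
    n_control: int = 18
    fold_changes: dict[str, float] = field(default_factory=dict)
    noise_sigma: float = 0.5
    depth: int = 50_000
    seed: int = 0
    kingdom: dict[str, str] | None = None
    phylum: dict[str, str] | None = None

    def __post_init__(self) -> None:
        unknown = set(self.fold_changes) - set(self.base_proportions.proportions)
        if unknown:
            raise ValueError(f"fold_changes for unknown taxa: {sorted(unknown)}")
        if any(f <= 0 for f in self.fold_changes.values()):
            raise ValueError("fold changes must be positive")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per group")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


# Saliva-like fungal community: the dominant taxon is depleted in cases
# and a rare Malassezia is enriched, the configuration under which a
# single species becomes a strong diagnostic marker.
_DEFAULT_FUNGI: dict[str, float] = {
    "Saccharomyces_cerevisiae": 0.700,
    "Candida_albicans": 0.070,
    "Malassezia_restricta": 0.040,
    "Candida_tropicalis": 0.030,
    "Aspergillus_fumigatus": 0.025,
    "Candida_parapsilosis": 0.020,
    "Cladosporium_herbarum": 0.018,
    "Penicillium_chrysogenum": 0.016,
    "Alternaria_alternata": 0.014,
    "Fusarium_oxysporum": 0.012,
    "Cryptococcus_neoformans": 0.010,
    "Rhodotorula_mucilaginosa": 0.009,
    "Debaryomyces_hansenii": 0.008,
    "Pichia_kudriavzevii": 0.007,
    "Wickerhamomyces_anomalus": 0.006,
    "Mucor_racemosus": 0.005,
    "Trichosporon_asahii": 0.005,
    "Malassezia_globosa": 0.005,
}

_BASIDIO = {"Malassezia_restricta", "Malassezia_globosa", "Cryptococcus_neoformans",
            "Rhodotorula_mucilaginosa", "Trichosporon_asahii"}
_MUCORO = {"Mucor_racemosus"}


def default_design(seed: int = 0) -> StudyDesign:
    """The package's default case-control design (26 cases vs 18 controls).

    Malassezia_globosa (base 0.5%) is 10x enriched in cases;
    Saccharomyces_cerevisiae (base 70%) is 10x depleted.
    """
    phylum = {sp: ("Basidiomycota" if sp in _BASIDIO
                   else "Mucoromycota" if sp in _MUCORO else "Ascomycota")
              for sp in _DEFAULT_FUNGI}
    return StudyDesign(
        base_proportions=CommunitySpec(dict(_DEFAULT_FUNGI), seed=seed),
        fold_changes={"Malassezia_globosa": 10.0, "Saccharomyces_cerevisiae": 0.1},
        noise_sigma=0.5,
        depth=50_000,
        seed=seed,
        kingdom={sp: "fungi" for sp in _DEFAULT_FUNGI},
        phylum=phylum,
    )


# ------------------------------------------------------------- genomes

def _random_bases(rng: np.random.Generator, n: int, gc_content: float) -> np.ndarray:
    p = np.array([(1 - gc_content) / 2, gc_content / 2,
                  gc_content / 2, (1 - gc_content) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _scrub_sites(seq: np.ndarray, enzyme: EnzymeSpec, rng: np.random.Generator,
                 gc_content: float, protected: frozenset[int] = frozenset(),
                 keep: set[tuple[int, str]] | None = None,
                 max_iter: int = 200) -> np.ndarray:
    """Re-randomize free bases until only the ``keep`` sites match."""
    keep = keep or set()
    plen = enzyme.pattern_length
    for _ in range(max_iter):
        text = _BASES[seq].tobytes().decode()
        spurious = [hit for hit in match_sites_all(text, enzyme) if hit not in keep]
        if not spurious:
            return seq
        for pos, _strand in spurious:
            free = [i for i in range(pos, pos + plen) if i not in protected]
            if not free:  # overlaps planted fixed bases entirely; redraw neighbors
                free = [i for i in range(max(0, pos - 1), min(len(seq), pos + plen + 1))
                        if i not in protected]
            seq[free] = _random_bases(rng, len(free), gc_content)
    raise RuntimeError("could not scrub incidental recognition sites")


def match_sites_all(sequence: str, enzyme: EnzymeSpec) -> list[tuple[int, str]]:
    """Recognition matches regardless of flank room (used while building genomes)."""
    hits = [(m.start(), "+") for m in enzyme.forward_regex.finditer(sequence)]
    hits += [(m.start(), "-") for m in enzyme.reverse_regex.finditer(sequence)]
    hits.sort()
    return hits


def make_genome(length: int, gc_content: float = 0.5, n_sites: int = 0,
                enzyme: EnzymeSpec = BCGI, seed: int | None = 0) -> str:
    """Random sequence with exactly ``n_sites`` planted recognition sites.

    The background is rejection-sampled to be free of incidental
    matches, then ``n_sites`` sites are planted (degenerate pattern
    positions filled with random bases) at non-overlapping tag windows,
    each with full flanks.  Raises if the requested sites cannot be
    packed into ``length``.  Deterministic per seed.
    """
    if not 0 < gc_content < 1:
        raise ValueError("gc_content must be in (0, 1)")
    rng = np.random.default_rng(seed)
    plen = enzyme.pattern_length
    seq = _random_bases(rng, length, gc_content)

    if n_sites == 0:
        seq = _scrub_sites(seq, enzyme, rng, gc_content)
        return _BASES[seq].tobytes().decode()

    smin = enzyme.left_flank
    smax = length - plen - enzyme.right_flank
    slack = (smax - smin) - (n_sites - 1) * enzyme.tag_length
    if smax < smin or slack < 0:
        raise ValueError(
            f"cannot pack {n_sites} non-overlapping tag windows into "
            f"length {length}")
    offsets = np.sort(rng.choice(slack + 1, size=n_sites, replace=False)) \
        if n_sites <= slack + 1 else np.zeros(n_sites, dtype=int)
    starts = smin + offsets + np.arange(n_sites) * enzyme.tag_length

    protected: set[int] = set()
    for s in starts:
        for k, code in enumerate(enzyme.recognition):
            allowed = [b"ACGT".index(c.encode()) for c in IUPAC_CODES[code]]
            if len(allowed) == 1:
                seq[s + k] = allowed[0]
                protected.add(int(s) + k)
            else:
                seq[s + k] = allowed[rng.integers(len(allowed))]
    keep = {(int(s), "+") for s in starts}
    seq = _scrub_sites(seq, enzyme, rng, gc_content,
                       protected=frozenset(protected), keep=keep)
    return _BASES[seq].tobytes().decode()


def build_synthetic_reference(species: list[str], tags_per_genome: int = 30,
                              genomes_per_species: int = 1,
                              genome_length: int | None = None,
                              enzyme: EnzymeSpec = BCGI, seed: int = 0):
    """Genomes + taxonomy + tags + marker database for a species list.

    Returns ``(genomes, taxonomy, tags_by_genome, db)`` where
    ``genomes`` maps genome_id -> sequence string.  Genome ids are
    ``<species>|g<k>``.  Each genome carries ``tags_per_genome`` planted
    sites; random backgrounds make cross-species tag collisions
    vanishingly unlikely, so nearly all tags become markers.
    """
    if genome_length is None:
        genome_length = tags_per_genome * (enzyme.tag_length + 10) + 200
    rng = np.random.default_rng(seed)
    genomes: dict[str, str] = {}
    taxonomy: dict[str, TaxonomyRecord] = {}
    tags_by_genome: dict[str, list[Tag]] = {}
    for sp in species:
        for k in range(genomes_per_species):
            gid = f"{sp}|g{k}"
            g = make_genome(genome_length, gc_content=0.5, n_sites=tags_per_genome,
                            enzyme=enzyme, seed=int(rng.integers(2**31 - 1)))
            genomes[gid] = g
            taxonomy[gid] = TaxonomyRecord(genome_id=gid, kingdom="bacteria",
                                           genus=sp.split("_")[0], species=sp)
            tags_by_genome[gid] = extract_tags({gid: g}, enzyme, genome_id=gid)
    db = build_database(tags_by_genome, taxonomy, enzyme)
    return genomes, taxonomy, tags_by_genome, db


# --------------------------------------------------------------- reads

def simulate_reads(tag_sets: dict[str, list[str]], community: CommunitySpec,
                   n_reads: int, error_rate: float = 0.0,
                   seed: int | None = 0) -> list[str]:
    """Draw tag reads from a community of known composition.

    A read's species is drawn with probability proportional to
    ``proportion x number of tags`` (genome-copy model), then a uniform
    tag of that species, then iid per-base substitution errors at
    ``error_rate``.  Returns the read sequences (all of tag length).
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    missing = [sp for sp in community.species if not tag_sets.get(sp)]
    if missing:
        raise ValueError(f"community species without tags: {missing}")
    rng = np.random.default_rng(seed)
    species = community.species
    weights = np.array([community.proportions[sp] * len(tag_sets[sp])
                        for sp in species], dtype=float)
    weights /= weights.sum()

    # encode each species' tags as a base-index matrix (n_tags x L)
    L = len(tag_sets[species[0]][0])
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    mats = {}
    for sp in species:
        enc = lut[np.frombuffer("".join(tag_sets[sp]).encode(), dtype=np.uint8)]
        mats[sp] = enc.reshape(len(tag_sets[sp]), L)

    counts = rng.multinomial(n_reads, weights)
    blocks = []
    for sp, c in zip(species, counts):
        if c == 0:
            continue
        idx = rng.integers(0, mats[sp].shape[0], c)
        blocks.append(mats[sp][idx])
    reads = np.concatenate(blocks, axis=0)
    reads = reads[rng.permutation(n_reads)]

    if error_rate > 0:
        mask = rng.random(reads.shape) < error_rate
        shift = rng.integers(1, 4, size=reads.shape, dtype=np.uint8)
        reads = np.where(mask, (reads + shift) % 4, reads)

    joined = _BASES[reads.astype(np.uint8)].tobytes()
    return [joined[i * L:(i + 1) * L].decode() for i in range(n_reads)]


# ------------------------------------------------------------- studies

def make_case_control(design: StudyDesign) -> AbundanceStudy:
    """Generate a two-group abundance study from a :class:`StudyDesign`.

    Per sample: base proportions, multiplied by the fold changes for
    case samples, perturbed by per-taxon log-normal noise, renormalized.
    The study's ``matrix`` holds these exact per-sample compositions;
    ``counts`` holds a multinomial draw of ``depth`` reads per sample.
    """
    base = np.array(list(design.base_proportions.proportions.values()), dtype=float)
    species = design.base_proportions.species
    if (base <= 0).any():
        raise ValueError("degenerate base proportions")
    fold = np.array([design.fold_changes.get(sp, 1.0) for sp in species])
    rng = np.random.default_rng(design.seed)

    sample_ids = [f"case_{i+1:02d}" for i in range(design.n_case)] + \
                 [f"control_{i+1:02d}" for i in range(design.n_control)]
    labels = ["case"] * design.n_case + ["control"] * design.n_control

    cols_p = {}
    cols_c = {}
    for sid, lab in zip(sample_ids, labels):
        p = base * (fold if lab == "case" else 1.0)
        if design.noise_sigma > 0:
            p = p * rng.lognormal(0.0, design.noise_sigma, len(p))
        p = p / p.sum()
        cols_p[sid] = p
        cols_c[sid] = rng.multinomial(design.depth, p)

    matrix = pd.DataFrame(cols_p, index=species)
    counts = pd.DataFrame(cols_c, index=species)
    groups = pd.Series(labels, index=sample_ids, name="group")
    kingdom = None if design.kingdom is None else pd.Series(design.kingdom)
    lineage = None
    if design.kingdom is not None or design.phylum is not None:
        lineage = pd.DataFrame(index=pd.Index(species, name="species"))
        if design.kingdom is not None:
            lineage["kingdom"] = pd.Series(design.kingdom)
        if design.phylum is not None:
            lineage["phylum"] = pd.Series(design.phylum)
    return AbundanceStudy(matrix=matrix, counts=counts, groups=groups,
                          kingdom=kingdom, lineage=lineage)
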