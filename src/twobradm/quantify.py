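"""Read assignment, G-score screening, and relative abundance.

For each species *i* in a sample:

* ``S_i`` — reads assigned to markers of species *i*,
* ``t_i`` — distinct markers of species *i* observed in the sample,
* ``T_i`` — markers of species *i* in the database,
* ``G_i = sqrt(S_i * t_i)`` — a joint depth/breadth score; species with
  ``G >= 5`` (inclusive, configurable) are screened in as candidate
  species to control false positives,
* relative abundance ``(S_i/T_i) / sum_j (S_j/T_j)`` over screened-in
  species.

The denominator normalization divides read counts by marker totals so
that genomes contributing more tags (larger genomes / deeper marker
sets) are not over-counted.  ``denominator_mode='database'`` uses T
(the default); ``'observed'`` uses t instead.

Matching is exact: each read is truncated to the tag length,
canonicalized, and looked up in the marker index; anything else counts
as unassigned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .enzymes import canonicalize, _ACGT
from .markers import MarkerDatabase

logger = logging.getLogger(__name__)

DEFAULT_G_THRESHOLD = 5.0


@dataclass
class SpeciesQuant:
    """Per-sample quantification record for one species."""

    species: str
    S: int
    t: int
    T: int
    g_score: float
    rel_abundance: float | None = None  # None when screened out


@dataclass
class SampleProfile:
    """All species quantifications for one sample plus read accounting."""

    sample_id: str
    quants: list[SpeciesQuant]
    n_reads_total: int
    n_reads_assigned: int
    screen_threshold: float = DEFAULT_G_THRESHOLD

    @property
    def screened(self) -> list[SpeciesQuant]:
        return [q for q in self.quants if q.rel_abundance is not None]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(q.species, q.S, q.t, q.T, q.g_score,
              float("nan") if q.rel_abundance is None else q.rel_abundance)
             for q in self.quants],
            columns=["species", "S", "t", "T", "g_score", "rel_abundance"],
        )


def g_score(S: int, t: int) -> float:
    """G score = sqrt(S * t); 0 when the species is unobserved."""
    if S < 0 or t < 0:
        raise ValueError(f"negative inputs to g_score: S={S}, t={t}")
    return math.sqrt(S * t)


def assign_reads(reads: Iterable, db: MarkerDatabase):
    """Exact-match reads against the marker index.

    ``reads`` is an iterable of sequences (strings or SeqRecord-like).
    Each read is truncated to the database tag length, canonicalized,
    and looked up; a hit increments its species' read count S and adds
    the marker to the species' observed set.  Reads that are too short,
    contain ambiguous bases, or match no marker are tallied unassigned.

    Returns ``(per_species, n_total, n_assigned)`` with ``per_species``
    a dict species -> (S, set of observed markers).
    """
    if not db.markers:
        raise ValueError("empty marker database")
    tag_len = db.enzyme.tag_length
    markers = db.markers
    per_species: dict[str, tuple[int, set]] = {}
    n_total = 0
    n_assigned = 0
    n_short = 0
    for read in reads:
        seq = read if isinstance(read, str) else str(read.seq)
        n_total += 1
        if len(seq) < tag_len:
            n_short += 1
            continue
        seq = seq[:tag_len].upper()
        if not _ACGT.issuperset(seq):
            continue
        rc = canonicalize(seq)
        sp = markers.get(rc)
        if sp is None:
            continue
        n_assigned += 1
        if sp in per_species:
            s, obs = per_species[sp]
            obs.add(rc)
            per_species[sp] = (s + 1, obs)
        else:
            per_species[sp] = (1, {rc})
    if n_total == 0:
        raise ValueError("no reads provided")
    if n_short:
        logger.info("assign_reads: %d read(s) shorter than tag length %d",
                    n_short, tag_len)
    return per_species, n_total, n_assigned


def screen_candidates(quants: list[SpeciesQuant],
                      threshold: float = DEFAULT_G_THRESHOLD,
                      inclusive: bool = True) -> list[SpeciesQuant]:
    """Species passing the G-score screen (``G >= threshold`` by default)."""
    if inclusive:
        return [q for q in quants if q.g_score >= threshold]
    return [q for q in quants if q.g_score > threshold]


def relative_abundance(screened: list[SpeciesQuant],
                       denominator_mode: str = "database") -> list[SpeciesQuant]:
    """Set ``rel_abundance = (S/T) / sum(S/T)`` on the screened-in quants.

    ``denominator_mode='database'`` divides by the database marker total
    T; ``'observed'`` divides by the in-sample marker count t.
    """
    if denominator_mode not in ("database", "observed"):
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    if not screened:
        return screened
    ratios = []
    for q in screened:
        denom = q.T if denominator_mode == "database" else q.t
        if denom <= 0:
            raise ValueError(f"species {q.species}: nonpositive denominator {denom}")
        ratios.append(q.S / denom)
    total = sum(ratios)
    if total <= 0:
        raise ValueError("all screened species have zero assigned reads")
    for q, r in zip(screened, ratios):
        q.rel_abundance = r / total
    return screened


def profile_sample(reads: Iterable, db: MarkerDatabase, sample_id: str = "sample",
                   threshold: float = DEFAULT_G_THRESHOLD, inclusive: bool = True,
                   denominator_mode: str = "database") -> SampleProfile:
    """Full per-sample quantification: assign, score, screen, normalize.

    Every species with markers in the database appears in the profile
    (S = t = 0 and G = 0 when unobserved); only screened-in species get
    a relative abundance.
    """
    per_species, n_total, n_assigned = assign_reads(reads, db)
    quants = []
    for sp in sorted(db.species_marker_count):
        S, obs = per_species.get(sp, (0, set()))
        t = len(obs)
        quants.append(SpeciesQuant(species=sp, S=S, t=t,
                                   T=db.species_marker_count[sp],
                                   g_score=g_score(S, t)))
    screened = screen_candidates(quants, threshold=threshold, inclusive=inclusive)
    if screened:
        relative_abundance(screened, denominator_mode=denominator_mode)
    else:
        logger.warning("sample %s: no species passed the G-score screen "
                       "(threshold %g)", sample_id, threshold)
    return SampleProfile(sample_id=sample_id, quants=quants,
                         n_reads_total=n_total, n_reads_assigned=n_assigned,
                         screen_threshold=threshold)


def profiles_to_matrices(profiles: list[SampleProfile]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge sample profiles into species x sample matrices.

    Returns ``(abundance, counts)``: screened-out species have abundance
    0; counts hold the raw assigned read counts S.
    """
    species = sorted({q.species for p in profiles for q in p.quants})
    samples = [p.sample_id for p in profiles]
    ab = pd.DataFrame(0.0, index=species, columns=samples)
    ct = pd.DataFrame(0, index=species, columns=samples)
    for p in profiles:
        for q in p.quants:
            if q.rel_abundance is not None:
                ab.loc[q.species, p.sample_id] = q.rel_abundance
            ct.loc[q.species, p.sample_id] = q.S
    return ab, ct
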