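"""In-silico MITE insertion polymorphism (MIP) typing.

The wet-lab assay amplifies across an insertion locus with flanking primers
and reads presence/absence off a gel: an occupied site yields a product
roughly element-sized longer than the empty site. Here the same decision is
made computationally: both flanks of a locus are located in an assembly and
the gap between them is compared to the element length. Occupied requires the
gap within +/-20% of the element length; empty requires the flanks to abut
(gap <= 50 bp, which accommodates the retained target-site duplication);
everything else — a missing flank, a multi-mapped flank, an off-size gap — is
ambiguous, just as the wet assay fails rather than mis-calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .align import DEFAULT_SCORING, AlignScoring, search_both_strands
from .config import PipelineConfig
from .discovery import MITECandidate
from .models import GenomeSequence, GenomicInterval

__all__ = [
    "MIPLocus",
    "MIPCall",
    "extract_loci",
    "type_locus",
    "polymorphism_summary",
]

log = logging.getLogger(__name__)

_EMPTY_MAX_GAP = 50  # bp; retained TSD plus slack
_OCCUPIED_TOL = 0.20  # fractional tolerance on the element-sized gap
_FLANK_MIN_IDENTITY = 0.90
_FLANK_MIN_COVERAGE = 0.80
_MULTIMAP_SCORE_RATIO = 0.90


@dataclass
class MIPLocus:
    locus_id: str
    left_flank: str
    right_flank: str
    element_len: int
    source: GenomicInterval


@dataclass
class MIPCall:
    locus_id: str
    assembly_id: str
    state: str  # occupied | empty | ambiguous
    observed_gap: int | None = None


def extract_loci(
    candidates: list[MITECandidate],
    genome: GenomeSequence,
    flank_len: int = 300,
) -> list[MIPLocus]:
    """Cut flank pairs around each candidate; candidates too close to a
    contig end are skipped with a warning."""
    loci: list[MIPLocus] = []
    for i, cand in enumerate(candidates, 1):
        iv = cand.element
        if iv.start < flank_len or iv.end + flank_len > len(genome):
            log.warning("locus %d skipped: insufficient flank near contig end", i)
            continue
        loci.append(
            MIPLocus(
                locus_id=f"locus{i}",
                left_flank=genome.residues[iv.start - flank_len : iv.start],
                right_flank=genome.residues[iv.end : iv.end + flank_len],
                element_len=iv.length,
                source=iv,
            )
        )
    return loci


def _locate_flank(flank: str, assembly: GenomeSequence, config: PipelineConfig,
                  scoring: AlignScoring):
    """Unique confident placement of a flank, or None (absent/multi-mapped)."""
    hits = search_both_strands(
        flank,
        assembly.residues,
        seed_len=config.seed_len_assembly,
        scoring=scoring,
        subject_id=assembly.id,
        query_id="flank",
    )
    good = [
        h
        for h in hits
        if h.identity >= _FLANK_MIN_IDENTITY and h.coverage >= _FLANK_MIN_COVERAGE
    ]
    if not good:
        return None
    if len(good) > 1 and good[1].score >= _MULTIMAP_SCORE_RATIO * good[0].score:
        return None  # the wet assay would also fail on a multi-mapping primer
    return good[0]


def type_locus(
    locus: MIPLocus,
    assembly: GenomeSequence,
    config: PipelineConfig,
    scoring: AlignScoring = DEFAULT_SCORING,
) -> MIPCall:
    """Type one locus in one assembly as occupied / empty / ambiguous."""
    left = _locate_flank(locus.left_flank, assembly, config, scoring)
    right = _locate_flank(locus.right_flank, assembly, config, scoring)
    if left is None or right is None:
        return MIPCall(locus.locus_id, assembly.id, "ambiguous")
    li, ri = left.subject_interval, right.subject_interval
    if li.seqid != ri.seqid or li.strand != ri.strand:
        return MIPCall(locus.locus_id, assembly.id, "ambiguous")
    if li.strand == "+":
        gap = ri.start - li.end
    else:
        gap = li.start - ri.end
    lo = int(locus.element_len * (1 - _OCCUPIED_TOL))
    hi = int(locus.element_len * (1 + _OCCUPIED_TOL))
    if lo <= gap <= hi:
        state = "occupied"
    elif gap <= _EMPTY_MAX_GAP:
        state = "empty"
    else:
        state = "ambiguous"
    return MIPCall(locus.locus_id, assembly.id, state, observed_gap=int(gap))


def polymorphism_summary(calls: list[MIPCall]) -> dict:
    """Summarize a locus x assembly call matrix.

    A locus is *amplified* when it has at least one non-ambiguous call,
    *polymorphic* when both occupied and empty states occur among its
    non-ambiguous calls, and *shared-occupied* when it is occupied in two or
    more assemblies. Percentages are rounded half away from zero.
    """
    assemblies = {c.assembly_id for c in calls}
    if len(assemblies) < 2:
        raise ValueError("polymorphism summary needs >= 2 assemblies")
    by_locus: dict[str, list[MIPCall]] = {}
    for c in calls:
        by_locus.setdefault(c.locus_id, []).append(c)

    n_loci = len(by_locus)
    amplified = polymorphic = shared_occupied = 0
    for lcalls in by_locus.values():
        states = [c.state for c in lcalls if c.state != "ambiguous"]
        if not states:
            continue
        amplified += 1
        if "occupied" in states and "empty" in states:
            polymorphic += 1
        if sum(1 for s in states if s == "occupied") >= 2:
            shared_occupied += 1

    def pct(num: int, den: int) -> int | None:
        if den == 0:
            return None
        return int(100.0 * num / den + 0.5)

    return {
        "n_loci": n_loci,
        "n_assemblies": len(assemblies),
        "n_amplified": amplified,
        "pct_amplified": pct(amplified, n_loci),
        "n_polymorphic": polymorphic,
        "pct_polymorphic_of_amplified": pct(polymorphic, amplified),
        "n_shared_occupied": shared_occupied,
        "pct_shared_occupied_of_amplified": pct(shared_occupied, amplified),
    }


def calls_to_frame(calls: list[MIPCall]) -> pd.DataFrame:
    rows = [
        {
            "locus_id": c.locus_id,
            "assembly_id": c.assembly_id,
            "state": c.state,
            "observed_gap": c.observed_gap,
        }
        for c in calls
    ]
    return pd.DataFrame(rows)
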