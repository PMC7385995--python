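"""Copy-number estimation from assemblies and from read depth.

Two estimators mirror common repeat-biology practice:

* intact-copy counting — a family consensus is swept across an assembly
  (both strands) and hits with identity >= 80% over >= 80% of the consensus
  are counted as intact copies;
* read-depth quantification — whole-genome reads are mapped to the consensus
  (kept when identity > 80% over > 50% of the read length), per-position depth
  is averaged over the central 80% of the consensus, and the result is
  normalized by haploid genome coverage (total read bases / genome size) to
  yield copies per haploid genome.

The inequality strictness intentionally differs between the two (>= for
assemblies, strict > for reads).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import (
    DEFAULT_SCORING,
    AlignScoring,
    AlignmentResult,
    SeedIndex,
    revcomp,
    sanitize,
    search_both_strands,
    seeded_local_align,
)
from .config import PipelineConfig
from .models import GenomeSequence

__all__ = [
    "CopyEstimate",
    "DepthProfile",
    "find_intact_copies",
    "map_reads",
    "estimate_haploid_coverage",
    "copy_number_from_depth",
    "genome_specificity",
]

log = logging.getLogger(__name__)


@dataclass
class CopyEstimate:
    family_id: str
    genome_id: str
    intact_count: int
    depth_copies: float = float("nan")
    mean_element_depth: float = float("nan")
    haploid_coverage: float = float("nan")


@dataclass
class DepthProfile:
    """Per-position read depth over a family consensus."""

    family_id: str
    depth: np.ndarray
    n_mapped: int = 0
    n_unmapped: int = 0

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=int)
        if (self.depth < 0).any():
            raise ValueError("negative depth")


def find_intact_copies(
    consensus: str,
    genome: GenomeSequence,
    config: PipelineConfig,
    scoring: AlignScoring = DEFAULT_SCORING,
) -> list[AlignmentResult]:
    """Non-overlapping intact hits of a consensus in an assembly (both strands)."""
    if len(consensus) < 50:
        raise ValueError("consensus too short for intact-copy search")
    hits = search_both_strands(
        consensus,
        genome.residues,
        seed_len=config.seed_len_assembly,
        scoring=scoring,
        subject_id=genome.id,
        query_id="consensus",
    )
    out = [
        h
        for h in hits
        if h.identity >= config.intact_min_identity
        and h.coverage >= config.intact_min_coverage
    ]
    # search_both_strands already keeps best-score non-overlapping hits
    out.sort(key=lambda h: h.subject_interval.start)
    return out


def map_reads(
    reads: list[tuple[str, str]] | list[str],
    consensus: str,
    config: PipelineConfig,
    scoring: AlignScoring = DEFAULT_SCORING,
    family_id: str = "family",
) -> DepthProfile:
    """Map reads to a consensus and accumulate per-position depth.

    Each read is searched against both strands of the consensus; only its
    best-scoring hit contributes, and only when identity > read_min_identity
    and aligned read fraction > read_min_coverage.
    """
    if not reads:
        raise ValueError("no reads supplied")
    seqs = [r[1] if isinstance(r, tuple) else r for r in reads]
    cons = sanitize(consensus)
    k = config.seed_len_read
    idx_fwd = SeedIndex(cons, k, "consensus")
    idx_rev = SeedIndex(revcomp(cons), k, "consensus_rc")
    n = len(cons)
    depth = np.zeros(n, dtype=int)
    n_mapped = 0
    for seq in seqs:
        if len(seq) < k:
            continue
        best = None
        for idx, is_rc in ((idx_fwd, False), (idx_rev, True)):
            for h in seeded_local_align(seq, idx, scoring=scoring):
                if best is None or h.score > best[0].score:
                    best = (h, is_rc)
        if best is None:
            continue
        h, is_rc = best
        if not (h.identity > config.read_min_identity and h.coverage > config.read_min_coverage):
            continue
        s, e = h.subject_interval.start, h.subject_interval.end
        if is_rc:
            s, e = n - e, n - s
        depth[s:e] += 1
        n_mapped += 1
    n_unmapped = len(seqs) - n_mapped
    if n_unmapped:
        log.info("map_reads: %d/%d reads unmapped", n_unmapped, len(seqs))
    return DepthProfile(family_id=family_id, depth=depth, n_mapped=n_mapped, n_unmapped=n_unmapped)


def estimate_haploid_coverage(total_read_bases: float, genome_size: float) -> float:
    """Total sequenced bases divided by haploid genome size."""
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    if total_read_bases == 0:
        log.warning("zero read bases: haploid coverage is 0")
        return 0.0
    if total_read_bases < 0:
        raise ValueError("negative read bases")
    return total_read_bases / genome_size


def copy_number_from_depth(profile: DepthProfile, haploid_coverage: float) -> float:
    """Copies per haploid genome from a depth profile.

    The consensus termini systematically under-recruit reads, so the mean is
    taken over the central 80% of positions (10% trimmed at each end) before
    normalizing by haploid coverage.
    """
    if haploid_coverage <= 0:
        raise ValueError("haploid coverage must be positive")
    d = profile.depth
    trim = len(d) // 10
    core = d[trim : len(d) - trim] if len(d) > 2 * trim else d
    return float(core.mean()) / haploid_coverage


def genome_specificity(estimates: list[CopyEstimate]) -> pd.DataFrame:
    """Fold-difference of intact counts between the top genome and the rest.

    For each family, the genome with the highest intact count is the
    reference; every other genome gets fold = max_count / its count
    (NA when its count is zero). ``fold_display`` is the integer floor used
    for reporting.
    """
    rows = []
    by_family: dict[str, list[CopyEstimate]] = {}
    for est in estimates:
        by_family.setdefault(est.family_id, []).append(est)
    for family_id, ests in by_family.items():
        if len(ests) < 2:
            continue
        top = max(ests, key=lambda e: e.intact_count)
        for e in ests:
            if e.genome_id == top.genome_id:
                continue
            fold = top.intact_count / e.intact_count if e.intact_count > 0 else np.nan
            rows.append(
                {
                    "family_id": family_id,
                    "top_genome": top.genome_id,
                    "top_count": top.intact_count,
                    "other_genome": e.genome_id,
                    "other_count": e.intact_count,
                    "fold": fold,
                    "fold_display": "NA" if np.isnan(fold) else int(fold),
                }
            )
    return pd.DataFrame(rows)
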