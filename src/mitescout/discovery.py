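"""De novo MITE detection, family clustering and superfamily classification.

MITEs are short (< 1 kb), AT-rich, non-autonomous class II elements bounded by
terminal inverted repeats (TIRs >= 10 bp) and flanked by a 2-10 bp target site
duplication (TSD). The scan below detects candidate elements directly from
that structural definition: an exact 8-mer inverted-repeat seed anchors each
putative TIR pair, the repeat is extended outward base-exactly, element
boundaries are refined to the trim that maximizes the flanking TSD, and the
maximal TIR length with >= 90% arm agreement (Hamming, no indels) is reported.

Diverged family members whose TIRs have eroded are not structurally visible;
:func:`discover_elements` therefore follows the field's two-stage practice:
structural scan -> single-linkage family clustering -> per-family consensus ->
homology sweep for intact copies.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass

from .align import (
    DEFAULT_SCORING,
    AlignScoring,
    progressive_msa,
    revcomp,
    sanitize,
)
from .config import PipelineConfig
from .models import GenomeSequence, GenomicInterval

__all__ = [
    "MITECandidate",
    "MITEFamily",
    "at_content",
    "find_tir_candidates",
    "detect_tsd",
    "cluster_families",
    "classify_superfamily",
    "discover_elements",
]

log = logging.getLogger(__name__)

_TIR_SEED = 8
_UNAMBIG = frozenset("ACGT")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class MITECandidate:
    """One detected element with its TIR/TSD evidence."""

    element: GenomicInterval
    sequence: str
    tir_len: int
    tir_identity: float
    tsd: str | None
    at_fraction: float
    family_id: str | None = None

    @property
    def length(self) -> int:
        return self.element.length


@dataclass
class MITEFamily:
    family_id: str
    members: list[MITECandidate]
    consensus: str
    superfamily: str = "unknown"
    tsd_len_mode: int | None = None

    @property
    def size(self) -> int:
        return len(self.members)


def at_content(seq: str) -> float:
    """(A + T) / unambiguous bases; errors when no unambiguous base exists."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    unamb = sum(seq.count(b) for b in "ACGT")
    if unamb == 0:
        raise ValueError("AT content undefined for all-ambiguous sequence")
    return (seq.count("A") + seq.count("T")) / unamb


# ---------------------------------------------------------------------------
# structural scan
# ---------------------------------------------------------------------------


def _longest_exact_dup(s: str, start: int, end: int, lo: int, hi: int) -> str | None:
    """Longest exact duplication (length in [lo, hi]) flanking [start, end)."""
    for L in range(hi, lo - 1, -1):
        if start - L < 0 or end + L > len(s):
            continue
        left = s[start - L : start]
        right = s[end : end + L]
        if left == right and set(left) <= _UNAMBIG:
            return left
    return None


def detect_tsd(genome: GenomeSequence, candidate: MITECandidate, config: PipelineConfig) -> str | None:
    """Longest exact target-site duplication immediately flanking the element."""
    lo, hi = config.tsd_len_range
    iv = candidate.element
    if iv.start < hi or iv.end + hi > len(genome):
        log.warning("candidate at %s:%d has insufficient flank for TSD search", iv.seqid, iv.start)
        return None
    return _longest_exact_dup(genome.residues, iv.start, iv.end, lo, hi)


def _tir_length(s: str, start: int, end: int, config: PipelineConfig) -> tuple[int, float]:
    """Maximal TIR length at fixed element bounds with >= 90% arm agreement.

    Agreement is Hamming (no indels) between the 5' arm and the reverse
    complement of the 3' arm; a reported TIR always ends on a matching pair.
    """
    max_t = min(config.max_tir_len, (end - start) // 2)
    mismatches = 0
    best_t, best_id = 0, 0.0
    for k in range(max_t):
        a = s[start + k]
        b = s[end - 1 - k]
        matched = a in _UNAMBIG and b in _UNAMBIG and _COMP[b] == a
        if not matched:
            mismatches += 1
        t = k + 1
        if matched and t >= config.min_tir_len and mismatches <= int(0.10 * t):
            best_t, best_id = t, 1.0 - mismatches / t
    return best_t, best_id


def find_tir_candidates(genome: GenomeSequence, config: PipelineConfig) -> list[MITECandidate]:
    """Scan one sequence for TIR/TSD-bounded MITE candidates.

    Inverted-repeat structure is strand-symmetric, so a single forward scan
    finds elements regardless of their insertion orientation.
    """
    s = sanitize(genome.residues)
    n = len(s)
    k = _TIR_SEED
    if n < config.min_element_len:
        return []

    index: dict[str, list[int]] = defaultdict(list)
    for i in range(n - k + 1):
        w = s[i : i + k]
        if "N" not in w:
            index[w].append(i)

    min_el, max_el = config.min_element_len, config.max_element_len
    lo_tsd, hi_tsd = config.tsd_len_range
    seen_bounds: set[tuple[int, int]] = set()
    raw: list[MITECandidate] = []

    import bisect

    lo_off = max(50, min_el - 2 * config.max_tir_len) - k
    hi_off = max_el - k
    seed_pairs: list[tuple[int, int]] = []
    for w, pps in index.items():
        positions = index.get(revcomp(w))
        if not positions:
            continue
        for p in pps:
            i0 = bisect.bisect_left(positions, p + lo_off)
            i1 = bisect.bisect_right(positions, p + hi_off)
            seed_pairs.extend((p, q) for q in positions[i0:i1])
    for p, q in seed_pairs:
        c = p + q + k - 1  # paired positions satisfy i + j == c
        # extend outward base-exactly
        i = p - 1
        while i >= 0 and c - i < n:
            j = c - i
            a, b = s[i], s[j]
            if a in _UNAMBIG and b in _UNAMBIG and _COMP[b] == a:
                i -= 1
            else:
                break
        s0 = i + 1
        e0 = c - s0 + 1
        if (s0, e0) in seen_bounds:
            continue
        seen_bounds.add((s0, e0))
        length = e0 - s0
        if not (min_el <= length <= max_el):
            continue
        outward_ext = p - s0  # exact outward steps available for trimming
        # Boundary refinement. Outward extension overshoots the true element
        # boundary whenever the flanking TSD bases happen to continue the
        # inverted repeat, so each symmetric trim delta is offered a chance to
        # expose the real TSD. Chance duplications at wrong boundaries are
        # almost always 2-3 bp, so the first trim showing a >= 4 bp TSD wins;
        # otherwise the first trim with any TSD; otherwise the maximal bounds.
        options = []
        for delta in range(0, min(6, outward_ext) + 1):
            st, en = s0 + delta, e0 - delta
            if en - st < min_el:
                break
            options.append((st, en, _longest_exact_dup(s, st, en, lo_tsd, hi_tsd)))
        chosen = next((o for o in options if o[2] and len(o[2]) >= 4), None)
        if chosen is None:
            chosen = next((o for o in options if o[2]), None)
        if chosen is None:
            chosen = (s0, e0, None)
        st, en, tsd = chosen
        tir_len, tir_id = _tir_length(s, st, en, config)
        if tir_len < config.min_tir_len:
            continue
        seq = s[st:en]
        try:
            atf = at_content(seq)
        except ValueError:
            continue
        raw.append(
            MITECandidate(
                element=GenomicInterval(genome.id, st, en),
                sequence=seq,
                tir_len=tir_len,
                tir_identity=tir_id,
                tsd=tsd,
                at_fraction=atf,
            )
        )

    # overlap resolution: keep longest TIR, then leftmost start
    raw.sort(key=lambda cand: (-cand.tir_len, cand.element.start))
    kept: list[MITECandidate] = []
    for cand in raw:
        if any(cand.element.overlaps(other.element) for other in kept):
            continue
        kept.append(cand)
    kept.sort(key=lambda cand: cand.element.start)
    return kept


# ---------------------------------------------------------------------------
# family clustering
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _pair_identity_coverage(a: str, b: str, scoring: AlignScoring) -> tuple[float, float]:
    """Best local-alignment identity and coverage of the shorter sequence.

    Local (not end-to-end) alignment matters here: a global alignment free to
    gap can align an LCS-like subsequence of two unrelated same-composition
    sequences at deceptively high gap-excluded identity, whereas a local
    alignment of unrelated sequences stays short and fails the coverage bar.
    """
    query, subject = (a, b) if len(a) <= len(b) else (b, a)
    from .align import seeded_local_align

    hits = seeded_local_align(query, subject, seed_len=12, scoring=scoring)
    if not hits:
        return 0.0, 0.0
    best = hits[0]
    return best.identity, best.coverage


def cluster_families(
    candidates: list[MITECandidate],
    config: PipelineConfig,
    scoring: AlignScoring = DEFAULT_SCORING,
) -> list[MITEFamily]:
    """Single-linkage clustering of candidates into families.

    An edge joins two candidates when their global identity is at least
    ``intact_min_identity`` over at least ``intact_min_coverage`` of the
    shorter sequence. A shared-k-mer prefilter avoids aligning pairs that
    cannot possibly clear the identity bar. Family ids are assigned in
    size-descending order; each family's consensus is the per-column majority
    over a progressive alignment of its members.
    """
    n = len(candidates)
    if n == 0:
        return []
    uf = _UnionFind(n)

    # inverted k-mer index -> shared-kmer pair counts
    kmer_owners: dict[str, list[int]] = defaultdict(list)
    K = 8
    for i, cand in enumerate(candidates):
        for kmer in {cand.sequence[j : j + K] for j in range(len(cand.sequence) - K + 1)}:
            kmer_owners[kmer].append(i)
    shared: Counter = Counter()
    for owners in kmer_owners.values():
        if len(owners) < 2 or len(owners) > 200:
            continue
        for ai in range(len(owners)):
            for bi in range(ai + 1, len(owners)):
                shared[(owners[ai], owners[bi])] += 1

    # adaptive prefilter: at >= 80% identity roughly a third of the shorter
    # sequence's 8-mers survive intact in both copies, while unrelated
    # same-composition pairs share only a thin low-complexity tail
    def min_shared(i: int, j: int) -> int:
        shorter = min(len(candidates[i].sequence), len(candidates[j].sequence))
        return max(15, int(0.10 * (shorter - 7)))

    # strongest pairs first so real families union early and the rest of
    # their pairs are skipped as already-connected
    for (i, j), cnt in sorted(shared.items(), key=lambda kv: (-kv[1], kv[0])):
        if cnt < min_shared(i, j) or uf.find(i) == uf.find(j):
            continue
        ident, cov = _pair_identity_coverage(candidates[i].sequence, candidates[j].sequence, scoring)
        if ident >= config.intact_min_identity and cov >= config.intact_min_coverage:
            uf.union(i, j)

    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        groups[uf.find(i)].append(i)
    ordered = sorted(
        groups.values(),
        key=lambda g: (-len(g), min(candidates[i].element.start for i in g)),
    )

    families: list[MITEFamily] = []
    for fi, group in enumerate(ordered, 1):
        members = [candidates[i] for i in sorted(group)]
        consensus = build_family_consensus([m.sequence for m in members], scoring)
        fam = MITEFamily(family_id=f"MITE-{fi}", members=members, consensus=consensus)
        for m in members:
            m.family_id = fam.family_id
        classify_superfamily(fam, config)
        families.append(fam)
    return families


def build_family_consensus(seqs: list[str], scoring: AlignScoring = DEFAULT_SCORING) -> str:
    """Majority consensus over the length-coherent core of a member set.

    Truncated fragments and chance boundary over-extensions stagger a
    progressive alignment and shred a naive majority consensus, so members far
    from the median length are left out of the vote (they remain family
    members), the longest core member seeds the profile, and columns carried
    by fewer than half of the core rows are dropped.
    """
    if not seqs:
        raise ValueError("no sequences")
    if len(seqs) == 1:
        return seqs[0]
    lens = sorted(len(x) for x in seqs)
    median_len = lens[len(lens) // 2]
    core = [x for x in seqs if 0.85 * median_len <= len(x) <= 1.15 * median_len]
    if len(core) < 2:
        core = list(seqs)
    if len(core) == 1:
        return core[0]
    core.sort(key=len, reverse=True)
    from .phylo import majority_consensus_row  # late import: no cycle at module load

    msa = progressive_msa(core, scoring)
    return majority_consensus_row(msa, min_occupancy=0.5).replace("-", "")


def classify_superfamily(family: MITEFamily, config: PipelineConfig | None = None) -> str:
    """Assign a superfamily label from the family's modal TSD.

    The 8 bp TSD is the hAT signature; other rules (TA -> Tc1/mariner,
    TTA/TAA -> PIF/Harbinger, 9-11 bp -> Mutator) are editable defaults in the
    config rule table. Families with no TSD-bearing member stay "unknown".
    """
    rules = (config.superfamily_rules if config else None) or {
        "motifs": {}, "lengths": {}
    }
    tsds = [m.tsd for m in family.members if m.tsd]
    if not tsds:
        family.superfamily = "unknown"
        family.tsd_len_mode = None
        return family.superfamily
    len_counts = Counter(len(t) for t in tsds)
    modal_len = min(
        len_counts, key=lambda L: (-len_counts[L], L)
    )
    family.tsd_len_mode = modal_len
    motif_counts = Counter(t for t in tsds if len(t) == modal_len)
    modal_motif = min(motif_counts, key=lambda m: (-motif_counts[m], m))
    motifs = rules.get("motifs", {})
    lengths = rules.get("lengths", {})
    if modal_motif in motifs:
        family.superfamily = motifs[modal_motif]
    elif modal_len in lengths:
        family.superfamily = lengths[modal_len]
    else:
        family.superfamily = "unknown"
    return family.superfamily


# ---------------------------------------------------------------------------
# end-to-end discovery
# ---------------------------------------------------------------------------


def discover_elements(
    genome: GenomeSequence,
    config: PipelineConfig,
    scoring: AlignScoring = DEFAULT_SCORING,
) -> list[MITEFamily]:
    """Full discovery pipeline on one genome sequence.

    Structural candidates are clustered into families; families with fewer
    than ``min_family_size`` structurally crisp members are dropped as chance
    inverted repeats; each surviving family's consensus is then swept across
    the genome for intact copies (>= 80% identity over >= 80% of the
    consensus), which recovers members whose TIRs or TSDs have degraded. The
    consensus is refined once: it is rebuilt from the first sweep's
    boundary-snapped members (whose edges are far more coherent than the
    structural candidates') and the sweep is repeated with it. Returned
    families carry the final member set.
    """
    from .copynum import find_intact_copies

    candidates = find_tir_candidates(genome, config)
    families = [
        f
        for f in cluster_families(candidates, config, scoring)
        if f.size >= config.min_family_size
    ]
    lo_tsd, hi_tsd = config.tsd_len_range
    s = genome.residues
    offsets = sorted(
        ((dl, dr) for dl in range(-3, 4) for dr in range(-3, 4)),
        key=lambda o: (abs(o[0]) + abs(o[1]), o),
    )

    def tsd_options(start: int, end: int) -> list[tuple[int, int, str]]:
        """Nearby boundary shifts that expose an exact flanking duplication."""
        opts = []
        for dl, dr in offsets:
            st, en = start + dl, end + dr
            if st < hi_tsd or en + hi_tsd > len(s) or en - st < config.min_element_len:
                continue
            tsd = _longest_exact_dup(s, st, en, lo_tsd, hi_tsd)
            if tsd:
                opts.append((st, en, tsd))
        return opts

    def trim_to_tir(cons: str, max_trim: int = 50) -> str:
        """Cut a flank-padded consensus back to its TIR-bounded element.

        The element must begin with an exact inverted-repeat pair in a
        majority consensus; the longest exact complementary run over all
        end-trim combinations marks the boundaries (ties prefer the least
        trimming).
        """
        L = len(cons)
        best_key: tuple[int, int, int] | None = None
        best_ab = (0, 0)
        for a in range(0, min(max_trim, L // 2) + 1):
            for b in range(0, min(max_trim, L // 2) + 1):
                span = L - a - b
                if span < config.min_element_len:
                    continue
                run = 0
                limit = min(config.max_tir_len, span // 2)
                while run < limit:
                    x, y = cons[a + run], cons[L - b - 1 - run]
                    if x in _UNAMBIG and y in _UNAMBIG and _COMP[y] == x:
                        run += 1
                    else:
                        break
                if run >= config.min_tir_len:
                    key = (run, -(a + b), -a)
                    if best_key is None or key > best_key:
                        best_key = key
                        best_ab = (a, b)
        if best_key is None:
            return cons
        a, b = best_ab
        return cons[a : L - b]

    def exact_tir_run(start: int, end: int) -> int:
        run = 0
        limit = min(config.max_tir_len, (end - start) // 2)
        while run < limit:
            x, y = s[start + run], s[end - 1 - run]
            if x in _UNAMBIG and y in _UNAMBIG and _COMP[y] == x:
                run += 1
            else:
                break
        return run

    def snap_bounds(start: int, end: int) -> tuple[int, int]:
        """Nudge homology-hit bounds onto the TIR/TSD joint optimum.

        Candidate boundary shifts are scored by TSD length plus twice the
        exact terminal inverted-repeat run starting there. Along the symmetric
        shift axis the decoys exactly tie the true boundary (one step outward
        trades 2 bp of TSD for at most 1 bp of chance TIR; one step inward
        trades 1 bp of in-register TIR for at most 2 bp of chance TSD), so the
        smaller-shift tie-break lands on the truth; any asymmetric shift
        destroys the TIR register entirely and scores far lower.
        """
        best_key = (
            len(_longest_exact_dup(s, start, end, lo_tsd, hi_tsd) or "")
            + 2 * exact_tir_run(start, end),
            0,
        )
        best = (start, end)
        for st, en, tsd in tsd_options(start, end):
            score = len(tsd) + 2 * exact_tir_run(st, en)
            cost = abs(st - start) + abs(en - end)
            key = (score, -cost)
            if key > best_key:
                best_key = key
                best = (st, en)
        return best

    def sweep(consensus: str, family_id: str) -> list[MITECandidate]:
        hits = find_intact_copies(consensus, genome, config, scoring)
        members: list[MITECandidate] = []
        for h in hits:
            st, en = snap_bounds(h.subject_interval.start, h.subject_interval.end)
            iv = GenomicInterval(genome.id, st, en, h.strand)
            seq = s[iv.start : iv.end]
            cand = MITECandidate(
                element=iv,
                sequence=seq,
                tir_len=0,
                tir_identity=0.0,
                tsd=None,
                at_fraction=at_content(seq),
                family_id=family_id,
            )
            cand.tir_len, cand.tir_identity = _tir_length(s, iv.start, iv.end, config)
            cand.tsd = detect_tsd(genome, cand, config)
            members.append(cand)
        members.sort(key=lambda m: m.element.start)
        return members

    def padded_sequences(members: list[MITECandidate], pad: int = 25) -> list[str]:
        # Rebuilding a consensus from reported member intervals bakes any
        # systematic boundary truncation into the next round. Padding each
        # extraction with flanking genome sequence guarantees the true element
        # edges are present in every row; the pads are mutually unrelated, so
        # their majority columns are weak junk that local alignment clips when
        # the refined consensus is swept.
        out = []
        for m in members:
            st = max(0, m.element.start - pad)
            en = min(len(s), m.element.end + pad)
            out.append(s[st:en])
        return out

    swept: list[MITEFamily] = []
    for fam in families:
        consensus = fam.consensus
        members = sweep(consensus, fam.family_id)
        if members:
            # round 2: flank-padded rebuild recovers boundary truncation
            # baked into the structural candidates, then TIR trimming removes
            # the pads
            refined = trim_to_tir(
                build_family_consensus(padded_sequences(members), scoring)
            )
            if refined != consensus:
                consensus = refined
                members = sweep(consensus, fam.family_id) or members
        if members:
            # round 3: the snapped member boundaries are now coherent, so a
            # plain rebuild converges on the exact element and the final sweep
            # lands hits on it directly
            refined = build_family_consensus([m.sequence for m in members], scoring)
            if refined != consensus:
                consensus = refined
                members = sweep(consensus, fam.family_id) or members
        out = MITEFamily(
            family_id=fam.family_id,
            members=members if members else fam.members,
            consensus=consensus,
        )
        classify_superfamily(out, config)
        swept.append(out)
    return swept
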