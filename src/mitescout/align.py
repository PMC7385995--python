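"""Shared pairwise-alignment machinery.

Global affine-gap alignment, k-mer seeded local search (a desk-scale stand-in
for a BLASTn-style homology scan), and a simple progressive multiple aligner.
The dynamic programming itself is delegated to Bio.Align.PairwiseAligner;
seeding, chaining, hit merging and the progressive strategy live here.

Conventions
-----------
* ``identity`` is the fraction of gap-free aligned columns whose residues are
  equal; N and IUPAC ambiguity codes never match anything, including
  themselves.
* ``coverage`` is the aligned query span divided by the query length, so a
  consensus searched against a genome is covered relative to the consensus and
  a read mapped to a consensus is covered relative to the read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .models import GenomicInterval

__all__ = [
    "AlignScoring",
    "AlignmentResult",
    "MultipleAlignment",
    "SeedIndex",
    "revcomp",
    "global_align",
    "seeded_local_align",
    "search_both_strands",
    "progressive_msa",
]

log = logging.getLogger(__name__)

_ALPHABET = "ACGTNRYSWKMBDHV"
_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")
_UNAMBIG = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def sanitize(seq: str) -> str:
    """Uppercase and map any non-IUPAC character to N."""
    s = seq.upper()
    if all(c in _ALPHABET for c in s):
        return s
    return "".join(c if c in _ALPHABET else "N" for c in s)


@dataclass(frozen=True)
class AlignScoring:
    """Affine-gap scoring; a gap of length L scores open + (L-1) * extend."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")


DEFAULT_SCORING = AlignScoring()


@dataclass
class AlignmentResult:
    query_interval: GenomicInterval
    subject_interval: GenomicInterval
    aligned_query: str
    aligned_subject: str
    score: float
    identity: float
    coverage: float

    @property
    def strand(self) -> str:
        return self.subject_interval.strand


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows over an ordered taxon list."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows of unequal length")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon ids")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


# ---------------------------------------------------------------------------
# pairwise alignment
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _substitution_matrix(match: float, mismatch: float):
    m = substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            m[a, b] = match if (a == b and a in _UNAMBIG) else mismatch
    return m


def _aligner(scoring: AlignScoring, mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = _substitution_matrix(scoring.match, scoring.mismatch)
    al.open_gap_score = scoring.gap_open
    al.extend_gap_score = scoring.gap_extend
    al.mode = mode
    return al


def _gapped_strings(aln, query: str, subject: str, full: bool = False):
    """Rebuild gapped strings from block coordinates.

    With ``full`` (global mode) leading/trailing end gaps are materialized so
    the gapped strings cover both sequences end to end; otherwise only the
    aligned region is returned (local mode).
    """
    qblocks, sblocks = aln.aligned
    if len(qblocks) == 0:
        return "", "", (0, 0), (0, 0)
    qa: list[str] = []
    sa: list[str] = []
    prev_q = 0 if full else int(qblocks[0][0])
    prev_s = 0 if full else int(sblocks[0][0])
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        if qs > prev_q:
            qa.append(query[prev_q:qs])
            sa.append("-" * (qs - prev_q))
        if ss > prev_s:
            sa.append(subject[prev_s:ss])
            qa.append("-" * (ss - prev_s))
        qa.append(query[qs:qe])
        sa.append(subject[ss:se])
        prev_q, prev_s = qe, se
    if full:
        if prev_q < len(query):
            qa.append(query[prev_q:])
            sa.append("-" * (len(query) - prev_q))
        if prev_s < len(subject):
            sa.append(subject[prev_s:])
            qa.append("-" * (len(subject) - prev_s))
    qspan = (int(qblocks[0][0]), int(qblocks[-1][1]))
    sspan = (int(sblocks[0][0]), int(sblocks[-1][1]))
    return "".join(qa), "".join(sa), qspan, sspan


def _identity(aq: str, asub: str) -> float:
    aligned = matched = 0
    for x, y in zip(aq, asub):
        if x == "-" or y == "-":
            continue
        aligned += 1
        if x == y and x in _UNAMBIG:
            matched += 1
    return matched / aligned if aligned else 0.0


def global_align(
    a: str,
    b: str,
    scoring: AlignScoring = DEFAULT_SCORING,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentResult:
    """Optimal end-to-end alignment of two sequences under affine gap scoring."""
    if not a or not b:
        raise ValueError("global_align requires two nonempty sequences")
    a = sanitize(a)
    b = sanitize(b)
    aln = _aligner(scoring, "global").align(a, b)[0]
    aq, asub, qspan, sspan = _gapped_strings(aln, a, b, full=True)
    return AlignmentResult(
        query_interval=GenomicInterval(query_id, 0, len(a)),
        subject_interval=GenomicInterval(subject_id, 0, len(b)),
        aligned_query=aq,
        aligned_subject=asub,
        score=float(aln.score),
        identity=_identity(aq, asub),
        coverage=1.0,
    )


class SeedIndex:
    """Exact k-mer position index over a subject sequence.

    Built once per subject so read mapping can reuse it across many queries.
    """

    def __init__(self, subject: str, seed_len: int, subject_id: str = "subject"):
        if seed_len < 8:
            raise ValueError("seed_len must be >= 8")
        self.subject = sanitize(subject)
        self.seed_len = seed_len
        self.subject_id = subject_id
        self._index: dict[str, list[int]] = {}
        s, k = self.subject, seed_len
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if "N" in w:
                continue
            self._index.setdefault(w, []).append(i)

    def positions(self, kmer: str) -> list[int]:
        return self._index.get(kmer, [])


def _cluster_seeds(matches: list[tuple[int, int]], query_len: int, band: int = 40):
    """Group (q, s) seed matches into diagonal clusters."""
    matches.sort(key=lambda m: (m[1] - m[0], m[1]))
    clusters: list[list[tuple[int, int]]] = []
    for q, s in matches:
        d = s - q
        placed = False
        if clusters:
            last = clusters[-1]
            ld = last[-1][1] - last[-1][0]
            if abs(d - ld) <= band and s - last[-1][1] <= query_len:
                last.append((q, s))
                placed = True
        if not placed:
            clusters.append([(q, s)])
    return clusters


def seeded_local_align(
    query: str,
    subject: str | SeedIndex,
    seed_len: int = 12,
    scoring: AlignScoring = DEFAULT_SCORING,
    subject_id: str = "subject",
    strand: str = "+",
    query_id: str = "query",
) -> list[AlignmentResult]:
    """Exact-seed-and-extend local search of query against subject.

    Exact ``seed_len``-mer matches are clustered by diagonal and each cluster
    is extended by local affine DP in a window around it. Hits overlapping on
    the subject are merged keeping the best score; the result is sorted by
    score descending.
    """
    if isinstance(subject, SeedIndex):
        index = subject
        subj = index.subject
        seed_len = index.seed_len
        subject_id = index.subject_id
    else:
        subj = sanitize(subject)
        index = SeedIndex(subj, seed_len, subject_id)
    query = sanitize(query)
    if len(query) < seed_len:
        raise ValueError("query shorter than seed length")

    matches: list[tuple[int, int]] = []
    for q in range(len(query) - seed_len + 1):
        w = query[q : q + seed_len]
        if "N" in w:
            continue
        for s in index.positions(w):
            matches.append((q, s))
    if not matches:
        return []

    aligner = _aligner(scoring, "local")
    pad = 40
    hits: list[AlignmentResult] = []
    seen_windows: set[tuple[int, int]] = set()
    for cluster in _cluster_seeds(matches, len(query)):
        dmin = min(s - q for q, s in cluster)
        dmax = max(s - q for q, s in cluster)
        w0 = max(0, dmin - pad)
        w1 = min(len(subj), dmax + len(query) + pad)
        if (w0, w1) in seen_windows:
            continue
        seen_windows.add((w0, w1))
        window = subj[w0:w1]
        aln = aligner.align(query, window)[0]
        aq, asub, qspan, sspan = _gapped_strings(aln, query, window)
        if not aq:
            continue
        hits.append(
            AlignmentResult(
                query_interval=GenomicInterval(query_id, qspan[0], qspan[1]),
                subject_interval=GenomicInterval(
                    subject_id, w0 + sspan[0], w0 + sspan[1], strand
                ),
                aligned_query=aq,
                aligned_subject=asub,
                score=float(aln.score),
                identity=_identity(aq, asub),
                coverage=(qspan[1] - qspan[0]) / len(query),
            )
        )

    # merge subject-overlapping hits, best score wins
    hits.sort(key=lambda h: -h.score)
    kept: list[AlignmentResult] = []
    for h in hits:
        if any(h.subject_interval.overlaps(k.subject_interval) for k in kept):
            continue
        kept.append(h)
    return kept


def search_both_strands(
    query: str,
    subject: str,
    seed_len: int = 12,
    scoring: AlignScoring = DEFAULT_SCORING,
    subject_id: str = "subject",
    query_id: str = "query",
) -> list[AlignmentResult]:
    """Seeded local search on the subject and its reverse complement.

    Minus-strand hits are reported in forward-subject coordinates with
    strand '-'.
    """
    subj = sanitize(subject)
    fwd = seeded_local_align(
        query, subj, seed_len, scoring, subject_id, "+", query_id
    )
    rc = seeded_local_align(
        query, revcomp(subj), seed_len, scoring, subject_id, "-", query_id
    )
    n = len(subj)
    flipped = []
    for h in rc:
        si = h.subject_interval
        flipped.append(
            AlignmentResult(
                query_interval=h.query_interval,
                subject_interval=GenomicInterval(subject_id, n - si.end, n - si.start, "-"),
                aligned_query=h.aligned_query,
                aligned_subject=h.aligned_subject,
                score=h.score,
                identity=h.identity,
                coverage=h.coverage,
            )
        )
    merged = fwd + flipped
    merged.sort(key=lambda h: -h.score)
    kept: list[AlignmentResult] = []
    for h in merged:
        if any(h.subject_interval.overlaps(k.subject_interval) for k in kept):
            continue
        kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# progressive multiple alignment
# ---------------------------------------------------------------------------

_BASE_ORDER = "ACGT"


def _profile_consensus(rows: list[list[str]]) -> str:
    out = []
    for col in zip(*rows):
        counts = {b: 0 for b in _BASE_ORDER}
        for c in col:
            if c in counts:
                counts[c] += 1
        best = max(_BASE_ORDER, key=lambda b: (counts[b], -_BASE_ORDER.index(b)))
        out.append(best if counts[best] > 0 else "N")
    return "".join(out)


def _kmer_set(seq: str, k: int = 8) -> frozenset:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def progressive_msa(
    seqs: list[str],
    scoring: AlignScoring = DEFAULT_SCORING,
    ids: list[str] | None = None,
) -> MultipleAlignment:
    """Deterministic progressive alignment.

    Sequences are added in descending k-mer similarity to the first input;
    each new sequence is aligned globally against the running profile's
    majority consensus and the gaps are projected into every existing row.
    Output rows are returned in the original input order and ungap exactly to
    the inputs.
    """
    if len(seqs) < 2:
        raise ValueError("progressive_msa requires >= 2 sequences")
    seqs = [sanitize(s) for s in seqs]
    if any(not s for s in seqs):
        raise ValueError("empty sequence in MSA input")
    if ids is None:
        ids = [f"seq{i}" for i in range(len(seqs))]
    if len(ids) != len(seqs):
        raise ValueError("ids/seqs length mismatch")

    ref_kmers = _kmer_set(seqs[0])
    order = [0] + sorted(
        range(1, len(seqs)),
        key=lambda i: (-len(ref_kmers & _kmer_set(seqs[i])), i),
    )

    rows: list[list[str]] = [list(seqs[order[0]])]
    for idx in order[1:]:
        new = seqs[idx]
        cons = _profile_consensus(rows)
        res = global_align(cons, new, scoring)
        aq, asub = res.aligned_query, res.aligned_subject
        new_rows: list[list[str]] = [[] for _ in rows]
        new_row: list[str] = []
        ci = 0
        for x, y in zip(aq, asub):
            if x == "-":
                for r in new_rows:
                    r.append("-")
                new_row.append(y)
            else:
                for r, old in zip(new_rows, rows):
                    r.append(old[ci])
                ci += 1
                new_row.append(y if y != "-" else "-")
        rows = new_rows + [new_row]

    # restore input order
    by_input: dict[int, str] = {}
    for pos, idx in enumerate(order):
        by_input[idx] = "".join(rows[pos])
    final = [by_input[i] for i in range(len(seqs))]
    msa = MultipleAlignment(taxa=list(ids), rows=final)
    for i, s in enumerate(seqs):
        assert msa.ungapped(i) == s, "progressive MSA lost sequence content"
    return msa
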