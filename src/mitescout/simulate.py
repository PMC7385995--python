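"""Synthetic genomes with planted MITE families and known truth tables.

Everything the pipeline measures can be rehearsed here without downloads:
background DNA with annotated genes, planted element families with the
geometry of well-characterized plant hAT MITEs (~670 bp elements, 12-25 bp
TIRs, 8 bp TSDs, 70-75% AT), per-copy ages drawn from a chosen distribution
and converted to divergence through the molecular clock (k = 2 r T), and
uniform-coverage single-end reads.

Element evolution is substitution-only under a Kimura 2-parameter process
with a 2:1 transition:transversion rate ratio, scaled so the expected number
of substitutions per site equals k — the same model family the estimator
assumes, so parameter-recovery tests are fair but not circular (the estimator
never sees the generator's rate ratio). Substitution-only decay keeps TIR and
TSD structure intact apart from point mutations; indel decay is a documented
extension, not a default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .models import GeneModel, GenomeSequence, GenomicInterval

__all__ = [
    "PlantSpec",
    "TruthRecord",
    "simulate_genome",
    "make_consensus",
    "plant_mites",
    "excise",
    "excise_many",
    "simulate_reads",
    "evaluate_discovery",
    "evolve_k2p",
    "default_family_specs",
]

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_BASE_STR = "ACGT"
# transition partner of A C G T (by index)
_TRANSITION = np.array([2, 3, 0, 1])
# the two transversion partners of each base
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


@dataclass
class PlantSpec:
    """Parameters of one planted MITE family."""

    family_id: str
    element_len: int = 670
    tir_len: int = 15
    tsd_len: int = 8
    at_fraction: float = 0.72
    n_copies: int = 50
    # mixture of (age in years, weight); mirrors a 2-3 Mya amplification
    # burst typical of recently proliferated families, with a slice of
    # brand-new insertions from ongoing activity
    age_distribution: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.0, 0.1), (1.0e6, 0.2), (2.0e6, 0.4), (3.0e6, 0.3)]
    )
    genic_bias: float = 0.7  # fraction of copies placed within 2 kb of a gene
    consensus: str | None = None  # generated when absent

    def __post_init__(self) -> None:
        if self.tir_len < 10:
            raise ValueError("tir_len must be >= 10")
        if not (2 <= self.tsd_len <= 10):
            raise ValueError("tsd_len must be in [2, 10]")
        w = sum(w for _, w in self.age_distribution)
        if not math.isclose(w, 1.0, rel_tol=1e-6):
            raise ValueError("age distribution weights must sum to 1")
        if self.consensus is not None:
            c = self.consensus.upper()
            from .align import revcomp

            if c[: self.tir_len] != revcomp(c[-self.tir_len :]):
                raise ValueError("consensus must begin/end with an exact TIR pair")
            self.consensus = c


@dataclass
class TruthRecord:
    element_id: str
    family_id: str
    interval: GenomicInterval
    true_T: float
    true_k: float
    tsd: str
    sequence: str


def default_family_specs() -> list[PlantSpec]:
    """Two families with the geometries of high-copy plant hAT MITEs:
    673 bp / 25 bp TIR / 8 bp TSD / 70% AT and 666 bp / 12 bp TIR /
    8 bp TSD / 75% AT."""
    return [
        PlantSpec(family_id="famA", element_len=673, tir_len=25, tsd_len=8,
                  at_fraction=0.70, n_copies=50),
        PlantSpec(family_id="famB", element_len=666, tir_len=12, tsd_len=8,
                  at_fraction=0.75, n_copies=50),
    ]


# ---------------------------------------------------------------------------
# background genome
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)].tobytes().decode()


def simulate_genome(
    length: int,
    gc: float,
    n_genes: int,
    seed: int,
    seqid: str = "chr1",
) -> tuple[GenomeSequence, list[GeneModel]]:
    """I.i.d. background at the given GC with non-overlapping gene models.

    Each gene has 1-5 exons (exons 150-400 bp, introns 100-800 bp) and is
    placed uniformly; placement retries are bounded, and failure to place all
    genes raises.
    """
    if length < 10_000:
        raise ValueError("genome length must be >= 10 kb")
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    rng = np.random.default_rng(seed)
    residues = _random_seq(rng, length, gc)
    genome = GenomeSequence(id=seqid, residues=residues)

    genes: list[GeneModel] = []
    occupied: list[tuple[int, int]] = []
    for gi in range(n_genes):
        placed = False
        for _try in range(200):
            n_exons = int(rng.integers(1, 6))
            exon_lens = rng.integers(150, 401, size=n_exons)
            intron_lens = rng.integers(100, 801, size=max(0, n_exons - 1))
            glen = int(exon_lens.sum() + intron_lens.sum())
            if glen + 200 >= length:
                continue
            start = int(rng.integers(100, length - glen - 100))
            end = start + glen
            if any(start < oe + 200 and os < end + 200 for os, oe in occupied):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            pos = start
            for ei in range(n_exons):
                exons.append(GenomicInterval(seqid, pos, pos + int(exon_lens[ei]), strand))
                pos += int(exon_lens[ei])
                if ei < n_exons - 1:
                    pos += int(intron_lens[ei])
            genes.append(
                GeneModel(
                    gene_id=f"gene{gi + 1:04d}",
                    span=GenomicInterval(seqid, start, end, strand),
                    exons=exons,
                )
            )
            occupied.append((start, end))
            placed = True
            break
        if not placed:
            raise RuntimeError(f"could not place gene {gi + 1} without overlap")
    genes.sort(key=lambda g: g.span.start)
    return genome, genes


# ---------------------------------------------------------------------------
# element evolution
# ---------------------------------------------------------------------------


def evolve_k2p(seq: str, k: float, rng: np.random.Generator) -> str:
    """Evolve a sequence under a K2P process to expected k substitutions/site.

    Transition rate alpha = 2 * beta (each of the two transversions at rate
    beta); exact finite-time substitution probabilities are used, so multiple
    hits are modeled and the K2P estimator is consistent for the generated
    divergence.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return seq
    # alpha*t = k/2, beta*t = k/4  (alpha + 2 beta = total rate, scaled to k)
    at = k / 2.0
    bt = k / 4.0
    p_ti = 0.25 + 0.25 * math.exp(-4 * bt) - 0.5 * math.exp(-2 * (at + bt))
    p_tv_each = 0.25 - 0.25 * math.exp(-4 * bt)
    enc = np.frombuffer(seq.encode(), dtype=np.uint8)
    idx = np.full(len(enc), -1, dtype=int)
    for i, b in enumerate(_BASE_STR):
        idx[enc == ord(b)] = i
    u = rng.random(len(enc))
    out = idx.copy()
    known = idx >= 0
    ti = known & (u < p_ti)
    tv1 = known & (u >= p_ti) & (u < p_ti + p_tv_each)
    tv2 = known & (u >= p_ti + p_tv_each) & (u < p_ti + 2 * p_tv_each)
    out[ti] = _TRANSITION[idx[ti]]
    out[tv1] = _TRANSVERSIONS[idx[tv1], 0]
    out[tv2] = _TRANSVERSIONS[idx[tv2], 1]
    chars = np.array(list(seq))
    chars[known] = np.array(list(_BASE_STR))[out[known]]
    return "".join(chars)


def make_consensus(spec: PlantSpec, rng: np.random.Generator) -> str:
    """Random AT-rich consensus bounded by an exact TIR pair."""
    if spec.consensus is not None:
        return spec.consensus
    from .align import revcomp

    at = spec.at_fraction
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    core_len = spec.element_len - 2 * spec.tir_len
    if core_len < 10:
        raise ValueError("element too short for its TIRs")
    tir = _BASES[rng.choice(4, size=spec.tir_len, p=p)].tobytes().decode()
    core = _BASES[rng.choice(4, size=core_len, p=p)].tobytes().decode()
    return tir + core + revcomp(tir)


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------


def _pick_sites(
    rng: np.random.Generator,
    genome_len: int,
    genes: list[GeneModel],
    n_total: int,
    genic_flags: list[bool],
    window: int,
    spacing: int = 1600,
    edge: int = 500,
) -> list[int]:
    """Insertion points on the original genome respecting genic bias.

    A genic point falls inside a gene or within (window - 100) bp of its
    span; a non-genic point is kept > window + 500 bp from every gene so the
    realized proximal fraction tracks the requested bias.
    """
    sites: list[int] = []

    def far_from_sites(p: int) -> bool:
        return all(abs(p - s) >= spacing for s in sites)

    spans = [(g.span.start, g.span.end) for g in genes]
    for want_genic in genic_flags:
        placed = False
        for _try in range(500):
            if want_genic and spans:
                gs, ge = spans[int(rng.integers(0, len(spans)))]
                lo = max(edge, gs - (window - 100))
                hi = min(genome_len - edge, ge + (window - 100))
                if hi <= lo:
                    continue
                p = int(rng.integers(lo, hi))
            else:
                p = int(rng.integers(edge, genome_len - edge))
                if any(gs - (window + 500) < p < ge + (window + 500) for gs, ge in spans):
                    continue
            if far_from_sites(p):
                sites.append(p)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place all copies; placed {len(sites)} of {n_total}"
            )
    return sites


def plant_mites(
    genome: GenomeSequence,
    genes: list[GeneModel],
    specs: PlantSpec | list[PlantSpec],
    config: PipelineConfig,
    seed: int,
) -> tuple[GenomeSequence, list[GeneModel], list[TruthRecord]]:
    """Insert diverged copies of each family and return the mutated genome,
    coordinate-shifted gene models and the truth table.

    Per copy: an age T is drawn from the family's age distribution, the
    divergence k = 2 r T is applied to the family consensus under the K2P
    process, and the copy is inserted with an exact duplication of the
    tsd_len target bases on both sides. Inserting sequence shifts every
    downstream coordinate, so gene models are remapped and truth intervals
    are reported in final coordinates.
    """
    if isinstance(specs, PlantSpec):
        specs = [specs]
    rng = np.random.default_rng(seed)
    r = config.substitution_rate_r

    plans = []  # (site, family_id, copy_idx, T, k, consensus)
    for spec in specs:
        consensus = make_consensus(spec, rng)
        ages = np.array([t for t, _ in spec.age_distribution])
        weights = np.array([w for _, w in spec.age_distribution])
        genic_flags = [bool(rng.random() < spec.genic_bias) for _ in range(spec.n_copies)]
        drawn_T = ages[rng.choice(len(ages), size=spec.n_copies, p=weights)]
        plans.append((spec, consensus, genic_flags, drawn_T))

    all_flags = [f for _, _, flags, _ in plans for f in flags]
    sites = _pick_sites(
        rng,
        len(genome),
        genes,
        len(all_flags),
        all_flags,
        config.genic_window,
    )

    entries = []  # (site, family_id, idx, T, k, evolved_seq, tsd_len)
    si = 0
    for spec, consensus, flags, drawn_T in plans:
        for ci in range(spec.n_copies):
            T = float(drawn_T[ci])
            k = 2.0 * r * T
            seq = evolve_k2p(consensus, k, rng)
            entries.append((sites[si], spec.family_id, ci, T, k, seq, spec.tsd_len))
            si += 1
    entries.sort(key=lambda e: e[0])

    s = genome.residues
    pieces: list[str] = []
    prev = 0
    shift = 0
    truth: list[TruthRecord] = []
    for site, family_id, ci, T, k, seq, tsd_len in entries:
        tsd = s[site : site + tsd_len]
        pieces.append(s[prev:site])
        pieces.append(tsd)
        pieces.append(seq)
        prev = site  # the original target bases become the right-hand TSD copy
        start = site + shift + tsd_len
        truth.append(
            TruthRecord(
                element_id=f"{family_id}_{ci + 1}",
                family_id=family_id,
                interval=GenomicInterval(genome.id, start, start + len(seq)),
                true_T=T,
                true_k=k,
                tsd=tsd,
                sequence=seq,
            )
        )
        shift += tsd_len + len(seq)
    pieces.append(s[prev:])
    new_genome = GenomeSequence(id=genome.id, residues="".join(pieces))

    insert_sites = [e[0] for e in entries]
    insert_sizes = [e[6] + len(e[5]) for e in entries]

    def remap(x: int) -> int:
        return x + sum(sz for p, sz in zip(insert_sites, insert_sizes) if p <= x)

    new_genes = [
        GeneModel(
            gene_id=g.gene_id,
            span=GenomicInterval(
                g.span.seqid, remap(g.span.start), remap(g.span.end), g.span.strand
            ),
            exons=[
                GenomicInterval(e.seqid, remap(e.start), remap(e.end), e.strand)
                for e in g.exons
            ],
        )
        for g in genes
    ]
    return new_genome, new_genes, truth


def excise(genome: GenomeSequence, record: TruthRecord) -> GenomeSequence:
    """Remove a planted element leaving one TSD copy (the pre-insertion state)."""
    iv = record.interval
    tsd_len = len(record.tsd)
    s = genome.residues
    if s[iv.start : iv.end] != record.sequence:
        raise ValueError(f"element {record.element_id}: genome content mismatch")
    if s[iv.start - tsd_len : iv.start] != record.tsd or s[iv.end : iv.end + tsd_len] != record.tsd:
        raise ValueError(f"element {record.element_id}: TSD mismatch at locus")
    return GenomeSequence(id=genome.id, residues=s[: iv.start] + s[iv.end + tsd_len :])


def excise_many(genome: GenomeSequence, records: list[TruthRecord]) -> GenomeSequence:
    """Excise several elements; processed right-to-left so earlier excisions
    do not shift later coordinates."""
    for rec in sorted(records, key=lambda r: -r.interval.start):
        genome = excise(genome, rec)
    return genome


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


def simulate_reads(
    genome: GenomeSequence,
    coverage: float,
    read_len: int,
    error_rate: float,
    seed: int,
) -> list[tuple[str, str]]:
    """Uniform single-end reads from both strands with i.i.d. substitution
    errors; total bases ~= coverage * genome length."""
    from .align import revcomp

    n = len(genome)
    if read_len > n:
        raise ValueError("read length exceeds genome length")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    n_reads = int(round(coverage * n / read_len))
    starts = rng.integers(0, n - read_len + 1, size=n_reads)
    strands = rng.random(n_reads) < 0.5
    reads: list[tuple[str, str]] = []
    for i in range(n_reads):
        seq = genome.residues[starts[i] : starts[i] + read_len]
        if strands[i]:
            seq = revcomp(seq)
        if error_rate > 0:
            arr = np.array(list(seq))
            errs = np.where(rng.random(read_len) < error_rate)[0]
            for j in errs:
                choices = [b for b in _BASE_STR if b != arr[j]]
                arr[j] = choices[int(rng.integers(0, len(choices)))]
            seq = "".join(arr)
        reads.append((f"read{i + 1}", seq))
    return reads


# ---------------------------------------------------------------------------
# benchmark fixtures
# ---------------------------------------------------------------------------


def make_discovery_benchmark(
    seed: int,
    config: PipelineConfig | None = None,
    genome_len: int = 1_000_000,
    n_genes: int = 100,
    n_copies: int = 50,
):
    """1 Mb genome with the two default hAT-geometry families planted at
    burst-age divergences (<= 10% per element). Returns (genome, genes,
    truth)."""
    cfg = config or PipelineConfig()
    genome, genes = simulate_genome(genome_len, 0.36, n_genes, seed)
    specs = default_family_specs()
    for sp in specs:
        sp.n_copies = n_copies
    return plant_mites(genome, genes, specs, cfg, seed + 1)


def make_copynumber_benchmark(
    seed: int,
    config: PipelineConfig | None = None,
    n_copies: int = 20,
    genome_len: int = 200_000,
    coverage: float = 10.0,
    read_len: int = 100,
):
    """Genome with one known-consensus family and error-free uniform reads.

    Returns (genome, consensus, truth, reads).
    """
    cfg = config or PipelineConfig()
    genome, genes = simulate_genome(genome_len, 0.36, 20, seed)
    spec = PlantSpec(
        family_id="fam", element_len=670, tir_len=15, tsd_len=8,
        at_fraction=0.72, n_copies=n_copies,
    )
    spec.consensus = make_consensus(spec, np.random.default_rng(seed + 7))
    planted, _, truth = plant_mites(genome, genes, spec, cfg, seed + 1)
    reads = simulate_reads(planted, coverage, read_len, 0.0, seed + 2)
    return planted, spec.consensus, truth, reads


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def _reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    ov = a.overlap_length(b)
    if ov == 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def evaluate_discovery(
    predicted,
    truth: list[TruthRecord],
    min_overlap: float = 0.8,
) -> tuple[float, float]:
    """Precision/recall of predicted elements against the truth table.

    A prediction matches a truth record when their reciprocal overlap is at
    least ``min_overlap``; matching is greedy by overlap, one prediction per
    truth record. With no predictions, precision is reported as 0 (logged).
    """
    pred_ivs = [p.element if hasattr(p, "element") else p for p in predicted]
    if not pred_ivs:
        if truth:
            log.warning("no predictions: precision undefined, reported as 0")
        return 0.0, 0.0
    scored = []
    for pi, p in enumerate(pred_ivs):
        for ti, t in enumerate(truth):
            ov = _reciprocal_overlap(p, t.interval)
            if ov >= min_overlap:
                scored.append((ov, pi, ti))
    scored.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_p: set[int] = set()
    used_t: set[int] = set()
    matches = 0
    for ov, pi, ti in scored:
        if pi in used_p or ti in used_t:
            continue
        used_p.add(pi)
        used_t.add(ti)
        matches += 1
    precision = matches / len(pred_ivs)
    recall = matches / len(truth) if truth else 0.0
    return precision, recall
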