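"""Genome scanning for Pr77-hallmark-like signatures.

The Pr77 hallmark is the conserved ~77-nt sequence at the 5' end of
L1Tc/ingi-clade non-LTR retrotransposons; at the RNA level it folds into an
HDV-like self-cleaving ribozyme.  This module locates hallmark homologues on
both strands of genomic contigs with a self-contained k-mer seed-and-extend
local aligner, and supports iterative re-screening in which newly found hits
are themselves used as queries so that diverged element families (e.g. the
SIDER1-beta class) are still recovered.

Defaults: seed length k=11, match +1, mismatch -1, gap -2, minimum identity
60%, minimum hit length 50 nt.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._align import IUPAC, revcomp, smith_waterman
from .errors import InputError, ParameterError

_GENOME_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class GenomeSequence:
    """A genomic contig: uppercase DNA over {A,C,G,T,N}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if len(self.residues) == 0:
            raise InputError(f"genome sequence {self.id!r} is empty")
        bad = set(self.residues) - _GENOME_ALPHABET
        if bad:
            raise InputError(
                f"genome sequence {self.id!r} contains non-ACGTN residues: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class QueryProfile:
    """A hallmark query: an IUPAC consensus, canonically 77 nt long."""

    id: str
    consensus: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "consensus", self.consensus.upper().replace("U", "T")
        )
        if not 40 <= len(self.consensus) <= 200:
            raise InputError(
                f"query {self.id!r}: length {len(self.consensus)} outside [40, 200]"
            )
        bad = set(self.consensus) - set(IUPAC)
        if bad:
            raise InputError(f"query {self.id!r}: invalid IUPAC codes {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class HallmarkHit:
    """One hallmark homology match, 0-based half-open on the forward strand."""

    contig: str
    start: int
    end: int
    strand: str  # '+' or '-'
    identity: float  # percent of aligned columns that match
    score: int
    query_id: str
    n_aligned: int


@dataclass(frozen=True)
class ScanParams:
    """Seed-and-extend parameters (match > 0 > mismatch, gap)."""

    k: int = 11
    min_identity: float = 60.0
    min_length: int = 50
    match: int = 1
    mismatch: int = -1
    gap: int = -2

    def validate(self) -> None:
        if self.k < 6:
            raise ParameterError(f"seed length k={self.k} < 6 (seeding degenerate)")
        if not (self.match > 0 > self.mismatch and self.gap < 0):
            raise ParameterError("scores must satisfy match > 0 > mismatch, gap")


# -- seeding ------------------------------------------------------------------

def _seed_positions(query: str, target: str, k: int) -> list[tuple[int, int]]:
    """Exact k-mer matches as (query_pos, target_pos) pairs.

    Seeds are taken only from unambiguous (ACGT-only) query k-mers; IUPAC
    positions still score as matches during extension.
    """
    seeds: list[tuple[int, int]] = []
    seen_kmers: dict[str, list[int]] = {}
    for qp in range(len(query) - k + 1):
        kmer = query[qp : qp + k]
        if set(kmer) <= {"A", "C", "G", "T"}:
            seen_kmers.setdefault(kmer, []).append(qp)
    for kmer, qpos_list in seen_kmers.items():
        tp = target.find(kmer)
        while tp != -1:
            for qp in qpos_list:
                seeds.append((qp, tp))
            tp = target.find(kmer, tp + 1)
    return seeds


def _cluster_seeds(
    seeds: list[tuple[int, int]], diag_tol: int = 15, pos_gap: int = 40
) -> list[list[tuple[int, int]]]:
    """Group seeds lying on nearby diagonals into extension windows.

    Tandem hallmark copies sit on diagonals offset by roughly the hallmark
    length, so they land in separate clusters and yield separate hits.
    """
    ordered = sorted(seeds, key=lambda s: (s[1] - s[0], s[1]))
    clusters: list[list[tuple[int, int]]] = []
    for qp, tp in ordered:
        d = tp - qp
        placed = False
        for cl in clusters:
            lq, lt = cl[-1]
            if abs(d - (lt - lq)) <= diag_tol and abs(tp - lt) <= pos_gap:
                cl.append((qp, tp))
                placed = True
                break
        if not placed:
            clusters.append([(qp, tp)])
    return clusters


# -- scanning -----------------------------------------------------------------

def _scan_strand(
    target: str, query: QueryProfile, params: ScanParams
) -> list[tuple[int, int, int, int, int]]:
    """Hits on one strand as (t_start, t_end, score, matches, columns)."""
    q = query.consensus
    seeds = _seed_positions(q, target, params.k)
    out = []
    seen_spans: set[tuple[int, int]] = set()
    for cluster in _cluster_seeds(seeds):
        qps = [s[0] for s in cluster]
        tps = [s[1] for s in cluster]
        w0 = max(0, min(t - s for t, s in zip(tps, qps)) - 10)
        w1 = min(
            len(target),
            max(t + (len(q) - s) for t, s in zip(tps, qps)) + 10,
        )
        aln = smith_waterman(
            q, target[w0:w1], params.match, params.mismatch, params.gap
        )
        if aln is None:
            continue
        t_start, t_end = w0 + aln.t_start, w0 + aln.t_end
        if (t_start, t_end) in seen_spans:
            continue
        seen_spans.add((t_start, t_end))
        out.append((t_start, t_end, aln.score, aln.matches, aln.columns))
    return out


def _merge_overlapping(hits: list[HallmarkHit]) -> list[HallmarkHit]:
    """Among same-contig same-strand overlapping hits keep the higher score."""
    kept: list[HallmarkHit] = []
    for h in sorted(hits, key=lambda h: (-h.score, h.contig, h.start)):
        clash = any(
            k.contig == h.contig
            and k.strand == h.strand
            and k.start < h.end
            and h.start < k.end
            for k in kept
        )
        if not clash:
            kept.append(h)
    return sorted(kept, key=lambda h: (h.contig, h.start, h.strand))


def scan_genome(
    genome: GenomeSequence, query: QueryProfile, params: ScanParams | None = None
) -> list[HallmarkHit]:
    """All maximal local alignments of ``query`` against either strand of
    ``genome`` passing the identity and length thresholds.

    Hits are reported on forward-strand coordinates (0-based half-open),
    sorted by (contig, start); overlapping same-strand hits are merged keeping
    the higher score.
    """
    params = params or ScanParams()
    params.validate()
    if params.k > query.length:
        raise ParameterError(
            f"seed length k={params.k} exceeds query length {query.length}"
        )

    L = genome.length
    hits: list[HallmarkHit] = []
    for strand, target in (("+", genome.residues), ("-", revcomp(genome.residues))):
        for t_start, t_end, score, matches, columns in _scan_strand(
            target, query, params
        ):
            identity = 100.0 * matches / columns if columns else 0.0
            if strand == "+":
                start, end = t_start, t_end
            else:
                start, end = L - t_end, L - t_start
            if end - start < params.min_length or identity < params.min_identity:
                continue
            hits.append(
                HallmarkHit(
                    contig=genome.id,
                    start=start,
                    end=end,
                    strand=strand,
                    identity=identity,
                    score=score,
                    query_id=query.id,
                    n_aligned=columns,
                )
            )
    return _merge_overlapping(hits)


# -- iterative screening ------------------------------------------------------

def _same_locus(a: HallmarkHit, b: HallmarkHit, min_fraction: float = 0.5) -> bool:
    """Two hits are duplicates when they cover the same genomic interval:
    overlap >= ``min_fraction`` of the shorter hit, on either strand.

    Strand is deliberately ignored: hallmark signatures are partially
    self-complementary (their helices pair internally), so every genuine hit
    casts a weaker reverse-complement "shadow" alignment over the same locus,
    and a genomic interval can only be one signature."""
    if a.contig != b.contig:
        return False
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return False
    shorter = min(a.end - a.start, b.end - b.start)
    return ov >= min_fraction * shorter


def iterative_scan(
    genome: GenomeSequence,
    initial_queries: list[QueryProfile],
    params: ScanParams | None = None,
    max_rounds: int = 5,
) -> list[HallmarkHit]:
    """Screen, then re-screen with hit-derived queries until no new hit appears.

    Round 1 is the union over ``initial_queries``; each later round adds the
    genomic sequences of previously unseen hits as queries.  Deduplication is
    by coordinates (reciprocal overlap >= 80% on the same contig/strand), so
    the result is always a superset of round 1.
    """
    if max_rounds < 1:
        raise ParameterError(f"max_rounds={max_rounds} must be >= 1")
    params = params or ScanParams()

    accepted: list[HallmarkHit] = []
    queries = list(initial_queries)
    tried_query_seqs: set[str] = {q.consensus for q in queries}
    for _round in range(max_rounds):
        candidates: list[HallmarkHit] = []
        for q in queries:
            candidates.extend(scan_genome(genome, q, params))
        # strongest alignment claims a locus first
        candidates.sort(key=lambda h: (-h.score, h.contig, h.start))
        new_hits: list[HallmarkHit] = []
        for h in candidates:
            if any(_same_locus(h, k) for k in accepted + new_hits):
                continue
            new_hits.append(h)
        if not new_hits:
            break
        accepted.extend(new_hits)
        queries = []
        for h in new_hits:
            seq = genome.residues[h.start : h.end]
            if h.strand == "-":
                seq = revcomp(seq)
            if not 60 <= len(seq) <= 200 or seq in tried_query_seqs:
                continue
            tried_query_seqs.add(seq)
            queries.append(
                QueryProfile(
                    id=f"hit:{h.contig}:{h.start}-{h.end}({h.strand})", consensus=seq
                )
            )
        if not queries:
            break
    return sorted(accepted, key=lambda h: (h.contig, h.start, h.strand))
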