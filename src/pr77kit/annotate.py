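"""Mobile-element context filtering and classification around hallmark hits.

A hallmark homology hit only counts as a mobile-element locus when it shows
the sequence context left behind by target-primed reverse transcription: a
poly-A tract downstream of the signature (at ~0.6 kb for short elements, or
5-6 kb for full-length LINEs), and a 7-11 nt target-site duplication (TSD)
partially or totally conserved at both ends of the insertion.  Loci are then
classified:

* two tandem hallmark signatures  -> SIDER2 (signature I = 5'-most, II = second)
* span >= 4 kb                    -> LINE_DIRE (full-length or degenerate LINE)
* single signature, short poly-A, both ends matching a reference long
  element                         -> SIDE_NAR (internally deleted LINE)
* single signature, short poly-A  -> SIDER1
* anything else                   -> UNCLASSIFIED

A missing TSD downgrades confidence to ``no_tsd`` but never changes the
class.  All coordinates are 0-based half-open on the forward strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from ._align import revcomp, smith_waterman
from .errors import InputError
from .fold import (
    DEFAULT_DESCRIPTOR,
    RibozymeDescriptor,
    ValidationResult,
    validate_hallmark,
)
from .scan import (
    GenomeSequence,
    HallmarkHit,
    QueryProfile,
    ScanParams,
    iterative_scan,
)

SHORT = "SHORT"
LONG = "LONG"

ELEMENT_CLASSES = ("SIDER1", "SIDER2", "LINE_DIRE", "SIDE_NAR", "UNCLASSIFIED")


@dataclass(frozen=True)
class PolyATrack:
    """A downstream adenosine tract (0-based half-open, forward strand).

    ``distance`` is measured element-wise: hallmark 3' end to track start on
    '+', track end to hallmark start on '-'.
    """

    start: int
    end: int
    a_fraction: float
    window_class: str  # SHORT (~0.6 kb) or LONG (5-6 kb)
    distance: int


@dataclass(frozen=True)
class TSDPair:
    """Direct repeat flanking an insertion (left/right copies, forward strand)."""

    length: int
    left_start: int
    right_start: int
    left_seq: str
    right_seq: str
    identity: float
    left_offset: int
    right_offset: int


@dataclass(frozen=True)
class PolyAConfig:
    short_window: tuple[int, int] = (300, 1000)
    long_window: tuple[int, int] = (4500, 6500)
    min_run: int = 10
    purity: float = 0.9
    # runs at least this long are treated as bona fide tails; the nearest one
    # wins over chance ~10-nt runs elsewhere in the windows
    tail_min_run: int = 15


@dataclass(frozen=True)
class TSDConfig:
    len_range: tuple[int, int] = (7, 11)
    max_offset: int = 5
    min_identity_pct: float = 75.0
    min_matches: int = 6
    # small inward slack: detected element boundaries can sit 1-2 nt inside
    # the true insertion when a terminal hallmark base is mutated (the local
    # alignment trims it) or the poly-A run bleeds over the boundary
    boundary_slack: int = 2


@dataclass(frozen=True)
class ClassifyConfig:
    tandem_gap: int = 200          # max nt between tandem signatures (SIDER2)
    long_span: int = 4000          # min element span for LINE_DIRE
    nar_min_identity_pct: float = 80.0
    nar_end_region: int = 200      # element end region compared to the reference
    nar_min_columns: int = 100


@dataclass
class ElementAnnotation:
    contig: str
    start: int
    end: int
    strand: str
    element_class: str
    hallmarks: list[HallmarkHit]
    polya: PolyATrack | None
    tsd: TSDPair | None
    folds: list[ValidationResult | None] = field(default_factory=list)
    confidence: str = "full"  # "full" | "no_tsd"

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


# -- poly-A detection ---------------------------------------------------------

def _maximal_a_runs(seq: str, base: str, min_run: int, purity: float) -> list[tuple[int, int]]:
    """Maximal runs of ``base`` (tolerating rare single-base interruptions).

    Pure runs separated by one other base are merged only when both sides are
    substantial (>= 3 nt) and the merged fraction of ``base`` stays >=
    ``purity`` -- so a long tail cannot absorb downstream sequence that merely
    starts with a couple of As.  Runs shorter than ``min_run`` are dropped.
    """
    runs: list[tuple[int, int, int]] = []  # (start, end, base count)
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == base:
            j = i
            while j < n and seq[j] == base:
                j += 1
            runs.append((i, j, j - i))
            i = j
        else:
            i += 1
    merged: list[tuple[int, int, int]] = []
    for rs, re_, rc in runs:
        if merged:
            s, e, c = merged[-1]
            gap = rs - e
            if (
                gap <= 1
                and rc >= 3
                and c >= 3
                and (c + rc) / (re_ - s) >= purity
            ):
                merged[-1] = (s, re_, c + rc)
                continue
        merged.append((rs, re_, rc))
    return [(s, e) for s, e, _c in merged if e - s >= min_run]


def find_polyA(
    genome: GenomeSequence,
    hallmark: HallmarkHit,
    config: PolyAConfig | None = None,
) -> list[PolyATrack]:
    """Poly-A tracts in the two distance windows downstream of a hallmark.

    Strand-aware: on '+' scans A-runs after the hallmark end; on '-' scans
    T-runs before the hallmark start (forward coordinates).  Windows running
    past the contig end are truncated with a warning.
    """
    config = config or PolyAConfig()
    if not (0 <= hallmark.start < hallmark.end <= genome.length):
        raise InputError(
            f"hallmark {hallmark.start}-{hallmark.end} outside contig "
            f"{genome.id} (length {genome.length})"
        )
    seq = genome.residues
    tracks: list[PolyATrack] = []
    for window_class, (w0, w1) in (
        (SHORT, config.short_window),
        (LONG, config.long_window),
    ):
        if hallmark.strand == "+":
            lo, hi = hallmark.end + w0, hallmark.end + w1
            if hi > genome.length:
                warnings.warn(
                    f"{window_class} poly-A window truncated at end of {genome.id}"
                )
                hi = genome.length
            lo = min(lo, genome.length)
            base = "A"
        else:
            lo, hi = hallmark.start - w1, hallmark.start - w0
            if lo < 0:
                warnings.warn(
                    f"{window_class} poly-A window truncated at start of {genome.id}"
                )
                lo = 0
            hi = max(hi, 0)
            base = "T"
        if hi <= lo:
            continue
        for rs, re_ in _maximal_a_runs(seq[lo:hi], base, config.min_run, config.purity):
            s, e = lo + rs, lo + re_
            frac = seq[s:e].count(base) / (e - s)
            distance = (s - hallmark.end) if hallmark.strand == "+" else (hallmark.start - e)
            tracks.append(
                PolyATrack(
                    start=s, end=e, a_fraction=frac,
                    window_class=window_class, distance=distance,
                )
            )
    tracks.sort(key=lambda t: t.distance)
    return tracks


# -- TSD detection ------------------------------------------------------------

def find_TSD(
    genome: GenomeSequence,
    element_span: tuple[int, int],
    config: TSDConfig | None = None,
) -> TSDPair | None:
    """Best target-site duplication flanking an element span, or None.

    For each length L (longest first) and per-side offsets 0..max_offset,
    compares the L-mer ending at the 5' boundary with the L-mer starting
    after the element's 3' end (the poly-A end).  Accepts identity >=
    min_identity_pct with >= min_matches matching positions; tie-break:
    longest L, highest identity, smallest total offset.
    """
    config = config or TSDConfig()
    start, end = element_span
    seq = genome.residues
    lmin, lmax = config.len_range
    if start < lmax + config.max_offset or end + lmax + config.max_offset > len(seq):
        warnings.warn(
            f"insufficient flank around {start}-{end} on {genome.id} for TSD search"
        )
        # fall through: offsets/lengths that do not fit are simply skipped
    def _search(min_off: int) -> TSDPair | None:
        best: tuple | None = None
        for L in range(lmax, lmin - 1, -1):
            for off_l in range(min_off, config.max_offset + 1):
                ls = start - off_l - L
                if ls < 0 or ls + L > len(seq):
                    continue
                left = seq[ls : ls + L]
                for off_r in range(min_off, config.max_offset + 1):
                    rs = end + off_r
                    if rs < 0 or rs + L > len(seq):
                        continue
                    right = seq[rs : rs + L]
                    matches = sum(a == b and a != "N" for a, b in zip(left, right))
                    identity = 100.0 * matches / L
                    if identity < config.min_identity_pct or matches < config.min_matches:
                        continue
                    key = (L, identity, -(abs(off_l) + abs(off_r)))
                    if best is None or key > best[0]:
                        best = (
                            key,
                            TSDPair(
                                length=L, left_start=ls, right_start=rs,
                                left_seq=left, right_seq=right,
                                identity=identity, left_offset=off_l, right_offset=off_r,
                            ),
                        )
        return best[1] if best else None

    # primary pass with outward offsets only; the inward boundary slack is a
    # fallback for spans whose detected ends sit slightly inside the insertion
    found = _search(0)
    if found is None and config.boundary_slack > 0:
        found = _search(-config.boundary_slack)
    return found


# -- classification -----------------------------------------------------------

def _ends_match_reference(
    element_seq: str, long_ref: str, config: ClassifyConfig
) -> bool:
    """True when both end regions of the element align to the corresponding
    ends of the reference long element at >= nar_min_identity_pct."""
    n = config.nar_end_region
    for part, ref_part in (
        (element_seq[:n], long_ref[: 2 * n]),
        (element_seq[-n:], long_ref[-2 * n :]),
    ):
        aln = smith_waterman(part, ref_part)
        if (
            aln is None
            or aln.columns < config.nar_min_columns
            or aln.identity < config.nar_min_identity_pct
        ):
            return False
    return True


def classify_element(
    hallmarks: list[HallmarkHit],
    polya: PolyATrack | None,
    tsd: TSDPair | None,
    long_ref: str | None = None,
    element_seq: str | None = None,
    config: ClassifyConfig | None = None,
) -> tuple[str, str]:
    """Apply the classification rules in order; returns (class, confidence).

    ``hallmarks`` must be sorted 5'->3' on the element strand.  ``long_ref``
    (the sequence of a reference full-length element) and ``element_seq`` are
    only needed to recognise SIDE_NAR.
    """
    config = config or ClassifyConfig()
    if not hallmarks:
        raise InputError("classify_element requires at least one hallmark")
    confidence = "full" if tsd is not None else "no_tsd"

    strand = hallmarks[0].strand
    if len(hallmarks) == 2:
        a, b = sorted(hallmarks, key=lambda h: h.start)
        gap = b.start - a.end
        if gap <= config.tandem_gap:
            return "SIDER2", confidence
    if polya is not None:
        if strand == "+":
            span = polya.end - min(h.start for h in hallmarks)
        else:
            span = max(h.end for h in hallmarks) - polya.start
        if span >= config.long_span:
            return "LINE_DIRE", confidence
        if len(hallmarks) == 1 and polya.window_class == SHORT:
            if (
                long_ref is not None
                and element_seq is not None
                and _ends_match_reference(element_seq, long_ref, config)
            ):
                return "SIDE_NAR", confidence
            return "SIDER1", confidence
    return "UNCLASSIFIED", confidence


# -- whole-genome annotation --------------------------------------------------

@dataclass(frozen=True)
class AnnotateConfig:
    scan: ScanParams = field(default_factory=ScanParams)
    polya: PolyAConfig = field(default_factory=PolyAConfig)
    tsd: TSDConfig = field(default_factory=TSDConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    descriptor: RibozymeDescriptor = DEFAULT_DESCRIPTOR
    max_scan_rounds: int = 5
    # hits counted as element signatures must cover most of the 77-nt
    # hallmark at solid identity; weaker partial matches (e.g. the hallmark's
    # own reverse-complement shadow from its internal helices) stay in the
    # scan output but are not used to build loci
    min_hallmark_len: int = 60
    min_hallmark_identity: float = 80.0


def _group_loci(hits: list[HallmarkHit], tandem_gap: int) -> list[list[HallmarkHit]]:
    """Group same-contig, same-strand hits separated by <= tandem_gap.

    Each (contig, strand) stream is grouped independently so a stray
    opposite-strand hit between two tandem signatures cannot split a locus.
    """
    loci: list[list[HallmarkHit]] = []
    last_for: dict[tuple[str, str], list[HallmarkHit]] = {}
    for h in sorted(hits, key=lambda h: (h.contig, h.start)):
        key = (h.contig, h.strand)
        prev = last_for.get(key)
        if prev is not None and h.start - prev[-1].end <= tandem_gap:
            prev.append(h)
        else:
            group = [h]
            loci.append(group)
            last_for[key] = group
    return loci


def _element_orientation(hits: list[HallmarkHit]) -> list[HallmarkHit]:
    """Hallmarks sorted 5'->3' on the element strand (signature I first)."""
    return sorted(hits, key=lambda h: h.start, reverse=hits[0].strand == "-")


def annotate_genome(
    genome: GenomeSequence,
    queries: list[QueryProfile],
    config: AnnotateConfig | None = None,
    long_ref: str | None = None,
) -> list[ElementAnnotation]:
    """Full per-contig pipeline: iterative hallmark scan, locus grouping,
    poly-A and TSD context, per-hallmark fold validation, classification.

    A stage failure on one locus marks it UNCLASSIFIED instead of aborting.
    Output is sorted by (contig, start).
    """
    config = config or AnnotateConfig()
    hits = iterative_scan(genome, queries, config.scan, config.max_scan_rounds)
    hits = [
        h for h in hits
        if h.end - h.start >= config.min_hallmark_len
        and h.identity >= config.min_hallmark_identity
    ]
    annotations: list[ElementAnnotation] = []
    for locus in _group_loci(hits, config.classify.tandem_gap):
        annotations.append(_annotate_locus(genome, locus, config, long_ref))
    annotations = _resolve_overlaps(annotations)
    annotations.sort(key=lambda a: (a.contig, a.start))
    return annotations


def _resolve_overlaps(annotations: list[ElementAnnotation]) -> list[ElementAnnotation]:
    """One genomic interval is one element: when two locus calls overlap,
    keep the better-supported one (classified beats UNCLASSIFIED, then more
    hallmark alignment score); the weaker call is the reverse-complement
    shadow of the stronger element's signatures."""

    def support(a: ElementAnnotation) -> tuple:
        return (
            a.element_class != "UNCLASSIFIED",
            sum(h.score for h in a.hallmarks),
            a.end - a.start,
        )

    kept: list[ElementAnnotation] = []
    for a in sorted(annotations, key=support, reverse=True):
        clash = any(
            k.contig == a.contig and k.start < a.end and a.start < k.end
            for k in kept
        )
        if not clash:
            kept.append(a)
    return kept


def _annotate_locus(
    genome: GenomeSequence,
    locus: list[HallmarkHit],
    config: AnnotateConfig,
    long_ref: str | None,
) -> ElementAnnotation:
    ordered = _element_orientation(locus)
    strand = ordered[0].strand
    three_prime = ordered[-1]  # 3'-most hallmark on the element strand

    tracks = find_polyA(genome, three_prime, config.polya)
    # tail-like runs (>= tail_min_run) beat chance minimum-length runs; among
    # tail-like candidates the nearest is the element's own tail
    tails = [t for t in tracks if t.end - t.start >= config.polya.tail_min_run]
    if tails:
        polya = min(tails, key=lambda t: t.distance)
    elif tracks:
        polya = max(tracks, key=lambda t: (t.end - t.start, -t.distance))
    else:
        polya = None

    if polya is not None:
        if strand == "+":
            span = (min(h.start for h in locus), polya.end)
        else:
            span = (polya.start, max(h.end for h in locus))
    else:
        span = (min(h.start for h in locus), max(h.end for h in locus))

    tsd = find_TSD(genome, span, config.tsd) if polya is not None else None

    folds: list[ValidationResult | None] = []
    for h in ordered:
        seq = genome.residues[h.start : h.end]
        if strand == "-":
            seq = revcomp(seq)
        d = config.descriptor
        if d.min_candidate_len <= len(seq) <= d.max_candidate_len:
            folds.append(validate_hallmark(seq, d))
        else:
            folds.append(None)

    element_seq = genome.residues[span[0] : span[1]]
    if strand == "-":
        element_seq = revcomp(element_seq)
    try:
        element_class, confidence = classify_element(
            ordered, polya, tsd,
            long_ref=long_ref, element_seq=element_seq, config=config.classify,
        )
    except Exception:  # pragma: no cover - defensive
        element_class, confidence = "UNCLASSIFIED", "no_tsd" if tsd is None else "full"

    return ElementAnnotation(
        contig=genome.id,
        start=span[0],
        end=span[1],
        strand=strand,
        element_class=element_class,
        hallmarks=ordered,
        polya=polya,
        tsd=tsd,
        folds=folds,
        confidence=confidence,
    )
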