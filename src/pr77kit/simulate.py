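"""Synthetic data generation for every pipeline stage.

Everything the pipeline consumes can be generated at desk scale with a known
ground truth: descriptor-satisfying (and deliberately broken) ribozyme
sequences, genomes with planted mobile elements carrying a 77-nt hallmark,
a downstream poly-A tract at the class-appropriate distance, flanking 7-11 nt
target-site duplications, point-mutation divergence, and noisy two-phase
cleavage time-courses.

Background sequence is i.i.d. (configurable GC fraction) rather than
Markov-correlated: sufficient for the false-positive-rate targets of the
detection rules and much easier to reason about.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._align import revcomp
from .errors import InputError, Pr77KitError, UnsatisfiableDescriptorError
from .fold import (
    DEFAULT_DESCRIPTOR,
    FoldAssignment,
    P1_GC_RUN_SHORT,
    P1_MISMATCH_AT_PLUS1,
    P1_TOO_SHORT,
    P2_TOO_SHORT,
    P3_UNFOLDED,
    P4_UNFOLDED,
    P11_UNFOLDED,
    VIOLATION_CODES,
    Placement,
    RibozymeDescriptor,
    _Enumerator,
    best_folding,
)
from .kinetics import TimeCourse, two_phase_model
from .scan import GenomeSequence, QueryProfile

_BASES = "ACGT"
_WC_CHOICES = [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]
_GC_CHOICES = [("G", "C"), ("C", "G")]
_WOBBLE_CHOICES = [("G", "T"), ("T", "G")]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(_BASES), size=n, p=p))


# -- ribozyme sampling --------------------------------------------------------

@dataclass(frozen=True)
class SampledRibozyme:
    seq: str
    truth: FoldAssignment

    @property
    def placement(self) -> Placement:
        return self.truth.placement


def _sample_geometry(
    rng: np.random.Generator, L: int, d: RibozymeDescriptor, max_tries: int = 2000
) -> Placement | None:
    """Sample one helix placement for a candidate of length L by drawing the
    free geometry variables and keeping draws the length budget can close."""
    from .fold import _right_combo_table, _RIGHT_TABLES

    rt = _RIGHT_TABLES.get(d)
    if rt is None:
        rt = _right_combo_table(d)
        _RIGHT_TABLES[d] = rt
    win0, win1 = d.p1_3p_window
    ri = rng.integers
    for _ in range(max_tries):
        p1_len = int(ri(d.p1.min_len, d.p1.max_len + 1))
        j12 = int(ri(d.j12[0], d.j12[1] + 1))
        p2_len = int(ri(d.p2.min_len, d.p2.max_len + 1))
        l2 = int(ri(d.loop2[0], d.loop2[1] + 1))
        j23 = int(ri(d.j23[0], d.j23[1] + 1))
        p3_len = int(ri(d.p3.min_len, d.p3.max_len + 1))
        gap = int(ri(d.gap_p11_p1[0], d.gap_p11_p1[1] + 1))
        s2 = p1_len + 1 + j12
        s3 = s2 + 2 * p2_len + l2 + j23
        w = s3 + p3_len + 2 + gap
        if not win0 <= w <= win1:
            continue
        budget = L - (w + p1_len + 2) + 1 - p3_len
        combos = rt.get(budget)
        if not combos:
            continue
        j4, p4_len, l4, j43, tail = combos[int(ri(len(combos)))]
        return Placement(
            p1_len, w, s2, p2_len, l2, s3, p3_len,
            w + p1_len + 2 + j4, p4_len, l4, L - tail - p3_len + 1, tail,
        )
    return None


def _fill_sequence(
    rng: np.random.Generator, L: int, pl: Placement, d: RibozymeDescriptor
) -> str:
    """Fill helices complementarily (respecting the P1 GC-run and P1.1 G:C
    rules) and junctions randomly."""
    seq: list[str | None] = [None] * L

    def put_pair(i: int, j: int, choices) -> None:
        a, b = choices[int(rng.integers(len(choices)))]
        seq[i - 1], seq[j - 1] = a, b

    def helix_choices(wobble_allowed: bool):
        if wobble_allowed and rng.random() < 0.15:
            return _WOBBLE_CHOICES
        return _WC_CHOICES

    # P1 with a guaranteed run of consecutive G:C pairs
    p1_pairs = [(k, pl.w + pl.p1_len - k) for k in range(1, pl.p1_len + 1)]
    run_len = d.p1_min_consecutive_gc
    run_at = int(rng.integers(0, pl.p1_len - run_len + 1))
    for idx, (i, j) in enumerate(p1_pairs):
        if run_at <= idx < run_at + run_len:
            put_pair(i, j, _GC_CHOICES)
        else:
            put_pair(i, j, helix_choices(d.p1.wobble_allowed))
    # P2 hairpin
    end2 = pl.s2 + 2 * pl.p2_len + pl.l2 - 1
    for i in range(pl.p2_len):
        put_pair(pl.s2 + i, end2 - i, helix_choices(d.p2.wobble_allowed))
    # P3 long-range helix
    for i in range(pl.p3_len):
        put_pair(pl.s3 + i, pl.s33 + pl.p3_len - 1 - i, helix_choices(d.p3.wobble_allowed))
    # P1.1: two G:C pairs
    a, b = pl.p11_5p, pl.p11_3p
    put_pair(a, b + 1, _GC_CHOICES)
    put_pair(a + 1, b, _GC_CHOICES)
    # P4 hairpin
    end4 = pl.s4 + 2 * pl.p4_len + pl.l4 - 1
    for i in range(pl.p4_len):
        put_pair(pl.s4 + i, end4 - i, helix_choices(d.p4.wobble_allowed))
    # junctions, loops, tail
    for idx in range(L):
        if seq[idx] is None:
            seq[idx] = _BASES[int(rng.integers(4))]
    return "".join(seq)


def sample_ribozyme(
    descriptor: RibozymeDescriptor = DEFAULT_DESCRIPTOR,
    rng_seed=0,
    length: int | None = None,
    length_range: tuple[int, int] = (77, 95),
) -> SampledRibozyme:
    """Generate a descriptor-satisfying hallmark sequence with its truth fold.

    The truth assignment is built from the sampled placement and is
    violation-free by construction, so ``validate_hallmark`` is guaranteed to
    pass.  Identical seeds give identical sequences.
    """
    rng = _rng(rng_seed)
    d = descriptor
    for _attempt in range(1000):
        L = length if length is not None else int(
            rng.integers(length_range[0], length_range[1] + 1)
        )
        pl = _sample_geometry(rng, L, d)
        if pl is None:
            if length is not None:
                raise UnsatisfiableDescriptorError(
                    f"no helix placement fits a candidate of length {L}; "
                    f"the P1 3' window {d.p1_3p_window} with the junction "
                    f"ranges is the binding constraint"
                )
            continue
        seq = _fill_sequence(rng, L, pl, d)
        truth = _Enumerator(seq, d).assignment(pl)
        if truth.violations == ():
            return SampledRibozyme(seq=seq, truth=truth)
    raise UnsatisfiableDescriptorError(
        "could not generate a violation-free sequence in 1000 attempts"
    )


# -- constraint breaking ------------------------------------------------------

def _scramble(rng, s: list, lo: int, hi: int, n: int) -> None:
    """Randomise up to ``n`` positions in the 1-based inclusive range."""
    lo, hi = max(lo, 1), min(hi, len(s))
    if hi < lo:
        return
    span = np.arange(lo - 1, hi)
    for p in rng.choice(span, size=min(n, len(span)), replace=False):
        s[p] = _BASES[int(rng.integers(4))]


def _illegal_partner(rng, base: str, wobble: bool) -> str:
    options = [
        b for b in _BASES
        if (base + b) not in {"AT", "TA", "GC", "CG"}
        and not (wobble and (base + b) in {"GT", "TG"})
    ]
    return options[int(rng.integers(len(options)))]


def _damage_placement(
    rng, s: list, fold: FoldAssignment, code: str, d: RibozymeDescriptor,
    intensity: int = 0,
) -> None:
    """Break the code's target helix in one concrete assignment, in place.

    ``intensity`` grows across retries: overlapping registers of the same
    helix can rescue each other in a two-cycle, so later rounds additionally
    scramble random positions around the targeted strand to break ties.
    """
    pl = fold.placement
    pairs_by_helix = dict(fold._pairs_by_helix)

    if code == P1_MISMATCH_AT_PLUS1:
        pairs = list(pairs_by_helix["P1"])
        if pairs and pairs[0][0] == 1:
            # keep a G:C run among the inner pairs so the +1 mismatch is the
            # only P1 defect, then install the LmexSIDER2A-style C1:A pair
            inner = pairs[1:]
            run = d.p1_min_consecutive_gc
            if inner:
                r0 = int(rng.integers(0, max(len(inner) - run, 0) + 1))
                for i, j in inner[r0 : r0 + run]:
                    a, b = _GC_CHOICES[int(rng.integers(2))]
                    s[i - 1], s[j - 1] = a, b
            s[0] = "C"
            s[pairs[0][1] - 1] = "A"
        else:
            # P1 of this placement is already damaged in the wrong way;
            # shuffle its 3' strand window to move the fold landscape
            _scramble(rng, s, pl.w, pl.w + pl.p1_len - 1, 1)
    elif code == P1_TOO_SHORT:
        # interior pairs right after +1: shared by every same-diagonal register
        pairs = [p for p in pairs_by_helix["P1"] if p[0] != 1][:2]
        for i, j in pairs:
            s[j - 1] = _illegal_partner(rng, s[i - 1], d.p1.wobble_allowed)
        if not pairs:
            _scramble(rng, s, pl.w, pl.w + pl.p1_len - 1, 1)
    elif code == P1_GC_RUN_SHORT:
        gc = [
            (i, j) for i, j in pairs_by_helix["P1"]
            if s[i - 1] + s[j - 1] in {"GC", "CG"}
        ]
        for i, j in gc:
            s[i - 1], s[j - 1] = ("A", "T") if rng.random() < 0.5 else ("T", "A")
        if not gc:
            _scramble(rng, s, pl.w, pl.w + pl.p1_len - 1, 1)
    elif code == P2_TOO_SHORT:
        pairs = list(pairs_by_helix["P2"])  # outermost first
        for i, j in pairs[: max(len(pairs) - 3, 1)]:
            s[i - 1] = _illegal_partner(rng, s[j - 1], d.p2.wobble_allowed)
        if intensity > 1:
            _scramble(rng, s, pl.p1_len + 1, pl.s3 - 1, 1 + intensity // 4)
    elif code == P3_UNFOLDED:
        for i, j in pairs_by_helix["P3"]:
            s[j - 1] = _illegal_partner(rng, s[i - 1], d.p3.wobble_allowed)
        if intensity > 1:
            _scramble(rng, s, pl.s33 - 2, len(s), 1 + intensity // 4)
    elif code == P11_UNFOLDED:
        s[pl.p11_3p - 1] = "A"
        s[pl.p11_3p] = "A"
        if intensity > 1:
            _scramble(rng, s, pl.p11_5p, pl.p11_5p + 1, 1)
    elif code == P4_UNFOLDED:
        pairs = list(pairs_by_helix["P4"])  # outermost first
        for i, j in pairs[-1:]:  # the loop-adjacent pair kills the zip
            s[j - 1] = _illegal_partner(rng, s[i - 1], d.p4.wobble_allowed)
        if intensity > 1:
            end4 = pl.s4 + 2 * pl.p4_len + pl.l4 - 1
            _scramble(rng, s, pl.s4 + pl.p4_len, end4, 1 + intensity // 4)
    else:
        raise InputError(f"cannot break constraint {code!r} by point mutation")


def break_constraint(
    seq: str,
    truth: FoldAssignment,
    code: str,
    rng_seed=0,
    max_attempts: int = 60,
    descriptor: RibozymeDescriptor = DEFAULT_DESCRIPTOR,
) -> str:
    """Minimally mutate a passing sequence so validation fails with ``code``.

    Adaptive: each round damages the requested helix of whichever assignment
    currently wins, so alternative placements that would rescue the fold are
    demoted one by one.  The result is re-validated: full enumeration finds no
    passing fold and the best fold carries the requested violation code.
    """
    rng = _rng(rng_seed)
    if truth.placement is None:
        raise InputError("truth assignment carries no placement")
    if code not in VIOLATION_CODES or code == "WINDOW_UNSATISFIABLE":
        raise InputError(f"cannot break constraint {code!r} by point mutation")
    d = descriptor

    s = list(seq)
    current = truth
    for _attempt in range(max_attempts):
        _damage_placement(rng, s, current, code, d, intensity=_attempt)
        mutated = "".join(s)
        res = best_folding(mutated, d)
        if not res.passes and code in res.violations:
            return mutated
        current = res
        if current.placement is None:  # pragma: no cover - length never changes
            break
    raise Pr77KitError(
        f"could not break constraint {code} for this sequence in {max_attempts} attempts"
    )


# -- element and genome construction ------------------------------------------

@dataclass(frozen=True)
class ElementOptions:
    divergence_pct: float = 5.0
    tsd_len: int | None = None          # None: drawn uniformly from 7..11
    polya_len: int = 25
    body_len: int | None = None         # None: class-appropriate random length
    tandem_gap: int | None = None       # SIDER2 signature spacing (None: 0..50)
    with_tsd: bool = True
    long_ref: str | None = None         # reference LINE sequence for SIDE_NAR


@dataclass(frozen=True)
class ElementBuild:
    element_class: str
    seq: str                            # hallmark(s) .. body .. poly-A
    hallmark_offsets: tuple[tuple[int, int], ...]  # within seq, 0-based half-open
    polya_offset: tuple[int, int]
    tsd: str | None
    n_hallmark_mutations: tuple[int, ...]


_SHORT_BODY = (400, 700)
_LINE_BODY = (4500, 6000)


def _sample_tsd(rng: np.random.Generator, n: int) -> str:
    """Random TSD whose edges cannot extend the planted homopolymer tails:
    first base is never A (it abuts the poly-A on '+') and the last base is
    never T (it abuts the poly-T start of a '-' insertion); A/T-saturated
    draws are rejected."""
    while True:
        tsd = _random_seq(rng, n)
        if tsd[0] == "A" or tsd[-1] == "T":
            continue
        if (tsd.count("A") + tsd.count("T")) / n > 0.7:
            continue
        return tsd


def _mutate(rng, seq: str, pct: float) -> tuple[str, int]:
    n = int(round(pct / 100.0 * len(seq)))
    if n == 0:
        return seq, 0
    pos = rng.choice(len(seq), size=n, replace=False)
    s = list(seq)
    for p in pos:
        s[p] = rng.choice([b for b in _BASES if b != s[p]])
    return "".join(s), n


def build_element(
    element_class: str,
    rng_seed=0,
    options: ElementOptions | None = None,
    hallmark_seq: str | None = None,
    descriptor: RibozymeDescriptor = DEFAULT_DESCRIPTOR,
) -> ElementBuild:
    """Assemble one mobile-element sequence of the requested class.

    SIDER1/SIDE_NAR: one hallmark, short body (~0.4-0.8 kb), poly-A.
    SIDER2: two tandem hallmarks, short body, poly-A.
    LINE_DIRE: one hallmark, long body (4.5-6 kb), poly-A.
    Hallmark copies are point-mutated at ``divergence_pct``.
    """
    rng = _rng(rng_seed)
    opts = options or ElementOptions()
    if element_class not in {"SIDER1", "SIDER2", "LINE_DIRE", "SIDE_NAR"}:
        raise InputError(f"unknown element class {element_class!r}")

    hm = hallmark_seq or sample_ribozyme(descriptor, rng, length=77).seq
    tsd = None
    if opts.with_tsd:
        tsd_len = opts.tsd_len or int(rng.integers(7, 12))
        tsd = _sample_tsd(rng, tsd_len)
    polya = "A" * opts.polya_len

    if element_class == "SIDE_NAR":
        if opts.long_ref is None:
            raise InputError("SIDE_NAR requires options.long_ref (a LINE sequence)")
        ref = opts.long_ref.rstrip("A")
        h1, n1 = _mutate(rng, hm, opts.divergence_pct)
        body = opts.long_ref[len(hm) : len(hm) + 300] + ref[-250:]
        seq = h1 + body + polya
        return ElementBuild(
            element_class, seq, ((0, len(h1)),),
            (len(seq) - len(polya), len(seq)), tsd, (n1,),
        )

    lo, hi = _LINE_BODY if element_class == "LINE_DIRE" else _SHORT_BODY
    body_len = opts.body_len if opts.body_len is not None else int(rng.integers(lo, hi + 1))
    body = _random_seq(rng, body_len)

    if element_class == "SIDER2":
        gap = opts.tandem_gap if opts.tandem_gap is not None else int(rng.integers(0, 51))
        h1, n1 = _mutate(rng, hm, opts.divergence_pct)
        h2, n2 = _mutate(rng, hm, opts.divergence_pct)
        gap_fill = _random_seq(rng, gap)
        seq = h1 + gap_fill + h2 + body + polya
        offs = (
            (0, len(h1)),
            (len(h1) + gap, len(h1) + gap + len(h2)),
        )
        return ElementBuild(
            element_class, seq, offs, (len(seq) - len(polya), len(seq)), tsd, (n1, n2)
        )

    h1, n1 = _mutate(rng, hm, opts.divergence_pct)
    seq = h1 + body + polya
    return ElementBuild(
        element_class, seq, ((0, len(h1)),),
        (len(seq) - len(polya), len(seq)), tsd, (n1,),
    )


# -- genome planting ----------------------------------------------------------

@dataclass(frozen=True)
class PlantSpec:
    element_class: str
    strand: str = "+"
    options: ElementOptions | None = None


@dataclass(frozen=True)
class TruthRecord:
    contig: str
    start: int
    end: int
    strand: str
    element_class: str
    hallmark_spans: tuple[tuple[int, int], ...]
    polya_span: tuple[int, int]
    tsd_seq: str | None
    has_tsd: bool


@dataclass(frozen=True)
class SyntheticTruth:
    records: tuple[TruthRecord, ...]
    manifest: dict


@dataclass(frozen=True)
class PlantedGenome:
    genomes: tuple[GenomeSequence, ...]
    truth: SyntheticTruth
    query: QueryProfile


def plant_genome(
    n_contigs: int,
    contig_len: int,
    element_specs: list[PlantSpec],
    rng_seed=0,
    gc_fraction: float = 0.5,
    spacing: int = 1000,
    margin: int = 2000,
    descriptor: RibozymeDescriptor = DEFAULT_DESCRIPTOR,
) -> PlantedGenome:
    """Plant elements in i.i.d. background contigs with duplicated TSDs.

    One hallmark consensus is sampled per genome (returned as the scan
    query); each planted copy diverges from it by its options'
    ``divergence_pct``.  The emitted FASTA length equals
    ``n_contigs * contig_len`` plus the total inserted length, and the same
    seed reproduces the genome byte-for-byte.
    """
    rng = _rng(rng_seed)
    consensus = sample_ribozyme(descriptor, rng, length=77).seq
    query = QueryProfile(id="hallmark_consensus", consensus=consensus)

    # distribute elements over contigs round-robin
    per_contig: list[list[PlantSpec]] = [[] for _ in range(n_contigs)]
    for i, spec in enumerate(element_specs):
        per_contig[i % n_contigs].append(spec)

    long_ref_cache: str | None = None
    genomes: list[GenomeSequence] = []
    records: list[TruthRecord] = []

    for ci in range(n_contigs):
        name = f"contig{ci + 1}"
        background = _random_seq(rng, contig_len, gc_fraction)
        specs = per_contig[ci]

        builds = []
        for spec in specs:
            opts = spec.options or ElementOptions()
            if spec.element_class == "SIDE_NAR" and opts.long_ref is None:
                if long_ref_cache is None:
                    long_ref_cache = build_element(
                        "LINE_DIRE", rng, ElementOptions(divergence_pct=0.0),
                        hallmark_seq=consensus, descriptor=descriptor,
                    ).seq
                opts = replace(opts, long_ref=long_ref_cache)
            builds.append(
                (spec, build_element(
                    spec.element_class, rng, opts,
                    hallmark_seq=consensus, descriptor=descriptor,
                ))
            )

        # insertion points in background coordinates
        total_needed = margin * 2 + sum(
            len(b.seq) + 2 * len(b.tsd or "") + spacing for _, b in builds
        )
        if total_needed > contig_len:
            raise InputError(
                f"{name}: {len(builds)} elements need {total_needed} nt but "
                f"contig is {contig_len} nt"
            )
        positions = sorted(
            int(p) for p in rng.choice(
                np.arange(margin, contig_len - margin), size=len(builds), replace=False
            )
        )
        # enforce spacing greedily
        for i in range(1, len(positions)):
            positions[i] = max(positions[i], positions[i - 1] + spacing)
        if positions and positions[-1] > contig_len - margin:
            raise InputError(f"{name}: cannot respect spacing; enlarge the contig")

        pieces: list[str] = []
        cursor = 0
        offset = 0
        for (spec, build), pos in zip(builds, positions):
            pieces.append(background[cursor:pos])
            cursor = pos
            tsd = build.tsd or ""
            oriented = build.seq if spec.strand == "+" else revcomp(build.seq)
            block = tsd + oriented + tsd
            pieces.append(block)

            elem_start = pos + offset + len(tsd)
            elem_end = elem_start + len(build.seq)
            if spec.strand == "+":
                hspans = tuple(
                    (elem_start + s, elem_start + e) for s, e in build.hallmark_offsets
                )
                pspan = (
                    elem_start + build.polya_offset[0],
                    elem_start + build.polya_offset[1],
                )
            else:
                n = len(build.seq)
                hspans = tuple(
                    (elem_start + n - e, elem_start + n - s)
                    for s, e in build.hallmark_offsets
                )
                pspan = (
                    elem_start + n - build.polya_offset[1],
                    elem_start + n - build.polya_offset[0],
                )
            records.append(
                TruthRecord(
                    contig=name, start=elem_start, end=elem_end,
                    strand=spec.strand, element_class=build.element_class,
                    hallmark_spans=hspans, polya_span=pspan,
                    tsd_seq=build.tsd, has_tsd=build.tsd is not None,
                )
            )
            offset += len(block)
        pieces.append(background[cursor:])
        genomes.append(GenomeSequence(id=name, residues="".join(pieces)))

    manifest = {
        "rng_seed": repr(rng_seed),
        "n_contigs": n_contigs,
        "contig_len": contig_len,
        "gc_fraction": gc_fraction,
        "spacing": spacing,
        "margin": margin,
        "n_elements": len(element_specs),
        "consensus": consensus,
    }
    return PlantedGenome(
        genomes=tuple(genomes),
        truth=SyntheticTruth(records=tuple(records), manifest=manifest),
        query=query,
    )


# -- kinetics simulation ------------------------------------------------------

@dataclass(frozen=True)
class KineticTruth:
    A: float
    B: float
    C: float
    k1: float
    k2: float
    times: tuple[float, ...] = (0.0, 1.0, 2.0, 5.0, 10.0, 20.0, 40.0, 80.0, 160.0)
    noise_sd: float = 2.0
    seed: int = 0
    mg_mM: float = 0.1
    replicate_id: str = "sim"

    def __post_init__(self) -> None:
        if not self.k1 >= self.k2 > 0:
            raise InputError("KineticTruth requires k1 >= k2 > 0")


def simulate_timecourse(kt: KineticTruth) -> TimeCourse:
    """Noisy observations of the two-phase decay curve, clipped to [0, 100]."""
    rng = np.random.default_rng(kt.seed)
    t = np.asarray(kt.times)
    fc = two_phase_model(kt.A, kt.B, kt.C, kt.k1, kt.k2, t)
    if kt.noise_sd > 0:
        fc = fc + rng.normal(0.0, kt.noise_sd, size=len(t))
    fc = np.clip(fc, 0.0, 100.0)
    return TimeCourse(
        times=tuple(t), fc_obs=tuple(fc),
        mg_mM=kt.mg_mM, replicate_id=kt.replicate_id,
    )
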