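"""Descriptor-based validation of the HDV-like ribozyme architecture.

A Pr77-hallmark RNA is accepted as a candidate self-cleaving ribozyme when it
can adopt the nested double-pseudoknot fold of the Hepatitis-Delta-Virus
ribozyme family: helices P1, P2 and P4 plus the two crossing pseudoknot
helices P3 and P1.1, with self-cleavage at the phosphodiester bond 5' of the
+1 nucleotide (the first nucleotide of P1's 5' strand).

The topology fixed here, 5' to 3' along the strand::

    [P1 5'] j1/2 [P2 hairpin] j2/3 [P3 5'] [P1.1 5'] gap [P1 3'] [P1.1 3']
        j4 [P4 hairpin] j4/3 [P3 3'] tail

P1, P2 and P4 are mutually nested; P3 crosses P1 (its 3' strand returns near
the 3' end of the molecule) and P1.1 crosses P1 (pairing two loop bases 5' of
the P1 3' strand with the two bases immediately 3' of it).  Every helix
placement consistent with the descriptor windows is enumerated exhaustively;
``best_folding`` is the maximum under a fixed total order, so it can serve as
an automated replacement for manual folding while remaining oracle-testable
against the full enumeration.

Base pairs are Watson-Crick (A:U/T, G:C) or, where the descriptor allows,
wobble G:U/T; P1.1 is restricted to G:C pairs.  T and U are equivalent
throughout.  The catalytic-nucleotide identity is deliberately not checked --
only the architecture is validated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, NamedTuple

from .errors import InputError, UnsatisfiableDescriptorError

# Violation codes ------------------------------------------------------------

P1_MISMATCH_AT_PLUS1 = "P1_MISMATCH_AT_PLUS1"
P1_GC_RUN_SHORT = "P1_GC_RUN_SHORT"
P1_TOO_SHORT = "P1_TOO_SHORT"
P2_TOO_SHORT = "P2_TOO_SHORT"
P3_UNFOLDED = "P3_UNFOLDED"
P11_UNFOLDED = "P11_UNFOLDED"
P4_UNFOLDED = "P4_UNFOLDED"
WINDOW_UNSATISFIABLE = "WINDOW_UNSATISFIABLE"

VIOLATION_CODES = (
    P1_MISMATCH_AT_PLUS1,
    P1_GC_RUN_SHORT,
    P1_TOO_SHORT,
    P2_TOO_SHORT,
    P3_UNFOLDED,
    P11_UNFOLDED,
    P4_UNFOLDED,
    WINDOW_UNSATISFIABLE,
)

_WC = {"AT", "TA", "GC", "CG"}
_WOBBLE = {"GT", "TG"}
_GC = {"GC", "CG"}


def _legal(a: str, b: str, wobble: bool) -> bool:
    p = a + b
    return p in _WC or (wobble and p in _WOBBLE)


# Descriptor ------------------------------------------------------------------

@dataclass(frozen=True)
class HelixSpec:
    """Length range (bp) and wobble policy for one helix."""

    min_len: int
    max_len: int
    wobble_allowed: bool = True

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise UnsatisfiableDescriptorError(
                f"helix min_len {self.min_len} > max_len {self.max_len}"
            )


@dataclass(frozen=True)
class RibozymeDescriptor:
    """Geometry of the HDV-like fold, positions 1-based relative to +1.

    ``p1_3p_window`` bounds the start (5'-most nucleotide) of the P1 3'
    strand; the default [30, 45] places the partner of the +1 nucleotide near
    position 39 for ~80-nt signatures, matching the C1:A39 register discussed
    for LmexSIDER2A.  ``p1_min_consecutive_gc`` is the minimum run of
    consecutive G:C pairs required inside P1 (3 by default; relaxable to 2,
    as for TvSIDER1).  Junction ranges are (min, max) nucleotide counts.
    """

    p1: HelixSpec = HelixSpec(6, 8, wobble_allowed=True)
    p11: HelixSpec = HelixSpec(2, 2, wobble_allowed=False)  # G:C only
    p2: HelixSpec = HelixSpec(4, 7, wobble_allowed=True)
    p3: HelixSpec = HelixSpec(3, 6, wobble_allowed=True)
    p4: HelixSpec = HelixSpec(3, 12, wobble_allowed=True)
    p1_3p_window: tuple[int, int] = (30, 45)
    p1_min_consecutive_gc: int = 3
    j12: tuple[int, int] = (0, 2)
    loop2: tuple[int, int] = (3, 5)
    j23: tuple[int, int] = (0, 1)
    gap_p11_p1: tuple[int, int] = (0, 5)
    j4: tuple[int, int] = (0, 2)
    loop4: tuple[int, int] = (3, 7)
    j43: tuple[int, int] = (0, 1)
    tail: tuple[int, int] = (0, 2)
    min_candidate_len: int = 60
    max_candidate_len: int = 140

    def __post_init__(self) -> None:
        if self.p1_min_consecutive_gc > self.p1.max_len:
            raise UnsatisfiableDescriptorError(
                f"p1_min_consecutive_gc={self.p1_min_consecutive_gc} exceeds "
                f"P1 max_len={self.p1.max_len}"
            )
        if not 1 <= self.p1_3p_window[0] <= self.p1_3p_window[1] <= 130:
            raise UnsatisfiableDescriptorError(
                f"P1 3' window {self.p1_3p_window} outside [1, 130]"
            )
        if self.p11.min_len != 2 or self.p11.max_len != 2:
            raise UnsatisfiableDescriptorError("P1.1 is fixed at 2 bp")


DEFAULT_DESCRIPTOR = RibozymeDescriptor()


# Geometric placements --------------------------------------------------------

class Placement(NamedTuple):
    """One concrete geometry of all five helices (1-based positions)."""

    p1_len: int
    w: int          # start of P1 3' strand
    s2: int         # start of P2 5' strand
    p2_len: int
    l2: int
    s3: int         # start of P3 5' strand
    p3_len: int
    s4: int         # start of P4 5' strand
    p4_len: int
    l4: int
    s33: int        # start of P3 3' strand
    tail: int

    @property
    def p11_5p(self) -> int:
        return self.s3 + self.p3_len

    @property
    def p11_3p(self) -> int:
        return self.w + self.p1_len


def _right_combo_table(d: RibozymeDescriptor) -> dict[int, list[tuple[int, int, int, int, int]]]:
    """Map from 3'-side nucleotide budget to all (j4, p4_len, l4, j43, tail)
    combinations consuming exactly that budget (P3 3' strand excluded)."""
    table: dict[int, list[tuple[int, int, int, int, int]]] = {}
    for j4 in range(d.j4[0], d.j4[1] + 1):
        for p4_len in range(d.p4.min_len, d.p4.max_len + 1):
            for l4 in range(d.loop4[0], d.loop4[1] + 1):
                for j43 in range(d.j43[0], d.j43[1] + 1):
                    for tail in range(d.tail[0], d.tail[1] + 1):
                        budget = j4 + 2 * p4_len + l4 + j43 + tail
                        table.setdefault(budget, []).append(
                            (j4, p4_len, l4, j43, tail)
                        )
    return table


_RIGHT_TABLES: dict[tuple, dict] = {}


def iter_geometries(length: int, descriptor: RibozymeDescriptor = DEFAULT_DESCRIPTOR) -> Iterator[Placement]:
    """Yield every helix placement consistent with the descriptor windows for a
    candidate of the given length.  Purely geometric: no sequence involved."""
    d = descriptor
    rt = _RIGHT_TABLES.get(d)
    if rt is None:
        rt = _right_combo_table(d)
        _RIGHT_TABLES[d] = rt
    win0, win1 = d.p1_3p_window
    for p1_len in range(d.p1.min_len, d.p1.max_len + 1):
        for j12 in range(d.j12[0], d.j12[1] + 1):
            s2 = p1_len + 1 + j12
            for p2_len in range(d.p2.min_len, d.p2.max_len + 1):
                for l2 in range(d.loop2[0], d.loop2[1] + 1):
                    end2 = s2 + 2 * p2_len + l2 - 1
                    for j23 in range(d.j23[0], d.j23[1] + 1):
                        s3 = end2 + 1 + j23
                        for p3_len in range(d.p3.min_len, d.p3.max_len + 1):
                            base = s3 + p3_len + 2  # first pos after P1.1 5'
                            for gap in range(d.gap_p11_p1[0], d.gap_p11_p1[1] + 1):
                                w = base + gap
                                if w < win0 or w > win1:
                                    continue
                                q = w + p1_len + 2  # first pos after P1.1 3'
                                budget = length - q + 1 - p3_len
                                for j4, p4_len, l4, j43, tail in rt.get(budget, ()):
                                    s4 = q + j4
                                    s33 = length - tail - p3_len + 1
                                    yield Placement(
                                        p1_len, w, s2, p2_len, l2, s3, p3_len,
                                        s4, p4_len, l4, s33, tail,
                                    )


# Fold assignment -------------------------------------------------------------

_LAYER = {"P1": "()", "P2": "()", "P4": "()", "P3": "[]", "P1.1": "{}"}


class FoldAssignment:
    """A concrete base-pair assignment for one candidate sequence.

    ``pairs`` lists (i, j, helix) with 1-based i < j; only chemically formed
    pairs are listed, so a placement with violations carries the pairs that do
    form.  ``passes`` is True iff the violation list is empty.
    """

    __slots__ = (
        "seq", "placement", "violations", "p1_gc_run",
        "_pairs_by_helix", "_total_pairs",
    )

    def __init__(self, seq, placement, violations, p1_gc_run, pairs_by_helix, total_pairs):
        self.seq = seq
        self.placement = placement
        self.violations = violations
        self.p1_gc_run = p1_gc_run
        self._pairs_by_helix = pairs_by_helix
        self._total_pairs = total_pairs

    @property
    def passes(self) -> bool:
        return not self.violations

    @property
    def total_pairs(self) -> int:
        return self._total_pairs

    @property
    def pairs(self) -> list[tuple[int, int, str]]:
        out = []
        for helix, helix_pairs in self._pairs_by_helix:
            for i, j in helix_pairs:
                out.append((i, j, helix) if i < j else (j, i, helix))
        return sorted(out)

    @property
    def helix_lengths(self) -> dict[str, int]:
        return {helix: len(ps) for helix, ps in self._pairs_by_helix}

    @property
    def dotbracket(self) -> str:
        """Layered dot-bracket: () for nested P1/P2/P4, [] for P3, {} for P1.1."""
        db = ["."] * len(self.seq)
        for i, j, helix in self.pairs:
            op, cl = _LAYER[helix]
            db[i - 1] = op
            db[j - 1] = cl
        return "".join(db)

    @property
    def sort_key(self) -> tuple:
        """Total order: fewest violations, most pairs, longest P1 GC run,
        leftmost P1 3' strand (ascending key; min is best)."""
        w = self.placement.w if self.placement is not None else 10**9
        return (len(self.violations), -self._total_pairs, -self.p1_gc_run, w)

    def to_dict(self) -> dict:
        return {
            "passes": self.passes,
            "violations": list(self.violations),
            "p1_gc_run": self.p1_gc_run,
            "helix_lengths": self.helix_lengths,
            "pairs": [list(p) for p in self.pairs],
            "dotbracket": self.dotbracket,
        }

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        status = "pass" if self.passes else ",".join(self.violations)
        return f"<FoldAssignment {status} pairs={self._total_pairs} gc_run={self.p1_gc_run}>"


def _normalize(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGT")
    if bad:
        raise InputError(f"candidate sequence contains non-ACGU/T residues: {sorted(bad)}")
    return s


class _Enumerator:
    """Per-sequence enumeration engine with per-helix classification caches."""

    def __init__(self, seq: str, d: RibozymeDescriptor):
        self.seq = seq
        self.d = d
        self._c1: dict = {}
        self._c2: dict = {}
        self._c3: dict = {}
        self._c11: dict = {}
        self._c4: dict = {}
        self._union: dict = {}

    # Each classifier returns (violations tuple, formed-pairs tuple, extra)

    def _p1(self, p1_len: int, w: int):
        key = (p1_len, w)
        hit = self._c1.get(key)
        if hit is not None:
            return hit
        s, wob = self.seq, self.d.p1.wobble_allowed
        pairs_all = [(k, w + p1_len - k) for k in range(1, p1_len + 1)]
        flags = [_legal(s[i - 1], s[j - 1], wob) for i, j in pairs_all]
        # Registers of different length at the same diagonal share the same
        # partner map (k pairs w + p1_len - k), so illegal pairs at the inner
        # (high-k) end are trimmed before classifying: the placement is then
        # equivalent to the shorter register and classifies identically.
        m = p1_len
        while m > 0 and not flags[m - 1]:
            m -= 1
        inner = flags[:m]
        if m >= self.d.p1.min_len and all(inner):
            viol: tuple = ()
        elif m >= self.d.p1.min_len and not inner[0] and all(inner[1:]):
            viol = (P1_MISMATCH_AT_PLUS1,)
        else:
            viol = (P1_TOO_SHORT,)
        formed = tuple(p for p, f in zip(pairs_all[:m], inner) if f)
        # longest run of consecutive G:C pairs among contiguously legal pairs
        gc_run = run = 0
        for (i, j), f in zip(pairs_all, flags):
            if f and s[i - 1] + s[j - 1] in _GC:
                run += 1
                gc_run = max(gc_run, run)
            else:
                run = 0
        if viol in ((), (P1_MISMATCH_AT_PLUS1,)) and gc_run < self.d.p1_min_consecutive_gc:
            viol = viol + (P1_GC_RUN_SHORT,)
        res = (viol, formed, gc_run)
        self._c1[key] = res
        return res

    def _hairpin(self, cache, start, n, loop, wobble, min_len, code):
        key = (start, n, loop)
        hit = cache.get(key)
        if hit is not None:
            return hit
        s = self.seq
        end = start + 2 * n + loop - 1
        pairs_all = [(start + i, end - i) for i in range(n)]
        # The helix zips from the loop outward: count contiguous legal pairs
        # starting at the loop-adjacent (innermost) pair.
        eff = 0
        for i, j in reversed(pairs_all):
            if _legal(s[i - 1], s[j - 1], wobble):
                eff += 1
            else:
                break
        viol = () if eff >= min_len else (code,)
        formed = tuple(pairs_all[n - eff:])
        res = (viol, formed)
        cache[key] = res
        return res

    def _p2(self, s2, p2_len, l2):
        return self._hairpin(
            self._c2, s2, p2_len, l2, self.d.p2.wobble_allowed,
            self.d.p2.min_len, P2_TOO_SHORT,
        )

    def _p4(self, s4, p4_len, l4):
        return self._hairpin(
            self._c4, s4, p4_len, l4, self.d.p4.wobble_allowed,
            self.d.p4.min_len, P4_UNFOLDED,
        )

    def _p3(self, s3, p3_len, s33):
        key = (s3, p3_len, s33)
        hit = self._c3.get(key)
        if hit is not None:
            return hit
        s, wob = self.seq, self.d.p3.wobble_allowed
        pairs_all = [(s3 + i, s33 + p3_len - 1 - i) for i in range(p3_len)]
        flags = [_legal(s[i - 1], s[j - 1], wob) for i, j in pairs_all]
        # longest contiguous legal run
        best_run, best_at, run = 0, 0, 0
        for idx, f in enumerate(flags):
            run = run + 1 if f else 0
            if run > best_run:
                best_run, best_at = run, idx - run + 1
        viol = () if best_run >= self.d.p3.min_len else (P3_UNFOLDED,)
        formed = tuple(pairs_all[best_at : best_at + best_run])
        res = (viol, formed)
        self._c3[key] = res
        return res

    def _p11(self, a, b):
        key = (a, b)
        hit = self._c11.get(key)
        if hit is not None:
            return hit
        s = self.seq
        pairs_all = [(a, b + 1), (a + 1, b)]
        formed = tuple(
            (i, j) for i, j in pairs_all if s[i - 1] + s[j - 1] in _GC
        )
        viol = () if len(formed) == 2 else (P11_UNFOLDED,)
        res = (viol, formed)
        self._c11[key] = res
        return res

    def _merge(self, vkey: tuple) -> tuple:
        merged = self._union.get(vkey)
        if merged is None:
            merged = tuple(sorted({v for vs in vkey for v in vs}))
            self._union[vkey] = merged
        return merged

    def assignment(self, pl: Placement) -> FoldAssignment:
        v1, f1, gc_run = self._p1(pl.p1_len, pl.w)
        v2, f2 = self._p2(pl.s2, pl.p2_len, pl.l2)
        v3, f3 = self._p3(pl.s3, pl.p3_len, pl.s33)
        v11, f11 = self._p11(pl.p11_5p, pl.p11_3p)
        v4, f4 = self._p4(pl.s4, pl.p4_len, pl.l4)
        violations = self._merge((v1, v2, v3, v11, v4))
        total = len(f1) + len(f2) + len(f3) + len(f11) + len(f4)
        pairs_by_helix = (
            ("P1", f1), ("P2", f2), ("P3", f3), ("P1.1", f11), ("P4", f4),
        )
        return FoldAssignment(self.seq, pl, violations, gc_run, pairs_by_helix, total)

    def iter_assignments(self) -> Iterator[FoldAssignment]:
        for pl in iter_geometries(len(self.seq), self.d):
            yield self.assignment(pl)

    def best(self) -> FoldAssignment | None:
        """Minimum-key assignment; skips object construction for placements
        that already lose on violation count.  Identical result to taking the
        minimum of :meth:`iter_assignments` under ``sort_key``."""
        best_fa: FoldAssignment | None = None
        best_nviol = 10**9
        p1c, p2c, p3c, p11c, p4c = self._p1, self._p2, self._p3, self._p11, self._p4
        merge = self._merge
        for pl in iter_geometries(len(self.seq), self.d):
            v1, f1, gc_run = p1c(pl.p1_len, pl.w)
            v2, f2 = p2c(pl.s2, pl.p2_len, pl.l2)
            v3, f3 = p3c(pl.s3, pl.p3_len, pl.s33)
            v11, f11 = p11c(pl.p11_5p, pl.p11_3p)
            v4, f4 = p4c(pl.s4, pl.p4_len, pl.l4)
            violations = merge((v1, v2, v3, v11, v4))
            nv = len(violations)
            if nv > best_nviol:
                continue
            total = len(f1) + len(f2) + len(f3) + len(f11) + len(f4)
            key = (nv, -total, -gc_run, pl.w)
            if best_fa is not None and key >= best_fa.sort_key:
                continue
            best_fa = FoldAssignment(
                self.seq, pl, violations, gc_run,
                (("P1", f1), ("P2", f2), ("P3", f3), ("P1.1", f11), ("P4", f4)),
                total,
            )
            best_nviol = nv
        return best_fa


def _unsatisfiable(seq: str) -> FoldAssignment:
    return FoldAssignment(seq, None, (WINDOW_UNSATISFIABLE,), 0, (), 0)


def _check_len(seq: str, d: RibozymeDescriptor) -> None:
    if not d.min_candidate_len <= len(seq) <= d.max_candidate_len:
        raise InputError(
            f"candidate length {len(seq)} outside "
            f"[{d.min_candidate_len}, {d.max_candidate_len}]"
        )


def iter_foldings(
    seq: str, descriptor: RibozymeDescriptor = DEFAULT_DESCRIPTOR
) -> Iterator[FoldAssignment]:
    """Lazily yield every descriptor-consistent assignment (memory-flat form of
    :func:`enumerate_foldings`); yields a single WINDOW_UNSATISFIABLE
    assignment when no geometry fits."""
    s = _normalize(seq)
    _check_len(s, descriptor)
    produced = False
    for fa in _Enumerator(s, descriptor).iter_assignments():
        produced = True
        yield fa
    if not produced:
        yield _unsatisfiable(s)


def enumerate_foldings(
    seq: str, descriptor: RibozymeDescriptor = DEFAULT_DESCRIPTOR
) -> list[FoldAssignment]:
    """Every helix placement consistent with the descriptor windows, each with
    its formed pairs and violation codes (exhaustive oracle for the manual
    folding step)."""
    return list(iter_foldings(seq, descriptor))


def best_folding(
    seq: str, descriptor: RibozymeDescriptor = DEFAULT_DESCRIPTOR
) -> FoldAssignment:
    """Top assignment under the order: fewest violations, then most base
    pairs, then longest P1 GC run, then leftmost P1 3' strand.

    Equals ``min(enumerate_foldings(seq), key=lambda a: a.sort_key)`` by
    construction.
    """
    s = _normalize(seq)
    _check_len(s, descriptor)
    best = _Enumerator(s, descriptor).best()
    return best if best is not None else _unsatisfiable(s)


@dataclass(frozen=True)
class ValidationResult:
    passes: bool
    violations: tuple[str, ...]
    fold: FoldAssignment


def validate_hallmark(
    seq: str,
    descriptor: RibozymeDescriptor = DEFAULT_DESCRIPTOR,
    max_violations: int = 0,
) -> ValidationResult:
    """Accept or reject a hallmark as an HDV-like ribozyme candidate.

    ``max_violations`` > 0 tolerates minor structural disruptions (0 by
    default: only clean folds pass).
    """
    fold = best_folding(seq, descriptor)
    return ValidationResult(
        passes=len(fold.violations) <= max_violations,
        violations=fold.violations,
        fold=fold,
    )


# Cleavage site ---------------------------------------------------------------

@dataclass(frozen=True)
class CleavageSite:
    """Predicted self-cleavage coordinate: the scissile bond lies 5' of the +1
    nucleotide of the ribozyme, i.e. immediately upstream of the hallmark."""

    contig: str
    position: int  # 0-based coordinate of the +1 nucleotide (forward strand)
    strand: str

    @property
    def scissile_bond(self) -> tuple[int, int]:
        """Forward-strand coordinates flanking the cleaved bond (on '+')."""
        return (self.position - 1, self.position)


def predicted_cleavage_site(hit) -> CleavageSite:
    """Map a hallmark hit to its predicted cleavage coordinate.

    On '+' the +1 nucleotide is the hit start; on '-' it is the last
    forward-strand base of the hit (hit.end - 1).
    """
    if hit.strand == "+":
        pos = hit.start
    else:
        pos = hit.end - 1
    return CleavageSite(contig=hit.contig, position=pos, strand=hit.strand)
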