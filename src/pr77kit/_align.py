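"""Smith-Waterman local alignment on small windows.

The scanner (`pr77kit.scan`) finds candidate regions with exact k-mer seeds and
calls :func:`smith_waterman` on a short genome window around each seed cluster,
so the quadratic DP only ever runs on query x window problems of a few hundred
nucleotides a side.  Linear gap penalty; IUPAC ambiguity codes in the query
match any contained base; ``N`` in the target never counts as a match.
"""

from __future__ import annotations

from dataclasses import dataclass

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHV", "TGCAANYRSWMKVHDB")


def revcomp(seq: str) -> str:
    """Reverse complement; IUPAC-aware, preserves case-insensitivity by uppercasing."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class LocalAlignment:
    """One local alignment of a query against a target window.

    Coordinates are 0-based half-open in the respective sequences; ``matches``
    counts identical (IUPAC-compatible) columns and ``columns`` the total
    aligned columns including gap columns.
    """

    score: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.columns if self.columns else 0.0


def _is_match(qc: str, tc: str) -> bool:
    if tc == "N":
        return False
    return tc in IUPAC.get(qc, qc)


def smith_waterman(
    query: str,
    target: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> LocalAlignment | None:
    """Best local alignment of ``query`` vs ``target`` (linear gap penalty).

    Returns ``None`` when no positive-scoring alignment exists.
    """
    query = query.upper().replace("U", "T")
    target = target.upper()
    n, m = len(query), len(target)
    if n == 0 or m == 0:
        return None

    # H[i][j]: best score of local alignment ending at query[:i], target[:j].
    # Pointers: 0 stop, 1 diagonal, 2 up (gap in target), 3 left (gap in query).
    H = [[0] * (m + 1) for _ in range(n + 1)]
    P = [[0] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        qc = query[i - 1]
        row, prow = H[i], H[i - 1]
        ptr = P[i]
        for j in range(1, m + 1):
            s = match if _is_match(qc, target[j - 1]) else mismatch
            diag = prow[j - 1] + s
            up = prow[j] + gap
            left = row[j - 1] + gap
            v = diag
            p = 1
            if up > v:
                v, p = up, 2
            if left > v:
                v, p = left, 3
            if v <= 0:
                v, p = 0, 0
            row[j] = v
            ptr[j] = p
            if v > best:
                best, bi, bj = v, i, j
    if best <= 0:
        return None

    # Traceback.
    i, j = bi, bj
    matches = columns = 0
    while i > 0 and j > 0 and P[i][j] != 0:
        p = P[i][j]
        if p == 1:
            if _is_match(query[i - 1], target[j - 1]):
                matches += 1
            i -= 1
            j -= 1
        elif p == 2:
            i -= 1
        else:
            j -= 1
        columns += 1
    return LocalAlignment(
        score=best, q_start=i, q_end=bi, t_start=j, t_end=bj,
        matches=matches, columns=columns,
    )
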