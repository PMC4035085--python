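# Methods

This note documents the models, detection rules, numerical choices and known
limitations behind `pr77kit`. Everything stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is asserted beyond what those
runs check.

## Hallmark scanning

The scanner finds local alignments of a hallmark consensus (canonically
77 nt, IUPAC codes allowed) against both strands of a contig. Exact k-mers
(default k = 11) drawn from unambiguous query positions seed candidate
regions; seeds on nearby diagonals (±15, gap ≤ 40 nt) are clustered, and a
full Smith–Waterman alignment (match +1, mismatch −1, linear gap −2) is
computed on a short window around each cluster. Tandem signature copies sit
on diagonals offset by roughly the hallmark length, so they form separate
clusters and yield separate hits. `N` in the genome never counts as a match;
IUPAC ambiguity in the query matches any contained base. Hits must reach 60%
identity (matches over aligned columns) across ≥ 50 nt by default —
permissive thresholds chosen to admit strongly diverged signature families
while rejecting chance alignments on i.i.d. sequence (a 100 kb random genome
yields zero hits at these defaults; asserted in the test suite).

Iterative screening re-uses the genomic sequence of each new full-length hit
(≥ 60 nt) as a query in the next round, so a family member too diverged for
the consensus is still reached through an intermediate copy; the chain test
in the suite constructs exactly this A→B→C situation. Deduplication across
rounds treats two hits as the same locus when they overlap by ≥ 50% of the
shorter one, on either strand, with the strongest alignment claiming the
locus first. Strand is deliberately ignored here: the hallmark is partially
self-complementary (its helices pair internally), so every genuine hit casts
a weaker reverse-complement "shadow" alignment over the same interval, and
treating shadows as new signatures lets each round breed further shadow
queries. One genomic interval is one signature.

## The fold descriptor

A hallmark RNA is accepted as an HDV-like ribozyme candidate when it can
adopt the family's nested double-pseudoknot architecture. The concrete
topology, 5′→3′ along the strand:

```
[P1 5'] j1/2 [P2 hairpin] j2/3 [P3 5'] [P1.1 5'] gap [P1 3'] [P1.1 3']
    j4 [P4 hairpin] j4/3 [P3 3'] tail
```

P1, P2 and P4 are mutually nested; P3 and P1.1 are the crossing pseudoknot
helices (P3's 3′ strand returns near the molecule's 3′ end; P1.1 pairs two
bases 5′ of the P1 3′ strand with the two bases immediately 3′ of it). In
dot-bracket output the three layers are rendered `()`, `[]` and `{}`.

Default geometry (all configurable): P1 6–8 bp with its 5′ strand starting
at the +1 nucleotide and its 3′ strand starting in window [30, 45] — which
places the partner of +1 near position 39 for ~80-nt signatures, matching
the documented C1:A39 mismatch register; P1.1 exactly 2 bp, G:C only; P2
4–7 bp (a 3 bp P2 is the dedicated violation `P2_TOO_SHORT`); P3 3–6 bp; P4
3–12 bp with a 3–8 nt loop; junctions of 0–2 nt (j1/2, j4, j4/3, tail), 0–1 nt
(j2/3), loop2 3–5 nt, and 0–5 nt between the P1.1 5′ partners and the P1 3′
strand. Pairs are Watson–Crick or wobble G:U (P1.1 excepted); T and U are
equivalent. P1 must additionally contain a run of consecutive G:C pairs
(default 3, relaxable to 2 for signatures like the one with only two such
pairs). The identity of the catalytic nucleotide is *not* checked — only
architecture. The predicted cleavage site is the phosphodiester bond 5′ of
the +1 nucleotide (the hit start on '+', the last hit base on '−').

**Enumeration and the total order.** All helix placements consistent with
the windows are enumerated (≈ 1.5 × 10⁵ for a 77-nt candidate, falling fast
with length; infeasible lengths report `WINDOW_UNSATISFIABLE`). Each
placement is classified per helix: hairpins zip from the loop outward, P3
takes its longest contiguous legal run, and P1 trims illegal pairs at its
inner end first — same-diagonal registers share the same partner map, so
trimming makes equivalent registers classify identically (without it, an
extended register with one extra illegal pair would masquerade as
`P1_TOO_SHORT` where the true defect is a +1 mismatch). `best_folding`
returns the minimum under (fewest violations, most pairs, longest P1 G:C
run, leftmost P1 3′ strand) and is exactly the enumeration's optimum; the
acceptance suite verifies this equivalence on 200 generated and broken
sequences.

## Element context and classification

*Poly-A.* Downstream windows 300–1 000 nt (SHORT) and 4 500–6 500 nt (LONG)
from the 3′-most hallmark end, strand-aware (T-runs upstream in forward
coordinates on '−'). A tract is a maximal base run of ≥ 10 nt; single-base
interruptions are tolerated only between runs of ≥ 3 nt while the overall
purity stays ≥ 0.9 — a deliberately conservative merge so a long tail cannot
absorb downstream sequence that merely starts with a couple of As. Among
detected tracts, runs of ≥ 15 nt are treated as bona fide tails and the
nearest one wins; chance ~10-nt runs elsewhere are used only as a fallback.
This prevents both a chance run in a LINE body from masquerading as a short
element's tail and a neighbouring element's tail from being adopted.

*TSD.* For lengths 11 down to 7 and per-side offsets 0–5, the L-mer ending
at the element 5′ boundary is compared position-wise with the L-mer starting
at the element 3′ end (the poly-A end; the duplication flanks the whole
insertion, the standard target-primed reverse transcription outcome).
Accepted at ≥ 75% identity with ≥ 6 matching positions; ties go to the
longest L, then highest identity, then smallest total offset. A fallback
pass allows the copies to sit up to 2 nt *inside* the detected boundary,
because a mutated terminal hallmark base trims the alignment and shifts the
detected edge inward. **Limitation:** "partially conserved" at these
thresholds is loose enough that ~12–17% of random flank pairs contain a
chance match, so a genuinely TSD-less locus is sometimes reported with a
TSD; the TSD evidence therefore only modulates `confidence`
(`full`/`no_tsd`), never the class.

*Classification*, applied in order: two tandem signatures (gap ≤ 200 nt) →
SIDER2; element span ≥ 4 000 nt → LINE_DIRE; single signature with a SHORT
poly-A whose 200-nt end regions align at ≥ 80% identity to a supplied
reference long element → SIDE_NAR; single signature with SHORT poly-A →
SIDER1; otherwise UNCLASSIFIED. Hits used for locus building must cover most
of a hallmark (≥ 60 nt at ≥ 80% identity), grouping runs per (contig,
strand) so an interleaved opposite-strand hit cannot split a tandem pair,
and overlapping locus calls are resolved in favour of the better-supported
annotation (classified beats unclassified, then total alignment score).

## Kinetics

The cleaved fraction follows `fc(t) = A + B·e^(−k1 t) + C·e^(−k2 t)` with
A ∈ [0, 100] (plateau, %), B, C ∈ [−100, 0] (−B, −C are the fast and slow
amplitudes) and k1 ≥ k2 > 0 (min⁻¹, enforced by relabeling after the fit).
Fitting is bounded least squares (trust-region reflective) from a
deterministic 5 × 5 grid of log-spaced rate starts in [10⁻³, 10] min⁻¹ —
no randomness, so fits are exactly reproducible. `fc(0)` is not constrained
to zero (reactions can carry a pre-cleaved fraction at time 0); `A + B + C`
is reported so users can inspect the intercept. R² = 1 − SS_res/SS_tot, with
constant data defined as R² = 1 when residuals are negligible. The
competing hyperbolic model is fixed as `fc = Amax·t/(K + t)` (one-site
saturation, the standard reading of a "hyperbolic" fit), which forces
fc(0) = 0 and cannot bend twice — on genuinely biphasic data the two-phase
model wins the R² comparison (100/100 seeded datasets in the acceptance
run).

*Identifiability.* On a single 9-point series with 2-pp noise, low plateaus
(≲ 40%) admit a degenerate mode in which a near-zero k2 trades off against
an inflated plateau. Cleavage reactions are run in triplicate, so recovery
simulations fit the replicate mean (`average_replicates`); under that
standard condition the plateau estimator is unbiased with sd < 1 pp at the
anchored plateaus (75.41, 67.32, 82.37%), each recovered to within ±2 pp in
the acceptance run. The published kinetic table's three-Mg layout is what
the wide fit table mirrors; the trailing per-row extra value in that table
has no unambiguous column and is not reproduced. Cleavage rates measured at
10 mM Mg²⁺ can be inflated by uncleaved-RNA instability; that caveat applies
to the anchor measured at 10 mM but does not affect the recovery simulation,
which only asks whether a known plateau is re-estimated correctly.

*Band quantification.* Body-labelled transcripts emit signal proportional to
their U content, so molar amounts are intensity/U-count and the cleaved
fraction is the 3′ fragment's molar share of (3′ fragment + uncleaved). The
5′ fragment gives an independent cross-check and is reported separately; the
estimate is invariant to uniform intensity rescaling. A raw-intensity mode
is available by passing U counts of 1.

## Synthetic data

The generator defines the test conditions. Ribozymes are built by sampling a
geometry from the descriptor's own placement space and filling helices
complementarily (wobble with probability 0.15 where allowed, the P1 G:C run
and P1.1 G:C pairs guaranteed), junctions randomly — so every positive
carries a violation-free truth assignment by construction.
`break_constraint` produces negatives adaptively: each round damages the
requested helix of whichever placement currently wins, demoting rescuing
alternatives until the requested code appears in the best fold. For a small
fraction of sequences a rival placement permanently masks a code; that is
reported as an error and callers draw a fresh sequence.

Planted genomes use i.i.d. background (default GC 0.5) — adequate for the
false-positive targets of the detection rules, though real genomes'
repetitive and compositionally skewed sequence would add false hallmark
hits that this background cannot produce. Elements carry a shared 77-nt
consensus hallmark (the scan query) with per-copy point mutations at 5%
divergence by default — typical of recognisable, recently inserted copies
and within the ≤ 10% regime in which recovery is complete; short elements
have 400–700 nt bodies, LINEs 4.5–6 kb, SIDER2 signature gaps 0–50 nt,
poly-A tails 25 nt. TSDs (7–11 nt) are planted flush and sampled so their
edges cannot extend the planted homopolymer tails (first base never A, last
never T, ≤ 70% A+T) — otherwise the poly-A end detection would swallow the
duplication itself. Kinetic simulations add Gaussian noise (sd 2 pp) to the
two-phase curve, clipped to [0, 100].

What passing tests show — and what they do not: recovery at 100% sensitivity
and class accuracy holds for this generator's conditions (clean insertions,
i.i.d. background, moderate divergence); real screens face fragmented
elements, nested insertions and repeat-rich background, and should expect
the UNCLASSIFIED fall-through and the `no_tsd` confidence tier to carry much
more of the load.

## Problem sizes

The shipped checks use: one 200 kb contig with 12 planted elements for
recovery; 100 positive + 100 negative candidates (77–95 nt) for
fold-validator/enumeration equivalence; 100 seeded triplicate simulations
per plateau anchor and 100 datasets for model comparison. These sizes give
stable percentages while keeping a full run in the low minutes on one CPU.
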