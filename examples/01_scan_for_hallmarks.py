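"""Scan a genome for Pr77-hallmark signatures.

Builds a small synthetic contig with two planted hallmark copies (one of
them diverged, one on the minus strand), scans it with the consensus as the
query, and prints the hits.  Identity is the percentage of matching aligned
columns; coordinates are 0-based half-open on the forward strand, and the
predicted self-cleavage point of each hallmark RNA lies immediately 5' of
its first nucleotide.
"""

import numpy as np

import pr77kit as pk
from pr77kit._align import revcomp

rng = np.random.default_rng(42)
consensus = pk.sample_ribozyme(rng_seed=3, length=77).seq
query = pk.QueryProfile(id="hallmark_consensus", consensus=consensus)

background = "".join(rng.choice(list("ACGT"), size=20_000))
diverged = list(consensus)
for p in rng.choice(np.arange(2, 75), size=5, replace=False):
    diverged[p] = rng.choice([b for b in "ACGT" if b != diverged[p]])
genome_seq = (
    background[:5_000] + consensus
    + background[5_077:12_000] + revcomp("".join(diverged))
    + background[12_077:]
)
genome = pk.GenomeSequence(id="contig1", residues=genome_seq)

hits = pk.scan_genome(genome, query)
print(f"{len(hits)} hits on {genome.id} ({genome.length} nt):")
for h in hits:
    site = pk.predicted_cleavage_site(h)
    print(
        f"  {h.start:>6}-{h.end:<6} strand {h.strand}  "
        f"identity {h.identity:5.1f}%  score {h.score}  "
        f"cleavage 5' of position {site.position}"
    )
print(
    "\nEach hit is a candidate HDV-like ribozyme; the exact copy scores "
    "identity 100% and the 5-substitution copy ~93.5%."
)
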