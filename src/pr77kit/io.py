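"""Readers and writers for every format the pipeline touches.

FASTA via Biopython (wrapped at 60 columns); GFF3 1-based inclusive with
explicit strand; hit tables and kinetic time-courses as TSV; fold reports as
JSON; secondary structures as layered dot-bracket text.  Every writer/reader
pair round-trips exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import ElementAnnotation, PolyATrack, TSDPair
from .errors import InputError
from .scan import GenomeSequence, HallmarkHit, QueryProfile


# -- FASTA --------------------------------------------------------------------

def read_fasta(path) -> list[GenomeSequence]:
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append(GenomeSequence(id=rec.id, residues=str(rec.seq)))
    except (ValueError, FileNotFoundError) as exc:
        raise InputError(f"cannot read FASTA {path}: {exc}") from exc
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return records


def read_query_fasta(path) -> list[QueryProfile]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(QueryProfile(id=rec.id, consensus=str(rec.seq)))
    if not out:
        raise InputError(f"no query records in {path}")
    return out


def write_fasta(records, path) -> None:
    """Write (id, sequence) providers -- GenomeSequence, QueryProfile or
    plain (id, seq) tuples -- wrapped at 60 columns."""
    seqrecs = []
    for r in records:
        if isinstance(r, GenomeSequence):
            rid, seq = r.id, r.residues
        elif isinstance(r, QueryProfile):
            rid, seq = r.id, r.consensus
        else:
            rid, seq = r
        seqrecs.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(seqrecs, str(path), "fasta")


# -- hit tables ---------------------------------------------------------------

_HIT_COLS = ["contig", "start", "end", "strand", "identity", "score", "query_id", "n_aligned"]


def write_hits_tsv(hits: list[HallmarkHit], path) -> None:
    df = pd.DataFrame([h.__dict__ for h in hits], columns=_HIT_COLS)
    df.to_csv(path, sep="\t", index=False)


def read_hits_tsv(path) -> list[HallmarkHit]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_HIT_COLS) - set(df.columns)
    if missing:
        raise InputError(f"hits TSV {path} missing columns {sorted(missing)}")
    return [
        HallmarkHit(
            contig=str(r.contig), start=int(r.start), end=int(r.end),
            strand=str(r.strand), identity=float(r.identity), score=int(r.score),
            query_id=str(r.query_id), n_aligned=int(r.n_aligned),
        )
        for r in df.itertuples()
    ]


def write_bed6(hits: list[HallmarkHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            score = min(1000, max(0, int(round(10 * h.identity))))
            fh.write(
                f"{h.contig}\t{h.start}\t{h.end}\t{h.query_id}\t{score}\t{h.strand}\n"
            )


# -- GFF3 ---------------------------------------------------------------------

_SOURCE = "pr77kit"


def _attrs(**kv) -> str:
    return ";".join(f"{k}={v}" for k, v in kv.items() if v is not None)


def write_gff3(annotations: list[ElementAnnotation], path) -> None:
    """Element annotations as GFF3: a ``dispersed_repeat`` parent per locus
    with ``hallmark``, ``polyA_site`` and ``target_site_duplication``
    children.  Coordinates are converted to 1-based inclusive."""
    lines = ["##gff-version 3"]
    for n, a in enumerate(annotations, start=1):
        eid = f"elem{n}"
        lines.append(
            "\t".join([
                a.contig, _SOURCE, "dispersed_repeat",
                str(a.start + 1), str(a.end), ".", a.strand, ".",
                _attrs(ID=eid, element_class=a.element_class, confidence=a.confidence),
            ])
        )
        for i, h in enumerate(a.hallmarks, start=1):
            lines.append(
                "\t".join([
                    a.contig, _SOURCE, "hallmark",
                    str(h.start + 1), str(h.end), ".", h.strand, ".",
                    _attrs(
                        ID=f"{eid}.sig{i}", Parent=eid, signature=i,
                        identity=f"{h.identity:.2f}", query_id=h.query_id,
                        score=h.score, n_aligned=h.n_aligned,
                    ),
                ])
            )
        if a.polya is not None:
            p = a.polya
            lines.append(
                "\t".join([
                    a.contig, _SOURCE, "polyA_site",
                    str(p.start + 1), str(p.end), ".", a.strand, ".",
                    _attrs(
                        ID=f"{eid}.polyA", Parent=eid,
                        a_fraction=f"{p.a_fraction:.3f}",
                        window_class=p.window_class, distance=p.distance,
                    ),
                ])
            )
        if a.tsd is not None:
            t = a.tsd
            for copy, cstart in (("left", t.left_start), ("right", t.right_start)):
                lines.append(
                    "\t".join([
                        a.contig, _SOURCE, "target_site_duplication",
                        str(cstart + 1), str(cstart + t.length), ".", a.strand, ".",
                        _attrs(
                            ID=f"{eid}.tsd_{copy}", Parent=eid, copy=copy,
                            identity=f"{t.identity:.2f}", tsd_length=t.length,
                        ),
                    ])
                )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_attrs(s: str) -> dict:
    out = {}
    for item in s.split(";"):
        if item:
            k, _, v = item.partition("=")
            out[k] = v
    return out


def read_gff3(path) -> list[ElementAnnotation]:
    """Parse a pr77kit GFF3 back into ElementAnnotation objects (coordinates
    to 0-based half-open; sub-features re-attached by Parent)."""
    parents: dict[str, ElementAnnotation] = {}
    order: list[str] = []
    children: list[tuple] = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw or raw.startswith("#"):
            continue
        cols = raw.split("\t")
        if len(cols) != 9:
            raise InputError(f"{path}:{ln}: expected 9 GFF3 columns, got {len(cols)}")
        contig, _src, ftype, start1, end1, _score, strand, _phase, attr_s = cols
        start, end = int(start1) - 1, int(end1)
        if start < 0 or end <= start:
            raise InputError(f"{path}:{ln}: bad coordinates {start1}..{end1}")
        attrs = _parse_attrs(attr_s)
        if ftype == "dispersed_repeat":
            a = ElementAnnotation(
                contig=contig, start=start, end=end, strand=strand,
                element_class=attrs.get("element_class", "UNCLASSIFIED"),
                hallmarks=[], polya=None, tsd=None, folds=[],
                confidence=attrs.get("confidence", "full"),
            )
            parents[attrs["ID"]] = a
            order.append(attrs["ID"])
        else:
            children.append((ftype, contig, start, end, strand, attrs))

    tsd_copies: dict[str, dict] = {}
    for ftype, contig, start, end, strand, attrs in children:
        parent = parents.get(attrs.get("Parent", ""))
        if parent is None:
            raise InputError(f"GFF3 child {attrs} references unknown parent")
        if ftype == "hallmark":
            parent.hallmarks.append(
                HallmarkHit(
                    contig=contig, start=start, end=end, strand=strand,
                    identity=float(attrs.get("identity", 0.0)),
                    score=int(attrs.get("score", 0)),
                    query_id=attrs.get("query_id", ""),
                    n_aligned=int(attrs.get("n_aligned", end - start)),
                )
            )
        elif ftype == "polyA_site":
            parent.polya = PolyATrack(
                start=start, end=end,
                a_fraction=float(attrs.get("a_fraction", 1.0)),
                window_class=attrs.get("window_class", "SHORT"),
                distance=int(attrs.get("distance", 0)),
            )
        elif ftype == "target_site_duplication":
            d = tsd_copies.setdefault(attrs["Parent"], {})
            d[attrs.get("copy", "left")] = (start, end, attrs)
    for pid, copies in tsd_copies.items():
        if "left" in copies and "right" in copies:
            (ls, le, lat), (rs, _re, _rat) = copies["left"], copies["right"]
            parents[pid].tsd = TSDPair(
                length=le - ls, left_start=ls, right_start=rs,
                left_seq="", right_seq="",
                identity=float(lat.get("identity", 100.0)),
                left_offset=0, right_offset=0,
            )
    return [parents[pid] for pid in order]


def write_truth_gff3(truth, path) -> None:
    """Ground-truth records from the synthetic generator as GFF3."""
    lines = ["##gff-version 3"]
    for n, r in enumerate(truth.records, start=1):
        eid = f"truth{n}"
        lines.append(
            "\t".join([
                r.contig, _SOURCE, "dispersed_repeat",
                str(r.start + 1), str(r.end), ".", r.strand, ".",
                _attrs(
                    ID=eid, element_class=r.element_class,
                    has_tsd=str(r.has_tsd).lower(), tsd_seq=r.tsd_seq,
                ),
            ])
        )
        for i, (s, e) in enumerate(r.hallmark_spans, start=1):
            lines.append(
                "\t".join([
                    r.contig, _SOURCE, "hallmark",
                    str(s + 1), str(e), ".", r.strand, ".",
                    _attrs(ID=f"{eid}.sig{i}", Parent=eid, signature=i),
                ])
            )
        lines.append(
            "\t".join([
                r.contig, _SOURCE, "polyA_site",
                str(r.polya_span[0] + 1), str(r.polya_span[1]), ".", r.strand, ".",
                _attrs(ID=f"{eid}.polyA", Parent=eid),
            ])
        )
    Path(path).write_text("\n".join(lines) + "\n")


# -- kinetics tables ----------------------------------------------------------

_TC_COLS = ["replicate_id", "mg_mM", "time_min", "fc_pct"]


def read_timecourse_tsv(path) -> list:
    """TSV with columns replicate_id, mg_mM, time_min, fc_pct -> TimeCourses
    grouped by (replicate_id, mg_mM), times sorted ascending."""
    from .kinetics import TimeCourse

    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise InputError(f"cannot read time-course TSV {path}: {exc}") from exc
    missing = set(_TC_COLS) - set(df.columns)
    if missing:
        raise InputError(f"time-course TSV {path} missing columns {sorted(missing)}")
    out = []
    for (rid, mg), grp in df.groupby(["replicate_id", "mg_mM"], sort=True):
        grp = grp.sort_values("time_min")
        out.append(
            TimeCourse(
                times=tuple(grp["time_min"].astype(float)),
                fc_obs=tuple(grp["fc_pct"].astype(float)),
                mg_mM=float(mg), replicate_id=str(rid),
            )
        )
    return out


def write_timecourse_tsv(timecourses, path) -> None:
    rows = []
    for tc in timecourses:
        for t, f in zip(tc.times, tc.fc_obs):
            rows.append(
                {"replicate_id": tc.replicate_id, "mg_mM": tc.mg_mM,
                 "time_min": t, "fc_pct": f}
            )
    pd.DataFrame(rows, columns=_TC_COLS).to_csv(path, sep="\t", index=False)


def fit_results_frame(results: list[dict]) -> pd.DataFrame:
    """Long-format fit table: one row per (replicate, Mg) series."""
    cols = [
        "replicate_id", "mg_mM", "r2_two_phase", "plateau_pct",
        "B", "C", "k1", "k2", "fc0", "r2_hyperbolic", "winner",
    ]
    return pd.DataFrame(results, columns=cols)


def table1_layout(df: pd.DataFrame) -> pd.DataFrame:
    """Wide per-replicate layout mirroring the published kinetics table:
    two-phase R^2 and plateau at each Mg concentration, then hyperbolic R^2.

    Columns are grouped per quantity with one column per Mg concentration
    (descending).  The published table's trailing per-row extra value has no
    unambiguous column; this layout sticks to the three-concentration grid.
    """
    mgs = sorted(df["mg_mM"].unique(), reverse=True)
    out = {}
    for mg in mgs:
        sub = df[df["mg_mM"] == mg].set_index("replicate_id")
        out[f"r2_two_phase_{mg}mM"] = sub["r2_two_phase"]
        out[f"plateau_{mg}mM"] = sub["plateau_pct"]
        out[f"r2_hyperbolic_{mg}mM"] = sub["r2_hyperbolic"]
    wide = pd.DataFrame(out)
    ordered = (
        [f"r2_two_phase_{mg}mM" for mg in mgs]
        + [f"plateau_{mg}mM" for mg in mgs]
        + [f"r2_hyperbolic_{mg}mM" for mg in mgs]
    )
    return wide[ordered]


def write_fit_tsv(results: list[dict], path, wide_path=None) -> None:
    df = fit_results_frame(results)
    df.to_csv(path, sep="\t", index=False)
    if wide_path is not None:
        table1_layout(df).to_csv(wide_path, sep="\t")


# -- fold reports -------------------------------------------------------------

def write_fold_json(results: dict, path) -> None:
    """Per-candidate fold validation report: pass flag, violations, helix
    table, dot-bracket."""
    Path(path).write_text(json.dumps(results, indent=2, sort_keys=True) + "\n")


def write_dotbracket(entries, path) -> None:
    """Entries of (id, sequence, dotbracket) as aligned three-line blocks;
    bracket layers: () nested helices, [] the P3 pseudoknot, {} P1.1."""
    with open(path, "w") as fh:
        for rid, seq, db in entries:
            fh.write(f">{rid}\n{seq}\n{db}\n")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
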