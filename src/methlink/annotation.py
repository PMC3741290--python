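"""Strand-aware mapping of array probes to transcripts, promoters, and CpG islands.

Coordinates are 0-based half-open internally.  A promoter window spans 1,000
bases upstream to 500 bases downstream of the TSS, mirrored on the minus
strand and clipped at the chromosome start.  A probe is assigned to a
transcript when it overlaps the transcript body or its promoter window by at
least one base; probes may map to multiple transcripts.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 500

TRANSCRIPT_COLUMNS = ["transcript_id", "chrom", "start", "end", "strand", "tss"]


class AnnotationError(ValueError):
    pass


@dataclass
class AnnotationSet:
    """Transcripts (with TSS/strand) and CpG islands, 0-based half-open."""

    transcripts: pd.DataFrame  # columns TRANSCRIPT_COLUMNS
    cpg_islands: pd.DataFrame  # columns chrom, start, end

    def __post_init__(self) -> None:
        t = self.transcripts
        if len(t):
            if t["transcript_id"].duplicated().any():
                dup = t.loc[t["transcript_id"].duplicated(), "transcript_id"].iloc[0]
                raise AnnotationError(f"duplicate transcript id: {dup}")
            if (t["end"] <= t["start"]).any():
                bad = t.loc[t["end"] <= t["start"], "transcript_id"].iloc[0]
                raise AnnotationError(f"transcript {bad}: end <= start")
            bad_strand = ~t["strand"].isin(["+", "-"])
            if bad_strand.any():
                raise AnnotationError(
                    f"unknown strand symbol {t.loc[bad_strand, 'strand'].iloc[0]!r}"
                )
        c = self.cpg_islands
        if len(c) and (c["end"] <= c["start"]).any():
            raise AnnotationError("CpG island with end <= start")


def tss_of(start: int, end: int, strand: str) -> int:
    """TSS in 0-based coordinates: leftmost base on +, rightmost on -."""
    return int(start) if strand == "+" else int(end) - 1


def promoter_of(transcript: pd.Series | dict) -> tuple[int, int]:
    """Promoter window [-1000, +500) relative to the TSS, strand-aware, clipped at 0.

    On the plus strand with 0-based TSS t the window is [t-1000, t+500); on the
    minus strand the mirror image [t-499, t+1001).
    """
    t = int(transcript["tss"])
    if transcript["strand"] == "+":
        lo, hi = t - PROMOTER_UPSTREAM, t + PROMOTER_DOWNSTREAM
    else:
        lo, hi = t - PROMOTER_DOWNSTREAM + 1, t + PROMOTER_UPSTREAM + 1
    return max(lo, 0), hi


_GTF_TID = re.compile(r'transcript_id "([^"]+)"')


def read_annotation(transcripts_path: str, cpg_path: str) -> AnnotationSet:
    """Read transcripts (GTF, 1-based inclusive, or TSV) and CpG islands (BED).

    GTF ``transcript`` features are converted to the internal 0-based
    half-open convention; a TSV is expected to already carry internal
    coordinates with a header naming ``transcript_id chrom start end strand``.
    Malformed lines raise with their line number.
    """
    path = str(transcripts_path)
    if path.endswith((".gtf", ".gff")):
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9:
                    raise AnnotationError(f"{path}:{lineno}: expected 9 GTF columns")
                chrom, _, feature, start, end, _, strand, _, attrs = parts[:9]
                if feature != "transcript":
                    continue
                m = _GTF_TID.search(attrs)
                if m is None:
                    raise AnnotationError(f"{path}:{lineno}: missing transcript_id attribute")
                try:
                    s1, e1 = int(start), int(end)
                except ValueError as exc:
                    raise AnnotationError(f"{path}:{lineno}: non-integer coordinate") from exc
                s0, e0 = s1 - 1, e1  # 1-based inclusive -> 0-based half-open
                if e0 <= s0:
                    raise AnnotationError(f"{path}:{lineno}: end <= start")
                if strand not in ("+", "-"):
                    raise AnnotationError(f"{path}:{lineno}: unknown strand {strand!r}")
                rows.append((m.group(1), chrom, s0, e0, strand, tss_of(s0, e0, strand)))
        transcripts = pd.DataFrame(rows, columns=TRANSCRIPT_COLUMNS)
    else:
        transcripts = pd.read_csv(path, sep="\t")
        if "tss" not in transcripts.columns:
            transcripts["tss"] = [
                tss_of(s, e, st)
                for s, e, st in zip(transcripts["start"], transcripts["end"], transcripts["strand"])
            ]
        transcripts = transcripts[TRANSCRIPT_COLUMNS]
    islands = pd.read_csv(
        cpg_path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"],
        comment="#",
    )
    return AnnotationSet(transcripts=transcripts.reset_index(drop=True),
                         cpg_islands=islands.reset_index(drop=True))


@dataclass
class ProbeAnnotation:
    """Long-format probe-to-feature assignments.

    ``table`` has one row per (probe, transcript) hit with flags:
    in_promoter (probe overlaps that transcript's promoter window),
    in_cpg_island (probe overlaps any island), cpg_in_promoter (the probe
    overlaps an island that itself overlaps the promoter window).
    ``unmapped`` lists probes hitting no transcript.
    """

    table: pd.DataFrame
    unmapped: list[str]


def map_probes(probes: pd.DataFrame, annotation: AnnotationSet) -> ProbeAnnotation:
    """Assign probes (columns probe_id, chrom, start, end) to overlapping features.

    Overlap rule: >= 1 shared base with the transcript body or its promoter
    window.  Probes on chromosomes absent from the annotation are reported
    unmapped with a warning.
    """
    tx = annotation.transcripts
    tx_trees: dict[str, IntervalTree] = {}
    promoters: dict[str, tuple[int, int]] = {}
    for row in tx.itertuples(index=False):
        p_lo, p_hi = promoter_of({"tss": row.tss, "strand": row.strand})
        promoters[row.transcript_id] = (p_lo, p_hi)
        lo = min(int(row.start), p_lo)
        hi = max(int(row.end), p_hi)
        tx_trees.setdefault(row.chrom, IntervalTree()).addi(lo, hi, row)
    isl_trees: dict[str, IntervalTree] = {}
    for row in annotation.cpg_islands.itertuples(index=False):
        isl_trees.setdefault(row.chrom, IntervalTree()).addi(int(row.start), int(row.end), None)

    known_chroms = set(tx_trees) | set(isl_trees)
    missing_chroms = set()
    rows = []
    unmapped = []
    for pr in probes.itertuples(index=False):
        chrom, lo, hi = pr.chrom, int(pr.start), int(pr.end)
        if chrom not in known_chroms:
            missing_chroms.add(chrom)
            unmapped.append(pr.probe_id)
            continue
        isl_hits = isl_trees[chrom].overlap(lo, hi) if chrom in isl_trees else set()
        in_island = bool(isl_hits)
        hit_any = False
        for iv in tx_trees.get(chrom, IntervalTree()).overlap(lo, hi):
            t = iv.data
            p_lo, p_hi = promoters[t.transcript_id]
            in_body = lo < t.end and hi > t.start
            in_prom = lo < p_hi and hi > p_lo
            if not (in_body or in_prom):
                continue  # tree stores the hull; confirm a real overlap
            cpg_in_prom = any(i.begin < p_hi and i.end > p_lo for i in isl_hits)
            rows.append(
                (pr.probe_id, t.transcript_id, in_prom, in_island, cpg_in_prom)
            )
            hit_any = True
        if not hit_any:
            unmapped.append(pr.probe_id)
    if missing_chroms:
        warnings.warn(
            f"probes on chromosomes absent from annotation left unmapped: "
            f"{sorted(missing_chroms)}",
            RuntimeWarning,
        )
    table = pd.DataFrame(
        rows,
        columns=["probe_id", "transcript_id", "in_promoter", "in_cpg_island", "cpg_in_promoter"],
    )
    return ProbeAnnotation(table=table, unmapped=unmapped)
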