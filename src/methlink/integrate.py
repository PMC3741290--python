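"""Joining methylation and expression evidence per transcript.

A transcript on both platforms carries its differential-expression record and
the DMR probes mapping to it (with promoter/CpG-island context flags).  The
concordance paradigm is that lower methylation goes with higher expression:
a hypomethylated-in-asthma DMR accords with up-regulation, a hypermethylated
one with down-regulation.  Among accordant DMRs of a transcript one is
selected as "influential" by the context priority
promoter-and-CpG-island > promoter > CpG island > neither, with ties broken
by the larger between-group methylation difference and then the smaller
genomic start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .methylation import DmrSet, HYPER_IN_ASTHMA, HYPO_IN_ASTHMA

__all__ = [
    "IntegratedTranscript",
    "SummaryReport",
    "join_platforms",
    "classify_concordance",
    "select_influential_dmr",
    "classify_context",
    "detect_dual_direction",
    "summarize",
    "format_percent",
    "CONTEXT_CLASSES",
]

CONTEXT_CLASSES = ("promoter_and_cpg", "promoter_only", "cpg_only", "body_only")

# context priority for influential-DMR selection, highest first
_PRIORITY = {"promoter_and_cpg": 3, "promoter_only": 2, "cpg_only": 1, "body_only": 0}

# the direction that accords with each expression direction under the
# "lower methylation, higher expression" paradigm
ACCORDANT_DIRECTION = {"up": HYPO_IN_ASTHMA, "down": HYPER_IN_ASTHMA}


def _context_of(in_promoter: bool, in_cpg: bool) -> str:
    if in_promoter and in_cpg:
        return "promoter_and_cpg"
    if in_promoter:
        return "promoter_only"
    if in_cpg:
        return "cpg_only"
    return "body_only"


@dataclass
class IntegratedTranscript:
    transcript_id: str
    on_both_platforms: bool
    de: pd.Series | None  # a row of the DE table, or None
    dmrs: pd.DataFrame  # probe_id, direction, in_promoter, in_cpg_island,
    #                     cpg_in_promoter, delta_lfc, start
    dual_direction: bool = False
    concordance: str = "n/a"  # concordant | discordant | n/a
    influential: str | None = None
    context_class: str | None = None

    @property
    def de_passes(self) -> bool:
        return self.de is not None and bool(self.de["passes"])


def join_platforms(
    dmrs: tuple[DmrSet, DmrSet],
    probe_annotation: pd.DataFrame,
    probe_coords: pd.DataFrame,
    de: pd.DataFrame,
) -> list[IntegratedTranscript]:
    """One record per transcript represented on both platforms.

    ``probe_annotation`` is the full probe-to-transcript table (its transcript
    universe defines the methylation platform); ``de`` is indexed by
    transcript_id (its index defines the expression platform);
    ``probe_coords`` supplies probe genomic starts for tie-breaking.
    """
    meth_platform = set(probe_annotation["transcript_id"].unique())
    expr_platform = set(de.index)
    shared = meth_platform & expr_platform

    dmr_rows = []
    for dmr in dmrs:
        if not dmr.table.empty:
            t = dmr.table.copy()
            t["direction"] = dmr.direction
            dmr_rows.append(t)
    dmr_table = (
        pd.concat(dmr_rows, ignore_index=True)
        if dmr_rows
        else pd.DataFrame(columns=["probe_id", "lfc_normal", "lfc_asthma", "delta_lfc", "direction"])
    )
    starts = probe_coords.set_index("probe_id")["start"]
    annotated = dmr_table.merge(probe_annotation, on="probe_id", how="inner")
    annotated["start"] = annotated["probe_id"].map(starts)

    records = []
    for tid in sorted(shared):
        sub = annotated[annotated["transcript_id"] == tid].reset_index(drop=True)
        rec = IntegratedTranscript(
            transcript_id=tid,
            on_both_platforms=True,
            de=de.loc[tid],
            dmrs=sub,
            dual_direction=sub["direction"].nunique() == 2,
        )
        if rec.de_passes and len(sub):
            rec.influential = select_influential_dmr(rec)
            rec.concordance = classify_concordance(rec)
            if rec.influential is not None:
                rec.context_class = classify_context(rec)
        records.append(rec)
    return records


def select_influential_dmr(record: IntegratedTranscript) -> str | None:
    """Pick the accordant DMR with the highest context priority.

    Candidates are DMRs whose direction accords with the transcript's
    expression direction; the winner has the highest priority class, then the
    largest |lfc_normal - lfc_asthma|, then the smallest genomic start.
    Returns None when no DMR accords.
    """
    if not record.de_passes or record.dmrs.empty:
        return None
    accordant_dir = ACCORDANT_DIRECTION[record.de["direction"]]
    cand = record.dmrs[record.dmrs["direction"] == accordant_dir]
    if cand.empty:
        return None
    priority = cand.apply(
        lambda r: _PRIORITY[_context_of(r["in_promoter"], r["in_cpg_island"])], axis=1
    )
    order = cand.assign(_prio=priority).sort_values(
        by=["_prio", "delta_lfc", "start", "probe_id"],
        ascending=[False, False, True, True],
    )
    return str(order.iloc[0]["probe_id"])


def classify_concordance(record: IntegratedTranscript) -> str:
    """Concordant when a DMR accords with the expression direction.

    Single-direction transcripts are concordant iff their DMR direction
    accords; dual-direction transcripts follow the influential DMR when one
    exists and are discordant otherwise.
    """
    if not record.de_passes or record.dmrs.empty:
        return "n/a"
    accordant_dir = ACCORDANT_DIRECTION[record.de["direction"]]
    directions = set(record.dmrs["direction"])
    if len(directions) == 1:
        return "concordant" if accordant_dir in directions else "discordant"
    return "concordant" if record.influential is not None else "discordant"


def classify_context(record: IntegratedTranscript) -> str:
    """Context class of the influential DMR probe."""
    if record.influential is None:
        raise ValueError(f"{record.transcript_id}: no influential DMR selected")
    row = record.dmrs[record.dmrs["probe_id"] == record.influential].iloc[0]
    return _context_of(bool(row["in_promoter"]), bool(row["in_cpg_island"]))


def detect_dual_direction(records: list[IntegratedTranscript]) -> pd.DataFrame:
    """Transcripts carrying both hyper- and hypomethylated DMRs, with probe lists."""
    rows = []
    for rec in records:
        if rec.dual_direction:
            for r in rec.dmrs.itertuples(index=False):
                rows.append((rec.transcript_id, r.probe_id, r.direction,
                             r.lfc_normal, r.lfc_asthma))
    return pd.DataFrame(
        rows, columns=["transcript_id", "probe_id", "direction", "lfc_normal", "lfc_asthma"]
    )


def format_percent(numerator: float, denominator: float) -> str:
    """Render a proportion the way the report prints it.

    One decimal below 10% (6.8%), nearest whole percent at or above 10% (26%).
    Undefined ratios render as "n/a".
    """
    if denominator == 0:
        return "n/a"
    v = 100.0 * numerator / denominator
    if v < 10.0:
        return f"{v:.1f}%"
    return f"{v:.0f}%"


@dataclass
class SummaryReport:
    """Cohort-level counts and proportions of the integrated analysis."""

    n_meth_platform: int
    n_expr_platform: int
    n_both_platforms: int
    n_de: int
    n_dm_transcripts: int
    n_de_and_dm: int
    n_dmr_transcripts_by_direction: dict[str, int]
    n_dual_direction: int
    n_concordant: int
    n_discordant: int
    n_influential: int
    context_counts: dict[str, int]
    context_proportions_influential: dict[str, float | None]
    context_proportions_de_dm: dict[str, float | None]
    probe_bookkeeping: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}

    def to_text(self) -> str:
        lines = [
            f"transcripts on methylation platform: {self.n_meth_platform}",
            f"transcripts on expression platform:  {self.n_expr_platform}",
            f"transcripts on both platforms:       {self.n_both_platforms}",
            f"differentially expressed (DE):       {self.n_de}",
            f"DMR-bearing transcripts (DM):        {self.n_dm_transcripts}",
            f"DE and DM:                           {self.n_de_and_dm} "
            f"({format_percent(self.n_de_and_dm, self.n_de) if self.n_de else 'n/a'} of DE)",
            f"dual-direction transcripts:          {self.n_dual_direction}",
            f"concordant / discordant:             {self.n_concordant} / {self.n_discordant}",
            f"transcripts with an influential DMR: {self.n_influential}",
        ]
        for cls in CONTEXT_CLASSES:
            p = self.context_proportions_influential.get(cls)
            lines.append(
                f"  context {cls}: {self.context_counts.get(cls, 0)}"
                + (f" ({p * 100:.0f}% of influential)" if p is not None else "")
            )
        for k, v in self.probe_bookkeeping.items():
            lines.append(f"probe bookkeeping {k}: {v}")
        return "\n".join(lines)


def summarize(
    records: list[IntegratedTranscript],
    n_meth_platform: int | None = None,
    n_expr_platform: int | None = None,
    probe_counts: dict[str, int] | None = None,
    total_probes: int | None = None,
) -> SummaryReport:
    """All counts and proportions of the integrated cohort.

    ``probe_counts`` / ``total_probes`` add the probe-level bookkeeping
    percentages (each count rendered over the total experimental probes).
    Context proportions are emitted against two denominators: transcripts with
    an influential DMR, and all DE-and-DM transcripts.
    """
    n_both = sum(r.on_both_platforms for r in records)
    de_recs = [r for r in records if r.de_passes]
    dm_recs = [r for r in records if len(r.dmrs)]
    de_dm = [r for r in de_recs if len(r.dmrs)]
    by_dir = {HYPER_IN_ASTHMA: 0, HYPO_IN_ASTHMA: 0}
    for r in records:
        for d in set(r.dmrs["direction"]) if len(r.dmrs) else ():
            by_dir[d] += 1
    influential = [r for r in records if r.influential is not None]
    context_counts = {c: 0 for c in CONTEXT_CLASSES}
    for r in influential:
        context_counts[r.context_class] += 1
    n_inf = len(influential)
    props_inf = {
        c: (context_counts[c] / n_inf if n_inf else None) for c in CONTEXT_CLASSES
    }
    props_dedm = {
        c: (context_counts[c] / len(de_dm) if de_dm else None) for c in CONTEXT_CLASSES
    }
    bookkeeping = {}
    if probe_counts and total_probes:
        for k, v in probe_counts.items():
            bookkeeping[k] = format_percent(v, total_probes)
    return SummaryReport(
        n_meth_platform=n_meth_platform if n_meth_platform is not None else n_both,
        n_expr_platform=n_expr_platform if n_expr_platform is not None else n_both,
        n_both_platforms=n_both,
        n_de=len(de_recs),
        n_dm_transcripts=len(dm_recs),
        n_de_and_dm=len(de_dm),
        n_dmr_transcripts_by_direction=by_dir,
        n_dual_direction=sum(r.dual_direction for r in records),
        n_concordant=sum(r.concordance == "concordant" for r in records),
        n_discordant=sum(r.concordance == "discordant" for r in records),
        n_influential=n_inf,
        context_counts=context_counts,
        context_proportions_influential=props_inf,
        context_proportions_de_dm=props_dedm,
        probe_bookkeeping=bookkeeping,
    )
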