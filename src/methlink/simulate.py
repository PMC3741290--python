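"""Synthetic study generator with planted truth.

Emulates the study design end-to-end: a small genome annotation (transcripts
with TSS/strand plus CpG islands), 9-vs-9 two-color methylation-sensitive
restriction arrays with lognormal intensities and a cut-signal model (an
unmethylated probe loses treated-channel signal so its expected M-value equals
the cut effect; methylated and control probes have expected M = 0), and
coupled probe-level expression matrices for two designs (4v4 and 5v5) with
planted differential expression at a tunable methylation-concordance rate.

Every generator draws from an independent substream derived from one master
seed, so identical configurations reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, tss_of, promoter_of
from .methylation import TwoColorArray, HYPER_IN_ASTHMA, HYPO_IN_ASTHMA

__all__ = [
    "SyntheticConfig",
    "TruthTable",
    "ExpressionSets",
    "ConfigError",
    "generate_annotation",
    "generate_methylation_arrays",
    "generate_expression",
]

# fixed substream offsets per generator (annotation, methylation, expression)
_STREAM_ANNOTATION = 0
_STREAM_METHYLATION = 1
_STREAM_EXPRESSION = 2


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the real study's shape: ~10% control probes, 9 arrays per
    group, a 1.0 log2 cut effect with 0.35 SD observation noise, ~28% of
    experimental probes unmethylated in both groups plus 1,000 group-specific
    unmethylated probes per direction, and 4v4 / 5v5 expression designs.
    """

    n_chromosomes: int = 2
    chrom_length: int = 25_000_000
    n_transcripts: int = 2_000
    n_cpg_islands: int = 1_200
    n_probes: int = 20_000
    control_fraction: float = 0.10
    n_arrays_per_group: int = 9
    planted_unmeth_normal_only: int = 1_000
    planted_unmeth_asthma_only: int = 1_000
    planted_unmeth_both: int = 5_000
    cut_effect_log2: float = 1.0
    noise_sd_log2: float = 0.35
    n_expr_replicates_per_group: tuple[int, int] = (4, 5)  # (set1, set2)
    planted_de_count: int = 300
    de_log2fc_mean: float = 1.0
    concordance_rate: float = 0.8
    planted_dual_count: int = 12  # transcripts given one probe of each direction
    master_seed: int = 1
    # geometry / coupling knobs
    probe_width: int = 50
    promoter_probe_fraction: float = 0.5  # planted DMR probes forced into promoters
    island_promoter_fraction: float = 0.5  # islands forced to overlap a promoter
    expr_noise_sd_log2: float = 0.25
    n_probes_per_probeset: int = 8
    qc_fail_arrays: tuple[str, ...] = ()
    qc_fail_noise_scale: float = 0.25

    def __post_init__(self) -> None:
        for name in (
            "n_chromosomes", "chrom_length", "n_transcripts", "n_cpg_islands",
            "n_probes", "n_arrays_per_group", "planted_unmeth_normal_only",
            "planted_unmeth_asthma_only", "planted_unmeth_both", "planted_de_count",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("control_fraction", "concordance_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        planted = (
            self.planted_unmeth_normal_only
            + self.planted_unmeth_asthma_only
            + self.planted_unmeth_both
        )
        if planted > self.n_probes * (1.0 - self.control_fraction):
            raise ConfigError(
                f"planted probe counts ({planted}) exceed available non-control "
                f"probes ({self.n_probes * (1 - self.control_fraction):.0f})"
            )
        if self.planted_dual_count < 0:
            raise ConfigError("planted_dual_count must be >= 0")

    def with_(self, **kw) -> "SyntheticConfig":
        return replace(self, **kw)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.master_seed, stream])


@dataclass
class TruthTable:
    """Planted ground truth for probes and transcripts.

    ``probes``: probe_id, chrom, start, end, is_control, state_normal,
    state_asthma ("methylated"/"unmethylated"), dmr_direction (one of the
    direction constants or "none"), transcript_id (the transcript a planted
    group-specific probe was placed in, else NA).
    ``transcripts``: transcript_id, dmr_direction, de_state (up/down/null),
    concordant (boolean, NA when not applicable).
    """

    probes: pd.DataFrame
    transcripts: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def probe_intervals(self) -> pd.DataFrame:
        return self.probes[["probe_id", "chrom", "start", "end"]]


@dataclass
class ExpressionSets:
    """Probe-level expression matrices for the two designs plus metadata."""

    set1: pd.DataFrame  # probes x samples, linear-scale intensities
    set2: pd.DataFrame
    samples: pd.DataFrame  # sample_id, dataset, condition, group
    probeset_map: pd.Series  # probe_id -> transcript_id


def generate_annotation(config: SyntheticConfig) -> AnnotationSet:
    """Random transcripts (>= 1,501 bp, promoter window always fits) and CpG islands.

    Transcript body-plus-promoter hulls are placed without mutual overlap by
    rejection sampling, so a probe inside one transcript's territory cannot
    also map to a neighbour — planted per-transcript truth stays exact.
    """
    rng = config.rng(_STREAM_ANNOTATION)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    max_len = 8_000
    margin = 1_501
    if config.n_transcripts > 0:
        if config.n_chromosomes == 0:
            raise ConfigError("transcripts requested but n_chromosomes is 0")
        if config.chrom_length < max_len + 2 * margin:
            raise ConfigError(
                f"chrom_length {config.chrom_length} too short for transcripts "
                f"(need >= {max_len + 2 * margin})"
            )
    from bisect import bisect_left, insort

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    rows = []
    for i in range(config.n_transcripts):
        placed = False
        for _ in range(2_000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            length = int(rng.integers(2_000, max_len + 1))
            start = int(rng.integers(margin, config.chrom_length - length - margin))
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            tss = tss_of(start, end, strand)
            p_lo, p_hi = promoter_of({"tss": tss, "strand": strand})
            hull = (min(start, p_lo), max(end, p_hi))
            occ = occupied[chrom]
            j = bisect_left(occ, hull)
            if (j > 0 and occ[j - 1][1] > hull[0]) or (j < len(occ) and occ[j][0] < hull[1]):
                continue
            insort(occ, hull)
            rows.append((f"TX{i:05d}", chrom, start, end, strand, tss))
            placed = True
            break
        if not placed:
            raise ConfigError(
                f"could not place transcript {i}: chromosomes too short for "
                f"{config.n_transcripts} non-overlapping transcripts"
            )
    transcripts = pd.DataFrame(
        rows, columns=["transcript_id", "chrom", "start", "end", "strand", "tss"]
    )
    isl = []
    for _ in range(config.n_cpg_islands):
        length = int(rng.integers(200, 1_501))
        if len(transcripts) and rng.random() < config.island_promoter_fraction:
            t = transcripts.iloc[int(rng.integers(len(transcripts)))]
            p_lo, p_hi = promoter_of(t)
            start = int(rng.integers(p_lo, max(p_hi - length, p_lo) + 1))
            chrom = t["chrom"]
        else:
            chrom = chroms[int(rng.integers(len(chroms)))] if chroms else "chr1"
            start = int(rng.integers(0, config.chrom_length - length))
        isl.append((chrom, start, min(start + length, config.chrom_length)))
    islands = pd.DataFrame(isl, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"], ignore_index=True
    )
    return AnnotationSet(transcripts=transcripts, cpg_islands=islands)


def _place_probe_in_transcript(
    rng: np.random.Generator, t: pd.Series, width: int, promoter_fraction: float,
    chrom_length: int,
) -> tuple[int, int]:
    """Position a probe inside a transcript's promoter (with given probability) or body."""
    if rng.random() < promoter_fraction:
        lo, hi = promoter_of(t)
    else:
        lo, hi = int(t["start"]), int(t["end"])
    start = int(rng.integers(lo, max(hi - width, lo) + 1))
    start = min(start, chrom_length - width)
    return start, start + width


def generate_methylation_arrays(
    config: SyntheticConfig, annotation: AnnotationSet
) -> tuple[list[TwoColorArray], TruthTable]:
    """Two-color arrays under the cut-signal model, with planted truth.

    Untreated-channel log2 intensities are N(10, 1).  For a probe unmethylated
    in a group the treated channel is attenuated by the cut effect, so its
    expected M equals ``cut_effect_log2`` on that group's arrays; methylated
    and control probes have expected M = 0.  Gaussian noise with
    ``noise_sd_log2`` is added to M on the log2 scale.  Arrays named in
    ``qc_fail_arrays`` emulate endonuclease treatment failure: the cut signal
    and its variability vanish, leaving only attenuated dye noise.
    """
    rng = config.rng(_STREAM_METHYLATION)
    n = config.n_probes
    n_control = int(round(n * config.control_fraction))
    n_exp = n - n_control
    planted_counts = (
        config.planted_unmeth_normal_only,
        config.planted_unmeth_asthma_only,
        config.planted_unmeth_both,
    )
    if sum(planted_counts) > n_exp:
        raise ConfigError("planted counts exceed available non-control probes")

    probe_ids = np.array([f"PR{i:06d}" for i in range(n)])
    is_control = np.zeros(n, dtype=bool)
    if n_control:
        is_control[rng.choice(n, size=n_control, replace=False)] = True
    exp_idx = np.flatnonzero(~is_control)
    shuffled = rng.permutation(exp_idx)
    n_no, n_ao, n_bo = planted_counts
    normal_only = shuffled[:n_no]
    asthma_only = shuffled[n_no:n_no + n_ao]
    both = shuffled[n_no + n_ao:n_no + n_ao + n_bo]

    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom = np.array([chroms[int(c)] for c in rng.integers(len(chroms), size=n)],
                     dtype=object)
    start = rng.integers(0, config.chrom_length - config.probe_width, size=n)
    tx_assigned = np.full(n, None, dtype=object)
    tx = annotation.transcripts
    if len(tx):
        # group-specific planted probes are placed inside transcripts so the
        # integration stage has DMR-bearing genes.  The first planted_dual_count
        # transcripts receive one probe of each direction; the remaining probes
        # of each direction cycle over disjoint transcript pools, so the number
        # of dual-direction transcripts is exactly planted_dual_count.
        order = rng.permutation(len(tx))
        # capped by what the layout can host; exact when counts are consistent
        n_dual = min(config.planted_dual_count, len(tx), n_no, n_ao)
        rem_no = normal_only[n_dual:]
        rem_ao = asthma_only[n_dual:]
        rest = order[n_dual:]
        n_pool_no = max(1, round(len(rest) * len(rem_no) / max(len(rem_no) + len(rem_ao), 1)))
        pools = {
            HYPER_IN_ASTHMA: rest[:n_pool_no] if len(rest) else order[:0],
            HYPO_IN_ASTHMA: rest[n_pool_no:] if len(rest) > n_pool_no else rest[:1],
        }

        def place(idx: int, tx_row: pd.Series) -> None:
            s, _ = _place_probe_in_transcript(
                rng, tx_row, config.probe_width, config.promoter_probe_fraction,
                config.chrom_length,
            )
            chrom[idx] = tx_row["chrom"]
            start[idx] = s
            tx_assigned[idx] = tx_row["transcript_id"]

        for k in range(n_dual):
            t = tx.iloc[int(order[k])]
            place(int(normal_only[k]), t)
            place(int(asthma_only[k]), t)
        for rem, key in ((rem_no, HYPER_IN_ASTHMA), (rem_ao, HYPO_IN_ASTHMA)):
            pool = pools[key]
            if len(pool) == 0 and len(rem):
                raise ConfigError("too few transcripts for the planted probe layout")
            for k, idx in enumerate(rem):
                place(int(idx), tx.iloc[int(pool[k % len(pool)])])
    end = start + config.probe_width

    state_normal = np.full(n, "methylated", dtype=object)
    state_asthma = np.full(n, "methylated", dtype=object)
    state_normal[normal_only] = "unmethylated"
    state_asthma[asthma_only] = "unmethylated"
    state_normal[both] = "unmethylated"
    state_asthma[both] = "unmethylated"
    direction = np.full(n, "none", dtype=object)
    direction[normal_only] = HYPER_IN_ASTHMA
    direction[asthma_only] = HYPO_IN_ASTHMA

    truth_probes = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": chrom,
            "start": start.astype(int),
            "end": end.astype(int),
            "is_control": is_control,
            "state_normal": state_normal,
            "state_asthma": state_asthma,
            "dmr_direction": direction,
            "transcript_id": tx_assigned,
        }
    )

    arrays = []
    for group, unmeth_state in (("normal", state_normal), ("asthma", state_asthma)):
        m_true = np.where((unmeth_state == "unmethylated") & ~is_control,
                          config.cut_effect_log2, 0.0)
        for r in range(config.n_arrays_per_group):
            array_id = f"{group}_{r + 1}"
            log2_u = rng.normal(10.0, 1.0, size=n)
            if array_id in config.qc_fail_arrays:
                m = rng.normal(0.0, config.noise_sd_log2 * config.qc_fail_noise_scale,
                               size=n)
            else:
                noise = (rng.normal(0.0, config.noise_sd_log2, size=n)
                         if config.noise_sd_log2 > 0 else 0.0)
                m = m_true + noise
            untreated = np.exp2(log2_u)
            treated = np.exp2(log2_u - m)
            arrays.append(
                TwoColorArray(
                    array_id=array_id,
                    group=group,
                    probe_ids=probe_ids,
                    treated=treated,
                    untreated=untreated,
                    is_control=is_control,
                )
            )
    return arrays, TruthTable(probes=truth_probes)


def generate_expression(
    config: SyntheticConfig, annotation: AnnotationSet, truth: TruthTable
) -> tuple[ExpressionSets, TruthTable]:
    """Coupled probe-level expression matrices with planted DE.

    All annotation transcripts sit on the simulated expression platform.
    Planted DE transcripts are drawn preferentially from transcripts carrying
    a planted group-specific DMR; a fraction ``concordance_rate`` of those
    receives the direction the methylation paradigm predicts (hypomethylated
    in asthma -> up, hypermethylated -> down), the rest the opposite.  The DE
    shift is applied to the allergen-stimulated asthma group of both designs.
    """
    rng = config.rng(_STREAM_EXPRESSION)
    tx = annotation.transcripts
    if config.planted_de_count > len(tx):
        raise ConfigError(
            f"planted_de_count {config.planted_de_count} exceeds the "
            f"{len(tx)} transcripts on the simulated platform"
        )
    planted = truth.probes[truth.probes["transcript_id"].notna()]
    tx_dir = (
        planted.groupby("transcript_id")["dmr_direction"]
        .agg(lambda s: s.iloc[0] if s.nunique() == 1 else "dual")
        if len(planted) else pd.Series(dtype=object)
    )
    dmr_ids = [t for t in tx["transcript_id"] if t in tx_dir.index]
    non_dmr_ids = [t for t in tx["transcript_id"] if t not in tx_dir.index]
    dmr_ids = list(rng.permutation(dmr_ids)) if dmr_ids else []
    non_dmr_ids = list(rng.permutation(non_dmr_ids)) if non_dmr_ids else []
    n_from_dmr = min(config.planted_de_count, len(dmr_ids))
    de_with_dmr = dmr_ids[:n_from_dmr]
    de_without = non_dmr_ids[: config.planted_de_count - n_from_dmr]

    # exact concordant count so the planted rate is honoured per run
    n_conc = int(round(config.concordance_rate * len(de_with_dmr)))
    conc_flags = np.array([True] * n_conc + [False] * (len(de_with_dmr) - n_conc))
    conc_flags = rng.permutation(conc_flags)

    de_state: dict[str, str] = {}
    concordant: dict[str, bool] = {}
    for tid, conc in zip(de_with_dmr, conc_flags):
        d = tx_dir[tid]
        if d == "dual":
            d = HYPO_IN_ASTHMA if rng.random() < 0.5 else HYPER_IN_ASTHMA
        paradigm = "up" if d == HYPO_IN_ASTHMA else "down"
        de_state[tid] = paradigm if conc else ("down" if paradigm == "up" else "up")
        concordant[tid] = bool(conc)
    for tid in de_without:
        de_state[tid] = "up" if rng.random() < 0.5 else "down"

    tx_truth = pd.DataFrame(
        {
            "transcript_id": tx["transcript_id"],
            "dmr_direction": [tx_dir.get(t, "none") for t in tx["transcript_id"]],
            "de_state": [de_state.get(t, "null") for t in tx["transcript_id"]],
            "concordant": pd.array(
                [concordant.get(t) for t in tx["transcript_id"]], dtype="boolean"
            ),
        }
    )

    n1, n2 = config.n_expr_replicates_per_group
    sample_rows = []
    for cond in ("naive", "stim"):
        for group in ("normal", "asthma"):
            for r in range(n1):
                sample_rows.append((f"s1_{cond}_{group}_{r + 1}", "set1", cond, group))
    for group in ("normal", "asthma"):
        for r in range(n2):
            sample_rows.append((f"s2_stim_{group}_{r + 1}", "set2", "stim", group))
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "dataset", "condition", "group"])

    n_pp = config.n_probes_per_probeset
    probe_ids = [f"{t}_p{j + 1}" for t in tx["transcript_id"] for j in range(n_pp)]
    probeset_map = pd.Series(
        np.repeat(tx["transcript_id"].to_numpy(), n_pp), index=probe_ids, name="transcript_id"
    )
    baseline = rng.normal(8.0, 1.0, size=len(tx))
    probe_offset = rng.normal(0.0, 0.5, size=len(probe_ids))
    base_per_probe = np.repeat(baseline, n_pp) + probe_offset
    shift = np.array(
        [
            (config.de_log2fc_mean if de_state.get(t) == "up"
             else -config.de_log2fc_mean if de_state.get(t) == "down" else 0.0)
            for t in tx["transcript_id"]
        ]
    )
    shift_per_probe = np.repeat(shift, n_pp)

    mats = {}
    for ds in ("set1", "set2"):
        sub = samples[samples["dataset"] == ds]
        cols = {}
        for row in sub.itertuples(index=False):
            mu = base_per_probe.copy()
            if row.condition == "stim" and row.group == "asthma":
                mu = mu + shift_per_probe
            noise = (rng.normal(0.0, config.expr_noise_sd_log2, size=len(mu))
                     if config.expr_noise_sd_log2 > 0 else 0.0)
            cols[row.sample_id] = np.exp2(mu + noise)
        mats[ds] = pd.DataFrame(cols, index=pd.Index(probe_ids, name="probe_id"))

    new_truth = TruthTable(probes=truth.probes, transcripts=tx_truth)
    sets = ExpressionSets(
        set1=mats["set1"], set2=mats["set2"], samples=samples, probeset_map=probeset_map
    )
    return sets, new_truth
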