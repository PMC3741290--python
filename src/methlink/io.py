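"""Readers and writers for the pipeline's plain-text interchange formats.

Arrays travel as one TSV per chip (probe_id, treated, untreated, is_control,
optionally chrom/start/end) plus a sample sheet (array_id, group, file);
annotation as GTF (transcripts, 1-based inclusive on disk) and BED (CpG
islands, 0-based half-open); everything else as TSV/JSON.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .annotation import AnnotationSet
from .methylation import DmrSet, TwoColorArray
from .simulate import ExpressionSets, TruthTable


def write_annotation(annotation: AnnotationSet, gtf_path: str, bed_path: str) -> None:
    with open(gtf_path, "w") as fh:
        for t in annotation.transcripts.itertuples(index=False):
            fh.write(
                f"{t.chrom}\tmethlink\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                f'{t.strand}\t.\ttranscript_id "{t.transcript_id}";\n'
            )
    annotation.cpg_islands.to_csv(bed_path, sep="\t", header=False, index=False)


def write_arrays(arrays: list[TwoColorArray], coords: pd.DataFrame | None,
                 outdir: str) -> str:
    """Write per-array TSVs plus a sample sheet; returns the sample-sheet path."""
    os.makedirs(outdir, exist_ok=True)
    rows = []
    for arr in arrays:
        fname = f"array_{arr.array_id}.tsv"
        df = pd.DataFrame(
            {
                "probe_id": arr.probe_ids,
                "treated": arr.treated,
                "untreated": arr.untreated,
                "is_control": arr.is_control.astype(int),
            }
        )
        if coords is not None:
            df = df.merge(coords, on="probe_id", how="left")
        df.to_csv(os.path.join(outdir, fname), sep="\t", index=False,
                  float_format="%.6f")
        rows.append((arr.array_id, arr.group, fname))
    sheet = pd.DataFrame(rows, columns=["array_id", "group", "file"])
    sheet_path = os.path.join(outdir, "sample_sheet.tsv")
    sheet.to_csv(sheet_path, sep="\t", index=False)
    return sheet_path


def read_arrays(sample_sheet_path: str) -> tuple[list[TwoColorArray], pd.DataFrame | None]:
    """Read arrays named by a sample sheet; returns (arrays, probe coordinates or None)."""
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    base = os.path.dirname(os.path.abspath(sample_sheet_path))
    arrays = []
    coords = None
    for row in sheet.itertuples(index=False):
        path = row.file if os.path.isabs(row.file) else os.path.join(base, row.file)
        df = pd.read_csv(path, sep="\t")
        arrays.append(
            TwoColorArray(
                array_id=str(row.array_id),
                group=str(row.group),
                probe_ids=df["probe_id"].to_numpy(dtype=object),
                treated=df["treated"].to_numpy(dtype=float),
                untreated=df["untreated"].to_numpy(dtype=float),
                is_control=df["is_control"].to_numpy().astype(bool),
            )
        )
        if coords is None and {"chrom", "start", "end"} <= set(df.columns):
            coords = df[["probe_id", "chrom", "start", "end"]].copy()
    return arrays, coords


def read_wide_arrays(path: str, sample_sheet_path: str) -> list[TwoColorArray]:
    """GEO-series-matrix-style wide TSV: probe_id, is_control, then
    ``<array_id>:treated`` / ``<array_id>:untreated`` column pairs."""
    wide = pd.read_csv(path, sep="\t")
    sheet = pd.read_csv(sample_sheet_path, sep="\t").set_index("array_id")
    arrays = []
    for aid in sheet.index.astype(str):
        arrays.append(
            TwoColorArray(
                array_id=aid,
                group=str(sheet.loc[aid, "group"]),
                probe_ids=wide["probe_id"].to_numpy(dtype=object),
                treated=wide[f"{aid}:treated"].to_numpy(dtype=float),
                untreated=wide[f"{aid}:untreated"].to_numpy(dtype=float),
                is_control=wide["is_control"].to_numpy().astype(bool),
            )
        )
    return arrays


def write_expression(sets: ExpressionSets, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    sets.set1.to_csv(os.path.join(outdir, "expression_set1.tsv"), sep="\t",
                     float_format="%.6f")
    sets.set2.to_csv(os.path.join(outdir, "expression_set2.tsv"), sep="\t",
                     float_format="%.6f")
    sets.samples.to_csv(os.path.join(outdir, "expression_samples.tsv"), sep="\t",
                        index=False)
    sets.probeset_map.rename_axis("probe_id").to_csv(
        os.path.join(outdir, "probeset_map.tsv"), sep="\t"
    )


def read_expression(outdir: str) -> ExpressionSets:
    set1 = pd.read_csv(os.path.join(outdir, "expression_set1.tsv"), sep="\t",
                       index_col="probe_id")
    set2 = pd.read_csv(os.path.join(outdir, "expression_set2.tsv"), sep="\t",
                       index_col="probe_id")
    samples = pd.read_csv(os.path.join(outdir, "expression_samples.tsv"), sep="\t")
    pm = pd.read_csv(os.path.join(outdir, "probeset_map.tsv"), sep="\t",
                     index_col="probe_id")["transcript_id"]
    return ExpressionSets(set1=set1, set2=set2, samples=samples, probeset_map=pm)


def write_truth(truth: TruthTable, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    truth.probes.to_csv(os.path.join(outdir, "truth_probes.tsv"), sep="\t", index=False)
    if len(truth.transcripts):
        truth.transcripts.to_csv(
            os.path.join(outdir, "truth_transcripts.tsv"), sep="\t", index=False
        )


def write_dmr_bed(dmr: DmrSet, coords: pd.DataFrame, bed_path: str,
                  sidecar_path: str) -> None:
    """BED with name=probe_id and score = 1000*|delta log2FC| capped at 1000,
    plus a sidecar TSV carrying both group estimates."""
    t = dmr.table.merge(coords, on="probe_id", how="left")
    score = np.minimum(1000.0 * t["delta_lfc"].abs(), 1000.0).round().astype(int)
    bed = pd.DataFrame(
        {
            "chrom": t["chrom"],
            "start": t["start"].astype("Int64"),
            "end": t["end"].astype("Int64"),
            "name": t["probe_id"],
            "score": score,
            "strand": ".",
        }
    )
    bed.to_csv(bed_path, sep="\t", header=False, index=False)
    dmr.table.assign(direction=dmr.direction).to_csv(
        sidecar_path, sep="\t", index=False, float_format="%.6f"
    )


def write_json(obj, path: str) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        return str(o)

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
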