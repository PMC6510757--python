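"""Readers and writers for the formats the pipeline touches.

FASTA in/out goes through Bio.SeqIO; annotation tables are TSV (plus BED6),
feature matrices are TSV with an ``id`` column (and ``label`` when
labeled), and experiment reports are JSON written with sorted keys so
repeated runs are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .encode import FeatureVector
from .experiments import ExperimentReport
from .hairpin import HairpinAnnotation
from .records import SequenceRecord, normalize_sequence


class FastaFormatError(ValueError):
    pass


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (wrapped or unwrapped) multi-FASTA into normalized records.

    Record order is preserved; case is normalized and U mapped to T.
    Duplicate ids are deterministically suffixed ``.2``, ``.3``, ...
    Empty files, non-FASTA content and blank records raise
    :class:`FastaFormatError`.
    """
    path = Path(path)
    text = path.read_text()
    first = next((ln for ln in text.splitlines() if ln.strip()), None)
    if first is None:
        raise FastaFormatError(f"{path}: empty file")
    if not first.startswith(">"):
        raise FastaFormatError(f"{path}: line 1: expected FASTA header '>'")
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    for ordinal, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        seq = str(rec.seq)
        if not seq:
            raise FastaFormatError(f"{path}: record {ordinal} ({rec.id!r}) is blank")
        rec_id = rec.id
        seen[rec_id] = seen.get(rec_id, 0) + 1
        if seen[rec_id] > 1:
            rec_id = f"{rec_id}.{seen[rec_id]}"
        records.append(SequenceRecord(id=rec_id, sequence=normalize_sequence(seq)))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    bio = [
        BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


_ANNOTATION_COLUMNS = [
    "seq_id",
    "span_start",
    "span_end",
    "left_arm_start",
    "left_arm_end",
    "loop_start",
    "loop_end",
    "right_arm_start",
    "right_arm_end",
    "stem_length",
    "mismatch_count",
    "mismatch_steps",
    "left_bulge_start",
    "left_bulge_end",
    "right_bulge_start",
    "right_bulge_end",
    "paired_left",
    "paired_right",
    "loop",
    "bulge_left",
    "bulge_right",
]


def annotations_to_dataframe(annotations: Sequence[HairpinAnnotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        rows.append(
            {
                "seq_id": a.seq_id,
                "span_start": a.span[0],
                "span_end": a.span[1],
                "left_arm_start": a.left_arm[0],
                "left_arm_end": a.left_arm[1],
                "loop_start": a.loop[0],
                "loop_end": a.loop[1],
                "right_arm_start": a.right_arm[0],
                "right_arm_end": a.right_arm[1],
                "stem_length": a.stem_length,
                "mismatch_count": a.mismatch_count,
                "mismatch_steps": ",".join(map(str, a.mismatch_steps)),
                "left_bulge_start": -1 if a.left_bulge is None else a.left_bulge[0],
                "left_bulge_end": -1 if a.left_bulge is None else a.left_bulge[1],
                "right_bulge_start": -1 if a.right_bulge is None else a.right_bulge[0],
                "right_bulge_end": -1 if a.right_bulge is None else a.right_bulge[1],
                "paired_left": a.paired_left_string,
                "paired_right": a.paired_right_string,
                "loop": a.loop_string,
                "bulge_left": a.bulge_left_string,
                "bulge_right": a.bulge_right_string,
            }
        )
    return pd.DataFrame(rows, columns=_ANNOTATION_COLUMNS)


def write_annotations_tsv(
    annotations: Sequence[HairpinAnnotation], path: str | Path
) -> None:
    annotations_to_dataframe(annotations).to_csv(str(path), sep="\t", index=False)


def read_annotations_tsv(path: str | Path) -> list[HairpinAnnotation]:
    df = pd.read_csv(str(path), sep="\t", keep_default_na=False, dtype={"mismatch_steps": str})
    out = []
    for _, r in df.iterrows():
        steps = tuple(int(x) for x in str(r["mismatch_steps"]).split(",") if x != "")
        out.append(
            HairpinAnnotation(
                seq_id=str(r["seq_id"]),
                left_arm=(int(r["left_arm_start"]), int(r["left_arm_end"])),
                loop=(int(r["loop_start"]), int(r["loop_end"])),
                right_arm=(int(r["right_arm_start"]), int(r["right_arm_end"])),
                stem_length=int(r["stem_length"]),
                mismatch_count=int(r["mismatch_count"]),
                mismatch_steps=steps,
                left_bulge=None
                if int(r["left_bulge_start"]) < 0
                else (int(r["left_bulge_start"]), int(r["left_bulge_end"])),
                right_bulge=None
                if int(r["right_bulge_start"]) < 0
                else (int(r["right_bulge_start"]), int(r["right_bulge_end"])),
                paired_left_string=str(r["paired_left"]),
                paired_right_string=str(r["paired_right"]),
                loop_string=str(r["loop"]),
                bulge_left_string=str(r["bulge_left"]),
                bulge_right_string=str(r["bulge_right"]),
            )
        )
    return out


def write_bed6(annotations: Sequence[HairpinAnnotation], path: str | Path) -> None:
    """BED6: chrom=seq_id, full hairpin span, name=stem:loop:mm, score=stem."""
    with open(path, "w") as fh:
        for a in annotations:
            name = f"stem{a.stem_length}:loop{a.loop_length}:mm{a.mismatch_count}"
            fh.write(
                f"{a.seq_id}\t{a.span[0]}\t{a.span[1]}\t{name}\t{a.stem_length}\t+\n"
            )


def read_bed6(path: str | Path) -> list[tuple[str, int, int, str, int, str]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        chrom, start, end, name, score, strand = line.split("\t")
        out.append((chrom, int(start), int(end), name, int(score), strand))
    return out


def feature_matrix_to_dataframe(
    vectors: Sequence[FeatureVector],
    ids: Sequence[str],
    labels: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    if not vectors:
        raise ValueError("no feature vectors to write")
    names = vectors[0].names
    data = {"id": list(ids)}
    if labels is not None:
        data["label"] = list(labels)
    for i, name in enumerate(names):
        data[name] = [float(v.values[i]) for v in vectors]
    return pd.DataFrame(data)


def write_feature_matrix(
    vectors: Sequence[FeatureVector],
    ids: Sequence[str],
    path: str | Path,
    labels: Optional[Sequence[int]] = None,
) -> None:
    # %.17g round-trips IEEE doubles exactly
    feature_matrix_to_dataframe(vectors, ids, labels).to_csv(
        str(path), sep="\t", index=False, float_format="%.17g"
    )


def read_feature_matrix(path: str | Path, scheme: str) -> tuple[list[FeatureVector], list[str], Optional[list[int]]]:
    import numpy as np

    df = pd.read_csv(str(path), sep="\t", float_precision="round_trip")
    ids = df["id"].astype(str).tolist()
    labels = df["label"].astype(int).tolist() if "label" in df.columns else None
    feature_cols = [c for c in df.columns if c not in ("id", "label")]
    names = tuple(feature_cols)
    vectors = [
        FeatureVector(names=names, values=np.asarray(row, dtype=float), scheme=scheme)
        for row in df[feature_cols].to_numpy()
    ]
    return vectors, ids, labels


def write_report_json(report: ExperimentReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, sort_keys=True, indent=2)
        fh.write("\n")


def read_report_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_report_plots(report: ExperimentReport, roc_path: str | Path, pr_path: str | Path) -> None:
    """PNG ROC and precision-recall curves for one report."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    xs, ys = zip(*report.roc_curve)
    ax.plot(xs, ys, label=f"AUC = {report.auc_mean:.3f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(report.name)
    ax.legend()
    fig.tight_layout()
    fig.savefig(roc_path, dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 4))
    xs, ys = zip(*report.pr_curve)
    ax.plot(xs, ys)
    ax.set_xlabel("Recall")
    ax.set_ylabel("Precision")
    ax.set_title(report.name)
    fig.tight_layout()
    fig.savefig(pr_path, dpi=120)
    plt.close(fig)
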