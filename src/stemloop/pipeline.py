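"""End-to-end chaining of detection, shuffling, encoding and training.

``run_pipeline`` reproduces the experiment design: take the terminal window
of every input element, build the positive class (window k-mers for the
sequence scheme, or the selected terminal stem-loop's 134-feature vector
for the structure scheme), build the negative class the same way from
dinucleotide-shuffled windows (or from a second explicit input set),
balance the classes 1:1, train and cross-validate a Random Forest, and
write annotations, the feature matrix and the report.  Everything is
driven by one seed and is byte-identical across repeated runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

from .encode import (
    SCHEME_KMER,
    SCHEME_STRUCTURE,
    DinucPropertyTable,
    FeatureVector,
    eligible_for_structure,
    encode_structure,
    kmer_frequencies,
)
from .experiments import (
    ExperimentReport,
    ExperimentSpec,
    TrainedModel,
    build_dataset,
    run_experiment,
    train_full,
)
from .hairpin import (
    THREE_PRIME,
    HairpinAnnotation,
    HairpinParams,
    extract_terminal_window,
    find_stem_loops,
    select_terminal_stemloops,
)
from .io import (
    write_annotations_tsv,
    write_bed6,
    write_feature_matrix,
    write_report_json,
)
from .records import SequenceRecord
from .shuffle import ShuffleConfig, shuffle_records

logger = logging.getLogger(__name__)

# loop >= 5 so every selected hairpin fits the 134-feature layout; the
# eligibility filter applies identically to positives and shuffled negatives
STRUCTURE_DETECTION_PARAMS = HairpinParams(loop_min=5)


@dataclass
class PipelineResult:
    report: ExperimentReport
    model: TrainedModel
    positive_annotations: list[HairpinAnnotation]
    negative_annotations: list[HairpinAnnotation]
    n_positive: int
    n_negative: int


def terminal_stemloop(
    record: SequenceRecord,
    params: HairpinParams = STRUCTURE_DETECTION_PARAMS,
    end: str = THREE_PRIME,
    window: int = 50,
) -> Optional[HairpinAnnotation]:
    """Best stem-loop fully inside the terminal window, in full-sequence
    coordinates (detection runs on the window only, for speed)."""
    sub = extract_terminal_window(record, end=end, window=window)
    annotations = find_stem_loops(sub, params)
    best = select_terminal_stemloops(sub, annotations, end=end, window=window)
    if best is None:
        return None
    offset = len(record) - len(sub) if end == THREE_PRIME else 0

    def shift(iv):
        return None if iv is None else (iv[0] + offset, iv[1] + offset)

    return HairpinAnnotation(
        seq_id=record.id,
        left_arm=shift(best.left_arm),
        loop=shift(best.loop),
        right_arm=shift(best.right_arm),
        stem_length=best.stem_length,
        mismatch_count=best.mismatch_count,
        mismatch_steps=best.mismatch_steps,
        left_bulge=shift(best.left_bulge),
        right_bulge=shift(best.right_bulge),
        paired_left_string=best.paired_left_string,
        paired_right_string=best.paired_right_string,
        loop_string=best.loop_string,
        bulge_left_string=best.bulge_left_string,
        bulge_right_string=best.bulge_right_string,
    )


def structure_features(
    records: Sequence[SequenceRecord],
    table: DinucPropertyTable,
    params: HairpinParams = STRUCTURE_DETECTION_PARAMS,
    end: str = THREE_PRIME,
    window: int = 50,
) -> tuple[list[FeatureVector], list[str], list[HairpinAnnotation]]:
    """Structure-based vectors for every record with an eligible terminal
    stem-loop; records without one are dropped (symmetrically per class)."""
    vectors, ids, annotations = [], [], []
    for rec in records:
        ann = terminal_stemloop(rec, params=params, end=end, window=window)
        if ann is None or not eligible_for_structure(ann):
            continue
        vectors.append(encode_structure(ann, table))
        ids.append(rec.id)
        annotations.append(ann)
    return vectors, ids, annotations


def kmer_features(
    records: Sequence[SequenceRecord], end: str = THREE_PRIME, window: int = 50
) -> tuple[list[FeatureVector], list[str]]:
    vectors, ids = [], []
    for rec in records:
        vectors.append(kmer_frequencies(extract_terminal_window(rec, end=end, window=window)))
        ids.append(rec.id)
    return vectors, ids


def run_pipeline(
    class1: Sequence[SequenceRecord],
    class2: Optional[Sequence[SequenceRecord]] = None,
    *,
    scheme: str = SCHEME_STRUCTURE,
    end: str = THREE_PRIME,
    window: int = 50,
    n_shuffles: int = 1,
    n_trees: int = 2000,
    cv_folds: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
    hairpin_params: Optional[HairpinParams] = None,
    outdir: Optional[str | Path] = None,
    name: str = "experiment",
) -> PipelineResult:
    """Detect -> shuffle -> encode -> train, reproducibly from one seed.

    When ``class2`` is None the negative class is built from
    ``n_shuffles`` dinucleotide shuffles of each positive terminal window.
    """
    if scheme not in (SCHEME_KMER, SCHEME_STRUCTURE):
        raise ValueError(f"unknown scheme {scheme!r}")
    params = hairpin_params or STRUCTURE_DETECTION_PARAMS
    table = DinucPropertyTable.load_default()

    windows1 = [extract_terminal_window(r, end=end, window=window) for r in class1]
    if class2 is None:
        negatives_raw = shuffle_records(
            windows1, ShuffleConfig(seed=seed, n_shuffles_per_sequence=n_shuffles)
        )
    else:
        negatives_raw = [extract_terminal_window(r, end=end, window=window) for r in class2]

    pos_ann: list[HairpinAnnotation] = []
    neg_ann: list[HairpinAnnotation] = []
    if scheme == SCHEME_KMER:
        pos_vecs, pos_ids = kmer_features(windows1, end=end, window=window)
        neg_vecs, neg_ids = kmer_features(negatives_raw, end=end, window=window)
    else:
        pos_vecs, pos_ids, pos_ann = structure_features(
            windows1, table, params=params, end=end, window=window
        )
        neg_vecs, neg_ids, neg_ann = structure_features(
            negatives_raw, table, params=params, end=end, window=window
        )

    n_keep = min(len(pos_vecs), len(neg_vecs))
    if n_keep == 0:
        raise ValueError("a class ended up empty after eligibility filtering")
    logger.info(
        "pipeline %s: %d positives, %d negatives (balanced to %d per class)",
        name, len(pos_vecs), len(neg_vecs), n_keep,
    )
    dataset = build_dataset(
        pos_vecs[:n_keep], neg_vecs[:n_keep], pos_ids[:n_keep], neg_ids[:n_keep]
    )
    spec = ExperimentSpec(
        name=name,
        scheme=scheme,
        class1_source="class1",
        class2_source="class2" if class2 is not None else "shuffled",
        n_trees=n_trees,
        cv_folds=cv_folds,
        seed=seed,
        threshold=threshold,
    )
    report = run_experiment(spec, dataset)
    model = train_full(spec, dataset)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_report_json(report, outdir / "report.json")
        write_feature_matrix(
            list(dataset_vectors(pos_vecs[:n_keep], neg_vecs[:n_keep])),
            list(dataset.ids),
            outdir / "features.tsv",
            labels=dataset.y.tolist(),
        )
        if scheme == SCHEME_STRUCTURE:
            write_annotations_tsv(pos_ann[:n_keep] + neg_ann[:n_keep], outdir / "annotations.tsv")
            write_bed6(pos_ann[:n_keep] + neg_ann[:n_keep], outdir / "annotations.bed")

    return PipelineResult(
        report=report,
        model=model,
        positive_annotations=pos_ann[:n_keep],
        negative_annotations=neg_ann[:n_keep],
        n_positive=n_keep,
        n_negative=n_keep,
    )


def dataset_vectors(pos_vecs, neg_vecs):
    yield from pos_vecs
    yield from neg_vecs
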