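"""End-to-end orchestration: FASTA in, annotations and reports out.

``run_pipeline`` drives transcript mode (six-frame ORF selection →
annotation → classification → precursor typing) or protein mode
(annotation directly), writes JSON/TSV outputs and logs every parameter.
``composition_table`` renders the per-precursor peptide composition in
the fixed column order id, n_peptides, LxF, FxF, FxL, LxL, atypical,
type_call.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
import yaml

from . import annotate as annotate_mod
from .annotate import AnnotationConfig, PrecursorAnnotation, annotate_precursor
from .orf import NoOrfError, longest_orf_protein
from .seqio import SequenceRecord, read_fasta

logger = logging.getLogger("salm")

REPORT_COLUMNS = ["id", "n_peptides", "LxF", "FxF", "FxL", "LxL", "atypical", "type_call"]


@dataclass(frozen=True)
class PipelineConfig:
    """Run parameters; round-trips losslessly through YAML."""

    input_path: str
    out_dir: str
    mode: Literal["protein", "transcript"] = "protein"
    min_len: int = 5
    require_amidation: bool = True
    min_orf_aa: int = 60
    signal_overrides: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("protein", "transcript"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.min_len < 1 or self.min_orf_aa < 30:
            raise ValueError("min_len must be ≥1 and min_orf_aa ≥30")

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls(**yaml.safe_load(text))

    def annotation_config(self) -> AnnotationConfig:
        return AnnotationConfig(
            min_len=self.min_len,
            require_amidation=self.require_amidation,
            signal_overrides=self.signal_overrides,
        )


def annotate_records(
    records: Iterable[SequenceRecord],
    mode: str = "protein",
    config: AnnotationConfig | None = None,
    min_orf_aa: int = 60,
) -> list[PrecursorAnnotation]:
    """Annotate protein records, or transcripts via their longest ORF.

    Transcripts without an anchored ORF of at least ``min_orf_aa``
    residues are skipped with a warning; everything else yields one
    annotation (possibly with zero peptides).
    """
    config = config or AnnotationConfig()
    annotations: list[PrecursorAnnotation] = []
    for rec in records:
        if mode == "protein":
            protein_rec = rec
        else:
            try:
                protein = longest_orf_protein(rec.seq, source_id=rec.id)
            except NoOrfError:
                logger.warning("no anchored ORF in %s; skipped", rec.id)
                continue
            if len(protein) < min_orf_aa:
                logger.info(
                    "longest ORF of %s is %d aa (< %d); skipped", rec.id, len(protein), min_orf_aa
                )
                continue
            protein_rec = SequenceRecord(
                id=rec.id, seq=protein, alphabet_kind="protein", description="longest ORF"
            )
        if len(protein_rec.seq) < config.min_protein_len:
            logger.info("%s shorter than %d aa; skipped", rec.id, config.min_protein_len)
            continue
        annotations.append(annotate_precursor(protein_rec, config))
    return annotations


def is_putative_precursor(ann: PrecursorAnnotation) -> bool:
    """Detection rule: a record is a putative SALMFamide precursor when it
    yields at least one amidated peptide that classifies into one of the
    four C-terminal motif categories.

    Family membership is defined by the motif, so an annotation whose
    peptides are all ATYPICAL (as happens by chance in random ORFs — any
    Gly-terminated inter-site segment is an amidation candidate) is not a
    detection.
    """
    from .motif import Category

    return any(
        p.category is not None and p.category.category is not Category.ATYPICAL
        for p in ann.peptides
    )


def composition_table(annotations: Iterable[PrecursorAnnotation]) -> pd.DataFrame:
    """One row per precursor: peptide count, per-category counts, type call."""
    rows = []
    for ann in annotations:
        comp = {str(cat): n for cat, n in ann.composition.items()}
        rows.append(
            {
                "id": ann.record.id,
                "n_peptides": len(ann.peptides),
                "LxF": comp.get("LxF", 0),
                "FxF": comp.get("FxF", 0),
                "FxL": comp.get("FxL", 0),
                "LxL": comp.get("LxL", 0),
                "atypical": comp.get("atypical", 0),
                "type_call": ann.type_call.call.value,
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def run_pipeline(config: PipelineConfig) -> list[PrecursorAnnotation]:
    """Execute the pipeline and write annotations.json, peptides.tsv, report.tsv."""
    logger.info("pipeline config:\n%s", config.to_yaml().rstrip())
    records = read_fasta(
        config.input_path,
        alphabet="nucleotide" if config.mode == "transcript" else "protein",
    )
    if not records:
        logger.warning("input %s contains no records; empty report", config.input_path)
    annotations = annotate_records(
        records,
        mode=config.mode,
        config=config.annotation_config(),
        min_orf_aa=config.min_orf_aa,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "annotations.json").write_text(annotate_mod.annotations_to_json(annotations))
    (out / "peptides.tsv").write_text(annotate_mod.peptides_to_bed(annotations))
    composition_table(annotations).to_csv(out / "report.tsv", sep="\t", index=False)
    logger.info("%d precursors annotated → %s", len(annotations), out)
    return annotations
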