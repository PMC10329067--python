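"""Comparative profiling of antigens and peptides across tissue groups.

An item (source protein or peptide) is tabulated against three groups:
tumors and autologous tumor-free dura are counted per sample, benign organs
per tissue (an organ is positive as soon as any of its donors presents the
item). Tumor exclusivity requires absence from dura and CNS-related benign
tissues, at most one positive non-CNS benign organ, and presence in at least
two tumors. Dura is included as a comparator precisely to subtract
dura-associated antigens.

Candidate curation then inspects the peptide evidence behind exclusive
antigens: class I evidence must be single-mapping binders for the presenting
patient's own typing; class II evidence must be single-mapping peptides
within the configured length window. Positivity is recomputed from the
surviving evidence and antigens falling below the tumor minimum are dropped.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .annotation import BinderAnnotation
from .config import PipelineConfig
from .errors import MissingReferenceError, ValidationError
from .io_formats import Peptidome, ProteinIndex, Sample

logger = logging.getLogger(__name__)


@dataclass
class ProfilingRow:
    """Positivity counts of one item across tumor / dura / benign groups."""

    item_id: str
    level: str  # "antigen" or "peptide"
    hla_class: str
    n_tumor: int
    n_dura: int
    n_benign_cns: int
    n_benign_noncns: int
    tumor_frequency: float
    exclusive: Optional[bool] = None
    tumor_samples: frozenset[str] = frozenset()
    dura_samples: frozenset[str] = frozenset()
    benign_cns_organs: frozenset[str] = frozenset()
    benign_noncns_organs: frozenset[str] = frozenset()


@dataclass
class CuratedCandidate:
    """An exclusive antigen that survived evidence curation."""

    antigen: str
    hla_class: str
    evidence: dict[str, frozenset[str]]  # peptide -> positive tumor samples
    tumor_samples: frozenset[str]
    tumor_frequency: float


def positivity_counts(peptidome: Peptidome, samples: Sequence[Sample],
                      index: ProteinIndex, level: str,
                      hla_class: str) -> list[ProfilingRow]:
    """Count positive samples/organs per item.

    At antigen level a sample is positive for a protein iff at least one of
    its peptides maps to it; unmapped peptides are excluded (logged count).
    Benign positivity is aggregated at the organ level.
    """
    if level not in ("antigen", "peptide"):
        raise ValidationError(f"unknown profiling level {level!r}")
    by_id = {s.sample_id: s for s in samples}
    n_tumor_samples = sum(1 for s in samples if s.tissue_class == "tumor")

    tumor: dict[str, set[str]] = defaultdict(set)
    dura: dict[str, set[str]] = defaultdict(set)
    benign_cns: dict[str, set[str]] = defaultdict(set)
    benign_noncns: dict[str, set[str]] = defaultdict(set)
    n_unmapped = 0

    for sample_id in peptidome.sample_ids():
        sample = by_id.get(sample_id)
        if sample is None:
            raise MissingReferenceError(
                f"sample {sample_id!r} in peptidome has no metadata row")
        for pep in peptidome.peptides(sample_id, hla_class):
            if level == "antigen":
                items = index.source_proteins(pep)
                if not items:
                    n_unmapped += 1
                    continue
            else:
                items = {pep}
            for item in items:
                if sample.tissue_class == "tumor":
                    tumor[item].add(sample_id)
                elif sample.tissue_class == "dura":
                    dura[item].add(sample_id)
                elif sample.cns_related:
                    benign_cns[item].add(sample.organ)
                else:
                    benign_noncns[item].add(sample.organ)
    if n_unmapped:
        logger.info("%d unmapped peptide observations excluded at antigen level",
                    n_unmapped)

    all_items = sorted(set(tumor) | set(dura) | set(benign_cns) | set(benign_noncns))
    rows = []
    for item in all_items:
        t = tumor.get(item, set())
        rows.append(ProfilingRow(
            item_id=item, level=level, hla_class=hla_class,
            n_tumor=len(t), n_dura=len(dura.get(item, set())),
            n_benign_cns=len(benign_cns.get(item, set())),
            n_benign_noncns=len(benign_noncns.get(item, set())),
            tumor_frequency=len(t) / n_tumor_samples if n_tumor_samples else 0.0,
            tumor_samples=frozenset(t),
            dura_samples=frozenset(dura.get(item, set())),
            benign_cns_organs=frozenset(benign_cns.get(item, set())),
            benign_noncns_organs=frozenset(benign_noncns.get(item, set())),
        ))
    return rows


def flag_exclusive(rows: Iterable[ProfilingRow],
                   config: PipelineConfig,
                   min_tumor_positives: Optional[int] = None) -> list[ProfilingRow]:
    """Set the tumor-exclusivity verdict on each row (in place).

    ``min_tumor_positives`` overrides the config value; the class II peptide
    set fed into hotspot detection uses a minimum of one tumor because patient
    support is enforced later by the hotspot rule itself.
    """
    min_tumor = (config.min_tumor_positives if min_tumor_positives is None
                 else min_tumor_positives)
    rows = list(rows)
    for row in rows:
        row.exclusive = (row.n_dura == 0
                         and row.n_benign_cns == 0
                         and row.n_benign_noncns <= config.max_noncns_benign
                         and row.n_tumor >= min_tumor)
    return rows


def curate_candidates(rows: Iterable[ProfilingRow], peptidome: Peptidome,
                      samples: Sequence[Sample], index: ProteinIndex,
                      annotations: Optional[Mapping[str, BinderAnnotation]],
                      config: PipelineConfig,
                      hla_class: str) -> dict[str, CuratedCandidate]:
    """Quality-control the peptide evidence behind exclusive antigens.

    Class I: evidence peptides must map to a single source protein and be
    binders for the presenting tumor sample's typing (``annotations`` maps
    sample_id to its BinderAnnotation). Class II: single mappers within the
    configured length window. Antigens whose surviving evidence spans fewer
    than ``min_tumor_positives`` tumors are dropped.
    """
    n_tumor_samples = sum(1 for s in samples if s.tissue_class == "tumor")
    tumor_ids = {s.sample_id for s in samples if s.tissue_class == "tumor"}

    # peptide -> single source protein, for mapped single-mappers only
    single_source: dict[str, str] = {
        pep: next(iter(index.source_proteins(pep)))
        for pep, multi in index.multimapper.items() if not multi
    }
    antigen_peps: dict[str, set[str]] = defaultdict(set)
    for pep, pid in single_source.items():
        antigen_peps[pid].add(pep)

    curated: dict[str, CuratedCandidate] = {}
    for row in rows:
        if row.level != "antigen" or not row.exclusive:
            continue
        candidates = antigen_peps.get(row.item_id, set())
        if hla_class == "II":
            candidates = {p for p in candidates
                          if config.classII_len_min <= len(p) <= config.classII_len_max}
        evidence: dict[str, set[str]] = defaultdict(set)
        for sid in sorted(row.tumor_samples & tumor_ids):
            present = peptidome.peptides(sid, hla_class) & candidates
            if hla_class == "I":
                if annotations is None or sid not in annotations:
                    raise MissingReferenceError(
                        f"no binder annotation for tumor sample {sid!r}")
                present = {p for p in present if annotations[sid].binds_sample(p)}
            for pep in present:
                evidence[pep].add(sid)
        positive = set().union(*evidence.values()) if evidence else set()
        if len(positive) >= config.min_tumor_positives:
            curated[row.item_id] = CuratedCandidate(
                antigen=row.item_id, hla_class=hla_class,
                evidence={p: frozenset(s) for p, s in sorted(evidence.items())},
                tumor_samples=frozenset(positive),
                tumor_frequency=(len(positive) / n_tumor_samples
                                 if n_tumor_samples else 0.0),
            )
    return curated


@dataclass
class GradeOverlap:
    """WHO-grade sharing of curated items across the tumor cohort."""

    grades_per_item: dict[str, frozenset[str]]
    all_grades: list[str] = field(default_factory=list)
    pairwise: dict[frozenset, list[str]] = field(default_factory=dict)
    single: dict[str, list[str]] = field(default_factory=dict)


def grade_overlap(item_tumor_samples: Mapping[str, Iterable[str]],
                  samples: Sequence[Sample]) -> GradeOverlap:
    """Partition items by the set of WHO grades they are positive in."""
    grade_of = {s.sample_id: s.who_grade for s in samples}
    grades_per_item: dict[str, frozenset[str]] = {}
    for item, sids in item_tumor_samples.items():
        grades = set()
        for sid in sids:
            g = grade_of.get(sid)
            if g is None:
                raise ValidationError(
                    f"tumor sample {sid!r} positive for {item!r} lacks a WHO grade")
            grades.add(g)
        grades_per_item[item] = frozenset(grades)

    result = GradeOverlap(grades_per_item=grades_per_item)
    all3 = frozenset({"I", "II", "III"})
    for item in sorted(grades_per_item):
        g = grades_per_item[item]
        if g == all3:
            result.all_grades.append(item)
        elif len(g) == 2:
            result.pairwise.setdefault(g, []).append(item)
        elif len(g) == 1:
            result.single.setdefault(next(iter(g)), []).append(item)
    return result


def cross_reference_targets(antigen_rows: Iterable[ProfilingRow],
                            peptide_rows: Iterable[ProfilingRow],
                            index: ProteinIndex,
                            target_list: set[str],
                            config: PipelineConfig) -> pd.DataFrame:
    """Cross-reference known CTA/TAA against the profiled dataset.

    Antigens identified exclusively on benign samples are omitted. Frequency
    columns retain multi-mapping peptides (they contribute to positivity
    counts), but the "represented by tumor-exclusive peptides" column
    considers single mappers only.
    """
    exclusive_single_peps: dict[str, set[str]] = defaultdict(set)
    for prow in peptide_rows:
        if (prow.exclusive and prow.n_tumor >= config.min_tumor_positives
                and not index.multimapper.get(prow.item_id, True)):
            for pid in index.source_proteins(prow.item_id):
                exclusive_single_peps[pid].add(prow.item_id)

    records = []
    for row in antigen_rows:
        if row.item_id not in target_list:
            continue
        if row.n_tumor == 0 and row.n_dura == 0:
            continue  # identified exclusively on benign samples
        peps = sorted(exclusive_single_peps.get(row.item_id, set()))
        records.append({
            "antigen": row.item_id,
            "hla_class": row.hla_class,
            "n_tumor": row.n_tumor,
            "n_dura": row.n_dura,
            "n_benign_cns": row.n_benign_cns,
            "n_benign_noncns": row.n_benign_noncns,
            "tumor_frequency": row.tumor_frequency,
            "exclusive_representation": bool(peps),
            "n_exclusive_peptides": len(peps),
        })
    return pd.DataFrame.from_records(
        records, columns=["antigen", "hla_class", "n_tumor", "n_dura",
                          "n_benign_cns", "n_benign_noncns", "tumor_frequency",
                          "exclusive_representation", "n_exclusive_peptides"]
    ).sort_values("antigen").reset_index(drop=True)


def rows_to_frame(rows: Iterable[ProfilingRow]) -> pd.DataFrame:
    """Flatten profiling rows for TSV export (waterfall-plot data)."""
    return pd.DataFrame.from_records([{
        "item_id": r.item_id, "level": r.level, "hla_class": r.hla_class,
        "n_tumor": r.n_tumor, "n_dura": r.n_dura,
        "n_benign_cns": r.n_benign_cns, "n_benign_noncns": r.n_benign_noncns,
        "tumor_frequency": round(r.tumor_frequency, 6),
        "exclusive": r.exclusive,
    } for r in rows])
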