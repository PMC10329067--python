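"""Binder annotation, eluate purity, length distributions and peptide yields.

A peptide is annotated as a binder for an allotype when its externally
supplied percentile rank is <= the rank threshold (default 2%) OR its
SYFPEITHI score is >= the score threshold (default 60%); both comparisons
are inclusive and the union of the two prediction routes is used. Scores
are consumed, never computed: the pipeline takes a (peptide, allotype) score
table as input. Pairs without a score row count as non-binders (conservative
for purity) and are tallied.

Eluate purity is the percentage of a sample's HLA class I peptides that are
binders for at least one allotype of that sample's own typing -- the
standard quality metric for immunoaffinity-purified ligandomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .config import PipelineConfig
from .errors import ValidationError

logger = logging.getLogger(__name__)

ScoreTable = Mapping[tuple[str, str], tuple[float, float]]


@dataclass
class BinderAnnotation:
    """Per-(peptide, allotype) binder verdicts for one sample's typing."""

    typing: tuple[str, ...]
    per_pair: dict[tuple[str, str], tuple[float, float, bool]]
    binder_peptides: frozenset[str]
    n_missing_scores: int

    def is_binder(self, peptide: str, allotype: str) -> bool:
        entry = self.per_pair.get((peptide, allotype))
        return entry is not None and entry[2]

    def binds_sample(self, peptide: str) -> bool:
        return peptide in self.binder_peptides


def annotate_binders(peptides: Iterable[str], typing: Sequence[str],
                     scores: ScoreTable,
                     config: PipelineConfig) -> BinderAnnotation:
    """Annotate each peptide against every allotype of one sample's typing."""
    typing = tuple(typing)
    if not typing:
        raise ValidationError("empty HLA typing: binder annotation undefined")
    per_pair: dict[tuple[str, str], tuple[float, float, bool]] = {}
    binders: set[str] = set()
    missing = 0
    for pep in sorted(set(peptides)):
        for allo in typing:
            entry = scores.get((pep, allo))
            if entry is None:
                missing += 1
                continue
            rank, syf = entry
            is_b = (rank <= config.rank_threshold
                    or syf >= config.syfpeithi_threshold)
            per_pair[(pep, allo)] = (rank, syf, is_b)
            if is_b:
                binders.add(pep)
    if missing:
        logger.debug("%d (peptide, allotype) pairs had no score row", missing)
    return BinderAnnotation(typing=typing, per_pair=per_pair,
                            binder_peptides=frozenset(binders),
                            n_missing_scores=missing)


def compute_purity(sample_peptides: Iterable[str],
                   annotation: BinderAnnotation) -> float:
    """Percent of class I peptides binding >= 1 allotype of the sample's typing."""
    peptides = set(sample_peptides)
    if not peptides:
        raise ValidationError("purity undefined for an empty peptide set")
    n_binders = sum(1 for p in peptides if annotation.binds_sample(p))
    return 100.0 * n_binders / len(peptides)


def length_histogram(peptides: Iterable[str]) -> tuple[dict[int, int], int]:
    """Length counts and modal length (ties break to the smaller length)."""
    peptides = set(peptides)
    if not peptides:
        raise ValidationError("length histogram undefined for an empty set")
    counts: dict[int, int] = {}
    for p in peptides:
        counts[len(p)] = counts.get(len(p), 0) + 1
    mode = min(sorted(counts), key=lambda k: (-counts[k], k))
    return dict(sorted(counts.items())), mode


def normalized_yield(per_replicate_unique_counts: Sequence[float],
                     tissue_mass_mg: float) -> float:
    """Mean unique peptides per technical replicate per mg of tissue."""
    if not len(per_replicate_unique_counts):
        raise ValidationError("at least one replicate count is required")
    if not tissue_mass_mg > 0:
        raise ValidationError("tissue mass must be strictly positive")
    return float(np.mean(per_replicate_unique_counts)) / tissue_mass_mg
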