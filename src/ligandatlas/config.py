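"""Pipeline configuration: every decision threshold in one validated record.

The defaults encode the published decision rules of comparative immunopeptidome
profiling: percentile rank <= 2% or SYFPEITHI >= 60% for binder annotation,
"maximum of one non-CNS-related tissue" and ">= 2 tumors" for exclusivity,
>= 8 AA / >= 5 patients for class II presentation hotspots, corrected
p <= 0.01 with mean-AUC fold change >= 4 (or <= 0.25) for LFQ modulation,
and the > 1% / threefold tetramer positivity rule.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, model_validator


class PipelineConfig(BaseModel):
    """All tunable cut-offs of the profiling pipeline.

    Attributes
    ----------
    rank_threshold:
        NetMHCpan-style percentile rank at or below which a peptide is
        annotated as a binder for an allotype (inclusive).
    syfpeithi_threshold:
        SYFPEITHI percent score at or above which a peptide is annotated
        as a binder (inclusive); binder status is the union of both routes.
    max_noncns_benign:
        Maximum number of positive non-CNS benign organs compatible with
        tumor exclusivity.
    min_tumor_positives:
        Minimum number of positive tumor samples required for exclusivity.
    hotspot_min_len:
        Minimum hotspot length in amino acids.
    hotspot_min_patients:
        Minimum number of distinct patients covering a hotspot position.
    hotspot_region_level:
        If True, the patient threshold applies to the region as a whole
        (distinct patients anywhere in the run) instead of per position.
    hotspot_exact_sequence:
        If True, benign exclusion removes only exclusive peptides whose exact
        sequence occurs in benign samples; the default forbids any positional
        overlap with benign-derived peptides of the same protein.
    q_threshold:
        BH-adjusted p-value cut-off for modulation calls.
    fc_up / fc_down:
        Mean-AUC fold-change gates for up-/down-modulation. ``fc_down``
        defaults to ``1 / fc_up``.
    tetramer_min_pct / tetramer_fold:
        Tetramer-positivity floor (percent of CD8+ cells, strict by default)
        and fold increase over the negative control (non-strict by default).
    classII_len_min / classII_len_max:
        Length window used when curating class II peptide evidence.
    min_replicates:
        Minimum LFQ replicates per side for a peptide to be evaluated.
    """

    rank_threshold: float = 2.0
    syfpeithi_threshold: float = 60.0
    max_noncns_benign: int = 1
    min_tumor_positives: int = 2
    hotspot_min_len: int = 8
    hotspot_min_patients: int = 5
    hotspot_region_level: bool = False
    hotspot_exact_sequence: bool = False
    q_threshold: float = 0.01
    fc_up: float = 4.0
    fc_down: Optional[float] = None
    tetramer_min_pct: float = 1.0
    tetramer_fold: float = 3.0
    tetramer_floor_strict: bool = True
    tetramer_fold_strict: bool = False
    classII_len_min: int = 12
    classII_len_max: int = 25
    min_replicates: int = 2
    test_method: Literal["welch", "ttest", "mannwhitney"] = "welch"
    rng_seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if self.fc_down is None:
            self.fc_down = 1.0 / self.fc_up
        positive = {
            "rank_threshold": self.rank_threshold,
            "syfpeithi_threshold": self.syfpeithi_threshold,
            "hotspot_min_len": self.hotspot_min_len,
            "hotspot_min_patients": self.hotspot_min_patients,
            "q_threshold": self.q_threshold,
            "fc_up": self.fc_up,
            "fc_down": self.fc_down,
            "tetramer_min_pct": self.tetramer_min_pct,
            "tetramer_fold": self.tetramer_fold,
            "classII_len_min": self.classII_len_min,
            "classII_len_max": self.classII_len_max,
            "min_tumor_positives": self.min_tumor_positives,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.max_noncns_benign < 0:
            raise ValueError("max_noncns_benign must be >= 0")
        if self.classII_len_min > self.classII_len_max:
            raise ValueError("classII_len_min must be <= classII_len_max")
        if self.min_replicates < 2:
            raise ValueError("min_replicates must be >= 2")
        return self


DEFAULT_CONFIG = PipelineConfig()
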