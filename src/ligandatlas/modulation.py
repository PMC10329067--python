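"""Label-free quantification: tumor-versus-dura modulation of HLA ligands.

For each patient with paired tumor and autologous tumor-free dura datasets,
per-peptide replicate AUCs are compared. The fold change is the ratio of
arithmetic means of raw AUCs (the published definition), while significance
is tested on log2-transformed replicate values with a two-sided Welch
unequal-variance t-test (standard LFQ practice; ordinary t and
Mann-Whitney are available via ``PipelineConfig.test_method``). Raw p-values
are Benjamini-Hochberg adjusted per patient pair and per HLA class; a
peptide is called up-modulated when q <= 0.01 and mean-AUC fold change >= 4,
down-modulated when q <= 0.01 and fold change <= 0.25, and unmodulated
otherwise. Peptides quantified on only one side (presence/absence, missing
not at random) are excluded from testing rather than imputed.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .errors import ValidationError
from .io_formats import ProteinIndex

logger = logging.getLogger(__name__)


@dataclass
class LfqPair:
    """Replicate AUCs of one patient's paired tumor / dura peptidomes."""

    patient_id: str
    tumor_aucs: dict[str, list[float]]
    dura_aucs: dict[str, list[float]]
    hla_class: str = "I"


@dataclass
class ModulationResult:
    peptide: str
    fc: float
    log2_fc: float
    p_raw: float
    q: float = float("nan")
    category: str = "unmodulated"


@dataclass
class PairSummary:
    patient_id: str
    n_evaluated: int
    n_excluded_one_sided: int
    n_excluded_replicates: int
    pct_up: float
    pct_down: float


def _check_aucs(values: Sequence[float], peptide: str, side: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size and (arr <= 0).any():
        raise ValidationError(
            f"non-positive AUC for peptide {peptide!r} on {side} side")
    return arr


def peptide_fold_change(tumor_aucs: Sequence[float],
                        dura_aucs: Sequence[float],
                        peptide: str = "?") -> tuple[float, float]:
    """Fold change of mean raw AUC (tumor / dura) and its log2."""
    t = _check_aucs(tumor_aucs, peptide, "tumor")
    d = _check_aucs(dura_aucs, peptide, "dura")
    if t.size == 0 or d.size == 0:
        raise ValidationError(f"peptide {peptide!r}: empty AUC side")
    fc = float(t.mean() / d.mean())
    return fc, float(np.log2(fc))


def welch_test_matrix(log_a: np.ndarray, log_b: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Welch t-test p-values with degenerate-row handling.

    Rows where both sides have zero variance get p = 1.0 for equal means and
    p = 0.0 otherwise (the test statistic is infinite).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(log_a, log_b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    var_a = log_a.var(axis=1, ddof=1)
    var_b = log_b.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    if degenerate.any():
        equal = np.isclose(log_a.mean(axis=1), log_b.mean(axis=1))
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    return p


def modulation_test(tumor_aucs: Sequence[float], dura_aucs: Sequence[float],
                    method: str = "welch") -> float:
    """Two-sided test of differential abundance on log2 AUCs."""
    t = _check_aucs(tumor_aucs, "?", "tumor")
    d = _check_aucs(dura_aucs, "?", "dura")
    if t.size < 2 or d.size < 2:
        raise ValidationError("modulation test requires >= 2 replicates per side")
    lt, ld = np.log2(t), np.log2(d)
    if method == "welch":
        return float(welch_test_matrix(lt[None, :], ld[None, :])[0])
    if method == "ttest":
        if lt.var(ddof=1) == 0 and ld.var(ddof=1) == 0:
            return 1.0 if np.isclose(lt.mean(), ld.mean()) else 0.0
        return float(stats.ttest_ind(lt, ld, equal_var=True).pvalue)
    if method == "mannwhitney":
        return float(stats.mannwhitneyu(lt, ld, alternative="two-sided").pvalue)
    raise ValidationError(f"unknown test method {method!r}")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving, capped at 1.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def classify_modulation(log2_fc: float, q: float,
                        config: PipelineConfig) -> str:
    """Apply the q-threshold and fold-change gates."""
    fc = 2.0 ** log2_fc
    if q <= config.q_threshold and fc >= config.fc_up:
        return "up"
    if q <= config.q_threshold and fc <= config.fc_down:
        return "down"
    return "unmodulated"


def analyze_pair(pair: LfqPair,
                 config: PipelineConfig) -> tuple[list[ModulationResult], PairSummary]:
    """Full per-patient analysis: test, BH adjust, classify, summarise."""
    shared = sorted(set(pair.tumor_aucs) & set(pair.dura_aucs))
    one_sided = (set(pair.tumor_aucs) | set(pair.dura_aucs)) - set(shared)
    evaluated: list[str] = []
    skipped_reps = 0
    tumor_rows, dura_rows = [], []
    for pep in shared:
        t = _check_aucs(pair.tumor_aucs[pep], pep, "tumor")
        d = _check_aucs(pair.dura_aucs[pep], pep, "dura")
        if t.size < config.min_replicates or d.size < config.min_replicates:
            skipped_reps += 1
            continue
        evaluated.append(pep)
        tumor_rows.append(t)
        dura_rows.append(d)
    if one_sided or skipped_reps:
        logger.info("patient %s: %d one-sided and %d under-replicated "
                    "peptides excluded", pair.patient_id, len(one_sided),
                    skipped_reps)
    if not evaluated:
        return [], PairSummary(pair.patient_id, 0, len(one_sided),
                               skipped_reps, 0.0, 0.0)

    rect = len({a.size for a in tumor_rows}) == 1 and len({a.size for a in dura_rows}) == 1
    if config.test_method == "welch" and rect:
        log_t = np.log2(np.vstack(tumor_rows))
        log_d = np.log2(np.vstack(dura_rows))
        p_raw = welch_test_matrix(log_t, log_d)
        fcs = np.vstack(tumor_rows).mean(axis=1) / np.vstack(dura_rows).mean(axis=1)
    else:
        p_raw = np.array([modulation_test(t, d, config.test_method)
                          for t, d in zip(tumor_rows, dura_rows)])
        fcs = np.array([t.mean() / d.mean()
                        for t, d in zip(tumor_rows, dura_rows)])

    q = bh_adjust(p_raw)
    results = []
    n_up = n_down = 0
    for pep, fc, p, qq in zip(evaluated, fcs, p_raw, q):
        log2_fc = float(np.log2(fc))
        cat = classify_modulation(log2_fc, float(qq), config)
        n_up += cat == "up"
        n_down += cat == "down"
        results.append(ModulationResult(peptide=pep, fc=float(fc),
                                        log2_fc=log2_fc, p_raw=float(p),
                                        q=float(qq), category=cat))
    n = len(evaluated)
    summary = PairSummary(pair.patient_id, n, len(one_sided), skipped_reps,
                          100.0 * n_up / n, 100.0 * n_down / n)
    return results, summary


def read_lfq_table(path) -> list[LfqPair]:
    """Read lfq.tsv (patient_id, peptide, side, replicate, auc) into pairs."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"patient_id", "peptide", "side", "replicate", "auc"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"lfq table missing column(s): {sorted(missing)}")
    bad = set(df["side"]) - {"tumor", "dura"}
    if bad:
        raise ValidationError(f"unknown side value(s): {sorted(bad)}")
    pairs = []
    for pid, sub in df.groupby("patient_id", sort=True):
        tumor: dict[str, list[float]] = defaultdict(list)
        dura: dict[str, list[float]] = defaultdict(list)
        for _, row in sub.iterrows():
            target = tumor if row["side"] == "tumor" else dura
            target[str(row["peptide"])].append(float(row["auc"]))
        pairs.append(LfqPair(patient_id=str(pid), tumor_aucs=dict(tumor),
                             dura_aucs=dict(dura)))
    return pairs


def results_to_frame(results_by_patient: Mapping[str, list[ModulationResult]]) -> pd.DataFrame:
    rows = []
    for pid in sorted(results_by_patient):
        for r in results_by_patient[pid]:
            rows.append({"patient_id": pid, "peptide": r.peptide,
                         "log2_fc": round(r.log2_fc, 6),
                         "p_raw": r.p_raw, "q": r.q, "category": r.category})
    return pd.DataFrame.from_records(
        rows, columns=["patient_id", "peptide", "log2_fc", "p_raw", "q",
                       "category"])


def profile_modulated_antigens(results_by_patient: Mapping[str, list[ModulationResult]],
                               index: ProteinIndex) -> pd.DataFrame:
    """Antigens exclusively represented by up- or down-modulated peptides.

    Per patient, an antigen is direction-exclusive when at least one of its
    single-mapping peptides is called in that direction and none in the
    opposite one; the cross-patient frequency is the fraction of patient
    pairs in which this holds. Multi-mapping peptides are excluded from
    antigen attribution.
    """
    n_pairs = len(results_by_patient)
    up_patients: dict[str, set[str]] = defaultdict(set)
    down_patients: dict[str, set[str]] = defaultdict(set)
    for pid, results in results_by_patient.items():
        per_antigen: dict[str, set[str]] = defaultdict(set)
        for r in results:
            if r.category == "unmodulated":
                continue
            if index.multimapper.get(r.peptide, True):
                continue
            for antigen in index.source_proteins(r.peptide):
                per_antigen[antigen].add(r.category)
        for antigen, cats in per_antigen.items():
            if cats == {"up"}:
                up_patients[antigen].add(pid)
            elif cats == {"down"}:
                down_patients[antigen].add(pid)

    rows = []
    for direction, table in (("up", up_patients), ("down", down_patients)):
        for antigen in sorted(table):
            rows.append({"antigen": antigen, "direction": direction,
                         "n_patients": len(table[antigen]),
                         "frequency": len(table[antigen]) / n_pairs if n_pairs else 0.0})
    return pd.DataFrame.from_records(
        rows, columns=["antigen", "direction", "n_patients", "frequency"])
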