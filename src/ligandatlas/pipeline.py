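"""End-to-end orchestration: simulate -> map -> qc -> profile -> hotspots ->
modulate -> coverage -> saturation.

The pipeline writes every stage's inputs and outputs as TSV so each step is
also runnable in isolation from the command line. All randomness flows from
one seed; rerunning with the same seed reproduces every output byte for
byte.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import annotation as ann
from . import coverage as cov
from . import hotspots as hs
from . import io_formats as io
from . import modulation as mod
from . import profiling as prof
from .config import PipelineConfig
from .synthetic_data import CohortParams, generate_cohort, generate_cohort_lfq

logger = logging.getLogger(__name__)


def tumor_annotations(peptidome: io.Peptidome, samples, typing, scores,
                      config: PipelineConfig) -> dict[str, ann.BinderAnnotation]:
    """Binder annotation of each tumor sample's class I peptidome."""
    out = {}
    for s in samples:
        if s.tissue_class != "tumor" or s.sample_id not in typing:
            continue
        class1 = [a for a in typing[s.sample_id]
                  if a.split("*")[0] in ("A", "B", "C")]
        peps = peptidome.peptides(s.sample_id, "I")
        if not class1 or not peps:
            continue
        out[s.sample_id] = ann.annotate_binders(peps, class1, scores, config)
    return out


def mapped_class2_peptides(peptidome: io.Peptidome, samples, index,
                           sample_filter) -> list[hs.MappedPeptide]:
    """Single-mapping class II peptides of the selected samples, with the
    presenting sample sets attached."""
    presenters: dict[str, set[str]] = defaultdict(set)
    for s in samples:
        if not sample_filter(s):
            continue
        for pep in peptidome.peptides(s.sample_id, "II"):
            presenters[pep].add(s.sample_id)
    out = []
    for pep in sorted(presenters):
        hits = index.peptide_hits.get(pep)
        if not hits or index.multimapper.get(pep, False):
            continue
        pid, start, end = hits[0]
        out.append(hs.MappedPeptide(peptide=pep, protein_id=pid, start=start,
                                    end=end,
                                    samples=frozenset(presenters[pep])))
    return out


def run_pipeline(outdir: str | Path, seed: int,
                 params: Optional[CohortParams] = None,
                 config: Optional[PipelineConfig] = None) -> dict:
    """Run the full synthetic-cohort pipeline; returns summary metrics."""
    config = config or PipelineConfig(rng_seed=seed)
    outdir = Path(outdir)
    inputs = outdir / "inputs"
    results = outdir / "results"
    results.mkdir(parents=True, exist_ok=True)

    cohort = generate_cohort(params, seed=seed)
    paths = cohort.write(inputs)

    # read everything back through the documented formats
    peptidome, samples = io.read_peptide_table(paths["peptides"],
                                               paths["samples"])
    index = io.read_proteome_fasta(paths["proteome"])
    typing = io.read_hla_typing(paths["typing"])
    scores = io.read_prediction_scores(paths["scores"])
    freqs = io.read_allele_frequencies(paths["freqs"])
    targets = io.read_target_list(paths["targets"])

    all_peps = peptidome.all_peptides("I") | peptidome.all_peptides("II")
    io.map_peptides(all_peps, index)
    io.write_hits_table(index, results / "hits.tsv")

    # ---- QC --------------------------------------------------------------
    annotations = tumor_annotations(peptidome, samples, typing, scores, config)
    qc_rows = []
    for s in samples:
        for cls in ("I", "II"):
            peps = peptidome.peptides(s.sample_id, cls)
            if not peps:
                continue
            hist, mode = ann.length_histogram(peps)
            purity = ""
            if cls == "I" and s.sample_id in annotations:
                purity = f"{ann.compute_purity(peps, annotations[s.sample_id]):.2f}"
            yld = ""
            if s.tissue_mass_mg and s.n_replicates:
                yld = f"{ann.normalized_yield([len(peps) / s.n_replicates], s.tissue_mass_mg):.4f}"
            qc_rows.append({"sample_id": s.sample_id, "hla_class": cls,
                            "n_peptides": len(peps), "modal_length": mode,
                            "purity_pct": purity, "yield_per_rep_per_mg": yld})
    qc = pd.DataFrame(qc_rows)
    io.write_results_table(qc, results / "qc.tsv")

    # ---- comparative profiling ------------------------------------------
    curated = {}
    profile_rows = {}
    for cls in ("I", "II"):
        arows = prof.flag_exclusive(
            prof.positivity_counts(peptidome, samples, index, "antigen", cls),
            config)
        prows = prof.flag_exclusive(
            prof.positivity_counts(peptidome, samples, index, "peptide", cls),
            config)
        profile_rows[cls] = (arows, prows)
        curated[cls] = prof.curate_candidates(
            arows, peptidome, samples, index,
            annotations if cls == "I" else None, config, cls)
        io.write_results_table(prof.rows_to_frame(arows),
                               results / f"profile_antigen_class{cls}.tsv")
        io.write_results_table(prof.rows_to_frame(prows),
                               results / f"profile_peptide_class{cls}.tsv")
        curated_df = pd.DataFrame(
            [{"antigen": c.antigen, "n_tumor": len(c.tumor_samples),
              "tumor_frequency": round(c.tumor_frequency, 6),
              "n_evidence_peptides": len(c.evidence)}
             for c in curated[cls].values()])
        io.write_results_table(curated_df,
                               results / f"curated_antigens_class{cls}.tsv")

    grade = prof.grade_overlap(
        {a: c.tumor_samples for a, c in curated["I"].items()}, samples)
    xref = prof.cross_reference_targets(profile_rows["I"][0],
                                        profile_rows["I"][1], index, targets,
                                        config)
    io.write_results_table(xref, results / "target_crossref_classI.tsv")

    # ---- class II hotspots ----------------------------------------------
    prows2 = prof.flag_exclusive(profile_rows["II"][1], config,
                                 min_tumor_positives=1)
    exclusive_seqs = {r.item_id for r in prows2 if r.exclusive}
    tumor_mapped = [p for p in mapped_class2_peptides(
        peptidome, samples, index, lambda s: s.tissue_class == "tumor")
        if p.peptide in exclusive_seqs]
    benign_mapped = mapped_class2_peptides(
        peptidome, samples, index, lambda s: s.tissue_class != "tumor")
    spots = hs.detect_hotspots(tumor_mapped, benign_mapped, index, config)
    spots_df = pd.DataFrame(
        [{"protein_id": h.protein_id, "start": h.start, "end": h.end,
          "length": h.length,
          "min_patients": min(h.patients_per_position),
          "n_peptides": len(h.supporting_peptides)} for h in spots])
    io.write_results_table(spots_df, results / "hotspots_classII.tsv")

    # ---- LFQ modulation --------------------------------------------------
    lfq_df, lfq_truth = generate_cohort_lfq(cohort, seed=seed + 1)
    lfq_path = inputs / "lfq.tsv"
    lfq_df.to_csv(lfq_path, sep="\t", index=False, float_format="%.6f")
    pairs = mod.read_lfq_table(lfq_path)
    results_by_patient = {}
    summaries = []
    for pair in pairs:
        res, summary = mod.analyze_pair(pair, config)
        results_by_patient[pair.patient_id] = res
        summaries.append(summary)
    io.write_results_table(mod.results_to_frame(results_by_patient),
                           results / "modulation_classI.tsv")
    mod_antigens = mod.profile_modulated_antigens(results_by_patient, index)
    io.write_results_table(mod_antigens, results / "modulated_antigens.tsv")

    # ---- population coverage and saturation ------------------------------
    cohort_allotypes = sorted({a for t in typing.values() for a in t
                               if a.split("*")[0] in ("A", "B", "C")})
    covres = cov.population_coverage(freqs, cohort_allotypes, "world")
    exclusive_pep_allos = []
    for pep in sorted({p for c in curated["I"].values() for p in c.evidence}):
        restr = sorted({allo for (pp, allo), (rank, syf) in scores.items()
                        if pp == pep and (rank <= config.rank_threshold
                                          or syf >= config.syfpeithi_threshold)})
        exclusive_pep_allos.append((pep, restr))
    expected_matches = cov.expected_matching_items(exclusive_pep_allos, freqs,
                                                   "world")
    antigen_sets = {
        s.sample_id: {pid for pep in peptidome.peptides(s.sample_id, "I")
                      for pid in index.source_proteins(pep)}
        for s in samples if s.tissue_class == "tumor"}
    sat = cov.saturation_estimate(antigen_sets, n_orderings=200, seed=seed + 2)

    # ---- summary ---------------------------------------------------------
    tumor_counts = sorted(
        len(peptidome.peptides(s.sample_id, "I"))
        for s in samples if s.tissue_class == "tumor")
    purities = [float(r["purity_pct"]) for r in qc_rows
                if r["hla_class"] == "I" and r["purity_pct"]]
    summary = {
        "seed": seed,
        "n_tumor_samples": sum(s.tissue_class == "tumor" for s in samples),
        "n_exclusive_antigens_classI": len(curated["I"]),
        "n_exclusive_antigens_classII": len(curated["II"]),
        "n_hotspots_classII": len(spots),
        "n_all_grade_antigens_classI": len(grade.all_grades),
        "median_classI_peptides_per_tumor": float(np.median(tumor_counts)),
        "mean_purity_pct": float(np.mean(purities)) if purities else None,
        "pct_up_modulated_mean": float(np.mean([s.pct_up for s in summaries])),
        "pct_down_modulated_mean": float(np.mean([s.pct_down for s in summaries])),
        "coverage_at_least_1_pct": 100.0 * covres.p_at_least(1),
        "coverage_at_least_3_pct": 100.0 * covres.p_at_least(3),
        "expected_matching_peptides_per_patient": expected_matches,
        "saturation_attained_fraction": sat.attained_fraction,
    }
    (results / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n")
    return summary
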