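"""Synthetic immunopeptidome cohorts with planted ground truth.

The generator emulates the structure of a comparative HLA ligandome study:
a cohort of tumor peptidomes (default 33, WHO grades in 22/9/2 proportion),
autologous tumor-free dura (default 9), and a benign multi-organ database
(default 12 organs, two of them CNS-related, some with several donors so
organ-level counting is exercised). Peptides are exact substrings of a
random proteome; class I lengths follow a categorical distribution with a
clear mode at nine residues, class II peptides are 12-25-mers peaked at
13-18.

Planted truth covers every pipeline stage:

* tumor-exclusive antigens presented by >= 2 tumors with single-mapping
  binder evidence (a subset additionally on exactly one non-CNS organ, the
  allowed boundary);
* decoys that must NOT be called: antigens on exactly two non-CNS organs,
  antigens in exactly one tumor, antigens whose entire evidence multi-maps
  to two proteins, class I antigens without binding motifs, and class II
  antigens represented only by sub-window-length peptides;
* class II presentation hotspots emitted as nested length variants around a
  core region in >= 5 patients, plus 4-patient and benign-overlap hotspot
  decoys;
* paired LFQ abundances with log-normal replicate noise and planted fold
  changes.

Background antigens are forced into at least two benign organs (every organ
donor presents the full repertoire) so that no background peptide can
satisfy the exclusivity rule by chance. Every generated peptide is checked
to occur exactly once in the proteome (designated multi-mapper decoys:
exactly twice); colliding repertoire peptides are redrawn, which keeps
planted truth exactly recoverable. A single seed fans out to independent
sub-streams (proteome, repertoires, presence, scores, typing).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .coverage import AlleleFrequencyTable
from .errors import ValidationError
from .io_formats import (ProteinIndex, Sample, map_peptides,
                         write_proteome_fasta)

logger = logging.getLogger(__name__)

AA = "ACDEFGHIKLMNPQRSTVWY"

CLASS1_LENGTHS = np.array([8, 9, 10, 11, 12])
CLASS1_WEIGHTS = np.array([0.10, 0.55, 0.20, 0.10, 0.05])
CLASS2_LENGTHS = np.arange(12, 26)
_w2 = np.array([2, 6, 8, 8, 7, 6, 5, 3, 2, 1.5, 1, 1, 0.8, 0.5])
CLASS2_WEIGHTS = _w2 / _w2.sum()

# class I allele pool with world-scale frequencies (per-locus sums < 1; the
# remainder is unlisted-allele mass). Typings are drawn within the pool.
ALLELE_POOL: dict[str, tuple[tuple[str, float], ...]] = {
    "A": (("A*02:01", 0.2751), ("A*01:01", 0.1521), ("A*03:01", 0.1280),
          ("A*24:02", 0.0981), ("A*11:01", 0.0601), ("A*26:01", 0.0390)),
    "B": (("B*07:02", 0.1201), ("B*08:01", 0.0920), ("B*44:02", 0.0801),
          ("B*35:01", 0.0650), ("B*15:01", 0.0521), ("B*51:01", 0.0490)),
    "C": (("C*07:01", 0.1490), ("C*07:02", 0.1410), ("C*04:01", 0.1180),
          ("C*06:02", 0.0870)),
    "DRB1": (("DRB1*15:01", 0.1410), ("DRB1*07:01", 0.1290),
             ("DRB1*03:01", 0.1090), ("DRB1*04:01", 0.0880)),
}

ORGAN_LOCATIONS = ("convexity", "falx", "skull base", "tentorium", "sphenoid")


@dataclass(frozen=True)
class CohortParams:
    """Study conditions of the synthetic cohort."""

    n_tumor: int = 33
    n_dura: int = 9
    # (organ, cns_related, n_donors); two CNS organs, two multi-donor organs
    benign_organs: tuple[tuple[str, bool, int], ...] = (
        ("liver", False, 2), ("skin", False, 2), ("lung", False, 1),
        ("kidney", False, 1), ("colon", False, 1), ("spleen", False, 1),
        ("heart", False, 1), ("muscle", False, 1), ("ovary", False, 1),
        ("thymus", False, 1), ("brain", True, 1), ("cerebellum", True, 1),
    )
    n_background: int = 300
    n_planted_exclusive: int = 20
    n_planted_boundary_noncns: int = 5
    n_decoy_two_noncns: int = 5
    n_decoy_single_tumor: int = 5
    n_decoy_multimapper: int = 3
    n_decoy_nonbinder: int = 3
    n_decoy_short_classII: int = 3
    n_benign_only: int = 3
    n_planted_hotspots: int = 6
    n_decoy_hotspot_few_patients: int = 3
    n_decoy_hotspot_benign: int = 3
    protein_length: tuple[int, int] = (200, 400)
    background_tumor_rate: tuple[float, float] = (0.05, 0.40)
    background_dura_rate: float = 0.25
    background_benign_extra: float = 1.2  # Poisson mean on top of 2 organs
    binder_prob: float = 0.85
    class1_repertoire: tuple[int, int] = (2, 4)  # inclusive bounds
    class2_repertoire: tuple[int, int] = (2, 3)
    n_replicates: int = 3


@dataclass
class SyntheticTruth:
    """Everything that was planted, serialised alongside the data."""

    planted_exclusive_antigens: set[str]
    # per HLA class, every antigen that must survive curation: the planted
    # exclusive antigens plus (class II) the hotspot host proteins, which are
    # tumor-exclusive by construction
    expected_exclusive_antigens_by_class: dict[str, set[str]]
    planted_exclusive_peptides: set[str]
    planted_exclusive_peptides_by_class: dict[str, set[str]]
    planted_hotspots: list[tuple[str, int, int]]
    decoy_hotspots_few_patients: list[tuple[str, int, int]]
    decoy_hotspots_benign_overlap: list[tuple[str, int, int]]
    decoy_two_noncns: set[str]
    decoy_single_tumor: set[str]
    decoy_multimapper: set[str]
    decoy_nonbinder: set[str]
    decoy_short_classII: set[str]
    benign_only_antigens: set[str]
    planted_modulated: dict[str, float]
    generator_params: dict

    def to_json(self) -> str:
        def enc(v):
            if isinstance(v, set):
                return sorted(v)
            if isinstance(v, dict):
                return {k: enc(x) for k, x in sorted(v.items())}
            if isinstance(v, (list, tuple)):
                return [enc(x) for x in v]
            return v
        return json.dumps({f.name: enc(getattr(self, f.name))
                           for f in dataclasses.fields(self)}, indent=1,
                          sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        raw = json.loads(text)
        sets = {"planted_exclusive_antigens", "planted_exclusive_peptides",
                "decoy_two_noncns", "decoy_single_tumor", "decoy_multimapper",
                "decoy_nonbinder", "decoy_short_classII", "benign_only_antigens"}
        kwargs = {}
        for f in dataclasses.fields(cls):
            v = raw[f.name]
            if f.name in sets:
                v = set(v)
            elif f.name in ("planted_exclusive_peptides_by_class",
                            "expected_exclusive_antigens_by_class"):
                v = {k: set(x) for k, x in v.items()}
            elif f.name.endswith("hotspots") or "hotspot" in f.name:
                v = [tuple(x) for x in v]
            kwargs[f.name] = v
        return cls(**kwargs)


@dataclass
class SyntheticCohort:
    """In-memory synthetic cohort: inputs for every pipeline stage."""

    proteins: dict[str, str]
    samples: list[Sample]
    peptide_rows: pd.DataFrame  # peptide, sample_id, hla_class
    typing: dict[str, list[str]]
    scores: dict[tuple[str, str], tuple[float, float]]
    freqs: AlleleFrequencyTable
    targets: set[str]
    truth: SyntheticTruth
    params: CohortParams
    seed: int

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write all inputs as text files; deterministic byte-for-byte."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {name: out / fname for name, fname in [
            ("proteome", "proteome.fasta"), ("peptides", "peptides.tsv"),
            ("samples", "samples.tsv"), ("typing", "typing.tsv"),
            ("scores", "scores.tsv"), ("freqs", "freqs.tsv"),
            ("targets", "targets.txt"), ("truth", "truth.json")]}
        write_proteome_fasta(self.proteins, paths["proteome"])
        self.peptide_rows.sort_values(["sample_id", "hla_class", "peptide"]) \
            .to_csv(paths["peptides"], sep="\t", index=False)
        rows = []
        for s in self.samples:
            rows.append({"sample_id": s.sample_id, "tissue_class": s.tissue_class,
                         "organ": s.organ, "cns_related": s.cns_related,
                         "who_grade": s.who_grade or "", "sex": s.sex or "",
                         "location": s.location or "",
                         "tissue_mass_mg": ("" if s.tissue_mass_mg is None
                                            else f"{s.tissue_mass_mg:.1f}"),
                         "n_replicates": s.n_replicates or ""})
        pd.DataFrame(rows).to_csv(paths["samples"], sep="\t", index=False)
        with open(paths["typing"], "w") as fh:
            fh.write("sample_id\tlocus\tallotype\n")
            for sid in sorted(self.typing):
                for allo in self.typing[sid]:
                    fh.write(f"{sid}\t{allo.split('*')[0]}\t{allo}\n")
        with open(paths["scores"], "w") as fh:
            fh.write("peptide\tallotype\trank_percentile\tsyfpeithi_percent\n")
            for (pep, allo) in sorted(self.scores):
                rank, syf = self.scores[(pep, allo)]
                fh.write(f"{pep}\t{allo}\t{rank:.3f}\t{syf:.1f}\n")
        with open(paths["freqs"], "w") as fh:
            fh.write("locus\tallotype\tpopulation\tfrequency\n")
            for pop in self.freqs.populations():
                for locus in self.freqs.loci(pop):
                    for allo, f in sorted(self.freqs.freqs[pop][locus].items()):
                        fh.write(f"{locus}\t{allo}\t{pop}\t{f:.4f}\n")
        paths["targets"].write_text("".join(f"{t}\n" for t in sorted(self.targets)))
        paths["truth"].write_text(self.truth.to_json() + "\n")
        return paths


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def generate_proteome(n_proteins: int, length_range: tuple[int, int],
                      seed: int) -> dict[str, str]:
    """Random proteome of i.i.d. uniform residues; deterministic under seed."""
    if n_proteins < 1:
        raise ValidationError("n_proteins must be >= 1")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValidationError(f"invalid length range {length_range}")
    rng = np.random.default_rng(seed)
    proteins = {}
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        proteins[f"PROT{i + 1:04d}"] = _random_protein(rng, length)
    return proteins


def _grade_counts(n_tumor: int) -> list[str]:
    """WHO grades in the cohort's 22:9:2 proportion."""
    n1 = max(1, round(n_tumor * 22 / 33))
    n3 = max(1, round(n_tumor * 2 / 33)) if n_tumor >= 8 else 0
    n2 = n_tumor - n1 - n3
    return ["I"] * n1 + ["II"] * n2 + ["III"] * n3


def _draw_typing(rng: np.random.Generator) -> list[str]:
    typing = []
    for locus in ("A", "B", "C", "DRB1"):
        names = [a for a, _ in ALLELE_POOL[locus]]
        freqs = np.array([f for _, f in ALLELE_POOL[locus]])
        p = freqs / freqs.sum()
        typing.extend(rng.choice(names, size=2, p=p))
    return typing


def _pool_frequency_table() -> AlleleFrequencyTable:
    freqs = {"world": {locus: dict(entries)
                       for locus, entries in ALLELE_POOL.items()}}
    return AlleleFrequencyTable(freqs=freqs)


@dataclass
class _Plan:
    """Internal bookkeeping for one synthetic antigen."""

    antigen: str
    role: str
    peptides: dict[str, list[str]] = field(default_factory=dict)  # class -> peps
    tumor_samples: list[str] = field(default_factory=list)
    dura_samples: list[str] = field(default_factory=list)
    benign_organs: list[str] = field(default_factory=list)
    full_repertoire_in_tumors: bool = True


def generate_cohort(params: CohortParams | None = None,
                    seed: int = 0) -> SyntheticCohort:
    """Generate a full cohort with planted, exactly recoverable truth."""
    params = params or CohortParams()
    streams = np.random.SeedSequence(seed).spawn(5)
    rng_prot = np.random.default_rng(streams[0])
    rng_rep = np.random.default_rng(streams[1])
    rng_pres = np.random.default_rng(streams[2])
    rng_scores = np.random.default_rng(streams[3])
    rng_typing = np.random.default_rng(streams[4])

    # ---- samples -------------------------------------------------------
    grades = _grade_counts(params.n_tumor)
    tumors = [f"MNG{i + 1:03d}" for i in range(params.n_tumor)]
    duras = [f"DUR{i + 1:03d}" for i in range(params.n_dura)]
    samples: list[Sample] = []
    for sid, grade in zip(tumors, grades):
        samples.append(Sample(
            sample_id=sid, tissue_class="tumor", organ="meninges",
            cns_related=True, who_grade=grade,
            sex=str(rng_typing.choice(["F", "M"], p=[2 / 3, 1 / 3])),
            location=str(rng_typing.choice(ORGAN_LOCATIONS)),
            tissue_mass_mg=float(np.round(rng_typing.uniform(80, 1200), 1)),
            n_replicates=params.n_replicates))
    for sid in duras:
        samples.append(Sample(sample_id=sid, tissue_class="dura", organ="dura",
                              cns_related=True,
                              tissue_mass_mg=float(np.round(
                                  rng_typing.uniform(50, 600), 1)),
                              n_replicates=params.n_replicates))
    organ_donors: dict[str, list[str]] = {}
    for organ, cns, n_donors in params.benign_organs:
        donors = []
        for d in range(n_donors):
            sid = f"BEN_{organ}_{d + 1}"
            donors.append(sid)
            samples.append(Sample(sample_id=sid, tissue_class="benign",
                                  organ=organ, cns_related=cns,
                                  n_replicates=params.n_replicates))
        organ_donors[organ] = donors
    noncns_organs = [o for o, cns, _ in params.benign_organs if not cns]
    all_organs = [o for o, _, _ in params.benign_organs]

    typing = {sid: _draw_typing(rng_typing) for sid in tumors}

    # ---- proteome & antigen plans --------------------------------------
    n_hot = (params.n_planted_hotspots + params.n_decoy_hotspot_few_patients
             + params.n_decoy_hotspot_benign)
    n_proteins = (params.n_planted_exclusive + params.n_background
                  + params.n_decoy_two_noncns + params.n_decoy_single_tumor
                  + 2 * params.n_decoy_multimapper + params.n_decoy_nonbinder
                  + params.n_decoy_short_classII + n_hot)
    proteins = generate_proteome(
        n_proteins, params.protein_length,
        int(rng_prot.integers(0, 2 ** 31 - 1)))
    pids = sorted(proteins)
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        out = pids[cursor:cursor + n]
        cursor += n
        return out

    planted_ids = take(params.n_planted_exclusive)
    background_ids = take(params.n_background)
    two_noncns_ids = take(params.n_decoy_two_noncns)
    single_tumor_ids = take(params.n_decoy_single_tumor)
    multi_a = take(params.n_decoy_multimapper)
    multi_b = take(params.n_decoy_multimapper)
    nonbinder_ids = take(params.n_decoy_nonbinder)
    short2_ids = take(params.n_decoy_short_classII)
    hot_planted_ids = take(params.n_planted_hotspots)
    hot_few_ids = take(params.n_decoy_hotspot_few_patients)
    hot_benign_ids = take(params.n_decoy_hotspot_benign)

    home: dict[str, tuple[str, str]] = {}  # peptide -> (antigen, hla_class)
    exempt_multimappers: set[str] = set()

    def draw_pep(pid: str, hla_class: str,
                 length: Optional[int] = None) -> str:
        seq = proteins[pid]
        if length is None:
            if hla_class == "I":
                length = int(rng_rep.choice(CLASS1_LENGTHS, p=CLASS1_WEIGHTS))
            else:
                length = int(rng_rep.choice(CLASS2_LENGTHS, p=CLASS2_WEIGHTS))
        start = int(rng_rep.integers(0, len(seq) - length + 1))
        return seq[start:start + length]

    plans: dict[str, _Plan] = {}

    def new_plan(pid: str, role: str, classes: Sequence[str],
                 lengths: Optional[dict[str, list[int]]] = None) -> _Plan:
        plan = _Plan(antigen=pid, role=role)
        for cls in classes:
            lo, hi = (params.class1_repertoire if cls == "I"
                      else params.class2_repertoire)
            k = int(rng_rep.integers(lo, hi + 1))
            peps = []
            for j in range(k):
                length = lengths[cls][j % len(lengths[cls])] if lengths else None
                peps.append(draw_pep(pid, cls, length))
            plan.peptides[cls] = peps
        plans[pid] = plan
        return plan

    for pid in planted_ids:
        new_plan(pid, "planted", ("I", "II"))
    for pid in background_ids:
        new_plan(pid, "background", ("I", "II"))
    for pid in two_noncns_ids:
        new_plan(pid, "decoy_two_noncns", ("I", "II"))
    for pid in single_tumor_ids:
        new_plan(pid, "decoy_single_tumor", ("I", "II"))
    for pid in nonbinder_ids:
        new_plan(pid, "decoy_nonbinder", ("I",))
    for pid in short2_ids:
        new_plan(pid, "decoy_short_classII", ("II",),
                 lengths={"II": [int(rng_rep.integers(9, 12))]})

    # multi-mapper decoys: identical peptides copied into a partner protein
    for pid_a, pid_b in zip(multi_a, multi_b):
        plan = _Plan(antigen=pid_a, role="decoy_multimapper")
        pep1 = draw_pep(pid_a, "I", 9)
        pep2 = draw_pep(pid_a, "II", 15)
        seq_b = list(proteins[pid_b])
        pos1 = int(rng_rep.integers(0, 40))
        pos2 = int(rng_rep.integers(80, len(seq_b) - 20))
        seq_b[pos1:pos1 + 9] = pep1
        seq_b[pos2:pos2 + 15] = pep2
        proteins[pid_b] = "".join(seq_b)
        plan.peptides = {"I": [pep1], "II": [pep2]}
        plans[pid_a] = plan
        exempt_multimappers |= {pep1, pep2}

    # ---- hotspot plants -------------------------------------------------
    def plant_hotspot(pid: str, n_pat: int,
                      benign_overlap: bool) -> tuple[tuple[str, int, int],
                                                     list[tuple[str, str]],
                                                     Optional[str]]:
        seq = proteins[pid]
        core_len = int(rng_rep.integers(10, 15))
        core_s = int(rng_rep.integers(9, len(seq) - core_len - 8))
        core_e = core_s + core_len - 1
        patients = [str(x) for x in rng_pres.choice(tumors, size=n_pat,
                                                    replace=False)]
        k = max(1, n_pat - 4)
        min_flank = max(1, 12 - core_len)
        variants: list[tuple[str, str]] = []
        for i, patient in enumerate(patients):
            left_forced = i < k
            right_forced = k <= i < 2 * k
            a = 0 if left_forced else int(
                rng_rep.integers(min_flank if right_forced else 1, 6))
            b = 0 if right_forced else int(
                rng_rep.integers(min_flank if left_forced else 1, 6))
            s, e = core_s - a, core_e + b
            variants.append((seq[s - 1:e], patient))
        benign_pep = seq[core_s - 2:core_e + 1] if benign_overlap else None
        return (pid, core_s, core_e), variants, benign_pep

    hotspot_truth: list[tuple[str, int, int]] = []
    hotspot_few_truth: list[tuple[str, int, int]] = []
    hotspot_benign_truth: list[tuple[str, int, int]] = []
    hotspot_variants: list[tuple[str, str]] = []  # (peptide, patient)
    hotspot_benign_peps: list[str] = []
    for pid in hot_planted_ids:
        spot, variants, _ = plant_hotspot(pid, int(rng_pres.integers(5, 8)), False)
        hotspot_truth.append(spot)
        hotspot_variants.extend(variants)
    for pid in hot_few_ids:
        spot, variants, _ = plant_hotspot(pid, 4, False)
        hotspot_few_truth.append(spot)
        hotspot_variants.extend(variants)
    for pid in hot_benign_ids:
        spot, variants, benign_pep = plant_hotspot(pid, 5, True)
        hotspot_benign_truth.append(spot)
        hotspot_variants.extend(variants)
        hotspot_benign_peps.append(benign_pep)

    # ---- uniqueness enforcement ----------------------------------------
    for pid, plan in plans.items():
        for cls, peps in plan.peptides.items():
            for pep in peps:
                home.setdefault(pep, (pid, cls))

    for attempt in range(10):
        every = (set(home) | exempt_multimappers
                 | {v for v, _ in hotspot_variants} | set(hotspot_benign_peps))
        idx = map_peptides(every, ProteinIndex(proteins=dict(proteins)))
        conflicts = []
        for pep in sorted(every):
            n_hits = len(idx.peptide_hits.get(pep, []))
            if pep in exempt_multimappers:
                if len(idx.source_proteins(pep)) < 2:
                    raise ValidationError("multi-mapper decoy lost its second site")
                continue
            if n_hits != 1:
                conflicts.append(pep)
        if not conflicts:
            break
        for pep in conflicts:
            if pep not in home:
                raise ValidationError(
                    f"hotspot-derived peptide {pep!r} is not unique in the "
                    "proteome; re-seed the generator")
            pid, cls = home.pop(pep)
            plan = plans[pid]
            fresh = draw_pep(pid, cls, len(pep))
            plan.peptides[cls] = [fresh if p == pep else p
                                  for p in plan.peptides[cls]]
            home[fresh] = (pid, cls)
    else:  # pragma: no cover
        raise ValidationError("could not resolve peptide collisions in 10 rounds")

    # ---- presence assignment -------------------------------------------
    def pick_tumors(n: int) -> list[str]:
        return sorted(str(x) for x in rng_pres.choice(tumors, size=n,
                                                      replace=False))

    boundary = set(planted_ids[:params.n_planted_boundary_noncns])
    for pid in planted_ids:
        plan = plans[pid]
        plan.tumor_samples = pick_tumors(int(rng_pres.integers(2, 9)))
        if pid in boundary:
            plan.benign_organs = [str(rng_pres.choice(noncns_organs))]
    benign_only = set(background_ids[-params.n_benign_only:])
    for pid in background_ids:
        plan = plans[pid]
        plan.full_repertoire_in_tumors = False
        rate = rng_pres.uniform(*params.background_tumor_rate)
        plan.tumor_samples = [t for t in tumors if rng_pres.random() < rate]
        n_org = min(len(all_organs), 2 + int(rng_pres.poisson(
            params.background_benign_extra)))
        plan.benign_organs = sorted(
            str(x) for x in rng_pres.choice(all_organs, size=n_org,
                                            replace=False))
        plan.dura_samples = [d for d in duras
                             if rng_pres.random() < params.background_dura_rate]
        if pid in benign_only:
            plan.tumor_samples = []
            plan.dura_samples = []
    for pid in two_noncns_ids:
        plan = plans[pid]
        plan.tumor_samples = pick_tumors(int(rng_pres.integers(2, 6)))
        plan.benign_organs = sorted(
            str(x) for x in rng_pres.choice(noncns_organs, size=2,
                                            replace=False))
    for pid in single_tumor_ids:
        plans[pid].tumor_samples = pick_tumors(1)
    for pid in multi_a + nonbinder_ids + short2_ids:
        plans[pid].tumor_samples = pick_tumors(int(rng_pres.integers(2, 5)))

    # ---- emit peptide rows ---------------------------------------------
    rows: list[tuple[str, str, str]] = []
    pep_tumor: dict[str, set[str]] = defaultdict(set)
    pep_dura: dict[str, set[str]] = defaultdict(set)
    pep_cns: dict[str, set[str]] = defaultdict(set)
    pep_noncns: dict[str, set[str]] = defaultdict(set)
    pep_class: dict[str, str] = {}

    def emit(pep: str, sid: str, cls: str, organ: Optional[str] = None,
             cns: bool = False, tissue: str = "tumor") -> None:
        rows.append((pep, sid, cls))
        pep_class[pep] = cls
        if tissue == "tumor":
            pep_tumor[pep].add(sid)
        elif tissue == "dura":
            pep_dura[pep].add(sid)
        elif cns:
            pep_cns[pep].add(organ)
        else:
            pep_noncns[pep].add(organ)

    organ_cns = {o: cns for o, cns, _ in params.benign_organs}
    for pid in sorted(plans):
        plan = plans[pid]
        for cls, peps in sorted(plan.peptides.items()):
            for sid in plan.tumor_samples:
                if plan.full_repertoire_in_tumors:
                    chosen = peps
                else:
                    chosen = [p for p in peps if rng_pres.random() < 0.7]
                    if not chosen:
                        chosen = [peps[int(rng_pres.integers(0, len(peps)))]]
                for pep in chosen:
                    emit(pep, sid, cls, tissue="tumor")
            for sid in plan.dura_samples:
                for pep in peps:
                    emit(pep, sid, cls, tissue="dura")
            for organ in plan.benign_organs:
                for donor in organ_donors[organ]:
                    for pep in peps:
                        emit(pep, donor, cls, organ=organ,
                             cns=organ_cns[organ], tissue="benign")
    for pep, patient in hotspot_variants:
        emit(pep, patient, "II", tissue="tumor")
    for pep in hotspot_benign_peps:
        organ = str(rng_pres.choice(noncns_organs))
        for donor in organ_donors[organ]:
            emit(pep, donor, "II", organ=organ, cns=False, tissue="benign")

    # ---- prediction scores ---------------------------------------------
    scores: dict[tuple[str, str], tuple[float, float]] = {}

    def add_score(pep: str, allo: str, rank: float, syf: float) -> None:
        key = (pep, allo)
        prev = scores.get(key)
        if prev is None or rank < prev[0]:
            scores[key] = (round(rank, 3), round(syf, 1))

    always_binder_roles = {"planted", "decoy_two_noncns", "decoy_single_tumor",
                           "decoy_multimapper"}
    for pid in sorted(plans):
        plan = plans[pid]
        for pep in plan.peptides.get("I", []):
            for sid in plan.tumor_samples:
                class1 = [a for a in typing[sid]
                          if a.split("*")[0] in ("A", "B", "C")]
                if plan.role == "decoy_nonbinder":
                    is_binder = False
                elif plan.role in always_binder_roles:
                    is_binder = True
                else:
                    is_binder = rng_scores.random() < params.binder_prob
                if is_binder:
                    allo = str(rng_scores.choice(class1))
                    add_score(pep, allo, rng_scores.uniform(0.05, 2.0),
                              rng_scores.uniform(60, 95))
                elif plan.role == "decoy_nonbinder":
                    for allo in class1:
                        key = (pep, allo)
                        if key not in scores:
                            scores[key] = (round(rng_scores.uniform(5, 90), 3),
                                           round(rng_scores.uniform(0, 40), 1))

    # ---- truth ----------------------------------------------------------
    exclusive_peps: set[str] = set()
    by_class: dict[str, set[str]] = {"I": set(), "II": set()}
    for pep in pep_class:
        if (len(pep_tumor.get(pep, ())) >= 2
                and not pep_dura.get(pep) and not pep_cns.get(pep)
                and len(pep_noncns.get(pep, ())) <= 1):
            exclusive_peps.add(pep)
            by_class[pep_class[pep]].add(pep)

    hotspot_hosts = set(hot_planted_ids) | set(hot_few_ids) | set(hot_benign_ids)
    truth = SyntheticTruth(
        planted_exclusive_antigens=set(planted_ids),
        expected_exclusive_antigens_by_class={
            "I": set(planted_ids),
            "II": set(planted_ids) | hotspot_hosts,
        },
        planted_exclusive_peptides=exclusive_peps,
        planted_exclusive_peptides_by_class=by_class,
        planted_hotspots=sorted(hotspot_truth),
        decoy_hotspots_few_patients=sorted(hotspot_few_truth),
        decoy_hotspots_benign_overlap=sorted(hotspot_benign_truth),
        decoy_two_noncns=set(two_noncns_ids),
        decoy_single_tumor=set(single_tumor_ids),
        decoy_multimapper=set(multi_a) | set(multi_b),
        decoy_nonbinder=set(nonbinder_ids),
        decoy_short_classII=set(short2_ids),
        benign_only_antigens=benign_only,
        planted_modulated={},
        # json round trip normalises tuples to lists so serialised truth
        # compares equal to the in-memory record
        generator_params=json.loads(json.dumps(
            {"seed": seed, **dataclasses.asdict(params)})),
    )

    targets = (set(planted_ids[:5]) | set(background_ids[:15])
               | set(list(benign_only)[:2]))
    frame = pd.DataFrame(sorted(set(rows)),
                         columns=["peptide", "sample_id", "hla_class"])
    return SyntheticCohort(proteins=proteins, samples=samples,
                           peptide_rows=frame, typing=typing, scores=scores,
                           freqs=_pool_frequency_table(), targets=targets,
                           truth=truth, params=params, seed=seed)


def generate_lfq(n_peptides: int = 1000, n_replicates: int = 3,
                 planted_fc: Mapping[str, float] | None = None,
                 cv: float = 0.1, seed: int = 0,
                 peptides: Sequence[str] | None = None,
                 patient_id: str = "P001") -> tuple[pd.DataFrame, dict[str, float]]:
    """Paired tumor/dura replicate AUCs with log-normal noise.

    Replicates are ``mean * exp(N(0, sigma))`` with
    ``sigma = sqrt(ln(1 + cv^2))`` so the linear-scale coefficient of
    variation equals ``cv``. Planted peptides get tumor mean = fc x dura
    mean; the returned truth maps each planted peptide to its true log2
    fold change.
    """
    if cv <= 0:
        raise ValidationError("cv must be positive")
    if n_replicates < 2:
        raise ValidationError("n_replicates must be >= 2")
    rng = np.random.default_rng(seed)
    if peptides is None:
        peps: list[str] = []
        seen = set()
        while len(peps) < n_peptides:
            p = "".join(rng.choice(list(AA), size=9))
            if p not in seen:
                seen.add(p)
                peps.append(p)
        peptides = peps
    else:
        peptides = list(peptides)
        n_peptides = len(peptides)
    planted_fc = dict(planted_fc or {})
    unknown = set(planted_fc) - set(peptides)
    if unknown:
        raise ValidationError(
            f"planted peptides absent from the peptide list: {sorted(unknown)[:5]}")

    sigma = float(np.sqrt(np.log1p(cv * cv)))
    rows = []
    truth = {}
    for pep in peptides:
        base = float(rng.lognormal(mean=np.log(1e6), sigma=1.0))
        fc = float(planted_fc.get(pep, 1.0))
        for side, mean in (("tumor", base * fc), ("dura", base)):
            noise = rng.normal(0.0, sigma, size=n_replicates)
            for r, eps in enumerate(noise, start=1):
                rows.append((patient_id, pep, side, r, mean * float(np.exp(eps))))
        if pep in planted_fc:
            truth[pep] = float(np.log2(fc))
    df = pd.DataFrame(rows, columns=["patient_id", "peptide", "side",
                                     "replicate", "auc"])
    return df, truth


def generate_cohort_lfq(cohort: SyntheticCohort, n_pairs: int = 5,
                        n_peptides: int = 400, n_planted_up: int = 20,
                        n_planted_down: int = 20, fc: float = 4.0,
                        cv: float = 0.1, seed: int = 0) -> tuple[pd.DataFrame,
                                                                 dict]:
    """LFQ tables for the first ``n_pairs`` tumor/dura patient pairs.

    Peptides are drawn from each tumor's class I peptidome so modulated
    peptides can be attributed to source antigens downstream.
    """
    rng = np.random.default_rng(seed)
    tumors = [s.sample_id for s in cohort.samples if s.tissue_class == "tumor"]
    frames = []
    truth: dict[str, dict[str, float]] = {}
    pep_col = cohort.peptide_rows
    for i in range(n_pairs):
        patient = tumors[i]
        pool = sorted(pep_col[(pep_col.sample_id == patient)
                              & (pep_col.hla_class == "I")]["peptide"])
        if len(pool) > n_peptides:
            pool = sorted(rng.choice(pool, size=n_peptides, replace=False))
        planted: dict[str, float] = {}
        chosen = list(rng.permutation(pool))
        for pep in chosen[:n_planted_up]:
            planted[pep] = fc
        for pep in chosen[n_planted_up:n_planted_up + n_planted_down]:
            planted[pep] = 1.0 / fc
        df, t = generate_lfq(n_replicates=cohort.params.n_replicates,
                             planted_fc=planted, cv=cv,
                             seed=int(rng.integers(0, 2 ** 31 - 1)),
                             peptides=pool, patient_id=patient)
        frames.append(df)
        truth[patient] = t
    return pd.concat(frames, ignore_index=True), truth
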