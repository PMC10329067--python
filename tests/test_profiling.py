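"""Comparative profiling: counting rules, exclusivity, curation, grades."""

import pytest

from ligandatlas import io_formats as io
from ligandatlas import profiling as prof
from ligandatlas.annotation import annotate_binders
from ligandatlas.config import PipelineConfig
from ligandatlas.errors import ValidationError
from ligandatlas.io_formats import Peptidome, Sample
from ligandatlas.pipeline import tumor_annotations
from ligandatlas.synthetic_data import generate_cohort

PEP_A = "CDEFGHIK"            # single mapper in P1 (class I)
PEP_10 = "KLMNPQRSTV"         # 10-mer in P1 (class II, below window)
PEP_15 = "ADEFGHIKLMNPQRS"    # 15-mer in P1 (class II, inside window)
PEP_M = "WYWYWYWY"            # multi-mapper, P1 and P2
PEP_B = "TSRQPNML"            # single mapper in P2

P1 = "AAA" + PEP_A + "GG" + PEP_10 + "GG" + PEP_15 + "GG" + PEP_M + "AA"
P2 = "CCC" + PEP_B + "GG" + PEP_M + "CC"


@pytest.fixture()
def index():
    idx = io.ProteinIndex(proteins={"P1": P1, "P2": P2})
    io.map_peptides({PEP_A, PEP_10, PEP_15, PEP_M, PEP_B}, idx)
    return idx


@pytest.fixture()
def samples():
    return [
        Sample("T1", "tumor", "meninges", True, who_grade="I"),
        Sample("T2", "tumor", "meninges", True, who_grade="II"),
        Sample("T3", "tumor", "meninges", True, who_grade="III"),
        Sample("D1", "dura", "dura", True),
        Sample("L1", "benign", "liver", False),
        Sample("L2", "benign", "liver", False),
        Sample("K1", "benign", "skin", False),
        Sample("BR1", "benign", "brain", True),
    ]


def _peptidome(assignments):
    pep = Peptidome()
    for sid, cls, peps in assignments:
        for p in peps:
            pep.add(sid, cls, p)
    return pep


class TestPositivityCounts:
    def test_two_donors_of_one_organ_count_once(self, index, samples):
        pep = _peptidome([("L1", "I", [PEP_A]), ("L2", "I", [PEP_A])])
        rows = prof.positivity_counts(pep, samples, index, "peptide", "I")
        (row,) = rows
        assert row.n_benign_noncns == 1 and row.n_benign_cns == 0

    def test_two_distinct_organs_count_twice(self, index, samples):
        pep = _peptidome([("L1", "I", [PEP_A]), ("K1", "I", [PEP_A])])
        (row,) = prof.positivity_counts(pep, samples, index, "peptide", "I")
        assert row.n_benign_noncns == 2

    def test_brain_counts_as_cns_benign(self, index, samples):
        pep = _peptidome([("BR1", "I", [PEP_A])])
        (row,) = prof.positivity_counts(pep, samples, index, "peptide", "I")
        assert row.n_benign_cns == 1 and row.n_benign_noncns == 0

    def test_antigen_level_frequency(self, index, samples):
        pep = _peptidome([("T1", "I", [PEP_A]), ("T2", "I", [PEP_A])])
        rows = prof.positivity_counts(pep, samples, index, "antigen", "I")
        (row,) = rows
        assert row.item_id == "P1"
        assert row.n_tumor == 2
        assert row.tumor_frequency == pytest.approx(2 / 3)

    def test_multimapper_credits_both_proteins(self, index, samples):
        pep = _peptidome([("T1", "I", [PEP_M])])
        rows = prof.positivity_counts(pep, samples, index, "antigen", "I")
        assert {r.item_id for r in rows} == {"P1", "P2"}

    def test_antigen_positivity_implied_by_peptide_positivity(self, index,
                                                              samples):
        pep = _peptidome([("T1", "I", [PEP_A]), ("T2", "I", [PEP_A, PEP_B]),
                          ("L1", "I", [PEP_B])])
        arow = {r.item_id: r for r in prof.positivity_counts(
            pep, samples, index, "antigen", "I")}
        prow = {r.item_id: r for r in prof.positivity_counts(
            pep, samples, index, "peptide", "I")}
        for pep_id, row in prow.items():
            for pid in index.source_proteins(pep_id):
                assert row.tumor_samples <= arow[pid].tumor_samples


class TestFlagExclusive:
    @pytest.mark.parametrize("counts,expected", [
        ((2, 0, 0, 1), True),    # boundary: one non-CNS organ allowed
        ((2, 0, 0, 2), False),   # two non-CNS organs
        ((1, 0, 0, 0), False),   # below the two-tumor minimum
        ((2, 1, 0, 0), False),   # dura hit
        ((2, 0, 1, 0), False),   # CNS benign hit
        ((2, 0, 0, 0), True),
    ])
    def test_rule(self, config, counts, expected):
        n_t, n_d, n_cns, n_non = counts
        row = prof.ProfilingRow("X", "antigen", "I", n_t, n_d, n_cns, n_non,
                                n_t / 33)
        prof.flag_exclusive([row], config)
        assert row.exclusive is expected

    def test_adding_a_benign_organ_never_creates_exclusivity(self, config):
        """Monotonicity: benign evidence can only destroy exclusivity."""
        for n_non in range(4):
            before = prof.ProfilingRow("X", "antigen", "I", 3, 0, 0, n_non, 0.1)
            after = prof.ProfilingRow("X", "antigen", "I", 3, 0, 0, n_non + 1, 0.1)
            prof.flag_exclusive([before, after], config)
            assert not (after.exclusive and not before.exclusive)


class TestCuration:
    def _curate(self, index, samples, assignments, hla_class, config=None,
                binder_peps=None):
        config = config or PipelineConfig()
        pep = _peptidome(assignments)
        rows = prof.flag_exclusive(
            prof.positivity_counts(pep, samples, index, "antigen", hla_class),
            config)
        annotations = None
        if hla_class == "I":
            binder_peps = set(binder_peps or [])
            scores = {(p, "A*02:01"): (1.0, 80.0) for p in binder_peps}
            annotations = {
                s.sample_id: annotate_binders(
                    pep.peptides(s.sample_id, "I"), ("A*02:01",), scores, config)
                for s in samples
                if s.tissue_class == "tumor" and pep.peptides(s.sample_id, "I")}
        return prof.curate_candidates(rows, pep, samples, index, annotations,
                                      config, hla_class)

    def test_antigen_with_only_multimapper_evidence_dropped(self, index,
                                                            samples):
        curated = self._curate(index, samples,
                               [("T1", "I", [PEP_M]), ("T2", "I", [PEP_M])],
                               "I", binder_peps=[PEP_M])
        assert curated == {}

    def test_class2_length_window_filters_evidence(self, index, samples):
        # the 10-mer is outside the 12-25 window; only the 15-mer counts
        curated = self._curate(
            index, samples,
            [("T1", "II", [PEP_10, PEP_15]), ("T2", "II", [PEP_10, PEP_15])],
            "II")
        assert set(curated) == {"P1"}
        assert set(curated["P1"].evidence) == {PEP_15}
        only_short = self._curate(
            index, samples,
            [("T1", "II", [PEP_10]), ("T2", "II", [PEP_10])], "II")
        assert only_short == {}

    def test_class1_requires_binder_for_presenting_sample(self, index, samples):
        kept = self._curate(index, samples,
                            [("T1", "I", [PEP_A]), ("T2", "I", [PEP_A])],
                            "I", binder_peps=[PEP_A])
        assert set(kept) == {"P1"}
        assert kept["P1"].tumor_samples == {"T1", "T2"}
        dropped = self._curate(index, samples,
                               [("T1", "I", [PEP_A]), ("T2", "I", [PEP_A])],
                               "I", binder_peps=[])
        assert dropped == {}

    def test_frequency_recomputed_from_surviving_evidence(self, index, samples):
        # PEP_B is a binder in two tumors; PEP_M adds a third tumor but
        # multi-maps, so the recomputed count ignores it
        curated = self._curate(
            index, samples,
            [("T1", "I", [PEP_B]), ("T2", "I", [PEP_B]), ("T3", "I", [PEP_M])],
            "I", binder_peps=[PEP_B, PEP_M])
        assert curated["P2"].tumor_samples == {"T1", "T2"}
        assert curated["P2"].tumor_frequency == pytest.approx(2 / 3)


class TestGradeOverlap:
    def test_partition(self, samples):
        overlap = prof.grade_overlap(
            {"ALL": ["T1", "T2", "T3"], "ONE": ["T1"], "PAIR": ["T1", "T3"]},
            samples)
        assert overlap.all_grades == ["ALL"]
        assert overlap.single == {"I": ["ONE"]}
        assert overlap.pairwise == {frozenset({"I", "III"}): ["PAIR"]}

    def test_grade_counts_conserve_tumor_positives(self, samples):
        tumor_sets = {"X": ["T1", "T2"], "Y": ["T1", "T2", "T3"]}
        overlap = prof.grade_overlap(tumor_sets, samples)
        grade_of = {s.sample_id: s.who_grade for s in samples}
        for item, sids in tumor_sets.items():
            per_grade = {g: sum(1 for s in sids if grade_of[s] == g)
                         for g in overlap.grades_per_item[item]}
            assert sum(per_grade.values()) == len(sids)

    def test_missing_grade_rejected(self, samples):
        samples[0].who_grade = None
        with pytest.raises(ValidationError):
            prof.grade_overlap({"X": ["T1", "T2"]}, samples)


class TestCrossReference:
    def _rows(self, index, samples, assignments, config):
        pep = _peptidome(assignments)
        arows = prof.flag_exclusive(prof.positivity_counts(
            pep, samples, index, "antigen", "I"), config)
        prows = prof.flag_exclusive(prof.positivity_counts(
            pep, samples, index, "peptide", "I"), config)
        return arows, prows

    def test_exclusive_single_mapper_representation(self, index, samples,
                                                    config):
        arows, prows = self._rows(index, samples,
                                  [("T1", "I", [PEP_A]), ("T2", "I", [PEP_A])],
                                  config)
        df = prof.cross_reference_targets(arows, prows, index, {"P1"}, config)
        assert df.loc[0, "exclusive_representation"]

    def test_benign_only_target_omitted(self, index, samples, config):
        arows, prows = self._rows(index, samples, [("L1", "I", [PEP_A])],
                                  config)
        df = prof.cross_reference_targets(arows, prows, index, {"P1"}, config)
        assert df.empty

    def test_multimapper_counts_for_frequency_but_not_representation(
            self, index, samples, config):
        arows, prows = self._rows(
            index, samples,
            [("T1", "I", [PEP_M]), ("T2", "I", [PEP_M]), ("T3", "I", [PEP_M])],
            config)
        df = prof.cross_reference_targets(arows, prows, index, {"P1"}, config)
        assert df.loc[0, "n_tumor"] == 3
        assert df.loc[0, "tumor_frequency"] == pytest.approx(1.0)
        assert not df.loc[0, "exclusive_representation"]


class TestPlantedTruthRecovery:
    @pytest.mark.parametrize("seed", range(5))
    def test_curated_set_equals_planted_set(self, seed, config):
        """Synthetic cohorts with planted exclusive antigens and boundary
        decoys: curation returns exactly the planted set for both classes."""
        cohort = generate_cohort(seed=seed)
        index = io.ProteinIndex(proteins=dict(cohort.proteins))
        pep = Peptidome()
        for r in cohort.peptide_rows.itertuples():
            pep.add(r.sample_id, r.hla_class, r.peptide)
        io.map_peptides(pep.all_peptides("I") | pep.all_peptides("II"), index)
        annotations = tumor_annotations(pep, cohort.samples, cohort.typing,
                                        cohort.scores, config)
        for cls in ("I", "II"):
            rows = prof.flag_exclusive(prof.positivity_counts(
                pep, cohort.samples, index, "antigen", cls), config)
            curated = prof.curate_candidates(
                rows, pep, cohort.samples, index,
                annotations if cls == "I" else None, config, cls)
            assert set(curated) == \
                cohort.truth.expected_exclusive_antigens_by_class[cls]
            prows = prof.flag_exclusive(prof.positivity_counts(
                pep, cohort.samples, index, "peptide", cls), config)
            assert {r.item_id for r in prows if r.exclusive} == \
                cohort.truth.planted_exclusive_peptides_by_class[cls]
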