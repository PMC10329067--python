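"""Length-variant grouping and presentation-hotspot detection."""

import numpy as np
import pytest

from ligandatlas import io_formats as io
from ligandatlas.config import PipelineConfig
from ligandatlas.hotspots import (CoreGroup, Hotspot, MappedPeptide,
                                  detect_hotspots, group_length_variants)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _protein(rng, n):
    return "".join(rng.choice(list(AA), size=n))


def _mp(pid, start, end, seq, samples):
    return MappedPeptide(peptide=seq[start - 1:end], protein_id=pid,
                         start=start, end=end, samples=frozenset(samples))


def oracle_scan(exclusive, benign, protein_len, min_patients, min_len):
    """Independent per-position hotspot oracle (brute force)."""
    patients_at = [set() for _ in range(protein_len)]
    for p in exclusive:
        for pos in range(p.start - 1, p.end):
            patients_at[pos] |= set(p.samples)
    forbidden = [False] * protein_len
    for b in benign:
        for pos in range(b.start - 1, b.end):
            forbidden[pos] = True
    ok = [len(patients_at[i]) >= min_patients and not forbidden[i]
          for i in range(protein_len)]
    spots, start = [], None
    for i, v in enumerate(ok + [False]):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start >= min_len:
                spots.append((start + 1, i))
            start = None
    return spots


def oracle_components(intervals, min_overlap):
    """Independent connected-components oracle (BFS on the overlap graph)."""
    n = len(intervals)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            (s1, e1), (s2, e2) = intervals[i], intervals[j]
            if min(e1, e2) - max(s1, s2) + 1 >= min_overlap:
                adj[i].append(j)
                adj[j].append(i)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        queue, comp = [i], set()
        while queue:
            k = queue.pop()
            if k in comp:
                continue
            comp.add(k)
            queue.extend(adj[k])
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


class TestGroupLengthVariants:
    def test_overlapping_pair_core_is_intersection(self):
        rng = np.random.default_rng(0)
        seq = _protein(rng, 40)
        peps = [_mp("P", 10, 24, seq, {"T1"}), _mp("P", 12, 26, seq, {"T2"})]
        (group,) = group_length_variants(peps, min_overlap=8)
        assert (group.core_start, group.core_end) == (12, 24)
        assert group.patients == {"T1", "T2"}

    def test_disjoint_intervals_form_two_groups(self):
        rng = np.random.default_rng(1)
        seq = _protein(rng, 60)
        peps = [_mp("P", 1, 12, seq, {"T1"}), _mp("P", 30, 45, seq, {"T2"})]
        groups = group_length_variants(peps, min_overlap=8)
        assert len(groups) == 2

    def test_chain_with_empty_intersection_reports_deepest_run(self):
        # A=[1,15], B=[10,25], C=[20,35]: one component, global intersection
        # empty; depth-2 runs are [10,15] and [20,25]; leftmost wins the tie
        rng = np.random.default_rng(2)
        seq = _protein(rng, 40)
        peps = [_mp("P", 1, 15, seq, {"T1"}), _mp("P", 10, 25, seq, {"T2"}),
                _mp("P", 20, 35, seq, {"T3"})]
        (group,) = group_length_variants(peps, min_overlap=6)
        assert len(group.members) == 3
        assert (group.core_start, group.core_end) == (10, 15)

    def test_components_match_bfs_oracle_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(2, 10))
            intervals = []
            for _ in range(n):
                s = int(rng.integers(1, 50))
                intervals.append((s, s + int(rng.integers(8, 25))))
            seq = _protein(rng, 100)
            peps = [_mp("P", s, e, seq, {f"T{i}"})
                    for i, (s, e) in enumerate(intervals)]
            groups = group_length_variants(peps, min_overlap=8)
            got = sorted(sorted((s, e) for _, s, e in g.members)
                         for g in groups)
            want = sorted(sorted(intervals[i] for i in comp)
                          for comp in oracle_components(intervals, 8))
            assert got == want


class TestDetectHotspots:
    def _index(self, seq):
        return io.ProteinIndex(proteins={"P": seq})

    def test_five_patient_region_called(self, config):
        rng = np.random.default_rng(3)
        seq = _protein(rng, 40)
        excl = [_mp("P", 10, 25, seq, {f"T{i}"}) for i in range(5)]
        (spot,) = detect_hotspots(excl, [], self._index(seq), config)
        assert (spot.start, spot.end, spot.length) == (10, 25, 16)
        assert min(spot.patients_per_position) == 5

    def test_four_patients_not_called(self, config):
        rng = np.random.default_rng(4)
        seq = _protein(rng, 40)
        excl = [_mp("P", 10, 25, seq, {f"T{i}"}) for i in range(4)]
        assert detect_hotspots(excl, [], self._index(seq), config) == []

    def test_benign_overlap_truncates_run(self, config):
        rng = np.random.default_rng(6)
        seq = _protein(rng, 40)
        excl = [_mp("P", 10, 25, seq, {f"T{i}"}) for i in range(5)]
        benign = [_mp("P", 18, 30, seq, {"L1"})]
        (spot,) = detect_hotspots(excl, benign, self._index(seq), config)
        assert (spot.start, spot.end, spot.length) == (10, 17, 8)

    def test_two_variants_from_one_patient_count_once(self, config):
        rng = np.random.default_rng(7)
        seq = _protein(rng, 40)
        excl = ([_mp("P", 10, 25, seq, {f"T{i}"}) for i in range(4)]
                + [_mp("P", 9, 24, seq, {"T0"})])  # T0 again
        assert detect_hotspots(excl, [], self._index(seq), config) == []

    def _random_instance(self, rng):
        n_prot = int(rng.integers(1, 3))
        proteins = {f"P{k}": _protein(rng, int(rng.integers(30, 61)))
                    for k in range(n_prot)}
        excl, benign = [], []
        for _ in range(int(rng.integers(0, 13))):
            pid = f"P{int(rng.integers(0, n_prot))}"
            L = len(proteins[pid])
            s = int(rng.integers(1, L - 8))
            e = min(L, s + int(rng.integers(8, 20)))
            samples = {f"T{int(x)}" for x in
                       rng.integers(0, 8, size=rng.integers(1, 4))}
            excl.append(_mp(pid, s, e, proteins[pid], samples))
        for _ in range(int(rng.integers(0, 4))):
            pid = f"P{int(rng.integers(0, n_prot))}"
            L = len(proteins[pid])
            s = int(rng.integers(1, L - 5))
            e = min(L, s + int(rng.integers(5, 15)))
            benign.append(_mp(pid, s, e, proteins[pid], {"B"}))
        return proteins, excl, benign

    def test_matches_per_position_oracle_on_random_instances(self, config):
        rng = np.random.default_rng(11)
        for _ in range(200):
            proteins, excl, benign = self._random_instance(rng)
            index = io.ProteinIndex(proteins=proteins)
            got = {(h.protein_id, h.start, h.end)
                   for h in detect_hotspots(excl, benign, index, config)}
            want = set()
            for pid, seq in proteins.items():
                for s, e in oracle_scan(
                        [p for p in excl if p.protein_id == pid],
                        [p for p in benign if p.protein_id == pid],
                        len(seq), config.hotspot_min_patients,
                        config.hotspot_min_len):
                    want.add((pid, s, e))
            assert got == want

    def test_monotonicity_in_benign_and_patient_evidence(self, config):
        """Adding benign peptides never lengthens a hotspot; adding another
        patient's peptide never shortens one."""
        rng = np.random.default_rng(13)
        for _ in range(50):
            proteins, excl, benign = self._random_instance(rng)
            index = io.ProteinIndex(proteins=proteins)
            base = {(h.protein_id, h.start): h.length
                    for h in detect_hotspots(excl, benign, index, config)}
            pid = sorted(proteins)[0]
            L = len(proteins[pid])
            s = int(rng.integers(1, max(2, L - 10)))
            extra_benign = _mp(pid, s, min(L, s + 9), proteins[pid], {"B2"})
            shrunk = detect_hotspots(excl, benign + [extra_benign], index,
                                     config)
            for h in shrunk:
                key = (h.protein_id, h.start)
                if key in base:
                    assert h.length <= base[key]
            total_base = sum(base.values())
            total_shrunk = sum(h.length for h in shrunk)
            assert total_shrunk <= total_base
            extra_excl = _mp(pid, s, min(L, s + 12), proteins[pid], {"T99"})
            grown = detect_hotspots(excl + [extra_excl], benign, index, config)
            assert sum(h.length for h in grown) >= total_base

    def test_hotspots_are_maximal_and_satisfy_invariants(self, config):
        rng = np.random.default_rng(19)
        for _ in range(100):
            proteins, excl, benign = self._random_instance(rng)
            index = io.ProteinIndex(proteins=proteins)
            for h in detect_hotspots(excl, benign, index, config):
                assert h.length == h.end - h.start + 1
                assert h.length >= config.hotspot_min_len
                assert min(h.patients_per_position) >= config.hotspot_min_patients
                # not extendable by one position on either side
                want = oracle_scan(
                    [p for p in excl if p.protein_id == h.protein_id],
                    [p for p in benign if p.protein_id == h.protein_id],
                    len(proteins[h.protein_id]), config.hotspot_min_patients,
                    1)
                assert (h.start, h.end) in want  # maximal run boundaries


class TestPlantedHotspotRecovery:
    @pytest.mark.parametrize("seed", range(5))
    def test_cohort_hotspot_hosts_yield_exactly_the_planted_cores(self, seed,
                                                                  config):
        from collections import defaultdict

        from ligandatlas import profiling as prof
        from ligandatlas.io_formats import Peptidome
        from ligandatlas.pipeline import mapped_class2_peptides
        from ligandatlas.synthetic_data import generate_cohort

        cohort = generate_cohort(seed=seed)
        index = io.ProteinIndex(proteins=dict(cohort.proteins))
        pep = Peptidome()
        for r in cohort.peptide_rows.itertuples():
            pep.add(r.sample_id, r.hla_class, r.peptide)
        io.map_peptides(pep.all_peptides("II"), index)
        prows = prof.flag_exclusive(prof.positivity_counts(
            pep, cohort.samples, index, "peptide", "II"), config,
            min_tumor_positives=1)
        exclusive = {r.item_id for r in prows if r.exclusive}
        tumor_mapped = [p for p in mapped_class2_peptides(
            pep, cohort.samples, index, lambda s: s.tissue_class == "tumor")
            if p.peptide in exclusive]
        benign_mapped = mapped_class2_peptides(
            pep, cohort.samples, index, lambda s: s.tissue_class != "tumor")
        spots = detect_hotspots(tumor_mapped, benign_mapped, index, config)
        hosts = ({p for p, _, _ in cohort.truth.planted_hotspots}
                 | {p for p, _, _ in cohort.truth.decoy_hotspots_few_patients}
                 | {p for p, _, _ in cohort.truth.decoy_hotspots_benign_overlap})
        got = sorted((h.protein_id, h.start, h.end) for h in spots
                     if h.protein_id in hosts)
        assert got == sorted(tuple(x) for x in cohort.truth.planted_hotspots)
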