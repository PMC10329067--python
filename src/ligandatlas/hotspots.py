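"""HLA class II presentation hotspots.

Class II peptides occur as nested length variants around a common core
because the open class II binding groove tolerates protruding flanks.
Comparative profiling of full sequences cannot see this structure, so
tumor-derived class II peptides are first grouped by shared core and then
scanned for presentation hotspots: maximal contiguous protein regions of at
least eight residues in which every position is covered by peptides from at
least five distinct patients and no position overlaps any benign- or
dura-derived peptide of the same protein.

The patient threshold is enforced per position (the strictest reading); a
region-level alternative -- at least five distinct patients anywhere in the
region -- is available via ``PipelineConfig.hotspot_region_level``. Benign
exclusion by positional overlap can be relaxed to exact sequence identity
via ``hotspot_exact_sequence``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .config import PipelineConfig
from .errors import MissingReferenceError, ValidationError
from .io_formats import ProteinIndex


@dataclass(frozen=True)
class MappedPeptide:
    """One peptide placed on one protein, with the samples presenting it."""

    peptide: str
    protein_id: str
    start: int  # 1-based inclusive
    end: int
    samples: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}] for {self.peptide}")


@dataclass
class CoreGroup:
    """A connected component of overlapping length variants on one protein."""

    protein_id: str
    members: list[tuple[str, int, int]]
    core_start: int
    core_end: int
    patients: frozenset[str]


@dataclass
class Hotspot:
    """A maximal benign-free region with sufficient patient coverage."""

    protein_id: str
    start: int
    end: int
    length: int
    patients_per_position: list[int]
    supporting_peptides: list[str]
    benign_free: bool = True


def _deepest_run(members: Sequence[tuple[str, int, int]]) -> tuple[int, int]:
    """Longest (leftmost on ties) run of positions at maximal coverage depth."""
    lo = min(s for _, s, _ in members)
    hi = max(e for _, _, e in members)
    depth = np.zeros(hi - lo + 1, dtype=int)
    for _, s, e in members:
        depth[s - lo:e - lo + 1] += 1
    best = depth.max()
    best_run, run_start, run_len = None, None, 0
    for i, d in enumerate(depth):
        if d == best:
            if run_start is None:
                run_start = i
            run_len = i - run_start + 1
            if best_run is None or run_len > best_run[1] - best_run[0] + 1:
                best_run = (run_start, i)
        else:
            run_start = None
    assert best_run is not None
    return best_run[0] + lo, best_run[1] + lo


def group_length_variants(peptides: Iterable[MappedPeptide],
                          min_overlap: int = 8) -> list[CoreGroup]:
    """Group single-protein peptides into core-sharing components.

    Two variants belong together when their intervals overlap by at least
    ``min_overlap`` positions; components are the transitive closure. The
    core is the intersection of all member intervals when it is non-empty;
    otherwise (chains whose extremes do not meet) the deepest-coverage run
    is reported as a single representative locus.
    """
    by_protein: dict[str, list[MappedPeptide]] = defaultdict(list)
    for p in peptides:
        by_protein[p.protein_id].append(p)

    groups: list[CoreGroup] = []
    for pid in sorted(by_protein):
        members = sorted(by_protein[pid], key=lambda m: (m.start, m.end, m.peptide))
        n = len(members)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                a, b = members[i], members[j]
                overlap = min(a.end, b.end) - max(a.start, b.start) + 1
                if overlap >= min_overlap:
                    parent[find(i)] = find(j)

        comps: dict[int, list[MappedPeptide]] = defaultdict(list)
        for i in range(n):
            comps[find(i)].append(members[i])
        for comp in sorted(comps.values(), key=lambda c: c[0].start):
            triples = [(m.peptide, m.start, m.end) for m in comp]
            inter_s = max(s for _, s, _ in triples)
            inter_e = min(e for _, _, e in triples)
            if inter_s > inter_e:
                inter_s, inter_e = _deepest_run(triples)
            patients = frozenset().union(*(m.samples for m in comp))
            groups.append(CoreGroup(protein_id=pid, members=triples,
                                    core_start=inter_s, core_end=inter_e,
                                    patients=patients))
    return groups


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as 0-based inclusive (start, end) pairs."""
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def detect_hotspots(exclusive_peptides: Iterable[MappedPeptide],
                    benign_peptides: Iterable[MappedPeptide],
                    index: ProteinIndex,
                    config: PipelineConfig) -> list[Hotspot]:
    """Call tumor-exclusive class II presentation hotspots.

    ``exclusive_peptides`` are mapped tumor-exclusive class II peptides
    (multi-mappers excluded upstream); ``benign_peptides`` are all mapped
    benign- and dura-derived class II peptides. Patient multiplicity counts
    distinct samples: two length variants from one patient contribute one.
    """
    exclusive = list(exclusive_peptides)
    benign = list(benign_peptides)
    for p in exclusive + benign:
        if p.protein_id not in index.proteins:
            raise MissingReferenceError(
                f"protein {p.protein_id!r} not present in the protein index")

    if config.hotspot_exact_sequence:
        benign_seqs = {p.peptide for p in benign}
        exclusive = [p for p in exclusive if p.peptide not in benign_seqs]

    excl_by_protein: dict[str, list[MappedPeptide]] = defaultdict(list)
    for p in exclusive:
        excl_by_protein[p.protein_id].append(p)
    benign_by_protein: dict[str, list[MappedPeptide]] = defaultdict(list)
    if not config.hotspot_exact_sequence:
        for p in benign:
            benign_by_protein[p.protein_id].append(p)

    hotspots: list[Hotspot] = []
    for pid in sorted(excl_by_protein):
        length = len(index.proteins[pid])
        coverage: dict[str, np.ndarray] = {}
        for p in excl_by_protein[pid]:
            if p.end > length:
                raise MissingReferenceError(
                    f"peptide {p.peptide} exceeds protein {pid} length {length}")
            for sid in p.samples:
                arr = coverage.setdefault(sid, np.zeros(length, dtype=bool))
                arr[p.start - 1:p.end] = True
        if not coverage:
            continue
        counts = np.sum(list(coverage.values()), axis=0).astype(int)
        forbidden = np.zeros(length, dtype=bool)
        for p in benign_by_protein.get(pid, []):
            forbidden[p.start - 1:min(p.end, length)] = True

        if config.hotspot_region_level:
            ok = (counts >= 1) & ~forbidden
        else:
            ok = (counts >= config.hotspot_min_patients) & ~forbidden

        for run_s, run_e in _runs(ok):
            if run_e - run_s + 1 < config.hotspot_min_len:
                continue
            start, end = run_s + 1, run_e + 1
            support = sorted({p.peptide for p in excl_by_protein[pid]
                              if p.start <= end and p.end >= start})
            if config.hotspot_region_level:
                region_patients = {
                    sid for p in excl_by_protein[pid]
                    if p.start <= end and p.end >= start for sid in p.samples}
                if len(region_patients) < config.hotspot_min_patients:
                    continue
            hotspots.append(Hotspot(
                protein_id=pid, start=start, end=end, length=end - start + 1,
                patients_per_position=counts[run_s:run_e + 1].tolist(),
                supporting_peptides=support))
    return hotspots
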