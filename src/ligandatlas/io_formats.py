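"""Readers, writers and the peptide-to-proteome mapping.

Tables are tab-separated UTF-8 with a header row; lines starting with ``#``
before the header are treated as comments. The proteome arrives as FASTA.
Coordinates are 1-based inclusive throughout (``protein[start-1:end]`` equals
the peptide), matching the peptide-position notation used for eluted ligands
(e.g. CTSK_7-15). Isoleucine and leucine are treated as distinct residues:
search engines report a single sequence assignment, so no I/L equivalencing
is attempted.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio import SeqIO

from .coverage import AlleleFrequencyTable
from .errors import FormatError, MissingReferenceError, ValidationError

logger = logging.getLogger(__name__)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
HLA_CLASSES = ("I", "II")
TISSUE_CLASSES = ("tumor", "dura", "benign")
WHO_GRADES = ("I", "II", "III")
KNOWN_LOCI = frozenset({
    "A", "B", "C", "E", "F", "G",
    "DRA", "DRB1", "DRB3", "DRB4", "DRB5",
    "DQA1", "DQB1", "DPA1", "DPB1",
})


@dataclass
class Sample:
    """Metadata of one peptidome dataset (tumor, autologous dura, or benign organ donor)."""

    sample_id: str
    tissue_class: str
    organ: str
    cns_related: bool
    who_grade: Optional[str] = None
    sex: Optional[str] = None
    location: Optional[str] = None
    tissue_mass_mg: Optional[float] = None
    n_replicates: Optional[int] = None
    hla_typing: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValidationError(
                f"sample {self.sample_id}: tissue_class {self.tissue_class!r} "
                f"not in {TISSUE_CLASSES}")
        if self.who_grade is not None and self.who_grade not in WHO_GRADES:
            raise ValidationError(
                f"sample {self.sample_id}: who_grade {self.who_grade!r} "
                f"not in {WHO_GRADES}")
        if self.tissue_mass_mg is not None and not self.tissue_mass_mg > 0:
            raise ValidationError(
                f"sample {self.sample_id}: tissue_mass_mg must be positive")


@dataclass
class Peptidome:
    """Unique eluted peptides per sample and HLA class."""

    entries: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    replicate_counts: dict[str, int] = field(default_factory=dict)

    def peptides(self, sample_id: str, hla_class: str) -> set[str]:
        return self.entries.get(sample_id, {}).get(hla_class, set())

    def sample_ids(self) -> list[str]:
        return sorted(self.entries)

    def all_peptides(self, hla_class: str) -> set[str]:
        out: set[str] = set()
        for classes in self.entries.values():
            out |= classes.get(hla_class, set())
        return out

    def add(self, sample_id: str, hla_class: str, peptide: str) -> None:
        self.entries.setdefault(sample_id, {}).setdefault(hla_class, set()).add(peptide)


@dataclass
class ProteinIndex:
    """Proteome sequences with exact peptide hits.

    ``peptide_hits`` maps each mapped peptide to every occurrence as
    ``(protein_id, start, end)`` with 1-based inclusive coordinates.
    ``multimapper`` is True iff the peptide occurs in more than one distinct
    protein; repeated occurrences within a single protein do not count.
    """

    proteins: dict[str, str] = field(default_factory=dict)
    peptide_hits: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    multimapper: dict[str, bool] = field(default_factory=dict)
    unmapped: set[str] = field(default_factory=set)

    def source_proteins(self, peptide: str) -> set[str]:
        return {pid for pid, _, _ in self.peptide_hits.get(peptide, [])}


def _validate_peptides(values: Iterable[str], where: str) -> None:
    bad = [(i, p) for i, p in enumerate(values)
           if not p or not set(p) <= AMINO_ACIDS]
    if bad:
        shown = ", ".join(f"row {i}: {p!r}" for i, p in bad[:10])
        raise ValidationError(
            f"{len(bad)} peptide(s) in {where} contain non-amino-acid "
            f"characters or are empty ({shown})")


def _read_tsv(path: str | Path, required: set[str], what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = required - set(df.columns)
    if missing:
        raise FormatError(
            f"{what} {path} is missing required column(s): {sorted(missing)}")
    return df


def _parse_bool(value: str, where: str) -> bool:
    v = str(value).strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no"):
        return False
    raise ValidationError(f"cannot parse boolean {value!r} in {where}")


def _opt(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return s or None


def read_sample_table(path: str | Path) -> list[Sample]:
    """Read samples.tsv (one row per sample)."""
    df = _read_tsv(path, {"sample_id", "tissue_class", "organ", "cns_related"},
                   "sample table")
    samples = []
    for _, row in df.iterrows():
        mass = _opt(row.get("tissue_mass_mg"))
        reps = _opt(row.get("n_replicates"))
        samples.append(Sample(
            sample_id=str(row["sample_id"]),
            tissue_class=str(row["tissue_class"]),
            organ=str(row["organ"]),
            cns_related=_parse_bool(row["cns_related"], "samples table"),
            who_grade=_opt(row.get("who_grade")),
            sex=_opt(row.get("sex")),
            location=_opt(row.get("location")),
            tissue_mass_mg=float(mass) if mass is not None else None,
            n_replicates=int(reps) if reps is not None else None,
        ))
    ids = [s.sample_id for s in samples]
    if len(ids) != len(set(ids)):
        raise ValidationError(f"duplicate sample_id in {path}")
    return samples


def read_peptide_table(path: str | Path,
                       metadata_path: str | Path) -> tuple[Peptidome, list[Sample]]:
    """Read peptides.tsv plus its sample metadata table.

    Duplicated (peptide, sample, class) rows collapse into sets; every
    sample_id appearing in the peptide table must have a metadata row.
    """
    df = _read_tsv(path, {"peptide", "sample_id", "hla_class"}, "peptide table")
    samples = read_sample_table(metadata_path)
    known = {s.sample_id for s in samples}
    if df.empty:
        logger.warning("peptide table %s has no data rows", path)
        return Peptidome(), samples

    bad_class = sorted(set(df["hla_class"]) - set(HLA_CLASSES))
    if bad_class:
        raise ValidationError(
            f"hla_class value(s) {bad_class} not in {list(HLA_CLASSES)}")
    _validate_peptides(df["peptide"].tolist(), str(path))
    orphans = sorted(set(df["sample_id"]) - known)
    if orphans:
        raise MissingReferenceError(
            f"sample(s) {orphans[:10]} in peptide table absent from metadata")

    pep = Peptidome()
    for p, sid, cls in zip(df["peptide"], df["sample_id"], df["hla_class"]):
        pep.add(str(sid), str(cls), str(p))
    for s in samples:
        if s.n_replicates is not None:
            pep.replicate_counts[s.sample_id] = s.n_replicates
    return pep, samples


def read_proteome_fasta(path: str | Path) -> ProteinIndex:
    """Read a FASTA proteome into a ProteinIndex (sequences only).

    Record ids are the first whitespace-delimited token of the header;
    sequences are upper-cased and trailing ``*`` stop characters stripped.
    """
    proteins: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        pid = record.id
        if pid in proteins:
            raise ValidationError(f"duplicate protein id {pid!r} in {path}")
        seq = str(record.seq).upper().rstrip("*")
        if not seq:
            raise ValidationError(f"protein {pid!r} has an empty sequence")
        invalid = set(seq) - AMINO_ACIDS
        if invalid:
            raise ValidationError(
                f"protein {pid!r} contains unsupported characters "
                f"{sorted(invalid)}; the 20 standard residues are required")
        proteins[pid] = seq
    if not proteins:
        raise FormatError(f"FASTA file {path} contains no records")
    return ProteinIndex(proteins=proteins)


def map_peptides(peptides: Iterable[str], index: ProteinIndex) -> ProteinIndex:
    """Exact substring search of peptides against the indexed proteome.

    Fills ``index.peptide_hits`` (every occurrence, 1-based inclusive),
    ``index.multimapper`` (> 1 distinct source protein) and
    ``index.unmapped``. Returns the same index. The scan slides one window
    per distinct peptide length over each protein, so the cost is
    O(total proteome length x number of distinct peptide lengths).
    """
    peptide_set = set(peptides)
    _validate_peptides(sorted(peptide_set), "mapping query")
    by_len: dict[int, set[str]] = defaultdict(set)
    for p in peptide_set:
        by_len[len(p)].add(p)

    hits: dict[str, list[tuple[str, int, int]]] = defaultdict(list)
    for pid in sorted(index.proteins):
        seq = index.proteins[pid]
        n = len(seq)
        for length, group in by_len.items():
            for i in range(n - length + 1):
                window = seq[i:i + length]
                if window in group:
                    hits[window].append((pid, i + 1, i + length))

    index.peptide_hits = {p: sorted(h) for p, h in hits.items()}
    index.multimapper = {
        p: len({pid for pid, _, _ in h}) > 1 for p, h in index.peptide_hits.items()
    }
    index.unmapped = peptide_set - set(index.peptide_hits)
    if index.unmapped:
        logger.info("%d peptide(s) did not map to the proteome", len(index.unmapped))
    return index


def read_hla_typing(path: str | Path) -> dict[str, list[str]]:
    """Read typing.tsv (sample_id, locus, allotype) into per-sample lists."""
    df = _read_tsv(path, {"sample_id", "locus", "allotype"}, "HLA typing table")
    bad = sorted(set(df["locus"]) - KNOWN_LOCI)
    if bad:
        raise ValidationError(f"unknown HLA locus label(s): {bad}")
    typing: dict[str, list[str]] = defaultdict(list)
    for sid, allo in zip(df["sample_id"], df["allotype"]):
        typing[str(sid)].append(str(allo))
    return dict(typing)


def read_allele_frequencies(path: str | Path) -> AlleleFrequencyTable:
    """Read freqs.tsv (locus, allotype, population, frequency)."""
    df = _read_tsv(path, {"locus", "allotype", "population", "frequency"},
                   "allele frequency table")
    bad = sorted(set(df["locus"]) - KNOWN_LOCI)
    if bad:
        raise ValidationError(f"unknown HLA locus label(s): {bad}")
    freqs: dict[str, dict[str, dict[str, float]]] = {}
    for _, row in df.iterrows():
        f = float(row["frequency"])
        if not (0.0 <= f <= 1.0):
            raise ValidationError(
                f"frequency of {row['allotype']} outside [0, 1]: {f}")
        freqs.setdefault(str(row["population"]), {}) \
             .setdefault(str(row["locus"]), {})[str(row["allotype"])] = f
    return AlleleFrequencyTable(freqs=freqs)


def read_prediction_scores(path: str | Path) -> dict[tuple[str, str], tuple[float, float]]:
    """Read scores.tsv into a (peptide, allotype) -> (rank, syfpeithi) map."""
    df = _read_tsv(path, {"peptide", "allotype", "rank_percentile",
                          "syfpeithi_percent"}, "prediction score table")
    scores: dict[tuple[str, str], tuple[float, float]] = {}
    for _, row in df.iterrows():
        rank = float(row["rank_percentile"])
        syf = float(row["syfpeithi_percent"])
        if rank < 0:
            raise ValidationError(f"negative percentile rank for {row['peptide']}")
        if not (0.0 <= syf <= 100.0):
            raise ValidationError(
                f"SYFPEITHI percent outside [0, 100] for {row['peptide']}")
        scores[(str(row["peptide"]), str(row["allotype"]))] = (rank, syf)
    return scores


def read_target_list(path: str | Path) -> set[str]:
    """Read a plain-text list of known antigen ids (one per line)."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def write_results_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write any results DataFrame as canonical TSV (round-trip stable)."""
    rows.to_csv(path, sep="\t", index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_proteome_fasta(proteins: Mapping[str, str], path: str | Path) -> None:
    """Write a proteome dict as FASTA with 60-column wrapping."""
    with open(path, "w") as fh:
        for pid in proteins:
            fh.write(f">{pid}\n")
            seq = proteins[pid]
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def write_hits_table(index: ProteinIndex, path: str | Path) -> None:
    """Write peptide hits as TSV (peptide, protein_id, start, end, multimapper)."""
    rows = []
    for pep in sorted(index.peptide_hits):
        for pid, start, end in index.peptide_hits[pep]:
            rows.append((pep, pid, start, end, index.multimapper[pep]))
    df = pd.DataFrame(rows, columns=["peptide", "protein_id", "start", "end",
                                     "multimapper"])
    write_results_table(df, path)
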