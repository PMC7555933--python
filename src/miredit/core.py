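"""Shared domain types and plain-text I/O.

Conventions used throughout the package:

* Sequences are stored internally as DNA over ``{A, C, G, T}`` (plus ``N``
  in raw reads). RNA input (``U``) is converted to ``T`` on load.
* All reported positions are 1-based coordinates in the mature-miRNA
  reference. The seed region is positions 2-7 inclusive.
* Inosine (the product of ADAR deamination of adenosine) base-pairs like
  guanosine and is therefore read as ``G`` by sequencers; an A-to-I editing
  event appears as an A>G substitution relative to the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# mature miRNAs are 17-24 nt single-stranded RNAs
MIN_MIRNA_LEN = 17
MAX_MIRNA_LEN = 24

# seed region: principal target-recognition element, positions 2-7 (1-based)
SEED_START = 2
SEED_END = 7

# sex x age study design of the aging rat cohort
SEXES = ("M", "F")
AGE_GROUPS_MONTHS = (3, 6, 15, 25, 30)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DNA_ALPHABET = frozenset("ACGT")
READ_ALPHABET = frozenset("ACGTN")


def in_seed(position: int) -> bool:
    """True when a 1-based reference position lies in the seed (2-7)."""
    return SEED_START <= position <= SEED_END


def revcomp(sequence: str) -> str:
    """Reverse complement of a DNA string (N self-complementary)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def normalize_sequence(sequence: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T)."""
    return sequence.upper().replace("U", "T")


def group_label(sex: str, age_months: int) -> str:
    """Canonical label for a (sex, age) study group, e.g. ``M_3``."""
    return f"{sex}_{age_months}"


@dataclass(frozen=True)
class MirnaReference:
    """Mature-miRNA reference: the coordinate frame for all editing calls.

    Parameters
    ----------
    ids : tuple of str
        Unique miRNA identifiers, in reference order.
    sequences : tuple of str
        DNA sequences over {A,C,G,T}, each 17-24 nt.
    """

    ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate miRNA identifiers in reference")
        for mid, seq in zip(self.ids, self.sequences):
            if not seq:
                raise ValueError(f"{mid}: empty sequence")
            if not set(seq) <= DNA_ALPHABET:
                raise ValueError(f"{mid}: non-ACGT characters in {seq!r}")
            if not MIN_MIRNA_LEN <= len(seq) <= MAX_MIRNA_LEN:
                raise ValueError(
                    f"{mid}: length {len(seq)} outside "
                    f"[{MIN_MIRNA_LEN}, {MAX_MIRNA_LEN}]"
                )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "MirnaReference":
        ids, seqs = [], []
        for mid, seq in pairs:
            ids.append(mid)
            seqs.append(normalize_sequence(seq))
        return cls(tuple(ids), tuple(seqs))

    @classmethod
    def from_fasta(cls, path: str | Path) -> "MirnaReference":
        records = SeqIO.parse(str(path), "fasta")
        return cls.from_pairs((rec.id, str(rec.seq)) for rec in records)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=mid, description="")
            for mid, seq in zip(self.ids, self.sequences)
        ]
        SeqIO.write(records, str(path), "fasta")

    def sequence(self, mirna_id: str) -> str:
        try:
            return self.sequences[self.ids.index(mirna_id)]
        except ValueError:
            raise KeyError(f"unknown miRNA id: {mirna_id}") from None

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(zip(self.ids, self.sequences))

    def __contains__(self, mirna_id: str) -> bool:
        return mirna_id in self.ids


@dataclass(frozen=True)
class SampleDesign:
    """Sample sheet of the sex x age study design.

    ``table`` has columns ``sample_id``, ``sex`` (M/F), ``age_months``
    (one of 3/6/15/25/30) and ``replicate`` (positive integer).
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "sex", "age_months", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        t = self.table
        if t["sample_id"].duplicated().any():
            dupes = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        bad_sex = set(t["sex"]) - set(SEXES)
        if bad_sex:
            raise ValueError(f"unknown sex values: {sorted(bad_sex)}")
        bad_age = set(t["age_months"]) - set(AGE_GROUPS_MONTHS)
        if bad_age:
            raise ValueError(f"unknown age groups: {sorted(bad_age)}")
        if (t["replicate"] < 1).any():
            raise ValueError("replicate must be a positive integer")

    @classmethod
    def from_rows(
        cls, rows: Iterable[tuple[str, str, int, int]]
    ) -> "SampleDesign":
        df = pd.DataFrame(
            rows, columns=["sample_id", "sex", "age_months", "replicate"]
        )
        return cls(df)

    @classmethod
    def full_factorial(
        cls,
        n_replicates: int = 2,
        sexes: Sequence[str] = SEXES,
        ages: Sequence[int] = AGE_GROUPS_MONTHS,
    ) -> "SampleDesign":
        """One sample per (sex, age, replicate) over the chosen groups."""
        rows = [
            (f"{sex}_{age}_r{rep}", sex, age, rep)
            for sex in sexes
            for age in ages
            for rep in range(1, n_replicates + 1)
        ]
        return cls.from_rows(rows)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleDesign":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def group_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"unknown sample id: {sample_id}")
        r = row.iloc[0]
        return group_label(r["sex"], int(r["age_months"]))

    def samples_in_group(self, sex: str, age_months: int) -> list[str]:
        t = self.table
        mask = (t["sex"] == sex) & (t["age_months"] == age_months)
        return t.loc[mask, "sample_id"].tolist()

    def groups(self) -> list[tuple[str, int]]:
        """Distinct (sex, age) groups present, in design order."""
        seen: list[tuple[str, int]] = []
        for _, r in self.table.iterrows():
            g = (r["sex"], int(r["age_months"]))
            if g not in seen:
                seen.append(g)
        return seen


@dataclass
class ReadSet:
    """Raw or cleaned reads of one sample.

    ``qualities`` is either None (no quality model; FASTQ output uses a
    constant Phred score) or a list of Phred+33 strings parallel to
    ``sequences``.
    """

    sample_id: str
    sequences: list[str]
    qualities: list[str] | None = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(
            self.sequences
        ):
            raise ValueError("qualities and sequences differ in length")

    def __len__(self) -> int:
        return len(self.sequences)

    @classmethod
    def from_fastq(cls, path: str | Path, sample_id: str | None = None) -> "ReadSet":
        seqs: list[str] = []
        quals: list[str] = []
        for title, seq, qual in _iter_fastq(path):
            seqs.append(seq.upper())
            quals.append(qual)
        sid = sample_id or Path(path).stem
        return cls(sid, seqs, quals)

    @classmethod
    def from_fasta(cls, path: str | Path, sample_id: str | None = None) -> "ReadSet":
        seqs = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
        return cls(sample_id or Path(path).stem, seqs, None)

    def to_fastq(self, path: str | Path, constant_phred: int = 40) -> None:
        """Write Phred+33 FASTQ; constant quality when none is attached."""
        qchar = chr(33 + constant_phred)
        with open(path, "w") as fh:
            for i, seq in enumerate(self.sequences):
                qual = (
                    self.qualities[i]
                    if self.qualities is not None
                    else qchar * len(seq)
                )
                fh.write(f"@{self.sample_id}:{i + 1}\n{seq}\n+\n{qual}\n")


def _iter_fastq(path: str | Path):
    """FASTQ records as (title, sequence, quality) tuples."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        yield from FastqGeneralIterator(fh)


@dataclass(frozen=True)
class CloneSequence:
    """One Sanger-sequenced bacterial colony carrying a cloned miRNA insert."""

    animal_id: str
    sex: str
    age_months: int
    colony_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = normalize_sequence(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if not set(seq) <= READ_ALPHABET:
            raise ValueError(f"{self.clone_id}: non-ACGTN characters")

    @property
    def clone_id(self) -> str:
        return f"{self.animal_id}.{self.colony_id}"


def read_clones(
    fasta_path: str | Path, metadata_path: str | Path
) -> list[CloneSequence]:
    """Load clones from FASTA plus a metadata sidecar TSV.

    The TSV must contain columns ``clone_id`` (matching FASTA record ids),
    ``animal_id``, ``sex``, ``age_months``, ``colony_id``.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"colony_id": str})
    meta = meta.set_index("clone_id")
    clones = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in meta.index:
            raise ValueError(f"clone {rec.id} missing from metadata table")
        m = meta.loc[rec.id]
        clones.append(
            CloneSequence(
                animal_id=str(m["animal_id"]),
                sex=str(m["sex"]),
                age_months=int(m["age_months"]),
                colony_id=str(m["colony_id"]),
                sequence=str(rec.seq),
            )
        )
    return clones


def write_clones(
    clones: Sequence[CloneSequence],
    fasta_path: str | Path,
    metadata_path: str | Path,
) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.clone_id, description="")
        for c in clones
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    meta = pd.DataFrame(
        {
            "clone_id": [c.clone_id for c in clones],
            "animal_id": [c.animal_id for c in clones],
            "sex": [c.sex for c in clones],
            "age_months": [c.age_months for c in clones],
            "colony_id": [c.colony_id for c in clones],
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a TSV with a stable float format so re-runs are byte-identical."""
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
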