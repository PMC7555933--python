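"""Synthetic small-RNA-seq data with planted editing and abundance effects.

The generator emulates the structure of an adipose small-RNA sequencing
study in aging rats: 50 nt raw reads consisting of a 17-24 nt mature-miRNA
insert followed by a 3' sequencing adapter; per-miRNA abundances drawn
negative-binomially across sex x age groups (3/6/15/25/30 months, M/F);
planted per-site A>G editing fractions (inosine emitted as G); uniform
per-base sequencing error on the insert; and group-wise log2 fold-change
effects on abundance.

Everything is deterministic given the master seed. Per-sample generators
are derived as ``SeedSequence(master_seed, spawn_key=(sample_index,))`` so
each sample is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    AGE_GROUPS_MONTHS,
    MIN_MIRNA_LEN,
    MAX_MIRNA_LEN,
    CloneSequence,
    MirnaReference,
    ReadSet,
    SampleDesign,
    group_label,
    revcomp,
    write_tsv,
)

# first 19 nt of the Illumina TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAA"

READ_LENGTH = 50

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


@dataclass(frozen=True)
class EditingSiteTruth:
    """One planted A>G editing site with per-group edited fractions."""

    mirna_id: str
    position: int  # 1-based, reference base is A
    fractions: Mapping[str, float]  # group label -> edited fraction


@dataclass(frozen=True)
class SimParams:
    """Generator settings.

    Attributes
    ----------
    n_de : number of miRNAs given a nonzero group log2 fold effect.
    log2fc : the planted effect, applied to every non-baseline age group
        (the 3-month group of each sex is the baseline, matching the
        study's use of 3-month animals as controls).
    n_edited_sites : number of planted A>G sites (at most one per miRNA).
    fraction_range : range the per-site edited fraction is drawn from.
    baseline_mean_range : per-miRNA baseline relative abundance is drawn
        log-uniformly from this range; only ratios matter, reads are
        scaled to the requested depth.
    dispersion : negative-binomial size parameter; var = m + m^2/size,
        so size = 25 gives CV ~ 0.2 at high counts.
    error_rate : per-base substitution error on the insert, in [0, 0.05].
    adapter : 3' adapter ligated after the insert.
    read_length : raw read length (50 nt).
    depth : default reads per sample.
    """

    n_de: int = 5
    log2fc: float = 2.0
    n_edited_sites: int = 3
    fraction_range: tuple[float, float] = (0.05, 0.40)
    baseline_mean_range: tuple[float, float] = (100.0, 10_000.0)
    dispersion: float = 25.0
    error_rate: float = 0.001
    adapter: str = DEFAULT_ADAPTER
    read_length: int = READ_LENGTH
    depth: int = 100_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        lo, hi = self.fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("fraction_range must be within [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass(frozen=True)
class SimulationTruth:
    """Planted abundances, effects and editing fractions.

    ``effects`` is a miRNA x group-label table of log2 fold effects on
    abundance (0 everywhere for non-DE miRNAs and baseline groups).
    """

    baseline: Mapping[str, float]
    effects: pd.DataFrame
    editing_sites: tuple[EditingSiteTruth, ...]
    dispersion: float
    error_rate: float
    adapter: str
    read_length: int
    master_seed: int

    def sites_of(self, mirna_id: str) -> list[EditingSiteTruth]:
        return [s for s in self.editing_sites if s.mirna_id == mirna_id]

    def group_mean(self, mirna_id: str, group: str) -> float:
        eff = float(self.effects.at[mirna_id, group]) if group in self.effects.columns else 0.0
        return self.baseline[mirna_id] * 2.0 ** eff

    def to_tsvs(self, out_dir: str | Path) -> None:
        """Write truth tables: editing sites and abundance effects."""
        out = Path(out_dir)
        rows = [
            {
                "mirna_id": s.mirna_id,
                "position": s.position,
                "group": g,
                "edited_fraction": f,
            }
            for s in self.editing_sites
            for g, f in s.fractions.items()
        ]
        write_tsv(
            pd.DataFrame(rows, columns=["mirna_id", "position", "group", "edited_fraction"]),
            out / "truth_editing_sites.tsv",
        )
        eff = self.effects.reset_index(names="mirna_id")
        eff.insert(1, "baseline_mean", [self.baseline[m] for m in self.effects.index])
        write_tsv(eff, out / "truth_abundance.tsv")


def nb_counts(
    mean: float | np.ndarray,
    dispersion: float,
    shape: int | tuple[int, ...],
    rng: np.random.Generator,
) -> np.ndarray:
    """Negative-binomial counts with the generator's (mean, size) model.

    ``var = mean + mean^2 / dispersion``; at high means the count CV is
    approximately ``1 / sqrt(dispersion)``. ``mean`` must broadcast
    against ``shape``.
    """
    p = dispersion / (dispersion + np.asarray(mean, dtype=float))
    return rng.negative_binomial(dispersion, p, size=shape)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return bytes(rng.choice(_BASES, size=length)).decode()


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def gen_reference(
    n_mirnas: int,
    length_range: tuple[int, int] = (MIN_MIRNA_LEN, MAX_MIRNA_LEN),
    seed: int = 0,
    min_distance: int = 5,
) -> MirnaReference:
    """Random mature-miRNA reference with well-separated sequences.

    Equal-length sequences are kept at pairwise Hamming distance >=
    ``min_distance`` so that mismatch-tolerant mapping is unambiguous by
    construction. Deterministic given ``seed``.

    Raises
    ------
    ValueError
        If ``n_mirnas`` sequences at the requested distance cannot be
        found (tiny length / too many sequences).
    """
    lo, hi = length_range
    if n_mirnas < 1:
        raise ValueError("n_mirnas must be >= 1")
    if not (MIN_MIRNA_LEN <= lo <= hi <= MAX_MIRNA_LEN):
        raise ValueError(
            f"length_range must lie within [{MIN_MIRNA_LEN}, {MAX_MIRNA_LEN}]"
        )
    rng = np.random.default_rng(seed)
    seqs: list[str] = []
    max_attempts = 2000  # per placement; reset on every success
    attempts = 0
    while len(seqs) < n_mirnas:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place sequence {len(seqs) + 1} of {n_mirnas} at "
                f"pairwise distance >= {min_distance} within "
                f"{max_attempts} attempts"
            )
        length = int(rng.integers(lo, hi + 1))
        cand = _random_sequence(rng, length)
        ok = all(
            _hamming(cand, s) >= min_distance
            for s in seqs
            if len(s) == len(cand)
        )
        if ok and cand not in seqs:
            seqs.append(cand)
            attempts = 0
    ids = [f"mir-{i + 1:03d}" for i in range(n_mirnas)]
    return MirnaReference(tuple(ids), tuple(seqs))


def _group_labels(design: SampleDesign) -> list[str]:
    return [group_label(sex, age) for sex, age in design.groups()]


def gen_truth(
    reference: MirnaReference,
    design: SampleDesign,
    params: SimParams = SimParams(),
    seed: int = 0,
) -> SimulationTruth:
    """Plant abundances, group effects and A>G editing sites.

    Editing sites are placed only at A positions of the mature (sense)
    strand. Exactly ``params.n_de`` miRNAs receive the log2 fold effect
    (in all non-3-month groups) and exactly ``params.n_edited_sites``
    miRNAs receive one edited site each, when feasible.
    """
    rng = np.random.default_rng(seed)
    n = len(reference)
    if params.n_de > n:
        raise ValueError(f"requested {params.n_de} DE miRNAs from {n}")
    groups = _group_labels(design)

    lo, hi = params.baseline_mean_range
    baseline = {
        mid: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        for mid in reference.ids
    }

    effects = pd.DataFrame(
        0.0, index=list(reference.ids), columns=groups
    )
    de_ids = rng.choice(n, size=params.n_de, replace=False)
    baseline_groups = {group_label(sex, AGE_GROUPS_MONTHS[0]) for sex in ("M", "F")}
    for i in de_ids:
        for g in groups:
            if g not in baseline_groups:
                effects.iat[int(i), groups.index(g)] = params.log2fc

    with_a = [mid for mid in reference.ids if "A" in reference.sequence(mid)]
    if params.n_edited_sites > 0 and not with_a:
        raise ValueError("no miRNA in the reference contains an A to edit")
    if params.n_edited_sites > len(with_a):
        raise ValueError(
            f"requested {params.n_edited_sites} edited miRNAs but only "
            f"{len(with_a)} contain an A"
        )
    chosen = rng.choice(len(with_a), size=params.n_edited_sites, replace=False)
    sites = []
    flo, fhi = params.fraction_range
    for i in sorted(int(c) for c in chosen):
        mid = with_a[i]
        seq = reference.sequence(mid)
        a_positions = [p + 1 for p, b in enumerate(seq) if b == "A"]
        pos = int(a_positions[rng.integers(len(a_positions))])
        frac = float(rng.uniform(flo, fhi))
        sites.append(
            EditingSiteTruth(mid, pos, {g: frac for g in groups})
        )
    return SimulationTruth(
        baseline=baseline,
        effects=effects,
        editing_sites=tuple(sites),
        dispersion=params.dispersion,
        error_rate=params.error_rate,
        adapter=params.adapter,
        read_length=params.read_length,
        master_seed=seed,
    )


def sample_seed(master_seed: int, sample_index: int) -> np.random.SeedSequence:
    """Stated per-sample seed derivation: spawn key on the sample index."""
    return np.random.SeedSequence(master_seed, spawn_key=(sample_index,))


def simulate_sample_counts(
    truth: SimulationTruth,
    reference: MirnaReference,
    group: str,
    depth: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Negative-binomial per-miRNA read counts for one sample.

    Means are ``depth * baseline_share * 2^(group effect)`` so the ratio
    of group means equals the planted fold change exactly (sample totals
    are allowed to drift with the effects rather than being renormalized).
    """
    base = np.array([truth.baseline[m] for m in reference.ids])
    eff = np.array(
        [
            float(truth.effects.at[m, group])
            if group in truth.effects.columns
            else 0.0
            for m in reference.ids
        ]
    )
    means = depth * (base / base.sum()) * 2.0 ** eff
    size = truth.dispersion
    p = size / (size + means)
    return rng.negative_binomial(size, p)


def _simulate_mirna_reads(
    seq: str,
    count: int,
    sites: Sequence[EditingSiteTruth],
    group: str,
    truth: SimulationTruth,
    rng: np.random.Generator,
) -> np.ndarray:
    """(count, read_length) uint8 matrix of raw reads for one miRNA."""
    L = len(seq)
    rl = truth.read_length
    insert = np.frombuffer(seq.encode(), dtype=np.uint8)
    reads = np.empty((count, rl), dtype=np.uint8)
    reads[:, :L] = insert
    # planted editing: Bernoulli per read at each site, A emitted as G
    for site in sites:
        frac = site.fractions.get(group, 0.0)
        if frac > 0:
            edited = rng.random(count) < frac
            reads[edited, site.position - 1] = ord("G")
    # per-base sequencing error on the insert: substitute a different base
    if truth.error_rate > 0:
        err = rng.random((count, L)) < truth.error_rate
        n_err = int(err.sum())
        if n_err:
            idx = _BASE_INDEX[reads[:, :L][err]]
            shift = rng.integers(1, 4, size=n_err)
            reads[:, :L][err] = _BASES[(idx + shift) % 4]
    # 3' adapter, then pad to the raw read length
    adapter = np.frombuffer(truth.adapter.encode(), dtype=np.uint8)
    tail = np.empty(rl - L, dtype=np.uint8)
    na = min(len(adapter), rl - L)
    tail[:na] = adapter[:na]
    tail[na:] = ord("A")
    reads[:, L:] = tail
    return reads


def simulate_sample_reads(
    truth: SimulationTruth,
    reference: MirnaReference,
    sample_id: str,
    design: SampleDesign,
    depth: int | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> ReadSet:
    """Raw 50 nt reads for one sample: insert + edits + errors + adapter.

    ``seed`` defaults to the per-sample seed derived from the truth's
    master seed and the sample's index in the design.
    """
    if sample_id not in design.sample_ids:
        raise KeyError(f"unknown sample id: {sample_id}")
    if depth is None:
        depth = 100_000
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if seed is None:
        seed = sample_seed(truth.master_seed, design.sample_ids.index(sample_id))
    rng = np.random.default_rng(seed)
    group = design.group_of(sample_id)
    counts = simulate_sample_counts(truth, reference, group, depth, rng)
    blocks = []
    for mid, c in zip(reference.ids, counts):
        if c == 0:
            continue
        blocks.append(
            _simulate_mirna_reads(
                reference.sequence(mid), int(c), truth.sites_of(mid),
                group, truth, rng,
            )
        )
    if blocks:
        mat = np.concatenate(blocks, axis=0)
        rng.shuffle(mat, axis=0)
        seqs = [row.tobytes().decode() for row in mat]
    else:
        seqs = []
    return ReadSet(sample_id, seqs, None)


def simulate_study(
    truth: SimulationTruth,
    reference: MirnaReference,
    design: SampleDesign,
    depth: int = 100_000,
) -> dict[str, ReadSet]:
    """Reads for every sample in the design, per-sample seeds derived."""
    return {
        sid: simulate_sample_reads(truth, reference, sid, design, depth)
        for sid in design.sample_ids
    }


# ---------------------------------------------------------------------------
# Sanger clone simulation (validation arm of the study)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedCloneEdit:
    clone_id: str
    position: int  # 1-based in the reference insert
    ref_base: str
    observed_base: str  # reference-strand convention


def simulate_clones(
    reference_seq: str,
    n_clones: int,
    edit_probability: float = 0.3,
    vector_length: tuple[int, int] = (150, 400),
    seed: int = 0,
    animals: Sequence[tuple[str, str, int]] | None = None,
    a_to_g_only: bool = True,
) -> tuple[list[CloneSequence], list[PlantedCloneEdit]]:
    """Synthetic plasmid clones: vector + miRNA insert (either strand) + vector.

    Each clone carries the insert in a random orientation; with probability
    ``edit_probability`` one planted substitution is introduced (an A>G
    edit at a random A when ``a_to_g_only``, else any substitution).
    Returns the clones and the planted truth in reference-strand
    coordinates.
    """
    rng = np.random.default_rng(seed)
    if animals is None:
        animals = [("rat1", "M", 3)]
    clones: list[CloneSequence] = []
    truth: list[PlantedCloneEdit] = []
    per_animal = {a[0]: 0 for a in animals}
    for i in range(n_clones):
        animal_id, sex, age = animals[i % len(animals)]
        per_animal[animal_id] += 1
        insert = reference_seq
        planted = None
        if rng.random() < edit_probability:
            if a_to_g_only:
                a_pos = [p for p, b in enumerate(insert) if b == "A"]
                if not a_pos:
                    raise ValueError("reference has no A to edit")
                p = int(a_pos[rng.integers(len(a_pos))])
                obs = "G"
            else:
                p = int(rng.integers(len(insert)))
                others = [b for b in "ACGT" if b != insert[p]]
                obs = others[int(rng.integers(3))]
            insert = insert[:p] + obs + insert[p + 1:]
            planted = (p + 1, reference_seq[p], obs)
        if rng.random() < 0.5:
            insert = revcomp(insert)
        left = _random_sequence(rng, int(rng.integers(*vector_length)))
        right = _random_sequence(rng, int(rng.integers(*vector_length)))
        clone = CloneSequence(
            animal_id=animal_id,
            sex=sex,
            age_months=age,
            colony_id=f"c{per_animal[animal_id]}",
            sequence=left + insert + right,
        )
        clones.append(clone)
        if planted is not None:
            truth.append(PlantedCloneEdit(clone.clone_id, *planted))
    return clones, truth
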