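"""Editing validation in Sanger-sequenced miRNA clones.

Each clone is a plasmid sequence (vector + insert) carrying one mature
miRNA, in either orientation. The insert is located by an ungapped
sliding-window identity scan of the reference (and its reverse
complement) across the clone; substitutions are then called in
reference coordinates with reference-strand bases — an A-to-I edit
cloned on the antisense strand appears as a C on the clone and is
complemented back to G before reporting (the A-I to G-C signature).

Ungapped alignment is deliberate: the inserts are short and an indel
inside a ~22 nt insert would make per-position editing calls
meaningless, so clones with apparent indels simply fail the identity
threshold and are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import CloneSequence, in_seed, revcomp

FORWARD = "forward"
REVERSE = "reverse_complement"

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class InsertAlignment:
    """Located miRNA insert within one clone (ungapped, full-length)."""

    clone: CloneSequence
    ref_seq: str
    orientation: str  # forward | reverse_complement
    offset: int  # 0-based start of the insert window in the clone
    identity: float
    clone_window: str  # clone bases over the insert window, clone strand

    def observed_reference_strand(self) -> str:
        """Clone window expressed on the reference strand."""
        if self.orientation == FORWARD:
            return self.clone_window
        return revcomp(self.clone_window)


def _window_identities(clone: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Identity of every length-L clone window against ref (uint8 arrays)."""
    L = len(ref)
    windows = np.lib.stride_tricks.sliding_window_view(clone, L)
    return (windows == ref).mean(axis=1)


def locate_insert(
    clone: CloneSequence,
    reference_seq: str,
    min_identity: float = 0.8,
) -> InsertAlignment | None:
    """Find the best ungapped placement of the reference in the clone.

    Scans the reference and its reverse complement across every clone
    offset; the best window by identity wins, with forward preferred on
    an exact tie. Returns None (insert not found) when no window reaches
    ``min_identity``.
    """
    if len(reference_seq) < 17:
        raise ValueError("reference must be at least 17 nt")
    L = len(reference_seq)
    if len(clone.sequence) < L:
        return None
    carr = np.frombuffer(clone.sequence.encode(), dtype=np.uint8)
    fwd = np.frombuffer(reference_seq.encode(), dtype=np.uint8)
    rev = np.frombuffer(revcomp(reference_seq).encode(), dtype=np.uint8)
    id_f = _window_identities(carr, fwd)
    id_r = _window_identities(carr, rev)
    best_f, best_r = id_f.max(), id_r.max()
    if max(best_f, best_r) < min_identity:
        return None
    orientation = FORWARD if best_f >= best_r else REVERSE
    ids = id_f if orientation == FORWARD else id_r
    offset = int(ids.argmax())
    return InsertAlignment(
        clone=clone,
        ref_seq=reference_seq,
        orientation=orientation,
        offset=offset,
        identity=float(ids[offset]),
        clone_window=clone.sequence[offset: offset + L],
    )


@dataclass(frozen=True)
class SubstitutionCall:
    """A clone/reference disagreement in reference-strand coordinates."""

    animal_id: str
    sex: str
    age_months: int
    colony_id: str
    clone_id: str
    position: int  # 1-based in the reference
    ref_base: str
    observed_base: str  # reference-strand convention
    is_a_to_g: bool
    in_seed: bool


def call_clone_substitutions(alignment: InsertAlignment) -> list[SubstitutionCall]:
    """Report every aligned mismatch in reference coordinates.

    Reverse-orientation observations are complemented back onto the
    reference strand before comparison, so a planted A>G edit yields the
    same call regardless of the cloned strand.
    """
    observed = alignment.observed_reference_strand()
    clone = alignment.clone
    calls = []
    for i, (ref_b, obs_b) in enumerate(zip(alignment.ref_seq, observed)):
        if obs_b == ref_b:
            continue
        pos = i + 1
        calls.append(
            SubstitutionCall(
                animal_id=clone.animal_id,
                sex=clone.sex,
                age_months=clone.age_months,
                colony_id=clone.colony_id,
                clone_id=clone.clone_id,
                position=pos,
                ref_base=ref_b,
                observed_base=obs_b,
                is_a_to_g=(ref_b == "A" and obs_b == "G"),
                in_seed=in_seed(pos),
            )
        )
    return calls


def call_all_clones(
    clones: Sequence[CloneSequence],
    reference_seq: str,
    min_identity: float = 0.8,
) -> tuple[list[SubstitutionCall], list[str]]:
    """Locate and call every clone; returns (calls, not_found clone ids)."""
    calls: list[SubstitutionCall] = []
    not_found: list[str] = []
    for clone in clones:
        aln = locate_insert(clone, reference_seq, min_identity)
        if aln is None:
            not_found.append(clone.clone_id)
            continue
        calls.extend(call_clone_substitutions(aln))
    return calls, not_found


def calls_to_frame(calls: Iterable[SubstitutionCall]) -> pd.DataFrame:
    rows = [
        {
            "clone_id": c.clone_id,
            "animal_id": c.animal_id,
            "sex": c.sex,
            "age_months": c.age_months,
            "colony_id": c.colony_id,
            "position": c.position,
            "substitution": f"{c.ref_base}>{c.observed_base}",
            "is_a_to_g": c.is_a_to_g,
            "in_seed": c.in_seed,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "clone_id", "animal_id", "sex", "age_months", "colony_id",
            "position", "substitution", "is_a_to_g", "in_seed",
        ],
    ).astype({"position": int, "is_a_to_g": bool, "in_seed": bool})


@dataclass(frozen=True)
class SangerSummary:
    """Editing summary across clones.

    ``per_group``: per (sex, age) clone and call tallies (A>G and any
    substitution, seed vs non-seed). ``per_position``: call recurrence
    by reference position. ``per_animal``: colony counts, with animals
    under 3 colonies flagged (the study sequenced >= 3 per animal).
    """

    per_group: pd.DataFrame
    per_position: pd.DataFrame
    per_animal: pd.DataFrame


def summarize_clone_editing(
    calls: Sequence[SubstitutionCall],
    clones: Sequence[CloneSequence],
    min_recurrence: int = 1,
) -> SangerSummary:
    """Tabulate editing by group, position and animal.

    ``min_recurrence`` > 1 applies a concordance filter: a call is kept
    only when the same (position, observed base) occurs in at least that
    many colonies of the same animal (off by default; single clones
    cannot distinguish editing from PCR/cloning error).
    """
    if not clones:
        raise ValueError("need at least one clone")
    if min_recurrence > 1:
        key = lambda c: (c.animal_id, c.position, c.observed_base)
        tally: dict[tuple, set[str]] = {}
        for c in calls:
            tally.setdefault(key(c), set()).add(c.colony_id)
        calls = [c for c in calls if len(tally[key(c)]) >= min_recurrence]

    cframe = pd.DataFrame(
        {
            "clone_id": [c.clone_id for c in clones],
            "animal_id": [c.animal_id for c in clones],
            "sex": [c.sex for c in clones],
            "age_months": [c.age_months for c in clones],
        }
    )
    calls_df = calls_to_frame(calls)
    group_rows = []
    for (sex, age), sub in cframe.groupby(["sex", "age_months"], sort=True):
        gcalls = calls_df[
            (calls_df["sex"] == sex) & (calls_df["age_months"] == age)
        ]
        ag = gcalls[gcalls["is_a_to_g"]]
        group_rows.append(
            {
                "sex": sex,
                "age_months": age,
                "clones_sequenced": len(sub),
                "clones_with_a_to_g": ag["clone_id"].nunique(),
                "clones_with_any_substitution": gcalls["clone_id"].nunique(),
                "a_to_g_calls_seed": int(ag["in_seed"].sum()),
                "a_to_g_calls_nonseed": int((~ag["in_seed"]).sum()),
                "calls_seed": int(gcalls["in_seed"].sum()),
                "calls_nonseed": int((~gcalls["in_seed"]).sum()),
            }
        )
    per_group = pd.DataFrame(group_rows)

    if len(calls_df):
        per_position = (
            calls_df.groupby(["position", "substitution"], sort=True)
            .agg(
                n_calls=("clone_id", "size"),
                n_clones=("clone_id", "nunique"),
                n_animals=("animal_id", "nunique"),
                is_a_to_g=("is_a_to_g", "first"),
                in_seed=("in_seed", "first"),
            )
            .reset_index()
        )
    else:
        per_position = pd.DataFrame(
            columns=[
                "position", "substitution", "n_calls", "n_clones",
                "n_animals", "is_a_to_g", "in_seed",
            ]
        )

    per_animal = (
        cframe.groupby(["animal_id", "sex", "age_months"], sort=True)
        .agg(n_colonies=("clone_id", "size"))
        .reset_index()
    )
    per_animal["under_three_colonies"] = per_animal["n_colonies"] < 3
    flagged = per_animal.loc[per_animal["under_three_colonies"], "animal_id"]
    if len(flagged):
        warnings.warn(
            f"animals with fewer than 3 colonies: {flagged.tolist()}"
        )
    return SangerSummary(per_group, per_position, per_animal)
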