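"""Majority-vote consensus disorder annotation from per-residue predictor scores.

External per-residue disorder predictors (e.g. three Espritz flavours and two
IUPred flavours) each emit a probability-like score per residue.  Each track
is binarized at a per-predictor threshold (conventionally 0.5 for
probability-valued predictors) and a residue is called disordered when a
strict majority of tracks agrees; an exact tie on an even track count
resolves to ordered.  Contiguous disordered runs of at least ``min_len``
residues (default 30) are the "disordered domains" of the downstream
measures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class ScoreTrack:
    """Per-residue disorder scores for one predictor on one protein."""

    protein_id: str
    predictor_name: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or self.scores.size == 0:
            raise ValueError(
                f"track {self.predictor_name!r}/{self.protein_id!r}: "
                "scores must be a nonempty 1-D vector"
            )
        if np.any(self.scores < 0) or np.any(self.scores > 1):
            raise ValueError(
                f"track {self.predictor_name!r}/{self.protein_id!r}: "
                "scores must lie in [0, 1]"
            )


@dataclass
class ConsensusMask:
    """Binary per-residue disorder call after the majority vote."""

    protein_id: str
    mask: np.ndarray
    n_tracks: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 1 or self.mask.size == 0:
            raise ValueError(f"mask for {self.protein_id!r} must be a nonempty 1-D vector")


def binarize_track(
    track: ScoreTrack, threshold: float = 0.5, expected_length: int | None = None
) -> np.ndarray:
    """Residue i is called disordered iff score_i >= threshold (boundary inclusive)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if expected_length is not None and track.scores.size != expected_length:
        raise ValueError(
            f"track {track.predictor_name!r}/{track.protein_id!r}: length "
            f"{track.scores.size} does not match protein length {expected_length}"
        )
    return track.scores >= threshold


def consensus_mask(
    binary_tracks: Sequence[np.ndarray], protein_id: str = ""
) -> ConsensusMask:
    """Strict-majority vote over >=2 binarized tracks; even ties resolve to ordered."""
    if len(binary_tracks) < 2:
        raise ValueError("consensus requires at least 2 tracks")
    arr = np.asarray([np.asarray(t, dtype=bool) for t in binary_tracks])
    if len({t.shape for t in arr}) > 1:
        raise ValueError("all tracks must have the same length")
    votes = arr.sum(axis=0)
    mask = votes * 2 > arr.shape[0]
    return ConsensusMask(protein_id=protein_id, mask=mask, n_tracks=arr.shape[0])


def disorder_content(mask: ConsensusMask | np.ndarray) -> float:
    """Fraction of residues called disordered."""
    m = mask.mask if isinstance(mask, ConsensusMask) else np.asarray(mask, dtype=bool)
    if m.size == 0:
        raise ValueError("empty mask")
    return float(m.mean())


def find_disordered_domains(
    mask: ConsensusMask | np.ndarray, min_len: int = 30
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive disordered residues of length >= min_len.

    Returns 0-based half-open ``[start, end)`` intervals in ascending order.
    """
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    m = mask.mask if isinstance(mask, ConsensusMask) else np.asarray(mask, dtype=bool)
    padded = np.concatenate(([False], m, [False])).astype(np.int8)
    diffs = np.diff(padded)
    starts = np.flatnonzero(diffs == 1)
    ends = np.flatnonzero(diffs == -1)
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_len]


def build_consensus(
    tracks: Iterable[ScoreTrack],
    thresholds: Mapping[str, float] | float = 0.5,
    expected_length: int | None = None,
    track_groups: Mapping[str, str] | None = None,
) -> ConsensusMask:
    """Binarize a protein's tracks and take the majority vote.

    ``thresholds`` may be a single cut applied to every predictor or a
    per-predictor mapping.  With ``track_groups`` (predictor name -> group
    label), tracks are first combined within each group by strict majority
    and the final vote runs over the group-level calls — this supports
    reading the consensus as a vote over predictors rather than over
    individual tracks.
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("no tracks supplied")
    pid = tracks[0].protein_id
    if any(t.protein_id != pid for t in tracks):
        raise ValueError("all tracks must belong to one protein")

    def _cut(t: ScoreTrack) -> float:
        if isinstance(thresholds, Mapping):
            return thresholds.get(t.predictor_name, 0.5)
        return thresholds

    binarized = {
        t.predictor_name: binarize_track(t, _cut(t), expected_length) for t in tracks
    }
    if track_groups:
        grouped: dict[str, list[np.ndarray]] = {}
        for name, vec in binarized.items():
            grouped.setdefault(track_groups.get(name, name), []).append(vec)
        # within-group majority; a single-track group passes through unchanged
        layer = []
        for group in sorted(grouped):
            vecs = grouped[group]
            if len(vecs) == 1:
                layer.append(vecs[0])
            else:
                arr = np.asarray(vecs)
                layer.append(arr.sum(axis=0) * 2 > arr.shape[0])
        return consensus_mask(layer, protein_id=pid)
    return consensus_mask([binarized[k] for k in sorted(binarized)], protein_id=pid)


# ---------------------------------------------------------------------------
# score-table and run-list I/O


def read_scores(path: str | Path) -> dict[str, list[ScoreTrack]]:
    """Read a score TSV (protein_id, predictor, position, score; 0-based positions).

    One file may hold many tracks; within each track positions must cover
    0..L-1 exactly.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "predictor": str})
    required = {"protein_id", "predictor", "position", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"score table must have columns {sorted(required)}")
    out: dict[str, list[ScoreTrack]] = {}
    for (pid, predictor), sub in df.groupby(["protein_id", "predictor"], sort=True):
        sub = sub.sort_values("position")
        positions = sub["position"].to_numpy()
        if not np.array_equal(positions, np.arange(len(positions))):
            raise ValueError(
                f"track {predictor!r}/{pid!r}: positions must be 0..L-1 with no gaps"
            )
        out.setdefault(str(pid), []).append(
            ScoreTrack(str(pid), str(predictor), sub["score"].to_numpy(dtype=float))
        )
    return out


def write_scores(tracks: Iterable[ScoreTrack], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tpredictor\tposition\tscore\n")
        for t in tracks:
            for i, s in enumerate(t.scores):
                fh.write(f"{t.protein_id}\t{t.predictor_name}\t{i}\t{s:.6g}\n")


def write_run_list(
    masks: Iterable[ConsensusMask], path: str | Path, min_len: int = 1
) -> None:
    """Export consensus masks as BED-like runs (protein_id, start, end; 0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("protein_id\tstart\tend\n")
        for cm in masks:
            for s, e in find_disordered_domains(cm, min_len=min_len):
                fh.write(f"{cm.protein_id}\t{s}\t{e}\n")
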