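"""Synthetic proteome, score-track, compartment, and PPI-network generator.

The generator emulates the statistical structure the analysis assumes, with
full ground-truth bookkeeping so that pipeline estimates can be checked
against programmed parameters:

- every protein is a two-state chain of alternating ordered/disordered
  segments with geometric lengths; the expected disordered fraction of a
  protein is its compartment-dependent target content;
- residues are drawn from segment-specific compositions (disordered segments
  use a disorder-promoting composition: more charged/polar, less
  hydrophobic), so CH-CDF coordinates behave qualitatively like real data;
- each predictor track scores residues from beta distributions centred low
  on ordered and high on disordered residues, with per-track spread, so the
  majority vote is informative but not trivial;
- compartment-assigned proteins receive 1-3 labels (moonlighting
  multiplicity) and their compartments' programmed target contents;
- the PPI network is an expected-degree (Chung-Lu) graph whose node weights
  couple to true disorder content through a coupling parameter rho, so hubs
  are disorder-enriched when rho > 0.

Defaults are scaled-down study conditions: a 2000-protein non-nuclear pool
with baseline content 0.12, eight compartments with target contents between
0.12 and 0.36 (six of them enriched over baseline), moonlighting
multiplicity probabilities (0.785, 0.19, 0.025), five predictor tracks, and
rho = 0.8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

logger = logging.getLogger(__name__)

from . import data_io
from .data_io import COMPARTMENTS, ProteinRecord
from .disorder_consensus import ScoreTrack, write_scores

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# residue sampling weights (unnormalized) for ordered vs disordered segments;
# the disordered composition is enriched in P/E/S/K/Q/D/R/G and depleted in
# the bulky hydrophobics, mirroring the known disorder-promoting bias
_ORDERED_W = {
    "A": 8, "C": 3, "D": 5, "E": 5, "F": 5, "G": 7, "H": 2, "I": 7, "K": 5,
    "L": 10, "M": 3, "N": 4, "P": 4, "Q": 3, "R": 4, "S": 6, "T": 6, "V": 8,
    "W": 2, "Y": 4,
}
_DISORDERED_W = {
    "A": 7, "C": 1, "D": 7, "E": 10, "F": 2, "G": 8, "H": 2, "I": 3, "K": 9,
    "L": 4, "M": 2, "N": 4, "P": 9, "Q": 6, "R": 6, "S": 10, "T": 6, "V": 4,
    "W": 1, "Y": 2,
}


def _composition(weights: Mapping[str, float]) -> np.ndarray:
    w = np.array([weights[a] for a in AMINO_ACIDS], dtype=float)
    return w / w.sum()


DEFAULT_TRACKS = ("espritz_d", "espritz_n", "espritz_x", "iupred_l", "iupred_s")

DEFAULT_COMPARTMENT_SIZES = {
    "nucleolus": 300,
    "chromatin": 250,
    "nuclear_speckle": 200,
    "pml_body": 100,
    "cajal_body": 80,
    "nuclear_lamina": 80,
    "nuclear_pore": 60,
    "perinucleolar": 40,
}

# programmed expected-content targets; six compartments are enriched over the
# baseline while lamina and pore are programmed null (the two compartments
# where nuclear disorder enrichment is absent or at best borderline)
DEFAULT_COMPARTMENT_CONTENT = {
    "nucleolus": 0.25,
    "chromatin": 0.33,
    "nuclear_speckle": 0.36,
    "pml_body": 0.31,
    "cajal_body": 0.30,
    "nuclear_lamina": 0.12,
    "nuclear_pore": 0.12,
    "perinucleolar": 0.36,
}


@dataclass
class SyntheticSpec:
    """Programmed conditions for one synthetic study."""

    n_nonnuclear: int = 2000
    compartment_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COMPARTMENT_SIZES)
    )
    compartment_content: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPARTMENT_CONTENT)
    )
    baseline_content: float = 0.12
    multiplicity_probs: tuple[float, float, float] = (0.785, 0.19, 0.025)
    #: optional tilt of multiplicity towards multi-domain proteins
    multiplicity_domain_coupling: float = 0.0
    annotated_fraction: float = 0.45
    mean_disordered_segment: float = 40.0
    length_log_mean: float = 6.0  # lognormal location (exp(6) ~ 400 residues)
    length_log_sigma: float = 0.45
    min_length: int = 50
    max_length: int = 3000
    track_names: tuple[str, ...] = DEFAULT_TRACKS
    ordered_score_mean: float = 0.25
    disordered_score_mean: float = 0.75
    track_concentrations: tuple[float, ...] = (8.0, 9.0, 10.0, 11.0, 12.0)
    #: expected-degree baseline of the Chung-Lu network
    expected_degree: float = 8.0
    #: disorder-degree coupling in [-1, 1]
    rho: float = 0.8

    def __post_init__(self) -> None:
        if abs(sum(self.multiplicity_probs) - 1.0) > 1e-9:
            raise ValueError("multiplicity probabilities must sum to 1")
        if any(p < 0 for p in self.multiplicity_probs):
            raise ValueError("multiplicity probabilities must be non-negative")
        if not -1 <= self.rho <= 1:
            raise ValueError(f"rho must lie in [-1, 1], got {self.rho}")
        if self.mean_disordered_segment < 1:
            raise ValueError("mean disordered segment length must be >= 1")
        contents = [self.baseline_content, *self.compartment_content.values()]
        for c in contents:
            if not 0 <= c < 1:
                raise ValueError(
                    f"target contents must lie in [0, 1); got {c} (a fully "
                    "disordered target is infeasible for a two-state chain)"
                )
        unknown = set(self.compartment_sizes) - set(COMPARTMENTS)
        unknown |= set(self.compartment_content) - set(COMPARTMENTS)
        if unknown:
            raise ValueError(f"unknown compartments in spec: {sorted(unknown)}")
        if len(self.track_names) != len(self.track_concentrations):
            raise ValueError("one concentration per track is required")


@dataclass
class GroundTruth:
    """Programmed per-protein and per-compartment facts for recovery tests."""

    true_mask: dict[str, np.ndarray]
    true_content: dict[str, float]
    true_n_domains: dict[str, int]
    target_content: dict[str, float]
    compartment_enriched: dict[str, bool]
    expected_degree: dict[str, float] = field(default_factory=dict)


@dataclass
class SyntheticProteome:
    records: list[ProteinRecord]
    tracks: dict[str, list[ScoreTrack]]
    compartment_map: dict[str, tuple[frozenset[str], str]]
    ground_truth: GroundTruth
    spec: SyntheticSpec

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit FASTA / score TSV / compartment TSV in the formats data_io reads."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "proteome.fasta",
            "scores": outdir / "scores.tsv",
            "compartments": outdir / "compartments.tsv",
        }
        data_io.write_fasta(self.records, paths["fasta"])
        all_tracks = [t for rec in self.records for t in self.tracks[rec.protein_id]]
        write_scores(all_tracks, paths["scores"])
        data_io.write_compartments(self.compartment_map, paths["compartments"])
        return paths


def _segment_mask(length: int, p: float, mean_dis: float, rng: np.random.Generator) -> np.ndarray:
    """Two-state ordered/disordered chain with geometric segments, E[fraction]=p."""
    if p <= 0:
        return np.zeros(length, dtype=bool)
    mean_ord = mean_dis * (1 - p) / p
    mask = np.empty(length, dtype=bool)
    pos = 0
    state = bool(rng.random() < p)
    while pos < length:
        mean = mean_dis if state else mean_ord
        seg = int(rng.geometric(min(1.0, 1.0 / max(mean, 1.0))))
        end = min(pos + seg, length)
        mask[pos:end] = state
        pos = end
        state = not state
    return mask


def _draw_length(spec: SyntheticSpec, rng: np.random.Generator) -> int:
    L = int(np.exp(rng.normal(spec.length_log_mean, spec.length_log_sigma)))
    return int(np.clip(L, spec.min_length, spec.max_length))


def _score_tracks(
    pid: str, mask: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator
) -> list[ScoreTrack]:
    tracks = []
    for name, conc in zip(spec.track_names, spec.track_concentrations):
        mu = np.where(mask, spec.disordered_score_mean, spec.ordered_score_mean)
        a = mu * conc
        b = (1 - mu) * conc
        tracks.append(ScoreTrack(pid, name, rng.beta(a, b)))
    return tracks


def generate_proteome(spec: SyntheticSpec, seed: int) -> SyntheticProteome:
    """Generate the full synthetic proteome; deterministic given (spec, seed)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    comp_names = [c for c in COMPARTMENTS if spec.compartment_sizes.get(c, 0) > 0]
    comp_weights = np.array([spec.compartment_sizes[c] for c in comp_names], dtype=float)
    comp_weights /= comp_weights.sum() if comp_weights.size else 1.0

    records: list[ProteinRecord] = []
    tracks: dict[str, list[ScoreTrack]] = {}
    comp_map: dict[str, tuple[frozenset[str], str]] = {}
    truth = GroundTruth(
        true_mask={},
        true_content={},
        true_n_domains={},
        target_content={},
        compartment_enriched={
            c: spec.compartment_content.get(c, spec.baseline_content)
            > spec.baseline_content
            for c in comp_names
        },
    )

    def _make_protein(pid: str, target: float) -> None:
        L = _draw_length(spec, rng)
        mask = _segment_mask(L, target, spec.mean_disordered_segment, rng)
        seq = np.where(
            mask,
            rng.choice(AMINO_ACIDS, size=L, p=_composition(_DISORDERED_W)),
            rng.choice(AMINO_ACIDS, size=L, p=_composition(_ORDERED_W)),
        )
        records.append(ProteinRecord(protein_id=pid, sequence="".join(seq)))
        tracks[pid] = _score_tracks(pid, mask, spec, rng)
        truth.true_mask[pid] = mask
        truth.true_content[pid] = float(mask.mean())
        # true domains: maximal disordered runs >= 30
        padded = np.concatenate(([False], mask, [False])).astype(np.int8)
        d = np.diff(padded)
        runs = np.flatnonzero(d == -1) - np.flatnonzero(d == 1)
        truth.true_n_domains[pid] = int(np.sum(runs >= 30))
        truth.target_content[pid] = target

    for i in range(spec.n_nonnuclear):
        _make_protein(f"NN{i:05d}", spec.baseline_content)

    counter = 0
    for ci, comp in enumerate(comp_names):
        for _ in range(spec.compartment_sizes[comp]):
            pid = f"NP{counter:05d}"
            counter += 1
            target = spec.compartment_content.get(comp, spec.baseline_content)
            _make_protein(pid, target)
            # moonlighting multiplicity, optionally tilted towards proteins
            # with many disordered domains
            probs = np.array(spec.multiplicity_probs, dtype=float)
            if spec.multiplicity_domain_coupling:
                tilt = spec.multiplicity_domain_coupling * min(
                    truth.true_n_domains[pid], 5
                ) / 5.0
                probs = probs * np.exp(tilt * np.arange(3))
                probs /= probs.sum()
            mult = 1 + int(rng.choice(3, p=probs))
            labels = {comp}
            others = [c for c in comp_names if c != comp]
            if others and mult > 1:
                w = np.array(
                    [spec.compartment_sizes[c] for c in others], dtype=float
                )
                w /= w.sum()
                extra = rng.choice(
                    len(others), size=min(mult - 1, len(others)), replace=False, p=w
                )
                labels.update(others[j] for j in extra)
            prov = "annotated" if rng.random() < spec.annotated_fraction else "predicted"
            comp_map[pid] = (frozenset(labels), prov)

    return SyntheticProteome(
        records=records,
        tracks=tracks,
        compartment_map=comp_map,
        ground_truth=truth,
        spec=spec,
    )


def generate_network(
    proteome: SyntheticProteome, spec: SyntheticSpec, seed: int
) -> tuple[list[tuple[str, str]], dict[str, float]]:
    """Chung-Lu expected-degree network coupled to true disorder content.

    Node weight = expected_degree * (1 + rho * standardized true content),
    floored at a small positive value; edge probability w_i * w_j / sum(w),
    clipped at 1 (with a log notice when clipping occurs).  Returns the
    sorted edge list and the per-node expected degrees (ground truth).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    ids = [r.protein_id for r in proteome.records]
    content = np.array([proteome.ground_truth.true_content[p] for p in ids])
    z = (content - content.mean()) / (content.std() or 1.0)
    w = spec.expected_degree * (1.0 + spec.rho * z)
    w = np.maximum(w, 0.05)
    total = w.sum()
    n = len(ids)
    edges: list[tuple[str, str]] = []
    n_clipped = 0
    # upper-triangle Bernoulli draws, chunked by row block to bound memory
    block = max(1, int(4e6 // max(n, 1)))
    for start in range(0, n, block):
        stop = min(start + block, n)
        p = np.outer(w[start:stop], w) / total
        if np.any(p > 1):
            n_clipped += int(np.sum(p > 1))
            p = np.minimum(p, 1.0)
        u = rng.random(p.shape)
        hit = u < p
        rows, cols = np.nonzero(hit)
        for r, c in zip(rows, cols):
            i = start + r
            if c > i:  # keep the strict upper triangle only
                a, b = ids[i], ids[c]
                edges.append((a, b) if a < b else (b, a))
    if n_clipped:
        logger.info("Chung-Lu edge probabilities clipped at 1 for %d pairs", n_clipped)
    edges = sorted(set(edges))
    expected = {pid: float(wi) for pid, wi in zip(ids, w)}
    proteome.ground_truth.expected_degree = expected
    return edges, expected
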