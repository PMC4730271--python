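"""Group-level disorder measures and the co-localization (moonlighting) analysis.

Per protein, the ingredients are the consensus disorder content and the
disordered domains (consensus-disordered runs of >= ``min_len`` residues).
Per protein set, six measures summarise the abundance of disorder:

- disorder-content quantiles and mean (box-plot style: q10/q25/median/q75/q90);
- %DisProt — fraction of proteins with content >= 0.4 (boundary inclusive);
- %DisDomProt — fraction with at least one disordered domain;
- %3+DisDomProt / %5+DisDomProt — at least three / five disordered domains;
- fraction with no disordered domain (the complement of %DisDomProt);
- %DisDom1K — disordered domains per 1000 residues.  By default the group is
  pooled (total domains over total residues); a mean of per-protein rates is
  available via ``disdom1k_mode="mean"``.

The moonlighting table groups compartment-assigned proteins by how many
compartments they carry (1, 2 or 3; proteins in more than three compartments
are excluded as too rare to summarise).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .disorder_consensus import ConsensusMask, disorder_content, find_disordered_domains

#: content cut-off above which a protein counts as disordered (%DisProt)
DISPROT_CONTENT_THRESHOLD = 0.4
#: minimum run length for a disordered domain, in residues
DISORDERED_DOMAIN_MIN_LEN = 30


@dataclass
class DisorderProfile:
    """Per-protein disorder ingredients feeding the group measures."""

    protein_id: str
    length: int
    content: float
    domain_lengths: tuple[int, ...]

    @property
    def n_domains(self) -> int:
        return len(self.domain_lengths)


@dataclass
class GroupSummary:
    """The disorder measures aggregated over one protein set."""

    group: str
    n_proteins: int
    content_q10: float
    content_q25: float
    content_median: float
    content_q75: float
    content_q90: float
    content_mean: float
    pct_disprot: float
    pct_disdomprot: float
    pct_3plus: float
    pct_5plus: float
    pct_nodom: float
    disdom1k: float


def protein_profile(
    mask: ConsensusMask, min_len: int = DISORDERED_DOMAIN_MIN_LEN
) -> DisorderProfile:
    domains = find_disordered_domains(mask, min_len=min_len)
    return DisorderProfile(
        protein_id=mask.protein_id,
        length=int(mask.mask.size),
        content=disorder_content(mask),
        domain_lengths=tuple(e - s for s, e in domains),
    )


def group_summary(
    profiles: Sequence[DisorderProfile],
    group: str = "",
    content_threshold: float = DISPROT_CONTENT_THRESHOLD,
    disdom1k_mode: str = "pooled",
) -> GroupSummary:
    if not profiles:
        raise ValueError(f"group {group!r}: cannot summarise an empty protein set")
    if disdom1k_mode not in ("pooled", "mean"):
        raise ValueError(f"disdom1k_mode must be 'pooled' or 'mean', got {disdom1k_mode!r}")
    contents = np.array([p.content for p in profiles])
    ndoms = np.array([p.n_domains for p in profiles])
    lengths = np.array([p.length for p in profiles])
    n = len(profiles)
    q10, q25, q50, q75, q90 = np.quantile(contents, [0.10, 0.25, 0.50, 0.75, 0.90])
    if disdom1k_mode == "pooled":
        disdom1k = 1000.0 * ndoms.sum() / lengths.sum()
    else:
        disdom1k = float(np.mean(1000.0 * ndoms / lengths))
    return GroupSummary(
        group=group,
        n_proteins=n,
        content_q10=float(q10),
        content_q25=float(q25),
        content_median=float(q50),
        content_q75=float(q75),
        content_q90=float(q90),
        content_mean=float(contents.mean()),
        pct_disprot=100.0 * float(np.mean(contents >= content_threshold)),
        pct_disdomprot=100.0 * float(np.mean(ndoms >= 1)),
        pct_3plus=100.0 * float(np.mean(ndoms >= 3)),
        pct_5plus=100.0 * float(np.mean(ndoms >= 5)),
        pct_nodom=100.0 * float(np.mean(ndoms == 0)),
        disdom1k=float(disdom1k),
    )


#: highest co-localization multiplicity that is summarised
MAX_MULTIPLICITY = 3


def multiplicity_summary(
    profiles: Iterable[DisorderProfile],
    compartments: Mapping[str, frozenset[str]],
) -> pd.DataFrame:
    """Disorder measures keyed by co-localization multiplicity (1, 2, 3).

    ``compartments`` maps protein_id -> set of compartment labels.  Proteins
    without labels, without a profile, or assigned to more than three
    compartments are excluded.
    """
    by_mult: dict[int, list[DisorderProfile]] = {}
    for prof in profiles:
        labels = compartments.get(prof.protein_id)
        if not labels:
            continue
        mult = len(labels)
        if mult > MAX_MULTIPLICITY:
            continue
        by_mult.setdefault(mult, []).append(prof)
    rows = []
    for mult in sorted(by_mult):
        gs = group_summary(by_mult[mult], group=f"multiplicity_{mult}")
        rows.append(
            {
                "multiplicity": mult,
                "n_proteins": gs.n_proteins,
                "pct_3plus": gs.pct_3plus,
                "pct_5plus": gs.pct_5plus,
                "content_q25": gs.content_q25,
                "content_median": gs.content_median,
                "content_q75": gs.content_q75,
                "content_mean": gs.content_mean,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "multiplicity",
            "n_proteins",
            "pct_3plus",
            "pct_5plus",
            "content_q25",
            "content_median",
            "content_q75",
            "content_mean",
        ],
    )


def summaries_to_frame(summaries: Iterable[GroupSummary]) -> pd.DataFrame:
    """Tabulate group summaries, one row per group."""
    return pd.DataFrame([vars(s) for s in summaries])
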