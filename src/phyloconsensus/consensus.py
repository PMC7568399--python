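"""Weighted consensus profiles and candidate substitution calling.

Given a family alignment and per-sequence weights, this module computes for
every query position the weighted frequency of each residue in that
alignment column, then nominates *candidate sites*: positions where the
most frequent residue (the consensus residue) differs from the query's and
its weighted frequency exceeds a cutoff (40% by default).

Positions are numbered 1-based along the ungapped query, so a site is
labelled in the familiar mutation notation, e.g. ``D17V`` — query aspartate
at position 17 proposed to become valine.

Gap handling: the weighted gap fraction at a column is tracked separately
as ``gap_mass`` and, by default, the cutoff test is made against the total
weight including gaps, so a residue must be frequent absolutely, not merely
among the sequences that happen to align there.  Set
``cutoff_basis="residues"`` to test against non-gap weight instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .family_io import AMINO_ACIDS, GAP, AlignedFamily
from .weighting import SequenceWeights

_RESIDUE_INDEX = {aa: k for k, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class ConsensusProfile:
    """Per-query-position weighted residue frequencies.

    ``frequencies`` has one row per query position (1-based positions in
    ``positions``) and one column per residue in
    :data:`~phyloconsensus.family_io.AMINO_ACIDS`; ``gap_mass`` holds the
    weighted gap fraction; ``column_index`` maps each query position to its
    0-based alignment column.  Row sums plus gap mass equal 1 (X residues
    are folded into gap_mass: unknown residues support no consensus).
    """

    positions: tuple[int, ...]
    query_residues: tuple[str, ...]
    column_index: tuple[int, ...]
    frequencies: np.ndarray
    gap_mass: np.ndarray

    def __post_init__(self):
        freq = np.asarray(self.frequencies, float)
        gaps = np.asarray(self.gap_mass, float)
        object.__setattr__(self, "frequencies", freq)
        object.__setattr__(self, "gap_mass", gaps)
        totals = freq.sum(axis=1) + gaps
        if not np.allclose(totals, 1.0, atol=1e-9):
            raise ValidationError("residue frequencies + gap mass must sum to 1")

    def __len__(self):
        return len(self.positions)

    def frequency(self, position: int, residue: str) -> float:
        row = self.positions.index(position)
        return float(self.frequencies[row, _RESIDUE_INDEX[residue]])

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: one row per query position with the top residue."""
        top = self.frequencies.argmax(axis=1)
        return pd.DataFrame(
            {
                "position": self.positions,
                "query_res": self.query_residues,
                "top_res": [AMINO_ACIDS[k] for k in top],
                "top_freq_pct": 100.0 * self.frequencies.max(axis=1),
                "gap_mass": self.gap_mass,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass(frozen=True)
class CandidateSite:
    """One proposed substitution: query residue → consensus residue."""

    position: int
    query_residue: str
    consensus_residue: str
    frequency: float  # percent
    filter_status: str = "candidate"
    distance_to_active_site: float | None = None
    bonds: tuple = ()

    def __post_init__(self):
        if self.consensus_residue == self.query_residue:
            raise ValidationError("consensus residue equals query residue")

    @property
    def label(self) -> str:
        return f"{self.query_residue}{self.position}{self.consensus_residue}"

    def with_status(self, status: str, **kw) -> "CandidateSite":
        return replace(self, filter_status=status, **kw)


def column_frequencies(
    family: AlignedFamily, weights: SequenceWeights
) -> ConsensusProfile:
    """Weighted residue frequencies at every non-gap query column.

    Only sequences present in ``weights`` contribute (the outgroup, absent
    from the weights, is thereby excluded).  Frequencies are normalized by
    the total participating weight, so they are invariant to weight scale.
    """
    weighted_ids = [sid for sid in family.ids if sid in weights.weights]
    if not weighted_ids:
        raise ValidationError("no overlap between weights and family ids")
    total_w = sum(weights[sid] for sid in weighted_ids)

    query = family.query_sequence
    positions, query_res, columns = [], [], []
    pos = 0
    for col, ch in enumerate(query):
        if ch != GAP:
            pos += 1
            positions.append(pos)
            query_res.append(ch)
            columns.append(col)
    if not positions:
        raise ValidationError("query sequence is all gaps")

    freq = np.zeros((len(positions), len(AMINO_ACIDS)))
    gap_mass = np.zeros(len(positions))
    seqs = {sid: family.sequence(sid) for sid in weighted_ids}
    for row, col in enumerate(columns):
        for sid in weighted_ids:
            w = weights[sid] / total_w
            ch = seqs[sid][col]
            idx = _RESIDUE_INDEX.get(ch)
            if idx is None:  # gap or 'X': mass that supports no consensus
                gap_mass[row] += w
            else:
                freq[row, idx] += w
    return ConsensusProfile(
        tuple(positions), tuple(query_res), tuple(columns), freq, gap_mass
    )


def consensus_sequence(profile: ConsensusProfile) -> str:
    """The plain consensus string over query positions (query residue kept
    where no residue wins or the top residue ties)."""
    out = []
    for row, q in enumerate(profile.query_residues):
        f = profile.frequencies[row]
        best = f.max()
        winners = np.flatnonzero(f == best)
        out.append(AMINO_ACIDS[winners[0]] if len(winners) == 1 and best > 0 else q)
    return "".join(out)


def candidate_sites(
    profile: ConsensusProfile,
    family: AlignedFamily,
    cutoff: float = 40.0,
    cutoff_basis: str = "total",
) -> list[CandidateSite]:
    """Nominate substitutions where the consensus beats the query.

    A site is emitted at query position p iff the most frequent residue c*
    (gaps excluded) differs from the query residue and its weighted
    frequency strictly exceeds ``cutoff`` percent.  Ties for the top residue
    are treated as no consensus and emit nothing.  Sites are returned sorted
    by descending frequency, with ``filter_status == "candidate"``.

    ``cutoff_basis``: ``"total"`` measures frequency against all weight
    including gap mass (default, conservative); ``"residues"`` against
    non-gap weight only.
    """
    if not (0.0 < cutoff < 100.0):
        raise ValidationError("cutoff must lie strictly between 0 and 100")
    if cutoff_basis not in ("total", "residues"):
        raise ValidationError(f"unknown cutoff_basis '{cutoff_basis}'")
    sites = []
    for row, pos in enumerate(profile.positions):
        f = profile.frequencies[row]
        best = f.max()
        if best <= 0:
            continue
        winners = np.flatnonzero(f == best)
        if len(winners) != 1:
            continue  # ambiguous consensus
        c_star = AMINO_ACIDS[winners[0]]
        q = profile.query_residues[row]
        if c_star == q:
            continue
        denom = 1.0 if cutoff_basis == "total" else 1.0 - profile.gap_mass[row]
        if denom <= 0:
            continue
        pct = 100.0 * best / denom
        if pct > cutoff:
            sites.append(CandidateSite(pos, q, c_star, pct))
    sites.sort(key=lambda s: (-s.frequency, s.position))
    return sites


def sites_to_frame(sites: list[CandidateSite]) -> pd.DataFrame:
    """Candidate table in the layout used for reporting single mutants."""
    return pd.DataFrame(
        {
            "label": [s.label for s in sites],
            "position": [s.position for s in sites],
            "query_res": [s.query_residue for s in sites],
            "consensus_res": [s.consensus_residue for s in sites],
            "frequency_pct": [round(s.frequency, 2) for s in sites],
            "filter_status": [s.filter_status for s in sites],
            "distance_A": [
                None if s.distance_to_active_site is None
                else round(s.distance_to_active_site, 2)
                for s in sites
            ],
            "n_bonds": [len(s.bonds) for s in sites],
        }
    )
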