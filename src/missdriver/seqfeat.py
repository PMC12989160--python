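"""Sequence-derived per-mutation features.

Feature families: physicochemical property changes (delta-P over an AAindex1
property set), AAindex2 substitution-matrix values, AAindex3 neighbor
contact-potential differences, six-class neighborhood composition in a
13-residue window, gapped di/tri-peptide motif odds ratios, PSSM-derived
scores, and site/window statistics over per-residue tracks (conservation,
disorder).

Missing features are returned as ``nan`` — downstream imputation is an
explicit pipeline step, never silent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._aminoacids import SIX_CLASS_ORDER, SIX_CLASSES
from .io import (
    AAindexEntry,
    MutationRecord,
    PSSMProfile,
    ProteinSequence,
    ResidueTrack,
    read_aaindex,
)

NAN = float("nan")


@dataclass(frozen=True)
class WindowConfig:
    """Symmetric sequence window: ``flank`` residues on each side of the site
    (default 6, total window 13)."""

    flank: int = 6

    def __post_init__(self) -> None:
        if self.flank < 1:
            raise ValueError(f"flank must be >= 1, got {self.flank}")

    def bounds(self, pos: int, length: int) -> tuple[int, int]:
        """In-bounds 1-based [start, end] of the window centred at ``pos``."""
        return max(1, pos - self.flank), min(length, pos + self.flank)


class PropertySet:
    """An ordered collection of named AAindex1-style 20-value tables.

    The reference configuration uses 152 physical, chemical, energetic and
    conformational parameters; the list is configurable and loaded from
    AAindex-format files. A single bundled property (Kyte-Doolittle
    hydropathy, KYTJ820101) ships with the package for demos and tests.
    """

    def __init__(self, entries: Sequence[AAindexEntry]):
        for e in entries:
            if e.kind != "index1":
                raise ValueError(f"{e.accession}: PropertySet needs index1 entries")
        self.entries: dict[str, AAindexEntry] = {e.accession: e for e in entries}
        if len(self.entries) != len(entries):
            raise ValueError("duplicate accessions in property set")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.values())

    @classmethod
    def from_files(cls, paths: Sequence[str | Path]) -> "PropertySet":
        entries: list[AAindexEntry] = []
        for p in paths:
            entries.extend(read_aaindex(p, kind="index1"))
        return cls(entries)

    @classmethod
    def bundled(cls) -> "PropertySet":
        data = Path(__file__).parent / "data" / "aaindex1_core.txt"
        return cls.from_files([data])


def delta_property(wt: str, mut: str, property_table: AAindexEntry) -> float:
    """Change in a physicochemical property on mutation: P(mut) - P(wt)."""
    if wt == "X" or mut == "X":
        return NAN
    try:
        return property_table.lookup(mut) - property_table.lookup(wt)
    except KeyError:
        return NAN


def substitution_matrix_feature(wt: str, mut: str, entry: AAindexEntry) -> float:
    """The (wt, mut) cell of an AAindex2 mutation matrix; nan when missing."""
    if wt == "X" or mut == "X":
        return NAN
    try:
        return entry.lookup(wt, mut)
    except KeyError:
        return NAN


def neighbor_contact_potential_delta(
    seq: ProteinSequence, pos: int, entry: AAindexEntry, mut: str
) -> tuple[float, float, float]:
    """Contact-potential changes of the mutation site's sequence neighbors.

    Returns (delta_N, delta_C, cp_LR):
      delta_N = CP(left_neighbor, mut) - CP(left_neighbor, wt)
      delta_C = CP(right_neighbor, mut) - CP(right_neighbor, wt)
      cp_LR   = CP(left_neighbor, right_neighbor), the pairing of the two
                flanking residues themselves.
    A terminal position yields nan for the absent side, never zero.
    """
    wt = seq.residue(pos)
    left = seq.residue(pos - 1) if pos > 1 else None
    right = seq.residue(pos + 1) if pos < len(seq) else None

    def cp(a: str | None, b: str | None) -> float:
        if a is None or b is None or "X" in (a, b):
            return NAN
        try:
            return entry.lookup(a, b)
        except KeyError:
            return NAN

    delta_n = cp(left, mut) - cp(left, wt)
    delta_c = cp(right, mut) - cp(right, wt)
    return delta_n, delta_c, cp(left, right)


def neighbor_composition(
    seq: ProteinSequence, pos: int, window: WindowConfig = WindowConfig()
) -> tuple[int, ...]:
    """Counts of window residues in the six physicochemical classes
    (aliphatic, sulfur, aromatic, polar, positive, negative).

    The mutation site itself is excluded; windows truncate at the termini,
    so the six counts sum to the number of in-bounds neighbors.
    """
    start, end = window.bounds(pos, len(seq))
    counts = dict.fromkeys(SIX_CLASS_ORDER, 0)
    for p in range(start, end + 1):
        if p == pos:
            continue
        res = seq.residue(p)
        for name in SIX_CLASS_ORDER:
            if res in SIX_CLASSES[name]:
                counts[name] += 1
                break
    return tuple(counts[name] for name in SIX_CLASS_ORDER)


# ---------------------------------------------------------------------------
# gapped di/tri-peptide motif odds ratios
# ---------------------------------------------------------------------------

# Pattern families as offsets relative to the mutation site (offset 0 = site).
# Di-peptides pair the site with a neighbor at gap 0/3/4; tri-peptides span
# the site and two neighbors, with and without a gap.
DEFAULT_MOTIF_FAMILIES: dict[str, tuple[int, ...]] = {
    "site_right0": (0, 1),
    "site_left0": (-1, 0),
    "site_right3": (0, 4),
    "site_left3": (-4, 0),
    "site_right4": (0, 5),
    "tri_adjacent": (-1, 0, 1),
    "tri_gapped": (-1, 0, 5),
}


def realize_motif(seq: ProteinSequence, pos: int, offsets: tuple[int, ...]) -> str | None:
    """The concrete motif string at (seq, pos) for an offset family, or None
    when any offset falls outside the sequence or on an X residue."""
    chars = []
    for off in offsets:
        p = pos + off
        if not 1 <= p <= len(seq):
            return None
        c = seq.residue(p)
        if c == "X":
            return None
        chars.append(c)
    return "".join(chars)


@dataclass
class MotifOddsTable:
    """Driver/passenger odds ratio per concrete motif of one pattern family.

    odds = ((n_D + c)/(N_D + c)) / ((n_P + c)/(N_P + c)) with pseudocount c
    (Haldane-Anscombe 0.5 by default) so zero counts never divide by zero.
    """

    pattern_class: str
    offsets: tuple[int, ...]
    odds: dict[str, float] = field(default_factory=dict)
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    pseudocount: float = 0.5

    def lookup(self, motif: str | None) -> float:
        """Stored odds of a concrete motif; unseen or unresolvable -> 1.0."""
        if motif is None:
            return 1.0
        return self.odds.get(motif, 1.0)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("motif\tn_driver\tn_passenger\todds\n")
            for motif in sorted(self.odds):
                n_d, n_p = self.counts[motif]
                fh.write(f"{motif}\t{n_d}\t{n_p}\t{self.odds[motif]:.6g}\n")


def build_motif_odds(
    driver_records: Sequence[MutationRecord],
    passenger_records: Sequence[MutationRecord],
    sequences: Mapping[str, ProteinSequence],
    pattern_class: str,
    offsets: tuple[int, ...] | None = None,
    pseudocount: float = 0.5,
) -> MotifOddsTable:
    """Count motif occurrences at driver vs passenger sites and store the
    pseudocounted odds ratio per concrete motif."""
    if offsets is None:
        offsets = DEFAULT_MOTIF_FAMILIES[pattern_class]
    if not passenger_records:
        raise ValueError("empty passenger set: motif odds are undefined")
    if not driver_records:
        raise ValueError("empty driver set: motif odds are undefined")

    def count(records: Sequence[MutationRecord]) -> dict[str, int]:
        c: dict[str, int] = {}
        for r in records:
            seq = sequences.get(r.protein_id)
            if seq is None:
                raise KeyError(f"no sequence for protein {r.protein_id!r}")
            motif = realize_motif(seq, r.position, offsets)
            if motif is not None:
                c[motif] = c.get(motif, 0) + 1
        return c

    driver_counts = count(driver_records)
    passenger_counts = count(passenger_records)
    n_d_total = len(driver_records)
    n_p_total = len(passenger_records)
    table = MotifOddsTable(
        pattern_class=pattern_class, offsets=offsets, pseudocount=pseudocount
    )
    for motif in sorted(set(driver_counts) | set(passenger_counts)):
        n_d = driver_counts.get(motif, 0)
        n_p = passenger_counts.get(motif, 0)
        c = pseudocount
        odds = ((n_d + c) / (n_d_total + c)) / ((n_p + c) / (n_p_total + c))
        table.odds[motif] = odds
        table.counts[motif] = (n_d, n_p)
    return table


def motif_features(
    seq: ProteinSequence, pos: int, tables: Sequence[MotifOddsTable]
) -> tuple[float, ...]:
    """Per-family odds of the concrete motifs realized at (seq, pos);
    unseen or unrealizable motifs score 1.0 (odds-neutral)."""
    return tuple(t.lookup(realize_motif(seq, pos, t.offsets)) for t in tables)


# ---------------------------------------------------------------------------
# PSSM features
# ---------------------------------------------------------------------------

def pssm_features(
    profile: PSSMProfile,
    pos: int,
    wt: str,
    mut: str,
    window: WindowConfig = WindowConfig(),
) -> tuple[float, float, float]:
    """Three PSSM-derived features of a mutation site:
    (window_mean, delta, site_score).

    window_mean averages, over the in-bounds 13-residue window, each
    position's log-odds score for its own native residue; delta is
    score(pos, mut) - score(pos, wt); site_score is score(pos, wt).
    """
    if profile.residues is None:
        raise ValueError(f"{profile.protein_id}: PSSM has no residue annotation")
    start, end = window.bounds(pos, len(profile))
    native = []
    for p in range(start, end + 1):
        res = profile.residues[p - 1]
        if res == "X":
            continue
        native.append(profile.score(p, res))
    window_mean = float(np.mean(native)) if native else NAN
    if wt == "X" or mut == "X":
        return window_mean, NAN, NAN
    site_score = profile.score(pos, wt)
    delta = profile.score(pos, mut) - site_score
    return window_mean, delta, site_score


# ---------------------------------------------------------------------------
# per-residue tracks
# ---------------------------------------------------------------------------

def track_features(
    track: ResidueTrack, pos: int, window: WindowConfig = WindowConfig()
) -> tuple[float, float]:
    """(site_value, window_mean) of a per-residue score track.

    Missing (nan) values are excluded from the mean; an all-missing window
    yields nan.
    """
    site_value = track.value(pos)
    start, end = window.bounds(pos, len(track))
    segment = track.values[start - 1 : end]
    finite = segment[np.isfinite(segment)]
    window_mean = float(np.mean(finite)) if finite.size else NAN
    return site_value, window_mean
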