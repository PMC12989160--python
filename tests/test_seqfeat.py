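import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from missdriver._aminoacids import AA20
from missdriver.io import MutationRecord, ProteinSequence, ResidueTrack, PSSMProfile
from missdriver.seqfeat import (
    DEFAULT_MOTIF_FAMILIES,
    WindowConfig,
    build_motif_odds,
    delta_property,
    motif_features,
    neighbor_composition,
    neighbor_contact_potential_delta,
    pssm_features,
    realize_motif,
    substitution_matrix_feature,
    track_features,
)


# ----------------------------------------------------------- delta properties

def test_delta_property_kyte_doolittle(toy_index1):
    # A (1.8) -> V (4.2): hydropathy increases by 2.4
    assert delta_property("A", "V", toy_index1) == pytest.approx(2.4)


def test_delta_property_antisymmetric(toy_index1):
    for wt, mut in [("A", "V"), ("R", "W"), ("G", "P")]:
        assert delta_property(wt, mut, toy_index1) == pytest.approx(
            -delta_property(mut, wt, toy_index1)
        )


def test_delta_property_unknown_residue_missing(toy_index1):
    assert math.isnan(delta_property("X", "V", toy_index1))


# ------------------------------------------------------ substitution matrices

def test_substitution_matrix_lookup_and_symmetry(toy_index3):
    assert substitution_matrix_feature("A", "Q", toy_index3) == 2.0
    assert substitution_matrix_feature("Q", "A", toy_index3) == 2.0


def test_substitution_matrix_missing_cell_is_nan(toy_index3):
    assert math.isnan(substitution_matrix_feature("W", "Y", toy_index3))


# --------------------------------------------------- neighbor contact deltas

def test_neighbor_contact_potential_hand_arithmetic(toy_index3):
    # seq ARC, site 2 (R -> Q): dN = CP(A,Q)-CP(A,R) = 1; dC = CP(C,Q)-CP(C,R) = 1
    seq = ProteinSequence("p", "ARC")
    dn, dc, lr = neighbor_contact_potential_delta(seq, 2, toy_index3, "Q")
    assert dn == pytest.approx(1.0)
    assert dc == pytest.approx(1.0)
    assert lr == pytest.approx(3.0)  # CP(A, C)


def test_neighbor_contact_potential_terminal_missing(toy_index3):
    seq = ProteinSequence("p", "AC")
    dn, dc, lr = neighbor_contact_potential_delta(seq, 1, toy_index3, "Q")
    assert math.isnan(dn) and math.isnan(lr)
    assert dc == pytest.approx(5.0 - 3.0)  # CP(C,Q) - CP(C,A)


# ------------------------------------------------------- window composition

def test_neighbor_composition_all_negative():
    seq = ProteinSequence("p", "DDDDDDRDDDDDD")
    counts = neighbor_composition(seq, 7)
    # order: aliphatic, sulfur, aromatic, polar, positive, negative
    assert counts == (0, 0, 0, 0, 0, 12)


def test_neighbor_composition_boundary_truncation():
    seq = ProteinSequence("p", "AR")
    counts = neighbor_composition(seq, 1)
    assert sum(counts) == 1  # only the right neighbor is in bounds


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    seq=st.text(alphabet=AA20, min_size=2, max_size=40),
    data=st.data(),
    flank=st.integers(min_value=1, max_value=8),
)
def test_neighbor_composition_counts_conserved(seq, data, flank):
    pos = data.draw(st.integers(min_value=1, max_value=len(seq)))
    counts = neighbor_composition(
        ProteinSequence("p", seq), pos, WindowConfig(flank=flank)
    )
    assert sum(counts) == min(pos - 1, flank) + min(len(seq) - pos, flank)


# ----------------------------------------------------------------- motif odds

def _records(sequences, sites, label):
    out = []
    for pid, pos in sites:
        seq = sequences[pid]
        wt = seq.residue(pos)
        mut = "A" if wt != "A" else "V"
        out.append(MutationRecord(pid, pos, wt, mut, "SYNTH", 0, label))
    return out


def test_build_motif_odds_basic_ratio():
    # one protein where site+right dipeptide 'RQ' appears at position 1
    seqs = {"p1": ProteinSequence("p1", "RQAAAAA"), "p2": ProteinSequence("p2", "KLAAAAA")}
    drivers = _records(seqs, [("p1", 1)] * 10 + [("p2", 1)] * 90, "driver")
    passengers = _records(seqs, [("p1", 1)] * 5 + [("p2", 1)] * 95, "passenger")
    table = build_motif_odds(drivers, passengers, seqs, "site_right0", pseudocount=0.0)
    assert table.odds["RQ"] == pytest.approx((10 / 100) / (5 / 100))


def test_build_motif_odds_identical_corpora_neutral():
    seqs = {"p1": ProteinSequence("p1", "RQWKLMNP")}
    sites = [("p1", i) for i in range(1, 8)]
    drivers = _records(seqs, sites, "driver")
    passengers = _records(seqs, sites, "passenger")
    table = build_motif_odds(drivers, passengers, seqs, "site_right0", pseudocount=0.5)
    assert all(v == pytest.approx(1.0) for v in table.odds.values())


def test_build_motif_odds_unseen_pseudocount():
    seqs = {"p1": ProteinSequence("p1", "RQWKLMNP")}
    drivers = _records(seqs, [("p1", 1)] * 100, "driver")
    passengers = _records(seqs, [("p1", 2)] * 100, "passenger")
    table = build_motif_odds(drivers, passengers, seqs, "site_right0", pseudocount=0.5)
    # motif QW is passenger-only: odds = (0.5/100.5) / (100.5/100.5)
    assert table.odds["QW"] == pytest.approx((0.5 / 100.5) / (100.5 / 100.5))


def test_build_motif_odds_requires_both_classes():
    seqs = {"p1": ProteinSequence("p1", "RQWKLMNP")}
    drivers = _records(seqs, [("p1", 1)], "driver")
    with pytest.raises(ValueError, match="passenger"):
        build_motif_odds(drivers, [], seqs, "site_right0")


def test_motif_features_unseen_and_terminal_neutral():
    seqs = {"p1": ProteinSequence("p1", "RQWKLMNP")}
    drivers = _records(seqs, [("p1", 2)] * 4, "driver")
    passengers = _records(seqs, [("p1", 3)] * 4, "passenger")
    tables = [
        build_motif_odds(drivers, passengers, seqs, name)
        for name in DEFAULT_MOTIF_FAMILIES
    ]
    other = ProteinSequence("q", "YYYYYYYY")
    assert motif_features(other, 4, tables) == tuple([1.0] * 7)
    # terminal site: left-anchored families cannot realize a motif
    left_table = [t for t in tables if t.pattern_class == "site_left0"][0]
    assert realize_motif(other, 1, left_table.offsets) is None
    assert motif_features(other, 1, [left_table]) == (1.0,)


def test_motif_odds_label_shuffle_centers_log_at_zero():
    rng = np.random.default_rng(11)
    seqs = {}
    sites = []
    for i in range(200):
        pid = f"p{i}"
        seqs[pid] = ProteinSequence(
            pid, "".join(rng.choice(list(AA20), size=60))
        )
        for pos in range(2, 60, 6):
            sites.append((pid, pos))
    rng.shuffle(sites)
    n = len(sites) // 2
    drivers = _records(seqs, sites[:n], "driver")
    passengers = _records(seqs, sites[n:], "passenger")
    table = build_motif_odds(drivers, passengers, seqs, "site_right0")
    logs = np.log([v for v in table.odds.values()])
    assert abs(np.mean(logs)) < 0.15


# --------------------------------------------------------------- PSSM features

def test_pssm_features_hand_arithmetic():
    scores = np.zeros((9, 20), dtype=int)
    # position 5: wt column (A, col 0) = +5, mut column (V, col 19) = -2
    scores[4, 0] = 5
    scores[4, 19] = -2
    profile = PSSMProfile("p", scores, residues="CCCCACCCC")
    wm, delta, site = pssm_features(profile, 5, "A", "V", WindowConfig(flank=2))
    assert site == 5.0
    assert delta == -7.0
    # window rows 3..7, native residue scores: 0,0,5,0,0
    assert wm == pytest.approx(1.0)


def test_pssm_features_degenerate_zero_profile():
    profile = PSSMProfile("p", np.zeros((5, 20), dtype=int), residues="AAAAA")
    assert pssm_features(profile, 3, "A", "V") == (0.0, 0.0, 0.0)


# -------------------------------------------------------------- track features

def test_track_features_constant():
    track = ResidueTrack("p", "cons", np.full(9, 0.5))
    assert track_features(track, 5) == (0.5, 0.5)


def test_track_features_missing_site_mean_over_neighbors():
    values = np.array([1.0, np.nan, 3.0])
    track = ResidueTrack("p", "cons", values)
    site, mean = track_features(track, 2, WindowConfig(flank=1))
    assert math.isnan(site)
    assert mean == pytest.approx(2.0)


def test_track_features_all_missing_window():
    track = ResidueTrack("p", "cons", np.full(5, np.nan))
    site, mean = track_features(track, 3)
    assert math.isnan(site) and math.isnan(mean)
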