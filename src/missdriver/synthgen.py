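"""Deterministic synthetic fixtures: sequences, helical structures, PSSMs,
conservation/disorder tracks and mutation tables with planted driver signal.

Every artifact is written in the real external format (FASTA, PDB, ascii
PSSM, TSV, CSV) so the format readers are exercised end to end without any
download. Seeded runs are bit-reproducible.

The generator emulates the *statistical shape* of a cancer mutation corpus —
recurrence-labelled drivers, a roughly 2:1 driver:passenger balance, feature
families carrying a configurable effect size — not realistic protein folds
or evolutionary covariation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import cos, pi, sin
from pathlib import Path

import numpy as np
import pandas as pd

from ._aminoacids import AA20, ONE_TO_THREE, PSSM_COLUMNS
from .io import MutationRecord, ProteinSequence, write_fasta, write_mutation_table
from .mlpipe import FeatureMatrix

# The 18 conservation methods of the AACon suite, plus one disorder track.
CONSERVATION_TRACKS = (
    "kabat", "jores", "schneider", "shenkin", "gerstein", "taylor_gaps",
    "taylor_no_gaps", "zvelebil", "karlin", "armon", "thompson", "not_lancet",
    "mirny", "williamson", "landgraf", "sander", "valdar", "smerfs",
)
DISORDER_TRACK = "iupred_disorder"


@dataclass
class SynthConfig:
    """Study conditions of the synthetic corpus.

    Defaults: 20 proteins of 80-200 residues, drivers:passengers 2:1,
    recurrence threshold 3 reproduced exactly by the sampled counts, planted
    conservation contrast d (site conservation of drivers sits d standard
    deviations above passengers).
    """

    n_proteins: int = 20
    protein_length_range: tuple[int, int] = (80, 200)
    n_driver: int = 200
    n_passenger: int = 100
    effect_size: float = 2.0
    noise_sd: float = 1.0
    plddt_mean: float = 85.0
    # fraction of driver sites forced to carry a favored right-neighbor
    # residue, emulating the motif enrichment seen in real corpora
    motif_bias: float = 0.5
    motif_residues: frozenset = frozenset("RKE")
    seed: int = 0
    cancer_type: str = "SYNTH"
    residue_freqs: dict[str, float] | None = None  # default uniform


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def gen_sequences(config: SynthConfig) -> list[ProteinSequence]:
    """Random sequences drawn from a configurable residue frequency table."""
    rng = np.random.default_rng(config.seed)
    if config.residue_freqs is None:
        probs = np.full(20, 1.0 / 20)
    else:
        probs = np.array([config.residue_freqs.get(a, 0.0) for a in AA20])
        probs = probs / probs.sum()
    lo, hi = config.protein_length_range
    out = []
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        residues = "".join(rng.choice(list(AA20), size=length, p=probs))
        out.append(ProteinSequence(id=f"SYN{i:04d}", residues=residues))
    return out


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

_HELIX_RISE = 1.5  # A per residue
_HELIX_TWIST = 100.0 * pi / 180.0  # rad per residue
_HELIX_RADIUS = 2.3  # A, C-alpha distance from axis


def gen_structure(
    sequence: ProteinSequence,
    jitter: float = 0.0,
    plddt: np.ndarray | None = None,
    seed: int = 0,
) -> str:
    """PDB text for an idealized alpha-helical backbone (rise 1.5 A, twist
    100 deg per residue) with optional Gaussian coordinate jitter; the
    B-factor column carries synthetic pLDDT values."""
    rng = np.random.default_rng(seed)
    if plddt is None:
        plddt = np.full(len(sequence), 90.0)
    lines = []
    serial = 1
    for i, aa in enumerate(sequence.residues):
        theta = _HELIX_TWIST * i
        ca = np.array(
            [_HELIX_RADIUS * cos(theta), _HELIX_RADIUS * sin(theta), _HELIX_RISE * i]
        )
        # approximate backbone companions around the C-alpha
        offsets = {
            "N": np.array([-0.5, 0.9, -0.9]),
            "CA": np.zeros(3),
            "C": np.array([0.6, -0.8, 0.9]),
            "O": np.array([1.4, -1.2, 0.6]),
        }
        resname = ONE_TO_THREE.get(aa, "GLY")
        b = float(np.clip(plddt[i], 0.0, 100.0))
        for atom_name, off in offsets.items():
            xyz = ca + off
            if jitter > 0:
                xyz = xyz + rng.normal(0.0, jitter, size=3)
            lines.append(
                f"ATOM  {serial:5d} {atom_name:<4s} {resname:3s} A{i + 1:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{b:6.2f}"
                f"          {atom_name[0]:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# PSSMs and tracks
# ---------------------------------------------------------------------------

def gen_pssm_text(
    sequence: ProteinSequence,
    conserved: np.ndarray | None = None,
    seed: int = 0,
) -> str:
    """PSI-BLAST ``-out_ascii_pssm`` dialect text for a sequence.

    At positions flagged ``conserved`` the native-residue column scores high
    (profile of a constrained site); elsewhere scores are near-neutral noise.
    """
    rng = np.random.default_rng(seed)
    if conserved is None:
        conserved = np.zeros(len(sequence), dtype=bool)
    header = (
        "\nLast position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts\n"
        "            " + "   ".join(PSSM_COLUMNS) + "\n"
    )
    rows = []
    for i, aa in enumerate(sequence.residues):
        scores = rng.integers(-3, 4, size=20)
        if aa in PSSM_COLUMNS:
            col = PSSM_COLUMNS.index(aa)
            scores[col] = 7 if conserved[i] else max(int(scores[col]), 1)
        row = f"{i + 1:5d} {aa}  " + " ".join(f"{s:3d}" for s in scores)
        rows.append(row)
    footer = "\n                      K         Lambda\nStandard Ungapped    0.1337     0.3110\n"
    return header + "\n".join(rows) + "\n" + footer


def gen_tracks_frame(
    length: int,
    site_scores: np.ndarray | None = None,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Per-residue TSV-ready frame with 18 conservation tracks + disorder.

    ``site_scores`` (standard-normal scale) shifts every conservation track,
    so a planted contrast between driver and passenger sites propagates into
    all conservation features; disorder moves the opposite way.
    """
    rng = np.random.default_rng(seed)
    if site_scores is None:
        site_scores = np.zeros(length)
    data = {"position": np.arange(1, length + 1)}
    for name in CONSERVATION_TRACKS:
        noise = rng.normal(0.0, noise_sd, size=length)
        raw = site_scores + noise
        data[name] = 1.0 / (1.0 + np.exp(-raw))  # squash to (0, 1)
    disorder_raw = -site_scores + rng.normal(0.0, noise_sd, size=length)
    data[DISORDER_TRACK] = 1.0 / (1.0 + np.exp(-disorder_raw))
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# mutation corpus
# ---------------------------------------------------------------------------

def gen_mutation_dataset(
    config: SynthConfig,
) -> tuple[list[MutationRecord], list[ProteinSequence], dict[str, np.ndarray]]:
    """Mutation table plus per-protein site scores with planted signal.

    Driver sites are drawn at positions whose latent conservation score is
    high (shifted by ``effect_size``); passengers come from the complement.
    A ``motif_bias`` fraction of driver sites is additionally constrained to
    carry a favored right-neighbor residue (and passengers a disfavored one),
    planting a transferable gapped-motif signal. Sample counts are drawn so
    that recurrence labelling at threshold 3 reproduces the intended labels
    exactly (drivers >= 3, passengers <= 2).

    Returns (records, sequences, site_scores by protein id); records carry
    only ``unknown``/``passenger`` labels so that ``label_by_recurrence``
    reconstructs the driver class downstream.
    """
    rng = np.random.default_rng(config.seed)
    sequences = gen_sequences(config)
    site_scores = {
        s.id: rng.normal(0.0, 1.0, size=len(s)) for s in sequences
    }
    records: list[MutationRecord] = []
    n_by_class = {"driver": config.n_driver, "passenger": config.n_passenger}
    used: set[tuple[str, int]] = set()
    for label, n in n_by_class.items():
        made = 0
        while made < n:
            seq = sequences[int(rng.integers(len(sequences)))]
            pos = int(rng.integers(1, len(seq) + 1))
            if (seq.id, pos) in used:
                continue
            wt = seq.residue(pos)
            if wt == "X":
                continue
            if rng.random() < config.motif_bias:
                right = (
                    seq.residue(pos + 1) if pos < len(seq) else None
                )
                favored = right is not None and right in config.motif_residues
                if label == "driver" and not favored:
                    continue
                if label == "passenger" and favored:
                    continue
            mut = wt
            while mut == wt:
                mut = AA20[int(rng.integers(20))]
            if label == "driver":
                site_scores[seq.id][pos - 1] += config.effect_size
                sample_count = 3 + int(rng.poisson(2.0))
                rec_label = "unknown"  # promoted by recurrence labelling
            else:
                sample_count = int(rng.integers(0, 3))
                rec_label = "passenger"
            used.add((seq.id, pos))
            records.append(
                MutationRecord(
                    protein_id=seq.id,
                    position=pos,
                    wt=wt,
                    mut=mut,
                    cancer_type=config.cancer_type,
                    sample_count=sample_count,
                    label=rec_label,
                )
            )
            made += 1
    return records, sequences, site_scores


def generate_corpus(config: SynthConfig, outdir: str | Path) -> Path:
    """Write a full synthetic corpus directory tree:

    fasta/, structures/, pssm/, tracks/, mutations.csv, manifest.json.
    """
    outdir = Path(outdir)
    for sub in ("fasta", "structures", "pssm", "tracks"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    records, sequences, site_scores = gen_mutation_dataset(config)
    write_fasta(sequences, outdir / "fasta" / "proteins.fasta")
    rng = np.random.default_rng(config.seed + 1)
    for seq in sequences:
        scores = site_scores[seq.id]
        plddt = np.clip(
            config.plddt_mean + 5.0 * scores + rng.normal(0, 2.0, len(seq)),
            0.0,
            100.0,
        )
        pdb_text = gen_structure(
            seq, jitter=0.25, plddt=plddt, seed=int(rng.integers(2**31))
        )
        (outdir / "structures" / f"{seq.id}.pdb").write_text(pdb_text)
        conserved = scores > 1.0
        (outdir / "pssm" / f"{seq.id}.pssm").write_text(
            gen_pssm_text(seq, conserved=conserved, seed=int(rng.integers(2**31)))
        )
        frame = gen_tracks_frame(
            len(seq),
            site_scores=scores,
            seed=int(rng.integers(2**31)),
            noise_sd=config.noise_sd,
        )
        frame.to_csv(outdir / "tracks" / f"{seq.id}.tsv", sep="\t", index=False)
    write_mutation_table(records, outdir / "mutations.csv")
    manifest = {
        "seed": config.seed,
        "n_proteins": config.n_proteins,
        "n_driver": config.n_driver,
        "n_passenger": config.n_passenger,
        "effect_size": config.effect_size,
        "cancer_type": config.cancer_type,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir


# ---------------------------------------------------------------------------
# direct feature-matrix generator
# ---------------------------------------------------------------------------

def gen_feature_matrix(
    n: int = 2000,
    n_features: int = 40,
    n_planted: int = 5,
    effect_size: float = 2.0,
    n_proteins: int = 50,
    driver_fraction: float = 2.0 / 3.0,
    seed: int = 0,
) -> FeatureMatrix:
    """Labelled feature matrix with a planted signal, for pipeline studies.

    ``n_planted`` features are shifted by ``effect_size`` standard deviations
    in drivers; the rest are pure noise. Rows are grouped into proteins so
    grouped splits can be exercised. Planted columns are named
    ``signal_##``, noise columns ``noise_##``.
    """
    if n_planted > n_features:
        raise ValueError("n_planted cannot exceed n_features")
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < driver_fraction).astype(int)
    x = rng.normal(0.0, 1.0, size=(n, n_features))
    x[:, :n_planted] += effect_size * y[:, None]
    names = [f"signal_{i:02d}" for i in range(n_planted)] + [
        f"noise_{i:02d}" for i in range(n_features - n_planted)
    ]
    groups = np.array([f"SYN{int(g):04d}" for g in rng.integers(0, n_proteins, n)])
    return FeatureMatrix(
        features=pd.DataFrame(x, columns=names),
        labels=y,
        groups=groups,
    )


def planted_feature_names(matrix: FeatureMatrix) -> list[str]:
    return [c for c in matrix.features.columns if c.startswith("signal_")]
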