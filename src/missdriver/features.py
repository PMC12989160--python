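"""Assembly of per-mutation feature vectors from all feature families.

Stable column naming is ``<family>.<detail>``:

  prop.<accession>          delta of an AAindex1 physicochemical property
  mat.<accession>           AAindex2 substitution-matrix value
  cp.<accession>.{n,c,lr}   AAindex3 neighbor contact-potential deltas
  comp.<class>              six-class window composition counts
  motif.<family>            gapped di/tri-peptide odds
  pssm.{window_mean,delta,site}
  track.<name>.{site,mean}  conservation / disorder tracks
  struct.{plddt,asa,rel_asa,depth,contact_count,ss_H,ss_E,ss_C}
  net.{closeness,betweenness,eigenvector,degree}

Records whose label is still ``unknown`` are excluded from a labelled matrix
(run recurrence labelling first); unavailable inputs leave their features
nan for downstream imputation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._aminoacids import SIX_CLASS_ORDER
from .io import (
    AAindexEntry,
    MutationRecord,
    PSSMProfile,
    ProteinSequence,
    ResidueTrack,
    StructureModel,
    read_fasta,
    read_mutation_table,
    read_pssm_ascii,
    read_structure,
    read_tracks,
)
from .mlpipe import FeatureMatrix
from .netfeat import all_centralities, build_contact_network
from .seqfeat import (
    DEFAULT_MOTIF_FAMILIES,
    MotifOddsTable,
    PropertySet,
    WindowConfig,
    build_motif_odds,
    delta_property,
    motif_features,
    neighbor_composition,
    neighbor_contact_potential_delta,
    pssm_features,
    substitution_matrix_feature,
    track_features,
)
from .structfeat import annotate_model, average_over_models

NAN = float("nan")

STRUCT_KEYS = ("plddt", "asa", "rel_asa", "depth", "contact_count", "ss_H", "ss_E", "ss_C")
NET_KEYS = ("closeness", "betweenness", "eigenvector", "degree")
ONEHOT_COLUMNS = frozenset({"struct.ss_H", "struct.ss_E", "struct.ss_C"})


@dataclass
class FeatureInputs:
    """Everything the extractor can draw on for one corpus."""

    sequences: Mapping[str, ProteinSequence]
    property_set: PropertySet | None = None
    aaindex2: Sequence[AAindexEntry] = ()
    aaindex3: Sequence[AAindexEntry] = ()
    pssms: Mapping[str, PSSMProfile] = field(default_factory=dict)
    tracks: Mapping[str, Sequence[ResidueTrack]] = field(default_factory=dict)
    structures: Mapping[str, Sequence[StructureModel]] = field(default_factory=dict)
    motif_tables: Sequence[MotifOddsTable] = ()
    window: WindowConfig = field(default_factory=WindowConfig)
    contact_cutoff: float = 7.0
    sasa_points: int = 240


def build_motif_tables(
    records: Sequence[MutationRecord],
    sequences: Mapping[str, ProteinSequence],
    families: Mapping[str, tuple[int, ...]] | None = None,
    pseudocount: float = 0.5,
) -> list[MotifOddsTable]:
    """Fit the seven gapped-motif odds tables on labelled training records."""
    if families is None:
        families = DEFAULT_MOTIF_FAMILIES
    drivers = [r for r in records if r.label == "driver"]
    passengers = [r for r in records if r.label == "passenger"]
    return [
        build_motif_odds(drivers, passengers, sequences, name, offsets, pseudocount)
        for name, offsets in families.items()
    ]


def _structure_annotation(
    models: Sequence[StructureModel], inputs: FeatureInputs
) -> dict[int, dict[str, float]]:
    maps = [
        annotate_model(
            m,
            n_points=inputs.sasa_points,
            contact_cutoff=inputs.contact_cutoff,
        )
        for m in models
    ]
    merged, _flagged = average_over_models(maps)
    return merged


def _network_annotation(
    models: Sequence[StructureModel], inputs: FeatureInputs
) -> dict[int, dict[str, float]]:
    maps = []
    for m in models:
        net = build_contact_network(m, cutoff=inputs.contact_cutoff)
        cent = all_centralities(net)
        maps.append(
            {num: dict(zip(NET_KEYS, vals)) for num, vals in cent.items()}
        )
    merged, _flagged = average_over_models(maps)
    return merged


def extract_features(
    records: Sequence[MutationRecord],
    inputs: FeatureInputs,
) -> FeatureMatrix:
    """One feature row per labelled mutation record."""
    labelled = [r for r in records if r.label in ("driver", "passenger")]
    skipped = len(records) - len(labelled)
    if skipped:
        warnings.warn(f"{skipped} unlabelled records excluded", stacklevel=2)

    struct_cache: dict[str, dict[int, dict[str, float]]] = {}
    net_cache: dict[str, dict[int, dict[str, float]]] = {}

    rows: list[dict[str, float]] = []
    labels: list[int] = []
    groups: list[str] = []
    for r in labelled:
        seq = inputs.sequences.get(r.protein_id)
        if seq is None:
            raise KeyError(f"no sequence for protein {r.protein_id!r}")
        r.check_against(seq)
        row: dict[str, float] = {}

        if inputs.property_set is not None:
            for entry in inputs.property_set:
                row[f"prop.{entry.accession}"] = delta_property(r.wt, r.mut, entry)
        for entry in inputs.aaindex2:
            row[f"mat.{entry.accession}"] = substitution_matrix_feature(
                r.wt, r.mut, entry
            )
        for entry in inputs.aaindex3:
            dn, dc, lr = neighbor_contact_potential_delta(
                seq, r.position, entry, r.mut
            )
            row[f"cp.{entry.accession}.n"] = dn
            row[f"cp.{entry.accession}.c"] = dc
            row[f"cp.{entry.accession}.lr"] = lr

        comp = neighbor_composition(seq, r.position, inputs.window)
        for name, count in zip(SIX_CLASS_ORDER, comp):
            row[f"comp.{name}"] = float(count)

        if inputs.motif_tables:
            vals = motif_features(seq, r.position, inputs.motif_tables)
            for table, v in zip(inputs.motif_tables, vals):
                row[f"motif.{table.pattern_class}"] = v

        profile = inputs.pssms.get(r.protein_id)
        if profile is not None:
            wm, delta, site = pssm_features(
                profile, r.position, r.wt, r.mut, inputs.window
            )
            row["pssm.window_mean"] = wm
            row["pssm.delta"] = delta
            row["pssm.site"] = site

        for track in inputs.tracks.get(r.protein_id, ()):
            site, mean = track_features(track, r.position, inputs.window)
            row[f"track.{track.track_name}.site"] = site
            row[f"track.{track.track_name}.mean"] = mean

        models = inputs.structures.get(r.protein_id)
        if models:
            if r.protein_id not in struct_cache:
                struct_cache[r.protein_id] = _structure_annotation(models, inputs)
                net_cache[r.protein_id] = _network_annotation(models, inputs)
            ann = struct_cache[r.protein_id].get(r.position, {})
            for key in STRUCT_KEYS:
                row[f"struct.{key}"] = ann.get(key, NAN)
            net_ann = net_cache[r.protein_id].get(r.position, {})
            for key in NET_KEYS:
                row[f"net.{key}"] = net_ann.get(key, NAN)

        rows.append(row)
        labels.append(1 if r.label == "driver" else 0)
        groups.append(r.protein_id)

    df = pd.DataFrame(rows)
    onehot = frozenset(c for c in ONEHOT_COLUMNS if c in df.columns)
    return FeatureMatrix(
        features=df,
        labels=np.asarray(labels),
        groups=np.asarray(groups),
        onehot_columns=onehot,
    )


def load_corpus_inputs(
    corpus_dir: str | Path,
    with_structures: bool = True,
    property_set: PropertySet | None = None,
) -> tuple[list[MutationRecord], FeatureInputs]:
    """Load a corpus directory tree (as written by synthgen.generate_corpus
    or assembled from real data) into records plus feature inputs."""
    corpus = Path(corpus_dir)
    sequences = {
        s.id: s for s in read_fasta(corpus / "fasta" / "proteins.fasta")
    }
    records = read_mutation_table(corpus / "mutations.csv")
    pssms: dict[str, PSSMProfile] = {}
    for path in sorted((corpus / "pssm").glob("*.pssm")):
        pid = path.stem
        pssms[pid] = read_pssm_ascii(path, sequences.get(pid))
    tracks: dict[str, list[ResidueTrack]] = {}
    for path in sorted((corpus / "tracks").glob("*.tsv")):
        tracks[path.stem] = read_tracks(path)
    structures: dict[str, list[StructureModel]] = {}
    if with_structures:
        for path in sorted((corpus / "structures").glob("*.pdb")):
            structures[path.stem] = read_structure(path)
    if property_set is None:
        property_set = PropertySet.bundled()
    inputs = FeatureInputs(
        sequences=sequences,
        property_set=property_set,
        pssms=pssms,
        tracks=tracks,
        structures=structures,
    )
    return records, inputs
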