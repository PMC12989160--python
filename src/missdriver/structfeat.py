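"""Structure-derived per-mutation features from AlphaFold-style models.

pLDDT (B-factor column), Shrake-Rupley solvent-accessible surface area,
relative ASA, 3-state secondary structure, residue depth to the accessible
surface, and inter-residue contact counts. When several structural models
exist for a protein, per-residue features are averaged across models.

SASA and residue depth are computed numerically here; DSSP output can be
ingested instead via :mod:`missdriver.io` and overrides computed SS/ASA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from ._aminoacids import MAX_ASA, THREE_TO_ONE, vdw_radius
from .io import StructureModel

NAN = float("nan")


def residue_plddt(model: StructureModel, pos: int) -> float:
    """Per-residue pLDDT: mean of the B-factor over the residue's atoms.

    AlphaFold writes the same pLDDT on every atom of a residue, so the mean
    is exact there; nan when the residue is absent from the model.
    """
    for num, _, atoms in model.residues:
        if num == pos:
            return float(np.mean([a[4] for a in atoms]))
    return NAN


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral lattice); deterministic."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass
class SasaResult:
    """Shrake-Rupley quadrature output: per-atom and per-residue accessible
    areas plus the retained (solvent-accessible) surface points."""

    per_atom: np.ndarray  # A^2, one entry per atom in model order
    per_residue: dict[int, float]  # residue_number -> A^2
    surface_points: np.ndarray  # (n_points_kept, 3)
    probe_radius: float
    n_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


def shrake_rupley(
    model: StructureModel, probe_radius: float = 1.4, n_points: int = 960
) -> SasaResult:
    """Shrake-Rupley accessible surface area.

    Each atom's sphere is expanded by the probe radius and sampled with a
    deterministic golden-spiral lattice of ``n_points`` test points; a point
    survives if it lies outside every other atom's expanded sphere. The atom's
    ASA is the surviving fraction of its expanded-sphere area.
    """
    atom_xyz = []
    atom_radius = []
    atom_residue = []
    for num, _, atoms in model.residues:
        for name, x, y, z, _ in atoms:
            atom_xyz.append((x, y, z))
            atom_radius.append(vdw_radius(name) + probe_radius)
            atom_residue.append(num)
    xyz = np.asarray(atom_xyz)
    radii = np.asarray(atom_radius)
    n_atoms = len(xyz)
    sphere = _fibonacci_sphere(n_points)

    tree = cKDTree(xyz)
    max_r = radii.max()
    per_atom = np.zeros(n_atoms)
    kept_points: list[np.ndarray] = []
    for i in range(n_atoms):
        pts = xyz[i] + radii[i] * sphere
        # candidate occluders: any atom whose expanded sphere can reach these points
        neighbors = tree.query_ball_point(xyz[i], radii[i] + max_r)
        neighbors = [j for j in neighbors if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            r2 = radii[j] ** 2
            # points exactly on a neighbor's sphere (coincident atoms) are
            # kept by the lower-index atom only, so shared surface counts once
            strictly_inside = d2 < r2 * (1.0 - 1e-9)
            tie = np.abs(d2 - r2) <= r2 * 1e-9
            occluded = strictly_inside | (tie if j < i else False)
            accessible &= ~occluded
        frac = accessible.mean()
        per_atom[i] = frac * 4.0 * math.pi * radii[i] ** 2
        if accessible.any():
            kept_points.append(pts[accessible])

    per_residue: dict[int, float] = {}
    for area, num in zip(per_atom, atom_residue):
        per_residue[num] = per_residue.get(num, 0.0) + float(area)
    surface = np.vstack(kept_points) if kept_points else np.empty((0, 3))
    return SasaResult(
        per_atom=per_atom,
        per_residue=per_residue,
        surface_points=surface,
        probe_radius=probe_radius,
        n_points=n_points,
    )


def sasa(
    model: StructureModel, probe_radius: float = 1.4, n_points: int = 960
) -> dict[int, float]:
    """Per-residue accessible surface area in A^2."""
    return shrake_rupley(model, probe_radius, n_points).per_residue


def relative_asa(model: StructureModel, asa_map: Mapping[int, float]) -> dict[int, float]:
    """ASA normalized by the residue type's theoretical maximum, clipped to [0, 1]."""
    out: dict[int, float] = {}
    for num, name, _ in model.residues:
        one = THREE_TO_ONE.get(name, "X")
        max_asa = MAX_ASA.get(one)
        a = asa_map.get(num)
        if a is None or max_asa is None:
            out[num] = NAN
        else:
            out[num] = min(1.0, max(0.0, a / max_asa))
    return out


def residue_depth(
    model: StructureModel,
    pos: int,
    sasa_result: SasaResult | None = None,
    probe_radius: float = 1.4,
) -> float:
    """Depth of a residue below the solvent-accessible surface: minimum
    distance from the residue's heavy-atom centroid to any retained
    Shrake-Rupley surface point.

    An isolated, fully exposed residue has depth <= r_atom + r_probe (its own
    surface points sit at atomic-plus-probe radius).
    """
    if sasa_result is None:
        sasa_result = shrake_rupley(model, probe_radius=probe_radius)
    heavy = [
        (x, y, z)
        for num, _, atoms in model.residues
        if num == pos
        for name, x, y, z, _ in atoms
        if not name.upper().startswith("H")
    ]
    if not heavy:
        return NAN
    centroid = np.mean(np.asarray(heavy), axis=0)
    if sasa_result.surface_points.size == 0:
        return NAN
    d = np.linalg.norm(sasa_result.surface_points - centroid, axis=1)
    return float(d.min())


def ss3_onehot(ss: str) -> tuple[int, int, int]:
    """One-hot encoding of 3-state secondary structure: H, E, C."""
    if ss == "H":
        return (1, 0, 0)
    if ss == "E":
        return (0, 1, 0)
    if ss == "C":
        return (0, 0, 1)
    raise ValueError(f"secondary-structure code must be H/E/C, got {ss!r}")


def residue_contacts(model: StructureModel, pos: int, cutoff: float = 7.0) -> int:
    """Number of other residues with >= 1 atom pair within ``cutoff`` A of
    this residue's atoms; trivial backbone neighbors (|residue-number
    difference| <= 1) are excluded."""
    target = None
    for num, _, atoms in model.residues:
        if num == pos:
            target = np.array([[x, y, z] for _, x, y, z, _ in atoms])
            break
    if target is None:
        raise KeyError(f"residue {pos} not in model {model.model_id}")
    count = 0
    for num, _, atoms in model.residues:
        if abs(num - pos) <= 1:
            continue
        other = np.array([[x, y, z] for _, x, y, z, _ in atoms])
        d2 = np.sum((target[:, None, :] - other[None, :, :]) ** 2, axis=2)
        if (d2 <= cutoff**2).any():
            count += 1
    return count


def average_over_models(
    feature_maps: Sequence[Mapping[int, Mapping[str, float]]],
) -> tuple[dict[int, dict[str, float]], set[int]]:
    """Arithmetic mean of per-residue features across structural models.

    Residues present in only some models are averaged over the models that
    contain them and returned in the flagged set. A single model passes
    through unchanged.
    """
    if not feature_maps:
        raise ValueError("need at least one model's feature map")
    all_residues = sorted({num for fm in feature_maps for num in fm})
    out: dict[int, dict[str, float]] = {}
    flagged: set[int] = set()
    for num in all_residues:
        present = [fm[num] for fm in feature_maps if num in fm]
        if len(present) < len(feature_maps):
            flagged.add(num)
        features = sorted({k for p in present for k in p})
        out[num] = {
            k: float(np.mean([p[k] for p in present if k in p])) for k in features
        }
    return out, flagged


def annotate_model(
    model: StructureModel,
    dssp: Sequence[tuple[int, str, float]] | None = None,
    probe_radius: float = 1.4,
    n_points: int = 960,
    contact_cutoff: float = 7.0,
) -> dict[int, dict[str, float]]:
    """Full per-residue structural annotation of one model.

    Returns residue_number -> {plddt, asa, rel_asa, depth, contact_count,
    ss_H, ss_E, ss_C}. When a DSSP parse is supplied its SS and ACC override
    the computed values; otherwise SS defaults to coil.
    """
    sr = shrake_rupley(model, probe_radius=probe_radius, n_points=n_points)
    asa_map = dict(sr.per_residue)
    ss_map: dict[int, str] = {}
    if dssp is not None:
        for num, ss, acc in dssp:
            ss_map[num] = ss
            asa_map[num] = acc
    rel = relative_asa(model, asa_map)
    out: dict[int, dict[str, float]] = {}
    for num, _, _atoms in model.residues:
        onehot = ss3_onehot(ss_map.get(num, "C"))
        out[num] = {
            "plddt": residue_plddt(model, num),
            "asa": asa_map.get(num, NAN),
            "rel_asa": rel.get(num, NAN),
            "depth": residue_depth(model, num, sasa_result=sr),
            "contact_count": float(residue_contacts(model, num, cutoff=contact_cutoff)),
            "ss_H": float(onehot[0]),
            "ss_E": float(onehot[1]),
            "ss_C": float(onehot[2]),
        }
    return out
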