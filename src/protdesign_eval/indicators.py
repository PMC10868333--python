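"""Per-method biological indicators computed from sequences and structures.

The indicators quantify, for a set of sequences designed on a fixed
backbone: how much of the native sequence is recovered, how different the
designs are from one another, how well the folded designs' secondary
structure and Cα geometry match the native, and whether hydrophobic
residues end up buried the way they are in the native structure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .datasets import default_nonpolar_set, max_sasa_reference
from .errors import (
    DegenerateInputError,
    DimensionMismatchError,
    InputTooSmallError,
)
from .io import IndicatorTable, SequenceRecord, StructureModel

#: Default strict qualification cutoff for the Cα RMSD of a folded design.
QUALIFIED_RMSD_CUTOFF = 2.0


# ---------------------------------------------------------------------------
# sequence indicators
# ---------------------------------------------------------------------------

def _positional_identity(a: str, b: str) -> float:
    """Fraction of identical positions; X positions are excluded."""
    if len(a) != len(b):
        raise DimensionMismatchError(
            f"sequences of different length ({len(a)} vs {len(b)}); "
            "fixed-backbone designs must match the native length"
        )
    pairs = [(x, y) for x, y in zip(a, b) if x != "X" and y != "X"]
    if not pairs:
        raise InputTooSmallError("no comparable positions (all X)")
    return sum(x == y for x, y in pairs) / len(pairs)


def compute_recovery(designed: SequenceRecord | str,
                     native: SequenceRecord | str) -> float:
    """Sequence recovery: positional identity of a design to the native."""
    d = designed.sequence if isinstance(designed, SequenceRecord) else designed
    n = native.sequence if isinstance(native, SequenceRecord) else native
    return _positional_identity(d, n)


def mean_recovery(designs: Iterable[SequenceRecord | str],
                  native: SequenceRecord | str) -> float:
    values = [compute_recovery(d, native) for d in designs]
    if not values:
        raise InputTooSmallError("no designs supplied")
    return float(np.mean(values))


def compute_diversity(designs: Sequence[SequenceRecord | str]) -> float:
    """One minus the mean pairwise identity over all unordered pairs."""
    seqs = [d.sequence if isinstance(d, SequenceRecord) else d
            for d in designs]
    if len(seqs) < 2:
        raise InputTooSmallError("diversity needs at least 2 sequences")
    identities = [_positional_identity(a, b)
                  for a, b in itertools.combinations(seqs, 2)]
    return 1.0 - float(np.mean(identities))


# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------

# Cα(i)-Cα(i+k) distance windows (Å) characteristic of the two regular
# conformations.  An ideal α-helix (rise 1.5 Å, 100° twist, radius 2.3 Å)
# gives d2 ≈ 5.4, d3 ≈ 5.1, d4 ≈ 6.2; a β-strand gives d2 ≈ 6.4-7.6 and
# d3 ≈ 9.5-11.4 depending on pleat.  Values follow the P-SEA approach of
# assigning states from short-range Cα distances alone.
_HELIX_D2 = (4.9, 6.1)
_HELIX_D3 = (4.5, 5.7)
_HELIX_D4 = (5.5, 7.0)
_STRAND_D2 = (6.2, 8.0)
_STRAND_D3 = (9.0, 12.0)


def assign_secondary_structure(model: StructureModel) -> str:
    """Assign a 3-state (H/E/C) string from Cα geometry.

    Windows of short-range Cα-Cα distances consistent with helix (or
    strand) geometry mark the residues they span as H (or E); everything
    else is coil.  Requires at least five residues.
    """
    n = len(model)
    if n < 5:
        raise InputTooSmallError(
            f"secondary-structure assignment needs ≥ 5 residues (got {n})"
        )
    ca = model.ca_coords

    def dist(i: int, k: int) -> float:
        return float(np.linalg.norm(ca[i + k] - ca[i]))

    labels = ["C"] * n
    for i in range(n - 3):
        d2, d3 = dist(i, 2), dist(i, 3)
        helix = _HELIX_D2[0] <= d2 <= _HELIX_D2[1] and \
            _HELIX_D3[0] <= d3 <= _HELIX_D3[1]
        if helix and i + 4 < n:
            d4 = dist(i, 4)
            helix = _HELIX_D4[0] <= d4 <= _HELIX_D4[1]
        if helix:
            for j in range(i, min(i + 4, n)):
                labels[j] = "H"
    for i in range(n - 3):
        d2, d3 = dist(i, 2), dist(i, 3)
        if _STRAND_D2[0] <= d2 <= _STRAND_D2[1] and \
                _STRAND_D3[0] <= d3 <= _STRAND_D3[1]:
            for j in range(i, i + 4):
                if labels[j] == "C":
                    labels[j] = "E"
    return "".join(labels)


def compute_ss_score(ss_designed: str, ss_native: str) -> float:
    """Positional identity between two 3-state secondary-structure strings."""
    if len(ss_designed) != len(ss_native):
        raise DimensionMismatchError(
            "secondary-structure strings differ in length "
            f"({len(ss_designed)} vs {len(ss_native)})"
        )
    return sum(a == b for a, b in zip(ss_designed, ss_native)) / len(ss_native)


# ---------------------------------------------------------------------------
# structural indicators
# ---------------------------------------------------------------------------

def compute_rmsd(a: StructureModel | np.ndarray,
                 b: StructureModel | np.ndarray) -> float:
    """Minimal Cα RMSD after optimal rigid (Kabsch) superposition.

    Centroids are removed and the optimal proper rotation is found by SVD
    (reflections excluded), so the value is invariant under any rigid
    motion of either argument and symmetric in them.
    """
    pa = a.ca_coords if isinstance(a, StructureModel) else np.asarray(a, float)
    pb = b.ca_coords if isinstance(b, StructureModel) else np.asarray(b, float)
    if pa.shape != pb.shape:
        raise DimensionMismatchError(
            f"coordinate sets differ in shape ({pa.shape} vs {pb.shape})"
        )
    n = pa.shape[0]
    if n < 3:
        raise InputTooSmallError("superposition needs at least 3 residues")
    ca_, cb_ = pa - pa.mean(axis=0), pb - pb.mean(axis=0)
    if min(np.linalg.matrix_rank(ca_, tol=1e-8),
           np.linalg.matrix_rank(cb_, tol=1e-8)) < 2:
        raise DegenerateInputError(
            "collinear coordinates: superposition is ill-defined"
        )
    rot, _ = Rotation.align_vectors(ca_, cb_)
    # residuals computed explicitly: the solver's internal RSSD loses
    # precision to cancellation when the fit is near-exact
    residuals = ca_ - rot.apply(cb_)
    return float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))


@dataclass
class QualifiedStats:
    """Fraction of designs folding within the cutoff, and their mean RMSD."""

    qualified_rate: float
    mean_qualified_rmsd: float | None

    @property
    def is_defined(self) -> bool:
        return self.mean_qualified_rmsd is not None


def qualified_stats(rmsds: Sequence[float],
                    cutoff: float = QUALIFIED_RMSD_CUTOFF) -> QualifiedStats:
    """Strict-inequality qualification: RMSD < cutoff.

    The mean is taken over qualified structures only and is undefined
    (None) when none qualifies.
    """
    values = np.asarray(list(rmsds), dtype=float)
    if values.size == 0:
        raise InputTooSmallError("qualified_stats needs at least one RMSD")
    if np.any(values < 0) or np.any(~np.isfinite(values)):
        raise DimensionMismatchError("RMSD values must be finite and ≥ 0")
    qualified = values[values < cutoff]
    rate = qualified.size / values.size
    mean = float(qualified.mean()) if qualified.size else None
    return QualifiedStats(qualified_rate=rate, mean_qualified_rmsd=mean)


# ---------------------------------------------------------------------------
# solvent exposure and nonpolar loss
# ---------------------------------------------------------------------------

@dataclass
class ExposureProfile:
    """Per-residue relative solvent accessibility plus nonpolar flags."""

    residue_numbers: list[int]
    codes: list[str]
    rsa: np.ndarray
    nonpolar: np.ndarray  # boolean


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=-1)


def compute_residue_exposure(model: StructureModel, probe_radius: float = 1.4,
                             n_points: int = 100,
                             nonpolar_set: frozenset[str] | None = None,
                             ) -> ExposureProfile:
    """Relative solvent accessibility by a coarse Shrake-Rupley scheme.

    The model carries at most backbone coordinates, so each residue is
    represented as a single sphere centred on its Cα whose radius is
    calibrated against the shipped maximal-SASA reference: an isolated
    residue exposes its full reference area, making RSA exactly 1 for it
    and a point-count fraction otherwise.  Sample points are a
    deterministic Fibonacci lattice; RSA is clamped to [0, 1].
    """
    if len(model) < 5:
        raise InputTooSmallError(
            f"exposure needs ≥ 5 residues (got {len(model)})"
        )
    nonpolar_set = default_nonpolar_set() if nonpolar_set is None \
        else frozenset(nonpolar_set)
    max_sasa = max_sasa_reference()
    centers = model.ca_coords
    # effective residue radius so that 4π(r+probe)² equals the reference
    radii = np.array([
        np.sqrt(max_sasa[r.code] / (4.0 * np.pi)) - probe_radius
        for r in model.residues
    ])
    sphere = _fibonacci_sphere(n_points)
    rsa = np.empty(len(model))
    for i in range(len(model)):
        shell = radii[i] + probe_radius
        points = centers[i] + shell * sphere
        exposed = np.ones(n_points, dtype=bool)
        for j in range(len(model)):
            if j == i:
                continue
            occlusion = radii[j] + probe_radius
            d2 = np.sum((points - centers[j]) ** 2, axis=1)
            exposed &= d2 > occlusion**2
            if not exposed.any():
                break
        rsa[i] = exposed.mean()
    rsa = np.clip(rsa, 0.0, 1.0)
    codes = [r.code for r in model.residues]
    return ExposureProfile(
        residue_numbers=[r.number for r in model.residues],
        codes=codes,
        rsa=rsa,
        nonpolar=np.array([c in nonpolar_set for c in codes]),
    )


def nonpolar_surface_score(model: StructureModel,
                           rsa_cutoff: float | None = None,
                           nonpolar_set: frozenset[str] | None = None,
                           **exposure_kwargs) -> float:
    """Exposure-weighted nonpolar surface content S = Σ RSA over nonpolar
    residues (optionally restricted to residues with RSA ≥ *rsa_cutoff*)."""
    profile = compute_residue_exposure(model, nonpolar_set=nonpolar_set,
                                       **exposure_kwargs)
    rsa = profile.rsa[profile.nonpolar]
    if rsa_cutoff is not None:
        rsa = rsa[rsa >= rsa_cutoff]
    return float(rsa.sum())


def compute_nonpolar_loss(design: StructureModel, native: StructureModel,
                          rsa_cutoff: float | None = None,
                          nonpolar_set: frozenset[str] | None = None,
                          **exposure_kwargs) -> float:
    """Nonpolar surface content of the design relative to the native.

    Values above 1 mean the designed structure exposes more hydrophobic
    surface than the native does — a sign of irrational residue placement.
    """
    s_native = nonpolar_surface_score(native, rsa_cutoff, nonpolar_set,
                                      **exposure_kwargs)
    if s_native == 0:
        raise DegenerateInputError(
            "native structure has zero nonpolar surface content"
        )
    s_design = nonpolar_surface_score(design, rsa_cutoff, nonpolar_set,
                                      **exposure_kwargs)
    return s_design / s_native


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------

@dataclass
class ProteinDesignSet:
    """All designs of one method for one target protein."""

    protein: str
    native_sequence: SequenceRecord
    native_structure: StructureModel
    designs: list[SequenceRecord]
    design_structures: list[StructureModel] = field(default_factory=list)


@dataclass
class MethodBundle:
    """One design method's outputs over the benchmark proteins."""

    method: str
    proteins: list[ProteinDesignSet]
    time_seconds: float | None = None


DENOVO_COLUMNS = ["Recovery", "Diversity", "Time (s)", "SS score",
                  "RMSD (Å)", "Nonpolar loss"]
SINGLECHAIN_COLUMNS = ["Recovery", "Diversity", "Time (s)", "SS score",
                       "Nonpolar loss", "RMSD (Å)", "Qualified rate"]
DEFAULT_ORIENTATIONS = {
    "Recovery": "benefit",
    "Diversity": "benefit",
    "Time (s)": "cost-linear",
    "SS score": "benefit",
    "RMSD (Å)": "cost-reciprocal",
    "Nonpolar loss": "cost-linear",
    "Qualified rate": "benefit",
}


def build_indicator_table(bundles: Sequence[MethodBundle],
                          mode: str = "de-novo",
                          qualified_cutoff: float = QUALIFIED_RMSD_CUTOFF,
                          rsa_cutoff: float | None = None,
                          ) -> IndicatorTable:
    """Assemble the methods × indicators matrix from raw design bundles.

    Per-method values are unweighted means of per-protein means, so every
    target protein counts equally regardless of its design count.  In
    ``single-chain`` mode the RMSD column holds the mean RMSD of qualified
    designs (strictly below *qualified_cutoff*) and a Qualified-rate
    column is added; Diversity is always computed on all designs,
    qualified or not.
    """
    if mode not in ("de-novo", "single-chain"):
        raise DimensionMismatchError(f"unknown mode {mode!r}")
    if not bundles:
        raise InputTooSmallError("no method bundles supplied")
    reference = {p.protein: p.native_sequence.sequence
                 for p in bundles[0].proteins}
    rows = {}
    for bundle in bundles:
        if {p.protein for p in bundle.proteins} != set(reference):
            raise DimensionMismatchError(
                f"method {bundle.method!r} does not cover the same native "
                "references as the other bundles"
            )
        rec, div, ss, rmsd_vals, rates, npl = [], [], [], [], [], []
        for pset in bundle.proteins:
            if not pset.designs or not pset.design_structures:
                raise InputTooSmallError(
                    f"method {bundle.method!r}, protein {pset.protein!r}: "
                    "missing designs or folded structures"
                )
            rec.append(mean_recovery(pset.designs, pset.native_sequence))
            div.append(compute_diversity(pset.designs))
            ss_native = assign_secondary_structure(pset.native_structure)
            ss.append(float(np.mean([
                compute_ss_score(assign_secondary_structure(m), ss_native)
                for m in pset.design_structures
            ])))
            rmsds = [compute_rmsd(m, pset.native_structure)
                     for m in pset.design_structures]
            if mode == "de-novo":
                rmsd_vals.append(float(np.mean(rmsds)))
            else:
                stats = qualified_stats(rmsds, qualified_cutoff)
                rates.append(stats.qualified_rate)
                if stats.is_defined:
                    rmsd_vals.append(stats.mean_qualified_rmsd)
            npl.append(float(np.mean([
                compute_nonpolar_loss(m, pset.native_structure,
                                      rsa_cutoff=rsa_cutoff)
                for m in pset.design_structures
            ])))
        row = {
            "Recovery": float(np.mean(rec)),
            "Diversity": float(np.mean(div)),
            "Time (s)": bundle.time_seconds,
            "SS score": float(np.mean(ss)),
            "RMSD (Å)": float(np.mean(rmsd_vals)) if rmsd_vals else np.nan,
            "Nonpolar loss": float(np.mean(npl)),
        }
        if mode == "single-chain":
            row["Qualified rate"] = float(np.mean(rates))
        rows[bundle.method] = row
    columns = DENOVO_COLUMNS if mode == "de-novo" else SINGLECHAIN_COLUMNS
    df = pd.DataFrame.from_dict(rows, orient="index")[columns].astype(float)
    orientation = {c: DEFAULT_ORIENTATIONS[c] for c in columns}
    return IndicatorTable(data=df, orientation=orientation)
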