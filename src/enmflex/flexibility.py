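"""MSF / RMSF / B-factor profiles from normal modes, and region statistics.

The mean square fluctuation of node i from the n_v slowest internal modes is

    MSF_i = (k_B T / m_i) * sum_j |U_ij|^2 / omega_j^2

with U_ij the eigenvector 3-vector of node i in mode j.  Rigid-body modes
never enter the sum.  B-factors follow the universal crystallographic
relation B = (8 pi^2 / 3) MSF; computed B is in reduced units until rescaled
against experiment by an origin shift (rigid-body contribution in the X-ray
data) and a scale factor, fitted by ordinary least squares.

Flexibility is reported as relative RMSF: sqrt(MSF) normalized so the mean
over the reporting node set is exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .elastic_network import BACKBONE_ATOMS, NodeSet
from .rtb_nma import ModeSet
from .structure_io import LAYER_NAMES, RegionAssignment

logger = logging.getLogger(__name__)

BFACTOR_CONSTANT = 8.0 * np.pi**2 / 3.0


def msf(
    modeset: ModeSet,
    n_v: int = 100,
    masses: Optional[np.ndarray] = None,
    kBT: float = 1.0,
) -> np.ndarray:
    """Per-node mean square fluctuation from the n_v slowest internal modes.

    Uses all internal modes when fewer than ``n_v`` exist (logged).  Raises
    if a zero-frequency mode would enter the sum.
    """
    internal = modeset.internal_indices()
    if len(internal) < n_v:
        logger.info("only %d internal modes available (requested %d); using all",
                    len(internal), n_v)
    use = internal[:n_v]
    lam = modeset.eigenvalues[use]
    if np.any(lam <= 0):
        raise ValueError("zero/negative eigenvalue among internal modes; "
                         "check connectivity and the zero-mode tolerance")
    u = modeset.eigenvectors[:, use]  # (3N, nv)
    n = u.shape[0] // 3
    per_node = (u**2).reshape(n, 3, -1).sum(axis=1)  # (N, nv)
    if masses is None:
        masses = np.ones(n)
    return kBT / masses * (per_node / lam).sum(axis=1)


def bfactor(msf_values: np.ndarray) -> np.ndarray:
    """B = (8 pi^2 / 3) * MSF, preserving relative ordering."""
    msf_values = np.asarray(msf_values, dtype=float)
    if np.any(msf_values < 0):
        raise ValueError("MSF must be non-negative")
    return BFACTOR_CONSTANT * msf_values


class DegenerateFitError(ValueError):
    """The computed B-factor profile has no variance to fit."""


@dataclass
class BfactorFit:
    """Affine rescaling of computed B onto experimental B (least squares)."""

    scale: float
    shift: float
    fitted: np.ndarray
    correlation: float

    @property
    def r(self) -> float:
        return self.correlation


def rescale_to_experiment(
    b_calc: np.ndarray, b_exp: np.ndarray
) -> BfactorFit:
    """Ordinary least squares of experimental on computed B-factors.

    Fits b_exp ~ scale * b_calc + shift; the intercept absorbs the
    rigid-body contribution present in X-ray B-factors but absent from
    internal-mode fluctuations.
    """
    b_calc = np.asarray(b_calc, dtype=float)
    b_exp = np.asarray(b_exp, dtype=float)
    if b_calc.shape != b_exp.shape or b_calc.ndim != 1:
        raise ValueError("b_calc and b_exp must be 1-D arrays of equal length")
    if len(b_calc) < 3:
        raise ValueError("need at least 3 nodes to fit")
    if np.ptp(b_calc) == 0:
        raise DegenerateFitError("computed B-factors have zero variance")
    A = np.column_stack([b_calc, np.ones_like(b_calc)])
    (scale, shift), *_ = np.linalg.lstsq(A, b_exp, rcond=None)
    fitted = scale * b_calc + shift
    r = float(np.corrcoef(b_calc, b_exp)[0, 1])
    return BfactorFit(scale=float(scale), shift=float(shift),
                      fitted=fitted, correlation=r)


def relative_rmsf(
    msf_values: np.ndarray,
    reporting_set: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """sqrt(MSF) normalized to mean 1 over the reporting node set."""
    msf_values = np.asarray(msf_values, dtype=float)
    rmsf = np.sqrt(msf_values)
    idx = (np.arange(len(rmsf)) if reporting_set is None
           else np.asarray(reporting_set, dtype=int))
    if idx.size == 0:
        raise ValueError("reporting set is empty")
    mean = rmsf[idx].mean()
    if mean == 0:
        raise ValueError("all-zero MSF; cannot normalize")
    return rmsf / mean


def residue_values(
    values: np.ndarray, nodes: NodeSet, scheme: str = "calpha_plus_hetero"
):
    """Aggregate per-node values to per-residue values.

    C-alpha mode: the residue value is its C-alpha node's value (hetero
    residues average over their atom nodes).  All-heavy mode: the average
    over backbone atoms (N, CA, C, O); hetero residues again average over
    all their heavy atoms.  Returns (residue_keys, residue_values).
    """
    groups: dict = {}
    order = []
    for i, lab in enumerate(nodes.labels):
        key = (lab.chain_id, lab.residue_number, lab.insertion_code)
        if key not in groups:
            groups[key] = []
            order.append((key, lab.residue_name, lab.is_hetero))
        groups[key].append(i)
    keys, vals = [], []
    for key, resname, het in order:
        idx = groups[key]
        if het or scheme == "calpha_plus_hetero":
            chosen = idx
        else:
            chosen = [i for i in idx if nodes.labels[i].atom_name in BACKBONE_ATOMS]
            if not chosen:
                chosen = idx
        keys.append(key)
        vals.append(float(np.mean([values[i] for i in chosen])))
    return keys, np.array(vals)


@dataclass
class FlexibilityProfile:
    """Per-node flexibility measures for one NMA run."""

    nodes: NodeSet
    msf: np.ndarray
    rel_rmsf: np.ndarray
    b_calc: np.ndarray
    fit: Optional[BfactorFit] = None
    n_v: int = 100

    def table(self, assignment: Optional[RegionAssignment] = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chain": [l.chain_id for l in self.nodes.labels],
                "residue": [l.residue_number for l in self.nodes.labels],
                "residue_name": [l.residue_name for l in self.nodes.labels],
                "atom": [l.atom_name for l in self.nodes.labels],
                "msf": self.msf,
                "rel_rmsf": self.rel_rmsf,
                "b_calc": self.b_calc,
            }
        )
        if self.fit is not None:
            df["b_fit"] = self.fit.fitted
        if self.nodes.b_experimental is not None:
            df["b_exp"] = self.nodes.b_experimental
        if assignment is not None:
            layer = np.array(
                [LAYER_NAMES[i] if i >= 0 else "" for i in assignment.layer_index]
            )
            df["layer"] = layer
            regions = np.array([""] * len(self.nodes), dtype=object)
            for name, idx in assignment.region_members.items():
                for i in idx:
                    regions[i] = (regions[i] + "+" + name) if regions[i] else name
            df["region"] = regions
        return df


def flexibility_profile(
    modeset: ModeSet,
    n_v: int = 100,
    masses: Optional[np.ndarray] = None,
    kBT: float = 1.0,
    fit_to_experiment: bool = False,
    terminal_trim: int = 0,
) -> FlexibilityProfile:
    """Full MSF -> relative RMSF -> B-factor pipeline for one mode set.

    ``terminal_trim`` residues at each chain end are excluded from the
    experimental fit (termini disagree with internal-mode predictions).
    """
    nodes = modeset.nodes
    m = msf(modeset, n_v=n_v, masses=masses, kBT=kBT)
    rel = relative_rmsf(m)
    b = bfactor(m)
    fit = None
    if fit_to_experiment:
        if nodes is None or nodes.b_experimental is None:
            raise ValueError("no experimental B-factors on the node set")
        keep = _trim_termini(nodes, terminal_trim)
        partial = rescale_to_experiment(b[keep], nodes.b_experimental[keep])
        fit = BfactorFit(
            scale=partial.scale,
            shift=partial.shift,
            fitted=partial.scale * b + partial.shift,
            correlation=partial.correlation,
        )
    return FlexibilityProfile(nodes=nodes, msf=m, rel_rmsf=rel, b_calc=b,
                              fit=fit, n_v=n_v)


def _trim_termini(nodes: NodeSet, trim: int) -> np.ndarray:
    if trim <= 0:
        return np.arange(len(nodes))
    keep = []
    by_chain: dict = {}
    for i, lab in enumerate(nodes.labels):
        if lab.is_hetero:
            keep.append(i)
            continue
        by_chain.setdefault(lab.chain_id, []).append((lab.residue_number, i))
    for chain, entries in by_chain.items():
        nums = sorted({n for n, _ in entries})
        lo = set(nums[:trim])
        hi = set(nums[-trim:])
        keep.extend(i for n, i in entries if n not in lo and n not in hi)
    return np.array(sorted(keep), dtype=int)


def region_layer_report(
    rel_rmsf: np.ndarray,
    assignment: RegionAssignment,
    nodes: Optional[NodeSet] = None,
    scheme: str = "calpha_plus_hetero",
) -> pd.DataFrame:
    """Mean relative RMSF per named region and per radial layer.

    Means are unweighted arithmetic means over residue-level values when a
    node set is supplied (each hetero group contributes its atom-averaged
    value per residue), else over raw node values.  Empty regions are
    omitted with a warning.  Rows come out in deterministic order: named
    regions sorted alphabetically, then the three layers inside-out.
    """
    rows = []

    def region_mean(idx):
        if nodes is None:
            return float(np.mean(rel_rmsf[idx])), int(len(idx))
        sub = nodes.subset(idx)
        _, vals = residue_values(rel_rmsf[idx], sub, scheme)
        return float(vals.mean()), int(len(vals))

    for name in sorted(assignment.region_members):
        idx = assignment.region_members[name]
        if len(idx) == 0:
            logger.warning("region %s is empty; omitted from report", name)
            continue
        mean, n = region_mean(idx)
        rows.append({"region": name, "mean_rel_rmsf": mean, "n": n})
    if np.any(assignment.layer_index >= 0):
        for li, lname in enumerate(LAYER_NAMES):
            idx = assignment.layer_members(li)
            if len(idx) == 0:
                logger.warning("layer %s is empty; omitted from report", lname)
                continue
            mean, n = region_mean(idx)
            rows.append({"region": lname, "mean_rel_rmsf": mean, "n": n})
    return pd.DataFrame(rows, columns=["region", "mean_rel_rmsf", "n"])


def compare_profiles(
    profile_a: FlexibilityProfile,
    profile_b: FlexibilityProfile,
    shared_a: Sequence[int],
    shared_b: Sequence[int],
    assignment: Optional[RegionAssignment] = None,
) -> dict:
    """Per-node (and optional per-region) relative-RMSF deltas, b minus a.

    ``shared_a``/``shared_b`` map the common nodes of the two runs (e.g. the
    protein nodes of a with-substrate and a without-substrate network).
    Positive delta means the node is more mobile in profile_b.  Region
    deltas use profile_a's node indexing via ``assignment``.
    """
    shared_a = np.asarray(shared_a, dtype=int)
    shared_b = np.asarray(shared_b, dtype=int)
    if shared_a.size == 0 or shared_a.size != shared_b.size:
        raise ValueError("shared node sets must be non-empty and same length")
    delta = profile_b.rel_rmsf[shared_b] - profile_a.rel_rmsf[shared_a]
    out = {"per_node": delta}
    if assignment is not None:
        pos_of = {int(a): k for k, a in enumerate(shared_a)}
        region_delta = {}
        for name, idx in assignment.region_members.items():
            local = [pos_of[int(i)] for i in idx if int(i) in pos_of]
            if local:
                region_delta[name] = float(np.mean(delta[local]))
        out["per_region"] = region_delta
    return out
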