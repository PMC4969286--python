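"""Reciprocity-based montage construction with safety constraints.

Given a lead-field matrix, a cortical target patch is projected to a scalp
voltage topography (the potential its unit dipole would produce at every
electrode).  Electrodes are ranked by that topography: the N most positive
become current sources (anodes) and the M most negative become sinks
(cathodes), each weighted proportionally to its voltage relative to the
side maximum and scaled to the per-channel safety cap.  The two sides are
then balanced to an exactly zero net current by scaling the
larger-magnitude side, and finally the whole montage is scaled down if the
one-sided total exceeds the requested or maximum allowed total current.

Sign convention: ``cortical-surface-anodal`` drives current *along* the
patch's averaged surface normal at the target (positive normal current
density, n.J > 0) and ``cortical-surface-cathodal`` is its exact negation.
Because the induced current density is J = -sigma grad(phi), maximizing
n.J requires injecting in proportion to the *negated* scalp projection of
the along-normal dipole; the projection returned for the anodal polarity is
therefore the negated lead-field column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tesplan.fdm import (
    FDMSystem,
    InjectionPattern,
    LeadFieldMatrix,
    _gradient_at,
    assemble_fdm_system,
    current_density,
    solve_injection,
)
from tesplan.phantom import ElectrodeSet, VoxelHeadModel

__all__ = [
    "SafetyLimits",
    "TargetSpec",
    "Montage",
    "project_target_to_scalp",
    "select_and_weight",
    "balance_and_cap",
    "plan_montage",
    "build_sham_montage",
    "evaluate_montage",
    "MontageEvaluator",
]

POLARITIES = ("cortical_surface_anodal", "cortical_surface_cathodal")


@dataclass(frozen=True)
class SafetyLimits:
    """Hardware safety caps: per-channel current (uA) and total current (mA)."""

    max_channel_ua: float = 200.0
    max_total_ma: float = 2.0

    def __post_init__(self) -> None:
        if self.max_channel_ua <= 0 or self.max_total_ma <= 0:
            raise ValueError("safety limits must be positive")
        if self.max_channel_ua > self.max_total_ma * 1000.0:
            raise ValueError("per-channel cap cannot exceed the total cap")


@dataclass(frozen=True)
class TargetSpec:
    """A planned stimulation target: patch, cortical-surface polarity, total current."""

    patch_id: int
    polarity: str
    requested_total_ma: float
    limits: SafetyLimits = field(default_factory=SafetyLimits)

    def __post_init__(self) -> None:
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}")
        if not 0 < self.requested_total_ma <= self.limits.max_total_ma:
            raise ValueError("requested total must be positive and within the safety total")


@dataclass
class Montage:
    """Signed per-electrode currents in uA (+ source/anode, - sink/cathode)."""

    electrode_ids: list[str]
    currents_ua: np.ndarray

    def __post_init__(self) -> None:
        self.currents_ua = np.asarray(self.currents_ua, dtype=float)
        if self.currents_ua.shape != (len(self.electrode_ids),):
            raise ValueError("one current per electrode id required")

    @property
    def n_sources(self) -> int:
        return int(np.sum(self.currents_ua > 0))

    @property
    def n_sinks(self) -> int:
        return int(np.sum(self.currents_ua < 0))

    @property
    def total_source_ua(self) -> float:
        return float(self.currents_ua[self.currents_ua > 0].sum())

    def net_current_ua(self) -> float:
        return float(self.currents_ua.sum())

    def negated(self) -> "Montage":
        return Montage(list(self.electrode_ids), -self.currents_ua)

    def validate(self, limits: SafetyLimits | None = None) -> None:
        mx = np.max(np.abs(self.currents_ua)) if self.currents_ua.size else 0.0
        if mx > 0 and abs(self.currents_ua.sum()) > 1e-9 * mx:
            raise ValueError("montage currents do not sum to zero")
        if limits is not None:
            if mx > limits.max_channel_ua * (1 + 1e-12):
                raise ValueError("per-channel safety cap exceeded")
            if self.total_source_ua > limits.max_total_ma * 1000.0 * (1 + 1e-12):
                raise ValueError("total current safety cap exceeded")

    def to_dict(self) -> dict[str, float]:
        return {e: float(c) for e, c in zip(self.electrode_ids, self.currents_ua)}


def project_target_to_scalp(
    lfm: LeadFieldMatrix, patch_id: int, polarity: str = "cortical_surface_anodal"
) -> np.ndarray:
    """Scalp voltage topography used to rank electrodes for a target patch.

    Returns the average-referenced lead-field column of the target's unit
    along-normal dipole, with the overall sign chosen so that injecting in
    proportion to the returned values drives current in the requested
    cortical-surface direction at the target (see module docstring); the
    cathodal projection is the elementwise negation of the anodal one.
    """
    if polarity not in POLARITIES:
        raise ValueError(f"polarity must be one of {POLARITIES}")
    col = lfm.column(patch_id)
    sign = -1.0 if polarity == "cortical_surface_anodal" else 1.0
    return sign * col


def select_and_weight(
    voltages: np.ndarray,
    n_sources: int,
    n_sinks: int,
    limits: SafetyLimits = SafetyLimits(),
    electrode_ids: list[str] | None = None,
) -> Montage:
    """Rank electrodes by projected voltage and weight them against the channel cap.

    The ``n_sources`` electrodes with the largest positive voltages become
    sources and the ``n_sinks`` with the largest-magnitude negative voltages
    become sinks.  The side maxima get weight +-1.0 and every other selected
    electrode is weighted proportionally; currents are weight times the
    per-channel cap.  Ranking ties are broken toward the lower electrode
    index.  Raises if fewer than ``n_sources`` positive or ``n_sinks``
    negative voltages exist.
    """
    v = np.asarray(voltages, dtype=float)
    if n_sources < 1 or n_sinks < 1:
        raise ValueError("need at least one source and one sink")
    if electrode_ids is None:
        electrode_ids = [f"E{i + 1:03d}" for i in range(v.size)]
    pos = np.flatnonzero(v > 0)
    neg = np.flatnonzero(v < 0)
    if pos.size < n_sources or neg.size < n_sinks:
        raise ValueError(
            f"insufficient polarity: {pos.size} positive / {neg.size} negative voltages "
            f"for N={n_sources}, M={n_sinks}"
        )
    # stable sorts keep the lowest index first among exact ties
    src = pos[np.argsort(-v[pos], kind="stable")][:n_sources]
    snk = neg[np.argsort(v[neg], kind="stable")][:n_sinks]

    currents = np.zeros_like(v)
    currents[src] = v[src] / v[src].max() * limits.max_channel_ua
    currents[snk] = -(np.abs(v[snk]) / np.abs(v[snk]).max()) * limits.max_channel_ua
    return Montage(list(electrode_ids), currents)


def balance_and_cap(
    montage: Montage,
    requested_total_ma: float,
    limits: SafetyLimits = SafetyLimits(),
) -> Montage:
    """Zero-sum balancing followed by the total-current normalization.

    The larger-magnitude side is scaled by the ratio of side sums so the
    total anodal and cathodal currents cancel exactly; then, if the
    one-sided total exceeds ``min(requested, safety total)``, every current
    is scaled down by that ratio.  Caps can only shrink currents, so the
    per-channel limit is preserved.
    """
    if requested_total_ma <= 0:
        raise ValueError("requested total current must be positive")
    c = montage.currents_ua.copy()
    pos_sum = c[c > 0].sum()
    neg_sum = -c[c < 0].sum()
    if pos_sum <= 0 or neg_sum <= 0:
        raise ValueError("montage needs both sources and sinks before balancing")
    if pos_sum > neg_sum:
        c[c > 0] *= neg_sum / pos_sum
    elif neg_sum > pos_sum:
        c[c < 0] *= pos_sum / neg_sum
    side = c[c > 0].sum()
    allowed = min(requested_total_ma, limits.max_total_ma) * 1000.0
    if side > allowed:
        c *= allowed / side
    out = Montage(list(montage.electrode_ids), c)
    out.validate(limits)
    return out


def plan_montage(
    lfm: LeadFieldMatrix,
    patch_id: int,
    polarity: str = "cortical_surface_anodal",
    n_sources: int = 8,
    n_sinks: int = 8,
    requested_total_ma: float = 2.0,
    limits: SafetyLimits = SafetyLimits(),
) -> Montage:
    """Full reciprocity plan: project, rank/weight, balance and cap."""
    v = project_target_to_scalp(lfm, patch_id, polarity)
    pre = select_and_weight(v, n_sources, n_sinks, limits, list(lfm.electrode_ids))
    return balance_and_cap(pre, requested_total_ma, limits)


def build_sham_montage(
    active: Montage,
    electrodes: ElectrodeSet,
    pair_current_ua: float = 100.0,
) -> Montage:
    """Placebo montage: one shallow local pair inside each active cluster.

    In the source cluster the active electrode carrying the lowest current
    is paired with its nearest neighbor in the full array (the neighbor
    takes the opposite sign), and likewise in the sink cluster, giving a
    total positive current of twice ``pair_current_ua`` (200 uA at the
    default).  A candidate neighbor that already carries active current of
    the opposite side — or is already used by the other sham pair — is
    skipped with a warning and the next-nearest electrode is used.
    """
    c = active.currents_ua
    src = np.flatnonzero(c > 0)
    snk = np.flatnonzero(c < 0)
    if src.size == 0 or snk.size == 0:
        raise ValueError("active montage needs at least one source and one sink")
    pos = electrodes.positions_mm
    sham = np.zeros_like(c)
    used: set[int] = set()

    def make_pair(cluster: np.ndarray, opposite: np.ndarray, sign: float) -> None:
        anchor = cluster[np.argmin(np.abs(c[cluster]))]
        used.add(int(anchor))
        d = np.linalg.norm(pos - pos[anchor], axis=1)
        d[anchor] = np.inf
        opposite_set = set(int(i) for i in opposite)
        for cand in np.argsort(d, kind="stable"):
            cand = int(cand)
            if cand in used or cand in opposite_set:
                warnings.warn(
                    f"sham neighbor {electrodes.ids[cand]} unavailable "
                    f"(active on the opposite side or already used); trying next-nearest"
                )
                continue
            sham[anchor] = sign * pair_current_ua
            sham[cand] = -sign * pair_current_ua
            used.add(cand)
            return
        raise ValueError("no eligible sham neighbor found")

    make_pair(src, snk, +1.0)
    make_pair(snk, src, -1.0)
    out = Montage(list(active.electrode_ids), sham)
    out.validate()
    return out


def _patch_voxels(system: FDMSystem, parcellation) -> list[tuple[int, int, int]]:
    out = []
    for p in parcellation.patches:
        i, j, k = system.model.point_to_voxel(p.centroid_mm)
        if system.index[i, j, k] < 0:
            d2 = np.sum((system.voxels - np.array([i, j, k])) ** 2, axis=1)
            best = int(np.argmin(d2))
            if d2[best] > 3**2:
                raise ValueError(f"patch {p.id} centroid lies in air, far from conducting tissue")
            i, j, k = (int(v) for v in system.voxels[best])
        out.append((i, j, k))
    return out


def evaluate_montage(
    model: VoxelHeadModel,
    electrodes: ElectrodeSet,
    montage: Montage,
    parcellation,
    system: FDMSystem | None = None,
    tol: float = 1e-8,
    threshold_lowest: float | None = None,
) -> pd.DataFrame:
    """Forward-solve a montage and report per-patch normal/tangential current density.

    At each patch centroid the current density J (A/m^2) is decomposed into
    its signed component along the patch normal and the tangential
    magnitude.  ``threshold_lowest=0.5`` adds a ``display`` column masking
    the lowest 50% of |normal| values (the usual display convention for
    cortical current-density maps).
    """
    if list(montage.electrode_ids) != list(electrodes.ids):
        unknown = set(montage.electrode_ids) - set(electrodes.ids)
        raise ValueError(f"montage references unknown electrodes: {sorted(unknown)}")
    montage.validate()
    if system is None:
        system = assemble_fdm_system(model)
    phi = solve_injection(system, electrodes, InjectionPattern(montage.currents_ua), tol=tol)
    J = current_density(model, phi).values
    rows = []
    for patch, vox in zip(parcellation.patches, _patch_voxels(system, parcellation)):
        j = J[vox]
        jn = float(j @ patch.normal)
        jt = float(np.linalg.norm(j - jn * patch.normal))
        rows.append({"patch_id": patch.id, "normal_a_per_m2": jn, "tangential_a_per_m2": jt})
    df = pd.DataFrame(rows)
    if threshold_lowest is not None:
        cut = df["normal_a_per_m2"].abs().quantile(threshold_lowest)
        df["display"] = df["normal_a_per_m2"].abs() >= cut
    return df


class MontageEvaluator:
    """Evaluate many montages on one head model via superposition.

    Precomputes one forward solve per electrode (against a fixed reference)
    and the potential gradients at every patch centroid; any zero-sum
    montage on the same electrode set is then evaluated as a weighted sum
    of the cached solutions — numerically identical (by linearity) to a
    dedicated forward solve of the montage.
    """

    def __init__(
        self,
        system: FDMSystem,
        electrodes: ElectrodeSet,
        parcellation,
        tol: float = 1e-8,
        reference_electrode: int = 0,
        solutions: np.ndarray | None = None,
    ):
        from tesplan.fdm import _grounded_solve

        self.system = system
        self.electrodes = electrodes
        self.parcellation = parcellation
        self.reference_electrode = reference_electrode
        self._voxels = _patch_voxels(system, parcellation)
        n_el = len(electrodes)
        if solutions is None:
            solutions = np.zeros((n_el, system.n_unknowns))
            ref_node = system.node_of_point(
                electrodes.positions_mm[reference_electrode], "reference electrode"
            )
            for e in range(n_el):
                if e == reference_electrode:
                    continue
                node = system.node_of_point(electrodes.positions_mm[e], f"electrode {electrodes.ids[e]}")
                b = np.zeros(system.n_unknowns)
                b[node] += 1.0
                b[ref_node] -= 1.0
                solutions[e] = _grounded_solve(system, b, tol)
        # gradients (V/m per A) of each electrode solution at each patch centroid
        self._grads = np.zeros((n_el, len(parcellation.patches), 3))
        for e in range(n_el):
            if not solutions[e].any():
                continue
            for pi, vox in enumerate(self._voxels):
                self._grads[e, pi] = _gradient_at(system, solutions[e], vox)
        self._sigma = np.array([system.model.conductivity[v] for v in self._voxels])
        self._normals = parcellation.normals()

    def evaluate(self, montage: Montage) -> pd.DataFrame:
        """Per-patch normal and tangential current density for one montage."""
        montage.validate()
        amps = montage.currents_ua * 1e-6
        grad = np.tensordot(amps, self._grads, axes=(0, 0))  # (patches, 3)
        J = -self._sigma[:, None] * grad
        jn = np.einsum("ij,ij->i", J, self._normals)
        jt = np.linalg.norm(J - jn[:, None] * self._normals, axis=1)
        return pd.DataFrame(
            {
                "patch_id": [p.id for p in self.parcellation.patches],
                "normal_a_per_m2": jn,
                "tangential_a_per_m2": jt,
            }
        )

    def target_normal_density(self, montage: Montage, patch_id: int) -> float:
        df = self.evaluate(montage)
        row = df[df["patch_id"] == patch_id]
        if row.empty:
            raise KeyError(f"patch {patch_id} not in parcellation")
        return float(row["normal_a_per_m2"].iloc[0])


def random_constraint_matched_montage(
    rng: np.random.Generator,
    n_electrodes: int,
    n_sources: int,
    n_sinks: int,
    total_source_ua: float,
    limits: SafetyLimits = SafetyLimits(),
    electrode_ids: list[str] | None = None,
) -> Montage:
    """Random zero-sum montage matching an active plan's electrode counts and totals.

    Used as the null family in Monte-Carlo comparisons against the
    reciprocity plan: same number of sources and sinks, same per-channel
    cap, same one-sided total current, electrodes chosen uniformly.
    """
    if electrode_ids is None:
        electrode_ids = [f"E{i + 1:03d}" for i in range(n_electrodes)]
    chosen = rng.choice(n_electrodes, size=n_sources + n_sinks, replace=False)
    src, snk = chosen[:n_sources], chosen[n_sources:]
    c = np.zeros(n_electrodes)
    for idx, side in ((src, +1.0), (snk, -1.0)):
        w = rng.uniform(0.2, 1.0, size=idx.size)
        w[rng.integers(idx.size)] = 1.0  # keep the side maximum at the cap pre-scaling
        c[idx] = side * w * limits.max_channel_ua
        scale = total_source_ua / np.abs(c[idx]).sum()
        if scale < 1.0 or np.abs(c[idx]).max() * scale <= limits.max_channel_ua:
            c[idx] *= scale
        else:
            c[idx] *= scale  # may exceed cap; renormalize below
    # enforce the per-channel cap while keeping side totals
    for idx in (src, snk):
        over = np.abs(c[idx]).max() / limits.max_channel_ua
        if over > 1.0:
            c[idx] /= over
    pos, neg = c[c > 0].sum(), -c[c < 0].sum()
    side_total = min(pos, neg, total_source_ua)
    c[c > 0] *= side_total / pos
    c[c < 0] *= side_total / neg
    m = Montage(list(electrode_ids), c)
    m.validate(limits)
    return m
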