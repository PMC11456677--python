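"""Winner-take-all parcellation of subcortical structures by voxel connectivity profile.

Each subcortical voxel carries one connection probability per cortical target
(as produced by probabilistic tractography); the voxel is assigned to the
target with the largest probability provided that maximum reaches a minimum
probability threshold tau, otherwise it is left unassigned.  Ties are broken
deterministically.  No spatial regularisation is applied by default; a
6-neighbourhood majority filter is available for 3D label grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

UNASSIGNED = -1


@dataclass
class ParcelMap:
    """Voxel -> subdivision assignment for one subcortical structure."""

    structure: str
    targets: tuple[str, ...]
    assignments: np.ndarray        # voxel -> target index, or UNASSIGNED
    tau: float
    tie_rule: str

    def label_name(self, target_index: int) -> str:
        return f"{self.structure}_{self.targets[target_index]}"


def winner_take_all(probs: np.ndarray, targets, structure: str = "",
                    tau: float = 0.01, tie_rule: str = "first-target") -> ParcelMap:
    """Assign each voxel to its maximal-probability cortical target.

    ``probs`` is voxels x targets with nonnegative entries (raw connection
    probabilities; tau compares against the raw maximum, so rescaling changes
    threshold behaviour but never the argmax).  ``tie_rule`` is
    ``first-target`` (earliest target in the recorded order wins) or
    ``unassigned`` (exact ties are left unassigned).
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[0] == 0:
        raise ValueError("empty profile set")
    if not np.isfinite(probs).all() or (probs < 0).any():
        raise ValueError("connection probabilities must be finite and nonnegative")
    if not (0 <= tau <= 1):
        raise ValueError("tau must be in [0, 1]")
    if tie_rule not in ("first-target", "unassigned"):
        raise ValueError(f"unknown tie rule {tie_rule!r}")
    targets = tuple(targets)
    if probs.shape[1] != len(targets):
        raise ValueError("profile width does not match the number of targets")

    winner = probs.argmax(axis=1)              # first maximal index (deterministic)
    peak = probs.max(axis=1)
    assignments = np.where(peak >= tau, winner, UNASSIGNED)
    if tie_rule == "unassigned":
        tied = (probs == peak[:, None]).sum(axis=1) > 1
        assignments = np.where(tied, UNASSIGNED, assignments)
    return ParcelMap(structure, targets, assignments.astype(int), tau, tie_rule)


def subdivision_mask(parcel_map: ParcelMap, structure: str, tag: str) -> np.ndarray:
    """Boolean voxel mask of the subdivision ``structure_tag`` (may be empty)."""
    if structure != parcel_map.structure:
        raise ValueError(f"parcel map is for {parcel_map.structure!r}, not {structure!r}")
    if tag not in parcel_map.targets:
        raise ValueError(f"unknown cortical tag {tag!r} for structure {structure!r}")
    return parcel_map.assignments == parcel_map.targets.index(tag)


def dice(mask_a, mask_b) -> float:
    """Dice overlap 2|A&B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    total = a.sum() + b.sum()
    if total == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / total


def recovery_dice(parcel_map: ParcelMap, true_labels: np.ndarray) -> dict[str, float]:
    """Per-subdivision Dice of the assignment against planted ground-truth labels."""
    true_labels = np.asarray(true_labels)
    return {
        tag: dice(parcel_map.assignments == t, true_labels == t)
        for t, tag in enumerate(parcel_map.targets)
    }


def majority_filter(labels: np.ndarray, n_iter: int = 1) -> np.ndarray:
    """6-neighbourhood majority relabeling for a 3D integer label grid.

    A voxel takes the modal label of its face neighbours when that mode is
    held by a strict majority; unassigned voxels never vote.  Off by default
    in the pipeline.
    """
    if labels.ndim != 3:
        raise ValueError("majority filter expects a 3D label grid")
    out = labels.copy()
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for _ in range(n_iter):
        cur = out.copy()
        padded = np.pad(cur, 1, constant_values=UNASSIGNED)
        neigh = np.stack([
            padded[1 + dx:cur.shape[0] + 1 + dx,
                   1 + dy:cur.shape[1] + 1 + dy,
                   1 + dz:cur.shape[2] + 1 + dz]
            for dx, dy, dz in offsets
        ])
        labels_present = np.unique(cur)
        labels_present = labels_present[labels_present != UNASSIGNED]
        counts = np.stack([(neigh == lab).sum(axis=0) for lab in labels_present]) \
            if labels_present.size else np.zeros((0,) + cur.shape, dtype=int)
        if labels_present.size:
            best = counts.argmax(axis=0)
            best_count = counts.max(axis=0)
            majority = best_count > 3  # strict majority of 6 face neighbours
            out = np.where(majority, labels_present[best], cur)
    return out


def resample_labels_integer_scale(labels: np.ndarray, factor: int) -> np.ndarray:
    """Nearest-neighbour up-sampling of a 3D label grid by an integer factor."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("scale factor must be a positive integer")
    return labels.repeat(factor, 0).repeat(factor, 1).repeat(factor, 2)
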