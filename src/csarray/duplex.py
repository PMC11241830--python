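"""Deterministic DUPLEX partitioning into training / monitoring / prediction sets.

Classical DUPLEX alternately seeds two subsets with the mutually farthest
remaining pair, then grows each subset with the point farthest from its
current members.  The calibration workflow here needs three subsets, so
the procedure is generalized round-robin: pair seeding and point growth
always go to the subset currently furthest below its target size.
Distances are Euclidean on autoscaled features; all ties break toward the
lowest index, so the split is a pure function of the feature matrix.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml

SET_NAMES = ("train", "monitor", "predict")


@dataclass
class SplitResult:
    train_idx: np.ndarray
    monitor_idx: np.ndarray
    predict_idx: np.ndarray
    ratios: tuple[float, ...]

    def __post_init__(self):
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.monitor_idx = np.asarray(self.monitor_idx, dtype=int)
        self.predict_idx = np.asarray(self.predict_idx, dtype=int)

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train_idx), len(self.monitor_idx), len(self.predict_idx))

    def subsets(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.train_idx, self.monitor_idx, self.predict_idx)

    def to_yaml(self, path, features: np.ndarray | None = None) -> None:
        raw = {
            "ratios": list(self.ratios),
            "train_idx": self.train_idx.tolist(),
            "monitor_idx": self.monitor_idx.tolist(),
            "predict_idx": self.predict_idx.tolist(),
        }
        if features is not None:
            raw["feature_checksum"] = hashlib.sha256(
                np.ascontiguousarray(features, dtype=float).tobytes()
            ).hexdigest()
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _target_sizes(m: int, ratios: Sequence[float]) -> list[int]:
    # largest-remainder apportionment; ties toward earlier sets
    exact = [m * r for r in ratios]
    base = [int(np.floor(e)) for e in exact]
    rem = m - sum(base)
    order = sorted(range(len(ratios)), key=lambda i: (-(exact[i] - base[i]), i))
    for i in order[:rem]:
        base[i] += 1
    return base


def duplex_split(
    features: np.ndarray, ratios: Sequence[float] = (0.5, 0.25, 0.25)
) -> SplitResult:
    """Partition samples into subsets by the generalized DUPLEX procedure.

    With the default ratios and m = 240 the sizes are 120/60/60.  Fully
    deterministic: identical features give an identical split.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    m = X.shape[0]
    n_sets = len(ratios)
    if any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must be positive and sum to 1")
    if m < 2 * n_sets:
        raise ValueError(f"need at least {2 * n_sets} samples for {n_sets} sets, got {m}")

    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    # full pairwise squared distances; m is a few hundred in this workflow
    D = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(axis=2)

    targets = _target_sizes(m, ratios)
    members: list[list[int]] = [[] for _ in range(n_sets)]
    unassigned = list(range(m))

    def neediest() -> int:
        deficits = [targets[k] - len(members[k]) for k in range(n_sets)]
        return max(range(n_sets), key=lambda k: (deficits[k], -k))

    # pair-seeding phase: every set starts with the farthest remaining pair
    for _ in range(n_sets):
        empties = [k for k in range(n_sets) if not members[k]]
        if not empties:
            break
        k = max(empties, key=lambda q: (targets[q] - len(members[q]), -q))
        best = None
        for a_pos, a in enumerate(unassigned):
            for b in unassigned[a_pos + 1:]:
                d = D[a, b]
                if best is None or d > best[0] + 1e-15:
                    best = (d, a, b)
        _, a, b = best
        members[k].extend([a, b])
        unassigned.remove(a)
        unassigned.remove(b)

    # growth phase: the neediest set takes the point with max min-distance
    while unassigned:
        k = neediest()
        sub = np.array(members[k])
        dmin = D[np.ix_(unassigned, sub)].min(axis=1)
        pick = unassigned[int(np.argmax(dmin))]  # argmax ties -> lowest position/index
        members[k].append(pick)
        unassigned.remove(pick)

    idx = [np.array(sorted(members[k])) for k in range(n_sets)]
    while len(idx) < 3:
        idx.append(np.array([], dtype=int))
    return SplitResult(idx[0], idx[1], idx[2], tuple(float(r) for r in ratios))
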