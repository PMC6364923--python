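"""Wavelet-base selection rules over an AUC grid, including resolution invariance.

Given cross-validated AUC for every (wavelet id, resolution, kernel) cell,
five selection conditions are computed per kernel:

* Condition 1 — the n (default 6) bases with outstanding AUC at one
  resolution;
* Condition 2 — the single best base at one resolution;
* Conditions 3/4/5 — the resolution-invariant set: for each base i compute
  SUM(i) = sum of its AUC over the three resolutions, keep the n largest,
  then order the kept set by AUC at the priority resolution (3: full
  resolution A; 4: A2; 5: A4).  The selected *set* is by construction the
  same for the three priorities; only the ordering differs.

AUC values equal after rounding to 3 decimals form tie groups (reported
parenthesized); the final deterministic tie-break is ascending wavelet id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .preprocess import RESOLUTIONS

TIE_DECIMALS = 3


@dataclass(frozen=True)
class AUCGrid:
    """AUC per (wavelet_id, resolution, kernel) cell."""

    auc: dict[tuple[int, str, str], float]

    def value(self, wavelet_id: int, resolution: str, kernel: str) -> float:
        try:
            return self.auc[(wavelet_id, resolution, kernel)]
        except KeyError:
            raise ValueError(
                f"grid has no cell (wavelet {wavelet_id}, {resolution}, {kernel})"
            ) from None

    def wavelet_ids(self) -> list[int]:
        return sorted({k[0] for k in self.auc})

    def kernels(self) -> list[str]:
        return sorted({k[2] for k in self.auc})

    def require_complete(self, kernel: str, resolutions: tuple[str, ...]) -> None:
        missing = [
            (i, r)
            for i in self.wavelet_ids()
            for r in resolutions
            if (i, r, kernel) not in self.auc
        ]
        if missing:
            raise ValueError(f"grid incomplete for kernel {kernel!r}: missing {missing[:5]}...")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"wavelet_id": i, "resolution": r, "kernel": k, "auc": v}
            for (i, r, k), v in sorted(self.auc.items())
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AUCGrid":
        return cls(
            auc={
                (int(r.wavelet_id), str(r.resolution), str(r.kernel)): float(r.auc)
                for r in df.itertuples()
            }
        )


@dataclass(frozen=True)
class ConditionResult:
    """Outcome of one selection condition: ordered ids plus tie groups."""

    condition: int
    kernel: str
    resolution: str  # the scoring resolution, or the priority resolution for 3-5
    selected: tuple[int, ...]
    ties: tuple[tuple[int, ...], ...] = field(default=())

    def formatted(self) -> str:
        """Render as the conventional row text with parenthesized tie groups."""
        tie_of = {i: g for g in self.ties for i in g}
        out, seen = [], set()
        for i in self.selected:
            if i in seen:
                continue
            g = tie_of.get(i)
            if g and len(g) > 1:
                out.append("(" + " ".join(str(j) for j in g) + ")")
                seen.update(g)
            else:
                out.append(str(i))
                seen.add(i)
        return " ".join(out)


def _rounded(v: float) -> float:
    return round(v, TIE_DECIMALS)


def _select_top(scores: dict[int, float], n: int) -> tuple[tuple[int, ...], tuple[tuple[int, ...], ...]]:
    """Top-n ids by score, descending; ties (after rounding) kept whole.

    The returned list may exceed n only to complete the tie group straddling
    the cut; within a tie group ids ascend.
    """
    groups: dict[float, list[int]] = {}
    for i, v in scores.items():
        groups.setdefault(_rounded(v), []).append(i)
    ordered_groups = [
        tuple(sorted(ids)) for v, ids in sorted(groups.items(), key=lambda kv: -kv[0])
    ]
    selected: list[int] = []
    ties: list[tuple[int, ...]] = []
    for g in ordered_groups:
        if len(selected) >= n:
            break
        selected.extend(g)
        if len(g) > 1:
            ties.append(g)
    return tuple(selected), tuple(ties)


def condition_top_n(grid: AUCGrid, kernel: str, resolution: str, n: int = 6) -> ConditionResult:
    """Condition 1: the n bases with outstanding AUC at one resolution."""
    grid.require_complete(kernel, (resolution,))
    scores = {i: grid.value(i, resolution, kernel) for i in grid.wavelet_ids()}
    selected, ties = _select_top(scores, n)
    return ConditionResult(condition=1, kernel=kernel, resolution=resolution,
                           selected=selected, ties=ties)


def condition_best(grid: AUCGrid, kernel: str, resolution: str) -> ConditionResult:
    """Condition 2: the single highest-AUC base (tie group if exactly tied)."""
    res = condition_top_n(grid, kernel, resolution, n=1)
    return ConditionResult(condition=2, kernel=kernel, resolution=resolution,
                           selected=res.selected, ties=res.ties)


def resolution_invariant_rank(
    grid: AUCGrid,
    kernel: str,
    priority_resolution: str,
    n: int = 6,
    resolutions: tuple[str, ...] = RESOLUTIONS,
) -> ConditionResult:
    """Conditions 3-5: bases keeping high AUC across all resolutions.

    SUM(i) = sum of AUC_i over ``resolutions``; the n ids with largest SUM
    are selected, then ordered descending by AUC at ``priority_resolution``,
    ties broken by SUM, then by smaller id.
    """
    if priority_resolution not in resolutions:
        raise ValueError(f"priority resolution {priority_resolution!r} not in {resolutions}")
    grid.require_complete(kernel, tuple(resolutions))
    ids = grid.wavelet_ids()
    sums = {i: sum(grid.value(i, r, kernel) for r in resolutions) for i in ids}
    # top-n by SUM with deterministic tie-break (larger SUM, then smaller id)
    chosen = sorted(ids, key=lambda i: (-sums[i], i))[:n]
    prio = {i: grid.value(i, priority_resolution, kernel) for i in chosen}
    ordered = sorted(chosen, key=lambda i: (-prio[i], -sums[i], i))
    # tie groups by equal priority-resolution AUC after rounding
    groups: dict[float, list[int]] = {}
    for i in ordered:
        groups.setdefault(_rounded(prio[i]), []).append(i)
    ties = tuple(tuple(sorted(g)) for g in groups.values() if len(g) > 1)
    condition = 3 + list(resolutions).index(priority_resolution)
    return ConditionResult(condition=condition, kernel=kernel,
                           resolution=priority_resolution,
                           selected=tuple(ordered), ties=ties)


def condition_table(grid: AUCGrid, kernel: str, n: int = 6,
                    resolutions: tuple[str, ...] = RESOLUTIONS) -> pd.DataFrame:
    """The full per-kernel selection table, one row per resolution.

    Columns: Condition 1 (top-n at that resolution), Condition 2 (best), and
    the resolution-invariant ordering whose priority matches the row's
    resolution (Condition 3 for A, 4 for A2, 5 for A4).
    """
    rows = []
    for r in resolutions:
        c1 = condition_top_n(grid, kernel, r, n=n)
        c2 = condition_best(grid, kernel, r)
        cinv = resolution_invariant_rank(grid, kernel, r, n=n, resolutions=resolutions)
        rows.append(
            {
                "kernel": kernel,
                "resolution": r,
                "condition_1": c1.formatted(),
                "condition_2": c2.formatted(),
                f"condition_{cinv.condition}": cinv.formatted(),
            }
        )
    return pd.DataFrame(rows)
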