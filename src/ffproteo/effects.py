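"""Per-protein log2 fold changes with bootstrap confidence intervals.

Repeat rows are first collapsed to fluid-level medians of log2 intensities so
resampling operates on (approximately) independent fluids rather than
pseudoreplicated technical repeats.  The bootstrap statistic is the difference
of group medians; intervals are percentile intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import AbundanceDataset


@dataclass
class FluidLevelMatrix:
    """Fluid-by-protein medians of log2 intensities."""

    values: pd.DataFrame  # index: fluid_id, columns: protein_ids
    fluid_to_group: dict[str, str]
    fluid_to_patient: dict[str, str]

    def group_values(self, protein_id: str, group: str) -> np.ndarray:
        fluids = [f for f in self.values.index if self.fluid_to_group[f] == group]
        return self.values.loc[fluids, protein_id].to_numpy()


@dataclass
class EffectEstimate:
    protein_id: str
    log2_fc: float
    ci_low: float
    ci_high: float
    n_boot: int = 10_000
    significant: bool = False

    def __post_init__(self):
        self.significant = not (self.ci_low <= 0.0 <= self.ci_high)


def aggregate_repeats(dataset: AbundanceDataset) -> FluidLevelMatrix:
    """Median over each fluid's repeats of log2-transformed intensities."""
    if np.any(dataset.intensities <= 0):
        raise ValueError("intensities must be strictly positive")
    log2 = pd.DataFrame(np.log2(dataset.intensities),
                        columns=dataset.protein_ids)
    log2["__fluid"] = dataset.fluid_ids
    values = log2.groupby("__fluid", sort=True).median()
    values.index.name = "fluid_id"
    return FluidLevelMatrix(
        values=values,
        fluid_to_group={r.fluid_id: r.group for r in dataset.rows},
        fluid_to_patient={r.fluid_id: r.patient_id for r in dataset.rows},
    )


def group_median_diff(values_pcos: Sequence[float],
                      values_control: Sequence[float]) -> float:
    """median(pcos) - median(control), on whatever scale the inputs are on."""
    a = np.asarray(values_pcos, dtype=float)
    b = np.asarray(values_control, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    return float(np.median(a) - np.median(b))


def bootstrap_ci(values_pcos: Sequence[float], values_control: Sequence[float],
                 n_boot: int = 10_000, level: float = 0.95,
                 seed: int | np.random.SeedSequence | None = None,
                 protein_id: str = "") -> EffectEstimate:
    """Percentile bootstrap CI for the difference of group medians.

    The two groups are resampled independently with replacement; the flag is
    set when the interval excludes zero.
    """
    a = np.asarray(values_pcos, dtype=float)
    b = np.asarray(values_control, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, a.size, size=(n_boot, a.size))
    idx_b = rng.integers(0, b.size, size=(n_boot, b.size))
    stats = np.median(a[idx_a], axis=1) - np.median(b[idx_b], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return EffectEstimate(
        protein_id=protein_id,
        log2_fc=group_median_diff(a, b),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
    )


def estimate_all(dataset: AbundanceDataset,
                 proteins: Sequence[str] | None = None,
                 n_boot: int = 10_000, level: float = 0.95,
                 seed: int | None = None,
                 resample_unit: str = "fluid") -> list[EffectEstimate]:
    """One effect estimate per requested protein, sorted by |log2 FC| descending.

    Each protein draws its bootstrap seed from a per-protein slot of the master
    seed, so estimates do not depend on which subset is requested.
    ``resample_unit`` may be ``"fluid"`` (default, follows the independence
    construction) or ``"patient"`` (cluster bootstrap for sensitivity checks).
    """
    if resample_unit not in ("fluid", "patient"):
        raise ValueError("resample_unit must be 'fluid' or 'patient'")
    fl = aggregate_repeats(dataset)
    if proteins is None:
        proteins = list(dataset.protein_ids)
    unknown = set(proteins) - set(dataset.protein_ids)
    if unknown:
        raise KeyError(f"unknown protein id(s): {sorted(unknown)}")

    child = dict(zip(dataset.protein_ids,
                     np.random.SeedSequence(seed).spawn(len(dataset.protein_ids))))

    if resample_unit == "patient":
        return _estimate_patient_level(fl, proteins, n_boot, level, child)

    estimates = []
    for pid in proteins:
        est = bootstrap_ci(fl.group_values(pid, "pcos"),
                           fl.group_values(pid, "control"),
                           n_boot=n_boot, level=level, seed=child[pid],
                           protein_id=pid)
        estimates.append(est)
    estimates.sort(key=lambda e: (-abs(e.log2_fc), e.protein_id))
    return estimates


def _estimate_patient_level(fl: FluidLevelMatrix, proteins, n_boot, level,
                            child) -> list[EffectEstimate]:
    # cluster bootstrap: resample patients with replacement, keep all of each
    # drawn patient's fluids
    groups = {"pcos": {}, "control": {}}
    for fid in fl.values.index:
        pat = fl.fluid_to_patient[fid]
        groups[fl.fluid_to_group[fid]].setdefault(pat, []).append(fid)
    estimates = []
    alpha = (1.0 - level) / 2.0
    for pid in proteins:
        rng = np.random.default_rng(child[pid])
        col = fl.values[pid]
        stats = np.empty(n_boot)
        obs = {}
        for g in ("pcos", "control"):
            obs[g] = np.concatenate([col.loc[f].to_numpy(dtype=float).reshape(-1)
                                     if hasattr(col.loc[f], "to_numpy")
                                     else np.atleast_1d(col.loc[f])
                                     for f in (groups[g][p] for p in groups[g])])
        for b in range(n_boot):
            meds = {}
            for g in ("pcos", "control"):
                pats = list(groups[g])
                draw = rng.integers(0, len(pats), size=len(pats))
                vals = np.concatenate([
                    col.loc[groups[g][pats[i]]].to_numpy(dtype=float)
                    for i in draw])
                meds[g] = np.median(vals)
            stats[b] = meds["pcos"] - meds["control"]
        lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
        estimates.append(EffectEstimate(
            protein_id=pid,
            log2_fc=float(np.median(obs["pcos"]) - np.median(obs["control"])),
            ci_low=float(lo), ci_high=float(hi), n_boot=n_boot))
    estimates.sort(key=lambda e: (-abs(e.log2_fc), e.protein_id))
    return estimates
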