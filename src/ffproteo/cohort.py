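"""Synthetic follicular-fluid proteome cohorts with a nested repeated-measures design.

Intensities follow a three-level lognormal model: per-protein baseline plus
independent patient, fluid and repeat effects on the natural-log scale, a group
shift (log2 units, converted by ln 2) for designated effect proteins in the
PCOS group, and an optional correlated protein block driven by a shared latent
factor with loading sqrt(block_rho) (the anti-protein loads negatively).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError

LN2 = math.log(2.0)

GROUPS = ("pcos", "control")


@dataclass(frozen=True)
class SampleRecord:
    """One measurement repeat: which patient/group/fluid it belongs to."""

    patient_id: str
    group: str
    fluid_id: str
    repeat_index: int


@dataclass(frozen=True)
class CohortConfig:
    n_pcos_patients: int = 34
    n_control_patients: int = 40
    fluids_per_patient_range: tuple[int, int] = (2, 3)
    repeats_per_fluid: int = 3
    n_proteins: int = 484
    effects: tuple[tuple[int, float], ...] = ()
    block_proteins: tuple[int, ...] = ()
    anti_protein: int | None = None
    block_rho: float = 0.5
    patient_sd: float = 0.15
    fluid_sd: float = 0.10
    repeat_sd: float = 0.20
    #: optional per-protein technical-noise range; overrides ``repeat_sd`` when
    #: set, so that only a fraction of proteins reach low technical CV
    repeat_sd_range: tuple[float, float] | None = None
    baseline_log_mean_range: tuple[float, float] = (8.0, 14.0)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_pcos_patients", "n_control_patients",
                     "repeats_per_fluid", "n_proteins"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(name, "must be >= 1")
        lo, hi = self.fluids_per_patient_range
        if lo < 1 or hi < lo:
            raise ConfigError("fluids_per_patient_range",
                              "must be an inclusive interval with 1 <= lo <= hi")
        idx = [i for i, _ in self.effects]
        if len(set(idx)) != len(idx):
            raise ConfigError("effects", "protein indices must be distinct")
        if any(i < 0 or i >= self.n_proteins for i in idx):
            raise ConfigError("effects", "protein index out of range")
        if any(i < 0 or i >= self.n_proteins for i in self.block_proteins):
            raise ConfigError("block_proteins", "protein index out of range")
        if not 0.0 < self.block_rho < 1.0:
            raise ConfigError("block_rho", "must lie in (0, 1)")
        for name in ("patient_sd", "fluid_sd", "repeat_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(name, "must be >= 0")
        if self.repeat_sd_range is not None:
            rlo, rhi = self.repeat_sd_range
            if rlo < 0 or rhi < rlo:
                raise ConfigError("repeat_sd_range", "must satisfy 0 <= lo <= hi")
        if self.anti_protein is not None:
            if self.anti_protein in self.block_proteins:
                raise ConfigError("anti_protein", "must not be in block_proteins")
            if not 0 <= self.anti_protein < self.n_proteins:
                raise ConfigError("anti_protein", "protein index out of range")
        blo, bhi = self.baseline_log_mean_range
        if bhi < blo:
            raise ConfigError("baseline_log_mean_range", "must satisfy lo <= hi")


@dataclass
class AbundanceDataset:
    """Strictly positive intensity matrix plus per-row nested metadata."""

    intensities: np.ndarray  # (n_rows, n_proteins)
    rows: list[SampleRecord]
    protein_ids: list[str]

    def validate(self) -> None:
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-d matrix")
        if self.intensities.shape[0] != len(self.rows):
            raise ValueError("row count must equal number of sample records")
        if self.intensities.shape[1] != len(self.protein_ids):
            raise ValueError("column count must equal number of protein ids")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValueError("protein_ids must be unique")
        if not np.all(np.isfinite(self.intensities)) or np.any(self.intensities <= 0):
            raise ValueError("intensities must be finite and strictly positive")
        fluid_patient: dict[str, str] = {}
        patient_group: dict[str, str] = {}
        seen: set[tuple[str, int]] = set()
        for r in self.rows:
            if r.group not in GROUPS:
                raise ValueError(f"unknown group label {r.group!r}")
            if r.repeat_index < 1:
                raise ValueError("repeat_index must be >= 1")
            if fluid_patient.setdefault(r.fluid_id, r.patient_id) != r.patient_id:
                raise ValueError(f"fluid {r.fluid_id!r} mapped to multiple patients")
            if patient_group.setdefault(r.patient_id, r.group) != r.group:
                raise ValueError(f"patient {r.patient_id!r} mapped to multiple groups")
            key = (r.fluid_id, r.repeat_index)
            if key in seen:
                raise ValueError(f"duplicate (fluid_id, repeat_index) {key!r}")
            seen.add(key)

    # -- convenience accessors -------------------------------------------------

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.group for r in self.rows])

    @property
    def patient_ids(self) -> np.ndarray:
        return np.array([r.patient_id for r in self.rows])

    @property
    def fluid_ids(self) -> np.ndarray:
        return np.array([r.fluid_id for r in self.rows])

    @property
    def n_patients(self) -> int:
        return len({r.patient_id for r in self.rows})

    @property
    def n_fluids(self) -> int:
        return len({r.fluid_id for r in self.rows})

    def equals(self, other: "AbundanceDataset") -> bool:
        return (self.protein_ids == other.protein_ids
                and self.rows == other.rows
                and np.array_equal(self.intensities, other.intensities))


# MYL6-like entry first; magnitudes and the single down-regulated protein follow
# the study design this simulator emulates.  Indices spread the effects across
# the default 484-protein panel.
_EFFECT_TABLE: tuple[tuple[str, float], ...] = (
    ("MYL6", -0.61),
    ("AFM", 0.21),
    ("SERPINA1", 0.23),
    ("A2M", 0.26),
    ("AGT", 0.41),
    ("CFB", 0.36),
    ("CP", 0.35),
    ("APOA1", 0.18),
    ("ITIH1", 0.19),
    ("SERPING1", 0.07),
    ("KNG1", 0.24),
    ("GC", 0.28),
    ("C9", 0.18),
    ("A1BG", 0.18),
    ("SERPINA6", 0.29),
    ("SERPINC1", 0.07),
    ("SERPINF1", 0.29),
    ("SELENBP1", 0.33),
    ("ITIH2", 0.23),
    ("PDIA6", 0.34),
)

DEFAULT_EFFECT_INDICES: tuple[int, ...] = tuple(range(10, 10 + 24 * 20, 24))

MYL6_INDEX: int = DEFAULT_EFFECT_INDICES[0]


def table2_default_effects() -> list[tuple[int, float]]:
    """The 20 default differential effects: one down-regulated, rest up.

    Returns ``(protein index, true log2 fold change)`` pairs on the default
    484-protein panel; the MYL6-like protein at :data:`MYL6_INDEX` carries the
    single negative effect (-0.61).
    """
    return [(i, fc) for i, (_, fc) in zip(DEFAULT_EFFECT_INDICES, _EFFECT_TABLE)]


def effect_gene_names() -> list[tuple[int, str]]:
    """Gene-style labels for the default effect proteins (for readable reports)."""
    return [(i, name) for i, (name, _) in zip(DEFAULT_EFFECT_INDICES, _EFFECT_TABLE)]


def study_default_config(seed: int = 0) -> CohortConfig:
    """Cohort configuration emulating the study geometry.

    34 + 40 patients, 2-3 fluids each, 3 repeats per fluid, 484 proteins with
    the default effect table injected; the 19 up-regulated effect proteins form
    a positively correlated block and the MYL6-like protein anti-correlates
    with it.  Technical noise varies per protein so only a minority of proteins
    reach CV < 20%.
    """
    effects = table2_default_effects()
    block = tuple(i for i, fc in effects if fc > 0)
    return CohortConfig(
        effects=tuple(effects),
        block_proteins=block,
        anti_protein=MYL6_INDEX,
        block_rho=0.5,
        repeat_sd_range=(0.10, 0.60),
        seed=seed,
    )


def simulate_cohort(config: CohortConfig) -> AbundanceDataset:
    """Draw a synthetic cohort; identical config (incl. seed) => identical data."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    p = config.n_proteins

    patients: list[tuple[str, str]] = []
    patients += [(f"P{i + 1:03d}", "pcos") for i in range(config.n_pcos_patients)]
    patients += [(f"C{i + 1:03d}", "control") for i in range(config.n_control_patients)]

    lo, hi = config.fluids_per_patient_range
    n_fluids_per_patient = rng.integers(lo, hi + 1, size=len(patients))

    rows: list[SampleRecord] = []
    fluid_counter = 0
    row_patient_idx: list[int] = []
    row_fluid_idx: list[int] = []
    for pi, (pid, grp) in enumerate(patients):
        for _ in range(int(n_fluids_per_patient[pi])):
            fid = f"F{fluid_counter + 1:04d}"
            for rep in range(1, config.repeats_per_fluid + 1):
                rows.append(SampleRecord(pid, grp, fid, rep))
                row_patient_idx.append(pi)
                row_fluid_idx.append(fluid_counter)
            fluid_counter += 1
    n_rows = len(rows)

    baseline = rng.uniform(*config.baseline_log_mean_range, size=p)
    if config.repeat_sd_range is not None:
        repeat_sds = rng.uniform(*config.repeat_sd_range, size=p)
    else:
        repeat_sds = np.full(p, config.repeat_sd)

    # latent-factor loadings: sqrt(rho) shared + sqrt(1-rho) own for block
    # members, negative shared loading for the anti-protein
    shared_load = np.zeros(p)
    own_load = np.ones(p)
    corr_members = list(config.block_proteins)
    if config.anti_protein is not None:
        corr_members.append(config.anti_protein)
    if corr_members:
        sq = math.sqrt(config.block_rho)
        for j in config.block_proteins:
            shared_load[j] = sq
        if config.anti_protein is not None:
            shared_load[config.anti_protein] = -sq
        own_load[corr_members] = math.sqrt(1.0 - config.block_rho)

    def level_effect(n_units: int, sd: float | np.ndarray) -> np.ndarray:
        shared = rng.standard_normal((n_units, 1))
        own = rng.standard_normal((n_units, p))
        return (shared * shared_load + own * own_load) * sd

    patient_eff = level_effect(len(patients), config.patient_sd)
    fluid_eff = level_effect(fluid_counter, config.fluid_sd)
    repeat_eff = level_effect(n_rows, repeat_sds)

    log_intensity = (baseline
                     + patient_eff[row_patient_idx]
                     + fluid_eff[row_fluid_idx]
                     + repeat_eff)

    if config.effects:
        is_pcos = np.array([r.group == "pcos" for r in rows])
        for j, log2fc in config.effects:
            log_intensity[is_pcos, j] += LN2 * log2fc

    dataset = AbundanceDataset(
        intensities=np.exp(log_intensity),
        rows=rows,
        protein_ids=[f"PROT{j + 1:04d}" for j in range(p)],
    )
    dataset.validate()
    return dataset


def with_seed(config: CohortConfig, seed: int) -> CohortConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
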