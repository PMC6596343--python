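"""Synthetic SIP gradients and microcosm process series.

Two generators provide downstream-testable data with the statistical
structure the CAP-SIP analysis assumes:

* :func:`simulate_gradient_libraries` builds OTU abundance tables for the
  pooled heavy/light libraries of ¹³C and ¹²C gradients over a time course.
  Each OTU's RNA mass is spread over a 10-point buoyant-density grid as a
  Gaussian whose center shifts linearly with the OTU's ¹³C atom fraction;
  per-fraction libraries are multinomial read samples from the fraction's
  mass composition; fractions are pooled into heavy/light classes; and an
  additive truncated-at-zero Gaussian library noise (the baseline-noise
  dial) perturbs the percent abundances before renormalization.

* :func:`simulate_process_series` integrates first-order chitin
  mineralization and routes the degraded residues to electron-balanced
  product pathways (CO₂ via O₂ or Fe(III) respiration, acetate /
  propionate / butyrate / H₂-CO₂ fermentations, methanogenesis), with
  anoxic phase gating: iron respiration until the ferric pool is spent,
  fermentation only after the initial phase, methanogenesis only in the
  final phase. With zero measurement noise, carbon and electrons are
  conserved exactly.

Randomness is routed through one global seed with documented substreams:
fraction-level read sampling is keyed by (day, fraction) and *shared
between the isotope treatments*, so treatments differ only through the
labeling signal and the per-library noise — with no labeling signal and no
noise, the ¹³C and ¹²C tables are identical under the same seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mass_balance import ChitinStoichiometry, PRODUCT_ELECTRONS, ProductInventory
from .sip_tables import AbundanceTable, LibraryKey, classify_fraction

__all__ = [
    "NATURAL_ABUNDANCE_13C",
    "GradientSimConfig",
    "ProcessSimConfig",
    "ProcessSeries",
    "PATHWAY_STOICHIOMETRY",
    "community_profile",
    "simulate_gradient_libraries",
    "expected_library_percents",
    "expected_heavy_excess",
    "simulate_process_series",
    "oxic_process_config",
    "anoxic_process_config",
]

#: Natural ¹³C atom fraction (the [¹²C]-substrate carries 1.1 atom % ¹³C).
NATURAL_ABUNDANCE_13C = 0.011

_DEFAULT_GRID = tuple(np.round(np.linspace(1.75, 1.84, 10), 6))


def community_profile(n_otus: int, seed: int = 0, sigma: float = 1.2) -> np.ndarray:
    """A lognormal rank-abundance community profile in percent (sums to 100).

    ``sigma`` controls evenness; 1.2 gives a few dominant OTUs over a long
    tail of rare ones, a typical soil amplicon-library shape.
    """
    if n_otus < 2:
        raise ValueError("need at least 2 OTUs")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0]))
    raw = rng.lognormal(mean=0.0, sigma=sigma, size=n_otus)
    p = 100.0 * raw / raw.sum()
    # exact renormalization to survive the strict config invariant
    return p * (100.0 / p.sum())


@dataclass
class GradientSimConfig:
    """Scenario for one oxygen treatment's SIP gradient time course.

    ``labeled_otus`` maps 1-based OTU ids to an atom-fraction trajectory
    (day → ¹³C atom fraction in [0, 1]); days absent from a trajectory fall
    back to natural abundance. The labeling signal applies to the ¹³C
    treatment only. ``noise_sd_percent`` is the SD of the additive
    truncated-at-zero Gaussian noise applied to each pooled library's
    percent abundances (the empirical baseline-noise dial).
    """

    n_otus: int = 200
    labeled_otus: Mapping[int, Mapping[float, float]] = field(default_factory=dict)
    baseline_abundances: np.ndarray | None = None
    noise_sd_percent: float = 0.19
    density_grid: Sequence[float] = _DEFAULT_GRID
    unlabeled_bd_mean: float = 1.775
    max_bd_shift: float = 0.04
    bd_spread_sd: float = 0.008
    reads_per_library: int = 10_000
    time_points: Sequence[float] = (0.0, 3.0, 10.0, 21.0, 70.0)
    oxygen: str = "oxic"
    slurry_sd_percent: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_otus < 2:
            raise ValueError("n_otus must be >= 2")
        if self.reads_per_library <= 0:
            raise ValueError("reads_per_library must be positive")
        if self.noise_sd_percent < 0 or self.slurry_sd_percent < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.bd_spread_sd <= 0:
            raise ValueError("bd_spread_sd must be positive")
        if self.max_bd_shift < 0:
            raise ValueError("max_bd_shift must be non-negative")
        grid = np.asarray(self.density_grid, dtype=float)
        if grid.size != 10:
            raise ValueError(f"density_grid must have exactly 10 densities, got {grid.size}")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("density_grid must be strictly increasing")
        self.density_grid = grid
        if self.baseline_abundances is None:
            self.baseline_abundances = community_profile(self.n_otus, self.seed)
        base = np.asarray(self.baseline_abundances, dtype=float)
        if base.shape != (self.n_otus,):
            raise ValueError(
                f"baseline_abundances must have shape ({self.n_otus},), got {base.shape}"
            )
        if np.any(base < 0):
            raise ValueError("baseline abundances must be non-negative")
        if abs(base.sum() - 100.0) > 1e-9:
            raise ValueError(f"baseline abundances sum to {base.sum()!r}, expected 100")
        self.baseline_abundances = base
        days = [float(d) for d in self.time_points]
        if len(days) != len(set(days)) or any(d < 0 for d in days):
            raise ValueError("time_points must be distinct non-negative days")
        self.time_points = tuple(days)
        for otu_id, traj in dict(self.labeled_otus).items():
            if not 1 <= int(otu_id) <= self.n_otus:
                raise ValueError(f"labeled OTU id {otu_id} not in 1..{self.n_otus}")
            for day, af in dict(traj).items():
                if not 0.0 <= float(af) <= 1.0:
                    raise ValueError(
                        f"atom fraction {af!r} for OTU {otu_id} day {day} outside [0, 1]"
                    )

    def otu_ids(self) -> list[str]:
        width = len(str(self.n_otus))
        return [f"OTU_{i:0{width}d}" for i in range(1, self.n_otus + 1)]

    def atom_fractions(self, isotope: str, day: float) -> np.ndarray:
        """Per-OTU ¹³C atom fraction at ``day`` for one isotope treatment."""
        af = np.full(self.n_otus, NATURAL_ABUNDANCE_13C)
        if isotope == "13C":
            for otu_id, traj in dict(self.labeled_otus).items():
                value = dict(traj).get(float(day))
                if value is not None:
                    af[int(otu_id) - 1] = float(value)
        return af


def _rng(seed: int, *key: int) -> np.random.Generator:
    # documented substream derivation: one SeedSequence per (seed, purpose, key...)
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _density_weights(config: GradientSimConfig, atom_fractions: np.ndarray) -> np.ndarray:
    """(n_otus, 10) matrix: share of each OTU's RNA mass per fraction.

    Gaussian in buoyant density centered at
    ``unlabeled_bd_mean + atom_fraction * max_bd_shift``, discretized on the
    grid and normalized per OTU.
    """
    centers = config.unlabeled_bd_mean + atom_fractions * config.max_bd_shift
    z = (config.density_grid[None, :] - centers[:, None]) / config.bd_spread_sd
    w = np.exp(-0.5 * z**2)
    return w / w.sum(axis=1, keepdims=True)


def _pooled_community(config: GradientSimConfig, isotope: str, day_idx: int) -> np.ndarray:
    """Equimolar pool of two duplicate-slurry community draws (percent)."""
    base = config.baseline_abundances
    if config.slurry_sd_percent == 0:
        return base
    iso_idx = 0 if isotope == "13C" else 1
    draws = []
    for rep in (0, 1):
        rng = _rng(config.seed, 3, iso_idx, day_idx, rep)
        draw = np.clip(base + rng.normal(0.0, config.slurry_sd_percent, base.size), 0.0, None)
        draws.append(100.0 * draw / draw.sum())
    pooled = np.mean(draws, axis=0)
    return 100.0 * pooled / pooled.sum()


def _class_mass_percent(
    config: GradientSimConfig, isotope: str, day: float, day_idx: int
) -> dict[str, np.ndarray]:
    """Noise-free per-class composition (percent) from the mass model."""
    pooled = _pooled_community(config, isotope, day_idx)
    weights = _density_weights(config, config.atom_fractions(isotope, day))
    mass = pooled[:, None] * weights  # (otu, fraction)
    out: dict[str, np.ndarray] = {}
    for cls in ("heavy", "light"):
        idx = [
            f for f, bd in enumerate(config.density_grid) if classify_fraction(bd) == cls
        ]
        if not idx:
            raise ValueError(f"density grid covers no {cls} fractions")
        total = mass[:, idx].sum(axis=1)
        out[cls] = 100.0 * total / total.sum()
    return out


def expected_library_percents(config: GradientSimConfig) -> AbundanceTable:
    """Infinite-read, noise-free expectation of the simulated tables.

    Ground truth for sensitivity analyses: the deterministic per-class
    compositions of the mass model without multinomial sampling or library
    noise.
    """
    cols: dict[LibraryKey, np.ndarray] = {}
    for day_idx, day in enumerate(config.time_points):
        for isotope in ("13C", "12C"):
            by_class = _class_mass_percent(config, isotope, day, day_idx)
            for cls, pct in by_class.items():
                cols[LibraryKey(isotope, config.oxygen, day, cls)] = pct
    df = pd.DataFrame(cols, index=pd.Index(config.otu_ids(), name="otu_id"))
    return AbundanceTable(df, "percent")


def expected_heavy_excess(config: GradientSimConfig, day: float) -> pd.Series:
    """Per-OTU expected heavy-fraction excess (¹³C minus ¹²C, percent) at ``day``."""
    day_idx = list(config.time_points).index(float(day))
    h13 = _class_mass_percent(config, "13C", day, day_idx)["heavy"]
    h12 = _class_mass_percent(config, "12C", day, day_idx)["heavy"]
    return pd.Series(h13 - h12, index=pd.Index(config.otu_ids(), name="otu_id"))


def simulate_gradient_libraries(config: GradientSimConfig) -> AbundanceTable:
    """Simulate pooled heavy/light libraries for both isotope treatments.

    Returns one percent-unit :class:`AbundanceTable` holding the heavy and
    light libraries of the ¹³C and ¹²C treatments at every configured time
    point. Identical config and seed give identical output.
    """
    grid_class = [classify_fraction(bd) for bd in config.density_grid]
    cols: dict[LibraryKey, np.ndarray] = {}
    for day_idx, day in enumerate(config.time_points):
        for iso_idx, isotope in enumerate(("13C", "12C")):
            pooled = _pooled_community(config, isotope, day_idx)
            weights = _density_weights(config, config.atom_fractions(isotope, day))
            mass = pooled[:, None] * weights
            class_counts = {
                "heavy": np.zeros(config.n_otus),
                "light": np.zeros(config.n_otus),
            }
            for f, cls in enumerate(grid_class):
                if cls == "excluded":
                    continue
                probs = mass[:, f] / mass[:, f].sum()
                # substream shared across isotopes: identical compositions
                # (no labeling signal) give identical read draws
                rng = _rng(config.seed, 1, day_idx, f)
                class_counts[cls] += rng.multinomial(config.reads_per_library, probs)
            for cls_idx, cls in enumerate(("heavy", "light")):
                counts = class_counts[cls]
                pct = 100.0 * counts / counts.sum()
                if config.noise_sd_percent > 0:
                    rng = _rng(config.seed, 2, iso_idx, cls_idx, day_idx)
                    pct = np.clip(
                        pct + rng.normal(0.0, config.noise_sd_percent, pct.size), 0.0, None
                    )
                    pct = 100.0 * pct / pct.sum()
                # tidy float dust so percent columns satisfy the 1e-6 invariant
                pct = pct * (100.0 / pct.sum())
                cols[LibraryKey(isotope, config.oxygen, day, cls)] = pct
    df = pd.DataFrame(cols, index=pd.Index(config.otu_ids(), name="otu_id"))
    return AbundanceTable(df, "percent")


# ---------------------------------------------------------------------------
# microcosm process simulation
# ---------------------------------------------------------------------------

#: Electron-balanced desk-scale pathways, per mmol of GlcNAc residue
#: (8 C, 32 e⁻) catabolized. "respiration" sends electrons to O₂ (untracked);
#: "iron_respiration" to Fe(III), yielding 32 Fe(II).
PATHWAY_STOICHIOMETRY: dict[str, dict[str, float]] = {
    "respiration": {"co2": 8},
    "iron_respiration": {"co2": 8, "fe2": 32},
    "acetate": {"acetate": 4},
    "propionate": {"propionate": 2, "co2": 2, "h2": 2},
    "butyrate": {"butyrate": 1, "co2": 4, "h2": 6},
    "isobutyrate": {"isobutyrate": 1, "co2": 4, "h2": 6},
    "h2_co2": {"co2": 8, "h2": 16},
    "methanogenesis": {"ch4": 4, "co2": 4},
}

_PRODUCT_COLUMNS = ("co2", "acetate", "propionate", "butyrate", "isobutyrate", "h2", "ch4", "fe2")


@dataclass
class ProcessSimConfig:
    """Scenario for one microcosm's chemistry time series.

    ``product_split`` allocates degraded residues to the pathways above;
    together with ``assimilated_fraction`` (carbon diverted to biomass,
    never recovered as products) the fractions sum to 1. Under the anoxic
    regime, pathways are phase-gated at ``anoxic_phase_boundaries`` (days):
    iron respiration runs until the second boundary, fermentations start at
    the first, methanogenesis at the second; inactive shares are
    redistributed proportionally among the active sinks.
    """

    chitin_carbon_mmol: float = 5.0
    first_order_rate_per_day: float = 0.0124
    oxygen_regime: str = "anoxic"
    anoxic_phase_boundaries: tuple[float, float] = (14.0, 42.0)
    product_split: Mapping[str, float] = field(
        default_factory=lambda: {
            "iron_respiration": 0.25,
            "acetate": 0.30,
            "propionate": 0.20,
            "h2_co2": 0.10,
            "butyrate": 0.03,
            "isobutyrate": 0.02,
            "methanogenesis": 0.05,
        }
    )
    assimilated_fraction: float = 0.05
    measurement_noise_rel: float = 0.0
    days: Sequence[float] = (0.0, 3.0, 7.0, 10.0, 14.0, 21.0, 28.0, 42.0, 56.0, 70.0)
    stoichiometry: ChitinStoichiometry = field(default_factory=ChitinStoichiometry)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.first_order_rate_per_day < 0:
            raise ValueError("first_order_rate_per_day must be non-negative")
        if self.chitin_carbon_mmol <= 0:
            raise ValueError("chitin_carbon_mmol must be positive")
        if self.oxygen_regime not in ("oxic", "anoxic"):
            raise ValueError(f"oxygen_regime must be oxic or anoxic, got {self.oxygen_regime!r}")
        if self.measurement_noise_rel < 0:
            raise ValueError("measurement_noise_rel must be non-negative")
        b1, b2 = self.anoxic_phase_boundaries
        if not 0 < b1 < b2:
            raise ValueError("anoxic_phase_boundaries must be increasing and positive")
        split = {k: float(v) for k, v in dict(self.product_split).items()}
        unknown = sorted(set(split) - set(PATHWAY_STOICHIOMETRY))
        if unknown:
            raise ValueError(f"unknown pathway(s) {unknown}; known: {sorted(PATHWAY_STOICHIOMETRY)}")
        if any(v < 0 for v in split.values()) or self.assimilated_fraction < 0:
            raise ValueError("split fractions must be non-negative")
        total = sum(split.values()) + self.assimilated_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"product_split plus assimilated_fraction must sum to 1, got {total!r}"
            )
        self.product_split = split
        days = sorted(float(d) for d in self.days)
        if days and days[0] < 0:
            raise ValueError("days must be non-negative")
        self.days = tuple(days)

    def _active(self, pathway: str, t: float) -> bool:
        if self.oxygen_regime == "oxic":
            return True
        b1, b2 = self.anoxic_phase_boundaries
        if pathway == "iron_respiration":
            return t < b2
        if pathway == "methanogenesis":
            return t >= b2
        if pathway == "respiration":
            return True
        return t >= b1  # fermentations


@dataclass
class ProcessSeries:
    """Cumulative process chemistry over time (all amounts mmol, chitin-derived).

    ``data`` is indexed by day with product columns plus bookkeeping columns
    ``degraded_carbon_mmol``, ``degraded_residues_mmol`` and
    ``assimilated_carbon_mmol``. Since the substrate is uniformly
    ¹³C-labeled, the ``co2`` column is the ¹³CO₂ curve.
    """

    data: pd.DataFrame
    config: ProcessSimConfig

    def inventory_at(self, day: float) -> ProductInventory:
        if float(day) not in self.data.index:
            raise KeyError(f"day {day:g} not in series (have {list(self.data.index)})")
        row = self.data.loc[float(day)]
        return ProductInventory(day=float(day), **{c: float(row[c]) for c in _PRODUCT_COLUMNS})

    def degraded_carbon_mmol(self, day: float) -> float:
        return float(self.data.loc[float(day), "degraded_carbon_mmol"])

    def degraded_residues_mmol(self, day: float) -> float:
        return float(self.data.loc[float(day), "degraded_residues_mmol"])

    def write_tsv(self, path: str | Path) -> None:
        """Long-format TSV: day, compound, amount, unit."""
        rows = []
        for day, row in self.data.iterrows():
            for compound in self.data.columns:
                rows.append((f"{day:g}", compound, f"{row[compound]:.12g}", "mmol"))
        with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("day\tcompound\tamount\tunit\n")
            for r in rows:
                fh.write("\t".join(r) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path, config: ProcessSimConfig | None = None) -> "ProcessSeries":
        df = pd.read_csv(path, sep="\t")
        expected = {"day", "compound", "amount", "unit"}
        if set(df.columns) != expected:
            raise ValueError(f"{path}: expected columns {sorted(expected)}, got {list(df.columns)}")
        wide = df.pivot(index="day", columns="compound", values="amount").sort_index()
        wide.index = wide.index.astype(float)
        wide.columns.name = None
        return cls(data=wide, config=config or ProcessSimConfig())


def oxic_process_config(**overrides) -> ProcessSimConfig:
    """Oxic defaults: complete respiration to CO₂, ~54% mineralized by day 21."""
    params = dict(
        oxygen_regime="oxic",
        first_order_rate_per_day=0.037,
        product_split={"respiration": 1.0},
        assimilated_fraction=0.0,
    )
    params.update(overrides)
    return ProcessSimConfig(**params)


def anoxic_process_config(**overrides) -> ProcessSimConfig:
    """Anoxic defaults: slow mineralization, iron respiration then fermentation."""
    return ProcessSimConfig(**overrides)


def simulate_process_series(config: ProcessSimConfig) -> ProcessSeries:
    """Integrate first-order chitin degradation into cumulative product curves.

    Residues degraded in each interval (intervals are cut at the phase
    boundaries) are allocated to the active pathways in proportion to
    ``product_split`` and converted by :data:`PATHWAY_STOICHIOMETRY`.
    Measurement noise, if any, is multiplicative truncated Gaussian on the
    product columns only; the bookkeeping columns stay exact.
    """
    stoich = config.stoichiometry
    total_residues = config.chitin_carbon_mmol / stoich.carbons_per_residue
    k = config.first_order_rate_per_day

    def residues_degraded(t: float) -> float:
        return total_residues * (1.0 - math.exp(-k * t))

    out_days = list(config.days)
    horizon = out_days[-1] if out_days else 0.0
    cut = sorted(
        set(out_days)
        | {b for b in config.anoxic_phase_boundaries if 0.0 < b < horizon}
        | {0.0}
    )
    pathway_res = {p: 0.0 for p in config.product_split}
    assimilated_res = 0.0
    records: dict[float, dict[str, float]] = {}

    def snapshot(day: float) -> None:
        rec = {c: 0.0 for c in _PRODUCT_COLUMNS}
        for p, res in pathway_res.items():
            for compound, coeff in PATHWAY_STOICHIOMETRY[p].items():
                rec[compound] += res * coeff
        rec["degraded_residues_mmol"] = residues_degraded(day)
        rec["degraded_carbon_mmol"] = rec["degraded_residues_mmol"] * stoich.carbons_per_residue
        rec["assimilated_carbon_mmol"] = assimilated_res * stoich.carbons_per_residue
        records[day] = rec

    if out_days and out_days[0] == 0.0:
        snapshot(0.0)
    for t_prev, t_next in zip(cut[:-1], cut[1:]):
        delta = residues_degraded(t_next) - residues_degraded(t_prev)
        mid = 0.5 * (t_prev + t_next)
        active = {p: w for p, w in config.product_split.items() if config._active(p, mid)}
        weight_sum = sum(active.values()) + config.assimilated_fraction
        if weight_sum > 0 and delta > 0:
            for p, w in active.items():
                pathway_res[p] += delta * w / weight_sum
            assimilated_res += delta * config.assimilated_fraction / weight_sum
        if t_next in out_days:
            snapshot(t_next)

    df = pd.DataFrame.from_dict(records, orient="index").sort_index()
    df.index.name = "day"
    if config.measurement_noise_rel > 0:
        rng = _rng(config.seed, 4)
        for col in _PRODUCT_COLUMNS:
            factors = np.clip(
                1.0 + rng.normal(0.0, config.measurement_noise_rel, len(df)), 0.0, None
            )
            df[col] = df[col].to_numpy() * factors
    return ProcessSeries(data=df, config=config)
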