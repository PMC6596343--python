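"""Data model and I/O for RNA-SIP fraction metadata and OTU abundance tables.

An isopycnic gradient is cut into fractions whose buoyant density (BD,
g ml⁻¹ at 25 °C) decides whether their RNA counts as "heavy" (potentially
¹³C-labeled) or "light" (unlabeled). Amplicon libraries sequenced from the
pooled heavy and pooled light RNA of one gradient are the unit of
observation; each library is identified by a :class:`LibraryKey`
(isotope treatment, oxygen regime, incubation day, fraction class).

The canonical in-memory container is :class:`AbundanceTable`, a thin wrapper
around a pandas DataFrame (rows = OTUs, columns = libraries) carrying a
units tag (``counts`` or ``percent``). Percent (0–100) is the canonical unit
downstream; all detection thresholds are expressed on that scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HEAVY_WINDOW",
    "LIGHT_WINDOW",
    "PLAUSIBLE_BD_RANGE",
    "FractionRecord",
    "LibraryKey",
    "AbundanceTable",
    "classify_fraction",
    "to_relative",
    "pool_fractions_by_class",
    "read_abundance_tsv",
    "write_abundance_tsv",
    "read_fraction_tsv",
    "write_fraction_tsv",
]

#: Default buoyant-density window (g ml⁻¹) for "heavy", potentially
#: ¹³C-labeled RNA. Closed interval.
HEAVY_WINDOW: tuple[float, float] = (1.81, 1.83)

#: Default buoyant-density window (g ml⁻¹) for "light", unlabeled RNA.
LIGHT_WINDOW: tuple[float, float] = (1.76, 1.77)

#: Densities outside this open interval are physically implausible for RNA
#: in a CsTFA/formamide gradient and are rejected outright.
PLAUSIBLE_BD_RANGE: tuple[float, float] = (1.70, 1.90)

ISOTOPES = ("13C", "12C", "control")
OXYGEN_REGIMES = ("oxic", "anoxic")
FRACTION_CLASSES = ("heavy", "light")


def classify_fraction(
    buoyant_density: float,
    *,
    heavy_window: tuple[float, float] = HEAVY_WINDOW,
    light_window: tuple[float, float] = LIGHT_WINDOW,
) -> str:
    """Classify a gradient fraction by buoyant density.

    Returns ``"heavy"`` if the density falls inside ``heavy_window``
    (closed interval), ``"light"`` if inside ``light_window``, otherwise
    ``"excluded"``. Window bounds are configurable; the defaults are the
    conventional 1.81–1.83 and 1.76–1.77 g ml⁻¹ windows.

    Raises
    ------
    ValueError
        If the density is outside the plausible range (1.70, 1.90) g ml⁻¹
        or the configured windows overlap.
    """
    lo, hi = PLAUSIBLE_BD_RANGE
    if not (lo < buoyant_density < hi):
        raise ValueError(
            f"buoyant density {buoyant_density!r} g/ml is outside the "
            f"plausible range ({lo}, {hi})"
        )
    _check_windows(heavy_window, light_window)
    if heavy_window[0] <= buoyant_density <= heavy_window[1]:
        return "heavy"
    if light_window[0] <= buoyant_density <= light_window[1]:
        return "light"
    return "excluded"


def _check_windows(heavy: tuple[float, float], light: tuple[float, float]) -> None:
    for name, (a, b) in (("heavy", heavy), ("light", light)):
        if not a < b:
            raise ValueError(f"{name} window bounds must be increasing, got {(a, b)}")
    if not (light[1] < heavy[0] or heavy[1] < light[0]):
        raise ValueError(f"heavy {heavy} and light {light} windows overlap")


@dataclass(frozen=True)
class FractionRecord:
    """One gradient fraction: identity, buoyant density, optional RNA yield."""

    gradient_id: str
    fraction_index: int
    buoyant_density: float
    rna_ng: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= int(self.fraction_index) <= 10:
            raise ValueError(
                f"fraction_index must be in 1..10, got {self.fraction_index}"
            )
        lo, hi = PLAUSIBLE_BD_RANGE
        if not lo < self.buoyant_density < hi:
            raise ValueError(
                f"buoyant density {self.buoyant_density!r} outside plausible "
                f"range ({lo}, {hi})"
            )
        if self.rna_ng is not None and self.rna_ng < 0:
            raise ValueError("rna_ng must be non-negative")

    @property
    def fraction_class(self) -> str:
        return classify_fraction(self.buoyant_density)


@dataclass(frozen=True, order=True)
class LibraryKey:
    """Identity of one amplicon library.

    ``isotope`` is the substrate treatment (``13C``, ``12C`` or
    ``control``), ``oxygen`` the incubation regime, ``day`` the sampling
    time point (days since substrate addition) and ``fraction_class`` the
    pooled gradient window the RNA came from.

    The TSV header token form is ``isotope|oxygen|day|fraction_class``,
    e.g. ``13C|oxic|3|heavy``.
    """

    isotope: str
    oxygen: str
    day: float
    fraction_class: str

    def __post_init__(self) -> None:
        if self.isotope not in ISOTOPES:
            raise ValueError(f"isotope must be one of {ISOTOPES}, got {self.isotope!r}")
        if self.oxygen not in OXYGEN_REGIMES:
            raise ValueError(
                f"oxygen must be one of {OXYGEN_REGIMES}, got {self.oxygen!r}"
            )
        if self.fraction_class not in FRACTION_CLASSES:
            raise ValueError(
                f"fraction_class must be one of {FRACTION_CLASSES}, "
                f"got {self.fraction_class!r}"
            )
        day = float(self.day)
        if not math.isfinite(day) or day < 0:
            raise ValueError(f"day must be a finite non-negative number, got {self.day!r}")
        object.__setattr__(self, "day", day)

    def token(self) -> str:
        return f"{self.isotope}|{self.oxygen}|{self.day:g}|{self.fraction_class}"

    @classmethod
    def from_token(cls, token: str) -> "LibraryKey":
        parts = token.strip().split("|")
        if len(parts) != 4:
            raise ValueError(
                f"malformed library key {token!r}: expected 4 '|'-separated "
                "tokens isotope|oxygen|day|fraction_class"
            )
        isotope, oxygen, day_s, fraction_class = parts
        try:
            day = float(day_s)
        except ValueError as exc:
            raise ValueError(f"malformed day {day_s!r} in library key {token!r}") from exc
        return cls(isotope=isotope, oxygen=oxygen, day=day, fraction_class=fraction_class)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.token()


class AbundanceTable:
    """OTU × library matrix of read counts or relative abundances.

    Parameters
    ----------
    values
        DataFrame with OTU ids as index (unique strings) and
        :class:`LibraryKey` columns. No negative entries.
    units
        ``"counts"`` or ``"percent"``. Percent columns must each sum to
        100 within 1e-6.
    """

    def __init__(self, values: pd.DataFrame, units: str) -> None:
        if units not in ("counts", "percent"):
            raise ValueError(f"units must be 'counts' or 'percent', got {units!r}")
        if values.index.has_duplicates:
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate OTU ids: {dupes}")
        if len(set(values.columns)) != len(values.columns):
            raise ValueError("duplicate library keys in columns")
        for col in values.columns:
            if not isinstance(col, LibraryKey):
                raise TypeError(f"column {col!r} is not a LibraryKey")
        arr = values.to_numpy(dtype=float)
        if np.any(arr < 0):
            raise ValueError("abundance values must be non-negative")
        if units == "percent" and arr.shape[0] > 0:
            sums = arr.sum(axis=0)
            bad = np.where(np.abs(sums - 100.0) > 1e-6)[0]
            if bad.size:
                key = values.columns[bad[0]]
                raise ValueError(
                    f"percent column {key} sums to {sums[bad[0]]!r}, expected 100"
                )
        self.values = values.astype(float)
        self.units = units

    # -- basic accessors -------------------------------------------------

    @property
    def otu_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def libraries(self) -> list[LibraryKey]:
        return list(self.values.columns)

    def column(self, key: LibraryKey) -> pd.Series:
        """Per-OTU values of one library; raises KeyError naming the key."""
        if key not in self.values.columns:
            raise KeyError(f"missing library {key.token()}")
        return self.values[key]

    def select(self, **criteria: object) -> "AbundanceTable":
        """Subset libraries by key fields, e.g. ``select(oxygen='oxic')``."""
        keep = [
            k
            for k in self.values.columns
            if all(getattr(k, f) == v for f, v in criteria.items())
        ]
        return AbundanceTable(self.values[keep], self.units)

    def days(self) -> list[float]:
        return sorted({k.day for k in self.values.columns})

    def equals(self, other: "AbundanceTable") -> bool:
        return self.units == other.units and self.values.equals(other.values)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<AbundanceTable {len(self.otu_ids)} OTUs x "
            f"{len(self.libraries)} libraries [{self.units}]>"
        )

    # -- transforms ------------------------------------------------------

    def to_relative(self, *, allow_renormalize: bool = False) -> "AbundanceTable":
        return to_relative(self, allow_renormalize=allow_renormalize)


def to_relative(table: AbundanceTable, *, allow_renormalize: bool = False) -> AbundanceTable:
    """Normalize a counts table to percent relative abundances.

    ``value[o, l] = 100 * count[o, l] / total[l]``. A table already in
    percent is rejected unless ``allow_renormalize`` is set, in which case
    the operation is an (idempotent) renormalization.

    Raises
    ------
    ValueError
        If a library has zero total reads (naming the LibraryKey), or units
        are percent without ``allow_renormalize``.
    """
    if table.units == "percent" and not allow_renormalize:
        raise ValueError("table is already in percent units; pass allow_renormalize=True")
    totals = table.values.sum(axis=0)
    zero = [k for k, t in totals.items() if t <= 0]
    if zero:
        raise ValueError(f"library {zero[0].token()} has zero total reads")
    out = table.values.div(totals, axis=1) * 100.0
    return AbundanceTable(out, "percent")


def pool_fractions_by_class(
    fraction_counts: pd.DataFrame,
    fractions: Sequence[FractionRecord],
    *,
    heavy_window: tuple[float, float] = HEAVY_WINDOW,
    light_window: tuple[float, float] = LIGHT_WINDOW,
) -> dict[str, pd.Series]:
    """Pool per-fraction OTU counts into heavy and light totals.

    ``fraction_counts`` columns are fraction indices matching the
    ``fractions`` metadata of one gradient. Counts of fractions falling in
    the same window are summed (the pooled heavy / pooled light library of
    that gradient); excluded fractions are dropped.
    """
    by_index = {f.fraction_index: f for f in fractions}
    if len(by_index) != len(fractions):
        raise ValueError("fraction_index values must be unique within a gradient")
    pooled: dict[str, pd.Series] = {}
    for col in fraction_counts.columns:
        if col not in by_index:
            raise KeyError(f"no fraction metadata for fraction index {col!r}")
        cls = classify_fraction(
            by_index[col].buoyant_density,
            heavy_window=heavy_window,
            light_window=light_window,
        )
        if cls == "excluded":
            continue
        if cls in pooled:
            pooled[cls] = pooled[cls] + fraction_counts[col]
        else:
            pooled[cls] = fraction_counts[col].copy()
    return pooled


# -- TSV I/O -------------------------------------------------------------

_UNITS_DIRECTIVE = "# units:"


def write_abundance_tsv(table: AbundanceTable, path: str | Path) -> None:
    """Write an abundance table as UTF-8 TSV ('.' decimal, 12 sig. digits).

    First line is a ``# units: …`` directive, then a header row of
    ``otu_id`` plus one ``isotope|oxygen|day|fraction_class`` token per
    library. Row and column order are preserved.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"{_UNITS_DIRECTIVE} {table.units}\n")
        fh.write("otu_id\t" + "\t".join(k.token() for k in table.libraries) + "\n")
        for otu, row in table.values.iterrows():
            fh.write(str(otu) + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def read_abundance_tsv(path: str | Path) -> AbundanceTable:
    """Read an abundance table written by :func:`write_abundance_tsv`.

    Errors (duplicate OTU id, malformed key, negative or non-numeric value,
    ragged row) are reported with the 1-based line number.
    """
    path = Path(path)
    units = "counts"
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    lineno = 0
    if lines and lines[0].startswith(_UNITS_DIRECTIVE):
        units = lines[0][len(_UNITS_DIRECTIVE):].strip()
        lines = lines[1:]
        lineno = 1
    if not lines:
        raise ValueError(f"{path}: empty abundance table")
    header = lines[0].split("\t")
    header_line = lineno + 1
    if header[0] != "otu_id":
        raise ValueError(f"{path}:{header_line}: first header column must be 'otu_id'")
    try:
        keys = [LibraryKey.from_token(tok) for tok in header[1:]]
    except ValueError as exc:
        raise ValueError(f"{path}:{header_line}: {exc}") from exc
    otus: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for offset, line in enumerate(lines[1:], start=header_line + 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(keys) + 1:
            raise ValueError(
                f"{path}:{offset}: expected {len(keys) + 1} columns, got {len(parts)}"
            )
        otu = parts[0]
        if otu in seen:
            raise ValueError(f"{path}:{offset}: duplicate OTU id {otu!r}")
        seen.add(otu)
        try:
            vals = [float(v) for v in parts[1:]]
        except ValueError as exc:
            raise ValueError(f"{path}:{offset}: non-numeric value ({exc})") from exc
        if any(v < 0 for v in vals):
            raise ValueError(f"{path}:{offset}: negative abundance for OTU {otu!r}")
        otus.append(otu)
        rows.append(vals)
    df = pd.DataFrame(rows, index=pd.Index(otus, name="otu_id"), columns=keys)
    return AbundanceTable(df, units)


def write_fraction_tsv(fractions: Iterable[FractionRecord], path: str | Path) -> None:
    """Write fraction metadata TSV: gradient_id, fraction_index, buoyant_density, rna_ng."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("gradient_id\tfraction_index\tbuoyant_density\trna_ng\n")
        for f in fractions:
            rna = "" if f.rna_ng is None else f"{f.rna_ng:.12g}"
            fh.write(f"{f.gradient_id}\t{f.fraction_index}\t{f.buoyant_density:.12g}\t{rna}\n")


def read_fraction_tsv(path: str | Path) -> list[FractionRecord]:
    path = Path(path)
    records: list[FractionRecord] = []
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].split("\t")[:3] != ["gradient_id", "fraction_index", "buoyant_density"]:
        raise ValueError(f"{path}: missing fraction metadata header")
    for offset, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) not in (3, 4):
            raise ValueError(f"{path}:{offset}: expected 3-4 columns, got {len(parts)}")
        try:
            rna = None
            if len(parts) == 4 and parts[3] != "":
                rna = float(parts[3])
            records.append(
                FractionRecord(
                    gradient_id=parts[0],
                    fraction_index=int(parts[1]),
                    buoyant_density=float(parts[2]),
                    rna_ng=rna,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{offset}: {exc}") from exc
    return records
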