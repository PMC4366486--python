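"""Domain types and I/O for genus-level ecospace data.

The central objects are a :class:`Timescale` of ordered, contiguous geologic
stages (oldest to youngest), a :class:`GenusRecord` carrying a genus's
stratigraphic range (first/last appearance stage and age) together with its
ecological mode of life — the (tiering, motility, feeding) triple of the
Bambach ecospace cube — and the :class:`OccurrenceTable` obtained by
range-through expansion: a genus is counted as present in every stage from
its first- to its last-appearance stage inclusive.

Input tables are plain delimited text.  Column names follow the snake_case
dialect (``taxon_name, phylum, class, fad_age, fad_int, lad_age, lad_int,
tiering, motility, feeding, ecological_mode, eco_ref``); a handful of common
aliases (e.g. ``"ecological mode"`` with a space) are accepted on read and
normalised on write.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "EcospaceError",
    "TableFormatError",
    "ValidationError",
    "TimescaleError",
    "GeologicStage",
    "Timescale",
    "EcologicalMode",
    "GenusRecord",
    "ModeCountVector",
    "OccurrenceTable",
    "build_timescale",
    "read_genus_table",
    "write_genus_table",
    "range_through",
    "stage_mode_counts",
    "era_group",
]


class EcospaceError(Exception):
    """Base class for all errors raised by this package."""


class TableFormatError(EcospaceError):
    """A delimited input file is structurally unusable (missing columns...)."""


class ValidationError(EcospaceError):
    """Row- or value-level validation failed; the message names offenders."""


class TimescaleError(EcospaceError):
    """The timescale is non-contiguous, non-monotone or a lookup failed."""


#: Canonical era groups used throughout the analyses.  The Cambrian is kept
#: separate from the rest of the Palaeozoic because its ecospace structure is
#: analysed (and plotted) apart from the post-Cambrian Palaeozoic.
ERA_GROUPS = ("Cambrian", "Palaeozoic_postCambrian", "Mesozoic", "Cenozoic")

_ERA_ALIASES = {
    "paleozoic": "Palaeozoic_postCambrian",
    "palaeozoic": "Palaeozoic_postCambrian",
    "mesozoic": "Mesozoic",
    "cenozoic": "Cenozoic",
    "cainozoic": "Cenozoic",
}


def era_group(period: str, era: str) -> str:
    """Map a (period, era) label pair to a canonical era group.

    Cambrian stages form their own group regardless of the raw era label;
    unrecognised era labels pass through unchanged (synthetic timescales may
    use arbitrary labels).
    """
    if str(period).strip().lower() == "cambrian":
        return "Cambrian"
    return _ERA_ALIASES.get(str(era).strip().lower(), str(era).strip())


@dataclass(frozen=True)
class GeologicStage:
    """One bin of the geologic timescale.

    Ages are in Ma (millions of years before present); ``base_age`` is the
    older bound, ``top_age`` the younger.  ``bin_level`` distinguishes true
    stages from epoch-level bins produced by early-Cambrian merging.
    """

    name: str
    base_age: float
    top_age: float
    period: str = ""
    era: str = ""
    bin_level: str = "stage"

    def __post_init__(self) -> None:
        if not (self.base_age > self.top_age >= 0):
            raise TimescaleError(
                f"stage {self.name!r}: need base_age > top_age >= 0, "
                f"got base={self.base_age}, top={self.top_age}"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.base_age + self.top_age)

    @property
    def duration(self) -> float:
        return self.base_age - self.top_age

    @property
    def era_group(self) -> str:
        return era_group(self.period, self.era)

    def contains_age(self, age: float) -> bool:
        """True if ``age`` falls in this bin (base-inclusive, top-exclusive;
        the youngest bin also includes its top)."""
        return self.base_age >= age > self.top_age or age == self.top_age == 0.0


_AGE_TOL = 1e-6


class Timescale(Sequence):
    """Ordered, contiguous sequence of geologic stages, oldest first.

    Contiguity (each stage's top age equals the next stage's base age) and
    strict monotonicity are enforced at construction.
    """

    def __init__(self, stages: Iterable[GeologicStage]):
        self._stages: tuple[GeologicStage, ...] = tuple(stages)
        if not self._stages:
            raise TimescaleError("timescale must contain at least one stage")
        names = [s.name for s in self._stages]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise TimescaleError(f"duplicate stage names: {dupes}")
        for older, younger in zip(self._stages, self._stages[1:]):
            if younger.base_age >= older.base_age:
                raise TimescaleError(
                    f"ages not strictly decreasing at {older.name!r} -> "
                    f"{younger.name!r}"
                )
            if abs(older.top_age - younger.base_age) > _AGE_TOL:
                raise TimescaleError(
                    f"gap or overlap between {older.name!r} (top "
                    f"{older.top_age}) and {younger.name!r} (base "
                    f"{younger.base_age})"
                )
        self._index = {s.name: i for i, s in enumerate(self._stages)}

    # -- Sequence protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._stages)

    def __getitem__(self, i):
        return self._stages[i]

    def __iter__(self) -> Iterator[GeologicStage]:
        return iter(self._stages)

    # -- lookups -----------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [s.name for s in self._stages]

    def __contains__(self, name: object) -> bool:
        return name in self._index

    def index(self, name: str) -> int:  # type: ignore[override]
        try:
            return self._index[name]
        except KeyError:
            raise TimescaleError(f"unknown stage name {name!r}") from None

    def stage(self, name: str) -> GeologicStage:
        return self._stages[self.index(name)]

    def stage_containing(self, age: float) -> GeologicStage:
        for s in self._stages:
            if s.contains_age(age):
                return s
        raise TimescaleError(f"no stage contains age {age} Ma")

    def stages_in_interval(self, older: float, younger: float) -> list[GeologicStage]:
        """Stages whose midpoint falls in the age interval [older, younger).

        The older bound is inclusive, the younger exclusive, so adjacent
        intervals partition the stages they jointly cover.
        """
        if older <= younger:
            raise TimescaleError(
                f"interval must run old -> young, got ({older}, {younger})"
            )
        return [s for s in self._stages if older >= s.midpoint > younger]

    def __repr__(self) -> str:
        return (
            f"Timescale({len(self)} bins, {self._stages[0].base_age:g}-"
            f"{self._stages[-1].top_age:g} Ma)"
        )


class EcologicalMode(tuple):
    """A mode of life: the ordered (tiering, motility, feeding) triple.

    Each axis takes an integer code 1-6 following the standard ecospace-cube
    numbering, so at most 216 distinct modes exist.  Modes compare equal iff
    their triples are equal (plain tuple semantics).
    """

    __slots__ = ()

    def __new__(cls, tiering: int, motility: int, feeding: int):
        for axis, code in (("tiering", tiering), ("motility", motility), ("feeding", feeding)):
            code_i = int(code)
            if code_i != code or not 1 <= code_i <= 6:
                raise ValidationError(f"{axis} code {code!r} outside 1-6")
        return super().__new__(cls, (int(tiering), int(motility), int(feeding)))

    tiering = property(lambda self: self[0])
    motility = property(lambda self: self[1])
    feeding = property(lambda self: self[2])

    @property
    def key(self) -> tuple[int, int, int]:
        return tuple(self)

    @classmethod
    def from_string(cls, s: str) -> "EcologicalMode":
        parts = str(s).replace("-", ".").split(".")
        if len(parts) != 3:
            raise ValidationError(f"cannot parse ecological mode {s!r}")
        return cls(*(int(p) for p in parts))

    def __str__(self) -> str:
        return f"{self[0]}.{self[1]}.{self[2]}"

    def __repr__(self) -> str:
        return f"EcologicalMode({self[0]}, {self[1]}, {self[2]})"


@dataclass(frozen=True)
class GenusRecord:
    """One marine animal genus: stratigraphic range plus mode of life.

    ``fad_*``/``lad_*`` are the first/last appearance datum; ages in Ma,
    intervals as stage names resolvable in the active timescale.  Each genus
    carries exactly one mode (the mode of the majority of its species).
    """

    taxon_name: str
    fad_age: float
    fad_int: str
    lad_age: float
    lad_int: str
    mode: EcologicalMode
    phylum: str = ""
    class_: str = ""
    eco_ref: str = ""

    def __post_init__(self) -> None:
        if self.fad_age < self.lad_age:
            raise ValidationError(
                f"genus {self.taxon_name!r}: fad_age ({self.fad_age}) is "
                f"younger than lad_age ({self.lad_age})"
            )


class ModeCountVector(Mapping):
    """Genus counts per occupied ecological mode for one stage or pool.

    ``S`` is the number of distinct occupied modes, ``N`` the total genus
    count; every stored count is >= 1 (unoccupied modes are absent).
    """

    def __init__(self, counts: Mapping[EcologicalMode, int] | None = None):
        items = {}
        for mode, n in (counts or {}).items():
            n = int(n)
            if n < 0:
                raise ValidationError(f"negative count for mode {mode}")
            if n > 0:
                items[mode] = n
        self._counts = items

    @classmethod
    def from_modes(cls, modes: Iterable[EcologicalMode]) -> "ModeCountVector":
        counts: dict[EcologicalMode, int] = {}
        for m in modes:
            counts[m] = counts.get(m, 0) + 1
        return cls(counts)

    # Mapping protocol
    def __getitem__(self, mode):
        return self._counts[mode]

    def __iter__(self):
        return iter(self._counts)

    def __len__(self):
        return len(self._counts)

    @property
    def S(self) -> int:
        return len(self._counts)

    @property
    def N(self) -> int:
        return sum(self._counts.values())

    @property
    def modes(self) -> list[EcologicalMode]:
        return list(self._counts)

    def counts_array(self) -> np.ndarray:
        return np.asarray(list(self._counts.values()), dtype=np.int64)

    def __repr__(self) -> str:
        return f"ModeCountVector(S={self.S}, N={self.N})"


# ---------------------------------------------------------------------------
# Timescale I/O

def build_timescale(
    path: str | Path,
    *,
    cambrian_epoch_binning: bool = False,
    exclude_holocene: bool = False,
) -> Timescale:
    """Read a timescale CSV and return an ordered, validated :class:`Timescale`.

    The file lists bins oldest to youngest with columns ``name, base_age,
    top_age, period, era`` and an optional ``epoch_group`` column.  With
    ``cambrian_epoch_binning``, consecutive rows sharing a non-empty
    ``epoch_group`` are merged into a single epoch-level bin spanning their
    union — stage-level resolution is unreliable for the earliest Cambrian.
    With ``exclude_holocene``, the terminal 0.117-0 Ma bin is dropped so
    living taxa do not inflate modern diversity.
    """
    df = pd.read_csv(path, dtype={"name": str})
    required = {"name", "base_age", "top_age"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"timescale file missing columns: {sorted(missing)}")
    for col in ("period", "era"):
        if col not in df.columns:
            df[col] = ""
    rows = df.to_dict("records")

    if cambrian_epoch_binning and "epoch_group" in df.columns:
        merged: list[dict] = []
        for row in rows:
            group = row.get("epoch_group")
            group = "" if group is None or (isinstance(group, float) and np.isnan(group)) else str(group).strip()
            if group and merged and merged[-1].get("_group") == group:
                prev = merged[-1]
                prev["top_age"] = min(prev["top_age"], row["top_age"])
                prev["base_age"] = max(prev["base_age"], row["base_age"])
            else:
                row = dict(row)
                row["_group"] = group
                if group:
                    row["name"] = group
                    row["_level"] = "epoch"
                merged.append(row)
        rows = merged

    stages = [
        GeologicStage(
            name=str(r["name"]),
            base_age=float(r["base_age"]),
            top_age=float(r["top_age"]),
            period=str(r.get("period", "") or ""),
            era=str(r.get("era", "") or ""),
            bin_level=r.get("_level", "stage"),
        )
        for r in rows
    ]

    if exclude_holocene:
        last = stages[-1]
        if last.top_age == 0.0 and last.base_age <= 0.5:
            stages = stages[:-1]
        elif last.top_age == 0.0:
            warnings.warn(
                f"terminal bin {last.name!r} spans {last.base_age}-0 Ma and "
                "cannot be identified as the Holocene; retained as-is"
            )
    return Timescale(stages)


# ---------------------------------------------------------------------------
# Genus table I/O

_COLUMN_ALIASES = {
    "taxon name": "taxon_name",
    "genus": "taxon_name",
    "ecological mode": "ecological_mode",
    "eco mode": "ecological_mode",
    "mode": "ecological_mode",
    "class": "class_",
    "class_name": "class_",
    "fad int": "fad_int",
    "lad int": "lad_int",
    "fad age": "fad_age",
    "lad age": "lad_age",
    "eco ref": "eco_ref",
}

_REQUIRED_COLUMNS = (
    "taxon_name",
    "fad_age",
    "fad_int",
    "lad_age",
    "lad_int",
    "tiering",
    "motility",
    "feeding",
)


def _normalise_columns(df: pd.DataFrame) -> pd.DataFrame:
    renames = {}
    for col in df.columns:
        key = str(col).strip().lower()
        renames[col] = _COLUMN_ALIASES.get(key, key.replace(" ", "_"))
    return df.rename(columns=renames)


def read_genus_table(path: str | Path, timescale: Timescale) -> list[GenusRecord]:
    """Read a delimited genus table and return validated records.

    Accepts CSV or TSV (sniffed) with at least the documented columns.  Rows
    failing validation (mode code outside 1-6, first appearance younger than
    last, interval name absent from ``timescale``) are reported together with
    their row numbers in a single :class:`ValidationError`.  Phylum/class are
    taken from dedicated columns if present, else parsed from a
    ``Phylum:Class:Genus`` compound taxon name.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype={"taxon_name": str})
    df = _normalise_columns(df)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"genus table missing required columns: {missing}")

    records: list[GenusRecord] = []
    problems: list[str] = []
    seen: set[str] = set()
    dupes: set[str] = set()

    for pos, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        row = row._asdict()
        name = str(row["taxon_name"]).strip()
        phylum = str(row.get("phylum", "") or "")
        cls = str(row.get("class_", "") or "")
        if (not phylum or not cls) and name.count(":") == 2:
            phylum, cls, name = (part.strip() for part in name.split(":"))
        try:
            mode = EcologicalMode(row["tiering"], row["motility"], row["feeding"])
            fad_int, lad_int = str(row["fad_int"]), str(row["lad_int"])
            for interval in (fad_int, lad_int):
                if interval not in timescale:
                    raise ValidationError(
                        f"interval {interval!r} not in the active timescale"
                    )
            if timescale.index(fad_int) > timescale.index(lad_int):
                raise ValidationError(
                    f"fad_int {fad_int!r} is younger than lad_int {lad_int!r}"
                )
            rec = GenusRecord(
                taxon_name=name,
                phylum=phylum,
                class_=cls,
                fad_age=float(row["fad_age"]),
                fad_int=fad_int,
                lad_age=float(row["lad_age"]),
                lad_int=lad_int,
                mode=mode,
                eco_ref=str(row.get("eco_ref", "") or ""),
            )
        except (ValidationError, ValueError) as exc:
            problems.append(f"row {pos} ({name!r}): {exc}")
            continue
        if name in seen:
            dupes.add(name)
        seen.add(name)
        records.append(rec)

    if problems:
        raise ValidationError(
            f"{len(problems)} invalid row(s):\n" + "\n".join(problems)
        )
    if dupes:
        warnings.warn(
            f"duplicate taxon_name(s) in genus table: {sorted(dupes)[:10]}"
            + ("..." if len(dupes) > 10 else "")
        )
    return records


def write_genus_table(records: Iterable[GenusRecord], path: str | Path) -> None:
    """Write records as a snake_case CSV round-trippable by
    :func:`read_genus_table`."""
    rows = [
        {
            "taxon_name": r.taxon_name,
            "phylum": r.phylum,
            "class": r.class_,
            "fad_age": r.fad_age,
            "fad_int": r.fad_int,
            "lad_age": r.lad_age,
            "lad_int": r.lad_int,
            "tiering": r.mode.tiering,
            "motility": r.mode.motility,
            "feeding": r.mode.feeding,
            "ecological_mode": str(r.mode),
            "eco_ref": r.eco_ref,
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=[
            "taxon_name", "phylum", "class", "fad_age", "fad_int", "lad_age",
            "lad_int", "tiering", "motility", "feeding", "ecological_mode",
            "eco_ref",
        ],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Range-through expansion

@dataclass
class OccurrenceTable:
    """Genus-by-stage occurrences from range-through expansion.

    ``frame`` has one row per (genus, stage) pair with columns ``taxon_name,
    phylum, class, stage, stage_index, tiering, motility, feeding``; a genus
    occurs in every stage from its first- through last-appearance stage
    inclusive and in no others.
    """

    frame: pd.DataFrame
    timescale: Timescale = field(repr=False)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def stages(self) -> list[str]:
        present = set(self.frame["stage"])
        return [n for n in self.timescale.names if n in present]

    def genus_counts(self) -> pd.Series:
        """Per-stage genus count X, indexed by stage name in timescale order."""
        counts = self.frame.groupby("stage", sort=False)["taxon_name"].nunique()
        return counts.reindex(self.timescale.names, fill_value=0)

    def stage_frame(self, stage: str) -> pd.DataFrame:
        if stage not in self.timescale:
            raise TimescaleError(f"unknown stage {stage!r}")
        return self.frame[self.frame["stage"] == stage]

    def modes_of(self, sub: pd.DataFrame) -> list[EcologicalMode]:
        return [
            EcologicalMode(t, m, f)
            for t, m, f in sub[["tiering", "motility", "feeding"]].itertuples(index=False)
        ]

    def interval_frame(self, older: float, younger: float) -> pd.DataFrame:
        """Rows in stages whose midpoint lies in [older, younger) Ma."""
        names = {s.name for s in self.timescale.stages_in_interval(older, younger)}
        if not names:
            raise TimescaleError(
                f"age interval ({older}, {younger}) Ma matches no timescale bin"
            )
        return self.frame[self.frame["stage"].isin(names)]


def range_through(records: Sequence[GenusRecord], timescale: Timescale) -> OccurrenceTable:
    """Expand genus ranges into one occurrence per (genus, stage) pair.

    Presence is determined by the named first/last intervals: a genus spanning
    stages i..j contributes exactly j-i+1 rows.  The carried ages are used
    only for plotting and age-window selection downstream.
    """
    if not records:
        frame = pd.DataFrame(
            columns=["taxon_name", "phylum", "class", "stage", "stage_index",
                     "tiering", "motility", "feeding"]
        )
        return OccurrenceTable(frame=frame, timescale=timescale)

    first = np.array([timescale.index(r.fad_int) for r in records])
    last = np.array([timescale.index(r.lad_int) for r in records])
    bad = first > last
    if bad.any():
        names = [records[i].taxon_name for i in np.flatnonzero(bad)[:10]]
        raise ValidationError(f"lad_int older than fad_int for: {names}")
    spans = last - first + 1
    rep = np.repeat(np.arange(len(records)), spans)
    stage_idx = np.concatenate([np.arange(f, l + 1) for f, l in zip(first, last)])
    names_arr = np.array(timescale.names, dtype=object)
    frame = pd.DataFrame(
        {
            "taxon_name": np.array([r.taxon_name for r in records], dtype=object)[rep],
            "phylum": np.array([r.phylum for r in records], dtype=object)[rep],
            "class": np.array([r.class_ for r in records], dtype=object)[rep],
            "stage": names_arr[stage_idx],
            "stage_index": stage_idx,
            "tiering": np.array([r.mode.tiering for r in records])[rep],
            "motility": np.array([r.mode.motility for r in records])[rep],
            "feeding": np.array([r.mode.feeding for r in records])[rep],
        }
    )
    return OccurrenceTable(frame=frame, timescale=timescale)


def stage_mode_counts(occurrences: OccurrenceTable, stage: str) -> ModeCountVector:
    """Genus counts per ecological mode within one stage.

    An empty stage yields an empty vector (S = N = 0); an unknown stage name
    raises :class:`TimescaleError`.
    """
    sub = occurrences.stage_frame(stage)
    return ModeCountVector.from_modes(occurrences.modes_of(sub))
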