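"""Data model and I/O for cross-experiment count tables and distance matrices.

The unit of analysis is one cross *combination* (female population x male
population, or one hybrid-dam backcross type), with offspring counts summed
over replicate pairs.  Per-replicate rows are accepted on input and
aggregated before modelling; the residual degrees of freedom of the
barrier models only make sense at combination level.

Every record must satisfy the full egg accounting identity

    eggs = sons + daughters + unhatched + dead_juv

i.e. every egg is either a viable son, a viable daughter, an unhatched egg
or a hatched offspring that died before adulthood.  Rows violating it are
rejected with their row number.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CROSS_CLASSES = ("control", "interpopulation", "backcross")

#: column order of the canonical cross-table CSV
CROSS_COLUMNS = (
    "female_pop",
    "male_pop",
    "cross_class",
    "dam_code",
    "n_pairs",
    "eggs",
    "sons",
    "daughters",
    "unhatched",
    "dead_juv",
)


class CrossTableError(ValueError):
    """Raised for malformed cross-table input (bad counts, bad labels)."""


@dataclass(frozen=True)
class CrossRecord:
    """Offspring counts for one cross combination.

    Parameters
    ----------
    female_pop, male_pop
        Population labels.  For backcrosses ``female_pop`` is ignored in
        favour of ``dam_code``.
    cross_class
        ``"control"`` (intra-population), ``"interpopulation"`` or
        ``"backcross"`` (F1 hybrid dam crossed to a parental male).
    dam_code
        For backcrosses, the hybrid dam's code: mother-population label
        followed by father-population label (``"TF"`` = Turkey dam x
        France sire).  Empty otherwise.
    n_pairs
        Number of replicate female-male pairs summed into this record.
    eggs, sons, daughters, unhatched, dead_juv
        Total eggs laid, viable male offspring, viable female offspring,
        unhatched eggs, and hatched offspring dead before adulthood.
    """

    female_pop: str
    male_pop: str
    cross_class: str
    dam_code: str = ""
    n_pairs: int = 1
    eggs: int = 0
    sons: int = 0
    daughters: int = 0
    unhatched: int = 0
    dead_juv: int = 0

    def __post_init__(self) -> None:
        if self.cross_class not in CROSS_CLASSES:
            raise CrossTableError(
                f"unknown cross_class {self.cross_class!r}; "
                f"expected one of {CROSS_CLASSES}"
            )
        for name in ("n_pairs", "eggs", "sons", "daughters", "unhatched", "dead_juv"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise CrossTableError(f"{name} must be a non-negative integer, got {v!r}")
        if self.eggs < 1:
            raise CrossTableError("eggs must be >= 1 for a record entering analysis")
        total = self.sons + self.daughters + self.unhatched + self.dead_juv
        if total != self.eggs:
            raise CrossTableError(
                "accounting identity violated: eggs="
                f"{self.eggs} but sons+daughters+unhatched+dead_juv={total}"
            )
        if self.cross_class == "backcross":
            if not self.dam_code:
                raise CrossTableError("backcross records require a dam_code")
        else:
            if self.dam_code:
                raise CrossTableError("dam_code is only valid for backcross records")
            is_control = self.female_pop == self.male_pop
            if is_control != (self.cross_class == "control"):
                raise CrossTableError(
                    f"cross_class {self.cross_class!r} inconsistent with "
                    f"female_pop={self.female_pop!r}, male_pop={self.male_pop!r}"
                )

    @property
    def key(self) -> tuple[str, str, str, str]:
        """Grouping key identifying the cross combination."""
        return (self.female_pop, self.male_pop, self.cross_class, self.dam_code)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise genetic distances (substitutions/site).

    ``labels`` fixes the population order; ``d`` is the square distance
    array with zero diagonal.
    """

    labels: tuple[str, ...]
    d: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError(f"distance array shape {d.shape} does not match {n} labels")
        if not np.all(np.isfinite(d)):
            raise ValueError("distances must be finite")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(
                f"population {label!r} not in distance matrix labels {self.labels}"
            ) from None

    def lookup(self, a: str, b: str) -> float:
        """Distance between populations ``a`` and ``b``."""
        return float(self.d[self.index(a), self.index(b)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.labels), columns=list(self.labels))

    def to_csv(self, path: str | Path) -> None:
        """Write as a square CSV with labels as header and index."""
        self.to_dataframe().to_csv(path, index_label="population")

    def to_phylip(self, path: str | Path) -> None:
        """Write in relaxed PHYLIP square distance format."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.d):
                fh.write(lab + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        labels = tuple(str(c) for c in df.columns)
        if tuple(str(i) for i in df.index) != labels:
            raise ValueError("distance CSV must have identical row and column labels")
        return cls(labels=labels, d=df.to_numpy(dtype=float))


# Printed COI K2P distance matrix over the seven study populations,
# lower triangle by row (T, I, CIM, CN, K, J) against earlier columns.
_TABLE2_LABELS = ("F", "T", "I", "CIM", "CN", "K", "J")
_TABLE2_LOWER = (
    (0.018,),
    (0.061, 0.057),
    (0.050, 0.057, 0.063),
    (0.050, 0.057, 0.063, 0.000),
    (0.050, 0.057, 0.063, 0.000, 0.000),
    (0.059, 0.063, 0.075, 0.068, 0.068, 0.068),
)


def table2_fixture() -> DistanceMatrix:
    """The study's published 7x7 COI K2P distance matrix.

    Populations: France (F), Turkey (T), Iran (I), Inner Mongolia (CIM),
    Eastern China (CN), Korea (K), Japan (J).  Distances range from 0
    (CIM/CN/K) to 0.075 (J vs I).
    """
    n = len(_TABLE2_LABELS)
    d = np.zeros((n, n))
    for i, row in enumerate(_TABLE2_LOWER, start=1):
        for j, val in enumerate(row):
            d[i, j] = d[j, i] = val
    return DistanceMatrix(labels=_TABLE2_LABELS, d=d)


def _records_from_frame(df: pd.DataFrame) -> list[CrossRecord]:
    records = []
    for idx, row in df.iterrows():
        dam = row.get("dam_code", "")
        dam = "" if (pd.isna(dam) or dam is None) else str(dam)
        try:
            rec = CrossRecord(
                female_pop=str(row["female_pop"]),
                male_pop=str(row["male_pop"]),
                cross_class=str(row["cross_class"]),
                dam_code=dam,
                n_pairs=int(row.get("n_pairs", 1)),
                eggs=int(row["eggs"]),
                sons=int(row["sons"]),
                daughters=int(row["daughters"]),
                unhatched=int(row["unhatched"]),
                dead_juv=int(row["dead_juv"]),
            )
        except (CrossTableError, ValueError) as exc:
            raise CrossTableError(f"row {idx + 2}: {exc}") from exc  # +2: header + 1-based
        records.append(rec)
    return records


def aggregate(records: Iterable[CrossRecord]) -> list[CrossRecord]:
    """Sum replicate records sharing the same cross-combination key.

    Input order of first appearance is preserved.
    """
    merged: dict[tuple, CrossRecord] = {}
    for rec in records:
        if rec.key in merged:
            prev = merged[rec.key]
            merged[rec.key] = replace(
                prev,
                n_pairs=prev.n_pairs + rec.n_pairs,
                eggs=prev.eggs + rec.eggs,
                sons=prev.sons + rec.sons,
                daughters=prev.daughters + rec.daughters,
                unhatched=prev.unhatched + rec.unhatched,
                dead_juv=prev.dead_juv + rec.dead_juv,
            )
        else:
            merged[rec.key] = rec
    return list(merged.values())


def read_cross_table(
    path: str | Path | io.IOBase, aggregate_replicates: bool = True
) -> list[CrossRecord]:
    """Read a comma-delimited cross table with a header naming the fields.

    Required columns: female_pop, male_pop, cross_class, eggs, sons,
    daughters, unhatched, dead_juv; optional: dam_code, n_pairs (default 1).
    Rows failing validation (negative counts, broken accounting identity,
    unknown cross_class) raise :class:`CrossTableError` naming the row.
    With ``aggregate_replicates`` (default) rows sharing a combination key
    are summed into one record.
    """
    df = pd.read_csv(path, dtype={"dam_code": str}, keep_default_na=False, na_values=[])
    required = {"female_pop", "male_pop", "cross_class", "eggs", "sons",
                "daughters", "unhatched", "dead_juv"}
    missing = required - set(df.columns)
    if missing:
        raise CrossTableError(f"missing column(s): {', '.join(sorted(missing))}")
    if "dam_code" not in df.columns:
        df["dam_code"] = ""
    if "n_pairs" not in df.columns:
        df["n_pairs"] = 1
    records = _records_from_frame(df)
    return aggregate(records) if aggregate_replicates else records


def write_cross_table(records: Sequence[CrossRecord], path: str | Path) -> None:
    """Write records to the canonical cross-table CSV."""
    df = pd.DataFrame(
        [{c: getattr(r, c) for c in CROSS_COLUMNS} for r in records],
        columns=list(CROSS_COLUMNS),
    )
    df.to_csv(path, index=False)


def split_dam_code(code: str, labels: Sequence[str]) -> tuple[str, str]:
    """Split a hybrid-dam code into (mother, father) population labels.

    Codes concatenate the mother's label and the father's label
    (``"TF"`` -> Turkey mother, France father; ``"CIMCN"`` -> CIM mother,
    CN father).  The split is found by matching both halves against the
    known labels; an ambiguous or unmatchable code is an error.
    """
    splits = [
        (code[:i], code[i:])
        for i in range(1, len(code))
        if code[:i] in labels and code[i:] in labels
    ]
    if not splits:
        raise CrossTableError(
            f"dam_code {code!r} cannot be split into two known population labels"
        )
    if len(splits) > 1:
        raise CrossTableError(f"dam_code {code!r} is ambiguous: {splits}")
    return splits[0]
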