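"""Core record types, docking-table IO, and activity-labeling rules.

Activity lives on the pChEMBL scale (-log10 molar IC50/Ki); the binary
label is derived from a pChEMBL cutoff (default 8.0, i.e. 10 nM).
Docking scores are Glide-SP-like: more negative = stronger predicted
binding, and a failed dock is a first-class missing entry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_ACTIVITY_THRESHOLD = 8.0


@dataclass
class CompoundRecord:
    """One molecule with its structure, activities, and docking scores.

    Parameters
    ----------
    compound_id : str
        Opaque unique key.
    smiles : str or None
        SMILES string, if known.
    pchembl_values : list of float
        One or more pChEMBL activity values (-log10 molar).
    activity_label : int or None
        1 = active, 0 = inactive; None until labeled.
    docking_scores : dict
        structure_id -> docking score. Absent key = docking failure.
    """

    compound_id: str
    smiles: str | None = None
    pchembl_values: list[float] = field(default_factory=list)
    activity_label: int | None = None
    docking_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.activity_label is not None and self.activity_label not in (0, 1):
            raise ValueError(
                f"activity_label must be 0 or 1, got {self.activity_label!r}"
            )
        for sid, s in self.docking_scores.items():
            if not np.isfinite(s):
                raise ValueError(
                    f"non-finite docking score {s!r} for {self.compound_id}/{sid}"
                )


class ScoreTable:
    """Compound x structure docking-score matrix with explicit missing entries.

    Backed by a pandas DataFrame (rows = compounds, columns = structures,
    NaN = failed dock).
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            raise ValueError("duplicate compound_ids in score table")
        if frame.columns.has_duplicates:
            raise ValueError("duplicate structure_ids in score table")
        values = frame.to_numpy(dtype=float)
        if np.isinf(values).any():
            raise ValueError("score table contains infinite entries")
        self._frame = frame.astype(float)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def compounds(self) -> list[str]:
        return list(self._frame.index)

    @property
    def structures(self) -> list[str]:
        return list(self._frame.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._frame.shape

    def n_missing(self) -> int:
        return int(self._frame.isna().to_numpy().sum())

    def missing_pairs(self) -> list[tuple[str, str]]:
        mask = self._frame.isna()
        rows, cols = np.nonzero(mask.to_numpy())
        return [(self._frame.index[r], self._frame.columns[c]) for r, c in zip(rows, cols)]

    def scores_for(self, compound_id: str) -> dict[str, float]:
        """Available (non-missing) scores of one compound."""
        row = self._frame.loc[compound_id]
        return {sid: float(v) for sid, v in row.items() if not np.isnan(v)}

    def column(self, structure_id: str) -> pd.Series:
        return self._frame[structure_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScoreTable):
            return NotImplemented
        return self._frame.equals(other._frame)


@dataclass(frozen=True)
class DatasetSplit:
    """A k-fold partition of compound ids, stratified by class."""

    fold_assignments: dict[str, int]
    k: int
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return [cid for cid, f in self.fold_assignments.items() if f == fold]


_DEFAULT_SCHEMA = {
    "compound_id": "compound_id",
    "structure_id": "structure_id",
    "docking_score": "docking_score",
}


def read_docking_csv(path, schema: dict[str, str] | None = None) -> ScoreTable:
    """Read a long-format docking CSV into a :class:`ScoreTable`.

    The CSV holds one row per (compound, structure) pair; pairs absent from
    the file become missing entries. ``schema`` maps the canonical column
    names (compound_id, structure_id, docking_score) to the file's headers.
    """
    colmap = dict(_DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, dtype={colmap["compound_id"]: str, colmap["structure_id"]: str})
    for canonical, name in colmap.items():
        if name not in df.columns:
            raise ValueError(f"column {name!r} (for {canonical}) not found in {path}")
    df = df.rename(columns={v: k for k, v in colmap.items()})
    dup = df.duplicated(subset=["compound_id", "structure_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate (compound, structure) pair in {path}: "
            f"({row['compound_id']}, {row['structure_id']})"
        )
    if not np.isfinite(df["docking_score"].to_numpy(dtype=float)).all():
        bad = df.loc[~np.isfinite(df["docking_score"].astype(float)), "compound_id"].iloc[0]
        raise ValueError(f"non-finite docking score for compound {bad!r} in {path}")
    wide = df.pivot(index="compound_id", columns="structure_id", values="docking_score")
    # preserve first-appearance order, pivot sorts lexicographically
    wide = wide.reindex(index=pd.unique(df["compound_id"]), columns=pd.unique(df["structure_id"]))
    wide.index.name = None
    wide.columns.name = None
    return ScoreTable(wide)


def write_docking_csv(table: ScoreTable, path) -> None:
    """Write a ScoreTable in the long CSV interchange format (missing entries omitted)."""
    long = (
        table.frame.stack()
        .rename("docking_score")
        .rename_axis(["compound_id", "structure_id"])
        .reset_index()
    )
    long.to_csv(path, index=False)


def read_molecules(path, fmt: str = "smiles_list") -> list[CompoundRecord]:
    """Read molecules from a SMILES list or an SDF file.

    Unparseable entries are skipped with a logged count; ids are taken from
    the file (second whitespace-separated token for SMILES lines, the title
    line or ``_Name`` for SDF) and fall back to ``mol<i>``.
    """
    from rdkit import Chem

    records: list[CompoundRecord] = []
    n_skipped = 0
    if fmt == "smiles_list":
        with open(path) as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
        for i, line in enumerate(lines):
            parts = line.split(None, 1)
            smi = parts[0]
            cid = parts[1].strip() if len(parts) > 1 else f"mol{i}"
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                n_skipped += 1
                continue
            records.append(CompoundRecord(compound_id=cid, smiles=Chem.MolToSmiles(mol)))
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path))
        for i, mol in enumerate(supplier):
            if mol is None:
                n_skipped += 1
                continue
            cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
            records.append(CompoundRecord(compound_id=cid, smiles=Chem.MolToSmiles(mol)))
    else:
        raise ValueError(f"unknown molecule format {fmt!r}")
    if n_skipped:
        logger.warning("skipped %d unparseable molecules from %s", n_skipped, path)
    return records


def merge_by_id(records: list[CompoundRecord]) -> list[CompoundRecord]:
    """Merge records sharing a compound_id into one entry pooling pChEMBL values."""
    merged: dict[str, CompoundRecord] = {}
    for rec in records:
        if rec.compound_id not in merged:
            merged[rec.compound_id] = CompoundRecord(
                compound_id=rec.compound_id,
                smiles=rec.smiles,
                pchembl_values=list(rec.pchembl_values),
                activity_label=rec.activity_label,
                docking_scores=dict(rec.docking_scores),
            )
        else:
            tgt = merged[rec.compound_id]
            tgt.pchembl_values.extend(rec.pchembl_values)
            tgt.docking_scores.update(rec.docking_scores)
            if tgt.smiles is None:
                tgt.smiles = rec.smiles
    return list(merged.values())


def label_activity(
    records: list[CompoundRecord],
    threshold: float = DEFAULT_ACTIVITY_THRESHOLD,
) -> list[CompoundRecord]:
    """Assign binary activity labels at a pChEMBL cutoff.

    A compound is active (1) iff *every* pChEMBL value is strictly above
    the threshold and inactive (0) iff every value is at or below it.
    Compounds whose values straddle the cutoff get conflicting labels and
    are dropped.
    """
    out: list[CompoundRecord] = []
    n_dropped = 0
    for rec in records:
        if not rec.pchembl_values:
            raise ValueError(f"compound {rec.compound_id} has no pChEMBL value")
        labels = {1 if v > threshold else 0 for v in rec.pchembl_values}
        if len(labels) > 1:
            n_dropped += 1
            continue
        out.append(
            CompoundRecord(
                compound_id=rec.compound_id,
                smiles=rec.smiles,
                pchembl_values=list(rec.pchembl_values),
                activity_label=labels.pop(),
                docking_scores=dict(rec.docking_scores),
            )
        )
    if n_dropped:
        logger.info("dropped %d compounds with conflicting activity labels", n_dropped)
    return out


def drop_multi_activity(records: list[CompoundRecord]) -> list[CompoundRecord]:
    """Keep only compounds with exactly one pChEMBL value."""
    return [r for r in records if len(r.pchembl_values) == 1]


def stratified_folds(
    labels: dict[str, int] | pd.Series,
    k: int = 5,
    seed: int = 0,
) -> DatasetSplit:
    """Deterministic stratified k-fold assignment.

    Shuffles each class independently under ``seed`` and deals members
    round-robin across folds, so per-fold class counts differ by at most
    one within every class.
    """
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    if k < 2:
        raise ValueError("k must be >= 2")
    by_class: dict[int, list[str]] = {}
    for cid, lab in labels.items():
        by_class.setdefault(int(lab), []).append(cid)
    if len(by_class) < 2:
        raise ValueError("both classes must be present for stratified folding")
    for lab, ids in by_class.items():
        if len(ids) < k:
            raise ValueError(f"class {lab} has {len(ids)} members, fewer than k={k} folds")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for lab in sorted(by_class):
        ids = sorted(by_class[lab])
        rng.shuffle(ids)
        for i, cid in enumerate(ids):
            assignment[cid] = i % k
    return DatasetSplit(fold_assignments=assignment, k=k, seed=seed)
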