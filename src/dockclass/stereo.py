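"""Paired R/S-configuration comparison.

SGLT2 inhibition is sensitive to the configuration of the sugar moiety:
inverting a single stereocenter (position C5) reduces activity sharply.
This module provides the stereocenter-inversion utility used to build
the epimeric library, the paired t-test comparing index-aligned docking
scores of the two libraries, and per-residue interaction-type loss
tallies from binary ligand-residue interaction fingerprints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PairedComparisonResult:
    """Summary of a paired docking-score comparison between two libraries."""

    n_pairs: int
    mean_R: float
    mean_S: float
    median_R: float
    median_S: float
    mean_diff: float  # mean of (S - R)
    t_statistic: float
    p_value: float  # two-sided
    ci95: tuple[float, float]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("need at least two pairs")
        if self.ci95[0] > self.ci95[1]:
            raise ValueError("confidence interval bounds out of order")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def invert_stereocenter(smiles: str, atom_index: int) -> str:
    """Invert the tetrahedral parity of one stereocenter; return canonical SMILES.

    The atom at ``atom_index`` (an index into the molecule parsed from
    ``smiles``) must carry a defined tetrahedral chiral tag. Applying the
    inversion twice returns the canonical form of the input.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    if atom_index < 0 or atom_index >= mol.GetNumAtoms():
        raise ValueError(f"atom index {atom_index} out of range")
    atom = mol.GetAtomWithIdx(atom_index)
    if atom.GetChiralTag() not in (
        Chem.ChiralType.CHI_TETRAHEDRAL_CW,
        Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
    ):
        raise ValueError(
            f"atom {atom_index} ({atom.GetSymbol()}) is not a defined tetrahedral stereocenter"
        )
    atom.InvertChirality()
    return Chem.MolToSmiles(mol)


def paired_score_test(scores_R, scores_S) -> PairedComparisonResult:
    """Classical paired-samples t-test on d = S - R with a 95% CI.

    The null hypothesis is no true mean difference between the two
    libraries' docking scores; the p-value is two-sided from the t
    distribution with n-1 degrees of freedom.
    """
    r = np.asarray(scores_R, dtype=float)
    s = np.asarray(scores_S, dtype=float)
    if r.shape != s.shape:
        raise ValueError("score vectors must be index-aligned and equal length")
    n = len(r)
    if n < 2:
        raise ValueError("need at least two pairs")
    d = s - r
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError(
            f"differences have zero variance (constant difference {d[0]:.6g}); "
            "t-test is degenerate"
        )
    res = stats.ttest_rel(s, r)
    mean_d = float(d.mean())
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return PairedComparisonResult(
        n_pairs=n,
        mean_R=float(r.mean()),
        mean_S=float(s.mean()),
        median_R=float(np.median(r)),
        median_S=float(np.median(s)),
        mean_diff=mean_d,
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        ci95=(mean_d - half, mean_d + half),
    )


class InteractionMatrix:
    """Ligands x (residue, interaction-type) binary occupancy matrix.

    Column labels are opaque strings such as ``GLU99:hbond_acceptor``; no
    structure-aware parsing is applied.
    """

    def __init__(self, frame: pd.DataFrame):
        values = frame.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("interaction matrix entries must be 0 or 1")
        self._frame = frame.astype(int)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def ligand_ids(self) -> list[str]:
        return list(self._frame.index)

    @property
    def columns(self) -> list[str]:
        return list(self._frame.columns)

    @property
    def n_ligands(self) -> int:
        return len(self._frame)

    def column_sums(self) -> pd.Series:
        return self._frame.sum(axis=0)

    @classmethod
    def from_csv(cls, path) -> "InteractionMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index.name = None
        return cls(df)

    def to_csv(self, path) -> None:
        self._frame.rename_axis("ligand_id").to_csv(path)


def interaction_loss_tally(
    matrix_R: InteractionMatrix,
    matrix_S: InteractionMatrix,
    min_loss: int = 5,
    denominator: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-column interaction losses going from the R to the S library.

    For each (residue, interaction-type) column, loss = sum_R - sum_S.
    Returns (losses, gains): losses holds columns with loss strictly
    greater than ``min_loss`` sorted descending, with ``loss_fraction``
    relative to ``denominator`` (default: the S matrix's ligand count,
    i.e. the docked S library); gains lists columns whose occupancy
    increased.
    """
    if list(matrix_R.columns) != list(matrix_S.columns):
        raise ValueError("interaction matrices must share an identical column set")
    if denominator is None:
        denominator = matrix_S.n_ligands
    diff = matrix_R.column_sums() - matrix_S.column_sums()
    losses = (
        diff[diff > min_loss]
        .sort_values(ascending=False)
        .rename("loss_count")
        .to_frame()
        .reset_index(names="column")
    )
    losses["loss_fraction"] = losses["loss_count"] / denominator
    gains = (
        (-diff[diff < 0])
        .sort_values(ascending=False)
        .rename("gain_count")
        .to_frame()
        .reset_index(names="column")
    )
    return losses, gains
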