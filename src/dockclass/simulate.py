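"""Synthetic inputs for every pipeline stage.

Nothing here touches a docking engine: the generators emulate the
*statistical shape* of a docking campaign against multiple structures of
one target --

- two-class (active/inactive) Gaussian docking-score distributions with
  a shared latent affinity term controlling inter-structure correlation,
- a combinatorial gliflozin-like SMILES library (sugar core x two aryl
  substituents) whose pChEMBL values carry a fragment-level
  structure-activity signal, so fingerprint similarity predicts activity,
- index-paired R/S stereoisomer score libraries with a configurable mean
  shift of the disadvantaged configuration,
- paired binary ligand-residue interaction matrices with per-column
  interaction-loss probabilities.

All generators are pure functions of their configuration (seed included).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CompoundRecord, ScoreTable


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (stable across runs and platforms)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# two-class multi-structure docking scores


@dataclass(frozen=True)
class ScoreSimConfig:
    """Two-class docking-score simulation settings.

    Scores are Glide-SP-like (more negative = stronger binding). Each
    compound carries one latent affinity draw shared across structures;
    ``rho`` is the fraction of the within-class variance carried by that
    shared term, hence the pairwise inter-structure score correlation.
    """

    n_active: int = 500
    n_inactive: int = 500
    mu_active: float = -10.0
    mu_inactive: float = -8.0
    sigma: float = 1.0
    n_structures: int = 5
    rho: float = 0.5
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")


def simulate_scores(cfg: ScoreSimConfig) -> tuple[ScoreTable, pd.Series]:
    """Simulate a compound x structure score table with binary labels.

    Per structure, class-conditional scores are Gaussian with the
    configured means and standard deviation ``sigma``; the correlation of
    any two structures' scores is ``rho``. Missing entries (failed docks)
    are placed i.i.d. at ``dropout_rate``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_active + cfg.n_inactive
    labels = np.concatenate(
        [np.ones(cfg.n_active, dtype=int), np.zeros(cfg.n_inactive, dtype=int)]
    )
    mu = np.where(labels == 1, cfg.mu_active, cfg.mu_inactive)
    z = rng.standard_normal(n)
    eps = rng.standard_normal((n, cfg.n_structures))
    scores = (
        mu[:, None]
        + cfg.sigma * (np.sqrt(cfg.rho) * z[:, None] + np.sqrt(1 - cfg.rho) * eps)
    )
    ids = [f"cpd{i:05d}" for i in range(n)]
    structures = [f"S{j + 1}" for j in range(cfg.n_structures)]
    frame = pd.DataFrame(scores, index=ids, columns=structures)
    if cfg.dropout_rate > 0:
        mask = rng.random((n, cfg.n_structures)) < cfg.dropout_rate
        frame = frame.mask(mask)
    return ScoreTable(frame), pd.Series(labels, index=ids, name="label")


# ---------------------------------------------------------------------------
# gliflozin-like combinatorial SMILES library

# sugar core C-linked to a methylene-bridged two-ring aglycone; {s1} sits on
# the proximal ring, {s2} para on the distal ring
_TEMPLATE = (
    "OC[C@H]1O[C@@H](c2cc({s1})ccc2Cc2ccc({s2})cc2)"
    "[C@H](O)[C@@H](O)[C@@H]1O"
)

ARYL_SUBSTITUENTS: tuple[str, ...] = (
    "[H]", "F", "Cl", "Br", "C", "CC", "C(C)C", "OC",
    "OCC", "O", "N", "C#N", "C(F)(F)F", "SC", "S(C)(=O)=O", "CO",
)

_PCHEMBL_BASE = 7.9
_FRAGMENT_EFFECT_SD = 0.7  # activity contribution per substituent
_PCHEMBL_NOISE_SD = 0.2  # residual activity spread within a substituent pair
_FRAGMENT_BIAS_SD = 0.7  # systematic docking-score error per substituent


def _simulate_library(
    n: int, seed: int
) -> tuple[list[CompoundRecord], np.ndarray]:
    """Library records plus each compound's fragment-linked docking bias."""
    rng = np.random.default_rng(seed)
    k = len(ARYL_SUBSTITUENTS)
    # per-fragment, per-position latent contributions, drawn once per call
    effect1 = rng.normal(0.0, _FRAGMENT_EFFECT_SD, size=k)
    effect2 = rng.normal(0.0, _FRAGMENT_EFFECT_SD, size=k)
    bias1 = rng.normal(0.0, _FRAGMENT_BIAS_SD, size=k)
    bias2 = rng.normal(0.0, _FRAGMENT_BIAS_SD, size=k)
    i1 = rng.integers(0, k, size=n)
    i2 = rng.integers(0, k, size=n)
    pchembl = (
        _PCHEMBL_BASE
        + effect1[i1]
        + effect2[i2]
        + rng.normal(0.0, _PCHEMBL_NOISE_SD, size=n)
    )
    records = [
        CompoundRecord(
            compound_id=f"lib{i:05d}",
            smiles=_TEMPLATE.format(
                s1=ARYL_SUBSTITUENTS[i1[i]], s2=ARYL_SUBSTITUENTS[i2[i]]
            ),
            pchembl_values=[float(pchembl[i])],
        )
        for i in range(n)
    ]
    return records, bias1[i1] + bias2[i2]


def simulate_library_smiles(n: int, seed: int = 0) -> list[CompoundRecord]:
    """Gliflozin-like SMILES library with a structure-activity neighborhood signal.

    Compounds are built combinatorially (core x substituent x substituent)
    and each substituent carries a latent activity contribution, so
    compounds sharing substituents have correlated pChEMBL values.
    """
    records, _ = _simulate_library(n, seed)
    return records


# ---------------------------------------------------------------------------
# full classification dataset (scores tied to the SMILES library)

_SCORE_SLOPE = 0.85  # docking-score units per pChEMBL unit
_SCORE_INTERCEPT = 1.5


@dataclass(frozen=True)
class DatasetSimConfig:
    """Full synthetic campaign: library + per-structure docking scores.

    Docking scores track activity linearly (slope ``score_slope``,
    negative orientation), distorted by a fragment-linked systematic bias
    (shared by structurally similar compounds), a compound-level shared
    error, and independent per-structure noise. ``rho`` splits the
    sigma-scaled error variance between the shared and independent parts,
    so ensemble averaging cancels only the independent part while
    similarity calibration can correct the fragment-linked bias.
    """

    n_compounds: int = 1197
    n_structures: int = 5
    rho: float = 0.5
    sigma: float = 0.8
    dropout_rate: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")


def simulate_classification_dataset(
    cfg: DatasetSimConfig,
) -> tuple[list[CompoundRecord], ScoreTable, pd.Series]:
    """Simulate a labeled library docked into several pseudo-structures.

    Returns the labeled records (SMILES, single pChEMBL value, binary
    label, per-structure docking scores), the score table, and the label
    series. Compounds with a missing score in some structure keep their
    remaining scores, mirroring partial docking failures.
    """
    rng = np.random.default_rng(derive_seed(cfg.seed, "dataset"))
    records, frag_bias = _simulate_library(cfg.n_compounds, derive_seed(cfg.seed, "library"))
    n, m = cfg.n_compounds, cfg.n_structures
    pchembl = np.array([r.pchembl_values[0] for r in records])
    base = -(_SCORE_SLOPE * pchembl + _SCORE_INTERCEPT)
    z = rng.standard_normal(n)
    eps = rng.standard_normal((n, m))
    scores = (
        base[:, None]
        + frag_bias[:, None]
        + cfg.sigma * (np.sqrt(cfg.rho) * z[:, None] + np.sqrt(1 - cfg.rho) * eps)
    )
    structures = [f"S{j + 1}" for j in range(m)]
    frame = pd.DataFrame(scores, index=[r.compound_id for r in records], columns=structures)
    if cfg.dropout_rate > 0:
        frame = frame.mask(rng.random((n, m)) < cfg.dropout_rate)
    table = ScoreTable(frame)
    labeled = []
    for rec in records:
        row = table.frame.loc[rec.compound_id]
        labeled.append(
            CompoundRecord(
                compound_id=rec.compound_id,
                smiles=rec.smiles,
                pchembl_values=list(rec.pchembl_values),
                activity_label=int(rec.pchembl_values[0] > 8.0),
                docking_scores={s: float(v) for s, v in row.items() if not np.isnan(v)},
            )
        )
    labels = pd.Series(
        [r.activity_label for r in labeled],
        index=[r.compound_id for r in labeled],
        name="label",
    )
    return labeled, table, labels


# ---------------------------------------------------------------------------
# paired stereoisomer score libraries


@dataclass(frozen=True)
class StereoSimConfig:
    """Paired R/S docking-score simulation.

    ``delta`` is the mean score shift of the disadvantaged (S)
    configuration in score units (positive = weaker predicted binding);
    ``sigma_pair`` the SD of the per-pair shift. Defaults mirror a
    291-pair campaign with a ~0.26 score-unit penalty.
    """

    n_pairs: int = 291
    delta: float = 0.26
    sigma_pair: float = 0.65
    mu_R: float = -9.5
    sigma_R: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_pair < 0:
            raise ValueError("sigma_pair must be non-negative")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be positive")


def simulate_paired_libraries(cfg: StereoSimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Index-aligned (scores_R, scores_S) with scores_S = scores_R + d,
    d ~ Normal(delta, sigma_pair^2)."""
    rng = np.random.default_rng(cfg.seed)
    scores_R = rng.normal(cfg.mu_R, cfg.sigma_R, size=cfg.n_pairs)
    d = rng.normal(cfg.delta, cfg.sigma_pair, size=cfg.n_pairs)
    return scores_R, scores_R + d


# ---------------------------------------------------------------------------
# paired binary interaction matrices

DEFAULT_INTERACTION_COLUMNS: tuple[str, ...] = (
    "GLU99:hbond_acceptor",
    "LYS321:hbond_donor",
    "LEU283:hydrophobic",
    "ASN75:hbond_donor",
    "SER287:hbond_donor",
    "GLN457:hbond_donor",
    "PHE98:pi_stacking",
    "VAL157:hydrophobic",
)


def simulate_interaction_matrices(
    n_ligands: int,
    columns: tuple[str, ...] = DEFAULT_INTERACTION_COLUMNS,
    loss_profile: dict[str, float] | None = None,
    seed: int = 0,
    base_rate: float = 0.5,
):
    """Paired ligand x interaction matrices with per-column bit losses.

    The first (R-library) matrix has i.i.d. Bernoulli(``base_rate``)
    occupancy; the second (S-library) matrix is derived from it by
    independently zeroing each set bit of a column with that column's
    loss probability.
    """
    from .stereo import InteractionMatrix

    loss_profile = loss_profile or {}
    for col, p in loss_profile.items():
        if not 0 <= p <= 1:
            raise ValueError(f"loss probability for {col!r} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    base = (rng.random((n_ligands, len(columns))) < base_rate).astype(int)
    lost = np.zeros_like(base)
    for j, col in enumerate(columns):
        p = loss_profile.get(col, 0.0)
        if p > 0:
            lost[:, j] = (rng.random(n_ligands) < p) & (base[:, j] == 1)
    ids = [f"lig{i:04d}" for i in range(n_ligands)]
    frame_R = pd.DataFrame(base, index=ids, columns=list(columns))
    frame_S = pd.DataFrame(base - lost, index=ids, columns=list(columns))
    return InteractionMatrix(frame_R), InteractionMatrix(frame_S)
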