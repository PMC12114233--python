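"""Similarity-weighted docking-score calibration with exponent grid search.

A query compound's docking score DSj0 is corrected by the reference
compounds' ratio of experimental activity to docking score, weighted by
Tanimoto similarity raised to an exponent p:

    DSj = DSj0 * (1/w) * sum_i Sij^p * (dG_i / DS_i),   w = sum_i Sij^p

where dG_i is the i-th reference activity on the pChEMBL scale and DS_i
its docking score. High p concentrates the weight on the nearest
structural neighbours; the calibrated scores approximate pChEMBL values,
so actives end up *above* the classification cutoff (orientation flips
relative to raw docking scores).

The exponent is chosen by stratified k-fold cross-validation: each fold
acts as the query set once against the union of the others, a KDE
threshold is fitted per fold on the calibrated scores, and the p with the
best mean fold MCC wins (ties go to the smaller p). The final cutoff is
the mean of the fold thresholds at the winning p.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .data import DEFAULT_ACTIVITY_THRESHOLD, CompoundRecord, stratified_folds
from .kde_threshold import classify, find_threshold
from .metrics import ConfusionCounts, balanced_accuracy, mcc

logger = logging.getLogger(__name__)

DEFAULT_P_GRID = (4, 12, 20, 28, 36, 44, 52, 60)

FINGERPRINT_KINDS = ("maccs_keys", "morgan_circular", "path_based")

MORGAN_RADIUS = 2
MORGAN_NBITS = 2048
PATH_MAX_LENGTH = 7
PATH_NBITS = 2048


@dataclass(frozen=True)
class Fingerprint:
    """A fixed-length binary structural fingerprint."""

    kind: str
    bits: np.ndarray  # bool vector; 166 for maccs_keys, 2048 otherwise

    def __post_init__(self) -> None:
        expected = 166 if self.kind == "maccs_keys" else 2048
        if self.bits.shape != (expected,):
            raise ValueError(
                f"{self.kind} fingerprint must have {expected} bits, got {self.bits.shape}"
            )


def compute_fingerprint(smiles: str, kind: str) -> Fingerprint:
    """Fingerprint a molecule from SMILES.

    Kinds: ``maccs_keys`` (166 structural keys), ``morgan_circular``
    (radius 2, 2048 bits), ``path_based`` (paths up to 7 bonds, 2048
    bits). The molecule is canonicalized by the parser, so any SMILES
    spelling of the same molecule yields the same bits.
    """
    from rdkit import Chem
    from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

    if kind not in FINGERPRINT_KINDS:
        raise ValueError(f"unknown fingerprint kind {kind!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    if kind == "maccs_keys":
        fp = MACCSkeys.GenMACCSKeys(mol)
        bits = np.zeros(167, dtype=bool)
        bits[list(fp.GetOnBits())] = True
        bits = bits[1:]  # bit 0 of the RDKit vector is unused padding
    elif kind == "morgan_circular":
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=MORGAN_RADIUS, fpSize=MORGAN_NBITS
        )
        fp = gen.GetFingerprint(mol)
        bits = np.zeros(MORGAN_NBITS, dtype=bool)
        bits[list(fp.GetOnBits())] = True
    else:
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(
            maxPath=PATH_MAX_LENGTH, fpSize=PATH_NBITS
        )
        fp = gen.GetFingerprint(mol)
        bits = np.zeros(PATH_NBITS, dtype=bool)
        bits[list(fp.GetOnBits())] = True
    return Fingerprint(kind=kind, bits=bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |a AND b| / |a OR b|; two empty fingerprints give 0."""
    if a.kind != b.kind:
        raise ValueError(f"fingerprint kind mismatch: {a.kind} vs {b.kind}")
    inter = int(np.sum(a.bits & b.bits))
    union = int(np.sum(a.bits | b.bits))
    if union == 0:
        warnings.warn("both fingerprints empty; Tanimoto defined as 0", stacklevel=2)
        return 0.0
    return inter / union


@dataclass(frozen=True)
class SimilarityMatrix:
    """Query x reference Tanimoto similarities."""

    values: np.ndarray  # shape (n_query, n_reference), entries in [0, 1]
    query_ids: tuple[str, ...]
    reference_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        nq, nr = self.values.shape
        if nq != len(self.query_ids) or nr != len(self.reference_ids):
            raise ValueError("similarity matrix shape does not match id lists")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("similarities must lie in [0, 1]")


def similarity_matrix(
    query_fps: list[Fingerprint],
    reference_fps: list[Fingerprint],
    query_ids: list[str] | None = None,
    reference_ids: list[str] | None = None,
) -> SimilarityMatrix:
    """Pairwise Tanimoto matrix between two fingerprint lists (same kind)."""
    kinds = {fp.kind for fp in query_fps} | {fp.kind for fp in reference_fps}
    if len(kinds) != 1:
        raise ValueError(f"mixed fingerprint kinds: {sorted(kinds)}")
    Q = np.stack([fp.bits for fp in query_fps]).astype(np.int32)
    R = np.stack([fp.bits for fp in reference_fps]).astype(np.int32)
    inter = Q @ R.T
    union = Q.sum(axis=1)[:, None] + R.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore"):
        values = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    if query_ids is None:
        query_ids = [f"q{i}" for i in range(len(query_fps))]
    if reference_ids is None:
        reference_ids = [f"r{i}" for i in range(len(reference_fps))]
    return SimilarityMatrix(
        values=values, query_ids=tuple(query_ids), reference_ids=tuple(reference_ids)
    )


def calibrate_scores(
    query_scores,
    reference_scores,
    reference_activities,
    S: SimilarityMatrix | np.ndarray,
    p: int,
    return_flags: bool = False,
):
    """Similarity-weighted calibration of query docking scores.

    Parameters
    ----------
    query_scores : array, shape (n_query,)
        Raw docking scores DSj0.
    reference_scores : array, shape (n_ref,)
        Reference docking scores DS_i; must be nonzero (exclude upstream).
    reference_activities : array, shape (n_ref,)
        Reference activities dG_i on the pChEMBL scale.
    S : SimilarityMatrix or array, shape (n_query, n_ref)
    p : int
        Similarity exponent, >= 1.
    return_flags : bool
        Also return the boolean mask of queries left uncalibrated because
        every similarity weight underflowed to zero.
    """
    if p < 1:
        raise ValueError("exponent p must be >= 1")
    ds0 = np.asarray(query_scores, dtype=float)
    ds_ref = np.asarray(reference_scores, dtype=float)
    dg = np.asarray(reference_activities, dtype=float)
    values = S.values if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    if values.shape != (len(ds0), len(ds_ref)):
        raise ValueError(
            f"similarity matrix shape {values.shape} does not match "
            f"{len(ds0)} queries x {len(ds_ref)} references"
        )
    if len(dg) != len(ds_ref):
        raise ValueError("reference activities and scores must be index-aligned")
    if (ds_ref == 0).any():
        raise ValueError("reference docking scores of 0 must be excluded upstream")
    W = values**p
    omega = W.sum(axis=1)
    ratio = dg / ds_ref
    calibrated = np.empty_like(ds0)
    zero = omega == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} query compounds have zero total similarity weight; "
            "returned uncalibrated",
            stacklevel=2,
        )
    nz = ~zero
    calibrated[nz] = ds0[nz] * (W[nz] @ ratio) / omega[nz]
    calibrated[zero] = ds0[zero]
    if return_flags:
        return calibrated, zero
    return calibrated


@dataclass
class CalibrationConfig:
    """Settings for the cross-validated exponent search."""

    fingerprint_kind: str = "morgan_circular"
    p_grid: tuple[int, ...] = DEFAULT_P_GRID
    n_folds: int = 5
    seed: int = 0
    activity_threshold: float = DEFAULT_ACTIVITY_THRESHOLD

    def __post_init__(self) -> None:
        if self.fingerprint_kind not in FINGERPRINT_KINDS:
            raise ValueError(f"unknown fingerprint kind {self.fingerprint_kind!r}")
        if any(p < 1 for p in self.p_grid):
            raise ValueError("all grid exponents must be >= 1")


@dataclass
class CalibrationResult:
    """Outcome of the cross-validated exponent grid search."""

    per_p: pd.DataFrame  # columns: p, mean_mcc, mean_threshold
    fold_mccs: dict[int, list[float]]
    fold_thresholds: dict[int, list[float]]
    best_p: int
    final_threshold: float  # mean of fold thresholds at best_p
    calibrated_scores: pd.Series = field(default_factory=pd.Series)  # best_p, by id
    fold_assignments: dict[str, int] = field(default_factory=dict)


def _records_frame(records: list[CompoundRecord]) -> pd.DataFrame:
    columns = ["compound_id", "smiles", "score", "pchembl", "label"]
    if not records:
        return pd.DataFrame(columns=columns).set_index("compound_id")
    rows = []
    for rec in records:
        if rec.smiles is None:
            raise ValueError(f"compound {rec.compound_id} lacks a SMILES")
        if rec.activity_label is None:
            raise ValueError(f"compound {rec.compound_id} is unlabeled")
        if len(rec.docking_scores) != 1:
            raise ValueError(
                f"compound {rec.compound_id} must carry exactly one structure's score"
            )
        if len(rec.pchembl_values) != 1:
            raise ValueError(
                f"compound {rec.compound_id} must carry exactly one pChEMBL value"
            )
        rows.append(
            {
                "compound_id": rec.compound_id,
                "smiles": rec.smiles,
                "score": next(iter(rec.docking_scores.values())),
                "pchembl": rec.pchembl_values[0],
                "label": rec.activity_label,
            }
        )
    return pd.DataFrame(rows).set_index("compound_id")


def cross_validate_calibration(
    records: list[CompoundRecord],
    cfg: CalibrationConfig,
    p_grid: tuple[int, ...] | None = None,
) -> CalibrationResult:
    """Grid-search the similarity exponent under stratified k-fold CV.

    Each fold is calibrated once as the query set against the union of
    the remaining folds; a KDE threshold is fitted on the calibrated fold
    and its MCC recorded. Reference compounds with a docking score of 0
    are excluded (division by zero in the activity/score ratio).
    """
    frame = _records_frame(records)
    grid = tuple(p_grid) if p_grid is not None else cfg.p_grid
    n_zero = int((frame["score"] == 0).sum())
    if n_zero:
        logger.info("excluding %d compounds with docking score 0", n_zero)
        frame = frame[frame["score"] != 0]
    split = stratified_folds(frame["label"], k=cfg.n_folds, seed=cfg.seed)
    fps = {
        cid: compute_fingerprint(smi, cfg.fingerprint_kind)
        for cid, smi in frame["smiles"].items()
    }
    fold_mccs: dict[int, list[float]] = {p: [] for p in grid}
    fold_thresholds: dict[int, list[float]] = {p: [] for p in grid}
    calibrated_by_p: dict[int, list[pd.Series]] = {p: [] for p in grid}
    failed: set[int] = set()
    for fold in range(cfg.n_folds):
        q_ids = [cid for cid in frame.index if split.fold_assignments[cid] == fold]
        r_ids = [cid for cid in frame.index if split.fold_assignments[cid] != fold]
        S = similarity_matrix(
            [fps[c] for c in q_ids], [fps[c] for c in r_ids], q_ids, r_ids
        )
        q_scores = frame.loc[q_ids, "score"].to_numpy()
        q_labels = frame.loc[q_ids, "label"].to_numpy(dtype=int)
        r_scores = frame.loc[r_ids, "score"].to_numpy()
        r_dg = frame.loc[r_ids, "pchembl"].to_numpy()
        for p in grid:
            if p in failed:
                continue
            cal = calibrate_scores(q_scores, r_scores, r_dg, S, p)
            try:
                model = find_threshold(cal[q_labels == 1], cal[q_labels == 0])
            except ValueError as exc:
                logger.warning("p=%d failed on fold %d: %s", p, fold, exc)
                failed.add(p)
                continue
            pred = classify(cal, model)
            c = ConfusionCounts.from_predictions(q_labels, pred)
            fold_mccs[p].append(mcc(c))
            fold_thresholds[p].append(model.threshold)
            calibrated_by_p[p].append(pd.Series(cal, index=q_ids))
    per_p = pd.DataFrame(
        {
            "p": list(grid),
            "mean_mcc": [
                np.mean(fold_mccs[p]) if p not in failed and fold_mccs[p] else np.nan
                for p in grid
            ],
            "mean_threshold": [
                np.mean(fold_thresholds[p])
                if p not in failed and fold_thresholds[p]
                else np.nan
                for p in grid
            ],
        }
    )
    valid = per_p.dropna(subset=["mean_mcc"])
    if valid.empty:
        raise ValueError("threshold fitting failed for every grid exponent")
    best_mcc = valid["mean_mcc"].max()
    # tie on mean MCC -> smallest p (least similarity dependence)
    best_p = int(valid.loc[np.isclose(valid["mean_mcc"], best_mcc), "p"].min())
    final_threshold = float(np.mean(fold_thresholds[best_p]))
    calibrated = pd.concat(calibrated_by_p[best_p]).reindex(frame.index)
    return CalibrationResult(
        per_p=per_p,
        fold_mccs={p: fold_mccs[p] for p in grid},
        fold_thresholds={p: fold_thresholds[p] for p in grid},
        best_p=best_p,
        final_threshold=final_threshold,
        calibrated_scores=calibrated,
        fold_assignments=dict(split.fold_assignments),
    )


def apply_final_model(
    external_records: list[CompoundRecord],
    final_threshold: float,
    reference_records: list[CompoundRecord],
    kind: str,
    best_p: int,
) -> tuple[ConfusionCounts, dict[str, float]]:
    """Calibrate an external set against the full reference set and classify.

    Calibrated scores approximate pChEMBL values, so classification uses
    the higher-is-active orientation at the supplied mean-fold threshold.
    The external and reference id sets must be disjoint.
    """
    ext = _records_frame(external_records)
    ref = _records_frame(reference_records)
    if ext.empty:
        raise ValueError("external set is empty")
    overlap = set(ext.index) & set(ref.index)
    if overlap:
        raise ValueError(f"external and reference sets overlap: {sorted(overlap)[:5]}")
    ref = ref[ref["score"] != 0]
    ext_fps = [compute_fingerprint(s, kind) for s in ext["smiles"]]
    ref_fps = [compute_fingerprint(s, kind) for s in ref["smiles"]]
    S = similarity_matrix(ext_fps, ref_fps, list(ext.index), list(ref.index))
    cal = calibrate_scores(
        ext["score"].to_numpy(), ref["score"].to_numpy(), ref["pchembl"].to_numpy(), S, best_p
    )
    pred = (cal > final_threshold).astype(int)
    y = ext["label"].to_numpy(dtype=int)
    c = ConfusionCounts.from_predictions(y, pred)
    try:
        ba = balanced_accuracy(c)
    except ValueError:  # single-class external set
        ba = float("nan")
    return c, {"mcc": mcc(c), "ba": ba}


class SimilarityCalibrator(BaseEstimator, TransformerMixin):
    """Transformer mapping raw docking scores to similarity-calibrated scores.

    ``fit`` stores the reference set; ``transform`` calibrates queries
    against it. X is a DataFrame with columns ``smiles`` and ``score``
    (plus ``pchembl`` at fit time).
    """

    def __init__(self, fingerprint_kind: str = "morgan_circular", p: int = 12):
        self.fingerprint_kind = fingerprint_kind
        self.p = p

    def fit(self, X: pd.DataFrame, y=None):
        for col in ("smiles", "score", "pchembl"):
            if col not in X.columns:
                raise ValueError(f"fit requires column {col!r}")
        ref = X[X["score"] != 0]
        self.reference_fps_ = [
            compute_fingerprint(s, self.fingerprint_kind) for s in ref["smiles"]
        ]
        self.reference_scores_ = ref["score"].to_numpy(dtype=float)
        self.reference_activities_ = ref["pchembl"].to_numpy(dtype=float)
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "reference_fps_")
        fps = [compute_fingerprint(s, self.fingerprint_kind) for s in X["smiles"]]
        S = similarity_matrix(fps, self.reference_fps_)
        cal = calibrate_scores(
            X["score"].to_numpy(dtype=float),
            self.reference_scores_,
            self.reference_activities_,
            S,
            self.p,
        )
        return cal.reshape(-1, 1)


class SimilarityCalibratedClassifier(BaseEstimator, ClassifierMixin):
    """Classifier running the full CV exponent search in ``fit``.

    X is a DataFrame with columns ``smiles``, ``score``, ``pchembl``; y
    holds binary activity labels (derived from pchembl at the activity
    threshold when omitted). After fitting, ``predict`` calibrates new
    compounds against the whole training set at the selected exponent and
    thresholds them at the mean fold cutoff.
    """

    def __init__(
        self,
        fingerprint_kind: str = "morgan_circular",
        p_grid: tuple[int, ...] = DEFAULT_P_GRID,
        n_folds: int = 5,
        seed: int = 0,
        activity_threshold: float = DEFAULT_ACTIVITY_THRESHOLD,
    ):
        self.fingerprint_kind = fingerprint_kind
        self.p_grid = p_grid
        self.n_folds = n_folds
        self.seed = seed
        self.activity_threshold = activity_threshold

    def _to_records(self, X: pd.DataFrame, y) -> list[CompoundRecord]:
        ids = [str(i) for i in X.index]
        return [
            CompoundRecord(
                compound_id=cid,
                smiles=row["smiles"],
                pchembl_values=[float(row["pchembl"])],
                activity_label=int(lab),
                docking_scores={"structure": float(row["score"])},
            )
            for cid, (_, row), lab in zip(ids, X.iterrows(), y)
        ]

    def fit(self, X: pd.DataFrame, y=None):
        if y is None:
            y = (X["pchembl"] > self.activity_threshold).astype(int).to_numpy()
        y = np.asarray(y, dtype=int)
        cfg = CalibrationConfig(
            fingerprint_kind=self.fingerprint_kind,
            p_grid=tuple(self.p_grid),
            n_folds=self.n_folds,
            seed=self.seed,
            activity_threshold=self.activity_threshold,
        )
        records = self._to_records(X, y)
        self.cv_result_ = cross_validate_calibration(records, cfg)
        self.best_p_ = self.cv_result_.best_p
        self.final_threshold_ = self.cv_result_.final_threshold
        self.classes_ = np.array([0, 1])
        ref = X[X["score"] != 0]
        self.reference_ = self._to_records(ref, y[(X["score"] != 0).to_numpy()])
        self._calibrator = SimilarityCalibrator(
            fingerprint_kind=self.fingerprint_kind, p=self.best_p_
        )
        self._calibrator.fit(ref)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "final_threshold_")
        cal = self._calibrator.transform(X)[:, 0]
        return (cal > self.final_threshold_).astype(int)
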