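"""MHC-I binding affinity scoring.

The screen design needs a predicted IC50 (nM) for every candidate peptide.
In production this comes from an external predictor (e.g. NetMHCpan run on
H-2Kb); this module reads such tables, and also bundles a seeded
position-weight-matrix *toy* model so the whole pipeline can run offline.
The toy model is a test double, not a scientific predictor.

The binder definition used throughout the package is the conventional
strict cut: predicted IC50 < 500 nM.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 20 canonical amino-acid residues, alphabetical.
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_RESIDUE_INDEX = {aa: i for i, aa in enumerate(CANONICAL_RESIDUES)}

#: Conventional MHC-I binder threshold (predicted IC50, nM).
DEFAULT_BINDER_THRESHOLD_NM = 500.0


class PredictionFormatError(ValueError):
    """A prediction table is missing required columns."""


class PredictionRecordError(ValueError):
    """A single prediction row is invalid (e.g. non-positive IC50)."""


def is_canonical(peptide: str) -> bool:
    """True iff ``peptide`` is non-empty and uses only the 20 canonical residues."""
    return bool(peptide) and all(aa in _RESIDUE_INDEX for aa in peptide)


@dataclass(frozen=True)
class AffinityPrediction:
    """A predicted binding affinity for one peptide on one MHC allele.

    Parameters
    ----------
    peptide : str
        Amino-acid sequence (canonical residues only).
    ic50 : float
        Predicted half-maximal inhibitory concentration in nM; lower means
        stronger binding. Must be positive.
    allele : str
        MHC allele label, e.g. ``"H-2Kb"``.
    """

    peptide: str
    ic50: float
    allele: str = "H-2Kb"

    def __post_init__(self) -> None:
        if not is_canonical(self.peptide):
            raise PredictionRecordError(
                f"peptide {self.peptide!r} contains non-canonical residues"
            )
        if not self.ic50 > 0:
            raise PredictionRecordError(
                f"ic50 must be positive, got {self.ic50!r} for {self.peptide}"
            )


@dataclass(frozen=True)
class AffinityModel:
    """Position-weight-matrix affinity model for fixed-length peptides.

    ``weights[i, j]`` is the score contribution of residue
    ``CANONICAL_RESIDUES[j]`` at peptide position ``i`` (0-based).  The
    summed score is mapped to an IC50 through ``calibration``, which must be
    strictly monotone (the bundled default is strictly decreasing, so higher
    score means stronger binding).
    """

    allele: str
    weights: np.ndarray  # shape (k, 20)
    calibration: Callable[[float], float] = field(
        default=lambda s: 50_000.0 * math.exp(-s)
    )

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != len(CANONICAL_RESIDUES):
            raise ValueError(
                f"weights must have shape (k, 20), got {w.shape}"
            )
        object.__setattr__(self, "weights", w)

    @property
    def k(self) -> int:
        """Peptide length the model scores."""
        return self.weights.shape[0]

    def score(self, peptide: str) -> float:
        """Summed per-position weight of ``peptide`` (no calibration)."""
        _check_peptide(peptide, self.k)
        return float(
            self.weights[np.arange(self.k), [_RESIDUE_INDEX[aa] for aa in peptide]].sum()
        )


def _check_peptide(peptide: str, k: int) -> None:
    if len(peptide) != k:
        raise ValueError(f"peptide {peptide!r} has length {len(peptide)}, model expects {k}")
    if not is_canonical(peptide):
        raise ValueError(f"peptide {peptide!r} contains non-canonical residues")


def predict_ic50(peptide: str, model: AffinityModel) -> float:
    """Predicted IC50 (nM) of ``peptide`` under a position-weight model.

    Deterministic: ``calibration`` applied to the summed per-position
    weights of the peptide's residues.
    """
    return float(model.calibration(model.score(peptide)))


def predict_ic50_many(peptides: Sequence[str], model: AffinityModel) -> pd.Series:
    """Vectorised :func:`predict_ic50` over many peptides.

    Returns a Series indexed by peptide. All peptides must have the model
    length and canonical residues.
    """
    peptides = list(peptides)
    if not peptides:
        return pd.Series(dtype=float)
    for p in peptides:
        _check_peptide(p, model.k)
    idx = np.array(
        [[_RESIDUE_INDEX[aa] for aa in p] for p in peptides], dtype=np.intp
    )
    scores = model.weights[np.arange(model.k)[None, :], idx].sum(axis=1)
    return pd.Series(
        [float(model.calibration(s)) for s in scores], index=peptides, dtype=float
    )


def toy_model(seed: int = 0, k: int = 8, allele: str = "H-2Kb") -> AffinityModel:
    """Bundled seeded toy affinity model (a test double).

    Weights are drawn i.i.d. Normal(0.6, 0.5) so that a random peptide's
    summed score is roughly Normal(0.6*k, 0.25*k); with the default
    calibration ``ic50 = 50000 * exp(-score)`` about half of random 8-mers
    fall under the 500 nM binder cut, which keeps synthetic design runs
    well supplied with binders. Not a scientific predictor.
    """
    rng = np.random.default_rng(seed)
    weights = rng.normal(0.6, 0.5, size=(k, len(CANONICAL_RESIDUES)))
    return AffinityModel(allele=allele, weights=weights)


def is_binder(
    prediction: AffinityPrediction | float,
    threshold: float = DEFAULT_BINDER_THRESHOLD_NM,
) -> bool:
    """True iff predicted IC50 is strictly below ``threshold`` (nM)."""
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    ic50 = prediction.ic50 if isinstance(prediction, AffinityPrediction) else float(prediction)
    return ic50 < threshold


def load_prediction_table(
    path: str | Path,
    *,
    peptide_col: str = "peptide",
    allele_col: str = "allele",
    ic50_col: str = "ic50_nM",
    sep: str = "\t",
    strict: bool = False,
) -> list[AffinityPrediction]:
    """Read a peptide -> IC50 prediction table.

    Duplicate (peptide, allele) rows are resolved by keeping the minimum
    IC50 (the most optimistic binding call). Invalid rows (non-positive
    IC50, non-canonical peptide) raise when ``strict`` is set, otherwise
    they are skipped with a logged reason.
    """
    try:
        frame = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        logger.warning("prediction table %s is empty", path)
        return []
    missing = {peptide_col, allele_col, ic50_col} - set(frame.columns)
    if missing:
        raise PredictionFormatError(
            f"prediction table {path} is missing columns: {sorted(missing)}"
        )
    best: dict[tuple[str, str], AffinityPrediction] = {}
    for peptide, allele, ic50 in zip(
        frame[peptide_col], frame[allele_col], frame[ic50_col]
    ):
        peptide, allele = str(peptide), str(allele)
        try:
            pred = AffinityPrediction(peptide=peptide, ic50=float(ic50), allele=allele)
        except (PredictionRecordError, ValueError) as exc:
            if strict:
                raise
            logger.warning("skipping prediction row (%s, %s): %s", peptide, allele, exc)
            continue
        key = (pred.peptide, pred.allele)
        if key not in best or pred.ic50 < best[key].ic50:
            best[key] = pred
    if not best:
        logger.warning("prediction table %s yielded no usable predictions", path)
    return list(best.values())


def write_prediction_table(
    predictions: Iterable[AffinityPrediction], path: str | Path
) -> None:
    """Write predictions as the package's canonical TSV (peptide/allele/ic50_nM)."""
    frame = pd.DataFrame(
        [(p.peptide, p.allele, p.ic50) for p in predictions],
        columns=["peptide", "allele", "ic50_nM"],
    )
    frame.to_csv(path, sep="\t", index=False)


def load_netmhcpan_table(path: str | Path) -> list[AffinityPrediction]:
    """Adapter for NetMHCpan v4 long-format output.

    Columns are located by header name (``Peptide``, an allele column named
    ``MHC``/``HLA``/``Allele`` and an affinity column named ``Aff(nM)`` or
    ``ic50``), never by position. Whitespace-delimited.
    """
    frame = pd.read_csv(path, sep=r"\s+", engine="python")
    cols = {c.lower(): c for c in frame.columns}

    def pick(*names: str) -> str | None:
        for n in names:
            if n.lower() in cols:
                return cols[n.lower()]
        return None

    pep = pick("Peptide")
    allele = pick("MHC", "HLA", "Allele")
    aff = pick("Aff(nM)", "Affinity(nM)", "ic50", "ic50_nM")
    if pep is None or allele is None or aff is None:
        raise PredictionFormatError(
            f"could not locate peptide/allele/affinity columns in {path}; "
            f"found {list(frame.columns)}"
        )
    best: dict[tuple[str, str], AffinityPrediction] = {}
    for peptide, mhc, ic50 in zip(frame[pep], frame[allele], frame[aff]):
        try:
            pred = AffinityPrediction(
                peptide=str(peptide), ic50=float(ic50), allele=str(mhc)
            )
        except (PredictionRecordError, ValueError) as exc:
            logger.warning("skipping NetMHCpan row: %s", exc)
            continue
        key = (pred.peptide, pred.allele)
        if key not in best or pred.ic50 < best[key].ic50:
            best[key] = pred
    return list(best.values())


def predictions_to_ic50(
    predictions: Iterable[AffinityPrediction],
) -> Mapping[str, float]:
    """Collapse predictions to a peptide -> IC50 mapping (minimum over alleles)."""
    out: dict[str, float] = {}
    for p in predictions:
        if p.peptide not in out or p.ic50 < out[p.peptide]:
            out[p.peptide] = p.ic50
    return out
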