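"""Two-colour mixture analysis: clonal-fraction depletion thresholds.

The experiment mixes eGFP-marked cells presenting a candidate immunogenic
antigen with mCherry-marked non-immunogenic cells at defined ratios
(50/10/1/0.1% eGFP), grows tumors in immunocompetent mice, and reads the
colour ratio back by flow cytometry. Within each intended-fraction group,
the per-tumor fold change

    FC = (eGFP% in tumor, normalised so eGFP + mCherry = 100) / (eGFP% at day 0)

is tested against no change on the log10 scale with a one-sample t-test.
Fully rejected tumors (no tumor cells recovered) are excluded from the
test but reported. The antigen-specific detection threshold is the
smallest fraction whose group shows significant depletion with every
larger fraction also significant (a monotone detection frontier).

Also provides the caliper tumor-volume utility (modified ellipsoid,
V = L x W^2 x 0.52).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Significance level mirroring the four-star reporting convention (p < 0.001).
DEFAULT_ALPHA = 0.001

MIXTURE_COLUMNS = (
    "antigen", "mouse", "fraction_d0_pct", "egfp_d0", "mcherry_d0",
    "egfp_tumor", "mcherry_tumor", "rejected",
)


class ClonalFractionError(ValueError):
    pass


class RejectedTumorError(ClonalFractionError):
    """No tumor cells of either colour were recovered."""


def normalize_two_color(egfp_pct: float, mcherry_pct: float) -> tuple[float, float]:
    """Rescale the two colour percentages to sum to 100.

    Non-fluorescent events (host infiltrate) are ignored by construction.
    Raises :class:`RejectedTumorError` when both are zero (the tumor is
    flagged rejected, not normalised).
    """
    if egfp_pct < 0 or mcherry_pct < 0:
        raise ClonalFractionError("percentages must be non-negative")
    total = egfp_pct + mcherry_pct
    if total == 0:
        raise RejectedTumorError("no fluorescent tumor cells recovered")
    return 100.0 * egfp_pct / total, 100.0 * mcherry_pct / total


@dataclass(frozen=True)
class FoldChange:
    fc: float
    log10_fc: float


def fold_change(egfp_norm_tumor_pct: float, egfp_pct_d0: float) -> FoldChange:
    """Fold change of the eGFP (antigen-bearing) compartment.

    (normalised eGFP% in tumor) / (eGFP% at day 0), with its log10.
    """
    if egfp_pct_d0 <= 0:
        raise ClonalFractionError("day-0 eGFP percentage must be positive")
    if egfp_norm_tumor_pct < 0:
        raise ClonalFractionError("tumor eGFP percentage must be non-negative")
    fc = egfp_norm_tumor_pct / egfp_pct_d0
    return FoldChange(fc=fc, log10_fc=float(np.log10(fc)) if fc > 0 else -np.inf)


@dataclass(frozen=True)
class DepletionTest:
    """One-sample t-test of per-tumor log10 fold changes against 0.

    ``significant`` is True when depletion is detected: p < alpha with a
    negative mean (the default alternative "less" makes the direction part
    of the test). With zero variance no t-statistic exists and the report
    falls back to the sign of the common value (``method="sign"``).
    """

    fraction_pct: float | None
    log10_fcs: tuple[float, ...]
    mean_log10_fc: float
    t: float
    p: float
    n: int
    n_rejected: int
    significant: bool
    alpha: float
    alternative: str = "less"
    method: str = "t"


def test_depletion(
    log10_fcs: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
    fraction_pct: float | None = None,
    n_rejected: int = 0,
    alternative: str = "less",
) -> DepletionTest:
    """Test a group of per-tumor log10 fold changes for depletion.

    The null is mean log10 FC = 0; the default alternative is one-sided
    depletion (mean < 0), the conventional directional choice for a
    drop-out readout. ``alternative="two-sided"`` is available and then a
    negative-mean direction guard is applied so enrichment is never
    labelled depletion. Requires n >= 2; warns below n = 3 (the reporting
    standard of the source experiments).
    """
    x = np.asarray(list(log10_fcs), dtype=float)
    n = x.size
    if n < 2:
        raise ClonalFractionError("need at least 2 analyzable tumors for a t-test")
    if n < 3:
        warnings.warn("fewer than 3 analyzable tumors; test is underpowered")
    mean = float(x.mean())
    if np.ptp(x) == 0.0:
        # zero variance: no t-statistic; report by sign
        return DepletionTest(
            fraction_pct=fraction_pct,
            log10_fcs=tuple(x),
            mean_log10_fc=mean,
            t=float("nan"),
            p=float("nan"),
            n=n,
            n_rejected=n_rejected,
            significant=mean < 0,
            alpha=alpha,
            alternative=alternative,
            method="sign",
        )
    res = stats.ttest_1samp(x, 0.0, alternative=alternative)
    significant = bool(res.pvalue < alpha and mean < 0)
    return DepletionTest(
        fraction_pct=fraction_pct,
        log10_fcs=tuple(x),
        mean_log10_fc=mean,
        t=float(res.statistic),
        p=float(res.pvalue),
        n=n,
        n_rejected=n_rejected,
        significant=significant,
        alpha=alpha,
        alternative=alternative,
    )


@dataclass
class MixtureExperiment:
    """Per-mouse two-colour observations for one antigen.

    ``records`` columns: mouse, fraction_d0_pct (intended eGFP fraction),
    egfp_d0, mcherry_d0, egfp_tumor, mcherry_tumor, rejected.
    """

    antigen: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(MIXTURE_COLUMNS[1:]) - set(self.records.columns)
        if missing:
            raise ClonalFractionError(f"mixture records missing columns: {sorted(missing)}")
        pct_cols = ["fraction_d0_pct", "egfp_d0", "mcherry_d0", "egfp_tumor", "mcherry_tumor"]
        if (self.records[pct_cols] < 0).any().any():
            raise ClonalFractionError("percentages must be non-negative")

    @classmethod
    def from_tsv(cls, path: str | Path, antigen: str | None = None) -> list["MixtureExperiment"]:
        frame = pd.read_csv(path, sep="\t")
        missing = set(MIXTURE_COLUMNS) - set(frame.columns)
        if missing:
            raise ClonalFractionError(f"{path} missing columns: {sorted(missing)}")
        out = []
        for name, grp in frame.groupby("antigen"):
            if antigen is None or name == antigen:
                out.append(cls(antigen=str(name), records=grp.reset_index(drop=True)))
        return out

    def log10_fold_changes(self) -> pd.DataFrame:
        """Per analyzable tumor: normalised tumor eGFP%, FC and log10 FC.

        Tumors flagged rejected, or with no fluorescent cells recovered,
        are excluded (reported via ``n_rejected`` downstream).
        """
        rows = []
        for row in self.records.itertuples(index=False):
            rejected = bool(row.rejected)
            if not rejected:
                try:
                    egfp_norm, _ = normalize_two_color(row.egfp_tumor, row.mcherry_tumor)
                except RejectedTumorError:
                    rejected = True
            if rejected:
                rows.append((row.mouse, row.fraction_d0_pct, np.nan, np.nan, np.nan, True))
                continue
            fc = fold_change(egfp_norm, row.egfp_d0)
            rows.append(
                (row.mouse, row.fraction_d0_pct, egfp_norm, fc.fc, fc.log10_fc, False)
            )
        return pd.DataFrame(
            rows,
            columns=["mouse", "fraction_d0_pct", "egfp_norm_tumor", "fc", "log10_fc", "rejected"],
        )


@dataclass(frozen=True)
class DetectionResult:
    """Outcome of detect_threshold for one antigen."""

    antigen: str
    threshold_pct: float | None  # smallest fraction with (frontier) detection
    tests: tuple[DepletionTest, ...]  # one per analyzable fraction group, descending
    n_rejected_total: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (t.fraction_pct, t.n, t.n_rejected, t.mean_log10_fc, t.t, t.p, t.significant)
                for t in self.tests
            ],
            columns=["fraction_pct", "n", "n_rejected", "mean_log10fc", "t", "p", "significant"],
        )


def detect_threshold(
    experiment: MixtureExperiment,
    alpha: float = DEFAULT_ALPHA,
    frontier: bool = True,
    min_n: int = 2,
    alternative: str = "less",
) -> DetectionResult:
    """Smallest mixture fraction at which depletion is detected.

    Groups tumors by intended day-0 fraction, excludes rejected tumors,
    tests each group with >= ``min_n`` analyzable tumors, and returns the
    minimal significant fraction. With ``frontier`` (default) the
    threshold is the smallest fraction such that it and every larger
    tested fraction are significant — the detection-limit reading. Without
    it, the smallest significant fraction regardless of larger groups.
    """
    fcs = experiment.log10_fold_changes()
    tests: list[DepletionTest] = []
    skipped = 0
    for frac, grp in fcs.groupby("fraction_d0_pct"):
        ok = grp[~grp["rejected"]]
        n_rej = int(grp["rejected"].sum())
        if len(ok) < min_n:
            logger.warning(
                "fraction group %s%% has %d analyzable tumors (<%d); skipped",
                frac, len(ok), min_n,
            )
            skipped += 1
            continue
        tests.append(
            test_depletion(
                ok["log10_fc"].tolist(),
                alpha=alpha,
                fraction_pct=float(frac),
                n_rejected=n_rej,
                alternative=alternative,
            )
        )
    if not tests:
        raise ClonalFractionError("no fraction group has enough analyzable tumors")
    tests.sort(key=lambda t: -t.fraction_pct)
    threshold: float | None = None
    if frontier:
        for t in tests:
            if t.significant:
                threshold = t.fraction_pct
            else:
                break
    else:
        sig = [t.fraction_pct for t in tests if t.significant]
        threshold = min(sig) if sig else None
    return DetectionResult(
        antigen=experiment.antigen,
        threshold_pct=threshold,
        tests=tuple(tests),
        n_rejected_total=int(fcs["rejected"].sum()),
    )


@dataclass(frozen=True)
class CaliperMeasurement:
    """Tumor caliper measurement: longest diameter L and width W, in mm."""

    L: float
    W: float

    def __post_init__(self) -> None:
        if not (self.W > 0 and self.L > 0):
            raise ClonalFractionError("L and W must be positive")


def tumor_volume(L: float | CaliperMeasurement, W: float | None = None) -> float:
    """Modified-ellipsoid caliper volume: V = L x W^2 x 0.52 (mm^3).

    If W > L the inputs are swapped with a warning (L is by definition the
    longest diameter).
    """
    if isinstance(L, CaliperMeasurement):
        L, W = L.L, L.W
    if W is None:
        raise ClonalFractionError("W is required")
    if not (L > 0 and W > 0):
        raise ClonalFractionError("L and W must be positive")
    if W > L:
        warnings.warn("W > L; swapping (L is the longest diameter)")
        L, W = W, L
    return L * W * W * 0.52


def write_depletion_tsv(results: Sequence[DetectionResult], path: str | Path) -> None:
    frames = []
    for r in results:
        s = r.summary()
        s.insert(0, "antigen", r.antigen)
        frames.append(s)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
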