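"""Screen deconvolution: reads -> counts -> abundances -> depletion calls.

Minigene amplicon reads are assigned to library members by exact or
one-mismatch matching over the epitope window (the peptide-as-barcode
property makes a general-purpose aligner unnecessary; anchored Hamming
matching is auditable and deterministic). Counts are normalised to
relative abundances, representation QC enforces the coverage rule used
during cloning (>= 1000x transformants per library member), and pretumor
vs tumor samples are compared per minigene: log2 fold change with a
scale-aware pseudocount, a LOESS trend of post vs pre abundance in log10
space, and a depletion call guarded by a pre-abundance floor so that
stochastic drop-out of rare clones (below ~1/10,000) is not mistaken for
immune depletion.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

#: Pre-abundance floor below which depletion is not called (the stochastic
#: drop-out regime: clones rarer than 1/10,000 at injection drop out by
#: sampling alone).
DEFAULT_ABUNDANCE_FLOOR = 1e-4

#: Depletion/enrichment call threshold on log2 fold change (2-fold).
DEFAULT_LFC_THRESHOLD = 1.0

DEFAULT_LOESS_SPAN = 0.5

DEFAULT_MIN_FOLD_REPRESENTATION = 1000


class DeconvolutionError(ValueError):
    pass


@dataclass
class CountTable:
    """Per-minigene read counts for one sample.

    ``unmapped`` counts reads matching no reference within the mismatch
    budget; ``ambiguous`` counts reads equidistant from two or more
    references (discarded). mapped + unmapped + ambiguous = total reads.
    """

    sample: str
    counts: pd.Series  # index: minigene key (peptide), values: int
    unmapped: int = 0
    ambiguous: int = 0

    def __post_init__(self) -> None:
        self.counts = pd.Series(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise DeconvolutionError("counts must be non-negative")

    @property
    def total_mapped(self) -> int:
        return int(self.counts.sum())

    @property
    def total_reads(self) -> int:
        return self.total_mapped + self.unmapped + self.ambiguous


@dataclass
class AbundanceTable:
    """Per-minigene relative abundance (fraction of mapped reads)."""

    sample: str
    abundance: pd.Series
    total_mapped: int | None = None

    def __post_init__(self) -> None:
        self.abundance = pd.Series(self.abundance, dtype=float)
        if (self.abundance < 0).any():
            raise DeconvolutionError("abundances must be non-negative")
        total = float(self.abundance.sum())
        if abs(total - 1.0) > 1e-9:
            raise DeconvolutionError(
                f"abundances must sum to 1 (got {total:.12f}) in sample {self.sample}"
            )


def _iter_fastq_seqs(path: str | Path) -> Iterable[str]:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "rt") as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                yield line.strip().upper()


_BASES = "ACGT"


def count_minigenes(
    reads: str | Path | Iterable[str],
    reference: Mapping[str, str],
    max_mismatch: int = 1,
    offset: int = 0,
    sample: str = "sample",
) -> CountTable:
    """Assign reads to minigenes by (near-)exact epitope-window matching.

    ``reference`` maps minigene key -> epitope DNA (unique). Each read's
    window ``read[offset:offset+L]`` is compared against every reference of
    length L; a read is counted for the unique reference at minimal
    Hamming distance <= ``max_mismatch`` and discarded as ambiguous when
    two or more references tie at the best distance. Implemented with
    exact-match dictionaries (references plus, for max_mismatch=1, all
    single-substitution neighbours), so counting is deterministic and
    linear in the number of reads.
    """
    if not reference:
        raise DeconvolutionError("reference is empty")
    if max_mismatch not in (0, 1):
        raise DeconvolutionError("max_mismatch must be 0 or 1")
    encodings = list(reference.values())
    if len(set(encodings)) != len(encodings):
        raise DeconvolutionError("reference encodings are not unique")

    exact: dict[str, str] = {dna.upper(): key for key, dna in reference.items()}
    lengths = sorted({len(dna) for dna in exact})
    neighbour: dict[str, set[str]] = {}
    if max_mismatch == 1:
        for dna, key in exact.items():
            for i, base in enumerate(dna):
                for alt in _BASES:
                    if alt != base:
                        n = dna[:i] + alt + dna[i + 1 :]
                        neighbour.setdefault(n, set()).add(key)

    if isinstance(reads, (str, Path)):
        seqs: Iterable[str] = _iter_fastq_seqs(reads)
    else:
        seqs = (s.upper() for s in reads)

    counts = {key: 0 for key in reference}
    unmapped = 0
    ambiguous = 0
    n_reads = 0
    for seq in seqs:
        n_reads += 1
        hits_exact: list[str] = []
        hits_one: set[str] = set()
        for L in lengths:
            window = seq[offset : offset + L]
            if len(window) < L:
                continue
            key = exact.get(window)
            if key is not None:
                hits_exact.append(key)
            elif max_mismatch == 1:
                hits_one |= neighbour.get(window, set())
        if len(hits_exact) == 1:
            counts[hits_exact[0]] += 1
        elif len(hits_exact) > 1:
            ambiguous += 1  # only possible across different window lengths
        elif len(hits_one) == 1:
            counts[hits_one.pop()] += 1
        elif len(hits_one) > 1:
            ambiguous += 1
        else:
            unmapped += 1
    if n_reads == 0:
        logger.warning("no reads in input; returning all-zero count table")
    return CountTable(
        sample=sample,
        counts=pd.Series(counts, dtype=np.int64),
        unmapped=unmapped,
        ambiguous=ambiguous,
    )


def brute_force_count(
    reads: Iterable[str],
    reference: Mapping[str, str],
    max_mismatch: int = 1,
    offset: int = 0,
    sample: str = "sample",
) -> CountTable:
    """All-pairs Hamming-scan counter (independent oracle for tests).

    Quadratic; intended for pools of <= ~100 references.
    """
    counts = {key: 0 for key in reference}
    unmapped = 0
    ambiguous = 0
    items = [(key, dna.upper()) for key, dna in reference.items()]
    for seq in reads:
        seq = seq.upper()
        best: list[str] = []
        best_d = max_mismatch + 1
        for key, dna in items:
            window = seq[offset : offset + len(dna)]
            if len(window) < len(dna):
                continue
            d = sum(a != b for a, b in zip(window, dna))
            if d < best_d:
                best, best_d = [key], d
            elif d == best_d:
                best.append(key)
        if best_d > max_mismatch or not best:
            unmapped += 1
        elif len(best) == 1:
            counts[best[0]] += 1
        else:
            ambiguous += 1
    return CountTable(
        sample=sample,
        counts=pd.Series(counts, dtype=np.int64),
        unmapped=unmapped,
        ambiguous=ambiguous,
    )


def relative_abundance(table: CountTable) -> AbundanceTable:
    """Counts divided by total mapped reads for the sample."""
    total = table.total_mapped
    if total <= 0:
        raise DeconvolutionError(
            f"sample {table.sample} has zero mapped reads; cannot normalise"
        )
    return AbundanceTable(
        sample=table.sample,
        abundance=table.counts / total,
        total_mapped=total,
    )


@dataclass(frozen=True)
class RepresentationQC:
    """Coverage check: observed transformants/cells vs required minimum."""

    n_observed: int
    library_size: int
    min_fold: int
    required: int
    passed: bool


def qc_representation(
    n_observed: int,
    library_size: int,
    min_fold: int = DEFAULT_MIN_FOLD_REPRESENTATION,
) -> RepresentationQC:
    """Require at least ``min_fold`` x library members (e.g. >=5e6 colonies
    for a 5000-member library at 1000x)."""
    if library_size < 1 or min_fold < 1:
        raise DeconvolutionError("library_size and min_fold must be >= 1")
    required = min_fold * library_size
    return RepresentationQC(
        n_observed=int(n_observed),
        library_size=int(library_size),
        min_fold=int(min_fold),
        required=required,
        passed=n_observed >= required,
    )


@dataclass(frozen=True)
class CellsEstimate:
    cells: float
    cells_rounded: int


def estimate_cells_at_injection(abundance: float, inoculum: int) -> CellsEstimate:
    """Absolute cells carrying a minigene at injection: abundance x inoculum."""
    if not 0 <= abundance <= 1:
        raise DeconvolutionError("abundance must be a fraction in [0, 1]")
    if inoculum <= 0:
        raise DeconvolutionError("inoculum must be positive")
    cells = abundance * inoculum
    return CellsEstimate(cells=cells, cells_rounded=int(round(cells)))


@dataclass
class ScreenComparison:
    """Per-minigene pre/post comparison.

    ``table`` columns: pre, post (replicate-mean abundances), lfc (log2
    fold change with pseudocount), fitted (LOESS-expected log10 post),
    residual (observed log10 post - fitted), call (depleted / neutral /
    enriched).
    """

    table: pd.DataFrame
    pseudocount: float
    span: float
    lfc_threshold: float
    floor: float
    per_animal: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def depleted(self) -> pd.Index:
        return self.table.index[self.table["call"] == "depleted"]

    @property
    def enriched(self) -> pd.Index:
        return self.table.index[self.table["call"] == "enriched"]


def _mean_abundance(tables: Sequence[AbundanceTable]) -> pd.Series:
    frames = [t.abundance for t in tables]
    idx = frames[0].index
    for f in frames[1:]:
        if set(f.index) != set(idx):
            raise DeconvolutionError("abundance tables cover different libraries")
    return pd.concat([f.reindex(idx) for f in frames], axis=1).mean(axis=1)


def _default_pseudocount(tables: Sequence[AbundanceTable]) -> float:
    totals = [t.total_mapped for t in tables if t.total_mapped]
    if totals:
        return 1.0 / (2.0 * max(totals))
    logger.warning(
        "no read totals available; using fallback pseudocount 1e-7 "
        "(pass pseudocount= explicitly to control this)"
    )
    return 1e-7


def _compare(
    pre_mean: pd.Series,
    post_mean: pd.Series,
    eps: float,
    span: float,
    lfc_threshold: float,
    floor: float,
) -> pd.DataFrame:
    lfc = np.log2((post_mean + eps) / (pre_mean + eps))
    x = np.log10(pre_mean + eps)
    y = np.log10(post_mean + eps)
    if len(pre_mean) >= 5:
        with np.errstate(invalid="ignore", divide="ignore"):
            fitted = pd.Series(
                lowess(y.values, x.values, frac=span, return_sorted=False),
                index=pre_mean.index,
            )
        # degenerate neighbourhoods (e.g. many identical abundances) can
        # yield NaN locally; fall back to the y = x expectation there
        fitted = fitted.where(np.isfinite(fitted), x)
    else:  # too few points for a meaningful local fit: expect y = x
        fitted = x
    residual = y - fitted
    call = pd.Series("neutral", index=pre_mean.index)
    eligible = pre_mean >= floor
    call[eligible & (lfc <= -lfc_threshold)] = "depleted"
    call[eligible & (lfc >= lfc_threshold)] = "enriched"
    return pd.DataFrame(
        {
            "pre": pre_mean,
            "post": post_mean,
            "lfc": lfc,
            "fitted": fitted,
            "residual": residual,
            "call": call,
        }
    )


def compare_screens(
    pre: Sequence[AbundanceTable] | AbundanceTable,
    post: Sequence[AbundanceTable] | AbundanceTable,
    pseudocount: float | None = None,
    span: float = DEFAULT_LOESS_SPAN,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    floor: float = DEFAULT_ABUNDANCE_FLOOR,
    per_animal: bool = False,
) -> ScreenComparison:
    """Compare pretumor and tumor abundances per minigene.

    Replicates are averaged arithmetically on the abundance scale; the
    pseudocount defaults to 1/(2 x max total mapped reads) across samples.
    ``per_animal`` additionally repeats the comparison of the pre mean
    against each tumor replicate separately.
    """
    pre_tables = [pre] if isinstance(pre, AbundanceTable) else list(pre)
    post_tables = [post] if isinstance(post, AbundanceTable) else list(post)
    if not pre_tables or not post_tables:
        raise DeconvolutionError("need at least one replicate on each side")
    pre_mean = _mean_abundance(pre_tables)
    post_mean = _mean_abundance(post_tables)
    if set(pre_mean.index) != set(post_mean.index):
        raise DeconvolutionError("pre and post tables cover different libraries")
    post_mean = post_mean.reindex(pre_mean.index)
    eps = (
        pseudocount
        if pseudocount is not None
        else _default_pseudocount(pre_tables + post_tables)
    )
    table = _compare(pre_mean, post_mean, eps, span, lfc_threshold, floor)
    animals: dict[str, pd.DataFrame] = {}
    if per_animal:
        for t in post_tables:
            animals[t.sample] = _compare(
                pre_mean, t.abundance.reindex(pre_mean.index), eps, span,
                lfc_threshold, floor,
            )
    return ScreenComparison(
        table=table,
        pseudocount=eps,
        span=span,
        lfc_threshold=lfc_threshold,
        floor=floor,
        per_animal=animals,
    )


def read_count_tsv(path: str | Path, sample: str | None = None) -> CountTable:
    """Read a pre-counted ``minigene<TAB>count`` table."""
    frame = pd.read_csv(path, sep="\t")
    if not {"minigene", "count"} <= set(frame.columns):
        raise DeconvolutionError(f"{path} must have columns 'minigene' and 'count'")
    return CountTable(
        sample=sample or Path(path).stem,
        counts=pd.Series(frame["count"].values, index=frame["minigene"].values),
    )


def write_abundance_tsv(table: AbundanceTable, path: str | Path) -> None:
    out = table.abundance.rename("abundance").rename_axis("minigene").reset_index()
    out.to_csv(path, sep="\t", index=False)


def write_comparison_tsv(comparison: ScreenComparison, path: str | Path) -> None:
    comparison.table.rename_axis("minigene").reset_index().to_csv(
        path, sep="\t", index=False
    )
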