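"""Synthetic inputs for the whole pipeline.

Everything the analysis consumes can be generated here with the
statistical structure the analysis assumes: random proteomes, Poisson
transduction, pooled screens passed through the real bottlenecks
(injection sampling, antigen-specific survival gated by clonal fraction,
growth, sequencing sampling), two-colour mixture experiments, and
amplicon FASTQ with substitution errors.

Generative assumptions (not biology): antigen-specific depletion acts as
a per-minigene survival multiplier applied ONLY when the minigene's
realised inoculum fraction reaches its clonal-fraction threshold;
stochastic drop-out of rare clones is not an explicit rule but emerges
from the multinomial injection bottleneck. The default strong-antigen
effect is near-complete elimination (log10 FC -2.5) above the threshold,
matching the qualitative fate of immunogenic subclones in bulk mixtures.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .affinity import CANONICAL_RESIDUES
from .clonal import MixtureExperiment
from .deconvolve import AbundanceTable, CountTable
from .design import Proteome
from .encoding import OligoPool

logger = logging.getLogger(__name__)

#: Default inoculum (cells injected per mouse).
DEFAULT_INOCULUM = 5_000_000

#: Observed pre-injection abundance range: ~1 cell per 5e6 up to ~0.5%.
DEFAULT_ABUNDANCE_RANGE = (2e-7, 5e-3)

#: Default effect of a strongly immunogenic antigen above its threshold
#: (log10 fold change; ~300-fold loss, i.e. near-complete elimination).
DEFAULT_KILL_LOG10FC = -2.5

DEFAULT_MOUSE_NOISE_SD = 0.2
DEFAULT_N_MICE = 4
DEFAULT_FRACTIONS = (50.0, 10.0, 1.0, 0.1)

#: Tumor rejection rule: rejected when surviving cells < this fraction of
#: the inoculum.
DEFAULT_REJECT_BELOW = 0.01


class SimulationError(ValueError):
    pass


def simulate_proteome(
    n_proteins: int = 60,
    length: int | Callable[[np.random.Generator], int] = 400,
    seed: int = 0,
    composition: Mapping[str, float] | None = None,
) -> Proteome:
    """Random protein sequences with i.i.d. residues.

    ``length`` may be a constant or a callable drawing a length from an
    rng. ``composition`` maps residues to weights (uniform by default).
    Deterministic under ``seed``.
    """
    if n_proteins < 1:
        raise SimulationError("n_proteins must be >= 1")
    rng = np.random.default_rng(seed)
    residues = list(CANONICAL_RESIDUES)
    if composition is None:
        probs = np.full(len(residues), 1.0 / len(residues))
    else:
        probs = np.array([composition.get(aa, 0.0) for aa in residues], dtype=float)
        if probs.sum() <= 0:
            raise SimulationError("composition has no positive weights")
        probs = probs / probs.sum()
    records = []
    for i in range(n_proteins):
        n = length(rng) if callable(length) else int(length)
        seq = "".join(rng.choice(residues, size=n, p=probs))
        records.append((f"synprot{i:05d}", seq))
    return Proteome(records=tuple(records), source=f"simulated(seed={seed})")


@dataclass(frozen=True)
class TransductionSummary:
    """Poisson integration statistics at a given MOI."""

    moi: float
    integrations_per_cell: np.ndarray
    fraction_transduced: float
    fraction_multi_among_transduced: float
    expected_fraction_multi: float


def expected_multi_integration_fraction(moi: float) -> float:
    """Closed-form fraction of transduced cells with >1 integration:
    (1 - e^-m - m e^-m) / (1 - e^-m)."""
    if moi <= 0:
        raise SimulationError("moi must be positive")
    em = math.exp(-moi)
    return (1.0 - em - moi * em) / (1.0 - em)


def simulate_transduction(
    library_size: int,
    moi: float = 0.3,
    n_cells: int = 100_000,
    seed: int = 0,
) -> TransductionSummary:
    """Per-cell integration counts under Poisson(MOI) transduction.

    At the screen's MOI (< 0.3) few transduced cells carry more than one
    minigene; the summary reports both the empirical and the closed-form
    multi-integration fraction.
    """
    if moi <= 0:
        raise SimulationError("moi must be positive")
    rng = np.random.default_rng(seed)
    integrations = (
        rng.poisson(moi, size=n_cells) if n_cells > 0 else np.zeros(0, dtype=int)
    )
    transduced = integrations[integrations > 0]
    frac_transduced = transduced.size / n_cells if n_cells else 0.0
    frac_multi = (
        float((transduced > 1).sum() / transduced.size) if transduced.size else 0.0
    )
    return TransductionSummary(
        moi=moi,
        integrations_per_cell=integrations,
        fraction_transduced=frac_transduced,
        fraction_multi_among_transduced=frac_multi,
        expected_fraction_multi=expected_multi_integration_fraction(moi),
    )


@dataclass
class ScreenSimConfig:
    """Conditions of a simulated pooled drop-out screen.

    minigenes: library member keys (peptides).
    pre_abundance: optional fixed pre-injection composition (sums to 1);
        drawn log-uniform over ``abundance_range`` and normalised when
        None, matching the ~4 orders of magnitude observed spread.
    inoculum: cells injected per tumor.
    depletion_effects: per-minigene survival multiplier in [0, 1]
        (1 = no immune effect).
    clonal_fraction_threshold: per-minigene realised inoculum fraction
        below which the survival multiplier is suppressed (set to 1).
    growth_factor: deterministic expansion between survival and harvest.
    sequencing_depth: mapped reads per sample.
    n_pre_replicates / n_tumor_replicates: samples sequenced per side
        (the screens used 3 pretumor samples and 5 tumors).
    """

    minigenes: tuple[str, ...]
    pre_abundance: np.ndarray | None = None
    abundance_range: tuple[float, float] = DEFAULT_ABUNDANCE_RANGE
    inoculum: int = DEFAULT_INOCULUM
    depletion_effects: Mapping[str, float] | None = None
    clonal_fraction_threshold: float | Mapping[str, float] = 0.0
    growth_factor: float = 400.0
    sequencing_depth: int = 1_000_000
    error_rate: float = 0.0
    n_pre_replicates: int = 3
    n_tumor_replicates: int = 5
    seed: int = 0

    def effects_array(self) -> np.ndarray:
        s = np.ones(len(self.minigenes))
        if self.depletion_effects:
            for i, m in enumerate(self.minigenes):
                s[i] = self.depletion_effects.get(m, 1.0)
        if ((s < 0) | (s > 1)).any():
            raise SimulationError("survival multipliers must be in [0, 1]")
        return s

    def thresholds_array(self) -> np.ndarray:
        if isinstance(self.clonal_fraction_threshold, Mapping):
            return np.array(
                [self.clonal_fraction_threshold.get(m, 0.0) for m in self.minigenes]
            )
        return np.full(len(self.minigenes), float(self.clonal_fraction_threshold))


@dataclass
class SimulatedScreen:
    """Truth and emitted observations of one simulated screen."""

    config: ScreenSimConfig
    pre_abundance: pd.Series  # true pre-injection composition
    inoculum_counts: list[pd.Series]  # realised cells per tumor
    post_counts_true: list[pd.Series]  # cells at harvest per tumor
    pre_tables: list[CountTable]  # sequenced pretumor replicates
    tumor_tables: list[CountTable]  # sequenced tumor replicates

    def pre_abundance_tables(self) -> list[AbundanceTable]:
        from .deconvolve import relative_abundance

        return [relative_abundance(t) for t in self.pre_tables]

    def tumor_abundance_tables(self) -> list[AbundanceTable]:
        from .deconvolve import relative_abundance

        return [relative_abundance(t) for t in self.tumor_tables]


def _draw_pre_abundance(config: ScreenSimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.pre_abundance is not None:
        p = np.asarray(config.pre_abundance, dtype=float)
        if p.shape != (len(config.minigenes),):
            raise SimulationError("pre_abundance length does not match minigenes")
        if (p < 0).any() or not math.isclose(p.sum(), 1.0, rel_tol=1e-9):
            raise SimulationError("pre_abundance must be a probability vector")
        return p
    lo, hi = config.abundance_range
    if not (0 < lo < hi):
        raise SimulationError("invalid abundance_range")
    raw = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(config.minigenes)))
    return raw / raw.sum()


def simulate_screen(config: ScreenSimConfig) -> SimulatedScreen:
    """Run the multinomial bottleneck pipeline of a pooled screen.

    Per tumor replicate: (1) the inoculum is a multinomial draw from the
    pre-injection composition (rare clones drop out here by sampling
    alone); (2) each minigene's cells survive independently with its
    survival multiplier — applied only when the realised inoculum fraction
    reaches its clonal-fraction threshold; (3) survivors expand by a
    common growth factor; (4) sequencing draws ``sequencing_depth`` reads
    multinomially from the harvested composition. Pretumor replicates are
    direct sequencing draws from the pre-injection composition.
    Reproducible under ``config.seed``.
    """
    if not config.minigenes:
        raise SimulationError("no minigenes")
    rng = np.random.default_rng(config.seed)
    names = list(config.minigenes)
    p_pre = _draw_pre_abundance(config, rng)
    s = config.effects_array()
    thr = config.thresholds_array()

    pre_tables = [
        CountTable(
            sample=f"pretumor_{r}",
            counts=pd.Series(
                rng.multinomial(config.sequencing_depth, p_pre), index=names
            ),
        )
        for r in range(config.n_pre_replicates)
    ]

    inoc_list, post_true, tumor_tables = [], [], []
    for r in range(config.n_tumor_replicates):
        inoc = rng.multinomial(config.inoculum, p_pre)
        frac = inoc / config.inoculum
        s_eff = np.where(frac >= thr, s, 1.0)
        survivors = rng.binomial(inoc, s_eff)
        grown = survivors * config.growth_factor
        total = grown.sum()
        if total <= 0:
            raise SimulationError(f"tumor replicate {r}: no surviving cells")
        reads = rng.multinomial(config.sequencing_depth, grown / total)
        inoc_list.append(pd.Series(inoc, index=names))
        post_true.append(pd.Series(grown, index=names))
        tumor_tables.append(
            CountTable(sample=f"tumor_{r}", counts=pd.Series(reads, index=names))
        )
    return SimulatedScreen(
        config=config,
        pre_abundance=pd.Series(p_pre, index=names),
        inoculum_counts=inoc_list,
        post_counts_true=post_true,
        pre_tables=pre_tables,
        tumor_tables=tumor_tables,
    )


def simulate_two_color(
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    threshold: float = 1.0,
    kill_log10fc: float = DEFAULT_KILL_LOG10FC,
    mouse_noise_sd: float = DEFAULT_MOUSE_NOISE_SD,
    n_mice: int = DEFAULT_N_MICE,
    reject_below: float = DEFAULT_REJECT_BELOW,
    seed: int = 0,
    antigen: str = "synthetic-antigen",
) -> MixtureExperiment:
    """Generate a two-colour mixture experiment with a known threshold.

    Per mouse at intended eGFP fraction f (%): the measured log10 fold
    change is Normal(kill_log10fc * 1[f >= threshold], mouse_noise_sd^2);
    tumor colour percentages are reconstructed from it (eGFP = f * FC,
    clipped to [0, 100], mCherry the complement). A tumor is emitted as
    rejected when the total surviving cell fraction
    (f * FC + (100 - f)) / 100 falls below ``reject_below``.
    """
    for f in fractions:
        if not 0 < f < 100:
            raise SimulationError("fractions must be in (0, 100)")
    if n_mice < 1:
        raise SimulationError("n_mice must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    mouse = 0
    for f in fractions:
        mu = kill_log10fc if f >= threshold else 0.0
        for _ in range(n_mice):
            x = rng.normal(mu, mouse_noise_sd)
            fc = 10.0 ** x
            egfp_tumor = min(f * fc, 100.0)
            mcherry_tumor = 100.0 - egfp_tumor
            surviving = (f * fc + (100.0 - f)) / 100.0
            rejected = surviving < reject_below
            rows.append(
                (
                    f"mouse{mouse:03d}", f, f, 100.0 - f,
                    egfp_tumor if not rejected else 0.0,
                    mcherry_tumor if not rejected else 0.0,
                    rejected,
                )
            )
            mouse += 1
    records = pd.DataFrame(
        rows,
        columns=[
            "mouse", "fraction_d0_pct", "egfp_d0", "mcherry_d0",
            "egfp_tumor", "mcherry_tumor", "rejected",
        ],
    )
    return MixtureExperiment(antigen=antigen, records=records)


_DNA = np.array(list("ACGT"))


def simulate_reads(
    reference: Mapping[str, str] | OligoPool,
    counts: Mapping[str, int],
    error_rate: float = 0.0,
    read_length: int | None = None,
    seed: int = 0,
    out: str | Path | None = None,
) -> list[tuple[str, str]]:
    """Emit amplicon reads covering the epitope window.

    ``reference`` maps minigene key -> epitope DNA (an :class:`OligoPool`
    is accepted and its epitope map used). Exactly ``counts[key]`` reads
    are emitted per minigene, with i.i.d. per-base substitution errors at
    ``error_rate``. Reads are truncated to ``read_length`` when given.
    Returns (read id, sequence) pairs; with ``out`` also writes FASTQ
    (constant placeholder qualities).
    """
    if isinstance(reference, OligoPool):
        reference = reference.epitopes()
    if not 0 <= error_rate < 1:
        raise SimulationError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    for key in reference:
        n = int(counts.get(key, 0))
        if n < 0:
            raise SimulationError("counts must be non-negative")
        template = reference[key]
        if read_length is not None:
            template = template[:read_length]
        arr = np.array(list(template))
        for i in range(n):
            seq = arr
            if error_rate > 0:
                mask = rng.random(arr.size) < error_rate
                if mask.any():
                    seq = arr.copy()
                    # substitute with a uniformly chosen different base
                    shifts = rng.integers(1, 4, size=int(mask.sum()))
                    base_idx = np.searchsorted(_DNA, seq[mask])
                    seq[mask] = _DNA[(base_idx + shifts) % 4]
            reads.append((f"{key}_{i}", "".join(seq)))
    if out is not None:
        with open(out, "w") as fh:
            for rid, seq in reads:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    return reads


def write_provenance(path: str | Path, seed: int, **params) -> None:
    """Record the config + seed used to generate an artifact."""
    payload = {"seed": seed, **{k: repr(v) for k, v in params.items()}}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
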