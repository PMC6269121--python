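"""Wild-type and single-mutant MHC-I peptide library design.

The screen's libraries are built from a proteome: all unique k-mers (k=8
for H-2Kb) are enumerated, those predicted to bind MHC-I (IC50 < 500 nM)
form the candidate pool, a fixed number (5000 by default) is sampled
uniformly as the wild-type library, and each wild-type member receives a
single random amino-acid substitution that keeps MHC binding and does not
recreate any proteome k-mer. Known immunogenic / non-immunogenic control
peptides are appended. Characterisation statistics summarise how the
mutant library differs from its wild-type partners (affinity shift,
mutated-position spectrum, residue-class transitions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .affinity import CANONICAL_RESIDUES, is_canonical

logger = logging.getLogger(__name__)

# Residue classes used for the substitution-class matrix. A fixed,
# documented convention (three coarse physicochemical groups).
RESIDUE_CLASSES: dict[str, str] = {
    **{aa: "hydrophobic" for aa in "ACFILMPVW"},
    **{aa: "polar" for aa in "GHNQSTY"},
    **{aa: "charged" for aa in "DEKR"},
}
CLASS_NAMES = ("hydrophobic", "polar", "charged")

# Default bins (nM) for the |delta IC50| histogram; the first bin is the
# dedicated "within 100 nM" bin.
DEFAULT_DELTA_BINS = (0.0, 100.0, 250.0, 500.0, 1000.0, float("inf"))


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class Proteome:
    """A set of protein sequences with unique ids."""

    records: tuple[tuple[str, str], ...]
    source: str | None = None

    def __post_init__(self) -> None:
        ids = [pid for pid, _ in self.records]
        if len(set(ids)) != len(ids):
            raise DesignError("proteome ids are not unique")
        for pid, seq in self.records:
            if not seq:
                raise DesignError(f"protein {pid} has an empty sequence")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Proteome":
        records = tuple(
            (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
        )
        return cls(records=records, source=str(path))

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for pid, seq in self.records:
                fh.write(f">{pid}\n{seq}\n")

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class LibraryDesignConfig:
    """Parameters of the library design.

    k: peptide length (8 for H-2Kb).
    n_select: wild-type library size.
    ic50_threshold: binder cut in nM, strict '<'.
    seed: master seed; the design is reproducible given it.
    max_mutation_attempts: rejection-sampling budget per peptide.
    exhaustive_mutation: enumerate admissible single-residue neighbours and
        pick uniformly instead of rejection sampling (deterministic search
        space; still seeded for the uniform pick).
    forbid_scope: "proteome" forbids mutants matching any proteome k-mer;
        "library" only forbids members of the wild-type library.
    """

    k: int = 8
    n_select: int = 5000
    ic50_threshold: float = 500.0
    seed: int = 0
    max_mutation_attempts: int = 200
    exhaustive_mutation: bool = False
    forbid_scope: str = "proteome"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise DesignError("k must be >= 2")
        if self.n_select < 1:
            raise DesignError("n_select must be >= 1")
        if not self.ic50_threshold > 0:
            raise DesignError("ic50_threshold must be positive")
        if self.forbid_scope not in ("proteome", "library"):
            raise DesignError("forbid_scope must be 'proteome' or 'library'")


@dataclass(frozen=True)
class PeptideRecord:
    """A library member with provenance.

    role is one of wild_type / mutant / control_immunogenic /
    control_nonimmunogenic. For mutants, ``partner`` is the paired
    wild-type peptide and ``mutated_position`` the 1-based substituted
    position.
    """

    peptide: str
    ic50: float | None = None
    role: str = "wild_type"
    partner: str | None = None
    mutated_position: int | None = None
    protein_id: str | None = None
    start: int | None = None  # 0-based start of first occurrence

    def __post_init__(self) -> None:
        if self.role == "mutant":
            if self.partner is None or self.mutated_position is None:
                raise DesignError("mutant records need partner and mutated_position")
            diffs = [
                i + 1
                for i, (a, b) in enumerate(zip(self.peptide, self.partner))
                if a != b
            ]
            if len(self.peptide) != len(self.partner) or diffs != [self.mutated_position]:
                raise DesignError(
                    f"mutant {self.peptide} is not a single substitution of "
                    f"{self.partner} at position {self.mutated_position}"
                )


# Control peptides named in the source screens: three known immunogenic
# and five known non-immunogenic H-2Kb ligands.
DEFAULT_CONTROLS: tuple[PeptideRecord, ...] = tuple(
    [
        PeptideRecord(p, role="control_immunogenic")
        for p in ("SIINFEKL", "SNFVFAGI", "VTFVFAGL")
    ]
    + [
        PeptideRecord(p, role="control_nonimmunogenic")
        for p in ("MSIIFFLPL", "FEKIILSN", "EQYKFYSV", "SNFVSAGI", "TWHRYHLL")
    ]
)


def enumerate_kmers(proteome: Proteome, k: int) -> dict[str, tuple[str, int]]:
    """All unique k-mers of a proteome, with first-occurrence provenance.

    Returns ``{peptide: (protein_id, start)}`` with 0-based starts. k-mers
    containing non-canonical residues (B, J, O, U, X, Z...) are excluded.
    """
    if k < 2:
        raise DesignError("k must be >= 2")
    if len(proteome) == 0:
        raise DesignError("proteome is empty")
    out: dict[str, tuple[str, int]] = {}
    for pid, seq in proteome.records:
        for start in range(len(seq) - k + 1):
            pep = seq[start : start + k]
            if pep not in out and is_canonical(pep):
                out[pep] = (pid, start)
    return out


def select_wildtype_library(
    kmers: Mapping[str, tuple[str, int]] | Iterable[str],
    affinities: Mapping[str, float],
    config: LibraryDesignConfig = LibraryDesignConfig(),
) -> list[PeptideRecord]:
    """Sample the wild-type library from the binder-filtered k-mer pool.

    Exactly ``config.n_select`` peptides with IC50 < threshold, sampled
    uniformly without replacement under ``config.seed``. Candidates are
    sorted before sampling so the selection is invariant to input order.
    """
    provenance: Mapping[str, tuple[str, int]]
    if isinstance(kmers, Mapping):
        provenance = kmers
        peptides = list(kmers)
    else:
        peptides = list(kmers)
        provenance = {}
    binders = sorted(
        p
        for p in peptides
        if p in affinities and affinities[p] < config.ic50_threshold
    )
    if len(binders) < config.n_select:
        raise DesignError(
            f"only {len(binders)} binders available, need n_select={config.n_select}"
        )
    rng = np.random.default_rng(config.seed)
    chosen = rng.choice(len(binders), size=config.n_select, replace=False)
    records = []
    for i in sorted(chosen):
        pep = binders[i]
        pid, start = provenance.get(pep, (None, None))
        records.append(
            PeptideRecord(
                pep, ic50=affinities[pep], role="wild_type", protein_id=pid, start=start
            )
        )
    return records


def mutate_peptide(
    wild_type: str,
    forbidden: frozenset[str] | set[str],
    ic50_of: Callable[[str], float],
    config: LibraryDesignConfig = LibraryDesignConfig(),
    rng: np.random.Generator | None = None,
) -> PeptideRecord | None:
    """Single random amino-acid substitution that keeps MHC binding.

    Position (1..k) and replacement residue (19 alternatives) are drawn
    uniformly with rejection resampling; a candidate is rejected when it is
    in ``forbidden`` or fails the binder cut. Returns None (caller flags
    the peptide unmutable) when no admissible mutant is found within
    ``max_mutation_attempts`` (or, in exhaustive mode, when the full
    neighbourhood is inadmissible).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    k = len(wild_type)

    def admissible(candidate: str) -> bool:
        return candidate not in forbidden and ic50_of(candidate) < config.ic50_threshold

    def record(candidate: str, pos0: int) -> PeptideRecord:
        return PeptideRecord(
            candidate,
            ic50=ic50_of(candidate),
            role="mutant",
            partner=wild_type,
            mutated_position=pos0 + 1,
        )

    if config.exhaustive_mutation:
        neighbours = [
            (wild_type[:i] + aa + wild_type[i + 1 :], i)
            for i in range(k)
            for aa in CANONICAL_RESIDUES
            if aa != wild_type[i]
        ]
        ok = [(c, i) for c, i in neighbours if admissible(c)]
        if not ok:
            return None
        c, i = ok[rng.integers(len(ok))]
        return record(c, i)

    for _ in range(config.max_mutation_attempts):
        i = int(rng.integers(k))
        alternatives = [aa for aa in CANONICAL_RESIDUES if aa != wild_type[i]]
        aa = alternatives[int(rng.integers(len(alternatives)))]
        candidate = wild_type[:i] + aa + wild_type[i + 1 :]
        if admissible(candidate):
            return record(candidate, i)
    return None


def build_mutant_library(
    wildtype_library: Sequence[PeptideRecord],
    proteome_kmers: Iterable[str],
    ic50_of: Callable[[str], float],
    config: LibraryDesignConfig = LibraryDesignConfig(),
) -> tuple[list[PeptideRecord], list[str]]:
    """One admissible single-residue mutant per wild-type peptide.

    Mutants may not recreate any forbidden peptide: every proteome k-mer
    under the default scope ("a mutation that generates a self peptide is
    not a neoantigen"), or just the wild-type library under
    ``forbid_scope="library"``. Mutants are also kept mutually distinct.
    Returns ``(mutants, unmutable)`` where ``unmutable`` lists wild-type
    peptides for which no admissible mutant was found.
    """
    if not wildtype_library:
        raise DesignError("wild-type library is empty")
    wt_peptides = {r.peptide for r in wildtype_library}
    base_forbidden = (
        set(proteome_kmers) | wt_peptides
        if config.forbid_scope == "proteome"
        else set(wt_peptides)
    )
    rng = np.random.default_rng(config.seed)
    mutants: list[PeptideRecord] = []
    taken: set[str] = set()
    unmutable: list[str] = []
    for rec in sorted(wildtype_library, key=lambda r: r.peptide):
        mut = mutate_peptide(
            rec.peptide, frozenset(base_forbidden | taken), ic50_of, config, rng
        )
        if mut is None:
            unmutable.append(rec.peptide)
            logger.info("no admissible mutant for %s; excluded", rec.peptide)
        else:
            mutants.append(mut)
            taken.add(mut.peptide)
    if unmutable:
        logger.warning("%d wild-type peptides were unmutable", len(unmutable))
    return mutants, unmutable


def add_controls(
    library: Sequence[PeptideRecord],
    controls: Sequence[PeptideRecord] = DEFAULT_CONTROLS,
) -> list[PeptideRecord]:
    """Append control peptides to a library.

    Controls may differ in length from library members (the screens carry
    9-mer controls in 8-mer libraries) but must not duplicate an existing
    peptide.
    """
    existing = {r.peptide for r in library}
    out = list(library)
    for ctl in controls:
        if ctl.role not in ("control_immunogenic", "control_nonimmunogenic"):
            raise DesignError(f"{ctl.peptide}: control role must be a control_* role")
        if ctl.peptide in existing:
            raise DesignError(f"control {ctl.peptide} duplicates a library peptide")
        existing.add(ctl.peptide)
        out.append(ctl)
    return out


@dataclass(frozen=True)
class LibraryCharacterization:
    """Summary statistics of the mutant library vs its wild-type partners."""

    affinity_delta_histogram: pd.Series  # counts per |delta IC50| bin
    position_histogram: pd.Series  # counts per 1-based mutated position
    substitution_class_matrix: pd.DataFrame  # (from class) x (to class) counts
    delta_bins: tuple[float, ...] = DEFAULT_DELTA_BINS

    @property
    def n_mutants(self) -> int:
        return int(self.position_histogram.sum())

    @property
    def fraction_within_100nM(self) -> float:
        total = self.affinity_delta_histogram.sum()
        return float(self.affinity_delta_histogram.iloc[0] / total) if total else 0.0


def characterize_library(
    wildtype_library: Sequence[PeptideRecord],
    mutant_library: Sequence[PeptideRecord],
    delta_bins: Sequence[float] = DEFAULT_DELTA_BINS,
) -> LibraryCharacterization:
    """Histogram the mutant library's affinity shifts, positions and classes.

    The first |delta IC50| bin is the "within 100 nM of the wild-type
    partner" bin by default. Histogram totals equal the mutant count.
    """
    wt_ic50 = {r.peptide: r.ic50 for r in wildtype_library}
    k = max((len(r.peptide) for r in wildtype_library), default=0)
    deltas = []
    positions = []
    transitions = []
    for mut in mutant_library:
        if mut.partner not in wt_ic50:
            raise DesignError(f"mutant {mut.peptide} has no wild-type partner in library")
        deltas.append(abs(mut.ic50 - wt_ic50[mut.partner]))
        positions.append(mut.mutated_position)
        pos0 = mut.mutated_position - 1
        transitions.append(
            (RESIDUE_CLASSES[mut.partner[pos0]], RESIDUE_CLASSES[mut.peptide[pos0]])
        )
    edges = list(delta_bins)
    labels = [
        f"[{lo:g}, {hi:g})" for lo, hi in zip(edges[:-1], edges[1:])
    ]
    counts, _ = np.histogram(deltas, bins=edges) if deltas else (
        np.zeros(len(labels), dtype=int),
        None,
    )
    delta_hist = pd.Series(counts, index=labels, name="count")
    pos_hist = pd.Series(
        np.bincount(positions, minlength=k + 1)[1:] if positions else np.zeros(k, dtype=int),
        index=pd.RangeIndex(1, k + 1, name="position"),
        name="count",
    )
    matrix = pd.DataFrame(0, index=list(CLASS_NAMES), columns=list(CLASS_NAMES))
    for frm, to in transitions:
        matrix.loc[frm, to] += 1
    return LibraryCharacterization(
        affinity_delta_histogram=delta_hist,
        position_histogram=pos_hist,
        substitution_class_matrix=matrix,
        delta_bins=tuple(delta_bins),
    )


def library_to_frame(library: Sequence[PeptideRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.peptide, r.role, r.partner, r.mutated_position, r.ic50, r.protein_id, r.start)
            for r in library
        ],
        columns=[
            "peptide", "role", "partner", "mutated_position", "ic50_nM",
            "protein_id", "start",
        ],
    )


def write_library_tsv(library: Sequence[PeptideRecord], path: str | Path) -> None:
    library_to_frame(library).to_csv(path, sep="\t", index=False)


def read_library_tsv(path: str | Path) -> list[PeptideRecord]:
    frame = pd.read_csv(path, sep="\t")
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            PeptideRecord(
                peptide=row.peptide,
                ic50=None if pd.isna(row.ic50_nM) else float(row.ic50_nM),
                role=row.role,
                partner=None if pd.isna(row.partner) else row.partner,
                mutated_position=(
                    None if pd.isna(row.mutated_position) else int(row.mutated_position)
                ),
                protein_id=None if pd.isna(row.protein_id) else row.protein_id,
                start=None if pd.isna(row.start) else int(row.start),
            )
        )
    return out


def write_peptides_fasta(library: Sequence[PeptideRecord], path: str | Path) -> None:
    """Plain peptide-per-record FASTA for hand-off to an external predictor."""
    with open(path, "w") as fh:
        for i, rec in enumerate(library):
            fh.write(f">{rec.role}_{i}\n{rec.peptide}\n")
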