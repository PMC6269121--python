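"""PresentER minigene oligo encoding.

Each library peptide is encoded as a DNA minigene: an ER signal-sequence
CDS, the reverse-translated epitope, and a stop codon, flanked by SfiI
cloning sites and amplification adapters. Because the epitope DNA is the
only variable region, the peptide doubles as its own sequencing barcode —
which is why encodings must be unique and free of internal SfiI sites.

Codon choice is the highest-frequency mouse codon per residue, with a
seeded fallback to synonymous codons whenever a forbidden motif (the
degenerate 13-bp SfiI site by default) would arise, including at the
junctions with the fixed flanks.
"""

from __future__ import annotations

import logging
import re
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

# Highest-frequency mouse codon per residue.
PREFERRED_CODON: dict[str, str] = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "CGG",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}

# All synonymous codons per residue (standard genetic code).
SYNONYMOUS_CODONS: dict[str, tuple[str, ...]] = {
    "A": ("GCC", "GCT", "GCA", "GCG"),
    "C": ("TGC", "TGT"),
    "D": ("GAC", "GAT"),
    "E": ("GAG", "GAA"),
    "F": ("TTC", "TTT"),
    "G": ("GGC", "GGT", "GGA", "GGG"),
    "H": ("CAC", "CAT"),
    "I": ("ATC", "ATT", "ATA"),
    "K": ("AAG", "AAA"),
    "L": ("CTG", "CTC", "CTT", "CTA", "TTG", "TTA"),
    "M": ("ATG",),
    "N": ("AAC", "AAT"),
    "P": ("CCC", "CCT", "CCA", "CCG"),
    "Q": ("CAG", "CAA"),
    "R": ("CGG", "CGC", "CGT", "CGA", "AGG", "AGA"),
    "S": ("AGC", "TCC", "TCT", "TCA", "TCG", "AGT"),
    "T": ("ACC", "ACT", "ACA", "ACG"),
    "V": ("GTG", "GTC", "GTT", "GTA"),
    "W": ("TGG",),
    "Y": ("TAC", "TAT"),
}

#: Degenerate SfiI recognition site, GGCCNNNNNGGCC. The site class is its
#: own reverse complement, so scanning the top strand covers both strands.
SFII_PATTERN = r"GGCC[ACGT]{5}GGCC"
DEFAULT_FORBIDDEN_MOTIFS = (SFII_PATTERN,)

DEFAULT_STOP_CODON = "TAA"

# Generic T3 / T7 promoter-primer amplification adapters (the cloning
# scheme amplifies the pool with T3_SfiI / T7_SfiI primers; exact vendor
# primers are config-overridable).
DEFAULT_ADAPTER_5P = "ATTAACCCTCACTAAAGGGA"
DEFAULT_ADAPTER_3P = "TAATACGACTCACTATAGGG"

# Concrete SfiI sites used as cloning flanks (N5 spacers chosen arbitrarily
# and fixed).
DEFAULT_SFII_5P = "GGCCAGTTTGGCC"
DEFAULT_SFII_3P = "GGCCTGACTGGCC"

# Placeholder ER signal-sequence CDS (a generic secretion signal peptide,
# MKTIIALSYIFCLVFA, in preferred mouse codons). The production construct's
# exact signal sequence is not bundled; users supply it via config.
DEFAULT_SIGNAL_DNA = (
    "ATGAAGACCATCATCGCCCTGAGCTACATCTTCTGCCTGGTGTTCGCC"
)


class EncodingError(ValueError):
    pass


def translate(dna: str) -> str:
    """Translate a CDS (no stop handling: '*' is returned for stops)."""
    return str(Seq(dna).translate())


def find_motifs(seq: str, motifs: Sequence[str] = DEFAULT_FORBIDDEN_MOTIFS) -> list[tuple[int, int]]:
    """(start, end) spans of every forbidden-motif match, overlapping included."""
    spans = []
    for motif in motifs:
        pat = re.compile(f"(?=({motif}))")
        for m in pat.finditer(seq):
            spans.append((m.start(1), m.end(1)))
    return sorted(spans)


def reverse_translate(
    peptide: str,
    codon_table: Mapping[str, str] | None = None,
    forbidden_motifs: Sequence[str] = DEFAULT_FORBIDDEN_MOTIFS,
    seed: int = 0,
    flank_5p: str = "",
    flank_3p: str = "",
    max_rounds: int = 500,
) -> str:
    """Reverse-translate ``peptide`` avoiding forbidden motifs.

    Starts from the preferred codon for every residue and, while the
    encoding (checked in context: ``flank_5p + dna + flank_3p``) contains a
    forbidden motif, re-draws a synonymous codon for a residue overlapping
    the first match. Deterministic given ``seed``.
    """
    table = dict(PREFERRED_CODON if codon_table is None else codon_table)
    for aa in peptide:
        if aa not in table:
            raise EncodingError(f"no codon for residue {aa!r}")
    rng = np.random.default_rng(seed)
    codons = [table[aa] for aa in peptide]
    for _ in range(max_rounds):
        dna = "".join(codons)
        spans = find_motifs(flank_5p + dna + flank_3p, forbidden_motifs)
        if not spans:
            return dna
        start, end = spans[0]
        # codon indices overlapping the first motif occurrence
        lo = max(0, (start - len(flank_5p)) // 3)
        hi = min(len(peptide) - 1, (end - 1 - len(flank_5p)) // 3)
        idx = [i for i in range(lo, hi + 1) if len(SYNONYMOUS_CODONS[peptide[i]]) > 1]
        if not idx:
            break
        i = idx[int(rng.integers(len(idx)))]
        options = [c for c in SYNONYMOUS_CODONS[peptide[i]] if c != codons[i]]
        codons[i] = options[int(rng.integers(len(options)))]
    raise EncodingError(
        f"could not find a motif-free encoding for peptide {peptide!r}"
    )


@dataclass(frozen=True)
class Minigene:
    """DNA encoding of one library peptide.

    full_insert = signal-sequence CDS + epitope DNA + stop codon;
    oligo = 5' adapter + SfiI site + full_insert + SfiI site + 3' adapter.
    """

    peptide: str
    epitope_dna: str
    full_insert: str
    oligo: str

    def __post_init__(self) -> None:
        if translate(self.epitope_dna) != self.peptide:
            raise EncodingError(
                f"epitope DNA does not translate to {self.peptide!r}"
            )


def _validate_signal(signal_dna: str) -> None:
    if not signal_dna.startswith("ATG"):
        raise EncodingError("signal sequence CDS must start with ATG")
    if len(signal_dna) % 3 != 0:
        raise EncodingError("signal sequence CDS length must be a multiple of 3")
    if "*" in translate(signal_dna):
        raise EncodingError("signal sequence CDS contains an internal stop")


def build_minigene(
    peptide: str,
    signal_dna: str = DEFAULT_SIGNAL_DNA,
    adapter_5p: str = DEFAULT_ADAPTER_5P,
    adapter_3p: str = DEFAULT_ADAPTER_3P,
    sfii_5p: str = DEFAULT_SFII_5P,
    sfii_3p: str = DEFAULT_SFII_3P,
    codon_table: Mapping[str, str] | None = None,
    stop_codon: str = DEFAULT_STOP_CODON,
    seed: int = 0,
) -> Minigene:
    """Encode one peptide as a complete minigene oligo.

    The epitope encoding is chosen so that the finished oligo contains
    exactly the two intended SfiI sites (the flanks) and no others.
    """
    _validate_signal(signal_dna)
    left = adapter_5p + sfii_5p + signal_dna
    right = stop_codon + sfii_3p + adapter_3p
    # The flanks each contain one intended SfiI site; the epitope and its
    # junctions must not add more. Pass only 12 bp of flanking context to
    # reverse_translate (one short of the 13-bp motif) so the intended
    # sites are invisible while any junction-spanning motif is still seen.
    epitope = reverse_translate(
        peptide,
        codon_table=codon_table,
        seed=seed,
        flank_5p=left[len(adapter_5p) + len(sfii_5p) - 12:],
        flank_3p=right[: len(stop_codon) + 12],
    )
    oligo = left + epitope + right
    n_sites = len(find_motifs(oligo, (SFII_PATTERN,)))
    if n_sites != 2:
        raise EncodingError(
            f"oligo for {peptide!r} contains {n_sites} SfiI sites (expected 2)"
        )
    return Minigene(
        peptide=peptide,
        epitope_dna=epitope,
        full_insert=signal_dna + epitope + stop_codon,
        oligo=oligo,
    )


@dataclass(frozen=True)
class OligoPool:
    """A set of minigenes sharing adapters."""

    minigenes: tuple[Minigene, ...]
    adapter_5p: str = DEFAULT_ADAPTER_5P
    adapter_3p: str = DEFAULT_ADAPTER_3P
    metadata: tuple[tuple[str, str], ...] = ()

    def __len__(self) -> int:
        return len(self.minigenes)

    def epitopes(self) -> dict[str, str]:
        """peptide -> epitope DNA mapping."""
        return {m.peptide: m.epitope_dna for m in self.minigenes}


def _peptide_seed(peptide: str, seed: int) -> int:
    # stable per-peptide sub-seed, independent of pool order
    return (zlib.crc32(peptide.encode()) ^ seed) & 0x7FFFFFFF


def build_pool(
    peptides: Iterable[str],
    seed: int = 0,
    **minigene_kwargs,
) -> OligoPool:
    """Build an oligo pool, one minigene per unique peptide.

    Each peptide's codon draws are seeded from a CRC of the peptide XOR the
    master seed, so permuting the input permutes the output identically.
    """
    minigenes = []
    seen = set()
    for pep in peptides:
        if pep in seen:
            raise EncodingError(f"duplicate peptide in pool input: {pep}")
        seen.add(pep)
        minigenes.append(
            build_minigene(pep, seed=_peptide_seed(pep, seed), **minigene_kwargs)
        )
    return OligoPool(
        minigenes=tuple(minigenes),
        adapter_5p=minigene_kwargs.get("adapter_5p", DEFAULT_ADAPTER_5P),
        adapter_3p=minigene_kwargs.get("adapter_3p", DEFAULT_ADAPTER_3P),
        metadata=(("seed", str(seed)),),
    )


def digest_sfii(oligo: str) -> list[str]:
    """In-silico SfiI digestion (top strand).

    SfiI cuts GGCCNNNN^NGGCC on the top strand, leaving 3-nt 3' overhangs;
    fragments are returned 5'->3' with the cut after position +8 of each
    site.
    """
    cut_points = [start + 8 for start, _ in find_motifs(oligo, (SFII_PATTERN,))]
    fragments = []
    prev = 0
    for cp in cut_points:
        fragments.append(oligo[prev:cp])
        prev = cp
    fragments.append(oligo[prev:])
    return fragments


@dataclass(frozen=True)
class PoolQC:
    """Report from validate_pool; hard violations make a pool unusable."""

    n_minigenes: int
    duplicate_epitopes: tuple[str, ...]
    oligos_with_wrong_sfii_count: tuple[str, ...]
    length_distribution: dict[int, int]
    min_pairwise_hamming: int | None  # informational (barcode confusability)

    @property
    def hard_violations(self) -> bool:
        return bool(self.duplicate_epitopes or self.oligos_with_wrong_sfii_count)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def validate_pool(pool: OligoPool, max_pairwise: int = 2000) -> PoolQC:
    """QC a pool: duplicate encodings, stray SfiI sites, lengths, min
    pairwise Hamming distance between same-length epitope encodings.

    The pairwise scan is quadratic and is capped at ``max_pairwise``
    encodings (a uniform subsample beyond that).
    """
    if len(pool) == 0:
        raise EncodingError("pool is empty")
    seen: dict[str, str] = {}
    duplicates = []
    wrong_sfii = []
    lengths: dict[int, int] = {}
    for m in pool.minigenes:
        if m.epitope_dna in seen:
            duplicates.append(m.peptide)
        seen.setdefault(m.epitope_dna, m.peptide)
        if len(find_motifs(m.oligo, (SFII_PATTERN,))) != 2:
            wrong_sfii.append(m.peptide)
        lengths[len(m.oligo)] = lengths.get(len(m.oligo), 0) + 1
    encodings = [m.epitope_dna for m in pool.minigenes]
    if len(encodings) > max_pairwise:
        step = len(encodings) // max_pairwise + 1
        encodings = encodings[::step]
    by_len: dict[int, list[str]] = {}
    for e in encodings:
        by_len.setdefault(len(e), []).append(e)
    min_d: int | None = None
    for group in by_len.values():
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                d = hamming(group[i], group[j])
                if min_d is None or d < min_d:
                    min_d = d
    return PoolQC(
        n_minigenes=len(pool),
        duplicate_epitopes=tuple(duplicates),
        oligos_with_wrong_sfii_count=tuple(wrong_sfii),
        length_distribution=lengths,
        min_pairwise_hamming=min_d,
    )


def write_pool_fasta(pool: OligoPool, path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in pool.minigenes:
            fh.write(f">{m.peptide}\n{m.oligo}\n")


def write_pool_manifest(pool: OligoPool, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [(m.peptide, m.epitope_dna, m.oligo, len(m.oligo)) for m in pool.minigenes],
        columns=["peptide", "epitope_dna", "oligo", "length"],
    ).to_csv(path, sep="\t", index=False)
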