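"""Per-gene sequence covariates: residue frequencies, CAI, start-window folding energy.

The codon adaptation index (CAI) follows the Sharp & Li definition: relative
adaptiveness ``w`` of each codon is its count in a highly expressed reference
set (ribosomal-protein genes, supplied by the user as an id list) divided by
the count of the most used synonymous codon, and a gene's CAI is the
geometric mean of ``w`` over its codons.  In the default ``sharp-li`` dialect
the single-codon amino acids (Met/ATG, Trp/TGG) and stop codons are excluded
from the mean; the ``emboss`` dialect keeps Met and Trp, as the EMBOSS ``cai``
program does.

The folding-energy covariate is the minimum free energy of the 42-nt window
spanning positions -4..+38 around the translation start (no position 0; +1 is
the first nucleotide of the start codon).  Energy evaluation is pluggable: a
callable engine (a ViennaRNA wrapper is provided) or a table of precomputed
energies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "ProteinRecord",
    "CodonUsageTable",
    "GeneStartWindow",
    "aa_frequencies",
    "protein_record",
    "build_codon_usage",
    "cai",
    "gene_start_window",
    "folding_energy",
    "vienna_mfe",
    "CANONICAL_AA",
]

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")

_STANDARD_TABLE = unambiguous_dna_by_id[1]
STOP_CODONS = set(_STANDARD_TABLE.stop_codons)
#: codon -> amino acid for the standard genetic code
CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
#: amino acid -> synonymous codons
SYNONYMOUS: dict[str, list[str]] = {}
for _codon, _aa in CODON_TO_AA.items():
    SYNONYMOUS.setdefault(_aa, []).append(_codon)

#: relative adaptiveness assigned to reference-unseen codons so the geometric
#: mean never collapses to zero
PSEUDO_WEIGHT = 0.01

WINDOW_UPSTREAM = 4
WINDOW_DOWNSTREAM = 38
WINDOW_LENGTH = WINDOW_UPSTREAM + WINDOW_DOWNSTREAM  # 42


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str
    aa_freq: dict[str, float]


@dataclass(frozen=True)
class GeneStartWindow:
    gene_id: str
    window_sequence: str
    folding_energy: float | None = None

    def __post_init__(self) -> None:
        if len(self.window_sequence) != WINDOW_LENGTH:
            raise ValueError(
                f"start window must be {WINDOW_LENGTH} nt, got {len(self.window_sequence)}"
            )


def aa_frequencies(sequence: str, alphabet: set[str] | None = None, strict: bool = True) -> dict[str, float]:
    """Residue frequencies (counts/length) of a protein sequence.

    A trailing stop symbol ``*`` is stripped.  Letters outside ``alphabet``
    (default: the 20 canonical residues) raise in strict mode and are dropped
    with the remainder renormalised otherwise.
    """
    if alphabet is None:
        alphabet = CANONICAL_AA
    seq = sequence.upper().rstrip("*")
    if not seq:
        raise ValueError("empty protein sequence")
    bad = sorted(set(seq) - alphabet)
    if bad:
        if strict:
            raise ValueError(f"non-canonical residue(s) {bad} in sequence")
        seq = "".join(c for c in seq if c in alphabet)
        if not seq:
            raise ValueError("no canonical residues left after dropping non-canonical ones")
    n = len(seq)
    freq: dict[str, float] = {}
    for c in seq:
        freq[c] = freq.get(c, 0.0) + 1.0
    return {c: k / n for c, k in freq.items()}


def protein_record(
    pid: str, sequence: str, alphabet: set[str] | None = None, strict: bool = True
) -> ProteinRecord:
    seq = sequence.upper().rstrip("*")
    return ProteinRecord(id=pid, sequence=seq, aa_freq=aa_frequencies(seq, alphabet, strict))


# ---------------------------------------------------------------------------
# codon usage and CAI
# ---------------------------------------------------------------------------


@dataclass
class CodonUsageTable:
    """Codon counts over a reference set and the derived relative adaptiveness.

    ``w[codon] = count / max count among its synonymous codons``; for every
    amino acid the most used codon has ``w = 1``.  Codons unseen in the
    reference get :data:`PSEUDO_WEIGHT`.
    """

    counts: dict[str, int]
    w: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        w: dict[str, float] = {}
        for aa, codons in SYNONYMOUS.items():
            m = max(self.counts.get(c, 0) for c in codons)
            for c in codons:
                if m == 0:
                    w[c] = 1.0  # amino acid absent from reference: uninformative
                else:
                    ratio = self.counts.get(c, 0) / m
                    w[c] = ratio if ratio > 0 else PSEUDO_WEIGHT
        self.w = w


def _codons(cds: str, strict_stops: bool = True) -> list[str]:
    seq = cds.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} not divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    if strict_stops and any(c in STOP_CODONS for c in codons):
        raise ValueError("internal stop codon in CDS")
    return codons


def build_codon_usage(reference_cds: list[str]) -> CodonUsageTable:
    """Aggregate codon counts over a highly expressed reference set."""
    if not reference_cds:
        raise ValueError("empty reference CDS set")
    counts: dict[str, int] = {}
    for cds in reference_cds:
        for c in _codons(cds):
            if c in CODON_TO_AA:
                counts[c] = counts.get(c, 0) + 1
    return CodonUsageTable(counts=counts)


def cai(cds: str, table: CodonUsageTable, dialect: str = "sharp-li") -> float:
    """Codon adaptation index: geometric mean of relative adaptiveness.

    ``sharp-li`` excludes Met, Trp and stop codons from the mean; ``emboss``
    keeps Met and Trp.
    """
    if dialect not in ("sharp-li", "emboss"):
        raise ValueError(f"unknown CAI dialect {dialect!r}")
    excluded = {"ATG", "TGG"} if dialect == "sharp-li" else set()
    log_sum, n = 0.0, 0
    for c in _codons(cds):
        if c in excluded or c not in CODON_TO_AA:
            continue
        log_sum += math.log(table.w[c])
        n += 1
    if n == 0:
        raise ValueError("no codons left after exclusions; CDS too short")
    return math.exp(log_sum / n)


# ---------------------------------------------------------------------------
# folding-energy window at the gene start
# ---------------------------------------------------------------------------


def gene_start_window(
    gene_id: str, genomic_context: str, start_offset: int
) -> GeneStartWindow | None:
    """Extract the 42-nt window -4..+38 around a translation start.

    ``start_offset`` is the 1-based position of the first nucleotide of the
    start codon in ``genomic_context`` (plus-strand, strand already resolved
    by the caller).  Returns ``None`` when fewer than 4 nt upstream or 38 nt
    of CDS are available (missing-value contract).
    """
    seq = genomic_context.upper().replace("U", "T")
    if start_offset < 1 or start_offset > len(seq):
        return None
    begin = start_offset - 1 - WINDOW_UPSTREAM  # 0-based
    end = start_offset - 1 + WINDOW_DOWNSTREAM
    if begin < 0 or end > len(seq):
        return None
    return GeneStartWindow(gene_id=gene_id, window_sequence=seq[begin:end])


def vienna_mfe(sequence: str) -> float:
    """Minimum free energy (kcal/mol) of a sequence via the ViennaRNA bindings."""
    import RNA

    _, mfe = RNA.fold(sequence)
    return float(mfe)


def folding_energy(
    window: GeneStartWindow,
    engine=None,
    table: dict[str, float] | None = None,
) -> float | None:
    """Folding energy of a start window: pluggable engine or precomputed table.

    The table (gene_id -> kcal/mol) takes precedence; with neither available
    the value is missing (``None``) and the pipeline continues.
    """
    if table is not None and window.gene_id in table:
        return float(table[window.gene_id])
    if engine is not None:
        return float(engine(window.window_sequence))
    return None
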