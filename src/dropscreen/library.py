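"""Degenerate-codon peptide libraries and their DNA templates.

A peptide scaffold (default the 12-mer MDM2 binder PMI, ``TSFAEYWNLLSP``)
is randomized at a small set of positions using degenerate codons such as
NNK (N = A/C/G/T, K = G/T).  NNK encodes all 20 amino acids in 32 codons
and admits exactly one stop codon, amber TAG.  On the antisense strand the
same scheme is written MNN (M = A/C); expansion always complements back to
the sense frame first.

The module enumerates the peptide-level variant space (e.g. 20^3 = 8000
variants for three NNK positions), groups synonymous codon combinations
("genotypes") per peptide, and materializes full-length expression
templates — upstream flank (T7 promoter context), the coding region with
variable codons substituted, and a downstream flank (DNA-binding-domain
fusion stub plus terminator context).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

__all__ = [
    "DegenerateCodon",
    "LibraryDesign",
    "PeptideVariant",
    "expand_degenerate_codon",
    "translate_codon",
    "enumerate_library",
    "expected_variant_frequency",
    "build_template",
    "write_templates_fasta",
    "variant_table",
]

STOP = "*"

#: IUPAC ambiguity code -> set of concrete bases (unambiguous codes map to
#: themselves; U is not accepted — inputs are DNA).
IUPAC_BASES: Mapping[str, frozenset[str]] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items()
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "X": "X",
}


def _validate_iupac(symbols: str) -> None:
    for ch in symbols:
        if ch not in IUPAC_BASES:
            raise ValueError(f"invalid IUPAC nucleotide code: {ch!r}")


@dataclass(frozen=True)
class DegenerateCodon:
    """A degenerate codon, e.g. NNK (sense) or its antisense form MNN.

    Parameters
    ----------
    symbols : str
        Three IUPAC nucleotide codes.
    orientation : {"sense", "antisense"}
        Antisense codons are reverse-complemented to the sense frame
        before expansion, so ``DegenerateCodon("MNN", "antisense")``
        denotes the same codon set as ``DegenerateCodon("NNK")``.
    """

    symbols: str = "NNK"
    orientation: str = "sense"

    def __post_init__(self) -> None:
        if len(self.symbols) != 3:
            raise ValueError("a codon has exactly three symbols")
        _validate_iupac(self.symbols)
        if self.orientation not in ("sense", "antisense"):
            raise ValueError(f"unknown orientation: {self.orientation!r}")

    def to_sense(self) -> "DegenerateCodon":
        if self.orientation == "sense":
            return self
        sense = "".join(_COMPLEMENT[ch] for ch in reversed(self.symbols))
        return DegenerateCodon(sense, "sense")


def expand_degenerate_codon(codon: DegenerateCodon | str) -> set[str]:
    """Expand a degenerate codon into its set of concrete codons.

    The result is the cartesian product of the per-position base sets;
    NNK expands to 4 x 4 x 2 = 32 codons.  Antisense input is converted
    to the sense frame first, so MNN (antisense) equals NNK (sense).
    """
    if isinstance(codon, str):
        codon = DegenerateCodon(codon)
    sense = codon.to_sense()
    sets = [sorted(IUPAC_BASES[ch]) for ch in sense.symbols]
    return {"".join(bases) for bases in itertools.product(*sets)}


# standard genetic code, built once from Biopython
_CODON_TABLE: dict[str, str] = {
    (c := a + b + d): str(Seq(c).translate(table=1))
    for a in "ACGT"
    for b in "ACGT"
    for d in "ACGT"
}


def translate_codon(codon: str) -> str:
    """Translate one concrete codon with the standard genetic code.

    Returns the one-letter amino acid, or ``"*"`` for a stop codon.
    """
    aa = _CODON_TABLE.get(codon) or _CODON_TABLE.get(codon.upper())
    if aa is None:
        raise ValueError(f"not an unambiguous DNA codon: {codon!r}")
    return aa


# -- default design -------------------------------------------------------

#: Codon-optimized CDS for the PMI scaffold TSFAEYWNLLSP, one codon per
#: residue.  The source construct's coding sequence is not published; these are common
#: E. coli codons and are a synthetic stand-in (any synonymous choice gives
#: the same peptide space).
DEFAULT_SCAFFOLD_CODONS: tuple[str, ...] = (
    "ACC",  # T
    "AGC",  # S
    "TTT",  # F
    "GCG",  # A
    "GAA",  # E
    "TAT",  # Y
    "TGG",  # W
    "AAC",  # N
    "CTG",  # L
    "TTG",  # L
    "AGT",  # S
    "CCG",  # P
)

#: T7 promoter with a short 5' UTR context (synthetic placeholder; the
#: real construct's flanks are not printed in the source protocol).
DEFAULT_UPSTREAM = (
    "TAATACGACTCACTATAGGGAGACCACAACGGTTTCCCTCTAGAAATAATTTTGTTTAACTTTAAGAAGGAGATATACAT"
)

#: 3' flank: start of the DNA-binding-domain fusion plus terminator
#: context, a 100-nt synthetic stub.
DEFAULT_DOWNSTREAM = (
    "GGTGGCTCTGGTGGCAGCATGAAACTGCTGAGCAGCATTGAACAGGCATGCGATATTTGCCGTCTGAAAAAACTGAAATGCAGCAAAGAAAAACCGAAAT"
)


@dataclass(frozen=True)
class LibraryDesign:
    """A scaffold peptide with degenerate codons at chosen positions.

    ``variable_positions`` are 1-based indices into the peptide; the
    default (3, 7, 10) randomizes the hydrophobic triad F3/W7/L10 of
    TSFAEYWNLLSP, the three residues critical for MDM2 binding.
    """

    scaffold_peptide: str = "TSFAEYWNLLSP"
    variable_positions: tuple[int, ...] = (3, 7, 10)
    codon_scheme: tuple[DegenerateCodon, ...] = (
        DegenerateCodon("NNK"),
        DegenerateCodon("NNK"),
        DegenerateCodon("NNK"),
    )
    scaffold_codons: tuple[str, ...] = DEFAULT_SCAFFOLD_CODONS
    upstream: str = DEFAULT_UPSTREAM
    downstream: str = DEFAULT_DOWNSTREAM

    def __post_init__(self) -> None:
        n = len(self.scaffold_peptide)
        if len(self.scaffold_codons) != n:
            raise ValueError("one scaffold codon per peptide residue required")
        if len(set(self.variable_positions)) != len(self.variable_positions):
            raise ValueError("variable positions must be distinct")
        for p in self.variable_positions:
            if not 1 <= p <= n:
                raise ValueError(f"variable position {p} outside peptide 1..{n}")
        if len(self.codon_scheme) != len(self.variable_positions):
            raise ValueError("one degenerate codon per variable position required")
        for aa, codon in zip(self.scaffold_peptide, self.scaffold_codons):
            if translate_codon(codon) != aa:
                raise ValueError(
                    f"scaffold codon {codon} does not encode residue {aa}"
                )

    # expansion of each variable position, cached lazily
    def position_codon_tables(self) -> list[dict[str, str]]:
        """Per variable position: concrete codon -> encoded amino acid."""
        return [
            {c: translate_codon(c) for c in sorted(expand_degenerate_codon(dc))}
            for dc in self.codon_scheme
        ]

    @property
    def n_variants(self) -> int:
        """Number of stop-free peptide variants (20^3 = 8000 for 3 x NNK)."""
        count = 1
        for table in self.position_codon_tables():
            count *= len({aa for aa in table.values() if aa != STOP})
        return count


@dataclass(frozen=True)
class PeptideVariant:
    """One peptide in the variant space with its encoding genotypes."""

    residues: str
    full_peptide: str
    genotypes: tuple[tuple[str, ...], ...]
    affinity_class: str = "low"
    kd_nm: float | None = None

    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)


def apply_residues(design: LibraryDesign, residues: str) -> str:
    """Substitute variable-position residues into the scaffold peptide."""
    peptide = list(design.scaffold_peptide)
    for pos, aa in zip(design.variable_positions, residues):
        peptide[pos - 1] = aa
    return "".join(peptide)


def enumerate_library(
    design: LibraryDesign,
    high_affinity: Mapping[str, float] | Iterable[str] = (),
) -> list[PeptideVariant]:
    """Enumerate all stop-free peptide variants of a design.

    Every combination of concrete codons at the variable positions is
    expanded and translated; combinations containing a stop codon are
    dropped at the peptide level (they remain countable at the codon
    level via the position tables).  Synonymous codon combinations are
    grouped under one :class:`PeptideVariant`.  Output is ordered
    lexicographically by residue string for reproducible indexing.

    ``high_affinity`` marks selected residue combinations (e.g. ``{"FWL":
    3.2}`` with a Kd in nM, or just ``["FWL"]``) as the screen's
    signal-positive binders.
    """
    if isinstance(high_affinity, Mapping):
        kd_map = dict(high_affinity)
    else:
        kd_map = {r: None for r in high_affinity}

    tables = design.position_codon_tables()
    # per position: amino acid -> codons encoding it (stop excluded)
    by_aa: list[dict[str, list[str]]] = []
    for table in tables:
        m: dict[str, list[str]] = {}
        for codon, aa in table.items():
            if aa != STOP:
                m.setdefault(aa, []).append(codon)
        by_aa.append(m)

    variants: list[PeptideVariant] = []
    for combo in itertools.product(*[sorted(m) for m in by_aa]):
        residues = "".join(combo)
        genotypes = tuple(
            itertools.product(*[by_aa[i][aa] for i, aa in enumerate(combo)])
        )
        is_high = residues in kd_map
        variants.append(
            PeptideVariant(
                residues=residues,
                full_peptide=apply_residues(design, residues),
                genotypes=genotypes,
                affinity_class="high" if is_high else "low",
                kd_nm=kd_map.get(residues),
            )
        )
    return variants


def expected_variant_frequency(design: LibraryDesign, residues: str) -> float:
    """Expected frequency of a residue combination under uniform synthesis.

    Assumes every concrete codon of the degenerate scheme is synthesized
    at equal molarity and stop-containing combinations are excluded from
    the peptide pool: the frequency is (number of codon combinations
    encoding ``residues``) / (total stop-free combinations).  Returns 0
    with a warning for unencodable residues.
    """
    if len(residues) != len(design.variable_positions):
        raise ValueError(
            "residues length must equal the number of variable positions"
        )
    tables = design.position_codon_tables()
    total_nonstop = 1
    encoding = 1
    for aa, table in zip(residues, tables):
        nonstop = [c for c, a in table.items() if a != STOP]
        total_nonstop *= len(nonstop)
        n_enc = sum(1 for c in nonstop if table[c] == aa)
        if n_enc == 0:
            warnings.warn(
                f"residue {aa!r} is not encodable under the codon scheme",
                stacklevel=2,
            )
            return 0.0
        encoding *= n_enc
    return encoding / total_nonstop


def cds_offset_of_position(design: LibraryDesign, position: int) -> int:
    """Nucleotide offset of a peptide position's codon within the CDS."""
    return 3 * (position - 1)


def build_cds(design: LibraryDesign, genotype: Sequence[str]) -> str:
    """The peptide coding sequence with variable codons substituted."""
    codons = list(design.scaffold_codons)
    for pos, codon in zip(design.variable_positions, genotype):
        codons[pos - 1] = codon
    return "".join(codons)


def build_template(design: LibraryDesign, genotype: Sequence[str]) -> str:
    """Full-length DNA template: upstream flank + CDS + downstream flank.

    All templates of one design have equal length because the flanks are
    fixed and every codon is 3 nt.
    """
    for codon in genotype:
        if len(codon) != 3 or any(b not in "ACGT" for b in codon):
            raise ValueError(f"invalid genotype codon: {codon!r}")
    return design.upstream + build_cds(design, genotype) + design.downstream


def write_templates_fasta(
    design: LibraryDesign, variants: Sequence[PeptideVariant], path
) -> int:
    """Write one FASTA record per genotype, ID ``peptide|codon-codon-codon``.

    Returns the number of records written.
    """
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = []
    for v in variants:
        for genotype in v.genotypes:
            records.append(
                SeqRecord(
                    Seq(build_template(design, genotype)),
                    id=f"{v.residues}|{'-'.join(genotype)}",
                    description="",
                )
            )
    return seqio_write(records, str(path), "fasta")


def variant_table(design: LibraryDesign, variants: Sequence[PeptideVariant]):
    """Variant summary as a DataFrame (peptide, genotype count, expected
    frequency under uniform synthesis)."""
    import pandas as pd

    tables = design.position_codon_tables()
    total_nonstop = 1
    for table in tables:
        total_nonstop *= sum(1 for a in table.values() if a != STOP)
    return pd.DataFrame(
        {
            "peptide": [v.residues for v in variants],
            "full_peptide": [v.full_peptide for v in variants],
            "n_genotypes": [v.n_genotypes for v in variants],
            "expected_frequency": [
                v.n_genotypes / total_nonstop for v in variants
            ],
            "affinity_class": [v.affinity_class for v in variants],
        }
    )
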