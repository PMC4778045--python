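"""RT-PCR amplification bias and short amplicon reads from sorted pools.

A sorted drop pool contains two genotype-bearing molecule classes: the
DNA templates loaded at encapsulation and stray mRNAs transcribed before
encapsulation ("leaked").  An expressed drop holds on the order of
hundreds of mRNA copies per DNA template, so when the pool is amplified
by RT-PCR a template contributes ~``transcripts_per_template`` molecules
while a leaked transcript contributes one.  Per-genotype amplification
efficiency is log-normal (one collapsed RT+PCR bias stage), which spreads
the observed frequencies of background sequences over a wide range, as
seen in real bright-pool sequencing data.

Reads are fixed-length (56 bp) windows of the template covering all
variable codons, with i.i.d. substitution errors and a Phred quality
profile that decays toward the 3' end so some tail bases fall below Q20
and quality trimming has real work to do.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .library import LibraryDesign, PeptideVariant, build_template, cds_offset_of_position
from .screen import SortResult

__all__ = [
    "AmplificationModel",
    "ReadConfig",
    "ReadPool",
    "pool_molecule_counts",
    "amplify_pool",
    "simulate_reads",
    "write_fastq",
    "read_window_offset",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class AmplificationModel:
    """One-stage RT-PCR bias model.

    ``transcripts_per_template`` is the mean number of mRNA copies made
    from one DNA template during in-drop expression (order hundreds); it
    sets the weight of a template relative to a single leaked transcript.
    ``efficiency_sd`` is the SD of the per-genotype log-normal
    amplification efficiency (0 = unbiased).  ``cycles`` is metadata.
    """

    transcripts_per_template: float = 300.0
    efficiency_sd: float = 0.5
    cycles: int = 25

    def __post_init__(self) -> None:
        if self.transcripts_per_template < 1:
            raise ValueError("transcripts_per_template must be >= 1")
        if self.efficiency_sd < 0:
            raise ValueError("efficiency_sd must be >= 0")


@dataclass(frozen=True)
class ReadConfig:
    """Amplicon read layout and error model."""

    read_length: int = 56
    window_offset: int | None = None  # template offset of the read window
    error_rate: float = 0.001
    base_quality: int = 35
    decay_start: int = 40  # 3' position where quality starts decaying
    decay_rate: float = 0.15  # exponential decay per base past decay_start
    quality_sd: float = 3.0
    adapter: str = ""  # optional adapter suffix appended when window runs short


def read_window_offset(design: LibraryDesign, read_length: int = 56) -> int:
    """Template offset of the read window covering all variable codons.

    The window is centered on the variable span of the CDS so that every
    randomized codon plus flanking constant anchors fit in one read.
    """
    first = cds_offset_of_position(design, min(design.variable_positions))
    last = cds_offset_of_position(design, max(design.variable_positions)) + 3
    span = last - first
    if span > read_length:
        raise ValueError("variable codons do not fit in one read")
    margin = (read_length - span) // 2
    offset = len(design.upstream) + first - margin
    return max(0, offset)


def pool_molecule_counts(
    sort_result: SortResult, pool: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant (template_count, leaked_count) tallies for one pool."""
    pop = sort_result.population
    drops = sort_result.pool_indices(pool)
    n_var = len(pop.high_affinity_mask)
    in_pool = np.zeros(pop.n_drops, dtype=bool)
    in_pool[drops] = True

    def tally(values: np.ndarray, offsets: np.ndarray) -> np.ndarray:
        per_drop = np.diff(offsets)
        mask = np.repeat(in_pool, per_drop)
        return np.bincount(values[mask], minlength=n_var)

    return (
        tally(pop.template_values, pop.template_offsets),
        tally(pop.leaked_values, pop.leaked_offsets),
    )


def amplify_pool(
    sort_result: SortResult,
    model: AmplificationModel,
    pool: str = "bright",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-variant post-amplification abundance (a probability vector).

    abundance(v) ∝ (templates(v) * transcripts_per_template + leaked(v))
    x LogNormal(0, efficiency_sd), normalized to sum to 1.  An empty pool
    returns an all-zero vector with a warning.
    """
    if rng is None:
        rng = np.random.default_rng()
    t_counts, l_counts = pool_molecule_counts(sort_result, pool)
    weights = t_counts * model.transcripts_per_template + l_counts
    if weights.sum() == 0:
        warnings.warn(f"pool {pool!r} contains no genotype-bearing molecules")
        return np.zeros_like(weights, dtype=float)
    if model.efficiency_sd > 0:
        bias = rng.lognormal(0.0, model.efficiency_sd, size=len(weights))
    else:
        bias = np.ones(len(weights))
    w = weights * bias
    return w / w.sum()


@dataclass
class ReadPool:
    """Simulated amplicon reads with Phred qualities for one pool."""

    pool_label: str
    reads: list[str]
    qualities: list[np.ndarray]  # Phred scores per base
    read_length: int
    source_variant: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def __len__(self) -> int:
        return len(self.reads)


def simulate_reads(
    abundances: np.ndarray,
    design: LibraryDesign,
    variants: list[PeptideVariant] | tuple[PeptideVariant, ...],
    n_reads: int,
    config: ReadConfig = ReadConfig(),
    pool_label: str = "input",
    rng: np.random.Generator | None = None,
) -> ReadPool:
    """Draw ``n_reads`` amplicon reads multinomially from abundances.

    Each read is the fixed window of its source template (a genotype
    drawn uniformly among the variant's synonymous codon combinations),
    with i.i.d. substitution errors at ``config.error_rate`` and a Phred
    profile that is flat at ``base_quality`` then decays exponentially
    past ``decay_start`` so the 3' tail dips below Q20.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_reads == 0:
        return ReadPool(pool_label, [], [], config.read_length)
    abundances = np.asarray(abundances, dtype=float)
    if not np.isclose(abundances.sum(), 1.0, atol=1e-6):
        raise ValueError("abundances must be normalized")

    offset = (
        config.window_offset
        if config.window_offset is not None
        else read_window_offset(design, config.read_length)
    )
    counts = rng.multinomial(n_reads, abundances)
    source = np.repeat(np.arange(len(abundances)), counts)
    rng.shuffle(source)

    # constant part of the window plus the variable-codon column indices
    ref_window = build_template(design, variants[0].genotypes[0])[
        offset : offset + config.read_length
    ]
    base = np.frombuffer(ref_window.encode(), dtype=np.uint8)
    slot_cols = []
    from .library import cds_offset_of_position

    # genotype codon i belongs to variable_positions[i]; keep design order
    for p in design.variable_positions:
        col = len(design.upstream) + cds_offset_of_position(design, p) - offset
        slot_cols.append(col)

    mat = np.tile(base, (n_reads, 1))
    # fill variable codons per read: genotype drawn uniformly per variant
    for vi in np.unique(source):
        rows = np.flatnonzero(source == vi)
        v = variants[vi]
        geno = np.array(
            [[ord(b) for codon in g for b in codon] for g in v.genotypes],
            dtype=np.uint8,
        )  # (n_genotypes, 3 * n_slots)
        picks = rng.integers(len(v.genotypes), size=len(rows))
        chosen = geno[picks]
        for si, col in enumerate(slot_cols):
            mat[rows, col : col + 3] = chosen[:, 3 * si : 3 * si + 3]

    if config.error_rate > 0:
        err = rng.random(mat.shape) < config.error_rate
        n_err = int(err.sum())
        if n_err:
            lut = np.zeros(256, dtype=np.uint8)
            for b, i in _BASE_INDEX.items():
                lut[ord(b)] = i
            shift = rng.integers(1, 4, size=n_err)
            mat[err] = _BASES[(lut[mat[err]] + shift) % 4]

    # quality: flat at base_quality, exponential 3' decay below Q20 tail
    pos = np.arange(config.read_length)
    decay = np.exp(-config.decay_rate * np.maximum(0, pos - config.decay_start))
    mean_q = 2 + (config.base_quality - 2) * decay
    qmat = np.clip(
        np.rint(rng.normal(mean_q, config.quality_sd, size=mat.shape)), 2, 41
    ).astype(np.int64)

    reads = [row.tobytes().decode() for row in mat]
    quals = list(qmat)
    return ReadPool(pool_label, reads, quals, config.read_length, source)


def write_fastq(pool: ReadPool, path) -> int:
    """Write a pool as Phred+33 FASTQ (4-line records); returns read count."""
    with open(path, "w") as fh:
        for i, (seq, q) in enumerate(zip(pool.reads, pool.qualities)):
            qstr = "".join(chr(33 + int(x)) for x in q)
            fh.write(f"@{pool.pool_label}_{i}\n{seq}\n+\n{qstr}\n")
    return len(pool.reads)


def read_fastq(path) -> tuple[list[str], list[np.ndarray]]:
    """Read a Phred+33 FASTQ into (sequences, quality arrays)."""
    from Bio import SeqIO

    seqs: list[str] = []
    quals: list[np.ndarray] = []
    for rec in SeqIO.parse(str(path), "fastq"):
        seqs.append(str(rec.seq))
        quals.append(np.array(rec.letter_annotations["phred_quality"], dtype=np.int64))
    return seqs, quals
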