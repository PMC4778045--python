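"""Deep-sequencing analysis of sorted-drop amplicon pools.

The pipeline mirrors a standard amplicon screen readout: 3' adapter and
quality trimming, anchor-guided extraction of the randomized codons,
translation, per-pool frequency tables (joint over the variable positions
and marginal per position), genotype-per-phenotype diversity, and
fold-enrichment of each peptide in the bright pool over the unsorted
input, with a bootstrap confidence interval standing in for a
significance test.

Quality trimming uses the running-sum algorithm: subtract the cutoff from
each Phred score and cut at the position that minimizes the partial sum
from the 3' end.  This is the behavior of standard adapter-trimming tools
and, unlike "cut at the first base < Q20", tolerates isolated low-quality
bases inside an otherwise good read.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import LibraryDesign, translate_codon
from .reads import ReadConfig, read_window_offset

__all__ = [
    "ExtractionSyntax",
    "FrequencyTable",
    "EnrichmentTable",
    "trim_read",
    "trim_batch",
    "extract_codons",
    "extract_batch",
    "tabulate",
    "enrichment",
    "enrichment_significance",
    "syntax_for_design",
]

REJECT_REASONS = ("anchor_mismatch", "truncated", "ambiguous", "empty")


def trim_read(
    seq: str,
    qualities: np.ndarray | list[int],
    adapter: str = "",
    q_cutoff: int = 20,
    adapter_max_mismatches: int = 0,
) -> tuple[str, np.ndarray]:
    """3'-trim a read: adapter suffix first, then low-quality tail.

    The adapter is removed when it matches a suffix of the read (within
    ``adapter_max_mismatches`` substitutions); partial 3' occurrences of
    the adapter's prefix are also removed, as happens when the insert is
    shorter than the read.  Quality trimming then subtracts ``q_cutoff``
    from each Phred score and cuts at the position minimizing the partial
    sum taken from the 3' end (the running-sum algorithm).  Never
    lengthens a read; trimming twice equals trimming once.
    """
    q = np.asarray(qualities, dtype=np.int64)
    if len(seq) != len(q):
        raise ValueError("sequence and quality lengths differ")

    if adapter:
        n, m = len(seq), len(adapter)
        # longest adapter prefix matching a read suffix, full match first
        for alen in range(min(n, m), 0, -1):
            tail = seq[n - alen :]
            mism = sum(a != b for a, b in zip(tail, adapter[:alen]))
            if mism <= adapter_max_mismatches:
                seq, q = seq[: n - alen], q[: n - alen]
                break

    # running-sum 3' quality trim
    best_pos = len(seq)  # cut point (keep seq[:best_pos])
    running = 0
    best = 0
    for i in range(len(seq) - 1, -1, -1):
        running += int(q[i]) - q_cutoff
        if running < best:
            best = running
            best_pos = i
    return seq[:best_pos], q[:best_pos]


def trim_batch(
    qmat: np.ndarray, q_cutoff: int = 20
) -> np.ndarray:
    """Vectorized running-sum 3' cut positions for equal-length reads.

    Returns, per row of the Phred matrix, the keep-length chosen by the
    same running-sum rule as :func:`trim_read` (no adapter handling).
    """
    qmat = np.asarray(qmat, dtype=np.int64)
    n = qmat.shape[1]
    c = np.cumsum(qmat[:, ::-1] - q_cutoff, axis=1)
    kstar = np.argmin(c, axis=1)  # first occurrence = least trimming
    min_val = c[np.arange(len(qmat)), kstar]
    return np.where(min_val < 0, n - (kstar + 1), n)


@dataclass(frozen=True)
class ExtractionSyntax:
    """Read-region layout: constant anchors separated by 3-nt codon slots.

    ``anchors`` has one more element than there are variable codons; the
    expected read region is ``anchors[0] + slot + anchors[1] + slot + ...
    + anchors[-1]``.  Each anchor may mismatch the read in at most
    ``max_mismatches_per_anchor`` positions (substitutions only).
    """

    anchors: tuple[str, ...]
    max_mismatches_per_anchor: int = 1

    def __post_init__(self) -> None:
        if len(self.anchors) < 2:
            raise ValueError("need at least two anchors (one variable slot)")
        if any(not a for a in self.anchors[1:-1]):
            raise ValueError("internal anchors must be nonempty")

    @property
    def n_slots(self) -> int:
        return len(self.anchors) - 1

    @property
    def region_length(self) -> int:
        return sum(len(a) for a in self.anchors) + 3 * self.n_slots

    def slot_offset(self, i: int) -> int:
        """Offset of variable slot i within the read region."""
        return sum(len(a) for a in self.anchors[: i + 1]) + 3 * i


def syntax_for_design(
    design: LibraryDesign,
    read_config: ReadConfig = ReadConfig(),
    max_mismatches_per_anchor: int = 1,
) -> ExtractionSyntax:
    """Derive the anchor/slot layout from the library design and the
    amplicon read window."""
    from .library import build_template, cds_offset_of_position

    offset = (
        read_config.window_offset
        if read_config.window_offset is not None
        else read_window_offset(design, read_config.read_length)
    )
    template = build_template(design, tuple(
        design.scaffold_codons[p - 1] for p in design.variable_positions
    ))
    window = template[offset : offset + read_config.read_length]
    slots = sorted(
        len(design.upstream) + cds_offset_of_position(design, p) - offset
        for p in design.variable_positions
    )
    anchors = []
    prev = 0
    for s in slots:
        anchors.append(window[prev:s])
        prev = s + 3
    anchors.append(window[prev:])
    return ExtractionSyntax(tuple(anchors), max_mismatches_per_anchor)


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def extract_codons(
    read: str, syntax: ExtractionSyntax
) -> tuple[tuple[str, ...] | None, str | None]:
    """Extract the variable codons from a trimmed read.

    Scans every alignment start of the fixed anchor/slot layout within
    the read; a placement is valid when each anchor matches within
    ``max_mismatches_per_anchor`` substitutions and the read covers the
    full region through the end of the last slot (the trailing anchor
    may be truncated but must match over its covered prefix).  Returns
    ``(codons, None)`` on success, ``(None, reason)`` on rejection with
    reason in {"empty", "truncated", "anchor_mismatch", "ambiguous"}.
    """
    if not read:
        return None, "empty"
    last_slot_end = syntax.slot_offset(syntax.n_slots - 1) + 3
    if len(read) < last_slot_end:
        return None, "truncated"

    placements: list[int] = []
    max_start = len(read) - last_slot_end
    for start in range(max_start + 1):
        ok = True
        pos = start
        for i, anchor in enumerate(syntax.anchors):
            if i == len(syntax.anchors) - 1:
                covered = anchor[: max(0, len(read) - pos)]
            else:
                covered = anchor
                if pos + len(anchor) > len(read):
                    ok = False
                    break
            if _mismatches(read[pos : pos + len(covered)], covered) > syntax.max_mismatches_per_anchor:
                ok = False
                break
            pos += len(anchor)
            if i < syntax.n_slots:
                pos += 3
        if ok:
            placements.append(start)
            if len(placements) > 1:
                return None, "ambiguous"
    if not placements:
        return None, "anchor_mismatch"
    start = placements[0]
    codons = tuple(
        read[start + syntax.slot_offset(i) : start + syntax.slot_offset(i) + 3]
        for i in range(syntax.n_slots)
    )
    return codons, None


def extract_batch(
    reads: list[str], syntax: ExtractionSyntax
) -> tuple[list[tuple[str, ...] | None], list[str | None]]:
    """Vectorized :func:`extract_codons` over a pool of reads.

    Groups reads by length and evaluates every alignment start of the
    anchor/slot layout as matrix comparisons; semantics (mismatch
    tolerance, truncation, ambiguity) are identical to the scalar scan.
    """
    n = len(reads)
    codons_out: list[tuple[str, ...] | None] = [None] * n
    reasons: list[str | None] = [None] * n
    slot_offsets = [syntax.slot_offset(k) for k in range(syntax.n_slots)]
    last_slot_end = slot_offsets[-1] + 3
    anchor_bytes = [
        np.frombuffer(a.encode(), dtype=np.uint8) for a in syntax.anchors
    ]

    by_length: dict[int, list[int]] = {}
    for i, r in enumerate(reads):
        by_length.setdefault(len(r), []).append(i)

    for length, idx in by_length.items():
        if length == 0:
            for i in idx:
                reasons[i] = "empty"
            continue
        if length < last_slot_end:
            for i in idx:
                reasons[i] = "truncated"
            continue
        mat = np.frombuffer(
            "".join(reads[i] for i in idx).encode(), dtype=np.uint8
        ).reshape(len(idx), length)
        n_valid = np.zeros(len(idx), dtype=np.int64)
        first_start = np.full(len(idx), -1, dtype=np.int64)
        for start in range(length - last_slot_end + 1):
            valid = np.ones(len(idx), dtype=bool)
            pos = start
            for ai, anchor in enumerate(anchor_bytes):
                if ai == syntax.n_slots:
                    covered = anchor[: max(0, length - pos)]
                else:
                    if pos + len(anchor) > length:
                        valid[:] = False
                        break
                    covered = anchor
                if len(covered):
                    mism = (
                        mat[:, pos : pos + len(covered)] != covered
                    ).sum(axis=1)
                    valid &= mism <= syntax.max_mismatches_per_anchor
                pos += len(anchor) + (3 if ai < syntax.n_slots else 0)
            first_start = np.where(valid & (first_start < 0), start, first_start)
            n_valid += valid
        for row, i in enumerate(idx):
            if n_valid[row] == 0:
                reasons[i] = "anchor_mismatch"
            elif n_valid[row] > 1:
                reasons[i] = "ambiguous"
            else:
                s = int(first_start[row])
                r = reads[i]
                codons_out[i] = tuple(
                    r[s + off : s + off + 3] for off in slot_offsets
                )
    return codons_out, reasons


@dataclass
class FrequencyTable:
    """Per-pool peptide frequencies from extracted codon tuples.

    ``per_peptide`` maps a residue combination (e.g. ``"FWL"``) to its
    frequency among stop-free reads; ``genotype_diversity`` counts the
    distinct DNA codon combinations observed per peptide; ``per_position``
    gives the amino-acid marginal at each randomized position.
    """

    pool_label: str
    per_peptide: dict[str, float]
    peptide_counts: dict[str, int]
    genotype_diversity: dict[str, int]
    per_position: list[dict[str, float]]
    n_reads_used: int
    n_stop: int
    n_reads_rejected: int = 0
    reject_reasons: Counter = field(default_factory=Counter)

    def frequency(self, peptide: str) -> float:
        return self.per_peptide.get(peptide, 0.0)

    def count(self, peptide: str) -> int:
        return self.peptide_counts.get(peptide, 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "peptide": list(self.per_peptide),
                "pool": self.pool_label,
                "count": [self.peptide_counts[p] for p in self.per_peptide],
                "frequency": list(self.per_peptide.values()),
                "genotype_diversity": [
                    self.genotype_diversity[p] for p in self.per_peptide
                ],
            }
        ).sort_values("frequency", ascending=False, ignore_index=True)

    def position_frame(self) -> pd.DataFrame:
        rows = []
        for i, marg in enumerate(self.per_position, start=1):
            for aa, f in sorted(marg.items()):
                rows.append({"position": i, "amino_acid": aa, "frequency": f})
        return pd.DataFrame(rows)


def tabulate(
    codon_tuples: list[tuple[str, ...]],
    pool_label: str,
    reject_reasons: Counter | None = None,
) -> FrequencyTable:
    """Translate codon tuples and build joint/marginal frequency tables.

    Stop-containing tuples are counted separately (expected under NNK via
    amber TAG) and excluded from peptide frequencies.
    """
    if not codon_tuples:
        raise ValueError("no codon tuples to tabulate")
    n_slots = len(codon_tuples[0])
    pep_counts: Counter = Counter()
    genotype_sets: dict[str, set] = {}
    n_stop = 0
    peptide_cache: dict[tuple[str, ...], str | None] = {}
    for codons in codon_tuples:
        pep = peptide_cache.get(codons, "")
        if pep == "":
            aas = tuple(translate_codon(c) for c in codons)
            pep = None if "*" in aas else "".join(aas)
            peptide_cache[codons] = pep
        if pep is None:
            n_stop += 1
            continue
        pep_counts[pep] += 1
        genotype_sets.setdefault(pep, set()).add(codons)
    used = sum(pep_counts.values())
    per_peptide = {p: c / used for p, c in pep_counts.items()} if used else {}
    per_position: list[dict[str, float]] = []
    for i in range(n_slots):
        marg: Counter = Counter()
        for pep, c in pep_counts.items():
            marg[pep[i]] += c
        per_position.append({aa: c / used for aa, c in marg.items()} if used else {})
    reject_reasons = reject_reasons or Counter()
    return FrequencyTable(
        pool_label=pool_label,
        per_peptide=per_peptide,
        peptide_counts=dict(pep_counts),
        genotype_diversity={p: len(s) for p, s in genotype_sets.items()},
        per_position=per_position,
        n_reads_used=used,
        n_stop=n_stop,
        n_reads_rejected=sum(reject_reasons.values()),
        reject_reasons=reject_reasons,
    )


@dataclass
class EnrichmentTable:
    """Fold-enrichment of each peptide: bright frequency / input frequency."""

    table: pd.DataFrame  # peptide, bright, dark, input, fold, rank, flagged

    def fold(self, peptide: str) -> float:
        row = self.table.loc[self.table["peptide"] == peptide]
        if row.empty:
            raise KeyError(peptide)
        return float(row["fold"].iloc[0])

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.head(n)


def enrichment(
    bright: FrequencyTable,
    input_: FrequencyTable,
    dark: FrequencyTable | None = None,
) -> EnrichmentTable:
    """Fold-enrichment table, ranked descending.

    Peptides absent from the input pool are flagged (fold undefined, NaN)
    rather than divided by zero.
    """
    peptides = sorted(set(bright.per_peptide) | set(input_.per_peptide))
    rows = []
    for p in peptides:
        f_in = input_.frequency(p)
        f_br = bright.frequency(p)
        fold = f_br / f_in if f_in > 0 else float("nan")
        rows.append(
            {
                "peptide": p,
                "bright": f_br,
                "dark": dark.frequency(p) if dark is not None else float("nan"),
                "input": f_in,
                "fold": fold,
                "flagged_no_input": f_in == 0,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        "fold", ascending=False, ignore_index=True, na_position="last"
    )
    df["rank"] = np.where(df["fold"].notna(), np.arange(1, len(df) + 1), -1)
    return EnrichmentTable(df)


def enrichment_significance(
    count_a: int,
    depth_a: int,
    count_b: int,
    depth_b: int,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Percentile-bootstrap CI for the frequency ratio of two pools.

    Resamples each pool's count binomially at its observed frequency and
    depth, forms the ratio ``(a / depth_a) / (b / depth_b)``, and returns
    the (alpha/2, 1 - alpha/2) percentile interval.  ``enriched`` is True
    when the CI excludes 1.  A zero reference count makes the ratio
    undefined.
    """
    if count_b == 0:
        return {
            "ratio": float("nan"),
            "ci_low": float("nan"),
            "ci_high": float("nan"),
            "enriched": False,
            "undefined": True,
        }
    rng = np.random.default_rng(seed)
    boot_a = rng.binomial(depth_a, count_a / depth_a, size=n_boot) / depth_a
    boot_b = rng.binomial(depth_b, count_b / depth_b, size=n_boot) / depth_b
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = boot_a / boot_b
    ratios = ratios[np.isfinite(ratios)]
    lo, hi = np.percentile(ratios, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    ratio = (count_a / depth_a) / (count_b / depth_b)
    return {
        "ratio": float(ratio),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "enriched": bool(lo > 1.0 or hi < 1.0),
        "undefined": False,
    }


def analyze_reads(
    seqs: list[str],
    quals: list[np.ndarray],
    syntax: ExtractionSyntax,
    pool_label: str,
    adapter: str = "",
    q_cutoff: int = 20,
) -> FrequencyTable:
    """Trim, extract and tabulate one pool of reads end to end."""
    tuples: list[tuple[str, ...]] = []
    reasons: Counter = Counter()
    lengths = {len(s) for s in seqs}
    if not adapter and len(lengths) == 1 and seqs:
        # uniform-length, no-adapter pools trim as one matrix
        cuts = trim_batch(np.vstack(quals), q_cutoff)
        trimmed = (s[:c] for s, c in zip(seqs, cuts))
    else:
        trimmed = (
            trim_read(s, q, adapter=adapter, q_cutoff=q_cutoff)[0]
            for s, q in zip(seqs, quals)
        )
    all_codons, all_reasons = extract_batch(list(trimmed), syntax)
    for codons, reason in zip(all_codons, all_reasons):
        if codons is None:
            reasons[reason] += 1
        else:
            tuples.append(codons)
    if not tuples:
        raise ValueError(f"no reads extracted from pool {pool_label!r}")
    return tabulate(tuples, pool_label, reject_reasons=reasons)
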